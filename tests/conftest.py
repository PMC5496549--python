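import numpy as np
import pandas as pd
import pytest

from coralsieve.synthetic_data import ModuleSpec, SimulationConfig, generate_transplant_data


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate_transplant_data(default_config)


@pytest.fixture(scope="session")
def default_fragments(default_dataset):
    return default_dataset[0]


def small_expression_config(seed: int, **overrides) -> SimulationConfig:
    """Compact expression config used by Monte-Carlo tests."""
    defaults = dict(
        n_genes=400,
        module_specs=[
            ModuleSpec(size=110, trait="-survival", corr=0.7),
            ModuleSpec(size=80, trait="growth", corr=0.7),
        ],
        library_size_range=(200_000, 500_000),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def toy_fragment_csv(tmp_path):
    """3-fragment table with hand-checkable growth: 2 g -> 5 g = 150%."""
    path = tmp_path / "fragments.csv"
    path.write_text(
        "fragment_id,colony_id,origin,location,crate_id,fate,"
        "initial_weight,final_weight,branch_count\n"
        "F1,C1,HV,HV,HV1,alive,2.0,5.0,4\n"
        "F2,C1,HV,MV,MV1,dead,3.0,,\n"
        "F3,C2,MV,MV,MV1,missing,4.0,,\n"
    )
    return path


def make_null_fragments(
    rng: np.random.Generator,
    n_colonies_mv: int = 13,
    n_colonies_hv: int = 8,
    n_crates_per_pool: int = 6,
    p_alive=None,
    loss_rate: float = 34.0 / 252.0,
) -> pd.DataFrame:
    """Direct Bernoulli fragment simulator, independent of the package's
    generator — used as the oracle-side data source for calibration runs.

    ``p_alive`` maps colony_id -> survival probability (default 0.6 for
    everyone: the exchangeable null).
    """
    colonies = [f"M{i}" for i in range(n_colonies_mv)] + [
        f"H{i}" for i in range(n_colonies_hv)
    ]
    origin = {c: ("MV" if c.startswith("M") else "HV") for c in colonies}
    if p_alive is None:
        p_alive = {c: 0.6 for c in colonies}
    rows = []
    for pool in ("HV", "MV"):
        for k in range(n_crates_per_pool):
            crate = f"{pool}{k}"
            for c in colonies:
                if rng.random() < loss_rate:
                    fate = "missing"
                else:
                    fate = "alive" if rng.random() < p_alive[c] else "dead"
                rows.append(
                    {
                        "fragment_id": f"{crate}-{c}",
                        "colony_id": c,
                        "origin": origin[c],
                        "location": pool,
                        "crate_id": crate,
                        "fate": fate,
                        "initial_weight": 10.0,
                        "final_weight": 20.0 if fate == "alive" else np.nan,
                        "branch_count": np.nan,
                        "growth": 100.0 if fate == "alive" else np.nan,
                    }
                )
    return pd.DataFrame(rows)
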