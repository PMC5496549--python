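"""Synthetic reciprocal-transplant datasets with known ground truth.

Emulates the study design the pipeline expects: 21 parent colonies (13
MV-origin, 8 HV-origin) fragmented across 12 replicate crates (6 per
pool), with random fragment loss, origin-dependent survival mean and
variance, location-dependent growth, a colony-level survival-growth
trade-off, and negative-binomial count matrices containing planted
coexpressed gene modules whose per-sample factors track the latent
fitness traits.

Every generator is deterministic given ``config.seed``; independent
random streams are derived per generator so stages can be rerun in
isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from coralsieve.io import attach_growth

# stream offsets so each generator gets an independent substream of the seed
_STREAM_TRANSPLANT = 1
_STREAM_EXPRESSION = 2
_STREAM_PANELS = 3
_STREAM_SYMBIONTS = 4


@dataclass(frozen=True)
class ModuleSpec:
    """A planted coexpressed module.

    ``trait`` names the latent colony trait the module's per-sample
    factor follows: ``"survival"``, ``"growth"``, or either prefixed
    with ``-`` for a negated loading.  ``corr`` is the target
    correlation between the module factor (hence its eigengene) and the
    trait.  ``outlier`` plants a module whose variance is carried by a
    single aberrant sample instead of a trait.
    """

    size: int
    trait: str = "survival"
    corr: float = 0.7
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("module size must be positive")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("|corr| must be <= 1")
        base = self.trait.lstrip("-")
        if base not in ("survival", "growth"):
            raise ValueError(f"unknown trait {self.trait!r}")


def _default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec(size=110, trait="-survival", corr=0.7),
        ModuleSpec(size=150, trait="growth", corr=0.7),
        ModuleSpec(size=80, trait="survival", corr=0.0, outlier=True),
        ModuleSpec(size=60, trait="survival", corr=0.0, outlier=True),
        ModuleSpec(size=100, trait="survival", corr=0.0, outlier=True),
    ]


@dataclass
class SimulationConfig:
    n_colonies_mv: int = 13
    n_colonies_hv: int = 8
    n_crates_per_pool: int = 6
    loss_rate: float = 34.0 / 252.0
    survival_logit_mean_by_origin: dict = field(
        default_factory=lambda: {"HV": 1.8, "MV": 0.4}
    )
    survival_logit_sd_by_origin: dict = field(
        default_factory=lambda: {"HV": 0.5, "MV": 1.5}
    )
    crate_sd: float = 0.5
    location_growth_means: dict = field(
        default_factory=lambda: {"HV": 200.0, "MV": 320.0}
    )
    growth_cv: float = 0.4
    growth_crate_sd: float = 0.15  # log-scale crate effect on growth
    survival_growth_corr: float = -0.5
    n_genes: int = 3000
    module_specs: list = field(default_factory=_default_modules)
    nb_dispersion: float = 0.2
    library_size_range: tuple = (450_000, 1_790_000)
    module_effect_size: float = 2.0  # log-scale loading amplitude
    symbiont_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_colonies_mv", "n_colonies_hv", "n_crates_per_pool", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.loss_rate <= 1.0:
            raise ValueError("loss_rate must be a probability in [0, 1]")
        if not -1.0 <= self.survival_growth_corr <= 1.0:
            raise ValueError("|survival_growth_corr| must be <= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        # survival logit means may be +/-inf (degenerate limits); NaN never allowed
        for pool in ("HV", "MV"):
            if math.isnan(self.survival_logit_mean_by_origin[pool]):
                raise ValueError("survival logit means must not be NaN")
            for d in (self.survival_logit_sd_by_origin, self.location_growth_means):
                if not math.isfinite(d[pool]):
                    raise ValueError("config values must be finite")
        for val in (self.crate_sd, self.growth_cv, self.growth_crate_sd):
            if not math.isfinite(val) or val < 0:
                raise ValueError("scale parameters must be finite and non-negative")
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")

    @property
    def colony_ids(self) -> list[str]:
        mv = [f"MVC{i + 1:02d}" for i in range(self.n_colonies_mv)]
        hv = [f"HVC{i + 1:02d}" for i in range(self.n_colonies_hv)]
        return mv + hv

    @property
    def colony_origins(self) -> dict:
        return {
            cid: ("MV" if cid.startswith("MV") else "HV") for cid in self.colony_ids
        }

    @property
    def crate_ids(self) -> list[str]:
        return [
            f"{pool}{i + 1}"
            for pool in ("HV", "MV")
            for i in range(self.n_crates_per_pool)
        ]

    @property
    def crate_locations(self) -> dict:
        return {crid: crid[:2] for crid in self.crate_ids}


@dataclass
class GroundTruth:
    """Latent quantities every simulated outcome derives from."""

    colony_ids: list
    origins: dict  # colony -> pool
    survival_logit: dict  # colony -> s_i, logit units (origin mean excluded)
    growth_pct: dict  # colony -> expected growth in % units
    latent_z: dict  # colony -> (z_survival, z_growth) standard bivariate draw
    crate_survival_effect: dict  # crate -> logit offset
    crate_growth_effect: dict  # crate -> log-scale offset
    gene_modules: dict = field(default_factory=dict)  # gene -> module label (0 = bg)
    gene_signs: dict = field(default_factory=dict)  # gene -> loading sign
    module_factors: dict = field(default_factory=dict)  # label -> per-sample factor
    module_specs: dict = field(default_factory=dict)  # label -> ModuleSpec

    def trait_vector(self, trait: str) -> np.ndarray:
        """Latent trait as a standardized vector over colonies."""
        sign = -1.0 if trait.startswith("-") else 1.0
        idx = 0 if trait.lstrip("-") == "survival" else 1
        z = np.array([self.latent_z[c][idx] for c in self.colony_ids])
        return sign * z

    def to_json(self, path: str | Path) -> None:
        payload = {
            "colony_ids": self.colony_ids,
            "origins": self.origins,
            "survival_logit": self.survival_logit,
            "growth_pct": self.growth_pct,
            "latent_z": {k: list(v) for k, v in self.latent_z.items()},
            "crate_survival_effect": self.crate_survival_effect,
            "crate_growth_effect": self.crate_growth_effect,
            "gene_modules": self.gene_modules,
            "gene_signs": self.gene_signs,
            "module_factors": {str(k): list(v) for k, v in self.module_factors.items()},
            "module_specs": {str(k): asdict(v) for k, v in self.module_specs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def generate_transplant_data(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the fragment-level transplant table.

    One fragment per colony x crate.  Survival is Bernoulli on the
    logistic scale (origin mean + colony latent + crate effect); growth
    is lognormal around the destination-pool mean and defined only for
    survivors; a ``loss_rate`` fraction of fragments goes missing
    completely at random.
    """
    rng = _rng(config, _STREAM_TRANSPLANT)
    colonies = config.colony_ids
    origins = config.colony_origins
    crates = config.crate_ids
    crate_loc = config.crate_locations

    rho = config.survival_growth_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=len(colonies))

    sigma_log = math.sqrt(math.log(1.0 + config.growth_cv**2))
    sigma_colony = sigma_log * math.sqrt(0.5)
    sigma_frag = sigma_log * math.sqrt(0.5)

    survival_logit = {}
    growth_pct = {}
    latent_z = {}
    grand_growth = float(np.mean(list(config.location_growth_means.values())))
    for i, cid in enumerate(colonies):
        sd = config.survival_logit_sd_by_origin[origins[cid]]
        survival_logit[cid] = float(sd * z[i, 0])
        growth_pct[cid] = float(
            grand_growth * math.exp(sigma_colony * z[i, 1] - 0.5 * sigma_colony**2)
        )
        latent_z[cid] = (float(z[i, 0]), float(z[i, 1]))

    crate_surv = {c: float(rng.normal(0.0, config.crate_sd)) for c in crates}
    crate_grow = {c: float(rng.normal(0.0, config.growth_crate_sd)) for c in crates}

    rows = []
    for crate in crates:
        location = crate_loc[crate]
        loc_mean = config.location_growth_means[location]
        for cid in colonies:
            origin = origins[cid]
            eta = (
                config.survival_logit_mean_by_origin[origin]
                + survival_logit[cid]
                + crate_surv[crate]
            )
            p_alive = float(expit(eta))
            alive = rng.random() < p_alive
            missing = rng.random() < config.loss_rate
            initial = float(rng.uniform(5.0, 15.0))
            fate = "missing" if missing else ("alive" if alive else "dead")
            if fate == "alive":
                log_growth = (
                    math.log(loc_mean)
                    + sigma_colony * z[colonies.index(cid), 1]
                    + crate_grow[crate]
                    + sigma_frag * rng.normal()
                    - 0.5 * sigma_frag**2
                    - 0.5 * sigma_colony**2
                )
                growth = math.exp(log_growth)
                final = initial * (1.0 + growth / 100.0)
                branches = int(rng.poisson(3.0 + growth / 100.0))
            else:
                # weight/branches unrecorded for dead or lost fragments
                final = np.nan
                branches = np.nan
            rows.append(
                {
                    "fragment_id": f"{crate}-{cid}",
                    "colony_id": cid,
                    "origin": origin,
                    "location": location,
                    "crate_id": crate,
                    "fate": fate,
                    "initial_weight": round(initial, 3),
                    "final_weight": round(final, 3) if np.isfinite(final) else np.nan,
                    "branch_count": branches,
                }
            )

    truth = GroundTruth(
        colony_ids=colonies,
        origins=origins,
        survival_logit=survival_logit,
        growth_pct=growth_pct,
        latent_z=latent_z,
        crate_survival_effect=crate_surv,
        crate_growth_effect=crate_grow,
    )
    return attach_growth(pd.DataFrame(rows)), truth


def _module_factor(
    spec: ModuleSpec, truth: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    n = len(truth.colony_ids)
    if spec.outlier:
        # shared factor so the genes cohere into a cluster, with one
        # sample >= 5 SD out carrying most of the factor variance; the
        # absolute log-scale shift stays modest so the outlier cannot
        # dominate library composition
        f = rng.normal(0.0, 0.3, size=n)
        f[rng.integers(n)] = 2.0
        return f
    t = truth.trait_vector(spec.trait)
    t = (t - t.mean()) / t.std()
    noise = rng.normal(size=n)
    noise = (noise - noise.mean()) / noise.std()
    # orthogonalize noise against the trait so corr(f, t) = spec.corr exactly
    noise = noise - (noise @ t) / (t @ t) * t
    noise = noise / noise.std()
    return spec.corr * t + math.sqrt(1.0 - spec.corr**2) * noise


def _draw_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def generate_expression_data(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate a gene x colony negative-binomial count matrix.

    Planted modules share a per-sample log-scale factor tied to a latent
    trait (or to a single outlier sample); background genes are
    independent.  Fills ``truth.gene_modules`` / ``gene_signs`` /
    ``module_factors``.
    """
    if set(truth.colony_ids) != set(config.colony_ids):
        raise ValueError("ground truth colonies do not match config")
    rng = _rng(config, _STREAM_EXPRESSION)
    n_samples = len(truth.colony_ids)
    n_genes = config.n_genes

    gene_ids = [f"contig{g + 1:05d}" for g in range(n_genes)]
    baseline = rng.lognormal(mean=math.log(20.0), sigma=1.2, size=n_genes)

    log_offset = np.zeros((n_genes, n_samples))
    labels = np.zeros(n_genes, dtype=int)
    signs = np.ones(n_genes)
    pos = 0
    for k, spec in enumerate(config.module_specs, start=1):
        f = _module_factor(spec, truth, rng)
        idx = np.arange(pos, pos + spec.size)
        pos += spec.size
        labels[idx] = k
        loadings = config.module_effect_size * rng.uniform(0.6, 1.4, size=spec.size)
        sgn = np.where(rng.random(spec.size) < 0.85, 1.0, -1.0)
        signs[idx] = sgn
        log_offset[idx, :] = (loadings * sgn)[:, None] * f[None, :]
        truth.module_factors[k] = f
        truth.module_specs[k] = spec

    mu = baseline[:, None] * np.exp(log_offset)
    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng.uniform(lib_lo, lib_hi, size=n_samples)
    mu *= lib_sizes / mu.sum(axis=0)

    counts = _draw_counts(mu, config.nb_dispersion, rng)
    truth.gene_modules = {g: int(l) for g, l in zip(gene_ids, labels)}
    truth.gene_signs = {g: float(s) for g, s in zip(gene_ids, signs)}
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                        columns=truth.colony_ids)


def generate_followup_panels(
    truth: GroundTruth,
    config: SimulationConfig,
    n_panels: int = 4,
    stable_module: int = 1,
    factor_noise_sd: float = 0.3,
) -> list[pd.DataFrame]:
    """Simulate follow-up count panels over the same colonies.

    The ``stable_module``'s per-sample factor is carried over (with
    fresh noise of SD ``factor_noise_sd``); every other planted module
    is re-drawn independently per panel, so only the stable module's
    expression pattern should reproduce.
    """
    if n_panels == 0:
        return []
    if stable_module not in truth.module_factors:
        raise KeyError(f"unknown module id {stable_module!r}")
    rng = _rng(config, _STREAM_PANELS)
    n_samples = len(truth.colony_ids)
    gene_ids = list(truth.gene_modules)
    labels = np.array([truth.gene_modules[g] for g in gene_ids])
    signs = np.array([truth.gene_signs[g] for g in gene_ids])
    baseline = rng.lognormal(mean=math.log(20.0), sigma=1.2, size=len(gene_ids))

    panels = []
    for _ in range(n_panels):
        log_offset = np.zeros((len(gene_ids), n_samples))
        for k, spec in truth.module_specs.items():
            if k == stable_module:
                f = truth.module_factors[k] + rng.normal(0, factor_noise_sd, n_samples)
            else:
                # transient modules decouple from the traits entirely, so
                # their panel PC1s are independent of the original data
                f = _module_factor(replace(spec, corr=0.0), truth, rng)
            idx = np.where(labels == k)[0]
            loadings = config.module_effect_size * rng.uniform(0.6, 1.4, size=len(idx))
            log_offset[idx, :] = (loadings * signs[idx])[:, None] * f[None, :]
        mu = baseline[:, None] * np.exp(log_offset)
        lib_lo, lib_hi = config.library_size_range
        lib_sizes = rng.uniform(lib_lo, lib_hi, size=n_samples)
        mu *= lib_sizes / mu.sum(axis=0)
        counts = _draw_counts(mu, config.nb_dispersion, rng)
        panels.append(
            pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                         columns=truth.colony_ids)
        )
    return panels


def generate_symbiont_table(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-colony clade-D symbiont proportions, beta-marginal with a
    configurable weak correlation to the latent survival trait."""
    rng = _rng(config, _STREAM_SYMBIONTS)
    c = config.symbiont_corr
    z_s = truth.trait_vector("survival")
    latent = c * z_s + math.sqrt(1.0 - c**2) * rng.normal(size=len(z_s))
    prop = beta_dist.ppf(norm.cdf(latent), 2.0, 5.0)
    return pd.DataFrame(
        {"colony_id": truth.colony_ids, "clade_d_proportion": prop}
    )


def write_dataset(
    config: SimulationConfig, out_dir: str | Path, n_panels: int = 4
) -> dict:
    """Generate and write the full synthetic dataset to ``out_dir``."""
    from coralsieve.io import write_counts_matrix, write_fragment_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fragments, truth = generate_transplant_data(config)
    counts = generate_expression_data(truth, config)
    panels = generate_followup_panels(truth, config, n_panels=n_panels)
    symbionts = generate_symbiont_table(truth, config)

    write_fragment_table(fragments, out / "fragments.csv")
    write_counts_matrix(counts, out / "counts.tsv")
    truth.to_json(out / "truth.json")
    symbionts.to_csv(out / "symbionts.csv", index=False)
    panel_dir = out / "panels"
    panel_dir.mkdir(exist_ok=True)
    for k, panel in enumerate(panels):
        write_counts_matrix(panel, panel_dir / f"panel{k + 1}.tsv")
    return {
        "fragments": str(out / "fragments.csv"),
        "counts": str(out / "counts.tsv"),
        "truth": str(out / "truth.json"),
        "symbionts": str(out / "symbionts.csv"),
        "panels": [str(panel_dir / f"panel{k + 1}.tsv") for k in range(len(panels))],
    }
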