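"""Configuration objects for the simulation and the analysis pipeline.

Plain dataclasses with validation in ``__post_init__``; everything is
serializable to/from dicts (and hence YAML) so a run can be reproduced
from its manifest alone.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic antibody-microarray survival cohort.

    The defaults mirror the cohort shape of the motivating study: 371
    antibody clones (scFv analytes) against 158 serum proteins with 1-9
    clones per target, triplicate spots, three scan-date batches and two
    slide batches, an 11-protein protective signature, and exponential
    proportional-hazards survival with right censoring.

    Parameters
    ----------
    n_patients : int
        Cohort size (the study profiled 44 relapsed patients; simulations
        elsewhere in this package use up to a few hundred).
    n_proteins, n_clones : int
        Number of target proteins and total clone-level analytes.
    n_signature_proteins : int
        Number of proteins with a planted survival effect.
    signature_log_hr_per_sd : float
        Log hazard ratio per SD of latent protein level for each signature
        protein; <= 0 (protective: high serum level, lower hazard).
    batch_shift, batch_scale : tuple of float
        Additive log2 offset and multiplicative noise dispersion per scan
        batch (length ``n_scan_batches``).
    slide_batch_shift : tuple of float
        Smaller additive log2 offset per slide batch.
    replicate_cv : float
        Target coefficient of variation across the three replicate spots.
    outlier_spot_rate : float
        Probability a triplet contains one corrupted replicate (exercises
        the CV > 15% elimination rule downstream).
    spot_flag_rate : float
        Probability a single spot carries a quality flag (removed upstream
        of aggregation).
    censoring_rate : float
        Target fraction of censored patients; the random-censoring hazard
        is calibrated numerically against the simulated linear predictors
        together with administrative censoring at ``follow_up_months``.
    baseline_hazard : float
        Events per month at linear predictor 0 (default gives a ~15-month
        median survival at the cohort average).
    mipi_effect : float
        Log hazard ratio per unit of (centred) MIPI score.
    """

    n_patients: int = 44
    n_proteins: int = 158
    n_clones: int = 371
    n_signature_proteins: int = 11
    signature_log_hr_per_sd: float = -1.0
    n_scan_batches: int = 3
    n_slide_batches: int = 2
    batch_shift: Sequence[float] = (0.0, 0.7, -0.4)
    batch_scale: Sequence[float] = (1.0, 1.15, 0.9)
    slide_batch_shift: Sequence[float] = (0.0, 0.25)
    replicate_cv: float = 0.08
    outlier_spot_rate: float = 0.02
    spot_flag_rate: float = 0.01
    censoring_rate: float = 0.40
    baseline_hazard: float = 0.046
    follow_up_months: float = 36.0
    mipi_effect: float = 0.68
    progression_hazard_ratio: float = 1.4
    clone_affinity_sd: float = 0.4
    clone_noise_sd: float = 0.25
    protein_level_mean: float = 10.0
    protein_level_sd: float = 1.0
    protein_block_rho: float = 0.0
    protein_block_size: int = 1
    mipi_missing_rate: float = 0.068
    ki67_missing_rate: float = 0.27
    tp53_missing_rate: float = 0.023
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if not (0 < self.n_proteins <= self.n_clones):
            raise ConfigError("need 1 <= n_proteins <= n_clones")
        if self.n_clones > 9 * self.n_proteins:
            raise ConfigError(
                f"{self.n_clones} clones cannot be allocated to "
                f"{self.n_proteins} proteins with at most 9 clones each"
            )
        if self.n_signature_proteins > self.n_proteins:
            raise ConfigError("signature proteins must be a subset of the protein set")
        if self.signature_log_hr_per_sd > 0:
            raise ConfigError("signature_log_hr_per_sd must be <= 0 (protective)")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        for name in ("replicate_cv", "outlier_spot_rate", "spot_flag_rate",
                     "follow_up_months", "clone_affinity_sd", "clone_noise_sd"):
            v = float(getattr(self, name))
            if not (v >= 0.0) or v != v:
                raise ConfigError(f"{name} must be finite and non-negative")
        if len(tuple(self.batch_shift)) != self.n_scan_batches:
            raise ConfigError("batch_shift must have one entry per scan batch")
        if len(tuple(self.batch_scale)) != self.n_scan_batches:
            raise ConfigError("batch_scale must have one entry per scan batch")
        if len(tuple(self.slide_batch_shift)) != self.n_slide_batches:
            raise ConfigError("slide_batch_shift must have one entry per slide batch")
        if not (0 <= self.protein_block_rho < 1):
            raise ConfigError("protein_block_rho must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("batch_shift", "batch_scale", "slide_batch_shift"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class BEConfig:
    """Backward-elimination (Cox-BE arm) settings.

    Each of ``n_runs`` runs draws a seeded patient subsample, filters the
    candidate analytes by Wilcoxon rank-sum p < ``wilcoxon_alpha`` between
    outcome classes, then backward-eliminates features against a
    leave-one-out cross-validated linear-SVM ROC AUC. The consensus panel
    is the intersection over all runs.
    """

    n_runs: int = 12
    subsample_fraction: float = 0.9
    wilcoxon_alpha: float = 0.05
    svm_c: float = 1.0
    auc_tolerance: float = 1e-6
    min_features: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise ConfigError("subsample_fraction must be in (0, 1]")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if not (0 < self.wilcoxon_alpha < 1):
            raise ConfigError("wilcoxon_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ENRConfig:
    """Elastic-net arm settings: alpha grid over the ridge-lasso mixing
    parameter, single seeded 80/20 train/test split, model chosen by
    minimum test RMSE (ties broken by maximum R^2)."""

    alpha_grid: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(11))
    train_fraction: float = 0.8
    n_lambda: int = 40
    cv_folds: int = 5
    n_splits: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(self.alpha_grid)
        if not grid or any(a < 0 or a > 1 for a in grid):
            raise ConfigError("alpha_grid must lie within [0, 1]")
        if not (0 < self.train_fraction < 1):
            raise ConfigError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_grid"] = list(d["alpha_grid"])
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (thresholds default to the published
    processing rules: CV 15%, 5% trim, screen alpha 0.05)."""

    cv_threshold: float = 0.15
    trim: float = 0.05
    trim_mode: str = "winsorize"
    batch_column: str = "scan_batch"
    screen_alpha: float = 0.05
    be: BEConfig = field(default_factory=BEConfig)
    enr: ENRConfig = field(default_factory=ENRConfig)
    ris_form: str = "ternary"
    index_weights: str = "refit"
    min_frac: float = 0.10
    endpoint: str = "OS"
    dichotomize: str = "event"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_threshold", "trim", "screen_alpha", "min_frac"):
            v = float(getattr(self, name))
            if not (0 < v < 1):
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.trim_mode not in ("winsorize", "discard"):
            raise ConfigError("trim_mode must be 'winsorize' or 'discard'")
        if self.ris_form not in ("ternary", "continuous"):
            raise ConfigError("ris_form must be 'ternary' or 'continuous'")
        if self.index_weights not in ("refit", "published"):
            raise ConfigError("index_weights must be 'refit' or 'published'")
        if self.endpoint not in ("OS", "PFS"):
            raise ConfigError("endpoint must be 'OS' or 'PFS'")
        if self.dichotomize not in ("event", "median"):
            raise ConfigError("dichotomize must be 'event' or 'median'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["be"] = self.be.to_dict()
        d["enr"] = self.enr.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("be"), dict):
            d["be"] = BEConfig(**d["be"])
        if isinstance(d.get("enr"), dict):
            d["enr"] = ENRConfig(**d["enr"])
        return cls(**d)


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed.

    Uses CRC32 of ``"<stage>:<seed>"`` so stages can be re-run in
    isolation with the same stream they would see inside ``run-all``.
    """
    import zlib

    return zlib.crc32(f"{stage}:{int(global_seed)}".encode()) & 0x7FFFFFFF
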