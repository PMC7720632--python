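"""Risk scores: MIPI, the coefficient-weighted serum-protein signature
score (RIS), the multivariate Cox fit combining them, and the combined
MIPI+RIS index.

MIPI (MCL International Prognostic Index) is the published clinical
score ``0.03535*age + 0.6978*[ECOG > 1] + 1.367*log10(LDH/ULN) +
0.9393*log10(WBC)`` with categories low (<= 5.7), intermediate
(5.7 < score < 6.2) and high (>= 6.2). The RIS score is the sum of
per-protein univariate Cox coefficients times standardized log2 signal;
its ternary coding (0/1/2 ascending in risk) comes from the log-rank
optimized two-cutpoint split. The combined index is a weighted sum of
MIPI and the ternary RIS, the weights being the multivariate Cox
coefficients (published reference weights: 0.708 and 1.327).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .survstats import CutpointSearchResult, optimal_cutpoints

logger = logging.getLogger(__name__)

#: multivariate Cox coefficients (MIPI, ternary RIS) from the reference
#: relapsed-MCL analysis; used when ``index_weights="published"``.
PUBLISHED_WEIGHTS: Tuple[float, float] = (0.708, 1.327)

MIPI_LOW_MAX = 5.7
MIPI_HIGH_MIN = 6.2


def mipi_score_from_components(age, ecog, ldh_ratio, wbc) -> np.ndarray:
    """Published MIPI formula (age in years, ECOG 0-4, LDH/ULN ratio,
    WBC in 1e9/L)."""
    age = np.asarray(age, float)
    ecog = np.asarray(ecog, float)
    ldh_ratio = np.asarray(ldh_ratio, float)
    wbc = np.asarray(wbc, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (
            0.03535 * age
            + 0.6978 * (ecog > 1).astype(float)
            + 1.367 * np.log10(ldh_ratio)
            + 0.9393 * np.log10(wbc)
        )
    return score


def mipi_category(score) -> np.ndarray:
    """LR <= 5.7 < IR < 6.2 <= HR (boundaries included per the quoted
    inequalities); NaN scores map to 'missing'."""
    s = np.asarray(score, float)
    cat = np.where(s <= MIPI_LOW_MAX, "LR", np.where(s >= MIPI_HIGH_MIN, "HR", "IR"))
    cat = np.asarray(cat, dtype=object)
    cat[~np.isfinite(s)] = "missing"
    return cat


def compute_mipi(clinical: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Per-patient MIPI score and category.

    Uses a precomputed ``mipi_score`` column when present (falling back
    to the component formula for rows where it is missing); patients with
    neither are flagged 'missing'.
    """
    n = len(clinical)
    score = np.full(n, np.nan)
    if "mipi_score" in clinical.columns:
        score = clinical["mipi_score"].to_numpy(dtype=float).copy()
    comp_cols = ("age", "ecog", "ldh_ratio", "wbc")
    if all(c in clinical.columns for c in comp_cols):
        computed = mipi_score_from_components(
            clinical["age"], clinical["ecog"], clinical["ldh_ratio"], clinical["wbc"]
        )
        missing = ~np.isfinite(score)
        score[missing] = computed[missing]
    n_missing = int((~np.isfinite(score)).sum())
    if n_missing:
        logger.info("MIPI missing for %d patients", n_missing)
    return score, mipi_category(score)


@dataclass
class RISResult:
    """Continuous and ternary signature score per patient."""

    scores: pd.DataFrame              # patient_id, s_continuous, s_ternary
    cutpoints: Optional[CutpointSearchResult]
    weights: Dict[str, float]

    @property
    def s_continuous(self) -> np.ndarray:
        return self.scores["s_continuous"].to_numpy()

    @property
    def s_ternary(self) -> np.ndarray:
        return self.scores["s_ternary"].to_numpy()


def compute_ris(
    panel_values: pd.DataFrame,
    weights: Dict[str, float],
    time=None,
    event=None,
    form: str = "ternary",
    min_frac: float = 0.10,
) -> RISResult:
    """Coefficient-weighted signature score.

    ``panel_values`` holds the (log2) signal of the representative clone
    per signature protein, one column per protein, indexed by patient.
    Columns are standardized within the cohort; a patient's missing panel
    values are imputed with the mean of their available panel z-scores
    (flagged in the log). ``s_continuous = sum_i beta_i * z_i``; the
    ternary code {0,1,2} ascends in risk via the log-rank-optimized
    two-cutpoint split of the continuous score (protective proteins carry
    negative betas, so low expression pushes the score, and the risk, up).
    """
    cols = list(weights.keys())
    missing_cols = [c for c in cols if c not in panel_values.columns]
    if missing_cols:
        raise KeyError(f"panel columns absent from expression data: {missing_cols}")
    X = panel_values[cols].to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[~(sd > 0)] = 1.0
    Z = (X - mu) / sd
    nan_mask = ~np.isfinite(Z)
    if nan_mask.any():
        logger.info(
            "imputing %d missing panel values with per-patient mean z", int(nan_mask.sum())
        )
        row_mean = np.nanmean(np.where(nan_mask, np.nan, Z), axis=1)
        row_mean = np.nan_to_num(row_mean)
        Z = np.where(nan_mask, row_mean[:, None], Z)
    beta = np.array([weights[c] for c in cols], dtype=float)
    s = Z @ beta

    cut = None
    tern = np.zeros(s.size, dtype=int)
    if form == "ternary":
        if time is None or event is None:
            raise ValueError("ternary RIS coding needs survival data for the cutpoint search")
        cut = optimal_cutpoints(s, time, event, n_groups=3, min_frac=min_frac)
        tern = cut.groups
    scores = pd.DataFrame(
        {
            "patient_id": panel_values.index,
            "s_continuous": s,
            "s_ternary": tern,
        }
    ).set_index("patient_id")
    return RISResult(scores=scores, cutpoints=cut, weights=dict(weights))


@dataclass
class IndexWeights:
    w_mipi: float
    w_ris: float
    source: str  # "published" | "refit"

    def to_dict(self) -> dict:
        return {"w_mipi": self.w_mipi, "w_ris": self.w_ris, "source": self.source}


def fit_multivariate(covariates: pd.DataFrame, time, event) -> Tuple[IndexWeights, pd.DataFrame]:
    """Multivariate Cox fit on complete cases; returns the refit index
    weights (MIPI and RIS coefficients) and the per-covariate table with
    Benjamini-Hochberg q-values.

    ``covariates`` must contain ``mipi_score`` and ``ris`` columns (an
    optional ``ki67_pct`` is supported); rows with any missing value are
    dropped (complete-case analysis).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from statsmodels.stats.multitest import multipletests

    df = covariates.copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, int)
    df = df.dropna()
    if len(df) < 5:
        raise ValueError(f"only {len(df)} complete cases; cannot fit")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as err:  # pragma: no cover - diagnostic path
        raise ValueError(f"multivariate Cox failed to converge: {err}") from err
    summ = cph.summary
    q = multipletests(summ["p"].to_numpy(), method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "covariate": summ.index,
            "n": len(df),
            "beta": summ["coef"].to_numpy(),
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
            "q": q,
        }
    ).reset_index(drop=True)
    beta = dict(zip(summ.index, summ["coef"]))
    weights = IndexWeights(
        w_mipi=float(beta["mipi_score"]), w_ris=float(beta["ris"]), source="refit"
    )
    return weights, table


def compute_mipi_ris(mipi_score, ris, weights: IndexWeights) -> np.ndarray:
    """Combined index ``w_mipi * MIPI + w_ris * RIS``.

    Patients missing either input get NaN (excluded from stratification
    downstream, logged)."""
    mipi = np.asarray(mipi_score, float)
    s = np.asarray(ris, float)
    out = weights.w_mipi * mipi + weights.w_ris * s
    n_missing = int((~np.isfinite(out)).sum())
    if n_missing:
        logger.info("combined index missing for %d patients", n_missing)
    return out


def published_weights() -> IndexWeights:
    return IndexWeights(*PUBLISHED_WEIGHTS, source="published")
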