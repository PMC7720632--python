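"""Spot-level pre-processing: replicate aggregation with the CV rule,
subarray QC, extreme-value trimming, log2 transform and batch
correction.

Pipeline order is fixed and logged: background subtraction -> replicate
aggregation -> trimming -> log2 -> ComBat. "Trimming" is implemented as
per-analyte winsorization at the 5th/95th percentiles by default (a
``discard`` mode that blanks the extremes instead is available); the
percentile uses numpy's linear-interpolation definition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .combat import combat_correct
from .config import PipelineConfig

logger = logging.getLogger(__name__)

SPOT_COLUMNS = [
    "sample_id", "slide_id", "scan_batch", "slide_batch", "subarray",
    "analyte_id", "clone_id", "replicate", "fg", "bg", "flag",
]


@dataclass
class ExpressionMatrix:
    """Samples x analytes log2 expression with sample and analyte metadata."""

    values: pd.DataFrame          # samples x analytes, log2, NaN = missing
    obs: pd.DataFrame             # per-sample metadata (scan_batch, slide_batch, ...)
    var: pd.DataFrame             # per-analyte annotation (clone_id, protein_id)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.obs.index):
            raise ValueError("sample annotation does not match the matrix rows")
        missing = [c for c in self.values.columns if c not in self.var.index]
        if missing:
            raise ValueError(f"analytes without annotation: {missing[:5]}...")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]


def aggregate_replicates(spots: pd.DataFrame, cv_threshold: float = 0.15) -> pd.DataFrame:
    """Collapse replicate spots to one signal per (sample, analyte).

    Background-subtracted replicates (fg - bg; flagged or non-positive
    replicates are invalid). A valid triplet with CV (SD/mean, ddof=1) at
    or below the threshold is averaged over all three; above it, the
    replicate farthest from the triplet median is eliminated (ties drop
    the higher replicate index) and the remaining two are averaged. Two
    valid replicates are averaged as-is; fewer leave the signal missing.

    Returns a frame with columns ``sample_id, analyte_id, signal, cv,
    n_used, eliminated_replicate`` where ``cv`` refers to the replicates
    actually used.
    """
    df = spots.copy()
    net = df["fg"].to_numpy(dtype=float) - df["bg"].to_numpy(dtype=float)
    valid = (df["flag"].to_numpy() == 0) & (net > 0)
    df["_net"] = np.where(valid, net, np.nan)

    wide = df.pivot_table(
        index=["sample_id", "analyte_id"], columns="replicate", values="_net",
        aggfunc="first", dropna=False,
    )
    for r in (1, 2, 3):
        if r not in wide.columns:
            wide[r] = np.nan
    arr = wide[[1, 2, 3]].to_numpy(dtype=float)
    n_valid = np.isfinite(arr).sum(axis=1)

    signal = np.full(len(wide), np.nan)
    cv = np.full(len(wide), np.nan)
    n_used = np.zeros(len(wide), dtype=int)
    eliminated = np.full(len(wide), -1, dtype=int)

    # triplets
    t3 = n_valid == 3
    if t3.any():
        a3 = arr[t3]
        m3 = a3.mean(axis=1)
        sd3 = a3.std(axis=1, ddof=1)
        cv3 = np.divide(sd3, m3, out=np.zeros_like(sd3), where=m3 != 0)
        keep3 = cv3 <= cv_threshold
        med = np.median(a3, axis=1)
        dev = np.abs(a3 - med[:, None])
        # farthest from the median; ties drop the higher replicate index
        out_idx = 2 - np.argmax(dev[:, ::-1], axis=1)
        rows = np.arange(a3.shape[0])
        a3_drop = a3.copy()
        a3_drop[rows, out_idx] = np.nan
        m2 = np.nanmean(a3_drop, axis=1)
        sd2 = np.nanstd(a3_drop, axis=1, ddof=1)
        cv2 = np.divide(sd2, m2, out=np.zeros_like(sd2), where=m2 != 0)

        idx3 = np.where(t3)[0]
        signal[idx3] = np.where(keep3, m3, m2)
        cv[idx3] = np.where(keep3, cv3, cv2)
        n_used[idx3] = np.where(keep3, 3, 2)
        eliminated[idx3] = np.where(keep3, -1, out_idx + 1)

    # pairs (one replicate already invalid)
    t2 = n_valid == 2
    if t2.any():
        a2 = arr[t2]
        m2 = np.nanmean(a2, axis=1)
        sd2 = np.nanstd(a2, axis=1, ddof=1)
        idx2 = np.where(t2)[0]
        signal[idx2] = m2
        cv[idx2] = np.divide(sd2, m2, out=np.zeros_like(sd2), where=m2 != 0)
        n_used[idx2] = 2

    out = pd.DataFrame(
        {
            "sample_id": wide.index.get_level_values(0),
            "analyte_id": wide.index.get_level_values(1),
            "signal": signal,
            "cv": cv,
            "n_used": n_used,
            "eliminated_replicate": np.where(eliminated > 0, eliminated, np.nan),
        }
    ).reset_index(drop=True)
    return out


def subarray_qc(spots: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Per-sample fraction of discarded spots (quality flag or signal at
    or below local background); ``repeat_flag`` is set iff the fraction
    strictly exceeds the threshold."""
    net = spots["fg"].to_numpy(dtype=float) - spots["bg"].to_numpy(dtype=float)
    discarded = (spots["flag"].to_numpy() != 0) | (net <= 0)
    frac = (
        pd.Series(discarded, index=spots["sample_id"].to_numpy())
        .groupby(level=0)
        .mean()
    )
    rep = pd.DataFrame(
        {
            "sample_id": frac.index,
            "fraction_discarded": frac.to_numpy(),
            "repeat_flag": frac.to_numpy() > threshold,
        }
    ).reset_index(drop=True)
    return rep


def trim_extremes(
    matrix: pd.DataFrame,
    lower: float = 0.05,
    upper: float = 0.95,
    mode: str = "winsorize",
    min_n: int = 10,
) -> pd.DataFrame:
    """Limit per-analyte extremes across samples at the given percentiles
    (linear-interpolation definition).

    ``winsorize`` clamps values to the percentile bounds; ``discard``
    blanks them to missing instead. Analytes with fewer than ``min_n``
    non-missing values are passed through with a warning.
    """
    if mode not in ("winsorize", "discard"):
        raise ValueError("mode must be 'winsorize' or 'discard'")
    X = matrix.to_numpy(dtype=float).copy()
    skipped = []
    for j, col in enumerate(matrix.columns):
        v = X[:, j]
        fin = np.isfinite(v)
        if fin.sum() < min_n:
            skipped.append(col)
            continue
        lo, hi = np.nanpercentile(v, [100 * lower, 100 * upper])
        if mode == "winsorize":
            X[:, j] = np.clip(v, lo, hi)
        else:
            X[fin & ((v < lo) | (v > hi)), j] = np.nan
    if skipped:
        logger.warning(
            "trimming skipped for %d analytes with < %d values", len(skipped), min_n
        )
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; non-positive or missing values stay missing."""
    X = matrix.to_numpy(dtype=float)
    out = np.full_like(X, np.nan)
    pos = np.isfinite(X) & (X > 0)
    out[pos] = np.log2(X[pos])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess_pipeline(
    spots: pd.DataFrame,
    annotation: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
) -> Tuple[ExpressionMatrix, pd.DataFrame, List[str]]:
    """Raw spot table -> batch-corrected log2 expression matrix.

    Returns ``(matrix, qc_report, log_lines)``. Samples whose subarray QC
    exceeds the 30% discard rule are excluded from the matrix (in the
    study protocol such assays were repeated).
    """
    cfg = cfg or PipelineConfig()
    log: List[str] = []
    if cfg.batch_column not in spots.columns:
        raise KeyError(f"spot table is missing the batch column {cfg.batch_column!r}")
    unknown = set(spots["analyte_id"]) - set(annotation["analyte_id"])
    if unknown:
        raise KeyError(f"analytes without annotation: {sorted(unknown)[:5]}")

    qc = subarray_qc(spots)
    bad = qc.loc[qc["repeat_flag"], "sample_id"].tolist()
    if bad:
        log.append(f"excluded {len(bad)} sample(s) failing subarray QC: {bad}")
        spots = spots[~spots["sample_id"].isin(bad)]

    agg = aggregate_replicates(spots, cv_threshold=cfg.cv_threshold)
    log.append(
        "aggregated replicates (CV rule at "
        f"{cfg.cv_threshold:.0%}): {int((agg['n_used'] == 2).sum())} pairs, "
        f"{int((agg['n_used'] == 0).sum())} missing"
    )
    wide = agg.pivot(index="sample_id", columns="analyte_id", values="signal")

    wide = trim_extremes(wide, lower=cfg.trim, upper=1 - cfg.trim, mode=cfg.trim_mode)
    log.append(f"trimmed extremes at {cfg.trim:.0%}/{1 - cfg.trim:.0%} ({cfg.trim_mode})")

    logged = log2_transform(wide)
    log.append("log2-transformed")

    meta_cols = ["scan_batch", "slide_batch", "slide_id"]
    meta = (
        spots[["sample_id"] + [c for c in meta_cols if c in spots.columns]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[logged.index]
    )
    batch = meta[cfg.batch_column]
    if batch.nunique() >= 2:
        corrected = combat_correct(logged, batch)
        log.append(f"ComBat batch correction on {cfg.batch_column!r} "
                   f"({batch.nunique()} batches)")
    else:
        corrected = logged
        log.append("single batch; ComBat skipped")

    var = annotation.set_index("analyte_id").loc[corrected.columns]
    matrix = ExpressionMatrix(values=corrected, obs=meta, var=var)
    for line in log:
        logger.info(line)
    return matrix, qc, log
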