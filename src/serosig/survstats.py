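"""Survival statistics: Kaplan-Meier, k-group log-rank, Harrell's C, and
the log-rank-maximizing two-cutpoint search used to trichotomize risk
scores.

The log-rank statistic is implemented directly (observed-minus-expected
sums with the hypergeometric variance) because the cutpoint search
evaluates it over every feasible ordered pair of candidate cutpoints;
lifelines' ``multivariate_logrank_test`` is the cross-check oracle in the
test suite. KM estimation wraps lifelines.

Convention used throughout: a higher score means higher risk (shorter
expected survival).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: step function over the observed times."""

    times: np.ndarray          # unique observed times (events and censorings)
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray        # number at risk just before each time
    n_events: np.ndarray       # deaths at each time
    n_censored: np.ndarray     # censorings at each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimator with right censoring (ties reduce the risk
    set simultaneously)."""
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    table = table[table.index > 0] if (table.index == 0).any() and table.loc[0, "observed"] == 0 and table.loc[0, "censored"] == 0 else table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
    )


# --------------------------------------------------------------------------
# k-sample log-rank test
# --------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank_test(time, event, group) -> LogRankResult:
    """k-sample log-rank test (chi-squared with k-1 df).

    Observed-minus-expected event counts per group summed over event
    times, with the hypergeometric variance-covariance; the statistic is
    the quadratic form over any k-1 groups (generalized inverse guards
    degenerate strata).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    codes, uniques = pd.factorize(np.asarray(group))
    k = len(uniques)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    counts = np.bincount(codes, minlength=k)
    if counts.min() == 0:
        raise ValueError("every group must contain at least one subject")

    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], codes[order]
    n = t.size
    at_risk = counts.astype(float).copy()
    oe = np.zeros(k)
    V = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        d = np.zeros(k)
        for idx in range(i, j + 1):
            if e[idx] == 1:
                d[g[idx]] += 1
        d_tot = d.sum()
        n_tot = at_risk.sum()
        if d_tot > 0 and n_tot > 0:
            expected = d_tot * at_risk / n_tot
            oe += d - expected
            if n_tot > 1:
                f = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
                V += f * (np.diag(at_risk) * n_tot - np.outer(at_risk, at_risk)) / n_tot**2
        for idx in range(i, j + 1):
            at_risk[g[idx]] -= 1
        i = j + 1

    sub = slice(0, k - 1)
    Vs = V[sub, sub]
    oes = oe[sub]
    chi2 = float(oes @ np.linalg.pinv(Vs) @ oes) if k > 1 else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# --------------------------------------------------------------------------
# Harrell's concordance index
# --------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    c: float
    n_concordant: int
    n_discordant: int
    n_tied: int
    n_usable: int


def harrell_c(score, time, event) -> ConcordanceResult:
    """Harrell's C over all usable pairs (higher score = higher risk).

    A pair is usable iff the ordering of the underlying event times is
    determinable under censoring: the earlier time is an event, or the
    times are equal and exactly one is an event (the censored subject
    survived longer). Concordant pairs have the higher score on the
    shorter time; score ties count one half.
    """
    s = np.asarray(score, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int).astype(bool)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    # usable ordered pairs (i = the determinably-shorter member)
    shorter = (t[:, None] < t[None, :]) & e[:, None]
    eq = (t[:, None] == t[None, :]) & e[:, None] & ~e[None, :]
    usable = shorter | eq
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs (all censored or fully tied)")
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    n_conc = int((usable & higher).sum())
    n_tied = int((usable & tied).sum())
    n_disc = n_usable - n_conc - n_tied
    c = (n_conc + 0.5 * n_tied) / n_usable
    return ConcordanceResult(float(c), n_conc, n_disc, n_tied, n_usable)


# --------------------------------------------------------------------------
# optimal two-cutpoint search
# --------------------------------------------------------------------------

@njit(cache=True)
def _logrank3_chi2(t, e, lvl, a, b, n1, n2, n3):
    """3-group log-rank chi2 for groups split at score-level indices a<b.

    ``t``/``e``/``lvl`` are sorted by ascending time; ``lvl`` is each
    subject's index into the sorted unique scores.
    """
    n = t.size
    r1, r2, r3 = float(n1), float(n2), float(n3)
    oe1 = 0.0
    oe2 = 0.0
    v11 = 0.0
    v22 = 0.0
    v12 = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        d1 = 0.0
        d2 = 0.0
        d3 = 0.0
        for idx in range(i, j + 1):
            if e[idx] == 1:
                if lvl[idx] <= a:
                    d1 += 1.0
                elif lvl[idx] <= b:
                    d2 += 1.0
                else:
                    d3 += 1.0
        d_tot = d1 + d2 + d3
        n_tot = r1 + r2 + r3
        if d_tot > 0.0 and n_tot > 0.0:
            oe1 += d1 - d_tot * r1 / n_tot
            oe2 += d2 - d_tot * r2 / n_tot
            if n_tot > 1.0:
                f = d_tot * (n_tot - d_tot) / (n_tot - 1.0) / (n_tot * n_tot)
                v11 += f * r1 * (n_tot - r1)
                v22 += f * r2 * (n_tot - r2)
                v12 += f * (-r1 * r2)
        for idx in range(i, j + 1):
            if lvl[idx] <= a:
                r1 -= 1.0
            elif lvl[idx] <= b:
                r2 -= 1.0
            else:
                r3 -= 1.0
        i = j + 1
    det = v11 * v22 - v12 * v12
    scale = v11 * v22 + v12 * v12 + 1e-300
    if det <= 1e-12 * scale:
        # near-singular covariance: fall back to the largest 1-df statistic
        c1 = oe1 * oe1 / v11 if v11 > 0.0 else 0.0
        c2 = oe2 * oe2 / v22 if v22 > 0.0 else 0.0
        return c1 if c1 > c2 else c2
    return (v22 * oe1 * oe1 - 2.0 * v12 * oe1 * oe2 + v11 * oe2 * oe2) / det


@njit(cache=True)
def _scan_pairs(t, e, lvl, cum, min_n):
    """Exhaustive scan over ordered cut-level pairs; returns the argmax.

    Ties in chi2 keep the first pair in (a asc, b asc) order, i.e. the
    smaller first cutpoint then the smaller second cutpoint.
    """
    m = cum.size
    n = t.size
    best_a = -1
    best_b = -1
    best_chi2 = -1.0
    for a in range(m - 1):
        n1 = cum[a]
        if n1 < min_n:
            continue
        if n - n1 < 2 * min_n:
            break
        for b in range(a + 1, m - 1):
            n2 = cum[b] - cum[a]
            if n2 < min_n:
                continue
            n3 = n - cum[b]
            if n3 < min_n:
                break
            chi2 = _logrank3_chi2(t, e, lvl, a, b, n1, n2, n3)
            if chi2 > best_chi2 + 1e-12:
                best_chi2 = chi2
                best_a = a
                best_b = b
    return best_a, best_b, best_chi2


@njit(cache=True)
def _scan_single(t, e, lvl, cum, min_n):
    """Single-cutpoint (two-group) variant of the scan."""
    m = cum.size
    n = t.size
    best_a = -1
    best_chi2 = -1.0
    for a in range(m - 1):
        n1 = cum[a]
        if n1 < min_n or n - n1 < min_n:
            continue
        chi2 = _logrank3_chi2(t, e, lvl, a, m - 1, n1, n - n1, 0)
        if chi2 > best_chi2 + 1e-12:
            best_chi2 = chi2
            best_a = a
    return best_a, best_chi2


@dataclass
class CutpointSearchResult:
    cutpoints: tuple            # (c1,) or (c1, c2) with c1 < c2
    chi2: float
    df: int
    p: float
    group_sizes: tuple
    groups: np.ndarray          # 0-based risk group per subject

    @property
    def c1(self) -> float:
        return self.cutpoints[0]

    @property
    def c2(self) -> float:
        return self.cutpoints[-1]


def optimal_cutpoints(score, time, event, n_groups: int = 3,
                      min_frac: float = 0.10) -> CutpointSearchResult:
    """Maximally selected log-rank stratification of a risk score.

    Exhaustive search over all ordered pairs of candidate cutpoints
    (midpoints between consecutive sorted unique scores) subject to a
    minimum group size of ``ceil(min_frac * n)``; returns the pair
    maximizing the log-rank chi-squared (equivalently minimizing its p at
    fixed df). Deterministic tie-break: smaller first cutpoint, then
    smaller second. Note the minimal-p approach inflates type-I error;
    the resulting p-value is descriptive, not a calibrated test.
    """
    s = np.asarray(score, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    n = s.size
    if n_groups not in (2, 3):
        raise ValueError("n_groups must be 2 or 3")
    min_n = max(1, int(np.ceil(min_frac * n)))
    if n < n_groups * min_n:
        raise ValueError(
            f"{n} subjects cannot form {n_groups} groups of >= {min_n}"
        )
    uniq = np.unique(s)
    if uniq.size < n_groups:
        raise ValueError(
            f"score has {uniq.size} distinct values; need >= {n_groups}"
        )
    lvl_all = np.searchsorted(uniq, s)
    order = np.argsort(t, kind="mergesort")
    ts = np.ascontiguousarray(t[order])
    es = np.ascontiguousarray(e[order])
    lvl = np.ascontiguousarray(lvl_all[order])
    cum = np.cumsum(np.bincount(lvl_all, minlength=uniq.size))

    if n_groups == 3:
        a, b, chi2 = _scan_pairs(ts, es, lvl, cum, min_n)
        if a < 0:
            raise ValueError(
                "no feasible cutpoint pair under the group-size constraint; "
                "try n_groups=2 or a smaller min_frac"
            )
        cuts = (float((uniq[a] + uniq[a + 1]) / 2), float((uniq[b] + uniq[b + 1]) / 2))
        groups = (s > cuts[0]).astype(int) + (s > cuts[1]).astype(int)
    else:
        a, chi2 = _scan_single(ts, es, lvl, cum, min_n)
        if a < 0:
            raise ValueError("no feasible cutpoint under the group-size constraint")
        cuts = (float((uniq[a] + uniq[a + 1]) / 2),)
        groups = (s > cuts[0]).astype(int)

    # internal consistency: the search objective must equal the public
    # log-rank statistic at the returned stratification
    check = logrank_test(t, e, groups)
    if not np.isclose(check.chi2, chi2, rtol=1e-8, atol=1e-8):
        warnings.warn(
            f"cutpoint-scan chi2 {chi2:.6g} != logrank_test chi2 "
            f"{check.chi2:.6g}; reporting the public statistic"
        )
    sizes = tuple(int((groups == g).sum()) for g in range(n_groups))
    return CutpointSearchResult(
        cutpoints=cuts,
        chi2=check.chi2,
        df=check.df,
        p=check.p,
        group_sizes=sizes,
        groups=groups,
    )


# --------------------------------------------------------------------------
# index comparison report
# --------------------------------------------------------------------------

def compare_indices(
    indices: Dict[str, np.ndarray],
    time,
    event,
    pfs_time=None,
    pfs_event=None,
    fixed_cutpoints: Optional[Dict[str, Sequence[float]]] = None,
    min_frac: float = 0.10,
) -> pd.DataFrame:
    """Side-by-side comparison of per-patient risk indices.

    For each index: ternary stratification (fixed cutpoints if supplied,
    otherwise log-rank-optimized), the log-rank chi2/p for OS (and PFS
    when provided) and Harrell's C. Indices whose stratification yields a
    single occupied group have the log-rank skipped with a note.
    """
    fixed_cutpoints = fixed_cutpoints or {}
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rows = []
    for name, score in indices.items():
        s = np.asarray(score, float)
        mask = np.isfinite(s)
        tt, ee, ss = time[mask], event[mask], s[mask]
        row: dict = {"index": name, "n": int(mask.sum())}
        row["harrell_c"] = harrell_c(ss, tt, ee).c
        note = ""
        use_optimized = name not in fixed_cutpoints
        if not use_optimized:
            cuts = tuple(sorted(fixed_cutpoints[name]))
            groups = np.digitize(ss, cuts)
            row["c1"], row["c2"] = (cuts + (np.nan,))[:2]
            row["cutpoint_source"] = "fixed"
            if np.unique(groups).size < 2:
                # fixed category boundaries off-scale for this cohort
                note = "fixed cutpoints yield one group; re-optimized"
                use_optimized = True
        if use_optimized:
            try:
                res = optimal_cutpoints(ss, tt, ee, n_groups=3, min_frac=min_frac)
                groups = res.groups
                row["c1"], row["c2"] = res.cutpoints
                row["cutpoint_source"] = "optimized"
            except ValueError as err:
                groups = np.zeros(ss.size, dtype=int)
                row["c1"] = row["c2"] = np.nan
                row["cutpoint_source"] = "none"
                note = str(err)
        occupied = np.unique(groups)
        if occupied.size >= 2:
            lr = logrank_test(tt, ee, groups)
            row["logrank_chi2"], row["logrank_df"], row["logrank_p"] = (
                lr.chi2, lr.df, lr.p,
            )
            if pfs_time is not None and pfs_event is not None:
                pt = np.asarray(pfs_time, float)[mask]
                pe = np.asarray(pfs_event, int)[mask]
                lr2 = logrank_test(pt, pe, groups)
                row["pfs_logrank_chi2"], row["pfs_logrank_p"] = lr2.chi2, lr2.p
        else:
            row["logrank_chi2"] = row["logrank_p"] = np.nan
            row["logrank_df"] = 0
            note = note or "single group; log-rank skipped"
        for g in range(3):
            row[f"n_group{g}"] = int((groups == g).sum())
        row["note"] = note
        rows.append(row)
    return pd.DataFrame(rows)


def plot_km_by_group(time, event, groups, path, title: str = "",
                     labels=("low risk", "intermediate risk", "high risk")) -> None:
    """Kaplan-Meier curves per risk group, written as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g in np.unique(groups):
        m = groups == g
        curve = km_estimate(time[m], event[m])
        lbl = labels[int(g)] if int(g) < len(labels) else str(g)
        ax.step(np.concatenate([[0.0], curve.times]),
                np.concatenate([[1.0], curve.survival]),
                where="post", label=f"{lbl} (n={int(m.sum())})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="best", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "serosig"})
    plt.close(fig)
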