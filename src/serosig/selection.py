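"""Dual-arm consensus protein selection.

Arm 1 (Cox-BE): univariate Cox screen at p < 0.05 on standardized log2
signal, then repeated backward elimination on seeded patient subsamples
-- Wilcoxon rank-sum pre-filter between outcome classes, then features
are removed while the leave-one-out cross-validated linear-SVM ROC AUC
does not drop -- with the consensus being the analytes selected in every
run. Arm 2 (ENR): elastic net over a grid of mixing parameters on an
80/20 split of observed survival months, the model with the lowest test
RMSE (ties: highest R^2) providing the nonzero-coefficient analytes.
Both arms are collapsed to protein level (the clone with the best
univariate Cox p represents its protein) and intersected into the final
signature panel, which carries the univariate Cox coefficients as score
weights.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._coxph import CoxFitError, fit_cox_univariate
from ._svm import _loocv_auc_each_removed, _loocv_auc_kernel, loocv_auc
from .config import BEConfig, ENRConfig, derive_seed

logger = logging.getLogger(__name__)


def impute_and_standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing values per analyte, then z-score each column.

    Constant columns are left at zero after centering (unit divisor).
    """
    V = X.to_numpy(dtype=float).copy()
    mu = np.nanmean(V, axis=0)
    nan_cols = ~np.isfinite(mu)
    mu[nan_cols] = 0.0
    idx = np.where(~np.isfinite(V))
    if idx[0].size:
        logger.info("mean-imputing %d missing values before model fitting", idx[0].size)
        V[idx] = mu[idx[1]]
    sd = V.std(axis=0, ddof=1)
    sd[~(sd > 0)] = 1.0
    return pd.DataFrame((V - V.mean(axis=0)) / sd, index=X.index, columns=X.columns)


# --------------------------------------------------------------------------
# univariate Cox screen
# --------------------------------------------------------------------------

def cox_screen(
    X: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    ph_alpha: float = 0.05,
    compute_ph: bool = True,
) -> pd.DataFrame:
    """Univariate Cox regression per analyte on standardized log2 signal.

    Returns one row per analyte: ``beta, hr, ci_low, ci_high, p, q,
    passed`` plus, for passing analytes, the Schoenfeld-residual
    proportional-hazards p-value ``ph_p`` (analytes violating PH are
    flagged via ``ph_flag``, not excluded). Analytes that cannot be fit
    (constant signal, non-convergence) are skipped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for the Cox screen")
    Z = impute_and_standardize(X)
    rows = []
    for col in Z.columns:
        x = Z[col].to_numpy()
        try:
            fit = fit_cox_univariate(x, time, event)
        except CoxFitError as err:
            warnings.warn(f"screen skipped analyte {col}: {err}")
            rows.append(
                dict(analyte_id=col, beta=np.nan, hr=np.nan, ci_low=np.nan,
                     ci_high=np.nan, p=np.nan, converged=False)
            )
            continue
        if not fit.converged:
            warnings.warn(f"screen skipped analyte {col}: no convergence")
        rows.append(
            dict(analyte_id=col, beta=fit.beta, hr=fit.hr, ci_low=fit.ci_low,
                 ci_high=fit.ci_high, p=fit.p, converged=fit.converged)
        )
    table = pd.DataFrame(rows)
    ok = table["converged"] & np.isfinite(table["p"])
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["passed"] = ok & (table["p"] < alpha)

    table["ph_p"] = np.nan
    table["ph_flag"] = False
    if compute_ph and table["passed"].any():
        ph = _schoenfeld_ph_pvalues(Z, time, event, table.loc[table["passed"], "analyte_id"])
        table.loc[table["passed"], "ph_p"] = table.loc[table["passed"], "analyte_id"].map(ph)
        table["ph_flag"] = table["ph_p"] < ph_alpha
    return table


def _schoenfeld_ph_pvalues(Z: pd.DataFrame, time, event, analytes) -> Dict[str, float]:
    """Scaled-Schoenfeld-residual PH test per analyte (lifelines)."""
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    out: Dict[str, float] = {}
    for col in analytes:
        df = pd.DataFrame({"x": Z[col].to_numpy(), "t": time, "e": event})
        try:
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="t", event_col="e")
                res = proportional_hazard_test(cph, df, time_transform="rank")
            out[col] = float(np.atleast_1d(res.p_value)[0])
        except Exception:  # pragma: no cover - diagnostic only
            out[col] = np.nan
    return out


# --------------------------------------------------------------------------
# Cox-BE arm
# --------------------------------------------------------------------------

def dichotomize_outcome(time, event, mode: str = "event") -> np.ndarray:
    """Binary outcome labels for the SVM wrapper.

    ``event`` mode labels patients by the event indicator (died during
    follow-up vs. not); ``median`` splits at the median observed time.
    Raises if only one class results.
    """
    event = np.asarray(event, int)
    if mode == "event":
        labels = event.copy()
    elif mode == "median":
        t = np.asarray(time, float)
        labels = (t < np.median(t)).astype(int)
    else:
        raise ValueError("mode must be 'event' or 'median'")
    if len(np.unique(labels)) < 2:
        raise ValueError("outcome dichotomization produced a single class")
    return labels


@dataclass
class BERunResult:
    run: int
    selected_analytes: FrozenSet[str]
    loocv_auc: float
    n_selected: int


def _backward_eliminate_once(
    V: np.ndarray,
    y: np.ndarray,
    names: List[str],
    wilcoxon_p: np.ndarray,
    cfg: BEConfig,
) -> Tuple[List[str], float]:
    """One backward-elimination pass; returns (selected names, final AUC)."""
    cur = list(range(len(names)))
    if len(cur) < 2:
        auc = float(_loocv_auc_kernel(np.ascontiguousarray(V), y, cfg.svm_c)) if cur else 0.5
        return [names[i] for i in cur], auc
    auc = float(_loocv_auc_kernel(np.ascontiguousarray(V), y, cfg.svm_c))
    while len(cur) > cfg.min_features:
        sub = np.ascontiguousarray(V[:, cur])
        aucs = _loocv_auc_each_removed(sub, y, cfg.svm_c)
        # best removal; ties prefer the least informative (largest Wilcoxon
        # p), then analyte id order
        order = sorted(
            range(len(cur)),
            key=lambda i: (-aucs[i], -wilcoxon_p[cur[i]], names[cur[i]]),
        )
        best = order[0]
        if aucs[best] >= auc - cfg.auc_tolerance:
            auc = float(aucs[best])
            cur.pop(best)
        else:
            break
    return [names[i] for i in cur], auc


def backward_eliminate(
    X: pd.DataFrame,
    time,
    event,
    candidates: Sequence[str],
    cfg: Optional[BEConfig] = None,
    dichotomize: str = "event",
) -> Tuple[List[BERunResult], FrozenSet[str]]:
    """Repeated SVM/LOOCV backward elimination over seeded subsamples.

    Per run: draw a ``subsample_fraction`` patient subsample, keep
    candidates with Wilcoxon rank-sum p < ``wilcoxon_alpha`` between the
    outcome classes on that subsample, then repeatedly drop the feature
    whose removal maximizes the LOOCV AUC as long as the AUC does not
    fall below the current value minus a tolerance. The consensus is the
    intersection of the selected sets over all runs.
    """
    cfg = cfg or BEConfig()
    candidates = list(candidates)
    if not candidates:
        warnings.warn("empty candidate set: BE consensus is empty")
        return [], frozenset()
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    V_all = impute_and_standardize(X[candidates]).to_numpy()
    n = V_all.shape[0]
    labels_all = dichotomize_outcome(time, event, mode=dichotomize)

    results: List[BERunResult] = []
    consensus: Optional[FrozenSet[str]] = None
    for r in range(cfg.n_runs):
        rng = np.random.default_rng(derive_seed(cfg.rng_seed, f"be_run_{r}"))
        size = max(2, int(round(cfg.subsample_fraction * n)))
        for _ in range(50):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            y = labels_all[idx]
            if 0 < y.sum() < size:
                break
        else:
            raise ValueError("could not draw a two-class subsample")
        V = V_all[idx]
        yy = np.where(y > 0, 1.0, -1.0)

        pvals = np.ones(len(candidates))
        for jc in range(len(candidates)):
            a = V[y == 1, jc]
            b = V[y == 0, jc]
            if np.ptp(V[:, jc]) == 0:
                continue
            pvals[jc] = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        keep = np.where(pvals < cfg.wilcoxon_alpha)[0]
        names = [candidates[j] for j in keep]
        if len(names) == 0:
            results.append(BERunResult(r, frozenset(), 0.5, 0))
            consensus = frozenset() if consensus is None else consensus & frozenset()
            continue
        sel, auc = _backward_eliminate_once(
            V[:, keep], yy, names, pvals[keep], cfg
        )
        fs = frozenset(sel)
        results.append(BERunResult(r, fs, auc, len(fs)))
        consensus = fs if consensus is None else consensus & fs
    return results, consensus if consensus is not None else frozenset()


# --------------------------------------------------------------------------
# clone -> protein deduplication
# --------------------------------------------------------------------------

def dedupe_clones(
    selected_analytes: Sequence[str],
    screen: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse clone-level selections to one representative per protein.

    For proteins hit by multiple clones the clone with the smallest
    univariate Cox p is kept (ties break on clone id). Returns a frame
    with ``protein_id, analyte_id, clone_id, beta, p``.
    """
    ann = annotation.set_index("analyte_id")
    missing = [a for a in selected_analytes if a not in ann.index]
    if missing:
        raise KeyError(f"unannotated analytes: {missing}")
    sc = screen.set_index("analyte_id")
    rows = []
    for a in selected_analytes:
        rows.append(
            dict(
                protein_id=ann.loc[a, "protein_id"],
                analyte_id=a,
                clone_id=ann.loc[a, "clone_id"] if "clone_id" in ann.columns else a,
                beta=sc.loc[a, "beta"] if a in sc.index else np.nan,
                p=sc.loc[a, "p"] if a in sc.index else np.nan,
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["protein_id", "p", "analyte_id"], kind="mergesort")
    return df.groupby("protein_id", sort=True).head(1).reset_index(drop=True)


# --------------------------------------------------------------------------
# elastic-net arm
# --------------------------------------------------------------------------

@dataclass
class ENRResult:
    chosen_alpha: float
    rmse: float
    r2: float
    coefficients: Dict[str, float]
    selected_analytes: List[str]
    per_alpha: pd.DataFrame
    ridge_degenerate: bool = False


def _lambda_grid(Xtr: np.ndarray, ytr: np.ndarray, l1_ratio: float, n_lambda: int) -> np.ndarray:
    """Descending penalty path (lasso-style lambda_max, floored mixing for
    the ridge end of the grid where lambda_max diverges)."""
    n = Xtr.shape[0]
    lam_max = np.abs(Xtr.T @ (ytr - ytr.mean())).max() / (n * max(l1_ratio, 0.05))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_lambda)


def enr_select(
    X: pd.DataFrame,
    time,
    event,
    cfg: Optional[ENRConfig] = None,
) -> ENRResult:
    """Elastic-net selection of analytes against observed survival months.

    The response is the observed time including censored values (a
    documented limitation inherited from the reference procedure; a
    censoring-aware variant can be had by passing only event rows). For
    each mixing parameter alpha the penalty strength is chosen by
    internal cross-validation on the 80% training split and the model is
    scored by RMSE and R^2 on the held-out 20%; the winner has minimum
    RMSE (ties: maximum R^2). Ridge (alpha = 0) cannot produce a sparse
    panel; if chosen it is flagged via ``ridge_degenerate``.
    """
    from sklearn.linear_model import ElasticNetCV
    from sklearn.metrics import r2_score
    from sklearn.model_selection import KFold

    cfg = cfg or ENRConfig()
    time = np.asarray(time, float)
    Z = impute_and_standardize(X)
    V = Z.to_numpy()
    y = time.copy()
    n = V.shape[0]
    rng = np.random.default_rng(derive_seed(cfg.rng_seed, "enr_split"))
    perm = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train, test = perm[:n_train], perm[n_train:]
    if len(test) < 5:
        raise ValueError(
            f"test split has {len(test)} samples (< 5); increase the cohort "
            "or lower train_fraction"
        )
    Xtr, ytr = V[train], y[train]
    Xte, yte = V[test], y[test]

    rows = []
    models = {}
    for a in cfg.alpha_grid:
        lambdas = _lambda_grid(Xtr, ytr, a, cfg.n_lambda)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enet = ElasticNetCV(
                l1_ratio=max(a, 1e-6),
                alphas=lambdas,
                cv=KFold(n_splits=cfg.cv_folds),
                max_iter=5000,
            )
            enet.fit(Xtr, ytr)
        pred = enet.predict(Xte)
        rmse = float(np.sqrt(np.mean((pred - yte) ** 2)))
        r2 = float(r2_score(yte, pred))
        rows.append(dict(alpha=a, lambda_=float(enet.alpha_), rmse=rmse, r2=r2,
                         n_nonzero=int(np.sum(enet.coef_ != 0))))
        models[a] = enet
    per_alpha = pd.DataFrame(rows)

    best = per_alpha.sort_values(["rmse", "r2"], ascending=[True, False],
                                 kind="mergesort").iloc[0]
    a_star = float(best["alpha"])
    model = models[a_star]
    coefs = dict(zip(Z.columns, model.coef_))
    selected = [c for c, v in coefs.items() if v != 0.0]
    ridge_degenerate = a_star == 0.0
    if ridge_degenerate:
        warnings.warn(
            "ridge (alpha=0) chosen: coefficients do not sparsify; "
            "selection degenerates to the full panel"
        )
    return ENRResult(
        chosen_alpha=a_star,
        rmse=float(best["rmse"]),
        r2=float(best["r2"]),
        coefficients=coefs,
        selected_analytes=selected,
        per_alpha=per_alpha,
        ridge_degenerate=ridge_degenerate,
    )


# --------------------------------------------------------------------------
# panel intersection and signature-length comparison
# --------------------------------------------------------------------------

@dataclass
class SignaturePanel:
    """Final protein panel with per-protein univariate Cox weights."""

    protein_ids: List[str]
    representative_clone: Dict[str, str]   # protein -> analyte id
    weights: Dict[str, float]              # protein -> univariate Cox beta

    def __len__(self) -> int:
        return len(self.protein_ids)

    def to_dict(self) -> dict:
        return {
            "proteins": [
                {
                    "protein_id": p,
                    "analyte_id": self.representative_clone[p],
                    "beta": self.weights[p],
                }
                for p in self.protein_ids
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignaturePanel":
        prot = [row["protein_id"] for row in d["proteins"]]
        return cls(
            protein_ids=prot,
            representative_clone={r["protein_id"]: r["analyte_id"] for r in d["proteins"]},
            weights={r["protein_id"]: float(r["beta"]) for r in d["proteins"]},
        )


def intersect_panels(
    coxbe_panel: pd.DataFrame,
    enr_panel: pd.DataFrame,
    screen: pd.DataFrame,
    annotation: pd.DataFrame,
) -> SignaturePanel:
    """Protein-level intersection of the two arms.

    The representative clone (and hence the score weight) is the clone
    with the best univariate Cox p among the clones either arm selected
    for that protein.
    """
    prot_a = set(coxbe_panel["protein_id"]) if len(coxbe_panel) else set()
    prot_b = set(enr_panel["protein_id"]) if len(enr_panel) else set()
    common = sorted(prot_a & prot_b)
    if not common:
        warnings.warn("the two selection arms share no proteins: empty panel")
        return SignaturePanel([], {}, {})
    both = pd.concat([coxbe_panel, enr_panel], ignore_index=True)
    both = both[both["protein_id"].isin(common)]
    best = dedupe_clones(both["analyte_id"].unique().tolist(), screen, annotation)
    best = best[best["protein_id"].isin(common)]
    rep = dict(zip(best["protein_id"], best["analyte_id"]))
    wts = dict(zip(best["protein_id"], best["beta"]))
    return SignaturePanel(protein_ids=sorted(common), representative_clone=rep, weights=wts)


def compare_signature_lengths(
    panels: Dict[str, SignaturePanel],
    X: pd.DataFrame,
    time,
    event,
) -> pd.DataFrame:
    """Rank candidate panels by the prognostic strength of their score.

    For each panel: compute the continuous weighted score, its univariate
    Cox p, and Harrell's C; rank by C (descending) then p (ascending).
    """
    from .scoring import compute_ris
    from .survstats import harrell_c

    if not panels:
        raise ValueError("need at least one candidate panel")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rows = []
    for name, panel in panels.items():
        cols = [panel.representative_clone[p] for p in panel.protein_ids]
        wts = {panel.representative_clone[p]: panel.weights[p] for p in panel.protein_ids}
        Xp = impute_and_standardize(X[cols])
        res = compute_ris(Xp, wts, form="continuous")
        s = res.s_continuous
        try:
            fit = fit_cox_univariate((s - s.mean()) / (s.std(ddof=1) or 1.0), time, event)
            p = fit.p
        except CoxFitError:
            p = np.nan
        c = harrell_c(s, time, event).c
        rows.append(dict(panel=name, n_proteins=len(panel), harrell_c=c, cox_p=p))
    out = pd.DataFrame(rows).sort_values(
        ["harrell_c", "cox_p"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
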