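"""Kaplan-Meier, log-rank, Harrell's C and the optimal-cutpoint search,
each checked against an independent oracle (brute-force recomputation or
lifelines)."""
import itertools

import numpy as np
import pytest

from serosig.survstats import (
    compare_indices,
    harrell_c,
    km_estimate,
    logrank_test,
    optimal_cutpoints,
)
from conftest import make_survival


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def km_bruteforce(time, event):
    """Product-limit by literal risk-set recomputation at every event time."""
    times = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return times, np.array(surv)


def harrell_bruteforce(score, time, event):
    """O(n^2) pair enumeration straight from the definition."""
    n = len(score)
    conc = disc = tied = usable = 0
    for i, j in itertools.permutations(range(n), 2):
        shorter = (time[i] < time[j] and event[i] == 1) or (
            time[i] == time[j] and event[i] == 1 and event[j] == 0
        )
        if not shorter:
            continue
        usable += 1
        if score[i] > score[j]:
            conc += 1
        elif score[i] == score[j]:
            tied += 1
        else:
            disc += 1
    return (conc + 0.5 * tied) / usable, conc, disc, tied, usable


def cutpoints_bruteforce(score, time, event, min_frac=0.10):
    """Double loop over every ordered midpoint pair, scoring each with the
    public log-rank test."""
    uniq = np.unique(score)
    mids = (uniq[:-1] + uniq[1:]) / 2
    n = len(score)
    min_n = int(np.ceil(min_frac * n))
    best = None
    for c1, c2 in itertools.combinations(mids, 2):
        groups = (score > c1).astype(int) + (score > c2).astype(int)
        sizes = np.bincount(groups, minlength=3)
        if sizes.min() < min_n:
            continue
        chi2 = logrank_test(time, event, groups).chi2
        if best is None or chi2 > best[0] + 1e-12:
            best = (chi2, c1, c2)
    return best


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

class TestKM:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate([3.0, 5.0, 8.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_single_death_among_four(self):
        curve = km_estimate([2.0, 4.0, 5.0, 9.0], [1, 0, 0, 0])
        assert curve.survival_at(2.0) == pytest.approx(0.75)
        assert curve.survival_at(9.0) == pytest.approx(0.75)
        assert curve.survival_at(1.0) == 1.0

    def test_matches_bruteforce_product_limit(self):
        for seed in range(5):
            t, e = make_survival(30, seed)
            curve = km_estimate(t, e)
            bt, bs = km_bruteforce(t, e)
            got = np.array([curve.survival_at(x) for x in bt])
            assert np.allclose(got, bs, atol=1e-12)

    def test_closed_form_at_last_event(self):
        t, e = make_survival(50, 3)
        curve = km_estimate(t, e)
        prod = np.prod(1.0 - curve.n_events[curve.n_events > 0] /
                       curve.at_risk[curve.n_events > 0])
        last_event = t[e == 1].max()
        assert curve.survival_at(last_event) == pytest.approx(prod, abs=1e-12)


# --------------------------------------------------------------------------
# log-rank
# --------------------------------------------------------------------------

class TestLogRank:
    def test_relabeled_copies_are_null(self):
        t, e = make_survival(40, 0)
        t3 = np.tile(t, 3)
        e3 = np.tile(e, 3)
        g = np.repeat([0, 1, 2], 40)
        res = logrank_test(t3, e3, g)
        assert res.chi2 < 1e-10
        assert res.df == 2

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(1)
        for seed in range(8):
            t, e = make_survival(60, seed)
            g = rng.integers(0, 3, 60)
            mine = logrank_test(t, e, g)
            ref = multivariate_logrank_test(t, g, e)
            assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariances(self):
        t, e = make_survival(80, 5)
        g = (np.arange(80) % 2)
        base = logrank_test(t, e, g).chi2
        relabeled = logrank_test(t, e, 1 - g).chi2
        transformed = logrank_test(np.exp(t / 10), e, g).chi2
        assert relabeled == pytest.approx(base, rel=1e-12)
        assert transformed == pytest.approx(base, rel=1e-12)

    def test_power_under_threefold_hazard(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tA = rng.exponential(1 / 0.05, 100)
            tB = rng.exponential(1 / 0.15, 100)
            t = np.concatenate([tA, tB])
            e = np.ones(200, dtype=int)
            g = np.repeat([0, 1], 100)
            if logrank_test(t, e, g).p < 0.001:
                hits += 1
        assert hits >= 190

    def test_group_requirements(self):
        t, e = make_survival(10, 0)
        with pytest.raises(ValueError):
            logrank_test(t, e, np.zeros(10))


# --------------------------------------------------------------------------
# Harrell's C
# --------------------------------------------------------------------------

class TestHarrellC:
    def test_perfect_score(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = harrell_c(-t, t, np.ones(5, dtype=int))
        assert res.c == 1.0

    def test_constant_score(self):
        t, e = make_survival(20, 2)
        res = harrell_c(np.zeros(20), t, e)
        assert res.c == 0.5
        assert res.n_tied == res.n_usable

    def test_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            t, e = make_survival(40, seed)
            s = rng.normal(size=40)
            mine = harrell_c(s, t, e)
            c, conc, disc, tied, usable = harrell_bruteforce(s, t, e)
            assert mine.c == c
            assert (mine.n_concordant, mine.n_discordant, mine.n_tied,
                    mine.n_usable) == (conc, disc, tied, usable)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        t, e = make_survival(50, 3)
        s = rng.normal(size=50)
        assert harrell_c(s, t, e).c == pytest.approx(1.0 - harrell_c(-s, t, e).c)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(4)
        t, e = make_survival(60, 4)
        s = rng.normal(size=60)
        # lifelines treats higher predictions as longer survival
        assert harrell_c(s, t, e).c == pytest.approx(concordance_index(t, -s, e))

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            harrell_c(np.arange(5.0), np.arange(5.0) + 1, np.zeros(5, dtype=int))


# --------------------------------------------------------------------------
# optimal cutpoints
# --------------------------------------------------------------------------

class TestOptimalCutpoints:
    def test_matches_bruteforce_double_loop(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            s = rng.normal(size=60)
            t, e = make_survival(60, seed, lp=0.8 * s)
            res = optimal_cutpoints(s, t, e)
            chi2, c1, c2 = cutpoints_bruteforce(s, t, e)
            assert res.cutpoints == (pytest.approx(c1), pytest.approx(c2))
            assert res.chi2 == pytest.approx(chi2, rel=1e-9)

    def test_recovers_separated_clusters(self):
        """Three well-separated score clusters with 4-fold hazard steps:
        the optimized stratification recovers the true clustering (the
        argmax can shift by a few ranks into a cluster, so recovery is
        scored by assignment accuracy)."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = np.concatenate([
                rng.normal(0, 0.3, 50), rng.normal(4, 0.3, 50),
                rng.normal(8, 0.3, 50),
            ])
            true_groups = np.repeat([0, 1, 2], 50)
            lp = np.repeat([0.0, np.log(4), 2 * np.log(4)], 50)
            t, e = make_survival(150, seed + 100, hazard=0.04, lp=lp,
                                 censor_hazard=0.005, admin=60.0)
            res = optimal_cutpoints(s, t, e)
            if (res.groups == true_groups).mean() >= 0.9:
                hits += 1
        assert hits >= 9

    def test_monotone_transform_keeps_groups(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=70)
        t, e = make_survival(70, 9, lp=0.7 * s)
        a = optimal_cutpoints(s, t, e)
        b = optimal_cutpoints(s**3, t, e)
        assert np.array_equal(a.groups, b.groups)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)

    def test_objective_equals_public_logrank(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=50)
        t, e = make_survival(50, 2, lp=s)
        res = optimal_cutpoints(s, t, e)
        assert res.chi2 == pytest.approx(logrank_test(t, e, res.groups).chi2)

    def test_group_size_constraint_and_feasibility(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        t, e = make_survival(40, 5)
        res = optimal_cutpoints(s, t, e, min_frac=0.2)
        assert min(res.group_sizes) >= 8
        with pytest.raises(ValueError):
            optimal_cutpoints(np.array([1.0, 1.0, 2.0, 2.0]), *make_survival(4, 1))

    def test_two_group_variant(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=60)
        t, e = make_survival(60, 6, lp=s)
        res = optimal_cutpoints(s, t, e, n_groups=2)
        assert len(res.cutpoints) == 1
        assert res.df == 1


# --------------------------------------------------------------------------
# index comparison
# --------------------------------------------------------------------------

class TestCompareIndices:
    def test_duplicated_index_gives_identical_rows(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        t, e = make_survival(60, 0, lp=s)
        rep = compare_indices({"a": s, "b": s.copy()}, t, e)
        cols = ["harrell_c", "logrank_chi2", "c1", "c2"]
        assert rep.loc[0, cols].tolist() == rep.loc[1, cols].tolist()

    def test_true_predictor_beats_noisy_copy(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lp = rng.normal(size=100)
            t, e = make_survival(100, seed + 50, lp=lp)
            noisy = lp + rng.normal(scale=2.0, size=100)
            rep = compare_indices({"true": lp, "noisy": noisy}, t, e).set_index("index")
            if rep.loc["true", "harrell_c"] >= rep.loc["noisy", "harrell_c"]:
                wins += 1
        assert wins >= 9

    def test_missing_scores_are_dropped(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=60)
        s[:5] = np.nan
        t, e = make_survival(60, 1, lp=np.nan_to_num(s))
        rep = compare_indices({"s": s}, t, e)
        assert rep.loc[0, "n"] == 55
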