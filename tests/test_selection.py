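"""Consensus selection: Cox screen, BE wrapper, clone deduplication,
elastic net and panel intersection."""
import warnings

import numpy as np
import pandas as pd
import pytest

from serosig import BEConfig, ENRConfig
from serosig.selection import (
    SignaturePanel,
    backward_eliminate,
    compare_signature_lengths,
    cox_screen,
    dedupe_clones,
    dichotomize_outcome,
    enr_select,
    impute_and_standardize,
    intersect_panels,
)
from conftest import make_survival


def planted_frame(n, n_noise, seed, beta=-1.0):
    """One informative column ('sig') among noise columns, with survival
    driven by the informative one."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise)),
        columns=[f"N{i:03d}" for i in range(n_noise)],
    )
    X.insert(0, "sig", z)
    t, e = make_survival(n, seed + 1000, lp=beta * z)
    return X, t, e


class TestCoxScreen:
    def test_planted_analyte_detected_with_correct_beta(self):
        """A single planted analyte at per-SD log-HR -1.0 is recovered:
        every seed detects it, each estimate lies within ~3.5 SE of the
        truth, and the 10-seed mean is within 0.1."""
        betas = []
        for seed in range(10):
            X, t, e = planted_frame(500, 3, seed)
            table = cox_screen(X, t, e, compute_ph=False).set_index("analyte_id")
            beta = table.loc["sig", "beta"]
            betas.append(beta)
            assert -1.35 <= beta <= -0.65
            assert table.loc["sig", "p"] < 0.05
            assert table.loc["sig", "passed"]
        assert -1.1 <= np.mean(betas) <= -0.9

    def test_standardization_invariance(self):
        X, t, e = planted_frame(200, 2, 3)
        a = cox_screen(X, t, e, compute_ph=False)
        X2 = X.copy()
        X2["sig"] = X2["sig"] * 731.0
        b = cox_screen(X2, t, e, compute_ph=False)
        pa = a.set_index("analyte_id").loc["sig", "p"]
        pb = b.set_index("analyte_id").loc["sig", "p"]
        assert pa == pytest.approx(pb, rel=1e-9)

    def test_constant_analyte_skipped_with_warning(self):
        X, t, e = planted_frame(100, 2, 4)
        X["const"] = 5.0
        with pytest.warns(UserWarning, match="const"):
            table = cox_screen(X, t, e, compute_ph=False)
        row = table.set_index("analyte_id").loc["const"]
        assert not row["passed"] and np.isnan(row["p"])

    def test_ph_flag_reported_not_excluding(self):
        X, t, e = planted_frame(150, 2, 5)
        table = cox_screen(X, t, e, compute_ph=True)
        passed = table[table["passed"]]
        assert passed["ph_p"].notna().all()
        assert "ph_flag" in table.columns

    def test_too_few_events_rejected(self):
        X, t, e = planted_frame(50, 2, 6)
        with pytest.raises(ValueError):
            cox_screen(X, t, np.zeros_like(e), compute_ph=False)

    def test_missing_values_imputed(self):
        X, t, e = planted_frame(200, 2, 7)
        X.iloc[:5, 1] = np.nan
        table = cox_screen(X, t, e, compute_ph=False)
        assert table["beta"].notna().all()


class TestDichotomize:
    def test_event_mode_counts(self):
        t, e = make_survival(44, 1)
        labels = dichotomize_outcome(t, e, mode="event")
        assert labels.sum() == e.sum()

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_outcome(np.arange(10.0) + 1, np.zeros(10, int))

    def test_median_mode_balanced(self):
        t = np.arange(1.0, 21.0)
        labels = dichotomize_outcome(t, np.ones(20, int), mode="median")
        assert abs(labels.sum() - 10) <= 1


class TestBackwardEliminate:
    def test_single_run_full_sample_equals_consensus(self):
        X, t, e = planted_frame(80, 5, 2)
        cfg = BEConfig(n_runs=1, subsample_fraction=1.0, rng_seed=0)
        runs, consensus = backward_eliminate(X, t, e, list(X.columns), cfg)
        assert consensus == runs[0].selected_analytes
        assert 0.0 <= runs[0].loocv_auc <= 1.0

    def test_informative_candidate_survives_consensus(self):
        hits = 0
        for seed in range(10):
            X, t, e = planted_frame(100, 9, seed, beta=-1.2)
            cfg = BEConfig(rng_seed=seed)
            _, consensus = backward_eliminate(X, t, e, list(X.columns), cfg)
            if "sig" in consensus:
                hits += 1
        assert hits >= 9

    def test_all_noise_consensus_collapses(self):
        small = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(100, 10)),
                             columns=[f"N{i}" for i in range(10)])
            t, e = make_survival(100, seed + 500)
            cfg = BEConfig(rng_seed=seed)
            _, consensus = backward_eliminate(X, t, e, list(X.columns), cfg)
            if len(consensus) <= 1:
                small += 1
        assert small >= 8

    def test_empty_candidates_warn(self):
        X, t, e = planted_frame(50, 2, 0)
        with pytest.warns(UserWarning, match="empty"):
            runs, consensus = backward_eliminate(X, t, e, [], BEConfig())
        assert consensus == frozenset() and runs == []

    def test_consensus_monotone_in_runs(self):
        """Adding runs can only shrink the all-runs intersection (runs are
        seeded per index, so a longer schedule extends the same runs)."""
        X, t, e = planted_frame(90, 6, 11, beta=-1.0)
        cons = {}
        for n_runs in (4, 8, 12):
            cfg = BEConfig(n_runs=n_runs, rng_seed=3)
            _, cons[n_runs] = backward_eliminate(X, t, e, list(X.columns), cfg)
        assert cons[12] <= cons[8] <= cons[4]


class TestDedupeClones:
    def setup_method(self):
        self.annotation = pd.DataFrame(
            {
                "analyte_id": ["A1", "A2", "A3"],
                "clone_id": ["P1_c1", "P1_c2", "P2_c1"],
                "protein_id": ["P1", "P1", "P2"],
            }
        )
        self.screen = pd.DataFrame(
            {"analyte_id": ["A1", "A2", "A3"], "beta": [-1.0, -0.8, -0.5],
             "p": [0.01, 0.03, 0.02]}
        )

    def test_superior_p_clone_kept(self):
        out = dedupe_clones(["A1", "A2", "A3"], self.screen, self.annotation)
        assert len(out) == 2
        assert out.set_index("protein_id").loc["P1", "analyte_id"] == "A1"

    def test_no_duplicates_identity(self):
        out = dedupe_clones(["A1", "A3"], self.screen, self.annotation)
        assert set(out["analyte_id"]) == {"A1", "A3"}

    def test_unannotated_clone_rejected(self):
        with pytest.raises(KeyError):
            dedupe_clones(["A9"], self.screen, self.annotation)

    def test_duplicated_protein_reduces_count(self):
        # 3 selected analytes over 2 proteins -> 2 representatives
        out = dedupe_clones(["A1", "A2", "A3"], self.screen, self.annotation)
        assert out["protein_id"].nunique() == len(out) == 2


class TestENR:
    def test_ridge_only_grid_is_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 20)))
        X.columns = [f"A{i}" for i in range(20)]
        t, e = make_survival(60, 1)
        cfg = ENRConfig(alpha_grid=(0.0,), rng_seed=0)
        with pytest.warns(UserWarning, match="ridge"):
            res = enr_select(X, t, e, cfg)
        assert res.ridge_degenerate
        assert len(res.selected_analytes) == 20

    def test_planted_signal_selected_sparsely(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=(150, 5))
            noise = rng.normal(size=(150, 45))
            X = pd.DataFrame(np.hstack([z, noise]),
                             columns=[f"S{i}" for i in range(5)]
                             + [f"N{i}" for i in range(45)])
            t, e = make_survival(150, seed + 30, lp=-0.8 * z.sum(axis=1))
            res = enr_select(X, t, e, ENRConfig(rng_seed=seed))
            sel = set(res.selected_analytes)
            if len(sel & {f"S{i}" for i in range(5)}) >= 4:
                hits += 1
        assert hits >= 4

    def test_tiny_test_split_rejected(self):
        X, t, e = planted_frame(20, 3, 0)
        with pytest.raises(ValueError, match="test split"):
            enr_select(X, t, e, ENRConfig(rng_seed=0))


class TestIntersect:
    def make_panel_df(self, proteins):
        return pd.DataFrame(
            {"protein_id": list(proteins),
             "analyte_id": [f"{p}_a" for p in proteins],
             "beta": [-1.0] * len(proteins), "p": [0.01] * len(proteins)}
        )

    def setup_method(self):
        prot = ["PA", "PB", "PC", "PD"]
        self.annotation = pd.DataFrame(
            {"analyte_id": [f"{p}_a" for p in prot],
             "clone_id": [f"{p}_c1" for p in prot], "protein_id": prot}
        )
        self.screen = pd.DataFrame(
            {"analyte_id": [f"{p}_a" for p in prot],
             "beta": [-1.0, -0.9, -0.8, -0.7], "p": [0.01, 0.02, 0.03, 0.04]}
        )

    def test_set_intersection(self):
        panel = intersect_panels(
            self.make_panel_df(["PA", "PB", "PC"]),
            self.make_panel_df(["PB", "PC", "PD"]),
            self.screen, self.annotation,
        )
        assert panel.protein_ids == ["PB", "PC"]
        assert panel.weights["PB"] == pytest.approx(-0.9)

    def test_disjoint_panels_warn_empty(self):
        with pytest.warns(UserWarning, match="no proteins"):
            panel = intersect_panels(
                self.make_panel_df(["PA"]), self.make_panel_df(["PD"]),
                self.screen, self.annotation,
            )
        assert len(panel) == 0

    def test_panel_roundtrip(self):
        panel = intersect_panels(
            self.make_panel_df(["PA", "PB"]), self.make_panel_df(["PB"]),
            self.screen, self.annotation,
        )
        again = SignaturePanel.from_dict(panel.to_dict())
        assert again.protein_ids == panel.protein_ids
        assert again.weights == panel.weights


class TestCompareSignatureLengths:
    def make_data(self, seed, n=120, n_sig=4, n_noise=20):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(n, n_sig))
        noise = rng.normal(size=(n, n_noise))
        cols = [f"S{i}" for i in range(n_sig)] + [f"N{i}" for i in range(n_noise)]
        X = pd.DataFrame(np.hstack([z, noise]), columns=cols)
        t, e = make_survival(n, seed + 60, lp=-0.9 * z.sum(axis=1))
        return X, t, e

    @staticmethod
    def panel_of(cols):
        return SignaturePanel(
            protein_ids=list(cols),
            representative_clone={c: c for c in cols},
            weights={c: -1.0 for c in cols},
        )

    def test_clean_panel_beats_noise_padded(self):
        wins = 0
        for seed in range(10):
            X, t, e = self.make_data(seed)
            clean = self.panel_of([f"S{i}" for i in range(4)])
            padded = self.panel_of([f"S{i}" for i in range(4)]
                                   + [f"N{i}" for i in range(5)])
            rank = compare_signature_lengths(
                {"clean": clean, "padded": padded}, X, t, e
            )
            if rank.iloc[0]["panel"] == "clean":
                wins += 1
        assert wins >= 8

    def test_planted_beats_random_panel(self):
        wins = 0
        for seed in range(10):
            X, t, e = self.make_data(seed)
            planted = self.panel_of([f"S{i}" for i in range(4)])
            random_panel = self.panel_of([f"N{i}" for i in range(4)])
            rank = compare_signature_lengths(
                {"planted": planted, "random": random_panel}, X, t, e
            ).set_index("panel")
            if rank.loc["planted", "harrell_c"] > rank.loc["random", "harrell_c"]:
                wins += 1
        assert wins >= 9

    def test_single_panel_rank_one(self):
        X, t, e = self.make_data(0)
        rank = compare_signature_lengths(
            {"only": self.panel_of(["S0", "S1"])}, X, t, e
        )
        assert rank.loc[0, "rank"] == 1


def test_impute_and_standardize_contract():
    X = pd.DataFrame({"a": [1.0, 2.0, np.nan, 3.0], "b": [5.0] * 4})
    Z = impute_and_standardize(X)
    assert np.isfinite(Z.to_numpy()).all()
    assert Z["a"].mean() == pytest.approx(0.0)
    assert Z["a"].std(ddof=1) == pytest.approx(1.0)
    assert (Z["b"] == 0.0).all()
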