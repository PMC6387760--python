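"""Lambda, PGLS, grade ANCOVA and conditional error probabilities."""

import math
import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frusta.phylo import (PGLS, DataError, GradeComparison, PhylANCOVA,
                          bm_covariance, calibrate_tree,
                          conditional_error_probability, estimate_lambda,
                          load_printed_ancova_table, tree_from_newick)
from frusta.synthetic import simulate_traits, simulate_tree

PRINTED_ALPHA_PAIRS = [
    (0.0014, 0.0244), (0.0004, 0.0084), (0.0024, 0.0379), (0.0013, 0.0229),
    (0.0011, 0.0200), (0.0005, 0.0102), (0.9421, 0.1325), (0.9301, 0.1548),
    (0.7044, 0.4015), (0.6938, 0.4081), (0.077, 0.3492),
]


class TestConditionalErrorProbability:
    def test_canonical_values(self):
        assert conditional_error_probability(0.05) == pytest.approx(0.289, abs=5e-4)
        assert conditional_error_probability(0.001) == pytest.approx(0.0184, abs=5e-5)

    @pytest.mark.parametrize("p,alpha", PRINTED_ALPHA_PAIRS)
    def test_reproduces_printed_pairs(self, p, alpha):
        assert round(conditional_error_probability(p), 4) == pytest.approx(alpha, abs=1e-4)

    def test_exactly_half_at_one_over_e(self):
        assert conditional_error_probability(1 / math.e) == pytest.approx(0.5, rel=1e-12)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                conditional_error_probability(bad)

    @settings(derandomize=True, max_examples=30)
    @given(p=st.floats(1e-8, 1 / math.e - 1e-6), dp=st.floats(1e-7, 0.05))
    def test_monotone_below_one_over_e(self, p, dp):
        hi = min(p + dp, 1 / math.e)
        assert conditional_error_probability(hi) >= conditional_error_probability(p)

    def test_printed_table_fixture_is_self_consistent(self):
        table = load_printed_ancova_table()
        for _, row in table.iterrows():
            assert round(conditional_error_probability(row["p"]), 4) == pytest.approx(
                row["alpha_printed"], abs=1e-4)


class TestCovariance:
    def test_lambda_zero_is_diagonal(self, yule_tree_20):
        _, V = bm_covariance(yule_tree_20, 0.0)
        assert np.allclose(V - np.diag(np.diag(V)), 0.0)

    def test_lambda_one_untransformed_and_psd(self, yule_tree_20):
        for lam in (0.0, 0.4, 1.0):
            _, V = bm_covariance(yule_tree_20, lam)
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() > -1e-8 * V.max()

    def test_four_tip_hand_computed(self):
        tree = tree_from_newick("((A:2,B:2):3,(C:4,D:4):1);")
        taxa, V = bm_covariance(tree, 1.0, taxa=["A", "B", "C", "D"])
        expected = np.array([
            [5.0, 3.0, 0.0, 0.0],
            [3.0, 5.0, 0.0, 0.0],
            [0.0, 0.0, 5.0, 1.0],
            [0.0, 0.0, 1.0, 5.0],
        ])
        np.testing.assert_allclose(V, expected, atol=1e-12)


class TestCalibration:
    OCC = {"A": (80.0, 75.0), "B": (75.0, 70.0), "C": (90.0, 85.0), "D": (85.0, 80.0)}

    def test_branches_positive(self):
        tree = calibrate_tree("((A,B),(C,D));", self.OCC)
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0

    def test_missing_dates_and_reversed_dates_rejected(self):
        with pytest.raises(DataError, match="no occurrence"):
            calibrate_tree("(A,B);", {"A": (80.0, 75.0)})
        with pytest.raises(DataError, match="FAD"):
            calibrate_tree("(A,B);", {"A": (70.0, 75.0), "B": (80.0, 75.0)})

    def test_polytomy_resolved_with_epsilon_and_equal_covariances(self):
        occ = {t: (70.0, 65.0) for t in "ABC"}
        occ["OUT"] = (90.0, 85.0)
        tree = calibrate_tree("((A,B,C),OUT);", occ, epsilon=1e-4)
        taxa, V = bm_covariance(tree, 1.0, taxa=["A", "B", "C"])
        off = [V[0, 1], V[0, 2], V[1, 2]]
        assert max(off) - min(off) <= 2e-4
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0

    def test_patristic_distances_match_path_sum_oracle(self):
        tree = calibrate_tree("((A,B),(C,D));", self.OCC)
        # independent oracle: sum of edge lengths along root-to-tip paths,
        # minus twice the shared root-to-MRCA depth
        taxa, V = bm_covariance(tree, 1.0)
        pdm = tree.phylogenetic_distance_matrix()
        taxon_by_label = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i >= j:
                    continue
                expected = V[i, i] + V[j, j] - 2 * V[i, j]
                got = pdm.patristic_distance(taxon_by_label[a], taxon_by_label[b])
                assert got == pytest.approx(expected, abs=1e-9)


class TestLambdaEstimation:
    def test_bm_traits_give_high_lambda_permuted_give_low(self, yule_tree_50):
        rng = np.random.default_rng(5)
        lams, lams_perm = [], []
        for rep in range(20):
            tr = simulate_traits(yule_tree_50, lam=1.0, slope=0.0, intercept=0.0,
                                 rate=1.0, seed=100 + rep)
            lams.append(estimate_lambda(tr["y"], yule_tree_50).lambda_)
            shuffled = tr["y"].to_numpy().copy()
            rng.shuffle(shuffled)
            lams_perm.append(
                estimate_lambda(pd.Series(shuffled, index=tr.index), yule_tree_50).lambda_)
        assert np.median(lams) > 0.9
        assert np.median(lams_perm) < 0.2

    def test_constant_trait_flagged(self, yule_tree_20):
        taxa, _ = bm_covariance(yule_tree_20)
        with pytest.raises(DataError, match="constant"):
            estimate_lambda(pd.Series(1.0, index=taxa), yule_tree_20)

    def test_loglik_at_lambda1_matches_independent_gls_formula(self, yule_tree_20):
        tr = simulate_traits(yule_tree_20, lam=1.0, slope=0.0, intercept=0.0,
                             rate=0.5, seed=3)
        res = estimate_lambda(tr["y"], yule_tree_20)
        # independent GLS likelihood at lambda = 1 via explicit inverses
        taxa, V = bm_covariance(yule_tree_20, 1.0)
        y = tr.loc[taxa, "y"].to_numpy()
        n = y.size
        Vinv = np.linalg.inv(V)
        one = np.ones(n)
        mu = (one @ Vinv @ y) / (one @ Vinv @ one)
        r = y - mu
        sigma2 = (r @ Vinv @ r) / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2)
                     + np.linalg.slogdet(V)[1] + n)
        assert res.loglik_lambda1 == pytest.approx(ll, abs=1e-8)

    def test_ml_lambda_beats_boundaries(self, yule_tree_50):
        tr = simulate_traits(yule_tree_50, lam=0.6, slope=0.0, intercept=0.0,
                             rate=1.0, seed=42)
        res = estimate_lambda(tr["y"], yule_tree_50)
        assert res.loglik >= res.loglik_lambda0 - 1e-9
        assert res.loglik >= res.loglik_lambda1 - 1e-9


class TestPGLS:
    def test_lambda_zero_equals_ols(self, yule_tree_20):
        tr = simulate_traits(yule_tree_20, lam=1.0, seed=9)
        fit = PGLS(tr["y"], tr["x"], yule_tree_20).fit(lambda_=0.0)
        # tips share a common depth on this ultrametric simulated tree, so
        # lambda = 0 whitening is a scalar multiple of the identity
        beta_ols = np.polyfit(tr["x"], tr["y"], 1)
        assert fit.slope == pytest.approx(beta_ols[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta_ols[1], abs=1e-10)

    def test_star_tree_equals_ols_for_any_lambda(self):
        star = tree_from_newick("(A:10,B:10,C:10,D:10,E:10,F:10);")
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=6), index=list("ABCDEF"))
        x = pd.Series(rng.normal(size=6), index=list("ABCDEF"))
        beta_ols = np.polyfit(x, y, 1)
        for lam in (0.0, 0.5, 1.0):
            fit = PGLS(y, x, star).fit(lambda_=lam)
            assert fit.slope == pytest.approx(beta_ols[0], abs=1e-10)

    def test_five_tip_closed_form_gls_oracle(self):
        tree = tree_from_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        taxa, V = bm_covariance(tree, 1.0)
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = 1.5 - 0.8 * x + rng.normal(size=5)
        fit = PGLS(y, x, tree, taxa=taxa).fit(lambda_=1.0)
        X = np.column_stack([np.ones(5), x])
        Vinv = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv @ y
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)

    def test_slope_ci_coverage_calibrated(self, yule_tree_50):
        hits = 0
        reps = 500
        for rep in range(reps):
            tr = simulate_traits(yule_tree_50, lam=1.0, slope=-1.0, intercept=2.9,
                                 rate=0.01, seed=2000 + rep)
            fit = PGLS(tr["y"], tr["x"], yule_tree_50).fit(lambda_=1.0)
            lo, hi = fit.conf_int()[1]
            hits += lo <= -1.0 <= hi
        assert hits / reps >= 0.93

    def test_rank_deficient_design_rejected(self, yule_tree_20):
        tr = simulate_traits(yule_tree_20, seed=1)
        x2 = np.column_stack([tr["x"], 2 * tr["x"]])
        with pytest.raises(np.linalg.LinAlgError):
            PGLS(tr["y"].to_numpy(), x2, yule_tree_20, taxa=list(tr.index))

    def test_prediction_interval_wider_than_confidence(self, yule_tree_20):
        tr = simulate_traits(yule_tree_20, seed=12)
        frame = PGLS(tr["y"], tr["x"], yule_tree_20).fit(lambda_=1.0).prediction_frame()
        assert (frame["pi_high"] >= frame["ci_high"]).all()
        assert (frame["pi_low"] <= frame["ci_low"]).all()

    def test_summary_mentions_lambda_and_slope(self, yule_tree_20):
        tr = simulate_traits(yule_tree_20, seed=12)
        text = PGLS(tr["y"], tr["x"], yule_tree_20).fit(lambda_=1.0).summary()
        assert "lambda" in text and "x1" in text


class TestPhylANCOVA:
    @staticmethod
    def _two_groups(tree, seed=0):
        taxa, _ = bm_covariance(tree)
        rng = np.random.default_rng(seed)
        g = np.array(["g0"] * len(taxa), dtype=object)
        g[rng.permutation(len(taxa))[: len(taxa) // 2]] = "g1"
        return taxa, g

    COMP = [GradeComparison("g1_vs_g0", {"g0": "g0", "g1": "g1"}, None)]

    def test_injected_grade_offset_detected(self, yule_tree_20):
        taxa, g = self._two_groups(yule_tree_20, seed=4)
        detected = 0
        for rep in range(10):
            tr = simulate_traits(yule_tree_20, lam=1.0, slope=-1.0, intercept=2.9,
                                 rate=1e-4, seed=300 + rep,
                                 groups=dict(zip(taxa, g)),
                                 grade_offsets={"g1": 0.4})
            rep_out = PhylANCOVA(tr["y"].to_numpy(), tr["x"].to_numpy(), yule_tree_20,
                                 tr["group"].to_numpy(), taxa=list(tr.index)).fit(self.COMP)
            detected += rep_out.rows[0].p < 0.001
        assert detected >= 6

    def test_f_invariant_to_affine_rescaling_of_y(self, yule_tree_20):
        taxa, g = self._two_groups(yule_tree_20, seed=5)
        tr = simulate_traits(yule_tree_20, seed=77, groups=dict(zip(taxa, g)))
        y = tr["y"].to_numpy()
        base = PhylANCOVA(y, tr["x"].to_numpy(), yule_tree_20,
                          tr["group"].to_numpy(), taxa=list(tr.index)).fit(self.COMP)
        scaled = PhylANCOVA(3.7 * y + 11.0, tr["x"].to_numpy(), yule_tree_20,
                            tr["group"].to_numpy(), taxa=list(tr.index)).fit(self.COMP)
        assert scaled.rows[0].F == pytest.approx(base.rows[0].F, rel=1e-6)

    def test_collinear_full_model_gives_zero_f(self, yule_tree_20):
        taxa, _ = bm_covariance(yule_tree_20)
        g = np.array(["same"] * len(taxa), dtype=object)
        tr = simulate_traits(yule_tree_20, seed=6)
        comp = [GradeComparison("degenerate", {"same": "same"}, None)]
        rep = PhylANCOVA(tr["y"].to_numpy(), tr["x"].to_numpy(), yule_tree_20, g,
                         taxa=list(tr.index)).fit(comp)
        assert rep.rows[0].F == 0.0 and rep.rows[0].p == 1.0

    def test_small_grade_rejected(self, yule_tree_20):
        taxa, _ = bm_covariance(yule_tree_20)
        g = np.array(["g0"] * len(taxa), dtype=object)
        g[0] = "tiny"
        tr = simulate_traits(yule_tree_20, seed=6)
        comp = [GradeComparison("c", {"g0": "g0", "tiny": "tiny"}, None)]
        with pytest.raises(DataError, match="fewer than 2"):
            PhylANCOVA(tr["y"].to_numpy(), tr["x"].to_numpy(), yule_tree_20, g,
                       taxa=list(tr.index)).fit(comp)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstR:
    def test_pgls_slope_matches_ape_gls(self, tmp_path, yule_tree_20):
        """Independent oracle: R {ape}/{nlme} GLS with Brownian correlation."""
        tr = simulate_traits(yule_tree_20, lam=1.0, slope=-1.0, intercept=2.9,
                             rate=0.01, seed=21)
        newick = yule_tree_20.as_string(schema="newick", suppress_rooting=True)
        (tmp_path / "tree.nwk").write_text(newick)
        tr.to_csv(tmp_path / "traits.csv")
        script = tmp_path / "pgls.R"
        script.write_text(
            'suppressMessages({library(ape); library(nlme)})\n'
            f'tree <- read.tree("{tmp_path}/tree.nwk")\n'
            f'd <- read.csv("{tmp_path}/traits.csv", row.names = 1)\n'
            'd <- d[tree$tip.label, ]\n'
            'fit <- gls(y ~ x, data = d,\n'
            '           correlation = corBrownian(1, tree, form = ~1))\n'
            'cat(coef(fit)[1], coef(fit)[2], "\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=300)
        assert out.returncode == 0, out.stderr
        r_int, r_slope = map(float, out.stdout.split())
        fit = PGLS(tr["y"], tr["x"], yule_tree_20).fit(lambda_=1.0)
        assert fit.slope == pytest.approx(r_slope, abs=1e-6)
        assert fit.intercept == pytest.approx(r_int, abs=1e-6)
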