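"""PCA screening, OSC, NIPALS PLS-DA, Q2, permutations, VIP, Kruskal-Wallis."""

import numpy as np
import pytest

import fingernet as fn
from fingernet.chemometrics import (
    PLSDA,
    cross_validated_q2,
    kruskal_wallis,
    osc_filter,
    pca_screen,
    permutation_test,
    vip_scores,
)
from fingernet.chemometrics.pls import PLSDAResults, VIPResult
from fingernet.design import StudyDesign


def two_groups(n=12, seed=0):
    return StudyDesign.from_group_sizes({"A_ctrl": n, "B_high": n}, "A_ctrl")


class TestPCAScreen:
    def test_line_data_one_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.outer(t, [1.0, 2.0, -0.5])
        res = pca_screen(X - X.mean(0), 1, 0.05)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        X[7] += 10.0 * np.array([1, 1, 0, 0, 0, 0]) / np.sqrt(2)
        X -= X.mean(0)
        res = pca_screen(X, 2, 0.05)
        assert res.outlier_flags[7]
        # T2 of the displaced sample computed directly matches
        lam = np.linalg.svd(X, compute_uv=False) ** 2 / (len(X) - 1)
        t2_direct = (res.scores[7] ** 2 / lam[:2]).sum()
        assert res.t2[7] == pytest.approx(t2_direct)

    def test_alpha_one_flags_everything(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        X -= X.mean(0)
        res = pca_screen(X, 2, 1.0)
        assert res.outlier_flags.all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca_screen(np.zeros((2, 4)), 1, 0.05)


@pytest.fixture(scope="module")
def planted():
    """Class signal plus a strong rank-one confounder orthogonal to labels."""
    design = StudyDesign.from_group_sizes({"ctrl": 20, "high": 20}, "ctrl")
    sig = fn.SignatureSpec("m", (2.0,), {"high": 2.0})
    m = fn.simulate_spectra(design, [sig], n_bins=100, noise_sd=1.0,
                            confounder_sd=5.0, seed=21, size_factor_sd=0.0)
    X = m.intensities - m.intensities.mean(0)
    return design, X


class TestOSC:
    def test_removed_scores_orthogonal_to_dummy(self, planted):
        design, X = planted
        res = osc_filter(X, design, n_osc=1)
        Y, _ = design.indicator_matrix(center=True)
        for j in range(Y.shape[1]):
            r = np.corrcoef(res.removed_scores[:, 0], Y[:, j])[0, 1]
            assert abs(r) < 1e-6

    def test_reconstruction_exact(self, planted):
        design, X = planted
        res = osc_filter(X, design, n_osc=2)
        recon = res.filtered_X + res.removed_scores @ res.removed_loadings.T
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_variance_removed_matches_planted_confounder(self, planted):
        """First removed component captures about the planted confounder's
        variance share (within 20% relative).  The planted share is measured
        directly by differencing runs with and without the confounder on the
        same noise stream."""
        design, X = planted
        res = osc_filter(X, design, n_osc=1)
        sig = fn.SignatureSpec("m", (2.0,), {"high": 2.0})
        m0 = fn.simulate_spectra(design, [sig], n_bins=100, noise_sd=1.0,
                                 confounder_sd=0.0, seed=21, size_factor_sd=0.0)
        conf = (X + m0.intensities.mean(0)) - m0.intensities  # the planted s v'
        conf -= conf.mean(0)
        share = float((conf**2).sum() / (X**2).sum())
        assert res.variance_removed[0] == pytest.approx(share, rel=0.20)

    def test_no_confounder_does_not_hurt_q2(self):
        """With no planted confounder, OSC removes little variance and the
        downstream Q2 drops by at most 0.05."""
        design = fn.default_design(("BPA",))
        sigs = fn.demo_signatures(design, effect=3.0, seed=31)
        m = fn.simulate_spectra(design, sigs, n_bins=120, noise_sd=1.0,
                                confounder_sd=0.0, seed=31)
        X = fn.scale(fn.normalize_total_area(m), "center_pareto").intensities
        res = osc_filter(X, design, n_osc=1)
        q2_before, _ = cross_validated_q2(X, design, 2, folds=7, seed=0)
        q2_after, _ = cross_validated_q2(res.filtered_X, design, 2, folds=7, seed=0)
        # class signal share of variance is larger than what OSC removed
        class_share = 1 - (res.filtered_X**2).sum() / (X**2).sum()
        assert res.variance_removed[0] < 0.5
        assert q2_after[-1] > q2_before[-1] - 0.05

    def test_zero_components_requested(self, planted):
        design, X = planted
        with pytest.raises(ValueError, match="n_osc"):
            osc_filter(X, design, n_osc=0)

    def test_single_group_rejected(self, planted):
        _, X = planted
        with pytest.raises(ValueError):
            lone = StudyDesign.from_group_sizes({"only": 40}, "only")
            osc_filter(X, lone, n_osc=1)


class TestPLSDA:
    def test_perfect_predictor_r2y_is_one(self):
        design = two_groups(8)
        y = np.where(design.labels == "B_high", 1.0, 0.0)
        y -= y.mean()
        X = y[:, None]
        res = PLSDA(X, design).fit(n_components=1, cv_folds=None)
        assert res.r2y == pytest.approx(1.0, abs=1e-10)

    def test_overfit_noise_has_low_q2(self):
        rng = np.random.default_rng(42)
        design = two_groups(12)
        X = rng.normal(size=(24, 50))
        X -= X.mean(0)
        res = PLSDA(X, design).fit(n_components=2, cv_folds=6, seed=0)
        assert res.r2y > 0.0
        assert res.q2 <= 0.4

    def test_sample_order_invariance(self, strong_spectra, bpa_design):
        X = strong_spectra.intensities
        res = PLSDA(X, bpa_design).fit(n_components=2, cv_folds=None)
        perm = np.random.default_rng(1).permutation(len(X))
        tab = bpa_design.table.iloc[perm].reset_index(drop=True)
        res_p = PLSDA(X[perm], StudyDesign(tab, "DMSO")).fit(
            n_components=2, cv_folds=None
        )
        assert res_p.r2y == pytest.approx(res.r2y, rel=1e-9)

    def test_weight_and_score_invariants(self, strong_spectra, bpa_design):
        res = PLSDA.from_spectra(strong_spectra, bpa_design).fit(
            n_components=3, cv_folds=None
        )
        norms = np.linalg.norm(res.weights, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)
        G = res.scores.T @ res.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))
        assert 0.0 <= res.r2y <= 1.0
        assert (res.ssy_explained >= 0).all()
        assert (np.diff(np.cumsum(res.r2y_per_component)) >= -1e-12).all()

    def test_two_balanced_groups_weight_is_mean_difference(self):
        """A=1, two balanced groups: the PLS weight direction equals the
        between-group difference of column means."""
        rng = np.random.default_rng(5)
        design = two_groups(10)
        X = rng.normal(size=(20, 15))
        X[design.labels == "B_high"] += rng.normal(scale=0.5, size=15)
        X -= X.mean(0)
        res = PLSDA(X, design).fit(n_components=1, cv_folds=None)
        delta = (X[design.labels == "B_high"].mean(0)
                 - X[design.labels == "A_ctrl"].mean(0))
        delta /= np.linalg.norm(delta)
        cos = abs(float(delta @ res.weights[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_component_count_beyond_rank_errors(self):
        design = two_groups(3)
        X = np.random.default_rng(0).normal(size=(6, 4))
        X -= X.mean(0)
        with pytest.raises(ValueError, match="n_components"):
            PLSDA(X, design).fit(n_components=6, cv_folds=None)

    def test_single_group_rejected(self):
        lone = StudyDesign.from_group_sizes({"only": 6}, "only")
        with pytest.raises(ValueError, match="2 groups"):
            PLSDA(np.zeros((6, 3)), lone)


class TestCrossValidation:
    def test_strong_signal_meets_robustness_rule(self, strong_spectra, bpa_design):
        """Paper-sized design with strong mixed-profile signal: R2Y > 0.5
        and Q2 > 0.4 (the robust-model rule of thumb)."""
        res = PLSDA.from_spectra(strong_spectra, bpa_design).fit(seed=0)
        assert res.r2y > 0.5
        assert res.q2 > 0.4

    def test_pure_noise_fails_robustness_rule(self, noise_spectra, bpa_design):
        res = PLSDA.from_spectra(noise_spectra, bpa_design).fit(seed=0)
        assert res.q2 < 0.4

    def test_q2_not_above_r2y(self, bpa_design):
        for seed in range(5):
            sigs = fn.demo_signatures(bpa_design, effect=2.0, seed=seed)
            m = fn.simulate_spectra(bpa_design, sigs, n_bins=80, seed=seed)
            ms = fn.scale(fn.normalize_total_area(m), "center_pareto")
            res = PLSDA.from_spectra(ms, bpa_design).fit(n_components=2, seed=seed)
            assert res.q2 <= res.r2y + 1e-12

    def test_too_many_folds(self, bpa_design):
        with pytest.raises(ValueError, match="folds"):
            cross_validated_q2(np.zeros((53, 5)), bpa_design, 1, folds=60)


class TestPermutation:
    def test_separated_groups_attain_minimum_p(self, two_group_design):
        sig = fn.SignatureSpec("m", (2.0,), {"BPA_high": 6.0})
        m = fn.simulate_spectra(two_group_design, [sig], n_bins=30, seed=3,
                                confounder_sd=0.0)
        X = fn.scale(fn.normalize_total_area(m), "center_pareto").intensities
        res = permutation_test(X, two_group_design, 1, n_perm=39, seed=0, folds=6)
        assert res.empirical_p_q2 == pytest.approx(1.0 / 40.0)
        assert len(res.permuted_q2) == 39 and len(res.permuted_r2y) == 39

    def test_null_labels_rarely_significant(self):
        """Random labels: empirical p above 0.05 in >= 90% of seeded runs."""
        design = StudyDesign.from_group_sizes({"a_ctrl": 10, "b_high": 10}, "a_ctrl")
        n_sig = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(20, 15))
            X -= X.mean(0)
            res = permutation_test(X, design, 1, n_perm=39, seed=seed, folds=4)
            n_sig += res.empirical_p_q2 <= 0.05
        assert n_sig <= 0.10 * runs

    def test_invalid_n_perm(self, two_group_design):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(np.zeros((36, 4)), two_group_design, 1, n_perm=0)


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        res = _fake_results(w=np.full((4, 1), 0.5), ssy=np.array([2.0]))
        assert np.allclose(vip_scores(res).vip, 1.0)

    def test_two_variable_closed_form(self):
        res = _fake_results(w=np.array([[0.8], [0.6]]), ssy=np.array([1.0]))
        assert vip_scores(res).vip == pytest.approx(
            [np.sqrt(2) * 0.8, np.sqrt(2) * 0.6], abs=1e-4
        )

    def test_normalization_identity_on_fitted_models(self, strong_spectra,
                                                     noise_spectra, bpa_design):
        for m in (strong_spectra, noise_spectra):
            res = PLSDA.from_spectra(m, bpa_design).fit(n_components=3,
                                                        cv_folds=None)
            v = vip_scores(res).vip
            assert (v >= 0).all()
            assert (v**2).sum() == pytest.approx(m.n_bins, abs=1e-8)

    def test_zero_ssy_errors(self):
        res = _fake_results(w=np.ones((3, 1)) / np.sqrt(3), ssy=np.array([0.0]))
        with pytest.raises(ValueError, match="VIP undefined"):
            vip_scores(res)


def _fake_results(w, ssy):
    A = w.shape[1]
    return PLSDAResults(
        model=None, n_components=A, weights=w, scores=np.zeros((2, A)),
        x_loadings=np.zeros_like(w), y_loadings=np.zeros((2, A)),
        ssy_explained=ssy, r2y=0.5, r2y_per_component=np.full(A, 0.5 / A),
        q2=None, q2_per_component=None, cv_folds=None, seed=None,
    )


class TestKruskalWallis:
    def test_hand_computed_example(self):
        design = StudyDesign.from_group_sizes({"a_ctrl": 3, "b_high": 3}, "a_ctrl")
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        h, p = kruskal_wallis(values, design)
        assert h == pytest.approx(27.0 / 7.0)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_groups(self):
        design = StudyDesign.from_group_sizes({"a_ctrl": 4, "b_high": 4}, "a_ctrl")
        h, p = kruskal_wallis(np.ones(8), design)
        assert h == 0.0 and p == 1.0

    def test_rank_invariance_under_scaling(self):
        design = StudyDesign.from_group_sizes({"a_ctrl": 5, "b_high": 5}, "a_ctrl")
        v = np.random.default_rng(2).normal(size=10)
        h1, _ = kruskal_wallis(v, design)
        h2, _ = kruskal_wallis(100.0 * v, design)
        assert h1 == pytest.approx(h2)
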