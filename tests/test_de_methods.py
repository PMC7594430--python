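"""DE battery: exactness, limit equivalences, calibration and shrinkage."""

import numpy as np
import pytest
from scipy import stats

import statsmodels.api as sm

from consensusde.io_model import CohortConfig, CountMatrix, DesignError, group_labels, pair_index
from consensusde.expression import NormFactors, tmm_factors
from consensusde.de_methods import (
    bh_adjust,
    de_clr_mc,
    de_moderated_t,
    de_nb_exact,
    de_nb_glm_lrt,
    de_nb_wald,
    deges_normalize,
    DispersionModel,
    estimate_dispersion,
)
from consensusde.synthetic import simulate_case_control, simulate_twins

from conftest import random_count_matrix


def _cm(counts):
    counts = np.asarray(counts)
    g, s = counts.shape
    return CountMatrix(
        [f"t{i}" for i in range(g)], [f"g{i}" for i in range(g)],
        [1000] * g, counts, [f"s{j}" for j in range(s)],
    )


def _disp(cm, phi):
    return DispersionModel(common=phi, tagwise=np.full(cm.n_transcripts, phi), prior_df=10)


class TestBhAdjust:
    def test_hand_step_up(self):
        # p(i) * m / i = 0.04 for every i; the cumulative minimum keeps 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        got = bh_adjust(p)
        # independent textbook step-up: sort, scale by m/i, cumulative min, unsort
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), rtol=1e-12)


class TestBhProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_and_dominating(self, p):
        adj = bh_adjust(np.array(p))
        assert np.all(adj >= np.array(p) - 1e-12)  # adjusted never below raw
        assert np.all(adj <= 1.0)
        # order of adjusted values follows the order of raw p-values
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestNbExact:
    def test_all_zero_transcript_gives_p_one(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 10)])
        cm = _cm(counts)
        groups = np.array([True] * 3 + [False] * 3)
        res = de_nb_exact(cm, groups, NormFactors.none(cm), _disp(cm, 0.2))
        assert res["p_raw"].iloc[0] == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(30)
        cm = _cm(rng.integers(0, 80, size=(40, 8)))
        cm.counts[:, :] += 1
        groups = np.array([True] * 4 + [False] * 4)
        nf = NormFactors.none(cm)
        a = de_nb_exact(cm, groups, nf, _disp(cm, 0.2))
        b = de_nb_exact(cm, ~groups, nf, _disp(cm, 0.2))
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], rtol=1e-9)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-9)

    def test_matches_full_enumeration_on_tiny_totals(self):
        # equal library sizes so no count rescaling happens; totals <= 30
        counts = np.array(
            [[3, 1, 0, 2, 5, 1], [0, 0, 1, 8, 7, 6], [4, 4, 4, 4, 4, 4], [9, 2, 3, 0, 1, 2]]
        )
        # pad a constant row so every column sums to the same total
        pad = counts.sum(axis=0).max() - counts.sum(axis=0)
        cm = _cm(np.vstack([counts, pad]))
        groups = np.array([True] * 3 + [False] * 3)
        phi = 0.3
        res = de_nb_exact(cm, groups, NormFactors.none(cm), _disp(cm, phi))
        for i in range(4):
            sa, sb = counts[i, :3].sum(), counts[i, 3:].sum()
            t = sa + sb
            m = t / 6
            # independent enumeration of the conditional outcome space
            fa = stats.nbinom.pmf(np.arange(t + 1), 3 / phi, (3 / phi) / (3 / phi + 3 * m))
            fb = stats.nbinom.pmf(t - np.arange(t + 1), 3 / phi, (3 / phi) / (3 / phi + 3 * m))
            f = fa * fb
            expected = f[f <= f[sa] * (1 + 1e-12)].sum() / f.sum()
            assert res["p_raw"].iloc[i] == pytest.approx(expected, rel=1e-8)

    def test_large_count_normal_branch_is_calibrated(self):
        # huge-mean null transcripts: p approximately uniform under either branch
        rng = np.random.default_rng(31)
        mu, phi = 5000.0, 0.05
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(400, 10))
        cm = _cm(counts)
        groups = np.array([True] * 5 + [False] * 5)
        res = de_nb_exact(cm, groups, NormFactors.none(cm), _disp(cm, phi))
        assert 0.02 <= (res["p_raw"] < 0.05).mean() <= 0.08


class TestNbGlm:
    def test_poisson_limit_matches_statsmodels(self):
        rng = np.random.default_rng(32)
        counts = rng.poisson(30, size=(6, 12))
        cm = _cm(counts)
        groups = np.array([True] * 6 + [False] * 6)
        nf = NormFactors.none(cm)
        res = de_nb_glm_lrt(cm, groups, nf, _disp(cm, 0.0))
        off = np.log(nf.effective_library_sizes(cm))
        off = off - off.mean()
        X = np.column_stack([np.ones(12), groups.astype(float)])
        for i in range(6):
            full = sm.GLM(counts[i], X, family=sm.families.Poisson(), offset=off).fit()
            null = sm.GLM(counts[i], X[:, :1], family=sm.families.Poisson(), offset=off).fit()
            lrt = 2 * (full.llf - null.llf)
            expected = stats.chi2.sf(lrt, 1)
            assert res["p_raw"].iloc[i] == pytest.approx(expected, abs=1e-6)

    def test_null_lrt_statistic_mean_near_one(self):
        cfg = CohortConfig(n_transcripts=1500, de_fraction=0.0, dispersion=0.2)
        cm, rows, _ = simulate_case_control(cfg, 33)
        groups = group_labels(rows, cm.sample_ids)
        nf = tmm_factors(cm)
        disp = estimate_dispersion(cm, groups, nf)
        res = de_nb_glm_lrt(cm, groups, nf, disp)
        lrt = stats.chi2.isf(res["p_raw"], 1)
        assert 0.8 <= np.mean(lrt[np.isfinite(lrt)]) <= 1.2

    def test_large_effect_detected_at_16_per_group(self):
        rng = np.random.default_rng(34)
        mu = 100.0
        counts = np.vstack(
            [
                np.concatenate([rng.poisson(mu * 8, 16), rng.poisson(mu, 16)]),
                rng.poisson(mu, 32),
            ]
        )
        cm = _cm(counts)
        groups = np.array([True] * 16 + [False] * 16)
        # unit exposures: library sizes of this 2-transcript toy are dominated
        # by the spiked transcript and would confound the flat one
        unit = NormFactors(list(cm.sample_ids), np.ones(32), "unit", relative=False)
        res = de_nb_glm_lrt(cm, groups, unit, _disp(cm, 0.1))
        assert res["p_raw"].iloc[0] < 1e-4
        assert res["p_raw"].iloc[1] > 0.01

    def test_wald_and_lrt_agree_in_rank(self):
        # informative expression range: agreement is about the tests, not
        # about rank noise among all-zero transcripts
        cfg = CohortConfig(n_transcripts=800, de_fraction=0.1, baseline_log2_range=(3.0, 10.0))
        cm, rows, _ = simulate_case_control(cfg, 55)
        groups = group_labels(rows, cm.sample_ids)
        nf = tmm_factors(cm)
        disp = estimate_dispersion(cm, groups, nf)
        lrt = de_nb_glm_lrt(cm, groups, nf, disp)
        wald = de_nb_wald(cm, groups, nf, disp)
        rho = stats.spearmanr(lrt["p_raw"], wald["p_raw"]).statistic
        assert rho >= 0.95

    def test_rank_deficient_design_rejected(self):
        cm = _cm(np.ones((3, 4), dtype=int))
        groups = np.array([True, True, True, True])  # group column == intercept
        with pytest.raises(DesignError):
            de_nb_wald(cm, groups, NormFactors.none(cm), _disp(cm, 0.1))


class TestModeratedT:
    def test_no_moderation_no_weights_is_ordinary_t(self):
        rng = np.random.default_rng(35)
        cm = _cm(rng.integers(5, 500, size=(30, 10)))
        groups = np.array([True] * 5 + [False] * 5)
        res = de_moderated_t(cm, groups, prior_df=0, trend_weights=False)
        lib = cm.counts.sum(axis=0)
        prior = 0.5 * lib / lib.mean()  # depth-scaled pseudocount of the log-CPM
        logcpm = np.log2((cm.counts + prior) / (lib + 2 * prior) * 1e6)
        expected = stats.ttest_ind(logcpm[:, :5], logcpm[:, 5:], axis=1, equal_var=True).pvalue
        np.testing.assert_allclose(res["p_raw"], expected, atol=1e-9)

    def test_constant_transcript_p_one(self):
        counts = np.vstack([np.full(8, 50), np.full(8, 100)])
        cm = _cm(counts)
        groups = np.array([True] * 4 + [False] * 4)
        res = de_moderated_t(cm, groups, trend_weights=False)
        assert res["p_raw"].iloc[0] == 1.0

    def test_null_type_one_error_calibrated(self):
        cfg = CohortConfig(n_transcripts=2000, de_fraction=0.0, dispersion=0.2)
        cm, rows, _ = simulate_case_control(cfg, 36)
        groups = group_labels(rows, cm.sample_ids)
        res = de_moderated_t(cm, groups)
        assert 0.03 <= (res["p_raw"] < 0.05).mean() <= 0.07

    def test_paired_beats_unpaired_on_pair_correlated_data(self):
        cfg = CohortConfig(
            n_transcripts=400, de_fraction=0.1, pair_effect_sd=0.6,
            de_log2fc=(1.0, 1.5), de_min_mean=50,
        )
        cm, rows, truth = simulate_twins(cfg, 37)
        groups = group_labels(rows, cm.sample_ids)
        pairs = pair_index(rows, cm.sample_ids)
        paired = de_moderated_t(cm, groups, pairs=pairs)
        unpaired = de_moderated_t(cm, groups)
        spiked = truth.is_de
        gain = np.mean(-np.log10(np.maximum(paired["p_raw"][spiked], 1e-300))) - np.mean(
            -np.log10(np.maximum(unpaired["p_raw"][spiked], 1e-300))
        )
        assert gain > 0


class TestClrMc:
    def test_seed_determinism(self):
        rng = np.random.default_rng(38)
        cm = _cm(rng.integers(0, 200, size=(30, 8)))
        groups = np.array([True] * 4 + [False] * 4)
        a = de_clr_mc(cm, groups, n_mc=32, seed=5)
        b = de_clr_mc(cm, groups, n_mc=32, seed=5)
        np.testing.assert_array_equal(a["p_raw"], b["p_raw"])
        c = de_clr_mc(cm, groups, n_mc=32, seed=6)
        assert not np.array_equal(a["p_raw"], c["p_raw"])

    def test_null_is_conservative(self):
        cfg = CohortConfig(n_transcripts=800, de_fraction=0.0, dispersion=0.2)
        cm, rows, _ = simulate_case_control(cfg, 39)
        groups = group_labels(rows, cm.sample_ids)
        res = de_clr_mc(cm, groups, n_mc=64, seed=39)
        assert (res["p_raw"] < 0.05).mean() <= 0.07

    def test_dominant_composition_shift_detected(self):
        rng = np.random.default_rng(40)
        g, n = 40, 20
        counts = rng.integers(50, 150, size=(g, n))
        lib = counts.sum(axis=0)
        # transcript 0 at ~50% of every affected library vs ~5% unaffected
        counts[0, :10] = lib[:10]
        counts[0, 10:] = lib[10:] // 20
        cm = _cm(counts)
        groups = np.array([True] * 10 + [False] * 10)
        res = de_clr_mc(cm, groups, n_mc=64, seed=41)
        assert res["p_raw"].iloc[0] < 0.01

    def test_small_mc_count_rejected(self):
        cm = _cm(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError):
            de_clr_mc(cm, np.array([True, True, False, False]), n_mc=8)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        cfg = CohortConfig(n_transcripts=2000, de_fraction=0.0, dispersion=0.0)
        cm, rows, _ = simulate_case_control(cfg, 44)
        groups = group_labels(rows, cm.sample_ids)
        d = estimate_dispersion(cm, groups, tmm_factors(cm))
        assert d.common <= 0.05

    def test_parameter_recovery_at_point_four(self):
        cfg = CohortConfig(n_transcripts=2000, de_fraction=0.0, dispersion=0.4)
        cm, rows, _ = simulate_case_control(cfg, 45)
        groups = group_labels(rows, cm.sample_ids)
        d = estimate_dispersion(cm, groups, tmm_factors(cm))
        assert 0.3 <= d.common <= 0.5

    def test_infinite_prior_df_collapses_tagwise_to_common(self, small_cc):
        cm, rows, truth, groups, cfg = small_cc
        d = estimate_dispersion(cm, groups, tmm_factors(cm), prior_df=np.inf)
        np.testing.assert_allclose(d.tagwise, d.common)

    def test_single_sample_per_group_rejected(self):
        cm = _cm([[1, 2], [3, 4]])
        with pytest.raises(DesignError):
            estimate_dispersion(cm, np.array([True, False]))


class TestDeges:
    def test_zero_removal_equals_plain_tmm(self, small_cc):
        cm, rows, truth, groups, cfg = small_cc
        deges = deges_normalize(cm, groups, iterations=1, removal_fraction=0.0)
        plain = tmm_factors(cm)
        np.testing.assert_allclose(deges.factors, plain.factors, rtol=1e-12)

    def test_no_de_matches_tmm_within_two_percent(self):
        # low biological dispersion so the trimmed-mean sampling noise of the
        # two (overlapping) transcript sets stays below the 2% band
        cfg = CohortConfig(n_transcripts=5000, de_fraction=0.0, dispersion=0.02)
        cm, rows, _ = simulate_case_control(cfg, 46)
        groups = group_labels(rows, cm.sample_ids)
        deges = deges_normalize(cm, groups)
        plain = tmm_factors(cm)
        np.testing.assert_allclose(deges.factors, plain.factors, rtol=0.02)

    def test_one_sided_de_factors_beat_tmm(self):
        cfg = CohortConfig(
            n_transcripts=1500, de_fraction=0.3, de_direction="up",
            de_log2fc=(1.5, 2.5), de_min_mean=20,
        )
        cm, rows, truth = simulate_case_control(cfg, 47)
        groups = group_labels(rows, cm.sample_ids)

        def max_rel_err(nf):
            est = nf.effective_library_sizes(cm)
            est = est / np.exp(np.mean(np.log(est)))
            true = truth.libsize_factors / np.exp(np.mean(np.log(truth.libsize_factors)))
            return np.max(np.abs(est / true - 1.0))

        assert max_rel_err(deges_normalize(cm, groups)) < max_rel_err(tmm_factors(cm))

    def test_excessive_removal_rejected(self, small_cc):
        cm, rows, truth, groups, cfg = small_cc
        with pytest.raises(DesignError):
            deges_normalize(cm, groups, removal_fraction=0.99)
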