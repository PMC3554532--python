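"""Conservation normalization, positional profile, ratio function, Welch."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epibias as eb
from epibias.conservation import (
    ConservationProfile,
    ConstantProfileError,
    conservation_ratio_function,
    curve_agreement,
    estimate_bias_from_conservation,
    normalize_profile,
    normalize_profiles,
    peptide_conservation,
    positional_conservation,
    welch_one_sided,
)
from epibias.mapping import PeptideMapping, PeptideRecord


def _profile(scores, aid="P1", normalized=False):
    return ConservationProfile(aid, np.asarray(scores, float), normalized=normalized)


class TestNormalize:
    def test_hand_z_scores(self):
        out = normalize_profile(_profile([1, 2, 3]))
        np.testing.assert_allclose(out.scores, [-1, 0, 1])
        assert out.normalized

    def test_output_moments(self, rng):
        out = normalize_profile(_profile(rng.uniform(0, 9, size=50)))
        assert out.scores.mean() == pytest.approx(0, abs=1e-9)
        assert out.scores.std(ddof=1) == pytest.approx(1, abs=1e-9)

    @given(
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance(self, a, b, seed):
        raw = np.random.default_rng(seed).normal(size=30)
        base = normalize_profile(_profile(raw))
        shifted = normalize_profile(_profile(a * raw + b))
        np.testing.assert_allclose(base.scores, shifted.scores, atol=1e-9)

    def test_constant_profile_excluded_with_reason(self):
        with pytest.raises(ConstantProfileError):
            normalize_profile(_profile([2.0, 2.0, 2.0]))
        kept, excluded = normalize_profiles(
            [_profile([1, 2, 3]), _profile([5, 5], aid="P2"), _profile([7], aid="P3")]
        )
        assert len(kept) == 1
        assert ("P2", "constant-profile") in excluded
        assert ("P3", "too-short") in excluded


class TestPositionalConservation:
    def test_flat_profiles_give_zero_means(self):
        profiles = [
            _profile(np.zeros(40), aid=f"P{i}", normalized=True) for i in range(5)
        ]
        pc = positional_conservation(profiles, n_boot=50, seed=0)
        np.testing.assert_allclose(pc.mean_score, 0.0)

    def test_synthetic_trend_peaks_centrally_with_tight_cis(self):
        config = eb.ScenarioConfig(
            n_proteins=500, n_peptides=10, conservation_trend=1.0, seed=8
        )
        antigens = eb.generate_proteome(config)
        table = eb.generate_conservation(antigens, config)
        profiles, _ = normalize_profiles(
            [
                ConservationProfile(aid, g["score"].to_numpy())
                for aid, g in table.groupby("antigen_id")
            ]
        )
        pc = positional_conservation(profiles, n_boot=300, seed=0)
        assert pc.mean_score[2] > pc.mean_score[0]
        assert pc.mean_score[2] > pc.mean_score[4]
        assert pc.whisker_lo[2] > pc.whisker_hi[0]  # CIs do not overlap
        assert pc.whisker_lo[2] > pc.whisker_hi[4]

    def test_single_protein_degenerates_to_point(self):
        profile = normalize_profile(_profile(np.arange(30, dtype=float)))
        pc = positional_conservation([profile], n_boot=50, seed=0)
        assert pc.degenerate
        np.testing.assert_allclose(pc.boot_p25, pc.mean_score)
        np.testing.assert_allclose(pc.whisker_hi, pc.mean_score)

    def test_unnormalized_profiles_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            positional_conservation([_profile([1, 2, 3])])


class TestPeptideConservation:
    def _mapping(self, start, k=3, aid="P1"):
        return PeptideMapping(
            peptide=PeptideRecord("A" * k, "positive"),
            antigen_id=aid,
            peptide_start=start,
            x=0.0,
        )

    def test_footprint_mean(self):
        profile = _profile([-1, 0, 1, 5], normalized=True)
        assert peptide_conservation(self._mapping(1), profile) == pytest.approx(0.0)

    def test_constant_footprint(self):
        profile = _profile([0.7] * 6, normalized=True)
        assert peptide_conservation(self._mapping(2), profile) == pytest.approx(0.7)

    def test_random_case_matches_direct_mean(self, rng):
        scores = rng.normal(size=50)
        profile = _profile(scores, normalized=True)
        got = peptide_conservation(self._mapping(11, k=9), profile)
        assert got == pytest.approx(scores[10:19].mean())

    def test_wrong_antigen_or_overflow_rejected(self):
        profile = _profile([0, 1], aid="OTHER", normalized=True)
        with pytest.raises(ValueError):
            peptide_conservation(self._mapping(1), profile)
        short = _profile([0, 1], normalized=True)
        with pytest.raises(ValueError):
            peptide_conservation(self._mapping(1, k=5), short)


class TestRatioFunction:
    def test_identical_distributions_near_unity(self, rng):
        xs = rng.normal(size=4000)
        f = conservation_ratio_function(xs, xs.copy(), n_boot=50, seed=0)
        np.testing.assert_allclose(f.ratio, 1.0, atol=1e-9)

    def test_shifted_positives_make_increasing_ratio(self, rng):
        pos = rng.normal(loc=1.0, size=4000)
        neg = rng.normal(size=8000)
        f = conservation_ratio_function(pos, neg, n_boot=50, seed=0)
        assert f.ratio[-1] > 1 > f.ratio[0]

    def test_hand_built_example(self):
        # pooled deciles -> 5 bins of 2 values each
        pos = [1.0, 2.0, 9.0, 10.0]
        neg = [3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        f = conservation_ratio_function(pos, neg, n_bins=5, n_boot=20, seed=0)
        # bin contents: {1,2} {3,4} {5,6} {7,8} {9,10}; terminal bins hold
        # only positives (zero negative mass -> undefined), middle bins hold
        # only negatives: ratio = (0/4) / (2/6) = 0
        assert not f.defined[0] and not f.defined[4]
        np.testing.assert_allclose(f.ratio[1:4], 0.0)

    def test_duplicate_heavy_data_merges_bins(self):
        pos = [1.0] * 12 + [2.0, 3.0, 4.0, 5.0]
        neg = [1.0] * 12 + [6.0, 7.0, 8.0, 9.0]
        f = conservation_ratio_function(pos, neg, n_bins=5, n_boot=10, seed=0)
        assert f.collapsed
        assert f.bin_edges.size - 1 < 5

    def test_fully_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            conservation_ratio_function([1.0] * 20, [1.0] * 20, n_boot=10)


class TestEstimateAndAgreement:
    def _flat_function(self, value=1.0):
        rng = np.random.default_rng(0)
        xs = rng.normal(size=2000)
        f = conservation_ratio_function(xs, xs.copy(), n_boot=20, seed=0)
        f.ratio = np.full_like(f.ratio, value)
        return f

    def test_flat_function_gives_flat_curve(self):
        config = eb.scenario_null(seed=2, n_peptides=100)
        antigens = eb.generate_proteome(config)
        table = eb.generate_conservation(antigens, config)
        profiles, _ = normalize_profiles(
            [
                ConservationProfile(aid, g["score"].to_numpy())
                for aid, g in table.groupby("antigen_id")
            ]
        )
        pc = positional_conservation(profiles, n_boot=50, seed=0)
        est = estimate_bias_from_conservation(pc, self._flat_function())
        np.testing.assert_allclose(est.ratio, 1.0)

    def test_monotone_function_preserves_central_peak(self, rng):
        pos = rng.normal(1.0, size=3000)
        neg = rng.normal(size=3000)
        f = conservation_ratio_function(pos, neg, n_boot=20, seed=0)
        config = eb.ScenarioConfig(
            n_proteins=300, n_peptides=10, conservation_trend=1.0, seed=8
        )
        antigens = eb.generate_proteome(config)
        table = eb.generate_conservation(antigens, config)
        profiles, _ = normalize_profiles(
            [
                ConservationProfile(aid, g["score"].to_numpy())
                for aid, g in table.groupby("antigen_id")
            ]
        )
        pc = positional_conservation(profiles, n_boot=50, seed=0)
        est = estimate_bias_from_conservation(pc, f)
        assert est.ratio[2] > est.ratio[0] and est.ratio[2] > est.ratio[4]

    def test_agreement_identity_is_one(self, rng):
        xs = rng.uniform(size=500)
        curve = eb.ratio_curve(xs, rng.uniform(size=500), n_boot=20, seed=0)
        assert curve_agreement(curve, curve) == pytest.approx(1.0)

    def test_reversed_curve_matches_hand_pearson(self, rng):
        from scipy import stats

        xs = rng.uniform(size=800)
        ys = rng.uniform(size=800)
        a = eb.ratio_curve(xs, ys, n_boot=20, seed=0)
        b = eb.ratio_curve(xs, ys, n_boot=20, seed=0)
        b.ratio = a.ratio[::-1].copy()
        hand = stats.pearsonr(a.ratio, a.ratio[::-1]).statistic
        assert curve_agreement(a, b) == pytest.approx(hand)

    def test_constant_curve_errors(self, rng):
        xs = rng.uniform(size=500)
        a = eb.ratio_curve(xs, rng.uniform(size=500), n_boot=20, seed=0)
        b = eb.ratio_curve(xs, rng.uniform(size=500), n_boot=20, seed=0)
        b.ratio = np.ones_like(b.ratio)
        with pytest.raises(ValueError, match="constant"):
            curve_agreement(a, b)


class TestWelch:
    def test_identical_groups_symmetric(self):
        res = welch_one_sided([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_hand_computed_example(self):
        """pos=(2,3,4), neg=(0,1,2): s^2=1 each, se^2 = 1/3 + 1/3."""
        res = welch_one_sided([2, 3, 4], [0, 1, 2])
        assert res.t == pytest.approx(np.sqrt(6))
        assert res.df == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0352, abs=2e-4)

    def test_degenerate_zero_variance_flagged(self):
        res = welch_one_sided([1.0, 1.0], [1.0, 1.0])
        assert res.p == 0.5 and res.degenerate

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_one_sided([1.0], [1.0, 2.0])
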