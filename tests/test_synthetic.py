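"""Generators: determinism, ground-truth structure, contract checks."""

import numpy as np
import pytest
from scipy import stats

import epibias as eb
from epibias.synthetic import (
    ScenarioConfig,
    default_supertype_map,
    density_bin_masses,
    with_seed,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_proteins": 0},
            {"n_peptides": 0},
            {"positive_fraction": 0.0},
            {"positive_fraction": 1.0},
            {"length_range": (5, 100)},  # min <= peptide_length
            {"length_range": (300, 200)},
            {"positional_density": "sideways"},
            {"density_strength": -1.0},
        ],
    )
    def test_invalid_rejected_with_field_name(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs)


class TestProteome:
    def test_counts_lengths_alphabet(self):
        config = ScenarioConfig(n_proteins=3, length_range=(50, 60), seed=1)
        antigens = eb.generate_proteome(config)
        assert len(antigens) == 3
        for a in antigens:
            assert 50 <= len(a) <= 60
            assert set(a.sequence) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_same_seed_identical(self):
        config = ScenarioConfig(n_proteins=3, length_range=(50, 60), seed=1)
        a = eb.generate_proteome(config)
        b = eb.generate_proteome(config)
        assert [x.sequence for x in a] == [x.sequence for x in b]

    def test_different_seed_differs(self):
        config = ScenarioConfig(n_proteins=3, length_range=(50, 60), seed=1)
        a = eb.generate_proteome(config)
        b = eb.generate_proteome(with_seed(config, 2))
        assert [x.sequence for x in a] != [x.sequence for x in b]


class TestAssayPeptides:
    def test_peptides_are_true_substrings(self, null_scenario):
        _, antigens, records, truth = null_scenario
        by_id = {a.id: a for a in antigens}
        for rec, t in zip(records[:300], truth[:300]):
            seq = by_id[t.antigen_id].sequence
            start0 = t.peptide_start - 1
            assert seq[start0 : start0 + len(rec.sequence)] == rec.sequence

    def test_uniform_density_positives_pass_uniformity(self):
        config = eb.scenario_null(seed=21, n_peptides=10_000)
        antigens = eb.generate_proteome(config)
        _, truth = eb.generate_assay_peptides(antigens, config)
        xs = [m.x for m in truth if m.peptide.label == "positive"]
        assert stats.kstest(xs, "uniform").pvalue > 0.01

    def test_central_density_pulls_positives_inward(self, central_scenario):
        _, _, _, truth = central_scenario
        pos = np.array([m.x for m in truth if m.peptide.label == "positive"])
        neg = np.array([m.x for m in truth if m.peptide.label == "negative"])
        assert np.abs(pos - 0.5).mean() < np.abs(neg - 0.5).mean()

    def test_terminal_densities_skew_expected_way(self):
        for density, sign in [("n_terminal", -1), ("c_terminal", +1)]:
            config = ScenarioConfig(
                n_peptides=5000, positional_density=density,
                density_strength=2.0, seed=5,
            )
            antigens = eb.generate_proteome(config)
            _, truth = eb.generate_assay_peptides(antigens, config)
            pos = np.mean([m.x for m in truth if m.peptide.label == "positive"])
            neg = np.mean([m.x for m in truth if m.peptide.label == "negative"])
            assert sign * (pos - neg) > 0

    def test_peptide_longer_than_shortest_protein_rejected(self):
        bad = ScenarioConfig(peptide_length=49, length_range=(50, 60), seed=1)
        with pytest.raises(ValueError):
            eb.generate_assay_peptides([eb.Antigen("T", "A" * 30)], bad)

    def test_immunogen_fraction_and_no_coupling_for_peptide_context(self):
        config = ScenarioConfig(
            n_peptides=8000, conservation_coupling=2.0,
            peptide_immunogen_fraction=0.3, seed=9,
        )
        antigens = eb.generate_proteome(config)
        records, _ = eb.generate_assay_peptides(antigens, config)
        frac = np.mean([r.immunogen == "peptide" for r in records])
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_marginal_positive_fraction_preserved_under_coupling(self):
        config = eb.scenario_conservation_recovery(seed=17, n_peptides=10_000)
        antigens = eb.generate_proteome(config)
        records, _ = eb.generate_assay_peptides(antigens, config)
        frac = np.mean([r.label == "positive" for r in records])
        assert frac == pytest.approx(config.positive_fraction, abs=0.02)

    def test_density_bin_masses_closed_form(self):
        # uniform: all bins 0.2; central s: quadratic integral by hand for bin 3
        np.testing.assert_allclose(density_bin_masses("uniform", 0.0), 0.2)
        s = 1.5
        hand_mid = ((1 + s) * 0.2 - (4 * s / 3) * (0.001 + 0.001)) / (1 + 2 * s / 3)
        assert density_bin_masses("central", s)[2] == pytest.approx(hand_mid)
        for density in ("central", "n_terminal", "c_terminal"):
            masses = density_bin_masses(density, 0.7)
            assert masses.sum() == pytest.approx(1.0)


class TestConservationGenerator:
    def test_profile_lengths_match_antigens(self, null_scenario):
        config, antigens, _, _ = null_scenario
        table = eb.generate_conservation(antigens, config)
        sizes = table.groupby("antigen_id").size()
        for a in antigens:
            assert sizes[a.id] == len(a)

    def test_flat_trend_has_no_positional_structure(self):
        config = ScenarioConfig(
            n_proteins=200, n_peptides=10, conservation_trend=0.0, seed=3
        )
        antigens = eb.generate_proteome(config)
        table = eb.generate_conservation(antigens, config)
        pos = table.groupby("antigen_id")["position_1based"].transform(
            lambda s: (s - 1) / (len(s) - 1)
        )
        bins = np.minimum((pos * 5).astype(int), 4)
        means = table.groupby(bins)["score"].mean()
        sem = table.groupby(bins)["score"].sem()
        assert np.all(np.abs(means) < 4 * sem)

    def test_positive_trend_peaks_centrally(self):
        config = ScenarioConfig(
            n_proteins=200, n_peptides=10, conservation_trend=1.0, seed=3
        )
        antigens = eb.generate_proteome(config)
        table = eb.generate_conservation(antigens, config)
        pos = table.groupby("antigen_id")["position_1based"].transform(
            lambda s: (s - 1) / (len(s) - 1)
        )
        bins = np.minimum((pos * 5).astype(int), 4)
        means = table.groupby(bins)["score"].mean()
        assert means[2] > means[0] and means[2] > means[4]

    def test_deterministic_given_seed(self, null_scenario):
        config, antigens, _, _ = null_scenario
        a = eb.generate_conservation(antigens, config)
        b = eb.generate_conservation(antigens, config)
        assert np.array_equal(a["score"], b["score"])


class TestToyPredictor:
    def test_deterministic_and_in_range(self):
        preds = eb.toy_binding_predictor(["ACDEFGHIK", "KLMNPQRST"], 3, seed=4)
        again = eb.toy_binding_predictor(["ACDEFGHIK", "KLMNPQRST"], 3, seed=4)
        assert np.array_equal(preds["ic50_nM"], again["ic50_nM"])
        assert ((preds["ic50_nM"] > 1) & (preds["ic50_nM"] < 50_000)).all()
        assert len(preds) == 6

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            eb.toy_binding_predictor(["ACDEF", "ACDEFGHIK"], 2, seed=0)

    def test_same_peptide_same_allele_same_score(self):
        preds = eb.toy_binding_predictor(["ACDEFGHIK"] * 3, 2, seed=0)
        assert len(preds) == 2  # duplicates collapse to unique peptides

    def test_supertype_map_covers_12_groups(self):
        m = default_supertype_map(24)
        assert m["supertype"].nunique() == 12
        assert m["allele"].is_unique
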