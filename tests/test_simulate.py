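import numpy as np
import pytest
from scipy import stats

from cinpipe.errors import ConfigurationError
from cinpipe.genome import GenomeBinning
from cinpipe.scores import aneuploidy_score, heterogeneity_score, structural_score
from cinpipe.simulate import (
    CloneSpec, CNEvent, DrugEffect, FateModel, GrowthModel,
    simulate_growth, simulate_karyotypes, simulate_mitosis_cohort,
    simulate_read_counts, simulate_variant_pairs,
)


class TestKaryotypes:
    def test_single_diploid_clone_is_all_twos(self, toy):
        cn = simulate_karyotypes(toy, (CloneSpec("d", 1.0),), n_cells=5,
                                 missegregation_rate=0.0, seed=0)
        assert (cn.states == 2).all()

    def test_whole_gain_applies_to_its_chromosome_only(self, toy):
        clone = CloneSpec("g", 1.0, events=(CNEvent("whole_gain", "chr1", +1),))
        cn = simulate_karyotypes(toy, (clone,), n_cells=3, seed=0)
        on = np.array(toy.bin_chromosomes()) == "chr1"
        assert (cn.states[:, on] == 3).all()
        assert (cn.states[:, ~on] == 2).all()

    def test_missegregation_fraction_matches_closed_form(self):
        # 22 chromosomes, per-chromosome hit rate 0.1:
        # P(cell has >= 1 whole-chromosome deviation) = 1 - 0.9**22
        genome = GenomeBinning(
            chromosomes=tuple((f"chr{i}", 10_000_000) for i in range(1, 23)))
        cn = simulate_karyotypes(genome, (CloneSpec("d", 1.0),), n_cells=2000,
                                 missegregation_rate=0.1, seed=7)
        deviated = (cn.states != 2).any(axis=1).mean()
        p = 1 - 0.9 ** 22
        half_width = 2.576 * np.sqrt(p * (1 - p) / 2000)  # binomial 99% interval
        assert abs(deviated - p) < half_width

    def test_clone_fractions_conserved(self, toy):
        clones = (CloneSpec("a", 0.5), CloneSpec("b", 0.3), CloneSpec("c", 0.2))
        cn = simulate_karyotypes(toy, clones, n_cells=10_000, seed=11)
        observed = [cn.clone_labels.count(c.label) for c in clones]
        expected = [c.fraction * 10_000 for c in clones]
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_unknown_chromosome_rejected(self, toy):
        clone = CloneSpec("x", 1.0, events=(CNEvent("whole_gain", "chr99", +1),))
        with pytest.raises(ConfigurationError, match="chr99"):
            simulate_karyotypes(toy, (clone,), n_cells=1, seed=0)

    def test_bad_fractions_rejected(self, toy):
        with pytest.raises(ConfigurationError, match="sum"):
            simulate_karyotypes(toy, (CloneSpec("a", 0.5), CloneSpec("b", 0.4)),
                                n_cells=1, seed=0)

    def test_seed_determinism(self, toy):
        clones = (CloneSpec("a", 0.6), CloneSpec("b", 0.4))
        a = simulate_karyotypes(toy, clones, 50, 0.1, seed=3)
        b = simulate_karyotypes(toy, clones, 50, 0.1, seed=3)
        assert (a.states == b.states).all() and a.clone_labels == b.clone_labels


class TestArchetypes:
    def test_event_grammar_expresses_the_four_archetypes(self, presets, preset_truths):
        # presence of the class-defining feature in each ground truth
        wc = preset_truths["whole_chromosome"]
        assert set(np.unique(wc.states)) == {1, 2, 3}
        mono = presets["monosomy"]["clones"][0].profile(wc.binning)
        assert 1 in mono
        tetra = presets["tetrasomy"]["clones"][0].profile(wc.binning)
        assert 4 in tetra

    def test_score_directions_separate_the_presets(self, preset_truths):
        S = {k: structural_score(v) for k, v in preset_truths.items()}
        A = {k: aneuploidy_score(v) for k, v in preset_truths.items()}
        assert max(S, key=S.get) == "rearranged"
        assert S["rearranged"] > max(v for k, v in S.items() if k != "rearranged")
        assert max(A, key=A.get) == "tetrasomy"

    def test_clonally_pure_whole_chromosome_preset_has_zero_heterogeneity(
            self, preset_truths):
        assert heterogeneity_score(preset_truths["whole_chromosome"]) == 0.0


class TestReadCounts:
    def test_deterministic_mode_is_exact(self, preset_truths):
        truth = preset_truths["whole_chromosome"]
        counts = simulate_read_counts(truth, reads_per_copy=100, deterministic=True)
        assert (counts.counts == truth.states * 100).all()

    def test_zero_state_bins_emit_background(self):
        genome = GenomeBinning(chromosomes=(("chr1", 10_000_000),), bin_size=1000)
        clone = CloneSpec("z", 1.0, 2,
                          (CNEvent("focal_del", "chr1", -2, span=(0, 5_000_000)),))
        truth = simulate_karyotypes(genome, (clone,), n_cells=1, seed=0)
        counts = simulate_read_counts(truth, 100, background=1.0, seed=5)
        zero_bins = counts.counts[0][truth.states[0] == 0]
        assert zero_bins.size == 5000
        assert abs(zero_bins.mean() - 1.0) < 5 / np.sqrt(zero_bins.size)

    def test_overdispersion_raises_variance(self, preset_truths):
        truth = preset_truths["whole_chromosome"]
        poisson = simulate_read_counts(truth, 100, dispersion=0.0, seed=1)
        nb = simulate_read_counts(truth, 100, dispersion=0.5, seed=1)
        assert nb.counts.var() > 2 * poisson.counts.var()

    def test_seed_determinism(self, preset_truths):
        truth = preset_truths["rearranged"]
        a = simulate_read_counts(truth, 50, 0.2, seed=9)
        b = simulate_read_counts(truth, 50, 0.2, seed=9)
        assert (a.counts == b.counts).all()


class TestMitosisCohort:
    def test_degenerate_mixture_all_normal(self):
        tab = simulate_mitosis_cohort(FateModel({"normal": 1.0}), 50, seed=0)
        assert (tab["terminal_fate"] == "division").all()
        assert (tab["annotations"] == "").all()

    def test_category_proportion_within_3_se(self):
        model = FateModel({"premature_anaphase": 0.12, "normal": 0.88})
        tab = simulate_mitosis_cohort(model, 2000, seed=1)
        obs = (tab["annotations"] == "premature_anaphase").mean()
        se = np.sqrt(0.12 * 0.88 / 2000)
        assert abs(obs - 0.12) < 3 * se

    def test_lognormal_duration_mean_matches_closed_form(self):
        mu, sd = np.log(40.0), 0.5
        model = FateModel({"normal": 1.0}, duration_model={"normal": (mu, sd)})
        tab = simulate_mitosis_cohort(model, 10_000, seed=2)
        expected = np.exp(mu + sd ** 2 / 2)
        assert abs(tab["duration_min"].mean() - expected) / expected < 0.02

    def test_empty_category_map_rejected(self):
        with pytest.raises(ConfigurationError):
            FateModel({})

    def test_no_mitosis_records_carry_no_duration(self):
        model = FateModel({"interphase_no_mitosis": 1.0})
        tab = simulate_mitosis_cohort(model, 10, seed=0)
        assert tab["duration_min"].isna().all()


class TestGrowth:
    def test_vehicle_exponential_is_exact(self):
        model = GrowthModel(initial_count=100, doubling_time=24, noise_cv=0.0)
        t = np.arange(0, 73.0)
        df = simulate_growth(model, [0.0], t, seed=0)
        np.testing.assert_allclose(df["value"].to_numpy(),
                                   100 * 2 ** (t / 24), rtol=1e-12)

    def test_auc_at_ec50_is_midway_between_bounding_curves(self):
        from cinpipe.growth import curve_auc, curves_from_frame
        model = GrowthModel(initial_count=100, doubling_time=24,
                            drug_effect=DrugEffect(ec50_uM=1.0), noise_cv=0.0)
        t = np.linspace(0, 72, 289)
        df = simulate_growth(model, [0.0, 1.0], t, seed=0)
        aucs = {c.concentration_uM: curve_auc(c) for c in curves_from_frame(df)}
        fully_suppressed = 100.0 * 72.0  # flat at the initial count
        midway = (aucs[0.0] + fully_suppressed) / 2
        assert abs(aucs[1.0] - midway) / midway < 0.01

    def test_negative_concentration_rejected(self):
        model = GrowthModel(drug_effect=DrugEffect(ec50_uM=1.0))
        with pytest.raises(ConfigurationError):
            simulate_growth(model, [-1.0], [0.0, 24.0], seed=0)

    def test_seed_determinism(self):
        model = GrowthModel(drug_effect=DrugEffect(ec50_uM=0.5), noise_cv=0.1)
        t = np.arange(0, 72, 4.0)
        a = simulate_growth(model, [0.0, 0.5], t, replicates=2, seed=4)
        b = simulate_growth(model, [0.0, 0.5], t, replicates=2, seed=4)
        assert a.equals(b)


class TestVariantPairs:
    def test_empty_request_gives_empty_table(self):
        tab = simulate_variant_pairs({}, depth=30, seed=0)
        assert len(tab) == 0

    def test_class_genotype_configurations(self):
        tab = simulate_variant_pairs(
            {"germline": 30, "somatic": 30, "loh": 30, "reference": 30},
            depth=10_000, seed=1)
        loh = tab[tab["truth_class"] == "loh"]
        t_af = loh["t_alt"] / (loh["t_alt"] + loh["t_ref"])
        s_af = loh["s_alt"] / (loh["s_alt"] + loh["s_ref"])
        assert (t_af == 1.0).all()
        assert np.allclose(s_af, 0.5, atol=0.05)
        som = tab[tab["truth_class"] == "somatic"]
        assert (som["s_alt"] == 0).all()
        ref = tab[tab["truth_class"] == "reference"]
        assert (ref["t_alt"] == 0).all() and (ref["s_alt"] == 0).all()

    def test_seed_determinism(self):
        a = simulate_variant_pairs({"germline": 20, "somatic": 20}, 30, seed=2)
        b = simulate_variant_pairs({"germline": 20, "somatic": 20}, 30, seed=2)
        assert a.equals(b)
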