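import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from isomirkit.classify import SampleProfile, classify_sample
from isomirkit.preprocess import CollapsedRead
from isomirkit.profiles import (
    arm_uridylation,
    bh_adjust,
    compare_group_fractions,
    composition_table,
    cov_equality,
    nucvar_spectrum,
    uridylation_table,
    welch_t,
)


def make_profile(sample_id, class_counts, mirna_id="miR-1"):
    prof = SampleProfile(sample_id=sample_id)
    for klass, n in class_counts.items():
        key = (mirna_id, (klass, 0, 0, "T" if klass.startswith("NTA") else "", None))
        prof.counts[key] = float(n)
        prof.class_totals[klass] = prof.class_totals.get(klass, 0.0) + n
        prof.mapped_total += n
    return prof


class TestComposition:
    def test_single_sample_percentages(self):
        prof = make_profile("s1", {"canonical": 75, "NucVar": 10, "NTA-U": 15})
        table = composition_table([prof])
        assert table.loc["s1", "canonical"] == pytest.approx(75.0)
        assert table.loc["s1", "NucVar"] == pytest.approx(10.0)
        assert table.loc["s1", "NTA-U"] == pytest.approx(15.0)

    def test_identical_samples_have_zero_sd(self):
        profs = [make_profile(s, {"canonical": 8, "NTA-U": 2}) for s in ("a", "b")]
        table = composition_table(profs, groups={"a": "g", "b": "g"})
        assert (table.loc["g/sd"] == 0).all()
        assert table.loc["g/mean", "canonical"] == pytest.approx(80.0)

    def test_zero_mapped_sample_excluded_with_warning(self):
        empty = SampleProfile(sample_id="empty")
        with pytest.warns(UserWarning, match="zero mapped"):
            table = composition_table([make_profile("s1", {"canonical": 1}), empty])
        assert list(table.index) == ["s1"]

    def test_percentages_sum_to_100(self, toy_ref):
        reads = [CollapsedRead(s, c, c) for s, c in
                 [("TGAGG", 7), ("TGAGGT", 2), ("GAGG", 4), ("TGCGG", 1)]]
        prof = classify_sample(reads, toy_ref)
        assert sum(prof.class_percentages().values()) == pytest.approx(100.0, abs=1e-9)


class TestNucVarSpectrum:
    def test_single_substitution(self):
        prof = SampleProfile(sample_id="s")
        prof.counts[("miR-1", ("NucVar", 0, 0, "", (5, "A", "G")))] = 1.0
        prof.counts[("miR-1", ("canonical", 0, 0, "", None))] = 99.0
        prof.class_totals = {"NucVar": 1.0, "canonical": 99.0}
        prof.mapped_total = 100.0
        spec = nucvar_spectrum(prof)
        assert spec["A>G"] == pytest.approx(1.0)
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_no_nucvar_all_zero(self):
        prof = make_profile("s", {"canonical": 10})
        assert set(nucvar_spectrum(prof).values()) == {0.0}

    def test_simulated_spectrum_ranks_recovered(self, sim_ref):
        from isomirkit.simulate import SimConfig, simulate_sample
        from isomirkit.preprocess import five_n_protocol, extract_and_trim, collapse_reads

        cfg = SimConfig(
            n_mirnas=10, seed=11, depth=20_000,
            class_probs={"canonical": 0.70, "NucVar": 0.30},
            subst_spectrum={"T>C": 0.4, "A>G": 0.3,
                            **{k: 0.03 for k in
                               [f"{a}>{b}" for a in "ACGT" for b in "ACGT"
                                if a != b and f"{a}>{b}" not in ("T>C", "A>G")]}},
        )
        reads, _ = simulate_sample(sim_ref, cfg, mode="cells")
        pairs, _ = extract_and_trim((s for _, s in reads), five_n_protocol())
        prof = classify_sample(collapse_reads(pairs), sim_ref)
        spec = nucvar_spectrum(prof)
        ranked = sorted(spec, key=spec.get, reverse=True)
        assert ranked[0] == "T>C" and ranked[1] == "A>G"


class TestUridylation:
    def test_per_mirna_percentage(self):
        prof = SampleProfile(sample_id="s")
        prof.counts[("miR-1", ("NTA-U", 0, 0, "T", None))] = 8.0
        prof.counts[("miR-1", ("canonical", 0, 0, "", None))] = 32.0
        prof.mapped_total = 40.0
        tab = uridylation_table(prof)
        assert tab.loc["miR-1", "pct_NTA_U"] == pytest.approx(20.0)
        assert not tab.loc["miR-1", "low_coverage"]

    def test_absent_mirna_has_no_row_and_low_coverage_flag(self):
        prof = make_profile("s", {"canonical": 5})
        tab = uridylation_table(prof, min_reads=10)
        assert list(tab.index) == ["miR-1"]
        assert bool(tab.loc["miR-1", "low_coverage"])

    def test_arm_aggregation_zero_on_untailed_arm(self, sim_ref):
        prof = SampleProfile(sample_id="s")
        three_p = next(e for e in sim_ref.entries if e.arm == "3p")
        five_p = next(e for e in sim_ref.entries if e.arm == "5p")
        prof.counts[(three_p.mirna_id, ("NTA-U", 0, 0, "T", None))] = 5.0
        prof.counts[(three_p.mirna_id, ("canonical", 0, 0, "", None))] = 5.0
        prof.counts[(five_p.mirna_id, ("canonical", 0, 0, "", None))] = 10.0
        tab = arm_uridylation([prof], sim_ref)
        assert tab.set_index("arm").loc["5p", "mean_pct_NTA_U"] == 0.0
        assert tab.set_index("arm").loc["3p", "mean_pct_NTA_U"] == pytest.approx(50.0)


class TestGroupComparison:
    def test_identical_groups_t0_p1(self):
        res = compare_group_fractions({"c": [10, 12, 11]}, {"c": [10, 12, 11]})
        assert res.loc["c", "t"] == pytest.approx(0.0)
        assert res.loc["c", "p"] == pytest.approx(1.0)

    def test_clear_shift_flagged(self):
        res = compare_group_fractions({"c": [10, 12, 11]}, {"c": [2, 3, 2]})
        assert res.loc["c", "p"] < 0.01
        assert bool(res.loc["c", "significant"])

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="group B"):
            compare_group_fractions({"c": [1, 2]}, {"c": [1]})

    def test_zero_variance_equal_means(self):
        assert welch_t([5, 5], [5, 5]) == (0.0, 1.0)
        t, p = welch_t([5, 5], [1, 1])
        assert np.isinf(t) and p == 0.0


class TestBH:
    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_at_least_p_and_monotone_in_sorted_order(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCoV:
    def test_equal_counts_give_zero(self):
        assert cov_equality([5, 5, 5]) == 0.0

    def test_hand_computed_value(self):
        assert cov_equality([1, 3]) == pytest.approx(0.70711, abs=1e-5)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100), st.lists(st.integers(1, 1000), min_size=2, max_size=20))
    def test_scale_invariance(self, scale, counts):
        assert cov_equality(np.array(counts) * scale) == pytest.approx(
            cov_equality(counts), rel=1e-9
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cov_equality([0, 0])
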