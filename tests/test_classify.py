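import numpy as np
import pytest

from isomirkit.classify import ClassifyParams, classify_read, classify_sample
from isomirkit.preprocess import CollapsedRead

from _oracle import oracle_classify


def one_call(read, ref, **kw):
    calls = classify_read(read, ref, ClassifyParams(**kw))
    assert len(calls) == 1
    return calls[0]


class TestToyHierarchy:
    """The class schema on the toy hairpin CCTGAGGAAG, mature TGAGG at [2,7)."""

    def test_exact_mature_is_canonical(self, toy_ref):
        c = one_call("TGAGG", toy_ref)
        assert (c.klass, c.shift5, c.shift3, c.tail, c.subst, c.weight) == (
            "canonical", 0, 0, "", None, 1.0)

    def test_nontemplated_t_is_nta_u(self, toy_ref):
        # downstream template base is A, so the trailing T is non-templated
        c = one_call("TGAGGT", toy_ref)
        assert (c.klass, c.tail, c.shift3) == ("NTA-U", "T", 0)

    def test_templated_a_is_3p_extension_not_nta(self, toy_ref):
        c = one_call("TGAGGA", toy_ref)
        assert (c.klass, c.shift3, c.tail) == ("lv3pE", 1, "")

    def test_internal_substitution_is_nucvar(self, toy_ref):
        c = one_call("TGCGG", toy_ref)
        assert c.klass == "NucVar"
        assert c.subst == (2, "A", "C")

    def test_5p_trim_is_lv5pt(self, toy_ref):
        c = one_call("GAGG", toy_ref)
        assert (c.klass, c.shift5) == ("lv5pT", -1)

    def test_5p_trim_plus_tail_is_mv(self, toy_ref):
        c = one_call("GAGGTT", toy_ref)
        assert c.klass == "mv"
        assert (c.shift5, c.tail) == (-1, "TT")

    def test_trimmed_then_uridylated_is_nta_by_default(self, toy_ref):
        # TGAG (trim 1) + T: tail over an imperfect templated 3' end
        c = one_call("TGAGT", toy_ref)
        assert (c.klass, c.shift3, c.tail) == ("NTA-U", -1, "T")
        # switchable off: routed to mv instead
        c2 = one_call("TGAGT", toy_ref, allow_nta_on_shifted3=False)
        assert c2.klass == "mv"

    def test_mixed_tail_is_nta_mixed(self, toy_ref):
        c = one_call("TGAGGTC", toy_ref)
        assert (c.klass, c.tail) == ("NTA-mixed", "TC")

    def test_two_internal_mismatches_unassigned(self, toy_ref):
        c = one_call("TCCGG", toy_ref)
        assert c.klass == "unassigned"
        assert c.mirna_id is None

    def test_terminal_mismatch_not_nucvar(self, toy_ref):
        # mismatch at the last base: trimmed-then-tailed, not NucVar
        c = one_call("TGAGC", toy_ref)
        assert c.klass == "NTA-C"


class TestMultiMapping:
    def test_equal_hits_share_weight(self, twin_ref):
        mature = twin_ref.entries[0].mature_seq
        calls = classify_read(mature, twin_ref)
        assert [c.mirna_id for c in calls] == ["twin-miR-a", "twin-miR-b"]
        assert all(c.weight == 0.5 for c in calls)
        assert sum(c.weight for c in calls) == pytest.approx(1.0)

    def test_weighted_counts_conserved_in_profile(self, twin_ref):
        mature = twin_ref.entries[0].mature_seq
        prof = classify_sample([CollapsedRead(mature, 10, 10)], twin_ref)
        assert prof.mapped_total == pytest.approx(10.0)
        assert prof.class_totals["canonical"] == pytest.approx(10.0)


class TestClassifySample:
    def test_pure_canonical_sample(self, toy_ref):
        prof = classify_sample([CollapsedRead("TGAGG", 10, 10)], toy_ref)
        assert prof.mapped_total == 10
        assert prof.class_percentages() == {"canonical": 100.0}

    def test_mixed_toy_set_class_counts(self, toy_ref):
        reads = [CollapsedRead(s, 1, 1) for s in
                 ["TGAGG", "TGAGGT", "TGAGGA", "TGCGG", "GAGG", "GAGGTT"]]
        prof = classify_sample(reads, toy_ref)
        assert prof.class_totals == {
            "canonical": 1.0, "NTA-U": 1.0, "lv3pE": 1.0,
            "NucVar": 1.0, "lv5pT": 1.0, "mv": 1.0,
        }
        assert prof.mapped_total == 6.0

    def test_unassigned_excluded_from_mapped(self, toy_ref):
        prof = classify_sample(
            [CollapsedRead("TGAGG", 5, 5), CollapsedRead("GCGCGCGCGCGCGCGC", 2, 2)], toy_ref
        )
        assert prof.mapped_total == 5
        assert prof.unassigned_total == 2

    def test_empty_read_collection_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            classify_sample([], toy_ref)


class TestOracleAgreement:
    """classify_read must agree with exhaustive decomposition enumeration."""

    @staticmethod
    def _random_instances(n, seed):
        from isomirkit.simulate import SimConfig, generate_reference

        rng = np.random.default_rng(seed)
        ref = generate_reference(SimConfig(n_mirnas=4, seed=seed))
        reads = []
        for _ in range(n):
            e = ref.entries[rng.integers(len(ref.entries))]
            kind = rng.integers(4)
            if kind == 0:  # random string
                read = "".join(rng.choice(list("ACGT"), size=rng.integers(16, 27)))
            else:  # perturbed mature
                hp = ref.hairpins[e.hairpin_id]
                s5 = int(rng.integers(-5, 6))
                s3 = int(rng.integers(-5, 6))
                start = max(0, e.start - s5)
                end = min(len(hp), e.end + s3)
                read = hp[start:end]
                if rng.random() < 0.5:  # tail
                    read += "".join(rng.choice(list("ACGT"), size=rng.integers(1, 4)))
                if rng.random() < 0.4:  # substitutions
                    chars = list(read)
                    for _ in range(rng.integers(1, 3)):
                        i = rng.integers(len(chars))
                        chars[i] = "ACGT"[rng.integers(4)]
                    read = "".join(chars)
            if len(read) >= 5:
                reads.append((read, ref))
        return reads

    def test_matches_bruteforce_on_random_instances(self):
        params = ClassifyParams()
        instances = self._random_instances(300, seed=5)
        for read, ref in instances:
            got = classify_read(read, ref, params)
            want = oracle_classify(read, ref, params)
            assert got == want, f"disagreement on read {read}"

    def test_determinism(self, toy_ref):
        a = classify_read("TGAGGT", toy_ref)
        b = classify_read("TGAGGT", toy_ref)
        assert a == b
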