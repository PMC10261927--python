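"""Independent brute-force isomiR classification oracle.

Enumerates every (shift5, templated span, tail) decomposition of a read
against every mature entry directly, without the production code's greedy
matching, and applies the class schema from first principles. Used to
verify ``isomirkit.classify.classify_read`` on random instances.
"""

from dataclasses import replace

from isomirkit.classify import ClassifyParams, IsomiRCall, UNASSIGNED, _CLASS_RANK


def _nta_class(tail: str) -> str:
    if len(set(tail)) == 1:
        return {"A": "NTA-A", "T": "NTA-U", "C": "NTA-C", "G": "NTA-G"}[tail[0]]
    return "NTA-mixed"


def _klass_of(shift5, shift3, tail, subst, params) -> str:
    if subst is not None:
        return "NucVar"
    if shift5 == 0 and shift3 == 0 and tail == "":
        return "canonical"
    if shift5 == 0 and tail != "":
        if params.allow_nta_on_shifted3 or shift3 == 0:
            return _nta_class(tail)
        return "mv"
    if shift5 != 0 and (shift3 != 0 or tail != ""):
        return "mv"
    if shift5 != 0:
        return "lv5pT" if shift5 < 0 else "lv5pE"
    return "lv3pT" if shift3 < 0 else "lv3pE"


def oracle_classify(read: str, ref, params: ClassifyParams = ClassifyParams()):
    per_entry_best = []
    for entry in ref.entries:
        hp = ref.hairpins[entry.hairpin_id]
        L = len(read)
        mature_len = entry.end - entry.start
        cands = []
        for shift5 in range(-params.max_5p_shift, params.max_5p_shift + 1):
            p5 = entry.start - shift5
            if p5 < 0:
                continue
            for t in range(0, params.max_tail + 1):
                m = L - t
                if m < 1 or p5 + m > len(hp):
                    continue
                mism = [i for i in range(m) if read[i] != hp[p5 + i]]
                tail = read[m:]
                shift3 = (p5 + m) - entry.end
                if abs(shift3) > params.max_3p_shift:
                    continue
                # maximality: a tail may not start with the templated base
                if t > 0 and p5 + m < len(hp) and read[m] == hp[p5 + m]:
                    continue
                if mism:
                    # mismatches only allowed in the NucVar shape: canonical
                    # ends, internal positions only
                    if (
                        shift5 == 0
                        and shift3 == 0
                        and t == 0
                        and L == mature_len
                        and len(mism) <= params.max_internal_mismatch
                        and all(0 < i < L - 1 for i in mism)
                    ):
                        subst = (mism[0], entry.mature_seq[mism[0]], read[mism[0]])
                        cands.append(
                            IsomiRCall(entry.mirna_id, "NucVar", 0, 0, "", subst)
                        )
                    continue
                klass = _klass_of(shift5, shift3, tail, None, params)
                cands.append(IsomiRCall(entry.mirna_id, klass, shift5, shift3, tail, None))
        if cands:
            per_entry_best.append(
                min(
                    cands,
                    key=lambda c: (
                        c.edits, _CLASS_RANK[c.klass], abs(c.shift5), abs(c.shift3),
                        len(c.tail), c.shift5, c.shift3, c.tail,
                    ),
                )
            )
    if not per_entry_best:
        return [UNASSIGNED]
    best = min(c.edits for c in per_entry_best)
    hits = sorted((c for c in per_entry_best if c.edits == best), key=lambda c: c.mirna_id)
    return [replace(c, weight=1.0 / len(hits)) for c in hits]
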