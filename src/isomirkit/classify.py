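"""Hierarchical isomiR classification.

Each read is aligned against every mature miRNA inside its hairpin and
decomposed into a 5' shift, a templated 3' span, and a residual
non-templated 3' tail.  The hairpin context is what tells a genuine
non-templated addition (NTA) apart from a templated 3' extension: a
trailing base is consumed as templated extension whenever it matches the
hairpin immediately downstream of the mature end, and only the residual
non-matching suffix is a tail (templated-first rule).

Classes, in strict hierarchical order:

1. ``canonical``  — exactly the annotated mature sequence.
2. ``NucVar``     — canonical ends, exactly one *internal* substitution.
3. ``NTA-A/U/C/G``/``NTA-mixed`` — canonical 5' end plus a non-templated
   3' tail (class by tail base when it is a homopolymer). A trimmed or
   templately extended 3' end under the tail is permitted by default
   (``allow_nta_on_shifted3``) and recorded in ``shift3``.
4. ``lv5pT/lv5pE/lv3pT/lv3pE`` — a single end trimmed (T) or templately
   extended (E).
5. ``mv``         — both ends deviate, or the 5' end deviates and there is
   a tail.

A read failing every candidate (e.g. two internal mismatches) is
``unassigned``. Reads matching several miRNAs equally well are fractionally
weighted 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .preprocess import CollapsedRead
from .refdata import MatureEntry, ReferenceSet

#: Report-order of classes; also the hierarchy rank used for tie-breaking.
CLASS_ORDER = [
    "canonical",
    "NucVar",
    "NTA-A",
    "NTA-U",
    "NTA-C",
    "NTA-G",
    "NTA-mixed",
    "lv5pT",
    "lv5pE",
    "lv3pT",
    "lv3pE",
    "mv",
    "unassigned",
]
_CLASS_RANK = {k: i for i, k in enumerate(CLASS_ORDER)}

#: DNA tail base -> reported NTA label (RNA convention for U).
NTA_LABEL = {"A": "NTA-A", "T": "NTA-U", "C": "NTA-C", "G": "NTA-G"}

SUBSTITUTION_CLASSES = [
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
]


@dataclass(frozen=True)
class ClassifyParams:
    max_5p_shift: int = 5
    max_3p_shift: int = 5
    max_tail: int = 3
    max_internal_mismatch: int = 1
    min_count: int = 1
    #: permit NTA calls on reads whose templated 3' end is itself shifted
    #: (e.g. trimmed by one then uridylated); off routes such reads to mv.
    allow_nta_on_shifted3: bool = True

    def __post_init__(self) -> None:
        for name in ("max_5p_shift", "max_3p_shift", "max_tail", "max_internal_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class IsomiRCall:
    """One read's class assignment against one miRNA.

    ``shift5``/``shift3``: negative = trimmed, positive = templated
    extension (templated portion only). ``tail`` is the non-templated 3'
    suffix. ``subst`` is (position in read, ref base, read base) for
    NucVar. ``weight`` is the multi-mapping fraction in (0, 1].
    """

    mirna_id: Optional[str]
    klass: str
    shift5: int = 0
    shift3: int = 0
    tail: str = ""
    subst: Optional[tuple[int, str, str]] = None
    weight: float = 1.0

    @property
    def edits(self) -> int:
        return (1 if self.subst else 0) + abs(self.shift5) + abs(self.shift3) + len(self.tail)


UNASSIGNED = IsomiRCall(mirna_id=None, klass="unassigned")


def _tail_class(tail: str) -> str:
    bases = set(tail)
    if len(bases) == 1:
        return NTA_LABEL[tail[0]]
    return "NTA-mixed"


def _assign_class(shift5: int, shift3: int, tail: str,
                  subst: Optional[tuple], params: ClassifyParams) -> str:
    if subst is not None:
        return "NucVar"
    if shift5 == 0 and shift3 == 0 and not tail:
        return "canonical"
    if shift5 == 0 and tail:
        if params.allow_nta_on_shifted3 or shift3 == 0:
            return _tail_class(tail)
        return "mv"
    if shift5 != 0 and (shift3 != 0 or tail):
        return "mv"
    if shift5 != 0:
        return "lv5pT" if shift5 < 0 else "lv5pE"
    return "lv3pT" if shift3 < 0 else "lv3pE"


def _entry_candidates(
    read: str, entry: MatureEntry, hairpin: str, params: ClassifyParams
) -> list[IsomiRCall]:
    """All valid decompositions of ``read`` against one mature entry."""
    cands: list[IsomiRCall] = []
    L = len(read)
    hp_len = len(hairpin)

    # End-anchored decompositions (mismatch-free templated span + tail).
    for shift5 in range(-params.max_5p_shift, params.max_5p_shift + 1):
        p5 = entry.start - shift5
        if p5 < 0 or p5 >= hp_len:
            continue
        lim = min(L, hp_len - p5)
        m = 0
        while m < lim and read[m] == hairpin[p5 + m]:
            m += 1
        if m == 0:
            continue  # no templated anchor at all
        tail = read[m:]
        if len(tail) > params.max_tail:
            continue
        shift3 = (p5 + m) - entry.end
        if abs(shift3) > params.max_3p_shift:
            continue
        klass = _assign_class(shift5, shift3, tail, None, params)
        cands.append(IsomiRCall(entry.mirna_id, klass, shift5, shift3, tail, None))

    # NucVar: same span as the mature, <= max_internal_mismatch internal
    # substitutions (terminal mismatches are end variants/tails, not NucVar).
    if L == entry.end - entry.start:
        mism = [
            (i, entry.mature_seq[i], read[i])
            for i in range(L)
            if read[i] != entry.mature_seq[i]
        ]
        if 1 <= len(mism) <= params.max_internal_mismatch and all(
            0 < i < L - 1 for i, _, _ in mism
        ):
            cands.append(
                IsomiRCall(entry.mirna_id, "NucVar", 0, 0, "", mism[0])
            )
    return cands


def _sort_key(c: IsomiRCall):
    return (c.edits, _CLASS_RANK[c.klass], abs(c.shift5), abs(c.shift3),
            len(c.tail), c.shift5, c.shift3, c.tail)


def classify_read(
    insert_seq: str, ref: ReferenceSet, params: ClassifyParams = ClassifyParams()
) -> list[IsomiRCall]:
    """Classify one read against the whole reference.

    Returns the minimal-edit call per miRNA tied at the global minimum edit
    count (mismatches + |shift5| + |shift3| + tail length), each weighted
    1/k, ordered by mirna_id; or a single ``unassigned`` call.
    """
    best_per_entry: list[IsomiRCall] = []
    for entry in ref.entries:
        cands = _entry_candidates(insert_seq, entry, ref.hairpins[entry.hairpin_id], params)
        if cands:
            best_per_entry.append(min(cands, key=_sort_key))
    if not best_per_entry:
        return [UNASSIGNED]
    min_edits = min(c.edits for c in best_per_entry)
    hits = sorted(
        (c for c in best_per_entry if c.edits == min_edits),
        key=lambda c: c.mirna_id,
    )
    w = 1.0 / len(hits)
    return [replace(c, weight=w) for c in hits]


@dataclass
class SampleProfile:
    """Per-sample weighted isomiR counts and class totals.

    ``counts`` maps (mirna_id, variant key) -> weighted count, where the
    variant key is (klass, shift5, shift3, tail, subst). ``mapped_total``
    excludes unassigned reads, which are tallied separately.
    """

    sample_id: str
    counts: dict = field(default_factory=dict)
    class_totals: dict = field(default_factory=dict)
    mapped_total: float = 0.0
    unassigned_total: float = 0.0

    def add_call(self, call: IsomiRCall, count: float) -> None:
        if call.klass == "unassigned":
            self.unassigned_total += count
            return
        w = call.weight * count
        key = (call.mirna_id, (call.klass, call.shift5, call.shift3, call.tail, call.subst))
        self.counts[key] = self.counts.get(key, 0.0) + w
        self.class_totals[call.klass] = self.class_totals.get(call.klass, 0.0) + w
        self.mapped_total += w

    def class_percentages(self) -> dict[str, float]:
        """Class shares of the miRNA-mapped total, in percent."""
        if self.mapped_total <= 0:
            return {}
        return {k: 100.0 * v / self.mapped_total for k, v in self.class_totals.items()}

    def mirna_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (mid, _), v in self.counts.items():
            out[mid] = out.get(mid, 0.0) + v
        return out


def classify_sample(
    reads: Iterable[CollapsedRead],
    ref: ReferenceSet,
    params: ClassifyParams = ClassifyParams(),
    sample_id: str = "sample",
) -> SampleProfile:
    """Classify a collapsed read set into a :class:`SampleProfile`.

    Classification results are cached per unique insert; reads below
    ``params.min_count`` are skipped.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("empty read collection")
    if not ref.entries:
        raise ValueError("empty reference")
    profile = SampleProfile(sample_id=sample_id)
    cache: dict[str, list[IsomiRCall]] = {}
    for read in reads:
        if read.count < params.min_count:
            continue
        calls = cache.get(read.insert_seq)
        if calls is None:
            calls = classify_read(read.insert_seq, ref, params)
            cache[read.insert_seq] = calls
        for call in calls:
            profile.add_call(call, read.count)
    return profile


def calls_table(
    reads: Iterable[CollapsedRead],
    ref: ReferenceSet,
    params: ClassifyParams = ClassifyParams(),
):
    """Per-read calls as a pandas DataFrame (read_seq, count, call fields)."""
    import pandas as pd

    rows = []
    for read in reads:
        for call in classify_read(read.insert_seq, ref, params):
            subst = (
                f"{call.subst[0]}:{call.subst[1]}>{call.subst[2]}" if call.subst else ""
            )
            rows.append(
                (read.insert_seq, read.count, call.mirna_id or "", call.klass,
                 call.shift5, call.shift3, call.tail, subst, call.weight)
            )
    return pd.DataFrame(
        rows,
        columns=["read_seq", "count", "mirna_id", "klass", "shift5",
                 "shift3", "tail", "subst", "weight"],
    )
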