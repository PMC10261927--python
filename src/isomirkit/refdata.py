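"""miRNA reference handling.

Mature miRNAs are located inside their precursor hairpins so that the
templated sequence immediately downstream of the mature 3' end is known.
That downstream template is what separates a genuine non-templated addition
(NTA) from an ordinary templated 3' extension.

All sequences are stored in DNA space (U -> T) with 0-based half-open
coordinates; labels are only converted back to RNA conventions ("NTA-U")
in reports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ARM_SUFFIX = re.compile(r"-(5p|3p)(\.\d+)?$", re.IGNORECASE)


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return str(seq).upper().replace("U", "T")


@dataclass(frozen=True)
class MatureEntry:
    """A mature miRNA located inside its hairpin.

    ``start``/``end`` are 0-based half-open offsets of the mature sequence
    in the hairpin; ``arm`` is "5p" or "3p".
    """

    mirna_id: str
    mature_seq: str
    hairpin_id: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.mirna_id}: invalid coordinates [{self.start}, {self.end})")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mirna_id}: arm must be 5p or 3p, got {self.arm!r}")
        if self.end - self.start != len(self.mature_seq):
            raise ValueError(f"{self.mirna_id}: span does not match mature length")


@dataclass
class ReferenceSet:
    """Validated collection of mature miRNAs plus their hairpins."""

    entries: list[MatureEntry]
    hairpins: dict[str, str]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.mirna_id in seen:
                raise ValueError(f"duplicate mirna_id {e.mirna_id!r}")
            seen.add(e.mirna_id)
            hp = self.hairpins.get(e.hairpin_id)
            if hp is None:
                raise ValueError(f"{e.mirna_id}: hairpin {e.hairpin_id!r} missing")
            if e.end > len(hp):
                raise ValueError(f"{e.mirna_id}: coordinates exceed hairpin length")
            if hp[e.start:e.end] != e.mature_seq:
                raise ValueError(f"{e.mirna_id}: hairpin slice does not equal mature sequence")
        self._by_id = {e.mirna_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, mirna_id: str) -> MatureEntry:
        try:
            return self._by_id[mirna_id]
        except KeyError:
            raise KeyError(f"unknown mirna_id {mirna_id!r}") from None

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._by_id


def _id_stem(mirna_id: str) -> str:
    """Strip the -5p/-3p (and trailing .N) suffix and lowercase.

    miRBase mature ids ("hsa-miR-30e-3p") map to hairpin ids ("hsa-mir-30e")
    by this stem, modulo miR/mir capitalisation.
    """
    return _ARM_SUFFIX.sub("", mirna_id).lower()


def _infer_arm(mirna_id: str, start: int, end: int, hairpin_len: int) -> str:
    m = _ARM_SUFFIX.search(mirna_id)
    if m:
        return m.group(1).lower()
    mid = (start + end) / 2.0
    return "5p" if mid < hairpin_len / 2.0 else "3p"


def _read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read FASTA {path}: {exc}") from exc
    for rec in parsed:
        rid = rec.id
        if rid in records:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        records[rid] = normalize_seq(rec.seq)
    if not records:
        raise ValueError(f"empty FASTA {path}")
    return records


def _read_coords_tsv(path: str | Path) -> dict[str, tuple[str, int, int]]:
    coords: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("mirna_id\t"):
                continue
            mirna_id, hairpin_id, start, end = line.split("\t")[:4]
            coords[mirna_id] = (hairpin_id, int(start), int(end))
    return coords


def load_reference(
    mature_fasta: str | Path,
    hairpin_fasta: str | Path,
    coords_tsv: str | Path | None = None,
) -> ReferenceSet:
    """Load mature + hairpin FASTA files into a validated :class:`ReferenceSet`.

    Each mature sequence is located in a hairpin by exact substring search,
    first among hairpins sharing the id stem, then over all hairpins.  An
    explicit TSV coordinates table (mirna_id, hairpin_id, start, end)
    overrides the search.  Matures not found in any hairpin are dropped and
    reported in ``ReferenceSet.dropped``; the leftmost occurrence is used
    (with a warning) when a mature occurs more than once.
    """
    matures = _read_fasta(mature_fasta)
    hairpins = _read_fasta(hairpin_fasta)
    coords = _read_coords_tsv(coords_tsv) if coords_tsv else {}

    stem_index: dict[str, list[str]] = {}
    for hid in hairpins:
        stem_index.setdefault(hid.lower(), []).append(hid)

    entries: list[MatureEntry] = []
    dropped: list[str] = []
    for mid, mseq in matures.items():
        placed = None
        if mid in coords:
            hid, start, end = coords[mid]
            if hid not in hairpins:
                raise ValueError(f"coordinates table: unknown hairpin {hid!r}")
            if hairpins[hid][start:end] != mseq:
                raise ValueError(f"coordinates table: {mid} slice mismatch in {hid}")
            placed = (hid, start, end)
        else:
            stem = _id_stem(mid)
            candidates = stem_index.get(stem, [])
            search_order = candidates + [h for h in hairpins if h not in candidates]
            for hid in search_order:
                pos = hairpins[hid].find(mseq)
                if pos >= 0:
                    if hairpins[hid].find(mseq, pos + 1) >= 0:
                        logger.warning(
                            "%s occurs more than once in %s; using leftmost occurrence", mid, hid
                        )
                    placed = (hid, pos, pos + len(mseq))
                    break
        if placed is None:
            dropped.append(mid)
            logger.warning("mature %s not found in any hairpin; dropped", mid)
            continue
        hid, start, end = placed
        arm = _infer_arm(mid, start, end, len(hairpins[hid]))
        entries.append(MatureEntry(mid, mseq, hid, start, end, arm))

    if not entries:
        raise ValueError("empty reference: no mature sequence could be placed")
    return ReferenceSet(entries=entries, hairpins=hairpins, dropped=dropped)


def write_reference(ref: ReferenceSet, mature_fasta: str | Path, hairpin_fasta: str | Path) -> None:
    """Write a ReferenceSet back to mature + hairpin FASTA files."""
    SeqIO.write(
        [SeqRecord(Seq(e.mature_seq), id=e.mirna_id, description="") for e in ref.entries],
        str(mature_fasta),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(seq), id=hid, description="") for hid, seq in ref.hairpins.items()],
        str(hairpin_fasta),
        "fasta",
    )


def downstream_template(ref: ReferenceSet, mirna_id: str, n: int) -> str:
    """Hairpin bases immediately 3' of the mature end (up to ``n``).

    Shorter than ``n`` near the hairpin boundary; empty for ``n == 0``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    entry = ref.get(mirna_id)
    hairpin = ref.hairpins[entry.hairpin_id]
    return hairpin[entry.end : entry.end + n]
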