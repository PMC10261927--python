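"""Adapter/UMI handling and read collapsing.

Supports both fixed-adapter protocols (no UMIs) and randomized-adapter
4N/5N layouts where each adapter carries random nucleotides that end up
flanking the insert after 3' adapter removal:

    read = [umi5][insert][umi3][3' adapter ...]

UMI sequencing errors are not corrected (no 1-mismatch UMI clustering);
quality scores are ignored after parsing, classification being purely
sequence-based.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .refdata import normalize_seq

#: 3' adapter of the NEBNext small RNA kit, the base chemistry of the 5N protocol.
DEFAULT_ADAPTER3 = "AGATCGGAAGAGCACACGTCT"


@dataclass(frozen=True)
class ProtocolSpec:
    """Library-layout description for one protocol.

    ``umi5_len``/``umi3_len`` are the number of random nucleotides the 5'
    and 3' adapters contribute to the read (5 and 5 for the 5N protocol,
    0 and 0 for fixed adapters). ``adapter3 == ""`` means the reads are
    already adapter-trimmed.
    """

    adapter3: str = DEFAULT_ADAPTER3
    umi5_len: int = 0
    umi3_len: int = 0
    min_insert: int = 16
    max_insert: int = 28

    def __post_init__(self) -> None:
        if not (0 <= self.umi5_len <= 8 and 0 <= self.umi3_len <= 8):
            raise ValueError("UMI lengths must be in [0, 8]")
        if self.min_insert > self.max_insert:
            raise ValueError("min_insert must be <= max_insert")


def five_n_protocol(**kw) -> ProtocolSpec:
    """5N randomized-adapter layout: 5 random nt on each adapter."""
    return ProtocolSpec(umi5_len=5, umi3_len=5, **kw)


def fixed_adapter_protocol(**kw) -> ProtocolSpec:
    """Fixed (invariant) adapter layout: no UMIs."""
    return ProtocolSpec(umi5_len=0, umi3_len=0, **kw)


@dataclass(frozen=True)
class CollapsedRead:
    """One unique insert with its (optionally UMI-deduplicated) count."""

    insert_seq: str
    count: int
    umi_distinct: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def find_adapter(read: str, adapter: str, min_overlap: int = 8, max_mismatch: int = 1) -> int:
    """Leftmost start of the 3' adapter in ``read``, or -1.

    A hit is a prefix of ``adapter`` aligned at position i covering
    min(len(adapter), len(read) - i) >= ``min_overlap`` bases with at most
    ``max_mismatch`` mismatches (seed-and-extend exact prefix scan).
    """
    n, a = len(read), len(adapter)
    for i in range(0, n - min_overlap + 1):
        k = min(a, n - i)
        if k < min_overlap:
            break
        mm = 0
        ok = True
        for x, y in zip(read[i : i + k], adapter[:k]):
            if x != y:
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            return i
    return -1


def _open_maybe_gz(path: str | Path) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_reads(source: str | Path | TextIO, fmt: str) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        handle = _open_maybe_gz(source)
    else:
        handle = source
    idx = -1
    try:
        parser = SeqIO.parse(handle, fmt)
        while True:
            idx += 1
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed {fmt.upper()} record #{idx}: {exc}") from exc
            yield normalize_seq(rec.seq)
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def extract_and_trim(
    reads: str | Path | TextIO | Iterable[str],
    spec: ProtocolSpec,
    fmt: str = "fastq",
) -> tuple[list[tuple[str, str]], Counter]:
    """Trim the 3' adapter, strip UMIs, and filter by insert length.

    ``reads`` may be a FASTQ/FASTA path (gz-transparent), an open handle,
    or an iterable of raw read strings. Returns the kept
    ``(insert_seq, umi_key)`` pairs plus a Counter of discard reasons
    (``no_adapter``, ``too_short``, ``too_long``) and the ``kept`` total.
    """
    if isinstance(reads, (str, Path)) or hasattr(reads, "read"):
        read_iter: Iterable[str] = _parse_reads(reads, fmt)
    else:
        read_iter = (normalize_seq(r) for r in reads)

    pairs: list[tuple[str, str]] = []
    stats: Counter = Counter()
    u5, u3 = spec.umi5_len, spec.umi3_len
    for read in read_iter:
        if spec.adapter3:
            pos = find_adapter(read, spec.adapter3)
            if pos < 0:
                stats["no_adapter"] += 1
                continue
            trimmed = read[:pos]
        else:
            trimmed = read
        if len(trimmed) < u5 + u3 + spec.min_insert:
            stats["too_short"] += 1
            continue
        umi5 = trimmed[:u5]
        umi3 = trimmed[len(trimmed) - u3 :] if u3 else ""
        insert = trimmed[u5 : len(trimmed) - u3] if u3 else trimmed[u5:]
        if len(insert) > spec.max_insert:
            stats["too_long"] += 1
            continue
        pairs.append((insert, umi5 + umi3))
        stats["kept"] += 1
    return pairs, stats


def collapse_reads(pairs: Iterable[tuple[str, str]], dedup: bool = True) -> list[CollapsedRead]:
    """Collapse (insert, umi_key) pairs into unique inserts.

    With ``dedup`` on, identical (insert, umi) pairs count once and the
    count is the number of distinct UMI keys per insert; with it off the
    count is the raw read count.
    """
    raw: Counter = Counter()
    umis: dict[str, set] = defaultdict(set)
    for insert, umi in pairs:
        raw[insert] += 1
        umis[insert].add(umi)
    out = []
    for insert in sorted(raw):
        n_umi = len(umis[insert])
        out.append(
            CollapsedRead(
                insert_seq=insert,
                count=n_umi if dedup else raw[insert],
                umi_distinct=n_umi,
            )
        )
    return out


def write_collapsed_fasta(reads: list[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``seq{i}-{count}`` headers."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">seq{i}-{r.count}\n{r.insert_seq}\n")


def write_collapsed_tsv(reads: list[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("insert\tcount\tumi_distinct\n")
        for r in reads:
            fh.write(f"{r.insert_seq}\t{r.count}\t{r.umi_distinct}\n")


def read_collapsed_tsv(path: str | Path) -> list[CollapsedRead]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("insert\t"):
            raise ValueError(f"{path}: not a collapsed-reads TSV")
        for line in fh:
            insert, count, umi = line.rstrip("\n").split("\t")
            out.append(CollapsedRead(insert, int(count), int(umi)))
    return out
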