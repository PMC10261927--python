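"""Synthetic small RNA-seq generator with exact ground truth.

Two regimes are emulated end-to-end (molecule -> ligation bias -> PCR
duplication -> UMI-carrying FASTQ):

* ``pool`` mode — an equimolar pool of chemically synthesised canonical
  miRNAs: no enzymatic tails and no biological length variants, only
  low-rate uniform oligosynthesis substitutions and a small optional
  truncation rate. Any NTA call on pool reads is by construction a
  classifier false positive.
* ``cells`` mode — cell-like samples: molecules drawn from a class mix
  with NTA-U/A tails (3p arms uridylated preferentially), an internal
  substitution spectrum enriched for T>C and A>G (RNA-editing-like), and
  3'-dominant length variants.

Both modes share the library mechanics: a per-sequence log-normal capture
efficiency (ligation bias), geometric PCR duplication, and 4N/5N-style
random nucleotides flanking the insert. Every molecule is recorded in a
truth table whose proportions equal the realized counts exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER3
from .refdata import MatureEntry, ReferenceSet

_BASES = "ACGT"

#: cells-mode class mix (canonical-heavy, lv3p-dominant length variants,
#: NTA-U/A tails, a few percent internal substitutions).
DEFAULT_CLASS_PROBS = {
    "canonical": 0.45,
    "lv3pT": 0.25,
    "NTA-U": 0.10,
    "NTA-A": 0.10,
    "NucVar": 0.05,
    "lv3pE": 0.05,
}

#: internal substitution spectrum, T>C and A>G enriched.
DEFAULT_SUBST_SPECTRUM = {
    "T>C": 0.30,
    "A>G": 0.25,
    **{
        f"{a}>{b}": 0.045
        for a in "ACGT"
        for b in "ACGT"
        if a != b and f"{a}>{b}" not in ("T>C", "A>G")
    },
}

_NTA_BASE = {"NTA-A": "A", "NTA-U": "T", "NTA-C": "C", "NTA-G": "G"}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults describe a 5N-protocol run."""

    n_mirnas: int = 30
    hairpin_len: int = 60
    mature_len_range: tuple[int, int] = (20, 23)
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    tail_len_probs: dict = field(default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    subst_spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SUBST_SPECTRUM))
    #: pool mode: per-base oligosynthesis substitution probability.
    synthesis_error_rate: float = 0.003
    #: pool mode: per-molecule probability of a small 5'/3' truncation.
    pool_trim5_rate: float = 0.02
    pool_trim3_rate: float = 0.01
    #: log-scale sd of the per-sequence capture multiplier (ligation bias);
    #: near 0 emulates randomized adapters, ~1 a fixed-adapter protocol.
    ligation_bias_sd: float = 0.25
    pcr_dup_mean: float = 3.0
    umi5_len: int = 5
    umi3_len: int = 5
    adapter3: str = DEFAULT_ADAPTER3
    #: multiplier on the NTA-U propensity of 3p-arm miRNAs.
    arm3p_ntau_multiplier: float = 5.0
    #: log-scale sd of the per-miRNA tail propensity (uridylation and the
    #: other NTAs are strongly miRNA-specific in cells; 0 disables).
    mirna_tail_dispersion: float = 0.8
    #: cells mode: emulate a TUT4/7 double knockout. Each NTA-U molecule is
    #: converted, with its miRNA's TUT4/7-dependence probability, to NTA-A
    #: (uridylation lost to the competing adenylase) or to a canonical
    #: molecule when adenylation is not templatable for that miRNA.
    knockout_tut4_7: bool = False
    depth: int = 50_000  # pre-PCR molecules per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for d in (self.class_probs, self.tail_len_probs, self.subst_spectrum):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth: one row per sequenced pre-PCR molecule.

    Columns: mol_id, mirna_id, klass, shift5, shift3, tail, subst, insert,
    n_reads (PCR copies actually emitted).
    """

    molecules: pd.DataFrame

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_reads(self) -> int:
        return int(self.molecules["n_reads"].sum())

    def class_proportions(self, level: str = "molecule") -> dict[str, float]:
        """Realized class proportions, by molecule or by (PCR-duplicated) read."""
        if level == "molecule":
            counts = self.molecules["klass"].value_counts()
        elif level == "read":
            counts = self.molecules.groupby("klass")["n_reads"].sum()
        else:
            raise ValueError("level must be 'molecule' or 'read'")
        total = counts.sum()
        return {k: float(v) / total for k, v in counts.items()}

    def tail_probabilities(self) -> pd.DataFrame:
        """Per-miRNA realized NTA fractions (molecule level)."""
        df = self.molecules
        rows = []
        for mid, sub in df.groupby("mirna_id"):
            n = len(sub)
            rows.append(
                {
                    "mirna_id": mid,
                    "n": n,
                    **{
                        k: float((sub["klass"] == k).sum()) / n
                        for k in ("NTA-U", "NTA-A", "NTA-C", "NTA-G")
                    },
                }
            )
        return pd.DataFrame(rows).set_index("mirna_id")

    def to_tsv(self, path: str | Path) -> None:
        self.molecules.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def generate_reference(cfg: SimConfig) -> ReferenceSet:
    """Random hairpins with embedded 5p/3p mature arms.

    Each hairpin carries up to two arms with >= 4 nt of flanking template
    on both sides (so templated 5'/3' extensions and the downstream
    template are always defined). Hairpins are resampled until every
    mature occurs exactly once across all hairpins, which keeps the
    classification ground truth unambiguous.
    """
    if cfg.n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    lo, hi = cfg.mature_len_range
    if hi + 8 > cfg.hairpin_len or 2 * hi + 10 > cfg.hairpin_len:
        raise ValueError("hairpin_len too short for the mature length range")
    rng = np.random.default_rng(cfg.seed)
    entries: list[MatureEntry] = []
    hairpins: dict[str, str] = {}
    i = 0
    while len(entries) < cfg.n_mirnas:
        i += 1
        hid = f"sim-mir-{i}"
        want = ["5p", "3p"][: min(2, cfg.n_mirnas - len(entries))]
        for _ in range(200):
            hp = _random_seq(rng, cfg.hairpin_len)
            cand: list[MatureEntry] = []
            for arm in want:
                L = int(rng.integers(lo, hi + 1))
                if arm == "5p":
                    start = 4
                else:
                    start = cfg.hairpin_len - 4 - L
                cand.append(
                    MatureEntry(f"sim-miR-{i}-{arm}", hp[start : start + L], hid, start, start + L, arm)
                )
            all_hp = list(hairpins.values()) + [hp]
            ok = all(
                sum(h.count(e.mature_seq) for h in all_hp) == 1 for e in cand
            ) and all(
                hp.count(e.mature_seq) == 0 for e in entries
            )
            if ok:
                hairpins[hid] = hp
                entries.extend(cand)
                break
        else:
            raise RuntimeError("could not sample a repeat-free hairpin")
    return ReferenceSet(entries=entries, hairpins=hairpins)


def _draw(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


class _CellsSampler:
    """Draws one cells-mode molecule at a time."""

    def __init__(self, ref: ReferenceSet, cfg: SimConfig, rng: np.random.Generator):
        self.ref, self.cfg, self.rng = ref, cfg, rng
        self.entries = list(ref.entries)
        # miRNA-specific tail propensity (shared across NTA classes); the
        # same reference always yields the same propensities so that WT and
        # DKO samples of a study agree on which miRNAs are tail-prone.
        prop_rng = np.random.default_rng(
            np.random.SeedSequence(
                [zlib.crc32(e.mirna_id.encode()) for e in self.entries]
            )
        )
        self.tail_propensity = {
            e.mirna_id: float(prop_rng.lognormal(0.0, cfg.mirna_tail_dispersion))
            for e in self.entries
        }
        # graded TUT4/7 dependence: the fraction of a miRNA's uridylation
        # that the two enzymes account for (the rest persists in the DKO).
        self.tut_dependence = {
            e.mirna_id: float(prop_rng.uniform()) for e in self.entries
        }
        # per-NTA-base feasible miRNAs: the first tail base must not be
        # templated, or the classifier would (correctly) read it as a
        # templated extension.
        self.nta_feasible: dict[str, tuple[list[MatureEntry], np.ndarray]] = {}
        for klass, base in _NTA_BASE.items():
            feas = []
            for e in self.entries:
                hp = ref.hairpins[e.hairpin_id]
                if e.end < len(hp) and hp[e.end] != base:
                    feas.append(e)
            if feas:
                if klass == "NTA-U":
                    # arm-level mass ratio 3p:5p equals the multiplier,
                    # split within each arm by miRNA tail propensity
                    n3 = sum(e.arm == "3p" for e in feas)
                    n5 = len(feas) - n3
                    w = np.array(
                        [
                            (cfg.arm3p_ntau_multiplier / n3 if e.arm == "3p" else 1.0 / n5)
                            if 0 < n3 < len(feas)
                            else 1.0
                            for e in feas
                        ]
                    )
                else:
                    w = np.ones(len(feas))
                w = w * np.array([self.tail_propensity[e.mirna_id] for e in feas])
                self.nta_feasible[klass] = (feas, w / w.sum())

    def _pick(self, entries, weights=None) -> MatureEntry:
        idx = self.rng.choice(len(entries), p=weights)
        return entries[idx]

    def molecule(self) -> dict:
        cfg, rng = self.cfg, self.rng
        klass = _draw(rng, cfg.class_probs)
        rec = {"klass": klass, "shift5": 0, "shift3": 0, "tail": "", "subst": ""}
        if klass in _NTA_BASE:
            feas, w = self.nta_feasible[klass]
            e = self._pick(feas, w)
            if (
                klass == "NTA-U"
                and cfg.knockout_tut4_7
                and rng.random() < self.tut_dependence[e.mirna_id]
            ):
                # TUT4/7-dependent uridylation lost in the knockout; the
                # competing adenylase takes over where templatable.
                hp = self.ref.hairpins[e.hairpin_id]
                if hp[e.end] != "A":
                    klass = "NTA-A"
                else:
                    rec.update(klass="canonical", mirna_id=e.mirna_id, insert=e.mature_seq)
                    return rec
            rec["klass"] = klass
            tail = _NTA_BASE[klass] * int(_draw(rng, cfg.tail_len_probs))
            rec.update(mirna_id=e.mirna_id, tail=tail)
            seq = e.mature_seq + tail
        else:
            e = self._pick(self.entries)
            hp = self.ref.hairpins[e.hairpin_id]
            if klass == "canonical":
                seq = e.mature_seq
            elif klass == "NucVar":
                seq = self._nucvar(e, rec)
            elif klass == "lv3pT":
                k = int(_draw(rng, {1: 0.7, 2: 0.3}))
                seq = e.mature_seq[:-k]
                rec["shift3"] = -k
            elif klass == "lv3pE":
                k = int(_draw(rng, {1: 0.8, 2: 0.2}))
                seq = e.mature_seq + hp[e.end : e.end + k]
                rec["shift3"] = k
            elif klass == "lv5pT":
                k = int(_draw(rng, {1: 0.7, 2: 0.3}))
                seq = e.mature_seq[k:]
                rec["shift5"] = -k
            elif klass == "lv5pE":
                k = int(_draw(rng, {1: 0.8, 2: 0.2}))
                seq = hp[e.start - k : e.start] + e.mature_seq
                rec["shift5"] = k
            elif klass == "mv":
                seq = e.mature_seq[1:-1]
                rec["shift5"], rec["shift3"] = -1, -1
            else:
                raise ValueError(f"unknown class label {klass!r} in class_probs")
            rec["mirna_id"] = e.mirna_id
        rec["insert"] = seq
        return rec

    def _nucvar(self, e: MatureEntry, rec: dict) -> str:
        rng = self.rng
        L = len(e.mature_seq)
        for _ in range(100):
            sub = _draw(rng, self.cfg.subst_spectrum)
            frm, to = sub.split(">")
            positions = [i for i in range(1, L - 1) if e.mature_seq[i] == frm]
            if positions:
                pos = int(rng.choice(positions))
                rec["subst"] = f"{pos}:{frm}>{to}"
                return e.mature_seq[:pos] + to + e.mature_seq[pos + 1 :]
        raise RuntimeError("no feasible substitution position")  # pragma: no cover


def _pool_molecule(ref: ReferenceSet, cfg: SimConfig, rng: np.random.Generator) -> dict:
    e = ref.entries[rng.integers(len(ref.entries))]
    seq = e.mature_seq
    shift5 = shift3 = 0
    if rng.random() < cfg.pool_trim5_rate:
        k = int(rng.integers(1, 3))
        seq, shift5 = seq[k:], -k
    if rng.random() < cfg.pool_trim3_rate:
        seq, shift3 = seq[:-1], -1
    # uniform oligosynthesis substitutions, no indels
    chars = list(seq)
    subs = []
    for i in range(len(chars)):
        if rng.random() < cfg.synthesis_error_rate:
            frm = chars[i]
            to = _BASES[(_BASES.index(frm) + 1 + rng.integers(3)) % 4]
            chars[i] = to
            subs.append(f"{i}:{frm}>{to}")
    seq = "".join(chars)
    if not subs and shift5 == 0 and shift3 == 0:
        klass = "canonical"
    elif len(subs) == 1 and shift5 == 0 and shift3 == 0:
        pos = int(subs[0].split(":")[0])
        klass = "NucVar" if 0 < pos < len(seq) - 1 else "terminal_subst"
    elif not subs:
        klass = ("mv" if shift5 and shift3 else ("lv5pT" if shift5 else "lv3pT"))
    else:
        klass = "multi_subst" if len(subs) > 1 else "trim_subst"
    return {
        "mirna_id": e.mirna_id,
        "klass": klass,
        "shift5": shift5,
        "shift3": shift3,
        "tail": "",
        "subst": ";".join(subs),
        "insert": seq,
    }


def simulate_sample(
    ref: ReferenceSet,
    cfg: SimConfig,
    mode: str = "cells",
    seed: Optional[int] = None,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Generate one sample: FASTQ-ready reads plus exact ground truth.

    Molecule generation, ligation bias (weighted resampling by a
    per-sequence log-normal capture multiplier), geometric PCR duplication
    and UMI attachment are all driven by one seeded generator. Returns
    ``(reads, truth)`` where reads are (read_id, full read sequence)
    including UMIs and the 3' adapter.
    """
    if mode not in ("pool", "cells"):
        raise ValueError("mode must be 'pool' or 'cells'")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if mode == "cells":
        sampler = _CellsSampler(ref, cfg, rng)
        molecules = [sampler.molecule() for _ in range(cfg.depth)]
    else:
        molecules = [_pool_molecule(ref, cfg, rng) for _ in range(cfg.depth)]

    # ligation bias: per-sequence capture efficiency, log-normal. The
    # efficiency is a deterministic function of the insert sequence — bias
    # is systematic, so the same sequence is captured equally well in every
    # sample and protocol run with the same bias sd.
    if cfg.ligation_bias_sd > 0:
        eff: dict[str, float] = {}
        for m in molecules:
            seq = m["insert"]
            if seq not in eff:
                seq_rng = np.random.default_rng(zlib.crc32(seq.encode()))
                eff[seq] = float(seq_rng.lognormal(0.0, cfg.ligation_bias_sd))
        w = np.array([eff[m["insert"]] for m in molecules])
        idx = rng.choice(len(molecules), size=cfg.depth, replace=True, p=w / w.sum())
        molecules = [dict(molecules[j]) for j in idx]

    # PCR duplication + UMIs
    reads: list[tuple[str, str]] = []
    records = []
    for i, m in enumerate(molecules):
        dups = int(rng.geometric(1.0 / cfg.pcr_dup_mean)) if cfg.pcr_dup_mean > 1 else 1
        umi5 = _random_seq(rng, cfg.umi5_len)
        umi3 = _random_seq(rng, cfg.umi3_len)
        full = umi5 + m["insert"] + umi3 + cfg.adapter3
        for d in range(dups):
            reads.append((f"mol{i}.{d}", full))
        records.append({"mol_id": f"mol{i}", **m, "n_reads": dups})
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    truth = SimTruth(molecules=pd.DataFrame(records))
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def pool_config(**overrides) -> SimConfig:
    """Pool-mode preset (fixed-adapter-like bias is NOT implied; override
    ``ligation_bias_sd`` to emulate specific protocols)."""
    return replace(SimConfig(), **overrides)


def cells_config(**overrides) -> SimConfig:
    return replace(SimConfig(), **overrides)
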