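"""Canonical-seed and tail-U (TUMR) target-site search over 3'-UTRs.

Canonical sites are the standard seed-match types: a 7mer-m8 site pairs
miRNA positions 2-8 by Watson-Crick rules, a 7mer-A1 site pairs positions
2-7 with an A opposite miRNA position 1, and an 8mer satisfies both.

Tail-U-mediated repression (TUMR) sites are recognised by the 3' end of
the mono-uridylated miRNA (mature + U): the 3'-terminal window of the
uridylated sequence is paired antiparallel against each UTR window,
allowing a bounded number of G:U wobble pairs. A multi-species
conservation filter keeps only targets whose site is present in enough of
the orthologous UTRs. Sequences are handled in DNA space (U as T).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .refdata import normalize_seq

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class TargetSite:
    utr_id: str
    species_id: str
    start: int
    end: int
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | TUMR
    wobbles: int = 0
    conserved_in: int = 0


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _pairs(query_base: str, site_base: str) -> tuple[bool, bool]:
    """(pairs, is_wobble) for an antiparallel query/site base pair."""
    if _COMP[query_base] == site_base:
        return True, False
    if (query_base == "G" and site_base == "T") or (query_base == "T" and site_base == "G"):
        return True, True
    return False, False


def seed_sites(
    mirna_seq: str,
    utr_seq: str,
    utr_id: str = "",
    species_id: str = "",
) -> list[TargetSite]:
    """Canonical seed-match sites of a miRNA in one UTR.

    The seed is miRNA positions 2-8 (1-based). Matches ending at the UTR
    boundary are reported; an 8mer is reported once (not additionally as
    its component 7mers).
    """
    mirna = normalize_seq(mirna_seq)
    utr = normalize_seq(utr_seq)
    if len(mirna) < 8:
        raise ValueError("miRNA must be >= 8 nt")
    s7 = revcomp(mirna[1:8])  # pairs seed 2-8, 5'->3' on the UTR
    sites: list[TargetSite] = []
    # m8-containing sites
    for i in range(len(utr) - 6):
        if utr[i : i + 7] != s7:
            continue
        if i + 7 < len(utr) and utr[i + 7] == "A":
            sites.append(TargetSite(utr_id, species_id, i, i + 8, "8mer"))
        else:
            sites.append(TargetSite(utr_id, species_id, i, i + 7, "7mer-m8"))
    # 7mer-A1: seed 2-7 match plus A at position 1, not extendable to m8
    s6 = s7[1:]
    for i in range(len(utr) - 6):
        if utr[i : i + 6] == s6 and utr[i + 6] == "A":
            if i > 0 and utr[i - 1] == s7[0]:
                continue  # part of an m8-containing site
            sites.append(TargetSite(utr_id, species_id, i, i + 7, "7mer-A1"))
    return sorted(sites, key=lambda s: (s.start, s.site_type))


def tumr_sites(
    mature_seq: str,
    utr_seq: str,
    max_wobbles: int = 3,
    window_len: int = 8,
    utr_id: str = "",
    species_id: str = "",
) -> list[TargetSite]:
    """Tail-U target sites of the mono-uridylated miRNA in one UTR.

    The query is the 3'-terminal ``window_len`` bases of mature + U. A UTR
    window of the same length is a site when every antiparallel base pair
    is Watson-Crick or G:U (query G with site T / query T with site G),
    with at most ``max_wobbles`` wobbles. ``max_wobbles=0`` reduces to an
    exact reverse-complement search.
    """
    mature = normalize_seq(mature_seq)
    utr = normalize_seq(utr_seq)
    uridylated = mature + "T"
    if window_len > len(uridylated):
        raise ValueError("window_len exceeds the uridylated miRNA length")
    query = uridylated[-window_len:]
    sites: list[TargetSite] = []
    for i in range(len(utr) - window_len + 1):
        window = utr[i : i + window_len]
        wob = 0
        ok = True
        for k in range(window_len):
            paired, is_wob = _pairs(query[k], window[window_len - 1 - k])
            if not paired:
                ok = False
                break
            wob += is_wob
        if ok and wob <= max_wobbles:
            sites.append(TargetSite(utr_id, species_id, i, i + window_len, "TUMR", wobbles=wob))
    return sites


def conservation_filter(
    sites_by_species: Mapping[str, Iterable[TargetSite]],
    min_species: int = 15,
    n_species: int = 23,
) -> pd.DataFrame:
    """Keep target genes whose site is conserved in enough species.

    ``sites_by_species`` maps species id -> sites found in that species'
    orthologous UTRs (site ``utr_id`` is the gene id). A gene is kept iff
    it has a qualifying site in at least ``min_species`` of the
    ``n_species`` declared species; its ``conserved_in`` count is reported.
    """
    if min_species > n_species:
        raise ValueError("min_species cannot exceed n_species")
    if len(sites_by_species) != n_species:
        raise ValueError(
            f"declared {n_species} species but got {len(sites_by_species)}"
        )
    genes_per_species: dict[str, set[str]] = {}
    for sp, sites in sites_by_species.items():
        genes_per_species[sp] = {s.utr_id for s in sites}
    counts: dict[str, int] = {}
    for genes in genes_per_species.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    kept = sorted((g, n) for g, n in counts.items() if n >= min_species)
    return pd.DataFrame(kept, columns=["gene", "conserved_in"]).set_index("gene")


def targetome_compare(canonical_targets: Iterable[str], tumr_targets: Iterable[str]) -> dict:
    """Partition canonical vs TUMR target gene sets into unique/overlap."""
    canon = set(canonical_targets)
    tumr = set(tumr_targets)
    overlap = canon & tumr
    return {
        "unique_canonical": sorted(canon - tumr),
        "unique_tumr": sorted(tumr - canon),
        "overlap": sorted(overlap),
        "n_unique_canonical": len(canon - tumr),
        "n_unique_tumr": len(tumr - canon),
        "n_overlap": len(overlap),
    }


def load_utr_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a multi-species 3'-UTR FASTA with ``gene|species`` headers.

    Returns species -> {gene -> sequence} (DNA space).
    """
    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"UTR header {rec.id!r} is not gene|species")
        gene, species = rec.id.split("|", 1)
        out.setdefault(species, {})[gene] = normalize_seq(rec.seq)
    if not out:
        raise ValueError(f"empty UTR FASTA {path}")
    return out


def find_targets(
    mirna_seq: str,
    utrs: Mapping[str, Mapping[str, str]],
    min_species: int = 15,
    max_wobbles: int = 3,
    window_len: int = 8,
) -> dict:
    """End-to-end canonical vs TUMR targetome comparison.

    Scans every species' UTRs for canonical seed sites and TUMR sites,
    applies the conservation filter to each targetome, and returns the
    kept gene tables plus the overlap partition.
    """
    n_species = len(utrs)
    canon_by_sp: dict[str, list[TargetSite]] = {}
    tumr_by_sp: dict[str, list[TargetSite]] = {}
    for sp, genes in utrs.items():
        canon_by_sp[sp] = []
        tumr_by_sp[sp] = []
        for gene, seq in genes.items():
            canon_by_sp[sp].extend(seed_sites(mirna_seq, seq, utr_id=gene, species_id=sp))
            tumr_by_sp[sp].extend(
                tumr_sites(mirna_seq, seq, max_wobbles=max_wobbles,
                           window_len=window_len, utr_id=gene, species_id=sp)
            )
    canon_kept = conservation_filter(canon_by_sp, min_species, n_species)
    tumr_kept = conservation_filter(tumr_by_sp, min_species, n_species)
    summary = targetome_compare(canon_kept.index, tumr_kept.index)
    return {
        "canonical": canon_kept,
        "tumr": tumr_kept,
        "summary": summary,
        "sites_canonical": canon_by_sp,
        "sites_tumr": tumr_by_sp,
    }
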