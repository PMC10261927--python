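"""Differential uridylation and the cross-study randomization test.

Compares per-miRNA uridylation percentages between wild-type cells and
cells lacking the terminal uridylyl transferases TUT4/7 (double knockout,
DKO): a per-miRNA Welch t-test with BH FDR control and a fold-change
filter flags differentially uridylated miRNAs.  When several independent
studies are available, the miRNAs flagged in all of them are intersected
and the overlap is judged against a seeded randomization null (draw each
study's set size uniformly from the universe, intersect, repeat) that
yields an expectation, a standard deviation, and hence a Z score and an
observed/expected ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import bh_adjust, welch_t

#: floor (percentage points) applied to the DKO mean when forming the
#: WT/DKO fold change, to keep near-zero denominators from blowing up.
FC_DENOM_FLOOR = 0.1


@dataclass(frozen=True)
class DiffUridResult:
    mirna_id: str
    mean_pct_wt: float
    mean_pct_dko: float
    fc: float
    p: float
    q: float
    significant: bool
    fc_floored: bool = False


@dataclass(frozen=True)
class IntersectionResult:
    observed: int
    expected: float
    sd: float
    z: Optional[float]
    oe_ratio: Optional[float]
    n_iter: int
    seed: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "sd": self.sd,
            "z": self.z,
            "oe_ratio": self.oe_ratio,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def diff_uridylation(
    wt: Sequence[pd.DataFrame],
    dko: Sequence[pd.DataFrame],
    fc_min: float = 1.5,
    alpha: float = 0.05,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Differential-uridylation test on per-sample uridylation tables.

    ``wt``/``dko`` are per-sample tables from
    :func:`isomirkit.profiles.uridylation_table` (indexed by mirna_id with
    ``pct_NTA_U`` and ``total_count`` columns). A miRNA is tested only if
    it reaches ``min_reads`` in every sample of both groups; it is called
    significant when q < ``alpha`` and the WT/DKO fold change of the mean
    uridylation percentage is >= ``fc_min``.
    """
    if len(wt) < 2 or len(dko) < 2:
        raise ValueError("need >= 2 samples per group (wt and dko)")

    def eligible(tables: Sequence[pd.DataFrame]) -> set:
        sets = [
            set(t.index[t["total_count"] >= min_reads]) for t in tables
        ]
        return set.intersection(*sets) if sets else set()

    shared = eligible(wt) & eligible(dko)
    if not shared:
        raise ValueError("no shared miRNAs between groups at the coverage threshold")

    rows = []
    for mid in sorted(shared):
        a = [float(t.loc[mid, "pct_NTA_U"]) for t in wt]
        b = [float(t.loc[mid, "pct_NTA_U"]) for t in dko]
        t_stat, p = welch_t(a, b)
        mean_wt, mean_dko = float(np.mean(a)), float(np.mean(b))
        floored = mean_dko < FC_DENOM_FLOOR
        fc = mean_wt / max(mean_dko, FC_DENOM_FLOOR)
        rows.append(
            {
                "mirna_id": mid,
                "mean_pct_wt": mean_wt,
                "mean_pct_dko": mean_dko,
                "fc": fc,
                "fc_floored": floored,
                "t": t_stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("mirna_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] < alpha) & (out["fc"] >= fc_min)
    return out


def significant_set(results: pd.DataFrame) -> set[str]:
    """The mirna_ids flagged significant in a diff_uridylation table."""
    return set(results.index[results["significant"]])


def intersect_studies(sets: Mapping[str, set]) -> tuple[int, pd.DataFrame]:
    """Intersection of per-study significant sets plus an upset-style table.

    Returns the observed common-to-all count and a membership DataFrame
    (rows = miRNAs in the union, one boolean column per study).
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 studies")
    for study, s in sets.items():
        if not isinstance(s, (set, frozenset)):
            raise TypeError(f"study {study}: expected a set")
    universe = sorted(set.union(*[set(s) for s in sets.values()])) if sets else []
    membership = pd.DataFrame(
        {study: [m in s for m in universe] for study, s in sets.items()},
        index=universe,
    )
    observed = int(membership.all(axis=1).sum()) if universe else 0
    return observed, membership


def expected_overlap(set_sizes: Sequence[int], universe_size: int) -> float:
    """Closed-form expected intersection size under independent uniform draws.

    Each universe element lands in study i's random set with probability
    s_i / N, independently across studies, so by linearity
    E = N * prod(s_i / N).
    """
    if universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    e = float(universe_size)
    for s in set_sizes:
        if not 0 <= s <= universe_size:
            raise ValueError("set sizes must lie in [0, N]")
        e *= s / universe_size
    return e


def randomization_z(
    sets: Mapping[str, set],
    universe: Sequence[str],
    n_iter: int = 1000,
    seed: int = 0,
) -> IntersectionResult:
    """Randomization null for the cross-study intersection.

    For each iteration, |s_i| ids are drawn uniformly without replacement
    from the universe per study and the sets are intersected; the observed
    intersection is scored as z = (observed - mean) / sd against the
    empirical distribution. sd uses the n-1 denominator. A zero sd flags
    the result degenerate (z and O/E unset as appropriate).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    universe = list(universe)
    uni_set = set(universe)
    for study, s in sets.items():
        if not set(s) <= uni_set:
            raise ValueError(f"study {study}: set not contained in universe")
    observed, _ = intersect_studies(sets)
    sizes = [len(s) for s in sets.values()]
    rng = np.random.default_rng(seed)
    n = len(universe)
    draws = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        common: Optional[set] = None
        for size in sizes:
            picked = set(rng.choice(n, size=size, replace=False))
            common = picked if common is None else (common & picked)
            if not common:
                break
        draws[it] = len(common) if common else 0
    expected = float(draws.mean())
    sd = float(draws.std(ddof=1)) if n_iter > 1 else 0.0
    degenerate = sd == 0.0
    z = None if degenerate else (observed - expected) / sd
    oe = observed / expected if expected > 0 else None
    return IntersectionResult(
        observed=observed,
        expected=expected,
        sd=sd,
        z=z,
        oe_ratio=oe,
        n_iter=n_iter,
        seed=seed,
        degenerate=degenerate,
    )
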