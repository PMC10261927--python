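"""Summary statistics over classified samples.

Class composition tables, the internal-substitution (NucVar) spectrum,
per-miRNA and per-arm uridylation, Welch t-test group comparisons with
Benjamini-Hochberg FDR control, and the coefficient-of-variation metric
used to judge equality of capture across equimolar spike-ins.

All percentages use miRNA-mapped reads as the denominator; unassigned
reads are excluded.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CLASS_ORDER, SUBSTITUTION_CLASSES, SampleProfile
from .refdata import ReferenceSet


# ---------------------------------------------------------------------------
# statistical plumbing


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j for sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-dimensional")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate zero-variance cases are resolved explicitly: equal means
    give (0, 1), unequal means with zero pooled variance give (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def cov_equality(counts: Sequence[float]) -> float:
    """Coefficient of variation (sample sd, n-1 denominator, over mean).

    Used as an equality-of-capture metric across equimolar spike-ins:
    perfectly even capture gives 0.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 counts")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return float(x.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# composition and spectra


def composition_table(
    profiles: Iterable[SampleProfile],
    groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-sample class percentages, with per-group mean and sd rows.

    Samples with zero mapped reads are excluded (with a warning column in
    mind, they simply do not appear). Rows are samples, then
    ``<group>/mean`` and ``<group>/sd`` when ``groups`` maps sample ids to
    group labels.
    """
    rows = {}
    for prof in profiles:
        if prof.mapped_total <= 0:
            import warnings

            warnings.warn(f"sample {prof.sample_id} has zero mapped reads; excluded")
            continue
        rows[prof.sample_id] = prof.class_percentages()
    classes = [k for k in CLASS_ORDER if k != "unassigned"]
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=classes).fillna(0.0)
    if groups:
        pieces = [table]
        for g in sorted(set(groups.values())):
            members = [s for s in table.index if groups.get(s) == g]
            if not members:
                continue
            sub = table.loc[members]
            pieces.append(
                pd.DataFrame(
                    {c: [sub[c].mean(), sub[c].std(ddof=1)] for c in classes},
                    index=[f"{g}/mean", f"{g}/sd"],
                )
            )
        table = pd.concat(pieces)
    return table


def nucvar_spectrum(profile: SampleProfile) -> dict[str, float]:
    """Percentage of miRNA-mapped reads per substitution class (12 classes).

    The class is reference base > read base, taken from the NucVar call's
    substitution record.
    """
    pct = {k: 0.0 for k in SUBSTITUTION_CLASSES}
    if profile.mapped_total <= 0:
        return pct
    for (_, variant), count in profile.counts.items():
        klass, _, _, _, subst = variant
        if klass == "NucVar" and subst is not None:
            pct[f"{subst[1]}>{subst[2]}"] += 100.0 * count / profile.mapped_total
    return pct


def uridylation_table(profile: SampleProfile, min_reads: int = 10) -> pd.DataFrame:
    """Per-miRNA NTA percentages.

    ``pct_NTA_X`` is the percentage of the miRNA's own reads carrying an
    NTA-X tail; miRNAs with fewer than ``min_reads`` total reads are
    flagged ``low_coverage``.
    """
    totals = profile.mirna_totals()
    nta = {mid: {"NTA-U": 0.0, "NTA-A": 0.0, "NTA-C": 0.0, "NTA-G": 0.0} for mid in totals}
    for (mid, variant), count in profile.counts.items():
        klass = variant[0]
        if klass in nta[mid]:
            nta[mid][klass] += count
    rows = []
    for mid in sorted(totals):
        tot = totals[mid]
        rows.append(
            {
                "mirna_id": mid,
                "pct_NTA_U": 100.0 * nta[mid]["NTA-U"] / tot,
                "pct_NTA_A": 100.0 * nta[mid]["NTA-A"] / tot,
                "pct_NTA_C": 100.0 * nta[mid]["NTA-C"] / tot,
                "pct_NTA_G": 100.0 * nta[mid]["NTA-G"] / tot,
                "total_count": tot,
                "low_coverage": tot < min_reads,
            }
        )
    return pd.DataFrame(rows).set_index("mirna_id") if rows else pd.DataFrame(
        columns=["pct_NTA_U", "pct_NTA_A", "pct_NTA_C", "pct_NTA_G",
                 "total_count", "low_coverage"]
    )


def arm_uridylation(
    profiles: Iterable[SampleProfile],
    ref: ReferenceSet,
    groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read-weighted NTA-U percentage per hairpin arm (5p vs 3p).

    For each sample, NTA-U reads of all miRNAs of an arm are summed and
    divided by the arm's total reads; rows are (group, arm) means over the
    group's samples (group "all" when no mapping is given).
    """
    arm_of = {e.mirna_id: e.arm for e in ref.entries}
    per_sample: list[tuple[str, dict[str, float]]] = []
    for prof in profiles:
        tot = {"5p": 0.0, "3p": 0.0}
        uri = {"5p": 0.0, "3p": 0.0}
        for (mid, variant), count in prof.counts.items():
            arm = arm_of.get(mid)
            if arm is None:
                continue
            tot[arm] += count
            if variant[0] == "NTA-U":
                uri[arm] += count
        pcts = {a: (100.0 * uri[a] / tot[a] if tot[a] > 0 else 0.0) for a in ("5p", "3p")}
        g = groups.get(prof.sample_id, "all") if groups else "all"
        per_sample.append((g, pcts))
    rows = []
    for g in sorted({g for g, _ in per_sample}):
        for arm in ("5p", "3p"):
            vals = [p[arm] for gg, p in per_sample if gg == g]
            rows.append({"group": g, "arm": arm, "mean_pct_NTA_U": float(np.mean(vals))})
    return pd.DataFrame(rows)


def compare_group_fractions(
    group_a: Mapping[str, Sequence[float]] | pd.DataFrame,
    group_b: Mapping[str, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per class between two groups of per-sample percentages.

    Inputs map class name -> per-sample percentage vectors (or DataFrames
    with samples as rows and classes as columns). BH correction is applied
    across the shared classes; rows with q < alpha are flagged.
    """
    if isinstance(group_a, pd.DataFrame):
        group_a = {c: group_a[c].to_numpy() for c in group_a.columns}
    if isinstance(group_b, pd.DataFrame):
        group_b = {c: group_b[c].to_numpy() for c in group_b.columns}
    classes = [c for c in group_a if c in group_b]
    for label, grp in (("A", group_a), ("B", group_b)):
        for c in classes:
            if len(grp[c]) < 2:
                raise ValueError(f"group {label} has fewer than 2 samples for class {c}")
    recs = []
    for c in classes:
        t, p = welch_t(group_a[c], group_b[c])
        recs.append({"klass": c, "t": t, "p": p})
    out = pd.DataFrame(recs).set_index("klass")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def plot_composition(table: pd.DataFrame, path: str) -> None:
    """Bar-plot a composition table (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = table.plot.bar(stacked=True, figsize=(10, 5))
    ax.set_ylabel("% of miRNA-mapped reads")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
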