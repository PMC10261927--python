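"""End-to-end orchestration: preprocess -> classify -> profile -> diffurid/tumr.

Driven by a YAML config plus a sample-sheet TSV (columns: sample, fastq,
group, study, protocol). Differential uridylation runs per study whenever
both WT and DKO groups have >= 2 samples; the cross-study intersection and
randomization Z score run when >= 2 studies yield results; the TUMR target
search runs when a UTR FASTA is configured. All outputs are plain TSV/JSON
and a manifest records versions, seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifyParams, SampleProfile, classify_sample, calls_table
from .diffurid import diff_uridylation, intersect_studies, randomization_z, significant_set
from .preprocess import ProtocolSpec, collapse_reads, extract_and_trim, write_collapsed_tsv
from .profiles import arm_uridylation, composition_table, nucvar_spectrum, uridylation_table
from .refdata import load_reference
from .tumr import find_targets, load_utr_fasta

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and sample."""


@dataclass
class RunConfig:
    mature_fasta: str
    hairpin_fasta: str
    sample_sheet: str
    outdir: str
    coords_tsv: str | None = None
    protocols: dict = field(default_factory=dict)  # name -> ProtocolSpec kwargs + dedup
    classify: dict = field(default_factory=dict)  # ClassifyParams kwargs
    diffurid: dict = field(
        default_factory=lambda: {"fc_min": 1.5, "alpha": 0.05, "min_reads": 10,
                                 "n_iter": 1000, "seed": 0}
    )
    tumr: dict | None = None  # utr_fasta, mirna_seq, min_species, max_wobbles, window_len
    write_calls: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ref = raw.pop("reference")
        cfg = cls(
            mature_fasta=ref["mature"],
            hairpin_fasta=ref["hairpin"],
            coords_tsv=ref.get("coords"),
            sample_sheet=raw.pop("sample_sheet"),
            outdir=raw.pop("outdir"),
            **raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, p in (
            ("mature FASTA", self.mature_fasta),
            ("hairpin FASTA", self.hairpin_fasta),
            ("sample sheet", self.sample_sheet),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} not found: {p}")
        if self.tumr and not Path(self.tumr["utr_fasta"]).exists():
            raise FileNotFoundError(f"UTR FASTA not found: {self.tumr['utr_fasta']}")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "fastq", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if "study" not in sheet.columns:
        sheet["study"] = "study1"
    if "protocol" not in sheet.columns:
        sheet["protocol"] = "default"
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sheet


def _protocol(cfg: RunConfig, name: str) -> tuple[ProtocolSpec, bool]:
    kwargs = dict(cfg.protocols.get(name, cfg.protocols.get("default", {})))
    dedup = bool(kwargs.pop("dedup", True))
    return ProtocolSpec(**kwargs), dedup


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of result objects.

    Writes per-sample collapsed reads and uridylation tables, the
    composition and NucVar-spectrum tables, per-study differential
    uridylation, the cross-study intersection JSON, the TUMR targetome
    summary, and a run manifest under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = load_reference(config.mature_fasta, config.hairpin_fasta, config.coords_tsv)
    sheet = read_sample_sheet(config.sample_sheet)
    params = ClassifyParams(**config.classify)

    profiles: list[SampleProfile] = []
    accounting = {}
    groups = dict(zip(sheet["sample"], sheet["group"]))
    for _, row in sheet.iterrows():
        sid = row["sample"]
        try:
            spec, dedup = _protocol(config, row["protocol"])
            pairs, stats = extract_and_trim(row["fastq"], spec)
            collapsed = collapse_reads(pairs, dedup=dedup)
            write_collapsed_tsv(collapsed, outdir / f"{sid}.collapsed.tsv")
            prof = classify_sample(collapsed, ref, params, sample_id=sid)
            if config.write_calls:
                calls_table(collapsed, ref, params).to_csv(
                    outdir / f"{sid}.calls.tsv", sep="\t", index=False
                )
            uridylation_table(prof, min_reads=config.diffurid["min_reads"]).to_csv(
                outdir / f"{sid}.uridylation.tsv", sep="\t"
            )
            profiles.append(prof)
            accounting[sid] = {**dict(stats), "mapped": prof.mapped_total,
                               "unassigned": prof.unassigned_total}
        except Exception as exc:
            raise PipelineError(f"stage preprocess/classify failed for sample {sid}: {exc}") from exc

    results: dict = {"profiles": profiles}
    comp = composition_table(profiles, groups=groups)
    comp.to_csv(outdir / "composition.tsv", sep="\t")
    results["composition"] = comp

    spectrum = pd.DataFrame({p.sample_id: nucvar_spectrum(p) for p in profiles}).T
    spectrum.to_csv(outdir / "nucvar_spectrum.tsv", sep="\t")
    results["nucvar_spectrum"] = spectrum

    arm = arm_uridylation(profiles, ref, groups=groups)
    arm.to_csv(outdir / "arm_uridylation.tsv", sep="\t", index=False)
    results["arm_uridylation"] = arm

    # differential uridylation per study, then cross-study intersection
    dcfg = config.diffurid
    study_sets: dict[str, set] = {}
    prof_by_id = {p.sample_id: p for p in profiles}
    for study, sub in sheet.groupby("study"):
        wt_ids = sub.loc[sub["group"].str.upper() == "WT", "sample"]
        dko_ids = sub.loc[sub["group"].str.upper() == "DKO", "sample"]
        if len(wt_ids) < 2 or len(dko_ids) < 2:
            logger.info("study %s: fewer than 2 samples per group, diffurid skipped", study)
            continue
        try:
            tables_wt = [uridylation_table(prof_by_id[s], dcfg["min_reads"]) for s in wt_ids]
            tables_dko = [uridylation_table(prof_by_id[s], dcfg["min_reads"]) for s in dko_ids]
            res = diff_uridylation(
                tables_wt, tables_dko, fc_min=dcfg["fc_min"],
                alpha=dcfg["alpha"], min_reads=dcfg["min_reads"],
            )
        except Exception as exc:
            raise PipelineError(f"stage diffurid failed for study {study}: {exc}") from exc
        res.to_csv(outdir / f"diffurid.{study}.tsv", sep="\t")
        study_sets[study] = significant_set(res)
        results.setdefault("diffurid", {})[study] = res

    if len(study_sets) >= 2:
        universe = sorted(set.union(*study_sets.values()))
        if universe:
            observed, membership = intersect_studies(study_sets)
            inter = randomization_z(
                study_sets, universe, n_iter=dcfg["n_iter"], seed=dcfg["seed"]
            )
            membership.to_csv(outdir / "intersection_membership.tsv", sep="\t")
            with open(outdir / "intersection.json", "w") as fh:
                json.dump(inter.to_dict(), fh, indent=2)
            results["intersection"] = inter

    if config.tumr:
        tcfg = dict(config.tumr)
        try:
            utrs = load_utr_fasta(tcfg.pop("utr_fasta"))
            targets = find_targets(tcfg.pop("mirna_seq"), utrs, **tcfg)
        except Exception as exc:
            raise PipelineError(f"stage tumr failed: {exc}") from exc
        with open(outdir / "targetome.json", "w") as fh:
            json.dump(targets["summary"], fh, indent=2)
        targets["canonical"].to_csv(outdir / "targets_canonical.tsv", sep="\t")
        targets["tumr"].to_csv(outdir / "targets_tumr.tsv", sep="\t")
        results["tumr"] = targets

    manifest = {
        "isomirkit_version": __version__,
        "reference": {
            "mature": str(config.mature_fasta),
            "hairpin": str(config.hairpin_fasta),
            "n_mirnas": len(ref),
            "dropped": ref.dropped,
        },
        "classify_params": dataclasses.asdict(params),
        "diffurid_params": dcfg,
        "samples": accounting,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    results["manifest"] = manifest
    return results
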