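"""End-to-end orchestration: ingest -> differences -> regions -> overlay -> rank.

One :func:`run_pipeline` call takes an apo uptake table, one or more
ligand-state tables and (optionally) a ligand-bound structure, and produces
per-ligand classified region reports, a cross-ligand comparison matrix, a
ligand ranking and a residue-coloring attribute file. Identical inputs and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import LigandReport, classify_regions, compare_ligands, rank_ligands
from .contacts import ContactSet, contact_residues, load_structure, \
    write_attribute_file, write_contact_tsv
from .uptake import compute_rdu, difference_profile, merge_regions, \
    read_uptake_csv, regions_to_frame, reporter_regions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (thresholds follow the study design)."""

    apo_path: str
    ligand_paths: dict[str, str]          # ligand name -> uptake CSV
    structure_path: str | None = None
    ligand_selector: str = "LIG"
    out_dir: str = "hdx_allomap_out"
    threshold_da: float = 0.5             # significance threshold on |delta|
    reporter_factor: float = 0.5          # fraction of max RDU for reporters
    contact_cutoff_A: float = 4.0
    max_gap: int = 0
    min_timepoints: int = 1
    short_times_min: tuple[float, ...] = (10.0,)
    residue_offset: int = 0
    n_fast_termini: int = 1
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("threshold_da", "reporter_factor", "contact_cutoff_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "short_times_min" in data:
            data["short_times_min"] = tuple(data["short_times_min"])
        return cls(**data)

    def digest(self) -> str:
        payload = {k: (sorted(v.items()) if isinstance(v, dict) else v)
                   for k, v in vars(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    reports: dict[str, LigandReport]
    ranking: list[dict]
    comparison: pd.DataFrame | None
    reporter_threshold: float
    max_rdu: float
    contacts: ContactSet | None


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    apo = _stage("ingest", read_uptake_csv, config.apo_path)
    log.info("ingest: apo table %d rows", len(apo))
    rdu = _stage("rdu", compute_rdu, apo, n_fast_termini=config.n_fast_termini)
    reporters = _stage("reporters", reporter_regions, rdu,
                       config.short_times_min, config.reporter_factor)
    log.info("reporters: threshold %.4f (max RDU %.4f), %d reporter peptides",
             reporters.threshold, reporters.max_rdu, len(reporters.peptide_ids))

    contacts = None
    if config.structure_path is not None:
        model = _stage("structure", load_structure, config.structure_path,
                       config.ligand_selector, config.residue_offset)
        contacts = _stage("contacts", contact_residues, model,
                          config.contact_cutoff_A)
        log.info("contacts: %d residues within %.1f A",
                 len(contacts.residues), config.contact_cutoff_A)
        write_contact_tsv(model, contacts, out / "contacts.tsv")
    else:
        log.warning("no structure provided: regions will be left unclassified")

    reports: dict[str, LigandReport] = {}
    all_region_frames = []
    for ligand in sorted(config.ligand_paths):
        bound = _stage("ingest", read_uptake_csv, config.ligand_paths[ligand])
        profile = _stage("difference", difference_profile, apo, bound,
                         config.threshold_da, config.min_timepoints)
        regions = _stage("merge", merge_regions, profile.significant_peptides,
                         config.max_gap)
        log.info("%s: %d significant peptides -> %d regions", ligand,
                 len(profile.significant_peptides), len(regions))
        if contacts is not None:
            classified = _stage("classify", classify_regions, regions, contacts)
        else:
            from .classify import ClassifiedRegion
            classified = []
            for n, region in enumerate(sorted(regions, key=lambda r: r.start), 1):
                region.label, region.name = None, f"R{n}"
                classified.append(ClassifiedRegion(region, "unclassified", ()))
        report = LigandReport(ligand, classified)
        report.to_json(out / f"{ligand}_report.json")
        frame = regions_to_frame(regions)
        frame.insert(0, "ligand", ligand)
        all_region_frames.append(frame)
        reports[ligand] = report

    frame = pd.concat(all_region_frames, ignore_index=True) \
        if all_region_frames else pd.DataFrame()
    frame.to_csv(out / "regions.tsv", sep="\t", index=False)

    comparison = None
    if len(reports) >= 2:
        comparison = _stage("compare", compare_ligands, list(reports.values()))
        comparison.to_csv(out / "ligand_matrix.tsv", sep="\t", index=False)
    ranking = _stage("rank", rank_ligands, list(reports.values()))
    with open(out / "ranking.json", "w") as fh:
        json.dump(ranking, fh, indent=2)
        fh.write("\n")

    labels: dict[int, str] = {}
    for rep in reports.values():
        for c in rep.regions:
            for r in range(c.start, c.end + 1):
                prev = labels.get(r)
                lab = c.label or "response"
                labels[r] = lab if prev in (None, lab) else "both"
    write_attribute_file(labels, out / "region_attributes.txt")

    provenance = {
        "package": "hdx-allomap",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "reporter_threshold": round(reporters.threshold, 6),
        "max_rdu": round(reporters.max_rdu, 6),
        "n_reporter_peptides": len(reporters.peptide_ids),
        "ligands": sorted(reports),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(reports, ranking, comparison,
                          reporters.threshold, reporters.max_rdu, contacts)
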