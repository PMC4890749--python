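"""Orthosteric/allosteric labeling of response regions and ligand ranking.

A response region is *orthosteric* when it contains at least one
ligand-contact residue from the bound structure, *allosteric* when it
contains none — exchange changes there reflect long-range conformational
effects rather than direct shielding. Orthosteric regions are auto-named
O1..On and allosteric regions A1..Am by ascending start. Ligands (e.g.
fragments in a screening campaign) are ranked by the number of responding
regions and, at equal counts, by the summed magnitude of their exchange
shifts. Direction (protection vs deprotection) is carried through but does
not influence the label: distal changes may go either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .contacts import ContactSet, peptide_contact_overlap
from .uptake import ResponseRegion, regions_to_frame

__all__ = ["ClassifiedRegion", "LigandReport", "classify_regions",
           "compare_ligands", "rank_ligands"]


@dataclass(frozen=True)
class ClassifiedRegion:
    """A response region with its orthosteric/allosteric label."""

    region: ResponseRegion
    label: str                       # orthosteric | allosteric
    contact_residues: tuple[int, ...]

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end

    @property
    def magnitude(self) -> float:
        return self.region.magnitude


def classify_regions(
    regions: Sequence[ResponseRegion],
    contacts: ContactSet | Iterable[int],
) -> list[ClassifiedRegion]:
    """Label every region orthosteric (>=1 contact residue inside) or allosteric.

    Also writes the label and an O1../A1.. name back onto the regions.
    Deterministic: names follow ascending start within each label class.
    """
    classified: list[ClassifiedRegion] = []
    for region in regions:
        overlap = tuple(peptide_contact_overlap(region, contacts))
        label = "orthosteric" if overlap else "allosteric"
        region.label = label
        classified.append(ClassifiedRegion(region, label, overlap))
    for prefix, label in (("O", "orthosteric"), ("A", "allosteric")):
        members = sorted((c for c in classified if c.label == label),
                         key=lambda c: (c.start, c.end))
        for i, c in enumerate(members, start=1):
            c.region.name = f"{prefix}{i}"
    classified.sort(key=lambda c: (c.start, c.end))
    return classified


@dataclass
class LigandReport:
    """Classified response regions and summary scores for one ligand."""

    ligand: str
    regions: list[ClassifiedRegion]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_orthosteric(self) -> int:
        return sum(1 for r in self.regions if r.label == "orthosteric")

    @property
    def n_allosteric(self) -> int:
        return sum(1 for r in self.regions if r.label == "allosteric")

    @property
    def total_magnitude(self) -> float:
        """Sum over regions of the max-over-exposures |delta| (Da)."""
        return sum(r.magnitude for r in self.regions)

    def to_dict(self) -> dict:
        return {
            "ligand": self.ligand,
            "n_regions": self.n_regions,
            "n_orthosteric": self.n_orthosteric,
            "n_allosteric": self.n_allosteric,
            "total_magnitude_da": round(self.total_magnitude, 4),
            "regions": [
                {
                    "name": c.region.name,
                    "start": c.start,
                    "end": c.end,
                    "label": c.label,
                    "direction": c.region.direction,
                    "contact_residues": list(c.contact_residues),
                    "max_delta_da": {f"{t:g}": round(d, 4)
                                     for t, d in sorted(c.region.max_delta_da.items())},
                    "magnitude_da": round(c.magnitude, 4),
                    "peptides": list(c.region.peptide_ids),
                }
                for c in self.regions
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=False)
            fh.write("\n")

    def region_frame(self) -> pd.DataFrame:
        return regions_to_frame([c.region for c in self.regions])


def _overlap_clusters(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals, clustered by >=1-residue overlap."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def compare_ligands(reports: Sequence[LigandReport]) -> pd.DataFrame:
    """Presence/absence and magnitude matrix of regions across ligands.

    Region identity across ligands is by >=1-residue interval overlap: the
    row set is the overlap-clustered union of all per-ligand regions; each
    ligand contributes a presence flag and its maximum |delta| within the
    row interval. Row content is independent of report order.
    """
    if len(reports) < 2:
        raise ValueError("compare_ligands needs at least two ligand reports")
    rows = _overlap_clusters([(c.start, c.end) for rep in reports
                              for c in rep.regions])
    records = []
    for s, e in rows:
        rec: dict = {"start": s, "end": e}
        labels = set()
        for rep in sorted(reports, key=lambda r: r.ligand):
            hits = [c for c in rep.regions if c.start <= e and c.end >= s]
            rec[f"{rep.ligand}_present"] = bool(hits)
            rec[f"{rep.ligand}_max_delta_da"] = (
                round(max(c.magnitude for c in hits), 4) if hits else 0.0)
            labels.update(c.label for c in hits)
        rec["label"] = "/".join(sorted(labels))
        records.append(rec)
    return pd.DataFrame(records)


def rank_ligands(reports: Sequence[LigandReport]) -> list[dict]:
    """Rank ligands by region count, then total magnitude shift.

    Primary key: number of responding regions (descending); secondary:
    summed max-over-exposures |delta| (descending); ties broken
    alphabetically by ligand name and flagged. Input order never matters.
    """
    if not reports:
        raise ValueError("rank_ligands needs at least one report")
    keyed = sorted(
        reports,
        key=lambda r: (-r.n_regions, -round(r.total_magnitude, 9), r.ligand),
    )
    out = []
    for rank, rep in enumerate(keyed, start=1):
        tied = any(
            other is not rep
            and other.n_regions == rep.n_regions
            and abs(other.total_magnitude - rep.total_magnitude) < 1e-9
            for other in reports
        )
        out.append({
            "rank": rank,
            "ligand": rep.ligand,
            "n_regions": rep.n_regions,
            "n_orthosteric": rep.n_orthosteric,
            "n_allosteric": rep.n_allosteric,
            "total_magnitude_da": round(rep.total_magnitude, 4),
            "tied": tied,
        })
    return out
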