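"""Peptide-level deuterium-uptake analysis.

Implements the comparative core of an HDX-MS ligand-mapping experiment:

* relative deuterium uptake (RDU = deuterons exchanged / exchangeable
  amides) per peptide and exposure;
* reporter-peptide selection: a peptide is a reporter when its short-time
  RDU exceeds half (configurable) the maximum RDU observed for the protein;
* apo-vs-bound difference profiles with a fixed significance threshold in
  Daltons (default 0.5 Da; positive delta = protection, i.e. decreased
  exchange in the bound state);
* merging of significant peptides into non-overlapping residue-interval
  response regions.

Uptake tables are pandas DataFrames in a fixed CSV dialect with columns
``protein, peptide_id, start, end, sequence, state, exposure_min,
uptake_da, sd_da``. Residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UPTAKE_COLUMNS = [
    "protein", "peptide_id", "start", "end", "sequence",
    "state", "exposure_min", "uptake_da", "sd_da",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    """A pepsin-digest fragment located in protein coordinates."""

    id: str
    start: int
    end: int
    sequence: str
    n_exchangeable: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"peptide {self.id}: invalid span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.id}: sequence length {len(self.sequence)} does not "
                f"match span {self.start}-{self.end}"
            )
        if self.n_exchangeable < 0:
            raise ValueError("n_exchangeable must be non-negative")

    @classmethod
    def from_sequence(cls, id: str, start: int, sequence: str,
                      n_fast_termini: int = 1) -> "Peptide":
        n_ex = exchangeable_amides(sequence, n_fast_termini)
        return cls(id, start, start + len(sequence) - 1, sequence, n_ex)


def exchangeable_amides(sequence: str, n_fast_termini: int = 1) -> int:
    """Number of backbone amides observable in HDX for one peptide.

    The first ``n_fast_termini`` residues are excluded (their amide
    deuterons back-exchange too fast to observe) and prolines after those
    positions carry no amide hydrogen. Floored at zero.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, ch in enumerate(sequence):
        if ch not in _AA:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")
    prolines = sequence[n_fast_termini:].count("P")
    return max(len(sequence) - n_fast_termini - prolines, 0)


def read_uptake_csv(path) -> pd.DataFrame:
    """Read an uptake table in the package CSV dialect (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table {path} missing columns {missing}")
    return df[UPTAKE_COLUMNS]


def write_uptake_csv(df: pd.DataFrame, path) -> None:
    df[UPTAKE_COLUMNS].to_csv(path, index=False)


def peptide_table(df: pd.DataFrame, n_fast_termini: int = 1) -> dict[str, Peptide]:
    """Unique peptides of an uptake table, keyed by id."""
    peptides: dict[str, Peptide] = {}
    sub = df[["peptide_id", "start", "end", "sequence"]].drop_duplicates()
    for row in sub.itertuples(index=False):
        pep = Peptide.from_sequence(str(row.peptide_id), int(row.start),
                                    str(row.sequence), n_fast_termini)
        prev = peptides.get(pep.id)
        if prev is not None and prev != pep:
            raise ValueError(f"conflicting definitions for peptide {pep.id}")
        peptides[pep.id] = pep
    return peptides


def compute_rdu(
    records: pd.DataFrame,
    peptides: Mapping[str, Peptide] | None = None,
    n_fast_termini: int = 1,
    d2o_fraction: float | None = None,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Relative deuterium uptake per (peptide, exposure).

    RDU = uptake_da / (n_exchangeable [* d2o_fraction if given]). Peptides
    with zero exchangeable amides are excluded with a warning; an RDU above
    1 + ``tolerance`` indicates a unit or assignment error and raises.
    """
    if peptides is None:
        peptides = peptide_table(records, n_fast_termini)
    unknown = set(records["peptide_id"].astype(str)) - set(peptides)
    if unknown:
        raise KeyError(f"unknown peptide ids in uptake table: {sorted(unknown)}")
    skipped = [pid for pid, p in peptides.items() if p.n_exchangeable == 0]
    if skipped:
        log.warning("excluding peptides with no exchangeable amides: %s", skipped)
    out = records[~records["peptide_id"].astype(str).isin(skipped)].copy()
    n_ex = out["peptide_id"].astype(str).map(lambda pid: peptides[pid].n_exchangeable)
    denom = n_ex * (d2o_fraction if d2o_fraction is not None else 1.0)
    out["rdu"] = out["uptake_da"] / denom
    bad = out[out["rdu"] > 1.0 + tolerance]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"RDU {r['rdu']:.3f} > 1 + {tolerance} for peptide {r['peptide_id']} "
            f"at {r['exposure_min']} min: check units or amide counts"
        )
    return out[["peptide_id", "start", "end", "state", "exposure_min", "rdu"]]


@dataclass(frozen=True)
class ReporterResult:
    threshold: float
    max_rdu: float
    peptide_ids: tuple[str, ...]


def reporter_regions(
    rdu: pd.DataFrame,
    short_times: Iterable[float],
    factor: float = 0.5,
) -> ReporterResult:
    """Select reporter peptides by the half-maximum-RDU rule.

    threshold = ``factor`` x (maximum RDU over all peptides at the short
    labeling times); a peptide is a reporter when its RDU at any short time
    exceeds the threshold.
    """
    if rdu.empty:
        raise ValueError("empty RDU table")
    if not 0 < factor < 1:
        raise ValueError("factor must lie strictly between 0 and 1")
    short = sorted(set(float(t) for t in short_times))
    if not short:
        raise ValueError("short_times must be non-empty")
    sub = rdu[rdu["exposure_min"].astype(float).isin(short)]
    if sub.empty:
        raise ValueError(f"no RDU rows at short times {short}")
    max_rdu = float(sub["rdu"].max())
    threshold = factor * max_rdu
    hits = sub[sub["rdu"] > threshold]["peptide_id"].astype(str)
    return ReporterResult(threshold, max_rdu, tuple(sorted(set(hits))))


@dataclass(frozen=True)
class SignificantPeptide:
    """One peptide whose apo-bound difference clears the Da threshold."""

    id: str
    start: int
    end: int
    direction: str  # protection | deprotection | mixed
    max_abs_delta: Mapping[float, float] = field(default_factory=dict)


@dataclass
class DifferenceProfile:
    """Apo-minus-bound uptake differences for one state comparison.

    ``table`` has one row per (peptide, exposure) with ``delta_da`` (positive
    = protection) and a ``significant`` flag on the exceeding exposures;
    ``significant_peptides`` lists peptides clearing the threshold at
    >= min_timepoints exposures.
    """

    table: pd.DataFrame
    threshold_da: float
    min_timepoints: int
    significant_peptides: list[SignificantPeptide]


def difference_profile(
    apo: pd.DataFrame,
    bound: pd.DataFrame,
    threshold_da: float = 0.5,
    min_timepoints: int = 1,
    strict: bool = True,
) -> DifferenceProfile:
    """Apo-vs-bound difference profile with the fixed-Da significance rule.

    delta = uptake(apo) - uptake(bound) per shared (peptide, exposure);
    a peptide is significant when |delta| > ``threshold_da`` at at least
    ``min_timepoints`` exposures. With ``strict`` the two tables must share
    identical (peptide, exposure) grids; otherwise the intersection is used.
    """
    key = ["peptide_id", "exposure_min"]
    a = apo.set_index(key)
    b = bound.set_index(key)
    only_a, only_b = a.index.difference(b.index), b.index.difference(a.index)
    if (len(only_a) or len(only_b)) and strict:
        raise ValueError(
            "apo and bound tables do not share identical (peptide, exposure) "
            f"grids; missing in bound: {list(only_a[:5])}, missing in apo: "
            f"{list(only_b[:5])} (pass strict=False to use the intersection)"
        )
    shared = a.index.intersection(b.index)
    merged = a.loc[shared, ["start", "end", "uptake_da", "sd_da"]].copy()
    merged["delta_da"] = a.loc[shared, "uptake_da"] - b.loc[shared, "uptake_da"]
    merged["sd_pooled"] = np.sqrt(
        a.loc[shared, "sd_da"] ** 2 + b.loc[shared, "sd_da"] ** 2
    )
    merged["significant"] = merged["delta_da"].abs() > threshold_da
    merged = merged.reset_index()

    significant: list[SignificantPeptide] = []
    for pid, grp in merged.groupby("peptide_id", sort=True):
        exceeding = grp[grp["significant"]]
        if len(exceeding) < min_timepoints:
            continue
        signs = set(np.sign(exceeding["delta_da"]))
        if signs == {1.0}:
            direction = "protection"
        elif signs == {-1.0}:
            direction = "deprotection"
        else:
            direction = "mixed"
        max_abs = {
            float(t): float(g["delta_da"].abs().max())
            for t, g in grp.groupby("exposure_min")
        }
        significant.append(SignificantPeptide(
            str(pid), int(grp["start"].iloc[0]), int(grp["end"].iloc[0]),
            direction, max_abs,
        ))
    return DifferenceProfile(merged, threshold_da, min_timepoints, significant)


@dataclass
class ResponseRegion:
    """A merged residue interval responding to ligand binding."""

    start: int
    end: int
    direction: str  # protection | deprotection | mixed
    peptide_ids: tuple[str, ...]
    max_delta_da: dict[float, float] = field(default_factory=dict)
    label: str | None = None  # orthosteric | allosteric, set by classification
    name: str | None = None   # O1.. / A1.., set at reporting time

    @property
    def magnitude(self) -> float:
        """Max-over-exposures |delta| (Da), the region's magnitude score."""
        return max(self.max_delta_da.values(), default=0.0)

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def _merge_same_direction(peps: list[SignificantPeptide], direction: str,
                          max_gap: int) -> list[ResponseRegion]:
    regions: list[ResponseRegion] = []
    for p in sorted(peps, key=lambda p: (p.start, p.end)):
        if regions and p.start - regions[-1].end <= max_gap:
            r = regions[-1]
            r.end = max(r.end, p.end)
            r.peptide_ids = tuple(sorted(set(r.peptide_ids) | {p.id}))
            for t, d in p.max_abs_delta.items():
                r.max_delta_da[t] = max(r.max_delta_da.get(t, 0.0), d)
        else:
            regions.append(ResponseRegion(
                p.start, p.end, direction, (p.id,), dict(p.max_abs_delta)))
    return regions


def merge_regions(
    significant: Sequence[SignificantPeptide],
    max_gap: int = 0,
) -> list[ResponseRegion]:
    """Merge significant peptides into non-overlapping response regions.

    Same-direction peptides merge when their spans overlap by at least one
    residue; ``max_gap`` >= 1 additionally bridges intervals separated by at
    most that many start-to-end residues (1 = directly adjacent). Opposite-
    direction peptides are never merged directly; where a protection and a
    deprotection region overlap they are fused into a single region of
    direction "mixed" with a warning. Idempotent: merging the output again
    changes nothing.
    """
    by_dir: dict[str, list[SignificantPeptide]] = {}
    for p in significant:
        by_dir.setdefault(p.direction, []).append(p)
    regions: list[ResponseRegion] = []
    for direction, peps in by_dir.items():
        regions.extend(_merge_same_direction(peps, direction, max_gap))
    regions.sort(key=lambda r: (r.start, r.end))

    # second pass: fuse overlapping opposite-direction regions into "mixed"
    fused: list[ResponseRegion] = []
    for r in regions:
        if fused and r.start <= fused[-1].end:
            prev = fused[-1]
            if prev.direction != r.direction:
                warnings.warn(
                    f"residues {r.start}-{min(prev.end, r.end)} are covered by "
                    "both protection and deprotection peptides; region marked "
                    "'mixed'", stacklevel=2,
                )
                prev.direction = "mixed"
            prev.end = max(prev.end, r.end)
            prev.peptide_ids = tuple(sorted(set(prev.peptide_ids) | set(r.peptide_ids)))
            for t, d in r.max_delta_da.items():
                prev.max_delta_da[t] = max(prev.max_delta_da.get(t, 0.0), d)
        else:
            fused.append(r)
    return fused


def regions_to_frame(regions: Sequence[ResponseRegion]) -> pd.DataFrame:
    """Tabular view of response regions (one row per region)."""
    rows = []
    for r in regions:
        row = {
            "name": r.name, "start": r.start, "end": r.end,
            "direction": r.direction, "label": r.label,
            "max_delta_da": round(r.magnitude, 4),
            "peptides": ";".join(r.peptide_ids),
        }
        for t in sorted(r.max_delta_da):
            row[f"max_delta_{t:g}min"] = round(r.max_delta_da[t], 4)
        rows.append(row)
    return pd.DataFrame(rows)
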