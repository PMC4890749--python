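"""Deterministic Hsp90 N-terminal ATPase domain fixture.

A fully synthetic, download-free dataset encoding the published region
catalogue for the Hsp90 NTD screen: four orthosteric regions (O1 45-70,
O2 89-119, O3 131-138, O4 171-197) and five allosteric regions (A1 2-16,
A2 62-90, A3 77-90, A4 120-127, A5 201-213), with per-ligand presence for
two high-affinity inhibitors (radicicol, 17-AAG) and two weak phenolic
fragments, plus the 17 ligand-contact residues of the ATP pocket.

The uptake tables are built so that running the full difference -> merge ->
classify pipeline at the 0.5 Da threshold reproduces the per-ligand
presence/absence pattern, and the synthetic structure's 4 A contact set
equals the catalogued contact residues. Peptides tile the 236-residue
domain along the region boundaries, so every peptide lies wholly inside or
wholly outside each catalogued region.

Note on overlapping catalogue entries: A2 (62-90) overlaps O1 and O2, and
A3 is contained in A2, so interval merging necessarily fuses 45-119 into a
single orthosteric region; A4 and A5 remain separate, distinguishable
allosteric marks (see EXPECTED_PIPELINE_REGIONS). The maximum relative
deuterium uptake of the apo tables is 0.67 at the 10 min labeling time,
so the half-maximum reporter threshold evaluates to 0.335.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import BindingKinetics
from .simulate import make_synthetic_structure
from .uptake import UPTAKE_COLUMNS, Peptide, exchangeable_amides

PROTEIN_LENGTH = 236

ORTHOSTERIC_REGIONS = {"O1": (45, 70), "O2": (89, 119),
                       "O3": (131, 138), "O4": (171, 197)}
ALLOSTERIC_REGIONS = {"A1": (2, 16), "A2": (62, 90), "A3": (77, 90),
                      "A4": (120, 127), "A5": (201, 213)}
REGIONS = {**ORTHOSTERIC_REGIONS, **ALLOSTERIC_REGIONS}

CONTACT_RESIDUES = frozenset(
    {48, 51, 54, 55, 58, 91, 93, 96, 97, 98, 106, 107, 112, 135, 138, 184, 186}
)

#: ligand name -> (K_D molar, exchange-condition concentration molar, regions)
LIGANDS: dict[str, dict] = {
    "radicicol": {
        "K_D": 19e-9, "conc": 20e-6,
        "regions": ["O1", "O2", "O3", "O4", "A1", "A2", "A3", "A4"],
    },
    "17-AAG": {
        "K_D": 33e-9, "conc": 20e-6,
        "regions": ["O1", "O2", "O3", "O4", "A1", "A2"],
    },
    "fragment-1": {
        "K_D": 490e-6, "conc": 5e-3,
        "regions": ["O1", "O2", "O3", "O4", "A1", "A2", "A3", "A4", "A5"],
    },
    "fragment-2": {
        "K_D": 570e-6, "conc": 5e-3,
        "regions": ["O1", "O2", "O3", "O4", "A1", "A2"],
    },
}

PROTEIN_CONC = 3.3e-6  # molar, exchange conditions
EXPOSURES_MIN = (0.5, 2.0, 5.0, 10.0)
D2O_FRACTION = 0.9

#: merged intervals the pipeline detects per ligand (overlapping catalogue
#: entries 45-70 / 62-90 / 77-90 / 89-119 fuse into one orthosteric 45-119)
EXPECTED_PIPELINE_REGIONS: dict[str, dict[tuple[int, int], str]] = {
    "radicicol": {(2, 16): "allosteric", (45, 119): "orthosteric",
                  (120, 127): "allosteric", (131, 138): "orthosteric",
                  (171, 197): "orthosteric"},
    "17-AAG": {(2, 16): "allosteric", (45, 119): "orthosteric",
               (131, 138): "orthosteric", (171, 197): "orthosteric"},
    "fragment-1": {(2, 16): "allosteric", (45, 119): "orthosteric",
                   (120, 127): "allosteric", (131, 138): "orthosteric",
                   (171, 197): "orthosteric", (201, 213): "allosteric"},
    "fragment-2": {(2, 16): "allosteric", (45, 119): "orthosteric",
                   (131, 138): "orthosteric", (171, 197): "orthosteric"},
}

# per-(ligand, region) protection depth in Da, chosen to echo the study's
# qualitative magnitudes: largest early protection at O2 for the strong
# binders, ~1 Da shifts for the fragments, fragment 2 weakest
_DEPTH: dict[str, dict[str, float]] = {
    "radicicol": {"O1": 1.2, "O2": 3.0, "O3": 1.2, "O4": 1.2,
                  "A1": 0.9, "A2": 1.0, "A3": 0.9, "A4": 0.8},
    "17-AAG": {"O1": 1.1, "O2": 2.5, "O3": 1.1, "O4": 1.1,
               "A1": 0.9, "A2": 0.9},
    "fragment-1": {"O1": 0.9, "O2": 1.2, "O3": 0.9, "O4": 0.9,
                   "A1": 0.8, "A2": 0.8, "A3": 0.7, "A4": 0.7, "A5": 0.8},
    "fragment-2": {"O1": 0.7, "O2": 0.8, "O3": 0.7, "O4": 0.7,
                   "A1": 0.7, "A2": 0.7},
}

# time-course weight of the protection, per exposure index (0.5/2/5/10 min):
# binding-pocket H-bond protection at O2 peaks early; elsewhere protection
# accumulates at the longer labeling times
_PROFILE_EARLY = (1.0, 0.8, 0.6, 0.4)
_PROFILE_LATE = (0.2, 0.5, 0.9, 1.0)
_PROFILE_EARLY_ONLY = (1.0, 0.3, 0.1, 0.05)  # fragment 2 at O2

_MAX_PEPTIDE_LEN = 15
_MAX_RDU = 0.67         # apo maximum relative uptake, at 10 min
_REGION_PLATEAU = 0.6   # plateau RDU of other region peptides
_KEX_FAST = 5.0         # min^-1, O2 peptides (observable protection at 0.5 min)
_KEX_SLOW = 0.15        # min^-1, other region peptides (late protection)

_SEQ_ALPHABET = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # proline-free


def _tile_region(s: int, e: int, length: int = 14, overlap: int = 4):
    """Overlapping tiles wholly inside [s, e] (one tile if span <= length)."""
    if e - s + 1 <= length:
        return [(s, e)]
    spans = []
    pos = s
    while pos + length - 1 < e:
        spans.append((pos, pos + length - 1))
        pos += length - overlap
    spans.append((e - length + 1, e))
    return spans


def _background_gaps() -> list[tuple[int, int]]:
    """Maximal intervals covered by no catalogued region."""
    covered = set()
    for s, e in REGIONS.values():
        covered.update(range(s, e + 1))
    gaps, start = [], None
    for r in range(1, PROTEIN_LENGTH + 2):
        if r <= PROTEIN_LENGTH and r not in covered:
            start = r if start is None else start
        elif start is not None:
            gaps.append((start, r - 1))
            start = None
    return gaps


def _split(seg: tuple[int, int], max_len: int = _MAX_PEPTIDE_LEN):
    s, e = seg
    n = e - s + 1
    k = -(-n // max_len)
    base, extra = divmod(n, k)
    start = s
    for i in range(k):
        size = base + (1 if i < extra else 0)
        yield (start, start + size - 1)
        start += size


def _peptide_spans() -> list[tuple[int, int]]:
    """The fixture pepsin map: overlapping tiles inside every catalogued
    region (so same-direction responses chain into contiguous merged
    intervals) plus disjoint tiles over the uncovered background."""
    spans: set[tuple[int, int]] = set()
    for s, e in REGIONS.values():
        spans.update(_tile_region(s, e))
    for gap in _background_gaps():
        spans.update(_split(gap))
    return sorted(spans)


def _regions_containing(span: tuple[int, int]) -> list[str]:
    s, e = span
    return [name for name, (rs, re_) in REGIONS.items() if rs <= s and e <= re_]


@dataclass
class Hsp90Fixture:
    """The complete fixture: tables, structure and ground-truth catalogue."""

    apo: pd.DataFrame
    bound: dict[str, pd.DataFrame]      # ligand -> uptake table
    structure_pdb: str
    ligand_selector: str
    peptides: list[Peptide]
    kinetics: dict[str, BindingKinetics]

    def manifest(self) -> dict:
        return {
            "protein_length": PROTEIN_LENGTH,
            "regions": {k: list(v) for k, v in REGIONS.items()},
            "contact_residues": sorted(CONTACT_RESIDUES),
            "ligands": {
                name: {"K_D_M": info["K_D"], "conc_M": info["conc"],
                       "regions": info["regions"]}
                for name, info in LIGANDS.items()
            },
            "expected_pipeline_regions": {
                lig: {f"{s}-{e}": lab for (s, e), lab in regs.items()}
                for lig, regs in EXPECTED_PIPELINE_REGIONS.items()
            },
            "exposures_min": list(EXPOSURES_MIN),
            "d2o_fraction": D2O_FRACTION,
            "protein_conc_M": PROTEIN_CONC,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.apo.to_csv(out / "hsp90_apo.csv", index=False)
        for name, df in self.bound.items():
            df.to_csv(out / f"hsp90_{name}.csv", index=False)
        (out / "hsp90_synthetic.pdb").write_text(self.structure_pdb)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
            fh.write("\n")


def make_hsp90_fixture() -> Hsp90Fixture:
    """Build the deterministic Hsp90 screening fixture (apo + 4 ligand states)."""
    rng = np.random.default_rng(1004840)
    sequence = "".join(rng.choice(_SEQ_ALPHABET, size=PROTEIN_LENGTH))

    peptides: list[Peptide] = []
    params: dict[str, tuple[float, float]] = {}  # id -> (plateau RDU, k)
    in_o2_first = True
    for i, span in enumerate(_peptide_spans(), start=1):
        seq = sequence[span[0] - 1:span[1]]
        if exchangeable_amides(seq) == 0:
            continue
        pep = Peptide.from_sequence(f"p{i:03d}", span[0], seq)
        peptides.append(pep)
        names = _regions_containing(span)
        if "O2" in names:
            plateau = _MAX_RDU if (in_o2_first and pep.n_exchangeable >= 5) \
                else _REGION_PLATEAU
            if plateau == _MAX_RDU:
                in_o2_first = False
            params[pep.id] = (plateau, _KEX_FAST)
        elif names:
            params[pep.id] = (_REGION_PLATEAU, _KEX_SLOW)
        else:
            params[pep.id] = (
                float(rng.uniform(0.30, 0.55)),
                float(rng.uniform(0.05, 0.30)),
            )

    t = np.asarray(EXPOSURES_MIN)

    def apo_uptake(pep: Peptide) -> np.ndarray:
        plateau, k = params[pep.id]
        return pep.n_exchangeable * plateau * -np.expm1(-k * t)

    def delta(pep: Peptide, ligand: str) -> np.ndarray:
        depths = _DEPTH[ligand]
        d = np.zeros_like(t)
        for name in _regions_containing((pep.start, pep.end)):
            if name not in depths:
                continue
            if name == "O2":
                profile = (_PROFILE_EARLY_ONLY if ligand == "fragment-2"
                           else _PROFILE_EARLY)
            else:
                profile = _PROFILE_LATE
            d = np.maximum(d, depths[name] * np.asarray(profile))
        return np.minimum(d, apo_uptake(pep))  # bound uptake floors at zero

    def table(state: str, ligand: str | None) -> pd.DataFrame:
        rows = []
        for pep in peptides:
            u = apo_uptake(pep)
            if ligand is not None:
                u = u - delta(pep, ligand)
            for j, tp in enumerate(EXPOSURES_MIN):
                rows.append(("Hsp90-NTD", pep.id, pep.start, pep.end,
                             pep.sequence, state, tp, round(float(u[j]), 6), 0.0))
        return pd.DataFrame(rows, columns=UPTAKE_COLUMNS)

    apo = table("apo", None)
    bound = {name: table(name, name) for name in LIGANDS}
    structure = make_synthetic_structure(PROTEIN_LENGTH, sorted(CONTACT_RESIDUES),
                                         ligand_name="LIG")
    kin = {
        name: BindingKinetics(K_D=info["K_D"], ligand_conc=info["conc"],
                              protein_conc=PROTEIN_CONC)
        for name, info in LIGANDS.items()
    }
    return Hsp90Fixture(apo=apo, bound=bound, structure_pdb=structure,
                        ligand_selector="LIG", peptides=peptides, kinetics=kin)
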