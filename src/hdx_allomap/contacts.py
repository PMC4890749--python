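"""Ligand-contact residues from a ligand-bound structure.

The orthosteric site is operationally defined by distance: a residue is a
ligand contact when any of its atoms lies within a cutoff (default 4.0 A,
inclusive) of any ligand atom; residues beyond the cutoff are distal. This
is a pure distance screen — no hydrogen-bond geometry is evaluated.

Structures are read from standard PDB (or mmCIF) files via gemmi; the
ligand is selected as a HETATM group by residue name. Waters are excluded,
only the first model and first alternate location are used, and hydrogens
are ignored by default so the screen is over heavy atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

__all__ = ["StructureModel", "ContactSet", "load_structure", "contact_residues",
           "peptide_contact_overlap", "write_contact_tsv", "write_attribute_file"]


@dataclass(frozen=True)
class StructureModel:
    """Protein/ligand atom partition of one structure.

    ``residue_offset`` is added to the author residue numbers to place them
    in the HDX sequence coordinate (0 when the numberings already agree).
    """

    protein_coords: np.ndarray       # (N, 3) in Angstrom
    protein_residues: np.ndarray     # (N,) residue index per atom, offset applied
    residue_names: Mapping[int, str]
    ligand_coords: np.ndarray        # (M, 3)
    ligand_name: str
    residue_offset: int = 0

    def __post_init__(self) -> None:
        if self.ligand_coords.shape[0] == 0:
            raise ValueError("ligand atom set is empty")
        if not (np.isfinite(self.protein_coords).all()
                and np.isfinite(self.ligand_coords).all()):
            raise ValueError("non-finite coordinates in structure")


@dataclass(frozen=True)
class ContactSet:
    """Residues within ``cutoff_A`` of any ligand atom, with min distances."""

    cutoff_A: float
    residues: frozenset[int]
    min_distance_A: Mapping[int, float]

    def __contains__(self, residue: int) -> bool:
        return residue in self.residues


def load_structure(
    source,
    ligand_selector: str,
    residue_offset: int = 0,
    include_hydrogens: bool = False,
) -> StructureModel:
    """Load a PDB/mmCIF file (path) or PDB text and partition it.

    ``ligand_selector`` names the HETATM residue of the ligand (e.g. "RDC").
    Waters and hetero groups other than the selected ligand enter neither
    partition. If several models are present the first is used with a
    warning; for each atom only the first alternate location is kept.
    """
    if isinstance(source, str) and "\n" in source:
        structure = gemmi.read_pdb_string(source)
    else:
        structure = gemmi.read_structure(str(source))
    if len(structure) == 0:
        raise ValueError("structure contains no models")
    if len(structure) > 1:
        warnings.warn(f"structure has {len(structure)} models; using the first",
                      stacklevel=2)
    model = structure[0]

    prot_xyz, prot_res = [], []
    res_names: dict[int, str] = {}
    lig_xyz: list[tuple[float, float, float]] = []
    het_names: set[str] = set()
    for chain in model:
        for residue in chain:
            name = residue.name.strip()
            is_het = residue.het_flag == "H"
            if name in _WATER_NAMES:
                continue
            seen_altloc: set[str] = set()
            for atom in residue:
                if not include_hydrogens and atom.is_hydrogen():
                    continue
                if atom.altloc and atom.name in seen_altloc:
                    continue
                if atom.altloc:
                    seen_altloc.add(atom.name)
                pos = (atom.pos.x, atom.pos.y, atom.pos.z)
                if is_het:
                    het_names.add(name)
                    if name == ligand_selector:
                        lig_xyz.append(pos)
                else:
                    idx = residue.seqid.num + residue_offset
                    prot_xyz.append(pos)
                    prot_res.append(idx)
                    res_names.setdefault(idx, name)
    if not lig_xyz:
        raise ValueError(
            f"no HETATM group named {ligand_selector!r}; present hetero groups: "
            f"{sorted(het_names) or 'none'}"
        )
    return StructureModel(
        protein_coords=np.asarray(prot_xyz, dtype=float),
        protein_residues=np.asarray(prot_res, dtype=int),
        residue_names=res_names,
        ligand_coords=np.asarray(lig_xyz, dtype=float),
        ligand_name=ligand_selector,
        residue_offset=residue_offset,
    )


def contact_residues(model: StructureModel, cutoff_A: float = 4.0) -> ContactSet:
    """Residues with any atom within ``cutoff_A`` of any ligand atom.

    The boundary is inclusive: a minimum distance of exactly the cutoff
    counts as a contact (distal means *strictly beyond* the cutoff).
    An all-pairs scan; exact, and fast enough at single-structure scale.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    dmat = cdist(model.protein_coords, model.ligand_coords)
    per_atom_min = dmat.min(axis=1)
    min_dist: dict[int, float] = {}
    for res, d in zip(model.protein_residues, per_atom_min):
        r = int(res)
        if d < min_dist.get(r, np.inf):
            min_dist[r] = float(d)
    residues = frozenset(r for r, d in min_dist.items() if d <= cutoff_A)
    return ContactSet(cutoff_A, residues,
                      {r: min_dist[r] for r in sorted(residues)})


def peptide_contact_overlap(span, contacts: ContactSet | Iterable[int]) -> list[int]:
    """Contact residues falling inside a peptide span.

    ``span`` is anything with ``start``/``end`` attributes or a (start, end)
    pair, in the same (offset-applied) coordinate as the contact set.
    """
    start = getattr(span, "start", None)
    end = getattr(span, "end", None)
    if start is None:
        start, end = span
    members = contacts.residues if isinstance(contacts, ContactSet) else set(contacts)
    return sorted(r for r in members if start <= r <= end)


def write_contact_tsv(model: StructureModel, contacts: ContactSet, path) -> None:
    """Contact list as TSV: residue, resname, min_distance_A."""
    with open(path, "w") as fh:
        fh.write("residue\tresname\tmin_distance_A\n")
        for r in sorted(contacts.residues):
            name = model.residue_names.get(r, "UNK")
            fh.write(f"{r}\t{name}\t{contacts.min_distance_A[r]:.2f}\n")


def write_attribute_file(labels: Mapping[int, str], path,
                         attribute: str = "hdx_response") -> None:
    """Residue->label attribute file for structure-viewer coloring."""
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\nmatch mode: 1-to-1\nrecipient: residues\n")
        for r in sorted(labels):
            fh.write(f"\t:{r}\t{labels[r]}\n")
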