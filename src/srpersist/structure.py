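"""Protein structure parsing and mutation-site atom-set selection.

A point mutation is described by a :class:`MutationSpec`: the wild-type and
mutant structure files, the chain and 1-based residue position, and the
one-letter amino-acid codes.  From a parsed structure the featurization
pipeline needs two site-specific atom sets: the mutation-site atoms (the
residue being mutated) and the neighborhood atoms of all other residues
within a cutoff radius r of any site atom (r = 16 A by default).  Atoms
are further split by element into C/N/O subsets, giving nine ordered
(site-element, neighborhood-element) combinations that encode distinct
interaction types -- C-C pairs track hydrophobic contacts, N-O pairs
hydrogen bonds and salt bridges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.spatial.distance import cdist

from .cloud import NEIGHBORHOOD, NONE, SITE, LabeledPointCloud

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: elements used for element-specific subsets; S/Se atoms are excluded
FEATURE_ELEMENTS = ("C", "N", "O")

DEFAULT_CUTOFF = 16.0  # neighborhood cutoff radius, angstroms


class MissingResidueError(ValueError):
    """The mutation-site residue is absent from the structure."""


@dataclass
class MutationSpec:
    """A single point mutation on a wild-type / mutant structure pair."""

    structure_path: str | Path
    mutant_structure_path: str | Path
    chain: str
    position: int
    wild_aa: str
    mutant_aa: str
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        for aa, label in ((self.wild_aa, "wild_aa"), (self.mutant_aa, "mutant_aa")):
            if aa.upper() not in ONE_TO_THREE:
                raise ValueError(f"{label} must be a 1-letter amino-acid code, got {aa!r}")
        self.wild_aa = self.wild_aa.upper()
        self.mutant_aa = self.mutant_aa.upper()
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")


def load_structure(path: str | Path) -> LabeledPointCloud:
    """Parse a PDB or mmCIF file into a labeled point cloud.

    Keeps heavy atoms of standard amino-acid residues in the first model;
    hydrogens, waters and heteroatoms are excluded, and alternate locations
    resolve to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())

    coords, elements, residue_ids = [], [], []
    for chain in model:
        for res in chain:
            if res.id[0] != " " or not is_aa(res, standard=True):
                continue
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                elem = (atom.element or "").strip().capitalize()
                if elem in ("H", "D", ""):
                    continue
                coords.append(atom.get_coord())
                elements.append(elem)
                residue_ids.append((chain.id, res.id[1], res.get_resname(), atom.get_name()))
    if not coords:
        raise ValueError(f"no standard heavy atoms found in {path}")
    return LabeledPointCloud(
        coords=np.asarray(coords, dtype=float),
        element=np.array(elements, dtype=object),
        residue_id=residue_ids,
    )


def _site_mask(cloud: LabeledPointCloud, chain: str, position: int) -> np.ndarray:
    if cloud.residue_id is None:
        raise ValueError("cloud carries no residue identifiers; parse a structure first")
    return np.array(
        [rid[0] == chain and rid[1] == position for rid in cloud.residue_id], dtype=bool
    )


def residue_name_at(cloud: LabeledPointCloud, chain: str, position: int) -> str:
    """Three-letter residue name at (chain, position); raises if absent."""
    mask = _site_mask(cloud, chain, position)
    if not mask.any():
        raise MissingResidueError(
            f"mutation site chain {chain!r} position {position} is missing from "
            "the structure (missing residues at the mutation site cannot be "
            "featurized; check the model completeness)"
        )
    names = {cloud.residue_id[i][2] for i in np.flatnonzero(mask)}
    if len(names) > 1:
        raise ValueError(f"conflicting residue names at {chain}{position}: {sorted(names)}")
    return names.pop()


def check_mutation(cloud: LabeledPointCloud, spec: MutationSpec, which: str = "wild") -> None:
    """Verify the residue at the mutation site matches the spec's amino acid."""
    expected = ONE_TO_THREE[spec.wild_aa if which == "wild" else spec.mutant_aa]
    found = residue_name_at(cloud, spec.chain, spec.position)
    if found != expected:
        raise ValueError(
            f"{which}-type residue at {spec.chain}{spec.position} is {found}, "
            f"expected {expected}"
        )


def select_site_sets(cloud: LabeledPointCloud, spec: MutationSpec) -> LabeledPointCloud:
    """Tag mutation-site and neighborhood atoms; drop everything else.

    Atoms of the residue at (chain, position) are tagged SITE.  Atoms of
    every other residue lying within ``spec.cutoff`` of *any* site atom are
    tagged NEIGHBORHOOD.  The returned cloud contains only these atoms.
    The selection is monotone in the cutoff: a larger r never removes
    neighborhood atoms.
    """
    site = _site_mask(cloud, spec.chain, spec.position)
    if not site.any():
        raise MissingResidueError(
            f"mutation site chain {spec.chain!r} position {spec.position} is "
            "missing from the structure"
        )
    dists = cdist(cloud.coords, cloud.coords[site])
    near = dists.min(axis=1) <= spec.cutoff
    nbhd = near & ~site
    if not nbhd.any():
        warnings.warn(
            f"no neighborhood atoms within {spec.cutoff} A of the mutation "
            "site; downstream complexes will be degenerate", stacklevel=2)
    keep = site | nbhd
    out = cloud.subset(keep)
    group = np.where(site[keep], SITE, NEIGHBORHOOD).astype(object)
    out.group = group
    return out


def element_pair_subcloud(tagged: LabeledPointCloud, e_site: str, e_nbhd: str) -> LabeledPointCloud:
    """SITE atoms of element ``e_site`` plus NEIGHBORHOOD atoms of ``e_nbhd``.

    Either side may be empty; the pair ordering is (site element,
    neighborhood element), so (N, O) means site nitrogens against
    neighborhood oxygens.
    """
    for e in (e_site, e_nbhd):
        if e not in FEATURE_ELEMENTS:
            raise ValueError(f"element must be one of {FEATURE_ELEMENTS}, got {e!r}")
    keep = ((tagged.group == SITE) & (tagged.element == e_site)) | (
        (tagged.group == NEIGHBORHOOD) & (tagged.element == e_nbhd)
    )
    return tagged.subset(keep)
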