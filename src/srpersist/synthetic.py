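"""Deterministic generators for geometric and biological test inputs.

Everything the test suite needs is generated here -- no downloads.  Each
generator returns a :class:`FixtureManifest` alongside its data, recording
the parameters, the seed and expected properties (counts, distance
multisets) computed at generation time, so tests can cross-check what was
built against what was intended.

The two reference point configurations are the ones used to narrate facet
persistence: a regular hexagon (side 2), the unique highly symmetric
six-point set matching every narrated barcode event (six dim-0 bars dying
at edge length 2, triangles forming by 3.5), and the 8 vertices of a
1 x 1 x 1.5 cuboid.  The toy wild-type/mutant PDB pairs use idealized
backbone geometry with per-residue heavy-atom compositions matching the
amino-acid code; they are geometric stand-ins, not physically minimized
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import NONE, LabeledPointCloud

#: heavy side-chain atoms per residue (standard PDB atom names)
SIDE_CHAIN_ATOMS: dict[str, list[str]] = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

BACKBONE_ATOMS = ["N", "CA", "C", "O"]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureManifest:
    """Provenance record for one generated fixture."""

    name: str
    parameters: dict
    seed: int | None = None
    expected: dict = field(default_factory=dict)


def make_cuboid(a: float = 1.0, b: float = 1.0, c: float = 1.5):
    """The 8 vertices of an axis-aligned a x b x c cuboid (default 1 x 1 x 1.5)."""
    if min(a, b, c) <= 0:
        raise ValueError("side lengths must be positive")
    corners = np.array([[x, y, z] for x in (0, a) for y in (0, b) for z in (0, c)], dtype=float)
    cloud = LabeledPointCloud(coords=corners)
    diffs = corners[:, None, :] - corners[None, :, :]
    dists = np.sqrt((diffs ** 2).sum(-1))
    iu = np.triu_indices(8, 1)
    manifest = FixtureManifest(
        name="cuboid",
        parameters={"a": a, "b": b, "c": c},
        expected={
            "n_points": 8,
            "pair_distances": sorted(np.round(dists[iu], 12).tolist()),
            "min_distance": float(np.round(dists[iu].min(), 12)),
        },
    )
    return cloud, manifest


def make_hexagon(side: float = 2.0):
    """A regular hexagon with the given side length in the z = 0 plane."""
    if side <= 0:
        raise ValueError("side must be positive")
    ang = np.arange(6) * np.pi / 3.0
    pts = np.stack([side * np.cos(ang), side * np.sin(ang), np.zeros(6)], axis=1)
    cloud = LabeledPointCloud(coords=pts)
    diffs = pts[:, None, :] - pts[None, :, :]
    dists = np.sqrt((diffs ** 2).sum(-1))
    iu = np.triu_indices(6, 1)
    manifest = FixtureManifest(
        name="hexagon",
        parameters={"side": side},
        expected={
            "n_points": 6,
            "pair_distances": sorted(np.round(dists[iu], 12).tolist()),
            "first_triangle_at": float(np.round(side * np.sqrt(3.0), 12)),
        },
    )
    return cloud, manifest


def make_random_cloud(n: int, seed: int, box: float = 5.0, groups=None):
    """``n`` uniform points in ``[0, box]^3``, reproducible by seed.

    ``groups`` optionally assigns SITE/NEIGHBORHOOD tags: either an explicit
    length-n sequence or the string ``"random"`` for a seeded random split
    with at least one point per group (when n >= 2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    if groups == "random":
        tags = np.where(rng.random(n) < 0.5, "SITE", "NEIGHBORHOOD").astype(object)
        if n >= 2 and len(set(tags)) == 1:
            tags[0] = "SITE" if tags[1] == "NEIGHBORHOOD" else "NEIGHBORHOOD"
        group = tags
    elif groups is not None:
        group = np.asarray(groups, dtype=object)
    else:
        group = np.full(n, NONE, dtype=object)
    cloud = LabeledPointCloud(coords=coords, group=group)
    manifest = FixtureManifest(
        name="random_cloud", parameters={"n": n, "box": box}, seed=seed,
        expected={"n_points": n},
    )
    return cloud, manifest


# ---------------------------------------------------------------- toy PDBs


def _residue_atoms(resname: str, ca: np.ndarray, rng: np.random.Generator):
    """Backbone plus side-chain heavy atoms for one residue, idealized geometry.

    The backbone uses fixed offsets from the C-alpha; side-chain atoms grow
    as a jittered chain away from the backbone so atoms never coincide.
    """
    atoms = [
        ("N", "N", ca + np.array([-1.20, 0.80, 0.00])),
        ("CA", "C", ca),
        ("C", "C", ca + np.array([1.20, 0.80, 0.00])),
        ("O", "O", ca + np.array([1.50, 1.90, 0.40])),
    ]
    prev = ca.copy()
    for k, name in enumerate(SIDE_CHAIN_ATOMS[resname]):
        direction = np.array([0.15, -0.55, 1.25]) + 0.35 * rng.standard_normal(3)
        direction *= 1.5 / np.linalg.norm(direction)
        pos = prev + direction
        atoms.append((name, name[0], pos))
        prev = pos
    return atoms


def _pdb_text(residues: list[tuple[str, list]], chain: str = "A") -> str:
    """Render residues (name, atom list) as standards-conformant PDB text."""
    lines = []
    serial = 1
    for resseq, (resname, atoms) in enumerate(residues, start=1):
        for name, element, pos in atoms:
            pad = name.ljust(3) if len(name) < 4 else name
            field = f" {pad}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {field}{'':1}{resname:3s} {chain}{resseq:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}  "
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_mutation_pair(seed: int, n_residues: int, site_index: int,
                       wt_aa: str, mt_aa: str, chain: str = "A"):
    """Toy wild-type / mutant PDB pair differing only at the site residue.

    Residues sit along an extended chain with C-alpha atoms 3.8 A apart.
    Non-site residues are drawn from the seeded generator and share
    identical coordinates in both files; the site residue carries the
    wild-type amino acid in the first file and the mutant in the second,
    both rebuilt with the same side-chain random stream so the backbone is
    shared.  ``site_index`` is 0-based; the PDB residue numbering is
    1-based.

    Returns ``(wild_pdb_text, mutant_pdb_text, manifest)``.
    """
    for aa in (wt_aa, mt_aa):
        if aa.upper() not in _ONE_TO_THREE:
            raise ValueError(f"invalid 1-letter amino-acid code: {aa!r}")
    if not 0 <= site_index < n_residues:
        raise ValueError("site_index out of range")
    wt_aa, mt_aa = wt_aa.upper(), mt_aa.upper()
    rng = np.random.default_rng(seed)
    aa_pool = [a for a in _ONE_TO_THREE if a not in ("G",)]
    sequence = [aa_pool[i] for i in rng.integers(0, len(aa_pool), size=n_residues)]
    sequence[site_index] = wt_aa

    wt_res, mt_res = [], []
    for i, aa in enumerate(sequence):
        ca = np.array([3.8 * i, 0.0, 0.0])
        res_rng = np.random.default_rng((seed, i))
        if i == site_index:
            wt_res.append((_ONE_TO_THREE[wt_aa], _residue_atoms(_ONE_TO_THREE[wt_aa], ca, res_rng)))
            res_rng2 = np.random.default_rng((seed, i))
            mt_res.append((_ONE_TO_THREE[mt_aa], _residue_atoms(_ONE_TO_THREE[mt_aa], ca, res_rng2)))
        else:
            atoms = _residue_atoms(_ONE_TO_THREE[aa], ca, res_rng)
            wt_res.append((_ONE_TO_THREE[aa], atoms))
            mt_res.append((_ONE_TO_THREE[aa], atoms))

    manifest = FixtureManifest(
        name="mutation_pair",
        parameters={
            "n_residues": n_residues, "site_index": site_index,
            "wt_aa": wt_aa, "mt_aa": mt_aa, "chain": chain,
        },
        seed=seed,
        expected={
            "sequence_wt": "".join(sequence),
            "position": site_index + 1,
            "wt_heavy_atoms_at_site": 4 + len(SIDE_CHAIN_ATOMS[_ONE_TO_THREE[wt_aa]]),
            "mt_heavy_atoms_at_site": 4 + len(SIDE_CHAIN_ATOMS[_ONE_TO_THREE[mt_aa]]),
        },
    )
    return _pdb_text(wt_res, chain), _pdb_text(mt_res, chain), manifest
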