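"""Labeled point clouds and distance matrices.

The geometric input throughout the package is a :class:`LabeledPointCloud`:
3-D coordinates in angstroms, optionally carrying a chemical element symbol,
a site/neighborhood group tag, and a residue identifier per point.  Bare
point clouds (no labels) are valid inputs for barcode computation; the
labels only matter for the protein featurization pipeline.

Two metrics are supported.  The ``euclidean`` kind is the ordinary L2
distance.  The ``modified`` kind sets the distance to +inf between two
points that share the SITE group or share the NEIGHBORHOOD group, so that
only cross-group (site <-> neighborhood) interactions can form simplices
in a Vietoris-Rips filtration.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

SITE = "SITE"
NEIGHBORHOOD = "NEIGHBORHOOD"
NONE = "NONE"

_VALID_GROUPS = {SITE, NEIGHBORHOOD, NONE}


@dataclass
class LabeledPointCloud:
    """Point cloud with per-point element, group and residue labels.

    Parameters
    ----------
    coords
        ``(n, 3)`` array of coordinates in angstroms; all entries finite.
    element
        Per-point element symbol (``"C"``, ``"N"``, ``"O"``, ...); defaults
        to ``""`` for bare geometric clouds.
    group
        Per-point tag in ``{"SITE", "NEIGHBORHOOD", "NONE"}``.
    residue_id
        Optional per-point ``(chain, resseq, resname, atom_name)`` tuple;
        ``resseq`` is 1-based as in PDB files.
    """

    coords: np.ndarray
    element: np.ndarray = field(default=None)  # type: ignore[assignment]
    group: np.ndarray = field(default=None)  # type: ignore[assignment]
    residue_id: list | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        if self.element is None:
            self.element = np.full(n, "", dtype=object)
        else:
            self.element = np.asarray(self.element, dtype=object)
        if self.group is None:
            self.group = np.full(n, NONE, dtype=object)
        else:
            self.group = np.asarray(self.group, dtype=object)
        if len(self.element) != n or len(self.group) != n:
            raise ValueError("element and group arrays must have length n")
        bad = set(self.group) - _VALID_GROUPS
        if bad:
            raise ValueError(f"invalid group tags: {sorted(bad)}")
        if self.residue_id is not None and len(self.residue_id) != n:
            raise ValueError("residue_id must have length n")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def subset(self, idx) -> "LabeledPointCloud":
        """Return the sub-cloud at the given indices (order preserved)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        rid = [self.residue_id[i] for i in idx] if self.residue_id is not None else None
        return LabeledPointCloud(
            coords=self.coords[idx],
            element=self.element[idx],
            group=self.group[idx],
            residue_id=rid,
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_xyz(cls, path) -> "LabeledPointCloud":
        """Read an XYZ file (count line, comment line, ``El x y z`` rows)."""
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if not lines:
            raise ValueError(f"empty XYZ file: {path}")
        try:
            n = int(lines[0])
            body = lines[2 : 2 + n]
        except ValueError:
            # headerless variant: every line is "El x y z" or "x y z"
            body = lines
        coords, elements = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) >= 4:
                elements.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
            elif len(parts) == 3:
                elements.append("")
                coords.append([float(v) for v in parts])
            else:
                raise ValueError(f"malformed XYZ line: {ln!r}")
        return cls(coords=np.array(coords, dtype=float).reshape(-1, 3),
                   element=np.array(elements, dtype=object))

    @classmethod
    def from_csv(cls, path) -> "LabeledPointCloud":
        """Read a CSV with columns ``x,y,z`` and optional ``element,group``."""
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ValueError(f"empty CSV file: {path}")
        coords = np.array([[float(r["x"]), float(r["y"]), float(r["z"])] for r in rows])
        element = np.array([r.get("element", "") or "" for r in rows], dtype=object)
        group = np.array([r.get("group", NONE) or NONE for r in rows], dtype=object)
        return cls(coords=coords, element=element, group=group)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "z", "element", "group"])
            for p, e, g in zip(self.coords, self.element, self.group):
                w.writerow([f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", e, g])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with entries in [0, +inf].

    ``metric_kind`` records whether the matrix is the plain Euclidean
    distance or the modified distance that is +inf exactly between two
    SITE points or two NEIGHBORHOOD points.
    """

    values: np.ndarray
    metric_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.values)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if n and (np.any(np.diag(self.values) != 0.0)
                  or not np.array_equal(self.values, self.values.T)):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if self.metric_kind not in ("euclidean", "modified"):
            raise ValueError(f"unknown metric_kind: {self.metric_kind}")

    def __len__(self) -> int:
        return len(self.values)


def pairwise_distances(cloud: LabeledPointCloud, metric_kind: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances of a cloud under the standard or modified metric.

    With ``metric_kind="modified"``, entries between two points sharing the
    SITE group, or sharing the NEIGHBORHOOD group, are set to +inf; all
    other entries are the Euclidean distance.  A cloud whose tagged points
    all fall in a single group yields an edgeless complex downstream, which
    is legal but degenerate, so a warning is emitted.
    """
    n = len(cloud)
    if n == 0:
        return DistanceMatrix(values=np.zeros((0, 0)), metric_kind=metric_kind)
    dist = squareform(pdist(cloud.coords)) if n > 1 else np.zeros((1, 1))
    if metric_kind == "euclidean":
        return DistanceMatrix(values=dist, metric_kind="euclidean")
    if metric_kind != "modified":
        raise ValueError(f"unknown metric_kind: {metric_kind}")
    groups = np.asarray(cloud.group, dtype=object)
    tagged = set(groups) - {NONE}
    if n > 1 and len(tagged) == 1:
        warnings.warn(
            "all tagged points fall in a single group under the modified "
            "metric; the resulting Rips complex will be edgeless",
            stacklevel=2,
        )
    for g in (SITE, NEIGHBORHOOD):
        mask = groups == g
        block = np.outer(mask, mask)
        np.fill_diagonal(block, False)
        dist[block] = np.inf
    return DistanceMatrix(values=dist, metric_kind="modified")
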