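"""Filtered Vietoris-Rips and Alpha complexes.

Both constructions share one filtration axis measured in angstroms so that
features from the two complexes can be sampled on a common grid.  The Rips
filtration uses the *edge-length* (diameter) convention: a simplex enters
when its longest pairwise distance is reached.  Alpha filtration values are
converted from the squared-circumradius convention to radius units.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .cloud import DistanceMatrix, LabeledPointCloud, pairwise_distances

#: relative tolerance under which two filtration values count as simultaneous
FILT_RTOL = 1e-9


@dataclass
class FilteredSimplicialComplex:
    """A simplicial complex with a filtration value per simplex.

    ``simplices`` maps ascending vertex-index tuples to filtration values
    (angstroms).  The complex is closed under taking faces and monotone:
    every face enters the filtration no later than any of its cofaces.
    ``max_dim`` is the dimension cap used during construction; ``f_max`` the
    filtration ceiling.  ``structural_max_dim``, when set, certifies that no
    simplex of a higher dimension exists at *any* filtration value (e.g. a
    Rips complex over a two-group modified metric can never contain a
    triangle), which lets facets of that dimension be scored without
    building their would-be cofacets.
    """

    simplices: dict[tuple[int, ...], float]
    max_dim: int
    f_max: float
    structural_max_dim: int | None = None

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")

    def dim_simplices(self, dim: int) -> dict[tuple[int, ...], float]:
        return {s: v for s, v in self.simplices.items() if len(s) == dim + 1}

    @property
    def n_vertices(self) -> int:
        return sum(1 for s in self.simplices if len(s) == 1)

    def validate(self) -> None:
        """Check face closure and monotonicity; raise on violation."""
        for s, v in self.simplices.items():
            if v > self.f_max * (1 + FILT_RTOL):
                raise ValueError(f"simplex {s} exceeds f_max")
            if len(s) == 1:
                continue
            for face in itertools.combinations(s, len(s) - 1):
                if face not in self.simplices:
                    raise ValueError(f"missing face {face} of {s}")
                if self.simplices[face] > v * (1 + FILT_RTOL) + 1e-300:
                    raise ValueError(f"non-monotone filtration at {face} < {s}")

    def to_json(self, path=None) -> str:
        payload = {
            "max_dim": self.max_dim,
            "f_max": self.f_max,
            "simplices": [
                {"vertices": list(s), "filtration": v}
                for s, v in sorted(self.simplices.items(), key=lambda kv: (len(kv[0]), kv[1], kv[0]))
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def rips_filtration(dist: DistanceMatrix, max_dim: int, f_max: float) -> FilteredSimplicialComplex:
    """Vietoris-Rips filtration from a distance matrix.

    A simplex on vertex set S (with ``|S| - 1 <= max_dim``) is included iff
    every pairwise distance within S is finite and at most ``f_max``; its
    filtration value is the maximum pairwise distance (0 for vertices).

    Under the modified metric with two tagged groups the complex is
    structurally bipartite -- any three vertices contain a same-group pair
    at infinite distance -- so ``structural_max_dim`` is set to 1.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    d = dist.values
    n = len(d)
    simplices: dict[tuple[int, ...], float] = {(i,): 0.0 for i in range(n)}

    # lower-index neighbor lists drive the incremental expansion
    finite = np.isfinite(d) & (d <= f_max)
    np.fill_diagonal(finite, False)
    if max_dim >= 1:
        frontier = []
        for i in range(n):
            for j in range(i + 1, n):
                if finite[i, j]:
                    simplices[(i, j)] = float(d[i, j])
                    frontier.append((i, j))
        for dim in range(2, max_dim + 1):
            new_frontier = []
            for s in frontier:
                # candidate extensions: vertices adjacent to all of s, above max(s)
                cand = np.flatnonzero(np.all(finite[list(s)], axis=0))
                for v in cand:
                    if v > s[-1]:
                        t = s + (int(v),)
                        simplices[t] = float(max(simplices[s], d[list(s), v].max()))
                        new_frontier.append(t)
            frontier = new_frontier
            if not frontier:
                break

    # dimensions provably absent at any threshold: n points cap dimension at
    # n - 1, and a two-group modified metric forbids triangles outright
    bound = n - 1
    if dist.metric_kind == "modified" and np.isinf(d).any():
        bound = min(bound, 1)
    structural = bound if 0 <= bound <= max_dim else None
    return FilteredSimplicialComplex(
        simplices=simplices, max_dim=max_dim, f_max=float(f_max),
        structural_max_dim=structural,
    )


# ---------------------------------------------------------------- alpha


def _circumradius2(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Squared circumradius and circumcenter of an affinely independent simplex.

    The circumcenter is found in the affine hull of the vertices by solving
    the equal-distance conditions in barycentric-free form.
    """
    p0 = points[0]
    rel = points[1:] - p0
    if len(rel) == 0:
        return 0.0, p0.copy()
    # c = p0 + rel.T @ x with 2 * rel @ (c - p0) = |rel_i|^2
    gram = 2.0 * rel @ rel.T
    rhs = np.einsum("ij,ij->i", rel, rel)
    x = np.linalg.solve(gram, rhs)
    center = p0 + rel.T @ x
    r2 = float(np.dot(center - p0, center - p0))
    return r2, center


def alpha_filtration(cloud: LabeledPointCloud, f_max: float) -> FilteredSimplicialComplex:
    """Alpha filtration of a point cloud, values in radius units (angstroms).

    The complex is the Delaunay triangulation filtered by the radius of the
    smallest empty circumscribing ball: a Delaunay simplex whose circumball
    is empty of other points (Gabriel) enters at its own circumradius;
    every other simplex enters with its first Delaunay cofacet.  Vertices
    enter at 0.  Simplices whose radius exceeds ``f_max`` are dropped.

    Degenerate inputs are handled by reducing dimension: exact duplicate
    points are collapsed with a warning, coplanar 3-D input is triangulated
    in-plane, and collinear input becomes a path of consecutive segments.
    """
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    coords = np.asarray(cloud.coords, dtype=float)
    n = len(coords)
    if n == 0:
        raise ValueError("alpha filtration requires at least one point")

    # collapse exact duplicates, remembering representative indices
    _, uniq_idx = np.unique(coords.round(12), axis=0, return_index=True)
    uniq_idx = np.sort(uniq_idx)
    if len(uniq_idx) < n:
        warnings.warn(
            f"collapsed {n - len(uniq_idx)} duplicate point(s) before "
            "Delaunay triangulation", stacklevel=2)
    pts = coords[uniq_idx]
    index_map = {k: int(orig) for k, orig in enumerate(uniq_idx)}
    m = len(pts)

    simplices: dict[tuple[int, ...], float] = {}

    def add(local_simplex: tuple[int, ...], value: float) -> None:
        s = tuple(sorted(index_map[v] for v in local_simplex))
        simplices[s] = value

    if m == 1:
        add((0,), 0.0)
        top_dim = 0
    else:
        centered = pts - pts.mean(axis=0)
        # affine dimension of the input, with a scale-aware threshold
        sv = np.linalg.svd(centered, compute_uv=False)
        scale = sv[0] if sv[0] > 0 else 1.0
        rank = int(np.sum(sv > 1e-9 * scale))
        _, _, vt = np.linalg.svd(centered)
        proj = centered @ vt[:rank].T if rank > 0 else np.zeros((m, 1))

        if rank <= 1:
            # collinear: consecutive segments along the line
            order = np.argsort(proj[:, 0])
            for i in range(m):
                add((i,), 0.0)
            seg_top = 0
            for a, b in zip(order[:-1], order[1:]):
                r = float(np.linalg.norm(pts[a] - pts[b])) / 2.0
                if r <= f_max:
                    add((int(a), int(b)), r)
                    seg_top = 1
            top_dim = seg_top
        else:
            if m < rank + 2:
                # too few points for qhull; the full simplex is the triangulation
                tri_simplices = [tuple(range(m))]
            else:
                try:
                    tri = Delaunay(proj[:, :rank])
                except QhullError:
                    try:
                        tri = Delaunay(proj[:, :rank], qhull_options="QJ")
                    except QhullError as err:  # pragma: no cover
                        raise ValueError(
                            "degenerate point configuration: Delaunay "
                            "triangulation failed even after joggling; supply "
                            "points in general position or perturb the input"
                        ) from err
                tri_simplices = [tuple(s) for s in tri.simplices]
            values = _alpha_values(pts, tri_simplices)
            top_dim = max((len(s) - 1 for s in values), default=0)
            for s, v in values.items():
                r = float(np.sqrt(max(v, 0.0)))
                if len(s) == 1 or r <= f_max:
                    add(s, 0.0 if len(s) == 1 else r)

    cx = FilteredSimplicialComplex(
        simplices=simplices, max_dim=top_dim, f_max=float(f_max),
        structural_max_dim=top_dim,
    )
    _enforce_monotone(cx)
    return cx


def _alpha_values(pts: np.ndarray, top_simplices: list[tuple[int, ...]]) -> dict[tuple[int, ...], float]:
    """Squared alpha values for every face of a Delaunay triangulation.

    A face is Gabriel when its circumball contains no input point strictly
    inside; Gabriel faces take their own squared circumradius, all others
    take the minimum over their Delaunay cofacets.  Dimensions are resolved
    top-down so cofacet values are final before faces are assigned.
    """
    by_dim: dict[int, set[tuple[int, ...]]] = {}
    top_dim = max(len(s) - 1 for s in top_simplices)
    by_dim[top_dim] = {tuple(sorted(s)) for s in top_simplices}
    for d in range(top_dim, 0, -1):
        faces = set()
        for s in by_dim[d]:
            faces.update(itertools.combinations(s, d))
        by_dim[d - 1] = faces

    values: dict[tuple[int, ...], float] = {}
    for s in by_dim[top_dim]:
        r2, _ = _circumradius2(pts[list(s)])
        values[s] = r2
    for d in range(top_dim - 1, 0, -1):
        cof_min: dict[tuple[int, ...], float] = {}
        for s in by_dim[d + 1]:
            for face in itertools.combinations(s, d + 1):
                v = values[s]
                if face not in cof_min or v < cof_min[face]:
                    cof_min[face] = v
        for s in by_dim[d]:
            r2, center = _circumradius2(pts[list(s)])
            d2 = np.einsum("ij,ij->i", pts - center, pts - center)
            inside = d2 < r2 * (1 - FILT_RTOL) - 1e-300
            inside[list(s)] = False
            if inside.any():  # not Gabriel
                values[s] = cof_min[s]
            else:
                values[s] = r2
    for s in by_dim[0]:
        values[s] = 0.0
    return values


def _enforce_monotone(cx: FilteredSimplicialComplex) -> None:
    """Clamp tiny floating-point monotonicity violations (faces above cofaces)."""
    for dim in range(cx.max_dim, 0, -1):
        for s, v in cx.dim_simplices(dim).items():
            for face in itertools.combinations(s, dim):
                if face in cx.simplices and cx.simplices[face] > v:
                    cx.simplices[face] = v


def rips_from_cloud(cloud: LabeledPointCloud, max_dim: int, f_max: float,
                    metric_kind: str = "euclidean") -> FilteredSimplicialComplex:
    """Convenience wrapper: distances then Rips filtration."""
    return rips_filtration(pairwise_distances(cloud, metric_kind), max_dim, f_max)
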