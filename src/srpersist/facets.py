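"""Persistent facet-ideal barcodes, f-vector curves and h-vectors.

In the Stanley-Reisner decomposition of a simplicial complex, each facet
(maximal simplex) sigma contributes a prime monomial ideal P_sigma.  Under
a filtration, a simplex is a facet over a filtration interval: it is born
when it enters the complex and dies when its first cofacet appears, at
which point it stops being maximal.  Tracking these intervals gives the
*facet persistence barcode*, and counting faces per dimension along the
filtration gives the *persistent f-vector curve*.  Both are the algebraic
descriptors this package turns into machine-learning features.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .complexes import FILT_RTOL, FilteredSimplicialComplex


@dataclass(frozen=True)
class FacetBar:
    """One facet-persistence interval [birth, death).

    ``open_ended`` marks bars still alive at the filtration ceiling; their
    ``death`` is reported as ``f_max`` (the plot limit), not a real event.
    """

    dim: int
    birth: float
    death: float
    vertices: tuple[int, ...]
    open_ended: bool = False

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class FacetBarcode:
    """Collection of facet bars with the filtration ceiling they refer to."""

    bars: list[FacetBar]
    f_max: float

    def by_dim(self, dim: int) -> list[FacetBar]:
        return [b for b in self.bars if b.dim == dim]

    @property
    def dims(self) -> list[int]:
        return sorted({b.dim for b in self.bars})

    def alive_at(self, t: float, dim: int | None = None) -> list[FacetBar]:
        """Bars alive at filtration value t (open-ended bars count through f_max)."""
        out = []
        for b in self.bars:
            if dim is not None and b.dim != dim:
                continue
            if b.birth <= t and (t < b.death or (b.open_ended and t <= self.f_max)):
                out.append(b)
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "f_max": self.f_max,
            "bars": [
                {"dim": b.dim, "birth": b.birth, "death": b.death,
                 "open": b.open_ended, "vertices": list(b.vertices)}
                for b in self.bars
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "FacetBarcode":
        payload = json.loads(text)
        bars = [
            FacetBar(dim=b["dim"], birth=b["birth"], death=b["death"],
                     vertices=tuple(b["vertices"]), open_ended=b["open"])
            for b in payload["bars"]
        ]
        return cls(bars=bars, f_max=payload["f_max"])


@dataclass
class FVectorCurve:
    """Per-dimension face counts sampled on a filtration grid.

    ``counts[k, i]`` is ``f_{i-1}`` at grid point k, with the conventional
    leading ``f_{-1} = 1`` (the empty face) in column 0.
    """

    grid: np.ndarray
    counts: np.ndarray

    def f(self, i: int) -> np.ndarray:
        """The curve of ``f_i`` over the grid (i = -1 is the empty face)."""
        return self.counts[:, i + 1]

    def to_tsv(self, path=None) -> str:
        lines = ["grid\t" + "\t".join(f"{t:g}" for t in self.grid)]
        for i in range(self.counts.shape[1]):
            lines.append(f"f_{i - 1}\t" + "\t".join(str(int(c)) for c in self.counts[:, i]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def facet_barcode(cx: FilteredSimplicialComplex,
                  dims: list[int] | None = None) -> FacetBarcode:
    """Compute the facet persistence barcode of a filtered complex.

    For each simplex, birth is its filtration value and death is the
    minimum filtration value over its cofacets (one dimension up); a
    simplex with no cofacet by the ceiling stays a facet and its bar is
    reported open-ended at ``f_max``.  Bars with persistence at most
    ``1e-9 * f_max`` are dropped, excluding zero-length bars robustly
    under floating point.

    Scoring dim-d deaths requires the (d+1)-simplices to have been built,
    or to be provably absent (``structural_max_dim``); otherwise a
    dim-(max_dim) simplex with no stored cofacet cannot be told apart from
    a true facet, and an error names the missing dimension.
    """
    max_scorable = cx.max_dim - 1
    if cx.structural_max_dim is not None and cx.structural_max_dim <= cx.max_dim:
        max_scorable = max(max_scorable, cx.structural_max_dim)
    if dims is None:
        dims = list(range(min(cx.max_dim, max_scorable) + 1))
    bad = [d for d in dims if d > max_scorable]
    if bad:
        raise ValueError(
            f"cannot score facet deaths in dimension {min(bad)}: the complex "
            f"was built with max_dim={cx.max_dim} and simplices of dimension "
            f"{min(bad) + 1} are neither present nor provably absent; rebuild "
            f"with max_dim >= {min(bad) + 1}"
        )

    tol = FILT_RTOL * cx.f_max
    # min cofacet value per simplex, via each cofacet's faces
    death: dict[tuple[int, ...], float] = {}
    for s, v in cx.simplices.items():
        if len(s) < 2:
            continue
        for face in itertools.combinations(s, len(s) - 1):
            if face not in death or v < death[face]:
                death[face] = v

    bars: list[FacetBar] = []
    for s, birth in cx.simplices.items():
        d = len(s) - 1
        if d not in dims:
            continue
        dv = death.get(s)
        if dv is None:
            bars.append(FacetBar(dim=d, birth=birth, death=cx.f_max,
                                 vertices=s, open_ended=True))
        elif dv - birth > tol:
            bars.append(FacetBar(dim=d, birth=birth, death=dv, vertices=s))
    bars.sort(key=lambda b: (b.dim, b.birth, b.death, b.vertices))
    return FacetBarcode(bars=bars, f_max=cx.f_max)


def facet_counts_on_grid(barcode: FacetBarcode, grid, dims) -> np.ndarray:
    """Matrix of alive-facet counts: entry (k, j) = bars of dims[j] alive at grid[k].

    A bar is alive at t when ``birth <= t < death``; open-ended bars count
    as alive through ``f_max``.  An empty barcode gives an all-zero matrix.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros((len(grid), len(dims)), dtype=int)
    for j, d in enumerate(dims):
        for b in barcode.bars:
            if b.dim != d:
                continue
            if b.open_ended:
                alive = (grid >= b.birth) & (grid <= barcode.f_max)
            else:
                alive = (grid >= b.birth) & (grid < b.death)
            out[:, j] += alive
    return out


def f_vector_curve(cx: FilteredSimplicialComplex, grid) -> FVectorCurve:
    """Sample the f-vector (face counts per dimension) along the filtration.

    Entry ``f_i(t)`` counts the i-simplices with filtration value <= t;
    ``f_{-1} = 1`` at every t by convention.  Counts are nondecreasing in t
    because the filtration is nested.
    """
    grid = np.asarray(grid, dtype=float)
    d_top = cx.max_dim
    counts = np.zeros((len(grid), d_top + 2), dtype=int)
    counts[:, 0] = 1
    values_by_dim: dict[int, np.ndarray] = {}
    for s, v in cx.simplices.items():
        values_by_dim.setdefault(len(s) - 1, []).append(v)  # type: ignore[arg-type]
    for i, vals in values_by_dim.items():
        vals = np.sort(np.asarray(vals))
        counts[:, i + 1] = np.searchsorted(vals, grid, side="right")
    return FVectorCurve(grid=grid, counts=counts)


def h_vector(f) -> tuple[int, ...]:
    """Stanley-Reisner h-vector of an f-vector ``(f_-1, f_0, ..., f_{d-1})``.

    ``h_j = sum_{i=0..j} (-1)^{j-i} C(d-i, j-i) f_{i-1}`` with
    ``d = len(f) - 1``.  The components sum to the top face count
    ``f_{d-1}``.
    """
    f = tuple(int(v) for v in f)
    if not f or f[0] != 1:
        raise ValueError("f-vector must start with f_-1 = 1")
    if any(v < 0 for v in f):
        raise ValueError("f-vector entries must be nonnegative")
    d = len(f) - 1
    return tuple(
        sum((-1) ** (j - i) * math.comb(d - i, j - i) * f[i] for i in range(j + 1))
        for j in range(d + 1)
    )
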