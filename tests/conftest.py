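"""Shared fixtures and the brute-force facet oracle.

The oracle is deliberately independent of the barcode implementation: at a
given filtration value it enumerates *all* vertex subsets up to a size cap,
keeps those whose diameter is within the value, and extracts the maximal
ones by direct superset checks.  Barcode correctness is then a set
comparison of alive facets at every critical value.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from srpersist import LabeledPointCloud, make_cuboid, make_hexagon


def subset_diameter(dist: np.ndarray, subset: tuple[int, ...]) -> float:
    if len(subset) == 1:
        return 0.0
    return max(dist[i, j] for i, j in itertools.combinations(subset, 2))


def oracle_alive_facets(dist: np.ndarray, t: float, max_card: int,
                        f_max: float) -> dict[int, set[tuple[int, ...]]]:
    """Maximal subsets (by one-larger superset check) present at value t.

    Returns facets of cardinality <= max_card, keyed by dimension.  A
    subset counts as present when its diameter is finite and <= min(t,
    f_max); it is maximal when no superset with one more vertex is present.
    """
    n = len(dist)
    cap = min(t, f_max)
    present: dict[int, set[tuple[int, ...]]] = {}
    for k in range(1, max_card + 2):
        found = set()
        for s in itertools.combinations(range(n), k):
            d = subset_diameter(dist, s)
            if np.isfinite(d) and d <= cap:
                found.add(s)
        present[k] = found
    alive: dict[int, set[tuple[int, ...]]] = {}
    for k in range(1, max_card + 1):
        maximal = {
            s for s in present[k]
            if not any(set(s) <= set(sup) for sup in present[k + 1])
        }
        if maximal:
            alive[k - 1] = maximal
    return alive


def barcode_alive_facets(barcode, t: float) -> dict[int, set[tuple[int, ...]]]:
    out: dict[int, set[tuple[int, ...]]] = {}
    for b in barcode.alive_at(t):
        out.setdefault(b.dim, set()).add(b.vertices)
    return out


def critical_values(dist: np.ndarray, f_max: float) -> list[float]:
    vals = sorted({0.0} | {
        float(d) for d in dist[np.triu_indices(len(dist), 1)]
        if np.isfinite(d) and d <= f_max
    })
    # probe at each critical value and between consecutive ones
    probes = list(vals)
    probes.extend((a + b) / 2 for a, b in zip(vals, vals[1:]))
    return sorted(probes)


@pytest.fixture(scope="session")
def cuboid():
    return make_cuboid()


@pytest.fixture(scope="session")
def hexagon():
    return make_hexagon()


@pytest.fixture()
def tagged_cloud():
    """A small two-group cloud for modified-metric tests."""
    coords = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
        [0.0, 2.0, 0.0], [1.5, 2.0, 0.0],
    ])
    group = np.array(["SITE", "SITE", "NEIGHBORHOOD", "NEIGHBORHOOD"], dtype=object)
    return LabeledPointCloud(coords=coords, group=group)
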