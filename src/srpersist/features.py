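"""Multiscale commutative-algebra embedding of mutation neighborhoods.

For each of the nine ordered (site-element, neighborhood-element) pairs in
{C,N,O} x {C,N,O}, two filtered complexes are built over the pair's atoms:
a Vietoris-Rips complex under the modified distance (site-site and
neighborhood-neighborhood pairs pushed to +inf, so only cross interactions
form simplices) and an alpha complex under the standard Euclidean
distance.  Four statistics are sampled on a common filtration grid
(default 1.0 to 11.8 A in 0.4 A steps, ceiling 12 A): the number of
dimension-0 and dimension-1 facet bars alive, and the f-vector face counts
f_0 and f_1.  Per structure this gives

    2 complexes x 9 pairs x 4 statistics x 28 grid points = 2016 values,

and the full embedding concatenates the wild-type block, the mutant block
and their difference (WT - MT), optionally followed by a precomputed
auxiliary feature row (surface area, secondary structure, transformer
embeddings) taken verbatim.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cloud import LabeledPointCloud, pairwise_distances
from .complexes import alpha_filtration, rips_filtration
from .facets import f_vector_curve, facet_barcode, facet_counts_on_grid
from .structure import FEATURE_ELEMENTS, MutationSpec, check_mutation, load_structure, select_site_sets

DEFAULT_F_MAX = 12.0

STATISTICS = ("facet_dim0", "facet_dim1", "f0", "f1")
COMPLEXES = ("rips", "alpha")
ELEMENT_PAIRS = tuple(itertools.product(FEATURE_ELEMENTS, FEATURE_ELEMENTS))


def default_grid() -> np.ndarray:
    """The 28-point filtration grid 1.0, 1.4, ..., 11.8 A.

    The nominal range 1-12 A with step 0.4 A does not land on 12 exactly;
    the grid is fixed at 28 points ending at 11.8 A with the filtration
    ceiling at 12 A, so feature vectors are reproducible bit-for-bit.
    """
    return np.round(1.0 + 0.4 * np.arange(28), 10)


@dataclass
class FeatureLayout:
    """Ordered descriptor of every coordinate in an embedding vector."""

    structures: tuple[str, ...] = ("WT", "MT", "DIFF")
    complexes: tuple[str, ...] = COMPLEXES
    pairs: tuple[tuple[str, str], ...] = ELEMENT_PAIRS
    statistics: tuple[str, ...] = STATISTICS
    grid: np.ndarray = field(default_factory=default_grid)
    aux_len: int = 0

    @property
    def block_length(self) -> int:
        return len(self.complexes) * len(self.pairs) * len(self.statistics) * len(self.grid)

    @property
    def length(self) -> int:
        return len(self.structures) * self.block_length + self.aux_len

    def labels(self) -> list[str]:
        out = [
            f"{s}:{c}:{es}{en}:{stat}:g{k}"
            for s in self.structures
            for c in self.complexes
            for (es, en) in self.pairs
            for stat in self.statistics
            for k in range(len(self.grid))
        ]
        out.extend(f"AUX:{j}" for j in range(self.aux_len))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "structures": list(self.structures),
            "complexes": list(self.complexes),
            "pairs": ["".join(p) for p in self.pairs],
            "statistics": list(self.statistics),
            "grid": [float(t) for t in self.grid],
            "aux_len": self.aux_len,
        })

    def matches(self, other: "FeatureLayout") -> bool:
        return (
            self.complexes == other.complexes
            and self.pairs == other.pairs
            and self.statistics == other.statistics
            and np.array_equal(self.grid, other.grid)
        )


@dataclass
class EmbeddingVector:
    """Flat feature vector plus the layout describing each coordinate."""

    values: np.ndarray
    layout: FeatureLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.layout.length:
            raise ValueError(
                f"vector length {len(self.values)} does not match layout "
                f"length {self.layout.length}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def block(self, structure: str) -> np.ndarray:
        i = self.layout.structures.index(structure)
        L = self.layout.block_length
        return self.values[i * L : (i + 1) * L]


def _pair_statistics(sub: LabeledPointCloud, kind: str, grid: np.ndarray,
                     f_max: float) -> np.ndarray:
    """The 4 x len(grid) statistics block for one element pair and complex kind."""
    out = np.zeros((len(STATISTICS), len(grid)))
    if len(sub) == 0:
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-group / duplicate warnings are routine here
        if kind == "rips":
            dist = pairwise_distances(sub, "modified")
            cx = rips_filtration(dist, max_dim=1, f_max=f_max)
        elif kind == "alpha":
            cx = alpha_filtration(sub, f_max=f_max)
        else:
            raise ValueError(f"unknown complex kind: {kind}")
    bar_dims = [d for d in (0, 1) if d <= (cx.structural_max_dim
                                           if cx.structural_max_dim is not None else cx.max_dim - 1)]
    bc = facet_barcode(cx, dims=bar_dims)
    counts = facet_counts_on_grid(bc, grid, dims=[0, 1])
    out[0] = counts[:, 0]
    out[1] = counts[:, 1]
    fv = f_vector_curve(cx, grid)
    out[2] = fv.f(0)
    out[3] = fv.f(1) if cx.max_dim >= 1 else 0
    return out


def embed_structure(tagged: LabeledPointCloud, grid=None, f_max: float = DEFAULT_F_MAX,
                    complexes: tuple[str, ...] = COMPLEXES) -> np.ndarray:
    """Per-structure feature block over all complexes, element pairs and statistics.

    ``tagged`` must carry SITE/NEIGHBORHOOD group tags (see
    :func:`srpersist.structure.select_site_sets`).  Empty element-pair
    subclouds contribute zero blocks so the vector length is constant
    across samples.
    """
    from .structure import element_pair_subcloud

    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    blocks = []
    for kind in complexes:
        for (e_site, e_nbhd) in ELEMENT_PAIRS:
            sub = element_pair_subcloud(tagged, e_site, e_nbhd)
            blocks.append(_pair_statistics(sub, kind, grid, f_max).ravel())
    return np.concatenate(blocks)


def assemble_feature_vector(wt_block: np.ndarray, mt_block: np.ndarray,
                            aux: np.ndarray | None = None,
                            layout: FeatureLayout | None = None) -> EmbeddingVector:
    """Concatenate [WT | MT | WT - MT | aux] into the final embedding.

    The difference block is wild-type minus mutant by convention.  An
    auxiliary row (precomputed physical / transformer features) is appended
    verbatim when given.
    """
    wt_block = np.asarray(wt_block, dtype=float)
    mt_block = np.asarray(mt_block, dtype=float)
    if wt_block.shape != mt_block.shape:
        raise ValueError(
            f"wild-type and mutant blocks disagree in layout: "
            f"{wt_block.shape} vs {mt_block.shape}"
        )
    if layout is None:
        layout = FeatureLayout()
    if len(wt_block) != layout.block_length:
        raise ValueError(
            f"block length {len(wt_block)} does not match layout block "
            f"length {layout.block_length}"
        )
    aux_arr = np.asarray(aux, dtype=float) if aux is not None else np.zeros(0)
    layout = FeatureLayout(
        structures=layout.structures, complexes=layout.complexes,
        pairs=layout.pairs, statistics=layout.statistics, grid=layout.grid,
        aux_len=len(aux_arr),
    )
    values = np.concatenate([wt_block, mt_block, wt_block - mt_block, aux_arr])
    return EmbeddingVector(values=values, layout=layout)


def featurize_mutation(spec: MutationSpec, grid=None, f_max: float = DEFAULT_F_MAX,
                       aux: np.ndarray | None = None) -> EmbeddingVector:
    """End-to-end embedding for one mutation: parse, select, embed, assemble."""
    wt = load_structure(spec.structure_path)
    mt = load_structure(spec.mutant_structure_path)
    check_mutation(wt, spec, "wild")
    check_mutation(mt, spec, "mutant")
    wt_block = embed_structure(select_site_sets(wt, spec), grid=grid, f_max=f_max)
    mt_block = embed_structure(select_site_sets(mt, spec), grid=grid, f_max=f_max)
    layout = FeatureLayout(grid=default_grid() if grid is None else np.asarray(grid, dtype=float))
    return assemble_feature_vector(wt_block, mt_block, aux=aux, layout=layout)


def write_feature_tsv(path, vectors: list[EmbeddingVector], ids: list[str]) -> None:
    """Write a feature matrix as TSV with a machine-readable layout header."""
    if len(vectors) != len(ids):
        raise ValueError("one id per vector required")
    if vectors:
        layout = vectors[0].layout
        for v in vectors[1:]:
            if not layout.matches(v.layout) or v.layout.aux_len != layout.aux_len:
                raise ValueError("all vectors must share one layout")
    with open(path, "w") as fh:
        if vectors:
            fh.write("#layout " + vectors[0].layout.to_json() + "\n")
            fh.write("id\t" + "\t".join(vectors[0].layout.labels()) + "\n")
            for mid, v in zip(ids, vectors):
                fh.write(mid + "\t" + "\t".join(f"{x:.10g}" for x in v.values) + "\n")


def read_feature_tsv(path):
    """Read a feature TSV back into (ids, matrix, layout-json or None)."""
    ids, rows, layout_json = [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#layout "):
                layout_json = line[len("#layout "):]
                continue
            if line.startswith("id\t"):
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ids, np.asarray(rows, dtype=float), layout_json
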