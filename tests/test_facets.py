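"""Facet barcodes, f-vector curves and h-vectors."""

import math
from collections import Counter

import numpy as np
import pytest

from srpersist import (
    FacetBarcode,
    LabeledPointCloud,
    f_vector_curve,
    facet_barcode,
    facet_counts_on_grid,
    h_vector,
    make_random_cloud,
    pairwise_distances,
    rips_filtration,
    rips_from_cloud,
)

from conftest import barcode_alive_facets, critical_values, oracle_alive_facets


class TestFacetBarcode:
    def test_two_points(self):
        cloud = LabeledPointCloud(coords=[[0, 0, 0], [0, 0, 2]])
        cx = rips_from_cloud(cloud, max_dim=1, f_max=5.0)
        bc = facet_barcode(cx)
        zero = [(b.birth, b.death, b.open_ended) for b in bc.by_dim(0)]
        assert zero == [(0.0, 2.0, False)] * 2
        one = bc.by_dim(1)
        assert len(one) == 1
        assert (one[0].birth, one[0].death, one[0].open_ended) == (2.0, 5.0, True)

    def test_cuboid_dim1_groups_and_no_dim2(self, cuboid):
        cloud, _ = cuboid
        cx = rips_from_cloud(cloud, max_dim=3, f_max=2.5)
        bc = facet_barcode(cx)
        births_deaths = Counter(
            (round(b.birth, 9), round(b.death, 9)) for b in bc.by_dim(1)
        )
        assert births_deaths[(1.0, round(math.sqrt(2), 9))] == 8
        assert births_deaths[(1.5, round(math.sqrt(3.25), 9))] == 4
        assert len(bc.by_dim(1)) == 12
        assert bc.by_dim(2) == []

    def test_hexagon_bars(self, hexagon):
        cloud, _ = hexagon
        cx = rips_from_cloud(cloud, max_dim=3, f_max=4.5)
        bc = facet_barcode(cx)
        zero = bc.by_dim(0)
        assert len(zero) == 6
        assert all(b.birth == 0.0 and b.death == pytest.approx(2.0) for b in zero)
        one = bc.by_dim(1)
        assert len(one) == 6
        assert all(b.birth == pytest.approx(2.0) for b in one)
        assert all(b.death == pytest.approx(2 * math.sqrt(3)) for b in one)

    def test_zero_persistence_bars_excluded(self):
        # equilateral triangle: edges and the triangle appear together,
        # so no edge ever shows up as a facet bar
        cloud = LabeledPointCloud(coords=[[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]])
        cx = rips_from_cloud(cloud, max_dim=2, f_max=2.0)
        bc = facet_barcode(cx)
        assert bc.by_dim(1) == []
        assert len(bc.by_dim(2)) == 1

    def test_unscorable_dimension_raises(self, cuboid):
        cloud, _ = cuboid
        cx = rips_from_cloud(cloud, max_dim=2, f_max=2.5)
        with pytest.raises(ValueError, match="dimension 3"):
            facet_barcode(cx, dims=[2, 3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_clouds(self, seed):
        cloud, _ = make_random_cloud(n=7, seed=100 + seed, box=3.0)
        f_max = 2.8
        dist = pairwise_distances(cloud)
        cx = rips_filtration(dist, max_dim=4, f_max=f_max)
        bc = facet_barcode(cx, dims=[0, 1, 2, 3])
        for t in critical_values(dist.values, f_max):
            oracle = oracle_alive_facets(dist.values, t, max_card=4, f_max=f_max)
            assert barcode_alive_facets(bc, t) == oracle, f"mismatch at t={t}"

    def test_bipartite_dim1_bars_never_die(self, tagged_cloud):
        dist = pairwise_distances(tagged_cloud, "modified")
        cx = rips_filtration(dist, max_dim=1, f_max=10.0)
        bc = facet_barcode(cx)
        assert bc.by_dim(1)
        assert all(b.open_ended and b.death == 10.0 for b in bc.by_dim(1))

    def test_json_round_trip(self, cuboid, tmp_path):
        cloud, _ = cuboid
        bc = facet_barcode(rips_from_cloud(cloud, max_dim=3, f_max=2.5))
        text = bc.to_json(tmp_path / "bc.json")
        back = FacetBarcode.from_json((tmp_path / "bc.json").read_text())
        assert back.f_max == bc.f_max
        assert back.bars == bc.bars
        assert text == bc.to_json()


class TestFacetCountsOnGrid:
    def test_cuboid_alive_counts(self, cuboid):
        cloud, _ = cuboid
        bc = facet_barcode(rips_from_cloud(cloud, max_dim=3, f_max=2.5))
        counts = facet_counts_on_grid(bc, [0.5, 1.2, 1.45, 1.6], dims=[0, 1])
        assert counts[:, 1].tolist() == [0, 8, 0, 4]  # dim 1 at each t
        assert counts[0, 0] == 8  # all vertices still facets below 1
        assert counts[1, 0] == 0

    def test_empty_barcode_gives_zeros(self):
        bc = FacetBarcode(bars=[], f_max=5.0)
        assert facet_counts_on_grid(bc, [0, 1, 2], dims=[0, 1, 2]).sum() == 0


class TestFVector:
    def test_below_min_distance(self):
        cloud, _ = make_random_cloud(n=5, seed=1, box=10.0)
        cx = rips_from_cloud(cloud, max_dim=2, f_max=20.0)
        fv = f_vector_curve(cx, [1e-6])
        assert fv.counts[0].tolist() == [1, 5, 0, 0]

    def test_full_simplex_at_max_distance(self):
        cloud, _ = make_random_cloud(n=6, seed=2, box=2.0)
        d = pairwise_distances(cloud).values
        t_max = d.max()
        cx = rips_from_cloud(cloud, max_dim=3, f_max=t_max + 0.1)
        fv = f_vector_curve(cx, [t_max])
        for i in range(4):
            assert fv.f(i)[0] == math.comb(6, i + 1)

    def test_cuboid_at_1p45(self, cuboid):
        cloud, _ = cuboid
        cx = rips_from_cloud(cloud, max_dim=3, f_max=2.5)
        fv = f_vector_curve(cx, [1.45])
        assert fv.counts[0].tolist() == [1, 8, 12, 8, 2]

    def test_monotone_with_leading_one(self, hexagon):
        cloud, _ = hexagon
        cx = rips_from_cloud(cloud, max_dim=3, f_max=4.5)
        grid = np.linspace(0, 4.5, 40)
        fv = f_vector_curve(cx, grid)
        assert np.all(np.diff(fv.counts, axis=0) >= 0)
        assert np.all(fv.f(-1) == 1)

    def test_tsv_round_trip_shape(self, hexagon, tmp_path):
        cloud, _ = hexagon
        cx = rips_from_cloud(cloud, max_dim=2, f_max=4.5)
        fv = f_vector_curve(cx, [1.0, 2.0, 3.0])
        text = fv.to_tsv(tmp_path / "fv.tsv")
        lines = text.strip().split("\n")
        assert lines[0].startswith("grid\t")
        assert len(lines) == 1 + fv.counts.shape[1]


class TestHVector:
    @pytest.mark.parametrize("f,h", [
        ((1, 3, 3), (1, 1, 1)),   # boundary of a triangle
        ((1, 1), (1, 0)),          # a single vertex
        ((1, 4, 6, 4), (1, 1, 1, 1)),  # boundary of a tetrahedron
    ])
    def test_known_values(self, f, h):
        assert h_vector(f) == h

    @pytest.mark.parametrize("seed", range(8))
    def test_sum_equals_top_face_count(self, seed):
        cloud, _ = make_random_cloud(n=6, seed=200 + seed, box=2.5)
        cx = rips_from_cloud(cloud, max_dim=3, f_max=3.0)
        fv = f_vector_curve(cx, [1.5])
        f = tuple(int(v) for v in fv.counts[0])
        assert sum(h_vector(f)) == f[-1]

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            h_vector((2, 3, 3))
        with pytest.raises(ValueError):
            h_vector(())
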