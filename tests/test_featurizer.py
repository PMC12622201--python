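"""Structure parsing, site-set selection and embedding assembly."""

import warnings

import numpy as np
import pytest

from srpersist import (
    MissingResidueError,
    MutationSpec,
    assemble_feature_vector,
    default_grid,
    element_pair_subcloud,
    embed_structure,
    featurize_mutation,
    load_structure,
    make_mutation_pair,
    select_site_sets,
)
from srpersist.cloud import NEIGHBORHOOD, SITE
from srpersist.features import FeatureLayout, read_feature_tsv, write_feature_tsv
from srpersist.synthetic import SIDE_CHAIN_ATOMS


@pytest.fixture(scope="module")
def pair_files(tmp_path_factory):
    root = tmp_path_factory.mktemp("pdbs")
    wt, mt, manifest = make_mutation_pair(seed=11, n_residues=6, site_index=2,
                                          wt_aa="D", mt_aa="K")
    (root / "wt.pdb").write_text(wt)
    (root / "mt.pdb").write_text(mt)
    return root / "wt.pdb", root / "mt.pdb", manifest


@pytest.fixture(scope="module")
def spec(pair_files):
    wt_path, mt_path, manifest = pair_files
    return MutationSpec(wt_path, mt_path, chain="A",
                        position=manifest.expected["position"],
                        wild_aa="D", mutant_aa="K")


class TestLoadStructure:
    def test_atom_counts_match_manifest(self, pair_files):
        wt_path, mt_path, manifest = pair_files
        wt = load_structure(wt_path)
        site_atoms = [rid for rid in wt.residue_id if rid[1] == manifest.expected["position"]]
        assert len(site_atoms) == manifest.expected["wt_heavy_atoms_at_site"]
        mt = load_structure(mt_path)
        site_atoms_mt = [rid for rid in mt.residue_id if rid[1] == manifest.expected["position"]]
        assert len(site_atoms_mt) == manifest.expected["mt_heavy_atoms_at_site"]

    def test_single_ala_residue(self, tmp_path):
        wt, _, _ = make_mutation_pair(seed=0, n_residues=1, site_index=0,
                                      wt_aa="A", mt_aa="A")
        p = tmp_path / "ala.pdb"
        p.write_text(wt)
        cloud = load_structure(p)
        assert len(cloud) == 5  # N, CA, C, O, CB

    def test_parses_without_warnings(self, pair_files):
        wt_path, _, _ = pair_files
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            load_structure(wt_path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_structure("/nonexistent/file.pdb")


class TestSiteSelection:
    def test_missing_site_is_explicit_error(self, pair_files):
        wt_path, mt_path, _ = pair_files
        spec = MutationSpec(wt_path, mt_path, chain="A", position=99,
                            wild_aa="D", mutant_aa="K")
        cloud = load_structure(wt_path)
        with pytest.raises(MissingResidueError, match="position 99"):
            select_site_sets(cloud, spec)

    def test_wrong_wild_aa_rejected(self, pair_files):
        from srpersist.structure import check_mutation

        wt_path, mt_path, manifest = pair_files
        bad = MutationSpec(wt_path, mt_path, chain="A",
                           position=manifest.expected["position"],
                           wild_aa="W", mutant_aa="K")
        with pytest.raises(ValueError, match="expected TRP"):
            check_mutation(load_structure(wt_path), bad, "wild")

    def test_r0_keeps_only_site(self, pair_files):
        wt_path, mt_path, manifest = pair_files
        spec = MutationSpec(wt_path, mt_path, chain="A",
                            position=manifest.expected["position"],
                            wild_aa="D", mutant_aa="K", cutoff=0.0)
        cloud = load_structure(wt_path)
        with pytest.warns(UserWarning, match="no neighborhood"):
            tagged = select_site_sets(cloud, spec)
        assert set(tagged.group) == {SITE}

    def test_cutoff_monotone(self, pair_files, spec):
        wt_path, _, _ = pair_files
        cloud = load_structure(wt_path)
        sizes = []
        for r in (4.0, 8.0, 16.0):
            s = MutationSpec(spec.structure_path, spec.mutant_structure_path,
                             chain=spec.chain, position=spec.position,
                             wild_aa=spec.wild_aa, mutant_aa=spec.mutant_aa, cutoff=r)
            sizes.append(int(np.sum(select_site_sets(cloud, s).group == NEIGHBORHOOD)))
        assert sizes == sorted(sizes)

    def test_default_cutoff_is_16(self, pair_files):
        wt_path, mt_path, _ = pair_files
        spec = MutationSpec(wt_path, mt_path, chain="A", position=3,
                            wild_aa="D", mutant_aa="K")
        assert spec.cutoff == 16.0

    def test_planted_distance_selection(self, tmp_path):
        # residues every 3.8 A along x: with a tight cutoff only the two
        # flanking residues fall in the neighborhood
        wt, mt, man = make_mutation_pair(seed=5, n_residues=9, site_index=4,
                                         wt_aa="S", mt_aa="T")
        (tmp_path / "w.pdb").write_text(wt)
        (tmp_path / "m.pdb").write_text(mt)
        spec = MutationSpec(tmp_path / "w.pdb", tmp_path / "m.pdb", chain="A",
                            position=5, wild_aa="S", mutant_aa="T", cutoff=4.0)
        tagged = select_site_sets(load_structure(tmp_path / "w.pdb"), spec)
        nb_res = {rid[1] for rid, g in zip(tagged.residue_id, tagged.group)
                  if g == NEIGHBORHOOD}
        assert nb_res <= {3, 4, 6, 7}
        assert {4, 6} <= nb_res


class TestElementPairs:
    def test_pair_filters_both_sides(self, pair_files, spec):
        wt_path, _, _ = pair_files
        tagged = select_site_sets(load_structure(wt_path), spec)
        sub = element_pair_subcloud(tagged, "N", "O")
        site = sub.group == SITE
        assert set(sub.element[site]) <= {"N"}
        assert set(sub.element[~site]) <= {"O"}

    def test_glycine_site_backbone_oxygen(self, tmp_path):
        wt, mt, _ = make_mutation_pair(seed=1, n_residues=4, site_index=1,
                                       wt_aa="G", mt_aa="A")
        (tmp_path / "w.pdb").write_text(wt)
        (tmp_path / "m.pdb").write_text(mt)
        spec = MutationSpec(tmp_path / "w.pdb", tmp_path / "m.pdb", chain="A",
                            position=2, wild_aa="G", mutant_aa="A")
        tagged = select_site_sets(load_structure(tmp_path / "w.pdb"), spec)
        sub = element_pair_subcloud(tagged, "O", "C")
        assert int(np.sum(sub.group == SITE)) == 1  # the backbone carbonyl O

    def test_invalid_element_rejected(self, pair_files, spec):
        wt_path, _, _ = pair_files
        tagged = select_site_sets(load_structure(wt_path), spec)
        with pytest.raises(ValueError):
            element_pair_subcloud(tagged, "S", "C")


class TestEmbedding:
    def test_layout_arithmetic(self, spec):
        vec = featurize_mutation(spec)
        assert vec.layout.block_length == 2 * 9 * 4 * 28 == 2016
        assert len(vec) == 3 * 2016

    def test_deterministic_across_reruns(self, spec):
        v1 = featurize_mutation(spec)
        v2 = featurize_mutation(spec)
        assert np.array_equal(v1.values, v2.values)

    def test_diff_zero_when_structures_equal(self, pair_files):
        wt_path, _, manifest = pair_files
        spec = MutationSpec(wt_path, wt_path, chain="A",
                            position=manifest.expected["position"],
                            wild_aa="D", mutant_aa="D")
        vec = featurize_mutation(spec)
        assert np.all(vec.block("DIFF") == 0)
        assert np.count_nonzero(vec.block("WT")) > 0

    def test_atom_permutation_invariance(self, pair_files, spec):
        wt_path, _, _ = pair_files
        cloud = load_structure(wt_path)
        tagged = select_site_sets(cloud, spec)
        block = embed_structure(tagged)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tagged))
        block_p = embed_structure(tagged.subset(perm))
        assert np.allclose(block, block_p)

    def test_rigid_motion_invariance(self, pair_files, spec):
        from scipy.spatial.transform import Rotation

        wt_path, _, _ = pair_files
        tagged = select_site_sets(load_structure(wt_path), spec)
        block = embed_structure(tagged)
        R = Rotation.from_euler("zyx", [31.0, -57.0, 12.0], degrees=True).as_matrix()
        moved = tagged.subset(np.arange(len(tagged)))
        moved.coords = tagged.coords @ R.T + np.array([5.0, -3.0, 11.0])
        assert np.allclose(block, embed_structure(moved), atol=1e-8)

    def test_bipartite_facet_dim1_nondecreasing(self, pair_files, spec):
        # modified-metric dim-1 bars never die, so alive counts only grow
        wt_path, _, _ = pair_files
        tagged = select_site_sets(load_structure(wt_path), spec)
        block = embed_structure(tagged).reshape(2, 9, 4, 28)
        rips_dim1 = block[0, :, 1, :]
        assert np.all(np.diff(rips_dim1, axis=1) >= 0)

    def test_aux_appended_verbatim(self, spec):
        aux = np.arange(17, dtype=float)
        vec = featurize_mutation(spec, aux=aux)
        assert len(vec) == 3 * 2016 + 17
        assert np.array_equal(vec.values[-17:], aux)

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            assemble_feature_vector(np.zeros(10), np.zeros(12))

    def test_tsv_round_trip(self, spec, tmp_path):
        vec = featurize_mutation(spec)
        write_feature_tsv(tmp_path / "f.tsv", [vec], ["m1"])
        ids, X, layout_json = read_feature_tsv(tmp_path / "f.tsv")
        assert ids == ["m1"]
        assert X.shape == (1, len(vec))
        assert np.allclose(X[0], vec.values)
        assert '"grid"' in layout_json
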