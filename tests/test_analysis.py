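"""Superposition, backbone RMSD, clustering and mimicry ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from cyclomimic.analysis import (ResidueMapping, backbone_rmsd, cluster,
                                 kabsch_superpose, mimicry_table,
                                 pairwise_backbone_rmsd)
from cyclomimic.errors import SuperpositionError
from cyclomimic.geometry import rotate_about_axis
from cyclomimic.peptide import build_initial_conformation
from cyclomimic.search import ConformerEnsemble


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(0.0, 2.0, (6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_rigid_match_recovered(self, rng):
        pts = rng.normal(0.0, 2.0, (7, 3))
        R = Rotation.from_euler("xyz", [0.5, -1.2, 2.0]).as_matrix()
        moved = pts @ R.T + np.array([4.0, -2.0, 9.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd <= 1e-9

    def test_rotation_is_proper_orthonormal(self, rng):
        a = rng.normal(0.0, 1.0, (5, 3))
        b = rng.normal(0.0, 1.0, (5, 3))
        res = kabsch_superpose(a, b)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                   atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent cross-check against scipy's superposition."""
        for _ in range(5):
            a = rng.normal(0.0, 2.0, (8, 3))
            b = rng.normal(0.0, 2.0, (8, 3))
            ours = kabsch_superpose(a, b)
            rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            scipy_rmsd = np.sqrt(rssd ** 2 / len(a))
            assert ours.rmsd == pytest.approx(scipy_rmsd, abs=1e-8)

    def test_rmsd_symmetry(self, rng):
        a = rng.normal(0.0, 2.0, (6, 3))
        b = rng.normal(0.0, 2.0, (6, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9)

    def test_invariant_to_rigid_pretransforms(self, rng):
        a = rng.normal(0.0, 2.0, (6, 3))
        b = rng.normal(0.0, 2.0, (6, 3))
        base = kabsch_superpose(a, b).rmsd
        R = Rotation.from_euler("zxy", [1.0, 0.2, -0.7]).as_matrix()
        assert kabsch_superpose(a @ R.T + 5.0, b).rmsd == \
            pytest.approx(base, abs=1e-9)
        assert kabsch_superpose(a, b @ R.T - 3.0).rmsd == \
            pytest.approx(base, abs=1e-9)

    def test_count_mismatch_and_degenerate_rejected(self, rng):
        with pytest.raises(SuperpositionError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(SuperpositionError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, rng.normal(size=(5, 3)))


class TestBackboneRmsd:
    def test_self_rmsd_zero(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        assert backbone_rmsd(conf, conf) == pytest.approx(0.0, abs=1e-9)

    def test_definitional_consistency_with_kabsch(self, topo11):
        a = build_initial_conformation(topo11, "random", seed=1)
        b = build_initial_conformation(topo11, "random", seed=2)
        r1 = backbone_rmsd(a, b)
        r2 = kabsch_superpose(a.backbone_coords(), b.backbone_coords()).rmsd
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_gaussian_noise_rmsd_matches_expectation(self, topo11):
        """Per-coordinate sigma noise gives RMSD ~ sqrt(3)*sigma on average."""
        conf = build_initial_conformation(topo11, "extended")
        sigma = 0.3
        rng = np.random.default_rng(42)
        n_bb = len(conf.backbone_coords())
        vals = []
        for _ in range(100):
            noisy = conf.copy()
            noisy.coords = conf.coords + rng.normal(0.0, sigma,
                                                    conf.coords.shape)
            vals.append(backbone_rmsd(conf, noisy))
        mean = float(np.mean(vals))
        expect = np.sqrt(3.0) * sigma
        assert 0.8 * expect <= mean <= 1.2 * expect


def _jittered(conf, centroid_shift, sigma, rng, energy):
    """Copy of conf with optional torsion shift plus Cartesian jitter."""
    out = conf.copy()
    x = conf.coords.copy()
    if centroid_shift:
        topo = conf.topology
        for name, ang in centroid_shift:
            tdef = [t for t in topo.backbone_torsions if t["name"] == name][0]
            i, j = tdef["quad"][1], tdef["quad"][2]
            x[tdef["moved"]] = rotate_about_axis(x[tdef["moved"]], x[i],
                                                 x[j] - x[i], ang)
    x = x + rng.normal(0.0, sigma, x.shape)
    out.coords = x
    out.energy = energy
    return out


class TestCluster:
    def test_ten_copies_form_single_cluster(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        confs = []
        for i in range(10):
            c = conf.copy()
            c.energy = float(i)
            confs.append(c)
        cs = cluster(ConformerEnsemble(conformations=confs), cutoff=2.0)
        assert cs.sizes == (10,)

    def test_singleton_cluster(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        conf.energy = 0.0
        cs = cluster(ConformerEnsemble(conformations=[conf]), cutoff=2.0)
        assert cs.sizes == (1,)

    def test_seven_three_split_around_two_centroids(self, topo11):
        """7 + 3 members around centroids well beyond the cutoff split 7/3."""
        rng = np.random.default_rng(7)
        a = build_initial_conformation(topo11, "extended")
        shift = [("psi3", 2.2), ("phi6", -2.0)]
        b_centre = _jittered(a, shift, 0.0, rng, 0.0)
        gap = backbone_rmsd(a, b_centre)
        assert gap > 3.0        # centroids far apart on the backbone
        members = [_jittered(a, None, 0.1, rng, float(i)) for i in range(7)]
        members += [_jittered(b_centre, None, 0.1, rng, float(10 + i))
                    for i in range(3)]
        cs = cluster(ConformerEnsemble(conformations=members), cutoff=2.0)
        assert cs.sizes == (7, 3)

    def test_cluster_count_monotone_in_cutoff(self, topo11):
        rng = np.random.default_rng(17)
        a = build_initial_conformation(topo11, "extended")
        members = [_jittered(a, [("psi3", rng.uniform(-2, 2))], 0.2, rng,
                             float(i)) for i in range(6)]
        ens = ConformerEnsemble(conformations=members)
        counts = [len(cluster(ens, cutoff=c).clusters)
                  for c in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_clusters_partition_the_ensemble(self, topo11):
        rng = np.random.default_rng(3)
        a = build_initial_conformation(topo11, "extended")
        members = [_jittered(a, None, 0.3, rng, float(i)) for i in range(5)]
        cs = cluster(ConformerEnsemble(conformations=members), cutoff=1.0)
        flat = sorted(i for c in cs.clusters for i in c)
        assert flat == list(range(5))

    def test_invalid_inputs_rejected(self, topo11):
        with pytest.raises(ValueError):
            cluster(ConformerEnsemble(conformations=[]), cutoff=2.0)


class TestMimicry:
    def test_reference_against_itself_is_zero(self, topo11):
        conf = build_initial_conformation(topo11, "extended")
        mapping = ResidueMapping.identity(topo11.n_residues)
        table = mimicry_table([("self", conf)], conf, mapping)
        assert table.loc[0, "rmsd_A"] == pytest.approx(0.0, abs=1e-9)

    def test_noisier_structure_ranks_last(self, topo11):
        rng = np.random.default_rng(11)
        ref = build_initial_conformation(topo11, "extended")
        near = _jittered(ref, None, 0.2, rng, 0.0)
        far = _jittered(ref, None, 1.5, rng, 0.0)
        mapping = ResidueMapping.identity(topo11.n_residues)
        table = mimicry_table([("far", far), ("near", near)], ref, mapping)
        assert list(table["structure_label"]) == ["near", "far"]
        assert table["rmsd_A"].is_monotonic_increasing

    def test_unmappable_structure_flagged_not_dropped(self, topo11):
        from cyclomimic.peptide import build_topology, parse_design
        ref = build_initial_conformation(topo11, "extended")
        small_topo = build_topology(parse_design("AGA", "", False))
        small = build_initial_conformation(small_topo, "extended")
        mapping = ResidueMapping.identity(topo11.n_residues)
        table = mimicry_table([("ok", ref), ("short", small)], ref, mapping)
        assert len(table) == 2
        row = table[table.structure_label == "short"].iloc[0]
        assert not row.mappable and np.isnan(row.rmsd_A)

    def test_epitope_mapping_excludes_linker(self):
        m = ResidueMapping.epitope(9)
        assert len(m.pairs) == 9
        assert all(a == b for a, b in m.pairs)


def test_pairwise_matrix_symmetry(topo11):
    rng = np.random.default_rng(2)
    a = build_initial_conformation(topo11, "extended")
    confs = [_jittered(a, None, 0.4, rng, float(i)) for i in range(4)]
    mat = pairwise_backbone_rmsd(confs)
    np.testing.assert_allclose(mat, mat.T, atol=1e-12)
    assert np.all(np.diag(mat) == 0)
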