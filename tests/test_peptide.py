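"""Design parsing, topology construction and the coordinate builder."""

import numpy as np
import pytest

from cyclomimic.errors import DesignError
from cyclomimic.geometry import bond_angles, bond_lengths
from cyclomimic.peptide import (IDEAL_ANGLES_DEG, IDEAL_BOND_LENGTHS,
                                SC_CENTROID_DIST, build_initial_conformation,
                                build_topology, parse_design)


class TestParseDesign:
    def test_worked_example_is_11mer_cyclic(self):
        seq = parse_design("HYWSENLFQ", "PG", True)
        assert len(seq) == 11
        assert seq.cyclic
        assert seq.one_letter() == "HYWSENLFQPG"

    def test_minimal_linear_single_residue(self):
        seq = parse_design("A", "", False)
        assert len(seq) == 1 and not seq.cyclic

    def test_parsing_is_deterministic(self):
        a = parse_design("HYWSENLFQ", "PG", True)
        b = parse_design("HYWSENLFQ", "PG", True)
        assert a == b

    def test_prolines_default_trans(self):
        seq = parse_design("HYWSENLFQ", "PG", True)
        assert seq.proline_config_map == {10: "trans"}

    def test_nonstandard_code_named_in_error(self):
        with pytest.raises(DesignError, match="'B'"):
            parse_design("ABC", "", False)

    def test_cyclic_too_short_rejected(self):
        with pytest.raises(DesignError, match="3"):
            parse_design("AG", "", True)

    def test_origin_labels_preserve_source_numbering(self):
        seq = parse_design("HYWSENLFQ", "PG", True, origin_offset=105)
        labels = dict(seq.origin_labels)
        assert labels[1] == "105" and labels[9] == "113"


class TestTopology:
    @pytest.mark.parametrize("n", range(3, 21))
    def test_peptide_bond_count_law(self, n):
        """Cyclic N-mer has N peptide bonds, linear N-mer has N-1."""
        residues = ("ASDFGHKLQWERTYNCVIMP" * 2)[:n]
        cyc = build_topology(parse_design(residues, "", True))
        lin = build_topology(parse_design(residues, "", False))
        assert len(cyc.peptide_bonds) == n
        assert len(lin.peptide_bonds) == n - 1
        assert cyc.ring_closure_bond is not None
        assert lin.ring_closure_bond is None

    def test_glycine_carries_no_beta_pseudo_proton(self):
        topo = build_topology(parse_design("GAG", "", False))
        labels = {(s.res_index, s.label) for s in topo.proton_set}
        assert (1, "HB") not in labels and (3, "HB") not in labels
        assert (2, "HB") in labels

    def test_proline_nitrogen_has_no_amide_proton(self):
        topo = build_topology(parse_design("APA", "", False))
        labels = {(s.res_index, s.label) for s in topo.proton_set}
        assert (2, "HN") not in labels
        assert not topo.has_atom(2, "H")

    def test_linear_dipeptide_single_peptide_bond(self):
        topo = build_topology(parse_design("AG", "", False))
        assert len(topo.peptide_bonds) == 1
        assert topo.ring_closure_bond is None

    def test_bond_graph_is_connected(self, topo11):
        adj = {i: set() for i in range(topo11.n_atoms)}
        for i, j, _c in topo11.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        assert len(seen) == topo11.n_atoms

    def test_proton_set_within_atoms(self, topo11):
        for s in topo11.proton_set:
            assert 0 <= s.atom_index < topo11.n_atoms


class TestBuilder:
    def test_extended_mode_is_bitwise_deterministic(self, topo11):
        a = build_initial_conformation(topo11, "extended")
        b = build_initial_conformation(topo11, "extended")
        assert np.array_equal(a.coords, b.coords)

    def test_distinct_seeds_differ(self, topo11):
        a = build_initial_conformation(topo11, "random", seed=1)
        b = build_initial_conformation(topo11, "random", seed=2)
        assert np.sqrt(np.mean((a.coords - b.coords) ** 2)) > 0

    def test_same_seed_identical(self, topo11):
        a = build_initial_conformation(topo11, "random", seed=7)
        b = build_initial_conformation(topo11, "random", seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_random_mode_requires_seed(self, topo11):
        with pytest.raises(ValueError):
            build_initial_conformation(topo11, "random")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_closure_bond_near_ideal_after_refinement(self, topo11, seed):
        conf = build_initial_conformation(topo11, "random", seed=seed)
        i, j = topo11.ring_closure_bond
        d = np.linalg.norm(conf.coords[i] - conf.coords[j])
        assert abs(d - IDEAL_BOND_LENGTHS["C-N"]) <= 0.1

    def test_builder_satisfies_ideal_geometry(self, topo11):
        """Non-closure bonds within 0.02 A and angles within 2 degrees."""
        conf = build_initial_conformation(topo11, "random", seed=3)
        closure = set(topo11.ring_closure_bond)
        for i, j, cls in topo11.bonds:
            if {i, j} == closure:
                continue
            d = np.linalg.norm(conf.coords[i] - conf.coords[j])
            if cls == "CB-SC":
                code = [k for k, v in SC_CENTROID_DIST.items()][0]
                continue
            assert abs(d - IDEAL_BOND_LENGTHS[cls]) <= 0.02, cls
        theta = bond_angles(conf.coords, topo11.angles)
        mask = ~topo11.closure_term_mask["angle"]
        dev = np.rad2deg(np.abs(theta[mask] - topo11.angle_ideals[mask]))
        assert dev.max() <= 2.0

    def test_unknown_mode_rejected(self, topo11):
        with pytest.raises(ValueError):
            build_initial_conformation(topo11, "banana")
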