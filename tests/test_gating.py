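"""Gating descriptors (torsions, minimum distances), state classification
and the built-in registry."""

import numpy as np
import pytest

from aquagate.errors import ConfigurationError, SelectionError, UndefinedTorsionError
from aquagate.gating import (
    StateDefinition,
    classify,
    default_registry,
    dihedral_angle,
    evaluate_metric_structure,
    min_sidechain_distance,
    registry_from_yaml,
    registry_to_yaml,
    state_populations,
)
from aquagate.synthetic import synthetic_reference_structure

from conftest import make_structure, random_rotation


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [np.array(v, float) for v in [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        p = [np.array(v, float) for v in [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
        assert abs(dihedral_angle(*p)) == pytest.approx(180.0, abs=1e-9)

    def test_domain_wrap(self):
        p = [np.array(v, float) for v in [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0.5, -1)]]
        a180 = dihedral_angle(*p, domain=(-180, 180))
        a360 = dihedral_angle(*p, domain=(0, 360))
        assert a360 == pytest.approx(a180 % 360.0)
        assert 0 <= a360 < 360
        assert -180 <= a180 < 180

    def test_colinear_triple_undefined(self):
        p = [np.array(v, float) for v in [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)]]
        with pytest.raises(UndefinedTorsionError):
            dihedral_angle(*p)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance_and_mirror_negation(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        base = dihedral_angle(*pts)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        moved = pts @ R.T + t
        assert dihedral_angle(*moved) == pytest.approx(base, abs=1e-8)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral_angle(*mirrored) == pytest.approx(-base, abs=1e-8)


class TestMinSidechainDistance:
    def _pair_structure(self, pos_a, pos_b):
        return make_structure(
            [
                (1, "CA", "ALA", 1, "A", "C", 0, 0, 0),
                (2, "CB", "ALA", 1, "A", "C", *pos_a),
                (3, "CA", "ALA", 2, "A", "C", 5, 5, 5),
                (4, "CB", "ALA", 2, "A", "C", *pos_b),
            ]
        )

    def test_three_four_five_triangle(self):
        s = self._pair_structure((0, 0, 0), (0.3, 0.4, 0.0))
        assert min_sidechain_distance(s, ("A", 1), ("A", 2)) == pytest.approx(0.5)

    def test_identical_position_zero(self):
        s = self._pair_structure((1, 1, 1), (1, 1, 1))
        assert min_sidechain_distance(s, ("A", 1), ("A", 2)) == pytest.approx(0.0)

    def test_symmetry(self):
        s = self._pair_structure((0, 0, 0), (0.7, 0.1, 0.2))
        d_ab = min_sidechain_distance(s, ("A", 1), ("A", 2))
        d_ba = min_sidechain_distance(s, ("A", 2), ("A", 1))
        assert d_ab == d_ba

    def test_minimum_image_convention(self):
        s = self._pair_structure((0.1, 0, 0), (0.9, 0, 0))
        box = np.array([1.0, 1.0, 1.0])
        d = min_sidechain_distance(s, ("A", 1), ("A", 2), box=box)
        assert d == pytest.approx(0.2)

    def test_glycine_has_no_sidechain(self):
        s = make_structure(
            [
                (1, "CA", "GLY", 1, "A", "C", 0, 0, 0),
                (2, "CB", "ALA", 2, "A", "C", 1, 0, 0),
            ]
        )
        with pytest.raises(SelectionError):
            min_sidechain_distance(s, ("A", 1), ("A", 2))

    def test_hydrogens_excluded_under_heavy_policy(self):
        s = make_structure(
            [
                (1, "CA", "ALA", 1, "A", "C", 0, 0, 0),
                (2, "CB", "ALA", 1, "A", "C", 0.5, 0, 0),
                (3, "HB1", "ALA", 1, "A", "H", 0.9, 0, 0),
                (4, "CA", "ALA", 2, "A", "C", 5, 0, 0),
                (5, "CB", "ALA", 2, "A", "C", 1.0, 0, 0),
            ]
        )
        assert min_sidechain_distance(s, ("A", 1), ("A", 2), policy="heavy") == pytest.approx(0.5)
        assert min_sidechain_distance(s, ("A", 1), ("A", 2), policy="all") == pytest.approx(0.1)


class TestClassification:
    def test_r206_crystal_bin(self):
        d = default_registry()["r206"]
        idx = d.classify_values(np.array([311.0]))[0]
        assert d.state_labels[idx] == "s290_360"

    def test_w48_blocked_bin(self):
        d = default_registry()["w48"]
        idx = d.classify_values(np.array([-120.0]))[0]
        assert d.state_labels[idx] == "blocked"

    def test_distance_threshold_is_strict(self):
        # exactly at the threshold -> the upper ("far") bin
        d = default_registry()["f200"]
        vals = np.array([0.36999, 0.37, 0.371])
        labels = [d.state_labels[i] for i in d.classify_values(vals)]
        assert labels == ["near", "far", "far"]

    def test_angle_wrap_into_domain(self):
        d = default_registry()["r206"]
        idx = d.classify_values(np.array([-49.0]))[0]  # wraps to 311
        assert d.state_labels[idx] == "s290_360"

    def test_populations_sum_to_one(self):
        d = default_registry()["w48"]
        rng = np.random.default_rng(0)
        trace = classify(rng.uniform(-180, 180, size=1000), d)
        pops = state_populations(trace)
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-12)

    def test_populations_counts(self):
        d = default_registry()["f200"]
        vals = np.array([0.1] * 3 + [0.5] * 7)
        trace = classify(vals, d)
        pops = state_populations(trace)
        assert pops["near"] == pytest.approx(0.3)
        assert pops["far"] == pytest.approx(0.7)

    def test_empty_range_is_error(self):
        d = default_registry()["f200"]
        trace = classify(np.array([0.5]), d)
        with pytest.raises(ConfigurationError):
            state_populations(trace, (5.0, 6.0))


class TestRegistry:
    def test_nine_definitions_with_unique_references(self):
        reg = default_registry()
        assert set(reg) == {"w48", "f200", "a201", "r206", "m202", "n203", "n68", "h66", "v173"}
        for d in reg.values():
            assert d.reference_state in d.state_labels

    def test_yaml_round_trip(self, tmp_path):
        reg = default_registry()
        path = tmp_path / "registry.yaml"
        registry_to_yaml(reg, path)
        back = registry_from_yaml(path)
        assert set(back) == set(reg)
        for k in reg:
            assert back[k] == reg[k]

    def test_reference_frame_classifies_open_for_all_nine(self):
        s = synthetic_reference_structure()
        for rid, d in default_registry().items():
            v = evaluate_metric_structure(s, d, chain_id="A")
            lab = d.state_labels[d.classify_values(np.array([v]))[0]]
            assert lab == d.reference_state, rid


class TestReferenceFrameDescriptors:
    """The stand-in reference frame realizes the published crystal values."""

    def test_r206_four_point_torsion(self):
        s = synthetic_reference_structure()
        d = default_registry()["r206"]
        assert evaluate_metric_structure(s, d, chain_id="A") == pytest.approx(311.0, abs=1.0)

    def test_w48_chi2_torsion(self):
        s = synthetic_reference_structure()
        d = default_registry()["w48"]
        assert evaluate_metric_structure(s, d, chain_id="A") == pytest.approx(103.0, abs=1.0)

    def test_m202_l21_separation(self):
        s = synthetic_reference_structure()
        d = default_registry()["m202"]
        assert evaluate_metric_structure(s, d, chain_id="A") == pytest.approx(0.82, abs=0.02)

    def test_expected_arginine_atoms_present(self):
        s = synthetic_reference_structure()
        arg = s.select(chain_id="A", residue_numbers=[206])
        assert {"CA", "CB", "CG", "CZ"} <= set(arg["atom_name"])
        assert not s.select(chain_id="A", residue_numbers=[29]).empty
        assert not s.select(chain_id="A", residue_numbers=[48]).empty
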