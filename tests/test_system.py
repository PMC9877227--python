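"""System container, periodic geometry, leaflet assignment, binding detection, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidprint.species import plasma_membrane_registry
from lipidprint.synth import SyntheticConfig, build_bilayer, generate, write_outputs
from lipidprint.system import (
    assign_leaflets,
    detect_binding_leaflet,
    load_system,
    minimal_image_distance,
    write_system,
)

from conftest import lipid_rows, make_system, protein_residue_rows, simple_registry


def brute_force_image_distance(a, b, box):
    """Oracle: minimum distance over all 27 neighbour images."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * np.asarray(box)
                best = min(best, float(np.linalg.norm(np.asarray(b) + shift - np.asarray(a))))
    return best


class TestMinimalImage:
    def test_identity(self):
        assert minimal_image_distance((0, 0, 0), (0, 0, 0), (10, 10, 10)) == 0.0

    def test_wrap_by_symmetry(self):
        d = minimal_image_distance((1, 0, 0), (99, 0, 0), (100, 100, 100))
        assert d == pytest.approx(2.0)

    def test_symmetric(self):
        a, b, box = (3.0, 7.0, 1.0), (9.0, 2.0, 8.0), (10.0, 12.0, 9.0)
        assert minimal_image_distance(a, b, box) == pytest.approx(
            minimal_image_distance(b, a, box))

    def test_matches_27_image_oracle(self):
        rng = np.random.default_rng(42)
        box = np.array([25.0, 40.0, 15.0])
        for _ in range(1000):
            a = rng.uniform(-10, 60, 3)
            b = rng.uniform(-10, 60, 3)
            got = minimal_image_distance(a, b, box)
            # oracle needs in-box points; wrap first
            aw, bw = a % box, b % box
            assert got == pytest.approx(brute_force_image_distance(aw, bw, box),
                                        abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_half_diagonal(self, vals):
        box = np.array([20.0, 30.0, 25.0])
        a, b = np.array(vals[:3]), np.array(vals[3:])
        d = minimal_image_distance(a, b, box)
        assert d <= np.linalg.norm(box / 2) + 1e-9

    def test_non_positive_box_rejected(self):
        with pytest.raises(ValueError):
            minimal_image_distance((0, 0, 0), (1, 1, 1), (10, -5, 10))


class TestLeaflets:
    def test_two_lipid_symmetry(self):
        rows = lipid_rows("DOPC", 1001) + lipid_rows("PIP2", 1002)
        coords = [[10, 10, 50], [10, 10, 10]]
        system = make_system(rows, coords)
        la = assign_leaflets(system, 0)
        assert la.midplane == pytest.approx(30.0)
        assert la.labels == {1001: "upper", 1002: "lower"}

    def test_generator_ground_truth_partition(self, small_build):
        la = assign_leaflets(small_build, 0)
        labs = list(la.labels.values())
        assert labs.count("upper") == 64
        assert labs.count("lower") == 64

    def test_full_scale_600_per_leaflet(self):
        system = build_bilayer(SyntheticConfig(n_frames=1, seed=0))
        la = assign_leaflets(system, 0)
        labs = list(la.labels.values())
        assert labs.count("upper") == 600 and labs.count("lower") == 600

    def test_degenerate_tie_all_upper_with_warning(self):
        rows = lipid_rows("DOPC", 1001) + lipid_rows("DOPC", 1002)
        coords = [[5, 5, 30], [25, 25, 30]]
        system = make_system(rows, coords, registry=simple_registry(DOPC=1.0))
        with pytest.warns(UserWarning):
            la = assign_leaflets(system, 0)
        assert set(la.labels.values()) == {"upper"}

    def test_partition_is_exhaustive_every_frame(self, recruitment_run):
        _, system, _ = recruitment_run
        n_lipids = len(system.marker_index_by_resid)
        for f in (0, 50, 199):
            la = assign_leaflets(system, f)
            assert len(la.labels) == n_lipids


class TestBindingDetection:
    def test_distant_protein_gives_none(self):
        rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001) + lipid_rows("PIP2", 1002)
        coords = [[10, 10, 150], [10, 10, 40], [10, 10, 20]]
        system = make_system(rows, coords, box=(300, 300, 300))
        assert detect_binding_leaflet(system) is None

    def test_zero_cutoff_gives_none(self, small_build):
        assert detect_binding_leaflet(small_build, cutoff=0.0) is None

    def test_descending_protein_matches_ground_truth(self, recruitment_run):
        _, system, truth = recruitment_run
        ev = detect_binding_leaflet(system)
        assert ev is not None
        assert ev.leaflet == truth["binding_leaflet"] == "upper"
        assert ev.frame == truth["first_contact_frame"]

    def test_empty_window_rejected(self, small_build):
        with pytest.raises(ValueError):
            detect_binding_leaflet(small_build, window=(0, 0))


class TestIO:
    def test_round_trip_counts_and_coordinates(self, tmp_path):
        cfg = SyntheticConfig.test_scale(n_frames=5, binding_frame=2, seed=3)
        system, truth = generate(cfg)
        paths = write_outputs(system, truth, tmp_path,
                              structure_formats=("pdb",),
                              trajectory_formats=("xtc",))
        re = load_system(paths["structure_pdb"], paths["trajectory_xtc"],
                         paths["species"], radii="occupancy")
        assert re.n_atoms == system.n_atoms
        assert re.n_frames == system.n_frames
        assert np.allclose(re.coords, system.coords, atol=5e-3)  # XTC float32
        # species census survives the round trip
        for sp in system.registry.names:
            assert (re.lipid_species_by_resid == sp).sum() == \
                (system.lipid_species_by_resid == sp).sum()

    def test_construction_echo_small_membrane(self, tmp_path):
        rows, coords = [], []
        for i in range(10):
            rows += lipid_rows("DOPC", 1001 + i)
            coords.append([3.0 * i + 1, 5.0, 40.0 if i % 2 else 20.0])
        for i in range(2):
            rows += lipid_rows("PIP2", 1011 + i)
            coords.append([3.0 * i + 2, 10.0, 40.0 if i % 2 else 20.0])
        system = make_system(rows, coords)
        write_system(system, tmp_path / "s.pdb")
        re = load_system(tmp_path / "s.pdb", None, simple_registry())
        assert len(re.marker_index_by_resid) == 12
        assert set(re.lipid_species_by_resid.unique()) == {"DOPC", "PIP2"}

    def test_unclassifiable_residue_listed(self, tmp_path):
        rows = lipid_rows("DOPC", 1001) + lipid_rows("XXX", 1002)
        system = make_system(rows, [[1, 1, 1], [2, 2, 2]],
                             registry=simple_registry(DOPC=0.5, XXX=0.5))
        write_system(system, tmp_path / "bad.pdb")
        with pytest.raises(ValueError, match="XXX"):
            load_system(tmp_path / "bad.pdb", None, simple_registry(DOPC=1.0))

    def test_atom_count_mismatch(self, tmp_path):
        cfg = SyntheticConfig.test_scale(n_frames=3, seed=1)
        small, truth = generate(cfg)
        write_outputs(small, truth, tmp_path / "a")
        cfg2 = SyntheticConfig.test_scale(n_frames=3, seed=1, lipids_per_leaflet=32,
                                          box_xy=40.0)
        other, truth2 = generate(cfg2)
        write_outputs(other, truth2, tmp_path / "b")
        with pytest.raises(Exception, match="(?i)atom|mismatch|number"):
            load_system(tmp_path / "a" / "structure.pdb",
                        tmp_path / "b" / "trajectory.xtc",
                        tmp_path / "a" / "species.yaml")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_system(tmp_path / "nope.pdb", None, plasma_membrane_registry())
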