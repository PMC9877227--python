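"""Contacts, COM distances, insertion depth, RMSD/RMSF."""

import numpy as np
import pytest

from lipidprint.binding import (
    domain_com_distance,
    domain_species_contacts,
    insertion_depth,
    residue_contact_frequency,
    rmsd_series,
    rmsf,
)
from lipidprint.system import pair_distances

from conftest import lipid_rows, make_system, protein_residue_rows, simple_registry


def _contact_fixture():
    """One residue whose Cα-marker distance is 11.9, 12.1, 5.0 over 3 frames."""
    rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001)
    coords = [
        [[10, 10, 20 + d], [10, 10, 20]] for d in (11.9, 12.1, 5.0)
    ]
    return make_system(rows, coords, box=(100, 100, 100),
                       registry=simple_registry(DOPC=1.0))


class TestContactFrequency:
    def test_hand_counted_two_of_three_frames(self):
        table = residue_contact_frequency(_contact_fixture()).per_residue
        assert table.pct_time.iloc[0] == pytest.approx(100 * 2 / 3)

    def test_cutoff_is_closed_interval(self):
        rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001)
        coords = [[[10, 10, 32.0], [10, 10, 20]]]
        system = make_system(rows, coords, registry=simple_registry(DOPC=1.0))
        table = residue_contact_frequency(system).per_residue
        assert table.pct_time.iloc[0] == 100.0  # exactly 12.0 counts

    def test_distant_protein_all_zero(self):
        rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001)
        coords = [[[10, 10, 150], [10, 10, 20]]]
        system = make_system(rows, coords, box=(400, 400, 400),
                             registry=simple_registry(DOPC=1.0))
        assert residue_contact_frequency(system).per_residue.pct_time.iloc[0] == 0.0

    def test_permanent_contact_saturates(self):
        rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001)
        coords = [[[10, 10, 25], [10, 10, 20]]] * 4
        system = make_system(rows, np.concatenate(coords).reshape(4, 2, 3),
                             registry=simple_registry(DOPC=1.0))
        assert residue_contact_frequency(system).per_residue.pct_time.iloc[0] == 100.0

    def test_invariant_under_rigid_translation(self, recruitment_run):
        _, system, _ = recruitment_run
        t1 = residue_contact_frequency(system, (150, 180)).per_residue
        shifted = make_system(
            list(system.atoms[["name", "resname", "resid", "segment",
                               "element"]].itertuples(index=False, name=None)),
            (system.coords[150:180] + np.array([13.0, -7.0, 0.0])) % system.boxes[0],
            box=tuple(system.boxes[0]), registry=system.registry,
        )
        shifted.domains = dict(system.domains)
        t2 = residue_contact_frequency(shifted).per_residue
        assert np.allclose(t1.pct_time.to_numpy(), t2.pct_time.to_numpy())


class TestDomainContacts:
    def test_three_markers_at_five_angstroms(self):
        rows = protein_residue_rows(1)
        coords = [[10.0, 10.0, 25.0]]
        for i, off in enumerate([(5.0, 0.0), (0.0, 5.0), (-5.0, 0.0)]):
            rows += lipid_rows("DOPC", 1001 + i)
            coords.append([10.0 + off[0], 10.0 + off[1], 25.0])
        rows += lipid_rows("DOPC", 1004)  # lower leaflet, far away
        coords.append([40.0, 40.0, 5.0])
        system = make_system(rows, coords, registry=simple_registry(DOPC=1.0),
                             domains={"4HB": (1, 10)})
        table = domain_species_contacts(system).per_domain_species
        dopc = table[(table.domain == "4HB") & (table.species == "DOPC")]
        assert dopc.mean_count.iloc[0] == pytest.approx(3.0)

    def test_absent_species_column_is_zero(self, small_build):
        table = domain_species_contacts(small_build).per_domain_species
        # species present in registry but absent in the box would read zero;
        # here check the weaker conservation property against the pooled scan
        total = table.mean_count.sum()
        heavy = small_build.protein_heavy_indices
        markers = small_build.marker_index_by_resid.to_numpy()
        z = small_build.coords[0, markers, 2]
        m = markers[z >= z.mean()]
        D = pair_distances(small_build.coords[0, heavy],
                           small_build.coords[0, m], small_build.boxes[0])
        assert total == pytest.approx((D <= 12.0).sum())

    def test_brute_force_oracle_small_system(self):
        rng = np.random.default_rng(5)
        rows = []
        coords = []
        for r in range(1, 6):
            rows += protein_residue_rows(r)
            coords.append(rng.uniform(5, 55, 3))
        for i in range(40):
            rows += lipid_rows("DOPC" if i % 2 else "PIP2", 1001 + i)
            coords.append(rng.uniform(5, 55, 3))
        system = make_system(rows, coords, registry=simple_registry(),
                             domains={"4HB": (1, 5)})
        table = domain_species_contacts(system, cutoff=20.0).per_domain_species
        markers = system.marker_index_by_resid.to_numpy()
        z = system.coords[0, markers, 2]
        upper = markers[z >= z.mean()]
        sp = system.lipid_species_by_resid
        heavy = system.protein_heavy_indices
        for species in ("DOPC", "PIP2"):
            expected = 0
            for h in heavy:
                for m in upper:
                    resid = int(system.atoms.resid[m])
                    if sp.loc[resid] != species:
                        continue
                    from lipidprint.system import minimal_image_distance
                    d = minimal_image_distance(system.coords[0, h],
                                               system.coords[0, m],
                                               system.boxes[0])
                    if d <= 20.0:
                        expected += 1
            got = table[(table.domain == "4HB") & (table.species == species)]
            assert got.mean_count.iloc[0] == pytest.approx(expected)


class TestComDistance:
    def test_flat_construction(self):
        rows = protein_residue_rows(1) + protein_residue_rows(2) + \
            lipid_rows("DOPC", 1001) + lipid_rows("DOPC", 1002)
        coords = [[5, 5, 50], [15, 15, 50], [10, 10, 20], [20, 20, 20]]
        system = make_system(np.array(rows, dtype=object), coords,
                             registry=simple_registry(DOPC=1.0),
                             domains={"4HB": (1, 2)})
        series = domain_com_distance(system, "4HB")
        assert series == pytest.approx([30.0])

    def test_descent_is_monotone_until_binding(self, recruitment_run):
        cfg, system, truth = recruitment_run
        series = domain_com_distance(system, "4HB", (0, cfg.binding_frame + 1))
        assert np.all(np.diff(series) <= 1e-9)

    def test_single_frame_window(self, recruitment_run):
        _, system, _ = recruitment_run
        assert len(domain_com_distance(system, "4HB", (0, 1))) == 1

    def test_unknown_domain(self, recruitment_run):
        _, system, _ = recruitment_run
        with pytest.raises(KeyError):
            domain_com_distance(system, "nope")


class TestInsertionDepth:
    def test_depth_sign_convention(self):
        # Cα 3 Å below the upper marker plane -> +3
        rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001) + \
            lipid_rows("DOPC", 1002)
        coords = [[10, 10, 37], [10, 10, 40], [20, 20, 40]]
        system = make_system(rows, coords, registry=simple_registry(DOPC=1.0))
        profile = insertion_depth(system)
        assert profile.depths.loc[1] == pytest.approx(3.0)

    def test_all_above_plane_deepest_least_negative(self):
        rows = protein_residue_rows(1) + protein_residue_rows(2) + \
            lipid_rows("DOPC", 1001) + lipid_rows("DOPC", 1002)
        coords = [[10, 10, 45], [20, 20, 50], [10, 10, 40], [20, 20, 40]]
        system = make_system(rows, coords, registry=simple_registry(DOPC=1.0),
                             domains={"4HB": (1, 2)})
        profile = insertion_depth(system)
        assert (profile.depths < 0).all()
        assert profile.deepest_resid == 1

    def test_generator_planted_deepest_residue(self, recruitment_run):
        _, system, truth = recruitment_run
        profile = insertion_depth(system, (150, 200))
        assert profile.deepest_resid == truth["deepest_resid"]

    def test_no_contact_raises(self):
        rows = protein_residue_rows(1) + lipid_rows("DOPC", 1001) + \
            lipid_rows("DOPC", 1002)
        coords = [[10, 10, 190], [10, 10, 40], [20, 20, 40]]
        system = make_system(rows, coords, box=(400, 400, 400),
                             registry=simple_registry(DOPC=1.0))
        with pytest.raises(ValueError):
            insertion_depth(system)


class TestRmsd:
    def test_static_trajectory_zero(self, recruitment_run):
        _, system, _ = recruitment_run
        static = make_system(
            list(system.atoms[["name", "resname", "resid", "segment",
                               "element"]].itertuples(index=False, name=None)),
            np.repeat(system.coords[:1], 5, axis=0), box=tuple(system.boxes[0]),
            registry=system.registry)
        assert np.allclose(rmsd_series(static), 0.0, atol=1e-12)
        assert np.allclose(rmsf(static).to_numpy(), 0.0, atol=1e-12)

    def test_rigid_translation_removed(self, small_build):
        base = small_build.coords[0]
        coords = np.stack([base, base + np.array([10.0, 0.0, 0.0])])
        system = make_system(
            list(small_build.atoms[["name", "resname", "resid", "segment",
                                    "element"]].itertuples(index=False, name=None)),
            coords, box=tuple(small_build.boxes[0]), registry=small_build.registry)
        assert rmsd_series(system)[1] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_removed(self, small_build):
        base = small_build.coords[0]
        theta = 0.4
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        coords = np.stack([base, base @ R.T + 3.0])
        system = make_system(
            list(small_build.atoms[["name", "resname", "resid", "segment",
                                    "element"]].itertuples(index=False, name=None)),
            coords, box=tuple(small_build.boxes[0]), registry=small_build.registry)
        assert rmsd_series(system)[1] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_mdanalysis_superposition(self, small_build):
        from MDAnalysis.analysis import rms as mda_rms

        rng = np.random.default_rng(8)
        base = small_build.coords[0]
        moved = base + rng.normal(0, 0.8, base.shape)
        system = make_system(
            list(small_build.atoms[["name", "resname", "resid", "segment",
                                    "element"]].itertuples(index=False, name=None)),
            np.stack([base, moved]), box=tuple(small_build.boxes[0]),
            registry=small_build.registry)
        got = rmsd_series(system)[1]
        ca = system.protein_ca_indices
        expected = mda_rms.rmsd(moved[ca], base[ca], superposition=True)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_two_frame_single_displacement_rmsf(self):
        # one atom displaced by d after superposition of many others -> d/2
        rng = np.random.default_rng(3)
        n = 200
        rows = []
        for r in range(1, n + 1):
            rows += protein_residue_rows(r)
        rows += lipid_rows("DOPC", 2001) + lipid_rows("DOPC", 2002)
        base = np.vstack([rng.uniform(10, 90, (n, 3)),
                          [[10, 10, 5], [20, 20, 5]]])
        second = base.copy()
        d = 2.0
        second[0, 2] += d
        system = make_system(rows, np.stack([base, second]), box=(100, 100, 100),
                             registry=simple_registry(DOPC=1.0),
                             domains={"4HB": (1, n)})
        fl = rmsf(system)
        assert fl.loc[1] == pytest.approx(d / 2, rel=0.05)
        assert fl.drop(1).max() < 0.2
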