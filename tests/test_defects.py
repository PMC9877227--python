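"""Packing-defect classification, labeling vs flood-fill oracle, planted patches."""

import numpy as np
import pytest

from lipidprint.defects import (
    HYDROPHILIC,
    HYDROPHOBIC,
    ClassifiedGrid,
    classify_surface,
    defect_stats,
    find_defects,
    local_defect_percent,
    _periodic_label,
)
from lipidprint.maps import ProteinMask
from lipidprint.synth import SyntheticConfig, build_bilayer, plant_defect_patch


def flood_fill_oracle(mask, connectivity=8):
    """Independent BFS labeling with periodic 8/4-connectivity."""
    nx, ny = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        neigh = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for i in range(nx):
        for j in range(ny):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            cells = []
            while stack:
                ci, cj = stack.pop()
                cells.append((ci, cj))
                for di, dj in neigh:
                    ni, nj = (ci + di) % nx, (cj + dj) % ny
                    if mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            comps.append(frozenset(cells))
    return set(comps)


def _grid_from_mask(mask, cell=1.0):
    labels = np.where(mask, HYDROPHOBIC, HYDROPHILIC).astype(np.int32)
    return ClassifiedGrid(labels=labels, cell_size=cell, leaflet="upper",
                          frame=0, box_xy=np.array(mask.shape, float) * cell)


class TestLabeling:
    def test_all_hydrophilic_no_defects(self):
        grid = _grid_from_mask(np.zeros((40, 40), bool))
        assert find_defects(grid) == []

    def test_square_patch_area(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 7:17] = True
        comps = find_defects(_grid_from_mask(mask))
        assert len(comps) == 1
        assert comps[0].area == pytest.approx(100.0)

    def test_patch_straddling_boundary_is_single_component(self):
        mask = np.zeros((40, 40), bool)
        mask[36:, 10:20] = True
        mask[:4, 10:20] = True
        comps = find_defects(_grid_from_mask(mask))
        assert len(comps) == 1
        assert comps[0].area == pytest.approx(80.0)

    def test_corner_wrap_diagonal_connectivity(self):
        mask = np.zeros((20, 20), bool)
        mask[19, 19] = True
        mask[0, 0] = True  # diagonal neighbours across both seams
        comps = find_defects(_grid_from_mask(mask), min_area=0.0)
        assert len(comps) == 1

    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(77)
        for density in (0.15, 0.4, 0.6):
            for _ in range(5):
                mask = rng.random((48, 48)) < density
                lab = _periodic_label(mask)
                got = set()
                for v in np.unique(lab):
                    if v == 0:
                        continue
                    got.add(frozenset(map(tuple, np.argwhere(lab == v))))
                assert got == flood_fill_oracle(mask)

    def test_min_area_monotonicity(self):
        rng = np.random.default_rng(3)
        mask = rng.random((50, 50)) < 0.3
        grid = _grid_from_mask(mask)
        small = find_defects(grid, min_area=5.0)
        big = find_defects(grid, min_area=10.0)
        assert len(big) <= len(small)
        assert sum(c.area for c in big) <= sum(c.area for c in small)

    def test_component_bookkeeping_identity(self):
        rng = np.random.default_rng(4)
        mask = rng.random((30, 30)) < 0.25
        comps = find_defects(_grid_from_mask(mask), min_area=0.0)
        assert sum(c.area for c in comps) == pytest.approx(mask.sum() * 1.0)


class TestClassification:
    def test_intact_bilayer_fully_hydrophilic(self, small_build):
        for leaflet in ("upper", "lower"):
            grid = classify_surface(small_build, 0, leaflet)
            frac_philic = (grid.labels == HYDROPHILIC).mean()
            assert frac_philic >= 0.95
            assert (grid.labels == HYDROPHOBIC).sum() == 0

    def test_planted_patch_cells_confined(self, small_build):
        patched = plant_defect_patch(small_build, 0, (20.0, 20.0), 5.64, "upper")
        grid = classify_surface(patched, 0, "upper")
        cells = np.argwhere(grid.labels == HYDROPHOBIC)
        centers = (cells + 0.5) * grid.cell_size
        d = np.linalg.norm(centers - np.array([20.0, 20.0]), axis=1)
        assert d.max() <= 5.64 + 1.5  # patch radius + grid slack

    def test_empty_leaflet_rejected(self, small_build):
        one_sided = plant_defect_patch(small_build, 0, (1, 1), 0.1, "upper")
        # build a degenerate single-leaflet view by filtering is complex;
        # instead verify the error path via a z-collapsed copy
        sys2 = one_sided
        sys2.coords[0, :, 2] = 200.0
        with pytest.raises(ValueError):
            classify_surface(sys2, 0, "lower")


class TestPlantedPatches:
    @pytest.mark.parametrize("center", [(20.0, 20.0), (0.5, 0.5), (33.0, 44.0)])
    @pytest.mark.parametrize("leaflet", ["upper", "lower"])
    def test_patch_area_recovered_within_ten_percent(self, center, leaflet):
        system = build_bilayer(SyntheticConfig.test_scale(n_frames=1, seed=6))
        patched = plant_defect_patch(system, 0, center, 5.64, leaflet)
        comps = find_defects(classify_surface(patched, 0, leaflet))
        assert len(comps) == 1
        assert comps[0].area == pytest.approx(100.0, rel=0.10)

    def test_two_disjoint_patches_two_components(self, small_build):
        p = plant_defect_patch(small_build, 0, (14.0, 14.0), 5.64, "upper")
        p = plant_defect_patch(p, 0, (42.0, 42.0), 5.64, "upper")
        comps = find_defects(classify_surface(p, 0, "upper"))
        assert len(comps) == 2

    def test_halving_cell_size_stable_area(self, small_build):
        patched = plant_defect_patch(small_build, 0, (25.0, 25.0), 5.64, "upper")
        a1 = find_defects(classify_surface(patched, 0, "upper", 1.0))[0].area
        a05 = find_defects(classify_surface(patched, 0, "upper", 0.5))[0].area
        assert abs(a05 - a1) / a1 < 0.10

    def test_zero_radius_rejected(self, small_build):
        with pytest.raises(ValueError):
            plant_defect_patch(small_build, 0, (10, 10), 0.0, "upper")


class TestLocalPercent:
    def _mask(self, nx=56, ny=56):
        m = np.zeros((nx, ny), bool)
        m[10:30, 10:30] = True  # 400 Å² at 1 Å cells
        return ProteinMask(mask=m, cell_size=1.0,
                           box_xy=np.array([float(nx), float(ny)]), window=(0, 1))

    def test_quarter_coverage_exact(self):
        mask = self._mask()
        defect = np.zeros((56, 56), bool)
        defect[15:25, 15:25] = True  # 100 Å² fully inside
        comps = find_defects(_grid_from_mask(defect))
        assert local_defect_percent(comps, mask) == pytest.approx(25.0)

    def test_no_defects_zero(self):
        assert local_defect_percent([], self._mask()) == 0.0

    def test_defect_outside_mask_zero(self):
        defect = np.zeros((56, 56), bool)
        defect[40:50, 40:50] = True
        comps = find_defects(_grid_from_mask(defect))
        assert local_defect_percent(comps, self._mask()) == 0.0
        assert comps[0].local is False


class TestStats:
    def test_static_frames_zero_se(self, small_build):
        patched = plant_defect_patch(small_build, 0, (20.0, 20.0), 5.64, "upper")
        coords = np.repeat(patched.coords, 10, axis=0)
        from conftest import make_system
        system = make_system(
            list(patched.atoms[["name", "resname", "resid", "segment",
                                "element"]].itertuples(index=False, name=None)),
            coords, box=tuple(patched.boxes[0]), registry=patched.registry)
        system.atoms["radius"] = patched.atoms.radius.to_numpy()
        stats = defect_stats(system, leaflets=("upper",))
        row = stats.per_leaflet.iloc[0]
        assert row.count_se == 0.0 and row.area_se == 0.0
        single = find_defects(classify_surface(system, 0, "upper"))
        assert row.mean_area == pytest.approx(sum(c.area for c in single))

    def test_upper_only_patches_asymmetric(self, small_build):
        patched = plant_defect_patch(small_build, 0, (30.0, 30.0), 5.64, "upper")
        stats = defect_stats(patched, leaflets=("upper", "lower"))
        by = stats.per_leaflet.set_index("leaflet")
        assert by.loc["upper", "mean_area"] > 50.0
        assert by.loc["lower", "mean_area"] < 10.0
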