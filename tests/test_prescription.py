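import numpy as np
import pytest

from vineweed import CLASS_CODES, ConfigurationError, GeoTransform
from vineweed.prescription import (PrescriptionConfig, apply_thresholds,
                                   build_grid, compute_coverage,
                                   estimate_row_azimuth, herbicide_saving,
                                   savings_report)
from vineweed.segmentation import ClassifiedMap
from vineweed.vine import detect_vines

SOIL = CLASS_CODES["bare_soil"]
WEED = CLASS_CODES["bermudagrass"]
VINE = CLASS_CODES["vine"]


def make_map(labels, pixel_size=0.05):
    t = GeoTransform.north_up(0.0, labels.shape[0] * pixel_size, pixel_size)
    return ClassifiedMap(labels=labels.astype(np.uint8), area_summary={},
                         threshold_used=0.0, index_name="ExGR", transform=t)


def soil_map(n=200, pixel_size=0.05):
    return make_map(np.full((n, n), SOIL), pixel_size)


def test_grid_tiling_arithmetic():
    # 10 x 10 m all inter-row, 1 x 0.5 m cells, rows east-west -> 10*20 cells
    cmap = soil_map()
    grid = build_grid(cmap, PrescriptionConfig(row_azimuth=90.0))
    assert grid.n_cells == 200
    areas = {round(c.polygon.area, 6) for c in grid.cells}
    assert areas == {0.5}


def test_rotated_rows_rotate_cell_polygons():
    cmap = soil_map()
    grid = build_grid(cmap, PrescriptionConfig(row_azimuth=30.0))
    cell = grid.cells[0]
    xs, ys = cell.polygon.exterior.xy
    # the long (1 m) edge must run along azimuth 30 degrees
    edges = [(xs[i + 1] - xs[i], ys[i + 1] - ys[i]) for i in range(4)]
    long_edge = max(edges, key=lambda e: np.hypot(*e))
    az = np.degrees(np.arctan2(long_edge[0], long_edge[1])) % 180
    assert az == pytest.approx(30.0, abs=1e-6)


def test_auto_azimuth_recovers_east_west_rows(small_scene):
    scene, labels, _ = small_scene
    vm = detect_vines(scene)
    lab = np.where(vm.mask, VINE, SOIL)
    cmap = ClassifiedMap(labels=lab.astype(np.uint8), area_summary={},
                         threshold_used=0.0, index_name="ExGR",
                         transform=scene.transform)
    az = estimate_row_azimuth(cmap)
    assert az == pytest.approx(90.0, abs=1.0)


def test_auto_azimuth_without_vines_demands_explicit():
    with pytest.raises(ConfigurationError, match="azimuth"):
        build_grid(soil_map(), PrescriptionConfig(row_azimuth="auto"))


def test_coverage_zero_half_and_conservation():
    lab = np.full((40, 40), SOIL)  # 2 x 2 m at 5 cm -> 2x4 grid of 1 x 0.5 cells
    lab[:10, :20] = WEED  # top-left quarter of the top-left 1x0.5m... cell rows
    cmap = make_map(lab)
    grid = build_grid(cmap, PrescriptionConfig(row_azimuth=90.0))
    grid = compute_coverage(grid, cmap)
    total_weed = sum(c.weed_px for c in grid.cells)
    assert total_weed == (lab == WEED).sum()
    covs = sorted({round(c.coverage_pct, 6) for c in grid.cells})
    assert covs[0] == 0.0
    # conservation: coverage-weighted not-vine area equals weed area
    recon = sum(c.coverage_pct / 100 * c.not_vine_px for c in grid.cells)
    assert recon == pytest.approx((lab == WEED).sum())


def test_half_weed_cell_is_fifty_percent():
    lab = np.full((10, 20), SOIL)  # exactly one 1 x 0.5 m cell at 5 cm px
    lab[:5, :] = WEED
    cmap = make_map(lab)
    grid = build_grid(cmap, PrescriptionConfig(row_azimuth=90.0))
    grid = compute_coverage(grid, cmap)
    assert grid.n_cells == 1
    assert grid.cells[0].coverage_pct == pytest.approx(50.0)


def test_vine_excluded_from_coverage_denominator():
    lab = np.full((10, 20), SOIL)
    lab[:5, :] = VINE
    lab[5:8, :] = WEED  # 3 of 5 not-vine rows
    cmap = make_map(lab)
    grid = compute_coverage(build_grid(cmap, PrescriptionConfig(row_azimuth=90.0)), cmap)
    assert grid.cells[0].coverage_pct == pytest.approx(60.0)
    cfg = PrescriptionConfig(row_azimuth=90.0, use_full_cell_area=True)
    grid2 = compute_coverage(build_grid(cmap, cfg), cmap)
    assert grid2.cells[0].coverage_pct == pytest.approx(30.0)


@pytest.mark.parametrize("coverage,expected", [
    (0.0, {0.0: False, 2.5: False, 5.0: False}),
    (3.0, {0.0: True, 2.5: True, 5.0: False}),
    (5.0, {0.0: True, 2.5: True, 5.0: True}),  # boundary: equal or higher
    (0.5, {0.0: True, 2.5: False, 5.0: False}),
])
def test_threshold_semantics(coverage, expected):
    lab = np.full((10, 20), SOIL)
    nweed = int(round(coverage / 100 * lab.size))
    lab.ravel()[:nweed] = WEED
    cmap = make_map(lab)
    grid = compute_coverage(build_grid(cmap, PrescriptionConfig(row_azimuth=90.0)), cmap)
    grid = apply_thresholds(grid)
    assert grid.cells[0].coverage_pct == pytest.approx(coverage)
    assert grid.cells[0].treat == expected


def test_savings_all_weed_free_is_hundred():
    cmap = soil_map(40)
    grid = apply_thresholds(compute_coverage(
        build_grid(cmap, PrescriptionConfig(row_azimuth=90.0)), cmap))
    for t in (0.0, 2.5, 5.0):
        assert herbicide_saving(grid, t) == 100.0


def test_savings_area_ratio_and_conservation():
    # 10 equal cells in a row; 4 infested -> savings 60%
    lab = np.full((10, 200), SOIL)  # 0.5 x 10 m at 5 cm: 10 cells of 1 x 0.5
    for k in range(4):
        lab[:, k * 20: k * 20 + 10] = WEED
    cmap = make_map(lab)
    grid = apply_thresholds(compute_coverage(
        build_grid(cmap, PrescriptionConfig(row_azimuth=90.0)), cmap))
    assert grid.n_cells == 10
    assert herbicide_saving(grid, 0.0) == pytest.approx(60.0)
    treated = sum(c.not_vine_px for c in grid.cells if c.treat[0.0])
    untreated = sum(c.not_vine_px for c in grid.cells if not c.treat[0.0])
    assert treated + untreated == sum(c.not_vine_px for c in grid.cells)


def test_savings_monotone_in_threshold(small_scene):
    scene, labels, _ = small_scene
    cmap = ClassifiedMap(labels=labels.labels, area_summary={}, threshold_used=0.0,
                         index_name="ExGR", transform=scene.transform)
    grid = apply_thresholds(compute_coverage(
        build_grid(cmap, PrescriptionConfig()), cmap))
    s = [herbicide_saving(grid, t) for t in (0.0, 2.5, 5.0)]
    assert s[0] <= s[1] <= s[2]
    # treat flags are monotone per cell
    for c in grid.cells:
        assert not (c.treat[2.5] and not c.treat[0.0])
        assert not (c.treat[5.0] and not c.treat[2.5])


def test_savings_at_zero_matches_direct_enumeration(small_scene):
    scene, labels, _ = small_scene
    cmap = ClassifiedMap(labels=labels.labels, area_summary={}, threshold_used=0.0,
                         index_name="ExGR", transform=scene.transform)
    grid = apply_thresholds(compute_coverage(
        build_grid(cmap, PrescriptionConfig()), cmap))
    total = sum(c.not_vine_px for c in grid.cells)
    infested = sum(c.not_vine_px for c in grid.cells if c.weed_px > 0)
    assert herbicide_saving(grid, 0.0) == pytest.approx(100 * (1 - infested / total))


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        PrescriptionConfig(cell_size=(0, 0.5))
    with pytest.raises(ConfigurationError):
        PrescriptionConfig(thresholds=(5, 2.5))


def test_savings_report_has_both_denominators(small_scene):
    scene, labels, _ = small_scene
    cmap = ClassifiedMap(labels=labels.labels, area_summary={}, threshold_used=0.0,
                         index_name="ExGR", transform=scene.transform)
    grid = apply_thresholds(compute_coverage(
        build_grid(cmap, PrescriptionConfig()), cmap))
    rep = savings_report(grid)
    assert set(rep["savings_pct_inter_row"]) == {"0.0", "2.5", "5.0"}
    assert set(rep["savings_pct_full_cell"]) == {"0.0", "2.5", "5.0"}
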