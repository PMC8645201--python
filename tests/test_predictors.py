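import itertools
import math

import numpy as np
import pytest

from introlens import (
    ClimateGrid,
    DResult,
    GriddedRange,
    Triad,
    assemble_predictor_table,
    climate_velocity,
    haversine,
    parse_tree,
    range_distance,
    range_summary,
    triad_times,
)
from introlens.predictors import (
    LGM_YEARS,
    MIN_GRADIENT,
    mean_velocity_over_ranges,
    read_esri_ascii,
    write_esri_ascii,
)
from introlens.trees import TreeValidationError


def grange(species, cells):
    """cells: dict cell_id -> (lat, lon); equal-area 100 km^2 cells."""
    return GriddedRange(species, frozenset(cells), dict(cells), cell_area=100.0)


class TestHaversine:
    def test_identical_points(self):
        assert haversine((12.0, -70.0), (12.0, -70.0)) == 0.0

    def test_half_circumference(self):
        assert haversine((0, 0), (0, 180)) == pytest.approx(math.pi * 6371, rel=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            b = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            assert haversine(a, b) == pytest.approx(haversine(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine((95, 0), (0, 0))


class TestRangeGeometry:
    def test_shared_cell_means_sympatry(self):
        r1 = grange("a", {"x": (0, 0), "y": (0, 1)})
        r2 = grange("b", {"y": (0, 1), "z": (0, 2)})
        assert range_distance(r1, r2) == 0.0

    def test_single_cell_ranges_reduce_to_haversine(self):
        r1 = grange("a", {"x": (5, -60)})
        r2 = grange("b", {"y": (7, -58)})
        assert range_distance(r1, r2) == pytest.approx(haversine((5, -60), (7, -58)))

    def test_matches_bruteforce_minimum(self):
        rng = np.random.default_rng(2)
        cells1 = {f"a{i}": (rng.uniform(-20, 0), rng.uniform(-70, -60)) for i in range(8)}
        cells2 = {f"b{i}": (rng.uniform(5, 25), rng.uniform(-55, -45)) for i in range(6)}
        r1, r2 = grange("a", cells1), grange("b", cells2)
        brute = min(
            haversine(p, q)
            for p, q in itertools.product(cells1.values(), cells2.values())
        )
        assert range_distance(r1, r2) == pytest.approx(brute)

    def test_identical_single_cell_overlap(self):
        r1 = grange("a", {"x": (0, 0)})
        r2 = grange("b", {"x": (0, 0)})
        size, overlap, lat = range_summary(r1, r2)
        assert overlap == pytest.approx(100.0)
        assert range_distance(r1, r2) == 0.0

    def test_mean_absolute_latitude(self):
        r1 = grange("a", {"x": (10, 0)})
        r2 = grange("b", {"y": (-30, 0)})
        _, overlap, lat = range_summary(r1, r2)
        assert lat == pytest.approx(20.0)
        assert overlap == 0.0

    def test_mean_range_size(self):
        r1 = grange("a", {"x": (0, 0), "y": (0, 1)})
        r2 = grange("b", {"z": (5, 5)})
        size, _, _ = range_summary(r1, r2)
        assert size == pytest.approx((200.0 + 100.0) / 2)


def make_grid(tp, tl, spacing=10.0):
    tp, tl = np.asarray(tp, float), np.asarray(tl, float)
    ids = np.array(
        [[f"c{i}_{j}" for j in range(tp.shape[1])] for i in range(tp.shape[0])],
        dtype=object,
    )
    return ClimateGrid(tp, tl, ids, spacing)


class TestClimateVelocity:
    def test_hand_ratio(self):
        # gradient 0.005 degC/km in one direction, warming 2.1 degC since LGM
        spacing = 10.0
        cols = np.arange(5) * spacing * 0.005
        tp = np.tile(cols, (5, 1))
        tl = tp - 2.1
        vel, capped = climate_velocity(make_grid(tp, tl, spacing))
        assert not capped
        assert vel["c2_2"] == pytest.approx((2.1 / LGM_YEARS) / 0.005)
        assert vel["c2_2"] == pytest.approx(0.02)

    def test_uniform_field_capped(self):
        tp = np.full((3, 3), 20.0)
        vel, capped = climate_velocity(make_grid(tp, tp - 1.0))
        assert capped == set(vel)
        assert vel["c1_1"] == pytest.approx((1.0 / LGM_YEARS) / MIN_GRADIENT)

    def test_no_change_zero_velocity(self):
        cols = np.arange(4) * 0.3
        tp = np.tile(cols, (4, 1))
        vel, _ = climate_velocity(make_grid(tp, tp.copy()))
        assert all(v == 0.0 for v in vel.values())

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(1)
        tp = rng.normal(20, 2, (5, 5))
        tl = tp - rng.normal(3, 0.5, (5, 5))
        v1, _ = climate_velocity(make_grid(tp, tl))
        v2, _ = climate_velocity(make_grid(tp + 7.0, tl + 7.0))
        for c in v1:
            assert v2[c] == pytest.approx(v1[c])

    def test_missing_epoch_cell_skipped(self):
        tp = np.tile(np.arange(3) * 0.5, (3, 1))
        tl = tp - 1
        tl[0, 0] = np.nan
        vel, _ = climate_velocity(make_grid(tp, tl))
        assert "c0_0" not in vel

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            climate_velocity(make_grid(np.zeros((2, 2)), np.zeros((2, 2))))


class TestTriadTimes:
    def test_divergence_and_internode(self):
        tree = parse_tree("(((A:1,B:1):2,C:3):1,D:4);")
        triad = Triad("T1", "A", "B", "C", "D", 3.0, 1.0)
        divergence, internode = triad_times(tree, triad)
        assert divergence == pytest.approx(3.0)
        assert internode == pytest.approx(2.0)

    def test_missing_species_error(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="X"):
            triad_times(tree, Triad("T1", "A", "B", "X", None))

    def test_undated_tree_rejected(self):
        tree = parse_tree("(((A:1,B:2):2,C:3):1,D:4);")
        with pytest.raises(TreeValidationError):
            triad_times(tree, Triad("T1", "A", "B", "C", "D"))


def small_study():
    tree = parse_tree("(((A:1,B:1):2,C:3):1,D:4);")
    triads = [Triad("T1", "A", "B", "C", "D", 3.0, 1.0)]
    ranges = {
        "A": grange("A", {"x": (5, -60), "y": (5, -59)}),
        "B": grange("B", {"y": (5, -59), "z": (5, -58)}),
    }
    velocity = {"x": 0.02, "y": 0.04, "z": 0.06}
    discordance = {"T1": 0.35}
    return tree, triads, ranges, velocity, discordance


def dresult(z, p):
    return DResult("T1", d=0.2, sd_boot=0.05, z=z, p=p, n_sites_used=250,
                   n_loci_used=100, subsample_size=250, seed=1)


class TestAssemble:
    def test_binary_coding_and_transforms(self):
        tree, triads, ranges, velocity, disc = small_study()
        table, dropped = assemble_predictor_table(
            {"T1": dresult(z=-2.5, p=0.012)}, triads, ranges, velocity, tree, disc
        )
        assert dropped.empty
        row = table.iloc[0]
        assert row["z_signal"] == pytest.approx(2.5)
        assert row["introgression_binary"] == 1
        assert row["geo_distance"] == 0.0  # shared cell y
        assert row["log_geo_distance"] == 0.0  # ln(0 + 1)
        assert row["log_divergence_time"] == pytest.approx(math.log(3.0))
        assert row["discordance"] == pytest.approx(0.35)
        assert "log_discordance" not in table.columns
        # union-mean climate velocity over cells x, y, z
        assert row["mean_climate_velocity"] == pytest.approx(0.04)

    def test_nonsignificant_z_binary_zero(self):
        tree, triads, ranges, velocity, disc = small_study()
        table, _ = assemble_predictor_table(
            {"T1": dresult(z=1.0, p=0.3173)}, triads, ranges, velocity, tree, disc
        )
        assert table.iloc[0]["introgression_binary"] == 0

    def test_incomplete_rows_reported(self):
        tree, triads, ranges, velocity, disc = small_study()
        table, dropped = assemble_predictor_table(
            {}, triads, ranges, velocity, tree, disc
        )
        assert table.empty and dropped.iloc[0]["reason"] == "no D-statistic result"

    def test_transforms_preserve_ranks(self):
        tree = parse_tree("((((A:1,B:1):2,C:3):1,(E:1,F:1):3):1,D:5);")
        triads = [
            Triad("T1", "A", "B", "C", "D", 3.0, 1.0),
            Triad("T2", "E", "F", "D", "A", 4.0, 1.0),
        ]
        ranges = {
            "A": grange("A", {"x": (5, -60)}),
            "B": grange("B", {"z": (7, -58)}),
            "E": grange("E", {"w": (-12, -48)}),
            "F": grange("F", {"v": (-14, -50)}),
        }
        velocity = {"x": 0.02, "z": 0.06, "w": 0.2, "v": 0.1}
        disc = {"T1": 0.35, "T2": 0.7}
        dres = {
            "T1": dresult(z=-2.5, p=0.012),
            "T2": DResult("T2", 0.1, 0.08, 1.2, 0.23, 250, 90, 250, 2),
        }
        table, dropped = assemble_predictor_table(dres, triads, ranges, velocity, tree, disc)
        assert len(table) == 2 and dropped.empty
        for col in ("z_signal", "geo_distance", "mean_range_size",
                    "mean_climate_velocity", "divergence_time", "internode"):
            raw_order = table[col].rank().tolist()
            log_order = table[f"log_{col}"].rank().tolist()
            assert raw_order == log_order


class TestEsriAscii:
    def test_roundtrip_with_nodata(self, tmp_path):
        arr = np.array([[1.5, 2.5, 3.0], [4.0, np.nan, 6.0], [7.0, 8.0, 9.25]])
        p = tmp_path / "grid.asc"
        write_esri_ascii(str(p), arr, cellsize=0.5)
        back, header = read_esri_ascii(str(p))
        assert header["cellsize"] == 0.5
        assert np.isnan(back[1, 1])
        assert np.allclose(np.nan_to_num(back), np.nan_to_num(arr))


class TestMeanVelocity:
    def test_union_mean_and_missing(self):
        r1 = grange("a", {"x": (0, 0)})
        r2 = grange("b", {"q": (1, 1)})
        assert math.isnan(mean_velocity_over_ranges(r1, r2, {}))
        assert mean_velocity_over_ranges(r1, r2, {"x": 0.1, "q": 0.3}) == pytest.approx(0.2)
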