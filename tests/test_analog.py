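"""Nearest-analog search, velocity fields, and their closed-form limits."""

import numpy as np
import pytest

from climvelocity import (
    ScoreMatrix,
    assign_bins,
    bin_width_sensitivity,
    climatic_velocity,
    ensemble_average,
    great_circle_distance,
    nearest_analog,
)
from climvelocity.analog import EARTH_RADIUS_KM, VelocityField

from conftest import grid_scores, line_scores


def brute_force_matches(src, tgt, src_bins, tgt_bins, mode):
    """Independent O(n^2) same-bin nearest search via the haversine matrix.

    Ties resolved by (distance, target cell_id) lexicographic order.
    """
    if mode == "sphere":
        a = np.column_stack((src.lon, src.lat))
        b = np.column_stack((tgt.lon, tgt.lat))
        D = great_circle_distance(a[:, None, :], b[None, :, :])
    else:
        D = np.sqrt(
            ((src.xy_km[:, None, :] - tgt.xy_km[None, :, :]) ** 2).sum(axis=2)
        )
    same = (src_bins.codes[:, None, :] == tgt_bins.codes[None, :, :]).all(axis=2)
    n_src = len(src.cell_id)
    target = np.full(n_src, -1, dtype=int)
    dist = np.full(n_src, np.nan)
    for i in range(n_src):
        js = np.nonzero(same[i])[0]
        if js.size == 0:
            continue
        d = D[i, js]
        dmin = d.min()
        ties = js[d == dmin]
        target[i] = tgt.cell_id[ties[np.argmin(np.asarray(tgt.cell_id)[ties])]]
        dist[i] = dmin
    return target, dist


def random_instance(rng, n, n_axes=2, mode="sphere", gridded=False):
    if gridded:
        lon = rng.integers(-120, -60, size=n).astype(float)
        lat = rng.integers(-30, 60, size=n).astype(float)
    else:
        lon = rng.uniform(-120, -60, size=n)
        lat = rng.uniform(-30, 60, size=n)
    ids = rng.permutation(n * 3)[:n]  # non-contiguous, shuffled ids
    return ScoreMatrix(
        cell_id=ids,
        scores=rng.uniform(-4, 4, size=(n, n_axes)),
        lon=lon,
        lat=lat,
        xy_km=np.column_stack((lon, lat)) * 50.0,
    )


class TestGreatCircle:
    def test_identity(self):
        assert great_circle_distance((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_quarter_great_circle(self):
        d = great_circle_distance((0.0, 0.0), (90.0, 0.0))
        assert d == pytest.approx(EARTH_RADIUS_KM * np.pi / 2, rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = np.column_stack((rng.uniform(-180, 180, 100), rng.uniform(-90, 90, 100)))
        b = np.column_stack((rng.uniform(-180, 180, 100), rng.uniform(-90, 90, 100)))
        assert np.array_equal(
            great_circle_distance(a, b), great_circle_distance(b, a)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance((200.0, 0.0), (0.0, 0.0))


class TestNearestAnalog:
    def test_identical_targets_match_self_at_zero(self):
        rng = np.random.default_rng(5)
        sm = random_instance(rng, 50)
        ba = assign_bins(sm, 2.0, 0.0)
        m = nearest_analog(ba, ba, sm, sm)
        assert m.has_analog.all()
        assert np.array_equal(m.target_cell, sm.cell_id)
        assert np.allclose(m.distance, 0.0)

    @pytest.mark.parametrize("mode", ["sphere", "planar"])
    @pytest.mark.parametrize("gridded", [False, True])
    def test_matches_brute_force(self, mode, gridded):
        rng = np.random.default_rng(11)
        for _ in range(5):
            src = random_instance(rng, 40, mode=mode, gridded=gridded)
            tgt = random_instance(rng, 35, mode=mode, gridded=gridded)
            sb, tb = assign_bins(src, 2.0, 0.3), assign_bins(tgt, 2.0, 0.3)
            m = nearest_analog(sb, tb, src, tgt, mode=mode)
            exp_t, exp_d = brute_force_matches(src, tgt, sb, tb, mode)
            assert np.array_equal(m.target_cell, exp_t)
            assert np.allclose(
                m.distance, exp_d, rtol=1e-9, atol=1e-6, equal_nan=True
            )

    def test_unoccupied_bin_gives_no_analog(self):
        src = line_scores(1, lambda x: np.array([0.0]))
        tgt = line_scores(3, lambda x: np.array([10.0, 11.0, 12.0]))
        m = nearest_analog(
            assign_bins(src, 2.0, 0.0), assign_bins(tgt, 2.0, 0.0), src, tgt
        )
        assert not m.has_analog[0]
        assert np.isnan(m.distance[0])
        assert m.target_cell[0] == -1

    def test_bin_parameter_mismatch_rejected(self):
        sm = line_scores(4, lambda x: x / 100.0)
        with pytest.raises(ValueError, match="bin parameters"):
            nearest_analog(
                assign_bins(sm, 2.0, 0.0), assign_bins(sm, 2.0, 0.5), sm, sm
            )


class TestClimaticVelocity:
    def test_static_climate_gives_zero_everywhere(self):
        rng = np.random.default_rng(2)
        sm = random_instance(rng, 60)
        out = climatic_velocity(sm, sm, n_offsets=7)
        for f in out.values():
            assert np.allclose(f.velocity, 0.0)
            assert np.allclose(f.no_analog_prob, 0.0)

    @pytest.mark.parametrize(
        "width,expected_km",
        [
            # Bins narrower than the per-cell score step resolve the exact
            # match: distance = shift / gradient = 200 km.
            (0.5, 200.0),
            # Coarser bins accept any cell within the same 2-unit-per-w
            # interval; offset-averaging the nearest in-bin cell gives
            # shift - w/2 (in gradient km) + half a cell:
            (1.0, 175.0),
            (2.0, 125.0),
        ],
    )
    def test_uniform_shift_on_gradient_matches_closed_form(self, width, expected_km):
        # 1 PCA unit per 100 km; +2 units over 110 years.  In the
        # small-bin limit the analog velocity equals the local-velocity
        # closed form (delta/T)/g = 1.82 km/yr.
        n, cell = 200, 50.0
        cur = line_scores(n, lambda xkm: 0.01 * xkm, cell_size_km=cell)
        fut = line_scores(n, lambda xkm: 0.01 * xkm + 2.0, cell_size_km=cell)
        out = climatic_velocity(
            cur, fut, bin_width=width, n_offsets=100, years_between=110.0, mode="planar"
        )
        f = out["forward"]
        interior = np.arange(n) * cell >= 250.0
        assert np.allclose(f.mean_distance[interior], expected_km, atol=1e-9)
        assert np.allclose(
            f.velocity[interior], expected_km / 110.0, atol=1e-12
        )
        if width <= 0.5:  # smooth-gradient limit: local closed form
            assert np.all(
                np.abs(f.velocity[interior] - 200.0 / 110.0) <= cell / 110.0
            )

    def test_disappearing_and_novel_census_on_bounded_gradient(self):
        # current scores span [0,10), future [2,12): the coolest current
        # bin [0,2) is forward-no-analog; the warmest future bin [10,12)
        # is backward-no-analog.
        n = 100
        s = np.linspace(0.0, 10.0, n, endpoint=False)
        cur = line_scores(n, lambda xkm: s)
        fut = line_scores(n, lambda xkm: s + 2.0)
        cb = assign_bins(cur, 2.0, 0.0)
        fb = assign_bins(fut, 2.0, 0.0)
        fwd = nearest_analog(cb, fb, cur, fut, mode="planar")
        bwd = nearest_analog(fb, cb, fut, cur, mode="planar")
        assert np.array_equal(~fwd.has_analog, s < 2.0)
        assert np.array_equal(~bwd.has_analog, s + 2.0 >= 10.0)
        # census conservation: no-analog bins = set difference of bin censuses
        cur_bins = {tuple(c) for c in cb.codes}
        fut_bins = {tuple(c) for c in fb.codes}
        missing_fwd = {tuple(c) for c, h in zip(cb.codes, fwd.has_analog) if not h}
        missing_bwd = {tuple(c) for c, h in zip(fb.codes, bwd.has_analog) if not h}
        assert missing_fwd == cur_bins - fut_bins
        assert missing_bwd == fut_bins - cur_bins

    def test_offset_shift_invariance_of_averaged_distance(self):
        rng = np.random.default_rng(8)
        n = 80
        base = rng.uniform(0, 6, size=n)
        cur = line_scores(n, lambda xkm: base)
        fut = line_scores(n, lambda xkm: base + rng.uniform(0.5, 1.5, size=n))
        n_off = 25
        a = climatic_velocity(cur, fut, n_offsets=n_off, mode="planar")["forward"]
        delta = 0.77
        cur2 = line_scores(n, lambda xkm: base + delta)
        fut2 = line_scores(n, lambda xkm: fut.scores[:, 0] + delta)
        b = climatic_velocity(cur2, fut2, n_offsets=n_off, mode="planar")["forward"]
        # averaged replicate schedules differ by at most one offset step
        tol = 1.0 / n_off
        both = ~np.isnan(a.mean_distance) & ~np.isnan(b.mean_distance)
        scale = np.nanmax(a.mean_distance) + 50.0
        assert np.mean(np.abs(a.no_analog_prob - b.no_analog_prob)) <= tol + 1e-9
        assert np.nanmean(np.abs(a.mean_distance[both] - b.mean_distance[both])) <= tol * scale


class TestEnsembleAverage:
    def _field(self, v, p=None, direction="forward"):
        v = np.asarray(v, dtype=float)
        n = len(v)
        return VelocityField(
            cell_id=np.arange(n), lon=np.zeros(n), lat=np.zeros(n),
            mean_distance=v * 110.0, velocity=v,
            no_analog_prob=np.zeros(n) if p is None else np.asarray(p, dtype=float),
            direction=direction, n_replicates=1, years_between=110.0,
        )

    def test_single_member_passthrough(self):
        f = self._field([1.0, 2.0])
        e = ensemble_average([f])
        assert np.allclose(e.velocity, f.velocity)
        assert np.allclose(e.sd_across_gcms, 0.0)

    def test_two_member_mean_and_sample_sd(self):
        e = ensemble_average([self._field([1.0]), self._field([3.0])])
        assert e.velocity[0] == pytest.approx(2.0)
        assert e.sd_across_gcms[0] == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_partially_defined_member_uses_defined_only(self):
        a = self._field([np.nan], p=[1.0])
        b = self._field([4.0], p=[0.0])
        e = ensemble_average([a, b])
        assert e.velocity[0] == pytest.approx(4.0)
        assert e.no_analog_prob[0] == pytest.approx(0.5)

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            ensemble_average(
                [self._field([1.0]), self._field([1.0], direction="backward")]
            )


class TestBinWidthSensitivity:
    def test_single_bin_limit_has_no_missing_analogs(self):
        rng = np.random.default_rng(4)
        cur = line_scores(30, lambda xkm: rng.uniform(0, 3, 30))
        fut = line_scores(30, lambda xkm: rng.uniform(0, 3, 30))
        tab = bin_width_sensitivity(cur, fut, [1e6], mode="planar")
        assert tab.no_analog_proportion.iloc[0] == 0.0
        # one bin: match is simply the nearest future cell
        d = np.abs(cur.xy_km[:, None, 0] - fut.xy_km[None, :, 0]).min(axis=1)
        assert tab.median_match_distance_km.iloc[0] == pytest.approx(np.median(d))

    def test_match_distance_monotone_under_aligned_doubling(self):
        rng = np.random.default_rng(9)
        n = 50
        cur = line_scores(n, lambda xkm: rng.uniform(0, 8, n))
        fut = line_scores(n, lambda xkm: rng.uniform(0, 8, n))
        w = 1.0
        m1 = nearest_analog(
            assign_bins(cur, w, 0.0), assign_bins(fut, w, 0.0), cur, fut, mode="planar"
        )
        m2 = nearest_analog(
            assign_bins(cur, 2 * w, 0.0), assign_bins(fut, 2 * w, 0.0),
            cur, fut, mode="planar",
        )
        both = m1.has_analog  # analogs can only be gained when bins widen
        assert np.all(m2.has_analog[both])
        assert np.all(m2.distance[both] <= m1.distance[both] + 1e-9)

    def test_vanishing_width_makes_everything_no_analog(self):
        n = 20
        vals = np.linspace(0, 1, n)
        cur = line_scores(n, lambda xkm: vals)
        fut = line_scores(n, lambda xkm: vals + 0.5 / n)  # shifted off every value
        tab = bin_width_sensitivity(cur, fut, [1e-9], mode="planar")
        assert tab.no_analog_proportion.iloc[0] == 1.0
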