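"""Per-species biotic velocity, disappearance probability, taxon aggregates."""

import numpy as np
import pytest

from climvelocity import (
    aggregate_taxa,
    assign_bins,
    disappearance_probability,
    nearest_analog,
    site_loss_probability,
    species_velocity,
)

from conftest import line_scores, stack_from_masks


def band(n, lo, hi):
    m = np.zeros(n, dtype=bool)
    m[lo:hi] = True
    return m


class TestSpeciesVelocity:
    def test_static_range_gives_zero(self):
        cur = stack_from_masks([band(20, 5, 12)])
        fut = stack_from_masks([band(20, 5, 12)], period="future", gcm_id="g0")
        (f,) = species_velocity(cur, fut, direction="forward", mode="planar")
        assert np.allclose(f.velocity, 0.0)
        assert not f.range_disappears

    def test_two_cell_shift_closed_form(self):
        # 1-row range shifted 2 cells (100 km at 50-km cells) with no
        # overlap: every range cell is 100 km from the nearest future
        # cell; trailing/leading structure appears when ranges overlap.
        cur = stack_from_masks([band(30, 10, 12)])
        fut = stack_from_masks([band(30, 12, 14)], period="future", gcm_id="g0")
        (f,) = species_velocity(cur, fut, years_between=110.0,
                                direction="forward", mode="planar")
        assert np.allclose(f.distance, [100.0, 50.0])
        # overlapping shift: leading edge 0, trailing edge largest
        cur2 = stack_from_masks([band(30, 10, 16)])
        fut2 = stack_from_masks([band(30, 12, 18)], period="future", gcm_id="g0")
        (f2,) = species_velocity(cur2, fut2, years_between=110.0,
                                 direction="forward", mode="planar")
        assert np.allclose(f2.distance, [100.0, 50.0, 0.0, 0.0, 0.0, 0.0])
        assert f2.velocity[0] == pytest.approx(100.0 / 110.0)

    def test_empty_future_range_flags_disappearance(self):
        cur = stack_from_masks([band(20, 5, 12)])
        fut = stack_from_masks([np.zeros(20, dtype=bool)], period="future", gcm_id="g0")
        (f,) = species_velocity(cur, fut, direction="forward", mode="planar")
        assert f.range_disappears
        assert np.all(np.isnan(f.distance))

    def test_expanding_range_forward_zero_backward_positive(self):
        cur = stack_from_masks([band(30, 10, 15)])
        fut = stack_from_masks([band(30, 8, 18)], period="future", gcm_id="g0")
        (fw,) = species_velocity(cur, fut, direction="forward", mode="planar")
        (bw,) = species_velocity(cur, fut, direction="backward", mode="planar")
        assert np.allclose(fw.velocity, 0.0)
        newly = ~np.isin(bw.cell_index, fw.cell_index)
        assert np.all(bw.velocity[newly] > 0)
        assert np.allclose(bw.velocity[~newly], 0.0)

    def test_species_mismatch_rejected(self):
        cur = stack_from_masks([band(10, 1, 3), band(10, 4, 6)])
        fut = stack_from_masks([band(10, 1, 3)], period="future", gcm_id="g0")
        with pytest.raises(ValueError, match="species"):
            species_velocity(cur, fut)

    def test_forward_biotic_bounded_by_forward_climatic(self):
        """When a species' suitable set contains every cell of its climate
        bin's analog set, the nearest suitable cell is never farther than
        the nearest same-bin cell."""
        rng = np.random.default_rng(6)
        n = 60
        scores = rng.uniform(0, 6, size=n)
        cur = line_scores(n, lambda xkm: scores)
        fut_scores = scores + 1.0
        fut = line_scores(n, lambda xkm: fut_scores)
        w = 2.0
        cb, fb = assign_bins(cur, w, 0.0), assign_bins(fut, w, 0.0)
        m = nearest_analog(cb, fb, cur, fut, mode="planar")
        # species envelope = one whole bin, i.e. suitable wherever the
        # climate falls in bin code k (suitable set contains the analog set)
        k = cb.codes[0, 0]
        cur_stack = stack_from_masks([cb.codes[:, 0] == k])
        fut_stack = stack_from_masks([fb.codes[:, 0] == k], period="future",
                                     gcm_id="g0")
        (f,) = species_velocity(cur_stack, fut_stack, direction="forward",
                                mode="planar")
        clim_d = m.distance[f.cell_index]
        ok = ~np.isnan(clim_d)
        assert np.all(f.distance[ok] <= clim_d[ok] + 1e-9)


class TestDisappearanceProbability:
    def _stacks(self):
        # 2 species sharing cell 5; species 0 loses its range in 5 of 10
        # pseudo-GCM futures, species 1 never does
        cur = stack_from_masks([band(20, 3, 8), band(20, 5, 12)])
        futs = []
        for g in range(10):
            sp0 = np.zeros(20, dtype=bool) if g < 5 else band(20, 3, 8)
            futs.append(
                stack_from_masks([sp0, band(20, 5, 12)], period="future",
                                 gcm_id=f"g{g}")
            )
        return cur, futs

    def test_counting_oracle(self):
        cur, futs = self._stacks()
        p = disappearance_probability(cur, futs)
        assert p[5] == pytest.approx(5 / 20)  # 2 species x 10 GCMs, 5 losses
        assert p[3] == pytest.approx(5 / 10)  # only species 0 present
        assert p[10] == pytest.approx(0.0)  # only species 1 present
        assert np.isnan(p[0])  # no species

    def test_no_disappearance_gives_zero(self):
        cur = stack_from_masks([band(20, 3, 8)])
        fut = stack_from_masks([band(20, 5, 10)], period="future", gcm_id="g0")
        p = disappearance_probability(cur, [fut])
        assert np.allclose(p[band(20, 3, 8)], 0.0)

    def test_total_loss_gives_one(self):
        cur = stack_from_masks([band(20, 3, 8), band(20, 4, 9)])
        fut = stack_from_masks(
            [np.zeros(20, dtype=bool)] * 2, period="future", gcm_id="g0"
        )
        p = disappearance_probability(cur, [fut])
        assert np.allclose(p[band(20, 4, 8)], 1.0)

    def test_invariant_to_species_duplication(self):
        cur, futs = self._stacks()
        p1 = disappearance_probability(cur, futs)
        dup_cur = stack_from_masks(np.vstack([cur.mask, cur.mask]))
        dup_futs = [
            stack_from_masks(np.vstack([f.mask, f.mask]), period="future",
                             gcm_id=f.gcm_id)
            for f in futs
        ]
        p2 = disappearance_probability(dup_cur, dup_futs)
        assert np.allclose(p1, p2, equal_nan=True)

    def test_site_loss_variant_differs_from_range_wide(self):
        # range persists elsewhere but the site itself is lost
        cur = stack_from_masks([band(20, 3, 8)])
        fut = stack_from_masks([band(20, 6, 11)], period="future", gcm_id="g0")
        range_wide = disappearance_probability(cur, [fut])
        site = site_loss_probability(cur, [fut])
        assert np.allclose(range_wide[band(20, 3, 8)], 0.0)
        assert np.allclose(site[band(20, 3, 6)], 1.0)
        assert np.allclose(site[band(20, 6, 8)], 0.0)


class TestAggregateTaxa:
    def test_single_species_single_gcm_passthrough(self):
        cur = stack_from_masks([band(20, 4, 9)], taxa=["mammal"])
        fut = stack_from_masks([band(20, 6, 11)], taxa=["mammal"],
                               period="future", gcm_id="g0")
        fields = species_velocity(cur, fut, direction="forward", mode="planar")
        out = aggregate_taxa([fields], cur.n_cells, cur.cell_id)
        np.testing.assert_allclose(
            out["mammal"].mean_velocity[fields[0].cell_index], fields[0].velocity
        )
        assert out["all"].n_species == 1

    def test_two_species_mean_and_sd(self):
        n = 20
        cur = stack_from_masks([band(n, 4, 9), band(n, 4, 9)],
                               taxa=["bird", "bird"])
        fields = species_velocity(cur, cur, direction="forward", mode="planar")
        # impose per-cell velocities 0.2 and 0.6 directly
        fields[0].velocity[:] = 0.2
        fields[1].velocity[:] = 0.6
        out = aggregate_taxa([fields], n, cur.cell_id)
        cells = fields[0].cell_index
        assert np.allclose(out["all"].mean_velocity[cells], 0.4)
        assert np.allclose(
            out["all"].sd_across_species[cells], np.std([0.2, 0.6], ddof=1)
        )

    def test_identical_gcms_have_zero_gcm_sd(self):
        cur = stack_from_masks([band(20, 4, 9)])
        fut = stack_from_masks([band(20, 6, 11)], period="future", gcm_id="g0")
        fields = species_velocity(cur, fut, direction="forward", mode="planar")
        out = aggregate_taxa([fields, fields, fields], 20, cur.cell_id)
        cells = fields[0].cell_index
        assert np.allclose(out["all"].sd_across_gcms[cells], 0.0)

    def test_disappearing_species_excluded_from_means(self):
        n = 20
        cur = stack_from_masks([band(n, 4, 9), band(n, 4, 9)])
        fut = stack_from_masks(
            [band(n, 6, 11), np.zeros(n, dtype=bool)], period="future", gcm_id="g0"
        )
        fields = species_velocity(cur, fut, direction="forward", mode="planar")
        out = aggregate_taxa([fields], n, cur.cell_id)
        # only the surviving species contributes
        np.testing.assert_allclose(
            out["all"].mean_velocity[fields[0].cell_index], fields[0].velocity
        )

    def test_unknown_taxon_rejected(self):
        cur = stack_from_masks([band(20, 4, 9)])
        fields = species_velocity(cur, cur, direction="forward", mode="planar")
        with pytest.raises(ValueError, match="unknown taxon"):
            aggregate_taxa([fields], 20, cur.cell_id, taxa=("reptile",))
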