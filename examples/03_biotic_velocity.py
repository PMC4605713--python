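"""Per-species biotic velocity and the species-disappearance probability.

Biotic velocity applies the analog logic to a species' binary suitability
map: from each current-range cell, the distance to the nearest cell that
stays or becomes suitable (forward); from each future-range cell, the
distance back to currently suitable habitat (backward).
"""

import numpy as np

from climvelocity import (
    ScenarioConfig, aggregate_taxa, disappearance_probability, make_bioclim,
    make_species, make_terrain, sample_niches, species_velocity,
)

terrain = make_terrain(nx=40, ny=40, n_mountains=2, max_elev=2200.0, seed=11)
scenario = ScenarioConfig(n_pseudo_gcms=3, warming_mean=[2.0, 3.0, 4.0],
                          spatial_noise_sd=0.15,
                          precip_change_frac=[0.0, 0.0, 0.05], seed=11)
current, futures = make_bioclim(terrain, scenario, n_vars=8)
niches = sample_niches(current, n_species=30, seed=11)
stack_cur, stacks_fut = make_species(current, futures, niches)

fwd_by_gcm = [species_velocity(stack_cur, sf, years_between=110.0,
                               direction="forward")
              for sf in stacks_fut]
summary = aggregate_taxa(fwd_by_gcm, stack_cur.n_cells, stack_cur.cell_id)
for taxon, ts in summary.items():
    v = ts.mean_velocity
    print(f"{taxon:>10}: n={ts.n_species:3d} species, "
          f"mean forward velocity {np.nanmean(v):.3f} km/yr "
          f"(sd across species {np.nanmean(ts.sd_across_species):.3f})")

disap = disappearance_probability(stack_cur, stacks_fut)
print(f"mean per-cell disappearance probability: {np.nanmean(disap):.4f}")
n_gone = sum(f.range_disappears for f in fwd_by_gcm[0])
print(f"species losing their whole range under {stacks_fut[0].gcm_id}: {n_gone}")
# The disappearance metric is a probability over (resident species x GCM)
# combinations, so it does not simply track current species richness.
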