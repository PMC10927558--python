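"""Generate a synthetic boreal-wetland scene and summarize it.

Builds the default desk-scale scene: 10 x 20 half-degree cells over
60-65 N, 60-70 E, weekly steps for 2002-2022, eight environmental drivers,
a wetland map partitioned into bog/fen/marsh/tundra, the ground-truth CH4
flux field, and a mixed network of eddy-covariance and chamber sites.
"""
import numpy as np

import wetch4 as w

grid = w.GridSpec()
cfg = w.TruthConfig(seed=1)

drivers = w.generate_drivers(grid, cfg)
wetlands = w.generate_wetlands(grid, cfg)
truth = w.generate_truth_flux(drivers, wetlands, cfg)
sites = w.sample_sites(truth, wetlands, n_ec=30, n_chamber=40, cfg=cfg)

print(f"grid: {grid.lats.size} x {grid.lons.size} cells, {grid.n_steps} weekly steps")
wet = wetlands["wetland_frac"].values
print(f"wetland cells: {(wet > 0).sum()} of {wet.size} "
      f"(mean fraction {wet[wet > 0].mean():.2f})")
for d in ("TS", "TA", "GPP"):
    v = drivers[d]
    print(f"driver {d}: {float(v.min()):7.2f} .. {float(v.max()):6.2f} {v.attrs['units']}")
mean_int = float(truth["intensity"].mean())
total_tg = float(truth["emission"].sum()) * 1e-12 / 20
print(f"truth flux: mean intensity {mean_int:.1f} nmol CH4 m-2 s-1, "
      f"domain emissions {total_tg:.3f} Tg CH4 yr-1")
n_ec = sum(r.frequency == "weekly" for r in sites)
print(f"sites: {n_ec} EC (weekly series), {len(sites) - n_ec} chamber (period means)")
# Each number above is the planted truth the rest of the pipeline must
# recover: the flux law, its magnitude, and where it was observed.
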