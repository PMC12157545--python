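"""Twin-structured cohort: does tract similarity respect family structure?

Builds a cohort of subject orientation fields around a small base
phantom.  Pair members share a smooth perturbation component whose
weight encodes the relationship (monozygotic twins share most, dizygotic
twins and siblings share half, unrelated pairs share none).  Tract
reconstructions are correlated within pairs and the groups compared
with Mann-Whitney tests under Bonferroni correction.
"""

import warnings

import cstract as cs
from cstract.tracking import Constraints, TrackingParams, run_seed_region

base = cs.build_phantom(cs.mini_cohort_spec(0))
cohort = cs.build_cohort(base.field,
                         n_pairs={"MZ": 20, "DZ": 20, "SIB": 20, "UNREL": 20},
                         shared_weights={"MZ": 0.9, "DZ": 0.45, "SIB": 0.45,
                                         "UNREL": 0.0},
                         rng_seed=0)
print(f"cohort: {len(cohort.subjects)} subjects, {len(cohort.pairs)} labelled pairs")

params = TrackingParams(rng_seed=11, step_mm=0.5, seeds_per_voxel=15, max_steps=200)
recon = {}
for sid, fld in cohort.subjects:
    maps = {}
    for tract, (s, t) in {"assoc": ("west_l", "east_l"),
                          "arc": ("south_l", "north_l")}.items():
        pd, _ = run_seed_region(fld, base.masks[s],
                                Constraints(waypoints=[base.masks[t]]), params, tract)
        maps[tract] = pd
    recon[sid] = maps

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    rep = cs.twin_analysis(cohort, recon)

print("\nmedian pairwise tract similarity (mean Pearson r across tracts):")
for g in ("MZ", "DZ", "SIB", "UNREL"):
    print(f"  {g:6s} {rep['medians'][g]:.3f}")
print("\ngroup comparisons (Mann-Whitney, Bonferroni-adjusted):")
for k, v in rep["tests"].items():
    mark = "*" if v["p_adjusted"] < 0.05 else " "
    print(f"  {k:10s} p_adj = {v['p_adjusted']:.2e} {mark}")
# Expected: similarity ordered MZ > DZ ~ SIB > UNREL, with every pairwise
# difference significant except dizygotic twins versus non-twin siblings.
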