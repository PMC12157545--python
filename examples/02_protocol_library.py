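"""Inspect the 23-tract protocol library and check relative positioning.

The library expands to 23 tract reconstructions: nine new bilateral
cortico-subcortical bundles (18 protocols) plus revised uncinate,
fornix and anterior commissure definitions (5 protocols).  The check at
the end verifies two anatomical organisation principles on the phantom:
the striatal bundle is medial to the extreme capsule, and the Muratoff
bundle runs dorsal to the caudate head.
"""

import cstract as cs

ph = cs.build_phantom(cs.default_spec("human", rng_seed=0))
lib = cs.load_library(ph.atlas, ph.masks, fld=ph.field, species="human")

print(f"{len(lib)} tract protocols:")
for p in lib.protocols:
    stop = " +stop" if p.stop is not None else ""
    rev = " (reverse-and-average)" if p.reverse_and_average else ""
    print(f"  {p.full_name:8s} [{p.provenance}] seed={p.seed.label:20s}"
          f" waypoints={len(p.waypoints)}{stop}{rev}")
print("by provenance:", lib.count_by_provenance())

params = cs.TrackingParams(rng_seed=2, step_mm=0.5, seeds_per_voxel=40)
stbf, _ = cs.execute_tract(ph.field, lib.get("StBf_l"), params)
emcf, _ = cs.execute_tract(ph.field, lib.get("EmCf_l"), params)
mb, _ = cs.execute_tract(ph.field, lib.get("MB_l"), params)

rep = cs.check_topology(stbf, emcf, mb, ph.masks["caudate_head_l"], "l")
print(f"\nStBf centroid x = {rep['stbf_centroid'][0]:.1f}, "
      f"EmCf centroid x = {rep['emcf_centroid'][0]:.1f} "
      f"-> StBf medial to EmCf: {rep['stbf_medial_to_emcf']}")
print(f"MB centroid z = {rep['mb_centroid'][2]:.1f}, "
      f"caudate head z = {rep['caudate_head_centroid'][2]:.1f} "
      f"-> MB dorsal to caudate head: {rep['mb_dorsal_to_caudate_head']}")
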