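"""End-to-end orchestration: phantom -> tracts -> blueprints -> divergence.

These helpers wire the modules together for the analyses the package
ships: left-hemisphere blueprint construction for a phantom "species",
cross-species homologue identification for the five deep nuclei and for
cortical test zones, striatal topography checks and the subcortical
blueprint variant comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .blueprints import (ConnectivityBlueprint, assemble, compare_subcortical_variants,
                         cortical_blueprint, gm_by_wm, subcortical_blueprint, wm_by_tracts)
from .core import MaskVolume
from .divergence import DivergenceConfig, best_match, divergence_map, specificity_contrast
from .phantom import Phantom
from .protocols import (ProtocolLibrary, TractProtocol, execute_tract, load_library,
                        reference_protocols)
from .tracking import PathDistribution, TrackingParams

NUCLEI = ("putamen", "caudate", "thalamus", "hippocampus", "amygdala")
CORTICAL_TEST_ZONES = ("dmpfc", "vmpfc", "ofcr", "fop")


def hemisphere_protocols(ph: Phantom, hemisphere: str = "l",
                         include_reference: bool = True) -> list[TractProtocol]:
    """Library protocols of one hemisphere plus the commissural AC and,
    optionally, the reference tract set."""
    lib = load_library(ph.atlas, ph.masks, fld=ph.field, species=ph.spec.species)
    chosen = [p for p in lib.protocols if p.hemisphere in (hemisphere, "commissural")]
    if include_reference:
        chosen += [p for p in reference_protocols(ph.atlas, ph.masks)
                   if p.hemisphere == hemisphere]
    return chosen


def run_tracts(ph: Phantom, params: TrackingParams, hemisphere: str = "l",
               include_reference: bool = True) -> tuple[dict[str, PathDistribution], dict[str, str]]:
    """Execute all blueprint tracts; returns distributions and tract classes."""
    protos = hemisphere_protocols(ph, hemisphere, include_reference)
    tracts, classes = {}, {}
    for p in protos:
        pd, _ = execute_tract(ph.field, p, params)
        if pd.n_valid == 0:
            warnings.warn(f"{p.full_name}: no valid streamlines")
        tracts[p.full_name] = pd
        classes[p.full_name] = p.tract_class
    return tracts, classes


def blueprint_nuclei(ph: Phantom, hemisphere: str = "l") -> dict[str, MaskVolume]:
    return {f"{n}_{hemisphere}": ph.masks[f"{n}_{hemisphere}"] for n in NUCLEI}


def build_species_blueprint(ph: Phantom, tracts: dict[str, PathDistribution],
                            classes: dict[str, str], params: TrackingParams,
                            hemisphere: str = "l", downsample: int = 2,
                            threshold: float = 0.001,
                            include_cortex: bool = True) -> ConnectivityBlueprint:
    """Full blueprint for one phantom: cortical rows via the intermediary
    GM x WM matrix, subcortical rows by direct intersection."""
    names = list(tracts)
    sub_rows, sub_meta, sub_names = subcortical_blueprint(
        tracts, blueprint_nuclei(ph, hemisphere), downsample, threshold)
    assert sub_names == names
    if include_cortex:
        elems = [(idx, h) for idx, h in ph.atlas.cortical_elements if h == hemisphere]
        seed_vox = np.array([idx for idx, _ in elems], dtype=np.int64)
        gmwm = gm_by_wm(ph.field, seed_vox, ph.masks["wm"], params, downsample=downsample)
        wmt, wmt_names = wm_by_tracts(tracts, gmwm.wm_columns, gmwm.coarse_grid,
                                      downsample=downsample, threshold=threshold)
        assert wmt_names == names
        ctx_rows = cortical_blueprint(gmwm, wmt)
        ctx_meta = [{"kind": "cortex", "hemisphere": hemisphere, "voxel": tuple(map(int, idx))}
                    for idx, _ in elems]
    else:
        ctx_rows = np.zeros((0, len(names)))
        ctx_meta = []
    return assemble(ctx_rows, ctx_meta, sub_rows, sub_meta, names, classes)


def nucleus_rows(bp: ConnectivityBlueprint, nucleus: str, hemisphere: str = "l") -> np.ndarray:
    return bp.rows_of(f"{nucleus}_{hemisphere}")


def cortical_zone_rows(bp: ConnectivityBlueprint, zone_mask: MaskVolume) -> np.ndarray:
    """Cortical rows whose element voxel lies inside a zone mask."""
    sel = []
    for i, m in enumerate(bp.row_meta):
        if m["kind"] != "cortex":
            continue
        v = m["voxel"]
        if zone_mask.membership[v[0], v[1], v[2]]:
            sel.append(i)
    return np.array(sel, dtype=int)


def homologue_analysis(bp_ref: ConnectivityBlueprint, bp_target: ConnectivityBlueprint,
                       hemisphere: str = "l", delta: float = 1e-6,
                       subsets: tuple[str, ...] = ("all", "cc")) -> dict:
    """Identify each reference nucleus's best-matching target nucleus.

    For each reference nucleus the mean reference pattern is compared to
    every target subcortical row; candidates are the five target nuclei.
    Reported per subset: the winning region, per-region median divergence
    and the specificity contrast of the true match.
    """
    candidates = {f"{n}_{hemisphere}": nucleus_rows(bp_target, n, hemisphere) for n in NUCLEI}
    out: dict = {}
    for n in NUCLEI:
        ref_name = f"{n}_{hemisphere}"
        rows = nucleus_rows(bp_ref, n, hemisphere)
        out[ref_name] = {}
        for subset in subsets:
            cfg = DivergenceConfig(delta=delta, tract_subset=subset)
            dmap = divergence_map(bp_ref, rows, bp_target, cfg, reference_name=ref_name)
            winner, medians = best_match(dmap, candidates)
            out[ref_name][subset] = {
                "winner": winner,
                "correct": winner == ref_name,
                "medians": medians,
                "contrast": specificity_contrast(medians, ref_name)
                if ref_name in medians else np.nan,
            }
    return out


def cortical_homologue_analysis(bp_ref: ConnectivityBlueprint, bp_target: ConnectivityBlueprint,
                                ph_ref: Phantom, ph_target: Phantom,
                                hemisphere: str = "l", delta: float = 1e-6,
                                subset: str = "all") -> dict:
    """Best-match identification for the four frontal cortical test zones."""
    cfg = DivergenceConfig(delta=delta, tract_subset=subset)
    candidates = {z: cortical_zone_rows(bp_target, ph_target.masks[f"{z}_{hemisphere}"])
                  for z in CORTICAL_TEST_ZONES}
    out = {}
    for z in CORTICAL_TEST_ZONES:
        rows = cortical_zone_rows(bp_ref, ph_ref.masks[f"{z}_{hemisphere}"])
        rows = rows[~bp_ref.flagged[rows]]
        if len(rows) == 0:
            out[z] = {"winner": None, "correct": False, "medians": {}}
            continue
        dmap = divergence_map(bp_ref, rows, bp_target, cfg, reference_name=z)
        winner, medians = best_match(dmap, candidates)
        out[z] = {"winner": winner, "correct": winner == z, "medians": medians}
    return out


def species_tracking_params(ph: Phantom, rng_seed: int, **overrides) -> TrackingParams:
    """Tracking parameters with the species' step size (half-scale phantom
    uses 0.2 mm steps, the full-scale one 0.5 mm)."""
    from .phantom import SPECIES_GRIDS
    step = SPECIES_GRIDS.get(ph.spec.species, {"step_mm": 0.5})["step_mm"]
    kw = dict(rng_seed=rng_seed, step_mm=step)
    kw.update(overrides)
    return TrackingParams(**kw)
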