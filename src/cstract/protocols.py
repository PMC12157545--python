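"""Declarative tract protocols and the shipped 23-tract library.

A protocol specifies one tract as a combination of seed, waypoint
(target), stop and exclusion masks, so that tract delineation is fully
automated and identical across subjects and species.  The shipped
library covers nine new bilateral cortico-subcortical bundles
(amygdalofugal pathway AMF; frontal, sensorimotor, parietal and temporal
striatal bundle parts StBf/StBm/StBp/StBt; Muratoff bundle MB; frontal,
parietal and temporal extreme capsule parts EmCf/EmCp/EmCt) plus revised
protocols for the uncinate fasciculus UF, fornix FX (both bilateral) and
the commissural anterior commissure AC — 23 tract reconstructions when
expanded over hemispheres.

Phantom-space masks realise the same verbal rules the anatomical
protocols use (e.g. each striatal-bundle part excludes the seeds of its
sibling parts; the AC protocol is run in both seed/target directions and
averaged); their geometric extents are phantom analogues, not anatomical
reproductions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from .core import GreyMatterAtlas, MaskVolume, ScalarVolume, write_volume, read_volume
from .field import OrientationField
from .tracking import Constraints, PathDistribution, TrackingParams, run_seed_region, threshold_distribution


@dataclass
class TractProtocol:
    name: str
    hemisphere: str                       # "l", "r" or "commissural"
    seed: MaskVolume
    waypoints: list[MaskVolume]
    exclusion: MaskVolume | None = None
    stop: MaskVolume | None = None
    reverse_and_average: bool = False
    ordered_waypoints: bool = False
    provenance: str = "new"               # "new" / "revised" / "reference"
    tract_class: str = "cs"               # "cs" or "cc"

    def __post_init__(self):
        if self.seed.n_voxels == 0:
            raise ValueError(f"protocol {self.full_name}: seed mask is empty")
        if self.exclusion is not None and (self.seed.membership & self.exclusion.membership).any():
            raise ValueError(f"protocol {self.full_name}: seed overlaps exclusion mask")

    @property
    def full_name(self) -> str:
        return self.name if self.hemisphere == "commissural" else f"{self.name}_{self.hemisphere}"

    def constraints(self) -> Constraints:
        return Constraints(waypoints=list(self.waypoints), exclusion=self.exclusion,
                           stop=self.stop, ordered_waypoints=self.ordered_waypoints)


@dataclass
class ProtocolLibrary:
    protocols: list[TractProtocol]
    species: str = ""

    def __post_init__(self):
        names = [p.full_name for p in self.protocols]
        if len(set(names)) != len(names):
            raise ValueError("duplicate protocol names in library")

    def __len__(self):
        return len(self.protocols)

    def get(self, full_name: str) -> TractProtocol:
        for p in self.protocols:
            if p.full_name == full_name:
                return p
        raise KeyError(full_name)

    def names(self) -> list[str]:
        return [p.full_name for p in self.protocols]

    def count_by_provenance(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.protocols:
            out[p.provenance] = out.get(p.provenance, 0) + 1
        return out


def amf_seed_mask(fld: OrientationField, slab: MaskVolume, angle_deg: float = 25.0,
                  min_fraction: float = 0.5) -> MaskVolume:
    """Anterior-posterior coherence seed for the amygdalofugal protocol.

    Voxels inside the sub-commissural slab whose dominant fibre population
    is within ``angle_deg`` of the anterior-posterior axis with volume
    fraction at least ``min_fraction`` — an orientation-based stand-in for
    a "high anterior-posterior fractional anisotropy" seed rule.
    """
    fld.grid.require_same(slab.grid)
    dom = np.argmax(fld.fractions, axis=-1)
    ii, jj, kk = np.indices(fld.grid.shape)
    f = fld.fractions[ii, jj, kk, dom]
    d = fld.mean_directions[ii, jj, kk, dom]
    ap = np.zeros(3)
    ap[1] = 1.0
    ap_world = fld.grid.affine[:3, :3] @ ap
    ap_world /= np.linalg.norm(ap_world)
    cosang = np.abs(d @ ap_world)
    keep = slab.membership & (f >= min_fraction) & (cosang >= np.cos(np.radians(angle_deg)))
    return MaskVolume(fld.grid, keep, label=f"amf_seed_{slab.label[-1]}" if slab.label else "amf_seed")


def _u(masks: dict[str, MaskVolume], *names: str) -> MaskVolume:
    return MaskVolume.union_all([masks[n] for n in names], label="|".join(names))


def load_library(atlas: GreyMatterAtlas, masks: dict[str, MaskVolume],
                 fld: OrientationField | None = None, species: str = "") -> ProtocolLibrary:
    """Bind the 23-tract library to a species atlas and mask set.

    Missing mask names raise an error listing them.  The amygdalofugal
    seed is derived from the orientation field when one is supplied,
    otherwise a precomputed ``amf_seed_{l,r}`` mask must be present.
    """
    required = ["midsagittal", "genu_plane", "dorsal_slab", "uf_posterior_plane", "ac_body"]
    for h in "lr":
        required += [f"{n}_{h}" for n in
                     ("frontal", "occipital", "sensorimotor", "parietal", "temporal",
                      "temporal_pole", "insula", "putamen", "caudate", "thalamus",
                      "hippocampus", "amygdala", "mb_seed", "mb_target", "mb_stop",
                      "fornix_target", "uf_seed", "hemisphere")]
        if fld is None:
            required.append(f"amf_seed_{h}")
        else:
            required.append(f"subcommissural_slab_{h}")
    missing = sorted(n for n in required if n not in masks)
    if missing:
        raise KeyError(f"atlas mask set is missing protocol masks: {missing}")

    subcortex = {h: _u(masks, *(f"{n}_{hh}" for n in
                                ("putamen", "caudate", "thalamus", "hippocampus", "amygdala")
                                for hh in "lr"))
                 for h in "lr"}  # same union either way; keyed for symmetry

    protocols: list[TractProtocol] = []
    stb_zone = {"StBf": "frontal", "StBm": "sensorimotor", "StBp": "parietal", "StBt": "temporal"}
    emc_zone = {"EmCf": "frontal", "EmCp": "parietal", "EmCt": "temporal"}

    for h in "lr":
        contra = "r" if h == "l" else "l"
        # striatal bundle parts: putamen target; exclusions share a midsagittal
        # plane, the subcortex except the putamen, the occipital lobe, and the
        # seeds of every sibling part
        for name, zone in stb_zone.items():
            siblings = [f"{z}_{h}" for nm, z in stb_zone.items() if nm != name]
            excl = MaskVolume.union_all(
                [masks["midsagittal"], subcortex[h].minus(masks[f"putamen_{h}"]),
                 masks[f"occipital_{h}"]] + [masks[s] for s in siblings],
                label=f"{name}_{h}_exclusion")
            protocols.append(TractProtocol(
                name=name, hemisphere=h, seed=masks[f"{zone}_{h}"],
                waypoints=[masks[f"putamen_{h}"]], exclusion=excl, provenance="new"))
        # extreme capsule parts: insula target, same seeds as the matching StB part
        for name, zone in emc_zone.items():
            siblings = [f"{z}_{h}" for nm, z in emc_zone.items() if nm != name]
            excl = MaskVolume.union_all(
                [masks["midsagittal"], subcortex[h], masks[f"occipital_{h}"]]
                + [masks[s] for s in siblings],
                label=f"{name}_{h}_exclusion")
            protocols.append(TractProtocol(
                name=name, hemisphere=h, seed=masks[f"{zone}_{h}"],
                waypoints=[masks[f"insula_{h}"]], exclusion=excl, provenance="new"))
        # Muratoff bundle: white matter adjacent to the caudate head seeds,
        # target adjacent to the tail, stop beyond the target
        mb_excl = MaskVolume.union_all(
            [masks[f"hemisphere_{contra}"], subcortex[h].minus(masks[f"caudate_{h}"]),
             masks[f"occipital_{h}"], masks[f"frontal_{h}"], masks[f"parietal_{h}"],
             masks[f"temporal_{h}"]],
            label=f"MB_{h}_exclusion")
        protocols.append(TractProtocol(
            name="MB", hemisphere=h, seed=masks[f"mb_seed_{h}"],
            waypoints=[masks[f"mb_target_{h}"]], exclusion=mb_excl,
            stop=masks[f"mb_stop_{h}"], provenance="new"))
        # amygdalofugal pathway: orientation-coherence seed, target plane at
        # the level of the caudal genu, dorsal and midline exclusions
        amf_seed = (amf_seed_mask(fld, masks[f"subcommissural_slab_{h}"])
                    if fld is not None else masks[f"amf_seed_{h}"])
        if amf_seed.n_voxels == 0:
            raise ValueError(f"AMF seed ({h}): no voxels satisfy the coherence rule")
        amf_excl = MaskVolume.union_all(
            [masks["dorsal_slab"], masks["midsagittal"], masks[f"occipital_{h}"]],
            label=f"AMF_{h}_exclusion")
        protocols.append(TractProtocol(
            name="AMF", hemisphere=h, seed=amf_seed,
            waypoints=[masks["genu_plane"]], exclusion=amf_excl, provenance="new"))
        # uncinate fasciculus (revised): anterior temporal seed, genu-level
        # target, basal-ganglia / posterior-plane / dorsal exclusions
        uf_excl = MaskVolume.union_all(
            [masks[f"putamen_{h}"], masks[f"caudate_{h}"], masks[f"thalamus_{h}"],
             masks["uf_posterior_plane"], masks["dorsal_slab"], masks["midsagittal"]],
            label=f"UF_{h}_exclusion")
        protocols.append(TractProtocol(
            name="UF", hemisphere=h, seed=masks[f"uf_seed_{h}"],
            waypoints=[masks["genu_plane"]], exclusion=uf_excl, provenance="revised"))
        # fornix (revised): hippocampal seed with an amygdala exclusion
        fx_excl = MaskVolume.union_all(
            [masks[f"amygdala_{h}"], masks[f"occipital_{h}"]],
            label=f"FX_{h}_exclusion")
        protocols.append(TractProtocol(
            name="FX", hemisphere=h, seed=masks[f"hippocampus_{h}"],
            waypoints=[masks[f"fornix_target_{h}"]], exclusion=fx_excl, provenance="revised"))

    # anterior commissure (revised, commissural): temporal pole seed, ordered
    # mid-body waypoint then contralateral pole, averaged over flipped runs
    ac_excl = MaskVolume.union_all(
        [masks["dorsal_slab"], masks["occipital_l"], masks["occipital_r"]],
        label="AC_exclusion")
    protocols.append(TractProtocol(
        name="AC", hemisphere="commissural", seed=masks["temporal_pole_l"],
        waypoints=[masks["ac_body"], masks["temporal_pole_r"]],
        exclusion=ac_excl, reverse_and_average=True, ordered_waypoints=True,
        provenance="revised"))
    return ProtocolLibrary(protocols=protocols, species=species)


def reference_protocols(atlas: GreyMatterAtlas, masks: dict[str, MaskVolume]) -> list[TractProtocol]:
    """Additional reference tracts used to widen blueprint columns.

    One cortico-subcortical thalamic radiation (ATR) and four
    cortico-cortical association/limbic bundles (CING, SLF, IFO, ILF) per
    hemisphere.  These are not part of the 23-tract library; they provide
    the cortico-cortical contrast set for divergence analyses.
    """
    out = []
    for h in "lr":
        excl = _u(masks, "midsagittal")
        out.append(TractProtocol(
            name="ATR", hemisphere=h, seed=masks[f"thalamus_{h}"],
            waypoints=[masks[f"dmpfc_{h}"]], exclusion=None,
            provenance="reference", tract_class="cs"))
        for name, seed, target in (("CING", f"vmpfc_{h}", f"parietal_{h}"),
                                   ("SLF", f"frontal_{h}", f"parietal_{h}"),
                                   ("IFO", f"frontal_{h}", f"occipital_{h}"),
                                   ("ILF", f"temporal_{h}", f"occipital_{h}")):
            out.append(TractProtocol(
                name=name, hemisphere=h, seed=masks[seed],
                waypoints=[masks[target]], exclusion=None,
                provenance="reference", tract_class="cc"))
    return out


def execute_tract(fld: OrientationField, protocol: TractProtocol,
                  params: TrackingParams) -> tuple[PathDistribution, dict]:
    """Run one protocol; flipped seed/target runs are averaged when flagged."""
    pd, tally = run_seed_region(fld, protocol.seed, protocol.constraints(), params,
                                tract_name=protocol.full_name)
    if not protocol.reverse_and_average:
        return pd, tally
    if not protocol.waypoints:
        raise ValueError("reverse_and_average requires at least one waypoint")
    rev_seed = protocol.waypoints[-1]
    rev_waypoints = protocol.waypoints[:-1] + [protocol.seed]
    rev = Constraints(waypoints=rev_waypoints, exclusion=protocol.exclusion,
                      stop=protocol.stop, ordered_waypoints=protocol.ordered_waypoints)
    pd2, tally2 = run_seed_region(fld, rev_seed, rev, params,
                                  tract_name=protocol.full_name + ":reversed")
    for p, t in ((pd, tally), (pd2, tally2)):
        if p.n_valid == 0:
            warnings.warn(f"{protocol.full_name}: a direction produced no valid "
                          "streamlines; it contributes zeros to the average")
    avg = PathDistribution(fld.grid, (pd.values + pd2.values) / 2.0,
                           pd.n_valid + pd2.n_valid, tract_name=protocol.full_name,
                           params=pd.params)
    merged = {k: tally.get(k, 0) + tally2.get(k, 0) for k in ("VALID", "EXCLUDED", "WAYPOINT_FAIL")}
    merged["terminations"] = {k: tally["terminations"][k] + tally2["terminations"][k]
                              for k in tally["terminations"]}
    return avg, merged


def run_library(fld: OrientationField, protocols: list[TractProtocol],
                params: TrackingParams) -> dict[str, PathDistribution]:
    """Execute a list of protocols, returning path distributions by name."""
    out = {}
    for p in protocols:
        pd, _ = execute_tract(fld, p, params)
        out[p.full_name] = pd
    return out


def group_average(distributions: list[PathDistribution], pre_threshold: float = 0.001) -> ScalarVolume:
    """Threshold each subject's distribution, then average voxelwise."""
    if not distributions:
        raise ValueError("group_average of an empty list")
    grid = distributions[0].grid
    acc = np.zeros(grid.shape)
    for pd in distributions:
        grid.require_same(pd.grid)
        acc += threshold_distribution(pd, pre_threshold).values
    return ScalarVolume(grid, acc / len(distributions))


def weighted_centroid(pd: PathDistribution) -> np.ndarray:
    """Centroid of a path distribution in voxel coordinates."""
    w = pd.values
    tot = w.sum()
    if tot <= 0:
        raise ValueError("cannot take centroid of an empty distribution")
    idx = np.indices(pd.grid.shape)
    return np.array([float((idx[a] * w).sum() / tot) for a in range(3)])


def check_topology(stbf: PathDistribution, emcf: PathDistribution, mb: PathDistribution,
                   caudate_head: MaskVolume, hemisphere: str = "l") -> dict:
    """Relative-positioning report for the frontal capsule bundles.

    Checks the medio-lateral separation (striatal bundle medial to the
    extreme capsule) and that the Muratoff bundle runs dorsal to the
    caudate head.  Medial direction is +x in the left hemisphere, -x in
    the right.
    """
    for pd in (stbf, emcf, mb):
        if pd.values.sum() <= 0:
            raise ValueError("empty path distribution in topology check")
    c_stbf = weighted_centroid(stbf)
    c_emcf = weighted_centroid(emcf)
    c_mb = weighted_centroid(mb)
    head_idx = caudate_head.voxel_indices()
    c_head = head_idx.mean(axis=0)
    medial_sign = 1.0 if hemisphere == "l" else -1.0
    return {
        "stbf_centroid": c_stbf, "emcf_centroid": c_emcf,
        "mb_centroid": c_mb, "caudate_head_centroid": c_head,
        "stbf_medial_to_emcf": bool(medial_sign * (c_stbf[0] - c_emcf[0]) > 0),
        "mb_dorsal_to_caudate_head": bool(c_mb[2] > c_head[2]),
    }


# -----------------------------------------------------------------------------
# on-disk protocol layout: one directory per tract
# -----------------------------------------------------------------------------

def save_protocol(protocol: TractProtocol, out_dir: str | Path):
    out = Path(out_dir) / protocol.full_name
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "name": protocol.name, "hemisphere": protocol.hemisphere,
        "reverse_and_average": protocol.reverse_and_average,
        "ordered_waypoints": protocol.ordered_waypoints,
        "provenance": protocol.provenance, "tract_class": protocol.tract_class,
        "seed": "seed.nii.gz",
        "waypoints": [f"waypoint{i}.nii.gz" for i in range(len(protocol.waypoints))],
        "exclusion": "exclusion.nii.gz" if protocol.exclusion is not None else None,
        "stop": "stop.nii.gz" if protocol.stop is not None else None,
    }
    write_volume(protocol.seed, out / "seed.nii.gz")
    for i, w in enumerate(protocol.waypoints):
        write_volume(w, out / f"waypoint{i}.nii.gz")
    if protocol.exclusion is not None:
        write_volume(protocol.exclusion, out / "exclusion.nii.gz")
    if protocol.stop is not None:
        write_volume(protocol.stop, out / "stop.nii.gz")
    (out / "protocol.json").write_text(json.dumps(meta, indent=1))


def load_protocol(in_dir: str | Path) -> TractProtocol:
    src = Path(in_dir)
    meta = json.loads((src / "protocol.json").read_text())
    seed = read_volume(src / meta["seed"])
    wps = [read_volume(src / w) for w in meta["waypoints"]]
    excl = read_volume(src / meta["exclusion"]) if meta["exclusion"] else None
    stop = read_volume(src / meta["stop"]) if meta["stop"] else None
    return TractProtocol(name=meta["name"], hemisphere=meta["hemisphere"], seed=seed,
                         waypoints=wps, exclusion=excl, stop=stop,
                         reverse_and_average=meta["reverse_and_average"],
                         ordered_waypoints=meta["ordered_waypoints"],
                         provenance=meta["provenance"], tract_class=meta["tract_class"])
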