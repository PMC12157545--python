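"""Synthetic fibre-orientation phantoms.

The phantom emulates the structure tractography needs, at desk scale:

* a brain box with a two-voxel cortical ribbon and an interior white
  matter compartment;
* five subcortical nuclei per hemisphere (caudate, putamen, thalamus,
  hippocampus, amygdala), pairwise disjoint;
* a library of fibre bundles as curved tubes of coherent orientation
  (with bounded angular dispersion in the per-population samples),
  crossing freely with at most three populations per voxel;
* four striatal-bundle parts terminating in distinct putamen sectors
  ordered along a dorsolateral-to-ventromedial axis;
* two geometrically different "species" sharing bundle topology; and
* subject cohorts with family (twin) structure, built by perturbing the
  base field with smooth random rotations that are partially shared
  within pairs.

All geometry is laid out in fractional coordinates of the grid so the
same topology renders at any resolution.  Generation is fully
deterministic from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .core import GreyMatterAtlas, MaskVolume, VolumeGrid
from .field import MAX_POPULATIONS, OrientationField

Frac = tuple[float, float]


@dataclass
class BundleSpec:
    """One fibre bundle: a tube of given radius around a centreline."""

    name: str
    control_points: np.ndarray     # (k, 3) fractional coordinates
    radius_mm: float
    endpoints: tuple[str, str]     # (origin region, terminus region)
    tract_class: str = "cs"        # "cs" cortico-subcortical, "cc" cortico-cortical
    peak_fraction: float = 0.55
    nucleus: str | None = None     # generator-assigned terminal nucleus, if any

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        if len(self.control_points) < 2:
            raise ValueError(f"bundle {self.name}: need >= 2 control points")
        if self.radius_mm <= 0:
            raise ValueError(f"bundle {self.name}: radius must be positive")
        if ((self.control_points < 0) | (self.control_points > 1)).any():
            raise ValueError(f"bundle {self.name}: centreline leaves the grid")


@dataclass
class PhantomSpec:
    grid: VolumeGrid
    bundles: list[BundleSpec]
    nuclei: dict[str, tuple[Frac, Frac, Frac]]
    zones: dict[str, tuple[Frac, Frac, Frac]]
    aux_boxes: dict[str, tuple[Frac, Frac, Frac]]
    rng_seed: int
    species: str = "speciesA"
    ribbon_thickness: int = 2
    n_samples: int = 8
    dispersion_deg: float = 10.0
    cortical_decimation: int = 2
    brain_box: tuple[Frac, Frac, Frac] = ((0.05, 0.95), (0.04, 0.96), (0.05, 0.95))

    def __post_init__(self):
        if self.rng_seed is None:
            raise ValueError("phantom generation requires an explicit rng_seed")


@dataclass
class Phantom:
    field: OrientationField
    masks: dict[str, MaskVolume]
    atlas: GreyMatterAtlas
    ground_truth: dict
    spec: PhantomSpec


# -----------------------------------------------------------------------------
# geometry helpers
# -----------------------------------------------------------------------------

def _box_mask(grid: VolumeGrid, fx: Frac, fy: Frac, fz: Frac, label="") -> MaskVolume:
    m = np.zeros(grid.shape, dtype=bool)
    sl = []
    for (lo, hi), n in zip((fx, fy, fz), grid.shape):
        a = int(round(lo * (n - 1)))
        b = int(round(hi * (n - 1)))
        sl.append(slice(a, b + 1))
    m[sl[0], sl[1], sl[2]] = True
    return MaskVolume(grid, m, label=label)


def _mirror_fracs(box):
    (x0, x1), fy, fz = box
    return ((1 - x1, 1 - x0), fy, fz)


def _mirror_points(points: np.ndarray) -> np.ndarray:
    out = points.copy()
    out[:, 0] = 1 - out[:, 0]
    return out


def _centreline_voxels(spec: PhantomSpec, b: BundleSpec):
    """Dense centreline samples and unit tangents, in voxel coordinates."""
    shape = np.asarray(spec.grid.shape, dtype=float)
    pts = b.control_points * (shape - 1)
    chord = np.r_[0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    if chord[-1] == 0:
        raise ValueError(f"bundle {b.name}: degenerate centreline")
    cs = CubicSpline(chord, pts, axis=0)
    s = np.append(np.arange(0, chord[-1], 0.25), chord[-1])
    line = cs(s)
    tang = cs(s, 1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return line, tang


# -----------------------------------------------------------------------------
# default layouts
# -----------------------------------------------------------------------------

def _left_layout():
    """Left-hemisphere structure boxes and bundle centrelines (fractions)."""
    nuclei = {
        "putamen_l":      ((0.30, 0.385), (0.40, 0.60), (0.35, 0.60)),
        "caudate_head_l": ((0.41, 0.48), (0.55, 0.72), (0.50, 0.65)),
        "caudate_tail_l": ((0.41, 0.48), (0.22, 0.38), (0.50, 0.65)),
        "thalamus_l":     ((0.41, 0.48), (0.38, 0.50), (0.32, 0.46)),
        "hippocampus_l":  ((0.25, 0.38), (0.18, 0.32), (0.18, 0.28)),
        "amygdala_l":     ((0.25, 0.36), (0.52, 0.62), (0.18, 0.28)),
    }
    zones = {
        "frontal_l":       ((0.05, 0.47), (0.80, 0.96), (0.05, 0.95)),
        "occipital_l":     ((0.05, 0.47), (0.04, 0.135), (0.05, 0.95)),
        "sensorimotor_l":  ((0.05, 0.47), (0.46, 0.75), (0.82, 0.95)),
        "parietal_l":      ((0.05, 0.47), (0.155, 0.445), (0.82, 0.95)),
        "temporal_l":      ((0.05, 0.35), (0.155, 0.775), (0.05, 0.16)),
        "temporal_pole_l": ((0.05, 0.35), (0.55, 0.775), (0.05, 0.16)),
        "insula_l":        ((0.05, 0.10), (0.35, 0.65), (0.35, 0.65)),
        "dmpfc_l":         ((0.30, 0.47), (0.87, 0.96), (0.60, 0.95)),
        "vmpfc_l":         ((0.36, 0.47), (0.87, 0.96), (0.25, 0.55)),
        "ofcr_l":          ((0.15, 0.45), (0.87, 0.96), (0.05, 0.20)),
        "fop_l":           ((0.05, 0.14), (0.87, 0.96), (0.25, 0.60)),
    }
    aux = {
        "mb_seed_l":       ((0.42, 0.47), (0.76, 0.83), (0.60, 0.72)),
        "mb_target_l":     ((0.42, 0.47), (0.14, 0.21), (0.52, 0.66)),
        "mb_stop_l":       ((0.40, 0.49), (0.04, 0.13), (0.45, 0.75)),
        "fornix_target_l": ((0.44, 0.49), (0.26, 0.34), (0.70, 0.78)),
        "uf_seed_l":       ((0.24, 0.34), (0.62, 0.74), (0.04, 0.12)),
        "subcommissural_slab_l": ((0.30, 0.45), (0.64, 0.76), (0.20, 0.32)),
    }
    # putamen sector terminals, dorsolateral (low x, high z) to
    # ventromedial (high x, low z); order StBp, StBm, StBf, StBt
    stb_ends = {
        "StBp": (0.315, 0.47, 0.565),
        "StBm": (0.340, 0.50, 0.500),
        "StBf": (0.355, 0.50, 0.450),
        "StBt": (0.375, 0.48, 0.400),
    }
    bundles = {
        "StBf": dict(points=[(0.30, 0.92, 0.12), (0.32, 0.75, 0.25), (0.35, 0.62, 0.40),
                             stb_ends["StBf"]],
                     endpoints=("frontal", "putamen"), nucleus="putamen"),
        "StBm": dict(points=[(0.34, 0.60, 0.93), (0.33, 0.55, 0.72), stb_ends["StBm"]],
                     endpoints=("sensorimotor", "putamen"), nucleus="putamen"),
        "StBp": dict(points=[(0.315, 0.30, 0.93), (0.315, 0.38, 0.75), stb_ends["StBp"]],
                     endpoints=("parietal", "putamen"), nucleus="putamen"),
        "StBt": dict(points=[(0.30, 0.35, 0.07), (0.34, 0.40, 0.20), (0.37, 0.45, 0.31),
                             stb_ends["StBt"]],
                     endpoints=("temporal", "putamen"), nucleus="putamen"),
        "EmCf": dict(points=[(0.12, 0.92, 0.40), (0.09, 0.75, 0.42), (0.08, 0.62, 0.45),
                             (0.07, 0.55, 0.50)],
                     endpoints=("frontal", "insula")),
        "EmCp": dict(points=[(0.12, 0.30, 0.93), (0.08, 0.35, 0.70), (0.07, 0.45, 0.55)],
                     endpoints=("parietal", "insula")),
        "EmCt": dict(points=[(0.12, 0.35, 0.07), (0.08, 0.40, 0.30), (0.07, 0.48, 0.42)],
                     endpoints=("temporal", "insula")),
        "MB":   dict(points=[(0.445, 0.79, 0.65), (0.445, 0.70, 0.62), (0.445, 0.60, 0.70),
                             (0.445, 0.40, 0.72), (0.445, 0.28, 0.70), (0.445, 0.18, 0.60)],
                     endpoints=("caudate_head_wm", "caudate_tail_wm"), nucleus="caudate"),
        "AMF":  dict(points=[(0.30, 0.57, 0.23), (0.37, 0.66, 0.26), (0.39, 0.80, 0.29),
                             (0.42, 0.93, 0.40)],
                     endpoints=("amygdala", "vmpfc"), nucleus="amygdala"),
        "UF":   dict(points=[(0.30, 0.68, 0.07), (0.26, 0.80, 0.10), (0.25, 0.90, 0.12),
                             (0.28, 0.94, 0.13)],
                     endpoints=("temporal_pole", "ofcr")),
        "FX":   dict(points=[(0.315, 0.25, 0.23), (0.38, 0.18, 0.38), (0.43, 0.16, 0.58),
                             (0.455, 0.22, 0.72), (0.465, 0.30, 0.74)],
                     endpoints=("hippocampus", "fornix_target"), nucleus="hippocampus"),
        "ATR":  dict(points=[(0.445, 0.44, 0.39), (0.445, 0.62, 0.42), (0.445, 0.82, 0.48),
                             (0.43, 0.89, 0.64), (0.41, 0.93, 0.75)],
                     endpoints=("thalamus", "dmpfc"), nucleus="thalamus", tract_class="cs"),
        "CING": dict(points=[(0.43, 0.93, 0.40), (0.45, 0.90, 0.62), (0.465, 0.72, 0.80),
                             (0.465, 0.45, 0.80), (0.46, 0.25, 0.92)],
                     endpoints=("vmpfc", "parietal"), tract_class="cc"),
        "SLF":  dict(points=[(0.15, 0.92, 0.70), (0.12, 0.75, 0.80), (0.12, 0.50, 0.82),
                             (0.13, 0.30, 0.92)],
                     endpoints=("frontal", "parietal"), tract_class="cc"),
        "IFO":  dict(points=[(0.20, 0.92, 0.45), (0.26, 0.70, 0.45), (0.28, 0.50, 0.45),
                             (0.25, 0.30, 0.45), (0.22, 0.07, 0.45)],
                     endpoints=("frontal", "occipital"), tract_class="cc"),
        "ILF":  dict(points=[(0.24, 0.60, 0.07), (0.225, 0.45, 0.16), (0.235, 0.28, 0.20),
                             (0.22, 0.07, 0.20)],
                     endpoints=("temporal", "occipital"), tract_class="cc"),
    }
    return nuclei, zones, aux, bundles, stb_ends


SPECIES_GRIDS = {
    "human": dict(shape=(48, 56, 40), voxel_mm=1.0, radius_mm=1.9, step_mm=0.5),
    "macaque": dict(shape=(40, 44, 32), voxel_mm=0.5, radius_mm=0.85, step_mm=0.2),
}


def default_spec(species: str = "human", rng_seed: int = 0, n_samples: int = 8,
                 dispersion_deg: float = 10.0) -> PhantomSpec:
    """Default two-hemisphere phantom layout for one of the shipped species."""
    if species not in SPECIES_GRIDS:
        raise ValueError(f"unknown species '{species}'; options: {sorted(SPECIES_GRIDS)}")
    g = SPECIES_GRIDS[species]
    grid = VolumeGrid.isotropic(g["shape"], g["voxel_mm"])
    nuclei_l, zones_l, aux_l, bundles_l, _ = _left_layout()

    nuclei = dict(nuclei_l)
    zones = dict(zones_l)
    aux = dict(aux_l)
    for name, box in list(nuclei_l.items()):
        nuclei[name[:-2] + "_r"] = _mirror_fracs(box)
    for name, box in list(zones_l.items()):
        zones[name[:-2] + "_r"] = _mirror_fracs(box)
    for name, box in list(aux_l.items()):
        aux[name[:-2] + "_r"] = _mirror_fracs(box)
    aux["midsagittal"] = ((0.48, 0.52), (0.04, 0.96), (0.05, 0.95))
    aux["genu_plane"] = ((0.05, 0.95), (0.80, 0.84), (0.05, 0.95))
    aux["dorsal_slab"] = ((0.05, 0.95), (0.04, 0.96), (0.60, 0.95))
    aux["uf_posterior_plane"] = ((0.05, 0.95), (0.50, 0.55), (0.05, 0.95))
    aux["ac_body"] = ((0.44, 0.56), (0.60, 0.70), (0.26, 0.34))
    aux["hemisphere_l"] = ((0.0, 0.479), (0.0, 1.0), (0.0, 1.0))
    aux["hemisphere_r"] = ((0.521, 1.0), (0.0, 1.0), (0.0, 1.0))

    bundles = []
    for name, d in bundles_l.items():
        pts = np.asarray(d["points"], dtype=float)
        for hemi, p in (("l", pts), ("r", _mirror_points(pts))):
            bundles.append(BundleSpec(
                name=f"{name}_{hemi}", control_points=p, radius_mm=g["radius_mm"],
                endpoints=d["endpoints"], tract_class=d.get("tract_class", "cs"),
                nucleus=(d.get("nucleus") + f"_{hemi}") if d.get("nucleus") else None))
    ac = np.array([(0.30, 0.68, 0.07), (0.33, 0.60, 0.22), (0.50, 0.64, 0.30),
                   (0.67, 0.60, 0.22), (0.70, 0.68, 0.07)])
    bundles.append(BundleSpec(name="AC", control_points=ac, radius_mm=g["radius_mm"],
                              endpoints=("temporal_pole_l", "temporal_pole_r"),
                              tract_class="cs", nucleus=None))
    return PhantomSpec(grid=grid, bundles=bundles, nuclei=nuclei, zones=zones,
                       aux_boxes=aux, rng_seed=rng_seed, species=species,
                       n_samples=n_samples, dispersion_deg=dispersion_deg)


# -----------------------------------------------------------------------------
# phantom construction
# -----------------------------------------------------------------------------

def _random_perpendicular(rg: np.random.Generator, v: np.ndarray) -> np.ndarray:
    """Uniform random unit vectors perpendicular to each row of v."""
    helper = np.zeros_like(v)
    smallest = np.argmin(np.abs(v), axis=1)
    helper[np.arange(len(v)), smallest] = 1.0
    e1 = np.cross(v, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(v, e1)
    phi = rg.uniform(0, 2 * np.pi, size=len(v))
    return e1 * np.cos(phi)[:, None] + e2 * np.sin(phi)[:, None]


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of unit vectors v about unit axes by given angles."""
    c = np.cos(angle)[..., None]
    s = np.sin(angle)[..., None]
    return (v * c + np.cross(axis, v) * s
            + axis * np.einsum("...j,...j->...", axis, v)[..., None] * (1 - c))


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Render a PhantomSpec into a field, masks, atlas and ground truth."""
    grid = spec.grid
    shape = grid.shape
    vox_mm = float(np.mean(grid.voxel_size_mm))
    rg = np.random.default_rng(spec.rng_seed)

    # ---- structural masks ---------------------------------------------------
    masks: dict[str, MaskVolume] = {}
    brain = _box_mask(grid, *spec.brain_box, label="brain")
    interior = ndimage.binary_erosion(
        brain.membership, ndimage.generate_binary_structure(3, 1),
        iterations=spec.ribbon_thickness)
    ribbon = MaskVolume(grid, brain.membership & ~interior, label="ribbon")
    masks["brain"] = brain
    masks["ribbon"] = ribbon
    for name, box in spec.nuclei.items():
        masks[name] = _box_mask(grid, *box, label=name)
    for name, box in spec.zones.items():
        m = _box_mask(grid, *box, label=name)
        m.membership &= ribbon.membership
        masks[name] = m
    for name, box in spec.aux_boxes.items():
        m = _box_mask(grid, *box, label=name)
        m.membership &= brain.membership
        masks[name] = m
    if "caudate_head_l" in masks:
        for h in "lr":
            masks[f"caudate_{h}"] = masks[f"caudate_head_{h}"].union(
                masks[f"caudate_tail_{h}"])
            masks[f"caudate_{h}"].label = f"caudate_{h}"
    nuclei_union = np.zeros(shape, dtype=bool)
    for name in spec.nuclei:
        nuclei_union |= masks[name].membership
    wm = MaskVolume(grid, interior & ~nuclei_union, label="wm")
    masks["wm"] = wm

    # ---- bundle tubes -> orientation populations ----------------------------
    vox_idx = np.indices(shape).reshape(3, -1).T.astype(float)
    contrib_f = np.zeros((len(spec.bundles), vox_idx.shape[0]), dtype=np.float32)
    contrib_d = np.zeros((len(spec.bundles), vox_idx.shape[0], 3), dtype=np.float32)
    tube_masks: dict[str, np.ndarray] = {}
    radius_vox_by_bundle = {}
    for bi, b in enumerate(spec.bundles):
        line, tang = _centreline_voxels(spec, b)
        r_vox = b.radius_mm / vox_mm
        radius_vox_by_bundle[b.name] = r_vox
        lo = np.maximum(line.min(axis=0) - r_vox - 1, 0).astype(int)
        hi = np.minimum(line.max(axis=0) + r_vox + 2, shape).astype(int)
        sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
        tree = cKDTree(line)
        dist, nearest = tree.query(sub.astype(float), distance_upper_bound=r_vox)
        inside = np.isfinite(dist) & (dist <= r_vox)
        if not inside.any():
            raise ValueError(f"bundle {b.name}: tube covers no voxels at this resolution")
        subin = sub[inside]
        flat = (subin[:, 0] * shape[1] + subin[:, 1]) * shape[2] + subin[:, 2]
        occupancy = 1.0 - (dist[inside] / r_vox) ** 2
        frac = b.peak_fraction * (0.4 + 0.6 * occupancy)
        contrib_f[bi, flat] = frac
        contrib_d[bi, flat] = tang[nearest[inside]]
        tube = np.zeros(shape, dtype=bool)
        tube[subin[:, 0], subin[:, 1], subin[:, 2]] = True
        tube_masks[b.name] = tube

    # keep the three largest-fraction populations per voxel (excess dropped),
    # then scale so fractions sum to at most 0.95
    nvox = vox_idx.shape[0]
    if len(spec.bundles) < MAX_POPULATIONS:
        pad = MAX_POPULATIONS - len(spec.bundles)
        contrib_f = np.concatenate([contrib_f, np.zeros((pad, nvox), dtype=np.float32)])
        contrib_d = np.concatenate([contrib_d, np.zeros((pad, nvox, 3), dtype=np.float32)])
    order = np.argsort(-contrib_f, axis=0)[:MAX_POPULATIONS]
    fr = np.take_along_axis(contrib_f, order, axis=0).T.astype(float)     # (nvox, 3)
    dirs = np.transpose(contrib_d[order, np.arange(nvox)[None, :], :], (1, 0, 2)).astype(float)
    total = fr.sum(axis=1)
    scale = np.where(total > 0.95, 0.95 / np.maximum(total, 1e-12), 1.0)
    fr *= scale[:, None]
    norms = np.linalg.norm(dirs, axis=2)
    present = fr > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(present[..., None], dirs / np.where(norms[..., None] > 0, norms[..., None], 1.0), 0.0)

    # orientation samples: mean rotated by a uniform angle within the
    # dispersion half-angle, about a uniform random perpendicular axis
    S = spec.n_samples
    theta_max = np.radians(spec.dispersion_deg)
    samples = np.zeros((nvox, MAX_POPULATIONS, S, 3))
    flat_present = np.argwhere(present)
    v = dirs[flat_present[:, 0], flat_present[:, 1]]
    for s in range(S):
        axis = _random_perpendicular(rg, v)
        ang = rg.uniform(0, theta_max, size=len(v))
        samples[flat_present[:, 0], flat_present[:, 1], s] = _rotate_about(v, axis, ang)

    fld = OrientationField(
        grid,
        dirs.reshape(*shape, MAX_POPULATIONS, 3),
        fr.reshape(*shape, MAX_POPULATIONS),
        samples.reshape(*shape, MAX_POPULATIONS, S, 3),
    )

    # ---- atlas --------------------------------------------------------------
    struct = ndimage.generate_binary_structure(3, 1)
    adj_wm = ndimage.binary_dilation(wm.membership, structure=struct) & ribbon.membership
    dec = spec.cortical_decimation
    idxs = np.argwhere(adj_wm)
    keep = (idxs % dec == 0).all(axis=1) if dec > 1 else np.ones(len(idxs), dtype=bool)
    mid = (shape[0] - 1) / 2.0
    elements = [((int(i), int(j), int(k)), "l" if i < mid else "r")
                for i, j, k in idxs[keep]]
    nuclei_masks = {n: masks[n] for n in spec.nuclei}
    atlas = GreyMatterAtlas(grid=grid, cortical_elements=elements,
                            subcortical_nuclei=nuclei_masks, wm_mask=wm,
                            zones={n: masks[n] for n in spec.zones})

    # ---- ground truth -------------------------------------------------------
    gt = _ground_truth(spec, masks, tube_masks)
    gt["mask_voxel_counts"] = {n: m.n_voxels for n, m in masks.items()}
    gt["tube_masks"] = {n: MaskVolume(grid, m, label=f"tube_{n}") for n, m in tube_masks.items()}
    gt["bundle_nucleus"] = {b.name: b.nucleus for b in spec.bundles if b.nucleus}
    gt["tract_class"] = {b.name: b.tract_class for b in spec.bundles}
    return Phantom(field=fld, masks=masks, atlas=atlas, ground_truth=gt, spec=spec)


def _ground_truth(spec, masks, tube_masks) -> dict:
    """Putamen sectors by nearest StB terminal, ordered dorsolateral->ventromedial."""
    gt: dict = {}
    shape = np.asarray(spec.grid.shape, dtype=float)
    for hemi in ("l", "r"):
        put = masks.get(f"putamen_{hemi}")
        if put is None or put.n_voxels == 0:
            continue
        parts = [f"StBp_{hemi}", f"StBm_{hemi}", f"StBf_{hemi}", f"StBt_{hemi}"]
        ends = []
        for p in parts:
            b = next(bb for bb in spec.bundles if bb.name == p)
            ends.append(b.control_points[-1] * (shape - 1))
        ends = np.array(ends)
        vox = put.voxel_indices().astype(float)
        d = np.linalg.norm(vox[:, None, :] - ends[None, :, :], axis=2)
        sector_of = np.argmin(d, axis=1)
        # dorsolateral -> ventromedial axis (medial is +x left, -x right)
        sign = 1.0 if hemi == "l" else -1.0
        axis = np.array([sign, 0.0, -1.0]) / np.sqrt(2)
        sectors = {}
        centroids = {}
        for si, p in enumerate(parts):
            m = np.zeros(spec.grid.shape, dtype=bool)
            sel = vox[sector_of == si].astype(int)
            m[sel[:, 0], sel[:, 1], sel[:, 2]] = True
            sectors[p] = MaskVolume(spec.grid, m, label=f"sector_{p}")
            centroids[p] = sel.mean(axis=0) if len(sel) else None
        ts = [float(np.dot(centroids[p], axis)) for p in parts if centroids[p] is not None]
        if any(ts[i] >= ts[i + 1] for i in range(len(ts) - 1)):
            raise RuntimeError(f"putamen sector centroids not monotone along axis ({hemi})")
        gt[f"putamen_sectors_{hemi}"] = sectors
        gt[f"sector_axis_{hemi}"] = axis
        gt[f"sector_order_{hemi}"] = parts
        gt[f"sector_centroids_{hemi}"] = centroids
    return gt


# -----------------------------------------------------------------------------
# two species
# -----------------------------------------------------------------------------

def build_two_species(spec_a: PhantomSpec, spec_b: PhantomSpec) -> tuple[Phantom, Phantom, dict]:
    """Build two phantoms sharing bundle topology; error on mismatched names."""
    names_a = {b.name for b in spec_a.bundles}
    names_b = {b.name for b in spec_b.bundles}
    if names_a != names_b:
        unmatched = sorted(names_a ^ names_b)
        raise ValueError(f"bundle topology mismatch between species: {unmatched}")
    ends_a = {b.name: b.endpoints for b in spec_a.bundles}
    ends_b = {b.name: b.endpoints for b in spec_b.bundles}
    bad = sorted(n for n in names_a if ends_a[n] != ends_b[n])
    if bad:
        raise ValueError(f"bundle endpoint mismatch between species: {bad}")
    pa, pb = build_phantom(spec_a), build_phantom(spec_b)
    table = {n: {"endpoints": ends_a[n],
                 spec_a.species: n, spec_b.species: n} for n in sorted(names_a)}
    return pa, pb, table


def default_species_pair(rng_seed: int = 0) -> tuple[Phantom, Phantom, dict]:
    return build_two_species(default_spec("human", rng_seed),
                             default_spec("macaque", rng_seed + 1))


# -----------------------------------------------------------------------------
# striatal topography phantom
# -----------------------------------------------------------------------------

def build_topography_phantom(rng_seed: int, species: str = "human") -> tuple[Phantom, dict]:
    """Phantom plus the ground-truth putamen sector ordering (left hemisphere)."""
    ph = build_phantom(default_spec(species, rng_seed))
    gt = {
        "sectors": ph.ground_truth["putamen_sectors_l"],
        "axis": ph.ground_truth["sector_axis_l"],
        "order": ph.ground_truth["sector_order_l"],
        "centroids": ph.ground_truth["sector_centroids_l"],
    }
    return ph, gt


def synthetic_tracer_injections(ph: Phantom, n_per_group: int = 60, rng_seed: int = 0,
                                hemi: str = "l") -> list[tuple[str, np.ndarray]]:
    """Synthetic anterograde-tracer termination sites within the putamen.

    For each cortical zone group, termination voxels are drawn from the
    ground-truth putamen sector that zone projects to, emulating recorded
    termination sites from cortical injections.
    """
    rg = np.random.default_rng(rng_seed)
    zone_of = {"StBf": "frontal", "StBm": "sensorimotor", "StBp": "parietal", "StBt": "temporal"}
    out = []
    for part, sector in ph.ground_truth[f"putamen_sectors_{hemi}"].items():
        vox = sector.voxel_indices()
        draw = vox[rg.integers(0, len(vox), size=n_per_group)]
        out.append((zone_of[part.rsplit("_", 1)[0]], draw))
    return out


# -----------------------------------------------------------------------------
# twin cohorts
# -----------------------------------------------------------------------------

RELATIONSHIPS = ("MZ", "DZ", "SIB", "UNREL")


@dataclass
class SubjectCohort:
    subjects: list[tuple[str, OrientationField]]
    pairs: list[tuple[str, str, str]]

    def __post_init__(self):
        ids = {s for s, _ in self.subjects}
        for a, b, rel in self.pairs:
            if rel not in RELATIONSHIPS:
                raise ValueError(f"unknown relationship '{rel}'")
            if a not in ids or b not in ids:
                raise ValueError(f"pair ({a}, {b}) references unknown subject")

    def field_of(self, sid: str) -> OrientationField:
        for s, f in self.subjects:
            if s == sid:
                return f
        raise KeyError(sid)


def _smooth_noise(rg: np.random.Generator, shape, scale: float, coarse: int = 4) -> np.ndarray:
    """Smooth scalar noise field with roughly unit variance, times scale."""
    cs = [max(2, s // coarse) for s in shape]
    coarse_noise = rg.standard_normal(cs)
    zoom = [s / c for s, c in zip(shape, cs)]
    out = ndimage.zoom(coarse_noise, zoom, order=1)
    out = out[: shape[0], : shape[1], : shape[2]]
    sd = out.std()
    return out / (sd if sd > 0 else 1.0) * scale


def _perturb_field(base: OrientationField, rot_fields: np.ndarray,
                   frac_field: np.ndarray) -> OrientationField:
    """Rotate all populations by a smooth rotation-vector field and jitter fractions."""
    shape = base.grid.shape
    present = base.fractions > 0
    rotvec = rot_fields.reshape(-1, 3)
    angle = np.linalg.norm(rotvec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(angle[:, None] > 1e-12, rotvec / np.maximum(angle[:, None], 1e-12), 0.0)
    nvox = rotvec.shape[0]
    dirs = base.mean_directions.reshape(nvox, MAX_POPULATIONS, 3).copy()
    samples = base.samples.reshape(nvox, MAX_POPULATIONS, base.n_samples, 3).copy()
    pm = present.reshape(nvox, MAX_POPULATIONS)
    vi, pi = np.nonzero(pm)
    dirs[vi, pi] = _rotate_about(dirs[vi, pi], axis[vi], angle[vi])
    for s in range(base.n_samples):
        samples[vi, pi, s] = _rotate_about(samples[vi, pi, s], axis[vi], angle[vi])
    fr = base.fractions.reshape(nvox, MAX_POPULATIONS).copy()
    gain = np.clip(1.0 + frac_field.reshape(nvox), 0.2, 1.8)
    fr = fr * gain[:, None]
    tot = fr.sum(axis=1)
    scale = np.where(tot > 0.99, 0.99 / np.maximum(tot, 1e-12), 1.0)
    fr *= scale[:, None]
    return OrientationField(base.grid, dirs.reshape(*shape, MAX_POPULATIONS, 3),
                            fr.reshape(*shape, MAX_POPULATIONS),
                            samples.reshape(*shape, MAX_POPULATIONS, base.n_samples, 3))


def build_cohort(base: PhantomSpec | OrientationField, n_pairs: Mapping[str, int],
                 shared_weights: Mapping[str, float], rng_seed: int,
                 rot_scale_deg: float = 9.0, frac_scale: float = 0.12) -> SubjectCohort:
    """Subject cohort with family structure.

    Each subject's field perturbs the base with a smooth random rotation
    field ``w * N_pair + sqrt(1 - w^2) * N_subject``: members of a pair
    share the component ``N_pair`` with weight ``w`` set by their
    relationship (1 for identical fields within a pair at w = 1, 0 for
    unrelated pairs).  The caller supplies weights ordered
    MZ >= DZ = SIB >= UNREL.
    """
    for rel, k in n_pairs.items():
        if rel not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship '{rel}'")
        if k <= 0:
            raise ValueError(f"non-positive pair count for {rel}")
    base_field = build_phantom(base).field if isinstance(base, PhantomSpec) else base
    shape = base_field.grid.shape
    rot_scale = np.radians(rot_scale_deg)
    subjects, pairs = [], []
    master = np.random.default_rng(rng_seed)
    for rel in RELATIONSHIPS:
        if rel not in n_pairs:
            continue
        w = float(shared_weights.get(rel, 0.0))
        if not 0 <= w <= 1:
            raise ValueError(f"shared weight for {rel} must lie in [0, 1]")
        wi = float(np.sqrt(max(0.0, 1.0 - w * w)))
        for p in range(n_pairs[rel]):
            rg_pair = np.random.default_rng(master.integers(0, 2**31))
            shared_rot = np.stack([_smooth_noise(rg_pair, shape, rot_scale) for _ in range(3)], axis=-1)
            shared_frac = _smooth_noise(rg_pair, shape, frac_scale)
            members = []
            for m in range(2):
                rg_subj = np.random.default_rng(master.integers(0, 2**31))
                own_rot = np.stack([_smooth_noise(rg_subj, shape, rot_scale) for _ in range(3)], axis=-1)
                own_frac = _smooth_noise(rg_subj, shape, frac_scale)
                rot = w * shared_rot + wi * own_rot
                fracs = w * shared_frac + wi * own_frac
                sid = f"{rel}{p:03d}{'ab'[m]}"
                subjects.append((sid, _perturb_field(base_field, rot, fracs)))
                members.append(sid)
            pairs.append((members[0], members[1], rel))
    return SubjectCohort(subjects=subjects, pairs=pairs)


def mini_cohort_spec(rng_seed: int = 0) -> PhantomSpec:
    """Small single-purpose phantom for cohort studies: two bundles, fast to track."""
    grid = VolumeGrid.isotropic((20, 22, 16), 1.0)
    bundles = [
        BundleSpec("assoc", np.array([(0.05, 0.5, 0.5), (0.5, 0.5, 0.55), (0.95, 0.5, 0.5)]),
                   radius_mm=1.8, endpoints=("west", "east")),
        BundleSpec("arc", np.array([(0.5, 0.05, 0.35), (0.45, 0.5, 0.75), (0.5, 0.95, 0.35)]),
                   radius_mm=1.8, endpoints=("south", "north")),
    ]
    # thick end slabs (not ribbon-restricted) so perturbed trajectories
    # still meet their targets
    aux = {
        "west_l": ((0.02, 0.22), (0.25, 0.75), (0.25, 0.80)),
        "east_l": ((0.78, 0.98), (0.25, 0.75), (0.25, 0.80)),
        "south_l": ((0.25, 0.75), (0.02, 0.22), (0.10, 0.65)),
        "north_l": ((0.25, 0.75), (0.78, 0.98), (0.10, 0.65)),
    }
    return PhantomSpec(grid=grid, bundles=bundles, nuclei={}, zones={},
                       aux_boxes=aux, rng_seed=rng_seed, species="mini",
                       n_samples=4, dispersion_deg=8.0, cortical_decimation=2,
                       brain_box=((0.02, 0.98), (0.02, 0.98), (0.05, 0.95)))
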