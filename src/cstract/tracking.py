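"""Probabilistic streamline tractography through crossing-fibre fields.

Propagation rule, applied independently per streamline:

* at the seed, a fibre population is chosen with probability proportional
  to its volume fraction among populations at or above the fraction
  threshold; one of its orientation samples is drawn and given a random
  sign;
* at each subsequent step the field is looked up at the nearest voxel
  (no interpolation of axial vectors), candidate populations are those at
  or above the fraction threshold, the candidate whose sign-aligned mean
  direction is closest to the current direction is selected, one of its
  samples is drawn and sign-aligned, and the step is rejected — the
  streamline ends as a curvature dead end — if the turning angle exceeds
  the curvature limit;
* the streamline advances a fixed step length in world millimetres and the
  new point is tested against the grid (exit = lost), the exclusion mask
  (entire streamline invalidated), waypoint masks (recorded) and the stop
  mask (point kept, propagation halts).

Every random draw is a pure function of (rng_seed, seed-voxel index,
streamline index, step, slot), so path distributions are bit-identical no
matter how streamlines are batched or ordered.

Path distributions count each valid streamline at most once per voxel and
are normalised by the number of valid streamlines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import MaskVolume, ScalarVolume, VolumeGrid, nearest_voxel
from .field import OrientationField
from . import rng as crng

# termination codes
ACTIVE, LOST, EXCLUDED, CURVATURE_DEAD_END, MAX_STEPS, STOPPED = 0, 1, 2, 3, 4, 5
_TERM_NAMES = {LOST: "LOST", EXCLUDED: "EXCLUDED", CURVATURE_DEAD_END: "CURVATURE_DEAD_END",
               MAX_STEPS: "MAX_STEPS", STOPPED: "STOPPED"}


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters.

    Defaults follow standard probabilistic-tracking practice for the
    larger phantom: 0.5 mm steps (0.2 mm suits the half-scale phantom),
    an 80 degree per-step curvature limit, at most 2000 steps, and
    subsidiary fibre populations considered above a 1% volume fraction.
    """

    rng_seed: int
    step_mm: float = 0.5
    curvature_limit_deg: float = 80.0
    max_steps: int = 2000
    fraction_threshold: float = 0.01
    seeds_per_voxel: int = 200

    def __post_init__(self):
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not 0 < self.curvature_limit_deg < 180:
            raise ValueError("curvature_limit_deg must lie in (0, 180)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if not 0 <= self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must lie in [0, 1)")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be positive")
        if self.rng_seed is None:
            raise ValueError("rng_seed is required; there is no implicit randomness")

    def snapshot(self) -> dict:
        return {
            "step_mm": self.step_mm, "curvature_limit_deg": self.curvature_limit_deg,
            "max_steps": self.max_steps, "fraction_threshold": self.fraction_threshold,
            "seeds_per_voxel": self.seeds_per_voxel, "rng_seed": self.rng_seed,
        }


@dataclass
class Streamline:
    points: np.ndarray          # (n, 3) continuous voxel coordinates
    status: str                 # VALID / EXCLUDED / WAYPOINT_FAIL after classification
    termination: str            # why propagation ended
    waypoints_hit: set[str]


@dataclass
class PathDistribution:
    """Visitation map: fraction of valid streamlines visiting each voxel."""

    grid: VolumeGrid
    values: np.ndarray
    n_valid: int
    tract_name: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("path distribution shape mismatch")

    def as_scalar(self) -> ScalarVolume:
        return ScalarVolume(self.grid, self.values)

    def save(self, path):
        """NIfTI volume plus a JSON sidecar with the normalisation count."""
        from .core import write_volume
        write_volume(self.as_scalar(), path,
                     meta={"n_valid": self.n_valid, "tract_name": self.tract_name,
                           "params": self.params, "kind": "path_distribution"})

    @classmethod
    def load(cls, path) -> "PathDistribution":
        import json
        from pathlib import Path as _P
        from .core import read_volume, _sidecar_path
        vol = read_volume(path)
        side = json.loads(_sidecar_path(_P(path)).read_text())
        if side.get("kind") != "path_distribution":
            raise ValueError(f"{path}: not a saved path distribution")
        values = vol.values if isinstance(vol, ScalarVolume) else vol.membership.astype(float)
        return cls(vol.grid, values, side["n_valid"], tract_name=side.get("tract_name", ""),
                   params=side.get("params", {}))


@dataclass
class Constraints:
    """Mask roles guiding one tracking run; all masks share the field grid."""

    waypoints: list[MaskVolume] = field(default_factory=list)
    exclusion: MaskVolume | None = None
    stop: MaskVolume | None = None
    ordered_waypoints: bool = False

    def validate(self, grid: VolumeGrid):
        for m in self.waypoints:
            grid.require_same(m.grid)
        for m in (self.exclusion, self.stop):
            if m is not None:
                grid.require_same(m.grid)


def _flatten_field(f: OrientationField):
    nx, ny, nz = f.grid.shape
    n = nx * ny * nz
    return (f.fractions.reshape(n, -1),
            f.mean_directions.reshape(n, -1, 3),
            f.samples.reshape(n, f.mean_directions.shape[3], f.n_samples, 3))


def _ravel(idx: np.ndarray, shape) -> np.ndarray:
    return (idx[:, 0] * shape[1] + idx[:, 1]) * shape[2] + idx[:, 2]


def _propagate_batch(fld: OrientationField, seed_idx: np.ndarray, rng_streams: np.ndarray,
                     params: TrackingParams, key: int, constraints: Constraints,
                     record_paths: bool = False):
    """Propagate a batch of streamlines; pure in (inputs, key, rng_streams).

    Returns termination codes, waypoint bitmasks (with first-hit steps if
    order matters), and the (streamline, voxel) visitation pairs of all
    non-excluded streamlines.
    """
    grid = fld.grid
    shape = grid.shape
    n = len(seed_idx)
    S = fld.n_samples
    fr_flat, md_flat, sm_flat = _flatten_field(fld)

    wps = [(m.label or f"wp{i}", m.membership.ravel()) for i, m in enumerate(constraints.waypoints)]
    excl = constraints.exclusion.membership.ravel() if constraints.exclusion is not None else None
    stop = constraints.stop.membership.ravel() if constraints.stop is not None else None
    n_wp = len(wps)
    all_bits = np.uint32((1 << n_wp) - 1)

    # advance in world mm; positions kept in continuous voxel coordinates
    step_vox = np.linalg.inv(grid.affine)[:3, :3] * params.step_mm
    cos_limit = math.cos(math.radians(params.curvature_limit_deg))

    term = np.zeros(n, dtype=np.int8)
    wp_bits = np.zeros(n, dtype=np.uint32)
    wp_first = np.full((n, max(n_wp, 1)), -1, dtype=np.int32) if constraints.ordered_waypoints else None
    pair_sid: list[np.ndarray] = []
    pair_vox: list[np.ndarray] = []
    paths = [[] for _ in range(n)] if record_paths else None

    flat0 = _ravel(seed_idx, shape)

    def mark_visits(ids, flat, t):
        pair_sid.append(ids.astype(np.int64))
        pair_vox.append(flat.astype(np.int64))
        if n_wp:
            for b, (_, wm) in enumerate(wps):
                hit = wm[flat]
                if hit.any():
                    bit = np.uint32(1 << b)
                    newly = hit & ((wp_bits[ids] & bit) == 0)
                    wp_bits[ids[hit]] |= bit
                    if wp_first is not None and newly.any():
                        wp_first[ids[newly], b] = t

    # ---- initialisation at the seed voxel -----------------------------------
    alive = np.ones(n, dtype=bool)
    if excl is not None:
        bad = excl[flat0]
        term[bad] = EXCLUDED
        alive &= ~bad
    ids = np.nonzero(alive)[0]
    if record_paths:
        for i in ids:
            paths[i].append(seed_idx[i].astype(float))
    mark_visits(ids, flat0[ids], 0)
    if stop is not None:
        stopped = stop[flat0[ids]]
        term[ids[stopped]] = STOPPED
        ids = ids[~stopped]

    fr0 = fr_flat[flat0[ids]]
    cand0 = fr0 >= params.fraction_threshold
    has = cand0.any(axis=1)
    term[ids[~has]] = LOST      # no populations above threshold at the seed
    ids = ids[has]

    if len(ids):
        fr0 = fr_flat[flat0[ids]] * (fr_flat[flat0[ids]] >= params.fraction_threshold)
        cum = np.cumsum(fr0, axis=1)
        u = crng.uniform(key, rng_streams[ids], 0, 0) * cum[:, -1]
        pop = np.minimum((cum < u[:, None]).sum(axis=1), fr0.shape[1] - 1)
        sidx = crng.randint(key, rng_streams[ids], 0, 1, S)
        vec = sm_flat[flat0[ids], pop, sidx]
        flip = crng.uniform(key, rng_streams[ids], 0, 2) < 0.5
        vec = np.where(flip[:, None], -vec, vec)
    else:
        vec = np.empty((0, 3))

    pos = seed_idx[ids].astype(float)
    direction = vec

    # ---- stepping loop ------------------------------------------------------
    for t in range(1, params.max_steps + 1):
        if len(ids) == 0:
            break
        pos = pos + direction @ step_vox.T / 1.0  # world step expressed in voxel units
        # nearest voxel with ties toward -inf
        idx = np.ceil(pos - 0.5).astype(np.int64)
        ingrid = ((idx >= 0).all(axis=1)
                  & (idx[:, 0] < shape[0]) & (idx[:, 1] < shape[1]) & (idx[:, 2] < shape[2]))
        term[ids[~ingrid]] = LOST
        ids, pos, direction, idx = ids[ingrid], pos[ingrid], direction[ingrid], idx[ingrid]
        if len(ids) == 0:
            break
        flat = _ravel(idx, shape)

        if excl is not None:
            bad = excl[flat]
            term[ids[bad]] = EXCLUDED
            ids, pos, direction, flat = ids[~bad], pos[~bad], direction[~bad], flat[~bad]
            if len(ids) == 0:
                break
        if record_paths:
            for i, p in zip(ids, pos):
                paths[i].append(p.copy())
        mark_visits(ids, flat, t)

        if stop is not None:
            stopped = stop[flat]
            term[ids[stopped]] = STOPPED
            ids, pos, direction, flat = ids[~stopped], pos[~stopped], direction[~stopped], flat[~stopped]
            if len(ids) == 0:
                break

        fr = fr_flat[flat]
        cand = fr >= params.fraction_threshold
        has = cand.any(axis=1)
        term[ids[~has]] = LOST
        ids, pos, direction, flat, cand = ids[has], pos[has], direction[has], flat[has], cand[has]
        if len(ids) == 0:
            break

        dots = np.einsum("npj,nj->np", md_flat[flat], direction)
        absd = np.where(cand, np.abs(dots), -1.0)
        pop = np.argmax(absd, axis=1)       # ties break to the lowest index

        sidx = crng.randint(key, rng_streams[ids], t, 0, S)
        vec = sm_flat[flat, pop, sidx]
        d = np.einsum("nj,nj->n", vec, direction)
        vec = np.where((d < 0)[:, None], -vec, vec)
        cosang = np.abs(d)
        turn_ok = cosang >= cos_limit
        term[ids[~turn_ok]] = CURVATURE_DEAD_END
        ids, pos, vec = ids[turn_ok], pos[turn_ok], vec[turn_ok]
        direction = vec
    else:
        term[ids] = MAX_STEPS

    sid = np.concatenate(pair_sid) if pair_sid else np.empty(0, dtype=np.int64)
    vox = np.concatenate(pair_vox) if pair_vox else np.empty(0, dtype=np.int64)
    return {
        "termination": term, "wp_bits": wp_bits, "wp_first": wp_first,
        "all_bits": all_bits, "pair_sid": sid, "pair_vox": vox,
        "wp_names": [nm for nm, _ in wps], "paths": paths,
    }


def _waypoints_ok(res) -> np.ndarray:
    ok = res["wp_bits"] == res["all_bits"]
    if res["wp_first"] is not None and res["wp_first"].shape[1] > 1:
        first = res["wp_first"]
        ordered = np.ones(len(first), dtype=bool)
        for b in range(first.shape[1] - 1):
            ordered &= first[:, b] <= first[:, b + 1]
        ok &= ordered
    return ok


def propagate(fld: OrientationField, seed_point: Sequence[float], constraints: Constraints,
              params: TrackingParams, stream_id: int = 0) -> Streamline:
    """Propagate a single streamline seeded at a continuous voxel coordinate."""
    constraints.validate(fld.grid)
    seed_idx = nearest_voxel(np.atleast_2d(seed_point))
    if not fld.grid.contains_voxel(seed_idx).all():
        raise ValueError("seed point outside grid")
    key = crng.derive_key(params.rng_seed, "track")
    res = _propagate_batch(fld, seed_idx, np.array([stream_id], dtype=np.uint64),
                           params, key, constraints, record_paths=True)
    pts = np.array(res["paths"][0]) if res["paths"][0] else np.empty((0, 3))
    term = _TERM_NAMES[int(res["termination"][0])] if res["termination"][0] else "MAX_STEPS"
    hit = {nm for b, nm in enumerate(res["wp_names"]) if res["wp_bits"][0] & (1 << b)}
    if res["termination"][0] == EXCLUDED:
        status = "EXCLUDED"
    elif bool(_waypoints_ok(res)[0]):
        status = "VALID"
    else:
        status = "WAYPOINT_FAIL"
    return Streamline(points=pts, status=status, termination=term, waypoints_hit=hit)


def run_seed_region(fld: OrientationField, seed_mask: MaskVolume, constraints: Constraints,
                    params: TrackingParams, tract_name: str = "",
                    batch_size: int = 60000) -> tuple[PathDistribution, dict]:
    """Launch ``seeds_per_voxel`` streamlines per seed voxel and normalise.

    A streamline is valid iff it hits every waypoint (in order, when order
    is required) and never enters the exclusion mask.  Visit counting is
    binary per streamline per voxel, and the distribution is divided by
    the number of valid streamlines.
    """
    fld.grid.require_same(seed_mask.grid)
    constraints.validate(fld.grid)
    seeds = seed_mask.voxel_indices()
    if len(seeds) == 0:
        raise ValueError(f"seed mask '{seed_mask.label}' is empty")
    spv = params.seeds_per_voxel
    shape = fld.grid.shape
    nvox = shape[0] * shape[1] * shape[2]
    key = crng.derive_key(params.rng_seed, "track")

    seed_rep = np.repeat(seeds, spv, axis=0)
    flat_rep = _ravel(seed_rep, shape)
    streams = flat_rep.astype(np.uint64) * np.uint64(spv) + np.tile(
        np.arange(spv, dtype=np.uint64), len(seeds))

    counts = np.zeros(nvox, dtype=np.int64)
    tally = {"VALID": 0, "EXCLUDED": 0, "WAYPOINT_FAIL": 0}
    term_tally = {name: 0 for name in _TERM_NAMES.values()}
    n_total = len(seed_rep)
    for lo in range(0, n_total, batch_size):
        hi = min(lo + batch_size, n_total)
        res = _propagate_batch(fld, seed_rep[lo:hi], streams[lo:hi], params, key, constraints)
        term = res["termination"]
        excluded = term == EXCLUDED
        ok = _waypoints_ok(res) & ~excluded
        tally["VALID"] += int(ok.sum())
        tally["EXCLUDED"] += int(excluded.sum())
        tally["WAYPOINT_FAIL"] += int((~ok & ~excluded).sum())
        for code, name in _TERM_NAMES.items():
            term_tally[name] += int((term == code).sum())
        sel = ok[res["pair_sid"]]
        if sel.any():
            keyed = res["pair_sid"][sel] * nvox + res["pair_vox"][sel]
            uniq = np.unique(keyed)
            counts += np.bincount(uniq % nvox, minlength=nvox)

    n_valid = tally["VALID"]
    values = counts.reshape(shape) / n_valid if n_valid > 0 else np.zeros(shape)
    pd = PathDistribution(fld.grid, values, n_valid, tract_name=tract_name,
                          params=params.snapshot())
    tally["terminations"] = term_tally
    return pd, tally


def threshold_distribution(pd: PathDistribution, level: float) -> PathDistribution:
    """Zero all voxels at or below ``level`` (strict survival: value > level)."""
    if not 0 <= level < 1:
        raise ValueError("threshold level must lie in [0, 1)")
    if pd.n_valid == 0:
        raise ValueError("cannot threshold an unnormalised (n_valid = 0) distribution")
    vals = np.where(pd.values > level, pd.values, 0.0)
    return PathDistribution(pd.grid, vals, pd.n_valid, tract_name=pd.tract_name,
                            params={**pd.params, "threshold": level})
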