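"""Connectivity blueprints: row-normalised GM x Tracts matrices.

A blueprint row gives one grey-matter element's pattern of membership in
a fixed, ordered set of white-matter tracts.  Cortical rows are built
through an intermediary whole-brain GM x WM matrix (seeding from the
grey-white boundary and targetting the white matter, then multiplying by
a WM x Tracts matrix of collated path distributions) to avoid the
near-cortex bias of raw path distributions.  Subcortical rows are built
by directly intersecting each tract's downsampled, thresholded path
distribution with the binary nucleus masks — the direct variant is more
specific in the subcortex, and the module can compute both variants for
comparison.

Rows are concatenated (cortex first, then subcortical voxels) and
sum-normalised; rows that are all-zero before normalisation are flagged
and excluded from divergence computations downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .core import (GreyMatterAtlas, MaskVolume, VolumeGrid, downsample_block_mean,
                   downsample_grid)
from .field import OrientationField
from .tracking import (EXCLUDED, Constraints, PathDistribution, TrackingParams,
                       _propagate_batch, _ravel, _waypoints_ok)
from . import rng as crng

DEFAULT_TRACT_THRESHOLD = 0.001


@dataclass
class GMxWMMatrix:
    """Visitation counts from boundary seeding: GM elements x coarse WM voxels."""

    element_ids: list                 # row identities (order preserved)
    coarse_grid: VolumeGrid
    wm_columns: np.ndarray            # flat coarse-voxel indices of the columns
    matrix: sparse.csr_matrix         # (n_elements, len(wm_columns)) counts

    def row_mass(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()


@dataclass
class ConnectivityBlueprint:
    values: np.ndarray                       # (n_rows, T)
    tract_names: list[str]
    tract_classes: dict[str, str]            # name -> "cc" | "cs"
    row_meta: list[dict]                     # per row: kind, hemisphere, ...
    normalised: bool
    flagged: np.ndarray                      # all-zero-before-normalisation rows

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_meta), len(self.tract_names)):
            raise ValueError("blueprint shape inconsistent with metadata")
        self.flagged = np.asarray(self.flagged, dtype=bool)

    def rows_of(self, kind: str, hemisphere: str | None = None) -> np.ndarray:
        """Row indices whose metadata matches (e.g. kind='putamen_l')."""
        sel = []
        for i, m in enumerate(self.row_meta):
            if m["kind"] != kind:
                continue
            if hemisphere is not None and m.get("hemisphere") != hemisphere:
                continue
            sel.append(i)
        return np.array(sel, dtype=int)

    def column_subset(self, tract_subset: str) -> np.ndarray:
        """Column indices for 'all', 'cc' (cortico-cortical) or 'cs' subsets."""
        if tract_subset == "all":
            return np.arange(len(self.tract_names))
        keep = [i for i, n in enumerate(self.tract_names)
                if self.tract_classes.get(n, "cs") == tract_subset]
        if not keep:
            raise ValueError(f"no tracts in subset '{tract_subset}'")
        return np.array(keep, dtype=int)

    def save(self, out_dir: str | Path):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        row_names = [f"{m['kind']}:{i}" for i, m in enumerate(self.row_meta)]
        pd.DataFrame(self.values, index=row_names, columns=self.tract_names) \
            .to_csv(out / "blueprint.tsv", sep="\t", float_format="%.10g")
        (out / "blueprint.json").write_text(json.dumps({
            "tract_names": self.tract_names,
            "tract_classes": self.tract_classes,
            "row_meta": self.row_meta,
            "normalised": self.normalised,
            "flagged": self.flagged.astype(int).tolist(),
        }, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ConnectivityBlueprint":
        src = Path(in_dir)
        meta = json.loads((src / "blueprint.json").read_text())
        table = pd.read_csv(src / "blueprint.tsv", sep="\t", index_col=0)
        return cls(values=table.to_numpy(), tract_names=meta["tract_names"],
                   tract_classes=meta["tract_classes"], row_meta=meta["row_meta"],
                   normalised=meta["normalised"],
                   flagged=np.array(meta["flagged"], dtype=bool))


# -----------------------------------------------------------------------------
# GM x WM via boundary seeding
# -----------------------------------------------------------------------------

def gm_by_wm(fld: OrientationField, seed_voxels: np.ndarray, wm_mask: MaskVolume,
             params: TrackingParams, downsample: int = 2,
             element_ids: list | None = None, batch_size: int = 60000) -> GMxWMMatrix:
    """Whole-brain matrix: seed each GM element, target the white matter.

    A streamline contributes iff it enters the white-matter mask; visit
    counting is binary per streamline per coarse WM voxel.
    """
    if wm_mask.n_voxels == 0:
        raise ValueError("white-matter mask is empty")
    fld.grid.require_same(wm_mask.grid)
    seed_voxels = np.asarray(seed_voxels, dtype=np.int64)
    n_elem = len(seed_voxels)
    if element_ids is None:
        element_ids = [tuple(v) for v in seed_voxels]
    shape = fld.grid.shape
    nvox = int(np.prod(shape))
    spv = params.seeds_per_voxel
    key = crng.derive_key(params.rng_seed, "track")
    constraints = Constraints(waypoints=[wm_mask])

    cg = downsample_grid(fld.grid, downsample)
    n_coarse = int(np.prod(cg.shape))
    fine_flat_to_coarse = _fine_to_coarse_lut(shape, cg.shape, downsample)

    seed_rep = np.repeat(seed_voxels, spv, axis=0)
    flat_rep = _ravel(seed_rep, shape)
    streams = flat_rep.astype(np.uint64) * np.uint64(spv) + np.tile(
        np.arange(spv, dtype=np.uint64), n_elem)
    elem_of_stream = np.repeat(np.arange(n_elem, dtype=np.int64), spv)

    rows_all, cols_all, counts_all = [], [], []
    n_total = len(seed_rep)
    for lo in range(0, n_total, batch_size):
        hi = min(lo + batch_size, n_total)
        res = _propagate_batch(fld, seed_rep[lo:hi], streams[lo:hi], params, key, constraints)
        ok = _waypoints_ok(res) & (res["termination"] != EXCLUDED)
        sel = ok[res["pair_sid"]]
        if not sel.any():
            continue
        sid = res["pair_sid"][sel] + lo          # global streamline index
        coarse = fine_flat_to_coarse[res["pair_vox"][sel]]
        uniq = np.unique(sid * n_coarse + coarse)
        rows_all.append(elem_of_stream[uniq // n_coarse])
        cols_all.append(uniq % n_coarse)
        counts_all.append(np.ones(len(uniq)))
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        cnts = np.concatenate(counts_all)
        mat = sparse.coo_matrix((cnts, (rows, cols)), shape=(n_elem, n_coarse)).tocsr()
    else:
        mat = sparse.csr_matrix((n_elem, n_coarse))

    coarse_wm = downsample_block_mean(wm_mask.membership.astype(float), downsample) > 0
    wm_cols = np.flatnonzero(coarse_wm.ravel())
    return GMxWMMatrix(element_ids=element_ids, coarse_grid=cg,
                       wm_columns=wm_cols, matrix=mat[:, wm_cols].tocsr())


def _fine_to_coarse_lut(fine_shape, coarse_shape, factor: int) -> np.ndarray:
    idx = np.indices(fine_shape) // factor
    return np.ravel_multi_index(idx, coarse_shape).ravel()


# -----------------------------------------------------------------------------
# WM x Tracts and the two blueprint halves
# -----------------------------------------------------------------------------

def wm_by_tracts(tracts: dict[str, PathDistribution], wm_columns: np.ndarray,
                 coarse_grid: VolumeGrid, downsample: int = 2,
                 threshold: float = DEFAULT_TRACT_THRESHOLD) -> tuple[np.ndarray, list[str]]:
    """Collate downsampled, thresholded path distributions over WM columns."""
    names = list(tracts)
    cols = np.zeros((len(wm_columns), len(names)))
    for t, name in enumerate(names):
        pd_ = tracts[name]
        coarse = downsample_block_mean(pd_.values, downsample)
        if coarse.size != int(np.prod(coarse_grid.shape)):
            raise ValueError(f"tract {name}: grid does not downsample onto the WM grid")
        v = coarse.ravel()[wm_columns]
        cols[:, t] = np.where(v > threshold, v, 0.0)
    return cols, names


def cortical_blueprint(gmwm: GMxWMMatrix, wmt: np.ndarray) -> np.ndarray:
    """Matrix product GM x WM times WM x Tracts (unnormalised cortical rows)."""
    if gmwm.matrix.shape[1] != wmt.shape[0]:
        raise ValueError(f"WM dimension mismatch: {gmwm.matrix.shape[1]} vs {wmt.shape[0]}")
    return np.asarray(gmwm.matrix @ wmt)


def subcortical_blueprint(tracts: dict[str, PathDistribution],
                          nuclei: dict[str, MaskVolume], downsample: int = 2,
                          threshold: float = DEFAULT_TRACT_THRESHOLD
                          ) -> tuple[np.ndarray, list[dict], list[str]]:
    """Direct-intersection subcortical rows.

    Path distributions are block-mean downsampled, then thresholded, then
    sampled at each coarse in-nucleus voxel; one row per voxel.
    """
    names = list(tracts)
    grid = tracts[names[0]].grid
    rows, meta = [], []
    coarse_cache = {}
    for name in names:
        grid.require_same(tracts[name].grid)
        c = downsample_block_mean(tracts[name].values, downsample)
        coarse_cache[name] = np.where(c > threshold, c, 0.0).ravel()
    for nuc, mask in nuclei.items():
        grid.require_same(mask.grid)
        coarse_m = downsample_block_mean(mask.membership.astype(float), downsample) > 0.5
        vox = np.argwhere(coarse_m)
        if len(vox) == 0:
            raise ValueError(f"nucleus {nuc} has no voxels at downsample factor {downsample}")
        flat = np.ravel_multi_index(vox.T, coarse_m.shape)
        block = np.stack([coarse_cache[n][flat] for n in names], axis=1)
        rows.append(block)
        hemi = nuc.rsplit("_", 1)[1] if "_" in nuc else ""
        meta.extend({"kind": nuc, "hemisphere": hemi, "voxel": tuple(int(x) for x in v)}
                    for v in vox)
    return np.vstack(rows), meta, names


def subcortical_blueprint_matrix_variant(fld: OrientationField, nuclei: dict[str, MaskVolume],
                                         tracts: dict[str, PathDistribution],
                                         params: TrackingParams, wm_mask: MaskVolume,
                                         downsample: int = 2,
                                         threshold: float = DEFAULT_TRACT_THRESHOLD
                                         ) -> tuple[np.ndarray, list[dict], list[str]]:
    """Intermediary-matrix subcortical rows (GM x WM times WM x Tracts).

    Seeds one representative fine voxel per coarse nucleus voxel so rows
    correspond one-to-one with the direct variant's rows.
    """
    meta = []
    seeds = []
    for nuc, mask in nuclei.items():
        coarse_m = downsample_block_mean(mask.membership.astype(float), downsample) > 0.5
        vox = np.argwhere(coarse_m)
        hemi = nuc.rsplit("_", 1)[1] if "_" in nuc else ""
        for v in vox:
            fine = v * downsample + downsample // 2
            fine = np.minimum(fine, np.array(fld.grid.shape) - 1)
            seeds.append(fine)
            meta.append({"kind": nuc, "hemisphere": hemi, "voxel": tuple(int(x) for x in v)})
    gmwm = gm_by_wm(fld, np.array(seeds), wm_mask, params, downsample=downsample)
    wmt, names = wm_by_tracts(tracts, gmwm.wm_columns, gmwm.coarse_grid,
                              downsample=downsample, threshold=threshold)
    return cortical_blueprint(gmwm, wmt), meta, names


def assemble(cortical_rows: np.ndarray, cortical_meta: list[dict],
             subcortical_rows: np.ndarray, subcortical_meta: list[dict],
             tract_names: list[str], tract_classes: dict[str, str]) -> ConnectivityBlueprint:
    """Concatenate cortex-then-subcortex rows and sum-normalise each row."""
    if cortical_rows.shape[1] != subcortical_rows.shape[1]:
        raise ValueError("cortical and subcortical parts have different tract columns")
    values = np.vstack([cortical_rows, subcortical_rows]).astype(float)
    if (values < 0).any():
        raise ValueError("blueprint entries must be non-negative")
    sums = values.sum(axis=1)
    flagged = sums <= 0
    norm = values.copy()
    norm[~flagged] /= sums[~flagged, None]
    return ConnectivityBlueprint(values=norm, tract_names=list(tract_names),
                                 tract_classes=dict(tract_classes),
                                 row_meta=list(cortical_meta) + list(subcortical_meta),
                                 normalised=True, flagged=flagged)


def group_average_blueprints(blueprints: list[ConnectivityBlueprint]) -> ConnectivityBlueprint:
    """Element-wise mean of structurally identical blueprints, renormalised."""
    if not blueprints:
        raise ValueError("group_average_blueprints of an empty list")
    ref = blueprints[0]
    for b in blueprints[1:]:
        if b.tract_names != ref.tract_names or len(b.row_meta) != len(ref.row_meta):
            raise ValueError("blueprint structure mismatch in group average")
    mean = np.mean([b.values for b in blueprints], axis=0)
    sums = mean.sum(axis=1)
    flagged = sums <= 0
    mean[~flagged] /= sums[~flagged, None]
    return ConnectivityBlueprint(values=mean, tract_names=ref.tract_names,
                                 tract_classes=ref.tract_classes, row_meta=ref.row_meta,
                                 normalised=True, flagged=flagged)


def tract_specificity(rows: np.ndarray, meta: list[dict], names: list[str],
                      bundle_nucleus: dict[str, str]) -> dict[str, float]:
    """Per-tract fraction of subcortical mass inside its assigned nucleus."""
    out = {}
    kinds = np.array([m["kind"] for m in meta])
    for t, name in enumerate(names):
        base = name.rsplit("_", 1)[0]
        hemi = name.rsplit("_", 1)[1] if "_" in name else ""
        nuc = bundle_nucleus.get(name) or bundle_nucleus.get(base)
        if nuc is None:
            continue
        if "_" not in nuc and hemi:
            nuc = f"{nuc}_{hemi}"
        col = rows[:, t]
        total = col.sum()
        if total <= 0:
            out[name] = np.nan
            continue
        out[name] = float(col[kinds == nuc].sum() / total)
    return out


def compare_subcortical_variants(fld: OrientationField, nuclei: dict[str, MaskVolume],
                                 tracts: dict[str, PathDistribution],
                                 params: TrackingParams, wm_mask: MaskVolume,
                                 bundle_nucleus: dict[str, str],
                                 downsample: int = 2,
                                 threshold: float = DEFAULT_TRACT_THRESHOLD) -> dict:
    """Specificity of direct-intersection vs intermediary-matrix subcortical rows."""
    direct_rows, meta, names = subcortical_blueprint(tracts, nuclei, downsample, threshold)
    matrix_rows, meta2, names2 = subcortical_blueprint_matrix_variant(
        fld, nuclei, tracts, params, wm_mask, downsample, threshold)
    assert names == names2 and len(meta) == len(meta2)
    return {
        "direct": tract_specificity(direct_rows, meta, names, bundle_nucleus),
        "matrix": tract_specificity(matrix_rows, meta, names, bundle_nucleus),
    }
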