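"""Similarity, group-comparison and topography statistics for tract maps.

Pairwise tract similarity is the Pearson correlation of two subjects'
normalised path distributions, computed per tract over the union of the
two thresholded supports (threshold 0.5% by default) and averaged across
tracts.  Group differences use a two-sided Mann-Whitney U test —
enumerated exactly when both groups have at most eight members,
otherwise the normal approximation with tie correction — with Bonferroni
adjustment over the requested comparisons.

Tracer-style termination maps count termination sites per target-nucleus
voxel and divide by the group total, then smooth with a separable cubic
B-spline kernel (negative ringing clipped at zero); probabilities sum to
one per group before smoothing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .core import MaskVolume, ScalarVolume, VolumeGrid
from .phantom import SubjectCohort
from .tracking import PathDistribution, threshold_distribution

DEFAULT_SIMILARITY_THRESHOLD = 0.005


@dataclass
class SimilarityTable:
    pairs: list[tuple[str, str, str]]          # (idA, idB, group label)
    mean_r: list[float]
    per_tract_r: list[dict[str, float]]
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD

    def by_group(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for (a, b, g), r in zip(self.pairs, self.mean_r):
            out.setdefault(g, []).append(r)
        return {g: np.asarray(v) for g, v in out.items()}


def pair_similarity(tracts_a: dict[str, PathDistribution],
                    tracts_b: dict[str, PathDistribution],
                    threshold: float = DEFAULT_SIMILARITY_THRESHOLD
                    ) -> tuple[float, dict[str, float]]:
    """Mean (and per-tract) Pearson correlation between two subjects' tracts.

    Each tract's maps are thresholded, correlated over the union of the
    surviving supports, and the correlations averaged across tracts.
    Tracts with fewer than three surviving voxels are excluded.
    """
    common = [t for t in tracts_a if t in tracts_b]
    if not common:
        raise ValueError("subjects share no tracts")
    per_tract: dict[str, float] = {}
    for t in common:
        pa, pb = tracts_a[t], tracts_b[t]
        pa.grid.require_same(pb.grid)
        if pa.n_valid == 0 or pb.n_valid == 0:
            warnings.warn(f"tract {t}: no valid streamlines in one subject; excluded")
            continue
        va = threshold_distribution(pa, threshold).values.ravel()
        vb = threshold_distribution(pb, threshold).values.ravel()
        support = (va > 0) | (vb > 0)
        if support.sum() < 3:
            warnings.warn(f"tract {t}: fewer than 3 voxels survive thresholding; excluded")
            continue
        x, y = va[support], vb[support]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            per_tract[t] = 0.0 if not np.allclose(x, y) else 1.0
            continue
        per_tract[t] = float(np.corrcoef(x, y)[0, 1])
    if not per_tract:
        raise ValueError("no tract had enough surviving voxels to correlate")
    return float(np.mean(list(per_tract.values()))), per_tract


# -----------------------------------------------------------------------------
# Mann-Whitney U with exact small-sample enumeration
# -----------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sstats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small groups.

    For groups of at most ``exact_max_n`` each, the p-value is computed by
    enumerating every assignment of the pooled values to the two groups
    (handling ties through midranks).  Larger groups use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    u = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        centre = n1 * n2 / 2.0
        obs_dev = abs(u - centre)
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(comb)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u_perm - centre) >= obs_dev - 1e-12:
                count += 1
        return float(u), count / total
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals: dict[str, float]) -> dict[str, float]:
    m = len(pvals)
    return {k: min(1.0, p * m) for k, p in pvals.items()}


def group_compare(values_by_group: dict[str, np.ndarray],
                  comparisons: list[tuple[str, str]]) -> dict[str, dict]:
    """Pairwise Mann-Whitney tests with Bonferroni adjustment."""
    for g, v in values_by_group.items():
        if len(v) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 values")
    raw = {}
    stats_out = {}
    for a, b in comparisons:
        u, p = mann_whitney(values_by_group[a], values_by_group[b])
        key = f"{a}-{b}"
        raw[key] = p
        stats_out[key] = {"U": u, "p": p}
    adj = bonferroni(raw)
    for key in stats_out:
        stats_out[key]["p_adjusted"] = adj[key]
    return stats_out


DEFAULT_TWIN_COMPARISONS = [("MZ", "DZ"), ("MZ", "SIB"), ("MZ", "UNREL"),
                            ("DZ", "SIB"), ("DZ", "UNREL"), ("SIB", "UNREL")]


def twin_analysis(cohort: SubjectCohort,
                  reconstructions: dict[str, dict[str, PathDistribution]],
                  threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                  comparisons: list[tuple[str, str]] | None = None) -> dict:
    """Similarity by relationship group, with all pairwise group tests.

    ``reconstructions`` maps subject id to its per-tract path
    distributions.  Pair similarity is computed for every labelled pair
    and the resulting distributions compared across groups.
    """
    for sid, _ in cohort.subjects:
        if sid not in reconstructions:
            raise ValueError(f"missing tract reconstructions for subject '{sid}'")
    pairs, mean_rs, per_tract = [], [], []
    for a, b, rel in cohort.pairs:
        try:
            r, pt = pair_similarity(reconstructions[a], reconstructions[b], threshold)
        except ValueError:
            warnings.warn(f"pair ({a}, {b}): no usable tract reconstructions; dropped")
            continue
        pairs.append((a, b, rel))
        mean_rs.append(r)
        per_tract.append(pt)
    table = SimilarityTable(pairs=pairs, mean_r=mean_rs, per_tract_r=per_tract,
                            threshold=threshold)
    groups = table.by_group()
    comps = comparisons if comparisons is not None else \
        [(a, b) for a, b in DEFAULT_TWIN_COMPARISONS if a in groups and b in groups]
    tests = group_compare(groups, comps)
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    return {"table": table, "medians": medians, "tests": tests}


# -----------------------------------------------------------------------------
# tracer termination maps and topography ordering
# -----------------------------------------------------------------------------

_BSPLINE3 = np.array([1.0, 4.0, 1.0]) / 6.0


@dataclass
class TerminationMap:
    group: str
    probabilities: ScalarVolume        # smoothed, clipped at 0
    pre_smoothing: ScalarVolume        # sums to 1 over the nucleus
    n_terminations: int


def termination_maps(injections: list[tuple[str, np.ndarray]], nucleus: MaskVolume,
                     smooth: bool = True) -> dict[str, TerminationMap]:
    """Termination probability maps per injection group.

    Counts each group's termination sites per nucleus voxel, divides by
    the group's total termination count, and smooths with a separable
    cubic B-spline kernel.
    """
    grid = nucleus.grid
    grouped: dict[str, list[np.ndarray]] = {}
    for label, vox in injections:
        grouped.setdefault(label, []).append(np.atleast_2d(np.asarray(vox, dtype=int)))
    out = {}
    for label, chunks in grouped.items():
        vox = np.vstack(chunks)
        if not grid.contains_voxel(vox).all():
            raise ValueError(f"group {label}: termination voxel outside grid")
        inside = nucleus.membership[vox[:, 0], vox[:, 1], vox[:, 2]]
        vox = vox[inside]
        if len(vox) == 0:
            warnings.warn(f"group {label}: no terminations inside the nucleus; excluded")
            continue
        counts = np.zeros(grid.shape)
        np.add.at(counts, (vox[:, 0], vox[:, 1], vox[:, 2]), 1.0)
        pre = counts / counts.sum()
        sm = pre
        if smooth:
            sm = pre.copy()
            for ax in range(3):
                sm = ndimage.correlate1d(sm, _BSPLINE3, axis=ax, mode="constant")
            sm = np.clip(sm, 0.0, None)
        out[label] = TerminationMap(group=label,
                                    probabilities=ScalarVolume(grid, sm),
                                    pre_smoothing=ScalarVolume(grid, pre),
                                    n_terminations=int(len(vox)))
    return out


def topography_order(maps: dict[str, np.ndarray | ScalarVolume], axis: np.ndarray,
                     within: MaskVolume | None = None,
                     ground_truth: list[str] | None = None) -> dict:
    """Order maps by their weighted centroid projected on an axis.

    ``maps`` values are volumetric weights (e.g. termination probabilities
    or path-distribution values inside a nucleus).  Zero-mass maps are
    excluded with a warning.  When a ground-truth ordering is supplied the
    report states whether the reconstructed ordering agrees.
    """
    axis = np.asarray(axis, dtype=float)
    coords: dict[str, float] = {}
    for name, m in maps.items():
        w = m.values if isinstance(m, ScalarVolume) else np.asarray(m, dtype=float)
        if within is not None:
            w = np.where(within.membership, w, 0.0)
        tot = w.sum()
        if tot <= 0:
            warnings.warn(f"map '{name}' has zero mass; excluded from ordering")
            continue
        idx = np.indices(w.shape)
        centroid = np.array([(idx[a] * w).sum() / tot for a in range(3)])
        coords[name] = float(centroid @ axis)
    if len(coords) < 2:
        raise ValueError("need at least two non-empty maps to order")
    ordering = sorted(coords, key=coords.get)
    report = {"ordering": ordering, "axis_coordinates": coords}
    if ground_truth is not None:
        gt = [g for g in ground_truth if g in coords]
        report["matches_ground_truth"] = ordering == gt
    return report
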