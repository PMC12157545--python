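"""Symmetric Kullback-Leibler comparison of grey-matter connection patterns.

Two grey-matter elements i (blueprint M, one brain) and j (blueprint H,
the other brain) are compared through their connection patterns over a
shared, homologously defined tract set k = 1..T:

    D_ij = sum_k M_ik log2(M_ik / H_jk) + sum_k H_jk log2(H_jk / M_ik)

Zeros would make the divergence degenerate, so patterns are shifted by a
small delta (default 1e-6) and re-normalised to sum to one before the
divergence is taken; the re-normalisation makes the compared patterns
proper distributions and is recorded in output metadata.

The module also provides divergence maps against a reference region's
average pattern, best-match identification over candidate region
partitions, specificity contrasts between tract subsets, and
nearest-rank percentile thresholding of divergence maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np

from .blueprints import ConnectivityBlueprint


@dataclass(frozen=True)
class DivergenceConfig:
    delta: float = 1e-6
    tract_subset: str = "all"       # "all", "cc" (cortico-cortical), "cs"

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.tract_subset not in ("all", "cc", "cs"):
            raise ValueError("tract_subset must be one of all/cc/cs")


@dataclass
class DivergenceMap:
    reference: str
    values: np.ndarray              # per target row; NaN where skipped
    row_meta: list[dict]
    config: DivergenceConfig
    renormalised_after_shift: bool = True

    def finite_rows(self) -> np.ndarray:
        return np.flatnonzero(np.isfinite(self.values))


def _shift_normalise(p: np.ndarray, delta: float) -> np.ndarray:
    p = p + delta
    return p / p.sum(axis=-1, keepdims=True)


def sym_kl(p: np.ndarray, q: np.ndarray, cfg: DivergenceConfig = DivergenceConfig()) -> float:
    """Symmetric KL divergence (bits) between two connection patterns."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"pattern length mismatch: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("connection patterns must be non-negative")
    ps = _shift_normalise(p, cfg.delta)
    qs = _shift_normalise(q, cfg.delta)
    lr = np.log2(ps / qs)
    return float(np.sum(ps * lr) - np.sum(qs * lr))


def _sym_kl_rows(ref: np.ndarray, rows: np.ndarray, delta: float) -> np.ndarray:
    """Vectorised symmetric KL of one reference pattern against many rows."""
    ps = _shift_normalise(ref[None, :], delta)
    qs = _shift_normalise(rows, delta)
    lr = np.log2(ps / qs)
    return np.sum(ps * lr, axis=1) - np.sum(qs * lr, axis=1)


def reference_pattern(bp: ConnectivityBlueprint, region_rows: np.ndarray,
                      columns: np.ndarray) -> np.ndarray:
    """Mean of a reference region's normalised rows (flagged rows excluded)."""
    region_rows = np.asarray(region_rows, dtype=int)
    keep = region_rows[~bp.flagged[region_rows]]
    if len(keep) == 0:
        raise ValueError("reference region has no unflagged rows")
    return bp.values[np.ix_(keep, columns)].mean(axis=0)


def divergence_map(reference_bp: ConnectivityBlueprint, reference_rows: np.ndarray,
                   target_bp: ConnectivityBlueprint,
                   cfg: DivergenceConfig = DivergenceConfig(),
                   reference_name: str = "") -> DivergenceMap:
    """Divergence of every target row from a reference region's mean pattern."""
    if reference_bp.tract_names != target_bp.tract_names:
        raise ValueError("blueprints have different tract columns")
    cols = reference_bp.column_subset(cfg.tract_subset)
    ref = reference_pattern(reference_bp, reference_rows, cols)
    vals = np.full(len(target_bp.row_meta), np.nan)
    ok = ~target_bp.flagged
    if ok.any():
        vals[ok] = _sym_kl_rows(ref, target_bp.values[np.ix_(np.flatnonzero(ok), cols)],
                                cfg.delta)
    return DivergenceMap(reference=reference_name, values=vals,
                         row_meta=target_bp.row_meta, config=cfg)


def best_match(dmap: DivergenceMap, regions: dict[str, np.ndarray]) -> tuple[str, dict[str, float]]:
    """Region with the lowest median divergence among candidate partitions."""
    medians: dict[str, float] = {}
    for name, rows in regions.items():
        rows = np.asarray(rows, dtype=int)
        vals = dmap.values[rows]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"candidate region '{name}' has no finite divergences; excluded")
            continue
        medians[name] = float(np.median(vals))
    if not medians:
        raise ValueError("no candidate region has finite divergences")
    winner = min(medians, key=medians.get)
    return winner, medians


def specificity_contrast(medians: dict[str, float], matching_region: str) -> float:
    """Best non-matching median minus the matching region's median.

    Positive and large when the match stands out; near zero when all
    candidate regions look alike.
    """
    if matching_region not in medians:
        raise ValueError(f"matching region '{matching_region}' absent from table")
    others = [v for k, v in medians.items() if k != matching_region]
    if not others:
        return 0.0
    return float(min(others) - medians[matching_region])


def percentile_threshold(dmap: DivergenceMap, pct: float = 7.0) -> np.ndarray:
    """Rows at or below the nearest-rank pct-th percentile of the map."""
    if not 0 < pct <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    rows = dmap.finite_rows()
    vals = np.sort(dmap.values[rows])
    rank = max(1, int(np.ceil(pct * len(vals) / 100.0 - 1e-9)))
    cut = vals[rank - 1]
    return rows[dmap.values[rows] <= cut]
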