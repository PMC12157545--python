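"""Counter-based random numbers for order-independent stochastic tracking.

Streamline propagation must be bit-reproducible regardless of execution
order, batching, or which subset of seeds is run.  Stateful generators
cannot give that, so every random draw is a pure function of
``(key, stream id, step, slot)`` built from a SplitMix64 mixing chain.
The statistical quality of SplitMix64 is far more than adequate for
choosing sample indices and signs.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U53 = float(1 << 53)


def _mix(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """SplitMix64 finaliser: bijective avalanche mix of a uint64."""
    z = (x + _GOLDEN).astype(np.uint64) if isinstance(x, np.ndarray) else np.uint64(x + _GOLDEN)
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


def derive_key(seed: int, *labels: str | int) -> int:
    """Derive an independent 64-bit stream key from a seed and labels.

    String labels let pipeline stages fan a single user seed out into
    per-stage substreams that are stable when stages are added or removed.
    """
    with np.errstate(over="ignore"):
        k = _mix(np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
        for lab in labels:
            if isinstance(lab, str):
                for b in lab.encode():
                    k = _mix(k ^ np.uint64(b))
            else:
                k = _mix(k ^ np.uint64(int(lab) & 0xFFFFFFFFFFFFFFFF))
    return int(k)


def uniform(key: int, stream: np.ndarray, step: np.ndarray | int, slot: int) -> np.ndarray:
    """Uniform(0, 1) draw, a pure function of (key, stream, step, slot).

    ``stream`` and ``step`` may be arrays (broadcast together); the result
    never depends on evaluation order.
    """
    stream = np.asarray(stream, dtype=np.uint64)
    step = np.asarray(step, dtype=np.uint64)
    with np.errstate(over="ignore"):
        h = _mix(stream ^ np.uint64(key))
        h = _mix(h ^ (step * np.uint64(0x9E3779B97F4A7C15)))
        h = _mix(h ^ np.uint64((slot * 0xD1B54A32D192ED03) & 0xFFFFFFFFFFFFFFFF))
    return (h >> np.uint64(11)).astype(np.float64) / _U53


def randint(key: int, stream: np.ndarray, step: np.ndarray | int, slot: int, n: int) -> np.ndarray:
    """Integer draw in [0, n) with the same purity guarantees as uniform."""
    u = uniform(key, stream, step, slot)
    return np.minimum((u * n).astype(np.int64), n - 1)
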