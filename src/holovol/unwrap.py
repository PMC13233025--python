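"""Quality-guided phase unwrapping.

The wrapped phase is known only modulo 2 pi. Unwrapping flood-fills from
the most reliable pixel, always expanding through the highest-quality
queued pixel (a max-priority queue), and assigns each newly reached pixel
the 2 pi multiple that brings it closest to its already-unwrapped
neighbor. Errors therefore cannot propagate through low-quality (noisy or
discontinuous) regions before the smooth regions are done.

Quality is the classical inverse gradient-variance measure: 1 / (1 + local
variance of the wrapped phase gradients in a 3x3 window), in [0, 1].
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

from .fields import PhaseMap

TWO_PI = 2.0 * np.pi


def _wrap(values: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - values, TWO_PI)


def quality_map(wrapped: PhaseMap) -> np.ndarray:
    """Per-pixel reliability in [0, 1]; smooth regions score near 1."""
    wrapped.require_state("wrapped")
    data = wrapped.data
    gx = _wrap(np.diff(data, axis=1, append=data[:, -1:]))
    gy = _wrap(np.diff(data, axis=0, append=data[-1:, :]))
    var = np.zeros_like(data)
    for g in (gx, gy):
        mean = ndimage.uniform_filter(g, size=3, mode="nearest")
        mean_sq = ndimage.uniform_filter(g * g, size=3, mode="nearest")
        var += np.clip(mean_sq - mean * mean, 0.0, None)
    return 1.0 / (1.0 + var)


@njit(cache=True)
def _heap_push(heap_q, heap_i, size, q, i):
    heap_q[size] = q
    heap_i[size] = i
    child = size
    while child > 0:
        parent = (child - 1) // 2
        better = heap_q[child] > heap_q[parent] or (
            heap_q[child] == heap_q[parent] and heap_i[child] < heap_i[parent]
        )
        if not better:
            break
        heap_q[child], heap_q[parent] = heap_q[parent], heap_q[child]
        heap_i[child], heap_i[parent] = heap_i[parent], heap_i[child]
        child = parent
    return size + 1


@njit(cache=True)
def _heap_pop(heap_q, heap_i, size):
    top = heap_i[0]
    size -= 1
    heap_q[0] = heap_q[size]
    heap_i[0] = heap_i[size]
    parent = 0
    while True:
        left = 2 * parent + 1
        if left >= size:
            break
        right = left + 1
        best = left
        if right < size:
            if heap_q[right] > heap_q[left] or (
                heap_q[right] == heap_q[left] and heap_i[right] < heap_i[left]
            ):
                best = right
        if heap_q[best] > heap_q[parent] or (
            heap_q[best] == heap_q[parent] and heap_i[best] < heap_i[parent]
        ):
            heap_q[parent], heap_q[best] = heap_q[best], heap_q[parent]
            heap_i[parent], heap_i[best] = heap_i[best], heap_i[parent]
            parent = best
        else:
            break
    return top, size


@njit(cache=True)
def _qg_flood(phase, quality):
    ny, nx = phase.shape
    n = ny * nx
    ph = phase.ravel()
    q = quality.ravel()
    out = np.zeros(n, np.float64)
    # 0 = untouched, 1 = queued (value assigned), 2 = accepted
    state = np.zeros(n, np.uint8)
    heap_q = np.empty(n, np.float64)
    heap_i = np.empty(n, np.int64)
    size = 0
    # seed at the global quality maximum, first occurrence (lexicographic)
    seed = 0
    best = q[0]
    for i in range(1, n):
        if q[i] > best:
            best = q[i]
            seed = i
    out[seed] = ph[seed]
    state[seed] = 1
    size = _heap_push(heap_q, heap_i, size, q[seed], seed)
    two_pi = 2.0 * np.pi
    while size > 0:
        i, size = _heap_pop(heap_q, heap_i, size)
        state[i] = 2
        row = i // nx
        col = i % nx
        for k in range(4):
            if k == 0:
                r, c = row - 1, col
            elif k == 1:
                r, c = row + 1, col
            elif k == 2:
                r, c = row, col - 1
            else:
                r, c = row, col + 1
            if r < 0 or r >= ny or c < 0 or c >= nx:
                continue
            j = r * nx + c
            if state[j] == 0:
                out[j] = ph[j] + two_pi * np.rint((out[i] - ph[j]) / two_pi)
                state[j] = 1
                size = _heap_push(heap_q, heap_i, size, q[j], j)
    return out.reshape(ny, nx)


def unwrap_quality_guided(wrapped: PhaseMap) -> PhaseMap:
    """Unwrap a wrapped phase map; output is congruent to the input mod 2 pi.

    Each pixel's output differs from its input by an exact integer multiple
    of 2 pi; the result is unique up to a single global 2 pi k offset fixed
    by the seed pixel (the global quality maximum).
    """
    wrapped.require_state("wrapped")
    quality = quality_map(wrapped)
    out = _qg_flood(
        np.ascontiguousarray(wrapped.data, dtype=np.float64),
        np.ascontiguousarray(quality, dtype=np.float64),
    )
    return PhaseMap(data=out, state="unwrapped", pixel_um=wrapped.pixel_um)
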