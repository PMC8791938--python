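"""Brute-force reference implementations used as independent oracles.

Deliberately naive (explicit Python loops, breadth-first search) so
they share no code path with the package implementations they check.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def bf_axial_gradient(img: np.ndarray, template) -> np.ndarray:
    """Sliding 4x1 correlation anchored at the third tap, clipped at 0.

    Rows outside the image replicate the edge rows.
    """
    img = np.asarray(img, dtype=float)
    template = np.asarray(template, dtype=float)
    h, w = img.shape
    out = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for k, off in enumerate((-2, -1, 0, 1)):
                r = min(max(i + off, 0), h - 1)
                acc += template[k] * img[r, j]
            out[i, j] = max(acc, 0.0)
    return out


def bf_nonmax_axial(arr: np.ndarray, min_response: float) -> np.ndarray:
    """Per-column scan for strict local maxima with the plateau rule.

    A run of equal values flanked by strictly smaller values yields one
    flag at its topmost row; border-touching runs are not peaks.
    """
    arr = np.asarray(arr, dtype=float)
    h, w = arr.shape
    flags = np.zeros((h, w), dtype=bool)
    for j in range(w):
        col = arr[:, j]
        i = 0
        while i < h:
            k = i
            while k + 1 < h and col[k + 1] == col[i]:
                k += 1
            left_smaller = i > 0 and col[i - 1] < col[i]
            right_smaller = k < h - 1 and col[k + 1] < col[i]
            if left_smaller and right_smaller and col[i] >= min_response:
                flags[i, j] = True
            i = k + 1
    return flags


def bf_hysteresis(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """8-connected flood fill from strong pixels through weak pixels."""
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    weak = values >= low
    keep = np.zeros((h, w), dtype=bool)
    q = deque(zip(*np.nonzero(values >= high)))
    for r, c in q:
        keep[r, c] = True
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and weak[rr, cc] and not keep[rr, cc]:
                    keep[rr, cc] = True
                    q.append((rr, cc))
    return keep
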