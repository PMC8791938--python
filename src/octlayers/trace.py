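"""Seeded boundary path search, path superposition and dual-threshold selection.

Peak points inside two narrow lateral bands seed paths that are grown
column by column across the whole B-scan. At each step the candidate
set is the 3 (or 5) pixels of the adjacent column centred on the
current row, and the pixel whose value is closest to the current
pixel's value is chosen, the running value updating at every step. Ties
keep the previous step's row displacement. Superposing all paths and
normalising by their count turns agreement into a per-pixel probability
(in percent); the true boundaries collect most paths, so the standard
Canny dual-threshold rule (keep strong pixels, keep weak pixels
connected to a strong one) isolates them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage

from .core import Polarity, ValidationError
from .enhance import EnhancedImage, PeakMap

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the boundary search.

    ``neighborhood`` 3 suits healthy eyes (|slope| <= 1 px/column);
    5 admits the steeper boundaries of diseased eyes. Thresholds are
    probabilities in percent of all paths traced in a channel; since a
    channel hosts five or six boundaries, even unanimous agreement on
    one boundary tops out near 100 / n_boundaries, so useful thresholds
    sit well below that plateau.
    """

    neighborhood: int = 3
    seed_band_width: int = 30
    low_threshold: float = 2.0
    high_threshold: float = 8.0
    value_reference: str = "seed"  # "seed": the comparison value starts
    # at the origin seed's intensity and adapts slowly (see
    # ref_adapt_rate); "running": compare to the current pixel,
    # updating fully at every step. The slow reference keeps a path
    # locked to its ridge under speckle (an off-ridge step is corrected
    # at the next column) yet follows gradual dimming along a diseased
    # dome, whereas the fully running value lets a single noisy step
    # strand the path on an adjacent level set.
    ref_adapt_rate: float = 0.0  # exponential update weight of the
    # comparison value in "seed" mode (0 freezes it entirely; any
    # adaptation lets speckle walk the reference off its interface)
    seed_min_separation: int = 8  # per column, keep only the strongest
    # peak within this axial distance (0 = keep every peak). Speckle
    # plants satellite peaks a few rows off a real interface; one seed
    # per interface per column keeps the path superposition sharp.
    seed_coherence_frac: float = 0.6  # a seed row must carry a peak
    # (within +-1 row) in at least this fraction of its band's columns.
    # Real interfaces are laterally continuous ridges, so every band
    # column holds a nearby peak; speckle peaks are scattered and fail
    # the vote. 0 disables the filter.
    lost_threshold_frac: float = 0.33  # when even the best candidate's
    # value falls below this fraction of the reference value, the
    # boundary signal is absent at this column (vessel shadow, locally
    # destroyed interface) and the path extends straight ahead,
    # resuming value tracking where the signal returns. 0 disables.
    # Without it a path that briefly loses its ridge chases background
    # noise and can dive into the next interface; a merely dimmed ridge
    # (a steep dome flank) stays above the threshold and is followed.
    tie_tolerance_frac: float = 0.01  # candidates whose value distance
    # to the reference is within this fraction of the signal maximum of
    # the best candidate count as tied, and the tie keeps the previous
    # step's direction. With continuous-valued noise an exact tie never
    # occurs, yet the direction-keeping rule is precisely what carries a
    # path straight across a vessel shadow, where every candidate is
    # equally uninformative.

    def __post_init__(self) -> None:
        if self.neighborhood not in (3, 5):
            raise ValidationError("neighborhood: must be 3 or 5")
        if self.seed_band_width < 1:
            raise ValidationError("seed_band_width: must be >= 1 px")
        if not 0 <= self.low_threshold < self.high_threshold <= 100:
            raise ValidationError("thresholds: need 0 <= low < high <= 100")
        if self.value_reference not in ("seed", "running"):
            raise ValidationError("value_reference: must be 'seed' or 'running'")

    @property
    def offsets(self) -> np.ndarray:
        half = self.neighborhood // 2
        return np.arange(-half, half + 1)


class Seed(NamedTuple):
    """A peak point used as a path origin."""

    row: int
    col: int
    polarity: Polarity


@dataclass(frozen=True)
class TracedPath:
    """One row index per column, grown from a single seed.

    ``lost`` marks the columns the path crossed without boundary
    signal (vessel shadow, destroyed interface), where it was extended
    straight instead of value-tracked.
    """

    rows: np.ndarray
    origin: Seed
    lost: Optional[np.ndarray] = None


@dataclass(frozen=True)
class ProbabilityMap:
    """Path-superposition probability in percent, per pixel."""

    values: np.ndarray
    n_paths: int
    polarity: Polarity


@dataclass(frozen=True)
class BoundaryMask:
    """Boolean boundary image after dual-threshold selection."""

    flags: np.ndarray
    polarity: Polarity


class TraceResult(NamedTuple):
    seeds: list[Seed]
    paths: list[TracedPath]
    probability: Optional[ProbabilityMap]
    mask: BoundaryMask
    lost_fraction: Optional[np.ndarray] = None  # per-pixel fraction of
    # passing paths that crossed this pixel in the lost state


def lost_fraction_map(paths: list[TracedPath], shape: tuple[int, int]) -> np.ndarray:
    """Fraction of the paths through each pixel that were signal-lost."""
    counts = np.zeros(shape, dtype=np.int64)
    lost = np.zeros(shape, dtype=np.int64)
    cols = np.arange(shape[1])
    for p in paths:
        counts[p.rows, cols] += 1
        if p.lost is not None:
            lost[p.rows, cols] += p.lost.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, lost / np.maximum(counts, 1), 0.0)
    return frac


def select_seeds(
    peaks: PeakMap,
    config: SearchConfig,
    enhanced: Optional[EnhancedImage] = None,
) -> list[Seed]:
    """Flagged pixels inside the two lateral seed bands.

    When ``enhanced`` is given and ``config.seed_min_separation`` is
    positive, peaks in the same column are thinned greedily by response
    strength so that no two seeds sit closer than the separation —
    speckle satellites next to a real interface lose to the interface
    peak, while genuinely distinct interfaces (which are farther apart)
    all keep a seed. Returned in deterministic order (column, then row).
    """
    h, w = peaks.flags.shape
    band = config.seed_band_width
    if w <= 2 * band:
        raise ValidationError(
            f"image width {w} must exceed twice the seed band width ({band})"
        )
    in_band = np.zeros(w, dtype=bool)
    in_band[:band] = True
    in_band[w - band:] = True
    flags = peaks.flags & in_band[None, :]
    if config.seed_coherence_frac > 0:
        flags = flags.copy()
        need = config.seed_coherence_frac * band
        near = np.zeros_like(peaks.flags)  # flag within +-1 row
        near[1:] |= peaks.flags[:-1]
        near[:-1] |= peaks.flags[1:]
        near |= peaks.flags
        for sl in (slice(0, band), slice(w - band, w)):
            support = near[:, sl].sum(axis=1)  # columns voting per row
            flags[:, sl] &= (support >= need)[:, None]
    rows, cols = np.nonzero(flags)
    sep = config.seed_min_separation
    if enhanced is not None and sep > 0 and rows.size:
        vals = enhanced.pixels[rows, cols]
        keep = np.ones(rows.size, dtype=bool)
        for col in np.unique(cols):
            idx = np.nonzero(cols == col)[0]
            # strongest first; break value ties toward the shallower row
            order = idx[np.lexsort((rows[idx], -vals[idx]))]
            taken: list[int] = []
            for i in order:
                if all(abs(int(rows[i]) - t) >= sep for t in taken):
                    taken.append(int(rows[i]))
                else:
                    keep[i] = False
        rows, cols = rows[keep], cols[keep]
    order = np.lexsort((rows, cols))
    return [Seed(int(rows[i]), int(cols[i]), peaks.polarity) for i in order]


def _sweep(
    signal: np.ndarray,
    seed_rows: np.ndarray,
    seed_cols: np.ndarray,
    offsets: np.ndarray,
    direction: int,
    adapt: float,
    tie_tol: float,
    lost_frac: float,
) -> np.ndarray:
    """Grow every seed one column at a time in one direction.

    Returns (n_seeds, width) rows, -1 where a path (in this direction)
    does not reach. All seeds are advanced together, activating each one
    when the sweep passes its column, so the whole search is a single
    pass over the columns.
    """
    h, w = signal.shape
    k = seed_rows.size
    out = np.full((k, w), -1, dtype=np.int64)
    lost_out = np.zeros((k, w), dtype=bool)
    if k == 0:
        return out, lost_out
    order = np.argsort(seed_cols, kind="stable")
    if direction < 0:
        order = order[::-1]
    sr = seed_rows[order]
    sc = seed_cols[order]
    out[np.arange(k), sc] = sr

    cur = np.zeros(k, dtype=np.int64)
    val = np.zeros(k, dtype=float)
    prev = np.zeros(k, dtype=np.int64)
    ptr = 0
    cols_iter = range(1, w) if direction > 0 else range(w - 2, -1, -1)
    for c in cols_iter:
        # Activate seeds whose column the sweep has just passed.
        if direction > 0:
            while ptr < k and sc[ptr] <= c - 1:
                cur[ptr] = sr[ptr]
                val[ptr] = signal[sr[ptr], sc[ptr]]
                prev[ptr] = 0
                ptr += 1
        else:
            while ptr < k and sc[ptr] >= c + 1:
                cur[ptr] = sr[ptr]
                val[ptr] = signal[sr[ptr], sc[ptr]]
                prev[ptr] = 0
                ptr += 1
        if ptr == 0:
            continue
        n = ptr
        cand = np.clip(cur[:n, None] + offsets[None, :], 0, h - 1)
        vals = signal[cand, c]
        d = np.abs(vals - val[:n, None])
        dmin = d.min(axis=1)
        elig = d == dmin[:, None]
        disp = cand - cur[:n, None]
        # Near-ties (within the tolerance of the best) may keep the
        # previous direction; exact ties without a direction match fall
        # through to the smallest eligible row.
        pref = (d <= dmin[:, None] + tie_tol) & (disp == prev[:n, None])
        has_pref = pref.any(axis=1)
        # Candidates are in ascending row order, so argmax of the boolean
        # masks lands on the smallest eligible row — the final tie-break.
        choice = np.where(has_pref, pref.argmax(axis=1), elig.argmax(axis=1))
        if lost_frac > 0:
            # Signal lost: even the best candidate is far dimmer than
            # the reference — extend straight ahead until the signal
            # returns. (Straight, not the previous direction: a path
            # that went lost next to the vitreous would otherwise keep
            # diving through featureless background.)
            lost = vals.max(axis=1) < lost_frac * val[:n]
            if lost.any():
                straight = int(np.nonzero(offsets == 0)[0][0])
                choice = np.where(lost, straight, choice)
                lost_out[:n, c] = lost
        new = cand[np.arange(n), choice]
        prev[:n] = new - cur[:n]
        cur[:n] = new
        if adapt > 0:
            val[:n] = (1.0 - adapt) * val[:n] + adapt * signal[new, c]
        out[:n, c] = new

    unsorted = np.empty_like(out)
    unsorted[order] = out
    unsorted_lost = np.empty_like(lost_out)
    unsorted_lost[order] = lost_out
    return unsorted, unsorted_lost


def trace_paths(
    seeds: list[Seed], enhanced: EnhancedImage, config: SearchConfig
) -> list[TracedPath]:
    """Trace every seed bidirectionally so each path spans the full width."""
    sig = enhanced.pixels
    h, w = sig.shape
    if not seeds:
        return []
    rows = np.array([s.row for s in seeds], dtype=np.int64)
    cols = np.array([s.col for s in seeds], dtype=np.int64)
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise ValidationError("seed outside the image")
    offs = config.offsets
    adapt = 1.0 if config.value_reference == "running" else config.ref_adapt_rate
    tie_tol = config.tie_tolerance_frac * (float(sig.max()) if sig.size else 0.0)
    lost = config.lost_threshold_frac
    right, right_lost = _sweep(sig, rows, cols, offs, +1, adapt, tie_tol, lost)
    left, left_lost = _sweep(sig, rows, cols, offs, -1, adapt, tie_tol, lost)
    full = np.where(right >= 0, right, left)
    full_lost = np.where(right >= 0, right_lost, left_lost)
    if (full < 0).any():
        raise AssertionError("path failed to span the image width")
    return [TracedPath(full[i], seeds[i], full_lost[i]) for i in range(len(seeds))]


def trace_path(seed: Seed, enhanced: EnhancedImage, config: SearchConfig) -> TracedPath:
    """Trace a single seed (see :func:`trace_paths`)."""
    return trace_paths([seed], enhanced, config)[0]


def accumulate(paths: list[TracedPath], shape: tuple[int, int]) -> ProbabilityMap:
    """Superpose paths and convert counts to probabilities in percent.

    ``values[i, j] = 100 * (#paths through (i, j)) / N``. Because every
    path contributes exactly one pixel per column, each column of the
    map sums to 100.
    """
    n = len(paths)
    if n == 0:
        raise ValidationError("accumulate: need at least one path")
    counts = np.zeros(shape, dtype=np.int64)
    cols = np.arange(shape[1])
    for p in paths:
        if p.rows.shape != (shape[1],):
            raise ValidationError("accumulate: every path must span the full width")
        counts[p.rows, cols] += 1
    values = counts * 100.0 / n
    return ProbabilityMap(values, n, paths[0].origin.polarity)


def hysteresis_select(prob: ProbabilityMap, config: SearchConfig) -> BoundaryMask:
    """Standard dual-threshold (hysteresis) selection, 8-connected.

    Pixels >= high are kept; pixels >= low are kept iff connected
    (directly or transitively) to a strong pixel.
    """
    weak = prob.values >= config.low_threshold
    strong = prob.values >= config.high_threshold
    labels, _ = ndimage.label(weak, structure=_EIGHT)
    keep = np.unique(labels[strong])
    keep = keep[keep > 0]
    mask = np.isin(labels, keep)
    return BoundaryMask(mask, prob.polarity)


def trace_channel(
    enhanced: EnhancedImage,
    peaks: PeakMap,
    config: SearchConfig,
    full: bool = False,
):
    """Seed selection -> path tracing -> superposition -> dual threshold.

    Returns the :class:`BoundaryMask`, or the full :class:`TraceResult`
    (seeds, paths, probability map, mask) when ``full`` is true. With no
    seeds an empty mask is returned with a warning.
    """
    seeds = select_seeds(peaks, config, enhanced=enhanced)
    if not seeds:
        warnings.warn(
            f"no seed points in the {peaks.polarity.value} channel; empty mask",
            stacklevel=2,
        )
        mask = BoundaryMask(np.zeros(peaks.flags.shape, dtype=bool), peaks.polarity)
        result = TraceResult(seeds, [], None, mask)
        return result if full else mask
    paths = trace_paths(seeds, enhanced, config)
    prob = accumulate(paths, enhanced.pixels.shape)
    mask = hysteresis_select(prob, config)
    result = TraceResult(
        seeds, paths, prob, mask, lost_fraction_map(paths, enhanced.pixels.shape)
    )
    return result if full else mask
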