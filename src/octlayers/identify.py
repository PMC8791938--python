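"""Naming, ordering and smoothing of the eleven retinal boundaries.

The two polarity masks are reduced to full-width candidate curves, and
anatomy rules assign the names in a fixed order: the ILM is the
shallowest dark-to-bright interface on each A-scan; the o-IS carries
the brightest enhanced response after the ILM; o-ONL and o-OS flank it;
the o-RPE is the brightest bright-to-dark interface below the o-OS; the
o-OSJ lies strictly between o-IS and o-OS; o-OPL and o-IPL sit above
the o-ONL and o-INL; the o-NFL is the first bright-to-dark interface
under the ILM; and the o-GCL — typically the faintest interface — is
assigned last, between o-NFL and o-IPL.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import (
    BOUNDARY_ORDER,
    IdentificationError,
    ValidationError,
    boundary_polarity,
)
from .enhance import EnhancedImage
from .trace import BoundaryMask, ProbabilityMap

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class BoundaryCurve:
    """A named boundary: one (fractional) row per column."""

    name: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        boundary_polarity(self.name)  # raises on unknown names
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))


@dataclass(frozen=True)
class Segmentation:
    """Eleven named boundary curves with enforced depth ordering."""

    curves: dict[str, np.ndarray]
    shape: tuple[int, int]
    source: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.curves) != set(BOUNDARY_ORDER):
            missing = set(BOUNDARY_ORDER) - set(self.curves)
            raise ValidationError(f"segmentation missing boundaries: {sorted(missing)}")
        rows = self.rows_array()
        h, w = self.shape
        if rows.shape != (11, w):
            raise ValidationError("curve length does not match the image width")
        if rows.min() < 0 or rows.max() > h - 1:
            raise ValidationError("boundary rows outside the image")
        if np.any(np.diff(rows, axis=0) <= 0):
            raise ValidationError("boundaries are not strictly ordered in depth")

    def rows_array(self) -> np.ndarray:
        return np.stack([self.curves[n] for n in BOUNDARY_ORDER])

    def curve(self, name: str) -> BoundaryCurve:
        return BoundaryCurve(name, self.curves[name])

    def to_frame(self) -> pd.DataFrame:
        w = self.shape[1]
        data = {"column_index": np.arange(w)}
        for name in BOUNDARY_ORDER:
            data[name] = self.curves[name]
        return pd.DataFrame(data)


def _column_runs(
    rows: np.ndarray, mass: np.ndarray, bright: Optional[np.ndarray] = None
) -> list[tuple[float, float, float]]:
    """(centroid, mass, brightness) per run of consecutive rows, top down."""
    breaks = np.nonzero(np.diff(rows) > 1)[0] + 1
    if bright is None:
        bright = np.zeros_like(mass)
    out = []
    for chunk_rows, chunk_mass, chunk_b in zip(
        np.split(rows, breaks), np.split(mass, breaks), np.split(bright, breaks)
    ):
        m = float(chunk_mass.sum())
        b = float(chunk_b.max()) if chunk_b.size else 0.0
        if m <= 0:
            out.append((float(chunk_rows.mean()), 0.0, b))
        else:
            out.append((float((chunk_rows * chunk_mass).sum() / m), m, b))
    return out


class _Track:
    """A boundary hypothesis grown column by column from mask runs."""

    __slots__ = ("cols", "rows", "bright")

    def __init__(self, col: int, row: float, bright: float) -> None:
        self.cols = [col]
        self.rows = [row]
        self.bright = bright  # running mean enhanced response

    def predict(self, col: int) -> float:
        k = min(16, len(self.cols))
        span = self.cols[-1] - self.cols[-k]
        slope = (self.rows[-1] - self.rows[-k]) / span if span > 0 else 0.0
        return self.rows[-1] + slope * (col - self.cols[-1])

    def add(self, col: int, row: float, bright: float) -> None:
        self.cols.append(col)
        self.rows.append(row)
        self.bright = 0.9 * self.bright + 0.1 * bright


def extract_components(
    mask: BoundaryMask,
    weights: Optional[Union[ProbabilityMap, np.ndarray]] = None,
    min_span_frac: float = 0.9,
    max_track_gap: int = 30,
    signal: Optional[Union[EnhancedImage, np.ndarray]] = None,
    dim_bar: float = 0.25,
    lost_fraction: Optional[np.ndarray] = None,
    max_lost_frac: float = 0.5,
) -> list[np.ndarray]:
    """Reduce a boundary mask to full-width candidate curves.

    Each column of the mask is collapsed to the probability-weighted
    centroids of its pixel runs, and the runs are associated across
    columns into tracks: a run extends the track whose
    slope-extrapolated prediction it matches best (within a tolerance
    that grows with the gap), and unmatched runs open new tracks. The
    tracking bridges mask breakpoints — an 8-connected mask cannot
    follow an interface steeper than one row per column, so steep
    disease domes fragment it — while stray-path streaks peel off into
    short tracks of their own. Tracks covering at least
    ``min_span_frac`` of the image width are kept, interior gaps are
    filled by linear interpolation, the ends extended with their edge
    values, and candidates returned sorted shallow to deep by mean row.

    ``signal`` (the boundary-enhanced image) sharpens the association:
    a run far dimmer than the track's running brightness is accepted
    only when no plausibly bright run matches — a genuine interface
    stays bright along its length, while a stray-path streak lies on
    dark background.
    """
    flags = mask.flags
    h, w = flags.shape
    wt = None
    if weights is not None:
        wt = weights.values if isinstance(weights, ProbabilityMap) else np.asarray(weights)
        if wt.shape != flags.shape:
            raise ValidationError("weights shape does not match the mask")
    sig = None
    if signal is not None:
        sig = signal.pixels if isinstance(signal, EnhancedImage) else np.asarray(signal)
        if sig.shape != flags.shape:
            raise ValidationError("signal shape does not match the mask")
    if lost_fraction is not None:
        # Pixels carried mostly by signal-lost paths (straight flights
        # across shadows or away from a lost steep flank) hold no
        # boundary evidence; drop them before curve formation. The
        # probability map itself is left untouched.
        flags = flags & (np.asarray(lost_fraction) <= max_lost_frac)

    grid = np.arange(w)
    # Scan in both lateral directions: a track that loses a steep
    # descending flank to a stray-path streak in one direction meets
    # the same flank as a well-anchored ascent in the other.
    pieces: list[dict[int, float]] = []
    for direction in (+1, -1):
        for t in _run_tracking(flags, wt, sig, direction, max_track_gap, dim_bar):
            if len(t.cols) >= 20:
                pieces.append(dict(zip(t.cols, t.rows)))
    # Pieces (from either pass) that agree on their overlap describe
    # the same interface; merging them joins the complementary halves
    # each scan direction recovers around a steep dome.
    merged = True
    while merged:
        merged = False
        for i in range(len(pieces)):
            if pieces[i] is None:
                continue
            for j in range(i + 1, len(pieces)):
                if pieces[j] is None:
                    continue
                common = pieces[i].keys() & pieces[j].keys()
                if len(common) < 3:
                    continue
                # Median: a duplicate track's few corrupt end columns
                # must not keep it from being absorbed.
                diff = np.median([abs(pieces[i][c] - pieces[j][c]) for c in common])
                if diff <= 1.5:
                    for c, rv in pieces[j].items():
                        pieces[i][c] = 0.5 * (pieces[i][c] + rv) if c in pieces[i] else rv
                    pieces[j] = None
                    merged = True
    pieces = _join_piece_halves([p for p in pieces if p is not None])
    out: list[np.ndarray] = []
    for piece in pieces:
        if piece is None:
            continue
        cols = np.array(sorted(piece))
        # Span is lateral extent; joined halves may hold a short
        # interior hole (interpolated below) but must still be real
        # measurements over most of the width.
        extent = cols[-1] - cols[0] + 1
        if extent < min_span_frac * w or cols.size < 0.7 * w:
            continue
        curve = np.interp(grid, cols, np.array([piece[c] for c in cols]))
        if sig is not None:
            rr = np.clip(np.rint(curve).astype(int), 0, h - 1)
            lit_frac = float((sig[rr, grid] >= 0.05 * sig.max()).mean())
            # A genuine interface is lit along essentially its whole
            # length; a streak spends much of it on dark background.
            if lit_frac < 0.75:
                continue
        out.append(curve)
    # Retinal boundaries never cross. Two candidates that genuinely do
    # (running above each other on one side and below on the other)
    # are segment-swapped hybrids of two interfaces — a track that
    # changed rails at a steep dome apex, mirrored in the opposite
    # scan. Their element-wise min and max recover the two interfaces.
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                d = out[i] - out[j]
                if (d > 1).mean() >= 0.05 and (d < -1).mean() >= 0.05:
                    upper = np.minimum(out[i], out[j])
                    lower = np.maximum(out[i], out[j])
                    out[i], out[j] = upper, lower
                    changed = True
    deduped: list[np.ndarray] = []
    for curve in out:
        if all(np.abs(curve - kept).mean() >= 2.5 for kept in deduped):
            deduped.append(curve)
    deduped.sort(key=lambda r: float(r.mean()))
    return deduped


def _trimmed_anchor(piece: dict[int, float], side: str, trim: int = 8, base: int = 10):
    """(anchor col, anchor row, local slope) with the corrupt end removed.

    The last few columns of a dying track often drift off the
    interface, so the anchor is taken ``trim`` columns inside, with the
    slope estimated over the ``base`` columns behind it.
    """
    cols = sorted(piece)
    if side == "right":
        cols = cols[::-1]
    idx = min(trim, max(len(cols) - base - 1, 0))
    a_col = cols[idx]
    b_col = cols[min(idx + base, len(cols) - 1)]
    a_row, b_row = piece[a_col], piece[b_col]
    slope = (a_row - b_row) / (a_col - b_col) if a_col != b_col else 0.0
    return a_col, a_row, slope


def _join_piece_halves(
    pieces: list[dict[int, float]], max_gap: int = 60, max_overlap: int = 30
) -> list[dict[int, float]]:
    """Join curve halves whose extrapolations meet between them.

    Around a steep dome each scan direction recovers one half of a deep
    interface; the halves abut — or overlap with mutually corrupted
    ends — and are joined when extrapolating both toward the junction
    midpoint lands within a tolerance bounded well below the spacing
    of neighbouring interfaces. Joins are applied globally greedily by
    extrapolation error.
    """

    def _probe(i: int, j: int):
        end_i, start_j = max(pieces[i]), min(pieces[j])
        gap = start_j - end_i
        if not -max_overlap <= gap <= max_gap:
            return None
        trim = max(8, -gap + 4)  # anchors must sit outside the overlap
        ac, ar, aslope = _trimmed_anchor(pieces[i], "right", trim)
        bc, br, bslope = _trimmed_anchor(pieces[j], "left", trim)
        if bc <= ac:
            return None
        mid = 0.5 * (ac + bc)
        err = abs((ar + aslope * (mid - ac)) - (br + bslope * (mid - bc)))
        tol = min(3.0 + 0.4 * (bc - ac), 18.0)
        return (err, ac, bc) if err <= tol else None

    while True:
        joins = []
        for i in range(len(pieces)):
            if pieces[i] is None:
                continue
            for j in range(len(pieces)):
                if i == j or pieces[j] is None:
                    continue
                probe = _probe(i, j)
                if probe is not None:
                    joins.append((probe[0], i, j, probe[1], probe[2]))
        if not joins:
            break
        joins.sort()
        used: set[int] = set()
        applied = False
        for err, i, j, ac, bc in joins:
            if i in used or j in used or pieces[i] is None or pieces[j] is None:
                continue
            # Drop the corrupt facing ends, then union.
            a = {c: r for c, r in pieces[i].items() if c <= ac}
            b = {c: r for c, r in pieces[j].items() if c >= bc}
            for c, r in b.items():
                a[c] = 0.5 * (a[c] + r) if c in a else r
            pieces[i] = a
            pieces[j] = None
            used.update((i, j))
            applied = True
        if not applied:
            break
    return [p for p in pieces if p is not None]


def _run_tracking(
    flags: np.ndarray,
    wt: Optional[np.ndarray],
    sig: Optional[np.ndarray],
    direction: int,
    max_track_gap: int,
    dim_bar: float = 0.25,
) -> list[_Track]:
    h, w = flags.shape
    open_tracks: list[_Track] = []
    done: list[_Track] = []
    col_iter = range(w) if direction > 0 else range(w - 1, -1, -1)
    for c in col_iter:
        rows = np.flatnonzero(flags[:, c])
        if rows.size == 0:
            continue
        mass = wt[rows, c] if wt is not None else np.ones(rows.size)
        bright = sig[rows, c] if sig is not None else None
        runs = _column_runs(rows, mass, bright)
        # Retire tracks that have been silent too long.
        still = []
        for t in open_tracks:
            (done if abs(c - t.cols[-1]) > max_track_gap else still).append(t)
        open_tracks = still
        # One-to-one matching, established tracks first: a long track's
        # prediction is trustworthy and must not lose its run to a
        # young satellite track with a transiently smaller error. A run
        # far dimmer than the track's running brightness is accepted
        # only if no plausibly bright run matches.
        used_r: set[int] = set()
        for t in sorted(open_tracks, key=lambda t: -len(t.cols)):
            gap = abs(c - t.cols[-1])
            pred = t.predict(c)
            tol = min(2.5 + 0.5 * gap, 8.0)
            eligible = [
                (ri, run)
                for ri, run in enumerate(runs)
                if ri not in used_r and abs(run[0] - pred) <= tol
            ]
            if sig is not None:
                # A bright track never steps onto a dark run (a
                # stray-path streak); it waits for its own interface to
                # reappear after the gap instead.
                eligible = [e for e in eligible if e[1][2] >= dim_bar * t.bright]
            if eligible:
                ri, run = min(eligible, key=lambda e: abs(e[1][0] - pred))
                t.add(c, run[0], run[2])
                used_r.add(ri)
        for ri, run in enumerate(runs):
            if ri not in used_r:
                open_tracks.append(_Track(c, run[0], run[2]))
    done.extend(open_tracks)
    return done


# -- assignment helpers -----------------------------------------------------


def _brightness(curve: np.ndarray, enhanced: EnhancedImage) -> float:
    """Mean enhanced response sampled along a candidate curve."""
    h, w = enhanced.pixels.shape
    rows = np.clip(np.rint(curve).astype(int), 0, h - 1)
    return float(enhanced.pixels[rows, np.arange(w)].mean())


def _pop(cands: list[np.ndarray], idx: int) -> np.ndarray:
    return cands.pop(idx)


def _nearest_above(cands: Sequence[np.ndarray], ref: np.ndarray, name: str) -> int:
    means = [float(c.mean()) for c in cands]
    ref_mean = float(ref.mean())
    above = [i for i, m in enumerate(means) if m < ref_mean]
    if not above:
        raise IdentificationError(f"could not assign {name}: no candidate above")
    return max(above, key=lambda i: means[i])


def _nearest_below(cands: Sequence[np.ndarray], ref: np.ndarray, name: str) -> int:
    means = [float(c.mean()) for c in cands]
    ref_mean = float(ref.mean())
    below = [i for i, m in enumerate(means) if m > ref_mean]
    if not below:
        raise IdentificationError(f"could not assign {name}: no candidate below")
    return min(below, key=lambda i: means[i])


def _first_crossing_vote(
    cands: Sequence[np.ndarray], above_of: Optional[np.ndarray], name: str
) -> int:
    """Per-column 'first interface below X' votes with column majority.

    With ``above_of`` None the shallowest candidate per column wins the
    vote; otherwise the shallowest candidate strictly deeper than
    ``above_of`` in that column.
    """
    if not cands:
        raise IdentificationError(f"could not assign {name}: no candidates")
    stack = np.stack(cands)  # (k, w)
    if above_of is not None:
        masked = np.where(stack > above_of[None, :], stack, np.inf)
    else:
        masked = stack
    col_ok = np.isfinite(masked).any(axis=0)
    if not col_ok.any():
        raise IdentificationError(f"could not assign {name}: no candidate below")
    votes = masked[:, col_ok].argmin(axis=0)
    counts = np.bincount(votes, minlength=stack.shape[0])
    return int(counts.argmax())


def _enforce_ordering(rows: np.ndarray, height: int) -> np.ndarray:
    """Minimal-repair strict ordering: each curve >= previous + 1 px."""
    fixed = rows.copy()
    for k in range(1, fixed.shape[0]):
        np.maximum(fixed[k], fixed[k - 1] + 1.0, out=fixed[k])
    if fixed.max() > height - 1:
        raise IdentificationError(
            "ordering repair pushed a boundary outside the image"
        )
    return fixed


def identify_boundaries(
    d2b: Sequence[np.ndarray],
    b2d: Sequence[np.ndarray],
    d2b_enhanced: EnhancedImage,
    b2d_enhanced: EnhancedImage,
    shape: Optional[tuple[int, int]] = None,
    source: str = "",
    min_relative_brightness: float = 0.1,
) -> Segmentation:
    """Assign the eleven boundary names to candidate curves.

    Candidates whose mean enhanced response along the curve falls below
    ``min_relative_brightness`` of the channel's median candidate are
    discarded first: a genuine interface is bright along its whole
    length, whereas a stray-path streak crosses dark background.
    Raises :class:`IdentificationError` naming the first boundary that
    cannot be assigned. The assignment is invariant to the order of the
    candidate lists.
    """
    if shape is None:
        shape = d2b_enhanced.pixels.shape
    d = sorted((np.asarray(c, float) for c in d2b), key=lambda c: float(c.mean()))
    b = sorted((np.asarray(c, float) for c in b2d), key=lambda c: float(c.mean()))
    if min_relative_brightness > 0:
        for cands, enh in ((d, d2b_enhanced), (b, b2d_enhanced)):
            if not cands:
                continue
            bright = [_brightness(c, enh) for c in cands]
            floor = min_relative_brightness * float(np.median(bright))
            keep = [c for c, v in zip(cands, bright) if v >= floor]
            cands[:] = keep
    assigned: dict[str, np.ndarray] = {}

    # (1) ILM: shallowest dark-to-bright interface per A-scan (majority vote).
    ilm_i = _first_crossing_vote(d, None, "ILM")
    assigned["ILM"] = _pop(d, ilm_i)
    # (2) o-IS: brightest remaining dark-to-bright interface.
    if not d:
        raise IdentificationError("could not assign o-IS: no candidates left")
    ois_i = max(
        range(len(d)),
        key=lambda i: (_brightness(d[i], d2b_enhanced), -float(d[i].mean())),
    )
    assigned["o-IS"] = _pop(d, ois_i)
    # (3) o-ONL above it, o-OS below it.
    assigned["o-ONL"] = _pop(d, _nearest_above(d, assigned["o-IS"], "o-ONL"))
    assigned["o-OS"] = _pop(d, _nearest_below(d, assigned["o-IS"], "o-OS"))
    # (4) o-INL: nearest remaining dark-to-bright interface above o-ONL.
    assigned["o-INL"] = _pop(d, _nearest_above(d, assigned["o-ONL"], "o-INL"))
    # (5) o-RPE: brightest bright-to-dark interface below o-OS.
    oos_mean = float(assigned["o-OS"].mean())
    rpe_cands = [i for i, c in enumerate(b) if float(c.mean()) > oos_mean]
    if not rpe_cands:
        raise IdentificationError("could not assign o-RPE: no candidate below o-OS")
    rpe_i = max(
        rpe_cands,
        key=lambda i: (_brightness(b[i], b2d_enhanced), -float(b[i].mean())),
    )
    assigned["o-RPE"] = _pop(b, rpe_i)
    # (6) o-OSJ: between o-IS and o-OS — in the mean and in nearly
    # every column (the detected flanking curves are themselves noisy
    # estimates, so a literal every-column test would reject the true
    # interface for a single grazing column).
    is_m, os_m = float(assigned["o-IS"].mean()), float(assigned["o-OS"].mean())
    osj_cands = [
        i
        for i, c in enumerate(b)
        if is_m < float(c.mean()) < os_m
        and ((c > assigned["o-IS"]) & (c < assigned["o-OS"])).mean() >= 0.75
    ]
    if not osj_cands:
        raise IdentificationError(
            "could not assign o-OSJ: no candidate strictly between o-IS and o-OS"
        )
    osj_i = max(
        osj_cands,
        key=lambda i: (_brightness(b[i], b2d_enhanced), -float(b[i].mean())),
    )
    assigned["o-OSJ"] = _pop(b, osj_i)
    # (7) o-OPL above o-ONL; o-IPL above o-INL.
    assigned["o-OPL"] = _pop(b, _nearest_above(b, assigned["o-ONL"], "o-OPL"))
    assigned["o-IPL"] = _pop(b, _nearest_above(b, assigned["o-INL"], "o-IPL"))
    # (8) o-NFL: first bright-to-dark interface under the ILM.
    nfl_i = _first_crossing_vote(b, assigned["ILM"], "o-NFL")
    assigned["o-NFL"] = _pop(b, nfl_i)
    # (9) o-GCL: remaining dark-to-bright interface between o-NFL and o-IPL.
    lo, hi = float(assigned["o-NFL"].mean()), float(assigned["o-IPL"].mean())
    gcl_cands = [i for i, c in enumerate(d) if lo < float(c.mean()) < hi]
    if not gcl_cands:
        raise IdentificationError(
            "could not assign o-GCL: no candidate between o-NFL and o-IPL"
        )
    gcl_i = max(
        gcl_cands,
        key=lambda i: (_brightness(d[i], d2b_enhanced), -float(d[i].mean())),
    )
    assigned["o-GCL"] = _pop(d, gcl_i)

    rows = np.stack([assigned[n] for n in BOUNDARY_ORDER])
    rows = _enforce_ordering(rows, shape[0])
    seg = Segmentation(
        curves={n: rows[k] for k, n in enumerate(BOUNDARY_ORDER)},
        shape=shape,
        source=source,
    )
    seg.validate()
    return seg


def smooth_curves(seg: Segmentation, sigma: float = 3.0) -> Segmentation:
    """Gaussian smoothing of every curve along the column axis.

    ``sigma`` is in columns; 0 is the identity. Ordering is re-enforced
    with a minimal 1 px separation afterwards.
    """
    if sigma < 0:
        raise ValidationError("sigma: must be >= 0")
    rows = seg.rows_array()
    if sigma > 0:
        rows = gaussian_filter1d(rows, sigma, axis=1, mode="nearest")
    rows = np.clip(rows, 0.0, None)
    rows = _enforce_ordering(rows, seg.shape[0])
    out = Segmentation(
        curves={n: rows[k] for k, n in enumerate(BOUNDARY_ORDER)},
        shape=seg.shape,
        source=seg.source,
        meta=dict(seg.meta, smoothed_sigma=sigma),
    )
    out.validate()
    return out
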