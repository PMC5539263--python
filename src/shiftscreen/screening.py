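"""From raw shift grids to ranked findings and localized regions.

A raw result matrix always contains high scores at very small shifts:
neighboring pixels resemble each other, so shifting an image by a pixel
or two over itself produces many coincidental identities.  These
*trivial shifts* are excluded (toroidal Chebyshev distance from the
zero shift up to a configurable radius, default 5) before ranking.
The remaining shifts that pass a threshold — above it for the counting
statistics, below it for the variance statistic — become ranked
candidate shifts.

Localization matrices answer the complementary question "where in the
image does the duplicated material sit": each entry counts, over all
shifts, how often the 3×3 block anchored there was identical (or had a
difference variance below a cut-point).  Finally,
:func:`reconstruct_moves` decomposes a single-shift match mask into the
axis-aligned rectangles that a copy-and-paste manipulation would have
produced, plus the residual matched pixels no rectangle explains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shiftcompare import (
    MatchMask,
    ShiftGrid,
    _block_variances,
    _nn_block_mask,
    _scan_setup,
    _values,
)

__all__ = [
    "CandidateShift",
    "RectangleMove",
    "MoveReconstruction",
    "AlgorithmFindings",
    "ConsistencyError",
    "EmptyCandidateSpaceError",
    "exclude_trivial_shifts",
    "find_candidate_shifts",
    "localization_nn",
    "localization_variance",
    "reconstruct_moves",
    "screening_report",
    "write_report",
    "candidates_table",
    "DEFAULT_TRIVIAL_RADIUS",
]

#: Default exclusion radius around the zero shift, in pixels.
DEFAULT_TRIVIAL_RADIUS = 5


class EmptyCandidateSpaceError(ValueError):
    """Raised when trivial-shift exclusion leaves no eligible shift."""


class ConsistencyError(ValueError):
    """Raised when report inputs disagree on which images were scanned."""


@dataclass(frozen=True)
class CandidateShift:
    """A conspicuous shift surviving trivial-shift exclusion.

    ``rank`` is 1-based in the score ordering (descending for counting
    statistics, ascending for variance); ties are broken row-major by
    ``(di, dj)`` for determinism.
    """

    di: int
    dj: int
    score: float
    rank: int
    algorithm: str


@dataclass(frozen=True)
class RectangleMove:
    """A (source, target) rectangle pair explained by one shift.

    Rectangles are ``(top, left, height, width)``.  ``source`` lies in
    the first image's window coordinates; ``target`` is the same
    rectangle displaced by the shift (modulo the second image's
    dimensions when known).
    """

    source: tuple[int, int, int, int]
    target: tuple[int, int, int, int]
    shift: tuple[int, int]

    @property
    def area(self) -> int:
        return self.source[2] * self.source[3]


@dataclass
class MoveReconstruction:
    moves: list[RectangleMove]
    residual_count: int
    residual_mask: np.ndarray


@dataclass
class AlgorithmFindings:
    """One algorithm's contribution to a screening report."""

    algorithm: str
    images: tuple[str, ...]
    direction: str
    threshold: float
    trivial_radius: int
    candidates: list[CandidateShift]
    localization_summary: dict | None = None
    notes: list[str] = field(default_factory=list)


def _toroidal_trivial_mask(M: int, N: int, radius: int) -> np.ndarray:
    ii = np.minimum(np.arange(M), M - np.arange(M))[:, None]
    jj = np.minimum(np.arange(N), N - np.arange(N))[None, :]
    return np.maximum(ii, jj) <= radius


def exclude_trivial_shifts(grid: ShiftGrid, radius: int = DEFAULT_TRIVIAL_RADIUS) -> ShiftGrid:
    """Flag shifts within ``radius`` of the zero shift as ineligible.

    Distance is toroidal Chebyshev, so shifts near ``(M−1, N−1)`` —
    which are small displacements in the opposite direction — are
    excluded symmetrically.  Radius 0 still removes the zero shift, the
    exact self-overlap.  Raises :class:`EmptyCandidateSpaceError` if
    nothing remains.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    excl = _toroidal_trivial_mask(grid.shift_rows, grid.shift_cols, radius)
    if grid.excluded is not None:
        excl = excl | grid.excluded
    if excl.all():
        raise EmptyCandidateSpaceError(
            f"trivial-shift radius {radius} excludes the entire "
            f"{grid.shift_rows}x{grid.shift_cols} shift space"
        )
    return ShiftGrid(scores=grid.scores, algorithm=grid.algorithm, excluded=excl)


def find_candidate_shifts(
    grid: ShiftGrid,
    threshold: float,
    direction: str = "high",
    radius: int = DEFAULT_TRIVIAL_RADIUS,
) -> list[CandidateShift]:
    """Rank eligible shifts passing a score threshold.

    ``direction='high'`` keeps shifts with score strictly above the
    threshold (counting statistics: "more identical pixels than");
    ``direction='low'`` keeps scores strictly below it (variance
    cut-point).  Candidates are ordered best-first with row-major
    tie-breaking and carry consecutive 1-based ranks.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    g = exclude_trivial_shifts(grid, radius)
    eligible = ~g.excluded
    passing = (
        (g.scores > threshold) if direction == "high" else (g.scores < threshold)
    ) & eligible
    coords = np.argwhere(passing)
    scores = g.scores[passing]
    sign = -1.0 if direction == "high" else 1.0
    order = np.lexsort((coords[:, 1], coords[:, 0], sign * scores))
    return [
        CandidateShift(
            di=int(coords[k, 0]),
            dj=int(coords[k, 1]),
            score=float(scores[k]) if grid.algorithm == "variance" else int(scores[k]),
            rank=rank,
            algorithm=grid.algorithm,
        )
        for rank, k in enumerate(order, start=1)
    ]


def localization_nn(A, B) -> np.ndarray:
    """Per-pixel count of identical 3×3 neighborhoods over all shifts.

    Entry ``(r, c)`` counts the shifts at which the block anchored at
    ``(r, c)`` is identical in both overlaid images.  Anchors beyond the
    non-wrapping interior are zero.  The grand total equals the sum of
    the nearest-neighbor shift grid: each identical block increments its
    anchor once per shift.
    """
    a_win, b_big, M, N, m, n = _scan_setup(A, B)
    if m < 3 or n < 3:
        raise ValueError("nearest-neighbor localization needs a window of at least 3x3")
    has_sent = a_win.min() < 0 or b_big.min() < 0
    a_valid = a_win >= 0
    counts = np.zeros((m, n), dtype=np.int64)
    for i in range(M):
        for j in range(N):
            b_win = b_big[i : i + m, j : j + n]
            eq = a_win == b_win
            if has_sent:
                eq &= a_valid & (b_win >= 0)
            counts[: m - 2, : n - 2] += _nn_block_mask(eq)
    return counts


def localization_variance(A, B, cutpoint: float) -> np.ndarray:
    """Per-pixel count of low-variance 3×3 blocks over all shifts.

    Entry ``(r, c)`` counts the shifts at which the difference variance
    of the (toroidal) block anchored at ``(r, c)`` is strictly below
    ``cutpoint``.  Rejects monochrome-masked inputs like the variance
    shift statistic itself.
    """
    if cutpoint < 0:
        raise ValueError("cutpoint must be >= 0")
    a = _values(A)
    b = _values(B)
    if a.min() < 0 or b.min() < 0:
        raise ValueError(
            "the variance algorithm does not support monochrome-masked images"
        )
    a_win, b_big, M, N, m, n = _scan_setup(a, b)
    if m < 3 or n < 3:
        raise ValueError("variance localization needs a window of at least 3x3")
    a_f = a_win.astype(np.float64)
    b_f = b_big.astype(np.float64)
    counts = np.zeros((m, n), dtype=np.int64)
    for i in range(M):
        for j in range(N):
            d = a_f - b_f[i : i + m, j : j + n]
            counts += _block_variances(d) < cutpoint
    return counts


def _largest_true_rectangle(mask: np.ndarray) -> tuple[int, int, int, int, int]:
    """Largest all-true axis-aligned rectangle of a boolean matrix.

    Returns ``(area, top, left, height, width)``; ties resolved toward
    the smallest ``(top, left)`` row-major.  Stack-of-heights algorithm,
    O(rows·cols).
    """
    rows, cols = mask.shape
    best = (0, 0, 0, 0, 0)
    heights = np.zeros(cols, dtype=np.int64)
    for r in range(rows):
        heights = (heights + 1) * mask[r]
        stack: list[tuple[int, int]] = []
        for c, h in enumerate(list(heights) + [0]):
            start = c
            while stack and stack[-1][1] >= h:
                sc, sh = stack.pop()
                area = int(sh) * (c - sc)
                top = r - int(sh) + 1
                cand = (area, top, sc, int(sh), c - sc)
                if area > best[0] or (
                    area == best[0] and (top, sc) < (best[1], best[2])
                ):
                    best = cand
                start = sc
            if h > 0 and (not stack or stack[-1][1] < h):
                stack.append((start, int(h)))
    return best


def reconstruct_moves(
    mask, shift=None, *, min_area: int = 9, wrap_shape=None
) -> MoveReconstruction:
    """Decompose a match mask into copy-and-paste rectangle moves.

    Greedily extracts the largest all-true rectangle, removes it and
    repeats while rectangles of at least ``min_area`` pixels remain
    (default 9, the area of one 3×3 neighborhood — the smallest region
    the block statistics can certify).  Each rectangle is reported with
    its shift-displaced counterpart; leftover true pixels are the
    residual, reported separately rather than forced into rectangles.
    """
    if isinstance(mask, MatchMask):
        if shift is None:
            shift = mask.shift
        if wrap_shape is None:
            wrap_shape = mask.b_shape
        work = mask.mask.copy()
    else:
        work = np.asarray(mask, dtype=bool).copy()
        if shift is None:
            raise ValueError("shift is required when passing a plain mask")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    di, dj = int(shift[0]), int(shift[1])
    moves: list[RectangleMove] = []
    while True:
        area, top, left, h, w = _largest_true_rectangle(work)
        if area < min_area:
            break
        tr, tc = top + di, left + dj
        if wrap_shape is not None:
            tr %= wrap_shape[0]
            tc %= wrap_shape[1]
        moves.append(
            RectangleMove(
                source=(top, left, h, w), target=(tr, tc, h, w), shift=(di, dj)
            )
        )
        work[top : top + h, left : left + w] = False
    return MoveReconstruction(
        moves=moves,
        residual_count=int(work.sum()),
        residual_mask=work,
    )


def _candidate_dict(c: CandidateShift) -> dict:
    return {"di": c.di, "dj": c.dj, "score": c.score, "rank": c.rank}


def screening_report(
    findings: Sequence[AlgorithmFindings],
    metadata: Mapping,
    artifact_paths: Mapping[str, str] | None = None,
) -> dict:
    """Assemble one scan's findings into a JSON-ready report.

    Field ordering is fixed by construction, so identical inputs yield
    byte-identical serialized reports.  All findings must refer to the
    same images as ``metadata['images']``.
    """
    images = tuple(metadata.get("images", ()))
    for f in findings:
        if tuple(f.images) != images:
            raise ConsistencyError(
                f"findings for images {f.images} mixed into a report for {images}"
            )
    algorithms = {}
    for f in findings:
        algorithms[f.algorithm] = {
            "direction": f.direction,
            "threshold": float(f.threshold),
            "trivial_radius": int(f.trivial_radius),
            "n_candidates": len(f.candidates),
            "candidates": [_candidate_dict(c) for c in f.candidates],
            "localization_summary": f.localization_summary,
            "notes": list(f.notes),
        }
    report = {
        "images": list(images),
        "mode": metadata.get("mode", "scan"),
        "config": dict(metadata.get("config", {})),
        "algorithms": algorithms,
        "artifacts": dict(artifact_paths or {}),
        "generated_at": metadata.get("generated_at"),
    }
    return report


def write_report(report: Mapping, path) -> None:
    """Serialize a report as pretty-printed JSON (insertion order kept)."""
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def candidates_table(findings: Sequence[AlgorithmFindings]) -> pd.DataFrame:
    """Flat candidate table across algorithms, for CSV export."""
    rows = []
    for f in findings:
        for c in f.candidates:
            rows.append(
                {
                    "image_a": f.images[0],
                    "image_b": f.images[-1],
                    "algorithm": c.algorithm,
                    "shift_rows": c.di,
                    "shift_cols": c.dj,
                    "score": c.score,
                    "rank": c.rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "image_a",
            "image_b",
            "algorithm",
            "shift_rows",
            "shift_cols",
            "score",
            "rank",
        ],
    )
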