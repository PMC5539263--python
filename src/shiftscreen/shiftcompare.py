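"""Exhaustive cyclic-shift comparison of two image matrices.

Two images (or an image against itself) are superimposed at every
possible relative displacement.  Rows and columns that do not overlap
wrap around to the opposite side, so a shift by one row pairs the first
row of one image with the last row of the other.  Under this cyclic
convention every pixel pair is superimposed at exactly one shift, which
gives the pixel-wise statistic an exact conservation law over the whole
shift space (see :func:`pixelwise_shift_counts`).

Three statistics score each shift:

``pixelwise``
    the number of exactly identical superimposed pixels;
``nearest_neighbor``
    the number of positions whose full 3×3 neighborhood is identical in
    both overlaid images, anchored at the block's top-left pixel;
``variance``
    the sum over 3×3 blocks of the population variance of the per-pixel
    differences — zero for regions identical up to a constant brightness
    offset, which makes this the statistic of choice for copies whose
    contrast was nudged to blend in.

Each statistic fills a *result matrix* (:class:`ShiftGrid`): entry
``(i, j)`` scores the shift by ``i`` rows and ``j`` columns.

For unequal image sizes the comparison window is the smaller image's
extent, the shift space is the larger extent in each dimension, and each
image is indexed modulo its own dimensions, so every relative placement
of the smaller image over the larger one is covered.  Callers comparing
a crop against a full image should pass the crop first: the window then
equals the crop and the shift equals the crop's position.

Block anchoring differs deliberately between the two 3×3 statistics.
Nearest-neighbor blocks never wrap: a count certifies a real contiguous
image neighborhood, and the zero-shift self-count is ``(m−2)(n−2)``.
Variance blocks wrap toroidally within the window, matching the cyclic
geometry of the overlay itself; this makes the variance grid exactly
symmetric under swapping the two images, a property non-wrapping
anchoring cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import MaskedImage, as_image_matrix, write_heatmap_png

__all__ = [
    "ALGORITHMS",
    "ShiftGrid",
    "MatchMask",
    "cyclic_overlay",
    "pixelwise_shift_counts",
    "nn_shift_counts",
    "variance_shift_sums",
    "match_mask",
    "block_template_search",
    "brute_force_oracle",
]

ALGORITHMS = ("pixelwise", "nearest_neighbor", "variance")


@dataclass
class ShiftGrid:
    """Per-shift statistic matrix.

    ``scores[i, j]`` scores the cyclic shift by ``i`` rows, ``j``
    columns.  ``excluded`` (optional) flags shifts ruled ineligible by
    trivial-shift filtering; ``None`` means no filtering was applied.
    """

    scores: np.ndarray
    algorithm: str
    excluded: np.ndarray | None = None

    @property
    def shift_rows(self) -> int:
        return self.scores.shape[0]

    @property
    def shift_cols(self) -> int:
        return self.scores.shape[1]

    def eligible_scores(self) -> np.ndarray:
        """Scores at non-excluded shifts, as a flat array."""
        if self.excluded is None:
            return self.scores.ravel()
        return self.scores[~self.excluded]

    def to_csv(self, path) -> None:
        """Write the grid as CSV; row index = row shift, column = column shift."""
        pd.DataFrame(self.scores).to_csv(Path(path))

    def to_heatmap_png(self, path) -> None:
        write_heatmap_png(self.scores, path)


@dataclass
class MatchMask:
    """Boolean map of exact matches at a single shift.

    For ``pixelwise`` the mask covers the comparison window and is true
    where the superimposed pixels are identical; for
    ``nearest_neighbor`` it covers the anchor positions
    ``(m−2)×(n−2)`` and is true where the full 3×3 block is identical.
    """

    mask: np.ndarray
    shift: tuple[int, int]
    algorithm: str
    b_shape: tuple[int, int] | None = None

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.mask))


def _values(x) -> np.ndarray:
    """int32 value grid from an image matrix or a MaskedImage."""
    if isinstance(x, MaskedImage):
        return x.values
    return as_image_matrix(x)


def _geometry(a: np.ndarray, b: np.ndarray):
    """Comparison window (min dims) and shift space (max dims)."""
    m = min(a.shape[0], b.shape[0])
    n = min(a.shape[1], b.shape[1])
    M = max(a.shape[0], b.shape[0])
    N = max(a.shape[1], b.shape[1])
    if m == 0 or n == 0:
        raise ValueError("empty comparison window")
    return M, N, m, n


def _tile_cover(b: np.ndarray, rows_needed: int, cols_needed: int) -> np.ndarray:
    """Tile ``b`` so that plain slicing realizes modular indexing."""
    reps_r = -(-rows_needed // b.shape[0])
    reps_c = -(-cols_needed // b.shape[1])
    return np.tile(b, (reps_r, reps_c))[:rows_needed, :cols_needed]


def cyclic_overlay(A, B, shift):
    """Pair the pixels of ``A`` and ``B`` at one cyclic shift.

    Returns ``(a_win, b_win)``, two arrays over the comparison window
    where ``a_win[r, c] = A[r, c]`` and
    ``b_win[r, c] = B[(r + di) mod rows_B, (c + dj) mod cols_B]``.
    """
    a = _values(A)
    b = _values(B)
    M, N, m, n = _geometry(a, b)
    di, dj = int(shift[0]), int(shift[1])
    if not (0 <= di < M and 0 <= dj < N):
        raise ValueError(f"shift {shift} outside shift space {M}x{N}")
    rows = (np.arange(m) + di) % b.shape[0]
    cols = (np.arange(n) + dj) % b.shape[1]
    return a[:m, :n], b[np.ix_(rows, cols)]


def _eq_window(a_win, b_win):
    """Exact equality with sentinel semantics: negatives never match."""
    eq = a_win == b_win
    if a_win.min() < 0 or b_win.min() < 0:
        eq &= (a_win >= 0) & (b_win >= 0)
    return eq


def _scan_setup(A, B):
    a = _values(A)
    b = _values(B)
    M, N, m, n = _geometry(a, b)
    a_win = a[:m, :n]
    b_big = _tile_cover(b, M + m, N + n)
    return a_win, b_big, M, N, m, n


def pixelwise_shift_counts(A, B) -> ShiftGrid:
    """Count identical superimposed pixels at every cyclic shift.

    For equal-size unmasked images the counts obey an exact histogram
    conservation law: summed over all shifts they equal
    ``Σ_v h_A(v)·h_B(v)`` where ``h`` is the gray-level histogram,
    because every pixel pair meets at exactly one shift.
    """
    a_win, b_big, M, N, m, n = _scan_setup(A, B)
    has_sent = a_win.min() < 0 or b_big.min() < 0
    a_valid = a_win >= 0
    out = np.zeros((M, N), dtype=np.int64)
    for i in range(M):
        for j in range(N):
            b_win = b_big[i : i + m, j : j + n]
            eq = a_win == b_win
            if has_sent:
                eq &= a_valid & (b_win >= 0)
            out[i, j] = np.count_nonzero(eq)
    return ShiftGrid(scores=out, algorithm="pixelwise")


def _nn_block_mask(eq: np.ndarray) -> np.ndarray:
    """Anchors of non-wrapping 3×3 blocks that are entirely equal."""
    r = eq[:-2, :] & eq[1:-1, :] & eq[2:, :]
    return r[:, :-2] & r[:, 1:-1] & r[:, 2:]


def nn_shift_counts(A, B) -> ShiftGrid:
    """Count identical 3×3 pixel blocks at every cyclic shift.

    A block counts only if all nine pixels are identical; the count is
    anchored at the block's top-left pixel and blocks never wrap, so
    scores lie in ``[0, (m−2)(n−2)]``.
    """
    a_win, b_big, M, N, m, n = _scan_setup(A, B)
    if m < 3 or n < 3:
        raise ValueError("nearest-neighbor comparison needs a window of at least 3x3")
    has_sent = a_win.min() < 0 or b_big.min() < 0
    a_valid = a_win >= 0
    out = np.zeros((M, N), dtype=np.int64)
    for i in range(M):
        for j in range(N):
            b_win = b_big[i : i + m, j : j + n]
            eq = a_win == b_win
            if has_sent:
                eq &= a_valid & (b_win >= 0)
            out[i, j] = np.count_nonzero(_nn_block_mask(eq))
    return ShiftGrid(scores=out, algorithm="nearest_neighbor")


def _block_variances(d: np.ndarray) -> np.ndarray:
    """Population variance of every toroidal 3×3 block of ``d``.

    Entry ``(r, c)`` is the variance (divide by 9) of the nine values at
    ``((r+dr) mod m, (c+dc) mod n)``, ``dr, dc ∈ {0, 1, 2}`` — one block
    per window position, wrapping at the window edge.
    """
    m, n = d.shape
    dt = _tile_cover(d, m + 2, n + 2)
    c1 = dt[:, :-2] + dt[:, 1:-1] + dt[:, 2:]
    s1 = c1[:-2, :] + c1[1:-1, :] + c1[2:, :]
    d2 = dt * dt
    c2 = d2[:, :-2] + d2[:, 1:-1] + d2[:, 2:]
    s2 = c2[:-2, :] + c2[1:-1, :] + c2[2:, :]
    return s2 / 9.0 - (s1 / 9.0) ** 2


def variance_shift_sums(A, B) -> ShiftGrid:
    """Sum of 3×3-block difference variances at every cyclic shift.

    At each shift the difference image ``d = A − B_shifted`` is formed
    over the comparison window and the population variances of all its
    toroidal 3×3 blocks are accumulated.  A constant difference has zero
    variance, so the statistic flags regions identical up to a uniform
    brightness offset; low scores signal similarity.

    Raises if either input contains monochrome-mask sentinels: a
    sentinel is an arbitrary placeholder, not a brightness, so block
    variances over it are meaningless — use the counting algorithms for
    masked images.
    """
    a = _values(A)
    b = _values(B)
    if a.min() < 0 or b.min() < 0:
        raise ValueError(
            "the variance algorithm does not support monochrome-masked images; "
            "use the pixelwise or nearest-neighbor algorithms instead"
        )
    M, N, m, n = _geometry(a, b)
    if m < 3 or n < 3:
        raise ValueError("variance comparison needs a window of at least 3x3")
    a_win = a[:m, :n].astype(np.float64)
    b_big = _tile_cover(b, M + m, N + n).astype(np.float64)
    out = np.zeros((M, N), dtype=np.float64)
    for i in range(M):
        for j in range(N):
            d = a_win - b_big[i : i + m, j : j + n]
            out[i, j] = float(_block_variances(d).sum())
    return ShiftGrid(scores=out, algorithm="variance")


def match_mask(A, B, shift, algorithm: str) -> MatchMask:
    """Boolean map of exact matches at a single shift.

    Supports ``pixelwise`` (per-pixel identity over the window) and
    ``nearest_neighbor`` (per-anchor 3×3 identity); the variance
    statistic has no per-pixel identity notion and is rejected.
    """
    if algorithm == "variance":
        raise ValueError("match_mask is undefined for the variance algorithm")
    if algorithm not in ("pixelwise", "nearest_neighbor"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    a_win, b_win = cyclic_overlay(A, B, shift)
    eq = _eq_window(a_win, b_win)
    if algorithm == "nearest_neighbor":
        if eq.shape[0] < 3 or eq.shape[1] < 3:
            raise ValueError("nearest-neighbor mask needs a window of at least 3x3")
        eq = _nn_block_mask(eq)
    return MatchMask(
        mask=eq,
        shift=(int(shift[0]), int(shift[1])),
        algorithm=algorithm,
        b_shape=_values(B).shape,
    )


def block_template_search(img, anchor, height, width) -> list[tuple[int, int]]:
    """Find every exact recurrence of a rectangular block in an image.

    The block of size ``height × width`` anchored at ``anchor`` is
    compared against every placement inside ``img``; the list of
    top-left positions of exact matches (always including the anchor
    itself) is returned in row-major order.  This is the direct check to
    run once a suspicious region has been spotted, without any prior
    knowledge of where its source might be.
    """
    a = as_image_matrix(img)
    r, c = int(anchor[0]), int(anchor[1])
    h, w = int(height), int(width)
    if h < 1 or w < 1:
        raise ValueError("block dimensions must be positive")
    if r < 0 or c < 0 or r + h > a.shape[0] or c + w > a.shape[1]:
        raise ValueError("block exceeds image bounds")
    block = a[r : r + h, c : c + w]
    windows = np.lib.stride_tricks.sliding_window_view(a, (h, w))
    hits = np.all(windows == block, axis=(2, 3))
    return [tuple(int(v) for v in pos) for pos in np.argwhere(hits)]


def brute_force_oracle(A, B, algorithm: str) -> ShiftGrid:
    """Reference implementation by direct nested loops.

    Shares no code with the scanning implementations above; intended as
    an independent cross-check on small inputs (≤ 16×16 recommended —
    the loops are pure Python and deliberately naive).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    a = _values(A).tolist()
    b = _values(B).tolist()
    Ra, Ca = len(a), len(a[0])
    Rb, Cb = len(b), len(b[0])
    M, N = max(Ra, Rb), max(Ca, Cb)
    m, n = min(Ra, Rb), min(Ca, Cb)
    if algorithm in ("nearest_neighbor", "variance") and (m < 3 or n < 3):
        raise ValueError("window of at least 3x3 required")
    if algorithm == "variance":
        for row in a + b:
            if any(v < 0 for v in row):
                raise ValueError("variance oracle does not support sentinels")
    dtype = np.float64 if algorithm == "variance" else np.int64
    out = np.zeros((M, N), dtype=dtype)
    for i in range(M):
        for j in range(N):
            if algorithm == "pixelwise":
                s = 0
                for r in range(m):
                    for c in range(n):
                        va = a[r][c]
                        vb = b[(r + i) % Rb][(c + j) % Cb]
                        if va >= 0 and vb >= 0 and va == vb:
                            s += 1
                out[i, j] = s
            elif algorithm == "nearest_neighbor":
                s = 0
                for r in range(m - 2):
                    for c in range(n - 2):
                        ok = True
                        for dr in range(3):
                            for dc in range(3):
                                va = a[r + dr][c + dc]
                                vb = b[(r + dr + i) % Rb][(c + dc + j) % Cb]
                                if va < 0 or vb < 0 or va != vb:
                                    ok = False
                                    break
                            if not ok:
                                break
                        if ok:
                            s += 1
                out[i, j] = s
            else:
                total = 0.0
                for r in range(m):
                    for c in range(n):
                        vals = []
                        for dr in range(3):
                            for dc in range(3):
                                rr = (r + dr) % m
                                cc = (c + dc) % n
                                vals.append(
                                    a[rr][cc] - b[(rr + i) % Rb][(cc + j) % Cb]
                                )
                        mean = sum(vals) / 9.0
                        total += sum((v - mean) ** 2 for v in vals) / 9.0
                out[i, j] = total
    return ShiftGrid(scores=out, algorithm=algorithm)
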