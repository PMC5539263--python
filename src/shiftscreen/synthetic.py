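"""Seeded synthetic fixtures with known ground truth.

The generators emulate the two manipulation scenarios the screening
pipeline targets: a micrograph/blot-like noisy background in which a
rectangle has been copied elsewhere in the same image (optionally with a
constant brightness offset, as happens when a pasted region's contrast
is nudged to blend in), and a duplicated crop reused as a second image.

Backgrounds are i.i.d. uniform integer levels over a configurable
range — the simplest model of the weak, high-entropy background noise
that makes copy-move detection feasible in real blots and micrographs.
Real backgrounds are textured and spatially correlated; these fixtures
emulate the *role* of such backgrounds (many distinct levels, negligible
chance of accidental 3×3 identity), not their statistics.

Every generator is a pure function of its arguments including the seed,
so fixtures are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .image_io import as_image_matrix, write_image

__all__ = [
    "CopySpec",
    "FixtureSpec",
    "gen_background",
    "plant_copy",
    "gen_duplicate_pair",
    "build_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class CopySpec:
    """One planted copy: source rectangle, destination origin, offset."""

    source: tuple[int, int, int, int]  # top, left, height, width
    dest: tuple[int, int]  # top, left
    offset: int = 0


@dataclass
class FixtureSpec:
    """Complete recipe for a synthetic fixture.

    ``copies`` are applied in order to the generated background;
    ``crop`` (top, left, height, width), if given, additionally yields a
    duplicated-crop partner image.
    """

    rows: int = 100
    cols: int = 100
    level_low: int = 96
    level_high: int = 159
    copies: list[CopySpec] = field(default_factory=list)
    crop: tuple[int, int, int, int] | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        d["copies"] = [
            CopySpec(
                source=tuple(c["source"]), dest=tuple(c["dest"]), offset=c["offset"]
            )
            for c in d.get("copies", [])
        ]
        if d.get("crop") is not None:
            d["crop"] = tuple(d["crop"])
        return cls(**d)


def gen_background(rows: int, cols: int, level_low: int, level_high: int, seed: int) -> np.ndarray:
    """i.i.d. uniform integer noise on ``[level_low, level_high]``.

    Identical arguments (including seed) produce bit-identical images.
    """
    if rows < 1 or cols < 1:
        raise ValueError("image dimensions must be positive")
    if not (0 <= level_low <= level_high <= 255):
        raise ValueError("need 0 <= level_low <= level_high <= 255")
    rng = np.random.default_rng(seed)
    return rng.integers(level_low, level_high + 1, size=(rows, cols), dtype=np.int32)


def plant_copy(img, source_rect, dest_origin, offset_levels: int = 0):
    """Copy a rectangle within an image, optionally brightness-offset.

    Destination pixels become source pixels plus ``offset_levels``.
    Returns ``(image, ground_truth_shift)`` where the shift is
    ``((dest_row − src_row) mod rows, (dest_col − src_col) mod cols)`` —
    the displacement at which the cyclic self-comparison superimposes
    the two copies.  Rejects out-of-bounds rectangles and any offset
    that would clip levels outside ``[0, 255]``.
    """
    a = as_image_matrix(img).copy()
    sr, sc, h, w = (int(v) for v in source_rect)
    dr, dc = (int(v) for v in dest_origin)
    rows, cols = a.shape
    if h < 1 or w < 1:
        raise ValueError("copy rectangle must be non-empty")
    if sr < 0 or sc < 0 or sr + h > rows or sc + w > cols:
        raise ValueError("source rectangle exceeds image bounds")
    if dr < 0 or dc < 0 or dr + h > rows or dc + w > cols:
        raise ValueError("destination rectangle exceeds image bounds")
    block = a[sr : sr + h, sc : sc + w] + int(offset_levels)
    if block.min() < 0 or block.max() > 255:
        raise ValueError("brightness offset would clip levels outside [0, 255]")
    a[dr : dr + h, dc : dc + w] = block
    shift = ((dr - sr) % rows, (dc - sc) % cols)
    return a, shift


def gen_duplicate_pair(img, crop_rect):
    """Original image plus a cropped detail, with the aligning shift.

    Returns ``(original, crop, ground_truth_shift)``.  When the crop is
    compared against the original (crop first, so the comparison window
    is the crop), the pixel-wise statistic scores the full crop area at
    ``ground_truth_shift = (crop_top, crop_left)``.
    """
    a = as_image_matrix(img)
    r, c, h, w = (int(v) for v in crop_rect)
    if h < 1 or w < 1:
        raise ValueError("crop rectangle must be non-empty")
    if r < 0 or c < 0 or r + h > a.shape[0] or c + w > a.shape[1]:
        raise ValueError("crop rectangle exceeds image bounds")
    crop = a[r : r + h, c : c + w].copy()
    return a, crop, (r, c)


def build_fixture(spec: FixtureSpec):
    """Materialize a fixture spec.

    Returns ``(image, ground_truth)`` where ``ground_truth`` is a dict
    with the planted shifts (one per copy) and, if a crop is requested,
    the partner image and its aligning shift under key ``pair``.
    """
    img = gen_background(spec.rows, spec.cols, spec.level_low, spec.level_high, spec.seed)
    shifts = []
    for cp in spec.copies:
        img, shift = plant_copy(img, cp.source, cp.dest, cp.offset)
        shifts.append(shift)
    truth: dict = {"copy_shifts": shifts}
    pair_img = None
    if spec.crop is not None:
        _, pair_img, pair_shift = gen_duplicate_pair(img, spec.crop)
        truth["pair_shift"] = pair_shift
    return img, pair_img, truth


def write_fixture(spec: FixtureSpec, outdir, stem: str = "fixture"):
    """Write a fixture as PNG(s) plus a JSON sidecar with ground truth.

    Returns the sidecar path.  The sidecar records the full spec and the
    planted shifts, so downstream checks never need to re-derive them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img, pair_img, truth = build_fixture(spec)
    png = outdir / f"{stem}.png"
    write_image(img, png)
    files = {"image": png.name}
    if pair_img is not None:
        pair_png = outdir / f"{stem}_crop.png"
        write_image(pair_img, pair_png)
        files["crop"] = pair_png.name
    sidecar = outdir / f"{stem}.json"
    payload = {
        "spec": json.loads(spec.to_json()),
        "ground_truth": {
            "copy_shifts": [list(s) for s in truth["copy_shifts"]],
            **(
                {"pair_shift": list(truth["pair_shift"])}
                if "pair_shift" in truth
                else {}
            ),
        },
        "files": files,
    }
    sidecar.write_text(json.dumps(payload, indent=2) + "\n")
    return sidecar
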