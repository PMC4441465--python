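"""Chaos Game Representation (CGR) of DNA sequences.

The CGR places the four bases at the corners of the unit square —
A, C, G, T clockwise starting from the bottom-left corner, with the y axis
pointing up::

    C (0,1) ---- G (1,1)
      |            |
    A (0,0) ---- T (1,0)

Starting from the center (0.5, 0.5), each successive base moves the current
point halfway toward its corner.  At raster resolution 2^k x 2^k every pixel
corresponds bijectively to one k-mer: a pixel is black (0) exactly when its
k-mer occurs in the sequence, white (255) otherwise.

Encoding is done directly from the sliding k-mer window rather than by
rasterizing the trajectory: the first k-1 trajectory points carry a
start-point transient (a residual of the initial center) and would blacken
pixels of k-mers that never occur.  The iterative trajectory is kept as a
verification oracle (the final point of the trajectory restricted to a
k-mer lands strictly inside that k-mer's pixel cell) and for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .sequence_io import SequenceRecord, encode

#: Unit-square corners, A,C,G,T clockwise from bottom-left (y up).
CORNERS = {
    "A": (0.0, 0.0),
    "C": (0.0, 1.0),
    "G": (1.0, 1.0),
    "T": (1.0, 0.0),
}

# Quadrant half-bits: x is 1 for G/T (right half), y is 1 for C/G (top half).
_XBIT = {"A": 0, "C": 0, "G": 1, "T": 1}
_YBIT = {"A": 0, "C": 1, "G": 1, "T": 0}


@dataclass
class CGRImage:
    """A 2^k x 2^k grayscale raster encoding k-mer occurrence.

    Binary mode (default): black (0) pixels mark occurring k-mers, white
    (255) pixels absent ones.  Count mode maps log-scaled k-mer counts onto
    0-255 (darker = more frequent).
    """

    k: int
    pixels: np.ndarray
    source_id: str
    mode: str = "binary"

    def __post_init__(self) -> None:
        side = 2**self.k
        if self.pixels.shape != (side, side):
            raise ValueError(
                f"pixel grid {self.pixels.shape} does not match 2^{self.k} per side"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")

    @property
    def side(self) -> int:
        return 2**self.k

    @property
    def occupied_count(self) -> int:
        """Number of black pixels = number of distinct k-mers present."""
        return int(np.count_nonzero(self.pixels == 0)) if self.mode == "binary" else int(
            np.count_nonzero(self.pixels < 255)
        )


def corner_of(base: str) -> tuple[float, float]:
    """Unit-square corner of a base (A bottom-left, then C,G,T clockwise)."""
    try:
        return CORNERS[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


def cgr_trajectory(residues: str) -> np.ndarray:
    """Iteratively plotted CGR points, one per residue.

    p_0 = (0.5, 0.5) (not emitted); p_i is the midpoint of p_{i-1} and the
    corner of residue i.  Returns an array of shape (len(residues), 2).
    """
    if not residues:
        raise ValueError("empty sequence has no CGR trajectory")
    pts = np.empty((len(residues), 2))
    x, y = 0.5, 0.5
    for i, base in enumerate(residues):
        cx, cy = corner_of(base)
        x = (x + cx) / 2.0
        y = (y + cy) / 2.0
        pts[i] = (x, y)
    return pts


def kmer_to_pixel(word: str, k: int) -> tuple[int, int]:
    """Raster cell (row, col) of a k-mer on the 2^k x 2^k grid.

    The last letter of the word contributes the most significant bit (the
    coarsest quadrant); row 0 is the top of the raster.  Bijective over the
    4^k words for fixed k.
    """
    if len(word) != k:
        raise ValueError(f"word {word!r} does not have length k={k}")
    col = 0
    yidx = 0
    for j, base in enumerate(word):  # weight 2^j: last letter most significant
        try:
            col += _XBIT[base] << j
            yidx += _YBIT[base] << j
        except KeyError:
            raise ValueError(f"not a DNA base: {base!r}") from None
    return (2**k - 1 - yidx, col)


def cgr_encode(record: SequenceRecord | str, k: int = 9, mode: str = "binary") -> CGRImage:
    """Build the CGR raster of a sequence by direct k-mer enumeration."""
    if isinstance(record, SequenceRecord):
        residues, source_id = record.residues, record.id
    else:
        residues, source_id = record, "<anonymous>"
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(residues) < k:
        raise ValueError(
            f"sequence {source_id!r} (length {len(residues)}) is shorter than k={k}"
        )
    if mode not in ("binary", "counts"):
        raise ValueError(f"unknown CGR mode {mode!r}")

    codes = encode(residues)
    xbits = (codes >= 2).astype(np.int64)          # G(2), T(3) on the right
    ybits = ((codes == 1) | (codes == 2)).astype(np.int64)  # C(1), G(2) on top
    weights = 1 << np.arange(k)                     # last letter = MSB
    win_x = np.lib.stride_tricks.sliding_window_view(xbits, k) @ weights
    win_y = np.lib.stride_tricks.sliding_window_view(ybits, k) @ weights
    rows = (2**k - 1) - win_y
    side = 2**k
    if mode == "binary":
        pixels = np.full((side, side), 255, dtype=np.uint8)
        pixels[rows, win_x] = 0
    else:
        counts = np.zeros((side, side), dtype=np.int64)
        np.add.at(counts, (rows, win_x), 1)
        scaled = np.zeros_like(counts, dtype=np.float64)
        occ = counts > 0
        if occ.any():
            logc = np.log1p(counts[occ])
            scaled[occ] = logc / logc.max() if logc.max() > 0 else 1.0
        pixels = np.round(255 * (1.0 - scaled)).astype(np.uint8)
    return CGRImage(k=k, pixels=pixels, source_id=source_id, mode=mode)


def render_cgr(image: CGRImage, path: str | Path) -> None:
    """Write a CGR raster as a lossless 8-bit grayscale PNG or PGM file.

    The format is chosen by file extension (.png or .pgm); PGM files are
    binary (P5).  Re-reading yields the identical pixel grid.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".png", ".pgm"):
        raise ValueError(f"unsupported image format {suffix!r} (use .png or .pgm)")
    Image.fromarray(image.pixels, mode="L").save(path)


def load_cgr_pixels(path: str | Path) -> np.ndarray:
    """Read back an 8-bit grayscale raster written by :func:`render_cgr`."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
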