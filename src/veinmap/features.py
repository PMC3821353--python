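"""Binary-pattern feature extraction.

Two operators turn a normalized grayscale image into a fixed-length binary
code:

* **LBP** — for every interior pixel, the sign of the difference between each
  of its eight 3x3 neighbours and the pixel itself gives one bit
  (``s(x) = 1 if x >= 0 else 0``), eight bits per pixel.
* **LLBP** (line local binary pattern) — for every pixel whose horizontal
  (resp. vertical) line of odd length ``N`` fits inside the image, the signs
  of the differences between the ``N - 1`` line pixels and the centre pixel
  give ``N - 1`` bits per direction; the full LLBP code concatenates the
  horizontal code and the vertical code.

Codes are stored bit-packed with an explicit logical length.  Pixels whose
kernel or line would leave the image are skipped rather than padded: padding
would invent intensities and perturb exactly the per-bit stability signal
that weight-map training later measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import IncompatibleCodesError, InvalidInputError

__all__ = [
    "BinaryCode",
    "threshold_sign",
    "lbp_code",
    "lbp_decimal",
    "llbp_h_code",
    "llbp_v_code",
    "llbp_code",
    "llbp_magnitude",
    "lbp_code_length",
    "llbp_code_length",
]

# 3x3 neighbour offsets (row, col): start at the top-left neighbour and
# proceed clockwise.  Bit n = 0 is the first offset.  Any fixed convention
# yields identical Hamming distances; this one is recorded in operator_tag
# so that codes from different conventions are never mixed.
_LBP_OFFSETS = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


@dataclass(frozen=True)
class BinaryCode:
    """A fixed-length bit string extracted from one image by one operator.

    Parameters
    ----------
    packed : np.ndarray
        ``uint8`` array holding the bits big-endian-packed (``np.packbits``
        order); trailing pad bits of the final byte are zero.
    length : int
        Logical number of bits.
    operator_tag : str
        Identifier of the producing operator and its parameters, e.g.
        ``"lbp"`` or ``"llbp-N21"``.  Codes are comparable only when their
        tags and lengths match.
    """

    packed: np.ndarray = field(repr=False)
    length: int
    operator_tag: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidInputError("binary code must contain at least one bit")
        expected = (self.length + 7) // 8
        if self.packed.dtype != np.uint8 or self.packed.ndim != 1:
            raise InvalidInputError("packed storage must be a 1-D uint8 array")
        if self.packed.size != expected:
            raise InvalidInputError(
                f"packed size {self.packed.size} inconsistent with length {self.length}"
            )

    @classmethod
    def from_bits(cls, bits: np.ndarray, operator_tag: str) -> "BinaryCode":
        bits = np.asarray(bits).ravel()
        if bits.size == 0:
            raise InvalidInputError("binary code must contain at least one bit")
        bits = bits.astype(np.uint8)
        if np.any(bits > 1):
            raise InvalidInputError("bits must be 0 or 1")
        return cls(packed=np.packbits(bits), length=int(bits.size), operator_tag=operator_tag)

    @property
    def bits(self) -> np.ndarray:
        """The code as a flat uint8 0/1 array of ``length`` entries."""
        return np.unpackbits(self.packed)[: self.length]

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryCode):
            return NotImplemented
        return (
            self.length == other.length
            and self.operator_tag == other.operator_tag
            and bool(np.array_equal(self.packed, other.packed))
        )

    def __xor__(self, other: "BinaryCode") -> np.ndarray:
        """Per-bit XOR with another compatible code, as an unpacked array."""
        require_compatible(self, other)
        return np.unpackbits(self.packed ^ other.packed)[: self.length]

    def complement(self) -> "BinaryCode":
        return BinaryCode.from_bits(1 - self.bits, self.operator_tag)


def require_compatible(a: BinaryCode, b: BinaryCode) -> None:
    """Raise unless two codes can be matched against each other."""
    if a.operator_tag != b.operator_tag:
        raise IncompatibleCodesError(
            f"operator tags differ: {a.operator_tag!r} vs {b.operator_tag!r}"
        )
    if a.length != b.length:
        raise IncompatibleCodesError(f"code lengths differ: {a.length} vs {b.length}")


def _check_image(img: np.ndarray, min_h: int = 1, min_w: int = 1) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    h, w = arr.shape
    if h < min_h or w < min_w:
        raise InvalidInputError(
            f"image {h}x{w} smaller than required {min_h}x{min_w}"
        )
    return arr


def _check_n(n_line: int) -> int:
    n_line = int(n_line)
    if n_line < 3 or n_line % 2 == 0:
        raise InvalidInputError(f"line length N must be odd and >= 3, got {n_line}")
    return n_line


def threshold_sign(x: float) -> int:
    """The sign-threshold function ``s(x)``: 1 for x >= 0, 0 for x < 0."""
    if not np.isfinite(x):
        raise InvalidInputError("threshold_sign requires a finite argument")
    return 1 if x >= 0 else 0


def _lbp_bits(img: np.ndarray) -> np.ndarray:
    """(H-2, W-2, 8) uint8 bit planes of the 3x3 LBP operator."""
    h, w = img.shape
    center = img[1:-1, 1:-1]
    bits = np.empty(center.shape + (8,), dtype=np.uint8)
    for n, (dy, dx) in enumerate(_LBP_OFFSETS):
        nb = img[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
        bits[..., n] = nb >= center  # s(neighbour - centre)
    return bits


def lbp_code(img: np.ndarray) -> BinaryCode:
    """Concatenated 8-bit-per-pixel LBP code over all interior pixels.

    Pixels are visited in row-major order; per pixel the eight bits follow
    the fixed clockwise-from-top-left neighbour order.  Total length is
    ``(H - 2) * (W - 2) * 8``.
    """
    arr = _check_image(img, 3, 3)
    return BinaryCode.from_bits(_lbp_bits(arr).ravel(), operator_tag="lbp")


def lbp_decimal(img: np.ndarray) -> np.ndarray:
    """Per-interior-pixel decimal LBP value, sum of ``bit_n * 2**n``.

    Diagnostic view only; matching always uses the binary code.
    """
    arr = _check_image(img, 3, 3)
    weights = (1 << np.arange(8)).astype(np.int64)
    return (_lbp_bits(arr).astype(np.int64) * weights).sum(axis=-1)


def _line_bits(img: np.ndarray, n_line: int, axis: int) -> np.ndarray:
    """Sign bits along length-``n_line`` lines parallel to ``axis``.

    Returns an array of shape (valid_h, valid_w, N-1) with bits in ascending
    line-position order (the centre position is skipped).
    """
    r = (n_line - 1) // 2
    h, w = img.shape
    if axis == 1:
        center = img[:, r : w - r]
    else:
        center = img[r : h - r, :]
    bits = np.empty(center.shape + (n_line - 1,), dtype=np.uint8)
    j = 0
    for d in range(-r, r + 1):
        if d == 0:
            continue
        if axis == 1:
            nb = img[:, r + d : w - r + d]
        else:
            nb = img[r + d : h - r + d, :]
        bits[..., j] = nb >= center
        j += 1
    return bits


def llbp_h_code(img: np.ndarray, n_line: int = 21) -> BinaryCode:
    """Horizontal LLBP code: ``N - 1`` bits per pixel whose horizontal line
    fits inside the image, concatenated in row-major pixel order.

    Total length is ``H * (W - (N - 1)) * (N - 1)``.
    """
    n_line = _check_n(n_line)
    arr = _check_image(img, 1, n_line)
    bits = _line_bits(arr, n_line, axis=1)
    return BinaryCode.from_bits(bits.ravel(), operator_tag=f"llbp-h-N{n_line}")


def llbp_v_code(img: np.ndarray, n_line: int = 21) -> BinaryCode:
    """Vertical LLBP code, symmetric to :func:`llbp_h_code`.

    Total length is ``(H - (N - 1)) * W * (N - 1)``.
    """
    n_line = _check_n(n_line)
    arr = _check_image(img, n_line, 1)
    bits = _line_bits(arr, n_line, axis=0)
    return BinaryCode.from_bits(bits.ravel(), operator_tag=f"llbp-v-N{n_line}")


def llbp_code(img: np.ndarray, n_line: int = 21) -> BinaryCode:
    """Full LLBP code: horizontal code followed by vertical code, each over
    its own valid-pixel domain; ``2 (N - 1)`` bits per pixel on the common
    domain."""
    hcode = llbp_h_code(img, n_line)
    vcode = llbp_v_code(img, n_line)
    bits = np.concatenate([hcode.bits, vcode.bits])
    return BinaryCode.from_bits(bits, operator_tag=f"llbp-N{n_line}")


def _line_decimal(img: np.ndarray, n_line: int, axis: int) -> np.ndarray:
    # decimal weight of a line position at signed offset d from the centre
    # is 2**(|d| - 1), on both sides.
    r = (n_line - 1) // 2
    bits = _line_bits(img, n_line, axis=axis).astype(np.int64)
    offsets = [d for d in range(-r, r + 1) if d != 0]
    weights = np.array([1 << (abs(d) - 1) for d in offsets], dtype=np.int64)
    return (bits * weights).sum(axis=-1)


def llbp_magnitude(img: np.ndarray, n_line: int = 21) -> np.ndarray:
    """Per-pixel magnitude ``sqrt(LLBPh**2 + LLBPv**2)`` of the
    decimal-weighted horizontal and vertical LLBP responses, over the
    intersection of the two valid domains.  Diagnostic only; matching uses
    the binary codes."""
    n_line = _check_n(n_line)
    arr = _check_image(img, n_line, n_line)
    r = (n_line - 1) // 2
    hdec = _line_decimal(arr, n_line, axis=1)  # all rows, cols r..W-1-r
    vdec = _line_decimal(arr, n_line, axis=0)  # rows r..H-1-r, all cols
    h_common = hdec[r:-r, :].astype(np.float64)
    v_common = vdec[:, r:-r].astype(np.float64)
    return np.hypot(h_common, v_common)


def lbp_code_length(height: int, width: int) -> int:
    """Length of the LBP code of a ``height x width`` image."""
    return (height - 2) * (width - 2) * 8


def llbp_code_length(height: int, width: int, n_line: int = 21) -> int:
    """Length of the concatenated LLBP code of a ``height x width`` image."""
    return (height * (width - (n_line - 1)) + (height - (n_line - 1)) * width) * (
        n_line - 1
    )


def extract_code(img: np.ndarray, operator: str, n_line: int = 21) -> BinaryCode:
    """Dispatch by operator name: ``lbp``, ``llbp``, ``llbp-h`` or ``llbp-v``."""
    if operator == "lbp":
        return lbp_code(img)
    if operator == "llbp":
        return llbp_code(img, n_line)
    if operator == "llbp-h":
        return llbp_h_code(img, n_line)
    if operator == "llbp-v":
        return llbp_v_code(img, n_line)
    raise InvalidInputError(f"unknown operator {operator!r}")
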