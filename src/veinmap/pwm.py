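"""Personalized weight maps: training, matching, and template files.

A *personalized weight map* (PWM) assigns every bit position of a class's
binary code a weight in [0, 1] that measures how stable that bit is across
the class's enrollment samples.  With ``k`` training codes in which bit *i*
takes value 1 ``m1`` times and 0 ``m0 = k - m1`` times, the average of all
``k x k`` pairwise XNOR matchings at that bit (self-matches included) has
the closed form

    p_i = (m1**2 + m0**2) / k**2          (always in [0.5, 1])

which is normalized to the weight

    w_i = 2 * p_i - 1                     (in [0, 1]).

Matching replaces the plain normalized Hamming distance by the weighted
similarity

    S(A, B) = 1 - sum_i w_i * xor(A_i, B_i) / sum_i w_i

where the weight map belongs to the *enrolled* class A.  The older
*personalized best-bit map* (PBBM) keeps only the bits that are perfectly
stable across training (w_i = 1) and matches on those alone; it is exactly
the 0/1 special case of the weighted similarity.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DegenerateTemplateError,
    DegenerateTemplateWarning,
    DegenerateWeightsError,
    IncompatibleCodesError,
    InsufficientTrainingError,
)
from .features import BinaryCode, require_compatible

__all__ = [
    "WeightMap",
    "BestBitMask",
    "ClassTemplate",
    "hamming_distance",
    "train_pwm",
    "train_pbbm",
    "train_template",
    "weighted_similarity",
    "pbbm_similarity",
    "decide",
    "achievable_weights",
    "PlainMatcher",
    "PBBMMatcher",
    "PWMMatcher",
    "make_matcher",
    "save_template",
    "load_template",
]


@dataclass(frozen=True)
class WeightMap:
    """Per-bit stability weights of one enrolled class."""

    weights: np.ndarray = field(repr=False)  # float64 in [0, 1]
    operator_tag: str
    k_train: int
    class_id: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size == 0:
            raise DegenerateWeightsError("weight map must be a nonempty 1-D vector")
        if w.min() < 0 or w.max() > 1:
            raise DegenerateWeightsError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class BestBitMask:
    """0/1 mask marking the bits that were constant across training codes."""

    mask: np.ndarray = field(repr=False)  # uint8 0/1
    operator_tag: str
    class_id: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=np.uint8)
        if m.ndim != 1 or m.size == 0 or np.any(m > 1):
            raise DegenerateTemplateError("mask must be a nonempty 1-D 0/1 vector")
        object.__setattr__(self, "mask", m)

    @property
    def n_best(self) -> int:
        return int(self.mask.sum())

    def __len__(self) -> int:
        return self.mask.size


def hamming_distance(a: BinaryCode, b: BinaryCode) -> float:
    """Fraction of differing bits between two compatible codes."""
    require_compatible(a, b)
    diff = np.bitwise_count(a.packed ^ b.packed).sum()  # pad bits XOR to 0
    return float(diff) / a.length


def _stack_training(codes: list[BinaryCode]) -> np.ndarray:
    if len(codes) < 2:
        raise InsufficientTrainingError(
            f"weight-map training needs at least 2 codes, got {len(codes)}"
        )
    first = codes[0]
    for other in codes[1:]:
        require_compatible(first, other)
    return np.stack([c.bits for c in codes]).astype(np.int64)


def train_pwm(codes: list[BinaryCode], class_id: str = "") -> WeightMap:
    """Train a weight map from ``k >= 2`` enrollment codes of one class.

    Uses the closed form ``p_i = (m1**2 + m0**2) / k**2`` of the k x k
    pairwise XNOR average (self-matches included), then ``w_i = 2 p_i - 1``.
    """
    bits = _stack_training(codes)
    k = bits.shape[0]
    m1 = bits.sum(axis=0)
    p = (m1 * m1 + (k - m1) * (k - m1)) / float(k * k)
    return WeightMap(
        weights=2.0 * p - 1.0,
        operator_tag=codes[0].operator_tag,
        k_train=k,
        class_id=class_id,
    )


def train_pbbm(codes: list[BinaryCode], class_id: str = "") -> tuple[BestBitMask, BinaryCode]:
    """Train a best-bit mask and template from enrollment codes.

    The mask marks bits constant across all training codes (equivalently,
    bits whose PWM weight is exactly 1); the template carries the constant
    value at masked positions and 0 elsewhere (unused).
    """
    bits = _stack_training(codes)
    k = bits.shape[0]
    m1 = bits.sum(axis=0)
    constant = (m1 == 0) | (m1 == k)
    mask = BestBitMask(
        mask=constant.astype(np.uint8),
        operator_tag=codes[0].operator_tag,
        class_id=class_id,
    )
    if mask.n_best == 0:
        warnings.warn(
            f"class {class_id!r}: no bit is constant across training; "
            "the best-bit mask is empty and cannot be used for matching",
            DegenerateTemplateWarning,
            stacklevel=2,
        )
    template_bits = np.where(constant, (m1 == k).astype(np.uint8), 0).astype(np.uint8)
    template = BinaryCode.from_bits(template_bits, codes[0].operator_tag)
    return mask, template


def achievable_weights(k_train: int) -> np.ndarray:
    """The finite set of weight values reachable with ``k_train`` codes,
    sorted ascending: ``{2 (m1^2 + (k-m1)^2) / k^2 - 1 : m1 = 0..k}``."""
    if k_train < 2:
        raise InsufficientTrainingError("k_train must be >= 2")
    m1 = np.arange(k_train + 1)
    p = (m1**2 + (k_train - m1) ** 2) / float(k_train**2)
    return np.unique(2.0 * p - 1.0)


def _check_map_compat(code: BinaryCode, tag: str, length: int, what: str) -> None:
    if code.operator_tag != tag:
        raise IncompatibleCodesError(
            f"{what} operator tag {tag!r} does not match code tag {code.operator_tag!r}"
        )
    if code.length != length:
        raise IncompatibleCodesError(
            f"{what} length {length} does not match code length {code.length}"
        )


def weighted_similarity(enrolled: BinaryCode, probe: BinaryCode, w: WeightMap) -> float:
    """Weight-map-modulated similarity in [0, 1].

    The map ``w`` belongs to the class of the *enrolled* code; the measure
    is asymmetric in that sense.  With all weights 1 it reduces to
    ``1 - hamming_distance``.
    """
    require_compatible(enrolled, probe)
    _check_map_compat(enrolled, w.operator_tag, len(w), "weight map")
    total = w.weights.sum()
    if total <= 0:
        raise DegenerateWeightsError("weight map sums to zero")
    xor = enrolled ^ probe
    return float(1.0 - (w.weights @ xor) / total)


def pbbm_similarity(template: BinaryCode, probe: BinaryCode, mask: BestBitMask) -> float:
    """Similarity restricted to the best bits: 1 minus the fraction of
    masked positions at which template and probe differ."""
    require_compatible(template, probe)
    _check_map_compat(template, mask.operator_tag, len(mask), "best-bit mask")
    n = mask.n_best
    if n == 0:
        raise DegenerateTemplateError("best-bit mask has no set bits")
    xor = template ^ probe
    diff = int(mask.mask.astype(np.int64) @ xor)
    return 1.0 - diff / n


def decide(similarity: float, threshold: float) -> bool:
    """Accept iff similarity is strictly greater than the threshold."""
    return similarity > threshold


# ---------------------------------------------------------------------------
# Matchers: uniform scoring closures over the three methods, so evaluation
# protocols run identical score pipelines for plain Hamming, PBBM and PWM.
# ---------------------------------------------------------------------------


class PlainMatcher:
    """Unweighted matcher: ``score = 1 - hamming_distance``."""

    kind = "plain"

    def __init__(self, training: dict[str, list[BinaryCode]] | None = None):
        pass

    def score(self, enrolled_class: str, enrolled: BinaryCode, probe: BinaryCode) -> float:
        return 1.0 - hamming_distance(enrolled, probe)


class PWMMatcher:
    """Weighted matcher using the enrolled class's trained weight map."""

    kind = "pwm"

    def __init__(self, training: dict[str, list[BinaryCode]]):
        self.maps = {cid: train_pwm(codes, cid) for cid, codes in training.items()}

    def score(self, enrolled_class: str, enrolled: BinaryCode, probe: BinaryCode) -> float:
        return weighted_similarity(enrolled, probe, self.maps[enrolled_class])


class PBBMMatcher:
    """Best-bit matcher: compares the pair on the enrolled class's stable
    bits only (the 0/1 weight-map special case)."""

    kind = "pbbm"

    def __init__(self, training: dict[str, list[BinaryCode]]):
        self.masks = {}
        self.templates = {}
        for cid, codes in training.items():
            mask, template = train_pbbm(codes, cid)
            self.masks[cid] = mask
            self.templates[cid] = template

    def score(self, enrolled_class: str, enrolled: BinaryCode, probe: BinaryCode) -> float:
        return pbbm_similarity(enrolled, probe, self.masks[enrolled_class])


_MATCHERS = {"plain": PlainMatcher, "pbbm": PBBMMatcher, "pwm": PWMMatcher}


def make_matcher(kind: str, training: dict[str, list[BinaryCode]]):
    """Build a trained matcher of the given kind (plain, pbbm, pwm)."""
    try:
        cls = _MATCHERS[kind]
    except KeyError:
        raise ValueError(f"unknown matcher kind {kind!r}") from None
    return cls(training)


# ---------------------------------------------------------------------------
# Template files
# ---------------------------------------------------------------------------

_MAGIC = b"PWMT"
_VERSION = 1


@dataclass
class ClassTemplate:
    """Everything enrolled for one class: codes, weight map, best-bit data.

    Serialized as ``<class_id>.pwm`` (binary, versioned magic header) plus a
    ``<class_id>.json`` metadata sidecar.  Byte layout after the 4-byte magic
    and little-endian uint16 version: class_id and operator_tag as
    length-prefixed UTF-8 (uint16 lengths), then uint32 k_train, uint64
    code_length, uint32 n_codes, the bit-packed enrollment codes, the
    bit-packed PBBM template and mask, and the weight vector as little-endian
    float32.
    """

    class_id: str
    codes: list[BinaryCode]
    weight_map: WeightMap
    mask: BestBitMask
    pbbm_template: BinaryCode

    @property
    def operator_tag(self) -> str:
        return self.weight_map.operator_tag


def train_template(codes: list[BinaryCode], class_id: str) -> ClassTemplate:
    """Train every per-class matching artifact from enrollment codes."""
    wm = train_pwm(codes, class_id)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateTemplateWarning)
        mask, template = train_pbbm(codes, class_id)
    return ClassTemplate(class_id, list(codes), wm, mask, template)


def _pack_str(s: str) -> bytes:
    raw = s.encode("utf-8")
    return struct.pack("<H", len(raw)) + raw


def save_template(tpl: ClassTemplate, directory: str | Path) -> Path:
    """Write ``<class_id>.pwm`` and ``<class_id>.json`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    length = tpl.pbbm_template.length
    blob = bytearray()
    blob += _MAGIC
    blob += struct.pack("<H", _VERSION)
    blob += _pack_str(tpl.class_id)
    blob += _pack_str(tpl.operator_tag)
    blob += struct.pack("<IQI", tpl.weight_map.k_train, length, len(tpl.codes))
    for code in tpl.codes:
        blob += code.packed.tobytes()
    blob += tpl.pbbm_template.packed.tobytes()
    blob += np.packbits(tpl.mask.mask).tobytes()
    blob += tpl.weight_map.weights.astype("<f4").tobytes()
    path = directory / f"{tpl.class_id}.pwm"
    path.write_bytes(bytes(blob))
    meta = {
        "format": "veinmap-template",
        "version": _VERSION,
        "class_id": tpl.class_id,
        "operator_tag": tpl.operator_tag,
        "k_train": tpl.weight_map.k_train,
        "code_length": length,
        "n_codes": len(tpl.codes),
        "n_best_bits": tpl.mask.n_best,
    }
    (directory / f"{tpl.class_id}.json").write_text(json.dumps(meta, indent=2))
    return path


def load_template(path: str | Path) -> ClassTemplate:
    """Read a ``.pwm`` template file written by :func:`save_template`."""
    data = Path(path).read_bytes()
    if data[:4] != _MAGIC:
        raise ValueError(f"{path}: not a veinmap template file")
    (version,) = struct.unpack_from("<H", data, 4)
    if version != _VERSION:
        raise ValueError(f"{path}: unsupported template version {version}")
    off = 6

    def read_str() -> str:
        nonlocal off
        (n,) = struct.unpack_from("<H", data, off)
        off += 2
        s = data[off : off + n].decode("utf-8")
        off += n
        return s

    class_id = read_str()
    tag = read_str()
    k_train, length, n_codes = struct.unpack_from("<IQI", data, off)
    off += 16
    nbytes = (length + 7) // 8

    def read_code() -> BinaryCode:
        nonlocal off
        packed = np.frombuffer(data, dtype=np.uint8, count=nbytes, offset=off).copy()
        off += nbytes
        return BinaryCode(packed=packed, length=length, operator_tag=tag)

    codes = [read_code() for _ in range(n_codes)]
    template = read_code()
    mask_bits = np.unpackbits(
        np.frombuffer(data, dtype=np.uint8, count=nbytes, offset=off)
    )[:length]
    off += nbytes
    weights = np.frombuffer(data, dtype="<f4", count=length, offset=off).astype(
        np.float64
    )
    wm = WeightMap(weights=weights, operator_tag=tag, k_train=k_train, class_id=class_id)
    mask = BestBitMask(mask=mask_bits, operator_tag=tag, class_id=class_id)
    return ClassTemplate(class_id, codes, wm, mask, template)
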