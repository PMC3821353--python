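"""Run configuration: defaults, TOML loading, and reproducibility digests."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .exceptions import InvalidInputError

__all__ = ["RunConfig", "load_config"]

_OPERATORS = ("lbp", "llbp", "llbp-h", "llbp-v")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run.

    ``size_height``/``size_width`` are the normalized feature-extraction
    region (default 96x64); ``llbp_n`` is the LLBP line length (default 21,
    odd).  ``threshold`` is the strict acceptance threshold of the match
    command.
    """

    operator: str = "lbp"
    llbp_n: int = 21
    roi_enabled: bool = True
    size_height: int = 96
    size_width: int = 64
    k_train: int = 10
    n_test: int = 10
    n_test_imposter: int = 2
    template_index: int = 0
    threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise InvalidInputError(
                f"operator must be one of {_OPERATORS}, got {self.operator!r}"
            )
        if self.llbp_n < 3 or self.llbp_n % 2 == 0:
            raise InvalidInputError("llbp_n must be odd and >= 3")
        if self.size_height < 3 or self.size_width < 3:
            raise InvalidInputError("normalized size must be at least 3x3")
        if self.operator != "lbp":
            limit = self.llbp_n
            if (self.operator in ("llbp", "llbp-h") and self.size_width < limit) or (
                self.operator in ("llbp", "llbp-v") and self.size_height < limit
            ):
                raise InvalidInputError(
                    f"normalized size {self.size_height}x{self.size_width} too small "
                    f"for {self.operator} with N={self.llbp_n}"
                )

    def digest(self) -> str:
        """Stable hash of the configuration for run logging."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# flat config keys (dotted) -> RunConfig field
_KEYMAP = {
    "operator": "operator",
    "llbp.n": "llbp_n",
    "roi.enabled": "roi_enabled",
    "size.height": "size_height",
    "size.width": "size_width",
    "protocol.k_train": "k_train",
    "protocol.n_test": "n_test",
    "protocol.n_test_imposter": "n_test_imposter",
    "protocol.template_index": "template_index",
    "protocol.seed": "seed",
    "match.threshold": "threshold",
}


def _flatten(table: dict, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for key, value in table.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, f"{dotted}."))
        else:
            out[dotted] = value
    return out


def load_config(path: str | Path | None) -> RunConfig:
    """Read a TOML config file of flat dotted keys (e.g. ``size.height``);
    unknown keys are rejected.  ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        table = tomllib.load(fh)
    flat = _flatten(table)
    kwargs = {}
    for dotted, value in flat.items():
        if dotted not in _KEYMAP:
            raise InvalidInputError(f"unknown config key {dotted!r}")
        kwargs[_KEYMAP[dotted]] = value
    return RunConfig(**kwargs)
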