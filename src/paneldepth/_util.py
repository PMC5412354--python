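"""Shared helpers: base encoding, half-up rounding, error types."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class PanelDepthError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PanelDepthError, ValueError):
    """A parameter is outside its documented domain."""


class CapacityError(PanelDepthError):
    """Requested variants do not fit in the available target space."""


class ConsistencyError(PanelDepthError):
    """A pedigree/genotype configuration is Mendelian-impossible."""


class ConfigError(PanelDepthError):
    """A run configuration is malformed; the message names the key."""


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as uint8 codes 0..3."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise InvalidParameterError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as results tables are conventionally printed.

    Uses the decimal representation of ``repr(x)`` so that values such as
    ``0.05 * 213.4 == 10.670000000000002`` round to 10.7, not 10.6.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    return int(Decimal(repr(float(x))).quantize(Decimal(1), rounding=ROUND_HALF_UP))
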