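"""Lossless delta codec for stored concentration-time profiles.

Simulated trajectories are smooth, so consecutive 32-bit float bit
patterns are close; storing the integer difference of consecutive
4-byte patterns (mod 2^32) concentrates the entropy in the low bytes
and makes a general-purpose compressor markedly more effective than on
the raw floats.  The transform is exactly invertible, so the round trip
is bit-exact on float32 data.  64-bit simulation values are
down-converted to float32 only here, inside the storage layer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["EncodedProfile", "encode_profile", "decode_profile"]

_MAGIC = b"PSD1"


@dataclass(frozen=True)
class EncodedProfile:
    """Delta-encoded, zlib-compressed float32 profile."""

    length: int
    compressed_payload: bytes

    @property
    def nbytes(self) -> int:
        return len(self.compressed_payload)


def encode_profile(values) -> EncodedProfile:
    """Encode a float sequence; empty input yields a length-0 encoding."""
    x = np.asarray(values, dtype=np.float32)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        return EncodedProfile(0, zlib.compress(_MAGIC))
    if not np.isfinite(x).all():
        raise ValueError("profile values must be finite")
    bits = x.view(np.uint32)
    # uint32 wraparound subtraction keeps every delta in 4 bytes and is
    # exactly invertible by cumulative summation mod 2^32.
    deltas = np.diff(bits)
    raw = _MAGIC + bits[:1].tobytes() + deltas.tobytes()
    return EncodedProfile(int(x.size), zlib.compress(raw, level=6))


def decode_profile(encoded: EncodedProfile) -> np.ndarray:
    """Invert :func:`encode_profile` bit-exactly."""
    raw = zlib.decompress(encoded.compressed_payload)
    if raw[:4] != _MAGIC:
        raise ValueError("not a delta-encoded profile payload")
    if encoded.length == 0:
        return np.empty(0, dtype=np.float32)
    body = np.frombuffer(raw[4:], dtype=np.uint32)
    first, deltas = body[0], body[1:]
    if deltas.size != encoded.length - 1:
        raise ValueError("payload length inconsistent with declared profile length")
    bits = np.empty(encoded.length, dtype=np.uint32)
    bits[0] = first
    np.cumsum(deltas, out=bits[1:], dtype=np.uint32)
    bits[1:] += first
    return bits.view(np.float32)


def compressed_size_without_delta(values) -> int:
    """Byte count of the plain (non-delta) compressed pipeline, for comparison."""
    x = np.asarray(values, dtype=np.float32).ravel()
    return len(zlib.compress(_MAGIC + x.tobytes(), level=6))
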