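"""Compression-ratio accounting and the relative compression-ratio gain.

Ratios are "folds": original bytes divided by compressed bytes.  Comparing
a fixed-single-reference ratio C_S with the clustering-based ratio C_E,

    G = (1 − C_S / C_E) × 100 %,

positive when the clustered plan wins, reported half-up to 2 decimals.
Both ratios are computed on raw file bytes with the final reference's
payload included in the denominator, so the comparison is apples-to-apples.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["GainReport", "compute_gain", "compression_ratio"]


def compression_ratio(original_bytes: int | float, compressed_bytes: int | float) -> float:
    """Folds: original size / compressed size."""
    if original_bytes <= 0 or compressed_bytes <= 0:
        raise ValueError("sizes must be positive")
    return float(original_bytes) / float(compressed_bytes)


def compute_gain(c_s: float, c_e: float) -> float:
    """Relative compression-ratio gain (1 − c_s/c_e)·100, rounded half-up
    to 2 decimals; negative when the clustered plan underperforms."""
    if c_s <= 0 or c_e <= 0:
        raise ValueError("compression ratios must be positive")
    g = (1.0 - c_s / c_e) * 100.0
    return float(Decimal(repr(g)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GainReport:
    """One fixed-reference-vs-clustered comparison."""

    reference_label: str
    c_s: float
    c_e: float

    @property
    def gain(self) -> float:
        return compute_gain(self.c_s, self.c_e)

    def __str__(self) -> str:
        return (
            f"reference={self.reference_label} C_S={self.c_s:.2f} "
            f"C_E={self.c_e:.2f} gain={self.gain:.2f}%"
        )
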