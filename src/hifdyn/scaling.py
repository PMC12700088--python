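"""Bridging absolute ELISA concentrations and relative western-blot series.

Two anchor ratios ``k1`` (HIF1A, 2 h) and ``k2`` (HIF2A, 8 h) convert each
protein's relative fold series to ng/mg of total protein; their quotient
``m = k2/k1`` equals the normoxic HIF2A/HIF1A concentration ratio (both
relative series are 1 at 0 h) and puts the HIF2A relative series on the
HIF1A concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default anchor times fixed by the measurement design.
HIF1A_ANCHOR_TIME = 2.0
HIF2A_ANCHOR_TIME = 8.0


def compute_ratio_k(absolute: float, relative: float) -> float:
    """Anchor ratio k = absolute (ng/mg) / relative (fold over 0 h)."""
    if relative <= 0:
        raise ValidationError(f"relative fold must be > 0, got {relative}")
    return absolute / relative


def compute_scaling_constant(k1: float, k2: float) -> float:
    """Scaling constant m = k2/k1, the normoxic HIF2A/HIF1A absolute ratio."""
    if k1 <= 0:
        raise ValidationError(f"k1 must be > 0, got {k1}")
    return k2 / k1


def scale_series(relative_series, m: float):
    """Element-wise product: scaled HIF2A series = relative series * m."""
    if m <= 0:
        raise ValidationError(f"scaling constant must be > 0, got {m}")
    series = np.asarray(relative_series, float)
    return series * m


def back_infer_absolute(relative: float, k: float) -> float:
    """Absolute concentration (ng/mg) = relative fold * anchor ratio k."""
    if k <= 0:
        raise ValidationError(f"k must be > 0, got {k}")
    return relative * k


@dataclass(frozen=True)
class ScalingConstants:
    """Anchor ratios and the derived scaling constant (m = k2/k1 exactly)."""

    k1: float
    k2: float

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValidationError("anchor ratios must be > 0")

    @property
    def m(self) -> float:
        return compute_scaling_constant(self.k1, self.k2)

    @classmethod
    def from_anchors(
        cls,
        hif1a_absolute: float,
        hif1a_relative: float,
        hif2a_absolute: float,
        hif2a_relative: float,
    ) -> "ScalingConstants":
        """Build from one (absolute, relative) anchor pair per protein.

        The measurement design fixes the anchors at 2 h (HIF1A) and 8 h
        (HIF2A), but any consistent pair may be supplied to examine the
        robustness of m to anchor choice.
        """
        return cls(
            k1=compute_ratio_k(hif1a_absolute, hif1a_relative),
            k2=compute_ratio_k(hif2a_absolute, hif2a_relative),
        )

    def normoxic_hif2a_absolute(self) -> float:
        """Back-inferred absolute normoxic HIF2A (relative value 1 at 0 h)."""
        return back_infer_absolute(1.0, self.k2)

    def __repr__(self) -> str:  # display convention: 4 decimals
        return (
            f"ScalingConstants(k1={self.k1:.4f}, k2={self.k2:.4f}, m={self.m:.4f})"
        )


def scale_table(
    table: pd.DataFrame,
    m: float,
    relative_column: str = "HIF2A protein",
    scaled_column: str = "HIF2A protein scaled",
) -> pd.DataFrame:
    """Return a copy of a time-series table with the scaled column added
    (or replaced)."""
    if relative_column not in table.columns:
        raise ValidationError(f"missing column {relative_column!r}")
    out = table.copy()
    out[scaled_column] = scale_series(out[relative_column].to_numpy(), m)
    return out
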