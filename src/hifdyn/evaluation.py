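"""Goodness-of-fit statistic and observed-vs-predicted summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import Trajectory


def gof_metric(
    observed: Sequence[float],
    predicted: Sequence[float],
    aggregation: str = "mean_of_ratios",
) -> float:
    """Absolute log2 of the time-averaged observed/predicted ratio.

    Order of operations: per-timepoint ratio, arithmetic mean over the
    time points, log2, absolute value.  ``aggregation="ratio_of_means"``
    selects the alternative reading (mean observed / mean predicted).
    Zero iff the aggregated ratio is exactly 1.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValidationError("observed and predicted must be equal-length, non-empty")
    if np.any(pred <= 0):
        raise ValidationError("predicted values must be > 0")
    if aggregation == "mean_of_ratios":
        ratio = np.mean(obs / pred)
    elif aggregation == "ratio_of_means":
        ratio = np.mean(obs) / np.mean(pred)
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    if ratio <= 0:
        raise ValidationError("aggregated ratio must be > 0")
    return float(abs(np.log2(ratio)))


@dataclass(frozen=True)
class GOFRecord:
    """One gene x HIF1B-level comparison cell."""

    gene: str
    hif1b_level: float
    times: tuple[float, ...]
    observed: tuple[float, ...]
    predicted: tuple[float, ...]

    @property
    def gof(self) -> float:
        return gof_metric(self.observed, self.predicted)


@dataclass(frozen=True)
class CombinedAlpha:
    """Element-wise sum of the HIF1A and scaled-HIF2A protein series."""

    times: np.ndarray
    combined: np.ndarray

    @property
    def argmax_time(self) -> float:
        return float(self.times[int(np.argmax(self.combined))])

    @property
    def max(self) -> float:
        return float(np.max(self.combined))

    def at(self, t: float) -> float:
        hits = np.nonzero(np.isclose(self.times, t))[0]
        if not hits.size:
            raise ValidationError(f"time {t} h not in table")
        return float(self.combined[hits[0]])


def combined_alpha_scaled(
    data: pd.DataFrame,
    time_column: str = "time (hours)",
    hif1a_column: str = "HIF1A protein",
    hif2a_scaled_column: str = "HIF2A protein scaled",
) -> CombinedAlpha:
    """Sum of the HIF1A relative and HIF2A scaled columns per time point."""
    for col in (time_column, hif1a_column, hif2a_scaled_column):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    return CombinedAlpha(
        times=data[time_column].to_numpy(float),
        combined=(
            data[hif1a_column].to_numpy(float)
            + data[hif2a_scaled_column].to_numpy(float)
        ),
    )


def fold_change_table(traj: Trajectory, t_obs: Sequence[float]) -> pd.DataFrame:
    """Per-species fold over 0 h at the requested times.

    Species with a 0 h value of 0 are reported as absolute values.
    """
    i0 = np.nonzero(np.isclose(traj.t, 0.0))[0]
    if not i0.size:
        raise ValidationError("trajectory grid must include 0 h")
    rows = {}
    for name in traj.model.species:
        series = traj.series(name)
        base = series[i0[0]]
        rows[name] = series / base if base != 0 else series
    table = pd.DataFrame(rows)
    table.insert(0, "time (hours)", traj.t)
    out = []
    for t in t_obs:
        hits = np.nonzero(np.isclose(traj.t, t))[0]
        if not hits.size:
            raise ValidationError(f"time {t} h not on trajectory grid")
        out.append(hits[0])
    return table.iloc[out].reset_index(drop=True)


def comparison_table(records: Sequence[GOFRecord]) -> pd.DataFrame:
    """Long-format observed-vs-predicted table (gene, level, time, obs, pred)."""
    rows = []
    for rec in records:
        for t, o, p in zip(rec.times, rec.observed, rec.predicted):
            rows.append(
                {
                    "gene": rec.gene,
                    "hif1b_level": rec.hif1b_level,
                    "time (hours)": t,
                    "observed": o,
                    "predicted": p,
                }
            )
    return pd.DataFrame(rows)


def gof_matrix(records: Sequence[GOFRecord]) -> pd.DataFrame:
    """Genes x HIF1B-levels matrix of the goodness-of-fit statistic."""
    table = pd.DataFrame(
        [
            {"gene": r.gene, "hif1b_level": r.hif1b_level, "gof": r.gof}
            for r in records
        ]
    )
    return table.pivot(index="gene", columns="hif1b_level", values="gof")
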