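"""Ground-truth-parameterized synthetic datasets in the training-table
layout, for scaling/fitting/evaluation tests without any download.

Noise is multiplicative log-normal (all observations are strictly positive
fold changes); the 0 h row is left exactly 1 by construction, mirroring
the normalization of the real table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import TIME_COLUMN, TimeSeriesData
from .network import ModelDefinition, ParameterSet, build_default_model
from .simulate import (
    DEFAULT_GRID,
    DEFAULT_INITIAL_HIF1B,
    DEFAULT_INITIAL_HIF2A,
    Trajectory,
    default_initial_state,
    simulate,
)

#: Times at which the generic-gene mRNA is unobserved in the training data.
GENE_UNOBSERVED_TIMES = (4.0, 6.0, 10.0, 12.0, 20.0, 24.0, 36.0, 48.0)

_VALUE_COLUMNS = (
    "HIF1A protein",
    "HIF2A protein",
    "HIF2A protein scaled",
    "PHD protein",
    "HIF1A mRNA",
    "HIF2A mRNA",
    "MIR210HG mRNA",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    base_params: Mapping[str, float] | None = None
    spread: float = 1.0  # log-normal geometric SD of parameter jitter
    grid: tuple[float, ...] = DEFAULT_GRID
    cv: float = 0.10  # geometric CV of the observation noise
    seed: int = 0
    hre1: int = 12
    hre2: int = 18
    hif1b_init: float = DEFAULT_INITIAL_HIF1B
    hif2a_protein_init: float = DEFAULT_INITIAL_HIF2A
    columns: tuple[str, ...] = _VALUE_COLUMNS
    blank_gene_times: tuple[float, ...] = GENE_UNOBSERVED_TIMES

    def __post_init__(self):
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.spread < 1:
            raise ValidationError("spread must be >= 1")
        if not any(np.isclose(self.grid, 0.0)):
            raise ValidationError("grid must include 0 h")

    def model(self) -> ModelDefinition:
        return build_default_model(self.hre1, self.hre2)

    def resolved_base_params(self) -> ParameterSet:
        if self.base_params is not None:
            return ParameterSet(self.base_params)
        return self.model().default_parameters()


def sample_params(spec: SyntheticSpec) -> ParameterSet:
    """Multiply every base parameter by a seeded log-normal factor with
    geometric SD ``spec.spread`` (spread 1 returns the base set exactly)."""
    base = spec.resolved_base_params()
    if spec.spread == 1.0:
        return base
    rng = np.random.default_rng([spec.seed, 0])
    sigma = np.log(spec.spread)
    factors = np.exp(sigma * rng.standard_normal(len(base)))
    return ParameterSet(
        {name: value * f for (name, value), f in zip(base.items(), factors)}
    )


def _observable_columns(traj: Trajectory) -> dict[str, np.ndarray]:
    """Noise-free fold columns in the training-table layout."""
    m = traj.hif2a_total[0]
    hif2a_rel = traj.hif2a_total / m
    return {
        "HIF1A protein": traj.hif1a_total / traj.hif1a_total[0],
        "HIF2A protein": hif2a_rel,
        "HIF2A protein scaled": hif2a_rel * m,
        "PHD protein": traj.fold("PHD_protein"),
        "HIF1A mRNA": traj.fold("HIF1A_mrna"),
        "HIF2A mRNA": traj.fold("HIF2A_mrna"),
        "MIR210HG mRNA": traj.gene_fold,
    }


def generate_dataset(
    params: Mapping[str, float], spec: SyntheticSpec
) -> tuple[TimeSeriesData, Trajectory]:
    """Simulate, sample on the grid, apply multiplicative noise to the
    post-0 h entries, and return the dataset with its noise-free truth."""
    model = spec.model()
    init = default_initial_state(
        model, hif1b=spec.hif1b_init, hif2a_protein=spec.hif2a_protein_init
    )
    truth = simulate(model, params, init, t_grid=spec.grid)
    clean = _observable_columns(truth)

    rng = np.random.default_rng([spec.seed, 1])
    sigma = np.log1p(spec.cv)  # geometric SD 1+cv -> geometric CV = cv
    t = truth.t
    after0 = ~np.isclose(t, 0.0)

    frame = {TIME_COLUMN: t}
    noisy_hif2a_rel = None
    for column in spec.columns:
        values = clean[column].copy()
        if column == "HIF2A protein scaled":
            # keep the scaled column an exact multiple of the relative one
            m = clean["HIF2A protein scaled"][0]
            base = (
                noisy_hif2a_rel
                if noisy_hif2a_rel is not None
                else _noised(clean["HIF2A protein"], after0, rng, sigma)
            )
            values = base * m
        else:
            values = _noised(values, after0, rng, sigma)
            if column == "HIF2A protein":
                noisy_hif2a_rel = values
        if column == "MIR210HG mRNA" and spec.blank_gene_times:
            blank = np.isin(t, np.asarray(spec.blank_gene_times, float))
            values = np.where(blank, np.nan, values)
        frame[column] = values
    data = TimeSeriesData.from_frame(pd.DataFrame(frame))
    return data, truth


def _noised(values, after0, rng, sigma):
    if sigma == 0:
        return values.copy()
    factors = np.ones_like(values)
    factors[after0] = np.exp(sigma * rng.standard_normal(int(after0.sum())))
    return values * factors


def synthetic_anchor_table(truth: Trajectory, k1: float = 0.1, k2: float = 0.6) -> pd.DataFrame:
    """Synthetic absolute-concentration anchors (2 h HIF1A, 8 h HIF2A),
    rounded to 3 significant figures as a real assay report would be."""
    cols = _observable_columns(truth)
    hif1a_rel_2h = truth.value_at(cols["HIF1A protein"], 2.0)
    hif2a_rel_8h = truth.value_at(cols["HIF2A protein"], 8.0)
    round3 = lambda x: float(f"{x:.3g}")
    return pd.DataFrame(
        [
            ("HIF1A", 2.0, round3(hif1a_rel_2h * k1)),
            ("HIF2A", 8.0, round3(hif2a_rel_8h * k2)),
        ],
        columns=["protein", "time (hours)", "ng_per_mg"],
    )


@dataclass
class RecoveryReport:
    """Outcome of one generate -> two-step-fit -> compare cycle.

    ``rmse`` is the relative RMSE of the fitted model against the
    noise-free truth over the observation grid, i.e. the non-missing
    cells of the emitted dataset; ``rmse_full_grid`` additionally scores
    the deliberately blanked (unobserved) gene cells.
    """

    rmse: float
    rmse_full_grid: float
    param_log_ratios: dict[str, float]
    seed: int
    cyto_loss: float
    full_loss: float


def recovery_experiment(
    spec: SyntheticSpec,
    cyto_config=None,
    nuclear_config=None,
) -> RecoveryReport:
    """Generate a dataset, run the two-step fit, and score trajectory
    recovery against the hidden noise-free truth."""
    from .fitting import two_step_fit

    params_true = sample_params(spec)
    data, truth = generate_dataset(params_true, spec)
    cyto, full = two_step_fit(
        data,
        cyto_config,
        nuclear_config,
        hre1=spec.hre1,
        hre2=spec.hre2,
        hif1b_init=spec.hif1b_init,
        hif2a_protein_init=spec.hif2a_protein_init,
    )

    model = spec.model()
    init = default_initial_state(
        model, hif1b=spec.hif1b_init, hif2a_protein=spec.hif2a_protein_init
    )
    fitted_traj = simulate(model, full.params, init, t_grid=spec.grid)
    truth_cols = _observable_columns(truth)
    fitted_cols = _observable_columns(fitted_traj)
    observed_errors = []
    all_errors = []
    for column in spec.columns:
        ref = truth_cols[column]
        est = fitted_cols[column]
        valid = ref > 0
        rel = (est[valid] - ref[valid]) / ref[valid]
        all_errors.append(rel)
        observed = np.isfinite(data.values(column)) & valid
        observed_errors.append((est[observed] - ref[observed]) / ref[observed])
    observed_errors = np.concatenate(observed_errors)
    all_errors = np.concatenate(all_errors)
    log_ratios = {
        name: float(np.log(full.params[name] / params_true[name]))
        for name in full.params
        if params_true.get(name, 0) > 0 and full.params[name] > 0
    }
    return RecoveryReport(
        rmse=float(np.sqrt(np.mean(observed_errors**2))),
        rmse_full_grid=float(np.sqrt(np.mean(all_errors**2))),
        param_log_ratios=log_ratios,
        seed=spec.seed,
        cyto_loss=cyto.loss,
        full_loss=full.loss,
    )
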