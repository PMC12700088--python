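"""Two-step parameter estimation.

Step one fits the cytoplasmic sub-model (mRNA turnover, translation,
protein outflow, hydroxylation, PHD production/decay) to the unscaled
relative series.  Step two fits the full network to the scaled HIF2A
series and the target-gene mRNA, with every cytoplasmic parameter frozen
except those of the three HIF2A-involving reactions
(hif2a_mrna_to_protein, hif2a_protein_out, phd_to_hif2a_protein).

The objective is (by default) the sum of squared proportional residuals
(predicted - observed)/observed; both the proportional and the absolute
scheme are selectable.  Optimization is bounded local least squares from
the canonical start point (rate constants 1, dissociation constants 1e-4),
optionally multi-started with seeded log-normal jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, SimulationError, ValidationError
from .io import TimeSeriesData
from .network import (
    CYTOPLASMIC_REACTIONS,
    HIF2A_CYTOPLASMIC_REACTIONS,
    NUCLEAR_REACTIONS,
    ModelDefinition,
    ParameterSet,
    build_cytoplasmic_model,
    build_default_model,
    parameter_names_for,
)
from .simulate import (
    DEFAULT_INITIAL_HIF1B,
    DEFAULT_INITIAL_HIF2A,
    OxygenProtocol,
    Trajectory,
    default_initial_state,
    simulate,
)

#: Observed column -> model output for the cytoplasmic step (unscaled HIF2A).
CYTO_MAPPING: dict[str, str] = {
    "HIF1A protein": "HIF1A_protein",
    "HIF2A protein": "HIF2A_protein",
    "PHD protein": "PHD_protein",
    "HIF1A mRNA": "HIF1A_mrna",
    "HIF2A mRNA": "HIF2A_mrna",
}

#: Observed column -> model output for the full-model step (scaled HIF2A;
#: western blots see the alpha totals, not the free subunits).
FULL_MAPPING: dict[str, str] = {
    "HIF1A protein": "hif1a_total",
    "HIF2A protein scaled": "hif2a_total",
    "PHD protein": "PHD_protein",
    "HIF1A mRNA": "HIF1A_mrna",
    "HIF2A mRNA": "HIF2A_mrna",
    "MIR210HG mRNA": "gene_fold",
}

_DERIVED_OUTPUTS = ("hif1a_total", "hif2a_total", "gene_fold")


def trajectory_output(traj: Trajectory, key: str) -> np.ndarray:
    """Resolve an observation-mapping output key on a trajectory."""
    if key in _DERIVED_OUTPUTS:
        return getattr(traj, key)
    return traj.series(key)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for one fitting step.

    Parameters are optimized in log space (which enforces the [0, inf)
    positivity bounds and evens out the 1 vs 1e-4 scale disparity between
    rate and dissociation constants); ``param_floor``/``param_ceil`` bound
    the search box.  ``restarts`` adds seeded log-normal multi-starts
    around the canonical start point.
    """

    free_parameters: tuple[str, ...] | None = None
    weighting: str = "proportional"  # or "absolute"
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int | None = None
    restarts: int = 0
    seed: int = 0
    jitter_sd: float = 1.5  # log-space SD of restart jitter
    param_floor: float = 1e-7
    param_ceil: float = 1e4
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-8

    def __post_init__(self):
        if self.weighting not in ("proportional", "absolute"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if not 0 < self.param_floor < self.param_ceil:
            raise ValidationError("need 0 < param_floor < param_ceil")


@dataclass
class FitResult:
    """Fitted parameters plus diagnostics.

    ``loss`` is the recomputed sum of squared residuals at ``params``.
    """

    params: ParameterSet
    loss: float
    residual_table: pd.DataFrame
    success: bool
    free: tuple[str, ...]
    frozen: tuple[str, ...]
    nfev: int
    history: list[float]
    provenance: dict

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self.free


def _observation_entries(
    data: TimeSeriesData, mapping: Mapping[str, str]
) -> list[tuple[str, str, float, float]]:
    """(column, output-key, time, observed) for every non-missing cell."""
    entries = []
    for column, output in mapping.items():
        if column not in data.columns:
            continue
        obs = data.values(column)
        for t, value in zip(data.times, obs):
            if np.isfinite(value):
                entries.append((column, output, float(t), float(value)))
    if not entries:
        raise ValidationError("no observed entries match the mapping")
    return entries


def residuals(
    model: ModelDefinition,
    params: Mapping[str, float],
    data: TimeSeriesData,
    mapping: Mapping[str, str],
    init: Mapping[str, float],
    protocol: OxygenProtocol | None = None,
    weighting: str = "proportional",
    **sim_kwargs,
) -> np.ndarray:
    """Residual per (observed column, timepoint); missing cells skipped.

    Proportional weighting divides by the observed value; an observed 0
    falls back to the absolute residual with a warning.
    """
    entries = _observation_entries(data, mapping)
    traj = simulate(model, params, init, protocol, t_grid=data.times, **sim_kwargs)
    return _residuals_on(traj, entries, weighting)


def _residuals_on(traj, entries, weighting):
    cache: dict[str, np.ndarray] = {}
    out = np.empty(len(entries))
    for i, (_, output, t, obs) in enumerate(entries):
        if output not in cache:
            cache[output] = trajectory_output(traj, output)
        pred = traj.value_at(cache[output], t)
        if weighting == "proportional":
            if obs == 0:
                warnings.warn(
                    "observed value 0 under proportional weighting; "
                    "using absolute residual for this entry",
                    stacklevel=2,
                )
                out[i] = pred - obs
            else:
                out[i] = (pred - obs) / obs
        else:
            out[i] = pred - obs
    return out


def _residual_table(entries, residual_vector) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "column": col,
                "output": output,
                "time (hours)": t,
                "observed": obs,
                "residual": r,
            }
            for (col, output, t, obs), r in zip(entries, residual_vector)
        ]
    )


def _fit(
    model: ModelDefinition,
    data: TimeSeriesData,
    mapping: Mapping[str, str],
    init: Mapping[str, float],
    free: Sequence[str],
    base_params: ParameterSet,
    config: FitConfig,
    protocol: OxygenProtocol | None,
) -> FitResult:
    entries = _observation_entries(data, mapping)
    n_obs = len(entries)
    t_grid = data.times
    history: list[float] = []

    def make_params(z: np.ndarray) -> ParameterSet:
        params = ParameterSet(base_params)
        params.update(zip(free, np.exp(z)))
        return params

    def resid(z: np.ndarray) -> np.ndarray:
        try:
            traj = simulate(
                model,
                make_params(z),
                init,
                protocol,
                t_grid=t_grid,
                rtol=config.sim_rtol,
                atol=config.sim_atol,
            )
            r = _residuals_on(traj, entries, config.weighting)
        except SimulationError:
            r = np.full(n_obs, 1e6)
        history.append(float(np.sum(r * r)))
        return r

    x0_base = np.array([base_params.require(name) for name in free])
    lo, hi = np.log(config.param_floor), np.log(config.param_ceil)
    z0_base = np.clip(np.log(np.maximum(x0_base, config.param_floor)), lo, hi)
    rng = np.random.default_rng(config.seed)
    starts = [z0_base]
    for _ in range(config.restarts):
        jitter = rng.normal(0.0, config.jitter_sd, size=z0_base.size)
        starts.append(np.clip(z0_base + jitter, lo + 1.0, hi - 1.0))

    best = None
    for start in starts:
        sol = least_squares(
            resid,
            start,
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=config.gtol,
            max_nfev=config.max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    fitted = make_params(best.x)
    final_residuals = residuals(
        model,
        fitted,
        data,
        mapping,
        init,
        protocol,
        weighting=config.weighting,
        rtol=config.sim_rtol,
        atol=config.sim_atol,
    )
    frozen = tuple(n for n in base_params if n not in free)
    return FitResult(
        params=fitted,
        loss=float(np.sum(final_residuals**2)),
        residual_table=_residual_table(entries, final_residuals),
        success=bool(best.success),
        free=tuple(free),
        frozen=frozen,
        nfev=int(best.nfev),
        history=history,
        provenance={
            "seed": config.seed,
            "restarts": config.restarts,
            "start_point": dict(zip(free, x0_base)),
            "optimizer": "scipy.optimize.least_squares(method='trf', log-space)",
            "weighting": config.weighting,
            "sim_rtol": config.sim_rtol,
            "sim_atol": config.sim_atol,
        },
    )


def cytoplasmic_free_parameters(model: ModelDefinition) -> tuple[str, ...]:
    return parameter_names_for(model, CYTOPLASMIC_REACTIONS)


def nuclear_free_parameters(model: ModelDefinition) -> tuple[str, ...]:
    """Free set of the second step: all nuclear-part parameters plus the
    three HIF2A-involving cytoplasmic reactions."""
    return parameter_names_for(
        model, NUCLEAR_REACTIONS + HIF2A_CYTOPLASMIC_REACTIONS
    )


def fit_cytoplasmic(
    data: TimeSeriesData,
    config: FitConfig | None = None,
    protocol: OxygenProtocol | None = None,
    init: Mapping[str, float] | None = None,
    base_params: ParameterSet | None = None,
) -> FitResult:
    """First step: fit the cytoplasmic sub-model to the unscaled series."""
    config = config or FitConfig()
    model = build_cytoplasmic_model()
    if init is None:
        # unscaled relative data: every observed species is 1 at 0 h
        init = default_initial_state(model, hif2a_protein=1.0)
    if base_params is None:
        base_params = model.default_parameters()
    allowed = cytoplasmic_free_parameters(model)
    free = config.free_parameters or allowed
    unknown = set(free) - set(allowed)
    if unknown:
        raise ConfigurationError(f"not cytoplasmic parameters: {sorted(unknown)}")
    return _fit(model, data, CYTO_MAPPING, init, free, base_params, config, protocol)


def fit_nuclear(
    data: TimeSeriesData,
    cyto_params: Mapping[str, float],
    config: FitConfig | None = None,
    hre1: int = 12,
    hre2: int = 18,
    hif1b_init: float = DEFAULT_INITIAL_HIF1B,
    hif2a_protein_init: float = DEFAULT_INITIAL_HIF2A,
    protocol: OxygenProtocol | None = None,
) -> FitResult:
    """Second step: fit the full model with cytoplasmic parameters frozen
    at their step-one values, except the three HIF2A-involving reactions."""
    config = config or FitConfig()
    model = build_default_model(hre1, hre2)
    base_params = model.default_parameters()
    base_params.update(cyto_params)
    allowed = nuclear_free_parameters(model)
    free = config.free_parameters or allowed
    frozen_requested = set(free) - set(allowed)
    if frozen_requested:
        raise ConfigurationError(
            f"parameters frozen after the cytoplasmic step: {sorted(frozen_requested)}"
        )
    init = default_initial_state(
        model, hif1b=hif1b_init, hif2a_protein=hif2a_protein_init
    )
    result = _fit(
        model, data, FULL_MAPPING, init, free, base_params, config, protocol
    )
    # freezing is exact by construction; assert it anyway
    for name in result.frozen:
        if result.params[name] != base_params[name]:
            raise ConfigurationError(f"frozen parameter {name!r} was perturbed")
    return result


def two_step_fit(
    data: TimeSeriesData,
    cyto_config: FitConfig | None = None,
    nuclear_config: FitConfig | None = None,
    hre1: int = 12,
    hre2: int = 18,
    hif1b_init: float = DEFAULT_INITIAL_HIF1B,
    hif2a_protein_init: float = DEFAULT_INITIAL_HIF2A,
) -> tuple[FitResult, FitResult]:
    """Run both fitting steps and return (cytoplasmic, full) results."""
    cyto = fit_cytoplasmic(data, cyto_config)
    full = fit_nuclear(
        data,
        cyto.params,
        nuclear_config,
        hre1=hre1,
        hre2=hre2,
        hif1b_init=hif1b_init,
        hif2a_protein_init=hif2a_protein_init,
    )
    return cyto, full
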