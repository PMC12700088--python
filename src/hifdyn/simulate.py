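"""ODE integration under oxygen protocols and the simulation experiments.

Oxygen is a piecewise-constant boundary input; integration restarts at
every protocol step so the discontinuity never crosses a solver step.
Level 1 corresponds to the 0.9 % O2 training hypoxia; the species initial
conditions encode the normoxic starting point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SimulationError, ValidationError
from .network import ModelDefinition, SpeciesState

#: Observation grid of the training time series (hours).
DEFAULT_GRID: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 12, 16, 20, 24, 36, 48)

#: Initial conditions of the final model (relative units).
DEFAULT_INITIAL_HIF1B = 60.0
DEFAULT_INITIAL_HIF2A = 5.26


@dataclass(frozen=True)
class OxygenProtocol:
    """Piecewise-constant oxygen input: ordered (time h, level) steps."""

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "steps", tuple((float(t), float(v)) for t, v in self.steps)
        )
        if not self.steps:
            raise ValidationError("protocol needs at least one step")
        times = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("protocol times must be strictly increasing")
        if times[0] > 0:
            raise ValidationError("first protocol time must be <= 0")
        if any(level < 0 for _, level in self.steps):
            raise ValidationError("oxygen levels must be >= 0")

    @classmethod
    def constant(cls, level: float = 1.0) -> "OxygenProtocol":
        return cls(((0.0, float(level)),))

    def level_at(self, t: float) -> float:
        level = self.steps[0][1]
        for step_t, step_level in self.steps:
            if step_t <= t:
                level = step_level
        return level

    def switch_times(self, t0: float, t1: float) -> list[float]:
        return [t for t, _ in self.steps if t0 < t < t1]


@dataclass
class Trajectory:
    """Simulated state on a time grid plus the derived observables."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, n_species)
    model: ModelDefinition
    protocol: OxygenProtocol

    def series(self, name: str) -> np.ndarray:
        return self.y[:, self.model.index(name)]

    def _total(self, free: str, bound: tuple[str, ...]) -> np.ndarray:
        total = self.series(free).copy()
        for name in bound:
            if name in self.model.species:
                total += self.series(name)
        return total

    @property
    def hif1a_total(self) -> np.ndarray:
        return self._total("HIF1A_protein", ("HIF1AB", "HIF1AB_HRE1", "HIF1AB_HRE2"))

    @property
    def hif2a_total(self) -> np.ndarray:
        return self._total("HIF2A_protein", ("HIF2AB", "HIF2AB_HRE1", "HIF2AB_HRE2"))

    @property
    def free_hre1(self) -> np.ndarray:
        return self.series("HRE1")

    @property
    def free_hre2(self) -> np.ndarray:
        return self.series("HRE2")

    @property
    def occupied_hre1(self) -> np.ndarray:
        return self.model.hre1_total - self.free_hre1

    @property
    def occupied_hre2(self) -> np.ndarray:
        return self.model.hre2_total - self.free_hre2

    def fold(self, name: str) -> np.ndarray:
        """Series divided by its 0 h value (requires 0 h on the grid)."""
        values = self.series(name)
        i0 = int(np.argmin(np.abs(self.t)))
        if abs(self.t[i0]) > 1e-9:
            raise ValidationError("fold requires 0 h on the time grid")
        if values[i0] == 0:
            return values.copy()
        return values / values[i0]

    @property
    def gene_fold(self) -> np.ndarray:
        return self.fold("Gene_mRNA")

    def value_at(self, series: np.ndarray, t: float) -> float:
        hits = np.nonzero(np.isclose(self.t, t, atol=1e-9))[0]
        if not hits.size:
            raise ValidationError(f"time {t} h not on trajectory grid")
        return float(series[hits[0]])

    def to_frame(self) -> pd.DataFrame:
        data = {"time (hours)": self.t}
        for name in self.model.species:
            data[name] = self.series(name)
        if "HIF1AB" in self.model.species:
            data["HIF1A_protein_total"] = self.hif1a_total
            data["HIF2A_protein_total"] = self.hif2a_total
            data["HRE1_occupied"] = self.occupied_hre1
            data["HRE2_occupied"] = self.occupied_hre2
            if np.any(np.isclose(self.t, 0.0)):
                data["Gene_mRNA_fold"] = self.gene_fold
        return pd.DataFrame(data)


def default_initial_state(
    model: ModelDefinition,
    hif1b: float = DEFAULT_INITIAL_HIF1B,
    hif2a_protein: float = DEFAULT_INITIAL_HIF2A,
) -> SpeciesState:
    """Normoxic initial conditions; complexes start empty and the free HRE
    pools start at the configured motif counts."""
    state = SpeciesState({name: 0.0 for name in model.species})
    for name in ("HIF1A_mrna", "HIF2A_mrna", "HIF1A_protein", "PHD_protein"):
        if name in model.species:
            state[name] = 1.0
    if "HIF2A_protein" in model.species:
        state["HIF2A_protein"] = float(hif2a_protein)
    if "HIF1B" in model.species:
        state["HIF1B"] = float(hif1b)
    if "HRE1" in model.species:
        state["HRE1"] = float(model.hre1_total)
        state["HRE2"] = float(model.hre2_total)
    if "Gene_mRNA" in model.species:
        state["Gene_mRNA"] = 1.0
    return state


def simulate(
    model: ModelDefinition,
    params: Mapping[str, float],
    init: Mapping[str, float],
    protocol: OxygenProtocol | None = None,
    t_grid: Sequence[float] = DEFAULT_GRID,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network over ``t_grid`` under the oxygen protocol.

    Integration is segmented at protocol steps; a grid point falling on a
    switch time takes the left-limit (pre-switch) state.  On solver
    failure a :class:`SimulationError` carries the failing time and the
    last valid state.
    """
    if protocol is None:
        protocol = OxygenProtocol.constant(1.0)
    SpeciesState(init).validate()
    t_grid = np.array(sorted(t_grid), float)
    if t_grid.size == 0:
        raise ValidationError("empty time grid")

    rhs = model.compile(params)
    t0 = min(0.0, float(t_grid[0]))
    t_end = float(t_grid[-1])
    boundaries = [t0, *protocol.switch_times(t0, t_end), t_end]

    y = model.state_vector(init)
    values = np.empty((t_grid.size, len(model.species)))
    assigned = np.zeros(t_grid.size, bool)
    if np.isclose(t_grid[0], t0):
        values[0] = y
        assigned[0] = True
    for a, b in zip(boundaries, boundaries[1:]):
        if b <= a:
            continue
        o2 = protocol.level_at(a)
        sol = solve_ivp(
            lambda t, yy: rhs(t, yy, o2),
            (a, b),
            y,
            method=method,
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last_t = float(sol.t[-1]) if sol.t.size else a
            last_y = sol.y[:, -1] if sol.t.size else y
            raise SimulationError(
                f"integration failed at t={last_t:.4g} h: {sol.message}",
                t_fail=last_t,
                last_state=model.state_dict(last_y),
            )
        in_seg = (~assigned) & (t_grid >= a) & (t_grid <= b)
        if np.any(in_seg):
            values[in_seg] = sol.sol(t_grid[in_seg]).T
            assigned[in_seg] = True
        y = sol.y[:, -1]

    return Trajectory(t_grid, values, model, protocol)


def titrate_hif1b(
    model: ModelDefinition,
    params_by_level,
    init: Mapping[str, float],
    levels: Sequence[float],
    **sim_kwargs,
) -> dict[float, "Trajectory | SimulationError"]:
    """Simulate the model at several initial HIF1B concentrations.

    ``params_by_level`` is either one shared parameter mapping (str keys)
    or a mapping level -> parameter set (per-level re-fits, mirroring the
    separate fits of the titration experiment).  A failed level is
    recorded as its exception without aborting the other levels.
    """
    shared = not params_by_level or isinstance(next(iter(params_by_level)), str)
    out: dict[float, Trajectory | SimulationError] = {}
    for level in levels:
        if level <= 0:
            raise ValidationError("HIF1B levels must be positive")
        params = params_by_level if shared else params_by_level[level]
        state = SpeciesState(dict(init))
        state["HIF1B"] = float(level)
        try:
            out[level] = simulate(model, params, state, **sim_kwargs)
        except SimulationError as err:
            out[level] = err
    return out


def predict_gene(
    model_params: Mapping[str, float],
    hre1: int,
    hre2: int,
    hif1b_init: float,
    t_obs: Sequence[float] = (0, 2, 8, 16),
    hif2a_protein_init: float = DEFAULT_INITIAL_HIF2A,
    **sim_kwargs,
) -> np.ndarray:
    """Predict target-gene fold induction over 0 h for a gene with the
    given HRE counts, using a previously fitted final-model parameter set."""
    from .network import build_default_model

    model = build_default_model(hre1, hre2)
    init = default_initial_state(
        model, hif1b=hif1b_init, hif2a_protein=hif2a_protein_init
    )
    grid = sorted({0.0, *map(float, t_obs)})
    traj = simulate(model, model_params, init, t_grid=grid, **sim_kwargs)
    folds = traj.fold("Gene_mRNA")
    return np.array([traj.value_at(folds, t) for t in t_obs])
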