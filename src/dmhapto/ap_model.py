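"""Mechanistic model of trigger-hair action potentials and turgor pressure.

The sensory cells at the base of the Venus flytrap trigger hair fire an
action potential (AP) when bent.  During the ~1 s depolarized (excited)
phase, K+ flows out of the cell through depolarization-activated channels,
electrically compensated by an equal anion efflux.  During the
hyperpolarized recovery phase an energized uptake pathway (the
acid/hyperpolarization-activated K+ channel KDM1 together with the
H+-ATPase) slowly pumps both ions back.  The combined salt movement changes
the osmotic — and hence hydrostatic — pressure difference dP across the
plasma membrane, i.e. the cell's turgor.  A stimulus only elicits an AP
while relative turgor is above a critical threshold, which produces the
characteristic dropout patterns under high-frequency stimulation.

The model tracks two compartments (cell and apoplast, volume ratio
``alpha``), two ion species (K+ and a monovalent counter-anion A-), and a
prescribed two-level membrane voltage; it is integrated with explicit Euler
at a fixed step ``dt``.

Units: voltages in mV, concentrations in mM, time in s, pressure in bar,
flux densities in mM/s.  The rate constant ``k`` (the channel conductance
density divided by cell volume) is in mol/(l*V*s), so ``k`` times a voltage
in mV is numerically a flux in mM/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrationError

FARADAY = 96485.33212  # C/mol

__all__ = [
    "FARADAY",
    "ModelParams",
    "CellState",
    "StimulusProtocol",
    "APEvent",
    "Trajectory",
    "potassium_equilibrium_voltage",
    "efflux_rate",
    "influx_rate",
    "step",
    "resting_pressure",
    "simulate",
    "single_ap_summary",
    "recovery_time",
    "operating_range",
    "dropout_pattern",
    "whole_cell_current",
]


def potassium_equilibrium_voltage(k_apo: float, k_cell: float, rt_over_f: float) -> float:
    """Nernst equilibrium voltage E_K = RT/F * ln([K+]apo / [K+]cell) in mV.

    Parameters
    ----------
    k_apo, k_cell : float
        Apoplastic and cytosolic K+ concentrations (mM); must be > 0.
    rt_over_f : float
        Thermal voltage RT/F in mV (~25 mV at room temperature).
    """
    if k_apo <= 0 or k_cell <= 0:
        raise ValueError(
            f"concentrations must be positive, got k_apo={k_apo}, k_cell={k_cell}"
        )
    return rt_over_f * math.log(k_apo / k_cell)


@dataclass(frozen=True)
class ModelParams:
    """All constants of the two-compartment K+/anion/turgor model.

    Attributes
    ----------
    alpha : float
        Apoplast-to-cell volume ratio (dimensionless, > 0).
    v_excited, v_rest : float
        Prescribed membrane voltage (mV) in the excited and recovery state.
    v0 : float or None
        Resting-offset voltage (mV) entering the uptake drive; the uptake
        stops when E_K reaches ``v_rest + v0``.  ``None`` (default) resolves
        to the value that makes the initial composition an exact fixed
        point, E_K0 - v_rest (54.87 mV at defaults); the nominal rounded
        55 mV can be set explicitly.
    k : float
        Flux rate constant a_K/Vol_cell in mol/(l*V*s).
    beta : float
        Dimensionless uptake efficiency, 0 < beta <= 1.  The energized
        uptake is ~100x slower than the passive efflux (beta = 0.01);
        Cs+ block of the uptake channel is modelled as a reduced beta.
    rt_over_f : float
        Thermal voltage RT/F (mV).
    dt : float
        Explicit-Euler step (s).
    excited_duration : float
        Length of the depolarized phase per fired stimulus (s).
    turgor_threshold : float
        Fraction of resting dP below which a stimulus fails to elicit an AP.
    k_cell0, k_apo0, a_cell0, a_apo0 : float
        Initial concentrations (mM).
    """

    alpha: float = 15.0
    v_excited: float = -60.0
    v_rest: float = -170.0
    v0: float | None = None
    k: float = 1.0
    beta: float = 0.01
    rt_over_f: float = 25.0
    dt: float = 0.05
    excited_duration: float = 1.0
    turgor_threshold: float = 0.5
    k_cell0: float = 100.0
    k_apo0: float = 1.0
    a_cell0: float = 100.0
    a_apo0: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must satisfy 0 < beta <= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.excited_duration <= 0:
            raise ValueError("excited_duration must be > 0")
        if not (0 < self.turgor_threshold < 1):
            raise ValueError("turgor_threshold must lie in (0, 1)")
        if self.v_excited <= self.v_rest:
            raise ValueError("v_excited must exceed v_rest")
        if self.rt_over_f <= 0:
            raise ValueError("rt_over_f must be > 0")
        for name in ("k_cell0", "k_apo0", "a_cell0", "a_apo0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v0 is None:
            # Exact resting fixed point: uptake drive vanishes at the
            # initial composition, preventing artificial drift.
            e_k0 = potassium_equilibrium_voltage(
                self.k_apo0, self.k_cell0, self.rt_over_f
            )
            object.__setattr__(self, "v0", e_k0 - self.v_rest)

    @property
    def rt_joule(self) -> float:
        """RT in J/mol, derived from the configured thermal voltage."""
        return self.rt_over_f * 1e-3 * FARADAY

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (v0 re-resolved if
        the composition or voltages change and v0 was not given)."""
        return replace(self, **kwargs)


@dataclass
class CellState:
    """Instantaneous state of the two-compartment model."""

    t: float
    k_cell: float
    k_apo: float
    a_cell: float
    a_apo: float
    dp: float
    trigger: int = 0
    excited_until: float = -math.inf

    def __post_init__(self) -> None:
        if self.trigger not in (0, 1):
            raise ValueError("trigger must be 0 or 1")
        if min(self.k_cell, self.k_apo, self.a_cell, self.a_apo) < 0:
            raise ValueError("concentrations must be non-negative")

    def pressure_from_concentrations(self, params: ModelParams) -> float:
        """dP recomputed directly from the state, RT*(c_in - c_out), in bar."""
        c_net = self.k_cell + self.a_cell - self.k_apo - self.a_apo  # mM
        return params.rt_joule * c_net / 1e5


def initial_state(params: ModelParams) -> CellState:
    """Equilibrium resting state (trigger = 0) at t = 0."""
    return CellState(
        t=0.0,
        k_cell=params.k_cell0,
        k_apo=params.k_apo0,
        a_cell=params.a_cell0,
        a_apo=params.a_apo0,
        dp=resting_pressure(params),
    )


def efflux_rate(state: CellState, params: ModelParams) -> float:
    """K+ efflux density through depolarization-activated channels (mM/s).

    j_efflux = k * (v_excited - E_K) * trigger; positive means out of the
    cell.  The compensating anion efflux is identical by construction.
    """
    if state.trigger == 0:
        return 0.0
    e_k = potassium_equilibrium_voltage(state.k_apo, state.k_cell, params.rt_over_f)
    return params.k * (params.v_excited - e_k)


def influx_rate(state: CellState, params: ModelParams) -> float:
    """Energized K+ re-uptake density during recovery (mM/s, <= 0).

    j_influx = min(0, k * beta * (v_rest - E_K + v0)) * (1 - trigger).
    The clamp encodes that uptake stops once the concentration gradients
    are re-established (E_K back at v_rest + v0); the pathway never runs
    backwards as an efflux.
    """
    if state.trigger == 1:
        return 0.0
    e_k = potassium_equilibrium_voltage(state.k_apo, state.k_cell, params.rt_over_f)
    drive = params.beta * params.k * (params.v_rest - e_k + params.v0)
    return min(0.0, drive)


def step(state: CellState, params: ModelParams) -> CellState:
    """One explicit-Euler step of size ``dt``.

    Conserves K_cell + alpha*K_apo (and the anion analogue) exactly;
    dP is decremented incrementally per the pressure balance
    dP -= 2*RT*(alpha+1)/alpha * j_total * dt.
    """
    j = efflux_rate(state, params) + influx_rate(state, params)  # mM/s
    d_cell = -j * params.dt
    d_apo = j * params.dt / params.alpha
    k_cell = state.k_cell + d_cell
    k_apo = state.k_apo + d_apo
    a_cell = state.a_cell + d_cell
    a_apo = state.a_apo + d_apo
    if min(k_cell, k_apo, a_cell, a_apo) < 0:
        raise IntegrationError(
            f"negative concentration after step at t={state.t:.3f}s; "
            "reduce dt or flux rates"
        )
    d_dp = params.rt_joule * 2.0 * (d_cell - d_apo) / 1e5  # bar
    t_next = state.t + params.dt
    trigger_next = 1 if t_next < state.excited_until else 0
    return CellState(
        t=t_next,
        k_cell=k_cell,
        k_apo=k_apo,
        a_cell=a_cell,
        a_apo=a_apo,
        dp=state.dp + d_dp,
        trigger=trigger_next,
        excited_until=state.excited_until,
    )


def resting_pressure(params: ModelParams) -> float:
    """Resting pressure difference dP0 = RT*(c_in,0 - c_out,0) in bar.

    With the default composition (200 mM osmotica inside vs 2 mM outside)
    and RT/F = 25 mV this is 4.78 bar, i.e. approximately 5 bar.
    """
    c_net = (params.k_cell0 + params.a_cell0) - (params.k_apo0 + params.a_apo0)
    return params.rt_joule * c_net / 1e5


def whole_cell_current(k: float, vol_cytosol: float, delta_v: float) -> float:
    """Whole-cell K+ current F*k*Vol*(V - E_K) in amperes.

    Parameters: ``k`` in mol/(l*V*s), ``vol_cytosol`` in litres, ``delta_v``
    in mV.  For a 50 fl cytosol under a 50 mV driving force at k = 1 this is
    ~241 pA, in the observed physiological range (~250 pA).
    """
    if vol_cytosol <= 0:
        raise ValueError("vol_cytosol must be positive")
    return FARADAY * k * vol_cytosol * delta_v * 1e-3


@dataclass(frozen=True)
class StimulusProtocol:
    """A sequence of mechanical stimulation times (s), strictly increasing."""

    stimulus_times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.stimulus_times)
        if any(t < 0 for t in times):
            raise ValueError("stimulus times must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stimulus times must be strictly increasing")
        object.__setattr__(self, "stimulus_times", times)

    @classmethod
    def periodic(cls, frequency: float, count: int, start: float = 0.0) -> "StimulusProtocol":
        """Evenly spaced stimuli: ``count`` events at ``frequency`` Hz."""
        if frequency <= 0:
            raise ValueError("frequency must be > 0")
        if count < 1:
            raise ValueError("count must be >= 1")
        period = 1.0 / frequency
        return cls(tuple(start + i * period for i in range(count)))


@dataclass(frozen=True)
class APEvent:
    """Outcome of one mechanical stimulus.

    ``fired`` is False either because relative turgor was below the
    threshold (a genuine dropout) or because the stimulus arrived during an
    ongoing excited phase (``skipped`` is then True and the event is not
    counted as a dropout).
    """

    stimulus_time: float
    fired: bool
    rel_dp_at_stimulus: float
    skipped: bool = False

    @property
    def dropout(self) -> bool:
        return not self.fired and not self.skipped


@dataclass
class Trajectory:
    """Time-sampled model output plus the AP event log."""

    t: np.ndarray
    k_cell: np.ndarray
    k_apo: np.ndarray
    a_cell: np.ndarray
    a_apo: np.ndarray
    dp: np.ndarray
    trigger: np.ndarray
    events: list[APEvent]
    params: ModelParams
    dp0: float

    @property
    def rel_dp(self) -> np.ndarray:
        return self.dp / self.dp0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "K_cell": self.k_cell,
                "K_apo": self.k_apo,
                "A_cell": self.a_cell,
                "A_apo": self.a_apo,
                "dP": self.dp,
                "rel_dP": self.rel_dp,
                "trigger": self.trigger,
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_time": [e.stimulus_time for e in self.events],
                "fired": [int(e.fired) for e in self.events],
                "rel_dP_at_stimulus": [e.rel_dp_at_stimulus for e in self.events],
                "skipped": [int(e.skipped) for e in self.events],
            }
        )


def simulate(
    params: ModelParams,
    protocol: StimulusProtocol | Sequence[float] | None = None,
    t_end: float = 10.0,
) -> Trajectory:
    """Integrate the model from equilibrium rest with a stimulation protocol.

    At each stimulus time the cell fires (trigger = 1 for
    ``excited_duration``) iff relative dP >= ``turgor_threshold`` and the
    cell is not already excited; sub-threshold stimuli are logged as
    dropouts, stimuli during an ongoing excited phase as skipped non-events.
    Stimulus times are snapped to the Euler grid.
    """
    if protocol is None:
        protocol = StimulusProtocol(())
    elif not isinstance(protocol, StimulusProtocol):
        protocol = StimulusProtocol(tuple(protocol))

    dt = params.dt
    n_steps = int(round(t_end / dt))
    if any(ts >= t_end for ts in protocol.stimulus_times):
        raise ValueError("all stimulus times must lie before t_end")
    stim_idx = {int(round(ts / dt)): ts for ts in protocol.stimulus_times}
    if len(stim_idx) != len(protocol.stimulus_times):
        raise ValueError("two stimuli snap to the same Euler grid point")

    dp0 = resting_pressure(params)
    state = initial_state(params)

    t = np.empty(n_steps + 1)
    k_cell = np.empty(n_steps + 1)
    k_apo = np.empty(n_steps + 1)
    a_cell = np.empty(n_steps + 1)
    a_apo = np.empty(n_steps + 1)
    dp = np.empty(n_steps + 1)
    trig = np.zeros(n_steps + 1, dtype=np.int8)
    events: list[APEvent] = []

    for i in range(n_steps + 1):
        if i in stim_idx:
            rel = state.dp / dp0
            if state.t < state.excited_until:
                events.append(APEvent(stim_idx[i], False, rel, skipped=True))
            elif rel >= params.turgor_threshold:
                state.excited_until = state.t + params.excited_duration
                state.trigger = 1
                events.append(APEvent(stim_idx[i], True, rel))
            else:
                events.append(APEvent(stim_idx[i], False, rel))
        t[i] = state.t
        k_cell[i] = state.k_cell
        k_apo[i] = state.k_apo
        a_cell[i] = state.a_cell
        a_apo[i] = state.a_apo
        dp[i] = state.dp
        trig[i] = state.trigger
        if i < n_steps:
            state = step(state, params)

    return Trajectory(t, k_cell, k_apo, a_cell, a_apo, dp, trig, events, params, dp0)


def single_ap_summary(params: ModelParams | None = None) -> dict[str, float]:
    """Headline quantities of a single AP from rest at the given parameters.

    Returns the percent decrease of [K+]cell and of dP over the excited
    phase, and the apoplastic [K+] at its end both as percent of its initial
    value (final/initial) and as the percent increment.
    """
    params = params or ModelParams()
    traj = simulate(params, StimulusProtocol((0.0,)), t_end=params.excited_duration)
    k_cell_end = traj.k_cell[-1]
    k_apo_end = traj.k_apo[-1]
    dp_end = traj.dp[-1]
    return {
        "k_cell_decrease_pct": float(
            100.0 * (params.k_cell0 - k_cell_end) / params.k_cell0
        ),
        "k_apo_final_pct_of_initial": float(100.0 * k_apo_end / params.k_apo0),
        "k_apo_increment_pct": float(
            100.0 * (k_apo_end - params.k_apo0) / params.k_apo0
        ),
        "dp_decrease_pct": float(100.0 * (traj.dp0 - dp_end) / traj.dp0),
    }


def recovery_time(
    params: ModelParams | None = None,
    tol: float = 0.01,
    time_cap: float = 1e5,
) -> float:
    """Time from the end of one AP's excited phase until relative dP has
    returned to within ``tol`` of resting (rel dP >= 1 - tol).

    The recovery flux scales linearly with ``beta``, so halving beta doubles
    this time (up to Euler discretization); a 5-fold reduced uptake activity
    (Cs+ block) makes recovery 5x slower.
    """
    if not (0 < tol < 1):
        raise ValueError("tol must lie in (0, 1)")
    params = params or ModelParams()
    dp0 = resting_pressure(params)
    state = initial_state(params)
    state.excited_until = params.excited_duration
    state.trigger = 1
    target = (1.0 - tol) * dp0
    t_excited_end = params.excited_duration
    while state.t <= time_cap:
        state = step(state, params)
        if state.t >= t_excited_end and state.dp >= target:
            return state.t - t_excited_end
    raise IntegrationError(
        f"no recovery to {1 - tol:.3%} of resting dP within {time_cap} s"
    )


def _cycle_extrema(traj: Trajectory, frequency: float, cycle: int) -> tuple[float, float]:
    """Min and max of relative dP (in percent) over one stimulation cycle."""
    period = 1.0 / frequency
    lo = traj.events[cycle].stimulus_time
    mask = (traj.t >= lo - 1e-9) & (traj.t <= lo + period + 1e-9)
    rel = traj.rel_dp[mask] * 100.0
    return float(rel.min()), float(rel.max())


def operating_range(
    params: ModelParams | None = None,
    frequency: float = 0.05,
    n_stimuli: int = 60,
    convergence_pp: float = 0.1,
) -> dict[str, float | bool]:
    """Steady per-cycle extrema of relative dP under periodic stimulation.

    Runs ``n_stimuli`` stimuli at ``frequency`` Hz, discards the first
    max(10, n/2) cycles as transient, and reports the (min, max) of
    dP/dP0 x 100 over the final complete cycle.  At the default 0.05 Hz the
    cell settles into an operating band of roughly 51-61% of resting turgor.

    Returns a dict with ``min_pct``, ``max_pct``, ``converged`` (consecutive
    final cycles' extrema agree within ``convergence_pp`` percentage points)
    and ``dropout_in_final_cycle``.
    """
    params = params or ModelParams()
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    protocol = StimulusProtocol.periodic(frequency, n_stimuli)
    period = 1.0 / frequency
    traj = simulate(params, protocol, t_end=n_stimuli * period)

    transient = max(10, n_stimuli // 2)
    if n_stimuli <= transient + 1:
        raise ValueError("n_stimuli too small to discard the transient")
    last = n_stimuli - 1
    lo_f, hi_f = _cycle_extrema(traj, frequency, last)
    lo_p, hi_p = _cycle_extrema(traj, frequency, last - 1)
    converged = abs(lo_f - lo_p) < convergence_pp and abs(hi_f - hi_p) < convergence_pp
    dropout = any(e.dropout for e in traj.events[transient:])
    return {
        "min_pct": lo_f,
        "max_pct": hi_f,
        "converged": bool(converged),
        "dropout_in_final_cycle": bool(dropout),
    }


def dropout_pattern(
    params: ModelParams | None = None,
    frequency: float = 0.05,
    n_stimuli: int = 60,
) -> dict[str, object]:
    """Fired/failed flags under periodic stimulation, with summary stats.

    Returns ``fired`` (boolean array per stimulus), ``fraction_fired`` and
    ``longest_failure_run``.  Skipped stimuli (arriving during an ongoing
    excited phase) count as not fired but are reported separately.
    """
    params = params or ModelParams()
    protocol = StimulusProtocol.periodic(frequency, n_stimuli)
    traj = simulate(params, protocol, t_end=n_stimuli / frequency)
    fired = np.array([e.fired for e in traj.events], dtype=bool)
    skipped = np.array([e.skipped for e in traj.events], dtype=bool)
    longest = run = 0
    for f in fired:
        run = 0 if f else run + 1
        longest = max(longest, run)
    return {
        "fired": fired,
        "skipped": skipped,
        "fraction_fired": float(fired.mean()),
        "longest_failure_run": int(longest),
        "events": traj.events,
    }
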