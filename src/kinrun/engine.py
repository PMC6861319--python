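"""Event-driven simulation of the dimeric kinesin stepping pathway.

The mechanochemical cycle is simulated as an exact race of competing
exponential channels (kinetic Monte Carlo).  Mechanical substeps —
detachment of a just-hydrolyzed ADP head into the one-head-bound INT
position, and diffusion of the tethered head to the forward site once
the bound head's neck linker docks — are instantaneous at the event
level; the Brownian validation layer (:mod:`kinrun.brownian`) checks
that these diffusive times are far below every chemical dwell time.

Reachable composite states
--------------------------
Two-heads-bound (``TH``), trailing head always in the ATP state with its
neck linker docked:

* ``TH(ATP, ADP)`` — just stepped; leading-head ADP release (k_D) races
  trailing-head hydrolysis (k_c).  Losing the race opens Period II.
* ``TH(ATP, PHI)`` — leading-head ATP binding races trailing hydrolysis.
* ``TH(ATP, ATP)`` — trailing hydrolysis (k_c) races the slow leading
  hydrolysis (k_c/ρ); the latter is the futile branch.

One-head-bound (``INT``), tethered head always in the ADP state:

* ``INT(PHI)`` — waits for ATP binding.
* ``INT(ATP)`` — neck-linker docking (k_NL) races bound-head hydrolysis
  (k_c/ρ once catalytically active, 0 while the kinesin-3 dimerization
  clock is still running).  Docking sends the tethered head to the
  forward site (a 8-nm step); hydrolysis opens Period I.

A futile INT passage (entered by leading-head hydrolysis) resolves by
the same docking event but returns the tethered head to the site it
came from, so no net displacement results; its Period-I exposure is
identical to a productive passage.

Dissociation is resolved by the calibrated escape model the moment a
weak-binding period is entered; the kinesin-3 dimerization clock runs
as one extra exponential channel (rate k_0) in every race.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clock import ClockState, advance_clock, new_clock
from .dissociation import EscapeModel, calibrate
from .params import (
    KINESIN1,
    MotorParameters,
    ParameterError,
    SimulationConfig,
    default_parameters,
)

# chemical states of one head; hydrolysis and Pi release are lumped into
# a single transition, so ADP_PI never persists between events
PHI = "PHI"
ATP = "ATP"
ADP_PI = "ADP_PI"
ADP = "ADP"

# dimer modes
TWO_HEADS_BOUND = "TWO_HEADS_BOUND"
INT = "INT"
DISSOCIATED = "DISSOCIATED"

PERIOD_I = "PERIOD_I"
PERIOD_II = "PERIOD_II"
CAP = "cap"


class EngineError(RuntimeError):
    """Model-integrity violation: an unreachable state/chemistry combination."""


class DimerState:
    """Mutable composite pathway state of one dimer.

    ``bound_site`` is the trailing-head lattice index in TWO_HEADS_BOUND
    and the bound-head index in INT.  ``futile`` marks an INT passage
    entered through leading-head hydrolysis, whose docking event returns
    the dimer to the same lattice position.
    """

    __slots__ = (
        "mode", "trailing", "leading", "bound_site", "futile",
        "clock", "t", "n_steps", "period_flag",
    )

    def __init__(self, clock: ClockState):
        self.mode = TWO_HEADS_BOUND
        self.trailing = ATP     # TH: trailing head; INT: bound head
        self.leading = PHI      # TH: leading head; INT: tethered head (ADP)
        self.bound_site = 0
        self.futile = False
        self.clock = clock
        self.t = 0.0
        self.n_steps = 0
        self.period_flag: Optional[str] = None

    @property
    def centroid(self) -> float:
        """Two-head centroid in lattice units."""
        if self.mode == TWO_HEADS_BOUND:
            return self.bound_site + 0.5
        return float(self.bound_site)


def initial_state(params: MotorParameters) -> DimerState:
    """Dimer at t = 0: two heads bound at sites 0 and 1, trailing head in
    the ATP state with its neck linker docked, leading head nucleotide
    free; the dimerization clock at stage 0 (or disabled)."""
    clock = new_clock(params.n_stages, disabled=not params.clock_gated)
    return DimerState(clock)


def int_hydrolysis_rate(params: MotorParameters, clock: ClockState) -> float:
    """ATP hydrolysis + Pi release rate of the bound head in INT state:
    0 while the kinesin-3 clock is incomplete, k_c/ρ otherwise."""
    return params.k_c_lead if clock.complete else 0.0


def enabled_transitions(
    state: DimerState,
    params: MotorParameters,
    config: SimulationConfig,
    include_futile: bool = True,
) -> list[tuple[str, float]]:
    """The exact set of competing exponential channels out of ``state``."""
    if state.mode == DISSOCIATED:
        return []
    channels: list[tuple[str, float]] = []
    if not state.clock.complete:
        channels.append(("clock_stage", params.k0))

    k_bt = params.k_b * config.atp_concentration
    if state.mode == TWO_HEADS_BOUND:
        if state.trailing != ATP:
            raise EngineError(
                f"unreachable chemistry: trailing head {state.trailing} in "
                "TWO_HEADS_BOUND (trailing head must hold ATP)"
            )
        channels.append(("hydrolysis_trailing", params.k_c))
        if state.leading == ADP:
            channels.append(("adp_release_leading", params.k_D))
        elif state.leading == PHI:
            channels.append(("atp_binding_leading", k_bt))
        elif state.leading == ATP:
            if include_futile:
                channels.append(("hydrolysis_leading", params.k_c_lead))
        else:
            raise EngineError(f"unreachable leading-head state {state.leading}")
    elif state.mode == INT:
        if state.leading != ADP:
            raise EngineError("tethered head must hold ADP in INT state")
        if state.trailing == PHI:
            channels.append(("atp_binding_bound", k_bt))
        elif state.trailing == ATP:
            channels.append(("nl_docking", params.k_NL))
            k_int = int_hydrolysis_rate(params, state.clock)
            if k_int > 0:
                channels.append(("hydrolysis_bound", k_int))
        else:
            raise EngineError(f"unreachable bound-head state {state.trailing}")
    else:
        raise EngineError(f"unknown mode {state.mode}")
    return channels


def _resolve_period_II(
    state: DimerState, params: MotorParameters, model: EscapeModel,
    rng: np.random.Generator,
) -> float:
    """Race escape from the E_w2 well against ADP release (rate k_D).

    Returns the extra elapsed time.  On escape the trace is absorbed; on
    survival ADP release has completed and the dimer is in the INT state
    with a nucleotide-free bound head.  The dimerization clock zips
    independently of head chemistry, so pending clock stages keep
    competing inside the exposure window.
    """
    k_off = model.k_off(params.E_w2)
    dt = 0.0
    while True:
        k_clock = params.k0 if not state.clock.complete else 0.0
        total = k_off + params.k_D + k_clock
        dt += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < k_off:
            state.mode = DISSOCIATED
            state.period_flag = PERIOD_II
            return dt
        if u < k_off + params.k_D:
            state.mode = INT
            state.trailing = PHI
            state.leading = ADP
            return dt
        state.clock = advance_clock(state.clock, state.t + dt)


def _resolve_period_I(
    state: DimerState, params: MotorParameters, model: EscapeModel,
    rng: np.random.Generator,
) -> float:
    """Escape from the E_w1 well within the fixed relaxation window t_r.

    On survival the local site has relaxed to depth E_w2 and the exposure
    continues as a Period-II race (a negligible path in the E_w1 ≤ 18
    k_B·T regime, where escape within t_r is ~certain).  Pending clock
    stages keep running during the window.
    """
    k_off = model.k_off(params.E_w1)
    t_r = params.t_r_s
    elapsed = 0.0
    while True:
        k_clock = params.k0 if not state.clock.complete else 0.0
        total = k_off + k_clock
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if elapsed + wait >= t_r:
            return t_r + _resolve_period_II(state, params, model, rng)
        elapsed += wait
        if rng.random() * total < k_off:
            state.mode = DISSOCIATED
            state.period_flag = PERIOD_I
            return elapsed
        state.clock = advance_clock(state.clock, state.t + elapsed)


def advance(
    state: DimerState,
    params: MotorParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
    escape_model: EscapeModel,
    include_futile: bool = True,
) -> tuple[DimerState, float, str]:
    """Execute one event of the race and mutate ``state`` in place.

    Returns ``(state, dt, event_label)`` where ``dt`` is the total time
    elapsed, including any weak-binding exposure window resolved within
    the same event.
    """
    channels = enabled_transitions(state, params, config, include_futile)
    if not channels:
        raise EngineError("advance() called on a state with no enabled transition")
    total = 0.0
    for _, r in channels:
        total += r
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    acc = 0.0
    for label, r in channels:
        acc += r
        if u < acc:
            break

    if label == "clock_stage":
        state.clock = advance_clock(state.clock, state.t + dt)
    elif label == "adp_release_leading":
        state.leading = PHI
    elif label == "atp_binding_leading":
        state.leading = ATP
    elif label == "hydrolysis_trailing":
        if state.leading == ADP:
            # both heads now hold ADP; the trailing head detaches from its
            # perturbed site and the sole bound (leading) head sits in the
            # E_w2 well: Period II
            state.bound_site += 1
            label = "period_II_entry"
            dt += _resolve_period_II(state, params, escape_model, rng)
        else:
            # trailing ADP head detaches into the INT position
            state.mode = INT
            state.trailing = state.leading  # bound head keeps its nucleotide
            state.leading = ADP
            state.bound_site += 1
            state.futile = False
    elif label == "hydrolysis_leading":
        # futile branch: the leading ADP head detaches to the INT position;
        # the trailing ATP head stays bound and the lattice position is kept
        state.mode = INT
        state.trailing = ATP
        state.leading = ADP
        state.futile = True
    elif label == "atp_binding_bound":
        state.trailing = ATP
    elif label == "nl_docking":
        # the tethered ADP head diffuses to the forward site (instantaneous
        # at the event level); in a futile passage that is the site it came
        # from, so no net step results
        if state.futile:
            label = "futile_rebinding"
        else:
            state.n_steps += 1
            label = "forward_step"
        state.mode = TWO_HEADS_BOUND
        state.trailing = ATP
        state.leading = ADP
        state.futile = False
    elif label == "hydrolysis_bound":
        label = "period_I_entry"
        dt += _resolve_period_I(state, params, escape_model, rng)
    else:  # pragma: no cover
        raise EngineError(f"unhandled event {label}")

    state.t += dt
    return state, dt, label


@dataclass
class Trace:
    """One processive run, from landing to dissociation (or time cap)."""

    run_length: float           # nm, step_d x centroid displacement
    total_time: float           # s
    velocity: float             # nm/s
    n_steps: int
    tau_realized: Optional[float]   # s; None if the clock never completed
    dissociation_period: str        # PERIOD_I | PERIOD_II | cap
    events: Optional[list[tuple[float, float, str, str]]] = None
    #                      (t, centroid, mode, label)

    @property
    def capped(self) -> bool:
        return self.dissociation_period == CAP


def simulate_trace(
    params: MotorParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
    escape_model: Optional[EscapeModel] = None,
    record_events: bool = False,
    include_futile: bool = True,
) -> Trace:
    """Simulate one run until dissociation or the time cap."""
    if escape_model is None:
        escape_model = default_escape_model()
    if config.load_F > 0:
        from .force import LoadSettings, apply_load
        params = apply_load(params, LoadSettings(F=config.load_F, lambda_NL=config.lambda_NL))

    state = initial_state(params)
    start = state.centroid
    events = [] if record_events else None
    while state.mode != DISSOCIATED:
        state, dt, label = advance(state, params, config, rng, escape_model, include_futile)
        if events is not None:
            events.append((state.t, state.centroid, state.mode, label))
        if state.mode != DISSOCIATED and state.t > config.max_sim_time:
            state.period_flag = CAP
            break

    run = params.step_d * (state.centroid - start)
    t_total = min(state.t, config.max_sim_time) if state.period_flag == CAP else state.t
    return Trace(
        run_length=run,
        total_time=t_total,
        velocity=run / t_total if t_total > 0 else 0.0,
        n_steps=state.n_steps,
        tau_realized=state.clock.effective_tau,
        dissociation_period=state.period_flag or CAP,
        events=events,
    )


def trace_rng(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-trace generator: traces keep their streams when
    ``n_traces`` changes."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, index))))


def simulate_traces(
    params: MotorParameters,
    config: SimulationConfig,
    escape_model: Optional[EscapeModel] = None,
    record_events: bool = False,
    include_futile: bool = True,
) -> list[Trace]:
    """Simulate ``config.n_traces`` independent runs with counter-derived
    per-trace seeds from ``config.rng_seed``."""
    if escape_model is None:
        escape_model = default_escape_model()
    return [
        simulate_trace(
            params, config, trace_rng(config.rng_seed, i), escape_model,
            record_events, include_futile,
        )
        for i in range(config.n_traces)
    ]


# -- analytic per-step occurrence probabilities (cross-checks) -----------

def p_period_I(params: MotorParameters, k_NL_effective: Optional[float] = None) -> float:
    """Probability per INT passage that bound-head hydrolysis beats
    neck-linker docking (with the clock complete): (k_c/ρ)/(k_c/ρ + k_NL)."""
    k_nl = params.k_NL if k_NL_effective is None else k_NL_effective
    k_int = params.k_c_lead
    if k_nl == math.inf:
        return 0.0
    return k_int / (k_int + k_nl)


def p_period_II_occurrence(params: MotorParameters) -> float:
    """Probability per completed step that trailing-head hydrolysis beats
    leading-head ADP release: k_c/(k_c + k_D)."""
    return params.k_c / (params.k_c + params.k_D)


_DEFAULT_ESCAPE_MODEL: Optional[EscapeModel] = None


def default_escape_model() -> EscapeModel:
    """The escape model calibrated once on the kinesin-1 preset."""
    global _DEFAULT_ESCAPE_MODEL
    if _DEFAULT_ESCAPE_MODEL is None:
        _DEFAULT_ESCAPE_MODEL = calibrate(default_parameters(KINESIN1))
    return _DEFAULT_ESCAPE_MODEL
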