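"""Escape from weak-binding wells: the dissociation model.

A processive run ends almost exclusively during two weak-binding
exposures of the single microtubule-bound ADP head:

Period I
    Right after Pi release at the still-perturbed local site: well depth
    E_w1 (≤ 18 k_B·T), exposure a fixed window t_r until the tubulin
    relaxes.  Escape is near certain in this regime.

Period II
    The sole bound head in the ADP state at an unperturbed site: well
    depth E_w2, exposed until microtubule-stimulated ADP release, i.e.
    racing an exponential exit channel of rate k_D.

Escape kinetics are phenomenological: a single Arrhenius form
k_off(E) = A·e^(−E) with one attempt rate A.  A absorbs all well-shape
detail and is calibrated once, against the 2.3-fold run-length increase
of kinesin-1 when its E_w2 is raised to the kinesin-3 level; it is
reported, not interpreted.  The same frozen model is reused for every
construct and every E_w2 via the exponential form.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any

from scipy.optimize import brentq

from .params import KINESIN1, E_W1_REGIME_MAX, MotorParameters, ParameterError

#: hard regime constraints the calibrated model must satisfy
P_I_MIN = 0.99        # Period-I escape ~certain for all E_w1 <= 18 kBT
P_II_MAX_HIGH_E = 1e-3  # Period-II escape negligible for E_w2 >= 45 kBT

#: the printed fold-increase of kinesin-1 mean run length on raising
#: E_w2 from 39 to >= 45 kBT; the single calibration target.
CALIBRATION_FOLD_CHANGE = 2.3


class CalibrationError(RuntimeError):
    """No attempt rate satisfies the calibration target and regime constraints."""


@dataclass(frozen=True)
class EscapeModel:
    """Arrhenius escape from a binding well of depth E (k_B·T units).

    k_off(E) = attempt_rate · e^(−E).  For a fixed exposure window the
    escape probability is 1 − e^(−k_off·window); when racing an
    exponential exit channel of rate k_exit it is k_off/(k_off + k_exit).
    """

    attempt_rate: float

    def __post_init__(self) -> None:
        if self.attempt_rate < 0:
            raise ParameterError("attempt_rate must be >= 0")

    def k_off(self, energy: float) -> float:
        if energy < 0:
            raise ParameterError("well depth must be >= 0 (k_B T)")
        return self.attempt_rate * math.exp(-energy)

    def p_fixed_window(self, energy: float, window: float) -> float:
        if window <= 0:
            raise ParameterError("window must be > 0 (s)")
        return -math.expm1(-self.k_off(energy) * window)

    def p_race(self, energy: float, exit_rate: float) -> float:
        if exit_rate <= 0:
            raise ParameterError("exit rate must be > 0 (s^-1)")
        k = self.k_off(energy)
        return k / (k + exit_rate)

    # convenience wrappers for the two periods -------------------------
    def p_period_I(self, params: MotorParameters) -> float:
        """Escape probability within t_r from the E_w1 well."""
        return self.p_fixed_window(params.E_w1, params.t_r_s)

    def p_period_II(self, params: MotorParameters) -> float:
        """Escape probability from the E_w2 well before ADP release."""
        return self.p_race(params.E_w2, params.k_D)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "EscapeModel":
        data = json.loads(text)
        unknown = set(data) - {"attempt_rate"}
        if unknown:
            raise ParameterError(f"unknown escape-model keys: {sorted(unknown)}")
        return cls(**data)


def escape_probability(
    energy: float,
    model: EscapeModel,
    *,
    window: float | None = None,
    exit_rate: float | None = None,
) -> float:
    """Escape probability from a well of depth ``energy`` (k_B·T).

    Exactly one of ``window`` (fixed exposure, s) or ``exit_rate``
    (competing exponential exit, s^-1) must be given.
    """
    if (window is None) == (exit_rate is None):
        raise ParameterError("give exactly one of window= or exit_rate=")
    if window is not None:
        return model.p_fixed_window(energy, window)
    return model.p_race(energy, exit_rate)


def check_regime(model: EscapeModel, params: MotorParameters) -> None:
    """Verify the two hard regime constraints; raise on violation."""
    p1 = model.p_fixed_window(E_W1_REGIME_MAX, params.t_r_s)
    if p1 < P_I_MIN:
        raise CalibrationError(
            f"Period-I escape probability {p1:.4g} at E_w1 = "
            f"{E_W1_REGIME_MAX} k_BT is below the required {P_I_MIN}"
        )
    p2 = model.p_race(45.0, params.k_D)
    if p2 > P_II_MAX_HIGH_E:
        raise CalibrationError(
            f"Period-II escape probability {p2:.4g} at E_w2 = 45 k_BT "
            f"exceeds the allowed {P_II_MAX_HIGH_E}"
        )


def calibrate(
    params_k1: MotorParameters,
    fold_change: float = CALIBRATION_FOLD_CHANGE,
) -> EscapeModel:
    """Solve for the attempt rate A from the printed fold-change.

    With p_I the per-INT-passage Period-I occurrence probability and
    p_IIocc the per-step Period-II occurrence probability of the
    kinesin-1 preset, raising E_w2 to >= 45 k_B·T removes essentially the
    whole Period-II term from the per-step dissociation hazard
    p_I·P_I + p_IIocc·P_II.  Requiring the hazard ratio (i.e. the mean
    run length fold-change) to equal ``fold_change`` fixes
    P_II(E_w2 = 39) and hence A.

    The result must also satisfy the regime constraints (P_I ≥ 0.99 at
    E_w1 = 18 k_B·T; P_II ≤ 1e-3 at E_w2 = 45 k_B·T) and the side
    condition that Period II contributes more than Period I for
    kinesin-1; otherwise :class:`CalibrationError` is raised.
    """
    from .engine import p_period_I, p_period_II_occurrence

    if params_k1.family != KINESIN1:
        raise ParameterError("calibration is defined on the kinesin-1 preset")
    if fold_change <= 1.0:
        raise CalibrationError("fold_change must exceed 1")

    p_i = p_period_I(params_k1)
    p_ii_occ = p_period_II_occurrence(params_k1)

    def residual(log10_a: float) -> float:
        m = EscapeModel(attempt_rate=10.0**log10_a)
        return p_ii_occ * m.p_period_II(params_k1) - (fold_change - 1.0) * p_i * m.p_period_I(params_k1)

    lo, hi = 0.0, 40.0
    if residual(lo) > 0 or residual(hi) < 0:
        raise CalibrationError("no attempt rate satisfies the fold-change target")
    log10_a = brentq(residual, lo, hi, xtol=1e-12)
    model = EscapeModel(attempt_rate=10.0**log10_a)

    check_regime(model, params_k1)
    # side condition: Period II dominates kinesin-1 dissociation
    if p_ii_occ * model.p_period_II(params_k1) <= p_i * model.p_period_I(params_k1):
        raise CalibrationError(
            "calibrated model violates the Period-II-dominance condition "
            "for kinesin-1"
        )
    return model


def dissociation_rate(k_I: float, P_I: float, k_II: float, P_II: float) -> float:
    """Overall dissociation rate ε = k_I·P_I + k_II·P_II (s^-1).

    ``k_I`` and ``k_II`` are the occurrence rates of the two weak-binding
    periods (per unit time), ``P_I`` and ``P_II`` the per-exposure escape
    probabilities.
    """
    for name, val in (("k_I", k_I), ("k_II", k_II)):
        if val < 0:
            raise ParameterError(f"{name} must be >= 0")
    for name, val in (("P_I", P_I), ("P_II", P_II)):
        if not 0 <= val <= 1:
            raise ParameterError(f"{name} must lie in [0, 1]")
    return k_I * P_I + k_II * P_II
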