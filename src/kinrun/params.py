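"""Motor parameter sets and simulation configuration.

All energies are carried in units of k_B·T; no absolute temperature is
exposed anywhere.  Rates are s^-1 except ``k_b`` (μM^-1 s^-1) and the
relaxation time ``t_r`` which is stored in μs (its conventional unit in
the kinetics literature).  The lattice spacing ``step_d`` is the 8-nm
tubulin repeat along a protofilament.

Two families are supported:

``kinesin1``
    A constitutive dimer.  The microtubule-bound head in the
    one-head-bound intermediate (INT) state is catalytically active from
    t = 0, so runs terminate with a constant per-step hazard and the run
    length distribution is single-exponential.

``kinesin3``
    A cargo-dimerized motor (KIF1/KIF13/KIF16 type).  Until the neck-coil
    coiled-coil has fully zipped (the Gamma-distributed dimerization time
    τ, see :mod:`kinrun.clock`), the INT-state ATPase of the bound head is
    inhibited, which suppresses the dominant dissociation pathway and
    produces superprocessive runs with a Gaussian-like run length
    distribution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from typing import Any

KINESIN1 = "kinesin1"
KINESIN3 = "kinesin3"
FAMILIES = (KINESIN1, KINESIN3)

#: maximum admissible depth (k_B·T) of the locally perturbed binding well;
#: above this the near-certain Period-I escape regime no longer holds.
E_W1_REGIME_MAX = 18.0

VARIANTS = ("l8_mutant", "kif1a_393", "kloop_swap", "ew2_enhanced_k1")


class ParameterError(ValueError):
    """Raised for invalid or out-of-regime parameter values."""


@dataclass(frozen=True)
class MotorParameters:
    """Kinetic and energetic constants for one motor construct.

    Attributes
    ----------
    family:
        ``"kinesin1"`` or ``"kinesin3"``; controls whether the
        dimerization clock gates the INT-state ATPase.
    t_r:
        Relaxation time of the locally weakened binding site, μs.
    E_w1:
        ADP-head affinity for the just-vacated, still-perturbed site
        (k_B·T).  Must be ≤ 18 k_B·T (Period-I escape ~certain regime).
    E_w2:
        ADP-head affinity for unperturbed sites (k_B·T).
    E_NL:
        Neck-linker docking free energy / backward barrier (k_B·T).
    E_I1, E_I2:
        Head–head binding energy with the bound head's neck linker
        undocked / docked (k_B·T).  Used only by the Brownian validation
        layer.
    k_NL:
        Neck-linker docking rate in the INT state (s^-1), ATP/ADP.Pi
        states of the bound head only.
    k_c:
        Lumped ATP hydrolysis + Pi release rate of the trailing head
        (forward neck-linker orientation), s^-1.
    rho:
        Suppression factor ≥ 1 for heads without the forward neck-linker
        orientation: leading-head and INT-state rates are ``k_c / rho``.
    k_D:
        Microtubule-stimulated ADP release rate, s^-1.
    k_b:
        Second-order ATP binding rate, μM^-1 s^-1.
    k_cc:
        Overall coiled-coil formation rate (kinesin-3 only), s^-1;
        1/k_cc is the mean full-zipper time.  ``None`` for kinesin-1.
    n_stages:
        Number of rate-limiting zipper stages n ≥ 1 (kinesin-3 only);
        each stage proceeds at k_0 = n·k_cc.
    step_d:
        Binding-site spacing along a protofilament, nm.
    int_atpase_active_at_start:
        If True, the INT-state ATPase is active from t = 0 (KIF1A(1–393)
        -like construct, or clock disrupted by backward load).
    """

    family: str
    t_r: float = 10.0
    E_w1: float = 18.0
    E_w2: float = 39.0
    E_NL: float = 5.0
    E_I1: float = 40.0
    E_I2: float = 20.0
    k_NL: float = 800.0
    k_c: float = 140.0
    rho: float = 40.0
    k_D: float = 350.0
    k_b: float = 2.0
    k_cc: float | None = None
    n_stages: int = 1
    step_d: float = 8.0
    int_atpase_active_at_start: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(
                f"unknown motor family {self.family!r}; expected one of {FAMILIES}"
            )
        for name in ("t_r", "k_NL", "k_c", "k_D", "k_b"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("E_w1", "E_w2", "E_NL", "E_I1", "E_I2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0 (k_B T units)")
        if self.rho < 1:
            raise ParameterError(f"rho must be >= 1, got {self.rho}")
        if self.n_stages < 1 or int(self.n_stages) != self.n_stages:
            raise ParameterError(f"n_stages must be an integer >= 1, got {self.n_stages}")
        if self.step_d <= 0:
            raise ParameterError(f"step_d must be > 0, got {self.step_d}")
        if self.E_w1 > E_W1_REGIME_MAX:
            raise ParameterError(
                f"E_w1 = {self.E_w1} k_BT is outside the model regime: the "
                f"near-certain Period-I escape assumption requires "
                f"E_w1 <= {E_W1_REGIME_MAX} k_BT"
            )
        if self.k_cc is not None and self.k_cc <= 0:
            raise ParameterError(f"k_cc must be > 0 when set, got {self.k_cc}")
        if self.family == KINESIN3 and self.k_cc is None:
            raise ParameterError("kinesin3 parameters require k_cc")

    # -- derived rates ----------------------------------------------------
    @property
    def k_c_lead(self) -> float:
        """Hydrolysis + Pi release rate of a head without forward NL orientation."""
        return self.k_c / self.rho

    @property
    def k0(self) -> float:
        """Per-stage zipper rate k_0 = n·k_cc (kinesin-3 only)."""
        if self.k_cc is None:
            raise ParameterError("k0 is undefined without k_cc")
        return self.n_stages * self.k_cc

    @property
    def t_r_s(self) -> float:
        """Relaxation time in seconds."""
        return self.t_r * 1e-6

    @property
    def clock_gated(self) -> bool:
        """Whether the INT-state ATPase waits on the dimerization clock."""
        return self.family == KINESIN3 and not self.int_atpase_active_at_start

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "MotorParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "MotorParameters":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one batch of simulated traces.

    ``atp_concentration`` is in μM (so ``k_b * atp_concentration`` is the
    first-order ATP binding rate in s^-1), ``load_F`` is a backward load
    in pN applied to the cargo, and ``lambda_NL`` the fold-reduction of
    the neck-linker docking rate under that load.  ``max_sim_time`` (s)
    is a safety cap; traces hitting it are flagged and excluded from
    run-length statistics.
    """

    atp_concentration: float = 2000.0
    load_F: float = 0.0
    lambda_NL: float = 1.0
    n_traces: int = 500
    rng_seed: int = 0
    max_sim_time: float = 300.0

    def __post_init__(self) -> None:
        if self.atp_concentration <= 0:
            raise ParameterError("atp_concentration must be > 0 (μM)")
        if self.load_F < 0:
            raise ParameterError("load_F must be >= 0 (backward load, pN)")
        if self.lambda_NL < 1:
            raise ParameterError("lambda_NL must be >= 1")
        if self.n_traces < 1:
            raise ParameterError("n_traces must be >= 1")
        if self.max_sim_time <= 0:
            raise ParameterError("max_sim_time must be > 0 (s)")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(json.loads(text))


def default_parameters(family: str) -> MotorParameters:
    """Return the standard parameter preset for a motor family.

    Kinesin-3's E_w2 defaults to 45 k_B·T, the lower bound of the regime
    in which results are insensitive to it; E_NL defaults to 5 k_B·T and
    E_I1/E_I2 to their threshold values 40/20 k_B·T.
    """
    if family == KINESIN1:
        return MotorParameters(
            family=KINESIN1,
            t_r=10.0,
            E_w1=18.0,
            E_w2=39.0,
            k_NL=800.0,
            k_c=140.0,
            rho=40.0,
            k_D=350.0,
            k_b=2.0,
        )
    if family == KINESIN3:
        return MotorParameters(
            family=KINESIN3,
            t_r=10.0,
            E_w1=18.0,
            E_w2=45.0,
            k_NL=3400.0,
            k_c=270.0,
            rho=20.0,
            k_D=350.0,
            k_b=2.0,
            k_cc=0.17,
            n_stages=10,
        )
    raise ParameterError(f"unknown motor family {family!r}; expected one of {FAMILIES}")


def preset_variant(base: MotorParameters, variant: str) -> MotorParameters:
    """Return a copy of ``base`` with one documented construct change.

    ``l8_mutant``
        Loop-8 mutant emulation on a kinesin-3 base: microtubule affinity
        of the ADP head lowered to E_w2 = 39 k_B·T.
    ``kif1a_393``
        KIF1A(1–393)-like construct on a kinesin-3 base: unstable neck
        coil, so the INT-state ATPase is active from t = 0.
    ``kloop_swap``
        K-loop swapped for the kinesin-1 loop on a kinesin-3 base:
        E_w2 = 40.5 k_B·T.
    ``ew2_enhanced_k1``
        Kinesin-1 with its ADP-head microtubule affinity raised to the
        kinesin-3 level, E_w2 = 45 k_B·T.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    required = KINESIN1 if variant == "ew2_enhanced_k1" else KINESIN3
    if base.family != required:
        raise ParameterError(
            f"variant {variant!r} applies to a {required} base, got {base.family}"
        )
    if variant == "l8_mutant":
        return replace(base, E_w2=39.0)
    if variant == "kif1a_393":
        return replace(base, int_atpase_active_at_start=True)
    if variant == "kloop_swap":
        return replace(base, E_w2=40.5)
    return replace(base, E_w2=45.0)  # ew2_enhanced_k1
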