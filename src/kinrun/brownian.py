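"""Overdamped 2-D Brownian dynamics: validation of event-level assumptions.

This layer never produces headline numbers.  It integrates a single
kinesin head as an overdamped Langevin particle in a piecewise potential
(truncated Gaussian wells and barrier bumps — a documented stand-in for
the detailed well shapes, which are not reproduced here) and checks,
qualitatively, the assumptions the event engine makes:

* free diffusion over the 8-nm site spacing and the 10-nm dissociation
  threshold is microseconds — far below every chemical dwell time, so
  treating the mechanical substeps as instantaneous is sound;
* escape from shallow wells within a fixed window decreases
  monotonically with well depth, the ordering the Arrhenius escape model
  assumes (deep wells, ≥ 18 k_B·T, are far outside the reachable BD
  timescale and are covered by the calibrated escape model only);
* the neck-linker docking barrier E_NL suppresses backward re-binding of
  the tethered head.

Coordinates are nm along the protofilament (x) and off the filament
(y); energies k_B·T; times s.  The drag coefficient comes from Stokes'
law for a 4-nm-radius sphere in water, which only sets the validation
timescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError

# Stokes drag for a 4 nm sphere in water (eta = 1e-3 Pa s):
# gamma = 6*pi*eta*r = 7.54e-11 kg/s;  D = kBT/gamma at ~295 K.
_KBT_J = 4.1e-21
_GAMMA = 6.0 * math.pi * 1.0e-3 * 4.0e-9
DIFFUSION_NM2_S = _KBT_J / _GAMMA * 1e18   # ~5.4e7 nm^2/s

#: off-filament distance beyond which the head counts as dissociated
DISSOCIATION_Y_NM = 10.0

#: largest admissible integrator step (s)
MAX_DT = 1e-9


@dataclass(frozen=True)
class PotentialField:
    """Sum of Gaussian wells/bumps plus optional harmonic confinement.

    ``gaussians`` holds (amplitude kBT, x0 nm, y0 nm, sigma nm) terms —
    negative amplitudes are binding wells, positive ones barriers.
    ``x_ridges`` holds (amplitude, x0, sigma) terms uniform in y, used
    for barriers that cannot be circumvented off-axis (the neck-linker
    docking barrier).  ``k_y`` confines the head to the filament axis;
    ``k_harm`` is an isotropic tether (used for the equipartition check).
    """

    gaussians: tuple[tuple[float, float, float, float], ...] = ()
    x_ridges: tuple[tuple[float, float, float], ...] = ()
    k_y: float = 0.0          # kBT / nm^2
    k_harm: float = 0.0       # kBT / nm^2

    def energy(self, pos: np.ndarray) -> np.ndarray:
        x, y = pos[..., 0], pos[..., 1]
        u = 0.5 * self.k_y * y**2 + 0.5 * self.k_harm * (x**2 + y**2)
        for a, x0, y0, s in self.gaussians:
            u = u + a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s**2))
        for a, x0, s in self.x_ridges:
            u = u + a * np.exp(-((x - x0) ** 2) / (2 * s**2))
        return u

    def grad(self, pos: np.ndarray) -> np.ndarray:
        x, y = pos[..., 0], pos[..., 1]
        gx = self.k_harm * x
        gy = self.k_y * y + self.k_harm * y
        for a, x0, y0, s in self.gaussians:
            g = a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s**2)) / s**2
            gx = gx - g * (x - x0)
            gy = gy - g * (y - y0)
        for a, x0, s in self.x_ridges:
            gx = gx - a * np.exp(-((x - x0) ** 2) / (2 * s**2)) / s**2 * (x - x0)
        return np.stack([gx, gy], axis=-1)


def _check_dt(dt: float) -> None:
    if dt <= 0 or dt > MAX_DT:
        raise ParameterError(f"dt must satisfy 0 < dt <= {MAX_DT} s for stability")


def _heun_step(pos: np.ndarray, f: PotentialField, dt: float,
               rng: np.random.Generator) -> np.ndarray:
    """One stochastic Runge–Kutta (Heun) step of dx = -D ∇U dt + √(2D dt) ξ."""
    noise = math.sqrt(2 * DIFFUSION_NM2_S * dt) * rng.standard_normal(pos.shape)
    drift0 = -DIFFUSION_NM2_S * f.grad(pos)
    predictor = pos + drift0 * dt + noise
    drift1 = -DIFFUSION_NM2_S * f.grad(predictor)
    return pos + 0.5 * (drift0 + drift1) * dt + noise


def integrate(
    position,
    fieldspec: PotentialField,
    dt: float,
    duration: float,
    rng: np.random.Generator,
    n_particles: int = 1,
) -> np.ndarray:
    """Integrate trajectories; returns array (n_steps+1, n_particles, 2).

    ``position`` is the common starting point (x, y) in nm.  Intended for
    first-passage analysis on sub-millisecond windows only.
    """
    _check_dt(dt)
    if duration > 1e-3:
        raise ParameterError("duration > 1 ms is outside the validation scale")
    n_steps = int(round(duration / dt))
    pos = np.broadcast_to(np.asarray(position, float), (n_particles, 2)).copy()
    out = np.empty((n_steps + 1, n_particles, 2))
    out[0] = pos
    for i in range(n_steps):
        pos = _heun_step(pos, fieldspec, dt, rng)
        out[i + 1] = pos
    return out


def escape_fraction(
    depth: float,
    window: float,
    rng: np.random.Generator,
    n_trials: int = 1000,
    sigma: float = 1.5,
    dt: float = 1e-9,
) -> float:
    """Fraction of heads leaving a well of the given depth within ``window``.

    The head starts at the bottom of a radially symmetric Gaussian well
    of depth ``depth`` (k_B·T) and counts as escaped once |y| exceeds the
    10-nm dissociation threshold.  Only the shallow-depth ordering is
    meaningful at BD timescales.
    """
    _check_dt(dt)
    if n_trials < 100:
        raise ParameterError("n_trials must be >= 100")
    f = PotentialField(gaussians=((-abs(depth), 0.0, 0.0, sigma),))
    pos = np.zeros((n_trials, 2))
    alive = np.ones(n_trials, dtype=bool)
    n_steps = int(round(window / dt))
    for _ in range(n_steps):
        pos[alive] = _heun_step(pos[alive], f, dt, rng)
        alive &= np.abs(pos[:, 1]) < DISSOCIATION_Y_NM
        if not alive.any():
            break
    return 1.0 - alive.mean()


def forward_binding_time(
    rng: np.random.Generator,
    n_trials: int = 500,
    e_nl: float = 5.0,
    head_attraction: float = 2.0,
    well_depth: float = 6.0,
    site_spacing: float = 8.0,
    dt: float = 1e-9,
    max_time: float = 5e-5,
) -> dict:
    """First-passage of the tethered ADP head to the forward binding site.

    The head starts at the INT position (x = 0) between binding wells at
    ±``site_spacing`` nm, held by a residual head–head attraction of
    ``head_attraction`` k_B·T (the docked-neck-linker, weakened-contact
    regime), with a barrier of height ``e_nl`` placed between the INT
    position and the rearward site.  Returns arrival times and the
    forward/backward split; with e_nl ≥ 4 k_B·T the backward fraction
    must be small.
    """
    _check_dt(dt)
    d = site_spacing
    terms = [(-abs(well_depth), d, 0.0, 1.5), (-abs(well_depth), -d, 0.0, 1.5)]
    if head_attraction > 0:
        terms.append((-abs(head_attraction), 0.0, 0.0, 1.5))
    ridges = ((abs(e_nl), -d / 2, 1.2),) if e_nl > 0 else ()
    f = PotentialField(gaussians=tuple(terms), x_ridges=ridges, k_y=0.5)

    pos = np.zeros((n_trials, 2))
    t_arr = np.full(n_trials, np.nan)
    forward = np.zeros(n_trials, dtype=bool)
    alive = np.ones(n_trials, dtype=bool)
    n_steps = int(round(max_time / dt))
    thresh = d - 0.5
    for i in range(n_steps):
        pos[alive] = _heun_step(pos[alive], f, dt, rng)
        arrived_f = alive & (pos[:, 0] >= thresh)
        arrived_b = alive & (pos[:, 0] <= -thresh)
        for mask, is_fwd in ((arrived_f, True), (arrived_b, False)):
            t_arr[mask] = (i + 1) * dt
            forward[mask] = is_fwd
        alive &= ~(arrived_f | arrived_b)
        if not alive.any():
            break
    done = ~np.isnan(t_arr)
    n_done = int(done.sum())
    return {
        "first_passage_times": t_arr[done],
        "median_fpt": float(np.median(t_arr[done])) if n_done else math.nan,
        "forward_fraction": float(forward[done].mean()) if n_done else math.nan,
        "backward_fraction": float((~forward[done]).mean()) if n_done else math.nan,
        "unresolved_fraction": 1.0 - n_done / n_trials,
    }
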