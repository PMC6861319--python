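"""Aggregate trace statistics, distribution fits and shape classification.

Run lengths and velocities are summarized from raw per-trace values
(histograms are for display only and never feed the statistics).  Run
length distributions are fit by maximum likelihood under two competing
models — single-exponential, the generic expectation for a processive
motor with a constant dissociation hazard, and Gaussian, the signature
of dissociation gated by the multi-stage dimerization clock — and the
shape verdict is the model with the lower AIC, ties going to the
exponential null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .engine import Trace
from .params import ParameterError

EXPONENTIAL = "exponential"
GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one candidate run-length distribution."""

    model: str
    parameters: dict[str, float]
    log_likelihood: float
    aic: float


@dataclass(frozen=True)
class RunSummary:
    """Statistics over the non-capped traces of one condition."""

    n_traces: int
    n_capped: int
    mean_run_length: float      # nm
    sem_run_length: float       # nm
    cv_run_length: float
    mean_velocity: float        # nm/s
    sem_velocity: float         # nm/s
    mean_detachment_time: float  # s
    k_d: float                  # s^-1, 1 / mean detachment time
    k_d_alt: float              # s^-1, mean velocity / mean run length
    hist_edges: tuple[float, ...]
    hist_counts: tuple[int, ...]


def summarize(traces: Iterable[Trace], n_bins: int = 20) -> RunSummary:
    """Aggregate a batch of traces; capped traces are excluded and counted."""
    traces = list(traces)
    kept = [t for t in traces if not t.capped]
    n_capped = len(traces) - len(kept)
    if len(kept) < 2:
        raise ParameterError(
            f"need at least 2 non-capped traces to summarize "
            f"({len(kept)} kept, {n_capped} capped)"
        )
    runs = np.array([t.run_length for t in kept])
    vels = np.array([t.velocity for t in kept])
    times = np.array([t.total_time for t in kept])
    n = len(kept)
    mean_run = float(runs.mean())
    sd_run = float(runs.std(ddof=1))
    mean_v = float(vels.mean())
    mean_t = float(times.mean())
    counts, edges = np.histogram(runs, bins=n_bins)
    return RunSummary(
        n_traces=n,
        n_capped=n_capped,
        mean_run_length=mean_run,
        sem_run_length=sd_run / math.sqrt(n),
        cv_run_length=sd_run / mean_run if mean_run > 0 else math.nan,
        mean_velocity=mean_v,
        sem_velocity=float(vels.std(ddof=1)) / math.sqrt(n),
        mean_detachment_time=mean_t,
        k_d=1.0 / mean_t,
        k_d_alt=mean_v / mean_run if mean_run > 0 else math.nan,
        hist_edges=tuple(edges),
        hist_counts=tuple(int(c) for c in counts),
    )


def _as_array(runs: Sequence[float], minimum: int) -> np.ndarray:
    x = np.asarray(runs, dtype=float)
    if x.ndim != 1 or x.size < minimum:
        raise ParameterError(f"need at least {minimum} values, got {x.size}")
    return x


def fit_exponential(runs: Sequence[float]) -> FitResult:
    """MLE exponential fit: rate = 1/mean; AIC = 2 - 2 logL."""
    x = _as_array(runs, 10)
    if np.any(x <= 0):
        raise ParameterError("exponential fit requires strictly positive values")
    rate = 1.0 / x.mean()
    loglik = x.size * math.log(rate) - rate * float(x.sum())
    return FitResult(EXPONENTIAL, {"rate": rate}, loglik, 2.0 * 1 - 2.0 * loglik)


def fit_gaussian(runs: Sequence[float]) -> FitResult:
    """MLE Gaussian fit (n-denominator SD); AIC = 4 - 2 logL."""
    x = _as_array(runs, 10)
    mu = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd <= 0:
        raise ParameterError("gaussian fit requires non-degenerate values")
    loglik = float(-0.5 * x.size * math.log(2 * math.pi * sd**2)
                   - 0.5 * np.sum((x - mu) ** 2) / sd**2)
    return FitResult(GAUSSIAN, {"mean": mu, "sd": sd}, loglik, 2.0 * 2 - 2.0 * loglik)


def classify_shape(runs: Sequence[float]) -> str:
    """AIC verdict between the exponential and Gaussian run-length models.

    Ties break toward the exponential, the null form expected for a
    motor with a constant per-step dissociation probability.  Runs with
    non-positive displacement (dissociation before the first completed
    step) lie outside the exponential support and are excluded from the
    comparison so both likelihoods see the same sample; at least 100
    positive values must remain.
    """
    x = np.asarray(runs, dtype=float)
    x = x[x > 0]
    x = _as_array(x, 100)
    gauss = fit_gaussian(x)  # raises on zero variance
    expo = fit_exponential(x)
    return EXPONENTIAL if expo.aic <= gauss.aic else GAUSSIAN


def run_lengths(traces: Iterable[Trace]) -> np.ndarray:
    """Run lengths (nm) of the non-capped traces."""
    return np.array([t.run_length for t in traces if not t.capped])


def velocities(traces: Iterable[Trace]) -> np.ndarray:
    """Velocities (nm/s) of the non-capped traces."""
    return np.array([t.velocity for t in traces if not t.capped])
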