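"""Directed coupling measures between ROI time courses.

Two measures are computed, both directed and both bounded in [0, 1]:

* the directed phase lag index (dPLI): the fraction of samples at which
  one signal's instantaneous phase leads another's,

      dPLI_xy = (1/N) * sum_t H(wrap(phi_x(t) - phi_y(t))),

  with H the Heaviside step (H(0) = 1/2 by convention here, which keeps
  the complement identity dPLI_xy + dPLI_yx = 1 exact when zero
  differences occur in finite precision).  dPLI_xy > 0.5 means x leads y;
  0.5 is the no-consistent-lead value.  Because it only looks at the sign
  of the phase difference, dPLI is insensitive to instantaneous (zero
  phase lag) linear leakage between reconstructed sources.

* the normalized modulation index (nMI) for phase-amplitude coupling:

      nMI_xy = (1/sqrt(N)) * |sum_t a_y(t) * exp(i phi_x(t))|
                              / sqrt(sum_t a_y(t)^2),

  where phi_x is the low-frequency (high-theta) phase of region x and a_y
  the high-frequency (gamma) amplitude envelope of region y.  nMI is in
  [0, 1] by Cauchy-Schwarz and invariant to positive rescaling of the
  amplitude.  The direction x -> y reads "the phase of x is coupled to
  the amplitude of y"; it carries no causal meaning.  The diagonal
  (x -> x, local coupling within a region) is meaningful and computed.

Because both measures live in (0, 1), group statistics are run on the
logit scale, log(p / (1-p)), which maps 0.5 to 0; on that scale a dPLI
matrix is anti-symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import AnalyticSeries, wrap_phase

logger = logging.getLogger(__name__)


def dpli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Directed phase lag index between two instantaneous-phase series.

    Phase differences are wrapped to (-pi, pi] before the sign test;
    exactly-zero differences count 1/2.
    """
    phase_x = np.asarray(phase_x, dtype=float).ravel()
    phase_y = np.asarray(phase_y, dtype=float).ravel()
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size == 0:
        raise ValueError("dPLI of empty series is undefined")
    d = wrap_phase(phase_x - phase_y)
    return float(np.mean(np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))))


def dpli_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs dPLI for an (n_roi, n_samples) phase array.

    Every ordered off-diagonal pair is evaluated from the definition (the
    complement identity M + M.T = 1 is a checked property of the result,
    not baked in).  The diagonal is undefined and set to NaN.
    """
    phases = np.asarray(phases, dtype=float)
    n_roi, n = phases.shape
    if n == 0:
        raise ValueError("dPLI of empty series is undefined")
    out = np.full((n_roi, n_roi), np.nan)
    for i in range(n_roi):
        for j in range(n_roi):
            if i != j:
                out[i, j] = dpli(phases[i], phases[j])
    return out


def nmi(phase_lo: np.ndarray, amp_hi: np.ndarray) -> float:
    """Normalized modulation index between a low-frequency phase series
    and a high-frequency amplitude envelope."""
    phase_lo = np.asarray(phase_lo, dtype=float).ravel()
    amp_hi = np.asarray(amp_hi, dtype=float).ravel()
    if phase_lo.shape != amp_hi.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if phase_lo.size == 0:
        raise ValueError("nMI of empty series is undefined")
    if np.any(amp_hi < 0):
        raise ValueError("amplitude envelope must be non-negative")
    denom = np.sqrt(np.sum(amp_hi**2))
    if denom == 0:
        raise ValueError("amplitude envelope is identically zero")
    n = phase_lo.size
    return float(
        np.abs(np.sum(amp_hi * np.exp(1j * phase_lo))) / (np.sqrt(n) * denom)
    )


def nmi_matrix(phase_lo: np.ndarray, amp_hi: np.ndarray) -> np.ndarray:
    """All ordered pairs of nMI, diagonal (local coupling) included.

    ``phase_lo`` and ``amp_hi`` are (n_roi, n_samples) and must be
    sample-aligned.  Entry [x, y] couples the phase of region x (row) to
    the amplitude of region y (column).
    """
    phase_lo = np.asarray(phase_lo, dtype=float)
    amp_hi = np.asarray(amp_hi, dtype=float)
    if phase_lo.shape != amp_hi.shape:
        raise ValueError("phase and amplitude arrays must share shape")
    if np.any(amp_hi < 0):
        raise ValueError("amplitude envelope must be non-negative")
    n = phase_lo.shape[1]
    if n == 0:
        raise ValueError("nMI of empty series is undefined")
    denom = np.sqrt(n) * np.sqrt(np.sum(amp_hi**2, axis=1))
    if np.any(denom == 0):
        raise ValueError("amplitude envelope is identically zero for some ROI")
    num = np.abs(np.exp(1j * phase_lo) @ amp_hi.T)  # [x, y]
    return num / denom[np.newaxis, :]


def logit(
    matrix: np.ndarray,
    n_samples: int | None = None,
    eps: float | None = None,
) -> np.ndarray:
    """Element-wise logit, log(p / (1-p)), for matrices of values in (0, 1).

    Finite-sample dPLI can saturate at exactly 0 or 1; such entries are
    clipped to [eps, 1-eps] with eps = 1/(2*n_samples) by default, which
    keeps the transform finite without reordering values.  Clipping is
    logged.  NaN entries (the undefined dPLI diagonal) pass through.
    """
    matrix = np.asarray(matrix, dtype=float)
    if eps is None:
        if n_samples is None:
            eps = np.finfo(float).tiny
        else:
            eps = 1.0 / (2.0 * n_samples)
    finite = np.isfinite(matrix)
    if np.any((matrix[finite] < 0) | (matrix[finite] > 1)):
        raise ValueError("logit expects values in [0, 1]")
    n_clip = int(np.sum(finite & ((matrix <= eps) | (matrix >= 1 - eps))))
    if n_clip:
        logger.info("logit: clipped %d saturated entries to eps=%g", n_clip, eps)
    p = np.clip(matrix, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


@dataclass
class ConnectivityMatrix:
    """A directed n_roi x n_roi coupling matrix with its provenance tags."""

    values: np.ndarray
    measure: str  # "dpli_theta" | "dpli_gamma" | "nmi"
    scale: str = "raw"  # "raw" | "logit"
    subject: int | None = None
    condition: str | None = None
    n_samples: int | None = None

    def to_logit(self) -> "ConnectivityMatrix":
        if self.scale != "raw":
            raise ValueError("matrix is already on the logit scale")
        return ConnectivityMatrix(
            values=logit(self.values, n_samples=self.n_samples),
            measure=self.measure,
            scale="logit",
            subject=self.subject,
            condition=self.condition,
            n_samples=self.n_samples,
        )


def connectivity_matrices(
    theta: AnalyticSeries,
    gamma: AnalyticSeries,
    subject: int | None = None,
    condition: str | None = None,
) -> dict[str, ConnectivityMatrix]:
    """The per-subject, per-condition matrix set: dPLI in the theta and
    gamma bands and theta-phase -> gamma-amplitude nMI.

    ``theta`` and ``gamma`` hold pooled clean analytic samples shaped
    (n_samples, n_roi).  For the nMI the two bands must be sample-aligned
    (same clean segments, same edge trim), hence equal lengths.
    """
    th_phase = np.atleast_2d(theta.phase.T)
    ga_phase = np.atleast_2d(gamma.phase.T)
    ga_amp = np.atleast_2d(gamma.amplitude.T)
    if th_phase.shape[0] != ga_phase.shape[0]:
        raise ValueError("theta and gamma series must cover the same ROIs")
    if th_phase.shape[1] != ga_amp.shape[1]:
        raise ValueError(
            "theta phase and gamma amplitude must be sample-aligned for nMI"
        )
    out = {}
    for measure, values, n in (
        ("dpli_theta", dpli_matrix(th_phase), th_phase.shape[1]),
        ("dpli_gamma", dpli_matrix(ga_phase), ga_phase.shape[1]),
        ("nmi", nmi_matrix(th_phase, ga_amp), th_phase.shape[1]),
    ):
        out[measure] = ConnectivityMatrix(
            values=values,
            measure=measure,
            subject=subject,
            condition=condition,
            n_samples=n,
        )
    return out
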