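"""Migration-model analysis for subdivided populations under strong migration.

Strong migration (a fixed, irreducible, aperiodic backward migration matrix M
whose rates do not scale with N) makes differences between subpopulation
gamete frequencies vanish on the diffusion time scale.  What remains of the
subdivision is a single scalar: the effective-size factor

    delta = [ sum_alpha xi_alpha^2 / q'_alpha ]^(-1),        N_e = delta * N,

where xi is the stationary distribution of M and q'_alpha the subpopulation
size fractions.  delta <= 1 with equality exactly for conservative migration
(sum_alpha q'_alpha m_alpha_beta = q'_beta).  Holding the per-generation
rates fixed, the population-scaled parameters for the combined, effectively
panmictic population are therefore (theta * delta, rho * delta), and a sample
spread over demes is scored as its elementwise combined sample.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._markov import check_primitive, check_stochastic
from ._markov import stationary_distribution as _stationary
from .exceptions import ParameterError, ValidationError
from .models import MigrationModel, SampleConfig, SubdividedSample

__all__ = [
    "stationary_distribution",
    "delta_factor",
    "effective_params",
    "EffectiveParams",
    "is_conservative",
    "combine_samples",
    "weighted_mean_and_deviation",
]


def stationary_distribution(M) -> np.ndarray:
    """Stationary distribution xi of an irreducible aperiodic stochastic matrix."""
    return _stationary(M, check=True)


def _check_prob_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ParameterError(f"{name} must be a 1-D probability vector")
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ParameterError(f"{name} must be non-negative and sum to 1")
    return x


def delta_factor(xi, q_prime) -> float:
    """Effective-size factor delta = [sum_alpha xi_alpha^2 / q'_alpha]^(-1).

    Always in (0, 1] by Cauchy-Schwarz, with delta = 1 iff xi = q'.
    """
    xi = _check_prob_vector(xi, "xi")
    q = _check_prob_vector(q_prime, "q_prime")
    if xi.shape != q.shape:
        raise ParameterError("xi and q_prime must have the same length")
    if np.any(q <= 0):
        raise ParameterError("q_prime entries must be strictly positive")
    delta = float(1.0 / np.sum(xi**2 / q))
    if delta > 1.0 + 1e-9:
        raise ParameterError(f"delta {delta!r} exceeds 1; inputs are inconsistent")
    if abs(delta - 1.0) < 1e-12:  # exact equality case (xi = q'), up to rounding
        delta = 1.0
    return delta


def effective_params(theta: float, rho: float, delta: float) -> tuple[float, float]:
    """Rescale reference (theta, rho) at N_e = N to the subdivided population.

    The per-generation rates u_0, r_0 are held fixed (calibrated so that
    theta = 4*N*u_0 and rho = 4*N*r_0); substructure replaces N_e = N by
    N_e = delta*N, so both scaled rates simply multiply by delta.
    """
    if not (0 < delta <= 1):
        raise ParameterError(f"delta must lie in (0, 1], got {delta!r}")
    if theta < 0 or rho < 0:
        raise ParameterError("theta and rho must be non-negative")
    return theta * delta, rho * delta


def is_conservative(mig: MigrationModel, tol: float = 1e-10) -> bool:
    """True iff sum_alpha q'_alpha m_alpha_beta = q'_beta for all beta."""
    return bool(np.max(np.abs(mig.q_prime @ mig.M - mig.q_prime)) <= tol)


@dataclass(frozen=True)
class EffectiveParams:
    """Population-scaled parameters implied by a migration model.

    ``theta_A``, ``theta_B`` and ``rho`` are the effective scaled rates
    (reference values times delta); ``N_e = delta * N`` when a census size N
    is supplied.
    """

    delta: float
    theta_A: float
    theta_B: float
    rho: float
    N_e: float | None = None

    @classmethod
    def from_migration(cls, mig: MigrationModel, theta_A: float, theta_B: float,
                       rho: float, N: float | None = None) -> "EffectiveParams":
        delta = mig.delta
        tA, r = effective_params(theta_A, rho, delta)
        tB, _ = effective_params(theta_B, rho, delta)
        return cls(delta=delta, theta_A=tA, theta_B=tB, rho=r,
                   N_e=None if N is None else delta * N)


def combine_samples(sample: SubdividedSample) -> SampleConfig:
    """Elementwise combined sample over demes: a_i = sum_alpha a_alpha_i, etc."""
    if not isinstance(sample, SubdividedSample):
        sample = SubdividedSample(tuple(sample))
    a = np.sum([s.a_vec for s in sample.configs], axis=0)
    b = np.sum([s.b_vec for s in sample.configs], axis=0)
    c = np.sum([s.c_mat for s in sample.configs], axis=0)
    return SampleConfig(a, b, c)


def weighted_mean_and_deviation(freqs, xi) -> tuple[np.ndarray, np.ndarray]:
    """xi-weighted mean frequencies P_ij and per-deme deviations d_alpha_ij.

    ``freqs`` has shape (Gamma, r_A, r_B) with each deme's slice on the
    simplex.  Returns (P, d) with P = sum_alpha xi_alpha * P_alpha and
    d_alpha = P_alpha - P, so sum_alpha xi_alpha * d_alpha = 0 exactly.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 3:
        raise ValidationError("freqs must have shape (Gamma, r_A, r_B)")
    xi = _check_prob_vector(xi, "xi")
    if xi.size != freqs.shape[0]:
        raise ParameterError("xi length must match the number of demes")
    sums = freqs.reshape(freqs.shape[0], -1).sum(axis=1)
    if np.any(freqs < -1e-9) or np.max(np.abs(sums - 1.0)) > 1e-9:
        raise ValidationError("each deme's frequencies must lie on the simplex")
    P = np.tensordot(xi, freqs, axes=(0, 0))
    d = freqs - P[None, :, :]
    return P, d
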