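"""Domain types shared by the exact solver and the forward simulator.

The two-locus model follows the classical finite-alleles neutral setup: locus
A with r_A alleles and locus B with r_B alleles, population-scaled mutation
rates theta = 4 N_e u per locus with row-stochastic mutation transition
matrices, and a population-scaled recombination rate rho = 4 N_e r.  Sample
configurations count gametes typed at locus A only (vector a), at locus B
only (vector b), or at both loci (matrix c).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._markov import check_primitive, check_stochastic, stationary_distribution
from .exceptions import ParameterError, ValidationError

__all__ = [
    "MutationModel",
    "TwoLocusParams",
    "SampleConfig",
    "SubdividedSample",
    "MigrationModel",
    "make_symmetric_diallelic",
    "validate_sample",
    "random_inputs",
]

_TOL = 1e-12


def _frozen_array(values, name: str) -> np.ndarray:
    arr = np.array(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} has non-finite entries")
    arr.setflags(write=False)
    return arr


def _check_distribution(pi: np.ndarray, name: str, tol: float = 1e-9) -> None:
    if np.any(pi < 0):
        raise ParameterError(f"{name} has negative entries")
    if abs(pi.sum() - 1.0) > tol:
        raise ParameterError(f"{name} must sum to 1 (got {pi.sum()!r})")


@dataclass(frozen=True)
class MutationModel:
    """Finite-alleles mutation model for the two loci.

    Parameters
    ----------
    theta_A, theta_B
        Population-scaled mutation rates 4*N_e*u at locus A and B (> 0).
    P_A, P_B
        Row-stochastic mutation transition matrices; entry [k, i] is the
        probability that a mutating allele k becomes allele i.  Diagonal
        entries must be strictly positive.
    pi_A, pi_B
        Optional stationary distributions of P_A and P_B; computed if omitted.
    """

    theta_A: float
    theta_B: float
    P_A: np.ndarray
    P_B: np.ndarray
    pi_A: np.ndarray | None = None
    pi_B: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("theta_A", "theta_B"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(f"{name} must be a positive finite number, got {value!r}")
            object.__setattr__(self, name, value)
        for mat_name, pi_name in (("P_A", "pi_A"), ("P_B", "pi_B")):
            P = check_stochastic(getattr(self, mat_name), mat_name, tol=_TOL)
            if P.shape[0] < 2:
                raise ParameterError(f"{mat_name} needs at least 2 alleles")
            if np.any(np.diag(P) <= 0):
                raise ParameterError(f"{mat_name} must have strictly positive diagonal entries")
            check_primitive(P, mat_name)
            pi = getattr(self, pi_name)
            if pi is None:
                pi = stationary_distribution(P, check=False)
            else:
                pi = np.asarray(pi, dtype=float)
                if pi.shape != (P.shape[0],):
                    raise ParameterError(f"{pi_name} has wrong length")
                _check_distribution(pi, pi_name)
                if np.max(np.abs(pi @ P - pi)) > _TOL:
                    raise ParameterError(f"{pi_name} is not stationary for {mat_name}")
            object.__setattr__(self, mat_name, _frozen_array(P, mat_name))
            object.__setattr__(self, pi_name, _frozen_array(pi, pi_name))

    @property
    def r_A(self) -> int:
        return self.P_A.shape[0]

    @property
    def r_B(self) -> int:
        return self.P_B.shape[0]


@dataclass(frozen=True)
class TwoLocusParams:
    """A mutation model together with the scaled recombination rate rho >= 0."""

    mutation: MutationModel
    rho: float

    def __post_init__(self) -> None:
        rho = float(self.rho)
        if not np.isfinite(rho) or rho < 0:
            raise ParameterError(f"rho must be finite and non-negative, got {rho!r}")
        object.__setattr__(self, "rho", rho)

    @property
    def r_A(self) -> int:
        return self.mutation.r_A

    @property
    def r_B(self) -> int:
        return self.mutation.r_B


def make_symmetric_diallelic(theta: float, rho: float) -> TwoLocusParams:
    """Symmetric diallelic model at both loci: P = all-1/2 matrix, pi = (1/2, 1/2).

    This is the parent-independent form of the mutation model used by LDhat;
    its mutation parameter theta_FD corresponds to theta = 2 * theta_FD here.
    """
    theta = float(theta)
    if not np.isfinite(theta) or theta <= 0:
        raise ParameterError(f"theta must be positive, got {theta!r}")
    P = np.full((2, 2), 0.5)
    pi = np.array([0.5, 0.5])
    mut = MutationModel(theta, theta, P, P, pi_A=pi, pi_B=pi)
    return TwoLocusParams(mut, rho)


def _count_tuple(values, name: str) -> tuple[int, ...]:
    arr = np.asarray(values)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D count vector")
    if not np.all(np.isreal(arr)) or np.any(np.mod(arr, 1) != 0):
        raise ValidationError(f"{name} must contain integers")
    if np.any(arr < 0):
        raise ValidationError(f"{name} has a negative count")
    return tuple(int(v) for v in arr)


@dataclass(frozen=True)
class SampleConfig:
    """Counts (a, b, c) of sampled gametes.

    ``a[i]`` counts gametes carrying allele A_i and untyped at locus B,
    ``b[j]`` counts gametes typed only as B_j, and ``c[i][j]`` counts fully
    typed A_i B_j gametes.  Stored as nested tuples, so configurations are
    hashable and can index probability tables directly.
    """

    a: tuple[int, ...]
    b: tuple[int, ...]
    c: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        a = _count_tuple(self.a, "a")
        b = _count_tuple(self.b, "b")
        c_in = self.c
        if c_in is None or (np.isscalar(c_in) and c_in == 0):
            c = tuple(tuple(0 for _ in b) for _ in a)
        else:
            c_arr = np.asarray(c_in)
            if c_arr.ndim != 2:
                raise ValidationError("c must be a 2-D count matrix")
            c = tuple(_count_tuple(row, "c") for row in c_arr)
        if len(c) != len(a) or any(len(row) != len(b) for row in c):
            raise ValidationError(
                f"c must have shape ({len(a)}, {len(b)}), got ({len(c)}, {len(c[0]) if c else 0})"
            )
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @classmethod
    def full(cls, c) -> "SampleConfig":
        """Configuration with full gamete information only (a = b = 0)."""
        c_arr = np.asarray(c)
        if c_arr.ndim != 2:
            raise ValidationError("c must be a 2-D count matrix")
        return cls(a=(0,) * c_arr.shape[0], b=(0,) * c_arr.shape[1], c=c_arr)

    @classmethod
    def from_flat(cls, flat, r_A: int = 2, r_B: int = 2) -> "SampleConfig":
        """Parse a row-major full-gamete tuple, e.g. ``"0,0,1,1"`` or ``(0, 0, 1, 1)``.

        The four entries of the diallelic case are (c_11, c_12, c_21, c_22).
        """
        if isinstance(flat, str):
            flat = [part.strip() for part in flat.split(",")]
        values = [int(v) for v in flat]
        if len(values) != r_A * r_B:
            raise ValidationError(
                f"expected {r_A * r_B} counts for an {r_A}x{r_B} model, got {len(values)}"
            )
        return cls.full(np.asarray(values).reshape(r_A, r_B))

    @property
    def n_a(self) -> int:
        return sum(self.a)

    @property
    def n_b(self) -> int:
        return sum(self.b)

    @property
    def n_c(self) -> int:
        return sum(sum(row) for row in self.c)

    @property
    def n(self) -> int:
        return self.n_a + self.n_b + self.n_c

    @property
    def a_vec(self) -> np.ndarray:
        return np.array(self.a, dtype=int)

    @property
    def b_vec(self) -> np.ndarray:
        return np.array(self.b, dtype=int)

    @property
    def c_mat(self) -> np.ndarray:
        return np.array(self.c, dtype=int)

    def key(self) -> tuple:
        return (self.a, self.b, self.c)

    def flat(self) -> tuple[int, ...]:
        """Row-major c counts; only meaningful for full-gamete configurations."""
        return tuple(v for row in self.c for v in row)


def validate_sample(config: SampleConfig, params: TwoLocusParams) -> SampleConfig:
    """Check a configuration against the model dimensions; return it unchanged."""
    if not isinstance(config, SampleConfig):
        raise ValidationError(f"expected a SampleConfig, got {type(config).__name__}")
    if len(config.a) != params.r_A:
        raise ValidationError(f"a has length {len(config.a)}, model has r_A = {params.r_A}")
    if len(config.b) != params.r_B:
        raise ValidationError(f"b has length {len(config.b)}, model has r_B = {params.r_B}")
    if config.n < 1:
        raise ValidationError("sample configuration is empty (n = 0)")
    return config


@dataclass(frozen=True)
class SubdividedSample:
    """Ordered tuple of per-subpopulation sample configurations (s_1, ..., s_Gamma)."""

    configs: tuple[SampleConfig, ...]

    def __post_init__(self) -> None:
        configs = tuple(self.configs)
        if len(configs) < 1:
            raise ValidationError("need at least one subpopulation configuration")
        if not all(isinstance(s, SampleConfig) for s in configs):
            raise ValidationError("all entries must be SampleConfig instances")
        dims = {(len(s.a), len(s.b)) for s in configs}
        if len(dims) != 1:
            raise ValidationError(f"per-deme configurations disagree on (r_A, r_B): {sorted(dims)}")
        object.__setattr__(self, "configs", configs)

    @classmethod
    def from_flat(cls, rows: Iterable, r_A: int = 2, r_B: int = 2) -> "SubdividedSample":
        """Build from per-deme row-major full-gamete c tuples."""
        return cls(tuple(SampleConfig.from_flat(row, r_A, r_B) for row in rows))

    @property
    def Gamma(self) -> int:
        return len(self.configs)

    @property
    def n(self) -> int:
        return sum(s.n for s in self.configs)

    def __iter__(self):
        return iter(self.configs)


@dataclass(frozen=True)
class MigrationModel:
    """Backward migration matrix with subpopulation size fractions.

    ``M[alpha, beta]`` is the probability that an individual now in deme alpha
    was in deme beta one generation earlier.  Strong migration requires M to
    be irreducible and aperiodic; ``xi`` is its stationary distribution and
    ``delta = [sum_alpha xi_alpha^2 / q'_alpha]^(-1)`` the effective-size
    factor, so N_e = delta * N.
    """

    M: np.ndarray
    q_prime: np.ndarray
    xi: np.ndarray | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        M = check_stochastic(self.M, "M", tol=_TOL)
        check_primitive(M, "M")
        q = np.asarray(self.q_prime, dtype=float)
        if q.shape != (M.shape[0],):
            raise ParameterError(
                f"q_prime has length {q.size}, migration matrix has {M.shape[0]} demes"
            )
        _check_distribution(q, "q_prime")
        if M.shape[0] > 1 and (np.any(q <= 0) or np.any(q >= 1)):
            raise ParameterError("subpopulation fractions must satisfy 0 < q'_alpha < 1")
        xi = stationary_distribution(M, check=False)
        delta = float(1.0 / np.sum(xi**2 / q))
        if delta > 1.0 + 1e-9:  # Cauchy-Schwarz guarantees delta <= 1
            raise ParameterError(f"computed delta {delta!r} exceeds 1")
        if abs(delta - 1.0) < 1e-12:
            delta = 1.0
        object.__setattr__(self, "M", _frozen_array(M, "M"))
        object.__setattr__(self, "q_prime", _frozen_array(q, "q_prime"))
        object.__setattr__(self, "xi", _frozen_array(xi, "xi"))
        object.__setattr__(self, "delta", delta)

    @property
    def Gamma(self) -> int:
        return self.M.shape[0]


def random_inputs(seed: int, Gamma: int, n_max: int, r_A: int = 2, r_B: int = 2
                  ) -> tuple[MigrationModel, SubdividedSample]:
    """Deterministic random fixture: a strictly positive migration model and a sample.

    Strictly positive migration matrices are automatically irreducible and
    aperiodic, so every output passes the MigrationModel invariants.  The
    subdivided sample has total size between 1 and ``n_max`` with gametes
    assigned uniformly to demes, typing kinds and allele types.
    """
    if Gamma < 1:
        raise ParameterError("Gamma must be >= 1")
    if n_max < 1:
        raise ParameterError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    M = rng.dirichlet(np.full(Gamma, 5.0), size=Gamma)
    q = rng.dirichlet(np.full(Gamma, 5.0))
    mig = MigrationModel(M, q)
    n = int(rng.integers(1, n_max + 1))
    a = np.zeros((Gamma, r_A), dtype=int)
    b = np.zeros((Gamma, r_B), dtype=int)
    c = np.zeros((Gamma, r_A, r_B), dtype=int)
    for _ in range(n):
        alpha = int(rng.integers(Gamma))
        kind = int(rng.integers(3))
        i = int(rng.integers(r_A))
        j = int(rng.integers(r_B))
        if kind == 0:
            a[alpha, i] += 1
        elif kind == 1:
            b[alpha, j] += 1
        else:
            c[alpha, i, j] += 1
    sample = SubdividedSample(tuple(
        SampleConfig(a[alpha], b[alpha], c[alpha]) for alpha in range(Gamma)
    ))
    return mig, sample
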