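"""Discrete-time multi-deme two-locus Wright-Fisher chain.

One generation follows the lifecycle reproduction -> recombination ->
migration -> mutation -> regulation.  Under monoecious random mating the
zygote gamete-pair law is the product measure, so reproduction followed by
recombination collapses to the deterministic frequency update
x'_ij = (1 - r0) x_ij + r0 x_i. x_.j.  Migration mixes deme frequencies with
the backward matrix M, mutation applies the per-locus transition
(1 - u0) I + u0 P independently at the two loci, and regulation resamples
each deme multinomially down to 2 N_alpha gametes — the only stochastic
step, and the only place drift enters.

Monte-Carlo estimation of stationary sample probabilities evaluates the
sampling monomial

    P_Gamma(state; s) = prod_alpha prod_i P_alpha_i.^a_alpha_i
                        prod_j P_alpha_.j^b_alpha_j  prod_ij P_alpha_ij^c_alpha_ij

at thinned post-burn-in states and averages, with a batch-means standard
error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._markov import check_primitive, check_stochastic
from .exceptions import ParameterError, ValidationError
from .models import MigrationModel, MutationModel, SubdividedSample
from .substructure import weighted_mean_and_deviation

__all__ = [
    "ChainSettings",
    "DemeState",
    "ChainRun",
    "deme_sizes",
    "discrete_rates",
    "recombination_update",
    "migration_update",
    "mutation_transition",
    "mutation_update",
    "regulation_sample",
    "step_generation",
    "run_chain",
    "sample_monomial_values",
    "batch_means_se",
    "estimate_from_run",
    "estimate_sample_probability",
    "estimate_replicated",
    "deviation_diagnostics",
]


def deme_sizes(N: int, q_prime) -> tuple[int, ...]:
    """Integer deme sizes N_alpha ~ q'_alpha * N, corrected by largest remainder."""
    q = np.asarray(q_prime, dtype=float)
    raw = q * N
    base = np.floor(raw).astype(int)
    short = int(N - base.sum())
    if short:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    if np.any(base < 1):
        raise ParameterError(f"every deme needs at least one individual, got {tuple(base)}")
    return tuple(int(v) for v in base)


def discrete_rates(theta: float, rho: float, N_e: float) -> tuple[float, float]:
    """Per-generation rates (u0, r0) from theta = 4 N_e u0 and rho = 4 N_e r0."""
    if N_e <= 0:
        raise ParameterError("N_e must be positive")
    u0 = theta / (4.0 * N_e)
    r0 = rho / (4.0 * N_e)
    for name, v in (("u0", u0), ("r0", r0)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} = {v!r} is outside [0, 1]; rates too large for N_e")
    return u0, r0


@dataclass(frozen=True)
class ChainSettings:
    """Run settings for the discrete chain.

    ``N`` is the total census size, ``N_alpha`` the per-deme sizes (2 N_alpha
    gametes are resampled at regulation), ``u0``/``r0`` the per-generation
    mutation and recombination probabilities, ``burn_in`` the discarded
    prefix, ``thin`` the spacing between retained states.
    """

    N: int
    N_alpha: tuple[int, ...]
    u0: float
    r0: float
    burn_in: int
    thin: int
    seed: int

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.N_alpha):
            raise ParameterError("N_alpha entries must be >= 1")
        if sum(self.N_alpha) != self.N:
            raise ParameterError("N_alpha must sum to N")
        for name in ("u0", "r0"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if self.burn_in < 0 or self.thin < 1:
            raise ParameterError("burn_in must be >= 0 and thin >= 1")

    @classmethod
    def for_population(cls, N: int, q_prime, u0: float, r0: float,
                       burn_in: int | None = None, thin: int | None = None,
                       seed: int = 0) -> "ChainSettings":
        """Desk-scale defaults: burn-in 10 N generations, thinning max(N, 1000)."""
        return cls(N=N, N_alpha=deme_sizes(N, q_prime), u0=u0, r0=r0,
                   burn_in=10 * N if burn_in is None else burn_in,
                   thin=max(N, 1000) if thin is None else thin, seed=seed)

    @property
    def Gamma(self) -> int:
        return len(self.N_alpha)


@dataclass
class DemeState:
    """Per-deme gamete-type frequencies, shape (Gamma, r_A, r_B)."""

    freqs: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 3:
            raise ValidationError("freqs must have shape (Gamma, r_A, r_B)")
        sums = freqs.reshape(freqs.shape[0], -1).sum(axis=1)
        if np.any(freqs < -1e-12) or np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ValidationError("each deme's frequencies must lie on the simplex")
        self.freqs = freqs


# ---------------------------------------------------------------------------
# one-generation updates

def recombination_update(freqs: np.ndarray, r0: float) -> np.ndarray:
    """x'_ij = (1 - r0) x_ij + r0 x_i. x_.j for one deme; marginals unchanged."""
    x = np.asarray(freqs, dtype=float)
    if r0 == 0:
        return x.copy()
    return (1.0 - r0) * x + r0 * np.outer(x.sum(axis=1), x.sum(axis=0))


def migration_update(freqs: np.ndarray, M) -> np.ndarray:
    """New deme-alpha frequencies are sum_beta m_alpha_beta * (deme-beta frequencies)."""
    return np.tensordot(np.asarray(M, dtype=float), np.asarray(freqs, dtype=float),
                        axes=(1, 0))


def mutation_transition(u0: float, P) -> np.ndarray:
    """Per-generation allele transition (1 - u0) I + u0 P (rows index the parent)."""
    if not (0.0 <= u0 <= 1.0):
        raise ParameterError(f"u0 must lie in [0, 1], got {u0!r}")
    P = np.asarray(P, dtype=float)
    return (1.0 - u0) * np.eye(P.shape[0]) + u0 * P


def mutation_update(freqs: np.ndarray, u0: float, P_A, P_B) -> np.ndarray:
    """Independent per-locus mutation: x'_ij = sum_kl x_kl T^A_ki T^B_lj."""
    TA = mutation_transition(u0, P_A)
    TB = mutation_transition(u0, P_B)
    return TA.T @ np.asarray(freqs, dtype=float) @ TB


def regulation_sample(freqs: np.ndarray, N_alpha: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Multinomial resampling of 2 N_alpha gametes; expectation equals the input."""
    x = np.asarray(freqs, dtype=float)
    p = np.maximum(x.ravel(), 0.0)
    p = p / p.sum()
    counts = rng.multinomial(2 * N_alpha, p)
    return (counts / (2.0 * N_alpha)).reshape(x.shape)


def step_generation(state: DemeState, settings: ChainSettings, model: MutationModel,
                    M, rng: np.random.Generator | None = None,
                    regulate: bool = True) -> DemeState:
    """Advance one generation: recombination, migration, mutation, regulation.

    With ``regulate=False`` the deterministic (effectively infinite deme
    size) flow is applied, which is the identity when all forces are off.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    X = np.stack([recombination_update(d, settings.r0) for d in state.freqs])
    X = migration_update(X, M)
    X = np.stack([mutation_update(d, settings.u0, model.P_A, model.P_B) for d in X])
    if regulate:
        X = np.stack([
            regulation_sample(d, n_alpha, rng)
            for d, n_alpha in zip(X, settings.N_alpha)
        ])
    return DemeState(X, state.generation + 1)


# ---------------------------------------------------------------------------
# chain runs

@dataclass
class ChainRun:
    """Retained thinned states of a chain run, shape (samples, Gamma, r_A, r_B)."""

    settings: ChainSettings
    states: np.ndarray
    init: str

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]


def _initial_freqs(init, Gamma: int, rA: int, rB: int) -> np.ndarray:
    if isinstance(init, str):
        if init == "uniform":
            return np.full((Gamma, rA, rB), 1.0 / (rA * rB))
        if init == "monomorphic":
            X = np.zeros((Gamma, rA, rB))
            X[:, 0, 0] = 1.0
            return X
        raise ParameterError(f"unknown init {init!r}; use 'uniform', 'monomorphic' or an array")
    X = np.asarray(init, dtype=float)
    if X.shape != (Gamma, rA, rB):
        raise ParameterError(f"init array must have shape {(Gamma, rA, rB)}")
    return X


def run_chain(settings: ChainSettings, model: MutationModel, M, n_samples: int,
              init="uniform") -> ChainRun:
    """Run the chain and retain ``n_samples`` states spaced ``thin`` generations apart.

    A single seeded generator drives all demes; the run is bit-reproducible
    given ``settings.seed``.
    """
    M = check_stochastic(M, "M")
    check_primitive(M, "M")
    Gamma = settings.Gamma
    if M.shape[0] != Gamma:
        raise ParameterError("migration matrix size must match the number of demes")
    rA, rB = model.r_A, model.r_B
    K = rA * rB
    rng = np.random.default_rng(settings.seed)
    X = _initial_freqs(init, Gamma, rA, rB).reshape(Gamma, K)

    T = np.kron(mutation_transition(settings.u0, model.P_A),
                mutation_transition(settings.u0, model.P_B))
    r0 = settings.r0
    two_N = np.asarray(settings.N_alpha, dtype=np.int64) * 2
    two_N_f = two_N.astype(float)[:, None]
    retained = np.empty((n_samples, Gamma, K))

    def step(X: np.ndarray) -> np.ndarray:
        if r0:
            Xr = X.reshape(Gamma, rA, rB)
            xa = Xr.sum(axis=2)
            xb = Xr.sum(axis=1)
            X = (1.0 - r0) * X + r0 * (xa[:, :, None] * xb[:, None, :]).reshape(Gamma, K)
        X = M @ X
        X = X @ T
        X = np.maximum(X, 0.0)
        X /= X.sum(axis=1, keepdims=True)
        return rng.multinomial(two_N, X) / two_N_f

    for _ in range(settings.burn_in):
        X = step(X)
    thin = settings.thin
    for s in range(n_samples):
        for _ in range(thin):
            X = step(X)
        retained[s] = X
    return ChainRun(settings=settings,
                    states=retained.reshape(n_samples, Gamma, rA, rB),
                    init=init if isinstance(init, str) else "array")


# ---------------------------------------------------------------------------
# estimation

def sample_monomial_values(states: np.ndarray, sample: SubdividedSample) -> np.ndarray:
    """P_Gamma(state; s) evaluated at each retained state; shape (samples,)."""
    states = np.asarray(states, dtype=float)
    S, Gamma, rA, rB = states.shape
    if sample.Gamma != Gamma:
        raise ValidationError(
            f"sample has {sample.Gamma} demes, run has {Gamma}"
        )
    a_exp = np.stack([s.a_vec for s in sample.configs])      # (Gamma, rA)
    b_exp = np.stack([s.b_vec for s in sample.configs])      # (Gamma, rB)
    c_exp = np.stack([s.c_mat for s in sample.configs])      # (Gamma, rA, rB)
    marg_a = states.sum(axis=3)
    marg_b = states.sum(axis=2)
    values = np.prod(marg_a ** a_exp[None], axis=(1, 2))
    values *= np.prod(marg_b ** b_exp[None], axis=(1, 2))
    values *= np.prod(states ** c_exp[None], axis=(1, 2, 3))
    return values


def batch_means_se(x: np.ndarray, n_batches: int = 25) -> float:
    """Batch-means standard error of the mean of a (possibly correlated) series."""
    x = np.asarray(x, dtype=float)
    S = x.size
    if S < 4:
        raise ValidationError("need at least 4 retained samples for a standard error")
    nb = min(n_batches, S // 2)
    width = S // nb
    means = x[: nb * width].reshape(nb, width).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


def estimate_from_run(run: ChainRun, sample: SubdividedSample) -> tuple[float, float]:
    """Time-average estimate of the sample probability and its batch-means SE."""
    values = sample_monomial_values(run.states, sample)
    return float(values.mean()), batch_means_se(values)


def estimate_sample_probability(settings: ChainSettings, model: MutationModel, M,
                                sample: SubdividedSample, n_samples: int = 1000,
                                init="uniform") -> tuple[float, float]:
    """Run the chain and estimate the stationary probability of ``sample``."""
    run = run_chain(settings, model, M, n_samples, init=init)
    return estimate_from_run(run, sample)


def estimate_replicated(settings: ChainSettings, model: MutationModel, M,
                        samples, n_replicates: int = 8,
                        samples_per_replicate: int = 500, init="uniform"
                        ) -> list[tuple[float, float]]:
    """Replicated estimates: independent chains, SE from the replicate spread.

    Statistics dominated by which gamete type is currently (nearly) fixed
    decorrelate only on the substitution timescale ~1/u0 generations, which
    at desk scale is comparable to an affordable run; within-chain
    batch-means standard errors are then badly overconfident.  Running
    ``n_replicates`` chains with independent seeds makes the replicate means
    independent draws, so ``SE = std(replicate means) / sqrt(R)`` is honest
    regardless of within-chain correlation.

    ``samples`` is one SubdividedSample or a sequence of them; returns one
    (estimate, se, n_events) triple per sample configuration, where
    ``n_events`` counts retained states with a non-zero monomial — a z test
    against the estimate is only meaningful when that count is well inside
    the CLT regime.
    """
    if isinstance(samples, SubdividedSample):
        samples = [samples]
    if n_replicates < 2:
        raise ParameterError("need at least 2 replicates for a standard error")
    means = np.empty((n_replicates, len(samples)))
    events = np.zeros(len(samples), dtype=int)
    for r in range(n_replicates):
        rep_settings = ChainSettings(
            N=settings.N, N_alpha=settings.N_alpha, u0=settings.u0, r0=settings.r0,
            burn_in=settings.burn_in, thin=settings.thin,
            seed=(settings.seed + 1_000_003 * r) % (2**31 - 1),
        )
        run = run_chain(rep_settings, model, M, samples_per_replicate, init=init)
        for s, sample in enumerate(samples):
            values = sample_monomial_values(run.states, sample)
            means[r, s] = values.mean()
            events[s] += int(np.count_nonzero(values))
    out = []
    for s in range(len(samples)):
        est = float(means[:, s].mean())
        se = float(means[:, s].std(ddof=1) / np.sqrt(n_replicates))
        out.append((est, se, int(events[s])))
    return out


@dataclass
class DeviationDiagnostics:
    """Per-retained-state max |d_alpha_ij| and its time average."""

    trajectory: np.ndarray
    time_average: float


def deviation_diagnostics(run: ChainRun, xi) -> DeviationDiagnostics:
    """Deviations of deme frequencies from their xi-weighted means.

    Under strong migration these shrink with migration strength and deme
    size; for a single deme they vanish identically.
    """
    traj = np.empty(run.n_samples)
    for s, state in enumerate(run.states):
        _, d = weighted_mean_and_deviation(state, xi)
        traj[s] = np.abs(d).max()
    return DeviationDiagnostics(trajectory=traj, time_average=float(traj.mean()))
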