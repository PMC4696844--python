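"""Exact ordered two-locus sample probabilities.

The stationary ordered sampling probabilities q(s; rho) of the neutral
finite-alleles two-locus diffusion satisfy a closed linear recursion: for a
configuration s = (a, b, c) with n gametes,

    [n(n-1) + theta_A (a+c) + theta_B (b+c) + rho c] q(s)
      = sum_i a_i (a_i - 1 + 2 c_i.) q(a - e_i, b, c)
      + sum_j b_j (b_j - 1 + 2 c_.j) q(a, b - e_j, c)
      + sum_ij [ c_ij (c_ij - 1) q(a, b, c - e_ij)
               + 2 a_i b_j q(a - e_i, b - e_j, c + e_ij) ]
      + theta_A sum_ij c_ij sum_k P^A_ki q(a, b, c - e_ij + e_kj)
      + theta_A sum_i  a_i  sum_k P^A_ki q(a - e_i + e_k, b, c)
      + theta_B sum_ij c_ij sum_l P^B_lj q(a, b, c - e_ij + e_il)
      + theta_B sum_j  b_j  sum_l P^B_lj q(a, b - e_j + e_l, c)
      + rho sum_ij c_ij q(a + e_i, b + e_j, c - e_ij),

with boundary values q(e_i, 0, 0) = pi^A_i and q(0, e_j, 0) = pi^B_j.  The
recombination move splits a fully typed gamete into two half-typed gametes,
so n itself can grow along the recursion; what never grows is the number of
typed loci t = a + b + 2c.  The solver therefore closes the configuration set
by breadth-first search, groups it into levels of constant t, and solves one
sparse linear system per level from t = 2 upwards.

For doubly stochastic mutation matrices the t = 2 level is singular (its
equations are the stationarity equations of a type chain, decoupled from the
boundary rows); such levels are resolved by augmenting the system with the
exact marginal-consistency identities sum_j q(a - e_i, b, c + e_ij) =
q(a, b, c) and solving in the least-squares sense.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import MatrixRankWarning, lsqr, spsolve

from .exceptions import ParameterError, SolverError, ValidationError
from .models import SampleConfig, TwoLocusParams, validate_sample

__all__ = [
    "ConfigUniverse",
    "ProbabilityTable",
    "enumerate_configs",
    "build_system",
    "solve_probabilities",
    "one_locus_probability",
    "one_locus_pair_probability",
    "unlinked_limit",
]

Key = tuple  # ((a_1, ..), (b_1, ..), ((c_11, ..), ..))

_RESID_TOL = 1e-10


# ---------------------------------------------------------------------------
# configuration keys and recursion moves

def _dec(t: tuple, i: int) -> tuple:
    return t[:i] + (t[i] - 1,) + t[i + 1:]

def _inc(t: tuple, i: int) -> tuple:
    return t[:i] + (t[i] + 1,) + t[i + 1:]

def _move(t: tuple, i: int, k: int) -> tuple:
    if i == k:
        return t
    return _inc(_dec(t, i), k)

def _c_add(c: tuple, i: int, j: int, d: int) -> tuple:
    row = c[i]
    return c[:i] + (row[:j] + (row[j] + d,) + row[j + 1:],) + c[i + 1:]

def _c_move_row(c: tuple, i: int, j: int, k: int) -> tuple:
    if i == k:
        return c
    return _c_add(_c_add(c, i, j, -1), k, j, +1)

def _c_move_col(c: tuple, i: int, j: int, l: int) -> tuple:
    if j == l:
        return c
    return _c_add(_c_add(c, i, j, -1), i, l, +1)


def _level(key: Key) -> int:
    a, b, c = key
    return sum(a) + sum(b) + 2 * sum(map(sum, c))


class _Ctx:
    """Plain-python view of the parameters, for fast term generation."""

    __slots__ = ("theta_A", "theta_B", "rho", "PA", "PB", "pi_A", "pi_B", "rA", "rB")

    def __init__(self, params: TwoLocusParams):
        mut = params.mutation
        self.theta_A = mut.theta_A
        self.theta_B = mut.theta_B
        self.rho = params.rho
        self.PA = [[float(v) for v in row] for row in mut.P_A]
        self.PB = [[float(v) for v in row] for row in mut.P_B]
        self.pi_A = [float(v) for v in mut.pi_A]
        self.pi_B = [float(v) for v in mut.pi_B]
        self.rA = mut.r_A
        self.rB = mut.r_B


def _diag(key: Key, ctx: _Ctx) -> float:
    a, b, c = key
    na, nb = sum(a), sum(b)
    nc = sum(map(sum, c))
    n = na + nb + nc
    return (n * (n - 1) + ctx.theta_A * (na + nc) + ctx.theta_B * (nb + nc)
            + ctx.rho * nc)


def _terms(key: Key, ctx: _Ctx):
    """Yield (child_key, coefficient) for every right-hand-side term.

    Terms whose child equals ``key`` (self-mutation, k = i) are included and
    must be moved to the diagonal by the caller.  Zero coefficients are
    skipped, which also keeps n >= 1 along the closure.
    """
    a, b, c = key
    rA, rB = ctx.rA, ctx.rB
    PA, PB = ctx.PA, ctx.PB
    thA, thB, rho = ctx.theta_A, ctx.theta_B, ctx.rho
    crow = [sum(row) for row in c]
    ccol = [sum(c[i][j] for i in range(rA)) for j in range(rB)]

    for i in range(rA):
        ai = a[i]
        if not ai:
            continue
        coef = ai * (ai - 1 + 2 * crow[i])
        if coef:
            yield (_dec(a, i), b, c), float(coef)
        for k in range(rA):
            p = PA[k][i]
            if p:
                yield (_move(a, i, k), b, c), thA * ai * p
    for j in range(rB):
        bj = b[j]
        if not bj:
            continue
        coef = bj * (bj - 1 + 2 * ccol[j])
        if coef:
            yield (a, _dec(b, j), c), float(coef)
        for l in range(rB):
            p = PB[l][j]
            if p:
                yield (a, _move(b, j, l), c), thB * bj * p
    for i in range(rA):
        for j in range(rB):
            cij = c[i][j]
            if not cij:
                continue
            if cij > 1:
                yield (a, b, _c_add(c, i, j, -1)), float(cij * (cij - 1))
            for k in range(rA):
                p = PA[k][i]
                if p:
                    yield (a, b, _c_move_row(c, i, j, k)), thA * cij * p
            for l in range(rB):
                p = PB[l][j]
                if p:
                    yield (a, b, _c_move_col(c, i, j, l)), thB * cij * p
            if rho:
                yield (_inc(a, i), _inc(b, j), _c_add(c, i, j, -1)), rho * cij
    for i in range(rA):
        if not a[i]:
            continue
        for j in range(rB):
            if b[j]:
                yield (_dec(a, i), _dec(b, j), _c_add(c, i, j, +1)), 2.0 * a[i] * b[j]


# ---------------------------------------------------------------------------
# universe enumeration

@dataclass
class ConfigUniverse:
    """All configurations coupled to a target by the recursion, by level t = a + b + 2c."""

    target: Key
    levels: dict[int, list[Key]]
    index: dict[Key, int] = field(repr=False)  # position of a key within its level

    @property
    def size(self) -> int:
        return sum(len(keys) for keys in self.levels.values())

    def __contains__(self, key: Key) -> bool:
        return key in self.index

    def keys(self):
        for lev in sorted(self.levels):
            yield from self.levels[lev]


def _boundary_keys(ctx: _Ctx) -> list[Key]:
    zero_a = (0,) * ctx.rA
    zero_b = (0,) * ctx.rB
    zero_c = tuple((0,) * ctx.rB for _ in range(ctx.rA))
    keys = [(_inc(zero_a, i), zero_b, zero_c) for i in range(ctx.rA)]
    keys += [(zero_a, _inc(zero_b, j), zero_c) for j in range(ctx.rB)]
    return keys


def enumerate_configs(target: SampleConfig, params: TwoLocusParams) -> ConfigUniverse:
    """Breadth-first closure of the target under all recursion moves.

    The boundary configurations (single half-typed gametes) are always
    included: they carry the boundary values and anchor the marginal
    consistency constraints even when no removal move reaches them.
    """
    target = validate_sample(target, params)
    ctx = _Ctx(params)
    start = target.key()
    seen = {start}
    stack = [start]
    while stack:
        key = stack.pop()
        if _level(key) <= 1:
            continue
        for child, _ in _terms(key, ctx):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    seen.update(_boundary_keys(ctx))
    levels: dict[int, list[Key]] = {}
    for key in seen:
        levels.setdefault(_level(key), []).append(key)
    index: dict[Key, int] = {}
    for lev in levels:
        levels[lev].sort()
        for i, key in enumerate(levels[lev]):
            index[key] = i
    return ConfigUniverse(target=start, levels=levels, index=index)


# ---------------------------------------------------------------------------
# system assembly and solution

def build_system(universe: ConfigUniverse, params: TwoLocusParams
                 ) -> tuple[sp.csr_matrix, np.ndarray, list[Key]]:
    """Assemble the full linear system over the whole universe at once.

    One row per configuration, in a fixed key order: boundary rows are pinned
    to the stationary allele frequencies, every other row transcribes the
    recursion.  Intended as a direct, global counterpart to the levelwise
    path of :func:`solve_probabilities`; useful for diagnostics and
    cross-checks on small universes.  Note that for doubly stochastic
    mutation models the matrix is rank deficient at the t = 2 component and
    the system must be solved together with marginal constraints.
    """
    ctx = _Ctx(params)
    order = list(universe.keys())
    pos = {key: i for i, key in enumerate(order)}
    m = len(order)
    rows, cols, data = [], [], []
    rhs = np.zeros(m)
    for r, key in enumerate(order):
        if _level(key) <= 1:
            a, b, _ = key
            rows.append(r); cols.append(r); data.append(1.0)
            if sum(a):
                rhs[r] = ctx.pi_A[a.index(1)]
            else:
                rhs[r] = ctx.pi_B[b.index(1)]
            continue
        rows.append(r); cols.append(r); data.append(_diag(key, ctx))
        for child, coef in _terms(key, ctx):
            rows.append(r); cols.append(pos[child]); data.append(-coef)
    A = sp.csr_matrix((data, (rows, cols)), shape=(m, m))
    return A, rhs, order


def _consistency_rows(level_keys: list[Key], idx: dict[Key, int],
                      below: list[Key], values: dict[Key, float], rB: int, rA: int
                      ) -> tuple[list[list[tuple[int, float]]], list[float]]:
    """Marginal identities tying level-t unknowns to solved level-(t-1) values.

    Replacing one half-typed gamete of a solved configuration by a fully
    typed one and summing over the unobserved allele leaves the probability
    unchanged: sum_j q(a - e_i, b, c + e_ij) = q(a, b, c).
    """
    rows, vals = [], []
    for low in below:
        a, b, c = low
        for i in range(rA):
            if a[i]:
                fam = [(_dec(a, i), b, _c_add(c, i, j, +1)) for j in range(rB)]
                if all(k in idx for k in fam):
                    rows.append([(idx[k], 1.0) for k in fam])
                    vals.append(values[low])
        for j in range(rB):
            if b[j]:
                fam = [(a, _dec(b, j), _c_add(c, i, j, +1)) for i in range(rA)]
                if all(k in idx for k in fam):
                    rows.append([(idx[k], 1.0) for k in fam])
                    vals.append(values[low])
    return rows, vals


def _constraint_violation(x: np.ndarray, cons, cons_vals) -> float:
    worst = 0.0
    for entries, v in zip(cons, cons_vals):
        worst = max(worst, abs(sum(x[col] * w for col, w in entries) - v))
    return worst


def _solve_level_augmented(A: sp.csr_matrix, rhs: np.ndarray, cons, cons_vals,
                           m: int) -> np.ndarray:
    if not cons:
        raise SolverError(
            f"singular level with {m} unknowns and no marginal constraints available"
        )
    k = len(cons)
    crow, ccol, cdat = [], [], []
    for r, entries in enumerate(cons):
        for col, v in entries:
            crow.append(r); ccol.append(col); cdat.append(v)
    C = sp.csr_matrix((cdat, (crow, ccol)), shape=(k, m))
    stacked = sp.vstack([A, C]).tocsr()
    full_rhs = np.concatenate([rhs, np.asarray(cons_vals)])
    if m <= 4000:
        x, *_ = np.linalg.lstsq(stacked.toarray(), full_rhs, rcond=None)
    else:
        x = lsqr(stacked, full_rhs, atol=1e-14, btol=1e-14, iter_lim=50 * m)[0]
    return x


def solve_probabilities(target: SampleConfig, params: TwoLocusParams) -> ProbabilityTable:
    """Solve the recursion for the target and everything it couples to.

    Returns a :class:`ProbabilityTable` with the ordered sample probability
    of every configuration in the universe, solved level by level in the
    typed-locus count t; each level is a sparse linear solve with the levels
    below already known.
    """
    universe = enumerate_configs(target, params)
    ctx = _Ctx(params)
    values: dict[Key, float] = {}
    for key in universe.levels.get(1, []):
        a, b, _ = key
        values[key] = ctx.pi_A[a.index(1)] if sum(a) else ctx.pi_B[b.index(1)]
    max_residual = 0.0
    for lev in sorted(universe.levels):
        if lev <= 1:
            continue
        keys = universe.levels[lev]
        idx = {key: i for i, key in enumerate(keys)}
        m = len(keys)
        rows, cols, data = [], [], []
        rhs = np.zeros(m)
        for r, key in enumerate(keys):
            rows.append(r); cols.append(r); data.append(_diag(key, ctx))
            for child, coef in _terms(key, ctx):
                ci = idx.get(child)
                if ci is not None:
                    rows.append(r); cols.append(ci); data.append(-coef)
                else:
                    rhs[r] += coef * values[child]
        A = sp.csr_matrix((data, (rows, cols)), shape=(m, m))
        # row-equilibrate by the diagonal so residuals are O(1)-scaled at any rho
        d = A.diagonal()
        A = sp.diags(1.0 / d) @ A
        rhs = rhs / d
        below = universe.levels.get(lev - 1, [])
        cons, cons_vals = _consistency_rows(keys, idx, below, values, ctx.rB, ctx.rA)
        x = None
        with warnings.catch_warnings():
            warnings.simplefilter("error", MatrixRankWarning)
            try:
                x = spsolve(A.tocsc(), rhs)
            except (MatrixRankWarning, RuntimeError, ValueError):
                x = None
        tol = _RESID_TOL * max(1.0, float(np.abs(rhs).max()))
        if x is not None and np.all(np.isfinite(x)):
            resid = float(np.abs(A @ x - rhs).max())
            # a singular homogeneous level solves to x = 0 with zero residual;
            # the marginal constraints expose it
            cons_err = _constraint_violation(x, cons, cons_vals)
            if cons_err > 1e-8 * max(1.0, max(map(abs, cons_vals), default=1.0)):
                resid = np.inf
        else:
            resid = np.inf
        if resid > tol:
            x = _solve_level_augmented(A, rhs, cons, cons_vals, m)
            resid = float(np.abs(A @ x - rhs).max())
            if resid > tol:
                raise SolverError(
                    f"level t={lev}: residual {resid:.3e} exceeds tolerance {tol:.3e}"
                )
        max_residual = max(max_residual, resid)
        for key, v in zip(keys, x):
            values[key] = float(v)
    for key, v in values.items():
        if not (0.0 < v <= 1.0 + 1e-9):
            raise SolverError(f"probability out of (0, 1] for {key}: {v!r}")
    return ProbabilityTable(params=params, values=values, universe=universe,
                            residual=max_residual)


@dataclass
class ProbabilityTable:
    """Ordered sample probabilities q(s; rho) for every configuration of a universe."""

    params: TwoLocusParams
    values: dict[Key, float]
    universe: ConfigUniverse
    residual: float

    def q(self, config) -> float:
        """Probability of a configuration (SampleConfig, key tuple, or flat c counts)."""
        if isinstance(config, SampleConfig):
            key = validate_sample(config, self.params).key()
        elif isinstance(config, tuple) and len(config) == 3 and isinstance(config[0], tuple):
            key = config
        else:
            key = SampleConfig.from_flat(config, self.params.r_A, self.params.r_B).key()
        try:
            return self.values[key]
        except KeyError:
            raise KeyError(f"configuration {key} is not in the solved universe") from None

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, config) -> bool:
        try:
            self.q(config)
        except KeyError:
            return False
        return True


# ---------------------------------------------------------------------------
# one-locus solves and closed forms (marginal / unlinked oracles)

def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def one_locus_table(n: int, theta: float, P, pi=None) -> dict[tuple[int, ...], float]:
    """Ordered sample probabilities for a single locus, all configurations of size <= n.

    Solves the one-locus recursion [m(m-1) + theta*m] q(a) =
    sum_i a_i(a_i-1) q(a-e_i) + theta sum_i a_i sum_k P_ki q(a-e_i+e_k)
    level by level with q(e_i) = pi_i.
    """
    P = np.asarray(P, dtype=float)
    r = P.shape[0]
    if pi is None:
        from ._markov import stationary_distribution
        pi = stationary_distribution(P)
    pi = np.asarray(pi, dtype=float)
    table: dict[tuple[int, ...], float] = {}
    for i in range(r):
        e = tuple(1 if k == i else 0 for k in range(r))
        table[e] = float(pi[i])
    for m in range(2, n + 1):
        keys = sorted(_compositions(m, r))
        idx = {k: i for i, k in enumerate(keys)}
        size = len(keys)
        A = np.zeros((size, size))
        rhs = np.zeros(size)
        for row, a in enumerate(keys):
            A[row, row] = m * (m - 1) + theta * m
            for i in range(r):
                if not a[i]:
                    continue
                if a[i] > 1:
                    rhs[row] += a[i] * (a[i] - 1) * table[_dec(a, i)]
                for k in range(r):
                    p = P[k, i]
                    if p:
                        A[row, idx[_move(a, i, k)]] -= theta * a[i] * p
        try:
            x = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        for a, v in zip(keys, x):
            table[a] = float(v)
    return table


def one_locus_probability(counts, theta: float, P, pi=None) -> float:
    """Ordered one-locus sample probability of an allele-count configuration."""
    counts = tuple(int(v) for v in counts)
    if any(v < 0 for v in counts) or sum(counts) < 1:
        raise ValidationError("counts must be non-negative with at least one gamete")
    return one_locus_table(sum(counts), theta, P, pi)[counts]


def one_locus_pair_probability(theta: float, pi, i: int, j: int, P=None) -> float:
    """Closed-form ordered pair probability under parent-independent mutation.

    Under PIM (every row of P equal to pi) the stationary law of the allele
    frequencies is Dirichlet(theta * pi), giving
    q(i, i) = pi_i (theta pi_i + 1) / (1 + theta) and
    q(i, j) = pi_i pi_j theta / (1 + theta) for i != j.
    """
    pi = np.asarray(pi, dtype=float)
    if P is not None:
        P = np.asarray(P, dtype=float)
        if np.max(np.abs(P - pi[None, :])) > 1e-12:
            raise ParameterError("closed form is valid only for parent-independent mutation")
    if theta <= 0:
        raise ParameterError("theta must be positive")
    if i == j:
        return float(pi[i] * (theta * pi[i] + 1.0) / (1.0 + theta))
    return float(pi[i] * pi[j] * theta / (1.0 + theta))


def unlinked_limit(target: SampleConfig, params: TwoLocusParams) -> float:
    """rho -> infinity factorisation: product of the two marginal one-locus solves.

    Only defined for full-gamete targets (a = b = 0); the marginal allele
    counts are the row and column sums of c.
    """
    target = validate_sample(target, params)
    if target.n_a or target.n_b:
        raise ValidationError("unlinked limit requires full gamete information (a = b = 0)")
    mut = params.mutation
    counts_A = tuple(int(v) for v in target.c_mat.sum(axis=1))
    counts_B = tuple(int(v) for v in target.c_mat.sum(axis=0))
    qA = one_locus_probability(counts_A, mut.theta_A, mut.P_A, mut.pi_A)
    qB = one_locus_probability(counts_B, mut.theta_B, mut.P_B, mut.pi_B)
    return qA * qB
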