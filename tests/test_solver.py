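import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import poch

from twolocus import (MutationModel, SampleConfig, TwoLocusParams, ValidationError,
                      enumerate_configs, build_system, make_symmetric_diallelic,
                      one_locus_pair_probability, one_locus_probability,
                      solve_probabilities, unlinked_limit)


# ---------------------------------------------------------------------------
# independent brute-force oracle: global dense least-squares solve of the
# recursion over ALL diallelic configurations with a + b + 2c <= t_max,
# assembled by direct transcription (no shared code with the package path)

def brute_force_table(theta, rho, t_max):
    P = [[0.5, 0.5], [0.5, 0.5]]
    pi = [0.5, 0.5]
    configs = []
    for counts in itertools.product(range(t_max + 1), repeat=8):
        a = counts[0:2]
        b = counts[2:4]
        c = ((counts[4], counts[5]), (counts[6], counts[7]))
        t = sum(counts[0:4]) + 2 * sum(counts[4:8])
        if 1 <= sum(counts) and 1 <= t <= t_max:
            configs.append((a, b, c))
    idx = {k: i for i, k in enumerate(configs)}

    def tlev(key):
        a, b, c = key
        return sum(a) + sum(b) + 2 * (c[0][0] + c[0][1] + c[1][0] + c[1][1])

    rows, rhs = [], []
    for (a, b, c) in configs:
        row = np.zeros(len(configs))
        here = idx[(a, b, c)]
        if tlev((a, b, c)) == 1:
            row[here] = 1.0
            rhs.append(pi[a.index(1)] if sum(a) else pi[b.index(1)])
            rows.append(row)
            continue
        na, nb = sum(a), sum(b)
        nc = c[0][0] + c[0][1] + c[1][0] + c[1][1]
        n = na + nb + nc
        row[here] = n * (n - 1) + theta * (na + nc) + theta * (nb + nc) + rho * nc

        def sub(key, coef):
            row[idx[key]] -= coef

        for i in range(2):
            ci_dot = c[i][0] + c[i][1]
            if a[i]:
                aa = list(a)
                aa[i] -= 1
                if a[i] - 1 + 2 * ci_dot:
                    sub((tuple(aa), b, c), a[i] * (a[i] - 1 + 2 * ci_dot))
                for k in range(2):
                    ak = list(a)
                    ak[i] -= 1
                    ak[k] += 1
                    sub((tuple(ak), b, c), theta * a[i] * P[k][i])
        for j in range(2):
            cdot_j = c[0][j] + c[1][j]
            if b[j]:
                bb = list(b)
                bb[j] -= 1
                if b[j] - 1 + 2 * cdot_j:
                    sub((a, tuple(bb), c), b[j] * (b[j] - 1 + 2 * cdot_j))
                for l in range(2):
                    bl = list(b)
                    bl[j] -= 1
                    bl[l] += 1
                    sub((a, tuple(bl), c), theta * b[j] * P[l][j])
        for i in range(2):
            for j in range(2):
                if not c[i][j]:
                    continue
                cm = [list(r) for r in c]
                cm[i][j] -= 1
                if c[i][j] > 1:
                    sub((a, b, tuple(map(tuple, cm))), c[i][j] * (c[i][j] - 1))
                for k in range(2):
                    ck = [list(r) for r in c]
                    ck[i][j] -= 1
                    ck[k][j] += 1
                    sub((a, b, tuple(map(tuple, ck))), theta * c[i][j] * P[k][i])
                for l in range(2):
                    cl = [list(r) for r in c]
                    cl[i][j] -= 1
                    cl[i][l] += 1
                    sub((a, b, tuple(map(tuple, cl))), theta * c[i][j] * P[l][j])
                if rho:
                    ar = list(a)
                    br = list(b)
                    ar[i] += 1
                    br[j] += 1
                    sub((tuple(ar), tuple(br), tuple(map(tuple, cm))), rho * c[i][j])
        for i in range(2):
            for j in range(2):
                if a[i] and b[j]:
                    ap = list(a)
                    bp = list(b)
                    cp = [list(r) for r in c]
                    ap[i] -= 1
                    bp[j] -= 1
                    cp[i][j] += 1
                    sub((tuple(ap), tuple(bp), tuple(map(tuple, cp))), 2 * a[i] * b[j])
        rows.append(row)
        rhs.append(0.0)

    # marginal-consistency closure: replacing one half-typed gamete by a full
    # one and summing over its unobserved allele is probability preserving
    for (a, b, c) in configs:
        if tlev((a, b, c)) + 1 > t_max:
            continue
        for i in range(2):
            if a[i]:
                row = np.zeros(len(configs))
                row[idx[(a, b, c)]] = -1.0
                for j in range(2):
                    aa = list(a)
                    aa[i] -= 1
                    cc = [list(r) for r in c]
                    cc[i][j] += 1
                    row[idx[(tuple(aa), b, tuple(map(tuple, cc)))]] = 1.0
                rows.append(row)
                rhs.append(0.0)
        for j in range(2):
            if b[j]:
                row = np.zeros(len(configs))
                row[idx[(a, b, c)]] = -1.0
                for i in range(2):
                    bb = list(b)
                    bb[j] -= 1
                    cc = [list(r) for r in c]
                    cc[i][j] += 1
                    row[idx[(a, tuple(bb), tuple(map(tuple, cc)))]] = 1.0
                rows.append(row)
                rhs.append(0.0)

    x, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return {k: x[i] for k, i in idx.items()}


@pytest.mark.parametrize("theta,rho", [(0.01, 50.0), (0.5, 2.0), (0.05, 0.0)])
def test_matches_independent_brute_force(theta, rho):
    """Levelwise solver agrees with a globally assembled dense least-squares solve."""
    oracle = brute_force_table(theta, rho, t_max=4)
    params = make_symmetric_diallelic(theta, rho)
    table = solve_probabilities(SampleConfig.full([[2, 0], [0, 0]]), params)
    checked = 0
    for key, expected in oracle.items():
        if key in table.universe:
            assert table.q(key) == pytest.approx(expected, rel=1e-8, abs=1e-12)
            checked += 1
    assert checked >= 10


# ---------------------------------------------------------------------------
# boundary values and elementary symmetries

def test_boundary_values_are_stationary_frequencies(table1):
    assert table1.q(((1, 0), (0, 0), ((0, 0), (0, 0)))) == 0.5
    assert table1.q(((0, 0), (0, 1), ((0, 0), (0, 0)))) == 0.5


@pytest.mark.parametrize("rho", [0.0, 1.0, 50.0])
def test_single_full_gamete_probability(rho):
    """Allele-swap symmetry at both loci forces q(one A_i B_j gamete) = 1/4."""
    params = make_symmetric_diallelic(0.01, rho)
    table = solve_probabilities(SampleConfig.full([[1, 0], [0, 0]]), params)
    for flat in [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)]:
        assert table.q(flat) == pytest.approx(0.25, rel=1e-12)


def test_allele_relabeling_symmetry(table1):
    """q is invariant under swapping A_1 <-> A_2 and/or B_1 <-> B_2."""
    assert table1.q((0, 0, 1, 1)) == pytest.approx(table1.q((1, 1, 0, 0)), rel=1e-9)
    assert table1.q((2, 0, 4, 0)) == pytest.approx(table1.q((0, 2, 0, 4)), rel=1e-9)
    assert table1.q((2, 0, 4, 0)) == pytest.approx(table1.q((4, 0, 2, 0)), rel=1e-9)
    assert table1.q((6, 0, 0, 0)) == pytest.approx(table1.q((0, 0, 0, 6)), rel=1e-9)


def test_sampling_consistency_small(table1):
    """Adding one fully typed gamete and summing over its type is neutral."""
    base = SampleConfig.full([[1, 0], [0, 1]])
    total = 0.0
    for i in range(2):
        for j in range(2):
            c = np.array(base.c)
            c[i, j] += 1
            total += table1.q(SampleConfig.full(c))
    assert total == pytest.approx(table1.q(base), abs=1e-12)


def test_residual_diagnostics(table1):
    assert table1.residual < 1e-10
    assert all(0 < v <= 1 for v in table1.values.values())


def test_universe_of_single_gamete():
    """The closure of one full gamete: 4 full types, 4 split pairs, 4 boundaries."""
    params = make_symmetric_diallelic(0.01, 1.0)
    universe = enumerate_configs(SampleConfig.full([[1, 0], [0, 0]]), params)
    assert universe.size == 12
    zero_c = ((0, 0), (0, 0))
    assert ((1, 0), (0, 0), zero_c) in universe
    assert ((0, 0), (1, 0), zero_c) in universe
    assert ((1, 0), (1, 0), zero_c) in universe


def test_universe_nesting():
    params = make_symmetric_diallelic(0.01, 50.0)
    small = enumerate_configs(SampleConfig.full([[5, 0], [0, 0]]), params)
    large = enumerate_configs(SampleConfig.full([[6, 0], [0, 0]]), params)
    assert set(small.index) <= set(large.index)


def test_global_assembly_consistent_with_levelwise(table1):
    """The package's levelwise solution satisfies the globally assembled system."""
    params = make_symmetric_diallelic(0.01, 50.0)
    universe = enumerate_configs(SampleConfig.full([[2, 0], [0, 0]]), params)
    A, rhs, order = build_system(universe, params)
    x = np.array([table1.q(key) for key in order])
    scale = np.abs(A).max()
    assert np.abs(A @ x - rhs).max() < 1e-10 * scale


# ---------------------------------------------------------------------------
# one-locus oracles

def test_pair_probability_closed_form_examples():
    assert one_locus_pair_probability(0.01, (0.5, 0.5), 0, 0) == pytest.approx(
        0.5 * 1.005 / 1.01, rel=1e-12)
    # vanishing mutation makes an ordered pair almost surely identical
    assert one_locus_pair_probability(1e-12, (0.3, 0.7), 0, 0) == pytest.approx(0.3, rel=1e-9)
    total = sum(one_locus_pair_probability(0.7, (0.3, 0.7), i, j)
                for i in range(2) for j in range(2))
    assert total == pytest.approx(1.0, rel=1e-12)


def test_pair_probability_refuses_non_pim():
    with pytest.raises(Exception):
        one_locus_pair_probability(0.01, (0.5, 0.5), 0, 0, P=[[0.9, 0.1], [0.2, 0.8]])


@given(counts=st.lists(st.integers(0, 3), min_size=2, max_size=2).filter(lambda c: sum(c) >= 1),
       theta=st.sampled_from([0.01, 0.3, 1.5]))
def test_one_locus_recursion_matches_dirichlet_closed_form(counts, theta):
    """For PIM the stationary law is Dirichlet(theta*pi):
    q(a) = prod_i (theta pi_i)_(a_i) / (theta)_(n) with rising factorials."""
    pi = np.array([0.5, 0.5])
    P = np.tile(pi, (2, 1))
    n = sum(counts)
    expected = np.prod([poch(theta * pi[i], counts[i]) for i in range(2)]) / poch(theta, n)
    got = one_locus_probability(counts, theta, P, pi)
    assert got == pytest.approx(expected, rel=1e-10)


def test_marginalization_identity_over_rho():
    """Summing the two-gamete table over locus-B patterns recovers the
    one-locus pair probability, independently of rho."""
    expected = one_locus_pair_probability(0.01, (0.5, 0.5), 0, 0)
    for rho in (1.0, 50.0, 1000.0):
        params = make_symmetric_diallelic(0.01, rho)
        table = solve_probabilities(SampleConfig.full([[2, 0], [0, 0]]), params)
        total = table.q((2, 0, 0, 0)) + 2 * table.q((1, 1, 0, 0)) + table.q((0, 2, 0, 0))
        assert total == pytest.approx(expected, abs=1e-8)


def test_unlinked_limit_agreement():
    """At rho = 1e6 the solved probability factorises over loci to 1e-4 relative."""
    params = make_symmetric_diallelic(0.01, 1e6)
    target = SampleConfig.full([[1, 0], [0, 1]])
    table = solve_probabilities(target, params)
    assert table.q(target) == pytest.approx(unlinked_limit(target, params), rel=1e-4)


def test_unlinked_limit_rejects_half_typed():
    params = make_symmetric_diallelic(0.01, 1.0)
    with pytest.raises(ValidationError):
        unlinked_limit(SampleConfig(a=(1, 0), b=(0, 0), c=0), params)


def test_unlinked_limit_single_gamete():
    params = make_symmetric_diallelic(0.01, 1.0)
    assert unlinked_limit(SampleConfig.full([[1, 0], [0, 0]]), params) == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# a general (non-doubly-stochastic) mutation model exercises the regular
# solve path at the single-gamete level

def test_asymmetric_mutation_model_marginals():
    P_A = np.array([[0.7, 0.3], [0.4, 0.6]])
    P_B = np.array([[0.8, 0.2], [0.1, 0.9]])
    mut = MutationModel(0.05, 0.08, P_A, P_B)
    params = TwoLocusParams(mut, 1.5)
    table = solve_probabilities(SampleConfig.full([[1, 0], [0, 0]]), params)
    total = sum(table.q(SampleConfig.full(np.outer(np.eye(2, dtype=int)[i],
                                                   np.eye(2, dtype=int)[j])))
                for i in range(2) for j in range(2))
    assert total == pytest.approx(1.0, abs=1e-10)
    # summing single-gamete probabilities over locus B recovers pi^A
    for i in range(2):
        row_total = sum(table.q(SampleConfig.full(np.outer(np.eye(2, dtype=int)[i],
                                                           np.eye(2, dtype=int)[j])))
                        for j in range(2))
        assert row_total == pytest.approx(mut.pi_A[i], abs=1e-10)
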