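"""Exact steady-state solvers for the TF-sharing master equation.

Two brute-force oracles live here:

* the stationary law of the mRNA-independent TF-binding chain over
  ``(n, c)`` — solved both as a sparse linear system and via the
  closed-form equilibrium product weights (the chain is reversible), with
  the two routes required to agree;
* the stationary solution of the full chemical master equation on the
  aggregate lattice ``(n, c, m)`` with the mRNA axis truncated at ``m_max``
  (auto-enlarged until the truncation tail is below tolerance).

Because the mRNA dynamics does not feed back on TF binding, the
``(n, c)``-marginal of the full solution must reproduce the binding chain's
stationary law; the test suite checks this.

The two-promoter mRNA correlation is computed exactly without any mRNA
truncation by solving the closed linear systems for the conditional first
and second mRNA moments given the occupancy microstate ``(s1, s2, c)`` —
transcription and decay propensities are linear in the mRNA counts, so
these systems close exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.special import gammaln

from .model import ModelSpec, RegulationMode, validate_model

__all__ = [
    "OccupancyDistribution",
    "CMEDistribution",
    "TruncationError",
    "binding_occupancy_distribution",
    "cme_steady_state",
    "cme_two_promoter_correlation",
    "total_variation",
]


class TruncationError(RuntimeError):
    """The mRNA truncation could not be made tight enough."""


def _occupancy_states(spec: ModelSpec) -> list[tuple[int, int]]:
    """All reachable (n, c) pairs, lexicographically ordered."""
    out = []
    for n in range(spec.max_promoter_occupancy + 1):
        for c in range(spec.max_competitor_occupancy(n) + 1):
            out.append((n, c))
    return out


def _occupancy_generator(spec: ModelSpec, states) -> sp.csr_matrix:
    """Generator matrix Q of the (n, c) binding chain; Q[i, j] = rate i->j."""
    index = {st: i for i, st in enumerate(states)}
    rows, cols, vals = [], [], []
    for (n, c), i in index.items():
        free = spec.n_tf - n - c
        moves = [
            ((n + 1, c), spec.k_on * free * (spec.n_promoters - n)),
            ((n - 1, c), spec.k_off * n),
            ((n, c + 1), spec.k_on_c * free * (spec.n_competitors - c)),
            ((n, c - 1), spec.k_off_c * c),
        ]
        for tgt, a in moves:
            if a > 0 and tgt in index:
                rows.append(i)
                cols.append(index[tgt])
                vals.append(a)
                rows.append(i)
                cols.append(i)
                vals.append(-a)
    K = len(states)
    return sp.coo_matrix((vals, (rows, cols)), shape=(K, K)).tocsr()


def _stationary(Q: sp.spmatrix) -> np.ndarray:
    """Stationary distribution of generator Q (replace one balance equation
    with the normalization constraint and solve the sparse system)."""
    K = Q.shape[0]
    A = Q.T.tolil()
    A[K - 1, :] = 1.0
    b = np.zeros(K)
    b[K - 1] = 1.0
    p = spsolve(A.tocsr().tocsc(), b)
    return np.asarray(p)


@dataclass
class OccupancyDistribution:
    """Stationary law of the TF-binding subsystem over (n, c)."""

    spec: ModelSpec
    states: list[tuple[int, int]]
    probabilities: np.ndarray

    def probability(self, n: int, c: int = 0) -> float:
        try:
            return float(self.probabilities[self.states.index((n, c))])
        except ValueError:
            return 0.0

    def n_marginal(self) -> np.ndarray:
        out = np.zeros(self.spec.max_promoter_occupancy + 1)
        for (n, _), p in zip(self.states, self.probabilities):
            out[n] += p
        return out

    def support(self) -> list[tuple[int, int]]:
        return [st for st, p in zip(self.states, self.probabilities) if p > 1e-12]


def _product_form_weights(spec: ModelSpec, states) -> np.ndarray | None:
    """Closed-form equilibrium weights of the reversible binding chain.

    P(n, c) ∝ C(N_P, n) C(N_C, c) N_TF!/(N_TF-n-c)! (k_on/k_off)^n
    (k_on_c/k_off_c)^c.  Returns None when an unbinding rate vanishes while
    the corresponding binding is active (no equilibrium ratio exists).
    """
    if spec.k_off == 0 and spec.k_on > 0 and spec.n_tf > 0:
        return None
    if spec.k_off_c == 0 and spec.k_on_c > 0 and spec.n_competitors > 0 and spec.n_tf > 0:
        return None
    logw = np.empty(len(states))
    log_kp = math.log(spec.k_on / spec.k_off) if spec.k_on > 0 else -math.inf
    log_kc = (
        math.log(spec.k_on_c / spec.k_off_c) if spec.k_on_c > 0 else -math.inf
    )
    for i, (n, c) in enumerate(states):
        lw = (
            gammaln(spec.n_promoters + 1)
            - gammaln(n + 1)
            - gammaln(spec.n_promoters - n + 1)
            + gammaln(spec.n_competitors + 1)
            - gammaln(c + 1)
            - gammaln(spec.n_competitors - c + 1)
            + gammaln(spec.n_tf + 1)
            - gammaln(spec.n_tf - n - c + 1)
        )
        lw += n * log_kp if n else 0.0
        lw += c * log_kc if c else 0.0
        logw[i] = lw
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def binding_occupancy_distribution(spec, cross_check_tol: float = 1e-10) -> OccupancyDistribution:
    """Exact stationary distribution of the (n, c) TF-binding chain.

    Solves the stationary linear system of the finite chain and verifies it
    against the closed-form equilibrium product weights (the chain satisfies
    detailed balance); disagreement beyond ``cross_check_tol`` raises.
    """
    spec = validate_model(spec)
    if spec.k_off == 0 and spec.k_on > 0 and spec.n_tf > 0 and spec.n_promoters > 0:
        warnings.warn(
            "k_off = 0 with active binding: the chain is absorbing and the "
            "stationary law degenerates to maximum occupancy",
            stacklevel=2,
        )
    states = _occupancy_states(spec)
    if len(states) == 1:
        return OccupancyDistribution(spec, states, np.array([1.0]))
    Q = _occupancy_generator(spec, states)
    p = _stationary(Q)
    w = _product_form_weights(spec, states)
    if w is not None:
        err = float(np.abs(p - w).max())
        if err > cross_check_tol:
            raise RuntimeError(
                f"stationary solve disagrees with product-form weights (max |Δp| = {err:.2e})"
            )
    return OccupancyDistribution(spec, states, p)


@dataclass
class CMEDistribution:
    """Exact steady state of the truncated master equation on (n, c, m).

    ``joint[k, m]`` is the probability of occupancy state ``states[k]`` with
    ``m`` total mRNA molecules; ``truncation_mass`` is the probability held
    at the truncation boundary ``m = m_max``.
    """

    spec: ModelSpec
    states: list[tuple[int, int]]
    m_max: int
    joint: np.ndarray  # (K, m_max + 1)
    truncation_mass: float
    tol: float

    def m_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def nc_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    def mean_m(self) -> float:
        p = self.m_marginal()
        return float(p @ np.arange(len(p)))

    def var_m(self) -> float:
        p = self.m_marginal()
        m = np.arange(len(p))
        mu = p @ m
        return float(p @ (m - mu) ** 2)

    def to_csv(self, path, marginal: bool = False) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        with open(path, "w") as fh:
            if marginal:
                fh.write("m,probability\n")
                for m, p in enumerate(self.m_marginal()):
                    fh.write(f"{m},{p:.12e}\n")
            else:
                fh.write("n,c,m,probability\n")
                for k, (n, c) in enumerate(self.states):
                    for m in range(self.m_max + 1):
                        fh.write(f"{n},{c},{m},{self.joint[k, m]:.12e}\n")
        sidecar = {
            "spec": self.spec.to_dict(),
            "m_max": self.m_max,
            "truncation_mass": self.truncation_mass,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _transcription_rate_aggregate(spec: ModelSpec, n: int) -> float:
    if spec.mode is RegulationMode.ACTIVATOR:
        return spec.r * n + spec.r_basal * (spec.n_promoters - n)
    return spec.r * (spec.n_promoters - n)


def default_m_max(spec: ModelSpec) -> int:
    """Initial mRNA truncation: saturated mean plus ten Poisson widths."""
    cap = max(spec.saturated_mean(), spec.n_promoters * spec.r_basal / spec.gamma, 1.0)
    return int(math.ceil(cap + 10.0 * math.sqrt(cap)))


def _solve_truncated(spec: ModelSpec, states, m_max: int) -> np.ndarray:
    K = len(states)
    M = m_max + 1
    N = K * M
    rows, cols, vals = [], [], []

    def add(i, j, a):
        rows.append(j)
        cols.append(i)
        vals.append(a)
        rows.append(i)
        cols.append(i)
        vals.append(-a)

    index = {st: k for k, st in enumerate(states)}
    marange = np.arange(M)
    for (n, c), k in index.items():
        free = spec.n_tf - n - c
        base = k * M
        # occupancy moves act blockwise on the whole mRNA axis
        occ_moves = [
            ((n + 1, c), spec.k_on * free * (spec.n_promoters - n)),
            ((n - 1, c), spec.k_off * n),
            ((n, c + 1), spec.k_on_c * free * (spec.n_competitors - c)),
            ((n, c - 1), spec.k_off_c * c),
        ]
        for tgt, a in occ_moves:
            if a > 0 and tgt in index:
                tb = index[tgt] * M
                for m in range(M):
                    add(base + m, tb + m, a)
        R = _transcription_rate_aggregate(spec, n)
        if R > 0:
            for m in range(M - 1):  # transcription off the top row is frozen
                add(base + m, base + m + 1, R)
        for m in range(1, M):
            add(base + m, base + m - 1, spec.gamma * m)

    QT = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
    A = QT.tolil()
    A[N - 1, :] = 1.0
    b = np.zeros(N)
    b[N - 1] = 1.0
    p = spsolve(A.tocsr().tocsc(), b)
    return np.asarray(p).reshape(K, M)


def cme_steady_state(spec, m_max: int | None = None, tol: float = 1e-8, max_doublings: int = 6) -> CMEDistribution:
    """Exact steady state of the full (n, c, m) master equation.

    The mRNA axis is truncated at ``m_max`` (default: a saturation-based
    heuristic) and doubled until the mass held at the truncation boundary
    falls below ``tol``; failure after ``max_doublings`` raises
    :class:`TruncationError` reporting the achieved tail mass.
    """
    spec = validate_model(spec)
    if m_max is not None and m_max < 1:
        raise ValueError("m_max must be >= 1")
    m_max = default_m_max(spec) if m_max is None else int(m_max)
    states = _occupancy_states(spec)
    tail = math.inf
    for _ in range(max_doublings + 1):
        joint = _solve_truncated(spec, states, m_max)
        tail = float(joint[:, -1].sum())
        if tail < tol:
            return CMEDistribution(spec, states, m_max, joint, tail, tol)
        m_max *= 2
    raise TruncationError(
        f"tail mass {tail:.3e} still above tol={tol:g} at m_max={m_max // 2}"
    )


def _per_promoter_occupancy_chain(spec: ModelSpec):
    """States (s1, s2, c) and generator of the two-promoter binding chain."""
    states = []
    for s1 in (0, 1):
        for s2 in (0, 1):
            cmax = min(spec.n_competitors, spec.n_tf - s1 - s2)
            if s1 + s2 > spec.n_tf:
                continue
            for c in range(cmax + 1):
                states.append((s1, s2, c))
    index = {st: i for i, st in enumerate(states)}
    rows, cols, vals = [], [], []
    for (s1, s2, c), i in index.items():
        free = spec.n_tf - s1 - s2 - c
        moves = []
        if s1 == 0:
            moves.append(((1, s2, c), spec.k_on * free))
        else:
            moves.append(((0, s2, c), spec.k_off))
        if s2 == 0:
            moves.append(((s1, 1, c), spec.k_on * free))
        else:
            moves.append(((s1, 0, c), spec.k_off))
        moves.append(((s1, s2, c + 1), spec.k_on_c * free * (spec.n_competitors - c)))
        moves.append(((s1, s2, c - 1), spec.k_off_c * c))
        for tgt, a in moves:
            if a > 0 and tgt in index:
                rows.append(i)
                cols.append(index[tgt])
                vals.append(a)
                rows.append(i)
                cols.append(i)
                vals.append(-a)
    K = len(states)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(K, K)).tocsr()
    return states, Q


def cme_two_promoter_correlation(spec, max_states: int = 50_000) -> float:
    """Exact stationary Pearson correlation of the two promoters' mRNA counts.

    Requires ``n_promoters == 2``.  Solves the per-promoter occupancy chain
    ``(s1, s2, c)`` and then the closed linear systems for the conditional
    moments E[m_j | occupancy] and E[m_j m_k | occupancy]; the result is
    exact with no mRNA truncation because all mRNA propensities are linear.
    """
    spec = validate_model(spec)
    if spec.n_promoters != 2:
        raise ValueError("two-promoter correlation requires n_promoters == 2")
    states, Q = _per_promoter_occupancy_chain(spec)
    if len(states) > max_states:
        raise ValueError(f"occupancy chain has {len(states)} states (cap {max_states})")
    pi = _stationary(Q)
    gamma = spec.gamma
    K = len(states)
    QT = Q.T.tocsr()
    eye = sp.identity(K, format="csr")

    def rho(j):
        out = np.empty(K)
        for i, st in enumerate(states):
            s = st[j]
            if spec.mode is RegulationMode.ACTIVATOR:
                out[i] = spec.r * s + spec.r_basal * (1 - s)
            else:
                out[i] = spec.r * (1 - s)
        return out

    r1, r2 = rho(0), rho(1)
    A1 = (gamma * eye - QT).tocsc()
    x1 = spsolve(A1, r1 * pi)  # E[1_state * m1]
    x2 = spsolve(A1, r2 * pi)
    A2 = (2.0 * gamma * eye - QT).tocsc()
    y12 = spsolve(A2, r1 * x2 + r2 * x1)
    y11 = spsolve(A2, 2.0 * r1 * x1 + r1 * pi + gamma * x1)
    y22 = spsolve(A2, 2.0 * r2 * x2 + r2 * pi + gamma * x2)

    m1, m2 = float(x1.sum()), float(x2.sum())
    cov = float(y12.sum()) - m1 * m2
    v1 = float(y11.sum()) - m1 * m1
    v2 = float(y22.sum()) - m2 * m2
    if v1 <= 0 or v2 <= 0:
        return float("nan")
    return cov / math.sqrt(v1 * v2)


def total_variation(p, q) -> float:
    """Total variation distance 0.5 * sum |p - q| between two pmfs.

    The shorter support is padded with zeros; negative entries are rejected.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 1 or q.ndim != 1:
        raise ValueError("total_variation expects 1-D pmfs")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("pmf entries must be >= 0")
    L = max(len(p), len(q))
    p = np.pad(p, (0, L - len(p)))
    q = np.pad(q, (0, L - len(q)))
    return float(0.5 * np.abs(p - q).sum())
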