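"""Chains of coupled multi-state synapses: exact master equation vs pair closure.

Ns synapses sit along a dendrite; synapse i occupies one of K discrete
morphological states s_i in {0..K-1} and flips with rates
w(s_i <- s_i' | s_{i-1}, s_{i+1}) that depend on the states of its nearest
neighbours (boundary synapses see their single neighbour only).  The exact
joint master equation lives on K^Ns states and is only tractable for small
chains; the pair approximation closes the hierarchy at nearest-neighbour
pairs,

    P(s1..sN) ~ prod_i P(s_i, s_{i+1}) / prod_{i interior} P(s_i),

yielding a coupled ODE system for the Ns*K singles and (Ns-1)*K^2 pair
tables (K(K+1)Ns/2 independent components after normalization and marginal
constraints).  Three-site probabilities appearing in the flip fluxes are
closed as P(l, m) P(m, r) / P(m).

On top of the dynamics the module provides the learning bookkeeping: the
rate of KL divergence from a reference steady state (information gain/loss
during LTP) and the per-synapse entropy production, whose total times the
per-synapse energy scale E0 (~1e5 kBT) is the physical energy cost rate of
plasticity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .core_markov import ProbTrajectory, RateMatrix, evolve_master

logger = logging.getLogger("neurotherm.pair_approx")

__all__ = [
    "ChainModel",
    "PairDistribution",
    "build_joint_rate_matrix",
    "exact_evolve",
    "pair_evolve",
    "reconstruct_joint",
    "info_gain_rate",
    "entropy_production",
    "stationary_pair",
]

EXACT_STATE_CAP = 65536
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ChainModel:
    """Ns synapses with K states and neighbour-dependent flip rates.

    ``rate(i, s_to, s_from, left, right)`` returns the rate (1/time) of the
    flip s_from -> s_to in synapse i given neighbour states; ``left`` is None
    for i == 0 and ``right`` is None for i == Ns-1.  The callable must be
    deterministic and side-effect free; its values are tabulated once.
    """

    Ns: int
    K: int
    rate: Callable[[int, int, int, Optional[int], Optional[int]], float]
    E0: float = 1e5  # per-synapse energy scale in kB*T units

    # cached rate tables, filled lazily
    _tables: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.Ns < 1 or self.K < 2:
            raise ValueError("need Ns >= 1 and K >= 2")

    def _table(self, i: int) -> np.ndarray:
        """Rate tensor for synapse i: interior (to, from, l, r); boundary (to, from, nb)."""
        if i in self._tables:
            return self._tables[i]
        K = self.K
        if self.Ns == 1:
            tab = np.zeros((K, K))
            for a in range(K):
                for b in range(K):
                    if a != b:
                        tab[a, b] = self.rate(i, a, b, None, None)
        elif i == 0:
            tab = np.zeros((K, K, K))
            for a in range(K):
                for b in range(K):
                    if a == b:
                        continue
                    for r in range(K):
                        tab[a, b, r] = self.rate(i, a, b, None, r)
        elif i == self.Ns - 1:
            tab = np.zeros((K, K, K))
            for a in range(K):
                for b in range(K):
                    if a == b:
                        continue
                    for l in range(K):
                        tab[a, b, l] = self.rate(i, a, b, l, None)
        else:
            tab = np.zeros((K, K, K, K))
            for a in range(K):
                for b in range(K):
                    if a == b:
                        continue
                    for l in range(K):
                        for r in range(K):
                            tab[a, b, l, r] = self.rate(i, a, b, l, r)
        if np.any(tab < 0):
            raise ValueError(f"negative rate for synapse {i}")
        self._tables[i] = tab
        return tab


@dataclass(frozen=True)
class PairDistribution:
    """Singles P_i(s) (Ns, K) and nearest-neighbour pairs P_{i,i+1}(s, s') (Ns-1, K, K)."""

    singles: np.ndarray
    pairs: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.singles, dtype=float)
        p = np.asarray(self.pairs, dtype=float)
        if s.ndim != 2:
            raise ValueError("singles must be (Ns, K)")
        ns, k = s.shape
        if ns > 1 and p.shape != (ns - 1, k, k):
            raise ValueError("pairs must be (Ns-1, K, K)")
        object.__setattr__(self, "singles", s)
        object.__setattr__(self, "pairs", p)

    @property
    def Ns(self) -> int:
        return self.singles.shape[0]

    @property
    def K(self) -> int:
        return self.singles.shape[1]

    def validate(self, tol: float = 1e-8) -> None:
        """Raise on bad normalization or marginal inconsistency (> tol)."""
        if np.abs(self.singles.sum(axis=1) - 1.0).max() > tol:
            raise ValueError("single-site tables not normalized")
        if self.Ns > 1 and np.abs(self.pairs.sum(axis=(1, 2)) - 1.0).max() > tol:
            raise ValueError("pair tables not normalized")
        err = self.marginal_mismatch()
        if err > tol:
            raise ValueError(f"pair/single marginal mismatch {err:.3g} exceeds {tol:.3g}")

    def marginal_mismatch(self) -> float:
        """Max abs deviation between pair marginals and the stored singles."""
        if self.Ns == 1:
            return 0.0
        left = np.abs(self.pairs.sum(axis=2) - self.singles[:-1]).max()
        right = np.abs(self.pairs.sum(axis=1) - self.singles[1:]).max()
        return float(max(left, right))

    @classmethod
    def from_joint(cls, joint: np.ndarray, Ns: int, K: int) -> "PairDistribution":
        """Marginalize a full joint table (shape (K,)*Ns or flat) down to pairs."""
        j = np.asarray(joint, dtype=float).reshape((K,) * Ns)
        singles = np.empty((Ns, K))
        for i in range(Ns):
            singles[i] = j.sum(axis=tuple(a for a in range(Ns) if a != i))
        pairs = np.empty((max(Ns - 1, 0), K, K))
        for i in range(Ns - 1):
            pairs[i] = j.sum(axis=tuple(a for a in range(Ns) if a not in (i, i + 1)))
        return cls(singles, pairs)

    @classmethod
    def product(cls, marginals: np.ndarray) -> "PairDistribution":
        """Independent-synapse distribution from per-site marginals (Ns, K)."""
        m = np.asarray(marginals, dtype=float)
        ns = m.shape[0]
        pairs = np.stack([np.outer(m[i], m[i + 1]) for i in range(ns - 1)]) if ns > 1 else np.zeros((0, m.shape[1], m.shape[1]))
        return cls(m.copy(), pairs)


# ---------------------------------------------------------------------------
# exact dynamics (small chains)
# ---------------------------------------------------------------------------


def build_joint_rate_matrix(chain: ChainModel) -> RateMatrix:
    """Flattened single-flip generator on the full K^Ns product space."""
    n_states = chain.K**chain.Ns
    if n_states > EXACT_STATE_CAP:
        raise ValueError(
            f"K^Ns = {n_states} exceeds the exact-solver cap {EXACT_STATE_CAP}; "
            "use pair_evolve for large chains"
        )
    states = list(itertools.product(range(chain.K), repeat=chain.Ns))
    index = {s: n for n, s in enumerate(states)}
    w = np.zeros((n_states, n_states))
    for s in states:
        for i in range(chain.Ns):
            left = s[i - 1] if i > 0 else None
            right = s[i + 1] if i < chain.Ns - 1 else None
            for b in range(chain.K):
                if b == s[i]:
                    continue
                r = chain.rate(i, b, s[i], left, right)
                if r:
                    dst = s[:i] + (b,) + s[i + 1 :]
                    w[index[dst], index[s]] = w[index[dst], index[s]] + r
    return RateMatrix(tuple(states), w)


def exact_evolve(chain: ChainModel, p0_joint: np.ndarray, times) -> ProbTrajectory:
    """Exact master-equation solution on the flattened product space."""
    rm = build_joint_rate_matrix(chain)
    return evolve_master(rm, np.ravel(p0_joint), times)


# ---------------------------------------------------------------------------
# pair-approximate dynamics
# ---------------------------------------------------------------------------


def _pair_rhs(chain: ChainModel, singles: np.ndarray, pairs: np.ndarray):
    """Time derivatives of singles and pairs under the pair closure."""
    Ns, K = singles.shape
    dS = np.zeros_like(singles)
    dP = np.zeros_like(pairs)

    safe = np.where(singles > P_FLOOR, singles, 1.0)
    valid = singles > P_FLOOR
    # Q[i, m, r] = P_{i,i+1}(m, r) / P_i(m), zero where the single vanishes
    if Ns > 1:
        Q = np.where(valid[:-1, :, None], pairs / safe[:-1, :, None], 0.0)

    if Ns == 1:
        tab = chain._table(0)  # (to, from)
        flux = tab * singles[0][None, :]
        dS[0] = flux.sum(axis=1) - flux.sum(axis=0)
        return dS, dP

    for i in range(Ns):
        tab = chain._table(i)
        if i == 0:
            # gain[a] = sum_{b,r} tab[a,b,r] P01(b,r); loss[b] = sum_{a,r} ...
            gain = np.einsum("abr,br->a", tab, pairs[0])
            dS[0] = gain - np.einsum("abr,br->b", tab, pairs[0])
        elif i == Ns - 1:
            gain = np.einsum("abl,lb->a", tab, pairs[Ns - 2])
            dS[i] = gain - np.einsum("abl,lb->b", tab, pairs[Ns - 2])
        else:
            # three-site closure T[l, m, r] = P(l,m) Q[i](m,r)
            T = pairs[i - 1][:, :, None] * Q[i][None, :, :]
            dS[i] = np.einsum("ablr,lbr->a", tab, T) - np.einsum("ablr,lbr->b", tab, T)

    for j in range(Ns - 1):
        # flips at site j (left member of the pair), right neighbour fixed = u
        tab = chain._table(j)
        if j == 0:
            gain = np.einsum("abu,bu->au", tab, pairs[0])
            loss = np.einsum("abu,bu->bu", tab, pairs[0])
            dP[0] += gain - loss
        else:
            # closure with pair (j-1, j): flux has P(l, s') Q[j](s', u)
            gain = np.einsum("ablu,lb,bu->au", tab, pairs[j - 1], Q[j])
            loss = np.einsum("ablu,lb,bu->bu", tab, pairs[j - 1], Q[j])
            dP[j] += gain - loss
        # flips at site j+1 (right member), left neighbour fixed = s
        tab = chain._table(j + 1)
        if j + 1 == Ns - 1:
            gain = np.einsum("abs,sb->sa", tab, pairs[j])
            loss = np.einsum("abs,sb->sb", tab, pairs[j])
            dP[j] += gain - loss
        else:
            gain = np.einsum("absr,sb,br->sa", tab, pairs[j], Q[j + 1])
            loss = np.einsum("absr,sb,br->sb", tab, pairs[j], Q[j + 1])
            dP[j] += gain - loss

    return dS, dP


def _ipf_project(singles: np.ndarray, pairs: np.ndarray, sweeps: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Restore marginal consistency: average the marginal estimates, then fit
    each pair table to the averaged targets by iterative proportional fitting."""
    Ns, K = singles.shape
    target = singles.copy()
    counts = np.ones(Ns)
    target[:-1] += pairs.sum(axis=2)
    counts[:-1] += 1
    target[1:] += pairs.sum(axis=1)
    counts[1:] += 1
    target /= counts[:, None]
    target = np.clip(target, 0.0, None)
    target /= target.sum(axis=1, keepdims=True)

    new_pairs = np.clip(pairs, 0.0, None)
    for j in range(Ns - 1):
        tab = new_pairs[j]
        tab = tab / max(tab.sum(), P_FLOOR)
        for _ in range(sweeps):
            rows = tab.sum(axis=1)
            tab = tab * np.where(rows > 0, target[j] / np.where(rows > 0, rows, 1.0), 0.0)[:, None]
            cols = tab.sum(axis=0)
            tab = tab * np.where(cols > 0, target[j + 1] / np.where(cols > 0, cols, 1.0), 0.0)[None, :]
            if abs(tab.sum(axis=1) - target[j]).max() < 1e-13:
                break
        new_pairs[j] = tab
    return target, new_pairs


def pair_evolve(
    chain: ChainModel,
    pd0: PairDistribution,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    consistency_tol: float = 1e-6,
) -> list[PairDistribution]:
    """Integrate the closed singles+pairs system on a time grid.

    Tables are renormalized after every output segment; if the pair/single
    marginal mismatch exceeds ``consistency_tol`` the distribution is
    projected back by iterative proportional fitting.
    """
    pd0.validate(tol=1e-6)
    times = np.asarray(times, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing and start at 0")
    Ns, K = pd0.Ns, pd0.K
    n_single = Ns * K

    def rhs(_t, y):
        singles = y[:n_single].reshape(Ns, K)
        pairs = y[n_single:].reshape(max(Ns - 1, 0), K, K)
        dS, dP = _pair_rhs(chain, singles, pairs)
        return np.concatenate([dS.ravel(), dP.ravel()])

    out = [PairDistribution(pd0.singles.copy(), pd0.pairs.copy())]
    y = np.concatenate([pd0.singles.ravel(), pd0.pairs.ravel()])
    for t0, t1 in zip(times[:-1], times[1:]):
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"pair-approximation integration failed: {sol.message}")
        y = sol.y[:, -1]
        singles = np.clip(y[:n_single].reshape(Ns, K), 0.0, None)
        pairs = np.clip(y[n_single:].reshape(max(Ns - 1, 0), K, K), 0.0, None)
        singles /= singles.sum(axis=1, keepdims=True)
        if Ns > 1:
            pairs /= pairs.sum(axis=(1, 2), keepdims=True)
        pd = PairDistribution(singles, pairs)
        if pd.marginal_mismatch() > consistency_tol:
            singles, pairs = _ipf_project(singles, pairs)
            pd = PairDistribution(singles, pairs)
        out.append(pd)
        y = np.concatenate([pd.singles.ravel(), pd.pairs.ravel()])
    return out


def reconstruct_joint(pd: PairDistribution) -> np.ndarray:
    """Pair-product estimate of the full joint table, shape (K,)*Ns.

    Exact whenever the true joint has nearest-neighbour (Markov-chain)
    dependence.  The result is renormalized if its total deviates from 1 by
    more than 1e-8 (deviation logged).
    """
    Ns, K = pd.Ns, pd.K
    if K**Ns > EXACT_STATE_CAP:
        raise ValueError("joint reconstruction capped at K^Ns <= %d" % EXACT_STATE_CAP)
    if Ns == 1:
        return pd.singles[0].copy()
    interior = pd.singles[1:-1]
    if np.any((interior <= 0) & (pd.pairs[:-1].sum(axis=1) > 0)):
        raise ValueError("zero interior single with nonzero adjacent pair mass")
    joint = pd.pairs[0]
    for i in range(1, Ns - 1):
        safe = np.where(pd.singles[i] > P_FLOOR, pd.singles[i], 1.0)
        cond = np.where(
            (pd.singles[i] > P_FLOOR)[:, None], pd.pairs[i] / safe[:, None], 0.0
        )
        # extend the chain product: joint(s1..si) * P(s_{i+1} | s_i)
        joint = joint[..., :, None] * cond
    total = joint.sum()
    if abs(total - 1.0) > 1e-8:
        logger.info("reconstructed joint total deviates from 1 by %.3g; renormalizing", total - 1.0)
        joint = joint / total
    return joint


# ---------------------------------------------------------------------------
# information gain and entropy production
# ---------------------------------------------------------------------------


def _safe_log_ratio(num: float, den: float) -> float:
    if num <= 0.0 or den <= 0.0:
        return 0.0 if num == den else (math.inf if den <= 0.0 else -math.inf)
    return math.log(num / den)


def info_gain_rate(chain: ChainModel, pd: PairDistribution, pd_ss: PairDistribution) -> float:
    """Rate of KL divergence between the current and steady-state pair laws.

    Positive while learning drives the chain away from the reference steady
    state, negative during forgetting, exactly zero at pd == pd_ss.
    """
    if pd.singles.shape != pd_ss.singles.shape:
        raise ValueError("mismatched shapes between pd and pd_ss")
    Ns, K = pd.Ns, pd.K
    if Ns == 1:
        tab = chain._table(0)
        total = 0.0
        for a in range(K):
            for b in range(K):
                flux = tab[a, b] * pd.singles[0][b] - tab[b, a] * pd.singles[0][a]
                total += flux * _safe_log_ratio(pd.singles[0][a], pd_ss.singles[0][a])
        return total

    total = 0.0
    # boundary synapse 0: flips at site 1 of pair (0, 1)
    tab = chain._table(0)
    for a in range(K):
        for b in range(K):
            if a == b:
                continue
            for r in range(K):
                flux = tab[a, b, r] * pd.pairs[0][b, r] - tab[b, a, r] * pd.pairs[0][a, r]
                total += flux * _safe_log_ratio(pd.pairs[0][a, r], pd_ss.pairs[0][a, r])
    # boundary synapse Ns-1
    tab = chain._table(Ns - 1)
    for a in range(K):
        for b in range(K):
            if a == b:
                continue
            for l in range(K):
                flux = tab[a, b, l] * pd.pairs[Ns - 2][l, b] - tab[b, a, l] * pd.pairs[Ns - 2][l, a]
                total += flux * _safe_log_ratio(pd.pairs[Ns - 2][l, a], pd_ss.pairs[Ns - 2][l, a])
    # interior synapses: closure fluxes and the pair-product log weight
    for i in range(1, Ns - 1):
        tab = chain._table(i)
        for a in range(K):
            for b in range(K):
                if a == b:
                    continue
                for l in range(K):
                    for r in range(K):
                        num_b = pd.pairs[i - 1][l, b] * pd.pairs[i][b, r]
                        num_a = pd.pairs[i - 1][l, a] * pd.pairs[i][a, r]
                        sb = pd.singles[i][b]
                        sa = pd.singles[i][a]
                        fa = tab[a, b, l, r] * (num_b / sb if sb > P_FLOOR else 0.0)
                        fb = tab[b, a, l, r] * (num_a / sa if sa > P_FLOOR else 0.0)
                        flux = fa - fb
                        if flux == 0.0:
                            continue
                        num = pd.pairs[i - 1][l, a] * pd.pairs[i][a, r] * pd_ss.singles[i][a]
                        den = (
                            pd_ss.pairs[i - 1][l, a] * pd_ss.pairs[i][a, r] * pd.singles[i][a]
                        )
                        total += flux * _safe_log_ratio(num, den)
    return total


def entropy_production(
    chain: ChainModel, pd: PairDistribution
) -> tuple[float, np.ndarray, float]:
    """(total S_pr, per-synapse array, energy cost rate E0 * S_pr in kB*T/time)."""
    Ns, K = pd.Ns, pd.K
    per = np.zeros(Ns)

    def accumulate(i, a_flux, b_flux):
        if a_flux == 0.0 and b_flux == 0.0:
            return 0.0
        if a_flux <= 0.0 or b_flux <= 0.0:
            return math.inf
        return 0.5 * (a_flux - b_flux) * math.log(a_flux / b_flux)

    if Ns == 1:
        tab = chain._table(0)
        for a in range(K):
            for b in range(K):
                if a == b:
                    continue
                per[0] += accumulate(0, tab[a, b] * pd.singles[0][b], tab[b, a] * pd.singles[0][a])
        total = float(per.sum())
        return total, per, chain.E0 * total

    tab = chain._table(0)
    for a in range(K):
        for b in range(K):
            if a == b:
                continue
            for r in range(K):
                per[0] += accumulate(
                    0,
                    tab[a, b, r] * pd.pairs[0][b, r],
                    tab[b, a, r] * pd.pairs[0][a, r],
                )
    tab = chain._table(Ns - 1)
    for a in range(K):
        for b in range(K):
            if a == b:
                continue
            for l in range(K):
                per[Ns - 1] += accumulate(
                    Ns - 1,
                    tab[a, b, l] * pd.pairs[Ns - 2][l, b],
                    tab[b, a, l] * pd.pairs[Ns - 2][l, a],
                )
    for i in range(1, Ns - 1):
        tab = chain._table(i)
        for a in range(K):
            for b in range(K):
                if a == b:
                    continue
                for l in range(K):
                    for r in range(K):
                        sb, sa = pd.singles[i][b], pd.singles[i][a]
                        fa = tab[a, b, l, r] * (
                            pd.pairs[i - 1][l, b] * pd.pairs[i][b, r] / sb
                            if sb > P_FLOOR
                            else 0.0
                        )
                        fb = tab[b, a, l, r] * (
                            pd.pairs[i - 1][l, a] * pd.pairs[i][a, r] / sa
                            if sa > P_FLOOR
                            else 0.0
                        )
                        per[i] += accumulate(i, fa, fb)
    total = float(per.sum())
    return total, per, chain.E0 * total


def stationary_pair(
    chain: ChainModel, pd0: PairDistribution, t_relax: float, n_checks: int = 4
) -> PairDistribution:
    """Relax the pair dynamics until the RHS is numerically stationary."""
    pd = pd0
    for _ in range(n_checks):
        pd = pair_evolve(chain, pd, np.array([0.0, t_relax]))[-1]
        dS, dP = _pair_rhs(chain, pd.singles, pd.pairs)
        if max(np.abs(dS).max(), np.abs(dP).max() if dP.size else 0.0) < 1e-10:
            break
    return pd
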