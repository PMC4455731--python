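"""Discrete-character evolution on trees: Mk fitting and stochastic mapping.

A character evolves by a continuous-time Markov chain with instantaneous
rate matrix Q (rows sum to zero, off-diagonals >= 0). The tip-data
likelihood is computed by the pruning algorithm; Q is fitted by maximum
likelihood over log-rates (ER: one shared rate; ARD: one rate per directed
transition). Stochastic character maps draw full branch-by-branch state
histories conditional on the tip data: node states from their joint
conditional distribution, then each branch path from the endpoint-conditioned
CTMC via uniformization, which is exact at any rate magnitude (no rejection).
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .trees import PhyloTree

__all__ = [
    "QMatrix", "DiscreteCharacter", "CharacterHistory", "MapSummary", "QFit",
    "transition_probability", "pruning_loglik", "fit_q", "sample_history",
    "sample_histories", "summarize_maps", "read_character_csv",
    "history_to_simmap_newick",
]


@dataclasses.dataclass(frozen=True)
class QMatrix:
    """Instantaneous rate matrix bound to an ordered state set."""
    rates: np.ndarray
    states: tuple[str, ...]

    def __post_init__(self):
        Q = np.asarray(self.rates, float)
        k = len(self.states)
        if Q.shape != (k, k):
            raise ValueError("Q shape does not match state count")
        off = Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.abs(Q.sum(axis=1)).max() > 1e-12:
            raise ValueError("Q rows must sum to 0")
        object.__setattr__(self, "rates", Q)

    @classmethod
    def binary(cls, forward: float, backward: float,
               states: Sequence[str] = ("0", "1")) -> "QMatrix":
        return cls(np.array([[-forward, forward], [backward, -backward]]),
                   tuple(states))

    @property
    def k(self) -> int:
        return len(self.states)

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left null vector of Q, normalized)."""
        w, V = np.linalg.eig(self.rates.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(V[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclasses.dataclass(frozen=True)
class DiscreteCharacter:
    """Taxon -> state assignment over an ordered state set."""
    data: dict[str, str]
    states: tuple[str, ...]

    @classmethod
    def from_dict(cls, data: Mapping[str, str],
                  states: Sequence[str] | None = None) -> "DiscreteCharacter":
        if states is None:
            states = tuple(sorted(set(data.values())))
        bad = set(data.values()) - set(states)
        if bad:
            raise ValueError(f"states not in state set: {sorted(bad)}")
        return cls(dict(data), tuple(states))

    def state_indices(self, taxa: Sequence[str]) -> np.ndarray:
        missing = [t for t in taxa if t not in self.data]
        if missing:
            raise ValueError(f"taxa without character state: {missing}")
        lut = {s: i for i, s in enumerate(self.states)}
        return np.array([lut[self.data[t]] for t in taxa], dtype=int)


def read_character_csv(path: str, taxon_col: str = "taxon",
                       state_col: str | None = None) -> DiscreteCharacter:
    df = pd.read_csv(path)
    if state_col is None:
        state_col = [c for c in df.columns if c != taxon_col][0]
    return DiscreteCharacter.from_dict(
        dict(zip(df[taxon_col].astype(str), df[state_col].astype(str))))


# --------------------------------------------------------------------- #
# CTMC kernel
# --------------------------------------------------------------------- #

def transition_probability(Q: QMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1."""
    Qm = Q.rates if isinstance(Q, QMatrix) else np.asarray(Q, float)
    if t < 0:
        raise ValueError("t must be >= 0")
    return scipy.linalg.expm(Qm * t)


def _branch_probs(Qm: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) for every t in ts, via eigendecomposition with expm fallback."""
    k = Qm.shape[0]
    try:
        w, V = np.linalg.eig(Qm)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(ts, w))           # (m, k)
        P = np.einsum("ij,mj,jl->mil", V, E, Vinv)
        P = np.real(P)
        check = scipy.linalg.expm(Qm * ts.max()) if len(ts) else None
        if check is not None and \
                np.abs(P[np.argmax(ts)] - check).max() > 1e-8:
            raise np.linalg.LinAlgError("eig reconstruction inaccurate")
    except np.linalg.LinAlgError:
        P = np.stack([scipy.linalg.expm(Qm * t) for t in ts])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    P[ts == 0] = np.eye(k)
    return P


def _root_prior_vec(mode, Q: QMatrix, partial_root: np.ndarray | None = None):
    if isinstance(mode, (list, tuple, np.ndarray)):
        pi = np.asarray(mode, float)
    elif mode == "flat":
        pi = np.full(Q.k, 1.0 / Q.k)
    elif mode == "stationary":
        pi = Q.stationary()
    elif mode == "fitzjohn":
        if partial_root is None:
            raise ValueError("fitzjohn prior needs root partials")
        pi = partial_root / partial_root.sum()
    else:
        raise ValueError(f"unknown root prior {mode!r}")
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("root prior must be a distribution")
    return pi


def _pruning(tree: PhyloTree, tip_states: np.ndarray, Q: QMatrix):
    """Per-node scaled conditional likelihoods, log-scalers, branch P(t)."""
    k = Q.k
    P = _branch_probs(Q.rates, tree.blen)
    L = np.zeros((tree.n_nodes, k))
    logscale = 0.0
    for i in tree.postorder:
        if not tree.children[i]:
            L[i, tip_states[i]] = 1.0
            continue
        li = np.ones(k)
        for c in tree.children[i]:
            li *= P[c] @ L[c]
        m = li.max()
        if m <= 0:
            return L, -np.inf, P
        L[i] = li / m
        logscale += np.log(m)
    return L, logscale, P


def pruning_loglik(tree: PhyloTree, char: DiscreteCharacter,
                   Q: QMatrix, root_prior="flat") -> float:
    """Log tip-data likelihood by post-order pruning with per-node rescaling."""
    tip_states = char.state_indices(tree.tip_labels)
    L, logscale, _ = _pruning(tree, tip_states, Q)
    if not np.isfinite(logscale):
        return -np.inf
    pi = _root_prior_vec(root_prior, Q, L[tree.root])
    lik = float(pi @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


# --------------------------------------------------------------------- #
# ML fit
# --------------------------------------------------------------------- #

@dataclasses.dataclass
class QFit:
    Q: QMatrix
    loglik: float
    converged: bool
    model: str
    root_prior: object
    n_starts: int
    start_logliks: list[float]


def _q_from_params(theta: np.ndarray, k: int, model: str) -> np.ndarray:
    rates = np.exp(theta)
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    else:  # ARD
        Q[~np.eye(k, dtype=bool)] = rates
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_q(tree: PhyloTree, char: DiscreteCharacter, model: str = "ARD",
          root_prior="flat", n_starts: int = 5, seed: int = 0,
          bounds: tuple[float, float] = (-11.5, 7.0)) -> QFit:
    """Maximum-likelihood Q by bounded multi-start optimization of log-rates.

    ER shares one rate; ARD has one free rate per directed transition (two
    for a binary character). Starts mix a parsimony-informed guess (observed
    state changes per unit tree length) with seeded log-uniform draws.
    """
    if model not in ("ER", "ARD"):
        raise ValueError(f"unknown model {model!r}")
    k = len(char.states)
    if len(set(char.data[t] for t in tree.tip_labels)) < 2:
        raise ValueError("character is constant on the tree; Q not identifiable")
    npar = 1 if model == "ER" else k * (k - 1)
    tip_states = char.state_indices(tree.tip_labels)

    def neg(theta):
        Q = QMatrix(_q_from_params(theta, k, model), char.states)
        return -pruning_loglik(tree, char, Q, root_prior)

    rng = np.random.default_rng(seed)
    guess = np.log(max(len(set(tip_states)) - 1, 1) /
                   max(tree.total_length(), 1e-9))
    starts = [np.full(npar, guess), np.full(npar, guess + 1.5)]
    while len(starts) < n_starts:
        starts.append(rng.uniform(guess - 3.0, guess + 3.0, size=npar))

    best, lls = None, []
    for x0 in starts[:n_starts]:
        res = scipy.optimize.minimize(
            neg, np.clip(x0, *bounds), method="L-BFGS-B",
            bounds=[bounds] * npar)
        lls.append(-res.fun)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"Q optimization failed in all {n_starts} starts; "
            f"logliks reached: {lls}")
    Q = QMatrix(_q_from_params(best.x, k, model), char.states)
    return QFit(Q=Q, loglik=float(-best.fun), converged=True, model=model,
                root_prior=root_prior, n_starts=n_starts, start_logliks=lls)


# --------------------------------------------------------------------- #
# Stochastic maps
# --------------------------------------------------------------------- #

@dataclasses.dataclass
class CharacterHistory:
    """One full state painting of the tree.

    ``segments[i]`` is the ordered (state_index, duration) list on the branch
    subtending node i, from the parent end to the node; the root's entry is a
    single zero-length segment in the root state. Durations sum to the branch
    length and the last segment's state equals ``node_states[i]``.
    """
    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]
    states: tuple[str, ...]

    @property
    def n_transitions(self) -> int:
        return sum(len(s) - 1 for s in self.segments)

    def transition_counts(self) -> np.ndarray:
        k = len(self.states)
        counts = np.zeros((k, k), dtype=int)
        for segs in self.segments:
            for (a, _), (b, _) in zip(segs[:-1], segs[1:]):
                counts[a, b] += 1
        return counts

    def state_times(self) -> np.ndarray:
        times = np.zeros(len(self.states))
        for segs in self.segments:
            for s, d in segs:
                times[s] += d
        return times


def _sample_path(Qm: np.ndarray, a: int, b: int, t: float,
                 rng: np.random.Generator, Pt_ab: float,
                 max_jumps: int = 10000) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on one branch, by uniformization.

    The jump count is drawn from its exact conditional distribution under
    the uniformized chain, intermediate states from the conditioned DTMC,
    and jump times as uniform order statistics; virtual (self) jumps are
    collapsed into the flanking segments.
    """
    if t <= 0:
        if a != b:
            raise ValueError("state change on zero-length branch")
        return [(a, 0.0)]
    k = Qm.shape[0]
    mu = 1.05 * max(-Qm.diagonal().min(), 1e-12)
    R = np.eye(k) + Qm / mu
    # draw the number of (possibly virtual) jumps
    u = rng.random()
    Rpow = [np.eye(k)]
    w = np.exp(-mu * t)       # Poisson(mu t) pmf at n, built iteratively
    cum, n = 0.0, 0
    while n < max_jumps:
        cum += w * Rpow[n][a, b] / Pt_ab
        if u <= cum or (n > mu * t + 10 and cum >= 1.0 - 1e-12):
            break
        n += 1
        w *= mu * t / n
        Rpow.append(Rpow[-1] @ R)
    if n == 0:
        return [(a, t)]
    # conditioned DTMC states s_0 = a, ..., s_n = b
    states = [a]
    for j in range(1, n):
        probs = R[states[-1]] * Rpow[n - j][:, b]
        tot = probs.sum()
        if tot <= 0:
            raise RuntimeError("uniformization: dead-end DTMC state")
        states.append(int(rng.choice(k, p=probs / tot)))
    states.append(b)
    times = np.sort(rng.random(n)) * t
    bounds = np.concatenate([[0.0], times, [t]])
    segs: list[tuple[int, float]] = []
    for s, d in zip(states, np.diff(bounds)):
        if segs and segs[-1][0] == s:
            segs[-1] = (s, segs[-1][1] + d)
        else:
            segs.append((s, float(d)))
    return segs


def sample_history(tree: PhyloTree, char: DiscreteCharacter, Q: QMatrix,
                   root_prior="flat",
                   rng: np.random.Generator | int | None = None
                   ) -> CharacterHistory:
    """Draw one stochastic character map conditional on the tip data.

    Node states come from their joint conditional distribution (root from
    prior x conditional likelihood; each child given its parent from
    P(t)[parent, .] x child conditional likelihood); branch interiors from
    the endpoint-conditioned CTMC.
    """
    rng = np.random.default_rng(rng)
    tip_states = char.state_indices(tree.tip_labels)
    L, logscale, P = _pruning(tree, tip_states, Q)
    if not np.isfinite(logscale):
        raise ValueError("tip data impossible under this Q")
    pi = _root_prior_vec(root_prior, Q, L[tree.root])
    node_states = np.full(tree.n_nodes, -1, dtype=int)
    pr = pi * L[tree.root]
    node_states[tree.root] = int(rng.choice(Q.k, p=pr / pr.sum()))
    for i in tree.preorder:
        for c in tree.children[i]:
            probs = P[c][node_states[i]] * L[c]
            tot = probs.sum()
            if tot <= 0:
                raise RuntimeError("zero-probability node assignment")
            node_states[c] = int(rng.choice(Q.k, p=probs / tot))
    segments: list[list[tuple[int, float]]] = [None] * tree.n_nodes
    segments[tree.root] = [(int(node_states[tree.root]), 0.0)]
    for i in tree.preorder:
        for c in tree.children[i]:
            segments[c] = _sample_path(
                Q.rates, int(node_states[i]), int(node_states[c]),
                float(tree.blen[c]), rng,
                float(P[c][node_states[i], node_states[c]]))
    return CharacterHistory(node_states=node_states, segments=segments,
                            states=char.states)


def sample_histories(tree: PhyloTree, char: DiscreteCharacter, Q: QMatrix,
                     n: int = 100, root_prior="flat",
                     rng: np.random.Generator | int | None = None
                     ) -> list[CharacterHistory]:
    rng = np.random.default_rng(rng)
    return [sample_history(tree, char, Q, root_prior, rng) for _ in range(n)]


@dataclasses.dataclass
class MapSummary:
    """Transition-count and state-occupancy summaries across maps."""
    states: tuple[str, ...]
    n_maps: int
    per_type: dict[str, dict[str, float]]
    total_counts: dict[int, int]
    modal_total: int
    mean_total: float
    state_time_proportion: dict[str, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_maps(histories: Sequence[CharacterHistory]) -> MapSummary:
    """Distributions of per-type and total transition counts over maps.

    Accepts maps pooled across trees; the headline total is the modal count.
    State-time proportions are averaged over maps and sum to 1.
    """
    if not histories:
        raise ValueError("at least one history required")
    states = histories[0].states
    k = len(states)
    counts = np.stack([h.transition_counts() for h in histories])
    totals = counts.sum(axis=(1, 2))
    times = np.stack([h.state_times() for h in histories])
    prop = (times / times.sum(axis=1, keepdims=True)).mean(axis=0)
    per_type = {}
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            c = counts[:, a, b]
            per_type[f"{states[a]}->{states[b]}"] = {
                "mean": float(c.mean()), "median": float(np.median(c)),
                "q025": float(np.quantile(c, 0.025)),
                "q975": float(np.quantile(c, 0.975)),
            }
    uniq, freq = np.unique(totals, return_counts=True)
    return MapSummary(
        states=states, n_maps=len(histories), per_type=per_type,
        total_counts={int(u): int(f) for u, f in zip(uniq, freq)},
        modal_total=int(uniq[np.argmax(freq)]),
        mean_total=float(totals.mean()),
        state_time_proportion={s: float(p) for s, p in zip(states, prop)})


def history_to_simmap_newick(tree: PhyloTree, hist: CharacterHistory) -> str:
    """SIMMAP-annotated Newick: each branch as {state,dur:...}, parent->tip order."""
    def annot(i: int) -> str:
        parts = ":".join(f"{hist.states[s]},{d:.10g}"
                         for s, d in hist.segments[i])
        return "{" + parts + "}"

    def rec(i: int) -> str:
        if not tree.children[i]:
            s = tree.tip_labels[i]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[i]) + ")"
        if tree.parent[i] >= 0:
            s += ":" + annot(i)
        return s

    return rec(tree.root) + ";"
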