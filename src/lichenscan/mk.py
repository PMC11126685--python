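"""Binary-trait Mk model: likelihood, rate fitting, marginal ASR, event counts.

The model is a two-state continuous-time Markov chain on a rooted tree with
gain rate ``q01`` (0 -> 1) and loss rate ``q10`` (1 -> 0).  ER constrains
``q01 == q10``; ARD lets them differ.  Transition probabilities have the
closed form

    P00(t) = (q10 + q01 * exp(-(q01+q10) t)) / (q01 + q10),   P01 = 1 - P00
    P11(t) = (q01 + q10 * exp(-(q01+q10) t)) / (q01 + q10),   P10 = 1 - P11

Tip data are propagated root-ward with Felsenstein pruning (polytomies are
handled natively as products over children); marginal posteriors combine the
pruning pass with an outside pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .tree import PhyloTree

__all__ = [
    "MkModel",
    "AsrResult",
    "TransitionCount",
    "mk_loglik",
    "fit_mk",
    "compare_models",
    "asr_marginal",
    "count_transitions",
]

RATE_MIN = 1e-8
RATE_MAX = 1e3


class _ZeroLikelihood(ArithmeticError):
    """Tip configuration impossible under the model (zero-length conflicts)."""


@dataclass
class MkModel:
    """Two-state Mk model; ``kind`` is "ER" (q01 == q10) or "ARD"."""

    q01: float
    q10: float
    kind: str = "ARD"
    root_prior: str | tuple[float, float] = "uniform"

    def __post_init__(self):
        if self.kind not in ("ER", "ARD"):
            raise ValueError(f"kind must be ER or ARD, got {self.kind!r}")
        if self.kind == "ER" and self.q01 != self.q10:
            raise ValueError("ER model requires q01 == q10")
        for q in (self.q01, self.q10):
            if not (np.isfinite(q) and q > 0):
                raise ValueError(f"rates must be finite and positive, got {q}")
        if isinstance(self.root_prior, (tuple, list)):
            pi = tuple(float(p) for p in self.root_prior)
            if len(pi) != 2 or abs(sum(pi) - 1.0) > 1e-12 or min(pi) < 0:
                raise ValueError("custom root prior must be two non-negative values summing to 1")
            self.root_prior = pi
        elif self.root_prior not in ("uniform", "stationary"):
            raise ValueError(f"unknown root prior {self.root_prior!r}")

    def prior(self) -> np.ndarray:
        if self.root_prior == "uniform":
            return np.array([0.5, 0.5])
        if self.root_prior == "stationary":
            s = self.q01 + self.q10
            return np.array([self.q10 / s, self.q01 / s])
        return np.asarray(self.root_prior, dtype=float)

    def transition_probs(self, t: float) -> np.ndarray:
        """2x2 matrix P[i, j] = P(child = j | parent = i) over a branch of length t."""
        s = self.q01 + self.q10
        e = math.exp(-s * t)
        p00 = (self.q10 + self.q01 * e) / s
        p11 = (self.q01 + self.q10 * e) / s
        return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])

    @property
    def n_free_rates(self) -> int:
        return 1 if self.kind == "ER" else 2


@dataclass
class TransitionCount:
    n_gains: int
    n_losses: int
    gain_edges: list[int]
    loss_edges: list[int]

    def __iter__(self):
        return iter((self.n_gains, self.n_losses, self.gain_edges, self.loss_edges))


@dataclass
class AsrResult:
    """Fitted model, likelihood and (optionally) marginal reconstruction."""

    model: MkModel
    log_likelihood: float
    posteriors: np.ndarray | None = None  # per-node P(state = 1)
    node_states: np.ndarray | None = None
    n_gains: int | None = None
    n_losses: int | None = None
    gain_edges: list[int] = field(default_factory=list)
    loss_edges: list[int] = field(default_factory=list)
    ambiguous_nodes: list[int] = field(default_factory=list)
    boundary_fit: bool = False
    data_key: tuple = ()


def _check_trait(tree: PhyloTree, trait: dict[str, int]) -> np.ndarray:
    tips = tree.tip_indices()
    missing = [tree.labels[i] for i in tips if tree.labels[i] not in trait]
    if missing:
        raise ValueError(f"tips missing from trait vector: {missing}")
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    for i in tips:
        s = int(trait[tree.labels[i]])
        if s not in (0, 1):
            raise ValueError(f"trait for {tree.labels[i]!r} must be 0 or 1, got {s}")
        states[i] = s
    return states


def _pruning_partials(tree: PhyloTree, tip_states: np.ndarray, model: MkModel):
    """Down-pass conditional likelihoods.

    Returns (partials[n_nodes, 2], log_scale, P[n_nodes, 2, 2]) where
    ``partials[v, i] * exp(log_scale[v])`` is the likelihood of the data below
    ``v`` given state ``i`` at ``v``, and ``P[v]`` is the transition matrix on
    the branch above ``v``.
    """
    n = tree.n_nodes
    s = model.q01 + model.q10
    e = np.exp(-s * tree.lengths)
    P = np.empty((n, 2, 2))
    P[:, 0, 0] = (model.q10 + model.q01 * e) / s
    P[:, 0, 1] = 1.0 - P[:, 0, 0]
    P[:, 1, 1] = (model.q01 + model.q10 * e) / s
    P[:, 1, 0] = 1.0 - P[:, 1, 1]
    partials = np.empty((n, 2))
    log_scale = np.zeros(n)
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            st = tip_states[v]
            partials[v, 0] = 1.0 - st
            partials[v, 1] = st
            continue
        l0 = 1.0
        l1 = 1.0
        ls = 0.0
        for c in kids:
            m0 = P[c, 0, 0] * partials[c, 0] + P[c, 0, 1] * partials[c, 1]
            m1 = P[c, 1, 0] * partials[c, 0] + P[c, 1, 1] * partials[c, 1]
            l0 *= m0
            l1 *= m1
            ls += log_scale[c]
        scale = max(l0, l1)
        if scale <= 0:
            raise _ZeroLikelihood
        partials[v, 0] = l0 / scale
        partials[v, 1] = l1 / scale
        log_scale[v] = ls + math.log(scale)
    return partials, log_scale, P


def mk_loglik(tree: PhyloTree, trait: dict[str, int], model: MkModel) -> float:
    """Log-likelihood of binary tip states under the Mk model (nats)."""
    tip_states = _check_trait(tree, trait)
    try:
        partials, log_scale, _ = _pruning_partials(tree, tip_states, model)
    except _ZeroLikelihood:
        return -math.inf
    pi = model.prior()
    root = tree.root
    lik = pi[0] * partials[root, 0] + pi[1] * partials[root, 1]
    if lik == 0.0:
        return -math.inf
    return math.log(lik) + log_scale[root]


def fit_mk(
    tree: PhyloTree,
    trait: dict[str, int],
    kind: str = "ARD",
    root_prior: str | tuple[float, float] = "uniform",
) -> AsrResult:
    """Maximum-likelihood Mk rate fit (multi-start L-BFGS-B on log rates)."""
    tip_states = _check_trait(tree, trait)
    observed = set(int(s) for s in tip_states[tip_states >= 0])
    boundary = len(observed) < 2
    if boundary:
        warnings.warn(
            "all tips share one state; the unobserved transition rate is pinned "
            "at the lower bound",
            stacklevel=2,
        )

    def build(rates: np.ndarray) -> MkModel:
        if kind == "ER":
            q = float(np.clip(rates[0], RATE_MIN, RATE_MAX))
            return MkModel(q, q, kind="ER", root_prior=root_prior)
        q01, q10 = (float(np.clip(r, RATE_MIN, RATE_MAX)) for r in rates)
        return MkModel(q01, q10, kind="ARD", root_prior=root_prior)

    def negloglik(log_rates: np.ndarray) -> float:
        model = build(np.exp(log_rates))
        return -mk_loglik(tree, trait, model)

    height = max(tree.height(), 1e-6)
    ndim = 1 if kind == "ER" else 2
    bounds = [(math.log(RATE_MIN), math.log(RATE_MAX))] * ndim
    best = None
    for base in (0.1, 1.0, 10.0):
        x0 = np.full(ndim, math.log(base / height))
        x0 = np.clip(x0, bounds[0][0], bounds[0][1])
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        start_val = negloglik(x0)
        val = min(res.fun, start_val)
        cand = res.x if res.fun <= start_val else x0
        if best is None or val < best[0]:
            best = (val, cand)
    model = build(np.exp(best[1]))
    logl = mk_loglik(tree, trait, model)
    return AsrResult(
        model=model,
        log_likelihood=logl,
        boundary_fit=boundary,
        data_key=_data_key(tree, trait),
    )


def _data_key(tree: PhyloTree, trait: dict[str, int]) -> tuple:
    labs = tuple(sorted(tree.tip_labels))
    return (labs, tuple(int(trait[l]) for l in labs), tree.n_nodes)


@dataclass
class ModelSelection:
    delta_loglik: float
    lr_statistic: float
    p_value: float
    aic_er: float
    aic_ard: float
    retained: str


def compare_models(er: AsrResult, ard: AsrResult, tol: float = 1e-6) -> ModelSelection:
    """ER vs ARD selection by log-likelihood (LR test and AIC reported).

    Mirrors retaining the richer model when it improves the log-likelihood,
    with ER as the parsimony tie-break.
    """
    if er.model.kind != "ER" or ard.model.kind != "ARD":
        raise ValueError("arguments must be (ER fit, ARD fit)")
    if er.data_key and ard.data_key and er.data_key != ard.data_key:
        raise ValueError("ER and ARD fits were made on different tree/trait data")
    delta = ard.log_likelihood - er.log_likelihood
    if delta < -tol:
        raise ValueError(
            f"ARD log-likelihood {ard.log_likelihood} below ER {er.log_likelihood}: "
            "nested models — check the optimizer"
        )
    delta = max(delta, 0.0)
    lr = 2.0 * delta
    p = float(stats.chi2.sf(lr, df=1))
    aic_er = 2.0 * 1 - 2.0 * er.log_likelihood
    aic_ard = 2.0 * 2 - 2.0 * ard.log_likelihood
    retained = "ARD" if delta > tol else "ER"
    return ModelSelection(delta, lr, p, aic_er, aic_ard, retained)


def asr_marginal(tree: PhyloTree, trait: dict[str, int], model: MkModel) -> AsrResult:
    """Marginal ancestral state posteriors P(state = 1) for every node.

    The outside pass computes, for each node ``v``, the likelihood of all data
    outside the subtree of ``v`` given the state at ``v``; multiplying by the
    pruning partials and normalizing yields the marginal posterior.
    """
    if not (np.isfinite(model.q01) and np.isfinite(model.q10)):
        raise ValueError("model rates must be finite (fit or supply them)")
    tip_states = _check_trait(tree, trait)
    try:
        partials, log_scale, P = _pruning_partials(tree, tip_states, model)
    except _ZeroLikelihood as exc:
        raise ValueError("tip data impossible under the supplied model") from exc
    n = tree.n_nodes
    outside = np.empty((n, 2))
    root = tree.root
    outside[root] = model.prior()
    for v in tree.preorder():
        kids = tree.children[v]
        if not kids:
            continue
        # message from child c into v: M[c, i] = sum_j P[c, i, j] * partials[c, j]
        msgs = {}
        for c in kids:
            msgs[c] = P[c] @ partials[c]
        for c in kids:
            sib = np.ones(2)
            for s in kids:
                if s != c:
                    sib *= msgs[s]
            pre = outside[v] * sib  # likelihood above v, per state at v
            out_c = pre @ P[c]  # sum_i pre[i] * P[c, i, j]
            m = out_c.max()
            outside[c] = out_c / m if m > 0 else out_c
    joint = outside * partials
    post1 = joint[:, 1] / joint.sum(axis=1)
    pi = model.prior()
    lik = pi[0] * partials[root, 0] + pi[1] * partials[root, 1]
    logl = math.log(lik) + log_scale[root]
    result = AsrResult(
        model=model,
        log_likelihood=logl,
        posteriors=post1,
        data_key=_data_key(tree, trait),
    )
    tc = count_transitions(result, tree)
    result.node_states = _call_states(result, tree, 0.5)[0]
    result.n_gains, result.n_losses = tc.n_gains, tc.n_losses
    result.gain_edges, result.loss_edges = tc.gain_edges, tc.loss_edges
    return result


def _call_states(asr: AsrResult, tree: PhyloTree, threshold: float):
    post = asr.posteriors
    states = np.zeros(tree.n_nodes, dtype=np.int64)
    ambiguous: list[int] = []
    for v in tree.preorder():
        p = post[v]
        if p > threshold:
            states[v] = 1
        elif p < threshold:
            states[v] = 0
        else:
            ambiguous.append(v)
            par = tree.parent[v]
            states[v] = states[par] if par >= 0 else 0
    return states, ambiguous


def count_transitions(
    asr: AsrResult, tree: PhyloTree, threshold: float = 0.5
) -> TransitionCount:
    """Count gain (0 -> 1) and loss (1 -> 0) edges from thresholded posteriors.

    A node exactly at the threshold is flagged ambiguous and inherits its
    parent's call (the root defaults to 0).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if asr.posteriors is None:
        raise ValueError("AsrResult has no posteriors; run asr_marginal first")
    states, ambiguous = _call_states(asr, tree, threshold)
    asr.ambiguous_nodes = ambiguous
    gain_edges: list[int] = []
    loss_edges: list[int] = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if states[p] == 0 and states[v] == 1:
            gain_edges.append(v)
        elif states[p] == 1 and states[v] == 0:
            loss_edges.append(v)
    return TransitionCount(len(gain_edges), len(loss_edges), gain_edges, loss_edges)
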