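"""Correlated-evolution screening of binary traits on a species tree.

Orthogroup presence/absence across species is modelled as a binary trait
evolving by a continuous-time Markov chain along the branches of a rooted
species tree.  For each pair of traits two models are compared:

* **independent** — each trait gains and loses independently; four free
  rates (gain and loss per trait).
* **dependent** — the two traits form a four-state chain over
  ``{00, 01, 10, 11}`` in which each trait's gain and loss rates may
  depend on the current state of the partner; eight free rates, with
  simultaneous changes of both traits given rate zero.

The independent model is nested in the dependent one, so the dependent
maximum log-likelihood can never be lower.  Model support is compared by
AICc (sample size = number of species) and a pair is called coevolving
when the dependent model is better by at least ``delta_threshold`` AICc
units (default 2).

Likelihoods are computed by Felsenstein's pruning algorithm with
per-branch transition matrices ``exp(Q t)``; the two-state matrix
exponential is closed-form, the four-state one uses an eigendecomposition
of the rate matrix with a `scipy.linalg.expm` fallback when the
eigenbasis is ill-conditioned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import SpeciesTree

__all__ = [
    "CtmcRates",
    "CoevoConfig",
    "FitResult",
    "AiccScore",
    "CoevolutionResult",
    "TraitMatrix",
    "prune_loglik",
    "fit_model",
    "aicc",
    "screen_pairs",
    "traits_from_orthogroups",
]

NEG_INF = float("-inf")

# 4-state pair chain: state s = 2*x + y over (x, y) in {0,1}^2
PAIR_STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]

#: Free-rate order for the dependent model:
#: (00->01, 00->10, 01->00, 01->11, 10->00, 10->11, 11->01, 11->10)
DEPENDENT_TRANSITIONS = [
    (0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2),
]


@dataclass
class CtmcRates:
    """Rates of a binary-trait (or trait-pair) Markov chain.

    ``model`` is one of:

    * ``"single"`` — one trait, rates ``(q01, q10)``.
    * ``"independent"`` — trait pair, rates ``(x01, x10, y01, y10)``.
    * ``"dependent"`` — trait pair, eight rates in the order of
      :data:`DEPENDENT_TRANSITIONS`.
    """

    model: str
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        expected = {"single": 2, "independent": 4, "dependent": 8}
        if self.model not in expected:
            raise ValueError(f"unknown model {self.model!r}")
        if self.rates.shape != (expected[self.model],):
            raise ValueError(
                f"{self.model} model needs {expected[self.model]} rates, "
                f"got shape {self.rates.shape}"
            )
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_states(self) -> int:
        return 2 if self.model == "single" else 4

    @property
    def k(self) -> int:
        """Free-parameter count."""
        return self.rates.size

    def q_matrix(self) -> np.ndarray:
        if self.model == "single":
            a, b = self.rates
            return np.array([[-a, a], [b, -b]])
        if self.model == "independent":
            return CtmcRates("dependent", independent_to_dependent(self.rates)).q_matrix()
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.rates, DEPENDENT_TRANSITIONS):
            Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def independent_to_dependent(rates4: np.ndarray) -> np.ndarray:
    """Embed independent-model rates into the 8-rate dependent space.

    Each trait's gain/loss rate is copied to both partner-state contexts,
    which makes the dependent chain exactly the product of the two
    independent chains.
    """
    x01, x10, y01, y10 = np.asarray(rates4, dtype=float)
    # order: 00->01(y gain), 00->10(x gain), 01->00(y loss), 01->11(x gain),
    #        10->00(x loss), 10->11(y gain), 11->01(x loss), 11->10(y loss)
    return np.array([y01, x01, y10, x01, x10, y01, x10, y10])


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """``exp(Q t)`` for every branch length, shape (n_branch, k, k)."""
    k = Q.shape[0]
    if k == 2:
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        P = np.empty((len(lengths), 2, 2))
        if s == 0:
            P[:] = np.eye(2)
            return P
        p1 = a / s  # stationary probability of state 1
        p0 = b / s
        e = np.exp(-s * lengths)
        P[:, 0, 0] = p0 + p1 * e
        P[:, 0, 1] = p1 - p1 * e
        P[:, 1, 0] = p0 - p0 * e
        P[:, 1, 1] = p1 + p0 * e
        return P
    # general case: eigendecompose once, exponentiate eigenvalues per branch
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(lengths, w))  # (n, k)
        P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
        # validate the eigenbasis reconstruction; rows of exp(Qt) sum to 1
        if (np.abs(P.imag).max() < 1e-10
                and np.abs(P.real.sum(axis=2) - 1.0).max() < 1e-9):
            P = P.real
            np.clip(P, 0.0, 1.0, out=P)
            return P
    except np.linalg.LinAlgError:
        pass
    P = np.stack([expm(Q * t) for t in lengths])
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _root_prior(prior, n_states: int, Q: np.ndarray | None = None) -> np.ndarray:
    if isinstance(prior, str):
        if prior == "flat":
            return np.full(n_states, 1.0 / n_states)
        if prior == "stationary":
            if Q is None:
                raise ValueError("stationary prior requires a rate matrix")
            # left null vector of Q
            w, V = np.linalg.eig(Q.T)
            i = int(np.argmin(np.abs(w)))
            pi = np.abs(V[:, i].real)
            return pi / pi.sum()
        raise ValueError(f"unknown root prior {prior!r}")
    pi = np.asarray(prior, dtype=float)
    if pi.shape != (n_states,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("root prior must be a probability vector over the states")
    return pi


def _tip_state_array(tree: SpeciesTree, tip_states) -> np.ndarray:
    idx = tree.index()
    out = np.empty(idx.n_nodes, dtype=int)
    out.fill(-1)
    if isinstance(tip_states, dict):
        missing = set(idx.tip_index) - set(tip_states)
        if missing:
            raise ValueError(f"tip states missing for: {sorted(missing)}")
        for label, i in idx.tip_index.items():
            out[i] = int(tip_states[label])
    else:
        states = np.asarray(tip_states, dtype=int)
        labels = tree.tip_labels
        if states.shape != (len(labels),):
            raise ValueError("tip-state vector length must equal tip count")
        for label, s in zip(labels, states):
            out[idx.tip_index[label]] = s
    return out


def _loglik_arrays(idx, states: np.ndarray, Q: np.ndarray, pi: np.ndarray) -> float:
    """Pruning likelihood over the indexed tree, batched level by level."""
    n_states = Q.shape[0]
    P = _transition_matrices(Q, idx.edge_length)
    partial = np.zeros((idx.n_nodes, n_states))
    tips = states >= 0
    partial[np.flatnonzero(tips), states[tips]] = 1.0
    logscale = 0.0
    for nodes, kids, n_pos in idx.levels():
        down = np.einsum("nij,nj->ni", P[kids], partial[kids])
        L = down.reshape(n_pos, len(nodes), n_states).prod(axis=0)
        m = L.max(axis=1)
        if np.any(m <= 0.0):
            return NEG_INF
        partial[nodes] = L / m[:, None]
        logscale += float(np.log(m).sum())
    site = float(pi @ partial[idx.root])
    if site <= 0.0:
        return NEG_INF
    return logscale + np.log(site)


def _batched_q(model: str, rates: np.ndarray) -> np.ndarray:
    """Rate matrices for a stack of rate vectors, shape (M, k, k)."""
    M = rates.shape[0]
    if model == "single":
        Q = np.zeros((M, 2, 2))
        Q[:, 0, 1] = rates[:, 0]
        Q[:, 1, 0] = rates[:, 1]
    else:
        Q = np.zeros((M, 4, 4))
        for col, (i, j) in enumerate(DEPENDENT_TRANSITIONS):
            Q[:, i, j] = rates[:, col]
    d = Q.sum(axis=2)
    for s in range(Q.shape[1]):
        Q[:, s, s] = -d[:, s]
    return Q


def _batched_transition(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """``exp(Q_m t_b)`` for a stack of rate matrices, shape (M, B, k, k)."""
    M, k, _ = Q.shape
    B = len(lengths)
    if k == 2:
        a, b = Q[:, 0, 1], Q[:, 1, 0]
        s = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(s > 0, a / np.where(s > 0, s, 1.0), 0.0)
        p0 = 1.0 - p1
        e = np.exp(-np.multiply.outer(s, lengths))  # (M, B)
        P = np.empty((M, B, 2, 2))
        P[..., 0, 0] = p0[:, None] + p1[:, None] * e
        P[..., 0, 1] = p1[:, None] * (1.0 - e)
        P[..., 1, 0] = p0[:, None] * (1.0 - e)
        P[..., 1, 1] = p1[:, None] + p0[:, None] * e
        # zero total rate: identity regardless of t
        P[s == 0] = np.eye(2)
        return P
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(w[:, None, :] * lengths[None, :, None])  # (M, B, k)
        P = np.einsum("mij,mbj,mjk->mbik", V, E, Vinv)
        bad = ~((np.abs(P.imag).reshape(M, -1).max(axis=1) < 1e-10)
                & (np.abs(P.real.sum(axis=3) - 1.0).reshape(M, -1).max(axis=1) < 1e-9))
        P = P.real.copy()
    except np.linalg.LinAlgError:
        P = np.empty((M, B, k, k))
        bad = np.ones(M, dtype=bool)
    for m in np.flatnonzero(bad):
        P[m] = np.stack([expm(Q[m] * t) for t in lengths])
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _batched_loglik(idx, states: np.ndarray, model: str, rates: np.ndarray,
                    pi: np.ndarray) -> np.ndarray:
    """Pruning log-likelihood for a stack of rate vectors at fixed data.

    Used by the optimiser to evaluate a finite-difference stencil in one
    pass; returns shape (M,) with ``-inf`` for zero-probability data.
    """
    M = rates.shape[0]
    Q = _batched_q(model, rates)
    n_states = Q.shape[1]
    P = _batched_transition(Q, idx.edge_length)
    partial = np.zeros((M, idx.n_nodes, n_states))
    tips = np.flatnonzero(states >= 0)
    partial[:, tips, states[tips]] = 1.0
    logscale = np.zeros(M)
    ok = np.ones(M, dtype=bool)
    for nodes, kids, n_pos in idx.levels():
        down = np.einsum("mnij,mnj->mni", P[:, kids], partial[:, kids])
        L = down.reshape(M, n_pos, len(nodes), n_states).prod(axis=1)
        m = L.max(axis=2)
        ok &= np.all(m > 0.0, axis=1)
        msafe = np.where(m > 0, m, 1.0)
        partial[:, nodes] = L / msafe[:, :, None]
        logscale += np.log(msafe).sum(axis=1)
    site = partial[:, idx.root] @ pi
    ok &= site > 0.0
    out = np.full(M, NEG_INF)
    out[ok] = logscale[ok] + np.log(site[ok])
    return out


def prune_loglik(tree: SpeciesTree, tip_states, rates: CtmcRates, root_prior="flat") -> float:
    """Log-likelihood of tip states by postorder pruning.

    ``tip_states`` maps tip label to state index (or is a vector aligned
    with ``tree.tip_labels``); states run over ``{0,1}`` for a single
    trait and ``{0..3}`` (``2*x + y``) for a pair.  Returns ``-inf`` for
    data of probability zero.
    """
    idx = tree.index()
    n_states = rates.n_states
    Q = rates.q_matrix()
    states = _tip_state_array(tree, tip_states)
    if states[states >= 0].max(initial=0) >= n_states:
        raise ValueError("tip state out of range for the model's state space")
    pi = _root_prior(root_prior, n_states, Q)
    return _loglik_arrays(idx, states, Q, pi)


def prune_loglik_bruteforce(
    tree: SpeciesTree, tip_states, rates: CtmcRates, root_prior="flat"
) -> float:
    """Reference likelihood by explicit enumeration of internal states.

    Exponential in the internal-node count; usable only on tiny trees.
    Kept in the package as the independent check of :func:`prune_loglik`.
    """
    idx = tree.index()
    n_states = rates.n_states
    Q = rates.q_matrix()
    states = _tip_state_array(tree, tip_states)
    P = np.stack([expm(Q * t) for t in idx.edge_length])
    pi = _root_prior(root_prior, n_states, Q)
    internal = [i for i in idx.postorder if idx.children[i]]
    parent = np.full(idx.n_nodes, -1)
    for i in idx.postorder:
        for c in idx.children[i]:
            parent[c] = i
    total = 0.0
    assign = states.copy()
    for combo in itertools.product(range(n_states), repeat=len(internal)):
        for node, s in zip(internal, combo):
            assign[node] = s
        prob = pi[assign[idx.root]]
        for node in idx.postorder:
            if node == idx.root:
                continue
            prob *= P[node][assign[parent[node]], assign[node]]
        total += prob
    return np.log(total) if total > 0 else NEG_INF


@dataclass
class FitResult:
    """Maximum-likelihood fit of one trait-evolution model."""

    model: str
    logL: float
    rates: np.ndarray
    k: int
    converged: bool
    restarts_used: int


@dataclass
class AiccScore:
    logL: float
    k: int
    n: int
    aicc: float

    @property
    def aic(self) -> float:
        return -2.0 * self.logL + 2.0 * self.k


def aicc(logL: float, k: int, n: int) -> AiccScore:
    """Small-sample-corrected Akaike information criterion.

    ``aicc = -2 logL + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    value = -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return AiccScore(logL=logL, k=k, n=n, aicc=value)


@dataclass
class CoevoConfig:
    delta_threshold: float = 2.0
    rate_bounds: tuple[float, float] = (1e-8, 1e3)
    restarts: int = 5
    tol: float = 1e-8
    root_prior: str = "flat"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise ValueError("rate bounds must be positive and ordered")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def _stencil_objective(idx, states: np.ndarray, model: str, pi: np.ndarray,
                       h: float = 1e-6):
    """Negative log-likelihood with a central-difference gradient.

    The value point and the ``2k`` perturbed points of the stencil are
    evaluated in one batched pruning pass, which is what makes the
    eight-parameter fits affordable.
    """
    def fun(logx):
        k = logx.size
        X = np.tile(logx, (2 * k + 1, 1))
        for i in range(k):
            X[1 + i, i] += h
            X[1 + k + i, i] -= h
        ll = _batched_loglik(idx, states, model, np.exp(X), pi)
        if not np.isfinite(ll[0]):
            return 1e12, np.zeros(k)
        grad = (ll[1:1 + k] - ll[1 + k:]) / (2.0 * h)
        grad[~np.isfinite(grad)] = 0.0
        return -ll[0], -grad

    return fun


def _maximize(neg_loglik, n_par: int, config: CoevoConfig, rng: np.random.Generator,
              extra_starts: list[np.ndarray] | None = None, jac: bool = False):
    """Bounded L-BFGS-B over log-rates from several seeded starts."""
    lo, hi = np.log(config.rate_bounds[0]), np.log(config.rate_bounds[1])
    best = None
    n_ok = 0
    starts = [rng.uniform(np.log(1e-2), np.log(1e1), size=n_par)
              for _ in range(config.restarts)]
    if extra_starts:
        starts = list(extra_starts) + starts
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        res = minimize(
            neg_loglik, x0, method="L-BFGS-B", jac=jac,
            bounds=[(lo, hi)] * n_par, options={"ftol": config.tol, "maxiter": 500},
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    return best, n_ok


def fit_single_trait(tree: SpeciesTree, states, config: CoevoConfig,
                     rng: np.random.Generator) -> tuple[float, np.ndarray, bool]:
    """ML gain/loss rates for one binary trait; returns (logL, rates, converged)."""
    idx = tree.index()
    node_states = _tip_state_array(tree, states)

    if config.root_prior == "flat":
        nll = _stencil_objective(idx, node_states, "single", np.full(2, 0.5))
        best, n_ok = _maximize(nll, 2, config, rng, jac=True)
    else:
        def nll(log_rates):
            r = CtmcRates("single", np.exp(log_rates))
            Q = r.q_matrix()
            ll = _loglik_arrays(idx, node_states, Q,
                                _root_prior(config.root_prior, 2, Q))
            return -ll if np.isfinite(ll) else 1e12

        best, n_ok = _maximize(nll, 2, config, rng)
    if best is None:
        return NEG_INF, np.full(2, np.nan), False
    return -best.fun, np.exp(best.x), n_ok > 0


def fit_model(tree: SpeciesTree, x, y, model: str, config: CoevoConfig | None = None,
              rng: np.random.Generator | None = None,
              indep_fit: FitResult | None = None) -> FitResult:
    """Fit the independent or dependent pair model by bounded ML.

    ``x`` and ``y`` are binary vectors aligned with ``tree.tip_labels``
    (or label-keyed dicts).  The independent fit factorises into two
    two-state problems whose log-likelihoods add.  The dependent fit uses
    ``config.restarts`` random starts plus one start at the independent
    solution embedded in the eight-rate space, which guarantees
    ``logL_dep >= logL_indep`` up to optimiser tolerance.
    """
    config = config or CoevoConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = np.asarray([x[lab] for lab in tree.tip_labels]) if isinstance(x, dict) else np.asarray(x)
    y = np.asarray([y[lab] for lab in tree.tip_labels]) if isinstance(y, dict) else np.asarray(y)
    if set(np.unique(x)) - {0, 1} or set(np.unique(y)) - {0, 1}:
        raise ValueError("trait vectors must be binary")
    pair_states = 2 * x + y

    if model == "independent":
        llx, rx, okx = fit_single_trait(tree, x, config, rng)
        lly, ry, oky = fit_single_trait(tree, y, config, rng)
        return FitResult(
            model="independent", logL=llx + lly,
            rates=np.concatenate([rx, ry]), k=4,
            converged=okx and oky, restarts_used=config.restarts,
        )
    if model != "dependent":
        raise ValueError(f"unknown model {model!r}")

    idx = tree.index()
    node_states = _tip_state_array(tree, pair_states)

    use_jac = config.root_prior == "flat"
    if use_jac:
        nll = _stencil_objective(idx, node_states, "dependent", np.full(4, 0.25))
    else:
        def nll(log_rates):
            r = CtmcRates("dependent", np.exp(log_rates))
            Q = r.q_matrix()
            ll = _loglik_arrays(idx, node_states, Q,
                                _root_prior(config.root_prior, 4, Q))
            return -ll if np.isfinite(ll) else 1e12

    extra = []
    if indep_fit is None:
        indep_fit = fit_model(tree, x, y, "independent", config, rng)
    if np.all(np.isfinite(indep_fit.rates)):
        lo = config.rate_bounds[0]
        extra.append(np.log(np.maximum(independent_to_dependent(indep_fit.rates), lo)))
    best, n_ok = _maximize(nll, 8, config, rng, extra_starts=extra, jac=use_jac)
    if best is None:
        return FitResult("dependent", NEG_INF, np.full(8, np.nan), 8, False,
                         config.restarts)
    return FitResult("dependent", -best.fun, np.exp(best.x), 8, n_ok > 0,
                     config.restarts)


@dataclass
class TraitMatrix:
    """Binary species-by-orthogroup matrix aligned with a tree's tips."""

    species: list[str]
    orthogroups: list[str]
    matrix: np.ndarray  # (n_species, n_orthogroups) of {0,1}
    puf_orthogroups: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.species), len(self.orthogroups)):
            raise ValueError("trait matrix shape does not match labels")
        if set(np.unique(self.matrix)) - {0, 1}:
            raise ValueError("trait matrix entries must be 0/1")

    def column(self, og: str) -> np.ndarray:
        return self.matrix[:, self.orthogroups.index(og)]


def traits_from_orthogroups(membership, tree: SpeciesTree,
                            puf_genes: set[str] | None = None) -> TraitMatrix:
    """Presence/absence trait matrix from orthogroup membership.

    A species scores 1 for an orthogroup when it carries at least one
    gene of that group; species on the tree missing from the membership
    table score 0 everywhere.  When ``puf_genes`` is given, orthogroups
    containing any such gene are flagged as PUF orthogroups.
    """
    tips = tree.tip_labels
    extra = set(membership.species) - set(tips)
    if extra:
        raise ValueError(f"membership species not on the tree: {sorted(extra)}")
    ogs = list(membership.orthogroups)
    mat = np.zeros((len(tips), len(ogs)), dtype=int)
    puf_ogs: set[str] = set()
    for j, og in enumerate(ogs):
        for i, sp in enumerate(tips):
            genes = membership.genes(og, sp)
            if genes:
                mat[i, j] = 1
            if puf_genes and any(g in puf_genes for g in genes):
                puf_ogs.add(og)
    return TraitMatrix(species=tips, orthogroups=ogs, matrix=mat,
                       puf_orthogroups=puf_ogs)


@dataclass
class CoevolutionResult:
    og_puf: str
    og_other: str
    fit_indep: FitResult
    fit_dep: FitResult
    aicc_indep: float
    aicc_dep: float
    delta: float
    coevolving: bool


def screen_pairs(traits: TraitMatrix, tree: SpeciesTree,
                 config: CoevoConfig | None = None):
    """Screen every (PUF orthogroup, other orthogroup) pair for coevolution.

    Returns ``(results, skipped)`` where ``skipped`` maps pair ids to the
    reason a pair was not testable (invariant trait columns are
    non-identifiable and are skipped, not silently dropped).
    """
    config = config or CoevoConfig()
    if not traits.puf_orthogroups:
        raise ValueError("no PUF orthogroups flagged in the trait matrix")
    rng = np.random.default_rng(config.seed)
    n = len(traits.species)
    if set(traits.species) != set(tree.tip_labels):
        raise ValueError("trait species do not match tree tips")
    variable = {
        og: 0 < traits.column(og).sum() < n for og in traits.orthogroups
    }
    results: list[CoevolutionResult] = []
    skipped: dict[tuple[str, str], str] = {}
    for og_p in sorted(traits.puf_orthogroups):
        for og_o in traits.orthogroups:
            if og_o == og_p:
                continue
            key = (og_p, og_o)
            if not variable[og_p]:
                skipped[key] = f"non-identifiable: {og_p} invariant across species"
                continue
            if not variable[og_o]:
                skipped[key] = f"non-identifiable: {og_o} invariant across species"
                continue
            x = np.array([traits.column(og_p)[traits.species.index(s)]
                          for s in tree.tip_labels])
            y = np.array([traits.column(og_o)[traits.species.index(s)]
                          for s in tree.tip_labels])
            fit_i = fit_model(tree, x, y, "independent", config, rng)
            fit_d = fit_model(tree, x, y, "dependent", config, rng, indep_fit=fit_i)
            sc_i = aicc(fit_i.logL, fit_i.k, n)
            sc_d = aicc(fit_d.logL, fit_d.k, n)
            delta = sc_i.aicc - sc_d.aicc
            results.append(CoevolutionResult(
                og_puf=og_p, og_other=og_o, fit_indep=fit_i, fit_dep=fit_d,
                aicc_indep=sc_i.aicc, aicc_dep=sc_d.aicc, delta=delta,
                coevolving=bool(delta >= config.delta_threshold
                                and fit_i.converged and fit_d.converged),
            ))
    return results, skipped
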