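"""Nested models of correlated, irreversible gene loss and the LRT.

Two genes inherited strictly as orthologs can be lost but never
regained, so their joint evolution on a species tree is a loss-only
continuous-time Markov chain started from a both-present root.  The
*independent* model gives each gene a single loss rate (beta1, beta2)
regardless of the partner's state — 2 free parameters.  The *dependent*
model splits each loss rate by the partner's presence, giving 4 free
parameters over the joint states (g1, g2):

    q42 : (1,1) -> (0,1)   loss of gene 1 while gene 2 is present
    q43 : (1,1) -> (1,0)   loss of gene 2 while gene 1 is present
    q31 : (1,0) -> (0,0)   loss of gene 1 after gene 2 is gone
    q21 : (0,1) -> (0,0)   loss of gene 2 after gene 1 is gone

All gain rates are identically zero, so state (0,0) is absorbing (and
state 0 is absorbing for a single trait).  The independent model is
nested in the dependent one at q42 = q31 = beta1, q43 = q21 = beta2, so
the models are compared with a likelihood-ratio test on 2 degrees of
freedom.  A significantly better dependent fit is evidence that the two
genes co-occur (are lost together) beyond what independent loss
explains.

The root state is fixed to present / both-present: with gains
impossible, any other root state assigns zero likelihood whenever a
gene is observed anywhere, so this is the only non-degenerate choice.
Likelihoods are computed by Felsenstein's pruning algorithm with
transition probabilities from the matrix exponential (scaling and
squaring, which is robust at the coincident-eigenvalue degeneracies of
the 4-state generator where closed forms are fragile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from phylocoev.phylo_io import Phylogeny, TraitMatrix

__all__ = [
    "LossGenerator",
    "ModelFit",
    "CooccurrenceResult",
    "transition_matrix",
    "pruning_loglik",
    "fit_independent",
    "fit_dependent",
    "lrt_cooccurrence",
    "PAIR_STATES",
]

# Joint-state order used throughout: index -> (gene1, gene2)
PAIR_STATES: tuple[tuple[int, int], ...] = ((1, 1), (1, 0), (0, 1), (0, 0))
_PAIR_INDEX = {s: i for i, s in enumerate(PAIR_STATES)}

# Single-trait state order: 0 = present, 1 = absent (absorbing).
SINGLE_STATES: tuple[int, ...] = (1, 0)

# Optimizer works on log(rate * mean_branch_length); bounds per unit
# mean branch length.
_LOG_RATE_LO = np.log(1e-6)
_LOG_RATE_HI = np.log(1e3)


@dataclass(frozen=True)
class LossGenerator:
    """Rate matrix of a loss-only CTMC over 2 (single) or 4 (pair) states.

    Construct with :meth:`single` or :meth:`pair`.
    """

    kind: str  # "independent-single" | "dependent-pair"
    rates: dict = field(default_factory=dict)

    @classmethod
    def single(cls, beta: float) -> "LossGenerator":
        if beta < 0:
            raise ValueError(f"loss rate must be >= 0, got {beta}")
        return cls(kind="independent-single", rates={"beta": float(beta)})

    @classmethod
    def pair(cls, q42: float, q43: float, q31: float, q21: float) -> "LossGenerator":
        vals = {"q42": q42, "q43": q43, "q31": q31, "q21": q21}
        for name, v in vals.items():
            if v < 0:
                raise ValueError(f"rate {name} must be >= 0, got {v}")
        return cls(kind="dependent-pair", rates={k: float(v) for k, v in vals.items()})

    @property
    def n_states(self) -> int:
        return 2 if self.kind == "independent-single" else 4

    def Q(self) -> np.ndarray:
        """Generator matrix; rows sum to zero, all gain entries exactly 0."""
        if self.kind == "independent-single":
            b = self.rates["beta"]
            return np.array([[-b, b], [0.0, 0.0]])
        q42, q43 = self.rates["q42"], self.rates["q43"]
        q31, q21 = self.rates["q31"], self.rates["q21"]
        Q = np.zeros((4, 4))
        Q[0, 2] = q42  # (1,1) -> (0,1)
        Q[0, 1] = q43  # (1,1) -> (1,0)
        Q[1, 3] = q31  # (1,0) -> (0,0)
        Q[2, 3] = q21  # (0,1) -> (0,0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def root_index(self) -> int:
        """Index of the fixed root state (present / both-present)."""
        return 0


# Padé-13 coefficients for the matrix exponential (scaling and squaring,
# the same scheme scipy uses; re-implemented here so the whole branch
# batch is exponentiated in one vectorized call).
_PADE13_B = np.array(
    [
        64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
        1187353796428800.0, 129060195264000.0, 10559470521600.0,
        670442572800.0, 33522128640.0, 1323241920.0, 40840800.0,
        960960.0, 16380.0, 182.0, 1.0,
    ]
)
_PADE13_THETA = 5.371920351148152  # double-precision order-13 threshold


def expm_batched(A: np.ndarray) -> np.ndarray:
    """exp(A) for a stack of small square matrices, shape (..., k, k).

    Scaling-and-squaring with a shared scale across the stack; accuracy
    matches the standard Pade-13 scheme (absolute error well below
    1e-12 for the generators used here).
    """
    A = np.asarray(A, dtype=float)
    b = _PADE13_B
    norm = np.abs(A).sum(axis=-1).max(axis=-1)
    maxnorm = float(norm.max()) if norm.size else 0.0
    s = max(0, int(np.ceil(np.log2(maxnorm / _PADE13_THETA)))) if maxnorm > _PADE13_THETA else 0
    A = A / (2.0 ** s)
    eye = np.broadcast_to(np.eye(A.shape[-1]), A.shape)
    A2 = A @ A
    A4 = A2 @ A2
    A6 = A2 @ A4
    U = A @ (A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
             + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * eye)
    V = (A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
         + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * eye)
    P = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        P = P @ P
    return P


def transition_matrix(gen: LossGenerator, t: float) -> np.ndarray:
    """P(t) = exp(Qt); row-stochastic, entries clipped to [0, 1]."""
    if t < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t}")
    P = expm_batched(gen.Q() * t)
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


class _PruningEngine:
    """Array-form tree for repeated likelihood evaluation.

    The tree is flattened once into postorder arrays; each call to
    :meth:`loglik` computes all edge transition matrices in a single
    batched ``expm`` and runs the conditional-likelihood recursion.
    The root's own (stem) edge is never used.
    """

    def __init__(self, phy: Phylogeny, tip_partials: dict[str, np.ndarray], n_states: int):
        nodes = list(phy.tree.postorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        self.n = len(nodes)
        self.k = n_states
        self.children: list[list[int]] = []
        self.lengths = np.zeros(self.n)
        self.base = np.ones((self.n, n_states))
        self.internal: list[int] = []
        for i, nd in enumerate(nodes):
            kids = [idx[id(c)] for c in nd.child_nodes()]
            self.children.append(kids)
            self.lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if kids:
                self.internal.append(i)
            else:
                label = nd.taxon.label
                if label not in tip_partials:
                    raise KeyError(f"tip {label!r} has no state assignment")
                self.base[i] = tip_partials[label]
        self.root = self.n - 1  # postorder: root last

    def loglik(self, Q: np.ndarray, root_index: int) -> float:
        P = expm_batched(Q[None, :, :] * self.lengths[:, None, None])
        L = self.base.copy()
        for i in self.internal:
            acc = None
            for c in self.children[i]:
                v = P[c] @ L[c]
                acc = v if acc is None else acc * v
            L[i] = acc
        val = L[self.root, root_index]
        if val <= 0.0:
            return -np.inf
        return float(np.log(val))


def _tip_partial_single(state) -> np.ndarray:
    """Partial likelihood vector for one tip of a single trait."""
    if state is None:
        return np.ones(2)
    s = int(state)
    if s == 1:
        return np.array([1.0, 0.0])
    if s == 0:
        return np.array([0.0, 1.0])
    raise ValueError(f"unknown single-trait state {state!r}")


def _tip_partial_pair(s1, s2) -> np.ndarray:
    """Partial for a tip given (possibly missing) states of the two genes."""
    v = np.zeros(4)
    for i, (g1, g2) in enumerate(PAIR_STATES):
        ok1 = s1 is None or int(s1) == g1
        ok2 = s2 is None or int(s2) == g2
        if ok1 and ok2:
            v[i] = 1.0
    return v


def pruning_loglik(phy: Phylogeny, tip_states: dict, gen: LossGenerator, root_state=None) -> float:
    """Log-probability of tip states given tree, generator, and root state.

    ``tip_states`` maps tip label to a state: for a single trait,
    1 / 0 / ``None`` (missing); for a pair, a tuple ``(g1, g2)`` whose
    entries may each be ``None``.  ``root_state`` defaults to present /
    both-present and may be given as a state value or index.
    """
    labels = set(phy.tip_labels)
    unknown = sorted(set(tip_states) - labels)
    if unknown:
        raise KeyError(f"tip states given for taxa not in tree: {unknown}")
    missing = sorted(labels - set(tip_states))
    if missing:
        raise KeyError(f"no state for tips: {missing}")

    if gen.kind == "independent-single":
        partials = {lab: _tip_partial_single(s) for lab, s in tip_states.items()}
        k = 2
        root_index = 0 if root_state in (None, 1) else 1
    else:
        partials = {}
        for lab, s in tip_states.items():
            if not (isinstance(s, (tuple, list)) and len(s) == 2):
                raise ValueError(f"pair state for {lab!r} must be a 2-tuple, got {s!r}")
            partials[lab] = _tip_partial_pair(s[0], s[1])
        k = 4
        if root_state is None:
            root_index = 0
        elif isinstance(root_state, (tuple, list)):
            root_index = _PAIR_INDEX[tuple(int(x) for x in root_state)]
        else:
            root_index = int(root_state)

    engine = _PruningEngine(phy, partials, k)
    return engine.loglik(gen.Q(), root_index)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    model: str  # "independent" | "dependent"
    rate_estimates: dict[str, float]
    log_likelihood: float
    n_restarts_converged: int
    optimizer_status: str


@dataclass
class CooccurrenceResult:
    gene1: str
    gene2: str
    lnL_independent: float
    lnL_dependent: float
    lrt_statistic: float
    df: int
    p_value: float
    fit_independent: ModelFit
    fit_dependent: ModelFit
    p_value_bonferroni: float | None = None


def _prepare(phy: Phylogeny, traits: TraitMatrix, gene1: str, gene2: str):
    """Prune the tree to scored species and collect per-gene tip states."""
    for g in (gene1, gene2):
        if g not in traits.genes:
            raise KeyError(f"gene {g!r} not in trait matrix")
    usable = [sp for sp in traits.species if sp in set(phy.tip_labels)]
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} trait-matrix species are tips of the tree; need >= 3"
        )
    from phylocoev.phylo_io import prune_to_taxa

    sub = prune_to_taxa(phy, usable)
    s1 = traits.states_for(gene1)
    s2 = traits.states_for(gene2)
    states1 = {sp: s1[sp] for sp in usable}
    states2 = {sp: s2[sp] for sp in usable}
    for g, st in ((gene1, states1), (gene2, states2)):
        n_obs = sum(1 for v in st.values() if v is not None)
        if n_obs < 3:
            raise ValueError(f"gene {g!r} has only {n_obs} non-missing species; need >= 3")
    return sub, states1, states2


def _start_points(rng: np.random.Generator, ndim: int, restarts: int, center: np.ndarray):
    """Deterministic center start plus seeded uniform draws over the box."""
    pts = [np.clip(center, _LOG_RATE_LO, _LOG_RATE_HI)]
    for _ in range(max(restarts - 1, 0)):
        pts.append(rng.uniform(np.log(1e-3), np.log(1e2), size=ndim))
    return pts


def _maximize(nll, starts, tol: float):
    best = None
    n_conv = 0
    for x0 in starts:
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_RATE_LO, _LOG_RATE_HI)] * len(x0),
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun:
            best = res
    status = "converged" if n_conv > 0 else f"no-start-converged: {best.message}"
    return best, n_conv, status


def _moment_start_single(states: dict, depth: float) -> float:
    """Crude loss-rate guess from the fraction of surviving tips."""
    obs = [v for v in states.values() if v is not None]
    frac = max(np.mean([v == 1 for v in obs]), 1e-3)
    return max(-np.log(frac) / max(depth, 1e-9), 1e-5)


def fit_independent(
    phy: Phylogeny,
    traits: TraitMatrix,
    gene1: str,
    gene2: str,
    restarts: int = 25,
    seed: int = 0,
    tol: float = 1e-8,
) -> ModelFit:
    """ML fit of the independent model: lnL(beta1) + lnL(beta2).

    Each term is a single-trait irreversible-loss likelihood with the
    root fixed present.  A gene never observed absent sits at the
    boundary beta = 0 with likelihood 1 exactly.
    """
    sub, states1, states2 = _prepare(phy, traits, gene1, gene2)
    mbl = sub.mean_branch_length()
    depth = sub.max_tip_depth()
    rng = np.random.default_rng(seed)

    betas = {}
    lnL = 0.0
    n_conv_min = None
    statuses = []
    for name, states in (("beta1", states1), ("beta2", states2)):
        if all(v != 0 for v in states.values() if v is not None):
            betas[name] = 0.0  # boundary MLE: no losses observed
            statuses.append("boundary")
            continue
        partials = {lab: _tip_partial_single(s) for lab, s in states.items()}
        engine = _PruningEngine(sub, partials, 2)

        def nll(x):
            beta = np.exp(x[0]) / mbl
            Q = np.array([[-beta, beta], [0.0, 0.0]])
            v = engine.loglik(Q, 0)
            return -v if np.isfinite(v) else 1e10  # finite penalty keeps L-BFGS-B stable

        center = np.array([np.log(_moment_start_single(states, depth) * mbl)])
        best, n_conv, status = _maximize(nll, _start_points(rng, 1, restarts, center), tol)
        betas[name] = float(np.exp(best.x[0]) / mbl)
        lnL += -best.fun
        n_conv_min = n_conv if n_conv_min is None else min(n_conv_min, n_conv)
        statuses.append(status)

    return ModelFit(
        model="independent",
        rate_estimates=betas,
        log_likelihood=float(lnL),
        n_restarts_converged=0 if n_conv_min is None else int(n_conv_min),
        optimizer_status="; ".join(statuses),
    )


_Q_NAMES = ("q42", "q43", "q31", "q21")


def fit_dependent(
    phy: Phylogeny,
    traits: TraitMatrix,
    gene1: str,
    gene2: str,
    restarts: int = 25,
    seed: int = 0,
    tol: float = 1e-8,
    independent_fit: ModelFit | None = None,
) -> ModelFit:
    """ML fit of the dependent 4-state model over (q42, q43, q31, q21).

    One start is always placed at the factorization point of the
    independent estimates (q42 = q31 = beta1, q43 = q21 = beta2), which
    guarantees lnL_dependent >= lnL_independent up to optimizer
    tolerance; the remaining starts are seeded random draws.
    """
    sub, states1, states2 = _prepare(phy, traits, gene1, gene2)
    mbl = sub.mean_branch_length()
    rng = np.random.default_rng(seed)

    if all(v != 0 for st in (states1, states2) for v in st.values() if v is not None):
        return ModelFit(
            model="dependent",
            rate_estimates={k: 0.0 for k in _Q_NAMES},
            log_likelihood=0.0,
            n_restarts_converged=0,
            optimizer_status="boundary",
        )

    partials = {
        lab: _tip_partial_pair(states1[lab], states2[lab]) for lab in states1
    }
    engine = _PruningEngine(sub, partials, 4)

    def nll(x):
        q42, q43, q31, q21 = np.exp(x) / mbl
        Q = np.zeros((4, 4))
        Q[0, 2], Q[0, 1], Q[1, 3], Q[2, 3] = q42, q43, q31, q21
        np.fill_diagonal(Q, -Q.sum(axis=1))
        v = engine.loglik(Q, 0)
        return -v if np.isfinite(v) else 1e10

    if independent_fit is None:
        independent_fit = fit_independent(
            phy, traits, gene1, gene2, restarts=restarts, seed=seed, tol=tol
        )
    b1 = max(independent_fit.rate_estimates["beta1"], 1e-6 / mbl)
    b2 = max(independent_fit.rate_estimates["beta2"], 1e-6 / mbl)
    center = np.log(np.array([b1, b2, b1, b2]) * mbl)
    best, n_conv, status = _maximize(nll, _start_points(rng, 4, restarts, center), tol)

    q42, q43, q31, q21 = np.exp(best.x) / mbl
    return ModelFit(
        model="dependent",
        rate_estimates={"q42": float(q42), "q43": float(q43), "q31": float(q31), "q21": float(q21)},
        log_likelihood=float(-best.fun),
        n_restarts_converged=int(n_conv),
        optimizer_status=status,
    )


def lrt_cooccurrence(
    phy: Phylogeny,
    traits: TraitMatrix,
    gene1: str,
    gene2: str,
    restarts: int = 25,
    seed: int = 0,
    tol: float = 1e-8,
    n_tests: int | None = None,
) -> CooccurrenceResult:
    """Likelihood-ratio test of co-occurrence for one gene pair.

    Lambda = 2 (lnL_dependent - lnL_independent), clipped at 0 (a value
    below -1e-6 signals optimization failure and is warned about), with
    the p-value from the upper tail of chi-square on 2 df.  Pass
    ``n_tests`` to additionally report a Bonferroni-adjusted p-value
    (off by default: raw p-values are the primary output).
    """
    fit_i = fit_independent(phy, traits, gene1, gene2, restarts=restarts, seed=seed, tol=tol)
    fit_d = fit_dependent(
        phy, traits, gene1, gene2, restarts=restarts, seed=seed, tol=tol,
        independent_fit=fit_i,
    )
    lam = 2.0 * (fit_d.log_likelihood - fit_i.log_likelihood)
    if lam < -1e-6:
        warnings.warn(
            f"negative LRT statistic {lam:.3g} for ({gene1}, {gene2}): "
            "dependent optimization failed to reach the independent optimum; "
            "clipping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = max(lam, 0.0)
    p = float(chi2.sf(lam, df=2))
    p_bonf = min(p * n_tests, 1.0) if n_tests else None
    return CooccurrenceResult(
        gene1=gene1,
        gene2=gene2,
        lnL_independent=fit_i.log_likelihood,
        lnL_dependent=fit_d.log_likelihood,
        lrt_statistic=float(lam),
        df=2,
        p_value=p,
        fit_independent=fit_i,
        fit_dependent=fit_d,
        p_value_bonferroni=p_bonf,
    )
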