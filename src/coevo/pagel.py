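"""Pagel's test of correlated evolution for two binary characters.

Two continuous-time Markov models are contrasted on a rooted tree with
branch lengths.  Under the *independent* model each character evolves by
its own 2-state chain (gain rate ``alpha``, loss rate ``beta``; 4 free
parameters in total).  Under the *dependent* model the pair evolves as a
joint 4-state chain over (0,0), (0,1), (1,0), (1,1) with 8 free
transition rates; simultaneous changes of both characters are forbidden
(those four rate-matrix entries are fixed at zero).  The likelihood-ratio
statistic ``LR = 2 (lnL_dep - lnL_indep)`` is referred to a chi-squared
distribution with 8 - 4 = 4 degrees of freedom.

Likelihoods use Felsenstein pruning with per-node rescaling; rates are
estimated by bounded multi-start quasi-Newton optimisation in log-rate
space after rescaling the tree to mean root-to-tip depth 1 (the LR is
invariant to that joint rescaling of rates and branch lengths).
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from ._pruning import (
    TreeTable,
    loglik_2state_kernel,
    loglik_4state_kernel,
    prune_loglik,
    transition_matrices_2state,
    transition_matrices_general,
)

__all__ = [
    "IndependentModel",
    "DependentModel",
    "FitOptions",
    "PairTestResult",
    "loglik_single_trait",
    "loglik_dependent",
    "fit_independent",
    "fit_dependent",
    "lrt_pair",
    "all_pairs_lrt",
    "LR_DEGREES_OF_FREEDOM",
]

#: Difference in free parameters between the dependent (8) and
#: independent (4) models: degrees of freedom of the LRT.
LR_DEGREES_OF_FREEDOM = 8 - 4

# joint states are ordered (0,0), (0,1), (1,0), (1,1); index = 2x + y
_STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]


@dataclass
class IndependentModel:
    """Two uncoupled 2-state chains: X gains at alpha1, loses at beta1;
    Y gains at alpha2, loses at beta2 (events per unit branch length)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self):
        for r in (self.alpha1, self.beta1, self.alpha2, self.beta2):
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"rates must be finite and >= 0, got {r}")

    def rates(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2])


@dataclass
class DependentModel:
    """Joint 4-state chain; qij is the rate from state Si to Sj with
    S1=(0,0), S2=(0,1), S3=(1,0), S4=(1,1).  Dual transitions
    (q14, q23, q32, q41) are structurally zero."""

    q12: float
    q13: float
    q21: float
    q24: float
    q31: float
    q34: float
    q42: float
    q43: float

    def __post_init__(self):
        for r in self.rates():
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"rates must be finite and >= 0, got {r}")

    def rates(self) -> np.ndarray:
        return np.array([self.q12, self.q13, self.q21, self.q24,
                         self.q31, self.q34, self.q42, self.q43])

    def rate_matrix(self) -> np.ndarray:
        Q = np.zeros((4, 4))
        Q[0, 1], Q[0, 2] = self.q12, self.q13
        Q[1, 0], Q[1, 3] = self.q21, self.q24
        Q[2, 0], Q[2, 3] = self.q31, self.q34
        Q[3, 1], Q[3, 2] = self.q42, self.q43
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    @classmethod
    def from_independent(cls, model: IndependentModel) -> "DependentModel":
        """The independence-structured point inside the dependent model."""
        a1, b1, a2, b2 = model.rates()
        return cls(q12=a2, q13=a1, q21=b2, q24=a1, q31=b1, q34=a2, q42=b1, q43=b2)


@dataclass
class FitOptions:
    """Optimiser settings for the maximum-likelihood fits.

    Rates are optimised as log10 values within ``rate_bounds`` on the
    depth-rescaled tree.  ``restarts`` counts starting points: a
    data-informed start plus ``restarts - 1`` log-uniform random draws.
    """

    restarts: int = 10
    seed: int = 0
    rate_bounds: tuple = (1e-7, 1e3)
    root_prior: str = "uniform"  # or "stationary"
    maxiter: int = 200
    explore_maxiter: int = 30  # short pass per restart; best point is polished
    length_floor: float = 1e-9
    negative_lr_tolerance: float = 1e-3


@dataclass
class PairTestResult:
    """Outcome of one likelihood-ratio test between two profiles."""

    lnl_indep: float
    lnl_dep: float
    independent: IndependentModel
    dependent: DependentModel
    lr: float
    p_value: float
    df: int = LR_DEGREES_OF_FREEDOM
    restarts_used: int = 0
    boundary: bool = False
    converged: bool = True
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------
# Priors and likelihood evaluation
# ---------------------------------------------------------------------


def _prior_2state(alpha: float, beta: float, kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.array([0.5, 0.5])
    s = alpha + beta
    if s <= 0:
        return np.array([0.5, 0.5])
    return np.array([beta / s, alpha / s])


def _prior_4state(Q: np.ndarray, kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.full(4, 0.25)
    # stationary law: left null vector of Q
    w, V = np.linalg.eig(Q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.abs(V[:, i].real)
    return pi / pi.sum()


def _as_table(tree, options: FitOptions) -> TreeTable:
    if isinstance(tree, TreeTable):
        return tree
    return TreeTable.from_phylo(tree, length_floor=options.length_floor)


_DEFAULT = FitOptions()


def loglik_single_trait(tree, x, alpha: float, beta: float,
                        root_prior: str = "uniform",
                        options: FitOptions = _DEFAULT) -> float:
    """Pruning log-likelihood of one binary character.

    ``x`` maps tip label to 0/1 (missing tips treated as ambiguous).
    Rates are on the scale of the *input* branch lengths.
    """
    if not np.isfinite(alpha) or not np.isfinite(beta) or alpha < 0 or beta < 0:
        raise ValueError("rates must be finite and non-negative")
    table = _as_table(tree, options)
    states = table.tip_state_array(x)
    # table branch lengths are rescaled; compensate on the rates
    a, b = alpha / table.scale, beta / table.scale
    P = transition_matrices_2state(a, b, table.edge_len)
    return prune_loglik(table, P, states, _prior_2state(a, b, root_prior))


def loglik_dependent(tree, x, y, model: DependentModel,
                     root_prior: str = "uniform",
                     options: FitOptions = _DEFAULT) -> float:
    """Pruning log-likelihood of a tip pair under the joint 4-state chain."""
    table = _as_table(tree, options)
    joint = _joint_states(table, x, y)
    Q = model.rate_matrix() / table.scale
    P = transition_matrices_general(Q, table.edge_len)
    return prune_loglik(table, P, joint, _prior_4state(Q, root_prior))


def _joint_states(table: TreeTable, x, y) -> np.ndarray:
    sx = table.tip_state_array(x)
    sy = table.tip_state_array(y)
    joint = 2 * sx + sy
    joint[(sx < 0) | (sy < 0)] = -1
    return joint


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------


def _neg_ll_2state(logr, table, states, prior_kind):
    a, b = 10.0 ** logr
    ll = loglik_2state_kernel(a, b, table.edge_len, table.postorder,
                              table.children_flat, table.children_ptr,
                              states, _prior_2state(a, b, prior_kind))
    return -ll if np.isfinite(ll) else 1e12


def _build_q(q: np.ndarray) -> np.ndarray:
    Q = np.zeros((4, 4))
    Q[0, 1], Q[0, 2] = q[0], q[1]
    Q[1, 0], Q[1, 3] = q[2], q[3]
    Q[2, 0], Q[2, 3] = q[4], q[5]
    Q[3, 1], Q[3, 2] = q[6], q[7]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _neg_ll_4state(logr, table, joint, prior_kind):
    q = 10.0 ** logr
    if prior_kind == "uniform":
        prior = np.full(4, 0.25)
        ll = loglik_4state_kernel(q, table.edge_len, table.postorder,
                                  table.children_flat, table.children_ptr,
                                  joint, prior)
        if not np.isnan(ll):
            return -ll if np.isfinite(ll) else 1e12
    # stationary prior, or a defective eigenbasis: reference numpy path
    Q = _build_q(q)
    P = transition_matrices_general(Q, table.edge_len)
    ll = prune_loglik(table, P, joint, _prior_4state(Q, prior_kind))
    return -ll if np.isfinite(ll) else 1e12


def _multistart(fun, args, n_par, starts_log10, bounds_log10, options):
    """Explore every start briefly, then polish the best one.

    The short exploratory passes rank the basins cheaply; only the most
    promising point gets a full-accuracy optimisation.
    """
    bounds = [bounds_log10] * n_par
    best = None
    for x0 in starts_log10:
        res = minimize(
            fun, x0, args=args, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.explore_maxiter,
                     "maxfun": 40 * options.explore_maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = minimize(
        fun, best.x, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": options.maxiter, "maxfun": 40 * options.maxiter,
                 "ftol": 1e-12, "gtol": 1e-7},
    )
    return res if res.fun <= best.fun else best


def _starts(rng, n_restarts, n_par, lo, hi, informed):
    starts = [np.asarray(informed, dtype=float)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(lo, hi, size=n_par))
    return starts


def _fit_one_trait(table: TreeTable, states: np.ndarray, options: FitOptions,
                   rng) -> tuple[float, float, float, bool]:
    """ML (alpha, beta) on the rescaled tree.  Returns (a, b, lnl, boundary)."""
    lo, hi = np.log10(options.rate_bounds)
    n1 = int((states == 1).sum())
    n01 = int((states >= 0).sum())
    frac = min(max(n1 / max(n01, 1), 0.05), 0.95)
    # informed start: one expected event per unit depth, split by tip frequency
    informed = np.log10([max(frac, 1e-3), max(1 - frac, 1e-3)])
    starts = _starts(rng, options.restarts, 2, lo, hi, informed)
    best = _multistart(_neg_ll_2state, (table, states, options.root_prior),
                       2, starts, (lo, hi), options)
    a, b = 10.0 ** best.x
    boundary = bool(np.any(np.abs(best.x - lo) < 1e-6) or
                    np.any(np.abs(best.x - hi) < 1e-6))
    return a, b, -best.fun, boundary


def fit_independent(tree, x, y, options: FitOptions = _DEFAULT):
    """ML fit of the 4-parameter independent model.

    Returns ``(IndependentModel, lnL)`` with rates on the input branch-
    length scale; the model factorises, so each trait is fitted alone.
    """
    table = _as_table(tree, options)
    rng = np.random.default_rng(np.random.SeedSequence((options.seed, 0)))
    a1, b1, l1, bd1 = _fit_one_trait(table, table.tip_state_array(x), options, rng)
    a2, b2, l2, bd2 = _fit_one_trait(table, table.tip_state_array(y), options, rng)
    model = IndependentModel(a1 * table.scale, b1 * table.scale,
                             a2 * table.scale, b2 * table.scale)
    model.boundary = bd1 or bd2
    return model, l1 + l2


def fit_dependent(tree, x, y, options: FitOptions = _DEFAULT, init=None):
    """ML fit of the 8-parameter dependent model.

    ``init`` (a DependentModel on the input scale) seeds the first start;
    when omitted, the independence point of a quick independent fit is
    used, which guarantees the fitted dependent likelihood can only
    improve on the independent one.
    """
    table = _as_table(tree, options)
    joint = _joint_states(table, x, y)
    lo, hi = np.log10(options.rate_bounds)
    if init is None:
        indep, _ = fit_independent(table, x, y, options)
        init = DependentModel.from_independent(indep)
    init_scaled = np.clip(init.rates() / table.scale,
                          options.rate_bounds[0], options.rate_bounds[1])
    rng = np.random.default_rng(np.random.SeedSequence((options.seed, 1)))
    starts = _starts(rng, options.restarts, 8, lo, hi, np.log10(init_scaled))
    best = _multistart(_neg_ll_4state, (table, joint, options.root_prior),
                       8, starts, (lo, hi), options)
    q = (10.0 ** best.x) * table.scale
    model = DependentModel(*q)
    model.boundary = bool(np.any(np.abs(best.x - lo) < 1e-6) or
                          np.any(np.abs(best.x - hi) < 1e-6))
    return model, -best.fun


def lrt_pair(tree, x, y, options: FitOptions = _DEFAULT) -> PairTestResult:
    """Likelihood-ratio test of dependent vs independent evolution.

    ``LR = 2 (lnL_dep - lnL_indep)`` clamped at zero; the chi-squared
    4-df p-value is reported for reference.  A negative excursion larger
    than ``options.negative_lr_tolerance`` triggers one refit of the
    dependent model with 5x the restarts before clamping and flagging.
    """
    table = _as_table(tree, options)
    flags: list[str] = []
    indep, lnl_i = fit_independent(table, x, y, options)
    dep, lnl_d = fit_dependent(table, x, y, options,
                               init=DependentModel.from_independent(indep))
    restarts_used = options.restarts
    lr = 2.0 * (lnl_d - lnl_i)
    if lr < -options.negative_lr_tolerance:
        boosted = replace(options, restarts=5 * options.restarts,
                          seed=options.seed + 1)
        dep2, lnl_d2 = fit_dependent(table, x, y, boosted,
                                     init=DependentModel.from_independent(indep))
        restarts_used += boosted.restarts
        if lnl_d2 > lnl_d:
            dep, lnl_d = dep2, lnl_d2
        lr = 2.0 * (lnl_d - lnl_i)
        if lr < -options.negative_lr_tolerance:
            flags.append("negative_lr_after_refit")
    lr = max(lr, 0.0)
    boundary = bool(getattr(indep, "boundary", False) or
                    getattr(dep, "boundary", False))
    return PairTestResult(
        lnl_indep=lnl_i, lnl_dep=lnl_d, independent=indep, dependent=dep,
        lr=lr, p_value=float(chi2.sf(lr, LR_DEGREES_OF_FREEDOM)),
        restarts_used=restarts_used, boundary=boundary,
        converged="negative_lr_after_refit" not in flags, flags=flags,
    )


# ---------------------------------------------------------------------
# All-pairs driver
# ---------------------------------------------------------------------


@dataclass
class AllPairsResult:
    """Symmetric LR matrix over informative profiles plus bookkeeping."""

    lr: pd.DataFrame  # square, diagonal = max off-diagonal LR
    pairs: pd.DataFrame  # i, j, lnl_indep, lnl_dep, lr, flags
    excluded_constant: list


def _pair_options(options: FitOptions, i: int, j: int) -> FitOptions:
    seq = np.random.SeedSequence((options.seed, i, j))
    sub = int(seq.generate_state(1)[0] % (2**31 - 1))
    return replace(options, seed=sub)


def all_pairs_lrt(matrix, tree, options: FitOptions = _DEFAULT,
                  checkpoint: str | None = None, chunk=None) -> AllPairsResult:
    """LRT for every unordered pair of distinct informative profiles.

    Profile columns constant across the tree's tips are excluded (and
    recorded).  Per-pair randomness is seeded from ``options.seed`` and
    the pair's position in sorted-id order, so results are identical
    regardless of evaluation order or chunking.  ``chunk=(k, n)``
    restricts computation to the k-th of n static partitions of the pair
    list; a checkpoint TSV collects finished pairs and makes the run
    resumable and mergeable.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    table = TreeTable.from_phylo(tree, length_floor=options.length_floor)
    missing = set(data.index) - set(table.tip_labels)
    if missing:
        raise ValueError(f"profile genomes absent from tree: {sorted(missing)}")
    ids = sorted(data.columns)
    informative, excluded = [], []
    for pid in ids:
        col = data[pid]
        (informative if 0 < col.sum() < len(col) else excluded).append(pid)
    done: dict[tuple, dict] = {}
    if checkpoint and os.path.exists(checkpoint):
        prev = pd.read_csv(checkpoint, sep="\t", comment="#")
        for rec in prev.to_dict("records"):
            done[(rec["i"], rec["j"])] = rec
    pair_list = list(itertools.combinations(range(len(informative)), 2))
    if chunk is not None:
        k, n = chunk
        pair_list = pair_list[k::n]
    records = []
    new_records = []
    for ii, jj in pair_list:
        pi, pj = informative[ii], informative[jj]
        if (pi, pj) in done:
            records.append(done[(pi, pj)])
            continue
        res = lrt_pair(table, data[pi], data[pj], _pair_options(options, ii, jj))
        rec = {"i": pi, "j": pj, "lnl_indep": res.lnl_indep,
               "lnl_dep": res.lnl_dep, "lr": res.lr,
               "flags": ";".join(res.flags) or "ok"}
        records.append(rec)
        new_records.append(rec)
    if checkpoint and new_records:
        header = not os.path.exists(checkpoint)
        pd.DataFrame(new_records).to_csv(checkpoint, sep="\t", index=False,
                                         mode="a", header=header)
    pairs = pd.DataFrame(records,
                         columns=["i", "j", "lnl_indep", "lnl_dep", "lr", "flags"])
    lr = pd.DataFrame(0.0, index=informative, columns=informative)
    for rec in records:
        lr.loc[rec["i"], rec["j"]] = rec["lr"]
        lr.loc[rec["j"], rec["i"]] = rec["lr"]
    if len(informative) > 1 and len(pairs):
        np.fill_diagonal(lr.values, float(pairs["lr"].max()))
    return AllPairsResult(lr=lr, pairs=pairs, excluded_constant=excluded)
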