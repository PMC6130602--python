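"""Simulators: birth–death trees and binary characters evolved on them.

These generators are a validation harness, not part of the inference
method: they produce trees and presence/absence data under exactly the
continuous-time Markov models that the likelihood machinery assumes, so
every statistic in the pipeline can be tested against known truth.

Correlated profile *blocks* are built from a latent "pathway presence"
character: one 2-state history is simulated per block and each member
profile copies its tip states with independent per-tip flips at a small
noise probability.  Profiles in different blocks (and the unstructured
background profiles) evolve independently.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from dendropy.model import birthdeath

from .pagel import DependentModel, IndependentModel
from .profiles import ProfileMatrix
from .treeio import PhyloTree

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_pair",
    "simulate_single_trait",
    "simulate_profile_set",
]

#: Default gain/loss rate for simulated characters, in events per unit
#: of mean root-to-tip depth: a handful of expected gains and losses
#: across a moderate tree, which is the patchy regime where
#: presence/absence profiles are informative.  ``rate_unit="branch"``
#: switches the simulators to raw branch-length units.
DEFAULT_RATE = 1.0


def _mean_depth(tree: PhyloTree) -> float:
    dtree = tree.dendropy_tree
    depth: dict = {}
    total, count = 0.0, 0
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = 0.0 if parent is None else (
            depth[id(parent)] + (node.edge.length or 0.0))
        if node.is_leaf():
            total += depth[id(node)]
            count += 1
    return total / count if count else 1.0


def _rate_scale(tree: PhyloTree, rate_unit: str) -> float:
    """Factor converting stated rates to per-branch-length rates."""
    if rate_unit == "branch":
        return 1.0
    if rate_unit == "depth":
        d = _mean_depth(tree)
        return 1.0 / d if d > 0 else 1.0
    raise ValueError(f"unknown rate_unit {rate_unit!r}")


@dataclass
class SimulationConfig:
    """Settings for :func:`simulate_profile_set`.

    ``block_sizes`` lists the sizes of the correlated blocks;
    ``n_independent`` background profiles evolve with no coupling.
    ``noise`` is the per-tip flip probability applied to each block
    member's copy of the latent block character.
    """

    block_sizes: list = field(default_factory=lambda: [5, 5])
    n_independent: int = 10
    noise: float = 0.05
    gain_rate: float = DEFAULT_RATE
    loss_rate: float = DEFAULT_RATE
    root_prior: str = "stationary"
    require_informative: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must lie in [0, 1]")
        for r in (self.gain_rate, self.loss_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


def simulate_tree(n_tips: int | None = None, birth_rate: float = 1.0,
                  death_rate: float = 0.0, seed: int = 0,
                  max_time: float | None = None) -> PhyloTree:
    """Random birth–death tree, conditioned on ``n_tips`` extant tips or
    run to ``max_time``.  Tip labels are t001, t002, ...; deterministic
    given ``seed``.  An unconditioned process that goes extinct returns
    ``None``.
    """
    if n_tips is None and max_time is None:
        raise ValueError("give n_tips or max_time")
    if birth_rate <= death_rate or death_rate < 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = random.Random(seed)
    kwargs = {}
    if n_tips is not None:
        if n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        kwargs["num_extant_tips"] = n_tips
    if max_time is not None:
        kwargs["max_time"] = max_time
    try:
        dtree = birthdeath.birth_death_tree(
            birth_rate, death_rate, rng=rng, repeat_until_success=n_tips is not None,
            **kwargs,
        )
    except birthdeath.TreeSimTotalExtinctionException:
        return None
    leaves = [n for n in dtree.leaf_node_iter()]
    ns = dendropy.TaxonNamespace()
    dtree.taxon_namespace = ns
    for i, leaf in enumerate(leaves):
        leaf.taxon = ns.new_taxon(label=f"t{i + 1:03d}")
    for node in dtree.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = 0.0
    return PhyloTree(dtree)


def _as_joint_model(model) -> DependentModel:
    if isinstance(model, IndependentModel):
        return DependentModel.from_independent(model)
    return model


def _draw_root(Q: np.ndarray, root_prior, rng) -> int:
    k = Q.shape[0]
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            p = np.full(k, 1.0 / k)
        elif root_prior == "stationary":
            w, V = np.linalg.eig(Q.T)
            v = np.abs(V[:, int(np.argmin(np.abs(w)))].real)
            p = v / v.sum() if v.sum() > 0 else np.full(k, 1.0 / k)
        else:
            raise ValueError(f"unknown root prior {root_prior!r}")
    else:
        p = np.asarray(root_prior, dtype=float)
        p = p / p.sum()
    return int(rng.choice(k, p=p))


def _evolve_branch(state: int, t: float, Q: np.ndarray, rng) -> int:
    """Exact CTMC realisation: exponential waiting times along a branch."""
    remaining = t
    while True:
        out = -Q[state, state]
        if out <= 0:
            return state
        wait = rng.exponential(1.0 / out)
        if wait >= remaining:
            return state
        remaining -= wait
        probs = Q[state].astype(float)
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(Q.shape[0], p=probs))


def _simulate_chain(tree: PhyloTree, Q: np.ndarray, root_prior, rng) -> dict:
    dtree = tree.dendropy_tree
    states: dict = {}
    tips: dict = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = _draw_root(Q, root_prior, rng)
        else:
            states[id(node)] = _evolve_branch(
                states[id(node.parent_node)], node.edge.length or 0.0, Q, rng)
        if node.is_leaf():
            tips[node.taxon.label] = states[id(node)]
    return tips


def simulate_pair(tree: PhyloTree, model, root_prior="stationary",
                  seed: int = 0, require_informative: bool = False,
                  max_attempts: int = 200, rate_unit: str = "depth"):
    """Joint binary tip states (x, y) for two characters.

    ``model`` is an :class:`IndependentModel` or :class:`DependentModel`;
    the joint 4-state chain is realised exactly along every branch.
    Rates are interpreted per unit of mean root-to-tip depth by default
    (``rate_unit="branch"`` uses the tree's raw scale).  With
    ``require_informative`` the draw is repeated (fresh sub-seeds)
    until both characters vary across tips.
    """
    Q = _as_joint_model(model).rate_matrix() * _rate_scale(tree, rate_unit)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        joint = _simulate_chain(tree, Q, root_prior, rng)
        x = {lab: s // 2 for lab, s in joint.items()}
        y = {lab: s % 2 for lab, s in joint.items()}
        if not require_informative:
            return x, y
        if 0 < sum(x.values()) < len(x) and 0 < sum(y.values()) < len(y):
            return x, y
    raise RuntimeError(f"no informative pair in {max_attempts} attempts")


def simulate_single_trait(tree: PhyloTree, alpha: float, beta: float,
                          root_prior="stationary", seed: int = 0,
                          require_informative: bool = False,
                          max_attempts: int = 200,
                          rate_unit: str = "depth") -> dict:
    """One binary character evolved by a 2-state chain (gain alpha,
    loss beta; per unit mean root-to-tip depth by default)."""
    Q = np.array([[-alpha, alpha], [beta, -beta]],
                 dtype=float) * _rate_scale(tree, rate_unit)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        x = _simulate_chain(tree, Q, root_prior, rng)
        if not require_informative or 0 < sum(x.values()) < len(x):
            return x
    raise RuntimeError(f"no informative character in {max_attempts} attempts")


def simulate_profile_set(tree: PhyloTree, config: SimulationConfig):
    """Profiles with known correlation structure (ground-truth labels).

    Returns ``(ProfileMatrix, labels)`` where ``labels`` maps each
    profile id to its block name (``block1``, ...) or to its own id for
    the independent background profiles.
    """
    labels: dict = {}
    columns: dict = {}
    tips = sorted(tree.tip_labels)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 99)))
    for b, size in enumerate(config.block_sizes, start=1):
        latent = simulate_single_trait(
            tree, config.gain_rate, config.loss_rate, config.root_prior,
            seed=int(rng.integers(2**31 - 1)),
            require_informative=config.require_informative)
        base = np.array([latent[t] for t in tips], dtype=np.int8)
        for m in range(1, size + 1):
            pid = f"block{b}_g{m}"
            for _ in range(200):
                flips = rng.random(len(tips)) < config.noise
                col = np.where(flips, 1 - base, base)
                if not config.require_informative or 0 < col.sum() < len(col):
                    break
            columns[pid] = col
            labels[pid] = f"block{b}"
    for k in range(1, config.n_independent + 1):
        pid = f"indep_g{k}"
        trait = simulate_single_trait(
            tree, config.gain_rate, config.loss_rate, config.root_prior,
            seed=int(rng.integers(2**31 - 1)),
            require_informative=config.require_informative)
        columns[pid] = np.array([trait[t] for t in tips], dtype=np.int8)
        labels[pid] = pid
    data = pd.DataFrame(columns, index=tips)
    dup = data.T.duplicated(keep=False)
    if dup.any():
        warnings.warn("simulated profile set contains duplicate columns")
    return ProfileMatrix(data=data), labels
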