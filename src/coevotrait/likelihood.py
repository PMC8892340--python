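"""Felsenstein pruning likelihood for binary and joint two-trait chains.

The same post-order dynamic program serves the single-trait (2-state) and the
paired dependent (4-state) models; node-level rescaling keeps partial
likelihoods in range on trees of hundreds of tips.  Uncertain tips enter as
ambiguous observations (partial likelihood 1 for every compatible state) and
additionally carry a constant 1/2 prior factor per uncertain observation; the
factor is identical under null and alternative models, so likelihood-ratio
statistics are unaffected by it.
"""

from __future__ import annotations

import math

import numpy as np

from coevotrait.ctmc import RateSpec2, RateSpec4, RootPrior, transition_probabilities
from coevotrait.phylo import Tree, TreeIndex
from coevotrait.traits import UNCERTAIN, TraitStates

__all__ = ["prune_loglik", "tip_partials_single", "tip_partials_joint", "prune_loglik_indexed"]

_LOG_HALF = math.log(0.5)

_PARTIAL2 = {
    "0": np.array([1.0, 0.0]),
    "1": np.array([0.0, 1.0]),
    UNCERTAIN: np.array([1.0, 1.0]),
}


def _states_for_tips(index: TreeIndex, states: TraitStates) -> list[str]:
    missing = [lab for lab in index.tip_index if lab not in states]
    if missing:
        raise KeyError(f"species missing from trait states: {sorted(missing)}")
    return [states[lab] for lab in index.tip_index]


def tip_partials_single(index: TreeIndex, states: TraitStates) -> tuple[np.ndarray, int]:
    """(n_tips, 2) partial-likelihood rows plus the count of uncertain tips."""
    symbols = _states_for_tips(index, states)
    partials = np.stack([_PARTIAL2[s] for s in symbols])
    return partials, sum(1 for s in symbols if s == UNCERTAIN)


def tip_partials_joint(
    index: TreeIndex, focal: TraitStates, gene: TraitStates
) -> tuple[np.ndarray, int]:
    """(n_tips, 4) joint partials on states ((0,0),(0,1),(1,0),(1,1)).

    The joint partial at a tip factorizes over the two traits:
    ``partial[2*f + g] = focal_partial[f] * gene_partial[g]``.
    """
    fsym = _states_for_tips(index, focal)
    gsym = _states_for_tips(index, gene)
    partials = np.empty((index.n_tips, 4))
    for i, (fs, gs) in enumerate(zip(fsym, gsym)):
        partials[i] = np.kron(_PARTIAL2[fs], _PARTIAL2[gs])
    n_unc = sum(1 for s in fsym if s == UNCERTAIN) + sum(
        1 for s in gsym if s == UNCERTAIN
    )
    return partials, n_unc


def prune_loglik_indexed(
    index: TreeIndex,
    tip_partials: np.ndarray,
    rates: RateSpec2 | RateSpec4,
    root_probs: np.ndarray,
    n_uncertain: int = 0,
) -> float:
    """Pruning log-likelihood over a prebuilt :class:`TreeIndex`.

    This is the hot path used by the optimizers; ``prune_loglik`` is the
    validated public wrapper.  Returns ``-inf`` for zero-probability
    configurations rather than raising.
    """
    k = tip_partials.shape[1]
    P = transition_probabilities(rates, np.asarray(index.lengths))
    partial = np.zeros((index.n_nodes, k))
    partial[: index.n_tips] = tip_partials
    log_scale = 0.0
    for i in index.postorder_internal:
        l, r = index.left[i], index.right[i]
        v = (P[l] @ partial[l]) * (P[r] @ partial[r])
        m = v.max()
        if m <= 0.0 or not np.isfinite(m):
            return -np.inf
        partial[i] = v / m
        log_scale += math.log(m)
    like = float(root_probs @ partial[index.root])
    if like <= 0.0:
        return -np.inf
    return math.log(like) + log_scale + n_uncertain * _LOG_HALF


def prune_loglik(
    tree: Tree,
    states: TraitStates | tuple[TraitStates, TraitStates],
    rates: RateSpec2 | RateSpec4,
    root: RootPrior,
) -> float:
    """Log-likelihood of tip states under a CTMC on a bifurcating tree.

    Parameters
    ----------
    tree : Tree
        Strictly bifurcating, time-calibrated.
    states : TraitStates or (focal, gene) pair
        A single trait for :class:`RateSpec2`; an ordered (focal, gene) pair
        of traits for :class:`RateSpec4`.
    rates : RateSpec2 | RateSpec4
    root : RootPrior
        Length-2 (single trait) or length-4 (joint) state prior at the root.

    Returns
    -------
    float
        Finite log-likelihood <= 0, or ``-inf`` when the configuration has
        probability zero (e.g. the root prior excludes every state the data
        allow).
    """
    index = TreeIndex(tree)
    root_probs = root.as_array()
    if isinstance(rates, RateSpec2):
        if not isinstance(states, TraitStates):
            raise TypeError("RateSpec2 requires a single TraitStates")
        if len(root_probs) != 2:
            raise ValueError("2-state model needs a length-2 root prior")
        partials, n_unc = tip_partials_single(index, states)
    else:
        if not (isinstance(states, tuple) and len(states) == 2):
            raise TypeError("RateSpec4 requires a (focal, gene) TraitStates pair")
        if len(root_probs) != 4:
            raise ValueError("4-state model needs a length-4 root prior")
        partials, n_unc = tip_partials_joint(index, states[0], states[1])
    return prune_loglik_indexed(index, partials, rates, root_probs, n_unc)
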