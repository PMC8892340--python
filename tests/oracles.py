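"""Independent brute-force oracles used to validate the dynamic programs.

These deliberately avoid the package's pruning/parsimony code paths: tree
likelihoods are computed by exhaustive summation over all internal-node
state assignments, and Dollo loss counts by exhaustive minimization over
all Dollo-consistent labelings.  Only feasible for tiny instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from coevotrait.ctmc import transition_matrix
from coevotrait.traits import UNCERTAIN


def _collect(tree):
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    tips = [n for n in nodes if n.is_leaf]
    return nodes, internal, tips


def brute_force_loglik(tree, tip_states, rates, root_probs, uncertain_factor=0.5):
    """Sum over every internal-node assignment; tips sum over compatible
    states.  ``tip_states`` maps label -> set of allowed state indices (and
    the number of uncertain observations is passed via states of full size).
    """
    k = len(root_probs)
    nodes, internal, tips = _collect(tree)
    P = {id(n): transition_matrix(rates, n.length) for n in nodes if n is not tree.root}

    n_unc = sum(1 for allowed in tip_states.values() if len(allowed) == k)

    def tree_prob(assign):
        total = 0.0
        # recursively sum over tip states given internal assignment
        def node_prob(node, state):
            prob = 1.0
            for child in node.children:
                if child.is_leaf:
                    s = 0.0
                    for cs in tip_states[child.label]:
                        s += P[id(child)][state, cs]
                    prob *= s
                else:
                    prob *= P[id(child)][state, assign[id(child)]] * node_prob(
                        child, assign[id(child)]
                    )
            return prob

        root_state = assign[id(tree.root)]
        return root_probs[root_state] * node_prob(tree.root, root_state)

    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        total += tree_prob(assign)
    if total <= 0:
        return -np.inf
    return math.log(total) + n_unc * math.log(uncertain_factor)


def binary_tip_sets(states):
    """TraitStates -> label -> allowed {0,1} indices."""
    out = {}
    for sp, s in states.items():
        out[sp] = {0, 1} if s == UNCERTAIN else {int(s)}
    return out


def joint_tip_sets(focal, gene):
    """(focal, gene) TraitStates -> allowed joint-state indices (focal first)."""
    out = {}
    for sp in focal:
        f = {0, 1} if focal[sp] == UNCERTAIN else {int(focal[sp])}
        g = {0, 1} if gene[sp] == UNCERTAIN else {int(gene[sp])}
        out[sp] = {2 * a + b for a in f for b in g}
    return out


def joint_uncertain_count(focal, gene):
    return sum(1 for s in focal.values() if s == UNCERTAIN) + sum(
        1 for s in gene.values() if s == UNCERTAIN
    )


def brute_force_dollo(tree, states):
    """Minimum 1->0 transitions over all Dollo-consistent labelings.

    Root fixed at 1; no 0->1 edge anywhere; certain tips must match.
    """
    nodes = list(tree.postorder())
    best = None
    for combo in itertools.product((0, 1), repeat=len(nodes)):
        assign = {id(n): s for n, s in zip(nodes, combo)}
        if assign[id(tree.root)] != 1:
            continue
        ok = True
        losses = 0
        for n in nodes:
            if n.is_leaf:
                s = states[n.label]
                if s != UNCERTAIN and int(s) != assign[id(n)]:
                    ok = False
                    break
            for c in n.children:
                if assign[id(n)] == 0 and assign[id(c)] == 1:
                    ok = False
                    break
                if assign[id(n)] == 1 and assign[id(c)] == 0:
                    losses += 1
            if not ok:
                break
        if ok and (best is None or losses < best):
            best = losses
    return best


def brute_force_codon_loglik(tree, seq_codons, Q, freqs):
    """Exhaustive codon-tree likelihood for tiny trees/alignments.

    ``seq_codons`` maps tip label -> list of codon indices; one shared Q.
    """
    import scipy.linalg

    nodes, internal, tips = _collect(tree)
    P = {
        id(n): scipy.linalg.expm(Q * n.length)
        for n in nodes
        if n is not tree.root
    }
    n_sites = len(next(iter(seq_codons.values())))
    total_ll = 0.0
    for site in range(n_sites):
        site_total = 0.0
        for combo in itertools.product(range(61), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, combo)}
            prob = freqs[assign[id(tree.root)]]
            stack = [tree.root]
            while stack:
                node = stack.pop()
                for child in node.children:
                    ps = assign[id(node)]
                    if child.is_leaf:
                        cs = seq_codons[child.label][site]
                    else:
                        cs = assign[id(child)]
                        stack.append(child)
                    prob *= P[id(child)][ps, cs]
            site_total += prob
        total_ll += math.log(site_total)
    return total_ll
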