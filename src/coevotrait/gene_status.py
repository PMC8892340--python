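"""Gene status calls, Dollo loss counting, and species-tree thinning.

Status calling turns tabulated domain hits (species, gene, domain, e-value)
into complete / partial / absent calls: a gene is a complete ortholog when
every required diagnostic domain passes the strict completeness threshold
(1e-4 by default), partial when some required domain is detectable at the
looser presence threshold (0.1) but the full set is not, and absent when no
required domain is detectable.  Genes without detectable domains are called
on hit presence alone.  Binarized calls (complete -> 1, otherwise 0, with an
explicit uncertain symbol) feed the coevolution screen.

Loss counting assumes a single origin of the gene (present at the root) with
any number of subsequent losses and no regains — Dollo parsimony — and
returns both the minimum number of 1 -> 0 transitions and the maximal
subtrees assigned state 0.  Uncertain tips are compatible with either state
and never force a loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from coevotrait.phylo import Node, Tree, TreeError
from coevotrait.traits import UNCERTAIN, TraitStates

__all__ = [
    "DomainHit",
    "GeneStatusCall",
    "CallConfig",
    "read_domain_hits",
    "call_status",
    "binarize",
    "count_losses",
    "thin_tree",
    "LossReport",
]


@dataclass(frozen=True)
class DomainHit:
    species: str
    gene: str
    domain: str
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class GeneStatusCall:
    species: str
    gene: str
    status: str  # complete | partial | absent | uncertain
    domains: dict[str, float] = field(default_factory=dict)  # best e-value each


@dataclass(frozen=True)
class CallConfig:
    """Thresholds and domain requirements for status calling.

    required_domains maps gene -> set of diagnostic (superfamily) domains;
    genes in ``domainless_genes`` are called from hit presence alone.  The
    presence threshold (0.1) decides whether a domain is detectable at all;
    the stricter completeness threshold (1e-4) decides whether it counts
    toward a complete ortholog.
    """

    required_domains: dict[str, frozenset[str]]
    domain_evalue: float = 0.1
    completeness_evalue: float = 1e-4
    domainless_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.domain_evalue <= 0 or self.completeness_evalue <= 0:
            raise ValueError("thresholds must be > 0")


def read_domain_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "gene": str, "domain": str})
    required = {"species", "gene", "domain", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain-hit table missing columns: {sorted(missing)}")
    return df


def call_status(
    hits: pd.DataFrame,
    config: CallConfig,
    gene: str,
    species: list[str] | None = None,
) -> dict[str, GeneStatusCall]:
    """Status call per species for one gene.

    Parameters
    ----------
    hits : DataFrame with columns species, gene, domain, evalue (may contain
        several genes; rows are filtered to ``gene``).
    species : optional universe of species; species without any hit row are
        called absent.  Defaults to the species appearing in ``hits``.
    """
    sub = hits[hits["gene"] == gene]
    universe = list(species) if species is not None else sorted(sub["species"].unique())
    domainless = gene in config.domainless_genes
    required = config.required_domains.get(gene)
    if required is None and not domainless:
        raise KeyError(
            f"gene {gene!r} has no required-domain entry and is not in the "
            "domain-less list"
        )
    best: dict[str, dict[str, float]] = {}
    for row in sub.itertuples():
        d = best.setdefault(row.species, {})
        e = float(row.evalue)
        if row.domain not in d or e < d[row.domain]:
            d[str(row.domain)] = e

    calls: dict[str, GeneStatusCall] = {}
    for sp in universe:
        doms = best.get(sp, {})
        if domainless:
            status = "complete" if sp in set(sub["species"]) else "absent"
            calls[sp] = GeneStatusCall(sp, gene, status, doms)
            continue
        detectable = {d for d in required if doms.get(d, float("inf")) <= config.domain_evalue}
        complete = all(
            doms.get(d, float("inf")) <= config.completeness_evalue for d in required
        )
        if complete:
            status = "complete"
        elif detectable:
            status = "partial"
        else:
            status = "absent"
        calls[sp] = GeneStatusCall(sp, gene, status, doms)
    return calls


def binarize(calls: dict[str, GeneStatusCall]) -> TraitStates:
    """Complete -> 1; partial/absent -> 0; uncertain -> '?'."""
    mapping = {"complete": "1", "partial": "0", "absent": "0", "uncertain": UNCERTAIN}
    out = {}
    for sp, call in calls.items():
        if call.status not in mapping:
            raise ValueError(f"unknown status {call.status!r} for {sp}")
        out[sp] = mapping[call.status]
    return TraitStates(out)


@dataclass
class LossReport:
    n_losses: int
    loss_clades: list[list[str]]  # tip labels of each maximal 0-subtree


def count_losses(tree: Tree, states: TraitStates) -> LossReport:
    """Minimum 1->0 transitions under Dollo parsimony (root present).

    A subtree is assigned 0 only when it contains at least one certain-0 tip
    and no certain-1 tip; subtrees of purely uncertain tips are compatible
    with presence and are never counted as losses.  Returns the count and
    the maximal state-0 subtrees (the loss clades).
    """
    missing = [t for t in tree.tip_labels if t not in states]
    if missing:
        raise KeyError(f"species missing from states: {sorted(missing)}")

    # resolution: '1' if any certain-1 tip below, else '0' if any certain-0,
    # else '?' (all-uncertain)
    resolved: dict[int, str] = {}
    tips_below: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            resolved[id(node)] = states[node.label]
            tips_below[id(node)] = [node.label]
        else:
            kid_states = [resolved[id(c)] for c in node.children]
            if "1" in kid_states:
                resolved[id(node)] = "1"
            elif "0" in kid_states:
                resolved[id(node)] = "0"
            else:
                resolved[id(node)] = UNCERTAIN
            tips_below[id(node)] = [
                t for c in node.children for t in tips_below[id(c)]
            ]

    clades: list[list[str]] = []

    def collect(node: Node, parent_present: bool) -> None:
        state = resolved[id(node)]
        if state == "0" and parent_present:
            clades.append(tips_below[id(node)])
            return
        for child in node.children:
            collect(child, parent_present=state == "1")
        # a 0-node under a 0-parent is inside an already-collected clade

    # root assumed present (single origin); its 0-children are losses
    for child in tree.root.children:
        collect(child, parent_present=True)
    if tree.root.is_leaf and resolved[id(tree.root)] == "0":
        clades.append(tips_below[id(tree.root)])
    return LossReport(n_losses=len(clades), loss_clades=clades)


# ---------------------------------------------------------------------------
# tree thinning


def _tip_set(node: Node) -> list[str]:
    return [n.label for n in _iter_tips(node)]


def _iter_tips(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(reversed(n.children))


def _pairwise_pd(tree: Tree, subset: tuple[str, ...]) -> float:
    # sum over pairs of path lengths; small subsets only
    depths: dict[str, float] = {}
    paths: dict[str, list[Node]] = {}

    def walk(node: Node, path: list[Node]):
        path = path + [node]
        if node.is_leaf and node.label in subset:
            paths[node.label] = path
        for c in node.children:
            walk(c, path)

    walk(tree.root, [])
    total = 0.0
    for a, b in itertools.combinations(subset, 2):
        pa, pb = paths[a], paths[b]
        shared = 0
        for x, y in zip(pa, pb):
            if x is y:
                shared += 1
            else:
                break
        total += sum(n.length for n in pa[shared:]) + sum(
            n.length for n in pb[shared:]
        )
    return total


def _choose_loss_representatives(
    tree: Tree, clade: list[str], quality: dict[str, float], k: int
) -> list[str]:
    """Pick k species from a loss clade: maximize phylogenetic diversity,
    then total quality, then lexicographic species ids."""
    if len(clade) <= k:
        return list(clade)
    candidates = sorted(clade)
    n_combos = (
        len(candidates) * (len(candidates) - 1) * (len(candidates) - 2) // 6
        if k == 3
        else None
    )
    if n_combos is not None and n_combos > 5000:
        # greedy farthest-point fallback for very large clades
        chosen = [max(candidates, key=lambda s: (quality.get(s, 0.0), s))]
        while len(chosen) < k:
            best = max(
                (c for c in candidates if c not in chosen),
                key=lambda s: (
                    _pairwise_pd(tree, tuple(chosen + [s])),
                    quality.get(s, 0.0),
                    s,
                ),
            )
            chosen.append(best)
        return sorted(chosen)
    best_key = None
    best_subset = None
    for subset in itertools.combinations(candidates, k):
        key = (
            _pairwise_pd(tree, subset),
            sum(quality.get(s, 0.0) for s in subset),
            tuple(sorted(subset, reverse=True)),
        )
        if best_key is None or key > best_key:
            best_key = key
            best_subset = subset
    return sorted(best_subset)


def thin_tree(
    tree: Tree,
    focal_states: TraitStates,
    quality: dict[str, float] | None = None,
    max_per_loss: int = 3,
) -> Tree:
    """Reduce the tree to a strictly bifurcating one per the screen's rules.

    Two passes: (1) resolve every polytomy by dropping whole child subtrees —
    the minimal species removal that can resolve a k-furcation keeps the two
    children that retain the most species while preserving every focal state
    observed among the node's children; (2) for each focal-gene loss clade
    with more than ``max_per_loss`` tips, keep ``max_per_loss`` species chosen
    to maximize pairwise path length, then assembly quality, then
    lexicographic order.

    Raises
    ------
    TreeError
        If thinning would eliminate a focal-state transition (the loss count
        on the retained species must match the original count).
    """
    quality = quality or {}
    before = count_losses(tree, focal_states)

    work = tree.copy()
    removed: set[str] = set()

    def certain_states(node: Node) -> set[str]:
        return {
            focal_states[t.label]
            for t in _iter_tips(node)
            if focal_states[t.label] != UNCERTAIN
        }

    for node in work.postorder():
        while len(node.children) > 2:
            kids = node.children
            needed = set().union(*(certain_states(k) for k in kids))
            best_pair = None
            best_key = None
            for pair in itertools.combinations(range(len(kids)), 2):
                cover = certain_states(kids[pair[0]]) | certain_states(kids[pair[1]])
                n_kept = sum(len(_tip_set(kids[i])) for i in pair)
                qual = sum(
                    quality.get(t, 0.0) for i in pair for t in _tip_set(kids[i])
                )
                labels = tuple(sorted(min(_tip_set(kids[i])) for i in pair))
                key = (cover >= needed, n_kept, qual, tuple(sorted(labels, reverse=True)))
                if best_key is None or key > best_key:
                    best_key = key
                    best_pair = pair
            if not best_key[0]:
                raise TreeError(
                    "cannot resolve polytomy without eliminating a focal-state "
                    "transition"
                )
            for i, kid in enumerate(kids):
                if i not in best_pair:
                    removed.update(_tip_set(kid))
            node.children = [kids[i] for i in best_pair]

    keep = set(work.tip_labels) - removed
    work = tree.prune_to(keep)

    # pass 2: cap each loss clade at max_per_loss representatives
    states_kept = focal_states.restrict(keep)
    report = count_losses(work, states_kept)
    for clade in report.loss_clades:
        if len(clade) > max_per_loss:
            reps = _choose_loss_representatives(work, clade, quality, max_per_loss)
            keep -= set(clade) - set(reps)
    result = tree.prune_to(keep)

    after = count_losses(result, focal_states.restrict(keep))
    if after.n_losses != before.n_losses:
        raise TreeError(
            f"thinning changed the focal loss count ({before.n_losses} -> "
            f"{after.n_losses}); a state transition was eliminated"
        )
    return result
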