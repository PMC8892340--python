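"""Branch-model dN/dS fitting and relaxation tests.

These are the codeml-style branch models used to ask whether a gene's
selective constraint relaxes on lineages that have lost the focal gene: a
null model with a single omega on every branch is compared against models
with a separate omega for the branches on which the focal gene is absent or
was lost (one extra class, 1 df), or with one extra omega per independent
loss (df = number of distinct omegas minus one).  A one-branch pairwise mode
covers the case where only two sequences are alignable, and a fixed-omega
variant supports the omega = 1 (neutrality) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from coevotrait.codon import (
    CodonAlignment,
    CodonModelParams,
    codon_Q,
    codon_frequencies,
    substitution_flows,
)
from coevotrait.phylo import Tree, TreeIndex
from coevotrait.traits import UNCERTAIN, TraitStates

__all__ = [
    "CodonBranchModel",
    "CodonFitResults",
    "OmegaTestResult",
    "branch_classes_two",
    "branch_classes_per_loss",
    "fit_branch_model",
    "lrt_relaxation",
    "test_omega_equals_1",
    "pairwise_omega",
    "PairwiseOmega",
    "write_omega_results",
    "write_branch_classes",
    "read_branch_classes",
]


# ---------------------------------------------------------------------------
# branch-class helpers


def _subtree_status(index: TreeIndex, states: TraitStates) -> list[str]:
    """Per node: '1' if any certain-present tip below, else '0' if any
    certain-absent tip, else '?'."""
    status = [""] * index.n_nodes
    for i in range(index.n_tips):
        status[i] = states[index.labels[i]]
    for i in index.postorder_internal:
        kids = (status[index.left[i]], status[index.right[i]])
        if "1" in kids:
            status[i] = "1"
        elif "0" in kids:
            status[i] = "0"
        else:
            status[i] = UNCERTAIN
    return status


def branch_classes_two(tree: Tree, focal_states: TraitStates) -> dict[int, str]:
    """Two-class map: 'absent' on every branch whose subtree lacks the focal
    gene (including the stem branch of each loss clade), 'present' elsewhere.

    Branches are keyed by the child-node index of ``TreeIndex(tree)``.
    """
    index = TreeIndex(tree)
    status = _subtree_status(index, focal_states)
    return {
        i: ("absent" if status[i] == "0" else "present")
        for i in range(index.n_nodes)
        if i != index.root
    }


def branch_classes_per_loss(tree: Tree, focal_states: TraitStates) -> dict[int, str]:
    """Like :func:`branch_classes_two` but the stem branch of each
    independent loss gets its own class ('loss1', 'loss2', ...)."""
    index = TreeIndex(tree)
    status = _subtree_status(index, focal_states)
    classes = {
        i: ("absent" if status[i] == "0" else "present")
        for i in range(index.n_nodes)
        if i != index.root
    }
    # stem branches: 0-status nodes whose parent subtree still has the gene
    parent = [-1] * index.n_nodes
    for i in index.postorder_internal:
        parent[index.left[i]] = i
        parent[index.right[i]] = i
    k = 0
    for i in range(index.n_nodes):
        if i == index.root or classes[i] != "absent":
            continue
        par = parent[i]
        if par == -1 or status[par] == "1" or par == index.root:
            k += 1
            classes[i] = f"loss{k}"
    return classes


# ---------------------------------------------------------------------------
# likelihood engine


class _CodonPruner:
    """Pattern-compressed pruning over the 61-codon state space."""

    def __init__(self, index: TreeIndex, aln: CodonAlignment, freqs: np.ndarray,
                 classes: dict[int, str]):
        self.index = index
        self.freqs = freqs
        order = [index.labels[i] for i in range(index.n_tips)]
        mat, self.dropped_columns = aln.encode(order)
        if mat.shape[1] == 0:
            raise ValueError("no ungapped codon columns left in the alignment")
        patterns, counts = np.unique(mat, axis=1, return_counts=True)
        self.patterns = patterns  # (n_tips, n_pat)
        self.counts = counts.astype(float)
        self.classes = classes
        self.class_labels = sorted(set(classes.values()))
        self.sqrt_pi = np.sqrt(freqs)

    def _eig(self, kappa: float, omega: float):
        Q = codon_Q(kappa, omega, self.freqs)
        B = (self.sqrt_pi[:, None] * Q) / self.sqrt_pi[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        return lam, V

    def loglik(self, t: np.ndarray, kappa: float, omega: dict[str, float]) -> float:
        """t: branch length above each node (root entry ignored)."""
        index = self.index
        eigs = {lab: self._eig(kappa, omega[lab]) for lab in self.class_labels}
        inv_sqrt = 1.0 / self.sqrt_pi
        P = [None] * index.n_nodes
        for i in range(index.n_nodes):
            if i == index.root:
                continue
            lam, V = eigs[self.classes[i]]
            # P(t) = D^{-1/2} V exp(lam t) V' D^{1/2}
            expl = np.exp(lam * t[i])
            M = (V * expl) @ V.T
            P[i] = (inv_sqrt[:, None] * M) * self.sqrt_pi[None, :]
        n_pat = self.patterns.shape[1]
        partial = [None] * index.n_nodes
        log_scale = np.zeros(n_pat)
        for i in index.postorder_internal:
            prod = np.ones((n_pat, 61))
            for child in (index.left[i], index.right[i]):
                if child < index.n_tips:
                    prod *= P[child][:, self.patterns[child]].T
                else:
                    prod *= partial[child] @ P[child].T
            m = prod.max(axis=1)
            if np.any(m <= 0) or not np.all(np.isfinite(m)):
                return -np.inf
            log_scale += np.log(m)
            partial[i] = prod / m[:, None]
        site_like = partial[index.root] @ self.freqs
        if np.any(site_like <= 0):
            return -np.inf
        return float(self.counts @ (np.log(site_like) + log_scale))


@dataclass
class CodonFitResults:
    """Fitted branch-class codon model."""

    params: CodonModelParams
    llf: float
    branch_lengths: dict[int, float]
    n_restarts: int
    seed: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    dropped_columns: list[int] = field(default_factory=list)

    @property
    def n_free_omega(self) -> int:
        fixed = getattr(self.params, "_fixed", None)
        return len(self.params.omega) - (len(fixed) if fixed else 0)

    def summary(self) -> str:
        lines = [
            "Branch-model codon fit",
            "=" * 30,
            f"log-likelihood {self.llf:.4f}",
            f"kappa {self.params.kappa:.4f}   freq model {self.params.freq_model}",
        ]
        for lab, w in sorted(self.params.omega.items()):
            lines.append(f"omega[{lab}] = {w:.4f}")
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


class CodonBranchModel:
    """A codon alignment on a tree with branch classes, ready to fit.

    Parameters
    ----------
    tree : Tree (bifurcating; alignment species must equal tree tips)
    aln : CodonAlignment
    branch_classes : dict node-index -> class label, or None for one class
        ('all'); see :func:`branch_classes_two` / :func:`branch_classes_per_loss`.
    freq_model : 'equal' | 'F1x4' | 'F3x4'
    """

    def __init__(
        self,
        tree: Tree,
        aln: CodonAlignment,
        branch_classes: dict[int, str] | None = None,
        freq_model: str = "F3x4",
    ):
        self.tree = tree
        self.index = TreeIndex(tree)
        if set(aln.species) != set(tree.tip_labels):
            raise ValueError("alignment species must match tree tips")
        if branch_classes is None:
            branch_classes = {
                i: "all" for i in range(self.index.n_nodes) if i != self.index.root
            }
        present = set(branch_classes.values())
        for i in range(self.index.n_nodes):
            if i != self.index.root and i not in branch_classes:
                raise ValueError(f"branch above node {i} has no class assignment")
        counts = {lab: 0 for lab in present}
        for i, lab in branch_classes.items():
            counts[lab] += 1
        empty = [lab for lab, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"branch class(es) with no branches: {empty}")
        self.aln = aln
        self.freq_model = freq_model
        self.freqs = codon_frequencies(freq_model, list(aln.sequences.values()))
        self.classes = dict(branch_classes)
        self.pruner = _CodonPruner(self.index, aln, self.freqs, self.classes)

    def fit(
        self,
        restarts: int = 5,
        seed: int = 0,
        fixed_omega: dict[str, float] | None = None,
        maxiter: int = 300,
    ) -> CodonFitResults:
        """Joint ML over branch lengths, kappa and per-class omega.

        ``fixed_omega`` pins selected classes (e.g. {'absent': 1.0} for the
        neutrality null); the remaining omegas stay free.  The first start
        is a heuristic (branch lengths from observed divergence, kappa = 2,
        omega = 0.3); further starts are drawn log-uniformly.
        """
        fixed_omega = fixed_omega or {}
        labels = self.pruner.class_labels
        free_labels = [lab for lab in labels if lab not in fixed_omega]
        index = self.index
        branch_nodes = [i for i in range(index.n_nodes) if i != index.root]
        nb = len(branch_nodes)
        dim = nb + 1 + len(free_labels)

        warnings: list[str] = []
        pat = self.pruner.patterns
        if np.all(pat == pat[:1, :]):
            warnings.append(
                "all sequences identical at retained columns; omega is "
                "unidentifiable (flat likelihood)"
            )
        if self.pruner.dropped_columns:
            warnings.append(
                f"dropped {len(self.pruner.dropped_columns)} gapped/ambiguous "
                "codon columns alignment-wide"
            )

        t_bounds = (math.log(1e-7), math.log(60.0))
        k_bounds = (math.log(1e-2), math.log(1e2))
        w_bounds = (math.log(1e-6), math.log(1e2))
        bounds = [t_bounds] * nb + [k_bounds] + [w_bounds] * len(free_labels)

        def unpack(x):
            t = np.zeros(index.n_nodes)
            t[branch_nodes] = np.exp(x[:nb])
            kappa = math.exp(x[nb])
            omega = dict(fixed_omega)
            for j, lab in enumerate(free_labels):
                omega[lab] = math.exp(x[nb + 1 + j])
            return t, kappa, omega

        def neg(x):
            t, kappa, omega = unpack(x)
            ll = self.pruner.loglik(t, kappa, omega)
            return -ll if np.isfinite(ll) else 1e12

        # heuristic start: mean pairwise codon divergence spread over branches
        div = self._mean_divergence()
        t0 = max(div, 1e-3)
        x0 = np.concatenate(
            [
                np.full(nb, math.log(t0)),
                [math.log(2.0)],
                np.full(len(free_labels), math.log(0.3)),
            ]
        )
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(restarts - 1):
            xt = np.concatenate(
                [
                    rng.uniform(math.log(1e-3), math.log(2.0), size=nb),
                    rng.uniform(math.log(0.5), math.log(10.0), size=1),
                    rng.uniform(math.log(0.02), math.log(3.0), size=len(free_labels)),
                ]
            )
            starts.append(xt)
        best = None
        ok = False
        for s in starts:
            res = scipy.optimize.minimize(
                neg, s, method="L-BFGS-B", bounds=bounds,
                # eps: the likelihood's numerical noise (~1e-7 relative)
                # defeats the default 1e-8 finite-difference step
                options={"ftol": 1e-9, "maxiter": maxiter, "eps": 1e-6},
            )
            ok = ok or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        t, kappa, omega = unpack(best.x)
        params = CodonModelParams(
            kappa=kappa,
            omega=omega,
            freqs=self.freqs,
            freq_model=self.freq_model,
            branch_classes=dict(self.classes),
        )
        object.__setattr__(params, "_fixed", dict(fixed_omega))
        return CodonFitResults(
            params=params,
            llf=-best.fun,
            branch_lengths={i: float(t[i]) for i in branch_nodes},
            n_restarts=restarts,
            seed=seed,
            converged=ok,
            warnings=warnings,
            dropped_columns=list(self.pruner.dropped_columns),
        )

    def _mean_divergence(self) -> float:
        pat = self.pruner.patterns
        counts = self.pruner.counts
        total = counts.sum()
        diffs = []
        for a in range(pat.shape[0]):
            for b in range(a + 1, pat.shape[0]):
                diffs.append(((pat[a] != pat[b]) * counts).sum() / total)
        return float(np.mean(diffs)) if diffs else 0.0


def fit_branch_model(
    tree: Tree,
    aln: CodonAlignment,
    branch_classes: dict[int, str] | None = None,
    freq_model: str = "F3x4",
    restarts: int = 5,
    seed: int = 0,
    fixed_omega: dict[str, float] | None = None,
) -> CodonFitResults:
    """Functional wrapper over :class:`CodonBranchModel`."""
    model = CodonBranchModel(tree, aln, branch_classes, freq_model)
    return model.fit(restarts=restarts, seed=seed, fixed_omega=fixed_omega)


@dataclass
class OmegaTestResult:
    tag: str
    lnL0: float
    lnL1: float
    df: int
    stat: float
    p: float
    omega: dict[str, float]


def _free_omega_count(fit: CodonFitResults) -> int:
    fixed = getattr(fit.params, "_fixed", {}) or {}
    return len(fit.params.omega) - len(fixed)


def lrt_relaxation(fit_null: CodonFitResults, fit_alt: CodonFitResults) -> OmegaTestResult:
    """LRT between nested branch-class fits; df = difference in free omegas.

    The null's class map must be a coarsening of the alternative's (every
    alternative class must map into exactly one null class on the same
    branches).
    """
    null_classes = fit_null.params.branch_classes
    alt_classes = fit_alt.params.branch_classes
    if set(null_classes) != set(alt_classes):
        raise ValueError("fits are on different trees/branches")
    mapping: dict[str, str] = {}
    for branch, alt_lab in alt_classes.items():
        null_lab = null_classes[branch]
        if mapping.setdefault(alt_lab, null_lab) != null_lab:
            raise ValueError(
                "models are not nested: alternative class "
                f"{alt_lab!r} spans several null classes"
            )
    df = _free_omega_count(fit_alt) - _free_omega_count(fit_null)
    if df < 0:
        raise ValueError("alternative has fewer free omegas than the null")
    if df == 0:
        stat = max(0.0, 2.0 * (fit_alt.llf - fit_null.llf))
        return OmegaTestResult("relaxation", fit_null.llf, fit_alt.llf, 0, stat, 1.0,
                               dict(fit_alt.params.omega))
    stat = max(0.0, 2.0 * (fit_alt.llf - fit_null.llf))
    p = float(scipy.stats.chi2.sf(stat, df))
    return OmegaTestResult(
        "relaxation", fit_null.llf, fit_alt.llf, df, stat, p,
        dict(fit_alt.params.omega),
    )


def test_omega_equals_1(
    tree: Tree,
    aln: CodonAlignment,
    branch_classes: dict[int, str] | None,
    target_class: str,
    freq_model: str = "F3x4",
    restarts: int = 5,
    seed: int = 0,
) -> OmegaTestResult:
    """Neutrality test: fix the target class's omega at 1 (null) vs free
    (alternative); 1 df."""
    model = CodonBranchModel(tree, aln, branch_classes, freq_model)
    if target_class not in model.pruner.class_labels:
        raise ValueError(f"no branch has class {target_class!r}")
    null = model.fit(restarts=restarts, seed=seed, fixed_omega={target_class: 1.0})
    alt = model.fit(restarts=restarts, seed=seed)
    stat = max(0.0, 2.0 * (alt.llf - null.llf))
    p = float(scipy.stats.chi2.sf(stat, 1))
    return OmegaTestResult(
        f"omega[{target_class}]=1", null.llf, alt.llf, 1, stat, p,
        dict(alt.params.omega),
    )


def write_omega_results(rows, path) -> None:
    """TSV of relaxation/neutrality tests: one row per (clade, gene, test).

    ``rows`` is an iterable of (clade, gene, OmegaTestResult).
    """
    import pandas as pd

    records = []
    for clade, gene, res in rows:
        rec = {
            "clade": clade, "gene": gene, "model_pair": res.tag,
            "lnL0": res.lnL0, "lnL1": res.lnL1, "df": res.df,
            "stat": res.stat, "p": res.p,
        }
        for lab, w in sorted(res.omega.items()):
            rec[f"omega_{lab}"] = w
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_branch_classes(classes: dict[int, str], path) -> None:
    """Two-column TSV: child-node index (TreeIndex order) -> class label."""
    with open(path, "w") as fh:
        fh.write("node\tclass\n")
        for node, lab in sorted(classes.items()):
            fh.write(f"{node}\t{lab}\n")


def read_branch_classes(path) -> dict[int, str]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {int(r.node): str(r["class"]) for _, r in df.iterrows()}


@dataclass
class PairwiseOmega:
    t: float
    kappa: float
    omega: float
    dN: float
    dS: float
    llf: float
    estimable: bool


def pairwise_omega(seq1: str, seq2: str, freq_model: str = "F3x4") -> PairwiseOmega:
    """Single-branch ML (t, kappa, omega) for two aligned in-frame sequences.

    dN and dS are derived from the fitted generator by the standard
    site-counting decomposition: the fitted substitution flow is split into
    nonsynonymous and synonymous shares, and per-site rates use the numbers
    of nonsynonymous/synonymous sites implied by the same kappa and codon
    frequencies at omega = 1.  Identical sequences give t ~ 0 with omega
    reported as not estimable (NaN) rather than raising.
    """
    aln = CodonAlignment({"a": seq1, "b": seq2})
    freqs = codon_frequencies(freq_model, [seq1, seq2])
    mat, _ = aln.encode(["a", "b"])
    if mat.shape[1] == 0:
        raise ValueError("no comparable ungapped codons")
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    a_obs, b_obs = pats[0], pats[1]
    identical = bool(np.all(a_obs == b_obs))
    sqrt_pi = np.sqrt(freqs)

    def loglik(t, kappa, omega):
        Q = codon_Q(kappa, omega, freqs)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        M = (V * np.exp(lam * t)) @ V.T
        P = (M / sqrt_pi[:, None]) * sqrt_pi[None, :]
        vals = freqs[a_obs] * np.clip(P[a_obs, b_obs], 1e-300, None)
        return float(counts @ np.log(vals))

    def neg(x):
        return -loglik(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]))

    x0 = np.array([math.log(max(np.mean(a_obs != b_obs), 1e-4)), math.log(2.0),
                   math.log(0.3)])
    res = scipy.optimize.minimize(
        neg, x0, method="L-BFGS-B",
        bounds=[(math.log(1e-7), math.log(60.0)),
                (math.log(1e-2), math.log(1e2)),
                (math.log(1e-6), math.log(1e2))],
        options={"ftol": 1e-10, "maxiter": 500, "eps": 1e-6},
    )
    t, kappa, omega = (math.exp(v) for v in res.x)
    if identical:
        return PairwiseOmega(t=0.0, kappa=kappa, omega=float("nan"),
                             dN=0.0, dS=0.0, llf=-res.fun, estimable=False)
    fn, fs = substitution_flows(kappa, omega, freqs)
    rho_n = fn / (fn + fs)
    fn1, fs1 = substitution_flows(kappa, 1.0, freqs)
    p_n1 = fn1 / (fn1 + fs1)  # proportion of nonsynonymous sites
    dN = t * rho_n / (3.0 * p_n1)
    dS = t * (1.0 - rho_n) / (3.0 * (1.0 - p_n1))
    return PairwiseOmega(t=t, kappa=kappa, omega=omega, dN=dN, dS=dS,
                         llf=-res.fun, estimable=True)
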