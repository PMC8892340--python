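"""Gene-by-gene coevolution screen: LRTs, q-value FDR, QQ diagnostics.

For every candidate gene that varies across species, the screen fits the
independent null and the dependent alternative, forms the 4-df
likelihood-ratio test, and controls the false-discovery rate over the
retained genes with Storey q-values.  Genes with no variation among their
certain calls carry no signal for the test and are skipped with a recorded
reason, mirroring the practice of testing only genes lost at least once.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from coevotrait.pagel import PagelModel, ScreenConfig, lrt_pvalue
from coevotrait.phylo import Tree
from coevotrait.traits import TraitStates

__all__ = [
    "ScreenConfig",
    "TestResult",
    "ScreenResult",
    "run_screen",
    "qvalues",
    "qq_band",
    "read_matrix",
    "write_matrix",
]


@dataclass
class TestResult:
    """One gene's dependent-vs-independent test."""

    gene: str
    lnL_H0: float
    lnL_Ha: float
    stat: float
    df: int
    p: float
    q: float = float("nan")


@dataclass
class ScreenResult:
    """Full screen output: per-gene tests (sorted by p) plus provenance."""

    results: list[TestResult]
    skipped: dict[str, str]
    config: ScreenConfig

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.results])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "restarts": self.config.restarts,
            "rate_bounds": list(self.config.rate_bounds),
            "n_tested": len(self.results),
            "skipped": self.skipped,
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))

    def significant(self, alpha: float = 0.05) -> list[TestResult]:
        return [r for r in self.results if r.p < alpha]

    def plot_qq(self, level: float = 0.95, ax=None):
        """QQ plot of screen p-values with a pointwise confidence band."""
        import matplotlib.pyplot as plt

        pvals = np.sort([r.p for r in self.results])
        n = len(pvals)
        expected = (np.arange(1, n + 1) - 0.5) / n
        lower, upper = qq_band(n, level)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(
            -np.log10(expected), -np.log10(upper), -np.log10(lower),
            color="0.85", label=f"{level:.0%} pointwise band",
        )
        ax.plot(-np.log10(expected), -np.log10(pvals), "o", ms=4)
        ax.plot(-np.log10(expected), -np.log10(expected), "k--", lw=1)
        ax.set_xlabel(r"expected $-\log_{10} p$")
        ax.set_ylabel(r"observed $-\log_{10} p$")
        return ax


def qvalues(pvals) -> np.ndarray:
    """Storey q-values with a smoother-based estimate of pi0.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is evaluated on the grid
    lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic polynomial and read
    off at lambda = 0.95, then clipped to (0, 1].  A degenerate estimate
    (<= 0 or non-finite, or too few p-values to smooth) falls back to pi0 = 1,
    which reduces the procedure to Benjamini-Hochberg.  Output is aligned to
    the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    pi0 = _estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * n * p[order] / np.arange(1, n + 1)
    # step-up: enforce monotone nonincreasing from the largest rank down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _estimate_pi0(p: np.ndarray) -> float:
    lam = np.arange(0.05, 0.96, 0.05)
    n = len(p)
    if n < 8:
        return 1.0
    pi0_lam = np.array([(p > l).sum() / (n * (1.0 - l)) for l in lam])
    try:
        poly = np.polynomial.Polynomial.fit(lam, pi0_lam, deg=3)
        pi0 = float(poly(lam[-1]))
    except Exception:
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def qq_band(n: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (lower, upper) bounds for ordered uniform p-values.

    The i-th smallest of n uniform p-values follows Beta(i, n - i + 1); the
    band spans that distribution's (1-level)/2 and 1-(1-level)/2 quantiles,
    as drawn on QQ plots of screen p-values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    i = np.arange(1, n + 1)
    alpha = 1.0 - level
    lower = scipy.stats.beta.ppf(alpha / 2.0, i, n - i + 1)
    upper = scipy.stats.beta.ppf(1.0 - alpha / 2.0, i, n - i + 1)
    return lower, upper


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a presence/absence matrix: first column species, gene columns of
    {0,1,?}."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(np.unique(df.values)) - {"0", "1", "?"}
    if bad:
        raise ValueError(f"matrix cells must be 0, 1 or '?'; found {sorted(bad)}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="species")


def run_screen(
    tree: Tree,
    focal_states: TraitStates,
    matrix: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Test every variable gene in the matrix for coevolution with the focal
    trait.

    Parameters
    ----------
    tree : Tree
        May contain extra tips; it is pruned to the matrix's species.
    focal_states : TraitStates
        Focal-gene (PRDM9) status per species.
    matrix : DataFrame
        Species (index) x genes, cells in {'0','1','?'}.
    config : ScreenConfig

    Returns
    -------
    ScreenResult
        Per-gene results sorted by increasing p, with q-values computed over
        the retained genes, plus the skip log and run provenance.
    """
    config = config or ScreenConfig()
    species = set(matrix.index.astype(str))
    extra = species - set(tree.tip_labels)
    if extra:
        raise ValueError(f"matrix species not in tree: {sorted(extra)}")
    work_tree = tree.prune_to(species) if species != set(tree.tip_labels) else tree
    focal = focal_states.restrict(species)

    results: list[TestResult] = []
    skipped: dict[str, str] = {}
    for j, gene in enumerate(matrix.columns):
        states = TraitStates(dict(zip(matrix.index.astype(str), matrix[gene])))
        if not states.is_variable():
            skipped[str(gene)] = "no variation among certain calls"
            continue
        cfg = ScreenConfig(
            restarts=config.restarts,
            tol=config.tol,
            rate_bounds=config.rate_bounds,
            seed=config.seed + j,
            root_focal=config.root_focal,
            root_gene=config.root_gene,
            maxiter=config.maxiter,
        )
        model = PagelModel(work_tree, focal, states, cfg)
        indep = model.fit("independent")
        dep = model.fit("dependent")
        stat, p = lrt_pvalue(indep.llf, dep.llf, 4)
        results.append(
            TestResult(
                gene=str(gene), lnL_H0=indep.llf, lnL_Ha=dep.llf,
                stat=stat, df=4, p=p,
            )
        )
    if not results:
        raise ValueError("no gene in the matrix varies; nothing to test")
    q = qvalues([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    results.sort(key=lambda r: (r.p, r.gene))
    return ScreenResult(results=results, skipped=skipped, config=config)
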