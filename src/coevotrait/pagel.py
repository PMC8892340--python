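"""Maximum-likelihood fitting of the dependent/independent two-trait models.

The screen compares a null model in which the focal gene (PRDM9) and a
candidate gene gain and are lost independently along the phylogeny (two
uncoupled 2-state chains, 4 free rates) against Pagel's dependent model in
which each trait's transition rates are conditional on the other's state
(8 free rates on the joint 4-state chain).  The two restricted models sit in
between: under ``dependent_X`` the candidate's rates depend on the focal
state while the focal trait evolves independently (6 free rates); under
``dependent_Y`` the roles are swapped.  All four are nested, so
likelihood-ratio tests with 4 (full) or 2 (restricted) degrees of freedom
apply.

Fitting follows a multi-restart strategy: rates are optimized in log space
with a bounded quasi-Newton method; the first start of any dependent-family
fit is the independent-model MLE (which the dependent model nests exactly,
guaranteeing the fitted log-likelihood respects the nesting), and the
remaining starts are drawn log-uniformly within the rate bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from coevotrait.ctmc import RateSpec2, RateSpec4
from coevotrait.likelihood import (
    prune_loglik_indexed,
    tip_partials_joint,
    tip_partials_single,
)
from coevotrait.phylo import Tree, TreeIndex
from coevotrait.traits import TraitStates

__all__ = [
    "MODEL_TAGS",
    "ScreenConfig",
    "PagelModel",
    "PagelResults",
    "fit_model",
    "lrt_pvalue",
    "restricted_model_constraints",
]

MODEL_TAGS = ("independent", "dependent", "dependent_X", "dependent_Y")

_RATE_NAMES = (
    "g01_f0", "g10_f0", "g01_f1", "g10_f1",
    "f01_g0", "f10_g0", "f01_g1", "f10_g1",
)

# free-parameter layout per dependent-family model: maps each of the eight
# joint rates to a position in the free vector
_FREE_MAP = {
    "dependent": {name: i for i, name in enumerate(_RATE_NAMES)},
    # X: candidate depends on focal; focal rates equal across gene states
    "dependent_X": {
        "g01_f0": 0, "g10_f0": 1, "g01_f1": 2, "g10_f1": 3,
        "f01_g0": 4, "f01_g1": 4, "f10_g0": 5, "f10_g1": 5,
    },
    # Y: focal depends on candidate; candidate rates equal across focal states
    "dependent_Y": {
        "g01_f0": 0, "g01_f1": 0, "g10_f0": 1, "g10_f1": 1,
        "f01_g0": 2, "f10_g0": 3, "f01_g1": 4, "f10_g1": 5,
    },
}

N_FREE = {"independent": 4, "dependent": 8, "dependent_X": 6, "dependent_Y": 6}


@dataclass(frozen=True)
class ScreenConfig:
    """Settings shared by single-gene fits and the full screen.

    restarts is the total number of optimizer starts per model fit; rate
    bounds are in events/My and apply on the log scale.  The root-prior
    policy follows the screen's biological prior: the focal trait is present
    at the root with probability ``root_focal[1]`` (default: fixed present)
    and each candidate gene is present with probability ``root_gene[1]``
    (default 50/50).
    """

    restarts: int = 100
    tol: float = 1e-8
    rate_bounds: tuple[float, float] = (1e-6, 1e3)
    seed: int = 0
    root_focal: tuple[float, float] = (0.0, 1.0)
    root_gene: tuple[float, float] = (0.5, 0.5)
    maxiter: int = 500

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise ValueError("rate bounds must be positive and ordered")

    @property
    def joint_root(self) -> np.ndarray:
        return np.kron(np.asarray(self.root_focal), np.asarray(self.root_gene))


def restricted_model_constraints(model_tag: str) -> list[tuple[str, str]]:
    """Equality constraints a restricted model imposes on the joint rates.

    Returns the pairs of :class:`RateSpec4` field names forced equal.  Model
    X leaves the candidate's rates conditional on the focal state but forces
    the focal trait's gain and loss rates to be equal across candidate
    states; model Y does the reverse.  Each restriction removes two free
    parameters, giving the 2-df tests against the independent null.
    """
    if model_tag == "dependent_X":
        return [("f01_g0", "f01_g1"), ("f10_g0", "f10_g1")]
    if model_tag == "dependent_Y":
        return [("g01_f0", "g01_f1"), ("g10_f0", "g10_f1")]
    raise ValueError(f"unknown restricted model tag: {model_tag!r}")


@dataclass
class PagelResults:
    """Fit of one model tag, statsmodels-results flavoured.

    Attributes
    ----------
    model_tag : which of the four nested models was fitted
    params : fitted rates by name (events/My); independent fits report the
        four marginal rates, dependent-family fits all eight joint rates
    llf : maximized log-likelihood
    df_model : number of free rate parameters (4, 6 or 8)
    n_restarts, seed : optimizer provenance
    converged : at least one start converged
    at_bound : some fitted rate sits on a bound (e.g. invariant traits)
    """

    model_tag: str
    params: dict[str, float]
    llf: float
    df_model: int
    n_restarts: int
    seed: int
    converged: bool
    at_bound: bool = False
    restart_llfs: list[float] = field(default_factory=list)

    @property
    def rates(self) -> RateSpec2 | RateSpec4:
        if self.model_tag == "independent":
            return RateSpec4.independent(
                RateSpec2(self.params["f01"], self.params["f10"]),
                RateSpec2(self.params["g01"], self.params["g10"]),
            )
        return RateSpec4(**{k: self.params[k] for k in _RATE_NAMES})

    def lrt_against(self, null: "PagelResults") -> tuple[float, int, float]:
        """(statistic, df, p) of this fit against a nested null fit."""
        df = self.df_model - null.df_model
        stat, p = lrt_pvalue(null.llf, self.llf, df)
        return stat, df, p

    def summary(self) -> str:
        lines = [
            f"Pagel {self.model_tag} model fit",
            "=" * 34,
            f"log-likelihood {self.llf:.5f}   free rates {self.df_model}",
            f"restarts {self.n_restarts}  seed {self.seed}  "
            f"converged {self.converged}  at_bound {self.at_bound}",
            "-" * 34,
        ]
        for name, val in self.params.items():
            lines.append(f"{name:>8s}  {val:12.6g} /My")
        return "\n".join(lines)


class PagelModel:
    """Two binary traits on a bifurcating time tree, ready to fit.

    Parameters
    ----------
    tree : Tree
        Strictly bifurcating; branch lengths in My.
    focal, gene : TraitStates
        States over the tree's tips; '?' marks uncertain species, which enter
        as ambiguous observations.
    config : ScreenConfig, optional

    Examples
    --------
    >>> model = PagelModel(tree, prdm9, zcwpw1, ScreenConfig(restarts=10, seed=1))
    >>> dep = model.fit("dependent")
    >>> indep = model.fit("independent")
    >>> stat, df, p = dep.lrt_against(indep)
    """

    def __init__(
        self,
        tree: Tree,
        focal: TraitStates,
        gene: TraitStates,
        config: ScreenConfig | None = None,
    ):
        self.config = config or ScreenConfig()
        self.index = TreeIndex(tree)
        self.tree = tree
        self.focal = focal
        self.gene = gene
        self._partials_focal, self._nu_focal = tip_partials_single(self.index, focal)
        self._partials_gene, self._nu_gene = tip_partials_single(self.index, gene)
        self._partials_joint, self._nu_joint = tip_partials_joint(
            self.index, focal, gene
        )
        self._indep_cache: dict[int, PagelResults] = {}

    # -- objective helpers ------------------------------------------------

    def _marginal_negloglik(self, partials, n_unc, root):
        def neg(theta):
            q01, q10 = np.exp(theta)
            ll = prune_loglik_indexed(
                self.index, partials, RateSpec2(q01, q10), root, n_unc
            )
            return -ll if np.isfinite(ll) else 1e12

        return neg

    def _joint_negloglik(self, free_map):
        root = self.config.joint_root
        idx = np.array([free_map[name] for name in _RATE_NAMES])

        def neg(theta):
            rates8 = np.exp(theta)[idx]
            ll = prune_loglik_indexed(
                self.index,
                self._partials_joint,
                RateSpec4(*rates8),
                root,
                self._nu_joint,
            )
            return -ll if np.isfinite(ll) else 1e12

        return neg

    def _optimize(self, neg, starts, log_bounds):
        best = None
        llfs = []
        any_ok = False
        for x0 in starts:
            res = scipy.optimize.minimize(
                neg,
                x0,
                method="L-BFGS-B",
                bounds=[log_bounds] * len(x0),
                options={"ftol": self.config.tol, "maxiter": self.config.maxiter},
            )
            llfs.append(-res.fun)
            any_ok = any_ok or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        return best, llfs, any_ok

    def _random_starts(self, rng, n, dim, log_bounds):
        lo, hi = log_bounds
        return [rng.uniform(lo, hi, size=dim) for _ in range(n)]

    def _heuristic_rate(self) -> float:
        # one event expected per total tree length: a sane mid-scale start
        total = max(self.tree.total_length(), 1e-9)
        return 2.0 / total

    # -- fitting ----------------------------------------------------------

    def fit(self, model_tag: str = "dependent") -> PagelResults:
        """Fit one of the four nested models by multi-restart ML."""
        if model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {model_tag!r}; expected {MODEL_TAGS}")
        if model_tag == "independent":
            return self._fit_independent()
        return self._fit_dependent(model_tag)

    def _fit_independent(self, restarts: int | None = None) -> PagelResults:
        """Independent fit; each marginal uses its own seeded start stream so
        the set of starts at ``restarts=r`` is a prefix of the set at any
        larger r (reported max lnL is monotone in the number of tries)."""
        cfg = self.config
        restarts = cfg.restarts if restarts is None else restarts
        if restarts in self._indep_cache:
            return self._indep_cache[restarts]
        lb = (math.log(cfg.rate_bounds[0]), math.log(cfg.rate_bounds[1]))
        h = math.log(self._heuristic_rate())
        params: dict[str, float] = {}
        llf = 0.0
        llfs_all: list[float] = []
        converged = True
        at_bound = False
        specs = [
            ("f", self._partials_focal, self._nu_focal, np.asarray(cfg.root_focal)),
            ("g", self._partials_gene, self._nu_gene, np.asarray(cfg.root_gene)),
        ]
        for stream, (prefix, partials, n_unc, root) in enumerate(specs):
            neg = self._marginal_negloglik(partials, n_unc, root)
            rng = np.random.default_rng([cfg.seed, stream])
            starts = [np.full(2, h)] + self._random_starts(rng, restarts - 1, 2, lb)
            best, llfs, ok = self._optimize(neg, starts, lb)
            q01, q10 = np.exp(best.x)
            params[f"{prefix}01"] = q01
            params[f"{prefix}10"] = q10
            llf += -best.fun
            llfs_all.append(max(llfs))
            converged = converged and ok
            at_bound = at_bound or bool(
                np.any(np.abs(best.x - lb[0]) < 1e-6)
                or np.any(np.abs(best.x - lb[1]) < 1e-6)
            )
        result = PagelResults(
            model_tag="independent",
            params=params,
            llf=llf,
            df_model=4,
            n_restarts=restarts,
            seed=cfg.seed,
            converged=converged,
            at_bound=at_bound,
            restart_llfs=llfs_all,
        )
        self._indep_cache[restarts] = result
        return result

    def _fit_dependent(self, model_tag: str) -> PagelResults:
        cfg = self.config
        lb = (math.log(cfg.rate_bounds[0]), math.log(cfg.rate_bounds[1]))
        free_map = _FREE_MAP[model_tag]
        dim = N_FREE[model_tag] if model_tag != "dependent" else 8
        dim = max(free_map.values()) + 1
        neg = self._joint_negloglik(free_map)

        # start 0: the independent MLE embedded in this model's free space --
        # every dependent-family model nests it, so the fitted llf can only
        # be >= the independent llf.  The embedding comes from an
        # independent fit with at least 8 tries so that, below that count,
        # the dependent start list is a pure prefix sequence in `restarts`.
        indep = self._fit_independent(max(8, cfg.restarts))
        joint = {
            "g01_f0": indep.params["g01"], "g01_f1": indep.params["g01"],
            "g10_f0": indep.params["g10"], "g10_f1": indep.params["g10"],
            "f01_g0": indep.params["f01"], "f01_g1": indep.params["f01"],
            "f10_g0": indep.params["f10"], "f10_g1": indep.params["f10"],
        }
        x0 = np.empty(dim)
        for name, pos in free_map.items():
            x0[pos] = math.log(np.clip(joint[name], *cfg.rate_bounds))

        rng = np.random.default_rng([cfg.seed, 2 + MODEL_TAGS.index(model_tag)])
        starts = [x0] + self._random_starts(rng, cfg.restarts - 1, dim, lb)
        best, llfs, ok = self._optimize(neg, starts, lb)
        theta = best.x
        params = {name: float(np.exp(theta[pos])) for name, pos in free_map.items()}
        full = {name: params[name] for name in _RATE_NAMES}
        at_bound = bool(
            np.any(np.abs(theta - lb[0]) < 1e-6) or np.any(np.abs(theta - lb[1]) < 1e-6)
        )
        return PagelResults(
            model_tag=model_tag,
            params=full,
            llf=-best.fun,
            df_model=N_FREE[model_tag],
            n_restarts=cfg.restarts,
            seed=cfg.seed,
            converged=ok,
            at_bound=at_bound,
            restart_llfs=llfs,
        )


def fit_model(
    tree: Tree,
    prdm9_states: TraitStates,
    gene_states: TraitStates,
    model_tag: str,
    config: ScreenConfig | None = None,
) -> PagelResults:
    """Functional wrapper: build a :class:`PagelModel` and fit one tag."""
    return PagelModel(tree, prdm9_states, gene_states, config).fit(model_tag)


def lrt_pvalue(lnL0: float, lnL1: float, df: int, eps: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio statistic and upper-tail chi-square p-value.

    ``Lambda = 2 (lnL1 - lnL0)`` is clamped at 0 within a small numerical
    slack ``eps`` (nested models cannot truly have lnL1 < lnL0).

    Returns
    -------
    (statistic, p)
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if lnL1 < lnL0 - eps:
        raise ValueError(
            f"nesting violated: alternative lnL {lnL1} < null lnL {lnL0} - {eps}"
        )
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    p = float(scipy.stats.chi2.sf(stat, df))
    return stat, p
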