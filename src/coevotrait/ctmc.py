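"""Two-state and paired four-state continuous-time Markov chains.

The two-trait (Pagel) model lives on the joint state space
``((0,0),(0,1),(1,0),(1,1))`` with the focal trait (PRDM9) first and the
candidate gene second.  Only one trait may change at a time, so the four
"diagonal" double transitions have rate exactly 0; the eight remaining rates
are free and state-conditional.  Units are events per million years when the
tree is time calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "RateSpec2",
    "RateSpec4",
    "RootPrior",
    "transition_matrix",
    "JOINT_STATES",
]

# Joint states, focal (PRDM9) first:  index -> (focal, gene)
JOINT_STATES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"rate {name} must be finite and >= 0, got {value}")
    return value


@dataclass(frozen=True)
class RateSpec2:
    """Gain/loss rates for a single binary trait.

    q01 is the 0->1 (gain) rate, q10 the 1->0 (loss) rate, both per My.
    """

    q01: float
    q10: float

    def __post_init__(self):
        _check_rate("q01", self.q01)
        _check_rate("q10", self.q10)

    def generator(self) -> np.ndarray:
        return np.array(
            [[-self.q01, self.q01], [self.q10, -self.q10]], dtype=float
        )


@dataclass(frozen=True)
class RateSpec4:
    """Rates of the dependent two-trait chain on ``JOINT_STATES``.

    Gene rates are conditional on the focal (PRDM9) state and focal rates are
    conditional on the gene state; simultaneous changes of both traits are
    structurally impossible (rate 0).

    Attributes
    ----------
    g01_f0, g10_f0 : gene gain / loss rate while the focal gene is absent
    g01_f1, g10_f1 : gene gain / loss rate while the focal gene is present
    f01_g0, f10_g0 : focal gain / loss rate while the gene is absent
    f01_g1, f10_g1 : focal gain / loss rate while the gene is present
    """

    g01_f0: float
    g10_f0: float
    g01_f1: float
    g10_f1: float
    f01_g0: float
    f10_g0: float
    f01_g1: float
    f10_g1: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            _check_rate(name, getattr(self, name))

    @classmethod
    def independent(cls, focal: RateSpec2, gene: RateSpec2) -> "RateSpec4":
        """Joint chain in which the two traits ignore each other."""
        return cls(
            g01_f0=gene.q01, g10_f0=gene.q10,
            g01_f1=gene.q01, g10_f1=gene.q10,
            f01_g0=focal.q01, f10_g0=focal.q10,
            f01_g1=focal.q01, f10_g1=focal.q10,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.g01_f0, self.g10_f0, self.g01_f1, self.g10_f1,
                self.f01_g0, self.f10_g0, self.f01_g1, self.f10_g1,
            ]
        )

    def generator(self) -> np.ndarray:
        # rows/cols ordered (0,0),(0,1),(1,0),(1,1) with focal first
        Q = np.zeros((4, 4))
        Q[0, 1] = self.g01_f0   # (0,0)->(0,1): gene gain, focal absent
        Q[1, 0] = self.g10_f0   # (0,1)->(0,0): gene loss, focal absent
        Q[2, 3] = self.g01_f1   # (1,0)->(1,1): gene gain, focal present
        Q[3, 2] = self.g10_f1   # (1,1)->(1,0): gene loss, focal present
        Q[0, 2] = self.f01_g0   # (0,0)->(1,0): focal gain, gene absent
        Q[2, 0] = self.f10_g0   # (1,0)->(0,0): focal loss, gene absent
        Q[1, 3] = self.f01_g1   # (0,1)->(1,1): focal gain, gene present
        Q[3, 1] = self.f10_g1   # (1,1)->(0,1): focal loss, gene present
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


@dataclass(frozen=True)
class RootPrior:
    """Probability vector over the model's states at the root."""

    probs: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or len(p) not in (2, 4):
            raise ValueError("root prior must have length 2 or 4")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("root prior entries must be >= 0 and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @classmethod
    def uniform(cls, k: int) -> "RootPrior":
        return cls(tuple([1.0 / k] * k))

    @classmethod
    def focal_present(cls) -> "RootPrior":
        """Joint prior: focal trait fixed present at the root, gene 50/50."""
        return cls((0.0, 0.0, 0.5, 0.5))


def _expm_eig(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(Q t) for a batch of durations via eigendecomposition.

    Falls back to scipy's scaling-and-squaring expm when the generator is
    defective (nearly repeated eigenvalues with an ill-conditioned
    eigenbasis).  Returns an array of shape ``(len(t), k, k)``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = Q.shape[0]
    ok = False
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        cond = np.linalg.norm(U, 2) * np.linalg.norm(Uinv, 2)
        if np.all(np.isfinite(Uinv)) and cond < 1e10:
            E = np.exp(np.outer(t, lam))  # (B, k)
            P = np.einsum("ij,bj,jk->bik", U, E, Uinv)
            P = np.real_if_close(P, tol=1e6).real
            ok = bool(np.all(np.abs(P.sum(axis=2) - 1.0) < 1e-8))
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        # defective or ill-conditioned generator: scaling-and-squaring
        P = np.stack([scipy.linalg.expm(Q * ti) for ti in t])
    # clean round-off (scaling-and-squaring at huge ||Qt|| can drift at the
    # 1e-7 level) and renormalize rows
    P = np.clip(P, 0.0, None)
    rows = P.sum(axis=2, keepdims=True)
    if not np.all(np.isfinite(rows)) or np.any(np.abs(rows - 1.0) > 1e-5):
        raise FloatingPointError("transition matrix rows far from 1")
    return P / rows


def transition_probabilities(
    rates: "RateSpec2 | RateSpec4", t: np.ndarray
) -> np.ndarray:
    """Batched P(t) = exp(Qt); shape ``(len(t), k, k)``.

    The two-state chain uses the closed form
    ``P00(t) = (q10 + q01 e^{-(q01+q10)t}) / (q01+q10)``; the four-state
    chain goes through the eigendecomposition of its generator.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("durations must be >= 0")
    if isinstance(rates, RateSpec2):
        a, b = rates.q01, rates.q10
        s = a + b
        P = np.empty((len(t), 2, 2))
        if s == 0.0:
            P[:] = np.eye(2)
            return P
        e = np.exp(-s * t)
        P[:, 0, 0] = (b + a * e) / s
        P[:, 0, 1] = (a - a * e) / s
        P[:, 1, 0] = (b - b * e) / s
        P[:, 1, 1] = (a + b * e) / s
        return P
    return _expm_eig(rates.generator(), t)


def transition_matrix(rates: "RateSpec2 | RateSpec4", t: float) -> np.ndarray:
    """Single stochastic matrix P(t) for a duration ``t`` >= 0."""
    if t < 0:
        raise ValueError(f"duration must be >= 0, got {t}")
    return transition_probabilities(rates, np.array([float(t)]))[0]
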