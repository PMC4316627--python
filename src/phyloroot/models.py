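"""Amino-acid substitution models with discrete-gamma rate heterogeneity.

A model is a time-reversible rate matrix Q = S·diag(pi) (S symmetric
exchangeabilities, pi equilibrium frequencies), scaled so the expected number
of substitutions per site per unit time at equilibrium is 1. Among-site rate
variation uses Yang's discrete gamma: k equal-probability categories, each
represented by its conditional mean rate, so category rates average to 1.

The default model is Poisson (equal exchangeabilities, equal frequencies),
which has closed-form transition probabilities — convenient both as a
simulation default and as an analytic oracle. An LG-style matrix can be
loaded from a PAML-format data file via :meth:`SubstitutionModel.from_paml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc, gammaincinv

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


class ModelError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """Reversible substitution model over an arbitrary state alphabet."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = 1.0          # gamma shape; None = rates homogeneous
    n_categories: int = 6
    states: str = AMINO_ACIDS

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        n = len(self.states)
        if S.shape != (n, n):
            raise ModelError(f"exchangeability matrix must be {n}x{n}")
        if not np.allclose(S, S.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if np.any(S < 0):
            raise ModelError("exchangeabilities must be non-negative")
        if pi.shape != (n,) or np.any(pi <= 0):
            raise ModelError("frequencies must be positive")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ModelError("frequencies must sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ModelError("need at least one rate category")
        self.exchangeabilities = S
        self.frequencies = pi
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ModelError("degenerate rate matrix")
        self._Q = Q / mu

    # -- constructors -------------------------------------------------------

    @classmethod
    def poisson(cls, alpha: float | None = 1.0, n_categories: int = 6,
                states: str = AMINO_ACIDS) -> "SubstitutionModel":
        n = len(states)
        S = np.ones((n, n)) - np.eye(n)
        pi = np.full(n, 1.0 / n)
        return cls(S, pi, alpha=alpha, n_categories=n_categories, states=states)

    @classmethod
    def from_paml(cls, path: str | Path, alpha: float | None = 1.0,
                  n_categories: int = 6) -> "SubstitutionModel":
        """Load a PAML-format amino-acid matrix file (LG, WAG, ... layout:
        19 lower-triangle exchangeability rows then 20 frequencies)."""
        values = []
        for line in Path(path).read_text().split("\n"):
            values.extend(float(x) for x in line.split())
        need = 19 * 20 // 2 + 20
        if len(values) < need:
            raise ModelError(f"{path}: expected at least {need} numbers")
        S = np.zeros((20, 20))
        k = 0
        for i in range(1, 20):
            for j in range(i):
                S[i, j] = S[j, i] = values[k]
                k += 1
        pi = np.array(values[k:k + 20])
        pi = pi / pi.sum()
        return cls(S, pi, alpha=alpha, n_categories=n_categories)

    # -- derived quantities -------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def rate_matrix(self) -> np.ndarray:
        """Q scaled to one expected substitution per site per unit time."""
        return self._Q

    def category_rates(self) -> np.ndarray:
        """Mean-1 rates of the k equal-probability gamma categories."""
        if self.alpha is None:
            return np.ones(1)
        a, k = self.alpha, self.n_categories
        if k == 1:
            return np.ones(1)
        # boundaries of Gamma(shape=a, rate=a) categories on the Gamma(a,1) scale
        z = np.concatenate([[0.0], gammaincinv(a, np.arange(1, k) / k), [np.inf]])
        upper = np.where(np.isinf(z[1:]), 1.0, gammainc(a + 1, z[1:]))
        lower = gammainc(a + 1, z[:-1])
        rates = k * (upper - lower)
        return rates / rates.mean()   # exact mean 1 against round-off

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q·t·rate); rows sum to 1."""
        if t * rate == 0.0:
            return np.eye(self.n_states)
        return expm(self._Q * (t * rate))


def poisson_p_distance(t: float, n_states: int = 20) -> float:
    """Expected proportion of differing sites at divergence t (Poisson model)."""
    n = n_states
    return (n - 1) / n * (1.0 - np.exp(-n / (n - 1) * t))
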