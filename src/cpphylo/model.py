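"""GTR+Gamma nucleotide substitution model.

The general time-reversible model is parameterized by six exchangeabilities
(AC, AG, AT, CG, CT, GT; GT fixed to 1 as the identifiability convention),
stationary base frequencies, and a discrete-Gamma model of among-site rate
heterogeneity (shape alpha, equal-probability categories, mean-of-bin rates
renormalized to mean exactly 1).  The rate matrix is scaled so one unit of
branch length is one expected substitution per site at rate 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = ("A", "C", "G", "T")
PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Category rates of the discrete-Gamma model (Yang's mean-of-bin scheme).

    The Gamma(alpha, alpha) density (mean 1) is cut at its ``i/k`` quantiles
    into ``k`` equal-probability bins; each category rate is the mean of its
    bin, computed from the incomplete-gamma function and renormalized so the
    category mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    k = int(n_categories)
    if k == 1:
        return np.array([1.0])
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # mean within a bin of Gamma(a, rate a): k * [P(a+1, a*hi) - P(a+1, a*lo)]
    upper = gammainc(alpha + 1, alpha * bounds[1:-1])
    cdf_hi = np.concatenate([upper, [1.0]])
    cdf_lo = np.concatenate([[0.0], upper])
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


@dataclass
class SubstModel:
    """GTR exchangeabilities + base frequencies + discrete-Gamma shape."""

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )  # AC, AG, AT, CG, CT, GT
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or (ex < 0).any() or ex[5] <= 0:
            raise ValueError("need 6 non-negative exchangeabilities with GT > 0")
        if fr.shape != (4,) or (fr < 0).any():
            raise ValueError("need 4 non-negative base frequencies")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"base frequencies must sum to 1, got {fr.sum()!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        self.exchangeabilities = ex / ex[5]  # GT == 1 convention
        self.base_freqs = fr
        self.n_categories = int(self.n_categories)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def rate_matrix(self) -> np.ndarray:
        """The 4x4 GTR generator Q, scaled to one expected substitution
        per unit branch length: -sum_i pi_i Q_ii = 1."""
        r = self.exchangeabilities
        pi = self.base_freqs
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = r[0]  # AC
        S[0, 2] = S[2, 0] = r[1]  # AG
        S[0, 3] = S[3, 0] = r[2]  # AT
        S[1, 2] = S[2, 1] = r[3]  # CG
        S[1, 3] = S[3, 1] = r[4]  # CT
        S[2, 3] = S[3, 2] = r[5]  # GT
        Q = S * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / scale

    def eigensystem(self):
        """Symmetric-similarity eigendecomposition of Q for fast exp(Qt).

        Returns (eigenvalues, U, U_inv) with Q = U diag(w) U_inv.
        """
        pi = self.base_freqs
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        Q = self.rate_matrix()
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        U = V / sqrt_pi[:, None]
        U_inv = V.T * sqrt_pi[None, :]
        return w, U, U_inv


def transition_probabilities(
    model: SubstModel, t: float, category_rate: float = 1.0
) -> np.ndarray:
    """P(t) = exp(Q * t * category_rate), a row-stochastic 4x4 matrix."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    w, U, U_inv = model.eigensystem()
    P = (U * np.exp(w * t * category_rate)) @ U_inv
    return np.clip(P, 0.0, None)


def empirical_base_freqs(alignment) -> np.ndarray:
    """Observed frequencies of unambiguous bases, as a model initialization."""
    masks = alignment.masks()
    counts = np.array([(masks == 1 << i).sum() for i in range(4)], dtype=float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    freqs = counts / total
    freqs = np.maximum(freqs, 1e-6)
    return freqs / freqs.sum()
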