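"""Reversible substitution models with discrete-gamma rate variation.

A model is defined by a symmetric exchangeability matrix S and stationary
frequencies pi; the rate matrix is Q_ij = S_ij * pi_j (i != j) with rows
summing to zero, normalised so the expected substitution rate at
stationarity is one. Among-site rate variation uses the usual k
equal-probability discrete categories of a mean-one gamma distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import _empirical
from .seqio import AMINO_ACIDS, MISSING_CODE, Alignment, Alphabet


def discrete_gamma(alpha: float, k: int) -> np.ndarray:
    """Category rates of the k-category discrete-gamma approximation.

    Each category has probability 1/k; its rate is the mean of the mean-one
    gamma(alpha, alpha) distribution over that probability slice, computed
    from the incomplete-gamma identity so the rates average exactly one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    # category boundaries: quantiles of gamma(alpha, scale=1/alpha)
    probs = np.arange(1, k) / k
    cuts = gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
    # mean within [a, b] of mean-1 gamma = k * (I(alpha+1, b*alpha) - I(alpha+1, a*alpha))
    reg = gammainc(alpha + 1.0, np.concatenate([[0.0], cuts * alpha, [np.inf]]))
    rates = k * np.diff(reg)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """Normalised reversible model plus its eigendecomposition.

    Attributes
    ----------
    alphabet:
        State alphabet (20 amino acids, or 4 groups after recoding).
    exchangeabilities:
        Symmetric positive matrix S with an arbitrary overall scale.
    frequencies:
        Stationary distribution pi.
    alpha:
        Discrete-gamma shape; ``None`` disables rate variation.
    n_categories:
        Number of equal-probability gamma categories.
    """

    alphabet: Alphabet
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        n = self.alphabet.n_states
        S = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.frequencies, float)
        if S.shape != (n, n):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if pi.shape != (n,) or (pi <= 0).any():
            raise ValueError("frequencies must be positive, one per state")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise: expected rate at stationarity = -sum_i pi_i Q_ii = 1
        mu = -np.dot(pi, np.diag(Q))
        Q = Q / mu
        # eigendecomposition of the pi-symmetrised form for exact, reusable
        # transition probabilities: B = D^{1/2} Q D^{-1/2} is symmetric
        sqrt_pi = np.sqrt(pi)
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        eigvals, U = np.linalg.eigh((B + B.T) / 2.0)
        right = U / sqrt_pi[:, None]          # columns: right eigenvectors of Q
        left = U * sqrt_pi[:, None]           # rows of left^T
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "rate_matrix", Q)
        object.__setattr__(self, "_eigvals", eigvals)
        object.__setattr__(self, "_right", right)
        object.__setattr__(self, "_left_t", left.T)

    @property
    def n_states(self) -> int:
        return self.alphabet.n_states

    @property
    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma(self.alpha, self.n_categories)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t) via the cached eigendecomposition."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        expd = np.exp(self._eigvals * rate * t)
        P = (self._right * expd[None, :]) @ self._left_t
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(rate_c * t) over the gamma categories, shape (k, n, n)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        rt = self.category_rates * t
        expd = np.exp(self._eigvals[None, :] * rt[:, None])  # (k, n)
        P = np.matmul(self._right[None, :, :] * expd[:, None, :], self._left_t)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def with_alpha(self, alpha: float | None, k: int | None = None) -> "SubstitutionModel":
        return replace(
            self, alpha=alpha, n_categories=k if k is not None else self.n_categories
        )


def empirical_frequencies(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """State frequencies pooled over all non-missing cells of an alignment.

    A small pseudocount keeps unobserved states at positive frequency, which
    reversible-model likelihoods require.
    """
    n = aln.alphabet.n_states
    counts = np.bincount(
        aln.codes[aln.codes != MISSING_CODE].astype(int), minlength=n
    ).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def build_model(
    name: str = "lg",
    frequencies: str = "model",
    alpha: float | None = None,
    k: int = 4,
    alignment: Alignment | None = None,
    alphabet: Alphabet | None = None,
) -> SubstitutionModel:
    """Construct a named amino-acid model.

    Parameters
    ----------
    name:
        ``"poisson"`` (all exchangeabilities equal), ``"lg"`` or ``"wag"``.
    frequencies:
        ``"model"`` (the published frequencies; uniform for Poisson),
        ``"empirical"`` (pooled from ``alignment``, the +F convention), or
        ``"uniform"``.
    alpha:
        Discrete-gamma shape, or ``None`` for rate homogeneity.
    k:
        Number of gamma categories.
    alphabet:
        Override for the Poisson model on recoded (non-20-state) data.
    """
    name = name.lower()
    if name == "poisson":
        ab = alphabet or AMINO_ACIDS
        n = ab.n_states
        S = np.ones((n, n)) - np.eye(n)
        model_freq = np.full(n, 1.0 / n)
    elif name == "lg":
        ab = AMINO_ACIDS
        S = _empirical.lg_exchangeabilities()
        model_freq = _empirical.lg_frequencies()
    elif name == "wag":
        ab = AMINO_ACIDS
        S = _empirical.wag_exchangeabilities()
        model_freq = _empirical.wag_frequencies()
    else:
        raise ValueError(f"unknown model {name!r} (expected poisson/lg/wag)")

    if frequencies == "model":
        pi = model_freq
    elif frequencies == "uniform":
        pi = np.full(ab.n_states, 1.0 / ab.n_states)
    elif frequencies == "empirical":
        if alignment is None:
            raise ValueError("empirical frequencies require an alignment")
        if alignment.alphabet.letters != ab.letters:
            raise ValueError("alignment alphabet does not match model alphabet")
        pi = empirical_frequencies(alignment)
    else:
        raise ValueError(f"unknown frequency mode {frequencies!r}")

    return SubstitutionModel(ab, S, pi, alpha=alpha, n_categories=k)
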