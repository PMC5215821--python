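"""Amino-acid substitution models with discrete-gamma rate heterogeneity.

A :class:`SubstitutionModel` bundles a symmetric exchangeability matrix
``s``, equilibrium frequencies ``pi``, and an optional gamma shape for
among-site rate variation.  The instantaneous rate matrix is the usual
general-time-reversible construction

    Q_ij = s_ij * pi_j   (i != j),

with the diagonal set so rows sum to zero and the whole matrix rescaled
so the expected number of substitutions per site per unit time,
``-sum_i pi_i Q_ii``, equals one.  Transition probabilities are computed
through a symmetric eigendecomposition of ``diag(pi)^1/2 Q diag(pi)^-1/2``,
which is exact for reversible models and guarantees a real spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._aa_data import (
    AA_ORDER,
    LG_EXCHANGEABILITIES,
    LG_FREQUENCIES,
    RTREV_EXCHANGEABILITIES,
    RTREV_FREQUENCIES,
)

__all__ = [
    "AA_ORDER",
    "SubstitutionModel",
    "build_rate_matrix",
    "discrete_gamma_rates",
    "transition_probabilities",
    "get_model",
    "load_paml_dat",
]

_FREQ_TOL = 1e-12
_gamma_rate_cache: dict[tuple[float, int], np.ndarray] = {}


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible amino-acid (or generic finite-alphabet) substitution model.

    Parameters
    ----------
    name:
        Human-readable label, e.g. ``"rtREV"``.
    exchangeabilities:
        Symmetric non-negative matrix with zero diagonal.
    frequencies:
        Equilibrium state frequencies ``pi`` (sum to 1).
    gamma_shape:
        Shape ``alpha`` of the discrete-gamma rates-across-sites
        distribution, or ``None`` for a single rate class.
    n_categories:
        Number of equal-probability gamma categories (ignored when
        ``gamma_shape`` is ``None``).
    plus_f:
        Whether frequencies are meant to be replaced by observed data
        frequencies (``+F``) when the model is fit.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 4
    plus_f: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("exchangeability matrix must be square")
        if s.shape[0] != pi.shape[0]:
            raise ValueError("exchangeabilities and frequencies disagree on alphabet size")
        if np.any(s < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if not np.allclose(s, s.T, rtol=0, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(pi < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"frequencies must sum to 1 (got {pi.sum()!r})")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def n_states(self) -> int:
        return self.frequencies.shape[0]

    def with_frequencies(self, pi: np.ndarray) -> "SubstitutionModel":
        """Return a copy with replaced equilibrium frequencies (``+F``)."""
        pi = np.asarray(pi, dtype=float)
        return replace(self, frequencies=pi / pi.sum())

    def with_gamma(self, alpha: float | None, n_categories: int | None = None) -> "SubstitutionModel":
        return replace(
            self,
            gamma_shape=alpha,
            n_categories=self.n_categories if n_categories is None else n_categories,
        )

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (a single 1.0 when no gamma)."""
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    def eigensystem(self) -> "ReversibleEigensystem":
        return ReversibleEigensystem.from_model(self)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Build the normalized GTR-form rate matrix Q for *model*.

    ``Q_ij = s_ij pi_j`` off the diagonal; rows sum to zero; globally
    rescaled to unit expected rate ``-sum_i pi_i Q_ii = 1``.
    """
    s = model.exchangeabilities
    pi = model.frequencies
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(q)))
    if mean_rate <= 0:
        raise ValueError("degenerate model: zero expected substitution rate")
    return q / mean_rate


@dataclass(frozen=True)
class ReversibleEigensystem:
    """Cached spectral decomposition of a reversible Q for fast exp(Qt).

    Uses the similarity transform ``B = diag(pi)^1/2 Q diag(pi)^-1/2``;
    B is symmetric for reversible Q, so ``Q = D^-1/2 U diag(w) U' D^1/2``
    with real eigenvalues ``w`` and orthonormal ``U``.
    """

    eigenvalues: np.ndarray
    left: np.ndarray   # D^-1/2 U,  shape (n, n)
    right: np.ndarray  # U' D^1/2,  shape (n, n)
    frequencies: np.ndarray

    @classmethod
    def from_model(cls, model: SubstitutionModel) -> "ReversibleEigensystem":
        q = build_rate_matrix(model)
        pi = model.frequencies
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)  # symmetrize against roundoff
        w, u = np.linalg.eigh(b)
        return cls(
            eigenvalues=w,
            left=u / sqrt_pi[:, None],
            right=u.T * sqrt_pi[None, :],
            frequencies=np.asarray(pi, float),
        )

    def expm(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), clipped to [0, 1] against tiny negative roundoff."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self.left * np.exp(self.eigenvalues * t)) @ self.right
        if p.min() < -1e-9:
            raise FloatingPointError(f"matrix exponential produced probability {p.min():.3g}")
        np.clip(p, 0.0, 1.0, out=p)
        return p


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-of-category discrete-gamma rates (Yang 1994).

    Results are memoized; the returned array must not be mutated.

    The gamma(alpha, alpha) distribution (mean 1) is cut into
    ``n_categories`` equal-probability slices; each category's rate is
    the conditional mean of its slice, renormalized so the category
    rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n = int(n_categories)
    if n < 1:
        raise ValueError("n_categories must be >= 1")
    if n == 1:
        return np.ones(1)
    cached = _gamma_rate_cache.get((float(alpha), n))
    if cached is not None:
        return cached
    dist = _gamma_dist(a=alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.linspace(0.0, 1.0, n + 1))
    # Mean of each slice via the incomplete-gamma identity:
    # E[X; X in (a,b)] = F_{alpha+1}(b) - F_{alpha+1}(a)  (for mean-1 gamma)
    dist_up = _gamma_dist(a=alpha + 1.0, scale=1.0 / alpha)
    cdf_up = dist_up.cdf(edges)
    cdf_up[0], cdf_up[-1] = 0.0, 1.0
    rates = np.diff(cdf_up) * n
    rates = rates / rates.mean()
    rates.setflags(write=False)
    if len(_gamma_rate_cache) > 4096:
        _gamma_rate_cache.clear()
    _gamma_rate_cache[(float(alpha), n)] = rates
    return rates


def transition_probabilities(q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * rate * t) for a reversible rate matrix Q.

    Accepts either a raw rate matrix or a cached eigensystem; rows of
    the result sum to 1 and entries are non-negative.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if isinstance(q, ReversibleEigensystem):
        return q.expm(t * rate)
    q = np.asarray(q, dtype=float)
    pi = _stationary_from_q(q)
    sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
    b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)
    w, u = np.linalg.eigh(b)
    p = ((u / sqrt_pi[:, None]) * np.exp(w * t * rate)) @ (u.T * sqrt_pi[None, :])
    if p.min() < -1e-9:
        raise FloatingPointError("matrix exponential produced a negative probability")
    np.clip(p, 0.0, 1.0, out=p)
    return p


def _stationary_from_q(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a reversible Q (left null vector)."""
    w, v = np.linalg.eig(q.T)
    idx = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


_NAMED = {
    "rtrev": (RTREV_EXCHANGEABILITIES, RTREV_FREQUENCIES),
    "lg": (LG_EXCHANGEABILITIES, LG_FREQUENCIES),
}


def get_model(
    name: str,
    gamma_shape: float | None = None,
    n_categories: int = 4,
    plus_f: bool = False,
) -> SubstitutionModel:
    """Look up a named amino-acid model (``rtREV`` or ``LG``)."""
    key = name.lower()
    for cand in ("rtrev", "lg"):
        if key.startswith(cand):
            s, pi = _NAMED[cand]
            return SubstitutionModel(
                name=name,
                exchangeabilities=np.asarray(s, float),
                frequencies=np.asarray(pi, float),
                gamma_shape=gamma_shape,
                n_categories=n_categories,
                plus_f=plus_f,
            )
    raise KeyError(f"unknown model {name!r}; available: rtREV, LG, or a PAML .dat file")


def load_paml_dat(
    path,
    name: str | None = None,
    gamma_shape: float | None = None,
    n_categories: int = 4,
    plus_f: bool = False,
) -> SubstitutionModel:
    """Load a PAML-style ``.dat`` amino-acid rate file.

    The format is 19 lines of lower-triangle exchangeabilities (row
    ``i`` holds entries against states ``0..i-1``) followed by 20
    equilibrium frequencies; whitespace is free-form.
    """
    with open(path) as fh:
        values = [float(tok) for line in fh
                  for tok in line.replace(",", " ").split()
                  if not line.lstrip().startswith("#")]
    if len(values) < 210:
        raise ValueError(f"PAML .dat file needs 190 exchangeabilities + 20 frequencies, got {len(values)} numbers")
    tri, freqs = values[:190], values[190:210]
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = tri[k]
            k += 1
    return SubstitutionModel(
        name=name or str(path),
        exchangeabilities=s,
        frequencies=np.asarray(freqs, float) / np.sum(freqs),
        gamma_shape=gamma_shape,
        n_categories=n_categories,
        plus_f=plus_f,
    )
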