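"""Closed-form building blocks of the proportional-abundance diffusion model.

A focal species' share ``x`` of a community evolves under linear birth and
death rates ``b(x) = b0 + b1*x``, ``d(x) = d0 + d1*x`` and a degenerate
fluctuation term ``c(x) = gamma*x*(1-x)``.  Whenever the shape parameters

    alpha = (b0 - d0) / gamma
    beta  = (d1 - b1) / gamma - alpha

are both positive, the stationary law of the diffusion is Beta(alpha, beta).
The neutral parameterisation (migration probability ``m``, species-choice
probability ``p``, fluctuation intensity ``lam``) maps onto these
coefficients as ``b0 = m*p``, ``b1 = -m*p``, ``d0 = 0``, ``d1 = m*(1-p)``,
``gamma = lam*(1-m)``, giving ``alpha = m*p/(lam*(1-m))`` and
``beta = m*(1-p)/(lam*(1-m))``.

Everything in this module is a pure function or an immutable value type;
all densities are evaluated in log space (the data sets of interest have
``beta`` of order 100-500, which overflows a naive Gamma-function product).
"""

from __future__ import annotations

import math
from dataclasses import InitVar, dataclass

import numpy as np
from scipy.special import betaln, xlog1py, xlogy

__all__ = [
    "ModelDomainError",
    "RateSpec",
    "NeutralParams",
    "BetaParams",
    "neutral_to_ratespec",
    "stationary_beta",
    "constrained_alpha",
    "implied_beta",
    "beta_logpdf",
    "beta_pdf",
]


class ModelDomainError(ValueError):
    """A parameter or argument lies outside the model's domain."""


@dataclass(frozen=True)
class RateSpec:
    """Linear rate coefficients of the diffusion.

    Parameters
    ----------
    b0, b1 : float
        Intercept and slope of the birth rate ``b(x) = b0 + b1*x``
        (per unit rescaled time).
    d0, d1 : float
        Intercept and slope of the death rate ``d(x) = d0 + d1*x``.
    gamma : float
        Fluctuation intensity multiplying ``x*(1-x)`` in ``c(x)``;
        must be strictly positive.
    validate : bool, keyword-only init flag
        When True (default) the coefficients are checked eagerly: the
        rates must be non-negative on [0, 1] and must admit a proper
        stationary Beta.  Use :meth:`unchecked` for exploratory specs.
    """

    b0: float
    b1: float
    d0: float
    d1: float
    gamma: float
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        for name in ("b0", "b1", "d0", "d1", "gamma"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if validate:
            self._check()

    def _check(self) -> None:
        if not self.gamma > 0:
            raise ModelDomainError(f"gamma must be > 0, got {self.gamma}")
        # linear rates: non-negativity at both endpoints is sufficient
        if self.b0 < 0 or self.b0 + self.b1 < 0:
            raise ModelDomainError(
                f"birth rate must be >= 0 on [0, 1]: b(0)={self.b0}, b(1)={self.b0 + self.b1}"
            )
        if self.d0 < 0 or self.d0 + self.d1 < 0:
            raise ModelDomainError(
                f"death rate must be >= 0 on [0, 1]: d(0)={self.d0}, d(1)={self.d0 + self.d1}"
            )
        alpha = (self.b0 - self.d0) / self.gamma
        beta = (self.d1 - self.b1) / self.gamma - alpha
        if alpha <= 0 or beta <= 0:
            raise ModelDomainError(
                "no proper stationary Beta for these rates: "
                f"alpha={alpha}, beta={beta} (both must be > 0)"
            )

    @classmethod
    def unchecked(cls, b0: float, b1: float, d0: float, d1: float, gamma: float) -> "RateSpec":
        """Build a RateSpec without any validation (exploratory use)."""
        return cls(b0, b1, d0, d1, gamma, validate=False)

    # -- rate functions -------------------------------------------------
    def birth(self, x):
        return self.b0 + self.b1 * np.asarray(x, dtype=float)

    def death(self, x):
        return self.d0 + self.d1 * np.asarray(x, dtype=float)

    def drift(self, x):
        """Net drift ``b(x) - d(x)``."""
        x = np.asarray(x, dtype=float)
        return (self.b0 - self.d0) + (self.b1 - self.d1) * x

    def fluctuation(self, x):
        """Diffusion-generating term ``c(x) = gamma*x*(1-x)``."""
        x = np.asarray(x, dtype=float)
        return self.gamma * x * (1.0 - x)


@dataclass(frozen=True)
class NeutralParams:
    """Neutral-community parameterisation (m, p, lam[, S]).

    ``m`` is the migration probability, ``p`` the probability of picking an
    individual of the focal species, ``lam`` the intensity of
    environment-induced demographic fluctuations (``lam = 0`` is allowed as
    the degenerate drift-only case, which admits no stationary Beta).
    When the optional species
    richness ``S`` is supplied the symmetric constraint ``p = 1/S`` must
    hold bit-exactly.
    """

    m: float
    p: float
    lam: float
    S: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.m < 1.0:
            raise ModelDomainError(f"m must lie in (0, 1), got {self.m}")
        if not 0.0 < self.p < 1.0:
            raise ModelDomainError(f"p must lie in (0, 1), got {self.p}")
        if not self.lam >= 0:
            raise ModelDomainError(f"lam must be >= 0, got {self.lam}")
        if self.S is not None:
            if int(self.S) != self.S or self.S < 2:
                raise ModelDomainError(f"S must be an integer >= 2, got {self.S}")
            object.__setattr__(self, "S", int(self.S))
            if self.p != 1.0 / self.S:
                raise ModelDomainError(
                    f"constrained parameterisation requires p == 1/S exactly: "
                    f"p={self.p!r}, 1/S={1.0 / self.S!r}"
                )

    @classmethod
    def constrained(cls, m: float, lam: float, S: int) -> "NeutralParams":
        """Symmetric (p = 1/S) parameter set for a community of S species."""
        if S < 2:
            raise ModelDomainError(f"S must be >= 2, got {S}")
        return cls(m=m, p=1.0 / S, lam=lam, S=int(S))


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta(alpha, beta) distribution on (0, 1)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ModelDomainError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ModelDomainError(f"beta must be > 0, got {self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def neutral_to_ratespec(params: NeutralParams) -> RateSpec:
    """Map neutral parameters onto linear rate coefficients.

    Returns the :class:`RateSpec` with ``b0 = m*p``, ``b1 = -m*p``,
    ``d0 = 0``, ``d1 = m*(1-p)`` and ``gamma = lam*(1-m)``.  The birth rate
    therefore vanishes at ``x = 1`` (a full community admits no immigrant
    of a new individual of the focal species) and the death rate at
    ``x = 0``.
    """
    if not isinstance(params, NeutralParams):
        raise TypeError("params must be a NeutralParams")
    mp = params.m * params.p
    return RateSpec(
        b0=mp,
        b1=-mp,
        d0=0.0,
        d1=params.m * (1.0 - params.p),
        gamma=params.lam * (1.0 - params.m),
    )


def stationary_beta(rates: RateSpec) -> BetaParams:
    """Shape parameters of the stationary Beta implied by linear rates.

    ``alpha = (b0 - d0)/gamma`` and ``beta = (d1 - b1)/gamma - alpha``.

    Raises
    ------
    ModelDomainError
        If either shape is non-positive ("no proper stationary Beta for
        these rates").
    """
    alpha = (rates.b0 - rates.d0) / rates.gamma
    beta = (rates.d1 - rates.b1) / rates.gamma - alpha
    if alpha <= 0 or beta <= 0:
        raise ModelDomainError(
            f"no proper stationary Beta for these rates: alpha={alpha}, beta={beta}"
        )
    return BetaParams(alpha=alpha, beta=beta)


def constrained_alpha(m: float, lam: float, S: int) -> float:
    """First shape parameter under the symmetric constraint ``p = 1/S``.

    Equals ``m / (S * (1 - m) * lam)``, which coincides with
    ``stationary_beta(neutral_to_ratespec(NeutralParams.constrained(m, lam, S))).alpha``
    to machine precision.
    """
    if int(S) != S or S < 2:
        raise ModelDomainError(
            f"S must be an integer >= 2 (beta = alpha*(S-1) degenerates otherwise), got {S}"
        )
    if not 0.0 < m < 1.0:
        raise ModelDomainError(f"m must lie in (0, 1), got {m}")
    if not lam > 0:
        raise ModelDomainError(f"lam must be > 0, got {lam}")
    return m / (S * (1.0 - m) * lam)


def implied_beta(alpha: float, S: int) -> float:
    """Second shape parameter ``beta = alpha * (S - 1)`` of the constrained model."""
    if not alpha > 0:
        raise ModelDomainError(f"alpha must be > 0, got {alpha}")
    if int(S) != S or S < 2:
        raise ModelDomainError(f"S must be an integer >= 2, got {S}")
    return alpha * (S - 1)


def beta_logpdf(x, params: BetaParams):
    """Log-density of Beta(alpha, beta) at interior points ``x``.

    Evaluated entirely in log space (log-Gamma via ``betaln``), so large
    shape parameters do not overflow.  ``x`` may be a scalar or an array;
    every value must lie strictly inside (0, 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ModelDomainError(
            "x must lie strictly inside (0, 1); endpoint densities are not defined"
        )
    a, b = params.alpha, params.beta
    out = xlogy(a - 1.0, x) + xlog1py(b - 1.0, -x) - betaln(a, b)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def beta_pdf(x, params: BetaParams):
    """Density of Beta(alpha, beta) at interior points ``x`` (log-space inside)."""
    out = np.exp(beta_logpdf(x, params))
    return float(out) if np.isscalar(out) or np.ndim(out) == 0 else out
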