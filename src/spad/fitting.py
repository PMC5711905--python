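"""Maximum-likelihood estimation of the Beta proportional-abundance law.

The likelihood treats the observed per-species proportions as i.i.d. Beta
draws.  The sum-to-one dependence across species is deliberately ignored
(a per-species marginal fit); under neutrality each marginal of the
symmetric Dirichlet is exactly Beta(alpha, alpha*(S-1)), so this is the
working approximation the whole approach rests on.

The Beta distribution has no closed-form maximum-likelihood estimator, so
both fitters maximise the log-likelihood numerically with Nelder-Mead in
log-parameter space, started from method-of-moments values:

``fit_constrained``
    One free parameter: alpha, with beta tied to alpha*(S-1) and S fixed
    by the sample.
``fit_free``
    Two free parameters (alpha, beta), for arbitrary proportion samples.

Goodness of fit follows the observed-vs-predicted frequency comparison:
species proportions are binned on a logarithmic grid spanning [1/J, 1]
and the Pearson correlation between observed and expected species-per-bin
vectors is reported.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betainc
from scipy.stats import pearsonr

from .model_core import BetaParams, ModelDomainError, beta_logpdf

__all__ = [
    "CommunitySample",
    "FitResult",
    "fit_free",
    "fit_constrained",
    "pearson_gof",
    "recover_from_trajectories",
    "write_fit_json",
]


@dataclass(frozen=True)
class CommunitySample:
    """Species counts of a single community.

    ``counts`` are positive integers, one per species; ``J`` is their sum,
    ``S`` the number of species and ``proportions`` the shares
    ``n_i / J`` (all within [1/J, 1)).
    """

    counts: np.ndarray
    species_ids: tuple | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ModelDomainError("counts must be a 1-D array with S >= 2 records")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ModelDomainError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 1):
            raise ModelDomainError("every count must be >= 1")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.species_ids is not None and len(self.species_ids) != counts.size:
            raise ModelDomainError("species_ids length must match counts")

    @property
    def J(self) -> int:
        return int(self.counts.sum())

    @property
    def S(self) -> int:
        return int(self.counts.size)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.J

    @classmethod
    def from_table(cls, path) -> "CommunitySample":
        """Read an abundance table (TSV or CSV) with columns
        ``species_id`` and ``count``; a header row is required.  Malformed
        rows are reported with their 1-based line number."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str)
        missing = {"species_id", "count"} - set(df.columns)
        if missing:
            raise ModelDomainError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        counts = np.empty(len(df), dtype=np.int64)
        for i, raw in enumerate(df["count"]):
            lineno = i + 2  # header is line 1
            try:
                value = int(str(raw).strip())
            except (TypeError, ValueError):
                raise ModelDomainError(
                    f"{path} line {lineno}: count {raw!r} is not an integer"
                ) from None
            if value < 1:
                raise ModelDomainError(
                    f"{path} line {lineno}: count must be a positive integer, got {value}"
                )
            counts[i] = value
        return cls(counts=counts, species_ids=tuple(df["species_id"]))


@dataclass
class FitResult:
    """Outcome of a Beta likelihood fit."""

    params: BetaParams
    loglik: float
    converged: bool
    n_iter: int
    constrained: bool
    S: int | None = None
    gof_r: float | None = None
    binning: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from . import __version__

        return {
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "constrained": self.constrained,
            "S": self.S,
            "gof_r": self.gof_r,
            "binning": self.binning,
            "extras": self.extras,
            "software_version": __version__,
        }


def _clean_proportions(values, context: str) -> np.ndarray:
    x = np.sort(np.asarray(values, dtype=float))  # sorted: permutation-invariant sums
    if x.size < 3:
        raise ModelDomainError(f"{context}: need at least 3 values")
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ModelDomainError(f"{context}: proportions must lie strictly in (0, 1)")
    if x[0] == x[-1]:
        raise ModelDomainError(f"{context}: degenerate sample (all values equal)")
    return x


def log_likelihood(proportions, params: BetaParams) -> float:
    """Sum of Beta log-densities (values summed in sorted order, so the
    result is invariant under permutation of species)."""
    x = np.sort(np.asarray(proportions, dtype=float))
    return float(np.sum(beta_logpdf(x, params)))


def _moment_start(x: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(x))
    v = float(np.var(x))
    scale = mu * (1.0 - mu) / v - 1.0 if v > 0 else 0.0
    if scale <= 0:
        scale = 1.0 / (mu * (1.0 - mu))  # very diffuse fallback
    return max(mu * scale, 1e-6), max((1.0 - mu) * scale, 1e-6)


_NM_OPTIONS = {"xatol": 1e-10, "fatol": 1e-8, "maxiter": 2000}


def fit_free(proportions, max_iter: int = 2000) -> FitResult:
    """Two-parameter Beta MLE on i.i.d. proportions in (0, 1).

    Nelder-Mead on (log alpha, log beta) from the method-of-moments
    start.  Non-convergence is flagged on the result, not raised.
    """
    x = _clean_proportions(proportions, "fit_free")
    a0, b0 = _moment_start(x)
    n = x.size
    slx = float(np.sum(np.log(x)))
    sl1x = float(np.sum(np.log1p(-x)))

    from scipy.special import betaln

    def nll(theta):
        a, b = np.exp(theta)
        return -((a - 1.0) * slx + (b - 1.0) * sl1x - n * betaln(a, b))

    opts = dict(_NM_OPTIONS, maxiter=max_iter)
    res = minimize(nll, np.log([a0, b0]), method="Nelder-Mead", options=opts)
    a, b = np.exp(res.x)
    return FitResult(
        params=BetaParams(float(a), float(b)),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        constrained=False,
        extras={"start": {"alpha": a0, "beta": b0}},
    )


def fit_constrained(sample: CommunitySample, max_iter: int = 2000) -> FitResult:
    """One-parameter constrained fit: beta = alpha*(S-1), S from the sample.

    Maximises ``sum_i log Beta(x_i; alpha, alpha*(S-1))`` over alpha > 0 by
    Nelder-Mead on log(alpha), started at the variance-matched value.  The
    result also carries the implied migration/fluctuation ratio
    ``m / ((1-m)*lam) = alpha * S``.
    """
    if not isinstance(sample, CommunitySample):
        raise ModelDomainError("fit_constrained expects a CommunitySample")
    x = _clean_proportions(sample.proportions, "fit_constrained")
    S = sample.S
    n = x.size
    slx = float(np.sum(np.log(x)))
    sl1x = float(np.sum(np.log1p(-x)))

    from scipy.special import betaln

    # moment start: sample mean is 1/S by construction, so match the variance
    mu = 1.0 / S
    v = float(np.var(x))
    a0 = (mu * (1.0 - mu) / v - 1.0) / S if v > 0 else 1.0
    if a0 <= 0:
        a0 = 1.0

    def nll(theta):
        a = float(np.exp(theta[0]))
        b = a * (S - 1.0)
        return -((a - 1.0) * slx + (b - 1.0) * sl1x - n * betaln(a, b))

    opts = dict(_NM_OPTIONS, maxiter=max_iter)
    res = minimize(nll, [np.log(a0)], method="Nelder-Mead", options=opts)
    a = float(np.exp(res.x[0]))
    return FitResult(
        params=BetaParams(a, a * (S - 1.0)),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        constrained=True,
        S=S,
        extras={"start": {"alpha": a0}, "m_over_one_minus_m_lam": a * S},
    )


def pearson_gof(sample: CommunitySample, params: BetaParams, n_bins: int = 12) -> float:
    """Pearson correlation between observed and predicted binned frequencies.

    Proportions are binned into ``n_bins`` logarithmically spaced bins
    spanning [1/J, 1]; the observed vector counts species per bin, the
    predicted vector is ``S`` times the Beta mass of each bin.
    """
    if n_bins < 4:
        raise ModelDomainError(f"n_bins must be >= 4, got {n_bins}")
    J, S = sample.J, sample.S
    edges = np.geomspace(1.0 / J, 1.0, n_bins + 1)
    edges[0] = np.nextafter(1.0 / J, 0.0)  # x = 1/J falls in the first bin
    observed, _ = np.histogram(sample.proportions, bins=edges)
    if np.count_nonzero(observed) < 3:
        raise ModelDomainError("fewer than 3 nonempty bins: use fewer bins or more data")
    predicted = S * np.diff(betainc(params.alpha, params.beta, np.clip(edges, 0.0, 1.0)))
    return float(pearsonr(observed, predicted).statistic)


def recover_from_trajectories(ens, t: float, min_mt: float = 5.0) -> FitResult:
    """Fit the stationary Beta from one terminal value per trajectory.

    Takes the ensemble's sample at time ``t`` as approximately i.i.d.
    stationary draws and applies :func:`fit_free`.  Warns when
    ``m * t < min_mt`` (insufficient burn-in biases the fit toward the
    initial condition); requires at least 10 trajectories.  Values clamped
    to the boundaries by the integrator are nudged inside (0, 1) and
    counted in ``extras['n_nudged']``.
    """
    from .simulator import terminal_sample

    if ens.n_traj < 10:
        raise ModelDomainError("need at least 10 trajectories for a stable fit")
    mt = ens.params.m * t
    if mt < min_mt:
        warnings.warn(
            f"m*t = {mt:.3g} is small; the terminal sample is unlikely to be "
            "stationary and the fit will be biased toward the initial state",
            stacklevel=2,
        )
    values = terminal_sample(ens, t)
    eps = 1e-9
    n_nudged = int(np.sum((values <= 0.0) | (values >= 1.0)))
    values = np.clip(values, eps, 1.0 - eps)
    result = fit_free(values)
    result.extras["n_nudged"] = n_nudged
    result.extras["m_times_t"] = mt
    return result


def write_fit_json(result: FitResult, path, seed: int | None = None) -> None:
    payload = result.to_dict()
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
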