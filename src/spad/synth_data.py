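"""Synthetic neutral communities with the exact statistical structure the
fitting machinery assumes.

``sample_community`` draws a symmetric Dirichlet(alpha, ..., alpha) vector
of proportional abundances (each marginal is exactly Beta(alpha,
alpha*(S-1))) and allocates ``J`` individuals multinomially.  Dirichlet
sampling goes through normalised independent Gamma(alpha, 1) draws, so
ports in other languages reproduce the same distributions (not the same
bit streams).

Species that receive zero individuals violate the all-positive structure
of real abundance tables; the ``zero_handling`` policy either resamples
the whole community until every species has at least one individual
(default, capped attempts) or drops the empty species, which reduces S
and is flagged in the output provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model_core import ModelDomainError, NeutralParams, constrained_alpha
from .fitting import CommunitySample

__all__ = ["SynthConfig", "sample_community", "sample_proportions", "ProportionSample",
           "write_abundance_table", "write_provenance"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the community generator.

    ``alpha`` may be given directly or derived from a constrained
    :class:`~spad.model_core.NeutralParams` (``p = 1/S``).
    """

    S: int
    J: int
    alpha: float | None = None
    params: NeutralParams | None = None
    seed: int = 0
    zero_handling: str = "resample"
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if int(self.S) != self.S or self.S < 2:
            raise ModelDomainError(f"S must be an integer >= 2, got {self.S}")
        if int(self.J) != self.J or self.J < self.S:
            raise ModelDomainError(f"J must be an integer >= S, got {self.J}")
        object.__setattr__(self, "S", int(self.S))
        object.__setattr__(self, "J", int(self.J))
        if (self.alpha is None) == (self.params is None):
            raise ModelDomainError("provide exactly one of alpha or params")
        if self.alpha is not None and not self.alpha > 0:
            raise ModelDomainError(f"alpha must be > 0, got {self.alpha}")
        if self.params is not None and self.params.S != self.S:
            raise ModelDomainError("params.S must match config.S")
        if self.zero_handling not in ("resample", "drop"):
            raise ModelDomainError(
                f"zero_handling must be 'resample' or 'drop', got {self.zero_handling!r}"
            )

    @property
    def effective_alpha(self) -> float:
        if self.alpha is not None:
            return float(self.alpha)
        p = self.params
        return constrained_alpha(p.m, p.lam, p.S)


def sample_community(config: SynthConfig) -> tuple[CommunitySample, dict]:
    """Draw one community: Dirichlet proportions, then multinomial counts.

    Returns the sample together with a provenance dict (resolved config,
    attempts used, dropped-species count).
    """
    rng = np.random.default_rng(config.seed)
    alpha = config.effective_alpha
    S, J = config.S, config.J
    dropped = 0
    for attempt in range(1, config.max_attempts + 1):
        gammas = rng.gamma(alpha, 1.0, size=S)
        proportions = gammas / gammas.sum()
        counts = rng.multinomial(J, proportions)
        if np.all(counts >= 1):
            break
        if config.zero_handling == "drop":
            dropped = int(np.sum(counts == 0))
            counts = counts[counts >= 1]
            if counts.size < 2:
                raise ModelDomainError(
                    "fewer than 2 species survived zero-dropping; increase J"
                )
            break
    else:
        raise ModelDomainError(
            f"no all-positive community in {config.max_attempts} attempts "
            f"(J={J} is too small for S={S} at alpha={alpha:.4g}); "
            "increase J or use zero_handling='drop'"
        )
    sample = CommunitySample(counts=counts.astype(np.int64))
    provenance = {
        "S_requested": S,
        "S_realized": sample.S,
        "J": J,
        "alpha": alpha,
        "seed": config.seed,
        "zero_handling": config.zero_handling,
        "attempts": attempt,
        "species_dropped": dropped,
    }
    return sample, provenance


class ProportionSample(NamedTuple):
    """i.i.d. Beta draws plus the number of boundary values nudged inward."""

    values: np.ndarray
    n_nudged: int


def sample_proportions(alpha: float, beta: float, n: int, seed: int) -> ProportionSample:
    """``n`` i.i.d. Beta(alpha, beta) values strictly inside (0, 1).

    Underflow to exactly 0 or 1 (possible for extreme shapes) is nudged to
    the nearest representable interior value and counted.
    """
    if not (alpha > 0 and beta > 0):
        raise ModelDomainError("shape parameters must be positive")
    if n < 1:
        raise ModelDomainError(f"n must be >= 1, got {n}")
    values = np.random.default_rng(seed).beta(alpha, beta, size=n)
    at_edge = (values <= 0.0) | (values >= 1.0)
    n_nudged = int(at_edge.sum())
    if n_nudged:
        values = np.clip(values, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return ProportionSample(values=values, n_nudged=n_nudged)


def write_abundance_table(sample: CommunitySample, path) -> None:
    """The TSV consumed by the fitting module (species_id, count)."""
    ids = (
        sample.species_ids
        if sample.species_ids is not None
        else [f"sp{i + 1}" for i in range(sample.S)]
    )
    pd.DataFrame({"species_id": ids, "count": sample.counts}).to_csv(
        path, sep="\t", index=False
    )


def write_provenance(provenance: dict, path) -> None:
    from . import __version__

    payload = dict(provenance, software_version=__version__)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
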