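"""Simulation of the community birth-death process and its diffusion limit.

Two schemes are provided:

``simulate_discrete``
    Exact event-driven (Gillespie) simulation of the finite-``J``
    continuous-time Markov chain with per-state rates

        b_J(n) = m*p*(1 - n/J)
        d_J(n) = m*(1-p)*n/J
        c_J(n) = lam_J*(1-m)*(n/J)*(J-n)/(J-1)

    combined as ``B_J = b_J + c_J`` (up-step) and ``D_J = d_J + c_J``
    (down-step).  The event clock runs in natural time; all user-facing
    times are in the rescaled scale ``t = (natural time)/J`` of the
    proportional-abundance process ``Z_J(t) = N(tJ)/J``.

``simulate_sde``
    Time-discrete integration of the limiting diffusion

        dZ = -m*(Z - p) dt + sqrt(2*lam*(1-m)*Z*(1-Z)) dW

    with full-truncation boundary handling: the diffusion argument
    ``Z*(1-Z)`` is clamped at 0 before the square root and the state is
    clamped back into [0, 1] after every step.  The default method adds
    the Milstein correction ``0.5*gamma*(1-2Z)*(xi^2 - 1)*dt`` to the
    Euler-Maruyama update: near ``Z = 0`` the corrected update is the
    exact square ``(sqrt(Z) + sqrt(gamma*dt/2)*xi)^2`` plus a small drift,
    which resolves the square-root degeneracy far better than plain
    Euler-Maruyama when a stationary shape parameter is below 1 (plain
    Euler at dt = 0.01 piles a spurious atom onto the boundary large
    enough to fail distribution-level checks; ``method="euler"`` is kept
    for comparison).

Reproducibility: the SDE integrator derives one independent RNG substream
per trajectory from the root seed via ``numpy.random.SeedSequence.spawn``;
the discrete simulator derives one 32-bit Mersenne-Twister seed per
trajectory from the same root sequence and consumes uniform doubles in a
fixed (dt, event-choice) order, so ensembles are bit-reproducible from
``(params, seed, scheme, step config)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ModelDomainError, NeutralParams

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "DiscreteBDConfig",
    "TrajectoryEnsemble",
    "discrete_rate_tables",
    "simulate_discrete",
    "simulate_sde",
    "ensemble_summary",
    "terminal_sample",
    "write_ensemble",
    "read_ensemble",
]


@dataclass(frozen=True)
class DiscreteBDConfig:
    """Configuration of the finite-J birth-death chain.

    Parameters
    ----------
    J : int
        Community size (total individuals); must be >= 2.
    params : NeutralParams
        Neutral rates (m, p, lam).
    n0 : int
        Initial abundance of the focal species, in {0, ..., J}.
    t_end : float
        Horizon in rescaled time units (natural horizon is ``t_end * J``).
    seed : int
        Root RNG seed.
    lam_J : float, optional
        Fluctuation coefficient of the finite chain.  Defaults to
        ``lam * J``, the simplest sequence with ``lam_J / J -> lam``.
    n_traj : int
        Number of independent trajectories.
    """

    J: int
    params: NeutralParams
    n0: int
    t_end: float
    seed: int
    lam_J: float | None = None
    n_traj: int = 1

    def __post_init__(self) -> None:
        if int(self.J) != self.J or self.J < 2:
            raise ModelDomainError(f"J must be an integer >= 2, got {self.J}")
        object.__setattr__(self, "J", int(self.J))
        if not 0 <= self.n0 <= self.J:
            raise ModelDomainError(f"n0 must lie in [0, J], got {self.n0}")
        object.__setattr__(self, "n0", int(self.n0))
        if not self.t_end > 0:
            raise ModelDomainError(f"t_end must be > 0, got {self.t_end}")
        if self.lam_J is not None and not self.lam_J > 0:
            raise ModelDomainError(f"lam_J must be > 0, got {self.lam_J}")
        if self.n_traj < 1:
            raise ModelDomainError(f"n_traj must be >= 1, got {self.n_traj}")

    @property
    def effective_lam_J(self) -> float:
        return self.params.lam * self.J if self.lam_J is None else self.lam_J


def discrete_rate_tables(config: DiscreteBDConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-state total up/down rates ``(B, D)`` for n = 0..J (natural time).

    ``D[0] = 0`` and ``B[J] = 0``: the chain never leaves [0, J].
    """
    J = config.J
    m, p = config.params.m, config.params.p
    lam_J = config.effective_lam_J
    n = np.arange(J + 1, dtype=float)
    x = n / J
    b = m * p * (1.0 - x)
    d = m * (1.0 - p) * x
    c = lam_J * (1.0 - m) * x * (J - n) / (J - 1.0)
    return b + c, d + c


@njit(cache=True)
def _gillespie_kernel(B, D, n0, seeds, grid_nat, out):  # pragma: no cover - jitted
    n_traj = seeds.shape[0]
    n_grid = grid_nat.shape[0]
    for k in range(n_traj):
        np.random.seed(seeds[k])
        n = n0
        g = 0
        t = 0.0
        while g < n_grid:
            total = B[n] + D[n]
            if total <= 0.0:
                # absorbing state: carry the value forward forever
                while g < n_grid:
                    out[k, g] = n
                    g += 1
                break
            u = np.random.random()
            t_next = t - math.log1p(-u) / total
            while g < n_grid and grid_nat[g] < t_next:
                out[k, g] = n
                g += 1
            if g >= n_grid:
                break
            if np.random.random() * total < B[n]:
                n += 1
            else:
                n -= 1
            t = t_next


def _gillespie_kernel_py(B, D, n0, seeds, grid_nat, out):
    """Pure-python fallback; consumes the same MT19937 stream as the kernel."""
    n_grid = grid_nat.shape[0]
    for k, seed in enumerate(seeds):
        rs = np.random.RandomState(int(seed))
        n = n0
        g = 0
        t = 0.0
        while g < n_grid:
            total = B[n] + D[n]
            if total <= 0.0:
                out[k, g:] = n
                break
            t_next = t - math.log1p(-rs.random_sample()) / total
            while g < n_grid and grid_nat[g] < t_next:
                out[k, g] = n
                g += 1
            if g >= n_grid:
                break
            if rs.random_sample() * total < B[n]:
                n += 1
            else:
                n -= 1
            t = t_next


@dataclass
class TrajectoryEnsemble:
    """A seeded set of proportional-abundance paths on a common time grid.

    ``paths`` has shape (n_traj, n_times) with every value in [0, 1];
    ``times`` is strictly increasing and in rescaled units.
    """

    times: np.ndarray
    paths: np.ndarray
    params: NeutralParams
    seed: int
    scheme: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.paths = np.asarray(self.paths, dtype=float)
        if self.times.ndim != 1 or self.paths.ndim != 2:
            raise ModelDomainError("times must be 1-D and paths 2-D")
        if self.paths.shape[1] != self.times.shape[0]:
            raise ModelDomainError("paths and times shapes do not match")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ModelDomainError("times must be strictly increasing")
        if np.any(self.paths < 0.0) or np.any(self.paths > 1.0):
            raise ModelDomainError("every path value must lie in [0, 1]")
        if self.scheme not in ("discrete", "diffusion"):
            raise ModelDomainError(f"unknown scheme {self.scheme!r}")

    @property
    def n_traj(self) -> int:
        return self.paths.shape[0]


def simulate_discrete(config: DiscreteBDConfig, record_grid) -> TrajectoryEnsemble:
    """Exact Gillespie simulation of the finite-J chain, recorded on a grid.

    ``record_grid`` is a strictly increasing array of rescaled times in
    [0, t_end].  Recorded values are ``n/J`` with the state carried forward
    from the last event at or before each grid point (right-continuous
    sample paths).
    """
    grid = np.asarray(record_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ModelDomainError("record_grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ModelDomainError("record_grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > config.t_end:
        raise ModelDomainError("record_grid must lie within [0, t_end]")
    B, D = discrete_rate_tables(config)
    interior = slice(1, config.J)
    if np.any((B[interior] + D[interior]) <= 0):
        raise ModelDomainError(
            "all-zero transition rates at an interior state: model misconfiguration"
        )
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_traj, dtype=np.uint32)
    out = np.empty((config.n_traj, grid.size), dtype=np.int64)
    kernel = _gillespie_kernel if _HAVE_NUMBA else _gillespie_kernel_py
    kernel(B, D, config.n0, seeds.astype(np.int64), grid * config.J, out)
    return TrajectoryEnsemble(
        times=grid,
        paths=out / config.J,
        params=config.params,
        seed=config.seed,
        scheme="discrete",
        meta={
            "J": config.J,
            "n0": config.n0,
            "lam_J": config.effective_lam_J,
            "t_end": config.t_end,
        },
    )


def _default_record_times(t_end: float, dt: float, max_points: int = 1000) -> np.ndarray:
    n_steps = int(round(t_end / dt))
    stride = max(1, n_steps // max_points)
    idx = np.arange(0, n_steps + 1, stride)
    if idx[-1] != n_steps:
        idx = np.append(idx, n_steps)
    return idx * dt


def simulate_sde(
    params: NeutralParams,
    z0: float,
    t_end: float,
    dt: float,
    n_traj: int,
    seed: int,
    record_times=None,
    method: str = "milstein",
    _chunk: int = 4096,
) -> TrajectoryEnsemble:
    """Integrate the limiting diffusion (Milstein by default, see module
    docstring; ``method="euler"`` drops the correction term).

    One independent RNG substream per trajectory is spawned from ``seed``.
    After every step the state is clamped into [0, 1] and the diffusion
    argument ``z*(1-z)`` is clamped at 0 before the square root ("full
    truncation").  ``record_times`` must align with step multiples of
    ``dt``; by default about 1000 evenly strided steps plus the endpoint
    are stored.
    """
    if method not in ("milstein", "euler"):
        raise ModelDomainError(f"method must be 'milstein' or 'euler', got {method!r}")
    if not 0.0 <= z0 <= 1.0:
        raise ModelDomainError(f"z0 must lie in [0, 1], got {z0}")
    if not dt > 0:
        raise ModelDomainError(f"dt must be > 0, got {dt}")
    if not t_end > 0:
        raise ModelDomainError(f"t_end must be > 0, got {t_end}")
    if params.m * dt >= 1.0:
        raise ModelDomainError(
            f"m*dt must be < 1 for the mean-reverting drift (got {params.m * dt})"
        )
    if n_traj < 1:
        raise ModelDomainError(f"n_traj must be >= 1, got {n_traj}")

    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9 * max(1.0, t_end):
        raise ModelDomainError("t_end must be an integer multiple of dt")
    if record_times is None:
        record_times = _default_record_times(t_end, dt)
    record_times = np.asarray(record_times, dtype=float)
    rec_idx = np.round(record_times / dt).astype(np.int64)
    if np.any(np.abs(rec_idx * dt - record_times) > 1e-9) or np.any(rec_idx < 0) or np.any(
        rec_idx > n_steps
    ):
        raise ModelDomainError("record_times must align with step multiples of dt in [0, t_end]")
    if np.any(np.diff(rec_idx) <= 0):
        raise ModelDomainError("record_times must be strictly increasing")

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_traj)]
    m, p, lam = params.m, params.p, params.lam
    gamma = lam * (1.0 - m)
    noise_scale = math.sqrt(2.0 * gamma * dt)
    milstein = method == "milstein"

    z = np.full(n_traj, float(z0))
    paths = np.empty((n_traj, rec_idx.size))
    col_of_step = {int(s): i for i, s in enumerate(rec_idx)}
    if 0 in col_of_step:
        paths[:, col_of_step[0]] = z

    xi = np.empty((n_traj, _chunk))
    step = 0
    while step < n_steps:
        csize = min(_chunk, n_steps - step)
        for i, rng in enumerate(rngs):
            xi[i, :csize] = rng.standard_normal(csize)
        for k in range(csize):
            step += 1
            w = xi[:, k]
            diff_arg = np.maximum(z * (1.0 - z), 0.0)
            incr = -m * (z - p) * dt + noise_scale * np.sqrt(diff_arg) * w
            if milstein:
                incr += 0.5 * gamma * (1.0 - 2.0 * z) * (w * w - 1.0) * dt
            z += incr
            np.clip(z, 0.0, 1.0, out=z)
            col = col_of_step.get(step)
            if col is not None:
                paths[:, col] = z

    return TrajectoryEnsemble(
        times=rec_idx * dt,
        paths=paths,
        params=params,
        seed=seed,
        scheme="diffusion",
        meta={"z0": float(z0), "dt": float(dt), "t_end": float(t_end), "method": method},
    )


def ensemble_summary(ens: TrajectoryEnsemble, level: float = 0.95) -> pd.DataFrame:
    """Cross-trajectory mean and empirical quantile band per time point.

    Returns a DataFrame with columns ``time``, ``mean``, ``lower``,
    ``upper``; the band holds the central ``level`` mass of the
    trajectory values at each time.
    """
    if ens.n_traj < 2:
        raise ModelDomainError("ensemble_summary requires at least 2 trajectories")
    if not 0.0 < level < 1.0:
        raise ModelDomainError(f"level must lie in (0, 1), got {level}")
    lo_q = (1.0 - level) / 2.0
    lower, upper = np.quantile(ens.paths, [lo_q, 1.0 - lo_q], axis=0)
    return pd.DataFrame(
        {
            "time": ens.times,
            "mean": ens.paths.mean(axis=0),
            "lower": lower,
            "upper": upper,
        }
    )


def terminal_sample(ens: TrajectoryEnsemble, t: float) -> np.ndarray:
    """One value per trajectory at the recorded grid time nearest ``t``.

    Intended as an i.i.d.-across-trajectories stationary sample when
    ``m * t >> 1``.  ``t`` must lie within the recorded range.
    """
    tmin, tmax = ens.times[0], ens.times[-1]
    tol = 1e-9 * max(1.0, tmax)
    if t < tmin - tol or t > tmax + tol:
        raise ModelDomainError(f"t={t} lies outside the simulated range [{tmin}, {tmax}]")
    idx = int(np.argmin(np.abs(ens.times - t)))
    return ens.paths[:, idx].copy()


# ---------------------------------------------------------------------------
# tidy TSV export/import with a JSON sidecar

def write_ensemble(ens: TrajectoryEnsemble, tsv_path, sidecar_path=None) -> None:
    """Write a tidy TSV (trajectory_id, time, value) plus a config sidecar.

    Floats are written with shortest round-trip repr, so
    :func:`read_ensemble` reproduces the ensemble exactly.
    """
    tsv_path = Path(tsv_path)
    n_traj, n_times = ens.paths.shape
    df = pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.arange(n_traj), n_times),
            "time": np.tile(ens.times, n_traj),
            "value": ens.paths.ravel(),
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if sidecar_path is None:
        sidecar_path = tsv_path.with_suffix(".json")
    sidecar = {
        "params": {
            "m": ens.params.m,
            "p": ens.params.p,
            "lam": ens.params.lam,
            "S": ens.params.S,
        },
        "seed": ens.seed,
        "scheme": ens.scheme,
        "meta": ens.meta,
        "n_traj": n_traj,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


def read_ensemble(tsv_path, sidecar_path=None) -> TrajectoryEnsemble:
    """Inverse of :func:`write_ensemble` (exact round trip)."""
    tsv_path = Path(tsv_path)
    if sidecar_path is None:
        sidecar_path = tsv_path.with_suffix(".json")
    sidecar = json.loads(Path(sidecar_path).read_text())
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    n_traj = int(sidecar["n_traj"])
    times = df.loc[df["trajectory_id"] == 0, "time"].to_numpy()
    paths = df["value"].to_numpy().reshape(n_traj, times.size)
    params = NeutralParams(**sidecar["params"])
    return TrajectoryEnsemble(
        times=times,
        paths=paths,
        params=params,
        seed=int(sidecar["seed"]),
        scheme=sidecar["scheme"],
        meta=sidecar.get("meta", {}),
    )
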