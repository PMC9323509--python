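"""Morris elementary-effects screening over the model's parameter space.

With 19 rate/transport constants and a small data set the calibration problem
is underdetermined; a screening pass ranks parameters by their influence on
the 24-h gel-average observables before any fitting.  The method perturbs one
parameter at a time along randomised trajectories through a p-level grid on
the unit hypercube, yielding one elementary effect (EE) per parameter per
trajectory.  The mean absolute EE (mu*) measures overall influence; the EE
standard deviation (sigma) flags nonlinearity and interactions.

Trajectories are selected from a larger random pool by a greedy maximin
spread criterion (Campolongo-style), which improves input-space coverage at
no extra model cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_core import LOG_SCALE_PARAMETERS, PARAMETER_BOUNDS

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "sample_trajectories",
    "elementary_effects",
    "morris_statistics",
    "map_to_physical",
    "unit_to_physical",
    "morris_screen",
]


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorrisDesign:
    """A set of r one-at-a-time trajectories on the unit hypercube.

    Each trajectory is a (k+1, k) array whose consecutive rows differ in
    exactly one coordinate by +/- delta.
    """

    trajectories: np.ndarray  # (r, k+1, k)
    delta: float
    levels: int

    @property
    def r(self) -> int:
        return self.trajectories.shape[0]

    @property
    def k(self) -> int:
        return self.trajectories.shape[2]


def _random_trajectory(k: int, p: int, delta: float, rng: np.random.Generator) -> np.ndarray:
    """One-at-a-time trajectory: a random grid base point, then each
    coordinate flipped once by +/- delta in a random visiting order.

    Base levels are restricted so every move stays inside [0, 1]: an upward
    move starts from ``{0, 1/(p-1), ...}``, a downward move from the mirrored
    high levels.
    """
    grid = np.arange(p // 2) / (p - 1)          # levels with x + delta <= 1
    base = rng.choice(grid, size=k)
    direction = rng.choice([-1.0, 1.0], size=k)
    x = np.where(direction > 0, base, 1.0 - base)
    traj = np.empty((k + 1, k))
    traj[0] = x
    for row, i in enumerate(rng.permutation(k), start=1):
        x = x.copy()
        x[i] += delta * direction[i]
        traj[row] = x
    return traj


def _trajectory_distance_matrix(trajs: np.ndarray) -> np.ndarray:
    """Pairwise trajectory spread: sum of all point-to-point distances."""
    from scipy.spatial.distance import cdist

    m, npts, k = trajs.shape
    flat = trajs.reshape(m * npts, k)
    dist = np.empty((m, m))
    for a in range(m):
        d = cdist(trajs[a], flat)
        dist[a] = d.reshape(npts, m, npts).sum(axis=(0, 2))
    np.fill_diagonal(dist, 0.0)
    return dist


def _greedy_maximin(dist: np.ndarray, r: int) -> np.ndarray:
    """Greedy subset selection maximising the summed squared spread."""
    d2 = dist**2
    first = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [first[0], first[1]]
    remaining = set(range(dist.shape[0])) - set(chosen)
    while len(chosen) < r:
        best = max(remaining, key=lambda j: d2[j, chosen].sum())
        chosen.append(best)
        remaining.discard(best)
    return np.array(sorted(chosen))


def sample_trajectories(
    k: int,
    r: int,
    p: int = 4,
    candidate_pool: int = 500,
    seed: int | None = None,
) -> MorrisDesign:
    """Sample ``candidate_pool`` random trajectories and keep the ``r`` most
    mutually spread ones (greedy maximin on pairwise trajectory distance).

    ``p`` must be even; the grid jump is the standard ``delta = p/(2(p-1))``.
    """
    if p < 2 or p % 2:
        raise ValueError("number of levels p must be even and >= 2")
    if r < 2:
        raise ValueError("r must be >= 2")
    if candidate_pool < r:
        raise ValueError("candidate_pool must be >= r")
    delta = p / (2.0 * (p - 1))
    rng = np.random.default_rng(seed)
    pool = np.stack([_random_trajectory(k, p, delta, rng) for _ in range(candidate_pool)])
    if candidate_pool == r:
        keep = np.arange(r)
    else:
        keep = _greedy_maximin(_trajectory_distance_matrix(pool), r)
    return MorrisDesign(trajectories=pool[keep], delta=delta, levels=p)


# ---------------------------------------------------------------------------
# Parameter-space mapping
# ---------------------------------------------------------------------------


def map_to_physical(
    u: np.ndarray,
    names: Sequence[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    log_names: frozenset[str] | None = None,
) -> dict[str, float]:
    """Affine map from unit-cube coordinates to physical parameter values.

    Parameters whose interval spans two or more decades are interpolated in
    log10 space, the rest linearly.
    """
    bounds = PARAMETER_BOUNDS if bounds is None else bounds
    log_names = LOG_SCALE_PARAMETERS if log_names is None else log_names
    out = {}
    for ui, name in zip(np.asarray(u, dtype=float), names):
        lo, hi = bounds[name]
        if name in log_names:
            out[name] = 10 ** (np.log10(lo) + ui * (np.log10(hi) - np.log10(lo)))
        else:
            out[name] = lo + ui * (hi - lo)
    return out


def unit_to_physical(u, names, **kw) -> np.ndarray:
    return np.array(list(map_to_physical(u, names, **kw).values()))


# ---------------------------------------------------------------------------
# Elementary effects & statistics
# ---------------------------------------------------------------------------


def elementary_effects(
    model_fn: Callable[[np.ndarray], float],
    design: MorrisDesign,
) -> np.ndarray:
    """One EE per (trajectory, parameter): finite difference along each move.

    ``model_fn`` maps a unit-cube vector to a scalar output (the caller wraps
    any physical-unit mapping).  A trajectory on which the model fails is
    excluded with a warning; rows of the returned (r_valid, k) matrix
    correspond to the surviving trajectories.
    """
    rows = []
    for j, traj in enumerate(design.trajectories):
        try:
            y = np.array([model_fn(x) for x in traj])
        except Exception as exc:  # noqa: BLE001 - model failures degrade to exclusion
            warnings.warn(f"model evaluation failed on trajectory {j}: {exc!r}; excluded")
            continue
        ee = np.full(design.k, np.nan)
        for step in range(design.k):
            dx = traj[step + 1] - traj[step]
            (i,) = np.nonzero(np.abs(dx) > 1e-12)
            i = int(i[0])
            ee[i] = (y[step + 1] - y[step]) / dx[i]
        rows.append(ee)
    if not rows:
        raise RuntimeError("model failed on every trajectory")
    return np.asarray(rows)


@dataclass(frozen=True)
class MorrisResult:
    """Screening statistics per parameter for one scalar output."""

    names: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray
    ee: np.ndarray  # (r, k)

    def to_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(self.mu_star > 0, self.sigma / self.mu_star, np.nan)
        return pd.DataFrame(
            {"parameter": self.names, "mu_star": self.mu_star,
             "sigma": self.sigma, "sigma_over_mu_star": ratio}
        )

    def ranking(self) -> list[str]:
        """Parameter names ordered by decreasing mu*."""
        order = np.argsort(-self.mu_star)
        return [self.names[i] for i in order]


def morris_statistics(ee: np.ndarray, names: Sequence[str] | None = None) -> MorrisResult:
    """mu* (mean |EE|) and sigma (EE standard deviation, 1/r normalisation)."""
    ee = np.asarray(ee, dtype=float)
    r = ee.shape[0]
    if r < 2:
        raise ValueError("sigma requires at least 2 trajectories")
    mu_star = np.abs(ee).mean(axis=0)
    sigma = np.sqrt(((ee - ee.mean(axis=0)) ** 2).mean(axis=0))
    if names is None:
        names = tuple(f"x{i}" for i in range(ee.shape[1]))
    return MorrisResult(names=tuple(names), mu_star=mu_star, sigma=sigma, ee=ee)


# ---------------------------------------------------------------------------
# Full-model screening driver
# ---------------------------------------------------------------------------


def morris_screen(
    output_fns: dict[str, Callable[[dict[str, float]], float]],
    names: Sequence[str] | None = None,
    r: int = 40,
    p: int = 4,
    candidate_pool: int = 500,
    seed: int | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[dict[str, MorrisResult], MorrisDesign]:
    """Screen several scalar outputs over the packaged parameter bounds.

    ``output_fns`` maps output labels to callables taking a physical
    parameter mapping (name -> value).  All outputs share one design, so a
    single pass of forward runs can back several observables: callables may
    close over a shared memoised forward model.
    """
    names = tuple(PARAMETER_BOUNDS) if names is None else tuple(names)
    design = sample_trajectories(len(names), r, p, candidate_pool, seed)
    results = {}
    for label, fn in output_fns.items():
        wrapped = lambda u, fn=fn: fn(map_to_physical(u, names, bounds=bounds))
        ee = elementary_effects(wrapped, design)
        results[label] = morris_statistics(ee, names)
    return results, design
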