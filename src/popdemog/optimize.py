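"""Three-round perturbed multi-start Nelder-Mead protocol.

The optimization runs in log-parameter space (demographic parameters are
positive and multiplicatively perturbed, so log-scale geometry is natural):

* round 1 - 50 replicates started from three-fold perturbations of the
  model's default parameters, each capped at 20 simplex iterations;
* round 2 - 50 replicates from two-fold perturbations of the round-1 best;
* round 3 - 100 replicates from one-fold perturbations of the round-2 best.

A "fold-f" perturbation multiplies each parameter independently by
``2**u, u ~ Uniform(-f, f)``, clamped to its bounds.  The returned best is
never worse than any single replicate; the full per-replicate trace is kept.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

__all__ = ["RoundConfig", "perturb", "nelder_mead", "three_round_protocol",
           "DEFAULT_ROUNDS"]

_PENALTY = 1e10


@dataclasses.dataclass
class RoundConfig:
    """One round of the multi-start protocol."""

    replicates: int
    fold: float
    maxiter: int = 20

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.fold < 0 or self.maxiter < 1:
            raise ValueError("invalid round configuration")


DEFAULT_ROUNDS: tuple[RoundConfig, ...] = (
    RoundConfig(replicates=50, fold=3, maxiter=20),
    RoundConfig(replicates=50, fold=2, maxiter=20),
    RoundConfig(replicates=100, fold=1, maxiter=20),
)


def perturb(
    params: np.ndarray,
    fold: float,
    bounds: list[tuple[float, float]],
    seed=None,
) -> np.ndarray:
    """Multiply each parameter by ``2**Uniform(-fold, fold)``, clamp to bounds."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = np.asarray(params, dtype=float)
    u = rng.uniform(-fold, fold, size=params.shape)
    out = params * 2.0**u
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(out, lo, hi)


def nelder_mead(
    objective,
    start: np.ndarray,
    maxiter: int,
    bounds: list[tuple[float, float]],
) -> tuple[np.ndarray, float, int]:
    """Downhill-simplex minimization in log-parameter space.

    Proposals outside the (log) bounds are penalized rather than clipped so
    the simplex retreats into the feasible region.  Returns
    ``(best_params, best_value, iterations_used)``; the best value is never
    worse than the starting value.
    """
    start = np.asarray(start, dtype=float)
    log_lo = np.log([b[0] for b in bounds])
    log_hi = np.log([b[1] for b in bounds])

    def wrapped(logp: np.ndarray) -> float:
        if (logp < log_lo).any() or (logp > log_hi).any():
            excess = np.maximum(logp - log_hi, 0) + np.maximum(log_lo - logp, 0)
            return _PENALTY * (1.0 + excess.sum())
        return objective(np.exp(logp))

    x0 = np.log(start)
    f0 = wrapped(x0)
    if not np.isfinite(f0):
        raise ValueError("objective not finite at the starting point")
    res = minimize(wrapped, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8})
    if res.fun <= f0:
        best_x, best_f = np.exp(res.x), float(res.fun)
    else:  # cannot happen with NM, but keep the descent contract explicit
        best_x, best_f = start, float(f0)
    return best_x, best_f, int(res.nit)


def three_round_protocol(
    objective,
    start_params: np.ndarray,
    bounds: list[tuple[float, float]],
    seed: int | None = None,
    rounds: tuple[RoundConfig, ...] = DEFAULT_ROUNDS,
) -> tuple[np.ndarray, float, list[dict]]:
    """Run the staged multi-start protocol; returns (best, value, trace).

    Each round perturbs the current center (the model defaults, then the
    previous round's best) and polishes every start with Nelder-Mead.  The
    trace records one row per replicate.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(start_params, dtype=float)
    best_params = center.copy()
    best_value = np.inf
    trace: list[dict] = []
    for rnd, cfg in enumerate(rounds, start=1):
        round_best_params = None
        round_best_value = np.inf
        for rep in range(cfg.replicates):
            start = perturb(center, cfg.fold, bounds, seed=rng)
            try:
                end, val, nit = nelder_mead(objective, start, cfg.maxiter, bounds)
            except ValueError:
                continue
            trace.append({
                "round": rnd,
                "replicate": rep,
                "start": start.tolist(),
                "end": end.tolist(),
                "neg_ll": val,
                "iterations": nit,
            })
            if val < round_best_value:
                round_best_value, round_best_params = val, end
        if round_best_params is not None:
            if round_best_value < best_value:
                best_value, best_params = round_best_value, round_best_params
            center = round_best_params
    return best_params, best_value, trace
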