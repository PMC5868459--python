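"""Two-component circular mixture model of continuous-report errors.

The error distribution is modelled as a probabilistic mixture of memory
and guessing:

    p(x) = p_mem * VonMises(x; 0, kappa) + (1 - p_mem) / 2π

where ``p_mem`` is the probability that a response is drawn from the
target-centred von Mises component and ``kappa`` its concentration
(precision). Parameters are estimated by maximum likelihood with
multi-start bounded quasi-Newton optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import optimize, special

__all__ = [
    "MixtureParams",
    "MixtureFit",
    "mixture_loglik",
    "fit_mixture",
    "grid_search",
    "KAPPA_MAX",
]

# kappa = 500 corresponds to a circular SD of about 2.6 degrees, beyond
# plausible motor precision in orientation reproduction.
KAPPA_MAX = 500.0

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureParams:
    p_mem: float
    kappa: float

    def __post_init__(self):
        if not 0.0 <= self.p_mem <= 1.0:
            raise ValueError(f"p_mem must be in [0, 1], got {self.p_mem}")
        if not 0.0 <= self.kappa <= KAPPA_MAX:
            raise ValueError(f"kappa must be in [0, {KAPPA_MAX}], got {self.kappa}")


@dataclass(frozen=True)
class MixtureFit:
    params: MixtureParams
    loglik: float
    n: int
    converged: bool
    n_starts: int


def _log_density(errors: np.ndarray, p_mem: float, kappa: float) -> np.ndarray:
    # log I0(kappa) via the exponentially scaled Bessel function: stable to
    # kappa ~ 1e4, far beyond KAPPA_MAX.
    log_i0 = np.log(special.ive(0, kappa)) + kappa
    log_vm = kappa * np.cos(errors) - _LOG_2PI - log_i0
    log_unif = -_LOG_2PI
    if p_mem <= 0.0:
        return np.full_like(errors, log_unif)
    if p_mem >= 1.0:
        return log_vm
    return np.logaddexp(np.log(p_mem) + log_vm, np.log1p(-p_mem) + log_unif)


def mixture_loglik(errors, params: MixtureParams) -> float:
    """Log-likelihood of wrapped signed errors under the mixture model."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("mixture_loglik requires at least one error")
    return float(_log_density(e, params.p_mem, params.kappa).sum())


_DEFAULT_P_STARTS = (0.1, 0.3, 0.5, 0.7, 0.9)
_DEFAULT_K_STARTS = (1.0, 4.0, 16.0, 64.0)


def fit_mixture(
    errors,
    *,
    min_n: int = 20,
    p_starts=_DEFAULT_P_STARTS,
    kappa_starts=_DEFAULT_K_STARTS,
    kappa_max: float = KAPPA_MAX,
) -> MixtureFit:
    """Maximum-likelihood fit of (p_mem, kappa) to wrapped signed errors.

    Runs L-BFGS-B from every point of a coarse start grid and keeps the best
    local optimum. ``converged`` is True if the winning start reported
    optimizer success.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < min_n:
        raise ValueError(f"fit_mixture needs n >= {min_n}, got n = {e.size}")
    cos_e = np.cos(e)

    def nll(theta: np.ndarray) -> float:
        p, k = theta
        log_i0 = np.log(special.ive(0, k)) + k
        log_vm = k * cos_e - _LOG_2PI - log_i0
        if p <= 0.0:
            return e.size * _LOG_2PI
        if p >= 1.0:
            return -float(log_vm.sum())
        ll = np.logaddexp(np.log(p) + log_vm, np.log1p(-p) - _LOG_2PI)
        return -float(ll.sum())

    best = None
    any_success = False
    n_starts = 0
    for p0, k0 in product(p_starts, kappa_starts):
        n_starts += 1
        res = optimize.minimize(
            nll,
            x0=np.array([p0, min(k0, kappa_max)]),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, kappa_max)],
        )
        if best is None or res.fun < best.fun:
            best = res
            any_success = bool(res.success)
        elif res.fun == best.fun and res.success:
            any_success = True
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    params = MixtureParams(p_mem=float(best.x[0]), kappa=float(best.x[1]))
    return MixtureFit(
        params=params,
        loglik=-float(best.fun),
        n=e.size,
        converged=any_success,
        n_starts=n_starts,
    )


def grid_search(errors, p_grid, kappa_grid) -> MixtureParams:
    """Exhaustive log-likelihood argmax over a parameter lattice.

    Deterministic: ties are broken toward the lowest ``p_mem``, then the
    lowest ``kappa``. Intended as a slow, transparent reference for the
    quasi-Newton fit.
    """
    e = np.asarray(errors, dtype=float)
    p_grid = np.asarray(sorted(p_grid), dtype=float)
    kappa_grid = np.asarray(sorted(kappa_grid), dtype=float)
    if p_grid.size == 0 or kappa_grid.size == 0:
        raise ValueError("grid must be non-empty")
    best_ll = -np.inf
    best = None
    for p in p_grid:
        for k in kappa_grid:
            ll = float(_log_density(e, p, k).sum())
            if ll > best_ll:
                best_ll = ll
                best = MixtureParams(p_mem=float(p), kappa=float(k))
    return best
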