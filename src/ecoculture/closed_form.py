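"""Analytical solutions of the three model equations, used as independent
oracles for the Euler integrator.

Each model equation is linear (capacity, culture) or Bernoulli-type
(logistic density) given the *paths* of the other variables, so all three
admit exact solutions in quadrature form:

* density:   rho(t) = rho0 e^{alpha t} / (1 + rho0 * I(t)) with
             I(t) = int_0^t alpha / K_eff(tau) * e^{alpha tau} dtau
* capacity:  K(t) = K_init e^{-eta t}
             + int_0^t e^{-eta (t-t')} [eta K0(t') - mu rho(t')] dt'
* culture:   c(t) = c0 e^{-lambda t}
             + sigma * sum_{t'<t} rho(t') xi(t') e^{-lambda (t-t')} dt

The initial-condition terms carry the exponential damping the exact
linear-ODE solutions require (without it the formulas would not satisfy
their own equations as t -> infinity; see docs/methods.md).

The quadratures default to a left-endpoint rule on the simulation grid so
the oracle's discretization error matches the Euler scheme's first order;
a trapezoid option exists for convergence studies.  The density solution is
evaluated in the numerically equivalent damped form
``rho(t) = 1 / (e^{-alpha t}/rho0 + J(t))`` with
``J(t) = int_0^t alpha / K_eff(tau) e^{-alpha (t-tau)} dtau`` to avoid
overflow of e^{alpha t} on long horizons.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np

from .errors import ParameterError

__all__ = [
    "logistic_solution",
    "carrying_capacity_solution",
    "culture_solution",
]

#: A model-variable path: either an array aligned with the time grid or a
#: callable evaluated on it.
PathFunction = Union[np.ndarray, Callable[[np.ndarray], np.ndarray]]


def _as_path(path: PathFunction, t_grid: np.ndarray, name: str) -> np.ndarray:
    values = path(t_grid) if callable(path) else np.asarray(path, dtype=float)
    if values.shape != t_grid.shape:
        raise ValueError(
            f"{name} has shape {values.shape}, expected {t_grid.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


def _decayed_accumulation(
    f: np.ndarray, t: np.ndarray, rate: float, rule: str
) -> np.ndarray:
    """S(t_n) = int_0^{t_n} e^{-rate (t_n - t')} f(t') dt' by recursion.

    Left rule takes the amplitude at the interval's left endpoint and starts
    the kernel decay at the interval's end (first-order, mirroring how Euler
    deposits an increment undamped and damps it on subsequent steps);
    trapezoid averages both endpoints.
    """
    n = len(t)
    out = np.zeros(n)
    s = 0.0
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        decay = np.exp(-rate * h)
        if rule == "left":
            s = decay * s + h * f[i]
        elif rule == "trapezoid":
            s = decay * s + 0.5 * h * (decay * f[i] + f[i + 1])
        else:
            raise ValueError(f"unknown quadrature rule {rule!r}")
        out[i + 1] = s
    return out


def logistic_solution(
    rho0: float,
    alpha: float,
    effective_K: PathFunction,
    t_grid: np.ndarray,
    rule: str = "left",
) -> np.ndarray:
    """Exact logistic density for a prescribed effective-capacity path.

    ``effective_K`` is the culture-boosted capacity K(t)(1+c(t)); it must be
    strictly positive on the grid.
    """
    t = np.asarray(t_grid, dtype=float)
    if rho0 <= 0:
        raise ParameterError("rho0 must be > 0")
    if alpha <= 0:
        raise ParameterError("alpha must be > 0")
    K_eff = _as_path(effective_K, t, "effective_K")
    if np.any(K_eff <= 0):
        raise ValueError("effective_K must be strictly positive on the grid")
    tau = t - t[0]
    J = _decayed_accumulation(alpha / K_eff, t, alpha, rule)
    return 1.0 / (np.exp(-alpha * tau) / rho0 + J)


def carrying_capacity_solution(
    K_init: float,
    eta: float,
    mu: float,
    K0_path: PathFunction,
    rho_path: PathFunction,
    t_grid: np.ndarray,
    rule: str = "left",
) -> np.ndarray:
    """Exact capacity for prescribed forcing and density paths."""
    t = np.asarray(t_grid, dtype=float)
    K0 = _as_path(K0_path, t, "K0_path")
    rho = _as_path(rho_path, t, "rho_path")
    if eta < 0 or mu < 0:
        raise ParameterError("eta and mu must be >= 0")
    tau = t - t[0]
    S = _decayed_accumulation(eta * K0 - mu * rho, t, eta, rule)
    return K_init * np.exp(-eta * tau) + S


def culture_solution(
    c0: float,
    lam: float,
    sigma: float,
    rho_path: PathFunction,
    xi_path: PathFunction,
    t_grid: np.ndarray,
    rule: str = "left",
) -> np.ndarray:
    """Exact culture for prescribed density and innovation-draw paths.

    ``xi_path`` holds the per-step draws; it may have length ``len(t_grid)``
    (last entry unused under the left rule) or ``len(t_grid) - 1``.  The
    equation is linear in c, so with the recorded draws of a stochastic run
    this reproduces the Euler culture trajectory to quadrature accuracy even
    for sigma > 0.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if c0 < 0 or lam < 0:
        raise ParameterError("c0 and lam must be >= 0")
    t = np.asarray(t_grid, dtype=float)
    rho = _as_path(rho_path, t, "rho_path")
    xi = xi_path(t) if callable(xi_path) else np.asarray(xi_path, dtype=float)
    if len(xi) == len(t) - 1:
        xi = np.concatenate([xi, [0.0]])
    if xi.shape != t.shape:
        raise ValueError(
            f"xi_path has length {len(xi)}, expected {len(t)} or {len(t) - 1}"
        )
    tau = t - t[0]
    S = _decayed_accumulation(sigma * rho * xi, t, lam, rule)
    return c0 * np.exp(-lam * tau) + S
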