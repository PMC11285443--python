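"""Three-equation stochastic ecocultural consumer-resource model.

State variables
---------------
rho : population density (consumer)
c   : culture, a dimensionless booster of the carrying capacity
K   : carrying capacity (resource)

Dynamics (continuous-time form)::

    drho/dt = alpha * rho * (1 - rho / (K * (1 + c)))
    dc/dt   = -lam * c + sigma * xi_t * rho
    dK/dt   = -eta * (K - K0(t)) - mu * rho

where ``xi_t`` are i.i.d. Weibull-distributed innovation draws (one per time
step), ``K*(1+c)`` is the culture-boosted ("cultural") carrying capacity,
``lam`` the intergenerational culture-loss rate, ``eta`` the resource
replenishment rate and ``mu`` the depletion (grazing) rate.

Integration uses a fully explicit, simultaneous Euler-forward scheme.  The
per-step innovation draw is *not* rescaled by sqrt(dt): the discrete scheme
at dt = 1 is taken as the definition of the stochastic process, so changing
dt changes the stochastic model (see docs/methods.md).

Two guards keep the discrete system well posed in the heavily depleted
regime (see docs/methods.md for the full rationale):

* exhausted resources -- when depletion drives the cultural carrying
  capacity K(1+c) to zero or below while the population is alive, the
  logistic growth target is undefined and the raw update is unstable
  (growth re-emerges from a negative capacity and the trajectory diverges).
  The integrator instead applies intrinsic decline ``drho = -alpha*rho`` for
  those steps and counts them.
* quasi-extinction floor -- the continuous model is multiplicative in rho
  and never reaches zero in finite time; an Euler overshoot clipped to
  exactly zero would create an absorbing extinction the model does not
  possess.  rho is clipped to ``rho_floor`` (default 1e-12) instead, and the
  clip is counted.  Setting ``rho_floor = 0`` restores absorbing extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from numba import njit

from .errors import DegenerateStateError, IntegrationError, ParameterError
from .forcing import ClimateForcing, constant_forcing

__all__ = [
    "ModelParameters",
    "ModelState",
    "StepEvents",
    "Trajectory",
    "standard_parameters",
    "deterministic_drift",
    "draw_innovations",
    "euler_step",
    "simulate",
    "equilibrium_fixed_point",
]


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, noise parameters, default forcing, initial
    conditions and integration settings of one model run.

    Defaults are the standard-run rates: alpha = lam = 0.01 (population
    growth and culture-loss e-folding times of 100 steps), mu = 0.001,
    eta = 0.1 (resource recovery time of 10 steps), sigma = 1e-8 with
    heavy-tailed Weibull(shape=0.1, scale=1) innovation bursts, constant
    unperturbed capacity K0_star = 1.

    ``rho0`` defaults to 1% of ``K0_star`` and ``K_init`` to ``K0_star``
    when left as None.  ``kappa > 0`` selects sinusoidal climate forcing
    K0(t) = K0_star*(1 + kappa*cos(omega*t)).
    """

    alpha: float = 0.01
    lam: float = 0.01
    mu: float = 0.001
    eta: float = 0.1
    sigma: float = 1e-8
    weibull_shape: float = 0.1
    weibull_scale: float = 1.0
    K0_star: float = 1.0
    kappa: float = 0.0
    omega: float = 0.0
    rho0: Optional[float] = None
    c0: float = 1.0
    K_init: Optional[float] = None
    rho_floor: float = 1e-12
    dt: float = 1.0
    n_steps: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho0 is None:
            object.__setattr__(self, "rho0", 0.01 * self.K0_star)
        if self.K_init is None:
            object.__setattr__(self, "K_init", self.K0_star)
        _require(self.alpha > 0, "alpha must be > 0")
        _require(self.lam >= 0, "lam must be >= 0")
        _require(self.mu >= 0, "mu must be >= 0")
        _require(self.eta >= 0, "eta must be >= 0")
        _require(self.sigma >= 0, "sigma must be >= 0")
        _require(self.weibull_shape > 0, "weibull_shape must be > 0")
        _require(self.weibull_scale > 0, "weibull_scale must be > 0")
        _require(self.K0_star > 0, "K0_star must be > 0")
        _require(0 <= self.kappa < 1, "kappa must lie in [0, 1)")
        _require(self.omega >= 0, "omega must be >= 0")
        _require(self.rho0 > 0, "rho0 must be > 0")
        _require(self.c0 >= 0, "c0 must be >= 0")
        _require(self.K_init > 0, "K_init must be > 0")
        _require(self.rho_floor >= 0, "rho_floor must be >= 0")
        _require(self.dt > 0, "dt must be > 0")
        _require(self.n_steps >= 1, "n_steps must be >= 1")

    def default_forcing(self) -> ClimateForcing:
        """Forcing implied by the (K0_star, kappa, omega) fields."""
        if self.kappa == 0.0:
            return constant_forcing(self.K0_star)
        return ClimateForcing(
            kind="periodic",
            K0_star=self.K0_star,
            kappa=self.kappa,
            omega=self.omega,
        )

    def with_(self, **kwargs) -> "ModelParameters":
        """Copy with replaced fields."""
        return replace(self, **kwargs)


def standard_parameters(**overrides) -> ModelParameters:
    """The standard-run parameter set; keyword overrides select variants
    (e.g. ``sigma=0`` for no culture, ``mu=0.01`` for high depletion,
    ``eta=1e-5`` for slow resource recovery)."""
    return ModelParameters(**overrides)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state (t, rho, c, K)."""

    t: float
    rho: float
    c: float
    K: float


class StepEvents(NamedTuple):
    """Bookkeeping for one Euler step."""

    clips: int  # negativity clips applied (rho to rho_floor, c to 0)
    exhausted: bool  # growth guard taken because K(1+c) <= 0


@dataclass
class Trajectory:
    """Time-indexed output of one simulation.

    ``t``, ``rho``, ``c``, ``K``, ``K0_t`` and ``per_capita`` have length
    ``n_steps + 1``; ``xi`` holds the ``n_steps`` innovation draws actually
    used.  ``per_capita`` is resources per capita K/rho (NaN where rho = 0).
    ``warnings`` counts negativity clips; ``exhausted_steps`` counts steps
    on which the exhausted-resources growth guard was active.
    """

    t: np.ndarray
    rho: np.ndarray
    c: np.ndarray
    K: np.ndarray
    K0_t: np.ndarray
    per_capita: np.ndarray
    xi: np.ndarray
    warnings: int
    exhausted_steps: int = 0
    params: ModelParameters = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        """Trajectory as a pandas DataFrame (xi padded with NaN at t[0])."""
        import pandas as pd

        xi_col = np.concatenate([[np.nan], self.xi])
        return pd.DataFrame(
            {
                "t": self.t,
                "rho": self.rho,
                "c": self.c,
                "K": self.K,
                "K0": self.K0_t,
                "per_capita": self.per_capita,
                "xi": xi_col,
            }
        )


def deterministic_drift(
    state: ModelState, K0_now: float, params: ModelParameters
) -> tuple[float, float, float]:
    """Deterministic right-hand sides (drho, dc, dK) at the current state.

    Extinction is absorbing: rho = 0 makes drho = 0 regardless of K or c.
    Raises :class:`DegenerateStateError` if the cultural carrying capacity
    K(1+c) is non-positive while rho > 0 (the logistic growth target is
    undefined there; the integrator substitutes intrinsic decline instead,
    see :func:`euler_step`).
    """
    rho, c, K = state.rho, state.c, state.K
    if rho == 0.0:
        drho = 0.0
    else:
        K_eff = K * (1.0 + c)
        if K_eff <= 0.0:
            raise DegenerateStateError(
                f"cultural carrying capacity K(1+c) = {K_eff:g} <= 0 "
                f"(K = {K:g}, c = {c:g}) with rho = {rho:g} > 0"
            )
        drho = params.alpha * rho * (1.0 - rho / K_eff)
    dc = -params.lam * c
    dK = -params.eta * (K - K0_now) - params.mu * rho
    return drho, dc, dK


def draw_innovations(
    rng: np.random.Generator, shape: float, scale: float, n: int
) -> np.ndarray:
    """Draw ``n`` i.i.d. Weibull(shape, scale) innovation magnitudes.

    Weibull density: (k/s)(x/s)^(k-1) exp(-(x/s)^k) with shape k and scale
    s.  A shape well below 1 produces rare, very large bursts -- the model's
    cartoon of breakthrough innovations.
    """
    if shape <= 0 or scale <= 0:
        raise ParameterError("Weibull shape and scale must be positive")
    if n < 1:
        raise ParameterError("n must be >= 1")
    return scale * rng.weibull(shape, size=n)


def euler_step(
    state: ModelState,
    xi_now: float,
    K0_now: float,
    params: ModelParameters,
) -> tuple[ModelState, StepEvents]:
    """One explicit Euler step; all right-hand sides use the current state.

    Mirrors the compiled integrator bit for bit.  Returns the successor
    state and the step's :class:`StepEvents`.  K is never clipped: depletion
    may legitimately drive it negative; only the growth term is guarded.
    """
    r, cc, k = state.rho, state.c, state.K
    if not (np.isfinite(r) and np.isfinite(cc) and np.isfinite(k)):
        raise IntegrationError("non-finite state")
    exhausted = False
    if r == 0.0:
        drho = 0.0
    else:
        K_eff = k * (1.0 + cc)
        if K_eff <= 0.0:
            drho = -params.alpha * r
            exhausted = True
        else:
            drho = params.alpha * r * (1.0 - r / K_eff)
    dc = -params.lam * cc + params.sigma * xi_now * r
    dK = -params.eta * (k - K0_now) - params.mu * r
    dt = params.dt
    rho_new = r + dt * drho
    c_new = cc + dt * dc
    K_new = k + dt * dK
    clips = 0
    if rho_new < params.rho_floor:
        rho_new = params.rho_floor
        clips += 1
    if c_new < 0.0:
        c_new = 0.0
        clips += 1
    if not (
        np.isfinite(rho_new) and np.isfinite(c_new) and np.isfinite(K_new)
    ):
        raise IntegrationError("state became non-finite after step")
    return (
        ModelState(t=state.t + dt, rho=rho_new, c=c_new, K=K_new),
        StepEvents(clips=clips, exhausted=exhausted),
    )


@njit(cache=True)
def _integrate(
    rho0, c0, K_init, alpha, lam, mu, eta, sigma, rho_floor, dt, n_steps,
    xi, K0_arr,
):  # pragma: no cover - exercised through simulate()
    rho = np.empty(n_steps + 1)
    c = np.empty(n_steps + 1)
    K = np.empty(n_steps + 1)
    rho[0] = rho0
    c[0] = c0
    K[0] = K_init
    clips = 0
    exhausted = 0
    bad_step = -1
    for i in range(n_steps):
        r = rho[i]
        cc = c[i]
        k = K[i]
        if r == 0.0:
            drho = 0.0
        else:
            K_eff = k * (1.0 + cc)
            if K_eff <= 0.0:
                drho = -alpha * r
                exhausted += 1
            else:
                drho = alpha * r * (1.0 - r / K_eff)
        dc = -lam * cc + sigma * xi[i] * r
        dK = -eta * (k - K0_arr[i]) - mu * r
        r_new = r + dt * drho
        c_new = cc + dt * dc
        k_new = k + dt * dK
        if r_new < rho_floor:
            r_new = rho_floor
            clips += 1
        if c_new < 0.0:
            c_new = 0.0
            clips += 1
        if not (
            np.isfinite(r_new) and np.isfinite(c_new) and np.isfinite(k_new)
        ):
            bad_step = i
            break
        rho[i + 1] = r_new
        c[i + 1] = c_new
        K[i + 1] = k_new
    return rho, c, K, clips, exhausted, bad_step


def simulate(
    params: ModelParameters, forcing: ClimateForcing | None = None
) -> Trajectory:
    """Integrate the model for ``params.n_steps`` Euler steps.

    One Weibull innovation is drawn per step from a generator seeded with
    ``params.seed``; with sigma = 0 no draws are made (the xi array is zero)
    so the run is bit-identical for any seed.  ``forcing`` overrides the
    forcing implied by the (K0_star, kappa, omega) parameter fields.
    """
    if forcing is None:
        forcing = params.default_forcing()
    n = params.n_steps
    t = params.dt * np.arange(n + 1)
    K0_t = np.asarray(forcing(t), dtype=float)

    if params.sigma == 0.0:
        xi = np.zeros(n)
    else:
        rng = np.random.default_rng(params.seed)
        xi = draw_innovations(
            rng, params.weibull_shape, params.weibull_scale, n
        )

    rho, c, K, clips, exhausted, bad_step = _integrate(
        float(params.rho0),
        float(params.c0),
        float(params.K_init),
        params.alpha,
        params.lam,
        params.mu,
        params.eta,
        params.sigma,
        params.rho_floor,
        params.dt,
        n,
        xi,
        K0_t,
    )
    if bad_step >= 0:
        raise IntegrationError(
            f"state became non-finite at step {bad_step}", step=bad_step
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        per_capita = np.where(rho > 0.0, K / rho, np.nan)
    return Trajectory(
        t=t,
        rho=rho,
        c=c,
        K=K,
        K0_t=K0_t,
        per_capita=per_capita,
        xi=xi,
        warnings=int(clips),
        exhausted_steps=int(exhausted),
        params=params,
    )


def equilibrium_fixed_point(
    params: ModelParameters,
) -> tuple[float, float, float]:
    """Deterministic fixed point (rho*, K*, c*) for sigma = 0 and constant
    forcing.

    Culture decays to c* = 0; the surviving equilibrium solves rho = K and
    K = K0 - mu*rho/eta simultaneously, giving rho* = K* = K0/(1 + mu/eta).
    """
    if params.sigma != 0.0:
        raise ParameterError(
            "fixed point defined only for the deterministic model (sigma = 0)"
        )
    if params.kappa != 0.0:
        raise ParameterError("fixed point requires constant forcing")
    if params.eta == 0.0 and params.mu > 0.0:
        raise ParameterError(
            "no finite equilibrium: depletion without replenishment"
        )
    ratio = 0.0 if params.mu == 0.0 else params.mu / params.eta
    rho_star = params.K0_star / (1.0 + ratio)
    return rho_star, rho_star, 0.0
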