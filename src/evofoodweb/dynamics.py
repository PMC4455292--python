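"""Trophic dynamics: feeding kernel, rates, functional response, ODE.

The population dynamics is a multi-species bioenergetic consumer-resource
model.  Biomass densities B_i obey

    dB_0/dt = G_0 B_0 - sum_j g_j0 B_j,          G_0 = R (1 - B_0/K)
    dB_i/dt = B_i sum_j e_j g_ij - sum_j g_ji B_j - x_i B_i,

where g_ij is a Beddington-DeAngelis functional response

    g_ij = a_ij B_j / (1 + h_i sum_k a_ik B_k + sum_l c_il B_l),

a_ij = a0 m_i^{p_a} N_ij is the attack rate with a Gaussian kernel N_ij
in log10 prey mass, h_i and x_i are allometric handling time and
respiration, and c_il is interference competition proportional to the
overlap of the feeding kernels of consumers i and l.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .community import Community, DynamicsParams

__all__ = [
    "RateCache",
    "feeding_kernel",
    "attack_rate",
    "kernel_overlap",
    "competition_matrix",
    "build_rate_cache",
    "functional_response",
    "rhs",
    "integrate",
    "IntegrationError",
]

LOG2PI_SQRT = np.sqrt(2.0 * np.pi)


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass
class RateCache:
    """Precomputed rates for a fixed species set.

    attack[i, j]: attack rate of consumer i (row) on prey j (column,
    resource = column 0).  comp[i, l]: interference of consumer l on
    consumer i, with diagonal c_food + c_intra.
    """

    handling: np.ndarray  # (S,)
    respiration: np.ndarray  # (S,)
    attack: np.ndarray  # (S, S+1)
    comp: np.ndarray  # (S, S)
    self_overlap: np.ndarray  # (S,) I_ii
    e: np.ndarray  # (S+1,) assimilation efficiency per prey column
    R: float
    K: float


def feeding_kernel(
    m_prey: float | np.ndarray, f: float | np.ndarray, s: float | np.ndarray
) -> float | np.ndarray:
    """Gaussian attack kernel on the log10 prey-mass axis.

    N(m_prey) = 1/(s sqrt(2 pi)) exp(-(log10(m_prey/f))^2 / (2 s^2)).

    Normalized over log10 prey mass, so a broader feeding range (large s)
    trades off against a lower peak attack rate.  Maximal at
    ``m_prey == f``.
    """
    m_prey, f, s = np.asarray(m_prey, float), np.asarray(f, float), np.asarray(s, float)
    if np.any(m_prey <= 0) or np.any(f <= 0) or np.any(s <= 0):
        raise ValueError("prey mass, feeding centre and width must be positive")
    z = np.log10(m_prey / f)
    out = np.exp(-(z * z) / (2.0 * s * s)) / (s * LOG2PI_SQRT)
    return out if out.ndim else float(out)


def attack_rate(
    m_consumer: float,
    f: float,
    s: float,
    m_prey: float | np.ndarray,
    dyn: DynamicsParams,
) -> float | np.ndarray:
    """Rate of successful attacks, a_ij = a0 m_i^{p_a} N_ij(m_j)."""
    return dyn.a0 * m_consumer**dyn.p_a * feeding_kernel(m_prey, f, s)


def max_attack_rate(m_consumer: float, s: float, dyn: DynamicsParams) -> float:
    """Peak of the attack kernel: the rate on prey exactly at the centre."""
    return dyn.a0 * m_consumer**dyn.p_a / (s * LOG2PI_SQRT)


def kernel_overlap(
    f_i: float | np.ndarray,
    s_i: float | np.ndarray,
    f_l: float | np.ndarray,
    s_l: float | np.ndarray,
) -> float | np.ndarray:
    """Overlap integral I_il of two feeding kernels over log10 prey mass.

    The product of two Gaussians integrates to a Gaussian in the
    centre separation:

        I_il = exp(-(log10 f_i - log10 f_l)^2 / (2 (s_i^2 + s_l^2)))
               / sqrt(2 pi (s_i^2 + s_l^2)),

    symmetric in (i, l), with self-overlap I_ii = 1/(2 s_i sqrt(pi)).
    """
    f_i, f_l = np.asarray(f_i, float), np.asarray(f_l, float)
    s_i, s_l = np.asarray(s_i, float), np.asarray(s_l, float)
    if np.any(f_i <= 0) or np.any(f_l <= 0) or np.any(s_i <= 0) or np.any(s_l <= 0):
        raise ValueError("feeding centres and widths must be positive")
    var = s_i * s_i + s_l * s_l
    d = np.log10(f_i) - np.log10(f_l)
    out = np.exp(-(d * d) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)
    return out if out.ndim else float(out)


def competition_matrix(
    f: np.ndarray, s: np.ndarray, c_food: float, c_intra: float
) -> np.ndarray:
    """Interference competition matrix c_il.

    Off-diagonal entries c_il = c_food * I_il / I_ii, normalised by the
    self-overlap of the focal consumer so that specialists (small s)
    exert a higher pressure than generalists.  Diagonal entries are
    c_food + c_intra.
    """
    f = np.asarray(f, float)
    s = np.asarray(s, float)
    n = len(f)
    I = kernel_overlap(f[:, None], s[:, None], f[None, :], s[None, :])
    I = np.atleast_2d(I)
    I_ii = np.diag(I)
    c = c_food * I / I_ii[:, None]
    np.fill_diagonal(c, c_food + c_intra)
    return c


def build_rate_cache(com: Community, dyn: DynamicsParams) -> RateCache:
    """Assemble all rates for the community's current species set."""
    m = np.array([sp.m for sp in com.species], float)
    f = np.array([sp.f for sp in com.species], float)
    s = np.array([sp.s for sp in com.species], float)
    n = len(m)
    prey_mass = np.concatenate(([com.resource.m0], m))
    if n:
        attack = dyn.a0 * (m**dyn.p_a)[:, None] * feeding_kernel(
            prey_mass[None, :], f[:, None], s[:, None]
        )
        comp = competition_matrix(f, s, dyn.c_food, dyn.c_intra)
        self_ov = 1.0 / (2.0 * s * np.sqrt(np.pi))
    else:
        attack = np.zeros((0, 1))
        comp = np.zeros((0, 0))
        self_ov = np.zeros(0)
    e = np.full(n + 1, dyn.e_animal)
    e[0] = dyn.e_plant
    return RateCache(
        handling=dyn.h0 * m**dyn.q_h,
        respiration=dyn.x0 * m**dyn.q_x,
        attack=attack,
        comp=comp,
        self_overlap=self_ov,
        e=e,
        R=com.resource.R,
        K=com.resource.K,
    )


def functional_response(B: np.ndarray, rates: RateCache) -> np.ndarray:
    """Mass-specific consumption rates g_ij (consumers x prey incl. resource).

    Beddington-DeAngelis: saturating in total available prey via the
    handling time and depressed by interference from all consumers.
    """
    B = np.asarray(B, float)
    if np.any(B < 0):
        raise ValueError("negative biomass in functional response")
    n = rates.attack.shape[0]
    if n == 0:
        return np.zeros((0, 1))
    denom = (
        1.0
        + rates.handling * (rates.attack @ B)
        + rates.comp @ B[1:]
    )
    return rates.attack * B[np.newaxis, :] / denom[:, np.newaxis]


def rhs(t: float, B: np.ndarray, rates: RateCache) -> np.ndarray:
    """Time derivatives of (B_0, B_1, ..., B_S)."""
    B = np.asarray(B, float)
    n = rates.attack.shape[0]
    if len(B) != n + 1:
        raise ValueError(f"state length {len(B)} != 1 + {n} consumers")
    Bc = np.maximum(B, 0.0)  # guard against tiny negative excursions
    g = functional_response(Bc, rates)
    dB = np.empty_like(B)
    G0 = rates.R * (1.0 - Bc[0] / rates.K)
    predation = g.T @ Bc[1:]  # loss of prey j to all consumers, per column j
    dB[0] = G0 * Bc[0] - predation[0]
    if n:
        gain = g @ rates.e  # sum_j e_j g_ij
        dB[1:] = gain * Bc[1:] - predation[1:] - rates.respiration * Bc[1:]
    return dB


def equilibrium_residual(B: np.ndarray, rates: RateCache) -> np.ndarray:
    """Convenience wrapper for root finders: rhs at fixed time 0."""
    return rhs(0.0, B, rates)


def integrate(
    com: Community,
    t_span: tuple[float, float],
    dyn: DynamicsParams | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
    negative_tol: float = 1e-8,
    rates: RateCache | None = None,
    method: str = "LSODA",
):
    """Advance the community over ``t_span`` with adaptive stepping.

    The default method is LSODA (via ``scipy.integrate.solve_ivp``),
    which switches between Adams and BDF: the community spends most of
    its time in a stiff quasi-stationary regime between speciation
    events, where explicit embedded Runge-Kutta pairs are forced into
    tiny steps ("RK45" remains available through ``method``).  Returns
    the ``OdeResult`` with dense output enabled so callers can probe the
    trajectory at integer times for extinction checks; the community is
    updated in place to the state at ``t_span[1]``.

    Negative biomass excursions beyond ``negative_tol`` raise
    :class:`IntegrationError`; small ones are clipped to zero.
    """
    dyn = dyn or DynamicsParams()
    t0, t1 = t_span
    if t1 < t0:
        raise ValueError("t_span must be increasing")
    if rates is None:
        rates = build_rate_cache(com, dyn)
    B0 = com.biomasses()
    if not np.all(np.isfinite(B0)):
        raise ValueError("non-finite state")
    if t1 == t0:
        com.t = t1
        return None
    sol = solve_ivp(
        rhs,
        (t0, t1),
        B0,
        args=(rates,),
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]), sol.y[:, -1])
    B_end = sol.y[:, -1]
    if np.any(B_end < -negative_tol):
        raise IntegrationError(
            f"negative biomass excursion beyond tolerance at t={t1}",
            t1,
            B_end,
        )
    com.set_biomasses(np.maximum(B_end, 0.0))
    com.t = t1
    return sol
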