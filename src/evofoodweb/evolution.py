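"""The outer eco-evolutionary loop.

Speciation events arrive as a Poisson process with rate ``omega``
(mean waiting time 1/omega, so rare that the community is typically close
to a population-dynamical fixed point before the next event).  At each
event a parent is chosen among the extant consumers and a "mutant"
daughter species is seeded at the extinction threshold with traits drawn
from intervals anchored at the parent.  Between events the ODE is
integrated and, at every unit time step, species whose population density
B/m has fallen below the threshold epsilon are removed.  All extinctions
between two consecutive speciation events form one extinction avalanche.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .community import (
    Community,
    DynamicsParams,
    EvolutionParams,
    Event,
    FoodWebSnapshot,
    Species,
    new_ancestor_community,
    snapshot,
)
from . import dynamics

__all__ = [
    "MutationDraw",
    "AvalancheRecord",
    "RunResult",
    "schedule_next_event",
    "choose_parent",
    "draw_mutant",
    "apply_extinctions",
    "run",
]


@dataclass
class MutationDraw:
    """Traits of a newly drawn mutant plus provenance labels."""

    parent_id: int
    m: float
    f: float
    s: float
    B: float
    parent_rule: str
    mass_rule: str


@dataclass
class AvalancheRecord:
    """One extinction avalanche: all removals between two speciation events."""

    t_start: float
    t_end: float
    size: int
    fraction: float  # of the pre-avalanche network size

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("avalanche size must be >= 1")
        if not 0 < self.fraction <= 1:
            raise ValueError("avalanche fraction must be in (0, 1]")


@dataclass
class RunResult:
    """Everything a simulation run produces."""

    community: Community
    snapshots: list[FoodWebSnapshot]
    avalanches: list[AvalancheRecord]
    seed: Optional[int] = None
    global_extinction_time: Optional[float] = None

    @property
    def event_log(self):
        return self.community.event_log


def schedule_next_event(t: float, omega: float, rng: np.random.Generator) -> float:
    """Time of the next speciation event after ``t``.

    The per-unit-time speciation probability omega is read as the rate of
    a Poisson process, so waiting times are exponential with mean
    1/omega.  At omega = 1e-4 this is indistinguishable from a
    per-unit-time Bernoulli trial.  omega = 0 disables speciation (the
    next event is at infinity).
    """
    if not 0 <= omega <= 1:
        raise ValueError("omega must be in [0, 1]")
    if omega == 0:
        return np.inf
    return t + rng.exponential(1.0 / omega)


def choose_parent(
    com: Community, rule: str, rng: np.random.Generator
) -> Species:
    """Pick the parent of the next mutant.

    uniform: every extant species with probability 1/S.
    biomass: probability proportional to B_i.
    generation_time: probability proportional to 1/t_gen with the
    standard allometry t_gen ~ m^0.25, i.e. weight m^-0.25, so that
    mutation rate tracks reproduction rate.
    """
    if not com.species:
        raise ValueError("cannot choose a parent in an empty community")
    if rule == "uniform":
        idx = rng.integers(len(com.species))
    elif rule == "biomass":
        w = np.array([sp.B for sp in com.species], float)
        if w.sum() <= 0:
            raise ValueError("biomass rule needs positive total biomass")
        idx = rng.choice(len(com.species), p=w / w.sum())
    elif rule == "generation_time":
        w = np.array([sp.m for sp in com.species], float) ** -0.25
        idx = rng.choice(len(com.species), p=w / w.sum())
    else:
        raise ValueError(f"unknown parent rule {rule!r}")
    return com.species[idx]


def _truncated_gaussian(
    centre: float, sigma: float, rng: np.random.Generator, n_sigma: float = 2.0
) -> float:
    """Gaussian draw rejected outside centre +/- n_sigma * sigma."""
    while True:
        x = rng.normal(centre, sigma)
        if abs(x - centre) <= n_sigma * sigma:
            return x


def draw_mutant(
    parent: Species, evo: EvolutionParams, rng: np.random.Generator
) -> MutationDraw:
    """Draw the traits of a mutant of ``parent``.

    Default rules: log10 body mass uniform on
    [log10(m_parent / mass_factor_max), log10(m_parent * mass_factor_max)]
    (at most a factor 2 from the parent by default); feeding centre
    0.5 to 3 decades below the mutant's own mass (prey 3 to 1000 times
    smaller); feeding range uniform on [0.5, 1.5].  Variant switches in
    ``evo`` replace individual rules; heredity variants draw f and s from
    truncated Gaussians around the parental values, clipped to the
    default intervals.  The mutant's initial biomass is m * epsilon.
    """
    # body mass
    if evo.mass_rule == "uniform_factor":
        lo = np.log10(parent.m / evo.mass_factor_max)
        hi = np.log10(parent.m * evo.mass_factor_max)
        log_m = rng.uniform(lo, hi)
    elif evo.mass_rule == "gaussian":
        log_m = _truncated_gaussian(np.log10(parent.m), evo.mass_sigma, rng)
    elif evo.mass_rule == "global_uniform":
        log_m = rng.uniform(
            np.log10(evo.global_mass_lo), np.log10(evo.global_mass_hi)
        )
    else:  # pragma: no cover - guarded in EvolutionParams
        raise ValueError(f"unknown mass rule {evo.mass_rule!r}")
    m = 10.0**log_m

    # feeding centre: f_offset decades below the mutant's own mass
    f_lo, f_hi = log_m - evo.f_offset_hi, log_m - evo.f_offset_lo
    if evo.heredity_f is not None:
        log_f = np.clip(
            _truncated_gaussian(np.log10(parent.f), evo.heredity_f, rng),
            f_lo,
            f_hi,
        )
    else:
        log_f = rng.uniform(f_lo, f_hi)
    f = 10.0**log_f

    # feeding range
    if evo.heredity_s is not None:
        s = float(
            np.clip(
                _truncated_gaussian(parent.s, evo.heredity_s, rng),
                evo.s_lo,
                evo.s_hi,
            )
        )
    else:
        s = rng.uniform(evo.s_lo, evo.s_hi)

    return MutationDraw(
        parent_id=parent.id,
        m=m,
        f=f,
        s=s,
        B=m * evo.epsilon,
        parent_rule=evo.parent_rule,
        mass_rule=evo.mass_rule,
    )


def apply_extinctions(com: Community, epsilon: float) -> list[Species]:
    """Remove species whose population density B/m is below the threshold.

    The comparison is strict (B < m * epsilon removes), so mutants seeded
    exactly at the threshold survive the check in which they appear.  The
    resource is never removed.  Removals are logged (the avalanche index
    is attached by the run loop).
    """
    removed = [sp for sp in com.species if sp.B < sp.m * epsilon]
    if removed:
        keep = {sp.id for sp in removed}
        com.species = [sp for sp in com.species if sp.id not in keep]
        for sp in removed:
            com.log_event(Event(t=com.t, species_id=sp.id, kind="extinction"))
    return removed


def _integrate_with_unit_checks(
    com: Community,
    t_end: float,
    dyn: DynamicsParams,
    evo: EvolutionParams,
    rtol: float,
    atol: float,
    eq_tol: float,
) -> list[Species]:
    """Integrate to ``t_end`` checking the extinction threshold at unit times.

    Integrates with dense output, evaluates the trajectory at every
    integer time, and truncates at the first time a species crosses the
    threshold; the species is removed there and integration restarts with
    the reduced community.  When the state is at a fixed point within
    ``eq_tol`` the segment is skipped (biomasses are constant), which is
    the typical case between rare speciation events.

    Returns all species removed within the segment.
    """
    removed_all: list[Species] = []
    while com.t < t_end:
        rates = dynamics.build_rate_cache(com, dyn)
        B = com.biomasses()
        scale = max(B.max(), 1.0)
        if np.max(np.abs(dynamics.rhs(com.t, B, rates))) < eq_tol * scale:
            com.t = t_end  # quasi-stationary: nothing can cross the threshold
            break
        # integer grid strictly inside the segment
        grid = np.arange(np.floor(com.t) + 1.0, t_end)
        sol = dynamics.integrate(
            com, (com.t, t_end), dyn, rtol=rtol, atol=atol, rates=rates
        )
        thresh = np.array([sp.m for sp in com.species]) * evo.epsilon
        t_cross = None
        if len(grid) and com.n_species:
            traj = sol.sol(grid)  # (S+1, T)
            below = traj[1:, :] < thresh[:, None]
            hits = np.nonzero(below.any(axis=0))[0]
            if hits.size:
                t_cross = float(grid[hits[0]])
        if t_cross is None:
            removed_all.extend(apply_extinctions(com, evo.epsilon))
        else:
            com.set_biomasses(np.maximum(sol.sol(t_cross), 0.0))
            com.t = t_cross
            removed_all.extend(apply_extinctions(com, evo.epsilon))
    return removed_all


def run(
    dyn: DynamicsParams | None = None,
    evo: EvolutionParams | None = None,
    t_end: float = 1e6,
    seed: int | np.random.Generator | None = 0,
    snapshot_start: float | None = None,
    snapshot_interval: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    eq_tol: float = 1e-12,
    community: Community | None = None,
) -> RunResult:
    """Run the full eco-evolutionary assembly from the single ancestor.

    Alternates ODE integration segments with stochastic speciation
    events; extinction thresholds are checked at every integer time.
    Snapshots are collected on the grid
    ``snapshot_start, snapshot_start + snapshot_interval, ...`` up to
    ``t_end`` (inclusive); with both set to None, a single snapshot is
    taken at ``t_end``.  Fully reproducible given (parameters, seed).

    If every consumer dies out, speciation becomes impossible (there is
    no parent to mutate); the run then coasts to ``t_end`` with the
    resource alone and the time of global extinction is flagged in the
    result.
    """
    dyn = dyn or DynamicsParams()
    evo = evo or EvolutionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    com = community if community is not None else new_ancestor_community(dyn, evo)
    next_id = max((sp.id for sp in com.species), default=0) + 1

    if snapshot_interval is not None:
        start = snapshot_start if snapshot_start is not None else snapshot_interval
        snap_times = [
            t
            for t in np.arange(start, t_end + snapshot_interval / 2, snapshot_interval)
            if t > com.t
        ]
    else:
        snap_times = [t_end]

    snapshots: list[FoodWebSnapshot] = []
    avalanches: list[AvalancheRecord] = []
    global_extinction_time: Optional[float] = None

    t_next_spec = schedule_next_event(com.t, evo.omega, rng)
    snap_iter = iter(snap_times)
    t_next_snap = next(snap_iter, None)

    # extinctions accumulated since the last speciation event
    pending: list[Species] = []
    pending_t0: Optional[float] = None
    pre_size = com.n_species
    avalanche_idx = 0

    def flush_avalanche(t_now: float) -> None:
        nonlocal pending, pending_t0, avalanche_idx
        if pending:
            avalanches.append(
                AvalancheRecord(
                    t_start=pending_t0,
                    t_end=t_now,
                    size=len(pending),
                    fraction=len(pending) / max(pre_size, 1),
                )
            )
            need = len(pending)
            for ev in reversed(com.event_log):
                if need == 0:
                    break
                if ev.kind == "extinction" and ev.avalanche is None:
                    ev.avalanche = avalanche_idx
                    need -= 1
            avalanche_idx += 1
        pending = []
        pending_t0 = None

    while com.t < t_end:
        stop = min(t_end, t_next_spec)
        if t_next_snap is not None:
            stop = min(stop, t_next_snap)

        removed = _integrate_with_unit_checks(com, stop, dyn, evo, rtol, atol, eq_tol)
        if removed:
            if not pending:
                pending_t0 = com.t
            pending.extend(removed)
        if com.n_species == 0 and global_extinction_time is None:
            global_extinction_time = com.t

        if t_next_snap is not None and com.t >= t_next_snap:
            snapshots.append(snapshot(com, dyn))
            t_next_snap = next(snap_iter, None)

        if com.t >= t_next_spec and com.t < t_end:
            flush_avalanche(com.t)
            if com.species:
                parent = choose_parent(com, evo.parent_rule, rng)
                draw = draw_mutant(parent, evo, rng)
                parent.B = max(parent.B - draw.B, 0.0)
                com.species.append(
                    Species(
                        id=next_id,
                        m=draw.m,
                        f=draw.f,
                        s=draw.s,
                        B=draw.B,
                        parent_id=draw.parent_id,
                        t_birth=com.t,
                    )
                )
                com.log_event(Event(t=com.t, species_id=next_id, kind="speciation"))
                next_id += 1
                pre_size = com.n_species
            t_next_spec = schedule_next_event(com.t, evo.omega, rng)

    flush_avalanche(com.t)
    return RunResult(
        community=com,
        snapshots=snapshots,
        avalanches=avalanches,
        seed=seed if isinstance(seed, int) else None,
        global_extinction_time=global_extinction_time,
    )
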