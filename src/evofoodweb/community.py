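"""Core domain types for the evolving community.

A community consists of a single external resource (index 0 in all
matrices) and a set of consumer species, each characterised by three
traits: body mass ``m``, feeding centre ``f`` (the prey mass at which its
attack rate peaks), and feeding range ``s`` (the standard deviation of its
Gaussian attack kernel on the log10 prey-mass axis).  All masses and
times are dimensionless model units; the resource has body mass 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "Resource",
    "DynamicsParams",
    "EvolutionParams",
    "Community",
    "FoodWebSnapshot",
    "Event",
    "new_ancestor_community",
    "snapshot",
]


@dataclass
class Species:
    """One consumer population.

    Parameters
    ----------
    id : int
        Global lineage identifier; never reused within a run.
    m : float
        Body mass (> 0).
    f : float
        Centre of the feeding range: the prey body mass at which the
        attack-rate kernel is maximal (> 0).
    s : float
        Width of the feeding range: standard deviation of the kernel on
        the log10 prey-mass axis.
    B : float
        Biomass density (>= 0 whenever exposed outside the integrator).
    parent_id : int or None
        Lineage parent; ``None`` for the ancestor.
    t_birth : float
        Simulation time at which the species entered the community.
    """

    id: int
    m: float
    f: float
    s: float
    B: float
    parent_id: Optional[int] = None
    t_birth: float = 0.0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.f <= 0 or self.s <= 0:
            raise ValueError(
                f"species {self.id}: traits must be positive "
                f"(m={self.m}, f={self.f}, s={self.s})"
            )
        if self.B < 0:
            raise ValueError(f"species {self.id}: negative biomass {self.B}")


@dataclass
class Resource:
    """The external basal resource (body mass fixed at 1).

    It grows logistically with maximum mass-specific rate ``R`` towards
    carrying capacity ``K`` and is never mutated or removed.
    """

    m0: float = 1.0
    R: float = 1.0
    K: float = 100.0
    B0: float = 100.0


@dataclass
class DynamicsParams:
    """Bioenergetic rate constants.

    Attack rate, handling time and respiration follow standard allometric
    scaling: ``a_i = a0 * m_i**p_a``, ``h_i = h0 * m_i**q_h``,
    ``x_i = x0 * m_i**q_x`` with the usual quarter-power exponents.
    Assimilation efficiency is 0.85 for animal prey and 0.45 for the
    (plant-like) resource.  ``c_food`` scales interference between
    consumers by the overlap of their feeding kernels; ``c_intra`` is the
    extra within-species interference, giving the diagonal
    ``c_ii = c_food + c_intra``.
    """

    e_animal: float = 0.85
    e_plant: float = 0.45
    a0: float = 1.0
    p_a: float = -0.25
    h0: float = 0.4
    q_h: float = 0.25
    x0: float = 0.314
    q_x: float = -0.25
    c_food: float = 0.8
    c_intra: float = 1.4

    def __post_init__(self) -> None:
        for name in ("a0", "h0", "x0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("e_animal", "e_plant"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class EvolutionParams:
    """Parameters of the speciation/extinction layer.

    ``omega`` is the speciation probability per unit time; ``epsilon``
    the extinction threshold on population density ``B/m``.  New species
    ("mutants") draw body mass within a factor ``mass_factor_max`` of the
    parent, feeding centre between ``f_offset_lo`` and ``f_offset_hi``
    decades below their own mass, and feeding range uniformly on
    ``[s_lo, s_hi]``.  The ``*_rule`` switches select robustness variants
    of the mutation scheme.
    """

    omega: float = 1e-4
    epsilon: float = 2e-4
    mass_factor_max: float = 2.0
    f_offset_lo: float = 0.5
    f_offset_hi: float = 3.0
    s_lo: float = 0.5
    s_hi: float = 1.5
    parent_rule: str = "uniform"  # uniform | biomass | generation_time
    mass_rule: str = "uniform_factor"  # uniform_factor | gaussian | global_uniform
    mass_sigma: float = 0.3  # log10 SD for the gaussian mass rule
    global_mass_lo: float = 10 ** -0.5
    global_mass_hi: float = 1e6
    heredity_f: Optional[float] = None  # log10 SD of Gaussian around parent f
    heredity_s: Optional[float] = None  # SD of Gaussian around parent s

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.f_offset_lo > self.f_offset_hi:
            raise ValueError("f_offset interval bounds out of order")
        if self.s_lo > self.s_hi:
            raise ValueError("s interval bounds out of order")
        if self.parent_rule not in ("uniform", "biomass", "generation_time"):
            raise ValueError(f"unknown parent_rule {self.parent_rule!r}")
        if self.mass_rule not in ("uniform_factor", "gaussian", "global_uniform"):
            raise ValueError(f"unknown mass_rule {self.mass_rule!r}")


@dataclass
class Event:
    """One entry of the community event log."""

    t: float
    species_id: int
    kind: str  # "speciation" | "extinction"
    avalanche: Optional[int] = None  # index of the extinction avalanche


@dataclass
class Community:
    """The full dynamical state: resource + extant consumers + event log."""

    t: float = 0.0
    resource: Resource = field(default_factory=Resource)
    species: list[Species] = field(default_factory=list)
    event_log: list[Event] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def biomasses(self) -> np.ndarray:
        """State vector (B_0, B_1, ..., B_S), resource first."""
        return np.array(
            [self.resource.B0] + [sp.B for sp in self.species], dtype=float
        )

    def set_biomasses(self, B: np.ndarray) -> None:
        if len(B) != self.n_species + 1:
            raise ValueError(
                f"state vector length {len(B)} != 1 + {self.n_species} species"
            )
        self.resource.B0 = float(B[0])
        for sp, b in zip(self.species, B[1:]):
            sp.B = float(b)

    def log_event(self, ev: Event) -> None:
        if self.event_log and ev.t < self.event_log[-1].t:
            raise ValueError("event log times must be non-decreasing")
        self.event_log.append(ev)

    def node_table(self) -> pd.DataFrame:
        """Traits and biomasses of all extant consumers (resource excluded)."""
        return pd.DataFrame(
            {
                "id": [sp.id for sp in self.species],
                "m": [sp.m for sp in self.species],
                "f": [sp.f for sp in self.species],
                "s": [sp.s for sp in self.species],
                "B": [sp.B for sp in self.species],
            }
        )

    def species_count_series(self) -> pd.DataFrame:
        """Replay the event log into S(t): extant species count after each event.

        Starts from one ancestor at t = 0 (the ancestor's own speciation
        event is in the log), so a cumulative sum over event signs
        reconstructs the count at any time.
        """
        times, counts = [], []
        n = 0
        for ev in self.event_log:
            n += 1 if ev.kind == "speciation" else -1
            times.append(ev.t)
            counts.append(n)
        return pd.DataFrame({"t": times, "S": counts})


@dataclass
class FoodWebSnapshot:
    """A time-stamped community with realized attack rates and flows.

    ``attack`` and ``flow`` have one row per consumer and one column per
    potential prey, the resource being column 0.  ``flow[i, j]`` is the
    mass-specific consumption rate g_ij evaluated at the sampled state.
    """

    t: float
    nodes: pd.DataFrame  # columns id, m, f, s, B (consumers only)
    resource_B: float
    attack: np.ndarray  # (S, S+1)
    flow: np.ndarray  # (S, S+1)
    e_plant: float = 0.45
    e_animal: float = 0.85

    @property
    def n_consumers(self) -> int:
        return len(self.nodes)

    def contributions(self) -> np.ndarray:
        """Assimilated intake w_ij = e_j * g_ij per consumer/prey pair."""
        e = np.full(self.n_consumers + 1, self.e_animal)
        e[0] = self.e_plant
        return self.flow * e[np.newaxis, :]

    def to_json(self) -> str:
        payload = {
            "t": self.t,
            "resource_B": self.resource_B,
            "e_plant": self.e_plant,
            "e_animal": self.e_animal,
            "nodes": self.nodes.to_dict(orient="list"),
            "attack": self.attack.tolist(),
            "flow": self.flow.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FoodWebSnapshot":
        d = json.loads(text)
        nodes = pd.DataFrame(d["nodes"], columns=["id", "m", "f", "s", "B"])
        return cls(
            t=d["t"],
            nodes=nodes,
            resource_B=d["resource_B"],
            attack=np.asarray(d["attack"], dtype=float).reshape(len(nodes), -1)
            if len(nodes)
            else np.zeros((0, 1)),
            flow=np.asarray(d["flow"], dtype=float).reshape(len(nodes), -1)
            if len(nodes)
            else np.zeros((0, 1)),
            e_plant=d.get("e_plant", 0.45),
            e_animal=d.get("e_animal", 0.85),
        )


def new_ancestor_community(
    dyn: DynamicsParams | None = None, evo: EvolutionParams | None = None
) -> Community:
    """Initial state: resource at carrying capacity plus one ancestor.

    The ancestor has body mass 100 and feeds on the resource at the peak
    of its kernel (f = 1, s = 1).  Its biomass is seeded exactly at the
    extinction threshold, B = m * epsilon.
    """
    evo = evo or EvolutionParams()
    res = Resource()
    res.B0 = res.K
    anc = Species(id=1, m=100.0, f=1.0, s=1.0, B=100.0 * evo.epsilon)
    com = Community(t=0.0, resource=res, species=[anc])
    com.log_event(Event(t=0.0, species_id=1, kind="speciation"))
    return com


def snapshot(com: Community, dyn: DynamicsParams | None = None) -> FoodWebSnapshot:
    """Freeze the community into a snapshot with attack and flow matrices.

    Deterministic for a fixed state: the matrices are pure functions of
    traits and biomasses.
    """
    from . import dynamics  # local import to avoid a cycle

    dyn = dyn or DynamicsParams()
    rates = dynamics.build_rate_cache(com, dyn)
    B = com.biomasses()
    if not np.all(np.isfinite(B)):
        raise ValueError("community state is not finite")
    flow = dynamics.functional_response(B, rates)
    return FoodWebSnapshot(
        t=com.t,
        nodes=com.node_table(),
        resource_B=com.resource.B0,
        attack=rates.attack.copy(),
        flow=flow,
        e_plant=dyn.e_plant,
        e_animal=dyn.e_animal,
    )
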