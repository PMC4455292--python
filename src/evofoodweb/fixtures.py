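"""Deterministic toy communities for tests and examples.

These fixtures make every analysis operation testable without running
long assembly simulations.
"""

from __future__ import annotations

import numpy as np

from .community import Community, Resource, Species

__all__ = ["four_species_community", "random_community", "FOUR_SPECIES_TRAITS"]

# Four-node illustration: two resource consumers of differing body mass
# and one large predator whose kernel covers both, with the higher attack
# rate on the heavier one.  Biomasses are chosen so that the
# 75%-of-average cutoff recovers exactly the edges
# 1->0, 2->0, 3->1, 3->2.
FOUR_SPECIES_TRAITS = {
    "resource_B": 40.0,
    "species": [
        # (id, m, f, s, B)
        (1, 10.0, 1.0, 0.5, 10.0),
        (2, 100.0, 1.0, 0.5, 10.0),
        (3, 10000.0, 100.0, 1.0, 1.0),
    ],
}


def four_species_community() -> Community:
    """Resource plus three consumers forming the canonical toy web.

    Species 1 and 2 are specialist consumers of the external resource
    (feeding centre at the resource mass); species 3 is a predator whose
    feeding centre sits at species 2's body mass, so it attacks species 2
    with a high rate and species 1 with a lower (but positive) one.
    """
    res = Resource()
    res.B0 = FOUR_SPECIES_TRAITS["resource_B"]
    species = [
        Species(id=i, m=m, f=f, s=s, B=B) for i, m, f, s, B in FOUR_SPECIES_TRAITS["species"]
    ]
    return Community(t=0.0, resource=res, species=species)


def random_community(n_species: int, seed: int = 0) -> Community:
    """A seeded random community with traits from the default mutation rules.

    Body masses are log-uniform on [10**0.5, 10**4]; the feeding centre
    sits 0.5 to 3 decades below the species' own mass and the feeding
    range is uniform on [0.5, 1.5].  Biomasses are set to 10 * m * epsilon
    (ten times the extinction threshold) so every species starts viable.
    Deterministic per seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    epsilon = 2e-4
    species = []
    for i in range(1, n_species + 1):
        log_m = rng.uniform(0.5, 4.0)
        log_f = log_m - rng.uniform(0.5, 3.0)
        s = rng.uniform(0.5, 1.5)
        m = 10.0**log_m
        species.append(
            Species(id=i, m=m, f=10.0**log_f, s=s, B=10.0 * m * epsilon)
        )
    res = Resource()
    res.B0 = res.K
    return Community(t=0.0, resource=res, species=species)
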