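"""Particle species registry.

The registry holds exactly the eight nuclides the fluence/LET scorers
track: the three possible primaries (H-1, He-4, C-12) and the nuclear
fragments H-1, He-4, Li-7, Be-9, B-10, N-14, O-16.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import AMU_MEV


@dataclass(frozen=True)
class ParticleSpecies:
    """A nuclide characterised by charge and mass number.

    ``mass_per_nucleon`` defaults to the atomic mass unit so that ions at
    equal kinetic energy per nucleon have identical velocity.
    """

    name: str
    Z: int
    A: int
    mass_per_nucleon: float = AMU_MEV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"{self.name}: Z must be >= 1, got {self.Z}")
        if self.A < self.Z:
            raise ValueError(f"{self.name}: A must be >= Z, got A={self.A}, Z={self.Z}")


SPECIES_REGISTRY: dict[str, ParticleSpecies] = {
    s.name: s
    for s in (
        ParticleSpecies("H-1", 1, 1),
        ParticleSpecies("He-4", 2, 4),
        ParticleSpecies("Li-7", 3, 7),
        ParticleSpecies("Be-9", 4, 9),
        ParticleSpecies("B-10", 5, 10),
        ParticleSpecies("C-12", 6, 12),
        ParticleSpecies("N-14", 7, 14),
        ParticleSpecies("O-16", 8, 16),
    )
}


def get_species(name: str) -> ParticleSpecies:
    """Look up a species by name; raises ``KeyError`` with the known names."""
    try:
        return SPECIES_REGISTRY[name]
    except KeyError:
        known = ", ".join(SPECIES_REGISTRY)
        raise KeyError(f"unknown species {name!r}; known species: {known}") from None
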