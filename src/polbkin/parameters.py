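"""Core parameter and condition containers for the six-state polymerase mechanism.

The mechanism is a sequential chain describing single-nucleotide incorporation
by a DNA polymerase:

    E·DNA + dNTP  ⇌  E(o)·DNA·dNTP  ⇌  E(c)·DNA·dNTP  ⇌  E(c*)·DNA·dNTP
                                      (fingers closing)        (NCS)
                  →  E(c*)·DNA+1  ⇌  E(o)·DNA+1
                    (chemistry)     (reopening)

Internal units are fixed: concentrations in μM, time in s, first-order rate
constants in s⁻¹, bimolecular constants in μM⁻¹·s⁻¹.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

#: Ordered species of the mechanism. The first six carry one enzyme each;
#: the last is the free nucleotide pool (μM).
SPECIES = ("E_DNA", "EO", "EC", "ECS", "ECP", "EOP", "dNTP")

#: Enzyme-containing species (their total is conserved).
ENZYME_SPECIES = SPECIES[:6]

#: Species in the fluorescently "open" conformation (unquenched AEDANS) and
#: the "closed" conformation (donor quenched by the DNA-borne acceptor).
OPEN_SPECIES = ("E_DNA", "EO", "EOP")
CLOSED_SPECIES = ("EC", "ECS", "ECP")

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the six-state mechanism for one enzyme/sequence condition.

    Parameters
    ----------
    KD_dNTP : float
        Dissociation constant of the nucleotide from the open ternary
        complex, μM. The dissociation rate is ``kon_dNTP * KD_dNTP``.
    kon_dNTP : float
        Bimolecular association rate of the nucleotide, μM⁻¹·s⁻¹. A
        convention parameter (near-diffusion-limited by default); only the
        ratio koff/kon = K_D is constrained by equilibrium data.
    k2f, k2r : float
        Fingers closing and reopening, s⁻¹.
    k3f, k3r : float
        Forward and reverse non-covalent step (NCS), s⁻¹.
    k4f : float
        Phosphodiester bond formation (chemistry), s⁻¹.
    k4r : float
        Pyrophosphorolysis, s⁻¹. Negligible under single-turnover
        conditions and fixed to zero unless explicitly overridden.
    k5f : float
        Post-chemistry reopening, s⁻¹.
    k5r : float
        Bimolecular reverse of the reopening step, μM⁻¹·s⁻¹. Its partner
        pool is empty by default so the reverse flux is zero.
    """

    KD_dNTP: float = 10.0
    kon_dNTP: float = 100.0
    k2f: float = 0.0
    k2r: float = 0.0
    k3f: float = 0.0
    k3r: float = 0.0
    k4f: float = 0.0
    k4r: float = 0.0
    k5f: float = 0.0
    k5r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k2f", "k2r", "k3f", "k3r", "k4f", "k4r", "k5f", "k5r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.KD_dNTP > 0:
            raise ValueError(f"KD_dNTP must be > 0, got {self.KD_dNTP}")
        if not self.kon_dNTP > 0:
            raise ValueError(f"kon_dNTP must be > 0, got {self.kon_dNTP}")

    @property
    def koff_dNTP(self) -> float:
        """Nucleotide dissociation rate from the open ternary complex, s⁻¹."""
        return self.kon_dNTP * self.KD_dNTP

    def replace(self, **changes) -> "RateParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateParameters":
        return cls(**dict(d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RateParameters":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "RateParameters":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class AssayConditions:
    """Mixing conditions of one transient-kinetics experiment.

    Concentrations in μM. The pre-formed binary complex is the limiting
    concentration min(enzyme_total, dna_total); surplus of either partner is
    kinetically silent here. ``chemistry_blocked`` marks a dideoxy-terminated
    primer, which forces k4f to zero during simulation.
    """

    enzyme_total: float = 0.4
    dna_total: float = 0.2
    dntp_0: float = 100.0
    temperature: float = 37.0  # °C, metadata only
    chemistry_blocked: bool = False

    def __post_init__(self) -> None:
        for name in ("enzyme_total", "dna_total", "dntp_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def complex_total(self) -> float:
        """Limiting binary-complex concentration, μM."""
        return min(self.enzyme_total, self.dna_total)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssayConditions":
        return cls(**dict(d))
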