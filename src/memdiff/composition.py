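"""Chemical-formula and electron bookkeeping for membrane components.

Absolute scaling of lamellar electron-density profiles requires the total
number of electrons in one lipid "unit cell" (a lipid molecule plus its
share of additives and hydration water).  This module provides exact
electron counts from chemical formulas, peptide formulas from one-letter
sequences by condensation arithmetic, and the per-lipid electron budget
of a mixed-composition leaflet.

Electron counts are sums of atomic numbers and therefore exact integers;
molar masses use standard IUPAC atomic weights rounded to three decimals.
Peptides are treated as neutral with free N/C termini; no protonation
states, isotopes, or post-translational modifications are modelled.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ChemicalFormula",
    "MolecularSpecies",
    "MembraneComposition",
    "electrons_of_formula",
    "molar_mass_of_formula",
    "parse_formula",
    "peptide_formula",
    "leaflet_electron_budget",
    "SPECIES_REGISTRY",
    "registry_species",
    "PrintedValueWarning",
]

# element symbol -> (atomic number, standard atomic weight / g mol^-1)
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "F": (9, 18.998),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "P": (15, 30.974),
    "S": (16, 32.060),
    "Cl": (17, 35.450),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
    "Zn": (30, 65.380),
}

ELECTRON_DENSITY_WATER = 0.333  # e/Å^3, bulk water reference
ELECTRONS_PER_WATER = 10


class PrintedValueWarning(UserWarning):
    """A published tabulated value disagrees with formula arithmetic."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Multiset of elements, e.g. ``ChemicalFormula({"H": 2, "O": 1})``."""

    element_counts: dict[str, int]

    def __post_init__(self):
        if not self.element_counts:
            raise ValueError("formula must contain at least one element")
        for sym, n in self.element_counts.items():
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise ValueError(f"count for {sym} must be a positive integer, got {n!r}")

    def merge(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ChemicalFormula(counts)

    def subtract(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise ValueError(f"subtraction would make {sym} count negative")
            if new == 0:
                del counts[sym]
            else:
                counts[sym] = new
        return ChemicalFormula(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        syms = sorted(self.element_counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(f"{s}{self.element_counts[s] if self.element_counts[s] > 1 else ''}"
                       for s in syms)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style formula string like ``"C27H46O"``."""
    if not text or not text.strip():
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    s = text.strip()
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        sym = m.group(1)
        if sym not in ELEMENTS:
            raise ValueError(f"unknown element symbol: {sym!r}")
        counts[sym] = counts.get(sym, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    return ChemicalFormula(counts)


def electrons_of_formula(formula: ChemicalFormula | str) -> int:
    """Total electron count: Σ atomic number × count (exact integer)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ELEMENTS[s][0] * n for s, n in formula.element_counts.items())


def molar_mass_of_formula(formula: ChemicalFormula | str) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ELEMENTS[s][1] * n for s, n in formula.element_counts.items())


@dataclass(frozen=True)
class MolecularSpecies:
    """A named molecule with its formula-derived electron count and mass.

    ``tabulated_electrons`` / ``tabulated_mass`` hold published bookkeeping
    values where a source table is the contract; they may legitimately
    disagree with formula arithmetic (see :func:`registry_species`).
    """

    name: str
    formula: ChemicalFormula
    electrons: int = field(default=0)
    molar_mass: float = field(default=0.0)
    tabulated_electrons: int | None = None
    tabulated_mass: float | None = None

    def __post_init__(self):
        derived_e = electrons_of_formula(self.formula)
        derived_m = molar_mass_of_formula(self.formula)
        if self.electrons == 0:
            object.__setattr__(self, "electrons", derived_e)
        elif self.electrons != derived_e:
            raise ValueError(
                f"{self.name}: electrons {self.electrons} != formula-derived {derived_e}"
            )
        if self.molar_mass == 0.0:
            object.__setattr__(self, "molar_mass", derived_m)
        if self.electrons <= 0 or self.molar_mass <= 0:
            raise ValueError("electrons and molar mass must be positive")

    @property
    def bookkeeping_electrons(self) -> int:
        """Electron count used in published budget arithmetic.

        Returns the tabulated value when one is registered, warning if it
        disagrees with the formula-derived count; otherwise the derived
        count.
        """
        if self.tabulated_electrons is not None:
            if self.tabulated_electrons != self.electrons:
                warnings.warn(
                    f"{self.name}: tabulated electron count "
                    f"{self.tabulated_electrons} disagrees with formula-derived "
                    f"{self.electrons}; using tabulated value",
                    PrintedValueWarning,
                    stacklevel=2,
                )
            return self.tabulated_electrons
        return self.electrons


# ---------------------------------------------------------------------------
# peptide condensation arithmetic

# free (zwitterion-neutral) amino-acid formulas, one-letter codes
AMINO_ACID_FORMULAS: dict[str, str] = {
    "A": "C3H7NO2",
    "R": "C6H14N4O2",
    "N": "C4H8N2O3",
    "D": "C4H7NO4",
    "C": "C3H7NO2S",
    "E": "C5H9NO4",
    "Q": "C5H10N2O3",
    "G": "C2H5NO2",
    "H": "C6H9N3O2",
    "I": "C6H13NO2",
    "L": "C6H13NO2",
    "K": "C6H14N2O2",
    "M": "C5H11NO2S",
    "F": "C9H11NO2",
    "P": "C5H9NO2",
    "S": "C3H7NO3",
    "T": "C4H9NO3",
    "W": "C11H12N2O2",
    "Y": "C9H11NO3",
    "V": "C5H11NO2",
}

WATER = parse_formula("H2O")


def peptide_formula(sequence: str) -> ChemicalFormula:
    """Neutral-peptide formula from a one-letter sequence.

    Condensation arithmetic: the sum of the free amino-acid formulas minus
    (n − 1) waters, i.e. unmodified free N and C termini.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total: ChemicalFormula | None = None
    for i, letter in enumerate(sequence):
        if letter not in AMINO_ACID_FORMULAS:
            raise ValueError(
                f"invalid amino-acid letter {letter!r} at position {i + 1}"
            )
        res = parse_formula(AMINO_ACID_FORMULAS[letter])
        total = res if total is None else total.merge(res)
    for _ in range(len(sequence) - 1):
        total = total.subtract(WATER)
    return total


# ---------------------------------------------------------------------------
# membrane composition and the per-lipid electron budget


@dataclass(frozen=True)
class MembraneComposition:
    """Molecular composition of one leaflet unit cell.

    ``lipid_fractions`` are mole fractions (must sum to 1);  ``additives``
    are per-lipid mole ratios (e.g. 0.03 peptide per lipid); hydration is
    ``waters_per_lipid``.  ``area_per_lipid`` (Å²) and ``lamellar_spacing``
    (Å) carry the geometry needed to convert electron budgets into
    densities.
    """

    lipid_fractions: tuple[tuple[MolecularSpecies, float], ...]
    additives: tuple[tuple[MolecularSpecies, float], ...] = ()
    waters_per_lipid: float = 0.0
    area_per_lipid: float = 60.6
    lamellar_spacing: float = 55.0

    def __post_init__(self):
        if not self.lipid_fractions:
            raise ValueError("composition needs at least one lipid species")
        tot = sum(f for _, f in self.lipid_fractions)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"lipid mole fractions sum to {tot}, expected 1")
        if self.waters_per_lipid < 0:
            raise ValueError("waters_per_lipid must be non-negative")
        if self.area_per_lipid <= 0 or self.lamellar_spacing <= 0:
            raise ValueError("area_per_lipid and lamellar_spacing must be positive")


def leaflet_electron_budget(
    composition: MembraneComposition, use_tabulated: bool = True
) -> float:
    """Electrons per lipid unit cell in one leaflet.

    Σ_lipids fraction·e + Σ_additives ratio·e + waters_per_lipid·10.
    With ``use_tabulated`` (default) species carrying published tabulated
    electron counts contribute those values, reproducing published budget
    arithmetic; otherwise strictly formula-derived counts are used.
    """
    def e_of(sp: MolecularSpecies) -> float:
        return sp.bookkeeping_electrons if use_tabulated else sp.electrons

    budget = sum(frac * e_of(sp) for sp, frac in composition.lipid_fractions)
    budget += sum(ratio * e_of(sp) for sp, ratio in composition.additives)
    budget += composition.waters_per_lipid * ELECTRONS_PER_WATER
    return budget


# ---------------------------------------------------------------------------
# built-in species registry

ABETA_25_35_SEQUENCE = "GSNKGAIIGLM"
ABETA_1_42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"


def _registry() -> dict[str, MolecularSpecies]:
    reg = {
        "DMPC": MolecularSpecies(
            "DMPC", parse_formula("C36H72NO8P"),
            tabulated_electrons=374, tabulated_mass=677.9,
        ),
        # free acid (372 e-, the count entering the published per-lipid
        # budget); the published 701.8 g/mol is the sodium salt's mass
        "DMPS": MolecularSpecies(
            "DMPS", parse_formula("C34H66NO10P"),
            tabulated_electrons=372, tabulated_mass=701.8,
        ),
        "cholesterol": MolecularSpecies(
            "cholesterol", parse_formula("C27H46O"),
            tabulated_electrons=216, tabulated_mass=384.7,
        ),
        "melatonin": MolecularSpecies(
            "melatonin", parse_formula("C13H16N2O2"),
            tabulated_electrons=124, tabulated_mass=232.3,
        ),
        "water": MolecularSpecies(
            "water", WATER, tabulated_electrons=10, tabulated_mass=18.0,
        ),
        "abeta42": MolecularSpecies(
            "abeta42", peptide_formula(ABETA_1_42_SEQUENCE),
            tabulated_electrons=2410, tabulated_mass=4514.1,
        ),
        # published table prints 678 e- for the 25-35 fragment; its printed
        # mass (1060.3) matches C45H81N13O14S, which has 570 electrons.
        # Formula-derived 570 is the default; requesting the tabulated value
        # raises PrintedValueWarning.
        "abeta25_35": MolecularSpecies(
            "abeta25_35", peptide_formula(ABETA_25_35_SEQUENCE),
            tabulated_electrons=678, tabulated_mass=1060.3,
        ),
    }
    return reg


SPECIES_REGISTRY: dict[str, MolecularSpecies] = _registry()


def registry_species(name: str) -> MolecularSpecies:
    """Look up a built-in species by name (case-insensitive)."""
    key = name.strip()
    for cand in (key, key.upper(), key.lower()):
        if cand in SPECIES_REGISTRY:
            return SPECIES_REGISTRY[cand]
    raise KeyError(f"unknown species {name!r}; known: {sorted(SPECIES_REGISTRY)}")
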