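"""Peptide mass and fragment arithmetic for tryptic LC-MS work.

Monoisotopic residue masses, precursor m/z, in-silico trypsin digestion,
b/y fragment ladders and ppm comparison. All masses are monoisotopic
(appropriate for high-resolution QTOF data); the neutral peptide mass is

    M = sum(residue masses) + water + sum(modification deltas)

and a z-protonated precursor appears at m/z = (M + z * m_proton) / z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

__all__ = [
    "WATER",
    "PROTON",
    "ResidueTable",
    "Modification",
    "OXIDATION",
    "DEAMIDATION",
    "BUILTIN_MODIFICATIONS",
    "PeptideSequence",
    "FragmentIon",
    "monoisotopic_mass",
    "precursor_mz",
    "ppm_error",
    "tryptic_digest",
    "fragment_ladder",
    "modification_hypotheses",
    "read_fasta_proteins",
]

#: Monoisotopic mass of H2O in Da.
WATER = 18.010565
#: Monoisotopic mass of a proton in Da.
PROTON = 1.0072765

# Monoisotopic residue (i.e. dehydrated amino-acid) masses, Da.
_STANDARD_RESIDUES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}


class UnknownResidueError(ValueError):
    """A sequence contains a symbol with no entry in the residue table."""

    def __init__(self, symbol: str, sequence: str = ""):
        self.symbol = symbol
        msg = f"unknown residue symbol {symbol!r}"
        if sequence:
            msg += f" in sequence {sequence!r}"
        super().__init__(msg)


@dataclass(frozen=True)
class ResidueTable:
    """Immutable monoisotopic residue-mass table plus the water/proton constants."""

    masses: Mapping[str, float] = field(default_factory=lambda: dict(_STANDARD_RESIDUES))
    water: float = WATER
    proton: float = PROTON

    def __post_init__(self) -> None:
        for sym, m in self.masses.items():
            if not (m > 0):
                raise ValueError(f"residue mass for {sym!r} must be positive, got {m}")
        # freeze the mapping so the table is immutable after construction
        object.__setattr__(self, "masses", dict(self.masses))

    def mass(self, symbol: str, sequence: str = "") -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise UnknownResidueError(symbol, sequence) from None

    def validate(self, sequence: str) -> None:
        for sym in sequence:
            if sym not in self.masses:
                raise UnknownResidueError(sym, sequence)

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "ResidueTable":
        """Load a table from plain text: one ``SYMBOL MASS`` pair per line.

        Lines starting with ``#`` are comments; optional ``water``/``proton``
        lines override the constants.
        """
        masses: dict[str, float] = {}
        water, proton = WATER, PROTON
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = line.split()
            if key.lower() == "water":
                water = float(value)
            elif key.lower() == "proton":
                proton = float(value)
            else:
                masses[key] = float(value)
        return cls(masses=masses, water=water, proton=proton)


DEFAULT_TABLE = ResidueTable()


@dataclass(frozen=True)
class Modification:
    """A fixed-list post-translational/artefactual modification.

    Only the mass delta and residue compatibility matter here; site
    localisation is never inferred beyond residue eligibility.
    """

    name: str
    delta: float
    residues: frozenset[str]
    max_per_peptide: int = 1

    def __post_init__(self) -> None:
        if not (self.delta == self.delta and abs(self.delta) != float("inf")):
            raise ValueError(f"modification delta must be finite, got {self.delta}")


OXIDATION = Modification("oxidation", 15.994915, frozenset("MW"))
DEAMIDATION = Modification("deamidation", 0.984016, frozenset("NQ"))

BUILTIN_MODIFICATIONS: dict[str, Modification] = {
    OXIDATION.name: OXIDATION,
    DEAMIDATION.name: DEAMIDATION,
}


@dataclass(frozen=True)
class PeptideSequence:
    """A residue string with explicit per-position modifications."""

    residues: str
    modifications: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        DEFAULT_TABLE.validate(self.residues)
        counts: dict[str, int] = {}
        for pos, mod in self.modifications:
            if not (0 <= pos < len(self.residues)):
                raise ValueError(
                    f"modification position {pos} outside peptide {self.residues!r}"
                )
            if self.residues[pos] not in mod.residues:
                raise ValueError(
                    f"{mod.name} not allowed on residue "
                    f"{self.residues[pos]!r} at position {pos}"
                )
            counts[mod.name] = counts.get(mod.name, 0) + 1
            if counts[mod.name] > mod.max_per_peptide:
                raise ValueError(f"more than {mod.max_per_peptide} {mod.name} on peptide")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def delta_at(self, position: int) -> float:
        return sum(m.delta for p, m in self.modifications if p == position)


Peptide = Union[str, PeptideSequence]


def _as_peptide(peptide: Peptide) -> PeptideSequence:
    if isinstance(peptide, PeptideSequence):
        return peptide
    return PeptideSequence(peptide)


@dataclass(frozen=True)
class FragmentIon:
    """One b- or y-series fragment ion with its theoretical m/z."""

    series: str  # "b" or "y"
    ordinal: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.ordinal < 1:
            raise ValueError("fragment ordinal must be >= 1")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")
        if not self.mz > 0:
            raise ValueError("fragment m/z must be positive")

    @property
    def label(self) -> str:
        return f"{self.series}{self.ordinal}" + ("" if self.charge == 1 else f"^{self.charge}+")


def monoisotopic_mass(peptide: Peptide, table: ResidueTable = DEFAULT_TABLE) -> float:
    """Neutral monoisotopic peptide mass in Da (residues + water + mod deltas)."""
    p = _as_peptide(peptide)
    table.validate(p.residues)
    mass = sum(table.mass(sym, p.residues) for sym in p.residues) + table.water
    mass += sum(mod.delta for _, mod in p.modifications)
    return mass


def precursor_mz(peptide: Peptide, z: int, table: ResidueTable = DEFAULT_TABLE) -> float:
    """m/z of the z-protonated precursor, (M + z * m_proton) / z."""
    if z < 1:
        raise ValueError(f"charge state must be >= 1, got {z}")
    return (monoisotopic_mass(peptide, table) + z * table.proton) / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative m/z deviation in parts per million."""
    if not theoretical > 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 0,
    table: ResidueTable = DEFAULT_TABLE,
) -> list[PeptideSequence]:
    """In-silico trypsin digestion: cleave C-terminal to K/R, not before P.

    Returns every peptide carrying 0..missed_cleavages missed cleavage
    sites, ordered by start position then by length. Deterministic.
    """
    if not protein:
        raise ValueError("protein sequence must be nonempty")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    table.validate(protein)

    # cut points: index i means a cut between protein[i-1] and protein[i]
    cuts = [0]
    for i in range(1, len(protein)):
        if protein[i - 1] in "KR" and protein[i] != "P":
            cuts.append(i)
    cuts.append(len(protein))

    # ordered by start cut, then by number of missed cleavages
    ordered: list[PeptideSequence] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            ordered.append(PeptideSequence(protein[cuts[a]:cuts[b]]))
    return ordered


def fragment_ladder(
    peptide: Peptide,
    max_charge: int = 1,
    table: ResidueTable = DEFAULT_TABLE,
) -> list[FragmentIon]:
    """All b_i / y_i fragment ions, i = 1..n-1, charges 1..max_charge.

    b_i carries the first i residues (plus their modifications) and z
    protons; y_i carries the last i residues plus water and z protons.
    """
    p = _as_peptide(peptide)
    n = len(p)
    if n < 2:
        raise ValueError("fragment ladder requires peptide length >= 2")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    residue_masses = [table.mass(sym, p.residues) + p.delta_at(i) for i, sym in enumerate(p.residues)]
    prefix = [0.0]
    for m in residue_masses:
        prefix.append(prefix[-1] + m)

    ions: list[FragmentIon] = []
    for i in range(1, n):
        b_neutral = prefix[i]  # sum of first i residues
        y_neutral = prefix[n] - prefix[n - i] + table.water  # last i residues + water
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon("b", i, z, (b_neutral + z * table.proton) / z))
            ions.append(FragmentIon("y", i, z, (y_neutral + z * table.proton) / z))
    return ions


def modification_hypotheses(
    sequence: str,
    modifications: Sequence[Modification] = (OXIDATION, DEAMIDATION),
) -> list[tuple[str, PeptideSequence]]:
    """Enumerate small modification hypotheses for a candidate sequence.

    Returns (label, peptide) pairs: the unmodified peptide plus every
    combination of at most one of each listed modification whose target
    residues occur in the sequence. Site assignment is nominal (first
    eligible residue) — only the mass delta is meaningful downstream.
    """
    base = PeptideSequence(sequence)
    hypotheses: list[tuple[str, PeptideSequence]] = [("none", base)]
    applicable: list[tuple[Modification, int]] = []
    for mod in modifications:
        pos = next((i for i, s in enumerate(sequence) if s in mod.residues), None)
        if pos is not None:
            applicable.append((mod, pos))
    # singles, then pairs (capped at one delta per modification type)
    for mod, pos in applicable:
        hypotheses.append((mod.name, PeptideSequence(sequence, ((pos, mod),))))
    for i in range(len(applicable)):
        for j in range(i + 1, len(applicable)):
            (m1, p1), (m2, p2) = applicable[i], applicable[j]
            if p1 == p2:
                continue
            label = f"{m1.name}+{m2.name}"
            hypotheses.append((label, PeptideSequence(sequence, ((p1, m1), (p2, m2)))))
    return hypotheses


def read_fasta_proteins(path: Union[str, Path]) -> dict[str, str]:
    """Read protein sequences from FASTA for digestion input."""
    proteins: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                proteins[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        proteins[name] = "".join(chunks)
    return proteins
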