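"""Marker selection: the three-criterion rule set and E/W/G category logic.

A qualitative authentication marker must (1) occur only in digested
edible bird's nest, never in any adulterant; (2) be a peptide; and
(3) be consistently found across batches of its target class. Markers
present in both white and grass EBN are EBN-specific (E); present only
in white EBN, white-specific (W); only in grass EBN, grass-specific (G).
Codes are assigned in ascending retention-time order within each
category (ties broken by m/z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import AlignedFeature, MatchParams
from .chem import ResidueTable, DEFAULT_TABLE, ppm_error
from .features import (
    CLASS_GRASS,
    CLASS_WHITE,
    Spectrum,
    is_adulterant_class,
)

__all__ = [
    "SelectionCriteria",
    "MarkerCandidate",
    "MarkerPanel",
    "PeptideEvidence",
    "is_peptide",
    "select_markers",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds operationalising the three marker criteria.

    adulterant_max: largest tolerated presence fraction in any adulterant
        class (default 0 — strict "found only in digested EBN").
    min_consistency: smallest batch-consistency fraction in the target
        class (default 1.0 — present in every batch).
    require_peptide: whether criterion 2 is enforced.
    peptide_default: verdict for features with no peptide evidence at all
        (permissive True for encoded presence/absence tables where the
        peptide column already reflects manual curation).
    """

    adulterant_max: float = 0.0
    min_consistency: float = 1.0
    require_peptide: bool = True
    peptide_default: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.adulterant_max <= 1.0):
            raise ValueError("adulterant_max must be in [0, 1]")
        if not (0.0 <= self.min_consistency <= 1.0):
            raise ValueError("min_consistency must be in [0, 1]")


@dataclass(frozen=True)
class PeptideEvidence:
    """Outcome of the peptide-ness check with a human-readable trail."""

    verdict: bool
    source: str  # "msms", "charge", "default"
    detail: str = ""


def is_peptide(
    feature: AlignedFeature,
    spectra: Sequence[Spectrum] = (),
    *,
    min_residue_hits: int = 3,
    ppm_tol: float = 20.0,
    table: ResidueTable = DEFAULT_TABLE,
    default: bool = True,
    params: MatchParams = MatchParams(),
) -> PeptideEvidence:
    """Decide whether an aligned feature is a peptide.

    Evidence, in order of priority: (a) an associated MS/MS spectrum in
    which at least ``min_residue_hits`` fragment peaks participate in
    pairwise mass differences matching amino-acid residue masses within
    ``ppm_tol``; (b) a charge call — charge >= 2 from isotope spacing
    says peptide, a bare 1+ call with no spectrum says not. With no
    evidence at all the configured ``default`` applies.
    """
    spectrum = _associated_spectrum(feature, spectra, params)
    if spectrum is not None:
        hits = _residue_difference_hits(spectrum.fragment_mzs, table, ppm_tol)
        verdict = hits >= min_residue_hits
        return PeptideEvidence(
            verdict, "msms", f"{hits} fragment peaks in residue-mass differences"
        )
    charges = feature.charges
    if charges:
        if max(charges) >= 2:
            return PeptideEvidence(True, "charge", f"charge {max(charges)} called")
        return PeptideEvidence(False, "charge", "only singly charged")
    return PeptideEvidence(default, "default", "no evidence available")


def _associated_spectrum(
    feature: AlignedFeature, spectra: Sequence[Spectrum], params: MatchParams
) -> Optional[Spectrum]:
    best, best_ppm = None, None
    for s in spectra:
        dppm = abs(ppm_error(s.precursor_mz, feature.consensus_mz))
        drt = abs(s.rt - feature.consensus_rt)
        if dppm <= params.ppm_tol and drt <= params.rt_tol:
            if best_ppm is None or dppm < best_ppm:
                best, best_ppm = s, dppm
    return best


def _residue_difference_hits(mzs: Sequence[float], table: ResidueTable, ppm_tol: float) -> int:
    """Count peaks participating in >=1 pairwise difference equal to a residue mass."""
    residue_masses = sorted(set(table.masses.values()))
    hit: set[int] = set()
    for i in range(len(mzs)):
        for j in range(i + 1, len(mzs)):
            diff = abs(mzs[j] - mzs[i])
            for rm in residue_masses:
                if abs(diff - rm) <= rm * ppm_tol * 1e-6:
                    hit.add(i)
                    hit.add(j)
                    break
    return len(hit)


@dataclass(frozen=True)
class MarkerCandidate:
    """One aligned feature with its selection flags and assigned category."""

    index: int
    mz: float
    rt: float
    in_white: bool
    in_grass: bool
    in_adulterant: bool
    peptide: bool
    common: bool
    category: str  # "E" | "W" | "G" | "none"
    code: str = ""  # e.g. "E7"; empty for non-markers


@dataclass(frozen=True)
class MarkerPanel:
    """The selected marker set with per-category counts."""

    markers: tuple[MarkerCandidate, ...]
    candidates: tuple[MarkerCandidate, ...] = ()

    @property
    def counts(self) -> dict[str, int]:
        out = {"E": 0, "W": 0, "G": 0}
        for m in self.markers:
            out[m.category] += 1
        return out

    @property
    def total(self) -> int:
        return len(self.markers)

    def by_code(self, code: str) -> MarkerCandidate:
        for m in self.markers:
            if m.code == code:
                return m
        raise KeyError(f"no marker with code {code!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "code": m.code,
                    "category": m.category,
                    "mz": m.mz,
                    "rt": m.rt,
                    "in_white": m.in_white,
                    "in_grass": m.in_grass,
                    "in_adulterant": m.in_adulterant,
                    "peptide": m.peptide,
                    "common": m.common,
                }
                for m in self.markers
            ]
        )


def select_markers(
    matrix: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> MarkerPanel:
    """Apply the three marker criteria to a presence matrix.

    ``matrix`` must carry columns ``mz``, ``rt``, ``presence:white_EBN``,
    ``presence:grass_EBN``, at least one ``presence:adulterant:*`` column,
    matching ``consistency:*`` columns for the two EBN classes, and
    (optionally) a boolean ``is_peptide`` column; absent peptide evidence
    falls back to ``criteria.peptide_default``.
    """
    for col in ("presence:" + CLASS_WHITE, "presence:" + CLASS_GRASS):
        if col not in matrix.columns:
            raise KeyError(f"presence matrix lacks required class column {col!r}")
    adulterant_cols = [
        c
        for c in matrix.columns
        if c.startswith("presence:") and is_adulterant_class(c.split(":", 1)[1])
    ]
    if not adulterant_cols:
        raise KeyError("presence matrix lacks any presence:adulterant:* column")

    cons_white = "consistency:" + CLASS_WHITE
    cons_grass = "consistency:" + CLASS_GRASS

    candidates: list[MarkerCandidate] = []
    for idx, row in matrix.iterrows():
        in_white = row["presence:" + CLASS_WHITE] > 0
        in_grass = row["presence:" + CLASS_GRASS] > 0
        adulterant_frac = max(row[c] for c in adulterant_cols)
        in_adulterant = adulterant_frac > criteria.adulterant_max
        peptide = bool(row["is_peptide"]) if "is_peptide" in matrix.columns else criteria.peptide_default
        cw = row.get(cons_white, row["presence:" + CLASS_WHITE])
        cg = row.get(cons_grass, row["presence:" + CLASS_GRASS])
        common_white = cw >= criteria.min_consistency
        common_grass = cg >= criteria.min_consistency

        category = "none"
        common = False
        peptide_ok = peptide or not criteria.require_peptide
        if not in_adulterant and peptide_ok:
            if in_white and in_grass and (common_white or common_grass):
                category, common = "E", True
            elif in_white and not in_grass and common_white:
                category, common = "W", True
            elif in_grass and not in_white and common_grass:
                category, common = "G", True
        candidates.append(
            MarkerCandidate(
                int(idx),
                float(row["mz"]),
                float(row["rt"]),
                bool(in_white),
                bool(in_grass),
                bool(in_adulterant),
                bool(peptide),
                common,
                category,
            )
        )

    markers: list[MarkerCandidate] = []
    for cat in ("E", "W", "G"):
        members = sorted(
            (c for c in candidates if c.category == cat), key=lambda c: (c.rt, c.mz)
        )
        for i, cand in enumerate(members, start=1):
            markers.append(
                MarkerCandidate(
                    cand.index,
                    cand.mz,
                    cand.rt,
                    cand.in_white,
                    cand.in_grass,
                    cand.in_adulterant,
                    cand.peptide,
                    cand.common,
                    cat,
                    f"{cat}{i}",
                )
            )
    return MarkerPanel(tuple(markers), tuple(candidates))
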