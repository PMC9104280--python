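"""Sequence-vs-spectrum confirmation of candidate marker peptides.

Given an MS/MS spectrum and an externally supplied candidate sequence
(from a database search, de novo sequencing or the literature), the
candidate is scored by b/y fragment-ion matching. A small hypothesis
space of artefactual modifications — at most one oxidation (M/W) and
one deamidation (N/Q) — is enumerated to reconcile the observed
precursor; the hypothesis minimising the absolute precursor ppm error
is scored. This confirms or refutes given sequences; it is not a
search engine.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .chem import (
    DEFAULT_TABLE,
    PeptideSequence,
    ResidueTable,
    fragment_ladder,
    modification_hypotheses,
    ppm_error,
    precursor_mz,
)
from .features import Spectrum
from .markers import MarkerPanel

__all__ = ["ConfirmParams", "ConfirmationResult", "confirm_sequence", "screen_panel"]


@dataclass(frozen=True)
class ConfirmParams:
    """Tolerances and pass thresholds for sequence confirmation.

    Fragment tolerance is absolute (Th), the natural unit for QTOF
    MS/MS fragments; the precursor tolerance is relative (ppm).
    """

    fragment_tol: float = 0.05
    precursor_tol_ppm: float = 25.0
    min_score: float = 0.5

    def __post_init__(self) -> None:
        if not self.fragment_tol > 0:
            raise ValueError("fragment_tol must be positive")
        if not self.precursor_tol_ppm > 0:
            raise ValueError("precursor_tol_ppm must be positive")


@dataclass(frozen=True)
class ConfirmationResult:
    """Outcome of matching one candidate sequence against one spectrum."""

    peptide: PeptideSequence
    charge: int
    hypothesis: str  # "none", "oxidation", "deamidation", ...
    precursor_ppm: float
    matched: int
    total: int
    passed: bool

    @property
    def score(self) -> float:
        return self.matched / self.total if self.total else 0.0


def _count_matches(theoretical: Sequence[float], observed: Sequence[float], tol: float) -> int:
    obs = sorted(observed)
    matched = 0
    for mz in theoretical:
        i = bisect_left(obs, mz)
        near = []
        if i < len(obs):
            near.append(obs[i])
        if i > 0:
            near.append(obs[i - 1])
        if near and min(abs(o - mz) for o in near) <= tol:
            matched += 1
    return matched


def confirm_sequence(
    spectrum: Spectrum,
    candidate: str,
    z: Optional[int] = None,
    params: ConfirmParams = ConfirmParams(),
    table: ResidueTable = DEFAULT_TABLE,
) -> ConfirmationResult:
    """Score a candidate sequence against an MS/MS spectrum.

    The modification hypothesis minimising |precursor ppm error| is
    selected; singly charged b/y ions of that hypothesis are matched
    within the fragment tolerance. The candidate passes iff the
    precursor error is within tolerance and the matched fraction
    reaches the minimum score.
    """
    if not spectrum.peaks:
        raise ValueError("spectrum has no fragment peaks")
    if z is None:
        z = spectrum.precursor_charge
    elif z != spectrum.precursor_charge:
        raise ValueError(
            f"candidate charge {z} does not match spectrum precursor charge "
            f"{spectrum.precursor_charge}"
        )

    best: Optional[tuple[float, str, PeptideSequence]] = None
    for label, peptide in modification_hypotheses(candidate):
        ppm = ppm_error(spectrum.precursor_mz, precursor_mz(peptide, z, table))
        if best is None or abs(ppm) < abs(best[0]):
            best = (ppm, label, peptide)
    assert best is not None
    ppm, label, peptide = best

    ladder = fragment_ladder(peptide, max_charge=1, table=table)
    theoretical = [ion.mz for ion in ladder]
    matched = _count_matches(theoretical, spectrum.fragment_mzs, params.fragment_tol)
    total = len(theoretical)
    score = matched / total
    passed = abs(ppm) <= params.precursor_tol_ppm and score >= params.min_score
    return ConfirmationResult(peptide, z, label, ppm, matched, total, passed)


def screen_panel(
    panel: MarkerPanel,
    spectra: Sequence[Spectrum],
    candidates: Mapping[str, Iterable[str]],
    params: ConfirmParams = ConfirmParams(),
    table: ResidueTable = DEFAULT_TABLE,
) -> dict[str, Optional[ConfirmationResult]]:
    """Best confirmation per marker; None marks an unidentified marker.

    ``candidates`` maps marker codes to candidate sequences (duplicates
    are collapsed). A marker's spectrum is the one whose precursor lies
    nearest its consensus m/z within the precursor tolerance; markers
    without a spectrum or without any passing candidate stay
    unidentified.
    """
    results: dict[str, Optional[ConfirmationResult]] = {}
    for marker in panel.markers:
        results[marker.code] = None
        seqs = sorted(set(candidates.get(marker.code, ())))
        if not seqs:
            continue
        spectrum = _nearest_spectrum(marker.mz, spectra, params.precursor_tol_ppm)
        if spectrum is None:
            continue
        best: Optional[ConfirmationResult] = None
        for seq in seqs:
            res = confirm_sequence(spectrum, seq, params=params, table=table)
            key = (res.passed, res.score, -abs(res.precursor_ppm))
            if best is None or key > (best.passed, best.score, -abs(best.precursor_ppm)):
                best = res
        if best is not None and best.passed:
            results[marker.code] = best
    return results


def _nearest_spectrum(
    mz: float, spectra: Sequence[Spectrum], ppm_tol: float
) -> Optional[Spectrum]:
    best, best_ppm = None, None
    for s in spectra:
        dppm = abs(ppm_error(s.precursor_mz, mz))
        if dppm <= ppm_tol and (best_ppm is None or dppm < best_ppm):
            best, best_ppm = s, dppm
    return best
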