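"""Shared fixtures: reference data, a small synthetic cohort, ladder spectra."""

from __future__ import annotations

import pytest

from nestmark.align import MatchParams, align_runs, presence_matrix
from nestmark.chem import fragment_ladder
from nestmark.features import Spectrum
from nestmark.reference import reference_marker_screen, reference_product_survey
from nestmark.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def screen():
    """The encoded 58-feature published screen (canonical flag resolution)."""
    return reference_marker_screen()


@pytest.fixture(scope="session")
def survey():
    """The encoded 46-product commercial survey."""
    return reference_product_survey()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (60 white + 10 grass + 9 adulterant classes)."""
    return generate_cohort(GeneratorConfig(seed=20260925))


@pytest.fixture(scope="session")
def cohort_matrix(cohort):
    """Presence matrix of the default cohort with peptide evidence attached."""
    from nestmark.markers import is_peptide

    params = MatchParams()
    aligned = align_runs(cohort.features, params)
    matrix = presence_matrix(aligned, cohort.runs, params)
    matrix["is_peptide"] = [
        is_peptide(g, cohort.spectra, params=params).verdict for g in aligned
    ]
    return matrix


def ladder_spectrum(sequence, precursor_mz: float, charge: int = 2,
                    run_id: str = "run0", rt: float = 10.0) -> Spectrum:
    """Full singly-charged b/y ladder of a peptide as a synthetic spectrum."""
    ions = fragment_ladder(sequence, max_charge=1)
    peaks = tuple(sorted((ion.mz, 100.0) for ion in ions))
    return Spectrum(precursor_mz, charge, peaks, run_id, rt)
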