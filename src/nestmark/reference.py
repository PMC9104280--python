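"""Published reference data for edible-bird's-nest peptide markers.

Encodes, as package fixtures: (1) the 58-feature presence/absence screen
of digested white EBN, grass EBN and nine common adulterants from which
the qualitative marker panel (10 E + 13 W + 3 G) was drawn; (2) the
survey of 46 commercial liquid EBN products with per-marker quantities
(mg per mL, from 250 uL aliquots) or "none detected"; (3) the three
assay markers whose sequences were identified by database searching and
de novo sequencing, together with every printed m/z variant.

One screen row (m/z 711.4410, coded W10) prints an adulterant-positive
flag that contradicts its marker code; the canonical encoding resolves
it in favour of the code and logs the deviation. ``strict_flags=True``
keeps the printed flag instead (one fewer white-specific marker).
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .features import ADULTERANT_PREFIX, CLASS_GRASS, CLASS_WHITE
from .quant import ProductRecord

__all__ = [
    "MARKER_SEQUENCES",
    "MARKER_MZ_VARIANTS",
    "reference_marker_screen",
    "reference_product_survey",
]

log = logging.getLogger(__name__)

#: Identified assay-marker sequences: code -> (sequence, charge state).
MARKER_SEQUENCES: dict[str, tuple[str, int]] = {
    "E7": ("VSAPGPVLTR", 2),
    "W2": ("AMESINSR", 2),
    "G1": ("SDDSLWR", 2),
}

#: Printed m/z values for the assay markers across the screen, the
#: identification run and the assay definition. W2's identification
#: value (454.6704) is irreconcilable with AMESINSR under <=1 oxidation
#: + <=1 deamidation (deamidated AMESINSR gives 454.7107, close to the
#: other two variants); it is recorded, not resolved.
MARKER_MZ_VARIANTS: dict[str, dict[str, float]] = {
    "E7": {"screen": 498.7967, "identification": 498.8056, "assay": 498.8056},
    "W2": {"screen": 454.7018, "identification": 454.6704, "assay": 454.7081},
    "G1": {"screen": 447.6996, "identification": 447.6998, "assay": 447.6998},
}

# (m/z, RT min, white, grass, adulterant, peptide, common, code) — 58 rows.
# Flags: 1 = "+", 0 = "-"; common 0 also covers "not applicable".
_SCREEN_ROWS: list[tuple[float, float, int, int, int, int, int, Optional[str]]] = [
    (375.2250, 7.96, 1, 0, 1, 0, 0, None),
    (280.6746, 7.97, 1, 1, 0, 1, 1, "E1"),
    (237.1235, 9.04, 1, 0, 1, 0, 0, None),
    (272.1722, 9.51, 1, 0, 1, 0, 0, None),
    (381.7042, 9.61, 1, 1, 0, 1, 1, "E2"),
    (447.6996, 9.81, 0, 1, 0, 1, 1, "G1"),
    (373.8247, 9.82, 1, 1, 0, 1, 1, "E3"),
    (292.1648, 10.05, 1, 0, 0, 1, 1, "W1"),
    (548.2486, 10.07, 1, 0, 0, 0, 0, None),
    (258.1691, 10.24, 1, 0, 1, 0, 0, None),
    (402.2467, 10.24, 1, 0, 1, 0, 0, None),
    (454.7018, 10.24, 1, 0, 0, 1, 1, "W2"),
    (467.2138, 10.38, 1, 0, 0, 0, 0, None),
    (231.1710, 10.67, 1, 0, 1, 0, 0, None),
    (305.1666, 10.99, 1, 0, 0, 1, 1, "W3"),
    (339.1850, 10.99, 1, 0, 1, 0, 0, None),
    (582.2528, 11.01, 1, 0, 1, 0, 0, None),
    (389.2400, 11.09, 1, 0, 1, 0, 0, None),
    (277.6512, 11.49, 1, 0, 0, 1, 1, "W4"),
    (347.6992, 11.63, 1, 0, 1, 0, 0, None),
    (382.1620, 12.01, 1, 0, 0, 0, 0, None),
    (629.3627, 12.56, 1, 0, 1, 0, 0, None),
    (258.6615, 12.59, 1, 0, 0, 0, 0, None),
    (288.2036, 12.59, 1, 0, 0, 0, 0, None),
    (280.1954, 12.86, 1, 0, 0, 1, 1, "W5"),
    (265.1557, 13.54, 1, 0, 1, 0, 0, None),
    (494.2616, 14.44, 1, 0, 1, 0, 0, None),
    (350.1712, 15.09, 1, 0, 0, 0, 0, None),
    (820.3634, 15.13, 1, 1, 0, 1, 1, "E4"),
    (335.2230, 15.39, 0, 1, 0, 1, 1, "G2"),
    (509.2615, 15.79, 1, 0, 1, 0, 0, None),
    (417.7010, 16.15, 0, 1, 0, 1, 1, "G3"),
    (804.3734, 16.24, 1, 0, 1, 0, 0, None),
    (404.1986, 16.65, 1, 1, 0, 1, 1, "E5"),
    (366.2030, 16.66, 1, 0, 0, 0, 0, None),
    (300.1459, 17.25, 1, 1, 0, 1, 1, "E6"),
    (498.7967, 17.87, 1, 1, 0, 1, 1, "E7"),
    (507.2456, 18.39, 1, 0, 1, 0, 0, None),
    (346.2350, 19.48, 1, 0, 0, 0, 0, None),
    (364.2235, 19.48, 1, 0, 0, 0, 0, None),
    (321.7031, 20.45, 1, 0, 0, 1, 1, "W6"),
    (844.3728, 20.63, 1, 1, 0, 1, 1, "E8"),
    (441.7166, 20.65, 1, 0, 0, 1, 1, "W7"),
    (294.8142, 20.70, 1, 0, 0, 1, 1, "W8"),
    (468.7439, 20.78, 1, 0, 0, 1, 1, "W9"),
    (350.2074, 21.07, 1, 0, 0, 0, 0, None),
    (344.2550, 21.32, 1, 0, 1, 0, 0, None),
    (336.1926, 21.40, 1, 0, 0, 0, 0, None),
    (525.7603, 22.46, 1, 0, 0, 0, 0, None),
    (477.7330, 23.14, 1, 1, 0, 1, 1, "E9"),
    (630.8100, 24.56, 1, 1, 0, 1, 1, "E10"),
    (479.2879, 24.73, 1, 0, 1, 0, 0, None),
    (472.3140, 25.78, 1, 0, 1, 1, 0, None),
    (711.4410, 26.43, 1, 0, 1, 1, 1, "W10"),  # printed adulterant "+" conflicts with code
    (391.7429, 27.35, 1, 0, 0, 1, 1, "W11"),
    (410.7169, 27.35, 1, 0, 0, 1, 1, "W12"),
    (433.7006, 28.04, 1, 0, 0, 1, 1, "W13"),
    (491.3200, 29.94, 1, 0, 1, 0, 0, None),
]

_CONFLICT_MZ = 711.4410


def reference_marker_screen(strict_flags: bool = False) -> pd.DataFrame:
    """The encoded 58-row presence/absence screen, matrix-shaped.

    Returns a presence matrix as produced by :func:`nestmark.align
    .presence_matrix` (adulterant classes pooled into one column), with
    an ``is_peptide`` column from the screen's peptide flag and a
    ``code`` column carrying the published marker codes for cross-checks.
    """
    rows = []
    for mz, rt, white, grass, adulterant, peptide, common, code in _SCREEN_ROWS:
        if mz == _CONFLICT_MZ and not strict_flags:
            if adulterant:
                log.warning(
                    "screen row at m/z %.4f: printed adulterant '+' conflicts with "
                    "marker code %s; canonical encoding follows the code "
                    "(adulterant '-'). Pass strict_flags=True to keep the flag.",
                    mz,
                    code,
                )
            adulterant = 0
        rows.append(
            {
                "mz": mz,
                "rt": rt,
                f"presence:{CLASS_WHITE}": float(white),
                f"presence:{CLASS_GRASS}": float(grass),
                f"presence:{ADULTERANT_PREFIX}pooled": float(adulterant),
                f"consistency:{CLASS_WHITE}": float(white and common),
                f"consistency:{CLASS_GRASS}": float(grass and common),
                "is_peptide": bool(peptide),
                "code": code or "",
            }
        )
    return pd.DataFrame(rows)


# (product id, W2, E7, G1, type, origin); None = "none detected".
_SURVEY_ROWS: list[tuple[str, Optional[float], Optional[float], Optional[float], str, str]] = [
    ("PD-01", 12.72, 14.16, 4.60, "instant product", "China"),
    ("PD-02", 3.21, 3.52, 3.40, "instant product", "China"),
    ("PD-03", 7.64, 7.32, 7.52, "instant product", "China"),
    ("PD-04", 12.24, 13.12, None, "instant product", "China"),
    ("PD-05", 15.52, 15.60, None, "instant product", "China"),
    ("PD-06", 5.92, 6.04, 5.41, "instant product", "China"),
    ("PD-07", 52.72, 55.32, 8.96, "instant product", "China"),
    ("PD-08", 61.08, 61.56, None, "instant product", "China"),
    ("PD-09", 74.80, 75.84, None, "instant product", "China"),
    ("PD-10", 41.84, 42.68, 5.41, "instant product", "China"),
    ("PD-11", 18.32, 21.88, 10.52, "instant product", "China"),
    ("PD-12", None, None, None, "instant product", "China"),
    ("PD-13", None, None, None, "instant product", "China"),
    ("PD-14", None, None, None, "instant product", "China"),
    ("PD-15", None, None, None, "instant product", "China"),
    ("PD-16", None, None, None, "instant product", "China"),
    ("PD-17", None, None, None, "instant product", "China"),
    ("PD-18", None, None, None, "instant product", "China"),
    ("PD-19", 3.20, 3.56, None, "beverage", "China"),
    ("PD-20", None, None, None, "beverage", "China"),
    ("PD-21", None, None, None, "beverage", "China"),
    ("PD-22", None, None, None, "instant product", "China"),
    ("PD-23", None, None, None, "instant product", "China"),
    ("PD-24", None, None, None, "instant product", "China"),
    ("PD-25", None, None, None, "instant product", "China"),
    ("PD-26", None, None, None, "instant product", "China"),
    ("PD-27", None, None, None, "instant product", "China"),
    ("PD-28", None, None, None, "instant product", "China"),
    ("PD-29", None, None, None, "beverage", "China"),
    ("PD-30", None, None, None, "beverage", "China"),
    ("PD-31", None, None, None, "instant product", "China"),
    ("PD-32", 4.81, 5.52, None, "instant product", "China"),
    ("PD-33", None, None, None, "instant product", "China"),
    ("PD-34", 22.24, 24.60, 6.64, "instant product", "China"),
    ("PD-35", 18.40, 20.12, None, "instant product", "China"),
    ("PD-36", 23.92, 24.64, None, "instant product", "China"),
    ("PD-37", 4.04, 7.01, 12.08, "instant product", "China"),
    ("PD-38", 16.96, 20.68, None, "instant product", "China"),
    ("PD-39", 8.04, 10.01, 3.32, "instant product", "China"),
    ("PD-40", 71.80, 73.56, 12.44, "instant product", "China"),
    ("PD-41", 14.92, 15.16, None, "instant product", "China"),
    ("PD-42", None, None, None, "beverage", "Vietnam"),
    ("PD-43", 4.04, 4.24, None, "beverage", "Vietnam"),
    ("PD-44", 15.44, 15.52, None, "beverage", "Vietnam"),
    ("PD-45", 13.12, 13.20, None, "beverage", "Vietnam"),
    ("PD-46", 3.48, 3.52, None, "beverage", "Vietnam"),
]


def reference_product_survey() -> list[ProductRecord]:
    """The encoded 46-product survey as :class:`ProductRecord` objects."""
    return [
        ProductRecord(pid, {"W2": w2, "E7": e7, "G1": g1}, ptype, origin)
        for pid, w2, e7, g1, ptype, origin in _SURVEY_ROWS
    ]
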