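"""Synthetic LC-MS cohorts with known ground truth.

Emulates the study design this pipeline targets: a cohort of 60 white
and 10 grass edible-bird's-nest digests plus nine adulterant materials,
carrying a planted panel of 10 EBN-specific, 13 white-specific and 3
grass-specific peptide markers on top of shared and class-specific
background peaks; MS/MS spectra of the planted marker peptides;
calibration series with Gaussian area noise; and designed product
panels pushed through the forward calibration model. Everything is
deterministic given the seed.

The generator produces centroided feature tables directly — there is no
chromatographic peak-shape or raw-profile simulation — so passing tests
demonstrate the pipeline logic, not vendor-data handling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .chem import PeptideSequence, fragment_ladder, precursor_mz, tryptic_digest
from .features import (
    ADULTERANT_PREFIX,
    CLASS_GRASS,
    CLASS_WHITE,
    Feature,
    Run,
    Spectrum,
)
from .quant import CalibrationCurve, NoiseEstimate, ProductRecord, fit_calibration, lod_loq

__all__ = [
    "GeneratorConfig",
    "PlantedMarker",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_calibration",
    "generate_products",
    "DEFAULT_PRODUCT_DESIGN",
]

# Decoy protein sequences (synthetic, fixed): tryptic digestion of these
# provides the pool of chemically real peptides assigned to planted
# markers beyond the three identified assay sequences.
_DECOY_PROTEINS = (
    "MAGTEILSVKDQWFPNHYRAETGVLSDKCIMPNQSWYRAFGHLTVEKDSPINQR"
    "TGAVLMEKWSDFYHPNRACILQGTVKESMDWFPRNHYAGTLSVK",
    "MSDELFGHKTPVWAYNQRCAGILMSEKDFHPTVRWYNAGQLSKECIMDFPTRHV"
    "WYAGNLSQKEDCIFMPTRGHVWLYANQSEKDTCIFMPRGHVWK",
    "MTEAGILSRKDNQWFPVHYCAETGMLSDRKIPNQSWYAFGHLTVERDSPINQK"
    "TGAVLMERWSDFYHPNKACILQGTVRESMDWFPKNHYAGTLSVR",
    "MGSTAEILVKRDQWFNPHYCAETGVLSDKIMPNQSWYRAFGHLTVEKDSAPINQR"
    "GTAVLMEKWSEFYHPNRACILQGTVKDSMEWFPRNHYAGTLSVK",
)

#: The three identified assay marker peptides with their target category
#: and nominal retention times (min), mirroring the reference screen.
_ASSAY_MARKERS = (
    ("W", "AMESINSR", 10.24),
    ("E", "VSAPGPVLTR", 17.87),
    ("G", "SDDSLWR", 9.81),
)

#: Cohort sizes per sample class (runs = batches, one injection each).
DEFAULT_CLASS_SIZES: dict[str, int] = {
    CLASS_WHITE: 60,
    CLASS_GRASS: 10,
    ADULTERANT_PREFIX + "agar": 10,
    ADULTERANT_PREFIX + "egg_white": 5,
    ADULTERANT_PREFIX + "gelatin": 8,
    ADULTERANT_PREFIX + "cow_milk": 8,
    ADULTERANT_PREFIX + "pork_skin": 4,
    ADULTERANT_PREFIX + "tremella": 6,
    ADULTERANT_PREFIX + "rice": 4,
    ADULTERANT_PREFIX + "starch": 3,
    ADULTERANT_PREFIX + "swim_bladder": 3,
}

#: Product design mirroring the commercial survey: (white mg, grass mg)
#: for 14 white-only, 11 mixed and 21 EBN-free products.
DEFAULT_PRODUCT_DESIGN: tuple[tuple[float, float], ...] = (
    tuple((float(10 + 2 * i), 0.0) for i in range(14))
    + tuple((float(8 + 2 * i), float(3 + i)) for i in range(11))
    + tuple((0.0, 0.0) for _ in range(21))
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    seed: int = 0
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    n_e_markers: int = 10
    n_w_markers: int = 13
    n_g_markers: int = 3
    shared_background: int = 30  # peaks common to EBN and adulterants
    class_background: int = 8  # peaks unique to each class, inconsistent across runs
    background_presence: float = 0.7  # per-run presence prob of class background
    rt_jitter_sd: float = 0.05  # min
    mz_error_ppm_sd: float = 3.0
    area_log_sd: float = 0.3  # log-normal spread of peak areas
    dropout: float = 0.0  # per-run marker dropout probability
    marker_area: float = 2.0e6  # median marker peak area ("high signal abundance")
    background_area: float = 2.0e5
    calibration_slope: float = 169511.0  # area per mg
    calibration_intercept: float = -106601.0
    calibration_noise_frac: float = 0.02  # noise SD as a fraction of signal
    calibration_levels: tuple[float, ...] = (0.5, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0)
    product_design: tuple[tuple[float, float], ...] = DEFAULT_PRODUCT_DESIGN
    product_noise_frac: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be a probability")
        if not (0.0 <= self.background_presence <= 1.0):
            raise ValueError("background_presence must be a probability")
        for name in ("rt_jitter_sd", "mz_error_ppm_sd", "area_log_sd",
                     "calibration_noise_frac", "product_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min((self.n_e_markers, self.n_w_markers, self.n_g_markers)) < 0:
            raise ValueError("panel sizes must be >= 0")
        if any(level < 0 for level in self.calibration_levels):
            raise ValueError("calibration levels must be >= 0")


@dataclass(frozen=True)
class PlantedMarker:
    category: str  # "E" | "W" | "G"
    sequence: str
    charge: int
    mz: float
    rt: float


@dataclass
class GroundTruth:
    markers: list[PlantedMarker] = field(default_factory=list)
    calibration: Optional[dict] = None
    products: list[dict] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "markers": [asdict(m) for m in self.markers],
            "calibration": self.calibration,
            "products": self.products,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class Cohort:
    runs: dict[str, Run]
    features: list[Feature]
    spectra: list[Spectrum]
    truth: GroundTruth


def _marker_peptide_pool() -> list[str]:
    """Tryptic peptides (length 6-14) from the bundled decoy proteins."""
    pool: list[str] = []
    seen: set[str] = set()
    for protein in _DECOY_PROTEINS:
        for pep in tryptic_digest(protein, missed_cleavages=0):
            seq = pep.residues
            if 6 <= len(seq) <= 14 and seq not in seen:
                seen.add(seq)
                pool.append(seq)
    return pool


def _plant_markers(config: GeneratorConfig) -> list[PlantedMarker]:
    """Assign peptide sequences, m/z and well-separated RTs to the panel."""
    pool = _marker_peptide_pool()
    assay_seqs = {seq for _, seq, _ in _ASSAY_MARKERS}
    pool = [p for p in pool if p not in assay_seqs]
    need = {"E": config.n_e_markers, "W": config.n_w_markers, "G": config.n_g_markers}
    markers: list[PlantedMarker] = []
    for cat, seq, rt in _ASSAY_MARKERS:
        if need[cat] > 0:
            markers.append(PlantedMarker(cat, seq, 2, precursor_mz(seq, 2), rt))
            need[cat] -= 1
    remaining = need["E"] + need["W"] + need["G"]
    if remaining > len(pool):
        raise ValueError(
            f"planted panel needs {remaining} more peptides but the decoy pool has {len(pool)}"
        )
    # markers spaced 0.45 min apart on an RT grid so cross-run grouping
    # can never merge two distinct markers at default tolerances
    grid = [6.0 + 0.45 * i for i in range(remaining + 10)]
    used_rts = {m.rt for m in markers}
    grid = [g for g in grid if all(abs(g - u) > 0.4 for u in used_rts)]
    i = 0
    for cat in ("E", "W", "G"):
        for _ in range(need[cat]):
            seq = pool[i]
            markers.append(PlantedMarker(cat, seq, 2, precursor_mz(seq, 2), grid[i]))
            i += 1
    return markers


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> Cohort:
    """Simulate the full class-structured cohort with planted markers.

    Planted markers appear (subject to dropout) in every run of their
    target classes and never in adulterant runs; shared background peaks
    appear everywhere; class-specific background peaks are singly
    charged and present in a random subset of their class's runs. Each
    planted marker also gets one MS/MS spectrum (its full singly-charged
    b/y ladder) attached to a run of its target class.
    """
    rng = np.random.default_rng(config.seed)
    markers = _plant_markers(config)

    # background peak positions, kept away from every planted marker
    def _draw_positions(n: int, sub_rng: np.random.Generator) -> list[tuple[float, float]]:
        out: list[tuple[float, float]] = []
        while len(out) < n:
            mz = float(sub_rng.uniform(200.0, 900.0))
            rt = float(sub_rng.uniform(5.0, 30.0))
            if all(
                abs(rt - m.rt) > 0.6 or abs(mz - m.mz) / m.mz > 50e-6 for m in markers
            ):
                out.append((mz, rt))
        return out

    shared_bg = _draw_positions(config.shared_background, rng)
    class_bg: dict[str, list[tuple[float, float]]] = {
        cls: _draw_positions(config.class_background, rng) for cls in config.class_sizes
    }

    target_classes = {"E": (CLASS_WHITE, CLASS_GRASS), "W": (CLASS_WHITE,), "G": (CLASS_GRASS,)}

    runs: dict[str, Run] = {}
    features: list[Feature] = []
    for cls, n_runs in config.class_sizes.items():
        short = cls.replace(ADULTERANT_PREFIX, "ad_")
        for k in range(n_runs):
            run_id = f"{short}_{k:03d}"
            runs[run_id] = Run(run_id, cls, batch=f"{short}_b{k:03d}")

            def _emit(mz: float, rt: float, median_area: float, charge: Optional[int]) -> None:
                obs_mz = mz * (1.0 + rng.normal(0.0, config.mz_error_ppm_sd) * 1e-6)
                obs_rt = max(0.0, rt + rng.normal(0.0, config.rt_jitter_sd))
                area = median_area * float(np.exp(rng.normal(0.0, config.area_log_sd)))
                features.append(Feature(obs_mz, obs_rt, area, run_id, charge))

            for m in markers:
                if cls in target_classes[m.category] and rng.random() >= config.dropout:
                    _emit(m.mz, m.rt, config.marker_area, m.charge)
            for mz, rt in shared_bg:
                _emit(mz, rt, config.background_area, 1)
            for mz, rt in class_bg[cls]:
                if rng.random() < config.background_presence:
                    _emit(mz, rt, config.background_area, 1)

    spectra: list[Spectrum] = []
    for m in markers:
        host_cls = target_classes[m.category][0]
        host = next((r.run_id for r in runs.values() if r.sample_class == host_cls), None)
        if host is None:  # target class absent from this cohort design
            continue
        ladder = fragment_ladder(PeptideSequence(m.sequence), max_charge=1)
        peaks = tuple(sorted((ion.mz, 1000.0) for ion in ladder))
        spectra.append(Spectrum(m.mz, m.charge, peaks, host, m.rt))

    return Cohort(runs, features, spectra, GroundTruth(markers=list(markers)))


def generate_calibration(
    config: GeneratorConfig = GeneratorConfig(),
    marker_code: str = "W2",
) -> tuple[list[tuple[float, float]], dict]:
    """Noisy calibration series areas = a*x + b + N(0, (frac*signal)^2)."""
    if len(config.calibration_levels) < 3:
        raise ValueError("calibration needs >= 3 levels")
    if any(level < 0 for level in config.calibration_levels):
        raise ValueError("calibration levels must be >= 0")
    rng = np.random.default_rng(config.seed)
    points: list[tuple[float, float]] = []
    for x in config.calibration_levels:
        signal = config.calibration_slope * x + config.calibration_intercept
        noise = rng.normal(0.0, config.calibration_noise_frac * abs(signal))
        points.append((float(x), float(signal + noise)))
    truth = {
        "marker_code": marker_code,
        "slope": config.calibration_slope,
        "intercept": config.calibration_intercept,
        "noise_frac": config.calibration_noise_frac,
    }
    return points, truth


def default_curves(config: GeneratorConfig = GeneratorConfig()) -> dict[str, CalibrationCurve]:
    """Noiseless calibration curves for the three assay markers.

    W2/E7 regress on total protein amount, G1 on raw-material amount;
    G1's shallower slope reflects its lower response. LODs come from a
    small synthetic blank noise floor.
    """
    specs = {
        "W2": (config.calibration_slope, config.calibration_intercept, "total_protein_mg"),
        "E7": (config.calibration_slope * 1.066, 14740.0, "total_protein_mg"),
        "G1": (config.calibration_slope * 0.206, 10205.0, "raw_material_mg"),
    }
    curves: dict[str, CalibrationCurve] = {}
    for code, (a, b, regressor) in specs.items():
        pts = [(x, a * x + b) for x in config.calibration_levels]
        curve = fit_calibration(pts, code, regressor)
        noise = NoiseEstimate(sigma=abs(a) * 0.02)  # ~0.06 mg LOD at the W2 slope
        curves[code] = curve.with_limits(*lod_loq(curve, noise))
    return curves


def generate_products(
    config: GeneratorConfig = GeneratorConfig(),
    curves: Optional[dict[str, CalibrationCurve]] = None,
) -> tuple[list[ProductRecord], GroundTruth]:
    """Forward-model designed products into per-marker quantities.

    White content drives W2 and dominates E7 (grass contributes weakly);
    grass content drives G1. EBN-free products emit sub-LOD signal only.
    Quantities below a curve's LOD are reported as not-detected, so the
    records feed ``classify_product`` directly.
    """
    from .quant import quantify

    curves = curves or default_curves(config)
    for code in ("W2", "E7", "G1"):
        if code not in curves:
            raise KeyError(f"missing calibration curve for marker {code}")
    rng = np.random.default_rng(config.seed + 1)
    records: list[ProductRecord] = []
    truth = GroundTruth()
    for i, (white_mg, grass_mg) in enumerate(config.product_design):
        pid = f"SP-{i + 1:02d}"
        true_amounts = {
            "W2": white_mg,
            "E7": white_mg + 0.15 * grass_mg,
            "G1": grass_mg,
        }
        amounts: dict[str, Optional[float]] = {}
        for code, amount in true_amounts.items():
            curve = curves[code]
            area = curve.forward(amount)
            if amount == 0:
                # sub-LOD residual signal, strictly below the detection limit
                area = curve.forward(0.2 * curve.lod)
            area += rng.normal(0.0, config.product_noise_frac * max(abs(area), 1.0))
            q = quantify(area, curve)
            amounts[code] = q.amount_mg if q.detected else None
        records.append(ProductRecord(pid, amounts, "synthetic product", "simulated"))
        truth.products.append({"product_id": pid, "white_mg": white_mg, "grass_mg": grass_mg})
    return records, truth
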