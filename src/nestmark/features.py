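"""Data model and I/O for LC-MS runs, centroided features and MS/MS spectra.

The canonical interchange format is a CSV feature table with header
``run_id,class,batch,mz,rt_min,area,charge,amount_mg`` (the last two
optional on read). Retention times are in minutes, m/z in Thomson, peak
areas unitless. mzML is supported read-only as an optional adapter;
MS/MS spectra travel as MGF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "CLASS_WHITE",
    "CLASS_GRASS",
    "ADULTERANT_PREFIX",
    "DEFAULT_ADULTERANTS",
    "SPECIAL_CLASSES",
    "Run",
    "Feature",
    "Spectrum",
    "FeatureTableError",
    "known_classes",
    "is_adulterant_class",
    "read_feature_table",
    "write_feature_table",
    "read_mzml_centroids",
    "write_spectra_mgf",
    "read_spectra_mgf",
]

CLASS_WHITE = "white_EBN"
CLASS_GRASS = "grass_EBN"
ADULTERANT_PREFIX = "adulterant:"

#: The nine common adulterant materials screened against EBN.
DEFAULT_ADULTERANTS = (
    "agar",
    "egg_white",
    "gelatin",
    "cow_milk",
    "pork_skin",
    "tremella",
    "rice",
    "starch",
    "swim_bladder",
)

SPECIAL_CLASSES = ("product", "blank", "calibration")


def known_classes(extra_adulterants: Iterable[str] = ()) -> frozenset[str]:
    """The closed sample-class vocabulary, extendable only by config."""
    names = list(DEFAULT_ADULTERANTS) + list(extra_adulterants)
    return frozenset(
        [CLASS_WHITE, CLASS_GRASS, *SPECIAL_CLASSES]
        + [ADULTERANT_PREFIX + a for a in names]
    )


def is_adulterant_class(sample_class: str) -> bool:
    return sample_class.startswith(ADULTERANT_PREFIX)


class FeatureTableError(ValueError):
    """Raised when a feature table is malformed; message names rows/columns."""


@dataclass(frozen=True)
class Run:
    """One LC-MS injection of a labelled sample."""

    run_id: str
    sample_class: str
    batch: str
    amount_mg: Optional[float] = None  # only meaningful for calibration runs

    def __post_init__(self) -> None:
        if self.amount_mg is not None and self.amount_mg < 0:
            raise ValueError(f"run {self.run_id}: amount_mg must be >= 0")


def validate_run_classes(runs: Iterable[Run], extra_adulterants: Iterable[str] = ()) -> None:
    vocab = known_classes(extra_adulterants)
    for run in runs:
        if run.sample_class not in vocab:
            raise FeatureTableError(
                f"run {run.run_id!r}: unknown sample class {run.sample_class!r}; "
                f"known classes are {sorted(vocab)}"
            )


@dataclass(frozen=True)
class Feature:
    """One centroided LC-MS peak inside a run."""

    mz: float
    rt: float
    area: float
    run_id: str
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"feature RT must be >= 0, got {self.rt}")
        if self.area < 0:
            raise ValueError(f"feature area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum: precursor plus a fragment peak list sorted by m/z."""

    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]
    run_id: str
    rt: float = 0.0

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(inten < 0 for _, inten in self.peaks):
            raise ValueError("fragment intensities must be >= 0")

    @property
    def fragment_mzs(self) -> list[float]:
        return [mz for mz, _ in self.peaks]


_COLUMNS = ["run_id", "class", "batch", "mz", "rt_min", "area", "charge", "amount_mg"]
_MANDATORY = ["run_id", "class", "batch", "mz", "rt_min", "area"]


def read_feature_table(
    path: Union[str, Path],
    extra_adulterants: Iterable[str] = (),
) -> tuple[dict[str, Run], list[Feature]]:
    """Parse the canonical CSV feature table into runs and features.

    Malformed rows are reported together with their 1-based data line
    numbers; a missing mandatory column or an unknown sample class is
    rejected by name.
    """
    df = pd.read_csv(path, dtype={"run_id": str, "class": str, "batch": str})
    for col in _MANDATORY:
        if col not in df.columns:
            raise FeatureTableError(f"missing mandatory column {col!r} in {path}")

    vocab = known_classes(extra_adulterants)
    runs: dict[str, Run] = {}
    features: list[Feature] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            cls = row["class"]
            if cls not in vocab:
                raise ValueError(f"unknown sample class {cls!r}")
            amount = row.get("amount_mg")
            amount = None if amount is None or (isinstance(amount, float) and math.isnan(amount)) else float(amount)
            run = Run(str(row["run_id"]), cls, str(row["batch"]), amount)
            prev = runs.setdefault(run.run_id, run)
            if prev != run:
                raise ValueError(f"run {run.run_id!r} redefined with different metadata")
            if isinstance(row["mz"], float) and math.isnan(row["mz"]):
                continue  # run-metadata-only row (a run with no features)
            charge = row.get("charge")
            charge = None if charge is None or (isinstance(charge, float) and math.isnan(charge)) else int(charge)
            features.append(
                Feature(float(row["mz"]), float(row["rt_min"]), float(row["area"]), run.run_id, charge)
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise FeatureTableError("malformed feature table rows:\n  " + "\n  ".join(errors))
    return runs, features


def write_feature_table(
    runs: Mapping[str, Run],
    features: Sequence[Feature],
    path: Union[str, Path],
) -> None:
    """Write the canonical CSV; numbers at 6 decimals so round trips are stable."""
    lines = [",".join(_COLUMNS)]
    for f in features:
        run = runs[f.run_id]
        charge = "" if f.charge is None else str(f.charge)
        amount = "" if run.amount_mg is None else f"{run.amount_mg:.6f}"
        lines.append(
            f"{f.run_id},{run.sample_class},{run.batch},"
            f"{f.mz:.6f},{f.rt:.6f},{f.area:.6f},{charge},{amount}"
        )
    # emit runs that carry no features so run counts round-trip
    seen = {f.run_id for f in features}
    for run_id, run in runs.items():
        if run_id not in seen:
            amount = "" if run.amount_mg is None else f"{run.amount_mg:.6f}"
            lines.append(f"{run_id},{run.sample_class},{run.batch},,,,,{amount}")
    Path(path).write_text("\n".join(lines) + "\n")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(node) -> "list[float]":
    import base64
    import struct
    import zlib

    names = {cv.get("name") for cv in node.iter(_MZML_NS + "cvParam")}
    raw = base64.b64decode((node.find(_MZML_NS + "binary").text or "").strip())
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    fmt = "f" if "32-bit float" in names else "d"
    width = 4 if fmt == "f" else 8
    return list(struct.unpack(f"<{len(raw) // width}{fmt}", raw))


def read_mzml_centroids(
    path: Union[str, Path],
    intensity_floor: float = 0.0,
    run_id: str = "mzml",
) -> tuple[list[Feature], list[Spectrum]]:
    """Read centroided MS1 peaks (as features) and MS2 scans from mzML.

    Optional adapter for vendor-converted data; the pipeline is fully
    exercisable from CSV tables without it. This is a minimal reader for
    centroided spectra with 32/64-bit float arrays (plain or zlib);
    profile-mode spectra are rejected explicitly.
    """
    import xml.etree.ElementTree as ET

    features: list[Feature] = []
    spectra: list[Spectrum] = []
    root = ET.parse(str(path)).getroot()
    for scan in root.iter(_MZML_NS + "spectrum"):
        params = {
            cv.get("name"): cv.get("value")
            for cv in scan.findall(_MZML_NS + "cvParam")
        }
        if "profile spectrum" in params:
            raise ValueError(
                f"profile-mode spectrum {scan.get('id')!r}: only centroided data supported"
            )
        rt = 0.0
        for cv in scan.iter(_MZML_NS + "cvParam"):
            if cv.get("name") == "scan start time":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        mzs: list[float] = []
        intens: list[float] = []
        for arr in scan.iter(_MZML_NS + "binaryDataArray"):
            names = {cv.get("name") for cv in arr.findall(_MZML_NS + "cvParam")}
            if "m/z array" in names:
                mzs = _decode_binary_array(arr)
            elif "intensity array" in names:
                intens = _decode_binary_array(arr)
        if not mzs:
            continue
        if params.get("ms level") == "2":
            pre = {
                cv.get("name"): cv.get("value")
                for ion in scan.iter(_MZML_NS + "selectedIon")
                for cv in ion.findall(_MZML_NS + "cvParam")
            }
            pre_mz = float(pre["selected ion m/z"])
            pre_z = int(pre.get("charge state", 1))
            peaks = tuple(sorted(zip(mzs, intens)))
            spectra.append(Spectrum(pre_mz, pre_z, peaks, run_id, rt))
        else:
            for mz, inten in zip(mzs, intens):
                if inten > intensity_floor:
                    features.append(Feature(mz, rt, inten, run_id))
    return features, spectra


def write_spectra_mgf(spectra: Sequence[Spectrum], path: Union[str, Path]) -> None:
    """Write MS/MS spectra as MGF blocks (pyteomics dialect)."""
    from pyteomics import mgf as _mgf

    entries = []
    for i, s in enumerate(spectra):
        entries.append(
            {
                "m/z array": [mz for mz, _ in s.peaks],
                "intensity array": [inten for _, inten in s.peaks],
                "params": {
                    "title": f"{s.run_id}|{i}",
                    "pepmass": s.precursor_mz,
                    "charge": s.precursor_charge,
                    "rtinseconds": s.rt * 60.0,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_spectra_mgf(path: Union[str, Path]) -> list[Spectrum]:
    from pyteomics import mgf as _mgf

    spectra: list[Spectrum] = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", "mgf|0"))
            run_id = title.split("|")[0]
            pepmass = params["pepmass"]
            pre_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge", [1])
            pre_z = int(charge[0]) if isinstance(charge, (list, tuple)) else int(charge)
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            peaks = tuple(
                sorted(zip(map(float, entry["m/z array"]), map(float, entry["intensity array"])))
            )
            spectra.append(Spectrum(pre_mz, pre_z, peaks, run_id, rt))
    return spectra
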