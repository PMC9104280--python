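"""Cross-run grouping of LC-MS features and the presence/absence structure.

Features from many runs are agglomerated greedily in descending area
order: each feature joins the existing group whose consensus lies within
both the ppm and RT tolerances (nearest in ppm wins), otherwise it seeds
a new group. The result is a partition of the input features; per-class
presence fractions and per-batch consistency fractions computed from it
drive marker selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .chem import ppm_error
from .features import Feature, Run

__all__ = ["MatchParams", "AlignedFeature", "align_runs", "presence_matrix"]


@dataclass(frozen=True)
class MatchParams:
    """Tolerances for cross-run feature matching and presence calls.

    ppm_tol: m/z tolerance in ppm (default 20 — wide enough to absorb
        instrument drift between acquisition blocks, tight enough to keep
        distinct tryptic peptides apart at QTOF accuracy).
    rt_tol: retention-time tolerance in minutes (default 0.3).
    min_area: smallest peak area that still counts as "present".
    """

    ppm_tol: float = 20.0
    rt_tol: float = 0.3
    min_area: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "rt_tol", "min_area"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MatchParams.{name} must be strictly positive")


@dataclass
class AlignedFeature:
    """A cross-run feature group with intensity-weighted consensus coordinates."""

    consensus_mz: float
    consensus_rt: float
    members: dict[str, Feature] = field(default_factory=dict)  # run_id -> feature

    def _update_consensus(self) -> None:
        feats = list(self.members.values())
        total = sum(f.area for f in feats)
        if total > 0:
            self.consensus_mz = sum(f.mz * f.area for f in feats) / total
        else:
            self.consensus_mz = sum(f.mz for f in feats) / len(feats)
        self.consensus_rt = sum(f.rt for f in feats) / len(feats)

    def add(self, feature: Feature) -> None:
        self.members[feature.run_id] = feature
        self._update_consensus()

    def present_in(self, run_id: str, min_area: float) -> bool:
        f = self.members.get(run_id)
        return f is not None and f.area >= min_area

    @property
    def charges(self) -> set[int]:
        return {f.charge for f in self.members.values() if f.charge is not None}


def align_runs(
    features: Sequence[Feature],
    params: MatchParams = MatchParams(),
) -> list[AlignedFeature]:
    """Partition features across runs into aligned groups.

    Greedy in descending area (ties broken by m/z, RT, run id for
    determinism). A feature may only join a group that has no member
    from its run yet; among eligible groups the nearest in ppm wins,
    ties going to the nearest RT.
    """
    if not isinstance(params, MatchParams):
        raise TypeError("params must be a MatchParams")
    ordered = sorted(features, key=lambda f: (-f.area, f.mz, f.rt, f.run_id))
    groups: list[AlignedFeature] = []
    for feat in ordered:
        best: Optional[AlignedFeature] = None
        best_key: Optional[tuple[float, float]] = None
        for group in groups:
            if feat.run_id in group.members:
                continue
            dppm = abs(ppm_error(feat.mz, group.consensus_mz))
            drt = abs(feat.rt - group.consensus_rt)
            if dppm <= params.ppm_tol and drt <= params.rt_tol:
                key = (dppm, drt)
                if best_key is None or key < best_key:
                    best, best_key = group, key
        if best is None:
            best = AlignedFeature(feat.mz, feat.rt)
            groups.append(best)
        best.add(feat)
    return groups


def presence_matrix(
    aligned: Sequence[AlignedFeature],
    runs: Mapping[str, Run],
    params: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """Per-class presence fractions and per-class batch-consistency fractions.

    A feature is present in a run iff its member there has area >=
    ``params.min_area``. Class presence fraction = present runs / class
    runs; batch consistency fraction = batches of the class with at least
    one present run / batches of the class. One row per aligned feature,
    columns ``mz``, ``rt``, ``presence:<class>``, ``consistency:<class>``.
    """
    for group in aligned:
        for run_id in group.members:
            if run_id not in runs:
                raise KeyError(f"aligned feature references unknown run {run_id!r}")

    classes: dict[str, list[Run]] = {}
    for run in runs.values():
        classes.setdefault(run.sample_class, []).append(run)

    rows = []
    for group in aligned:
        row: dict[str, float] = {"mz": group.consensus_mz, "rt": group.consensus_rt}
        row["n_members"] = len(group.members)
        for cls, cls_runs in sorted(classes.items()):
            present = [r for r in cls_runs if group.present_in(r.run_id, params.min_area)]
            row[f"presence:{cls}"] = len(present) / len(cls_runs)
            batches = {r.batch for r in cls_runs}
            present_batches = {r.batch for r in present}
            row[f"consistency:{cls}"] = len(present_batches) / len(batches)
        rows.append(row)
    return pd.DataFrame(rows)
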