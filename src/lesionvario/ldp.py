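"""Lesion Discrimination Plot (LDP) descriptors and evolution vectors.

Each lesion pattern is reduced to a single point in a 2D space:

    A = (ln a_x + ln a_y + ln a_z) / 3     (abscissa)
    C = (ln c_x + ln c_y + ln c_z) / 3     (ordinate)

where (a, c) are the per-direction exponential-variogram range (mm) and sill.
Natural logarithms are used throughout, which lets patterns of both mild and
severe lesion load share one plot.  High A means smooth, spatially continuous
lesion surfaces (few extended lesions); low A means complex, fragmented
patterns (many small lesions or ragged aggregates).  C tracks total lesion
volume.  Longitudinal series of descriptors become evolution paths whose step
vectors (dA, dC) summarise growth/confluence (up-right) versus
shrinkage/breakup (down-left); vector magnitudes live in log units and are
semi-quantitative only.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .mask_io import LesionMask, SubjectRecord, total_lesion_volume
from .variography import VariographyConfig, VariogramFit, directional_fits

__all__ = [
    "PatternDescriptor",
    "EvolutionPath",
    "PatternDescriptorExtractor",
    "ldp_coordinates",
    "describe_pattern",
    "describe_cohort",
    "evolution_vector",
    "build_paths",
    "subgroup_total_vector",
    "delta_table",
    "descriptor_frame",
]

logger = logging.getLogger(__name__)

#: Per-axis fits with r^2 below this are flagged (never dropped) in output.
R2_FLAG_THRESHOLD = 0.8


@dataclasses.dataclass
class PatternDescriptor:
    """(A, C) LDP coordinates plus TLV for one subject-timepoint.

    Per-axis fit parameters are retained for audit; ``flagged`` marks any
    axis whose fit quality fell below :data:`R2_FLAG_THRESHOLD`.
    """

    subject_id: str
    timepoint: int
    A: float
    C: float
    tlv_cm3: float
    a_mm: dict[str, float]
    c: dict[str, float]
    r2: dict[str, float]
    flagged: bool = False


def ldp_coordinates(
    fit_x: VariogramFit, fit_y: VariogramFit, fit_z: VariogramFit
) -> tuple[float, float]:
    """Collapse three directional fits to the (A, C) LDP point.

    Requires all three fits converged with strictly positive range and sill.
    """
    fits = (fit_x, fit_y, fit_z)
    for f in fits:
        if not f.converged:
            raise ValueError(f"{f.direction}-direction fit did not converge")
        if f.range_a <= 0 or f.sill_c <= 0:
            raise ValueError(
                f"{f.direction}-direction fit has non-positive parameters "
                f"(a={f.range_a}, c={f.sill_c})"
            )
    A = sum(math.log(f.range_a) for f in fits) / 3.0
    C = sum(math.log(f.sill_c) for f in fits) / 3.0
    return A, C


def describe_pattern(
    mask: LesionMask, config: VariographyConfig | None = None
) -> PatternDescriptor:
    """Full descriptor pipeline for one mask: variograms -> fits -> (A, C) + TLV."""
    try:
        fits = directional_fits(mask, config)
        A, C = ldp_coordinates(fits["x"], fits["y"], fits["z"])
    except ValueError as err:
        raise ValueError(
            f"subject {mask.subject_id!r} timepoint {mask.timepoint}: {err}"
        ) from err
    r2 = {d: f.r_squared for d, f in fits.items()}
    flagged = any(v < R2_FLAG_THRESHOLD for v in r2.values())
    if flagged:
        logger.warning(
            "low-quality variogram fit (r2 < %.2f) for subject %s t%d: %s",
            R2_FLAG_THRESHOLD,
            mask.subject_id,
            mask.timepoint,
            r2,
        )
    return PatternDescriptor(
        subject_id=mask.subject_id,
        timepoint=mask.timepoint,
        A=A,
        C=C,
        tlv_cm3=total_lesion_volume(mask),
        a_mm={d: f.range_a for d, f in fits.items()},
        c={d: f.sill_c for d, f in fits.items()},
        r2=r2,
        flagged=flagged,
    )


class PatternDescriptorExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping lesion masks to LDP descriptor rows.

    A stateless scikit-learn transformer: ``fit`` only validates parameters,
    ``transform`` turns an iterable of :class:`LesionMask` into the
    descriptor :class:`~pandas.DataFrame` (one row per mask, columns
    ``subject_id, timepoint, A, C, tlv_cm3, a_x..r2_z, flagged``), so the
    extraction step composes with sklearn pipelines.

    Parameters
    ----------
    max_lag : float
        Largest variogram lag in mm.
    lag_step : float or None
        Lag increment in mm; ``None`` uses the voxel spacing per axis.
    """

    def __init__(self, max_lag: float = 40.0, lag_step: float | None = None):
        self.max_lag = max_lag
        self.lag_step = lag_step

    def fit(self, X: Iterable[LesionMask] | None = None, y=None):
        if self.max_lag <= 0:
            raise ValueError("max_lag must be positive")
        self.config_ = VariographyConfig(max_lag=self.max_lag, lag_step=self.lag_step)
        return self

    def transform(self, X: Iterable[LesionMask]) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        descriptors = [describe_pattern(mask, self.config_) for mask in X]
        return descriptor_frame(descriptors)


def describe_cohort(
    masks: Iterable[LesionMask], config: VariographyConfig | None = None
) -> list[PatternDescriptor]:
    """Descriptor for every mask; order preserved."""
    return [describe_pattern(m, config) for m in masks]


def descriptor_frame(descriptors: Sequence[PatternDescriptor]) -> pd.DataFrame:
    """Flatten descriptors to the canonical CSV layout."""
    rows = []
    for d in descriptors:
        row = {
            "subject_id": d.subject_id,
            "timepoint": d.timepoint,
            "A": d.A,
            "C": d.C,
            "tlv_cm3": d.tlv_cm3,
        }
        for ax in ("x", "y", "z"):
            row[f"a_{ax}"] = d.a_mm[ax]
            row[f"c_{ax}"] = d.c[ax]
            row[f"r2_{ax}"] = d.r2[ax]
        row["flagged"] = d.flagged
        rows.append(row)
    return pd.DataFrame(rows)


def evolution_vector(
    d1: PatternDescriptor, d2: PatternDescriptor
) -> tuple[float, float, float]:
    """(dA, dC, magnitude) of the LDP step from d1 to d2 (same subject)."""
    if d1.subject_id != d2.subject_id:
        raise ValueError(
            f"descriptors belong to different subjects "
            f"({d1.subject_id!r} vs {d2.subject_id!r})"
        )
    if d2.timepoint <= d1.timepoint:
        raise ValueError(
            f"timepoints must increase, got {d1.timepoint} -> {d2.timepoint}"
        )
    dA = d2.A - d1.A
    dC = d2.C - d1.C
    return dA, dC, math.hypot(dA, dC)


@dataclasses.dataclass
class EvolutionPath:
    """Ordered LDP positions of one subject with per-step vectors."""

    subject_id: str
    descriptors: list[PatternDescriptor]
    steps: list[tuple[float, float, float]]

    @classmethod
    def from_descriptors(cls, descriptors: Iterable[PatternDescriptor]) -> "EvolutionPath":
        descs = sorted(descriptors, key=lambda d: d.timepoint)
        if not descs:
            raise ValueError("cannot build a path from zero descriptors")
        subject = descs[0].subject_id
        if any(d.subject_id != subject for d in descs):
            raise ValueError("path descriptors must share one subject")
        steps = [
            evolution_vector(a, b) for a, b in zip(descs[:-1], descs[1:])
        ]
        return cls(subject_id=subject, descriptors=descs, steps=steps)

    @property
    def first(self) -> PatternDescriptor:
        return self.descriptors[0]

    @property
    def last(self) -> PatternDescriptor:
        return self.descriptors[-1]

    def total_vector(self) -> tuple[float, float, float]:
        """Endpoint-to-endpoint (dA, dC, magnitude); equals the step sum."""
        return evolution_vector(self.first, self.last)


def build_paths(
    descriptors: Iterable[PatternDescriptor],
) -> dict[str, EvolutionPath]:
    """Group descriptors by subject into evolution paths (subjects with a
    single timepoint yield a path with no steps)."""
    by_subject: dict[str, list[PatternDescriptor]] = {}
    for d in descriptors:
        by_subject.setdefault(d.subject_id, []).append(d)
    return {
        sid: EvolutionPath.from_descriptors(ds) for sid, ds in by_subject.items()
    }


def subgroup_total_vector(
    paths: Mapping[str, EvolutionPath] | Sequence[EvolutionPath],
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-subgroup total vectors from componentwise medians.

    The start of a subgroup's total vector is the (median A, median C) of its
    members at their first timepoint, the end the same at the last timepoint;
    the vector is end minus start.
    """
    if not isinstance(paths, Mapping):
        paths = {p.subject_id: p for p in paths}
    by_group: dict[str, list[EvolutionPath]] = {}
    for sid, path in paths.items():
        if sid not in labels:
            logger.warning("subject %s has no subgroup label; skipped", sid)
            continue
        by_group.setdefault(labels[sid], []).append(path)
    if not by_group:
        raise ValueError("no labelled subjects; cannot form subgroup vectors")
    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        A1 = float(np.median([p.first.A for p in members]))
        C1 = float(np.median([p.first.C for p in members]))
        A2 = float(np.median([p.last.A for p in members]))
        C2 = float(np.median([p.last.C for p in members]))
        rows.append(
            {
                "subgroup": group,
                "n": len(members),
                "A_start": A1,
                "C_start": C1,
                "A_end": A2,
                "C_end": C2,
                "dA": A2 - A1,
                "dC": C2 - C1,
                "magnitude": math.hypot(A2 - A1, C2 - C1),
            }
        )
    return pd.DataFrame(rows)


def delta_table(
    paths: Mapping[str, EvolutionPath] | Sequence[EvolutionPath],
    labels: Mapping[str, str],
    records: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Subgroup table relating A to EDSS at the first and last timepoints.

    A is summarised by subgroup medians (consistent with box-plot medians);
    EDSS by subgroup means.  Subjects missing an EDSS value at either
    endpoint are excluded with a logged warning.
    """
    if not isinstance(paths, Mapping):
        paths = {p.subject_id: p for p in paths}
    edss = {(r.subject_id, r.timepoint): r.edss for r in records}
    by_group: dict[str, list[tuple[EvolutionPath, float, float]]] = {}
    for sid, path in paths.items():
        if sid not in labels:
            continue
        key1 = (sid, path.first.timepoint)
        key2 = (sid, path.last.timepoint)
        if key1 not in edss or key2 not in edss:
            logger.warning("subject %s lacks EDSS at an endpoint; excluded", sid)
            continue
        by_group.setdefault(labels[sid], []).append((path, edss[key1], edss[key2]))
    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        A1 = float(np.median([p.first.A for p, _, _ in members]))
        A2 = float(np.median([p.last.A for p, _, _ in members]))
        E1 = float(np.mean([e1 for _, e1, _ in members]))
        E2 = float(np.mean([e2 for _, _, e2 in members]))
        rows.append(
            {
                "subgroup": group,
                "n": len(members),
                "A_first": A1,
                "EDSS_first": E1,
                "A_last": A2,
                "EDSS_last": E2,
                "dA": A2 - A1,
                "dEDSS": E2 - E1,
            }
        )
    return pd.DataFrame(rows)
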