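"""End-to-end orchestration: simulate/load -> describe -> subgroup -> vectors
-> longitudinal statistics -> report.

A run is driven by a single :class:`RunConfig` (loadable from YAML/JSON) and
writes a self-describing output directory: descriptor CSV, subgroup
assignments, per-subject and per-subgroup vector CSVs, the delta table,
nonparametric test results, the mixed-model report and plots, plus a
``manifest.json`` recording the configuration hash, seeds and library
versions so every output is regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ldp import (
    PatternDescriptorExtractor,
    build_paths,
    delta_table,
    subgroup_total_vector,
)
from .mask_io import LesionMask, SubjectRecord, read_mask, read_metadata, write_mask
from .stats import fit_longitudinal_model, kruskal_wallis, mann_whitney
from .subgrouping import bic_report, subgroup_baseline
from .synthetic import default_cohort_spec, generate_cohort
logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    mode: str = "simulate"  # "simulate" | "masks"
    output_dir: str = "lesionvario_run"
    master_seed: int = 0
    # simulate mode
    cohort: dict[str, Any] = dataclasses.field(
        default_factory=lambda: {"nF1": 10, "nF2": 5, "nM1": 10, "nM2": 5}
    )
    write_masks: bool = False
    # masks mode
    mask_paths: dict[str, Any] | None = None  # {subject_id: {timepoint: path}}
    metadata_csv: str | None = None
    # analysis parameters
    max_lag: float = 40.0
    lag_step: float | None = None
    gmm_seed: int = 0
    gmm_restarts: int = 20
    make_plots: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls(**payload)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_masks(config: RunConfig) -> tuple[list[LesionMask], list[SubjectRecord], dict | None]:
    if config.mode == "simulate":
        spec = default_cohort_spec(master_seed=config.master_seed, **config.cohort)
        masks, records, truth = generate_cohort(spec)
        return masks, records, truth
    if config.mode != "masks":
        raise ValueError(f"unknown mode {config.mode!r}; expected simulate or masks")
    if not config.mask_paths or not config.metadata_csv:
        raise ValueError("masks mode needs mask_paths and metadata_csv")
    records = read_metadata(config.metadata_csv)
    masks = []
    for sid, by_tp in config.mask_paths.items():
        for tp, path in sorted(by_tp.items(), key=lambda kv: int(kv[0])):
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"mask for {sid} t{tp} not found: {p}")
            masks.append(read_mask(p, subject_id=str(sid), timepoint=int(tp)))
    return masks, records, None


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        masks, records, truth = _load_masks(config)
        metadata = pd.DataFrame([dataclasses.asdict(r) for r in records])
        metadata.to_csv(out / "metadata.csv", index=False)
        if truth is not None:
            pd.DataFrame(
                sorted(truth.items()), columns=["subject_id", "true_label"]
            ).to_csv(out / "ground_truth_labels.csv", index=False)
        if config.mode == "simulate" and config.write_masks:
            mask_dir = out / "masks"
            mask_dir.mkdir(exist_ok=True)
            for m in masks:
                write_mask(m, mask_dir / f"{m.subject_id}_t{m.timepoint}.nii.gz")

        stage = "describe"
        extractor = PatternDescriptorExtractor(
            max_lag=config.max_lag, lag_step=config.lag_step
        ).fit()
        descriptors = extractor.transform(masks)
        descriptors.to_csv(out / "descriptors.csv", index=False)

        stage = "subgroups"
        assignments, models = subgroup_baseline(
            descriptors, metadata, seed=config.gmm_seed
        )
        assignments.to_csv(out / "assignments.csv", index=False)
        model_params = {
            gender: {
                "weights": model.weights_.tolist(),
                "means": model.means_.tolist(),
                "covariances": model.covariances_.tolist(),
                "log_likelihood": model.log_likelihood_,
                "avg_map_per_label": _avg_map(assignments, gender),
            }
            for gender, model in models.items()
        }
        (out / "gmm_models.json").write_text(json.dumps(model_params, indent=2))
        base = descriptors[descriptors["timepoint"] == descriptors["timepoint"].min()]
        bic_frames = []
        for gender in models:
            subj = assignments.loc[assignments["gender"] == gender, "subject_id"]
            pts = base[base["subject_id"].isin(subj)][["A", "C"]].to_numpy()
            rep = bic_report(pts, seed=config.gmm_seed)
            rep.insert(0, "gender", gender)
            bic_frames.append(rep)
        pd.concat(bic_frames).to_csv(out / "gmm_bic_diagnostic.csv", index=False)

        stage = "vectors"
        from .ldp import PatternDescriptor

        desc_objs = _rows_to_descriptors(descriptors)
        paths = build_paths(desc_objs)
        labels = dict(zip(assignments["subject_id"], assignments["label"]))
        incomplete = [
            sid for sid, p in paths.items() if len(p.descriptors) < 2
        ]
        for sid in incomplete:
            logger.warning("subject %s has a single timepoint; no vectors", sid)
        vec_rows = [
            {
                "subject_id": sid,
                "label": labels.get(sid, ""),
                "A_start": p.first.A,
                "C_start": p.first.C,
                "A_end": p.last.A,
                "C_end": p.last.C,
                **dict(zip(("dA", "dC", "magnitude"), p.total_vector())),
            }
            for sid, p in paths.items()
            if len(p.descriptors) >= 2
        ]
        pd.DataFrame(vec_rows).to_csv(out / "subject_vectors.csv", index=False)
        full_paths = {s: p for s, p in paths.items() if len(p.descriptors) >= 2}
        totals = subgroup_total_vector(full_paths, labels)
        totals.to_csv(out / "subgroup_total_vectors.csv", index=False)
        deltas = delta_table(full_paths, labels, records)
        deltas.to_csv(out / "delta_table.csv", index=False)

        stage = "longitudinal"
        merged = descriptors.merge(
            assignments[["subject_id", "gender", "label"]], on="subject_id"
        )
        tests = _nonparametric_tests(merged)
        tests.to_csv(out / "tests.csv", index=False)
        mm_reports = {}
        small = merged[merged["label"].isin(["F2", "M2"])]
        if small["gender"].nunique() == 2 and (
            small.groupby("gender")["subject_id"].nunique() >= 2
        ).all():
            for response in ("A", "C"):
                res = fit_longitudinal_model(small, response=response)
                mm_reports[response] = {
                    "fixed_effects": res.fixed_effects.to_dict(orient="index"),
                    "random_intercept_var": res.random_intercept_var,
                    "random_slope_var": res.random_slope_var,
                    "random_corr": res.random_corr,
                    "residual_var": res.residual_var,
                    "n_subjects": res.n_subjects,
                    "n_observations": res.n_observations,
                    "converged": res.converged,
                    "singular": res.singular,
                    "method": res.method,
                }
        (out / "mixed_model.json").write_text(json.dumps(mm_reports, indent=2))

        if config.make_plots:
            stage = "plots"
            from . import plots

            plots.ldp_scatter(
                merged, hue="label", path=out / "ldp_scatter.png"
            )
            plots.evolution_plot(
                full_paths, labels, totals, path=out / "evolution.png"
            )
            plots.box_whisker_longitudinal(
                descriptors, assignments, "A", path=out / "box_A.png"
            )
            plots.box_whisker_longitudinal(
                descriptors, assignments, "C", path=out / "box_C.png"
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "n_masks": len(masks),
        "n_subjects": int(metadata["subject_id"].nunique()),
        "versions": _versions(),
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _avg_map(assignments: pd.DataFrame, gender: str) -> dict[str, float]:
    sub = assignments[assignments["gender"] == gender]
    return {
        str(lab): float(grp["map_prob"].mean()) for lab, grp in sub.groupby("label")
    }


def _rows_to_descriptors(frame: pd.DataFrame):
    from .ldp import PatternDescriptor

    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PatternDescriptor(
                subject_id=row.subject_id,
                timepoint=int(row.timepoint),
                A=float(row.A),
                C=float(row.C),
                tlv_cm3=float(row.tlv_cm3),
                a_mm={ax: float(getattr(row, f"a_{ax}")) for ax in "xyz"},
                c={ax: float(getattr(row, f"c_{ax}")) for ax in "xyz"},
                r2={ax: float(getattr(row, f"r2_{ax}")) for ax in "xyz"},
                flagged=bool(getattr(row, "flagged", False)),
            )
        )
    return out


def _nonparametric_tests(merged: pd.DataFrame) -> pd.DataFrame:
    """KW across timepoints within each subgroup; MW between subgroups at each
    timepoint (within gender, plus F2 vs M2). Raw p-values, alpha=0.05."""
    rows = []
    for response in ("A", "C"):
        for label, sub in merged.groupby("label"):
            groups = [g[response].to_numpy() for _, g in sub.groupby("timepoint")]
            if len(groups) >= 2 and all(len(g) for g in groups):
                H, p = kruskal_wallis(*groups)
                rows.append(
                    {
                        "response": response,
                        "test": "kruskal_wallis",
                        "contrast": f"{label}: across timepoints",
                        "statistic": H,
                        "p_value": p,
                    }
                )
        contrasts = [("F1", "F2"), ("M1", "M2"), ("F2", "M2")]
        for tp, at_tp in merged.groupby("timepoint"):
            for g1, g2 in contrasts:
                v1 = at_tp.loc[at_tp["label"] == g1, response].to_numpy()
                v2 = at_tp.loc[at_tp["label"] == g2, response].to_numpy()
                if len(v1) and len(v2):
                    U, p = mann_whitney(v1, v2)
                    rows.append(
                        {
                            "response": response,
                            "test": "mann_whitney",
                            "contrast": f"{g1} vs {g2} @ t{tp}",
                            "statistic": U,
                            "p_value": p,
                        }
                    )
    return pd.DataFrame(rows)


def _versions() -> dict[str, str]:
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "nibabel": nibabel.__version__,
    }
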