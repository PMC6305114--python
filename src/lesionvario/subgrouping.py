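"""Baseline subgrouping of (A, C) LDP points with Gaussian mixtures.

Within each gender, the baseline (first-MRI) LDP coordinates are modelled as
a 2-component full-covariance Gaussian mixture fitted by EM.  Each subject is
assigned to the component with the larger posterior; the posterior maximum is
the MAP class-membership probability.  By convention subgroup 1 is the
larger cluster (the one stretching along the LDP diagonal) and subgroup 2
the smaller, high-(A, C) cluster; ties are broken toward the component with
the lower mean A.  k is fixed at 2 — a diagnostic BIC table over k = 1..4
can be produced but never changes the model.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SubgroupMixture",
    "SubgroupAssignment",
    "fit_gmm",
    "assign_subgroups",
    "bic_report",
    "subgroup_baseline",
]


@dataclasses.dataclass
class SubgroupAssignment:
    """Cluster assignment of one baseline LDP point."""

    subject_id: str
    label: int  # 1 = larger subgroup, 2 = smaller
    posteriors: tuple[float, float]  # ordered by label
    map_prob: float


class DegenerateMixtureError(ValueError):
    """EM collapsed (a component's covariance lost rank)."""


class SubgroupMixture(BaseEstimator):
    """Two-component Gaussian mixture over baseline (A, C) points.

    A scikit-learn estimator wrapping EM with multiple seeded restarts and a
    deterministic relabelling convention, so the reported subgroup labels do
    not depend on initialisation order.

    Parameters
    ----------
    n_components : int
        Number of mixture components (fixed at 2 for the analysis; exposed
        for diagnostics only).
    n_restarts : int
        EM restarts; the best log-likelihood solution is kept.
    tol, max_iter : float, int
        EM convergence tolerance on the log-likelihood and iteration cap.
    random_state : int
        Seed controlling all restarts.

    Attributes
    ----------
    weights_ : ndarray of shape (k,)
        Mixing weights, ordered so component 0 is subgroup 1 (larger).
    means_ : ndarray of shape (k, 2)
        Component means in (A, C) space.
    covariances_ : ndarray of shape (k, 2, 2)
        Full covariance matrices.
    log_likelihood_ : float
        Total log-likelihood of the training points.
    labels_ : ndarray of shape (n,)
        Training-point labels in {1, 2}.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 20,
        tol: float = 1e-6,
        max_iter: int = 500,
        reg_covar: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (A, C) points")
        if not np.isfinite(X).all():
            raise ValueError("(A, C) points must be finite")
        if len(X) < 2 * self.n_components:
            raise ValueError(
                f"need at least {2 * self.n_components} points to fit "
                f"{self.n_components} components, got {len(X)}"
            )
        if np.allclose(X, X[0]):
            raise DegenerateMixtureError(
                "all points identical; mixture covariances would collapse"
            )
        gm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            tol=self.tol,
            max_iter=self.max_iter,
            n_init=self.n_restarts,
            reg_covar=self.reg_covar,
            random_state=self.random_state,
        )
        gm.fit(X)
        hard = gm.predict(X)
        for i in range(self.n_components):
            members = X[hard == i]
            # a component whose members carry no scatter at all has collapsed
            # onto duplicated points; regularisation alone props it up
            if len(members) >= 2 and np.allclose(members, members[0]):
                raise DegenerateMixtureError(
                    f"component {i} collapsed onto {len(members)} identical points"
                )
        order = self._label_order(gm, X)
        self.weights_ = gm.weights_[order]
        self.means_ = gm.means_[order]
        self.covariances_ = gm.covariances_[order]
        self.log_likelihood_ = float(gm.score(X) * len(X))
        self._gm = gm
        self._order = order
        self.labels_ = self.predict(X)
        return self

    @staticmethod
    def _label_order(gm: GaussianMixture, X: np.ndarray) -> np.ndarray:
        """Component order: subgroup 1 = more assigned members, ties -> lower mean A."""
        hard = gm.predict(X)
        counts = np.bincount(hard, minlength=gm.n_components)
        meanA = gm.means_[:, 0]
        # sort by (-count, mean A): biggest cluster first, lower-A first on ties
        return np.lexsort((meanA, -counts))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_gm")
        return self._gm.predict_proba(np.asarray(X, dtype=float))[:, self._order]

    def predict(self, X) -> np.ndarray:
        """Labels in {1, 2} (1 = larger subgroup)."""
        return np.argmax(self.predict_proba(X), axis=1) + 1

    def map_probabilities(self, X) -> np.ndarray:
        """Per-point maximum a posteriori membership probability."""
        return self.predict_proba(X).max(axis=1)

    def bic(self, X) -> float:
        check_is_fitted(self, "_gm")
        return float(self._gm.bic(np.asarray(X, dtype=float)))


def fit_gmm(
    points: Sequence[Sequence[float]] | np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
) -> SubgroupMixture:
    """Fit the k-component mixture to baseline (A, C) points (thin wrapper)."""
    return SubgroupMixture(
        n_components=k, n_restarts=n_restarts, random_state=seed
    ).fit(np.asarray(points, dtype=float))


def assign_subgroups(
    model: SubgroupMixture,
    points: np.ndarray,
    subject_ids: Sequence[str] | None = None,
) -> tuple[list[SubgroupAssignment], dict[int, float]]:
    """Label each point by argmax posterior; report average MAP per label."""
    points = np.asarray(points, dtype=float)
    proba = model.predict_proba(points)
    labels = np.argmax(proba, axis=1) + 1
    if subject_ids is None:
        subject_ids = [str(i) for i in range(len(points))]
    assignments = [
        SubgroupAssignment(
            subject_id=sid,
            label=int(lab),
            posteriors=tuple(float(p) for p in row),
            map_prob=float(row.max()),
        )
        for sid, lab, row in zip(subject_ids, labels, proba)
    ]
    avg_map = {
        int(lab): float(np.mean([a.map_prob for a in assignments if a.label == lab]))
        for lab in np.unique(labels)
    }
    return assignments, avg_map


def bic_report(points: np.ndarray, seed: int = 0, k_range=range(1, 5)) -> pd.DataFrame:
    """Diagnostic BIC over candidate component counts; never selects k."""
    points = np.asarray(points, dtype=float)
    rows = []
    for k in k_range:
        if len(points) < 2 * k:
            continue
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=5, random_state=seed
        ).fit(points)
        rows.append({"k": k, "bic": float(gm.bic(points))})
    return pd.DataFrame(rows)


def subgroup_baseline(
    descriptors: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 0,
    baseline_timepoint: int | None = None,
) -> tuple[pd.DataFrame, dict[str, SubgroupMixture]]:
    """Per-gender baseline GMM subgrouping of a descriptor table.

    ``descriptors`` is the canonical descriptor frame (subject_id, timepoint,
    A, C, ...); ``metadata`` supplies gender per subject.  Returns an
    assignment frame with columns ``subject_id, gender, label, map_prob``
    (label like ``F1``/``F2``/``M1``/``M2``) and the fitted model per gender.
    """
    gender_by_subject = (
        metadata.drop_duplicates("subject_id").set_index("subject_id")["gender"]
    )
    tp = baseline_timepoint or int(descriptors["timepoint"].min())
    base = descriptors[descriptors["timepoint"] == tp].copy()
    base["gender"] = base["subject_id"].map(gender_by_subject)
    if base["gender"].isna().any():
        missing = base.loc[base["gender"].isna(), "subject_id"].tolist()
        raise ValueError(f"subjects missing gender metadata: {missing}")
    rows = []
    models: dict[str, SubgroupMixture] = {}
    for gender, sub in base.groupby("gender"):
        pts = sub[["A", "C"]].to_numpy()
        model = fit_gmm(pts, seed=seed)
        models[str(gender)] = model
        assignments, _ = assign_subgroups(model, pts, sub["subject_id"].tolist())
        for a in assignments:
            rows.append(
                {
                    "subject_id": a.subject_id,
                    "gender": gender,
                    "label": f"{gender}{a.label}",
                    "map_prob": a.map_prob,
                }
            )
    frame = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    return frame, models
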