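"""Hit calling on aligned profiles, with or without a positive control.

Positive-control mode: a linear discriminant axis is computed from the two
control populations, w ∝ S_pooled⁻¹ (μ_pos − μ_neg), every well is projected
on it, and the conditions whose projections exceed the (1 − f) quantile of
per-condition scores (f defaults to 1% of the tested compounds) in *every*
replicate are called hits.

No-positive-control mode: the negative-control wells define a multivariate
baseline distribution (mean + shrinkage-regularized covariance); each well's
Mahalanobis distance to it measures phenotypic departure from untreated
cells.  Conditions beyond a distance threshold are hits, and the hits are
grouped by Ward hierarchical clustering so each phenotype cluster can be
inspected through its representative (the member closest to the cluster
center).

Profile dimensionality D (512 per channel for deep features) typically
exceeds the number of control wells by far, so covariances are shrunk toward
a scaled identity, S_reg = (1−λ)S + λ·(tr(S)/D)·I, with λ from the
Ledoit–Wolf analytic rule unless overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .plate_model import ControlRole, FeatureTable, PlateLayout, split_channel_blocks

logger = logging.getLogger(__name__)

DEFAULT_HIT_FRACTION = 0.01
DEFAULT_N_CLUSTERS = 6


class HitSelectionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Condition bookkeeping


def condition_frame(table: FeatureTable, layouts: list[PlateLayout]) -> pd.DataFrame:
    """Per-row (condition_id, role) annotation of a feature table."""
    lookup = {
        (lay.plate_id, lay.replicate_id, str(well)): (cond, role.value)
        for lay in layouts
        for well, (cond, role) in lay.wells.items()
    }
    rows = []
    for key in table.data.index:
        if key not in lookup:
            raise HitSelectionError(f"no plate-map entry for well {key}")
        rows.append(lookup[key])
    return pd.DataFrame(rows, index=table.data.index, columns=["condition_id", "role"])


def _rows_with_role(table: FeatureTable, layouts: list[PlateLayout], role: ControlRole) -> np.ndarray:
    ann = condition_frame(table, layouts)
    mask = (ann["role"] == role.value).to_numpy()
    if not mask.any():
        raise HitSelectionError(f"screen has no {role.value}-control wells")
    return table.data.to_numpy()[mask]


# ---------------------------------------------------------------------------
# Covariance with shrinkage


def _shrunk_covariance(
    centered: np.ndarray, regularization: str | float = "auto"
) -> tuple[np.ndarray, float]:
    """Covariance of already-centered rows, shrunk toward tr(S)/D · I."""
    n, d = centered.shape
    emp = centered.T @ centered / n
    if regularization == "none":
        lam = 0.0
    elif regularization == "auto":
        from sklearn.covariance import ledoit_wolf_shrinkage

        lam = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    else:
        lam = float(regularization)
        if not 0.0 <= lam <= 1.0:
            raise HitSelectionError(f"shrinkage must be in [0, 1], got {lam}")
    mu = np.trace(emp) / d
    cov = (1.0 - lam) * emp + lam * mu * np.eye(d)
    return cov, lam


@dataclass
class CovarianceModel:
    """Gaussian model of the negative-control distribution."""

    mean: np.ndarray
    covariance: np.ndarray
    shrinkage: float
    condition_number: float
    regularization: str = "ledoit-wolf"
    _chol: tuple = field(default=None, repr=False)

    def __post_init__(self):
        try:
            self._chol = cho_factor(self.covariance)
        except np.linalg.LinAlgError as err:
            raise HitSelectionError(
                "covariance is singular (not positive-definite); "
                "fit with shrinkage regularization"
            ) from err

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.shape[0]:
            raise HitSelectionError(
                f"dimension mismatch: model is {self.mean.shape[0]}-d, data is {X.shape[1]}-d"
            )
        delta = X - self.mean
        solved = cho_solve(self._chol, delta.T)
        return np.sqrt(np.einsum("ij,ji->i", delta, solved))


def fit_negative_model(
    neg_rows: np.ndarray, regularization: str | float = "auto"
) -> CovarianceModel:
    """Mean and shrinkage-regularized covariance of the negative controls.

    With fewer control wells than feature dimensions the sample covariance is
    singular; ``regularization='none'`` then refuses, while the default
    Ledoit–Wolf shrinkage guarantees a positive-definite estimate.
    """
    X = np.asarray(neg_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise HitSelectionError("need at least 2 negative-control wells to fit a model")
    mean = X.mean(axis=0)
    cov, lam = _shrunk_covariance(X - mean, regularization)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0:
        raise HitSelectionError(
            f"covariance not positive-definite (min eigenvalue {eigvals[0]:.3g}); "
            "increase shrinkage"
        )
    cond = float(eigvals[-1] / eigvals[0])
    reg_name = "none" if regularization == "none" else (
        "ledoit-wolf" if regularization == "auto" else "fixed"
    )
    return CovarianceModel(mean, cov, shrinkage=lam, condition_number=cond, regularization=reg_name)


def mahalanobis_scores(table: FeatureTable, model: CovarianceModel) -> pd.Series:
    """Mahalanobis distance of every well to the negative-control distribution."""
    d = model.mahalanobis(table.data.to_numpy())
    return pd.Series(d, index=table.data.index, name="distance")


# ---------------------------------------------------------------------------
# Positive-control branch: linear discriminant axis


def fit_discriminant_axis(
    neg: np.ndarray, pos: np.ndarray, regularization: str | float = "auto"
) -> np.ndarray:
    """Direction best separating negative from positive controls.

    Closed-form two-class LDA: w ∝ S_pooled⁻¹ (μ_pos − μ_neg) with the pooled
    within-class covariance shrunk as above; returned with unit norm and
    oriented so positive controls project higher than negative ones.
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.shape[0] < 2 or pos.shape[0] < 2:
        raise HitSelectionError("need at least 2 wells per control class")
    mu_n, mu_p = neg.mean(axis=0), pos.mean(axis=0)
    delta = mu_p - mu_n
    if np.allclose(delta, 0.0):
        raise HitSelectionError("controls not separable: identical class means")
    within = np.vstack([neg - mu_n, pos - mu_p])
    cov, _ = _shrunk_covariance(within, regularization)
    w = cho_solve(cho_factor(cov), delta)
    w = w / np.linalg.norm(w)
    if w @ delta < 0:  # orient positive-control-high
        w = -w
    return w


@dataclass
class DiscriminantResult:
    """LDA axis, per-well projections, threshold, and gated hit calls."""

    axis: np.ndarray
    scores: pd.Series  # per (plate, replicate, well)
    per_condition: pd.DataFrame  # condition × [display_score, replicate scores..., hit]
    threshold: float
    hit_fraction: float
    hits: set[str]


def _gate_conditions(
    scores: pd.Series,
    ann: pd.DataFrame,
    hit_fraction: float,
    threshold: float | None = None,
    score_name: str = "display_score",
) -> tuple[pd.DataFrame, float, set[str]]:
    """Shared quantile-threshold + all-replicates gating of per-well scores.

    The threshold is the (1 − f) quantile of per-condition display scores
    (mean over replicates) of sample conditions only; controls are excluded
    from the quantile.  A condition is a hit iff the score of *every* one of
    its replicates strictly exceeds the threshold.
    """
    df = pd.DataFrame({"score": scores, "condition_id": ann["condition_id"], "role": ann["role"]})
    df = df.reset_index()
    samples = df[df["role"] == ControlRole.sample.value]
    n_reps = df["replicate_id"].nunique()
    per_rep = samples.groupby(["condition_id", "replicate_id"])["score"].mean().unstack("replicate_id")
    complete = per_rep.dropna()
    dropped = per_rep.index.difference(complete.index)
    if len(dropped):
        logger.warning(
            "%d condition(s) excluded for missing replicates: %s",
            len(dropped), list(dropped[:5]),
        )
    if per_rep.shape[1] != n_reps:
        logger.warning("some replicates contributed no sample wells")
    display = complete.mean(axis=1)
    if threshold is None:
        if not 0.0 < hit_fraction < 0.5:
            raise HitSelectionError(f"hit_fraction must be in (0, 0.5), got {hit_fraction}")
        threshold = float(np.quantile(display.to_numpy(), 1.0 - hit_fraction))
    hits = set(complete.index[(complete > threshold).all(axis=1)])
    out = complete.copy()
    out.columns = [f"score_{c}" for c in out.columns]
    out.insert(0, score_name, display)
    out["hit"] = [c in hits for c in out.index]
    return out, float(threshold), hits


def project_and_threshold(
    table: FeatureTable,
    layouts: list[PlateLayout],
    axis: np.ndarray,
    hit_fraction: float = DEFAULT_HIT_FRACTION,
) -> DiscriminantResult:
    """Project every well on the discriminant axis and call hits.

    The displayed score of a condition is the mean of its replicate
    projections, but every replicate must individually clear the threshold
    for the condition to be a hit — a condition whose mean sits above the
    line can still fail the gate.
    """
    scores = pd.Series(table.data.to_numpy() @ axis, index=table.data.index, name="score")
    ann = condition_frame(table, layouts)
    per_condition, threshold, hits = _gate_conditions(scores, ann, hit_fraction)
    return DiscriminantResult(
        axis=axis,
        scores=scores,
        per_condition=per_condition,
        threshold=threshold,
        hit_fraction=hit_fraction,
        hits=hits,
    )


def run_positive_mode(
    table: FeatureTable,
    layouts: list[PlateLayout],
    hit_fraction: float = DEFAULT_HIT_FRACTION,
    regularization: str | float = "auto",
) -> DiscriminantResult:
    """Fit the control axis and call hits in one step (positive-control mode)."""
    neg = _rows_with_role(table, layouts, ControlRole.negative)
    pos = _rows_with_role(table, layouts, ControlRole.positive)
    axis = fit_discriminant_axis(neg, pos, regularization)
    return project_and_threshold(table, layouts, axis, hit_fraction)


# ---------------------------------------------------------------------------
# No-positive-control branch: Mahalanobis outliers + phenotype clustering


@dataclass
class OutlierReport:
    """Distances, hit calls and phenotype clusters of the no-control branch."""

    distances: pd.Series  # per (plate, replicate, well)
    per_condition: pd.DataFrame  # condition × [distance, replicate distances..., hit]
    distance_threshold: float
    hits: set[str]
    cluster_labels: dict[str, int] = field(default_factory=dict)
    representatives: dict[int, str] = field(default_factory=dict)
    model: CovarianceModel | None = None
    per_channel_distances: pd.DataFrame | None = None


def call_outlier_hits(
    distances: pd.Series,
    ann: pd.DataFrame,
    hit_fraction: float = DEFAULT_HIT_FRACTION,
    distance_threshold: float | None = None,
) -> tuple[pd.DataFrame, float, set[str]]:
    """Threshold Mahalanobis distances into hits.

    Default threshold is the (1 − f) quantile of per-condition sample
    distances (same default fraction as the positive-control branch); an
    absolute distance may be supplied instead.  Replicate gating is identical
    to the discriminant branch: all replicates must exceed the threshold.
    """
    return _gate_conditions(
        distances, ann, hit_fraction, threshold=distance_threshold, score_name="distance"
    )


def cluster_hits(
    hit_profiles: pd.DataFrame, k: int = DEFAULT_N_CLUSTERS
) -> tuple[dict[str, int], dict[int, str]]:
    """Group hit conditions into k phenotype clusters (Ward linkage, Euclidean).

    ``hit_profiles`` is condition × features (replicate-averaged aligned
    profiles).  Returns cluster labels 1..k per condition and, per cluster,
    the representative condition closest to the cluster mean.  If fewer hits
    than k exist, k is lowered with a warning.
    """
    from sklearn.cluster import AgglomerativeClustering

    n = hit_profiles.shape[0]
    if n == 0:
        return {}, {}
    if n < k:
        logger.warning("only %d hits; lowering cluster count from %d", n, k)
        k = n
    X = hit_profiles.to_numpy()
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    cluster_labels = {cond: int(lab) + 1 for cond, lab in zip(hit_profiles.index, labels)}
    representatives: dict[int, str] = {}
    for lab in range(k):
        members = np.where(labels == lab)[0]
        center = X[members].mean(axis=0)
        best = members[int(np.argmin(np.linalg.norm(X[members] - center, axis=1)))]
        representatives[lab + 1] = hit_profiles.index[best]
    return cluster_labels, representatives


def per_channel_scores(
    table: FeatureTable,
    layouts: list[PlateLayout],
    channel: int,
    regularization: str | float = "auto",
) -> pd.Series:
    """Mahalanobis distances computed on one channel's feature block only.

    Separates channel-specific effects (e.g. a brightness phenotype confined
    to the cell channel) from whole-profile distance.
    """
    channels = layouts[0].channels
    if not 1 <= channel <= channels:
        raise HitSelectionError(f"channel {channel} out of range 1..{channels}")
    block = split_channel_blocks(table.n_features, channels)[channel - 1]
    sub = FeatureTable(table.data.iloc[:, block], state=table.state)
    neg = _rows_with_role(sub, layouts, ControlRole.negative)
    model = fit_negative_model(neg, regularization)
    return mahalanobis_scores(sub, model).rename(f"distance_ch{channel}")


def run_negative_mode(
    table: FeatureTable,
    layouts: list[PlateLayout],
    hit_fraction: float = DEFAULT_HIT_FRACTION,
    distance_threshold: float | None = None,
    k: int = DEFAULT_N_CLUSTERS,
    regularization: str | float = "auto",
    per_channel: bool = False,
) -> OutlierReport:
    """Full no-positive-control analysis: distances → hits → phenotype clusters."""
    neg = _rows_with_role(table, layouts, ControlRole.negative)
    model = fit_negative_model(neg, regularization)
    distances = mahalanobis_scores(table, model)
    ann = condition_frame(table, layouts)
    per_condition, threshold, hits = call_outlier_hits(
        distances, ann, hit_fraction, distance_threshold
    )
    # replicate-averaged aligned profiles of the hit conditions
    prof = table.data.copy()
    prof["condition_id"] = ann["condition_id"]
    mean_profiles = prof.groupby("condition_id").mean()
    hit_profiles = mean_profiles.loc[sorted(hits)]
    cluster_labels, representatives = cluster_hits(hit_profiles, k)
    report = OutlierReport(
        distances=distances,
        per_condition=per_condition,
        distance_threshold=threshold,
        hits=hits,
        cluster_labels=cluster_labels,
        representatives=representatives,
        model=model,
    )
    if per_channel:
        cols = {
            f"ch{c}": per_channel_scores(table, layouts, c, regularization)
            for c in range(1, layouts[0].channels + 1)
        }
        report.per_channel_distances = pd.DataFrame(cols)
    return report
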