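"""Nearest-shrunken-centroid classification, limited-signature selection,
the combined normalized-sum score, and ROC evaluation.

Features for the centroid model are expected on a variance-stabilized
scale; the conventional transform for spectral counts is log2(count+1)
(:func:`specdiff.multivariate.log_zscore` without the z-step, or
``np.log2(counts + 1)`` directly).

The shrunken-centroid machinery follows the canonical formulation:

    d_ik  = (xbar_ik - xbar_i) / (m_k * (s_i + s_0))
    d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)
    xbar'_ik = xbar_i + m_k * (s_i + s_0) * d'_ik

with s_i the pooled within-class SD, s_0 the median of the s_i, and
m_k = sqrt(1/n_k - 1/n).  Classification minimizes the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s_0)^2 - 2 log pi_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import DifferentialResult
from .io import CountMatrix, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ShrunkenCentroidModel",
    "Signature",
    "ROCCurve",
    "fit_nsc",
    "cross_validate_delta",
    "select_signature",
    "combined_score",
    "roc_curve",
]


@dataclass(frozen=True)
class ShrunkenCentroidModel:
    """Fitted nearest-shrunken-centroid classifier for two classes."""

    class_labels: tuple[str, str]
    feature_ids: tuple[str, ...]
    overall_centroid: np.ndarray  # features
    class_centroids: np.ndarray  # features x 2
    pooled_sd: np.ndarray  # features
    s0: float
    m_k: np.ndarray  # 2
    delta: float
    shrunken_diff: np.ndarray  # features x 2 (d'_ik)
    shrunken_centroids: np.ndarray  # features x 2
    priors: np.ndarray  # 2

    def discrimination_scores(self) -> np.ndarray:
        """Per-feature max_k |d'_ik|."""
        return np.abs(self.shrunken_diff).max(axis=1)

    def discriminant(self, x: np.ndarray) -> np.ndarray:
        """delta_k for each row of ``x`` (samples x features); lower wins."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        denom = (self.pooled_sd + self.s0) ** 2
        scores = np.empty((x.shape[0], 2))
        for k in range(2):
            diff = x - self.shrunken_centroids[:, k]
            scores[:, k] = (diff**2 / denom).sum(axis=1) - 2.0 * np.log(self.priors[k])
        return scores

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.discriminant(x)
        idx = np.argmin(scores, axis=1)
        return np.array([self.class_labels[i] for i in idx])

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "feature_ids": list(self.feature_ids),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "delta": self.delta,
            "shrunken_diff": self.shrunken_diff.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "priors": self.priors.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ShrunkenCentroidModel":
        return cls(
            class_labels=tuple(payload["class_labels"]),
            feature_ids=tuple(payload["feature_ids"]),
            overall_centroid=np.array(payload["overall_centroid"]),
            class_centroids=np.array(payload["class_centroids"]),
            pooled_sd=np.array(payload["pooled_sd"]),
            s0=float(payload["s0"]),
            m_k=np.array(payload["m_k"]),
            delta=float(payload["delta"]),
            shrunken_diff=np.array(payload["shrunken_diff"]),
            shrunken_centroids=np.array(payload["shrunken_centroids"]),
            priors=np.array(payload["priors"]),
        )


@dataclass(frozen=True)
class Signature:
    """Small ordered protein panel with discrimination scores and directions."""

    proteins: tuple[str, ...]
    scores: tuple[float, ...]
    directions: tuple[int, ...]  # +1 if up in the positive class
    positive_label: str

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_point: tuple[float, float, float]  # (threshold, sens, spec)


def fit_nsc(
    features: np.ndarray,
    design: StudyDesign,
    delta: float = 0.0,
    feature_ids: tuple[str, ...] | None = None,
    sample_ids: tuple[str, ...] | None = None,
) -> ShrunkenCentroidModel:
    """Fit a two-class nearest-shrunken-centroid model.

    ``features`` is features x samples (matching count-matrix orientation).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    x = np.asarray(features, dtype=float)
    labels = design.require_two_groups()
    if sample_ids is None:
        sample_ids = design.sample_ids
    if x.shape[1] != len(sample_ids):
        raise ValueError("feature matrix width does not match sample count")
    if feature_ids is None:
        feature_ids = tuple(str(i) for i in range(x.shape[0]))

    masks = [design.mask(g, tuple(sample_ids)) for g in labels]
    n_k = np.array([m.sum() for m in masks])
    n = int(n_k.sum())

    overall = x.mean(axis=1)
    centroids = np.column_stack([x[:, m].mean(axis=1) for m in masks])
    within_ss = sum(
        ((x[:, m] - centroids[:, [k]]) ** 2).sum(axis=1) for k, m in enumerate(masks)
    )
    pooled_sd = np.sqrt(within_ss / (n - 2))
    if np.all(pooled_sd == 0):
        raise ValueError("all features have zero pooled within-class SD")
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)

    scale = m_k[None, :] * (pooled_sd + s0)[:, None]
    d = (centroids - overall[:, None]) / scale
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken_centroids = overall[:, None] + scale * d_shrunk
    priors = n_k / n
    return ShrunkenCentroidModel(
        class_labels=labels,
        feature_ids=feature_ids,
        overall_centroid=overall,
        class_centroids=centroids,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        delta=float(delta),
        shrunken_diff=d_shrunk,
        shrunken_centroids=shrunken_centroids,
        priors=priors,
    )


def cross_validate_delta(
    features: np.ndarray,
    design: StudyDesign,
    delta_grid: np.ndarray | None = None,
    scheme: str = "loo",
    feature_ids: tuple[str, ...] | None = None,
    n_grid: int = 30,
) -> tuple[float, pd.DataFrame]:
    """Choose the shrinkage delta by cross-validated error.

    Default scheme is leave-one-out.  Ties in CV error are broken toward the
    largest delta (fewest surviving features).
    """
    x = np.asarray(features, dtype=float)
    sample_ids = design.sample_ids
    labels = np.array([design.assignments[s] for s in sample_ids])
    if delta_grid is None:
        full = fit_nsc(x, design, delta=0.0, feature_ids=feature_ids)
        d_max = float(np.abs(full.shrunken_diff).max())
        delta_grid = np.linspace(0.0, d_max, n_grid)
    delta_grid = np.unique(np.asarray(delta_grid, dtype=float))
    if delta_grid.size < 1:
        raise ValueError("delta grid is empty")

    if scheme == "loo":
        folds = [np.array([i]) for i in range(len(sample_ids))]
    elif scheme == "stratified5":
        folds = _stratified_folds(labels, 5)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    errors = np.zeros(delta_grid.size)
    for test_idx in folds:
        train_mask = np.ones(len(sample_ids), dtype=bool)
        train_mask[test_idx] = False
        train_labels = labels[train_mask]
        if len(set(train_labels)) < 2:
            raise ValueError("cross-validation fold left a single class in training")
        train_design = StudyDesign(
            assignments={
                s: design.assignments[s]
                for s, m in zip(sample_ids, train_mask)
                if m
            }
        )
        for j, delta in enumerate(delta_grid):
            model = fit_nsc(
                x[:, train_mask], train_design, delta=float(delta), feature_ids=feature_ids
            )
            pred = model.predict(x[:, test_idx].T)
            errors[j] += int((pred != labels[test_idx]).sum())

    error_rate = errors / len(sample_ids)
    best_rate = error_rate.min()
    # ties -> largest delta (sparser model)
    chosen = float(delta_grid[np.where(error_rate == best_rate)[0][-1]])
    table = pd.DataFrame({"delta": delta_grid, "cv_error": error_rate})
    logger.info("cross-validation: chose delta=%.4g (error %.3f)", chosen, best_rate)
    return chosen, table


def _stratified_folds(labels: np.ndarray, k: int) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        for j, idx in enumerate(np.where(labels == cls)[0]):
            folds[j % k].append(int(idx))
    return [np.array(sorted(f)) for f in folds if f]


def select_signature(
    model: ShrunkenCentroidModel,
    differential: DifferentialResult,
    size: int = 3,
    positive_label: str | None = None,
) -> Signature:
    """Top proteins by discrimination score among SI-significant proteins.

    Eligible proteins have a nonzero shrunken difference in the model AND a
    significant spectral index; they are ranked by max_k |d'_ik| descending
    and truncated to ``size``.  Direction is the SI sign relative to the
    positive class (default: the model's first class label, the differential
    result's group A).
    """
    if positive_label is None:
        positive_label = differential.group_A
    if positive_label not in (differential.group_A, differential.group_B):
        raise ValueError(f"unknown positive label {positive_label!r}")
    si_by_protein = {r.protein_id: r for r in differential.records}
    scores = model.discrimination_scores()
    eligible = []
    for i, pid in enumerate(model.feature_ids):
        rec = si_by_protein.get(pid)
        if rec is None or not rec.significant or scores[i] == 0:
            continue
        sign = 1 if rec.si > 0 else -1
        if positive_label == differential.group_B:
            sign = -sign
        eligible.append((pid, float(scores[i]), sign))
    eligible.sort(key=lambda t: (-t[1], t[0]))
    if len(eligible) < size:
        logger.warning(
            "only %d eligible proteins for a size-%d signature", len(eligible), size
        )
    chosen = eligible[:size]
    return Signature(
        proteins=tuple(p for p, _, _ in chosen),
        scores=tuple(s for _, s, _ in chosen),
        directions=tuple(d for _, _, d in chosen),
        positive_label=positive_label,
    )


def combined_score(matrix: CountMatrix, signature: Signature) -> pd.Series:
    """Per-sample combined classifier score.

    Each signature protein's raw counts are z-scored across all samples,
    multiplied by the protein's direction sign, and summed per sample.
    Zero-variance proteins contribute 0 (with a warning).
    """
    missing = [p for p in signature.proteins if p not in matrix.protein_ids]
    if missing:
        raise KeyError(f"signature proteins absent from matrix: {missing}")
    index = {p: i for i, p in enumerate(matrix.protein_ids)}
    total = np.zeros(len(matrix.sample_ids))
    for protein, direction in zip(signature.proteins, signature.directions):
        row = matrix.counts[index[protein]].astype(float)
        sd = row.std()
        if sd == 0:
            logger.warning("signature protein %r has zero variance; contributes 0", protein)
            continue
        total += direction * (row - row.mean()) / sd
    return pd.Series(total, index=list(matrix.sample_ids), name="combined_score")


def roc_curve(
    scores: pd.Series | np.ndarray,
    design: StudyDesign,
    positive_label: str,
    sample_ids: tuple[str, ...] | None = None,
) -> ROCCurve:
    """ROC over all distinct score thresholds (score >= threshold => positive).

    AUC is the trapezoidal area under (1-specificity, sensitivity); the
    Youden point maximizes sensitivity + specificity - 1, ties resolved
    toward higher sensitivity.
    """
    if isinstance(scores, pd.Series):
        sample_ids = tuple(scores.index)
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        if sample_ids is None:
            sample_ids = design.sample_ids
    truth = np.array([design.assignments[s] == positive_label for s in sample_ids])
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty for ROC analysis")

    thresholds = np.concatenate([[np.inf], np.unique(values)[::-1]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        called_pos = values >= t
        sens[i] = (called_pos & truth).sum() / n_pos
        spec[i] = (~called_pos & ~truth).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    youden = sens + spec - 1.0
    best = np.lexsort((sens, youden))[-1]  # max youden, ties -> max sensitivity
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_point=(float(thresholds[best]), float(sens[best]), float(spec[best])),
    )
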