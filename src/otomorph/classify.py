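"""Ecological classification of labyrinth shapes by canonical variates.

A canonical variates analysis (CVA) is fitted on the retained principal
component scores of the training taxa (groups of n = 1 are removed first,
since between/within decomposition is undefined for them).  Specimens of
unknown ecology are projected onto the canonical axes; their affinity to each
ecological group is quantified by Mahalanobis distances under the pooled
within-group covariance, bootstrap typicality probabilities, and normalized
Gaussian likelihood assignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, stats

from otomorph.shape_stats import bonferroni_alpha
from otomorph.types import EstimationError, SpecimenRecord, ValidationError


def filter_singleton_groups(
    records: Sequence[SpecimenRecord],
) -> Tuple[List[SpecimenRecord], List[SpecimenRecord]]:
    """Drop training specimens whose ecology group has n = 1.

    CVA cannot estimate a within-group covariance contribution from a single
    specimen, so singleton groups are removed before fitting (the dropped
    records are returned for logging).
    """
    counts = Counter(r.ecology for r in records)
    kept = [r for r in records if counts[r.ecology] >= 2]
    dropped = [r for r in records if counts[r.ecology] < 2]
    if len({r.ecology for r in kept}) < 2:
        raise ValidationError("fewer than 2 ecology groups remain after filtering")
    return kept, dropped


@dataclass
class CVAModel:
    """Canonical variates of group-labelled PC scores.

    ``canonical_basis`` maps centered PC scores to canonical scores; axes are
    scaled so pooled within-group variance along each axis is 1 and ordered
    by descending between/within eigenvalue.
    """

    retained_pc_count: int
    canonical_basis: np.ndarray  # k x n_axes
    group_means: np.ndarray  # g x n_axes (canonical space)
    group_means_pc: np.ndarray  # g x k (PC space)
    pooled_within_covariance: np.ndarray  # k x k
    group_sizes: np.ndarray
    groups: List[str]
    grand_mean: np.ndarray  # k
    eigenvalues: np.ndarray  # n_axes, descending
    training_scores: np.ndarray  # n x n_axes (canonical space)
    training_pc_scores: np.ndarray  # n x k (PC space)
    training_labels: List[str]

    @property
    def n_axes(self) -> int:
        return self.canonical_basis.shape[1]


@dataclass
class TypicalityResult:
    """Group affinities of one projected specimen."""

    distances: Dict[str, float]
    typicality_p: Dict[str, float]
    likelihoods: Dict[str, float]
    assigned_group: str
    alpha_corrected: float
    significantly_different: Dict[str, bool]


def fit_cva(scores: np.ndarray, labels: Sequence[str]) -> CVAModel:
    """Canonical variates analysis of n x k PC scores with group labels."""
    X = np.asarray(scores, dtype=float)
    labels = list(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValidationError("scores must be n x k with one label per row")
    n, k = X.shape
    groups = sorted(set(labels))
    g = len(groups)
    if g < 2:
        raise ValidationError("need at least 2 groups")
    sizes = np.array([labels.count(gr) for gr in groups])
    if np.any(sizes < 2):
        raise ValidationError(f"group(s) of size 1: use filter_singleton_groups first")
    if n - g <= k:
        raise EstimationError(
            f"pooled within-group covariance singular (n - g = {n - g} <= k = {k}); "
            "retain fewer PCs"
        )
    grand_mean = X.mean(axis=0)
    means = np.stack([X[[l == gr for l in labels]].mean(axis=0) for gr in groups])
    W = np.zeros((k, k))
    for gr, mu in zip(groups, means):
        R = X[[l == gr for l in labels]] - mu
        W += R.T @ R
    W /= n - g
    B = np.zeros((k, k))
    for sz, mu in zip(sizes, means):
        d = mu - grand_mean
        B += sz * np.outer(d, d)
    B /= n - g
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise EstimationError(f"singular within-group covariance: {exc}") from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, k)
    evals = evals[order][:n_axes]
    A = evecs[:, order][:, :n_axes]  # scipy normalizes a' W a = 1 already
    # deterministic sign: largest-magnitude coefficient positive
    for j in range(n_axes):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] *= -1.0
    return CVAModel(
        retained_pc_count=k,
        canonical_basis=A,
        group_means=(means - grand_mean) @ A,
        group_means_pc=means,
        pooled_within_covariance=W,
        group_sizes=sizes,
        groups=groups,
        grand_mean=grand_mean,
        eigenvalues=np.maximum(evals, 0.0),
        training_scores=(X - grand_mean) @ A,
        training_pc_scores=X.copy(),
        training_labels=labels,
    )


def project(model: CVAModel, specimen_scores: np.ndarray) -> np.ndarray:
    """Map a k-vector of PC scores into canonical space."""
    x = np.asarray(specimen_scores, dtype=float)
    if x.shape[-1] != model.retained_pc_count:
        raise ValidationError(
            f"expected {model.retained_pc_count} PC scores, got {x.shape[-1]}"
        )
    return (x - model.grand_mean) @ model.canonical_basis


def _mahalanobis_sq(model: CVAModel, x: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of PC-score vector x to each group mean
    under the pooled within-group covariance."""
    Winv = np.linalg.inv(model.pooled_within_covariance)
    d = model.group_means_pc - x
    return np.einsum("gi,ij,gj->g", d, Winv, d)


def typicality(
    model: CVAModel,
    specimen_scores: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TypicalityResult:
    """Mahalanobis distances, bootstrap typicality and likelihood assignment.

    Typicality p for a group is the add-one-corrected fraction of ``n_perm``
    bootstrap draws of that group's own members whose Mahalanobis distance to
    the group mean is at least the specimen's; specimens farther from a group
    mean than (1 - alpha) of within-group distances (after Bonferroni
    correction over the pairwise comparisons) are flagged significantly
    different.  Assignment likelihoods are equal-prior multivariate-normal
    densities under the pooled covariance, normalized to sum to 1.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    x = np.asarray(specimen_scores, dtype=float)
    d2 = _mahalanobis_sq(model, x)
    Winv = np.linalg.inv(model.pooled_within_covariance)
    labels = np.asarray(model.training_labels, dtype=object)
    rng = np.random.default_rng(seed)
    p_typ = {}
    for gi, gr in enumerate(model.groups):
        members = model.training_pc_scores[labels == gr]
        resid = members - model.group_means_pc[gi]
        member_d2 = np.einsum("ni,ij,nj->n", resid, Winv, resid)
        draws = member_d2[rng.integers(0, len(member_d2), size=n_perm)]
        p_typ[gr] = (np.sum(draws >= d2[gi]) + 1) / (n_perm + 1)
    # equal-prior Gaussian likelihoods under the pooled covariance
    loglik = -0.5 * d2
    loglik -= loglik.max()
    lik = np.exp(loglik)
    lik /= lik.sum()
    a_corr = bonferroni_alpha(alpha, len(model.groups))
    distances = {gr: float(np.sqrt(v)) for gr, v in zip(model.groups, d2)}
    likelihoods = {gr: float(v) for gr, v in zip(model.groups, lik)}
    assigned = model.groups[int(np.argmax(lik))]
    sig = {gr: bool(p_typ[gr] < a_corr) for gr in model.groups}
    return TypicalityResult(
        distances=distances,
        typicality_p={gr: float(v) for gr, v in p_typ.items()},
        likelihoods=likelihoods,
        assigned_group=assigned,
        alpha_corrected=a_corr,
        significantly_different=sig,
    )


def confidence_ellipse(
    model: CVAModel,
    group: str,
    level: float = 0.95,
    axes: Tuple[int, int] = (0, 1),
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Gaussian confidence ellipse of one group in a canonical-axis plane.

    Returns (center, semi-axis lengths, orientation angle in radians).  The
    ellipse is the chi-square(2 df) contour of the group's 2D canonical-score
    covariance at the requested coverage level.
    """
    if not (0.0 <= level < 1.0):
        raise ValidationError(f"level must be in [0, 1), got {level}")
    labels = np.asarray(model.training_labels, dtype=object)
    members = model.training_scores[labels == group][:, list(axes)]
    if len(members) < 3:
        raise ValidationError(f"group {group!r} needs n >= 3 for an ellipse")
    center = members.mean(axis=0)
    S = np.cov(members.T)
    evals, evecs = np.linalg.eigh(S)
    if evals.min() <= 0:
        raise EstimationError(f"degenerate 2D covariance for group {group!r}")
    q = stats.chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(evals * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return center, semi, angle


def classify(model: CVAModel, scores: np.ndarray) -> str:
    """Maximum-likelihood group assignment of one PC-score vector."""
    d2 = _mahalanobis_sq(model, np.asarray(scores, dtype=float))
    return model.groups[int(np.argmin(d2))]


def classification_accuracy(
    scores: np.ndarray,
    labels: Sequence[str],
    mode: str = "resubstitution",
    model: Optional[CVAModel] = None,
) -> float:
    """Fraction of specimens whose assignment matches their label.

    ``resubstitution`` classifies training specimens with the model fitted on
    all of them; ``loo`` refits the CVA with each specimen held out.
    """
    X = np.asarray(scores, dtype=float)
    labels = list(labels)
    if mode == "resubstitution":
        mdl = model if model is not None else fit_cva(X, labels)
        hits = sum(classify(mdl, x) == l for x, l in zip(X, labels))
    elif mode == "loo":
        hits = 0
        idx = np.arange(len(labels))
        for i in idx:
            keep = idx != i
            try:
                mdl = fit_cva(X[keep], [labels[j] for j in idx[keep]])
            except (ValidationError, EstimationError):
                continue  # held-out member broke a group; count as miss
            if classify(mdl, X[i]) == labels[i]:
                hits += 1
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return hits / len(labels)
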