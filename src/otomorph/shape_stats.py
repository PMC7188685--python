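"""Permutation linear models for shape: Procrustes ANCOVA and PGLS.

Both tests relate a high-dimensional shape matrix to ecology (a factor) and
centroid size (a covariate) with sequential (Type I) sums of squares and
significance assessed by residual randomization in a permutation procedure
(RRPP): for each model term, residuals of the reduced model are permuted
across specimens, added back to the reduced-model fit, and the term's F
statistic recomputed.  PGLS whitens data and design by the inverse square
root of the Brownian-motion covariance implied by a time-calibrated
phylogeny before applying the identical machinery, so on a star phylogeny it
collapses to the ordinary ANCOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from otomorph.phylo import TimeTree, bm_covariance
from otomorph.types import EstimationError, ValidationError

TERM_NAMES = ("ecology", "size", "ecology:size")


@dataclass
class AnovaTable:
    """Sequential sums-of-squares table with RRPP permutation p-values."""

    table: pd.DataFrame  # rows: terms, Residual, Total; cols: df, SS, R2, F, Z, p
    n_permutations: int
    seed: int
    alpha_corrected: float

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected alpha, truncated to three significant figures."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError("number of tests must be >= 1")
    a = alpha / m
    exp = math.floor(math.log10(a))
    factor = 10.0 ** (exp - 2)
    return math.floor(round(a / factor, 9)) * factor


def _design_blocks(ecology: Sequence[str], size: np.ndarray) -> list:
    eco = pd.Series(list(ecology), dtype="object")
    counts = eco.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"ecology group(s) of size 1: {sorted(small.index)}")
    dummies = pd.get_dummies(eco, drop_first=True).to_numpy(dtype=float)
    size = np.asarray(size, dtype=float).reshape(-1, 1)
    n = len(eco)
    return [
        np.ones((n, 1)),
        dummies,
        size,
        dummies * size,
    ]


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _rrpp_table(
    Y: np.ndarray,
    blocks: list,
    n_perm: int,
    seed: int,
    alpha: float,
) -> AnovaTable:
    n = Y.shape[0]
    designs = [np.hstack(blocks[: j + 1]) for j in range(len(blocks))]
    ranks = [np.linalg.matrix_rank(X) for X in designs]
    hats = [_hat(X) for X in designs]
    df_terms = [ranks[j] - ranks[j - 1] for j in range(1, len(designs))]
    df_res = n - ranks[-1]
    if df_res < 2:
        raise ValidationError(
            f"too few specimens ({n}) for the model ({ranks[-1]} parameters)"
        )
    SS_total = float(np.sum(((np.eye(n) - hats[0]) @ Y) ** 2))
    if SS_total <= 1e-12 * max(float(np.sum(Y**2)), 1.0):
        raise EstimationError("constant shape matrix: zero total variation")

    term_proj = [hats[j] - hats[j - 1] for j in range(1, len(designs))]
    resid_proj = np.eye(n) - hats[-1]
    SS_terms = [float(np.sum((M @ Y) ** 2)) for M in term_proj]
    RSS = float(np.sum((resid_proj @ Y) ** 2))
    F_obs = [
        (ss / df) / (RSS / df_res) if df > 0 else np.nan
        for ss, df in zip(SS_terms, df_terms)
    ]

    rng = np.random.default_rng(seed)
    n_terms = len(term_proj)
    n_ge = np.zeros(n_terms, dtype=int)  # permuted F >= observed F
    n_lt = np.zeros(n_terms, dtype=int)
    red_fit = [hats[j - 1] @ Y for j in range(1, len(designs))]
    red_res = [Y - f for f in red_fit]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        for t in range(n_terms):
            Ystar = red_fit[t] + red_res[t][perm]
            ss = np.sum((term_proj[t] @ Ystar) ** 2)
            rss = np.sum((resid_proj @ Ystar) ** 2)
            f = (ss / df_terms[t]) / (rss / df_res)
            if f >= F_obs[t]:
                n_ge[t] += 1
            else:
                n_lt[t] += 1

    p = (n_ge + 1) / (n_perm + 1)
    z = stats.norm.ppf((n_lt + 0.5) / (n_perm + 1))
    rows = {}
    for t, name in enumerate(TERM_NAMES):
        rows[name] = {
            "df": df_terms[t],
            "SS": SS_terms[t],
            "R2": SS_terms[t] / SS_total,
            "F": F_obs[t],
            "Z": float(z[t]),
            "p": float(p[t]),
        }
    rows["Residual"] = {
        "df": df_res, "SS": RSS, "R2": RSS / SS_total,
        "F": np.nan, "Z": np.nan, "p": np.nan,
    }
    rows["Total"] = {
        "df": n - 1, "SS": SS_total, "R2": 1.0,
        "F": np.nan, "Z": np.nan, "p": np.nan,
    }
    table = pd.DataFrame(rows).T[["df", "SS", "R2", "F", "Z", "p"]]
    return AnovaTable(
        table=table,
        n_permutations=n_perm,
        seed=seed,
        alpha_corrected=bonferroni_alpha(alpha, len(TERM_NAMES)),
    )


def procrustes_ancova(
    shape: np.ndarray,
    ecology: Sequence[str],
    size: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AnovaTable:
    """RRPP ANCOVA of shape ~ ecology + size + ecology:size (Type I SS)."""
    Y = np.asarray(shape, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(ecology):
        raise ValidationError("shape must be n x p with one row per specimen")
    blocks = _design_blocks(ecology, size)
    return _rrpp_table(Y, blocks, n_perm, seed, alpha)


def procrustes_pgls(
    shape: np.ndarray,
    ecology: Sequence[str],
    size: np.ndarray,
    tree: TimeTree,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    taxa: Optional[Sequence[str]] = None,
) -> AnovaTable:
    """Phylogenetic RRPP ANCOVA: whiten by the inverse square root of the BM
    covariance, then apply the ordinary RRPP machinery in the transformed
    space.  Row order of ``shape`` must follow ``taxa`` (default: sorted tips).
    """
    Y = np.asarray(shape, dtype=float)
    C = bm_covariance(tree, taxa=taxa)
    if Y.shape[0] != C.shape[0]:
        raise ValidationError("shape rows must match tree tips")
    evals, evecs = np.linalg.eigh(C)
    if evals.min() <= 1e-12 * evals.max():
        raise EstimationError(
            "singular phylogenetic covariance; consider a minimum branch-length floor"
        )
    E = evecs @ np.diag(evals**-0.5) @ evecs.T
    blocks = [E @ b for b in _design_blocks(ecology, size)]
    return _rrpp_table(E @ Y, blocks, n_perm, seed, alpha)
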