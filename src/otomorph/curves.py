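"""Canal centerlines, the 60-landmark scheme, and semilandmark sliding.

Digitized semicircular-canal centerlines are converted into 20 evenly spaced
landmarks per canal (60 per labyrinth).  Curve endpoints are fixed (type 1)
landmarks; interior points are semilandmarks that slide along the curve to
minimize thin-plate-spline bending energy against the Procrustes consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from otomorph.types import (
    CANAL_NAMES,
    LANDMARKS_PER_CANAL,
    N_LANDMARKS,
    CanalCurve,
    GeometryError,
    LabyrinthConfiguration,
    SpecimenRecord,
)


def resample_curve(curve: CanalCurve, n: int) -> np.ndarray:
    """Project ``n`` evenly spaced points onto a piecewise-linear curve.

    The first and last output points coincide with the curve endpoints and
    consecutive points are separated by equal arc length along the polyline.
    """
    if n < 2:
        raise GeometryError("need n >= 2 resampled points")
    pts = curve.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise GeometryError(f"curve {curve.canal!r} has zero arc length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    # locate each target arc length in the cumulative table
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / seg[idx]
    out = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def landmarks_from_curves(
    specimen: SpecimenRecord, curves: Sequence[CanalCurve]
) -> LabyrinthConfiguration:
    """Build the 60-landmark configuration from the three canal centerlines."""
    by_name = {c.canal: c for c in curves}
    missing = [name for name in CANAL_NAMES if name not in by_name]
    if missing:
        raise GeometryError(
            f"specimen {specimen.specimen_id!r}: missing canal curve(s) {missing}"
        )
    blocks = [resample_curve(by_name[name], LANDMARKS_PER_CANAL) for name in CANAL_NAMES]
    return LabyrinthConfiguration(
        specimen=specimen,
        landmarks=np.vstack(blocks),
        curves=tuple(by_name[name] for name in CANAL_NAMES),
    )


def mirror_configuration(config: LabyrinthConfiguration) -> LabyrinthConfiguration:
    """Reflect a configuration through the sagittal (x = 0) plane.

    Used to substitute a mirrored right labyrinth for a missing left one.
    Landmark ordering is preserved and the side flag is flipped.
    """
    flip = np.array([-1.0, 1.0, 1.0])
    new_side = "left" if config.specimen.side == "right" else "right"
    spec = SpecimenRecord(
        specimen_id=config.specimen.specimen_id,
        taxon=config.specimen.taxon,
        side=new_side,
        ecology=config.specimen.ecology,
        group_role=config.specimen.group_role,
    )
    curves = None
    if config.curves is not None:
        curves = tuple(
            CanalCurve(c.canal, c.points * flip, c.start_anatomy, c.end_anatomy)
            for c in config.curves
        )
    return LabyrinthConfiguration(
        specimen=spec,
        landmarks=config.landmarks * flip,
        curves=curves,
        fixed_indices=config.fixed_indices,
    )


@dataclass
class BendingEnergyModel:
    """Thin-plate-spline bending-energy quadratic form for a reference shape.

    ``bending_matrix`` is the upper-left block of the inverse of the TPS
    L-matrix built on the reference landmarks with the 3D kernel U(r) = -r.
    It is symmetric positive semi-definite and annihilates any affine
    transform of the reference, so bending energy measures pure non-affine
    deformation.
    """

    reference_landmarks: np.ndarray
    bending_matrix: np.ndarray

    @classmethod
    def from_reference(cls, reference: np.ndarray) -> "BendingEnergyModel":
        ref = np.asarray(reference, dtype=float)
        k = ref.shape[0]
        d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
        dup = np.argwhere((d + np.eye(k)) == 0.0)
        if dup.size:
            raise GeometryError(
                f"coincident reference landmarks at index pairs {dup.tolist()}"
            )
        K = -d  # 3D thin-plate kernel
        P = np.hstack([np.ones((k, 1)), ref])
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        try:
            Linv = np.linalg.inv(L)
        except np.linalg.LinAlgError as exc:
            raise GeometryError(f"singular TPS system for reference: {exc}") from exc
        B = Linv[:k, :k]
        return cls(reference_landmarks=ref, bending_matrix=0.5 * (B + B.T))


def bending_energy(model: BendingEnergyModel, target: np.ndarray) -> float:
    """TPS bending energy of mapping the model reference onto ``target``."""
    T = np.asarray(target, dtype=float)
    e = float(np.trace(T.T @ model.bending_matrix @ T))
    return max(e, 0.0)  # clip tiny negative round-off


# ---------------------------------------------------------------------------
# polyline helpers for sliding


def _project_onto_polyline(point: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Closest point on a piecewise-linear curve to ``point``."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / denom, 0.0, 1.0)
    cand = a + t[:, None] * ab
    return cand[np.argmin(np.linalg.norm(cand - point, axis=1))]


def _tangents(landmarks: np.ndarray, neighbors: dict) -> np.ndarray:
    """Unit along-curve tangent per landmark (zero rows for fixed points)."""
    U = np.zeros_like(landmarks)
    for i, (prev, nxt) in neighbors.items():
        t = landmarks[nxt] - landmarks[prev]
        nrm = np.linalg.norm(t)
        if nrm > 0:
            U[i] = t / nrm
    return U


def _config_polylines(config: LabyrinthConfiguration) -> List[np.ndarray]:
    """Per-canal polylines sliders must stay on: the digitized centerlines
    when available, otherwise the chain through the landmarks themselves."""
    if config.curves is not None:
        by_name = {c.canal: c.points for c in config.curves}
        return [by_name[name] for name in CANAL_NAMES]
    return [
        config.landmarks[c * LANDMARKS_PER_CANAL : (c + 1) * LANDMARKS_PER_CANAL]
        for c in range(len(CANAL_NAMES))
    ]


def _slide_one(
    aligned: np.ndarray,
    polylines: List[np.ndarray],
    model: BendingEnergyModel,
    neighbors: dict,
    slider_idx: np.ndarray,
) -> np.ndarray:
    """One tangent-direction sliding step for a single aligned configuration.

    Minimizes TPS bending energy against the consensus over slide amounts
    along each semilandmark's local tangent, then re-projects the moved
    points onto the original polyline.  Backtracking halving guards against
    energy increases caused by the re-projection.
    """
    B = model.bending_matrix
    U = _tangents(aligned, neighbors)
    A = B * (U @ U.T)
    b = -np.einsum("id,id->i", U, B @ aligned)
    s = slider_idx
    t = np.zeros(len(aligned))
    t[s] = np.linalg.lstsq(A[np.ix_(s, s)], b[s], rcond=None)[0]
    # cap each slide at half the local landmark spacing: the tangent
    # linearization is only valid locally on a curved polyline
    for i in s:
        prev, nxt = neighbors[i]
        local = 0.5 * min(
            np.linalg.norm(aligned[i] - aligned[prev]),
            np.linalg.norm(aligned[i] - aligned[nxt]),
        )
        t[i] = np.clip(t[i], -local, local)

    e0 = bending_energy(model, aligned)
    step = 1.0
    canal_of = np.repeat(np.arange(len(CANAL_NAMES)), LANDMARKS_PER_CANAL)
    for _ in range(6):
        moved = aligned + (step * t)[:, None] * U
        out = aligned.copy()
        for i in s:
            out[i] = _project_onto_polyline(moved[i], polylines[canal_of[i]])
        if bending_energy(model, out) <= e0 + 1e-12:
            return out
        step *= 0.5
    return aligned


def slide_semilandmarks(
    configs: Sequence[LabyrinthConfiguration],
    max_iter: int = 10,
    tol: float = 1e-6,
) -> Tuple[List[LabyrinthConfiguration], dict]:
    """Slide semilandmarks to minimize bending energy against the consensus.

    Outer iterations alternate (1) generalized Procrustes alignment and
    consensus estimation with (2) per-specimen tangent sliding constrained to
    each specimen's original centerline polyline.  Fixed curve endpoints never
    move.  Returns the slid configurations (in their original coordinate
    frames) and a diagnostics dict with the per-iteration total energy and a
    convergence flag.
    """
    from otomorph.procrustes import gpa_transforms

    configs = list(configs)
    lms = [c.landmarks.copy() for c in configs]
    neighbors = configs[0].slider_neighbors
    slider_idx = np.array(sorted(neighbors.keys()))
    fixed0 = [c.landmarks[list(c.fixed_indices)].copy() for c in configs]
    energies = []
    converged = False
    prev_lms = None

    for _ in range(max_iter):
        aligned, consensus, transforms = gpa_transforms(lms)
        model = BendingEnergyModel.from_reference(consensus)
        total = sum(bending_energy(model, a) for a in aligned)
        if energies and total > energies[-1] * (1.0 + 1e-12):
            # consensus drift made the last slide counter-productive: revert
            # it and treat the plateau as converged
            lms = prev_lms
            converged = True
            break
        if energies and energies[-1] > 0 and (energies[-1] - total) / energies[-1] < tol:
            energies.append(total)
            converged = True
            break
        energies.append(total)
        prev_lms = [lm.copy() for lm in lms]
        for i, cfg in enumerate(configs):
            tr = transforms[i]
            polys = [tr.apply(p) for p in _config_polylines(cfg)]
            slid = _slide_one(aligned[i], polys, model, neighbors, slider_idx)
            lms[i] = tr.invert(slid)
            lms[i][list(cfg.fixed_indices)] = fixed0[i]  # endpoints never move

    out = [cfg.with_landmarks(lm) for cfg, lm in zip(configs, lms)]
    return out, {"energies": energies, "converged": converged}
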