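"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CANAL_NAMES = ("anterior", "posterior", "lateral")
ECOLOGY_LABELS = ("aerial", "aquatic", "arboreal", "fossorial", "terrestrial")

#: landmarks per canal and per configuration
LANDMARKS_PER_CANAL = 20
N_LANDMARKS = LANDMARKS_PER_CANAL * len(CANAL_NAMES)

#: indices of the six fixed (type 1) curve endpoints within the 60-landmark scheme
FIXED_INDICES = tuple(
    c * LANDMARKS_PER_CANAL + i
    for c in range(len(CANAL_NAMES))
    for i in (0, LANDMARKS_PER_CANAL - 1)
)


class OtomorphError(Exception):
    """Base class for all package errors."""


class ParseError(OtomorphError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(OtomorphError):
    """Input data violate a documented invariant."""


class GeometryError(OtomorphError):
    """A geometric operation received degenerate input."""


class EstimationError(OtomorphError):
    """A statistical estimate could not be formed from the data."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One digitized labyrinth: identity, taxon, side and ecological role.

    ``ecology`` may be absent only for projection specimens (fossils of
    unknown ecology that are projected onto a fitted ordination rather than
    used to train it).
    """

    specimen_id: str
    taxon: str
    side: str = "left"
    ecology: Optional[str] = None
    group_role: str = "training"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.group_role not in ("training", "projection"):
            raise ValidationError(
                f"group_role must be 'training' or 'projection', got {self.group_role!r}"
            )
        if self.ecology is not None and self.ecology not in ECOLOGY_LABELS:
            raise ValidationError(f"unknown ecology label {self.ecology!r}")
        if self.group_role == "training" and self.ecology is None:
            raise ValidationError(
                f"training specimen {self.specimen_id!r} must have an ecology label"
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    """Stratigraphic range of one taxon in Ma (first ≥ last ≥ 0)."""

    taxon: str
    first_appearance: float
    last_appearance: float

    def __post_init__(self) -> None:
        if not (self.first_appearance >= self.last_appearance >= 0.0):
            raise ValidationError(
                f"occurrence for {self.taxon!r}: need first_appearance >= "
                f"last_appearance >= 0, got ({self.first_appearance}, {self.last_appearance})"
            )

    @property
    def duration(self) -> float:
        return self.first_appearance - self.last_appearance


@dataclass(frozen=True)
class CanalCurve:
    """Ordered 3D centerline polyline for one semicircular canal.

    Points are in mm; the polyline is treated as piecewise linear.  The
    anatomical tags record where the digitized curve starts and ends (e.g.
    "anterior ampulla", "junction with crus communis").
    """

    canal: str
    points: np.ndarray
    start_anatomy: str = ""
    end_anatomy: str = ""

    def __post_init__(self) -> None:
        if self.canal not in CANAL_NAMES:
            raise ValidationError(f"canal must be one of {CANAL_NAMES}, got {self.canal!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise GeometryError(f"curve {self.canal!r}: need >= 2 points of dim 3")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise GeometryError(f"curve {self.canal!r}: consecutive points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class LabyrinthConfiguration:
    """The 60-landmark scheme for one labyrinth: 20 per canal, anterior then
    posterior then lateral; curve endpoints are fixed (type 1) landmarks and
    the rest are sliding semilandmarks.

    ``curves`` optionally keeps the digitized source polylines so sliders can
    be re-projected onto the original centerline during sliding; when absent,
    the chain through the landmarks themselves serves as the polyline.
    """

    specimen: SpecimenRecord
    landmarks: np.ndarray
    curves: Optional[Sequence[CanalCurve]] = None
    fixed_indices: tuple = FIXED_INDICES

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.shape != (N_LANDMARKS, 3):
            raise ValidationError(
                f"specimen {self.specimen.specimen_id!r}: expected "
                f"{N_LANDMARKS}x3 landmarks, got {lm.shape}"
            )
        self.landmarks = lm

    @property
    def slider_neighbors(self) -> dict:
        """Map slider index -> (previous, next) along-curve neighbor indices."""
        out = {}
        for c in range(len(CANAL_NAMES)):
            base = c * LANDMARKS_PER_CANAL
            for i in range(1, LANDMARKS_PER_CANAL - 1):
                out[base + i] = (base + i - 1, base + i + 1)
        return out

    def canal_slice(self, canal: str) -> slice:
        c = CANAL_NAMES.index(canal)
        return slice(c * LANDMARKS_PER_CANAL, (c + 1) * LANDMARKS_PER_CANAL)

    def with_landmarks(self, landmarks: np.ndarray) -> "LabyrinthConfiguration":
        return LabyrinthConfiguration(
            specimen=self.specimen,
            landmarks=np.asarray(landmarks, dtype=float),
            curves=self.curves,
            fixed_indices=self.fixed_indices,
        )

    def with_specimen(self, specimen: SpecimenRecord) -> "LabyrinthConfiguration":
        return LabyrinthConfiguration(
            specimen=specimen,
            landmarks=self.landmarks,
            curves=self.curves,
            fixed_indices=self.fixed_indices,
        )
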