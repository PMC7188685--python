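"""Run configuration: permutation counts, calibration replicates, thresholds."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from otomorph.types import ValidationError


@dataclass
class RunConfig:
    """Pipeline-wide tunables.

    Defaults follow standard practice for permutation tests in geometric
    morphometrics: 1000 permutations for phylogenetic signal and the shape
    ANCOVA/PGLS, 10000 resampling draws for Mahalanobis typicality, 250
    stochastically time-calibrated trees averaged into a consensus, principal
    components retained up to 95% cumulative variance, and a 5% alpha level
    (Bonferroni-corrected per family of tests downstream).
    """

    random_seed: int = 0
    n_perm_signal: int = 1000
    n_perm_anova: int = 1000
    n_perm_typicality: int = 10000
    n_calibrated_trees: int = 250
    variance_threshold: float = 0.95
    alpha: float = 0.05
    log_base: float = 10.0  # base of the hearing-regression log transform

    def __post_init__(self) -> None:
        for name in ("n_perm_signal", "n_perm_anova", "n_perm_typicality", "n_calibrated_trees"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("variance_threshold", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValidationError("log_base must be positive and != 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` configuration file."""
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = float(value) if key in ("variance_threshold", "alpha", "log_base") else int(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")
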