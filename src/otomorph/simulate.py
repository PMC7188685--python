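"""Synthetic labyrinth datasets with controlled phylogenetic and ecological
structure.

The generator emulates the statistical situation of a comparative
semicircular-canal study: ~60 taxa whose 60-landmark labyrinth shapes evolve
by Brownian motion along a time-calibrated phylogeny, displaced by a fixed
per-ecology deformation field and blurred by landmark digitization noise,
plus a matched occurrence table and an extant hearing reference table where
log-scaled duct length predicts hearing frequency linearly with Gaussian
noise.  Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from otomorph.curves import landmarks_from_curves
from otomorph.phylo import TimeTree, bm_covariance
from otomorph.types import (
    ECOLOGY_LABELS,
    CanalCurve,
    LabyrinthConfiguration,
    OccurrenceRecord,
    SpecimenRecord,
    ValidationError,
)

#: fixed seed for the per-ecology deformation fields, so planted effects are
#: identical across runs and versions (the fields are package constants, not
#: per-dataset draws)
_FIELD_SEED = 918273645

#: ecology-group proportions: one dominant terrestrial class, substantial
#: aquatic and aerial classes, few arboreal, and a rare fossorial class
DEFAULT_PROPORTIONS = {
    "aerial": 0.20,
    "aquatic": 0.25,
    "arboreal": 0.15,
    "fossorial": 0.05,
    "terrestrial": 0.35,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic comparative dataset.

    ``bm_rate`` is per-coordinate shape variance per Myr; the ecology effect
    size is the norm of the group mean-shape offset in landmark units (the
    template canals have radius ~1); ``landmark_noise_sd`` is iid Gaussian
    digitization noise per coordinate.
    """

    n_taxa: int = 61
    proportions: Optional[Dict[str, float]] = None
    bm_rate: float = 5e-5
    ecology_effect_size: float = 0.3
    landmark_noise_sd: float = 0.005
    seed: int = 0

    def group_proportions(self) -> Dict[str, float]:
        props = dict(self.proportions) if self.proportions else dict(DEFAULT_PROPORTIONS)
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"group proportions must sum to 1, got {total}")
        if any(v < 0 for v in props.values()):
            raise ValidationError("group proportions must be nonnegative")
        return props


def base_labyrinth_template() -> Tuple[CanalCurve, CanalCurve, CanalCurve]:
    """Deterministic idealized labyrinth: three near-orthogonal circular arcs.

    The anterior and posterior canal planes are vertical and meet at 90
    degrees (as in most amniotes); the lateral canal is near-horizontal with
    a smaller radius.  Endpoints sit at plausible ampulla and crus positions.
    """

    def arc(center, u, v, radius, theta0, theta1, n=200):
        th = np.linspace(np.deg2rad(theta0), np.deg2rad(theta1), n)
        u = np.asarray(u) / np.linalg.norm(u)
        v = np.asarray(v) / np.linalg.norm(v)
        return np.asarray(center) + radius * (
            np.outer(np.cos(th), u) + np.outer(np.sin(th), v)
        )

    sq = 1.0 / np.sqrt(2.0)
    anterior = CanalCurve(
        canal="anterior",
        points=arc((0.0, 0.0, 1.0), (sq, sq, 0.0), (0.0, 0.0, 1.0), 1.0, -110, 100),
        start_anatomy="anterior ampulla",
        end_anatomy="junction with crus communis",
    )
    posterior = CanalCurve(
        canal="posterior",
        points=arc((0.0, 0.0, 1.0), (sq, -sq, 0.0), (0.0, 0.0, 1.0), 1.0, 100, -110),
        start_anatomy="junction with crus communis",
        end_anatomy="posterior ampulla",
    )
    lateral = CanalCurve(
        canal="lateral",
        points=arc((0.0, 0.0, 0.25), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), 0.8, 30, 280),
        start_anatomy="lateral ampulla",
        end_anatomy="confluence with pars inferior",
    )
    return anterior, posterior, lateral


def simulate_tree(
    n_taxa: int,
    seed: int = 0,
    fossil_fraction: float = 0.3,
    merge_scale: float = 40.0,
) -> Tuple[TimeTree, List[OccurrenceRecord]]:
    """Random time tree with fossil and extant tips plus occurrence records.

    Topology and node ages come from random pairwise joins with exponential
    waiting times (rate proportional to the number of open lineages); a
    fraction of tips is truncated above the present to act as fossils.
    """
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    names = [f"t{i+1}" for i in range(n_taxa)]
    nodes = [{"name": nm, "age": 0.0, "children": []} for nm in names]
    active = list(range(n_taxa))
    age = 0.0
    all_nodes = list(nodes)
    while len(active) > 1:
        age += rng.exponential(merge_scale / len(active))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]  # pop larger index first
        node = {"name": None, "age": age, "children": [all_nodes[a], all_nodes[b]]}
        all_nodes.append(node)
        active.pop(j)
        active.pop(i)
        active.append(len(all_nodes) - 1)
    root = all_nodes[active[0]]

    # parent ages for leaves
    parent_age: Dict[str, float] = {}

    def walk(nd, pa):
        if not nd["children"]:
            parent_age[nd["name"]] = pa
        for ch in nd["children"]:
            walk(ch, nd["age"])

    walk(root, root["age"])

    occurrences = []
    is_fossil = rng.random(n_taxa) < fossil_fraction
    for k, nm in enumerate(names):
        pa = parent_age[nm]
        if is_fossil[k]:
            tip_age = rng.uniform(0.05, 0.6) * pa
            fad = tip_age + rng.uniform(0.0, 0.5) * (pa - tip_age)
        else:
            tip_age = 0.0
            fad = 0.0 if rng.random() < 0.3 else rng.uniform(0.0, 0.5) * pa
        # update leaf age for branch-length computation
        for nd in all_nodes:
            if nd["name"] == nm:
                nd["age"] = tip_age
        occurrences.append(
            OccurrenceRecord(taxon=nm, first_appearance=float(fad), last_appearance=float(tip_age))
        )

    def newick(nd):
        if not nd["children"]:
            return nd["name"], nd["age"]
        parts = []
        for ch in nd["children"]:
            s, a = newick(ch)
            parts.append(f"{s}:{nd['age'] - a:.10f}")
        return "(" + ",".join(parts) + ")", nd["age"]

    s, _ = newick(root)
    tree = dendropy.Tree.get(data=s + ";", schema="newick", preserve_underscores=True)
    tip_ages = {o.taxon: o.last_appearance for o in occurrences}
    return TimeTree(tree=tree, tip_ages=tip_ages), occurrences


def ecology_deformation_fields(n_coords: int = 180) -> Dict[str, np.ndarray]:
    """Fixed orthonormal unit deformation fields, one per ecology label.

    Seeded once with a package constant so the planted group effects are
    reproducible across datasets and versions.
    """
    rng = np.random.default_rng(_FIELD_SEED)
    M = rng.normal(size=(n_coords, len(ECOLOGY_LABELS)))
    Q, _ = np.linalg.qr(M)
    return {label: Q[:, i].copy() for i, label in enumerate(ECOLOGY_LABELS)}


def simulate_shapes(
    spec: SimulationSpec,
    tree: TimeTree,
    projection_taxa: Sequence[str] = (),
) -> Tuple[List[LabyrinthConfiguration], Dict[str, str]]:
    """Landmark configurations evolving by BM on the tree plus ecology effects.

    Each taxon's 60x3 landmark block is the resampled template plus (1) a
    multivariate Brownian deviation with tip covariance from the tree, (2) a
    fixed deformation field for its ecology group scaled by the effect size,
    and (3) iid Gaussian landmark noise.  ``projection_taxa`` are emitted with
    unknown ecology and role "projection" (their true group is still returned
    in the label map for validation studies).
    """
    taxa = tree.taxa
    props = spec.group_proportions()
    groups = [g for g in ECOLOGY_LABELS if props.get(g, 0.0) > 0]
    if len(taxa) < len(groups):
        raise ValidationError("need at least as many tips as ecology groups")
    rng = np.random.default_rng(spec.seed)
    template = landmarks_from_curves(
        SpecimenRecord("template", "template", ecology="terrestrial"),
        base_labyrinth_template(),
    ).landmarks
    t = template.reshape(-1)

    C = bm_covariance(tree)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(taxa)))
    dev = np.sqrt(spec.bm_rate) * (L @ rng.standard_normal((len(taxa), t.size)))

    p = np.array([props[g] for g in groups])
    labels = {tx: groups[i] for tx, i in zip(taxa, rng.choice(len(groups), size=len(taxa), p=p))}
    # guarantee every group is represented
    for i, g in enumerate(groups):
        if g not in labels.values():
            labels[taxa[i]] = g
    fields = ecology_deformation_fields(t.size)

    configs = []
    out_labels = {}
    proj = set(projection_taxa)
    for r, tx in enumerate(taxa):
        g = labels[tx]
        vec = (
            t
            + dev[r]
            + spec.ecology_effect_size * fields[g]
            + spec.landmark_noise_sd * rng.standard_normal(t.size)
        )
        lm = vec.reshape(-1, 3)
        # a labyrinth whose total deviation rivals the template's own size is
        # no longer a recognizable canal system
        if np.linalg.norm(vec - t) > 0.5 * np.linalg.norm(t - t.mean()):
            raise ValidationError(
                "effect sizes large enough to collapse curves; reduce magnitudes"
            )
        record = SpecimenRecord(
            specimen_id=tx,
            taxon=tx,
            side="left",
            ecology=None if tx in proj else g,
            group_role="projection" if tx in proj else "training",
        )
        # the landmark chains double as the digitized centerline polylines,
        # so downstream sliding is constrained to the original curves
        curves = tuple(
            CanalCurve(canal=name, points=lm[c * 20 : (c + 1) * 20].copy())
            for c, name in enumerate(("anterior", "posterior", "lateral"))
        )
        configs.append(
            LabyrinthConfiguration(specimen=record, landmarks=lm, curves=curves)
        )
        out_labels[tx] = g
    return configs, out_labels


def simulate_hearing_table(
    n: int = 30,
    slope: float = 3391.3,
    intercept: float = 4026.8,
    noise_sd: float = 700.0,
    seed: int = 0,
    range_slope: float = 6190.0,
    range_intercept: float = 7003.193,
) -> pd.DataFrame:
    """Extant hearing reference table with a linear log-duct-length signal.

    Scaled log duct lengths are drawn uniformly on [-1.2, -0.2] (the
    biologically occupied band for reptiles and birds); both hearing
    responses are linear in x with Gaussian noise.  One taxon is emitted with
    a missing duct length to exercise the fitting exclusion rule.
    """
    if n < 3:
        raise ValidationError("need n >= 3 reference taxa")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.2, -0.2, size=n)
    basicranium = rng.uniform(8.0, 30.0, size=n)
    duct = basicranium * 10.0**x
    # strictly linear responses (no truncation): the generator's estimand is
    # the regression line itself, so rare sub-zero draws near x = -1.2 are
    # tolerated rather than clipping and biasing the fit
    best_freq = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    best_range = range_slope * x + range_intercept + rng.normal(0.0, noise_sd, size=n)
    df = pd.DataFrame(
        {
            "taxon": [f"ref{i+1}" for i in range(n)],
            "duct_length": duct,
            "basicranium": basicranium,
            "best_frequency": best_freq,
            "best_range": best_range,
        }
    )
    df.loc[n - 1, "duct_length"] = np.nan  # taxon without duct-length data
    return df


def simulate_bundle(spec: SimulationSpec, outdir, n_projection: int = 2) -> Dict[str, str]:
    """Write a complete synthetic input bundle for the pipeline.

    Emits curve-csv landmarks, specimen metadata, a Newick topology, an
    occurrence table and a hearing reference table under ``outdir``; the last
    ``n_projection`` taxa (sorted order) are emitted as fossils of unknown
    ecology.  Returns the path map.
    """
    from pathlib import Path

    from otomorph import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tt, occurrences = simulate_tree(spec.n_taxa, seed=spec.seed)
    proj = tt.taxa[-n_projection:] if n_projection else []
    configs, _ = simulate_shapes(spec, tt, projection_taxa=proj)
    paths = {
        "landmarks": str(outdir / "landmarks.csv"),
        "metadata": str(outdir / "metadata.csv"),
        "tree": str(outdir / "tree.nwk"),
        "occurrences": str(outdir / "occurrences.csv"),
        "hearing_table": str(outdir / "hearing.csv"),
    }
    io_formats.write_landmarks(configs, paths["landmarks"])
    io_formats.write_metadata([c.specimen for c in configs], paths["metadata"])
    # topology only: calibration assigns branch durations downstream
    topo = tt.tree.clone(depth=1)
    for nd in topo.preorder_node_iter():
        nd.edge.length = None
    io_formats.write_newick(topo, paths["tree"])
    io_formats.write_occurrences(occurrences, paths["occurrences"])
    io_formats.write_hearing_table(
        simulate_hearing_table(seed=spec.seed), paths["hearing_table"]
    )
    return paths
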