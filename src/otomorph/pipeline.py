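"""End-to-end pipeline: from curve files and a topology to statistics,
classification and hearing predictions on disk.

Every stochastic stage draws its seed deterministically from the run seed, so
re-running with identical inputs and configuration reproduces every output
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from otomorph.classify import (
    classification_accuracy,
    filter_singleton_groups,
    fit_cva,
    project,
    typicality,
)
from otomorph.config import RunConfig
from otomorph.curves import mirror_configuration, slide_semilandmarks
from otomorph.hearing import fit_hearing_model, predict, summarize
from otomorph.io_formats import (
    attach_metadata,
    read_hearing_table,
    read_landmarks,
    read_metadata,
    read_newick,
    read_occurrences,
    write_newick,
)
from otomorph.phylo import (
    TimeTree,
    blomberg_k_mult,
    consensus_tree,
    estimate_rates,
    time_calibrate,
)
from otomorph.procrustes import gpa, min_pcs_for_variance, pca_shapes
from otomorph.shape_stats import procrustes_ancova, procrustes_pgls
from otomorph.types import OtomorphError, ValidationError

_FLOAT = "%.12g"
_STAGES = ("timecal", "signal_size", "signal_shape", "anova", "pgls", "typicality")


@dataclass
class PipelineInputs:
    landmarks: str
    metadata: str
    tree: str
    occurrences: str
    hearing_table: Optional[str] = None
    hearing_x: Optional[float] = None
    landmark_dialect: str = "curve-csv"


def _stage_seeds(seed: int) -> Dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=_FLOAT)


def run_pipeline(config: RunConfig, inputs: PipelineInputs, outdir) -> Dict[str, object]:
    """Run every stage and write the result bundle under ``outdir``.

    Returns a summary dict mirroring what was written.  Any stage failure is
    re-raised with the stage name prepended.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.random_seed)
    summary: Dict[str, object] = {"seed": config.random_seed, "stage_seeds": seeds}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and isinstance(exc, OtomorphError):
                    raise type(exc)(f"[stage {name}] {exc}") from exc
                return False

        return _Ctx()

    with stage("ingest"):
        configs = read_landmarks(inputs.landmarks, dialect=inputs.landmark_dialect)
        records = read_metadata(inputs.metadata)
        configs = attach_metadata(configs, records)
        configs = [
            mirror_configuration(c) if c.specimen.side == "right" else c for c in configs
        ]
        topology = read_newick(inputs.tree)
        occurrences = read_occurrences(inputs.occurrences)

    with stage("slide"):
        slid, slide_info = slide_semilandmarks(configs)

    with stage("gpa"):
        aligned = gpa([c.landmarks for c in slid])
        ids = [c.specimen.specimen_id for c in slid]
        n = len(ids)
        coords = aligned.coordinates.reshape(n, -1)
        cols = [f"{ax}{i}" for i in range(coords.shape[1] // 3) for ax in "xyz"]
        _write_df(
            pd.DataFrame(coords, index=pd.Index(ids, name="specimen_id"), columns=cols),
            outdir / "aligned_coordinates.csv",
        )

    with stage("pca"):
        space = pca_shapes(aligned)
        k = min_pcs_for_variance(space, config.variance_threshold)
        score_df = pd.DataFrame(
            space.scores,
            index=pd.Index(ids, name="specimen_id"),
            columns=[f"PC{i+1}" for i in range(space.scores.shape[1])],
        )
        _write_df(score_df, outdir / "pc_scores.csv")
        _write_df(
            pd.DataFrame(
                {
                    "eigenvalue": space.eigenvalues,
                    "variance_fraction": space.variance_fractions,
                },
                index=pd.Index(
                    [f"PC{i+1}" for i in range(len(space.eigenvalues))], name="axis"
                ),
            ),
            outdir / "pc_variance.csv",
        )
        summary["retained_pcs"] = k

    with stage("timecal"):
        durations = [o.duration for o in occurrences]
        rates = estimate_rates(durations)
        trees = time_calibrate(
            topology, occurrences, rates,
            n_trees=config.n_calibrated_trees, seed=seeds["timecal"],
        )
        cons = consensus_tree(trees)
        write_newick(cons.tree, outdir / "consensus_tree.nwk")
        summary["rates"] = {
            "sampling_rate": rates.sampling_rate,
            "extinction_rate": rates.extinction_rate,
            "speciation_rate": rates.speciation_rate,
        }

    # one specimen per tip, in sorted-taxon order, for the comparative stages
    tip_labels = set(cons.taxa)
    by_taxon: Dict[str, int] = {}
    for i in sorted(range(n), key=lambda i: ids[i]):
        tx = slid[i].specimen.taxon
        if tx in tip_labels and tx not in by_taxon:
            by_taxon[tx] = i
    phylo_taxa = sorted(by_taxon)
    rows = [by_taxon[t] for t in phylo_taxa]

    with stage("physignal"):
        sizes = aligned.centroid_sizes
        tangent = coords
        sig_size = blomberg_k_mult(
            sizes[rows, None], cons, n_perm=config.n_perm_signal,
            seed=seeds["signal_size"], taxa=phylo_taxa,
        )
        sig_shape = blomberg_k_mult(
            tangent[rows], cons, n_perm=config.n_perm_signal,
            seed=seeds["signal_shape"], taxa=phylo_taxa,
        )
        summary["phylo_signal"] = {
            "centroid_size": {"K": sig_size.K, "p": sig_size.p_value},
            "shape": {"K": sig_shape.K, "p": sig_shape.p_value},
        }

    with stage("anova"):
        train = [i for i in range(n) if slid[i].specimen.group_role == "training"]
        for i in train:
            if slid[i].specimen.ecology is None:
                raise ValidationError(
                    f"training specimen {ids[i]!r} lacks an ecology label"
                )
        # the permutation linear models and the CVA all need >= 2 specimens
        # per ecology group; singleton groups are dropped once here
        kept, dropped = filter_singleton_groups([slid[i].specimen for i in train])
        kept_ids = {r.specimen_id for r in kept}
        fit_rows = [i for i in train if ids[i] in kept_ids]
        eco = [slid[i].specimen.ecology for i in fit_rows]
        anova = procrustes_ancova(
            tangent[fit_rows], eco, sizes[fit_rows],
            n_perm=config.n_perm_anova, seed=seeds["anova"], alpha=config.alpha,
        )
        _write_df(anova.table, outdir / "ancova.csv")

    with stage("pgls"):
        ptrain = [t for t in phylo_taxa if by_taxon[t] in set(fit_rows)]
        # deduplication to one specimen per tip can recreate singleton groups
        pkept, _ = filter_singleton_groups([slid[by_taxon[t]].specimen for t in ptrain])
        pkept_ids = {r.specimen_id for r in pkept}
        ptrain = [t for t in ptrain if ids[by_taxon[t]] in pkept_ids]
        prows = [by_taxon[t] for t in ptrain]
        pgls = procrustes_pgls(
            tangent[prows],
            [slid[i].specimen.ecology for i in prows],
            sizes[prows],
            cons,
            n_perm=config.n_perm_anova, seed=seeds["pgls"], alpha=config.alpha,
            taxa=ptrain,
        )
        _write_df(pgls.table, outdir / "pgls.csv")

    with stage("cva"):
        labels = [slid[i].specimen.ecology for i in fit_rows]
        # the variance rule caps k, but the pooled within-group covariance
        # must stay invertible: k < n - g
        g = len(set(labels))
        k = max(1, min(k, len(fit_rows) - g - 1))
        scores_k = space.scores[:, :k]
        model = fit_cva(scores_k[fit_rows], labels)
        acc_resub = classification_accuracy(
            scores_k[fit_rows], labels, mode="resubstitution", model=model
        )
        acc_loo = classification_accuracy(scores_k[fit_rows], labels, mode="loo")
        proj_rows = [i for i in range(n) if slid[i].specimen.group_role == "projection"]
        report = {}
        for j, i in enumerate(proj_rows):
            res = typicality(
                model, scores_k[i],
                n_perm=config.n_perm_typicality,
                seed=(seeds["typicality"] + j) % (2**31),
                alpha=config.alpha,
            )
            report[ids[i]] = {
                "canonical_scores": [float(v) for v in project(model, scores_k[i])],
                "mahalanobis": res.distances,
                "typicality_p": res.typicality_p,
                "likelihood": res.likelihoods,
                "assigned_group": res.assigned_group,
                "alpha_corrected": res.alpha_corrected,
                "significantly_different": res.significantly_different,
            }
        summary["classification"] = {
            "dropped_singletons": sorted(r.specimen_id for r in dropped),
            "retained_pcs": k,
            "accuracy_resubstitution": acc_resub,
            "accuracy_loo": acc_loo,
            "projections": report,
        }
        (outdir / "classification.json").write_text(
            json.dumps(summary["classification"], indent=2, sort_keys=True) + "\n"
        )

    if inputs.hearing_table is not None:
        with stage("hearing"):
            table = read_hearing_table(inputs.hearing_table)
            x_ref = np.log10(table["duct_length"] / table["basicranium"])
            if config.log_base != 10.0:
                x_ref = x_ref * np.log(10.0) / np.log(config.log_base)
            m_freq = fit_hearing_model(
                x_ref, table["best_frequency"], response="mean_best_frequency"
            )
            m_range = fit_hearing_model(x_ref, table["best_range"], response="best_range")
            hearing = {
                "mean_best_frequency": {
                    "slope": m_freq.slope, "intercept": m_freq.intercept,
                    "r_squared": m_freq.r_squared, "p_value": m_freq.p_value, "n": m_freq.n,
                },
                "best_range": {
                    "slope": m_range.slope, "intercept": m_range.intercept,
                    "r_squared": m_range.r_squared, "p_value": m_range.p_value, "n": m_range.n,
                },
            }
            if inputs.hearing_x is not None:
                f = predict(m_freq, inputs.hearing_x)
                w = predict(m_range, inputs.hearing_x)
                pred = summarize(f, max(w, 0.0))
                hearing["prediction"] = {
                    "x": inputs.hearing_x,
                    "best_frequency": pred.best_frequency,
                    "best_range_width": pred.best_range_width,
                    "range_low": pred.range_low,
                    "range_high": pred.range_high,
                }
            summary["hearing"] = hearing
            (outdir / "hearing.json").write_text(
                json.dumps(hearing, indent=2, sort_keys=True) + "\n"
            )

    summary["slide"] = {
        "converged": slide_info["converged"],
        "energies": [float(e) for e in slide_info["energies"]],
    }
    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "seed": config.random_seed,
                "stage_seeds": seeds,
                "config": {
                    "n_perm_signal": config.n_perm_signal,
                    "n_perm_anova": config.n_perm_anova,
                    "n_perm_typicality": config.n_perm_typicality,
                    "n_calibrated_trees": config.n_calibrated_trees,
                    "variance_threshold": config.variance_threshold,
                    "alpha": config.alpha,
                },
                "phylo_signal": summary["phylo_signal"],
                "rates": summary["rates"],
                "retained_pcs": summary["retained_pcs"],
                "slide": summary["slide"],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return summary
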