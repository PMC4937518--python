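"""End-to-end orchestration of the complex-prediction pipeline.

Stages: read + QC-filter the protein-groups table -> smoothed normalized
mean profiles -> whole-profile clustering -> (optional) known-complex
comparison against the native condition -> wavelet peak extraction and
filtering (mean profiles and per replicate) -> candidate peak pairs with the
six features -> gold standard + 100-classifier logistic-regression ensemble
-> thresholded interaction network -> cohesiveness clustering with grid
search.  Every stage writes its TSV beside a summary JSON of stage counts;
a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assembly, classifier, clustering, features, known_complexes, peaks
from . import profile_io

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All tunable parameters with the study's published defaults."""

    # inputs
    protein_groups: str = ""
    protein_groups_native: str | None = None
    calibration: str = ""
    catalogue: str | None = None
    string_scores: str | None = None
    hippie_scores: str | None = None
    mentha_scores: str | None = None
    # profile processing
    n_fractions: int = 48
    n_fractions_native: int = 40
    n_replicates: int = 3
    min_peptides: int = 2
    min_replicates: int = 2
    # clustering
    tree_cut_target_pcc: float = 0.95
    # peak extraction
    wavelet_width_min: int = 2
    wavelet_width_max: int = 8
    noise_frac: float = 0.15
    void_fraction_max: int = 4
    min_apex_sep: int = 3
    dimer_slack: float = 1.0
    # pair features
    max_apex_delta: int = 1
    ordered_pairs: bool = False
    # classifier
    n_negative_sets: int = 100
    cv_folds: int = 10
    score_cutoff: float = 0.75
    # assembly
    cluster_min_size: int = 2
    cluster_penalty: float = 2.0
    cluster_overlap_merge: float = 0.8
    grid_step: float = 0.1
    # control
    seed: int = 0
    stop_after: str | None = None  # stage name for partial runs

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reraise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the pipeline; returns the summary dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    summary: dict = {"seed": config.seed, "counts": {}}
    counts = summary["counts"]
    schema = profile_io.TableSchema(n_replicates=config.n_replicates)

    # ---- profile IO ------------------------------------------------------
    @_stage("profile_io")
    def load():
        groups, reps = profile_io.read_protein_groups(
            config.protein_groups, schema, "crosslinked", config.n_fractions
        )
        counts["groups_total"] = len(groups)
        groups, reps = profile_io.qc_filter(
            groups, reps, config.min_peptides, config.min_replicates
        )
        counts["groups_retained"] = len(groups)
        means = profile_io.build_mean_profiles(reps)
        calibration = profile_io.read_calibration(config.calibration)
        return groups, reps, means, calibration

    groups, reps, means, calibration = load()
    profile_io.write_mean_profiles(means, out / "mean_profiles.tsv")
    if config.stop_after == "profile_io":
        return _finish(summary, out)

    # ---- basic clustering ------------------------------------------------
    @_stage("clustering")
    def cluster():
        dendrogram = clustering.hierarchical_cluster(means)
        assignment = clustering.cut_by_mean_pcc(
            dendrogram, means, config.tree_cut_target_pcc
        )
        counts["clusters"] = len(set(assignment.labels.values()))
        return assignment

    assignment = cluster()
    import pandas as pd

    pd.DataFrame(
        sorted(assignment.labels.items()), columns=["group_id", "cluster_id"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    (out / "clusters_summary.json").write_text(
        json.dumps(
            {
                "n_clusters": len(set(assignment.labels.values())),
                "achieved_mean_pcc": assignment.achieved_mean_pcc,
                "cut_height": assignment.cut_height,
            },
            indent=2,
        )
    )
    if config.stop_after == "clustering":
        return _finish(summary, out)

    # ---- known-complex comparison (needs catalogue + native table) -------
    catalogue = (
        known_complexes.read_catalogue(config.catalogue) if config.catalogue else []
    )
    if catalogue and config.protein_groups_native:

        @_stage("known_complexes")
        def compare():
            ngroups, nreps = profile_io.read_protein_groups(
                config.protein_groups_native, schema, "native",
                config.n_fractions_native,
            )
            ngroups, nreps = profile_io.qc_filter(
                ngroups, nreps, config.min_peptides, config.min_replicates
            )
            nmeans = profile_io.build_mean_profiles(nreps)
            by_acc_nat = {
                a: mp
                for g, mp in zip(ngroups, nmeans)
                for a in g.accessions
            }
            by_acc_xl = {}
            means_by_gid = {m.group_id: m for m in means}
            for g in groups:
                mp = means_by_gid.get(g.group_id)
                if mp is not None:
                    for a in g.accessions:
                        by_acc_xl[a] = mp
            scores = known_complexes.score_complexes(
                catalogue, by_acc_nat, by_acc_xl
            )
            counts["known_complexes_scored"] = len(scores)
            return scores

        scores = compare()
        known_complexes.condition_scatter(scores).to_csv(
            out / "known_complexes.tsv", sep="\t", index=False
        )
    if config.stop_after == "known_complexes":
        return _finish(summary, out)

    # ---- peak extraction -------------------------------------------------
    @_stage("peaks")
    def extract():
        widths = range(config.wavelet_width_min, config.wavelet_width_max + 1)
        void = frozenset(range(1, config.void_fraction_max + 1))
        mw_by_gid = {g.group_id: g.monomer_mw_kda for g in groups}
        mean_peaks: list[peaks.Peak] = []
        n_raw = 0
        for mp in means:
            raw = peaks.extract_peaks(
                mp, widths, calibration, mw_by_gid.get(mp.group_id)
            )
            n_raw += len(raw)
            mean_peaks.extend(
                peaks.filter_peaks(
                    raw, float(mp.mean.max()), calibration, void,
                    config.noise_frac, config.min_apex_sep, config.dimer_slack,
                )
            )
        rep_peaks: dict[str, dict[int, list[peaks.Peak]]] = {}
        for rp in reps:
            processed = profile_io.process_replicate(rp)
            raw = peaks.extract_peaks(
                processed, widths, calibration, mw_by_gid.get(rp.group_id),
                source=f"rep{rp.replicate_index}",
            )
            kept = peaks.filter_peaks(
                raw, float(processed.intensities.max()), calibration, void,
                config.noise_frac, config.min_apex_sep, config.dimer_slack,
            )
            rep_peaks.setdefault(rp.group_id, {})[rp.replicate_index] = kept
        counts["peaks_raw"] = n_raw
        counts["peaks_filtered"] = len(mean_peaks)
        return mean_peaks, rep_peaks

    mean_peaks, rep_peaks = extract()
    peaks.peaks_to_table(mean_peaks).to_csv(out / "peaks.tsv", sep="\t", index=False)
    if config.stop_after == "peaks":
        return _finish(summary, out)

    # ---- pair features ---------------------------------------------------
    @_stage("features")
    def featurize():
        pairs = features.candidate_pairs(
            mean_peaks, config.max_apex_delta, config.ordered_pairs
        )
        features.compute_features(pairs, rep_peaks, config.n_replicates)
        acc_by_gid = {g.group_id: g.accessions for g in groups}
        tables = []
        for path in (config.string_scores, config.hippie_scores, config.mentha_scores):
            tables.append(features.load_score_table(path) if path else {})
        features.join_db_scores(pairs, *tables, acc_by_gid)
        counts["candidate_pairs"] = len(pairs)
        return pairs

    pairs = featurize()
    features.pairs_to_table(pairs).to_csv(out / "pair_features.tsv", sep="\t", index=False)
    if config.stop_after == "features":
        return _finish(summary, out)

    # ---- classifier ------------------------------------------------------
    @_stage("classifier")
    def score():
        acc_by_gid = {g.group_id: g.accessions for g in groups}
        gold = classifier.build_gold_standard(
            catalogue, pairs, acc_by_gid, config.seed, config.n_negative_sets
        )
        counts["gold_positives"] = len(gold.positives)
        counts["negative_pool"] = len(gold.negative_pool)
        ensemble = classifier.train_ensemble(gold, config.cv_folds)
        scored = classifier.score_pairs(ensemble, pairs)
        edges = classifier.threshold_pairs(scored, config.score_cutoff)
        counts["edges"] = len(edges)
        return gold, ensemble, scored, edges

    gold, ensemble, scored, edges = score()
    tab = features.pairs_to_table([s.pair for s in scored])
    tab["score"] = [s.score for s in scored]
    tab["passed"] = [s.score > config.score_cutoff for s in scored]
    tab.to_csv(out / "scored_pairs.tsv", sep="\t", index=False)
    (out / "ensemble_summary.json").write_text(
        json.dumps(
            {"cv_auc": ensemble.cv_auc, "seed": config.seed,
             "cutoff": config.score_cutoff},
            indent=2,
        )
    )
    if config.stop_after == "classifier":
        return _finish(summary, out)

    # ---- complex assembly ------------------------------------------------
    @_stage("assembly")
    def assemble():
        graph = assembly.build_network(edges)
        gold_nodes = {
            frozenset(
                {
                    (p.group_a, p.peak_a.apex_fraction),
                    (p.group_b, p.peak_b.apex_fraction),
                }
            )
            for p in gold.positives
        }
        n_steps = int(round(1.0 / config.grid_step))
        grid_vals = [round(config.grid_step * i, 10) for i in range(1, n_steps + 1)]
        result = assembly.grid_search(
            graph, gold_nodes, grid_vals, grid_vals,
            s=config.cluster_min_size,
            overlap_merge=config.cluster_overlap_merge,
            penalty=config.cluster_penalty,
        )
        counts["complexes"] = len(result.complexes)
        return graph, result

    graph, result = assemble()
    assembly.complexes_to_table(result.complexes).to_csv(
        out / "complexes.tsv", sep="\t", index=False
    )
    result.table.to_csv(out / "grid_search.tsv", sep="\t", index=False)
    assembly.export_network(graph, out / "network_nodes.tsv", out / "network_edges.tsv")
    summary["grid_best"] = {
        "d": result.best_d,
        "haircut": result.best_haircut,
        "objective": result.objective,
    }
    return _finish(summary, out)


def _finish(summary: dict, out: Path) -> dict:
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
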