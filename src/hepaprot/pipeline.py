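"""End-to-end orchestration: quantification -> clustering/PCA -> enrichment -> markers.

The pipeline runs either on files (per-run quantification tables, sample
metadata, OBO ontology, annotation TSV) or in simulate mode, where the
synthetic generator produces all inputs from one seed.  Every intermediate
is written as TSV and a manifest records the configuration hash, the seed,
row/column counts at each stage and drop events, so a run is auditable and
two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cluster, goenrich, markers, pca, quantio, synthdata
from .errors import ConfigurationError, HepaprotError

logger = logging.getLogger(__name__)

#: Orientation anchors reproducing the study's sign conventions: hepatic
#: maturity positive on PC1, fresh fetal positive on PC2, dedifferentiated
#: ECM-sandwich culture positive on PC3.
DEFAULT_ANCHORS = (
    ("PC1", "fresh_adult", "positive"),
    ("PC2", "fresh_fetal", "positive"),
    ("PC3", "adult_ecm", "positive"),
)


@dataclass
class PipelineConfig:
    # run-mode inputs
    run_tables: tuple[str, ...] = ()
    sample_meta: str | None = None
    ontology: str | None = None
    annotations: str | None = None
    pool_channel: str = synthdata.ITRAQ8_CHANNELS[0]
    # simulate mode
    simulate: bool = False
    synth: dict = field(default_factory=dict)     # SynthConfig overrides
    synth_n_terms: int = 60                       # ontology size in simulate mode
    # analysis parameters
    transform: str = "log2"
    linkage: str = "complete"
    anchors: tuple[tuple[str, str, str], ...] = DEFAULT_ANCHORS
    n_score_components: int = 4
    score_methods: tuple[str, ...] = ("absWilcox",)
    elim_threshold: float = 1e-3
    report_threshold: float = 1e-3
    min_term_size: int = 3
    k: int = markers.DEFAULT_K
    signatures: dict = field(default_factory=lambda: {
        name: tuple(crit) for name, crit in markers.DEFAULT_SIGNATURES.items()
    })
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate:
            if not self.run_tables or self.sample_meta is None:
                raise ConfigurationError("run mode requires run_tables and sample_meta")
            for p in list(self.run_tables) + [self.sample_meta, self.ontology, self.annotations]:
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"input file does not exist: {p}")
        if not 0 <= self.elim_threshold <= 1 or not 0 < self.report_threshold <= 1:
            raise ConfigurationError("thresholds must lie in (0, 1] (elim may be 0)")
        if self.k < 1:
            raise ConfigurationError("marker list size k must be >= 1")
        if self.transform not in pca.TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.linkage not in cluster.LINKAGES:
            raise ConfigurationError(f"unknown linkage {self.linkage!r}")
        for m in self.score_methods:
            if m not in goenrich.SCORE_TEST_METHODS:
                raise ConfigurationError(f"unknown score test {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        cfg = cls(**raw)
        # normalize YAML lists to tuples for hashing stability
        cfg.run_tables = tuple(cfg.run_tables)
        cfg.anchors = tuple(tuple(a) for a in cfg.anchors)
        cfg.score_methods = tuple(cfg.score_methods)
        cfg.signatures = {n: tuple(tuple(c) for c in crit) for n, crit in cfg.signatures.items()}
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(HepaprotError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except HepaprotError as exc:
        raise PipelineError(name, exc) from exc


def _simulate_inputs(config: PipelineConfig, outdir: Path):
    synth_cfg = synthdata.SynthConfig(seed=config.seed, **config.synth)
    dag = ann = None
    if config.synth_n_terms > 0:
        dag, ann = synthdata.generate_ontology(
            config.synth_n_terms, synth_cfg.n_proteins, seed=config.seed
        )
    runs, meta, truth = synthdata.generate_experiment(synth_cfg, annotations=ann)
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)
    for run in runs:
        quantio.write_run_table(run, data / f"{run.run_id}.tsv")
    quantio.write_sample_meta(meta, data / "sample_meta.tsv")
    if dag is not None:
        goenrich.write_obo(dag, data / "ontology.obo")
        goenrich.write_annotations(ann.direct, data / "annotations.tsv")
    synthdata.write_truth(truth, data / "truth.txt")
    return runs, meta, dag, ann, meta.attrs["pool_channel"]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order, writing TSV intermediates and a manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "events": [],
    }

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        runs, meta, dag, ann_map, pool = _stage("simulate", _simulate_inputs, config, outdir)
    else:
        pool = config.pool_channel
        runs = [
            _stage("read_runs", quantio.read_run_table, p, pool)
            for p in config.run_tables
        ]
        meta = _stage("read_meta", quantio.read_sample_meta, config.sample_meta)
        dag = ann_map = None
        if config.ontology and config.annotations:
            dag = _stage("read_ontology", goenrich.read_obo, config.ontology)
            direct = _stage("read_annotations", goenrich.read_annotations, config.annotations)
            ann_map = _stage("propagate", goenrich.propagate_annotations, direct, dag)
    manifest["stages"]["input"] = {
        "n_runs": len(runs),
        "n_samples": int(len(meta)),
        "identified_per_run": {r.run_id: int(len(r.table)) for r in runs},
        "n_identified_union": int(len(set().union(*(set(r.accessions) for r in runs)))),
    }

    # ---- quantification ---------------------------------------------------
    filtered = [_stage("filter_identifications", quantio.filter_identifications, r) for r in runs]
    normalized = [_stage("relative_to_pool", quantio.relative_to_pool, r) for r in filtered]
    for r in normalized:
        if r.n_dropped_pool:
            manifest["events"].append(
                f"run {r.run_id}: {r.n_dropped_pool} records dropped (missing/zero pool)"
            )
    merged = _stage("merge_runs", quantio.merge_runs, normalized, meta)
    quantio.write_expression_matrix(merged, outdir / "expression_merged.tsv")
    common = _stage("filter_common_proteins", quantio.filter_common_proteins, merged)
    if len(common.values) < 2:
        raise PipelineError("filter_common_proteins",
                            HepaprotError("fewer than 2 proteins quantified in every sample"))
    pre_means = quantio.sample_means(common)
    normalized_m = _stage("equalize_sample_means", quantio.equalize_sample_means, common)
    quantio.write_expression_matrix(normalized_m, outdir / "expression_common.tsv")
    manifest["stages"]["quantification"] = {
        "n_merged": int(len(merged.values)),
        "n_common": int(len(common.values)),
        "pre_normalization_sample_means": {s: float(v) for s, v in pre_means.items()},
    }

    # ---- clustering -------------------------------------------------------
    log_flag = config.transform == "log2"
    dist = _stage("distances", cluster.sample_distance_matrix, normalized_m, log_flag)
    dist.to_csv(outdir / "distances.tsv", sep="\t")
    dend = _stage("cluster", cluster.hierarchical_cluster, dist, config.linkage)
    (outdir / "dendrogram.newick").write_text(cluster.to_newick(dend) + "\n")
    n_groups = int(meta["group"].nunique())
    assign = dend.cut(min(n_groups, len(dend.labels)))
    assign.rename_axis("sample_id").to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
    purity = cluster.group_purity(dend, meta, min(n_groups, len(dend.labels)))
    manifest["stages"]["cluster"] = {
        "linkage": config.linkage,
        "leaf_order": dend.leaf_order,
        "k": n_groups,
        "group_purity": purity,
    }

    # ---- PCA --------------------------------------------------------------
    result = _stage("pca", pca.run_pca, normalized_m, config.transform)
    present_groups = set(meta["group"])
    usable_anchors = [
        a for a in config.anchors
        if a[0] in result.components and a[1] in present_groups
    ]
    result = _stage("orient", pca.orient_components, result, usable_anchors, meta)
    pca.write_pca(result, outdir / "pca_scores.tsv", outdir / "pca_loadings.tsv",
                  outdir / "pca_variance.tsv")
    manifest["stages"]["pca"] = {
        "n_components": len(result.components),
        "variance_fraction": {c: float(v) for c, v in result.variance_fraction.items()},
        "anchors_applied": [list(a) for a in usable_anchors],
    }

    # ---- enrichment -------------------------------------------------------
    if dag is not None and ann_map is not None:
        foreground = sorted(set(normalized_m.accessions) & set(ann_map.proteins))
        enrich_stage: dict = {}
        if foreground:
            det = _stage("detection_test", goenrich.detection_test,
                         foreground, ann_map, dag, config.min_term_size)
            goenrich.records_to_frame(det).to_csv(
                outdir / "enrichment_detection.tsv", sep="\t", index=False)
            enrich_stage["detection_n_terms_tested"] = len(det)
            enrich_stage["detection_foreground"] = len(foreground)
        n_comp = min(config.n_score_components, len(result.components))
        score_background = 0
        for method in config.score_methods:
            for j in range(1, n_comp + 1):
                comp = f"PC{j}"
                # background is every scored protein, annotated or not
                scores = result.protein_scores[comp]
                score_background = len(scores)
                recs = _stage(
                    "elim_enrichment", goenrich.elim_enrichment,
                    scores, dag, ann_map, method,
                    config.elim_threshold, config.report_threshold,
                    config.min_term_size, comp,
                )
                goenrich.records_to_frame(recs).to_csv(
                    outdir / f"enrichment_{comp}_{method}.tsv", sep="\t", index=False)
                goenrich.violin_table(recs, scores).to_csv(
                    outdir / f"violin_{comp}_{method}.tsv", sep="\t", index=False)
                if recs:
                    clusters = goenrich.cluster_terms(recs)
                    pd.DataFrame(
                        [
                            {"cluster": i + 1, "terms": ";".join(c["terms"]),
                             "proteins": ";".join(c["proteins"])}
                            for i, c in enumerate(clusters)
                        ]
                    ).to_csv(outdir / f"term_clusters_{comp}_{method}.tsv",
                             sep="\t", index=False)
                enrich_stage[f"{comp}_{method}_n_reported"] = len(recs)
        enrich_stage["score_test_background"] = score_background
        manifest["stages"]["enrichment"] = enrich_stage

    # ---- markers ----------------------------------------------------------
    k = min(config.k, len(normalized_m.values))
    if k < config.k:
        manifest["events"].append(
            f"marker list size reduced to {k} (only {len(normalized_m.values)} common proteins)"
        )
    marker_stage = {}
    for name, criteria in config.signatures.items():
        if any(c not in result.components for c, _ in criteria):
            manifest["events"].append(f"signature {name!r} skipped: component unavailable")
            continue
        ms = _stage("markers", markers.signature, result.protein_scores, criteria, k, name)
        markers.write_marker_set(ms, outdir / f"markers_{name}.tsv")
        marker_stage[name] = len(ms)
    manifest["stages"]["markers"] = {"k": k, "signature_sizes": marker_stage}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
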