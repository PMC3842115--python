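"""Synthetic multi-run isobaric quantification data with planted ground truth.

The generator emulates the statistical structure of a pooled-reference
8-plex study of liver-cell proteomes: four labeling runs, each with one
reference-pool channel; six sample groups (fresh fetal hepatocytes, fresh
adult hepatocytes, HepG2 cells, and three culture formats); ~1,500 proteins
of which a core fraction is detectable everywhere; log2-normal group, run and
channel effects; and abundance-dependent run-level dropout.  It also builds a
small random is_a ontology with protein annotations so that enrichment can be
tested against planted signal.

Generative model (log2 scale).  Protein p measured in channel of sample s
(group g) in run r:

    q(p, s) = 2 ** (b_p + e_{p,g} + u_r + eps),     eps ~ N(0, noise_sd)

with per-protein baseline b_p ~ N(0, baseline_sd), group effect matrix e,
and run offset u_r ~ N(0, run_effect_sd).  The pool channel of run r carries
the equal-weight mean of the group mean abundances:

    pool(p, r) = 2 ** (b_p + mean_g e_{p,g} + u_r + eps_pool)

so the pool-relative ratio cancels both baseline and run offset up to noise.
Detection operates per (protein, run): core proteins are always detected,
the rest with probability ``expit(detect_slope * (b_p - detect_midpoint))``,
modeling the abundance dependence of shotgun identification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .goenrich import AnnotationMap, OntologyDAG, propagate_annotations
from .quantio import ADULT_GROUPS, GROUPS, RunTable

import networkx as nx

#: iTRAQ 8-plex reporter-ion channel labels.
ITRAQ8_CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")

#: Default per-group sample counts: 24 samples over four 8-plex runs.
DEFAULT_GROUPS = (
    ("fresh_fetal", 8),
    ("fresh_adult", 4),
    ("hepg2", 3),
    ("fetal_ali3d", 3),
    ("adult_ali3d", 3),
    ("adult_ecm", 3),
)

#: Latent axes of the default "axes" effect structure and their group design.
#: Axis 1: hepatic maturity (adult-derived high, fetal and HepG2 low).
#: Axis 2: transformed line (HepG2 low, fresh fetal high).
#: Axis 3: culture dedifferentiation (ECM-sandwich high, fresh adult low).
#: Axis 4: membrane-culture signature, so each culture format carries its own
#: coherent proteome shift and cosegregates as a group adjacent to — but
#: distinct from — its fresh parent cell type.
AXIS_DESIGN = pd.DataFrame(
    {
        "fresh_fetal": [-1.0, 0.6, 0.0, 0.0],
        "fresh_adult": [1.0, 0.0, -0.6, 0.0],
        "hepg2": [-1.0, -1.0, 0.0, 0.0],
        "fetal_ali3d": [-0.8, 0.5, 0.2, 1.0],
        "adult_ali3d": [0.8, 0.0, -0.2, 1.0],
        "adult_ecm": [0.6, 0.0, 1.0, 0.3],
    },
    index=["axis1", "axis2", "axis3", "axis4"],
)

#: Relative strength of the latent axes.
AXIS_WEIGHTS = (1.0, 0.6, 0.45, 0.35)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study; defaults mirror the study design."""

    n_proteins: int = 1500
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_runs: int = 4
    channels_per_run: int = 8
    effect_sd: float = 1.0           # log2 group-effect scale
    run_effect_sd: float = 0.3       # log2 run-offset scale
    noise_sd: float = 0.25           # log2 channel noise
    baseline_sd: float = 2.0         # log2 spread of protein abundances
    detect_midpoint: float = 2.0     # logistic dropout midpoint (log2 baseline)
    detect_slope: float = 0.6        # logistic dropout steepness
    frac_core: float = 0.28          # fraction of proteins always detected
    frac_low_evidence: float = 0.05  # fraction with single weak peptide evidence
    effect_structure: str = "axes"   # {"axes", "adult_vs_rest", "independent"}
    n_enriched_terms: int = 0        # terms planted on axes (needs annotations)
    enrichment_shift: float = 2.0    # planted shift, in units of effect_sd
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_runs < 1 or self.channels_per_run < 2:
            raise ConfigurationError("counts must be positive (>=2 channels per run)")
        if not self.groups:
            raise ConfigurationError("at least one sample group required")
        for name, count in self.groups:
            if name not in GROUPS:
                raise ConfigurationError(f"unknown group {name!r}; allowed: {list(GROUPS)}")
            if count < 1:
                raise ConfigurationError(f"group {name!r}: sample count must be >= 1")
        for attr in ("effect_sd", "run_effect_sd", "noise_sd", "baseline_sd"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")
        if not 0.0 <= self.frac_core <= 1.0:
            raise ConfigurationError("frac_core must be in [0, 1]")
        if not 0.0 <= self.frac_low_evidence <= 1.0:
            raise ConfigurationError("frac_low_evidence must be in [0, 1]")
        if self.effect_structure not in ("axes", "adult_vs_rest", "independent"):
            raise ConfigurationError(f"unknown effect_structure {self.effect_structure!r}")
        n_samples = sum(c for _, c in self.groups)
        capacity = self.n_runs * (self.channels_per_run - 1)
        if n_samples > capacity:
            raise ConfigurationError(
                f"{n_samples} samples do not fit {self.n_runs} runs x "
                f"{self.channels_per_run - 1} non-pool channels"
            )

    @property
    def n_samples(self) -> int:
        return sum(c for _, c in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)


@dataclass
class SynthTruth:
    """Planted ground truth recorded alongside a generated experiment."""

    baseline: pd.Series                  # per-protein log2 abundance
    group_effect: pd.DataFrame           # proteins x groups, log2
    run_effect: pd.Series                # per-run log2 offset
    core: frozenset[str]                 # always-detected proteins
    enriched_terms: tuple[tuple[str, str, str], ...]  # (term, axis/PC role, direction)
    seed: int

    def adult_vs_rest_effect(self) -> pd.Series:
        """Planted adult-vs-rest contrast: mean effect in adult-derived groups
        minus mean effect in the remaining groups."""
        adult = [g for g in self.group_effect.columns if g in ADULT_GROUPS]
        rest = [g for g in self.group_effect.columns if g not in ADULT_GROUPS]
        return self.group_effect[adult].mean(axis=1) - self.group_effect[rest].mean(axis=1)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so that changing one parameter (e.g. the
    dropout midpoint) does not perturb unrelated draws."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_ontology(
    n_terms: int, n_proteins: int, seed: int = 0
) -> tuple[OntologyDAG, AnnotationMap]:
    """Random rooted is_a DAG with direct and propagated protein annotations.

    The first term is the root; every later term gets one parent among the
    earlier terms (keeping the graph acyclic and rooted) and, with small
    probability, a second parent.  Each protein is directly annotated to one
    to three non-root terms (or to the root if it is the only term), so the
    propagated sets satisfy the true-path rule by construction.
    """
    if n_terms < 1 or n_proteins < 1:
        raise ConfigurationError("n_terms and n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    terms = [f"T:{i:07d}" for i in range(1, n_terms + 1)]
    g = nx.DiGraph()
    g.add_node(terms[0])
    for i, term in enumerate(terms[1:], start=1):
        parent = terms[int(rng.integers(0, i))]
        g.add_edge(term, parent)
        if i >= 2 and rng.random() < 0.2:
            second = terms[int(rng.integers(0, i))]
            if second != parent:
                g.add_edge(term, second)
    names = {t: f"synthetic term {i + 1}" for i, t in enumerate(terms)}
    dag = OntologyDAG(g, names)
    candidates = terms[1:] if n_terms > 1 else terms
    direct: dict[str, frozenset[str]] = {}
    for j in range(n_proteins):
        k = int(rng.integers(1, min(3, len(candidates)) + 1))
        chosen = rng.choice(len(candidates), size=k, replace=False)
        direct[f"P{j:05d}"] = frozenset(candidates[c] for c in chosen)
    return dag, propagate_annotations(direct, dag)


def assign_samples(config: SynthConfig) -> pd.DataFrame:
    """Deterministic sample -> (run, channel) layout.

    Fresh-adult samples are spread one per run (round-robin); the other
    groups are packed run-by-run into the remaining non-pool channels.  The
    first channel of every run is the pool.
    """
    config.validate()
    channels = [f"ch{c}" for c in range(config.channels_per_run)]
    if config.channels_per_run == 8:
        channels = list(ITRAQ8_CHANNELS)
    pool = channels[0]
    free: list[list[str]] = [channels[1:].copy() for _ in range(config.n_runs)]
    rows = []

    def place(group: str, idx: int, run: int) -> None:
        chan = free[run].pop(0)
        rows.append(
            {
                "sample_id": f"{group}_{idx + 1}",
                "group": group,
                "donor_id": f"donor_{group}_{idx + 1}",
                "run_id": f"run{run + 1}",
                "channel": chan,
            }
        )

    spread = [(g, c) for g, c in config.groups if g == "fresh_adult"]
    packed = [(g, c) for g, c in config.groups if g != "fresh_adult"]
    for group, count in spread:
        for i in range(count):
            run = i % config.n_runs
            if not free[run]:
                run = max(range(config.n_runs), key=lambda r: len(free[r]))
            place(group, i, run)
    run_cursor = 0
    for group, count in packed:
        for i in range(count):
            while not free[run_cursor]:
                run_cursor = (run_cursor + 1) % config.n_runs
            place(group, i, run_cursor)
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "donor_id", "run_id", "channel"])
    meta.attrs["pool_channel"] = pool
    return meta


def _group_effects(
    config: SynthConfig,
    accessions: pd.Index,
    rng: np.random.Generator,
    annotations: AnnotationMap | None,
) -> tuple[pd.DataFrame, tuple[tuple[str, str, str], ...]]:
    groups = list(config.group_names)
    n = len(accessions)
    enriched: list[tuple[str, str, str]] = []
    if config.effect_structure == "independent":
        eff = rng.normal(0.0, config.effect_sd, size=(n, len(groups)))
        return pd.DataFrame(eff, index=accessions, columns=groups), ()
    if config.effect_structure == "adult_vs_rest":
        per_protein = rng.normal(0.0, config.effect_sd, size=n)
        eff = pd.DataFrame(0.0, index=accessions, columns=groups)
        for g in groups:
            if g in ADULT_GROUPS:
                eff[g] = per_protein
        return eff, ()
    # "axes": low-rank structure mirroring maturity / cell-line / culture axes
    loadings = np.column_stack(
        [rng.normal(0.0, config.effect_sd * w, size=n) for w in AXIS_WEIGHTS]
    )
    if annotations is not None and config.n_enriched_terms > 0:
        candidates = sorted(
            t
            for t, members in annotations.propagated.items()
            if 5 <= len(members) <= max(6, n // 8)
        )
        if candidates:
            take = min(config.n_enriched_terms, len(candidates))
            chosen = rng.choice(len(candidates), size=take, replace=False)
            acc_pos = {a: i for i, a in enumerate(accessions)}
            for slot, c in enumerate(sorted(chosen)):
                term = candidates[c]
                axis = slot % len(AXIS_WEIGHTS)
                direction = 1.0 if rng.random() < 0.5 else -1.0
                shift = direction * config.enrichment_shift * config.effect_sd
                idx = sorted(acc_pos[p] for p in annotations.propagated[term] if p in acc_pos)
                loadings[idx, axis] = shift + rng.normal(
                    0.0, 0.1 * config.effect_sd, size=len(idx)
                )
                enriched.append(
                    (term, f"axis{axis + 1}", "positive" if direction > 0 else "negative")
                )
    design = AXIS_DESIGN.loc[:, groups].to_numpy()
    eff = loadings @ design
    return pd.DataFrame(eff, index=accessions, columns=groups), tuple(enriched)


def generate_experiment(
    config: SynthConfig,
    annotations: AnnotationMap | None = None,
    group_effect: pd.DataFrame | None = None,
) -> tuple[list[RunTable], pd.DataFrame, SynthTruth]:
    """Generate run tables, sample metadata and the planted truth.

    ``annotations`` (from :func:`generate_ontology`) enables planting of
    score-enriched terms under the default ``axes`` structure.  An explicit
    ``group_effect`` matrix (proteins x groups, log2) overrides the drawn one.
    """
    config.validate()
    meta = assign_samples(config)
    pool_channel = meta.attrs["pool_channel"]
    accessions = pd.Index([f"P{j:05d}" for j in range(config.n_proteins)], name="accession")
    (rng_baseline, rng_effect, rng_run, rng_noise,
     rng_detect, rng_evidence) = _streams(config.seed, 6)

    baseline = pd.Series(
        rng_baseline.normal(0.0, config.baseline_sd, size=config.n_proteins),
        index=accessions,
    )
    if group_effect is not None:
        eff = group_effect.reindex(index=accessions, columns=list(config.group_names))
        eff = eff.fillna(0.0)
        enriched: tuple[tuple[str, str, str], ...] = ()
    else:
        eff, enriched = _group_effects(config, accessions, rng_effect, annotations)
    run_ids = [f"run{r + 1}" for r in range(config.n_runs)]
    run_effect = pd.Series(
        rng_run.normal(0.0, config.run_effect_sd, size=config.n_runs), index=run_ids
    )

    n_core = int(round(config.frac_core * config.n_proteins))
    core_idx = rng_detect.choice(config.n_proteins, size=n_core, replace=False)
    core = frozenset(accessions[i] for i in core_idx)
    # dropout uniforms drawn once so detection is monotone in the midpoint
    detect_u = rng_detect.random(size=(config.n_proteins, config.n_runs))
    detect_p = expit(config.detect_slope * (baseline.to_numpy()[:, None] - config.detect_midpoint))
    detected = detect_u < detect_p
    detected[[accessions.get_loc(a) for a in core], :] = True

    # identification evidence is independent of detection (core or not)
    n_low = int(round(config.frac_low_evidence * config.n_proteins))
    low_idx = set(
        rng_evidence.choice(config.n_proteins, size=n_low, replace=False).tolist()
    ) if n_low else set()
    n_peptides = 2 + rng_evidence.poisson(3.0, size=config.n_proteins)
    best_conf = np.full(config.n_proteins, 99.0)
    for i in low_idx:
        n_peptides[i] = 1
        best_conf[i] = float(90.0 + rng_evidence.random() * 8.0)

    pool_log = baseline.to_numpy()[:, None] + eff.to_numpy().mean(axis=1)[:, None]
    runs: list[RunTable] = []
    for r, run_id in enumerate(run_ids):
        rows_mask = detected[:, r]
        sub = meta[meta["run_id"] == run_id]
        channels = tuple([pool_channel] + list(sub["channel"]))
        quantities = {}
        pool_eps = rng_noise.normal(0.0, config.noise_sd, size=config.n_proteins)
        quantities[pool_channel] = 2.0 ** (pool_log[:, 0] + run_effect.iloc[r] + pool_eps)
        for row in sub.itertuples(index=False):
            eps = rng_noise.normal(0.0, config.noise_sd, size=config.n_proteins)
            log_q = (
                baseline.to_numpy()
                + eff[row.group].to_numpy()
                + run_effect.iloc[r]
                + eps
            )
            quantities[row.channel] = 2.0 ** log_q
        table = pd.DataFrame(quantities, index=accessions)
        table.insert(0, "fdr_pass", True)
        table.insert(0, "best_single_conf", best_conf)
        table.insert(0, "n_peptides", n_peptides)
        table = table.loc[rows_mask]
        runs.append(RunTable(run_id, channels, pool_channel, table))

    truth = SynthTruth(baseline, eff, run_effect, core, enriched, config.seed)
    return runs, meta, truth


def expected_pool_ratio(truth: SynthTruth, protein: str, group: str) -> float:
    """Noise-free pool-relative ratio from the generative model:
    2 ** (e_{p,g} - mean_g' e_{p,g'})."""
    e = truth.group_effect.loc[protein]
    return float(2.0 ** (e[group] - e.mean()))


def write_truth(truth: SynthTruth, path: str | Path) -> None:
    """Plain-text (key: value) sidecar recording the planted truth."""
    lines = [f"seed: {truth.seed}"]
    lines.append("core: " + ",".join(sorted(truth.core)))
    for term, role, direction in truth.enriched_terms:
        lines.append(f"enriched_term: {term}\t{role}\t{direction}")
    for run_id, u in truth.run_effect.items():
        lines.append(f"run_effect: {run_id}\t{u!r}")
    for acc in truth.baseline.index:
        effs = "\t".join(repr(v) for v in truth.group_effect.loc[acc])
        lines.append(f"protein: {acc}\t{truth.baseline[acc]!r}\t{effs}")
    Path(path).write_text("\n".join(lines) + "\n")
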