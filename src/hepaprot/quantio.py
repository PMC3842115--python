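"""Reading, filtering and merging of per-run isobaric quantification tables.

An 8-plex isobaric (iTRAQ-style) run quantifies up to eight samples at once
through reporter-ion channels.  One channel of every run carries a common
reference pool — a mixture of all study samples — and dividing each channel by
the pool channel of the same run yields pool-relative quantities that are
comparable across runs.  This module implements that normalization together
with the identification-confidence filter, the multi-run merge, the
common-protein filter (proteins quantified in every sample) and per-sample
mean equalization.

Missing values are represented explicitly (``NaN``) and never imputed; the
common-protein filter is the only missingness-handling mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, InvalidDataError

logger = logging.getLogger(__name__)

#: Closed vocabulary of sample groups in the study design.
GROUPS = (
    "fresh_fetal",
    "fresh_adult",
    "hepg2",
    "fetal_ali3d",
    "adult_ali3d",
    "adult_ecm",
)

#: Adult-derived groups (used for orientation anchors and planted contrasts).
ADULT_GROUPS = ("fresh_adult", "adult_ali3d", "adult_ecm")

EVIDENCE_COLUMNS = ("n_peptides", "best_single_conf", "fdr_pass")

#: Column names as they appear in run-table files on disk.
_FILE_EVIDENCE = {
    "n_peptides": "n_peptides",
    "best_single_peptide_conf": "best_single_conf",
    "fdr_pass": "fdr_pass",
}

META_COLUMNS = ("sample_id", "group", "donor_id", "run_id", "channel")


@dataclass
class RunTable:
    """One run's per-protein channel quantities plus identification evidence.

    ``table`` is indexed by accession and holds the evidence columns
    (``n_peptides``, ``best_single_conf``, ``fdr_pass``) followed by one
    float column per reporter channel (``NaN`` = not quantified).
    """

    run_id: str
    channel_labels: tuple[str, ...]
    pool_channel: str
    table: pd.DataFrame
    n_dropped_pool: int = 0

    def __post_init__(self) -> None:
        if self.pool_channel not in self.channel_labels:
            raise FormatError(
                f"run {self.run_id}: pool channel {self.pool_channel!r} "
                f"not among channels {list(self.channel_labels)}"
            )
        missing = [c for c in EVIDENCE_COLUMNS if c not in self.table.columns]
        missing += [c for c in self.channel_labels if c not in self.table.columns]
        if missing:
            raise FormatError(f"run {self.run_id}: missing columns {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"run {self.run_id}: duplicate accessions {dups}")

    @property
    def accessions(self) -> pd.Index:
        return self.table.index

    @property
    def sample_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_labels if c != self.pool_channel)

    def quantities(self) -> pd.DataFrame:
        """Channel-quantity block only (evidence columns stripped)."""
        return self.table.loc[:, list(self.channel_labels)]


@dataclass
class ExpressionMatrix:
    """Proteins × samples pool-relative quantities with explicit missingness.

    All present values must be strictly positive: they are ratios to the
    reference pool.
    """

    values: pd.DataFrame  # index: accession, columns: sample_id, NaN = missing

    def __post_init__(self) -> None:
        present = self.values.to_numpy(dtype=float)
        if np.any(present[~np.isnan(present)] <= 0):
            raise InvalidDataError("pool-relative quantities must be > 0")

    @property
    def mask(self) -> pd.DataFrame:
        """Detection indicator (True where quantified)."""
        return self.values.notna()

    @property
    def accessions(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def is_complete(self) -> bool:
        return bool(self.values.notna().all().all())


def read_run_table(path: str | Path, pool_channel: str, run_id: str | None = None) -> RunTable:
    """Read a tab-separated run table (header row, ``NA`` for missing).

    Expected columns: ``accession``, ``n_peptides``, ``best_single_peptide_conf``,
    ``fdr_pass`` and one column per reporter channel.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"accession": str}, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    if "accession" not in raw.columns:
        raise FormatError(f"{path}: missing 'accession' column")
    for col in _FILE_EVIDENCE:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing evidence column {col!r}")
    bad = raw.index[raw["accession"].isna()].tolist()
    if bad:
        # +2: header line plus 1-based numbering
        raise FormatError(f"{path}: rows without accession at lines {[i + 2 for i in bad]}")
    channels = tuple(c for c in raw.columns if c not in _FILE_EVIDENCE and c != "accession")
    if pool_channel not in channels:
        raise FormatError(f"{path}: pool channel {pool_channel!r} column is absent")
    table = raw.rename(columns=_FILE_EVIDENCE).set_index("accession")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate accessions {dups}")
    table["n_peptides"] = table["n_peptides"].astype(int)
    table["best_single_conf"] = table["best_single_conf"].astype(float)
    table["fdr_pass"] = table["fdr_pass"].astype(bool)
    table[list(channels)] = table[list(channels)].astype(float)
    return RunTable(
        run_id=run_id if run_id is not None else path.stem,
        channel_labels=channels,
        pool_channel=pool_channel,
        table=table[list(EVIDENCE_COLUMNS) + list(channels)],
    )


def write_run_table(run: RunTable, path: str | Path) -> None:
    """Write a run table in the same TSV dialect that :func:`read_run_table` reads."""
    out = run.table.copy()
    out.insert(0, "accession", out.index)
    out = out.rename(columns={v: k for k, v in _FILE_EVIDENCE.items()})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV (closed group vocabulary)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata: missing columns {missing}")
    unknown = sorted(set(meta["group"]) - set(GROUPS))
    if unknown:
        raise FormatError(f"sample metadata: unknown groups {unknown}; allowed: {list(GROUPS)}")
    pairs = meta[["run_id", "channel"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].to_records(index=False).tolist()
        raise ConsistencyError(f"sample metadata: duplicate (run, channel) pairs {dup}")
    if meta["sample_id"].duplicated().any():
        raise ConsistencyError("sample metadata: duplicate sample ids")
    return meta.reset_index(drop=True)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.loc[:, list(META_COLUMNS)].to_csv(path, sep="\t", index=False)


def filter_identifications(run: RunTable) -> RunTable:
    """Apply the identification-confidence filter.

    A protein is retained when it passed the run-level FDR cutoff and was
    identified either by two or more peptides at >=90% confidence or by a
    single peptide at >=99% confidence.  Idempotent.
    """
    t = run.table
    keep = t["fdr_pass"] & ((t["n_peptides"] >= 2) | (t["best_single_conf"] >= 99.0))
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("run %s: identification filter removed %d of %d proteins",
                    run.run_id, n_removed, len(t))
    return RunTable(run.run_id, run.channel_labels, run.pool_channel, t.loc[keep].copy(),
                    n_dropped_pool=run.n_dropped_pool)


def relative_to_pool(run: RunTable) -> RunTable:
    """Divide every channel by the same protein's pool-channel quantity.

    Records whose pool quantity is missing or zero cannot be normalized; they
    are dropped and counted in ``n_dropped_pool``.
    """
    t = run.table
    pool = t[run.pool_channel]
    usable = pool.notna() & (pool > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("run %s: dropped %d proteins with missing/zero pool quantity",
                    run.run_id, n_dropped)
    t = t.loc[usable].copy()
    chans = list(run.channel_labels)
    t[chans] = t[chans].div(t[run.pool_channel], axis=0)
    return RunTable(run.run_id, run.channel_labels, run.pool_channel, t,
                    n_dropped_pool=run.n_dropped_pool + n_dropped)


def merge_runs(runs: Sequence[RunTable], meta: pd.DataFrame) -> ExpressionMatrix:
    """Merge pool-normalized runs into one proteins × samples matrix.

    The row set is the union of accessions over runs.  The value for
    (protein, sample) is taken from the sample's run; it is missing wherever
    the protein was not quantified in that run.  Pool channels are never
    samples.  No re-scaling happens at merge time: the pool ratio is the
    cross-run normalization.
    """
    meta = validate_sample_meta(meta)
    by_id = {r.run_id: r for r in runs}
    if len(by_id) != len(runs):
        raise ConsistencyError("duplicate run ids")
    columns: dict[str, pd.Series] = {}
    for row in meta.itertuples(index=False):
        run = by_id.get(row.run_id)
        if run is None:
            raise ConsistencyError(f"sample {row.sample_id}: unknown run {row.run_id!r}")
        if row.channel == run.pool_channel:
            raise ConsistencyError(
                f"sample {row.sample_id}: channel {row.channel!r} is run "
                f"{row.run_id!r}'s pool channel"
            )
        if row.channel not in run.channel_labels:
            raise ConsistencyError(
                f"sample {row.sample_id}: unknown channel {row.channel!r} in run {row.run_id!r}"
            )
        columns[row.sample_id] = run.table[row.channel]
    merged = pd.DataFrame(columns).sort_index()
    merged = merged[list(meta["sample_id"])]
    return ExpressionMatrix(merged)


def filter_common_proteins(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the proteins quantified in every sample."""
    keep = m.values.notna().all(axis=1)
    out = ExpressionMatrix(m.values.loc[keep].copy())
    logger.info("common-protein filter: %d of %d proteins quantified in all %d samples",
                len(out.values), len(m.values), m.values.shape[1])
    if len(out.values) < 2:
        logger.warning("common-protein set has %d proteins; downstream stages need >= 2",
                       len(out.values))
    return out


def sample_means(m: ExpressionMatrix) -> pd.Series:
    """Per-sample arithmetic mean over proteins (QC diagnostic)."""
    return m.values.mean(axis=0)


def equalize_sample_means(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column so its arithmetic mean over proteins is 1.

    Within-column value ratios are preserved exactly.  Requires a complete
    matrix (run after the common-protein filter).
    """
    if not m.is_complete:
        raise InvalidDataError("equalize_sample_means requires a complete matrix")
    means = m.values.mean(axis=0)
    bad = means.index[~(means > 0)].tolist()
    if bad:
        raise InvalidDataError(f"non-positive column means for samples {bad}")
    logger.info("mean equalization factors: %s",
                {s: round(1.0 / v, 6) for s, v in means.items()})
    return ExpressionMatrix(m.values.div(means, axis=1))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, "accession", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    raw = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"accession": str})
    if "accession" not in raw.columns:
        raise FormatError(f"{path}: missing 'accession' column")
    return ExpressionMatrix(raw.set_index("accession").astype(float))
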