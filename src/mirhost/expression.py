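"""Expression-matrix input and preprocessing.

Expression is handled on the *linear* intensity scale throughout: the model
treats miRNA-mediated repression as additive in expression units, so incoming
matrices must not be log-transformed (the reader performs no transform and no
check is possible — pre-logged input silently degrades the model).

Preprocessing order is fixed: (1) genes with any missing value are dropped,
(2) low-intensity genes are dropped by a percentile filter on the per-gene
maximum absolute intensity, (3) per-gene down-regulation vectors and unit-norm
host profiles are computed over the *filtered* gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateProfileError,
    EmptyDatasetError,
    ExpressionParseError,
    MissingGeneError,
)

logger = logging.getLogger(__name__)

#: tokens treated as a missing measurement in expression tables
NA_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", "null", "NULL"})


@dataclass
class ExpressionDataset:
    """One study's genes x samples matrix of linear-scale intensities.

    ``values`` has one row per entry of ``gene_ids`` and one column per entry
    of ``sample_ids``.  Missing measurements are ``NaN`` until
    :func:`filter_genes` removes the affected genes; after filtering all
    values are finite.
    """

    dataset_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionParseError(
                f"{self.dataset_id}: expression values must be 2-D"
            )
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ExpressionParseError(
                f"{self.dataset_id}: shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ExpressionParseError(
                f"{self.dataset_id}: duplicate gene symbol(s): {sorted(dupes)[:5]}"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ExpressionParseError(
                    f"{self.dataset_id}: non-finite expression values"
                )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise MissingGeneError(
                f"{self.dataset_id}: gene {gene_id!r} not present"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dataset_id: str) -> "ExpressionDataset":
        return cls(
            dataset_id=dataset_id,
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class DownregulationVector:
    """Per-sample decrease of one gene's expression below the dataset mean.

    ``d[s]`` is the mean expression over all (filtered) genes at sample ``s``
    minus the gene's own expression at ``s``; it is the regression response.
    Summed over the full gene universe at any sample it is exactly zero.
    """

    dataset_id: str
    gene_id: str
    d: np.ndarray


@dataclass
class HostProfile:
    """A host gene's expression row rescaled to unit Euclidean norm."""

    dataset_id: str
    host_gene_id: str
    x: np.ndarray


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup


def read_expression_tsv(path: str | Path, dataset_id: str) -> ExpressionDataset:
    """Read a genes x samples TSV into an :class:`ExpressionDataset`.

    Layout: header row ``gene_id<TAB>sample1<TAB>...``, one gene per row.
    Cells matching :data:`NA_TOKENS` become ``NaN`` (dropped later by
    :func:`filter_genes`); any other non-numeric cell is a parse error that
    names the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.name is None or raw.shape[1] == 0:
        raise ExpressionParseError(f"{path}: malformed header (need gene_id + samples)")
    gene_ids = [str(g) for g in raw.index]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ExpressionParseError(
            f"{path}: duplicate gene symbol(s): {sorted(dupes)[:5]}"
        )
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].str.strip()
        numeric = pd.to_numeric(cells, errors="coerce")
        is_na_token = cells.isin(NA_TOKENS)
        bad = numeric.isna() & ~is_na_token
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ExpressionParseError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)
    values[np.asarray(raw.isin(NA_TOKENS) | (raw == ""))] = np.nan
    ds = ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=gene_ids,
        sample_ids=[str(c) for c in raw.columns],
        values=values,
    )
    return ds


def read_gds_soft(
    path: str | Path,
    dataset_id: str | None = None,
    probe_map: str | Path | Mapping[str, str] | None = None,
    collapse: str = "first",
) -> ExpressionDataset:
    """Read the dataset table of a GEO GDS SOFT file.

    Only the ``!dataset_table_begin`` .. ``!dataset_table_end`` section is
    parsed.  Probe IDs (``ID_REF``) are mapped to gene symbols either through
    ``probe_map`` (a two-column probe<TAB>symbol TSV or mapping) or, when no
    map is given, through the table's ``IDENTIFIER`` column.  Probes with no
    symbol are dropped.  Multiple probes per symbol are collapsed with the
    ``collapse`` policy: ``first`` (table order), ``mean`` or ``max``
    (element-wise over samples, ignoring missing values).
    """
    path = Path(path)
    if collapse not in ("first", "mean", "max"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    mapping: Mapping[str, str] | None
    if probe_map is None:
        mapping = None
    elif isinstance(probe_map, Mapping):
        mapping = dict(probe_map)
    else:
        pm = pd.read_csv(probe_map, sep="\t", header=None, dtype=str)
        if pm.shape[1] < 2:
            raise ExpressionParseError(f"{probe_map}: probe map needs two columns")
        mapping = dict(zip(pm.iloc[:, 0].str.strip(), pm.iloc[:, 1].str.strip()))

    header: list[str] | None = None
    rows: list[list[str]] = []
    in_table = False
    soft_id = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("^DATASET"):
                soft_id = line.split("=", 1)[-1].strip()
            elif line.lower().startswith("!dataset_table_begin"):
                in_table = True
            elif line.lower().startswith("!dataset_table_end"):
                break
            elif in_table:
                if header is None:
                    header = line.split("\t")
                elif line:
                    rows.append(line.split("\t"))
    if header is None or not rows:
        raise ExpressionParseError(f"{path}: no dataset table found")
    if header[0] != "ID_REF":
        raise ExpressionParseError(f"{path}: dataset table must start with ID_REF")
    has_identifier = len(header) > 1 and header[1] == "IDENTIFIER"
    sample_start = 2 if has_identifier else 1
    sample_ids = header[sample_start:]
    if not sample_ids:
        raise ExpressionParseError(f"{path}: dataset table has no sample columns")

    symbols: list[str] = []
    data: list[np.ndarray] = []
    n_dropped = 0
    for row in rows:
        if len(row) != len(header):
            raise ExpressionParseError(
                f"{path}: table row with {len(row)} fields, expected {len(header)}"
            )
        probe = row[0].strip()
        if mapping is not None:
            symbol = mapping.get(probe, "")
        elif has_identifier:
            symbol = row[1].strip()
        else:
            symbol = ""
        if not symbol or symbol.upper() in ("--CONTROL", "NONE"):
            n_dropped += 1
            continue
        vals = np.array(
            [np.nan if c.strip() in NA_TOKENS else float(c) for c in row[sample_start:]]
        )
        symbols.append(symbol)
        data.append(vals)
    if n_dropped:
        logger.info("%s: dropped %d probes without a gene symbol", path, n_dropped)
    if not symbols:
        raise EmptyDatasetError(f"{path}: no probe mapped to a gene symbol")

    frame = pd.DataFrame(np.vstack(data), index=symbols, columns=sample_ids)
    if frame.index.has_duplicates:
        if collapse == "first":
            frame = frame[~frame.index.duplicated(keep="first")]
        elif collapse == "mean":
            frame = frame.groupby(level=0, sort=False).mean()
        else:
            frame = frame.groupby(level=0, sort=False).max()
    return ExpressionDataset.from_frame(frame, dataset_id or soft_id or path.stem)


def filter_genes(ds: ExpressionDataset, percentile: float = 0.10) -> ExpressionDataset:
    """Drop missing-value genes, then low-intensity genes.

    A gene survives the intensity filter when its maximum absolute expression
    across samples is at least the given percentile (linear interpolation
    between order statistics) of the per-gene maximum-absolute-value
    distribution; genes strictly below are removed, ties at the threshold are
    kept.  Gene order is preserved.
    """
    if not 0.0 <= percentile <= 1.0:
        raise ValueError(f"percentile must be in [0, 1], got {percentile}")
    complete = ~np.isnan(ds.values).any(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info(
            "%s: dropped %d gene(s) with missing values", ds.dataset_id, n_missing
        )
    values = ds.values[complete]
    genes = [g for g, keep in zip(ds.gene_ids, complete) if keep]
    if values.shape[0] == 0:
        raise EmptyDatasetError(f"{ds.dataset_id}: no genes without missing values")
    max_abs = np.abs(values).max(axis=1)
    threshold = float(np.quantile(max_abs, percentile))
    survive = max_abs >= threshold
    n_low = int((~survive).sum())
    if n_low:
        logger.info(
            "%s: dropped %d low-intensity gene(s) below the %.0fth percentile",
            ds.dataset_id,
            n_low,
            100 * percentile,
        )
    if not survive.any():
        raise EmptyDatasetError(f"{ds.dataset_id}: intensity filter removed all genes")
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        gene_ids=[g for g, keep in zip(genes, survive) if keep],
        sample_ids=list(ds.sample_ids),
        values=values[survive],
    )


def compute_downregulation(ds: ExpressionDataset, gene_id: str) -> DownregulationVector:
    """Down-regulation vector of one gene over the dataset's gene universe."""
    row = ds.row(gene_id)
    column_means = ds.values.mean(axis=0)
    return DownregulationVector(
        dataset_id=ds.dataset_id, gene_id=gene_id, d=column_means - row
    )


def normalize_host_profile(ds: ExpressionDataset, host_gene_id: str) -> HostProfile:
    """Host gene's expression row scaled to unit Euclidean norm.

    Raises :class:`MissingGeneError` when the host is not in the dataset
    (callers drop the corresponding design column for this dataset) and
    :class:`DegenerateProfileError` for an all-zero row.
    """
    row = ds.row(host_gene_id)
    norm = float(np.linalg.norm(row))
    if norm == 0.0:
        raise DegenerateProfileError(
            f"{ds.dataset_id}: host {host_gene_id!r} has a zero-norm profile"
        )
    return HostProfile(
        dataset_id=ds.dataset_id, host_gene_id=host_gene_id, x=row / norm
    )
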