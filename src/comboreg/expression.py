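"""Parallel expression matrices: reading, filtering, centering, probe collapsing.

The inference pipeline consumes two log2 expression matrices measured on the
same samples — one for miRNAs, one for mRNAs. Preprocessing follows the
standard microarray-panel recipe: keep only "frequently expressed" molecules
(rows whose log2 value exceeds a platform-specific floor in more than a given
number of arrays), centre every row to zero mean, and average rows of
synonymous probes into one row per molecule.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOLECULE_KINDS = ("mRNA", "miRNA")


class ExpressionParseError(ValueError):
    """Malformed expression matrix file (ragged row, non-numeric or NA cell)."""


@dataclass
class ExpressionMatrix:
    """A molecules x samples grid of log2 expression values.

    Parameters
    ----------
    data
        DataFrame with one row per molecule (index = molecule/probe ids,
        possibly duplicated before :func:`collapse_synonymous`) and one
        column per sample.
    kind
        ``"mRNA"`` or ``"miRNA"``; a matrix holds one molecule kind.
    """

    data: pd.DataFrame
    kind: str = "mRNA"

    def __post_init__(self) -> None:
        if self.kind not in MOLECULE_KINDS:
            raise ValueError(f"unknown molecule kind: {self.kind!r}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.data = self.data.astype(float)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, molecule_id: str) -> np.ndarray:
        return self.data.loc[molecule_id].to_numpy()

    def drop_samples(self, sample_ids) -> "ExpressionMatrix":
        """Remove samples (e.g. an excluded cell line); unknown ids ignored."""
        keep = [c for c in self.data.columns if c not in set(sample_ids)]
        return replace(self, data=self.data[keep])

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")


@dataclass(frozen=True)
class FilterPolicy:
    """'Frequently expressed' criterion: log2 value strictly greater than
    ``min_value`` in strictly more than ``min_samples`` arrays."""

    min_value: float
    min_samples: int = field(default=0)

    def __post_init__(self) -> None:
        if self.min_samples < 0:
            raise ValueError("min_samples must be non-negative")


def read_matrix(path, kind: str = "mRNA") -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row is the header of sample ids, first column the molecule/probe
    id. Duplicate probe ids are permitted (they are merged later by
    :func:`collapse_synonymous`). A ragged row, an empty/NA cell or a
    non-numeric cell raises :class:`ExpressionParseError` naming the line.
    """
    rows: list[list[float]] = []
    ids: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ExpressionParseError(f"{path}: empty file") from None
        samples = header[1:]
        width = len(header)
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != width:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: expected {width} fields, got {len(record)}"
                )
            ids.append(record[0])
            try:
                rows.append([float(cell) for cell in record[1:]])
            except ValueError:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: non-numeric expression value"
                ) from None
        values = np.asarray(rows, dtype=float).reshape(len(ids), len(samples))
        if np.isnan(values).any():
            bad = int(np.flatnonzero(np.isnan(values).any(axis=1))[0])
            raise ExpressionParseError(
                f"{path}: line {bad + 2}: missing (NA) expression value"
            )
    frame = pd.DataFrame(values, index=ids, columns=samples)
    return ExpressionMatrix(frame, kind=kind)


def filter_frequently_expressed(
    m: ExpressionMatrix, policy: FilterPolicy
) -> ExpressionMatrix:
    """Keep rows expressed above ``policy.min_value`` in more than
    ``policy.min_samples`` samples (both inequalities strict). Row order is
    preserved; an empty result is legal."""
    counts = (m.data.to_numpy() > policy.min_value).sum(axis=1)
    mask = counts > policy.min_samples
    kept = m.data.loc[mask]
    logger.info(
        "frequent-expression filter (%s): %d of %d rows kept",
        m.kind, int(mask.sum()), len(mask),
    )
    return replace(m, data=kept)


def center_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift every row to zero mean. Idempotent; covariances unchanged."""
    centered = m.data.sub(m.data.mean(axis=1), axis=0)
    return replace(m, data=centered)


def collapse_synonymous(
    m: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Average rows of synonymous probes into one row per molecule.

    ``probe_map`` maps probe id -> molecule id. Probes missing from the map
    keep their own id (identity mapping) with a logged warning. Output rows
    are ordered by first appearance of each molecule.
    """
    unmapped = [p for p in m.data.index if p not in probe_map]
    if unmapped:
        logger.warning(
            "%d probe ids absent from probe map; kept as their own molecules "
            "(first: %s)", len(unmapped), unmapped[0],
        )
    molecules = [probe_map.get(p, p) for p in m.data.index]
    grouped = m.data.groupby(pd.Index(molecules, name=m.data.index.name), sort=False)
    collapsed = grouped.mean()
    return replace(m, data=collapsed)


def preprocess(
    m: ExpressionMatrix,
    policy: FilterPolicy | None = None,
    probe_map: Mapping[str, str] | None = None,
    drop_samples=(),
) -> ExpressionMatrix:
    """Full preprocessing chain: sample drop -> filter -> centre -> collapse."""
    out = m.drop_samples(drop_samples) if drop_samples else m
    if policy is not None:
        out = filter_frequently_expressed(out, policy)
    out = center_rows(out)
    out = collapse_synonymous(out, probe_map or {})
    return out
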