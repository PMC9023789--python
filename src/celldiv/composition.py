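"""Sample-by-cell-type count and proportion matrices.

This module turns long-format per-cell annotation tables (one row per
cell) into a samples x cell-types count matrix, normalizes counts to
proportions, and re-aggregates a fine-grained cell type panel into a
coarser one (e.g. subtypes -> lineages) through a hierarchy mapping.

The number of panel columns ``k`` is a property of the declared analysis
panel, not of the individual sample: zero-count types stay in the matrix
so that the diversity statistic is comparable across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required columns of a per-cell annotation table
CELL_COLUMNS = ("cell_id", "sample_id", "cell_type")


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cell_table(
    path: str | Path,
    *,
    sep: str | None = None,
    cell_id_col: str = "cell_id",
    sample_id_col: str = "sample_id",
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Read a per-cell annotation table (CSV/TSV) and validate it.

    Returns a DataFrame with canonical columns ``cell_id``, ``sample_id``,
    ``cell_type`` regardless of the source column names.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    missing = [c for c in (cell_id_col, sample_id_col, cell_type_col) if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing required column(s): {', '.join(missing)}")
    df = df.rename(
        columns={cell_id_col: "cell_id", sample_id_col: "sample_id", cell_type_col: "cell_type"}
    )[list(CELL_COLUMNS)]
    return validate_cell_table(df)


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check CellTable invariants: required columns, unique ids, no missing values."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required column(s): {', '.join(missing)}")
    if len(cells) == 0:
        raise ValueError("no cells")
    for col in ("sample_id", "cell_type"):
        if cells[col].isna().any():
            raise ValueError(f"cell table has missing values in column {col!r}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id: {dup!r}")
    return cells


@dataclass(frozen=True)
class CompositionMatrix:
    """Samples x cell-types integer count matrix.

    ``counts`` is a DataFrame indexed by sample_id with one column per
    panel type label; per-sample totals and the panel size ``k`` derive
    from it.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] < 1:
            raise ValueError("composition matrix needs at least one type label")
        if df.columns.duplicated().any():
            raise ValueError("duplicate type labels in panel")
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def type_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> pd.Series:
        """Per-sample cell totals n_s."""
        return self.counts.sum(axis=1)

    def write(self, path: str | Path, *, sep: str | None = None) -> None:
        self.counts.to_csv(path, sep=_infer_sep(path, sep), index_label="sample_id")

    @classmethod
    def read(cls, path: str | Path, *, sep: str | None = None) -> "CompositionMatrix":
        df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col="sample_id")
        df.index = df.index.astype(str)
        return cls(df)


@dataclass(frozen=True)
class ProportionMatrix:
    """Samples x cell-types proportion matrix; each row lies on the simplex.

    ``totals`` carries the per-sample cell counts n_s the proportions were
    derived from, when known.
    """

    props: pd.DataFrame
    totals: pd.Series | None = field(default=None)

    _ROW_SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        arr = self.props.to_numpy(dtype=float)
        if arr.shape[1] < 1:
            raise ValueError("proportion matrix needs at least one type label")
        if (arr < -self._ROW_SUM_TOL).any() or (arr > 1 + self._ROW_SUM_TOL).any():
            raise ValueError("proportions must lie in [0, 1]")
        row_sums = arr.sum(axis=1)
        bad = np.abs(row_sums - 1.0) > self._ROW_SUM_TOL
        if bad.any():
            sid = self.props.index[int(np.argmax(bad))]
            raise ValueError(f"proportions for sample {sid!r} sum to {row_sums[bad][0]!r}, not 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.props.index)

    @property
    def type_labels(self) -> list[str]:
        return list(self.props.columns)

    @property
    def k(self) -> int:
        return self.props.shape[1]

    def write(self, path: str | Path, *, sep: str | None = None) -> None:
        self.props.to_csv(path, sep=_infer_sep(path, sep), index_label="sample_id")


def count_composition(
    cells: pd.DataFrame, panel: Sequence[str] | None = None
) -> CompositionMatrix:
    """Tally per-cell annotations into a sample-by-cell-type count matrix.

    Parameters
    ----------
    cells:
        CellTable with columns ``cell_id``, ``sample_id``, ``cell_type``.
    panel:
        Optional ordered list of type labels. Labels in the panel that are
        absent from ``cells`` get a zero column; labels in ``cells`` that
        are outside the panel are an error. Without a panel, the observed
        labels are used in lexicographic order.

    Sample rows are ordered lexicographically so the output is stable
    under row permutations of the input.
    """
    cells = validate_cell_table(cells)
    observed = pd.unique(cells["cell_type"])
    if panel is not None:
        panel = list(panel)
        if len(set(panel)) != len(panel):
            raise ValueError("panel labels must be unique")
        unknown = sorted(set(observed) - set(panel))
        if unknown:
            raise ValueError(f"cell_type outside panel: {unknown[0]!r}")
        columns = panel
    else:
        columns = sorted(observed)
    tab = pd.crosstab(cells["sample_id"], cells["cell_type"])
    tab = tab.reindex(columns=columns, fill_value=0).sort_index()
    tab.index.name = "sample_id"
    tab.columns.name = None
    return CompositionMatrix(tab.astype(np.int64))


def to_proportions(comp: CompositionMatrix) -> ProportionMatrix:
    """Normalize counts to per-sample proportions p_is = n_is / n_s.

    Samples with zero cells are dropped with a logged warning; an error is
    raised only if no sample has any cells.
    """
    totals = comp.totals
    empty = totals == 0
    if empty.all():
        raise ValueError("all samples have zero cells")
    if empty.any():
        dropped = list(totals.index[empty])
        logger.warning("dropping %d zero-cell sample(s): %s", len(dropped), ", ".join(dropped))
    kept = comp.counts.loc[~empty]
    props = kept.div(totals[~empty], axis=0)
    return ProportionMatrix(props, totals=totals[~empty])


def read_hierarchy(path: str | Path, *, sep: str | None = None) -> dict[str, str]:
    """Read a two-column fine->coarse cell type mapping (header required)."""
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"hierarchy {path} must have two columns (fine, coarse)")
    fine, coarse = df.columns[:2]
    if df[fine].duplicated().any():
        dup = df.loc[df[fine].duplicated(), fine].iloc[0]
        raise ValueError(f"fine label {dup!r} mapped more than once")
    return dict(zip(df[fine], df[coarse]))


def aggregate(
    comp: CompositionMatrix,
    hierarchy: Mapping[str, str],
    *,
    other_bucket: bool = False,
) -> CompositionMatrix:
    """Collapse a fine cell type panel into coarse labels, summing counts.

    Per-sample totals are conserved. Fine labels missing from the mapping
    raise unless ``other_bucket`` is set, in which case they collapse into
    a literal ``"Other"`` coarse label. Coarse columns are ordered by first
    appearance along the fine panel.
    """
    mapped = {}
    for label in comp.type_labels:
        if label in hierarchy:
            mapped[label] = hierarchy[label]
        elif other_bucket:
            mapped[label] = "Other"
        else:
            raise ValueError(f"unmapped label: {label}")
    coarse_order = list(dict.fromkeys(mapped[label] for label in comp.type_labels))
    out = comp.counts.T.groupby(comp.counts.columns.map(mapped), sort=False).sum().T
    out = out.reindex(columns=coarse_order)
    out.index.name = "sample_id"
    out.columns.name = None
    return CompositionMatrix(out)
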