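"""Per-sample cell type diversity statistic.

The statistic is the Shannon entropy of a sample's cell type proportions
normalized by ``log(k)`` (so samples measured at different panel
resolutions are comparable) and shifted by -1:

    Es = (-sum_i p_i * log(p_i)) / log(k) - 1

It ranges over [-1, 0]: Es = 0 for a perfectly even composition
(all p_i = 1/k) and Es = -1 when every cell belongs to a single type.
Zero proportions contribute nothing (the 0*log(0) = 0 limit), which is
required because real samples routinely lack some panel types.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from celldiv.composition import ProportionMatrix, _infer_sep

logger = logging.getLogger(__name__)

#: values this close to a range boundary are snapped onto it
_BOUNDARY_TOL = 1e-12
_SUM_TOL = 1e-9

#: columns of the per-sample diversity table, in output order
DIVERSITY_COLUMNS = ("sample_id", "resolution", "k", "n_cells", "diversity")


def diversity_statistic(p: Sequence[float] | np.ndarray) -> float:
    """Normalized-entropy diversity of one proportion vector.

    Parameters
    ----------
    p:
        Proportions over the k panel types; non-negative, summing to 1
        within 1e-9, with k >= 2.

    Returns
    -------
    float
        Es in [-1, 0]. Results within 1e-12 of a boundary are clamped to
        exactly -1.0 or 0.0 so downstream range checks are not tripped by
        floating-point overshoot.

    Raises
    ------
    ValueError
        If k < 2 (the log(k) normalization is undefined), any entry is
        negative, or the entries do not sum to 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("proportion vector must be one-dimensional")
    k = arr.size
    if k < 2:
        raise ValueError("statistic undefined for k<2 (log k = 0)")
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    total = float(arr.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"proportions sum to {total!r}, not 1")
    # sort before summing: makes the float result bitwise invariant under
    # permutations of the panel columns, not just mathematically invariant
    arr = np.sort(arr)
    entropy = float(-xlogy(arr, arr).sum())  # nats; 0*log(0) handled as 0
    es = entropy / math.log(k) - 1.0
    if abs(es) <= _BOUNDARY_TOL:
        return 0.0
    if abs(es + 1.0) <= _BOUNDARY_TOL:
        return -1.0
    return float(min(0.0, max(-1.0, es)))


def diversity_per_sample(props: ProportionMatrix, resolution: str) -> pd.DataFrame:
    """Compute the diversity statistic for every sample of a proportion matrix.

    Returns a DiversityTable: one row per sample with columns
    ``sample_id``, ``resolution``, ``k``, ``n_cells``, ``diversity``.
    ``n_cells`` is the per-sample total the proportions were derived from
    (NA when the matrix was built directly from proportions).
    """
    k = props.k
    if k < 2:
        raise ValueError("statistic undefined for k<2 (log k = 0)")
    records = []
    for sample_id, row in zip(props.sample_ids, props.props.to_numpy(dtype=float)):
        try:
            es = diversity_statistic(row)
        except ValueError as exc:
            raise ValueError(f"sample {sample_id!r}: {exc}") from exc
        n_cells = (
            int(props.totals.loc[sample_id]) if props.totals is not None else pd.NA
        )
        records.append((sample_id, resolution, k, n_cells, es))
    return pd.DataFrame.from_records(records, columns=DIVERSITY_COLUMNS)


def write_diversity(table: pd.DataFrame, path, *, sep: str | None = None) -> None:
    table.to_csv(path, sep=_infer_sep(path, sep), index=False)


def read_diversity(path, *, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype={"sample_id": str})
    missing = [c for c in DIVERSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diversity table {path} missing column(s): {', '.join(missing)}")
    return df
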