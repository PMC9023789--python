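"""Group comparison of per-sample diversity statistics.

One-way fixed-effects ANOVA across sample groups followed by two-sample
pairwise t-tests (all unordered pairs, or one reference group against each
other group). Raw p-values are always reported; Holm or Benjamini-Hochberg
adjustment is optional, matching common reporting practice for this kind
of sample-level comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from celldiv.composition import _infer_sep

logger = logging.getLogger(__name__)

VARIANCE_MODES = ("pooled", "welch")
ADJUST_METHODS = ("none", "holm", "bh")
_ADJUST_TO_STATSMODELS = {"holm": "holm", "bh": "fdr_bh"}

PAIRWISE_COLUMNS = ("group_a", "group_b", "n_a", "n_b", "t", "p_value")


def read_sample_groups(path: str | Path, *, sep: str | None = None) -> pd.Series:
    """Read a two-column sample metadata table (sample_id, group).

    Group order (first appearance in the file) is preserved and used for
    pair enumeration and plotting downstream.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"sample metadata {path} must have columns (sample_id, group)")
    sid, grp = df.columns[:2]
    if df[sid].duplicated().any():
        dup = df.loc[df[sid].duplicated(), sid].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    s = pd.Series(df[grp].to_numpy(), index=df[sid], name="group")
    s.index.name = "sample_id"
    return s


def _split_by_group(
    div: pd.DataFrame, groups: Mapping[str, str] | pd.Series, *, min_size: int = 2
) -> dict[str, np.ndarray]:
    """Map each sample's Es into its group, preserving group order.

    Group order follows the metadata when it is an ordered Series,
    otherwise first appearance in the diversity table.
    """
    groups = pd.Series(groups)
    missing = [s for s in div["sample_id"] if s not in groups.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no group in the metadata")
    labels = groups.loc[div["sample_id"]].to_numpy()
    order = [g for g in pd.unique(groups.to_numpy()) if g in set(labels)]
    values = div["diversity"].to_numpy(dtype=float)
    out = {g: values[labels == g] for g in order}
    if len(out) < 2:
        raise ValueError("need at least 2 groups to compare")
    for g, v in out.items():
        if v.size < min_size:
            raise ValueError(f"group {g!r} has fewer than {min_size} samples")
    return out


def anova_across_groups(
    div: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> tuple[float, float]:
    """One-way ANOVA of the diversity statistic across sample groups.

    Returns ``(F, p_value)``. Requires >= 2 groups with >= 2 samples each
    and nonzero total within-group variance.
    """
    split = _split_by_group(div, groups)
    if all(np.var(v) == 0.0 for v in split.values()):
        raise ValueError("degenerate ANOVA: zero within-group variance in every group")
    f_stat, p = stats.f_oneway(*split.values())
    return float(f_stat), float(p)


def pairwise_ttests(
    div: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    *,
    reference: str | None = None,
    variance_mode: str = "pooled",
    adjust: str = "none",
) -> pd.DataFrame:
    """Two-sample t-tests between groups of the diversity statistic.

    With ``reference`` set, tests reference vs each other group; otherwise
    all unordered pairs in group order. ``variance_mode`` selects the
    classic pooled-variance test or Welch's unequal-variance test. Tests
    are two-sided. When ``adjust`` is ``holm`` or ``bh`` an adjusted
    p-value column is appended; raw p-values are always reported.
    """
    if variance_mode not in VARIANCE_MODES:
        raise ValueError(f"variance_mode must be one of {VARIANCE_MODES}")
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {ADJUST_METHODS}")
    split = _split_by_group(div, groups)
    order = list(split)
    if reference is not None:
        if reference not in split:
            raise ValueError(f"reference group {reference!r} not present")
        pairs = [(reference, g) for g in order if g != reference]
    else:
        pairs = list(itertools.combinations(order, 2))
    rows = []
    for a, b in pairs:
        res = stats.ttest_ind(split[a], split[b], equal_var=(variance_mode == "pooled"))
        rows.append((a, b, split[a].size, split[b].size, float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame.from_records(rows, columns=PAIRWISE_COLUMNS)
    if adjust != "none":
        table["p_adjusted"] = multipletests(
            table["p_value"].to_numpy(), method=_ADJUST_TO_STATSMODELS[adjust]
        )[1]
    return table


@dataclass
class ComparisonResult:
    """ANOVA summary plus the pairwise t-test table for one comparison."""

    F: float
    p_anova: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"F": [self.F], "p_value": [self.p_anova], "alpha": [self.alpha]}
        )

    def write(self, anova_path, pairwise_path, *, sep: str | None = None) -> None:
        self.anova_frame().to_csv(anova_path, sep=_infer_sep(anova_path, sep), index=False)
        self.pairwise.to_csv(pairwise_path, sep=_infer_sep(pairwise_path, sep), index=False)


def compare_groups(
    div: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    *,
    reference: str | None = None,
    variance_mode: str = "pooled",
    adjust: str = "none",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Run the full comparison: ANOVA then pairwise t-tests."""
    f_stat, p = anova_across_groups(div, groups)
    pw = pairwise_ttests(
        div, groups, reference=reference, variance_mode=variance_mode, adjust=adjust
    )
    return ComparisonResult(F=f_stat, p_anova=p, pairwise=pw, alpha=alpha)
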