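"""Dirichlet-multinomial simulation of cell type composition data.

Generates per-cell annotation tables and sample-by-cell-type count
matrices with group structure: each sample's true proportions are drawn
from its group's Dirichlet distribution and its counts from a multinomial
conditioned on the sample's cell total. The hierarchy induces the negative
dependence among type counts that a fixed per-sample total imposes.

Seeding: one root seed spawns an independent stream per sample (keyed by
the sample's global index), so adding samples or groups to a config never
perturbs the draws of earlier samples.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from celldiv.composition import CompositionMatrix, read_hierarchy, to_proportions
from celldiv.diversity import diversity_per_sample
from celldiv.group_stats import anova_across_groups

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: label, size, and Dirichlet concentration over the panel."""

    label: str
    n_samples: int
    alpha: tuple[float, ...]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulated cohort."""

    groups: tuple[GroupSpec, ...]
    panel: tuple[str, ...]
    cells_per_sample: int | tuple[int, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("config needs at least one group")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel labels must be unique")
        k = len(self.panel)
        for g in self.groups:
            if g.n_samples < 1:
                raise ValueError(f"group {g.label!r} needs at least one sample")
            if len(g.alpha) != k:
                raise ValueError(
                    f"group {g.label!r}: alpha has {len(g.alpha)} entries, panel has {k}"
                )
            if any(a <= 0 for a in g.alpha):
                raise ValueError(f"group {g.label!r}: alpha entries must be > 0")
        cps = self.cells_per_sample
        if isinstance(cps, tuple):
            lo, hi = cps
            if lo < 1 or hi < lo:
                raise ValueError("cells_per_sample range must satisfy 1 <= min <= max")
        elif cps < 1:
            raise ValueError("cells_per_sample must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return dataclasses.replace(self, seed=seed)

    @property
    def n_samples(self) -> int:
        return sum(g.n_samples for g in self.groups)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_counts(cfg: SimulationConfig) -> tuple[CompositionMatrix, pd.Series]:
    """Draw a cohort of count compositions.

    For each sample: n_s from ``cells_per_sample`` (fixed or uniform over
    a range), p ~ Dirichlet(alpha_group), counts ~ Multinomial(n_s, p).
    Sample ids embed a zero-padded global index so that lexicographic
    order equals generation order.

    Returns the count matrix and a sample_id -> group label Series.
    """
    rows, ids, labels = [], [], []
    index = 0
    for g in cfg.groups:
        for _ in range(g.n_samples):
            rng = _sample_rng(cfg.seed, index)
            if isinstance(cfg.cells_per_sample, tuple):
                lo, hi = cfg.cells_per_sample
                n_s = int(rng.integers(lo, hi + 1))
            else:
                n_s = int(cfg.cells_per_sample)
            p = rng.dirichlet(np.asarray(g.alpha, dtype=float))
            rows.append(rng.multinomial(n_s, p))
            ids.append(f"s{index:04d}_{g.label}")
            labels.append(g.label)
            index += 1
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=ids, columns=list(cfg.panel))
    counts.index.name = "sample_id"
    groups = pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="group")
    return CompositionMatrix(counts), groups


def simulate_cells(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Expand a simulated count matrix to one row per cell.

    Counting the returned table with the same panel reproduces
    ``simulate_counts(cfg)`` exactly (same seed, same draw order).
    """
    comp, groups = simulate_counts(cfg)
    sample_col, type_col, cell_col = [], [], []
    for sample_id in comp.sample_ids:
        row = comp.counts.loc[sample_id]
        cell_index = 0
        for label in comp.type_labels:
            for _ in range(int(row[label])):
                cell_col.append(f"{sample_id}_c{cell_index:05d}")
                sample_col.append(sample_id)
                type_col.append(label)
                cell_index += 1
    cells = pd.DataFrame(
        {"cell_id": cell_col, "sample_id": sample_col, "cell_type": type_col}
    )
    return cells, groups


def calibration_experiment(
    null_cfg: SimulationConfig,
    alt_cfgs: Sequence[SimulationConfig] = (),
    *,
    replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the ANOVA under given configurations.

    Each replicate simulates a cohort, computes per-sample diversity at the
    fine panel resolution, and tests the group effect; the table reports
    the fraction of replicates with p < alpha per configuration. Replicate
    seeds are spawned deterministically from ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    records = []
    for ci, (name, cfg) in enumerate(
        [("null", null_cfg)] + [(f"alt{i}", c) for i, c in enumerate(alt_cfgs)]
    ):
        rejections = 0
        for rep in range(replicates):
            rep_seed = int(np.random.SeedSequence(seed, spawn_key=(ci, rep)).generate_state(1)[0])
            comp, groups = simulate_counts(cfg.with_seed(rep_seed))
            div = diversity_per_sample(to_proportions(comp), resolution="fine")
            _, p = anova_across_groups(div, groups)
            rejections += p < alpha
        records.append((name, replicates, rejections, rejections / replicates))
    return pd.DataFrame.from_records(
        records, columns=("config", "replicates", "rejections", "rejection_rate")
    )


# ---------------------------------------------------------------------------
# bundled presets


def _preset_path(name: str):
    return importlib.resources.files("celldiv").joinpath("presets", name)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file.

    Expected keys: ``panel`` (list of labels), ``cells_per_sample`` (int or
    [min, max]), ``seed`` (optional int), ``groups`` (list of mappings with
    ``label``, ``n_samples``, ``alpha``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_mapping(raw)


def _config_from_mapping(raw: dict) -> SimulationConfig:
    cps = raw["cells_per_sample"]
    if isinstance(cps, (list, tuple)):
        cps = (int(cps[0]), int(cps[1]))
    else:
        cps = int(cps)
    groups = tuple(
        GroupSpec(
            label=str(g["label"]),
            n_samples=int(g["n_samples"]),
            alpha=tuple(float(a) for a in g["alpha"]),
        )
        for g in raw["groups"]
    )
    return SimulationConfig(
        groups=groups,
        panel=tuple(str(t) for t in raw["panel"]),
        cells_per_sample=cps,
        seed=int(raw.get("seed", 0)),
    )


def paper_shaped_config(*, seed: int = 0, null: bool = False) -> SimulationConfig:
    """Bundled 4-group PBMC-like preset (group sizes 12/26/14/14, k=12).

    The fourth group's concentration vector is closer to uniform than the
    other three, so its expected diversity is the highest. Under ``null``,
    every group reuses the first group's alpha (no group effect). Alpha
    values are artifact choices, not estimates from any dataset.
    """
    with _preset_path("paper_shaped.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    cfg = _config_from_mapping(raw)
    if null:
        base = cfg.groups[0].alpha
        cfg = dataclasses.replace(
            cfg,
            groups=tuple(dataclasses.replace(g, alpha=base) for g in cfg.groups),
        )
    return cfg.with_seed(seed)


def pbmc_hierarchy() -> dict[str, str]:
    """Bundled 12-subtype -> 2-lineage mapping matching the preset panel."""
    with importlib.resources.as_file(_preset_path("pbmc_hierarchy.csv")) as p:
        return read_hierarchy(p)
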