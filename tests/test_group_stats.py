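import numpy as np
import pandas as pd
import pytest
from scipy import stats

from celldiv.group_stats import (
    anova_across_groups,
    compare_groups,
    pairwise_ttests,
    read_sample_groups,
)


def make_div(values_by_group):
    """Build a DiversityTable + group Series from {group: [Es, ...]}."""
    sids, es, grp = [], [], []
    i = 0
    for g, vals in values_by_group.items():
        for v in vals:
            sids.append(f"s{i}")
            es.append(v)
            grp.append(g)
            i += 1
    div = pd.DataFrame(
        {"sample_id": sids, "resolution": "subtype", "k": 12, "n_cells": 500, "diversity": es}
    )
    groups = pd.Series(grp, index=pd.Index(sids, name="sample_id"), name="group")
    return div, groups


class TestAnova:
    def test_identical_groups_f_zero(self):
        div, groups = make_div({"A": [-0.5, -0.4, -0.3], "B": [-0.5, -0.4, -0.3]})
        f, p = anova_across_groups(div, groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        # A=(-0.9,-0.8,-0.85), B=(-0.2,-0.1,-0.15): group means -0.85/-0.15,
        # SSB = 2*3*0.35^2 = 0.735 (df 1), SSW = 2*0.005 = 0.01 (df 4),
        # F = 0.735 / (0.01/4) = 294.
        div, groups = make_div({"A": [-0.9, -0.8, -0.85], "B": [-0.2, -0.1, -0.15]})
        f, p = anova_across_groups(div, groups)
        assert f == pytest.approx(294.0, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(294.0, 1, 4), rel=1e-9)

    def test_single_group_errors(self):
        div, groups = make_div({"A": [-0.5, -0.4]})
        with pytest.raises(ValueError, match="2 groups"):
            anova_across_groups(div, groups)

    def test_small_group_named(self):
        div, groups = make_div({"A": [-0.5, -0.4], "B": [-0.3]})
        with pytest.raises(ValueError, match="'B'"):
            anova_across_groups(div, groups)

    def test_degenerate_variance_errors(self):
        div, groups = make_div({"A": [-0.5, -0.5], "B": [-0.3, -0.3]})
        with pytest.raises(ValueError, match="degenerate"):
            anova_across_groups(div, groups)

    def test_missing_group_named(self):
        div, groups = make_div({"A": [-0.5, -0.4], "B": [-0.3, -0.2]})
        groups = groups.drop("s3")
        with pytest.raises(ValueError, match="'s3'"):
            anova_across_groups(div, groups)

    def test_relabeling_invariance(self):
        div, groups = make_div(
            {"A": [-0.9, -0.8, -0.85], "B": [-0.2, -0.1, -0.15], "C": [-0.5, -0.45, -0.55]}
        )
        f1, p1 = anova_across_groups(div, groups)
        relabeled = groups.map({"A": "x", "B": "y", "C": "z"})
        f2, p2 = anova_across_groups(div, relabeled)
        assert f1 == pytest.approx(f2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestPairwise:
    def test_identical_groups_null(self):
        div, groups = make_div({"A": [-0.5, -0.4, -0.3], "B": [-0.5, -0.4, -0.3]})
        table = pairwise_ttests(div, groups)
        assert len(table) == 1
        assert table.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_pooled_hand_oracle(self):
        # A=(-0.9,-0.8), B=(-0.2,-0.1): s^2 = 0.005 each, pooled SE =
        # sqrt(0.005 * (1/2 + 1/2)) = 0.0707107, t = -0.7 / SE = -9.8995.
        div, groups = make_div({"A": [-0.9, -0.8], "B": [-0.2, -0.1]})
        table = pairwise_ttests(div, groups, variance_mode="pooled")
        assert table.loc[0, "t"] == pytest.approx(-0.7 / np.sqrt(0.005), rel=1e-12)
        assert table.loc[0, "p_value"] == pytest.approx(
            2 * stats.t.sf(0.7 / np.sqrt(0.005), 2), rel=1e-9
        )

    def test_welch_differs_for_unequal_variances(self):
        div, groups = make_div({"A": [-0.9, -0.8, -0.7, -0.6], "B": [-0.21, -0.2, -0.19]})
        pooled = pairwise_ttests(div, groups, variance_mode="pooled")
        welch = pairwise_ttests(div, groups, variance_mode="welch")
        assert pooled.loc[0, "p_value"] != pytest.approx(welch.loc[0, "p_value"], rel=1e-6)

    def test_all_pairs_count(self):
        div, groups = make_div(
            {g: [-0.5 - i / 10, -0.4 - i / 10] for i, g in enumerate("ABCD")}
        )
        assert len(pairwise_ttests(div, groups)) == 6  # C(4,2)

    def test_reference_contrasts(self):
        div, groups = make_div(
            {g: [-0.5 - i / 10, -0.4 - i / 10] for i, g in enumerate("ABCD")}
        )
        table = pairwise_ttests(div, groups, reference="D")
        assert len(table) == 3
        assert set(table["group_a"]) == {"D"}

    @staticmethod
    def _holm_by_hand(raw):
        # step-down: sort ascending, multiply by (m - rank), enforce monotone
        raw = np.asarray(raw, dtype=float)
        m = raw.size
        order = np.argsort(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        return adj

    def test_holm_by_hand_reference_case(self):
        assert list(self._holm_by_hand([0.01, 0.02, 0.04])) == pytest.approx(
            [0.03, 0.04, 0.04]
        )

    def test_holm_adjustment_matches_hand_oracle(self):
        div, groups = make_div(
            {g: [-0.5 - i / 10, -0.4 - i / 10] for i, g in enumerate("ABC")}
        )
        table = pairwise_ttests(div, groups, adjust="holm")
        expected = self._holm_by_hand(table["p_value"].to_numpy())
        assert table["p_adjusted"].to_numpy() == pytest.approx(expected, rel=1e-12)

    def test_raw_p_always_reported(self):
        div, groups = make_div({"A": [-0.9, -0.8], "B": [-0.2, -0.1]})
        raw = pairwise_ttests(div, groups, adjust="none")
        adj = pairwise_ttests(div, groups, adjust="bh")
        assert raw.loc[0, "p_value"] == adj.loc[0, "p_value"]
        assert "p_adjusted" not in raw.columns

    def test_small_group_errors(self):
        div, groups = make_div({"A": [-0.5, -0.4], "B": [-0.3]})
        with pytest.raises(ValueError, match="'B'"):
            pairwise_ttests(div, groups)

    def test_bad_options_rejected(self):
        div, groups = make_div({"A": [-0.5, -0.4], "B": [-0.3, -0.2]})
        with pytest.raises(ValueError, match="variance_mode"):
            pairwise_ttests(div, groups, variance_mode="robust")
        with pytest.raises(ValueError, match="adjust"):
            pairwise_ttests(div, groups, adjust="bonferroni")


class TestCompareGroups:
    def test_bundles_anova_and_pairwise(self):
        div, groups = make_div(
            {"A": [-0.9, -0.8, -0.85], "B": [-0.2, -0.1, -0.15], "C": [-0.5, -0.45, -0.55]}
        )
        result = compare_groups(div, groups, alpha=0.05)
        assert result.F > 0
        assert 0 <= result.p_anova <= 1
        assert len(result.pairwise) == 3
        assert (result.pairwise["p_value"].between(0, 1)).all()

    def test_writer(self, tmp_path):
        div, groups = make_div({"A": [-0.9, -0.8], "B": [-0.2, -0.1]})
        result = compare_groups(div, groups)
        result.write(tmp_path / "anova.csv", tmp_path / "pairwise.csv")
        anova = pd.read_csv(tmp_path / "anova.csv")
        assert list(anova.columns) == ["F", "p_value", "alpha"]
        pw = pd.read_csv(tmp_path / "pairwise.csv")
        assert len(pw) == 1


class TestMetadataReader:
    def test_reader_preserves_order(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("sample_id,group\ns1,old\ns2,young\ns3,old\n")
        groups = read_sample_groups(p)
        assert list(groups.loc[["s1", "s2", "s3"]]) == ["old", "young", "old"]
        assert list(pd.unique(groups.to_numpy())) == ["old", "young"]

    def test_duplicate_sample_errors(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("sample_id,group\ns1,old\ns1,young\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_groups(p)
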