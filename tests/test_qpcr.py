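import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirlens.qpcr import (
    QpcrTable,
    analyze_assays,
    delta_delta_ct,
    nested_anova,
    read_qpcr_table,
)


def table_from(rows):
    return QpcrTable(pd.DataFrame(rows, columns=["assay", "group", "bio_rep", "tech_rep", "ct"]))


def plate(target_cts, ref_ct=15.0, ref_assays=("Ref",)):
    """Build a table from {(group, bio): [tech cts]} plus constant references."""
    rows = []
    for (group, bio), cts in target_cts.items():
        for t, ct in enumerate(cts, start=1):
            rows.append(("Tgt", group, bio, f"t{t}", ct))
        for ref in ref_assays:
            rows.append((ref, group, bio, "t1", ref_ct))
    return table_from(rows)


WORKED = {
    ("case", "b1"): [20.0, 20.2],
    ("case", "b2"): [20.4, 20.6],
    ("control", "b1"): [22.0, 22.2],
    ("control", "b2"): [22.2, 22.4],
}


class TestDeltaDeltaCt:
    def test_worked_example(self):
        # constant reference 15: bio means 20.1/20.5 vs 22.1/22.3
        # ddCt = (20.3 - 15) - (22.2 - 15) = -1.9 -> rel = 2^1.9
        res = delta_delta_ct(plate(WORKED), "Tgt", ["Ref"])
        assert res.ddct == pytest.approx(-1.9)
        assert res.rel_expr == pytest.approx(2.0**1.9)
        assert res.direction == "up"

    def test_reference_shift_invariance(self):
        # adding a constant to every Ct (target and reference) leaves ddCt fixed
        shifted = {k: [c + 3.0 for c in v] for k, v in WORKED.items()}
        res = delta_delta_ct(plate(shifted, ref_ct=18.0), "Tgt", ["Ref"])
        assert res.ddct == pytest.approx(-1.9)

    def test_two_references_arithmetic_mean(self):
        rows = []
        for (group, bio), cts in WORKED.items():
            for t, ct in enumerate(cts, start=1):
                rows.append(("Tgt", group, bio, f"t{t}", ct))
            rows.append(("RefA", group, bio, "t1", 14.0))
            rows.append(("RefB", group, bio, "t1", 16.0))
        res = delta_delta_ct(table_from(rows), "Tgt", ["RefA", "RefB"])
        # mean reference = 15 in every stratum -> same ddCt as worked example
        assert res.ddct == pytest.approx(-1.9)

    def test_higher_case_ct_is_down(self):
        flipped = {
            ("case", b if g == "control" else b): v
            for (g, b), v in WORKED.items()
            if g == "control"
        }
        flipped.update(
            {("control", b): v for (g, b), v in WORKED.items() if g == "case"}
        )
        res = delta_delta_ct(plate(flipped), "Tgt", ["Ref"])
        assert res.ddct == pytest.approx(1.9)
        assert res.rel_expr == pytest.approx(2.0**-1.9)
        assert res.direction == "down"

    def test_missing_target_rejected(self):
        with pytest.raises(ValueError, match="Nope"):
            delta_delta_ct(plate(WORKED), "Nope", ["Ref"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            delta_delta_ct(plate(WORKED), "Tgt", ["NoRef"])

    def test_target_without_control_group_rejected(self):
        rows = [("Tgt", "case", "b1", "t1", 20.0), ("Tgt", "case", "b2", "t1", 20.5),
                ("Ref", "case", "b1", "t1", 15.0), ("Ref", "case", "b2", "t1", 15.0)]
        with pytest.raises(ValueError, match="control"):
            delta_delta_ct(table_from(rows), "Tgt", ["Ref"])


def brute_force_ss(values):
    """Sums of squares from first principles for {(group, bio): [techs]}."""
    all_vals = [v for cts in values.values() for v in cts]
    grand = sum(all_vals) / len(all_vals)
    groups = sorted({g for g, _ in values})
    ss_group = ss_bio = ss_resid = 0.0
    for g in groups:
        gvals = [v for (gg, _), cts in values.items() if gg == g for v in cts]
        gmean = sum(gvals) / len(gvals)
        ss_group += len(gvals) * (gmean - grand) ** 2
        for (gg, b), cts in values.items():
            if gg != g:
                continue
            bmean = sum(cts) / len(cts)
            ss_bio += len(cts) * (bmean - gmean) ** 2
            ss_resid += sum((c - bmean) ** 2 for c in cts)
    return ss_group, ss_bio, ss_resid


class TestNestedAnova:
    def test_worked_plate_matches_brute_force(self):
        result = nested_anova(plate(WORKED), "Tgt", ["Ref"])
        # constant reference: dCt SS decomposition equals the raw-Ct one
        ss_group, ss_bio, ss_resid = brute_force_ss(WORKED)
        assert result.ss_group == pytest.approx(ss_group)
        assert result.ss_bio == pytest.approx(ss_bio)
        assert result.ss_resid == pytest.approx(ss_resid)
        assert (result.df_group, result.df_bio, result.df_resid) == (1, 2, 4)
        ms_group = ss_group / 1
        ms_bio = ss_bio / 2
        assert result.f_group == pytest.approx(ms_group / ms_bio)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(21)
        values = {
            (g, f"b{i}"): list(rng.normal(20 + (g == "case"), 0.5, 3))
            for g in ("case", "control")
            for i in range(1, 4)
        }
        result = nested_anova(plate(values), "Tgt", ["Ref"])
        flat = [v for cts in values.values() for v in cts]
        grand = sum(flat) / len(flat)
        total = sum((v - grand) ** 2 for v in flat)
        assert result.ss_total == pytest.approx(total)

    def test_unbalanced_design(self):
        values = {
            ("case", "b1"): [20.0, 20.3, 20.1],
            ("case", "b2"): [20.6, 20.8],
            ("control", "b1"): [22.0],
            ("control", "b2"): [22.4, 22.5],
        }
        result = nested_anova(plate(values), "Tgt", ["Ref"])
        ss_group, ss_bio, ss_resid = brute_force_ss(values)
        assert result.ss_group == pytest.approx(ss_group)
        assert result.ss_bio == pytest.approx(ss_bio)
        assert result.ss_resid == pytest.approx(ss_resid)
        assert (result.df_group, result.df_bio, result.df_resid) == (1, 2, 4)

    def test_group_effect_tested_against_bio_stratum(self):
        """Huge technical precision must not inflate significance when
        biological replicates disagree: the F test runs on MS_bio, not MS_resid."""
        noisy_bio = {
            ("case", "b1"): [20.0, 20.0],
            ("case", "b2"): [23.0, 23.0],
            ("control", "b1"): [21.0, 21.0],
            ("control", "b2"): [24.0, 24.0],
        }
        result = nested_anova(plate(noisy_bio), "Tgt", ["Ref"])
        # group means 21.5 vs 22.5 but bio variance is large -> not significant
        assert result.p_group > 0.4

    def test_single_bio_rep_rejected(self):
        values = {("case", "b1"): [20.0, 20.1], ("control", "b1"): [22.0], ("control", "b2"): [22.1]}
        with pytest.raises(ValueError, match="biological replicate"):
            nested_anova(plate(values), "Tgt", ["Ref"])

    def test_zero_bio_variance_edges(self):
        same = {
            ("case", "b1"): [20.0],
            ("case", "b2"): [20.0],
            ("control", "b1"): [22.0],
            ("control", "b2"): [22.0],
        }
        result = nested_anova(plate(same), "Tgt", ["Ref"])
        assert math.isinf(result.f_group) and result.p_group == 0.0
        flat = {k: [20.0] for k in same}
        result2 = nested_anova(plate(flat), "Tgt", ["Ref"])
        assert result2.p_group == 1.0

    def test_raw_ct_mode_without_references(self):
        result = nested_anova(plate(WORKED), "Tgt")
        ss_group, ss_bio, ss_resid = brute_force_ss(WORKED)
        assert result.ss_group == pytest.approx(ss_group)


class TestTableValidation:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            QpcrTable(pd.DataFrame({"assay": ["a"], "ct": [20.0]}))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown groups"):
            table_from([("Tgt", "treated", "b1", "t1", 20.0)])

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            table_from([("Tgt", "case", "b1", "t1", float("nan"))])

    def test_read_round_trip(self, tmp_path):
        path = tmp_path / "plate.tsv"
        rows = [("Tgt", g, b, t, ct) for (g, b), cts in WORKED.items() for t, ct in zip(("t1", "t2"), cts)]
        pd.DataFrame(rows, columns=["assay", "group", "bio_rep", "tech_rep", "ct"]).to_csv(
            path, sep="\t", index=False
        )
        table = read_qpcr_table(path)
        assert table.assays() == ["Tgt"]
        assert len(table.subset("tgt")) == 8


class TestAnalyzeAssays:
    def test_fills_p_values(self):
        results = analyze_assays(plate(WORKED), ["Tgt"], ["Ref"])
        (res,) = results
        assert res.ddct == pytest.approx(-1.9)
        assert res.p is not None and 0.0 <= res.p <= 1.0
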