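import hashlib
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mirlens.de import differential_test
from mirlens.qpcr import QpcrTable, analyze_assays
from mirlens.synthetic import (
    DEFAULT_QPCR_DDCT,
    SyntheticDesign,
    generate,
    generate_qpcr,
)


def dir_digest(paths):
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(key.encode())
        h.update(paths[key].read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_design, small_dataset, tmp_path):
        again = generate(small_design, tmp_path / "again")
        assert dir_digest(small_dataset.paths) == dir_digest(again.paths)

    def test_different_seed_differs(self, small_design, small_dataset, tmp_path):
        other = generate(replace(small_design, seed=12), tmp_path / "other")
        assert dir_digest(small_dataset.paths) != dir_digest(other.paths)


class TestMatrix:
    def test_shape_and_groups(self, small_dataset):
        matrix = small_dataset.matrix
        assert matrix.values.shape == (150, 6)
        assert sorted(matrix.group_of.values()).count("case") == 3

    def test_noise_free_effects_exact(self, small_design):
        from mirlens.synthetic import _mirna_matrix

        design = replace(small_design, sigma=0.0)
        matrix = _mirna_matrix(design)
        records = {r.feature_id: r for r in differential_test(matrix)}
        for i in range(1, 8):
            rec = records[f"mir-u{i:02d}"]
            assert rec.direction == "up" and rec.fc == pytest.approx(2.0, abs=1e-4)
        for i in range(1, 5):
            rec = records[f"mir-d{i:02d}"]
            assert rec.direction == "down" and rec.fc == pytest.approx(-2.0, abs=1e-4)
        background = [r for fid, r in records.items() if fid.startswith("mir-b")]
        assert all(r.direction == "unchanged" for r in background)

    def test_planted_recovery_at_default_noise(self, small_dataset):
        records = {r.feature_id: r for r in differential_test(small_dataset.matrix)}
        truth = small_dataset.truth_mirnas
        hits = sum(
            records[row.mirna].direction == row.direction for row in truth.itertuples()
        )
        assert hits >= 0.9 * len(truth)


class TestTargetMap:
    def test_true_and_decoy_score_ranges(self, small_dataset):
        targets = pd.read_csv(small_dataset.paths["targets"], sep="\t")
        true_keys = set(
            zip(small_dataset.truth_pairs["mirna"], small_dataset.truth_pairs["mrna"])
        )
        for row in targets.itertuples():
            if (row.mirna, row.mrna) in true_keys:
                assert row.score >= 50.0
            else:
                assert row.score < 50.0

    def test_excluded_mirnas_absent(self, small_dataset):
        targets = pd.read_csv(small_dataset.paths["targets"], sep="\t")
        assert "mir-u01" not in set(targets["mirna"])
        assert "mir-u01" in set(small_dataset.truth_mirnas["mirna"])

    def test_no_duplicate_edges(self, small_dataset):
        targets = pd.read_csv(small_dataset.paths["targets"], sep="\t")
        assert not targets.duplicated(["mirna", "mrna"]).any()


class TestMrnaTables:
    def test_planted_genes_differential_at_p4(self, small_dataset):
        table = pd.read_csv(small_dataset.paths["mrna_de_p4"], sep="\t").set_index("feature")
        for row in small_dataset.truth_pairs.itertuples():
            rec = table.loc[row.mrna]
            assert rec["direction"] == ("down" if row.fc_p4 < 0 else "up")
            assert rec["p"] <= 0.05 and abs(rec["fc"]) >= 1.2

    def test_p30_truth_flags_match_table(self, small_dataset):
        table = pd.read_csv(small_dataset.paths["mrna_de_p30"], sep="\t").set_index("feature")
        for row in small_dataset.truth_pairs.itertuples():
            if row.de_p30:
                rec = table.loc[row.mrna]
                assert rec["direction"] in ("up", "down")
            elif row.mrna in table.index:
                assert table.loc[row.mrna, "direction"] == "unchanged"

    def test_expected_tiers_consistent_with_flags(self, small_dataset):
        for row in small_dataset.truth_pairs.itertuples():
            if row.expected_tier == "top":
                assert row.de_p30 and row.enriched_p4 and row.enriched_p30
            elif row.expected_tier == "high":
                assert row.de_p30 and (row.enriched_p4 or row.enriched_p30)
            elif row.expected_tier == "promising":
                assert row.enriched_p4 or row.enriched_p30
            else:
                assert not (row.enriched_p4 or row.enriched_p30)


class TestEnrichmentTables:
    def test_enrichment_flags_reproduce_from_files(self, small_dataset):
        for stage in ("p4", "p30"):
            table = pd.read_csv(small_dataset.paths[f"isyte_{stage}"], sep="\t").set_index("gene")
            for row in small_dataset.truth_pairs.itertuples():
                flagged = getattr(row, f"enriched_{stage}")
                in_table = row.mrna in table.index
                passes = (
                    in_table
                    and table.loc[row.mrna, "expression_intensity"] >= 100.0
                    and table.loc[row.mrna, "enrichment_fc"] > 1.0
                )
                assert passes == flagged, (stage, row.mrna)


class TestPerturbations:
    def test_concordance_truth_columns(self, small_dataset):
        truth = small_dataset.truth_concordance
        assert set(truth.columns) == {"target", "reference_direction", "concordant", "n_misexpressed"}
        assert set(truth["reference_direction"]) <= {"up", "down"}

    def test_misexpression_calls_follow_concordance_coin(self, small_dataset):
        """Every significant perturbation call agrees with the target's planted
        concordance flag once gain datasets are read in the loss frame."""
        manifest = pd.read_csv(small_dataset.paths["perturbation_manifest"], sep="\t")
        truth = small_dataset.truth_concordance.set_index("target")
        for row in manifest.itertuples():
            table = pd.read_csv(
                small_dataset.paths[f"perturbation_{row.dataset_id}"], sep="\t"
            )
            for rec in table.itertuples():
                if rec.direction == "unchanged":
                    continue
                observed = rec.direction
                if row.perturbation_kind == "gain":
                    observed = "down" if observed == "up" else "up"
                t = truth.loc[rec.feature]
                expected = (
                    t["reference_direction"]
                    if t["concordant"]
                    else ("up" if t["reference_direction"] == "down" else "down")
                )
                assert observed == expected

    def test_agreement_rate_near_planted(self, small_dataset):
        truth = small_dataset.truth_concordance
        rate = truth["concordant"].mean()
        n = len(truth)
        # binomial 3-sigma band around the planted coin probability
        assert abs(rate - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / n)


class TestQpcr:
    def test_planted_ddct_recovered(self):
        design = SyntheticDesign(seed=5)
        table = QpcrTable(generate_qpcr(design))
        results = analyze_assays(table, sorted(DEFAULT_QPCR_DDCT), list(design.qpcr_references))
        for res in results:
            planted = DEFAULT_QPCR_DDCT[res.assay_id]
            assert res.ddct == pytest.approx(planted, abs=0.45)
            assert res.direction == ("up" if planted < 0 else "down")

    def test_reference_overlap_rejected(self):
        design = SyntheticDesign(qpcr_ddct={"Gapdh": 1.0})
        with pytest.raises(ValueError, match="reference"):
            generate_qpcr(design)

    def test_replicate_structure(self):
        design = SyntheticDesign(seed=3)
        table = generate_qpcr(design)
        one = table[(table["assay"] == "mir-15a") & (table["group"] == "case")]
        assert one["bio_rep"].nunique() == 3
        assert len(one) == 9


class TestManifest:
    def test_manifest_lists_outputs_and_design(self, small_dataset):
        text = small_dataset.paths["manifest"].read_text()
        assert "mirna_matrix: mirna_matrix.tsv" in text
        assert "design.seed: 11" in text
        assert "design.sigma: 0.1" in text
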