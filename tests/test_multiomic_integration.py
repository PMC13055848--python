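import numpy as np
import pandas as pd
import pytest

from endoprofiler.io_model import RunConfig
from endoprofiler.multiomic_integration import (
    BOTH,
    NEITHER,
    ORN_ONLY,
    PN_ONLY,
    average_timepoints,
    call_cell_types,
    is_enriched,
    join_ligand_receptors,
    summarize_expression_matrix,
)


def long_expr(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_class", "time_point", "mean_log2cpm1", "frac_expressing"],
    )


class TestAverageTimepoints:
    def test_arithmetic_means(self):
        expr = long_expr(
            [
                ("g1", "ORN", "24h", 3.0, 0.2),
                ("g1", "ORN", "48h", 5.0, 0.4),
                ("g1", "PN", "24h", 1.0, 0.1),
                ("g1", "PN", "48h", 1.0, 0.1),
            ]
        )
        avg = average_timepoints(expr)
        assert avg.loc[("g1", "ORN"), "mean_log2cpm1"] == pytest.approx(4.0)
        assert avg.loc[("g1", "ORN"), "frac_expressing"] == pytest.approx(0.3)

    def test_incomplete_gene_excluded_with_warning(self, caplog):
        expr = long_expr(
            [
                ("g1", "ORN", "24h", 3.0, 0.2),
                ("g1", "ORN", "48h", 5.0, 0.4),
                ("g1", "PN", "24h", 1.0, 0.1),
                ("g1", "PN", "48h", 1.0, 0.1),
                ("g2", "ORN", "24h", 6.0, 0.5),  # missing 48h and PN
            ]
        )
        with caplog.at_level("WARNING"):
            avg = average_timepoints(expr)
        assert "g2" not in avg.index.get_level_values("gene")
        assert any("g2" in r.message for r in caplog.records)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        for g in range(8):
            for cls in ("ORN", "PN"):
                for tp in ("24h", "48h"):
                    rows.append(
                        (f"g{g}", cls, tp, rng.uniform(0, 8), rng.uniform(0, 1))
                    )
        expr = long_expr(rows)
        avg = average_timepoints(expr)
        for g in range(8):
            for cls in ("ORN", "PN"):
                sel = expr[(expr.gene == f"g{g}") & (expr.cell_class == cls)]
                assert avg.loc[(f"g{g}", cls), "mean_log2cpm1"] == pytest.approx(
                    sel["mean_log2cpm1"].mean()
                )


class TestEnrichmentRule:
    @pytest.mark.parametrize(
        "mean,frac,expected",
        [
            (4.5, 0.40, True),
            (5.0, 0.30, False),  # fraction threshold is strict
            (3.9, 0.50, False),  # level threshold is inclusive at 4.0
            (4.0, 0.31, True),
            (0.0, 0.0, False),
        ],
    )
    def test_threshold_asymmetry(self, mean, frac, expected):
        assert is_enriched(mean, frac, RunConfig()) is expected

    def test_monotone_in_both_arguments(self):
        cfg = RunConfig()
        grid = np.linspace(0, 8, 9)
        for m1 in grid:
            for f1 in np.linspace(0, 1, 6):
                if is_enriched(m1, f1, cfg):
                    assert is_enriched(m1 + 1, f1, cfg)
                    assert is_enriched(m1, min(1.0, f1 + 0.1), cfg)


class TestCellTypeCalls:
    def _avg(self, orn, pn):
        rows = []
        for cls, (mean, frac) in (("ORN", orn), ("PN", pn)):
            for tp in ("24h", "48h"):
                rows.append(("g", cls, tp, mean, frac))
        return average_timepoints(long_expr(rows))

    @pytest.mark.parametrize(
        "orn,pn,expected",
        [
            ((6.0, 0.6), (1.0, 0.1), ORN_ONLY),
            ((1.0, 0.1), (6.0, 0.6), PN_ONLY),
            ((6.0, 0.6), (6.0, 0.6), BOTH),
            ((1.0, 0.1), (1.0, 0.1), NEITHER),
        ],
    )
    def test_category_assignment(self, orn, pn, expected):
        calls = call_cell_types(self._avg(orn, pn))
        assert calls.loc["g", "enriched_in"] == expected

    def test_categories_partition_gene_set(self):
        rng = np.random.default_rng(6)
        rows = []
        for g in range(40):
            for cls in ("ORN", "PN"):
                mean, frac = rng.uniform(0, 8), rng.uniform(0, 1)
                for tp in ("24h", "48h"):
                    rows.append((f"g{g}", cls, tp, mean, frac))
        calls = call_cell_types(average_timepoints(long_expr(rows)))
        counts = calls["enriched_in"].value_counts()
        assert counts.sum() == 40
        assert set(counts.index) <= {ORN_ONLY, PN_ONLY, BOTH, NEITHER}

    def test_more_abundant_in_pn_flag(self):
        calls = call_cell_types(self._avg((4.5, 0.5), (6.0, 0.6)))
        assert bool(calls.loc["g", "more_abundant_in_pn"])
        calls2 = call_cell_types(self._avg((7.0, 0.9), (6.0, 0.6)))
        assert not bool(calls2.loc["g", "more_abundant_in_pn"])


class TestLigandReceptorJoin:
    def test_planted_pairs_recover_exact_statuses(self, clean_synthetic):
        """Zero-noise synthetic truth: every ligand record carries the
        generator's planted receptor status. Noise-free replicates have zero
        residual variance (degenerate for a t-test), so compartment calls
        come from the exact fold-change signs."""
        from endoprofiler.compartment_analysis import subset_by_category
        from endoprofiler.enrichment_stats import log_transform
        from endoprofiler.filtering import apply_filter_cascade
        from endoprofiler.io_model import Condition
        from endoprofiler.tmt_quant import compute_nc_ratios, correct_impurities

        spec, (table, ann, imp, truth) = clean_synthetic
        corrected = correct_impurities(table, imp)
        ratios = compute_nc_ratios(corrected, table.design, pseudocount=0.0)
        proteome, _, _ = apply_filter_cascade(corrected, ratios, ann)
        logr = log_transform(ratios)
        fc = (
            logr[table.design.channels(Condition.SURF)].mean(axis=1)
            - logr[table.design.channels(Condition.ENDO)].mean(axis=1)
        ).round(9)
        enr = pd.DataFrame({"log2fc": fc}, index=logr.index)
        enr = enr.loc[[i for i in enr.index if i in proteome.union]]
        enr["call"] = np.select(
            [enr["log2fc"] < 0, enr["log2fc"] > 0],
            ["ENDO_ENRICHED", "SURF_ENRICHED"],
            default="NOT_SIGNIFICANT",
        )
        secreted_endo = subset_by_category(enr, ann, "secreted")
        secreted_endo = secreted_endo[secreted_endo["call"] == "ENDO_ENRICHED"]
        records = join_ligand_receptors(secreted_endo, ann, enr, proteome, None)
        got = {r.ligand_id: r.receptor_status for r in records}
        t = truth.proteins
        ligands = t.index[t["class_label"] == "SECRETED_LIGAND"]
        assert set(got) == set(ligands)
        for lig in ligands:
            rec = t.loc[lig, "receptor_id"]
            assert got[lig][rec] == t.loc[lig, "true_receptor_status"]

    def test_ligand_without_receptor_annotation(self, small_annotations):
        from endoprofiler.filtering import assemble_filtered_proteome

        enr = pd.DataFrame(
            {"log2fc": [-1.0], "call": ["ENDO_ENRICHED"]},
            index=pd.Index(["A"], name="protein_id"),
        )
        ann = small_annotations
        ann.data.at["A", "receptor_ids"] = ()
        records = join_ligand_receptors(
            enr, ann, enr, assemble_filtered_proteome({"A"}, set()), None
        )
        assert len(records) == 1
        assert records[0].receptor_ids == []
        assert records[0].ligand_cell_type == "NOT_PROFILED"

    def test_one_record_per_ligand(self, default_synthetic):
        from endoprofiler.pipeline import run_pipeline
        from endoprofiler.synthetic_data import generate_expression

        spec, (table, ann, imp, truth) = default_synthetic
        expr = generate_expression(truth, spec)
        result = run_pipeline(table, ann, impurities=imp, expression=expr)
        assert len(result.ligand_receptor) == len(result.secreted_endo)
        ids = [r.ligand_id for r in result.ligand_receptor]
        assert len(ids) == len(set(ids))


class TestExpressionMatrixHelper:
    def test_cpm_log_mean_and_fraction(self):
        counts = pd.DataFrame(
            {"gA": [10, 0, 5, 0], "gB": [90, 100, 45, 50]},
            index=pd.Index(["c1", "c2", "c3", "c4"], name="cell"),
        )
        classes = pd.Series(["ORN", "ORN", "PN", "PN"], index=counts.index)
        out = summarize_expression_matrix(counts, classes, "24h")
        orn_gA = out[(out.gene == "gA") & (out.cell_class == "ORN")].iloc[0]
        # cell c1: CPM = 1e5 -> log2(1e5+1); cell c2: 0 -> log2(1)=0
        assert orn_gA["mean_log2cpm1"] == pytest.approx(np.log2(1e5 + 1) / 2)
        assert orn_gA["frac_expressing"] == pytest.approx(0.5)

    def test_zero_total_cell_rejected(self):
        counts = pd.DataFrame({"g": [0]}, index=pd.Index(["c1"], name="cell"))
        with pytest.raises(ValueError, match="positive total"):
            summarize_expression_matrix(
                counts, pd.Series(["ORN"], index=counts.index), "24h"
            )
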