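"""Filter cascade: rule semantics, audit completeness, order invariance."""

import numpy as np
import pandas as pd
import pytest

from noapipe import prioritization as pz
from noapipe import synthetic_data as sd


def mk_finding(
    sample="S1",
    gene="G1",
    model="AR_hom",
    key="V1",
    consequence="lof",
    maf=1e-4,
    psap=1e-5,
    phase=pd.NA,
    dist=pd.NA,
):
    return {
        "sample_id": sample,
        "gene_id": gene,
        "model": model,
        "genotype_key": key,
        "consequence": consequence,
        "popmax_maf": maf,
        "psap_p": psap,
        "phase": phase,
        "pair_distance_bp": dist,
    }


def mk_genes(rows):
    """rows: (gene_id, chromosome, testis_class, known_infertility, tpm)"""
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chromosome", "testis_class", "known_infertility", "premeiotic_tpm"],
    )


class TestVariantFilters:
    def test_high_psap_dropped(self):
        f = pd.DataFrame([mk_finding(psap=0.01)])
        res = pz.apply_variant_filters(f)
        assert res.surviving.empty
        assert res.audit.iloc[0] == "psap_p"

    def test_hand_counted_fixture(self):
        """6 findings: 2 fail on MAF, 1 hom genotype shared by 4 individuals,
        1 cis comphet -> 2 survive."""
        hot = [
            mk_finding(sample=f"S{i}", gene="G9", key="HOT", psap=5e-4)
            for i in range(4)
        ]
        f = pd.DataFrame(
            [
                mk_finding(sample="A", gene="G1", key="V1", maf=0.02),
                mk_finding(sample="B", gene="G2", key="V2", maf=0.02),
                hot[0],
                mk_finding(
                    sample="C",
                    gene="G3",
                    model="AR_comphet",
                    key="P1",
                    phase="cis",
                    dist=500,
                ),
                mk_finding(sample="D", gene="G4", key="V4"),
                mk_finding(sample="E", gene="G5", key="V5"),
            ]
            + hot[1:]
        )
        res = pz.apply_variant_filters(f)
        assert set(res.surviving["sample_id"]) == {"D", "E"}
        assert res.audit.value_counts().to_dict() == {
            "recurrent_hom_hemi": 4,
            "popmax_maf": 2,
            "cis_comphet": 1,
            "pass": 2,
        }

    def test_comphet_pair_in_single_case_retained(self):
        f = pd.DataFrame(
            [mk_finding(model="AR_comphet", key="P1", phase="trans", dist=500)]
        )
        assert len(pz.apply_variant_filters(f).surviving) == 1

    def test_comphet_pair_in_two_cases_dropped(self):
        f = pd.DataFrame(
            [
                mk_finding(sample="A", model="AR_comphet", key="P1", phase="trans", dist=500),
                mk_finding(sample="B", model="AR_comphet", key="P1", phase="trans", dist=500),
            ]
        )
        res = pz.apply_variant_filters(f)
        assert res.surviving.empty
        assert (res.audit == "recurrent_comphet_pair").all()

    def test_missing_phase_retained_as_unknown(self):
        f = pd.DataFrame([mk_finding(model="AR_comphet", key="P1", dist=500)])
        assert len(pz.apply_variant_filters(f).surviving) == 1

    def test_comphet_proximity_rule_when_enabled(self):
        cfg = pz.FilterConfig(comphet_min_distance_bp=10)
        f = pd.DataFrame(
            [
                mk_finding(model="AR_comphet", key="P1", phase="trans", dist=5),
                mk_finding(
                    sample="S2", model="AR_comphet", key="P2", phase="trans", dist=50
                ),
            ]
        )
        res = pz.apply_variant_filters(f, cfg=cfg)
        assert res.audit.tolist() == ["comphet_proximity", "pass"]

    def test_gene_enrichment_needs_distinct_variants(self):
        # 4 individuals, 4 distinct ultra-rare variants in one gene -> all dropped
        distinct = [
            mk_finding(sample=f"S{i}", gene="GE", key=f"K{i}", psap=1e-5)
            for i in range(4)
        ]
        res = pz.apply_variant_filters(pd.DataFrame(distinct))
        assert (res.audit == "gene_enrichment").all()
        # 3 individuals only -> kept (rule is "> 3")
        res3 = pz.apply_variant_filters(pd.DataFrame(distinct[:3]))
        assert (res3.audit == "pass").all()

    def test_unknown_sample_rejected(self):
        cohort = pd.DataFrame(
            {"sample_id": ["S1"], "status": ["case"], "consanguineous": [False]}
        )
        f = pd.DataFrame([mk_finding(sample="GHOST")])
        with pytest.raises(ValueError, match="unknown samples"):
            pz.apply_variant_filters(f, cohort)


class TestAggregation:
    GENES = mk_genes(
        [
            ("G_none", "1", "none", False, 0.1),
            ("G_tpm", "2", "none", False, 0.8),
            ("G_inf", "3", "none", True, 0.8),
            ("G_enh", "4", "tissue_enhanced", False, 0.1),
            ("G_x_enh", "X", "tissue_enhanced", False, 2.0),
            ("G_x_none", "X", "none", False, 2.0),
            ("G_y", "Y", "none", False, 0.0),
        ]
    )

    def run(self, rows, cfg=None):
        cfg = cfg or pz.FilterConfig()
        stage1 = pz.apply_variant_filters(pd.DataFrame(rows), cfg=cfg)
        return pz.apply_aggregation_criteria(stage1, self.GENES, cfg)

    def test_autosomal_missense_meeting_no_criterion_dropped(self):
        res = self.run([mk_finding(gene="G_none", consequence="missense")])
        assert res.audit.iloc[0] == "aggregation_autosomal"

    def test_y_linked_lof_kept(self):
        res = self.run([mk_finding(gene="G_y", model="YL", consequence="lof")])
        assert len(res.surviving) == 1

    def test_y_linked_missense_dropped(self):
        res = self.run([mk_finding(gene="G_y", model="YL", consequence="missense")])
        assert res.audit.iloc[0] == "aggregation_y"

    def test_autosomal_missense_with_infertility_evidence_kept(self):
        # known infertility gene, no testis class, premeiotic TPM 0.8 -> kept
        res = self.run([mk_finding(gene="G_inf", consequence="missense")])
        assert len(res.surviving) == 1

    def test_premeiotic_tpm_rule_on_kept_findings(self):
        # lof meets criterion 1, but testis_class none and TPM 0.1 -> dropped
        res = self.run([mk_finding(gene="G_none", consequence="lof")])
        assert res.audit.iloc[0] == "premeiotic_tpm"
        # same but TPM 0.8 -> kept
        res2 = self.run([mk_finding(gene="G_tpm", consequence="lof")])
        assert len(res2.surviving) == 1

    def test_x_requires_testis_expression(self):
        res = self.run([mk_finding(gene="G_x_none", model="XL", consequence="lof")])
        assert res.audit.iloc[0] == "aggregation_x"
        res2 = self.run([mk_finding(gene="G_x_enh", model="XL", consequence="lof")])
        assert len(res2.surviving) == 1

    def test_unknown_chromosome_rejected(self):
        genes = mk_genes([("G_bad", "MT", "none", False, 1.0)])
        stage1 = pz.apply_variant_filters(pd.DataFrame([mk_finding(gene="G_bad")]))
        with pytest.raises(ValueError, match="chromosome"):
            pz.apply_aggregation_criteria(stage1, genes)


class TestSubtractSharedGenes:
    def mk_result(self, genes):
        f = pd.DataFrame([mk_finding(sample=f"S{i}", gene=g) for i, g in enumerate(genes)])
        return pz.apply_variant_filters(f)

    @pytest.mark.parametrize(
        "case_genes,control_genes,expect_case,expect_control",
        [
            (["A", "B"], ["C", "D"], {"A", "B"}, {"C", "D"}),  # disjoint unchanged
            (["A", "B"], ["A", "B"], set(), set()),  # identical -> both empty
            (["A", "B", "C"], ["B", "D"], {"A", "C"}, {"D"}),  # set algebra
        ],
    )
    def test_set_semantics(self, case_genes, control_genes, expect_case, expect_control):
        case, control = pz.subtract_shared_genes(
            self.mk_result(case_genes), self.mk_result(control_genes)
        )
        assert case.surviving_genes == expect_case
        assert control.surviving_genes == expect_control
        assert not (case.surviving_genes & control.surviving_genes)


class TestDetectionSummary:
    def test_all_solved_rate_one(self, gene_universe, ready_pool):
        ind, findings, _ = sd.generate_cohort(
            gene_universe,
            ready_pool,
            n_cases=30,
            n_controls=0,
            consang_fraction=0.0,
            case_discovery_rate_by_stratum={"consanguineous": 1.0, "outbred": 1.0},
            fp_rate=0.0,
            seed=21,
        )
        res = pz.apply_aggregation_criteria(
            pz.apply_variant_filters(findings, ind), gene_universe
        )
        rates, _ = pz.detection_summary(res, ind)
        assert rates["outbred"]["rate"] == 1.0
        assert rates["consanguineous"]["empty_stratum"]

    def test_contingency_table_back_derivation(self):
        """55/72 consanguineous vs 127/852 outbred -> [[55,17],[127,725]]."""
        ind = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(924)],
                "status": "case",
                "consanguineous": [True] * 72 + [False] * 852,
            }
        )
        solved = list(range(55)) + list(range(72, 72 + 127))
        f = pd.DataFrame(
            [mk_finding(sample=f"S{i}", gene=f"G{i}", key=f"K{i}") for i in solved]
        )
        res = pz.apply_variant_filters(f, ind)
        rates, table = pz.detection_summary(res, ind)
        assert table.to_array().tolist() == [[55, 17], [127, 725]]
        assert rates["consanguineous"]["rate"] == pytest.approx(0.764, abs=0.001)
        assert rates["outbred"]["rate"] == pytest.approx(0.149, abs=0.001)

    def test_planted_rate_recovered(self, gene_universe, ready_pool):
        ind, findings, truth = sd.generate_cohort(
            gene_universe,
            ready_pool,
            n_cases=400,
            n_controls=0,
            consang_fraction=0.0,
            case_discovery_rate_by_stratum={"consanguineous": 0.2, "outbred": 0.2},
            fp_rate=0.0,
            seed=22,
        )
        res = pz.apply_aggregation_criteria(
            pz.apply_variant_filters(findings, ind), gene_universe
        )
        rates, _ = pz.detection_summary(res, ind)
        sigma = np.sqrt(0.2 * 0.8 / 400)
        assert rates["outbred"]["rate"] == pytest.approx(0.2, abs=3 * sigma)


class TestCascadeProperties:
    def full_cascade(self, findings, ind, genes, cfg=None):
        cfg = cfg or pz.FilterConfig()
        return pz.apply_aggregation_criteria(
            pz.apply_variant_filters(findings, ind, cfg), genes, cfg
        )

    def test_idempotence(self, gene_universe, cohort):
        ind, findings, _ = cohort
        once = self.full_cascade(findings, ind, gene_universe)
        twice = self.full_cascade(once.surviving, ind, gene_universe)
        pd.testing.assert_frame_equal(once.surviving, twice.surviving)

    def test_audit_partitions_input(self, gene_universe, cohort):
        ind, findings, _ = cohort
        res = self.full_cascade(findings, ind, gene_universe)
        assert len(res.audit) == len(findings)
        assert len(res.surviving) + int((res.audit != "pass").sum()) == len(findings)
        assert set(res.surviving.index) == set(res.audit[res.audit == "pass"].index)

    def test_monotonicity_relaxing_thresholds(self, gene_universe, cohort):
        """Relaxing every threshold never shrinks the surviving set."""
        ind, findings, _ = cohort
        strict = self.full_cascade(findings, ind, gene_universe)
        lax = self.full_cascade(
            findings,
            ind,
            gene_universe,
            pz.FilterConfig(
                psap_p_max=1e-2,
                popmax_maf_max=0.05,
                identical_hom_hemi_max_individuals=10,
                identical_comphet_pair_max_individuals=5,
                gene_enrichment_max_individuals=10,
                premeiotic_tpm_min=0.0,
            ),
        )
        assert set(strict.surviving.index) <= set(lax.surviving.index)

    def test_planted_truth_fully_retained_without_fps(self, gene_universe, ready_pool):
        """With fp_rate=0 and an aggregation-compatible pool, the cascade
        rejects no planted-true finding."""
        ind, findings, truth = sd.generate_cohort(
            gene_universe,
            ready_pool,
            n_cases=300,
            n_controls=0,
            consang_fraction=0.1,
            fp_rate=0.0,
            seed=23,
        )
        res = self.full_cascade(findings, ind, gene_universe)
        true_idx = truth.finding_truth[truth.finding_truth].index
        assert set(true_idx) <= set(res.surviving.index)

    def test_rule_order_changes_audit_only(self, cohort):
        """Every stage-1 rule is a predicate on the input table, so applying
        the rules in any order changes which rule an overlapping finding is
        attributed to, never the surviving set."""
        ind, findings, _ = cohort
        cfg = pz.FilterConfig()
        baseline = pz.apply_variant_filters(findings, ind, cfg)
        case_ids = pd.Index(ind.loc[ind["status"] == "case", "sample_id"])
        masks = pz._stage1_masks(findings, case_ids, cfg)
        rng = np.random.default_rng(24)
        for _ in range(5):
            order = rng.permutation(list(pz.STAGE1_RULES))
            audit = pd.Series("pass", index=findings.index, dtype=object)
            for rule in order:
                audit[masks[rule] & (audit == "pass")] = rule
            assert set(findings.index[audit == "pass"]) == set(
                baseline.surviving.index
            )
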