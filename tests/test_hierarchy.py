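"""H-scores, hub calling under a gamma null, and SE taxonomy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from capture3c.genome import GeneModel, GenomicInterval
from capture3c.hierarchy import (
    EnhancerRecord,
    SEHierarchyModel,
    SuperEnhancer,
    call_hubs,
    categorize_se_interactions,
    classify_hierarchical,
    classify_se_gene_patterns,
    compare_distance_sets,
    h_score,
    se_gene_distance,
)


class TestHScore:
    def test_worked_example(self):
        assert h_score([10, 20, 30], [1, 1, 1]) == pytest.approx([0.5, 1.0, 1.5])

    def test_scale_invariance_in_EN(self):
        base = h_score([10, 20, 30], [1, 1, 1])
        scaled = h_score([70, 140, 210], [1, 1, 1])
        assert scaled == pytest.approx(base)

    def test_hand_arithmetic_oracle(self):
        EN = [7, 3, 5, 9]
        L = [2, 1, 1, 3]
        mean_en = sum(EN) / 4  # 6.0
        expected = [en / (l * mean_en) for en, l in zip(EN, L)]
        assert h_score(EN, L) == pytest.approx(expected)

    def test_sum_identity(self, rng):
        # sum_i H_i * L_i = s exactly, for any SE
        for _ in range(100):
            s = int(rng.integers(1, 12))
            EN = rng.integers(0, 50, size=s).astype(float)
            if EN.sum() == 0:
                EN[0] = 1
            L = rng.uniform(0.2, 5.0, size=s)
            h = h_score(EN, L)
            assert float(np.sum(h * L)) == pytest.approx(s, rel=1e-12)

    def test_zero_total_pets(self):
        assert h_score([0, 0], [1, 2]) == pytest.approx([0.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            h_score([1, 2], [1.0])


def records_from_scores(scores):
    return [
        EnhancerRecord(f"e{i}", f"SE{i % 7}",
                       GenomicInterval("c", 1000 * i + 1, 1000 * i + 1001), EN=1, H=h)
        for i, h in enumerate(scores)
    ]


class TestCallHubs:
    def test_all_equal_scores_no_hubs(self):
        recs = records_from_scores([1.0] * 30)
        out, _ = call_hubs(recs)
        assert not any(r.hub for r in out)

    def test_too_few_positive_scores_rejected(self):
        recs = records_from_scores([1.0, 2.0, 0.0])
        with pytest.raises(ValueError, match="positive H-scores"):
            call_hubs(recs)

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(2024)
        null = stats.gamma.rvs(2.0, scale=1.0, size=500, random_state=rng)
        planted_value = stats.gamma.ppf(0.999, 2.0, scale=1.0)
        scores = np.concatenate([null, np.full(5, planted_value)])
        recs = records_from_scores(scores)
        out, gnull = call_hubs(recs, alpha=0.05)
        planted_hits = sum(r.hub for r in out[-5:])
        assert planted_hits >= 4
        false_rate = sum(r.hub for r in out[:500]) / 500
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(false_rate - 0.05) <= 3 * se
        # hubs lie above the (1-alpha) null quantile
        q95 = gnull.quantile(0.95)
        assert all(r.H >= q95 * 0.999 for r in out if r.hub)

    def test_zero_scores_never_hubs(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([stats.gamma.rvs(2, size=50, random_state=rng), [0.0]])
        out, _ = call_hubs(records_from_scores(scores))
        assert not out[-1].hub
        assert out[-1].p_value == 1.0


class TestClassifyHierarchical:
    def test_one_hub_suffices(self):
        recs = records_from_scores([1.0, 1.0, 1.0])
        for r in recs:
            r.se_id = "SEx"
        recs[2].hub = True
        ses = [SuperEnhancer("SEx", [r.enhancer_id for r in recs])]
        out = classify_hierarchical(ses, recs)
        assert out[0].hierarchical

    def test_no_hub_not_hierarchical(self):
        recs = records_from_scores([1.0, 1.0])
        for r in recs:
            r.se_id = "SEy"
        ses = [SuperEnhancer("SEy", [r.enhancer_id for r in recs])]
        assert not classify_hierarchical(ses, recs)[0].hierarchical

    def test_fraction_matches_enumeration(self, rng):
        recs = []
        ses = []
        expected_hier = 0
        for j in range(40):
            members = []
            any_hub = False
            for i in range(int(rng.integers(1, 6))):
                r = EnhancerRecord(f"s{j}e{i}", f"S{j}",
                                   GenomicInterval("c", 1, 100), EN=1, H=1.0)
                r.hub = bool(rng.random() < 0.2)
                any_hub |= r.hub
                members.append(r)
            expected_hier += any_hub
            recs.extend(members)
            ses.append(SuperEnhancer(f"S{j}", [m.enhancer_id for m in members]))
        out = classify_hierarchical(ses, recs)
        assert sum(s.hierarchical for s in out) == expected_hier


class TestCategorizeSeInteractions:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel("g1", "G1", GenomicInterval("c1", 50_000, 90_000, strand="+")),
            GeneModel("g2", "G2", GenomicInterval("c1", 200_000, 260_000, strand="-")),
        ]

    def make_calls(self, rows):
        return pd.DataFrame(rows, columns=["bait_id", "chrom", "start", "end"])

    def test_promoter_precedence(self, genes):
        # partner spanning TSS-500 of g1 (TSS=50000)
        calls = self.make_calls([("SE1", "c1", 49_400, 49_600)])
        out = categorize_se_interactions(calls, genes, promoter_window=2000)
        assert list(out) == ["SE-P"]

    def test_gene_body(self, genes):
        calls = self.make_calls([("SE1", "c1", 70_000, 70_200)])  # mid-gene, > 2 kb from TSS
        out = categorize_se_interactions(calls, genes, promoter_window=2000)
        assert list(out) == ["SE-G"]

    def test_gene_desert(self, genes):
        calls = self.make_calls([("SE1", "c1", 500_000, 500_200)])
        out = categorize_se_interactions(calls, genes, promoter_window=2000)
        assert list(out) == ["SE-O"]

    def test_minus_strand_tss(self, genes):
        # g2 TSS at 259_999
        calls = self.make_calls([("SE1", "c1", 260_500, 260_700)])
        out = categorize_se_interactions(calls, genes, promoter_window=2000)
        assert list(out) == ["SE-P"]

    def test_every_call_gets_exactly_one_label(self, genes, rng):
        rows = [("SE1", "c1", int(s), int(s) + 200)
                for s in rng.integers(0, 900_000, size=200)]
        out = categorize_se_interactions(self.make_calls(rows), genes)
        assert set(out) <= {"SE-P", "SE-G", "SE-O"}
        assert len(out) == 200


class TestSeGenePatterns:
    def test_five_classes(self):
        links = [
            ("SE1", "gA"),
            ("SE2", "gB"), ("SE2", "gC"), ("SE2", "gD"),
            ("SE3", "gE"), ("SE4", "gE"),
            ("SE5", "gF"), ("SE5", "gG"), ("SE6", "gF"),
        ]
        out = classify_se_gene_patterns(
            links, ["SE1", "SE2", "SE3", "SE4", "SE5", "SE6", "SE7"]
        )
        assert out["SE1"] == "single SE to single gene"
        assert out["SE2"] == "single SE to multiple genes"
        assert out["SE3"] == out["SE4"] == "multiple SEs to single gene"
        assert out["SE5"] == out["SE6"] == "multiple SEs to multiple genes"
        assert out["SE7"] == "no significant interacting gene"

    def test_labels_partition_all_ses(self, rng):
        all_ses = [f"SE{i}" for i in range(30)]
        links = [
            (all_ses[int(rng.integers(30))], f"g{int(rng.integers(15))}")
            for _ in range(40)
        ]
        out = classify_se_gene_patterns(links, all_ses)
        assert sorted(out) == sorted(all_ses)
        assert all(isinstance(v, str) and v for v in out.values())


class TestSeGeneDistance:
    def make_links(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "tss", "enhancer_id", "enh_mid", "strength", "bf"]
        )

    def test_single_enhancer(self):
        out = se_gene_distance(self.make_links([("g", 50_000, "e1", 10_000, 5, 100.0)]))
        assert out.iloc[0]["distance"] == 40_000

    def test_strongest_enhancer_wins(self):
        links = self.make_links(
            [("g", 50_000, "e1", 10_000, 5, 100.0),
             ("g", 50_000, "e2", 30_000, 9, 50.0)]
        )
        out = se_gene_distance(links)
        assert out.iloc[0]["enhancer_id"] == "e2"
        assert out.iloc[0]["distance"] == 20_000

    def test_tie_breaks_by_bf_then_position(self):
        links = self.make_links(
            [("g", 50_000, "eL", 20_000, 5, 80.0),
             ("g", 50_000, "eR", 40_000, 5, 80.0),
             ("g", 50_000, "eB", 45_000, 5, 90.0)]
        )
        out = se_gene_distance(links)
        assert out.iloc[0]["enhancer_id"] == "eB"  # higher BF first
        links2 = self.make_links(
            [("g", 50_000, "eR", 40_000, 5, 80.0),
             ("g", 50_000, "eL", 20_000, 5, 80.0)]
        )
        assert se_gene_distance(links2).iloc[0]["enhancer_id"] == "eL"  # leftmost

    def test_cohort_t_test_matches_textbook_formula(self, rng):
        a = rng.normal(200_000, 50_000, size=40)
        b = rng.normal(120_000, 40_000, size=35)
        t, p = compare_distance_sets(a, b)
        # pooled-variance two-sample t statistic, by hand
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(t_hand, rel=1e-10)
        assert p == pytest.approx(
            2 * stats.t.sf(abs(t_hand), len(a) + len(b) - 2), rel=1e-10
        )


class TestSEHierarchyModel:
    @pytest.fixture
    def cohort(self, rng):
        rows = []
        for j in range(20):
            s = int(rng.integers(2, 6))
            for i in range(s):
                rows.append(
                    (f"se{j}_e{i}", f"SE{j}", "c1",
                     1_000_000 * j + 10_000 * i, 1_000_000 * j + 10_000 * i + 2_000,
                     int(rng.integers(5, 60)))
                )
        return pd.DataFrame(
            rows, columns=["enhancer_id", "se_id", "chrom", "start", "end", "EN"]
        )

    def test_fit_produces_consistent_tables(self, cohort):
        res = SEHierarchyModel(cohort, alpha=0.05).fit()
        enh = res.enhancer_table
        ses = res.se_table
        assert len(enh) == len(cohort)
        assert set(ses["se_id"]) == set(cohort["se_id"])
        # hierarchical flag equals any-hub over members
        for _, se in ses.iterrows():
            members = enh[enh["se_id"] == se["se_id"]]
            assert se["hierarchical"] == members["hub"].any()
        # H identity per SE (L in kb)
        for se_id, members in enh.groupby("se_id"):
            ident = float((members["H"] * members["L"] / 1000.0).sum())
            assert ident == pytest.approx(len(members), rel=1e-9)

    def test_hub_calls_unit_invariant(self, cohort):
        res1 = SEHierarchyModel(cohort).fit()
        scaled = cohort.copy()
        scaled["EN"] = scaled["EN"] * 13  # global EN rescale: H per SE unchanged
        res2 = SEHierarchyModel(scaled).fit()
        assert [r.hub for r in res1.records] == [r.hub for r in res2.records]

    def test_summary_reports_fraction(self, cohort):
        res = SEHierarchyModel(cohort).fit()
        assert "hierarchical SEs" in res.summary()
        n = sum(s.hierarchical for s in res.ses)
        assert res.hierarchical_fraction_pct == round(100 * n / len(res.ses), 1)
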