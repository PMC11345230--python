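import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apa_regulon.dapa import (
    adjust_direction,
    cross_cellline_consistency,
    dapa_cohort,
    dapa_perturbation,
    pau_from_betas,
    pooled_chi2_tester,
    rbp_effect_summary,
    weighted_pas_rank,
)
from apa_regulon.io_formats import PasAnnotation, PasCountMatrix
from apa_regulon.pas_quant import pau_table


def exact_fit_matrix(beta0, beta1, n_per_arm=12, base=40):
    """Noiseless counts with r_PAS = beta0*r_other (+ beta1*D*r_other).

    Other-PAS counts vary across samples; the proximal count is an exact
    multiple so the no-intercept median regression must recover the betas.
    """
    samples = {}
    for i in range(2 * n_per_arm):
        other = base * (1 + i % 4)  # 40, 80, 120, 160
        b = beta0 + (beta1 if i >= n_per_arm else 0.0)
        samples[f"s{i:02d}"] = (int(round(b * other)), other)
    anns = [
        PasAnnotation("e:pas1", "e", "g", "chr1", 1000, 1001, "+", 1, False),
        PasAnnotation("e:pas2", "e", "g", "chr1", 2000, 2001, "+", 2, True),
    ]
    counts = pd.DataFrame(
        {"e:pas1": [v[0] for v in samples.values()],
         "e:pas2": [v[1] for v in samples.values()]},
        index=list(samples),
    ).T
    m = PasCountMatrix(annotations=anns, counts=counts)
    cond = pd.Series([0] * n_per_arm + [1] * n_per_arm, index=list(samples))
    sf = pd.Series(1.0, index=list(samples))
    return m, cond, sf


class TestPauFromBetas:
    @pytest.mark.parametrize(
        "b0,b1,pau0,pau1,dpau",
        [(1.0, 0.0, 0.5, 0.5, 0.0), (1.0, 1.0, 0.5, 2 / 3, 1 / 6)],
    )
    def test_printed_formula_examples(self, b0, b1, pau0, pau1, dpau):
        got = pau_from_betas(b0, b1)
        assert got == pytest.approx((pau0, pau1, dpau), abs=1e-12)

    def test_delta_identity_for_random_nonnegative_betas(self):
        rng = np.random.default_rng(0)
        b0 = rng.exponential(1.0, size=2000)
        b1 = rng.exponential(1.0, size=2000) - b0.clip(max=0.5)
        for a, b in zip(b0, b1):
            pau0, pau1, dpau = pau_from_betas(a, b)
            assert dpau == pytest.approx(pau1 - pau0, abs=1e-12)


class TestDapaCohort:
    def test_exact_fit_recovers_betas(self):
        m, cond, sf = exact_fit_matrix(1.0, 0.0)
        res = dapa_cohort(m, cond, sf).set_index("pas_id")
        assert res.loc["e:pas1", "beta0"] == pytest.approx(1.0, abs=1e-8)
        assert res.loc["e:pas1", "beta1"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc["e:pas1", "pau0"] == pytest.approx(0.5, abs=1e-8)
        assert res.loc["e:pas1", "delta_pau"] == pytest.approx(0.0, abs=1e-8)

    def test_exact_fit_with_condition_effect(self):
        m, cond, sf = exact_fit_matrix(0.5, 0.25)
        res = dapa_cohort(m, cond, sf).set_index("pas_id")
        assert res.loc["e:pas1", "beta0"] == pytest.approx(0.5, abs=1e-8)
        assert res.loc["e:pas1", "beta1"] == pytest.approx(0.25, abs=1e-8)
        pau0, pau1, dpau = pau_from_betas(0.5, 0.25)
        assert res.loc["e:pas1", "pau1"] == pytest.approx(pau1, abs=1e-8)

    def test_condition_label_swap_flips_beta1_and_delta(self):
        m, cond, sf = exact_fit_matrix(0.5, 0.25)
        res = dapa_cohort(m, cond, sf).set_index("pas_id")
        res_sw = dapa_cohort(m, 1 - cond, sf).set_index("pas_id")
        b0, b1 = res.loc["e:pas1", ["beta0", "beta1"]]
        b0s, b1s = res_sw.loc["e:pas1", ["beta0", "beta1"]]
        assert b0s == pytest.approx(b0 + b1, abs=1e-8)
        assert b1s == pytest.approx(-b1, abs=1e-8)
        assert res_sw.loc["e:pas1", "delta_pau"] == pytest.approx(
            -res.loc["e:pas1", "delta_pau"], abs=1e-8
        )

    def test_too_few_samples_rejected(self):
        m, cond, sf = exact_fit_matrix(1.0, 0.0, n_per_arm=4)
        with pytest.raises(ValueError, match="fewer than"):
            dapa_cohort(m, cond, sf)

    def test_zero_r_other_condition_untested(self, two_pas_exon_factory):
        data = {f"s{i}": ((10, 0) if i < 10 else (10, 20)) for i in range(20)}
        m = two_pas_exon_factory(data)
        cond = pd.Series([0] * 10 + [1] * 10, index=list(data))
        res = dapa_cohort(m, cond, pd.Series(1.0, index=list(data)))
        assert res.iloc[0]["reason"] == "all-zero r_other in a condition"
        assert np.isnan(res.iloc[0]["q"])

    def test_planted_cohort_effect_detected_with_fdr_control(self):
        from apa_regulon import SimulationConfig, simulate_cohort
        from apa_regulon.pas_quant import size_factors

        cfg = SimulationConfig(n_exons=80, n_samples_per_condition=30,
                               n_true_regulations=0, frac_condition_pas=0.15,
                               condition_effect_logit=2.0, seed=23)
        counts, _, clinical, truth = simulate_cohort(cfg)
        cond = (clinical.set_index("sample_id")["subtype"] == "cond1").astype(int)
        res = dapa_cohort(counts, cond, size_factors(counts.counts))
        # a shift planted on one site also moves its exon siblings
        # (usage is compositional), so truth lives at the exon level
        exon_of = {a.pas_id: a.exon_id for a in counts.annotations}
        hit_exons = {exon_of[p] for p in res.loc[res["q"] < 0.05, "pas_id"]}
        planted_exons = {exon_of[p] for p in truth.condition_dapa_pas}
        sensitivity = len(hit_exons & planted_exons) / len(planted_exons)
        fdr = len(hit_exons - planted_exons) / max(len(hit_exons), 1)
        assert sensitivity >= 0.6
        assert fdr <= 0.15


class TestAdjustDirection:
    def _exon(self, strand, k=2):
        anns = []
        for rank in range(1, k + 1):
            offset = rank if strand == "+" else (k + 1 - rank)
            anns.append(PasAnnotation(f"e:pas{rank}", "e", "g", "chr1",
                                      1000 * offset, 1000 * offset + 1, strand,
                                      rank, rank == k))
        return anns

    def _result_row(self, delta):
        return pd.DataFrame(
            [{"pas_id": "e:pas1", "exon_id": "e", "delta_pau": delta,
              "direction": "none"}]
        )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_two_site_higher_proximal_pau_means_shortening(self, strand):
        anns = self._exon(strand)
        pau = pd.DataFrame(
            {"s0": [0.2, 0.8], "s1": [0.25, 0.75], "s2": [0.7, 0.3],
             "s3": [0.75, 0.25]},
            index=["e:pas1", "e:pas2"],
        )
        cond = pd.Series([0, 0, 1, 1], index=pau.columns)
        out = adjust_direction(self._result_row(0.5), anns, pau, cond)
        assert out.iloc[0]["direction"] == "shortening"
        assert out.iloc[0]["delta_pau"] > 0

    def test_three_site_shift_to_distal_is_lengthening(self):
        anns = self._exon("+", k=3)
        # usage moves from the middle (rank-2, proximal) site to the distal one
        pau = pd.DataFrame(
            {"s0": [0.2, 0.6, 0.2], "s1": [0.2, 0.55, 0.25],
             "s2": [0.2, 0.1, 0.7], "s3": [0.2, 0.15, 0.65]},
            index=["e:pas1", "e:pas2", "e:pas3"],
        )
        cond = pd.Series([0, 0, 1, 1], index=pau.columns)
        res = pd.DataFrame(
            [{"pas_id": "e:pas2", "exon_id": "e", "delta_pau": -0.45,
              "direction": "none"}]
        )
        out = adjust_direction(res, anns, pau, cond)
        assert out.iloc[0]["direction"] == "lengthening"
        assert out.iloc[0]["delta_pau"] == pytest.approx(-0.45)

    def test_single_pas_exon_has_no_direction(self):
        ann = [PasAnnotation("e:pas1", "e", "g", "chr1", 10, 11, "+", 1, True)]
        pau = pd.DataFrame({"s0": [1.0], "s1": [1.0]}, index=["e:pas1"])
        cond = pd.Series([0, 1], index=pau.columns)
        out = adjust_direction(self._result_row(0.1), ann, pau, cond)
        assert out.iloc[0]["direction"] == "none"

    def test_weighted_rank_strand_invariance(self):
        pau_vals = {"s0": [0.3, 0.7], "s1": [0.6, 0.4]}
        ranks = {}
        for strand in "+-":
            anns = self._exon(strand)
            pau = pd.DataFrame(pau_vals, index=["e:pas1", "e:pas2"])
            ranks[strand] = weighted_pas_rank(pau, anns)
        pd.testing.assert_frame_equal(ranks["+"], ranks["-"])


class TestDapaPerturbation:
    def _panel(self, ctrl_counts, depl_counts):
        data = {}
        design_rows = []
        for i, c in enumerate(ctrl_counts):
            sid = f"c{i}"
            data[sid] = c
            design_rows.append({"experiment_id": "x", "cell_line": "K",
                                "target_rbp": "R", "sample_id": sid,
                                "arm": "control", "replicate": i + 1})
        for i, c in enumerate(depl_counts):
            sid = f"d{i}"
            data[sid] = c
            design_rows.append({"experiment_id": "x", "cell_line": "K",
                                "target_rbp": "R", "sample_id": sid,
                                "arm": "depleted", "replicate": i + 1})
        from tests.conftest import make_two_pas_exon

        return make_two_pas_exon(data), pd.DataFrame(design_rows)

    def test_identical_proportions_give_null_result(self):
        m, design = self._panel([(10, 30), (10, 30)], [(20, 60), (20, 60)])
        res = dapa_perturbation(m, design, "x")
        assert res.iloc[0]["delta_pau"] == pytest.approx(0.0)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_strong_shift_significant_with_positive_delta(self):
        m, design = self._panel(
            [(100, 900), (110, 890), (95, 905)],
            [(500, 500), (510, 490), (480, 520)],
        )
        res = dapa_perturbation(m, design, "x").set_index("pas_id")
        assert res.loc["exonA:pas1", "delta_pau"] > 0.3
        assert res.loc["exonA:pas1", "q"] < 0.05
        assert res.loc["exonA:pas1", "direction"] == "shortening"
        res_logit = dapa_perturbation(m, design, "x", method="logit")
        assert res_logit.set_index("pas_id").loc["exonA:pas1", "q"] < 0.05

    def test_zero_coverage_arm_untested(self):
        m, design = self._panel([(0, 0), (0, 0)], [(10, 10), (10, 10)])
        res = dapa_perturbation(m, design, "x")
        assert res.iloc[0]["reason"] == "zero exon coverage in an arm"

    def test_too_few_replicates_rejected(self):
        m, design = self._panel([(1, 1)], [(1, 1), (1, 1)])
        with pytest.raises(ValueError, match="control replicates"):
            dapa_perturbation(m, design, "x")

    def test_pooled_tester_switches_to_exact_for_sparse_tables(self):
        sparse = np.array([[3, 1], [1, 3]])  # min expected cell = 2
        assert pooled_chi2_tester(sparse) == pytest.approx(
            stats.fisher_exact(sparse)[1]
        )
        dense = np.array([[100, 50], [60, 90]])
        assert pooled_chi2_tester(dense) == pytest.approx(
            stats.chi2_contingency(dense)[1]
        )


class TestRbpEffectSummary:
    def _tables(self, spec_per_exp):
        """spec_per_exp: {exp: list of (exon, direction, q, delta)}."""
        tables = {}
        meta_rows = []
        for exp, rows in spec_per_exp.items():
            tables[exp] = pd.DataFrame(
                [{"pas_id": f"{exon}:p1", "exon_id": exon, "direction": d,
                  "q": q, "delta_pau": delta, "p": q}
                 for exon, d, q, delta in rows]
            )
            meta_rows.append({"experiment_id": exp, "target_rbp": exp.split("_")[1],
                              "cell_line": exp.split("_")[0]})
        return tables, pd.DataFrame(meta_rows)

    def test_eight_two_split_binomial(self):
        rows = [(f"e{i}", "shortening", 0.01, 0.2) for i in range(8)]
        rows += [(f"e{i+8}", "lengthening", 0.01, -0.2) for i in range(2)]
        tables, meta = self._tables({"K_R1": rows})
        s = rbp_effect_summary(tables, meta).iloc[0]
        assert s["n_shortening"] == 8 and s["n_lengthening"] == 2
        assert s["log2_ratio"] == pytest.approx(2.0)
        assert s["p_binomial"] == pytest.approx(112 / 1024)

    def test_balanced_split_is_null(self):
        rows = [(f"e{i}", "shortening", 0.01, 0.2) for i in range(5)]
        rows += [(f"e{i+5}", "lengthening", 0.01, -0.2) for i in range(5)]
        tables, meta = self._tables({"K_R1": rows})
        s = rbp_effect_summary(tables, meta).iloc[0]
        assert s["log2_ratio"] == pytest.approx(0.0)
        assert s["p_binomial"] == pytest.approx(1.0)

    def test_no_significant_events_reported_untested(self):
        tables, meta = self._tables({"K_R1": [("e0", "shortening", 0.9, 0.1)]})
        s = rbp_effect_summary(tables, meta).iloc[0]
        assert s["n_significant"] == 0
        assert np.isnan(s["p_binomial"])
        assert not s["fdr_flag"]

    def test_exon_counted_once_by_dominant_direction(self):
        rows = [("e0", "shortening", 0.01, 0.3), ("e0", "shortening", 0.01, 0.2),
                ("e0", "lengthening", 0.01, -0.1)]
        tables, meta = self._tables({"K_R1": rows})
        s = rbp_effect_summary(tables, meta).iloc[0]
        assert s["n_shortening"] == 1 and s["n_lengthening"] == 0


class TestCrossCelllineConsistency:
    def _summary(self, exp, vec):
        df = pd.DataFrame([{"experiment_id": exp, "rbp_id": exp.split("_")[1],
                            "cell_line": exp.split("_")[0]}])
        df.attrs["effect_vectors"] = {
            exp: pd.Series(vec, index=[f"p{i}" for i in range(len(vec))])
        }
        return df

    @pytest.mark.parametrize(
        "vec_b,expected",
        [([1.0, 2.0, 3.0], 1.0), ([-1.0, -2.0, -3.0], -1.0)],
    )
    def test_identical_and_negated_vectors(self, vec_b, expected):
        a = self._summary("K_R1", [1.0, 2.0, 3.0])
        b = self._summary("H_R1", vec_b)
        out = cross_cellline_consistency(a, b)
        assert out.iloc[0]["cosine"] == pytest.approx(expected)

    def test_orthogonal_vectors(self):
        a = self._summary("K_R1", [1.0, 0.0, 1.0, 0.0])
        b = self._summary("H_R1", [0.0, 1.0, 0.0, 1.0])
        assert cross_cellline_consistency(a, b).iloc[0]["cosine"] == pytest.approx(0.0)

    def test_too_few_shared_sites_undefined(self):
        a = self._summary("K_R1", [1.0, 2.0])
        b = self._summary("H_R1", [1.0, 2.0])
        out = cross_cellline_consistency(a, b)
        assert np.isnan(out.iloc[0]["cosine"])
        assert "fewer than" in out.iloc[0]["reason"]
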