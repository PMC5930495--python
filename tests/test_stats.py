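"""Empirical p-values, bivariate-normal conditioning, and the full report."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from deamotif import (
    MotifSpec,
    ShuffleConfig,
    SyntheticSpec,
    build_null,
    build_report,
    classify_representation,
    conditional_pvalue,
    count_motifs,
    deplete_motif,
    empirical_below,
    motif_metrics,
    pairwise_correlation,
    random_cds,
)


class TestEmpiricalBelow:
    @pytest.mark.parametrize(
        "null,obs,expected",
        [
            ([5, 6, 7, 8], 4, 0.0),
            ([1, 2, 3, 4], 10, 1.0),
            ([1, 2, 3, 4], 3, 0.5),  # strict inequality: ties excluded
        ],
    )
    def test_strict_definition(self, null, obs, expected):
        assert empirical_below(null, obs) == expected

    def test_mid_p_variant_counts_half_the_ties(self):
        assert empirical_below([1, 2, 3, 3, 4], 3, mid_p=True) == pytest.approx(
            (2 + 0.5 * 2) / 5
        )

    def test_missing_entries_dropped(self):
        assert empirical_below([1.0, np.nan, 3.0, np.nan], 2.0) == 0.5

    def test_all_missing_reports_missing(self):
        assert empirical_below([np.nan, np.nan], 1.0) is None
        assert empirical_below([1, 2], None) is None

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            null = rng.integers(0, 30, size=200).astype(float)
            null[rng.random(200) < 0.1] = np.nan
            obs = float(rng.integers(0, 30))
            kept = [v for v in null if not math.isnan(v)]
            oracle = sum(v < obs for v in kept) / len(kept)
            assert empirical_below(null, obs) == pytest.approx(oracle)


class TestClassification:
    @pytest.mark.parametrize(
        "p,call",
        [(0.008, "under"), (0.36, "neutral"), (0.96, "over"),
         (0.05, "neutral"), (0.95, "neutral")],
    )
    def test_thresholding(self, p, call):
        assert classify_representation(p, q=0.05) == call

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_representation(0.5, q=0.7)


class TestPairwiseCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=100)
        assert pairwise_correlation(x, x) == pytest.approx(1.0)
        assert pairwise_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(pairwise_correlation(x, y)) < 0.05  # ~3/sqrt(r)

    def test_zero_variance_is_missing(self, rng):
        assert pairwise_correlation([1, 1, 1], [1, 2, 3]) is None

    def test_pairwise_deletion(self, rng):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 100.0, 8.0, 10.0])
        assert pairwise_correlation(x, y) == pytest.approx(1.0)


class TestConditionalPvalue:
    def test_independence_reduces_to_marginal(self):
        for obs in (8.0, 10.0, 13.5):
            p = conditional_pvalue(obs, 99.0, 10.0, 50.0, 2.0, 5.0, rho=0.0)
            assert p == pytest.approx(
                sps.norm.cdf(obs, 10.0, 2.0), abs=1e-12
            )

    def test_closed_form_conditional_mean(self):
        # conditional mean = 10 + 0.5*(2/2)*(12-10) = 11 = obs_x -> p = 0.5
        p = conditional_pvalue(11.0, 12.0, 10.0, 10.0, 2.0, 2.0, rho=0.5)
        assert p == pytest.approx(0.5)

    def test_extreme_observation_limits(self):
        assert conditional_pvalue(-1e9, 0, 0, 0, 1, 1, 0.3) == pytest.approx(0)
        assert conditional_pvalue(1e9, 0, 0, 0, 1, 1, 0.3) == pytest.approx(1)

    def test_degenerate_inputs_missing(self):
        assert conditional_pvalue(1, 1, 0, 0, 0.0, 1, 0.2) is None
        assert conditional_pvalue(1, 1, 0, 0, 1, 1, 1.0) is None


MOTIFS = [MotifSpec("TAC"), MotifSpec("WRC"), MotifSpec("CG")]


@pytest.fixture(scope="module")
def small_report():
    seq = random_cds(SyntheticSpec(n_codons=80, gc3=0.5, seed=17))
    cfg = ShuffleConfig(method="gc3", replicates=400, seed=23)
    return seq, cfg, build_report(seq, cfg, MOTIFS)


class TestReport:
    UNIVARIATE = ("observed{x}", "repTr_observed{x}", "repTrFrac_observed{x}",
                  "expected{x}", "expectedSd{x}", "repTr_expected{x}",
                  "repTr_expectedSd{x}", "repTrFrac_expected{x}",
                  "repTrFrac_expectedSd{x}", "below{x}", "repTr_below{x}",
                  "repTrFrac_below{x}")

    def test_schema_covers_all_metric_families(self, small_report):
        _, _, report = small_report
        for m in MOTIFS:
            for template in self.UNIVARIATE:
                assert template.format(x=m.name) in report
        assert "corTACxWRC" in report
        assert "corRepTrFracTACxCG" in report
        assert "pTACcondWRC" in report
        assert "pWRCcondTAC" in report  # both orderings
        assert "pTACcondRepTrFracWRC" in report

    def test_p_values_lie_in_unit_interval(self, small_report):
        _, _, report = small_report
        for key, value in report.values.items():
            if key.startswith(("below", "repTr_below", "repTrFrac_below",
                               "p", "BH_")):
                if value is not None:
                    assert 0.0 <= value <= 1.0, key

    def test_expected_matches_recomputed_null_mean(self, small_report):
        seq, cfg, report = small_report
        null = build_null(seq, cfg, MOTIFS)  # same seed -> same replicates
        for m in MOTIFS:
            assert report[f"expected{m.name}"] == pytest.approx(
                null.counts[m.name].mean(), abs=1e-9
            )
            assert report[f"expectedSd{m.name}"] == pytest.approx(
                null.counts[m.name].std(ddof=1), abs=1e-9
            )

    def test_observed_matches_direct_measurement(self, small_report):
        seq, _, report = small_report
        for m in MOTIFS:
            met = motif_metrics(seq, m)
            assert report[f"observed{m.name}"] == met.motif_count
            assert report[f"repTr_observed{m.name}"] == (
                met.replacement_transitions
            )

    def test_same_seed_reproduces_report(self, small_report):
        seq, cfg, report = small_report
        again = build_report(seq, cfg, MOTIFS)
        assert report.values == again.values

    def test_correlations_bounded(self, small_report):
        _, _, report = small_report
        for key, value in report.values.items():
            if key.startswith("cor") and value is not None:
                assert -1.0 <= value <= 1.0

    def test_to_frame_mirrors_values(self, small_report):
        _, _, report = small_report
        frame = report.to_frame()
        assert list(frame.columns) == ["key", "value"]
        assert len(frame) == len(report.values)
        row = frame.set_index("key").loc["observedTAC", "value"]
        assert row == report["observedTAC"]

    def test_classification_helper(self, small_report):
        _, _, report = small_report
        call = report.classification("TAC")
        assert call in ("under", "over", "neutral")
        assert call == classify_representation(
            report["belowTAC"], 0.05
        )


class TestPlantedDepletion:
    def test_depleted_subject_is_under_represented(self):
        """A subject synonymously stripped of TAC should sit far in the
        lower tail of its own shuffle null."""
        tac = MotifSpec("TAC")
        seq = random_cds(SyntheticSpec(n_codons=150, gc3=0.5, seed=31))
        depleted = deplete_motif(seq, tac, strength=1.0)
        cfg = ShuffleConfig(method="gc3", replicates=500, seed=37)
        report = build_report(depleted, cfg, [tac], bivariate=False)
        assert report["observedTAC"] < report["expectedTAC"]
        assert report["belowTAC"] < 0.05
        assert report.classification("TAC") == "under"


class TestMissingPropagation:
    def test_absent_motif_yields_missing_fraction_stats(self):
        # a motif that cannot occur: CCC in a sequence without C or G
        seq_str = "AAATTTAAATTT"
        from deamotif import CodingSequence

        seq = CodingSequence(seq_str)
        cfg = ShuffleConfig(method="n3", replicates=50, seed=3)
        report = build_report(seq, cfg, [MotifSpec("CCC")], bivariate=False)
        assert report["observedCCC"] == 0
        assert report["repTrFrac_observedCCC"] is None
        assert report["repTrFrac_belowCCC"] is None
        assert report["repTrFrac_expectedCCC"] is None
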