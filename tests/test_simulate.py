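"""Synthetic cohort generator: planted structure, calibration, round trips."""

import numpy as np
import pandas as pd
import pytest

from cernet.coexpression import pearson_with_pvalue
from cernet.simulate import (
    SimulationConfig,
    read_cohort,
    simulate_cohort,
    simulate_expression,
    simulate_interactions,
    simulate_survival,
    true_pairs,
    write_cohort,
)
from cernet.survival import cox_univariate


def small_config(**overrides):
    base = dict(
        n_mirnas=80, n_lncrnas=8, n_mrnas=20, n_samples=60, n_true_pairs=3, seed=9
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"n_mirnas": 0},
            {"n_true_pairs": 10**6},
            {"shared_fraction": 0.0},
            {"shared_fraction": 1.2},
            {"pair_correlation": 1.0},
            {"censoring_rate": 1.0},
            {"baseline_hazard": 0.0},
            {"mirnas_per_lncrna": (5, 2)},
            {"mirnas_per_lncrna": (5, 200)},
            {"risk_log_hazards": (0.7, 0.3)},
            {"planted_biclique": (100, 2)},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            small_config(**bad)


class TestInteractions:
    def test_identical_seed_gives_identical_interactions(self):
        a = simulate_interactions(small_config())
        b = simulate_interactions(small_config())
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_planted_pair_shares_at_least_the_forced_core(self):
        config = small_config(
            n_mirnas=50,
            mirnas_per_lncrna=(10, 10),
            mirnas_per_mrna=(10, 10),
            shared_fraction=0.8,
            n_true_pairs=1,
        )
        iset = simulate_interactions(config)
        (lnc, mrna), = true_pairs(config)
        shared = iset.mirna_sets("lncRNA")[lnc] & iset.mirna_sets("mRNA")[mrna]
        assert len(shared) >= 8

    def test_full_sharing_with_equal_sizes_gives_identical_sets(self):
        config = small_config(
            shared_fraction=1.0,
            mirnas_per_lncrna=(12, 12),
            mirnas_per_mrna=(12, 12),
            n_true_pairs=2,
        )
        iset = simulate_interactions(config)
        for lnc, mrna in true_pairs(config):
            assert iset.mirna_sets("lncRNA")[lnc] == iset.mirna_sets("mRNA")[mrna]

    def test_no_planted_pairs_matches_hypergeometric_chance(self):
        # empirical mean overlap across many unplanted pairs ~ K*M/N
        config = small_config(
            n_lncrnas=30, n_mrnas=60, n_true_pairs=0,
            mirnas_per_lncrna=(10, 10), mirnas_per_mrna=(10, 10), n_mirnas=100,
        )
        iset = simulate_interactions(config)
        lsets = iset.mirna_sets("lncRNA")
        msets = iset.mirna_sets("mRNA")
        overlaps = [len(a & b) for a in lsets.values() for b in msets.values()]
        assert np.mean(overlaps) == pytest.approx(10 * 10 / 100, abs=0.15)

    def test_biclique_pairs_counted_within_true_pairs(self):
        config = small_config(planted_biclique=(2, 3), n_true_pairs=8)
        pairs = true_pairs(config)
        assert len(pairs) == 8
        assert ("LNC0001", "MRNA0003") in pairs
        assert ("LNC0003", "MRNA0004") in pairs  # singleton after the module


class TestExpression:
    def test_planted_pair_correlation_calibrated(self):
        config = small_config(n_samples=500, pair_correlation=0.9, n_true_pairs=2)
        iset = simulate_interactions(config)
        lnc, mrna, _ = simulate_expression(config, iset)
        for l, m in true_pairs(config):
            r, _ = pearson_with_pvalue(lnc.loc[l], mrna.loc[m])
            assert r == pytest.approx(0.9, abs=0.05)

    def test_noiseless_planted_pair_is_perfectly_correlated(self):
        config = small_config(noise_sd=0.0, n_samples=50, n_true_pairs=1)
        iset = simulate_interactions(config)
        lnc, mrna, _ = simulate_expression(config, iset)
        (l, m), = true_pairs(config)
        r, _ = pearson_with_pvalue(lnc.loc[l], mrna.loc[m])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_pairs_have_chance_level_correlation(self):
        config = small_config(n_samples=500, n_true_pairs=0, n_lncrnas=20, n_mrnas=30)
        iset = simulate_interactions(config)
        lnc, mrna, _ = simulate_expression(config, iset)
        rs = np.corrcoef(np.vstack([lnc.to_numpy(), mrna.to_numpy()]))
        off = rs[:20, 20:].ravel()
        # mean |r| under the null is ~ sqrt(2 / (pi n))
        assert np.mean(np.abs(off)) == pytest.approx(np.sqrt(2 / (np.pi * 500)), rel=0.2)

    def test_truth_table_lists_pairs_and_risk_genes(self):
        config = small_config(n_true_pairs=3, n_risk_genes=1)
        iset = simulate_interactions(config)
        _, _, truth = simulate_expression(config, iset)
        assert (truth["role"] == "cerna_pair").sum() == 3
        assert (truth["role"] == "risk_gene").sum() == 1


class TestSurvival:
    def test_no_censoring_means_all_events(self):
        config = small_config(censoring_rate=0.0)
        cohort = simulate_cohort(config)
        assert (cohort.clinical["event"] == 1).all()

    def test_censoring_rate_approximately_achieved(self):
        config = small_config(n_samples=4000, censoring_rate=0.3)
        cohort = simulate_cohort(config)
        censored = 1 - cohort.clinical["event"].mean()
        assert censored == pytest.approx(0.3, abs=0.03)

    def test_null_hazards_give_near_zero_cox_coefficient(self):
        config = small_config(
            n_samples=400, n_risk_genes=1, risk_log_hazards=(0.0,), censoring_rate=0.0
        )
        cohort = simulate_cohort(config)
        gene = cohort.truth.loc[cohort.truth["role"] == "risk_gene", "pair_or_gene"].iloc[0]
        expr = cohort.mrna_expression.loc[gene]
        z = (expr - expr.mean()) / expr.std()
        fit = cox_univariate(z, cohort.clinical)
        assert abs(fit.coefficient) < 0.2

    def test_planted_log_hazard_recovered(self):
        config = small_config(
            n_samples=600, risk_log_hazards=(0.7,), censoring_rate=0.0, seed=21
        )
        cohort = simulate_cohort(config)
        gene = cohort.truth.loc[cohort.truth["role"] == "risk_gene", "pair_or_gene"].iloc[0]
        expr = cohort.mrna_expression.loc[gene]
        z = (expr - expr.mean()) / expr.std()
        fit = cox_univariate(z, cohort.clinical)
        assert fit.coefficient == pytest.approx(0.7, abs=0.15)

    def test_missing_risk_gene_is_hard_error(self):
        config = small_config()
        cohort = simulate_cohort(config)
        with pytest.raises(ValueError, match="GHOST"):
            simulate_survival(
                config, cohort.lnc_expression, cohort.mrna_expression, ["GHOST"]
            )


class TestCohortIO:
    def test_write_then_read_round_trips(self, tmp_path):
        cohort = simulate_cohort(small_config())
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c", cohort.config)
        pd.testing.assert_frame_equal(
            back.lnc_expression, cohort.lnc_expression, check_exact=False, atol=1e-9
        )
        pd.testing.assert_frame_equal(
            back.mrna_expression, cohort.mrna_expression, check_exact=False, atol=1e-9
        )
        pd.testing.assert_frame_equal(back.truth, cohort.truth)
        assert sorted(back.interactions.table.itertuples(index=False)) == sorted(
            cohort.interactions.table.itertuples(index=False)
        )

    def test_expression_file_shape(self, tmp_path):
        config = small_config(n_lncrnas=3, n_samples=4, n_true_pairs=1)
        cohort = simulate_cohort(config)
        paths = write_cohort(cohort, tmp_path / "c")
        lines = paths["lnc"].read_text().strip().splitlines()
        assert len(lines) == 1 + 3
        assert all(len(line.split("\t")) == 5 for line in lines)

    def test_empty_truth_round_trips_as_header_only(self, tmp_path):
        config = small_config(n_true_pairs=0, n_risk_genes=0, risk_log_hazards=())
        cohort = simulate_cohort(config)
        paths = write_cohort(cohort, tmp_path / "c")
        assert paths["truth"].read_text().strip() == "pair_or_gene\trole\teffect"
        back = read_cohort(tmp_path / "c", config)
        assert len(back.truth) == 0

    def test_identical_seed_gives_identical_cohort_files(self, tmp_path):
        a = write_cohort(simulate_cohort(small_config()), tmp_path / "a")
        b = write_cohort(simulate_cohort(small_config()), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
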