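"""Synthetic cohort generator: planted structure, determinism, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tilscore import (SynthConfig, TIL_COMPONENTS, cox_univariate,
                      generate_clinical, generate_cohort, generate_counts,
                      generate_marker_map, logrank_test)
from tilscore.synth import ConfigurationError, _draw_counts


def test_marker_map_counts_and_background():
    # 13 cell types x 3 markers on a 770-gene endogenous union
    cfg = SynthConfig(n_endog_a=770, n_endog_b=300, n_common=300,
                      markers_per_type=3, seed=3)
    mmap = generate_marker_map(cfg)
    assigned = [g for genes in mmap.entries.values() for g in genes]
    assert len(assigned) == 39 and len(set(assigned)) == 39  # disjoint
    assert len(set(cfg.endogenous_union) - set(assigned)) == 770 - 39
    # every marker exists in at least one panel
    panel_genes = set(cfg.common_genes) | set(cfg.unique_genes_a) | set(cfg.unique_genes_b)
    assert set(assigned) <= panel_genes


@pytest.mark.parametrize("bad", [0, 1])
def test_degenerate_markers_per_type_rejected(bad):
    with pytest.raises(ConfigurationError):
        SynthConfig(markers_per_type=bad)


def test_marker_capacity_exceeded():
    cfg = SynthConfig(n_endog_a=10, n_endog_b=10, n_common=5, markers_per_type=2)
    with pytest.raises(ConfigurationError):
        generate_marker_map(cfg)


def test_same_seed_identical_outputs(small_config):
    a = generate_cohort(small_config)
    b = generate_cohort(dataclasses.replace(small_config))
    assert a.marker_map.entries == b.marker_map.entries
    pd.testing.assert_frame_equal(a.panel_a.values, b.panel_a.values)
    pd.testing.assert_frame_equal(a.panel_b.values, b.panel_b.values)
    pd.testing.assert_frame_equal(a.clinical, b.clinical)


def test_conservation_of_dimensions(small_cohort, small_config):
    cfg = small_config
    assert small_cohort.panel_a.values.shape == (cfg.n_endog_a + cfg.n_hk_a, cfg.n_samples)
    assert small_cohort.panel_b.values.shape == (cfg.n_endog_b + cfg.n_hk_b, cfg.n_samples)
    common = set(small_cohort.panel_a.gene_names) & set(small_cohort.panel_b.gene_names)
    assert len(common) == cfg.n_common
    assert len(small_cohort.clinical) == cfg.n_samples


def test_noise_free_limit_equal_counts():
    cfg = SynthConfig(n_samples=6, n_endog_a=30, n_endog_b=30, n_common=10,
                      n_hk_a=3, n_hk_b=3, markers_per_type=2, dispersion=0.0,
                      size_factor_sd=0.0, abundance_sd=0.0, seed=7)
    mmap = generate_marker_map(cfg)
    panel_a, _, _ = generate_counts(cfg, mmap)
    for genes in mmap.entries.values():
        present = [g for g in genes if g in set(panel_a.gene_names)]
        for g in present:
            row = panel_a.values.loc[g].to_numpy()
            assert np.all(row == row[0])  # equal up to integer rounding
            assert row[0] == np.rint(cfg.baseline_count)


def test_marker_means_track_abundance(small_cohort, small_config):
    # mean = baseline * 2**abundance * size_factor for every marker gene
    truth = small_cohort.truth
    mu_a = truth.gene_means["A"]
    for cell_type, genes in small_cohort.marker_map.entries.items():
        expected = (small_config.baseline_count
                    * np.exp2(truth.abundance.loc[cell_type])
                    * truth.size_factors)
        for g in genes:
            if g in mu_a.index:
                np.testing.assert_allclose(mu_a.loc[g], expected, rtol=1e-12)


def test_housekeeping_means_independent_of_abundance(small_cohort):
    truth = small_cohort.truth
    for g in small_cohort.panel_a.housekeeping_genes:
        mu = truth.gene_means["A"].loc[g] / truth.size_factors
        assert np.allclose(mu, mu.iloc[0])


def test_count_noise_matches_generative_mean(rng):
    # Monte-Carlo: replicate draws around a fixed mean land within 3 SE
    mu = np.array([5.0, 50.0, 500.0])
    d = 0.1
    n_rep = 2000
    draws = np.array([_draw_counts(rng, mu, d) for _ in range(n_rep)])
    se = np.sqrt((mu + d * mu ** 2) / n_rep)
    assert np.all(np.abs(draws.mean(axis=0) - mu) < 3 * se)


def test_planted_negative_effect_shortens_low_score_times():
    cfg = SynthConfig(n_samples=400, n_endog_a=30, n_endog_b=30, n_common=10,
                      n_hk_a=3, n_hk_b=3, markers_per_type=2,
                      effect_map=(("mast_cells:TIL", -1.0, "metastasis"),),
                      censor_rate=0.0, seed=21)
    cohort = generate_cohort(cfg)
    score = cohort.truth.score("mast_cells:TIL")
    low = score < score.median()
    times = cohort.clinical.set_index("sample")["time_metastasis"]
    assert times[low.values].mean() < times[~low.values].mean()


def test_cox_recovers_planted_coefficient_from_truth():
    # oracle = the generative model itself: fitted beta near the planted -1
    betas = []
    for seed in range(50):
        cfg = SynthConfig(n_samples=200, n_endog_a=30, n_endog_b=30, n_common=10,
                          n_hk_a=3, n_hk_b=3, markers_per_type=2,
                          effect_map=(("mast_cells:TIL", -1.0, "metastasis"),),
                          censor_rate=0.3, seed=seed)
        cohort = generate_cohort(cfg)
        score = cohort.truth.score("mast_cells:TIL")
        cl = cohort.clinical.set_index("sample")
        beta, _, _, _ = cox_univariate(cl["time_metastasis"].to_numpy(),
                                       cl["event_metastasis"].to_numpy(),
                                       score.to_numpy())
        betas.append(beta)
    assert abs(np.mean(betas) - (-1.0)) < 0.25


def test_null_logrank_pvalues_uniform():
    # no planted effects: median-split log-rank p ~ Uniform(0, 1)
    pvals = []
    for seed in range(200):
        cfg = SynthConfig(n_samples=40, n_endog_a=30, n_endog_b=30, n_common=10,
                          n_hk_a=3, n_hk_b=3, markers_per_type=2,
                          effect_map=(), censor_rate=0.2, seed=seed)
        cohort = generate_cohort(cfg)
        score = cohort.truth.score("mast_cells:TIL")
        group = (score > score.median()).astype(int).to_numpy()
        cl = cohort.clinical.set_index("sample")
        _, p = logrank_test(cl["time_bcr"].to_numpy(),
                            cl["event_bcr"].to_numpy(), group)
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_censor_rate_calibrated():
    cfg = SynthConfig(n_samples=3000, n_endog_a=30, n_endog_b=30, n_common=10,
                      n_hk_a=3, n_hk_b=3, markers_per_type=2,
                      effect_map=(("mast_cells:TIL", -1.0, "metastasis"),),
                      censor_rate=0.3, seed=5)
    cohort = generate_cohort(cfg)
    censored_frac = 1.0 - cohort.clinical["event_metastasis"].mean()
    assert abs(censored_frac - 0.3) < 0.03


def test_negative_baseline_hazard_rejected():
    with pytest.raises(ConfigurationError):
        SynthConfig(baseline_hazard=-0.1)


def test_qc_failure_planting():
    cfg = SynthConfig(n_samples=12, n_endog_a=30, n_endog_b=30, n_common=10,
                      n_hk_a=3, n_hk_b=3, markers_per_type=2, n_qc_fail=2, seed=9)
    cohort = generate_cohort(cfg)
    totals = cohort.panel_a.values.sum(axis=0).sort_values()
    # the two planted failures are orders of magnitude below the rest
    assert totals.iloc[1] < totals.iloc[2] / 100
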