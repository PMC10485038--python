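"""Synthetic cohort generator: calibration, missingness, outcomes."""

import numpy as np
import pandas as pd
import pytest

from sgasnf import (CohortConfig, ConfigurationError, generate_cohort,
                    generate_outcomes, inject_missingness, read_cohort,
                    write_cohort)
from sgasnf.cohort import DEFAULT_MISSING_RATES, FeatureSpec, default_features

from conftest import two_cluster_config


def test_reproducibility_bit_identical():
    cfg = CohortConfig(n_patients=100, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert np.array_equal(a.true_labels, b.true_labels)
    for dom in a.blocks:
        pd.testing.assert_frame_equal(a.blocks[dom].values, b.blocks[dom].values)
    pd.testing.assert_frame_equal(a.outcomes.data, b.outcomes.data)


def test_cluster_sizes_match_fractions_in_expectation():
    # fractions 216/574, 358/574 -> sizes near 216/358 for n=574
    cfg = CohortConfig(n_patients=574, seed=1)
    cohort = generate_cohort(cfg)
    sizes = np.bincount(cohort.true_labels)[1:]
    assert sizes.sum() == 574
    for size, frac in zip(sizes, cfg.cluster_fractions):
        se = np.sqrt(574 * frac * (1 - frac))
        assert abs(size - 574 * frac) < 3 * se


def test_per_cluster_means_match_configuration():
    # oracle: direct group-wise means of the generated matrix
    cfg = two_cluster_config(n=200, gap_sd=3.0, n_features=5, seed=7)
    cohort = generate_cohort(cfg)
    labels = cohort.true_labels
    for dom, block in cohort.blocks.items():
        X = block.values.to_numpy()
        for c, target in ((1, 0.0), (2, 3.0)):
            means = X[labels == c].mean(axis=0)
            tol = 3.0 / np.sqrt((labels == c).sum())
            assert np.all(np.abs(means - target) < 3 * tol + 1e-9)


def test_lognormal_features_match_on_log_scale():
    cfg = CohortConfig(n_patients=2000, seed=3)
    cohort = generate_cohort(cfg)
    spec = next(s for s in cfg.features if s.name == "sflt1_plgf_ratio")
    x = cohort.blocks["clinical"].values["sflt1_plgf_ratio"].to_numpy()
    for c in (1, 2):
        sel = cohort.true_labels == c
        lx = np.log(x[sel])
        se = spec.scale[c - 1] / np.sqrt(sel.sum())
        assert abs(lx.mean() - np.log(spec.loc[c - 1])) < 4 * se


def test_no_signal_config_gives_null_clustering():
    from sklearn.metrics import adjusted_rand_score
    from sgasnf import SNFusion, spectral_cluster, prepare_cohort
    cfg = two_cluster_config(n=90, gap_sd=0.0, seed=5)
    cohort = generate_cohort(cfg)
    _, std = prepare_cohort(cohort, seed=5)
    fused = SNFusion(K=10, T=10).fit(std).fused_affinity_
    assign = spectral_cluster(fused, 2, seed=5)
    assert abs(adjusted_rand_score(cohort.true_labels, assign.labels)) < 0.1


@pytest.mark.parametrize("bad", [
    dict(n_patients=0),
    dict(cluster_fractions=(0.5, 0.4)),
    dict(within_domain_correlation=1.0),
    dict(missing_rates={"clinical": 1.0}),
    dict(outcome_profile={"preeclampsia": (1.2, 0.1)}),
    dict(interval_scales=(4.0, -1.0)),
])
def test_invalid_configuration_rejected(bad):
    with pytest.raises(ConfigurationError):
        generate_cohort(CohortConfig(**bad))


def test_feature_spec_rejects_nonpositive_sd():
    with pytest.raises(ConfigurationError):
        FeatureSpec("x", "clinical", (0.0, 1.0), (1.0, 0.0))


class TestMissingness:
    def test_default_rates_hit_expected_patient_counts(self):
        cfg = CohortConfig(n_patients=574, seed=9)
        cohort = inject_missingness(generate_cohort(cfg), cfg.missing_rates,
                                    seed=10, features=cfg.features)
        # expected affected patient-rows: 66, 24, 181, 181
        expected = {"clinical": 66, "ultrasound": 24,
                    "cord_metabolomics": 181, "maternal_metabolomics": 181}
        for dom, block in cohort.blocks.items():
            rows_hit = int((~block.mask).any(axis=1).sum())
            rate = DEFAULT_MISSING_RATES[dom]
            sd = np.sqrt(574 * rate * (1 - rate))
            assert abs(rows_hit - expected[dom]) < 3 * sd

    def test_rate_zero_leaves_block_unchanged(self, small_cohort):
        cfg = CohortConfig(n_patients=60, seed=2)
        cohort = generate_cohort(cfg)
        out = inject_missingness(cohort, {d: 0.0 for d in cohort.blocks}, seed=3)
        for dom in cohort.blocks:
            assert out.blocks[dom].mask.all()
            pd.testing.assert_frame_equal(out.blocks[dom].values,
                                          cohort.blocks[dom].values)

    def test_mask_deterministic_given_seed(self):
        # oracle: an independent re-draw with the same seed
        cfg = two_cluster_config(n=100, n_features=10, seed=4)
        cohort = generate_cohort(cfg)
        rates = {d: 0.5 for d in cohort.blocks}
        a = inject_missingness(cohort, rates, seed=3, features=cfg.features)
        b = inject_missingness(cohort, rates, seed=3, features=cfg.features)
        for dom in a.blocks:
            assert np.array_equal(a.blocks[dom].mask, b.blocks[dom].mask)
        n_masked = sum((~a.blocks[d].mask).sum() for d in a.blocks)
        assert n_masked > 0

    def test_rate_one_rejected(self):
        cfg = CohortConfig(n_patients=50, seed=1)
        cohort = generate_cohort(cfg)
        with pytest.raises(ConfigurationError):
            inject_missingness(cohort, {"clinical": 1.0}, seed=0)

    def test_complete_blocks_retained(self, small_cohort):
        assert small_cohort.complete_blocks is not None
        for dom, block in small_cohort.complete_blocks.items():
            assert block.mask.all()

    def test_always_observed_features_stay_complete(self, small_cohort):
        clin = small_cohort.blocks["clinical"]
        for name in ("gestational_age_dx", "sflt1_plgf_ratio"):
            assert not clin.values[name].isna().any()


class TestOutcomes:
    def test_cluster_rates_match_profile(self):
        # cluster probabilities 0.551 / 0.0896 at sizes 216/358 -> ~119/32
        labels = np.repeat([1, 2], [216, 358])
        ot = generate_outcomes(labels, {"preeclampsia": (0.551, 0.0896)},
                               (4.0, 42.0), seed=21)
        y = ot.binary("preeclampsia")
        for c, p, n_c, expect in ((1, 0.551, 216, 119), (2, 0.0896, 358, 32)):
            count = y[labels == c].sum()
            sd = np.sqrt(n_c * p * (1 - p))
            assert abs(count - expect) < 3 * sd

    def test_zero_probability_means_no_events(self):
        labels = np.repeat([1, 2], [30, 30])
        ot = generate_outcomes(labels, {"apo": (0.0, 0.0)}, (4.0, 4.0), seed=0)
        assert ot.binary("apo").sum() == 0

    def test_event_count_within_binomial_error_of_independent_redraw(self):
        # oracle: independent Bernoulli simulation at the same probability
        labels = np.ones(1000, dtype=int)
        ot = generate_outcomes(labels, {"apo": (0.3,)}, (4.0,), seed=11)
        count = ot.binary("apo").sum()
        sd = np.sqrt(1000 * 0.3 * 0.7)
        assert abs(count - 300) < 3 * sd
        redraw = (np.random.default_rng(999).random(1000) < 0.3).sum()
        assert abs(count - redraw) < 6 * sd

    def test_interval_scales_and_event_indicator(self):
        labels = np.repeat([1, 2], [400, 400])
        ot = generate_outcomes(labels, {}, (4.0, 42.0), seed=5)
        t = ot.data["interval_weeks"].to_numpy()
        assert (ot.data["event"] == 1).all()
        assert abs(t[labels == 1].mean() - 4.0) < 3 * 4.0 / np.sqrt(400)
        assert abs(t[labels == 2].mean() - 42.0) < 3 * 42.0 / np.sqrt(400)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_outcomes(np.array([1, 2]), {"apo": (1.5, 0.0)},
                              (4.0, 42.0), seed=0)


def test_cohort_tsv_roundtrip(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path)
    back = read_cohort(tmp_path)
    assert back.patient_ids == small_cohort.patient_ids
    assert np.array_equal(back.true_labels, small_cohort.true_labels)
    for dom in small_cohort.blocks:
        pd.testing.assert_frame_equal(
            back.blocks[dom].values, small_cohort.blocks[dom].values,
            check_exact=False, rtol=1e-12)
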