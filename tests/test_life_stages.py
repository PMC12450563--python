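import math

import numpy as np
import pytest
from scipy import stats

from popshape.life_stages import (
    GammaFit,
    ReproductionProfile,
    bucket_boundaries,
    estimate_afr,
    fit_gamma,
    reproduction_profile,
    senescence_onset,
)
from popshape.studbook_io import SpeciesConfig

from conftest import record, studbook


def onset_oracle(k, theta, frac=0.75, step=0.001):
    """Dense-grid search for the right-tail crossing, independent of the
    root-finding implementation under test."""
    mode = (k - 1) * theta if k > 1 else 0.0
    peak = stats.gamma.pdf(max(mode, 1e-12), k, scale=theta)
    x = max(mode, step)
    while stats.gamma.pdf(x, k, scale=theta) > frac * peak:
        x += step
    return math.ceil(x)


class TestEstimateAfr:
    def test_floored_minimum_parent_age(self):
        recs = [
            record("F1", birth="1990-01-01"),
            record("F2", birth="1991-01-01"),
            record("K1", birth="1993-03-15", dam="F1"),   # F1 aged 3.2
            record("K2", birth="1995-02-07", dam="F2"),   # F2 aged 4.1
            record("K3", birth="1998-01-01", dam="F1"),   # later birth
        ]
        assert estimate_afr(studbook(recs), "female") == 3

    def test_override_wins_over_data(self):
        recs = [record("F1", birth="1990-01-01"),
                record("K1", birth="1993-03-15", dam="F1")]
        sb = studbook(recs, afr_override={"female": 4})
        assert estimate_afr(sb, "female") == 4

    def test_no_links_and_no_override_raises(self):
        with pytest.raises(ValueError, match="afr_override"):
            estimate_afr(studbook([record("F1")]), "female")


class TestReproductionProfile:
    def test_direct_ratio_when_all_alive(self):
        recs = [record(f"F{i}", birth="1990-06-01", death="2005-06-01")
                for i in range(10)]
        for i in range(10):
            # everyone proves breeding at age 2; four breed again at age 5
            recs.append(record(f"A{i}", birth="1992-08-01", dam=f"F{i}"))
        for i in range(4):
            recs.append(record(f"B{i}", birth="1995-08-01", dam=f"F{i}"))
        profile = reproduction_profile(studbook(recs), "female")
        assert profile.n_breeders == 10
        assert profile.probabilities[list(profile.ages).index(5)] == 0.4

    def test_dead_breeders_leave_the_denominator(self):
        # five breeders prove at age 3; two die before age 8; of the three
        # alive at 8, two reproduce there -> p(8) = 2/3
        recs = []
        for i in range(5):
            death = "1997-06-01" if i < 2 else "2005-06-01"
            recs.append(record(f"F{i}", birth="1990-01-01", death=death))
            recs.append(record(f"A{i}", birth="1993-06-01", dam=f"F{i}"))
        for i in (2, 3):
            recs.append(record(f"B{i}", birth="1998-06-01", dam=f"F{i}"))
        profile = reproduction_profile(studbook(recs), "female")
        idx = list(profile.ages).index(8)
        assert profile.probabilities[idx] == pytest.approx(2 / 3)

    def test_single_breeder_gives_unit_probabilities(self):
        recs = [
            record("F1", birth="1990-01-01", death="2000-01-01"),
            record("A", birth="1993-06-01", dam="F1"),
            record("B", birth="1994-06-01", dam="F1"),
        ]
        profile = reproduction_profile(studbook(recs), "female")
        ages = list(profile.ages)
        assert profile.probabilities[ages.index(3)] == 1.0
        assert profile.probabilities[ages.index(4)] == 1.0

    def test_no_breeders_raises(self):
        with pytest.raises(ValueError, match="breeder"):
            reproduction_profile(studbook([record("F1")]), "female")


class TestFitGamma:
    def test_exact_profile_recovers_parameters_within_one_percent(self):
        ages = np.arange(25)
        k, theta, amp = 4.0, 2.0, 0.8
        probs = amp * stats.gamma.pdf(ages + 0.5, k, scale=theta)
        fit = fit_gamma(ReproductionProfile("female", ages, probs, 100))
        assert fit.shape == pytest.approx(k, rel=0.01)
        assert fit.scale == pytest.approx(theta, rel=0.01)
        assert fit.amplitude == pytest.approx(amp, rel=0.01)
        assert fit.rss < 1e-10

    def test_noisy_profile_recovers_the_mode(self, rng):
        ages = np.arange(30)
        k, theta = 5.0, 1.8
        peak = stats.gamma.pdf((k - 1) * theta, k, scale=theta)
        truth = (0.5 / peak) * stats.gamma.pdf(ages + 0.5, k, scale=theta)
        probs = np.clip(truth + rng.normal(0, 0.02, ages.size), 0, 1)
        fit = fit_gamma(ReproductionProfile("female", ages, probs, 2000))
        assert fit.mode == pytest.approx(4.0 * 1.8, abs=0.5)

    def test_all_zero_profile_raises(self):
        profile = ReproductionProfile(
            "female", np.arange(10), np.zeros(10), 5
        )
        with pytest.raises(ValueError, match="manual"):
            fit_gamma(profile)


class TestSenescenceOnset:
    def test_exponential_closed_form(self):
        # k=1, theta=4: crossing at 4*ln(4/3) ~ 1.151 -> class 2
        fit = GammaFit(shape=1.0, scale=4.0, amplitude=1.0, rss=0.0)
        assert senescence_onset(fit) == 2

    @pytest.mark.parametrize("k,theta", [(2, 3), (4, 2), (8, 1.5)])
    def test_matches_dense_grid_oracle(self, k, theta):
        fit = GammaFit(shape=k, scale=theta, amplitude=0.7, rss=0.0)
        assert senescence_onset(fit) == onset_oracle(k, theta)

    def test_unit_tail_fraction_gives_ceiling_of_mode(self):
        fit = GammaFit(shape=4.0, scale=2.0, amplitude=1.0, rss=0.0)
        config = SpeciesConfig(gamma_tail_fraction=1.0)
        assert senescence_onset(fit, config) == 6

    def test_smaller_tail_fraction_means_later_onset(self):
        fit = GammaFit(shape=4.0, scale=2.0, amplitude=1.0, rss=0.0)
        onsets = [
            senescence_onset(fit, SpeciesConfig(gamma_tail_fraction=f))
            for f in (0.9, 0.75, 0.5, 0.25)
        ]
        assert onsets == sorted(onsets)

    def test_override_wins(self):
        fit = GammaFit(shape=4.0, scale=2.0, amplitude=1.0, rss=0.0)
        config = SpeciesConfig(senescence_override={"female": 12})
        assert senescence_onset(fit, config, sex="female") == 12


class TestBucketBoundaries:
    def test_divisible_adult_span(self):
        t = bucket_boundaries(4, 13, 20)
        assert t.bucket_ranges == ((0, 4), (4, 7), (7, 10), (10, 13), (13, 21))

    def test_remainder_goes_to_the_lower_blocks(self):
        t = bucket_boundaries(2, 6, 10)
        assert t.bucket_ranges[1:4] == ((2, 4), (4, 5), (5, 6))

    def test_adult_span_below_three_is_an_error(self):
        with pytest.raises(ValueError, match="three"):
            bucket_boundaries(5, 7, 20)

    @pytest.mark.parametrize("afr,onset,longevity", [
        (1, 4, 8), (2, 6, 15), (3, 10, 20), (5, 15, 40), (4, 8, 8),
    ])
    def test_ranges_partition_all_age_classes(self, afr, onset, longevity):
        t = bucket_boundaries(afr, onset, longevity)
        widths = [hi - lo for lo, hi in t.bucket_ranges]
        assert sum(widths) == longevity + 1
        assert t.bucket_ranges[0][0] == 0
        assert t.bucket_ranges[-1][1] == longevity + 1
        for (_, hi), (lo, _) in zip(t.bucket_ranges, t.bucket_ranges[1:]):
            assert hi == lo

    def test_age_group_labels_follow_the_thresholds(self):
        t = bucket_boundaries(3, 10, 20)
        assert t.age_group(2) == "juvenile"
        assert t.age_group(3) == "adult"
        assert t.age_group(9) == "adult"
        assert t.age_group(10) == "senior"


class TestPipelineRecovery:
    def test_simulated_studbook_recovers_the_senescence_onset(
        self, steady_small
    ):
        sb, truth = steady_small
        profile = reproduction_profile(sb, "female")
        fit = fit_gamma(profile)
        onset = senescence_onset(fit, sb.species)
        assert abs(onset - truth.senescence_onset) <= 1
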