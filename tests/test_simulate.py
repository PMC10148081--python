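import math

import numpy as np
import pytest
from scipy.stats import binom, chisquare

from pccsort.simulate import (
    ALPHA_MISSING,
    ALPHA_PRESENT,
    BindingModel,
    ErrorModel,
    apply_classification_error,
    sample_true_occupancy,
    truth_formula_counts,
)

# ------------------------------------------------------------- validation


def test_independent_model_validates_probability():
    with pytest.raises(ValueError):
        BindingModel.independent(1.5)
    with pytest.raises(ValueError):
        BindingModel.independent(-0.1)


def test_explicit_model_validates_weights():
    with pytest.raises(ValueError):
        BindingModel.explicit([0.5, 0.5])  # wrong length
    with pytest.raises(ValueError):
        BindingModel.explicit([0.5, 0.5, 0.5, 0, 0, 0, 0])  # not normalized
    with pytest.raises(ValueError):
        BindingModel.explicit([1.5, -0.5, 0, 0, 0, 0, 0])  # negative


def test_error_model_validates_range():
    with pytest.raises(ValueError):
        ErrorModel(eps_fn=1.0)
    with pytest.raises(ValueError):
        ErrorModel(eps_fp=-0.01)


def test_zero_particles_rejected():
    with pytest.raises(ValueError):
        sample_true_occupancy(BindingModel.independent(0.5), 0, seed=1)


# ------------------------------------------------------------- boundaries


def test_p_one_gives_all_occupied():
    truth = sample_true_occupancy(BindingModel.independent(1.0), 100, seed=3)
    assert all(gt.true_config.n_alpha == 6 for gt in truth)


def test_p_zero_gives_all_empty():
    truth = sample_true_occupancy(BindingModel.independent(0.0), 100, seed=3)
    assert all(gt.true_config.n_alpha == 0 for gt in truth)


def test_particle_ids_contiguous():
    truth = sample_true_occupancy(BindingModel.independent(0.5), 50, seed=0)
    assert [gt.particle_id for gt in truth] == list(range(50))


# ------------------------------------------------------------- distributions


def test_half_occupancy_matches_binomial_mode():
    # oracle: P(n_alpha = 3 | p = 0.5) = C(6,3)/64 = 0.3125 exactly
    n = 60_000
    truth = sample_true_occupancy(BindingModel.independent(0.5), n, seed=1)
    frac = sum(gt.true_config.n_alpha == 3 for gt in truth) / n
    expected = 0.3125
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) < 3 * se


@pytest.mark.parametrize("p", [0.3, 0.5, 0.8])
@pytest.mark.parametrize("seed", [11, 22, 33])
def test_formula_counts_fit_binomial(p, seed):
    # chi-square GOF against the closed-form Binomial(6, p) pmf
    n = 50_000
    truth = sample_true_occupancy(BindingModel.independent(p), n, seed=seed)
    observed = truth_formula_counts(truth)
    expected = binom.pmf(np.arange(7), 6, p) * n
    stat, pvalue = chisquare(observed, expected)
    assert pvalue > 0.01


def test_explicit_mode_respects_degenerate_weights():
    weights = [0, 0, 0, 0, 1.0, 0, 0]
    truth = sample_true_occupancy(BindingModel.explicit(weights), 500, seed=2)
    assert all(gt.true_config.n_alpha == 4 for gt in truth)


def test_explicit_mode_uniform_within_formula():
    # all 15 two-occupied patterns should appear about equally often
    weights = [0, 0, 1.0, 0, 0, 0, 0]
    n = 30_000
    truth = sample_true_occupancy(BindingModel.explicit(weights), n, seed=4)
    counts: dict[str, int] = {}
    for gt in truth:
        counts[gt.true_config.as_string()] = counts.get(gt.true_config.as_string(), 0) + 1
    assert len(counts) == 15
    stat, pvalue = chisquare(list(counts.values()))
    assert pvalue > 0.01


def test_explicit_mode_mixture_matches_weights():
    weights = [0.1, 0, 0.2, 0, 0, 0.3, 0.4]
    n = 50_000
    truth = sample_true_occupancy(BindingModel.explicit(weights), n, seed=5)
    observed = truth_formula_counts(truth)
    stat, pvalue = chisquare(observed[np.array(weights) > 0],
                             np.array(weights)[np.array(weights) > 0] * n)
    assert pvalue > 0.01
    assert observed[[1, 3, 4]].sum() == 0


# ------------------------------------------------------------- expansion


def test_record_cardinality_and_copy_indices():
    truth = sample_true_occupancy(BindingModel.independent(0.5), 200, seed=6)
    records = apply_classification_error(truth, ErrorModel(), seed=7)
    assert len(records) == 6 * 200
    by_pid: dict[int, set[int]] = {}
    for rec in records:
        by_pid.setdefault(rec.particle_id, set()).add(rec.copy_index)
    assert all(v == set(range(6)) for v in by_pid.values())


def test_noiseless_round_trip_is_exact():
    truth = sample_true_occupancy(BindingModel.independent(0.5), 500, seed=8)
    records = apply_classification_error(truth, ErrorModel(), seed=9)
    by_pid = {gt.particle_id: gt.true_config for gt in truth}
    for rec in records:
        expected = by_pid[rec.particle_id].bits[rec.copy_index]
        assert (rec.class_label == ALPHA_PRESENT) == expected


def test_total_false_negative_flips_everything():
    truth = sample_true_occupancy(BindingModel.independent(1.0), 50, seed=10)
    records = apply_classification_error(truth, ErrorModel(eps_fn=0.999999), seed=11)
    # eps_fn < 1 by contract, but at 1 - 1e-6 essentially every label flips
    assert sum(r.class_label == ALPHA_MISSING for r in records) == len(records)


def test_false_negative_rate_matches_binomial_oracle():
    # oracle: P(zero missing labels | all 6 occupied, eps_fn=0.1) = 0.9^6
    n = 50_000
    truth = sample_true_occupancy(BindingModel.independent(1.0), n, seed=12)
    records = apply_classification_error(truth, ErrorModel(eps_fn=0.1), seed=13)
    missing_per_pid = [0] * n
    for rec in records:
        missing_per_pid[rec.particle_id] += rec.class_label == ALPHA_MISSING
    frac_clean = sum(k == 0 for k in missing_per_pid) / n
    expected = 0.9**6  # = 0.531441
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(frac_clean - expected) < 3 * se


# ------------------------------------------------------------- determinism


def test_seed_determinism():
    model = BindingModel.independent(0.7)
    a = sample_true_occupancy(model, 300, seed=42)
    b = sample_true_occupancy(model, 300, seed=42)
    assert a == b
    ra = apply_classification_error(a, ErrorModel(eps_fn=0.2, eps_fp=0.1), seed=5)
    rb = apply_classification_error(b, ErrorModel(eps_fn=0.2, eps_fp=0.1), seed=5)
    assert ra == rb
    rc = apply_classification_error(a, ErrorModel(eps_fn=0.2, eps_fp=0.1), seed=6)
    assert ra != rc
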