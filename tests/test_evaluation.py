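"""Concordance index against exhaustive pair enumeration and an
independent library, risk-group construction, relative-hazard curves,
bootstrap bands, and weight-transport validation."""

import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import concordance_index_censored

from coxladder import (
    FPSpec,
    PrognosticModel,
    bootstrap_band,
    derivation_config,
    generate_cohort,
    generate_validation_cohort,
    harrell_c,
    make_risk_groups,
    prognostic_index,
    relative_hazard_curve,
    transport_validate,
    validation_config,
)
from coxladder.evaluation import fit_univariable_fp
from coxladder.pipeline import fit_model_class
from coxladder.synthetic_data import EffectSpec


def brute_force_c(pred, time, event):
    """Independent double loop over all pairs, straight from the
    definition: evaluable iff times differ and the shorter time is an
    event; concordant iff the shorter-lived has higher predicted
    hazard; prediction ties count one half."""
    n = len(pred)
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            s, l = (i, j) if time[i] < time[j] else (j, i)
            if not event[s]:
                continue
            den += 1
            if pred[s] > pred[l]:
                num += 1
            elif pred[s] == pred[l]:
                num += 0.5
    return None if den == 0 else num / den, int(den)


def random_small_cohort(rng):
    n = rng.integers(5, 51)
    time = np.round(rng.exponential(5, n), 1)  # rounding injects time ties
    event = (rng.random(n) < 0.6).astype(int)
    pred = rng.choice([0.1, 0.5, 0.9, 1.5], n)  # heavy prediction ties
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return pred, time, event


def test_constant_predictions_give_exactly_half(small_cohort):
    res = harrell_c(np.ones(len(small_cohort)), small_cohort["time_years"],
                    small_cohort["event"])
    assert res.c == 0.5
    assert res.n_tied_prediction_pairs == res.n_evaluable_pairs


def test_reverse_ranked_uncensored_is_perfect():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    res = harrell_c(-t, t, np.ones(6, dtype=int))
    assert res.c == 1.0
    assert res.n_evaluable_pairs == 15


def test_matches_brute_force_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(30):
        pred, time, event = random_small_cohort(rng)
        expected, n_pairs = brute_force_c(pred, time, event)
        res = harrell_c(pred, time, event)
        assert res.c == pytest.approx(expected, abs=1e-12)
        assert res.n_evaluable_pairs == n_pairs


def test_matches_scikit_survival(small_cohort):
    t = small_cohort["time_years"].to_numpy()
    d = small_cohort["event"].to_numpy().astype(bool)
    pred = np.sqrt(small_cohort["tumor_size_mm"].to_numpy())
    res = harrell_c(pred, t, d)
    y = np.array(list(zip(d, t)), dtype=[("e", bool), ("t", float)])
    sk = concordance_index_censored(d, t, pred)[0]
    assert res.c == pytest.approx(sk, abs=1e-12)


def test_invariant_under_monotone_transform(small_cohort):
    t, d = small_cohort["time_years"], small_cohort["event"]
    pred = small_cohort["n_pos_nodes"].to_numpy().astype(float)
    a = harrell_c(pred, t, d)
    b = harrell_c(np.exp(2.0 * pred + 1.0), t, d)
    assert a.c == b.c


def test_negated_predictions_complement():
    rng = np.random.default_rng(3)
    t = rng.exponential(5, 40)
    d = (rng.random(40) < 0.7).astype(int)
    pred = rng.normal(size=40)  # continuous: no prediction ties
    a = harrell_c(pred, t, d)
    b = harrell_c(-pred, t, d)
    assert a.c + b.c == pytest.approx(1.0, abs=1e-12)


def test_no_events_rejected():
    with pytest.raises(ValueError):
        harrell_c([1.0, 2.0], [1.0, 2.0], [0, 0])


# ---------------------------------------------------------------------------
# prognostic index and relative-hazard curves

def _sqrt_size_model(weight=0.35):
    return PrognosticModel(
        transforms={"tumor_size_mm": FPSpec("tumor_size_mm", (0.5,))},
        weights=np.array([weight]))


def test_reference_patient_has_relative_hazard_one(small_cohort):
    model = fit_model_class("fp", small_cohort)
    ref = pd.DataFrame(
        {"age_years": [35.0], "tumor_size_mm": [20.0], "n_pos_nodes": [0]})
    assert model.relative_hazard(ref)[0] == pytest.approx(1.0, abs=1e-12)


def test_zero_weights_give_zero_pi(small_cohort):
    model = _sqrt_size_model(weight=0.0)
    np.testing.assert_array_equal(
        prognostic_index(model, small_cohort), 0.0)


def test_pi_centering_does_not_change_c(small_cohort):
    model = _sqrt_size_model()
    pi = prognostic_index(model, small_cohort)
    t, d = small_cohort["time_years"], small_cohort["event"]
    assert harrell_c(pi, t, d).c == harrell_c(pi + 17.3, t, d).c


def test_curve_passes_through_one_at_reference():
    curve = relative_hazard_curve(_sqrt_size_model(), "tumor_size_mm",
                                  np.array([5.0, 20.0, 60.0]))
    assert curve["relative_hazard"].iloc[1] == pytest.approx(1.0, abs=1e-12)


def test_curve_closed_form_sqrt_weights():
    w = 0.35
    grid = np.array([4.0, 9.0, 25.0])
    curve = relative_hazard_curve(_sqrt_size_model(w), "tumor_size_mm", grid)
    np.testing.assert_allclose(
        curve["relative_hazard"],
        np.exp(w * (np.sqrt(grid) - np.sqrt(20.0))), rtol=1e-12)


def test_curve_linear_unit_weight_closed_form():
    model = PrognosticModel(
        transforms={"age_years": FPSpec("age_years", (1.0,))},
        weights=np.array([1.0]))
    grid = np.array([30.0, 35.0, 40.0])
    curve = relative_hazard_curve(model, "age_years", grid)
    np.testing.assert_allclose(curve["relative_hazard"],
                               np.exp(grid - 35.0), rtol=1e-12)


def test_curve_rejects_empty_grid():
    with pytest.raises(ValueError):
        relative_hazard_curve(_sqrt_size_model(), "tumor_size_mm", [])


# ---------------------------------------------------------------------------
# bootstrap band

@pytest.fixture(scope="module")
def band_cohort():
    return generate_cohort(derivation_config(n_patients=500, seed=31))


def test_band_contains_one_at_reference(band_cohort):
    grid = np.array([10.0, 20.0, 40.0])
    band = bootstrap_band(band_cohort, "tumor_size_mm", grid, B=40, seed=9)
    at_ref = band.loc[band["tumor_size_mm"] == 20.0]
    assert at_ref["lower"].iloc[0] <= 1.0 <= at_ref["upper"].iloc[0]


def test_band_deterministic_given_seed(band_cohort):
    grid = np.array([10.0, 30.0])
    a = bootstrap_band(band_cohort, "tumor_size_mm", grid, B=25, seed=4)
    b = bootstrap_band(band_cohort, "tumor_size_mm", grid, B=25, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_band_covers_null_curve_without_effect():
    """No true size effect: the band should cover relative hazard 1
    at (nearly) all grid points."""
    cfg = derivation_config(
        n_patients=500, seed=17, size_effect=EffectSpec(0.0, "sqrt"))
    coh = generate_cohort(cfg)
    grid = np.array([8.0, 15.0, 22.0, 30.0, 45.0])
    band = bootstrap_band(coh, "tumor_size_mm", grid, B=60, seed=2)
    covered = ((band["lower"] <= 1.0) & (1.0 <= band["upper"])).mean()
    assert covered >= 0.8


def test_band_rejects_tiny_b(band_cohort):
    with pytest.raises(ValueError):
        bootstrap_band(band_cohort, "tumor_size_mm", [20.0], B=1, seed=0)


# ---------------------------------------------------------------------------
# risk groups

def test_continuous_pi_achieves_requested_fractions():
    rng = np.random.default_rng(0)
    pi = rng.normal(size=20000)
    g = make_risk_groups(pi)
    np.testing.assert_allclose(g.achieved_percentiles, (16.0, 50.0, 84.0),
                               atol=0.1)
    fracs = np.bincount(g.assign(pi), minlength=4) / pi.size
    np.testing.assert_allclose(fracs, [0.16, 0.34, 0.34, 0.16], atol=0.005)


def test_cutoffs_never_split_tied_pi():
    """With a PI taking 4 distinct values in lumps, every lump must land
    wholly in one group."""
    pi = np.repeat([0.0, 1.0, 2.0, 3.0], [10, 40, 40, 10])
    g = make_risk_groups(pi)
    groups = g.assign(pi)
    for v in np.unique(pi):
        assert np.unique(groups[pi == v]).size == 1


def test_heavily_tied_pi_reports_achieved_percentiles(small_cohort):
    model = fit_model_class("dichotomized", small_cohort)
    pi = prognostic_index(model, small_cohort)
    g = make_risk_groups(pi)
    assert g.achieved_percentiles != g.requested_percentiles


def test_identical_pi_rejected():
    with pytest.raises(ValueError):
        make_risk_groups(np.ones(100))


def test_bad_percentiles_rejected():
    with pytest.raises(ValueError):
        make_risk_groups(np.arange(100.0), percentiles=(50.0, 16.0, 84.0))


# ---------------------------------------------------------------------------
# transport validation

def test_transport_identity_reproduces_derivation_c(small_cohort):
    model = fit_model_class("fp", small_cohort)
    pi = prognostic_index(model, small_cohort)
    grouping = make_risk_groups(pi)
    rep = transport_validate(model, grouping, small_cohort)
    assert rep.c_index.c == harrell_c(pi, small_cohort["time_years"],
                                      small_cohort["event"]).c
    assert rep.n_patients == len(small_cohort)


def test_transport_shifted_validation_reshapes_groups():
    deriv = generate_cohort(derivation_config(n_patients=2500, seed=19))
    valid = generate_validation_cohort(validation_config(n_patients=1200,
                                                         seed=19))
    model = fit_model_class("fp", deriv)
    grouping = make_risk_groups(prognostic_index(model, deriv))
    rep = transport_validate(model, grouping, valid)
    assert rep.group_fractions["G1"] > 0.16
    assert rep.group_fractions["G4"] < 0.16


def test_transport_group_hazard_ratios_ordered():
    """Monotone-risk truth: HRs of G2, G3, G4 versus G1 must increase."""
    deriv = generate_cohort(derivation_config(n_patients=3000, seed=23))
    model = fit_model_class("fp", deriv)
    grouping = make_risk_groups(prognostic_index(model, deriv))
    rep = transport_validate(model, grouping, deriv)
    hrs = rep.group_hazard_ratios["hr"].to_numpy()
    assert np.all(np.diff(hrs) > 0)
    assert hrs[0] > 1.0


def test_transport_clamps_out_of_domain_covariates(small_cohort):
    model = fit_univariable_fp(small_cohort, "tumor_size_mm")
    grouping = make_risk_groups(prognostic_index(model, small_cohort))
    weird = small_cohort.copy()
    weird.loc[weird.index[:3], "tumor_size_mm"] = 500.0
    domains = {"tumor_size_mm": (1.0, 120.0)}
    rep = transport_validate(model, grouping, weird, domains=domains)
    assert rep.n_clamped == 3
    with pytest.raises(ValueError):
        transport_validate(model, grouping, weird, domains=domains,
                           strict_domain=True)


def test_transport_ten_year_survival_decreases_across_groups(medium_cohort):
    model = fit_model_class("rcs", medium_cohort)
    grouping = make_risk_groups(prognostic_index(model, medium_cohort))
    rep = transport_validate(model, grouping, medium_cohort)
    s10 = [rep.survival_10yr[g]["estimate"] for g in ("G1", "G2", "G3", "G4")]
    assert all(a > b for a, b in zip(s10, s10[1:]))
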