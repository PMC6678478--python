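import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bloomlasso.design import build_design
from bloomlasso.eblasso import NEGHyperparams, fit_eblasso
from bloomlasso.inference import (
    ReportError,
    build_report,
    coefficient_cv,
    explanation_ratios,
    format_equation,
    parse_equation,
    pearson_table,
    posterior_density,
)
from bloomlasso.survey_io import standardize
from bloomlasso.synthetic import (
    REFERENCE_EQUATIONS,
    SyntheticConfig,
    generate_survey,
)
from bloomlasso.pipeline import fit_equation_replicate

from conftest import toy_design
from test_eblasso import _fake_fit


# ------------------------------------------------------------------
# explanation ratios
# ------------------------------------------------------------------

@pytest.mark.parametrize(
    "coefs, expected",
    [
        ((0.959, 0.134, 0.167), (0.761, 0.106, 0.133)),
        ((1.0,), (1.0,)),
        ((0.5, -0.5), (0.5, 0.5)),
        ((0.327, 0.246, 0.147, -0.064, -0.347), (0.289, 0.218, 0.130, 0.057, 0.307)),
    ],
)
def test_explanation_ratio_worked_examples(coefs, expected):
    np.testing.assert_allclose(explanation_ratios(coefs), expected, atol=5e-4)


def test_er_all_zero_rejected():
    with pytest.raises(ReportError):
        explanation_ratios([0.0, 0.0])


@given(
    coefs=st.lists(
        st.floats(min_value=-10, max_value=10).filter(lambda x: abs(x) > 1e-3),
        min_size=1, max_size=8,
    ),
    scale=st.floats(min_value=0.01, max_value=100).filter(lambda c: c != 0),
    flip=st.booleans(),
)
def test_er_normalised_and_rescale_invariant(coefs, scale, flip):
    er = explanation_ratios(coefs)
    assert er.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(er >= 0)
    c = (-scale if flip else scale) * np.asarray(coefs)
    np.testing.assert_allclose(explanation_ratios(c), er, atol=1e-9)


# ------------------------------------------------------------------
# posterior summaries
# ------------------------------------------------------------------

@pytest.mark.parametrize("mean, var, expected", [(2.0, 1.0, 0.5), (-2.0, 1.0, 0.5)])
def test_coefficient_cv_hand_computable(mean, var, expected):
    fit = _fake_fit([mean], [var], n=58)
    assert coefficient_cv(fit)[0] == pytest.approx(expected)


def test_posterior_density_tail_probability():
    fit = _fake_fit([1.0, 0.0], [0.04, 0.0], n=58)
    dens = posterior_density(fit, 0)
    assert dens["p_negative"] == pytest.approx(2.87e-7, rel=0.01)
    grid, pdf = dens["grid"], dens["density"]
    assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-3)


def test_posterior_density_symmetric_at_zero_mean():
    fit = _fake_fit([1e-300, 0.0], [0.04, 0.0], n=58)
    fit.beta_mean[0] = 0.0
    fit.support = np.array([0])
    fit.beta_var[0] = 0.04
    assert posterior_density(fit, 0)["p_negative"] == pytest.approx(0.5)


def test_posterior_density_off_support_rejected():
    fit = _fake_fit([1.0, 0.0], [0.04, 0.0], n=58)
    with pytest.raises(ReportError):
        posterior_density(fit, 1)


def test_reference_refit_tp_has_lowest_cv():
    """Refitting the ferrous-iron equation at survey-like noise, the TP
    coefficient carries the smallest posterior CV of the three terms."""
    fit, report, design = fit_equation_replicate(
        REFERENCE_EQUATIONS["Fe(II)"], n=500, seed=30
    )
    by_name = dict(zip((t.name for t in report.terms), report.coef_cv))
    assert "TP" in by_name
    others = [v for k, v in by_name.items() if k != "TP"]
    assert all(by_name["TP"] < v for v in others)


# ------------------------------------------------------------------
# correlation table
# ------------------------------------------------------------------

def test_pearson_diagonal_and_symmetry(small_survey):
    corr = pearson_table(standardize(small_survey))
    r = corr.r.to_numpy()
    assert np.allclose(np.diag(r), 1.0)
    assert np.allclose(r, r.T)
    assert np.all(np.abs(r) <= 1.0 + 1e-12)


@pytest.mark.parametrize(
    "r, n, starred",
    [(0.26, 58, True), (0.24, 58, False), (0.34, 58, True)],
)
def test_star_threshold_against_t_oracle(r, n, starred):
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), n - 2)
    assert (p < 0.05) == starred


def test_star_assignment_matches_closed_form(small_survey):
    corr = pearson_table(standardize(small_survey))
    n = small_survey.n_sites
    names = corr.r.columns
    for i, j in itertools.combinations(range(len(names)), 2):
        r = corr.r.iloc[i, j]
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = 2 * stats.t.sf(abs(t), n - 2)
        expected = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        assert corr.stars.iloc[i, j] == expected
        assert corr.p_values.iloc[i, j] == pytest.approx(p, abs=1e-12)


def test_correlation_converges_to_generator_target(big_survey):
    corr = pearson_table(standardize(big_survey))
    from bloomlasso.synthetic import survey_correlation

    target = survey_correlation()
    assert np.max(np.abs(corr.r.to_numpy() - target)) < 0.02


# ------------------------------------------------------------------
# equation formatting
# ------------------------------------------------------------------

def test_format_equation_descending_and_parsable():
    fit, report, design = fit_equation_replicate(
        REFERENCE_EQUATIONS["Fe(II)"], n=5000, seed=31
    )
    text = report.equation_text
    assert text.startswith("Fe(II) = ")
    resp, terms, intercept = parse_equation(text)
    assert resp == "Fe(II)"
    mags = [abs(c) for _, c in terms]
    assert mags == sorted(mags, reverse=True)
    # round-trip at the printed precision
    by_name = {tuple(f): c for f, c in terms}
    for t, c in zip(report.terms, report.coef):
        assert by_name[t.factors] == pytest.approx(c, abs=5e-4)
    assert intercept == pytest.approx(report.intercept, abs=5e-4)


def test_format_empty_support_is_intercept_only():
    d = toy_design(n=100, p=4, beta=None, noise=1.0, seed=32)
    fit = fit_eblasso(d, NEGHyperparams(1.0, 0.01))
    report = build_report(fit, d)
    assert report.equation_text == f"y = {fit.mu:.3f}"


def test_negative_coefficients_formatted():
    fit, report, design = fit_equation_replicate(
        REFERENCE_EQUATIONS["SSC"], n=5000, seed=33
    )
    text = report.equation_text
    assert " - " in text  # the depth and iron-by-depth terms are negative
    _, terms, _ = parse_equation(text)
    signs = {tuple(f): np.sign(c) for f, c in terms}
    assert signs.get(("Fe(II)", "DEP")) == -1.0
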