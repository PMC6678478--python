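"""Post-fit reporting: explanation ratios, posterior uncertainty, correlations.

The screen's variable-importance summary is the explanation ratio

    ER_i = |beta_i| / sum_j |beta_j|

over the non-intercept standardised coefficients of the final equation;
because every design column has unit variance the ratios are unit-free
and sum to one.  Posterior uncertainty per coefficient is summarised by
its coefficient of variation (posterior SD / |posterior mean|) and by the
full Gaussian posterior density, including the probability that the
coefficient has the opposite sign.  The module also produces the
starred Pearson correlation table that accompanies the regressions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import FeatureDesign, Term
from .eblasso import EBLassoFit, adjusted_r2, goodness
from .survey_io import StandardizedTable


class ReportError(ValueError):
    pass


def explanation_ratios(coefs) -> np.ndarray:
    """ER_i = |c_i| / sum_j |c_j| over the non-intercept coefficients."""
    c = np.abs(np.asarray(coefs, dtype=float))
    total = c.sum()
    if total == 0.0:
        raise ReportError("explanation ratios undefined: all coefficients zero")
    return c / total


def coefficient_cv(fit: EBLassoFit) -> np.ndarray:
    """Posterior SD / |posterior mean| per retained coefficient.

    A zero posterior mean makes the ratio undefined; that entry is
    returned as NaN rather than raising.
    """
    if fit.support_size == 0:
        raise ReportError("empty support: no coefficients to summarise")
    mean = fit.beta_mean[fit.support]
    sd = np.sqrt(fit.beta_var[fit.support])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean != 0.0, sd / np.abs(mean), np.nan)
    return out


def posterior_density(
    fit: EBLassoFit,
    term_index: int,
    n_grid: int = 401,
) -> dict:
    """Gaussian posterior density curve of one retained coefficient.

    Evaluated on mean +/- 4 SD; also reports P(coefficient < 0), the
    operational version of "small probability the coefficient is
    negative".
    """
    if term_index not in fit.support:
        raise ReportError(f"column {term_index} is not in the fitted support")
    m = float(fit.beta_mean[term_index])
    v = float(fit.beta_var[term_index])
    sd = np.sqrt(v)
    grid = np.linspace(m - 4 * sd, m + 4 * sd, n_grid)
    dens = stats.norm.pdf(grid, loc=m, scale=sd)
    return {
        "grid": grid,
        "density": dens,
        "mean": m,
        "variance": v,
        "p_negative": float(stats.norm.cdf(0.0, loc=m, scale=sd)),
    }


@dataclass
class ERReport:
    """Final-equation summary for one response."""

    response_name: str
    terms: list[Term]
    coef: np.ndarray
    coef_var: np.ndarray
    er: np.ndarray
    coef_cv: np.ndarray
    intercept: float
    r2: float
    adj_r2: float
    p_values: np.ndarray
    equation_text: str = ""

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "intercept": self.intercept,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "equation": self.equation_text,
            "terms": [
                {
                    "name": t.name,
                    "factors": list(t.factors),
                    "coef": float(c),
                    "coef_var": float(v),
                    "er": float(e),
                    "er_percent": round(100.0 * float(e), 1),
                    "cv": None if np.isnan(cv) else float(cv),
                    "p_value": float(p),
                }
                for t, c, v, e, cv, p in zip(
                    self.terms, self.coef, self.coef_var, self.er,
                    self.coef_cv, self.p_values,
                )
            ],
        }


def build_report(
    fit: EBLassoFit,
    design: FeatureDesign,
    alpha: float = 0.05,
    significance_filter: bool = True,
) -> ERReport:
    """Assemble the explanation-ratio report for a fitted equation.

    With ``significance_filter`` the equation keeps only terms whose
    t-test p-value is below ``alpha`` (the final reported equations
    contain significant terms only); ERs are computed over the kept
    terms.  R^2/adjusted R^2 are those of the kept-term equation.
    """
    if fit.support_size == 0:
        gof = {"r2": 0.0, "adj_r2": 0.0}
        return ERReport(
            response_name=design.response_name, terms=[], coef=np.zeros(0),
            coef_var=np.zeros(0), er=np.zeros(0), coef_cv=np.zeros(0),
            intercept=fit.mu, r2=gof["r2"], adj_r2=gof["adj_r2"],
            p_values=np.zeros(0),
            equation_text=format_equation_parts(design.response_name, [], [], fit.mu),
        )
    keep = np.ones(fit.support_size, dtype=bool)
    if significance_filter:
        keep = fit.p_values < alpha
        if not keep.any():   # never report an empty equation if terms exist
            keep = fit.p_values == fit.p_values.min()
    idx = fit.support[keep]
    coef = fit.beta_mean[idx]
    coef_var = fit.beta_var[idx]
    terms = [design.terms[i] for i in idx]
    cv_all = coefficient_cv(fit)[keep]
    er = explanation_ratios(coef)

    # goodness of fit of the reported (kept-term) equation
    yhat = fit.mu + design.X[:, idx] @ coef
    y = design.y
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        raise ReportError("degenerate response: zero total sum of squares")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    report = ERReport(
        response_name=design.response_name,
        terms=terms,
        coef=coef,
        coef_var=coef_var,
        er=er,
        coef_cv=cv_all,
        intercept=fit.mu,
        r2=r2,
        adj_r2=adjusted_r2(r2, design.n, len(terms)),
        p_values=fit.p_values[keep],
    )
    report.equation_text = format_equation(report)
    return report


def format_equation(report: ERReport) -> str:
    """Deterministic equation string: terms by descending |coefficient|,
    coefficients at 3 decimals, trailing intercept."""
    order = np.argsort(-np.abs(report.coef), kind="stable")
    terms = [report.terms[i] for i in order]
    coefs = [float(report.coef[i]) for i in order]
    return format_equation_parts(report.response_name, terms, coefs, report.intercept)


def format_equation_parts(
    response_name: str,
    terms: list[Term],
    coefs: list[float],
    intercept: float,
) -> str:
    parts = [f"{response_name} ="]
    first = True
    for t, c in zip(terms, coefs):
        sign = "-" if c < 0 else "+"
        if first:
            lead = "-" if c < 0 else ""
            parts.append(f"{lead}{abs(c):.3f} × {t.name}")
            first = False
        else:
            parts.append(f"{sign} {abs(c):.3f} × {t.name}")
    sign = "-" if intercept < 0 else "+"
    if first:
        parts.append(f"{intercept:.3f}")
    else:
        parts.append(f"{sign} {abs(intercept):.3f}")
    return " ".join(parts)


_TERM_RE = re.compile(r"([+-]?)\s*(\d+\.\d+)(?:\s*×\s*(.+))?$")


def parse_equation(text: str) -> tuple[str, list[tuple[tuple[str, ...], float]], float]:
    """Invert :func:`format_equation`: response, [(factors, coef)], intercept."""
    lhs, rhs = text.split(" = ", 1)
    chunks = re.split(r"\s(?=[+-]\s)|\s(?=[+-]\d)", rhs)
    terms: list[tuple[tuple[str, ...], float]] = []
    intercept = 0.0
    for chunk in chunks:
        chunk = chunk.replace("+ ", "+").replace("- ", "-").strip()
        m = _TERM_RE.match(chunk)
        if not m:
            raise ReportError(f"cannot parse equation chunk {chunk!r}")
        sign = -1.0 if m.group(1) == "-" else 1.0
        val = sign * float(m.group(2))
        if m.group(3) is None:
            intercept = val
        else:
            factors = tuple(f.strip() for f in m.group(3).split("×"))
            terms.append((factors, val))
    return lhs.strip(), terms, intercept


@dataclass
class CorrelationTable:
    """Pairwise Pearson correlations with significance stars."""

    r: pd.DataFrame
    p_values: pd.DataFrame
    stars: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        out = self.r.round(2).astype(str)
        return out + self.stars.where(self.stars != "", "").radd(" ").where(
            self.stars != "", ""
        )


def pearson_table(table: StandardizedTable) -> CorrelationTable:
    """Pearson r, two-sided p (t with n-2 df) and stars per factor pair.

    Stars: ``**`` for p < 0.01, ``*`` for p < 0.05.  A constant column
    makes its pairs undefined; standardised input precludes that.
    """
    vals = table.values.to_numpy(dtype=float)
    n = vals.shape[0]
    if n < 3:
        raise ReportError("need at least 3 sites for correlation tests")
    r = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(n - 2) / np.sqrt(1.0 - rr * rr)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    p = np.where(np.isnan(p) & (np.abs(rr) >= 1.0), 0.0, p)
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    np.fill_diagonal(stars, "")
    cols = table.factor_names
    return CorrelationTable(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p_values=pd.DataFrame(p, index=cols, columns=cols),
        stars=pd.DataFrame(stars, index=cols, columns=cols),
    )
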