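"""Survey-like synthetic data with the black-bloom survey's statistics.

The original 58-site field survey of a eutrophic lake bay during black
bloom was never deposited, so the pipeline is exercised on synthetic
tables that emulate its published statistical structure: the per-factor
means and SDs, the pairwise Pearson correlation matrix, and responses
regenerated from the reported regression equations at their reported R²
levels.  Sites are drawn as correlated Gaussian vectors on the
standardised scale (the correlation matrix, assembled pairwise from real
data, is first repaired to the nearest positive-semidefinite matrix) and
rescaled to the target marginal moments.  An optional lognormal mode
moment-matches the skewed nonnegative factors instead; it is off by
default because the regression model assumes Gaussian errors, not
Gaussian predictors, and the Gaussian copula keeps the correlation
targets exact.

Everything is driven by one integer seed, so any table is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import Term
from .schema import FACTORS
from .survey_io import SurveyTable, standardize_vector

# ------------------------------------------------------------------
# Published survey statistics (58 sites, July sampling, lake-bay black
# bloom): marginal mean and SD per factor, and the pairwise Pearson
# correlation matrix.  These are the generator's default targets.
# ------------------------------------------------------------------

SURVEY_N = 58

SURVEY_MEANS: dict[str, float] = {
    "Fe(II)": 1.27, "S(-II)": 0.04, "SSC": 114.41, "TN": 2.17, "TP": 0.37,
    "SP": 0.11, "DO": 6.88, "CHLA": 53.0, "COD_Mn": 77.96, "ORP": 131.13,
    "TEMP": 25.35, "DEP": 1.21, "VEL": 11.04, "pH": 8.04,
}

SURVEY_SDS: dict[str, float] = {
    "Fe(II)": 0.96, "S(-II)": 0.02, "SSC": 192.45, "TN": 1.18, "TP": 0.27,
    "SP": 0.08, "DO": 0.99, "CHLA": 31.0, "COD_Mn": 7.06, "ORP": 25.33,
    "TEMP": 1.84, "DEP": 0.15, "VEL": 8.05, "pH": 0.24,
}

# Lower triangle of the survey correlation matrix, rows in schema order.
_CORR_LOWER: list[list[float]] = [
    [1.0],
    [0.72, 1.0],
    [0.87, 0.83, 1.0],
    [0.50, 0.41, 0.49, 1.0],
    [0.76, 0.68, 0.80, 0.78, 1.0],
    [0.39, 0.26, 0.37, 0.62, 0.73, 1.0],
    [-0.18, 0.05, -0.04, -0.40, -0.34, -0.51, 1.0],
    [-0.03, 0.04, 0.02, 0.23, 0.08, -0.04, 0.18, 1.0],
    [0.35, 0.41, 0.41, 0.58, 0.58, 0.52, -0.27, 0.20, 1.0],
    [-0.21, 0.07, -0.05, -0.26, -0.09, 0.07, 0.24, -0.03, -0.12, 1.0],
    [-0.15, -0.06, 0.00, -0.15, -0.09, 0.07, -0.13, 0.04, 0.04, 0.37, 1.0],
    [-0.36, -0.28, -0.34, -0.27, -0.38, -0.17, 0.07, 0.03, -0.24, 0.38, 0.20, 1.0],
    [-0.02, 0.02, 0.00, -0.03, 0.06, 0.12, 0.11, 0.00, -0.11, 0.44, 0.18, 0.14, 1.0],
    [-0.15, 0.14, 0.06, -0.20, -0.11, -0.17, 0.68, 0.10, -0.24, 0.67, 0.20, 0.24, 0.33, 1.0],
]


def survey_correlation() -> np.ndarray:
    """The survey's 14 x 14 Pearson correlation matrix (point values)."""
    p = len(FACTORS)
    R = np.eye(p)
    for i, row in enumerate(_CORR_LOWER):
        for j, v in enumerate(row):
            R[i, j] = R[j, i] = v
    return R


@dataclass(frozen=True)
class EquationSpec:
    """A generating regression truth: response = sum(coef * term) + intercept.

    Coefficients are on the standardised scale (unit-variance response
    and design columns); ``target_r2`` fixes the population share of
    response variance explained by the linear predictor.
    """

    response: str
    terms: tuple[tuple[Term, float], ...]
    intercept: float
    target_r2: float

    def __post_init__(self):
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError(f"target_r2 must be in (0,1), got {self.target_r2}")

    @property
    def coefs(self) -> np.ndarray:
        return np.array([c for _, c in self.terms])

    @property
    def term_list(self) -> list[Term]:
        return [t for t, _ in self.terms]


#: The three reported survey regression equations, used as default truths.
REFERENCE_EQUATIONS: dict[str, EquationSpec] = {
    "Fe(II)": EquationSpec(
        response="Fe(II)",
        terms=(
            (Term.of("TP"), 0.959),
            (Term.of("TN", "DO"), 0.134),
            (Term.of("ORP", "CHLA"), 0.167),
        ),
        intercept=0.0653,
        target_r2=0.841,
    ),
    "S(-II)": EquationSpec(
        response="S(-II)",
        terms=(
            (Term.of("TP"), 0.535),
            (Term.of("TP", "DEP"), -0.325),
            (Term.of("TP", "pH"), 0.421),
            (Term.of("TP", "COD_Mn"), 0.170),
        ),
        intercept=-0.0128,
        target_r2=0.628,
    ),
    "SSC": EquationSpec(
        response="SSC",
        terms=(
            (Term.of("Fe(II)"), 0.327),
            (Term.of("S(-II)"), 0.246),
            (Term.of("TP"), 0.147),
            (Term.of("DEP"), -0.064),
            (Term.of("Fe(II)", "DEP"), -0.347),
        ),
        intercept=0.0,
        target_r2=0.796,
    ),
}


@dataclass
class SyntheticConfig:
    """Targets for the synthetic survey generator."""

    n: int = SURVEY_N
    means: dict[str, float] = field(default_factory=lambda: dict(SURVEY_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(SURVEY_SDS))
    corr: np.ndarray = field(default_factory=survey_correlation)
    equation_specs: dict[str, EquationSpec] = field(
        default_factory=lambda: dict(REFERENCE_EQUATIONS)
    )
    seed: int = 0
    lognormal: bool = False

    def validate(self) -> "SyntheticConfig":
        if self.n < 3:
            raise ValueError("need n >= 3 sites")
        for f in FACTORS:
            if self.sds[f] <= 0:
                raise ValueError(f"SD for {f!r} must be positive")
        R = np.asarray(self.corr, dtype=float)
        if R.shape != (len(FACTORS), len(FACTORS)):
            raise ValueError("correlation matrix has wrong shape")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        return self

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def nearest_psd(corr: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Nearest (Frobenius) positive-semidefinite correlation matrix.

    Alternating projections between the PSD cone and the unit-diagonal
    affine set, with Dykstra's correction (Higham's algorithm).  Input
    already PSD (min eigenvalue >= -1e-8) is returned unchanged.
    """
    A = np.asarray(corr, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("input must be symmetric")
    if np.linalg.eigvalsh(A).min() >= -1e-8:
        return A.copy()
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        Rk = Y - dS
        w, V = np.linalg.eigh((Rk + Rk.T) / 2.0)
        Xk = (V * np.clip(w, 0.0, None)) @ V.T
        dS = Xk - Rk
        Y = Xk.copy()
        np.fill_diagonal(Y, 1.0)
        if np.max(np.abs(Y - Xk)) < tol:
            break
    Y = (Y + Y.T) / 2.0
    np.fill_diagonal(Y, 1.0)
    # final clip so the factorisation below never sees negative eigenvalues
    w, V = np.linalg.eigh(Y)
    if w.min() < 0.0:
        Y = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.diag(Y))
        Y = Y / np.outer(d, d)
        np.fill_diagonal(Y, 1.0)
    return Y


def _mvn_factor(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    return V * np.sqrt(np.clip(w, 0.0, None))


def generate_survey(config: SyntheticConfig) -> SurveyTable:
    """Draw a synthetic survey table with the configured moments and correlations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    R = nearest_psd(np.asarray(config.corr, dtype=float))
    L = _mvn_factor(R)
    Z = rng.standard_normal((config.n, len(FACTORS))) @ L.T
    data = {}
    for j, f in enumerate(FACTORS):
        m, s = config.means[f], config.sds[f]
        if config.lognormal and m > 0:
            # moment-match a lognormal to (m, s) through the Gaussian copula
            s2 = np.log1p((s / m) ** 2)
            data[f] = np.exp(np.log(m) - s2 / 2.0 + np.sqrt(s2) * Z[:, j])
        else:
            data[f] = m + s * Z[:, j]
    df = pd.DataFrame(data, columns=list(FACTORS))
    df.index = [f"site{i + 1:03d}" for i in range(config.n)]
    return SurveyTable(data=df)


@dataclass
class EquationTruth:
    """Generating truth recorded next to an equation-driven table."""

    spec: EquationSpec
    noise_var: float
    response_offset: float     # affine embedding of the standardised-scale
    response_scale: float      # response into the stored survey column
    response_std: np.ndarray = field(repr=False, default=None)

    def recover_response(self, table: SurveyTable) -> np.ndarray:
        """Invert the affine storage back to the equation-scale response."""
        col = table.data[self.spec.response].to_numpy(dtype=float)
        return (col - self.response_offset) / self.response_scale

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "terms": [
                {"factors": list(t.factors), "coef": float(c)}
                for t, c in self.spec.terms
            ],
            "intercept": self.spec.intercept,
            "target_r2": self.spec.target_r2,
            "noise_var": self.noise_var,
            "response_offset": self.response_offset,
            "response_scale": self.response_scale,
        }


def generate_from_equation(
    config: SyntheticConfig,
    spec: EquationSpec | str | None = None,
) -> tuple[SurveyTable, EquationTruth]:
    """Synthetic survey whose response column obeys a known regression truth.

    Predictors are drawn as in :func:`generate_survey`; the response is
    rebuilt on the standardised scale as the spec's linear predictor over
    sample-standardised main/product columns plus Gaussian noise with
    variance Var(linpred)·(1 - R²)/R², so the population R² of the true
    predictor equals the target.  The stored response column is an exact
    affine embedding of that standardised-scale response (using the
    response's survey mean/SD), recorded in the returned truth so it can
    be inverted when refitting.
    """
    config.validate()
    if spec is None:
        spec = "Fe(II)"
    if isinstance(spec, str):
        spec = config.equation_specs[spec]
    table = generate_survey(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    std_cols = {
        f: standardize_vector(table.data[f].to_numpy(dtype=float)) for f in FACTORS
    }

    def term_column(term: Term) -> np.ndarray:
        if term.is_interaction:
            fa, fb = term.factors
            return standardize_vector(std_cols[fa] * std_cols[fb])
        return std_cols[term.factors[0]]

    for t, _ in spec.terms:
        for f in t.factors:
            if f == spec.response:
                raise ValueError("equation terms cannot involve the response")

    linpred = sum(c * term_column(t) for t, c in spec.terms)
    v_lin = float(np.var(linpred, ddof=1))
    noise_var = v_lin * (1.0 - spec.target_r2) / spec.target_r2
    y_std = spec.intercept + linpred + rng.normal(0.0, np.sqrt(noise_var), config.n)

    offset = config.means[spec.response]
    scale = config.sds[spec.response]
    out = table.data.copy()
    out[spec.response] = offset + scale * y_std
    truth = EquationTruth(
        spec=spec, noise_var=noise_var, response_offset=offset,
        response_scale=scale, response_std=y_std,
    )
    return SurveyTable(data=out), truth
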