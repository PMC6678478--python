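"""Oversaturated regression designs: main effects plus all pairwise interactions.

For each response the design drops the response itself plus any factors so
collinear with it that they would crowd out every other predictor (the
screen's exclusion rules), takes the remaining m standardised factors as
main effects, and adds the m(m-1)/2 elementwise products of every
unordered pair.  Product columns are re-standardised so every design
column lives on the same unit-variance scale; explanation ratios are then
directly comparable across main and interaction terms.

With the 14-factor survey schema this gives 11 + 55 = 66 candidate
predictors for the Fe(II) and S(-II) regressions and 13 + 78 = 91 for SSC
— far more than the number of sites, which is why a sparsity-inducing fit
is needed at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .schema import FACTORS, RESPONSES, factor_index
from .survey_io import DegenerateColumnError, StandardizedTable, standardize_vector

# Response-specific predictor exclusions.  Fe(II), S(-II) and SSC are so
# strongly intercorrelated that keeping the other state variables as
# predictors would mask every environmental factor; for SSC both Fe(II)
# and S(-II) stay in (SSC is their downstream product, FeS particles).
_EXCLUSIONS: dict[str, frozenset[str]] = {
    "Fe(II)": frozenset({"S(-II)", "SSC"}),
    "S(-II)": frozenset({"Fe(II)", "SSC"}),
    "SSC": frozenset(),
}


class DesignError(ValueError):
    pass


def excluded_factors(response_name: str) -> frozenset[str]:
    """Factors excluded from the predictor set for a given response."""
    try:
        return _EXCLUSIONS[response_name]
    except KeyError:
        raise DesignError(
            f"unsupported response {response_name!r}; expected one of {RESPONSES}"
        ) from None


@dataclass(frozen=True)
class Term:
    """Provenance of one design column: a main effect or a pairwise product.

    Factors are stored in canonical schema order, so ``Term`` instances
    compare and hash consistently regardless of the order a pair was
    written in.
    """

    factors: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= len(self.factors) <= 2:
            raise DesignError("a term is one factor or an unordered pair")

    @staticmethod
    def of(*factors: str) -> "Term":
        ordered = tuple(sorted(set(factors), key=_order_key))
        return Term(ordered)

    @property
    def is_interaction(self) -> bool:
        return len(self.factors) == 2

    @property
    def name(self) -> str:
        return " × ".join(self.factors)

    def __str__(self) -> str:
        return self.name


def _order_key(name: str):
    try:
        return (0, factor_index(name))
    except KeyError:
        return (1, name)


@dataclass
class FeatureDesign:
    """Standardised response + predictor matrix with per-column provenance."""

    response_name: str
    y: np.ndarray          # length n
    X: np.ndarray          # n x q, every column mean 0, sample SD 1
    terms: list[Term]      # length q, mains first then pairs

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def main_terms(self) -> list[Term]:
        return [t for t in self.terms if not t.is_interaction]

    def term_index(self, term: Term) -> int:
        return self.terms.index(term)

    def column_manifest(self) -> list[dict]:
        return [
            {"index": i, "kind": "interaction" if t.is_interaction else "main",
             "factors": list(t.factors), "name": t.name}
            for i, t in enumerate(self.terms)
        ]


def build_design(
    table: StandardizedTable,
    response_name: str,
    response: np.ndarray | None = None,
    mains: Sequence[str] | None = None,
) -> FeatureDesign:
    """Assemble the oversaturated design for one response.

    Main effects are every factor except the response and its exclusions
    (or an explicit ``mains`` list for toy designs), in canonical order;
    interaction columns are products of pairs of standardised mains,
    re-standardised, in lexicographic pair order.  ``response`` overrides
    the table's own (standardised) response column — used when refitting
    simulated data whose response is already on the generating equation's
    scale.
    """
    names = table.factor_names
    if mains is None:
        if response_name not in names:
            raise DesignError(f"response {response_name!r} not in table")
        dropped = excluded_factors(response_name) | {response_name}
        mains = [f for f in names if f not in dropped]
    else:
        mains = list(mains)
        if response_name in mains:
            raise DesignError("response cannot be one of the main effects")
    if table.n_sites < 3:
        raise DesignError("need at least 3 sites")

    cols: list[np.ndarray] = []
    terms: list[Term] = []
    for f in mains:
        cols.append(table.column(f))
        terms.append(Term.of(f))
    for fa, fb in combinations(mains, 2):
        prod = table.column(fa) * table.column(fb)
        if np.std(prod, ddof=1) == 0.0:
            raise DegenerateColumnError(
                f"zero-variance interaction column: {fa!r} x {fb!r}"
            )
        cols.append(standardize_vector(prod))
        terms.append(Term.of(fa, fb))

    if response is None:
        y = table.column(response_name)
    else:
        y = np.asarray(response, dtype=float)
        if y.shape != (table.n_sites,):
            raise DesignError("response override has wrong length")
    X = np.column_stack(cols) if cols else np.empty((table.n_sites, 0))
    return FeatureDesign(response_name=response_name, y=y, X=X, terms=terms)
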