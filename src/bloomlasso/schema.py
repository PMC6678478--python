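"""Canonical variable schema for the lake-bay black-bloom survey.

The survey measures 14 aquatic factors at each monitoring site: the three
black-bloom state variables — ferrous iron Fe(II), sulfide S(-II) and
suspended sediment concentration SSC — plus eleven candidate environmental
drivers (nutrients, oxygen status, algal biomass, physical conditions).
All downstream modules refer to factors by the canonical spellings below.
"""

from __future__ import annotations

# Canonical factor order; every table, design and report uses this order.
FACTORS: tuple[str, ...] = (
    "Fe(II)",
    "S(-II)",
    "SSC",
    "TN",
    "TP",
    "SP",
    "DO",
    "CHLA",
    "COD_Mn",
    "ORP",
    "TEMP",
    "DEP",
    "VEL",
    "pH",
)

UNITS: dict[str, str] = {
    "Fe(II)": "mg/L",
    "S(-II)": "mg/L",
    "SSC": "mg/L",
    "TN": "mg/L",
    "TP": "mg/L",
    "SP": "mg/L",
    "DO": "mg/L",
    "CHLA": "ug/L",
    "COD_Mn": "mg/L",
    "ORP": "mV",
    "TEMP": "degC",
    "DEP": "m",
    "VEL": "cm/s",
    "pH": "",
}

# Physically nonnegative quantities (validated on read).
NONNEGATIVE: frozenset[str] = frozenset({"SSC", "SP", "CHLA", "COD_Mn", "DEP", "VEL"})

# Responses the regression screen supports.
RESPONSES: tuple[str, ...] = ("Fe(II)", "S(-II)", "SSC")

# Spelling aliases normalised on read: Unicode minus/en-dash hyphens,
# the "TEP" misprint for temperature, and case variants of pH.
_ALIASES: dict[str, str] = {
    "S(−II)": "S(-II)",   # Unicode minus
    "S(–II)": "S(-II)",   # en dash
    "Fe(Ⅱ)": "Fe(II)",
    "TEP": "TEMP",
    "Ph": "pH",
    "PH": "pH",
    "CODMn": "COD_Mn",
    "COD": "COD_Mn",
}


def normalize_factor(name: str) -> str:
    """Map a factor-name variant to its canonical spelling.

    Unknown names are returned stripped but otherwise untouched; the
    caller decides whether that is a schema error.
    """
    s = name.strip().replace("−", "-").replace("–", "-")
    return _ALIASES.get(s, s)


def factor_index(name: str) -> int:
    """Position of a canonical factor name in the fixed schema order."""
    try:
        return FACTORS.index(name)
    except ValueError:
        raise KeyError(f"unknown aquatic factor: {name!r}") from None
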