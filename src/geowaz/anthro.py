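"""Anthropometric z-scores and underweight classification.

A child's weight-for-age z-score (WAZ) standardizes the measured weight
against the median and standard deviation of a sex- and age-specific
reference population:

    Z = (AI - MI) / SD

where ``AI`` is the individual's anthropometric index (e.g. weight), ``MI``
the reference median for the child's age/sex stratum and ``SD`` the
reference standard deviation. A child is *underweight* when WAZ is strictly
below -2.

The main modelling pipeline treats WAZ itself as the response (surveys such
as the DHS distribute it precomputed); this module is an optional
pre-processing stage for raw measurements. Reference medians and SDs are
user-supplied (CSV with columns ``stratum_age_months, sex, median, sd``) —
no growth-standard tables are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnthroReference",
    "UNDERWEIGHT_THRESHOLD",
    "compute_zscore",
    "classify_underweight",
]

#: z-score below which a child is classified underweight (strict inequality).
UNDERWEIGHT_THRESHOLD = -2.0

_REFERENCE_COLUMNS = ("stratum_age_months", "sex", "median", "sd")


class InvalidReferenceError(ValueError):
    """Raised when a reference stratum has a non-positive SD or duplicates."""


@dataclass(frozen=True)
class AnthroReference:
    """Reference table keyed by (age-in-months, sex) stratum.

    Parameters
    ----------
    table
        One row per stratum with columns ``stratum_age_months``, ``sex``,
        ``median`` and ``sd``. SDs must be strictly positive and stratum
        keys unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REFERENCE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if (self.table["sd"] <= 0).any() or not np.isfinite(self.table["sd"]).all():
            raise InvalidReferenceError("reference SD must be strictly positive and finite")
        keys = self.table[["stratum_age_months", "sex"]]
        if keys.duplicated().any():
            raise InvalidReferenceError("duplicate (age, sex) strata in reference table")

    @classmethod
    def from_csv(cls, path) -> "AnthroReference":
        return cls(pd.read_csv(path))

    def lookup(self, age_months, sex):
        """Return (median, sd) arrays aligned with the requested strata."""
        idx = self.table.set_index(["stratum_age_months", "sex"])
        key = pd.MultiIndex.from_arrays([np.asarray(age_months), np.asarray(sex)])
        try:
            rows = idx.loc[key]
        except KeyError as exc:
            raise KeyError(f"stratum not in reference table: {exc}") from exc
        return rows["median"].to_numpy(), rows["sd"].to_numpy()

    def zscores(self, values, age_months, sex) -> np.ndarray:
        mi, sd = self.lookup(age_months, sex)
        return compute_zscore(values, mi, sd)


def compute_zscore(ai, mi, sd):
    """Standardize an anthropometric index against its reference stratum.

    Returns ``(ai - mi) / sd`` elementwise. All inputs must be finite and
    ``sd`` strictly positive.
    """
    ai = np.asarray(ai, dtype=float)
    mi = np.asarray(mi, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if not (np.isfinite(ai).all() and np.isfinite(mi).all() and np.isfinite(sd).all()):
        raise ValueError("z-score inputs must be finite")
    if (sd <= 0).any():
        raise InvalidReferenceError("reference SD must be strictly positive")
    z = (ai - mi) / sd
    return z if z.ndim else float(z)


def classify_underweight(z):
    """True where the z-score is strictly below -2."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    flag = z < UNDERWEIGHT_THRESHOLD
    return flag if flag.ndim else bool(flag)
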