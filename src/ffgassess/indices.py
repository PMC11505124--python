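"""Hilsenhoff Biological Index and Shannon-Wiener diversity with
five-level water-quality classifications.

HBI is the abundance-weighted mean of per-taxon pollution-tolerance
values X_i (higher = more tolerant community = worse water quality):

    HBI = sum_i n_i X_i / N

H' is Shannon-Wiener diversity in bits, H' = -sum_i P_i log2 P_i with
P_i = n_i / N.  Both are invariant to uniform rescaling of abundances,
so densities and raw counts give identical values.

Class bands (five levels each):

    HBI:  [0, 3.9) Excellent; [3.9, 5.4) Good; [5.4, 7.0) Moderate;
          [7.0, 8.5) Bad; >= 8.5 Very bad       (lower-inclusive)
    H':   > 3 Excellent; (2, 3] Good; (1, 2] Moderate; (0, 1] Bad;
          exactly 0 Very bad                    (upper-inclusive)

The published band endpoints overlap (3.9-5.4 / 5.4-7.0 ...), so the
half-open orientation is a package policy, chosen once and applied
consistently; alternative breakpoints can be passed to ``classify``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CommunityMatrix, TaxonAttributes, ValidationError
from .ffg import iter_strata

CLASS_LABELS = ("Excellent", "Good", "Moderate", "Bad", "Very bad")

#: HBI breakpoints: value in [b_k, b_{k+1}) gets the k-th label.
HBI_BREAKS = (3.9, 5.4, 7.0, 8.5)

#: H' breakpoints: value in (b_k, b_{k+1}] gets the k-th label from the top.
SHANNON_BREAKS = (3.0, 2.0, 1.0, 0.0)


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed survey
    tables), avoiding banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mean_half_up(values, ndigits: int) -> float:
    """Arithmetic mean rounded half away from zero, computed in decimal
    so that means of printed decimal values (e.g. 104.31/18 = 5.795)
    round on their exact value, not a binary approximation."""
    vals = [Decimal(repr(float(v))) for v in values]
    if not vals:
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float((sum(vals) / len(vals)).quantize(q, rounding=ROUND_HALF_UP))


def _as_series(abundances: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(abundances, dtype=float)
    if (s < 0).any():
        raise ValidationError("negative abundances")
    return s[s > 0]


def hbi(
    abundances: Mapping[str, float] | pd.Series,
    attrs: Mapping[str, TaxonAttributes],
) -> float:
    """Abundance-weighted mean pollution tolerance of one sample.

    Returns NaN for an empty sample; raises if any present taxon lacks a
    tolerance value.
    """
    s = _as_series(abundances)
    if s.empty:
        return float("nan")
    missing = [t for t in s.index if t not in attrs]
    if missing:
        raise ValidationError(
            "taxa lacking tolerance values: " + ", ".join(sorted(missing))
        )
    tol = np.array([attrs[t].tolerance for t in s.index])
    return float(np.average(tol, weights=s.to_numpy()))


def shannon(abundances: Mapping[str, float] | pd.Series) -> float:
    """Shannon-Wiener diversity H' in bits; NaN for an empty sample."""
    s = _as_series(abundances)
    if s.empty:
        return float("nan")
    p = s.to_numpy() / s.sum()
    return float(-(p * np.log2(p)).sum())


def classify(
    index_name: str,
    value: float,
    breaks: Sequence[float] | None = None,
) -> str:
    """Map an index value to one of the five water-quality classes."""
    if not np.isfinite(value):
        raise ValidationError(f"cannot classify non-finite value {value!r}")
    if value < 0:
        raise ValidationError(f"{index_name} must be >= 0, got {value}")
    name = index_name.lower()
    if name == "hbi":
        b = tuple(breaks) if breaks is not None else HBI_BREAKS
        for label, upper in zip(CLASS_LABELS, b):
            if value < upper:
                return label
        return CLASS_LABELS[-1]
    if name in ("shannon", "h'", "h"):
        b = tuple(breaks) if breaks is not None else SHANNON_BREAKS
        if value == 0:
            return "Very bad"
        for label, lower in zip(CLASS_LABELS, b):
            if value > lower:
                return label
        return CLASS_LABELS[-1]
    raise ValidationError(f"unknown index {index_name!r}")


def index_report(
    matrix: CommunityMatrix,
    attrs: Mapping[str, TaxonAttributes],
    stratify_by: Sequence[str] = ("section", "month"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample HBI/H' with classes, plus per-stratum arithmetic means.

    Display rounding follows survey-table convention: HBI to 2 decimals,
    H' to 4 decimals, half away from zero; classification of stratum
    means is applied to the rounded mean.
    """
    rows = []
    for (site, month), dens in matrix.density.iterrows():
        h = hbi(dens, attrs)
        d = shannon(dens)
        rows.append(
            {
                "site_id": site,
                "month": month,
                "section": matrix.meta.loc[(site, month), "section"],
                "hbi": round_half_up(h, 2) if np.isfinite(h) else np.nan,
                "shannon": round_half_up(d, 4) if np.isfinite(d) else np.nan,
                "hbi_class": classify("hbi", h) if np.isfinite(h) else "NA",
                "shannon_class": classify("shannon", d) if np.isfinite(d) else "NA",
            }
        )
    per_sample = pd.DataFrame(rows)

    means = []
    for label, mask in iter_strata(matrix, stratify_by):
        sub = per_sample.loc[mask]
        mh = mean_half_up(sub["hbi"], 2)
        ms = mean_half_up(sub["shannon"], 4)
        means.append(
            {
                "stratum": label,
                "n_samples": int(mask.sum()),
                "hbi_mean": mh,
                "shannon_mean": ms,
                "hbi_class": classify("hbi", mh),
                "shannon_class": classify("shannon", ms),
            }
        )
    return per_sample, pd.DataFrame(means)


def stratum_index_means(
    per_sample: pd.DataFrame,
    by: Sequence[str] = ("section", "month"),
) -> pd.DataFrame:
    """Arithmetic means of already-computed per-sample index values,
    grouped by the given columns, with survey-table rounding and classes.

    Useful when per-site index values come from an external table rather
    than from a community matrix.
    """
    grouped = per_sample.groupby(list(by), sort=False)
    out = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        mh = mean_half_up(sub["hbi"], 2)
        ms = mean_half_up(sub["shannon"], 4)
        out.append(
            {
                **dict(zip(by, key)),
                "n_samples": len(sub),
                "hbi_mean": mh,
                "shannon_mean": ms,
                "hbi_class": classify("hbi", mh),
                "shannon_class": classify("shannon", ms),
            }
        )
    return pd.DataFrame(out)
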