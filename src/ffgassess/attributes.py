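"""The eleven FFG-based ecosystem-attribute parameters.

Each parameter summarizes one ecosystem function from the stratum-mean
densities (ind./m^2) of the five functional feeding groups and the
stratum-mean total biomass (g/m^2):

    F1  primary production            density of SC
    F2  secondary production          total biomass
    F3  autotrophy/heterotrophy       SC / (CF + CG)
    F4  decomposition                 SH + CG
    F5  longitudinal transport        density of CF
    F6  relative longitudinal transp. CF / (SH + CG)
    F7  lateral input                 density of SH
    F8  relative lateral input        SH / total density
    F9  CPOM/FPOM input               SH / (CF + CG)
    F10 top-down predator control     PR / total density
    F11 habitat stability             (SC + CF) / (SH + CG)

A ratio with zero denominator is undefined (NaN, rendered "NA"), never
coerced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CommunityMatrix, TaxonAttributes
from .ffg import FfgProfile, ffg_profile, iter_strata

logger = logging.getLogger(__name__)

ATTRIBUTE_NAMES = {
    "F1": "Primary production",
    "F2": "Secondary production",
    "F3": "Autotrophy/heterotrophy",
    "F4": "Decomposition",
    "F5": "Longitudinal transport",
    "F6": "Relative longitudinal transport",
    "F7": "Lateral input",
    "F8": "Relative lateral input",
    "F9": "CPOM input/FPOM input",
    "F10": "Top-down predator control",
    "F11": "Habitat stability",
}


@dataclass
class AttributeVector:
    stratum: str
    F1: float
    F2: float
    F3: float
    F4: float
    F5: float
    F6: float
    F7: float
    F8: float
    F9: float
    F10: float
    F11: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "stratum"}


def _ratio(num: float, den: float, label: str, stratum: str) -> float:
    if den == 0:
        logger.warning("stratum %s: %s undefined (zero denominator)", stratum, label)
        return float("nan")
    return num / den


def attribute_vector(profile: FfgProfile) -> AttributeVector:
    """Compute F1-F11 from one stratum's FFG profile."""
    d = profile.density_by_ffg
    total = profile.total_density
    s = profile.stratum
    sh_cg = d["SH"] + d["CG"]
    cf_cg = d["CF"] + d["CG"]
    return AttributeVector(
        stratum=s,
        F1=d["SC"],
        F2=profile.biomass_total,
        F3=_ratio(d["SC"], cf_cg, "F3", s),
        F4=sh_cg,
        F5=d["CF"],
        F6=_ratio(d["CF"], sh_cg, "F6", s),
        F7=d["SH"],
        F8=_ratio(d["SH"], total, "F8", s),
        F9=_ratio(d["SH"], cf_cg, "F9", s),
        F10=_ratio(d["PR"], total, "F10", s),
        F11=_ratio(d["SC"] + d["CF"], sh_cg, "F11", s),
    )


def attribute_table(
    matrix: CommunityMatrix,
    attrs: Mapping[str, TaxonAttributes],
    strata: Sequence[Sequence[str]] = (("section",), ("month",)),
) -> pd.DataFrame:
    """F1-F11 per stratum, parameters as rows and strata as columns.

    By default the section strata pool all months and the month strata
    pool both sections, giving the six columns gorge, plain, March, May,
    July, October.
    """
    cols = {}
    for by in strata:
        for label, mask in iter_strata(matrix, by):
            prof = ffg_profile(matrix, attrs, mask, label)
            cols[label] = attribute_vector(prof).as_dict()
    table = pd.DataFrame(cols)
    table.index.name = "parameter"
    return table


def render_attribute_table(table: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Human-readable rendering: rounded values, NaN shown as "NA"."""
    out = table.round(ndigits).astype(object)
    return out.where(~table.isna(), "NA")
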