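"""FFG aggregation, relative-abundance composition and species dominance.

Strata are defined by grouping the per-sample metadata: by ``section``,
by ``month``, by both, or the pooled total.  Within a stratum a taxon's
abundance is its mean density over the stratum's samples; the dominance
index of taxon *i* is

    Y_i = (n_i / N_g) * f_i

where n_i is that mean density, N_g the summed mean density of all taxa
sharing i's functional feeding group, and f_i the fraction of the
stratum's samples in which the taxon occurs.  Y > 0.02 marks a dominant
species.  Y is invariant to uniform rescaling of densities, so counts,
summed densities or mean densities all give the same Y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FFG_CODES, CommunityMatrix, TaxonAttributes, ValidationError

DOMINANCE_THRESHOLD = 0.02


def _ffg_of(matrix: CommunityMatrix, attrs: Mapping[str, TaxonAttributes]) -> pd.Series:
    missing = [t for t in matrix.taxa if t not in attrs]
    if missing:
        raise ValidationError(
            "taxa lacking FFG attributes: " + ", ".join(sorted(missing))
        )
    return pd.Series({t: attrs[t].ffg for t in matrix.taxa})


def iter_strata(
    matrix: CommunityMatrix, stratify_by: Sequence[str]
) -> Iterator[tuple[str, np.ndarray]]:
    """Yield (stratum label, boolean sample mask) pairs.

    ``stratify_by`` names metadata columns ("section", "month"); the empty
    sequence yields the single pooled stratum "total".  Labels join the
    level values with "/".
    """
    stratify_by = list(stratify_by)
    if not stratify_by:
        yield "total", np.ones(matrix.n_samples, dtype=bool)
        return
    meta = matrix.meta
    for col in stratify_by:
        if col not in meta.columns:
            raise ValidationError(f"unknown stratification column {col!r}")
    keys = meta[stratify_by].apply(lambda r: "/".join(map(str, r)), axis=1)
    order: dict[str, None] = {}
    from .core import MONTHS, SECTIONS

    canonical = {
        ("section",): ["/".join([s]) for s in SECTIONS],
        ("month",): list(MONTHS),
        ("section", "month"): [f"{s}/{m}" for s in SECTIONS for m in MONTHS],
        ("month", "section"): [f"{m}/{s}" for m in MONTHS for s in SECTIONS],
    }
    labels = canonical.get(tuple(stratify_by))
    if labels is None:
        labels = sorted(keys.unique())
    for label in labels:
        mask = (keys == label).to_numpy()
        if mask.any():
            yield label, mask


@dataclass
class FfgProfile:
    """Per-stratum FFG summary: mean densities per group, mean total
    biomass, and the number of samples pooled."""

    stratum: str
    density_by_ffg: dict[str, float]
    biomass_total: float
    n_samples: int

    @property
    def total_density(self) -> float:
        return float(sum(self.density_by_ffg.values()))


def ffg_profile(
    matrix: CommunityMatrix,
    attrs: Mapping[str, TaxonAttributes],
    mask: np.ndarray,
    stratum: str = "total",
) -> FfgProfile:
    """Aggregate one stratum's samples into per-FFG mean densities."""
    if not mask.any():
        raise ValidationError(f"stratum {stratum!r} has no samples")
    ffg = _ffg_of(matrix, attrs)
    dens = matrix.density.loc[mask].mean(axis=0)
    by_ffg = {g: float(dens[ffg[ffg == g].index].sum()) for g in FFG_CODES}
    biomass = float(matrix.biomass.loc[mask].sum(axis=1).mean())
    return FfgProfile(
        stratum=stratum,
        density_by_ffg=by_ffg,
        biomass_total=biomass,
        n_samples=int(mask.sum()),
    )


def ffg_relative_abundance(
    matrix: CommunityMatrix,
    attrs: Mapping[str, TaxonAttributes],
    stratify_by: Sequence[str] = ("section", "month"),
) -> pd.DataFrame:
    """Percent relative abundance of each FFG per stratum.

    Rows are strata, columns the five FFG codes; percentages sum to 100
    within each stratum.  A stratum with zero total density gets all-NaN
    (undefined, not zero) and is logged.
    """
    rows = {}
    for label, mask in iter_strata(matrix, stratify_by):
        prof = ffg_profile(matrix, attrs, mask, label)
        total = prof.total_density
        if total == 0:
            import logging

            logging.getLogger(__name__).warning(
                "stratum %s has zero total density; composition undefined", label
            )
            rows[label] = {g: np.nan for g in FFG_CODES}
        else:
            rows[label] = {
                g: 100.0 * prof.density_by_ffg[g] / total for g in FFG_CODES
            }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(FFG_CODES))


def dominance_index(
    matrix: CommunityMatrix,
    attrs: Mapping[str, TaxonAttributes],
    stratify_by: Sequence[str] = ("section",),
) -> pd.DataFrame:
    """Dominance index Y per taxon per stratum.

    Returns a long DataFrame with columns stratum, taxon_id, ffg,
    mean_density, occurrence (f_i), Y and the dominant flag (Y > 0.02).
    Taxa whose whole FFG is absent from a stratum get Y = NaN and are
    never flagged dominant.
    """
    ffg = _ffg_of(matrix, attrs)
    out = []
    for label, mask in iter_strata(matrix, stratify_by):
        sub = matrix.density.loc[mask]
        mean_d = sub.mean(axis=0)
        freq = (sub > 0).mean(axis=0)
        n_ffg = mean_d.groupby(ffg).sum()
        for taxon in matrix.taxa:
            g = ffg[taxon]
            denom = n_ffg.get(g, 0.0)
            if denom > 0:
                y = float(mean_d[taxon] / denom * freq[taxon])
            else:
                y = np.nan
            out.append(
                {
                    "stratum": label,
                    "taxon_id": taxon,
                    "ffg": g,
                    "mean_density": float(mean_d[taxon]),
                    "occurrence": float(freq[taxon]),
                    "Y": y,
                    "dominant": bool(y > DOMINANCE_THRESHOLD) if np.isfinite(y) else False,
                }
            )
    return pd.DataFrame(out)


def dominant_species_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot dominance results into a taxa x strata table of Y values.

    Only dominant entries (Y > 0.02) are rendered; everything else is
    blank (NaN).  Rows are ordered by FFG (canonical code order) then
    taxon name; taxa never dominant anywhere are dropped.
    """
    dom = results[results["dominant"]]
    if dom.empty:
        strata = list(dict.fromkeys(results["stratum"])) if len(results) else []
        return pd.DataFrame(columns=["ffg"] + strata)
    wide = dom.pivot_table(index=["taxon_id", "ffg"], columns="stratum",
                           values="Y", aggfunc="first")
    strata_order = list(dict.fromkeys(results["stratum"]))
    wide = wide.reindex(columns=strata_order)
    wide = wide.reset_index().set_index("taxon_id")
    order = {g: i for i, g in enumerate(FFG_CODES)}
    wide = wide.sort_values(
        by=["ffg", "taxon_id"],
        key=lambda s: s.map(order) if s.name == "ffg" else s,
    )
    return wide
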