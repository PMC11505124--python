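"""Domain types, delimited-text I/O and areal conversion.

The raw unit of observation is one taxon counted and weighed in one
site-month collection event (replicate grabs/sweeps already pooled, so a
single sampled area applies to the whole event).  Counts and wet weights
are converted to areal density (ind./m^2) and biomass (g/m^2) by dividing
by that sampled area, and assembled into a samples x taxa community
matrix with explicit zeros for taxa absent from a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five functional feeding groups: collector-gatherers, predators,
#: scrapers, collector-filterers, shredders.
FFG_CODES: tuple[str, ...] = ("CG", "PR", "SC", "CF", "SH")

#: Survey months, in within-year order.
MONTHS: tuple[str, ...] = ("March", "May", "July", "October")

#: River section types: dam-regulated canyon reach vs. alluvial reach.
SECTIONS: tuple[str, ...] = ("gorge", "plain")

#: The twelve water-environment factors, with fixed units per column:
#: T (degC), pH (-), DO (mg/L), Cond (uS/cm), PO4 (mg/L), TP (mg/L),
#: TN (mg/L), NH3N (mg/L), CODMn (mg/L), Chla (ug/L), SSol (mg/L),
#: SSed (mg/L).
ENV_FACTORS: tuple[str, ...] = (
    "T", "pH", "DO", "Cond", "PO4", "TP", "TN", "NH3N",
    "CODMn", "Chla", "SSol", "SSed",
)

SAMPLE_COLUMNS = (
    "site_id", "section", "month", "taxon_id", "count", "wet_weight",
    "sampled_area",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A value violates a domain constraint (vocabulary, sign, range)."""


class ConsistencyError(ValueError):
    """Rows of one sample disagree on a quantity that must be shared."""


@dataclass(frozen=True)
class TaxonAttributes:
    """FFG membership and pollution-tolerance value of one taxonomic unit."""

    taxon_id: str
    ffg: str
    tolerance: float

    def __post_init__(self) -> None:
        if self.ffg not in FFG_CODES:
            raise ValidationError(
                f"unknown FFG code {self.ffg!r} for taxon {self.taxon_id!r}; "
                f"expected one of {FFG_CODES}"
            )
        if not np.isfinite(self.tolerance) or self.tolerance < 0:
            raise ValidationError(
                f"tolerance of {self.taxon_id!r} must be finite and >= 0, "
                f"got {self.tolerance!r}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One taxon's count and wet weight in one site-month collection event."""

    site_id: str
    section: str
    month: str
    taxon_id: str
    count: int
    wet_weight: float
    sampled_area: float

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValidationError(
                f"unknown section {self.section!r}; expected one of {SECTIONS}"
            )
        if self.month not in MONTHS:
            raise ValidationError(
                f"unknown month {self.month!r}; expected one of {MONTHS}"
            )
        if self.count < 0:
            raise ValidationError(f"negative count for {self.taxon_id!r}")
        if self.wet_weight < 0:
            raise ValidationError(f"negative wet weight for {self.taxon_id!r}")
        if self.sampled_area <= 0:
            raise ValidationError(
                f"sampled_area must be > 0, got {self.sampled_area!r}"
            )
        if self.count == 0 and self.wet_weight != 0:
            raise ValidationError(
                f"count = 0 implies wet_weight = 0 (taxon {self.taxon_id!r})"
            )


@dataclass
class CommunityMatrix:
    """Samples x taxa density (ind./m^2) and biomass (g/m^2) matrices.

    ``density`` and ``biomass`` share an identical (site_id, month)
    MultiIndex and taxon columns; ``meta`` carries per-sample ``section``
    and ``month`` labels on the same index.
    """

    density: pd.DataFrame
    biomass: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.density.index.equals(self.biomass.index):
            raise ConsistencyError("density and biomass row order differ")
        if list(self.density.columns) != list(self.biomass.columns):
            raise ConsistencyError("density and biomass taxa differ")
        if not self.density.index.equals(self.meta.index):
            raise ConsistencyError("metadata rows do not match matrix rows")
        if (self.density.to_numpy() < 0).any() or (self.biomass.to_numpy() < 0).any():
            raise ValidationError("negative entries in community matrix")

    @property
    def taxa(self) -> list[str]:
        return list(self.density.columns)

    @property
    def n_samples(self) -> int:
        return len(self.density)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text table, sniffing the delimiter
    from the header line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Parse a long-format sample table into :class:`SampleRecord` rows.

    The file must have a header naming every SampleRecord field; rows are
    validated against the closed section/month vocabularies and sign
    constraints, with the offending row number reported on failure.
    """
    df = _read_delimited(path)
    _require_columns(df, SAMPLE_COLUMNS, "sample table")
    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SampleRecord(
                    site_id=str(row.site_id),
                    section=str(row.section),
                    month=str(row.month),
                    taxon_id=str(row.taxon_id),
                    count=int(row.count),
                    wet_weight=float(row.wet_weight),
                    sampled_area=float(row.sampled_area),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i} of {path}: {exc}") from exc
    return records


def read_taxon_attributes(path: str | Path) -> dict[str, TaxonAttributes]:
    """Parse the taxon attribute table (taxon_id, ffg, tolerance)."""
    df = _read_delimited(path)
    _require_columns(df, ("taxon_id", "ffg", "tolerance"), "taxon attribute table")
    attrs: dict[str, TaxonAttributes] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ta = TaxonAttributes(str(row.taxon_id), str(row.ffg), float(row.tolerance))
        except ValidationError as exc:
            raise ValidationError(f"row {i} of {path}: {exc}") from exc
        if ta.taxon_id in attrs:
            raise ValidationError(f"row {i} of {path}: duplicate taxon {ta.taxon_id!r}")
        attrs[ta.taxon_id] = ta
    return attrs


def read_environment(path: str | Path) -> pd.DataFrame:
    """Parse the site-by-environmental-factor table.

    Returns a DataFrame indexed by (site_id, month) with the twelve factor
    columns in canonical order; a missing factor column is a schema error.
    """
    df = _read_delimited(path)
    _require_columns(df, ("site_id", "month") + ENV_FACTORS, "environment table")
    bad_month = set(df["month"]) - set(MONTHS)
    if bad_month:
        raise ValidationError(f"unknown month value(s) {sorted(bad_month)}")
    out = df.set_index(["site_id", "month"])[list(ENV_FACTORS)].astype(float)
    if out.isna().any().any():
        offending = out.columns[out.isna().any()].tolist()
        raise ValidationError(f"missing factor values in column(s) {offending}")
    return out


def build_matrix(records: Sequence[SampleRecord]) -> CommunityMatrix:
    """Assemble pooled sample records into a :class:`CommunityMatrix`.

    density[s, t] = count / sampled_area and biomass[s, t] =
    wet_weight / sampled_area; taxa never seen in a sample are explicit
    zeros so distances are well-defined.  Duplicate (sample, taxon) rows
    are summed (and logged); rows of one sample disagreeing on
    sampled_area raise :class:`ConsistencyError`.
    """
    if not records:
        raise ValidationError("no records supplied")
    df = pd.DataFrame([r.__dict__ for r in records])

    area = df.groupby(["site_id", "month"])["sampled_area"].nunique()
    conflicts = area[area > 1]
    if len(conflicts):
        raise ConsistencyError(
            "conflicting sampled_area within sample(s): "
            + ", ".join(f"{s}/{m}" for s, m in conflicts.index)
        )

    dups = df.duplicated(["site_id", "month", "taxon_id"], keep=False)
    if dups.any():
        n = df.loc[dups, ["site_id", "month", "taxon_id"]].drop_duplicates()
        logger.info("summing %d duplicate (sample, taxon) row group(s)", len(n))

    agg = (
        df.groupby(["site_id", "month", "taxon_id"], sort=True)
        .agg(
            count=("count", "sum"),
            wet_weight=("wet_weight", "sum"),
            sampled_area=("sampled_area", "first"),
            section=("section", "first"),
        )
        .reset_index()
    )
    agg["density"] = agg["count"] / agg["sampled_area"]
    agg["biomass_aerial"] = agg["wet_weight"] / agg["sampled_area"]

    density = (
        agg.pivot_table(index=["site_id", "month"], columns="taxon_id",
                        values="density", fill_value=0.0, aggfunc="sum")
        .sort_index(axis=1)
    )
    biomass = (
        agg.pivot_table(index=["site_id", "month"], columns="taxon_id",
                        values="biomass_aerial", fill_value=0.0, aggfunc="sum")
        .sort_index(axis=1)
    )
    biomass = biomass.reindex(index=density.index, columns=density.columns,
                              fill_value=0.0)
    meta = (
        agg[["site_id", "month", "section"]]
        .drop_duplicates()
        .set_index(["site_id", "month"])
        .reindex(density.index)
    )
    meta["month"] = meta.index.get_level_values("month")
    return CommunityMatrix(density=density, biomass=biomass, meta=meta)


def missing_attributes(
    matrix: CommunityMatrix, attrs: Mapping[str, TaxonAttributes]
) -> list[str]:
    """Taxa present in the matrix but absent from the attribute table."""
    return sorted(t for t in matrix.taxa if t not in attrs)


def write_matrix(matrix: CommunityMatrix, directory: str | Path) -> None:
    """Write density.csv, biomass.csv and meta.csv (full float precision,
    so a read round-trips bit-exactly)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix.density.to_csv(directory / "density.csv")
    matrix.biomass.to_csv(directory / "biomass.csv")
    matrix.meta.to_csv(directory / "meta.csv")


def read_matrix(directory: str | Path) -> CommunityMatrix:
    """Inverse of :func:`write_matrix`."""
    directory = Path(directory)
    density = pd.read_csv(directory / "density.csv", index_col=[0, 1])
    biomass = pd.read_csv(directory / "biomass.csv", index_col=[0, 1])
    meta = pd.read_csv(directory / "meta.csv", index_col=[0, 1])
    return CommunityMatrix(density=density, biomass=biomass, meta=meta)


def sample_labels(matrix: CommunityMatrix) -> list[str]:
    """Flat "site_id/month" labels for distance matrices and reports."""
    return [f"{s}/{m}" for s, m in matrix.density.index]
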