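"""End-to-end orchestration: from the three input tables to the report
bundle (composition, PERMANOVA, dominance, section density contrasts,
Mantel grid, ecosystem attributes, biotic indices), deterministic for a
fixed seed."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CommunityMatrix,
    FFG_CODES,
    MONTHS,
    SECTIONS,
    TaxonAttributes,
    ValidationError,
    build_matrix,
    missing_attributes,
    read_environment,
    read_samples,
    read_taxon_attributes,
)
from .attributes import attribute_table
from .ffg import dominance_index, dominant_species_table, ffg_relative_abundance, _ffg_of
from .indices import index_report, round_half_up
from .stats import (
    DISTANCES,
    mann_whitney,
    mantel_screen,
    permanova,
    spawn_seeds,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis settings shared by the CLI and :func:`run_all`."""

    n_permutations: int = 999
    seed: int = 0
    distance: str = "braycurtis"
    mantel_method: str = "pearson"
    stratify_by: tuple[str, ...] = ("section", "month")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "stratify_by" in known:
            known["stratify_by"] = tuple(known["stratify_by"])
        return cls(**known)


def richness_by_ffg(attrs: Mapping[str, TaxonAttributes],
                    observed_taxa: Sequence[str] | None = None) -> pd.DataFrame:
    """Taxon counts and percentages per FFG (2 d.p., half away from zero).

    ``observed_taxa`` restricts the attribute table to the taxa actually
    recorded; by default all attributed taxa count.
    """
    taxa = list(attrs) if observed_taxa is None else [t for t in observed_taxa
                                                      if t in attrs]
    if not taxa:
        raise ValidationError("no observed taxa")
    counts = {g: 0 for g in FFG_CODES}
    for t in taxa:
        counts[attrs[t].ffg] += 1
    total = sum(counts.values())
    rows = [
        {"ffg": g, "n_taxa": counts[g],
         "percent": round_half_up(100.0 * counts[g] / total, 2)}
        for g in FFG_CODES
    ]
    return pd.DataFrame(rows).sort_values("n_taxa", ascending=False,
                                          kind="stable").reset_index(drop=True)


def ffg_density_matrix(matrix: CommunityMatrix,
                       attrs: Mapping[str, TaxonAttributes]) -> pd.DataFrame:
    """Per-sample summed density of each FFG (samples x 5)."""
    ffg = _ffg_of(matrix, attrs)
    out = pd.DataFrame(index=matrix.density.index, columns=list(FFG_CODES),
                       dtype=float)
    for g in FFG_CODES:
        out[g] = matrix.density[ffg[ffg == g].index].sum(axis=1)
    return out


def section_density_tests(matrix: CommunityMatrix,
                          attrs: Mapping[str, TaxonAttributes]) -> pd.DataFrame:
    """Mann-Whitney gorge-vs-plain contrast of each FFG's density, per
    month (Z < 0 when the gorge tends below the plain)."""
    ffg_dens = ffg_density_matrix(matrix, attrs)
    meta = matrix.meta
    rows = []
    for month in dict.fromkeys(meta["month"]):
        m_mask = (meta["month"] == month).to_numpy()
        g_mask = m_mask & (meta["section"] == "gorge").to_numpy()
        p_mask = m_mask & (meta["section"] == "plain").to_numpy()
        if not g_mask.any() or not p_mask.any():
            continue
        for g in FFG_CODES:
            res = mann_whitney(ffg_dens.loc[g_mask, g], ffg_dens.loc[p_mask, g])
            rows.append({
                "month": month, "ffg": g,
                "gorge_mean": float(ffg_dens.loc[g_mask, g].mean()),
                "plain_mean": float(ffg_dens.loc[p_mask, g].mean()),
                "U": res.u, "Z": res.z, "p_value": res.p, "method": res.method,
            })
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """In-memory results of :func:`run_all` plus the emitted artifact paths."""

    composition: pd.DataFrame
    permanova_table: pd.DataFrame
    dominance: pd.DataFrame
    dominant_table: pd.DataFrame
    density_tests: pd.DataFrame
    mantel_grid: pd.DataFrame
    attribute_table: pd.DataFrame
    index_per_sample: pd.DataFrame
    index_means: pd.DataFrame
    richness: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_all(
    samples_path: str | Path,
    taxa_path: str | Path,
    env_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> ReportBundle:
    """Run the full bioassessment sequence and write the report bundle.

    Emits seven CSV artifacts (composition, permanova, dominance,
    density_tests, mantel, attributes, indices), a plain-text summary
    with species richness by FFG, and a JSON manifest sufficient to
    re-run bit-identically.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "read inputs"
    try:
        records = read_samples(samples_path)
        attrs = read_taxon_attributes(taxa_path)
        env = read_environment(env_path)

        stage = "build matrix"
        matrix = build_matrix(records)
        missing = missing_attributes(matrix, attrs)
        if missing:
            raise ValidationError(
                "taxa without attributes: " + ", ".join(missing)
            )
        env = env.reindex(matrix.density.index)
        if env.isna().any().any():
            raise ValidationError("environment table missing retained samples")

        seeds = spawn_seeds(config.seed, 2)

        stage = "composition"
        composition = ffg_relative_abundance(matrix, attrs, config.stratify_by)

        stage = "permanova"
        dist = DISTANCES[config.distance]
        dm = dist(ffg_density_matrix(matrix, attrs))
        perm = permanova(
            dm, matrix.meta, terms=("section", "month"), interaction=True,
            n_perm=config.n_permutations, seed=seeds[0],
        )

        stage = "dominance"
        dom = dominance_index(matrix, attrs, stratify_by=("section",))
        dom_month = dominance_index(matrix, attrs, stratify_by=("section", "month"))
        dom_all = pd.concat([dom_month, dom], ignore_index=True)
        dom_table = dominant_species_table(dom_all)

        stage = "density contrasts"
        tests = section_density_tests(matrix, attrs)

        stage = "mantel screen"
        grid = mantel_screen(
            matrix, attrs, env, n_perm=config.n_permutations,
            seed=seeds[1], method=config.mantel_method,
        )

        stage = "ecosystem attributes"
        attr_tab = attribute_table(matrix, attrs)

        stage = "biotic indices"
        per_sample, means = index_report(matrix, attrs, config.stratify_by)

        stage = "richness"
        observed = [t for t in matrix.taxa
                    if (matrix.density[t] > 0).any()]
        rich = richness_by_ffg(attrs, observed)
    except Exception:
        logger.exception("pipeline aborted at stage: %s", stage)
        _write_manifest(out_dir, config, [], samples_path, taxa_path, env_path,
                        failed_stage=stage)
        raise

    artifacts = {
        "composition.csv": composition,
        "permanova.csv": perm.table,
        "dominance.csv": dom_table,
        "density_tests.csv": tests,
        "mantel.csv": grid,
        "attributes.csv": attr_tab,
        "indices.csv": per_sample,
    }
    for fname, df in artifacts.items():
        df.to_csv(out_dir / fname)
    means.to_csv(out_dir / "index_means.csv", index=False)

    lines = ["Species richness by functional feeding group", ""]
    total = int(rich["n_taxa"].sum())
    for _, r in rich.iterrows():
        lines.append(f"  {r.ffg}: {int(r.n_taxa)} taxa ({r.percent:.2f}%)")
    lines.append(f"  total: {total} taxa")
    lines.append("")
    lines.append(f"elapsed: computed in {time.time() - t0:.1f} s")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    manifest = _write_manifest(
        out_dir, config, sorted(artifacts), samples_path, taxa_path, env_path
    )
    return ReportBundle(
        composition=composition,
        permanova_table=perm.table,
        dominance=dom_all,
        dominant_table=dom_table,
        density_tests=tests,
        mantel_grid=grid,
        attribute_table=attr_tab,
        index_per_sample=per_sample,
        index_means=means,
        richness=rich,
        manifest=manifest,
    )


def _write_manifest(out_dir: Path, config: RunConfig, artifacts: list[str],
                    samples_path, taxa_path, env_path,
                    failed_stage: str | None = None) -> dict:
    cfg = asdict(config)
    cfg["stratify_by"] = list(cfg["stratify_by"])
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "inputs": {
            "samples": str(samples_path),
            "taxa": str(taxa_path),
            "environment": str(env_path),
        },
        "artifacts": artifacts,
        "failed_stage": failed_stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
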