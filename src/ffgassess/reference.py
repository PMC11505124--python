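"""Bundled reference data.

``site_indices_reference.csv`` holds published per-site Hilsenhoff and
Shannon-Wiener index values from the upper Yellow River survey the
default synthetic scenario emulates (18 gorge + 15 plain sites in four
months).  They serve as a fixed input for recomputing the survey's
per-section monthly averages and their water-quality classes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import MONTHS


def load_site_indices() -> pd.DataFrame:
    """Long-format reference values: one row per (section, site, month)
    with columns ``hbi`` and ``shannon``."""
    ref = resources.files("ffgassess.data") / "site_indices_reference.csv"
    with resources.as_file(ref) as path:
        wide = pd.read_csv(path)
    rows = []
    for _, r in wide.iterrows():
        for m in MONTHS:
            rows.append(
                {
                    "section": r["section"],
                    "site_id": r["site_id"],
                    "month": m,
                    "hbi": float(r[f"hbi_{m}"]),
                    "shannon": float(r[f"shannon_{m}"]),
                }
            )
    return pd.DataFrame(rows)
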