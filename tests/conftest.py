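import numpy as np
import pandas as pd
import pytest

from ffgassess.core import SampleRecord, TaxonAttributes, build_matrix


@pytest.fixture
def toy_attrs():
    """Five taxa covering three FFGs with distinct tolerance values."""
    return {
        "Gammarus sp.": TaxonAttributes("Gammarus sp.", "CG", 4.0),
        "Limnodrilus": TaxonAttributes("Limnodrilus", "CG", 9.0),
        "Baetis": TaxonAttributes("Baetis", "CG", 5.0),
        "Ecdyonurus": TaxonAttributes("Ecdyonurus", "SC", 3.0),
        "Hydropsyche": TaxonAttributes("Hydropsyche", "CF", 6.0),
    }


def _rec(site, section, month, taxon, count, ww=None, area=0.5):
    if ww is None:
        ww = 0.01 * count
    return SampleRecord(site, section, month, taxon, count, ww, area)


@pytest.fixture
def toy_matrix():
    """4 samples (2 gorge, 2 plain; March/May) x 5 taxa."""
    records = [
        _rec("G1", "gorge", "March", "Gammarus sp.", 10),
        _rec("G1", "gorge", "March", "Limnodrilus", 4),
        _rec("G1", "gorge", "March", "Ecdyonurus", 2),
        _rec("G2", "gorge", "May", "Gammarus sp.", 8),
        _rec("G2", "gorge", "May", "Baetis", 2),
        _rec("P1", "plain", "March", "Gammarus sp.", 3),
        _rec("P1", "plain", "March", "Ecdyonurus", 5),
        _rec("P1", "plain", "March", "Hydropsyche", 4),
        _rec("P2", "plain", "May", "Limnodrilus", 1),
        _rec("P2", "plain", "May", "Hydropsyche", 6),
    ]
    return build_matrix(records)


@pytest.fixture
def sample_csv(tmp_path):
    """A minimal valid sample table on disk."""
    path = tmp_path / "samples.csv"
    path.write_text(
        "site_id,section,month,taxon_id,count,wet_weight,sampled_area\n"
        "G1,gorge,March,Gammarus sp.,5,0.02,0.25\n",
        encoding="utf-8",
    )
    return path
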