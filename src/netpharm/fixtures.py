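"""Published reference data from the QLQX / chronic-heart-failure case study.

The packaged fixture is the high-confidence (STRING association score
>= 0.9) protein-protein interaction table among the hub targets of the
Qiliqiangxin (QLQX) herbal formula against chronic heart failure: 28
interactions over 16 proteins.  Two small symbol lists from the same
case study — the 32 major targets passed by the degree threshold of the
compound-target network, and the 17-node top MCODE cluster (mixing
component ids and target symbols) — support the hub-consensus step.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .io import read_scored_edges
from .symbols import normalize_symbols

#: The 32 major targets retained by the degree-above-mean-neighbors
#: threshold in the compound-target network of the case study.
MAJOR_TARGETS_32 = normalize_symbols([
    "SLCO1B1", "SLCO1B3", "CA7", "CA4", "VEGFA", "SLC22A8", "AKR1B1",
    "ABCB1", "STAT4", "SLCO1A2", "STAT3", "CYP2B6", "CYP2C8", "ATP1A1",
    "CYP1A1", "TTR", "CYP3A4", "ADRB2", "CA3", "ABCG2", "CA14", "SLC6A4",
    "SLC6A2", "CA12", "SCN5A", "CYP3A7", "CYP3A5", "CYP2D6", "ADRB1",
    "MMP3", "CA2", "SLC22A2",
])

#: The 17 members of the top MCODE cluster of the same network: 8 target
#: genes plus 9 herbal components (QLQX-n labels).
TOP_CLUSTER_17 = frozenset([
    "SLC22A8", "SLCO1B3", "QLQX-9", "QLQX-11", "QLQX-5", "QLQX-8",
    "CYP1A1", "QLQX-12", "QLQX-6", "ATP1A1", "VEGFA", "CYP2B6", "STAT3",
    "SLCO1A2", "QLQX-10", "QLQX-4", "STAT4",
])


def load_fixture_ppi() -> pd.DataFrame:
    """Load the packaged hub-target PPI table.

    Returns the 28-row (node1, node2, score) DataFrame; every score is
    >= 0.9 by construction of the source export.
    """
    path = files("netpharm") / "data" / "hub_ppi_edges.tsv"
    return read_scored_edges(str(path))
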