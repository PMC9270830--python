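"""Published per-plant salience/p rankings shipped as package data.

Four ranked columns transcribed from the published study of medicinal-plant
knowledge in Vale do Catimbau (NE Brazil): the 49-informant whole sample in
2017 and 2019, and the Muquem community's adults and children/adolescents
in 2019.  Each table lists, in salience order, the plant's vernacular name,
its Smith's salience and the null-model p-value, which is all the core
classifier needs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .salience import SalienceTable

PRINTED_TABLES = (
    "whole_sample_2017",
    "whole_sample_2019",
    "muquem_adults_2019",
    "muquem_children_2019",
)

# core sizes reported alongside the printed rankings
PUBLISHED_CORE_SIZES = {
    "whole_sample_2017": 15,
    "whole_sample_2019": 11,
    "muquem_adults_2019": 9,
    "muquem_children_2019": 2,
}


def load_printed_table(name: str) -> SalienceTable:
    """Load one published ranking as a SalienceTable (rank, item, salience,
    p_value); no ``side`` column is available in print."""
    if name not in PRINTED_TABLES:
        raise KeyError(f"unknown table {name!r}; choose from {PRINTED_TABLES}")
    ref = resources.files("ethnocore.data") / f"printed_salience_{name}.csv"
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    return SalienceTable(table=df, summary=None)
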