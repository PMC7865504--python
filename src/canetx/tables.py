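"""Packaged topology-table fixtures.

Two small TSVs transcribe the published topology profiles of the 28
metabolite association networks (14 cancer / 14 matched control) and the
16 gene association networks (8 / 8) that the cross-analysis
classification operates on.  Rows are networks; columns are the 12
topology measures plus the network label and cancer/control group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_metabolite_topology", "load_gene_topology"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("canetx.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("network")


def load_metabolite_topology() -> pd.DataFrame:
    """28 metabolite-network topology profiles (14 cancer, 14 control)."""
    return _load("metabolite_network_topology.tsv")


def load_gene_topology() -> pd.DataFrame:
    """16 gene-network topology profiles (8 cancer, 8 control)."""
    return _load("gene_network_topology.tsv")
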