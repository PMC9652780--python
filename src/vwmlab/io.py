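"""Delimited-text I/O for trial tables, similarity functions and results.

All tabular interchange uses tab-separated values with a header row; the
epoch store (binary array + JSON sidecar) lives on
:class:`~vwmlab.erp.EpochSet`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .tcc import SimilarityFunction


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_similarity(sim: SimilarityFunction, path) -> None:
    write_table(sim.to_frame(), path)


def read_similarity(path, domain: str) -> SimilarityFunction:
    df = read_table(path)
    return SimilarityFunction(
        domain=domain, offsets=df["offset"].to_numpy(), f=df["f"].to_numpy()
    )
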