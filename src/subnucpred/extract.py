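"""Batch feature extraction: dataset -> per-method feature matrices.

The eleven extractors are registered by short method name; a matrix is
built per method (rows = sequences, columns = named features) so the
two-step selection can treat each method as its own block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comp_features as cf
from . import physchem_features as pf
from . import signal_features as sf
from .properties import TABLE_SLOTS, load_property_table
from .seq_io import Dataset, SequenceRecord

METHOD_NAMES = ("laac", "ldc", "gd", "lzc", "ad", "sd", "ac", "ppdd", "rqa", "dwt", "hht")


@dataclass
class ExtractionConfig:
    """Which extractors run and with what scheme/property scope."""

    methods: tuple[str, ...] = METHOD_NAMES
    schemes: str | list[str] = "all"          # laac / gd / lzc
    ldc_schemes: list[str] | None = None      # None -> bounded default subset
    properties: tuple[str, ...] | None = None  # None -> packaged table
    ad_max_lag: int = 30
    ac_max_lag: int = 30
    qso_w: float = 0.1
    n_window: int = 60
    c_window: int = 15
    dwt_wavelet: str = "bior3.1"
    dwt_level: int = 5
    hht_n_keep: int = 6

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def extract_record(seq: SequenceRecord | str, config: ExtractionConfig, table=None):
    """All configured feature blocks for one sequence, keyed by method."""
    if table is None:
        table = load_property_table()
    props = config.properties
    slot_props = TABLE_SLOTS if props is None else props
    out = {}
    for m in config.methods:
        if m == "laac":
            out[m] = cf.laac_all(seq, config.schemes,
                                 n_window=config.n_window, c_window=config.c_window)
        elif m == "ldc":
            out[m] = cf.ldc_all(seq, config.ldc_schemes,
                                n_window=config.n_window, c_window=config.c_window)
        elif m == "gd":
            out[m] = cf.gd_all(seq, config.schemes)
        elif m == "lzc":
            out[m] = cf.lzc_features(seq, config.schemes)
        elif m == "ad":
            out[m] = pf.ad_features(seq, slot_props, config.ad_max_lag, table)
        elif m == "sd":
            out[m] = pf.qso_descriptors(seq, w=config.qso_w)
        elif m == "ac":
            out[m] = pf.ac_features(seq, slot_props, config.ac_max_lag, table)
        elif m == "ppdd":
            out[m] = pf.ppdd_all(seq, props, table)
        elif m == "rqa":
            out[m] = sf.rqa_features(seq, props, table)
        elif m == "dwt":
            out[m] = sf.dwt_features(seq, props, table,
                                     wavelet=config.dwt_wavelet, level=config.dwt_level)
        elif m == "hht":
            out[m] = sf.hht_features(seq, props, table, n_keep=config.hht_n_keep)
    return out


def extract_blocks(
    dataset: Dataset | list[SequenceRecord],
    config: ExtractionConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Feature matrices and feature names per method for a whole dataset."""
    config = config or ExtractionConfig()
    records = dataset.records if isinstance(dataset, Dataset) else dataset
    table = load_property_table()
    matrices: dict[str, list[np.ndarray]] = {m: [] for m in config.methods}
    names: dict[str, list[str]] = {}
    for rec in records:
        blocks = extract_record(rec, config, table)
        for m, b in blocks.items():
            matrices[m].append(b.values)
            if m not in names:
                names[m] = b.names
    return {m: np.vstack(v) for m, v in matrices.items()}, names


def blocks_to_frame(
    blocks: dict[str, np.ndarray],
    names: dict[str, list[str]],
    ids: list[str],
) -> pd.DataFrame:
    """Wide table: one row per sequence, columns = all feature names."""
    cols, data = [], []
    for m, X in blocks.items():
        cols.extend(names[m])
        data.append(X)
    return pd.DataFrame(np.concatenate(data, axis=1), index=ids, columns=cols)


def write_features_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="id")


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
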