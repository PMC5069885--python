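"""Normalized expression per barcode.

The normalization anchors cDNA counts to a spike-in pool added at a fixed
cell proportion, which makes expression comparable across samples and
conditions, then corrects for barcode representation in the cell pool with
gDNA counts per million:

    norm_expr = (cdna_count / spike_sum) / gdna_cpm

Barcodes must carry at least ``min_gdna`` gDNA reads in every sample to be
kept, and replicate means are set to 0 whenever one replicate has no cDNA
signal at all (a reporter that is off in one replicate is treated as off).
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


def cpm(counts: pd.Series) -> pd.Series:
    """Counts per million: ``count * 1e6 / total``. Errors on a zero total."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("cpm undefined for an all-zero or empty count table")
    return counts * 1e6 / total


def normalize_expression(
    cdna: pd.Series, gdna_cpm: pd.Series, spike_sum: float
) -> pd.Series:
    """Spike-anchored, representation-corrected expression per barcode.

    The result is indexed by the gDNA barcodes: barcodes missing from the
    cDNA table get expression 0 (not detected), while cDNA barcodes missing
    from the gDNA table cannot be representation-corrected and are excluded
    (logged).
    """
    if spike_sum <= 0:
        raise ValueError("spike_sum must be positive to normalize expression")
    unknown = cdna.index.difference(gdna_cpm.index)
    if len(unknown):
        logger.info(
            "normalize_expression: excluding %d cDNA barcodes absent from gDNA",
            len(unknown),
        )
    aligned = cdna.reindex(gdna_cpm.index, fill_value=0)
    return (aligned / spike_sum) / gdna_cpm


def apply_gdna_cutoff(
    gdna_tables: Sequence[pd.Series], min_gdna: int = 100
) -> pd.Index:
    """Barcodes with at least ``min_gdna`` reads in *every* gDNA sample.

    An empty sample list keeps everything (union of observed barcodes).
    """
    if not len(gdna_tables):
        return pd.Index([])
    universe = gdna_tables[0].index
    for t in gdna_tables[1:]:
        universe = universe.union(t.index)
    keep = pd.Series(True, index=universe)
    for t in gdna_tables:
        keep &= t.reindex(universe, fill_value=0) >= min_gdna
    return universe[keep]


def combine_replicates(*replicates: pd.Series) -> pd.Series:
    """Mean normalized expression across replicates, zeroed on dropout.

    A barcode with zero expression (no cDNA reads) in any replicate gets a
    combined value of 0 rather than the mean, so downstream fold changes
    treat it as off.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    df = pd.concat(replicates, axis=1)
    if df.isna().any().any():
        raise ValueError("replicates must share one barcode set")
    mean = df.mean(axis=1)
    mean[(df == 0).any(axis=1)] = 0.0
    return mean


def display_value(expr: pd.Series | float, pseudocount: float = 0.1):
    """Expression with a pseudocount, for plotting silent reporters on a
    log axis only; never enters any statistic."""
    return expr + pseudocount
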