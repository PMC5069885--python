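"""Barcode count-table processing.

TRIP/MPRA libraries identify each reporter integration by a random 21-nt
barcode transcribed with the reporter. Sequencing introduces substitution
errors, so raw count tables contain low-abundance "mutant" barcodes at small
Hamming distance from their true parent. This module collapses those mutants
back into their parents (abundance-ordered greedy with the directional
``2n - 1`` count rule, the standard UMI-style correction) and splits
spike-in barcodes from reporter barcodes.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

MERGE_LOG_COLUMNS = ["absorbed", "absorber", "count", "distance"]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences.

    Raises
    ------
    ValueError
        If the sequences differ in length.
    """
    if len(a) != len(b):
        raise ValueError(
            f"hamming distance undefined for unequal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def _as_counts(table: Mapping[str, int] | pd.Series) -> pd.Series:
    counts = pd.Series(table, dtype="int64") if not isinstance(table, pd.Series) else table.astype("int64")
    if counts.index.has_duplicates:
        raise ValueError("duplicate barcode keys in count table")
    if (counts < 0).any():
        raise ValueError("negative counts in barcode table")
    return counts


def _chunk_slices(length: int, n_chunks: int) -> list[slice]:
    bounds = np.linspace(0, length, n_chunks + 1).astype(int)
    return [slice(int(bounds[i]), int(bounds[i + 1])) for i in range(n_chunks)]


def collapse_barcodes(
    table: Mapping[str, int] | pd.Series,
    max_dist: int = 2,
    whitelist: Iterable[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Collapse sequencing-mutant barcodes into their parent barcodes.

    Barcodes are visited in order of decreasing count (ties broken
    lexicographically). A visited barcode is absorbed into the most abundant
    already-accepted barcode within ``max_dist`` substitutions, provided the
    absorber's count is at least ``2 * count - 1`` (the directional rule that
    distinguishes an error cloud from an independent barcode). Abundance and
    the directional test both use the original input counts, so the result
    does not depend on accumulation order.

    If ``whitelist`` is given, only whitelist members may act as absorbers;
    whitelist members present in the table are always retained, and
    non-members that find no absorber are dropped and itemized in the merge
    log (``absorber`` empty, ``distance`` -1). Barcodes containing non-ACGT
    characters are likewise dropped and logged.

    Returns
    -------
    (collapsed, merge_log)
        ``collapsed`` maps retained barcodes to their accumulated counts;
        ``merge_log`` has columns absorbed/absorber/count/distance. Total
        count is conserved up to the dropped rows itemized in the log.
    """
    counts = _as_counts(table)
    log_rows: list[tuple[str, str, int, int]] = []
    if counts.empty:
        return counts.copy(), pd.DataFrame(columns=MERGE_LOG_COLUMNS)

    clean_mask = [set(b) <= _VALID_BASES for b in counts.index]
    for bc, c in counts[~np.asarray(clean_mask)].items():
        log_rows.append((bc, "", int(c), -1))
    counts = counts[np.asarray(clean_mask)]
    if counts.empty:
        return counts.copy(), pd.DataFrame(log_rows, columns=MERGE_LOG_COLUMNS)

    lengths = {len(b) for b in counts.index}
    if len(lengths) != 1:
        raise ValueError(f"barcodes of mixed lengths {sorted(lengths)}")
    (length,) = lengths

    wl = set(whitelist) if whitelist is not None else None
    order = sorted(counts.index, key=lambda b: (-counts[b], b))
    # any pair within max_dist substitutions shares at least one of
    # max_dist + 1 equal-width chunks (pigeonhole), so an exact-chunk index
    # over accepted barcodes prunes the candidate set
    slices = _chunk_slices(length, max_dist + 1)
    chunk_index: dict[tuple[int, str], list[str]] = {}
    original: dict[str, int] = {}
    totals: dict[str, int] = {}

    for bc in order:
        c = int(counts[bc])
        candidates: set[str] = set()
        for si, sl in enumerate(slices):
            candidates.update(chunk_index.get((si, bc[sl]), ()))
        best: tuple[tuple[int, str], str, int] | None = None
        for cand in candidates:
            d = hamming(bc, cand)
            if 0 < d <= max_dist:
                key = (-original[cand], cand)
                if best is None or key < best[0]:
                    best = (key, cand, d)
        if best is not None and original[best[1]] >= 2 * c - 1:
            totals[best[1]] += c
            log_rows.append((bc, best[1], c, best[2]))
            continue
        if wl is not None and bc not in wl:
            log_rows.append((bc, "", c, -1))
            continue
        original[bc] = c
        totals[bc] = totals.get(bc, 0) + c
        for si, sl in enumerate(slices):
            chunk_index.setdefault((si, bc[sl]), []).append(bc)

    collapsed = pd.Series(totals, dtype="int64").sort_index()
    collapsed.name = counts.name
    log = pd.DataFrame(log_rows, columns=MERGE_LOG_COLUMNS)
    n_dropped = int((log["distance"] == -1).sum())
    if n_dropped:
        logger.info("collapse_barcodes dropped %d barcodes with no absorber", n_dropped)
    return collapsed, log


def collapse_barcodes_exhaustive(
    table: Mapping[str, int] | pd.Series,
    max_dist: int = 2,
    whitelist: Iterable[str] | None = None,
) -> pd.Series:
    """Reference implementation of the collapsing rule by all-pairs scan.

    Enumerates every accepted barcode for each visited barcode instead of
    using a chunk index; intended as an independent cross-check on small
    tables (quadratic in table size).
    """
    counts = _as_counts(table)
    counts = counts[[set(b) <= _VALID_BASES for b in counts.index]]
    wl = set(whitelist) if whitelist is not None else None
    accepted: list[str] = []
    original: dict[str, int] = {}
    totals: dict[str, int] = {}
    for bc in sorted(counts.index, key=lambda b: (-counts[b], b)):
        c = int(counts[bc])
        within = [
            (a, hamming(bc, a))
            for a in accepted
            if 0 < hamming(bc, a) <= max_dist
        ]
        if within:
            absorber = min(within, key=lambda t: (-original[t[0]], t[0]))[0]
            if original[absorber] >= 2 * c - 1:
                totals[absorber] += c
                continue
        if wl is not None and bc not in wl:
            continue
        accepted.append(bc)
        original[bc] = c
        totals[bc] = totals.get(bc, 0) + c
    return pd.Series(totals, dtype="int64").sort_index()


def split_spike_in(
    table: Mapping[str, int] | pd.Series, spike_barcodes: Iterable[str]
) -> tuple[pd.Series, pd.Series]:
    """Partition a count table into (reporter table, spike-in table).

    Every input barcode lands in exactly one of the two outputs; membership
    in ``spike_barcodes`` decides which.
    """
    counts = _as_counts(table)
    spike_set = set(spike_barcodes)
    is_spike = counts.index.isin(spike_set)
    return counts[~is_spike], counts[is_spike]
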