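"""Integration-site calling from inverse-PCR alignment records.

Each barcoded reporter is localized by paired iPCR reads: a forward read
crossing the transposon-genome junction and a reverse read from the other
end of the circularized fragment. Alignment records (one row per read pair:
barcode, chromosome, forward position, reverse position, strand, mapq) are
clustered per mate with single-linkage windows (500 nt forward / 20 nt
reverse by default), and a barcode is accepted as uniquely mapped only if

1. more than ``min_reads`` (default 2) reads support both mates,
2. at least 80 % of each mate's reads fall in its top cluster and less
   than 10 % in the second cluster,
3. the top cluster's mapq is at least 10 for both mates, and
4. the forward and reverse top clusters are concordant (same chromosome,
   representatives within the forward window), which also excludes tandem
   integration events.

Rejection reasons record the first failing criterion in the fixed order
``reads, frac_top, frac_second, mapq, concordance``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["barcode", "chrom", "fwd_pos", "rev_pos", "strand", "mapq"]
REASONS = ("reads", "frac_top", "frac_second", "mapq", "concordance")

SITE_COLUMNS = [
    "barcode", "chrom", "position", "strand", "status", "reason",
    "n_fwd_reads", "n_rev_reads", "frac_top", "frac_second", "top_mapq",
]


@dataclass(frozen=True)
class Cluster:
    """A single-linkage cluster of read positions on one mate."""

    chrom: str
    position: int          # weighted modal position (tie -> smallest)
    weight: int            # total read weight in the cluster
    top_mapq: int          # highest mapq among member reads
    strand: str            # weight-majority strand of member reads


@dataclass
class IntegrationSite:
    barcode: str
    chrom: str | None
    position: int | None
    strand: str | None
    n_fwd_reads: int
    n_rev_reads: int
    frac_top: float        # min over the two mates
    frac_second: float     # max over the two mates
    top_mapq: int          # min over the two mates
    status: str            # "accepted" | "rejected"
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _weighted_mode(positions: np.ndarray, weights: np.ndarray) -> int:
    uniq, inv = np.unique(positions, return_inverse=True)
    w = np.bincount(inv, weights=weights)
    # highest weight wins; ties go to the smallest coordinate (np.unique is
    # sorted ascending and argmax returns the first maximum)
    return int(uniq[np.argmax(w)])


def _cluster_mate(df: pd.DataFrame, pos_col: str, window: int) -> list[Cluster]:
    clusters: list[Cluster] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp[pos_col].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        w = grp["weight"].to_numpy()[order]
        mq = grp["mapq"].to_numpy()[order]
        st = grp["strand"].to_numpy()[order]
        breaks = np.flatnonzero(np.diff(pos) > window) + 1
        for seg in np.split(np.arange(len(pos)), breaks):
            weight = int(w[seg].sum())
            strand_w = pd.Series(w[seg]).groupby(pd.Series(st[seg])).sum()
            clusters.append(
                Cluster(
                    chrom=str(chrom),
                    position=_weighted_mode(pos[seg], w[seg]),
                    weight=weight,
                    top_mapq=int(mq[seg].max()),
                    strand=str(strand_w.sort_values(ascending=False).index[0]),
                )
            )
    clusters.sort(key=lambda c: (-c.weight, c.chrom, c.position))
    return clusters


def cluster_positions(
    records: pd.DataFrame, window_fwd: int = 500, window_rev: int = 20
) -> dict[str, list[Cluster]]:
    """Cluster one barcode's read positions per mate.

    Positions on the same chromosome whose sorted adjacent gaps are at most
    the mate's window join one cluster. Clusters are ranked by total weight
    (ties by chromosome then coordinate). Returns ``{"fwd": [...], "rev":
    [...]}``; empty input yields empty lists.
    """
    if records.empty:
        return {"fwd": [], "rev": []}
    df = records.copy()
    if "weight" not in df.columns:
        df["weight"] = 1
    return {
        "fwd": _cluster_mate(df, "fwd_pos", window_fwd),
        "rev": _cluster_mate(df, "rev_pos", window_rev),
    }


def call_site(
    barcode: str,
    clusters: dict[str, list[Cluster]],
    min_reads: int = 2,
    min_frac_top: float = 0.8,
    max_frac_second: float = 0.1,
    min_mapq: int = 10,
    concordance_window: int = 500,
) -> IntegrationSite:
    """Apply the acceptance filters to one barcode's clusters.

    ``min_reads`` is exclusive ("more than 2 reads"), ``min_frac_top``
    inclusive, ``max_frac_second`` exclusive ("less than 10 %"), ``min_mapq``
    inclusive ("10 or higher"). Fractions are computed over all of the
    mate's reads on every chromosome.
    """
    fwd, rev = clusters["fwd"], clusters["rev"]
    n_fwd = sum(c.weight for c in fwd)
    n_rev = sum(c.weight for c in rev)

    def mate_stats(cl: list[Cluster], total: int) -> tuple[float, float, int]:
        if not cl or total == 0:
            return 0.0, 0.0, 0
        top = cl[0].weight / total
        second = cl[1].weight / total if len(cl) > 1 else 0.0
        return top, second, cl[0].top_mapq

    f_top, f_sec, f_mq = mate_stats(fwd, n_fwd)
    r_top, r_sec, r_mq = mate_stats(rev, n_rev)

    reason = None
    if not (n_fwd > min_reads and n_rev > min_reads):
        reason = "reads"
    elif not (f_top >= min_frac_top and r_top >= min_frac_top):
        reason = "frac_top"
    elif not (f_sec < max_frac_second and r_sec < max_frac_second):
        reason = "frac_second"
    elif not (f_mq >= min_mapq and r_mq >= min_mapq):
        reason = "mapq"
    elif not (
        fwd[0].chrom == rev[0].chrom
        and abs(fwd[0].position - rev[0].position) <= concordance_window
    ):
        reason = "concordance"

    top = fwd[0] if fwd else None
    return IntegrationSite(
        barcode=barcode,
        chrom=top.chrom if top else None,
        position=top.position if top else None,
        strand=top.strand if top else None,
        n_fwd_reads=n_fwd,
        n_rev_reads=n_rev,
        frac_top=min(f_top, r_top),
        frac_second=max(f_sec, r_sec),
        top_mapq=min(f_mq, r_mq),
        status="rejected" if reason else "accepted",
        reason=reason,
    )


@dataclass
class MappingSummary:
    n_barcodes: int = 0
    n_accepted: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)
    duplicate_sites: int = 0


def map_library(
    records: pd.DataFrame,
    window_fwd: int = 500,
    window_rev: int = 20,
    min_reads: int = 2,
    min_frac_top: float = 0.8,
    max_frac_second: float = 0.1,
    min_mapq: int = 10,
) -> tuple[pd.DataFrame, MappingSummary]:
    """Call one integration site per barcode for a whole record table.

    Output is independent of input row order (barcodes are processed in
    sorted order and clustering sorts internally). Distinct barcodes
    accepted at the same position are kept (co-integration) but counted in
    the summary.
    """
    summary = MappingSummary()
    sites: list[IntegrationSite] = []
    for barcode, grp in records.groupby("barcode", sort=True):
        clusters = cluster_positions(grp, window_fwd, window_rev)
        site = call_site(
            str(barcode), clusters,
            min_reads=min_reads, min_frac_top=min_frac_top,
            max_frac_second=max_frac_second, min_mapq=min_mapq,
            concordance_window=window_fwd,
        )
        sites.append(site)
        summary.n_barcodes += 1
        if site.accepted:
            summary.n_accepted += 1
        else:
            summary.rejected_by_reason[site.reason] = (
                summary.rejected_by_reason.get(site.reason, 0) + 1
            )
    table = pd.DataFrame([vars(s) for s in sites], columns=SITE_COLUMNS)
    acc = table[table["status"] == "accepted"]
    dup = acc.duplicated(subset=["chrom", "position"], keep=False)
    summary.duplicate_sites = int(dup.sum())
    if summary.duplicate_sites:
        logger.info(
            "map_library: %d accepted barcodes share a position (co-integration)",
            summary.duplicate_sites,
        )
    return table, summary


def accepted_sites(site_table: pd.DataFrame) -> pd.DataFrame:
    """Accepted rows of a site table, indexed by barcode."""
    acc = site_table[site_table["status"] == "accepted"]
    return acc.set_index("barcode")[["chrom", "position", "strand"]]
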