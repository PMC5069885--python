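"""Chromatin-context statistics for tethering fold changes.

Given per-barcode expression in a control condition (DNA-binding domain
alone) and a tethered condition (DNA-binding domain fused to a chromatin
protein), this module computes per-reporter fold changes, overlays them on
a chromatin-state segmentation and on continuous occupancy tracks, and runs
the comparative statistics: state-vs-rest Wilcoxon rank-sum tests,
expression-matched control comparisons, covariate correlations, marked
subset tests, and the long-term (memory) summary.

Conventions: a reporter with detectable control expression but zero
tethered cDNA is "silenced" and carries fold change 0; silenced reporters
enter medians and rank tests but are excluded from mean +/- sd summaries,
which the assay reports only for reporters detectable in both conditions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STATE_LABEL_PREFIX = "state_"

EFFECT_CLASSES = ("silenced", "down2x", "within2x", "up2x")


class ChromatinStateMap:
    """Non-overlapping labeled intervals segmenting a genome into states.

    Intervals are 0-based half-open. Construction sorts and validates
    non-overlap per chromosome.
    """

    def __init__(self, intervals: pd.DataFrame):
        required = {"chrom", "start", "end", "state"}
        if not required <= set(intervals.columns):
            raise ValueError(f"state map needs columns {sorted(required)}")
        df = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            raise ValueError("empty or inverted interval in state map")
        for chrom, grp in df.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path) -> "ChromatinStateMap":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name"],
            dtype={"chrom": str},
        )
        df["state"] = (
            df["name"].astype(str).str.removeprefix(STATE_LABEL_PREFIX).astype(int)
        )
        return cls(df[["chrom", "start", "end", "state"]])

    def to_bed(self, path) -> None:
        out = self.intervals.copy()
        out["name"] = STATE_LABEL_PREFIX + out["state"].astype(str)
        out[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def state_at(self, chroms, positions) -> pd.Series:
        """State label containing each position; <NA> when uncovered."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), np.nan)
        for chrom, grp in self.intervals.groupby("chrom"):
            mask = chroms == chrom
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            states = grp["state"].to_numpy()
            idx = np.searchsorted(starts, positions[mask], side="right") - 1
            ok = (idx >= 0) & (positions[mask] < ends[np.clip(idx, 0, None)])
            vals = np.full(mask.sum(), np.nan)
            vals[ok] = states[idx[ok]]
            out[mask] = vals
        return pd.Series(out).astype("Int64")


def assign_state(sites: pd.DataFrame, states: ChromatinStateMap) -> pd.Series:
    """State label at each site (index: barcode); positions outside the
    segmentation are unassigned (<NA>, logged)."""
    labels = states.state_at(sites["chrom"], sites["position"])
    labels.index = sites.index
    n_miss = int(labels.isna().sum())
    if n_miss:
        logger.info("assign_state: %d sites outside the segmentation", n_miss)
    return labels


def _classify(fc: float) -> str:
    if fc == 0:
        return "silenced"
    if fc < 0.5:
        return "down2x"
    if fc > 2:
        return "up2x"
    return "within2x"


def compute_effects(
    control: pd.Series,
    tethered: pd.Series,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-barcode tethering fold change, class, and annotations.

    ``control`` and ``tethered`` are combined-replicate normalized
    expression on the same (post-cutoff) barcode set. ``annotations`` may
    carry per-barcode columns (state, occupancy scores, site coordinates)
    merged by index.

    The summary reports the assay's headline numbers: fraction more than
    twofold down (silenced included) among control-detectable reporters,
    fraction completely silenced among control-detectable, count of more
    than twofold upregulated, and mean +/- sd of fold change among
    reporters detectable in both conditions.
    """
    idx = control.index
    if not idx.equals(tethered.index):
        raise ValueError("control and tethered must share one barcode set")
    eff = pd.DataFrame({"control_expr": control, "tethered_expr": tethered})
    detectable = eff["control_expr"] > 0
    eff["fc"] = np.where(detectable, eff["tethered_expr"] / eff["control_expr"], np.nan)
    eff["effect_class"] = [
        _classify(fc) if np.isfinite(fc) else None for fc in eff["fc"]
    ]
    if annotations is not None:
        eff = eff.join(annotations.reindex(idx))

    det = eff[detectable]
    both = det[det["fc"] > 0]
    summary = {
        "n": len(eff),
        "n_control_detectable": len(det),
        "n_both_detectable": len(both),
        "frac_down2x": float((det["fc"] < 0.5).mean()) if len(det) else np.nan,
        "frac_silenced": float((det["fc"] == 0).mean()) if len(det) else np.nan,
        "n_up2x": int((det["fc"] > 2).sum()),
        "mean_fc_both_detectable": float(both["fc"].mean()) if len(both) else np.nan,
        "sd_fc_both_detectable": float(both["fc"].std(ddof=1)) if len(both) > 1 else np.nan,
    }
    return eff, summary


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples (both sizes <= 25),
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return np.nan
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


@dataclass
class GroupComparison:
    """Wilcoxon comparison of fold changes between a group and the rest."""

    label: str
    n_group: int
    n_rest: int
    median_group: float
    median_rest: float
    median_ratio: float      # >= 1; see direction
    direction: str           # "enhanced_repression" | "attenuated_repression"
    pvalue: float


def _compare_groups(label: str, fc_group: np.ndarray, fc_rest: np.ndarray) -> GroupComparison:
    med_g = float(np.median(fc_group))
    med_r = float(np.median(fc_rest))
    if med_g <= med_r:
        direction = "enhanced_repression"
        ratio = med_r / med_g if med_g > 0 else np.inf
    else:
        direction = "attenuated_repression"
        ratio = med_g / med_r if med_r > 0 else np.inf
    return GroupComparison(
        label=label,
        n_group=len(fc_group),
        n_rest=len(fc_rest),
        median_group=med_g,
        median_rest=med_r,
        median_ratio=float(ratio),
        direction=direction,
        pvalue=rank_sum_test(fc_group, fc_rest),
    )


def state_vs_rest_test(
    effects: pd.DataFrame, state: int, min_members: int = 5
) -> GroupComparison | None:
    """Fold-change comparison of one chromatin state against all others.

    Silenced reporters (fc = 0) are included in medians and ranks;
    reporters without a defined fold change (undetectable control) or
    without a state label are excluded. Returns None (logged) when the
    state has fewer than ``min_members`` usable reporters.
    """
    usable = effects.dropna(subset=["fc", "state"])
    in_state = usable["state"] == state
    if int(in_state.sum()) < min_members:
        logger.info("state_vs_rest_test: state %s has < %d reporters", state, min_members)
        return None
    return _compare_groups(
        f"state_{state}",
        usable.loc[in_state, "fc"].to_numpy(),
        usable.loc[~in_state, "fc"].to_numpy(),
    )


def mark_subset_test(
    effects: pd.DataFrame, mark: pd.Series, label: str = "mark"
) -> GroupComparison | None:
    """Fold-change comparison of reporters at marked vs unmarked sites.

    ``mark`` is boolean per barcode (e.g. H3K36me3-bound). Returns None on
    an empty marked or unmarked set.
    """
    usable = effects.dropna(subset=["fc"])
    m = mark.reindex(usable.index)
    if m.isna().any():
        raise ValueError("mark annotation missing for some reporters")
    m = m.astype(bool)
    if m.sum() == 0 or (~m).sum() == 0:
        logger.info("mark_subset_test: empty marked or unmarked set")
        return None
    return _compare_groups(
        label, usable.loc[m, "fc"].to_numpy(), usable.loc[~m, "fc"].to_numpy()
    )


def covariate_correlation(
    effects: pd.DataFrame,
    covariate: pd.Series | str,
    method: str = "spearman",
    state: int | None = None,
    min_n: int = 5,
) -> tuple[float, float, int]:
    """Correlation between fold change and a per-site covariate.

    Restricted to reporters detectable in both conditions (fold change
    strictly positive); optionally to one chromatin state. ``covariate``
    may be a column name of ``effects`` (e.g. ``"control_expr"`` for the
    expression-independence check) or a Series indexed by barcode. Returns
    ``(coefficient, pvalue, n)``; a zero-variance covariate yields NaN
    (logged).
    """
    sub = effects[effects["fc"] > 0]
    if state is not None:
        sub = sub[sub["state"] == state]
    cov = sub[covariate] if isinstance(covariate, str) else covariate.reindex(sub.index)
    ok = cov.notna() & sub["fc"].notna()
    sub, cov = sub[ok], cov[ok]
    if len(sub) < min_n:
        logger.info("covariate_correlation: only %d usable reporters", len(sub))
        return np.nan, np.nan, len(sub)
    if float(np.std(cov.to_numpy())) == 0.0:
        logger.info("covariate_correlation: zero-variance covariate")
        return np.nan, np.nan, len(sub)
    if method == "spearman":
        r, p = stats.spearmanr(cov, sub["fc"])
    elif method == "pearson":
        r, p = stats.pearsonr(cov, sub["fc"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), len(sub)


@dataclass
class MatchedComparison:
    pairs: pd.DataFrame          # focal_barcode, matched_barcode, exprs, fcs
    excluded: list[str]          # focal reporters outside the pool's range
    median_ratio: float
    direction: str
    pvalue: float                # paired Wilcoxon signed-rank on fc


def expression_matched_controls(
    effects: pd.DataFrame, focal_state: int, seed: int = 0
) -> MatchedComparison:
    """Compare a state against expression-matched reporters elsewhere.

    Because baseline expression differs strongly between chromatin states,
    a state-vs-rest difference in repression could in principle reflect
    expression level rather than chromatin context. This picks, for each
    control-detectable reporter in ``focal_state``, the unused reporter
    from the other states with the closest control expression (greedy
    1-nearest-neighbour on log10 expression, focal order randomized under
    ``seed``); focal reporters outside the pool's expression range cannot
    be matched and are reported as excluded.
    """
    usable = effects.dropna(subset=["fc", "state"])
    focal = usable[(usable["state"] == focal_state)]
    pool = usable[(usable["state"] != focal_state)]
    if focal.empty or pool.empty:
        raise ValueError("focal and non-focal sets must be non-empty")
    if len(pool) < len(focal):
        raise ValueError("matching pool smaller than focal set")

    lo, hi = pool["control_expr"].min(), pool["control_expr"].max()
    in_range = focal["control_expr"].between(lo, hi)
    excluded = list(focal.index[~in_range])
    focal = focal[in_range]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(focal))
    pool_log = np.log10(pool["control_expr"].to_numpy())
    pool_idx = np.array(pool.index)
    available = np.ones(len(pool), dtype=bool)
    rows = []
    for i in order:
        fb = focal.index[i]
        fx = np.log10(focal["control_expr"].iloc[i])
        cand = np.flatnonzero(available)
        j = cand[np.argmin(np.abs(pool_log[cand] - fx))]
        available[j] = False
        mb = pool_idx[j]
        rows.append(
            (fb, mb,
             focal["control_expr"].iloc[i], pool.at[mb, "control_expr"],
             focal["fc"].iloc[i], pool.at[mb, "fc"])
        )
    pairs = pd.DataFrame(
        rows,
        columns=["focal_barcode", "matched_barcode",
                 "focal_expr", "matched_expr", "focal_fc", "matched_fc"],
    )
    med_f = float(pairs["focal_fc"].median())
    med_m = float(pairs["matched_fc"].median())
    if med_f <= med_m:
        direction, ratio = "enhanced_repression", (med_m / med_f if med_f > 0 else np.inf)
    else:
        direction, ratio = "attenuated_repression", (med_f / med_m if med_m > 0 else np.inf)
    diffs = pairs["focal_fc"] - pairs["matched_fc"]
    if np.allclose(diffs, 0):
        pvalue = 1.0
    else:
        pvalue = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
    return MatchedComparison(
        pairs=pairs, excluded=excluded,
        median_ratio=float(ratio), direction=direction, pvalue=pvalue,
    )


@dataclass
class MemorySummary:
    mean_fc: float
    sd_fc: float
    n: int
    per_state: pd.DataFrame      # state, n, median_ratio, pvalue


def memory_summary(
    control: pd.Series, tethered_day16: pd.Series,
    states: pd.Series | None = None,
) -> MemorySummary:
    """Fold-change summary after tethering has been lost (day 16).

    Reports mean +/- sd of tethered/control fold change over all reporters
    with detectable control expression, plus a per-state Wilcoxon
    (state vs rest) which, when silencing leaves no mitotic memory, should
    show no significant state dependence.
    """
    eff, _ = compute_effects(
        control, tethered_day16,
        annotations=None if states is None else states.rename("state").to_frame(),
    )
    fc = eff["fc"].dropna()
    rows = []
    if states is not None:
        for state in sorted(pd.unique(states.dropna())):
            cmp_ = state_vs_rest_test(eff, state)
            if cmp_ is not None:
                rows.append((state, cmp_.n_group, cmp_.median_ratio, cmp_.pvalue))
    per_state = pd.DataFrame(rows, columns=["state", "n", "median_ratio", "pvalue"])
    return MemorySummary(
        mean_fc=float(fc.mean()),
        sd_fc=float(fc.std(ddof=1)) if len(fc) > 1 else np.nan,
        n=len(fc),
        per_state=per_state,
    )
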