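"""End-to-end analysis: counts -> collapsed tables -> normalized expression
-> mapped sites -> chromatin-context statistics.

This wires the stage modules together exactly as the assay's data flow
runs: per-sample barcode collapsing, spike-in extraction, spike-anchored
normalization against replicate gDNA cpm, the 100-read gDNA cutoff,
replicate averaging with the zero rule, integration mapping, state/track
overlay, and the comparative statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import barcodes, context, expression, mapping
from .simulate import SimConfig, SimulationResult, simulate_experiment, spike_reference_set


@dataclass
class PipelineResult:
    sites: pd.DataFrame                    # full site table with status/reason
    mapping_summary: mapping.MappingSummary
    mean_expr: dict                        # condition -> combined-replicate Series
    effects: pd.DataFrame
    summary: dict
    state_tests: dict                      # state -> GroupComparison (or None)
    k36_test: context.GroupComparison | None
    occupancy_pearson: tuple               # (r, p, n) within state 7
    expr_spearman: tuple                   # (rho, p, n) over all states
    state_expr_means: pd.Series            # per-state mean control expression
    state_expr_spread: float               # max/min of the above
    memory: context.MemorySummary | None
    kept_barcodes: pd.Index = field(default_factory=lambda: pd.Index([]))


def quantify_samples(
    cdna_tables: dict,
    gdna_tables: dict,
    spike_set,
    min_gdna: int = 100,
    max_dist: int = 2,
) -> tuple[dict, pd.Index]:
    """Collapse, split spike-ins, normalize and apply the gDNA cutoff.

    ``cdna_tables`` maps (condition, replicate) to raw cDNA counts;
    ``gdna_tables`` maps replicate to the library gDNA counts used for
    every condition of that replicate. Returns per-sample normalized
    expression and the barcodes passing the cutoff in all gDNA samples.
    """
    gdna_collapsed = {
        rep: barcodes.collapse_barcodes(tbl, max_dist=max_dist)[0]
        for rep, tbl in gdna_tables.items()
    }
    kept = expression.apply_gdna_cutoff(list(gdna_collapsed.values()), min_gdna=min_gdna)

    norm: dict = {}
    for (cond, rep), tbl in cdna_tables.items():
        collapsed, _ = barcodes.collapse_barcodes(tbl, max_dist=max_dist)
        reporter, spike = barcodes.split_spike_in(collapsed, spike_set)
        spike_sum = float(spike.sum())
        gcpm = expression.cpm(gdna_collapsed[rep])
        norm[(cond, rep)] = expression.normalize_expression(reporter, gcpm, spike_sum)
    return norm, kept


def combine_conditions(norm: dict, kept: pd.Index) -> dict:
    """Replicate-averaged expression per condition, on the kept barcodes."""
    out: dict = {}
    for cond in {c for c, _ in norm}:
        reps = [v.reindex(kept, fill_value=0.0) for (c, r), v in sorted(norm.items()) if c == cond]
        out[cond] = expression.combine_replicates(*reps)
    return out


def run_pipeline(
    sim: SimulationResult,
    seed: int = 0,
    control: str = "control",
    tethered: str = "tethered",
    day16: str | None = "tethered_day16",
) -> PipelineResult:
    """Analyze one simulated experiment exactly as real data would be.

    ``seed`` only randomizes the focal-reporter order of expression
    matching; every other stage is deterministic in its inputs.
    """
    spike_set = spike_reference_set(sim.spike_reference)
    norm, kept = quantify_samples(sim.cdna, sim.gdna, spike_set)
    mean_expr = combine_conditions(norm, kept)

    site_table, map_summary = mapping.map_library(sim.mapping_reads)
    acc = mapping.accepted_sites(site_table)

    universe = kept.intersection(acc.index).sort_values()
    annotations = acc.loc[universe].rename(columns={"position": "pos"})
    annotations["state"] = context.assign_state(
        annotations.rename(columns={"pos": "position"}), sim.states
    )
    occ = sim.occupancy.set_index(["chrom", "pos"])
    keyed = annotations.set_index(["chrom", "pos"], append=True)
    joined = occ.reindex(keyed.index.droplevel(0))
    for col in ("hp1_score", "k36", "k36_score"):
        annotations[col] = joined[col].to_numpy()

    ctrl = mean_expr[control].reindex(universe)
    teth = mean_expr[tethered].reindex(universe)
    effects, summary = context.compute_effects(ctrl, teth, annotations)

    state_tests = {
        s: context.state_vs_rest_test(effects, s)
        for s in sorted(pd.unique(effects["state"].dropna()))
    }
    k36_test = context.mark_subset_test(
        effects, effects["k36"].astype(bool), label="H3K36me3"
    )
    occupancy_pearson = context.covariate_correlation(
        effects, "hp1_score", method="pearson", state=7
    )
    expr_spearman = context.covariate_correlation(
        effects, "control_expr", method="spearman"
    )

    det = effects[effects["control_expr"] > 0]
    state_means = det.groupby("state", observed=True)["control_expr"].mean()
    spread = float(state_means.max() / state_means.min()) if len(state_means) else np.nan

    memory = None
    if day16 is not None and day16 in mean_expr:
        memory = context.memory_summary(
            ctrl, mean_expr[day16].reindex(universe), states=effects["state"]
        )

    return PipelineResult(
        sites=site_table,
        mapping_summary=map_summary,
        mean_expr=mean_expr,
        effects=effects,
        summary=summary,
        state_tests=state_tests,
        k36_test=k36_test,
        occupancy_pearson=occupancy_pearson,
        expr_spearman=expr_spearman,
        state_expr_means=state_means,
        state_expr_spread=spread,
        memory=memory,
        kept_barcodes=kept,
    )


def run_default_metrics(seed: int) -> dict:
    """One full default run and the headline numbers it recovers.

    Simulates the default experiment under ``seed``, analyzes it, and
    returns the summary statistics the assay reports: accepted
    integrations, silencing and twofold-down fractions, mean fold change,
    state-7 and H3K36me3 median-repression ratios, the occupancy and
    expression correlations, the per-state expression spread and the
    day-16 memory summary.
    """
    cfg = SimConfig(seed=seed)
    sim = simulate_experiment(cfg)
    res = run_pipeline(sim, seed=seed)
    s7 = res.state_tests.get(7)
    mem = res.memory
    return {
        "n_reporters": res.summary["n"],
        "n_accepted": res.mapping_summary.n_accepted,
        "rejected_by_reason": dict(res.mapping_summary.rejected_by_reason),
        "frac_down2x": res.summary["frac_down2x"],
        "frac_silenced": res.summary["frac_silenced"],
        "n_up2x": res.summary["n_up2x"],
        "mean_fc_both_detectable": res.summary["mean_fc_both_detectable"],
        "sd_fc_both_detectable": res.summary["sd_fc_both_detectable"],
        "state7_median_ratio": np.nan if s7 is None else s7.median_ratio,
        "k36_median_ratio": np.nan if res.k36_test is None else res.k36_test.median_ratio,
        "occupancy_pearson": res.occupancy_pearson[0],
        "expr_spearman": res.expr_spearman[0],
        "state_expr_spread": res.state_expr_spread,
        "day16_mean_fc": np.nan if mem is None else mem.mean_fc,
        "day16_sd_fc": np.nan if mem is None else mem.sd_fc,
        "day16_state_pvalues": [] if mem is None else list(mem.per_state["pvalue"]),
    }
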