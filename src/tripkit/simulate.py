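"""Seeded generative model of a tethered-TRIP experiment.

Emulates a pool of ~1100 barcoded reporters integrated at random genomic
positions, read out before and after recruiting a heterochromatin protein
(HP1) to each reporter's promoter:

* a genome segmented into nine chromatin states, with pericentromeric
  heterochromatin (state 7) confined to the centromere-proximal third of
  each chromosome arm;
* state-dependent baseline expression spanning more than 30-fold between
  the most active and most repressed states, lognormal within a state;
* a tethering response mixture: 18 % of reporters silenced outright, 52 %
  repressed more than twofold, ~30 % mildly affected and 0.27 % upregulated
  more than twofold, calibrated so that the non-silenced fold changes have
  mean 0.23 and sd ~0.27;
* repression strengthened in state 7 (median fold change halved, and
  coupled to the local HP1 occupancy score so that occupancy and fold
  change correlate at Pearson r = -0.35 within the state) and weakened at
  H3K36me3-marked sites (median fold change x 1.4);
* an independent ~200-barcode spike-in pool contributing 2.5 % of the cDNA
  material, anchoring cross-sample normalization;
* iPCR mapping read tables in which every true barcode passes the mapping
  filters and dedicated decoy barcodes each violate exactly one filter;
* Poisson sequencing counts with barcode substitution errors; and
* a day-16 condition in which silencing memory is lost (fold changes drawn
  around 0.92 +/- 0.53 independent of chromatin state).

All randomness flows from a single master seed; each output draws from a
child stream keyed by a fixed label, so adding outputs never perturbs
existing ones and identical configurations produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .context import ChromatinStateMap

CONDITIONS = ("control", "tethered", "untethered_control", "tethered_day16")

#: fold-change mixture over reporter classes (fractions of all reporters)
DEFAULT_EFFECT_MIXTURE = {
    "p_silenced": 0.18,
    "p_strong": 0.52,
    "p_mild": 0.2973,
    "p_up": 0.0027,
}

#: within-class truncated-lognormal parameters (mu, sigma, low, high),
#: fitted once by moment matching so that jointly with the class weights
#: the non-silenced mixture has mean 0.230 and sd 0.274
#: (see scripts/calibrate_mixture.py)
DEFAULT_CLASS_PARAMS = {
    "strong": (-3.4786, 0.80, 0.0, 0.5),
    "mild": (-4.840187, 0.55, 0.5, 2.0),
    "up": (math.log(2.2), 0.20, 2.0, math.inf),
}

DEFAULT_GENOME = (
    ("chr2L", 8_000_000),
    ("chr2R", 8_000_000),
    ("chr3L", 8_000_000),
    ("chrX", 6_000_000),
)

#: genomic share of each chromatin state
DEFAULT_STATE_WEIGHTS = {
    1: 0.16, 2: 0.11, 3: 0.14, 4: 0.14, 5: 0.13,
    6: 0.10, 7: 0.06, 8: 0.07, 9: 0.09,
}

#: geometric-mean baseline expression per state (arbitrary units); active
#: states 1-2 highest, polycomb state 6 and heterochromatin 7-8 lowest,
#: spanning > 30-fold
DEFAULT_STATE_EXPR_MEANS = {
    1: 9.0, 2: 7.5, 3: 2.8, 4: 1.8, 5: 1.1,
    6: 0.28, 7: 0.42, 8: 0.35, 9: 1.3,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """All knobs of the generative model (defaults = study conditions)."""

    seed: int = 0
    n_integrations: int = 1093
    barcode_length: int = 21
    n_spike_barcodes: int = 200
    spike_fraction: float = 0.025
    genome: tuple = DEFAULT_GENOME
    mean_segment_length: int = 20_000
    state_weights: dict = field(default_factory=lambda: dict(DEFAULT_STATE_WEIGHTS))
    state_expr_means: dict = field(default_factory=lambda: dict(DEFAULT_STATE_EXPR_MEANS))
    expr_dispersion: float = 0.6          # lognormal sigma within a state
    effect_mixture: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MIXTURE))
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    state7_modifier: float = 2.0          # median repression strengthening
    k36_modifier: float = 1.4             # median repression weakening
    k36_states: tuple = (2,)              # states carrying the H3K36me3 mark
    #: logistic slope tilting strong-vs-mild class membership with the
    #: occupancy z-score inside state 7 (marginal mixture preserved);
    #: calibrated so occupancy and fold change correlate at r = -0.35
    occupancy_coupling: float = 0.997
    occ_state7_mean: float = 4.0
    occ_other_mean: float = 1.0
    occ_sd: float = 0.75
    k36_score_high: float = 2.5
    k36_score_low: float = 0.3
    k36_score_sd: float = 0.35
    day16_fc: tuple = (0.92, 0.53)        # (mean, sd) of the memory-loss lognormal
    mean_gdna_depth: float = 2500.0       # reads per barcode, gDNA samples
    mean_cdna_depth: float = 1500.0       # reads per reporter barcode, control cDNA
    spike_gdna_depth: float = 5000.0      # reads per spike barcode, spike-pool gDNA
    spike_abundance_sigma: float = 0.8    # lognormal spread of spike pool complexity
    mutation_rate: float = 0.001          # per-base substitution probability
    n_decoys: int = 4                     # decoy barcodes per mapping-failure class
    min_barcode_separation: int = 5       # pairwise Hamming floor between real barcodes

    def validate(self) -> None:
        for name in ("spike_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        probs = self.effect_mixture
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ConfigError("effect mixture probabilities must be in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ConfigError("effect mixture must sum to 1")
        if self.n_integrations <= 0:
            raise ConfigError("n_integrations must be positive")
        if self.barcode_length < 8:
            raise ConfigError("barcode_length must be at least 8 nt")
        if not self.genome:
            raise ConfigError("genome must have at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ConfigError(f"zero-length chromosome {chrom}")
            if length < 10 * self.mean_segment_length:
                raise ConfigError(
                    f"{chrom} shorter than 10x the mean segment length"
                )
        if set(self.state_weights) != set(self.state_expr_means):
            raise ConfigError("state_weights and state_expr_means must share states")
        if any(w < 0 for w in self.state_weights.values()):
            raise ConfigError("state weights must be non-negative")


def _child_rng(seed: int, *labels) -> np.random.Generator:
    """Independent stream for one output, keyed by a fixed label path."""
    key = zlib.crc32("/".join(str(x) for x in labels).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def pericentromere_start(chrom_length: int) -> int:
    """First coordinate of the designated pericentromeric third (the
    centromere is placed at the end of each simulated chromosome)."""
    return (2 * chrom_length) // 3


def generate_genome_and_states(config: SimConfig) -> ChromatinStateMap:
    """Tile each chromosome with exponential-length state segments.

    State 7 (pericentromeric heterochromatin) is only drawn inside the
    pericentromeric third of each chromosome, where its weight is tripled
    so that its genome-wide share stays near the configured weight; the
    remaining weights are renormalized on either side.
    """
    config.validate()
    rng = _child_rng(config.seed, "states")
    states = np.array(sorted(config.state_weights))
    w = np.array([config.state_weights[s] for s in states], dtype=float)
    w_out = w.copy()
    w_out[states == 7] = 0.0
    w_out /= w_out.sum()
    w_peri = w.copy()
    w_peri[states == 7] *= 3.0
    w_peri /= w_peri.sum()

    rows = []
    for chrom, length in config.genome:
        peri = pericentromere_start(length)
        pos = 0
        while pos < length:
            seg = max(500, int(rng.exponential(config.mean_segment_length)))
            end = min(pos + seg, length)
            p = w_peri if pos >= peri else w_out
            state = int(rng.choice(states, p=p))
            rows.append((chrom, pos, end, state))
            pos = end
    return ChromatinStateMap(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )


def _random_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int
) -> list[str]:
    """Random ACGT barcodes with pairwise Hamming distance >= min_dist.

    The separation floor guarantees that a read mutated by up to
    ``(min_dist - 1) // 2`` substitutions is closer to its parent than to
    any other real barcode, so error collapsing is unambiguous.
    """
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chosen = np.empty((n, length), dtype=np.uint8)
    # any pair closer than min_dist leaves at least one of min_dist
    # equal-width chunks untouched, so an exact-chunk index prunes the
    # pairwise screening to near neighbours only
    bounds = np.linspace(0, length, min_dist + 1).astype(int)
    slices = [slice(int(bounds[i]), int(bounds[i + 1])) for i in range(min_dist)]
    chunk_index: list[dict[bytes, list[int]]] = [{} for _ in slices]
    n_chosen = 0
    while n_chosen < n:
        batch = alphabet[rng.integers(0, 4, size=(max(64, n - n_chosen), length))]
        for row in batch:
            if n_chosen >= n:
                break
            cand: set[int] = set()
            for si, sl in enumerate(slices):
                cand.update(chunk_index[si].get(row[sl].tobytes(), ()))
            if cand:
                rows = chosen[sorted(cand)]
                if int((rows != row).sum(axis=1).min()) < min_dist:
                    continue
            chosen[n_chosen] = row
            for si, sl in enumerate(slices):
                chunk_index[si].setdefault(row[sl].tobytes(), []).append(n_chosen)
            n_chosen += 1
    return [bytes(r).decode() for r in chosen]


DECOY_CLASSES = ("reads", "frac_top", "frac_second", "mapq", "concordance")


def generate_barcode_pools(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    """(truth, spike, decoy) barcode pools, mutually disjoint and
    deterministic given the master seed."""
    rng = _child_rng(config.seed, "barcodes")
    n_decoy = config.n_decoys * len(DECOY_CLASSES)
    n_total = config.n_integrations + config.n_spike_barcodes + n_decoy
    pool = _random_barcodes(
        rng, n_total, config.barcode_length, config.min_barcode_separation
    )
    n1 = config.n_integrations
    n2 = n1 + config.n_spike_barcodes
    return pool[:n1], pool[n1:n2], pool[n2:]


def _truncated_lognormal(
    rng: np.random.Generator, mu: np.ndarray, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Inverse-CDF sampling of lognormal(mu, sigma) restricted to [lo, hi);
    mu may vary per draw (covariate-coupled location)."""
    mu = np.asarray(mu, dtype=float)
    a = np.full_like(mu, -np.inf) if lo <= 0 else (np.log(lo) - mu) / sigma
    b = np.full_like(mu, np.inf) if np.isinf(hi) else (np.log(hi) - mu) / sigma
    # sample in survival-function space: sf/isf stay accurate when the
    # truncation window sits many sigmas into the tail, where cdf/ppf
    # differences near 1 lose all precision
    sf_a, sf_b = norm.sf(a), norm.sf(b)
    s = sf_b + rng.random(mu.shape) * (sf_a - sf_b)
    return np.exp(mu + sigma * norm.isf(s))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logistic_intercept(slope: float, target_mean: float) -> float:
    """Intercept a such that E_z[expit(a + slope * z)] = target_mean for
    standard-normal z (fixed-grid Gaussian quadrature + bisection)."""
    z = np.linspace(-8.0, 8.0, 4001)
    w = norm.pdf(z)
    w /= w.sum()
    from scipy.optimize import brentq

    return float(
        brentq(lambda a: float(np.sum(w * _expit(a + slope * z))) - target_mean, -40, 40)
    )


TRUTH_COLUMNS = [
    "barcode", "chrom", "pos", "strand", "state", "expr", "effect_class",
    "fc", "occupancy", "k36", "k36_score", "day16_fc",
]


def sample_integrations(config: SimConfig, states: ChromatinStateMap) -> pd.DataFrame:
    """Draw the ground truth: sites, states, baseline expression, tethering
    fold changes, occupancy scores and day-16 fold changes per barcode.

    The fold change is drawn independently of baseline expression; inside
    state 7 the strong-vs-mild class balance follows the occupancy z-score
    so that occupancy and fold change correlate negatively, and the
    state-7 / H3K36me3 modifiers shift the median of the repression
    classes.
    """
    config.validate()
    total_len = sum(length for _, length in config.genome)
    if config.n_integrations > total_len:
        raise ConfigError("more integrations requested than genome positions")
    truth_bcs, _, _ = generate_barcode_pools(config)
    rng = _child_rng(config.seed, "integrations")

    chrom_names = [c for c, _ in config.genome]
    chrom_lens = np.array([l for _, l in config.genome], dtype=float)
    p_chrom = chrom_lens / chrom_lens.sum()
    n = config.n_integrations
    seen: set[tuple[int, int]] = set()
    chrom_idx = np.empty(n, dtype=int)
    pos = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        k = n - i
        cis = rng.choice(len(chrom_names), size=k, p=p_chrom)
        pjs = rng.integers(0, chrom_lens[cis].astype(np.int64))
        for ci, pj in zip(cis, pjs):
            key = (int(ci), int(pj))
            if key in seen:
                continue
            seen.add(key)
            chrom_idx[i], pos[i] = key
            i += 1
    chroms = np.array(chrom_names, dtype=object)[chrom_idx]
    strand = np.array(list("+-"))[rng.integers(0, 2, n)]
    state = states.state_at(chroms, pos).astype(int).to_numpy()

    gmean = np.array([config.state_expr_means[s] for s in state])
    expr = gmean * np.exp(config.expr_dispersion * rng.standard_normal(n))

    occ_mean = np.where(state == 7, config.occ_state7_mean, config.occ_other_mean)
    occ_z = rng.standard_normal(n)
    occupancy = occ_mean + config.occ_sd * occ_z
    k36 = np.isin(state, config.k36_states)
    k36_score = (
        np.where(k36, config.k36_score_high, config.k36_score_low)
        + config.k36_score_sd * rng.standard_normal(n)
    )

    mix = config.effect_mixture
    classes = np.array(["silenced", "strong", "mild", "up"])
    cls = classes[
        rng.choice(4, size=n, p=[mix["p_silenced"], mix["p_strong"], mix["p_mild"], mix["p_up"]])
    ]
    # inside state 7, tilt strong-vs-mild membership with the occupancy
    # z-score (a logistic whose intercept preserves the marginal mixture):
    # high local HP1 makes outright strong repression more likely, which
    # couples occupancy and fold change without touching the global
    # class fractions
    p_sm = mix["p_strong"] + mix["p_mild"]
    in7_sm = (state == 7) & np.isin(cls, ("strong", "mild"))
    if config.occupancy_coupling != 0 and p_sm > 0 and in7_sm.any():
        g = config.occupancy_coupling
        a = _logistic_intercept(g, mix["p_strong"] / p_sm)
        p_strong = _expit(a + g * occ_z[in7_sm])
        cls[in7_sm] = np.where(
            rng.random(int(in7_sm.sum())) < p_strong, "strong", "mild"
        )
    fc = np.zeros(n)
    for name in ("strong", "mild", "up"):
        idx = np.flatnonzero(cls == name)
        if not len(idx):
            continue
        mu0, sigma, lo, hi = config.class_params[name]
        mu = np.full(len(idx), float(mu0))
        if name in ("strong", "mild"):       # the repression distribution
            mu[state[idx] == 7] -= math.log(config.state7_modifier)
            mu[k36[idx]] += math.log(config.k36_modifier)
        fc[idx] = _truncated_lognormal(rng, mu, sigma, lo, hi)

    d16_mean, d16_sd = config.day16_fc
    sigma2 = math.log(1.0 + (d16_sd / d16_mean) ** 2)
    day16 = rng.lognormal(math.log(d16_mean) - sigma2 / 2, math.sqrt(sigma2), n)

    return pd.DataFrame(
        {
            "barcode": truth_bcs,
            "chrom": chroms,
            "pos": pos,
            "strand": strand,
            "state": state,
            "expr": expr,
            "effect_class": cls,
            "fc": fc,
            "occupancy": occupancy,
            "k36": k36,
            "k36_score": k36_score,
            "day16_fc": day16,
        },
        columns=TRUTH_COLUMNS,
    )


def _far_position(
    rng: np.random.Generator, config: SimConfig, avoid: list[tuple[str, int]],
    min_gap: int = 5_000,
) -> tuple[str, int]:
    chrom_names = [c for c, _ in config.genome]
    lengths = dict(config.genome)
    while True:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        p = int(rng.integers(0, lengths[chrom] - 1))
        if all(c != chrom or abs(p - q) > min_gap for c, q in avoid):
            return chrom, p


def emit_mapping_reads(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Paired iPCR alignment records for truth barcodes plus decoys.

    Truth barcodes get >= 12 read pairs: most stacked at the exact junction
    (so the weighted modal position is the true site), the rest jittered
    within the clustering windows, and at most ``n // 10`` stray singleton
    pairs at mutually distant positions — guaranteeing every mapping filter
    passes. Decoy barcodes violate exactly one filter each: (a) <= 2 read
    pairs, (b) top-cluster fraction < 80 %, (c) second-cluster fraction
    >= 10 %, (d) top mapq < 10, (e) discordant forward/reverse sites.
    """
    config.validate()
    _, _, decoy_bcs = generate_barcode_pools(config)
    rng = _child_rng(config.seed, "mapping_reads")
    rows: list[tuple] = []

    def emit_top(bc, chrom, p, strand, n_pairs, mapq_lo=20, mapq_hi=43,
                 fwd_jitter=300, rev_jitter=8):
        n_exact = max(1, math.ceil(0.6 * n_pairs))
        for j in range(n_pairs):
            fo = 0 if j < n_exact else int(rng.integers(1, fwd_jitter + 1))
            ro = 0 if j < n_exact else int(rng.integers(1, rev_jitter + 1))
            mq = int(rng.integers(mapq_lo, mapq_hi))
            rows.append((bc, chrom, p + fo, p + ro, strand, mq))

    for t in truth.itertuples(index=False):
        n_pairs = 12 + int(rng.poisson(8))
        k = min(int(rng.binomial(n_pairs, 0.06)), n_pairs // 10)
        emit_top(t.barcode, t.chrom, int(t.pos), t.strand, n_pairs - k)
        placed = [(t.chrom, int(t.pos))]
        for _ in range(k):
            sc, sp = _far_position(rng, config, placed)
            placed.append((sc, sp))
            rows.append((t.barcode, sc, sp, sp, t.strand, 25))

    for ci, cls_name in enumerate(DECOY_CLASSES):
        for d in range(config.n_decoys):
            bc = decoy_bcs[ci * config.n_decoys + d]
            chrom, p = _far_position(rng, config, [])
            strand = "+" if rng.random() < 0.5 else "-"
            if cls_name == "reads":
                emit_top(bc, chrom, p, strand, 2)
            elif cls_name == "frac_top":
                emit_top(bc, chrom, p, strand, 14)
                placed = [(chrom, p)]
                for _ in range(6):
                    sc, sp = _far_position(rng, config, placed)
                    placed.append((sc, sp))
                    rows.append((bc, sc, sp, sp, strand, 25))
            elif cls_name == "frac_second":
                emit_top(bc, chrom, p, strand, 17)
                sc, sp = _far_position(rng, config, [(chrom, p)])
                for _ in range(3):
                    rows.append((bc, sc, sp, sp, strand, 25))
            elif cls_name == "mapq":
                emit_top(bc, chrom, p, strand, 12, mapq_lo=2, mapq_hi=10)
            elif cls_name == "concordance":
                # forward reads pile at the site while reverse reads pile
                # 100 kb away on the same chromosome — the tandem-like
                # signature the concordance filter exists to remove
                length = dict(config.genome)[chrom]
                rp = p + 100_000 if p + 100_000 < length else p - 100_000
                n_exact = math.ceil(0.6 * 12)
                for j in range(12):
                    fo = 0 if j < n_exact else int(rng.integers(1, 301))
                    ro = 0 if j < n_exact else int(rng.integers(1, 9))
                    rows.append((bc, chrom, p + fo, rp + ro, strand, 30))
    df = pd.DataFrame(
        rows, columns=["barcode", "chrom", "fwd_pos", "rev_pos", "strand", "mapq"]
    )
    return df


DEFAULT_REPLICATES = (1, 2)


def _spike_shares(config: SimConfig) -> np.ndarray:
    rng = _child_rng(config.seed, "spike_profile")
    shares = rng.lognormal(0.0, config.spike_abundance_sigma, config.n_spike_barcodes)
    return shares / shares.sum()


def _mutate_barcode(bc: str, d: int, rng: np.random.Generator) -> str:
    seq = list(bc)
    for p in rng.choice(len(seq), size=d, replace=False):
        others = [b for b in "ACGT" if b != seq[p]]
        seq[p] = others[int(rng.integers(0, 3))]
    return "".join(seq)


def _apply_sequencing_errors(
    counts: pd.Series, rate: float, rng: np.random.Generator
) -> pd.Series:
    """Move a binomial share of each barcode's reads onto Hamming-1/2
    mutant barcodes; total count is conserved."""
    if rate <= 0 or counts.empty:
        return counts
    length = len(counts.index[0])
    p_read = 1.0 - (1.0 - rate) ** length
    p1 = length * rate * (1.0 - rate) ** (length - 1)
    p2_given = max(0.0, (p_read - p1) / p_read)
    vals = counts.to_numpy()
    m = rng.binomial(vals, p_read)
    m2 = rng.binomial(m, p2_given)
    m1 = m - m2
    out: dict[str, int] = {}
    for bc, c, a, b in zip(counts.index, vals, m1, m2):
        kept = int(c - a - b)
        if kept:
            out[bc] = out.get(bc, 0) + kept
        if a:
            mut = _mutate_barcode(bc, 1, rng)
            out[mut] = out.get(mut, 0) + int(a)
        if b:
            mut = _mutate_barcode(bc, 2, rng)
            out[mut] = out.get(mut, 0) + int(b)
    return pd.Series(out, dtype="int64").sort_index()


def emit_spike_reference(config: SimConfig) -> pd.Series:
    """gDNA counts of the separately sequenced spike-in pool; the most
    abundant members (> 1000 reads) form the spike extraction list."""
    config.validate()
    _, spike_bcs, _ = generate_barcode_pools(config)
    rng = _child_rng(config.seed, "spike_gdna")
    lam = _spike_shares(config) * config.n_spike_barcodes * config.spike_gdna_depth
    counts = pd.Series(rng.poisson(lam), index=spike_bcs, name="spike_gdna")
    return counts.sort_index()


def spike_reference_set(spike_gdna: pd.Series, min_count: int = 1000) -> pd.Index:
    return spike_gdna.index[spike_gdna > min_count]


def emit_count_tables(
    truth: pd.DataFrame, config: SimConfig, condition: str, replicate: int
) -> tuple[pd.Series, pd.Series]:
    """(cDNA counts, gDNA counts) for one condition and replicate.

    gDNA counts are Poisson around the configured depth, independent of
    expression (one integration copy per reporter), and are keyed only by
    replicate: the same library gDNA normalizes every condition of that
    replicate. cDNA reads are allocated over reporter material
    (baseline expression x condition fold change) plus the spike-in pool's
    fixed material share, at a fixed total sequencing depth per sample; a
    silenced reporter contributes no material and can never yield a read.
    Barcode substitution errors move a small share of reads onto
    Hamming-1/2 mutants. Zero-count barcodes are omitted, as in a real
    count table.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    config.validate()
    _, spike_bcs, _ = generate_barcode_pools(config)

    g_rng = _child_rng(config.seed, "gdna", replicate)
    gdna = pd.Series(
        g_rng.poisson(config.mean_gdna_depth, len(truth)),
        index=list(truth["barcode"]),
        name=f"gdna_rep{replicate}",
    )
    gdna = _apply_sequencing_errors(gdna, config.mutation_rate, g_rng)
    gdna = gdna[gdna > 0]

    c_rng = _child_rng(config.seed, "cdna", condition, replicate)
    if condition in ("control", "untethered_control"):
        cond_fc = np.ones(len(truth))
    elif condition == "tethered":
        cond_fc = truth["fc"].to_numpy()
    else:  # tethered_day16
        cond_fc = truth["day16_fc"].to_numpy()

    expr = truth["expr"].to_numpy()
    material = expr * cond_fc
    f = config.spike_fraction
    spike_total = f / (1.0 - f) * expr.sum()   # fixed cell amount, sized on control
    spike_material = spike_total * _spike_shares(config)
    total_material = material.sum() + spike_total
    total_reads = config.n_integrations * config.mean_cdna_depth / (1.0 - f)
    lam = np.concatenate([material, spike_material]) * (total_reads / total_material)
    cdna = pd.Series(
        c_rng.poisson(lam),
        index=list(truth["barcode"]) + list(spike_bcs),
        name=f"cdna_{condition}_rep{replicate}",
    )
    cdna = cdna[cdna > 0]
    cdna = _apply_sequencing_errors(cdna, config.mutation_rate, c_rng)
    cdna.name = f"cdna_{condition}_rep{replicate}"
    return cdna, gdna


def emit_occupancy_track(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-site score table: HP1 occupancy (fourfold enriched in state 7
    under the defaults) and the H3K36me3 indicator/score at each
    integration site."""
    return pd.DataFrame(
        {
            "chrom": truth["chrom"].to_numpy(),
            "pos": truth["pos"].to_numpy(),
            "hp1_score": truth["occupancy"].to_numpy(),
            "k36": truth["k36"].astype(int).to_numpy(),
            "k36_score": truth["k36_score"].to_numpy(),
        }
    )


@dataclass
class SimulationResult:
    """Everything one simulated experiment emits, in memory."""

    config: SimConfig
    states: ChromatinStateMap
    truth: pd.DataFrame
    mapping_reads: pd.DataFrame
    occupancy: pd.DataFrame
    spike_reference: pd.Series
    cdna: dict               # (condition, replicate) -> counts
    gdna: dict               # replicate -> counts


def simulate_experiment(
    config: SimConfig,
    conditions: tuple = ("control", "tethered", "tethered_day16"),
    replicates: tuple = DEFAULT_REPLICATES,
) -> SimulationResult:
    """Run the full generative model for the requested conditions."""
    config.validate()
    states = generate_genome_and_states(config)
    truth = sample_integrations(config, states)
    reads = emit_mapping_reads(truth, config)
    occupancy = emit_occupancy_track(truth, config)
    spike_ref = emit_spike_reference(config)
    cdna: dict = {}
    gdna: dict = {}
    for rep in replicates:
        for cond in conditions:
            c, g = emit_count_tables(truth, config, cond, rep)
            cdna[(cond, rep)] = c
            gdna[rep] = g
    return SimulationResult(
        config=config, states=states, truth=truth, mapping_reads=reads,
        occupancy=occupancy, spike_reference=spike_ref, cdna=cdna, gdna=gdna,
    )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["genome"] = [[c, int(l)] for c, l in config.genome]
    d["class_params"] = {
        k: [v[0], v[1], v[2], ("inf" if math.isinf(v[3]) else v[3])]
        for k, v in config.class_params.items()
    }
    d["k36_states"] = list(config.k36_states)
    d["day16_fc"] = list(config.day16_fc)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "genome" in d:
        d["genome"] = tuple((c, int(l)) for c, l in d["genome"])
    if "class_params" in d:
        d["class_params"] = {
            k: (v[0], v[1], v[2], (math.inf if v[3] == "inf" else float(v[3])))
            for k, v in d["class_params"].items()
        }
    if "k36_states" in d:
        d["k36_states"] = tuple(d["k36_states"])
    if "day16_fc" in d:
        d["day16_fc"] = tuple(d["day16_fc"])
    if "state_weights" in d:
        d["state_weights"] = {int(k): float(v) for k, v in d["state_weights"].items()}
    if "state_expr_means" in d:
        d["state_expr_means"] = {int(k): float(v) for k, v in d["state_expr_means"].items()}
    return SimConfig(**d)
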