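"""Synthetic MA-experiment generator.

Generates a random bacterial-style draft genome (target GC, tiled CDS,
prophage islands, planted simple-sequence repeats), mutational histories for
replicate MA lines, noisy per-site read summaries, and fluctuation assays —
everything the analysis consumes, with known ground truth.

Mutations are placed as end-state Poisson draws, not generation-by-generation
histories: the MA estimators only observe end states, so per-line histories
are exchangeable.  The per-site substitution rate is

    lambda(site) = r_class(ref base) x context multiplier x topology
                   multiplier x generations,

with the class rates solved from the configured genomic mean rate, the
transition:transversion ratio, and the GC->AT : AT->GC rate ratio; the joint
context x topology multiplier field is normalized to mean 1 over the genome
so the configured mean rate is exact.  Selection is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import ReadSummaryMatrix
from .context import TRIPLETS, load_reference_context_rates
from .fluctuation import FluctuationAssay
from .genome import BASES, AnnotationSet, CDSFeature, ReferenceGenome, \
    ReplichoreMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_genome",
    "simulate_ma",
    "simulate_read_summaries",
    "simulate_fluctuation",
    "class_rates",
    "site_rate_field",
]

_TS_PARTNER = np.array([2, 3, 0, 1])      # A<->G, C<->T


@dataclass
class SimulationConfig:
    """Study conditions of the emulated MA experiment (defaults follow the
    mutator-strain design: 45 lines, ~5,240 generations, ~60% GC)."""

    genome_length: int = 1_000_000
    gc_target: float = 0.6071
    n_lines: int = 45
    generations: float = 5240.0
    base_sub_rate: float = 2.34e-8          # per site per generation
    ts_tv_ratio: float = 39.14
    gc_at_vs_at_gc_rate_ratio: float = 0.67
    context_multipliers: np.ndarray | None = None   # None -> published profile
    topology_amplitude: float = 0.5         # peak at terminus, trough at origin
    indel_rate: float = 1.65e-9
    indel_ssr_fraction: float = 0.9773
    insertion_bias: float = 0.6
    cds_fraction: float = 0.9153
    cds_mean_length: int = 828              # bp, multiple of 3
    prophage_fraction: float = 0.05
    prophage_piece: int = 20_000
    ssr_density: float = 0.01               # genome fraction in planted SSRs
    depth_mean: float = 82.72
    per_read_error: float = 0.0039
    paralog_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("base_sub_rate", "indel_rate", "depth_mean",
                     "per_read_error", "topology_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cds_fraction", "prophage_fraction", "ssr_density",
                     "paralog_fraction", "indel_ssr_fraction", "gc_target"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cds_fraction + 0 > 1:
            raise ValueError("coverage fraction > 1")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")

    def resolved_context_multipliers(self) -> np.ndarray:
        if self.context_multipliers is None:
            ref = load_reference_context_rates()
            vec = np.array([ref[t] for t in TRIPLETS], dtype=float)
        else:
            vec = np.asarray(self.context_multipliers, dtype=float)
            if vec.shape != (64,):
                raise ValueError("context_multipliers must be a 64-vector")
            if (vec < 0).any():
                raise ValueError("context multipliers must be >= 0")
        return vec / vec.mean()

    def line_ids(self) -> list[str]:
        return [f"line{i + 1:02d}" for i in range(self.n_lines)]


@dataclass
class GroundTruth:
    """Planted mutations per line, with the per-line analyzed-site mask."""

    substitutions: pd.DataFrame      # line_id, position, ref, alt
    indels: pd.DataFrame             # line_id, position, kind, seq
    analyzed_mask: np.ndarray | None = None

    def __post_init__(self):
        sub = self.substitutions
        if len(sub):
            if (sub["ref"] == sub["alt"]).any():
                raise ValueError("ground truth contains ref == alt")
            if sub.duplicated(["line_id", "position"]).any():
                raise ValueError("duplicate (line, position) in ground truth")


def _rng(config_or_seed, stage: int, rng: np.random.Generator | None):
    if rng is not None:
        return rng
    seed = config_or_seed.seed if isinstance(config_or_seed, SimulationConfig) \
        else config_or_seed
    return np.random.default_rng([int(seed) % (2 ** 31), stage])


# -- genome generation ---------------------------------------------------------


def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[ReferenceGenome, AnnotationSet]:
    """Random genome with tiled CDS, prophage islands, and planted SSRs."""
    rng = _rng(config, 0, rng)
    L = config.genome_length
    g = config.gc_target
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    codes = rng.choice(4, size=L, p=p).astype(np.uint8)

    # plant SSR tracts (slippage-prone loci for indels)
    ssr_intervals: list[tuple[int, int]] = []
    target_bp = int(config.ssr_density * L)
    planted = 0
    while planted < target_bp:
        unit_len = int(rng.integers(1, 4))
        copies = int(rng.integers(6, 11)) if unit_len == 1 else \
            int(rng.integers(3, 6))
        span = unit_len * copies
        start = int(rng.integers(0, L - span))
        unit = rng.choice(4, size=unit_len, p=p)
        codes[start:start + span] = np.tile(unit, copies)
        ssr_intervals.append((start, start + span))
        planted += span

    seq = bytes(np.frombuffer(b"ACGT", np.uint8)[codes]).decode("ascii")

    # tile CDS/gap alternation to hit the target coding fraction
    cds: list[CDSFeature] = []
    mean_gap = max(1.0, config.cds_mean_length *
                   (1 / config.cds_fraction - 1)) if config.cds_fraction else L
    pos = int(rng.integers(0, int(mean_gap) + 1))
    while config.cds_fraction > 0 and pos < L - 90:
        n_codons = max(30, int(round(rng.normal(config.cds_mean_length / 3,
                                                config.cds_mean_length / 9))))
        glen = min(3 * n_codons, L - pos - (L - pos) % 3)
        if glen < 90:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        first = seq[pos:pos + 3] if strand == "+" else None
        cds.append(CDSFeature(pos, pos + glen, strand, 0, first))
        pos += glen + max(1, int(rng.exponential(mean_gap)))

    # prophage islands, non-overlapping
    prophages: list[tuple[int, int]] = []
    n_pieces = int(round(config.prophage_fraction * L / config.prophage_piece))
    attempts = 0
    while len(prophages) < n_pieces and attempts < 100 * max(n_pieces, 1):
        attempts += 1
        s = int(rng.integers(0, L - config.prophage_piece))
        e = s + config.prophage_piece
        if all(e <= ps or s >= pe for ps, pe in prophages):
            prophages.append((s, e))
    prophages.sort()

    genome = ReferenceGenome([("scaffold_1", seq)], origin_pos=0,
                             terminus_pos=L // 2)
    annotations = AnnotationSet(cds, prophages, ssr_intervals)
    return genome, annotations


# -- substitution machinery ----------------------------------------------------


def class_rates(config: SimulationConfig, gc: float) -> dict[str, float]:
    """Per-site per-generation class rates solved from the configured means.

    u1: AT->GC transition rate per A:T site; u2 = ratio x u1 per G:C site;
    v: each of the four transversion classes per source site.
    """
    mu, R, rho = config.base_sub_rate, config.ts_tv_ratio, \
        config.gc_at_vs_at_gc_rate_ratio
    s_ts = mu * R / (1 + R)
    s_tv = mu / (1 + R)
    u1 = s_ts / ((1 - gc) + gc * rho)
    return {"u1": u1, "u2": rho * u1, "v": s_tv / 2}


def _context_multiplier_field(genome: ReferenceGenome,
                              vec: np.ndarray) -> np.ndarray:
    """Per-site context multiplier from the leading-strand triplet."""
    L = genome.total_length
    rmap = ReplichoreMap.from_genome(genome)
    codes = genome.codes.astype(np.int64)
    prev_i = (np.arange(L) - 1) % L
    next_i = (np.arange(L) + 1) % L
    a, b, c = codes[prev_i], codes, codes[next_i]
    comp = np.array([3, 2, 1, 0, 4])
    left = np.asarray(rmap.replichore_of(np.arange(L))) == "left"
    idx = np.where(left,
                   16 * comp[np.minimum(c, 4)] + 4 * comp[b] + comp[a],
                   16 * a + 4 * b + c)
    valid = (a < 4) & (b < 4) & (c < 4)
    out = np.ones(L)
    out[valid] = vec[idx[valid].astype(int)]
    return out


def _topology_multiplier_field(genome: ReferenceGenome,
                               amplitude: float) -> np.ndarray:
    """Mean-1 cosine profile: trough at the origin, peak at the terminus."""
    L = genome.total_length
    if amplitude == 0:
        return np.ones(L)
    theta = 2 * np.pi * ((np.arange(L) - genome.origin_pos) % L) / L
    prof = 1.0 - amplitude * np.cos(theta)
    return prof / prof.mean()


def site_rate_field(genome: ReferenceGenome, config: SimulationConfig
                    ) -> np.ndarray:
    """Per-site per-line expected substitution count over the experiment."""
    from .genome import gc_content
    gc = gc_content(genome)
    rates = class_rates(config, gc)
    codes = genome.codes
    per_class = np.where(np.isin(codes, (0, 3)),
                         rates["u1"] + 2 * rates["v"],
                         rates["u2"] + 2 * rates["v"])
    mult = _context_multiplier_field(
        genome, config.resolved_context_multipliers())
    mult = mult * _topology_multiplier_field(genome, config.topology_amplitude)
    mult /= mult.mean()      # keep the genomic mean rate exact
    return per_class * mult * config.generations


def simulate_ma(genome: ReferenceGenome, annotations: AnnotationSet,
                config: SimulationConfig,
                rng: np.random.Generator | None = None) -> GroundTruth:
    """End-state mutational histories for all MA lines."""
    rng = _rng(config, 1, rng)
    L = genome.total_length
    lam = site_rate_field(genome, config) if config.base_sub_rate > 0 else None
    codes = genome.codes.astype(np.int64)
    rates = class_rates(config, float(np.mean(np.isin(codes, (1, 2)))))
    sub_rows = []
    base_arr = np.array(list(BASES))
    for line in config.line_ids():
        if lam is None:
            continue
        total = lam.sum()
        n_mut = rng.poisson(total)
        if n_mut == 0:
            continue
        pos = rng.choice(L, size=n_mut, replace=True, p=lam / total)
        # multiple hits at one site collapse to the last drawn state
        _, keep_rev = np.unique(pos[::-1], return_index=True)
        pos = pos[::-1][keep_rev]
        ref = codes[pos]
        is_at = np.isin(ref, (0, 3))
        p_ts = np.where(is_at,
                        rates["u1"] / (rates["u1"] + 2 * rates["v"]),
                        rates["u2"] / (rates["u2"] + 2 * rates["v"]))
        ts = rng.random(len(pos)) < p_ts
        alt = np.empty(len(pos), dtype=np.int64)
        alt[ts] = _TS_PARTNER[ref[ts]]
        # transversion: pick one of the two non-self, non-transition bases
        tv = ~ts
        choice = rng.integers(0, 2, size=tv.sum())
        tv_opts = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])  # per ref code
        alt[tv] = tv_opts[ref[tv], choice]
        for p_, r_, a_ in zip(pos.tolist(), ref.tolist(), alt.tolist()):
            sub_rows.append((line, p_, BASES[r_], BASES[a_]))

    subs = pd.DataFrame(sub_rows,
                        columns=["line_id", "position", "ref", "alt"])

    # indels, concentrated in SSR tracts
    indel_rows = []
    ssr_positions = np.concatenate(
        [np.arange(s, e) for s, e in annotations.ssr_intervals]) \
        if annotations.ssr_intervals else np.empty(0, dtype=int)
    mean_indels = config.indel_rate * L * config.generations
    for line in config.line_ids():
        n_ind = rng.poisson(mean_indels) if mean_indels > 0 else 0
        for _ in range(n_ind):
            in_ssr = (len(ssr_positions) > 0 and
                      rng.random() < config.indel_ssr_fraction)
            p_ = int(rng.choice(ssr_positions)) if in_ssr else \
                int(rng.integers(1, L - 30))
            length = int(rng.integers(1, 4))
            if rng.random() < config.insertion_bias:
                seq = genome.sequence[p_:p_ + length]   # local duplication
                kind = "insertion"
            else:
                seq = genome.sequence[p_:p_ + length]
                kind = "deletion"
            indel_rows.append((line, p_, kind, seq))
    indels = pd.DataFrame(indel_rows,
                          columns=["line_id", "position", "kind", "seq"])
    mask = np.ones((config.n_lines, L), dtype=bool)
    return GroundTruth(subs, indels, mask)


# -- sequencing layer ----------------------------------------------------------


def simulate_read_summaries(genome: ReferenceGenome, truth: GroundTruth,
                            config: SimulationConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[ReadSummaryMatrix, pd.DataFrame]:
    """Noisy per-line, per-site strand-split read counts plus indel summaries.

    Depth is Poisson per line x site, read strands are Bernoulli(1/2), and
    each read reports the line's true base miscalled to a uniformly chosen
    other base with probability ``per_read_error``.  A configurable fraction
    of sites receives a paralog-like second allele at 20-50% of reads in
    every line.
    """
    rng = _rng(config, 2, rng)
    L = genome.total_length
    lines = config.line_ids()
    nl = len(lines)
    line_index = {l: i for i, l in enumerate(lines)}

    true = np.broadcast_to(genome.codes, (nl, L)).copy()
    if len(truth.substitutions):
        li = truth.substitutions["line_id"].map(line_index).to_numpy()
        pos = truth.substitutions["position"].to_numpy()
        alt = np.array([BASES.index(a) for a in truth.substitutions["alt"]])
        true[li, pos] = alt

    depth = rng.poisson(config.depth_mean, size=(nl, L)).astype(np.int64)
    e = config.per_read_error
    if e > 0:
        nerr = rng.binomial(depth, e)
    else:
        nerr = np.zeros_like(depth)
    correct = depth - nerr
    b1 = rng.binomial(nerr, 1 / 3)
    rest = nerr - b1
    b2 = rng.binomial(rest, 1 / 2)
    b3 = rest - b2

    counts_base = np.zeros((nl, L, 4), dtype=np.int64)
    for t in range(4):
        mask = true == t
        others = [x for x in range(4) if x != t]
        counts_base[..., t][mask] += correct[mask]
        counts_base[..., others[0]][mask] += b1[mask]
        counts_base[..., others[1]][mask] += b2[mask]
        counts_base[..., others[2]][mask] += b3[mask]

    # paralog cross-mapping: a second allele at 20-50% of reads, every line
    n_par = int(round(config.paralog_fraction * L))
    if n_par:
        sites = rng.choice(L, size=n_par, replace=False)
        for s in sites:
            ref_code = int(genome.codes[s])
            alt_opts = [x for x in range(4) if x != ref_code]
            alt_code = int(rng.choice(alt_opts))
            frac = rng.uniform(0.2, 0.5)
            for li_ in range(nl):
                tb = int(true[li_, s])
                moved = int(rng.binomial(counts_base[li_, s, tb], frac))
                counts_base[li_, s, tb] -= moved
                counts_base[li_, s, alt_code] += moved

    fwd = rng.binomial(counts_base, 0.5)
    counts = np.stack([fwd, counts_base - fwd], axis=-1).astype(np.int32)
    matrix = ReadSummaryMatrix(counts, lines)

    # indel-allele read summaries: supporting reads displace reference reads
    ind_rows = []
    for rec in truth.indels.itertuples(index=False):
        li_ = line_index[rec.line_id]
        s = int(rec.position)
        tb = int(true[li_, s])
        site_depth = int(matrix.counts[li_, s].sum())
        supp = int(rng.binomial(site_depth, rng.uniform(0.5, 0.8)))
        take_f = min(int(matrix.counts[li_, s, tb, 0]), supp // 2)
        take_r = min(int(matrix.counts[li_, s, tb, 1]), supp - supp // 2)
        matrix.counts[li_, s, tb, 0] -= take_f
        matrix.counts[li_, s, tb, 1] -= take_r
        supp_f = int(rng.binomial(supp, 0.5))
        ind_rows.append((rec.line_id, s, rec.kind, rec.seq,
                         supp_f, supp - supp_f))
    indel_summaries = pd.DataFrame(
        ind_rows, columns=["line_id", "position", "kind", "seq", "fwd", "rev"])
    return matrix, indel_summaries


# -- fluctuation assays --------------------------------------------------------


def simulate_fluctuation(n0: int, nt: float, mu_per_generation: float,
                         n_replicates: int,
                         seed: int | np.random.Generator = 0
                         ) -> FluctuationAssay:
    """Synchronous binary-fission Luria-Delbrueck cultures.

    The population doubles each generation from ``n0`` until it reaches
    ``nt``; each division mutates with probability ``mu_per_generation``, and
    each mutant lineage thereafter doubles deterministically.
    """
    if not (nt > n0 >= 1):
        raise ValueError("need nt > n0 >= 1")
    if mu_per_generation < 0:
        raise ValueError("mutation rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(int(seed) % (2 ** 31))
    g = int(np.ceil(np.log2(nt / n0)))
    n_final = n0 * 2 ** g
    counts = np.zeros(n_replicates, dtype=np.int64)
    for i in range(1, g + 1):
        divisions = n0 * 2 ** (i - 1)
        new = rng.poisson(divisions * mu_per_generation, size=n_replicates)
        counts += new * 2 ** (g - i)
    return FluctuationAssay(counts.tolist(), float(n_final),
                            plated_fraction=1.0, n_initial=float(n0))
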