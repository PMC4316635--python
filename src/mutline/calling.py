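"""Consensus mutation calling across replicate MA lines.

The caller compares, at every site, each line's own read consensus against the
consensus pooled over all lines; a mutation is a line consensus that differs
from the overall consensus.  Sites are screened by a paralog (apparent
heterozygosity) filter and by strand-support requirements before being
counted as analyzed — the analyzed-site count is the denominator of every
downstream rate.

All fraction thresholds are strict (">") and are evaluated in integer
arithmetic so the boundary semantics are exact:

* overall consensus: pooled count of a base strictly > 50% of pooled depth;
* line consensus: count strictly > 80% of the line's depth;
* paralog drop: within-line minor-allele fraction strictly > 20%
  (configurable to a pooled-across-lines check);
* indel call: supporting reads strictly > 30% of the line's total reads,
  with at least 3 forward and 3 reverse supporting reads.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, ReferenceGenome

__all__ = [
    "SiteReadSummary",
    "ReadSummaryMatrix",
    "CallerConfig",
    "CallResult",
    "overall_consensus",
    "line_consensus",
    "paralog_filter",
    "call_substitutions",
    "call_indels",
    "estimate_sequencing_error",
    "classify_indel_context",
    "SSRConfig",
]

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SiteReadSummary:
    """Quality-passed read counts for one line at one site, split by strand."""

    line_id: str
    position: int                       # 0-based concatenated coordinate
    counts: np.ndarray                  # shape (4, 2): base x (fwd, rev)

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the consensus caller (defaults follow the MA protocol)."""

    overall_consensus_min: float = 0.50     # strict
    line_consensus_min: float = 0.80        # strict
    min_fwd: int = 3
    min_rev: int = 3
    paralog_minor_max: float = 0.20         # strict drop above this
    paralog_scope: str = "line"             # "line" or "pooled"
    indel_support_min_frac: float = 0.30    # strict
    indel_min_fwd: int = 3
    indel_min_rev: int = 3
    indel_max_len: int = 27                 # events must be < 28 bp

    def __post_init__(self):
        for name in ("overall_consensus_min", "line_consensus_min",
                     "paralog_minor_max", "indel_support_min_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("min_fwd", "min_rev", "indel_min_fwd", "indel_min_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.paralog_scope not in ("line", "pooled"):
            raise ValueError("paralog_scope must be 'line' or 'pooled'")


class ReadSummaryMatrix:
    """Dense per-line, per-site read counts: shape (n_lines, n_sites, 4, 2).

    ``positions`` maps the site axis to concatenated genome coordinates
    (defaults to 0..n_sites-1).  Sites absent from the matrix are simply
    unanalyzed.
    """

    TSV_COLUMNS = ["line_id", "scaffold", "pos",
                   "A_fwd", "A_rev", "C_fwd", "C_rev",
                   "G_fwd", "G_rev", "T_fwd", "T_rev"]

    def __init__(self, counts: np.ndarray, line_ids: list[str],
                 positions: np.ndarray | None = None):
        counts = np.asarray(counts)
        if counts.ndim != 4 or counts.shape[2:] != (4, 2):
            raise ValueError("counts must have shape (n_lines, n_sites, 4, 2)")
        if (counts < 0).any():
            raise ValueError("read counts must be non-negative")
        if len(line_ids) != counts.shape[0]:
            raise ValueError("line_ids length mismatch")
        self.counts = counts
        self.line_ids = list(line_ids)
        if positions is None:
            positions = np.arange(counts.shape[1], dtype=np.int64)
        self.positions = np.asarray(positions, dtype=np.int64)
        if self.positions.shape != (counts.shape[1],):
            raise ValueError("positions length mismatch")

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def site(self, line_id: str, position: int) -> SiteReadSummary:
        li = self.line_ids.index(line_id)
        si = int(np.searchsorted(self.positions, position))
        if si >= self.n_sites or self.positions[si] != position:
            raise KeyError(f"position {position} not in matrix")
        return SiteReadSummary(line_id, position, self.counts[li, si])

    # ---- TSV interchange (1-based positions) --------------------------------

    def to_tsv(self, path, genome: ReferenceGenome | None = None) -> None:
        rows = []
        for li, line in enumerate(self.line_ids):
            for si in range(self.n_sites):
                pos = int(self.positions[si])
                if genome is not None:
                    scaff, off = genome.locate(pos)
                    pos1 = off + 1
                else:
                    scaff, pos1 = "genome", pos + 1
                c = self.counts[li, si]
                rows.append([line, scaff, pos1, *c.reshape(-1).tolist()])
        pd.DataFrame(rows, columns=self.TSV_COLUMNS).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome: ReferenceGenome | None = None
                 ) -> "ReadSummaryMatrix":
        df = pd.read_csv(path, sep="\t")
        missing = set(cls.TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"summary TSV missing columns {sorted(missing)}")
        if genome is not None:
            pos = np.array([genome.concat_coord(s, p - 1)
                            for s, p in zip(df["scaffold"], df["pos"])])
        else:
            pos = df["pos"].to_numpy() - 1
        line_ids = sorted(df["line_id"].astype(str).unique())
        upos = np.unique(pos)
        counts = np.zeros((len(line_ids), len(upos), 4, 2), dtype=np.int64)
        li = pd.Series(range(len(line_ids)), index=line_ids)[
            df["line_id"].astype(str)].to_numpy()
        si = np.searchsorted(upos, pos)
        block = df[cls.TSV_COLUMNS[3:]].to_numpy().reshape(-1, 4, 2)
        counts[li, si] = block
        return cls(counts, line_ids, upos)


# -- definitional per-site operations -----------------------------------------


def _as_base_counts(counts) -> np.ndarray:
    """Accept a {base: n} dict, a (4,) array, or a (4,2) strand-split array."""
    if isinstance(counts, dict):
        arr = np.zeros(4, dtype=np.int64)
        for b, n in counts.items():
            arr[_BASE_IDX[b]] = n
        return arr
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim == 2:
        arr = arr.sum(axis=-1)
    return arr


def _pool_to_base_vector(counts) -> np.ndarray:
    """Pool a dict / (4,) / (4,2) / (L,4) / (L,4,2) table to a (4,) vector."""
    if isinstance(counts, dict):
        return _as_base_counts(counts)
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim >= 2 and arr.shape[-1] == 2:
        arr = arr.sum(axis=-1)
    while arr.ndim > 1:
        arr = arr.sum(axis=0)
    if arr.shape != (4,):
        raise ValueError("expected a base-count table with a 4-base axis")
    return arr


def overall_consensus(counts) -> str | None:
    """Base whose pooled count strictly exceeds half the pooled depth.

    ``counts`` may be a {base: count} dict or an array pooled over all lines
    and strands; an array of shape (n_lines, 4[, 2]) is pooled first.
    """
    arr = _pool_to_base_vector(counts)
    depth = arr.sum()
    if depth == 0:
        return None
    top = int(arr.argmax())
    return BASES[top] if 2 * arr[top] > depth else None


def line_consensus(counts) -> str | None:
    """Base with count strictly > 80% of one line's depth at the site."""
    arr = _as_base_counts(counts)
    depth = arr.sum()
    if depth == 0:
        return None
    top = int(arr.argmax())
    return BASES[top] if 5 * arr[top] > 4 * depth else None


def paralog_filter(per_line_counts, minor_max: float = 0.20,
                   scope: str = "line") -> bool:
    """True (keep) unless the minor-allele fraction exceeds ``minor_max``.

    Paralogous reads co-mapping to one locus look like heterozygosity in a
    haploid, so the default scope checks the second-most-frequent base within
    each line and drops the site if any line exceeds the threshold.  The
    pooled scope applies the same test to counts summed over lines.

    ``per_line_counts``: dict / (4,) / (4,2) for a single table, or an array
    of shape (n_lines, 4[, 2]).
    """
    arr = np.asarray(per_line_counts if not isinstance(per_line_counts, dict)
                     else _as_base_counts(per_line_counts))
    if arr.ndim == 1:
        tables = arr[None, :]
    elif arr.ndim == 2 and arr.shape == (4, 2):
        tables = arr.sum(axis=-1)[None, :]
    elif arr.ndim == 3:
        tables = arr.sum(axis=-1)
    else:
        tables = arr
    tables = tables.astype(np.int64)
    if scope == "pooled":
        tables = tables.sum(axis=0, keepdims=True)
    srt = np.sort(tables, axis=1)
    minor = srt[:, -2]
    depth = tables.sum(axis=1)
    live = depth > 0
    # strict: minor/depth > minor_max  <=>  minor > minor_max * depth
    drop = np.zeros(len(tables), dtype=bool)
    drop[live] = minor[live] > minor_max * depth[live]
    return not drop.any()


# -- the vectorized caller ----------------------------------------------------


@dataclass
class CallResult:
    """Substitution calls plus the per-line analyzed-site denominators."""

    calls: pd.DataFrame                  # line_id, position, ref, alt, fwd, rev
    analyzed_sites: dict[str, int]
    filter_stats: dict[str, int]
    analyzed_mask: np.ndarray | None = None   # (n_lines, n_sites) bool


def _consensus_arrays(matrix: ReadSummaryMatrix, config: CallerConfig):
    counts = matrix.counts
    line_base = counts.sum(axis=-1)                     # (L, S, 4)
    pooled = line_base.sum(axis=0)                      # (S, 4)
    pooled_depth = pooled.sum(axis=-1)                  # (S,)

    top = pooled.argmax(axis=-1)
    topc = np.take_along_axis(pooled, top[:, None], axis=-1)[:, 0]
    has_overall = topc > config.overall_consensus_min * pooled_depth
    has_overall &= pooled_depth > 0
    overall = np.where(has_overall, top, -1)

    ldepth = line_base.sum(axis=-1)                     # (L, S)
    ltop = line_base.argmax(axis=-1)                    # (L, S)
    ltopc = np.take_along_axis(line_base, ltop[..., None], axis=-1)[..., 0]
    has_line = (ltopc > config.line_consensus_min * ldepth) & (ldepth > 0)
    lcons = np.where(has_line, ltop, -1)
    return line_base, pooled, overall, lcons


def _paralog_keep(matrix: ReadSummaryMatrix, config: CallerConfig) -> np.ndarray:
    line_base = matrix.counts.sum(axis=-1)
    if config.paralog_scope == "pooled":
        tables = line_base.sum(axis=0)[None, ...]       # (1, S, 4)
    else:
        tables = line_base                              # (L, S, 4)
    srt = np.sort(tables, axis=-1)
    minor = srt[..., -2]
    depth = tables.sum(axis=-1)
    drop = (depth > 0) & (minor > config.paralog_minor_max * depth)
    return ~drop.any(axis=0)                            # (S,) keep mask


def call_substitutions(matrix: ReadSummaryMatrix,
                       config: CallerConfig | None = None,
                       genome: ReferenceGenome | None = None) -> CallResult:
    """Call base substitutions and count analyzed sites per line.

    A site is analyzed for a line iff it survives the paralog filter, has an
    overall consensus, the line has its own consensus, and that consensus base
    is supported by at least ``min_fwd`` forward and ``min_rev`` reverse
    reads.  A call is emitted iff the line consensus differs from the overall
    consensus.  Calls shared by more than half the lines are flagged as
    suspect ancestral variants but retained.
    """
    config = config or CallerConfig()
    counts = matrix.counts
    L, S = counts.shape[:2]

    keep = _paralog_keep(matrix, config)
    line_base, pooled, overall, lcons = _consensus_arrays(matrix, config)

    idx = np.maximum(lcons, 0)[..., None, None]
    strand = np.take_along_axis(counts, np.broadcast_to(idx, (L, S, 1, 2)),
                                axis=2)[:, :, 0, :]     # (L, S, 2)
    strand_ok = (strand[..., 0] >= config.min_fwd) & \
                (strand[..., 1] >= config.min_rev)

    analyzed = (keep[None, :] & (overall[None, :] >= 0) & (lcons >= 0)
                & strand_ok)                            # (L, S)
    is_call = analyzed & (lcons != overall[None, :]) & (overall[None, :] >= 0)

    li, si = np.nonzero(is_call)
    positions = matrix.positions[si]
    refs = np.array(list(BASES))[overall[si]]
    alts = np.array(list(BASES))[lcons[li, si]]
    fwd = strand[li, si, 0]
    rev = strand[li, si, 1]
    calls = pd.DataFrame({
        "line_id": [matrix.line_ids[i] for i in li],
        "position": positions,
        "ref": refs,
        "alt": alts,
        "fwd": fwd,
        "rev": rev,
        "type": "substitution",
    })
    # suspect ancestral variants: same site+alt in >50% of lines
    if len(calls):
        grp = calls.groupby(["position", "alt"])["line_id"].transform("size")
        calls["suspect_ancestral"] = grp > L / 2
    else:
        calls["suspect_ancestral"] = pd.Series([], dtype=bool)

    analyzed_sites = {line: int(analyzed[i].sum())
                      for i, line in enumerate(matrix.line_ids)}
    covered = counts.sum(axis=(0, 2, 3)) > 0
    filter_stats = {
        "sites_total": S,
        "sites_with_reads": int(covered.sum()),
        "paralog_dropped": int((~keep & covered).sum()),
        "no_overall_consensus": int((keep & covered & (overall < 0)).sum()),
        "line_sites_no_line_consensus": int(((lcons < 0) & keep[None, :]
                                             & (overall[None, :] >= 0)).sum()),
        "line_sites_strand_fail": int((keep[None, :] & (overall[None, :] >= 0)
                                       & (lcons >= 0) & ~strand_ok).sum()),
        "calls": len(calls),
    }
    return CallResult(calls.sort_values(["position", "line_id"],
                                        ignore_index=True),
                      analyzed_sites, filter_stats, analyzed)


def call_indels(matrix: ReadSummaryMatrix, indel_summaries: pd.DataFrame,
                config: CallerConfig | None = None) -> pd.DataFrame:
    """Call short insertions/deletions from indel-allele read summaries.

    ``indel_summaries`` columns: line_id, position (0-based), kind
    ("insertion"/"deletion"), seq, fwd, rev.  The supporting reads must number
    at least 3 forward and 3 reverse and be strictly more than 30% of the
    line's total reads (base reads + indel reads) at the site.  Alleles of
    28 bp or longer are rejected with a warning column rather than called.
    """
    config = config or CallerConfig()
    required = {"line_id", "position", "kind", "seq", "fwd", "rev"}
    if not required <= set(indel_summaries.columns):
        raise ValueError(f"indel summaries need columns {sorted(required)}")
    if len(indel_summaries) == 0:
        return pd.DataFrame(columns=["line_id", "position", "kind", "seq",
                                     "fwd", "rev", "type"])
    line_pos = {line: i for i, line in enumerate(matrix.line_ids)}
    pos_idx = {int(p): i for i, p in enumerate(matrix.positions)}
    rows = []
    for rec in indel_summaries.itertuples(index=False):
        if len(rec.seq) > config.indel_max_len:
            import warnings
            warnings.warn(f"indel allele of length {len(rec.seq)} at position "
                          f"{rec.position} exceeds {config.indel_max_len} bp; "
                          "rejected", stacklevel=2)
            continue
        support = int(rec.fwd) + int(rec.rev)
        li = line_pos.get(rec.line_id)
        si = pos_idx.get(int(rec.position))
        base_depth = int(matrix.counts[li, si].sum()) if (
            li is not None and si is not None) else 0
        total = base_depth + support
        if (rec.fwd >= config.indel_min_fwd and rec.rev >= config.indel_min_rev
                and 10 * support > 3 * total):    # strict > 30%
            rows.append([rec.line_id, int(rec.position), rec.kind, rec.seq,
                         int(rec.fwd), int(rec.rev), rec.kind])
    return pd.DataFrame(rows, columns=["line_id", "position", "kind", "seq",
                                       "fwd", "rev", "type"])


def estimate_sequencing_error(matrix: ReadSummaryMatrix,
                              config: CallerConfig | None = None) -> dict:
    """Per-base and pooled sequencing-error rates from concordant sites.

    Restricted to sites where every line has a consensus and all line
    consensuses equal the overall consensus; the error rate for consensus base
    X is (#reads != X at X-consensus sites) / (#reads at X-consensus sites).
    """
    config = config or CallerConfig()
    line_base, pooled, overall, lcons = _consensus_arrays(matrix, config)
    concordant = (overall[None, :] >= 0) & (lcons == overall[None, :])
    site_ok = concordant.all(axis=0) & (overall >= 0)
    if not site_ok.any():
        raise ValueError("no sites with all-line concordant consensus")
    result: dict[str, float] = {}
    tot_disc = tot_reads = 0
    for bi, base in enumerate(BASES):
        sel = site_ok & (overall == bi)
        depth = pooled[sel].sum()
        match = pooled[sel][:, bi].sum()
        disc = depth - match
        result[base] = float(disc / depth) if depth else float("nan")
        tot_disc += disc
        tot_reads += depth
    result["pooled"] = float(tot_disc / tot_reads)
    result["n_sites"] = int(site_ok.sum())
    return result


# -- simple-sequence-repeat classification ------------------------------------


@dataclass(frozen=True)
class SSRConfig:
    """What counts as a simple sequence repeat for indel-context calls."""

    max_unit: int = 6          # tandem-repeat unit length <= 6 bp
    min_copies: int = 3        # >= 3 contiguous copies
    min_homopolymer: int = 4   # homopolymer run >= 4


def classify_indel_context(genome: ReferenceGenome | str, position: int,
                           config: SSRConfig | None = None) -> bool:
    """True iff the indel locus lies inside a simple sequence repeat.

    Scans the local sequence for a tandem repeat (unit length <=
    ``max_unit``, at least ``min_copies`` contiguous copies, homopolymers
    needing ``min_homopolymer``) whose footprint covers the position.
    """
    config = config or SSRConfig()
    seq = genome.sequence if isinstance(genome, ReferenceGenome) else genome
    L = len(seq)
    if not (0 <= position < L):
        raise ValueError("position out of bounds")
    radius = config.max_unit * (config.min_copies + 4)
    lo = max(0, position - radius)
    hi = min(L, position + radius + 1)
    window = seq[lo:hi]
    focal = position - lo
    for unit in range(1, config.max_unit + 1):
        need = config.min_homopolymer if unit == 1 else config.min_copies
        for start in range(0, len(window) - unit * need + 1):
            motif = window[start:start + unit]
            if "N" in motif:
                continue
            end = start + unit
            while window[end:end + unit] == motif:
                end += unit
            copies = (end - start) // unit
            if copies >= need and start <= focal < end:
                return True
    return False
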