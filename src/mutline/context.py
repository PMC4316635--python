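"""Trinucleotide-context mutation rates on replichore leading strands.

A site's context is its focal base plus the immediate 5' and 3' neighbors on
the leading strand of its replichore: on the right replichore (origin ->
terminus clockwise) that is the reference strand; on the left replichore the
leading strand is the reverse complement, so the focal base and its flanks
are complement-flipped relative to reference coordinates.  Triplet exposure
is counted with a 3-bp sliding window (1-bp step) over each leading strand,
and each context's mutation count is converted to a rate by dividing by
(triplet count x number of lines x generations).

Sites matching potential methylation motifs (Dam, Dcm, type-I systems) can
be excluded before rate estimation, since methylated sites are known
mutational hotspots that would otherwise confound context effects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BASES, ReferenceGenome, ReplichoreMap, revcomp

__all__ = [
    "TRIPLETS",
    "MethylationMotifSet",
    "ContextRateMatrix",
    "count_triplets",
    "triplet_index",
    "exclude_methylation_sites",
    "context_rates",
    "replichore_comparison",
    "load_reference_context_rates",
]

TRIPLETS = [a + b + c for a in BASES for b in BASES for c in BASES]
_TRIPLET_IDX = {t: i for i, t in enumerate(TRIPLETS)}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

#: REBASE consensus recognition sites; type-I bipartite patterns carry fixed
#: unspecified spacers.
DEFAULT_MOTIFS = {
    "Dam": "GATC",
    "Dcm": "CCWGG",
    "EcoKI": "AACNNNNNNGTGC",
    "EcoBI": "TGANNNNNNNNTGCT",
    "HgiDII": "GRCGYC",
}


def triplet_index(triplet: str) -> int:
    return _TRIPLET_IDX[triplet]


def count_triplets(sequence: str) -> np.ndarray:
    """Overlapping 3-mer counts (64-vector); windows containing N are skipped."""
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one 3-bp window")
    from .genome import encode
    codes = encode(sequence.upper()).astype(np.int64)
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a < 4) & (b < 4) & (c < 4)
    idx = (16 * a + 4 * b + c)[valid]
    return np.bincount(idx, minlength=64)


@dataclass
class MethylationMotifSet:
    """Named IUPAC motifs whose occurrences (both strands) flag positions."""

    motifs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS))
    footprint: str = "motif"     # "motif" (whole occurrence) or "focal_base"

    def __post_init__(self):
        for name, pat in self.motifs.items():
            bad = set(pat.upper()) - set(_IUPAC)
            if bad:
                raise ValueError(f"motif {name!r} has non-IUPAC symbols {bad}")
        if self.footprint not in ("motif", "focal_base"):
            raise ValueError("footprint must be 'motif' or 'focal_base'")

    def _regex(self, pattern: str) -> re.Pattern:
        body = "".join(_IUPAC[ch] for ch in pattern.upper())
        return re.compile(f"(?=({body}))")    # overlapping matches

    def position_mask(self, genome: ReferenceGenome | str) -> np.ndarray:
        """Boolean mask of positions covered by any motif on either strand."""
        seq = genome.sequence if isinstance(genome, ReferenceGenome) else genome
        L = len(seq)
        mask = np.zeros(L, dtype=bool)
        rc = revcomp(seq)
        for pattern in self.motifs.values():
            rx = self._regex(pattern)
            w = len(pattern)
            for m in rx.finditer(seq):
                mask[m.start():m.start() + w] = True
            for m in rx.finditer(rc):
                # map reverse-strand occurrence back to reference coordinates
                end = L - m.start()
                mask[end - w:end] = True
        return mask


def exclude_methylation_sites(calls: pd.DataFrame,
                              genome: ReferenceGenome,
                              motif_set: MethylationMotifSet | None = None
                              ) -> tuple[pd.DataFrame, int]:
    """Drop calls whose focal position falls inside any motif occurrence."""
    if motif_set is None:
        motif_set = MethylationMotifSet()
    if not motif_set.motifs or len(calls) == 0:
        return calls.copy(), 0
    mask = motif_set.position_mask(genome)
    hit = mask[calls["position"].to_numpy()]
    return calls.loc[~hit].reset_index(drop=True), int(hit.sum())


@dataclass
class ContextRateMatrix:
    """Per-replichore 64-context exposures, mutation counts, and rates."""

    triplet_counts: dict[str, np.ndarray]     # replichore -> (64,) exposure
    mutation_counts: dict[str, np.ndarray]    # replichore -> (64,)
    rates: dict[str, np.ndarray]              # replichore -> (64,) per site/gen
    n_lines: int
    generations: float
    n_skipped_edge: int = 0

    @property
    def mean_rates(self) -> np.ndarray:
        """Across-replichore arithmetic mean of the two 64-rate vectors."""
        return (self.rates["left"] + self.rates["right"]) / 2

    @property
    def pooled_rates(self) -> np.ndarray:
        """Rates from pooled counts over both replichores (for comparison)."""
        muts = self.mutation_counts["left"] + self.mutation_counts["right"]
        trips = self.triplet_counts["left"] + self.triplet_counts["right"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = muts / (trips * self.n_lines * self.generations)
        return np.where(trips > 0, out, 0.0)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for rep in ("left", "right"):
            for i, t in enumerate(TRIPLETS):
                rows.append([rep, t, int(self.triplet_counts[rep][i]),
                             int(self.mutation_counts[rep][i]),
                             self.rates[rep][i]])
        return pd.DataFrame(rows, columns=["replichore", "triplet",
                                           "triplet_count", "mutations",
                                           "rate"])


def _leading_triplet_indices(genome: ReferenceGenome, rmap: ReplichoreMap,
                             positions: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """(replichore 0=right/1=left, triplet index) per call; -1 when undefined.

    Arcs are treated as linear: triplets spanning the origin/terminus
    junctions (or containing N) are skipped.
    """
    L = genome.total_length
    codes = genome.codes.astype(np.int64)
    pos = np.asarray(positions, dtype=np.int64)
    left_mask = np.asarray(rmap.replichore_of(pos)) == "left"

    prev_i = (pos - 1) % L
    next_i = (pos + 1) % L
    a, b, c = codes[prev_i], codes[pos], codes[next_i]
    valid = (a < 4) & (b < 4) & (c < 4)
    # flanks must stay inside the same replichore arc
    same_arc = (np.asarray(rmap.replichore_of(prev_i)) ==
                np.asarray(rmap.replichore_of(pos))) & \
               (np.asarray(rmap.replichore_of(next_i)) ==
                np.asarray(rmap.replichore_of(pos)))
    valid &= same_arc

    idx = np.full(len(pos), -1, dtype=np.int64)
    right = valid & ~left_mask
    idx[right] = 16 * a[right] + 4 * b[right] + c[right]
    # left replichore: leading strand is the reverse complement, so the
    # triplet is complement-flipped and read in the opposite direction
    comp = np.array([3, 2, 1, 0, 4])
    left = valid & left_mask
    idx[left] = 16 * comp[c[left]] + 4 * comp[b[left]] + comp[a[left]]
    return np.where(left_mask, 1, 0), idx


def context_rates(calls: pd.DataFrame, genome: ReferenceGenome,
                  replichore_map: ReplichoreMap | None = None,
                  n_lines: int = 45, generations: float = 5240.0
                  ) -> ContextRateMatrix:
    """Context-specific mutation rates on each replichore's leading strand."""
    from .genome import leading_strand_sequence

    rmap = replichore_map or ReplichoreMap.from_genome(genome)
    trip_counts = {
        "right": count_triplets(leading_strand_sequence(genome, rmap, "right")),
        "left": count_triplets(leading_strand_sequence(genome, rmap, "left")),
    }
    mut = {"right": np.zeros(64, dtype=np.int64),
           "left": np.zeros(64, dtype=np.int64)}
    skipped = 0
    if len(calls):
        pos = calls["position"].to_numpy()
        rep, idx = _leading_triplet_indices(genome, rmap, pos)
        skipped = int((idx < 0).sum())
        for code, name in ((0, "right"), (1, "left")):
            sel = (rep == code) & (idx >= 0)
            mut[name] = np.bincount(idx[sel], minlength=64)
    rates = {}
    for name in ("right", "left"):
        exp = trip_counts[name] * n_lines * generations
        if ((trip_counts[name] == 0) & (mut[name] > 0)).any():
            raise ValueError("mutations observed in a context absent from the "
                             f"{name} leading strand; genome/calls mismatch")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = mut[name] / exp
        rates[name] = np.where(trip_counts[name] > 0, r, 0.0)
    return ContextRateMatrix(trip_counts, mut, rates, n_lines,
                             float(generations), skipped)


def replichore_comparison(rates_left, rates_right
                          ) -> tuple[float, float, int]:
    """Paired t-test on ln context rates of the two replichores.

    Pairs where either rate is zero are dropped (reported via the returned
    pair count).  Returns (t, two-sided p, n_pairs).
    """
    a = np.asarray(rates_left, dtype=float)
    b = np.asarray(rates_right, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rate vectors must have identical shape")
    usable = (a > 0) & (b > 0)
    n = int(usable.sum())
    if n < 2:
        raise ValueError("fewer than 2 usable context pairs")
    la, lb = np.log(a[usable]), np.log(b[usable])
    diff = la - lb
    if np.allclose(diff.std(ddof=1), 0):
        if np.allclose(diff.mean(), 0):
            raise ValueError("degenerate comparison: all paired differences "
                             "are identically zero")
        return float(np.inf) * np.sign(diff.mean()), 0.0, n
    t, p = sps.ttest_rel(la, lb)
    return float(t), float(p), n


# -- published reference context-rate matrix ----------------------------------


def load_reference_context_rates() -> dict[str, float]:
    """Published 64-context mutation rates for the MMR-deficient
    *P. fluorescens* mutator strain, in units of 1e-9 per site per generation
    (mean of the two replichore leading strands).
    """
    from .io import read_context_matrix
    ref = resources.files("mutline.data") / "pfluorescens_context_rates.tsv"
    with resources.as_file(ref) as path:
        return read_context_matrix(path)
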