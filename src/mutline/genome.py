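"""Reference-genome and annotation data model.

A draft bacterial assembly is represented as an ordered, oriented list of
scaffolds laid out on a single concatenated circular coordinate system, with
the replication origin and terminus marked.  Every downstream analysis
(region classification, replichore assignment, leading-strand extraction,
GC accounting) runs on this coordinate system.

Coordinates are 0-based half-open internally; 1-based only at GFF/VCF
interchange boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ReferenceGenome",
    "CDSFeature",
    "AnnotationSet",
    "ReplichoreMap",
    "load_genome",
    "gc_content",
    "classify_site",
    "leading_strand_sequence",
    "annotate_substitution_effect",
    "revcomp",
    "CODING",
    "INTERGENIC",
    "OVERLAPPING_OR_GAP",
]

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")

# region-class labels
INTERGENIC = "intergenic"
CODING = "coding"
OVERLAPPING_OR_GAP = "overlapping_or_gap"
_CLASS_CODES = {0: INTERGENIC, 1: CODING, 2: OVERLAPPING_OR_GAP}

# bacterial / archaeal genetic code
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, c in _CODE.items():
        lut[ord(b)] = c
    codes = lut[arr]
    if (codes == 255).any():
        bad = chr(arr[codes == 255][0])
        raise ValueError(f"sequence contains disallowed character {bad!r}; "
                         "only A/C/G/T/N are accepted")
    return codes


@dataclass
class ReferenceGenome:
    """Ordered, oriented scaffolds on a concatenated circular coordinate system."""

    scaffolds: list[tuple[str, str]]
    origin_pos: int = 0
    terminus_pos: int | None = None
    circular: bool = True

    sequence: str = field(init=False, repr=False)
    codes: np.ndarray = field(init=False, repr=False)
    offsets: dict[str, int] = field(init=False, repr=False)
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise ValueError("genome requires at least one scaffold")
        self.offsets = {}
        pos = 0
        parts = []
        for name, seq in self.scaffolds:
            seq = seq.upper()
            if name in self.offsets:
                raise ValueError(f"duplicate scaffold id {name!r}")
            self.offsets[name] = pos
            pos += len(seq)
            parts.append(seq)
        self.sequence = "".join(parts)
        self.codes = encode(self.sequence)
        self.total_length = pos
        if self.terminus_pos is None:
            self.terminus_pos = self.total_length // 2
        for label, p in (("origin_pos", self.origin_pos),
                         ("terminus_pos", self.terminus_pos)):
            if not (0 <= p < self.total_length):
                raise ValueError(f"{label}={p} outside [0, {self.total_length})")

    # -- coordinate transforms ------------------------------------------------

    def concat_coord(self, scaffold: str, offset: int) -> int:
        """Concatenated coordinate of a (scaffold, offset) pair."""
        base = self.offsets[scaffold]
        length = self.scaffold_length(scaffold)
        if not (0 <= offset < length):
            raise ValueError(f"offset {offset} outside scaffold {scaffold!r}")
        return base + offset

    def locate(self, position: int) -> tuple[str, int]:
        """Invert :meth:`concat_coord`."""
        if not (0 <= position < self.total_length):
            raise ValueError(f"position {position} out of bounds")
        for name, seq in self.scaffolds:
            start = self.offsets[name]
            if start <= position < start + len(seq):
                return name, position - start
        raise AssertionError("unreachable")

    def scaffold_length(self, scaffold: str) -> int:
        for name, seq in self.scaffolds:
            if name == scaffold:
                return len(seq)
        raise KeyError(scaffold)

    def scaffold_boundaries(self) -> list[int]:
        """Concatenated start coordinates of each scaffold."""
        return [self.offsets[name] for name, _ in self.scaffolds]

    def cyclic_slice(self, start: int, end: int) -> str:
        """Sequence from start to end walking clockwise; wraps if end <= start."""
        if start <= end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    @property
    def gc_content(self) -> float:
        return gc_content(self)


def load_genome(fasta_path, origin_pos: int = 0, terminus_pos: int | None = None,
                circular: bool = True) -> ReferenceGenome:
    """Load a multi-scaffold FASTA in file order into a :class:`ReferenceGenome`.

    The scaffold order and orientation in the file define the concatenated
    coordinate system, so the FASTA must already be ordered and oriented
    (e.g. by homology to a finished relative).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    scaffolds = [(r.id, str(r.seq).upper()) for r in records]
    return ReferenceGenome(scaffolds, origin_pos=origin_pos,
                           terminus_pos=terminus_pos, circular=circular)


def gc_content(genome: ReferenceGenome | str,
               interval: tuple[int, int] | None = None) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); N excluded on both sides.

    Raises ValueError when the effective interval contains no called bases.
    """
    codes = genome.codes if isinstance(genome, ReferenceGenome) else encode(genome)
    if interval is not None:
        s, e = interval
        if not (0 <= s <= e <= len(codes)):
            raise ValueError(f"interval {interval} out of bounds")
        codes = codes[s:e]
    called = np.count_nonzero(codes < 4)
    if called == 0:
        raise ValueError("no called (non-N) bases in interval")
    gc = np.count_nonzero((codes == 1) | (codes == 2))
    return gc / called


# -- annotations ---------------------------------------------------------------


@dataclass(frozen=True)
class CDSFeature:
    """A protein-coding feature on the concatenated coordinate system."""

    start: int           # 0-based inclusive
    end: int             # exclusive
    strand: str          # "+" or "-"
    frame: int = 0
    start_codon: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty CDS interval")

    def __len__(self) -> int:
        return self.end - self.start


class AnnotationSet:
    """CDS, prophage, SSR, and methylation annotations for one genome.

    A position's region class is deterministic: covered by exactly one CDS
    frame -> coding; by two or more (or an assembly-gap N) ->
    overlapping_or_gap; otherwise intergenic.  The prophage flag is orthogonal
    to the coding/intergenic classification.
    """

    def __init__(self, cds_features: Sequence[CDSFeature] = (),
                 prophage_intervals: Sequence[tuple[int, int]] = (),
                 ssr_intervals: Sequence[tuple[int, int]] = ()):
        self.cds_features = list(cds_features)
        self.prophage_intervals = [tuple(iv) for iv in prophage_intervals]
        self.ssr_intervals = [tuple(iv) for iv in ssr_intervals]
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _check_bounds(self, length: int) -> None:
        for f in self.cds_features:
            if f.start < 0 or f.end > length:
                raise ValueError(f"CDS {f} outside genome of length {length}")
        for s, e in self.prophage_intervals:
            if s < 0 or e > length:
                raise ValueError(f"prophage interval ({s},{e}) out of bounds")

    def region_class_codes(self, genome: ReferenceGenome) -> np.ndarray:
        """uint8 array over the genome: 0 intergenic, 1 coding, 2 overlapping/gap."""
        key = id(genome)
        if key in self._cache:
            return self._cache[key][0]
        L = genome.total_length
        self._check_bounds(L)
        cover = np.zeros(L, dtype=np.int32)
        for f in self.cds_features:
            cover[f.start:f.end] += 1
        cls = np.zeros(L, dtype=np.uint8)
        cls[cover == 1] = 1
        cls[cover >= 2] = 2
        cls[genome.codes == 4] = 2          # assembly gaps
        cds_idx = np.full(L, -1, dtype=np.int32)
        for i, f in enumerate(self.cds_features):
            span = slice(f.start, f.end)
            sel = cover[span] == 1
            idx = cds_idx[span]
            idx[sel] = i
            cds_idx[span] = idx
        self._cache[key] = (cls, cds_idx)
        return cls

    def cds_index(self, genome: ReferenceGenome) -> np.ndarray:
        """Per-position index of the unique covering CDS, -1 elsewhere."""
        self.region_class_codes(genome)
        return self._cache[id(genome)][1]

    def prophage_mask(self, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for s, e in self.prophage_intervals:
            mask[s:e] = True
        return mask

    def coding_fraction(self, genome: ReferenceGenome) -> float:
        cls = self.region_class_codes(genome)
        return float(np.mean(cls == 1))


def classify_site(genome: ReferenceGenome, annotations: AnnotationSet,
                  position: int) -> tuple[str, bool]:
    """Region class of a position plus its prophage flag."""
    if not (0 <= position < genome.total_length):
        raise ValueError(f"position {position} out of bounds")
    cls = annotations.region_class_codes(genome)[position]
    prophage = bool(annotations.prophage_mask(genome.total_length)[position])
    return _CLASS_CODES[int(cls)], prophage


# -- replichores ---------------------------------------------------------------


@dataclass
class ReplichoreMap:
    """Partition of the circular chromosome into the two replication arms.

    The right replichore is the arc from the origin clockwise (increasing
    concatenated coordinate) to the terminus; the left replichore is the
    complement.  Every position maps to exactly one replichore.
    """

    origin_pos: int
    terminus_pos: int
    total_length: int

    def __post_init__(self):
        L = self.total_length
        if not (0 <= self.origin_pos < L and 0 <= self.terminus_pos < L):
            raise ValueError("origin/terminus outside genome")
        if self.origin_pos == self.terminus_pos:
            raise ValueError("origin and terminus coincide")

    @classmethod
    def from_genome(cls, genome: ReferenceGenome) -> "ReplichoreMap":
        return cls(genome.origin_pos, genome.terminus_pos, genome.total_length)

    def replichore_of(self, positions) -> np.ndarray | str:
        """'right' for positions on the origin->terminus clockwise arc."""
        pos = np.asarray(positions)
        L = self.total_length
        arc = (pos - self.origin_pos) % L
        span = (self.terminus_pos - self.origin_pos) % L
        out = np.where(arc < span, "right", "left")
        if np.isscalar(positions) or out.ndim == 0:
            return str(out)
        return out

    def arc_length(self, which: str) -> int:
        span = (self.terminus_pos - self.origin_pos) % self.total_length
        return span if which == "right" else self.total_length - span


def leading_strand_sequence(genome: ReferenceGenome, replichore_map: ReplichoreMap,
                            which: str) -> str:
    """Leading-strand sequence of one replichore.

    The right replichore's leading strand is the reference strand read
    origin -> terminus.  The left replichore is replicated in the opposite
    physical direction, so its leading strand is the reverse complement of the
    terminus -> origin arc read on the reference strand.
    """
    if which not in ("right", "left"):
        raise ValueError("replichore must be 'right' or 'left'")
    o, t = replichore_map.origin_pos, replichore_map.terminus_pos
    if which == "right":
        return genome.cyclic_slice(o, t)
    return revcomp(genome.cyclic_slice(t, o))


# -- substitution functional effects ------------------------------------------


def _translate_codon(codon: str) -> str:
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def annotate_substitution_effect(genome: ReferenceGenome,
                                 annotations: AnnotationSet,
                                 position: int, ref: str, alt: str) -> str:
    """Functional class of a base substitution.

    Returns one of ``synonymous``, ``nonsynonymous``, ``intergenic``,
    ``overlapping_or_gap``.  Codons are read on the CDS strand and translated
    with the bacterial genetic code (translation table 11).  Substitutions in
    an annotated start codon are classed nonsynonymous (initiator codons
    encode fMet regardless of identity, so any change there is a functional
    change).  CDSs whose length is not divisible by three are flagged as
    annotation defects and their sites classed overlapping_or_gap.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical; not a substitution")
    cls = annotations.region_class_codes(genome)[position]
    if cls == 0:
        return INTERGENIC
    if cls == 2:
        return OVERLAPPING_OR_GAP
    cds = annotations.cds_features[annotations.cds_index(genome)[position]]
    if len(cds) % 3 != 0:
        return OVERLAPPING_OR_GAP
    if genome.sequence[position] != ref:
        raise ValueError(
            f"ref base {ref!r} does not match genome at position {position}")
    if cds.strand == "+":
        within = position - cds.start - cds.frame
    else:
        within = (cds.end - 1 - position) - cds.frame
    if within < 0:
        return OVERLAPPING_OR_GAP   # inside the phase-trimmed overhang
    codon_index, codon_pos = divmod(within, 3)
    if cds.strand == "+":
        cstart = cds.start + cds.frame + 3 * codon_index
        codon = genome.sequence[cstart:cstart + 3]
        ref_codon, alt_codon = codon, _subst(codon, codon_pos, alt)
    else:
        cend = cds.end - cds.frame - 3 * codon_index
        codon = revcomp(genome.sequence[cend - 3:cend])
        ref_codon, alt_codon = codon, _subst(codon, codon_pos, revcomp(alt))
    if codon_index == 0 and cds.start_codon is not None:
        return "nonsynonymous"
    aa_ref, aa_alt = _translate_codon(ref_codon), _translate_codon(alt_codon)
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _subst(codon: str, pos: int, base: str) -> str:
    return codon[:pos] + base + codon[pos + 1:]
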