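"""Flat-file interchange: FASTA/GFF3/BED annotations, summary and call
tables, the 16x4 context-matrix layout, fluctuation-assay tables, and a
minimal VCF writer.

Positions are 1-based in every on-disk format (GFF3, BED end-exclusive
start-zero excepted) and 0-based everywhere in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotationSet, BASES, CDSFeature, ReferenceGenome
from .fluctuation import FluctuationAssay

__all__ = [
    "write_genome_fasta",
    "write_annotations_gff3",
    "read_annotations_gff3",
    "read_intervals_bed",
    "write_truth_tsv",
    "write_calls_tsv",
    "write_calls_vcf",
    "read_assay_tsv",
    "write_assay_tsv",
    "read_context_matrix",
    "write_context_matrix",
    "read_codon_usage",
]


def write_genome_fasta(genome: ReferenceGenome, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.scaffolds]
    SeqIO.write(records, str(path), "fasta")


def write_annotations_gff3(annotations: AnnotationSet,
                           genome: ReferenceGenome, path) -> None:
    lines = ["##gff-version 3"]
    for i, f in enumerate(annotations.cds_features):
        scaff, off = genome.locate(f.start)
        lines.append("\t".join([
            scaff, "mutline", "CDS", str(off + 1), str(off + len(f)),
            ".", f.strand, str(f.frame),
            f"ID=cds{i}" + (f";start_codon={f.start_codon}"
                            if f.start_codon else ""),
        ]))
    for i, (s, e) in enumerate(annotations.prophage_intervals):
        scaff, off = genome.locate(s)
        lines.append("\t".join([scaff, "mutline", "prophage", str(off + 1),
                                str(off + (e - s)), ".", ".", ".",
                                f"ID=prophage{i}"]))
    for i, (s, e) in enumerate(annotations.ssr_intervals):
        scaff, off = genome.locate(s)
        lines.append("\t".join([scaff, "mutline", "SSR", str(off + 1),
                                str(off + (e - s)), ".", ".", ".",
                                f"ID=ssr{i}"]))
    Path(path).write_text("\n".join(lines) + "\n")


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def read_annotations_gff3(path, genome: ReferenceGenome) -> AnnotationSet:
    """Read CDS, prophage, and SSR features from a GFF3 file.

    Feature types recognized: ``CDS``; ``prophage`` / ``prophage_region``;
    ``SSR`` / ``repeat_region``.  Coordinates are mapped onto the genome's
    concatenated system via the scaffold column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLS,
                     dtype={"seqid": str})
    cds, prophage, ssr = [], [], []
    for rec in df.itertuples(index=False):
        start = genome.concat_coord(rec.seqid, int(rec.start) - 1)
        end = start + (int(rec.end) - int(rec.start) + 1)
        if rec.type == "CDS":
            phase = 0 if rec.phase in (".", None) else int(rec.phase)
            start_codon = None
            for field in str(rec.attributes).split(";"):
                if field.startswith("start_codon="):
                    start_codon = field.split("=", 1)[1]
            cds.append(CDSFeature(start, end, str(rec.strand), phase,
                                  start_codon))
        elif rec.type in ("prophage", "prophage_region"):
            prophage.append((start, end))
        elif rec.type in ("SSR", "repeat_region"):
            ssr.append((start, end))
    return AnnotationSet(cds, prophage, ssr)


def read_intervals_bed(path, genome: ReferenceGenome) -> list[tuple[int, int]]:
    """BED3 intervals mapped to concatenated coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    out = []
    for rec in df.itertuples(index=False):
        s = genome.concat_coord(rec.chrom, int(rec.start))
        out.append((s, s + int(rec.end) - int(rec.start)))
    return out


def write_truth_tsv(truth, path) -> None:
    subs = truth.substitutions.assign(type="substitution")
    subs = subs.rename(columns={"position": "pos"})
    ind = truth.indels.rename(columns={"position": "pos", "kind": "type"})
    ind = ind.assign(ref=".", alt=ind["seq"])
    cols = ["line_id", "pos", "ref", "alt", "type"]
    out = pd.concat([subs[cols], ind[cols]], ignore_index=True)
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["pos"] = out["position"] + 1
    out.drop(columns=["position"]).to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls: pd.DataFrame, genome: ReferenceGenome, path,
                    line_ids: list[str] | None = None) -> None:
    """Minimal VCF 4.2 with one sample column per MA line, calls as GT."""
    if line_ids is None:
        line_ids = sorted(calls["line_id"].unique())
    header = [
        "##fileformat=VCFv4.2",
        "##source=mutline",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(line_ids),
    ]
    rows = []
    for (pos, ref), grp in calls.groupby(["position", "ref"], sort=True):
        alts = sorted(grp["alt"].unique())
        alt_idx = {a: i + 1 for i, a in enumerate(alts)}
        gts = {l: "0" for l in line_ids}
        for rec in grp.itertuples(index=False):
            gts[rec.line_id] = str(alt_idx[rec.alt])
        scaff, off = genome.locate(int(pos))
        rows.append("\t".join([scaff, str(off + 1), ".", ref, ",".join(alts),
                               ".", "PASS", ".", "GT",
                               "\t".join(gts[l] for l in line_ids)]))
    Path(path).write_text("\n".join(header + rows) + "\n")


def write_assay_tsv(assay: FluctuationAssay, path) -> None:
    lines = [f"# n_final={assay.n_final}",
             f"# plated_fraction={assay.plated_fraction}",
             "replicate_id\tmutant_count"]
    for i, c in enumerate(assay.mutant_counts):
        lines.append(f"r{i + 1}\t{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_assay_tsv(path, n_final: float | None = None,
                   plated_fraction: float | None = None) -> FluctuationAssay:
    meta = {}
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition("=")
            meta[k.strip()] = float(v)
        elif line.strip():
            body.append(line)
    df = pd.read_csv(pd.io.common.StringIO("\n".join(body)), sep="\t")
    nf = n_final if n_final is not None else meta.get("n_final")
    if nf is None:
        raise ValueError("n_final not given and absent from the file header")
    pf = plated_fraction if plated_fraction is not None else \
        meta.get("plated_fraction", 1.0)
    return FluctuationAssay(df["mutant_count"].astype(int).tolist(),
                            float(nf), plated_fraction=float(pf))


# -- 16x4 context-matrix layout ------------------------------------------------

_FLANKS = [(f5, f3) for f5 in BASES for f3 in BASES]


def write_context_matrix(rates: dict[str, float], path,
                         float_format: str = "%.6g") -> None:
    """Write a 64-context rate table in the 16-row x 4-column layout
    (5' flank, focal-base columns A/C/G/T, 3' flank)."""
    rows = []
    for f5, f3 in _FLANKS:
        rows.append([f5] + [rates[f5 + b + f3] for b in BASES] + [f3])
    df = pd.DataFrame(rows, columns=["five_prime", *BASES, "three_prime"])
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_context_matrix(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    need = {"five_prime", "three_prime", *BASES}
    if not need <= set(df.columns):
        raise ValueError(f"context matrix needs columns {sorted(need)}")
    rates = {}
    for rec in df.itertuples(index=False):
        for b in BASES:
            rates[rec.five_prime + b + rec.three_prime] = float(
                getattr(rec, b))
    if len(rates) != 64:
        raise ValueError(f"expected 64 contexts, found {len(rates)}")
    return rates


def read_codon_usage(path) -> dict[str, float]:
    """Two-column TSV (codon, frequency); frequencies renormalized to 1."""
    df = pd.read_csv(path, sep="\t")
    cod_col, freq_col = df.columns[:2]
    usage = {str(c).upper().replace("U", "T"): float(f)
             for c, f in zip(df[cod_col], df[freq_col])}
    total = sum(usage.values())
    if total <= 0:
        raise ValueError("codon usage has no positive mass")
    return {c: f / total for c, f in usage.items()}
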