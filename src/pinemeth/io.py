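"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
All *internal* coordinates are 0-based half-open.  Emitted BED and bedGraph
are 0-based half-open; emitted GFF3 and cytosine reports are 1-based, as
their formats require.

The per-cytosine count table follows the Bismark "cytosine report" layout:
``chrom  pos(1-based)  strand  count_methylated  count_unmethylated
context  trinucleotide``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import CONTEXTS, DEFAULT_AGES


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number when known."""


# ---------------------------------------------------------------------------
# annotation types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with its exon structure (0-based half-open coordinates).

    ``exons`` are stored in genomic order, non-overlapping, within the gene
    bounds; transcript (5'->3') order is genomic order on '+' genes and
    reversed on '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        ex = sorted(tuple(e) for e in self.exons)
        for (s, e) in ex:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene bounds")
        for (_, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = ex

    @property
    def introns(self) -> list:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def exons_transcript_order(self) -> list:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_transcript_order(self) -> list:
        intr = self.introns
        return intr if self.strand == "+" else list(reversed(intr))


@dataclass
class GenomeAnnotation:
    """Chromosome lengths, gene models and TE intervals for one genome."""

    chrom_lengths: dict
    genes: list = field(default_factory=list)
    tes: pd.DataFrame = field(default_factory=lambda: _empty_bed())

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _empty_bed() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64), "name": pd.Series(dtype=str),
         "score": pd.Series(dtype=object), "strand": pd.Series(dtype=str)}
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict, path) -> None:
    """Write ``{chrom: sequence-string}`` to FASTA."""
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

_CX_COLUMNS = ["chrom", "pos", "strand", "mc", "uc", "context", "subcontext"]


def _empty_cx() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
         "strand": pd.Series(dtype=str), "mc": pd.Series(dtype=np.int64),
         "uc": pd.Series(dtype=np.int64), "context": pd.Series(dtype=str),
         "subcontext": pd.Series(dtype=str)}
    )


def read_cytosine_report(path, genome: dict | None = None) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a typed site table.

    Positions are converted to 0-based.  If *genome* (``{chrom: seq}``) is
    given, context labels are re-derived from the sequence and the number of
    mismatching rows is reported via a warning.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "subcontext": str},
        )
    except pd.errors.EmptyDataError:
        return _empty_cx()

    for col in ("pos", "mc", "uc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ParseError(f"line {int(np.flatnonzero(bad)[0]) + 1}: non-numeric {col}")
        df[col] = vals.astype(np.int64)

    _raise_on(df["pos"] < 1, "position < 1")
    _raise_on((df["mc"] < 0) | (df["uc"] < 0), "negative count")
    _raise_on(~df["strand"].isin(["+", "-"]), "bad strand")
    _raise_on(~df["context"].isin(CONTEXTS), "unknown context")
    sub = df["subcontext"].astype(str)
    _raise_on((sub.str.len() != 3) | (sub.str[0] != "C"), "bad trinucleotide")
    expected = np.where(sub.str[1] == "G", "CG", np.where(sub.str[2] == "G", "CHG", "CHH"))
    _raise_on(df["context"].to_numpy() != expected, "context inconsistent with trinucleotide")

    df["pos"] = df["pos"] - 1  # to 0-based
    if genome is not None:
        unknown = set(df["chrom"]) - set(genome)
        if unknown:
            raise ParseError(f"chromosomes not in genome: {sorted(unknown)}")
        from .core import classify_contexts  # deferred: avoid import cycle
        mismatch = 0
        for chrom, grp in df.groupby("chrom", observed=True):
            ref, _ = classify_contexts(genome[chrom], chrom=chrom)
            key = ref.set_index(["pos", "strand"])["context"]
            idx = pd.MultiIndex.from_arrays([grp["pos"], grp["strand"]])
            ref_ctx = key.reindex(idx)
            mismatch += int((ref_ctx.to_numpy() != grp["context"].to_numpy()).sum())
        if mismatch:
            warnings.warn(f"{mismatch} rows disagree with genome-derived context")
    return df


def _raise_on(mask, message: str) -> None:
    mask = np.asarray(mask)
    if mask.any():
        raise ParseError(f"line {int(np.flatnonzero(mask)[0]) + 1}: {message}")


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    out = df[_CX_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Emit gene models as GFF3 (1-based inclusive), with sequence-region
    pragmas carrying the chromosome lengths."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes:
            fh.write("\t".join([
                g.chrom, "pinemeth", "gene", str(g.start + 1), str(g.end), ".",
                g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.chrom, "pinemeth", "exon", str(s + 1), str(e), ".",
                    g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                ]) + "\n")


def read_gff3(path) -> GenomeAnnotation:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_lengths = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_lengths[parts[1]] = int(parts[3])
    genes = []
    for feat in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end) for e in db.children(feat, featuretype="exon")]
        if not exons:
            warnings.warn(f"gene {feat.id} has no exons; skipped")
            continue
        genes.append(GeneModel(
            gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
            start=feat.start - 1, end=feat.end, exons=exons,
        ))
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED (3-6 columns), 0-based half-open, into a typed frame."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return _empty_bed()
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ParseError(f"line {int(np.flatnonzero(bad)[0]) + 1}: end <= start")
    for col, default in (("name", "."), ("score", "."), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    return df


def read_bedgraph(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sample sheet / expression table
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[["sample_id", "age_years", "replicate"]].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path, ages=DEFAULT_AGES) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "age_years", "replicate"}
    if not required <= set(sheet.columns):
        raise ParseError(f"sample sheet must have columns {sorted(required)}")
    if not set(sheet["age_years"]) <= set(ages):
        raise ParseError(f"ages must be among {tuple(ages)}")
    if sheet.duplicated(["age_years", "replicate"]).any():
        raise ParseError("duplicate (age, replicate) pair in sample sheet")
    return sheet


def write_tpm_table(tpm: pd.DataFrame, path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene_id")


def read_tpm_table(path, sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    tpm = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (tpm.to_numpy() < 0).any():
        raise ParseError("negative TPM value")
    if sheet is not None:
        extra = set(tpm.columns) - set(sheet["sample_id"])
        if extra:
            raise ParseError(f"samples not in sheet: {sorted(extra)}")
    return tpm


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

DMR_COLUMNS = ["chrom", "start", "end", "context", "comparison",
               "level_older", "level_younger", "diff", "p", "p_adj", "direction"]


def write_dmrs(df: pd.DataFrame, path) -> None:
    """DMRs as BED-like TSV (0-based half-open) with all statistics."""
    df[DMR_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dmrs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_profiles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results(tables: dict, outdir, config=None, seed=None) -> None:
    """Write a dict of tidy DataFrames as TSVs plus a small run log."""
    from pathlib import Path
    from .config import config_hash, to_yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    log = {"seed": seed}
    if config is not None:
        log["config_hash"] = config_hash(config)
        to_yaml(config, outdir / "effective_config.yaml")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict() if hasattr(truth, "to_dict") else truth, fh, indent=2)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
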