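"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open; conversion to and from
1-based conventions (GFF3, VCF, tabular similarity hits) happens only here,
at the format boundary.  All readers validate and return plain in-memory
containers: dataclasses for sequences and sites, pandas DataFrames for
feature/hit/map tables.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: column order of the 12-column tabular similarity-hit dialect (BLAST outfmt 6)
HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
]

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "kind", "id", "parent", "phase"]

_VALID_BASES = re.compile(r"[^ACGTN]")


@dataclass
class ChromosomeRecord:
    """A named chromosome sequence with species and ancestral-homolog labels."""

    id: str
    species: str
    sequence: str
    homology_group: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenotypeSite:
    """One variant site with unphased diploid genotypes and DP/GQ per sample."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray  # (n_samples, 2) allele indices, -1 = missing
    dp: np.ndarray
    gq: np.ndarray

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass
class VariantTable:
    """Column-wise collection of GenotypeSite records for one call set."""

    samples: list[str]
    chroms: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    ref: list[str] = field(default_factory=list)
    alts: list[tuple[str, ...]] = field(default_factory=list)
    genotypes: np.ndarray | None = None  # (n_sites, n_samples, 2), -1 missing
    dp: np.ndarray | None = None  # (n_sites, n_samples)
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, s = len(self.pos), len(self.samples)
        if self.genotypes is None:
            self.genotypes = np.full((n, s, 2), -1, dtype=np.int8)
        if self.dp is None:
            self.dp = np.zeros((n, s), dtype=np.int32)
        if self.gq is None:
            self.gq = np.zeros((n, s), dtype=np.int32)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sites(self) -> Iterator[GenotypeSite]:
        for i in range(self.n_sites):
            yield GenotypeSite(
                chrom=str(self.chroms[i]), pos=int(self.pos[i]), ref=self.ref[i],
                alts=tuple(self.alts[i]), genotypes=self.genotypes[i],
                dp=self.dp[i], gq=self.gq[i],
            )

    def copy(self) -> "VariantTable":
        return VariantTable(
            samples=list(self.samples), chroms=self.chroms.copy(),
            pos=self.pos.copy(), ref=list(self.ref),
            alts=[tuple(a) for a in self.alts],
            genotypes=self.genotypes.copy(), dp=self.dp.copy(), gq=self.gq.copy(),
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike, species: str = "") -> list[ChromosomeRecord]:
    """Read a FASTA file into ChromosomeRecords.

    Soft-masked (lowercase) bases are uppercased; characters outside ACGTN are
    replaced by N with a logged count.  Duplicate ids and empty files raise.
    """
    records: list[ChromosomeRecord] = []
    seen: set[str] = set()
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = _VALID_BASES.sub("N", seq)
        n_subst += sum(a != b for a, b in zip(seq, cleaned)) if cleaned != seq else 0
        records.append(ChromosomeRecord(id=rec.id, species=species, sequence=cleaned))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    if n_subst:
        logger.warning("%s: %d non-ACGTN characters replaced by N", path, n_subst)
    return records


def write_fasta(records: Iterable[ChromosomeRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def synthesize_introns(features: pd.DataFrame) -> pd.DataFrame:
    """Derive intron intervals as gaps between consecutive exons per transcript."""
    exons = features[features["kind"] == "exon"]
    rows = []
    for parent, grp in exons.groupby("parent", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for i in range(len(grp) - 1):
            if starts[i + 1] > ends[i]:
                rows.append({
                    "chrom": grp["chrom"].iloc[0], "start": int(ends[i]),
                    "end": int(starts[i + 1]), "strand": grp["strand"].iloc[0],
                    "kind": "intron", "id": f"{parent}.intron{i + 1}",
                    "parent": parent, "phase": -1,
                })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_gff3(path: str | os.PathLike, synthesize: bool = True) -> pd.DataFrame:
    """Read a GFF3 gene/mRNA/exon/CDS hierarchy into a feature table.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Introns are synthesized from exon gaps per transcript.  CDS rows lacking a
    resolvable parent transcript raise, as do malformed coordinates.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    transcript_ids: set[str] = set()
    for f in db.all_features():
        if f.end < f.start:
            raise ValueError(f"{path}: feature {f.id} has end < start")
        kind = "mRNA" if f.featuretype in ("mRNA", "transcript") else f.featuretype
        fid = f.attributes.get("ID", [f.id])[0]
        parent = f.attributes.get("Parent", [""])[0]
        if kind == "mRNA":
            transcript_ids.add(fid)
        rows.append({
            "chrom": f.seqid, "start": f.start - 1, "end": f.end,
            "strand": f.strand or ".", "kind": kind, "id": fid, "parent": parent,
            "phase": int(f.frame) if f.frame in ("0", "1", "2") else -1,
        })
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    bad_cds = features[(features["kind"] == "CDS")
                       & ~features["parent"].isin(transcript_ids)]
    if len(bad_cds):
        raise ValueError(
            f"{path}: {len(bad_cds)} CDS features without a parent transcript"
        )
    if synthesize:
        introns = synthesize_introns(features)
        if len(introns):
            features = pd.concat([features, introns], ignore_index=True)
    return features


def write_gff3(features: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table as GFF3 (introns are derived data and skipped)."""
    order = {"gene": 0, "mRNA": 1, "exon": 2, "CDS": 3}
    feats = features[features["kind"].isin(order)].copy()
    feats["_k"] = feats["kind"].map(order)
    feats = feats.sort_values(["chrom", "start", "_k"], kind="stable")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in feats.itertuples():
            attrs = []
            if row.id:
                attrs.append(f"ID={row.id}")
            if row.parent:
                attrs.append(f"Parent={row.parent}")
            phase = str(row.phase) if row.kind == "CDS" and row.phase >= 0 else "."
            fh.write("\t".join([
                row.chrom, "karyofuse", row.kind, str(row.start + 1),
                str(row.end), ".", row.strand, phase, ";".join(attrs) or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | os.PathLike, samples: Sequence[str] | None = None) -> VariantTable:
    """Read GT/DP/GQ fields from a VCF into a VariantTable (0-based positions).

    Multiallelic records are kept whole.  Requesting an absent sample raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    available = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise ValueError(f"samples not present in {path}: {missing}")
        vcf.set_samples(list(samples))
    use_samples = list(vcf.samples)
    n_s = len(use_samples)

    chroms, pos, ref, alts, gts, dps, gqs = [], [], [], [], [], [], []
    for v in vcf:
        chroms.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alts.append(tuple(v.ALT))
        g = np.asarray(v.genotypes, dtype=np.int64)[:, :2] if n_s else np.empty((0, 2))
        gts.append(g.astype(np.int8))
        dp = v.format("DP")
        gq = v.format("GQ")
        dps.append(np.zeros(n_s, dtype=np.int32) if dp is None
                   else np.maximum(dp.reshape(-1).astype(np.int32), 0))
        gqs.append(np.zeros(n_s, dtype=np.int32) if gq is None
                   else np.maximum(gq.reshape(-1).astype(np.int32), 0))
    n = len(pos)
    return VariantTable(
        samples=use_samples,
        chroms=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref, alts=alts,
        genotypes=(np.stack(gts) if n else None),
        dp=(np.stack(dps) if n else None),
        gq=(np.stack(gqs) if n else None),
    )


def write_vcf(table: VariantTable, path: str | os.PathLike,
              contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            alt = ",".join(table.alts[i]) if table.alts[i] else "."
            cols = [str(table.chroms[i]), str(int(table.pos[i]) + 1), ".",
                    table.ref[i], alt, ".", "PASS", ".", "GT:DP:GQ"]
            for j in range(len(table.samples)):
                a, b = table.genotypes[i, j]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                cols.append(f"{gt}:{table.dp[i, j]}:{table.gq[i, j]}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BED / hits / linkage map


def read_bed(path: str | os.PathLike, kind: str = "repeat") -> pd.DataFrame:
    """Read BED3+ intervals (already 0-based half-open) as a feature table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            rows.append({
                "chrom": parts[0], "start": int(parts[1]), "end": int(parts[2]),
                "strand": strand, "kind": kind, "id": name, "parent": "",
                "phase": -1,
            })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_bed(features: pd.DataFrame, path: str | os.PathLike) -> None:
    feats = features.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        for row in feats.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.id or '.'}\n")


def read_hits(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 12-column tabular similarity-hit table.

    The 1-based inclusive q/s coordinates of this dialect are preserved as-is;
    they are never mixed with the internal 0-based convention.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            rows.append(parts)
    if not rows:
        return pd.DataFrame(columns=HIT_COLUMNS)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    for col in ("percent_identity", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("alignment_length", "mismatches", "gap_opens",
                "q_start", "q_end", "s_start", "s_end"):
        df[col] = df[col].astype(np.int64)
    return df


def write_hits(hits: pd.DataFrame, path: str | os.PathLike) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=HIT_COLUMNS)


def read_linkage_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV linkage map (marker_id, chrom, pos_bp, cM) and validate it."""
    df = pd.read_csv(path, sep="\t",
                     names=["marker_id", "chrom", "pos", "cM"], header=0)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        if (np.diff(grp["cM"].to_numpy()) < 0).any():
            raise ValueError(f"linkage map: cM decreases along {chrom}")
    return df


def map_lengths(linkage_map: pd.DataFrame) -> pd.Series:
    """Per-chromosome genetic map length: max(cM) - min(cM)."""
    g = linkage_map.groupby("chrom")["cM"]
    return g.max() - g.min()
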