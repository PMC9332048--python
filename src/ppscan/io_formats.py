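"""Genome/annotation I/O, promoter-region extraction, and PPS export.

Coordinate conventions: everything user-facing is 1-based inclusive (the
convention of the PPS database and GFF3); BED output is converted to 0-based
half-open. Internally slices are taken with Python half-open indexing.

A promoter region is the fixed 600-nt window around an annotated gene start
(the TSS proxy): 500 nt upstream plus 100 nt from the start onward, so that
region coordinate 501 is the annotated +1 position. Reverse-strand regions
are stored reverse-complemented, i.e. every stored promoter reads 5'->3'
toward its gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRANSFORM_MODES = ("identity", "reverse_complement", "complement_only", "reverse_only")

PPS_TSV_COLUMNS = [
    "id",
    "chromosome",
    "start",
    "end",
    "strand",
    "Z",
    "score",
    "class_id",
    "alignment",
]

# TSV/BED strand codes per variant; the two shuffle-control variants have no
# biological strand and are exported as '.' in BED.
_VARIANT_CODE = {
    "forward": "+",
    "reverse": "-",
    "complement_only": "comp",
    "reverse_only": "rev",
}
_CODE_VARIANT = {v: k for k, v in _VARIANT_CODE.items()}


def clean_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT IUPAC code to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into {name: uppercase sequence over A,C,G,T,N}."""
    genome: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the offending content
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    for rec in records:
        if rec.id in genome:
            raise ValueError(f"duplicate sequence name in {path}: {rec.id}")
        seq = clean_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty FASTA record in {path}: {rec.id}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: its TSS-proxy coordinate (1-based) and strand."""

    gene_id: str
    chrom: str
    start: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from GFF3.

    The TSS proxy is the 5'-most coordinate of each feature of type "gene":
    the start column on '+', the end column on '-'.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        tss = feat.start if feat.strand == "+" else feat.end
        genes.append(
            GeneAnnotation(
                gene_id=feat.id, chrom=feat.seqid, start=tss, strand=feat.strand
            )
        )
    return genes


@dataclass(frozen=True)
class PromoterRegion:
    """600-nt promoter window with provenance coordinates.

    ``sequence`` is renumbered 1..600 reading toward the gene; positions
    1..500 are upstream and position 501 is the annotated start.
    """

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive genomic interval
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with interval")


def sequence_transform(seq: str, mode: str) -> str:
    """Strand/mirror transforms used for the scan control variants.

    reverse_complement is the biological opposite strand; complement_only
    substitutes complementary bases without the 180-degree flip; reverse_only
    flips the sequence without complementing.
    """
    if mode == "identity":
        return seq
    if mode == "reverse_complement":
        return seq.translate(_COMPLEMENT)[::-1]
    if mode == "complement_only":
        return seq.translate(_COMPLEMENT)
    if mode == "reverse_only":
        return seq[::-1]
    raise ValueError(f"unknown transform mode: {mode!r}")


def extract_promoters(
    genome: dict[str, str],
    annotation: list[GeneAnnotation],
    upstream: int = 500,
    downstream: int = 100,
) -> list[PromoterRegion]:
    """One fixed-length promoter region per gene, on the gene's own strand.

    For a '+' gene with start g the genomic interval is [g-upstream,
    g+downstream-1]; for a '-' gene it is [g-downstream+1, g+upstream] and
    the stored sequence is the reverse complement of that slice. Genes whose
    window leaves the chromosome are dropped (and logged), not clipped: all
    downstream matrices require the fixed length.
    """
    regions = []
    length = upstream + downstream
    for gene in annotation:
        if gene.chrom not in genome:
            raise KeyError(f"gene {gene.gene_id}: chromosome {gene.chrom} not in genome")
        chrom_seq = genome[gene.chrom]
        if gene.strand == "+":
            start, end = gene.start - upstream, gene.start + downstream - 1
        else:
            start, end = gene.start - downstream + 1, gene.start + upstream
        if start < 1 or end > len(chrom_seq):
            logger.info(
                "dropping %s: window [%d, %d] outside chromosome %s",
                gene.gene_id, start, end, gene.chrom,
            )
            continue
        seq = chrom_seq[start - 1 : end]
        if gene.strand == "-":
            seq = sequence_transform(seq, "reverse_complement")
        assert len(seq) == length
        regions.append(
            PromoterRegion(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                start=start,
                end=end,
                strand=gene.strand,
                sequence=seq,
            )
        )
    return regions


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic feature used in overlap analyses (annotated promoter, SINE, ...)."""

    feature_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."
    feature_type: str = "other"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")


def read_features(path: str | Path, feature_type: str = "other") -> list[FeatureInterval]:
    """Read intervals from BED6 (0-based half-open) or GFF3 (1-based)."""
    path = Path(path)
    feats: list[FeatureInterval] = []
    if path.suffix.lower() == ".bed":
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"feat{i}"
            strand = f[5] if len(f) > 5 else "."
            feats.append(
                FeatureInterval(
                    feature_id=name,
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    strand=strand,
                    feature_type=feature_type,
                )
            )
    else:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.all_features():
            feats.append(
                FeatureInterval(
                    feature_id=feat.id,
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand or ".",
                    feature_type=feat.featuretype or feature_type,
                )
            )
    return feats


@dataclass
class PPSRecord:
    """One row of the PPS database: a significant local alignment locus."""

    record_id: str
    chrom: str
    start: int  # i0, 1-based inclusive, forward reference frame
    end: int  # i_max
    strand_variant: str  # forward | reverse | complement_only | reverse_only
    z: float
    score: float  # E_max (or F_max for whole-region records)
    class_id: int
    cigar: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"record {self.record_id}: start > end")
        if self.strand_variant not in _VARIANT_CODE:
            raise ValueError(f"bad strand variant {self.strand_variant!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def records_to_frame(records: list[PPSRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.record_id,
            "chromosome": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": _VARIANT_CODE[r.strand_variant],
            "Z": round(r.z, 4),
            "score": round(r.score, 4),
            "class_id": r.class_id,
            "alignment": r.cigar,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=PPS_TSV_COLUMNS)


def export_pps(
    records: list[PPSRecord],
    path: str | Path,
    fmt: str = "tsv",
    header: str | None = None,
) -> None:
    """Write PPS records as TSV, BED6, or GFF3.

    TSV columns: id, chromosome, start, end, strand, Z, score, class_id,
    alignment (CIGAR-like). BED is 0-based half-open with the Z value in the
    score slot scaled x100 and clamped to 1000. GFF3 uses feature type
    "promoter" with class_id and Z attributes.
    """
    path = Path(path)
    lines: list[str] = []
    if fmt == "tsv":
        if header:
            lines.append(f"# {header}")
        df = records_to_frame(records)
        lines.append("\t".join(PPS_TSV_COLUMNS))
        for row in df.itertuples(index=False):
            lines.append("\t".join(str(v) for v in row))
    elif fmt == "bed":
        if header:
            lines.append(f"# {header}")
        for r in records:
            bed_score = min(1000, int(round(r.z * 100)))
            strand = _VARIANT_CODE[r.strand_variant]
            if strand not in "+-":
                strand = "."
            lines.append(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.record_id}\t{bed_score}\t{strand}"
            )
    elif fmt == "gff3":
        lines.append("##gff-version 3")
        if header:
            lines.append(f"# {header}")
        for r in records:
            strand = _VARIANT_CODE[r.strand_variant]
            if strand not in "+-":
                strand = "."
            attrs = (
                f"ID={r.record_id};class_id={r.class_id};Z={r.z:.4f}"
                f";variant={r.strand_variant}"
            )
            lines.append(
                f"{r.chrom}\tppscan\tpromoter\t{r.start}\t{r.end}\t"
                f"{r.score:.4f}\t{strand}\t.\t{attrs}"
            )
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def parse_pps_tsv(path: str | Path) -> list[PPSRecord]:
    """Inverse of export_pps(..., fmt="tsv")."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"alignment": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PPSRecord(
                record_id=str(row.id),
                chrom=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                strand_variant=_CODE_VARIANT[str(row.strand)],
                z=float(row.Z),
                score=float(row.score),
                class_id=int(row.class_id),
                cigar=str(row.alignment),
            )
        )
    return records


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_gff3(
    genes: list[GeneAnnotation],
    path: str | Path,
    gene_span: int = 200,
    header: str | None = None,
) -> None:
    """Write gene features; the TSS proxy is recoverable as start ('+') / end ('-')."""
    lines = ["##gff-version 3"]
    if header:
        lines.append(f"# {header}")
    for g in genes:
        if g.strand == "+":
            start, end = g.start, g.start + gene_span - 1
        else:
            start, end = max(1, g.start - gene_span + 1), g.start
        lines.append(
            f"{g.chrom}\tppscan\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
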