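"""Readers, writers and configuration for every external representation.

Conventions
-----------
All coordinates in external files (FASTA-relative positions, BLAST tabular
columns, site tables) are 1-based inclusive, following the BLAST convention.
Internal interval arithmetic is 0-based half-open; the conversion happens
here, at the I/O boundary, and nowhere else.

Alignments are BLAST ``outfmt 6``-compatible (12 tab-separated columns) with
an optional 13th column carrying a per-base trace string over the alphabet
``M`` (match), ``X`` (mismatch), ``D`` (gap in query: consumes subject only),
``I`` (gap in subject: consumes query only).  Without a trace, gapped HSPs
cannot be projected base-exactly and downstream code refuses to interpolate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPE_CODES = ("A", "H", "B", "-")
MISSING_CODE = "-"

TRACE_OPS = frozenset("MXDI")
#: trace ops that consume a query base / a subject base
_Q_CONSUMING = frozenset("MXI")
_S_CONSUMING = frozenset("MXD")


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (unigene or genome scaffold).

    Lowercase letters are interpreted as soft-masked positions.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.seq) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One BLAST-style HSP between a query (unigene) and subject (scaffold).

    ``sstart > send`` encodes a minus-strand hit.  ``trace``, when present,
    is the per-base op string described in the module docstring and must
    consume exactly the query span ``qend - qstart + 1`` and the subject
    span ``|send - sstart| + 1``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    trace: str | None = None

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise FormatError(
                f"alignment {self.query_id}/{self.subject_id}: qstart > qend"
            )
        if self.trace is not None:
            bad = set(self.trace) - TRACE_OPS
            if bad:
                raise FormatError(f"trace contains unknown ops {sorted(bad)}")
            qlen = sum(1 for op in self.trace if op in _Q_CONSUMING)
            slen = sum(1 for op in self.trace if op in _S_CONSUMING)
            if qlen != self.query_span or slen != self.subject_span:
                raise FormatError(
                    f"trace consumes ({qlen} q, {slen} s) but span is "
                    f"({self.query_span} q, {self.subject_span} s)"
                )

    @property
    def strand(self) -> str:
        return "-" if self.sstart > self.send else "+"

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart + 1

    @property
    def subject_span(self) -> int:
        return abs(self.send - self.sstart) + 1

    @property
    def is_gapless(self) -> bool:
        if self.trace is not None:
            return "D" not in self.trace and "I" not in self.trace
        return self.query_span == self.subject_span == self.aln_len


@dataclass(frozen=True)
class MapAnchor:
    """Genetic-map knowledge for one unigene.

    ``category`` is ``anchored`` (chromosome and cM position known),
    ``chromosome_only`` (linkage group known, position not), or
    ``no_information``.
    """

    unigene_id: str
    chromosome: str | None = None
    cm_position: float | None = None

    def __post_init__(self) -> None:
        if self.cm_position is not None and self.chromosome is None:
            raise FormatError(
                f"anchor {self.unigene_id}: cM position without a chromosome"
            )

    @property
    def category(self) -> str:
        if self.chromosome is None:
            return "no_information"
        if self.cm_position is None:
            return "chromosome_only"
        return "anchored"


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and design parameters of the pipeline.

    Variant-calling thresholds follow fixed-ploidy RNA-seq calling practice:
    a site needs ``min_coverage`` reads, ``min_count`` reads supporting the
    variant and an allele frequency of at least ``min_freq`` percent to be
    called at all; calls above ``hom_cutoff`` percent are homozygous,
    otherwise heterozygous (a frequency of exactly ``hom_cutoff`` is
    heterozygous).
    """

    # variant calling (reads / percent)
    min_coverage: int = 5
    min_count: int = 2
    min_freq: float = 20.0
    hom_cutoff: float = 80.0
    # within-line fixation: fraction of individuals required; None = (n-1)/n
    min_support_fraction: float | None = None
    # F2 matrix filters
    max_missing: float = 0.10
    distortion_alpha: float = 0.001
    # marker design (bp)
    flank: int = 150
    amplicon_min: int = 120
    amplicon_max: int = 160
    primer_len_min: int = 18
    primer_len_max: int = 25
    tm_min: float = 57.0
    tm_max: float = 63.0
    tm_pair_max_diff: float = 3.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_homopolymer: int = 4
    kmer_k: int = 16
    blacklist_cutoff: int = 10
    binding_seed_len: int = 15
    max_product_separation: int = 1000
    min_panel_spacing: int = 1000
    pool_size: int = 48
    # linkage
    lod_threshold: float = 4.0
    max_group_rf: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 < self.hom_cutoff < 100.0:
            raise FormatError("hom_cutoff must lie strictly between 0 and 100")
        if not self.amplicon_min <= self.amplicon_max <= 2 * self.flank:
            raise FormatError(
                "amplicon size window must satisfy "
                "amplicon_min <= amplicon_max <= 2*flank"
            )

    def hash(self) -> str:
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in fields(self)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a ``key = value`` config file; unknown keys are an error."""
    known = {f.name: f for f in fields(PipelineConfig)}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = (part.strip() for part in line.partition("="))
        if key not in known:
            raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _coerce(val, known[key].type)
    values.update(overrides)
    return PipelineConfig(**values)


def _coerce(val: str, annot) -> object:
    text = str(annot)
    if val.lower() in {"none", ""}:
        return None
    if "int" in text and "float" not in text:
        return int(val)
    return float(val)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# BLAST tabular alignments


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Parse BLAST outfmt-6-compatible alignments (optional trace column)."""
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    trace=parts[12] if len(parts) > 12 and parts[12] else None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_alignments(
    records: Iterable[AlignmentRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.query_id, r.subject_id, f"{r.pct_identity:g}",
                str(r.aln_len), str(r.mismatches), str(r.gap_opens),
                str(r.qstart), str(r.qend), str(r.sstart), str(r.send),
                f"{r.evalue:g}", f"{r.bitscore:g}",
            ]
            if r.trace is not None:
                cols.append(r.trace)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Anchor tables


def read_anchors(path: str | Path) -> dict[str, MapAnchor]:
    """Read a unigene -> (chromosome, cM) anchor TSV keyed by unigene id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"unigene_id", "chromosome", "cm_position"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"anchor table {path} must have columns {sorted(required)}"
        )
    anchors: dict[str, MapAnchor] = {}
    for row in df.itertuples(index=False):
        chrom = None if pd.isna(row.chromosome) or row.chromosome in {"", "."} \
            else str(row.chromosome)
        cm = None if pd.isna(row.cm_position) or row.cm_position in {"", "."} \
            else float(row.cm_position)
        anchors[row.unigene_id] = MapAnchor(row.unigene_id, chrom, cm)
    return anchors


def write_anchors(anchors: Mapping[str, MapAnchor], path: str | Path) -> None:
    rows = [
        {
            "unigene_id": a.unigene_id,
            "chromosome": a.chromosome if a.chromosome is not None else ".",
            "cm_position": a.cm_position if a.cm_position is not None else ".",
        }
        for a in anchors.values()
    ]
    pd.DataFrame(rows, columns=["unigene_id", "chromosome", "cm_position"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Variant tables (canonical TSV dialect)

VARIANT_COLUMNS = [
    "sample_id", "line_id", "unigene_id", "position",
    "ref_allele", "alt_allele", "total_depth", "alt_count",
]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a per-individual variant TSV (one allele observation per row)."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={
            "sample_id": str, "line_id": str, "unigene_id": str,
            "ref_allele": str, "alt_allele": str,
        },
    )
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(
            f"variant table {path} missing columns {sorted(missing)}"
        )
    if (df["alt_count"] > df["total_depth"]).any():
        raise FormatError(f"variant table {path}: alt_count > total_depth")
    return df[VARIANT_COLUMNS]


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variant_vcf(
    path: str | Path, sample_to_line: Mapping[str, str]
) -> pd.DataFrame:
    """Read per-sample variant observations from a VCF with AD depth fields.

    The VCF CHROM column is taken as the unigene id.  Only samples present
    in ``sample_to_line`` are kept; each alt allele of each record yields one
    observation row per sample.  The canonical dialect for the pipeline is
    the TSV of :func:`read_variant_table`; this reader maps onto it.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for sample, call in rec.samples.items():
                if sample not in sample_to_line:
                    continue
                ad = call.get("AD")
                if ad is None or ad[0] is None:
                    continue
                total = int(sum(x for x in ad if x is not None))
                for i, alt in enumerate(rec.alts or ()):
                    alt_count = int(ad[i + 1]) if i + 1 < len(ad) and ad[i + 1] is not None else 0
                    rows.append(
                        {
                            "sample_id": sample,
                            "line_id": sample_to_line[sample],
                            "unigene_id": rec.chrom,
                            "position": rec.pos,
                            "ref_allele": rec.ref,
                            "alt_allele": alt,
                            "total_depth": total,
                            "alt_count": alt_count,
                        }
                    )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# Amplicon site-depth tables

DEPTH_COLUMNS = [
    "sample_id", "marker_id", "scaffold", "position",
    "ref_allele", "alt_allele", "is_hotspot", "ref_count", "alt_count",
]


def read_depth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={
            "sample_id": str, "marker_id": str, "scaffold": str,
            "ref_allele": str, "alt_allele": str,
        },
    )
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"depth table {path} missing columns {sorted(missing)}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise FormatError(f"depth table {path}: negative read counts")
    df["is_hotspot"] = df["is_hotspot"].astype(bool)
    return df[DEPTH_COLUMNS]


def write_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrices


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a markers x individuals matrix of A/H/B/- codes as TSV."""
    bad = set(matrix.to_numpy().ravel()) - set(GENOTYPE_CODES)
    if bad:
        raise FormatError(f"unknown genotype codes {sorted(bad)}")
    matrix.to_csv(path, sep="\t", index_label="marker_id")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="marker_id", dtype=str)
    matrix.index = matrix.index.astype(str)
    bad = set(matrix.to_numpy().ravel()) - set(GENOTYPE_CODES)
    if bad:
        raise FormatError(f"unknown genotype codes {sorted(bad)} in {path}")
    return matrix


__all__ = [
    "AlignmentRecord",
    "FormatError",
    "GENOTYPE_CODES",
    "MISSING_CODE",
    "MapAnchor",
    "PipelineConfig",
    "SequenceRecord",
    "load_config",
    "read_alignments",
    "read_anchors",
    "read_depth_table",
    "read_fasta",
    "read_genotype_matrix",
    "read_variant_table",
    "read_variant_vcf",
    "write_alignments",
    "write_anchors",
    "write_depth_table",
    "write_fasta",
    "write_genotype_matrix",
    "write_variant_table",
    "replace",
]
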