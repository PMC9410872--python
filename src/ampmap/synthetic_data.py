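"""Synthetic study generator: references, heterogeneous lines, F2 cross,
amplicon depths.

The generator emulates the data-generating process the pipeline is built
for: a spliced transcriptome (unigenes) over a repeat-containing genome,
two outcrossing parental lines whose individuals are only incompletely
fixed (a plant is homozygous for the line's founder allele with
probability ``fixation_rate``, heterozygous otherwise), an F1 from the two
founder gametes, F2 progeny produced by meiosis without crossover
interference (Haldane model), and amplicon read depths with log-normal
per-marker depth heterogeneity, beta-binomial allele sampling and
marker-by-line dropout (one parental allele failing to amplify, as when a
polymorphism disrupts a primer's 3' binding).

Everything is deterministic given ``SimConfig.seed``: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ampmap.formats import (
    AlignmentRecord,
    MapAnchor,
    SequenceRecord,
    VARIANT_COLUMNS,
    DEPTH_COLUMNS,
)
from ampmap.linkage import haldane_rf

PARENT1 = "parent1"
PARENT2 = "parent2"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults follow the study design the pipeline targets: five and six
    sequenced individuals for the two parental lines (the all-but-one
    fixation rule then asks for 4/5 and 5/6 homozygous calls), three
    replicate parent plants and one F1 in the amplicon run, and a
    63-plant F2 population.
    """

    seed: int = 0
    # reference structure
    n_scaffolds: int = 4
    n_genes: int = 24
    exons_per_gene: int = 3
    exon_length: int = 260
    intron_length: int = 300
    gap_length: int = 200
    minus_strand_fraction: float = 0.3
    # repeats
    repeat_families: int = 2
    repeat_length: int = 200
    repeat_copies: int = 30
    # genetic map
    n_chromosomes: int = 2
    chromosome_cm: float = 100.0
    anchored_fraction: float = 0.6
    chromosome_only_fraction: float = 0.25
    # polymorphism structure
    snps_per_gene: int = 2
    shared_variant_fraction: float = 0.25
    # lines and cross
    fixation_rate: float = 0.85
    segregating_founder_freq: float = 0.7
    n_parent1_individuals: int = 5
    n_parent2_individuals: int = 6
    n_parent_replicates: int = 3
    n_f2: int = 63
    rnaseq_depth: float = 30.0
    # amplicon depth model
    depth_log_mean: float = math.log(100.0)
    depth_log_sd: float = 1.0
    allele_overdispersion: float = 0.05
    dropout_probability: float = 0.04
    base_error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.fixation_rate <= 1.0:
            raise ValueError("fixation_rate must lie in [0, 1]")
        for name in ("n_scaffolds", "n_genes", "exons_per_gene",
                     "exon_length", "n_chromosomes", "n_f2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    unigene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive genome intervals
    chromosome: str
    cm: float
    anchor_category: str


@dataclass(frozen=True)
class Locus:
    """One true variant locus, in both transcript and genome coordinates."""

    locus_id: str
    unigene_id: str
    transcript_pos: int  # 1-based on the unigene
    scaffold: str
    genome_pos: int      # 1-based on the scaffold
    chromosome: str
    cm: float
    ref_allele: str
    alt_allele: str
    kind: str            # founder_diff | shared_alt
    fixed_line: str | None  # line carrying the alt allele (founder_diff)


@dataclass
class TruthSet:
    genes: list[Gene] = field(default_factory=list)
    loci: list[Locus] = field(default_factory=list)
    #: planted repeat copies as (scaffold, start, end), 1-based inclusive
    repeats: list[tuple[str, int, int]] = field(default_factory=list)

    def locus_by_genome(self) -> dict[tuple[str, int], Locus]:
        return {(l.scaffold, l.genome_pos): l for l in self.loci}

    def founder_diff_loci(self) -> list[Locus]:
        return [l for l in self.loci if l.kind == "founder_diff"]


@dataclass
class Reference:
    genome: list[SequenceRecord]
    unigenes: list[SequenceRecord]
    alignments: list[AlignmentRecord]
    anchors: dict[str, MapAnchor]
    truth: TruthSet


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _transcript_to_genome(
    exons: Sequence[tuple[int, int]], strand: str, tpos: int
) -> int:
    """Project a 1-based transcript position through exon intervals.

    Independent of the alignment-walking liftover: used as ground truth.
    """
    lengths = [e - s + 1 for s, e in exons]
    total = sum(lengths)
    if not 1 <= tpos <= total:
        raise ValueError("transcript position outside unigene")
    fwd = tpos if strand == "+" else total - tpos + 1
    for (start, end), length in zip(exons, lengths):
        if fwd <= length:
            return start + fwd - 1
        fwd -= length
    raise AssertionError("unreachable")


def _spliced_alignment(
    unigene_id: str, scaffold: str, exons: Sequence[tuple[int, int]],
    strand: str, unigene_len: int,
) -> AlignmentRecord:
    introns = [
        exons[i + 1][0] - exons[i][1] - 1 for i in range(len(exons) - 1)
    ]
    genome_order = list(exons)
    ops: list[str] = []
    if strand == "+":
        for i, (s, e) in enumerate(genome_order):
            ops.append("M" * (e - s + 1))
            if i < len(introns):
                ops.append("D" * introns[i])
        sstart, send = exons[0][0], exons[-1][1]
    else:
        for i in range(len(genome_order) - 1, -1, -1):
            s, e = genome_order[i]
            ops.append("M" * (e - s + 1))
            if i > 0:
                ops.append("D" * introns[i - 1])
        sstart, send = exons[-1][1], exons[0][0]
    trace = "".join(ops)
    span = abs(send - sstart) + 1
    return AlignmentRecord(
        query_id=unigene_id, subject_id=scaffold, pct_identity=100.0,
        aln_len=span, mismatches=0, gap_opens=len(introns),
        qstart=1, qend=unigene_len, sstart=sstart, send=send,
        evalue=0.0, bitscore=2.0 * unigene_len, trace=trace,
    )


def simulate_reference(cfg: SimConfig) -> Reference:
    """Build genome scaffolds, spliced unigenes, alignments and anchors.

    Genes are laid down left to right with random inter-gene gaps; repeat
    family copies are planted inside the gaps (where they can overlap
    primer design windows and must be caught by masking).  The unigene is
    the spliced exon sequence, reverse-complemented for minus-strand
    genes, so transcript-to-genome projections must cross intron gaps.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TruthSet()

    families = [
        _random_seq(rng, cfg.repeat_length) for _ in range(cfg.repeat_families)
    ]
    insertions = [fam for fam in families for _ in range(cfg.repeat_copies)]
    rng.shuffle(insertions)

    gene_span = (
        cfg.exons_per_gene * cfg.exon_length
        + (cfg.exons_per_gene - 1) * cfg.intron_length
    )
    genes_per_scaffold = [
        len([g for g in range(cfg.n_genes) if g % cfg.n_scaffolds == s])
        for s in range(cfg.n_scaffolds)
    ]
    n_gaps = cfg.n_genes + cfg.n_scaffolds
    per_gap = max(1, -(-len(insertions) // n_gaps))

    genome: list[SequenceRecord] = []
    unigenes: list[SequenceRecord] = []
    alignments: list[AlignmentRecord] = []
    anchors: dict[str, MapAnchor] = {}

    gene_index = 0
    for s in range(cfg.n_scaffolds):
        scaffold_id = f"scf{s + 1:03d}"
        parts: list[str] = []
        cursor = 0  # 0-based length so far

        def gap() -> None:
            nonlocal cursor
            chunk = [_random_seq(rng, cfg.gap_length)]
            cursor += cfg.gap_length
            for _ in range(per_gap):
                if insertions:
                    rep = insertions.pop()
                    spacer = _random_seq(rng, 40)
                    truth.repeats.append(
                        (scaffold_id, cursor + 1, cursor + len(rep))
                    )
                    chunk.append(rep)
                    chunk.append(spacer)
                    cursor += len(rep) + len(spacer)
            parts.append("".join(chunk))

        for _ in range(genes_per_scaffold[s]):
            gap()
            gene_id = f"gene{gene_index + 1:03d}"
            unigene_id = f"ug{gene_index + 1:03d}"
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            exon_seqs = [
                _random_seq(rng, cfg.exon_length)
                for _ in range(cfg.exons_per_gene)
            ]
            intron_seqs = [
                _random_seq(rng, cfg.intron_length)
                for _ in range(cfg.exons_per_gene - 1)
            ]
            exons = []
            pos = cursor  # 0-based start of gene
            block = []
            for i, ex in enumerate(exon_seqs):
                exons.append((pos + 1, pos + cfg.exon_length))
                block.append(ex)
                pos += cfg.exon_length
                if i < len(intron_seqs):
                    block.append(intron_seqs[i])
                    pos += cfg.intron_length
            parts.append("".join(block))
            cursor += gene_span

            spliced = "".join(exon_seqs)
            if strand == "-":
                spliced = spliced.translate(
                    str.maketrans("ACGT", "TGCA")
                )[::-1]
            unigenes.append(SequenceRecord(unigene_id, spliced))
            alignments.append(
                _spliced_alignment(
                    unigene_id, scaffold_id, exons, strand, len(spliced)
                )
            )

            chromosome = str(gene_index % cfg.n_chromosomes + 1)
            cm = float(rng.uniform(0.0, cfg.chromosome_cm))
            u = rng.random()
            if u < cfg.anchored_fraction:
                category = "anchored"
                anchors[unigene_id] = MapAnchor(unigene_id, chromosome, cm)
            elif u < cfg.anchored_fraction + cfg.chromosome_only_fraction:
                category = "chromosome_only"
                anchors[unigene_id] = MapAnchor(unigene_id, chromosome, None)
            else:
                category = "no_information"
                anchors[unigene_id] = MapAnchor(unigene_id, None, None)
            gene = Gene(
                gene_id, unigene_id, scaffold_id, strand, tuple(exons),
                chromosome, cm, category,
            )
            truth.genes.append(gene)

            # plant variant loci inside the spliced transcript
            n_total = len(spliced)
            tpositions = sorted(
                rng.choice(
                    np.arange(1, n_total + 1),
                    size=min(cfg.snps_per_gene, n_total),
                    replace=False,
                )
            )
            for j, tpos in enumerate(tpositions):
                gpos = _transcript_to_genome(exons, strand, int(tpos))
                ref = spliced[int(tpos) - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                if rng.random() < cfg.shared_variant_fraction:
                    kind, fixed_line = "shared_alt", None
                else:
                    kind = "founder_diff"
                    fixed_line = PARENT1 if rng.random() < 0.5 else PARENT2
                truth.loci.append(
                    Locus(
                        locus_id=f"{unigene_id}_L{j + 1}",
                        unigene_id=unigene_id,
                        transcript_pos=int(tpos),
                        scaffold=scaffold_id,
                        genome_pos=gpos,
                        chromosome=chromosome,
                        cm=cm,
                        ref_allele=ref,
                        alt_allele=alt,
                        kind=kind,
                        fixed_line=fixed_line,
                    )
                )
            gene_index += 1
        gap()  # trailing gap
        genome.append(SequenceRecord(scaffold_id, "".join(parts)))

    return Reference(genome, unigenes, alignments, anchors, truth)


# ---------------------------------------------------------------------------
# lines and cross


@dataclass
class Cross:
    """Simulated genotypes: parent plants, F1, F2.

    All genotypes are alt-allele dosages in {0, 1, 2}.  ``variants`` is the
    RNA-seq-like per-individual variant table for the line-sequencing
    individuals; ``line_fixed_state`` records, per locus and line, whether
    the line is truly fixed there; ``f1_haplotypes`` holds the two alleles
    (alt copies, 0/1) the F1 actually inherited, one per parental gamete.
    """

    variants: pd.DataFrame
    parent_replicate_genotypes: dict[str, dict[str, int]]
    f1_genotypes: dict[str, int]
    f1_haplotypes: dict[str, list[int]]
    f2_genotypes: dict[str, dict[str, int]]
    line_individual_genotypes: dict[str, dict[str, int]]
    line_fixed_state: dict[str, dict[str, bool]]


def _plant_dosage(
    rng: np.random.Generator, founder_alt: int, fixed: bool, q: float
) -> int:
    """Alt dosage of one plant: founder dosage when the line is fixed at
    the locus, otherwise a Hardy-Weinberg draw at founder frequency q."""
    if fixed:
        return founder_alt
    p_founder = q
    copies = int(rng.random() < p_founder) + int(rng.random() < p_founder)
    # `copies` counts founder-allele copies; translate to alt dosage
    return copies if founder_alt == 2 else 2 - copies


def _gamete(
    rng: np.random.Generator,
    loci_by_chrom: Mapping[str, Sequence[Locus]],
    haplotypes: Mapping[str, list[int]],
) -> dict[str, int]:
    """One F1 gamete (alt copies per locus).

    Crossovers follow the Haldane model: between adjacent loci the chosen
    parental haplotype switches with probability rf = haldane_rf(delta cM),
    independently per interval (no interference).
    """
    alleles: dict[str, int] = {}
    for chrom, loci in loci_by_chrom.items():
        current = int(rng.random() < 0.5)
        prev_cm = None
        for locus in loci:
            if prev_cm is not None:
                rf = haldane_rf(abs(locus.cm - prev_cm))
                if rng.random() < rf:
                    current = 1 - current
            alleles[locus.locus_id] = haplotypes[locus.locus_id][current]
            prev_cm = locus.cm
    return alleles


def simulate_lines_and_cross(cfg: SimConfig, truth: TruthSet) -> Cross:
    """Simulate parental-line individuals, the F1 and the F2 population.

    Within-line heterogeneity is hierarchical: each locus x line is truly
    fixed for the line's founder allele with probability ``fixation_rate``
    and otherwise still segregates within the line at founder-allele
    frequency ``segregating_founder_freq``.  Raising the fixation rate
    therefore monotonically raises the fraction of founder differences the
    polymorphism screen can recover.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    loci = truth.loci

    def founder_alt(locus: Locus, line: str) -> int:
        if locus.kind == "shared_alt":
            return 2
        return 2 if locus.fixed_line == line else 0

    q = cfg.segregating_founder_freq
    fixed_state: dict[str, dict[str, bool]] = {PARENT1: {}, PARENT2: {}}
    for locus in loci:
        for line in (PARENT1, PARENT2):
            fixed_state[line][locus.locus_id] = (
                rng.random() < cfg.fixation_rate
            )

    # per-line sequencing individuals
    line_geno: dict[str, dict[str, int]] = {}
    rows: list[dict] = []
    for line, count in (
        (PARENT1, cfg.n_parent1_individuals),
        (PARENT2, cfg.n_parent2_individuals),
    ):
        for i in range(count):
            sample = f"{line}_{i + 1}"
            geno: dict[str, int] = {}
            for locus in loci:
                dosage = _plant_dosage(
                    rng, founder_alt(locus, line),
                    fixed_state[line][locus.locus_id], q,
                )
                geno[locus.locus_id] = dosage
                depth = int(rng.poisson(cfg.rnaseq_depth))
                if depth == 0:
                    continue
                p_alt = {0: cfg.base_error_rate, 1: 0.5,
                         2: 1.0 - cfg.base_error_rate}[dosage]
                alt_count = int(rng.binomial(depth, p_alt))
                if alt_count == 0:
                    continue
                rows.append(
                    {
                        "sample_id": sample,
                        "line_id": line,
                        "unigene_id": locus.unigene_id,
                        "position": locus.transcript_pos,
                        "ref_allele": locus.ref_allele,
                        "alt_allele": locus.alt_allele,
                        "total_depth": depth,
                        "alt_count": alt_count,
                    }
                )
            line_geno[sample] = geno
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)

    # replicate parent plants for the amplicon run (same latent line state)
    replicates: dict[str, dict[str, int]] = {}
    for line in (PARENT1, PARENT2):
        for i in range(cfg.n_parent_replicates):
            sample = f"{line}_rep{i + 1}"
            replicates[sample] = {
                locus.locus_id: _plant_dosage(
                    rng, founder_alt(locus, line),
                    fixed_state[line][locus.locus_id], q,
                )
                for locus in loci
            }

    # F1: one gamete per line; from a fixed line the gamete carries the
    # founder allele, from a segregating line a frequency-q draw
    f1_hap: dict[str, list[int]] = {}
    f1: dict[str, int] = {}
    for locus in loci:
        alleles = []
        for line in (PARENT1, PARENT2):
            fa = founder_alt(locus, line) // 2  # alt copies of the founder
            if fixed_state[line][locus.locus_id]:
                alleles.append(fa)
            else:
                carries_founder = rng.random() < q
                alleles.append(fa if carries_founder else 1 - fa)
        f1_hap[locus.locus_id] = alleles
        f1[locus.locus_id] = sum(alleles)

    # F2: selfed F1 with Haldane meiosis over the F1's actual haplotypes
    loci_by_chrom: dict[str, list[Locus]] = {}
    for locus in loci:
        loci_by_chrom.setdefault(locus.chromosome, []).append(locus)
    for members in loci_by_chrom.values():
        members.sort(key=lambda l: (l.cm, l.locus_id))

    f2: dict[str, dict[str, int]] = {}
    for i in range(cfg.n_f2):
        g1 = _gamete(rng, loci_by_chrom, f1_hap)
        g2 = _gamete(rng, loci_by_chrom, f1_hap)
        f2[f"F2_{i + 1:03d}"] = {
            locus.locus_id: g1[locus.locus_id] + g2[locus.locus_id]
            for locus in loci
        }

    return Cross(
        variants=variants,
        parent_replicate_genotypes=replicates,
        f1_genotypes=f1,
        f1_haplotypes=f1_hap,
        f2_genotypes=f2,
        line_individual_genotypes=line_geno,
        line_fixed_state=fixed_state,
    )


# ---------------------------------------------------------------------------
# amplicon depths


def simulate_amplicon_depths(
    markers: Sequence,
    cross: Cross,
    truth: TruthSet,
    cfg: SimConfig,
    depth_override: float | None = None,
    read_resample: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Simulate per-sample hotspot read depths for a designed panel.

    ``markers`` is any sequence of objects with ``marker_id``, ``scaffold``
    and ``hotspot_position`` attributes (e.g. MarkerDesign).  Per-marker
    mean depth is log-normal (heterogeneous amplification); per-sample
    depth is Poisson; heterozygote alt counts are beta-binomial around
    0.5; a marker can drop one parental line's allele entirely.  Returns
    the depth table and the expected hotspot class per marker implied by
    the dropout flags and replicate-parent genotypes.

    Marker-level properties (mean amplification, dropout) and read-level
    noise come from separate streams: a nonzero ``read_resample`` redraws
    only the reads, emulating a sequencing rerun of the same library in
    which marker-specific amplification failures recur.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    read_rng = np.random.default_rng(cfg.seed + 3 + read_resample)
    by_pos = truth.locus_by_genome()
    rho = cfg.allele_overdispersion
    ab = 0.5 * (1.0 / rho - 1.0) if rho > 0 else None

    samples: list[tuple[str, Mapping[str, int]]] = []
    for name, geno in cross.parent_replicate_genotypes.items():
        samples.append((name, geno))
    samples.append(("F1_A", cross.f1_genotypes))
    for name, geno in cross.f2_genotypes.items():
        samples.append((name, geno))

    def consensus_of(line: str, locus_id: str) -> str:
        calls = {
            {0: "ref_hom", 1: "het", 2: "alt_hom"}[geno[locus_id]]
            for name, geno in cross.parent_replicate_genotypes.items()
            if name.startswith(line)
        }
        return calls.pop() if len(calls) == 1 else "unfixed"

    rows: list[dict] = []
    true_class: dict[str, int] = {}
    for marker in markers:
        locus = by_pos.get((marker.scaffold, marker.hotspot_position))
        if locus is None:
            raise ValueError(
                f"marker {marker.marker_id} hotspot not on a true locus"
            )
        mean_depth = (
            depth_override
            if depth_override is not None
            else float(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))
        )
        if locus.kind == "shared_alt":
            drop1 = drop2 = False  # line-specific dropout needs a
            # line-specific flanking haplotype; shared variants have none
        else:
            drop1 = rng.random() < cfg.dropout_probability
            drop2 = rng.random() < cfg.dropout_probability

        # the allele each line's dropout removes
        alt_line = locus.fixed_line  # line whose founder allele is alt
        drop_alt = (drop1 and alt_line == PARENT1) or (
            drop2 and alt_line == PARENT2
        )
        drop_ref = (drop1 and alt_line != PARENT1) or (
            drop2 and alt_line != PARENT2
        )

        # expected hotspot class under noiseless calling
        if drop1 and drop2:
            true_class[marker.marker_id] = 3
        elif drop1 or drop2:
            true_class[marker.marker_id] = 4
        else:
            c1 = consensus_of(PARENT1, locus.locus_id)
            c2 = consensus_of(PARENT2, locus.locus_id)
            called = {"ref_hom", "het", "alt_hom"}
            if c1 in called and c2 in called and c1 != c2:
                true_class[marker.marker_id] = 1
            elif "unfixed" in (c1, c2):
                true_class[marker.marker_id] = 5
            else:
                true_class[marker.marker_id] = 2

        for sample, geno in samples:
            alt_copies = geno[locus.locus_id]
            ref_copies = 2 - alt_copies
            if drop_alt:
                alt_copies = 0
            if drop_ref:
                ref_copies = 0
            surviving = alt_copies + ref_copies
            depth = int(read_rng.poisson(mean_depth))
            if surviving == 0 or depth == 0:
                ref_count = alt_count = 0
            else:
                depth = int(read_rng.binomial(depth, surviving / 2.0))
                if alt_copies == 0:
                    alt_count = int(read_rng.binomial(depth, cfg.base_error_rate))
                elif ref_copies == 0:
                    alt_count = depth - int(
                        read_rng.binomial(depth, cfg.base_error_rate)
                    )
                else:  # heterozygous among surviving copies
                    p = float(read_rng.beta(ab, ab)) if ab is not None else 0.5
                    alt_count = int(read_rng.binomial(depth, p))
                ref_count = depth - alt_count
            rows.append(
                {
                    "sample_id": sample,
                    "marker_id": marker.marker_id,
                    "scaffold": marker.scaffold,
                    "position": marker.hotspot_position,
                    "ref_allele": locus.ref_allele,
                    "alt_allele": locus.alt_allele,
                    "is_hotspot": True,
                    "ref_count": ref_count,
                    "alt_count": alt_count,
                }
            )
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS), true_class


# ---------------------------------------------------------------------------
# (de)serialization for stage hand-off


def truth_to_dict(truth: TruthSet) -> dict:
    return {
        "genes": [
            {
                "gene_id": g.gene_id, "unigene_id": g.unigene_id,
                "scaffold": g.scaffold, "strand": g.strand,
                "exons": [list(e) for e in g.exons],
                "chromosome": g.chromosome, "cm": g.cm,
                "anchor_category": g.anchor_category,
            }
            for g in truth.genes
        ],
        "loci": [
            {
                "locus_id": l.locus_id, "unigene_id": l.unigene_id,
                "transcript_pos": l.transcript_pos, "scaffold": l.scaffold,
                "genome_pos": l.genome_pos, "chromosome": l.chromosome,
                "cm": l.cm, "ref_allele": l.ref_allele,
                "alt_allele": l.alt_allele, "kind": l.kind,
                "fixed_line": l.fixed_line,
            }
            for l in truth.loci
        ],
        "repeats": [list(r) for r in truth.repeats],
    }


def truth_from_dict(data: dict) -> TruthSet:
    truth = TruthSet()
    for g in data["genes"]:
        truth.genes.append(
            Gene(
                g["gene_id"], g["unigene_id"], g["scaffold"], g["strand"],
                tuple(tuple(e) for e in g["exons"]), g["chromosome"],
                g["cm"], g["anchor_category"],
            )
        )
    for l in data["loci"]:
        truth.loci.append(Locus(**l))
    for r in data.get("repeats", []):
        truth.repeats.append((r[0], int(r[1]), int(r[2])))
    return truth


def cross_to_dict(cross: Cross) -> dict:
    return {
        "parent_replicate_genotypes": cross.parent_replicate_genotypes,
        "f1_genotypes": cross.f1_genotypes,
        "f1_haplotypes": cross.f1_haplotypes,
        "f2_genotypes": cross.f2_genotypes,
        "line_individual_genotypes": cross.line_individual_genotypes,
        "line_fixed_state": cross.line_fixed_state,
    }


def cross_from_dict(data: dict, variants: pd.DataFrame) -> Cross:
    return Cross(
        variants=variants,
        parent_replicate_genotypes=data["parent_replicate_genotypes"],
        f1_genotypes=data["f1_genotypes"],
        f1_haplotypes=data["f1_haplotypes"],
        f2_genotypes=data["f2_genotypes"],
        line_individual_genotypes=data["line_individual_genotypes"],
        line_fixed_state=data["line_fixed_state"],
    )


__all__ = [
    "Cross",
    "Gene",
    "Locus",
    "PARENT1",
    "PARENT2",
    "Reference",
    "SimConfig",
    "TruthSet",
    "simulate_amplicon_depths",
    "simulate_lines_and_cross",
    "simulate_reference",
]
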