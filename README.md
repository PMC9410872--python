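# ampmap

Genome-wide amplicon-panel marker design and F2 genotyping for highly
heterozygous, large-genome outcrossing crops (developed with onion,
*Allium cepa*, as the motivating system).

## The problem

Large-genome outcrossers are awkward to genotype: arrays do not exist,
RAD-seq wastes depth across a 16-Gb genome, and single-marker assays
(KASP/HRM) do not multiplex. Target amplicon sequencing solves this —
*if* you can design a few hundred primer pairs that (i) capture
polymorphisms that are actually fixed between the parental lines of your
cross, (ii) amplify a single locus each despite massive repeat content,
(iii) avoid splice junctions even though polymorphism discovery happened
on transcripts, and (iv) tile the whole genetic map.

`ampmap` implements that workflow end to end:

1. **Polymorphism detection** — per-individual RNA-seq variant tables of
   two parental lines are threshold-called (minimum coverage 5 reads,
   minimum variant count 2, minimum frequency 20%; allele frequency
   > 80% ⇒ homozygous, otherwise heterozygous). Because outcrossing
   lines are internally heterogeneous, a variant counts as a **line
   allele** only when ≥ *n*−1 of the line's *n* individuals carry the
   same homozygous call; a site is an inter-line polymorphism when it is
   fixed in one line and no individual of the other line has any called
   variant there. Sites are categorized *anchored* / *chromosome-only* /
   *no-information* from a prior genetic map of the transcript set.
2. **Liftover** — transcript positions are projected onto genome
   scaffolds through each transcript's best alignment (highest bitscore,
   deterministic tie-breaks), walking per-base alignment traces across
   intron gaps. Gapped alignments without a trace are refused, never
   interpolated; sites within 150 bp of an alignment edge are dropped as
   junction-adjacent.
3. **Panel design** — canonical k-mers occurring > 10 times in the
   genome (k = 16) form a blacklist; the 300-bp window around each
   projected site (150 up, site, 149 down) is masked wherever a
   blacklisted k-mer covers it; primer pairs (18–25 nt, nearest-neighbour
   Tm 57–63 °C, pair ΔTm ≤ 3 °C, GC 30–70%, no homopolymer ≥ 5, 3′ base
   unmasked) are enumerated to give 120–160-bp amplicons containing the
   site. Specificity is checked by exact 3′ 15-mer matching over both
   genome strands with facing-hit product prediction. Selected markers
   get the universal CS1/CS2 tails (`ACACTGACGACATGGTTCTACA` /
   `TACGGTAGCAGAGACTTGGTCT`) and are split into balanced multiplex pools
   (48 pairs each) that keep 3′-complementary primers apart.
4. **Genotyping** — per-sample ref/alt depths at each amplicon "hotspot"
   are genotype-called, replicate parent plants give per-line consensus,
   and every marker is classified: 1 = polymorphism captured, 2 = no
   variant, 3 = no call, 4 = one parent only, 5 = unfixed line. Class-1
   hotspots (or flanking sites heterozygous in the F1) are coded
   A/H/B per F2 individual; rows with > 10% missing data or 1:2:1
   segregation distortion (χ², df = 2, P < 0.001) are removed.
5. **Linkage QC** — pairwise recombination fractions by EM under the F2
   codominant model (the double-heterozygote class hides its recombinant
   count; its posterior weight is r²/(r²+(1−r)²)), LOD against r = 0.5,
   single-linkage grouping above a LOD threshold (default 4.0), and
   Haldane distances d = −50 ln(1 − 2r) cM.

A synthetic-data module generates every input — spliced transcripts over
a repeat-seeded genome, incompletely fixed parental lines, Haldane
meiosis, log-normal amplicon depth heterogeneity with marker dropout —
so the whole pipeline is testable offline with known truth.

## Worked example

```sh
ampmap simulate --out run --seed 1     # synthetic study: references + cross
ampmap all --out run                   # detect → liftover → design → genotype → linkage
```

The manifest (`run/manifest.json`) traces each stage; with seed 1 and the
default study size (24 genes on 4 scaffolds, two 100-cM chromosomes,
5 + 6 line individuals, 63 F2):

```
simulate              {scaffolds: 4, unigenes: 24, true_loci: 48, variant_rows: 382}
detect-polymorphisms  {calls: 354, fixed_parent1: 28, fixed_parent2: 28, polymorphic_sites: 24}
liftover              {sites_in: 24, projected: 14, dropped: 10}
design-panel          {candidate_sites: 14, designable: 14, panel: 8, pools: 1}
genotype              {markers_called: 7, markers_kept: 7, class_counts: {1: 7, 2: 0, 3: 0, 4: 1, 5: 0}}
linkage-qc            {markers: 7, pairs: 21, groups: 3}
```

Reading this: of 48 true variant loci, 24 pass the within-line fixation
screen (incomplete fixation hides the rest — the expected behaviour for
outcrossing lines); 10 of the 24 sit too close to an exon/alignment edge
for a 150-bp flank and are dropped; all 14 remaining sites yield a
specific primer pair; panel selection keeps 8 spread over the genetic
map; 7 markers capture the polymorphism (class 1) and segregate; linkage
grouping at LOD 4 with only 63 F2 splits the 7 markers into 3 groups
(the two simulated chromosomes, one marker unlinked at this population
size). Stage outputs are plain TSV (`sites.tsv`, `panel.tsv`,
`matrix.tsv`, `pairwise.tsv`, `groups.tsv`) plus a BED of amplicons.

As a library:

```python
from ampmap.linkage import estimate_rf_em, haldane_cm
res = estimate_rf_em([[20, 5, 0], [6, 35, 4], [0, 7, 19]])
print(round(res.rf_hat, 3), round(res.lod, 1), round(haldane_cm(res.rf_hat), 1))
# 0.121 17.8 13.9   (rf, LOD, Haldane cM)
```

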