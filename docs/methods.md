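# Methods

This note documents the models, defaults and numerical choices behind
`ampmap`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Variant thresholding and the within-line fixation rule

Outcrossing breeding lines are not inbred: the same nominal line
segregates at many loci. The pipeline therefore never trusts a single
plant. RNA-seq variant observations are called per individual with four
thresholds (`min_coverage` = 5 reads, `min_count` = 2 reads,
`min_freq` = 20%, `hom_cutoff` = 80%); a site below any detection
threshold is *uncalled*, and a detected variant is homozygous only
strictly above the 80% frequency cutoff — a frequency of exactly 80% is
deliberately heterozygous, since the cutoff itself is not part of either
open interval. A site becomes a **line allele** when at least *n*−1 of
the line's *n* sequenced individuals agree on the same homozygous call
(the all-but-one rule: 4/5 and 5/6 at the default study design); the
denominator is the number of individuals actually sequenced for that
line. "Not detected in the other line" is enforced against *called*
variants only: sub-threshold reads cannot veto a site, because detection
is defined exclusively through the calling thresholds. Multi-allelic
positions are keyed per alt allele, but the opposite-line veto is
positional — any variant there, whatever the allele, disqualifies the
site.

## Coordinate projection

Positions are lifted from transcripts to scaffolds through the best
alignment per transcript (bitscore, then identity, then length, then
lexicographic subject id; equally scoring hits on different scaffolds
survive but carry an `ambiguous-hit` flag). Projection is exact or
refused: gapless HSPs use the linear offset, gapped HSPs are walked
base-by-base through an `M/X/D/I` trace, and a gapped HSP without a
trace is rejected outright — interpolating across an intron would put a
150-bp primer window on the wrong bases, which is precisely the failure
mode the genomic lifting exists to prevent. Sites projecting within one
flank length (150 bp) of either end of the aligned span are dropped as
`near-junction`: their design window would extend beyond sequence known
to be colinear with the transcript.

## Panel design

Repeat masking uses a canonical k-mer blacklist: k = 16, occurrence
cutoff 10, both strands pooled via canonical form. These two parameters
are conventions, not measurements — they are exposed in the config, and
k = 16 with cutoff 10 behaves sensibly at both the synthetic scale and
multi-Gb scale (any 16-mer seen > 10 times is a poor primer seed
anywhere). The 300-bp design window is 150 bp upstream + the site base +
149 bp downstream; the alternative reading (150 + 1 + 150 = 301) was
rejected to honour the stated 300-bp total.

Primer constraints (length 18–25 nt, nearest-neighbour Tm 57–63 °C with
SantaLucia parameters via Biopython, pair ΔTm ≤ 3 °C, GC 30–70%, no
homopolymer run ≥ 5, unmasked 3′ base) are standard panel-design
practice; candidate pairs are ranked by |Tm−60| so the emitted design is
deterministic. Binding-site counting deliberately replaces thermodynamic
annealing models with an exact-match contract: a binding site is an
exact occurrence of the primer's 3′-terminal 15-mer on either strand,
and a predicted product is a facing pair of sites ≤ 1 kb apart. This is
conservative in the direction that matters for panel curation (any
marker failing it is discarded).

Panel selection is a binning heuristic over the genetic map: each
chromosome's anchored cM range is cut into quota-many equal bins and the
site nearest each bin centre is taken; chromosome-only quotas are filled
preferring unseen transcripts and scaffolds; no two panel members may
lie within 1 kb on one scaffold. Only the goal (genome coverage without
redundancy) is externally specified; the binning rule is this package's
choice and is tested for determinism and spread, not optimality.
Pooling is greedy: pools of ≤ 48 pairs, sizes within one of each other,
each design placed where its worst 3′-terminal 8-mer reverse-complement
match against the pool is smallest.

## Amplicon genotyping and marker classes

Hotspot calling reuses the RNA-seq thresholds (the upstream caller's
internals are not part of the contract): no call below 5 reads, alt
frequency > 80% ⇒ alt-homozygous, < 20% ⇒ ref-homozygous, else
heterozygous when the minor allele has ≥ 2 reads. Parental consensus
over the three replicate plants requires unanimity among non-missing
calls — the published workflow determined consensus manually; unanimity
is the strictest mechanical substitute and pushes every ambiguous case
into the *unfixed* class rather than guessing. Marker classes follow
the five-way validation scheme (1 captured, 2 no variant, 3 no call,
4 one parent, 5 unfixed); both-parents-fixed-for-the-same-genotype
falls to class 2, since no inter-parental variant was captured. The
one-parent-no-call case is class 4 (the footnote definitions are taken
as normative over a looser narrative mention that groups them with
class 3).

A/H/B coding is parent-relative, not allele-relative: A is parent-1's
homozygote whichever physical allele that is. Which line is "parent 1"
is configuration, since the orientation is a labelling convention.
Matrix filters are strict inequalities as printed: missing fraction
> 0.10, and 1:2:1 χ² (df = 2) P < 0.001.

## Two-point linkage

For two codominant F2 markers the 3×3 genotype table determines the
recombination fraction up to the double-heterozygote ambiguity (AB/ab
vs Ab/aB both appear as HH). The EM step uses the known recombinant
gamete counts for the eight unambiguous classes and the posterior
expectation 2r²/(r²+(1−r)²) for HH; convergence at |Δr| < 1e−8 or 200
iterations from r₀ = 0.25, estimate clipped to [0, 0.5]. LOD is the
log10 likelihood ratio against r = 0.5. Equivalence with direct
grid-search maximization (step 1e−4) is enforced in tests to 1e−3.
Grouping is single-linkage closure over edges with LOD above the
threshold *and* r̂ < 0.45; the r̂ guard is this package's addition — a
pair of jointly distorted markers can reach a high LOD at r̂ near 0.5,
and such edges should not fuse chromosomes. Marker *ordering* and
multipoint mapping are out of scope; the module stops at groups and
pairwise Haldane distances (d = −50 ln(1−2r), no interference,
consistent with the meiosis simulator).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline must
survive: spliced transcripts over a repeat-seeded genome (repeats are
planted in inter-gene gaps, where they can invade design windows);
**hierarchical within-line heterogeneity** — each locus × line is truly
fixed for the founder allele with probability `fixation_rate` (default
0.85) and otherwise still segregates within the line at founder-allele
frequency 0.7, so sites that pass the fixation screen are mostly, but
not always, reliable, and unfixed (class-5) markers arise naturally;
an F1 drawn as one gamete per line (founder allele from fixed loci,
a frequency-0.7 draw otherwise, so some captured markers fail to
segregate — the reason refined panels retain parent-polymorphic
non-segregating markers); F2 meiosis as per-interval Haldane
recombination (equivalent to a Poisson crossover process, no
interference); and amplicon depths that are log-normal across markers
(sd 1.0 gives the >10× spread between depth deciles seen in multiplex
PCR), Poisson within marker, beta-binomial at heterozygotes
(overdispersion ρ = 0.05), with per-marker-per-line dropout
(probability 0.04 per line) emulating primer-binding-site polymorphisms
that silence one parental allele. Marker-level draws (amplification,
dropout) and read-level draws come from separate streams, so a
"sequencing rerun" resamples reads while marker failures recur — that is
what the resampled duplicate-concordance check measures.

Default study shape: 5 + 6 line individuals, 3 replicate parent plants,
one F1, 63 F2, two 100-cM chromosomes. The default reference is 24
genes on 4 scaffolds; the end-to-end acceptance study uses 60 genes on
6 scaffolds so that class-recovery percentages rest on ~20 panel
markers, and fixes per-site depth at 60 reads where the contract under
test is "behaviour at adequate depth" rather than the depth-
heterogeneity model. These sizes keep the full suite in seconds.

What passing does **not** show: no sequencing-error model beyond a flat
0.5% base error, no PCR chimeras, no alignment or demultiplexing errors
(upstream tools are consumed, not simulated), no crossover
interference, and repeats are exact copies rather than diverged
families — real repeat masking faces decayed copies that an exact
k-mer blacklist only partially covers.

## Degenerate inputs and tie-breaks

Empty alignment lists, empty genotype rows and empty panels raise;
all-missing consensus is `no_call`, not `unfixed`. Ties are always
broken deterministically (lexicographic ids, smallest coordinate,
lowest missing fraction first), and panel selection pre-sorts
candidates by (transcript, position) so input order never matters.
Every generator is seed-deterministic; identical seeds give
byte-identical outputs, which the CLI tests verify end to end.

## Known limitations

- Binding-site counting is exact-match; primers with near-match
  off-targets pass the check (conservatively mitigated by repeat
  masking upstream).
- The EM model assumes coupling-phase coding, which A/H/B
  parent-relative coding guarantees; raw allele-coded input in
  repulsion phase would need recoding first.
- Chromosome labels for linkage groups are majority votes over
  anchored members; a group with no anchored member stays unlabelled.
- VCF input support covers AD-bearing records only; the canonical
  interchange dialect is the TSV.
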