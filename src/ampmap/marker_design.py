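"""Repeat-masked primer-panel design over projected polymorphic sites.

The design step mirrors the k-mer blacklist approach of genome-masking
primer designers: over-represented k-mers of the (large, repeat-rich)
genome are collected into a blacklist, the 300-bp window around each
projected site is masked wherever a blacklisted k-mer covers it, and primer
pairs are enumerated on the unmasked sequence so that no primer terminates
inside a repeat.  Specificity is then checked by counting exact genomic
matches of each primer's 3'-terminal seed and pairing facing hits into
predicted PCR products.

Selected markers receive the universal CS1/CS2 tails used by two-round
amplicon library construction, and the panel is split into multiplex pools
that keep mutually complementary primers apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp

from ampmap.formats import PipelineConfig, SequenceRecord
from ampmap.polymorphism import PolymorphicSite, SiteKey

log = logging.getLogger(__name__)

CS1_TAG = "ACACTGACGACATGGTTCTACA"
CS2_TAG = "TACGGTAGCAGAGACTTGGTCT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# k-mer blacklist


@dataclass(frozen=True)
class KmerBlacklist:
    """Canonical k-mers over-represented in the genome."""

    k: int
    cutoff: int
    kmers: frozenset[str]

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer.upper()) in self.kmers


def build_kmer_blacklist(
    genome: Sequence[SequenceRecord], k: int, cutoff: int
) -> KmerBlacklist:
    """Collect canonical k-mers occurring more than ``cutoff`` times.

    Each duplex position is counted once via its canonical form, so a motif
    and its reverse complement accumulate into one blacklist entry
    (occurrences on both strands are pooled).  k-mers containing N are
    skipped.
    """
    if k < 8:
        raise ValueError("k must be at least 8")
    if not genome:
        raise ValueError("empty genome")
    if all(len(rec.seq) < k for rec in genome):
        log.warning("k=%d exceeds every scaffold length; empty blacklist", k)
        return KmerBlacklist(k, cutoff, frozenset())
    counts: dict[str, int] = {}
    for rec in genome:
        seq = rec.seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            key = canonical(kmer)
            counts[key] = counts.get(key, 0) + 1
    return KmerBlacklist(
        k, cutoff, frozenset(km for km, n in counts.items() if n > cutoff)
    )


# ---------------------------------------------------------------------------
# flanking windows


@dataclass(frozen=True)
class FlankWindow:
    """300-bp design window centred on a projected site.

    ``start`` is the 1-based genome position of the window's first base;
    the site base sits at 0-based ``site_offset`` inside the window
    (``flank`` bases upstream, ``flank - 1`` downstream).
    """

    site_key: SiteKey
    scaffold: str
    start: int
    seq: str
    site_offset: int
    mask: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            object.__setattr__(self, "mask", (False,) * len(self.seq))
        if len(self.mask) != len(self.seq):
            raise ValueError("mask length must equal window length")

    def __len__(self) -> int:
        return len(self.seq)


def extract_window(
    genome: Mapping[str, str],
    scaffold: str,
    pos: int,
    flank: int = 150,
    site_key: SiteKey | None = None,
) -> FlankWindow | None:
    """Cut the ``2*flank``-bp window around 1-based position ``pos``.

    The window is ``flank`` bases upstream, the site base, and ``flank - 1``
    bases downstream (300 bp at the default flank).  Returns None when the
    site sits too close to a scaffold end for a full window
    ("near-scaffold-end").
    """
    if scaffold not in genome:
        raise KeyError(f"unknown scaffold {scaffold}")
    seq = genome[scaffold]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside scaffold {scaffold}")
    lo = pos - 1 - flank  # 0-based window start
    hi = pos - 1 + flank  # 0-based, exclusive
    if lo < 0 or hi > len(seq):
        log.info("site %s:%d skipped: near-scaffold-end", scaffold, pos)
        return None
    return FlankWindow(
        site_key=site_key or (scaffold, pos, "?"),
        scaffold=scaffold,
        start=lo + 1,
        seq=seq[lo:hi].upper(),
        site_offset=flank,
    )


def mask_window(window: FlankWindow, blacklist: KmerBlacklist) -> FlankWindow:
    """Mark every window position covered by a blacklisted k-mer."""
    k = blacklist.k
    mask = np.zeros(len(window), dtype=bool)
    seq = window.seq
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in blacklist:
            mask[i : i + k] = True
    return replace(window, mask=tuple(bool(b) for b in mask))


# ---------------------------------------------------------------------------
# primer pair design


@dataclass(frozen=True)
class MarkerDesign:
    """A designed primer pair with its amplicon on a genome scaffold.

    Intervals are 1-based inclusive genome coordinates.  The reverse primer
    sequence is given 5'->3' (reverse complement of the top strand).
    """

    marker_id: str
    scaffold: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    product_size: int
    hotspot_position: int
    fwd_tm: float
    rev_tm: float
    tagged_fwd: str | None = None
    tagged_rev: str | None = None
    pool_id: int | None = None

    @property
    def amplicon_start(self) -> int:
        return self.fwd_start

    @property
    def amplicon_end(self) -> int:
        return self.rev_end

    def validate(self, cfg: PipelineConfig) -> None:
        assert cfg.amplicon_min <= self.product_size <= cfg.amplicon_max
        assert self.amplicon_start < self.hotspot_position < self.amplicon_end
        assert not self.fwd_start <= self.hotspot_position <= self.fwd_end
        assert not self.rev_start <= self.hotspot_position <= self.rev_end
        assert self.product_size == self.rev_end - self.fwd_start + 1


def gc_percent(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def primer_tm(seq: str) -> float:
    """Nearest-neighbour melting temperature (SantaLucia 1997 defaults)."""
    return float(MeltingTemp.Tm_NN(seq))


def design_primer_pair(
    window: FlankWindow,
    cfg: PipelineConfig,
    marker_id: str | None = None,
    max_candidates: int = 10,
) -> tuple[list[MarkerDesign], str | None]:
    """Enumerate feasible primer pairs in a masked window.

    Constraints: primer length 18-25 nt, nearest-neighbour Tm in
    [tm_min, tm_max], pair Tm difference <= tm_pair_max_diff, GC content
    30-70%, no homopolymer run longer than ``max_homopolymer``, 3'-terminal
    base unmasked; product size within [amplicon_min, amplicon_max] with
    the site strictly inside the amplicon and outside both primers.

    Returns (candidates ranked by |Tm-60| closeness, failure reason or
    None).  Reasons: "masked" (no unmasked primer footprint on one side),
    "no-feasible-pair" otherwise.
    """
    seq, mask, off = window.seq, window.mask, window.site_offset
    n = len(seq)
    lmin, lmax = cfg.primer_len_min, cfg.primer_len_max

    tm_cache: dict[str, float] = {}

    def tm_of(s: str) -> float:
        if s not in tm_cache:
            tm_cache[s] = primer_tm(s)
        return tm_cache[s]

    def primer_ok(s: str) -> bool:
        if "N" in s:
            return False
        if not cfg.gc_min <= gc_percent(s) <= cfg.gc_max:
            return False
        if max_homopolymer_run(s) > cfg.max_homopolymer:
            return False
        return True

    # forward candidates: 0-based [fs, fe), 3' base at fe-1, must end at or
    # before the site so the hotspot stays outside the primer
    fwd: list[tuple[int, int, float]] = []  # (fs, fe, tm)
    for fe in range(off, lmin - 1, -1):
        if mask[fe - 1]:
            continue
        for length in range(lmin, lmax + 1):
            fs = fe - length
            if fs < 0:
                break
            s = seq[fs:fe]
            if not primer_ok(s):
                continue
            tm = tm_of(s)
            if cfg.tm_min <= tm <= cfg.tm_max:
                fwd.append((fs, fe, tm))

    # reverse candidates: top-strand footprint [rs, re), 3' base of the
    # reverse-complement primer sits at rs; must start after the site
    rev: list[tuple[int, int, float]] = []
    for rs in range(off + 1, n - lmin + 1):
        if mask[rs]:
            continue
        for length in range(lmin, lmax + 1):
            re_ = rs + length
            if re_ > n:
                break
            s = revcomp(seq[rs:re_])
            if not primer_ok(s):
                continue
            tm = tm_of(s)
            if cfg.tm_min <= tm <= cfg.tm_max:
                rev.append((rs, re_, tm))

    if not fwd or not rev:
        return [], ("masked" if any(mask) else "no-feasible-pair")

    pairs: list[tuple[float, int, int, int, int, float, float]] = []
    rev_sorted = sorted(rev, key=lambda r: r[1])
    for fs, fe, ftm in fwd:
        for rs, re_, rtm in rev_sorted:
            size = re_ - fs
            if size < cfg.amplicon_min:
                continue
            if size > cfg.amplicon_max:
                break
            if abs(ftm - rtm) > cfg.tm_pair_max_diff:
                continue
            score = abs(ftm - 60.0) + abs(rtm - 60.0)
            pairs.append((score, fs, fe, rs, re_, ftm, rtm))
    if not pairs:
        return [], "no-feasible-pair"
    pairs.sort(key=lambda p: (p[0], p[1], p[3]))

    base = window.start  # genome coordinate of window index 0 (1-based)
    mid = marker_id or f"{window.scaffold}_{base + off}"
    out = []
    for score, fs, fe, rs, re_, ftm, rtm in pairs[:max_candidates]:
        out.append(
            MarkerDesign(
                marker_id=mid,
                scaffold=window.scaffold,
                fwd_seq=seq[fs:fe],
                rev_seq=revcomp(seq[rs:re_]),
                fwd_start=base + fs,
                fwd_end=base + fe - 1,
                rev_start=base + rs,
                rev_end=base + re_ - 1,
                product_size=re_ - fs,
                hotspot_position=base + off,
                fwd_tm=ftm,
                rev_tm=rtm,
            )
        )
    return out, None


# ---------------------------------------------------------------------------
# specificity


@dataclass(frozen=True)
class BindingSite:
    scaffold: str
    strand: str
    three_prime_pos: int  # 1-based genome coordinate of the 3'-terminal base


def find_binding_sites(
    primer: str,
    genome: Sequence[SequenceRecord],
    seed_len: int = 15,
) -> list[BindingSite]:
    """Exact matches of the primer's 3'-terminal seed on either strand."""
    if len(primer) < seed_len:
        raise ValueError(f"primer shorter than seed length {seed_len}")
    seed = primer[-seed_len:].upper()
    seed_rc = revcomp(seed)
    sites: list[BindingSite] = []
    for rec in genome:
        seq = rec.seq.upper()
        i = seq.find(seed)
        while i != -1:
            sites.append(BindingSite(rec.id, "+", i + seed_len))
            i = seq.find(seed, i + 1)
        i = seq.find(seed_rc)
        while i != -1:
            sites.append(BindingSite(rec.id, "-", i + 1))
            i = seq.find(seed_rc, i + 1)
    return sites


def count_binding_sites(
    fwd_primer: str,
    rev_primer: str,
    genome: Sequence[SequenceRecord],
    seed_len: int = 15,
    max_separation: int = 1000,
) -> tuple[int, int, list[tuple[str, int, int]]]:
    """Count binding sites of a primer pair and predict PCR products.

    A product is a plus-strand site of one primer and a minus-strand site
    of the other on the same scaffold with facing 3' ends no more than
    ``max_separation`` bp apart.  Returns (n_fwd_sites, n_rev_sites,
    [(scaffold, start, end)]) with product bounds as the outer 5' ends
    approximated by the 3'-end span.
    """
    fwd_sites = find_binding_sites(fwd_primer, genome, seed_len)
    rev_sites = find_binding_sites(rev_primer, genome, seed_len)
    products = []
    for a_sites, b_sites in ((fwd_sites, rev_sites), (rev_sites, fwd_sites)):
        for a in a_sites:
            if a.strand != "+":
                continue
            for b in b_sites:
                if b.strand != "-" or b.scaffold != a.scaffold:
                    continue
                if b.three_prime_pos <= a.three_prime_pos:
                    continue
                if b.three_prime_pos - a.three_prime_pos + 1 > max_separation:
                    continue
                products.append(
                    (a.scaffold, a.three_prime_pos, b.three_prime_pos)
                )
    return len(fwd_sites), len(rev_sites), sorted(set(products))


# ---------------------------------------------------------------------------
# tagging, panel selection, pooling


def append_common_tags(design: MarkerDesign) -> MarkerDesign:
    """Prefix CS1/CS2 universal tails onto the primer pair (idempotent)."""
    tagged_fwd = design.tagged_fwd
    tagged_rev = design.tagged_rev
    if tagged_fwd is None or not tagged_fwd.startswith(CS1_TAG):
        tagged_fwd = CS1_TAG + design.fwd_seq
    if tagged_rev is None or not tagged_rev.startswith(CS2_TAG):
        tagged_rev = CS2_TAG + design.rev_seq
    return replace(design, tagged_fwd=tagged_fwd, tagged_rev=tagged_rev)


def select_panel(
    sites: Sequence[PolymorphicSite],
    quotas: Mapping[str, tuple[int, int]],
    min_spacing: int = 1000,
) -> list[PolymorphicSite]:
    """Pick a genome-covering marker subset from designable sites.

    ``quotas`` maps chromosome -> (anchored quota, chromosome_only quota).
    Anchored sites: the chromosome's cM range is cut into ``quota`` equal
    bins and the site nearest each bin centre is taken.  Chromosome-only
    sites fill their quota preferring unigenes then scaffolds not already
    represented.  No two selected sites may lie within ``min_spacing`` bp
    on one scaffold.  Deterministic: candidates are pre-sorted by
    (unigene, position).
    """
    ordered = sorted(sites, key=lambda s: (s.unigene_id, s.position, s.alt_allele))
    selected: list[PolymorphicSite] = []
    occupied: dict[str, list[int]] = {}

    def clashes(site: PolymorphicSite) -> bool:
        for pos in occupied.get(site.genome_scaffold, ()):  # type: ignore[arg-type]
            if abs(pos - (site.genome_position or 0)) < min_spacing:
                return True
        return False

    def take(site: PolymorphicSite) -> None:
        selected.append(site)
        occupied.setdefault(site.genome_scaffold, []).append(  # type: ignore[arg-type]
            site.genome_position or 0
        )

    for chrom in sorted(quotas):
        anchored_quota, chr_only_quota = quotas[chrom]
        anchored = [
            s for s in ordered
            if s.category == "anchored" and s.anchor.chromosome == chrom
        ]
        if anchored and anchored_quota > 0:
            if len(anchored) <= anchored_quota:
                log.warning(
                    "chromosome %s: quota %d exceeds %d anchored candidates",
                    chrom, anchored_quota, len(anchored),
                )
                for s in anchored:
                    if not clashes(s):
                        take(s)
            else:
                cms = [s.anchor.cm_position for s in anchored]
                lo, hi = min(cms), max(cms)
                width = (hi - lo) / anchored_quota if hi > lo else 0.0
                for b in range(anchored_quota):
                    centre = lo + (b + 0.5) * width if width else lo
                    pool = [
                        s for s in anchored
                        if s not in selected and not clashes(s)
                    ]
                    if not pool:
                        log.info("chromosome %s: bin %d unfilled", chrom, b)
                        continue
                    take(min(pool, key=lambda s: abs(s.anchor.cm_position - centre)))
        chr_only = [
            s for s in ordered
            if s.category == "chromosome_only" and s.anchor.chromosome == chrom
        ]
        used_unigenes = {s.unigene_id for s in selected}
        used_scaffolds = {s.genome_scaffold for s in selected}
        n_taken = 0
        for prefer_new_unigene, prefer_new_scaffold in (
            (True, True), (False, True), (False, False)
        ):
            for s in chr_only:
                if n_taken >= chr_only_quota:
                    break
                if s in selected or clashes(s):
                    continue
                if prefer_new_unigene and s.unigene_id in used_unigenes:
                    continue
                if prefer_new_scaffold and s.genome_scaffold in used_scaffolds:
                    continue
                take(s)
                used_unigenes.add(s.unigene_id)
                used_scaffolds.add(s.genome_scaffold)
                n_taken += 1
        if n_taken < chr_only_quota and len(chr_only) > n_taken:
            log.warning(
                "chromosome %s: chromosome_only quota %d not met (%d taken)",
                chrom, chr_only_quota, n_taken,
            )
    return selected


def _complementarity(p: str, q: str) -> int:
    """Length of the longest 3'-terminal stretch of p's last 8 nt whose
    reverse complement occurs in q (a primer-dimer risk heuristic)."""
    tail = p[-8:].upper()
    q = q.upper()
    for length in range(len(tail), 0, -1):
        if revcomp(tail[-length:]) in q:
            return length
    return 0


def pair_interaction(d1: MarkerDesign, d2: MarkerDesign) -> int:
    """Worst 3'-complementarity between any primers of two designs."""
    score = 0
    for p in (d1.fwd_seq, d1.rev_seq):
        for q in (d2.fwd_seq, d2.rev_seq):
            score = max(score, _complementarity(p, q), _complementarity(q, p))
    return score


def pool_primers(
    panel: Sequence[MarkerDesign], pool_size: int = 48
) -> list[MarkerDesign]:
    """Partition the panel into balanced multiplex pools.

    ceil(n/pool_size) pools with sizes differing by at most one; each
    design goes (greedily, in panel order) to the open pool where its worst
    3'-complementarity against the pool's members is smallest.
    """
    if not panel:
        raise ValueError("empty panel")
    n = len(panel)
    n_pools = -(-n // pool_size)
    base, extra = divmod(n, n_pools)
    capacities = [base + 1 if i < extra else base for i in range(n_pools)]
    pools: list[list[MarkerDesign]] = [[] for _ in range(n_pools)]
    for design in panel:
        best_pool, best_score = None, None
        for i, pool in enumerate(pools):
            if len(pool) >= capacities[i]:
                continue
            score = max(
                (pair_interaction(design, other) for other in pool), default=0
            )
            if best_score is None or score < best_score:
                best_pool, best_score = i, score
        pools[best_pool].append(design)  # type: ignore[arg-type]
    out = []
    for i, pool in enumerate(pools):
        for design in pool:
            out.append(replace(design, pool_id=i + 1))
    return out


__all__ = [
    "CS1_TAG",
    "CS2_TAG",
    "BindingSite",
    "FlankWindow",
    "KmerBlacklist",
    "MarkerDesign",
    "append_common_tags",
    "build_kmer_blacklist",
    "canonical",
    "count_binding_sites",
    "design_primer_pair",
    "extract_window",
    "find_binding_sites",
    "gc_percent",
    "mask_window",
    "max_homopolymer_run",
    "pair_interaction",
    "pool_primers",
    "primer_tm",
    "revcomp",
    "select_panel",
]
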