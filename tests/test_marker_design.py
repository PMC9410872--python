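import numpy as np
import pytest

from ampmap.formats import MapAnchor, PipelineConfig, SequenceRecord
from ampmap.marker_design import (
    CS1_TAG,
    CS2_TAG,
    FlankWindow,
    append_common_tags,
    build_kmer_blacklist,
    canonical,
    count_binding_sites,
    design_primer_pair,
    extract_window,
    find_binding_sites,
    mask_window,
    pool_primers,
    revcomp,
    select_panel,
)
from ampmap.polymorphism import PolymorphicSite


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_kmer_counts(seqs, k):
    """Oracle: canonical k-mer counts by direct enumeration."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            key = canonical(km)
            counts[key] = counts.get(key, 0) + 1
    return counts


class TestKmerBlacklist:
    def test_homopolymer_blacklisted(self):
        genome = [SequenceRecord("s", "A" * 100)]
        bl = build_kmer_blacklist(genome, k=10, cutoff=10)
        assert "A" * 10 in bl  # 91 occurrences > 10

    def test_unique_random_scaffold_gives_empty_blacklist(self, rng):
        genome = [SequenceRecord("s", random_seq(rng, 1000))]
        bl = build_kmer_blacklist(genome, k=16, cutoff=1)
        oracle = brute_force_kmer_counts([genome[0].seq], 16)
        assert max(oracle.values()) == 1
        assert bl.kmers == frozenset()

    @pytest.mark.parametrize("copies,expected", [(12, True), (9, False)])
    def test_planted_16mer_against_cutoff(self, rng, copies, expected):
        motif = random_seq(rng, 16)
        spacers = [random_seq(rng, 40) for _ in range(copies + 1)]
        seq = spacers[0]
        for i in range(copies):
            seq += motif + spacers[i + 1]
        bl = build_kmer_blacklist([SequenceRecord("s", seq)], 16, cutoff=10)
        assert (motif in bl) is expected
        oracle = brute_force_kmer_counts([seq], 16)
        assert oracle[canonical(motif)] == copies

    def test_matches_brute_force_exactly(self, rng):
        seqs = [random_seq(rng, 300) for _ in range(3)]
        seqs.append(seqs[0][:120] * 2)  # force duplication
        genome = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        bl = build_kmer_blacklist(genome, k=12, cutoff=2)
        oracle = brute_force_kmer_counts(seqs, 12)
        assert bl.kmers == frozenset(
            km for km, n in oracle.items() if n > 2
        )

    def test_reverse_complement_occurrences_pool(self):
        motif = "ACGTTGCACGGATCCA"
        seq = ("T" * 30).join([motif] * 6 + [revcomp(motif)] * 6)
        bl = build_kmer_blacklist([SequenceRecord("s", seq)], 16, cutoff=10)
        assert motif in bl and revcomp(motif) in bl


class TestMaskWindow:
    def brute_force_mask(self, seq, bl):
        k = bl.k
        return tuple(
            any(
                seq[j : j + k] in bl
                for j in range(max(0, i - k + 1), min(i + 1, len(seq) - k + 1))
            )
            for i in range(len(seq))
        )

    def test_no_hit_all_false(self, rng):
        genome = [SequenceRecord("g", "A" * 100)]
        bl = build_kmer_blacklist(genome, 10, 10)
        w = FlankWindow(("u", 1, "G"), "s", 1, random_seq(rng, 300), 150)
        assert not any(mask_window(w, bl).mask)

    def test_single_hit_masks_k_positions(self, rng):
        body = random_seq(rng, 300)
        window_seq = "A" * 10 + body[10:]
        bl = build_kmer_blacklist([SequenceRecord("g", "A" * 100)], 10, 10)
        w = FlankWindow(("u", 1, "G"), "s", 1, window_seq, 150)
        masked = mask_window(w, bl)
        assert masked.mask[:10] == (True,) * 10
        assert masked.mask == self.brute_force_mask(window_seq, bl)

    def test_overlapping_hits_union(self, rng):
        genome_seq = random_seq(rng, 2000)
        genome = [SequenceRecord("g", genome_seq + genome_seq)]  # everything repeated
        bl = build_kmer_blacklist(genome, 16, 1)
        window_seq = genome_seq[:300]
        w = FlankWindow(("u", 1, "G"), "s", 1, window_seq, 150)
        masked = mask_window(w, bl)
        assert masked.mask == self.brute_force_mask(window_seq, bl)
        assert all(masked.mask)


class TestExtractWindow:
    genome = {"s": "ACGT" * 250}  # 1 kb

    def test_interior_site_window_span(self):
        w = extract_window(self.genome, "s", 200, flank=150)
        assert w.start == 50 and len(w) == 300
        assert w.seq == self.genome["s"][49:349].upper()
        assert w.seq[w.site_offset] == self.genome["s"][199]

    def test_near_start_skipped(self):
        assert extract_window(self.genome, "s", 100) is None

    def test_boundary_site_starts_at_base_one(self):
        w = extract_window(self.genome, "s", 151)
        assert w.start == 1

    def test_outside_scaffold_rejected(self):
        with pytest.raises(ValueError):
            extract_window(self.genome, "s", 2000)


class TestDesignPrimerPair:
    def test_benign_window_yields_valid_candidates(self, cfg, rng):
        w = FlankWindow(("u", 1, "G"), "s", 1001, random_seq(rng, 300), 150)
        candidates, reason = design_primer_pair(w, cfg)
        assert candidates, f"no candidates: {reason}"
        for cand in candidates:
            cand.validate(cfg)
            assert cfg.amplicon_min <= cand.product_size <= cfg.amplicon_max
            assert cfg.tm_min <= cand.fwd_tm <= cfg.tm_max
            assert abs(cand.fwd_tm - cand.rev_tm) <= cfg.tm_pair_max_diff

    def test_fully_masked_window_reports_masked(self, cfg, rng):
        w = FlankWindow(
            ("u", 1, "G"), "s", 1, random_seq(rng, 300), 150,
            mask=(True,) * 300,
        )
        candidates, reason = design_primer_pair(w, cfg)
        assert candidates == [] and reason == "masked"

    def test_no_primer_three_prime_end_on_masked_base(self, cfg, rng):
        seq = random_seq(rng, 300)
        mask = tuple(120 <= i < 180 for i in range(300))  # ring around site
        w = FlankWindow(("u", 1, "G"), "s", 1, seq, 150, mask=mask)
        candidates, _ = design_primer_pair(w, cfg)
        for cand in candidates:
            fwd_3p = cand.fwd_end - 1  # 0-based window index (start==1)
            rev_3p = cand.rev_start - 1
            assert not mask[fwd_3p]
            assert not mask[rev_3p]

    def test_amplicon_size_window_respected(self, cfg, rng):
        """A site too close to the window edge cannot fit a 120-bp product
        plus the far primer; design must fail rather than shrink."""
        w = FlankWindow(("u", 1, "G"), "s", 1, random_seq(rng, 300), 290)
        candidates, reason = design_primer_pair(w, cfg)
        assert candidates == []


class TestBindingSites:
    def brute_force_sites(self, primer, genome, seed_len=15):
        seed = primer[-seed_len:]
        hits = []
        for rec in genome:
            seq = rec.seq
            for i in range(len(seq) - seed_len + 1):
                if seq[i : i + seed_len] == seed:
                    hits.append((rec.id, "+", i + seed_len))
                if seq[i : i + seed_len] == revcomp(seed):
                    hits.append((rec.id, "-", i + 1))
        return sorted(hits)

    def test_unique_primer_single_site_single_product(self, cfg, rng):
        w = FlankWindow(("u", 1, "G"), "s", 1, random_seq(rng, 300), 150)
        genome = [SequenceRecord("s", w.seq)]
        candidates, _ = design_primer_pair(w, cfg)
        cand = candidates[0]
        nf, nr, products = count_binding_sites(
            cand.fwd_seq, cand.rev_seq, genome
        )
        assert (nf, nr, len(products)) == (1, 1, 1)

    def test_duplicated_region_counts_two_sites(self, rng):
        primer = random_seq(rng, 20)
        filler = random_seq(rng, 100)
        genome = [
            SequenceRecord("a", filler + primer + filler),
            SequenceRecord("b", primer),
        ]
        sites = find_binding_sites(primer, genome)
        assert len(sites) == 2
        assert [
            (s.scaffold, s.strand, s.three_prime_pos) for s in sorted(
                sites, key=lambda s: s.scaffold
            )
        ] == self.brute_force_sites(primer, genome)

    def test_second_locus_within_range_gives_two_products(self, rng):
        fwd = random_seq(rng, 20)
        rev = random_seq(rng, 20)
        insert = random_seq(rng, 100)
        locus = fwd + insert + revcomp(rev)
        genome = [SequenceRecord("s", locus + random_seq(rng, 1200) + locus)]
        nf, nr, products = count_binding_sites(fwd, rev, genome)
        assert (nf, nr) == (2, 2)
        # two proper loci; cross-locus pairing exceeds the separation limit
        assert len(products) == 2
        # bring the loci close and the facing cross-pair becomes a third
        near = [SequenceRecord("s", locus + random_seq(rng, 300) + locus)]
        _, _, near_products = count_binding_sites(fwd, rev, near)
        assert len(near_products) == 3

    def test_facing_orientation_required(self, rng):
        fwd = random_seq(rng, 20)
        rev = random_seq(rng, 20)
        # reverse site upstream of forward site: 3' ends point apart
        genome = [
            SequenceRecord("s", revcomp(rev) + random_seq(rng, 50) + fwd)
        ]
        _, _, products = count_binding_sites(fwd, rev, genome)
        assert products == []


class TestTags:
    def test_tag_sequences_prepended(self, cfg, rng):
        w = FlankWindow(("u", 1, "G"), "s", 1, random_seq(rng, 300), 150)
        cand = design_primer_pair(w, cfg)[0][0]
        tagged = append_common_tags(cand)
        assert tagged.tagged_fwd == CS1_TAG + cand.fwd_seq
        assert tagged.tagged_rev == CS2_TAG + cand.rev_seq

    def test_idempotent(self, cfg, rng):
        w = FlankWindow(("u", 1, "G"), "s", 1, random_seq(rng, 300), 150)
        cand = design_primer_pair(w, cfg)[0][0]
        once = append_common_tags(cand)
        assert append_common_tags(once) == once


def make_site(unigene, cm, scaffold="scf1", gpos=10_000, chrom="1"):
    anchor = MapAnchor(unigene, chrom, cm)
    return PolymorphicSite(
        unigene, 100, "A", "G", "parent1", 4, anchor=anchor,
        genome_scaffold=scaffold, genome_position=gpos, genome_strand="+",
    )


class TestSelectPanel:
    def test_binning_spreads_selection_over_cm_range(self):
        sites = [
            make_site(f"u{i:02d}", cm=float(10 * i), gpos=10_000 * (i + 1))
            for i in range(10)
        ]  # 0..90 cM
        panel = select_panel(sites, {"1": (5, 0)})
        assert len(panel) == 5
        cms = sorted(s.anchor.cm_position for s in panel)
        gaps = [b - a for a, b in zip(cms, cms[1:])]
        assert min(gaps) >= 10  # bin width is (90-0)/5 = 18; centres 10 apart
        # exhaustive check of the rule: each bin centre's nearest site chosen
        lo, hi = 0.0, 90.0
        width = (hi - lo) / 5
        expected = {
            min(sites, key=lambda s: abs(s.anchor.cm_position - (lo + (b + 0.5) * width))).unigene_id
            for b in range(5)
        }
        assert {s.unigene_id for s in panel} == expected

    def test_quota_exceeding_candidates_takes_all(self):
        sites = [
            make_site(f"u{i}", cm=float(30 * i), gpos=10_000 * (i + 1))
            for i in range(3)
        ]
        panel = select_panel(sites, {"1": (5, 0)})
        assert len(panel) == 3

    def test_min_spacing_excludes_close_neighbours(self):
        a = make_site("u1", cm=10.0, gpos=5_000)
        b = make_site("u2", cm=90.0, gpos=5_500)  # 500 bp away on same scaffold
        panel = select_panel([a, b], {"1": (2, 0)})
        assert len(panel) == 1

    def test_deterministic_under_input_shuffle(self, rng):
        sites = [
            make_site(f"u{i:02d}", cm=float(7 * i), gpos=3_000 * (i + 1))
            for i in range(12)
        ]
        shuffled = list(sites)
        rng.shuffle(shuffled)
        p1 = select_panel(sites, {"1": (4, 0)})
        p2 = select_panel(shuffled, {"1": (4, 0)})
        assert [s.unigene_id for s in p1] == [s.unigene_id for s in p2]


class TestPoolPrimers:
    def _designs(self, rng, n):
        from ampmap.marker_design import MarkerDesign

        out = []
        for i in range(n):
            out.append(
                MarkerDesign(
                    marker_id=f"m{i:03d}", scaffold="s",
                    fwd_seq=random_seq(rng, 20), rev_seq=random_seq(rng, 20),
                    fwd_start=1, fwd_end=20, rev_start=120, rev_end=140,
                    product_size=140, hotspot_position=60,
                    fwd_tm=60.0, rev_tm=60.0,
                )
            )
        return out

    def test_480_pairs_make_ten_pools_of_48(self, rng):
        pooled = pool_primers(self._designs(rng, 480), pool_size=48)
        sizes = {}
        for d in pooled:
            sizes[d.pool_id] = sizes.get(d.pool_id, 0) + 1
        assert len(sizes) == 10 and set(sizes.values()) == {48}

    def test_441_pairs_make_ten_balanced_pools(self, rng):
        pooled = pool_primers(self._designs(rng, 441), pool_size=48)
        sizes = {}
        for d in pooled:
            sizes[d.pool_id] = sizes.get(d.pool_id, 0) + 1
        assert len(sizes) == 10
        assert max(sizes.values()) - min(sizes.values()) <= 1

    def test_single_pair_single_pool(self, rng):
        pooled = pool_primers(self._designs(rng, 1), pool_size=48)
        assert pooled[0].pool_id == 1
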