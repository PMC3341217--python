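"""Tests for the cryptic att-like site scanner against a naive oracle."""

import numpy as np
import pytest

import attkit as ak
from attkit.scanner import ScanQuery, core_scan, find_pairs, merge_hits, scan
from attkit.synthetic import ATTB, ATTP, CORE20, CORE_QUERY, PlantingSpec, generate_genome

from conftest import random_dna


def brute_force_scan(genome: dict, query: ScanQuery, strict=True):
    """Independent regeneration of unmerged scan results with naive loops."""
    results = []
    L = len(query.sequence)
    for seq_id, seq in genome.items():
        seq = seq.upper()
        for strand, q in (("+", query.sequence), ("-", ak.reverse_complement(query.sequence))):
            for i in range(len(seq) - L + 1):
                window = seq[i : i + L]
                if any(c not in "ACGT" for c in window):
                    continue
                matches = sum(a == b for a, b in zip(window, q))
                if query.mode == "identity":
                    ident = matches / L
                    keep = ident > query.threshold if strict else ident >= query.threshold
                else:
                    keep = (L - matches) <= int(query.threshold)
                if keep:
                    results.append((seq_id, i, i + L, strand, matches))
    return sorted(results)


def hits_tuples(hits):
    return sorted((h.seq_id, h.start, h.end, h.strand, h.matches) for h in hits)


ATTP48 = ScanQuery("attP_min48", ATTP.sequence[:48], "identity", 0.60, ATTP.core_offset)


class TestScan:
    def test_exact_planted_copy(self):
        genome, truth = generate_genome(
            5000, 0.4, [PlantingSpec(ScanQuery.from_site(ATTP), 2000)], seed=7
        )
        hits = scan(genome, ScanQuery.from_site(ATTP, threshold=0.9))
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (2000, 2051, "+")
        assert h.identity == 1.0 and h.has_gt_core

    def test_planted_degenerate_site_identity(self):
        """A 48 bp attP-like planting with 18 mismatches (30/48 matches) is
        reported at identity 0.625 under the >0.60 threshold."""
        genome, truth = generate_genome(
            100_000, 0.36, [PlantingSpec(ATTP48, 50_000, mismatches=18)], seed=11
        )
        hits = scan(genome, ATTP48)
        overlapping = [h for h in hits if h.start < truth[0].end and h.end > truth[0].start]
        assert len(overlapping) == 1
        assert overlapping[0].matches == 30
        assert overlapping[0].identity == pytest.approx(30 / 48)
        # verify by direct string comparison against the planted window
        window = genome["chr_synth"][50_000 : 50_048]
        assert sum(a == b for a, b in zip(window, ATTP48.sequence)) == 30

    def test_minus_strand_planting(self):
        genome, truth = generate_genome(
            4000, 0.4, [PlantingSpec(ScanQuery.from_site(ATTB), 1500, strand="-")], seed=3
        )
        hits = scan(genome, ScanQuery.from_site(ATTB, threshold=0.9))
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].has_gt_core

    def test_reverse_complement_symmetry(self, rng):
        """Reverse-complementing the genome flips strands and mirrors
        coordinates but preserves the hit set."""
        seq = random_dna(rng, 3000)
        pos = 1200
        seq = seq[:pos] + ATTP.sequence + seq[pos + 51 :]
        q = ScanQuery.from_site(ATTP, threshold=0.55)
        fwd = scan({"g": seq}, q, merge=False)
        rev = scan({"g": ak.reverse_complement(seq)}, q, merge=False)
        n = len(seq)
        mirrored = sorted(
            (n - h.end, n - h.start, "-" if h.strand == "+" else "+", h.matches)
            for h in fwd
        )
        assert mirrored == sorted((h.start, h.end, h.strand, h.matches) for h in rev)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            genome = {"s": random_dna(rng, int(rng.integers(100, 1500)))}
            q = ScanQuery(
                "q",
                random_dna(rng, int(rng.integers(8, 30))),
                "identity",
                float(rng.uniform(0.5, 0.8)),
                0,
            )
            got = hits_tuples(scan(genome, q, merge=False))
            expected = [("s",) + t[1:] for t in brute_force_scan(genome, q)]
            assert got == sorted(expected)

    def test_ambiguous_windows_skipped(self):
        seq = "ACGT" * 20 + "N" + "ACGT" * 20
        q = ScanQuery("q", "ACGTACGTACGT", "identity", 0.95, 0)
        hits = scan({"s": seq}, q, merge=False)
        assert hits  # clean windows on both sides of the N still report
        assert all("N" not in seq[h.start : h.end] for h in hits)

    def test_query_longer_than_genome_warns_empty(self, caplog):
        q = ScanQuery.from_site(ATTP)
        with caplog.at_level("WARNING", logger="attkit.scanner"):
            assert scan({"tiny": "ACGTACGT"}, q) == []
        assert "longer than every genome sequence" in caplog.text

    def test_threshold_monotonicity(self, rng):
        """Raising the identity threshold never adds hits."""
        genome = {"s": random_dna(rng, 5000)}
        prev = None
        for thr in (0.5, 0.6, 0.7, 0.8):
            got = {
                (h.start, h.strand)
                for h in scan(genome, ScanQuery("q", ATTP.sequence, "identity", thr, 25), merge=False)
            }
            if prev is not None:
                assert got <= prev
            prev = got

    def test_merge_keeps_best_window(self):
        base = scan(
            {"s": "T" * 30 + "AAAAAAAAAA" + "T" * 30},
            ScanQuery("q", "AAAAAAAA", "identity", 0.5, 0),
            merge=False,
        )
        merged = merge_hits(base)
        plus = [h for h in merged if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].matches == 8 and plus[0].start == 30  # leftmost best window


class TestCoreScan:
    def plant_core(self, mismatches, seed=5, include_gt=True):
        spec = PlantingSpec(
            CORE_QUERY, 2000, mismatches=mismatches, include_gt_core=include_gt
        )
        return generate_genome(5000, 0.4, [spec], seed=seed)

    def test_exact_core_hit(self):
        genome, _ = self.plant_core(0)
        hits = core_scan(genome, CORE_QUERY, ak.fixture_site_specs())
        at_locus = [h for h in hits if h.start == 2000]
        assert len(at_locus) == 1
        h = at_locus[0]
        assert h.core_mismatches == 0 and h.has_gt_core
        assert set(h.site_identities) == {"attP", "attB"}
        # the fixture sites share the core verbatim, so frame identity is high
        assert h.site_identities["attP"] >= 20 / 51

    def test_three_mismatches_excluded_at_budget_two(self):
        genome, _ = self.plant_core(3)
        hits = core_scan(genome, CORE_QUERY, ak.fixture_site_specs(), max_mismatch=2)
        assert [h for h in hits if h.start == 2000] == []

    def test_mismatch_budget_monotonicity(self):
        genome, _ = self.plant_core(2)
        loci = []
        for budget in (0, 1, 2, 3):
            hits = core_scan(genome, CORE_QUERY, ak.fixture_site_specs(), max_mismatch=budget)
            loci.append({(h.start, h.strand) for h in hits})
        for small, large in zip(loci, loci[1:]):
            assert small <= large

    def test_planted_inventory_recovered_exactly(self):
        """10 cores planted at 0-2 mismatches among 5 decoys at 3+ mismatches
        are recovered exactly, by comparison against the truth table."""
        rng = np.random.default_rng(99)
        positions = np.arange(10, dtype=int) * 3000 + 500
        decoy_positions = np.arange(5, dtype=int) * 3000 + 17_000
        plantings = [
            PlantingSpec(CORE_QUERY, int(p), mismatches=int(rng.integers(0, 3)))
            for p in positions
        ] + [
            PlantingSpec(CORE_QUERY, int(p), mismatches=int(rng.integers(3, 6)))
            for p in decoy_positions
        ]
        genome, truth = generate_genome(40_000, 0.4, plantings, seed=42)
        hits = core_scan(genome, CORE_QUERY, ak.fixture_site_specs(), max_mismatch=2)
        hit_starts = {h.start for h in hits}
        assert hit_starts == set(positions.tolist())

    def test_truncated_extension_flagged(self):
        seq = CORE20 + random_dna(np.random.default_rng(1), 200)
        hits = core_scan({"s": seq}, CORE_QUERY, ak.fixture_site_specs())
        edge = [h for h in hits if h.start == 0]
        assert edge and edge[0].truncated

    def test_gt_core_destroyed_when_requested(self):
        genome, truth = self.plant_core(2, include_gt=False)
        assert truth[0].has_gt_core is False
        hits = core_scan(genome, CORE_QUERY, ak.fixture_site_specs())
        at_locus = [h for h in hits if h.start == 2000]
        assert at_locus and not at_locus[0].has_gt_core


class TestFindPairs:
    def make_hit(self, seq_id, start, end, strand, gt=True, query="attP_full"):
        return ak.ScanHit(query, seq_id, start, end, strand, 40, 0.8, None, gt)

    def test_direct_pair_distance(self):
        """Two GT-bearing hits in direct orientation 105 kb apart pair up with
        a predicted excision outcome."""
        hp = self.make_hit("chr4", 5000, 5051, "+")
        hb = self.make_hit("chr4", 110_051, 110_093, "+", query="attB_full")
        pairs = find_pairs([hp], [hb], require_gt=True)
        assert len(pairs) == 1
        assert pairs[0].distance == 105_000
        assert pairs[0].orientation == "direct"
        assert pairs[0].predicted_outcome == "excision"

    def test_different_sequences_do_not_pair(self):
        hp = self.make_hit("chr1", 100, 151, "+")
        hb = self.make_hit("chr2", 100, 142, "+", query="attB_full")
        assert find_pairs([hp], [hb]) == []

    def test_require_gt_excludes_coreless_hit(self):
        hp = self.make_hit("chr1", 100, 151, "+", gt=False)
        hb = self.make_hit("chr1", 5000, 5042, "+", query="attB_full")
        assert find_pairs([hp], [hb], require_gt=True) == []
        assert len(find_pairs([hp], [hb], require_gt=False)) == 1

    def test_inverted_orientation_and_sorting(self):
        hp = self.make_hit("c", 0, 51, "+")
        near = self.make_hit("c", 100, 142, "-", query="attB_full")
        far = self.make_hit("c", 9000, 9042, "+", query="attB_full")
        pairs = find_pairs([hp], [near, far])
        assert [p.orientation for p in pairs] == ["inverted", "direct"]
        assert pairs[0].distance < pairs[1].distance
        assert pairs[0].predicted_outcome == "inversion"
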