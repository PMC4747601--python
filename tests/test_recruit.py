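"""Read alignment, hit filtering, and recruitment profile aggregation.

The seed-and-extend aligner is cross-checked against a full Smith-Waterman
(Biopython local aligner) oracle on constructed reads; depth accumulation
is checked by exact integer conservation.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from panrecruit import GeneSequence, build_pangenome, cluster_greedy
from panrecruit.align import READ_TOO_SHORT
from panrecruit.recruit import (
    AlignmentHit,
    PanGenomeIndex,
    align_read,
    filter_hits,
    profile,
    recruit_reads,
    recruitment_plot_points,
)
from panrecruit.sequtils import random_dna, revcomp


def _pangenome(sp: str, seqs: dict[str, str]):
    genes = [GeneSequence(gid, sp, "ref", s) for gid, s in seqs.items()]
    return build_pangenome(cluster_greedy(genes), sp)


def _sub(seq: str, positions) -> str:
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = alt[out[p]]
    return "".join(out)


def _sw_oracle(read: str, target: str) -> tuple[int, int, int]:
    """(identities, start, end) of the best local alignment, full DP."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(target, read)[0]
    counts = aln.counts()
    start = int(aln.coordinates[0][0])
    end = int(aln.coordinates[0][-1])
    return counts.identities, start, end


@pytest.fixture(scope="module")
def single_gene_index(rng_module=None):
    rng = np.random.default_rng(7)
    gene = random_dna(1000, rng)
    pg = _pangenome("spA", {"g0": gene})
    return gene, pg, PanGenomeIndex([pg])


class TestAlignRead:
    def test_exact_slice_full_identity_and_coordinates(self, single_gene_index):
        gene, _, index = single_gene_index
        hits, reason = align_read(gene[200:450], index, read_id="r")
        assert reason is None
        primary = hits[0]
        assert primary.identity == 1.0
        assert primary.read_aligned_fraction == 1.0
        assert (primary.target_start, primary.target_end) == (200, 450)
        assert primary.strand == "+"

    def test_reverse_complement_same_coordinates_minus_strand(self, single_gene_index):
        gene, _, index = single_gene_index
        hits, _ = align_read(revcomp(gene[200:450]), index, read_id="r")
        primary = hits[0]
        assert (primary.target_start, primary.target_end) == (200, 450)
        assert primary.strand == "-"
        assert primary.identity == 1.0

    def test_ten_percent_substitutions_match_smith_waterman_oracle(
        self, single_gene_index
    ):
        gene, _, index = single_gene_index
        positions = np.random.default_rng(21).choice(250, 25, replace=False)
        read = _sub(gene[100:350], positions.tolist())  # 25 substitutions (10%)
        hits, _ = align_read(read, index, read_id="r")
        primary = hits[0]
        assert primary.identity == pytest.approx(0.90, abs=0.005)
        assert (primary.target_start, primary.target_end) == (100, 350)
        identities, start, end = _sw_oracle(read, gene)
        assert primary.matches == identities
        assert (primary.target_start, primary.target_end) == (start, end)

    def test_short_read_reports_reason_code(self, single_gene_index):
        _, _, index = single_gene_index
        hits, reason = align_read("ACGTACGT", index)
        assert hits == [] and reason == READ_TOO_SHORT

    def test_read_with_indels_recovered(self, single_gene_index):
        """A read with one insertion and one deletion still maps to its
        true locus (gap handling of the extension step)."""
        gene, _, index = single_gene_index
        raw = gene[300:550]
        read = raw[:80] + "A" + raw[80:170] + raw[171:]
        hits, _ = align_read(read, index, read_id="r")
        primary = hits[0]
        assert primary.target_start == pytest.approx(300, abs=2)
        assert primary.target_end == pytest.approx(550, abs=2)
        assert primary.identity > 0.97


class TestFilterHits:
    def _hit(self, read_id="r", species="spA", gene="g0", frac=1.0, score=100.0,
             identity=0.95):
        return AlignmentHit(
            read_id=read_id, species_id=species, target_gene_id=gene,
            target_start=0, target_end=100, strand="+", matches=95,
            alignment_length=100, identity=identity,
            read_aligned_fraction=frac, score=score,
        )

    def test_fraction_below_boundary_removed(self):
        assert filter_hits([self._hit(frac=0.79)]) == []

    def test_fraction_at_boundary_kept_inclusive(self):
        assert len(filter_hits([self._hit(frac=0.80)])) == 1

    def test_best_score_per_read_species_wins(self):
        lo = self._hit(gene="g1", score=95.0)
        hi = self._hit(gene="g2", score=120.0)
        kept = filter_hits([lo, hi])
        assert len(kept) == 1 and kept[0].target_gene_id == "g2"

    def test_score_tie_breaks_by_identity_then_gene_id(self):
        a = self._hit(gene="zz", score=100.0, identity=0.99)
        b = self._hit(gene="aa", score=100.0, identity=0.95)
        assert filter_hits([a, b])[0].target_gene_id == "zz"
        c = self._hit(gene="bb", score=100.0, identity=0.99)
        assert filter_hits([a, c])[0].target_gene_id == "bb"

    def test_different_species_kept_independently(self):
        a = self._hit(species="spA")
        b = self._hit(species="spB")
        assert len(filter_hits([a, b])) == 2


class TestProfile:
    def test_perfect_tiling_coverage_one_consensus_reference(self):
        rng = np.random.default_rng(11)
        gene = random_dna(1000, rng)
        pg = _pangenome("spA", {"g0": gene})
        index = PanGenomeIndex([pg])
        hits = []
        for i in range(10):
            h, _ = align_read(gene[i * 100 : (i + 1) * 100], index, read_id=f"r{i}")
            hits.extend(h)
        prof = profile(filter_hits(hits), pg)
        assert prof.recruited_reads == 10
        assert prof.coverage_depth == pytest.approx(1.0)
        assert prof.breadth == pytest.approx(1.0)
        assert prof.average_identity == pytest.approx(1.0)
        assert prof.consensus == gene

    def test_no_hits_zero_profile_all_n(self):
        rng = np.random.default_rng(12)
        pg = _pangenome("spA", {"g0": random_dna(300, rng)})
        prof = profile([], pg)
        assert prof.recruited_reads == 0
        assert prof.coverage_depth == 0.0
        assert set(prof.consensus) == {"N"}
        assert len(prof.consensus) == 300

    def test_depth_conservation_is_integer_exact(self, small_community, small_pangenomes):
        cfg, _, _, _, reads, _ = small_community
        from panrecruit.qc import merge_pairs

        merged, _ = merge_pairs(reads.r1[:400], reads.r2[:400], reads.quality,
                                reads.ids[:400])
        grouped = recruit_reads(
            ((r.id, r.sequence) for r in merged), list(small_pangenomes.values())
        )
        for sp, pg in small_pangenomes.items():
            prof = profile(grouped[sp], pg)
            aligned_bases = sum(
                int(np.count_nonzero(h.qcodes < 4)) for h in grouped[sp]
            )
            assert int(prof.depth_vector.sum()) == aligned_bases

    def test_consensus_recovers_dominant_strain_variant(self):
        """Deep coverage of a diverged population: the consensus matches the
        strain, not the reference, at substituted sites."""
        rng = np.random.default_rng(13)
        gene = random_dna(600, rng)
        strain = _sub(gene, range(10, 600, 50))
        pg = _pangenome("spA", {"g0": gene})
        index = PanGenomeIndex([pg])
        hits = []
        for i in range(20):
            start = int(rng.integers(0, 600 - 200))
            h, _ = align_read(strain[start : start + 200], index, read_id=f"r{i}")
            hits.extend(h)
        prof = profile(filter_hits(hits), pg)
        covered = prof.depth_vector > 0
        for p in range(10, 600, 50):
            if covered[p] and prof.depth_vector[p] >= 3:
                assert prof.consensus[p] == strain[p]


class TestPlotPoints:
    def test_single_hit_midpoint_and_identity(self):
        rng = np.random.default_rng(14)
        pg = _pangenome("spA", {"g0": random_dna(1000, rng)})
        hit = AlignmentHit(
            read_id="r", species_id="spA", target_gene_id="g0",
            target_start=0, target_end=100, strand="+", matches=100,
            alignment_length=100, identity=1.0, read_aligned_fraction=1.0,
            score=100.0,
        )
        points = recruitment_plot_points([hit], pg)
        assert points.shape == (1, 2)
        assert points.iloc[0]["position"] == 50.0
        assert points.iloc[0]["identity_pct"] == 100.0

    def test_empty_input_empty_set(self):
        rng = np.random.default_rng(15)
        pg = _pangenome("spA", {"g0": random_dna(100, rng)})
        assert len(recruitment_plot_points([], pg)) == 0

    def test_points_lie_on_concatenated_axis(self, small_community, small_pangenomes):
        cfg, _, strains, _, reads, _ = small_community
        from panrecruit.qc import merge_pairs

        merged, _ = merge_pairs(reads.r1[:200], reads.r2[:200], reads.quality,
                                reads.ids[:200])
        grouped = recruit_reads(
            ((r.id, r.sequence) for r in merged), list(small_pangenomes.values())
        )
        for sp, pg in small_pangenomes.items():
            points = recruitment_plot_points(grouped[sp], pg)
            if len(points):
                assert (points["position"] >= 0).all()
                assert (points["position"] < pg.total_length).all()
                assert len(points) == len(grouped[sp])
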