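"""Protein-hit aggregation, chimera calling/splitting, ORF finding and
contamination screening."""

import numpy as np
import pytest

from chimeraloci.annotate import (
    aggregate_pair_stats,
    call_gene_blocks,
    dedupe_protein_level,
    filter_protein_hits,
    find_longest_orf,
    screen_contamination,
    split_chimera,
    ChimeraCandidate,
    GeneBlock,
    PairStats,
)
from chimeraloci.tabio import Hit, SeqRecord

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


def phit(q, s, npos=100, nident=90, alen=120, qstart=1, qend=360, evalue=1e-50):
    return Hit(q, s, 90.0, alen, 0, 0, qstart, qend, 1, alen, evalue, 200.0, nident, npos)


def stats_row(q, s, npos, alen, qmin, qmax, evalue=1e-50, nident=None):
    return PairStats(q, s, npos, nident if nident is not None else npos, alen, evalue, [(qmin, qmax)])


class TestAggregate:
    def test_two_hsps_summed(self):
        hits = [
            phit("t1", "P1", npos=40, nident=35, alen=50, qstart=100, qend=249),
            phit("t1", "P1", npos=30, nident=28, alen=40, qstart=400, qend=519),
        ]
        (s,) = aggregate_pair_stats(hits)
        assert (s.total_positive, s.total_align_len) == (70, 90)
        assert s.homology_pct == pytest.approx(100 * 70 / 90)
        assert s.qspan == [(100, 249), (400, 519)]

    def test_single_hsp_passthrough(self):
        (s,) = aggregate_pair_stats([phit("t1", "P1", npos=40, nident=30, alen=50)])
        assert (s.total_positive, s.total_identical, s.total_align_len) == (40, 30, 50)

    def test_two_proteins_two_rows(self):
        rows = aggregate_pair_stats([phit("t1", "P1"), phit("t1", "P2")])
        assert {r.subject_id for r in rows} == {"P1", "P2"}


class TestOrthologyFilter:
    def test_boundary_retained(self):
        s = stats_row("t", "P", npos=35, alen=70, qmin=1, qmax=210, evalue=1e-05)
        assert filter_protein_hits([s]) == [s]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(npos=34, alen=60),  # too few positives
            dict(npos=35, alen=71),  # homology 49.3% < 50
            dict(npos=35, alen=70, evalue=2e-05),  # evalue above cutoff
        ],
    )
    def test_below_threshold_dropped(self, kw):
        assert filter_protein_hits([stats_row("t", "P", qmin=1, qmax=210, **kw)]) == []


class TestChimeraCalling:
    def test_separated_blocks_called_chimera(self):
        rows = [
            stats_row("t1", "P1", 100, 100, 100, 400),
            stats_row("t1", "P2", 100, 100, 600, 900),
        ]
        blocks, cands = call_gene_blocks(rows)
        assert len(blocks["t1"]) == 2
        assert cands[0].n_genes == 2
        assert [b.gene_id for b in cands[0].blocks] == ["t1.g1", "t1.g2"]

    def test_cooccupying_homologs_merge_into_one_block(self):
        rows = [
            stats_row("t1", "P1", 100, 100, 100, 400),
            stats_row("t1", "P2", 90, 100, 120, 410),
        ]
        blocks, cands = call_gene_blocks(rows)
        assert cands == []
        (b,) = blocks["t1"]
        assert (b.qstart, b.qend) == (100, 410)
        assert b.representative_protein == "P1"  # higher positives
        assert b.members == ["P1", "P2"]

    def test_single_subject_not_chimera(self):
        blocks, cands = call_gene_blocks([stats_row("t1", "P1", 100, 100, 1, 300)])
        assert cands == [] and len(blocks["t1"]) == 1

    def test_half_overlap_boundary_is_separate(self):
        # overlap exactly 50% of the shorter interval -> not merged (> rule)
        rows = [
            stats_row("t1", "P1", 100, 100, 1, 200),
            stats_row("t1", "P2", 100, 100, 101, 300),
        ]
        blocks, _ = call_gene_blocks(rows)
        assert len(blocks["t1"]) == 2

    def test_hit_order_invariance(self):
        rows = [
            stats_row("t1", "P1", 100, 100, 100, 400),
            stats_row("t1", "P2", 90, 100, 150, 420),
            stats_row("t1", "P3", 80, 100, 700, 990),
        ]
        rng = np.random.default_rng(0)
        base = call_gene_blocks(rows)
        for _ in range(6):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            assert call_gene_blocks(perm) == base


class TestSplit:
    def mkcand(self, spans, tid="t1"):
        blocks = [
            GeneBlock(tid, i, s, e, f"P{i}", [f"P{i}"]) for i, (s, e) in enumerate(spans, 1)
        ]
        return ChimeraCandidate(tid, blocks)

    def test_extension_and_ids(self):
        seq = SeqRecord("t1", "A" * 1000)
        subs = split_chimera(self.mkcand([(100, 400), (600, 900)]), seq)
        assert [r.id for r in subs] == ["t1.g1", "t1.g2"]
        assert len(subs[0]) == 475 - 25 + 1  # 100-75 .. 400+75

    def test_clipping_at_sequence_ends(self):
        seq = SeqRecord("t1", "A" * 300)
        sub = split_chimera(self.mkcand([(1, 200), (280, 300)]), seq, ext=75)[0]
        assert len(sub) == 275  # clipped start 1, end 200 + 75

    def test_subrecords_are_exact_substrings(self):
        rng = np.random.default_rng(1)
        seq = SeqRecord("t1", "".join("ACGT"[i] for i in rng.integers(0, 4, 1200)))
        subs = split_chimera(self.mkcand([(50, 300), (500, 800), (900, 1150)]), seq)
        assert len(subs) == 3
        for sub in subs:
            assert sub.sequence in seq.sequence

    def test_block_outside_sequence_is_error(self):
        seq = SeqRecord("t1", "A" * 100)
        with pytest.raises(ValueError, match="outside"):
            split_chimera(self.mkcand([(50, 200), (300, 400)]), seq)


def brute_force_orf(seq: str, min_aa: int):
    """Independent quadratic scan over all six frames."""
    stops = {"TAA", "TAG", "TGA"}
    n = len(seq)
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= n:
                if s[j : j + 3] in stops:
                    if j == i:
                        break
                    aa = (j - i) // 3
                    if strand == "+":
                        start, end = i + 1, j + 3
                    else:
                        start, end = n - (j + 3) + 1, n - i
                    cand = (-aa, 0 if strand == "+" else 1, start, end)
                    if best is None or cand < best:
                        best = cand
                    break
                j += 3
            # only the first in-frame stop closes an ORF; ATGs inside longer
            # ORFs are handled by scanning every ATG independently
    if best is None or -best[0] < min_aa:
        return None
    return best


class TestOrf:
    def test_hand_readable(self):
        orf = find_longest_orf(SeqRecord("t", "ATGAAATGA"), min_aa=2)
        assert (orf.start, orf.end, orf.strand, orf.protein_length) == (1, 9, "+", 2)

    def test_minus_strand_symmetry(self):
        plus = "CC" + "ATG" + "GCA" * 30 + "TAA" + "GG"
        fwd = find_longest_orf(SeqRecord("t", plus), min_aa=10)
        rev = find_longest_orf(SeqRecord("t", revcomp(plus)), min_aa=10)
        assert fwd.protein_length == rev.protein_length == 31
        assert rev.strand == "-"
        assert (rev.start, rev.end) == (len(plus) - fwd.end + 1, len(plus) - fwd.start + 1)

    def test_below_min_aa_absent(self):
        assert find_longest_orf(SeqRecord("t", "ATGAAATGA"), min_aa=3) is None

    def test_matches_brute_force_on_fuzzed_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(30, 300))))
            got = find_longest_orf(SeqRecord("t", seq), min_aa=1)
            want = brute_force_orf(seq, min_aa=1)
            if want is None:
                assert got is None
            else:
                aa, srank, start, end = want
                assert (got.protein_length, got.start, got.end) == (-aa, start, end)
                assert (0 if got.strand == "+" else 1) == srank


class TestContamination:
    def chit(self, q, pident, npos):
        return Hit(q, "chrX", pident, 200, 0, 0, 1, 200, 1, 200, 1e-80, 300.0, min(npos, 200), npos)

    def test_boundary_flagged(self):
        assert screen_contamination([self.chit("t1", 90.0, 100)]) == {"t1"}

    def test_below_identity_not_flagged(self):
        assert screen_contamination([self.chit("t1", 89.9, 150)]) == set()

    def test_no_hits_not_flagged(self):
        assert screen_contamination([]) == set()

    def test_protein_level_dedupe_drops_shorter(self):
        h = Hit("a", "b", 95.0, 150, 0, 0, 1, 150, 1, 150, 1e-60, 250.0, 140, 140)
        assert dedupe_protein_level([h], {"a": 500, "b": 300}) == {"b"}
        assert dedupe_protein_level([h], {"a": 300, "b": 300}) == {"b"}  # tie: larger id
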