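"""Locus placement, pair-configuration classification against a geometric
oracle, summary accounting and lineage specificity."""

import pytest

from chimeraloci.locusval import (
    GenomeEvidence,
    GenomeRoles,
    GenePlacement,
    PairConfiguration,
    best_loci,
    best_locus,
    classify_pair_configuration,
    filter_genome_hits,
    round_half_up_percent,
    specificity_sets,
    summarize_validation,
    validate_chimeras,
)
from chimeraloci.tabio import GffFeature, Hit


def placement(start, end, strand="+", gene="g", scaffold="s1", genome="Ah",
              bitscore=300.0, coverage=90.0, pident=80.0):
    return GenePlacement(gene, genome, scaffold, start, end, strand, bitscore, pident, coverage)


def ghit(gene, scaffold, sstart, send, pident=80.0, alen=100, qstart=1, qend=300, bits=300.0):
    nid = int(alen * pident / 100)
    return Hit(gene, scaffold, pident, alen, 0, 0, qstart, qend, sstart, send, 1e-60, bits, nid, nid)


class TestPlacementFilter:
    def test_boundary_identity_and_coverage_kept(self):
        hits = [ghit("g", "s1", 1000, 1299, pident=60.0, qstart=1, qend=300)]
        (p,) = filter_genome_hits(hits, {"g": 500})
        assert (p.start, p.end, p.strand) == (1000, 1299, "+")
        assert p.query_coverage == pytest.approx(60.0)

    def test_coverage_below_threshold_dropped(self):
        hits = [ghit("g", "s1", 1000, 1299, qstart=1, qend=299)]  # 59.8% of 500
        assert filter_genome_hits(hits, {"g": 500}) == []

    def test_split_hsps_chain_and_sum_coverage(self):
        hits = [
            ghit("g", "s1", 1000, 1299, qstart=1, qend=150),
            ghit("g", "s1", 2000, 2299, qstart=151, qend=300),
        ]
        (p,) = filter_genome_hits(hits, {"g": 500})
        assert (p.start, p.end) == (1000, 2299)
        assert p.query_coverage == pytest.approx(60.0)

    def test_distant_hsps_not_chained(self):
        hits = [
            ghit("g", "s1", 1000, 1299, qstart=1, qend=300),
            ghit("g", "s1", 50_000, 50_299, qstart=1, qend=300),
        ]
        assert len(filter_genome_hits(hits, {"g": 500})) == 2

    def test_minus_strand_normalised(self):
        (p,) = filter_genome_hits([ghit("g", "s1", 1299, 1000)], {"g": 500})
        assert (p.start, p.end, p.strand) == (1000, 1299, "-")

    def test_unknown_gene_length_is_error(self):
        with pytest.raises(ValueError, match="unknown gene length"):
            filter_genome_hits([ghit("g", "s1", 1, 300)], {"other": 10})


class TestBestLocus:
    def test_bitscore_then_coverage(self):
        lo = placement(1, 100, bitscore=200.0)
        hi = placement(500, 600, bitscore=380.0)
        assert best_locus([lo, hi]) is hi
        a = placement(1, 100, bitscore=300.0, coverage=80.0)
        b = placement(500, 600, bitscore=300.0, coverage=60.0)
        assert best_locus([a, b]) is a

    def test_co_optimal_loci_all_retained(self):
        a = placement(1, 100)
        b = placement(9000, 9099)
        assert best_loci([a, b]) == [a, b]

    def test_empty_is_absent(self):
        assert best_locus([]) is None and best_loci([]) == []


# ---------------------------------------------------------------------------
# Independent geometric oracle


def oracle(a, b, max_gap=50_000):
    """Brute-force classification via explicit base sets."""
    if (a.scaffold, a.start, a.end, a.strand) == (b.scaffold, b.start, b.end, b.strand):
        return ("excluded_identical_coords", None, None)
    if a.scaffold != b.scaffold:
        return ("excluded_diff_scaffold", None, None)
    sa, sb = set(range(a.start, a.end + 1)), set(range(b.start, b.end + 1))
    inter = sa & sb
    if inter:
        category = "contained" if (sa <= sb or sb <= sa) else "overlapping"
    else:
        gap = min(abs(a.start - b.end), abs(b.start - a.end)) - 1
        if gap > max_gap:
            return ("excluded_distance", None, None)
        category = "non_overlapping"
    if a.strand == b.strand:
        ori = "co_oriented"
    else:
        d33 = abs((a.end if a.strand == "+" else a.start) - (b.end if b.strand == "+" else b.start))
        d55 = abs((a.start if a.strand == "+" else a.end) - (b.start if b.strand == "+" else b.end))
        if not inter:
            up, down = (a, b) if a.start <= b.start else (b, a)
            ori = "convergent" if up.strand == "+" else "divergent"
        else:
            ori = "convergent" if d33 <= d55 else "divergent"
    return ("validated", category, ori)


GRID_B_SPANS = [
    (950, 980),      # disjoint, upstream of a
    (950, 1999),     # overlap left edge
    (1000, 2000),    # equal span
    (1200, 1600),    # contained in a
    (900, 2100),     # contains a
    (1900, 2900),    # overlap right edge
    (2001, 2600),    # adjacent, gap 0
    (2613, 3600),    # the 612-base worked gap
    (52_001, 52_100),  # boundary: gap exactly 50,000
    (52_002, 52_100),  # boundary: gap 50,001
]


class TestClassificationGrid:
    @pytest.mark.parametrize("strand_a", "+-")
    @pytest.mark.parametrize("strand_b", "+-")
    @pytest.mark.parametrize("span_b", GRID_B_SPANS)
    def test_matches_geometric_oracle(self, strand_a, strand_b, span_b):
        a = placement(1000, 2000, strand_a, gene="ga")
        b = placement(span_b[0], span_b[1], strand_b, gene="gb")
        got = classify_pair_configuration(a, b)
        want_status, want_cat, want_ori = oracle(a, b)
        assert got.status == want_status
        assert got.overlap_category == want_cat
        assert got.orientation == want_ori

    @pytest.mark.parametrize("strand_a", "+-")
    @pytest.mark.parametrize("strand_b", "+-")
    @pytest.mark.parametrize("span_b", GRID_B_SPANS)
    def test_symmetry(self, strand_a, strand_b, span_b):
        a = placement(1000, 2000, strand_a, gene="ga")
        b = placement(span_b[0], span_b[1], strand_b, gene="gb")
        ab = classify_pair_configuration(a, b)
        ba = classify_pair_configuration(b, a)
        assert (ab.status, ab.overlap_category, ab.orientation, ab.gap) == (
            ba.status, ba.overlap_category, ba.orientation, ba.gap
        )

    def test_worked_readthrough_geometry(self):
        # convergent pair separated by exactly 612 intervening bases
        a = placement(1000, 2000, "+", gene="dhdps1")
        b = placement(2613, 3600, "-", gene="a_glucosidase")
        got = classify_pair_configuration(a, b)
        assert got.status == "validated"
        assert got.overlap_category == "non_overlapping"
        assert got.orientation == "convergent"
        assert got.gap == 612

    def test_identical_coordinates_excluded_before_all_else(self):
        a = placement(1000, 2000, "+", gene="ga")
        b = placement(1000, 2000, "+", gene="gb")
        assert classify_pair_configuration(a, b).status == "excluded_identical_coords"

    def test_unannotated_placement_excluded_when_gff_given(self):
        a = placement(1000, 2000, "+", gene="ga")
        b = placement(2613, 3600, "-", gene="gb")
        gff = [GffFeature("s1", "gene", 900, 2100, "+", "x")]  # covers a only
        assert classify_pair_configuration(a, b, gff=gff).status == "excluded_unannotated"
        gff.append(GffFeature("s1", "gene", 2500, 3700, "-", "y"))
        assert classify_pair_configuration(a, b, gff=gff).status == "validated"

    def test_no_gff_skips_annotation_check(self):
        a = placement(1000, 2000, "+", gene="ga")
        b = placement(2613, 3600, "-", gene="gb")
        assert classify_pair_configuration(a, b, gff=None).status == "validated"

    def test_distance_boundary_inclusive(self):
        a = placement(1000, 2000, "+", gene="ga")
        at = classify_pair_configuration(a, placement(52_001, 52_500, "-", gene="gb"))
        over = classify_pair_configuration(a, placement(52_002, 52_500, "-", gene="gb"))
        assert (at.status, at.gap) == ("validated", 50_000)
        assert over.status == "excluded_distance"

    def test_cross_genome_pair_is_error(self):
        a = placement(1, 10, genome="Ah")
        b = placement(1, 20, genome="Bv")
        with pytest.raises(ValueError, match="different genomes"):
            classify_pair_configuration(a, b)


class TestSummary:
    def mkconfig(self, tid, cat, ori, genome="Ah", dup=False, multigene=False, ga="a", gb="b"):
        a = placement(1000, 2000, "+", gene=ga, genome=genome)
        b = placement(2500, 3000, "-", gene=gb, genome=genome)
        return PairConfiguration(
            genome_id=genome, transcript_id=tid, gene_a=a, gene_b=b,
            status="validated", same_scaffold=True, gap=499,
            overlap_category=cat, orientation=ori, duplicated=dup,
            from_multigene=multigene,
        )

    def test_pair_accounting_with_duplicates(self):
        configs = [self.mkconfig(f"t{i}", "non_overlapping", "convergent") for i in range(400)]
        for i in (400, 401):
            configs += [self.mkconfig(f"t{i}", "overlapping", "convergent", dup=True)] * 2
        s = summarize_validation(configs)["Ah"]
        assert (s.n_pairs, s.n_unique, s.n_duplicated) == (404, 402, 2)
        assert s.n_chimera == 402

    def test_multigene_counted_separately(self):
        configs = [
            self.mkconfig("t1", "non_overlapping", "convergent"),
            self.mkconfig("m1", "non_overlapping", "co_oriented", multigene=True, ga="m1.g1", gb="m1.g2"),
            self.mkconfig("m1", "non_overlapping", "co_oriented", multigene=True, ga="m1.g2", gb="m1.g3"),
        ]
        s = summarize_validation(configs)["Ah"]
        assert (s.n_chimera, s.n_multi_gene, s.n_pairs) == (2, 1, 1)

    def test_category_rows_sum_to_totals(self):
        configs = [
            self.mkconfig("t1", "overlapping", "convergent"),
            self.mkconfig("t2", "overlapping", "divergent"),
            self.mkconfig("t3", "non_overlapping", "co_oriented"),
        ]
        s = summarize_validation(configs)["Ah"]
        assert s.category_total("overlapping") == 2
        assert s.category_total("non_overlapping") == 1
        assert s.n_pairs == sum(s.category_total(c) for c in s.grid)

    def test_empty_input_all_zero(self):
        assert summarize_validation([]) == {}


class TestPercent:
    @pytest.mark.parametrize(
        "count,base,want",
        [
            (581, 1810, 32), (406, 581, 70), (351, 581, 60),
            (139, 581, 24), (83, 581, 14),
            (88_999_253, 466_000_000, 19),
            (1, 200, 1),  # 0.5% rounds half up to 1%
            (0, 5, 0),
        ],
    )
    def test_round_half_up(self, count, base, want):
        assert round_half_up_percent(count, base) == want

    def test_zero_base_absent(self):
        assert round_half_up_percent(3, 0) is None


class TestSpecificity:
    ROLES = GenomeRoles(all_genomes=("Ah", "Bv", "Sl", "Gm", "At", "Zm"))

    def label(self, genomes):
        validated = {g: ({"c1"} if g in genomes else set()) for g in self.ROLES.all_genomes}
        labels, _ = specificity_sets(validated, self.ROLES)
        return labels["c1"]

    def test_labels(self):
        assert self.label({"Ah"}) == "amaranth_specific"
        assert self.label({"Ah", "Bv"}) == "caryophyllales_specific"
        assert self.label(set(self.ROLES.all_genomes)) == "conserved_all"
        assert self.label({"Ah", "Sl"}) == "shared_other"
        assert self.label({"Bv"}) == "shared_other"

    def test_venn_regions(self):
        validated = {"Ah": {"a", "b"}, "Bv": {"b"}, "Sl": set(), "Gm": set(), "At": set(), "Zm": set()}
        _, venn = specificity_sets(validated, self.ROLES)
        assert venn == {("Ah",): 1, ("Ah", "Bv"): 1}

    def test_unconfigured_genome_is_error(self):
        with pytest.raises(ValueError, match="without a configured role"):
            specificity_sets({"XX": {"a"}}, self.ROLES)


class TestValidateChimeras:
    def test_duplicated_pair_from_co_optimal_loci(self, synth_dir):
        _, manifest = synth_dir
        dup = [p for p in manifest["pairs"] if p["duplicated"]]
        assert dup, "the synthetic study plants a duplicated pair"
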