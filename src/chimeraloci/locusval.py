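"""Genomic validation of chimera candidates.

The two (or more) genes of a candidate chimera are aligned against
annotated plant genomes.  A chimera is a *real positive* when its gene
pair lands in the same locus of at least one genome: either overlapping in
coding coordinates, or separated by at most 50 kilobases.  Pairs are
excluded when the two genes hit identical coordinates (one locus annotated
under two protein names — a pipeline artefact, not a readthrough), when a
placement falls in a region not annotated as a gene, when the genes land
on different scaffolds, or when they are farther apart than the distance
limit.

Validated pairs are classified by overlap category — ``non_overlapping``
(disjoint spans within the limit), ``overlapping`` (partial span
intersection), ``contained`` (one span inside the other) — and by
orientation: ``convergent`` (opposite strands, 3' ends facing),
``divergent`` (opposite strands, 5' ends facing) or ``co_oriented`` (same
strand).  Cross-genome membership then yields lineage-specificity labels
(e.g. validated only in the amaranth genome, or only in the two
Caryophyllales genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

from .annotate import ChimeraCandidate
from .tabio import GffFeature, Hit

__all__ = [
    "GenePlacement", "PairConfiguration", "ValidationSummary", "GenomeRoles",
    "filter_genome_hits", "best_locus", "best_loci",
    "classify_pair_configuration", "validate_chimeras",
    "summarize_validation", "specificity_sets", "round_half_up_percent",
]

OVERLAP_CATEGORIES = ("overlapping", "contained", "non_overlapping")
ORIENTATIONS = ("convergent", "divergent", "co_oriented")

MAX_PAIR_GAP = 50_000
HSP_CHAIN_GAP = 10_000
MIN_LOCUS_IDENTITY = 60.0
MIN_LOCUS_COVERAGE = 60.0


def round_half_up_percent(count: int, base: int) -> int | None:
    """Integer percentage with exact round-half-up; ``None`` when the base
    is zero (undefined, reported as absent)."""
    if base == 0:
        return None
    num = 200 * count + base  # 100*count/base + 1/2, over a common denominator
    return num // (2 * base)


@dataclass(frozen=True)
class GenePlacement:
    """The genomic locus of one chimera gene in one genome: scaffold,
    1-based inclusive span, explicit strand, and the chained-alignment
    quality used to rank competing loci."""

    gene_id: str
    genome_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    bitscore: float
    pct_identity: float
    query_coverage: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("placement start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError("placement strand must be '+' or '-'")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValueError("query_coverage outside [0, 100]")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class PairConfiguration:
    """Validated/excluded status and, when validated, the overlap category
    and orientation of one gene pair at one locus pair of one genome."""

    genome_id: str
    transcript_id: str
    gene_a: GenePlacement
    gene_b: GenePlacement
    status: str
    same_scaffold: bool
    gap: int | None = None  # intervening bases; negative when spans intersect
    overlap_category: str | None = None
    orientation: str | None = None
    duplicated: bool = False
    from_multigene: bool = False

    def __post_init__(self) -> None:
        validated = self.status == "validated"
        if validated != (self.overlap_category is not None) or validated != (
            self.orientation is not None
        ):
            raise ValueError("category/orientation set iff status == validated")
        if self.overlap_category is not None and self.overlap_category not in OVERLAP_CATEGORIES:
            raise ValueError(f"unknown overlap category {self.overlap_category!r}")
        if self.orientation is not None and self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class ValidationSummary:
    """Per-genome accounting of validated chimeras, in the layout of the
    cross-genome validation table: chimera / multi-gene / pair counts and a
    3x3 overlap-category x orientation grid."""

    genome_id: str
    n_chimera: int = 0
    n_multi_gene: int = 0
    n_pairs: int = 0
    n_unique: int = 0
    n_duplicated: int = 0
    grid: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            cat: {ori: 0 for ori in ORIENTATIONS} for cat in OVERLAP_CATEGORIES
        }
    )

    def category_total(self, category: str) -> int:
        return sum(self.grid[category].values())


# ---------------------------------------------------------------------------
# Placement from genome hit tables


def filter_genome_hits(
    hits: list[Hit],
    gene_lengths: dict[str, int],
    min_pct_identity: float = MIN_LOCUS_IDENTITY,
    min_query_coverage: float = MIN_LOCUS_COVERAGE,
    chain_gap: int = HSP_CHAIN_GAP,
) -> list[GenePlacement]:
    """Chain gene-vs-genome HSPs into candidate loci and keep credible ones.

    HSPs of one gene on one scaffold and strand are chained when their
    subject spans lie within ``chain_gap`` bases of each other.  A chained
    locus is kept when its length-weighted percent identity is >= 60 and
    the merged HSPs cover >= 60% of the gene.  Coordinates are normalised
    so start <= end with an explicit strand.
    """
    grouped: dict[tuple[str, str, str], list[Hit]] = {}
    for h in hits:
        if h.query_id not in gene_lengths:
            raise ValueError(f"unknown gene length for {h.query_id!r}")
        grouped.setdefault((h.query_id, h.subject_id, h.subject_strand), []).append(h)

    placements: list[GenePlacement] = []
    for (gene_id, scaffold, strand), hs in sorted(grouped.items()):
        hs = sorted(hs, key=lambda h: h.subject_span)
        chains: list[list[Hit]] = []
        for h in hs:
            if chains and h.subject_span[0] - max(x.subject_span[1] for x in chains[-1]) - 1 <= chain_gap:
                chains[-1].append(h)
            else:
                chains.append([h])
        for chain in chains:
            total_len = sum(h.align_len for h in chain)
            pident = sum(h.pct_identity * h.align_len for h in chain) / total_len
            qcov_bases = _merged_length([(h.qstart, h.qend) for h in chain])
            coverage = 100.0 * qcov_bases / gene_lengths[gene_id]
            coverage = min(coverage, 100.0)
            if pident >= min_pct_identity and coverage >= min_query_coverage:
                placements.append(
                    GenePlacement(
                        gene_id=gene_id,
                        genome_id="",
                        scaffold=scaffold,
                        start=min(h.subject_span[0] for h in chain),
                        end=max(h.subject_span[1] for h in chain),
                        strand=strand,
                        bitscore=sum(h.bitscore for h in chain),
                        pct_identity=pident,
                        query_coverage=coverage,
                    )
                )
    return placements


def _merged_length(ivs: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in _merge(ivs):
        total += e - s + 1
    return total


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _rank_key(p: GenePlacement) -> tuple:
    return (-p.bitscore, -p.query_coverage, -(p.end - p.start + 1), p.scaffold, p.start)


def best_locus(placements: list[GenePlacement]) -> GenePlacement | None:
    """The single best locus of a gene: highest bitscore, then higher query
    coverage, then longer span, then scaffold name, then smaller start."""
    if not placements:
        return None
    return min(placements, key=_rank_key)


def best_loci(placements: list[GenePlacement]) -> list[GenePlacement]:
    """All co-optimal loci (tied on bitscore, coverage and span length);
    more than one means the gene places equally well at several loci and a
    pair built from it may be *duplicated*."""
    if not placements:
        return []
    top = _rank_key(best_locus(placements))[:3]
    return sorted([p for p in placements if _rank_key(p)[:3] == top], key=_rank_key)


# ---------------------------------------------------------------------------
# Pair classification


def _overlaps_annotation(p: GenePlacement, gff: list[GffFeature] | None) -> bool:
    if gff is None:
        return True  # no annotation supplied -> check skipped, never excludes
    for f in gff:
        if f.scaffold == p.scaffold and p.start <= f.end and f.start <= p.end:
            return True
    return False


def classify_pair_configuration(
    a: GenePlacement,
    b: GenePlacement,
    max_gap: int = MAX_PAIR_GAP,
    gff: list[GffFeature] | None = None,
    transcript_id: str = "",
    genome_id: str = "",
) -> PairConfiguration:
    """Classify one gene pair's arrangement in one genome.

    Checks run in order: identical coordinates (excluded — one locus under
    two names), unannotated placement (excluded when a GFF3 is supplied),
    different scaffolds (excluded), containment, partial overlap, and
    finally the intervening distance against ``max_gap`` (inclusive).

    Orientation: same strand is co-oriented.  On opposite strands a
    disjoint pair is convergent when the 3' ends face each other (upstream
    gene on plus) and divergent when the 5' ends face; an overlapping or
    contained pair is convergent when its 3'-3' end distance is smaller
    than its 5'-5' distance (ties count as convergent).

    The result is symmetric in (a, b) apart from the stored operand order.
    """
    if genome_id == "":
        genome_id = a.genome_id
    if a.genome_id != b.genome_id:
        raise ValueError("placements come from different genomes")

    def make(status: str, **kw) -> PairConfiguration:
        return PairConfiguration(
            genome_id=genome_id,
            transcript_id=transcript_id,
            gene_a=a,
            gene_b=b,
            status=status,
            same_scaffold=a.scaffold == b.scaffold,
            **kw,
        )

    # 1) both genes hit one and the same locus
    if (
        a.scaffold == b.scaffold
        and a.start == b.start
        and a.end == b.end
        and a.strand == b.strand
    ):
        return make("excluded_identical_coords")
    # 2) placement in unannotated territory
    if not _overlaps_annotation(a, gff) or not _overlaps_annotation(b, gff):
        return make("excluded_unannotated")
    # 3) different scaffolds
    if a.scaffold != b.scaffold:
        return make("excluded_diff_scaffold")

    up, down = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
    gap = down.start - up.end - 1

    if up.start <= down.start and down.end <= up.end or down.start <= up.start and up.end <= down.end:
        category = "contained"
    elif a.start <= b.end and b.start <= a.end:
        category = "overlapping"
    elif gap <= max_gap:
        category = "non_overlapping"
    else:
        return make("excluded_distance", gap=gap)

    if a.strand == b.strand:
        orientation = "co_oriented"
    elif category == "non_overlapping":
        orientation = "convergent" if up.strand == "+" else "divergent"
    else:
        d33 = abs(a.three_prime - b.three_prime)
        d55 = abs(a.five_prime - b.five_prime)
        orientation = "convergent" if d33 <= d55 else "divergent"

    return make("validated", gap=gap, overlap_category=category, orientation=orientation)


# ---------------------------------------------------------------------------
# Candidate-level validation across genomes


@dataclass
class GenomeEvidence:
    """Placements and (optional) annotation for one genome."""

    genome_id: str
    placements: list[GenePlacement]
    gff: list[GffFeature] | None = None

    def loci_for(self, gene_id: str) -> list[GenePlacement]:
        return [
            p if p.genome_id == self.genome_id else replace(p, genome_id=self.genome_id)
            for p in self.placements
            if p.gene_id == gene_id
        ]


def validate_chimeras(
    candidates: list[ChimeraCandidate],
    evidence: list[GenomeEvidence],
    max_gap: int = MAX_PAIR_GAP,
) -> tuple[list[PairConfiguration], dict[str, set[str]]]:
    """Classify every candidate's gene pair(s) in every genome.

    Two-block candidates contribute one configuration per co-optimal locus
    pair (extra copies flagged ``duplicated``).  Candidates with three or
    more blocks are tallied as multi-gene: their adjacent block pairs are
    classified (flagged ``from_multigene``) but excluded from the pair
    summary.  A chimera is validated in genome G when at least one of its
    pairs is validated there, and is a global real positive when validated
    in at least one genome.

    Returns (all configurations, genome_id -> set of validated transcript ids).
    """
    configs: list[PairConfiguration] = []
    validated_in: dict[str, set[str]] = {ev.genome_id: set() for ev in evidence}

    for cand in candidates:
        gene_ids = [b.gene_id for b in cand.blocks]
        adjacent = list(zip(gene_ids, gene_ids[1:]))
        multigene = cand.n_genes >= 3
        for ev in evidence:
            for ga, gb in adjacent:
                loci_a = best_loci(ev.loci_for(ga))
                loci_b = best_loci(ev.loci_for(gb))
                if not loci_a or not loci_b:
                    continue  # unvalidated in this genome, not an error
                pair_configs = [
                    classify_pair_configuration(
                        pa, pb, max_gap=max_gap, gff=ev.gff,
                        transcript_id=cand.transcript_id, genome_id=ev.genome_id,
                    )
                    for pa, pb in product(loci_a, loci_b)
                ]
                kept = [c for c in pair_configs if c.status == "validated"]
                if not kept:
                    # keep one exclusion record for reporting
                    kept = pair_configs[:1]
                if len(kept) > 1:
                    for c in kept:
                        c.duplicated = True
                for c in kept:
                    c.from_multigene = multigene
                    configs.append(c)
                    if c.status == "validated":
                        validated_in[ev.genome_id].add(cand.transcript_id)
    return configs, validated_in


def summarize_validation(configs: list[PairConfiguration]) -> dict[str, ValidationSummary]:
    """Tabulate validated configurations per genome.

    ``n_chimera`` counts distinct validated transcripts (paired and
    multi-gene); ``n_pairs`` counts validated two-block configurations,
    duplicated locus pairs included once per copy; ``n_unique`` counts
    distinct validated gene pairs and ``n_duplicated`` the extra copies,
    so n_pairs = n_unique + n_duplicated.
    """
    summaries: dict[str, ValidationSummary] = {}
    seen_pairs: dict[str, set[tuple[str, str]]] = {}
    multigene_seen: dict[str, set[str]] = {}
    for c in configs:
        s = summaries.setdefault(c.genome_id, ValidationSummary(genome_id=c.genome_id))
        seen = seen_pairs.setdefault(c.genome_id, set())
        mg = multigene_seen.setdefault(c.genome_id, set())
        if c.status != "validated":
            continue
        if c.from_multigene:
            mg.add(c.transcript_id)
            continue
        s.n_pairs += 1
        key = (c.transcript_id, tuple(sorted((c.gene_a.gene_id, c.gene_b.gene_id))))
        if key in seen:
            s.n_duplicated += 1
        else:
            seen.add(key)
            s.n_unique += 1
        s.grid[c.overlap_category][c.orientation] += 1
    for gid, s in summaries.items():
        paired_transcripts = {k[0] for k in seen_pairs.get(gid, set())}
        s.n_multi_gene = len(multigene_seen.get(gid, set()))
        s.n_chimera = len(paired_transcripts) + s.n_multi_gene
    return summaries


# ---------------------------------------------------------------------------
# Lineage specificity


@dataclass(frozen=True)
class GenomeRoles:
    """Which genome ids play which lineage role in the specificity labels."""

    all_genomes: tuple[str, ...]
    amaranth: str = "Ah"
    caryophyllales: frozenset[str] = frozenset({"Ah", "Bv"})

    def __post_init__(self) -> None:
        if self.amaranth not in self.all_genomes:
            raise ValueError("amaranth genome missing from all_genomes")
        if not self.caryophyllales <= set(self.all_genomes):
            raise ValueError("caryophyllales genomes missing from all_genomes")


def specificity_sets(
    validated: dict[str, set[str]], roles: GenomeRoles
) -> tuple[dict[str, str], dict[tuple[str, ...], int]]:
    """Lineage-specificity label per chimera, plus Venn-region counts.

    ``amaranth_specific``: validated in the amaranth genome only.
    ``caryophyllales_specific``: validated in every Caryophyllales genome
    and in no outgroup genome.  ``conserved_all``: validated in every
    genome.  Everything else: ``shared_other``.  Venn counts cover every
    non-empty region of the genome power set.
    """
    unknown = set(validated) - set(roles.all_genomes)
    if unknown:
        raise ValueError(f"genomes without a configured role: {sorted(unknown)}")
    outgroups = set(roles.all_genomes) - roles.caryophyllales

    membership: dict[str, set[str]] = {}
    for gid, tids in validated.items():
        for tid in tids:
            membership.setdefault(tid, set()).add(gid)

    labels: dict[str, str] = {}
    for tid, genomes in membership.items():
        if genomes == {roles.amaranth}:
            labels[tid] = "amaranth_specific"
        elif roles.caryophyllales <= genomes and not genomes & outgroups:
            labels[tid] = "caryophyllales_specific"
        elif genomes == set(roles.all_genomes):
            labels[tid] = "conserved_all"
        else:
            labels[tid] = "shared_other"

    venn: dict[tuple[str, ...], int] = {}
    for genomes in membership.values():
        key = tuple(sorted(genomes))
        venn[key] = venn.get(key, 0) + 1
    return labels, venn
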