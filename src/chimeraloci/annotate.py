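"""Coding annotation, chimera calling and splitting, ORF finding, and
contamination screening.

A transcript is annotated as protein coding when at least one protein
passes the orthology filter on the per-pair aggregated alignment statistics
(homology >= 50%, >= 35 positives, E-value <= 1e-05).  Proteins hitting a
transcript are merged into *gene blocks* along the transcript: hits to
homologous proteins or isoforms land on the same region and must collapse
into one block, otherwise every multi-isoform hit would look like a fusion
of two genes.  A transcript whose surviving proteins form two or more
well-separated blocks is a chimera candidate — either a genuine
readthrough transcript spanning two adjacent genes or a mis-assembly — and
is split into per-gene sub-transcripts for genomic validation, with each
block extended by 75 bases on either end to compensate for the
non-orthologous termini of first and last exons.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .tabio import Hit, SeqRecord

__all__ = [
    "PairStats", "GeneBlock", "ChimeraCandidate", "ORF",
    "aggregate_pair_stats", "filter_protein_hits", "call_gene_blocks",
    "split_chimera", "find_longest_orf", "screen_contamination",
    "dedupe_protein_level",
]

HOMOLOGY_MIN_PCT = 50.0
POSITIVES_MIN = 35
EVALUE_MAX = 1e-05
SPLIT_EXTENSION = 75
BLOCK_MERGE_OVERLAP = 0.5  # fraction of the shorter interval


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class PairStats:
    """Alignment statistics of one (transcript, protein) pair, HSPs summed."""

    query_id: str
    subject_id: str
    total_positive: int
    total_identical: int
    total_align_len: int
    best_evalue: float
    qspan: list[tuple[int, int]]  # merged query intervals, 1-based inclusive

    def __post_init__(self) -> None:
        if not (0 <= self.total_identical <= self.total_positive <= self.total_align_len):
            raise ValueError(
                "require total_identical <= total_positive <= total_align_len"
            )
        if self.best_evalue < 0:
            raise ValueError("negative best_evalue")

    @property
    def homology_pct(self) -> float:
        """Percent homology: 100 x positives / aligned length (summed HSPs)."""
        return 100.0 * self.total_positive / self.total_align_len

    @property
    def qmin(self) -> int:
        return self.qspan[0][0]

    @property
    def qmax(self) -> int:
        return self.qspan[-1][1]


@dataclass
class GeneBlock:
    """A contiguous transcript segment supported by protein hits to one gene
    — the unit from which chimeras are decomposed."""

    transcript_id: str
    block_index: int  # 1-based, ordered by qstart along the transcript
    qstart: int
    qend: int
    representative_protein: str
    members: list[str]

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError("block qstart > qend")

    @property
    def gene_id(self) -> str:
        return f"{self.transcript_id}.g{self.block_index}"


@dataclass
class ChimeraCandidate:
    """A transcript with orthology to two or more distinct gene blocks."""

    transcript_id: str
    blocks: list[GeneBlock]

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("a chimera candidate needs >= 2 blocks")
        if [b.qstart for b in self.blocks] != sorted(b.qstart for b in self.blocks):
            raise ValueError("blocks must be ordered by qstart")

    @property
    def n_genes(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ORF:
    """An ATG-initiated, stop-terminated open reading frame.

    ``start``/``end`` are 1-based inclusive on the input sequence (plus
    strand coordinates even for minus-strand ORFs) and include the stop
    codon; ``protein_length`` excludes it.
    """

    start: int
    end: int
    strand: str
    frame: int  # 0-2 on the scanned strand
    protein_length: int


def aggregate_pair_stats(hits: list[Hit]) -> list[PairStats]:
    """Collapse transcript-vs-protein HSPs into one row per (query, subject):
    positives, identities and aligned length summed, best (minimum) E-value,
    merged query intervals."""
    grouped: dict[tuple[str, str], list[Hit]] = {}
    order: list[tuple[str, str]] = []
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(h)
    out = []
    for key in order:
        hs = grouped[key]
        out.append(
            PairStats(
                query_id=key[0],
                subject_id=key[1],
                total_positive=sum(h.n_positive for h in hs),
                total_identical=sum(h.n_identical for h in hs),
                total_align_len=sum(h.align_len for h in hs),
                best_evalue=min(h.evalue for h in hs),
                qspan=_merge_intervals([(h.qstart, h.qend) for h in hs]),
            )
        )
    return out


def filter_protein_hits(
    stats: list[PairStats],
    min_homology_pct: float = HOMOLOGY_MIN_PCT,
    min_positives: int = POSITIVES_MIN,
    max_evalue: float = EVALUE_MAX,
) -> list[PairStats]:
    """Keep pairs with homology >= 50%, >= 35 positives and E-value <= 1e-05.
    A transcript with at least one surviving pair is coding by orthology."""
    return [
        s
        for s in stats
        if s.homology_pct >= min_homology_pct
        and s.total_positive >= min_positives
        and s.best_evalue <= max_evalue
    ]


def call_gene_blocks(
    stats: list[PairStats], merge_overlap: float = BLOCK_MERGE_OVERLAP
) -> tuple[dict[str, list[GeneBlock]], list[ChimeraCandidate]]:
    """Group surviving proteins into gene blocks per transcript and call
    chimera candidates.

    Proteins are scanned along the transcript by their merged query span;
    a protein joins the current block when its span overlaps the block's
    span by more than ``merge_overlap`` of the shorter of the two
    (homologs and isoforms hit the same region and collapse together).
    Transcripts with >= 2 blocks become :class:`ChimeraCandidate`.

    Returns (blocks per transcript, chimera candidates); both orderings are
    deterministic and independent of input hit order.
    """
    per_transcript: dict[str, list[PairStats]] = {}
    for s in stats:
        per_transcript.setdefault(s.query_id, []).append(s)

    blocks_by_tid: dict[str, list[GeneBlock]] = {}
    candidates: list[ChimeraCandidate] = []
    for tid in sorted(per_transcript):
        rows = sorted(per_transcript[tid], key=lambda s: (s.qmin, s.qmax, s.subject_id))
        groups: list[list[PairStats]] = []
        spans: list[tuple[int, int]] = []
        for s in rows:
            if groups:
                bs, be = spans[-1]
                ov = min(be, s.qmax) - max(bs, s.qmin) + 1
                shorter = min(be - bs + 1, s.qmax - s.qmin + 1)
                if ov > merge_overlap * shorter:
                    groups[-1].append(s)
                    spans[-1] = (min(bs, s.qmin), max(be, s.qmax))
                    continue
            groups.append([s])
            spans.append((s.qmin, s.qmax))

        blocks = []
        for idx, (group, (bs, be)) in enumerate(zip(groups, spans), start=1):
            rep = min(group, key=lambda s: (-s.total_positive, s.best_evalue, s.subject_id))
            blocks.append(
                GeneBlock(
                    transcript_id=tid,
                    block_index=idx,
                    qstart=bs,
                    qend=be,
                    representative_protein=rep.subject_id,
                    members=sorted(s.subject_id for s in group),
                )
            )
        blocks_by_tid[tid] = blocks
        if len(blocks) >= 2:
            candidates.append(ChimeraCandidate(transcript_id=tid, blocks=blocks))
    return blocks_by_tid, candidates


def split_chimera(
    candidate: ChimeraCandidate, seq: SeqRecord, ext: int = SPLIT_EXTENSION
) -> list[SeqRecord]:
    """Split a chimeric transcript into one sub-transcript per gene block,
    each block extended by ``ext`` bases on both ends (clipped to the
    transcript), with ids ``<transcript_id>.g<block_index>``."""
    if candidate.transcript_id != seq.id:
        raise ValueError("candidate and sequence ids differ")
    out = []
    for block in candidate.blocks:
        if block.qstart < 1 or block.qend > len(seq):
            raise ValueError(
                f"block {block.gene_id} [{block.qstart},{block.qend}] outside "
                f"sequence of length {len(seq)}"
            )
        s = max(1, block.qstart - ext)
        e = min(len(seq), block.qend + ext)
        out.append(SeqRecord(block.gene_id, seq.sequence[s - 1 : e]))
    return out


_STOPS = {"TAA", "TAG", "TGA"}


def find_longest_orf(seq: SeqRecord, min_aa: int = 100) -> ORF | None:
    """Longest ATG-initiated, stop-terminated ORF over all six frames.

    Returns ``None`` when the longest ORF codes for fewer than ``min_aa``
    amino acids.  Ties are broken toward the plus strand, then the smaller
    start coordinate on the input sequence.
    """
    n = len(seq)
    best: tuple[tuple, ORF] | None = None
    for strand, s in (("+", seq.sequence), ("-", str(Seq(seq.sequence).reverse_complement()))):
        for frame in range(3):
            start_codon: int | None = None  # 0-based on scanned strand
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    if start_codon is not None:
                        aa = (pos - start_codon) // 3
                        orf = _to_plus_coords(start_codon, pos + 2, strand, frame, aa, n)
                        rank = (-aa, 0 if orf.strand == "+" else 1, orf.start)
                        if best is None or rank < best[0]:
                            best = (rank, orf)
                        start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    if best is None or best[1].protein_length < min_aa:
        return None
    return best[1]


def _to_plus_coords(s0: int, e0: int, strand: str, frame: int, aa: int, n: int) -> ORF:
    if strand == "+":
        return ORF(start=s0 + 1, end=e0 + 1, strand="+", frame=frame, protein_length=aa)
    # map [s0, e0] on the reverse complement back onto the input sequence
    return ORF(start=n - e0, end=n - s0, strand="-", frame=frame, protein_length=aa)


def screen_contamination(
    hits: list[Hit], min_pct_identity: float = 90.0, min_positives: int = 100
) -> set[str]:
    """Transcript ids with any hit to a contaminant reference (human or
    microbial genomes) at >= 90% identity with >= 100 positives; these are
    removed from all downstream sets."""
    return {
        h.query_id
        for h in hits
        if h.pct_identity >= min_pct_identity and h.n_positive >= min_positives
    }


def dedupe_protein_level(
    self_hits: list[Hit],
    lengths: dict[str, int],
    min_pct_identity: float = 90.0,
    min_positives: int = 100,
) -> set[str]:
    """Protein-level redundancy reduction on a translated self-hit table:
    for every cross pair passing the 90%-identity / 100-identities filter,
    drop the shorter member (ties: the lexicographically larger id).
    Returns the set of ids to drop."""
    dropped: set[str] = set()
    for h in self_hits:
        if h.query_id == h.subject_id:
            continue
        if h.pct_identity >= min_pct_identity and h.n_positive >= min_positives:
            a, b = h.query_id, h.subject_id
            for tid in (a, b):
                if tid not in lengths:
                    raise ValueError(f"unknown transcript length for {tid!r}")
            loser = max((a, b), key=lambda t: (-lengths[t], t))
            dropped.add(loser)
    return dropped
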