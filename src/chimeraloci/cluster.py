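"""Greedy clustering of redundant de novo transcripts.

Multiple assemblies (different assemblers, different k-mer sizes, different
read pools) of the same transcriptome produce many near-identical copies of
each transcript.  Two assembled sequences that align at >= 95% identity
across a stretch of >= 100 identical bases are treated as the same
underlying transcript (or isoforms of it) differing only by
sequencing/assembly error.  A filtered all-vs-all self-alignment table is
turned into an undirected graph and transcripts are clustered greedily: a
transcript hitting any member of a cluster joins that cluster, which makes
the partition exactly the connected components of the retained hit graph.

Filters applied before clustering, in order:

(i)   where a query-subject pair has several alignment blocks, keep only
      the longest block (mis-assemblies, short k-mers in particular,
      produce spurious extra blocks);
(ii)  drop transcripts from excluded assembly sources (by default 21-mer
      assemblies, whose mis-assemblies bridge otherwise distinct clusters);
(iii) optionally drop transcripts shorter than a minimum length
      (default 300 bases, on by default);
(iv)  keep only hits with >= ``min_pct_identity`` identity and
      >= ``min_identical_bases`` identical bases; self-hits passing this
      are kept so isolated transcripts still receive cluster numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tabio import Hit, SeqRecord

__all__ = ["ClusterParams", "ClusterAssignment", "filter_self_hits",
           "assign_clusters", "select_representatives"]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for the self-hit filters.

    min_pct_identity : percent identity a retained hit must reach (default 95).
    min_identical_bases : identical bases the retained block must span (default 100).
    min_transcript_len : transcripts shorter than this are dropped when
        ``apply_length_filter`` is on (default 300).
    excluded_source_tags : assembly source tags removed before clustering
        (default ``{"k21"}``).
    """

    min_pct_identity: float = 95.0
    min_identical_bases: int = 100
    min_transcript_len: int = 300
    apply_length_filter: bool = True
    excluded_source_tags: frozenset[str] = frozenset({"k21"})

    def __post_init__(self) -> None:
        if not (0.0 < self.min_pct_identity <= 100.0):
            raise ValueError("min_pct_identity must be in (0, 100]")
        if self.min_identical_bases < 1:
            raise ValueError("min_identical_bases must be >= 1")


@dataclass
class ClusterAssignment:
    """A partition of transcript ids into clusters, ids dense from 1."""

    transcript_to_cluster: dict[str, int]
    clusters: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clusters:
            self.clusters = {}
            for tid, cid in self.transcript_to_cluster.items():
                self.clusters.setdefault(cid, []).append(tid)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def surviving_ids(
    seqs: list[SeqRecord], params: ClusterParams = ClusterParams()
) -> list[str]:
    """Transcript ids that survive the source-tag and length filters
    (filters (ii) and (iii)); these are the ids to be clustered."""
    out = []
    for rec in seqs:
        if rec.source_tag in params.excluded_source_tags:
            continue
        if params.apply_length_filter and len(rec) < params.min_transcript_len:
            continue
        out.append(rec.id)
    return out


def filter_self_hits(
    hits: list[Hit], seqs: list[SeqRecord], params: ClusterParams = ClusterParams()
) -> list[Hit]:
    """Apply the four pre-clustering filters to a transcript self-hit table."""
    by_id = {rec.id: rec for rec in seqs}
    for h in hits:
        for tid in (h.query_id, h.subject_id):
            if tid not in by_id:
                raise ValueError(f"hit references unknown transcript {tid!r}")

    # (i) keep the longest block per unordered query-subject pair;
    # ties: higher bitscore, then lower evalue, then input order
    best: dict[frozenset[str], tuple[tuple, Hit]] = {}
    for order, h in enumerate(hits):
        key = frozenset((h.query_id, h.subject_id))
        rank = (-h.align_len, -h.bitscore, h.evalue, order)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, h)
    retained = [h for _, h in sorted(best.values(), key=lambda t: t[0][3])]

    dropped = set(by_id) - set(surviving_ids(seqs, params))

    out = []
    for h in retained:
        # (ii) + (iii) source-tag and length exclusions
        if h.query_id in dropped or h.subject_id in dropped:
            continue
        # (iv) identity thresholds; self-hits kept when they pass
        if h.pct_identity >= params.min_pct_identity and h.n_identical >= params.min_identical_bases:
            out.append(h)
    return out


def assign_clusters(filtered_hits: list[Hit], all_ids: list[str]) -> ClusterAssignment:
    """Cluster transcripts by the transitive closure of retained hits.

    Transcripts are scanned in ``all_ids`` order; reaching an unassigned
    transcript allocates the next cluster number, which then propagates to
    everything reachable from it through non-self hits.  The result equals
    the connected components of the hit graph with dense cluster ids
    starting at 1.
    """
    id_set = set(all_ids)
    if len(id_set) != len(all_ids):
        raise ValueError("duplicate transcript ids in all_ids")
    adj: dict[str, set[str]] = {tid: set() for tid in all_ids}
    for h in filtered_hits:
        for tid in (h.query_id, h.subject_id):
            if tid not in id_set:
                raise ValueError(f"hit references id {tid!r} not in all_ids")
        if h.query_id != h.subject_id:
            adj[h.query_id].add(h.subject_id)
            adj[h.subject_id].add(h.query_id)

    assignment: dict[str, int] = {}
    next_cid = 1
    for tid in all_ids:
        if tid in assignment:
            continue
        cid = next_cid
        next_cid += 1
        stack = [tid]
        assignment[tid] = cid
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in assignment:
                    assignment[nb] = cid
                    stack.append(nb)
    return ClusterAssignment(transcript_to_cluster=assignment)


def select_representatives(
    assignment: ClusterAssignment, seqs: list[SeqRecord]
) -> list[SeqRecord]:
    """One representative per cluster: the longest member, ties broken by
    the lexicographically smallest id.  Returned in cluster-id order."""
    by_id = {rec.id: rec for rec in seqs}
    reps = []
    for cid in sorted(assignment.clusters):
        members = assignment.clusters[cid]
        if not members:
            raise RuntimeError(f"cluster {cid} is empty")
        for tid in members:
            if tid not in by_id:
                raise ValueError(f"cluster member {tid!r} has no sequence")
        rep = min(members, key=lambda tid: (-len(by_id[tid]), tid))
        reps.append(by_id[rep])
    return reps
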