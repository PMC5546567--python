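"""End-to-end orchestration: cluster -> screen -> annotate -> validate -> express.

One :class:`RunConfig` (optionally loaded from a TOML file) names every
input and parameter; :func:`run_pipeline` writes stage outputs under one
run directory with per-stage subfolders, logs filter tallies to standard
error, and produces a machine-readable ``report.json`` next to a human
``report.txt``.  Reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate, cluster, express, locusval, tabio

__all__ = ["RunConfig", "GenomeInput", "run_pipeline"]

log = logging.getLogger("chimeraloci")


@dataclass(frozen=True)
class GenomeInput:
    genome_id: str
    hits_path: str
    gff_path: str | None = None


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Threshold defaults are the study's: clustering at 95% identity across
    100 identical bases with the 300-base length filter and 21-mer
    exclusion; orthology at homology >= 50%, >= 35 positives, E <= 1e-05;
    chimera splitting extended by 75 bases; genome placement at >= 60%
    identity and >= 60% coverage; a 50-kb locus distance limit;
    contamination at >= 90% identity with >= 100 positives; and
    co-regulation thresholds r = +/-0.6.
    """

    transcripts_fasta: str
    self_hits: str
    protein_hits: str
    outdir: str
    genomes: list[GenomeInput] = field(default_factory=list)
    contam_hits: str | None = None
    counts: str | None = None
    totals: str | None = None
    amaranth: str = "Ah"
    caryophyllales: tuple[str, ...] = ("Ah", "Bv")
    min_pct_identity: float = 95.0
    min_identical_bases: int = 100
    min_transcript_len: int = 300
    apply_length_filter: bool = True
    excluded_source_tags: tuple[str, ...] = ("k21",)
    min_homology_pct: float = 50.0
    min_positives: int = 35
    max_evalue: float = 1e-05
    split_extension: int = 75
    min_locus_identity: float = 60.0
    min_locus_coverage: float = 60.0
    max_pair_gap: int = 50_000
    contam_min_identity: float = 90.0
    contam_min_positives: int = 100
    positive_r: float = 0.6
    negative_r: float = -0.6
    log_rpkm: bool = False
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        genomes = [GenomeInput(**g) for g in raw.pop("genomes", [])]
        if "caryophyllales" in raw:
            raw["caryophyllales"] = tuple(raw["caryophyllales"])
        if "excluded_source_tags" in raw:
            raw["excluded_source_tags"] = tuple(raw["excluded_source_tags"])
        return cls(genomes=genomes, **raw)

    def _require(self, path: str | None, stage: str) -> None:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"stage {stage}: missing input {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(levelname)s %(message)s")

    # ---- cluster --------------------------------------------------------
    config._require(config.transcripts_fasta, "cluster")
    config._require(config.self_hits, "cluster")
    stage = outdir / "cluster"
    stage.mkdir(exist_ok=True)
    seqs = tabio.read_fasta(config.transcripts_fasta)
    hits = tabio.read_hit_table(config.self_hits)
    params = cluster.ClusterParams(
        min_pct_identity=config.min_pct_identity,
        min_identical_bases=config.min_identical_bases,
        min_transcript_len=config.min_transcript_len,
        apply_length_filter=config.apply_length_filter,
        excluded_source_tags=frozenset(config.excluded_source_tags),
    )
    all_ids = cluster.surviving_ids(seqs, params)
    filtered = cluster.filter_self_hits(hits, seqs, params)
    log.info("cluster: %d transcripts in, %d survive source/length filters, "
             "%d of %d self-hits retained", len(seqs), len(all_ids), len(filtered), len(hits))
    assignment = cluster.assign_clusters(filtered, all_ids)
    reps = cluster.select_representatives(assignment, seqs)
    with open(stage / "clusters.tsv", "w") as fh:
        fh.write("transcript_id\tcluster_id\n")
        for tid in all_ids:
            fh.write(f"{tid}\t{assignment.transcript_to_cluster[tid]}\n")
    tabio.write_fasta(reps, stage / "representatives.fasta")
    log.info("cluster: %d clusters", assignment.n_clusters)

    # ---- contamination screen ------------------------------------------
    flagged: set[str] = set()
    if config.contam_hits is not None:
        config._require(config.contam_hits, "screen")
        contam = tabio.read_hit_table(config.contam_hits)
        flagged = annotate.screen_contamination(
            contam, config.contam_min_identity, config.contam_min_positives
        )
    reps = [r for r in reps if r.id not in flagged]
    log.info("screen: %d representatives flagged as contamination", len(flagged))

    # ---- annotate -------------------------------------------------------
    config._require(config.protein_hits, "annotate")
    stage = outdir / "annotate"
    stage.mkdir(exist_ok=True)
    rep_ids = {r.id for r in reps}
    phits = [h for h in tabio.read_hit_table(config.protein_hits) if h.query_id in rep_ids]
    stats = annotate.aggregate_pair_stats(phits)
    surviving = annotate.filter_protein_hits(
        stats, config.min_homology_pct, config.min_positives, config.max_evalue
    )
    blocks_by_tid, candidates = annotate.call_gene_blocks(surviving)
    coding_ids = sorted(blocks_by_tid)
    by_id = {r.id: r for r in reps}
    split_records: list[tabio.SeqRecord] = []
    for cand in candidates:
        split_records.extend(
            annotate.split_chimera(cand, by_id[cand.transcript_id], config.split_extension)
        )
    log.info("annotate: %d/%d protein pairs survive filters; %d coding transcripts, "
             "%d chimera candidates (%d multi-gene)",
             len(surviving), len(stats), len(coding_ids), len(candidates),
             sum(1 for c in candidates if c.n_genes >= 3))
    with open(stage / "coding.tsv", "w") as fh:
        fh.write("transcript_id\tn_blocks\tis_chimera_candidate\n")
        for tid in coding_ids:
            n = len(blocks_by_tid[tid])
            fh.write(f"{tid}\t{n}\t{int(n >= 2)}\n")
    with open(stage / "chimera_blocks.tsv", "w") as fh:
        fh.write("transcript_id\tgene_id\tqstart\tqend\trepresentative_protein\n")
        for cand in candidates:
            for b in cand.blocks:
                fh.write(f"{cand.transcript_id}\t{b.gene_id}\t{b.qstart}\t{b.qend}\t{b.representative_protein}\n")
    if split_records:
        tabio.write_fasta(split_records, stage / "split_genes.fasta")

    # ---- validate -------------------------------------------------------
    stage = outdir / "validate"
    stage.mkdir(exist_ok=True)
    split_lengths = {r.id: len(r) for r in split_records}
    evidence = []
    for g in config.genomes:
        config._require(g.hits_path, "validate")
        ghits = [h for h in tabio.read_hit_table(g.hits_path) if h.query_id in split_lengths]
        gff = tabio.read_gff3(g.gff_path) if g.gff_path else None
        placements = locusval.filter_genome_hits(
            ghits, split_lengths, config.min_locus_identity, config.min_locus_coverage
        )
        log.info("validate[%s]: %d placements from %d hits", g.genome_id, len(placements), len(ghits))
        evidence.append(locusval.GenomeEvidence(g.genome_id, placements, gff))
    configs, validated_in = locusval.validate_chimeras(candidates, evidence, config.max_pair_gap)
    summaries = locusval.summarize_validation(configs)
    real_positives = sorted(set().union(*validated_in.values())) if validated_in else []
    with open(stage / "pair_configurations.tsv", "w") as fh:
        fh.write("genome\ttranscript_id\tgene_a\tgene_b\tscaffold_a\tspan_a\tstrand_a\t"
                 "scaffold_b\tspan_b\tstrand_b\tstatus\tcategory\torientation\tgap\tduplicated\tmultigene\n")
        for c in configs:
            fh.write("\t".join(str(v) for v in (
                c.genome_id, c.transcript_id, c.gene_a.gene_id, c.gene_b.gene_id,
                c.gene_a.scaffold, f"{c.gene_a.start}-{c.gene_a.end}", c.gene_a.strand,
                c.gene_b.scaffold, f"{c.gene_b.start}-{c.gene_b.end}", c.gene_b.strand,
                c.status, c.overlap_category or ".", c.orientation or ".",
                "." if c.gap is None else c.gap, int(c.duplicated), int(c.from_multigene),
            )) + "\n")
    labels: dict[str, str] = {}
    venn: dict = {}
    if config.genomes:
        genome_ids = tuple(g.genome_id for g in config.genomes)
        # lineage roles degrade gracefully when a run uses fewer genomes
        roles = locusval.GenomeRoles(
            all_genomes=genome_ids,
            amaranth=config.amaranth if config.amaranth in genome_ids else genome_ids[0],
            caryophyllales=frozenset(config.caryophyllales) & set(genome_ids)
            or frozenset({genome_ids[0]}),
        )
        labels, venn = locusval.specificity_sets(validated_in, roles)
        with open(stage / "specificity.tsv", "w") as fh:
            fh.write("transcript_id\tlabel\n")
            for tid in sorted(labels):
                fh.write(f"{tid}\t{labels[tid]}\n")
        with open(stage / "venn_regions.json", "w") as fh:
            json.dump({"|".join(k): v for k, v in sorted(venn.items())}, fh, indent=1)
            fh.write("\n")
    _write_summary_table(summaries, [g.genome_id for g in config.genomes], stage / "summary.tsv")

    # ---- express --------------------------------------------------------
    corr_counts = {"positive": 0, "negative": 0, "none": 0}
    calls = []
    if config.counts is not None and config.totals is not None:
        config._require(config.counts, "express")
        config._require(config.totals, "express")
        stage = outdir / "express"
        stage.mkdir(exist_ok=True)
        matrix = tabio.read_counts(config.counts, config.totals)
        lengths = dict(split_lengths)
        lengths.update({r.id: len(r) for r in reps})
        lengths = {t: lengths[t] for t in matrix.counts.index if t in lengths}
        matrix.counts = matrix.counts.loc[sorted(lengths)]
        rpkm = express.compute_rpkm(matrix, lengths)
        rpkm.to_csv(stage / "rpkm.tsv", sep="\t", index_label="transcript_id", float_format="%.4f")
        pair_list = []
        for cand in candidates:
            if cand.n_genes != 2 or cand.transcript_id not in real_positives:
                continue
            ga, gb = (b.gene_id for b in cand.blocks)
            if ga in rpkm.index and gb in rpkm.index:
                pair_list.append((cand.transcript_id, ga, gb))
        calls = express.call_pair_correlations(rpkm, pair_list, log_transform=config.log_rpkm)
        with open(stage / "correlations.tsv", "w") as fh:
            fh.write("pair_id\tr\tcall\n")
            for c in calls:
                fh.write(f"{c.pair_id}\t{'NA' if c.r is None else f'{c.r:.4f}'}\t{c.call}\n")
        for c in calls:
            corr_counts[c.call] += 1
        log.info("express: %d pair profiles classified", len(calls))

    # ---- report ---------------------------------------------------------
    n_candidates = len(candidates)
    n_validated = len(real_positives)
    report = {
        "n_transcripts_in": len(seqs),
        "n_clustered": len(all_ids),
        "n_clusters": assignment.n_clusters,
        "n_contaminant": len(flagged),
        "n_coding_orthology": len(coding_ids),
        "n_chimera_candidates": n_candidates,
        "n_multi_gene_candidates": sum(1 for c in candidates if c.n_genes >= 3),
        "n_validated_chimeras": n_validated,
        "validated_pct": locusval.round_half_up_percent(n_validated, n_candidates),
        "validated_per_genome": {g: len(v) for g, v in sorted(validated_in.items())},
        "summary_tables": {
            gid: _summary_dict(s) for gid, s in sorted(summaries.items())
        },
        "specificity_counts": _label_counts(labels),
        "venn_regions": {"|".join(k): v for k, v in sorted(venn.items())},
        "correlation_calls": corr_counts,
        "seed": config.seed,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_text_report(report, outdir / "report.txt")
    return report


def _summary_dict(s: locusval.ValidationSummary) -> dict:
    return {
        "n_chimera": s.n_chimera,
        "n_multi_gene": s.n_multi_gene,
        "n_pairs": s.n_pairs,
        "n_unique": s.n_unique,
        "n_duplicated": s.n_duplicated,
        "grid": s.grid,
    }


def _label_counts(labels: dict[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for lab in labels.values():
        out[lab] = out.get(lab, 0) + 1
    return out


def _write_summary_table(
    summaries: dict[str, locusval.ValidationSummary], genome_order: list[str], path: Path
) -> None:
    rows = ["n_chimera", "n_multi_gene", "n_pairs", "n_unique", "n_duplicated"]
    with open(path, "w") as fh:
        fh.write("row\t" + "\t".join(genome_order) + "\n")
        for row in rows:
            vals = [getattr(summaries.get(g, locusval.ValidationSummary(g)), row) for g in genome_order]
            fh.write(row + "\t" + "\t".join(str(v) for v in vals) + "\n")
        for cat in locusval.OVERLAP_CATEGORIES:
            vals = [summaries.get(g, locusval.ValidationSummary(g)).category_total(cat) for g in genome_order]
            fh.write(f"n_{cat}\t" + "\t".join(str(v) for v in vals) + "\n")
            for ori in locusval.ORIENTATIONS:
                vals = [summaries.get(g, locusval.ValidationSummary(g)).grid[cat][ori] for g in genome_order]
                fh.write(f"n_{cat}.{ori}\t" + "\t".join(str(v) for v in vals) + "\n")


def _write_text_report(report: dict, path: Path) -> None:
    lines = [
        "chimeraloci pipeline report",
        "===========================",
        f"transcripts in           : {report['n_transcripts_in']}",
        f"clustered (post-filter)  : {report['n_clustered']}",
        f"clusters                 : {report['n_clusters']}",
        f"contaminants removed     : {report['n_contaminant']}",
        f"coding (orthology)       : {report['n_coding_orthology']}",
        f"chimera candidates       : {report['n_chimera_candidates']}",
        f"validated (real positive): {report['n_validated_chimeras']}"
        + (f" ({report['validated_pct']}%)" if report["validated_pct"] is not None else ""),
    ]
    for gid, n in report["validated_per_genome"].items():
        lines.append(f"  validated in {gid:<10}: {n}")
    if report["specificity_counts"]:
        lines.append("specificity:")
        for lab, n in sorted(report["specificity_counts"].items()):
            lines.append(f"  {lab:<24}: {n}")
    lines.append(
        "correlation calls        : "
        + ", ".join(f"{k}={v}" for k, v in sorted(report["correlation_calls"].items()))
    )
    path.write_text("\n".join(lines) + "\n")
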