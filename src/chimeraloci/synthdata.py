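"""Deterministic generator of a miniature synthetic study with known truth.

The generator emits everything the pipeline consumes — per-genome FASTA
and GFF3, a protein FASTA, a transcript FASTA with redundant copies from
multiple simulated assemblies, self/protein/genome/contaminant hit tables
and a 16-condition count matrix — plus a JSON truth manifest recording
every planted gene pair's overlap category, orientation, gap,
lineage-specificity label and planted expression correlation.

Planted structures emulate the phenomena the pipeline is built for:

* readthrough chimera transcripts assembled strand-unaware across two
  adjacent genes (gene A mRNA + intergenic linker + reverse complement of
  gene B mRNA), including a convergent pair separated by a 612-base
  intergenic gap with overlapping 3' regions;
* gene pairs in all nine overlap-category x orientation cells, placed per
  genome according to a lineage-specificity plan (amaranth-only,
  Caryophyllales-only, conserved in all genomes);
* mis-assembly false chimeras whose two "genes" hit identical genomic
  coordinates;
* a multi-gene (3-block) chimera;
* redundant assembly copies at >= 95% identity (plus 21-mer copies that
  the clustering filters must drop) and decoy self-hits below threshold;
* contaminant transcripts with strong hits to a contaminant reference;
* per-condition read counts with planted pairwise Pearson correlations
  through a shared latent condition effect.

Hit tables are computed analytically from the planted coordinates (ideal
alignments with configurable identity jitter and decoys below the filter
thresholds) rather than by running an aligner, which keeps generation
dependency-free and byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tabio
from .tabio import GffFeature, Hit, SeqRecord

__all__ = ["SynthConfig", "generate_dataset", "plant_correlated_counts"]

_DNA = np.array(list("ACGT"))

CATEGORY_CELLS = [
    (cat, ori)
    for cat in ("non_overlapping", "overlapping", "contained")
    for ori in ("convergent", "divergent", "co_oriented")
]

SPECIFICITY_CYCLE = ("amaranth_specific", "caryophyllales_specific", "conserved_all")

TISSUES = ("leaf", "stem", "root", "inflorescence")
STAGES = ("stage1", "stage2", "stage3", "stage4")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults give a miniature of the real study design: three genomes with
    amaranth/Caryophyllales roles, five pairs in each of the nine overlap x
    orientation cells (the first non-overlapping convergent pair gets the
    612-base gap of the worked readthrough example), two identical-
    coordinate false chimeras, one 3-gene chimera, one duplicated pair,
    redundant assembly copies including excluded 21-mer ones, three
    contaminant transcripts, and 16 expression conditions (4 tissues x 4
    developmental stages) with anti-correlated convergent pairs (rho -0.9,
    the readthrough signature), co-regulated co-oriented pairs (rho 0.9)
    and uncorrelated divergent pairs.
    """

    seed: int = 0
    genome_ids: tuple[str, ...] = ("Ah", "Bv", "Sl")
    amaranth: str = "Ah"
    caryophyllales: tuple[str, ...] = ("Ah", "Bv")
    n_per_cell: int = 5
    gap_range: tuple[int, int] = (150, 5000)
    worked_example_gap: int = 612
    n_singleton_genes: int = 10
    n_false_chimeras: int = 2
    n_multi_gene: int = 1
    n_duplicated_pairs: int = 1
    n_contaminants: int = 3
    gene_len_range: tuple[int, int] = (300, 900)
    linker_len: int = 100
    identity_jitter: float = 0.0
    n_conditions: int = 16
    rho_by_orientation: tuple[tuple[str, float], ...] = (
        ("convergent", -0.9), ("divergent", 0.0), ("co_oriented", 0.9),
    )
    pair_margin: int = 2000

    def __post_init__(self) -> None:
        for name in ("n_per_cell", "n_singleton_genes", "n_false_chimeras",
                     "n_multi_gene", "n_duplicated_pairs", "n_contaminants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_conditions < 3:
            raise ValueError("n_conditions must be >= 3")
        if self.amaranth not in self.genome_ids:
            raise ValueError("amaranth genome not in genome_ids")
        if not set(self.caryophyllales) <= set(self.genome_ids):
            raise ValueError("caryophyllales genomes not in genome_ids")
        if self.linker_len < 80:
            raise ValueError("linker_len must be >= 80 (split extension clearance)")

    @property
    def condition_labels(self) -> list[str]:
        labels = [f"{t}_{s}" for t in TISSUES for s in STAGES]
        if self.n_conditions <= len(labels):
            return labels[: self.n_conditions]
        return labels + [f"cond{i}" for i in range(len(labels), self.n_conditions)]


# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[rng.integers(0, 4, size=n)])


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _pair_geometry(
    category: str, orientation: str, start: int, len_a: int, len_b: int, gap: int
) -> tuple[tuple[int, int, str], tuple[int, int, str], int]:
    """Genomic spans and strands realising one (category, orientation) cell
    with gene A anchored at ``start``; returns (span_a, span_b, planted_gap)
    where the gap is the signed intervening-base count."""
    a = (start, start + len_a - 1)
    if category == "non_overlapping":
        b = (a[1] + gap + 1, a[1] + gap + len_b)
        strands = {
            "convergent": ("+", "-"),
            "divergent": ("-", "+"),
            "co_oriented": ("+", "+"),
        }[orientation]
        planted_gap = gap
    elif category == "overlapping":
        ov = min(len_a, len_b) // 2
        b = (a[1] - ov + 1, a[1] - ov + len_b)
        strands = {
            "convergent": ("+", "-"),
            "divergent": ("-", "+"),
            "co_oriented": ("+", "+"),
        }[orientation]
        planted_gap = -ov
    elif category == "contained":
        # gene B inside gene A; len_a must exceed len_b comfortably
        if orientation == "co_oriented":
            b = (a[0] + 100, a[0] + 99 + len_b)
            strands = ("+", "+")
        elif orientation == "convergent":
            b = (a[1] - 9 - len_b + 1 - 1, a[1] - 10)  # B near A's 3' end
            strands = ("+", "-")
        else:  # divergent: B near A's 5' end
            b = (a[0] + 10, a[0] + 9 + len_b)
            strands = ("+", "-")
        planted_gap = b[0] - a[1] - 1
    else:
        raise ValueError(f"unknown category {category!r}")
    return (a[0], a[1], strands[0]), (b[0], b[1], strands[1]), planted_gap


def plant_correlated_counts(
    n_conditions: int,
    rho: float,
    seed: int | np.random.Generator,
    base: float = 500.0,
    scale: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two non-negative integer count vectors targeting Pearson ``rho``.

    Both vectors share a latent condition effect weighted by sqrt(|rho|)
    (sign-flipped on the second vector for negative rho) plus independent
    noise, shifted and rounded to counts; the construction gives sample
    correlations centred on rho.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    if n_conditions < 3:
        raise ValueError("n_conditions must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n_conditions)
    e1 = rng.standard_normal(n_conditions)
    e2 = rng.standard_normal(n_conditions)
    w = np.sqrt(abs(rho))
    u = np.sqrt(1.0 - abs(rho))
    x = w * z + u * e1
    y = np.sign(rho) * w * z + u * e2 if rho != 0 else e2
    cx = np.clip(np.rint(base + scale * x), 0, None).astype(int)
    cy = np.clip(np.rint(base + scale * y), 0, None).astype(int)
    return cx, cy


# ---------------------------------------------------------------------------


def generate_dataset(config: SynthConfig, outdir: str | Path) -> dict:
    """Emit the full synthetic study under ``outdir`` and return the truth
    manifest (also written to ``manifest.json``).

    Raises before writing any file when the configured geometry is
    impossible, and self-checks the emitted GFF3 against the manifest
    after writing.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_len_range
    if lo < 300 or hi < lo:
        raise ValueError("gene_len_range must satisfy 300 <= lo <= hi")

    rho_map = dict(config.rho_by_orientation)
    caryo = set(config.caryophyllales)
    outgroups = [g for g in config.genome_ids if g not in caryo]

    # ---- plan the pairs -------------------------------------------------
    pairs = []
    spec_cycle = 0
    pair_no = 0
    for cat, ori in CATEGORY_CELLS:
        for i in range(config.n_per_cell):
            pair_no += 1
            len_b = int(rng.integers(lo, hi + 1)) // 3 * 3
            if cat == "contained":
                len_a = len_b + 300 + int(rng.integers(0, 100)) // 3 * 3
            else:
                len_a = int(rng.integers(lo, hi + 1)) // 3 * 3
            if cat == "non_overlapping":
                if pair_no == 1 and ori == "convergent":
                    gap = config.worked_example_gap
                else:
                    gap = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
            else:
                gap = 0  # derived from geometry below
            label = SPECIFICITY_CYCLE[spec_cycle % len(SPECIFICITY_CYCLE)]
            spec_cycle += 1
            if label == "amaranth_specific":
                val_genomes = [config.amaranth]
            elif label == "caryophyllales_specific":
                val_genomes = sorted(caryo)
            else:
                val_genomes = list(config.genome_ids)
            if label == "caryophyllales_specific" and not outgroups:
                label = "conserved_all"
                val_genomes = list(config.genome_ids)
            pairs.append(
                {
                    "pair_id": f"TRC{pair_no:04d}",
                    "category": cat,
                    "orientation": ori,
                    "len_a": len_a,
                    "len_b": len_b,
                    "gap_param": gap,
                    "specificity": label,
                    "validated_genomes": val_genomes,
                    "rho": rho_map.get(ori, 0.0),
                    "duplicated_in_first": False,
                }
            )
    for p in pairs[: config.n_duplicated_pairs]:
        p["duplicated_in_first"] = True

    # ---- genomic placements --------------------------------------------
    cursors: dict[tuple[str, str], int] = {}
    scaffold_names = ("s1", "s2")

    def alloc(genome: str, scaffold: str, length: int) -> int:
        key = (genome, scaffold)
        start = cursors.get(key, 1000)
        cursors[key] = start + length + config.pair_margin
        return start

    placements: dict[str, dict[str, list[dict]]] = {g: {} for g in config.genome_ids}

    def place(genome: str, gene_id: str, scaffold: str, span: tuple[int, int, str]) -> None:
        placements[genome].setdefault(gene_id, []).append(
            {"scaffold": scaffold, "start": span[0], "end": span[1], "strand": span[2]}
        )

    manifest_pairs = []
    for p in pairs:
        tid = p["pair_id"]
        gid_a, gid_b = f"{tid}.g1", f"{tid}.g2"
        planted_gap = None
        for genome in config.genome_ids:
            if genome in p["validated_genomes"]:
                extent = p["len_a"] + p["len_b"] + abs(p["gap_param"]) + 200
                start = alloc(genome, "s1", extent)
                span_a, span_b, g = _pair_geometry(
                    p["category"], p["orientation"], start, p["len_a"], p["len_b"], p["gap_param"]
                )
                planted_gap = g
                place(genome, gid_a, "s1", span_a)
                place(genome, gid_b, "s1", span_b)
                if p["duplicated_in_first"] and genome == config.genome_ids[0]:
                    start2 = alloc(genome, "s1", extent + 120_000) + 120_000
                    span_a2, span_b2, _ = _pair_geometry(
                        p["category"], p["orientation"], start2, p["len_a"], p["len_b"], p["gap_param"]
                    )
                    place(genome, gid_a, "s1", span_a2)
                    place(genome, gid_b, "s1", span_b2)
            else:
                # genes exist but on different scaffolds: never a shared locus
                sa = alloc(genome, "s1", p["len_a"])
                sb = alloc(genome, "s2", p["len_b"])
                place(genome, gid_a, "s1", (sa, sa + p["len_a"] - 1, "+"))
                place(genome, gid_b, "s2", (sb, sb + p["len_b"] - 1, "-"))
        manifest_pairs.append(
            {
                "pair_id": p["pair_id"],
                "transcript_id": tid,
                "gene_ids": [gid_a, gid_b],
                "category": p["category"],
                "orientation": p["orientation"],
                "gap": planted_gap,
                "specificity": p["specificity"],
                "validated_genomes": sorted(p["validated_genomes"]),
                "rho": p["rho"],
                "duplicated": bool(p["duplicated_in_first"]),
            }
        )

    # false chimeras: both halves hit one locus at identical coordinates
    false_ids = []
    for i in range(config.n_false_chimeras):
        tid = f"FLS{i + 1:03d}"
        false_ids.append(tid)
        length = 600
        for genome in config.genome_ids:
            s = alloc(genome, "s1", length)
            span = (s, s + length - 1, "+")
            place(genome, f"{tid}.g1", "s1", span)
            place(genome, f"{tid}.g2", "s1", span)

    # multi-gene chimeras: three co-oriented genes in a row in every genome
    multi_ids = []
    multi_lens = {}
    for i in range(config.n_multi_gene):
        tid = f"MLT{i + 1:03d}"
        multi_ids.append(tid)
        lens = [int(rng.integers(lo, hi + 1)) // 3 * 3 for _ in range(3)]
        multi_lens[tid] = lens
        for genome in config.genome_ids:
            s = alloc(genome, "s1", sum(lens) + 2200)
            pos = s
            for k, ln in enumerate(lens, start=1):
                place(genome, f"{tid}.g{k}", "s1", (pos, pos + ln - 1, "+"))
                pos += ln + 1000
    # singletons carry no genomic placements (not chimera candidates)
    singleton_ids = [f"SGL{i + 1:03d}" for i in range(config.n_singleton_genes)]
    singleton_lens = {t: int(rng.integers(lo, hi + 1)) // 3 * 3 for t in singleton_ids}
    contaminant_ids = [f"CNT{i + 1:03d}" for i in range(config.n_contaminants)]

    # ---- sequences ------------------------------------------------------
    transcripts: dict[str, str] = {}
    blocks: dict[str, list[tuple[int, int]]] = {}  # transcript -> block spans
    proteins: dict[str, str] = {}
    _AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def random_protein(n_aa: int) -> str:
        return "".join(_AA[rng.integers(0, 20, size=n_aa)])

    for p in pairs:
        tid = p["pair_id"]
        mrna_a = _random_dna(rng, p["len_a"])
        mrna_b = _random_dna(rng, p["len_b"])
        linker = _random_dna(rng, config.linker_len)
        # strand-unaware assembly of a readthrough across the pair
        transcripts[tid] = mrna_a + linker + _revcomp(mrna_b)
        a_span = (1, p["len_a"])
        b_start = p["len_a"] + config.linker_len + 1
        blocks[tid] = [a_span, (b_start, b_start + p["len_b"] - 1)]
        proteins[f"P_{tid}_A"] = random_protein(p["len_a"] // 3)
        proteins[f"P_{tid}_A2"] = random_protein(p["len_a"] // 3 - 2)
        proteins[f"P_{tid}_B"] = random_protein(p["len_b"] // 3)
    for tid in false_ids:
        seq = _random_dna(rng, 600 + config.linker_len + 600)
        transcripts[tid] = seq
        blocks[tid] = [(1, 600), (600 + config.linker_len + 1, 1200 + config.linker_len)]
        proteins[f"P_{tid}_A"] = random_protein(200)
        proteins[f"P_{tid}_B"] = random_protein(200)
    for tid in multi_ids:
        lens = multi_lens[tid]
        parts, spans, pos = [], [], 1
        for k, ln in enumerate(lens, start=1):
            parts.append(_random_dna(rng, ln))
            spans.append((pos, pos + ln - 1))
            pos += ln
            if k < len(lens):
                parts.append(_random_dna(rng, config.linker_len))
                pos += config.linker_len
            proteins[f"P_{tid}_{k}"] = random_protein(ln // 3)
        transcripts[tid] = "".join(parts)
        blocks[tid] = spans
    for tid in singleton_ids:
        transcripts[tid] = _random_dna(rng, singleton_lens[tid])
        blocks[tid] = [(1, singleton_lens[tid])]
        proteins[f"P_{tid}"] = random_protein(singleton_lens[tid] // 3)
    for tid in contaminant_ids:
        transcripts[tid] = _random_dna(rng, 500)

    # redundant assembly copies
    records: list[SeqRecord] = []
    cluster_truth: dict[str, str] = {}
    for tid, seq in transcripts.items():
        records.append(SeqRecord(tid, seq, "k25"))
        cluster_truth[tid] = tid
        trimmed = seq[: max(300, len(seq) - 30)]  # stays above the length filter
        records.append(SeqRecord(f"{tid}c31", trimmed, "k31"))
        cluster_truth[f"{tid}c31"] = tid
        if hash_mod(tid) == 0:
            records.append(SeqRecord(f"{tid}c21", seq[: max(120, len(seq) - 15)], "k21"))
            cluster_truth[f"{tid}c21"] = tid

    # ---- hit tables -----------------------------------------------------
    jit = config.identity_jitter

    def jitter() -> float:
        return float(rng.uniform(-jit, 0.0)) if jit > 0 else 0.0

    def make_hit(q, s, pident, alen, qs, qe, ss, se, nident, npos, evalue=1e-150, bits=500.0):
        mism = max(0, alen - nident)
        return Hit(q, s, round(pident, 2), alen, mism, 0, qs, qe, ss, se, evalue, bits, nident, npos)

    self_hits: list[Hit] = []
    copies_by_base: dict[str, list[SeqRecord]] = {}
    for rec in records:
        copies_by_base.setdefault(cluster_truth[rec.id], []).append(rec)
    for base_tid, copies in copies_by_base.items():
        for rec in copies:
            n = len(rec)
            self_hits.append(make_hit(rec.id, rec.id, 100.0, n, 1, n, 1, n, n, n))
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                a, b = copies[i], copies[j]
                n = min(len(a), len(b))
                pid = 99.0 + jitter()
                nid = int(n * pid / 100.0)
                self_hits.append(make_hit(a.id, b.id, pid, n, 1, n, 1, n, nid, nid))
    # decoys: below-threshold cross-cluster hits and a short extra block
    base_ids = sorted(transcripts)
    for i in range(0, len(base_ids) - 1, 7):
        a, b = base_ids[i], base_ids[i + 1]
        n = min(len(transcripts[a]), len(transcripts[b]), 400)
        self_hits.append(make_hit(a, b, 94.0, n, 1, n, 1, n, int(n * 0.94), int(n * 0.94), 1e-40, 150.0))
    for i in range(3, len(base_ids) - 1, 11):
        a, b = base_ids[i], base_ids[i + 1]
        self_hits.append(make_hit(a, b, 96.0, 95, 1, 95, 1, 95, 91, 91, 1e-20, 80.0))
    # an extra short alignment block for an intra-cluster pair: filter (i)
    first = base_ids[0]
    self_hits.append(make_hit(first, f"{first}c31", 82.0, 60, 1, 60, 1, 60, 49, 49, 1e-10, 40.0))

    protein_hits: list[Hit] = []

    def protein_hit(tid: str, prot: str, qs: int, qe: int) -> None:
        alen = (qe - qs + 1) // 3
        pid = 98.0 + jitter()
        nid = int(alen * pid / 100.0)
        protein_hits.append(make_hit(tid, prot, pid, alen, qs, qe, 1, alen, nid, alen))

    for p in pairs:
        tid = p["pair_id"]
        (a1, a2), (b1, b2) = blocks[tid]
        protein_hit(tid, f"P_{tid}_A", a1, a2)
        # homolog hitting the same region: must merge into the same block
        protein_hit(tid, f"P_{tid}_A2", a1 + 3, a2 - 3)
        protein_hit(tid, f"P_{tid}_B", b1, b2)
    for tid in false_ids:
        (a1, a2), (b1, b2) = blocks[tid]
        protein_hit(tid, f"P_{tid}_A", a1, a2)
        protein_hit(tid, f"P_{tid}_B", b1, b2)
    for tid in multi_ids:
        for k, (s, e) in enumerate(blocks[tid], start=1):
            protein_hit(tid, f"P_{tid}_{k}", s, e)
    for tid in singleton_ids:
        s, e = blocks[tid][0]
        protein_hit(tid, f"P_{tid}", s, e)

    contam_hits: list[Hit] = []
    for tid in contaminant_ids:
        contam_hits.append(make_hit(tid, "chrContam", 95.0, 400, 1, 400, 5000, 5399, 380, 380, 1e-100, 300.0))
    if singleton_ids:
        # weak decoy hit on a genuine transcript: below both thresholds
        t = singleton_ids[0]
        contam_hits.append(make_hit(t, "chrContam", 85.0, 110, 1, 110, 900, 1009, 90, 93, 1e-8, 60.0))

    genome_hits: dict[str, list[Hit]] = {g: [] for g in config.genome_ids}
    split_lengths: dict[str, int] = {}
    for tid, spans in blocks.items():
        if tid in singleton_ids:
            continue
        seq_len = len(transcripts[tid])
        for k, (s, e) in enumerate(spans, start=1):
            split_lengths[f"{tid}.g{k}"] = min(seq_len, e + 75) - max(1, s - 75) + 1
    for genome in config.genome_ids:
        for gene_id, locs in placements[genome].items():
            qlen = split_lengths[gene_id]
            mrna_len = min(qlen, 3 * ((qlen - 75) // 3))  # aligned mRNA portion
            for loc in locs:
                alen = mrna_len // 3
                pid = 95.0 + jitter()
                nid = int(alen * pid / 100.0)
                if loc["strand"] == "+":
                    ss, se = loc["start"], loc["end"]
                else:
                    ss, se = loc["end"], loc["start"]
                genome_hits[genome].append(
                    make_hit(gene_id, loc["scaffold"], pid, alen, 1, mrna_len, ss, se, nid, alen)
                )

    # ---- counts ---------------------------------------------------------
    labels = config.condition_labels
    count_rows: dict[str, np.ndarray] = {}
    for p, mp in zip(pairs, manifest_pairs):
        ca, cb = plant_correlated_counts(config.n_conditions, clamp_rho(p["rho"]), rng)
        count_rows[mp["gene_ids"][0]] = ca
        count_rows[mp["gene_ids"][1]] = cb
    for tid in multi_ids:
        for k in range(1, len(blocks[tid]) + 1):
            count_rows[f"{tid}.g{k}"] = rng.poisson(400, size=config.n_conditions)
    for tid in singleton_ids:
        count_rows[tid] = rng.poisson(400, size=config.n_conditions)
    counts_df = _counts_frame(count_rows, labels)
    totals = {c: 10_000_000 for c in labels}

    # ---- write ----------------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(exist_ok=True)
    gff_by_genome: dict[str, list[GffFeature]] = {}
    for genome in config.genome_ids:
        feats: list[GffFeature] = []
        seen_locus: set[tuple] = set()
        for gene_id, locs in sorted(placements[genome].items()):
            for loc in locs:
                key = (loc["scaffold"], loc["start"], loc["end"], loc["strand"])
                if key in seen_locus:
                    continue  # identical-coordinate loci are one annotated gene
                seen_locus.add(key)
                feats.append(
                    GffFeature(loc["scaffold"], "gene", loc["start"], loc["end"], loc["strand"], f"{genome}_{gene_id}")
                )
        feats.sort(key=lambda f: (f.scaffold, f.start, f.end, f.feature_id))
        gff_by_genome[genome] = feats
        tabio.write_gff3(
            feats + [GffFeature(f.scaffold, "mRNA", f.start, f.end, f.strand, f"{f.feature_id}.m1") for f in feats[:3]],
            outdir / "genomes" / f"{genome}.gff3",
        )
        scaffold_lens = {}
        for f in feats:
            scaffold_lens[f.scaffold] = max(scaffold_lens.get(f.scaffold, 0), f.end + 500)
        tabio.write_fasta(
            [SeqRecord(s, _random_dna(rng, ln)) for s, ln in sorted(scaffold_lens.items())],
            outdir / "genomes" / f"{genome}.fasta",
        )
        tabio.write_hit_table(genome_hits[genome], outdir / f"genome_hits.{genome}.tsv")

    tabio.write_fasta(records, outdir / "transcripts.fasta")
    with open(outdir / "proteins.fasta", "w") as fh:
        for pid_, seq in sorted(proteins.items()):
            fh.write(f">{pid_}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    tabio.write_hit_table(self_hits, outdir / "self_hits.tsv")
    tabio.write_hit_table(protein_hits, outdir / "protein_hits.tsv")
    tabio.write_hit_table(contam_hits, outdir / "contam_hits.tsv")
    counts_df.to_csv(outdir / "counts.tsv", sep="\t", index_label="transcript_id")
    pd.Series(totals).to_csv(outdir / "totals.tsv", sep="\t", header=False)

    manifest = {
        "seed": config.seed,
        "genomes": list(config.genome_ids),
        "roles": {"amaranth": config.amaranth, "caryophyllales": sorted(caryo)},
        "condition_labels": labels,
        "pairs": manifest_pairs,
        "false_chimeras": false_ids,
        "multi_gene": multi_ids,
        "singletons": singleton_ids,
        "contaminants": contaminant_ids,
        "clusters": cluster_truth,
        "blocks": {tid: [list(s) for s in spans] for tid, spans in blocks.items()},
        "placements": placements,
    }
    tabio.write_manifest_json(manifest, outdir / "manifest.json")
    _self_check(manifest, gff_by_genome)
    return manifest


def clamp_rho(rho: float) -> float:
    return min(0.999, max(-0.999, rho))


def hash_mod(tid: str, mod: int = 3) -> int:
    return sum(ord(c) for c in tid) % mod


def _counts_frame(rows: dict[str, np.ndarray], labels: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels).sort_index()


def _self_check(manifest: dict, gff_by_genome: dict[str, list[GffFeature]]) -> None:
    """Every manifest placement must match an annotated gene exactly."""
    for genome, genes in manifest["placements"].items():
        annotated = {
            (f.scaffold, f.start, f.end, f.strand) for f in gff_by_genome[genome]
        }
        for gene_id, locs in genes.items():
            for loc in locs:
                key = (loc["scaffold"], loc["start"], loc["end"], loc["strand"])
                if key not in annotated:
                    raise RuntimeError(
                        f"manifest placement {gene_id} {key} missing from {genome} GFF3"
                    )
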