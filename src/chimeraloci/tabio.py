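"""Readers and writers for the tabular and sequence formats the pipeline consumes.

Every on-disk format is plain text: FASTA (60-column wrap, optional
``src=<tag>`` token in the header carrying the assembly source, e.g. the
k-mer size used), a 14-column tab-separated alignment hit table (the
standard 12 BLAST tabular columns plus ``nident`` and ``positive``), GFF3
gene annotations, and read-count matrices with a sidecar of per-condition
total mapped reads.

All coordinates are 1-based inclusive throughout the package.  The only
place minus strand is encoded by reversed coordinates is the raw
:class:`Hit` (``sstart > send``); every later type carries an explicit
strand field.  Readers validate strictly and raise :class:`TabioError`
with a line number — downstream modules never see malformed records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "TabioError",
    "SeqRecord",
    "Hit",
    "GffFeature",
    "CountsMatrix",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "read_gff3",
    "write_gff3",
    "read_counts",
    "write_counts",
    "read_manifest_json",
    "write_manifest_json",
]

IUPAC_DNA = set("ACGTN")

HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "nident", "positive",
)


class TabioError(ValueError):
    """Raised for any malformed record in an input file."""


@dataclass(frozen=True)
class SeqRecord:
    """One sequence: a whitespace-free id, an uppercase DNA string and an
    optional assembly source tag (e.g. ``k25`` for a 25-mer assembly)."""

    id: str
    sequence: str
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise TabioError(f"invalid sequence id {self.id!r}")
        if len(self.sequence) < 1:
            raise TabioError(f"empty sequence for id {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hit:
    """One local alignment record (HSP) from a 14-column hit table.

    Subject coordinates with ``sstart > send`` encode a minus-strand
    subject; query coordinates always satisfy ``qstart <= qend``.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    n_identical: int
    n_positive: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise TabioError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.align_len < 1:
            raise TabioError(f"align_len {self.align_len} < 1")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise TabioError("negative mismatch/gapopen count")
        for name in ("qstart", "qend", "sstart", "send"):
            if getattr(self, name) < 1:
                raise TabioError(f"{name} must be a positive 1-based coordinate")
        if self.qstart > self.qend:
            raise TabioError(f"qstart {self.qstart} > qend {self.qend}")
        if self.evalue < 0:
            raise TabioError(f"negative evalue {self.evalue}")
        if not (0 <= self.n_identical <= self.n_positive <= self.align_len):
            raise TabioError(
                "require n_identical <= n_positive <= align_len, got "
                f"{self.n_identical}/{self.n_positive}/{self.align_len}"
            )

    @property
    def subject_strand(self) -> str:
        return "-" if self.sstart > self.send else "+"

    @property
    def subject_span(self) -> tuple[int, int]:
        """Subject interval normalised so start <= end."""
        return (min(self.sstart, self.send), max(self.sstart, self.send))


@dataclass(frozen=True)
class GffFeature:
    """A GFF3 feature; the pipeline consumes only ``gene`` (and optionally
    ``mRNA``) rows."""

    scaffold: str
    ftype: str
    start: int
    end: int
    strand: str
    feature_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TabioError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise TabioError(
                f"feature {self.feature_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class CountsMatrix:
    """Raw read counts per transcript across conditions, plus the
    per-condition total of mapped reads used as the RPKM denominator.

    Column sums may be below the stated totals: reads may map to
    transcripts outside the matrix.
    """

    counts: pd.DataFrame  # index transcript_id, columns condition labels
    totals: pd.Series  # index condition labels -> total mapped reads

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise TabioError("duplicate condition labels")
        if self.counts.index.duplicated().any():
            raise TabioError("duplicate transcript ids in counts")
        if (self.counts.values < 0).any():
            raise TabioError("negative read count")
        missing = set(self.counts.columns) - set(self.totals.index)
        if missing:
            raise TabioError(f"conditions without totals: {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, in file order.

    Headers may carry a ``src=<tag>`` token after the id, recording which
    assembly the transcript came from.  Sequences are uppercased; duplicate
    ids, non-IUPAC characters and empty files are errors.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_tag: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise TabioError(f"{path}: record {cur_id!r} has no sequence")
        records.append(SeqRecord(cur_id, seq, cur_tag))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                if not fields:
                    raise TabioError(f"{path}:{lineno}: empty FASTA header")
                cur_id = fields[0]
                if cur_id in seen:
                    raise TabioError(f"{path}:{lineno}: duplicate id {cur_id!r}")
                seen.add(cur_id)
                cur_tag = None
                for tok in fields[1:]:
                    if tok.startswith("src="):
                        cur_tag = tok[4:]
                chunks = []
            else:
                if cur_id is None:
                    raise TabioError(f"{path}:{lineno}: sequence before first header")
                seq = line.strip().upper()
                bad = set(seq) - IUPAC_DNA
                if bad:
                    raise TabioError(
                        f"{path}:{lineno}: non-IUPAC character(s) {sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    if not records:
        raise TabioError(f"{path}: no records")
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records in FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.source_tag is not None:
                header += f" src={rec.source_tag}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Hit tables


def _parse_hit_fields(fields: list[str]) -> Hit:
    return Hit(
        query_id=fields[0],
        subject_id=fields[1],
        pct_identity=float(fields[2]),
        align_len=int(fields[3]),
        mismatches=int(fields[4]),
        gap_opens=int(fields[5]),
        qstart=int(fields[6]),
        qend=int(fields[7]),
        sstart=int(fields[8]),
        send=int(fields[9]),
        evalue=float(fields[10]),
        bitscore=float(fields[11]),
        n_identical=int(fields[12]),
        n_positive=int(fields[13]),
    )


def read_hit_table(path: str | Path) -> list[Hit]:
    """Read a 14-column tab-separated hit table (BLAST outfmt-6 dialect with
    ``nident`` and ``positive`` appended).  Lines starting '#' are skipped."""
    path = Path(path)
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise TabioError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = _parse_hit_fields(fields)
            except TabioError as exc:
                raise TabioError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise TabioError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_hit_table(hits: list[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.align_len,
                        h.mismatches, h.gap_opens, h.qstart, h.qend,
                        h.sstart, h.send, h.evalue, h.bitscore,
                        h.n_identical, h.n_positive,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path, keep_types: tuple[str, ...] = ("gene",)
) -> list[GffFeature]:
    """Read a GFF3 file, keeping only features of the given types
    (by default just ``gene``).

    Features without an ``ID`` attribute get a synthesized
    ``scaffold:start-end`` id.  A kept feature with an undefined ('.')
    strand is an error — orientation classification needs a strand.
    """
    path = Path(path)
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise TabioError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            scaffold, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in keep_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TabioError(f"{path}:{lineno}: non-numeric coordinate") from None
            feature_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("ID="):
                    feature_id = part[3:]
            if feature_id is None:
                feature_id = f"{scaffold}:{start}-{end}"
            try:
                feats.append(GffFeature(scaffold, ftype, start, end, strand, feature_id))
            except TabioError as exc:
                raise TabioError(f"{path}:{lineno}: {exc}") from None
    return feats


def write_gff3(features: list[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    (
                        f.scaffold, "chimeraloci", f.ftype, str(f.start),
                        str(f.end), ".", f.strand, ".", f"ID={f.feature_id}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Counts


def read_counts(counts_path: str | Path, totals_path: str | Path) -> CountsMatrix:
    """Read a counts TSV (header ``transcript_id`` + condition labels) and a
    two-column sidecar TSV of per-condition total mapped reads."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if not counts.map(lambda v: float(v).is_integer()).values.all():
        raise TabioError(f"{counts_path}: non-integer read count")
    counts = counts.astype(int)
    totals_df = pd.read_csv(totals_path, sep="\t", header=None, names=["condition", "total"])
    totals = totals_df.set_index("condition")["total"].astype(int)
    if (totals <= 0).any():
        raise TabioError(f"{totals_path}: non-positive total mapped reads")
    return CountsMatrix(counts=counts, totals=totals)


def write_counts(matrix: CountsMatrix, counts_path: str | Path, totals_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
    matrix.totals.to_csv(totals_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Manifest JSON (synthetic-data ground truth)


def read_manifest_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
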