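"""RPKM normalisation and co-regulation calls for chimeric gene pairs.

Expression is measured as RPKM — reads per kilobase of transcript per
million mapped reads:

    RPKM[t, c] = 1e9 * count[t, c] / (total_mapped[c] * length[t])

with the per-condition total of mapped reads taken from the sidecar file
(reads map to the whole transcriptome, not only to the transcripts in the
matrix; column sums can be used instead via ``totals="column_sums"``).

The two genes of each validated chimeric pair are profiled through their
split sub-transcripts across the condition panel (by default 16: four
tissues at four developmental stages) and their Pearson correlation is
classified as positively correlated (r >= 0.6), negatively correlated
(r <= -0.6) or uncorrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tabio import CountsMatrix

__all__ = ["CorrelationCall", "compute_rpkm", "pearson_r",
           "classify_correlation", "call_pair_correlations"]

POSITIVE_R = 0.6
NEGATIVE_R = -0.6


@dataclass(frozen=True)
class CorrelationCall:
    """Pearson correlation of a gene pair's expression profiles and its
    co-regulation call; ``r`` is ``None`` when undefined (constant profile)."""

    pair_id: str
    r: float | None
    call: str  # positive | negative | none

    def __post_init__(self) -> None:
        if self.r is not None and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r {self.r} outside [-1, 1]")
        if self.call not in {"positive", "negative", "none"}:
            raise ValueError(f"unknown call {self.call!r}")


def compute_rpkm(
    counts: CountsMatrix,
    lengths: dict[str, int],
    totals: str = "sidecar",
) -> pd.DataFrame:
    """RPKM matrix from raw counts, transcript lengths (bases) and
    per-condition mapped-read totals."""
    missing = [t for t in counts.counts.index if t not in lengths]
    if missing:
        raise ValueError(f"missing transcript lengths: {missing[:5]}")
    if totals == "sidecar":
        tot = counts.totals.reindex(counts.conditions)
    elif totals == "column_sums":
        tot = counts.counts.sum(axis=0)
    else:
        raise ValueError("totals must be 'sidecar' or 'column_sums'")
    if (tot <= 0).any():
        raise ValueError("per-condition total mapped reads must be > 0")
    lens = pd.Series({t: lengths[t] for t in counts.counts.index})
    if (lens < 1).any():
        raise ValueError("transcript lengths must be >= 1")
    return 1e9 * counts.counts.div(tot, axis=1).div(lens, axis=0)


def pearson_r(x, y) -> float | None:
    """Sample Pearson correlation; ``None`` when either vector is constant
    (the coefficient is undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        return None
    return float(dx @ dy) / (sx * sy)


def classify_correlation(
    r: float | None, positive_r: float = POSITIVE_R, negative_r: float = NEGATIVE_R
) -> str:
    """positive iff r >= 0.6, negative iff r <= -0.6, otherwise none;
    an undefined r is classified none."""
    if r is None:
        return "none"
    if r >= positive_r:
        return "positive"
    if r <= negative_r:
        return "negative"
    return "none"


def call_pair_correlations(
    rpkm: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    log_transform: bool = False,
) -> list[CorrelationCall]:
    """Correlation calls for (pair_id, gene_a, gene_b) triples over the RPKM
    matrix; optionally on log2(RPKM + 1)."""
    mat = np.log2(rpkm + 1.0) if log_transform else rpkm
    calls = []
    for pair_id, ga, gb in pairs:
        for g in (ga, gb):
            if g not in mat.index:
                raise ValueError(f"pair {pair_id}: no expression row for {g!r}")
        r = pearson_r(mat.loc[ga].to_numpy(), mat.loc[gb].to_numpy())
        calls.append(CorrelationCall(pair_id=pair_id, r=r, call=classify_correlation(r)))
    return calls
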