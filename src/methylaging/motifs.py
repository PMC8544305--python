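"""PSSM motif scanning for hormone-response elements.

A position frequency matrix (PFM, raw counts) is column-normalized into a
probability matrix (PPM) and converted to a log-odds score matrix in bits,
PSSM[b][j] = log2(PPM[b][j] / 0.25), against a uniform base background; zero
probabilities are floored at a small epsilon so scores stay finite. The exact
null distribution of the total window score under i.i.d. uniform bases is
computed by positionwise convolution on a fine discretized grid, giving exact
p-values; windows on either strand scoring with p below the threshold
(default 1e-4) are reported as hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SCORE_BIN = 1e-3  # bits; discretization grid of the exact score distribution


@dataclass
class MotifMatrix:
    """PFM counts with derived PPM and PSSM (4 x L, rows in A, C, G, T order)."""

    name: str
    counts: np.ndarray
    probs: np.ndarray
    scores: np.ndarray

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


def pfm_to_pssm(counts: np.ndarray, name: str = "motif", epsilon: float = 1e-6) -> MotifMatrix:
    """Counts -> PPM (column-normalized) -> PSSM in bits vs uniform background.

    Zero PPM entries are floored at ``epsilon`` before the log so impossible
    bases keep a large negative, finite score.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4 or counts.ndim != 2:
        raise ValueError("PFM must be 4 x L")
    if (counts < 0).any():
        raise ValueError("negative PFM counts")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero PFM column")
    probs = counts / totals
    scores = np.log2(np.maximum(probs, epsilon) / 0.25)
    return MotifMatrix(name=name, counts=counts, probs=probs, scores=scores)


def read_jaspar_pfm(path: str | Path) -> list[MotifMatrix]:
    """Read JASPAR-style PFM text: a '>' header then four A/C/G/T count rows."""
    motifs = []
    name = None
    rows: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None and rows:
                motifs.append(_finish_jaspar(name, rows))
            name = line[1:].split()[0]
            rows = {}
        else:
            base = line[0].upper()
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    if name is not None and rows:
        motifs.append(_finish_jaspar(name, rows))
    return motifs


def _finish_jaspar(name, rows) -> MotifMatrix:
    counts = np.array([rows[b] for b in BASES])
    return pfm_to_pssm(counts, name=name)


@dataclass
class ScoreDistribution:
    """Exact discretized distribution of the total PSSM score under uniform bases.

    Per-position scores are rounded to a grid of ``SCORE_BIN`` bits *before*
    summation, so the support is exact on that grid and the survival function
    is exact for the discretized scores.
    """

    offsets: np.ndarray  # integer grid values with nonzero mass
    pmf: np.ndarray
    _sf: np.ndarray = field(init=False)

    def __post_init__(self):
        # survival: P(score >= s) for each support point
        self._sf = np.cumsum(self.pmf[::-1])[::-1]

    def sf(self, score_bits) -> np.ndarray:
        """P(total score >= score) for scores given in bits."""
        s = np.atleast_1d(np.asarray(score_bits, dtype=float))
        grid = np.round(s / SCORE_BIN).astype(np.int64)
        idx = np.searchsorted(self.offsets, grid, side="left")
        out = np.where(idx < len(self.offsets), self._sf[np.clip(idx, 0, len(self._sf) - 1)], 0.0)
        return out if np.ndim(score_bits) else float(out[0])

    def threshold_score(self, p_threshold: float) -> float:
        """Smallest achievable score with P(score >= s) < p_threshold (+inf if none)."""
        ok = self._sf < p_threshold
        if not ok.any():
            return np.inf
        return float(self.offsets[np.argmax(ok)] * SCORE_BIN)


def score_distribution(pssm: np.ndarray) -> ScoreDistribution:
    """Exact total-score distribution by positionwise convolution (uniform bases)."""
    pssm = np.asarray(pssm, dtype=float)
    grid = np.round(pssm / SCORE_BIN).astype(np.int64)
    pmf = np.array([1.0])
    lo = 0
    for j in range(pssm.shape[1]):
        col = grid[:, j]
        col_lo, col_hi = int(col.min()), int(col.max())
        step = np.zeros(col_hi - col_lo + 1)
        for v in col:
            step[int(v) - col_lo] += 0.25
        pmf = np.convolve(pmf, step)
        lo += col_lo
    offsets = np.arange(lo, lo + len(pmf))
    keep = pmf > 0
    return ScoreDistribution(offsets=offsets[keep], pmf=pmf[keep])


@dataclass
class MotifHit:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    score: float
    p: float
    motif: str = ""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def scan_sequence(
    sequence: str,
    motif: MotifMatrix,
    p_threshold: float = 1e-4,
    chrom: str = "chr",
    dist: ScoreDistribution | None = None,
) -> pd.DataFrame:
    """Scan both strands for windows with exact score p-value below threshold.

    Windows containing non-ACGT characters are skipped. Returns a DataFrame
    (chrom, start, end, strand, score, p, motif) with 0-based half-open
    coordinates on the forward strand.
    """
    if dist is None:
        dist = score_distribution(motif.scores)
    thr = dist.threshold_score(p_threshold)
    L = motif.length
    n = len(sequence)
    cols = ["chrom", "start", "end", "strand", "score", "p", "motif"]
    if n < L or not np.isfinite(thr):
        return pd.DataFrame(columns=cols)
    seq = sequence.upper()
    idx = np.full(n, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    valid = idx >= 0
    # discretized per-position scores, matching the null distribution's grid
    grid = np.round(motif.scores / SCORE_BIN).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    win_valid = np.lib.stride_tricks.sliding_window_view(valid, L).all(axis=1)
    rows = []
    for strand in ("+", "-"):
        g = grid if strand == "+" else grid[::-1, ::-1]  # reverse complement scoring
        safe = np.where(windows >= 0, windows, 0)
        scores_int = np.take_along_axis(g.T[None, :, :], safe[:, :, None], axis=2)[:, :, 0].sum(
            axis=1
        )
        scores = scores_int * SCORE_BIN
        hit = win_valid & (scores >= thr - 1e-12)
        for w in np.flatnonzero(hit):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(w),
                    "end": int(w) + L,
                    "strand": strand,
                    "score": float(scores[w]),
                    "p": float(dist.sf(scores[w])),
                    "motif": motif.name,
                }
            )
    return pd.DataFrame(rows, columns=cols)


def scan_genome(
    sequences: dict, motifs: list[MotifMatrix], p_threshold: float = 1e-4
) -> pd.DataFrame:
    """Scan every chromosome with every motif; concatenated hit table."""
    frames = []
    for motif in motifs:
        dist = score_distribution(motif.scores)
        for chrom, seq in sequences.items():
            frames.append(scan_sequence(seq, motif, p_threshold, chrom=chrom, dist=dist))
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "score", "p", "motif"])
    return pd.concat(frames, ignore_index=True)


def hre_overlap_enrichment(
    focal_sites: pd.DataFrame,
    background_sites: pd.DataFrame,
    hits: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Binomial enrichment of motif-hit overlap near focal vs background sites.

    A site overlaps when the symmetric window around it (``window``/2 bp each
    side, i.e. 1 kb up- and downstream by default) shares any base with a hit
    interval. One test per motif, reusing the exact-binomial machinery.
    """
    from .context import enrichment_test

    half = window // 2
    motif_names = list(pd.unique(hits["motif"])) if len(hits) else []
    rows = []
    for name in motif_names or ["(none)"]:
        sub = hits[hits["motif"] == name] if len(hits) else hits
        f = _overlap_flags(focal_sites, sub, half)
        b = _overlap_flags(background_sites, sub, half)
        res = enrichment_test(
            np.where(f, "overlap", "no"), np.where(b, "overlap", "no"), categories=["overlap"]
        )
        res.insert(0, "motif", name)
        rows.append(res)
    return pd.concat(rows, ignore_index=True)


def _overlap_flags(sites: pd.DataFrame, hits: pd.DataFrame, half: int) -> np.ndarray:
    flags = np.zeros(len(sites), dtype=bool)
    if len(hits) == 0:
        return flags
    pos0 = sites["pos"].to_numpy() - 1
    for chrom in pd.unique(sites["chrom"]):
        m = (sites["chrom"] == chrom).to_numpy()
        sub = hits[hits["chrom"] == chrom]
        if len(sub) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        w_lo = pos0[m] - half
        w_hi = pos0[m] + half + 1  # half-open window
        overlap = (w_lo[:, None] < ends[None, :]) & (w_hi[:, None] > starts[None, :])
        flags[np.flatnonzero(m)] = overlap.any(axis=1)
    return flags


def hits_to_bed6(hits: pd.DataFrame, path: str | Path) -> None:
    out = hits[["chrom", "start", "end", "motif", "score", "strand"]].copy()
    out.to_csv(path, sep="\t", header=False, index=False)
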