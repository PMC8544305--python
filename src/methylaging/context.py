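"""Genomic context: CpG-island detection, CGI/genic context labels, and exact
binomial enrichment of a focal site set against a background set.

CpG islands follow the classic sliding-window definition: 100 bp windows
(step 1) pass when GC >= 50% and observed/expected CpG >= 0.6 with
Exp = count(C) * count(G) / window length; overlapping passing windows are
merged and merged runs of >= 200 bp are reported. Context labels use the
island / shore (<= 2 kb) / shelf (2-4 kb) / open sea (> 4 kb) distance rule.
Intervals are 0-based half-open; site positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import interval_distance

WINDOW = 100
MIN_ISLAND_LENGTH = 200
MIN_GC = 50.0
MIN_OBS_EXP = 0.6
SHORE_BP = 2000
SHELF_BP = 4000


@dataclass
class CgiInterval:
    chrom: str
    start: int
    end: int
    obs_exp: float
    gc: float


def detect_cgi(sequence: str, chrom: str = "chr") -> pd.DataFrame:
    """Detect CpG islands in one sequence.

    Returns a DataFrame (chrom, start, end, gc, obs_exp) of merged passing
    runs of length >= 200, with the mean window statistics of each run.
    Ambiguous bases (N) count as non-GC. Sequences shorter than the window
    yield an empty result.
    """
    n = len(sequence)
    cols = ["chrom", "start", "end", "gc", "obs_exp"]
    if n < WINDOW:
        return pd.DataFrame(columns=cols)
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def win_sums(x):
        c = np.concatenate([[0], np.cumsum(x)])
        return c[WINDOW:] - c[:-WINDOW]

    c_cnt = win_sums(is_c)
    g_cnt = win_sums(is_g)
    cg_cnt = win_sums(is_cg)  # includes a CG straddling the window end; subtract it
    straddle = np.zeros_like(cg_cnt)
    straddle[: n - WINDOW] = is_cg[WINDOW - 1 : n - 1]
    cg_cnt = cg_cnt - straddle

    gc_pct = 100.0 * (c_cnt + g_cnt) / WINDOW
    exp = c_cnt * g_cnt / WINDOW
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(exp > 0, cg_cnt / exp, 0.0)
    passing = (gc_pct >= MIN_GC) & (obs_exp >= MIN_OBS_EXP)

    rows = []
    ps = np.flatnonzero(passing)
    if len(ps) == 0:
        return pd.DataFrame(columns=cols)
    run_start = int(ps[0])
    run_end = run_start + WINDOW
    members = [run_start]

    def close_run():
        if run_end - run_start >= MIN_ISLAND_LENGTH:
            sel = np.array(members)
            rows.append(
                {
                    "chrom": chrom,
                    "start": run_start,
                    "end": run_end,
                    "gc": float(gc_pct[sel].mean()),
                    "obs_exp": float(obs_exp[sel].mean()),
                }
            )

    for s in ps[1:]:
        s = int(s)
        if s < run_end:  # window overlaps the current merged run
            run_end = s + WINDOW
            members.append(s)
        else:
            close_run()
            run_start, run_end, members = s, s + WINDOW, [s]
    close_run()
    return pd.DataFrame(rows, columns=cols)


def detect_cgi_genome(sequences: dict) -> pd.DataFrame:
    """Run :func:`detect_cgi` across a {chrom: sequence} dict."""
    frames = [detect_cgi(seq, chrom) for chrom, seq in sequences.items()]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "gc", "obs_exp"])
    return pd.concat(frames, ignore_index=True)


def assign_cgi_context(sites: pd.DataFrame, islands: pd.DataFrame) -> pd.Series:
    """CGI context label per site: island / shore / shelf / open_sea.

    Distance is the bp gap from the site to the nearest island edge on the
    same chromosome (0 inside an island); shore <= 2000 < shelf <= 4000 <
    open sea, with boundaries closed on the right. Chromosomes without any
    island are entirely open sea.
    """
    labels = np.full(len(sites), "open_sea", dtype=object)
    pos0 = sites["pos"].to_numpy() - 1
    for chrom in pd.unique(sites["chrom"]):
        mask = (sites["chrom"] == chrom).to_numpy()
        isl = islands[islands["chrom"] == chrom].sort_values("start")
        d = interval_distance(
            pos0[mask], isl["start"].to_numpy(), isl["end"].to_numpy()
        )
        lab = np.where(
            d == 0,
            "island",
            np.where(d <= SHORE_BP, "shore", np.where(d <= SHELF_BP, "shelf", "open_sea")),
        )
        labels[mask] = lab
    return pd.Series(labels, index=sites.index, name="cgi_context")


def label_from_islands(sites: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """Return ``sites`` with a ``cgi_context`` column (convenience wrapper)."""
    out = sites.copy()
    out["cgi_context"] = assign_cgi_context(sites, islands)
    return out


class GenomeAnnotation:
    """Gene models with exon blocks; classifies sites as exon/intron/intergenic.

    ``genes``: DataFrame with chrom, start, end (0-based half-open span),
    name, strand, exons (list of (start, end) blocks inside the span).
    """

    def __init__(self, genes: pd.DataFrame):
        for _, g in genes.iterrows():
            for es, ee in g["exons"]:
                if es < g["start"] or ee > g["end"]:
                    raise ValueError(f"exon [{es},{ee}) outside gene span in {g['name']}")
        self.genes = genes.reset_index(drop=True)

    def genic_context(self, sites: pd.DataFrame) -> pd.Series:
        """exon if inside any exon block; else intron if inside a gene span;
        else intergenic. Exon takes precedence across overlapping genes."""
        labels = np.full(len(sites), "intergenic", dtype=object)
        pos0 = sites["pos"].to_numpy() - 1
        for chrom in pd.unique(sites["chrom"]):
            mask = (sites["chrom"] == chrom).to_numpy()
            sub = self.genes[self.genes["chrom"] == chrom]
            if len(sub) == 0:
                continue
            p = pos0[mask]
            in_gene = np.zeros(len(p), dtype=bool)
            in_exon = np.zeros(len(p), dtype=bool)
            for _, g in sub.iterrows():
                in_gene |= (p >= g["start"]) & (p < g["end"])
                for es, ee in g["exons"]:
                    in_exon |= (p >= es) & (p < ee)
            lab = np.where(in_exon, "exon", np.where(in_gene, "intron", "intergenic"))
            labels[mask] = lab
        return pd.Series(labels, index=sites.index, name="genic_context")

    # ------------------------------------------------------------- BED12 IO
    def to_bed12(self, path) -> None:
        with open(path, "w") as fh:
            for _, g in self.genes.iterrows():
                exons = sorted(g["exons"])
                sizes = ",".join(str(ee - es) for es, ee in exons)
                starts = ",".join(str(es - g["start"]) for es, ee in exons)
                fh.write(
                    f"{g['chrom']}\t{g['start']}\t{g['end']}\t{g['name']}\t0\t{g['strand']}\t"
                    f"{g['start']}\t{g['end']}\t0\t{len(exons)}\t{sizes},\t{starts},\n"
                )

    @classmethod
    def from_bed12(cls, path) -> "GenomeAnnotation":
        rows = []
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 12:
                    continue
                chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "name": name,
                        "strand": strand,
                        "exons": exons,
                    }
                )
        return cls(pd.DataFrame(rows))


@dataclass
class EnrichmentResult:
    category: str
    focal_hits: int
    focal_n: int
    background_hits: int
    background_n: int
    p0: float
    p: float
    direction: str


def enrichment_test(
    focal_labels: pd.Series | np.ndarray,
    background_labels: pd.Series | np.ndarray,
    categories: list | None = None,
) -> pd.DataFrame:
    """Two-sided exact binomial enrichment of focal label counts vs background.

    For each category, tests focal_hits ~ Binomial(focal_n, p0) with p0 the
    background proportion (minimum-likelihood two-sided p). Direction is
    'enriched' when the focal proportion exceeds p0, else 'depleted'.
    """
    focal = np.asarray(focal_labels)
    background = np.asarray(background_labels)
    if len(background) == 0:
        raise ValueError("empty background")
    if len(focal) == 0:
        raise ValueError("empty focal set")
    if categories is None:
        categories = list(pd.unique(background))
    rows = []
    n_f = len(focal)
    n_b = len(background)
    for cat in categories:
        k_f = int((focal == cat).sum())
        k_b = int((background == cat).sum())
        p0 = k_b / n_b
        if p0 in (0.0, 1.0):
            p = 1.0 if k_f == round(p0 * n_f) else 0.0
        else:
            p = stats.binomtest(k_f, n_f, p0, alternative="two-sided").pvalue
        rows.append(
            {
                "category": cat,
                "focal_hits": k_f,
                "focal_n": n_f,
                "background_hits": k_b,
                "background_n": n_b,
                "p0": p0,
                "p": float(p),
                "direction": "enriched" if k_f / n_f >= p0 else "depleted",
            }
        )
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write (chrom, start, end[, ...]) intervals as BED (0-based half-open)."""
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
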