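"""Methylation count container and Bismark-coverage-style file IO.

The central object is :class:`MethylationDataset`: a site x sample matrix of
(methylated, unmethylated) read counts from reduced-representation bisulfite
sequencing, together with site coordinates and per-sample metadata (age in
days, library batch, radiation dose, group label). Percent methylation is
derived from counts; after k-nearest-neighbour imputation a dataset instead
carries an explicit, fully observed percent matrix (counts keep their gaps).

Coordinates are 1-based inclusive, matching the coverage-file dialect;
cytosines on opposite strands are distinct sites and are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITE_COLS = ["chrom", "pos", "strand"]
SAMPLE_COLS = ["sample_id", "age_days", "batch", "dose", "group"]


@dataclass(frozen=True, order=True)
class CytosineSite:
    """A single cytosine, uniquely keyed by (chrom, pos, strand); pos is 1-based."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "CytosineSite":
        chrom, pos, strand = key.rsplit(":", 2)
        return cls(chrom, int(pos), strand)


class MethylationDataset:
    """Site x sample methylated/unmethylated counts with metadata.

    Parameters
    ----------
    sites : DataFrame with columns chrom, pos, strand (1-based positions).
    samples : DataFrame with columns sample_id, age_days, batch, dose, group.
    meth, unmeth : float arrays (n_sites, n_samples); NaN marks missing cells.
    percent : optional explicit percent matrix (set by imputation).
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        samples: pd.DataFrame,
        meth: np.ndarray,
        unmeth: np.ndarray,
        percent: np.ndarray | None = None,
    ):
        sites = sites.reset_index(drop=True)[SITE_COLS].copy()
        samples = samples.reset_index(drop=True).copy()
        for col in SAMPLE_COLS:
            if col not in samples.columns:
                samples[col] = np.nan if col != "sample_id" else None
        meth = np.asarray(meth, dtype=float)
        unmeth = np.asarray(unmeth, dtype=float)
        if meth.shape != (len(sites), len(samples)) or unmeth.shape != meth.shape:
            raise ValueError("count matrices must be (n_sites, n_samples)")
        if np.nanmin(meth, initial=0) < 0 or np.nanmin(unmeth, initial=0) < 0:
            raise ValueError("negative counts")
        order = np.lexsort((sites["strand"], sites["pos"], sites["chrom"]))
        if not np.array_equal(order, np.arange(len(sites))):
            sites = sites.iloc[order].reset_index(drop=True)
            meth = meth[order]
            unmeth = unmeth[order]
            if percent is not None:
                percent = np.asarray(percent, dtype=float)[order]
        self.sites = sites
        self.samples = samples
        self.meth = meth
        self.unmeth = unmeth
        self._percent = None if percent is None else np.asarray(percent, dtype=float)

    # ---------------------------------------------------------------- basics
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def percent(self) -> np.ndarray:
        """Percent methylation; NaN where a cell is missing (zero coverage)."""
        if self._percent is not None:
            return self._percent
        total = self.meth + self.unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.meth / total
        pct[~(total > 0)] = np.nan
        return pct

    @property
    def is_imputed(self) -> bool:
        return self._percent is not None

    def site_keys(self) -> np.ndarray:
        s = self.sites
        return (s["chrom"].astype(str) + ":" + s["pos"].astype(str) + ":" + s["strand"]).to_numpy()

    def site_objects(self) -> list[CytosineSite]:
        return [CytosineSite(c, int(p), st) for c, p, st in self.sites.itertuples(index=False)]

    def ages(self) -> np.ndarray:
        return self.samples["age_days"].to_numpy(dtype=float)

    def groups(self) -> np.ndarray:
        return self.samples["group"].to_numpy()

    # ------------------------------------------------------------- subsetting
    def subset_sites(self, mask_or_idx) -> "MethylationDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MethylationDataset(
            self.sites.iloc[idx],
            self.samples,
            self.meth[idx],
            self.unmeth[idx],
            None if self._percent is None else self._percent[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationDataset":
        lookup = {sid: j for j, sid in enumerate(self.sample_ids)}
        cols = np.array([lookup[s] for s in sample_ids])
        return MethylationDataset(
            self.sites,
            self.samples.iloc[cols],
            self.meth[:, cols],
            self.unmeth[:, cols],
            None if self._percent is None else self._percent[:, cols],
        )

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            self.sites.copy(),
            self.samples.copy(),
            self.meth.copy(),
            self.unmeth.copy(),
            None if self._percent is None else self._percent.copy(),
        )

    def __repr__(self) -> str:
        tag = ", imputed" if self.is_imputed else ""
        return f"<MethylationDataset {self.n_sites} sites x {self.n_samples} samples{tag}>"


# ------------------------------------------------------------------ file IO

def read_coverage_file(path: str | Path, sample_metadata: dict) -> MethylationDataset:
    """Read one Bismark-coverage-style file into a single-sample dataset.

    Expected columns (tab-separated): chrom, start, end, percent methylation,
    count methylated, count unmethylated; start == end for CpG rows. The file's
    percent column is checked against counts (within 0.1) and then discarded —
    percent is always recomputed from counts. Cells with zero total coverage
    are recorded as missing.
    """
    path = Path(path)
    chroms, poss, strands, meths, unmeths = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                pct = float(fields[3])
                m = int(fields[4])
                u = int(fields[5])
                strand = fields[6] if len(fields) == 7 else "+"
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if m < 0 or u < 0:
                raise ValueError(f"{path}:{lineno}: negative counts")
            if m + u > 0 and abs(pct - 100.0 * m / (m + u)) > 0.1:
                raise ValueError(
                    f"{path}:{lineno}: percent column inconsistent with counts "
                    f"({pct} vs {100.0 * m / (m + u):.4f})"
                )
            chroms.append(chrom)
            poss.append(start)
            strands.append(strand)
            meths.append(m if m + u > 0 else np.nan)
            unmeths.append(u if m + u > 0 else np.nan)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "strand": strands})
    meta = dict(sample_metadata)
    samples = pd.DataFrame(
        [
            {
                "sample_id": meta.get("sample_id", path.stem),
                "age_days": meta.get("age_days", np.nan),
                "batch": meta.get("batch", "batch1"),
                "dose": meta.get("dose", np.nan),
                "group": meta.get("group", ""),
            }
        ]
    )
    return MethylationDataset(
        sites, samples, np.array(meths)[:, None], np.array(unmeths)[:, None]
    )


def write_coverage_file(ds: MethylationDataset, sample_id: str, path: str | Path) -> None:
    """Write one sample as a Bismark-coverage-style TSV (1-based inclusive).

    Missing cells are omitted, matching how absent cytosines appear in real
    coverage files.
    """
    j = ds.sample_ids.index(sample_id)
    with open(path, "w") as fh:
        for i in range(ds.n_sites):
            m, u = ds.meth[i, j], ds.unmeth[i, j]
            if not np.isfinite(m) or not np.isfinite(u) or m + u <= 0:
                continue
            pct = 100.0 * m / (m + u)
            row = ds.sites.iloc[i]
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{int(row.pos)}\t{pct:.6g}\t{int(m)}\t{int(u)}\t{row.strand}\n"
            )


def write_metadata(ds: MethylationDataset, path: str | Path) -> None:
    ds.samples[SAMPLE_COLS].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def merge_single_sample(datasets: Iterable[MethylationDataset]) -> MethylationDataset:
    """Outer-join single-sample datasets on site keys into one multi-sample dataset."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to merge")
    frames = []
    for k, ds in enumerate(datasets):
        if ds.n_samples != 1:
            raise ValueError("merge_single_sample expects single-sample datasets")
        df = ds.sites.copy()
        df["meth"] = ds.meth[:, 0]
        df["unmeth"] = ds.unmeth[:, 0]
        df["__k"] = k
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    wide_m = long.pivot_table(index=SITE_COLS, columns="__k", values="meth", aggfunc="first")
    wide_u = long.pivot_table(index=SITE_COLS, columns="__k", values="unmeth", aggfunc="first")
    cols = list(range(len(datasets)))
    wide_m = wide_m.reindex(columns=cols)
    wide_u = wide_u.reindex(columns=cols)
    sites = wide_m.index.to_frame(index=False)
    samples = pd.concat([ds.samples for ds in datasets], ignore_index=True)
    return MethylationDataset(sites, samples, wide_m.to_numpy(), wide_u.to_numpy())
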