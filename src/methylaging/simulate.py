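"""Synthetic RRBS aging studies with known ground truth.

The generator emulates the structure of a cross-sectional fish aging study:
seven age groups spanning 2-14 months (47 males), a four-arm chronic
ionizing-radiation (IR) exposure cohort (0/5/50/500 mGy/day, 24 fish), tens of
thousands of CpG sites with negative-binomial 5-100x coverage, two library
batches, a small minority of genuinely age-associated sites whose methylation
changes faster in early life, per-read CpG call patterns whose expected
discordance rises with log age, and a small genome with planted CpG islands,
gene models, and motif instances.

Every random draw flows from a single integer seed through named substreams,
so one seed fixes the whole study and all outputs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._utils import spearman_rows, substream
from .association import assign_bin
from .dataset import MethylationDataset

#: mean age in days of a fish aged m months (365.25/12 days per month)
DAYS_PER_MONTH = 365.25 / 12

#: the aging-cohort design: (age in days, males sampled) for 2, 4, 5, 6, 9,
#: 12 and 14 months — 47 fish in two library batches
DEFAULT_AGE_GROUPS = [
    (61, 7),
    (122, 6),
    (152, 6),
    (183, 8),
    (274, 6),
    (365, 8),
    (426, 6),
]


@dataclass
class SimulationConfig:
    """All tunable knobs of the synthetic study.

    Defaults reproduce the study conditions: ~0.5% of sites planted as
    age-associated with an early:late rate ratio of ~2, percent-scale batch
    shifts, an IR cohort whose effects preferentially hit moderately
    age-correlated sites, and a per-read discordance (PDR) trend of
    ~3 percentage points per unit log(age in days).
    """

    seed: int = 0
    n_sites: int = 20_000
    age_groups: list = field(default_factory=lambda: list(DEFAULT_AGE_GROUPS))
    frac_age_sites: float = 0.005
    effect_scale: float = 40.0  # max % methylation change across the sampled lifespan
    early_late_rate_ratio: float = 2.0
    maturity_age_days: float = 183.0  # breakpoint of the piecewise trajectory
    hyper_fraction: float = 0.8  # fraction of planted trends that gain methylation
    baseline_beta_params: tuple = (0.4, 0.4)
    noise_logit_sd: float = 0.3
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    n_batches: int = 2
    batch_sd: float = 2.0  # percent-methylation units
    missing_rate: float = 0.08
    # IR cohort
    ir_doses: list = field(default_factory=lambda: [0, 5, 50, 500])
    ir_n_per_arm: int = 6
    ir_age_days: float = 232.0  # 6-month-old fish after a 7-week exposure
    ir_effect_size: float = 30.0  # percent-methylation shift at affected sites
    frac_ir_sites: float = 0.01
    ir_target_bins: list = field(default_factory=lambda: ["0.25 to 0.5"])
    ir_bin_weights: list | None = None  # planting weight per target bin; None = by occupancy
    ir_direction_mode: str = "opposite"  # opposite / same / random vs the age trend
    # read-level patterns
    pdr_intercept: float = 2.0
    pdr_slope: float = 3.01  # percent PDR per unit ln(age in days)
    pdr_batch_sd: float = 0.5  # percentage-point batch offset on PDR
    reads_per_sample: int = 3000
    read_cpg_mean: float = 3.0
    # genome
    genome_n_chroms: int = 3
    genome_chrom_length: int = 200_000
    genome_gc: float = 0.40
    islands_per_chrom: int = 8
    genes_per_chrom: int = 12

    def validate(self) -> None:
        if not 0 <= self.frac_age_sites <= 1:
            raise ValueError("frac_age_sites must be in [0,1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0,1]")
        if not 0 <= self.effect_scale <= 100:
            raise ValueError("effect_scale must be in [0,100]")
        if self.early_late_rate_ratio <= 0:
            raise ValueError("early_late_rate_ratio must be > 0")
        for age, n in self.age_groups:
            if n < 1:
                raise ValueError(f"age group {age} declared with zero samples")
        if self.ir_effect_size > 0 and not self.ir_target_bins:
            raise ValueError("ir_target_bins empty while ir_effect_size > 0")
        for age, _ in self.age_groups:
            pdr = self.pdr_intercept + self.pdr_slope * np.log(age)
            if not 0 <= pdr <= 100:
                raise ValueError(f"expected PDR {pdr:.1f} outside [0,100] at age {age} d")


class TruthTable:
    """Per-site ground truth of a simulated study (thin DataFrame wrapper).

    Columns: site coordinates; ``direction`` (+1/-1/0), ``baseline`` percent,
    signed per-day ``slope_early``/``slope_late``, the empirical Spearman rho
    and correlation ``bin`` of the generated aging cohort, and (after the IR
    simulation) ``ir_affected`` plus per-dose ``ir_dir_<dose>`` signs.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.df.to_json(orient="records"))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        import io

        return cls(pd.read_json(io.StringIO(Path(path).read_text()), orient="records"))


# --------------------------------------------------------------- helpers

def _aging_samples(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    k = 0
    for gi, (age, n) in enumerate(config.age_groups):
        batch = f"batch{(gi % max(config.n_batches, 1)) + 1}"
        for _ in range(n):
            k += 1
            rows.append(
                {
                    "sample_id": f"A{k:02d}",
                    "age_days": float(age),
                    "batch": batch,
                    "dose": np.nan,
                    "group": f"{age}d",
                }
            )
    return pd.DataFrame(rows)


def _random_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_chrom = 24
    chrom_len = 5_000_000
    chroms = rng.integers(1, n_chrom + 1, size=config.n_sites)
    pos = rng.integers(1, chrom_len, size=config.n_sites)
    strand = rng.choice(["+", "-"], size=config.n_sites)
    df = pd.DataFrame(
        {"chrom": [f"chr{c}" for c in chroms], "pos": pos, "strand": strand}
    ).drop_duplicates(subset=["chrom", "pos", "strand"])
    while len(df) < config.n_sites:  # top up collisions
        extra = config.n_sites - len(df)
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    {
                        "chrom": [f"chr{c}" for c in rng.integers(1, n_chrom + 1, extra)],
                        "pos": rng.integers(1, chrom_len, extra),
                        "strand": rng.choice(["+", "-"], extra),
                    }
                ),
            ]
        ).drop_duplicates(subset=["chrom", "pos", "strand"])
    df = df.iloc[: config.n_sites]
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _latent_fraction(
    baseline: np.ndarray,
    slope_early: np.ndarray,
    slope_late: np.ndarray,
    t0: float,
    t_break: float,
    ages: np.ndarray,
) -> np.ndarray:
    """Piecewise-linear latent methylation fraction, anchored at the first age."""
    ages = np.asarray(ages, dtype=float)
    early_days = np.minimum(ages, t_break) - t0
    late_days = np.maximum(ages - t_break, 0.0)
    pct = baseline[:, None] + slope_early[:, None] * early_days[None, :] + slope_late[
        :, None
    ] * late_days[None, :]
    return np.clip(pct / 100.0, 0.0, 1.0)


def _observe(
    q_latent: np.ndarray,
    config: SimulationConfig,
    samples: pd.DataFrame,
    rng: np.random.Generator,
    batch_effects: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent fractions -> (meth, unmeth, observed-fraction) with noise/coverage."""
    n_sites, n_samples = q_latent.shape
    eps = rng.normal(0.0, config.noise_logit_sd, size=q_latent.shape)
    q = expit(logit(np.clip(q_latent, 1e-4, 1 - 1e-4)) + eps)
    if batch_effects and config.n_batches > 1:
        batches = samples["batch"].to_numpy()
        labels = pd.unique(batches)
        shift = rng.normal(0.0, config.batch_sd, size=(n_sites, len(labels)))
        for bi, b in enumerate(labels):
            cols = batches == b
            q[:, cols] = q[:, cols] + shift[:, [bi]] / 100.0
        q = np.clip(q, 0.0, 1.0)
    disp = config.coverage_dispersion
    p_nb = disp / (disp + config.coverage_mean)
    cov = rng.negative_binomial(disp, p_nb, size=q.shape).astype(float)
    meth = rng.binomial(cov.astype(int), q).astype(float)
    unmeth = cov - meth
    missing = rng.random(q.shape) < config.missing_rate
    missing |= cov == 0
    meth[missing] = np.nan
    unmeth[missing] = np.nan
    return meth, unmeth, q


# ------------------------------------------------------------ aging cohort

def simulate_aging_cohort(
    config: SimulationConfig, sites: pd.DataFrame | None = None
) -> tuple[MethylationDataset, TruthTable]:
    """Generate the cross-sectional aging cohort and its truth table.

    Null sites hold a constant baseline; planted age sites follow a
    piecewise-linear trajectory in age whose early-life per-day slope exceeds
    the late-life slope by ``early_late_rate_ratio``, with the breakpoint at
    ``maturity_age_days``. Observed counts are binomial draws at
    negative-binomial coverage after logit-normal site-by-sample jitter and
    percent-scale batch shifts; cells are masked at ``missing_rate``.

    The truth table also records each site's *empirical* Spearman rho with age
    in the generated cohort (missing cells filled with their latent value for
    this bookkeeping only) and the corresponding correlation bin, so that the
    IR simulation can target bins along the aging continuum.
    """
    config.validate()
    rng_sites = substream(config.seed, "sites")
    rng_traj = substream(config.seed, "trajectory")
    rng_obs = substream(config.seed, "aging-observe")

    if sites is None:
        sites = _random_sites(config, rng_sites)
    else:
        sites = sites.reset_index(drop=True)
        if len(sites) != config.n_sites:
            config = _replace(config, n_sites=len(sites))
    samples = _aging_samples(config)
    ages = samples["age_days"].to_numpy()
    t0 = min(a for a, _ in config.age_groups)
    t_max = max(a for a, _ in config.age_groups)
    t_break = min(max(config.maturity_age_days, t0), t_max)

    n = config.n_sites
    n_age = int(round(config.frac_age_sites * n))
    direction = np.zeros(n)
    age_idx = rng_traj.choice(n, size=n_age, replace=False) if n_age else np.array([], int)
    signs = np.where(rng_traj.random(n_age) < config.hyper_fraction, 1.0, -1.0)
    direction[age_idx] = signs

    baseline = 100.0 * rng_traj.beta(*config.baseline_beta_params, size=n)
    total_change = np.zeros(n)
    if n_age:
        total_change[age_idx] = config.effect_scale * rng_traj.uniform(0.75, 1.0, size=n_age)
    # split the lifespan change into early/late slopes with the configured ratio
    denom = (t_break - t0) + (t_max - t_break) / config.early_late_rate_ratio
    s_early = np.where(direction != 0, direction * total_change / denom, 0.0)
    s_late = s_early / config.early_late_rate_ratio
    # keep trajectories inside [1, 99] percent
    lo = np.where(direction < 0, 1.0 + total_change, 1.0)
    hi = np.where(direction > 0, 99.0 - total_change, 99.0)
    baseline = np.clip(baseline, lo, hi)

    q_latent = _latent_fraction(baseline, s_early, s_late, t0, t_break, ages)
    meth, unmeth, q_obs = _observe(q_latent, config, samples, rng_obs)
    ds = MethylationDataset(sites, samples, meth, unmeth)

    # empirical rho for truth bookkeeping: observed percent, latent fill-in
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * meth / total
    pct = np.where(np.isfinite(pct), pct, 100.0 * q_obs)
    # MethylationDataset sorts sites; mirror its order for truth alignment
    order = np.lexsort((sites["strand"], sites["pos"], sites["chrom"]))
    rho = spearman_rows(pct[order], ages)
    truth_df = sites.iloc[order].reset_index(drop=True).copy()
    truth_df["direction"] = direction[order].astype(int)
    truth_df["baseline"] = baseline[order]
    truth_df["slope_early"] = s_early[order]
    truth_df["slope_late"] = s_late[order]
    truth_df["rho_empirical"] = rho
    truth_df["bin"] = [assign_bin(v) for v in rho]
    return ds, TruthTable(truth_df)


def _replace(config: SimulationConfig, **kw) -> SimulationConfig:
    d = asdict(config)
    d.update(kw)
    return SimulationConfig(**d)


# --------------------------------------------------------------- IR cohort

def simulate_ir_cohort(
    config: SimulationConfig, truth: TruthTable
) -> tuple[MethylationDataset, TruthTable]:
    """Generate the four-arm exposure cohort at a single age.

    All arms share the latent aging state at ``ir_age_days``. IR-affected
    sites — drawn from truth sites whose correlation bin is in
    ``ir_target_bins`` — are shifted by ``ir_effect_size`` percent at every
    nonzero dose, in a direction set by ``ir_direction_mode`` relative to the
    site's age trend; unaffected arms are identical in distribution to the
    control arm. Returns the cohort and a truth table extended with the
    planted IR flags and per-dose directions.
    """
    config.validate()
    rng = substream(config.seed, "ir")
    tdf = truth.df
    n = len(tdf)

    rows = []
    k = 0
    for dose in config.ir_doses:
        group = "control" if dose == 0 else f"{dose}mGy"
        for _ in range(config.ir_n_per_arm):
            k += 1
            rows.append(
                {
                    "sample_id": f"IR{k:02d}",
                    "age_days": float(config.ir_age_days),
                    "batch": "lodif",
                    "dose": float(dose),
                    "group": group,
                }
            )
    samples = pd.DataFrame(rows)

    t0 = min(a for a, _ in config.age_groups)
    t_max = max(a for a, _ in config.age_groups)
    t_break = min(max(config.maturity_age_days, t0), t_max)
    q_base = _latent_fraction(
        tdf["baseline"].to_numpy(),
        tdf["slope_early"].to_numpy(),
        tdf["slope_late"].to_numpy(),
        t0,
        t_break,
        np.array([config.ir_age_days]),
    )[:, 0]

    affected = np.zeros(n, dtype=bool)
    ir_dir = np.zeros(n)
    if config.ir_effect_size > 0:
        bins = tdf["bin"].to_numpy()
        per_bin = {b: np.flatnonzero(bins == b) for b in config.ir_target_bins}
        candidates = np.concatenate(list(per_bin.values())) if per_bin else np.array([], int)
        n_aff = min(int(round(config.frac_ir_sites * n)), len(candidates))
        if config.ir_bin_weights is None:
            chosen = rng.choice(candidates, size=n_aff, replace=False) if n_aff else []
        else:
            # preferential planting: allocate across target bins by weight
            w = np.asarray(config.ir_bin_weights, dtype=float)
            if len(w) != len(config.ir_target_bins):
                raise ValueError("ir_bin_weights must align with ir_target_bins")
            alloc = np.floor(n_aff * w / w.sum()).astype(int)
            while alloc.sum() < n_aff:
                alloc[int(np.argmax(w))] += 1
            chosen = []
            for b, take in zip(config.ir_target_bins, alloc):
                pool = per_bin[b]
                take = min(int(take), len(pool))
                if take:
                    chosen.extend(rng.choice(pool, size=take, replace=False))
            chosen = np.array(chosen, dtype=int)
        affected[chosen] = True
        age_sign = np.sign(tdf["rho_empirical"].to_numpy())
        rand_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if config.ir_direction_mode == "opposite":
            ir_dir = np.where(age_sign != 0, -age_sign, rand_sign)
        elif config.ir_direction_mode == "same":
            ir_dir = np.where(age_sign != 0, age_sign, rand_sign)
        elif config.ir_direction_mode == "random":
            ir_dir = rand_sign
        else:
            raise ValueError(f"unknown ir_direction_mode {config.ir_direction_mode!r}")
        ir_dir[~affected] = 0.0

    doses = samples["dose"].to_numpy()
    q_latent = np.repeat(q_base[:, None], len(samples), axis=1)
    exposed = doses > 0
    shift = (ir_dir[:, None] * config.ir_effect_size / 100.0) * exposed[None, :]
    q_latent = np.clip(q_latent + shift, 0.01, 0.99)

    meth, unmeth, _ = _observe(q_latent, config, samples, rng, batch_effects=False)
    sites = tdf[["chrom", "pos", "strand"]]
    ds = MethylationDataset(sites, samples, meth, unmeth)

    out = tdf.copy()
    out["ir_affected"] = affected
    for dose in config.ir_doses:
        if dose == 0:
            continue
        out[f"ir_dir_{dose}"] = np.where(affected, ir_dir, 0.0).astype(int)
    return ds, TruthTable(out)


# ------------------------------------------------------------ read patterns

class ReadPatternSet:
    """Per-read ordered CpG methylation calls, one row per read.

    ``df`` columns: sample_id, chrom, start, calls (string of 0/1 characters).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def for_sample(self, sample_id: str) -> list[np.ndarray]:
        sub = self.df[self.df["sample_id"] == sample_id]
        return [np.frombuffer(c.encode(), dtype=np.uint8) - ord("0") for c in sub["calls"]]

    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.df["sample_id"]))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReadPatternSet":
        df = pd.read_csv(path, sep="\t", dtype={"calls": str})
        return cls(df)


def simulate_read_patterns(
    config: SimulationConfig, samples: pd.DataFrame | None = None
) -> ReadPatternSet:
    """Generate per-read CpG call patterns for each (aging-cohort) sample.

    Read CpG counts are truncated-Poisson (>= 1). Among reads with >= 2 CpGs
    the probability of a discordant pattern (within-read methylation between
    10% and 90%) equals the sample's expected PDR,
    ``pdr_intercept + pdr_slope * ln(age_days)``; concordant reads are all-0
    or all-1. Raises if the expected PDR leaves [0, 100] for any configured
    age.
    """
    config.validate()
    rng = substream(config.seed, "reads")
    if samples is None:
        samples = _aging_samples(config)
    batch_labels = list(pd.unique(samples["batch"]))
    batch_offset = {
        b: rng.normal(0.0, config.pdr_batch_sd) if config.pdr_batch_sd > 0 else 0.0
        for b in batch_labels
    }
    frames = []
    for _, s in samples.iterrows():
        age = float(s["age_days"])
        p_disc = (
            config.pdr_intercept
            + config.pdr_slope * np.log(age)
            + batch_offset[s["batch"]]
        ) / 100.0
        p_disc = float(np.clip(p_disc, 0.0, 1.0))
        n = config.reads_per_sample
        k = rng.poisson(config.read_cpg_mean, size=2 * n)
        k = k[k >= 1][:n]
        while len(k) < n:
            extra = rng.poisson(config.read_cpg_mean, size=n)
            k = np.concatenate([k, extra[extra >= 1]])[:n]
        discordant = (k >= 2) & (rng.random(n) < p_disc)
        conc_all1 = rng.random(n) < 0.5
        calls_strs = np.empty(n, dtype=object)
        for ki in np.unique(k):
            rows_k = np.flatnonzero(k == ki)
            disc_k = rows_k[discordant[rows_k]]
            conc_k = rows_k[~discordant[rows_k]]
            for i in conc_k:
                calls_strs[i] = ("1" if conc_all1[i] else "0") * int(ki)
            if len(disc_k):
                valid = [j for j in range(1, int(ki)) if 10 <= 100 * j / ki <= 90]
                j = np.array(valid)[rng.integers(0, len(valid), size=len(disc_k))]
                ranks = np.argsort(rng.random((len(disc_k), int(ki))), axis=1)
                mat = (ranks < j[:, None]).astype(np.uint8) + ord("0")
                for row, i in enumerate(disc_k):
                    calls_strs[i] = mat[row].tobytes().decode()
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s["sample_id"],
                    "chrom": [f"chr{c}" for c in rng.integers(1, 25, size=n)],
                    "start": rng.integers(1, 5_000_000, size=n),
                    "calls": calls_strs,
                }
            )
        )
    return ReadPatternSet(pd.concat(frames, ignore_index=True))


# ----------------------------------------------------------------- genome

@dataclass
class GenomeSimulation:
    """A small synthetic genome with planted, recorded features."""

    sequences: dict  # chrom -> str
    annotation: "object"  # context.GenomeAnnotation
    islands: pd.DataFrame  # planted CG-dense segments (chrom, start, end), 0-based
    motif_instances: pd.DataFrame  # chrom, start, end, strand, motif
    sites: pd.DataFrame  # chrom, pos, strand + truth cgi/genic context labels

    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


DEFAULT_MOTIFS = {
    # palindromic nuclear-receptor-like elements (synthetic stand-ins)
    "ERE_like": "GGTCACAGTGACC",
    "GRE_like": "AGAACATTCTGTTCT",
    "ARE_like": "GGTACATTATGTTCT",
}


def simulate_genome(
    config: SimulationConfig, motifs: dict | None = None
) -> GenomeSimulation:
    """Generate a genome with planted CpG islands, genes, and motif instances.

    Background bases are i.i.d. at ``genome_gc`` GC content. CG-dense segments
    (250-600 bp) are planted to be detectable as CpG islands; gene models get
    2-6 exon blocks; motif consensus strings are written at recorded
    positions. CpG sites are then sampled from the realized sequence and
    labelled with their true CpG-island and genic context.
    """
    from .context import GenomeAnnotation, label_from_islands

    config.validate()
    rng = substream(config.seed, "genome")
    if motifs is None:
        motifs = dict(DEFAULT_MOTIFS)
    L = config.genome_chrom_length
    base_p = np.array(
        [
            (1 - config.genome_gc) / 2,
            config.genome_gc / 2,
            config.genome_gc / 2,
            (1 - config.genome_gc) / 2,
        ]
    )
    alphabet = np.array(list("ACGT"))
    sequences = {}
    island_rows, gene_rows, motif_rows = [], [], []
    for ci in range(config.genome_n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(alphabet, size=L, p=base_p)
        # deplete background CpGs (vertebrate genomes are CpG-poor outside islands)
        cg_pos = _find_cpg_positions("".join(seq))
        hit = cg_pos[rng.random(len(cg_pos)) < 0.7]
        seq[hit + 1] = rng.choice(np.array(list("AT")), size=len(hit))
        # plant islands in disjoint slots
        slots = np.sort(rng.choice(L // 1000 - 2, size=config.islands_per_chrom, replace=False))
        for sl in slots:
            length = int(rng.integers(250, 600))
            start = int(sl) * 1000 + int(rng.integers(0, 200))
            end = min(start + length, L)
            island = _cg_rich_segment(end - start, rng)
            seq[start:end] = island
            island_rows.append({"chrom": chrom, "start": start, "end": end})
        # plant motif instances outside islands
        for name, consensus in motifs.items():
            for _ in range(6):
                pos = int(rng.integers(0, L - len(consensus)))
                if any(
                    r["chrom"] == chrom and r["start"] - 20 <= pos <= r["end"] + 20
                    for r in island_rows
                ):
                    continue
                seq[pos : pos + len(consensus)] = list(consensus)
                motif_rows.append(
                    {
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + len(consensus),
                        "strand": "+",
                        "motif": name,
                    }
                )
        # gene models with exon blocks
        span_starts = np.sort(rng.choice(L - 10_000, size=config.genes_per_chrom, replace=False))
        for gi, gs in enumerate(span_starts):
            span = int(rng.integers(2000, 8000))
            g_start, g_end = int(gs), min(int(gs) + span, L)
            n_exon = int(rng.integers(2, 7))
            exon_starts = np.sort(
                rng.choice(range(g_start, g_end - 300, 10), size=n_exon, replace=False)
            )
            exons = []
            prev_end = g_start
            for es in exon_starts:
                es = max(int(es), prev_end)
                ee = min(es + int(rng.integers(100, 300)), g_end)
                if ee > es:
                    exons.append((es, ee))
                    prev_end = ee
            if not exons:
                exons = [(g_start, min(g_start + 200, g_end))]
            gene_rows.append(
                {
                    "chrom": chrom,
                    "start": g_start,
                    "end": g_end,
                    "name": f"{chrom}_g{gi}",
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "exons": exons,
                }
            )
        sequences[chrom] = "".join(seq)

    islands = pd.DataFrame(island_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    genes = pd.DataFrame(gene_rows)
    annotation = GenomeAnnotation(genes)

    # sample CpG sites from the realized sequence
    site_rows = []
    for chrom, seq in sequences.items():
        cpg0 = _find_cpg_positions(seq)
        take = min(len(cpg0), max(config.n_sites // config.genome_n_chroms, 1))
        chosen = np.sort(rng.choice(cpg0, size=take, replace=False))
        for p0 in chosen:
            site_rows.append({"chrom": chrom, "pos": int(p0) + 1, "strand": "+"})
    sites = pd.DataFrame(site_rows)
    sites = label_from_islands(sites, islands)
    sites["genic_context"] = annotation.genic_context(sites)
    return GenomeSimulation(sequences, annotation, islands, motifs and pd.DataFrame(motif_rows), sites)


def _cg_rich_segment(length: int, rng: np.random.Generator) -> np.ndarray:
    """A segment dense in CG dinucleotides (GC ~70%, obs/exp CpG >> 0.6)."""
    out = []
    while len(out) < length:
        if rng.random() < 0.40:
            out.extend(["C", "G"])
        else:
            out.append(str(rng.choice(np.array(list("GCGCAT")))))
    return np.array(out[:length])


def _find_cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr[:-1] == ord("C")
    is_g = arr[1:] == ord("G")
    return np.flatnonzero(is_c & is_g)
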