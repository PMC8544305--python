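"""End-to-end orchestration: simulate -> preprocess -> age association ->
clocks -> genomic context -> motif scan -> PDR -> IR interaction.

One configuration (YAML/JSON-friendly dict) drives the whole analysis; every
stage writes self-describing TSV/JSON outputs under the output directory and
is logged in a manifest with parameter echoes and content hashes, so a run is
reproducible and any stage can be re-run in isolation from its predecessors'
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, clocks, context, ir, motifs, pdr as pdr_mod, preprocess
from .dataset import write_metadata
from .simulate import SimulationConfig, simulate_aging_cohort, simulate_genome, \
    simulate_ir_cohort, simulate_read_patterns

log = logging.getLogger("methylaging")


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full run; defaults match the study protocol."""

    seed: int = 0
    output_dir: str = "methylaging_out"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    min_cov: int = 5
    max_cov: int = 100
    min_per_group: int = 5
    knn_k: int = 4
    diff_threshold: float = 25.0
    q_threshold: float = 0.01
    rho_threshold: float = 0.5
    clock_families: list = field(default_factory=lambda: ["linear", "enet", "pca"])
    test_size: int = 10
    run_genome_stages: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulate)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the aggregated report (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    report: dict = {"seed": config.seed}

    def stage(name, params, fn):
        t0 = time.time()
        log.info("stage %s start", name)
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        entry = {
            "stage": name,
            "params": params,
            "seconds": round(time.time() - t0, 2),
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        manifest.append(entry)
        log.info("stage %s done in %.1fs", name, entry["seconds"])

    sim_cfg = config.simulation_config()

    # ------------------------------------------------------------- simulate
    holder: dict = {}

    def do_simulate():
        aging_ds, truth = simulate_aging_cohort(sim_cfg)
        ir_ds, truth = simulate_ir_cohort(sim_cfg, truth)
        patterns = simulate_read_patterns(sim_cfg)
        holder.update(aging_raw=aging_ds, ir_raw=ir_ds, truth=truth, patterns=patterns)
        meta_path = out / "aging_metadata.tsv"
        write_metadata(aging_ds, meta_path)
        truth_path = out / "truth.json"
        truth.to_json(truth_path)
        patt_path = out / "read_patterns.tsv"
        patterns.write_tsv(patt_path)
        return [meta_path, truth_path, patt_path]

    stage("simulate", asdict(sim_cfg), do_simulate)

    # ----------------------------------------------------------- preprocess
    def do_preprocess():
        ds = preprocess.preprocess_chain(
            holder["aging_raw"],
            min_cov=config.min_cov,
            max_cov=config.max_cov,
            min_per_group=config.min_per_group,
            knn_k=config.knn_k,
        )
        holder["aging"] = ds
        path = out / "preprocess_summary.json"
        path.write_text(
            json.dumps(
                {
                    "n_sites_raw": holder["aging_raw"].n_sites,
                    "n_sites_retained": ds.n_sites,
                    "n_samples": ds.n_samples,
                },
                indent=1,
            )
        )
        report["n_sites_retained"] = ds.n_sites
        return [path]

    stage(
        "preprocess",
        {
            "min_cov": config.min_cov,
            "max_cov": config.max_cov,
            "min_per_group": config.min_per_group,
            "knn_k": config.knn_k,
        },
        do_preprocess,
    )

    # -------------------------------------------------------- age association
    def do_age_assoc():
        table = association.site_age_correlation(holder["aging"])
        table, occupancy = association.classify_and_bin(table)
        holder["age_table"] = table
        path = out / "age_association.tsv"
        table.to_csv(path, sep="\t", index=False)
        n_assoc = int(table["age_associated"].sum())
        n_hyper = int((table["age_associated"] & (table["rho"] > 0)).sum())
        n_hypo = n_assoc - n_hyper
        report["age_association"] = {
            "n_sites": len(table),
            "n_age_associated": n_assoc,
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "bin_occupancy": {k: int(v) for k, v in occupancy.items()},
        }
        # early vs late rates over the age-associated sites
        groups = [g for g, _ in _group_order(holder["aging"])]
        if table["age_associated"].any() and len(groups) >= 4:
            rates = association.early_late_rates(
                holder["aging"],
                table["age_associated"].to_numpy(),
                early=(groups[0], groups[3]),
                late=(groups[4], groups[-1]) if len(groups) >= 6 else (groups[-2], groups[-1]),
            )
            report["rates"] = {
                k: rates[k]
                for k in (
                    "mean_abs_change_early",
                    "mean_abs_change_late",
                    "mean_rate_early_per_day",
                    "mean_rate_late_per_day",
                    "t",
                    "p",
                )
            }
        return [path]

    stage("age_association", {"rho_threshold": config.rho_threshold}, do_age_assoc)

    # ---------------------------------------------------------------- clocks
    def do_clocks():
        ds = holder["aging"]
        train_ids, test_ids = clocks.split_train_test(ds, config.test_size, seed=config.seed)
        train = ds.subset_samples(train_ids)
        test = ds.subset_samples(test_ids)
        paths = []
        report["clocks"] = {}
        for fam in config.clock_families:
            fit = clocks.fit_clock(train, fam)
            ev_train = fit.evaluate(train, "train")
            ev_test = fit.evaluate(test, "test")
            overfit = clocks.compare_overfit(ev_train, ev_test)
            path = out / f"clock_{fam}.json"
            fit.to_json(path)
            paths.append(path)
            report["clocks"][fam] = {
                "train_mae": ev_train.mae,
                "train_r2": ev_train.r2,
                "test_mae": ev_test.mae,
                "test_r2": ev_test.r2,
                "overfit_p": overfit["p"],
            }
            holder[f"clock_{fam}"] = fit
        return paths

    stage("clocks", {"families": config.clock_families, "test_size": config.test_size}, do_clocks)

    # ------------------------------------------------- genome context + motifs
    if config.run_genome_stages:

        def do_context():
            genome = simulate_genome(sim_cfg)
            holder["genome"] = genome
            islands = context.detect_cgi_genome(genome.sequences)
            sites = genome.sites.copy()
            sites["cgi_detected"] = context.assign_cgi_context(sites, islands)
            sites["genic"] = genome.annotation.genic_context(sites)
            path = out / "context_labels.tsv"
            sites.to_csv(path, sep="\t", index=False)
            bed = out / "cgi_detected.bed"
            context.write_bed(islands, bed)
            report["context"] = {
                "n_islands_detected": len(islands),
                "cgi_counts": sites["cgi_detected"].value_counts().to_dict(),
                "genic_counts": sites["genic"].value_counts().to_dict(),
            }
            return [path, bed]

        stage("context", {}, do_context)

        def do_hre():
            genome = holder["genome"]
            pfms = [
                motifs.pfm_to_pssm(_consensus_pfm(cons), name=name)
                for name, cons in _planted_motifs(genome).items()
            ]
            hits = motifs.scan_genome(genome.sequences, pfms)
            path = out / "hre_hits.bed"
            motifs.hits_to_bed6(hits, path)
            report["hre"] = {"n_hits": len(hits)}
            return [path]

        stage("hre_scan", {"p_threshold": 1e-4}, do_hre)

    # ------------------------------------------------------------------- PDR
    def do_pdr():
        table = pdr_mod.pdr_table(holder["patterns"])
        trend = pdr_mod.pdr_age_trend(table, holder["aging_raw"].samples)
        path = out / "pdr.tsv"
        table.to_csv(path, sep="\t", index=False)
        report["pdr"] = {
            "slope": trend.slope,
            "se": trend.se,
            "p": trend.p,
            "model": trend.model,
        }
        return [path]

    stage("pdr", {}, do_pdr)

    # ---------------------------------------------------------- IR interaction
    def do_ir():
        ir_ds = preprocess.filter_by_coverage(
            holder["ir_raw"], config.min_cov, config.max_cov
        )
        ir_ds = preprocess.unite_sites(ir_ds, min_per_group=config.min_per_group)
        dmcs = ir.call_ir_dmcs(
            ir_ds,
            diff_threshold=config.diff_threshold,
            q_threshold=config.q_threshold,
        )
        ir_keys = ir_ds.site_keys()
        summary, enr = ir.overlap_and_bin_enrichment(
            dmcs, holder["age_table"], ir_covered_keys=ir_keys
        )
        records, dir_summary = ir.classify_directionality(dmcs, holder["age_table"])
        p1 = out / "ir_bin_enrichment.tsv"
        enr.to_csv(p1, sep="\t", index=False)
        p2 = out / "ir_directionality.tsv"
        dir_summary.to_csv(p2, sep="\t", index=False)
        # ANOVA of predicted age by exposure group, per clock family
        anova = {}
        for fam in config.clock_families:
            fit = holder.get(f"clock_{fam}")
            if fit is None:
                continue
            preds = fit.predict(ir_ds)
            anova[fam] = clocks.compare_groups(preds, ir_ds.groups())
        report["ir"] = {
            "overlap": summary.as_dict(),
            "bin_enrichment": enr.to_dict(orient="records"),
            "directionality": dir_summary.to_dict(orient="records"),
            "age_prediction_anova": anova,
        }
        return [p1, p2]

    stage(
        "ir_interaction",
        {"diff_threshold": config.diff_threshold, "q_threshold": config.q_threshold},
        do_ir,
    )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _group_order(ds) -> list:
    sub = ds.samples[["group", "age_days"]].drop_duplicates().sort_values("age_days")
    return list(sub.itertuples(index=False, name=None))


def _planted_motifs(genome) -> dict:
    from .simulate import DEFAULT_MOTIFS

    names = (
        set(genome.motif_instances["motif"]) if genome.motif_instances is not None else set()
    )
    return {k: v for k, v in DEFAULT_MOTIFS.items() if not names or k in names}


def _consensus_pfm(consensus: str) -> np.ndarray:
    from .motifs import BASE_INDEX

    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts[BASE_INDEX[b], j] += 60.0
    return counts
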