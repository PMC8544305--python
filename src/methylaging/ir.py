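"""Ionizing-radiation x epigenetic-aging interaction analysis.

Joins per-dose differential-methylation calls from the exposure cohort to the
aging cohort's correlation-bin table, tests bin-wise enrichment of IR-affected
sites along the aging continuum (exact binomial against the shared-site
background), and classifies whether each IR effect points in the same or the
opposite direction as the site's age trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import BIN_LABELS, call_dmcs
from .context import enrichment_test
from .dataset import MethylationDataset
from .reporting import percent


def call_ir_dmcs(
    ir_ds: MethylationDataset,
    control_group: str = "control",
    diff_threshold: float = 25.0,
    q_threshold: float = 0.01,
) -> dict:
    """Per-dose DMC tables (control vs each exposure arm) and their union.

    Returns {"per_dose": {group: table}, "union": site-key array of sites
    significant in at least one comparison}.
    """
    groups = [g for g in pd.unique(ir_ds.groups()) if g != control_group]
    if not groups:
        raise ValueError("no exposure groups besides control")
    per_dose = {}
    union_keys: set[str] = set()
    for g in groups:
        table = call_dmcs(
            ir_ds,
            control_group,
            g,
            diff_threshold=diff_threshold,
            q_threshold=q_threshold,
        )
        keys = (
            table["chrom"].astype(str) + ":" + table["pos"].astype(str) + ":" + table["strand"]
        )
        table = table.assign(site_key=keys)
        per_dose[g] = table
        union_keys |= set(keys[table["is_dmc"]])
    return {"per_dose": per_dose, "union": np.array(sorted(union_keys))}


@dataclass
class OverlapSummary:
    """Counts linking the aging and exposure datasets, with derived percents.

    Percentages are reported as 100 * ratio rounded to one decimal.
    """

    n_aging: int
    n_ir_covered: int
    n_shared: int
    n_ir_dmc: int
    n_ir_dmc_shared: int

    @property
    def pct_shared_of_aging(self) -> float:
        return percent(self.n_shared, self.n_aging)

    @property
    def pct_dmc_shared_of_dmc(self) -> float:
        return percent(self.n_ir_dmc_shared, self.n_ir_dmc) if self.n_ir_dmc else 0.0

    def as_dict(self) -> dict:
        return {
            "n_aging": self.n_aging,
            "n_ir_covered": self.n_ir_covered,
            "n_shared": self.n_shared,
            "n_ir_dmc": self.n_ir_dmc,
            "n_ir_dmc_shared": self.n_ir_dmc_shared,
            "pct_shared_of_aging": self.pct_shared_of_aging,
            "pct_dmc_shared_of_dmc": self.pct_dmc_shared_of_dmc,
        }


def overlap_and_bin_enrichment(
    ir_dmcs: dict,
    age_table: pd.DataFrame,
    ir_covered_keys: np.ndarray | None = None,
) -> tuple[OverlapSummary, pd.DataFrame]:
    """Overlap bookkeeping plus per-bin enrichment of shared IR DMCs.

    The background is the set of sites present in both analyses, labelled
    with their aging-continuum bins; the focal set is the shared IR DMCs.
    ``ir_covered_keys`` defaults to the sites of the per-dose tables.
    """
    age_keys = (
        age_table["chrom"].astype(str)
        + ":"
        + age_table["pos"].astype(str)
        + ":"
        + age_table["strand"]
    )
    age_bins = pd.Series(age_table["bin"].to_numpy(), index=age_keys.to_numpy())
    if ir_covered_keys is None:
        any_table = next(iter(ir_dmcs["per_dose"].values()))
        ir_covered_keys = any_table["site_key"].to_numpy()
    shared = np.intersect1d(age_keys.to_numpy(), np.asarray(ir_covered_keys))
    if len(shared) == 0:
        raise ValueError("no sites shared between aging and exposure datasets")
    union = np.asarray(ir_dmcs["union"])
    dmc_shared = np.intersect1d(shared, union)
    summary = OverlapSummary(
        n_aging=len(age_keys),
        n_ir_covered=len(np.unique(ir_covered_keys)),
        n_shared=len(shared),
        n_ir_dmc=len(union),
        n_ir_dmc_shared=len(dmc_shared),
    )
    background = age_bins.loc[shared]
    if len(dmc_shared) == 0:
        enr = pd.DataFrame(
            {
                "category": BIN_LABELS,
                "focal_hits": 0,
                "focal_n": 0,
                "background_hits": [int((background == b).sum()) for b in BIN_LABELS],
                "background_n": len(background),
                "p0": [float((background == b).mean()) for b in BIN_LABELS],
                "p": 1.0,
                "direction": "depleted",
            }
        )
        return summary, enr
    focal = age_bins.loc[dmc_shared]
    enr = enrichment_test(focal, background, categories=BIN_LABELS)
    return summary, enr


def classify_directionality(
    ir_dmcs: dict,
    age_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direction of each shared IR DMC's shift relative to its age trend.

    Per site: the age direction is sign(Spearman rho); per significant dose,
    the IR direction is sign(meth_diff, exposed - control). The relation is
    ``dose_dependent`` when two or more significant doses disagree in sign,
    else ``same`` when the common IR sign equals the age direction, else
    ``opposite``. Sites with rho exactly 0 are excluded and counted
    separately (relation ``undefined``).

    Returns (per-site records, per bin-and-dose summary with the percent of
    same/opposite sites and a binomial test of the split against 50:50).
    """
    age_keys = (
        age_table["chrom"].astype(str)
        + ":"
        + age_table["pos"].astype(str)
        + ":"
        + age_table["strand"]
    ).to_numpy()
    age_info = pd.DataFrame(
        {"rho": age_table["rho"].to_numpy(), "bin": age_table["bin"].to_numpy()},
        index=age_keys,
    )
    rows = []
    for key in ir_dmcs["union"]:
        if key not in age_info.index:
            continue
        rho = float(age_info.loc[key, "rho"])
        age_dir = int(np.sign(rho))
        dose_signs = {}
        for g, table in ir_dmcs["per_dose"].items():
            rec = table[(table["site_key"] == key) & table["is_dmc"]]
            if len(rec):
                dose_signs[g] = int(np.sign(rec["meth_diff"].iloc[0]))
        if not dose_signs:
            continue
        signs = set(dose_signs.values())
        if age_dir == 0:
            relation = "undefined"
        elif len(signs) > 1:
            relation = "dose_dependent"
        elif signs == {age_dir}:
            relation = "same"
        else:
            relation = "opposite"
        rows.append(
            {
                "site_key": key,
                "bin": age_info.loc[key, "bin"],
                "age_direction": age_dir,
                "ir_directions": dose_signs,
                "relation": relation,
            }
        )
    records = pd.DataFrame(
        rows, columns=["site_key", "bin", "age_direction", "ir_directions", "relation"]
    )
    summary_rows = []
    defined = records[records["relation"].isin(["same", "opposite"])]
    for b in BIN_LABELS:
        sub = defined[defined["bin"] == b]
        n_same = int((sub["relation"] == "same").sum())
        n_opp = int((sub["relation"] == "opposite").sum())
        n = n_same + n_opp
        p = stats.binomtest(n_same, n, 0.5).pvalue if n else 1.0
        summary_rows.append(
            {
                "bin": b,
                "n_same": n_same,
                "n_opposite": n_opp,
                "pct_same": percent(n_same, n) if n else 0.0,
                "pct_opposite": percent(n_opp, n) if n else 0.0,
                "p_vs_50_50": float(p),
            }
        )
    return records, pd.DataFrame(summary_rows)
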