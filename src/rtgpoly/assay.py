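"""URA3-loss (5-FOA) assay statistics.

Cells that lose the URA3 marker by LOH survive counter-selection on 5-FOA,
so the LOH rate at a timepoint is the percentage of 5-FOA-resistant
colony-forming units among total viable CFU:

    LOH rate_T = 100 x (CFU_5-FOA,T / CFU_YPD,T)

with both counts corrected to the same dilution. The unsporulated culture
(T0) gives the background; the RTG effect is summarised as the fold
increase rate_T / rate_T0 and the absolute difference rate_T - rate_T0,
and tested with a one-sided Wilcoxon rank-sum comparison of the replicate
rates.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TIMEPOINTS = ("T0", "T6", "T14")


@dataclass(frozen=True)
class CFURecord:
    """One plating: colony counts on 5-FOA and YPD with their dilutions.

    ``dilution_*`` is the fold-dilution of the culture applied before
    plating, so ``count * dilution`` estimates CFU per unit of the original
    culture. Counts are raw colonies on the plate.
    """

    strain: str
    replicate: str
    timepoint: str
    cfu_5foa: float
    cfu_ypd: float
    dilution_5foa: float = 1.0
    dilution_ypd: float = 1.0

    def __post_init__(self):
        if self.cfu_5foa < 0 or self.cfu_ypd < 0:
            raise ValueError("CFU counts must be >= 0")
        if self.dilution_5foa <= 0 or self.dilution_ypd <= 0:
            raise ValueError("dilution factors must be positive")


@dataclass
class AssayResult:
    rates: dict[str, float]              # timepoint -> mean rate (%)
    rate_sd: dict[str, float]
    fold_increase: dict[str, float]      # timepoint -> mean_T / mean_T0
    abs_difference: dict[str, float]     # timepoint -> mean_T - mean_T0 (points)
    p_values: dict[str, float]
    per_replicate: pd.DataFrame = field(default_factory=pd.DataFrame)


def loh_rate(rec: CFURecord) -> float:
    """LOH rate (%) of one plating: 100 x corrected CFU_5FOA / CFU_YPD."""
    ypd = rec.cfu_ypd * rec.dilution_ypd
    if ypd == 0:
        raise ValueError("CFU_YPD is 0 after dilution correction; rate undefined")
    return 100.0 * (rec.cfu_5foa * rec.dilution_5foa) / ypd


def summarize_assay(
    records: list[CFURecord],
    alternative: str = "greater",
) -> AssayResult:
    """Per-timepoint mean rates, fold increases, differences and tests.

    Rates are averaged over replicates per timepoint; fold increase and
    absolute difference compare each later timepoint's mean with the T0
    mean (a zero T0 mean leaves the fold undefined — NaN with a warning —
    but the difference is still reported). The p-value per timepoint is a
    one-sided rank-sum test of that timepoint's replicate rates against T0
    (requires >= 2 replicates on both sides, else NaN).
    """
    per_rep = pd.DataFrame(
        [
            {
                "strain": r.strain,
                "replicate": r.replicate,
                "timepoint": r.timepoint,
                "rate": loh_rate(r),
            }
            for r in records
        ]
    )
    if "T0" not in set(per_rep["timepoint"]):
        raise ValueError("assay needs at least one T0 replicate")
    rates, sds = {}, {}
    for tp, g in per_rep.groupby("timepoint"):
        rates[tp] = float(g["rate"].mean())
        sds[tp] = float(g["rate"].std(ddof=1)) if len(g) > 1 else 0.0
    t0_rates = per_rep.loc[per_rep["timepoint"] == "T0", "rate"].to_numpy()
    fold, diff, pvals = {}, {}, {}
    for tp in sorted(set(per_rep["timepoint"]) - {"T0"}):
        if rates["T0"] == 0:
            warnings.warn(f"T0 mean rate is 0; fold increase undefined for {tp}")
            fold[tp] = float("nan")
        else:
            fold[tp] = rates[tp] / rates["T0"]
        diff[tp] = rates[tp] - rates["T0"]
        t_rates = per_rep.loc[per_rep["timepoint"] == tp, "rate"].to_numpy()
        pvals[tp] = (
            rate_increase_test(t0_rates, t_rates, alternative=alternative)
            if len(t0_rates) >= 2 and len(t_rates) >= 2
            else float("nan")
        )
    return AssayResult(rates, sds, fold, diff, pvals, per_rep)


def _exact_tied_ranksum_p(t0, t, alternative):
    """Exact permutation p for the rank-sum statistic with midranks.

    Enumerates every assignment of the pooled observations to the two
    groups; feasible for total n <= ~20.
    """
    pooled = np.concatenate([t, t0])
    ranks = stats.rankdata(pooled)     # midranks
    n_t = len(t)
    observed = ranks[:n_t].sum()
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_t):
        s = ranks[list(combo)].sum()
        total += 1
        if alternative == "greater":
            count += s >= observed - 1e-9
        elif alternative == "less":
            count += s <= observed + 1e-9
        else:
            mean = n_t * (len(pooled) + 1) / 2
            count += abs(s - mean) >= abs(observed - mean) - 1e-9
    return count / total


def rate_increase_test(
    t0_rates,
    t_rates,
    alternative: str = "greater",
    exact_limit: int = 20,
) -> float:
    """One-sided Wilcoxon rank-sum p-value for an LOH-rate increase over T0.

    ``alternative='greater'`` tests whether the later-timepoint rates are
    stochastically greater than the T0 rates. For small tie-free groups the
    p is exact (full enumeration of rank assignments: complete separation
    of 5 vs 5 replicates gives exactly 1/252); ties in small samples are
    handled by exact enumeration with midranks; large samples use the
    normal approximation with continuity and tie corrections. Two
    completely identical groups return p = 1 with a warning.
    """
    t0 = np.asarray(t0_rates, dtype=float)
    t = np.asarray(t_rates, dtype=float)
    if len(t0) < 2 or len(t) < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate([t0, t])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p reported as 1")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= exact_limit
    if small and not has_ties:
        return float(
            stats.mannwhitneyu(t, t0, alternative=alternative, method="exact").pvalue
        )
    if small and has_ties:
        return float(_exact_tied_ranksum_p(t0, t, alternative))
    return float(
        stats.mannwhitneyu(
            t, t0, alternative=alternative, method="asymptotic", use_continuity=True
        ).pvalue
    )


def read_cfu_tsv(path) -> list[CFURecord]:
    """CFU table TSV: strain, replicate, timepoint, plate, count, dilution.

    One row per plate; the 5-FOA and YPD rows of a (strain, replicate,
    timepoint) group are paired into a :class:`CFURecord`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "replicate": str})
    records = []
    for (strain, rep, tp), g in df.groupby(["strain", "replicate", "timepoint"]):
        by_plate = {row.plate: row for row in g.itertuples(index=False)}
        if "5FOA" not in by_plate or "YPD" not in by_plate:
            raise ValueError(f"{strain}/{rep}/{tp}: need one 5FOA and one YPD row")
        records.append(
            CFURecord(
                strain=strain, replicate=rep, timepoint=tp,
                cfu_5foa=by_plate["5FOA"].count,
                cfu_ypd=by_plate["YPD"].count,
                dilution_5foa=by_plate["5FOA"].dilution,
                dilution_ypd=by_plate["YPD"].dilution,
            )
        )
    return records


def result_to_frame(res: AssayResult) -> pd.DataFrame:
    """AssayResult flattened to a tidy one-row-per-timepoint table."""
    rows = []
    for tp in sorted(res.rates):
        rows.append(
            {
                "timepoint": tp,
                "mean_rate_pct": res.rates[tp],
                "sd_rate_pct": res.rate_sd[tp],
                "fold_vs_t0": res.fold_increase.get(tp, 1.0 if tp == "T0" else math.nan),
                "diff_vs_t0_points": res.abs_difference.get(tp, 0.0 if tp == "T0" else math.nan),
                "p_value": res.p_values.get(tp, math.nan),
            }
        )
    return pd.DataFrame(rows)
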