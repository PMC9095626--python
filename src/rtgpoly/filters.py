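"""Cohort-level and positional exclusion filters for AF-shift regions.

Three filters are applied in a fixed order, each only ever removing or
shrinking regions:

1. *Recurrence*: within a dataset (wild-type RTG, marker-selected RTG,
   ndt80-arrested RTG, ...), a region overlapped for more than 80% of its
   length by a single region of at least 70% of the samples is taken to be
   a pre-meiotic event shared through the culture, not an RTG product, and
   removed everywhere it occurs.
2. *T0*: regions covered for at least 90% of their length by the union of
   the unsporulated control's regions were already present before meiosis.
3. *Positional*: subtelomeric margins (unreliable short-read mapping),
   annotated parental CNVs and parental engineered/pre-existing regions are
   excluded — a region mostly (> 50%) inside exclusions is dropped, one
   merely clipped by them is trimmed.

All intervals are 0-based half-open; overlap fractions are always measured
against the focal region's own length.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass
class FilterConfig:
    recurrence_overlap: float = 0.8      # ">80% of their length" (strict)
    recurrence_samples: float = 0.7      # ">= 70% of the samples" (inclusive)
    t0_overlap: float = 0.9              # ">= 90%" (inclusive)
    min_dataset_size: int = 3
    drop_fraction: float = 0.5           # positional: drop vs trim pivot
    positional_mode: str = "auto"        # "auto" | "drop" | "trim"

    def __post_init__(self):
        for name in ("recurrence_overlap", "recurrence_samples", "t0_overlap"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome."""
    rows = []
    for chrom, g in df.groupby("chrom", sort=False):
        g = g.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def _covered_length(start: int, end: int, others: pd.DataFrame) -> int:
    """Length of [start, end) covered by the union of ``others`` (same chrom)."""
    if len(others) == 0:
        return 0
    merged = merge_intervals(others)
    ov = np.minimum(merged["end"], end) - np.maximum(merged["start"], start)
    return int(np.maximum(ov, 0).sum())


def _best_single_overlap(start: int, end: int, others: pd.DataFrame) -> int:
    """Largest overlap of [start, end) with any single interval in ``others``."""
    if len(others) == 0:
        return 0
    ov = np.minimum(others["end"], end) - np.maximum(others["start"], start)
    return int(max(0, ov.max()))


def filter_recurrent(
    regions_by_sample: dict[str, pd.DataFrame],
    dataset_of: dict[str, str],
    cfg: FilterConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Remove regions recurring across most samples of the same dataset.

    A focal region is removed when the fraction of samples in its dataset
    (the focal sample included in numerator and denominator) that contain a
    *single* region covering strictly more than ``recurrence_overlap`` of
    the focal region's length reaches ``recurrence_samples``. Datasets with
    fewer than ``min_dataset_size`` samples skip the filter. Returns the
    filtered map and an audit table of removals.
    """
    cfg = cfg or FilterConfig()
    for s in regions_by_sample:
        if s not in dataset_of:
            raise ValueError(f"sample {s!r} has no dataset label")
    datasets: dict[str, list[str]] = {}
    for s in regions_by_sample:
        datasets.setdefault(dataset_of[s], []).append(s)

    out: dict[str, pd.DataFrame] = {}
    audit = []
    for sample, regions in regions_by_sample.items():
        members = datasets[dataset_of[sample]]
        if len(members) < cfg.min_dataset_size or len(regions) == 0:
            out[sample] = regions.reset_index(drop=True)
            continue
        keep = []
        for row in regions.itertuples(index=False):
            length = row.end - row.start
            n_hit = 0
            for other in members:
                og = regions_by_sample[other]
                og = og[og["chrom"] == row.chrom]
                best = _best_single_overlap(row.start, row.end, og)
                if best > cfg.recurrence_overlap * length:
                    n_hit += 1
            frac = n_hit / len(members)
            if frac >= cfg.recurrence_samples:
                keep.append(False)
                audit.append(
                    {"sample": sample, "chrom": row.chrom, "start": row.start,
                     "end": row.end, "filter": "recurrent", "action": "drop",
                     "detail": f"{n_hit}/{len(members)} samples"}
                )
            else:
                keep.append(True)
        out[sample] = regions[np.array(keep, dtype=bool)].reset_index(drop=True)
    audit_df = pd.DataFrame(
        audit, columns=["sample", "chrom", "start", "end", "filter", "action", "detail"]
    )
    return out, audit_df


def filter_t0(
    regions: pd.DataFrame,
    t0_regions: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove regions covered >= ``t0_overlap`` of their length by T0 regions."""
    cfg = cfg or FilterConfig()
    keep, audit = [], []
    for row in regions.itertuples(index=False):
        t0 = t0_regions[t0_regions["chrom"] == row.chrom]
        cov = _covered_length(row.start, row.end, t0)
        frac = cov / (row.end - row.start)
        if frac >= cfg.t0_overlap - 1e-12:
            keep.append(False)
            audit.append(
                {"chrom": row.chrom, "start": row.start, "end": row.end,
                 "filter": "t0", "action": "drop", "detail": f"coverage={frac:.3f}"}
            )
        else:
            keep.append(True)
    mask = np.array(keep, dtype=bool) if keep else np.array([], dtype=bool)
    audit_df = pd.DataFrame(audit, columns=["chrom", "start", "end", "filter", "action", "detail"])
    return regions[mask].reset_index(drop=True), audit_df


def subtract_intervals(start: int, end: int, exclusions: pd.DataFrame) -> list[tuple[int, int]]:
    """[start, end) minus the union of exclusion intervals (same chrom)."""
    pieces = []
    cur = start
    merged = merge_intervals(exclusions).sort_values("start") if len(exclusions) else exclusions
    for row in merged.itertuples(index=False):
        s, e = max(row.start, start), min(row.end, end)
        if s >= e:
            continue
        if s > cur:
            pieces.append((cur, s))
        cur = max(cur, e)
    if cur < end:
        pieces.append((cur, end))
    return pieces


def apply_positional_exclusions(
    regions: pd.DataFrame,
    exclusions: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop or trim regions intersecting positional exclusion intervals.

    ``exclusions`` is the concatenation of subtelomere margins, parental
    CNVs and parental engineered regions (they are unioned first). In the
    default ``auto`` mode a region losing more than ``drop_fraction`` of
    its length is dropped, otherwise the excluded parts are trimmed away
    (a region split in two keeps both pieces).
    """
    cfg = cfg or FilterConfig()
    if len(exclusions) == 0:
        return regions.reset_index(drop=True), pd.DataFrame(
            columns=["chrom", "start", "end", "filter", "action", "detail"]
        )
    rows, audit = [], []
    for row in regions.itertuples(index=False):
        ex = exclusions[exclusions["chrom"] == row.chrom]
        length = row.end - row.start
        cov = _covered_length(row.start, row.end, ex)
        if cov == 0:
            rows.append(row._asdict())
            continue
        frac = cov / length
        drop = cfg.positional_mode == "drop" or (
            cfg.positional_mode == "auto" and frac > cfg.drop_fraction
        )
        if drop:
            audit.append(
                {"chrom": row.chrom, "start": row.start, "end": row.end,
                 "filter": "positional", "action": "drop", "detail": f"excluded={frac:.3f}"}
            )
            continue
        for s, e in subtract_intervals(row.start, row.end, ex):
            d = row._asdict()
            d["start"], d["end"] = s, e
            rows.append(d)
        audit.append(
            {"chrom": row.chrom, "start": row.start, "end": row.end,
             "filter": "positional", "action": "trim", "detail": f"excluded={frac:.3f}"}
        )
    out = pd.DataFrame(rows, columns=list(regions.columns))
    audit_df = pd.DataFrame(audit, columns=["chrom", "start", "end", "filter", "action", "detail"])
    return out.reset_index(drop=True), audit_df


def subtelomere_bed(chrom_lengths: dict[str, int], margin: int) -> pd.DataFrame:
    """Margin intervals at both ends of every chromosome (BED, half-open)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        m = min(margin, length)
        rows.append((chrom, 0, m))
        if length > m:
            rows.append((chrom, max(length - m, m), length))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = BED_COLUMNS
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)
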