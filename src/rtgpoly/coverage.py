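"""Windowed read-depth normalization, CNV calls and aneuploidy flags.

Depth is averaged over fixed non-overlapping windows (10 kbp for large
CNVs, 1 kbp for short ones) and normalized by the median window depth of
the same chromosome, so a region present in c of p haplotypes sits at
ratio c/p. Whole-chromosome changes are invisible to chromosome-median
normalization by construction, so aneuploidy screening compares each
chromosome's median depth to the genome-wide median instead, flagging a
chromosome when its log2 ratio exceeds half the one-copy shift
log2((p±1)/p).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PROFILE_COLUMNS = ["chrom", "start", "end", "mean_depth", "ratio", "log2_ratio"]
CNV_COLUMNS = ["chrom", "start", "end", "direction", "mean_ratio", "copy_change", "n_windows", "scale"]


def rebin_track(track: pd.DataFrame, window: int) -> pd.DataFrame:
    """Re-aggregate a fine depth track onto fixed ``window`` bp windows.

    Window means are length-weighted so a coarse window built from unequal
    fine windows (trailing partials) equals the true per-base average.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, g in track.groupby("chrom", sort=False):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        depth = g["mean_depth"].to_numpy(dtype=float)
        chrom_end = int(ends.max())
        out_starts = np.arange(0, chrom_end, window)
        out_ends = np.minimum(out_starts + window, chrom_end)
        mass = np.zeros(len(out_starts))
        span = np.zeros(len(out_starts))
        for s, e, d in zip(starts, ends, depth):
            w0, w1 = int(s // window), int((e - 1) // window)
            for w in range(w0, w1 + 1):
                ov = min(e, (w + 1) * window) - max(s, w * window)
                if ov > 0 and w < len(mass):
                    mass[w] += d * ov
                    span[w] += ov
        ok = span > 0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": out_starts[ok],
                    "end": out_ends[ok],
                    "mean_depth": mass[ok] / span[ok],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def profile_coverage(
    track: pd.DataFrame,
    window: int = 10_000,
    normalizer: str = "chromosome_median",
) -> pd.DataFrame:
    """Normalized coverage profile from a depth track.

    ``track`` is a (chrom, start, end, mean_depth) table at any resolution
    at or below ``window``; it is re-binned first. ``normalizer`` is
    ``chromosome_median`` (intra-chromosomal CNV work) or ``genome_median``
    (aneuploidy work). Chromosomes with no positive-depth window are
    skipped with a warning.
    """
    prof = rebin_track(track, window)
    if normalizer == "genome_median":
        med = float(np.median(prof["mean_depth"]))
        prof["ratio"] = prof["mean_depth"] / med if med > 0 else np.nan
    elif normalizer == "chromosome_median":
        parts = []
        for chrom, g in prof.groupby("chrom", sort=False):
            med = float(np.median(g["mean_depth"]))
            if med <= 0:
                warnings.warn(f"chromosome {chrom} has zero median depth; skipped")
                continue
            g = g.copy()
            g["ratio"] = g["mean_depth"] / med
            parts.append(g)
        prof = pd.concat(parts, ignore_index=True) if parts else prof.iloc[0:0].assign(ratio=[])
    else:
        raise ValueError("normalizer must be 'chromosome_median' or 'genome_median'")
    with np.errstate(divide="ignore"):
        prof["log2_ratio"] = np.where(prof["ratio"] > 0, np.log2(prof["ratio"]), np.nan)
    _warn_terminal_bias(prof)
    return prof[PROFILE_COLUMNS]


def _warn_terminal_bias(prof: pd.DataFrame, n_edge: int = 3, tol: float = 0.15) -> None:
    """Warn when terminal windows systematically deviate (smiley-pattern cue)."""
    devs = []
    for _, g in prof.groupby("chrom", sort=False):
        if len(g) > 4 * n_edge:
            edge = pd.concat([g.head(n_edge), g.tail(n_edge)])["ratio"]
            devs.append(edge.mean() - g["ratio"].median())
    if devs and abs(float(np.mean(devs))) > tol:
        warnings.warn(
            "terminal windows systematically deviate from chromosome medians; "
            "possible positional coverage bias (not corrected here)"
        )


def call_cnv(
    profile: pd.DataFrame,
    ploidy: dict[str, int],
    ratio_thresholds: tuple[float, float] = (0.8, 1.2),
    min_windows: int = 3,
    scale: str = "large",
) -> pd.DataFrame:
    """Runs of at least ``min_windows`` windows beyond the ratio thresholds.

    Copy change is reported in haplotype units: ``mean_ratio * p - p``
    rounded to the nearest integer, for a chromosome of ploidy p.
    """
    lo, hi = ratio_thresholds
    rows = []
    for chrom, g in profile.groupby("chrom", sort=False):
        ratio = g["ratio"].to_numpy()
        state = np.where(ratio < lo, -1, np.where(ratio > hi, 1, 0))
        i = 0
        while i < len(state):
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j < len(state) and state[j] == state[i]:
                j += 1
            if j - i >= min_windows:
                p = ploidy[chrom]
                mean_ratio = float(ratio[i:j].mean())
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(g["start"].to_numpy()[i]),
                        "end": int(g["end"].to_numpy()[j - 1]),
                        "direction": "gain" if state[i] > 0 else "loss",
                        "mean_ratio": mean_ratio,
                        "copy_change": int(round(mean_ratio * p - p)),
                        "n_windows": j - i,
                        "scale": scale,
                    }
                )
            i = j
    return pd.DataFrame(rows, columns=CNV_COLUMNS)


def call_cnv_two_scale(
    track: pd.DataFrame,
    ploidy: dict[str, int],
    large_window: int = 10_000,
    small_window: int = 1_000,
    ratio_thresholds: tuple[float, float] = (0.8, 1.2),
    min_windows: int = 3,
) -> pd.DataFrame:
    """Large-scale (10 kbp) plus small-scale (1 kbp) CNV pass, merged.

    Small-scale calls entirely contained in a same-direction large call are
    redundant and dropped.
    """
    large = call_cnv(
        profile_coverage(track, large_window), ploidy, ratio_thresholds, min_windows, "large"
    )
    small = call_cnv(
        profile_coverage(track, small_window), ploidy, ratio_thresholds, min_windows, "small"
    )
    keep = []
    for row in small.itertuples(index=False):
        contained = (
            (large["chrom"] == row.chrom)
            & (large["start"] <= row.start)
            & (large["end"] >= row.end)
            & (large["direction"] == row.direction)
        ).any()
        keep.append(not contained)
    parts = [df for df in (large, small[np.array(keep, dtype=bool)] if len(small) else small)
             if len(df)]
    if not parts:
        return large
    merged = pd.concat(parts, ignore_index=True)
    return merged.sort_values(["chrom", "start"]).reset_index(drop=True)


def flag_aneuploidy(
    track: pd.DataFrame,
    ploidy: dict[str, int],
    window: int = 10_000,
) -> pd.DataFrame:
    """Flag whole-chromosome gains/losses from genome-median-normalized depth.

    A chromosome of ploidy p is flagged when its median log2 ratio against
    the genome median exceeds half the expected one-copy shift
    (|log2((p±1)/p)| / 2). Requires >= 2 chromosomes.
    """
    prof = profile_coverage(track, window, normalizer="genome_median")
    if prof["chrom"].nunique() < 2:
        raise ValueError("aneuploidy flagging needs >= 2 chromosomes")
    rows = []
    for chrom, g in prof.groupby("chrom", sort=False):
        p = ploidy[chrom]
        med = float(np.nanmedian(g["log2_ratio"]))
        gain_thr = np.log2((p + 1) / p) / 2
        loss_thr = -np.log2(p / (p - 1)) / 2 if p > 1 else -gain_thr
        if med >= gain_thr:
            rows.append({"chrom": chrom, "direction": "gain", "median_log2": med})
        elif med <= loss_thr:
            rows.append({"chrom": chrom, "direction": "loss", "median_log2": med})
    return pd.DataFrame(rows, columns=["chrom", "direction", "median_log2"])
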