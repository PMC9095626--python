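"""Per-marker allele-frequency shift calling and region assembly.

A marker's observed alternative-allele frequency (AF) in an evolved sample
is compared against the parental dosage k/p. The sample's dosage k' is the
nearest integer to p * AF (ties resolved toward the parental dosage, the
conservative choice), and the marker is a *shift* when it is sequenced
deeply enough, k' differs from k, and the AF moved at least a guard band
(0.4 dosage steps by default) away from the parental value. Runs of at
least ``min_run`` consecutive
shifted markers (nine by default, the stringent threshold used to avoid
false positives in polyploids) become AF-shift regions, regardless of the
direction in which individual markers move — local haplotype structure
fragments a single recombination event into mixed-direction runs.

An alternative per-marker criterion (exact binomial test of AF = k/p) is
available via ``method="binomial"``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markers import STATUS_HET, STATUS_HOMREF, STATUS_MISSING

# guard band in dosage units: a shift needs |AF - k/p| >= DEFAULT_GUARD / p.
# Slightly inside the rounding midpoint (0.5/p): per-marker false shifts are
# cheap (the >= 9-consecutive-marker rule absorbs them) while per-marker
# misses chop runs and are expensive, so the operating point trades a little
# per-marker specificity for run-level sensitivity.
DEFAULT_GUARD = 0.4

SHIFT = "shift"
NO_SHIFT = "no_shift"
MISSING = "missing"

TOWARD_ALT = "toward_alt"
TOWARD_REF = "toward_ref"
NONE = "none"

REGION_COLUMNS = [
    "chrom", "start", "end", "first_idx", "last_idx",
    "n_markers", "mean_abs_daf", "n_toward_alt", "n_toward_ref",
]


@dataclass(frozen=True)
class ShiftCall:
    """Scalar per-marker shift decision (see :func:`classify_marker`)."""

    status: str
    direction: str
    k_hat: int | None
    magnitude: int


def _round_to_dosage(x: np.ndarray, parent_k: np.ndarray) -> np.ndarray:
    """Nearest integer with exact half-way ties resolved toward parent_k."""
    lo = np.floor(x)
    frac = x - lo
    k_hat = np.where(frac > 0.5, lo + 1, lo)
    tie = np.isclose(frac, 0.5)
    # at a tie the two candidates are lo and lo+1; prefer the parental dosage
    k_hat = np.where(tie & (parent_k == lo + 1), lo + 1, np.where(tie, lo, k_hat))
    return k_hat.astype(int)


def classify_sample(
    table: pd.DataFrame,
    min_depth: int = 10,
    guard: float | None = None,
    method: str = "dosage",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorised shift classification of a joined sample allele table.

    ``table`` needs columns (chrom, pos, k, p, ref_depth, alt_depth,
    total_depth, af, status). Adds columns ``shift_status``
    (shift/no_shift/missing), ``direction`` (toward_alt/toward_ref/none),
    ``k_hat`` and ``delta_af``. Markers whose join status is missing stay
    missing, as do markers below the depth floor; hom_ref_candidate markers
    carry AF 0 and map to k' = 0. The default guard band is
    ``DEFAULT_GUARD / p`` (0.4 dosage steps; see the constant's comment for
    the operating-point rationale).
    """
    df = table.copy()
    k = df["k"].to_numpy()
    p = df["p"].to_numpy()
    depth = df["total_depth"].to_numpy()
    af = df["af"].to_numpy(dtype=float)
    usable = (df["status"].to_numpy() != STATUS_MISSING) & (depth >= min_depth)
    af_safe = np.where(np.isfinite(af), af, 0.0)
    k_hat = _round_to_dosage(p * af_safe, k)
    k_hat = np.clip(k_hat, 0, p)
    g = (DEFAULT_GUARD / p) if guard is None else np.full_like(af_safe, guard)
    delta = af_safe - k / p
    # past the guard but short of the rounding midpoint the inferred dosage
    # is the adjacent level in the direction of the shift
    beyond_guard = np.abs(delta) >= g - 1e-12
    k_hat = np.where(
        beyond_guard & (k_hat == k),
        np.clip(k + np.sign(delta).astype(int), 0, p),
        k_hat,
    )
    if method == "dosage":
        is_shift = usable & (k_hat != k) & beyond_guard
    elif method == "binomial":
        alt = df["alt_depth"].to_numpy()
        pvals = np.ones(len(df))
        idx = np.flatnonzero(usable & (depth > 0))
        pvals[idx] = stats.binom.cdf(alt[idx], depth[idx], k[idx] / p[idx])
        pvals[idx] = 2 * np.minimum(pvals[idx], 1 - stats.binom.cdf(alt[idx] - 1, depth[idx], k[idx] / p[idx]))
        is_shift = usable & (k_hat != k) & (pvals < alpha)
    else:
        raise ValueError("method must be 'dosage' or 'binomial'")
    df["shift_status"] = np.where(~usable, MISSING, np.where(is_shift, SHIFT, NO_SHIFT))
    df["direction"] = np.where(
        is_shift, np.where(k_hat > k, TOWARD_ALT, TOWARD_REF), NONE
    )
    df["k_hat"] = np.where(usable, k_hat, -1)
    df["delta_af"] = np.where(usable, delta, np.nan)
    return df


def classify_marker(
    parent_k: int,
    p: int,
    ref_depth: int,
    alt_depth: int,
    min_depth: int = 10,
    guard: float | None = None,
) -> ShiftCall:
    """Classify a single marker from raw depths (scalar convenience API)."""
    if not (0 < parent_k < p):
        raise ValueError("parent dosage must satisfy 0 < k < p")
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be >= 0")
    total = ref_depth + alt_depth
    table = pd.DataFrame(
        {
            "chrom": ["_"], "pos": [1], "k": [parent_k], "p": [p],
            "ref_depth": [ref_depth], "alt_depth": [alt_depth],
            "total_depth": [total],
            "af": [alt_depth / total if total > 0 else np.nan],
            "status": [STATUS_HET if total > 0 else STATUS_MISSING],
        }
    )
    row = classify_sample(table, min_depth=min_depth, guard=guard).iloc[0]
    k_hat = int(row["k_hat"]) if row["shift_status"] != MISSING else None
    return ShiftCall(
        status=row["shift_status"],
        direction=row["direction"],
        k_hat=k_hat,
        magnitude=abs(k_hat - parent_k) if k_hat is not None else 0,
    )


def call_regions(calls: pd.DataFrame, min_run: int = 9) -> pd.DataFrame:
    """Assemble maximal runs of consecutive shifted markers into regions.

    ``calls`` must be in catalogue order. Missing markers break runs (no
    bridging across unsequenced gaps); mixed directions within a run are
    allowed. Runs of length >= ``min_run`` become regions whose interval is
    the first-to-last shifted marker, exported 0-based half-open. Row
    indices of ``calls`` are preserved in first_idx/last_idx so members can
    be recovered as the contiguous slice.
    """
    rows = []
    for chrom, g in calls.groupby("chrom", sort=False):
        status = g["shift_status"].to_numpy()
        pos = g["pos"].to_numpy()
        idx = g.index.to_numpy()
        run_start = None
        for i in range(len(g) + 1):
            is_shift = i < len(g) and status[i] == SHIFT
            if is_shift and run_start is None:
                run_start = i
            elif not is_shift and run_start is not None:
                if i - run_start >= min_run:
                    sl = slice(run_start, i)
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[run_start]) - 1,
                            "end": int(pos[i - 1]),
                            "first_idx": int(idx[run_start]),
                            "last_idx": int(idx[i - 1]),
                            "n_markers": i - run_start,
                            "mean_abs_daf": float(np.abs(g["delta_af"].to_numpy()[sl]).mean()),
                            "n_toward_alt": int((g["direction"].to_numpy()[sl] == TOWARD_ALT).sum()),
                            "n_toward_ref": int((g["direction"].to_numpy()[sl] == TOWARD_REF).sum()),
                        }
                    )
                run_start = None
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def region_marker_indices(regions: pd.DataFrame) -> np.ndarray:
    """Catalogue row indices of all markers inside the given regions."""
    if len(regions) == 0:
        return np.array([], dtype=int)
    return np.concatenate(
        [np.arange(r.first_idx, r.last_idx + 1) for r in regions.itertuples(index=False)]
    )


def percent_shifted_markers(
    regions: pd.DataFrame,
    catalog_df: pd.DataFrame,
    exclude_chroms: tuple[str, ...] = (),
    subtel_margin: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> float:
    """Percentage of catalogue markers lying inside retained shift regions.

    Both numerator and denominator exclude ``exclude_chroms`` (e.g. the
    chromosome carrying an engineered selection locus) and, when
    ``subtel_margin`` > 0 and chromosome lengths are known, markers within
    the subtelomeric margins.
    """
    keep = ~catalog_df["chrom"].isin(exclude_chroms)
    if subtel_margin > 0 and chrom_lengths:
        lengths = catalog_df["chrom"].map(chrom_lengths)
        keep &= (catalog_df["pos"] > subtel_margin) & (
            catalog_df["pos"] <= lengths - subtel_margin
        )
    denom = int(keep.sum())
    if denom == 0:
        raise ValueError("no catalogue markers left after exclusions")
    inside = np.zeros(len(catalog_df), dtype=bool)
    idx = region_marker_indices(regions)
    if len(idx):
        inside[idx] = True
    num = int((inside & keep.to_numpy()).sum())
    return 100.0 * num / denom


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED with n_markers, mean |dAF| and direction summary."""
    out = regions.copy()
    out["direction_summary"] = [
        f"alt:{r.n_toward_alt},ref:{r.n_toward_ref}" for r in regions.itertuples(index=False)
    ]
    out[["chrom", "start", "end", "n_markers", "mean_abs_daf", "direction_summary"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.4f"
    )
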