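"""Mother-daughter pair analysis: reciprocity, landscapes, local phasing.

An RTG mother and daughter receive complementary chromatids, so a
crossover whose recombinant chromatids split between the two cells shows as
opposite-direction AF shifts over the same interval — the reciprocity
signature used to recognise genuine M-D pairs. One-sided (non-reciprocal)
events are gene-conversion candidates. Within a reciprocal region each
shifted marker exposes the alleles of the two recombining haplotypes (the
gained allele came from the donor haplotype, the lost one was the
recipient's), and the dosage identity (alleles across all p haplotypes sum
to the parental k) pins down the remaining haplotypes: with initial
genotype Ref/Alt/Alt and a shift toward Ref, the recombining pair carried
one Ref and one Alt, and the third haplotype must carry Alt.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afshift import SHIFT, TOWARD_ALT

RECIPROCAL = "reciprocal"
NON_RECIPROCAL = "non_reciprocal"


@dataclass
class MDPair:
    """Shift-call tables and retained regions for one mother-daughter pair.

    Both call tables must derive from the same catalogue (same marker rows
    in the same order).
    """

    mother_id: str
    daughter_id: str
    mother_calls: pd.DataFrame
    daughter_calls: pd.DataFrame
    mother_regions: pd.DataFrame
    daughter_regions: pd.DataFrame

    def __post_init__(self):
        a, b = self.mother_calls, self.daughter_calls
        if len(a) != len(b) or not (a["pos"].to_numpy() == b["pos"].to_numpy()).all():
            raise ValueError("mother and daughter must share one marker catalogue")

    def swapped(self) -> "MDPair":
        return MDPair(
            self.daughter_id, self.mother_id,
            self.daughter_calls, self.mother_calls,
            self.daughter_regions, self.mother_regions,
        )


def classify_reciprocity(
    pair: MDPair,
    agreement_threshold: float = 0.8,
    overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Match mother and daughter regions and classify each as reciprocal or not.

    Regions are matched when their overlap covers at least
    ``overlap_fraction`` of the shorter region's span. A matched pair is
    ``reciprocal`` when, over the markers shifted in both cells, the shift
    directions are opposite in at least ``agreement_threshold`` of them.
    Unmatched regions (either cell) are ``non_reciprocal`` gene-conversion
    candidates. Output columns: chrom, start, end (union span of the
    match), cells, call, agreement, n_shared.
    """
    m_dir = pair.mother_calls["direction"].to_numpy()
    d_dir = pair.daughter_calls["direction"].to_numpy()
    m_shift = pair.mother_calls["shift_status"].to_numpy() == SHIFT
    d_shift = pair.daughter_calls["shift_status"].to_numpy() == SHIFT

    rows = []
    matched_d: set[int] = set()
    for mrow in pair.mother_regions.itertuples(index=False):
        best, best_j = None, None
        for j, drow in enumerate(pair.daughter_regions.itertuples(index=False)):
            if drow.chrom != mrow.chrom:
                continue
            ov = min(mrow.end, drow.end) - max(mrow.start, drow.start)
            shorter = min(mrow.end - mrow.start, drow.end - drow.start)
            if shorter <= 0 or ov < overlap_fraction * shorter:
                continue
            if best is None or ov > best:
                best, best_j = ov, j
        if best_j is None:
            rows.append(_call_row(mrow, None, NON_RECIPROCAL, np.nan, 0, "mother"))
            continue
        drow = pair.daughter_regions.iloc[best_j]
        matched_d.add(best_j)
        lo = max(mrow.first_idx, int(drow["first_idx"]))
        hi = min(mrow.last_idx, int(drow["last_idx"]))
        shared = np.arange(lo, hi + 1)
        shared = shared[m_shift[shared] & d_shift[shared]]
        if len(shared):
            opposite = float((m_dir[shared] != d_dir[shared]).mean())
        else:
            opposite = 0.0
        call = RECIPROCAL if (len(shared) and opposite >= agreement_threshold) else NON_RECIPROCAL
        rows.append(_call_row(mrow, drow, call, opposite, len(shared), "both"))
    for j, drow in enumerate(pair.daughter_regions.itertuples(index=False)):
        if j not in matched_d:
            rows.append(_call_row(drow, None, NON_RECIPROCAL, np.nan, 0, "daughter"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cells", "call", "agreement", "n_shared"]
    )


def _call_row(a, b, call, agreement, n_shared, cells):
    start = int(a.start if b is None else min(a.start, b["start"]))
    end = int(a.end if b is None else max(a.end, b["end"]))
    return {
        "chrom": a.chrom, "start": start, "end": end,
        "cells": cells, "call": call, "agreement": agreement, "n_shared": n_shared,
    }


def pairwise_landscape_distance(shifted_sets: dict[str, set[int]]) -> pd.DataFrame:
    """Jaccard distance matrix between samples' shifted-marker sets.

    Distance is 1 - |intersection| / |union|; two samples with no shifted
    markers at all are at distance 0, a single empty sample is at distance
    1 from every non-empty one.
    """
    names = list(shifted_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 samples")
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            sa, sb = shifted_sets[a], shifted_sets[b]
            union = len(sa | sb)
            d = 0.0 if union == 0 else 1.0 - len(sa & sb) / union
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def shifted_marker_set(calls: pd.DataFrame) -> set[int]:
    return set(np.flatnonzero(calls["shift_status"].to_numpy() == SHIFT).tolist())


def phase_md_pair(
    pair: MDPair,
    region: pd.Series | dict,
    catalog_df: pd.DataFrame,
    focal: str = "mother",
    reciprocity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Locally phase the haplotypes across one reciprocal region.

    For every marker shifted by exactly one dosage unit in the focal cell,
    the gained allele is the donor (recombining) haplotype's allele and its
    complement is the recipient's; the remaining p-2 haplotypes together
    carry k minus one Alt allele. Markers not shifted (or violating the
    dosage identity) get confidence 0 and no assignment.

    Returns a table (chrom, pos, k, p, hap_recipient, hap_donor,
    n_rest_alt, rest, confidence); the recipient/donor labelling is
    arbitrary per block (the swap is unidentifiable from one pair).
    """
    calls = pair.mother_calls if focal == "mother" else pair.daughter_calls
    region = dict(region) if not isinstance(region, dict) else region
    if reciprocity is not None:
        rec = reciprocity[
            (reciprocity["call"] == RECIPROCAL)
            & (reciprocity["chrom"] == region["chrom"])
            & (reciprocity["start"] < region["end"])
            & (reciprocity["end"] > region["start"])
        ]
        if len(rec) == 0:
            raise ValueError("region is not classified reciprocal; phasing undefined")
    lo, hi = int(region["first_idx"]), int(region["last_idx"])
    sl = calls.iloc[lo : hi + 1]
    rows = []
    for idx, row in sl.iterrows():
        k, p = int(row["k"]), int(row["p"])
        shifted = row["shift_status"] == SHIFT and abs(int(row["k_hat"]) - k) == 1
        if not shifted:
            rows.append(_phase_row(row, idx, None, None, None, 0.0))
            continue
        gained = "Alt" if row["direction"] == TOWARD_ALT else "Ref"
        recipient = "Ref" if gained == "Alt" else "Alt"
        rest_alt = k - 1   # recombining pair always carries exactly one Alt
        if not (0 <= rest_alt <= p - 2):
            rows.append(_phase_row(row, idx, None, None, None, 0.0))
            continue
        rest = ",".join(["Alt"] * rest_alt + ["Ref"] * (p - 2 - rest_alt))
        rows.append(_phase_row(row, idx, recipient, gained, rest, 1.0, rest_alt))
    return pd.DataFrame(
        rows,
        columns=["marker_idx", "chrom", "pos", "k", "p",
                 "hap_recipient", "hap_donor", "n_rest_alt", "rest", "confidence"],
    )


def _phase_row(row, idx, recipient, donor, rest, conf, rest_alt=None):
    return {
        "marker_idx": idx,
        "chrom": row["chrom"], "pos": int(row["pos"]),
        "k": int(row["k"]), "p": int(row["p"]),
        "hap_recipient": recipient, "hap_donor": donor,
        "n_rest_alt": rest_alt, "rest": rest, "confidence": conf,
    }


def cross_validate_phasing(block: pd.DataFrame, other_block: pd.DataFrame) -> tuple[float, int]:
    """Concordance of two independently phased blocks over shared markers.

    Compares the recipient-haplotype allele vector marker by marker, under
    both labelings (the recipient/donor swap is unidentifiable), and
    returns the better agreement plus the number of comparable markers.
    Symmetric in its arguments. Raises when the blocks share no confidently
    phased marker.
    """
    a = block[block["confidence"] > 0].set_index("marker_idx")
    b = other_block[other_block["confidence"] > 0].set_index("marker_idx")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("phased blocks do not overlap on any confident marker")
    va = a.loc[shared, "hap_recipient"].to_numpy()
    vb = b.loc[shared, "hap_recipient"].to_numpy()
    direct = float((va == vb).mean())
    return max(direct, 1.0 - direct), int(len(shared))
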