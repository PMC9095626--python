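"""Heterozygous marker catalogue: the coordinate spine of the pipeline.

The catalogue lists every reliable heterozygous position of the polyploid
parent (chrom, pos, ref, alt, Alt-dosage k of ploidy p). Sample VCFs are
joined onto it by exact (chrom, pos, ref, alt) identity; a parental marker
absent from a sample's VCF is treated as having reached a homozygous
reference genotype if the position was sequenced (depth evidence from the
sample's depth track), and as missing otherwise. The same catalogue drives
the 50 kbp window scan for pre-existing LOH in the parents.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATALOG_COLUMNS = ["chrom", "pos", "ref", "alt", "k", "p"]

STATUS_HET = "genotyped_het"
STATUS_HOMREF = "hom_ref_candidate"
STATUS_MISSING = "missing"


@dataclass
class MarkerCatalog:
    """Ordered heterozygous markers plus the per-chromosome ploidy table."""

    df: pd.DataFrame                       # chrom, pos, ref, alt, k, p (+ af)
    ploidy: dict[str, int]
    chrom_lengths: dict[str, int] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        if (df["k"] <= 0).any() or (df["k"] >= df["p"]).any():
            raise ValueError("catalogue markers must be heterozygous (0 < k < p)")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("catalogue positions must be unique per chromosome")
        if "af" not in df.columns:
            df["af"] = df["k"] / df["p"]
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def to_tsv(self, path) -> None:
        self.df[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ploidy: dict[str, int], chrom_lengths=None) -> "MarkerCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        return cls(df[CATALOG_COLUMNS], ploidy, chrom_lengths, {"source": str(path)})

    @classmethod
    def from_parent(cls, parent) -> "MarkerCatalog":
        """Truth catalogue straight from a simulated :class:`ParentGenome`."""
        spec = parent.spec
        return cls(
            parent.marker_frame()[CATALOG_COLUMNS],
            ploidy=dict(zip(spec.chrom_names, spec.ploidy)),
            chrom_lengths=dict(zip(spec.chrom_names, spec.chrom_lengths)),
            provenance={"source": "simulate_parent", "seed": spec.seed},
        )


def read_ploidy_table(path) -> tuple[dict[str, int], dict[str, int] | None]:
    """TSV with columns chrom, ploidy and optionally length."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ploidy = dict(zip(df["chrom"], df["ploidy"].astype(int)))
    lengths = dict(zip(df["chrom"], df["length"].astype(int))) if "length" in df else None
    return ploidy, lengths


def load_parent_markers(
    parent_vcf,
    ploidy: dict[str, int],
    min_qual: float = 20.0,
    min_depth: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[MarkerCatalog, dict[str, int]]:
    """Build the marker catalogue from a parental VCF.

    Retains single-nucleotide biallelic records with QUAL > ``min_qual``,
    DP > ``min_depth`` (both strict, matching the upstream bcftools filter
    ``QUAL > 20, DP > 10``) and a heterozygous genotype (0 < Alt dosage < p
    at the contig's ploidy). Returns the catalogue and a QC dict counting
    records dropped per filter.
    """
    import pysam

    qc = {"non_snp": 0, "multiallelic": 0, "low_qual": 0, "low_depth": 0,
          "not_het": 0, "kept": 0}
    rows = []
    with pysam.VariantFile(str(parent_vcf)) as vf:
        sample = list(vf.header.samples)[0]
        if chrom_lengths is None:
            chrom_lengths = {
                c: vf.header.contigs[c].length
                for c in vf.header.contigs
                if vf.header.contigs[c].length
            } or None
        for rec in vf:
            if rec.chrom not in ploidy:
                raise ValueError(f"contig {rec.chrom!r} missing from the ploidy table")
            p = ploidy[rec.chrom]
            alts = rec.alts or ()
            if len(alts) > 1:
                qc["multiallelic"] += 1
                continue
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                qc["non_snp"] += 1
                continue
            if rec.qual is None or not rec.qual > min_qual:
                qc["low_qual"] += 1
                continue
            fmt = rec.samples[sample]
            dp = fmt.get("DP")
            if dp is None and fmt.get("AD") is not None:
                dp = int(sum(x for x in fmt["AD"] if x is not None))
            if dp is None or not dp > min_depth:
                qc["low_depth"] += 1
                continue
            gt = fmt.get("GT") or ()
            k = sum(1 for a in gt if a not in (None, 0))
            if not (0 < k < p):
                qc["not_het"] += 1
                continue
            qc["kept"] += 1
            rows.append((rec.chrom, rec.pos, rec.ref, alts[0], k, p))
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    cat = MarkerCatalog(
        df, ploidy, chrom_lengths,
        provenance={"source": str(parent_vcf), "min_qual": min_qual, "min_depth": min_depth},
    )
    return cat, qc


class DepthTrack:
    """Windowed depth lookup (TSV: chrom, start 0-based, end, mean_depth)."""

    def __init__(self, df: pd.DataFrame):
        self.df = df
        self._by_chrom = {
            chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["mean_depth"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=False)
        }

    @classmethod
    def from_tsv(cls, path) -> "DepthTrack":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def depth_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Window mean depth at 1-based positions (0 where uncovered)."""
        pos = np.asarray(pos)
        if chrom not in self._by_chrom:
            return np.zeros(len(pos))
        starts, ends, depth = self._by_chrom[chrom]
        idx = np.searchsorted(starts, pos - 1, side="right") - 1
        ok = (idx >= 0) & (pos - 1 < ends[np.clip(idx, 0, len(ends) - 1)])
        out = np.zeros(len(pos))
        out[ok] = depth[idx[ok]]
        return out


def join_sample(
    catalog: MarkerCatalog,
    sample_vcf,
    depth_track: DepthTrack | None = None,
    min_depth: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join a sample VCF onto the catalogue, marker by marker.

    Each catalogue marker is matched by exact (chrom, pos, ref, alt);
    sample-only variants are ignored. Matched markers get the sample's AD
    depths and status ``genotyped_het``. Unmatched markers become
    ``hom_ref_candidate`` when the depth track shows >= ``min_depth``
    coverage at the position (AF recorded as 0), ``missing`` otherwise.
    A shared position whose alleles disagree with the catalogue is set to
    missing and counted in the QC report.

    Joining is idempotent: the output depends only on the catalogue and the
    sample files.
    """
    import pysam

    found: dict[tuple[str, int], tuple[str, str, int, int, float]] = {}
    with pysam.VariantFile(str(sample_vcf)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                continue
            found[(rec.chrom, rec.pos)] = (
                rec.ref, alts[0], int(ad[0]), int(ad[1]), float(rec.qual or 0.0)
            )

    df = catalog.df.copy()
    n = len(df)
    ref_depth = np.zeros(n, dtype=int)
    alt_depth = np.zeros(n, dtype=int)
    qual = np.zeros(n)
    status = np.full(n, STATUS_MISSING, dtype=object)
    qc = {"matched": 0, "allele_mismatch": 0, "hom_ref_candidate": 0, "missing": 0}

    mismatch = np.zeros(n, dtype=bool)
    keys = list(zip(df["chrom"], df["pos"]))
    for i, key in enumerate(keys):
        hit = found.get(key)
        if hit is not None:
            ref, alt, rd, ad, q = hit
            if ref != df["ref"].iat[i] or alt != df["alt"].iat[i]:
                qc["allele_mismatch"] += 1
                mismatch[i] = True   # stays missing: the observed allele is
                continue             # not the catalogued ancestral one
            ref_depth[i], alt_depth[i], qual[i] = rd, ad, q
            status[i] = STATUS_HET
            qc["matched"] += 1
    absent = (status == STATUS_MISSING) & ~mismatch
    if depth_track is not None and absent.any():
        for chrom, g in df[absent].groupby("chrom", sort=False):
            d = depth_track.depth_at(chrom, g["pos"].to_numpy())
            ok = d >= min_depth
            idx = g.index.to_numpy()
            status[idx[ok]] = STATUS_HOMREF
            ref_depth[idx[ok]] = np.round(d[ok]).astype(int)
    qc["hom_ref_candidate"] = int((status == STATUS_HOMREF).sum())
    qc["missing"] = int((status == STATUS_MISSING).sum())

    df["ref_depth"] = ref_depth
    df["alt_depth"] = alt_depth
    df["total_depth"] = ref_depth + alt_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        df["af"] = np.where(df["total_depth"] > 0, alt_depth / df["total_depth"], np.nan)
    df.loc[status == STATUS_HOMREF, "af"] = 0.0
    df["status"] = status
    df["qual"] = qual
    return df, qc


def find_preexisting_loh(
    catalog: MarkerCatalog,
    window: int = 50_000,
    max_het: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Scan non-overlapping windows for pre-existing LOH in the parent.

    Chromosomes are tiled into fixed ``window`` bp windows starting at
    position 1; a window with ``max_het`` or fewer heterozygous catalogue
    markers is reported as a pre-existing LOH region. The trailing partial
    window is skipped when shorter than half a window and otherwise judged
    pro-rata (threshold scaled by its length). Output BED-style: chrom,
    start (0-based), end, n_het.
    """
    lengths = chrom_lengths or catalog.chrom_lengths
    rows = []
    for chrom, g in catalog.df.groupby("chrom", sort=False):
        pos = g["pos"].to_numpy()
        length = (lengths or {}).get(chrom, int(pos.max()) if len(pos) else 0)
        n_full, rem = divmod(length, window)
        edges = [(i * window, (i + 1) * window, max_het) for i in range(n_full)]
        if rem >= window / 2:
            edges.append((n_full * window, length, max_het * rem / window))
        for start, end, thr in edges:
            count = int(((pos > start) & (pos <= end)).sum())
            if count <= thr:
                rows.append({"chrom": chrom, "start": start, "end": end, "n_het": count})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_het"])
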