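"""End-to-end orchestration of the AF-shift workflow.

Stage order mirrors the study's analysis: build the marker catalogue from
the parent, join every sample, call per-marker shifts and >= 9-marker
regions, then filter (recurrence within dataset -> T0 overlap ->
subtelomeres / parental CNVs / engineered loci), call CNVs and
aneuploidies from the depth tracks, and summarise the percentage of
markers in retained AF-shift regions per sample. Optionally classifies
declared mother-daughter pairs for reciprocity. A manifest records
parameters and input checksums so a run can be reproduced bit for bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import pandas as pd

from . import afshift, coverage, filters, markers, mdpairs
from .config import PipelineConfig, validate_config

log = logging.getLogger("rtgpoly")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured workflow; returns the result bundle.

    The bundle maps stage names to their tables; everything is also
    written under ``cfg['out_dir']`` as deterministic TSV/BED plus a
    ``manifest.json``.
    """
    failures = validate_config(cfg)
    if failures:
        raise StageError("validate", ValueError("; ".join(failures)))
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    t_start = time.time()
    bundle: dict = {}
    checksums = {}

    # --- catalogue -------------------------------------------------------
    stage = "markers"
    try:
        paths = cfg["paths"]
        if paths.get("catalog_tsv"):
            ploidy, lengths = (
                markers.read_ploidy_table(paths["ploidy_table"])
                if paths.get("ploidy_table")
                else ({}, None)
            )
            catalog = markers.MarkerCatalog.from_tsv(paths["catalog_tsv"], ploidy, lengths)
            checksums["catalog_tsv"] = _sha256(paths["catalog_tsv"])
        else:
            ploidy, lengths = markers.read_ploidy_table(paths["ploidy_table"])
            catalog, qc = markers.load_parent_markers(
                paths["parent_vcf"], ploidy,
                min_qual=cfg["markers"]["min_qual"],
                min_depth=cfg["markers"]["min_depth"],
                chrom_lengths=lengths,
            )
            bundle["catalog_qc"] = qc
            checksums["parent_vcf"] = _sha256(paths["parent_vcf"])
        catalog.to_tsv(os.path.join(out_dir, "catalog.tsv"))
        bundle["catalog"] = catalog
        preloh = markers.find_preexisting_loh(
            catalog, window=cfg["preloh"]["window"], max_het=cfg["preloh"]["max_het"]
        )
        preloh.to_csv(os.path.join(out_dir, "preexisting_loh.bed"),
                      sep="\t", index=False, header=False)
        bundle["preexisting_loh"] = preloh
        log.info("catalogue: %d markers", len(catalog))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- join + call per sample -----------------------------------------
    stage = "call"
    calls_by_sample: dict[str, pd.DataFrame] = {}
    regions_by_sample: dict[str, pd.DataFrame] = {}
    dataset_of: dict[str, str] = {}
    t0_ids = []
    try:
        for s in cfg["samples"]:
            sid = s["id"]
            dataset_of[sid] = s["dataset"]
            if s.get("is_t0"):
                t0_ids.append(sid)
            track = (
                markers.DepthTrack.from_tsv(s["depth_track"]) if s.get("depth_track") else None
            )
            joined, qc = markers.join_sample(
                catalog, s["vcf"], track, min_depth=cfg["afshift"]["min_depth"]
            )
            calls = afshift.classify_sample(
                joined,
                min_depth=cfg["afshift"]["min_depth"],
                guard=cfg["afshift"]["guard"],
                method=cfg["afshift"]["method"],
            )
            regions = afshift.call_regions(calls, min_run=cfg["afshift"]["min_run"])
            calls_by_sample[sid] = calls
            regions_by_sample[sid] = regions
            checksums[f"sample:{sid}"] = _sha256(s["vcf"])
            calls.to_csv(os.path.join(out_dir, f"{sid}.shifts.tsv"),
                         sep="\t", index=False, float_format="%.5f")
            log.info("%s: %d raw regions", sid, len(regions))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- filters ---------------------------------------------------------
    stage = "filter"
    try:
        fcfg = filters.FilterConfig(
            recurrence_overlap=cfg["filters"]["recurrence_overlap"],
            recurrence_samples=cfg["filters"]["recurrence_samples"],
            t0_overlap=cfg["filters"]["t0_overlap"],
            min_dataset_size=cfg["filters"]["min_dataset_size"],
            drop_fraction=cfg["filters"]["drop_fraction"],
            positional_mode=cfg["filters"]["positional_mode"],
        )
        rtg_ids = [s["id"] for s in cfg["samples"] if not s.get("is_t0")]
        rtg_regions = {sid: regions_by_sample[sid] for sid in rtg_ids}
        rtg_regions, audit_rec = filters.filter_recurrent(
            rtg_regions, dataset_of, fcfg
        )
        t0_union = (
            pd.concat([regions_by_sample[sid] for sid in t0_ids], ignore_index=True)
            if t0_ids
            else pd.DataFrame(columns=filters.BED_COLUMNS)
        )
        audits = [audit_rec]
        exclusions = []
        lengths = bundle["catalog"].chrom_lengths
        if cfg["filters"]["subtel_margin"] and lengths:
            exclusions.append(filters.subtelomere_bed(lengths, cfg["filters"]["subtel_margin"]))
        for key in ("subtelomere_bed", "cnv_bed", "engineered_bed"):
            if cfg["paths"].get(key):
                exclusions.append(filters.read_bed(cfg["paths"][key]))
        exclusion_df = (
            pd.concat(exclusions, ignore_index=True)
            if exclusions
            else pd.DataFrame(columns=filters.BED_COLUMNS)
        )
        for sid in rtg_ids:
            regs, audit_t0 = filters.filter_t0(rtg_regions[sid], t0_union, fcfg)
            regs, audit_pos = filters.apply_positional_exclusions(regs, exclusion_df, fcfg)
            rtg_regions[sid] = regs
            for a in (audit_t0, audit_pos):
                a = a.copy()
                a["sample"] = sid
                audits.append(a)
            filters.write_bed(regs, os.path.join(out_dir, f"{sid}.regions.bed"))
        audit = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
        audit.to_csv(os.path.join(out_dir, "filter_audit.tsv"), sep="\t", index=False)
        bundle["regions"] = rtg_regions
        bundle["filter_audit"] = audit
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- coverage --------------------------------------------------------
    stage = "cnv"
    try:
        cnv_calls, aneuploidies = {}, {}
        ploidy = bundle["catalog"].ploidy
        for s in cfg["samples"]:
            if not s.get("depth_track"):
                continue
            track = pd.read_csv(s["depth_track"], sep="\t", dtype={"chrom": str})
            cnv_calls[s["id"]] = coverage.call_cnv_two_scale(
                track, ploidy,
                large_window=cfg["cnv"]["large_window"],
                small_window=cfg["cnv"]["small_window"],
                ratio_thresholds=(cfg["cnv"]["ratio_low"], cfg["cnv"]["ratio_high"]),
                min_windows=cfg["cnv"]["min_windows"],
            )
            if track["chrom"].nunique() >= 2:
                aneuploidies[s["id"]] = coverage.flag_aneuploidy(
                    track, ploidy, window=cfg["cnv"]["large_window"]
                )
        if cnv_calls:
            pd.concat(cnv_calls, names=["sample"]).to_csv(
                os.path.join(out_dir, "cnv_calls.tsv"), sep="\t", float_format="%.4f"
            )
        bundle["cnv"] = cnv_calls
        bundle["aneuploidy"] = aneuploidies
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- summaries -------------------------------------------------------
    stage = "summary"
    try:
        rows = []
        for sid in [s["id"] for s in cfg["samples"] if not s.get("is_t0")]:
            pct = afshift.percent_shifted_markers(
                bundle["regions"][sid],
                bundle["catalog"].df,
                exclude_chroms=tuple(cfg["filters"]["exclude_chroms"]),
                subtel_margin=cfg["filters"]["subtel_margin"],
                chrom_lengths=bundle["catalog"].chrom_lengths,
            )
            rows.append({"sample": sid, "dataset": dataset_of[sid],
                         "n_regions": len(bundle["regions"][sid]),
                         "pct_markers_shifted": pct})
        summary = pd.DataFrame(rows)
        summary.to_csv(os.path.join(out_dir, "summary.tsv"),
                       sep="\t", index=False, float_format="%.4f")
        bundle["summary"] = summary

        # declared mother-daughter pairs
        pair_rows = []
        by_id = {s["id"]: s for s in cfg["samples"]}
        for s in cfg["samples"]:
            mate = s.get("mate")
            if not mate or mate not in by_id or s["id"] > mate:
                continue
            pair = mdpairs.MDPair(
                s["id"], mate,
                calls_by_sample[s["id"]], calls_by_sample[mate],
                bundle["regions"].get(s["id"], regions_by_sample[s["id"]]),
                bundle["regions"].get(mate, regions_by_sample[mate]),
            )
            rec = mdpairs.classify_reciprocity(
                pair,
                agreement_threshold=cfg["mdpairs"]["agreement_threshold"],
                overlap_fraction=cfg["mdpairs"]["overlap_fraction"],
            )
            rec.insert(0, "pair", f"{s['id']}-{mate}")
            pair_rows.append(rec)
        if pair_rows:
            rec_all = pd.concat(pair_rows, ignore_index=True)
            rec_all.to_csv(os.path.join(out_dir, "reciprocity.tsv"),
                           sep="\t", index=False, float_format="%.4f")
            bundle["reciprocity"] = rec_all
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "config": cfg.data,
        "input_checksums": checksums,
        "n_markers": len(bundle["catalog"]),
        "elapsed_s": round(time.time() - t_start, 3),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle
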