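"""Pipeline configuration: one flat YAML file, validated up front.

Keys are namespaced per stage (``markers.min_qual``, ``afshift.min_run``,
``filters.t0_overlap``, ...) with the defaults documented on the stage
functions; CLI flags override file values. The same config plus the seed
reproduces a run bit for bit.
"""
from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "rtgpoly_out",
    "paths": {
        "parent_vcf": None,
        "ploidy_table": None,
        "catalog_tsv": None,          # alternative to parent_vcf
        "subtelomere_bed": None,
        "cnv_bed": None,
        "engineered_bed": None,
    },
    "samples": [],                    # {id, vcf, depth_track, dataset, is_t0, mate}
    "markers": {"min_qual": 20.0, "min_depth": 10},
    "preloh": {"window": 50_000, "max_het": 10},
    "afshift": {"min_depth": 10, "min_run": 9, "guard": None, "method": "dosage"},
    "filters": {
        "recurrence_overlap": 0.8,
        "recurrence_samples": 0.7,
        "t0_overlap": 0.9,
        "min_dataset_size": 3,
        "drop_fraction": 0.5,
        "positional_mode": "auto",
        "subtel_margin": 25_000,
        "exclude_chroms": [],
    },
    "cnv": {
        "large_window": 10_000,
        "small_window": 1_000,
        "ratio_low": 0.8,
        "ratio_high": 1.2,
        "min_windows": 3,
    },
    "mdpairs": {"agreement_threshold": 0.8, "overlap_fraction": 0.5},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(_deep_update(DEFAULTS, user))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(_deep_update(DEFAULTS, d))

    def __getitem__(self, key):
        return self.data[key]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Check invariants; returns a list of human-readable failures (empty = valid)."""
    failures: list[str] = []
    d = cfg.data
    paths = d["paths"]
    if not paths.get("parent_vcf") and not paths.get("catalog_tsv"):
        failures.append("paths: one of parent_vcf or catalog_tsv is required")
    for key, value in paths.items():
        if value and not os.path.exists(value):
            failures.append(f"paths.{key}: {value} does not exist")
    if not paths.get("ploidy_table") and not paths.get("catalog_tsv"):
        failures.append("paths.ploidy_table is required when building from a VCF")
    seen = set()
    for i, s in enumerate(d["samples"]):
        sid = s.get("id")
        if not sid:
            failures.append(f"samples[{i}]: missing id")
        elif sid in seen:
            failures.append(f"samples[{i}]: duplicate id {sid!r}")
        seen.add(sid)
        if not s.get("dataset"):
            failures.append(f"samples[{i}] ({sid}): missing dataset label")
        for key in ("vcf", "depth_track"):
            if s.get(key) and not os.path.exists(s[key]):
                failures.append(f"samples[{i}] ({sid}): {key} {s[key]} does not exist")
        if not s.get("vcf"):
            failures.append(f"samples[{i}] ({sid}): missing vcf")
    f = d["filters"]
    for key in ("recurrence_overlap", "recurrence_samples", "t0_overlap"):
        if not (0 < f[key] <= 1):
            failures.append(f"filters.{key}: {f[key]} not in (0, 1]")
    if d["afshift"]["min_run"] < 1:
        failures.append("afshift.min_run must be >= 1")
    if d["cnv"]["ratio_low"] >= d["cnv"]["ratio_high"]:
        failures.append("cnv.ratio_low must be below cnv.ratio_high")
    return failures
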