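"""End-to-end orchestration: biometry (synthetic or from file) to metric tables.

``run_pipeline`` builds every eye for both epochs, applies the epoch
focusing rule per pupil, evaluates the metric grid, and writes tidy CSV
reports, group summaries and a machine-readable run manifest.  All
randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    cohort_from_jsonl,
    cohort_to_jsonl,
    group_summary,
    sample_cohort,
)
from .eye import BiometryRecord, RGB_WAVELENGTHS, build_eye
from .metrics import evaluate_eye

log = logging.getLogger("ocusim")

__all__ = ["RunConfig", "run_pipeline", "validate_biometry", "ValidationReport"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults match the evaluated study grid."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_path: Optional[str] = None  # JSONL cohort overrides the generator
    fields: Sequence[float] = (0.0, 10.0, 20.0, 30.0)
    pupils: Sequence[float] = (2.0, 4.0, 6.0)
    wavelengths: Sequence[float] = RGB_WAVELENGTHS
    psf_grid: int = 36
    spot_rings: int = 6
    out_dir: str = "ocusim_out"
    log_level: str = "INFO"
    limit: Optional[int] = None  # evaluate only the first N eyes

    def __post_init__(self) -> None:
        for name in ("fields", "pupils", "wavelengths"):
            if not len(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")

    def as_dict(self) -> dict:
        return {
            "cohort": self.cohort.as_dict(),
            "input_path": self.input_path,
            "fields": list(self.fields),
            "pupils": list(self.pupils),
            "wavelengths": list(self.wavelengths),
            "psf_grid": self.psf_grid,
            "spot_rings": self.spot_rings,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "limit": self.limit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = CohortConfig.from_dict(d.get("cohort", {})) if "cohort" in d \
            else CohortConfig()
        kw = {k: v for k, v in d.items() if k != "cohort"}
        if "fields" in kw:
            kw["fields"] = tuple(kw["fields"])
        if "pupils" in kw:
            kw["pupils"] = tuple(kw["pupils"])
        if "wavelengths" in kw:
            kw["wavelengths"] = tuple(kw["wavelengths"])
        return cls(cohort=cohort, **kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of written artifact paths."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.input_path:
        records = cohort_from_jsonl(cfg.input_path)
        log.info("loaded %d cohort records from %s", len(records), cfg.input_path)
    else:
        records = sample_cohort(cfg.cohort)
        log.info("sampled %d synthetic eyes (seed %d)", len(records), cfg.cohort.seed)
    if cfg.limit is not None:
        records = records[: cfg.limit]

    cohort_path = out / "cohort.jsonl"
    cohort_to_jsonl(records, cohort_path)

    frames = []
    failures = 0
    for k, rec in enumerate(records):
        for epoch_rec in (rec.pre, rec.post):
            try:
                eye = build_eye(epoch_rec, stop_diameter=cfg.pupils[0], focus=False)
                rep = evaluate_eye(eye, fields=cfg.fields, pupils=cfg.pupils,
                                   wavelengths=cfg.wavelengths,
                                   psf_grid=cfg.psf_grid, spot_rings=cfg.spot_rings,
                                   refocus=True)
                frames.append(rep.df)
            except Exception as err:
                failures += 1
                log.error("eye %s/%s failed: %s", rec.id, epoch_rec.epoch, err)
        if (k + 1) % 10 == 0:
            log.info("evaluated %d/%d eyes (%.1f s elapsed)", k + 1, len(records),
                     time.time() - t0)
    if not frames:
        raise RuntimeError("all eyes failed to evaluate")
    df = pd.concat(frames, ignore_index=True)
    report_path = out / "quality_report.csv"
    df.to_csv(report_path, index=False)

    summary = group_summary(df, records)
    summary_path = out / "group_summary.csv"
    summary.to_csv(summary_path, index=False)

    manifest = {
        "package": "ocusim",
        "version": __version__,
        "config": cfg.as_dict(),
        "n_eyes": len(records),
        "n_failures": failures,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline done in %.1f s (%d failures)", time.time() - t0, failures)
    return {
        "cohort": str(cohort_path),
        "report": str(report_path),
        "summary": str(summary_path),
        "manifest": str(manifest_path),
        "n_failures": failures,
    }


def run_from_manifest(manifest_path, out_dir: Optional[str] = None) -> dict:
    """Re-run a pipeline from its manifest (byte-identical outputs)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg = RunConfig.from_dict(manifest["config"])
    if out_dir is not None:
        cfg = replace(cfg, out_dir=out_dir)
    return run_pipeline(cfg)


@dataclass
class ValidationReport:
    violations: list  # (record index, message)
    warnings: list

    @property
    def ok(self) -> bool:
        return not self.violations


_REQUIRED = ("S", "anterior", "posterior", "CCT", "T_AC", "T_L", "T_V")


def validate_biometry(path) -> ValidationReport:
    """Schema and invariant check of a biometry JSON/JSONL file.

    Accepts a JSON list of biometry records or JSON-lines of cohort
    records; returns line-level diagnostics.  A missing Zernike block is
    filled as zero with a warning.
    """
    path = Path(path)
    text = path.read_text()
    violations: list = []
    warns: list = []
    try:
        if path.suffix == ".jsonl":
            raw = [json.loads(line) for line in text.splitlines() if line.strip()]
        else:
            raw = json.loads(text)
            if isinstance(raw, dict):
                raw = [raw]
    except json.JSONDecodeError as err:
        return ValidationReport([(0, f"parse error: {err}")], [])

    def _check_record(i: int, d: dict) -> None:
        missing = [k for k in _REQUIRED if k not in d]
        if missing:
            violations.append((i, f"missing fields: {missing}"))
            return
        for side in ("anterior", "posterior"):
            if "zernike" not in d[side]:
                warns.append((i, f"{side} Zernike terms absent; filled with zeros"))
        try:
            rec = BiometryRecord.from_dict(d)
        except Exception as err:
            violations.append((i, f"malformed record: {err}"))
            return
        for msg in rec.violations():
            violations.append((i, msg))

    for i, d in enumerate(raw):
        if "pre" in d and "post" in d:
            _check_record(i, d["pre"])
            _check_record(i, d["post"])
        else:
            _check_record(i, d)
    return ValidationReport(violations, warns)
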