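"""Per-sample orchestration, replicate aggregation and run compilation.

A run is a manifest of samples (alignment path, developmental-stage label,
replicate group, total-gene TPM) processed against one marker set.  Two
modes mirror the two ways replicate data can be combined: ``per-sample``
estimates a composition for every sample and then aggregates mean and
standard deviation per stage; ``pooled`` merges the pileups first and
estimates one composition from the combined reads (the higher-depth route
— note the two disagree when replicate depths are unbalanced, since
pooling weights replicates by their read counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolve import (
    DEFAULT_MIN_DEPTH,
    AbundancePartition,
    CompositionEstimate,
    estimate_composition,
    partition_abundance,
)
from .markers import MarkerSet
from .pileup import PileupProfile, build_pileup, merge_pileups

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """A sample's inputs are missing or inconsistent."""


@dataclass
class SampleSpec:
    """One sample in a run manifest."""

    sample_id: str
    stage_label: str
    alignment_path: str
    total_tpm: float
    group: str | None = None

    def __post_init__(self) -> None:
        if self.total_tpm < 0:
            raise ValueError(f"sample {self.sample_id}: total_tpm must be >= 0")
        if self.group is None:
            self.group = self.stage_label


@dataclass
class SampleResult:
    spec: SampleSpec
    pileup: PileupProfile
    composition: CompositionEstimate
    partition: AbundancePartition


def run_sample(
    spec: SampleSpec,
    ms: MarkerSet,
    min_depth: int = DEFAULT_MIN_DEPTH,
    out_dir: str | Path | None = None,
) -> SampleResult:
    """Pileup -> composition -> TPM partition for one sample.

    Deterministic given the inputs; module errors propagate annotated with
    the sample id.  When ``out_dir`` is given, per-sample composition and
    partition TSVs are written there.
    """
    if not Path(spec.alignment_path).exists():
        raise DataError(
            f"sample '{spec.sample_id}': alignment file not found: {spec.alignment_path}"
        )
    try:
        p = build_pileup(
            spec.alignment_path, ms.reference_name, ms.reference_length
        )
        comp = estimate_composition(ms, p, min_depth=min_depth)
        part = partition_abundance(comp, spec.total_tpm)
    except Exception as exc:
        msg = f"sample '{spec.sample_id}': {exc}"
        try:
            annotated = type(exc)(msg)
        except Exception:  # exceptions with non-string constructors
            annotated = RuntimeError(msg)
        raise annotated from exc
    result = SampleResult(spec=spec, pileup=p, composition=comp, partition=part)
    marker_depths = [e.depth for e in comp.evidence if e.passed_filter]
    logger.info(
        "sample %s: markers_used=%d markers_filtered=%d mean_marker_depth=%.1f",
        spec.sample_id,
        comp.markers_used,
        comp.markers_filtered,
        float(np.mean(marker_depths)) if marker_depths else 0.0,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        composition_table([result]).to_csv(
            out_dir / f"{spec.sample_id}.composition.tsv", sep="\t", index=False
        )
        partition_table([result]).to_csv(
            out_dir / f"{spec.sample_id}.partition.tsv", sep="\t", index=False
        )
    return result


def composition_table(results: list[SampleResult]) -> pd.DataFrame:
    """Long-format per-sample composition: sample class percent n_markers mean_depth."""
    rows = []
    for r in results:
        by_class: dict[str, list[int]] = {}
        for e in r.composition.evidence:
            if e.passed_filter:
                by_class.setdefault(e.class_label, []).append(e.depth)
        for label, pct in sorted(r.composition.per_class_percent.items()):
            depths = by_class.get(label, [])
            rows.append(
                {
                    "sample": r.spec.sample_id,
                    "stage": r.spec.stage_label,
                    "class": label,
                    "percent": None if pct is None else round(pct, 2),
                    "n_markers": len(depths),
                    "mean_depth": round(float(np.mean(depths)), 1) if depths else 0.0,
                }
            )
    return pd.DataFrame(rows)


def partition_table(results: list[SampleResult]) -> pd.DataFrame:
    """Long-format per-sample TPM partition: sample class tpm."""
    rows = []
    for r in results:
        for label, tpm in sorted(r.partition.per_class_tpm.items()):
            rows.append(
                {
                    "sample": r.spec.sample_id,
                    "stage": r.spec.stage_label,
                    "class": label,
                    "tpm": None if tpm is None else round(tpm, 3),
                }
            )
    return pd.DataFrame(rows)


def aggregate_replicates(results: list[SampleResult]) -> pd.DataFrame:
    """Mean and sample SD of percent and TPM per (group, class).

    Uses the n-1 denominator; the SD column is empty for single
    replicates, and a class missing in a sample (no marker above the depth
    filter there) is excluded from that class's n rather than counted as
    zero.
    """
    rows = []
    groups: dict[str, list[SampleResult]] = {}
    for r in results:
        groups.setdefault(r.spec.group or r.spec.stage_label, []).append(r)
    for group in sorted(groups):
        members = groups[group]
        stage = members[0].spec.stage_label
        labels = sorted(
            {c for m in members for c in m.composition.per_class_percent}
        )
        for label in labels:
            pcts = [
                m.composition.per_class_percent[label]
                for m in members
                if m.composition.per_class_percent.get(label) is not None
            ]
            tpms = [
                m.partition.per_class_tpm[label]
                for m in members
                if m.partition.per_class_tpm.get(label) is not None
            ]
            n = len(pcts)
            rows.append(
                {
                    "stage_label": stage,
                    "class_label": label,
                    "mean_percent": float(np.mean(pcts)) if pcts else None,
                    "sd_percent": float(np.std(pcts, ddof=1)) if n >= 2 else None,
                    "mean_tpm": float(np.mean(tpms)) if tpms else None,
                    "sd_tpm": float(np.std(tpms, ddof=1)) if len(tpms) >= 2 else None,
                    "n_replicates": n,
                }
            )
    return pd.DataFrame(rows)


def compile_run(
    specs: list[SampleSpec],
    ms: MarkerSet,
    mode: str = "per-sample",
    min_depth: int = DEFAULT_MIN_DEPTH,
    out_dir: str | Path | None = None,
) -> dict:
    """Process a whole manifest in per-sample or pooled mode.

    per-sample: estimate each sample independently, then aggregate mean/SD
    per replicate group.  pooled: merge all pileups, estimate a single
    composition from the combined reads, and apply it to each sample's own
    total TPM (so pooled-of-one equals per-sample-of-one).
    """
    if mode not in ("per-sample", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    results: list[SampleResult] = []
    report: dict = {"mode": mode, "min_depth": min_depth, "samples": []}

    if mode == "per-sample":
        for spec in specs:
            results.append(run_sample(spec, ms, min_depth=min_depth))
    else:
        pileups: list[tuple[SampleSpec, PileupProfile]] = []
        for spec in specs:
            if not Path(spec.alignment_path).exists():
                raise DataError(
                    f"sample '{spec.sample_id}': alignment file not found: "
                    f"{spec.alignment_path}"
                )
            pileups.append(
                (spec, build_pileup(spec.alignment_path, ms.reference_name,
                                    ms.reference_length))
            )
        mismatched = [
            s.sample_id
            for s, p in pileups
            if p.reference_name != ms.reference_name or p.length != ms.reference_length
        ]
        if mismatched:
            raise DataError(
                "reference mismatch across samples: " + ", ".join(mismatched)
            )
        merged = merge_pileups([p for _, p in pileups])
        comp = estimate_composition(ms, merged, min_depth=min_depth)
        for spec, p in pileups:
            part = partition_abundance(comp, spec.total_tpm)
            results.append(
                SampleResult(spec=spec, pileup=p, composition=comp, partition=part)
            )
        report["pooled_mean_depth"] = float(merged.depth.mean())

    for r in results:
        report["samples"].append(
            {
                "sample_id": r.spec.sample_id,
                "stage": r.spec.stage_label,
                "markers_used": r.composition.markers_used,
                "markers_filtered": r.composition.markers_filtered,
                "total_tpm": r.spec.total_tpm,
            }
        )
    timecourse = aggregate_replicates(results)

    out = {
        "results": results,
        "composition": composition_table(results),
        "partition": partition_table(results),
        "timecourse": timecourse,
        "report": report,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out["composition"].to_csv(out_dir / "composition.tsv", sep="\t", index=False)
        out["partition"].to_csv(out_dir / "partition.tsv", sep="\t", index=False)
        timecourse.to_csv(out_dir / "timecourse.tsv", sep="\t", index=False)
        (out_dir / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return out
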