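"""Probe-exclusion cascade with per-stage attrition reporting.

Stages run in a fixed order (detection-P, bead-count, non-CpG,
SNP/cross-reactive, sex chromosomes); a probe failing several rules is
attributed to the first stage that removes it, so the per-stage removed sets
partition the removed probes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .manifest_io import BetaMatrix, Manifest

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "detection_p",
    "beadcount",
    "non_cpg",
    "snp_or_crossreactive",
    "sex_chromosome",
)


@dataclass
class FilterConfig:
    detection_p_threshold: float = 0.01
    min_beads: int = 3
    beadcount_sample_frac: float = 0.05
    drop_non_cpg: bool = True
    drop_snp_crossreactive: bool = True
    drop_sex_chromosomes: bool = True


@dataclass
class FilterReport:
    """Per-stage attrition bookkeeping for one cascade run."""

    n_input: int
    per_stage: list[tuple[str, int, int]] = field(default_factory=list)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    n_retained: int = 0

    def validate(self) -> None:
        removed_total = sum(n for _, n, _ in self.per_stage)
        if self.n_input - removed_total != self.n_retained:
            raise AssertionError("filter report does not conserve probes")
        seen: set[str] = set()
        for stage, ids in self.removed_ids.items():
            s = set(ids)
            if s & seen:
                raise AssertionError(f"stage {stage} re-removes already-removed probes")
            seen |= s

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "per_stage": [
                {"stage": s, "n_removed": n, "n_remaining": r} for s, n, r in self.per_stage
            ],
            "removed_ids": {k: sorted(v) for k, v in self.removed_ids.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def filter_detection_p(bm: BetaMatrix, threshold: float = 0.01) -> set[str]:
    """Probes with detection P >= threshold (inclusive) in at least one sample."""
    if bm.detection_p is None:
        logger.warning("no detection-P matrix; detection-P stage skipped")
        return set()
    fails = np.nan_to_num(bm.detection_p, nan=1.0) >= threshold
    mask = fails.any(axis=1)
    return {bm.probe_ids[i] for i in np.flatnonzero(mask)}


def filter_beadcount(
    bm: BetaMatrix, min_beads: int = 3, sample_frac: float = 0.05
) -> set[str]:
    """Probes with < min_beads beads in at least ceil(sample_frac * n) samples.

    The sample-count threshold is at least one, so a single failing sample in
    a small cohort is enough.
    """
    if bm.beadcount is None:
        logger.warning("no bead-count matrix; bead-count stage skipped")
        return set()
    n_needed = max(1, math.ceil(sample_frac * bm.n_samples))
    low = np.nan_to_num(bm.beadcount, nan=0.0) < min_beads
    mask = low.sum(axis=1) >= n_needed
    return {bm.probe_ids[i] for i in np.flatnonzero(mask)}


def filter_flags(manifest: Manifest) -> tuple[set[str], set[str], set[str]]:
    """(non-CpG, SNP-or-cross-reactive, sex-chromosome) probe id sets."""
    non_cpg = {p.probe_id for p in manifest if not p.is_cpg}
    snp_xr = {p.probe_id for p in manifest if p.is_snp_associated or p.is_cross_reactive}
    sex = {p.probe_id for p in manifest if p.chromosome in ("X", "Y")}
    return non_cpg, snp_xr, sex


def apply_filter_cascade(
    bm: BetaMatrix, manifest: Manifest, config: FilterConfig | None = None
) -> tuple[BetaMatrix, FilterReport]:
    """Run all exclusion stages in order and return retained matrix + report."""
    config = config or FilterConfig()
    non_cpg, snp_xr, sex = filter_flags(manifest)
    stage_sets = {
        "detection_p": filter_detection_p(bm, config.detection_p_threshold),
        "beadcount": filter_beadcount(bm, config.min_beads, config.beadcount_sample_frac),
        "non_cpg": non_cpg if config.drop_non_cpg else set(),
        "snp_or_crossreactive": snp_xr if config.drop_snp_crossreactive else set(),
        "sex_chromosome": sex if config.drop_sex_chromosomes else set(),
    }
    report = FilterReport(n_input=bm.n_probes)
    removed: set[str] = set()
    present = set(bm.probe_ids)
    remaining = bm.n_probes
    for stage in STAGE_ORDER:
        hit = (stage_sets[stage] & present) - removed
        removed |= hit
        remaining -= len(hit)
        report.per_stage.append((stage, len(hit), remaining))
        report.removed_ids[stage] = sorted(hit)
    keep = [pid for pid in bm.probe_ids if pid not in removed]
    report.n_retained = len(keep)
    report.validate()
    return bm.subset_probes(keep), report
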