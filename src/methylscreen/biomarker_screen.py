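"""Three-criterion promoter biomarker screen.

The cascade narrows called DMPs to candidate genes: (1) keep (probe, gene)
mappings in promoter categories, (2) keep probes with extreme group-mean
methylation, (3) keep genes with at least ``min_dmps`` surviving probes.
Stage counts are recorded so the narrowing is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .dmp_analysis import DMPRecord
from .manifest_io import Manifest, PROMOTER_REGIONS


@dataclass(frozen=True)
class ScreenParams:
    promoter_regions: tuple[str, ...] = PROMOTER_REGIONS
    beta_lo: float = 0.3
    beta_hi: float = 0.7
    min_dmps: int = 3
    extreme_group: Literal["case", "control", "either", "both"] = "case"


@dataclass
class Candidate:
    gene: str
    dmp_ids: list[str]
    case_means: list[float]
    control_means: list[float]
    regions: list[str]


@dataclass
class ScreenReport:
    stage_counts: list[tuple[str, int, int]]  # (stage, n_dmps, n_genes)
    candidates: list[Candidate]
    params: ScreenParams

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage_counts": [
                {"stage": s, "n_dmps": d, "n_genes": g} for s, d, g in self.stage_counts
            ],
            "candidates": [
                {
                    "gene": c.gene,
                    "dmp_ids": c.dmp_ids,
                    "case_means": c.case_means,
                    "control_means": c.control_means,
                    "regions": c.regions,
                }
                for c in self.candidates
            ],
            "params": {
                "promoter_regions": list(self.params.promoter_regions),
                "beta_lo": self.params.beta_lo,
                "beta_hi": self.params.beta_hi,
                "min_dmps": self.params.min_dmps,
                "extreme_group": self.params.extreme_group,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


Pair = tuple[str, str, str]  # (probe_id, gene, region)


def promoter_filter(
    dmps: Sequence[DMPRecord],
    manifest: Manifest,
    promoter_regions: Sequence[str] = PROMOTER_REGIONS,
) -> list[Pair]:
    """(probe, gene, region) mappings of DMPs that fall in promoter categories.

    A probe survives via any one of its mappings, and may support several
    genes.
    """
    regions = set(promoter_regions)
    pairs: list[Pair] = []
    for d in dmps:
        for gene, region in manifest[d.probe_id].gene_mappings:
            if region in regions:
                pairs.append((d.probe_id, gene, region))
    return pairs


def extreme_beta_filter(
    pairs: Sequence[Pair],
    case_means: Mapping[str, float],
    control_means: Mapping[str, float] | None = None,
    beta_lo: float = 0.3,
    beta_hi: float = 0.7,
    group: Literal["case", "control", "either", "both"] = "case",
) -> list[Pair]:
    """Keep pairs whose probe shows extreme group-mean methylation.

    'Extreme' means strictly below ``beta_lo`` or strictly above ``beta_hi``.
    ``group`` selects which group mean must be extreme.
    """

    def _extreme(v: float) -> bool:
        return v < beta_lo or v > beta_hi

    out: list[Pair] = []
    for pair in pairs:
        pid = pair[0]
        c = _extreme(case_means[pid])
        if group == "case":
            keep = c
        else:
            if control_means is None:
                raise ValueError(f"group={group!r} requires control means")
            n = _extreme(control_means[pid])
            keep = {"control": n, "either": c or n, "both": c and n}[group]
        if keep:
            out.append(pair)
    return out


def min_dmp_gene_filter(pairs: Sequence[Pair], min_dmps: int = 3) -> dict[str, list[str]]:
    """Genes backed by at least ``min_dmps`` distinct surviving probes.

    Returns gene -> ordered distinct probe ids.
    """
    by_gene: dict[str, list[str]] = {}
    for pid, gene, _ in pairs:
        by_gene.setdefault(gene, [])
        if pid not in by_gene[gene]:
            by_gene[gene].append(pid)
    return {g: ids for g, ids in by_gene.items() if len(ids) >= min_dmps}


def _stage_count(pairs: Sequence[Pair]) -> tuple[int, int]:
    return len({p for p, _, _ in pairs}), len({g for _, g, _ in pairs})


def run_screen(
    dmps: Sequence[DMPRecord],
    manifest: Manifest,
    params: ScreenParams | None = None,
) -> ScreenReport:
    """Apply the three criteria in order, recording per-stage counts."""
    params = params or ScreenParams()
    case_means = {d.probe_id: d.mean_beta_case for d in dmps}
    control_means = {d.probe_id: d.mean_beta_control for d in dmps}

    input_genes = {g for d in dmps for g, _ in manifest[d.probe_id].gene_mappings}
    stages: list[tuple[str, int, int]] = [("input", len(dmps), len(input_genes))]

    pairs = promoter_filter(dmps, manifest, params.promoter_regions)
    stages.append(("promoter", *_stage_count(pairs)))

    pairs = extreme_beta_filter(
        pairs,
        case_means,
        control_means,
        beta_lo=params.beta_lo,
        beta_hi=params.beta_hi,
        group=params.extreme_group,
    )
    stages.append(("extreme_beta", *_stage_count(pairs)))

    survivors = min_dmp_gene_filter(pairs, params.min_dmps)
    region_of = {(p, g): r for p, g, r in pairs}
    candidates = []
    for gene in sorted(survivors):
        ids = survivors[gene]
        candidates.append(
            Candidate(
                gene=gene,
                dmp_ids=ids,
                case_means=[case_means[p] for p in ids],
                control_means=[control_means[p] for p in ids],
                regions=[region_of[(p, gene)] for p in ids],
            )
        )
    n_final_dmps = len({p for ids in survivors.values() for p in ids})
    stages.append(("min_dmps", n_final_dmps, len(survivors)))
    return ScreenReport(stage_counts=stages, candidates=candidates, params=params)


def candidates_to_frame(report: ScreenReport) -> pd.DataFrame:
    rows = []
    for c in report.candidates:
        for pid, cm, nm, r in zip(c.dmp_ids, c.case_means, c.control_means, c.regions):
            rows.append(
                {
                    "gene": c.gene,
                    "probe_id": pid,
                    "mean_beta_case": cm,
                    "mean_beta_control": nm,
                    "region": r,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "probe_id", "mean_beta_case", "mean_beta_control", "region"]
    )
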