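"""Synthetic 850K-like manifest and cohort generator with full truth tables.

Probe means follow a bimodal Beta mixture; per-sample values are
inverse-logit of the probe's group mean logit plus Gaussian noise, so beta
stays in (0, 1) with array-like heteroscedasticity.  Differential effects,
QC failures for every exclusion stage, and one promoter biomarker gene whose
methylation anti-correlates with expression and TSH are planted and recorded
in a :class:`PlantedTruth` so downstream stages can be scored exactly.

All special probe sets are chosen disjointly from one seeded plan, so a
QC-failing probe is never also a planted effect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .manifest_io import (
    BetaMatrix,
    ISLAND_REGIONS,
    Manifest,
    ProbeAnnotation,
    SampleSheet,
)

_PROMOTER_CHOICES = ("TSS1500", "TSS200", "1stExon")

DEFAULT_REGION_FREQS = {
    "TSS1500": 0.10,
    "TSS200": 0.08,
    "5UTR": 0.10,
    "1stExon": 0.06,
    "Body": 0.45,
    "3UTR": 0.08,
    "IGR": 0.13,
}

DEFAULT_ISLAND_FREQS = {
    "Island": 0.30,
    "N_Shore": 0.10,
    "S_Shore": 0.10,
    "N_Shelf": 0.03,
    "S_Shelf": 0.03,
    "OpenSea": 0.44,
}


@dataclass(frozen=True)
class BiomarkerSpec:
    """Planted promoter biomarker gene."""

    gene: str = "MKGENE1"
    k: int = 5
    control_mean: float = 0.80
    case_mean: float = 0.10
    expression_r: float = -0.80
    case_expression_mean: float = 3.88
    tsh_coupling: float = 5.0  # log-TSH decrease per unit composite beta

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("biomarker needs k >= 3 probes")
        lo, hi = sorted((self.case_mean, self.control_mean))
        if not (lo < 0.3 and hi > 0.7):
            raise ValueError("biomarker group means must sit on opposite extremes")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 17
    n_probes: int = 1000
    n_per_group: int = 10
    # bimodal Beta mixture for probe base means
    mixture_weight_high: float = 0.55
    mode_low: tuple[float, float] = (2.0, 8.0)
    mode_high: tuple[float, float] = (8.0, 2.0)
    noise_sd_logit: float = 0.5
    # planted differential effects
    n_planted_dmps: int = 60
    planted_delta_beta: float = 0.2
    planted_base_range: tuple[float, float] = (0.35, 0.45)
    # planted QC failures, one count per exclusion stage
    n_fail_detection_p: int = 7
    n_fail_beadcount: int = 5
    n_non_cpg: int = 3
    n_snp: int = 2
    n_cross_reactive: int = 2
    n_sex_chromosome: int = 6
    biomarker: BiomarkerSpec | None = field(default_factory=BiomarkerSpec)
    region_freqs: dict = field(default_factory=lambda: dict(DEFAULT_REGION_FREQS))
    island_freqs: dict = field(default_factory=lambda: dict(DEFAULT_ISLAND_FREQS))
    # phenotype anchors; TSH/FT3/FT4 reference ranges 0.27-4.2 mIU/L,
    # 3.1-6.8 pmol/L, 11.5-22.7 pmol/L
    control_tsh_log_mean: float = 0.69
    ft4_intercept: float = 11.0
    ft4_slope: float = 6.5

    def __post_init__(self) -> None:
        for name, freqs in (("region", self.region_freqs), ("island", self.island_freqs)):
            s = sum(freqs.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} frequencies sum to {s}, not 1")
        n_special = (
            self.n_planted_dmps
            + self.n_fail_detection_p
            + self.n_fail_beadcount
            + self.n_non_cpg
            + self.n_snp
            + self.n_cross_reactive
            + self.n_sex_chromosome
            + (self.biomarker.k if self.biomarker else 0)
        )
        if n_special > self.n_probes:
            raise ValueError("more planted special probes than probes")
        lo, hi = self.planted_base_range
        if not (0 < lo <= hi < 1) or hi + self.planted_delta_beta >= 1:
            raise ValueError("infeasible planted delta-beta target")


@dataclass
class PlantedTruth:
    """Generator bookkeeping for recovery testing."""

    true_dmp_delta: dict[str, float]  # probe -> signed planted delta beta
    qc_fail_ids: dict[str, list[str]]  # stage -> probe ids
    biomarker_gene: str | None
    biomarker_probe_ids: list[str]
    expression: dict[str, float]  # sample -> latent relative expression
    composite_beta: dict[str, float]  # sample -> latent biomarker composite

    @property
    def true_dmp_ids(self) -> set[str]:
        return set(self.true_dmp_delta)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_dmp_delta": self.true_dmp_delta,
                    "qc_fail_ids": self.qc_fail_ids,
                    "biomarker_gene": self.biomarker_gene,
                    "biomarker_probe_ids": self.biomarker_probe_ids,
                    "expression": self.expression,
                    "composite_beta": self.composite_beta,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass(frozen=True)
class _Plan:
    """Disjoint special-probe index sets, a pure function of the config."""

    sex: np.ndarray
    non_cpg: np.ndarray
    snp: np.ndarray
    cross_reactive: np.ndarray
    fail_detp: np.ndarray
    fail_beads: np.ndarray
    planted_dmps: np.ndarray
    biomarker: np.ndarray


def _plan(config: SimConfig) -> _Plan:
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(config.n_probes)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor : cursor + n]
        cursor += n
        return np.sort(out)

    return _Plan(
        sex=take(config.n_sex_chromosome),
        non_cpg=take(config.n_non_cpg),
        snp=take(config.n_snp),
        cross_reactive=take(config.n_cross_reactive),
        fail_detp=take(config.n_fail_detection_p),
        fail_beads=take(config.n_fail_beadcount),
        planted_dmps=take(config.n_planted_dmps),
        biomarker=take(config.biomarker.k if config.biomarker else 0),
    )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_manifest(config: SimConfig) -> Manifest:
    """Deterministic synthetic probe manifest for the given config."""
    rng = np.random.default_rng(config.seed + 1000)
    plan = _plan(config)
    n = config.n_probes
    sex_set = set(plan.sex.tolist())
    noncpg_set = set(plan.non_cpg.tolist())
    snp_set = set(plan.snp.tolist())
    xr_set = set(plan.cross_reactive.tolist())
    bmk_set = set(plan.biomarker.tolist())

    region_cats = list(config.region_freqs)
    region_p = np.array([config.region_freqs[c] for c in region_cats])
    island_cats = list(config.island_freqs)
    island_p = np.array([config.island_freqs[c] for c in island_cats])

    chrom_draw = rng.integers(1, 23, size=n)
    pos_draw = rng.integers(1, 120_000_000, size=n)
    region_draw = rng.choice(len(region_cats), size=n, p=region_p)
    island_draw = rng.choice(len(island_cats), size=n, p=island_p)
    type_draw = rng.random(size=n) < 0.85  # mostly type II, like the array
    gene_pool = max(50, n // 3)
    gene_draw = rng.integers(0, gene_pool, size=n)
    second_map = rng.random(size=n) < 0.15
    second_region = rng.choice(len(region_cats), size=n, p=region_p)
    sex_chrom = rng.random(size=n) < 0.5
    bmk_regions = rng.choice(len(_PROMOTER_CHOICES), size=n)
    bmk_chrom = int(rng.integers(1, 23))

    probes = []
    for i in range(n):
        if i in noncpg_set:
            pid = f"ch.{i:08d}"
        else:
            pid = f"cg{i:08d}"
        chrom = ("X" if sex_chrom[i] else "Y") if i in sex_set else str(chrom_draw[i])
        if i in bmk_set:
            chrom = str(bmk_chrom)
            mappings = ((config.biomarker.gene, _PROMOTER_CHOICES[bmk_regions[i]]),)
        else:
            region = region_cats[region_draw[i]]
            if region == "IGR":
                mappings = ()
            else:
                gene = f"GENE{gene_draw[i]:05d}"
                mappings = [(gene, region)]
                r2 = region_cats[second_region[i]]
                if second_map[i] and r2 != "IGR" and r2 != region:
                    mappings.append((gene, r2))
                mappings = tuple(mappings)
        probes.append(
            ProbeAnnotation(
                probe_id=pid,
                chromosome=chrom,
                position=int(pos_draw[i]),
                probe_type="II" if type_draw[i] else "I",
                gene_mappings=mappings,
                island_region=island_cats[island_draw[i]],
                is_cpg=i not in noncpg_set,
                is_snp_associated=i in snp_set,
                is_cross_reactive=i in xr_set,
            )
        )
    return Manifest(probes)


def _draw_base_means(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    n = config.n_probes
    high = rng.random(n) < config.mixture_weight_high
    lo = rng.beta(*config.mode_low, size=n)
    hi = rng.beta(*config.mode_high, size=n)
    return np.clip(np.where(high, hi, lo), 0.01, 0.99)


def generate_cohort(
    manifest: Manifest, config: SimConfig
) -> tuple[BetaMatrix, SampleSheet, PlantedTruth]:
    """Beta matrix + QC matrices + sample sheet + truth for one cohort."""
    rng = np.random.default_rng(config.seed + 2000)
    plan = _plan(config)
    n = config.n_probes
    npg = config.n_per_group
    n_samples = 2 * npg
    probe_ids = manifest.probe_ids
    if len(probe_ids) != n:
        raise ValueError("manifest does not match config.n_probes")

    mean_control = _draw_base_means(rng, config)
    mean_case = mean_control.copy()

    # planted differential effects: half hyper, half hypo, base mean drawn
    # from the configured band so realised case means are controllable
    lo, hi = config.planted_base_range
    delta = config.planted_delta_beta
    true_dmp_delta: dict[str, float] = {}
    for j, i in enumerate(plan.planted_dmps):
        base = rng.uniform(lo, hi)
        if j % 2 == 0:  # hypermethylated in cases
            mean_control[i] = base
            mean_case[i] = base + delta
            true_dmp_delta[probe_ids[i]] = delta
        else:
            mean_control[i] = base + delta
            mean_case[i] = base
            true_dmp_delta[probe_ids[i]] = -delta

    if config.biomarker:
        for i in plan.biomarker:
            mean_control[i] = config.biomarker.control_mean
            mean_case[i] = config.biomarker.case_mean

    case_logit = _logit(mean_case)[:, None] + rng.normal(
        0, config.noise_sd_logit, size=(n, npg)
    )
    control_logit = _logit(mean_control)[:, None] + rng.normal(
        0, config.noise_sd_logit, size=(n, npg)
    )
    beta = np.hstack([_expit(case_logit), _expit(control_logit)])
    beta = np.round(np.clip(beta, 0.0, 1.0), 6)

    sample_ids = [f"HT{i + 1}" for i in range(npg)] + [f"C{i + 1}" for i in range(npg)]
    groups = ["case"] * npg + ["control"] * npg

    # detection P: clean background, planted probes fail in >= 1 sample
    detp = np.round(rng.uniform(0.0, 0.005, size=(n, n_samples)), 6)
    for i in plan.fail_detp:
        j = int(rng.integers(0, n_samples))
        detp[i, j] = np.round(rng.uniform(0.05, 0.9), 6)
    # bead counts: background >= 8, planted probes low in just enough samples
    beads = rng.integers(8, 25, size=(n, n_samples)).astype(float)
    n_bad = max(1, math.ceil(0.05 * n_samples))
    for i in plan.fail_beads:
        cols = rng.choice(n_samples, size=n_bad, replace=False)
        beads[i, cols] = rng.integers(0, 3, size=n_bad)

    bm = BetaMatrix(
        probe_ids=list(probe_ids),
        sample_ids=sample_ids,
        beta=beta,
        detection_p=detp,
        beadcount=beads,
    )

    # latent biomarker composite per sample and coupled phenotypes
    if config.biomarker and len(plan.biomarker):
        composite = beta[plan.biomarker].mean(axis=0)
    else:
        composite = np.full(n_samples, 0.5)
    spec = config.biomarker

    log_tsh = config.control_tsh_log_mean
    if spec:
        log_tsh = log_tsh + spec.tsh_coupling * (spec.control_mean - composite)
    tsh = np.exp(log_tsh + rng.normal(0, 0.25, size=n_samples))
    ft4 = config.ft4_intercept + config.ft4_slope * composite + rng.normal(
        0, 1.0, size=n_samples
    )
    ft3 = 3.4 + 1.6 * composite + rng.normal(0, 0.35, size=n_samples)
    age = np.clip(np.round(rng.normal(42, 9, size=n_samples)), 18, 70)
    bmi = np.round(rng.normal(23, 2.2, size=n_samples), 2)
    tpoab = np.where(
        np.array(groups) == "case",
        rng.uniform(80, 1300, size=n_samples),
        rng.uniform(5, 45, size=n_samples),
    )
    tgab = np.where(
        np.array(groups) == "case",
        rng.uniform(60, 900, size=n_samples),
        rng.uniform(4, 40, size=n_samples),
    )

    # expression: linear in composite methylation with level-proportional
    # noise sized so the cohort-wide correlation hits the target r
    if spec:
        slope = (1.0 - spec.case_expression_mean) / (
            spec.control_mean - spec.case_mean
        )
        intercept = 1.0 - slope * spec.control_mean
        mu = intercept + slope * composite
        r = abs(spec.expression_r)
        var_mu = float(np.var(mu))
        sigma_rel = math.sqrt(
            max(var_mu * (1.0 / r**2 - 1.0) / float(np.mean(mu**2)), 1e-9)
        )
        expression = mu * (1.0 + sigma_rel * rng.normal(size=n_samples))
        expression = np.maximum(expression, 0.05)
    else:
        expression = np.maximum(rng.normal(1.0, 0.1, size=n_samples), 0.05)

    ct_reference = np.round(rng.normal(18.0, 0.15, size=n_samples), 4)
    ct_target = np.round(ct_reference + 4.0 - np.log2(expression), 4)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "pair_id": [f"P{i % npg + 1}" for i in range(n_samples)],
                "age": age,
                "sex": ["F"] * n_samples,
                "bmi": bmi,
                "tsh": np.round(tsh, 4),
                "ft3": np.round(ft3, 4),
                "ft4": np.round(ft4, 4),
                "tpoab": np.round(tpoab, 2),
                "tgab": np.round(tgab, 2),
                "ct_target": ct_target,
                "ct_reference": ct_reference,
            }
        )
    )

    truth = PlantedTruth(
        true_dmp_delta=true_dmp_delta,
        qc_fail_ids={
            "detection_p": [probe_ids[i] for i in plan.fail_detp],
            "beadcount": [probe_ids[i] for i in plan.fail_beads],
            "non_cpg": [probe_ids[i] for i in plan.non_cpg],
            "snp_or_crossreactive": [
                probe_ids[i] for i in np.concatenate([plan.snp, plan.cross_reactive])
            ],
            "sex_chromosome": [probe_ids[i] for i in plan.sex],
        },
        biomarker_gene=spec.gene if spec else None,
        biomarker_probe_ids=[probe_ids[i] for i in plan.biomarker],
        expression={s: float(e) for s, e in zip(sample_ids, expression)},
        composite_beta={s: float(c) for s, c in zip(sample_ids, composite)},
    )
    return bm, sheet, truth


def default_paper_like_config(seed: int = 17) -> SimConfig:
    """Documented default cohort: 10 cases vs 10 controls, 1,000 probes,
    disjoint QC failures 7/5/3/4/6 per stage, 60 planted effects, and one
    5-probe promoter biomarker gene (case means ~0.15, control ~0.8) whose
    methylation anti-correlates with expression (r = -0.8) and TSH."""
    return SimConfig(seed=seed)


def recovery_config(seed: int = 17, n_probes: int = 5000, n_planted: int = 200) -> SimConfig:
    """Power-oriented config for differential-effect recovery checks: planted
    base means sit where logit noise is small on the beta scale."""
    return SimConfig(
        seed=seed,
        n_probes=n_probes,
        n_planted_dmps=n_planted,
        planted_base_range=(0.08, 0.12),
        n_fail_detection_p=0,
        n_fail_beadcount=0,
        n_non_cpg=0,
        n_snp=0,
        n_cross_reactive=0,
        n_sex_chromosome=0,
        biomarker=None,
    )


def null_config(seed: int = 17, n_probes: int = 5000) -> SimConfig:
    """No planted effects at all: for false-positive smoke tests."""
    return replace(recovery_config(seed, n_probes), n_planted_dmps=0)
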