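"""Categorisation of probes by gene region, island relation, and chromosome,
plus chi-square enrichment between probe sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .manifest_io import AUTOSOMES, GENE_REGIONS, ISLAND_REGIONS, Manifest

GENE_REGION_CATEGORIES = GENE_REGIONS + ("IGR",)


class UntestableCategoryError(ValueError):
    """Raised when a 2x2 enrichment table has a zero margin."""


@dataclass
class DistributionTable:
    categories: list[str]
    counts: list[int]
    total: int

    @property
    def percentages(self) -> list[float]:
        if self.total == 0:
            return [0.0 for _ in self.counts]
        return [100.0 * c / self.total for c in self.counts]

    def count(self, category: str) -> int:
        return self.counts[self.categories.index(category)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.categories, "count": self.counts, "percent": self.percentages}
        )


@dataclass
class EnrichmentResult:
    category: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: set A/B; cols: in/out
    chi2: float
    p: float
    direction: str  # "over" | "under"
    low_expected: bool = False
    fisher_p: float | None = None


def classify_island_region(
    position: int,
    island_start: int | None,
    island_end: int | None,
) -> str:
    """Island relation from the nearest island interval (1-based, inclusive).

    Shores are 0-2 kb from an island edge, shelves 2-4 kb; the N_/S_ prefix
    marks the lower-/higher-coordinate side of the island.  No island means
    open sea.
    """
    if island_start is None or island_end is None:
        return "OpenSea"
    if island_start > island_end:
        raise ValueError("island_start must be <= island_end")
    if island_start <= position <= island_end:
        return "Island"
    if position < island_start:
        d = island_start - position
        side = "N"
    else:
        d = position - island_end
        side = "S"
    if d <= 2000:
        return f"{side}_Shore"
    if d <= 4000:
        return f"{side}_Shelf"
    return "OpenSea"


def distribution_table(
    probe_ids: Iterable[str], manifest: Manifest, axis: str
) -> DistributionTable:
    """Category counts over a probe set.

    For gene_region each probe contributes one count to its first-listed
    mapping (IGR if unmapped), keeping the table total equal to the probe
    count.
    """
    ids = list(probe_ids)
    for pid in ids:
        if pid not in manifest:
            raise KeyError(f"probe {pid!r} not in manifest")
    if axis == "gene_region":
        categories = list(GENE_REGION_CATEGORIES)
        keys = [manifest[pid].first_region() for pid in ids]
    elif axis == "island_region":
        categories = list(ISLAND_REGIONS)
        keys = [manifest[pid].island_region for pid in ids]
    elif axis == "chromosome":
        categories = [c for c in AUTOSOMES + ("X", "Y")]
        keys = [manifest[pid].chromosome for pid in ids]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    counts = {c: 0 for c in categories}
    for k in keys:
        counts[k] += 1
    return DistributionTable(categories, [counts[c] for c in categories], len(ids))


def pearson_chi2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise UntestableCategoryError("zero margin in 2x2 table")
    num = a * d - b * c
    return n * num * num / denom


def enrichment_chisq(
    set_a_table: DistributionTable,
    set_b_table: DistributionTable,
    category: str,
) -> EnrichmentResult:
    """Chi-square enrichment of one category between two probe sets.

    Builds the 2x2 table (in/out of category x set A/set B) and applies the
    Pearson statistic without continuity correction.  Expected counts below 5
    set ``low_expected`` and attach a Fisher exact p as a fallback.
    """
    if set_a_table.categories != set_b_table.categories:
        raise ValueError("tables do not share a category axis")
    a_in = set_a_table.count(category)
    b_in = set_b_table.count(category)
    a_out = set_a_table.total - a_in
    b_out = set_b_table.total - b_in
    chi2 = pearson_chi2(a_in, a_out, b_in, b_out)
    p = float(stats.chi2.sf(chi2, df=1))
    prop_a = a_in / set_a_table.total
    prop_b = b_in / set_b_table.total
    direction = "over" if prop_a > prop_b else "under"
    n = a_in + a_out + b_in + b_out
    expected = np.outer(
        [a_in + a_out, b_in + b_out], [a_in + b_in, a_out + b_out]
    ) / n
    low = bool((expected < 5).any())
    fisher_p = None
    if low:
        warnings.warn(
            f"expected count < 5 for category {category!r}; "
            "chi-square approximation unreliable, Fisher p attached",
            stacklevel=2,
        )
        fisher_p = float(stats.fisher_exact([[a_in, a_out], [b_in, b_out]])[1])
    return EnrichmentResult(
        category=category,
        table=((a_in, a_out), (b_in, b_out)),
        chi2=float(chi2),
        p=p,
        direction=direction,
        low_expected=low,
        fisher_p=fisher_p,
    )


def enrichment_scan(
    set_a_table: DistributionTable, set_b_table: DistributionTable
) -> list[EnrichmentResult]:
    """Enrichment for every testable category on the shared axis."""
    out = []
    for cat in set_a_table.categories:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out.append(enrichment_chisq(set_a_table, set_b_table, cat))
        except UntestableCategoryError:
            continue
    return out


def chromosome_tally(dmps, manifest: Manifest) -> pd.DataFrame:
    """Per-chromosome DMP counts, hyper/hypo split, and unique mapped genes."""
    rows: dict[str, dict] = {}
    genes: dict[str, set[str]] = {}
    for d in dmps:
        p = manifest[d.probe_id]
        c = p.chromosome
        if c not in rows:
            rows[c] = {"chromosome": c, "n_dmps": 0, "n_hyper": 0, "n_hypo": 0}
            genes[c] = set()
        rows[c]["n_dmps"] += 1
        if d.direction == "hyper":
            rows[c]["n_hyper"] += 1
        else:
            rows[c]["n_hypo"] += 1
        genes[c].update(g for g, _ in p.gene_mappings)
    for c in rows:
        rows[c]["n_unique_genes"] = len(genes[c])

    def _key(c: str) -> tuple[int, str]:
        return (int(c), "") if c.isdigit() else (100, c)

    ordered = [rows[c] for c in sorted(rows, key=_key)]
    return pd.DataFrame(
        ordered, columns=["chromosome", "n_dmps", "n_hyper", "n_hypo", "n_unique_genes"]
    )
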