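"""Reading/writing of probe manifests, beta matrices, sample sheets and BED export.

The manifest dialect follows the common array-annotation convention: gene
symbols and gene regions are parallel semicolon-delimited lists.  A
pre-exploded long format (one row per gene mapping, probe_id repeated) is
accepted as well.  Positions are 1-based single-base coordinates; BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
ISLAND_REGIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
PROMOTER_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon")
AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y")

#: normalisation map for gene-region spellings seen in the wild
_REGION_ALIASES = {
    "TSS1500": "TSS1500",
    "TSS200": "TSS200",
    "5UTR": "5UTR",
    "5'UTR": "5UTR",
    "1STEXON": "1stExon",
    "1STEXON;": "1stExon",
    "FIRSTEXON": "1stExon",
    "BODY": "Body",
    "GENEBODY": "Body",
    "3UTR": "3UTR",
    "3'UTR": "3UTR",
}

_ISLAND_ALIASES = {
    "ISLAND": "Island",
    "CPGISLAND": "Island",
    "N_SHORE": "N_Shore",
    "NORTHSHORE": "N_Shore",
    "S_SHORE": "S_Shore",
    "SOUTHSHORE": "S_Shore",
    "N_SHELF": "N_Shelf",
    "NORTHSHELF": "N_Shelf",
    "S_SHELF": "S_Shelf",
    "SOUTHSHELF": "S_Shelf",
    "OPENSEA": "OpenSea",
    "": "OpenSea",
}

MANIFEST_COLUMNS = (
    "probe_id",
    "chr",
    "pos",
    "type",
    "gene",
    "gene_region",
    "island_region",
    "is_cpg",
    "snp",
    "cross_reactive",
)


class ManifestFormatError(ValueError):
    """Raised when a manifest file violates the expected dialect."""


class BetaValidationError(ValueError):
    """Raised when beta/detection-P values fall outside their valid range."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """One array probe's genomic and functional context."""

    probe_id: str
    chromosome: str
    position: int
    probe_type: str  # "I" or "II"
    gene_mappings: tuple[tuple[str, str], ...]  # ordered (gene, region); empty == IGR
    island_region: str
    is_cpg: bool = True
    is_snp_associated: bool = False
    is_cross_reactive: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.probe_id}: position must be >= 1")

    @property
    def is_igr(self) -> bool:
        return len(self.gene_mappings) == 0

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.gene_mappings)

    def first_region(self) -> str:
        """Gene-region category for one-count-per-probe tallies (IGR if unmapped)."""
        return self.gene_mappings[0][1] if self.gene_mappings else "IGR"


class Manifest:
    """Ordered collection of :class:`ProbeAnnotation`, indexed by probe id."""

    def __init__(self, probes: Iterable[ProbeAnnotation]):
        self._probes: dict[str, ProbeAnnotation] = {}
        for p in probes:
            if p.probe_id in self._probes:
                raise ManifestFormatError(f"duplicate probe_id {p.probe_id!r}")
            self._probes[p.probe_id] = p

    def __len__(self) -> int:
        return len(self._probes)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._probes

    def __getitem__(self, probe_id: str) -> ProbeAnnotation:
        return self._probes[probe_id]

    def __iter__(self):
        return iter(self._probes.values())

    @property
    def probe_ids(self) -> list[str]:
        return list(self._probes)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with optional QC matrices."""

    probe_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray
    detection_p: np.ndarray | None = None
    beadcount: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("beta shape does not match probe/sample ids")
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise BetaValidationError("beta values outside [0, 1]")
        for name in ("detection_p", "beadcount"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != self.beta.shape:
                    raise ValueError(f"{name} shape does not match beta")
                setattr(self, name, m)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        return {pid: i for i, pid in enumerate(self.probe_ids)}

    def subset_probes(self, keep_ids: Sequence[str]) -> "BetaMatrix":
        idx = self.probe_index()
        rows = [idx[p] for p in keep_ids]
        return BetaMatrix(
            probe_ids=list(keep_ids),
            sample_ids=list(self.sample_ids),
            beta=self.beta[rows],
            detection_p=None if self.detection_p is None else self.detection_p[rows],
            beadcount=None if self.beadcount is None else self.beadcount[rows],
        )


@dataclass
class SampleSheet:
    """Per-sample group labels and clinical covariates."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "group")
    NUMERIC = ("age", "bmi", "tsh", "ft3", "ft4", "tpoab", "tgab", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ManifestFormatError(f"sample sheet missing required column {col!r}")
        groups = set(self.df["group"].unique())
        if not groups <= {"case", "control"}:
            raise ManifestFormatError(f"unexpected group labels: {sorted(groups)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def group_mask(self, group: str) -> np.ndarray:
        return (self.df["group"] == group).to_numpy()

    def require_two_groups(self, min_per_group: int = 2) -> None:
        for g in ("case", "control"):
            n = int(self.group_mask(g).sum())
            if n < min_per_group:
                raise ValueError(f"group {g!r} has {n} samples; need >= {min_per_group}")


# ---------------------------------------------------------------------------
# parsing helpers


def _norm_region(token: str, probe_id: str) -> str:
    key = token.strip().upper().replace(" ", "")
    if key in _REGION_ALIASES:
        return _REGION_ALIASES[key]
    raise ManifestFormatError(f"unparseable gene region {token!r} for probe {probe_id!r}")


def _norm_island(token: str, probe_id: str) -> str:
    key = str(token).strip().upper().replace(" ", "").replace("-", "_")
    if key in ("NAN", "NONE"):
        key = ""
    if key in _ISLAND_ALIASES:
        return _ISLAND_ALIASES[key]
    raise ManifestFormatError(f"unparseable island region {token!r} for probe {probe_id!r}")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no", "", "nan"):
        return False
    raise ManifestFormatError(f"unparseable boolean flag {v!r}")


def _parse_mappings(gene_field, region_field, probe_id: str) -> tuple[tuple[str, str], ...]:
    gene_s = "" if pd.isna(gene_field) else str(gene_field).strip()
    region_s = "" if pd.isna(region_field) else str(region_field).strip()
    if not gene_s:
        return ()
    genes = gene_s.split(";")
    regions = region_s.split(";") if region_s else []
    if len(genes) != len(regions):
        raise ManifestFormatError(
            f"probe {probe_id!r}: gene list ({len(genes)}) and region list "
            f"({len(regions)}) have different lengths"
        )
    seen: list[tuple[str, str]] = []
    for g, r in zip(genes, regions):
        pair = (g.strip(), _norm_region(r, probe_id))
        if pair not in seen:
            seen.append(pair)
    return tuple(seen)


def load_manifest(path: str | Path) -> Manifest:
    """Load a probe-annotation TSV into a :class:`Manifest`.

    Both the semicolon-delimited parallel-list dialect and a pre-exploded long
    format (repeated probe_id rows, one mapping each) are accepted.  Duplicate
    (gene, region) pairs are collapsed, order preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ManifestFormatError(f"manifest missing required column {col!r}")
    probes: list[ProbeAnnotation] = []
    order: list[str] = []
    acc: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        pid = str(row.probe_id)
        mappings = _parse_mappings(row.gene, row.gene_region, pid)
        if pid not in acc:
            order.append(pid)
            chrom = str(row.chr).removeprefix("chr")
            if chrom not in CHROMOSOMES:
                raise ManifestFormatError(f"probe {pid!r}: unknown chromosome {row.chr!r}")
            acc[pid] = dict(
                probe_id=pid,
                chromosome=chrom,
                position=int(row.pos),
                probe_type=str(row.type),
                mappings=list(mappings),
                island_region=_norm_island(row.island_region, pid),
                is_cpg=_parse_bool(row.is_cpg),
                is_snp_associated=_parse_bool(row.snp),
                is_cross_reactive=_parse_bool(row.cross_reactive),
            )
        else:  # long-format continuation row for an already-seen probe
            for pair in mappings:
                if pair not in acc[pid]["mappings"]:
                    acc[pid]["mappings"].append(pair)
    for pid in order:
        d = acc[pid]
        probes.append(
            ProbeAnnotation(
                probe_id=d["probe_id"],
                chromosome=d["chromosome"],
                position=d["position"],
                probe_type=d["probe_type"],
                gene_mappings=tuple(d["mappings"]),
                island_region=d["island_region"],
                is_cpg=d["is_cpg"],
                is_snp_associated=d["is_snp_associated"],
                is_cross_reactive=d["is_cross_reactive"],
            )
        )
    return Manifest(probes)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest TSV in the parallel-list dialect (inverse of load)."""
    rows = []
    for p in manifest:
        rows.append(
            {
                "probe_id": p.probe_id,
                "chr": p.chromosome,
                "pos": p.position,
                "type": p.probe_type,
                "gene": ";".join(g for g, _ in p.gene_mappings),
                "gene_region": ";".join(r for _, r in p.gene_mappings),
                "island_region": p.island_region,
                "is_cpg": int(p.is_cpg),
                "snp": int(p.is_snp_associated),
                "cross_reactive": int(p.is_cross_reactive),
            }
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def load_beta_matrix(
    path: str | Path,
    manifest: Manifest,
    detection_p_path: str | Path | None = None,
    beadcount_path: str | Path | None = None,
) -> BetaMatrix:
    """Load a beta matrix, restricting and ordering probes by the manifest.

    Probes absent from the manifest are dropped with a logged count; beta
    values outside [0, 1] raise :class:`BetaValidationError` identifying the
    offending probe and sample.
    """
    df = _read_matrix(path)
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(vals) & ((vals < 0) | (vals > 1)))
    if bad.size:
        i, j = bad[0]
        raise BetaValidationError(
            f"beta value {vals[i, j]} outside [0, 1] at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    in_manifest = [pid for pid in df.index if pid in manifest]
    n_dropped = len(df.index) - len(in_manifest)
    if n_dropped:
        logger.warning("dropped %d probes absent from manifest", n_dropped)
    keep = [pid for pid in manifest.probe_ids if pid in set(in_manifest)]
    df = df.loc[keep]

    def _aligned(p: str | Path | None, lo: float, hi: float | None, name: str):
        if p is None:
            return None
        m = _read_matrix(p)
        if list(m.columns) != list(df.columns):
            raise ManifestFormatError(f"{name} samples do not match beta matrix")
        m = m.loc[keep]
        v = m.to_numpy(dtype=float)
        fin = v[np.isfinite(v)]
        if fin.size and ((fin < lo).any() or (hi is not None and (fin > hi).any())):
            raise BetaValidationError(f"{name} values out of range")
        return v

    return BetaMatrix(
        probe_ids=keep,
        sample_ids=[str(c) for c in df.columns],
        beta=df.to_numpy(dtype=float),
        detection_p=_aligned(detection_p_path, 0.0, 1.0, "detection_p"),
        beadcount=_aligned(beadcount_path, 0.0, None, "beadcount"),
    )


def write_beta_matrix(bm: BetaMatrix, path: str | Path, decimals: int = 6) -> None:
    df = pd.DataFrame(bm.beta, index=bm.probe_ids, columns=bm.sample_ids)
    df.index.name = "probe_id"
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, float_format=f"%.{decimals}f")


def write_matrix(values: np.ndarray, probe_ids, sample_ids, path: str | Path, fmt: str = "%.6f") -> None:
    df = pd.DataFrame(values, index=list(probe_ids), columns=list(sample_ids))
    df.index.name = "probe_id"
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, float_format=fmt)


def load_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    for col in SampleSheet.NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, index=False, float_format="%.6f")


def export_dmps_bed(dmps, manifest: Manifest, path: str | Path) -> None:
    """Write called DMPs as BED6 (chr<chrom>, 0-based half-open single base).

    Score is round(1000 * |delta_beta|) capped at 1000; strand is ".".
    """
    lines = []
    for d in dmps:
        if d.probe_id not in manifest:
            raise KeyError(f"DMP probe {d.probe_id!r} not in manifest")
        p = manifest[d.probe_id]
        score = min(1000, int(round(1000 * abs(d.delta_beta))))
        lines.append(
            f"chr{p.chromosome}\t{p.position - 1}\t{p.position}\t{p.probe_id}\t{score}\t."
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
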