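import numpy as np
import pandas as pd
import pytest

from methylscreen import synthetic_data as sd
from methylscreen.manifest_io import BetaMatrix, Manifest, ProbeAnnotation, SampleSheet


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default synthetic cohort shared across tests."""
    cfg = sd.default_paper_like_config(seed=11)
    manifest = sd.generate_manifest(cfg)
    bm, sheet, truth = sd.generate_cohort(manifest, cfg)
    return cfg, manifest, bm, sheet, truth


def make_probe(
    probe_id="cg00000001",
    chromosome="1",
    position=1000,
    probe_type="II",
    gene_mappings=(),
    island_region="OpenSea",
    is_cpg=True,
    is_snp_associated=False,
    is_cross_reactive=False,
):
    return ProbeAnnotation(
        probe_id=probe_id,
        chromosome=chromosome,
        position=position,
        probe_type=probe_type,
        gene_mappings=tuple(gene_mappings),
        island_region=island_region,
        is_cpg=is_cpg,
        is_snp_associated=is_snp_associated,
        is_cross_reactive=is_cross_reactive,
    )


@pytest.fixture
def probe_factory():
    return make_probe


def make_sheet(n_case=2, n_control=2, **extra_cols):
    ids = [f"HT{i+1}" for i in range(n_case)] + [f"C{i+1}" for i in range(n_control)]
    data = {"sample_id": ids, "group": ["case"] * n_case + ["control"] * n_control}
    data.update(extra_cols)
    return SampleSheet(pd.DataFrame(data))


@pytest.fixture
def sheet_factory():
    return make_sheet


def make_beta(values, probe_ids=None, sample_ids=None, **kw):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:08d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i+1}" for i in range(values.shape[1])]
    return BetaMatrix(probe_ids=probe_ids, sample_ids=sample_ids, beta=values, **kw)


@pytest.fixture
def beta_factory():
    return make_beta
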