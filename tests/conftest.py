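"""Shared fixtures: one synthetic cross at the reference study conditions
(200 genes, 4-fold allelic bias, 60 informative reads/gene, 3 replicates,
CG DMRs shifted by 0.5 at 20x coverage) and one null methylome, both
session-scoped because several suites measure different properties of the
same dataset."""

import pandas as pd
import pytest

from hybridscope import (
    CrossSimConfig,
    simulate_cross,
    simulate_null_methylome,
    read_vcf,
    hard_filter,
    select_diagnostic,
    assign_to_genes,
    read_gff3,
    read_cx_report,
    call_dmrs,
)
from hybridscope.variants import diagnostics_to_frame


@pytest.fixture(scope="session")
def cross(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cross")
    config = CrossSimConfig(n_genes=200, seed=11)
    out = simulate_cross(config, outdir)
    out["config"] = config
    return out


@pytest.fixture(scope="session")
def gene_models(cross):
    return read_gff3(str(cross["gff3"]))


@pytest.fixture(scope="session")
def diagnostics(cross, gene_models):
    passing = hard_filter(read_vcf(str(cross["vcf"])))
    snps = select_diagnostic(passing, father="FATHER", mother="MOTHER")
    return diagnostics_to_frame(assign_to_genes(snps, gene_models))


@pytest.fixture(scope="session")
def allele_depths(cross):
    return pd.concat(
        [pd.read_csv(p, sep="\t") for p in cross["allele_depths"]], ignore_index=True
    )


@pytest.fixture(scope="session")
def methylomes(cross):
    return (
        read_cx_report(str(cross["methylation"]["hybrid"])),
        read_cx_report(str(cross["methylation"]["maternal"])),
    )


@pytest.fixture(scope="session")
def dmr_calls(methylomes):
    return call_dmrs(*methylomes)


@pytest.fixture(scope="session")
def null_methylome(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("null_meth")
    paths = simulate_null_methylome(CrossSimConfig(n_genes=100, seed=3), outdir)
    return (
        read_cx_report(str(paths["groupA"])),
        read_cx_report(str(paths["groupB"])),
    )
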