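import os

os.environ.setdefault("MPLBACKEND", "Agg")

import math

import pytest

from famvar.simulate import GenotypePanelSpec, simulate_genotype_panel


@pytest.fixture(scope="session")
def small_panel_spec() -> GenotypePanelSpec:
    """A small genotype panel with a strong planted 5-variant region."""
    return GenotypePanelSpec(
        n_samples=300,
        n_variants=40,
        seed=20,
        planted_region=(10, 14),
        causal_log_or=math.log(2.0),
        ld_block_size=5,
    )


@pytest.fixture(scope="session")
def small_panel_files(small_panel_spec, tmp_path_factory):
    """The small panel written as VCF + phenotype TSV."""
    root = tmp_path_factory.mktemp("panel")
    return simulate_genotype_panel(
        small_panel_spec, root / "panel.vcf", root / "panel.pheno.tsv"
    )
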