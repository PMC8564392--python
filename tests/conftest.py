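from pathlib import Path

import pytest

from scboolnet.pipeline import PipelineConfig
from scboolnet.synthetic_data import write_fixture


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory) -> dict[str, Path]:
    """Full synthetic input bundle (103-gene network, 549 cells, 14 samples)."""
    outdir = tmp_path_factory.mktemp("inputs")
    return write_fixture(outdir, seed=1)


@pytest.fixture(scope="session")
def make_pipeline_config(fixture_bundle):
    """Factory for a PipelineConfig over the session fixture bundle."""

    def make(outdir, **overrides) -> PipelineConfig:
        base = dict(
            expression=str(fixture_bundle["expression"]),
            annotations=str(fixture_bundle["annotations"]),
            outdir=str(outdir),
            seed=1,
            pathway_lists={k.removeprefix("pathway_"): str(v)
                           for k, v in fixture_bundle.items()
                           if k.startswith("pathway_")},
            cell_line_expression=str(fixture_bundle["cell_line_expression"]),
            control_columns=("CONTROL_LINE",),
            de_table=str(fixture_bundle["de_status"]),
            interactome=str(fixture_bundle["interactome"]),
            tf_table=str(fixture_bundle["tf_table"]),
            sign_table=str(fixture_bundle["sign_table"]),
            low_expression_threshold=1.0,
            reference_sample="TUMOR_LINE",
            seed_genes=("HSP90AB1", "YWHAB", "VIM", "CSNK2B", "TK1"),
        )
        base.update(overrides)
        return PipelineConfig(**base)

    return make
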