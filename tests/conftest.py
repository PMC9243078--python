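import numpy as np
import pandas as pd
import pytest

import adhescreen as a


@pytest.fixture(scope="session")
def small_library():
    return a.build_library(10, 3, seed=1)


@pytest.fixture(scope="session")
def null_truth(small_library):
    """No receptors, no off-target noise: deterministic multipliers."""
    return a.sample_ground_truth(
        small_library, receptor_fraction=0.0, offtarget_sd=0.0, seed=2
    )


@pytest.fixture(scope="session")
def render_spec():
    """Small field used by most imaging tests (fast to render)."""
    return a.RenderSpec(
        image_shape=(320, 320), nuclei_per_well=25, bacteria_per_nucleus_baseline=4.0
    )


@pytest.fixture(scope="session")
def noise_free_render(null_truth, render_spec):
    well = a.WellSpec("neg_ctrl_scrambled")
    return a.render_well(well, null_truth, render_spec.noise_free(), seed=7)


def make_quant_table(
    sample_ratios,
    *,
    plate_id="P001",
    neg_ratios=(2.0, 2.0, 2.0, 2.0),
    ab_ratios=(0.1, 0.1, 0.1, 0.1),
    death=None,
    untreated=None,
    content_class="gene_pool",
):
    """Hand-built joined quant+layout table for normalization/QC tests.

    ``sample_ratios``: mapping gene_id -> ratio (pooled) or gene_id ->
    list of per-siRNA ratios (singles, when ``sirna_per_gene`` is set).
    """
    rows = []
    w = iter(
        f"{r}{c:02d}" for c in range(1, 25) for r in "ABCDEFGHIJKLMNOP"
    )
    for cls, ratios in (
        ("neg_ctrl_scrambled", neg_ratios),
        ("ab_block", ab_ratios),
        ("pos_ctrl_death", death or ()),
        ("untreated", untreated or ()),
    ):
        for r in ratios:
            rows.append(
                {
                    "plate_id": plate_id, "well": next(w), "content_class": cls,
                    "gene_id": "", "sirna_ids": "", "n_nuclei": 300,
                    "n_bacteria": int(300 * r), "bac_nuc_ratio": r, "flags": "",
                }
            )
    if isinstance(sample_ratios, dict):
        items = sample_ratios.items()
    else:
        items = [(f"G{i + 1:05d}", r) for i, r in enumerate(sample_ratios)]
    for gene, val in items:
        vals = val if isinstance(val, (list, tuple)) else [val]
        for j, r in enumerate(vals):
            rows.append(
                {
                    "plate_id": plate_id, "well": next(w),
                    "content_class": content_class, "gene_id": gene,
                    "sirna_ids": f"{gene}_s{j + 1}", "n_nuclei": 300,
                    "n_bacteria": int(300 * r), "bac_nuc_ratio": r, "flags": "",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def quant_table_factory():
    return make_quant_table
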