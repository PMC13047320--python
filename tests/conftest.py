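import numpy as np
import pytest

from skinsynergy import io_formats, nbglm, synthetic


@pytest.fixture
def small_samples():
    samples = []
    for trt in io_formats.TREATMENTS:
        for rep in (1, 2, 3):
            samples.append(
                io_formats.SampleInfo(
                    sample_id=f"k_{trt}_r{rep}",
                    cell_type="keratinocyte",
                    treatment=trt,
                    replicate=rep,
                )
            )
    return samples


@pytest.fixture
def keratinocyte_sim():
    """One-cell-type simulated experiment with planted DE genes."""
    cfg = synthetic.SimConfig(
        n_genes=300, cell_types=("keratinocyte",), seed=1
    )
    expt, truth = synthetic.simulate_counts(cfg)
    return expt.for_cell_type("keratinocyte"), truth


def two_group_pair(expt, treatment):
    """Subset an experiment to control + one treatment, with the design."""
    mask = np.array(
        [s.treatment in ("control", treatment) for s in expt.samples]
    )
    pair = expt.subset_samples(mask)
    indicator = np.array(
        [1.0 if s.treatment == treatment else 0.0 for s in pair.samples]
    )
    return pair, nbglm.two_group_design(indicator), mask
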