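import pytest

import tarscribe as ts


@pytest.fixture(scope="session")
def config():
    return ts.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(config):
    """Full synthetic dataset shared across recovery tests."""
    annotation, truth = ts.generate_annotation(config)
    alignments = ts.simulate_alignments(annotation, truth, config)
    coverage = ts.compute_coverage(alignments, config.chrom_sizes)
    tars = []
    for chrom in sorted(coverage):
        tars.extend(ts.call_tars(coverage[chrom]))
    return {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "alignments": alignments,
        "coverage": coverage,
        "tars": tars,
    }
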