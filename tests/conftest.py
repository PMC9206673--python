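import warnings

import pytest

from exonarch.pipeline import run_pipeline
from exonarch.simulate import SimScenario, build_toy_gene, make_sample_sheet, \
    simulate_long_reads, simulate_short_reads

warnings.filterwarnings("ignore", message=".*zero reads.*")


@pytest.fixture(scope="session")
def small_gene():
    """5 exons, one alternative-acceptor group, 4 isoforms."""
    return build_toy_gene(5, {2}, seed=11, n_isoforms=4)


@pytest.fixture(scope="session")
def small_sheet():
    return make_sample_sheet(2, seed=5)


@pytest.fixture(scope="session")
def clean_run(small_gene, small_sheet):
    """Zero-noise end-to-end run on the small gene."""
    sc = SimScenario(n_samples=2, reads_per_sample=60,
                     error_rates=(0.0, 0.0, 0.0), seed=4,
                     short_reads_per_sample=400, short_read_length=100)
    sim = simulate_long_reads(small_gene, sc, small_sheet)
    short = simulate_short_reads(small_gene, sc)
    res = run_pipeline(small_gene.locus, sim.reads, small_sheet,
                       short_reads=short.reads)
    return {"gene": small_gene, "sheet": small_sheet, "scenario": sc,
            "sim": sim, "short": short, "res": res}
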