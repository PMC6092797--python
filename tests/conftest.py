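import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from clipmap.io_formats import RunConfig
from clipmap.models import GeneModel, Genome
from clipmap.pipeline import run_full_analysis
from clipmap.synthetic import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def demo_dataset():
    """One moderately sized simulated study shared across read-only tests."""
    return simulate_dataset(SimulationParams(n_genes=48, seed=1))


@pytest.fixture(scope="session")
def demo_results(demo_dataset, cfg):
    return run_full_analysis(demo_dataset, cfg)


@pytest.fixture(scope="session")
def recovery_runs(cfg):
    """Ten independent simulated studies with their full analyses.

    Shared by the parameter-recovery and RNA-map suites; 48 genes per seed
    keeps ten full pipeline runs affordable.
    """
    runs = []
    for seed in range(1, 11):
        ds = simulate_dataset(SimulationParams(n_genes=48, seed=seed))
        runs.append((ds, run_full_analysis(ds, cfg)))
    return runs


@pytest.fixture(scope="session")
def null_runs(cfg):
    """Five simulated studies with no differential truth (type-I control)."""
    from clipmap.pipeline import run_binding_analysis
    from clipmap.splicing import multiple_testing_and_filters, quantify_events

    runs = []
    for seed in range(101, 106):
        ds = simulate_dataset(
            SimulationParams(n_genes=48, seed=seed, differential_fraction=0.0)
        )
        binding = run_binding_analysis(ds.reads, ds.genes, ds.genome, cfg)
        events = multiple_testing_and_filters(
            quantify_events(ds.junction_counts, cfg), cfg
        )
        runs.append((ds, binding, events))
    return runs


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    start=0,
    end=1000,
    tu_start=None,
    tu_end=None,
    exons=(),
):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        tu_start=start if tu_start is None else tu_start,
        tu_end=end if tu_end is None else tu_end,
        exons=list(exons),
        transcripts={f"{gene_id}_t1": list(exons) or [(start, end)]},
    )


def make_genome(length=2000, chrom="chr1", seed=0):
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Genome({chrom: seq})
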