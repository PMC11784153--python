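import dataclasses

import pytest

from maekit import Genome, LineRecord, ExperimentDesign, synthetic


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 50 kb single-chromosome genome with 10 genes."""
    genome, genes = synthetic.generate_genome(
        length=50_000, gc=0.5, n_genes=10, seed=11)
    return genome, genes


@pytest.fixture(scope="session")
def spontaneous_design():
    """The 21-line spontaneous experiment layout: 11x103 + 10x120 cycles."""
    lines = ([LineRecord(f"wy{i}", "spontaneous", 103) for i in range(11)]
             + [LineRecord(f"wy{i + 11}", "spontaneous", 120) for i in range(10)])
    return ExperimentDesign(lines, t=25, genome_size=20_500_000)


@pytest.fixture
def toy_genome():
    return Genome({"c1": "ACGTACGTAC", "c2": "CAAAAGTTTT"})


def boosted_profile(name: str, factor: float) -> synthetic.ConditionProfile:
    """A preset with all per-base rates scaled up for small test genomes."""
    p = synthetic.PRESETS[name]
    return dataclasses.replace(
        p,
        snv_rates={k: v * factor for k, v in p.snv_rates.items()},
        indel_rates={k: v * factor for k, v in p.indel_rates.items()},
    )
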