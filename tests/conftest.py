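import numpy as np
import pytest

from gensurvey.sequence_io import SurveyRead


def random_seq(rng, n: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20_100_203)


@pytest.fixture
def planted_genome():
    """Small genome with one 60-copy repeat family, plus reads."""
    from gensurvey.synthetic_data import (GenomeSpec, ReadProfile,
                                          RepeatFamilySpec,
                                          simulate_genome,
                                          simulate_survey_reads)

    spec = GenomeSpec(
        genome_size_bp=200_000,
        families=[RepeatFamilySpec("fam1", "retrotransposon", 1000, 60,
                                   intra_family_divergence=0.005)],
        rng_seed=7,
    )
    genome, truth = simulate_genome(spec)
    reads = simulate_survey_reads(
        genome, ReadProfile(coverage_fraction=0.05), seed=11, truth=truth)
    return {"spec": spec, "genome": genome, "truth": truth, "reads": reads}


def make_reads(seqs) -> list[SurveyRead]:
    return [SurveyRead(f"r{i}", s) for i, s in enumerate(seqs)]
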