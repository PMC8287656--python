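import pytest

from mitocomp import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    """A compact full-panel genome with one intron-bearing cox1."""
    spec = sd.GenomeSpec(
        id="syn1",
        length=24000,
        gc=0.23,
        at_skew=-0.05,
        gc_skew=0.08,
        introns=[sd.IntronSpec("cox1", 383, 400, orf_length=300)],
    )
    return sd.generate_genome(spec, seed=101)


@pytest.fixture(scope="session")
def repeat_genome():
    """Genome with planted duplications and a tandem array."""
    spec = sd.GenomeSpec(
        id="rep1",
        length=26000,
        duplications=[
            sd.DuplicationSpec(52),
            sd.DuplicationSpec(45, inverted=True),
        ],
        tandems=[sd.TandemSpec(12, 12)],
    )
    return sd.generate_genome(spec, seed=202)


@pytest.fixture(scope="session")
def mutated_pair():
    """Ancestor plus a descendant with known per-gene rates."""
    spec = sd.GenomeSpec(id="anc", length=24000)
    ancestor, manifest = sd.generate_genome(spec, seed=303)
    rates = {
        "rps3": {"syn": 0.05, "nonsyn": 0.15},
        "atp9": {"syn": 0.02, "nonsyn": 0.002},
        "cox1": {"syn": 0.10, "nonsyn": 0.01},
    }
    descendant, realized = sd.mutate_genome(
        ancestor, rates, seed=304, new_id="desc"
    )
    return ancestor, descendant, rates, realized
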