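import numpy as np
import pytest

from vlwd.genomes import Chromosome, Genome, gene_content


@pytest.fixture(scope="session")
def example_genomes():
    """The three-genome worked example, each genome one circular chromosome."""
    return [
        Genome("G1", (Chromosome((-2, -1, -3), circular=True),)),
        Genome("G2", (Chromosome((-1, 4, 2), circular=True),)),
        Genome("G3", (Chromosome((-2, -1, -4, 1, 2), circular=True),)),
    ]


@pytest.fixture(scope="session")
def example_encodings(example_genomes):
    """All four encodings of the worked example, reduction off."""
    from vlwd.adjacencies import build_profile
    from vlwd.encodings import encode

    profile = build_profile(example_genomes)
    content = {g.name: gene_content(g) for g in example_genomes}
    return {
        scheme: encode(profile, content, scheme, reduce_invariant_columns=False)
        for scheme in ("vlbe1", "vlbe2", "vlbe3", "mlwd")
    }


def random_genome(rng: np.random.Generator, name: str, max_label: int = 30) -> Genome:
    """Random multichromosomal genome with duplications, both topologies."""
    n_chrom = int(rng.integers(1, 4))
    chroms = []
    for _ in range(n_chrom):
        length = int(rng.integers(1, 12))
        labels = rng.integers(1, max_label + 1, size=length)
        signs = rng.choice([-1, 1], size=length)
        chroms.append(
            Chromosome(tuple(int(l * s) for l, s in zip(labels, signs)),
                       circular=bool(rng.integers(2)))
        )
    return Genome(name, tuple(chroms))
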