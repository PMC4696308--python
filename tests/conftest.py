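import numpy as np
import pandas as pd
import pytest

from ssrscape.popgen import GenotypeMatrix
from ssrscape.regions import Transcript
from ssrscape.simulate import GenomeSimSpec, PopSimSpec, simulate_genome, simulate_populations


@pytest.fixture()
def toy_transcript():
    """Single + strand gene on a 5 kb scaffold: UTR5 1001-1200, CDS
    1201-2800, UTR3 2801-3000."""
    return Transcript("t1", "s1", 1001, 3000, "+",
                      exons=[(1001, 3000)], cds=[(1201, 2800)],
                      utr5=[(1001, 1200)], utr3=[(2801, 3000)])


@pytest.fixture()
def toy_genotypes():
    """Two species x two populations x three individuals, three loci."""
    individuals = [f"i{k}" for k in range(12)]
    rng = np.random.default_rng(7)
    base = np.repeat([[100, 200, 300]], 12, axis=0)
    base[6:] += 3  # species 2 shifted one repeat unit at every locus
    base += 3 * rng.integers(0, 2, size=base.shape)
    alleles = pd.DataFrame(base, index=individuals, columns=["L1", "L2", "L3"])
    population = pd.Series([p for p in ("p1", "p2", "p3", "p4") for _ in range(3)],
                           index=individuals)
    species = pd.Series(["A"] * 6 + ["B"] * 6, index=individuals)
    category = pd.Series({"L1": "OUT", "L2": "IN", "L3": "UP"})
    return GenotypeMatrix(alleles, population, species, category)


@pytest.fixture(scope="session")
def sim_genome(tmp_path_factory):
    spec = GenomeSimSpec(
        scaffold_lengths={"s1": 30000, "s2": 25000},
        planting=[("EXON", "ACG", 6, 5), ("INTRON", "AT", 8, 3),
                  ("DISTAL", "AAG", 7, 4), ("UP_0_50", "CCG", 5, 2),
                  ("UTR3", "AGC", 6, 2), ("DOWN_50_500", "AAT", 6, 2)],
        seed=42)
    out = tmp_path_factory.mktemp("sim_genome")
    fasta, gff, truth = simulate_genome(spec, out)
    return {"spec": spec, "fasta": fasta, "gff3": gff,
            "truth": pd.read_csv(truth, sep="\t")}


@pytest.fixture(scope="session")
def sim_pops():
    g, truth = simulate_populations(PopSimSpec(seed=11))
    return g, truth
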