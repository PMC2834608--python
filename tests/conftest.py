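import numpy as np
import pytest

from ssgblup.pedigree import AnimalPartition, Pedigree, a11_inverse_projection
from ssgblup.grm import GeneContent, build_G
from ssgblup.simulate import SimConfig, gene_drop, random_pedigree, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def trio():
    """Sire, dam and one offspring; parents unrelated."""
    return Pedigree.from_records([("o", "s", "d"), ("s", "0", "0"), ("d", "0", "0")])


@pytest.fixture
def fullsib_offspring():
    """Offspring of two full sibs: inbreeding coefficient 0.25."""
    return Pedigree.from_records(
        [
            ("p1", "0", "0"),
            ("p2", "0", "0"),
            ("s1", "p1", "p2"),
            ("s2", "p1", "p2"),
            ("o", "s1", "s2"),
        ]
    )


def make_instance(rng, n_founders=6, n_extra=18, n_genotyped=9, n_loci=40):
    """Random pedigree + partition + gene-dropped markers + G, the standard
    small instance for oracle checks."""
    ped = random_pedigree(n_founders, n_extra, rng)
    k = min(n_genotyped, len(ped))
    genotyped = [ped.ids[i] for i in sorted(rng.choice(len(ped), k, replace=False))]
    part = AnimalPartition.from_pedigree(ped, genotyped)
    proj = a11_inverse_projection(ped, part)
    rho = rng.uniform(0.15, 0.85, n_loci)
    m = gene_drop(ped, rho, rng)[ped.index(genotyped)]
    gc = GeneContent(genotyped, m, rho)
    return ped, part, proj, gc, build_G(gc)


@pytest.fixture(scope="session")
def scaled_sim():
    """One tenth-scale breeding-program replicate shared across tests."""
    return simulate(SimConfig(seed=0).scaled(10))


@pytest.fixture(scope="session")
def tiny_sim():
    """Very small program for fast pipeline checks."""
    cfg = SimConfig(seed=5).scaled(30, n_snps=400, n_qtl=60)
    return simulate(cfg)
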