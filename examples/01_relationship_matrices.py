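"""Build A, G and the pedigree-extended G* on a toy pedigree.

Six animals, three genotyped: shows how the genomic relationship matrix is
extended to non-genotyped relatives through the pedigree, and that the
extension collapses to A when markers carry no extra information.
"""

import numpy as np

from ssgblup import (
    AnimalPartition,
    GeneContent,
    Pedigree,
    a11_inverse_projection,
    build_A,
    build_G,
    extend_G_star,
)

ped = Pedigree.from_records(
    [
        ("sireA", "0", "0"),
        ("damA", "0", "0"),
        ("sireB", "0", "0"),
        ("calf1", "sireA", "damA"),
        ("calf2", "sireA", "damA"),
        ("calf3", "sireB", "damA"),
    ]
)
A = build_A(ped)
print("pedigree relationship A[calf1, calf2] =", A.loc("calf1", "calf2"))

# calf1 and calf2 are full sibs (expected relationship 0.5), but markers can
# tell how much genome they actually share
genotyped = ["sireA", "calf1", "calf2"]
rng = np.random.default_rng(1)
rho = rng.uniform(0.2, 0.8, 200)
m = rng.choice([-1, 0, 1], size=(3, 200), p=[0.25, 0.5, 0.25])
gc = GeneContent(genotyped, m, rho)
G = build_G(gc)
print("marker-realised G[calf1, calf2]   =", round(G.loc("calf1", "calf2"), 3))

part = AnimalPartition.from_pedigree(ped, genotyped)
proj = a11_inverse_projection(ped, part)
G_star = extend_G_star(G, proj)
print("extended G*[calf1, damA]          =", round(G_star.loc("calf1", "damA"), 3))
print("(damA is not genotyped: her relationships are imputed through the pedigree)")
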