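"""GEBV prediction for animals outside the estimation run.

Two routes are provided.  ``predict_extended`` augments the mixed-model
equations with the extra animals (zero records) and re-solves; by block
elimination this leaves the estimation animals' solutions untouched while
giving BLUPs (and PEVs) for the extras.  ``predict_shortcut`` handles the
common scenario of many *genotyped* outside animals (index 3): when such
animals are related to the non-genotyped block only through the genotyped
estimation animals (A32 - A31 A11^-1 A12 = 0), their GEBVs collapse to

    ghat_3 = G_w,31 G_w^-1 ghat_1,       G_w,31 = (1-w) G_31 + w A_31,

which needs only the genotyped estimation animals' solutions ghat_1, the
cross-block of G, and one sparse solve against the full-pedigree A^-1 for
the A_31 product; the index-3 self block of G is never formed.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import splu

from .grm import GeneContent, GRMError, blend_Gw, build_G, combined_inverse
from .mme import MMESolution, ModelFrame, VarianceComponents, assemble_mme, solve_mme
from .pedigree import AnimalPartition, Pedigree, a11_inverse_projection, build_A, build_A_inverse

__all__ = ["predict_extended", "predict_shortcut"]


def predict_extended(
    vc: VarianceComponents,
    ped_all: Pedigree,
    genotyped_ids,
    gc_all: GeneContent,
    record_animals,
    y,
    X=None,
    pev_for=False,
) -> MMESolution:
    """Solve the MME extended to every animal of ``ped_all``.

    ``gc_all`` holds gene contents for all genotyped animals (estimation
    and extra); records are (record_animals, y, X) with X defaulting to an
    intercept.  Animals without records enter with empty incidence rows, so
    estimation animals' GEBVs are reproduced exactly and extra animals get
    conditional-expectation BLUPs.
    """
    missing = [a for a in record_animals if a not in ped_all]
    if missing:
        raise GRMError(f"record animals not in pedigree: {missing[:5]}")
    part = AnimalPartition.from_pedigree(ped_all, list(genotyped_ids))
    proj = a11_inverse_projection(ped_all, part)
    order = {a: i for i, a in enumerate(gc_all.ids)}
    try:
        rows = [order[a] for a in part.genotyped]
    except KeyError as e:
        raise GRMError(f"genotyped animal {e.args[0]!r} lacks a genotype row") from None
    gc = GeneContent(list(part.genotyped), gc_all.m[rows], gc_all.rho, gc_all.loci)
    G = build_G(gc)
    hw_inv = combined_inverse(proj, blend_Gw(G, proj.A11, vc.w))
    y = np.asarray(y, dtype=float)
    X = np.ones((y.size, 1)) if X is None else np.asarray(X, dtype=float)
    est_order = part.estimation_order
    pos = {a: i for i, a in enumerate(est_order)}
    frame = ModelFrame(y, X, np.array([pos[a] for a in record_animals]), est_order)
    system = assemble_mme(frame, hw_inv, vc)
    return solve_mme(system, vc, pev_for=pev_for)


def predict_shortcut(
    solution: MMESolution,
    ped_all: Pedigree,
    genotyped_est,
    gc_est: GeneContent,
    gc_other: GeneContent,
    w: float,
    check_condition=False,
    cond_tol=1e-8,
) -> dict:
    """Point GEBVs for genotyped animals outside the estimation run.

    ``solution`` is the estimation-run solve; ``gc_est``/``gc_other`` hold
    gene contents for the genotyped estimation (index 1) and outside
    (index 3) animals on the same locus panel.  The exactness condition
    A32 - A31 A11^-1 A12 = 0 is assumed; ``check_condition`` verifies it
    with dense pedigree algebra (small problems only).  PEVs are not
    produced by this route.  Returns {animal: gebv}.
    """
    if list(gc_other.rho.shape) != list(gc_est.rho.shape) or not np.allclose(
        gc_other.rho, gc_est.rho
    ):
        raise GRMError("estimation and outside panels must share loci and frequencies")
    ids1 = list(gc_est.ids)
    ids3 = list(gc_other.ids)
    missing = [a for a in ids3 if a not in ped_all]
    if missing:
        raise GRMError(f"outside animals not in pedigree: {missing[:5]}")
    # A11 over the genotyped estimation animals, from the full pedigree
    part1 = AnimalPartition.from_pedigree(ped_all, ids1)
    proj = a11_inverse_projection(ped_all, part1)
    Gw = blend_Gw(build_G(gc_est), proj.A11, w)
    ghat1 = solution.gebv_of(ids1)
    u = Gw.solve(ghat1)  # G_w^-1 ghat_1

    # marker cross block G_31 u
    s = gc_est.s
    c1 = gc_est.m - gc_est.p[None, :]
    c3 = gc_other.m - gc_other.p[None, :]
    g_term = (c3 @ (c1.T @ u)) / s

    # pedigree cross block A_31 u via one sparse solve with (A_all)^-1
    Ainv_all = build_A_inverse(ped_all)
    inj = np.zeros(len(ped_all))
    inj[ped_all.index(ids1)] = u
    a_cols_u = splu(Ainv_all.tocsc(), permc_spec="MMD_AT_PLUS_A").solve(inj)  # = A_all[:, 1] u
    a_term = a_cols_u[ped_all.index(ids3)]

    if check_condition:
        A = build_A(ped_all).values
        i1 = ped_all.index(ids1)
        others = set(solution.ids) - set(ids1)
        i2 = ped_all.index([a for a in ped_all.ids if a in others])
        i3 = ped_all.index(ids3)
        A11 = A[np.ix_(i1, i1)]
        gap = A[np.ix_(i3, i2)] - A[np.ix_(i3, i1)] @ np.linalg.solve(A11, A[np.ix_(i1, i2)])
        if np.max(np.abs(gap)) > cond_tol:
            raise GRMError(
                "shortcut condition A32 - A31 A11^-1 A12 = 0 violated "
                f"(max |gap| = {np.max(np.abs(gap)):.3g})"
            )

    gebv3 = (1.0 - w) * g_term + w * a_term
    return dict(zip(ids3, gebv3))
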