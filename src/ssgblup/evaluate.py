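"""Three-way comparison of breeding-value estimation methods.

``run_onestep`` fits the single-step model (phenotypes + pedigree + markers
jointly, genetic covariance sigma2_g H_w), ``run_ped`` the classical animal
model (A only; identical to one-step at w = 1), and ``run_two_step`` the
two-stage comparator that regresses precomputed pedigree EBVs of the
genotyped animals on a blended genomic relationship matrix
G_w = 0.99 G + 0.01 A11 and projects onto candidates.  Accuracy is the
Pearson correlation between (G)EBVs and true breeding values over the
selection candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grm import GeneContent, blend_Gw, build_G, combined_inverse, estimate_allele_freqs
from .mme import (
    DensePrecision,
    MMEError,
    ModelFrame,
    VarianceComponents,
    assemble_mme,
    estimate_vc,
    pedigree_precision,
    profile_w,
    solve_mme,
)
from .pedigree import AnimalPartition, a11_inverse_projection
from .predict import predict_extended
from .simulate import SimOutput

__all__ = [
    "onestep_inputs",
    "run_onestep",
    "run_ped",
    "run_two_step",
    "evaluate_accuracy",
    "compare_methods",
    "allele_freq_sensitivity",
]


def onestep_inputs(sim: SimOutput, include_candidates=True, rho=None):
    """Partition, pedigree projection, G and model frame for a simulated
    data set.  Allele frequencies default to the base-boar estimates (the
    study's reference choice); monomorphic loci are dropped."""
    geno_pos = {a: i for i, a in enumerate(sim.geno_ids)}
    genotyped = list(sim.base_boars) + list(sim.selected_boars)
    if include_candidates:
        genotyped += list(sim.candidates)
    rows = [geno_pos[a] for a in genotyped]
    m = sim.geno_m[rows]
    if rho is None:
        base_rows = sim.geno_m[[geno_pos[a] for a in sim.base_boars]]
        rho, _ = estimate_allele_freqs(base_rows, mode="base-sample")
    gc = GeneContent(genotyped, m, rho).drop_monomorphic()
    part = AnimalPartition.from_pedigree(sim.ped, genotyped)
    proj = a11_inverse_projection(sim.ped, part)
    G = build_G(gc)
    mask = ~np.isnan(sim.y)
    rec_animals = [sim.ped.ids[i] for i in np.where(mask)[0]]
    pos = {a: i for i, a in enumerate(part.estimation_order)}
    frame = ModelFrame(
        sim.y[mask], np.ones((int(mask.sum()), 1)),
        np.array([pos[a] for a in rec_animals]), part.estimation_order,
    )
    return part, proj, G, gc, frame


def run_onestep(sim: SimOutput, w=0.01, include_candidates=True, profile=False,
                grid=None, rho=None) -> dict:
    """Single-step GBLUP on a simulated data set.

    With ``profile`` the polygenic weight is estimated on the grid first
    and the reported fit uses w_hat; otherwise ``w`` is fixed (the study's
    operational choice is w = 0.01).  When candidates are excluded from the
    estimation (the one-step-2 shortcut) their GEBVs are recovered from the
    extended system that does use their genotypes.
    """
    part, proj, G, gc, frame = onestep_inputs(sim, include_candidates, rho=rho)
    out = {"partition": part}
    if profile:
        prof = profile_w(frame, proj, G, grid=grid)
        out["profile"] = prof
        w = prof.w_hat
    hw_inv = combined_inverse(proj, blend_Gw(G, proj.A11, w))
    vc, logL = estimate_vc(frame, hw_inv, w)
    solution = solve_mme(assemble_mme(frame, hw_inv, vc), vc, pev_for=False)
    out.update(vc=vc, logL=logL, solution=solution)
    if include_candidates:
        out["cand_gebv"] = dict(zip(sim.candidates, solution.gebv_of(sim.candidates)))
    else:
        geno_pos = {a: i for i, a in enumerate(sim.geno_ids)}
        all_geno = list(gc.ids) + list(sim.candidates)
        rows = [geno_pos[a] for a in all_geno]
        gc_all = GeneContent(all_geno, sim.geno_m[rows][:, _kept_cols(sim, gc)], gc.rho)
        mask = ~np.isnan(sim.y)
        rec_animals = [sim.ped.ids[i] for i in np.where(mask)[0]]
        ext = predict_extended(vc, sim.ped, all_geno, gc_all, rec_animals, sim.y[mask])
        out["cand_gebv"] = dict(zip(sim.candidates, ext.gebv_of(sim.candidates)))
        out["extended"] = ext
    return out


def _kept_cols(sim: SimOutput, gc: GeneContent) -> list:
    """Column indices of the full SNP panel retained in ``gc`` (after the
    monomorphic drop)."""
    name_to_col = {l: j for j, l in enumerate([f"snp{j}" for j in range(sim.geno_m.shape[1])])}
    return [name_to_col[l] for l in gc.loci]


def run_ped(sim: SimOutput) -> dict:
    """Classical pedigree BLUP (no markers): the w = 1 limit of one-step."""
    hw_inv = pedigree_precision(sim.ped)
    mask = ~np.isnan(sim.y)
    idx = np.where(mask)[0]
    frame = ModelFrame(sim.y[mask], np.ones((idx.size, 1)), idx, list(sim.ped.ids))
    vc, logL = estimate_vc(frame, hw_inv, 1.0)
    solution = solve_mme(assemble_mme(frame, hw_inv, vc), vc, pev_for=False)
    return {
        "vc": vc,
        "logL": logL,
        "solution": solution,
        "cand_gebv": dict(zip(sim.candidates, solution.gebv_of(sim.candidates))),
    }


def run_two_step(sim: SimOutput, ebv, blend=(0.99, 0.01), rho=None) -> dict:
    """Two-step genomic evaluation on genotyped animals only.

    ``ebv`` maps genotyped training animals (base + selected boars) to
    their pedigree EBVs; the response y_EBV is fitted with genetic
    covariance sigma2 * (0.99 G + 0.01 A11) and iid residuals, and
    candidates are predicted through the genomic relationships.
    """
    train = list(sim.base_boars) + list(sim.selected_boars)
    cand = list(sim.candidates)
    missing = [a for a in cand if a not in set(sim.geno_ids)]
    if missing:
        raise MMEError(f"candidates without genotypes: {missing[:5]}")
    geno_pos = {a: i for i, a in enumerate(sim.geno_ids)}
    animals = train + cand
    m = sim.geno_m[[geno_pos[a] for a in animals]]
    if rho is None:
        base_rows = sim.geno_m[[geno_pos[a] for a in sim.base_boars]]
        rho, _ = estimate_allele_freqs(base_rows, mode="base-sample")
    gc = GeneContent(animals, m, rho).drop_monomorphic()
    part = AnimalPartition.from_pedigree(sim.ped, animals)
    A11 = a11_inverse_projection(sim.ped, part).A11
    # reorder A11 (partition order == animals order here) and blend
    G = build_G(gc).values
    Gw = blend[0] * G + blend[1] * A11
    nt = len(train)
    y_ebv = np.array([ebv[a] for a in train])
    prec = DensePrecision(train, Gw[:nt, :nt])
    frame = ModelFrame(y_ebv, np.ones((nt, 1)), np.arange(nt), train)
    vc, logL = estimate_vc(frame, prec, 0.0)
    solution = solve_mme(assemble_mme(frame, prec, vc), vc, pev_for=False)
    ghat_t = solution.gebv
    ghat_c = Gw[nt:, :nt] @ np.linalg.solve(Gw[:nt, :nt], ghat_t)
    return {
        "vc": vc,
        "logL": logL,
        "solution": solution,
        "cand_gebv": dict(zip(cand, ghat_c)),
    }


def evaluate_accuracy(gebv, truth) -> float:
    """Pearson correlation between predicted and true breeding values over
    the animals present in both maps."""
    common = [a for a in gebv if a in truth]
    if len(common) < 3:
        raise MMEError("fewer than 3 animals shared between GEBVs and truth")
    g = np.array([gebv[a] for a in common])
    t = np.array([truth[a] for a in common])
    return float(np.corrcoef(g, t)[0, 1])


def compare_methods(sim: SimOutput, w=0.01, include_onestep2=True,
                    profile=False, grid=None) -> tuple[pd.DataFrame, dict]:
    """Accuracy table over the selection candidates, one row per method
    (method, sigma2_g, sigma2_e, correlation with true BVs)."""
    truth = dict(zip(sim.candidates, sim.tbv_of(sim.candidates)))
    details = {}
    rows = []

    one = run_onestep(sim, w=w, include_candidates=True, profile=profile, grid=grid)
    details["one-step"] = one
    rows.append(("one-step", one["vc"].sigma2_g, one["vc"].sigma2_e,
                 evaluate_accuracy(one["cand_gebv"], truth)))

    ped = run_ped(sim)
    details["ped"] = ped
    rows.append(("ped", ped["vc"].sigma2_g, ped["vc"].sigma2_e,
                 evaluate_accuracy(ped["cand_gebv"], truth)))

    ebv_all = dict(zip(ped["solution"].ids, ped["solution"].gebv))
    two = run_two_step(sim, ebv_all)
    details["two-step"] = two
    rows.append(("two-step", two["vc"].sigma2_g, two["vc"].sigma2_e,
                 evaluate_accuracy(two["cand_gebv"], truth)))

    if include_onestep2:
        one2 = run_onestep(sim, w=w, include_candidates=False)
        details["one-step-2"] = one2
        rows.append(("one-step-2", one2["vc"].sigma2_g, one2["vc"].sigma2_e,
                     evaluate_accuracy(one2["cand_gebv"], truth)))

    table = pd.DataFrame(rows, columns=["method", "sigma2_g", "sigma2_e", "cor_true_bv"])
    return table, details


def allele_freq_sensitivity(sim: SimOutput, grid=None) -> pd.DataFrame:
    """Profile w-hat under different allele-frequency choices: base-boar
    estimates, current (last genotyped boar generation) estimates, and the
    Gengler GLS estimates.  Reports w_hat per mode (no assertion: the study
    finding is qualitative — with selection, sample-estimated frequencies
    can push w-hat to 1, i.e. back to the plain animal model)."""
    geno_pos = {a: i for i, a in enumerate(sim.geno_ids)}
    base_rows = sim.geno_m[[geno_pos[a] for a in sim.base_boars]]
    n_per_gen = sim.config.n_boars
    current_ids = sim.selected_boars[:n_per_gen]  # first genotyped selection
    current_rows = sim.geno_m[[geno_pos[a] for a in current_ids]]
    genotyped = list(sim.base_boars) + list(sim.selected_boars) + list(sim.candidates)
    modes = {
        "base": estimate_allele_freqs(base_rows, mode="base-sample")[0],
        "current": estimate_allele_freqs(current_rows, mode="current-sample")[0],
        "gengler": estimate_allele_freqs(
            sim.geno_m[[geno_pos[a] for a in genotyped]], mode="gengler",
            ped=sim.ped, genotyped=genotyped,
        )[0],
    }
    rows = []
    for name, rho in modes.items():
        _, proj, G, _, frame = onestep_inputs(sim, include_candidates=True, rho=rho)
        prof = profile_w(frame, proj, G, grid=grid)
        rows.append((name, prof.w_hat, prof.ci[0], prof.ci[1]))
    return pd.DataFrame(rows, columns=["freq_mode", "w_hat", "ci_low", "ci_high"])
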