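"""Gene-content handling, the VanRaden G matrix, its pedigree extension G*
and the blended H_w, checked against brute force, dense algebra and
gene-dropping Monte Carlo."""

import numpy as np
import pytest

from ssgblup.grm import (
    GeneContent,
    GRMError,
    blend_Gw,
    build_G,
    combined_inverse,
    estimate_allele_freqs,
    extend_G_star,
    extend_G_star_dense,
    predict_gene_content,
)
from ssgblup.pedigree import (
    AnimalPartition,
    Pedigree,
    RelationshipMatrix,
    a11_inverse_projection,
    build_A,
)
from ssgblup.simulate import gene_drop, random_pedigree

from conftest import make_instance


class TestAlleleFrequencies:
    def test_all_heterozygous_gives_half(self):
        rho, flagged = estimate_allele_freqs(np.zeros((5, 3)))
        assert np.allclose(rho, 0.5)
        assert not flagged.any()

    def test_base_sample_counting(self):
        m = np.array([[-1.0], [-1.0], [1.0]])
        rho, _ = estimate_allele_freqs(m, mode="base-sample")
        assert np.allclose(rho, 1 / 3)

    def test_monomorphic_flagged_and_clamped(self):
        m = np.full((4, 2), -1.0)
        rho, flagged = estimate_allele_freqs(m)
        assert flagged.all()
        assert np.all(rho >= 1e-6)
        with pytest.raises(GRMError, match="monomorphic"):
            estimate_allele_freqs(m, on_monomorphic="error")

    def test_gengler_reduces_to_mean_when_all_founders_genotyped(self, rng):
        ped = Pedigree.from_records([(f"f{i}", "0", "0") for i in range(12)])
        m = rng.integers(-1, 2, (12, 6)).astype(float)
        rho_g, _ = estimate_allele_freqs(m, mode="gengler", ped=ped, genotyped=list(ped.ids))
        rho_c, _ = estimate_allele_freqs(m, mode="current-sample")
        assert np.allclose(rho_g, rho_c)

    def test_gengler_is_gls_intercept(self, rng):
        ped, part, proj, gc, _ = make_instance(rng, 5, 10, 8, n_loci=5)
        rho_g, _ = estimate_allele_freqs(
            gc.m.astype(float), mode="gengler", ped=ped, genotyped=list(gc.ids)
        )
        A11 = build_A(ped, subset=list(gc.ids)).values
        one = np.ones(len(gc.ids))
        w = np.linalg.solve(A11, one)
        mu = (w @ gc.m) / (w @ one)
        assert np.allclose(rho_g, np.clip((mu + 1) / 2, 1e-6, 1 - 1e-6))


class TestGeneContentPrediction:
    def test_offspring_of_two_genotyped_parents_is_parent_average(self):
        ped = Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])
        part = AnimalPartition.from_pedigree(ped, ["s", "d"])
        proj = a11_inverse_projection(ped, part)
        gc = GeneContent(["s", "d"], np.array([[-1], [-1]]), np.array([0.4]))
        pred = predict_gene_content(proj, gc)
        assert np.allclose(pred, [[-1.0]])

    def test_all_genotyped_returns_observed(self, rng):
        ped = random_pedigree(4, 6, rng)
        part = AnimalPartition.from_pedigree(ped, list(ped.ids))
        proj = a11_inverse_projection(ped, part)
        rho = rng.uniform(0.3, 0.7, 7)
        m = gene_drop(ped, rho, rng)
        gc = GeneContent(list(ped.ids), m, rho)
        pred = predict_gene_content(proj, gc)
        assert pred.shape == (0, 7)  # nothing left to predict

    def test_matches_dense_conditional_mean(self, rng):
        ped, part, proj, gc, _ = make_instance(rng, 5, 15, 8)
        A = build_A(ped, subset=part.estimation_order).values
        n1 = part.n1
        cond = gc.p[None, :] + A[n1:, :n1] @ np.linalg.solve(A[:n1, :n1], gc.m - gc.p[None, :])
        assert np.abs(predict_gene_content(proj, gc) - np.clip(cond, -1, 1)).max() < 1e-9


class TestBuildG:
    def test_single_heterozygote_zero(self):
        gc = GeneContent(["a"], np.array([[0]]), np.array([0.5]))
        assert gc.s == 0.5
        assert np.allclose(build_G(gc).values, [[0.0]])

    def test_identical_genotype_rows_duplicate_in_G(self, rng):
        m = np.vstack([rng.integers(-1, 2, 10)] * 2)
        gc = GeneContent(["a", "b"], m, np.full(10, 0.3))
        G = build_G(gc).values
        assert np.allclose(G[0], G[1])

    def test_brute_force_double_loop(self, rng):
        m = rng.integers(-1, 2, (5, 8))
        rho = rng.uniform(0.2, 0.8, 8)
        gc = GeneContent(list("abcde"), m, rho)
        G = build_G(gc).values
        s, p = gc.s, gc.p
        expect = np.array(
            [
                [sum((m[i, j] - p[j]) * (m[k, j] - p[j]) for j in range(8)) / s
                 for k in range(5)]
                for i in range(5)
            ]
        )
        assert np.abs(G - expect).max() < 1e-12

    def test_explicit_locus_weights(self, rng):
        m = rng.integers(-1, 2, (4, 6))
        rho = rng.uniform(0.2, 0.8, 6)
        gc = GeneContent(list("abcd"), m, rho)
        h = np.full(6, 1.0 / gc.s)
        assert np.allclose(build_G(gc, weights=h).values, build_G(gc).values)
        with pytest.raises(GRMError, match="nonnegative"):
            build_G(gc, weights=-h)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=15, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_G_invariant_to_locus_order(seed):
    """G sums over loci, so permuting the panel (and its frequencies
    consistently) leaves it unchanged."""
    rng = np.random.default_rng(seed)
    m = rng.integers(-1, 2, (6, 12))
    rho = rng.uniform(0.2, 0.8, 12)
    perm = rng.permutation(12)
    G1 = build_G(GeneContent(list("abcdef"), m, rho)).values
    G2 = build_G(GeneContent(list("abcdef"), m[:, perm], rho[perm])).values
    assert np.abs(G1 - G2).max() < 1e-12


class TestGStar:
    def test_all_genotyped_reduces_to_G(self, rng):
        ped = random_pedigree(4, 8, rng)
        part = AnimalPartition.from_pedigree(ped, list(ped.ids))
        proj = a11_inverse_projection(ped, part)
        rho = rng.uniform(0.3, 0.7, 20)
        gc = GeneContent(list(ped.ids), gene_drop(ped, rho, rng), rho)
        G = build_G(gc)
        assert np.abs(extend_G_star(G, proj).values - G.values).max() < 1e-12

    def test_none_genotyped_reduces_to_A(self, rng):
        ped = random_pedigree(4, 8, rng)
        part = AnimalPartition([], list(ped.ids))
        G_empty = RelationshipMatrix([], np.zeros((0, 0)), flavor="G")
        Gs = extend_G_star_dense(G_empty, ped, part)
        A = build_A(ped, subset=part.estimation_order).values
        assert np.abs(Gs.values - A).max() < 1e-12

    def test_G_equal_A11_collapses_to_A(self, rng):
        ped, part, proj, _, _ = make_instance(rng, 5, 10, 6)
        A = build_A(ped, subset=part.estimation_order).values
        GA = RelationshipMatrix(list(part.genotyped), A[: part.n1, : part.n1], flavor="G")
        assert np.abs(extend_G_star(GA, proj).values - A).max() < 1e-10

    def test_operator_matches_dense_oracle(self, rng):
        ped, part, proj, gc, G = make_instance(rng, 5, 12, 7)
        a = extend_G_star(G, proj).values
        b = extend_G_star_dense(G, ped, part).values
        assert np.abs(a - b).max() < 1e-10

    def test_expected_G_equals_A_by_gene_dropping(self, rng):
        # the defining condition for the locus weights: E[G(M)] = A
        ped = random_pedigree(4, 8, rng)
        A = build_A(ped).values
        rho = rng.uniform(0.2, 0.8, 30)
        nrep = 2000
        acc = np.empty((nrep, len(ped), len(ped)))
        for r in range(nrep):
            gc = GeneContent(list(ped.ids), gene_drop(ped, rho, rng), rho)
            acc[r] = build_G(gc).values
        err = acc.mean(axis=0) - A
        se = acc.std(axis=0) / np.sqrt(nrep)
        assert np.all(np.abs(err) < 4 * np.maximum(se, 1e-3))

    def test_conditional_variance_matches_rejection_sampling(self, rng):
        # 4 animals, 1 locus at rho = 1/2; observed parents (het, hom)
        # chosen so the pedigree-linear conditional moments are exact
        ped = Pedigree.from_records(
            [("f1", "0", "0"), ("f2", "0", "0"), ("f3", "0", "0"), ("o", "f1", "f2")]
        )
        part = AnimalPartition.from_pedigree(ped, ["f1", "f2"])
        proj = a11_inverse_projection(ped, part)
        rho = np.array([0.5])
        m_obs = np.array([[0], [-1]])
        gc = GeneContent(["f1", "f2"], m_obs, rho)
        Gs = extend_G_star(build_G(gc), proj).values
        order = part.estimation_order
        # rejection sampling of the offspring's content given the parents';
        # each gene_drop call carries 64 independent loci as a batch
        n = 40000
        draws = []
        rng2 = np.random.default_rng(12345)
        while len(draws) < n:
            m = gene_drop(ped, np.full(64, 0.5), rng2)
            i1, i2, io = ped.index(["f1", "f2", "o"])
            ok = (m[i1] == 0) & (m[i2] == -1)
            draws.extend(m[io][ok].tolist())
        draws = np.asarray(draws[:n], dtype=float)
        s = gc.s
        g_star_oo = Gs[order.index("o"), order.index("o")]
        mc = np.mean((draws - 0.0) ** 2) / s  # E[(M_o - p)^2 | obs] / s
        se = np.std((draws) ** 2 / s) / np.sqrt(n)
        assert abs(g_star_oo - mc) < 3 * se + 1e-4


class TestBlendAndInverse:
    def test_w_one_gives_A11(self, rng):
        _, _, proj, _, G = make_instance(rng)
        Gw = blend_Gw(G, proj.A11, 1.0)
        assert np.abs(Gw.values - proj.A11).max() < 1e-12

    def test_w_zero_gives_G_or_fails_for_singular(self, rng):
        _, _, proj, gc, G = make_instance(rng, n_loci=60)
        Gw = blend_Gw(G, proj.A11, 0.0)
        assert np.allclose(Gw.values, G.values)
        # duplicate genotype rows make G singular; a small w rescues it
        m = np.vstack([gc.m, gc.m[:1]])
        ids = list(gc.ids) + ["dup"]
        # build a singular G directly
        Gdup = (m - gc.p) @ (m - gc.p).T / gc.s
        A11x = np.eye(len(ids))
        from ssgblup.pedigree import RelationshipMatrix

        Gsing = RelationshipMatrix(ids, Gdup, flavor="G")
        with pytest.raises(GRMError, match="positive definite"):
            blend_Gw(Gsing, A11x, 0.0)
        blend_Gw(Gsing, A11x, 0.01)  # Cholesky succeeds

    def test_w_out_of_range_rejected(self, rng):
        _, _, proj, _, G = make_instance(rng)
        with pytest.raises(GRMError):
            blend_Gw(G, proj.A11, 1.5)

    def test_w_one_correction_vanishes(self, rng):
        _, _, proj, _, G = make_instance(rng)
        hw = combined_inverse(proj, blend_Gw(G, proj.A11, 1.0))
        assert np.abs(hw.sparse().toarray() - proj.Ainv.toarray()).max() == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_and_logdet_match_dense(self, seed):
        rng = np.random.default_rng(300 + seed)
        ped, part, proj, gc, G = make_instance(rng, 5, 15, 8)
        w = float(rng.uniform(0.02, 0.9))
        Gw = blend_Gw(G, proj.A11, w)
        hw = combined_inverse(proj, Gw)
        Hd = (1 - w) * extend_G_star_dense(G, ped, part).values + w * build_A(
            ped, subset=part.estimation_order
        ).values
        n = len(ped)
        assert np.abs(hw.sparse().toarray() @ Hd - np.eye(n)).max() < 1e-8
        assert abs(hw.logdet - np.linalg.slogdet(Hd)[1]) < 1e-6
        v = rng.normal(size=n)
        assert np.allclose(hw.matvec(v), hw.sparse() @ v)

    def test_Hw_interpolates_continuously(self, rng):
        ped, part, proj, _, G = make_instance(rng)
        A = build_A(ped, subset=part.estimation_order).values
        h1 = combined_inverse(proj, blend_Gw(G, proj.A11, 1.0))
        assert np.abs(np.linalg.inv(h1.sparse().toarray()) - A).max() < 1e-8
        ha = combined_inverse(proj, blend_Gw(G, proj.A11, 0.30))
        hb = combined_inverse(proj, blend_Gw(G, proj.A11, 0.31))
        assert np.abs(ha.sparse().toarray() - hb.sparse().toarray()).max() < 0.5
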