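"""Marker-based relationship matrices and their pedigree extension.

Gene contents are coded -1/0/1 for genotypes 11/12/22 at biallelic SNPs.
With rho_j the frequency of the second allele, p_j = 2(rho_j - 1/2) is the
expected gene content and s = sum_j 2 rho_j (1 - rho_j) the normaliser, the
genomic relationship matrix over the genotyped animals is

    G = (m - 1 p^T)(m - 1 p^T)^T / s

(the VanRaden form; a per-locus weight vector h generalises 1/s).  The
extension to non-genotyped animals conditions their unobserved gene
contents on the observed ones through the pedigree:

    G*_11 = G
    G*_21 = A21 A11^-1 G
    G*_22 = A22 - A21 A11^-1 (A11 - G) A11^-1 A12

The combined matrix H_w = (1-w) G* + w A carries a polygenic share w of the
genetic variance on the pedigree; its inverse is sparse-plus-block,

    H_w^-1 = A^-1 + blockdiag(G_w^-1 - A11^-1, 0),   G_w = (1-w) G + w A11,

with log det H_w = log det G_w + log det(A22 - A21 A11^-1 A12).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import (
    AnimalPartition,
    Pedigree,
    PedigreeProjection,
    RelationshipMatrix,
    build_A,
)

__all__ = [
    "GeneContent",
    "read_genotypes",
    "estimate_allele_freqs",
    "predict_gene_content",
    "build_G",
    "extend_G_star",
    "extend_G_star_dense",
    "blend_Gw",
    "combined_inverse",
    "HwInverse",
]

EPS_FREQ = 1e-6  # allele-frequency clamp


class GRMError(ValueError):
    pass


@dataclass
class GeneContent:
    """Gene-content matrix for the genotyped animals.

    m is animals x loci with entries in {-1, 0, 1}; rho holds per-locus
    second-allele frequencies in (0, 1).
    """

    ids: list
    m: np.ndarray
    rho: np.ndarray
    loci: list | None = None

    def __post_init__(self):
        self.m = np.asarray(self.m)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.m.shape != (len(self.ids), self.rho.size):
            raise GRMError("gene-content shape does not match ids/rho")
        vals = np.unique(self.m)
        if not np.all(np.isin(vals, [-1, 0, 1])):
            raise GRMError("gene contents must be coded -1/0/1")
        if np.any(self.rho <= 0) or np.any(self.rho >= 1):
            raise GRMError("allele frequencies must lie strictly in (0, 1)")
        if self.loci is None:
            self.loci = [f"snp{j}" for j in range(self.rho.size)]

    @property
    def p(self) -> np.ndarray:
        """Per-locus centering value p_j = 2(rho_j - 1/2)."""
        return 2.0 * (self.rho - 0.5)

    @property
    def s(self) -> float:
        """Normaliser s = sum_j 2 rho_j (1 - rho_j)."""
        return float(np.sum(2.0 * self.rho * (1.0 - self.rho)))

    def drop_monomorphic(self, eps=EPS_FREQ) -> "GeneContent":
        keep = (self.rho > eps) & (self.rho < 1 - eps)
        return GeneContent(self.ids, self.m[:, keep], self.rho[keep],
                           [l for l, k in zip(self.loci, keep) if k])


def read_genotypes(path, coding="dosage") -> tuple[list, np.ndarray, list]:
    """Read a headered TSV: first column animal id, remaining columns SNPs.

    ``coding`` "dosage" expects allele counts 0/1/2 (converted to -1/0/1);
    "centered" expects -1/0/1 directly.  Returns (ids, m, loci).
    """
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    loci = list(df.columns[1:])
    m = df.iloc[:, 1:].to_numpy(dtype=float)
    if coding == "dosage":
        m = m - 1.0
    elif coding != "centered":
        raise GRMError(f"unknown genotype coding {coding!r}")
    if np.isnan(m).any():
        # per-locus mean imputation for sporadic missing calls; the method
        # itself treats animals as wholly genotyped or not
        col_mean = np.nanmean(m, axis=0)
        nan_r, nan_c = np.where(np.isnan(m))
        m[nan_r, nan_c] = col_mean[nan_c]
        import warnings

        warnings.warn(f"{len(nan_r)} missing genotype calls mean-imputed")
    return ids, m, loci


def estimate_allele_freqs(m_obs, mode="current-sample", sample_index=None,
                          ped: Pedigree | None = None, genotyped=None,
                          eps=EPS_FREQ, on_monomorphic="flag"):
    """Second-allele frequencies rho_j from observed gene contents.

    Modes: "base-sample"/"current-sample" count alleles in the designated
    rows (``sample_index``, default all); "gengler" fits a per-locus GLS
    intercept of gene content with covariance A over the genotyped animals,
    so information is weighted by pedigree relationships.

    Monomorphic loci (rho outside [eps, 1-eps]) are clamped and flagged;
    ``on_monomorphic="error"`` raises instead.  Returns (rho, flagged).
    """
    m_obs = np.asarray(m_obs, dtype=float)
    if mode in ("base-sample", "current-sample"):
        rows = m_obs if sample_index is None else m_obs[np.asarray(sample_index)]
        rho = (rows.mean(axis=0) + 1.0) / 2.0
    elif mode == "gengler":
        if ped is None or genotyped is None:
            raise GRMError("gengler mode needs a pedigree and the genotyped id list")
        from .pedigree import a11_inverse_projection

        part = AnimalPartition.from_pedigree(ped, list(genotyped))
        A11 = a11_inverse_projection(ped, part).A11
        one = np.ones(A11.shape[0])
        cf = la.cho_factor(A11)
        w = la.cho_solve(cf, one)
        mu = (w @ m_obs) / (w @ one)  # GLS intercept per locus
        rho = (mu + 1.0) / 2.0
    else:
        raise GRMError(f"unknown allele-frequency mode {mode!r}")
    flagged = (rho < eps) | (rho > 1 - eps)
    if on_monomorphic == "error" and flagged.any():
        raise GRMError(f"{int(flagged.sum())} monomorphic loci")
    return np.clip(rho, eps, 1 - eps), flagged


def predict_gene_content(proj: PedigreeProjection, gc: GeneContent) -> np.ndarray:
    """Expected gene contents of non-genotyped animals given the observed.

    Linear (BLUP-type) prediction E[M_2j | m_1j] = p_j + A21 A11^-1
    (m_1j - p_j) per locus, clamped to [-1, 1]; rows follow the partition's
    non-genotyped order.
    """
    centred = gc.m - gc.p[None, :]
    pred = gc.p[None, :] + proj.proj_21(centred)
    return np.clip(pred, -1.0, 1.0)


def build_G(gc: GeneContent, weights=None) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix on the genotyped block.

    Default weights 1/s per locus; ``weights`` (length n_loci, nonnegative)
    replaces them, G = (m - 1p^T) diag(h) (m - 1p^T)^T.
    """
    if gc.s <= 0:
        raise GRMError("all loci monomorphic: s = 0")
    centred = gc.m - gc.p[None, :]
    if weights is None:
        G = (centred @ centred.T) / gc.s
    else:
        h = np.asarray(weights, dtype=float)
        if np.any(h < 0):
            raise GRMError("locus weights must be nonnegative")
        G = (centred * h[None, :]) @ centred.T
    return RelationshipMatrix(list(gc.ids), G, flavor="G")


def extend_G_star(G: RelationshipMatrix, proj: PedigreeProjection,
                  A22: np.ndarray | None = None) -> RelationshipMatrix:
    """Densely materialised G*: the pedigree extension of G to the
    non-genotyped block (intended for tests and small problems; the
    estimation path only ever uses H_w^-1).

    ``A22`` may be passed to reuse a precomputed non-genotyped block;
    otherwise it is reconstructed from A11 and the projections.
    """
    n1 = proj.n1
    if G.values.shape[0] != n1:
        raise GRMError("G dimension does not match the genotyped block")
    n2 = proj.n2
    order = proj.partition.estimation_order
    out = np.zeros((n1 + n2, n1 + n2))
    out[:n1, :n1] = G.values
    if n2:
        P21 = proj.proj_21(np.eye(n1))  # A21 A11^-1
        out[n1:, :n1] = P21 @ G.values
        out[:n1, n1:] = out[n1:, :n1].T
        if A22 is None:
            # A22 = Schur + A21 A11^-1 A12, with Schur = ((A^-1)_22)^-1
            schur = np.linalg.inv(proj.Ainv[n1:, n1:].toarray())
            A22 = schur + P21 @ proj.A11 @ P21.T
        out[n1:, n1:] = A22 - P21 @ (proj.A11 - G.values) @ P21.T
    return RelationshipMatrix(order, 0.5 * (out + out.T), flavor="G_star")


def extend_G_star_dense(G: RelationshipMatrix, ped: Pedigree,
                        part: AnimalPartition) -> RelationshipMatrix:
    """Oracle-path G* computed entirely with dense pedigree algebra."""
    A = build_A(ped, subset=part.estimation_order).values
    n1 = part.n1
    A11, A12, A22 = A[:n1, :n1], A[:n1, n1:], A[n1:, n1:]
    P = np.linalg.solve(A11, A12)  # A11^-1 A12
    Gv = G.values
    top = np.hstack([Gv, Gv @ P])
    bot = np.hstack([P.T @ Gv, A22 - P.T @ (A11 - Gv) @ P])
    out = np.vstack([top, bot])
    return RelationshipMatrix(part.estimation_order, 0.5 * (out + out.T), flavor="G_star")


@dataclass
class GwBlock:
    """G_w = (1-w) G + w A11 on the genotyped block, with cached Cholesky."""

    values: np.ndarray
    w: float

    def __post_init__(self):
        try:
            self._chol = la.cho_factor(self.values, lower=True)
        except la.LinAlgError as e:
            raise GRMError(
                "G_w is not positive definite; use a polygenic weight w > 0"
            ) from e

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol[0]))))

    def solve(self, B):
        return la.cho_solve(self._chol, B)

    @property
    def inverse(self) -> np.ndarray:
        if not hasattr(self, "_inv"):
            self._inv = self.solve(np.eye(self.values.shape[0]))
        return self._inv


def blend_Gw(G: RelationshipMatrix, A11: np.ndarray, w: float) -> GwBlock:
    """Polygenic blend G_w = (1-w) G + w A11; invertible for any w > 0."""
    if not 0.0 <= w <= 1.0:
        raise GRMError("w must lie in [0, 1]")
    if G.values.shape != A11.shape:
        raise GRMError("G and A11 shapes differ")
    return GwBlock((1.0 - w) * G.values + w * A11, w)


@dataclass
class HwInverse:
    """Sparse-plus-block inverse of H_w = (1-w) G* + w A.

    ``sparse()`` yields A^-1 + blockdiag(G_w^-1 - A11^-1, 0) for MME
    assembly; ``logdet`` is log det G_w + log det(A22 - A21 A11^-1 A12).
    Animal order is the partition's (genotyped block first).
    """

    ids: list
    Ainv: sp.csc_matrix
    correction: np.ndarray  # G_w^-1 - A11^-1 on the genotyped block
    logdet: float
    w: float

    @property
    def n(self) -> int:
        return self.Ainv.shape[0]

    def sparse(self) -> sp.csc_matrix:
        n1 = self.correction.shape[0]
        if n1 == 0:
            return self.Ainv
        corr = sp.coo_matrix(
            (
                self.correction.ravel(),
                tuple(np.indices(self.correction.shape).reshape(2, -1)),
            ),
            shape=(self.n, self.n),
        )
        return (self.Ainv + corr.tocsc()).tocsc()

    def matvec(self, v: np.ndarray) -> np.ndarray:
        n1 = self.correction.shape[0]
        out = self.Ainv @ v
        out[:n1] += self.correction @ v[:n1]
        return out


def combined_inverse(proj: PedigreeProjection, Gw: GwBlock) -> HwInverse:
    """Inverse and log-determinant of H_w from A^-1 and the small G_w.

    H_w^-1 = A^-1 + blockdiag(G_w^-1 - A11^-1, 0); at w = 1 the correction
    vanishes and H_1^-1 = A^-1 exactly.
    """
    n1 = proj.n1
    if Gw.values.shape[0] != n1:
        raise GRMError("G_w dimension does not match the genotyped block")
    if Gw.w == 1.0:
        corr = np.zeros((n1, n1))
    else:
        corr = Gw.inverse - proj.A11_inv
    logdet = Gw.logdet + proj.schur_logdet
    return HwInverse(proj.partition.estimation_order, proj.Ainv, corr, logdet, Gw.w)
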