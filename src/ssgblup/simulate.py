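"""Stochastic simulator of a simplified pig-nucleus breeding program.

The genome carries equidistant SNP markers and randomly placed QTL on a
fixed number of chromosomes; recombination follows the Haldane model
(Poisson crossovers along the cM map, no interference).  A base population
drifts for a configurable number of discrete generations at effective size
Ne (half males, half females, random mating) starting from unlinked loci at
frequency 0.5, and is then expanded into the generation-0 breeding animals.
Each subsequent generation mates every sow to a random selected boar; boars
of the next generation are selected on their own phenotype (truncation),
sows at random.  QTL effect sizes are Gamma draws with random signs, scaled
so the base-population additive variance hits a configured target, and the
phenotype is y = mu + TBV + e with Gaussian noise set by the target
heritability.

The module doubles as the package's fixture generator: ``random_pedigree``
and ``gene_drop`` provide the small pedigrees and gene-dropped genotypes
that the oracle tests are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "SimOutput",
    "BasePopulation",
    "simulate_base",
    "simulate_program",
    "simulate",
    "draw_qtl_effects",
    "random_pedigree",
    "gene_drop",
    "write_sim",
]


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Breeding-program parameters.

    Defaults mirror the full-scale study design: 10 chromosomes of 160 cM,
    5000 equidistant SNPs, 500 QTL with Gamma(shape 0.42, rate 5.4) effect
    sizes, a base population of effective size 100 drifting 50 generations,
    then 150 boars x 1500 sows producing 15000 offspring per generation for
    5 generations with top-150 own-phenotype boar selection.  7000 random
    males are phenotyped per generation (35000 records);
    ``phenotype_all_males`` records every male instead.  Genotyping: the
    base boars, the boars selected in the last three generations, and the
    generation-6 selection candidates.
    """

    n_chrom: int = 10
    chrom_len_cm: float = 160.0
    n_snps: int = 5000
    n_qtl: int = 500
    qtl_gamma_shape: float = 0.42
    qtl_gamma_rate: float = 5.4
    base_ne: int = 100
    base_generations: int = 50
    n_boars: int = 150
    n_sows: int = 1500
    n_offspring: int = 15000
    n_generations: int = 5
    phenotyped_males_per_gen: int = 7000
    phenotype_all_males: bool = False
    n_selected_gens_genotyped: int = 3
    genotype_base_boars: bool = True
    n_candidates: int = 300
    genotype_candidates: bool = True
    heritability: float = 0.2
    target_genetic_var: float = 4.0
    mu: float = 0.0
    snp_panel: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chrom", "n_snps", "n_qtl", "base_ne", "base_generations",
                     "n_boars", "n_sows", "n_offspring", "n_generations"):
            if getattr(self, name) <= 0:
                raise SimError(f"{name} must be positive")
        if self.n_offspring % self.n_sows:
            raise SimError("n_offspring must be a multiple of n_sows (constant litter size)")
        litter = self.n_offspring // self.n_sows
        if litter % 2:
            raise SimError("litter size must be even (half of offspring are male)")
        if self.base_ne % 2:
            raise SimError("base_ne must be even (half males, half females)")
        if not 0 < self.heritability < 1:
            raise SimError("heritability must lie in (0, 1)")

    @property
    def sigma2_e(self) -> float:
        return self.target_genetic_var * (1.0 - self.heritability) / self.heritability

    def scaled(self, factor: int = 10, n_snps=None, n_qtl=None) -> "SimConfig":
        """Animal counts divided by ``factor`` (phenotyping scaled too);
        locus counts optionally overridden."""
        return replace(
            self,
            n_boars=self.n_boars // factor,
            n_sows=self.n_sows // factor,
            n_offspring=self.n_offspring // factor,
            phenotyped_males_per_gen=self.phenotyped_males_per_gen // factor,
            n_snps=self.n_snps if n_snps is None else n_snps,
            n_qtl=self.n_qtl if n_qtl is None else n_qtl,
        )


@dataclass
class BasePopulation:
    boar_hap: np.ndarray  # (n_boars, 2, L) int8
    sow_hap: np.ndarray
    pos_cm: np.ndarray  # locus positions, concatenated over chromosomes
    chrom: np.ndarray  # chromosome index per locus
    is_snp: np.ndarray  # bool per locus
    qtl_pos: np.ndarray
    base_freqs: np.ndarray  # second-allele frequency per locus in gen 0


@dataclass
class SimOutput:
    """Everything the estimation modules consume, plus the truth tables."""

    ped: Pedigree
    sex_male: np.ndarray
    generation: np.ndarray
    tbv: np.ndarray
    y: np.ndarray  # NaN where unrecorded
    base_boars: list
    selected_boars: list  # genotyped selected boars (last three selections)
    candidates: list
    geno_ids: list
    geno_m: np.ndarray  # gene contents (-1/0/1) for geno_ids, SNP panel
    snp_base_freqs: np.ndarray
    qtl_effects: np.ndarray
    qtl_pos: np.ndarray
    config: SimConfig
    qtl_content: np.ndarray | None = None  # truth table: animals x QTL in {-1,0,1}

    @property
    def records(self) -> pd.DataFrame:
        mask = ~np.isnan(self.y)
        return pd.DataFrame(
            {"animal": np.asarray(self.ped.ids, dtype=object)[mask], "y": self.y[mask]}
        )

    def tbv_of(self, animals) -> np.ndarray:
        return self.tbv[self.ped.index(animals)]


def _genome(config: SimConfig, rng) -> tuple:
    """Locus map: equidistant SNPs plus uniform QTL, positions disjoint."""
    per_chr_snp = config.n_snps // config.n_chrom
    per_chr_qtl = config.n_qtl // config.n_chrom
    pos, chrom, is_snp = [], [], []
    L = config.chrom_len_cm
    for c in range(config.n_chrom):
        snp = (np.arange(per_chr_snp) + 0.5) * L / per_chr_snp if config.snp_panel else np.empty(0)
        while True:
            qtl = np.sort(rng.uniform(0, L, per_chr_qtl))
            if np.unique(np.concatenate([snp, qtl])).size == snp.size + qtl.size:
                break
        allpos = np.concatenate([snp, qtl])
        order = np.argsort(allpos)
        flags = np.concatenate([np.ones(snp.size, bool), np.zeros(qtl.size, bool)])
        pos.append(allpos[order])
        is_snp.append(flags[order])
        chrom.append(np.full(allpos.size, c))
    return np.concatenate(pos), np.concatenate(chrom), np.concatenate(is_snp)


def _gametes(par_hap: np.ndarray, pos_cm: np.ndarray, chrom: np.ndarray,
             chrom_len: float, rng) -> np.ndarray:
    """One gamete per parent row under Haldane recombination.

    ``par_hap`` is (B, 2, L); crossovers are Poisson(len/100) per
    chromosome with independent starting phase per chromosome.
    """
    B, _, L = par_hap.shape
    out = np.empty((B, L), dtype=np.int8)
    for c in np.unique(chrom):
        sel = chrom == c
        pos = pos_cm[sel]
        k = rng.poisson(chrom_len / 100.0, B)
        kmax = max(int(k.max()), 1)
        xo = rng.uniform(0, chrom_len, (B, kmax))
        xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
        counts = (xo[:, :, None] <= pos[None, None, :]).sum(axis=1)
        phase = rng.integers(0, 2, B)
        origin = ((phase[:, None] + counts) & 1).astype(np.int8)
        sub = par_hap[:, :, sel]
        out[:, sel] = np.take_along_axis(sub, origin[:, None, :], axis=1)[:, 0, :]
    return out


def _mate(sire_hap, dam_hap, pos_cm, chrom, chrom_len, rng, chunk=2000):
    """Offspring haplotypes (B, 2, L) from per-offspring parent haplotypes."""
    B = sire_hap.shape[0]
    out = np.empty((B, 2, sire_hap.shape[2]), dtype=np.int8)
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        out[lo:hi, 0] = _gametes(sire_hap[lo:hi], pos_cm, chrom, chrom_len, rng)
        out[lo:hi, 1] = _gametes(dam_hap[lo:hi], pos_cm, chrom, chrom_len, rng)
    return out


def simulate_base(config: SimConfig, rng=None) -> BasePopulation:
    """Drift a base population and expand it into generation-0 breeders.

    Ne/2 males and Ne/2 females mate randomly for ``base_generations``
    discrete generations from unlinked frequency-0.5 founders; the final
    generation is then expanded (parents drawn with replacement) into
    ``n_boars`` boars and ``n_sows`` sows.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pos, chrom, is_snp = _genome(config, rng)
    L = pos.size
    half = config.base_ne // 2
    male = rng.integers(0, 2, (half, 2, L), dtype=np.int8)
    female = rng.integers(0, 2, (half, 2, L), dtype=np.int8)
    for _ in range(config.base_generations):
        sires = rng.integers(0, half, config.base_ne)
        dams = rng.integers(0, half, config.base_ne)
        off = _mate(male[sires], female[dams], pos, chrom, config.chrom_len_cm, rng)
        male, female = off[:half], off[half:]
    sires = rng.integers(0, half, config.n_boars + config.n_sows)
    dams = rng.integers(0, half, config.n_boars + config.n_sows)
    expanded = _mate(male[sires], female[dams], pos, chrom, config.chrom_len_cm, rng)
    boar_hap, sow_hap = expanded[: config.n_boars], expanded[config.n_boars:]
    base_freqs = expanded.mean(axis=(0, 1))
    return BasePopulation(boar_hap, sow_hap, pos, chrom, is_snp,
                          pos[~is_snp], base_freqs)


def draw_qtl_effects(config: SimConfig, rng, base: BasePopulation | None = None) -> np.ndarray:
    """Signed Gamma QTL effect sizes, scaled to the target base variance.

    |effect| ~ Gamma(shape, scale = 1/rate), sign +/- with probability 1/2.
    When ``base`` is given, effects are rescaled so the realised TBV
    variance over the generation-0 animals equals ``target_genetic_var``.
    """
    n = config.n_qtl
    eff = rng.gamma(config.qtl_gamma_shape, 1.0 / config.qtl_gamma_rate, n)
    eff *= rng.choice([-1.0, 1.0], n)
    if base is not None:
        qtl_content = np.concatenate(
            [base.boar_hap[:, :, ~base.is_snp].sum(axis=1),
             base.sow_hap[:, :, ~base.is_snp].sum(axis=1)]
        ) - 1.0
        tbv = qtl_content @ eff
        v = tbv.var()
        if v <= 0:
            raise SimError("degenerate base population: zero TBV variance")
        eff *= np.sqrt(config.target_genetic_var / v)
    return eff


def simulate_program(base: BasePopulation, config: SimConfig, rng=None,
                     qtl_effects=None) -> SimOutput:
    """Run the selection scheme for ``n_generations`` plus the candidate
    generation, tracking pedigree, TBVs, phenotypes and genotyping flags."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if qtl_effects is None:
        qtl_effects = draw_qtl_effects(config, rng, base)
    qtl_mask = ~base.is_snp
    snp_mask = base.is_snp
    litter = config.n_offspring // config.n_sows

    ids: list = []
    sires: list = []
    dams: list = []
    sex_male: list = []
    generation: list = []
    tbv: list = []
    y: list = []
    geno_ids: list = []
    geno_rows: list = []
    qtl_rows: list = []

    def tbv_of(hap):
        content = hap[:, :, qtl_mask].sum(axis=1).astype(np.int8) - 1
        qtl_rows.append(content)
        return content @ qtl_effects

    def add_animals(n, sire_ids, dam_ids, males, gen, hap):
        start = len(ids)
        new = list(range(start, start + n))
        ids.extend(new)
        sires.extend(sire_ids)
        dams.extend(dam_ids)
        sex_male.extend(males)
        generation.extend([gen] * n)
        tbv.extend(tbv_of(hap))
        y.extend([np.nan] * n)
        return new

    def genotype(animal_ids, hap_rows):
        geno_ids.extend(animal_ids)
        geno_rows.append(hap_rows[:, :, snp_mask].sum(axis=1).astype(np.int8) - 1)

    sigma_e = np.sqrt(config.sigma2_e)

    boar_ids = add_animals(config.n_boars, [None] * config.n_boars,
                           [None] * config.n_boars, [True] * config.n_boars, 0,
                           base.boar_hap)
    sow_ids = add_animals(config.n_sows, [None] * config.n_sows,
                          [None] * config.n_sows, [False] * config.n_sows, 0,
                          base.sow_hap)
    base_boars = list(boar_ids)
    if config.genotype_base_boars and config.snp_panel:
        genotype(base_boars, base.boar_hap)

    boar_hap, sow_hap = base.boar_hap, base.sow_hap
    selected_geno: list = []
    first_geno_gen = config.n_generations - config.n_selected_gens_genotyped + 1

    for gen in range(1, config.n_generations + 1):
        # every sow gets one litter from a random selected boar
        sow_boar = rng.integers(0, len(boar_ids), config.n_sows)
        off_sire = np.repeat(sow_boar, litter)
        off_dam = np.repeat(np.arange(config.n_sows), litter)
        off_hap = _mate(boar_hap[off_sire], sow_hap[off_dam], base.pos_cm,
                        base.chrom, config.chrom_len_cm, rng)
        males = np.tile(np.array([True] * (litter // 2) + [False] * (litter // 2)),
                        config.n_sows)
        new = add_animals(
            config.n_offspring,
            [boar_ids[s] for s in off_sire],
            [sow_ids[d] for d in off_dam],
            list(males), gen, off_hap,
        )
        new = np.asarray(new)
        male_idx = np.where(males)[0]
        if config.phenotype_all_males:
            recorded = male_idx
        else:
            if config.phenotyped_males_per_gen > male_idx.size:
                raise SimError("phenotyped_males_per_gen exceeds male offspring count")
            recorded = rng.choice(male_idx, config.phenotyped_males_per_gen, replace=False)
        tbv_arr = np.asarray(tbv)
        for i in recorded:
            y[new[i]] = config.mu + tbv_arr[new[i]] + sigma_e * rng.normal()
        # truncation selection of boars on own phenotype, ties by id
        rec_sorted = recorded[np.argsort(recorded)]
        pheno = np.array([y[new[i]] for i in rec_sorted])
        top = rec_sorted[np.argsort(-pheno, kind="stable")[: config.n_boars]]
        if top.size < config.n_boars:
            raise SimError("not enough phenotyped males to select boars")
        new_boar_ids = [int(new[i]) for i in top]
        fem_idx = np.where(~males)[0]
        keep_sows = rng.choice(fem_idx, config.n_sows, replace=False)
        new_sow_ids = [int(new[i]) for i in keep_sows]
        if gen >= first_geno_gen:
            selected_geno.extend(new_boar_ids)
            if config.snp_panel:
                genotype(new_boar_ids, off_hap[top])
        boar_hap, sow_hap = off_hap[top], off_hap[keep_sows]
        boar_ids, sow_ids = new_boar_ids, new_sow_ids

    # generation-6 selection candidates: no phenotypes, genotyped
    cand_ids: list = []
    if config.n_candidates:
        c_sire = rng.integers(0, len(boar_ids), config.n_candidates)
        c_dam = rng.integers(0, len(sow_ids), config.n_candidates)
        c_hap = _mate(boar_hap[c_sire], sow_hap[c_dam], base.pos_cm, base.chrom,
                      config.chrom_len_cm, rng)
        cand_ids = add_animals(
            config.n_candidates,
            [boar_ids[s] for s in c_sire],
            [sow_ids[d] for d in c_dam],
            list(rng.integers(0, 2, config.n_candidates).astype(bool)),
            config.n_generations + 1, c_hap,
        )
        if config.genotype_candidates and config.snp_panel:
            genotype(cand_ids, c_hap)

    records = [(a, "0" if s is None else s, "0" if d is None else d)
               for a, s, d in zip(ids, sires, dams)]
    ped = Pedigree.from_records([(a, s, d) for a, s, d in records], unknown="0")
    # ids are ints and already topologically ordered; re-index arrays to ped order
    order = ped.index(ids)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(ids))

    geno_m = (np.concatenate(geno_rows, axis=0) if geno_rows
              else np.zeros((0, int(snp_mask.sum())), dtype=np.int8))
    return SimOutput(
        ped=ped,
        sex_male=np.asarray(sex_male)[inv],
        generation=np.asarray(generation)[inv],
        tbv=np.asarray(tbv)[inv],
        y=np.asarray(y, dtype=float)[inv],
        base_boars=base_boars,
        selected_boars=selected_geno,
        candidates=cand_ids,
        geno_ids=geno_ids,
        geno_m=geno_m,
        snp_base_freqs=base.base_freqs[snp_mask],
        qtl_effects=qtl_effects,
        qtl_pos=base.qtl_pos,
        config=config,
        qtl_content=np.concatenate(qtl_rows, axis=0)[inv],
    )


def simulate(config: SimConfig) -> SimOutput:
    """Base population + breeding program in one call, seeded from
    ``config.seed`` with per-stage substreams."""
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_prog = (np.random.default_rng(s) for s in ss.spawn(2))
    base = simulate_base(config, rng_base)
    return simulate_program(base, config, rng_prog)


# ---------------------------------------------------------------------------
# small fixture generators used by the oracle tests


def random_pedigree(n_founders: int, n_extra: int, rng, prefix="a") -> Pedigree:
    """Random acyclic pedigree: founders first, each later animal gets two
    (possibly unknown) parents among earlier animals."""
    records = [(f"{prefix}{i}", "0", "0") for i in range(n_founders)]
    for i in range(n_founders, n_founders + n_extra):
        s = f"{prefix}{rng.integers(0, i)}" if rng.random() < 0.9 else "0"
        d = f"{prefix}{rng.integers(0, i)}" if rng.random() < 0.9 else "0"
        records.append((f"{prefix}{i}", s, d))
    return Pedigree.from_records(records, unknown="0")


def gene_drop(ped: Pedigree, rho, rng, return_haplotypes=False):
    """Drop unlinked genes down a pedigree.

    Founders draw two alleles Bernoulli(rho_j) per locus; every offspring
    inherits one random allele from each parent per locus (unknown parents
    contribute founder draws).  Returns gene contents in {-1, 0, 1} in the
    pedigree's topological order.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    n, L = len(ped), rho.size
    hap = np.empty((n, 2, L), dtype=np.int8)
    for i in range(n):
        for k, p in enumerate((ped.sire[i], ped.dam[i])):
            if p < 0:
                hap[i, k] = rng.random(L) < rho
            else:
                pick = rng.integers(0, 2, L)
                hap[i, k] = hap[p, pick, np.arange(L)]
    m = hap.sum(axis=1).astype(np.int8) - 1
    return (m, hap) if return_haplotypes else m


def read_sim(outdir) -> SimOutput:
    """Reload a directory written by ``write_sim`` into a SimOutput.

    The manifest carries the full config; haplotype-level state is not
    stored, so re-simulation requires the seed, not this loader.
    """
    import os

    import yaml

    from .pedigree import read_pedigree

    with open(os.path.join(outdir, "manifest.yml")) as fh:
        manifest = yaml.safe_load(fh)
    config = SimConfig(**manifest["config"])
    ped = read_pedigree(os.path.join(outdir, "pedigree.csv"))
    ped = Pedigree(
        [int(a) for a in ped.ids], ped.sire, ped.dam,
        input_order=[int(a) for a in ped.input_order],
    )
    rec = pd.read_csv(os.path.join(outdir, "phenotypes.csv"))
    y = np.full(len(ped), np.nan)
    y[ped.index(rec["animal"].astype(int))] = rec["y"].to_numpy(float)
    tbv_df = pd.read_csv(os.path.join(outdir, "tbv.tsv"), sep="\t")
    tbv = np.empty(len(ped))
    tbv[ped.index(tbv_df["animal"].astype(int))] = tbv_df["tbv"].to_numpy(float)
    geno = pd.read_csv(os.path.join(outdir, "genotypes.tsv"), sep="\t")
    geno_ids = geno["animal"].astype(int).tolist()
    geno_m = geno.iloc[:, 1:].to_numpy(np.int8) - 1
    freqs = pd.read_csv(os.path.join(outdir, "allele_freqs.tsv"), sep="\t")["rho"].to_numpy(float)
    qtl = pd.read_csv(os.path.join(outdir, "qtl.tsv"), sep="\t")
    groups = pd.read_csv(os.path.join(outdir, "groups.tsv"), sep="\t")
    by_group = {g: sub["animal"].astype(int).tolist() for g, sub in groups.groupby("group")}
    return SimOutput(
        ped=ped,
        sex_male=np.zeros(len(ped), bool),
        generation=np.zeros(len(ped), int),
        tbv=tbv,
        y=y,
        base_boars=by_group.get("base_boars", []),
        selected_boars=by_group.get("selected_boars", []),
        candidates=by_group.get("candidates", []),
        geno_ids=geno_ids,
        geno_m=geno_m,
        snp_base_freqs=freqs,
        qtl_effects=qtl["effect"].to_numpy(float),
        qtl_pos=qtl["position_cm"].to_numpy(float),
        config=config,
    )


def write_sim(out: SimOutput, outdir, unknown="0"):
    """Emit pedigree/genotype/phenotype/truth files in the formats the
    estimation modules read."""
    import os

    os.makedirs(outdir, exist_ok=True)
    from .pedigree import write_pedigree

    ped = out.ped
    write_pedigree(ped, os.path.join(outdir, "pedigree.csv"), unknown=unknown)
    rec = out.records
    rec.to_csv(os.path.join(outdir, "phenotypes.csv"), index=False)
    geno = pd.DataFrame(out.geno_m + 1, columns=[f"snp{j}" for j in range(out.geno_m.shape[1])])
    geno.insert(0, "animal", out.geno_ids)
    geno.to_csv(os.path.join(outdir, "genotypes.tsv"), sep="\t", index=False)
    pd.DataFrame({"snp": [f"snp{j}" for j in range(out.snp_base_freqs.size)],
                  "rho": out.snp_base_freqs}).to_csv(
        os.path.join(outdir, "allele_freqs.tsv"), sep="\t", index=False)
    pd.DataFrame({"animal": out.ped.ids, "tbv": out.tbv}).to_csv(
        os.path.join(outdir, "tbv.tsv"), sep="\t", index=False)
    pd.DataFrame({"position_cm": out.qtl_pos, "effect": out.qtl_effects}).to_csv(
        os.path.join(outdir, "qtl.tsv"), sep="\t", index=False)
    groups = {"base_boars": out.base_boars, "selected_boars": out.selected_boars,
              "candidates": out.candidates}
    rows = [(g, a) for g, animals in groups.items() for a in animals]
    pd.DataFrame(rows, columns=["group", "animal"]).to_csv(
        os.path.join(outdir, "groups.tsv"), sep="\t", index=False)
    import dataclasses

    import yaml

    with open(os.path.join(outdir, "manifest.yml"), "w") as fh:
        yaml.safe_dump({"config": dataclasses.asdict(out.config),
                        "seed": out.config.seed}, fh)
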