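"""Gene-dropping simulator of a reciprocal full-sib/half-sib factorial design.

Two founder groups (A and B) with independently drawn per-locus allele
frequencies are crossed reciprocally (sires of A × dams of B and vice
versa) in a partial factorial where every parent contributes to at least
two full-sib families, so offspring are both full- and half-sibs. Offspring
genotypes are obtained by Mendelian sampling from stored founder haplotypes
(independent loci, no linkage), which makes offspring genotype frequencies
genuinely depart from Hardy–Weinberg proportions — the condition that
separates the NOIA and HWE kernel parameterizations.

Phenotypes follow the decomposition the analysis fits: additive effects,
directional dominance (a common positive heterozygote effect that produces
inbreeding depression with near-zero dominance variance — the infinitesimal
dominance regime — plus optional dominance deviations), additive-by-additive
epistasis on locus pairs, one maternal effect per dam, categorical fixed
effects, and a normal residual. Every simulated effect vector is rescaled
to hit its target variance exactly, and the truth is recorded for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "Founders",
    "SyntheticDataset",
    "simulate_founders",
    "mate_and_drop",
    "simulate_phenotypes",
    "simulate_dataset",
    "desk_config",
    "paper_like_config",
]


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture parameters.

    Defaults are a desk-scale version of the reciprocal factorial (32
    families, ~300 offspring, 800 loci); :func:`paper_like_config` returns
    the study-scale preset (76 families × ~15 offspring, 2000 loci).
    Variance targets are in trait units²; ``directional_dominance`` is the
    trait decline per unit homozygosity (δ ≥ 0 produces depression).
    """

    n_sires_a: int = 8
    n_dams_a: int = 8
    n_sires_b: int = 8
    n_dams_b: int = 8
    matings_per_parent: int = 2
    offspring_mean: float = 10.0
    offspring_sd: float = 4.0
    m_loci: int = 800
    founder_beta_a: tuple[float, float] = (5.0, 5.0)
    founder_beta_b: tuple[float, float] = (5.0, 5.0)
    sigma2_a: float = 0.10
    sigma2_d: float = 0.0
    sigma2_eaa: float = 0.15
    sigma2_m: float = 0.09
    sigma2_e: float = 0.66
    directional_dominance: float = 10.0
    trait_mean: float = 10.0
    n_epistatic_pairs: int = 400
    fixed_effect_levels: dict = field(
        default_factory=lambda: {"batch": 3, "day": 8, "filleter": 3}
    )
    fixed_effect_sd: float = 0.3
    cross_effect: float = 0.3
    missing_genotype_rate: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sires_a", "n_dams_a", "n_sires_b", "n_dams_b",
                     "matings_per_parent", "m_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sigma2_a", "sigma2_d", "sigma2_eaa", "sigma2_m", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for beta in (self.founder_beta_a, self.founder_beta_b):
            if beta[0] <= 0 or beta[1] <= 0:
                raise ValueError("Beta law parameters must be positive")
        if self.offspring_mean < 1:
            raise ValueError("offspring_mean must be >= 1")


def desk_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale default configuration (fast enough for unit tests)."""
    return SimulationConfig(seed=seed, **overrides)


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale preset: 76 full-sib families, ~15 offspring/family, 2000 loci.

    Architecture targets h² ≈ 0.10, m² ≈ 0.09, e²aa ≈ 0.15 with zero
    dominance variance, and directional dominance calibrated so relative
    inbreeding depression b_R ≈ 1 (δ equal to the trait mean).
    """
    base = dict(
        n_sires_a=19,
        n_dams_a=19,
        n_sires_b=19,
        n_dams_b=19,
        matings_per_parent=2,
        offspring_mean=15.1,
        offspring_sd=11.2,
        m_loci=2000,
        n_epistatic_pairs=1000,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class Founders:
    """Founder haplotypes per breeding role; alleles coded 0/1 per haplotype."""

    ids: list[str]
    roles: dict[str, list[str]]  # 'sires_a', 'dams_a', 'sires_b', 'dams_b'
    haplotypes: np.ndarray  # n_founders × m × 2, uint8
    group_freqs: dict[str, np.ndarray]

    @property
    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=2).astype(np.int8)


@dataclass
class SyntheticDataset:
    """Genotypes (parents + offspring), pedigree, phenotypes and the simulation truth."""

    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame  # id, sire, dam, group, cross
    phenotypes: pd.DataFrame
    truth: dict

    @property
    def offspring_ids(self) -> list[str]:
        return self.phenotypes["id"].tolist()


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> Founders:
    """Draw per-group allele frequencies from the Beta laws and founder haplotypes.

    Frequencies are drawn independently per group, so the groups diverge
    locus by locus even under identical Beta laws — the source of the
    offspring excess heterozygosity (HWE departure) after crossing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.m_loci
    freq_a = rng.beta(*config.founder_beta_a, size=m)
    freq_b = rng.beta(*config.founder_beta_b, size=m)
    counts = {
        "sires_a": config.n_sires_a,
        "dams_a": config.n_dams_a,
        "sires_b": config.n_sires_b,
        "dams_b": config.n_dams_b,
    }
    ids: list[str] = []
    roles: dict[str, list[str]] = {}
    haps = []
    for role, n_role in counts.items():
        freq = freq_a if role.endswith("_a") else freq_b
        role_ids = [f"{role[-1].upper()}_{role[:-2]}{i}" for i in range(n_role)]
        roles[role] = role_ids
        ids.extend(role_ids)
        haps.append((rng.random((n_role, m, 2)) < freq[None, :, None]).astype(np.uint8))
    return Founders(ids, roles, np.concatenate(haps, axis=0), {"A": freq_a, "B": freq_b})


def _family_sizes(n_families: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Family sizes ≥ 1 from a negative binomial matching the configured mean/SD."""
    mean, sd = config.offspring_mean, config.offspring_sd
    if sd <= 0 or sd**2 <= mean:
        return np.maximum(np.round(rng.normal(mean, max(sd, 0.0), n_families)), 1).astype(int)
    r = mean**2 / (sd**2 - mean)
    p = r / (r + mean)
    return np.maximum(rng.negative_binomial(r, p, size=n_families), 1)


def mate_and_drop(
    founders: Founders, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Partial-factorial matings in both cross directions; Mendelian gene dropping.

    Within each direction, sire i is mated to dams i, i+1, …, i+f−1 (mod
    n_dams) for f = ``matings_per_parent``, so every sire and dam appears in
    at least two full-sib families when f ≥ 2. Offspring draw one allele per
    locus from each parent's two haplotypes (independent loci).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    f = config.matings_per_parent
    directions = [
        ("AxB", founders.roles["sires_a"], founders.roles["dams_b"]),
        ("BxA", founders.roles["sires_b"], founders.roles["dams_a"]),
    ]
    for _, sires, dams in directions:
        if len(dams) < f or len(sires) < 1:
            raise ValueError(
                f"infeasible connectivity: need >= {f} dams per direction"
            )
    matings: list[tuple[str, str, str]] = []
    for cross, sires, dams in directions:
        for i, sire in enumerate(sires):
            for k in range(f):
                matings.append((sire, dams[(i + k) % len(dams)], cross))

    sizes = _family_sizes(len(matings), config, rng)
    idx = {fid: j for j, fid in enumerate(founders.ids)}
    haps = founders.haplotypes
    m = config.m_loci

    ped_rows = []
    off_codes = []
    off_ids = []
    counter = 0
    for (sire, dam, cross), size in zip(matings, sizes):
        hs, hd = haps[idx[sire]], haps[idx[dam]]
        pick_s = rng.integers(0, 2, size=(size, m))
        pick_d = rng.integers(0, 2, size=(size, m))
        codes = (
            np.take_along_axis(hs[None, :, :].repeat(size, 0), pick_s[:, :, None], 2)[:, :, 0]
            + np.take_along_axis(hd[None, :, :].repeat(size, 0), pick_d[:, :, None], 2)[:, :, 0]
        ).astype(np.int8)
        for row in codes:
            oid = f"O{counter:05d}"
            counter += 1
            off_ids.append(oid)
            off_codes.append(row)
            ped_rows.append({"id": oid, "sire": sire, "dam": dam,
                             "group": "offspring", "cross": cross})

    founder_rows = [
        {"id": fid, "sire": None, "dam": None,
         "group": "A" if fid.startswith("A") else "B", "cross": None}
        for fid in founders.ids
    ]
    pedigree = pd.DataFrame(founder_rows + ped_rows)
    locus_ids = [f"snp{j}" for j in range(m)]
    all_codes = np.vstack([founders.genotypes, np.array(off_codes, dtype=np.int8)])
    genotypes = GenotypeMatrix(founders.ids + off_ids, all_codes, locus_ids)
    return pedigree, genotypes


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one trait on the offspring with the full ADME architecture.

    Every effect vector (additive, dominance deviations, epistatic, maternal,
    residual) is rescaled so its realized offspring variance equals the
    configured target exactly. Directional dominance enters as a common
    heterozygote effect δ/m per locus, so the expected phenotype declines by
    δ per unit homozygosity; the intercept is set so the realized phenotypic
    mean equals ``trait_mean``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    off = pedigree[pedigree["group"] == "offspring"].reset_index(drop=True)
    ids = off["id"].tolist()
    codes = genotypes.subset(ids).codes.astype(float)
    n, m = codes.shape

    def rescale(v: np.ndarray, target: float, center: bool = True) -> np.ndarray:
        if center:
            v = v - v.mean()
        if target == 0.0:
            return np.zeros_like(v)
        s = v.std()
        if s < 1e-12:
            raise ValueError("cannot rescale a constant effect vector to a positive variance")
        return v * np.sqrt(target) / s

    poly = codes.std(axis=0) > 0
    if config.sigma2_a > 0 and not poly.any():
        raise ValueError("no polymorphic loci; additive variance unachievable")

    W = codes - codes.mean(axis=0)
    alpha = rng.normal(size=m) * poly
    g_add = rescale(W @ alpha, config.sigma2_a)

    het = (codes == 1).astype(float)
    hom_frac = 1.0 - het.mean(axis=1)
    delta = config.directional_dominance
    g_dir = delta * (1.0 - hom_frac)  # declines by delta per unit homozygosity
    if config.sigma2_d > 0:
        dev = rng.normal(size=m) * poly
        g_dom = rescale((het - het.mean(axis=0)) @ dev, config.sigma2_d)
    else:
        g_dom = np.zeros(n)

    if config.sigma2_eaa > 0:
        if poly.sum() < 2:
            raise ValueError("need >= 2 polymorphic loci for epistasis")
        poly_idx = np.nonzero(poly)[0]
        pairs = rng.choice(poly_idx, size=(config.n_epistatic_pairs, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        gamma = rng.normal(size=len(pairs))
        g_epi = rescale((W[:, pairs[:, 0]] * W[:, pairs[:, 1]]) @ gamma, config.sigma2_eaa)
    else:
        pairs = np.empty((0, 2), dtype=int)
        g_epi = np.zeros(n)

    dams = off["dam"].tolist()
    dam_levels = sorted(set(dams))
    dam_eff = dict(zip(dam_levels, rng.normal(size=len(dam_levels))))
    g_mat = rescale(np.array([dam_eff[d] for d in dams]), config.sigma2_m)

    resid = rescale(rng.normal(size=n), config.sigma2_e)

    fixed_cols: dict[str, np.ndarray] = {}
    fixed_contrib = np.zeros(n)
    cross = off["cross"].to_numpy()
    fixed_cols["cross"] = cross
    fixed_contrib += np.where(cross == "AxB", 0.5, -0.5) * config.cross_effect
    fixed_truth: dict[str, dict] = {}
    for name, n_lev in config.fixed_effect_levels.items():
        levels = rng.integers(0, n_lev, size=n)
        effects = rng.normal(0.0, config.fixed_effect_sd, size=n_lev)
        fixed_cols[name] = np.array([f"{name}{v}" for v in levels])
        fixed_contrib += effects[levels]
        fixed_truth[name] = {f"{name}{i}": float(e) for i, e in enumerate(effects)}

    total = g_add + g_dir + g_dom + g_epi + g_mat + resid + fixed_contrib
    intercept = config.trait_mean - total.mean()
    y = intercept + total

    phen = pd.DataFrame({"id": ids, "dam": dams, "cross": cross})
    for name, col in fixed_cols.items():
        phen[name] = col
    phen["homozygosity_true"] = hom_frac
    phen["y"] = y

    truth = {
        "config": asdict(config),
        "intercept": float(intercept),
        "additive": g_add,
        "dominance": g_dom,
        "directional": g_dir,
        "epistatic": g_epi,
        "maternal": g_mat,
        "residual": resid,
        "fixed_effects": fixed_truth,
        "epistatic_pairs": pairs,
        "realized_variances": {
            "additive": float(g_add.var()),
            "dominance": float(g_dom.var()),
            "epistatic_aa": float(g_epi.var()),
            "maternal": float(g_mat.var()),
            "residual": float(resid.var()),
        },
        "delta": float(delta),
    }
    return phen, truth


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """End-to-end simulation: founders → matings → genotypes → phenotypes.

    All randomness flows from one generator seeded by ``config.seed`` (or the
    ``seed`` override); the seed is recorded in the truth record. Missing
    genotype calls are masked at ``missing_genotype_rate`` after phenotype
    simulation (phenotypes derive from the complete genotypes).
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    pedigree, genotypes = mate_and_drop(founders, config, rng)
    phenotypes, truth = simulate_phenotypes(genotypes, pedigree, config, rng)
    if config.missing_genotype_rate > 0:
        mask = rng.random(genotypes.codes.shape) < config.missing_genotype_rate
        codes = genotypes.codes.copy()
        codes[mask] = MISSING
        genotypes = GenotypeMatrix(genotypes.ids, codes, genotypes.locus_ids)
    truth["seed"] = config.seed
    return SyntheticDataset(genotypes, pedigree, phenotypes, truth)
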