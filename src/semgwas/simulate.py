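"""Synthetic genotypes and recursively structured multi-trait phenotypes.

The generator emulates a compact inbred-line association panel: unlinked
biallelic markers in Hardy-Weinberg proportions, a polygenic additive
effect drawn from Sigma_g (x) G, residuals from Sigma_e (x) I, a handful
of planted QTLs, and phenotypes that solve a recursive structural system

    y = Lambda y + z,    z_k = W beta_qtl + u_k + e_k

traversed in topological order (equivalently y = (I - Lambda)^{-1} z per
individual).  QTL effects enter the exogenous term z, so the generating
"direct" effects coincide with the structural-model definition of a direct
SNP effect — which is what makes decomposition recovery testable.  Raw
plot-level records add block effects and plot noise on top of the
genotype-level values, mirroring a randomized-block trial.

The ``soy96`` preset matches the scale of a 96-line soybean panel with
4,070 post-QC SNPs, 3 blocks and the four-trait chain NP -> NG -> HGW ->
PT, with trait means/SDs, heritabilities and genetic/residual correlation
structure taken from the study system it emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, center_genotypes, compute_grm
from .phenotypes import RawPhenotypes

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_traits",
    "soy96_config",
    "chain_config",
]

SOY96_TRAITS = ["NP", "NG", "HGW", "PT"]
# trait means and SDs of the emulated soybean panel (pods/plant,
# grains/plant, g/100 grains, mm)
SOY96_MEANS = np.array([53.47, 111.40, 14.57, 6.41])
SOY96_SDS = np.array([11.72, 22.54, 3.04, 0.87])
SOY96_H2 = np.array([0.89, 0.79, 0.39, 0.45])
SOY96_RG = np.array([
    [1.00, 0.96, -0.84, -0.54],
    [0.96, 1.00, -0.88, -0.57],
    [-0.84, -0.88, 1.00, 0.61],
    [-0.54, -0.57, 0.61, 1.00],
])
SOY96_RE = np.array([
    [1.00, -0.47, 0.45, 0.17],
    [-0.47, 1.00, -0.24, -0.04],
    [0.45, -0.24, 1.00, 0.59],
    [0.17, -0.04, 0.59, 1.00],
])
SOY96_LAMBDA = {("NP", "NG"): 0.00006, ("NG", "HGW"): -0.05450,
                ("HGW", "PT"): 0.00697}


@dataclass
class SimulationConfig:
    """Generating parameters; defaults are the study-scale soybean panel."""

    n: int = 96
    m: int = 4070
    traits: list[str] = field(default_factory=lambda: list(SOY96_TRAITS))
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_blocks: int = 3
    mu: np.ndarray | None = None
    Sigma_g: np.ndarray | None = None
    Sigma_e: np.ndarray | None = None
    Lambda: np.ndarray | None = None          # Lambda[child, parent]
    qtls: list[tuple[int, str, float]] = field(default_factory=list)
    block_sd: np.ndarray | None = None
    plot_sd: np.ndarray | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.traits)
        if self.mu is None:
            self.mu = np.zeros(t)
        if self.Sigma_g is None:
            self.Sigma_g = np.eye(t)
        if self.Sigma_e is None:
            self.Sigma_e = np.eye(t)
        if self.Lambda is None:
            self.Lambda = np.zeros((t, t))
        for name in ("mu", "Sigma_g", "Sigma_e", "Lambda", "block_sd", "plot_sd"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, float))
        if self.block_sd is None:
            self.block_sd = np.zeros(t)
        if self.plot_sd is None:
            self.plot_sd = np.zeros(t)
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for nm, S in (("Sigma_g", self.Sigma_g), ("Sigma_e", self.Sigma_e)):
            if not np.allclose(S, S.T) or np.linalg.eigvalsh(S).min() < -1e-10:
                raise ValueError(f"{nm} must be symmetric positive semidefinite")
        t = len(self.traits)
        if np.abs(np.linalg.matrix_power(self.Lambda, t)).max() > 1e-12:
            raise ValueError("Lambda must describe an acyclic (recursive) system")
        for idx, tr, _ in self.qtls:
            if not (0 <= idx < self.m) or tr not in self.traits:
                raise ValueError(f"invalid QTL specification ({idx}, {tr})")


@dataclass
class SyntheticTruth:
    """Everything needed to reproduce the simulated phenotypes exactly."""

    config: SimulationConfig
    genetic_values: np.ndarray     # u, n x t
    residuals: np.ndarray          # e, n x t
    genotype_values: np.ndarray    # y = (I - Lambda)^-1 z, n x t
    block_effects: np.ndarray      # n_blocks x t
    plot_noise: np.ndarray         # (n * n_blocks) x t

    def to_manifest(self) -> str:
        cfg = asdict(self.config)
        for k, v in cfg.items():
            if isinstance(v, np.ndarray):
                cfg[k] = v.tolist()
        cfg["qtls"] = [[int(i), t, float(b)] for i, t, b in self.config.qtls]
        return json.dumps({"config": cfg}, indent=1)


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Unlinked HWE dosages: p_j ~ U(maf range), x_ij ~ Binomial(2, p_j)."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    p = rng.uniform(*cfg.maf_range, size=cfg.m)
    dosages = rng.binomial(2, p, size=(cfg.n, cfg.m)).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n, cfg.m)) < cfg.missing_rate
        dosages[mask] = np.nan
    n_chrom = 20
    markers = pd.DataFrame({
        "id": [f"snp{j:05d}" for j in range(cfg.m)],
        "chrom": [str(j % n_chrom + 1) for j in range(cfg.m)],
        "pos": [100_000 + 1_000 * (j // n_chrom) for j in range(cfg.m)],
    })
    ids = [f"g{i:03d}" for i in range(cfg.n)]
    return GenotypeMatrix(ids=ids, dosages=dosages, markers=markers)


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    d, U = np.linalg.eigh((S + S.T) / 2.0)
    return U * np.sqrt(np.clip(d, 0.0, None)) @ U.T


def simulate_traits(
    geno: GenotypeMatrix, cfg: SimulationConfig
) -> tuple[RawPhenotypes, SyntheticTruth]:
    """Recursive multi-trait phenotypes with known truth.

    Draws u with covariance Sigma_g (x) G (G built from the simulated
    panel itself), e with Sigma_e (x) I, adds planted QTL effects on
    centered dosages to the exogenous term, solves the structural system,
    then replicates to plots with block effects and plot noise.
    """
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))
    t = len(cfg.traits)
    n = geno.n_individuals
    tindex = {tr: k for k, tr in enumerate(cfg.traits)}

    centered = center_genotypes(geno)
    G = compute_grm(centered).G
    A = _psd_sqrt(G)                       # AA' = G
    Bg = _psd_sqrt(cfg.Sigma_g)
    u = A @ rng.standard_normal((n, t)) @ Bg.T       # cov = Sigma_g (x) G
    e = rng.standard_normal((n, t)) @ _psd_sqrt(cfg.Sigma_e).T

    z = u + e
    for idx, tr, beta in cfg.qtls:
        z[:, tindex[tr]] += beta * centered.W[:, idx]

    # solve y = Lambda y + z row-wise: y_i = (I - Lambda)^-1 z_i
    y = np.linalg.solve(np.eye(t) - cfg.Lambda, z.T).T + cfg.mu

    block_eff = rng.standard_normal((cfg.n_blocks, t)) * cfg.block_sd
    plot_noise = rng.standard_normal((n * cfg.n_blocks, t)) * cfg.plot_sd

    rows = []
    r = 0
    for b in range(cfg.n_blocks):
        for i, gid in enumerate(geno.ids):
            rec = {"id": gid, "block": f"b{b + 1}"}
            for k, tr in enumerate(cfg.traits):
                rec[tr] = y[i, k] + block_eff[b, k] + plot_noise[r, k]
            rows.append(rec)
            r += 1
    raw = RawPhenotypes(data=pd.DataFrame(rows))
    truth = SyntheticTruth(config=cfg, genetic_values=u, residuals=e,
                           genotype_values=y, block_effects=block_eff,
                           plot_noise=plot_noise)
    return raw, truth


def _chain_lambda(traits: list[str], coefs: dict[tuple[str, str], float]) -> np.ndarray:
    t = len(traits)
    idx = {tr: k for k, tr in enumerate(traits)}
    L = np.zeros((t, t))
    for (p, c), lam in coefs.items():
        L[idx[c], idx[p]] = lam
    return L


def soy96_config(seed: int = 0, n_qtls: int = 5) -> SimulationConfig:
    """The study-scale preset: 96 lines, 4,070 SNPs, 3 blocks, 4 traits.

    Trait scales, heritabilities, correlation structure and chain
    coefficients follow the emulated soybean panel.  A handful of QTLs
    (default 5, spread over traits and chromosomes, each ~0.3 trait-SD per
    allele) is planted on top of the polygenic background.
    """
    sd = SOY96_SDS
    sg = sd * np.sqrt(SOY96_H2)
    se = sd * np.sqrt(1.0 - SOY96_H2)
    Sigma_g = np.outer(sg, sg) * SOY96_RG
    Sigma_e = np.outer(se, se) * SOY96_RE
    qtl_traits = [SOY96_TRAITS[i % 3] for i in range(n_qtls)]  # NP/NG/HGW
    qtls = [
        (int(j), tr, 0.3 * float(sd[SOY96_TRAITS.index(tr)]))
        for j, tr in zip(np.linspace(100, 3900, n_qtls, dtype=int), qtl_traits)
    ]
    return SimulationConfig(
        n=96, m=4070, traits=list(SOY96_TRAITS), n_blocks=3,
        mu=SOY96_MEANS.copy(),
        Sigma_g=Sigma_g, Sigma_e=Sigma_e,
        Lambda=_chain_lambda(SOY96_TRAITS, SOY96_LAMBDA),
        qtls=qtls,
        block_sd=0.3 * sd, plot_sd=0.25 * sd,
        seed=seed,
    )


def chain_config(
    n: int = 500,
    m: int = 1000,
    lambdas: tuple[float, float, float] = (0.5, -0.3, 0.2),
    h2: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5),
    qtls: list[tuple[int, str, float]] | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """A unit-scale four-trait chain NP->NG->HGW->PT for recovery tests.

    Exogenous trait variances are 1 with the genetic share set by ``h2``;
    ``lambdas`` are the chain coefficients in order.
    """
    traits = list(SOY96_TRAITS)
    h2v = np.asarray(h2, float)
    Sigma_g = np.diag(h2v)
    Sigma_e = np.diag(1.0 - h2v)
    coefs = dict(zip([("NP", "NG"), ("NG", "HGW"), ("HGW", "PT")], lambdas))
    return SimulationConfig(
        n=n, m=m, traits=traits, n_blocks=2,
        Sigma_g=Sigma_g, Sigma_e=Sigma_e,
        Lambda=_chain_lambda(traits, coefs),
        qtls=qtls or [], block_sd=np.full(4, 0.3), plot_sd=np.full(4, 0.2),
        seed=seed,
    )
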