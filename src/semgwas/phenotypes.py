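"""Stage-1 phenotype adjustment for block effects.

Raw plot-level phenotypes from a randomized-block trial are modelled as

    y = X u + Z g + W r + e,      g ~ N(0, I sg2),  e ~ N(0, I se2)

with u the overall mean and r the block effects (both fixed), g the
genotypic effects (random) and e the residual.  Variance components are
estimated by REML (profile likelihood over the variance ratio), genotypic
effects by BLUP at the REML estimates, and the adjusted phenotype is the
sum of the random-effect estimates, y* = Z ghat + ehat — i.e. the raw data
with the fitted fixed effects removed — aggregated to one value per
genotype by averaging over plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "RawPhenotypes",
    "BlockModelFit",
    "AdjustedPhenotypes",
    "fit_block_model",
    "adjust_phenotypes",
    "adjust_all_traits",
]


@dataclass
class RawPhenotypes:
    """Plot-level records: one row per (genotype, block) with trait columns."""

    data: pd.DataFrame  # columns: id, block, <trait>...

    def __post_init__(self) -> None:
        for col in ("id", "block"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table must contain column {col!r}")
        if self.data.duplicated(["id", "block"]).any():
            raise ValueError("duplicate (genotype, block) records")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("id", "block")]


@dataclass
class BlockModelFit:
    """REML fit of the randomized-block mixed model for one trait."""

    trait: str
    genotype_ids: list[str]
    beta: np.ndarray          # fixed effects: intercept then block contrasts
    fixed_names: list[str]
    g_hat: np.ndarray         # genotype BLUPs, one per genotype
    e_hat: np.ndarray         # plot-level residuals
    sigma2_g: float
    sigma2_e: float
    X: np.ndarray             # fixed design (plots x fixed)
    Z: np.ndarray             # genotype incidence (plots x genotypes)
    y: np.ndarray             # raw plot observations


@dataclass
class AdjustedPhenotypes:
    """Adjusted phenotypes y*, one row per genotype, one column per trait."""

    values: pd.DataFrame      # index: genotype id; columns: traits
    variance_components: pd.DataFrame  # columns: trait, sigma2_g, sigma2_e


def _reml_neg_loglik(log_gamma: float, y, X, ZZt):
    n, p = X.shape
    gamma = np.exp(log_gamma)
    V0 = np.eye(n) + gamma * ZZt
    L = np.linalg.cholesky(V0)
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V0, y)
    Vi_X = np.linalg.solve(V0, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = np.linalg.solve(V0, r)
    rss = float(r @ Vi_r)
    s2e = rss / (n - p)
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    ll = -0.5 * (logdet_V0 + (n - p) * np.log(s2e) + logdet_XtViX + (n - p))
    return -ll


def fit_block_model(raw: RawPhenotypes, trait: str) -> BlockModelFit:
    """Fit y = Xu + Zg + Wr + e by REML for one trait.

    The fixed part holds the intercept and block contrasts (first block as
    reference); g is random with identity covariance.  The variance ratio
    gamma = sg2/se2 is profiled out and optimized on the log scale.
    """
    if trait not in raw.traits:
        raise ValueError(f"unknown trait {trait!r}")
    df = raw.data[["id", "block", trait]].dropna()
    blocks = sorted(df["block"].astype(str).unique())
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks to estimate block effects")
    genotypes = sorted(df["id"].astype(str).unique())

    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    gid = pd.Categorical(df["id"].astype(str), categories=genotypes).codes
    bid = pd.Categorical(df["block"].astype(str), categories=blocks).codes
    Z = np.zeros((n, len(genotypes)))
    Z[np.arange(n), gid] = 1.0
    X = np.ones((n, len(blocks)))
    for j in range(1, len(blocks)):
        X[:, j] = (bid == j).astype(float)
    fixed_names = ["intercept"] + [f"block[{b}]" for b in blocks[1:]]

    ZZt = Z @ Z.T
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(-12.0, 12.0), args=(y, X, ZZt),
        method="bounded", options={"xatol": 1e-10},
    )
    gamma = float(np.exp(res.x))
    # boundary: essentially no genotypic variance
    if gamma < 2e-5:
        warnings.warn(
            f"REML variance ratio for {trait!r} is at the zero boundary; "
            "genotypic variance may be indistinguishable from 0",
            stacklevel=2,
        )

    n_, p = X.shape
    V0 = np.eye(n) + gamma * ZZt
    Vi_y = np.linalg.solve(V0, y)
    Vi_X = np.linalg.solve(V0, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = np.linalg.solve(V0, r)
    s2e = float(r @ Vi_r) / (n_ - p)
    s2g = gamma * s2e
    g_hat = gamma * (Z.T @ Vi_r)
    e_hat = y - X @ beta - Z @ g_hat
    return BlockModelFit(
        trait=trait, genotype_ids=genotypes, beta=beta, fixed_names=fixed_names,
        g_hat=g_hat, e_hat=e_hat, sigma2_g=s2g, sigma2_e=s2e, X=X, Z=Z, y=y,
    )


def adjust_phenotypes(fit: BlockModelFit) -> pd.Series:
    """y* = Z ghat + ehat averaged within genotype.

    Equals the raw observations minus the fitted fixed effects, so adding a
    constant to every observation leaves y* unchanged (absorbed by the
    intercept).
    """
    ystar_plot = fit.Z @ fit.g_hat + fit.e_hat
    agg = pd.Series(ystar_plot).groupby(
        pd.Series(fit.Z.argmax(axis=1))
    ).mean()
    out = pd.Series(agg.to_numpy(), index=[fit.genotype_ids[i] for i in agg.index],
                    name=fit.trait)
    return out.reindex(fit.genotype_ids)


def adjust_all_traits(raw: RawPhenotypes, traits: list[str] | None = None) -> AdjustedPhenotypes:
    """Run the stage-1 adjustment for every requested trait."""
    traits = traits or raw.traits
    cols, vcs = {}, []
    for t in traits:
        fit = fit_block_model(raw, t)
        cols[t] = adjust_phenotypes(fit)
        vcs.append({"trait": t, "sigma2_g": fit.sigma2_g, "sigma2_e": fit.sigma2_e})
    values = pd.DataFrame(cols)
    values.index.name = "id"
    return AdjustedPhenotypes(values=values, variance_components=pd.DataFrame(vcs))
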