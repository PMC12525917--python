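"""Single-SNP multi-trait association scan with a fixed covariance.

Each trait is scaled to zero mean and unit variance, dosage columns are
residualized on the leading principal components (population-structure
correction), and every SNP is tested one at a time per trait by
generalized least squares under the trait's marginal covariance

    V_k = sg2_k G + se2_k I

held fixed at the multi-trait GBLUP posterior means.  Because V_k does not
change across SNPs, it is factorized once (through the eigendecomposition
of G) and reused for every marker — the economy that makes a
single-marker mixed-model scan linear in the number of SNPs.  The test
statistic is t = s / se(s) with a standard-normal reference, and
Benjamini-Hochberg step-up q-values are computed per trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import norm, t as t_dist

from .genotypes import GenotypeMatrix, PCACorrection, center_genotypes

__all__ = [
    "SNPScanResult",
    "SignificanceTable",
    "scale_phenotypes",
    "correct_structure",
    "scan_snps",
    "fdr_qvalues",
    "significant_snps",
]


@dataclass
class SNPScanResult:
    """Long-format scan table: one row per SNP x trait."""

    table: pd.DataFrame  # snp, chrom, pos, trait, effect, se, t, p, q


@dataclass
class SignificanceTable:
    table: pd.DataFrame
    threshold: float
    counts: pd.Series  # significant SNPs per trait


def scale_phenotypes(y_star: pd.DataFrame) -> pd.DataFrame:
    """Center each trait to mean 0 and scale to unit variance."""
    sd = y_star.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(sd.index[(sd == 0) | sd.isna()])
        raise ValueError(f"zero-variance trait(s): {bad}")
    return (y_star - y_star.mean()) / sd


def correct_structure(geno: GenotypeMatrix, pcs: PCACorrection) -> np.ndarray:
    """Residualize each centered dosage column on the first k PC scores.

    With k = 0 the dosages are merely centered.  The returned columns are
    orthogonal to the retained score columns.
    """
    W = center_genotypes(geno).W
    k = pcs.k
    if k >= geno.n_individuals:
        raise ValueError("cannot project out as many components as individuals")
    if k == 0:
        return W
    Q = np.column_stack([np.ones(geno.n_individuals), pcs.scores[:, :k]])
    beta, *_ = np.linalg.lstsq(Q, W, rcond=None)
    return W - Q @ beta


def scan_snps(
    scaled: pd.DataFrame,
    geno_corrected: np.ndarray,
    geno: GenotypeMatrix,
    G: np.ndarray,
    var_g: dict[str, float],
    var_e: dict[str, float],
    df_reference: int | None = None,
) -> SNPScanResult:
    """Per-trait GLS effect, SE, t, p and BH q for every SNP.

    ``var_g``/``var_e`` are per-trait variances on the scaled-phenotype
    scale; p-values use the standard-normal reference by default (pass
    ``df_reference`` for a Student-t reference instead).  SNPs whose
    corrected dosage has zero variance yield an NA row with a warning.
    """
    n, m = geno_corrected.shape
    traits = list(scaled.columns)
    d, U = eigh((np.asarray(G, float) + np.asarray(G, float).T) / 2.0)
    d = np.clip(d, 0.0, None)
    Wr = U.T @ geno_corrected          # rotate all SNPs once
    ones_r = U.T @ np.ones(n)

    dead = Wr.std(axis=0) == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance corrected dosage column(s); "
                      "reported as NA", stacklevel=2)

    frames = []
    for k_t, tr in enumerate(traits):
        sg, se = float(var_g[tr]), float(var_e[tr])
        if se <= 0:
            raise ValueError(f"non-positive residual variance for {tr!r}")
        wgt = 1.0 / (sg * d + se)      # V_k^-1 in the rotated basis
        yr = U.T @ scaled[tr].to_numpy(float)
        # per-SNP GLS with design [1, w_j]; all cross-products vectorized
        a11 = float(ones_r * wgt @ ones_r)
        a12 = (ones_r * wgt) @ Wr                    # (m,)
        a22 = np.einsum("ij,ij->j", Wr * wgt[:, None], Wr)
        b1 = float(ones_r * wgt @ yr)
        b2 = (yr * wgt) @ Wr                         # (m,)
        det = a11 * a22 - a12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (a11 * b2 - a12 * b1) / det
            se_s = np.sqrt(a11 / det)
            tstat = s / se_s
        s[dead] = se_s[dead] = tstat[dead] = np.nan
        if df_reference is None:
            p = 2.0 * norm.sf(np.abs(tstat))
        else:
            p = 2.0 * t_dist.sf(np.abs(tstat), df_reference)
        q = fdr_qvalues(p)
        frames.append(pd.DataFrame({
            "snp": geno.markers["id"].to_numpy(),
            "chrom": geno.markers["chrom"].to_numpy(),
            "pos": geno.markers["pos"].to_numpy(),
            "trait": tr,
            "effect": s, "se": se_s, "t": tstat, "p": p, "q": q,
        }))
    return SNPScanResult(table=pd.concat(frames, ignore_index=True))


def fdr_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, q_(i) = min_{j>=i} m p_(j) / j.

    NaN p-values propagate to NaN q-values and do not count toward m.
    """
    p = np.asarray(pvalues, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def significant_snps(result: SNPScanResult, threshold: float = 0.01) -> SignificanceTable:
    """SNPs passing the per-trait FDR threshold, with per-trait counts."""
    tab = result.table
    sig = tab[tab["q"] < threshold].reset_index(drop=True)
    counts = sig.groupby("trait")["snp"].nunique().reindex(
        sorted(tab["trait"].unique()), fill_value=0
    )
    return SignificanceTable(table=sig, threshold=threshold, counts=counts)
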