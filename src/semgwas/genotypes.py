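"""Genotype I/O, marker quality control, and the genomic relationship matrix.

Dosages are minor-allele counts in {0, 1, 2} with NaN for missing calls.
The genomic relationship matrix follows the centered-dosage construction
G = WW' / 2 * sum_j p_j (1 - p_j), with W the column-centered dosage matrix
and p_j the sample allele frequency of marker j.  Population-structure
principal components are eigenvectors of the same centered matrix and are
used downstream to residualize the dosage columns before the association
scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "CenteredMatrix",
    "GRMatrix",
    "PCACorrection",
    "read_genotypes",
    "write_dosage_tsv",
    "filter_markers",
    "center_genotypes",
    "compute_grm",
    "compute_pcs",
]


@dataclass
class GenotypeMatrix:
    """An individuals x markers dosage panel with per-marker metadata.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, one per row of ``dosages``.
    dosages : ndarray of shape (n, m)
        Minor-allele counts in {0, 1, 2}; missing calls are NaN.
    markers : pandas.DataFrame
        One row per marker with columns ``id``, ``chrom``, ``pos``.
    """

    ids: list[str]
    dosages: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x markers array")
        if len(self.ids) != self.dosages.shape[0]:
            raise ValueError("number of ids does not match dosage rows")
        if len(self.markers) != self.dosages.shape[1]:
            raise ValueError("marker table does not match dosage columns")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual IDs")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele (non-missing calls only)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency in [0, 0.5]."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)


@dataclass
class CenteredMatrix:
    """Column-centered dosages w_ij = x_ij - 2 p_j, missing imputed to the mean."""

    W: np.ndarray
    freqs: np.ndarray


@dataclass
class GRMatrix:
    """Genomic relationship matrix G = WW'/denom with denom = 2 sum p_j(1-p_j)."""

    G: np.ndarray
    denom: float
    ids: list[str] = field(default_factory=list)


@dataclass
class PCACorrection:
    """Principal-component scores of the centered dosage matrix.

    ``k`` is the smallest number of components whose cumulative variance
    fraction reaches ``target`` (or a forced component count).
    """

    scores: np.ndarray
    variance_explained: np.ndarray
    k: int
    target: float


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    markers = pd.DataFrame(
        {"id": marker_ids, "chrom": "0", "pos": np.arange(1, len(marker_ids) + 1)}
    )
    dosages = df.to_numpy(dtype=float)
    return GenotypeMatrix(ids=ids, dosages=dosages, markers=markers)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple[str, str, int]] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = missing
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        meta.append((vid, variant.CHROM, variant.POS))
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multiallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic records found in {path}")
    dosages = np.vstack(rows).T
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    return GenotypeMatrix(ids=ids, dosages=dosages, markers=markers)


def read_genotypes(path: str, format: str = "dosage-tsv") -> GenotypeMatrix:
    """Read a genotype panel from a VCF or a plain dosage TSV.

    The dosage TSV has a header row of marker IDs and one row per
    individual, first column the individual ID.  VCF records that are not
    biallelic are skipped with a logged warning.
    """
    if format in ("dosage-tsv", "tsv"):
        return _read_dosage_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_dosage_tsv(g: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(g.dosages, index=g.ids, columns=list(g.markers["id"]))
    df.to_csv(path, sep="\t", na_rep="NA")


def filter_markers(
    g: GenotypeMatrix, min_call_rate: float = 0.95, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Marker QC: keep markers with call rate >= threshold and MAF >= threshold.

    Marker order is preserved; removal counts per criterion are logged.
    Raises if every marker is removed.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    cr_ok = g.call_rate >= min_call_rate
    maf_ok = g.maf >= min_maf
    keep = cr_ok & maf_ok
    logger.info(
        "marker QC: %d/%d retained (%d failed call rate, %d failed MAF)",
        int(keep.sum()), g.n_markers, int((~cr_ok).sum()), int((~maf_ok).sum()),
    )
    if not keep.any():
        raise ValueError("marker QC removed every marker (empty panel)")
    return GenotypeMatrix(
        ids=list(g.ids),
        dosages=g.dosages[:, keep],
        markers=g.markers.loc[keep].reset_index(drop=True),
    )


def center_genotypes(g: GenotypeMatrix) -> CenteredMatrix:
    """Center dosages to w_ij = x_ij - 2 p_j; missing cells become exactly 0.

    p_j is the sample frequency of the counted allele.  Monomorphic columns
    are rejected: they carry no information and break the GRM denominator —
    apply :func:`filter_markers` first.
    """
    p = g.allele_freq
    if np.any((p <= 0) | (p >= 1)) or np.any(np.isnan(p)):
        raise ValueError("monomorphic or all-missing marker present; run marker QC first")
    W = g.dosages - 2.0 * p
    W = np.where(np.isnan(W), 0.0, W)
    return CenteredMatrix(W=W, freqs=p)


def compute_grm(w: CenteredMatrix, ids: list[str] | None = None) -> GRMatrix:
    """G = WW' / (2 * sum_j p_j (1 - p_j))."""
    if w.W.size == 0:
        raise ValueError("empty centered matrix")
    denom = 2.0 * float(np.sum(w.freqs * (1.0 - w.freqs)))
    if denom <= 0:
        raise ValueError("non-positive GRM denominator; markers are monomorphic")
    G = (w.W @ w.W.T) / denom
    G = (G + G.T) / 2.0
    return GRMatrix(G=G, denom=denom, ids=list(ids) if ids else [])


def compute_pcs(
    g: GenotypeMatrix, target: float = 0.80, k: int | None = None
) -> PCACorrection:
    """Principal components of the centered dosage matrix.

    Directions coincide with the eigenvectors of G.  ``k`` defaults to the
    smallest component count whose cumulative variance fraction reaches
    ``target``; pass ``k`` to force a fixed count (e.g. 23 components for
    roughly 80% of the genetic variability on a real panel).
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target cumulative variance must lie in (0, 1]")
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals for PCA")
    # column-centered only, so variance fractions equal eigenvalues of G
    # normalized by trace(G)
    W = center_genotypes(g).W
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("centered dosage matrix has zero variance")
    frac = var / total
    if k is None:
        k_sel = int(np.searchsorted(np.cumsum(frac), target - 1e-12) + 1)
    else:
        if not (1 <= k <= len(frac)):
            raise ValueError("forced component count out of range")
        k_sel = int(k)
    scores = U * s
    return PCACorrection(
        scores=scores, variance_explained=frac, k=k_sel, target=target
    )
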