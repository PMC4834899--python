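"""Single-marker parent-of-origin scan.

For every marker the phenotype is regressed by ordinary least squares on an
intercept, the shared covariates and the maternal and paternal A1-allele
indicators; the reported test is the two-sided t-test of the contrast
``alpha_maternal - alpha_paternal = 0`` (the imprinting deviation of the
one-locus model).  Family-wise error across the p markers is controlled by
the Sidak threshold ``1 - (1 - alpha)^(1/p)`` and the significant set Phi
feeds the ADD_POE model.

Markers whose two parental indicators are collinear with each other or with
the covariates (e.g. no reciprocal-heterozygote contrast in the sample) are
flagged and excluded from testing with a warning.

The scan is vectorized: covariates are projected out of the phenotype and
of all marker columns once (Frisch-Waugh-Lovell), leaving a batched
2-predictor OLS per marker with the correct residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import OrderedGenotypes

__all__ = ["ScanResult", "scan_poe", "sidak_threshold", "select_phi"]

_RCOND = 1e-10


@dataclass
class ScanResult:
    """Per-marker estimates and the contrast test of maternal vs paternal effect."""

    table: pd.DataFrame  # marker, alpha_maternal, alpha_paternal, diff, se_diff,
                         # t_stat, p_value, tested

    def significant(self, threshold: float) -> np.ndarray:
        t = self.table
        return t.loc[t["tested"] & (t["p_value"] < threshold), "marker"].to_numpy()


def scan_poe(y: np.ndarray,
             genotypes: OrderedGenotypes,
             covariates: Optional[np.ndarray] = None) -> ScanResult:
    """OLS parent-of-origin contrast test for every marker.

    Parameters
    ----------
    y
        Phenotypes of the individuals in ``genotypes`` (same order).
    covariates
        Optional n x k matrix carried into each per-marker regression
        (an intercept is always included).
    """
    y = np.asarray(y, dtype=np.float64)
    n = genotypes.n_individuals
    if len(y) != n:
        raise ValueError("phenotype length does not match genotypes")
    Q = np.ones((n, 1))
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        Q = np.hstack([Q, covariates])
    k = Q.shape[1]
    if n <= k + 2:
        raise ValueError("need more observations than fitted coefficients")

    # project covariates out of y and the marker indicator columns
    Qq, _ = np.linalg.qr(Q)
    def _resid(Z):
        return Z - Qq @ (Qq.T @ Z)
    ry = _resid(y)
    Fm = _resid(genotypes.maternal.astype(np.float64))
    Fp = _resid(genotypes.paternal.astype(np.float64))

    # batched 2x2 normal equations per marker
    a = np.einsum("ij,ij->j", Fm, Fm)
    b = np.einsum("ij,ij->j", Fm, Fp)
    c = np.einsum("ij,ij->j", Fp, Fp)
    gm = Fm.T @ ry
    gp = Fp.T @ ry
    det = a * c - b * b
    scale = np.maximum(a, c)
    tested = det > _RCOND * np.maximum(scale, 1.0) ** 2
    n_bad = int((~tested).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} marker(s) excluded from the parent-of-origin scan: "
            "monomorphic or collinear parental indicators", stacklevel=2)

    det_safe = np.where(tested, det, 1.0)
    am = (c * gm - b * gp) / det_safe          # maternal substitution effect
    ap = (a * gp - b * gm) / det_safe          # paternal substitution effect
    rss = ry @ ry - (am * gm + ap * gp)
    dof = n - k - 2
    s2 = np.maximum(rss, 0.0) / dof
    # var(am - ap) = sigma2 * cT (X'X)^-1 c with c = (1, -1)
    var_diff = s2 * (a + c + 2.0 * b) / det_safe
    diff = am - ap
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = diff / np.sqrt(var_diff)
    p_val = 2.0 * stats.t.sf(np.abs(t_stat), dof)
    table = pd.DataFrame({
        "marker": genotypes.marker_ids,
        "alpha_maternal": np.where(tested, am, np.nan),
        "alpha_paternal": np.where(tested, ap, np.nan),
        "diff": np.where(tested, diff, np.nan),
        "se_diff": np.where(tested, np.sqrt(var_diff), np.nan),
        "t_stat": np.where(tested, t_stat, np.nan),
        "p_value": np.where(tested, p_val, np.nan),
        "tested": tested,
    })
    return ScanResult(table=table)


def sidak_threshold(alpha: float, p: int) -> float:
    """Per-test threshold 1 - (1 - alpha)^(1/p) controlling family-wise error."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if p < 1:
        raise ValueError("number of tests must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / p)


def select_phi(scan: ScanResult, threshold: float) -> np.ndarray:
    """Marker ids with p-value strictly below the threshold."""
    return scan.significant(threshold)
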