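"""Structural covariance norms and individualized differential SCN (IDSCN).

A structural covariance network (SCN) is the region x region partial
correlation of regional gray-matter volume across subjects, controlling for
age, gender and total intracranial volume.  The individualized differential
SCN of one patient is obtained by inserting that single patient into a
healthy-control norm, recomputing the SCN, and standardizing the elementwise
change

    Z = dSCN / ((1 - nSCN^2) / (n - 1))

where ``nSCN`` is the control-only norm, ``dSCN = pSCN - nSCN`` the change
caused by the inserted patient, and ``n`` the number of controls in the norm.
The formula is applied literally (no square root in the denominator), so |Z|
values are large by construction; they are compared against each other and
against permutation nulls, never against normal quantiles.

Norms are built per acquisition site to absorb scanner bias; patients are
only ever inserted into their own site's norm.  After computation, matrices
of right-lesion patients are mirrored homotopically so that the left
hemisphere slot always denotes ipsilesional cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .atlas import GMVTable, RegionAtlas, mirror_matrix

NSCN_GUARD = 1.0 - 1e-9  # |nSCN| above this is treated as singular


@dataclass(frozen=True)
class SCNMatrix:
    """Partial-correlation SCN with the control count it was built from."""

    r: np.ndarray
    n: int
    site: str = ""
    covariates: tuple[str, ...] = ("age", "gender", "tiv")

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("SCN matrix must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("SCN matrix must be symmetric")
        if self.n <= len(self.covariates) + 3:
            raise ValueError(
                f"n={self.n} controls insufficient for {len(self.covariates)} covariates"
            )
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class IDSCNResult:
    """Per-patient differential SCN and its Z standardization."""

    subject_id: str
    site: str
    delta: np.ndarray
    z: np.ndarray
    oriented: str = "native"  # "native" | "lesion-oriented"
    lesion_side: str = "none"


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of y on [1, centered covariates]."""
    n = y.shape[0]
    if covariates.size:
        c = covariates - covariates.mean(axis=0)
        X = np.column_stack([np.ones(n), c])
    else:
        X = np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_corr_matrix(
    values: np.ndarray,
    covariates: np.ndarray,
    region_names: list[str] | None = None,
) -> np.ndarray:
    """Region x region partial correlation controlling for covariates.

    Entry (i, j) is the Pearson correlation of the residuals of regions i
    and j after least-squares regression on the covariates plus intercept.
    Covariates are centered first (affects only the intercept).

    Parameters
    ----------
    values : (n_subjects, n_regions) array
    covariates : (n_subjects, n_covariates) array; may have zero columns,
        in which case the result is the plain Pearson correlation.
    """
    values = np.asarray(values, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n, p = values.shape
    if covariates.shape[0] != n:
        raise ValueError("values and covariates have different numbers of rows")
    if n <= covariates.shape[1] + 3:
        raise ValueError(
            f"need more than {covariates.shape[1] + 3} subjects, got {n}"
        )
    resid = _residualize(values, covariates)
    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        j = dead[0]
        name = region_names[j] if region_names else f"column {j}"
        raise ValueError(
            f"region {name} has (near-)constant residual after covariate removal"
        )
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def idscn_z(delta, nscn, n: int):
    """Standardize a differential-SCN entry into a Z score.

    ``Z = delta / ((1 - nscn**2) / (n - 1))`` applied elementwise; the
    diagonal of matrix inputs is forced to zero.  Raises when the norm entry
    is at +/-1 (zero denominator) or n < 2.
    """
    if n < 2:
        raise ValueError(f"need at least 2 controls in the norm, got n={n}")
    delta = np.asarray(delta, dtype=float)
    nscn = np.asarray(nscn, dtype=float)
    off = ~np.eye(nscn.shape[0], dtype=bool) if nscn.ndim == 2 else slice(None)
    if np.any(np.abs(nscn[off] if nscn.ndim == 2 else nscn) > NSCN_GUARD):
        raise ValueError("norm SCN entry at +/-1: Z denominator vanishes")
    denom = (1.0 - nscn**2) / (n - 1)
    if nscn.ndim == 2:
        z = np.zeros_like(delta)
        z[off] = delta[off] / denom[off]
        return z
    return float(delta / denom)


class IDSCN(BaseEstimator):
    """Individualized differential SCN transformer.

    Fit on healthy-control GMV (building the partial-correlation norm),
    then transform patients one at a time into Z matrices by single-subject
    insertion.

    Parameters
    ----------
    guard : float
        Norm entries with ``|r|`` above this are treated as singular.

    Attributes (after fit)
    ----------------------
    norm_ : (R, R) ndarray — control-only partial-correlation SCN (nSCN).
    n_ : int — number of controls in the norm (the ``n`` of the Z formula).
    n_features_in_ : int — number of regions R.
    """

    def __init__(self, guard: float = NSCN_GUARD):
        self.guard = guard

    def fit(self, X: np.ndarray, y=None, *, covariates: np.ndarray = None):
        X = np.asarray(X, dtype=float)
        if covariates is None:
            covariates = np.empty((X.shape[0], 0))
        covariates = np.asarray(covariates, dtype=float)
        self.norm_ = partial_corr_matrix(X, covariates)
        self.n_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self._X = X
        self._covariates = covariates
        return self

    def perturbed(self, x: np.ndarray, cov: np.ndarray) -> np.ndarray:
        """SCN over (controls + this one subject): the pSCN."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("patient row length does not match norm regions")
        cov = np.asarray(cov, dtype=float).reshape(1, -1)
        return partial_corr_matrix(
            np.vstack([self._X, x]), np.vstack([self._covariates, cov])
        )

    def transform(
        self, X: np.ndarray, *, covariates: np.ndarray = None
    ) -> np.ndarray:
        """Z matrices, one per row of X, by single-subject insertion."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if covariates is None:
            covariates = np.empty((X.shape[0], 0))
        covariates = np.asarray(covariates, dtype=float)
        out = np.empty((X.shape[0], self.n_features_in_, self.n_features_in_))
        for k in range(X.shape[0]):
            delta = self.perturbed(X[k], covariates[k]) - self.norm_
            out[k] = idscn_z(delta, self.norm_, self.n_)
        return out

    def fit_transform(self, X, y=None, **kw):  # controls in, controls out
        return self.fit(X, **kw).transform(X, **kw)


def build_norms(cohort: GMVTable) -> dict[str, SCNMatrix]:
    """One control-only SCN norm per site.

    Raises if any site has too few controls for the three covariates.
    """
    norms = {}
    for site in cohort.sites:
        mask = cohort.mask(group="control", site=site)
        n = int(mask.sum())
        if n <= 3 + 3:
            raise ValueError(
                f"site {site!r} has only {n} controls; need more than 6 "
                "for a 3-covariate partial correlation"
            )
        r = partial_corr_matrix(
            cohort.values[mask],
            cohort.covariate_matrix(mask),
            region_names=cohort.atlas.names,
        )
        norms[site] = SCNMatrix(r=r, n=n, site=site)
    return norms


def perturbed_scn(
    controls: GMVTable, patient_values: np.ndarray, patient_covariates: np.ndarray
) -> SCNMatrix:
    """SCN over (site controls + one patient); n stays the HC count."""
    values = np.vstack([controls.values, np.asarray(patient_values).reshape(1, -1)])
    cov = np.vstack(
        [controls.covariate_matrix(), np.asarray(patient_covariates).reshape(1, -1)]
    )
    r = partial_corr_matrix(values, cov, region_names=controls.atlas.names)
    return SCNMatrix(r=r, n=controls.n_subjects, site=controls.subjects[0].site)


def orient_patient(result: IDSCNResult, lesion_side: str, atlas: RegionAtlas) -> IDSCNResult:
    """Mirror right-lesion matrices so the left slot is always ipsilesional.

    Left-lesion patients pass through unchanged.  Applying orientation to an
    already oriented result raises.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(f"cannot orient lesion_side={lesion_side!r}")
    if result.oriented == "lesion-oriented":
        raise ValueError(f"patient {result.subject_id} is already lesion-oriented")
    if lesion_side == "left":
        return replace(result, oriented="lesion-oriented", lesion_side=lesion_side)
    return replace(
        result,
        delta=mirror_matrix(result.delta, atlas),
        z=mirror_matrix(result.z, atlas),
        oriented="lesion-oriented",
        lesion_side=lesion_side,
    )


def compute_idscn(cohort: GMVTable, orient: bool = True) -> list[IDSCNResult]:
    """Per-patient IDSCN for a whole multi-site cohort.

    For each patient: perturbed SCN against the own-site control norm, the
    differential SCN, the Z matrix, then lesion-side orientation (right
    lesions mirrored).  Deterministic; results keyed by subject order.
    """
    patient_mask = cohort.mask(group="patient")
    if not patient_mask.any():
        return []
    sites_with_patients = sorted(
        {s.site for s in cohort.subjects if s.group == "patient"}
    )
    estimators: dict[str, IDSCN] = {}
    for site in sites_with_patients:
        cmask = cohort.mask(group="control", site=site)
        if cmask.sum() <= 6:
            raise ValueError(f"site {site!r} has too few controls to build a norm")
        est = IDSCN().fit(
            cohort.values[cmask], covariates=cohort.covariate_matrix(cmask)
        )
        estimators[site] = est
    results = []
    for idx in np.flatnonzero(patient_mask):
        subj = cohort.subjects[idx]
        est = estimators[subj.site]
        delta = est.perturbed(
            cohort.values[idx], cohort.covariate_matrix()[idx]
        ) - est.norm_
        z = idscn_z(delta, est.norm_, est.n_)
        res = IDSCNResult(
            subject_id=subj.subject_id,
            site=subj.site,
            delta=delta,
            z=z,
            lesion_side=subj.lesion_side,
        )
        if orient:
            res = orient_patient(res, subj.lesion_side, cohort.atlas)
        results.append(res)
    return results


def z_stack(results: list[IDSCNResult]) -> np.ndarray:
    """Stack patient Z matrices into (n_patients, R, R)."""
    return np.stack([r.z for r in results])
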