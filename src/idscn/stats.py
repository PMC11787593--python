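"""Downstream analyses on the significant network and the cohort.

Covers: hemisphere / subnetwork decomposition of aberrant edges, regional
GMV group comparison with an effective-number-of-tests FWE threshold,
GMV-network association (Spearman, FDR), clinical partial correlations, and
the demographic table statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import CLINICAL_SCORES, GMVTable, RegionAtlas, mirror_vector
from .nbs import NBSResult
from .scn import IDSCNResult, _residualize


# ---------------------------------------------------------------------------
# edge classification

#: after lesion orientation the left-hemisphere slot denotes ipsilesional
HEMI_CLASS = {"left": "ipsilesional", "right": "contralesional"}


def classify_edges(
    edges: list[dict], atlas: RegionAtlas, oriented: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Label significant edges by hemisphere class and subnet pair.

    Parameters
    ----------
    edges : list of dicts as produced by ``nbs_run`` (``significant_edges``),
        each with region indices (atlas positions), sign, statistics.
    oriented : matrices must be lesion-oriented for the ipsi/contra reading.

    Returns
    -------
    (per-edge table, hemisphere x sign counts, subnet-pair x sign counts,
     node degree table)
    """
    if not oriented:
        raise ValueError("edge classification requires lesion-oriented matrices")
    hemis = atlas.hemispheres
    subnets = atlas.subnets
    names = atlas.names
    rows = []
    for e in edges:
        i, j = e["region_i"], e["region_j"]
        hi, hj = hemis[i], hemis[j]
        if hi != hj:
            hclass = "interhemispheric"
        else:
            hclass = HEMI_CLASS[hi]
        pair = " - ".join(sorted([subnets[i], subnets[j]]))
        rows.append(
            {
                **e,
                "name_i": names[i],
                "name_j": names[j],
                "hemisphere_class": hclass,
                "subnet_pair": pair,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        empty = pd.DataFrame()
        return table, empty, empty, empty
    hemi_counts = (
        table.pivot_table(
            index="hemisphere_class", columns="sign", aggfunc="size", fill_value=0
        )
        .rename_axis(columns=None)
    )
    subnet_counts = (
        table.pivot_table(
            index="subnet_pair", columns="sign", aggfunc="size", fill_value=0
        )
        .rename_axis(columns=None)
    )
    degree = (
        pd.concat([table.region_i, table.region_j])
        .value_counts()
        .rename_axis("region")
        .reset_index(name="degree")
    )
    degree["name"] = [names[r] for r in degree.region]
    return table, hemi_counts, subnet_counts, degree


# ---------------------------------------------------------------------------
# regional GMV group analysis


@dataclass
class RegionGMVStats:
    region: int
    name: str
    t: float
    p: float
    direction: str  # "atrophy" | "increase"
    significant_after_fwe: bool


def oriented_patient_values(cohort: GMVTable) -> np.ndarray:
    """Patient GMV rows with right-lesion rows homotopically mirrored."""
    pat = cohort.mask(group="patient")
    vals = cohort.values[pat].copy()
    sides = [s.lesion_side for s in cohort.subjects if s.group == "patient"]
    for k, side in enumerate(sides):
        if side == "right":
            vals[k] = mirror_vector(vals[k], cohort.atlas)
    return vals


def effective_tests(corr: np.ndarray) -> float:
    """Li-Ji effective number of independent tests from a correlation matrix.

    ``Meff = sum_i [ 1{lam_i >= 1} + frac(lam_i) ]`` over the eigenvalues of
    the correlation matrix; equals R for the identity and 1 for perfect
    redundancy.
    """
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    if lam.min() < -1e-6:
        raise ValueError("correlation matrix is not positive semidefinite")
    # round before floor: an eigenvalue that is 2 up to machine precision
    # must contribute frac 0, not frac ~1
    lam = np.round(np.abs(lam), 9)
    meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return float(np.clip(meff, 1.0, corr.shape[0]))


def gmv_group_test(
    cohort: GMVTable, alpha: float = 0.05
) -> tuple[list[RegionGMVStats], float]:
    """Per-region two-sample t (oriented patients vs controls) with Li-Ji FWE.

    Returns the per-region statistics and the Meff actually used; the FWE
    threshold is ``alpha / Meff``, with Meff estimated from the region
    correlation of the pooled (oriented) GMV matrix.
    """
    ctrl = cohort.values[cohort.mask(group="control")]
    pat = oriented_patient_values(cohort)
    if len(ctrl) == 0 or len(pat) == 0:
        raise ValueError("both groups must be nonempty")
    if (ctrl.std(axis=0) < 1e-12).any() or (pat.std(axis=0) < 1e-12).any():
        raise ValueError("zero-variance region")
    t, p = stats.ttest_ind(pat, ctrl, axis=0, equal_var=True)
    pooled = np.vstack([pat, ctrl])
    meff = effective_tests(np.corrcoef(pooled, rowvar=False))
    thr = alpha / meff
    out = []
    for k in range(cohort.atlas.n_regions):
        out.append(
            RegionGMVStats(
                region=k,
                name=cohort.atlas.names[k],
                t=float(t[k]),
                p=float(p[k]),
                direction="atrophy" if pat[:, k].mean() < ctrl[:, k].mean() else "increase",
                significant_after_fwe=bool(p[k] < thr),
            )
        )
    return out, meff


# ---------------------------------------------------------------------------
# GMV-network association


def adjusted_gmv_z(cohort: GMVTable) -> np.ndarray:
    """Patient GMV as covariate-adjusted z-scores against own-site controls.

    Per site: regress control GMV on [age, gender, TIV]; a patient's score
    at each region is the residual of the patient under the control fit,
    divided by the control residual SD.  Right-lesion rows are mirrored
    afterwards so the left slot is ipsilesional.
    """
    patients = [s for s in cohort.subjects if s.group == "patient"]
    out = np.empty((len(patients), cohort.atlas.n_regions))
    row = 0
    all_cov = cohort.covariate_matrix()
    for idx, subj in enumerate(cohort.subjects):
        if subj.group != "patient":
            continue
        cmask = cohort.mask(group="control", site=subj.site)
        C = cohort.values[cmask]
        cov_c = cohort.covariate_matrix(cmask)
        mean_cov = cov_c.mean(axis=0)
        Xc = np.column_stack([np.ones(len(C)), cov_c - mean_cov])
        beta, *_ = np.linalg.lstsq(Xc, C, rcond=None)
        resid_c = C - Xc @ beta
        sd = resid_c.std(axis=0, ddof=1)
        xp = np.concatenate([[1.0], all_cov[idx] - mean_cov])
        z = (cohort.values[idx] - xp @ beta) / sd
        if subj.lesion_side == "right":
            z = mirror_vector(z, cohort.atlas)
        out[row] = z
        row += 1
    return out


def nodal_idscn(
    results: list[IDSCNResult], nbs_result: NBSResult, reduce: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient nodal summary: mean (or sum of) Z over each region's
    NBS-significant incident edges.

    Returns (patients x regions matrix, per-region significant-edge degree);
    regions with no significant incident edge get NaN.
    """
    R = results[0].z.shape[0]
    deg = np.zeros(R, dtype=int)
    incident: dict[int, list[tuple[int, int]]] = {k: [] for k in range(R)}
    for e in nbs_result.significant_edges:
        i, j = e["region_i"], e["region_j"]
        deg[i] += 1
        deg[j] += 1
        incident[i].append((i, j))
        incident[j].append((i, j))
    out = np.full((len(results), R), np.nan)
    for m, res in enumerate(results):
        for k in range(R):
            if deg[k]:
                vals = [res.z[i, j] for (i, j) in incident[k]]
                out[m, k] = np.sum(vals) if reduce == "sum" else np.mean(vals)
    return out, deg


def bh_fdr(p_list) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the 0.05 mask."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q, reject


@dataclass
class AssociationResult:
    label: str
    rho: float
    p: float
    q: float
    n: int
    sign: str

    def as_dict(self):
        return {
            "label": self.label,
            "rho": self.rho,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "sign": self.sign,
        }


def gmv_idscn_association(
    cohort: GMVTable,
    idscn_results: list[IDSCNResult],
    nbs_result: NBSResult,
    mode: str = "per_region_across_patients",
    min_patients: int = 5,
) -> list[AssociationResult]:
    """Spearman association between regional GMV change and network deviation.

    ``per_region_across_patients`` (default): for each region touched by at
    least one significant edge, correlate across patients the covariate-
    adjusted GMV z-score with the nodal mean Z; BH-FDR across regions.

    ``spatial_across_regions``: a single correlation across regions between
    the group GMV t-map and the nodal mean |Z| map.
    """
    if mode == "spatial_across_regions":
        region_stats, _ = gmv_group_test(cohort)
        tmap = np.array([r.t for r in region_stats])
        nodal, deg = nodal_idscn(idscn_results, nbs_result)
        keep = deg > 0
        if keep.sum() < 3:
            return []
        zmap = np.nanmean(np.abs(nodal[:, keep]), axis=0)
        rho, p = stats.spearmanr(tmap[keep], zmap)
        return [
            AssociationResult(
                label="spatial", rho=float(rho), p=float(p), q=float(p),
                n=int(keep.sum()), sign="positive" if rho > 0 else "negative",
            )
        ]
    if mode != "per_region_across_patients":
        raise ValueError(f"unknown mode {mode!r}")
    gmv_z = adjusted_gmv_z(cohort)
    nodal, deg = nodal_idscn(idscn_results, nbs_result)
    labels, rhos, ps, ns = [], [], [], []
    for k in np.flatnonzero(deg > 0):
        x, y = gmv_z[:, k], nodal[:, k]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_patients:
            raise ValueError(
                f"region {cohort.atlas.names[k]} has fewer than "
                f"{min_patients} contributing patients"
            )
        rho, p = stats.spearmanr(x[ok], y[ok])
        labels.append(cohort.atlas.names[k])
        rhos.append(float(rho))
        ps.append(float(p))
        ns.append(int(ok.sum()))
    if not labels:
        return []
    q, _ = bh_fdr(ps)
    return [
        AssociationResult(
            label=l, rho=r, p=p, q=float(qq), n=n,
            sign="positive" if r > 0 else "negative",
        )
        for l, r, p, qq, n in zip(labels, rhos, ps, q, ns)
    ]


# ---------------------------------------------------------------------------
# clinical associations


def partial_corr(x: np.ndarray, y: np.ndarray, covariates: np.ndarray,
                 rank: bool = False) -> tuple[float, float, int]:
    """Partial correlation of x and y given covariates.

    Pearson correlation of the residuals of both variables on the covariate
    design (with intercept); p from the t transform with
    ``df = m - n_covariates - 2``.  ``rank=True`` rank-transforms first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if rank:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        covariates = np.column_stack(
            [stats.rankdata(c) for c in covariates.T]
        )
    m = len(x)
    k = covariates.shape[1]
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise ValueError("constant variable in partial correlation")
    rx = _residualize(x[:, None], covariates)[:, 0]
    ry = _residualize(y[:, None], covariates)[:, 0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = m - k - 2
    if df <= 0:
        raise ValueError("not enough observations for partial correlation")
    tstat = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(tstat), df=df))
    return r, p, df


def clinical_partial_corr(
    summaries: dict[str, np.ndarray],
    clinical: pd.DataFrame,
    age: np.ndarray,
    gender: np.ndarray,
    min_patients: int = 10,
    rank: bool = False,
    fallback_alpha: float = 0.01,
) -> pd.DataFrame:
    """Partial correlations of network summaries with clinical scores.

    Parameters
    ----------
    summaries : mapping label -> per-patient network value (nodal or edge).
    clinical : per-patient score table (columns are score names; NaN = missing).
    age, gender : covariates, aligned to patients (gender as 0/1).

    Missing scores are dropped pairwise; BH-FDR is applied within each
    clinical score family; significance is also reported at the uncorrected
    fallback threshold.
    """
    rows = []
    gender = np.asarray(gender, dtype=float)
    for score in clinical.columns:
        s = clinical[score].to_numpy(dtype=float)
        fam = []
        for label, vals in summaries.items():
            vals = np.asarray(vals, dtype=float)
            ok = np.isfinite(s) & np.isfinite(vals)
            if ok.sum() < min_patients:
                continue
            if np.nanstd(s[ok]) < 1e-12:
                raise ValueError(f"constant clinical score {score!r}")
            r, p, df = partial_corr(
                vals[ok], s[ok], np.column_stack([age[ok], gender[ok]]), rank=rank
            )
            fam.append({"score": score, "label": label, "r": r, "p": p,
                        "n": int(ok.sum()), "df": df})
        if fam:
            q, rej = bh_fdr([f["p"] for f in fam])
            for f, qq, rr in zip(fam, q, rej):
                f["q"] = float(qq)
                f["significant_fdr"] = bool(rr)
                f["significant_uncorrected"] = bool(f["p"] < fallback_alpha)
            rows.extend(fam)
    return pd.DataFrame(
        rows,
        columns=["score", "label", "r", "p", "q", "n", "df",
                 "significant_fdr", "significant_uncorrected"],
    )


# ---------------------------------------------------------------------------
# demographics


def t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics."""
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), float(p)


def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction, as Z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1))))
    z = (u - mu) / sigma
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def demography_tests(cohort: GMVTable, normality_alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison table: t or Mann-Whitney per continuous variable
    (chosen by a KS normality check), chi-square for gender.

    Mirrors the usual demographic table layout: one row per variable with
    the statistic name, value and p.
    """
    pat = [s for s in cohort.subjects if s.group == "patient"]
    ctl = [s for s in cohort.subjects if s.group == "control"]
    if len(pat) < 3 or len(ctl) < 3:
        raise ValueError("each group needs at least 3 subjects")
    rows = []

    def _continuous(name, xv, yv):
        xv, yv = np.asarray(xv, float), np.asarray(yv, float)
        normal = True
        for v in (xv, yv):
            vv = (v - v.mean()) / max(v.std(ddof=1), 1e-12)
            if stats.kstest(vv, "norm").pvalue < normality_alpha:
                normal = False
        if normal:
            t, p = stats.ttest_ind(xv, yv, equal_var=True)
            rows.append({"variable": name, "test": "t", "statistic": float(t),
                         "p": float(p), "n_patient": len(xv), "n_control": len(yv)})
        else:
            z, p = mannwhitney_z(xv, yv)
            rows.append({"variable": name, "test": "Z", "statistic": z,
                         "p": p, "n_patient": len(xv), "n_control": len(yv)})

    _continuous("age", [s.age for s in pat], [s.age for s in ctl])
    _continuous("tiv", [s.tiv for s in pat], [s.tiv for s in ctl])
    table = np.array(
        [
            [sum(s.gender == "M" for s in pat), sum(s.gender == "F" for s in pat)],
            [sum(s.gender == "M" for s in ctl), sum(s.gender == "F" for s in ctl)],
        ]
    )
    chi2, p = chi_square_counts(table)
    rows.append({"variable": "gender", "test": "chi2", "statistic": chi2,
                 "p": p, "n_patient": len(pat), "n_control": len(ctl)})
    for score in CLINICAL_SCORES:
        xv = [s.clinical[score] for s in pat if score in s.clinical]
        yv = [s.clinical[score] for s in ctl if score in s.clinical]
        if len(xv) >= 3 and len(yv) >= 3:
            _continuous(score, xv, yv)
    return pd.DataFrame(rows)
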