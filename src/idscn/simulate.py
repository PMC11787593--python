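"""Multi-site synthetic GMV cohort generator with known ground truth.

Emulates the data the pipeline consumes in the real study design: regional
gray-matter volumes for patients and healthy controls scanned at several
sites, with

* block covariance by subnetwork plus extra homotopic coupling,
* additive age/TIV and gender effects on every region,
* per-site offset and scale (scanner bias),
* patient-specific regional atrophy applied on the lesion side,
* patient-specific edge-covariance perturbations (the signal the
  individualized differential-network analysis must recover),
* clinical scores linearly coupled to the patients' true nodal deviations.

Defaults mirror the study conditions: 218 regions, 4 sites, 112 patients and
122 controls in total, ages uniform on 40-75 years.  Everything downstream
is validated against the stored :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    CLINICAL_SCORES,
    GMVTable,
    RegionAtlas,
    SubjectRecord,
    default_atlas,
    load_cohort,
    write_cohort,
)

Edge = tuple[int, int]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the cohort.

    Region units are mL.  ``site_offsets``/``site_scales`` model scanner
    bias; correlations are on the generating (pre-noise) scale.
    """

    n_regions: int = 218
    n_controls_per_site: tuple[int, ...] = (31, 31, 30, 30)   # total 122
    n_patients_per_site: tuple[int, ...] = (28, 28, 28, 28)   # total 112
    sites: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    site_offsets: tuple[float, ...] = (0.0, 0.15, -0.1, 0.05)
    site_scales: tuple[float, ...] = (1.0, 1.05, 0.95, 1.02)
    rho_within: float = 0.35
    rho_between: float = 0.10
    rho_homotopic: float = 0.25
    beta_age: float = -0.01      # mL per year
    beta_tiv: float = 0.002      # mL per mL TIV
    delta_gender: float = 0.15   # mL, male minus female
    p_male: float = 0.65
    age_range: tuple[float, float] = (40.0, 75.0)
    tiv_mean: float = 1450.0
    tiv_sd: float = 120.0
    baseline_gmv: float = 5.0    # mean regional GMV, mL
    region_sd: float = 0.6       # marginal SD of regional GMV, mL
    atrophy_regions: tuple[int, ...] = ()   # region_ids, left-hemisphere slots
    atrophy_d: float = 0.0                  # standardized mean decrease
    perturbed_edges: tuple[Edge, ...] = ()  # canonical (i<j) region_id pairs
    edge_delta: float = 0.0                 # signed correlation change
    clinical_coupling: dict = field(default_factory=dict)  # score -> weight
    clinical_noise_sd: float = 1.0
    noise_sd: float = 0.05       # iid measurement noise, mL
    seed: int = 0

    def __post_init__(self):
        for rho in (self.rho_within, self.rho_between, self.rho_homotopic):
            if abs(rho) >= 1:
                raise ValueError("correlation magnitudes must be < 1")
        if not (
            len(self.sites)
            == len(self.n_controls_per_site)
            == len(self.n_patients_per_site)
            == len(self.site_offsets)
            == len(self.site_scales)
        ):
            raise ValueError("per-site fields must all have the same length")


@dataclass
class GroundTruth:
    """What the generator actually injected, in canonical (i<j) region ids."""

    perturbed_edges: list[tuple[int, int, float]]  # (i, j, signed delta)
    atrophy_regions: list[int]
    atrophy_d: float
    control_correlation: np.ndarray | None = None
    patient_correlation: np.ndarray | None = None


def nearest_positive_definite(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to PD, then renormalize diagonal."""
    corr = (corr + corr.T) / 2.0
    lam, V = np.linalg.eigh(corr)
    if lam.min() >= floor:
        return corr
    lam = np.clip(lam, floor, None)
    fixed = (V * lam) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def build_covariance(
    config: SimulationConfig, atlas: RegionAtlas, group: str, project: bool = True
) -> np.ndarray:
    """Generating correlation matrix for one group.

    Within-subnet blocks get ``rho_within``, cross-subnet entries
    ``rho_between``, homotopic pairs an extra ``rho_homotopic``; for
    patients, ``perturbed_edges`` are shifted by ``edge_delta`` before the
    positive-definite projection.  ``project=False`` returns the raw block
    construction (useful for inspecting the injected differences).
    """
    R = atlas.n_regions
    subnets = atlas.subnets
    corr = np.full((R, R), config.rho_between)
    same = subnets[:, None] == subnets[None, :]
    corr[same] = config.rho_within
    perm = atlas.mirror_permutation()
    for i in range(R):
        j = perm[i]
        corr[i, j] += config.rho_homotopic
    if group == "patient" and config.perturbed_edges:
        pos = {rid: k for k, rid in enumerate(atlas.region_ids)}
        for (a, b) in config.perturbed_edges:
            i, j = pos[a], pos[b]
            corr[i, j] += config.edge_delta
            corr[j, i] += config.edge_delta
    corr = np.clip(corr, -0.99, 0.99)
    np.fill_diagonal(corr, 1.0)
    if not project:
        return corr
    corr = nearest_positive_definite(corr)
    lam = np.linalg.eigvalsh(corr)
    if lam.min() <= 0:
        raise ValueError("covariance projection failed to reach positive definiteness")
    return corr


def _canonical_edges(edges, atlas: RegionAtlas) -> list[tuple[int, int]]:
    ids = set(atlas.region_ids.tolist())
    out = []
    for (a, b) in edges:
        if a not in ids or b not in ids:
            raise ValueError(f"edge ({a},{b}) references a region not in the atlas")
        out.append((min(a, b), max(a, b)))
    return out


def simulate_cohort(
    config: SimulationConfig, atlas: RegionAtlas | None = None
) -> tuple[GMVTable, GroundTruth]:
    """Draw a full multi-site cohort; identical seed gives identical output."""
    if atlas is None:
        atlas = default_atlas(config.n_regions)
    if atlas.n_regions != config.n_regions:
        raise ValueError("atlas size does not match config.n_regions")
    rng = np.random.default_rng(config.seed)
    pos = {rid: k for k, rid in enumerate(atlas.region_ids)}
    for rid in config.atrophy_regions:
        if rid not in pos:
            raise ValueError(f"atrophy region {rid} not in atlas")
    corr_hc = build_covariance(config, atlas, "control")
    corr_pt = build_covariance(config, atlas, "patient")
    perm = atlas.mirror_permutation()
    # perturbed edges are specified in ipsilesional (left-slot) coordinates;
    # right-lesion patients carry the homotopically mirrored perturbation,
    # so lesion orientation downstream re-aligns the signal
    corr_pt_right = corr_pt[np.ix_(perm, perm)]
    chol = {("control", "left"): np.linalg.cholesky(corr_hc),
            ("control", "right"): np.linalg.cholesky(corr_hc),
            ("patient", "left"): np.linalg.cholesky(corr_pt),
            ("patient", "right"): np.linalg.cholesky(corr_pt_right)}
    atrophy_idx = np.array([pos[r] for r in config.atrophy_regions], dtype=int)

    subjects, rows = [], []
    counter = 0
    for s, site in enumerate(config.sites):
        plan = [("control", config.n_controls_per_site[s]),
                ("patient", config.n_patients_per_site[s])]
        for group, n in plan:
            for _ in range(n):
                counter += 1
                age = rng.uniform(*config.age_range)
                gender = "M" if rng.random() < config.p_male else "F"
                tiv = rng.normal(config.tiv_mean, config.tiv_sd)
                lesion_side = "none"
                if group == "patient":
                    lesion_side = "left" if rng.random() < 0.5 else "right"
                draw_side = lesion_side if lesion_side != "none" else "left"
                z = chol[(group, draw_side)] @ rng.standard_normal(config.n_regions)
                gmv = config.baseline_gmv + config.region_sd * z
                gmv = (
                    gmv
                    + config.beta_age * (age - np.mean(config.age_range))
                    + config.beta_tiv * (tiv - config.tiv_mean)
                    + (config.delta_gender if gender == "M" else 0.0)
                )
                nodal_dev = np.zeros(config.n_regions)
                if group == "patient":
                    idx = atrophy_idx
                    if lesion_side == "right" and idx.size:
                        idx = perm[idx]  # atrophy follows the lesioned side
                    gmv = gmv.copy()
                    gmv[idx] -= config.atrophy_d * config.region_sd
                    nodal_dev[idx] = -config.atrophy_d
                gmv = gmv + rng.normal(0.0, config.noise_sd, config.n_regions)
                gmv = gmv * config.site_scales[s] + config.site_offsets[s]
                gmv = np.maximum(gmv, 1e-3)  # GMV is strictly positive
                clinical = {}
                if group == "patient":
                    clinical = _draw_clinical(config, nodal_dev, rng)
                subjects.append(
                    SubjectRecord(
                        subject_id=f"sub-{counter:04d}",
                        group=group,
                        site=site,
                        age=float(age),
                        gender=gender,
                        tiv=float(tiv),
                        lesion_side=lesion_side,
                        clinical=clinical,
                    )
                )
                rows.append(gmv)

    cohort = GMVTable(subjects, np.array(rows), atlas)
    truth = GroundTruth(
        perturbed_edges=[
            (i, j, config.edge_delta)
            for (i, j) in _canonical_edges(config.perturbed_edges, atlas)
        ],
        atrophy_regions=sorted(config.atrophy_regions),
        atrophy_d=config.atrophy_d,
        control_correlation=corr_hc,
        patient_correlation=corr_pt,
    )
    return cohort, truth


_CLINICAL_BASE = {
    "FMT": (96.0, (0.0, 100.0)),
    "F_RT": (560.0, (100.0, None)),
    "F_ACC": (0.97, (0.0, 1.0)),
    "N_RT": (800.0, (100.0, None)),
    "N_ACC": (0.93, (0.0, 1.0)),
    "S_RT": (860.0, (100.0, None)),
    "S_ACC": (0.92, (0.0, 1.0)),
}


def _draw_clinical(config, nodal_dev: np.ndarray, rng) -> dict:
    """Scores = baseline + coupling * (summed true nodal deviation) + noise.

    Bounded scores (accuracies, motor total) are clamped to their range.
    """
    total_dev = float(nodal_dev.sum())
    out = {}
    for score, (base, (lo, hi)) in _CLINICAL_BASE.items():
        w = config.clinical_coupling.get(score, 0.0)
        scale = 0.01 * base if "ACC" in score else (1.0 if score == "FMT" else 30.0)
        val = base + w * total_dev + rng.normal(0.0, config.clinical_noise_sd * scale)
        if lo is not None:
            val = max(val, lo)
        if hi is not None:
            val = min(val, hi)
        out[score] = float(val)
    return out


# ---------------------------------------------------------------------------
# fixture round trip


def write_fixture(
    cohort: GMVTable, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write atlas/GMV/metadata interface files plus a ground-truth sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "atlas": d / "atlas.tsv",
        "gmv": d / "gmv.tsv",
        "metadata": d / "metadata.tsv",
        "truth": d / "ground_truth.tsv",
    }
    cohort.atlas.to_frame().to_csv(paths["atlas"], sep="\t", index=False)
    write_cohort(cohort, paths["gmv"], paths["metadata"])
    recs = [
        {"kind": "edge", "region_i": i, "region_j": j, "value": delta}
        for (i, j, delta) in truth.perturbed_edges
    ] + [
        {"kind": "atrophy", "region_i": r, "region_j": "", "value": truth.atrophy_d}
        for r in truth.atrophy_regions
    ]
    pd.DataFrame(recs, columns=["kind", "region_i", "region_j", "value"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    edges = [
        (int(r.region_i), int(r.region_j), float(r.value))
        for r in df[df.kind == "edge"].itertuples()
    ]
    atrophy = df[df.kind == "atrophy"]
    d = float(atrophy.value.iloc[0]) if len(atrophy) else 0.0
    return GroundTruth(
        perturbed_edges=edges,
        atrophy_regions=sorted(int(r) for r in atrophy.region_i),
        atrophy_d=d,
    )


def load_fixture(directory: str | Path) -> tuple[GMVTable, GroundTruth]:
    from .atlas import load_atlas

    d = Path(directory)
    atlas = load_atlas(d / "atlas.tsv")
    cohort = load_cohort(d / "gmv.tsv", d / "metadata.tsv", atlas)
    truth = read_truth(d / "ground_truth.tsv")
    return cohort, truth
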