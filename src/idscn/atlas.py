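"""Region atlas and cohort data model.

The analysis operates on a parcellated cortex: an ordered list of regions,
each with a hemisphere, a homotopic (mirror-symmetric) partner in the
opposite hemisphere, and a Yeo-style subnetwork label.  The atlas defines
matrix row/column order for every network downstream.

The shipped 218-region default atlas is *synthetic*: the pairing and the
eight-subnetwork labels are constructed, not taken from any published
parcellation, and serve only to exercise the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SUBNETS = ("AN", "CN", "DMN", "DAN", "LN", "SMN", "VAN", "VN")
HEMISPHERES = ("left", "right")
LESION_SIDES = ("left", "right", "none")
CLINICAL_SCORES = ("FMT", "F_RT", "F_ACC", "N_RT", "N_ACC", "S_RT", "S_ACC")

ATLAS_COLUMNS = ["region_id", "name", "hemisphere", "homotopic_partner_id", "subnet"]
META_COLUMNS = ["subject_id", "group", "site", "age", "gender", "tiv", "lesion_side"]


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates a structural invariant."""


class CohortValidationError(ValueError):
    """Raised when GMV/metadata tables are inconsistent or malformed."""


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    hemisphere: str
    homotopic_partner_id: int
    subnet: str


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region list; order defines matrix rows/columns.

    Attributes
    ----------
    regions : tuple of Region
    """

    regions: tuple[Region, ...]

    def __post_init__(self):
        if len(self.regions) < 4 or len(self.regions) % 2:
            raise AtlasValidationError(
                f"atlas must have an even number of regions >= 4, got {len(self.regions)}"
            )
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise AtlasValidationError("region_ids are not unique")
        by_id = {r.region_id: r for r in self.regions}
        for r in self.regions:
            if r.hemisphere not in HEMISPHERES:
                raise AtlasValidationError(
                    f"region {r.region_id}: unknown hemisphere {r.hemisphere!r}"
                )
            if r.subnet not in SUBNETS:
                raise AtlasValidationError(
                    f"region {r.region_id}: unknown subnet label {r.subnet!r}"
                )
            p = by_id.get(r.homotopic_partner_id)
            if p is None:
                raise AtlasValidationError(
                    f"region {r.region_id}: partner {r.homotopic_partner_id} not in atlas"
                )
            if p.region_id == r.region_id:
                raise AtlasValidationError(f"region {r.region_id} is its own partner")
            if p.homotopic_partner_id != r.region_id:
                raise AtlasValidationError(
                    f"homotopic pairing not an involution at region {r.region_id} "
                    f"(partner {p.region_id} points back to {p.homotopic_partner_id})"
                )
            if p.hemisphere == r.hemisphere:
                raise AtlasValidationError(
                    f"regions {r.region_id} and {p.region_id} are homotopic partners "
                    f"but share hemisphere {r.hemisphere!r}"
                )
            if p.subnet != r.subnet:
                raise AtlasValidationError(
                    f"homotopic partners {r.region_id}/{p.region_id} have different "
                    f"subnet labels ({r.subnet} vs {p.subnet})"
                )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions])

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def hemispheres(self) -> np.ndarray:
        return np.array([r.hemisphere for r in self.regions])

    @property
    def subnets(self) -> np.ndarray:
        return np.array([r.subnet for r in self.regions])

    def index_of(self, region_id: int) -> int:
        for i, r in enumerate(self.regions):
            if r.region_id == region_id:
                return i
        raise KeyError(region_id)

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation ``perm`` with ``perm[i]`` = position of i's partner.

        Satisfies ``perm[perm] == arange(R)`` (an involution with no fixed
        points, since partners differ).
        """
        pos = {r.region_id: i for i, r in enumerate(self.regions)}
        return np.array([pos[r.homotopic_partner_id] for r in self.regions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.region_id, r.name, r.hemisphere, r.homotopic_partner_id, r.subnet)
                for r in self.regions
            ],
            columns=ATLAS_COLUMNS,
        )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    site: str
    age: float
    gender: str  # "M" | "F"
    tiv: float
    lesion_side: str  # "left" | "right" | "none"
    clinical: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if self.lesion_side not in LESION_SIDES:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown lesion_side {self.lesion_side!r}"
            )
        if (self.lesion_side == "none") != (self.group == "control"):
            raise CohortValidationError(
                f"subject {self.subject_id}: lesion_side {self.lesion_side!r} "
                f"inconsistent with group {self.group!r}"
            )
        for k, v in self.clinical.items():
            if v is not None and not np.isfinite(v):
                raise CohortValidationError(
                    f"subject {self.subject_id}: non-finite clinical score {k}"
                )


@dataclass
class GMVTable:
    """Subjects x regions gray-matter volumes (mL) with metadata.

    ``values`` rows follow ``subjects`` order; columns follow atlas order.
    """

    subjects: list[SubjectRecord]
    values: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), self.atlas.n_regions):
            raise CohortValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {self.atlas.n_regions} regions"
            )
        bad = ~np.isfinite(self.values) | (self.values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"non-positive or missing GMV for subject "
                f"{self.subjects[i].subject_id!r}, region {self.atlas.names[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def sites(self) -> list[str]:
        return sorted({s.site for s in self.subjects})

    def mask(self, group: str | None = None, site: str | None = None) -> np.ndarray:
        m = np.ones(self.n_subjects, dtype=bool)
        if group is not None:
            m &= np.array([s.group == group for s in self.subjects])
        if site is not None:
            m &= np.array([s.site == site for s in self.subjects])
        return m

    def subset(self, mask: np.ndarray) -> "GMVTable":
        subs = [s for s, keep in zip(self.subjects, mask) if keep]
        return GMVTable(subs, self.values[mask], self.atlas)

    def covariate_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Design columns [age, gender(0/1, M=1), tiv] for the masked subjects."""
        subs = self.subjects if mask is None else [
            s for s, keep in zip(self.subjects, mask) if keep
        ]
        return np.array(
            [[s.age, 1.0 if s.gender == "M" else 0.0, s.tiv] for s in subs]
        )

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "site": s.site,
                "age": s.age,
                "gender": s.gender,
                "tiv": s.tiv,
                "lesion_side": s.lesion_side,
            }
            for k in CLINICAL_SCORES:
                if k in s.clinical:
                    row[k] = s.clinical[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def values_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.atlas.names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# ---------------------------------------------------------------------------
# readers / writers


def load_atlas(path: str | Path) -> RegionAtlas:
    """Read a TSV atlas table and validate all region invariants."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasValidationError(f"atlas file {path}: missing columns {missing}")
    regions = tuple(
        Region(
            region_id=int(row.region_id),
            name=str(row.name_),
            hemisphere=str(row.hemisphere),
            homotopic_partner_id=int(row.homotopic_partner_id),
            subnet=str(row.subnet),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    )
    return RegionAtlas(regions)


def save_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def default_atlas(n_regions: int = 218) -> RegionAtlas:
    """Construct the synthetic default atlas.

    Regions come in homotopic (left, right) pairs; pair ``k`` gets subnet
    ``SUBNETS[k % 8]``, so partners always share a subnet and subnets form
    contiguous-ish blocks when sorted by id.
    """
    if n_regions < 4 or n_regions % 2:
        raise AtlasValidationError("n_regions must be even and >= 4")
    regions = []
    for k in range(n_regions // 2):
        subnet = SUBNETS[k % len(SUBNETS)]
        lid, rid = 2 * k + 1, 2 * k + 2
        regions.append(Region(lid, f"L.{subnet}-{k + 1}", "left", rid, subnet))
        regions.append(Region(rid, f"R.{subnet}-{k + 1}", "right", lid, subnet))
    return RegionAtlas(tuple(regions))


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # round_trip parsing keeps written values bit-identical on reload
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_cohort(
    gmv_path: str | Path, meta_path: str | Path, atlas: RegionAtlas
) -> GMVTable:
    """Read GMV and metadata tables, align subjects, validate everything."""
    gmv = _read_table(gmv_path)
    meta = _read_table(meta_path)
    for name, df, cols in (
        ("GMV", gmv, ["subject_id"]),
        ("metadata", meta, META_COLUMNS),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortValidationError(f"{name} file: missing columns {missing}")
    missing_regions = [n for n in atlas.names if n not in gmv.columns]
    if missing_regions:
        raise CohortValidationError(
            f"GMV file: missing region columns {missing_regions[:5]}"
        )
    g_ids, m_ids = set(gmv.subject_id), set(meta.subject_id)
    if g_ids != m_ids:
        odd = sorted((g_ids ^ m_ids))[:5]
        raise CohortValidationError(
            f"subjects present in only one file: {odd}"
        )
    meta = meta.set_index("subject_id").loc[gmv.subject_id.tolist()]
    subjects = []
    for sid, row in meta.iterrows():
        clinical = {
            k: float(row[k])
            for k in CLINICAL_SCORES
            if k in meta.columns and pd.notna(row[k])
        }
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                group=str(row.group),
                site=str(row.site),
                age=float(row.age),
                gender=str(row.gender),
                tiv=float(row.tiv),
                lesion_side=str(row.lesion_side),
                clinical=clinical,
            )
        )
    values = gmv[atlas.names].to_numpy(dtype=float)
    nan = np.argwhere(~np.isfinite(values))
    if len(nan):
        i, j = nan[0]
        raise CohortValidationError(
            f"missing GMV for subject {gmv.subject_id.iloc[i]!r}, "
            f"region {atlas.names[j]!r}"
        )
    return GMVTable(subjects, values, atlas)


def write_cohort(cohort: GMVTable, gmv_path: str | Path, meta_path: str | Path) -> None:
    cohort.values_frame().to_csv(gmv_path, sep="\t", index=False)
    cohort.metadata_frame().to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mirroring


def mirror_matrix(M: np.ndarray, atlas: RegionAtlas) -> np.ndarray:
    """Exchange each region with its homotopic partner: returns P M P^T.

    An involution: applying it twice returns the input exactly.
    """
    M = np.asarray(M, dtype=float)
    R = atlas.n_regions
    if M.shape != (R, R):
        raise ValueError(f"matrix shape {M.shape} does not match atlas size {R}")
    perm = atlas.mirror_permutation()
    return M[np.ix_(perm, perm)]


def mirror_vector(v: np.ndarray, atlas: RegionAtlas) -> np.ndarray:
    """Exchange vector entries between homotopic partners."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != atlas.n_regions:
        raise ValueError("vector length does not match atlas size")
    return v[..., atlas.mirror_permutation()]
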