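"""Configuration-driven end-to-end runner.

Chains load -> per-site norms -> per-patient Z matrices -> NBS ->
edge classification -> regional GMV analysis -> associations -> demography,
writing every table as TSV plus a run log.  Identical config and seed give
a byte-identical output bundle.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import GMVTable, load_atlas, load_cohort
from .nbs import NBSConfig, nbs_run
from .scn import build_norms, compute_idscn, z_stack
from .stats import (
    classify_edges,
    clinical_partial_corr,
    demography_tests,
    gmv_group_test,
    gmv_idscn_association,
    nodal_idscn,
)
from .atlas import CLINICAL_SCORES


@dataclass
class PipelineConfig:
    atlas_path: str = ""
    gmv_path: str = ""
    metadata_path: str = ""
    output_dir: str = "idscn_out"
    edge_alpha: float = 0.001
    fwe_alpha: float = 0.05
    fdr_alpha: float = 0.05
    gmv_alpha: float = 0.05
    n_perm: int = 1000
    association_mode: str = "per_region_across_patients"
    design: str = "one_sample_vs_zero"
    seed: int = 0

    def __post_init__(self):
        for a in (self.edge_alpha, self.fwe_alpha, self.fdr_alpha, self.gmv_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)


def run_pipeline(config: PipelineConfig, cohort: GMVTable | None = None) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict with the in-memory results and the list of files written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            raise PipelineError(name, exc) from exc

    if cohort is None:
        def _load():
            atlas = load_atlas(config.atlas_path)
            return load_cohort(config.gmv_path, config.metadata_path, atlas)
        cohort = stage("load", _load)
    atlas = cohort.atlas

    norms = stage("norms", lambda: build_norms(cohort))
    results = stage("idscn", lambda: compute_idscn(cohort))
    if not results:
        raise PipelineError("idscn", ValueError("cohort contains no patients"))

    nbs_cfg = NBSConfig(
        n_perm=config.n_perm, edge_alpha=config.edge_alpha,
        fwe_alpha=config.fwe_alpha, design=config.design, seed=config.seed,
    )
    nbs_result = stage("nbs", lambda: nbs_run(z_stack(results), nbs_cfg))

    edge_table, hemi_counts, subnet_counts, degree = stage(
        "classify", lambda: classify_edges(nbs_result.significant_edges, atlas)
    )
    region_stats, meff = stage(
        "gmv", lambda: gmv_group_test(cohort, alpha=config.gmv_alpha)
    )
    assoc = stage(
        "association",
        lambda: gmv_idscn_association(
            cohort, results, nbs_result, mode=config.association_mode
        )
        if nbs_result.significant_edges
        else [],
    )
    demo = stage("demography", lambda: demography_tests(cohort))

    def _clinical():
        patients = [s for s in cohort.subjects if s.group == "patient"]
        nodal, deg = nodal_idscn(results, nbs_result)
        summaries = {
            atlas.names[k]: nodal[:, k] for k in np.flatnonzero(deg > 0)
        }
        clin = pd.DataFrame(
            [{k: s.clinical.get(k, np.nan) for k in CLINICAL_SCORES}
             for s in patients]
        )
        age = np.array([s.age for s in patients])
        gender = np.array([1.0 if s.gender == "M" else 0.0 for s in patients])
        if not summaries or clin.dropna(how="all", axis=1).empty:
            return pd.DataFrame()
        return clinical_partial_corr(
            summaries, clin.dropna(how="all", axis=1), age, gender
        )
    clinical = stage("clinical", _clinical)

    # ---- write bundle ------------------------------------------------
    def w(name, df, **kw):
        p = out / name
        _tsv(df, p, **kw)
        written.append(p)

    w("significant_edges.tsv",
      edge_table if not edge_table.empty else pd.DataFrame(
          columns=["region_i", "region_j", "t", "p", "mean_z", "sign",
                   "component_id", "fwe_p", "name_i", "name_j",
                   "hemisphere_class", "subnet_pair"]))
    w("hemisphere_counts.tsv", hemi_counts, index=True)
    w("subnet_counts.tsv", subnet_counts, index=True)
    w("node_degree.tsv", degree)
    w("null_max_sizes.tsv",
      pd.DataFrame({"max_component_size": nbs_result.null_max_sizes}))
    w("region_gmv_stats.tsv", pd.DataFrame([asdict(r) for r in region_stats]))
    w("gmv_idscn_association.tsv",
      pd.DataFrame([a.as_dict() for a in assoc]) if assoc
      else pd.DataFrame(columns=["label", "rho", "p", "q", "n", "sign"]))
    w("clinical_associations.tsv", clinical if not clinical.empty
      else pd.DataFrame(columns=["score", "label", "r", "p", "q", "n", "df",
                                 "significant_fdr", "significant_uncorrected"]))
    w("demography.tsv", demo)
    edge_long = []
    iu, ju = np.triu_indices(atlas.n_regions, k=1)
    mean_z = nbs_result.mean_z
    for i, j in zip(iu, ju):
        edge_long.append((atlas.names[i], atlas.names[j], mean_z[i, j]))
    w("mean_z_edges.tsv",
      pd.DataFrame(edge_long, columns=["region_i", "region_j", "mean_z"]))

    log = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "n_perm": config.n_perm,
        "edge_alpha": config.edge_alpha,
        "fwe_alpha": config.fwe_alpha,
        "fdr_alpha": config.fdr_alpha,
        "gmv_alpha": config.gmv_alpha,
        "gmv_meff": round(meff, 6),
        "association_mode": config.association_mode,
        "design": config.design,
        "n_subjects": cohort.n_subjects,
        "n_patients": len(results),
        "sites": {site: norms[site].n for site in sorted(norms)},
        "n_significant_edges": len(nbs_result.significant_edges),
        "n_significant_components": len(nbs_result.significant_components),
    }
    logp = out / "run_log.yaml"
    with open(logp, "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    written.append(logp)

    summary = (
        f"subjects={cohort.n_subjects} patients={len(results)} "
        f"sites={len(norms)}\n"
        f"significant components={len(nbs_result.significant_components)} "
        f"edges={len(nbs_result.significant_edges)}\n"
        f"regions FWE-significant (Meff={meff:.2f}): "
        f"{sum(r.significant_after_fwe for r in region_stats)}\n"
        f"associations FDR<{config.fdr_alpha}: "
        f"{sum(a.q < config.fdr_alpha for a in assoc)}\n"
    )
    sp = out / "summary.txt"
    sp.write_text(summary)
    written.append(sp)

    return {
        "cohort": cohort,
        "norms": norms,
        "idscn": results,
        "nbs": nbs_result,
        "edge_table": edge_table,
        "region_stats": region_stats,
        "meff": meff,
        "associations": assoc,
        "clinical": clinical,
        "demography": demo,
        "files": written,
        "log": log,
    }
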