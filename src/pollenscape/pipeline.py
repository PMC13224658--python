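"""Staged pipeline: simulate -> qc -> assign -> metrics -> landscape -> model.

Each stage reads the previous stage's artifacts from the run directory and
writes its own atomically (temp file + rename); a manifest JSON records the
config hash, master seed, package version and per-stage row counts so a run
can be re-executed from the manifest alone.  Floating-point CSV cells are
written with repr() (17 significant digits) for round-trip equality.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping

from . import __version__
from .genotypes import (
    GenotypeSet,
    Role,
    clonality_report,
    deduplicate,
    read_allele_table,
    repeated_mlg_counts,
    write_allele_table,
    write_removal_log,
)
from .geneflow import donor_statistics, receptor_summaries
from .landscape import LandUseMap, LinearElementSet, PopulationSet, metric_table
from .models import (
    all_subsets_average,
    boxcox_standardize,
    collinearity_filter,
    screen_metrics,
)
from .models.selection import LMMFitter, ZIFitter
from .paternity import UNASSIGNED, PaternityConfig, assign_all
from .simulate import SCENARIOS, SimConfig, simulate_study

STAGES = ("simulate", "qc", "assign", "metrics", "landscape", "model")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    scenario: str = "trapline_mixed"
    sim: dict = field(default_factory=dict)
    paternity: dict = field(default_factory=dict)
    rarefaction_g: int = 5
    radii: tuple = (50.0, 250.0, 1000.0)
    allow_custom_radii: bool = False
    screen_alpha: float = 0.15
    collinearity_r: float = 0.7
    delta_aicc: float = 2.0
    gh_nodes: int = 9
    model_max_metrics: int = 4

    def __post_init__(self):
        if not self.allow_custom_radii and not set(self.radii) <= {50.0, 250.0, 1000.0}:
            raise ValueError("radii must be within {50, 250, 1000} (or allow_custom_radii)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["radii"] = tuple(float(r) for r in raw.get("radii", (50, 250, 1000)))
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> SimConfig:
        kwargs = dict(SCENARIOS.get(self.scenario, {}))
        kwargs.update(self.sim)
        kwargs["seed"] = self.seed
        return SimConfig(**kwargs)

    def paternity_config(self) -> PaternityConfig:
        return PaternityConfig(seed=self.seed, **self.paternity)


class MissingArtifact(FileNotFoundError):
    pass


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp_")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    _atomic_write(path, lambda tmp: out.to_csv(tmp, index=False))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifact(f"stage '{stage}' requires missing artifact {path}")
    return path


def _geojson(features) -> dict:
    return {"type": "FeatureCollection", "features": list(features)}


def _update_manifest(out: Path, cfg: RunConfig, stage: str, counts: dict) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
    }
    manifest["stages"][stage] = counts
    _atomic_write(mpath, lambda tmp: tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True)))


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    sim = cfg.sim_config()
    (lum, elems, patches), pop, gs, truth = simulate_study(sim)
    _atomic_write(out / "allele_table.csv", lambda p: write_allele_table(gs, p))
    coords = pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "patch_id": c.patch_id, "x": c.center[0],
             "y": c.center[1], "shoots": c.shoots}
            for c in pop.clusters
        ]
    )
    _write_df(coords, out / "clusters.csv")
    land = _geojson(
        {"type": "Feature", "properties": {"class": cls}, "geometry": mapping(g)}
        for cls, geoms in lum.by_class.items()
        for g in geoms
    )
    _atomic_write(out / "landuse.geojson", lambda p: p.write_text(json.dumps(land)))
    lines = _geojson(
        {"type": "Feature", "properties": {"type": t}, "geometry": mapping(g)}
        for t, geoms in elems.by_type.items()
        for g in geoms
    )
    _atomic_write(out / "elements.geojson", lambda p: p.write_text(json.dumps(lines)))
    pops = _geojson(
        {"type": "Feature", "properties": {"patch_id": pid, "occupied": True},
         "geometry": mapping(poly)}
        for pid, poly in sorted(patches.items())
    )
    _atomic_write(out / "populations.geojson", lambda p: p.write_text(json.dumps(pops)))
    truth_df = pd.DataFrame(
        [
            {
                "offspring_id": oid,
                "father_genet": truth.father_genet[oid],
                "father_patch": truth.father_patch[oid],
                "father_sampled_as": truth.father_sampled_as[oid] or "",
                "immigrant": int(truth.immigrant[oid]),
            }
            for oid in sorted(truth.father_genet)
        ]
    )
    _write_df(truth_df, out / "truth.csv")
    counts = {
        "samples": len(gs),
        "offspring": len(gs.by_role(Role.OFFSPRING)),
        "clusters": len(pop.clusters),
        "starved_receptors": len(truth.starved_receptors),
    }
    _update_manifest(out, cfg, "simulate", counts)
    return counts


def _load_gs(cfg: RunConfig, name: str, stage: str) -> GenotypeSet:
    out = Path(cfg.out_dir)
    path = _require(out / name, stage)
    return read_allele_table(path, cfg.sim_config().panel())


def stage_qc(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    gs = _load_gs(cfg, "allele_table.csv", "qc")
    mlg_counts = repeated_mlg_counts(gs)
    deduped, removals = deduplicate(gs)
    _atomic_write(out / "removal_log.csv", lambda p: write_removal_log(removals, p))
    _atomic_write(out / "allele_table_dedup.csv", lambda p: write_allele_table(deduped, p))
    clusters_path = out / "clusters.csv"
    clonality = None
    if clusters_path.exists():
        shoots = dict(
            pd.read_csv(clusters_path)[["cluster_id", "shoots"]].itertuples(index=False)
        )
        try:
            rep = clonality_report(gs, shoots)
            clonality = {
                "overall_monoclonal_fraction": rep.overall_monoclonal_fraction,
                "by_size_class": rep.by_size_class,
                "n_clusters": rep.n_clusters,
                "n_singleton_excluded": rep.n_singleton_excluded,
            }
        except ValueError:
            clonality = None
    qc = {"repeated_mlgs": mlg_counts, "clonality": clonality}
    _atomic_write(out / "qc.json", lambda p: p.write_text(json.dumps(qc, indent=1)))
    counts = {"removed": len(removals), "kept": len(deduped), **mlg_counts}
    _update_manifest(out, cfg, "qc", counts)
    return counts


def stage_assign(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    gs = _load_gs(cfg, "allele_table_dedup.csv", "assign")
    pat = cfg.paternity_config()
    cons = assign_all(gs, pat)
    rows = [
        {
            "offspring_id": oid,
            "patch_id": cons.patch.get(oid, ""),
            "mother_id": cons.mother.get(oid, ""),
            "assigned_donor_id": d if d != UNASSIGNED else "",
            "support": cons.support.get(oid, 0),
            "status": "assigned" if d != UNASSIGNED else "unassigned",
        }
        for oid, d in sorted(cons.assignment.items())
    ] + [
        {"offspring_id": oid, "patch_id": "", "mother_id": "", "assigned_donor_id": "",
         "support": 0, "status": f"excluded:{reason}"}
        for oid, reason in sorted(cons.excluded.items())
    ]
    _write_df(pd.DataFrame(rows), out / "assignments.csv")
    counts = {
        "offspring": len(cons.assignment),
        "assigned": len(cons.assigned()),
        "excluded": len(cons.excluded),
    }
    _update_manifest(out, cfg, "assign", counts)
    return counts


def _load_consensus(cfg: RunConfig, stage: str):
    from .paternity import ConsensusAssignment

    out = Path(cfg.out_dir)
    df = pd.read_csv(_require(out / "assignments.csv", stage), dtype=str).fillna("")
    cons = ConsensusAssignment()
    for row in df.itertuples(index=False):
        if row.status.startswith("excluded"):
            cons.excluded[row.offspring_id] = row.status.split(":", 1)[1]
            continue
        cons.assignment[row.offspring_id] = row.assigned_donor_id or UNASSIGNED
        cons.support[row.offspring_id] = int(row.support)
        cons.mother[row.offspring_id] = row.mother_id
        cons.patch[row.offspring_id] = row.patch_id
    return cons


def stage_metrics(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    gs = _load_gs(cfg, "allele_table_dedup.csv", "metrics")
    cons = _load_consensus(cfg, "metrics")
    recs = receptor_summaries(cons, gs, g_individuals=cfg.rarefaction_g)
    rec_df = pd.DataFrame(
        [
            {
                "receptor_id": r.receptor_id, "patch_id": r.patch_id,
                "n_offspring": r.n_offspring, "n_within": r.n_within,
                "pf_within": r.pf_within, "immigration_rate": r.immigration_rate,
                "a_r": np.nan if r.a_r is None else r.a_r,
                "a_r_sum": np.nan if r.a_r_sum is None else r.a_r_sum,
            }
            for r in recs
        ]
    )
    _write_df(rec_df, out / "receptor_summary.csv")
    clusters_path = out / "clusters.csv"
    coords = None
    n_clusters = None
    if clusters_path.exists():
        cdf = pd.read_csv(clusters_path)
        coords = {r.cluster_id: (r.x, r.y) for r in cdf.itertuples(index=False)}
        n_clusters = len(cdf)
    boundaries = None
    pops_path = out / "populations.geojson"
    if pops_path.exists():
        from shapely.geometry import shape

        fc = json.loads(pops_path.read_text())
        boundaries = {
            f["properties"]["patch_id"]: shape(f["geometry"]) for f in fc["features"]
        }
    donors, agg = donor_statistics(
        cons, gs, cluster_coords=coords, patch_boundaries=boundaries,
        n_clusters_total=n_clusters,
    )
    don_df = pd.DataFrame(
        [
            {
                "donor_id": d.donor_id, "cluster_id": d.cluster_id or "",
                "n_assigned_offspring": d.n_assigned_offspring,
                "distance_to_edge": np.nan if d.distance_to_edge is None else d.distance_to_edge,
                "median_receptor_distance": (
                    np.nan if not d.receptor_distances else float(np.median(d.receptor_distances))
                ),
            }
            for d in donors
        ]
    )
    _write_df(don_df, out / "donor_summary.csv")
    agg_d = {
        "n_effective_donors": agg.n_effective_donors,
        "n_clusters": agg.n_clusters,
        "fraction_clusters_donating": agg.fraction_clusters_donating,
        "median_offspring_per_donor": agg.median_offspring_per_donor,
        "median_donor_receptor_distance": agg.median_donor_receptor_distance,
        "median_distance_to_edge": agg.median_distance_to_edge,
        "median_pf_within": float(rec_df["pf_within"].median()) if len(rec_df) else None,
        "median_immigration_rate": (
            float(rec_df["immigration_rate"].median()) if len(rec_df) else None
        ),
        "median_a_r": (
            float(rec_df["a_r"].median()) if rec_df["a_r"].notna().any() else None
        ),
    }
    _atomic_write(out / "geneflow_aggregate.json", lambda p: p.write_text(json.dumps(agg_d, indent=1)))
    counts = {"receptors": len(rec_df), "effective_donors": agg.n_effective_donors}
    _update_manifest(out, cfg, "metrics", counts)
    return counts


def stage_landscape(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    gs = _load_gs(cfg, "allele_table_dedup.csv", "landscape")
    lum = LandUseMap.from_geojson(_require(out / "landuse.geojson", "landscape"))
    elems = LinearElementSet.from_geojson(_require(out / "elements.geojson", "landscape"))
    pops = PopulationSet.from_geojson(_require(out / "populations.geojson", "landscape"))
    receptors = [
        (s.sample_id, s.coords, s.patch_id)
        for s in gs.by_role(Role.RECEPTOR)
        if s.coords is not None
    ]
    table = metric_table(receptors, lum, elems, pops, radii=cfg.radii)
    _write_df(table, out / "landscape_metrics.csv")
    counts = {"rows": len(table)}
    _update_manifest(out, cfg, "landscape", counts)
    return counts


def stage_model(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    rec = pd.read_csv(_require(out / "receptor_summary.csv", "model"))
    land = pd.read_csv(_require(out / "landscape_metrics.csv", "model"))
    counts: dict = {}
    for radius in cfg.radii:
        sub = land[land["radius"] == radius].set_index("receptor_id")
        metric_cols = [
            c for c in sub.columns
            if c not in ("radius",) and sub[c].notna().all() and sub[c].nunique() > 2
        ]
        df = rec.merge(sub[metric_cols], left_on="receptor_id", right_index=True)
        transformed = {}
        for c in metric_cols:
            try:
                z, _ = boxcox_standardize(df[c].to_numpy())
                transformed[c] = z
            except ValueError:
                continue
        for c, z in transformed.items():
            df[c] = z
        metrics = list(transformed)[: cfg.model_max_metrics]
        if not metrics or df["patch_id"].nunique() < 2:
            continue
        # PF_within: zero-inflated binomial on (n_within | n_offspring)
        zi = ZIFitter(
            df, "n_within", "patch_id", family="binomial", trials="n_offspring",
            nodes=cfg.gh_nodes, seed=cfg.seed,
        )
        area = [m for m in metrics if m in ("MAIZE", "SEMNATGRASS", "RAPESEED")]
        op_partner = {
            m: f"OP_{m}" for m in metrics if m.startswith("L_") and f"OP_{m}" in metrics
        }
        screen = screen_metrics(
            zi, metrics, alpha=cfg.screen_alpha, area_metrics=area, op_partner=op_partner
        )
        excl = collinearity_filter(df, metrics, r_max=cfg.collinearity_r)
        try:
            avg = all_subsets_average(
                zi, screen.candidates, excl, delta_aicc=cfg.delta_aicc
            )
            _write_df(avg.table, out / f"model_pf_within_{int(radius)}m.csv")
            _write_df(avg.selection, out / f"selection_pf_within_{int(radius)}m.csv")
            counts[f"pf_within_{int(radius)}m_models"] = len(avg.selection)
        except (ValueError, RuntimeError):
            counts[f"pf_within_{int(radius)}m_models"] = 0
        # A_r: Gaussian LMM on receptors with >= g offspring
        adf = df[df["a_r"].notna()].copy()
        if len(adf) >= 10 and adf["patch_id"].nunique() >= 2:
            lmm = LMMFitter(adf, "a_r", "patch_id")
            screen_a = screen_metrics(
                lmm, metrics, alpha=cfg.screen_alpha, area_metrics=area,
                op_partner=op_partner,
            )
            try:
                avg_a = all_subsets_average(
                    lmm, screen_a.candidates, excl, delta_aicc=cfg.delta_aicc
                )
                _write_df(avg_a.table, out / f"model_a_r_{int(radius)}m.csv")
                _write_df(avg_a.selection, out / f"selection_a_r_{int(radius)}m.csv")
                counts[f"a_r_{int(radius)}m_models"] = len(avg_a.selection)
            except (ValueError, RuntimeError):
                counts[f"a_r_{int(radius)}m_models"] = 0
    _update_manifest(out, cfg, "model", counts)
    return counts


_STAGE_FN = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "assign": stage_assign,
    "metrics": stage_metrics,
    "landscape": stage_landscape,
    "model": stage_model,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    """Run one named stage (or 'all' to chain every stage in order)."""
    if name == "all":
        out = {}
        for s in STAGES:
            out[s] = _STAGE_FN[s](cfg)
        return out
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES + ('all',)}")
    return {name: _STAGE_FN[name](cfg)}
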