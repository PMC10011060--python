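"""End-to-end orchestration: filter -> cluster -> select -> profile -> stats.

`analyze_cohort` is the in-memory core; `run_pipeline` wraps it with file
loading from a dataset directory and writes every result table plus a run
manifest (seed, adjusted thresholds, stage bookkeeping counts, config
hash) so a run is fully reproducible: identical inputs, config and seed
give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Tractogram, endpoint_centroid
from .io import load_scalar_volume, load_tractogram
from .ushape import UShapeCriteria, filter_u_shaped
from .clustering import (
    ClusterSet,
    LabelVolume,
    ParcelInfo,
    TemplateTract,
    assign_tract_nodes,
    map_tracts_to_surface,
    propagate_labels,
    select_analysis_tracts,
)
from .tractometry import METRICS, ProfileMatrix, tract_profile, segment_mean
from .stats import (
    AlongTractResult,
    TestResult,
    clinical_correlation_table,
    compare_along_tract,
    compare_densities,
    load_cohort_table,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze_cohort", "run_pipeline", "load_dataset"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated values."""

    dataset: str = "."
    output: str = "results"
    # U-shape criterion
    min_length: float = 20.0
    max_length: float = 80.0
    max_endpoint_ratio: float = 1.0 / 3.0
    min_endpoint_ratio: float = 0.0
    # clustering
    max_dist: float | None = None
    parcel_radius: float = 4.0
    # analysis criteria
    min_streamlines: int = 5
    presence: float = 0.70
    lobe: str = "frontal"
    # statistics
    n_perm: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    min_run: int = 1
    metrics: tuple[str, ...] = METRICS
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.presence <= 1:
            raise ValueError("presence must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_streamlines < 1 or self.n_perm < 1:
            raise ValueError("min_streamlines and n_perm must be >= 1")

    @property
    def ushape(self) -> UShapeCriteria:
        return UShapeCriteria(
            min_length=self.min_length,
            max_length=self.max_length,
            max_endpoint_ratio=self.max_endpoint_ratio,
            min_endpoint_ratio=self.min_endpoint_ratio,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in known:
            known["metrics"] = tuple(known["metrics"])
        return cls(**known)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["metrics"] = list(d["metrics"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded)."""
        d = asdict(self)
        d.pop("dataset")
        d.pop("output")
        d["metrics"] = list(d["metrics"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a run computes, ready for writing or inspection."""

    config: RunConfig
    selected_tracts: list[int]
    tract_nodes: dict[int, tuple[int, int] | None]
    densities: pd.DataFrame  # subjects x all tract ids
    density_tests: pd.DataFrame
    total_density_test: TestResult
    profiles: ProfileMatrix
    along_tract: dict[str, AlongTractResult]
    segment_means: pd.DataFrame
    correlations: pd.DataFrame
    surface_labels: np.ndarray
    counts: dict

    def segments_frame(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.along_tract.items():
            for tid, runs in sorted(res.segments.items()):
                for a, b in runs:
                    rows.append((metric, tid, a + 1, b + 1))
        return pd.DataFrame(rows, columns=["metric", "tract_id", "start_node", "end_node"])


def analyze_cohort(
    template: list[TemplateTract],
    labels: LabelVolume,
    surface_vertices: np.ndarray,
    subjects: list[tuple[str, Tractogram, dict]],
    cohort: pd.DataFrame,
    cfg: RunConfig,
) -> PipelineResult:
    """Run the full analysis on in-memory data.

    ``subjects`` is a list of (subject_id, tractogram, {metric: volume})
    in the cohort-table order.
    """
    cohort = cohort.reset_index(drop=True)
    order = {sid: i for i, (sid, _, _) in enumerate(subjects)}
    if set(cohort["subject_id"]) != set(order):
        raise ValueError("cohort table and subject data disagree on subject ids")
    subjects = sorted(subjects, key=lambda s: list(cohort["subject_id"]).index(s[0]))

    counts = {"n_subjects": len(subjects), "input_streamlines": 0, "u_shaped": 0, "assigned": 0}
    clustersets: list[ClusterSet] = []
    for sid, tractogram, _ in subjects:
        filtered, _idx = filter_u_shaped(tractogram, cfg.ushape)
        cs = propagate_labels(filtered, template, max_dist=cfg.max_dist)
        counts["input_streamlines"] += len(tractogram)
        counts["u_shaped"] += len(filtered)
        counts["assigned"] += sum(len(m) for m in cs.clusters.values())
        clustersets.append(cs)

    # anatomical node assignment is done once, on the template (analysis space)
    tract_nodes = {
        t.tract_id: assign_tract_nodes(t.streamlines, labels, radius=cfg.parcel_radius)
        for t in template
    }

    all_ids = sorted(t.tract_id for t in template)
    densities = pd.DataFrame(
        {tid: [cs.density(tid) for cs in clustersets] for tid in all_ids},
        index=[sid for sid, _, _ in subjects],
    )
    densities.index.name = "subject_id"

    ctrl_mask = cohort["group"].to_numpy() == "control"
    selected = select_analysis_tracts(
        [cs for cs, c in zip(clustersets, ctrl_mask) if c],
        [cs for cs, c in zip(clustersets, ctrl_mask) if not c],
        tract_nodes,
        labels,
        min_streamlines=cfg.min_streamlines,
        presence=cfg.presence,
        lobe=cfg.lobe,
    )
    counts["tracts_total"] = len(all_ids)
    counts["tracts_retained"] = len(selected)
    log.info("%d of %d tracts retained for analysis", len(selected), len(all_ids))
    if not selected:
        raise ValueError("no tract satisfies the analysis criteria")

    protos = {t.tract_id: t.prototype for t in template}
    n_nodes = 20
    data = np.full((len(subjects), len(selected), n_nodes, len(cfg.metrics)), np.nan)
    missing = set()
    for si, ((sid, _, vols), cs) in enumerate(zip(subjects, clustersets)):
        for ti, tid in enumerate(selected):
            members = cs.clusters.get(tid, [])
            if len(members) < cfg.min_streamlines:
                missing.add((sid, tid))
                continue
            for mi, metric in enumerate(cfg.metrics):
                prof = tract_profile(members, vols[metric], protos[tid], n_nodes, tract_id=tid)
                data[si, ti, :, mi] = prof.values
    profiles = ProfileMatrix(
        data=data,
        subject_ids=[sid for sid, _, _ in subjects],
        tract_ids=list(selected),
        metrics=tuple(cfg.metrics),
        missing=missing,
    )

    density_tests, total_test = compare_densities(densities[selected], cohort, q=cfg.fdr_q)

    along = {}
    for k, metric in enumerate(cfg.metrics):
        along[metric] = compare_along_tract(
            profiles,
            cohort,
            metric,
            n_perm=cfg.n_perm,
            alpha=cfg.alpha,
            seed=cfg.seed + k,
            min_run=cfg.min_run,
        )

    # mean over each tract's significant segment nodes, per patient, per metric
    seg_rows = []
    patients = cohort.loc[cohort["group"] == "patient", "subject_id"]
    for metric, res in along.items():
        mi = profiles.metric_index(metric)
        for tid, runs in sorted(res.segments.items()):
            nodes = sorted({n for a, b in runs for n in range(a, b + 1)})
            ti = profiles.tract_ids.index(tid)
            for sid in patients:
                if (sid, tid) in profiles.missing:
                    continue
                si = profiles.subject_ids.index(sid)
                vals = profiles.data[si, ti, nodes, mi]
                if np.all(np.isnan(vals)):
                    continue
                seg_rows.append((sid, tid, metric, float(np.nanmean(vals))))
    segment_means = pd.DataFrame(seg_rows, columns=["subject", "tract_id", "metric", "value"])

    correlations = (
        clinical_correlation_table(segment_means, cohort, q=cfg.fdr_q)
        if len(segment_means)
        else pd.DataFrame(
            columns=["tract_id", "metric", "variable", "n", "r", "p", "p_adjusted"]
        )
    )

    centroids = {}
    for t in template:
        if t.tract_id in selected:
            centroids[t.tract_id] = np.stack(
                [
                    endpoint_centroid(t.streamlines, "first"),
                    endpoint_centroid(t.streamlines, "last"),
                ]
            )
    surface_labels = map_tracts_to_surface(centroids, surface_vertices)

    return PipelineResult(
        config=cfg,
        selected_tracts=list(selected),
        tract_nodes=tract_nodes,
        densities=densities,
        density_tests=density_tests,
        total_density_test=total_test,
        profiles=profiles,
        along_tract=along,
        segment_means=segment_means,
        correlations=correlations,
        surface_labels=surface_labels,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# disk dataset


def load_dataset(root) -> tuple[list[TemplateTract], LabelVolume, np.ndarray, list, pd.DataFrame]:
    """Load a dataset directory in the layout `ufib synth` writes."""
    root = Path(root)
    tdir = root / "template"
    tmpl_tract = load_tractogram(tdir / "template.tck")
    lab_tab = pd.read_csv(tdir / "template_labels.tsv", sep="\t")
    tracts = []
    for tid, grp in lab_tab.groupby("tract_id", sort=True):
        members = [tmpl_tract.streamlines[i] for i in grp["streamline_index"]]
        tracts.append(TemplateTract(tract_id=int(tid), streamlines=members))

    vol = load_scalar_volume(tdir / "parcellation.nii.gz", "labels")
    lut = pd.read_csv(tdir / "parcel_lookup.tsv", sep="\t")
    lookup = {
        int(r.label): ParcelInfo(str(r.name_), str(r.lobe), str(r.hemisphere), str(r.network))
        for r in lut.rename(columns={"name": "name_"}).itertuples()
    }
    labels = LabelVolume(
        grid=np.rint(vol.grid).astype(np.int32), affine=vol.affine, lookup=lookup
    )
    vertices = pd.read_csv(tdir / "surface_vertices.tsv", sep="\t").to_numpy(dtype=float)

    cohort = load_cohort_table(root / "cohort.tsv")
    subjects = []
    for sid in cohort["subject_id"]:
        sdir = root / "subjects" / sid
        tck = sdir / f"{sid}.tck"
        if not tck.exists():
            raise FileNotFoundError(f"missing tractogram for subject {sid}: {tck}")
        vols = {m: load_scalar_volume(sdir / f"{sid}_{m}.nii.gz", m) for m in METRICS}
        subjects.append((sid, load_tractogram(tck), vols))
    return tracts, labels, vertices, subjects, cohort


def _write_result(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    float_fmt = "%.10g"

    result.profiles.to_tidy().to_csv(out / "profiles.tsv", sep="\t", index=False, float_format=float_fmt)
    result.densities.reset_index().to_csv(out / "densities.tsv", sep="\t", index=False)
    result.density_tests.to_csv(out / "density_tests.tsv", sep="\t", index=False, float_format=float_fmt)
    for metric, res in result.along_tract.items():
        res.to_frame().to_csv(out / f"alongtract_{metric}.tsv", sep="\t", index=False, float_format=float_fmt)
    result.segments_frame().to_csv(out / "segments.tsv", sep="\t", index=False)
    result.segment_means.to_csv(out / "segment_means.tsv", sep="\t", index=False, float_format=float_fmt)
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format=float_fmt)
    pd.DataFrame({"vertex": np.arange(len(result.surface_labels)), "tract_id": result.surface_labels}).to_csv(
        out / "surface_labels.tsv", sep="\t", index=False
    )

    manifest = {
        "version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "selected_tracts": result.selected_tracts,
        "tract_nodes": {str(t): list(p) if p else None for t, p in result.tract_nodes.items()},
        "alpha_adjusted": {m: r.permutation.alpha_adjusted for m, r in result.along_tract.items()},
        "family_size": {m: int(np.prod(r.p.shape)) for m, r in result.along_tract.items()},
        "total_density_test": {
            "t": result.total_density_test.statistic,
            "df": result.total_density_test.df,
            "p": result.total_density_test.p,
        },
        "counts": result.counts,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    cfg.to_yaml(out / "config_used.yaml")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full pipeline on a dataset directory and write all outputs."""
    tracts, labels, vertices, subjects, cohort = load_dataset(cfg.dataset)
    result = analyze_cohort(tracts, labels, vertices, subjects, cohort, cfg)
    _write_result(result, Path(cfg.output))
    return result
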