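"""Synthetic U-fibre cohorts with known ground truth.

Every stage of the tractometry pipeline is exercised on data this module
generates: a labelled template of U-shaped bundles, per-subject
tractograms, the four DTI scalar volumes, a cohort table with covariates
and clinical scores, and a truth manifest tying each generated object to
its origin.

Bundle cores are circular arcs (default 270-300 degrees, radius 8-14 mm),
which gives closed-form control of the length/chord criterion: an arc of
angle theta has chord/arc ratio 2 sin(theta/2)/theta, below 1/3 for
theta >= ~262 degrees, so every core is U-shaped by construction while
straight-line distractors are not.  Scalar fields are piecewise-smooth
tubes around the cores: axially symmetric eigenvalues (axial diffusivity
fixed, radial solved for the target FA) keep FA/MD/AD/RD mutually
consistent.  Patients receive a localized mid-tract FA decrease and RD
increase inside a Gaussian arc-length window; axial diffusivity is
untouched, mirroring the microstructural pattern the analysis is meant to
detect.  All generation is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import ScalarVolume, Tractogram
from .clustering import LabelVolume, ParcelInfo, TemplateTract
from .tractometry import radial_for_target_fa

__all__ = [
    "SynthConfig",
    "SynthTemplate",
    "SynthSubject",
    "CohortData",
    "make_template",
    "make_subject",
    "make_cohort",
    "make_filter_fixture",
    "write_cohort",
]

_NETWORKS = ("default", "salience", "control", "attention")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for a synthetic U-fibre cohort.

    Geometry is in world mm on a 2 mm isotropic voxel grid.  Defaults
    describe a two-group cohort (30 controls, 30 patients) of five
    well-separated frontal bundles with one bundle carrying a mid-tract
    FA decrease / RD increase of fractional size ``delta`` in patients.
    """

    # template geometry
    n_bundles: int = 5
    arc_deg_range: tuple[float, float] = (270.0, 300.0)
    radius_range: tuple[float, float] = (8.0, 14.0)
    template_streamlines_per_bundle: int = 10
    template_offset_sd: float = 0.4  # mm, rigid member offset within a bundle
    template_point_noise_sd: float = 0.1  # mm
    min_core_separation: float = 10.0  # mm between bundle cores
    max_placement_tries: int = 500
    nonfrontal_bundles: tuple[int, ...] = ()  # tract ids whose parcels get lobe="other"

    # subject tractograms
    streamlines_per_bundle_mean: float = 25.0
    streamlines_per_bundle_sd: float = 5.0
    point_noise_sd: float = 0.3  # mm
    rigid_jitter_sd: float = 0.5  # mm, one offset per subject
    streamline_step: float = 3.0  # mm spacing of stored polyline points
    n_distractor_straight: int = 50
    n_distractor_short: int = 0

    # volumes
    voxel_size: float = 2.0  # mm, isotropic (matches typical dMRI resolution)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    tube_radius: float = 3.0  # mm
    parcel_radius: float = 6.0  # mm, endpoint parcel spheres
    fa_background: float = 0.20
    fa_bundle: float = 0.45
    ad_background: float = 1.0e-3  # mm^2/s
    ad_bundle: float = 1.7e-3

    # cohort and injected effect
    n_controls: int = 30
    n_patients: int = 30
    affected_bundles: tuple[int, ...] = (1,)  # tract ids
    delta: float = 0.15  # fractional FA decrease (RD divided by same factor)
    effect_center: float = 0.5  # arc fraction
    effect_width: float = 0.08  # Gaussian SD in arc fraction
    effect_subject_sd: float = 0.15  # relative SD of per-patient effect size
    subject_fa_sd: float = 0.03  # relative between-subject FA variation
    subject_ad_sd: float = 0.02
    age_fa_slope: float = -0.002  # relative FA change per year from cohort mean age
    sex_fa_delta: float = 0.01  # relative FA offset for F vs M

    # covariates and clinical scores
    age_range: tuple[float, float] = (18.0, 35.0)
    p_female: float = 0.5
    clinical_effect_r: float = 0.0  # corr between per-patient effect and PANSS-8 total

    # surface
    n_surface_vertices: int = 300

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bundles < 1 or self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")
        # the chord/arc ratio of the smallest arc must satisfy the U criterion
        theta = np.radians(self.arc_deg_range[0])
        if 2 * np.sin(theta / 2) / theta > 1 / 3:
            raise ValueError("arc_deg_range lower bound gives chord/arc > 1/3 (not U-shaped)")


# ---------------------------------------------------------------------------
# template


@dataclass
class _Bundle:
    tract_id: int
    center: np.ndarray
    radius: float
    theta: float  # arc angle, radians
    u: np.ndarray  # in-plane basis
    v: np.ndarray
    phi0: float

    def core(self, step: float) -> np.ndarray:
        n = max(int(np.ceil(self.radius * self.theta / step)) + 1, 8)
        phi = self.phi0 + np.linspace(0.0, self.theta, n)
        return (
            self.center[None, :]
            + self.radius * np.cos(phi)[:, None] * self.u[None, :]
            + self.radius * np.sin(phi)[:, None] * self.v[None, :]
        )


@dataclass
class SynthTemplate:
    tracts: list[TemplateTract]
    labels: LabelVolume
    surface_vertices: np.ndarray
    bundles: list[_Bundle]
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    seed: int

    @property
    def tract_meta(self) -> pd.DataFrame:
        rows = []
        for b in self.bundles:
            lab = 2 * (b.tract_id - 1) + 1
            info = self.labels.lookup[lab]
            rows.append((b.tract_id, f"tract_{b.tract_id:02d}", info.lobe, info.hemisphere, info.network))
        return pd.DataFrame(rows, columns=["tract_id", "tract_name", "lobe", "hemisphere", "network"])


def _random_basis(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    while True:
        u = rng.normal(size=3)
        nu = np.linalg.norm(u)
        if nu > 1e-6:
            u /= nu
            break
    while True:
        w = rng.normal(size=3)
        v = w - (w @ u) * u
        nv = np.linalg.norm(v)
        if nv > 1e-6:
            return u, v / nv


def make_template(cfg: SynthConfig, seed: int | None = None) -> SynthTemplate:
    """Generate the labelled bundle template, parcellation and surface.

    Bundles are placed by rejection sampling until all dense cores are at
    least ``min_core_separation`` apart; each bundle's template members
    are the core plus a small rigid offset and point noise; the
    parcellation carves one labelled sphere around each core endpoint
    (labels 2i-1, 2i for bundle i) so endpoints always fall within the
    4 mm assignment radius.  Deterministic under (cfg, seed).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    v = cfg.voxel_size
    box = np.asarray(cfg.grid_shape, dtype=float) * v
    margin = cfg.radius_range[1] + cfg.parcel_radius + 2.0

    for _ in range(cfg.max_placement_tries):
        bundles = []
        for i in range(cfg.n_bundles):
            center = rng.uniform(margin, box - margin)
            radius = rng.uniform(*cfg.radius_range)
            theta = np.radians(rng.uniform(*cfg.arc_deg_range))
            u, w = _random_basis(rng)
            bundles.append(
                _Bundle(
                    tract_id=i + 1,
                    center=center,
                    radius=radius,
                    theta=theta,
                    u=u,
                    v=w,
                    phi0=rng.uniform(0, 2 * np.pi),
                )
            )
        cores = [b.core(0.7) for b in bundles]
        ok = True
        for i in range(len(cores)):
            tree = cKDTree(cores[i])
            for j in range(i + 1, len(cores)):
                if tree.query(cores[j])[0].min() < cfg.min_core_separation:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise RuntimeError("could not place non-colliding bundles; relax the configuration")

    tracts = []
    for b in bundles:
        core = b.core(cfg.streamline_step)
        members = []
        for _ in range(cfg.template_streamlines_per_bundle):
            offset = rng.normal(0.0, cfg.template_offset_sd, size=3)
            noise = rng.normal(0.0, cfg.template_point_noise_sd, size=core.shape)
            members.append(core + offset + noise)
        tracts.append(TemplateTract(tract_id=b.tract_id, streamlines=members))

    # parcellation: a labelled sphere around each core endpoint
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = v
    grid = np.zeros(cfg.grid_shape, dtype=np.int32)
    idx = np.indices(cfg.grid_shape).reshape(3, -1).T
    centers = idx * v  # voxel centers in world mm
    lookup: dict[int, ParcelInfo] = {}
    for b in bundles:
        core = b.core(0.7)
        lobe = "other" if b.tract_id in cfg.nonfrontal_bundles else "frontal"
        for k, end in enumerate((core[0], core[-1])):
            lab = 2 * (b.tract_id - 1) + 1 + k
            inside = np.linalg.norm(centers - end[None, :], axis=1) <= cfg.parcel_radius
            flat = grid.reshape(-1)
            paint = inside & (flat == 0)
            flat[paint] = lab
            hemi = "L" if end[0] < box[0] / 2 else "R"
            lookup[lab] = ParcelInfo(
                name=f"parcel_{lab:03d}",
                lobe=lobe,
                hemisphere=hemi,
                network=_NETWORKS[(b.tract_id - 1) % len(_NETWORKS)],
            )
    labels = LabelVolume(grid=grid, affine=affine, lookup=lookup)

    # surface: Fibonacci sphere enclosing the volume
    n = cfg.n_surface_vertices
    k = np.arange(n)
    phi = np.arccos(1 - 2 * (k + 0.5) / n)
    theta_s = np.pi * (1 + 5**0.5) * (k + 0.5)
    r_s = 0.6 * box.min()
    verts = box / 2 + r_s * np.c_[
        np.sin(phi) * np.cos(theta_s), np.sin(phi) * np.sin(theta_s), np.cos(phi)
    ]

    return SynthTemplate(
        tracts=tracts,
        labels=labels,
        surface_vertices=verts,
        bundles=bundles,
        affine=affine,
        grid_shape=cfg.grid_shape,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scalar fields


@dataclass
class _BaseFields:
    """Control-group eigen-metric grids plus the effect-window weight grid."""

    fa: np.ndarray
    rd: np.ndarray
    ad: np.ndarray
    window: np.ndarray  # in [0, 1]; Gaussian arc-length window inside affected tubes


def _base_fields(template: SynthTemplate, cfg: SynthConfig) -> _BaseFields:
    shape = template.grid_shape
    v = cfg.voxel_size
    fa = np.full(shape, cfg.fa_background)
    ad = np.full(shape, cfg.ad_background)
    rd = np.full(shape, radial_for_target_fa(cfg.ad_background, cfg.fa_background))
    window = np.zeros(shape)
    rd_bundle = radial_for_target_fa(cfg.ad_bundle, cfg.fa_bundle)

    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * v
    for b in template.bundles:
        core = b.core(0.7)
        lo = core.min(axis=0) - cfg.tube_radius - v
        hi = core.max(axis=0) + cfg.tube_radius + v
        near = np.all((centers >= lo) & (centers <= hi), axis=1)
        if not near.any():
            continue
        tree = cKDTree(core)
        d, nearest = tree.query(centers[near])
        inside = d <= cfg.tube_radius
        sel = np.where(near)[0][inside]
        flat_fa = fa.reshape(-1)
        flat_ad = ad.reshape(-1)
        flat_rd = rd.reshape(-1)
        flat_fa[sel] = cfg.fa_bundle
        flat_ad[sel] = cfg.ad_bundle
        flat_rd[sel] = rd_bundle
        if b.tract_id in cfg.affected_bundles:
            s = nearest[inside] / (len(core) - 1)  # arc fraction of nearest core point
            g = np.exp(-((s - cfg.effect_center) ** 2) / (2 * cfg.effect_width**2))
            window.reshape(-1)[sel] = g
    return _BaseFields(fa=fa, rd=rd, ad=ad, window=window)


def affected_node_window(cfg: SynthConfig, n_nodes: int = 20, level: float = 0.5) -> list[int]:
    """0-based node indices where the effect window weight is >= ``level``."""
    s = np.arange(n_nodes) / (n_nodes - 1)
    g = np.exp(-((s - cfg.effect_center) ** 2) / (2 * cfg.effect_width**2))
    return [int(i) for i in np.where(g >= level)[0]]


# ---------------------------------------------------------------------------
# subjects


@dataclass
class SynthSubject:
    subject_id: str
    group: str
    tractogram: Tractogram
    volumes: dict[str, ScalarVolume]
    record: dict
    streamline_bundle: list[int]  # generating tract id per streamline; 0 = distractor


def _subject_fields(
    base: _BaseFields,
    cfg: SynthConfig,
    affine: np.ndarray,
    fa_mult: float,
    ad_mult: float,
    delta_s: float,
) -> dict[str, ScalarVolume]:
    factor = 1.0 - delta_s * base.window
    fa = np.clip(base.fa * fa_mult * factor, 0.0, 1.0)
    rd = base.rd / (fa_mult * factor)
    ad = base.ad * ad_mult
    md = (ad + 2.0 * rd) / 3.0
    return {
        "FA": ScalarVolume(fa, affine, "FA"),
        "RD": ScalarVolume(rd, affine, "RD"),
        "AD": ScalarVolume(ad, affine, "AD"),
        "MD": ScalarVolume(md, affine, "MD"),
    }


def make_subject(
    template: SynthTemplate,
    group: str,
    cfg: SynthConfig,
    seed: int,
    base: _BaseFields | None = None,
    subject_id: str = "sub-000",
    age: float | None = None,
    sex: str | None = None,
    delta_s: float | None = None,
) -> SynthSubject:
    """Generate one subject: tractogram, scalar volumes and record.

    Bundle streamlines copy randomly chosen template members with point
    noise and one per-subject rigid offset; straight-line (and optional
    too-short arc) distractors exercise the U-shape filter.  Scalar
    volumes scale the control-group base fields by per-subject FA/AD
    multipliers (with age and sex trends) and, for patients, by the
    localized effect factor 1 - delta_s * window.
    """
    rng = np.random.default_rng(seed)
    if base is None:
        base = _base_fields(template, cfg)
    if age is None:
        age = float(rng.uniform(*cfg.age_range))
    if sex is None:
        sex = "F" if rng.random() < cfg.p_female else "M"
    if delta_s is None:
        delta_s = cfg.delta if group == "patient" else 0.0

    age_mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    fa_mult = float(
        1.0
        + cfg.age_fa_slope * (age - age_mid)
        + cfg.sex_fa_delta * (sex == "F")
        + rng.normal(0.0, cfg.subject_fa_sd)
    )
    ad_mult = float(1.0 + rng.normal(0.0, cfg.subject_ad_sd))
    volumes = _subject_fields(base, cfg, template.affine, fa_mult, ad_mult, delta_s)

    jitter = rng.normal(0.0, cfg.rigid_jitter_sd, size=3)
    streamlines: list[np.ndarray] = []
    bundle_of: list[int] = []
    counts: dict[int, int] = {}
    for tract in template.tracts:
        n = max(int(round(rng.normal(cfg.streamlines_per_bundle_mean, cfg.streamlines_per_bundle_sd))), 0)
        counts[tract.tract_id] = n
        for _ in range(n):
            member = tract.streamlines[rng.integers(len(tract.streamlines))]
            noise = rng.normal(0.0, cfg.point_noise_sd, size=member.shape)
            streamlines.append(member + noise + jitter)
            bundle_of.append(tract.tract_id)
    box = np.asarray(cfg.grid_shape, dtype=float) * cfg.voxel_size
    for _ in range(cfg.n_distractor_straight):
        start = rng.uniform(0.15 * box, 0.85 * box)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(30.0, 70.0)
        npts = max(int(length / cfg.streamline_step) + 1, 2)
        t = np.linspace(0.0, length, npts)
        streamlines.append(start[None, :] + t[:, None] * direction[None, :])
        bundle_of.append(0)
    for _ in range(cfg.n_distractor_short):
        # a U-shaped arc too short for the length band (270 deg, r=3.5 -> ~16.5 mm)
        center = rng.uniform(0.2 * box, 0.8 * box)
        u, w = _random_basis(rng)
        phi = rng.uniform(0, 2 * np.pi) + np.linspace(0.0, 1.5 * np.pi, 12)
        streamlines.append(center[None, :] + 3.5 * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * w))
        bundle_of.append(0)

    record = {
        "subject_id": subject_id,
        "group": group,
        "age": round(age, 2),
        "sex": sex,
        "seed": int(seed),
        "delta_s": float(delta_s),
        "fa_mult": fa_mult,
        "ad_mult": ad_mult,
        "counts": counts,
    }
    return SynthSubject(
        subject_id=subject_id,
        group=group,
        tractogram=Tractogram(streamlines, space_id=f"synth:{subject_id}"),
        volumes=volumes,
        record=record,
        streamline_bundle=bundle_of,
    )


# ---------------------------------------------------------------------------
# cohort


def _clinical_scores(rng: np.random.Generator, group: str, age: float, z_clin: float) -> dict:
    """PANSS-like clinical and cognitive scores (patients shifted, controls floored)."""
    if group == "patient":
        total = float(np.clip(round(20 + 6 * z_clin + rng.normal(0, 2)), 8, 48))
        positive = float(np.clip(round(total * 0.35 + rng.normal(0, 1.5)), 4, 28))
        negative = float(np.clip(round(total * 0.3 + rng.normal(0, 1.5)), 4, 28))
        dup = float(np.round(np.clip(rng.lognormal(1.8, 0.7), 0.5, 120), 1))
        scores = {
            "panss8_total": total,
            "panss8_positive": positive,
            "panss8_negative": negative,
            "cgi_s": float(np.clip(round(4 + rng.normal(0, 1)), 1, 7)),
            "sofas": float(np.clip(round(rng.normal(55, 10)), 1, 100)),
            "dup_months": dup,
            "age_of_onset": round(max(age - dup / 12.0, 12.0), 1),
            "tmtb_time": round(float(np.clip(rng.normal(95, 25), 30, 300)), 1),
            "tmtb_errors": float(rng.poisson(2.0)),
            "category_fluency": float(np.clip(round(rng.normal(16, 4)), 2, 40)),
        }
    else:
        scores = {
            "panss8_total": 8.0,
            "panss8_positive": 4.0,
            "panss8_negative": 4.0,
            "cgi_s": 1.0,
            "sofas": float(np.clip(round(rng.normal(85, 5)), 1, 100)),
            "dup_months": np.nan,
            "age_of_onset": np.nan,
            "tmtb_time": round(float(np.clip(rng.normal(60, 15), 20, 300)), 1),
            "tmtb_errors": float(rng.poisson(0.7)),
            "category_fluency": float(np.clip(round(rng.normal(22, 4)), 2, 40)),
        }
    return scores


@dataclass
class CohortData:
    """A complete in-memory synthetic dataset plus its truth manifest."""

    config: SynthConfig
    template: SynthTemplate
    subjects: list[SynthSubject]
    cohort: pd.DataFrame
    manifest: dict


def make_cohort(cfg: SynthConfig) -> CohortData:
    """Generate the full two-group cohort as a pure function of (cfg, cfg.seed).

    Per-subject seeds are derived deterministically from the master seed.
    Patients draw a per-subject effect magnitude delta_s around
    ``cfg.delta``; when ``clinical_effect_r`` is nonzero the PANSS-8 total
    is coupled to delta_s with that correlation.
    """
    master = np.random.default_rng(cfg.seed)
    template_seed = int(master.integers(2**31))
    template = make_template(cfg, seed=template_seed)
    base = _base_fields(template, cfg)

    groups = ["control"] * cfg.n_controls + ["patient"] * cfg.n_patients
    subjects: list[SynthSubject] = []
    rows = []
    rho = float(np.clip(cfg.clinical_effect_r, -0.999, 0.999))
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        sub_seed = int(master.integers(2**31))
        clin_rng = np.random.default_rng(int(master.integers(2**31)))
        if group == "patient":
            z_eff = clin_rng.normal()
            z_clin = rho * z_eff + np.sqrt(1 - rho**2) * clin_rng.normal()
            delta_s = float(np.clip(cfg.delta * (1.0 + cfg.effect_subject_sd * z_eff), 0.0, 0.95))
        else:
            z_clin = clin_rng.normal()
            delta_s = 0.0
        sub = make_subject(
            template, group, cfg, seed=sub_seed, base=base, subject_id=sid, delta_s=delta_s
        )
        subjects.append(sub)
        row = {
            "subject_id": sid,
            "group": group,
            "age": sub.record["age"],
            "sex": sub.record["sex"],
        }
        row.update(_clinical_scores(clin_rng, group, sub.record["age"], z_clin))
        rows.append(row)
    cohort = pd.DataFrame(rows)

    manifest = {
        "seed": cfg.seed,
        "template_seed": template_seed,
        "n_bundles": cfg.n_bundles,
        "affected_bundles": list(cfg.affected_bundles),
        "affected_nodes": affected_node_window(cfg),
        "delta": cfg.delta,
        "subjects": [
            {
                **{k: v for k, v in s.record.items() if k != "counts"},
                "counts": {str(k): v for k, v in s.record["counts"].items()},
                "streamline_bundle": s.streamline_bundle,
            }
            for s in subjects
        ],
    }
    return CohortData(config=cfg, template=template, subjects=subjects, cohort=cohort, manifest=manifest)


def write_cohort(data: CohortData, out_dir) -> Path:
    """Write a cohort to disk in the layout the pipeline consumes.

    out_dir/
      template/template.tck, template_labels.tsv
      template/parcellation.nii.gz, parcel_lookup.tsv, surface_vertices.tsv
      subjects/<id>/<id>.tck, <id>_FA.nii.gz, _RD, _AD, _MD
      cohort.tsv, truth_manifest.json
    """
    from .io import save_scalar_volume, save_tractogram

    out = Path(out_dir)
    tdir = out / "template"
    tdir.mkdir(parents=True, exist_ok=True)

    template = data.template
    all_streamlines, rows = [], []
    k = 0
    for tract in template.tracts:
        meta = data.template.tract_meta.set_index("tract_id").loc[tract.tract_id]
        for s in tract.streamlines:
            all_streamlines.append(s)
            rows.append((k, tract.tract_id, meta["tract_name"], meta["lobe"], meta["hemisphere"], meta["network"]))
            k += 1
    save_tractogram(Tractogram(all_streamlines, space_id="synth:template"), tdir / "template.tck")
    pd.DataFrame(
        rows, columns=["streamline_index", "tract_id", "tract_name", "lobe", "hemisphere", "network"]
    ).to_csv(tdir / "template_labels.tsv", sep="\t", index=False)

    lab = ScalarVolume(template.labels.grid.astype(float), template.labels.affine, "labels")
    save_scalar_volume(lab, tdir / "parcellation.nii.gz")
    pd.DataFrame(
        [
            (l, p.name, p.lobe, p.hemisphere, p.network)
            for l, p in sorted(template.labels.lookup.items())
        ],
        columns=["label", "name", "lobe", "hemisphere", "network"],
    ).to_csv(tdir / "parcel_lookup.tsv", sep="\t", index=False)
    pd.DataFrame(template.surface_vertices, columns=["x", "y", "z"]).to_csv(
        tdir / "surface_vertices.tsv", sep="\t", index=False
    )

    for sub in data.subjects:
        sdir = out / "subjects" / sub.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        save_tractogram(sub.tractogram, sdir / f"{sub.subject_id}.tck")
        for metric, vol in sub.volumes.items():
            save_scalar_volume(vol, sdir / f"{sub.subject_id}_{metric}.nii.gz")

    data.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(data.manifest, fh, indent=1)
    return out


# ---------------------------------------------------------------------------
# small deterministic fixtures


def make_filter_fixture(
    n_arcs: int = 50,
    n_straight: int = 50,
    n_short: int = 10,
    seed: int = 0,
) -> tuple[Tractogram, list[bool]]:
    """A mixed tractogram for exercising the U-shape filter.

    ``n_arcs`` qualifying arcs (270-300 deg, radius 9-13 mm), ``n_straight``
    straight lines in the length band (chord ratio 1), and ``n_short``
    too-short arcs (< 20 mm).  Returns the tractogram and the per-streamline
    expected filter verdicts.
    """
    rng = np.random.default_rng(seed)
    streamlines, truth = [], []

    def arc(radius, theta_deg):
        u, w = _random_basis(rng)
        center = rng.uniform(20, 80, size=3)
        theta = np.radians(theta_deg)
        n = max(int(radius * theta / 1.5) + 1, 8)
        phi = rng.uniform(0, 2 * np.pi) + np.linspace(0, theta, n)
        return center[None, :] + radius * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * w)

    for _ in range(n_arcs):
        streamlines.append(arc(rng.uniform(9, 13), rng.uniform(270, 300)))
        truth.append(True)
    for _ in range(n_straight):
        start = rng.uniform(10, 90, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(30, 70)
        t = np.linspace(0, length, 12)
        streamlines.append(start[None, :] + t[:, None] * d[None, :])
        truth.append(False)
    for _ in range(n_short):
        streamlines.append(arc(rng.uniform(3.0, 4.0), 270.0))
        truth.append(False)
    return Tractogram(streamlines, space_id="synth:filter-fixture"), truth
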