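"""DTI scalar metrics and along-tract profiling.

The diffusion tensor's sorted eigenvalues (l1 >= l2 >= l3 >= 0, mm^2/s)
summarise to four scalars:

    MD = (l1 + l2 + l3) / 3          mean diffusivity
    AD = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy, in [0, 1]

Profiling maps a scalar volume onto 20 equidistant nodes of each
streamline (trilinear interpolation in voxel space) and averages node-wise
over the flip-aligned members of a tract, giving one 20-node profile per
(subject, tract, metric).  Samples falling outside the grid become NaN and
are excluded node-wise, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .geometry import ScalarVolume, resample_equidistant

__all__ = [
    "DTIMetrics",
    "TractProfile",
    "ProfileMatrix",
    "METRICS",
    "dti_metrics",
    "fa_from_eigenvalues",
    "radial_for_target_fa",
    "sample_volume_along",
    "tract_profile",
    "tract_mean",
    "tract_density",
    "segment_mean",
]

METRICS = ("FA", "RD", "AD", "MD")
N_NODES = 20


@dataclass(frozen=True)
class DTIMetrics:
    FA: float
    MD: float
    AD: float
    RD: float


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from eigenvalues; 0 where the tensor is null."""
    l1, l2, l3 = (np.asarray(x, dtype=np.float64) for x in (l1, l2, l3))
    md = (l1 + l2 + l3) / 3.0
    num = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    den = np.sqrt(l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def dti_metrics(l1: float, l2: float, l3: float) -> DTIMetrics:
    """Closed-form DTI scalars from sorted eigenvalues (l1 >= l2 >= l3).

    Negative eigenvalues are clipped to zero (they arise from noisy tensor
    fits and have no physical meaning).
    """
    lam = np.clip(np.asarray([l1, l2, l3], dtype=np.float64), 0.0, None)
    l1, l2, l3 = lam
    md = float(lam.mean())
    return DTIMetrics(
        FA=float(fa_from_eigenvalues(l1, l2, l3)),
        MD=md,
        AD=float(l1),
        RD=float((l2 + l3) / 2.0),
    )


def radial_for_target_fa(ad: float, fa: float) -> float:
    """Radial eigenvalue x such that (ad, x, x) has the requested FA.

    For an axially symmetric tensor FA = (ad - x)/sqrt(ad^2 + 2 x^2)
    (x <= ad), which inverts to x = ad (1 - f sqrt(3 - 2 f^2))/(1 - 2 f^2).
    Valid for fa < 1/sqrt(2) onto the prolate branch.
    """
    if not 0 <= fa < 1 / np.sqrt(2):
        raise ValueError("target FA must be in [0, 1/sqrt(2)) for the prolate branch")
    f2 = fa * fa
    return float(ad * (1.0 - fa * np.sqrt(3.0 - 2.0 * f2)) / (1.0 - 2.0 * f2))


def sample_volume_along(nodes: np.ndarray, vol: ScalarVolume) -> np.ndarray:
    """Trilinear samples of a scalar volume at world-mm node positions.

    Nodes outside the grid yield NaN (missing downstream, never clamped).
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=np.float64))
    inv = np.linalg.inv(vol.affine)
    vox = (inv[:3, :3] @ nodes.T + inv[:3, 3:4])
    return map_coordinates(vol.grid, vox, order=1, mode="constant", cval=np.nan)


@dataclass
class TractProfile:
    """Node-wise mean of one metric along one tract for one subject."""

    tract_id: int
    metric_name: str
    values: np.ndarray  # (n_nodes,), NaN where every sample was missing
    n_streamlines: int


def tract_profile(
    cluster: list[np.ndarray],
    vol: ScalarVolume,
    prototype: np.ndarray,
    n_nodes: int = N_NODES,
    tract_id: int = -1,
) -> TractProfile:
    """Along-tract profile: flip-align, resample, sample, node-wise mean.

    Members are flip-aligned to the prototype (so node k means the same
    arc position on every member), resampled to ``n_nodes`` equidistant
    points, sampled trilinearly, and averaged node-wise ignoring missing
    samples.
    """
    if not cluster:
        raise ValueError("empty cluster")
    proto = resample_equidistant(prototype, n_nodes)
    rows = np.empty((len(cluster), n_nodes))
    for i, s in enumerate(cluster):
        rs = resample_equidistant(s, n_nodes)
        direct = np.linalg.norm(rs - proto, axis=1).mean()
        flipped = np.linalg.norm(rs[::-1] - proto, axis=1).mean()
        if flipped < direct:
            rs = rs[::-1]
        rows[i] = sample_volume_along(rs, vol)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(rows, axis=0)
    return TractProfile(
        tract_id=tract_id,
        metric_name=vol.metric_name,
        values=values,
        n_streamlines=len(cluster),
    )


def tract_mean(profile: TractProfile) -> float:
    """Mean over the profile's non-missing nodes (NaN if all missing)."""
    v = profile.values
    if np.all(np.isnan(v)):
        return float("nan")
    return float(np.nanmean(v))


def tract_density(cluster) -> int:
    """Streamline count of a tract cluster."""
    return len(cluster)


def segment_mean(profile: TractProfile, node_set) -> float:
    """Mean of the profile over a node subset (0-based indices)."""
    idx = np.asarray(sorted(set(int(i) for i in node_set)))
    if idx.size == 0:
        raise ValueError("node_set is empty")
    if idx.min() < 0 or idx.max() >= len(profile.values):
        raise ValueError("node_set outside profile range")
    return float(np.nanmean(profile.values[idx]))


@dataclass
class ProfileMatrix:
    """subjects x tracts x nodes x metrics array of along-tract means.

    Missing (subject, tract) entries are NaN-filled and tracked in
    ``missing`` rather than silently zeroed.
    """

    data: np.ndarray  # (n_subjects, n_tracts, n_nodes, n_metrics)
    subject_ids: list[str]
    tract_ids: list[int]
    metrics: tuple[str, ...] = METRICS
    missing: set = field(default_factory=set)  # {(subject_id, tract_id)}

    def metric_index(self, metric: str) -> int:
        return self.metrics.index(metric)

    def metric_slab(self, metric: str) -> np.ndarray:
        """(n_subjects, n_tracts, n_nodes) view for one metric."""
        return self.data[..., self.metric_index(metric)]

    def to_tidy(self, groups: dict[str, str] | None = None) -> pd.DataFrame:
        """Long-format table: subject, group, tract_id, metric, node, value."""
        recs = []
        for si, sid in enumerate(self.subject_ids):
            for ti, tid in enumerate(self.tract_ids):
                if (sid, tid) in self.missing:
                    continue
                for mi, metric in enumerate(self.metrics):
                    for node in range(self.data.shape[2]):
                        recs.append(
                            (
                                sid,
                                groups.get(sid, "") if groups else "",
                                tid,
                                metric,
                                node + 1,
                                self.data[si, ti, node, mi],
                            )
                        )
        return pd.DataFrame(
            recs, columns=["subject", "group", "tract_id", "metric", "node", "value"]
        )
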