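"""Synthetic time-lapse microscopy stage.

Renders ensemble trajectories into cluster-level fluorescence traces shaped
like the time-lapse experiment the model describes: GFP intensity averaged
over a cluster of cells, one frame every 20 min over 1080 min, with
multiplicative measurement noise and an additive background.  Cluster
membership may drift from frame to frame, emulating cells joining and
leaving the imaged groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleTrajectory
from .errors import InvalidArgumentError
from .model import GFP_INDEX

#: Acquisition cadence of the emulated microscope (minutes).
DEFAULT_FRAME_INTERVAL = 20.0
#: Emulated experiment duration (minutes); frames at k*20 for k = 0..54.
DEFAULT_DURATION = 1080.0
#: Number of emulated cell clusters.
DEFAULT_N_CLUSTERS = 5


@dataclass
class ClusterTraceSet:
    """Per-cluster fluorescence intensities at microscope cadence."""

    frame_times: np.ndarray            # minutes, regular grid
    cluster_ids: np.ndarray            # shape (n_clusters,)
    intensities: np.ndarray            # [frame, cluster], arbitrary units, >= 0
    memberships: np.ndarray            # [frame, cell] -> cluster id
    noise_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.intensities < 0):
            raise InvalidArgumentError("intensities must be >= 0")
        steps = np.diff(self.frame_times)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise InvalidArgumentError("frame grid must be regular")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def frame_interval(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])


def assign_clusters(n_cells: int, n_clusters: int, n_frames: int, seed: int,
                    churn: float = 0.0) -> np.ndarray:
    """Frame-by-frame cluster memberships with random churn.

    Cells are partitioned uniformly at random into ``n_clusters`` groups at
    frame 0; at every subsequent frame each cell independently switches to a
    uniformly chosen other cluster with probability ``churn`` (the cluster
    populations therefore drift over time).  Reproducible from ``seed``.

    Returns an integer array of shape (n_frames, n_cells).
    """
    if not 1 <= n_clusters <= n_cells:
        raise InvalidArgumentError("need 1 <= n_clusters <= n_cells")
    if not 0 <= churn < 1:
        raise InvalidArgumentError("churn must lie in [0, 1)")
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    member = np.empty((n_frames, n_cells), dtype=int)
    member[0] = rng.integers(0, n_clusters, size=n_cells)
    for f in range(1, n_frames):
        cur = member[f - 1].copy()
        if churn > 0 and n_clusters > 1:
            switch = rng.random(n_cells) < churn
            if switch.any():
                shift = rng.integers(1, n_clusters, size=int(switch.sum()))
                cur[switch] = (cur[switch] + shift) % n_clusters
        member[f] = cur
    return member


def render(traj: EnsembleTrajectory, memberships: np.ndarray | None = None,
           frame_interval: float = DEFAULT_FRAME_INTERVAL,
           duration: float = DEFAULT_DURATION,
           gain: float = 1.0, background: float = 0.0,
           noise_cv: float = 0.0, seed: int = 0,
           n_clusters: int = DEFAULT_N_CLUSTERS,
           churn: float = 0.0) -> ClusterTraceSet:
    """Render a trajectory into microscope-like cluster fluorescence.

    Each cluster's intensity at a frame is ``gain * mean(GFP over member
    cells) + background``, perturbed multiplicatively by lognormal noise with
    coefficient of variation ``noise_cv`` and clipped at zero.  Frame times
    sample the trajectory by linear interpolation.  If ``memberships`` is
    None, :func:`assign_clusters` is called with ``n_clusters``/``churn`` and
    a seed derived from ``seed``.
    """
    if duration > traj.times[-1] + 1e-9:
        raise InvalidArgumentError(
            f"duration {duration} min exceeds trajectory span {traj.times[-1]} min")
    if noise_cv < 0 or gain < 0 or background < 0:
        raise InvalidArgumentError("gain, background, noise_cv must be >= 0")
    frame_times = np.arange(0.0, duration + frame_interval / 2, frame_interval)
    n_frames = len(frame_times)
    n_cells = traj.n_cells
    rng = np.random.default_rng(seed)
    if memberships is None:
        memberships = assign_clusters(n_cells, n_clusters, n_frames,
                                      seed=int(rng.integers(2**31)), churn=churn)
    memberships = np.asarray(memberships)
    if memberships.shape != (n_frames, n_cells):
        raise InvalidArgumentError(
            f"memberships must have shape {(n_frames, n_cells)}")

    gfp = traj.gfp  # (time, cell)
    sampled = np.empty((n_frames, n_cells))
    for i in range(n_cells):
        sampled[:, i] = np.interp(frame_times, traj.times, gfp[:, i])

    cluster_ids = np.arange(int(memberships.max()) + 1)
    intensities = np.zeros((n_frames, len(cluster_ids)))
    for f in range(n_frames):
        for c in cluster_ids:
            mask = memberships[f] == c
            mean_gfp = sampled[f, mask].mean() if mask.any() else 0.0
            intensities[f, c] = gain * mean_gfp + background
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv ** 2)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2),
                                size=intensities.shape)
        intensities = intensities * factors
    intensities = np.clip(intensities, 0.0, None)
    return ClusterTraceSet(frame_times=frame_times, cluster_ids=cluster_ids,
                           intensities=intensities, memberships=memberships,
                           noise_meta={"gain": gain, "background": background,
                                       "noise_cv": noise_cv, "seed": seed,
                                       "noise_model": "multiplicative lognormal, mean 1"})
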