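"""Membrane and ion observables along trajectories.

``lipid_density_map`` reproduces the classic "where do the lipid
phosphorus atoms sit around the protein" analysis: every frame is aligned
onto the first frame using a protein selection, lipid atom positions are
split into upper/lower leaflet by z, and their xy positions are
accumulated on a 2D grid (counts normalized per frame).

``ion_occupancy`` counts, per frame, the ions within a cutoff of any
binding-site atom — the desk-scale version of counting K+/Ca2+ at the
transmembrane sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import apply_transform, superpose
from .structure import SelectionError, Trajectory

__all__ = ["GridSpec", "lipid_density_map", "ion_occupancy"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """A square xy histogram grid: [x_min, x_max] x [y_min, y_max], n x n bins."""

    x_min: float = -70.0
    x_max: float = 70.0
    y_min: float = -70.0
    y_max: float = 70.0
    n_bins: int = 35

    @property
    def x_edges(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_bins + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.n_bins + 1)

    def bin_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        xe, ye = self.x_edges, self.y_edges
        return 0.5 * (xe[:-1] + xe[1:]), 0.5 * (ye[:-1] + ye[1:])


def lipid_density_map(
    traj: Trajectory,
    lipid_sel: str = "element P",
    frame_alignment_sel: Optional[str] = "name CA",
    grid: GridSpec = GridSpec(),
    leaflet_split_z: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-leaflet 2D lipid density maps, counts per frame.

    Returns ``(upper, lower)`` histograms of shape ``(n_bins, n_bins)``
    (x along axis 0).  Frames are rigid-aligned on
    ``frame_alignment_sel`` to frame 0 before binning (pass ``None`` to
    skip).  The leaflet split is at ``leaflet_split_z``; by default the
    per-frame median z of the lipid atoms, which is robust to a drifting
    membrane.
    """
    lipid_mask = traj.mask(lipid_sel)
    if not lipid_mask.any():
        raise SelectionError(f"lipid selection {lipid_sel!r} matches no atoms")
    align_mask = None
    if frame_alignment_sel is not None:
        align_mask = traj.mask(frame_alignment_sel)
        if not align_mask.any():
            raise SelectionError(
                f"alignment selection {frame_alignment_sel!r} matches no atoms"
            )

    coords = traj.coords
    upper = np.zeros((grid.n_bins, grid.n_bins))
    lower = np.zeros((grid.n_bins, grid.n_bins))
    n_total = 0
    n_inside = 0
    ref = coords[0][align_mask] if align_mask is not None else None
    for f in range(traj.n_frames):
        frame = coords[f]
        if align_mask is not None and f > 0:
            R, t, _ = superpose(frame[align_mask], ref)
            frame = apply_transform(frame, R, t)
        lipids = frame[lipid_mask]
        split = float(np.median(lipids[:, 2])) if leaflet_split_z is None else leaflet_split_z
        for half, hist in ((lipids[:, 2] >= split, upper), (lipids[:, 2] < split, lower)):
            pts = lipids[half]
            h, _, _ = np.histogram2d(
                pts[:, 0], pts[:, 1], bins=[grid.x_edges, grid.y_edges]
            )
            hist += h
            n_total += len(pts)
            n_inside += int(h.sum())
    if n_total and n_inside < 0.5 * n_total:
        log.warning(
            "lipid density grid covers only %.0f%% of lipid atoms",
            100.0 * n_inside / n_total,
        )
    return upper / traj.n_frames, lower / traj.n_frames


def ion_occupancy(
    traj: Trajectory,
    ion_sel: str,
    site_sel: str,
    cutoff: float = 4.0,
) -> np.ndarray:
    """Per-frame count of ions within ``cutoff`` A of any site atom.

    Summary statistics (mode, mean) are left to the caller; the raw count
    series is the fundamental observable.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ion_mask = traj.mask(ion_sel)
    site_mask = traj.mask(site_sel)
    if not ion_mask.any():
        raise SelectionError(f"ion selection {ion_sel!r} matches no atoms")
    if not site_mask.any():
        raise SelectionError(f"site selection {site_sel!r} matches no atoms")
    coords = traj.coords
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        d = cdist(coords[f][ion_mask], coords[f][site_mask])
        counts[f] = int((d.min(axis=1) < cutoff).sum())
    return counts
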