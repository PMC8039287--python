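"""Micro-post array detector (mPAD) calibration.

Elastomeric micro-posts (8.3 um tall, 1.83 um diameter, hexagonally
packed at 4 um pitch) bend when a fluid pulse loads them; for small
deflections each post is a linear spring with an end-load constant of
7.22 nN/um.  Given centroid tables of the posts before and during the
pulse, this module computes the displacement field, the force field
``F = k * |x|``, and a pressure estimate from the post cross-section,
``P = F / (pi (d/2)^2)``, reported in kPa and PSI.

With forces in nN and areas in um^2, 1 nN/um^2 equals exactly 1 kPa.
Note that the pressure obtained from the post cross-sectional area for
the calibrated 0.4-1.2 nN force range lands near 0.15-0.46 kPa
(0.02-0.07 PSI); pressure figures quoted from other area conventions
will differ, so both the formula and its inputs are reported alongside
the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PostGrid",
    "displacement_field",
    "force_field",
    "pressure_estimate",
    "analyze_post_table",
]

DEFAULT_SPRING_NN_PER_UM = 7.22
DEFAULT_POST_DIAMETER_UM = 1.83
DEFAULT_POST_HEIGHT_UM = 8.3
DEFAULT_PITCH_UM = 4.0
KPA_TO_PSI = 0.1450377377


@dataclass
class PostGrid:
    """Matched before/during post centroids with the post mechanics."""

    before: np.ndarray                      # (n, 2) um
    during: np.ndarray                      # (n, 2) um
    spring_constant: float = DEFAULT_SPRING_NN_PER_UM   # nN/um
    post_diameter: float = DEFAULT_POST_DIAMETER_UM     # um
    post_height: float = DEFAULT_POST_HEIGHT_UM         # um
    pitch: float = DEFAULT_PITCH_UM                     # um

    def __post_init__(self) -> None:
        self.before = np.asarray(self.before, dtype=float)
        self.during = np.asarray(self.during, dtype=float)
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.before.shape != self.during.shape:
            raise ValueError("before/during centroid counts differ")


def displacement_field(
    before: np.ndarray, during: np.ndarray, pitch: float = DEFAULT_PITCH_UM
) -> np.ndarray:
    """Per-post displacement vectors (um) from matched centroid sets.

    ``during`` centroids are matched to ``before`` posts by nearest
    neighbor; a match farther than half the pitch, or two during-points
    claiming one post, is ambiguous and raises with the offending post
    indices.
    """
    before = np.asarray(before, dtype=float)
    during = np.asarray(during, dtype=float)
    if before.shape != during.shape:
        raise ValueError("before/during centroid counts differ")
    tree = cKDTree(before)
    dist, idx = tree.query(during)
    bad = np.nonzero(dist > pitch / 2.0)[0]
    if bad.size:
        raise ValueError(f"ambiguous matching: during-centroids {bad.tolist()} "
                         f"exceed half-pitch from any post")
    counts = np.bincount(idx, minlength=before.shape[0])
    dup = np.nonzero(counts > 1)[0]
    if dup.size:
        raise ValueError(f"ambiguous matching: posts {dup.tolist()} claimed twice")
    disp = np.empty_like(before)
    disp[idx] = during - before[idx]
    return disp


def force_field(displacements: np.ndarray, k: float = DEFAULT_SPRING_NN_PER_UM) -> np.ndarray:
    """Per-post force vectors (nN): linear spring, direction preserved."""
    if k <= 0:
        raise ValueError("spring constant must be positive")
    return k * np.asarray(displacements, dtype=float)


def pressure_estimate(
    force_nn: np.ndarray | float, post_diameter: float = DEFAULT_POST_DIAMETER_UM
) -> dict:
    """Pressure over the post cross-section, in kPa and PSI.

    ``P = F / (pi (d/2)^2)`` with F in nN and d in um gives kPa
    directly (1 nN/um^2 = 1 kPa).
    """
    if post_diameter <= 0:
        raise ValueError("post diameter must be positive")
    f = np.asarray(force_nn, dtype=float)
    area = np.pi * (post_diameter / 2.0) ** 2
    kpa = f / area
    return {
        "area_um2": float(area),
        "pressure_kpa": kpa if kpa.ndim else float(kpa),
        "pressure_psi": kpa * KPA_TO_PSI if kpa.ndim else float(kpa * KPA_TO_PSI),
    }


def analyze_post_table(
    table: pd.DataFrame,
    k: float = DEFAULT_SPRING_NN_PER_UM,
    post_diameter: float = DEFAULT_POST_DIAMETER_UM,
    pitch: float = DEFAULT_PITCH_UM,
) -> pd.DataFrame:
    """Displacement, force and pressure per post from a centroid table.

    Expects columns ``post_id, x_before, y_before, x_during, y_during``
    in micrometers (the dialect the synthetic generator writes).
    """
    before = table[["x_before", "y_before"]].to_numpy()
    during = table[["x_during", "y_during"]].to_numpy()
    disp = displacement_field(before, during, pitch)
    force = force_field(disp, k)
    mag = np.linalg.norm(force, axis=1)
    pres = pressure_estimate(mag, post_diameter)
    return pd.DataFrame(
        {
            "post_id": table["post_id"].to_numpy(),
            "dx_um": disp[:, 0], "dy_um": disp[:, 1],
            "displacement_um": np.linalg.norm(disp, axis=1),
            "force_nN": mag,
            "pressure_kPa": pres["pressure_kpa"],
            "pressure_PSI": pres["pressure_psi"],
        }
    )
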