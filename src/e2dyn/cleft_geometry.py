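"""Stage 4: catalytic-cleft geometry and accessibility.

Shrake–Rupley solvent-accessible surface area of the catalytic cysteine
side chain, the distance between the centers of mass of the catalytic
residue and the acidic loop, open/closed classification of the loop, and
their joint per-frame profile (avSAS, state fractions, and the d–SAS
correlation).

Relative side-chain SASA uses a self-consistent reference: the same atoms
computed in isolation with the same engine and parameters, so the
percentage does not depend on an external normalisation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .structio import ConformerSet, RegionSpec, select_atoms, sidechain_indices
from .convergence import ScalarSeries

__all__ = [
    "VDW_RADII",
    "StateThresholds",
    "CleftProfile",
    "fibonacci_sphere",
    "atom_radii",
    "shrake_rupley",
    "relative_sidechain_sasa",
    "loop_cys_distance",
    "classify_state",
    "cleft_profile",
]

#: van-der-Waals radii (Å) — a fixed published table
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class StateThresholds:
    """Loop-state classification cutoffs on the loop–cysteine COM distance.

    closed: d ≤ d_closed (inclusive); open: d ≥ d_open; else intermediate.
    """

    d_closed: float = 8.0
    d_open: float = 12.0

    def __post_init__(self) -> None:
        if not self.d_closed < self.d_open:
            raise ValueError("need d_closed < d_open")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def atom_radii(cs: ConformerSet) -> np.ndarray:
    """Per-atom van-der-Waals radii from the element column."""
    return np.array([VDW_RADII.get(e, VDW_RADII["C"]) for e in cs.atoms["element"]])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    subset=None,
    sphere_points: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Ų).

    Each atom's expanded sphere of radius r + probe carries ``n_points``
    quasi-uniform test points; SASA = 4π(r+probe)² × the fraction of
    points not *strictly* inside any neighboring expanded sphere (boundary
    contacts count as exposed).  ``subset`` restricts which atoms' areas
    are computed (all atoms still act as blockers).  ``sphere_points``
    overrides the default golden-spiral lattice with caller-supplied unit
    vectors (e.g. a rotated copy, for exact rigid-motion equivariance).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be > 0")
    if n_points < 32:
        raise ValueError("need at least 32 sphere points")
    A = coords.shape[0]
    if subset is None:
        subset = np.arange(A)
    subset = np.asarray(subset)
    if sphere_points is None:
        sphere = fibonacci_sphere(n_points)
    else:
        sphere = np.asarray(sphere_points, dtype=float)
        n_points = sphere.shape[0]
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(A)
    rmax = expanded.max()
    for i in subset:
        pts = coords[i] + expanded[i] * sphere
        neighbor_ids = tree.query_ball_point(coords[i], expanded[i] + rmax)
        neighbor_ids = [j for j in neighbor_ids if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_ids:
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= expanded[i] + expanded[j]:
                continue
            dist2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= dist2 >= expanded[j] ** 2  # strictly inside -> buried
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return out


def relative_sidechain_sasa(
    cs: ConformerSet,
    residue: int,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> ScalarSeries:
    """Per-frame relative side-chain SASA (%) of a residue.

    100 × (side-chain SASA in the full structural context) / (side-chain
    SASA of the same atoms in isolation, same engine and parameters).
    """
    sc = sidechain_indices(cs, residue)
    if sc.size == 0:
        raise ValueError(f"residue {residue} has no side-chain atoms")
    radii = atom_radii(cs)
    values = np.empty(cs.n_frames)
    for f in range(cs.n_frames):
        frame = cs.frames[f]
        context = shrake_rupley(frame, radii, probe, n_points, subset=sc)[sc].sum()
        iso = shrake_rupley(frame[sc], radii[sc], probe, n_points).sum()
        values[f] = 100.0 * context / iso
    return ScalarSeries(times=cs.times, values=values, label=f"relSASA_{residue}", unit="%")


def loop_cys_distance(cs: ConformerSet, region: RegionSpec) -> ScalarSeries:
    """Per-frame distance (Å) between the centroids of the acidic-loop
    atoms and the catalytic-residue atoms."""
    if region.acidic_loop is None:
        raise ValueError("region has no acidic loop (distance not applicable)")
    loop_idx = select_atoms(cs, residues=region.acidic_loop)
    cat_idx = select_atoms(cs, residues=region.catalytic_residue)
    if loop_idx.size == 0:
        raise ValueError("acidic-loop selection is empty")
    if cat_idx.size == 0:
        raise ValueError("catalytic-residue selection is empty")
    d = np.linalg.norm(
        cs.frames[:, loop_idx, :].mean(axis=1) - cs.frames[:, cat_idx, :].mean(axis=1),
        axis=1,
    )
    return ScalarSeries(times=cs.times, values=d, label="loop_cys_distance", unit="A")


def classify_state(
    d: np.ndarray, sas: np.ndarray | None = None, thresholds: StateThresholds = StateThresholds()
) -> np.ndarray:
    """Label each frame open/closed/intermediate from the loop distance.

    The SAS values are carried alongside in the joint profile but do not
    enter the label.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    labels = np.where(
        d <= thresholds.d_closed, "closed", np.where(d >= thresholds.d_open, "open", "intermediate")
    )
    return labels


@dataclass
class CleftProfile:
    """Joint per-frame loop-distance / accessibility table with summaries."""

    table: pd.DataFrame  # frame, d_A, d_nm, sas_pct, state
    avsas: float
    state_fractions: dict[str, float]
    pearson_r: float | None
    pearson_note: str = ""
    thresholds: StateThresholds = field(default_factory=StateThresholds)


def cleft_profile(
    cs: ConformerSet,
    region: RegionSpec,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    thresholds: StateThresholds = StateThresholds(),
) -> CleftProfile:
    """Joint distribution of loop–cysteine distance and relative SASA.

    Returns the per-frame table plus summary statistics: avSAS (mean
    relative side-chain SASA, %), open/closed/intermediate fractions, and
    the Pearson correlation between distance and SASA (undefined for a
    zero-variance input, reported with a note).
    """
    d = loop_cys_distance(cs, region)
    sas = relative_sidechain_sasa(cs, region.catalytic_residue, probe, n_points)
    states = classify_state(d.values, sas.values, thresholds)
    table = pd.DataFrame(
        {
            "frame": np.arange(cs.n_frames),
            "d_A": d.values,
            "d_nm": d.values / 10.0,
            "sas_pct": sas.values,
            "state": states,
        }
    )
    fractions = {
        s: float(np.mean(states == s)) for s in ("closed", "intermediate", "open")
    }
    r: float | None
    note = ""
    if cs.n_frames < 2 or np.std(d.values) == 0 or np.std(sas.values) == 0:
        r = None
        note = "correlation undefined (zero variance or single frame)"
    else:
        r = float(stats.pearsonr(d.values, sas.values).statistic)
    return CleftProfile(
        table=table,
        avsas=float(np.mean(sas.values)),
        state_fractions=fractions,
        pearson_r=r,
        pearson_note=note,
        thresholds=thresholds,
    )
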