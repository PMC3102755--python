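"""Stage 1: convergence diagnostics.

RMSD series against the initial structure, plateau-based equilibration
detection, assembly of macro-trajectories (the equilibrated portions of all
replicas of one system joined together), per-residue Cα RMSF profiles, and
the cross-replica RMSF consistency check (pairwise Pearson r, pass above a
0.6 threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .structio import ConformerSet, select_atoms, superpose, align_frames

__all__ = [
    "ScalarSeries",
    "FlexibilityProfile",
    "EquilibrationResult",
    "ConsistencyResult",
    "rmsd_series",
    "detect_equilibration",
    "build_macrotrajectory",
    "rmsf_profile",
    "rmsf_consistency",
]


@dataclass
class ScalarSeries:
    """A per-frame scalar quantity with its time base (ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) > 0) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing when time-ordered")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, self.label or "value": self.values})


@dataclass
class FlexibilityProfile:
    """Per-residue Cα RMSF (Å)."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residue_numbers.shape != self.rmsf.shape:
            raise ValueError("residue_numbers and rmsf must have equal length")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_numbers, "rmsf_A": self.rmsf})


@dataclass(frozen=True)
class EquilibrationResult:
    cut: int
    converged: bool


@dataclass
class ConsistencyResult:
    matrix: np.ndarray
    passed: bool
    threshold: float
    reasons: list[str]

    @property
    def min_offdiagonal(self) -> float:
        n = self.matrix.shape[0]
        off = self.matrix[~np.eye(n, dtype=bool)]
        return float(np.nanmin(off))


# ---------------------------------------------------------------------------


def rmsd_series(
    cs: ConformerSet,
    reference=0,
    fit_indices=None,
    measure_indices=None,
) -> ScalarSeries:
    """Per-frame RMSD after least-squares superposition.

    ``reference`` is a frame index or an external (A, 3) coordinate array;
    fitting uses ``fit_indices`` and the RMSD is measured over
    ``measure_indices`` (both default to all atoms).
    """
    if isinstance(reference, (int, np.integer)):
        ref = cs.frames[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (cs.n_atoms, 3):
            raise ValueError("external reference must match the atom count")
    if fit_indices is None:
        fit_indices = np.arange(cs.n_atoms)
    if measure_indices is None:
        measure_indices = np.arange(cs.n_atoms)
    measure_indices = np.asarray(measure_indices)
    superpose(cs.frames[0], ref, fit_indices)  # contract checks (count, collinearity)
    aligned = align_frames(cs.frames, ref, fit_indices)
    diff = aligned[:, measure_indices, :] - ref[measure_indices]
    values = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return ScalarSeries(times=cs.times, values=values, label="rmsd", unit="A")


def detect_equilibration(
    s: ScalarSeries,
    window: int | None = None,
    slope_tol: float = 1e-3,
    plateau_tol: float = 0.5,
) -> EquilibrationResult:
    """Smallest cut index from which the series has reached a plateau.

    A candidate cut ``i`` is accepted when the least-squares slope of the
    values over ``[i, i + window)`` is below ``slope_tol`` (Å/frame) in
    magnitude and the window mean lies within ``plateau_tol`` (Å) of the
    mean of the whole remaining series ``values[i:]``.  If no cut
    satisfies both, the full length is returned with ``converged=False``.

    The window defaults to 10% of the series (minimum 10 frames).
    """
    v = s.values
    n = len(v)
    if window is None:
        window = max(10, n // 10)
    if n <= 2 * window:
        raise ValueError(f"series of length {n} too short for window {window}")
    x = np.arange(window, dtype=float)
    x -= x.mean()
    denom = float(np.sum(x * x))
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(n - window + 1):
        w = v[i : i + window]
        slope = float(np.sum(x * w)) / denom
        if abs(slope) >= slope_tol:
            continue
        rest_mean = (csum[n] - csum[i]) / (n - i)
        if abs(w.mean() - rest_mean) < plateau_tol:
            return EquilibrationResult(cut=i, converged=True)
    return EquilibrationResult(cut=n, converged=False)


def build_macrotrajectory(replicas: list[ConformerSet], cuts: list[int]) -> ConformerSet:
    """Join the equilibrated portions ``frames[cut:]`` of all replicas.

    Per-frame provenance (replica id and original frame index) is kept in
    ``meta['frame_replica']`` / ``meta['frame_origin']``.
    """
    if len(replicas) != len(cuts):
        raise ValueError("one cut per replica required")
    if not replicas:
        raise ValueError("need at least one replica")
    first = replicas[0]
    blocks, rep_ids, origins = [], [], []
    for cs, cut in zip(replicas, cuts):
        if not first.same_atom_table(cs):
            raise ValueError(
                f"replica {cs.replica_id}: atom table differs from replica {first.replica_id}"
            )
        if not (0 <= cut <= cs.n_frames):
            raise ValueError(f"cut {cut} out of range for {cs.n_frames} frames")
        if cut == cs.n_frames:
            warnings.warn(
                f"replica {cs.replica_id} fully discarded by its equilibration cut",
                stacklevel=2,
            )
            continue
        blocks.append(cs.frames[cut:])
        rep_ids.append(np.full(cs.n_frames - cut, cs.replica_id))
        origins.append(np.arange(cut, cs.n_frames))
    if not blocks:
        raise ValueError("all replicas were fully discarded")
    spacings = {cs.frame_spacing for cs in replicas}
    return ConformerSet(
        atoms=first.atoms.copy(),
        frames=np.concatenate(blocks, axis=0),
        frame_spacing=first.frame_spacing if len(spacings) == 1 else 0.0,
        system_name=first.system_name,
        replica_id=-1,
        meta={
            "frame_replica": np.concatenate(rep_ids),
            "frame_origin": np.concatenate(origins),
            "kind": "macrotrajectory",
        },
    )


def two_pass_align(cs: ConformerSet, fit_indices=None) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass superposition onto the iteratively computed average.

    Fit every frame to the plain coordinate mean (an order-invariant
    starting reference, so macro-trajectory results do not depend on how
    replicas were concatenated), average the aligned frames, refit the
    original frames to that average and re-average.  Returns
    (aligned frames, final average).
    """
    if fit_indices is None:
        fit_indices = np.arange(cs.n_atoms)
    superpose(cs.frames[0], cs.frames[0], fit_indices)  # contract checks
    target = cs.frames.mean(axis=0)
    aligned = cs.frames
    for _ in range(2):
        aligned = align_frames(cs.frames, target, fit_indices)
        target = aligned.mean(axis=0)
    return aligned, target


def rmsf_profile(cs: ConformerSet, fit_indices=None) -> FlexibilityProfile:
    """Per-residue Cα RMSF about the average structure.

    Frames are superposed on ``fit_indices`` onto their two-pass average
    (fit to frame 0 → average → refit → re-average); the profile is
    rmsf_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) evaluated on the Cα atoms.
    """
    if cs.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    aligned, mean = two_pass_align(cs, fit_indices)
    dev = aligned - aligned.mean(axis=0)
    rmsf_all = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    ca = select_atoms(cs, atom_names={"CA"})
    return FlexibilityProfile(
        residue_numbers=cs.atoms["residue_number"].to_numpy()[ca],
        rmsf=rmsf_all[ca],
    )


def rmsf_consistency(
    profiles: list[FlexibilityProfile], threshold: float = 0.6
) -> ConsistencyResult:
    """Pairwise Pearson matrix across replica RMSF profiles.

    Passes when every off-diagonal coefficient exceeds ``threshold``
    (default 0.6, the conventional replica-consistency criterion).  A
    zero-variance profile makes its pairs undefined and is reported as a
    failure with a reason.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    lengths = {len(p.rmsf) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have unequal lengths")
    n = len(profiles)
    matrix = np.eye(n)
    reasons: list[str] = []
    ok = True
    for i in range(n):
        for j in range(i + 1, n):
            a, b = profiles[i].rmsf, profiles[j].rmsf
            if np.std(a) == 0 or np.std(b) == 0:
                matrix[i, j] = matrix[j, i] = np.nan
                reasons.append(f"pair ({i},{j}): zero-variance profile, r undefined")
                ok = False
                continue
            r = float(stats.pearsonr(a, b).statistic)
            matrix[i, j] = matrix[j, i] = r
            if r <= threshold:
                ok = False
                reasons.append(f"pair ({i},{j}): r = {r:.3f} <= {threshold}")
    return ConsistencyResult(matrix=matrix, passed=ok, threshold=threshold, reasons=reasons)
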