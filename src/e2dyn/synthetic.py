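"""Synthetic conformational-ensemble generator.

Generates :class:`~e2dyn.structio.ConformerSet` objects with the statistical
structure the downstream analyses assume, so the whole pipeline is testable
without externally supplied trajectories:

* a smooth helix-like Cα scaffold with 3.8 Å spacing (geometry only; no
  force field),
* per-residue heterogeneous baseline flexibility,
* a small number of metastable conformations of the acidic β4α2 loop
  ("basins"), sampled by a slow first-order Markov process, positioned as
  rigid loop displacements either occluding ("closed") or exposing ("open")
  a pseudo side-chain atom (SG) on the catalytic cysteine,
* Gaussian collective modes (rigid-body-free displacement fields),
* an initial non-equilibrated transient relaxing linearly from a displaced
  start.

Variant presets mirror the simulated-system roster of a Cdc34-like study:
the wild-type-like system interconverts between closed and open loop
states, phospho-mimicking variants are open-shifted with reduced loop
flexibility, and the Δ-loop variant lacks residues 103–114 entirely.

Everything is deterministic given the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structio import ConformerSet, RegionSpec

__all__ = [
    "CollectiveMode",
    "Basin",
    "SyntheticSpec",
    "PRESET_NAMES",
    "preset_spec",
    "preset_region",
    "generate_ensemble",
    "generate_replicas",
    "build_scaffold",
    "rigid_free_mode",
]

PRESET_NAMES = ("cdc34_like", "phospho_like", "s130e_like", "delta12_like", "ubc1_like")

# helix geometry: radius/rise/turn chosen to give ~3.8 Å Cα-Cα spacing
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0
_SG_BOND_LENGTH = 2.0


@dataclass(frozen=True)
class CollectiveMode:
    """A collective displacement field: frames receive ``t * shape`` with
    t ~ N(0, stdev²).  ``shape`` is an (A, 3) field of unit Frobenius norm."""

    shape: np.ndarray
    stdev: float


@dataclass(frozen=True)
class Basin:
    """A metastable loop conformation: a rigid centroid offset of the loop
    atoms, its occupancy, and the within-basin isotropic jitter (Å)."""

    loop_offset: np.ndarray
    occupancy: float
    within_sigma: float = 0.0


@dataclass
class SyntheticSpec:
    """Full description of one synthetic system (one replica's recipe)."""

    residue_numbers: tuple[int, ...]
    catalytic_residue: int
    loop: tuple[int, int] | None
    baseline_sigma: np.ndarray  # per-residue, Å
    modes: list[CollectiveMode] = field(default_factory=list)
    basins: list[Basin] = field(default_factory=list)
    equil_frames: int = 200
    n_frames: int = 2000
    frame_spacing: float = 10.0  # ps
    seed: int = 0
    switching_prob: float = 0.02  # per-frame probability of a state redraw
    state_process: str = "markov"  # or "iid"
    equil_displacement: float = 3.0  # RMS Å of the displaced start
    name: str = "custom"

    def __post_init__(self) -> None:
        self.baseline_sigma = np.broadcast_to(
            np.asarray(self.baseline_sigma, dtype=float), (len(self.residue_numbers),)
        ).copy()
        if np.any(self.baseline_sigma < 0):
            raise ValueError("baseline_sigma must be >= 0")
        if self.basins:
            total = sum(b.occupancy for b in self.basins)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"basin occupancies sum to {total}, expected 1")
            if any(b.within_sigma < 0 for b in self.basins):
                raise ValueError("within-basin sigma must be >= 0")
        if any(m.stdev < 0 for m in self.modes):
            raise ValueError("mode stdev must be >= 0")
        if not (self.n_frames > self.equil_frames >= 0):
            raise ValueError("need n_frames > equil_frames >= 0")
        if self.state_process not in ("markov", "iid"):
            raise ValueError("state_process must be 'markov' or 'iid'")
        n_atoms = len(self.residue_numbers) + 1  # + pseudo-SG
        for m in self.modes:
            if m.shape.shape != (n_atoms, 3):
                raise ValueError(
                    f"mode shape {m.shape.shape} does not match atom count {n_atoms}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.residue_numbers) + 1


# ---------------------------------------------------------------------------
# Scaffold geometry
# ---------------------------------------------------------------------------

def _helix_curve(n: int) -> np.ndarray:
    theta = np.deg2rad(_HELIX_TURN_DEG) * np.arange(n)
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * np.arange(n)]
    )


def build_scaffold(spec: SyntheticSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Atom table and reference coordinates for a spec.

    One CA per residue along an ideal helix-like curve, plus a single
    pseudo side-chain atom SG on the catalytic residue, placed radially
    outward so the loop can occlude it when displaced into the cleft.
    """
    res = list(spec.residue_numbers)
    n = len(res)
    ca = _helix_curve(n)
    cat_pos = res.index(spec.catalytic_residue)
    radial = ca[cat_pos] * np.array([1.0, 1.0, 0.0])
    radial /= np.linalg.norm(radial)
    sg = ca[cat_pos] + _SG_BOND_LENGTH * radial

    records = []
    coords = []
    serial = 1
    for i, r in enumerate(res):
        records.append((serial, "CA", "ALA" if r != spec.catalytic_residue else "CYS", r, "A", "C"))
        coords.append(ca[i])
        serial += 1
        if r == spec.catalytic_residue:
            records.append((serial, "SG", "CYS", r, "A", "S"))
            coords.append(sg)
            serial += 1
    atoms = pd.DataFrame(
        records,
        columns=["serial", "atom_name", "residue_name", "residue_number", "chain_id", "element"],
    )
    return atoms, np.asarray(coords)


def _atom_indices(atoms: pd.DataFrame, spec: SyntheticSpec):
    resnum = atoms["residue_number"].to_numpy()
    names = atoms["atom_name"].to_numpy()
    if spec.loop is not None:
        loop_idx = np.flatnonzero((resnum >= spec.loop[0]) & (resnum <= spec.loop[1]))
    else:
        loop_idx = np.array([], dtype=int)
    cat_idx = np.flatnonzero(resnum == spec.catalytic_residue)
    sg_idx = np.flatnonzero((resnum == spec.catalytic_residue) & (names == "SG"))
    return loop_idx, cat_idx, int(sg_idx[0])


def rigid_free_mode(shape: np.ndarray, scaffold: np.ndarray) -> np.ndarray:
    """Project the 6 rigid-body degrees of freedom out of a displacement
    field and renormalise to unit Frobenius norm.

    Designed mode variances are only recoverable after superposition if the
    mode carries no net translation or torque; presets route every mode
    through this helper.
    """
    A = shape.shape[0]
    centered = scaffold - scaffold.mean(axis=0)
    basis = []
    for k in range(3):  # translations
        b = np.zeros((A, 3))
        b[:, k] = 1.0
        basis.append(b)
    for k in range(3):  # infinitesimal rotations about the centroid
        e = np.zeros(3)
        e[k] = 1.0
        basis.append(np.cross(np.broadcast_to(e, (A, 3)), centered))
    # rotation fields are not mutually orthogonal in general: orthonormalise
    # the 6-dimensional rigid subspace first (QR), then project it out
    B = np.stack([b.ravel() for b in basis], axis=1)
    Q, _ = np.linalg.qr(B)
    flat = shape.astype(float).ravel()
    flat = flat - Q @ (Q.T @ flat)
    out = flat.reshape(A, 3)
    norm = np.linalg.norm(out)
    if norm < 1e-12:
        raise ValueError("mode shape is purely rigid-body")
    return out / norm


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sample_states(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    occ = np.array([b.occupancy for b in spec.basins])
    F = spec.n_frames
    if spec.state_process == "iid":
        return rng.choice(len(occ), size=F, p=occ)
    # slow Markov chain: with probability p, redraw the state from the
    # occupancy distribution (stationary distribution = occupancies exactly)
    states = np.empty(F, dtype=int)
    states[0] = rng.choice(len(occ), p=occ)
    redraw = rng.random(F) < spec.switching_prob
    draws = rng.choice(len(occ), size=F, p=occ)
    for f in range(1, F):
        states[f] = draws[f] if redraw[f] else states[f - 1]
    return states


def _equil_field(spec: SyntheticSpec, scaffold: np.ndarray) -> np.ndarray:
    """Smooth internal deformation with RMS amplitude equil_displacement.

    A sinusoidally modulated field (not a rigid transform), so the
    transient survives least-squares superposition and is visible in RMSD
    series.
    """
    A = scaffold.shape[0]
    w = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
    profile = np.sin(2.0 * np.pi * 2.0 * np.arange(A) / A)
    field_ = profile[:, None] * w[None, :]
    field_ = rigid_free_mode(field_, scaffold)  # unit Frobenius norm
    return field_ * spec.equil_displacement * np.sqrt(A)


def generate_ensemble(spec: SyntheticSpec) -> ConformerSet:
    """Generate one replica: scaffold + basin offsets + collective modes +
    baseline jitter, preceded by a linearly relaxing displaced transient.

    Bit-identical output for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    atoms, scaffold = build_scaffold(spec)
    loop_idx, _, _ = _atom_indices(atoms, spec)
    A, F = spec.n_atoms, spec.n_frames

    if spec.basins and loop_idx.size == 0:
        raise ValueError("basins specified but the spec has no loop region")

    # fixed draw order => determinism
    if spec.basins:
        states = _sample_states(rng, spec)
        within = rng.standard_normal((F, loop_idx.size, 3))
    else:
        states = np.zeros(F, dtype=int)
        within = None
    mode_ts = rng.standard_normal((F, len(spec.modes)))
    per_atom_sigma = np.empty(A)
    res_sigma = dict(zip(spec.residue_numbers, spec.baseline_sigma))
    per_atom_sigma[:] = [res_sigma[r] for r in atoms["residue_number"]]
    jitter = rng.standard_normal((F, A, 3)) * per_atom_sigma[None, :, None]

    frames = np.broadcast_to(scaffold, (F, A, 3)).copy()
    if spec.basins:
        offsets = np.array([b.loop_offset for b in spec.basins])
        sigmas = np.array([b.within_sigma for b in spec.basins])
        frames[:, loop_idx, :] += offsets[states][:, None, :]
        frames[:, loop_idx, :] += within * sigmas[states][:, None, None]
    for m, mode in enumerate(spec.modes):
        frames += mode_ts[:, m, None, None] * (mode.stdev * mode.shape)[None, :, :]
    frames += jitter

    if spec.equil_frames > 0:
        D = _equil_field(spec, scaffold)
        ramp = 1.0 - np.arange(spec.equil_frames) / spec.equil_frames
        frames[: spec.equil_frames] += ramp[:, None, None] * D[None, :, :]

    return ConformerSet(
        atoms=atoms,
        frames=frames,
        frame_spacing=spec.frame_spacing,
        system_name=spec.name,
        replica_id=0,
        meta={"states": states, "seed": spec.seed},
    )


def generate_replicas(spec: SyntheticSpec, n_replicas: int, base_seed: int) -> list[ConformerSet]:
    """Independent replicas r = 1..n of the same system; replica r uses
    seed ``base_seed + r``."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    out = []
    for r in range(1, n_replicas + 1):
        cs = generate_ensemble(replace(spec, seed=base_seed + r))
        cs.replica_id = r
        out.append(cs)
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _baseline_profile(n: int) -> np.ndarray:
    """Smoothly varying per-residue flexibility, mobile termini: 0.25-0.45 Å."""
    i = np.arange(n)
    return (
        0.25
        + 0.10 * np.sin(2.0 * np.pi * i / n) ** 2
        + 0.20 * (np.exp(-i / 4.0) + np.exp(-(n - 1 - i) / 4.0))
    )


# loop-COM-to-C95-COM targets (axial, lateral) in Å for the five metastable
# loop conformations; net distances [5.0, 9.01, 11.88, 15.30, 17.76]:
# one closed, two intermediate, two open states
_BASIN_GEOMETRY = [(5.0, 0.0), (8.5, 3.0), (11.5, -3.0), (15.0, 3.0), (17.5, -3.0)]
_OCCUPANCIES = {
    "cdc34_like": [0.28, 0.22, 0.19, 0.16, 0.15],
    "phospho_like": [0.04, 0.06, 0.10, 0.30, 0.50],
    "s130e_like": [0.10, 0.12, 0.18, 0.28, 0.32],
}
_LOOP_MODE_STDEV = {"cdc34_like": 1.0, "phospho_like": 0.4, "s130e_like": 0.6}
_WITHIN_SIGMA = {"cdc34_like": 0.25, "phospho_like": 0.20, "s130e_like": 0.22}


def _loop_basins(spec: SyntheticSpec, occupancies, within_sigma) -> list[Basin]:
    atoms, scaffold = build_scaffold(spec)
    loop_idx, cat_idx, _ = _atom_indices(atoms, spec)
    L0 = scaffold[loop_idx].mean(axis=0)
    C = scaffold[cat_idx].mean(axis=0)
    u = L0 - C
    u /= np.linalg.norm(u)
    v = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, np.array([1.0, 0.0, 0.0]))
    v /= np.linalg.norm(v)
    basins = []
    for (d, lat), occ in zip(_BASIN_GEOMETRY, occupancies):
        target = C + d * u + lat * v
        basins.append(Basin(loop_offset=target - L0, occupancy=occ, within_sigma=within_sigma))
    return basins


def _loop_mode(spec: SyntheticSpec, stdev: float) -> CollectiveMode:
    atoms, scaffold = build_scaffold(spec)
    loop_idx, cat_idx, _ = _atom_indices(atoms, spec)
    L0 = scaffold[loop_idx].mean(axis=0)
    C = scaffold[cat_idx].mean(axis=0)
    u = (L0 - C) / np.linalg.norm(L0 - C)
    shape = np.zeros((spec.n_atoms, 3))
    envelope = np.sin(np.pi * (np.arange(loop_idx.size) + 0.5) / loop_idx.size)
    shape[loop_idx] = envelope[:, None] * u[None, :]
    return CollectiveMode(shape=rigid_free_mode(shape, scaffold), stdev=stdev)


def _breathing_mode(spec: SyntheticSpec, stdev: float = 0.5) -> CollectiveMode:
    atoms, scaffold = build_scaffold(spec)
    radial = scaffold * np.array([1.0, 1.0, 0.0])
    norms = np.linalg.norm(radial, axis=1)
    radial[norms > 0] /= norms[norms > 0, None]
    envelope = np.sin(np.pi * np.arange(spec.n_atoms) / spec.n_atoms)
    shape = envelope[:, None] * radial
    return CollectiveMode(shape=rigid_free_mode(shape, scaffold), stdev=stdev)


def preset_spec(name: str, seed: int = 0) -> SyntheticSpec:
    """Fully populated spec for a named variant preset.

    ``cdc34_like``   five loop basins (closed ... open), slow interconversion
    ``phospho_like`` same basins, open-shifted occupancies, stiffer loop
    ``s130e_like``   milder open shift (mono-anionic mimic)
    ``delta12_like`` residues 103-114 deleted, no loop basins
    ``ubc1_like``    insertion-free homolog, no loop basins
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    if name in ("delta12_like", "ubc1_like"):
        residues = tuple(r for r in range(7, 171) if not (103 <= r <= 114))
        sigma = _baseline_profile(len(residues))
        if name == "ubc1_like":
            sigma = sigma * 1.2
        spec = SyntheticSpec(
            residue_numbers=residues,
            catalytic_residue=95,
            loop=None,
            baseline_sigma=sigma,
            equil_frames=200,
            n_frames=2000,
            seed=seed,
            name=name,
        )
        spec.modes = [_breathing_mode(spec)]
        return spec

    residues = tuple(range(7, 171))
    spec = SyntheticSpec(
        residue_numbers=residues,
        catalytic_residue=95,
        loop=(103, 114),
        baseline_sigma=_baseline_profile(len(residues)),
        equil_frames=200,
        n_frames=2000,
        seed=seed,
        name=name,
    )
    spec.basins = _loop_basins(spec, _OCCUPANCIES[name], _WITHIN_SIGMA[name])
    spec.modes = [_loop_mode(spec, _LOOP_MODE_STDEV[name]), _breathing_mode(spec)]
    return spec


def preset_region(name: str) -> RegionSpec:
    """Region annotations matching a preset (loop absent for Δ-loop/Ubc1)."""
    if name in ("delta12_like", "ubc1_like"):
        return RegionSpec(acidic_loop=None, catalytic_residue=95, first_residue=7, last_residue=170)
    return RegionSpec()
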