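"""Structure I/O, atom selection and rigid-body superposition.

The universal in-memory container is :class:`ConformerSet`: an ordered set of
frames (an MD trajectory slice, an NMR model set, or a synthetic ensemble)
over a fixed atom table.  All distances are in Å (the PDB native unit);
summary layers additionally report nm where conventional.

Multi-model PDB reading/writing is delegated to biotite; this module only
adds the contract checks (per-model atom-count consistency, fixed-column
coordinate limits) and the conversion to/from the ConformerSet container.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "ConformerSet",
    "RegionSpec",
    "Superposition",
    "read_conformers",
    "write_conformers",
    "select_atoms",
    "superpose",
    "apply_superposition",
    "kabsch",
]

ATOM_COLUMNS = ["serial", "atom_name", "residue_name", "residue_number", "chain_id", "element"]

#: PDB fixed columns hold coordinates as %8.3f -> |x| < 10000 Å.
_PDB_COORD_LIMIT = 9999.999


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus (optionally) a coordinate.

    ``residue_number`` uses author numbering from the input file throughout.
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    element: str = "C"
    coords: np.ndarray | None = None


@dataclass
class ConformerSet:
    """An ordered set of conformers over a fixed atom table.

    Parameters
    ----------
    atoms
        DataFrame with columns ``serial, atom_name, residue_name,
        residue_number, chain_id, element`` (coordinates excluded).
    frames
        ``(F, A, 3)`` float array of coordinates in Å.
    frame_spacing
        ps per frame; 0 for unordered sets (e.g. NMR models).
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    frame_spacing: float = 0.0
    system_name: str = ""
    replica_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("a ConformerSet needs at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"atom table length {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")
        if self.frame_spacing < 0:
            raise ValueError("frame_spacing must be >= 0")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table lacks columns {missing}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (all-zero for unordered sets)."""
        return np.arange(self.n_frames) * self.frame_spacing

    def subset_frames(self, index) -> "ConformerSet":
        """A new ConformerSet restricted to the given frame index/slice."""
        idx = np.arange(self.n_frames)[index]
        meta = dict(self.meta)
        for key in ("frame_replica", "frame_origin"):
            if key in meta:
                meta[key] = np.asarray(meta[key])[idx]
        return replace(self, frames=self.frames[idx], meta=meta)

    def same_atom_table(self, other: "ConformerSet") -> bool:
        a, b = self.atoms[ATOM_COLUMNS], other.atoms[ATOM_COLUMNS]
        return len(a) == len(b) and bool((a.reset_index(drop=True) == b.reset_index(drop=True)).all().all())


def _as_ranges(value) -> list[tuple[int, int]]:
    if value is None:
        return []
    if isinstance(value, (int, np.integer)):
        return [(int(value), int(value))]
    if isinstance(value, tuple) and len(value) == 2 and all(isinstance(v, (int, np.integer)) for v in value):
        return [value]
    out = []
    for item in value:
        if isinstance(item, int):
            out.append((item, item))
        else:
            lo, hi = item
            out.append((int(lo), int(hi)))
    return out


@dataclass(frozen=True)
class RegionSpec:
    """Named residue annotations of the reference Cdc34-like system.

    Defaults describe the yeast Cdc34 UBC domain (author numbering 7–170):
    the 12-residue acidic β4α2 insertion 103–114, the catalytic cysteine
    C95 and the CK2 phospho-serines S130 (Psite-1) and S167 (Psite-2).
    ``fit_region`` is the common E2 fold used for least-squares fitting:
    everything except the acidic loop.
    """

    acidic_loop: tuple[int, int] | None = (103, 114)
    catalytic_residue: int = 95
    psite1: int = 130
    psite2: int = 167
    first_residue: int = 7
    last_residue: int = 170
    fit_region: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.acidic_loop is not None:
            lo, hi = self.acidic_loop
            if hi < lo:
                raise ValueError("acidic_loop range is empty")
            if lo <= self.catalytic_residue <= hi:
                raise ValueError("catalytic residue cannot lie inside the acidic loop")

    def loop_residues(self) -> list[int]:
        if self.acidic_loop is None:
            return []
        return list(range(self.acidic_loop[0], self.acidic_loop[1] + 1))

    def loop_length(self) -> int:
        return len(self.loop_residues())

    def fit_ranges(self) -> list[tuple[int, int]]:
        """Fit region as residue ranges; default = all minus acidic loop."""
        if self.fit_region is not None:
            return _as_ranges(self.fit_region)
        if self.acidic_loop is None:
            return [(self.first_residue, self.last_residue)]
        lo, hi = self.acidic_loop
        ranges = []
        if lo > self.first_residue:
            ranges.append((self.first_residue, lo - 1))
        if hi < self.last_residue:
            ranges.append((hi + 1, self.last_residue))
        return ranges


@dataclass(frozen=True)
class Superposition:
    """Proper rigid-body transform x -> R x + t with its fit RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")
        if self.fit_rmsd < 0:
            raise ValueError("fit_rmsd must be >= 0")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _model_atom_counts(path) -> list[int]:
    """ATOM/HETATM line counts per MODEL block (one block if no MODEL)."""
    counts, current, in_model, seen_model = [], 0, False, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model, in_model, current = True, True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not seen_model:
        counts = [current]
    elif in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_conformers(path, format: str = "pdb_multimodel") -> ConformerSet:
    """Read a multi-model PDB file into a ConformerSet.

    Each MODEL becomes one frame (a file without MODEL records is a single
    frame).  All models must contain the same atoms in the same order; the
    first offending model is named in the error.  Multi-chain files are
    reduced to their first chain with a warning.
    """
    if format != "pdb_multimodel":
        raise ValueError(f"unsupported format {format!r}")
    counts = _model_atom_counts(path)
    if not counts or counts[0] == 0:
        raise ValueError(f"{path}: no atoms found")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise ValueError(
                f"{path}: model {i} has {c} atoms, expected {counts[0]} "
                f"(atom-count mismatch between models)"
            )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    chains = np.unique(stack.chain_id)
    if len(chains) > 1:
        warnings.warn(
            f"{path}: {len(chains)} chains found; keeping first chain {chains[0]!r}",
            stacklevel=2,
        )
        stack = stack[..., stack.chain_id == chains[0]]
    atoms = pd.DataFrame(
        {
            "serial": np.arange(1, stack.array_length() + 1),
            "atom_name": stack.atom_name,
            "residue_name": stack.res_name,
            "residue_number": stack.res_id,
            "chain_id": stack.chain_id,
            "element": stack.element,
        }
    )
    return ConformerSet(atoms=atoms, frames=np.asarray(stack.coord, dtype=float))


def write_conformers(cs: ConformerSet, path) -> None:
    """Write a ConformerSet as a standard multi-model PDB (MODEL/ENDMDL)."""
    if np.any(np.abs(cs.frames) > _PDB_COORD_LIMIT):
        raise ValueError("coordinates exceed the PDB fixed-column limit (|x| >= 10000 Å)")
    arr = struc.AtomArray(cs.n_atoms)
    arr.chain_id = cs.atoms["chain_id"].to_numpy(dtype="U4")
    arr.res_id = cs.atoms["residue_number"].to_numpy(dtype=int)
    arr.res_name = cs.atoms["residue_name"].to_numpy(dtype="U5")
    arr.atom_name = cs.atoms["atom_name"].to_numpy(dtype="U6")
    arr.element = cs.atoms["element"].to_numpy(dtype="U2")
    arr.hetero = np.zeros(cs.n_atoms, dtype=bool)
    stack = struc.from_template(arr, cs.frames.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(cs: ConformerSet, residues=None, atom_names=None) -> np.ndarray:
    """Indices (atom-table order) of atoms matching residue ranges and names.

    ``residues`` may be None (all), a single (lo, hi) tuple, or an iterable
    of ints / (lo, hi) tuples.  ``atom_names`` may be None (all) or a set of
    names such as ``{"CA"}``.  An empty selection is allowed but flagged
    with a warning.
    """
    mask = np.ones(cs.n_atoms, dtype=bool)
    if residues is not None:
        resnum = cs.atoms["residue_number"].to_numpy()
        rmask = np.zeros(cs.n_atoms, dtype=bool)
        for lo, hi in _as_ranges(residues):
            rmask |= (resnum >= lo) & (resnum <= hi)
        mask &= rmask
    if atom_names is not None:
        names = set(atom_names)
        mask &= cs.atoms["atom_name"].isin(names).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn("atom selection is empty", stacklevel=2)
    return idx


def sidechain_indices(cs: ConformerSet, residue: int) -> np.ndarray:
    """Side-chain atoms of a residue: everything but the N/CA/C/O backbone
    (hydrogens ignored)."""
    atoms = cs.atoms
    mask = (
        (atoms["residue_number"] == residue)
        & ~atoms["atom_name"].isin(["N", "CA", "C", "O"])
        & ~atoms["atom_name"].str.startswith("H")
        & ~(atoms["element"] == "H")
    )
    return np.flatnonzero(mask.to_numpy())


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising |R P + t − Q|.

    Reflections are corrected by flipping the sign of the smallest singular
    vector, so det(R) = +1 always.
    """
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def superpose(mobile: np.ndarray, reference: np.ndarray, fit_indices=None) -> Superposition:
    """Least-squares fit of ``mobile`` onto ``reference`` over ``fit_indices``.

    Requires at least 3 non-collinear fit atoms; the returned rotation is
    always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    fit_indices = np.asarray(fit_indices)
    P = mobile[fit_indices]
    Q = reference[fit_indices]
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    s = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("fit atoms are collinear; rotation is underdetermined")
    R, t = kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, fit_rmsd=rmsd)


def apply_superposition(sup: Superposition, coords: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t to an (A, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ sup.rotation.T + sup.translation


def align_frames(frames: np.ndarray, reference: np.ndarray, fit_indices=None) -> np.ndarray:
    """Superpose every frame of an (F, A, 3) block onto a reference frame.

    Batched Kabsch (one SVD of a 3×3 cross-covariance per frame, computed
    in a single vectorised call) — equivalent to calling
    :func:`superpose` + :func:`apply_superposition` per frame, which the
    tests assert.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(frames.shape[1])
    fit_indices = np.asarray(fit_indices)
    P = frames[:, fit_indices, :]
    Q = reference[fit_indices]
    cp = P.mean(axis=1, keepdims=True)
    cq = Q.mean(axis=0)
    H = np.einsum("fai,aj->fij", P - cp, Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    Vt[:, 2, :] *= d[:, None]
    R = np.transpose(np.einsum("fij,fjk->fik", U, Vt), (0, 2, 1))  # R = Vtᵀ D Uᵀ
    out = np.einsum("fai,fji->faj", frames - cp, R) + cq
    return out
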