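"""Structural observables from coordinates and MD trajectories.

Implements the feature extraction used by the distance-based models:
minimum inter-residue distances (heavy atoms by default), replicate-pooled
averages over the retained trajectory window, hydrophobic-pocket contact
counts and solvent-accessible surface area (Shrake-Rupley sphere
sampling), backbone dihedrals, and least-squares superposition RMSD.

Structures are held in a light :class:`StructureFrame` (names, elements,
residue ids in author numbering, Cartesian Å coordinates); helpers
convert from ``mdtraj`` trajectories (PDB topology with DCD/XTC frames),
which remains the I/O layer for real structure files.  Coordinates are
assumed re-imaged; no periodic minimum-image handling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: van der Waals radii (Å) by element for surface-area calculations.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "MG": 1.73, "NA": 2.27, "K": 2.75, "ZN": 1.39,
}


@dataclass
class StructureFrame:
    """Atoms of one structure snapshot.

    ``residue_ids`` use author numbering (Rpb1 1076-1106 for the trigger
    loop, ~810-845 for the bridge helix); mapping from file numbering is
    applied at load time via an offset.
    """

    names: np.ndarray          # atom names, e.g. "CA"
    elements: np.ndarray       # element symbols, e.g. "C"
    residue_ids: np.ndarray    # author residue numbering
    coords: np.ndarray         # (n_atoms, 3) in Å

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray([str(e).upper() for e in self.elements], dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.coords.shape != (len(self.names), 3):
            raise ValueError("coords must be (n_atoms, 3)")

    def atom_mask(self, residue_id: int, heavy_only: bool = True) -> np.ndarray:
        mask = self.residue_ids == residue_id
        if heavy_only:
            mask &= self.elements != "H"
        return mask

    def residue_coords(self, residue_id: int, heavy_only: bool = True) -> np.ndarray:
        sel = self.coords[self.atom_mask(residue_id, heavy_only)]
        if sel.shape[0] == 0:
            raise KeyError(f"residue {residue_id} has no selected atoms")
        return sel


def frames_from_mdtraj(traj, resid_offset: int = 0) -> list[StructureFrame]:
    """Convert an ``mdtraj.Trajectory`` to StructureFrames (nm -> Å).

    ``resid_offset`` is added to the file's residue sequence numbers to
    recover author numbering.
    """
    names = np.array([a.name for a in traj.topology.atoms], dtype=object)
    elements = np.array(
        [a.element.symbol if a.element is not None else "C" for a in traj.topology.atoms],
        dtype=object,
    )
    resids = np.array([a.residue.resSeq + resid_offset for a in traj.topology.atoms])
    return [StructureFrame(names, elements, resids, traj.xyz[i] * 10.0)
            for i in range(traj.n_frames)]


def load_replicates(topology_path, traj_paths: Sequence, resid_offset: int = 0
                    ) -> list[list[StructureFrame]]:
    """Load one frame list per replicate trajectory file via mdtraj."""
    import mdtraj as md

    replicates = []
    for path in traj_paths:
        traj = md.load(str(path), top=str(topology_path))
        replicates.append(frames_from_mdtraj(traj, resid_offset))
    return replicates


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def min_pair_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum Euclidean distance between two atom coordinate sets."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def min_residue_distance(frame: StructureFrame, res_a: int, res_b: int,
                         heavy_only: bool = True) -> float:
    """Minimum atom-atom distance between two residues (heavy atoms by
    default); symmetric in its arguments, zero for a residue against
    itself."""
    return min_pair_distance(frame.residue_coords(res_a, heavy_only),
                             frame.residue_coords(res_b, heavy_only))


def resolve_frame_range(n_frames: int, frame_range) -> slice:
    """Normalise a frame-range spec: a slice, ``"last-half"``, or None."""
    if frame_range is None:
        return slice(0, n_frames)
    if frame_range == "last-half":
        return slice(n_frames // 2, n_frames)
    if isinstance(frame_range, slice):
        return frame_range
    raise ValueError(f"unsupported frame range {frame_range!r}")


def extract_pair_distances(replicates: Sequence[Sequence[StructureFrame]],
                           pairs: Sequence[tuple[str, int, int]],
                           frame_range="last-half", heavy_only: bool = True
                           ) -> tuple[dict[str, list[np.ndarray]], dict[str, float]]:
    """Per-frame distance series and replicate-pooled averages.

    ``pairs`` holds (name, residue_a, residue_b) entries.  Each replicate
    contributes the frames selected by ``frame_range``; the pooled average
    of a pair is the mean over the concatenation of all replicates'
    retained frames (the combined distribution, not a mean of means).
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    series: dict[str, list[np.ndarray]] = {name: [] for name, _, _ in pairs}
    for frames in replicates:
        window = list(frames)[resolve_frame_range(len(frames), frame_range)]
        for name, res_a, res_b in pairs:
            vals = np.array([min_residue_distance(f, res_a, res_b, heavy_only)
                             for f in window])
            series[name].append(vals)
    pooled = {name: float(np.concatenate(chunks).mean())
              for name, chunks in series.items()}
    return series, pooled


def load_pair_list(path) -> list[tuple[str, int, int, str]]:
    """Read a residue-pair catalog from YAML.

    Layout: a top-level ``pairs`` list of entries with ``name``,
    ``residues`` (two author-numbered residue ids) and ``category``
    (one of the five structural categories).  Returns
    ``(name, res_a, res_b, category)`` tuples.
    """
    import yaml

    from .io import DISTANCE_CATEGORIES

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pairs" not in doc:
        raise ValueError("pair catalog must have a top-level 'pairs' list")
    out = []
    seen: set[str] = set()
    for entry in doc["pairs"]:
        name = str(entry["name"])
        res_a, res_b = (int(r) for r in entry["residues"])
        category = str(entry["category"])
        if category not in DISTANCE_CATEGORIES:
            raise ValueError(f"{name}: unknown category {category!r}")
        if name in seen:
            raise ValueError(f"duplicate pair name {name!r}")
        seen.add(name)
        out.append((name, res_a, res_b, category))
    return out


# ---------------------------------------------------------------------------
# Hydrophobic pocket
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketSpec:
    """The nine-residue hydrophobic pocket near the trigger loop."""

    residues: tuple[int, ...] = (837, 841, 1076, 1079, 1097, 1101, 1352, 1355, 1356)
    contact_cutoff: float = 6.0     # Å, boundary inclusive
    probe_radius: float = 1.4       # Å
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


def pocket_contacts(frame: StructureFrame, spec: PocketSpec = PocketSpec(),
                    heavy_only: bool = True) -> int:
    """Number of residue pairs within the pocket at contact distance.

    Two residues are in contact if their minimum distance is <= the
    cutoff (6 Å, inclusive); all unordered pairs among the pocket
    residues are considered.
    """
    res = spec.residues
    count = 0
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            if min_residue_distance(frame, res[i], res[j], heavy_only) <= spec.contact_cutoff:
                count += 1
    return count


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def atom_radius(element: str) -> float:
    try:
        return ELEMENT_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"no van der Waals radius for element {element!r}") from None


def pocket_surface_area(frame: StructureFrame, spec: PocketSpec = PocketSpec()) -> float:
    """Solvent-accessible surface area (Å²) of the pocket residues.

    Shrake-Rupley sphere sampling with >= 960 points per atom and a 1.4 Å
    probe; all atoms of the frame act as occluders, the area is summed
    over the pocket residues' atoms only.
    """
    points = _sphere_points(spec.n_sphere_points)
    radii = np.array([atom_radius(e) for e in frame.elements])
    extended = radii + spec.probe_radius
    pocket_mask = np.isin(frame.residue_ids, spec.residues)
    if not pocket_mask.any():
        raise KeyError("no pocket residues present in the frame")
    area = 0.0
    coords = frame.coords
    for i in np.flatnonzero(pocket_mask):
        r_i = extended[i]
        shell = coords[i] + r_i * points
        # Occlusion by any other atom's probe-extended sphere.
        accessible = np.ones(len(shell), dtype=bool)
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.flatnonzero((d_atoms < r_i + extended) & (np.arange(len(coords)) != i))
        for j in neighbors:
            accessible &= np.linalg.norm(shell - coords[j], axis=1) >= extended[j]
            if not accessible.any():
                break
        area += 4.0 * np.pi * r_i ** 2 * accessible.mean()
    return float(area)


# ---------------------------------------------------------------------------
# Dihedrals and RMSD
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) from four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(angle, -180.0) else float(angle)


def _backbone_atom(frame: StructureFrame, residue_id: int, name: str) -> np.ndarray:
    mask = (frame.residue_ids == residue_id) & (frame.names == name)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise KeyError(f"backbone atom {name} missing in residue {residue_id}")
    return frame.coords[idx[0]]


def backbone_dihedrals(frame: StructureFrame, residues: Iterable[int]) -> dict[int, dict[str, float]]:
    """phi/psi backbone dihedrals (degrees) for the requested residues.

    phi(i) uses C(i-1)-N(i)-CA(i)-C(i); psi(i) uses N(i)-CA(i)-C(i)-N(i+1).
    Residues whose neighbours are absent get only the defined angle(s).
    """
    out: dict[int, dict[str, float]] = {}
    present = set(frame.residue_ids.tolist())
    for res in residues:
        if res not in present:
            raise KeyError(f"residue {res} not found")
        angles: dict[str, float] = {}
        n = _backbone_atom(frame, res, "N")
        ca = _backbone_atom(frame, res, "CA")
        c = _backbone_atom(frame, res, "C")
        if res - 1 in present:
            angles["phi"] = dihedral(_backbone_atom(frame, res - 1, "C"), n, ca, c)
        if res + 1 in present:
            angles["psi"] = dihedral(n, ca, c, _backbone_atom(frame, res + 1, "N"))
        out[res] = angles
    return out


def superpose_rmsd(reference: np.ndarray, mobile: np.ndarray) -> float:
    """RMSD after optimal least-squares rigid-body superposition (Kabsch).

    Both inputs are (n, 3) coordinate arrays with consistent atom
    ordering.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    if ref.shape != mob.shape:
        raise ValueError(f"selection size mismatch: {ref.shape} vs {mob.shape}")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    aligned = mob_c @ R
    return float(np.sqrt(np.mean(np.sum((aligned - ref_c) ** 2, axis=1))))
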