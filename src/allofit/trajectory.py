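"""Trajectory-frame statistics: polar contacts, helix displacement, occupancy.

Works on :class:`FrameSet` objects — an ordered stack of coordinate
snapshots sharing one atom table — ingested from multi-model PDB files
(MODEL/ENDMDL records) or plain per-frame XYZ tables. The statistics mirror
standard MD post-processing for class A GPCR activation:

* polar contacts: a residue pair is "in contact" in a frame when the
  minimum distance over its nitrogen/oxygen atom pairs is below a cutoff
  (default 4.0 A, strict "<"; an inclusive "<=" variant is a flag — at
  continuous coordinates the difference is measure-zero);
* contact occupancy: the fraction of frames in contact, reported per
  replicate with the across-replicate SD;
* per-frame polar-network size: the number of residue pairs from a chosen
  residue set in contact;
* cytoplasmic helix position: the distance between the Calpha centroid of a
  helix segment (e.g. the TM6 cytoplasmic window) and the Calpha centroid of
  the 7TM bundle;
* occupancy grids: per-voxel fraction of frames in which any selected atom
  (default main-chain N/CA/C) visits the voxel, exportable with an
  iso-threshold (default 0.5, i.e. a 50% iso-value map).

Replicate-level statistics use per-replicate means with n = number of
replicates, not per-frame n, to avoid pseudoreplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

__all__ = [
    "FrameSet",
    "ContactDefinition",
    "SegmentSpec",
    "OccupancyGrid",
    "DensityEstimate",
    "SelectionError",
    "read_frames_pdb",
    "write_frames_pdb",
    "read_frames_xyz_table",
    "write_frames_xyz_table",
    "pair_contact_present",
    "pair_contact_occupancy",
    "ContactOccupancy",
    "network_contact_count",
    "segment_com_distance",
    "displacement_density",
    "occupancy_grid",
    "kabsch_align",
    "write_grid_dx",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
MAINCHAIN_ATOMS = ("N", "CA", "C")


class SelectionError(ValueError):
    """A residue/segment selection resolved to no atoms."""


@dataclass
class FrameSet:
    """Ordered coordinate frames with a shared atom annotation table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``atoms`` is a
    DataFrame with columns name, element, resid (1-based, as in PDB),
    resname, chain.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    replicate_id: str = "rep1"
    frame_spacing: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        required = {"name", "element", "resid", "resname", "chain"}
        if not required <= set(self.atoms.columns):
            raise ValueError(f"atom table must carry columns {sorted(required)}")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, resid: int, chain: str | None = None) -> np.ndarray:
        m = self.atoms["resid"].to_numpy() == resid
        if chain is not None:
            m &= self.atoms["chain"].to_numpy() == chain
        return np.flatnonzero(m)


@dataclass(frozen=True)
class ContactDefinition:
    """Polar-contact rule: which atoms count and how close they must be."""

    cutoff: float = 4.0  # Angstrom
    elements: tuple[str, ...] = ("N", "O")
    scope: str = "sidechain"  # "sidechain" | "all"
    inclusive: bool = False  # "<=" instead of strict "<"

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.scope not in ("sidechain", "all"):
            raise ValueError("scope must be 'sidechain' or 'all'")


@dataclass(frozen=True)
class SegmentSpec:
    """An inclusive 1-based residue range reduced to Calpha atoms."""

    name: str
    start: int
    stop: int
    chain: str | None = None
    atom_rule: str = "CA"

    def __post_init__(self):
        if self.stop < self.start:
            raise ValueError("empty residue range")


@dataclass
class OccupancyGrid:
    """Per-voxel visitation fractions over a frame stack."""

    origin: np.ndarray  # Angstrom, lower corner
    voxel: float  # Angstrom
    values: np.ndarray  # (nx, ny, nz) fractions in [0, 1]
    iso_threshold: float = 0.5

    def iso_surface_mask(self) -> np.ndarray:
        """Boolean field values >= iso_threshold (the exported iso-map)."""
        return self.values >= self.iso_threshold


@dataclass
class DensityEstimate:
    """Gaussian-kernel probability density of a per-frame distance series."""

    support: np.ndarray  # Angstrom grid
    density: np.ndarray  # integrates to ~1
    bandwidth: float
    per_replicate_means: list[float]

    def at(self, x: float) -> float:
        return float(np.interp(x, self.support, self.density))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_frames_pdb(path, replicate_id: str = "rep1") -> FrameSet:
    """Read a multi-model PDB (MODEL/ENDMDL records) into a FrameSet.

    Residue numbering is taken as printed (1-based); chain IDs are honored.
    All models must share the same atom list.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("frames", str(path))
    frames, meta = [], None
    for model in structure:
        coords, rows = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append(atom.coord)
                    rows.append(
                        (
                            atom.get_name(),
                            (atom.element or atom.get_name()[0]).strip().upper(),
                            res.id[1],
                            res.get_resname(),
                            chain.id,
                        )
                    )
        frames.append(np.asarray(coords, dtype=float))
        if meta is None:
            meta = rows
        elif rows != meta:
            raise ValueError("atom table differs between models")
    if not frames:
        raise ValueError("no MODEL records found")
    atoms = pd.DataFrame(meta, columns=["name", "element", "resid", "resname", "chain"])
    return FrameSet(np.stack(frames), atoms, replicate_id=replicate_id)


def write_frames_pdb(fs: FrameSet, path) -> None:
    """Write a FrameSet as a multi-model PDB."""
    with open(path, "w") as fh:
        for f in range(fs.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, row in fs.atoms.iterrows():
                x, y, z = fs.coords[f, i]
                name = row["name"]
                # PDB v3 alignment: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i + 1:5d} {name_field}"
                    f" {row['resname']:<3s} {row['chain']}{row['resid']:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {row['element']:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_frames_xyz_table(path, replicate_id: str = "rep1") -> FrameSet:
    """Read a plain per-frame XYZ table (CSV with columns frame, name,
    element, resid, resname, chain, x, y, z)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "name", "element", "resid", "resname", "chain", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    atoms = first[["name", "element", "resid", "resname", "chain"]].reset_index(drop=True)
    coords = np.stack(
        [df[df["frame"] == f][["x", "y", "z"]].to_numpy(float) for f in frames]
    )
    return FrameSet(coords, atoms, replicate_id=replicate_id)


def write_frames_xyz_table(fs: FrameSet, path) -> None:
    rows = []
    for f in range(fs.n_frames):
        block = fs.atoms.copy()
        block.insert(0, "frame", f)
        block[["x", "y", "z"]] = fs.coords[f]
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


def _polar_atom_indices(fs: FrameSet, resid: int, cdef: ContactDefinition,
                        chain: str | None = None) -> np.ndarray:
    idx = fs.atom_indices(resid, chain)
    if idx.size == 0:
        raise SelectionError(f"residue {resid} not present")
    sub = fs.atoms.iloc[idx]
    keep = sub["element"].str.upper().isin(cdef.elements)
    if cdef.scope == "sidechain":
        keep &= ~sub["name"].isin(BACKBONE_ATOMS)
    out = idx[keep.to_numpy()]
    if out.size == 0:
        raise SelectionError(
            f"residue {resid} has no {cdef.scope} atoms of element {cdef.elements}"
        )
    return out


def _segment_ca_indices(fs: FrameSet, seg: SegmentSpec) -> np.ndarray:
    m = (
        (fs.atoms["resid"].to_numpy() >= seg.start)
        & (fs.atoms["resid"].to_numpy() <= seg.stop)
        & (fs.atoms["name"].to_numpy() == seg.atom_rule)
    )
    if seg.chain is not None:
        m &= fs.atoms["chain"].to_numpy() == seg.chain
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise SelectionError(f"segment {seg.name} ({seg.start}-{seg.stop}) unresolvable")
    return idx


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def _min_pair_distance(frame_xyz: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> float:
    return float(cdist(frame_xyz[idx_i], frame_xyz[idx_j]).min())


def pair_contact_present(
    fs: FrameSet,
    frame: int,
    res_i: int,
    res_j: int,
    cdef: ContactDefinition = ContactDefinition(),
) -> bool:
    """Whether residues i and j form a polar contact in one frame.

    True iff the minimum N/O–N/O distance over the selected atoms is below
    (or, with ``inclusive``, at or below) the cutoff.
    """
    ii = _polar_atom_indices(fs, res_i, cdef)
    jj = _polar_atom_indices(fs, res_j, cdef)
    d = _min_pair_distance(fs.coords[frame], ii, jj)
    return d <= cdef.cutoff if cdef.inclusive else d < cdef.cutoff


@dataclass
class ContactOccupancy:
    combined: float  # frame-pooled occupancy over all replicates
    per_replicate: list[float]
    sd: float  # SD between replicate occupancies


def _occupancy_one(fs: FrameSet, res_i, res_j, cdef) -> float:
    ii = _polar_atom_indices(fs, res_i, cdef)
    jj = _polar_atom_indices(fs, res_j, cdef)
    d = np.array(
        [_min_pair_distance(fs.coords[f], ii, jj) for f in range(fs.n_frames)]
    )
    hits = d <= cdef.cutoff if cdef.inclusive else d < cdef.cutoff
    return float(hits.mean())


def pair_contact_occupancy(
    frames: FrameSet | Sequence[FrameSet],
    res_i: int,
    res_j: int,
    cdef: ContactDefinition = ContactDefinition(),
) -> ContactOccupancy:
    """Fraction of frames in which the residue pair is in polar contact.

    Accepts a single FrameSet or a list of replicate FrameSets; reports
    per-replicate occupancies, their SD (error bars between replicates) and
    the frame-pooled combined occupancy (the frame-count-weighted mean of
    the per-replicate values).
    """
    reps = [frames] if isinstance(frames, FrameSet) else list(frames)
    if not reps:
        raise ValueError("need at least one replicate")
    per = [_occupancy_one(r, res_i, res_j, cdef) for r in reps]
    n_frames = np.array([r.n_frames for r in reps], dtype=float)
    combined = float(np.average(per, weights=n_frames))
    sd = float(np.std(per, ddof=1)) if len(per) > 1 else 0.0
    return ContactOccupancy(combined=combined, per_replicate=per, sd=sd)


def network_contact_count(
    fs: FrameSet,
    residue_set: Sequence[int],
    cdef: ContactDefinition = ContactDefinition(),
) -> np.ndarray:
    """Per-frame count of residue pairs from the set in polar contact.

    Counts unordered pairs; equals the sum of :func:`pair_contact_present`
    over all C(k, 2) pairs on every frame.
    """
    residues = sorted(set(residue_set))
    if len(residues) < 2:
        raise ValueError("residue_set must contain >= 2 residues")
    sel = {r: _polar_atom_indices(fs, r, cdef) for r in residues}
    counts = np.zeros(fs.n_frames, dtype=int)
    for f in range(fs.n_frames):
        xyz = fs.coords[f]
        c = 0
        for i, ri in enumerate(residues):
            for rj in residues[i + 1:]:
                d = _min_pair_distance(xyz, sel[ri], sel[rj])
                if (d <= cdef.cutoff) if cdef.inclusive else (d < cdef.cutoff):
                    c += 1
        counts[f] = c
    return counts


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def segment_com_distance(
    fs: FrameSet, segment: SegmentSpec, bundle: Sequence[SegmentSpec]
) -> np.ndarray:
    """Per-frame distance between a segment's Calpha centroid and the
    Calpha centroid of the union of the bundle segments (Angstrom).

    The centroid is unweighted (Calpha center of mass in the helix-position
    sense). Invariant under rigid-body transformation of the frame.
    """
    seg_idx = _segment_ca_indices(fs, segment)
    bundle_idx = np.unique(np.concatenate([_segment_ca_indices(fs, s) for s in bundle]))
    seg_com = fs.coords[:, seg_idx].mean(axis=1)
    bundle_com = fs.coords[:, bundle_idx].mean(axis=1)
    return np.linalg.norm(seg_com - bundle_com, axis=1)


def kabsch_align(fs: FrameSet, reference_frame: int = 0,
                 atom_name: str = "CA") -> FrameSet:
    """Least-squares (Kabsch) superposition of every frame onto a reference.

    Alignment uses the named atoms (default Calpha). Returns a new FrameSet;
    the original is untouched.
    """
    sel = np.flatnonzero(fs.atoms["name"].to_numpy() == atom_name)
    if sel.size < 3:
        raise SelectionError(f"need >= 3 {atom_name} atoms to align")
    ref = fs.coords[reference_frame, sel]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(fs.coords)
    for f in range(fs.n_frames):
        mob = fs.coords[f, sel]
        mu = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mu)
        out[f] = rot.apply(fs.coords[f] - mu) + ref.mean(axis=0)
    return FrameSet(out, fs.atoms.copy(), fs.replicate_id, fs.frame_spacing)


# ---------------------------------------------------------------------------
# Densities and occupancy maps
# ---------------------------------------------------------------------------


def displacement_density(
    series: Sequence[np.ndarray] | np.ndarray,
    bandwidth: str | float = "silverman",
    n_grid: int = 512,
) -> DensityEstimate:
    """Gaussian-KDE probability density of per-frame distances.

    ``series`` is one distance array or a list of per-replicate arrays.
    Bandwidth follows Silverman's rule by default. The density is normalized
    to integrate to 1 on its support; per-replicate means are retained for
    replicate-level tests. Below 50 frames per replicate a histogram
    fallback is used with a warning.
    """
    reps = [np.asarray(series, float)] if np.ndim(series[0]) == 0 else [
        np.asarray(s, float) for s in series
    ]
    pooled = np.concatenate(reps)
    means = [float(r.mean()) for r in reps]
    spread = pooled.std()
    pad = 4.0 * spread if spread > 0 else max(1e-3, 0.05 * max(1.0, abs(pooled[0])))
    support = np.linspace(pooled.min() - pad, pooled.max() + pad, n_grid)

    if min(len(r) for r in reps) < 50:
        warnings.warn("fewer than 50 frames per replicate; histogram fallback")
        hist, edges = np.histogram(pooled, bins="auto", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.interp(support, centers, hist, left=0.0, right=0.0)
        area = np.trapezoid(dens, support)
        dens = dens / area if area > 0 else dens
        return DensityEstimate(support, dens, bandwidth=float(np.diff(edges).mean()),
                               per_replicate_means=means)

    if spread == 0.0:
        # degenerate: collapse to a narrow peak at the constant value
        sigma = 1e-6
        dens = np.exp(-0.5 * ((support - pooled[0]) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
        return DensityEstimate(support, dens, bandwidth=sigma, per_replicate_means=means)

    kde = gaussian_kde(pooled, bw_method=bandwidth)
    dens = kde(support)
    dens /= np.trapezoid(dens, support)
    return DensityEstimate(
        support, dens, bandwidth=float(kde.factor * spread), per_replicate_means=means
    )


def occupancy_grid(
    fs: FrameSet,
    atom_names: Sequence[str] = MAINCHAIN_ATOMS,
    voxel: float = 1.0,
    iso_threshold: float = 0.5,
) -> OccupancyGrid:
    """Per-voxel fraction of frames with >= 1 selected atom in the voxel.

    Frames must already share a reference orientation (use
    :func:`kabsch_align` first for raw trajectories). The grid covers all
    selected atoms in all frames.
    """
    sel = np.flatnonzero(fs.atoms["name"].isin(atom_names).to_numpy())
    if sel.size == 0:
        raise SelectionError(f"no atoms named {list(atom_names)}")
    xyz = fs.coords[:, sel]  # (F, S, 3)
    lo = xyz.reshape(-1, 3).min(axis=0)
    origin = lo - 0.5 * voxel
    shape = np.floor((xyz.reshape(-1, 3).max(axis=0) - origin) / voxel).astype(int) + 1
    values = np.zeros(shape, dtype=float)
    for f in range(fs.n_frames):
        ijk = np.floor((xyz[f] - origin) / voxel).astype(int)
        ijk = np.unique(ijk, axis=0)
        values[ijk[:, 0], ijk[:, 1], ijk[:, 2]] += 1.0
    values /= fs.n_frames
    return OccupancyGrid(origin=origin, voxel=voxel, values=values,
                         iso_threshold=iso_threshold)


def write_grid_dx(grid: OccupancyGrid, path) -> None:
    """Export an occupancy grid as OpenDX scalar data (plus plain values).

    The format is readable by common molecular-visualization tools.
    """
    nx, ny, nz = grid.values.shape
    ox, oy, oz = grid.origin
    v = grid.voxel
    with open(path, "w") as fh:
        fh.write(f"# occupancy grid, iso threshold {grid.iso_threshold}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {v:.6f} 0 0\ndelta 0 {v:.6f} 0\ndelta 0 0 {v:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{x:.6f}" for x in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "occupancy" class field\n')
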