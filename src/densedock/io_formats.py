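"""Structure and density I/O: MRC/CCP4 maps, PDB models, and docking pose sets.

All physical coordinates are Angstrom, right-handed, with 0-based voxel
indexing: the physical position of voxel (i, j, k) is
``origin + (i, j, k) * voxel_size``.  Density grids are stored with axis 0
along x, so they are congruent with the coordinate convention used for
atomic models and ligand poses.

File handling is delegated to :mod:`gemmi` (maps and PDB) and :mod:`rdkit`
(SDF); the PDBQT dialect is narrow enough (coordinates plus the Vina score
remark) that it is parsed directly here.
"""

from __future__ import annotations

import logging
import struct
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyModelError,
    MapFormatError,
    PoseInconsistencyError,
)

logger = logging.getLogger(__name__)

_MODE_BYTES = {0: 1, 1: 2, 2: 4, 6: 2, 12: 2}

# Two-letter symbols that are unambiguous at the start of an atom name.
_TWO_LETTER = {
    "CL", "BR", "FE", "MG", "ZN", "MN", "NA", "SE", "CU", "CO", "NI",
    "SI", "LI", "AL", "CD", "HG", "AS", "MO", "PT", "AU", "AG",
}
_ONE_LETTER = set("HBCNOFPSKIVWU")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelMap:
    """A 3-D scalar density grid with physical origin and voxel size."""

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    nominal_resolution: Optional[float] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("density grid must be 3-D with >= 2 voxels per axis")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive on all axes")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def copy(self, data: Optional[np.ndarray] = None) -> "VoxelMap":
        return VoxelMap(
            data=self.data.copy() if data is None else np.asarray(data, float),
            voxel_size=self.voxel_size.copy(),
            origin=self.origin.copy(),
            nominal_resolution=self.nominal_resolution,
        )

    def congruent(self, other: "VoxelMap", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def index_to_position(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, float) * self.voxel_size

    def position_to_index(self, xyz) -> np.ndarray:
        """Fractional (float) voxel index of a physical position."""
        return (np.asarray(xyz, float) - self.origin) / self.voxel_size

    def contains(self, xyz) -> bool:
        idx = self.position_to_index(xyz)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))


@dataclass
class Atom:
    chain: str
    res_num: int
    res_name: str
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class AtomicModel:
    """Chains/residues/atoms of a fitted structure, in map coordinates."""

    atoms: list
    source_id: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def residues(self) -> Iterator[tuple]:
        """Yield ((chain, res_num, res_name), atoms) in file order."""
        key = None
        group: list = []
        for a in self.atoms:
            k = (a.chain, a.res_num, a.res_name)
            if k != key and group:
                yield key, group
                group = []
            key = k
            group.append(a)
        if group:
            yield key, group

    def subset(self, atoms: Sequence[Atom]) -> "AtomicModel":
        return AtomicModel(atoms=list(atoms), source_id=self.source_id)

    def translated(self, shift) -> "AtomicModel":
        shift = np.asarray(shift, float)
        return AtomicModel(
            atoms=[replace(a, xyz=a.xyz + shift) for a in self.atoms],
            source_id=self.source_id,
        )


@dataclass
class LigandPose:
    """One ligand conformation in the receptor frame."""

    names: list
    elements: list
    coords: np.ndarray
    engine: str = ""
    engine_score: Optional[float] = None
    lower_is_better: Optional[bool] = None
    pose_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not (len(self.names) == len(self.elements) == len(self.coords)):
            raise ValueError("names, elements and coords must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def heavy_index(self) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self.elements) if e.upper() not in ("H", "D")],
            dtype=int,
        )

    def element_multiset(self) -> Counter:
        return Counter(e.upper() for e in self.elements)

    def to_model(self, res_name: str = "LIG", chain: str = "X") -> AtomicModel:
        atoms = [
            Atom(chain=chain, res_num=1, res_name=res_name, name=n,
                 element=e, xyz=x)
            for n, e, x in zip(self.names, self.elements, self.coords)
        ]
        return AtomicModel(atoms=atoms, source_id=self.pose_id)

    def transformed(self, rotation: np.ndarray, translation) -> "LigandPose":
        """Rigidly transform about the pose centroid."""
        c = self.centroid
        new = (self.coords - c) @ np.asarray(rotation, float).T + c
        new = new + np.asarray(translation, float)
        return replace(self, coords=new)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def _validate_mrc_header(path: Path) -> None:
    raw = path.read_bytes()[:1024]
    if len(raw) < 1024:
        raise MapFormatError(f"{path}: header truncated ({len(raw)} < 1024 bytes)")
    words_i = struct.unpack("<10i", raw[:40])
    nx, ny, nz, mode = words_i[0], words_i[1], words_i[2], words_i[3]
    cell = struct.unpack("<6f", raw[40:64])
    mapc, mapr, maps = struct.unpack("<3i", raw[64:76])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    if mode not in _MODE_BYTES:
        raise MapFormatError(f"{path}: unsupported MODE={mode}")
    if min(nx, ny, nz) < 2:
        raise MapFormatError(f"{path}: degenerate dimensions NX/NY/NZ={nx},{ny},{nz}")
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise MapFormatError(f"{path}: invalid axis order MAPC/MAPR/MAPS={mapc},{mapr},{maps}")
    for angle, label in zip(cell[3:], ("alpha", "beta", "gamma")):
        if abs(angle - 90.0) > 1e-3:
            raise MapFormatError(
                f"{path}: non-orthogonal cell ({label}={angle:.3f} deg) is unsupported"
            )
    expected = 1024 + max(nsymbt, 0) + nx * ny * nz * _MODE_BYTES[mode]
    actual = path.stat().st_size
    if actual < expected:
        raise MapFormatError(
            f"{path}: file holds {actual} bytes but NX*NY*NZ declares {expected}"
        )


def read_density_map(path) -> VoxelMap:
    """Read an MRC/CCP4 density map.

    The origin is taken from the ORIGIN header record when any component is
    nonzero, else from ``nstart * voxel_size``.  Axes are normalized to
    x, y, z regardless of the MAPC/MAPR/MAPS permutation in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_mrc_header(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise MapFormatError(f"{path}: {exc}") from exc

    # nstart words 5-7 are in column/row/section order; permute to x,y,z.
    axis_of = {ccp4.header_i32(17 + k): k for k in range(3)}  # axis -> crs slot
    nstart_crs = [ccp4.header_i32(5 + k) for k in range(3)]
    nstart_xyz = np.array([nstart_crs[axis_of[ax]] for ax in (1, 2, 3)], float)
    origin_rec = np.array([ccp4.header_float(w) for w in (50, 51, 52)], float)

    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = ccp4.grid
    data = np.array(grid, copy=True).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise MapFormatError(f"{path}: map contains non-finite voxel values")
    uc = grid.unit_cell
    voxel = np.array([uc.a / grid.nu, uc.b / grid.nv, uc.c / grid.nw], float)
    origin = origin_rec if np.any(origin_rec != 0) else nstart_xyz * voxel
    return VoxelMap(data=data, voxel_size=voxel, origin=origin)


def write_density_map(vmap: VoxelMap, path) -> None:
    """Write a VoxelMap as MRC/CCP4 (mode 2, ORIGIN record set)."""
    path = Path(path)
    grid = gemmi.FloatGrid(np.ascontiguousarray(vmap.data, dtype=np.float32))
    nx, ny, nz = vmap.shape
    vx, vy, vz = vmap.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, value in zip((50, 51, 52), vmap.origin):
        ccp4.set_header_float(w, float(value))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# atomic models
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    letters = "".join(c for c in name.strip() if c.isalpha()).upper()
    if len(letters) >= 2 and letters[:2] in _TWO_LETTER:
        return letters[:2].capitalize()
    if letters and letters[0] in _ONE_LETTER:
        return letters[0]
    warnings.warn(f"cannot infer element for atom name {name!r}; assuming carbon")
    return "C"


def _resolve_altlocs(residue_atoms: list) -> list:
    """Keep the highest-occupancy altloc per atom name (tie: first in file)."""
    by_name: dict = {}
    order: list = []
    for at in residue_atoms:
        key = at.name
        if key not in by_name:
            by_name[key] = at
            order.append(key)
        elif at.occupancy > by_name[key].occupancy:
            by_name[key] = at
    return [by_name[k] for k in order]


def read_model(path, source_id: Optional[str] = None) -> AtomicModel:
    """Read a PDB file into an AtomicModel (first model only).

    Alternate locations are resolved to the highest-occupancy conformer;
    missing element columns fall back to inference from the atom name.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    atoms: list = []
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models found")
    model = st[0]
    for chain in model:
        for res in chain:
            res_atoms = []
            for at in res:
                elem = at.element.name
                if not elem or elem.upper() == "X":
                    elem = _element_from_name(at.name)
                res_atoms.append(
                    Atom(
                        chain=chain.name,
                        res_num=res.seqid.num,
                        res_name=res.name,
                        name=at.name,
                        element=elem,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ),
                        b_factor=float(at.b_iso),
                    )
                )
            atoms.extend(_resolve_altlocs(res_atoms))
    if not atoms:
        raise EmptyModelError(f"{path}: no ATOM/HETATM records parsed")
    return AtomicModel(atoms=atoms, source_id=source_id or path.stem)


def write_model(model: AtomicModel, path) -> None:
    st = _model_to_gemmi(model)
    st.write_pdb(str(path))


def _model_to_gemmi(model: AtomicModel, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    chains: dict = {}
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        chain = chains[a.chain]
        if (len(chain) == 0 or chain[-1].seqid.num != a.res_num
                or chain[-1].name != a.res_name):
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_num, " ")
            res.het_flag = "A" if a.res_name in _STANDARD_RESIDUES else "H"
            chain.add_residue(res)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        res.add_atom(at)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# ---------------------------------------------------------------------------
# ligand pose sets
# ---------------------------------------------------------------------------

def _check_pose_consistency(poses: list) -> None:
    if not poses:
        return
    ref = poses[0]
    bad = [
        p.pose_id
        for p in poses
        if p.n_atoms != ref.n_atoms or p.element_multiset() != ref.element_multiset()
    ]
    if bad:
        raise PoseInconsistencyError(
            "poses disagree in atom count or element composition: "
            + ", ".join(bad),
            pose_ids=bad,
        )


def _meta_field(meta: dict, key: str) -> str:
    value = meta.get(key, "")
    return "" if value == "-" else value


def _scan_pose_remarks(path: Path) -> list:
    """Per-MODEL metadata remarks as written by :func:`write_pose_set`."""
    metas: list = []
    current: Optional[dict] = None
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = {}
            metas.append(current)
        elif line.startswith("REMARK   3 POSE_ID") and current is not None:
            fields = line.split()
            kv = dict(zip(fields[2::2], fields[3::2]))
            current.update(kv)
    return metas


def _poses_from_multimodel_pdb(path: Path, engine: str) -> list:
    # renumber MODEL records so concatenated pose files parse cleanly
    lines = path.read_text().splitlines()
    n_model = 0
    cleaned = []
    for line in lines:
        if line[:6].strip() == "MODEL":
            n_model += 1
            cleaned.append(f"MODEL     {n_model:4d}")
        elif line.strip() == "END" and n_model > 0:
            continue  # END between concatenated blocks would stop the parser
        else:
            cleaned.append(line)
    st = gemmi.read_pdb_string("\n".join(cleaned) + "\nEND\n")
    metas = _scan_pose_remarks(path)
    poses = []
    for k, gm in enumerate(st):
        names, elements, coords = [], [], []
        for chain in gm:
            for res in chain:
                for at in res:
                    elem = at.element.name
                    if not elem or elem.upper() == "X":
                        elem = _element_from_name(at.name)
                    names.append(at.name)
                    elements.append(elem)
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
        if coords:
            meta = metas[k] if k < len(metas) else {}
            score = meta.get("SCORE")
            orient = meta.get("ORIENT")
            poses.append(
                LigandPose(
                    names=names, elements=elements, coords=np.array(coords),
                    engine=engine or _meta_field(meta, "ENGINE"),
                    engine_score=float(score) if score not in (None, "None") else None,
                    lower_is_better={"lower": True, "higher": False}.get(orient),
                    pose_id=_meta_field(meta, "POSE_ID") or f"{path.stem}_m{k + 1}",
                )
            )
    return poses


_PDBQT_TYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "SA": "S", "S": "S", "P": "P", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "H": "H", "HD": "H", "HS": "H", "ZN": "Zn", "FE": "Fe", "MG": "Mg",
    "MN": "Mn", "CA": "Ca",
}


def _poses_from_pdbqt(path: Path, engine: str) -> list:
    """Parse a (multi-MODEL) PDBQT pose file.

    Only coordinates and the ``REMARK VINA RESULT`` score are read; partial
    charges and AutoDock atom types beyond element mapping are ignored.
    """
    poses = []
    names: list = []
    elements: list = []
    coords: list = []
    score: Optional[float] = None
    model_no = 0
    in_model = False

    def flush():
        nonlocal names, elements, coords, score
        if coords:
            poses.append(
                LigandPose(
                    names=list(names), elements=list(elements),
                    coords=np.array(coords), engine=engine,
                    engine_score=score, lower_is_better=True,
                    pose_id=f"{path.stem}_m{len(poses) + 1}",
                )
            )
        names, elements, coords, score = [], [], [], None

    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                flush()
            in_model = True
            model_no += 1
        elif rec == "ENDMDL":
            flush()
            in_model = False
        elif line.startswith("REMARK VINA RESULT:"):
            try:
                score = float(line.split()[3])
            except (IndexError, ValueError):
                raise MapFormatError(f"{path}: malformed VINA RESULT remark: {line!r}")
        elif rec in ("ATOM", "HETATM"):
            name = line[12:16].strip()
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            # the AutoDock atom type is the last field of a PDBQT atom record
            ad_type = line.split()[-1].upper()
            elem = _PDBQT_TYPE_TO_ELEMENT.get(ad_type) or _element_from_name(name)
            names.append(name)
            elements.append(elem)
            coords.append([x, y, z])
    flush()
    return poses


_SDF_SCORE_TAGS = (
    "Gold.Chemscore.Fitness", "Gold.Goldscore.Fitness", "Gold.PLP.Fitness",
    "Gold.ChemPLP.Fitness", "SCORE", "score", "minimizedAffinity",
)


def _poses_from_sdf(path: Path, engine: str) -> list:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    poses = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise MapFormatError(f"{path}: unreadable SDF record #{k + 1}")
        conf = mol.GetConformer()
        names, elements, coords = [], [], []
        counts: Counter = Counter()
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            counts[sym] += 1
            names.append(f"{sym.upper()}{counts[sym]}")
            elements.append(sym)
            p = conf.GetAtomPosition(atom.GetIdx())
            coords.append([p.x, p.y, p.z])
        score = None
        lower = None
        for tag in _SDF_SCORE_TAGS:
            if mol.HasProp(tag):
                score = float(mol.GetProp(tag))
                # GOLD fitness values are higher-is-better; affinities lower.
                lower = tag == "minimizedAffinity"
                break
        poses.append(
            LigandPose(
                names=names, elements=elements, coords=np.array(coords),
                engine=engine, engine_score=score, lower_is_better=lower,
                pose_id=f"{path.stem}_m{k + 1}",
            )
        )
    return poses


_DIALECT_READERS = {
    "pdb": _poses_from_multimodel_pdb,
    "pdbqt": _poses_from_pdbqt,
    "sdf": _poses_from_sdf,
}


def read_pose_set(path, dialect: Optional[str] = None, engine: str = "") -> list:
    """Read a set of ligand poses from one docking-output file.

    Parameters
    ----------
    dialect : {"pdb", "pdbqt", "sdf"}, optional
        Multi-model PDB, AutoDock PDBQT, or SDF.  Inferred from the file
        extension when omitted.
    engine : str
        Label of the producing engine, recorded on every pose.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        dialect = {"ent": "pdb"}.get(suffix, suffix)
    if dialect not in _DIALECT_READERS:
        raise ValueError(f"unknown pose dialect {dialect!r}")
    poses = _DIALECT_READERS[dialect](path, engine)
    if not poses:
        raise EmptyModelError(f"{path}: no poses parsed")
    _check_pose_consistency(poses)
    return poses


def write_pose_set(poses: Iterable[LigandPose], path, res_name: str = "LIG") -> None:
    """Write poses as a multi-model PDB readable by standard viewers."""
    path = Path(path)
    lines = []
    for k, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {k:4d}")
        orient = {True: "lower", False: "higher", None: "na"}[pose.lower_is_better]
        lines.append(f"REMARK   3 POSE_ID {pose.pose_id or '-'} "
                     f"ENGINE {pose.engine or '-'} "
                     f"SCORE {pose.engine_score} ORIENT {orient}")
        for i, (name, elem, xyz) in enumerate(
            zip(pose.names, pose.elements, pose.coords), start=1
        ):
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"HETATM{i:5d} {pdb_name[:4]:4s} {res_name:<3s} X   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {elem.rjust(2)[:2]}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
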