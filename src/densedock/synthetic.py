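"""Seeded synthetic scenes with the statistical structure the analysis assumes.

A scene emulates the experimental setup of ligand localization by cryo-EM
difference mapping: two reconstructions of the same receptor, one with a
bound small molecule (plus, optionally, a local conformational change),
both at a stated nominal resolution with additive voxel noise.  The
receptor is an abstract two-helix cleft — not a homology model of any real
motor — so no external structures are ever required.  Engine emulation
produces per-engine scored pose sets containing one near-native pose and
rigid-transform decoys, with scores arranged so that the near-native pose
is *not* the score leader in any engine: density, not the docking score,
must identify it, which is exactly the situation the density-constrained
selection stage exists for.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .density_sim import SimulationParams, simulate_map
from .errors import ConfigurationError
from .io_formats import Atom, AtomicModel, LigandPose, VoxelMap
from .kinetics import hill_inhibition, michaelis_menten
from .pose_analysis import graph_automorphisms, pose_rmsd

_HELIX_RADIUS = 2.3       # A, C-alpha helix radius
_HELIX_RISE = 1.5         # A per residue
_HELIX_TURN = 100.0       # degrees per residue


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _helix_chain(
    chain_id: str, n_res: int, offset: np.ndarray, phase_deg: float = 0.0
) -> List[Atom]:
    """An idealized poly-Ala-like helix along +x with 5 heavy atoms/residue."""
    atoms = []
    for i in range(n_res):
        def ring_pos(u: float, radius: float = _HELIX_RADIUS) -> np.ndarray:
            ang = np.deg2rad(phase_deg + u * _HELIX_TURN)
            return offset + np.array(
                [u * _HELIX_RISE, radius * np.cos(ang), radius * np.sin(ang)]
            )

        ca = ring_pos(i)
        n = ring_pos(i - 0.35)
        c = ring_pos(i + 0.35)
        o = ring_pos(i + 0.35, _HELIX_RADIUS + 1.2)
        cb = ring_pos(i, _HELIX_RADIUS + 1.5)
        for name, elem, xyz in (
            ("N", "N", n), ("CA", "C", ca), ("C", "C", c),
            ("O", "O", o), ("CB", "C", cb),
        ):
            atoms.append(
                Atom(chain=chain_id, res_num=i + 1, res_name="ALA",
                     name=name, element=elem, xyz=xyz)
            )
    return atoms


def _hexagon(center: np.ndarray, normal_axis: int, bond: float = 1.40):
    """Vertices of a planar six-ring, plane perpendicular to normal_axis."""
    pts = []
    axes = [d for d in range(3) if d != normal_axis]
    for k in range(6):
        ang = np.deg2rad(60 * k)
        p = center.copy()
        p[axes[0]] += bond * np.cos(ang)
        p[axes[1]] += bond * np.sin(ang)
        pts.append(p)
    return pts


def _build_ligand() -> LigandPose:
    """A rigid biaryl-like fragment of 20 heavy atoms centred near origin.

    Two six-membered carbon rings joined along x, a trifluoromethyl group
    on one end and a short amide-like tail on the other.
    """
    names, elements, coords = [], [], []

    def add(prefix, elem, xyz):
        names.append(f"{prefix}{len(names) + 1}")
        elements.append(elem)
        coords.append(np.asarray(xyz, float))

    for p in _hexagon(np.array([-2.1, 0.0, 0.0]), normal_axis=2):
        add("C", "C", p)
    ring2 = _hexagon(np.array([2.1, 0.0, 0.0]), normal_axis=2)
    tilt = Rotation.from_euler("x", 30, degrees=True)
    ring2 = [
        np.array([2.1, 0, 0]) + tilt.apply(p - np.array([2.1, 0, 0]))
        for p in ring2
    ]
    for p in ring2:
        add("C", "C", p)
    # CF3 on ring 1 far vertex (-3.5, 0, 0)
    cf = np.array([-5.0, 0.0, 0.0])
    add("C", "C", cf)
    for k in range(3):
        ang = np.deg2rad(120 * k)
        add("F", "F", cf + np.array([-0.9, 1.1 * np.cos(ang), 1.1 * np.sin(ang)]))
    # amide-like tail on ring 2 far vertex (3.5, 0, 0)
    n_pos = np.array([5.0, 0.0, 0.0])
    add("N", "N", n_pos)
    c_pos = n_pos + np.array([1.3, 0.6, 0.0])
    add("C", "C", c_pos)
    add("O", "O", c_pos + np.array([0.4, 1.1, 0.0]))
    add("C", "C", c_pos + np.array([1.4, -0.4, 0.0]))
    pose = LigandPose(
        names=names, elements=elements, coords=np.array(coords),
        engine="truth", pose_id="truth",
    )
    return pose


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScene:
    receptor: AtomicModel          # state in the ligand-bound map
    receptor_reference: AtomicModel  # state in the reference map
    true_pose: LigandPose
    map_with: VoxelMap
    map_without: VoxelMap
    ligand_peak_height: float
    noise_sigma: float
    resolution: float
    voxel: float
    seed: int
    conformational_change: bool
    sim_params: SimulationParams = field(repr=False, default=None)


def make_scene(
    resolution: float = 4.0,
    voxel: float = 1.0,
    noise_sigma: float = 0.1,
    conformational_change: bool = False,
    seed: int = 0,
    n_res: int = 30,
) -> SyntheticScene:
    """Build a paired-reconstruction scene with a planted ligand.

    Two 30-residue idealized helices (chains A and B, axes 14 A apart)
    form a cleft holding a rigid 20-heavy-atom biaryl fragment.  Both maps
    are simulated on a shared grid; independent white Gaussian voxel noise
    of standard deviation ``noise_sigma * (noise-free ligand peak height)``
    is added to each.  With ``conformational_change`` on, four residues at
    the far end of chain A are displaced between the two states, emulating
    receptor loops that move upon ligand binding and produce additional
    difference peaks.
    """
    if resolution < 2 * voxel:
        raise ConfigurationError(
            f"resolution {resolution} must be >= 2 * voxel ({voxel})"
        )
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    params = SimulationParams(resolution=resolution, voxel_size=voxel)

    chain_a = _helix_chain("A", n_res, offset=np.array([-n_res * _HELIX_RISE / 2, -7.0, 0.0]))
    chain_b = _helix_chain("B", n_res, offset=np.array([-n_res * _HELIX_RISE / 2, 7.0, 0.0]),
                           phase_deg=180.0)
    receptor_bound = AtomicModel(atoms=chain_a + chain_b, source_id="synthetic-receptor")

    if conformational_change:
        # displace the last 4 residues of chain A in the reference state
        moved = []
        for a in receptor_bound.atoms:
            if a.chain == "A" and a.res_num > n_res - 4:
                moved.append(replace(a, xyz=a.xyz + np.array([0.0, 0.0, 4.0])))
            else:
                moved.append(replace(a))
        receptor_ref = AtomicModel(atoms=moved, source_id="synthetic-receptor-ref")
    else:
        receptor_ref = AtomicModel(
            atoms=[replace(a) for a in receptor_bound.atoms],
            source_id="synthetic-receptor-ref",
        )

    ligand = _build_ligand()
    complex_model = AtomicModel(
        atoms=receptor_bound.atoms + ligand.to_model().atoms,
        source_id="synthetic-complex",
    )
    # one grid spanning every atom of both states plus the ligand
    span_atoms = complex_model.atoms + receptor_ref.atoms
    from .density_sim import empty_grid_for

    grid = empty_grid_for(span_atoms, params)

    clean_with = simulate_map(complex_model, params, grid=grid)
    clean_without = simulate_map(receptor_ref, params, grid=grid)
    ligand_only = simulate_map(ligand.to_model(), params, grid=grid)
    peak = float(ligand_only.data.max())

    sd = noise_sigma * peak
    noisy_with = clean_with.copy(
        data=clean_with.data + rng.normal(0.0, sd, clean_with.shape)
        if sd > 0 else clean_with.data
    )
    noisy_without = clean_without.copy(
        data=clean_without.data + rng.normal(0.0, sd, clean_without.shape)
        if sd > 0 else clean_without.data
    )
    noisy_with.nominal_resolution = resolution
    noisy_without.nominal_resolution = resolution

    return SyntheticScene(
        receptor=receptor_bound,
        receptor_reference=receptor_ref,
        true_pose=ligand,
        map_with=noisy_with,
        map_without=noisy_without,
        ligand_peak_height=peak,
        noise_sigma=noise_sigma,
        resolution=resolution,
        voxel=voxel,
        seed=seed,
        conformational_change=conformational_change,
        sim_params=params,
    )


# ---------------------------------------------------------------------------
# docking-engine emulation
# ---------------------------------------------------------------------------

_ENGINE_NAMES = ("vina", "chemscore", "goldscore", "chemplp", "engine5", "engine6")


@dataclass
class EngineEmulation:
    pose_sets: Dict[str, list]
    true_pose: LigandPose
    decoy_range: Tuple[float, float]
    consensus_fraction: float
    seed: int

    @property
    def engines(self) -> List[str]:
        return list(self.pose_sets)


def _random_rigid_pose(
    pose: LigandPose, rng: np.random.Generator, box_lo, box_hi
) -> LigandPose:
    rot = Rotation.random(random_state=rng).as_matrix()
    target = rng.uniform(box_lo, box_hi)
    moved = pose.transformed(rot, np.zeros(3))
    return replace(moved, coords=moved.coords - moved.centroid + target)


def _perturbed_pose(
    pose: LigandPose, rng: np.random.Generator, max_rmsd: float = 1.0
) -> LigandPose:
    for _ in range(1000):
        angle = rng.uniform(0.0, 8.0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
        shift = rng.normal(0.0, 0.3, size=3)
        cand = pose.transformed(rot, shift)
        if pose_rmsd(pose, cand, symmetry=False) <= max_rmsd:
            return cand
    raise RuntimeError("could not draw a near-native perturbation")  # pragma: no cover


def make_engine_outputs(
    scene: SyntheticScene,
    n_engines: int = 3,
    n_poses: int = 20,
    decoy_range: Tuple[float, float] = (5.0, 20.0),
    consensus_fraction: float = 1.0,
    seed: int = 0,
) -> EngineEmulation:
    """Per-engine scored pose sets with a planted near-native pose.

    Each engine receives one pose perturbed <= 1 A from the planted truth
    (in engines selected by ``consensus_fraction``; default all) plus rigid
    decoys whose symmetry-corrected RMSD to truth lies in ``decoy_range``.
    Engine scores are drawn so the near-native pose sits at the median of
    its engine's score distribution — never rank 1 by score alone.
    """
    if n_engines < 2 or n_poses < 2:
        raise ConfigurationError("need n_engines >= 2 and n_poses >= 2")
    if decoy_range[0] < 2.0:
        warnings.warn(
            "decoy_range lower bound < 2 A: decoys may alias the native cluster"
        )
    rng = np.random.default_rng(seed)
    truth = scene.true_pose
    autos = graph_automorphisms(
        [truth.elements[i] for i in truth.heavy_index()],
        truth.coords[truth.heavy_index()],
    )

    # decoy centres roam the receptor cleft bounding box, kept inside the map
    rec = scene.receptor.coords
    box_lo = rec.min(axis=0) + 2.0
    box_hi = rec.max(axis=0) - 2.0
    grid = scene.map_with

    n_native_engines = max(1, int(round(consensus_fraction * n_engines)))
    pose_sets: Dict[str, list] = {}
    for e_idx in range(n_engines):
        engine = _ENGINE_NAMES[e_idx] if e_idx < len(_ENGINE_NAMES) else f"engine{e_idx}"
        lower = engine == "vina"
        poses = []
        n_decoys = n_poses - (1 if e_idx < n_native_engines else 0)
        attempts = 0
        while len(poses) < n_decoys:
            attempts += 1
            if attempts > 20_000:  # pragma: no cover - generator guard
                raise RuntimeError("decoy rejection sampling failed")
            cand = _random_rigid_pose(truth, rng, box_lo, box_hi)
            if not all(grid.contains(x) for x in cand.coords):
                continue
            r = pose_rmsd(truth, cand, symmetry=True, automorphisms=autos)
            if decoy_range[0] <= r <= decoy_range[1]:
                poses.append(cand)
        if e_idx < n_native_engines:
            poses.append(_perturbed_pose(truth, rng))
        order = rng.permutation(len(poses))
        poses = [poses[i] for i in order]
        native_pos = None
        # score the set: decoys from the engine's score distribution,
        # near-native forced to the median (strictly worse than the best half)
        if lower:
            scores = rng.normal(-7.5, 1.0, size=len(poses))
        else:
            scores = rng.normal(45.0, 8.0, size=len(poses))
        for i, p in enumerate(poses):
            is_native = pose_rmsd(truth, p, symmetry=False) <= 1.0 + 1e-9
            if is_native:
                native_pos = i
        if native_pos is not None:
            others = np.delete(scores, native_pos)
            med = float(np.median(others))
            spread = float(others.std()) or 1.0
            scores[native_pos] = med + (0.05 * spread if lower else -0.05 * spread)
        labelled = []
        for i, p in enumerate(poses):
            labelled.append(
                replace(
                    p,
                    engine=engine,
                    engine_score=float(scores[i]),
                    lower_is_better=lower,
                    pose_id=f"{engine}_p{i:03d}",
                )
            )
        pose_sets[engine] = labelled
    return EngineEmulation(
        pose_sets=pose_sets, true_pose=truth, decoy_range=tuple(decoy_range),
        consensus_fraction=consensus_fraction, seed=seed,
    )


def make_pockets(
    scene: SyntheticScene,
    n_decoys: int = 2,
    jitter: float = 1.0,
    seed: int = 0,
) -> List[np.ndarray]:
    """A pocket-prediction stand-in: the true site (jittered) plus decoys.

    Decoy pockets sit on the receptor surface at least 10 A from the true
    site, emulating the spurious pockets a predictor reports.
    """
    rng = np.random.default_rng(seed)
    true_center = scene.true_pose.centroid + rng.normal(0.0, jitter / np.sqrt(3), 3)
    pockets = [true_center]
    rec = scene.receptor.coords
    attempts = 0
    while len(pockets) < n_decoys + 1:
        attempts += 1
        if attempts > 10_000:  # pragma: no cover
            break
        anchor = rec[rng.integers(len(rec))] + rng.normal(0.0, 1.0, 3)
        if np.linalg.norm(anchor - scene.true_pose.centroid) >= 10.0:
            pockets.append(anchor)
    return pockets


# ---------------------------------------------------------------------------
# kinetic titrations
# ---------------------------------------------------------------------------

def make_titration(
    model: str,
    truth: Optional[dict] = None,
    n_points: int = 8,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic titration table for the kinetics fits.

    ``model="mm"``: linear activator series 0..4*K with rates
    Vmax*S/(K+S) — a series concentrated around K, where the
    half-activation constant is identifiable; default truth
    Vmax = 1.22 /s, K = 13.5 (nM scale).
    ``model="ic50"``: log-spaced inhibitor series spanning two decades
    either side of b, activities a/(1+(x/b)^c); default truth a = 100,
    b = 0.8, c = 1.  Noise is multiplicative Gaussian of relative width
    ``noise_sigma``.
    """
    rng = np.random.default_rng(seed)
    if model == "mm":
        truth = dict({"vmax": 1.22, "k_half": 13.5}, **(truth or {}))
        conc = np.linspace(0.0, 4.0 * truth["k_half"], n_points)
        clean = michaelis_menten(conc, truth["vmax"], truth["k_half"])
        noisy = clean * (1.0 + rng.normal(0.0, noise_sigma, n_points))
        return pd.DataFrame({"concentration": conc, "rate": np.clip(noisy, 0, None)})
    if model == "ic50":
        truth = dict({"a": 100.0, "b": 0.8, "c": 1.0}, **(truth or {}))
        conc = np.logspace(
            np.log10(truth["b"]) - 2.0, np.log10(truth["b"]) + 2.0, n_points
        )
        clean = hill_inhibition(conc, truth["a"], truth["b"], truth["c"])
        noisy = clean * (1.0 + rng.normal(0.0, noise_sigma, n_points))
        return pd.DataFrame({"concentration": conc, "activity": noisy})
    raise ConfigurationError(f"unknown titration model {model!r}")
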