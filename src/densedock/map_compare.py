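"""Map comparison: amplitude-scaled difference maps, masked CCC, SMOC, peaks.

The difference-mapping workflow localizes a bound ligand (and conformational
changes) by subtracting a reference reconstruction from a ligand-bound
reconstruction after matching their radial amplitude spectra; positive
difference density then marks features present only in the first map.
Model-to-map agreement is quantified by the Pearson cross-correlation
coefficient (CCC) over a voxel mask, and locally by SMOC: the CCC of a
sliding window of residues (default 9) along each chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .density_sim import SimulationParams, simulate_map
from .errors import CongruenceError
from .io_formats import AtomicModel, VoxelMap

logger = logging.getLogger(__name__)

MIN_RELIABLE_MASK = 30


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class DifferenceResult:
    scaled_b: VoxelMap
    difference: VoxelMap
    positive: VoxelMap


@dataclass
class CCCResult:
    """A single masked cross-correlation."""

    value: float
    mask_voxel_count: int
    reliable: bool
    mask_mode: str
    sigma_coeff: float

    def __float__(self) -> float:
        return self.value


@dataclass
class FitScores:
    """CCC of one probe against the full and the difference map."""

    ccc_full: float
    ccc_diff: float
    mask_voxel_count: int
    reliable: bool = True

    @property
    def avg_ccc(self) -> float:
        return 0.5 * (self.ccc_full + self.ccc_diff)


@dataclass
class LocalFitProfile:
    records: list  # of dicts {chain, res_num, res_name, smoc, mask_voxels}
    window: int

    def values(self) -> np.ndarray:
        return np.array([r["smoc"] for r in self.records], float)

    def minimum(self) -> dict:
        return min(self.records, key=lambda r: r["smoc"])


@dataclass
class DifferencePeak:
    centroid: np.ndarray
    volume: int
    max_value: float
    threshold_used: float

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, float).reshape(3)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_congruent(a: VoxelMap, b: VoxelMap) -> None:
    if not a.congruent(b):
        raise CongruenceError(
            f"grids are not congruent: shapes {a.shape} vs {b.shape}, "
            f"voxel {a.voxel_size} vs {b.voxel_size}, "
            f"origin {a.origin} vs {b.origin}"
        )


def resample_onto(src: VoxelMap, template: VoxelMap) -> VoxelMap:
    """Trilinear resampling of ``src`` onto ``template``'s grid."""
    idx = [
        (template.origin[d]
         + np.arange(template.shape[d]) * template.voxel_size[d]
         - src.origin[d]) / src.voxel_size[d]
        for d in range(3)
    ]
    grid = np.meshgrid(*idx, indexing="ij")
    data = ndimage.map_coordinates(
        src.data, np.array(grid), order=1, mode="constant", cval=0.0
    )
    return template.copy(data=data)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


# ---------------------------------------------------------------------------
# amplitude scaling and difference maps
# ---------------------------------------------------------------------------

def scale_amplitudes(
    b: VoxelMap, a: VoxelMap, shell_width: Optional[float] = None
) -> VoxelMap:
    """Scale ``b``'s Fourier amplitudes so its radial power matches ``a``'s.

    Amplitudes within each Fourier shell of width ``shell_width`` (A^-1)
    are multiplied by a single factor so the shell's power equals that of
    ``a``; phases are untouched.  The DC term is scaled separately so the
    means match.  ``shell_width=inf`` (one shell) therefore reduces to
    global mean/std matching.  Default shell width is 1/(10 * box length),
    i.e. finer than the Fourier sampling — effectively per-radius matching.
    """
    _require_congruent(a, b)
    if shell_width is None:
        box = float(np.max(np.array(a.shape) * a.voxel_size))
        shell_width = 1.0 / (10.0 * box)

    fa = np.fft.fftn(a.data)
    fb = np.fft.fftn(b.data)

    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(a.shape, a.voxel_size)]
    s2 = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    s = np.sqrt(s2)

    if np.isinf(shell_width):
        shell_idx = np.zeros(a.shape, dtype=np.int64)
    else:
        shell_idx = np.floor(s / shell_width).astype(np.int64)
    dc = (s == 0)
    shell_idx = shell_idx.copy()
    shell_idx[dc] = -1  # DC handled separately

    n_shells = int(shell_idx.max()) + 1
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    flat_idx = shell_idx.ravel()
    valid = flat_idx >= 0
    pow_a = np.bincount(flat_idx[valid], weights=pa.ravel()[valid], minlength=n_shells)
    pow_b = np.bincount(flat_idx[valid], weights=pb.ravel()[valid], minlength=n_shells)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.sqrt(pow_a / pow_b)
    factors[~np.isfinite(factors)] = 1.0

    scale = np.ones(a.shape)
    scale[~dc] = factors[shell_idx[~dc]]
    fb_scaled = fb * scale
    # DC term is real for real input; matching it matches the means exactly.
    fb_scaled[0, 0, 0] = fa[0, 0, 0]
    out = np.real(np.fft.ifftn(fb_scaled))
    return b.copy(data=out)


def difference_map(
    a: VoxelMap, b: VoxelMap, shell_width: Optional[float] = None
) -> DifferenceResult:
    """Amplitude-scaled difference ``a - scale(b -> a)`` with positive clamp."""
    if not a.congruent(b):
        b = resample_onto(b, a)
    scaled = scale_amplitudes(b, a, shell_width=shell_width)
    diff = a.copy(data=a.data - scaled.data)
    pos = a.copy(data=np.clip(diff.data, 0.0, None))
    return DifferenceResult(scaled_b=scaled, difference=diff, positive=pos)


# ---------------------------------------------------------------------------
# masks and CCC
# ---------------------------------------------------------------------------

def proximity_mask(
    grid: VoxelMap, coords: np.ndarray, radius: float
) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` A of any coordinate."""
    mask = np.zeros(grid.shape, dtype=bool)
    shape = np.array(grid.shape)
    vox = grid.voxel_size
    half = np.ceil(radius / vox).astype(int)
    r2_cut = radius * radius
    for xyz in np.atleast_2d(coords):
        center_idx = (xyz - grid.origin) / vox
        lo = np.maximum(np.floor(center_idx).astype(int) - half, 0)
        hi = np.minimum(np.floor(center_idx).astype(int) + half + 2, shape)
        if np.any(lo >= hi):
            continue
        ax = [
            (np.arange(lo[d], hi[d]) * vox[d] + grid.origin[d] - xyz[d]) ** 2
            for d in range(3)
        ]
        r2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= r2 <= r2_cut
    return mask


def _mask_radius(params: SimulationParams) -> float:
    return max(2.5, params.resolution / 2.0)


def ccc(
    exp_map: VoxelMap,
    probe: Union[AtomicModel, VoxelMap],
    params: SimulationParams,
    mask_mode: str = "model-proximity",
    contour_frac: float = 0.1,
) -> CCCResult:
    """Masked Pearson correlation of experimental vs simulated density.

    ``probe`` may be an atomic model (simulated on the experimental grid)
    or an already-simulated congruent map.  Mask modes:

    - ``model-proximity``: voxels within max(2.5 A, resolution/2) of any
      probe atom (requires a model probe).  Default, because local fit is
      what distinguishes ligand poses; a whole-map CCC is dominated by the
      large receptor/tubulin density.
    - ``sim-contour``: voxels where the simulated map exceeds
      ``contour_frac`` of its maximum.
    - ``whole-map``: all voxels.
    """
    if isinstance(probe, VoxelMap):
        _require_congruent(exp_map, probe)
        sim = probe
        model = None
    else:
        model = probe
        sim = simulate_map(model, params, grid=exp_map)

    if mask_mode == "model-proximity":
        if model is None:
            raise ValueError("model-proximity masking requires an atomic model probe")
        coords = np.array([a.xyz for a in model.heavy_atoms()])
        mask = proximity_mask(exp_map, coords, _mask_radius(params))
    elif mask_mode == "sim-contour":
        mask = sim.data > contour_frac * sim.data.max()
    elif mask_mode == "whole-map":
        mask = np.ones(exp_map.shape, dtype=bool)
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")

    count = int(mask.sum())
    reliable = count >= MIN_RELIABLE_MASK
    if not reliable:
        warnings.warn(
            f"CCC mask has only {count} voxels (<{MIN_RELIABLE_MASK}); "
            "score flagged unreliable"
        )
    value = pearson(exp_map.data[mask], sim.data[mask]) if count > 1 else 0.0
    return CCCResult(
        value=value, mask_voxel_count=count, reliable=reliable,
        mask_mode=mask_mode, sigma_coeff=params.sigma_coeff,
    )


# ---------------------------------------------------------------------------
# SMOC
# ---------------------------------------------------------------------------

def smoc(
    model: AtomicModel,
    exp_map: VoxelMap,
    params: SimulationParams,
    window: int = 9,
) -> LocalFitProfile:
    """Per-residue local fit: CCC over a sliding window of residues.

    For each residue the mask covers the atoms of the ``window`` residues
    centred on it (truncated at chain ends), and the experimental map is
    correlated with the map simulated from the whole model over that mask.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and >= 1")
    sim = simulate_map(model, params, grid=exp_map, on_outside="ignore")
    radius = _mask_radius(params)
    half = window // 2
    records = []

    by_chain: dict = {}
    for key, atoms in model.residues():
        by_chain.setdefault(key[0], []).append((key, atoms))

    for chain_id, residues in by_chain.items():
        inside = [
            (key, atoms)
            for key, atoms in residues
            if any(exp_map.contains(a.xyz) for a in atoms)
        ]
        if not inside:
            warnings.warn(f"chain {chain_id}: no residue inside the map; skipped")
            continue
        for i, (key, _) in enumerate(inside):
            lo = max(0, i - half)
            hi = min(len(inside), i + half + 1)
            coords = np.array(
                [a.xyz for _, atoms in inside[lo:hi] for a in atoms
                 if not a.is_hydrogen]
            )
            mask = proximity_mask(exp_map, coords, radius)
            count = int(mask.sum())
            value = pearson(exp_map.data[mask], sim.data[mask]) if count > 1 else 0.0
            records.append(
                {
                    "chain": key[0], "res_num": key[1], "res_name": key[2],
                    "smoc": value, "mask_voxels": count,
                }
            )
    return LocalFitProfile(records=records, window=window)


# ---------------------------------------------------------------------------
# difference peaks
# ---------------------------------------------------------------------------

def find_difference_peaks(
    diff: VoxelMap, threshold_sigma: float = 3.0, min_volume: int = 5
) -> List[DifferencePeak]:
    """Connected components of voxels above mean + threshold_sigma * std.

    Components (26-connectivity) of at least ``min_volume`` voxels are
    returned sorted by maximum value (desc), ties broken by larger volume
    then lexicographic centroid.  Centroids are density-weighted physical
    coordinates.  Mean/std are taken over the whole grid.
    """
    data = diff.data
    if not np.all(np.isfinite(data)):
        raise ValueError("difference map contains non-finite values")
    thr = data.mean() + threshold_sigma * data.std()
    above = data > thr
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    peaks = []
    for lab in range(1, n + 1):
        sel = labels == lab
        vol = int(sel.sum())
        if vol < min_volume:
            continue
        w = data[sel]
        idx = np.argwhere(sel).astype(float)
        centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
        centroid = diff.index_to_position(centroid_idx)
        peaks.append(
            DifferencePeak(
                centroid=centroid, volume=vol, max_value=float(w.max()),
                threshold_used=threshold_sigma,
            )
        )
    peaks.sort(
        key=lambda p: (-p.max_value, -p.volume, tuple(np.round(p.centroid, 6)))
    )
    return peaks
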