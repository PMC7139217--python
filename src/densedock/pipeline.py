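"""Two-stage density-constrained consensus docking protocol.

Stage 1 — site identification: difference mapping between the ligand-bound
and reference reconstructions, merging of repeated blind-docking runs with
redundancy grouping, centroid clustering of the unique conformations into
candidate sites, and consensus of the three evidence sources (pocket
prediction, dock clusters, difference peaks).  Stage 2 — pose selection:
cross-engine consensus of the scored pose sets followed by ranking on the
average CCC against the full and the difference map; optionally repeated
with focused pose sets restricted to a tight radius around the chosen site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .density_sim import SimulationParams, simulate_map
from .errors import ConfigurationError, OutOfBoundsError
from .io_formats import AtomicModel, LigandPose, VoxelMap
from .map_compare import (
    DifferencePeak,
    FitScores,
    ccc,
    difference_map,
    find_difference_peaks,
)
from .pose_analysis import (
    ConsensusSet,
    PoseCluster,
    cluster_by_centroid,
    consensus,
    deduplicate,
)

logger = logging.getLogger(__name__)


@dataclass
class SiteCandidate:
    center: np.ndarray
    evidence: set                      # subset of {pocket, dock-cluster, diff-peak}
    linked_ids: dict                   # kind -> list of indices/ids
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, float).reshape(3)

    @property
    def is_consensus(self) -> bool:
        return self.evidence == {"pocket", "dock-cluster", "diff-peak"}


@dataclass
class RankedPose:
    pose: LigandPose
    scores: FitScores
    rank: int
    flagged: bool = False

    @property
    def avg_ccc(self) -> float:
        return self.scores.avg_ccc


@dataclass
class PipelineConfig:
    resolution: float
    voxel_size: float = 1.0
    rmsd_threshold: float = 2.0
    n_blind_runs: int = 100
    stage1_radius: float = 12.0
    stage2_radius: float = 6.0
    peak_threshold_sigma: float = 3.0
    min_peak_volume: int = 5
    match_radius: float = 5.0
    link_threshold: float = 5.0
    sigma_coeff: float = 0.356
    symmetry: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.stage1_radius <= 0 or self.stage2_radius <= 0:
            raise ConfigurationError("site radii must be positive")
        if self.stage2_radius > self.stage1_radius:
            raise ConfigurationError("stage-2 radius must be <= stage-1 radius")

    def sim_params(self) -> SimulationParams:
        return SimulationParams(
            resolution=self.resolution,
            voxel_size=self.voxel_size,
            sigma_coeff=self.sigma_coeff,
        )


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def merge_blind_runs(
    run_outputs: Sequence[Sequence[LigandPose]],
    threshold: float = 2.0,
    symmetry: bool = True,
) -> List[PoseCluster]:
    """Merge repeated blind-docking runs and group redundant conformations.

    All runs are concatenated and deduplicated at ``threshold`` RMSD; each
    representative carries the best score among its duplicates.
    """
    merged = [p for run in run_outputs for p in run]
    if not merged:
        raise ConfigurationError("no poses in any blind run")
    return deduplicate(merged, threshold=threshold, symmetry=symmetry)


def identify_sites(
    clusters: Sequence[PoseCluster],
    peaks: Sequence[DifferencePeak],
    pockets: Sequence,
    match_radius: float = 5.0,
    site_radius: float = 12.0,
) -> List[SiteCandidate]:
    """Link the three evidence sources into candidate binding sites.

    Evidence items (dock-cluster centroids, difference-peak centroids,
    predicted pocket centers) are linked when their centers lie within
    ``match_radius`` of each other; connected groups become candidates.  A
    candidate supported by all three kinds is a consensus site.  Candidates
    are sorted consensus-first, then by the max value of any linked peak.
    """
    items = (
        [("dock-cluster", i, np.asarray(c.centroid, float)) for i, c in enumerate(clusters)]
        + [("diff-peak", i, np.asarray(p.centroid, float)) for i, p in enumerate(peaks)]
        + [("pocket", i, np.asarray(p, float)) for i, p in enumerate(pockets)]
    )
    if not items:
        raise ConfigurationError("identify_sites needs at least one evidence item")

    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(items[i][2] - items[j][2]) <= match_radius:
                parent[find(i)] = find(j)

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    candidates = []
    for group in groups.values():
        kinds = {items[i][0] for i in group}
        linked: dict = {}
        for i in group:
            linked.setdefault(items[i][0], []).append(items[i][1])
        center = np.mean([items[i][2] for i in group], axis=0)
        candidates.append(
            SiteCandidate(
                center=center, evidence=kinds, linked_ids=linked,
                radius=site_radius,
            )
        )

    def peak_strength(cand: SiteCandidate) -> float:
        ids = cand.linked_ids.get("diff-peak", [])
        return max((peaks[i].max_value for i in ids), default=-np.inf)

    candidates.sort(
        key=lambda c: (
            not c.is_consensus,
            -len(c.evidence),
            -peak_strength(c),
            tuple(np.round(c.center, 6)),
        )
    )
    return candidates


def select_pose(
    poses: Sequence[LigandPose],
    full_map: VoxelMap,
    diff_map: VoxelMap,
    params: SimulationParams,
) -> List[RankedPose]:
    """Rank poses by average CCC against the full and difference maps.

    Each pose is scored with model-proximity masking; the best conformation
    is the one with the highest average of the two CCCs.  Ties break on the
    higher full-map CCC (the full map is better determined than a
    difference map), then lexicographic pose id.  A pose falling outside
    either map is flagged and ranked last.
    """
    if not poses:
        raise ConfigurationError("select_pose needs at least one pose")
    entries = []
    for pose in poses:
        try:
            model = pose.to_model()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c_full = ccc(full_map, model, params, mask_mode="model-proximity")
                c_diff = ccc(diff_map, model, params, mask_mode="model-proximity")
            scores = FitScores(
                ccc_full=c_full.value, ccc_diff=c_diff.value,
                mask_voxel_count=c_full.mask_voxel_count,
                reliable=c_full.reliable and c_diff.reliable,
            )
            flagged = False
        except OutOfBoundsError:
            scores = FitScores(
                ccc_full=-np.inf, ccc_diff=-np.inf, mask_voxel_count=0,
                reliable=False,
            )
            flagged = True
            logger.warning("pose %s outside map; ranked last", pose.pose_id)
        entries.append((pose, scores, flagged))
    entries.sort(
        key=lambda e: (
            e[2],
            -e[1].avg_ccc if np.isfinite(e[1].avg_ccc) else np.inf,
            -e[1].ccc_full if np.isfinite(e[1].ccc_full) else np.inf,
            e[0].pose_id,
        )
    )
    return [
        RankedPose(pose=p, scores=s, rank=i + 1, flagged=f)
        for i, (p, s, f) in enumerate(entries)
    ]


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolInputs:
    map_with: VoxelMap
    map_without: VoxelMap
    stage1_pose_sets: Dict[str, Sequence[LigandPose]]
    blind_runs: Optional[Sequence[Sequence[LigandPose]]] = None
    stage2_pose_sets: Optional[Dict[str, Sequence[LigandPose]]] = None
    pockets: Sequence = ()


def _rank_normalized(poses: Sequence[LigandPose]) -> List[LigandPose]:
    """Copies of one engine's poses with score replaced by within-engine rank."""
    from dataclasses import replace

    from .pose_analysis import _score_order

    order = _score_order(list(poses))
    out = [None] * len(poses)
    for rank, idx in enumerate(order):
        out[idx] = replace(poses[idx], engine_score=float(rank), lower_is_better=True)
    return out


def _restrict_to_site(
    poses: Sequence[LigandPose], center: np.ndarray, radius: float
) -> List[LigandPose]:
    return [p for p in poses if np.linalg.norm(p.centroid - center) <= radius]


def run_protocol(config: PipelineConfig, inputs: ProtocolInputs) -> dict:
    """Execute the full two-stage protocol and return a report dict.

    Steps: difference map -> difference peaks -> merge blind runs ->
    centroid clustering -> site identification -> stage-1 cross-engine
    consensus restricted to the top site -> density-constrained pose
    ranking; then, if stage-2 pose sets are supplied, consensus + ranking
    again within the tight stage-2 radius.  Deterministic given fixed
    inputs and config.
    """
    if inputs.map_with is None or inputs.map_without is None:
        raise ConfigurationError("both reconstructions are required")
    if not inputs.stage1_pose_sets:
        raise ConfigurationError("stage-1 pose sets are required")

    params = config.sim_params()
    report: dict = {
        "config": {
            "resolution": config.resolution,
            "voxel_size": config.voxel_size,
            "rmsd_threshold": config.rmsd_threshold,
            "stage1_radius": config.stage1_radius,
            "stage2_radius": config.stage2_radius,
            "peak_threshold_sigma": config.peak_threshold_sigma,
            "min_peak_volume": config.min_peak_volume,
            "match_radius": config.match_radius,
            "link_threshold": config.link_threshold,
            "sigma_coeff": config.sigma_coeff,
            "symmetry": config.symmetry,
            "seed": config.seed,
        },
        "stages": {},
        "flags": [],
    }

    # --- difference mapping ------------------------------------------------
    diff = difference_map(inputs.map_with, inputs.map_without)
    peaks = find_difference_peaks(
        diff.positive,
        threshold_sigma=config.peak_threshold_sigma,
        min_volume=config.min_peak_volume,
    )
    report["stages"]["difference"] = {
        "n_peaks": len(peaks),
        "peaks": [
            {
                "centroid": [float(round(v, 3)) for v in p.centroid],
                "volume": p.volume,
                "max_value": float(round(p.max_value, 6)),
            }
            for p in peaks
        ],
    }
    logger.info("difference mapping: %d peaks above %.1f sigma",
                len(peaks), config.peak_threshold_sigma)

    # --- blind-run merging and clustering ----------------------------------
    blind_runs = inputs.blind_runs
    if blind_runs is None:
        # engines score on incomparable scales; replace raw scores by the
        # within-engine rank so the pooled dedup never compares them directly
        blind_runs = [
            _rank_normalized(list(v)) for v in inputs.stage1_pose_sets.values()
        ]
    merged = merge_blind_runs(
        blind_runs, threshold=config.rmsd_threshold, symmetry=config.symmetry
    )
    site_clusters = cluster_by_centroid(
        [c.representative for c in merged], link_threshold=config.link_threshold
    )
    report["stages"]["blind_docking"] = {
        "poses_in": sum(len(r) for r in blind_runs),
        "unique_conformations": len(merged),
        "site_clusters": len(site_clusters),
    }

    # --- site identification ------------------------------------------------
    sites = identify_sites(
        site_clusters, peaks, inputs.pockets,
        match_radius=config.match_radius, site_radius=config.stage1_radius,
    )
    top_site = sites[0]
    report["stages"]["sites"] = {
        "n_candidates": len(sites),
        "top_site": {
            "center": [float(round(v, 3)) for v in top_site.center],
            "evidence": sorted(top_site.evidence),
            "consensus": top_site.is_consensus,
        },
        "table": [
            {
                "center": [float(round(v, 3)) for v in s.center],
                "evidence": sorted(s.evidence),
                "consensus": s.is_consensus,
            }
            for s in sites
        ],
    }

    # --- stage-1 consensus and ranking --------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dedup_sets = {
            engine: [
                c.representative
                for c in deduplicate(
                    list(poses), threshold=config.rmsd_threshold,
                    symmetry=config.symmetry,
                )
            ]
            for engine, poses in inputs.stage1_pose_sets.items()
        }
        cons = consensus(
            dedup_sets, threshold=config.rmsd_threshold, symmetry=config.symmetry
        )
    eligible = _restrict_to_site(cons.poses, top_site.center, config.stage1_radius)
    fallback = False
    if not eligible:
        # no cross-engine consensus at the site: fall back to ranking the
        # per-engine unique representatives near the site instead
        fallback = True
        pool = [p for reps in dedup_sets.values() for p in reps]
        eligible = _restrict_to_site(pool, top_site.center, config.stage1_radius)
        report["flags"].append("empty-consensus-fallback")
        if not eligible:
            eligible = list(cons.poses) or pool
            report["flags"].append("no-pose-near-top-site")

    ranked = select_pose(eligible, inputs.map_with, diff.positive, params)
    report["stages"]["stage1"] = {
        "per_engine_unique": {e: len(v) for e, v in dedup_sets.items()},
        "consensus_size": len(cons),
        "eligible_at_site": len(eligible),
        "fallback": fallback,
        "ranked": _pose_table(ranked),
    }

    final_ranked = ranked
    stage_label = "stage-1 only"

    # --- optional stage 2 ----------------------------------------------------
    if inputs.stage2_pose_sets:
        site2_center = ranked[0].pose.centroid
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dedup2 = {
                engine: [
                    c.representative
                    for c in deduplicate(
                        list(poses), threshold=config.rmsd_threshold,
                        symmetry=config.symmetry,
                    )
                ]
                for engine, poses in inputs.stage2_pose_sets.items()
            }
            cons2 = consensus(
                dedup2, threshold=config.rmsd_threshold, symmetry=config.symmetry
            )
        eligible2 = _restrict_to_site(cons2.poses, site2_center, config.stage2_radius)
        if eligible2:
            final_ranked = select_pose(
                eligible2, inputs.map_with, diff.positive, params
            )
            stage_label = "two-stage"
            report["stages"]["stage2"] = {
                "consensus_size": len(cons2),
                "eligible_at_site": len(eligible2),
                "ranked": _pose_table(final_ranked),
            }
        else:
            report["flags"].append("stage2-empty-at-site")

    best = final_ranked[0]
    assert all(
        best.avg_ccc >= r.avg_ccc or r.flagged for r in final_ranked
    ), "rank-1 pose must have maximal average CCC"
    report["mode"] = stage_label
    report["final"] = {
        "pose_id": best.pose.pose_id,
        "engine": best.pose.engine,
        "ccc_full": float(round(best.scores.ccc_full, 6)),
        "ccc_diff": float(round(best.scores.ccc_diff, 6)),
        "avg_ccc": float(round(best.avg_ccc, 6)),
        "centroid": [float(round(v, 3)) for v in best.pose.centroid],
    }
    report["final_pose"] = best.pose
    report["ranked_poses"] = final_ranked
    return report


def _pose_table(ranked: Sequence[RankedPose]) -> list:
    return [
        {
            "rank": r.rank,
            "pose_id": r.pose.pose_id,
            "engine": r.pose.engine,
            "ccc_full": float(round(r.scores.ccc_full, 6))
            if np.isfinite(r.scores.ccc_full) else None,
            "ccc_diff": float(round(r.scores.ccc_diff, 6))
            if np.isfinite(r.scores.ccc_diff) else None,
            "avg_ccc": float(round(r.avg_ccc, 6)) if np.isfinite(r.avg_ccc) else None,
            "flagged": r.flagged,
        }
        for r in ranked
    ]
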