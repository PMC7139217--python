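"""Ligand pose comparison: in-frame RMSD, redundancy grouping, clustering,
and cross-engine consensus.

Docking poses produced against a fixed receptor share the receptor frame,
so RMSD is computed without superposition — a rigid translation of 2 A is
an RMSD of 2 A.  With symmetry handling on, the RMSD is minimized over the
chemically equivalent atom mappings (automorphisms of the element-colored
bond graph), so e.g. a 180-degree ring flip does not inflate the distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import CorrespondenceError, ScoreOrientationError
from .io_formats import LigandPose

MAX_AUTOMORPHISMS = 10_000


@dataclass
class PoseCluster:
    representative: LigandPose
    members: list  # pose ids
    centroid: np.ndarray

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, float).reshape(3)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSet:
    poses: list
    support: dict  # pose_id -> {engine: matched pose id}
    threshold: float

    def __len__(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _heavy(pose: LigandPose):
    idx = pose.heavy_index()
    return (
        [pose.names[i] for i in idx],
        [pose.elements[i].upper() for i in idx],
        pose.coords[idx],
    )


def _correspondence(p: LigandPose, q: LigandPose):
    """Heavy-atom coordinate arrays of p and q matched by atom name."""
    pn, pe, pc = _heavy(p)
    qn, qe, qc = _heavy(q)
    if len(pn) != len(qn):
        raise CorrespondenceError(
            f"poses {p.pose_id!r} and {q.pose_id!r} differ in heavy-atom "
            f"count ({len(pn)} vs {len(qn)})"
        )
    if pn == qn:
        pass  # same order
    elif sorted(pn) == sorted(qn) and len(set(pn)) == len(pn):
        order = [qn.index(n) for n in pn]
        qc = qc[order]
        qe = [qe[i] for i in order]
    else:
        raise CorrespondenceError(
            f"cannot match atoms of poses {p.pose_id!r} and {q.pose_id!r} by name"
        )
    if pe != qe:
        raise CorrespondenceError(
            f"element mismatch between poses {p.pose_id!r} and {q.pose_id!r}"
        )
    return pc, qc


def infer_bonds(elements: Sequence[str], coords: np.ndarray, slack: float = 0.45):
    """Bond list inferred from covalent radii: d < r_i + r_j + slack."""
    radii = np.array(
        [max(gemmi.Element(e).covalent_r, 0.3) for e in elements], float
    )
    n = len(elements)
    bonds = []
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < radii[i] + radii[j] + slack:
                bonds.append((i, j))
    return bonds


def graph_automorphisms(
    elements: Sequence[str], coords: np.ndarray, cap: int = MAX_AUTOMORPHISMS
) -> Optional[List[np.ndarray]]:
    """Automorphisms of the element-colored bond graph, or None past cap."""
    g = nx.Graph()
    for i, e in enumerate(elements):
        g.add_node(i, element=e.upper())
    g.add_edges_from(infer_bonds(elements, coords))
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    maps = []
    for iso in matcher.isomorphisms_iter():
        maps.append(np.array([iso[i] for i in range(len(elements))], int))
        if len(maps) > cap:
            warnings.warn(
                f"more than {cap} graph automorphisms; "
                "falling back to identity mapping only"
            )
            return None
    return maps


def pose_rmsd(
    p: LigandPose,
    q: LigandPose,
    symmetry: bool = True,
    automorphisms: Optional[List[np.ndarray]] = None,
) -> float:
    """Heavy-atom RMSD in the shared receptor frame (no superposition).

    With ``symmetry`` on, the minimum over chemically equivalent atom
    mappings is returned; precomputed ``automorphisms`` (e.g. from
    :func:`graph_automorphisms` on any conformer of the same molecule) can
    be passed to avoid recomputation in all-pairs workloads.
    """
    pc, qc = _correspondence(p, q)
    direct = float(np.sqrt(np.mean(np.sum((pc - qc) ** 2, axis=-1))))
    if not symmetry:
        return direct
    if automorphisms is None:
        _, pe, _ = _heavy(p)
        automorphisms = graph_automorphisms(pe, pc)
    if automorphisms is None:  # enumeration was capped
        return direct
    best = direct
    for perm in automorphisms:
        r = float(np.sqrt(np.mean(np.sum((pc[perm] - qc) ** 2, axis=-1))))
        if r < best:
            best = r
    return best


def rmsd_matrix(
    poses: Sequence[LigandPose], symmetry: bool = True
) -> np.ndarray:
    """All-pairs pose RMSD; automorphisms computed once for the set."""
    n = len(poses)
    autos = None
    if symmetry and n > 1:
        names, elems, coords = _heavy(poses[0])
        autos = graph_automorphisms(elems, coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pose_rmsd(
                poses[i], poses[j], symmetry=symmetry, automorphisms=autos
            )
    return out


# ---------------------------------------------------------------------------
# redundancy grouping (greedy, best score first)
# ---------------------------------------------------------------------------

def _score_order(poses: Sequence[LigandPose]):
    """Indices sorted best-score-first; ties broken by pose_id."""
    orientations = {p.lower_is_better for p in poses if p.lower_is_better is not None}
    if len(orientations) > 1:
        raise ScoreOrientationError(
            "poses mix lower-is-better and higher-is-better scores"
        )
    have_scores = all(p.engine_score is not None for p in poses)
    if not have_scores:
        warnings.warn(
            "poses lack engine scores; input order used as score proxy"
        )
        return list(range(len(poses)))
    lower = orientations.pop() if orientations else True
    sign = 1.0 if lower else -1.0
    return sorted(
        range(len(poses)),
        key=lambda i: (sign * poses[i].engine_score, poses[i].pose_id),
    )


def deduplicate(
    poses: Sequence[LigandPose],
    threshold: float = 2.0,
    symmetry: bool = True,
) -> List[PoseCluster]:
    """Group redundant conformations (<= threshold RMSD), best score first.

    Greedy: poses are visited in best-score order; a pose within
    ``threshold`` of an existing representative joins that representative's
    group, otherwise it founds a new group.  Representatives are the
    returned unique conformations and always carry the best score of their
    group.
    """
    poses = list(poses)
    if not poses:
        return []
    order = _score_order(poses)
    autos = None
    if symmetry:
        _, elems, coords = _heavy(poses[0])
        autos = graph_automorphisms(elems, coords)
    reps: List[int] = []
    members: List[list] = []
    for i in order:
        placed = False
        for r, rep_idx in enumerate(reps):
            if pose_rmsd(
                poses[rep_idx], poses[i], symmetry=symmetry, automorphisms=autos
            ) <= threshold:
                members[r].append(i)
                placed = True
                break
        if not placed:
            reps.append(i)
            members.append([i])
    clusters = []
    for rep_idx, mem in zip(reps, members):
        centroid = np.mean([poses[i].centroid for i in mem], axis=0)
        clusters.append(
            PoseCluster(
                representative=poses[rep_idx],
                members=[poses[i].pose_id for i in mem],
                centroid=centroid,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# centroid clustering (binding-site discovery)
# ---------------------------------------------------------------------------

def cluster_by_centroid(
    poses: Sequence[LigandPose], link_threshold: float = 5.0
) -> List[PoseCluster]:
    """Single-linkage clustering of pose centroids at a distance cutoff.

    Groups unique conformations into putative binding sites; the cluster
    centroid is the mean of member pose centroids.  The returned
    representative is the member with the best engine score when scores are
    present (first member otherwise).
    """
    poses = list(poses)
    if not poses:
        raise ValueError("cluster_by_centroid requires at least one pose")
    centroids = np.array([p.centroid for p in poses])
    if len(poses) == 1:
        assignments = np.array([1])
    else:
        z = linkage(pdist(centroids), method="single")
        assignments = fcluster(z, t=link_threshold, criterion="distance")
    clusters = []
    for lab in sorted(set(assignments)):
        idx = [i for i, a in enumerate(assignments) if a == lab]
        sub = [poses[i] for i in idx]
        try:
            rep = sub[_score_order(sub)[0]]
        except ScoreOrientationError:
            rep = sub[0]
        clusters.append(
            PoseCluster(
                representative=rep,
                members=[p.pose_id for p in sub],
                centroid=centroids[idx].mean(axis=0),
            )
        )
    clusters.sort(key=lambda c: (-c.size, tuple(np.round(c.centroid, 6))))
    return clusters


# ---------------------------------------------------------------------------
# cross-engine consensus
# ---------------------------------------------------------------------------

def consensus(
    pose_sets: Dict[str, Sequence[LigandPose]],
    threshold: float = 2.0,
    symmetry: bool = True,
) -> ConsensusSet:
    """Poses reproduced by every engine within an RMSD threshold.

    A pose is a consensus pose iff each *other* engine contains a pose
    within ``threshold`` RMSD of it.  The union of such poses is returned,
    deduplicated at the same threshold.  Per-engine sets are expected to be
    pre-deduplicated.
    """
    engines = sorted(pose_sets)
    if len(engines) < 2:
        raise ValueError("consensus requires at least two engines")
    if any(len(pose_sets[e]) == 0 for e in engines):
        warnings.warn("an engine contributed no poses; consensus is empty")
        return ConsensusSet(poses=[], support={}, threshold=threshold)

    all_poses = [p for e in engines for p in pose_sets[e]]
    autos = None
    if symmetry:
        _, elems, coords = _heavy(all_poses[0])
        autos = graph_automorphisms(elems, coords)

    def matched(pose, engine):
        best, best_id = np.inf, None
        for q in pose_sets[engine]:
            r = pose_rmsd(pose, q, symmetry=symmetry, automorphisms=autos)
            if r < best:
                best, best_id = r, q.pose_id
        return (best_id, best) if best <= threshold else (None, best)

    supported = []
    support: dict = {}
    for engine in engines:
        for pose in pose_sets[engine]:
            sup = {engine: pose.pose_id}
            ok = True
            for other in engines:
                if other == engine:
                    continue
                mid, _ = matched(pose, other)
                if mid is None:
                    ok = False
                    break
                sup[other] = mid
            if ok:
                supported.append(pose)
                support[pose.pose_id] = sup

    # deduplicate the union at the same threshold, deterministically by id
    supported.sort(key=lambda p: p.pose_id)
    kept: list = []
    for pose in supported:
        if all(
            pose_rmsd(k, pose, symmetry=symmetry, automorphisms=autos) > threshold
            for k in kept
        ):
            kept.append(pose)
    support = {p.pose_id: support[p.pose_id] for p in kept}
    return ConsensusSet(poses=kept, support=support, threshold=threshold)
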