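"""Rigid-domain decomposition (motion tree) and domain rotation analysis.

Given two conformations of the same protein, the *difference distance
matrix* D_ij = |d_ij(A) - d_ij(B)| over Calpha pairs measures how much the
internal geometry between residues i and j changes.  Residues moving as
one rigid body have near-zero mutual entries; hierarchical (average
linkage) clustering of D therefore produces a *motion tree* whose
low-height subtrees are rigid structural units, and a height cut of the
tree yields the rigid domains.

``domain_rotation`` quantifies the motion of one (user-specified) domain
relative to a reference domain between two structures: after superposing
on the reference domain, the residual transform of the mobile domain is
decomposed into a screw motion (rotation angle and axis, a point on the
axis, and the translation along it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .geometry import apply_transform, superpose
from .structure import SelectionError, Structure, matched_coords

__all__ = [
    "DifferenceDistanceMatrix",
    "MotionTree",
    "motion_tree",
    "DomainRotation",
    "domain_rotation",
]


@dataclass
class DifferenceDistanceMatrix:
    """|d_ij(A) - d_ij(B)| over matched Calpha pairs, in Angstrom."""

    labels: List[str]
    matrix: np.ndarray

    @classmethod
    def from_structures(cls, a: Structure, b: Structure, selection: str = "name CA"):
        ca, cb = matched_coords(a, b, selection)
        keys = a.select(selection).atom_keys()
        labels = [f"{c}:{r}" for c, r, _ in keys]
        D = np.abs(squareform(pdist(ca)) - squareform(pdist(cb)))
        np.fill_diagonal(D, 0.0)
        return cls(labels=labels, matrix=D)


@dataclass
class MotionTree:
    """Binary merge tree over residues; heights in Angstrom.

    ``linkage_matrix`` follows the scipy convention; ``labels`` name the
    leaves (residues).  Rigid domains are read off by cutting the tree at
    a height threshold.
    """

    linkage_matrix: np.ndarray
    labels: List[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def rigid_domains(self, threshold: float = 2.0, min_size: int = 30) -> List[List[int]]:
        """Partition of leaf indices into rigid domains at ``threshold`` A.

        Clusters smaller than ``min_size`` are merged into the large
        cluster with the lowest mean difference-distance to them (so the
        result is always a partition into domains of >= min_size residues,
        unless no cluster reaches min_size, in which case the raw cut is
        returned).  A final consistency sweep reassigns each residue to
        the domain with the smallest mean difference-distance: single
        atom pairs whose mutual distance is accidentally conserved across
        the two conformations would otherwise seed spurious cross-domain
        merges at near-zero height.
        """
        labels = fcluster(self.linkage_matrix, t=threshold, criterion="distance")
        groups = [np.where(labels == c)[0] for c in np.unique(labels)]
        large = [g for g in groups if len(g) >= min_size]
        small = [g for g in groups if len(g) < min_size]
        if not large:
            return [sorted(g.tolist()) for g in groups]
        D = self._leaf_distance_matrix()
        out = [list(g) for g in large]
        for g in small:
            means = [D[np.ix_(g, np.array(h))].mean() for h in out]
            out[int(np.argmin(means))].extend(g.tolist())

        # membership refinement
        assign = np.empty(self.n_leaves, dtype=int)
        for lab, g in enumerate(out):
            assign[np.asarray(g, dtype=int)] = lab
        for _ in range(20):
            changed = False
            for i in range(self.n_leaves):
                means = []
                for lab in range(len(out)):
                    members = np.where(assign == lab)[0]
                    members = members[members != i]
                    means.append(D[i, members].mean() if len(members) else np.inf)
                best = int(np.argmin(means))
                if best != assign[i] and np.sum(assign == assign[i]) > 1:
                    assign[i] = best
                    changed = True
            if not changed:
                break
        return [sorted(np.where(assign == lab)[0].tolist()) for lab in range(len(out))]

    def _leaf_distance_matrix(self) -> np.ndarray:
        if not hasattr(self, "_D"):
            raise RuntimeError("leaf distance matrix not attached")
        return self._D

    def to_json(self) -> str:
        """Nested-node JSON (children, height, member residues)."""

        n = self.n_leaves

        def node(idx: int):
            if idx < n:
                return {"height": 0.0, "members": [self.labels[idx]]}
            row = self.linkage_matrix[idx - n]
            left, right = node(int(row[0])), node(int(row[1]))
            return {
                "height": float(row[2]),
                "children": [left, right],
                "members": left["members"] + right["members"],
            }

        return json.dumps(node(n + len(self.linkage_matrix) - 1), indent=1)


def motion_tree(a: Structure, b: Structure, selection: str = "name CA") -> MotionTree:
    """Build the motion tree of two conformations.

    Average-linkage agglomerative clustering of the Calpha difference
    distance matrix: at each step the two clusters with the smallest mean
    inter-cluster |delta d| merge, and the node height is that mean.
    Average-linkage merge heights are monotone non-decreasing toward the
    root.
    """
    ddm = DifferenceDistanceMatrix.from_structures(a, b, selection)
    n = len(ddm.labels)
    if n < 10:
        raise SelectionError(f"need >= 10 matched residues for a motion tree, got {n}")
    Z = linkage(squareform(ddm.matrix, checks=False), method="average")
    tree = MotionTree(linkage_matrix=Z, labels=ddm.labels)
    tree._D = ddm.matrix  # used when re-attaching small clusters
    return tree


@dataclass
class DomainRotation:
    """Screw decomposition of a domain motion.

    Convention: the rotation is represented by its rotation vector, giving
    a unique axis with angle in [0, 180); the translation along the axis
    is reported signed.  For near-zero angles the axis direction is
    numerically meaningless and ``axis_defined`` is False.
    """

    angle: float                        # degrees
    axis: Optional[np.ndarray]          # unit 3-vector, None if undefined
    screw_point: Optional[np.ndarray]   # point on the axis, Angstrom
    translation_along_axis: float       # Angstrom, signed
    axis_defined: bool = True
    rmsd_ref: float = 0.0               # post-fit RMSD of the reference domain
    rmsd_mobile: float = 0.0            # post-fit RMSD of the mobile domain


def domain_rotation(
    a: Structure,
    b: Structure,
    ref_selection: str,
    mobile_selection: str,
    min_angle: float = 0.1,
) -> DomainRotation:
    """Rotation of the mobile domain relative to the reference domain.

    ``b`` is first superposed onto ``a`` using ``ref_selection``; the
    least-squares rigid transform mapping the superposed mobile domain of
    ``b`` onto that of ``a`` is then decomposed into angle, axis, a point
    on the screw axis (minimum-norm solution of (I - R) p = t_perp) and
    the translation component along the axis.
    """
    ref_a, ref_b = matched_coords(a, b, ref_selection)
    mob_a, mob_b = matched_coords(a, b, mobile_selection)

    R0, t0, rmsd_ref = superpose(ref_b, ref_a)
    mob_b_fit = apply_transform(mob_b, R0, t0)
    # transform describing the mobile domain's motion from A to B
    # (reference-domain motion removed): x_B = R x_A + t
    R, t, rmsd_mob = superpose(mob_a, mob_b_fit)

    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < min_angle:
        return DomainRotation(
            angle=angle, axis=None, screw_point=None,
            translation_along_axis=float(np.linalg.norm(t)),
            axis_defined=False, rmsd_ref=rmsd_ref, rmsd_mobile=rmsd_mob,
        )
    axis = rotvec / np.linalg.norm(rotvec)
    t_par = float(np.dot(t, axis))
    t_perp = t - t_par * axis
    # minimum-norm point on the screw axis
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    p = p - np.dot(p, axis) * axis  # remove the null-space (axis) component
    return DomainRotation(
        angle=angle, axis=axis, screw_point=p,
        translation_along_axis=t_par, axis_defined=True,
        rmsd_ref=rmsd_ref, rmsd_mobile=rmsd_mob,
    )
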