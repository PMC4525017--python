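"""BOX-fingerprint relatedness survey: similarity, grouping, dereplication.

Gel lanes enter as densitometric intensity curves.  Curves are resampled
to a common length and min-max scaled, compared with the Pearson
product-moment correlation expressed as a similarity percentage (r x 100,
GelCompar style), clustered agglomeratively with complete linkage on
distance = 100 - similarity, and cut at a similarity limit (70% by
default).  Complete linkage makes the cut a hard guarantee: every pair
inside a group meets the limit.  Dereplication keeps one representative
per (group, habitat) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FingerprintProfile",
    "SimilarityMatrix",
    "GroupAssignment",
    "DereplicationResult",
    "normalize_curve",
    "normalize_profile",
    "pearson_similarity",
    "similarity_matrix",
    "complete_linkage_groups",
    "dereplicate",
    "read_fingerprint_csv",
    "DEFAULT_SIMILARITY_LIMIT",
    "DEFAULT_CURVE_LENGTH",
]

#: similarity limit (%) defining distinct fingerprint groups
DEFAULT_SIMILARITY_LIMIT = 70.0
DEFAULT_CURVE_LENGTH = 256


@dataclass(frozen=True)
class FingerprintProfile:
    """One gel lane: a strain's densitometric curve plus its habitat."""

    strain_id: str
    habitat_id: str
    curve: np.ndarray

    def __post_init__(self) -> None:
        curve = np.asarray(self.curve, dtype=float)
        object.__setattr__(self, "curve", curve)
        if curve.ndim != 1 or curve.size < 2:
            raise ValueError("curve must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(curve)):
            raise ValueError("curve must contain finite values")
        if np.any(curve < 0):
            raise ValueError("intensities must be nonnegative")


def normalize_curve(raw: np.ndarray, target_length: int = DEFAULT_CURVE_LENGTH) -> tuple[np.ndarray, bool]:
    """Linearly resample to *target_length* and min-max scale to [0, 1].

    Returns (curve, constant_flag); a constant curve is resampled but left
    unscaled (flagged) because min-max scaling is undefined for it.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("raw curve must be a 1-D vector of length >= 2")
    x_new = np.linspace(0.0, raw.size - 1.0, target_length)
    resampled = np.interp(x_new, np.arange(raw.size), raw)
    lo, hi = resampled.min(), resampled.max()
    if hi - lo == 0:
        return resampled, True
    return (resampled - lo) / (hi - lo), False


def normalize_profile(profile: FingerprintProfile, target_length: int = DEFAULT_CURVE_LENGTH) -> FingerprintProfile:
    curve, _constant = normalize_curve(profile.curve, target_length)
    return FingerprintProfile(profile.strain_id, profile.habitat_id, curve)


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation as a percentage (r x 100)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant curve")
    r = float(np.corrcoef(a, b)[0, 1])
    return 100.0 * r


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric percent-similarity matrix with an exact 100 diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < -100.0 - 1e-9 or v.max() > 100.0 + 1e-9:
            raise ValueError("similarities must lie in [-100, 100]")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def similarity_matrix(profiles: Sequence[FingerprintProfile], target_length: int = DEFAULT_CURVE_LENGTH) -> SimilarityMatrix:
    """Normalize all profiles and compute the full pairwise matrix."""
    curves = np.vstack([normalize_curve(p.curve, target_length)[0] for p in profiles])
    if np.any(np.ptp(curves, axis=1) == 0):
        raise ValueError("constant curve: similarity undefined")
    r = np.corrcoef(curves)
    values = 100.0 * r
    np.fill_diagonal(values, 100.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(tuple(p.strain_id for p in profiles), values)


@dataclass(frozen=True)
class GroupAssignment:
    """Flat grouping of strains at a similarity threshold."""

    groups: Mapping[str, str]  # strain_id -> group id
    threshold: float
    n_groups: int
    n_singletons: int
    linkage: np.ndarray
    ids: tuple[str, ...]

    def members(self, group_id: str) -> list[str]:
        return sorted(s for s, g in self.groups.items() if g == group_id)

    def group_ids(self) -> list[str]:
        return sorted(set(self.groups.values()))


def complete_linkage_groups(sim: SimilarityMatrix, threshold: float = DEFAULT_SIMILARITY_LIMIT) -> GroupAssignment:
    """Cut a complete-linkage dendrogram at the similarity limit.

    Merging happens on distance = 100 - similarity; the tree is cut at
    distance 100 - threshold, which with complete linkage guarantees every
    within-group pairwise similarity >= threshold.  Group ids are ordered
    by decreasing size, ties by smallest member id.
    """
    n = len(sim.ids)
    if n == 1:
        return GroupAssignment({sim.ids[0]: "B001"}, threshold, 1, 1, np.empty((0, 4)), sim.ids)
    dist = 100.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(Z, t=100.0 - threshold, criterion="distance")
    raw_groups: dict[int, list[str]] = {}
    for sid, g in zip(sim.ids, flat):
        raw_groups.setdefault(int(g), []).append(sid)
    ordered = sorted(raw_groups.values(), key=lambda ms: (-len(ms), min(ms)))
    groups = {sid: f"B{i + 1:03d}" for i, ms in enumerate(ordered) for sid in ms}
    n_singletons = sum(1 for ms in ordered if len(ms) == 1)
    return GroupAssignment(groups, threshold, len(ordered), n_singletons, Z, sim.ids)


def dendrogram_newick(assignment: GroupAssignment) -> str:
    """The complete-linkage dendrogram as Newick with height-derived branch lengths."""
    if assignment.linkage.size == 0:
        return f"{assignment.ids[0]};"
    tree = hierarchy.to_tree(assignment.linkage)
    ids = assignment.ids

    def rec(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = node.get_left(), node.get_right()
        return "({}:{:.6g},{}:{:.6g})".format(
            rec(left), node.dist - left.dist, rec(right), node.dist - right.dist
        )

    return rec(tree) + ";"


@dataclass(frozen=True)
class DereplicationResult:
    representatives: tuple[str, ...]
    replicate_of: Mapping[str, str]  # replicate strain -> its representative


def dereplicate(profiles: Sequence[FingerprintProfile], assignment: GroupAssignment) -> DereplicationResult:
    """One representative per (group, habitat) pair.

    Strains sharing a fingerprint group *and* a habitat are treated as
    re-isolates of one organism; the lexicographically smallest strain id
    represents each such set.
    """
    habitat = {p.strain_id: p.habitat_id for p in profiles}
    missing = set(assignment.groups) - set(habitat)
    if missing:
        raise ValueError(f"profiles missing for strains: {sorted(missing)[:3]}")
    cells: dict[tuple[str, str], list[str]] = {}
    for sid, gid in assignment.groups.items():
        cells.setdefault((gid, habitat[sid]), []).append(sid)
    reps: list[str] = []
    replicate_of: dict[str, str] = {}
    for members in cells.values():
        members.sort()
        reps.append(members[0])
        for other in members[1:]:
            replicate_of[other] = members[0]
    return DereplicationResult(tuple(sorted(reps)), replicate_of)


def read_fingerprint_csv(path, habitats: Mapping[str, str] | None = None) -> list[FingerprintProfile]:
    """CSV with one lane per column, header row = strain ids."""
    import pandas as pd

    df = pd.read_csv(path)
    habitats = habitats or {}
    return [
        FingerprintProfile(str(col), habitats.get(str(col), "unknown"), df[col].to_numpy(dtype=float))
        for col in df.columns
    ]


def write_groups_tsv(assignment: GroupAssignment, derep: DereplicationResult | None, path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tgroup\trepresentative\n")
        reps = set(derep.representatives) if derep else set()
        for sid in sorted(assignment.groups):
            flag = ("yes" if sid in reps else "no") if derep else "."
            fh.write(f"{sid}\t{assignment.groups[sid]}\t{flag}\n")
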