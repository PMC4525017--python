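"""Distance-based placement of hemA fragments into metabolite-type branches.

Screened 519-bp hemA fragments are compared against a labelled reference
panel whose branches correspond to the C5N metabolite classes of known
type producers (manumycin, colabomycin, annimycin/ECO-02301,
reductiomycin, the two moenomycin subgroups, bafilomycin, the unassigned
orange and brown branches, and the two horizontally transferred blue
branches).  Assignment is k-nearest-neighbour majority vote on nucleotide
distance, with support estimated by bootstrap resampling of alignment
columns.  A neighbor-joining tree over panel + queries is produced for
reporting; the assignment never depends on the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skbio.tree import TreeNode

__all__ = [
    "PanelEntry",
    "ReferencePanel",
    "DistanceMatrix",
    "BranchAssignment",
    "pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "assign_branch",
    "BRANCH_LABELS",
]

BRANCH_LABELS = (
    "manumycin",
    "colabomycin",
    "annimycin_ECO",
    "reductiomycin",
    "moenomycin_I",
    "moenomycin_II_L155175",
    "bafilomycin",
    "orange",
    "brown",
    "blue_I",
    "blue_II",
)


@dataclass(frozen=True)
class PanelEntry:
    id: str
    fragment: str  # aligned nucleotide fragment (gaps allowed)
    branch_label: str

    def __post_init__(self) -> None:
        if self.branch_label not in BRANCH_LABELS:
            raise ValueError(f"unknown branch label {self.branch_label!r}")


@dataclass(frozen=True)
class ReferencePanel:
    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        lengths = {len(e.fragment) for e in self.entries}
        if len(lengths) > 1:
            raise ValueError("all panel fragments must have equal (aligned) length")
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.branch_label] = counts.get(e.branch_label, 0) + 1
        thin = [b for b, k in counts.items() if k < 2]
        if thin:
            raise ValueError(f"branches need >= 2 reference entries for support: {sorted(thin)}")

    @property
    def fragment_length(self) -> int:
        return len(self.entries[0].fragment)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.id} branch={e.branch_label}\n{e.fragment}\n")


def _encode(fragment: str) -> np.ndarray:
    """0-4 codes; 4 marks a column excluded from comparison (gap or N)."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(fragment.upper().encode("ascii"), dtype=np.uint8)]


def pairwise_distance(a: str, b: str, model: Literal["p_distance", "jc69"] = "p_distance") -> float:
    """Distance between two aligned fragments.

    Columns where either sequence has a gap or N are excluded.  p-distance
    is the mismatch fraction over compared columns; JC69 corrects it as
    -(3/4) ln(1 - 4p/3), undefined (error) at p >= 3/4.
    """
    if len(a) != len(b):
        raise ValueError("fragments must have equal aligned length")
    ea, eb = _encode(a), _encode(b)
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable columns")
    p = float(np.sum((ea != eb) & valid)) / n
    if model == "p_distance":
        return p
    if model == "jc69":
        if p >= 0.75:
            raise ValueError(f"JC69 distance saturates at p >= 0.75 (p = {p:.3f})")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "p_distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if v.min() < 0:
            raise ValueError("distances must be nonnegative")


def distance_matrix(ids: Sequence[str], fragments: Sequence[str], model: str = "p_distance") -> DistanceMatrix:
    n = len(ids)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = pairwise_distance(fragments[i], fragments[j], model)
    return DistanceMatrix(tuple(ids), v, model)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining agglomeration to an unrooted tree.

    Negative branch lengths produced by the NJ formulas are clamped to
    zero with the deficit moved to the sister edge, preserving the path
    length between the joined pair.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k not in (i, j):
                new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, length in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(length, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


@dataclass(frozen=True)
class BranchAssignment:
    query_id: str
    branch_label: str
    mean_distance: float  # mean model distance to the k nearest references
    support: float  # fraction of bootstrap replicates agreeing

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must lie in [0, 1]")


def _knn_label(dists: np.ndarray, labels: Sequence[str], k: int) -> tuple[str, float]:
    """Majority label among the k nearest; ties break toward the label with
    the smaller mean vote distance, then lexicographically.  Returns the
    winning label and the mean distance over all k neighbours."""
    order = np.lexsort((np.arange(len(dists)), dists))[:k]
    votes: dict[str, list[float]] = {}
    for idx in order:
        votes.setdefault(labels[idx], []).append(float(dists[idx]))
    best = sorted(
        votes.items(), key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0])
    )[0]
    return best[0], float(np.mean(dists[order]))


def assign_branch(
    query_id: str,
    query_fragment: str,
    panel: ReferencePanel,
    k: int = 3,
    bootstrap_B: int = 100,
    seed: int = 0,
    model: Literal["p_distance", "jc69"] = "p_distance",
) -> BranchAssignment:
    """Place a query fragment: majority branch among its k nearest panel
    references; ties break toward the smaller mean distance, then
    lexicographically.  Support is the fraction of *bootstrap_B* column
    resamples reproducing the point label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(panel.entries) < k:
        raise ValueError("panel has fewer than k references")
    if len(query_fragment) != panel.fragment_length:
        query_fragment = _project_to_panel(query_fragment, panel)
    labels = [e.branch_label for e in panel.entries]
    eq = _encode(query_fragment)
    enc = np.vstack([_encode(e.fragment) for e in panel.entries])
    valid = (enc < 4) & (eq[None, :] < 4)
    mism = (enc != eq[None, :]) & valid

    def dists(cols: np.ndarray | slice) -> np.ndarray:
        v = valid[:, cols].sum(axis=1)
        m = mism[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(v > 0, m / np.maximum(v, 1), 1.0)
        if model == "jc69":
            p = np.where(p < 0.7499, -0.75 * np.log(1.0 - 4.0 * np.minimum(p, 0.7499) / 3.0), 10.0)
        return p

    label, mean_d = _knn_label(dists(slice(None)), labels, k)
    rng = np.random.default_rng([abs(int(seed)), 40_009])
    L = panel.fragment_length
    agree = 0
    for _ in range(bootstrap_B):
        cols = rng.integers(0, L, L)
        b_label, _ = _knn_label(dists(cols), labels, k)
        agree += b_label == label
    support = agree / bootstrap_B if bootstrap_B else 1.0
    return BranchAssignment(query_id, label, mean_d, support)


def _project_to_panel(query: str, panel: ReferencePanel) -> str:
    """Map a query of different length onto panel coordinates by global
    nucleotide alignment (match +1, mismatch -1, gap -2, free end gaps)
    against the first panel fragment."""
    from Bio import Align

    ref = panel.entries[0].fragment.replace("-", "")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_gap_score = 0
    alignment = aligner.align(ref, query.upper())[0]
    ref_blocks, query_blocks = alignment.aligned
    out = ["-"] * len(ref)
    for (rs, re), (qs, _qe) in zip(ref_blocks, query_blocks):
        for off in range(re - rs):
            out[rs + off] = query[qs + off]
    # panel fragments may themselves contain gap columns; re-expand
    cols = [i for i, b in enumerate(panel.entries[0].fragment) if b != "-"]
    projected = ["-"] * panel.fragment_length
    for ref_idx, col in enumerate(cols):
        projected[col] = out[ref_idx]
    return "".join(projected)


def write_assignments_tsv(assignments: Sequence[BranchAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tbranch\tmean_distance\tsupport\n")
        for a in assignments:
            fh.write(f"{a.query_id}\t{a.branch_label}\t{a.mean_distance:.6f}\t{a.support:.3f}\n")
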