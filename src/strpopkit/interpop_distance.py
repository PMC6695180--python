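"""Inter-population comparison from allele-frequency tables.

Populations typed on partially overlapping STR panels are first aligned
to their common loci (allele unions zero-filled), then compared by:

* pairwise fixation index — Nei's GST, per locus (Ht - Hs)/Ht with Ht
  from the mean frequency vector, combined across loci by Ht weighting;
  or the Weir-Cockerham variance-components estimator theta (needs
  sample sizes; heterozygosities taken at their HWE expectation since
  published tables carry frequencies only), loci combined by summing
  components;
* Nei's genetic distances — standard Ds = -ln(Jxy / sqrt(Jx Jy)) with
  the identity sums accumulated over loci, and DA = 1 - mean_l sum_i
  sqrt(x_i y_i);
* neighbor-joining (Saitou-Nei) tree construction with deterministic
  lowest-index tie-breaking and Newick serialization;
* Kruskal nonmetric MDS: Torgerson initialization, primary-approach
  isotonic disparities (pool-adjacent-violators), Guttman-transform
  iterations minimizing stress-1.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .str_data import FrequencyTable, StrAllele, StrDataError

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "Ordination",
    "AlignedFrequencies",
    "align_loci",
    "pairwise_fst",
    "nei_distance",
    "neighbor_joining",
    "to_newick",
    "from_newick",
    "tree_distance_matrix",
    "nmds",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative population distances with labels."""

    labels: list[str]
    matrix: np.ndarray
    estimator: str = ""
    loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(m)).max() > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if (m < 0).any():
            logger.info(
                "clamping %d negative %s distances to 0",
                int((m < 0).sum()), self.estimator,
            )
            m = np.maximum(m, 0.0)
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    def submatrix_value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class AlignedFrequencies:
    """Populations restricted to common loci, allele unions zero-filled.

    ``vectors[p][l]`` is population p's frequency vector at locus l over
    the shared allele list ``alleles[l]``.
    """

    labels: list[str]
    loci: list[str]
    alleles: dict[str, list[StrAllele]]
    vectors: list[dict[str, np.ndarray]]


def align_loci(tables: Sequence[FrequencyTable]) -> AlignedFrequencies:
    """Restrict frequency tables to their locus intersection.

    Locus order follows the first table; per-locus allele lists are the
    union across populations, zero-filled where a population lacks an
    allele.
    """
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    common = [
        locus for locus in tables[0].loci
        if all(locus in t.frequencies for t in tables)
    ]
    if not common:
        raise StrDataError("no loci shared by all populations")
    alleles = {
        locus: sorted(
            {a for t in tables for a in t.frequencies[locus]},
            key=StrAllele.sort_key,
        )
        for locus in common
    }
    labels = []
    vectors = []
    for i, t in enumerate(tables):
        labels.append(t.population_label or f"pop{i+1}")
        vecs = {}
        for locus in common:
            d = t.frequencies[locus]
            vecs[locus] = np.array([d.get(a, 0.0) for a in alleles[locus]])
        vectors.append(vecs)
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i+1}" for i, lab in enumerate(labels)]
    return AlignedFrequencies(labels, common, alleles, vectors)


def _as_aligned(tables) -> AlignedFrequencies:
    if isinstance(tables, AlignedFrequencies):
        return tables
    return align_loci(tables)


# ---------------------------------------------------------------------------
# FST


def _nei_gst_pair(px: dict[str, np.ndarray], py: dict[str, np.ndarray],
                  loci: Sequence[str]) -> float:
    ht_sum = 0.0
    num_sum = 0.0
    for locus in loci:
        x, y = px[locus], py[locus]
        hs = 1.0 - 0.5 * ((x * x).sum() + (y * y).sum())
        pbar = 0.5 * (x + y)
        ht = 1.0 - (pbar * pbar).sum()
        ht_sum += ht
        num_sum += ht - hs
    if ht_sum <= 0:
        raise StrDataError("populations monomorphic at every shared locus; FST undefined")
    return num_sum / ht_sum


def _wc_theta_pair(px, py, nx: int, ny: int, loci: Sequence[str]) -> float:
    """Weir-Cockerham theta for two populations from frequencies.

    Observed heterozygosities are taken at their HWE expectation
    2 p (1 - p), the only option when genotype data are unavailable.
    """
    r = 2
    a_sum = b_sum = c_sum = 0.0
    ns = np.array([nx, ny], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
    for locus in loci:
        for x_i, y_i in zip(px[locus], py[locus]):
            p = np.array([x_i, y_i])
            pbar = (ns * p).sum() / (r * nbar)
            s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * 2 * p * (1 - p)).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            a_sum += a
            b_sum += b
            c_sum += c
    denom = a_sum + b_sum + c_sum
    if denom == 0:
        raise StrDataError("populations monomorphic at every shared locus; FST undefined")
    return a_sum / denom


def pairwise_fst(
    tables,
    sample_sizes: Sequence[int] | None = None,
    estimator: str = "nei_gst",
) -> DistanceMatrix:
    """Pairwise FST matrix between populations.

    ``estimator`` is ``"nei_gst"`` (frequency-only) or
    ``"weir_cockerham"`` (requires per-population diploid sample sizes).
    Small negative estimates are clamped to zero.
    """
    al = _as_aligned(tables)
    n = len(al.labels)
    if estimator == "weir_cockerham":
        if sample_sizes is None or len(sample_sizes) != n:
            raise ValueError("weir_cockerham needs one sample size per population")
    elif estimator != "nei_gst":
        raise ValueError(f"unknown estimator {estimator!r}")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if estimator == "nei_gst":
                v = _nei_gst_pair(al.vectors[i], al.vectors[j], al.loci)
            else:
                v = _wc_theta_pair(
                    al.vectors[i], al.vectors[j],
                    sample_sizes[i], sample_sizes[j], al.loci,
                )
            m[i, j] = m[j, i] = v
    return DistanceMatrix(list(al.labels), m, estimator, tuple(al.loci))


# ---------------------------------------------------------------------------
# Nei genetic distances


def nei_distance(tables, variant: str = "standard_ds") -> DistanceMatrix:
    """Nei genetic distance matrix.

    ``standard_ds``: Ds = -ln( Jxy / sqrt(Jx Jy) ) with J terms summed
    over loci and alleles. ``da``: DA = 1 - (1/L) sum_l sum_i
    sqrt(x_i y_i). Pairs sharing no alleles anywhere have infinite Ds;
    these are reported as twice the largest finite entry (flagged in the
    metadata via the estimator name) rather than propagating inf.
    """
    if variant not in ("standard_ds", "da"):
        raise ValueError(f"unknown variant {variant!r}")
    al = _as_aligned(tables)
    n = len(al.labels)
    m = np.zeros((n, n))
    flagged = False
    for i in range(n):
        for j in range(i + 1, n):
            x, y = al.vectors[i], al.vectors[j]
            if variant == "standard_ds":
                jx = sum(float((x[l] ** 2).sum()) for l in al.loci)
                jy = sum(float((y[l] ** 2).sum()) for l in al.loci)
                jxy = sum(float((x[l] * y[l]).sum()) for l in al.loci)
                if jxy <= 0:
                    m[i, j] = m[j, i] = math.inf
                    flagged = True
                else:
                    d = -math.log(jxy / math.sqrt(jx * jy))
                    m[i, j] = m[j, i] = max(d, 0.0)
            else:
                s = np.mean(
                    [float(np.sqrt(x[l] * y[l]).sum()) for l in al.loci]
                )
                m[i, j] = m[j, i] = 1.0 - min(s, 1.0)
    name = variant
    if flagged:
        finite = m[np.isfinite(m)]
        cap = 2.0 * float(finite.max()) if finite.size and finite.max() > 0 else 1.0
        m[~np.isfinite(m)] = cap
        name += "+capped_infinite"
        logger.warning("no shared alleles for some pairs; Ds capped at %.4f", cap)
    return DistanceMatrix(list(al.labels), m, name, tuple(al.loci))


# ---------------------------------------------------------------------------
# neighbor-joining and Newick


@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree, stored rooted at an internal trifurcation."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor-joining from a distance matrix.

    Ties in the Q criterion break on the lowest (i, j) index pair.
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling edge, preserving the pair's path length.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 populations")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    dist = d.matrix.astype(float).copy()
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
        r = len(active)
        sub = dist[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (r - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest flat index wins ties -> lowest (i, j) pair
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = dist[i, j]
        li = 0.5 * dij + (totals[i_s] - totals[j_s]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        dnew = 0.5 * (dist[i, :] + dist[j, :] - dij)
        k = len(nodes)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[k, :k] = dnew
        dist[:k, k] = dnew
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    # three-point formulas
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    root = TreeNode(children=[
        (nodes[i], max(li, 0.0)),
        (nodes[j], max(lj, 0.0)),
        (nodes[k], max(lk, 0.0)),
    ])
    return Tree(root)


_UNQUOTED_OK = re.compile(r"^[A-Za-z0-9_.\-|]+$")


def _newick_label(name: str) -> str:
    if _UNQUOTED_OK.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(t: Tree, decimals: int = 9) -> str:
    """Serialize a tree as Newick with branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.name)
        inner = ",".join(
            f"{render(child)}:{length:.{decimals}g}" for child, length in node.children
        )
        return f"({inner})" + (_newick_label(node.name) if node.name else "")

    return render(t.root) + ";"


def from_newick(text: str) -> Tree:
    """Parse a Newick string (labels, quoted labels, branch lengths)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise ValueError("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        return s[start:pos]

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child, length = parse_node()
                node.children.append((child, length))
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        node.name = parse_label()
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            length = float(s[start:pos])
        return node, length

    root, _ = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing Newick content at position {pos}")
    return Tree(root)


def tree_distance_matrix(t: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (the additive metric it encodes)."""
    leaves = t.leaf_names()
    idx = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    m = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[int, float]:
        """Distances from every leaf under ``node`` up to ``node``."""
        if node.is_leaf:
            return {idx[node.name]: 0.0}
        below: dict[int, float] = {}
        child_maps = []
        for child, length in node.children:
            cm = {leaf: dist + length for leaf, dist in walk(child).items()}
            child_maps.append(cm)
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for la, da in child_maps[a].items():
                    for lb, db in child_maps[b].items():
                        m[la, lb] = m[lb, la] = da + db
        for cm in child_maps:
            below.update(cm)
        return below

    walk(t.root)
    return DistanceMatrix(leaves, m, "tree_path_length")


# ---------------------------------------------------------------------------
# nonmetric MDS


@dataclass
class Ordination:
    """NMDS result: configuration, Kruskal stress-1 and fit diagnostics."""

    labels: list[str]
    coordinates: np.ndarray   # (n, k)
    stress: float             # Kruskal stress-1
    rsq: float                # squared correlation of disparities vs distances
    n_iter: int
    stress_history: list[float]
    converged: bool


def _torgerson(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def configuration_stress(d: DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an arbitrary configuration against a dissimilarity matrix."""
    delta = squareform(d.matrix, checks=False)
    dist = pdist(coords)
    dhat = _disparities(delta, dist)
    return _stress1(dist, dhat)


def _disparities(delta: np.ndarray, dist: np.ndarray) -> np.ndarray:
    # primary approach to ties: within tied delta blocks, order by current
    # distance so tied dissimilarities impose no constraint on each other
    order = np.lexsort((dist, delta))
    fit = isotonic_regression(dist[order]).x
    dhat = np.empty_like(dist)
    dhat[order] = fit
    return dhat


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((dist ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dist - dhat) ** 2).sum()) / denom)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> Ordination:
    """Kruskal nonmetric MDS of a distance matrix into k dimensions.

    Torgerson (classical scaling) initialization, isotonic
    (pool-adjacent-violators) disparities with primary tie handling, and
    Guttman-transform updates; iteration stops when stress-1 improves by
    less than ``tol``. Stress is non-increasing across the reported
    history and the best configuration is returned.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("NMDS needs at least 3 populations")
    if not 1 <= k < n:
        raise ValueError(f"embedding dimension must be in [1, {n-1}), got {k}")
    delta = squareform(d.matrix, checks=False)
    x = _torgerson(d.matrix, k)
    if not np.isfinite(x).all() or np.allclose(x, 0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, k))

    history: list[float] = []
    best_x = x
    best_stress = math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(x)
        if (dist == 0).all():
            break
        dhat = _disparities(delta, dist)
        stress = _stress1(dist, dhat)
        if stress < best_stress - 1e-15:
            best_stress = stress
            best_x = x.copy()
        if history and history[-1] - stress < tol:
            history.append(min(stress, history[-1]))
            converged = True
            break
        history.append(stress if not history else min(stress, history[-1]))
        if stress <= tol:
            converged = True
            break
        # Guttman transform with unit weights
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        bmat = -squareform(ratio, checks=False)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x = (bmat @ x) / n

    dist = pdist(best_x)
    dhat = _disparities(delta, dist)
    if dist.std() == 0 or dhat.std() == 0:
        rsq = 1.0 if best_stress <= tol else 0.0
    else:
        rsq = float(np.corrcoef(dhat, dist)[0, 1] ** 2)
    return Ordination(
        labels=list(d.labels),
        coordinates=best_x - best_x.mean(axis=0),
        stress=0.0 if best_stress == math.inf else best_stress,
        rsq=rsq,
        n_iter=it,
        stress_history=history,
        converged=converged,
    )
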