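"""Trees, alignments, phylogenetic covariances and nucleotide distances.

The phylogeny enters the comparative analyses in two forms: as the
shared-ancestry covariance matrix (root-to-MRCA path lengths) that PGLS
and the trait-evolution models condition on, and as a pairwise distance
matrix (patristic, or Tamura--Nei model-based when an alignment is
available) used for the economic-distance regressions.

Newick parsing and writing are backed by dendropy; FASTA I/O by
Biopython.  The TN93 distance, its gamma-rate variant, and the
neighbor-joining builder are implemented here.
"""
from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NewickError",
    "Tree",
    "PhyloCovariance",
    "Alignment",
    "DistanceMatrix",
    "TN93Result",
    "parse_newick",
    "write_newick",
    "tree_vcv",
    "patristic_distances",
    "read_fasta",
    "write_fasta",
    "tn93_distance",
    "pairwise_tn93",
    "nj_tree",
    "write_distance_matrix",
    "read_distance_matrix",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate or
    unlabelled tips, negative branch lengths)."""


@dataclass(frozen=True)
class Tree:
    """Rooted tree with branch lengths.

    Nodes are integer indices; ``parent[i]`` is -1 for the root,
    ``lengths[i]`` is the length of the branch above node ``i`` (0 for
    the root).  Tips are the childless nodes; their labels are unique.
    Internal labels (bootstrap/support strings) are stored but unused.
    """

    parent: tuple[int, ...]
    children: tuple[tuple[int, ...], ...]
    lengths: tuple[float, ...]
    labels: tuple[str | None, ...]
    root: int
    arbitrarily_rooted: bool = False

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise NewickError("tree must have at least 2 tips")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_indices(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.tip_indices())  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.lengths[node]
        return d

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children[node]))

    def postorder(self) -> Iterator[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return iter(reversed(out))


@dataclass(frozen=True)
class PhyloCovariance:
    """Shared-ancestry covariance: C_ij = root-to-MRCA(i,j) path length.

    The diagonal holds the root-to-tip depths.  PGLS and the BM/lambda/OU
    likelihoods use this matrix (possibly rescaled) as the expected
    residual covariance structure.
    """

    labels: tuple[str, ...]
    C: np.ndarray
    tip_depths: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def lambda_scaled(self, lam: float) -> np.ndarray:
        """Off-diagonals multiplied by lambda, diagonal unchanged."""
        Cl = lam * self.C
        np.fill_diagonal(Cl, np.diag(self.C))
        return Cl

    def subset(self, labels: Sequence[str]) -> "PhyloCovariance":
        """Restrict to a subset of tips (equals the VCV of the pruned tree,
        since dropping tips does not change root-to-MRCA depths)."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"labels not in covariance: {missing}")
        idx = np.array([pos[lab] for lab in labels])
        return PhyloCovariance(
            labels=tuple(labels),
            C=self.C[np.ix_(idx, idx)],
            tip_depths=self.tip_depths[idx],
        )

    def patristic(self) -> np.ndarray:
        """D_ij = depth_i + depth_j - 2 C_ij."""
        t = self.tip_depths
        return t[:, None] + t[None, :] - 2.0 * self.C


@dataclass(frozen=True)
class Alignment:
    """Aligned nucleotide matrix over {A,C,G,T,-,N} with unique labels."""

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site); entries that
    could not be computed (saturation) are NaN with ``undefined`` True."""

    labels: tuple[str, ...]
    D: np.ndarray
    undefined: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.D[i, j])


# ---------------------------------------------------------------------------
# Newick I/O

def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    index: dict[int, int] = {}
    parents: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    for node in dtree.preorder_node_iter():
        idx = len(parents)
        index[id(node)] = idx
        if node.parent_node is None:
            parents.append(-1)
            lengths.append(0.0)
        else:
            p = index[id(node.parent_node)]
            parents.append(p)
            children[p].append(idx)
            el = node.edge.length
            if el is None:
                el = 0.0
            label = node.taxon.label if node.taxon else node.label
            if el < 0:
                raise NewickError(
                    f"negative branch length {el} on branch above "
                    f"{label or 'an internal node'}"
                )
            lengths.append(float(el))
        children.append([])
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickError("unlabelled tip in Newick input")
            labels.append(node.taxon.label)
        else:
            labels.append(node.taxon.label if node.taxon else node.label)
    tips = [labels[i] for i, ch in enumerate(children) if not ch]
    seen: set[str] = set()
    for lab in tips:
        if lab in seen:
            raise NewickError(f"duplicate tip label {lab!r}")
        seen.add(lab)  # type: ignore[arg-type]
    return Tree(
        parent=tuple(parents),
        children=tuple(tuple(ch) for ch in children),
        lengths=tuple(lengths),
        labels=tuple(labels),
        root=0,
    )


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree string into a :class:`Tree`.

    Internal labels / support values are preserved but never used.
    Raises :class:`NewickError` naming the offending token for
    unbalanced parentheses, duplicate tips or negative branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except NewickError:
        raise
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialise a tree to Newick; branch lengths at 10 significant digits."""

    def render(node: int) -> str:
        ch = tree.children[node]
        if ch:
            inner = ",".join(render(c) for c in ch)
            lab = tree.labels[node]
            body = f"({inner}){_quote_label(lab) if lab else ''}"
        else:
            body = _quote_label(tree.labels[node] or "")
        if node == tree.root:
            return body
        return f"{body}:{tree.lengths[node]:.10g}"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Covariance and patristic distances

def tree_vcv(tree: Tree) -> PhyloCovariance:
    """Shared-path covariance matrix: C_ij = depth of MRCA(i, j)."""
    tips = tree.tip_indices()
    pos = {node: k for k, node in enumerate(tips)}
    depth = tree.depths()
    n = len(tips)
    C = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder():
        ch = tree.children[node]
        if not ch:
            tipsets[node] = [pos[node]]
            continue
        groups = [tipsets.pop(c) for c in ch]
        d = depth[node]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        C[a, b] = C[b, a] = d
        tipsets[node] = [x for g in groups for x in g]
    tip_depths = depth[np.array(tips)]
    C[np.diag_indices(n)] = tip_depths
    labels = tuple(tree.labels[t] for t in tips)
    return PhyloCovariance(labels=labels, C=C, tip_depths=tip_depths)  # type: ignore[arg-type]


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    cov = tree_vcv(tree)
    return DistanceMatrix(labels=cov.labels, D=cov.patristic())


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(source) -> Alignment:
    """Read an aligned FASTA file (path or handle); uppercase, U -> T."""
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        records = list(SeqIO.parse(str(source), "fasta"))
    else:
        records = list(SeqIO.parse(source, "fasta"))
    labels = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper().replace("U", "T") for r in records)
    return Alignment(labels=labels, sequences=seqs)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for lab, s in zip(alignment.labels, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TN93 distance

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(frozen=True)
class TN93Result:
    """A single pairwise TN93 distance with its site bookkeeping.

    ``defined`` is False when the distance is saturated (a logarithm
    argument went non-positive); the distance is then NaN and ``note``
    carries the diagnostic.
    """

    distance: float
    defined: bool
    usable_sites: int
    p1: float  # A<->G difference fraction
    p2: float  # C<->T difference fraction
    q: float   # transversion difference fraction
    note: str = ""


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def tn93_distance(
    seq_a: str,
    seq_b: str,
    *,
    gamma_shape: float | None = None,
    site_mask: np.ndarray | None = None,
) -> TN93Result:
    """Tamura–Nei (1993) pairwise distance between two aligned sequences.

    The model distinguishes the two transition types (A<->G, C<->T) from
    transversions and allows unequal base frequencies, pooled empirically
    over the two sequences.  With difference fractions P1 (A<->G), P2
    (C<->T) and Q (transversions) and pooled frequencies g:

        gR = gA+gG, gY = gC+gT,
        k1 = 2 gA gG / gR,  k2 = 2 gC gT / gY,
        k3 = 2 (gR gY - gA gG gY/gR - gC gT gR/gY),
        d  = -k1 ln(w1) - k2 ln(w2) - k3 ln(w3)

    with w1 = 1 - P1/k1 - Q/(2 gR), w2 = 1 - P2/k2 - Q/(2 gY),
    w3 = 1 - Q/(2 gR gY).  If ``gamma_shape`` a is given (rate variation
    across sites), each term -k ln(w) becomes k a (w^(-1/a) - 1).

    Sites where either sequence has a gap or ambiguity are dropped
    (pairwise deletion); ``site_mask`` restricts to a caller-supplied set
    of columns (used for complete deletion across an alignment).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = _encode(seq_a)
    b = _encode(seq_b)
    usable = (a >= 0) & (b >= 0)
    if site_mask is not None:
        usable &= site_mask
    L = int(usable.sum())
    if L < 1:
        raise ValueError("no usable (ungapped, unambiguous) sites in pair")
    a = a[usable]
    b = b[usable]

    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    g = counts / counts.sum()
    gA, gC, gG, gT = (float(x) for x in g)
    gR, gY = gA + gG, gC + gT

    diff = a != b
    p1 = float(np.mean(diff & (((a == _A) & (b == _G)) | ((a == _G) & (b == _A)))))
    p2 = float(np.mean(diff & (((a == _C) & (b == _T)) | ((a == _T) & (b == _C)))))
    q = float(np.mean(diff)) - p1 - p2

    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = (
        2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        if gR > 0 and gY > 0
        else 0.0
    )

    class _Saturated(Exception):
        def __init__(self, what: str, w: float):
            self.what, self.w = what, w

    def term(k: float, w: float | None, what: str, numerator: float) -> float:
        # k == 0 with no observed differences of this class contributes 0;
        # k == 0 with differences present means a required base is absent.
        if k == 0.0:
            if numerator > 0.0:
                raise ValueError(
                    f"zero pooled frequency for a base required by the "
                    f"{what} term (frequencies A={gA:.4g} C={gC:.4g} "
                    f"G={gG:.4g} T={gT:.4g})"
                )
            return 0.0
        assert w is not None
        if w <= 0.0:
            raise _Saturated(what, w)
        if gamma_shape is not None:
            return k * gamma_shape * (w ** (-1.0 / gamma_shape) - 1.0)
        return -k * math.log(w)

    try:
        terms = 0.0
        for k, w, what, num in (
            (k1, 1.0 - p1 / k1 - q / (2.0 * gR) if k1 > 0 else None, "A<->G transition", p1),
            (k2, 1.0 - p2 / k2 - q / (2.0 * gY) if k2 > 0 else None, "C<->T transition", p2),
            (k3, 1.0 - q / (2.0 * gR * gY) if k3 != 0 else None, "transversion", q),
        ):
            terms += term(k, w, what, num)
    except _Saturated as sat:
        note = (
            f"saturated: log argument {sat.w:.4g} <= 0 in {sat.what} term "
            f"(P1={p1:.4g}, P2={p2:.4g}, Q={q:.4g})"
        )
        return TN93Result(float("nan"), False, L, p1, p2, q, note)
    return TN93Result(float(terms), True, L, p1, p2, q)


def pairwise_tn93(
    alignment: Alignment,
    *,
    deletion: str = "pairwise",
    gamma_shape: float | None = None,
) -> DistanceMatrix:
    """Apply :func:`tn93_distance` to every pair in an alignment.

    ``deletion`` is ``"pairwise"`` (drop bad sites per pair, the default)
    or ``"complete"`` (drop columns with a gap/ambiguity in any sequence).
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    mask = None
    if deletion == "complete":
        codes = np.stack([_encode(s) for s in alignment.sequences])
        mask = np.all(codes >= 0, axis=0)
    n = alignment.n
    D = np.zeros((n, n))
    undef = np.zeros((n, n), dtype=bool)
    n_sat = 0
    for i in range(n):
        for j in range(i + 1, n):
            res = tn93_distance(
                alignment.sequences[i],
                alignment.sequences[j],
                gamma_shape=gamma_shape,
                site_mask=mask,
            )
            D[i, j] = D[j, i] = res.distance
            if not res.defined:
                undef[i, j] = undef[j, i] = True
                n_sat += 1
    if n_sat:
        logger.warning("pairwise_tn93: %d saturated pair(s) flagged NA", n_sat)
    return DistanceMatrix(labels=alignment.labels, D=D, undefined=undef)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a distance matrix (Q-criterion).

    Negative branch lengths are clamped to zero (a warning reports the
    count).  The output is rooted at the final agglomeration point and
    flagged ``arbitrarily_rooted``.
    """
    if dm.undefined is not None and dm.undefined.any():
        bad = [
            (dm.labels[i], dm.labels[j])
            for i, j in zip(*np.nonzero(np.triu(dm.undefined)))
        ]
        raise ValueError(f"undefined distances for pairs: {bad}")
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    parents: list[int] = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    lengths: list[float] = [0.0] * n
    labels: list[str | None] = list(dm.labels)
    n_clamped = 0

    active = list(range(n))  # tree-node id per active cluster
    D = dm.D.astype(float).copy()

    def new_node(kids: list[int], kid_lengths: list[float]) -> int:
        nonlocal n_clamped
        idx = len(parents)
        parents.append(-1)
        children.append([])
        lengths.append(0.0)
        labels.append(None)
        for kid, bl in zip(kids, kid_lengths):
            if bl < 0:
                n_clamped += 1
                bl = 0.0
            parents[kid] = idx
            children[idx].append(kid)
            lengths[kid] = bl
        return idx

    while len(active) > 2:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        node = new_node([active[i], active[j]], [li, lj])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [node]

    # join the last two clusters at an (arbitrary) root splitting the
    # remaining distance equally
    d = D[0, 1]
    root = new_node(active, [d / 2.0, d / 2.0])
    if n_clamped:
        logger.warning("nj_tree: clamped %d negative branch length(s) to 0", n_clamped)

    # reindex so the root is node 0 in preorder (Tree requires no order,
    # but preorder construction keeps parent < child unnecessary; Tree
    # only needs consistent links)
    return Tree(
        parent=tuple(parents),
        children=tuple(tuple(ch) for ch in children),
        lengths=tuple(lengths),
        labels=tuple(labels),
        root=root,
        arbitrarily_rooted=True,
    )


# ---------------------------------------------------------------------------
# Distance-matrix I/O

def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square tab-separated matrix with header row/column; NA for
    flagged-undefined entries."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for i, lab in enumerate(dm.labels):
            cells = []
            for j in range(dm.n):
                if dm.undefined is not None and dm.undefined[i, j]:
                    cells.append("NA")
                else:
                    cells.append(f"{dm.D[i, j]:.10g}")
            fh.write(lab + "\t" + "\t".join(cells) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        undef_rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")[1:]
            undef_rows.append([p == "NA" for p in parts])
            rows.append([float("nan") if p == "NA" else float(p) for p in parts])
    return DistanceMatrix(
        labels=tuple(header),
        D=np.array(rows, dtype=float),
        undefined=np.array(undef_rows, dtype=bool),
    )
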