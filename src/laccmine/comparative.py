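"""Pairwise similarity, distances, and neighbor-joining family trees.

Similarity between laccases is percent identity over compared columns
(columns where neither aligned sequence has a gap) of a Needleman-Wunsch
global alignment under BLOSUM62 with affine gaps. This convention makes
isoform pairs that differ only by short in-frame insertions score 100.0.

Trees are built with the classical Saitou-Nei neighbor-joining
agglomeration from pairwise-deletion p-distances (Poisson correction
optional) on a multiple alignment, with clade support estimated by
bootstrap resampling of alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .errors import NumericalError, ValidationError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5

GAP = "-"


@dataclass(frozen=True)
class AlignmentPair:
    """A global pairwise alignment and its identity summary."""

    ids: tuple[str, str]
    aligned: tuple[str, str]
    identities: int
    compared_columns: int

    def __post_init__(self):
        if len(self.aligned[0]) != len(self.aligned[1]):
            raise ValidationError("aligned rows differ in length")
        if self.identities > self.compared_columns:
            raise ValidationError("identities exceed compared columns")


@dataclass(frozen=True)
class DistanceMatrix:
    names: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValidationError("distance matrix shape does not match names")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite distances")
        if np.any(v < 0) or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix must be symmetric, nonnegative, zero-diagonal")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    ids: tuple[str, str] = ("a", "b"),
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentPair:
    """Needleman-Wunsch global alignment with affine gaps (first optimal traceback)."""
    if not a or not b:
        raise ValidationError("cannot align empty peptides")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    ra, rb = alignment[0], alignment[1]
    identities, compared = _column_identity(ra, rb)
    return AlignmentPair(ids=ids, aligned=(ra, rb), identities=identities, compared_columns=compared)


def alignment_score(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal global alignment score (for oracle comparisons)."""
    return float(_make_aligner(matrix, gap_open, gap_extend).score(a, b))


def _column_identity(ra: str, rb: str) -> tuple[int, int]:
    identities = compared = 0
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x == y:
            identities += 1
    return identities, compared


def percent_similarity(pair: AlignmentPair) -> float:
    """100 * identities / compared columns, reported to 1 decimal."""
    if pair.compared_columns == 0:
        raise NumericalError("no compared columns between " + "/".join(pair.ids))
    return round(100.0 * pair.identities / pair.compared_columns, 1)


def similarity_matrix(named_seqs: Sequence[tuple[str, str]], **align_kw):
    """Symmetric percent-similarity table (pandas DataFrame, diagonal 100.0)."""
    import pandas as pd

    names = [n for n, _ in named_seqs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate sequence names in similarity matrix input")
    n = len(names)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(
                named_seqs[i][1], named_seqs[j][1], ids=(names[i], names[j]), **align_kw
            )
            mat[i, j] = mat[j, i] = percent_similarity(pair)
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# multiple alignment (simple progressive aligner)

def _encode_profile(rows: list[str], alphabet: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    return lut[arr]


def _profile_column_scores(rows_a, rows_b, matrix) -> np.ndarray:
    """Mean substitution score between columns; gap/residue pairs score 0."""
    alphabet = str(matrix.alphabet)
    k = len(alphabet)
    m = np.zeros((k + 1, k + 1))
    m[:k, :k] = np.asarray(matrix)
    ext_alpha = alphabet + GAP
    ea = _encode_profile([r.replace(GAP, ext_alpha[k]) for r in rows_a], ext_alpha)
    eb = _encode_profile([r.replace(GAP, ext_alpha[k]) for r in rows_b], ext_alpha)
    la, lb = ea.shape[1], eb.shape[1]
    S = np.zeros((la, lb))
    for i in range(ea.shape[0]):
        for j in range(eb.shape[0]):
            S += m[ea[i][:, None], eb[j][None, :]]
    return S / (ea.shape[0] * eb.shape[0])


def _align_profiles(prof_a, prof_b, matrix, gap_open, gap_extend):
    """Affine-gap global alignment of two profiles.

    Traceback prefers diagonal, then a gap in the second profile, then a
    gap in the first (deterministic).
    """
    rows_a = [s for _, s in prof_a]
    rows_b = [s for _, s in prof_b]
    S = _profile_column_scores(rows_a, rows_b, matrix)
    la, lb = S.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = S[i - 1, j - 1] + best_prev
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback
    i, j = la, lb
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    cols: list[str] = []
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            cols.append("D")
            prev = max(
                ("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i - 1, j - 1]
            )
            i, j, state = i - 1, j - 1, prev
        elif state == "X" and i > 0:
            cols.append("A")
            state = "M" if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend else "X"
            i -= 1
        elif state == "Y" and j > 0:
            cols.append("B")
            state = "M" if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_extend else "Y"
            j -= 1
        elif i > 0:
            cols.append("A")
            i -= 1
        else:
            cols.append("B")
            j -= 1
    cols.reverse()
    out_a = {name: [] for name, _ in prof_a}
    out_b = {name: [] for name, _ in prof_b}
    ia = ib = 0
    for c in cols:
        if c in ("D", "A"):
            for name, s in prof_a:
                out_a[name].append(s[ia])
            ia += 1
        else:
            for name, _ in prof_a:
                out_a[name].append(GAP)
        if c in ("D", "B"):
            for name, s in prof_b:
                out_b[name].append(s[ib])
            ib += 1
        else:
            for name, _ in prof_b:
                out_b[name].append(GAP)
    merged = [(name, "".join(out_a[name])) for name, _ in prof_a]
    merged += [(name, "".join(out_b[name])) for name, _ in prof_b]
    return merged


def progressive_msa(
    named_seqs: Sequence[tuple[str, str]],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[tuple[str, str]]:
    """Progressive multiple alignment along a UPGMA guide tree.

    Guide distances are pairwise p-distances from global pairwise
    alignments; profiles are merged with affine-gap profile alignment
    using mean column substitution scores.
    """
    names = [n for n, _ in named_seqs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate sequence names")
    n = len(named_seqs)
    if n == 0:
        return []
    if n == 1:
        return list(named_seqs)
    mat = substitution_matrices.load(matrix)
    if n == 2:
        pair = global_align(named_seqs[0][1], named_seqs[1][1],
                            ids=(names[0], names[1]), matrix=matrix,
                            gap_open=gap_open, gap_extend=gap_extend)
        return [(names[0], pair.aligned[0]), (names[1], pair.aligned[1])]
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(named_seqs[i][1], named_seqs[j][1],
                                matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
            d = 1.0 - (pair.identities / pair.compared_columns if pair.compared_columns else 0.0)
            condensed.append(d)
    Z = linkage(np.asarray(condensed), method="average")
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [named_seqs[i]] for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        profiles[n + k] = _align_profiles(
            profiles.pop(int(a)), profiles.pop(int(b)), mat, gap_open, gap_extend
        )
    final = profiles[2 * n - 2]
    order = {name: i for i, name in enumerate(names)}
    return sorted(final, key=lambda t: order[t[0]])


# ---------------------------------------------------------------------------
# distances

def _pairwise_p_distance(enc: np.ndarray, gap_code: int) -> np.ndarray:
    n = enc.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (enc[i] != gap_code) & (enc[j] != gap_code)
            comp = int(mask.sum())
            if comp == 0:
                d[i, j] = d[j, i] = 1.0
            else:
                mism = int(((enc[i] != enc[j]) & mask).sum())
                d[i, j] = d[j, i] = mism / comp
    return d


def _encode_msa(rows: list[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)


def distance_matrix(msa: Sequence[tuple[str, str]], model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion p-distances from a gapped alignment; Poisson optional.

    p-distance: mismatches over columns where neither row is gapped.
    Poisson correction: -ln(1 - d); undefined (error) when d reaches 1.
    """
    names = tuple(n for n, _ in msa)
    rows = [s for _, s in msa]
    if len(rows) < 3:
        raise ValidationError("distance matrix requires >= 3 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValidationError("alignment rows differ in length")
    enc = _encode_msa(rows)
    d = _pairwise_p_distance(enc, ord(GAP))
    if model == "poisson":
        if np.any(d >= 1.0 - 1e-12):
            raise NumericalError("Poisson correction undefined: p-distance reached 1")
        d = -np.log(1.0 - d)
        np.fill_diagonal(d, 0.0)
    elif model != "p":
        raise ValidationError(f"unknown distance model {model!r}")
    return DistanceMatrix(names=names, values=d)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic lowest-index tie-break.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch (their sum is preserved); disable with
    ``clamp_negative=False``. The returned dendropy tree is unrooted with
    a trifurcating seed node.
    """
    m = len(dm.names)
    if m < 3:
        raise ValidationError("neighbor-joining requires >= 3 taxa")
    tns = dendropy.TaxonNamespace(list(dm.names))
    nodes = [dendropy.Node(taxon=tns.get_taxon(n)) for n in dm.names]
    D = dm.values.astype(float).copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        return li, lj

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        best, bi, bj = math.inf, -1, -1
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                if q < best - 1e-12:
                    best, bi, bj = q, i, j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (k - 2))
        lj = D[bi, bj] - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[bi])
        parent.add_child(nodes[bj])
        nodes[bi].edge.length = li
        nodes[bj].edge.length = lj
        newd = 0.5 * (D[bi, :] + D[bj, :] - D[bi, bj])
        keep = [x for x in range(k) if x not in (bi, bj)]
        D2 = np.zeros((k - 1, k - 1))
        D2[: k - 2, : k - 2] = D[np.ix_(keep, keep)]
        D2[k - 2, : k - 2] = D2[: k - 2, k - 2] = newd[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    # resolve the final three around a central (trifurcating) node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    if clamp_negative:
        lens = [max(x, 0.0) for x in lens]
    center = dendropy.Node()
    for node, ln in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical internal bipartitions as frozensets of leaf labels (smaller side)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    bips: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            side = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
            bips.add(side)
    return bips


def is_cherry(tree: dendropy.Tree, a: str, b: str) -> bool:
    """True when leaves a and b are separated from all others by one edge."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    pair = frozenset({a, b})
    if len(all_leaves) == 3:
        return pair <= all_leaves
    side = min(pair, all_leaves - pair, key=lambda s: (len(s), tuple(sorted(s))))
    return side in tree_bipartitions(tree)


def cherry_support(tree: dendropy.Tree, a: str, b: str) -> Optional[float]:
    """Bootstrap support of the (a, b) cherry edge, or None if absent."""
    pair = {a, b}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == pair:
            return getattr(node, "support", None)
    return None


def bootstrap_support(
    msa: Sequence[tuple[str, str]],
    reps: int = 1000,
    seed: int = 0,
    model: str = "p",
    clamp_negative: bool = True,
) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``reps`` times; the support of
    an internal edge is the percentage of replicate trees containing its
    bipartition. Supports are stored on ``node.support`` and mirrored into
    ``node.label`` for Newick output.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    names = [n for n, _ in msa]
    rows = [s for _, s in msa]
    full = nj_tree(distance_matrix(msa, model=model), clamp_negative=clamp_negative)
    enc = _encode_msa(rows)
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        sub = enc[:, cols]
        d = _pairwise_p_distance(sub, ord(GAP))
        if model == "poisson":
            d = -np.log(1.0 - np.minimum(d, 1.0 - 1e-9))
            np.fill_diagonal(d, 0.0)
        rep_tree = nj_tree(DistanceMatrix(names=tuple(names), values=d),
                           clamp_negative=clamp_negative)
        for bip in tree_bipartitions(rep_tree):
            counts[bip] = counts.get(bip, 0) + 1
    all_leaves = frozenset(names)
    for node in full.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not 1 < len(below) < len(all_leaves) - 1:
            continue
        side = min(below, all_leaves - below, key=lambda s: (len(s), tuple(sorted(s))))
        support = 100.0 * counts.get(side, 0) / reps
        node.support = support
        node.label = f"{support:g}"
    return full


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)

def write_newick(tree: dendropy.Tree, path) -> None:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise ValidationError(f"malformed Newick in {path}: {exc}") from exc


def read_msa(path, fmt: str = "fasta") -> list[tuple[str, str]]:
    """Read an externally computed alignment (aligned FASTA or Clustal)."""
    from Bio import AlignIO

    try:
        aln = AlignIO.read(str(path), fmt)
    except (ValueError, OSError) as exc:
        raise ValidationError(f"cannot parse {fmt} alignment {path}: {exc}") from exc
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def write_msa(msa: Sequence[tuple[str, str]], path, fmt: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or Clustal."""
    from Bio import AlignIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=n, description="") for n, s in msa]
    )
    AlignIO.write(aln, str(path), fmt)
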