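"""Reference-anchored multiple alignment, p-distances, neighbor joining, and
bootstrap supports.

The family tree is built the distance way: sequences are aligned into a
common coordinate system anchored on a reference, pairwise p-distances
(mismatch fraction over gap-free comparable columns) are collected into a
matrix, and the Saitou-Nei neighbor-joining algorithm produces an unrooted
tree. Bootstrap supports come from resampling alignment columns with
replacement and counting how often each internal bipartition of the
full-data tree recurs. Trees are scikit-bio ``TreeNode`` objects, so Newick
round-tripping is the library's.
"""

from __future__ import annotations

import io
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seq import GAP, ProteinRecord, ScoringScheme, global_align, percent_identity


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over the amino-acid alphabet plus '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len(self.rows) < 2:
            raise ValueError("a multiple alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)


def reference_anchored_msa(
    seqs: Sequence[ProteinRecord],
    anchor: ProteinRecord,
    scheme: ScoringScheme | None = None,
) -> MultipleAlignment:
    """Merge pairwise alignments against ``anchor`` into one alignment.

    Each sequence is globally aligned to the anchor; columns are merged on
    anchor coordinates, and insertions relative to the anchor are placed in
    padded blocks, left-justified. Adequate for high-identity families; for
    arbitrary inputs an externally produced aligned FASTA can be loaded
    instead. A warning is issued for sequences under 30% identity to the
    anchor.
    """
    if not seqs:
        raise ValueError("reference_anchored_msa requires at least one sequence")
    n_anchor = len(anchor)
    per_seq_res: list[dict[int, str]] = []
    per_seq_ins: list[dict[int, str]] = []
    for seq in seqs:
        aln = global_align(seq, anchor, scheme)
        if percent_identity(aln) < 30.0:
            warnings.warn(
                f"{seq.id!r} aligns to anchor {anchor.id!r} at under 30% identity"
            )
        res: dict[int, str] = {}
        ins: dict[int, str] = defaultdict(str)
        apos = 0
        for q, s in zip(aln.aligned_query, aln.aligned_subject):
            if s == GAP:
                ins[apos] += q
            else:
                apos += 1
                res[apos] = q
        per_seq_res.append(res)
        per_seq_ins.append(dict(ins))

    ins_width = {
        slot: max(len(ins.get(slot, "")) for ins in per_seq_ins)
        for slot in range(n_anchor + 1)
    }
    rows = []
    for res, ins in zip(per_seq_res, per_seq_ins):
        parts = []
        for slot in range(n_anchor + 1):
            if ins_width[slot]:
                parts.append(ins.get(slot, "").ljust(ins_width[slot], GAP))
            if slot < n_anchor:
                parts.append(res[slot + 1])
        rows.append("".join(parts))
    return MultipleAlignment(ids=[s.id for s in seqs], rows=rows)


def p_distance_matrix(
    msa: MultipleAlignment, correction: str = "p"
) -> DistanceMatrix:
    """Pairwise p-distances: mismatches / compared columns, both rows gap-free.

    ``correction='poisson'`` applies the Poisson multiple-hit correction
    -ln(1 - p); the uncorrected p-distance is the default.
    """
    if correction not in {"p", "poisson"}:
        raise ValueError(f"unknown distance correction {correction!r}")
    n = len(msa.ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            compared = mismatches = 0
            for x, y in zip(a, b):
                if x != GAP and y != GAP:
                    compared += 1
                    if x != y:
                        mismatches += 1
            if compared == 0:
                raise ValueError(
                    f"no gap-free comparable columns between {msa.ids[i]!r} "
                    f"and {msa.ids[j]!r}"
                )
            d = mismatches / compared
            if correction == "poisson":
                if d >= 1.0:
                    raise ValueError(
                        f"saturated pair {msa.ids[i]!r}/{msa.ids[j]!r}: "
                        "Poisson correction undefined at p = 1"
                    )
                d = -np.log(1.0 - d)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=msa.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic, negative lengths clamped to 0.

    When two pairs minimise the Q-criterion equally the lowest (i, j) index
    pair wins. The returned tree is unrooted, represented with a
    trifurcating root (internal nodes have degree 3); for two taxa the single
    edge is split evenly between the pendant branches.
    """
    d = np.asarray(dm.data, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance matrix has negative entries")
    n = d.shape[0]
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    if n == 2:
        for node in nodes:
            node.length = d[0, 1] / 2.0
        return TreeNode(children=nodes)

    d = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)  # row-major: lowest (i,j)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        reduced = np.zeros((len(keep) + 1, len(keep) + 1))
        reduced[0, 1:] = reduced[1:, 0] = new_d[keep]
        reduced[1:, 1:] = d[np.ix_(keep, keep)]
        d = reduced
        nodes = [parent] + [nodes[k] for k in keep]

    # resolve the final three nodes around a star with closed-form lengths
    d12, d13, d23 = d[0, 1], d[0, 2], d[1, 2]
    lengths = (
        (d12 + d13 - d23) / 2.0,
        (d12 + d23 - d13) / 2.0,
        (d13 + d23 - d12) / 2.0,
    )
    for node, length in zip(nodes, lengths):
        node.length = max(0.0, length)
    return TreeNode(children=nodes)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an unrooted tree, normalised to the
    side not containing the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


def bootstrap_support(
    msa: MultipleAlignment, replicates: int = 1000, seed: int = 42
) -> TreeNode:
    """Full-data NJ tree with internal-node bootstrap supports (percent).

    Columns are resampled with replacement per replicate, a replicate tree is
    built, and the support of each internal bipartition of the full-data tree
    is the percentage of replicate trees containing it. Reproducible for a
    fixed seed. Supports are stored as internal node names.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if msa.n_columns < 2:
        raise ValueError("bootstrap needs an alignment with at least 2 columns")
    tree = neighbor_joining(p_distance_matrix(msa))
    counts: dict[frozenset, int] = defaultdict(int)
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, msa.n_columns, size=msa.n_columns)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep_msa = MultipleAlignment(ids=list(msa.ids), rows=rows)
        try:
            rep_tree = neighbor_joining(p_distance_matrix(rep_msa))
        except ValueError:
            continue  # a replicate can lose all comparable columns for a pair
        for split in bipartitions(rep_tree):
            counts[split] += 1

    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            node.name = str(int(round(100.0 * counts.get(side, 0) / replicates)))
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
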