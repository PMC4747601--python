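"""Rank-labeled taxonomy trees, lowest-common-ancestor read assignment, and
marker-gene (16S-like) read screening.

The taxonomy is a rooted tree over a fixed eight-level rank ladder
(root > domain > phylum > class > order > family > genus > species), stored
as a node table (taxon_id, parent_id, rank, name) in the style of the NCBI
taxonomy dump.  The root's parent is itself.  Trees built from tables that
skip intermediate ranks can be padded with synthetic ``unranked_<rank>_<id>``
nodes so that every leaf lineage crosses every rank exactly once.

Reads are assigned taxonomically MEGAN-style: hits below a score floor are
dropped, hits within ``top_percent`` of the best score are retained, and the
read is placed on the lowest common ancestor (LCA) of the retained taxa --
the deepest node ancestral to (or equal to) all of them.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import Align

from .errors import ConfigError

RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Karlin-Altschul parameters for ungapped DNA scoring (match +1, mismatch -2).
#: Used only to turn local alignment scores into approximate e-values; the
#: screening contract is threshold behaviour, not e-value exactness.
KA_LAMBDA = 1.33
KA_K = 0.621


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.rank not in _RANK_INDEX:
            raise ConfigError(f"unknown rank {self.rank!r} for taxon {self.taxon_id!r}")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    taxon_id: str
    n_hits_used: int


class TaxonomyTree:
    """Rooted rank-labeled tree with LCA queries over a node table."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise ConfigError(f"duplicate taxon_id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node
        roots = [n for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise ConfigError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0].taxon_id
        self._depth: dict[str, int] = {self.root_id: 0}
        for tid in self.nodes:
            self.depth(tid)  # also detects cycles / dangling parents

    def depth(self, taxon_id: str) -> int:
        """Number of edges from the root (root has depth 0)."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon_id {taxon_id!r}")
        path = []
        tid = taxon_id
        while tid not in self._depth:
            path.append(tid)
            tid = self.nodes[tid].parent_id
            if tid not in self.nodes:
                raise ConfigError(f"parent {tid!r} of a node is not in the tree")
            if len(path) > len(self.nodes):
                raise ConfigError("cycle detected in taxonomy parent chain")
        d = self._depth[tid]
        for p in reversed(path):
            d += 1
            self._depth[p] = d
        return self._depth[taxon_id]

    def parent(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].parent_id

    def lineage(self, taxon_id: str) -> list[str]:
        """Taxon ids from the root down to (and including) the node."""
        self.depth(taxon_id)
        out = []
        tid = taxon_id
        while True:
            out.append(tid)
            if tid == self.root_id:
                break
            tid = self.nodes[tid].parent_id
        return out[::-1]

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor: deepest node ancestral to or equal to all
        input taxa.  Raises ``KeyError`` naming the first unknown id."""
        ids = list(taxa)
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        for tid in ids:
            if tid not in self.nodes:
                raise KeyError(f"unknown taxon_id {tid!r}")
        cur = ids[0]
        for other in ids[1:]:
            a, b = cur, other
            da, db = self.depth(a), self.depth(b)
            while da > db:
                a = self.nodes[a].parent_id
                da -= 1
            while db > da:
                b = self.nodes[b].parent_id
                db -= 1
            while a != b:
                a = self.nodes[a].parent_id
                b = self.nodes[b].parent_id
            cur = a
        return cur

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """The node's ancestor (or itself) at the requested rank, or None if
        the node sits above that rank or its lineage skips it."""
        if rank not in _RANK_INDEX:
            raise ConfigError(f"unknown rank {rank!r}")
        tid = taxon_id
        while True:
            node = self.nodes[tid]
            if node.rank == rank:
                return tid
            if _RANK_INDEX[node.rank] < _RANK_INDEX[rank]:
                return None
            if tid == self.root_id:
                return None
            tid = node.parent_id

    def leaves(self) -> list[str]:
        parents = {n.parent_id for n in self.nodes.values()}
        return [tid for tid in self.nodes if tid not in parents]

    # -- node-table (TSV) round trip ------------------------------------

    def to_table(self) -> pd.DataFrame:
        rows = [
            (n.taxon_id, n.parent_id, n.rank, n.name)
            for n in sorted(self.nodes.values(), key=lambda n: (self.depth(n.taxon_id), n.taxon_id))
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame, pad_ranks: bool = True) -> "TaxonomyTree":
        nodes = [
            TaxonNode(str(r.taxon_id), str(r.parent_id), str(r.rank), str(r.name))
            for r in table.itertuples(index=False)
        ]
        tree = cls(nodes)
        return tree.pad_ranks() if pad_ranks else tree

    @classmethod
    def from_tsv(cls, path: str | Path, pad_ranks: bool = True) -> "TaxonomyTree":
        return cls.from_table(pd.read_csv(path, sep="\t", dtype=str), pad_ranks=pad_ranks)

    def pad_ranks(self) -> "TaxonomyTree":
        """Insert synthetic ``unranked_<rank>_<id>`` nodes wherever a child's
        rank is more than one ladder step below its parent's."""
        new_nodes: list[TaxonNode] = []
        for node in self.nodes.values():
            if node.taxon_id == self.root_id:
                new_nodes.append(node)
                continue
            parent = self.nodes[node.parent_id]
            gap = _RANK_INDEX[node.rank] - _RANK_INDEX[parent.rank]
            if gap <= 1:
                new_nodes.append(node)
                continue
            above = parent.taxon_id
            for ri in range(_RANK_INDEX[parent.rank] + 1, _RANK_INDEX[node.rank]):
                rank = RANKS[ri]
                tid = f"unranked_{rank}_{node.taxon_id}"
                new_nodes.append(TaxonNode(tid, above, rank, tid))
                above = tid
            new_nodes.append(TaxonNode(node.taxon_id, above, node.rank, node.name))
        return TaxonomyTree(new_nodes)


def lca(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Functional alias for :meth:`TaxonomyTree.lca`."""
    return tree.lca(taxa)


def assign_read(
    hits: Sequence[tuple[str, float]],
    tree: TaxonomyTree,
    top_percent: float = 0.10,
    min_score: float = 50.0,
    read_id: str = "",
) -> ReadAssignment | None:
    """MEGAN-style LCA assignment over (taxon_id, score) hits.

    Hits scoring below ``min_score`` are discarded; of the rest, hits with
    score >= (1 - top_percent) * best are retained and the read is assigned
    to the LCA of their taxa.  Returns None when no hit survives.
    """
    if not 0 < top_percent <= 1:
        raise ConfigError("top_percent must be in (0, 1]")
    scored = [(tid, s) for tid, s in hits if s >= min_score]
    if not scored:
        return None
    best = max(s for _, s in scored)
    kept = [tid for tid, s in scored if s >= (1.0 - top_percent) * best]
    return ReadAssignment(read_id, tree.lca(kept), len(kept))


def rank_profile(
    assignments: Iterable[ReadAssignment], tree: TaxonomyTree, rank: str
) -> pd.Series:
    """Collapse read assignments to counts per taxon at the requested rank.

    Assignments above the rank (or whose lineage skips it) fall into an
    ``unclassified_at_<rank>`` bucket, so the column total always equals the
    number of assignments.
    """
    unclassified = f"unclassified_at_{rank}"
    counts: dict[str, int] = {}
    for a in assignments:
        anc = tree.ancestor_at_rank(a.taxon_id, rank)
        key = anc if anc is not None else unclassified
        counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def screen_marker_reads(
    reads: Sequence[tuple[str, str]],
    marker_db: Sequence[tuple[str, str]],
    min_alignment_length: int = 20,
    max_evalue: float = 1e-10,
) -> list[str]:
    """Retain reads homologous to a marker-gene database (e.g. 16S rRNA).

    A read is kept when its best local alignment to any marker sequence (both
    strands searched) spans at least ``min_alignment_length`` columns and has
    a Karlin-Altschul ungapped e-value (corrected for total database size) of
    at most ``max_evalue``.  Returns the retained read ids in input order.
    """
    from .sequtils import revcomp

    if not marker_db:
        raise ConfigError("marker database is empty")
    aligner = _local_aligner()
    db_len = sum(len(s) for _, s in marker_db)
    kept = []
    for read_id, seq in reads:
        best_ok = False
        for query in (seq, revcomp(seq)):
            for _, marker in marker_db:
                alns = aligner.align(marker, query)
                if len(alns) == 0 or alns.score <= 0:
                    continue
                aln = alns[0]
                length = aln.length
                evalue = KA_K * len(seq) * db_len * math.exp(-KA_LAMBDA * aln.score)
                if length >= min_alignment_length and evalue <= max_evalue:
                    best_ok = True
                    break
            if best_ok:
                break
        if best_ok:
            kept.append(read_id)
    return kept


def write_assignments(assignments: Iterable[ReadAssignment], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.read_id, a.taxon_id, a.n_hits_used) for a in assignments],
        columns=["read_id", "taxon_id", "n_hits_used"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_profile(profile: pd.Series, path: str | Path) -> None:
    total = int(profile.sum())
    df = pd.DataFrame(
        {
            "taxon": profile.index,
            "count": profile.values,
            "percent": 100.0 * profile.values / total if total else 0.0,
        }
    )
    df.to_csv(path, sep="\t", index=False)
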