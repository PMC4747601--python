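"""Per-species pan-genome construction by greedy identity clustering.

A species' pan-genome here is the non-redundant union of its gene sequences
across strains: genes are pooled per species, sorted longest-first, and
clustered greedily in the cd-hit-est style -- each sequence joins the first
existing representative (in representative creation order) whose identity to
it reaches the threshold, and otherwise founds a new cluster.  Identity uses
the cd-hit convention: matching columns of the optimal alignment divided by
the length of the shorter sequence, so a contained gene scores 1.0 against
its container.

A shared-word prefilter (at least one exact ``word_size``-mer in common)
skips hopeless alignments; it is a heuristic that can, on adversarial
inputs, reject a pair whose true identity reaches the threshold, and an
exact mode without it exists for oracle comparisons.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd
from Bio import Align

from .errors import ConfigError


@dataclass(frozen=True)
class GeneSequence:
    gene_id: str
    species_id: str
    strain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigError(f"gene {self.gene_id!r} has an empty sequence")


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.90
    word_size: int = 8

    def __post_init__(self) -> None:
        if not 0.5 <= self.identity_threshold <= 1.0:
            raise ConfigError("identity_threshold must be in [0.5, 1]")
        if self.word_size < 4:
            raise ConfigError("word_size must be >= 4")


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring for clustering identity (artifact defaults)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class Cluster:
    representative: GeneSequence
    members: list[str]  # gene ids, representative included


@dataclass
class PanGenome:
    """Non-redundant representative gene set of one species."""

    species_id: str
    representatives: list[GeneSequence]
    member_map: dict[str, str]  # gene_id -> representative gene_id

    @property
    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self.representatives)

    @property
    def offsets(self) -> dict[str, int]:
        """Start of each representative on the concatenated coordinate axis."""
        out: dict[str, int] = {}
        pos = 0
        for rep in self.representatives:
            out[rep.gene_id] = pos
            pos += len(rep.sequence)
        return out

    def representative(self, gene_id: str) -> GeneSequence:
        for rep in self.representatives:
            if rep.gene_id == gene_id:
                return rep
        raise KeyError(gene_id)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rep in self.representatives:
                fh.write(f">{rep.gene_id}\n{rep.sequence}\n")

    def write_clusters_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.member_map.items()), columns=["gene_id", "representative_id"]
        )
        df.to_csv(path, sep="\t", index=False)


def pool_species_genes(
    genes: Iterable[GeneSequence],
) -> dict[str, list[GeneSequence]]:
    """Group genes by species, ordered by decreasing length then gene_id.

    Raises on a duplicate gene_id (naming it), since the member map must be
    unambiguous.
    """
    seen: set[str] = set()
    pools: dict[str, list[GeneSequence]] = {}
    for gene in genes:
        if gene.gene_id in seen:
            raise ConfigError(f"duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        pools.setdefault(gene.species_id, []).append(gene)
    for pool in pools.values():
        pool.sort(key=lambda g: (-len(g.sequence), g.gene_id))
    return pools


def _glocal_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps on the longer (target) sequence: the shorter aligns
    # globally against its best-matching region of the longer
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


_DEFAULT_ALIGNER = _glocal_aligner(AlignScoring())


def pairwise_identity(
    a: str, b: str, scoring: AlignScoring | None = None
) -> float:
    """Identity of the best affine-gap alignment of the shorter sequence
    against the longer, as matching columns / shorter length."""
    if not a or not b:
        raise ConfigError("pairwise_identity requires non-empty sequences")
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    aligner = _DEFAULT_ALIGNER if scoring is None else _glocal_aligner(scoring)
    aln = aligner.align(longer, shorter)[0]
    return aln.counts().identities / len(shorter)


def _words(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


def _could_reach_identity(a: str, b: str, threshold: float) -> bool:
    """Exact triage: can the glocal identity of (a, b) possibly reach the
    threshold?

    Any alignment of the shorter (length Ls) inside the longer (Ll) is a
    global edit path once the free end gaps are counted, so its edit count
    is at least the global edit distance D; matches are then bounded by
    Ls - (D - (Ll - Ls)) / 2.  When that bound falls below threshold * Ls
    the expensive affine alignment cannot succeed and is skipped.  The
    bound is an upper bound, so no pair that could reach the threshold is
    ever skipped — this is a speedup, not a heuristic filter.
    """
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    ls, ll = len(shorter), len(longer)
    # skip condition: D > 2*Ls*(1 - threshold) + (Ll - Ls)
    k = int(2 * ls * (1.0 - threshold)) + (ll - ls) + 1
    res = edlib.align(shorter, longer, mode="NW", task="distance", k=k)
    d = res["editDistance"]
    if d < 0:
        return False
    return 2 * ls - (d - (ll - ls)) >= 2.0 * threshold * ls


def cluster_greedy(
    pool: Sequence[GeneSequence],
    params: ClusterParams = ClusterParams(),
    use_prefilter: bool = True,
    scoring: AlignScoring | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering of a longest-first gene pool.

    Each sequence is compared against existing representatives in creation
    order and joins the first one reaching ``identity_threshold`` (after the
    shared-word prefilter when enabled); otherwise it founds a new cluster.
    Deterministic given the pool order produced by
    :func:`pool_species_genes`.
    """
    clusters: list[Cluster] = []
    rep_words: list[set[str]] = []
    for gene in pool:
        gene_words = _words(gene.sequence, params.word_size) if use_prefilter else None
        joined = False
        for ci, cluster in enumerate(clusters):
            if use_prefilter and not (gene_words & rep_words[ci]):
                continue
            if not _could_reach_identity(
                gene.sequence, cluster.representative.sequence, params.identity_threshold
            ):
                continue
            ident = pairwise_identity(
                gene.sequence, cluster.representative.sequence, scoring
            )
            if ident >= params.identity_threshold:
                cluster.members.append(gene.gene_id)
                joined = True
                break
        if not joined:
            clusters.append(Cluster(gene, [gene.gene_id]))
            if use_prefilter:
                rep_words.append(gene_words)
    return clusters


def build_pangenome(clusters: Sequence[Cluster], species_id: str) -> PanGenome:
    """Assemble a PanGenome from one species' clusters (empty input yields a
    valid empty pan-genome that recruits nothing)."""
    member_map: dict[str, str] = {}
    reps: list[GeneSequence] = []
    for cluster in clusters:
        if cluster.representative.species_id != species_id:
            raise ConfigError(
                f"cluster representative {cluster.representative.gene_id!r} "
                f"belongs to {cluster.representative.species_id!r}, not {species_id!r}"
            )
        reps.append(cluster.representative)
        for gid in cluster.members:
            member_map[gid] = cluster.representative.gene_id
    return PanGenome(species_id, reps, member_map)


def build_pangenomes(
    genes: Iterable[GeneSequence],
    params: ClusterParams = ClusterParams(),
    use_prefilter: bool = True,
) -> dict[str, PanGenome]:
    """Pool, cluster, and assemble pan-genomes for every species present."""
    pools = pool_species_genes(genes)
    return {
        sp: build_pangenome(cluster_greedy(pool, params, use_prefilter), sp)
        for sp, pool in sorted(pools.items())
    }
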