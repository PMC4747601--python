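"""Fragment recruitment: align reads to pan-genomes and aggregate profiles.

Each QC-passed read is aligned against every species pan-genome through one
combined seed index.  Hits must cover a minimum fraction of the read
(aligned-fraction filter, inclusive at the threshold) and only the
best-score hit per read per species survives, so paralogous representatives
are never double-counted.  Per species the filtered hits are aggregated
into a recruitment profile: coverage depth (total aligned read bases over
pan-genome length), breadth (fraction of positions covered at least once),
alignment-length-weighted average identity, a per-position depth vector on
the concatenated representative axis, and a majority-vote consensus
sequence (ties fall back to the reference base; uncovered positions are N).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignResult, Hit, ReferenceIndex
from .errors import ConfigError
from .pangenome import PanGenome
from .sequtils import decode, encode


@dataclass
class AlignmentHit:
    """One read-to-pan-genome alignment (coordinates 0-based half-open on
    the representative gene; TSV outputs are 1-based inclusive)."""

    read_id: str
    species_id: str
    target_gene_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    alignment_length: int
    identity: float
    read_aligned_fraction: float
    score: float
    tpos: np.ndarray | None = field(default=None, repr=False)
    qcodes: np.ndarray | None = field(default=None, repr=False)


@dataclass
class RecruitmentProfile:
    species_id: str
    recruited_reads: int
    coverage_depth: float
    breadth: float
    average_identity: float
    depth_vector: np.ndarray
    consensus: str


class PanGenomeIndex:
    """Combined seed index over the representatives of many pan-genomes."""

    def __init__(self, pangenomes: Sequence[PanGenome], seed_length: int = 15):
        records = []
        for pg in pangenomes:
            for rep in pg.representatives:
                records.append(((pg.species_id, rep.gene_id), rep.sequence))
        if not records:
            raise ConfigError("no representatives to index")
        self.index = ReferenceIndex(records, seed_length=seed_length)
        self.seed_length = seed_length

    def align_read(
        self,
        read_seq: str,
        read_id: str = "",
        min_identity: float = 0.7,
        collect_bases: bool = True,
    ) -> AlignResult:
        return self.index.map_read(
            read_seq,
            read_id=read_id,
            min_identity=min_identity,
            collect_bases=collect_bases,
        )


def _to_alignment_hit(hit: Hit) -> AlignmentHit:
    species_id, gene_id = hit.target_id
    return AlignmentHit(
        read_id=hit.read_id,
        species_id=species_id,
        target_gene_id=gene_id,
        target_start=hit.target_start,
        target_end=hit.target_end,
        strand=hit.strand,
        matches=hit.matches,
        alignment_length=hit.alignment_length,
        identity=hit.identity,
        read_aligned_fraction=hit.read_aligned_fraction,
        score=hit.score,
        tpos=hit.tpos,
        qcodes=hit.qcodes,
    )


def align_read(
    read_seq: str,
    index: PanGenomeIndex,
    read_id: str = "",
    min_identity: float = 0.7,
    collect_bases: bool = True,
) -> tuple[list[AlignmentHit], str | None]:
    """All hits of one read across the indexed pan-genomes, best score
    first; the second element is a reason code when no hit is returned."""
    result = index.align_read(
        read_seq, read_id=read_id, min_identity=min_identity, collect_bases=collect_bases
    )
    return [_to_alignment_hit(h) for h in result.hits], result.reason


def filter_hits(
    hits: Iterable[AlignmentHit], min_read_fraction: float = 0.8
) -> list[AlignmentHit]:
    """Apply the aligned-fraction filter (inclusive at the threshold) and
    keep only the primary (best-score) hit per read per species, breaking
    ties by identity then lexicographic target gene id."""
    if not 0 < min_read_fraction <= 1:
        raise ConfigError("min_read_fraction must be in (0, 1]")
    best: dict[tuple[str, str], AlignmentHit] = {}
    order: list[tuple[str, str]] = []
    for hit in hits:
        if hit.read_aligned_fraction < min_read_fraction:
            continue
        key = (hit.read_id, hit.species_id)
        cur = best.get(key)
        if cur is None:
            best[key] = hit
            order.append(key)
        elif (-hit.score, -hit.identity, hit.target_gene_id) < (
            -cur.score,
            -cur.identity,
            cur.target_gene_id,
        ):
            best[key] = hit
    return [best[k] for k in order]


def recruit_reads(
    reads: Iterable[tuple[str, str]],
    pangenomes: Sequence[PanGenome],
    min_identity: float = 0.7,
    min_read_fraction: float = 0.8,
    seed_length: int = 15,
    collect_bases: bool = True,
) -> dict[str, list[AlignmentHit]]:
    """Recruit (read_id, sequence) pairs against every pan-genome.

    Returns the filtered hits grouped by species (one primary hit per read
    per species)."""
    index = PanGenomeIndex(pangenomes, seed_length=seed_length)
    all_hits: list[AlignmentHit] = []
    for read_id, seq in reads:
        hits, _ = align_read(
            seq, index, read_id=read_id, min_identity=min_identity,
            collect_bases=collect_bases,
        )
        all_hits.extend(hits)
    filtered = filter_hits(all_hits, min_read_fraction=min_read_fraction)
    grouped: dict[str, list[AlignmentHit]] = {pg.species_id: [] for pg in pangenomes}
    for hit in filtered:
        grouped[hit.species_id].append(hit)
    return grouped


def profile(hits: Sequence[AlignmentHit], pangenome: PanGenome) -> RecruitmentProfile:
    """Aggregate filtered hits of one species into a recruitment profile."""
    total = pangenome.total_length
    offsets = pangenome.offsets
    depth = np.zeros(total, dtype=np.int64)
    votes = np.zeros((4, total), dtype=np.int64)
    aligned_bases = 0
    weighted_identity = 0.0
    weight = 0
    for hit in hits:
        if hit.species_id != pangenome.species_id:
            raise ConfigError(
                f"hit for {hit.species_id!r} passed to pan-genome "
                f"{pangenome.species_id!r}"
            )
        if hit.tpos is None or hit.qcodes is None:
            raise ConfigError("profile needs hits with collected aligned bases")
        gpos = hit.tpos + offsets[hit.target_gene_id]
        valid = hit.qcodes < 4
        np.add.at(depth, gpos[valid], 1)
        np.add.at(votes, (hit.qcodes[valid], gpos[valid]), 1)
        aligned_bases += int(np.count_nonzero(valid))
        weighted_identity += hit.identity * hit.alignment_length
        weight += hit.alignment_length
    reference = np.concatenate(
        [encode(rep.sequence) for rep in pangenome.representatives]
    ) if total else np.empty(0, dtype=np.uint8)
    consensus = _consensus(votes, depth, reference)
    return RecruitmentProfile(
        species_id=pangenome.species_id,
        recruited_reads=len(hits),
        coverage_depth=aligned_bases / total if total else 0.0,
        breadth=float(np.count_nonzero(depth)) / total if total else 0.0,
        average_identity=weighted_identity / weight if weight else 0.0,
        depth_vector=depth,
        consensus=consensus,
    )


def _consensus(votes: np.ndarray, depth: np.ndarray, reference: np.ndarray) -> str:
    if depth.size == 0:
        return ""
    top = votes.max(axis=0)
    winner = votes.argmax(axis=0).astype(np.uint8)
    tied = (votes == top).sum(axis=0) > 1
    out = np.where(tied, reference, winner)
    out = np.where(depth > 0, out, np.uint8(255))  # uncovered -> N
    return decode(out.astype(np.uint8))


def recruitment_plot_points(
    hits: Sequence[AlignmentHit], pangenome: PanGenome
) -> pd.DataFrame:
    """Recruitment-plot points: one (concatenated position, identity%) pair
    per hit, at the alignment midpoint."""
    offsets = pangenome.offsets
    rows = [
        (
            offsets[h.target_gene_id] + (h.target_start + h.target_end) / 2.0,
            100.0 * h.identity,
        )
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["position", "identity_pct"])


def write_hits_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Hit table with 1-based inclusive coordinates (stated in the header)."""
    rows = [
        (
            h.read_id,
            h.species_id,
            h.target_gene_id,
            h.target_start + 1,
            h.target_end,
            h.strand,
            h.matches,
            h.alignment_length,
            round(h.identity, 6),
            round(h.read_aligned_fraction, 6),
            h.score,
        )
        for h in hits
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "species_id",
            "target_gene_id",
            "target_start_1based",
            "target_end_inclusive",
            "strand",
            "matches",
            "alignment_length",
            "identity",
            "read_aligned_fraction",
            "score",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def write_summary_tsv(
    profiles: Sequence[RecruitmentProfile], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (
                p.species_id,
                p.recruited_reads,
                round(p.coverage_depth, 6),
                round(p.breadth, 6),
                round(p.average_identity, 6),
            )
            for p in profiles
        ],
        columns=[
            "species_id",
            "recruited_reads",
            "coverage_depth",
            "breadth",
            "average_identity",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
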