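"""Read preprocessing: pair merging, quality filtering, host subtraction.

The preprocessing contract mirrors the usual shotgun workflow for short
overlapping paired-end libraries: merge each pair on its best 3' overlap
with a per-base quality vote, discard merged reads unless a minimum fraction
of bases exceeds a Phred threshold (pass/fail on the whole read rather than
trimming, so downstream recruitment sees full-length reads), then align the
survivors sequentially against an ordered panel of host/contaminant genomes
and discard the first match.
"""

from __future__ import annotations

from collections import OrderedDict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .align import ReferenceIndex
from .errors import ConfigError, EmptyReadError
from .sequtils import decode, encode


@dataclass
class QualityRead:
    """A read with per-base Phred qualities (0-60)."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != self.qualities.size:
            raise ConfigError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ConfigError(f"read {self.id!r}: qualities outside [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QcParams:
    """Merging and filtering knobs.

    ``q_threshold``/``min_pass_fraction`` encode the quality rule: a read
    passes when at least ``min_pass_fraction`` of its bases are strictly
    above ``q_threshold`` (boundary inclusive on the fraction).
    """

    q_threshold: int = 30
    min_pass_fraction: float = 0.98
    min_overlap: int = 10
    max_overlap_mismatch_rate: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_pass_fraction <= 1:
            raise ConfigError("min_pass_fraction must be in (0, 1]")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        if not 0 <= self.max_overlap_mismatch_rate <= 1:
            raise ConfigError("max_overlap_mismatch_rate must be in [0, 1]")


def _merge_at(
    a_seq: np.ndarray,
    a_qual: np.ndarray,
    b_seq: np.ndarray,
    b_qual: np.ndarray,
    overlap: int,
    read_id: str,
) -> QualityRead:
    """Join R1 codes and reverse-complemented R2 codes over a known overlap.

    In the overlap the base with the higher quality wins and its quality is
    kept (ties keep R1's base); agreeing bases keep the higher quality.
    """
    n1 = a_seq.size
    ov_a, ov_b = a_seq[n1 - overlap :], b_seq[:overlap]
    qa, qb = a_qual[n1 - overlap :], b_qual[:overlap]
    take_b = qb > qa
    ov_seq = np.where(take_b, ov_b, ov_a)
    ov_qual = np.maximum(qa, qb)
    seq = np.concatenate([a_seq[: n1 - overlap], ov_seq, b_seq[overlap:]])
    qual = np.concatenate([a_qual[: n1 - overlap], ov_qual, b_qual[overlap:]])
    return QualityRead(read_id, decode(seq.astype(np.uint8)), qual)


def merge_pair(
    r1: QualityRead, r2: QualityRead, params: QcParams = QcParams()
) -> QualityRead | None:
    """Merge one pair on its best (longest admissible) 3' overlap.

    The reverse mate is supplied in sequencing orientation and is
    reverse-complemented internally.  Overlap lengths are scanned from the
    longest possible down; the first one with mismatch rate at most
    ``max_overlap_mismatch_rate`` (and length >= ``min_overlap``) wins.
    Returns None when no admissible overlap exists.
    """
    a = encode(r1.sequence)
    b = 3 - encode(r2.sequence)[::-1]  # reverse complement, code space
    bq = np.asarray(r2.qualities)[::-1]
    max_l = min(a.size, b.size)
    for ov in range(max_l, params.min_overlap - 1, -1):
        mism = int(np.count_nonzero(a[a.size - ov :] != b[:ov]))
        if mism <= params.max_overlap_mismatch_rate * ov:
            rid = r1.id.removesuffix("/1")
            return _merge_at(a, np.asarray(r1.qualities), b, bq, ov, rid)
    return None


def merge_pairs(
    r1_seqs: np.ndarray,
    r2_seqs: np.ndarray,
    quality: int,
    ids: Sequence[str],
    params: QcParams = QcParams(),
) -> tuple[list[QualityRead], int]:
    """Vectorized merge of an equal-length read-pair batch (code matrices).

    Semantics are identical to :func:`merge_pair` with constant qualities.
    Returns the merged reads (pairs without an admissible overlap are
    dropped) and the count of merge failures.
    """
    n, L = r1_seqs.shape
    b = np.ascontiguousarray((3 - r2_seqs)[:, ::-1])
    best = np.zeros(n, dtype=np.int64)
    unresolved = np.arange(n)
    for ov in range(L, params.min_overlap - 1, -1):
        if unresolved.size == 0:
            break
        mism = np.count_nonzero(
            r1_seqs[unresolved, L - ov :] != b[unresolved, :ov], axis=1
        )
        ok = mism <= params.max_overlap_mismatch_rate * ov
        best[unresolved[ok]] = ov
        unresolved = unresolved[~ok]
    merged: list[QualityRead] = []
    qrow = np.full(L, quality, dtype=np.int16)
    for i in range(n):
        ov = int(best[i])
        if ov == 0:
            continue
        merged.append(_merge_at(r1_seqs[i], qrow, b[i], qrow, ov, str(ids[i])))
    return merged, int(n - len(merged))


def quality_filter(read: QualityRead, params: QcParams = QcParams()) -> bool:
    """Pass iff the fraction of bases with quality strictly above
    ``q_threshold`` is at least ``min_pass_fraction``."""
    if len(read) == 0:
        raise EmptyReadError(f"read {read.id!r} is empty")
    frac = np.count_nonzero(read.qualities > params.q_threshold) / len(read)
    return bool(frac >= params.min_pass_fraction)


def host_subtract(
    reads: Iterable[QualityRead],
    references: Sequence[tuple[str, str]],
    min_identity: float = 0.9,
    min_read_fraction: float = 0.8,
    seed_length: int = 15,
) -> tuple[list[QualityRead], "OrderedDict[str, int]"]:
    """Sequentially subtract reads matching an ordered reference panel.

    Each read is tested against the references in order; the first reference
    producing an alignment with identity >= ``min_identity`` covering at
    least ``min_read_fraction`` of the read removes the read and is credited
    with it.  Surviving reads pass through unchanged.  Returns (kept reads,
    per-reference removal counts); kept + removed always partitions the
    input exactly.
    """
    if not references:
        raise ConfigError("host_subtract needs at least one reference")
    if not (0 < min_identity <= 1 and 0 < min_read_fraction <= 1):
        raise ConfigError("thresholds must be in (0, 1]")
    indexes = [
        (name, ReferenceIndex([(name, seq)], seed_length=seed_length))
        for name, seq in references
    ]
    removed: "OrderedDict[str, int]" = OrderedDict((name, 0) for name, _ in references)
    kept: list[QualityRead] = []
    for read in reads:
        hit_ref = None
        for name, index in indexes:
            result = index.map_read(read.sequence, min_identity=min_identity)
            if any(h.read_aligned_fraction >= min_read_fraction for h in result.hits):
                hit_ref = name
                break
        if hit_ref is None:
            kept.append(read)
        else:
            removed[hit_ref] += 1
    return kept, removed
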