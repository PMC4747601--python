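"""Seed-and-extend read alignment against a set of reference sequences.

The aligner is a k-mer index over the reference records plus an extension
step: exact seed matches on either strand nominate candidate records and
diagonals, a window around the seeded diagonal range is cut from the
reference, and the read is aligned semi-globally into the window (the whole
read must be consumed; the window's ends are free).  The extension uses
edit-distance alignment (edlib) for the path and then rescores the path with
affine-gap scoring (match +1, mismatch -1, gap open -4, gap extend -1 per
additional gap column), which is what hit ranking and LCA score filtering
operate on.

Seeding first probes non-overlapping read k-mers; if none hits, every read
position is probed, so a read sharing any exact ``seed_length``-mer with a
reference is always extended.
"""

from __future__ import annotations

import re
from collections.abc import Sequence
from dataclasses import dataclass, field

import edlib
import numpy as np

from .errors import ConfigError
from .sequtils import encode, revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -4
GAP_EXTEND = -1

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

#: reason codes for empty alignment results
READ_TOO_SHORT = "read_too_short"
NO_SEED = "no_seed"
NO_HIT_ABOVE_IDENTITY = "no_hit_above_identity"


@dataclass
class Hit:
    """One read-to-reference alignment.

    ``target_start``/``target_end`` are 0-based half-open on the reference
    record.  ``identity`` is matches / alignment columns and
    ``read_aligned_fraction`` is read bases inside the alignment / read
    length.  ``tpos``/``qcodes`` hold, for every aligned column that consumes
    a reference base and a read base, the reference position and the read
    base code; they feed depth and consensus accumulation.
    """

    read_id: str
    target_id: object
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
class AlignResult:
    hits: list[Hit]
    reason: str | None = None

    @property
    def primary(self) -> Hit | None:
        return self.hits[0] if self.hits else None


def _affine_score_and_counts(cigar: str) -> tuple[int, int, int]:
    """(affine score, matches, alignment columns) from an extended cigar."""
    score = 0
    matches = 0
    columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        k = int(num)
        columns += k
        if op == "=":
            matches += k
            score += MATCH_SCORE * k
        elif op == "X":
            score += MISMATCH_SCORE * k
        else:  # I or D: one gap run
            score += GAP_OPEN + GAP_EXTEND * (k - 1)
    return score, matches, columns


class ReferenceIndex:
    """Exact k-mer index over reference records supporting read mapping."""

    def __init__(self, records: Sequence[tuple[object, str]], seed_length: int = 15):
        if seed_length < 4:
            raise ConfigError("seed_length must be >= 4")
        self.seed_length = seed_length
        self.ids = [rid for rid, _ in records]
        self.seqs = [seq.upper() for _, seq in records]
        for rid, seq in zip(self.ids, self.seqs):
            if not seq:
                raise ConfigError(f"reference {rid!r} has an empty sequence")
        self.codes = [encode(s) for s in self.seqs]
        self._index: dict[str, list[tuple[int, int]]] = {}
        for rec_i, seq in enumerate(self.seqs):
            for pos in range(len(seq) - seed_length + 1):
                self._index.setdefault(seq[pos : pos + seed_length], []).append((rec_i, pos))

    def _seed_positions(self, seq: str, step: int) -> dict[tuple[int, str], list[int]]:
        """Candidate diagonals per record for one read orientation."""
        k = self.seed_length
        diags: dict[int, list[int]] = {}
        positions = list(range(0, len(seq) - k + 1, step))
        if positions and positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        for q in positions:
            for rec_i, pos in self._index.get(seq[q : q + k], ()):
                diags.setdefault(rec_i, []).append(pos - q)
        return diags

    def map_read(
        self,
        seq: str,
        read_id: str = "",
        min_identity: float = 0.7,
        max_candidates: int = 8,
        collect_bases: bool = False,
    ) -> AlignResult:
        """Align a read on both strands; hits sorted by score (best first)."""
        if len(seq) < self.seed_length:
            return AlignResult([], READ_TOO_SHORT)
        oriented = (("+", seq.upper()), ("-", revcomp(seq).upper()))
        candidates: list[tuple[int, int, str, str, int, int]] = []
        for step in (self.seed_length, 1):
            for strand, s in oriented:
                for rec_i, dlist in self._seed_positions(s, step=step).items():
                    candidates.append((len(dlist), rec_i, strand, s, dlist))
            if candidates:
                break
        if not candidates:
            return AlignResult([], NO_SEED)
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        hits: list[Hit] = []
        for _, rec_i, strand, s, dlist in candidates[:max_candidates]:
            hit = self._extend(s, rec_i, strand, dlist, read_id, collect_bases)
            if hit is not None and hit.identity >= min_identity:
                hits.append(hit)
        if not hits:
            return AlignResult([], NO_HIT_ABOVE_IDENTITY)
        hits.sort(key=lambda h: (-h.score, -h.identity, str(h.target_id)))
        return AlignResult(hits, None)

    def _extend(
        self,
        oriented_read: str,
        rec_i: int,
        strand: str,
        diagonals: list[int],
        read_id: str,
        collect_bases: bool,
    ) -> Hit | None:
        ref = self.seqs[rec_i]
        n = len(oriented_read)
        pad = 30 + n // 10
        w_start = max(0, min(diagonals) - pad)
        w_end = min(len(ref), max(diagonals) + n + pad)
        window = ref[w_start:w_end]
        res = edlib.align(oriented_read, window, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            return None
        loc = res["locations"][0]
        t_start = w_start + loc[0]
        t_end = w_start + loc[1] + 1
        cigar = res["cigar"]
        score, matches, columns = _affine_score_and_counts(cigar)
        read_codes = encode(oriented_read)
        # Edit-distance paths can re-explain adjacent substitutions with
        # equal-cost indel pairs; the pure-substitution interpretation at the
        # dominant seed diagonal is checked and preferred when its affine
        # score is at least as good (it is the exact affine optimum for
        # substitution-only reads).
        diag_counts: dict[int, int] = {}
        for d in diagonals:
            diag_counts[d] = diag_counts.get(d, 0) + 1
        best_diag = min(diag_counts, key=lambda d: (-diag_counts[d], d))
        if 0 <= best_diag and best_diag + n <= len(ref):
            matches_u = int(
                np.count_nonzero(self.codes[rec_i][best_diag : best_diag + n] == read_codes)
            )
            score_u = MATCH_SCORE * matches_u + MISMATCH_SCORE * (n - matches_u)
            if score_u >= score:
                score, matches, columns = score_u, matches_u, n
                t_start, t_end = best_diag, best_diag + n
                cigar = None  # ungapped
        if cigar is None:
            read_bases = n
        else:
            read_bases = sum(
                int(num) for num, op in _CIGAR_RE.findall(cigar) if op in "=XI"
            )
        hit = Hit(
            read_id=read_id,
            target_id=self.ids[rec_i],
            target_start=t_start,
            target_end=t_end,
            strand=strand,
            matches=matches,
            alignment_length=columns,
            identity=matches / columns if columns else 0.0,
            read_aligned_fraction=read_bases / n,
            score=float(score),
        )
        if collect_bases:
            if cigar is None:
                hit.tpos = np.arange(t_start, t_end, dtype=np.int64)
                hit.qcodes = read_codes
            else:
                hit.tpos, hit.qcodes = self._aligned_columns(
                    cigar, t_start, read_codes
                )
        return hit

    @staticmethod
    def _aligned_columns(
        cigar: str, t_start: int, read_codes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Reference positions and read base codes for =/X columns."""
        tpos_parts: list[np.ndarray] = []
        qcode_parts: list[np.ndarray] = []
        t = t_start
        q = 0
        for num, op in _CIGAR_RE.findall(cigar):
            k = int(num)
            if op in "=X":
                tpos_parts.append(np.arange(t, t + k, dtype=np.int64))
                qcode_parts.append(read_codes[q : q + k])
                t += k
                q += k
            elif op == "D":  # reference consumed, no read base
                t += k
            else:  # I: read consumed, no reference position
                q += k
        if tpos_parts:
            return np.concatenate(tpos_parts), np.concatenate(qcode_parts)
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
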