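"""Multi-mapping read-to-allele alignments and their likelihoods.

HLA allele sequences within a locus are nearly identical, so a read
typically aligns acceptably to many alleles.  This module produces those
multi-hits — either by ingesting a SAM/BAM produced by an external
aligner run in report-all mode, or with a built-in k-mer seed-and-extend
aligner suitable for panel-sized references — and converts each hit into
a read-given-allele log-likelihood log P(R_n | t) under a simple
per-base error model.  The per-read likelihood vectors are assembled
into the sparse matrix the variational inference consumes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pysam
from scipy import sparse

from .alleles import AlleleDatabase

__all__ = [
    "ErrorModel",
    "AlignmentHit",
    "ReadLikelihoodMatrix",
    "hit_log_likelihood",
    "read_sam_alignments",
    "KmerIndex",
    "builtin_align",
    "build_matrix",
]

_LOG_QUARTER = math.log(0.25)
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().encode().translate(_COMP)[::-1].decode()


@dataclass(frozen=True)
class ErrorModel:
    """Per-base alignment error model.

    substitution: probability a reference base is read as a (specific set
    of 3) wrong base(s); a mismatch contributes log(substitution / 3).
    gap_open / gap_extend: probability of opening a gap / extending it by
    one base.  Soft-clipped bases are priced at the random-sequence rate
    log(1/4) so clipping cannot inflate a likelihood.
    """

    substitution: float = 0.01
    gap_open: float = 0.002
    gap_extend: float = 0.1

    def __post_init__(self) -> None:
        for name in ("substitution", "gap_open", "gap_extend"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"ErrorModel.{name} must be in (0,1), got {v}")


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of one mate of a read to one allele.

    ``gap_opens`` counts indel runs; a run of length L is priced as one
    gap open plus L-1 extensions.
    """

    read_id: str
    mate: int
    allele_index: int
    matches: int
    mismatches: int = 0
    insertions: int = 0
    deletions: int = 0
    soft_clipped: int = 0
    gap_opens: int = 0

    @property
    def read_length(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.soft_clipped


def hit_log_likelihood(hit: AlignmentHit, params: ErrorModel = ErrorModel()) -> float:
    """log P(mate | allele) from alignment counts under the error model."""
    counts = (hit.matches, hit.mismatches, hit.insertions, hit.deletions,
              hit.soft_clipped, hit.gap_opens)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative alignment counts: {hit}")
    gap_bases = hit.insertions + hit.deletions
    opens = hit.gap_opens
    if gap_bases and not opens:
        # run structure unknown: price each indel base as its own event
        opens = gap_bases
    extends = gap_bases - opens
    if extends < 0:
        raise ValueError(f"gap_opens exceeds indel bases: {hit}")
    return (
        hit.matches * math.log1p(-params.substitution)
        + hit.mismatches * math.log(params.substitution / 3.0)
        + opens * math.log(params.gap_open)
        + extends * math.log(params.gap_extend)
        + hit.soft_clipped * _LOG_QUARTER
    )


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

_MD_MISMATCH = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")


def _mismatches_from_md(md: str) -> int:
    """Count substitution letters in an MD tag (letters after '^' are deletions)."""
    n = 0
    for num, dele, letter in _MD_MISMATCH.findall(md):
        if letter:
            n += 1
    return n


def _decompose(aln: pysam.AlignedSegment) -> dict[str, int]:
    m_aligned = eq = xx = ins = dels = soft = opens = 0
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            m_aligned += length
            if op == 7:
                eq += length
            elif op == 8:
                xx += length
        elif op == 1:  # I
            ins += length
            opens += 1
        elif op == 2:  # D
            dels += length
            opens += 1
        elif op == 4:  # S
            soft += length
        # H, P, N carry no read bases we price
    if aln.has_tag("NM"):
        mism = int(aln.get_tag("NM")) - ins - dels
    elif xx or eq:
        mism = xx
    elif aln.has_tag("MD"):
        mism = _mismatches_from_md(str(aln.get_tag("MD")))
    else:
        raise ValueError(
            f"alignment {aln.query_name!r}: neither NM nor MD tag present; "
            "cannot decompose matches/mismatches"
        )
    mism = max(0, mism)
    return dict(matches=m_aligned - mism, mismatches=mism, insertions=ins,
                deletions=dels, soft_clipped=soft, gap_opens=opens)


def read_sam_alignments(path: str | Path, db: AlleleDatabase) -> list[AlignmentHit]:
    """Load all mapped records (primary and secondary) from a SAM/BAM.

    Reference names must be allele names resolvable by the panel (bare
    or IMGT-style headers).  Match/mismatch counts are decomposed from
    CIGAR + NM (falling back to =/X ops, then the MD tag).
    """
    hits: list[AlignmentHit] = []
    unknown: set[str] = set()
    ref_map: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for ref in fh.references:
            try:
                ref_map[ref] = db.resolve_reference(ref)
            except KeyError:
                unknown.add(ref)
        for aln in fh:
            if aln.is_unmapped:
                continue
            ref = aln.reference_name
            if ref in unknown:
                continue
            counts = _decompose(aln)
            mate = 2 if aln.is_read2 else 1
            hits.append(AlignmentHit(read_id=aln.query_name, mate=mate,
                                     allele_index=ref_map[ref], **counts))
    if unknown:
        raise KeyError(
            "SAM reference names not present in the allele panel: "
            + ", ".join(sorted(unknown))
        )
    return hits


# ---------------------------------------------------------------------------
# Built-in seed-and-extend aligner
# ---------------------------------------------------------------------------


class KmerIndex:
    """Exact k-mer index over all panel sequences.

    Seeding requires one exact shared k-mer; candidate (allele, diagonal)
    pairs are verified ungapped and, when the ungapped mismatch count
    suggests an indel, re-aligned with edlib on a small window.
    """

    #: ungapped mismatch count beyond which the gapped fallback runs
    MAX_UNGAPPED_MISMATCH = 5
    #: extra reference bases on each side of the gapped-extension window
    PAD = 8
    #: per-base alignment score used for the report-all cutoff
    MISMATCH_COST = 3
    GAP_COST = 4

    def __init__(self, db: AlleleDatabase, k: int = 25):
        if len(db) == 0:
            raise ValueError("empty allele database")
        if k < 11:
            raise ValueError(f"seed length k must be >= 11, got {k}")
        self.k = k
        self.db = db
        self._seq_bytes = [rec.sequence.encode() for rec in db.records]
        self._seq_arr = [np.frombuffer(b, dtype=np.uint8) for b in self._seq_bytes]
        table: dict[bytes, list[tuple[int, int]]] = {}
        for t, b in enumerate(self._seq_bytes):
            for pos in range(len(b) - k + 1):
                table.setdefault(b[pos : pos + k], []).append((t, pos))
        self._table = table

    def _candidate_diagonals(self, q: bytes) -> dict[int, int]:
        """allele -> best diagonal offset (reference pos of read base 0)."""
        k, L = self.k, len(q)
        seed_starts = list(range(0, L - k + 1, k))
        if seed_starts[-1] != L - k:
            seed_starts.append(L - k)
        votes: dict[tuple[int, int], int] = {}
        for sp in seed_starts:
            for t, pos in self._table.get(q[sp : sp + k], ()):
                key = (t, pos - sp)
                votes[key] = votes.get(key, 0) + 1
        best: dict[int, tuple[int, int]] = {}
        for (t, d), v in votes.items():
            cur = best.get(t)
            if cur is None or v > cur[1] or (v == cur[1] and d < cur[0]):
                best[t] = (d, v)
        return {t: dv[0] for t, dv in best.items()}

    def _evaluate(self, q: bytes, t: int, diag: int) -> dict[str, int] | None:
        L = len(q)
        ref = self._seq_arr[t]
        if len(ref) < L:
            return None
        d = min(max(diag, 0), len(ref) - L)
        qa = np.frombuffer(q, dtype=np.uint8)
        mism = int(np.count_nonzero(ref[d : d + L] != qa))
        if mism <= self.MAX_UNGAPPED_MISMATCH:
            return dict(matches=L - mism, mismatches=mism, insertions=0,
                        deletions=0, soft_clipped=0, gap_opens=0)
        w0 = max(0, diag - self.PAD)
        w1 = min(len(ref), diag + L + self.PAD)
        res = edlib.align(q.decode(), self._seq_bytes[t][w0:w1].decode(),
                          mode="HW", task="path")
        cigar = res.get("cigar")
        if cigar is None:
            return None
        eq = xx = ins = dels = opens = 0
        for length, op in re.findall(r"(\d+)([=XID])", cigar):
            n = int(length)
            if op == "=":
                eq += n
            elif op == "X":
                xx += n
            elif op == "I":
                ins += n
                opens += 1
            else:
                dels += n
                opens += 1
        return dict(matches=eq, mismatches=xx, insertions=ins, deletions=dels,
                    soft_clipped=0, gap_opens=opens)

    def _score(self, c: dict[str, int]) -> int:
        return (c["matches"] - self.MISMATCH_COST * c["mismatches"]
                - self.GAP_COST * (c["insertions"] + c["deletions"])
                - c["soft_clipped"])

    def align_sequence(self, seq: str, max_hits: int = 100,
                       min_score_frac: float = 0.9) -> list[tuple[int, dict[str, int]]]:
        """All near-best hits of one read sequence (both strands).

        Returns ``(allele_index, counts)`` pairs for every allele scoring
        at least ``min_score_frac`` times the best hit, best first.
        """
        q_fwd = seq.upper().encode()
        per_allele: dict[int, tuple[int, dict[str, int]]] = {}
        best_score = None
        for q in (q_fwd, q_fwd.translate(_COMP)[::-1]):
            for t, diag in self._candidate_diagonals(q).items():
                counts = self._evaluate(q, t, diag)
                if counts is None:
                    continue
                score = self._score(counts)
                if score <= 0:
                    continue
                cur = per_allele.get(t)
                if cur is None or score > cur[0]:
                    per_allele[t] = (score, counts)
            # a strand with a perfect hit cannot be beaten by the other
            if per_allele and max(s for s, _ in per_allele.values()) >= len(q_fwd):
                break
        if not per_allele:
            return []
        best_score = max(s for s, _ in per_allele.values())
        cutoff = min_score_frac * best_score
        ranked = sorted(per_allele.items(), key=lambda kv: (-kv[1][0], kv[0]))
        return [(t, counts) for t, (s, counts) in ranked if s >= cutoff][:max_hits]


def builtin_align(
    pairs: Iterable[tuple[str, str | None, str | None]],
    db: AlleleDatabase,
    k: int = 25,
    max_hits: int = 100,
    min_score_frac: float = 0.9,
    index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """Align paired reads against the panel with the built-in aligner.

    ``pairs`` yields ``(read_id, seq1, seq2)`` (``seq2`` may be None for
    single-end data).  Reads shorter than ``k`` are skipped.  Output is
    deterministic given input order.
    """
    idx = index if index is not None else KmerIndex(db, k=k)
    hits: list[AlignmentHit] = []
    for read_id, s1, s2 in pairs:
        for mate, s in ((1, s1), (2, s2)):
            if s is None or len(s) < idx.k:
                continue
            for t, counts in idx.align_sequence(s, max_hits=max_hits,
                                                min_score_frac=min_score_frac):
                hits.append(AlignmentHit(read_id=read_id, mate=mate,
                                         allele_index=t, **counts))
    return hits


# ---------------------------------------------------------------------------
# Likelihood matrix
# ---------------------------------------------------------------------------


@dataclass
class ReadLikelihoodMatrix:
    """Sparse read-pair x allele matrix of log P(R_n | t).

    Only (read, allele) pairs with at least one alignment hit are stored;
    every stored value is <= 0.  ``read_ids[n]`` names row n.
    """

    loglik: sparse.csr_matrix
    read_ids: list[str]

    def __post_init__(self) -> None:
        if self.loglik.shape[0] != len(self.read_ids):
            raise ValueError("row count does not match read_ids")
        if self.loglik.data.size and self.loglik.data.max() > 1e-12:
            raise ValueError("log-likelihoods must be <= 0")
        counts = np.diff(self.loglik.indptr)
        if np.any(counts == 0):
            raise ValueError("every read must have at least one allele hit")

    @property
    def n_reads(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.loglik.shape[1]


def build_matrix(
    hits: Sequence[AlignmentHit],
    db: AlleleDatabase,
    params: ErrorModel = ErrorModel(),
    paired: bool = True,
) -> ReadLikelihoodMatrix:
    """Combine per-mate hits into per-read-pair log-likelihoods.

    For a read pair and allele t, log P(R_n | t) sums the two mates' hit
    log-likelihoods when both mates hit t; a mate with no hit on t (but
    part of the pair) contributes the random-sequence penalty
    read_len * log(1/4).  The best hit per (read, mate, allele) is kept
    when duplicates exist.
    """
    # best log-likelihood per (read, mate, allele); insertion order kept
    per_read: dict[str, dict[int, dict[int, float]]] = {}
    mate_len: dict[tuple[str, int], int] = {}
    for h in hits:
        ll = hit_log_likelihood(h, params)
        mates = per_read.setdefault(h.read_id, {})
        alleles = mates.setdefault(h.mate, {})
        if h.allele_index not in alleles or ll > alleles[h.allele_index]:
            alleles[h.allele_index] = ll
        key = (h.read_id, h.mate)
        mate_len[key] = max(mate_len.get(key, 0), h.read_length)

    read_ids: list[str] = []
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for read_id, mates in per_read.items():
        expected = (1, 2) if paired else tuple(sorted(mates))
        alleles = sorted(set().union(*(m.keys() for m in mates.values())))
        n = len(read_ids)
        read_ids.append(read_id)
        any_len = max(mate_len[(read_id, m)] for m in mates)
        for t in alleles:
            total = 0.0
            for m in expected:
                if m in mates and t in mates[m]:
                    total += mates[m][t]
                else:
                    # missing mate: use its own length if it hit anywhere
                    length = mate_len.get((read_id, m), any_len)
                    total += length * _LOG_QUARTER
            rows.append(n)
            cols.append(t)
            data.append(min(total, 0.0))

    mat = sparse.csr_matrix(
        (np.asarray(data), (np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp))),
        shape=(len(read_ids), len(db)),
    )
    return ReadLikelihoodMatrix(loglik=mat, read_ids=read_ids)
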