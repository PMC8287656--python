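"""Interspersed duplications, tandem repeats and cross-genome fragments.

The duplication/fragment detector is a seed-and-extend local aligner
(exact word seeds, ungapped x-drop extension) with Karlin-Altschul
E-values under fixed blastn-like scores (+2/-3).  Threshold semantics
(E < 1e-10) follow the screening convention; numeric parity with NCBI
BLASTN is not claimed.  The tandem detector is a deterministic
exhaustive period scan suitable for desk-scale genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mito_io import MitoGenome, reverse_complement

MATCH = 2
MISMATCH = -3
XDROP = 20
KA_K = 0.333


def _lambda_for_scores(match: int, mismatch: int) -> float:
    """Ungapped Karlin-Altschul lambda at uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


KA_LAMBDA = _lambda_for_scores(MATCH, MISMATCH)


def evalue(score: int, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


@dataclass
class RepeatHit:
    query_interval: tuple[int, int]  # 1-based inclusive
    subject_interval: tuple[int, int]
    relation: str  # 'direct' or 'inverted'
    identity: float  # percent
    aligned_length: int
    e_value: float
    score: int = 0
    same_genome: bool = True


@dataclass
class TandemRepeat:
    interval: tuple[int, int]  # 1-based inclusive
    period: int
    copy_number: float
    consensus: str

    @property
    def total_length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


# ---------------------------------------------------------------------------
# seed-and-extend engine


def _extend(q: str, s: str, qi: int, si: int, word: int):
    """Ungapped x-drop extension of an exact word seed.

    Returns (q_start, q_end, s_start, s_end, score, matches, length) in
    0-based half-open coordinates.
    """
    score = MATCH * word
    # right extension
    best = score
    best_r = 0
    cur = score
    k = 0
    while qi + word + k < len(q) and si + word + k < len(s):
        cur += MATCH if q[qi + word + k] == s[si + word + k] else MISMATCH
        k += 1
        if cur > best:
            best = cur
            best_r = k
        if best - cur > XDROP:
            break
    score = best
    # left extension
    best = score
    best_l = 0
    cur = score
    k = 0
    while qi - k - 1 >= 0 and si - k - 1 >= 0:
        cur += MATCH if q[qi - k - 1] == s[si - k - 1] else MISMATCH
        k += 1
        if cur > best:
            best = cur
            best_l = k
        if best - cur > XDROP:
            break
    score = best
    q0, q1 = qi - best_l, qi + word + best_r
    s0, s1 = si - best_l, si + word + best_r
    length = q1 - q0
    matches = sum(q[q0 + t] == s[s0 + t] for t in range(length))
    return q0, q1, s0, s1, score, matches, length


def _kmer_index(s: str, word: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(s) - word + 1):
        idx.setdefault(s[i : i + word], []).append(i)
    return idx


def _scan(q: str, s: str, word: int, self_direct: bool) -> list[tuple]:
    """All x-drop extensions of exact word seeds, deduped per diagonal."""
    idx = _kmer_index(s, word)
    covered: dict[int, list[tuple[int, int]]] = {}
    raw = []
    for i in range(len(q) - word + 1):
        for j in idx.get(q[i : i + word], ()):
            if self_direct and j <= i:
                continue  # skip the trivial self-diagonal and mirror pairs
            diag = j - i
            spans = covered.get(diag)
            if spans and any(a <= i < b for a, b in spans):
                continue
            q0, q1, s0, s1, score, matches, length = _extend(q, s, i, j, word)
            covered.setdefault(diag, []).append((q0, q1))
            raw.append((q0, q1, s0, s1, score, matches, length))
    return raw


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _merge_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Keep the lower-E hit among pairs overlapping >=50% of the shorter."""
    hits = sorted(hits, key=lambda h: (h.e_value, h.query_interval))
    kept: list[RepeatHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if k.relation != h.relation:
                continue
            qo = _overlap(h.query_interval, k.query_interval)
            so = _overlap(h.subject_interval, k.subject_interval)
            shorter_q = min(
                h.query_interval[1] - h.query_interval[0] + 1,
                k.query_interval[1] - k.query_interval[0] + 1,
            )
            shorter_s = min(
                h.subject_interval[1] - h.subject_interval[0] + 1,
                k.subject_interval[1] - k.subject_interval[0] + 1,
            )
            if qo >= 0.5 * shorter_q and so >= 0.5 * shorter_s:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.query_interval, h.subject_interval))
    return kept


def _hits_from_raw(
    raw, m: int, n: int, e_max: float, relation: str, rc_len: int | None,
    same_genome: bool,
) -> list[RepeatHit]:
    out = []
    for q0, q1, s0, s1, score, matches, length in raw:
        e = evalue(score, m, n)
        if e >= e_max:
            continue
        if rc_len is not None:
            # map subject coordinates back from the reverse complement
            s0, s1 = rc_len - s1, rc_len - s0
        qiv = (q0 + 1, q1)
        siv = (s0 + 1, s1)
        if same_genome and qiv == siv:
            continue
        if same_genome and relation == "inverted" and siv < qiv:
            continue  # mirror duplicate of an already-seen orientation
        out.append(
            RepeatHit(
                query_interval=qiv,
                subject_interval=siv,
                relation=relation,
                identity=100.0 * matches / length,
                aligned_length=length,
                e_value=e,
                score=score,
                same_genome=same_genome,
            )
        )
    return out


def find_duplications(
    genome: MitoGenome, e_max: float = 1e-10, word: int = 11
) -> list[RepeatHit]:
    """Intra-genomic interspersed duplications (direct and inverted)."""
    seq = genome.sequence
    if len(seq) < word:
        raise ValueError(f"sequence shorter than word size {word}")
    m = n = len(seq)
    hits = _hits_from_raw(
        _scan(seq, seq, word, self_direct=True), m, n, e_max, "direct", None, True
    )
    rc = reverse_complement(seq)
    hits += _hits_from_raw(
        _scan(seq, rc, word, self_direct=False), m, n, e_max, "inverted", len(seq), True
    )
    return _merge_hits(hits)


def cross_genome_fragments(
    mito: MitoGenome, other: list[tuple[str, str]], e_max: float = 1e-10,
    word: int = 11,
) -> list[RepeatHit]:
    """Fragments of the mitogenome shared with other (e.g. nuclear) sequences.

    Subject coordinates refer to the concatenated coordinate space of each
    subject record; hits are returned sorted by E-value.
    """
    seq = mito.sequence
    hits: list[RepeatHit] = []
    for _, sub in other:
        sub = sub.upper()
        m, n = len(seq), len(sub)
        hits += _hits_from_raw(
            _scan(seq, sub, word, self_direct=False), m, n, e_max, "direct", None, False
        )
        rc = reverse_complement(sub)
        hits += _hits_from_raw(
            _scan(seq, rc, word, self_direct=False), m, n, e_max, "inverted", n, False
        )
    hits = _merge_hits(hits)
    hits.sort(key=lambda h: h.e_value)
    return hits


# ---------------------------------------------------------------------------
# tandem repeats


def _match_runs(mask: np.ndarray, min_identity: float = 0.8):
    """Maximal True runs, greedily merged across gaps while identity >= floor."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]  # half-open runs
    keep = (ends - starts) >= 3  # sub-3 nt runs never seed a qualifying array
    runs = list(zip(starts[keep].tolist(), ends[keep].tolist()))
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        span = e - ps
        matches = int(mask[ps:e].sum())
        if matches / span >= min_identity:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def find_tandem_repeats(
    genome: MitoGenome,
    min_total: int = 11,
    min_copies: float = 2.0,
    max_period: int = 500,
) -> list[TandemRepeat]:
    """Deterministic exhaustive period scan for tandem arrays.

    A run qualifies when consecutive period-p windows match at >= 80%
    identity, the array spans >= ``min_copies`` copies and exceeds
    ``min_total``-1 nt in total.  Each array is reported once, at its
    smallest qualifying period.
    """
    seq = genome.sequence
    if not seq:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    found: list[TandemRepeat] = []
    limit = min(max_period, len(seq) // 2)
    for p in range(1, limit + 1):
        mask = arr[:-p] == arr[p:]
        for s, e in _match_runs(mask):
            run = e - s
            total = run + p
            if total < min_total or total / p < min_copies:
                continue
            iv = (s + 1, s + total)  # 1-based inclusive
            redundant = any(
                _overlap(iv, t.interval) >= 0.5 * (iv[1] - iv[0] + 1) for t in found
            )
            if redundant:
                continue
            found.append(
                TandemRepeat(
                    interval=iv,
                    period=p,
                    copy_number=total / p,
                    consensus=seq[s : s + p],
                )
            )
    found.sort(key=lambda t: t.interval)
    return found


# ---------------------------------------------------------------------------
# coverage


def repeat_fraction(genome: MitoGenome, hits: list) -> float:
    """Percent of the genome covered by the union of hit intervals."""
    intervals: list[tuple[int, int]] = []
    for h in hits:
        if isinstance(h, TandemRepeat):
            intervals.append(h.interval)
        else:
            intervals.append(h.query_interval)
            if h.same_genome:
                intervals.append(h.subject_interval)
    L = genome.length
    for s, e in intervals:
        if not (1 <= s <= e <= L):
            raise ValueError(f"interval ({s},{e}) outside [1,{L}]")
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            covered += ce - cs + 1
            cs, ce = s, e
    covered += ce - cs + 1
    return 100.0 * covered / L
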