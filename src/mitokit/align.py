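"""Seeded, gapped local alignment with BLAST-like scoring and E-values.

Seeding is exact word matching (default W=7); extension around each seed
cluster is an optimal local alignment restricted to a window, computed with
Biopython's C PairwiseAligner kernel.  Long single-diagonal clusters (large
substitution-only repeats) take a fast ungapped X-drop path instead, so the
engine scales to multi-kilobase repeat copies without quadratic DP.

Scoring: match +M, mismatch N (negative), gap of length k costs Q + k*R.
E-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*score), with
lambda solved from the scoring scheme under uniform base composition and K
left configurable (the ungapped-regime constants are reused for gapped hits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align as _BioAlign

from .seqio import reverse_complement


@dataclass
class AlignParams:
    match: int = 1
    mismatch: int = -3
    gap_open: int = 3
    gap_extend: int = 3
    word_size: int = 7
    evalue_cutoff: float = 1.0
    min_identity: float = 0.0
    min_coverage: float = 0.0
    karlin_k: float = 0.711
    band: int = 25
    xdrop: int = 20
    max_dp_cells: int = 25_000_000
    max_hits: int | None = None

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.evalue_cutoff < 0 or self.min_identity < 0 or self.min_coverage < 0:
            raise ValueError("cutoffs must be >= 0")

    @property
    def karlin_lambda(self) -> float:
        return _solve_lambda(self.match, self.mismatch)


def _solve_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for uniform base frequencies."""
    # f(L) = 0.25*exp(L*match) + 0.75*exp(L*mismatch) - 1, increasing for L>0
    lo, hi = 1e-6, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = 0.25 * math.exp(mid * match) + 0.75 * math.exp(mid * mismatch) - 1.0
        if val > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class AlignmentHit:
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    orientation: str  # '+' or '-'; '-' => subject interval is on the reverse strand
    aligned_length: int
    matches: int
    score: float
    evalue: float = math.inf
    ops: str = ""  # cigar-like, e.g. '120M1I30M'

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_length if self.aligned_length else 0.0

    def coverage(self, query_len: int) -> float:
        return 100.0 * (self.query_end - self.query_start) / query_len

    def as_row(self) -> dict:
        return {
            "qstart": self.query_start,
            "qend": self.query_end,
            "sstart": self.subject_start,
            "send": self.subject_end,
            "strand": self.orientation,
            "length": self.aligned_length,
            "identity": round(self.identity, 2),
            "score": self.score,
            "evalue": self.evalue,
        }


def evalue(score: float, query_len: int, subject_len: int, params: AlignParams) -> float:
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    lam = params.karlin_lambda
    return params.karlin_k * query_len * subject_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# seeding


def _seed_matches(query: str, subject: str, w: int, exclude_main_diagonal: bool):
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - w + 1):
        word = subject[i : i + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    by_diag: dict[int, list[int]] = {}
    for q in range(len(query) - w + 1):
        word = query[q : q + w]
        positions = index.get(word)
        if not positions:
            continue
        for s in positions:
            d = q - s
            if exclude_main_diagonal and d == 0:
                continue
            by_diag.setdefault(d, []).append(q)
    return by_diag


def _diagonal_runs(by_diag: dict[int, list[int]], w: int, max_gap: int = 60):
    """Collapse seed positions on each diagonal into (diag, qlo, qhi) runs."""
    runs = []
    for d, qs in by_diag.items():
        qs.sort()
        lo = prev = qs[0]
        for q in qs[1:]:
            if q - prev > max_gap:
                runs.append((d, lo, prev + w))
                lo = q
            prev = q
        runs.append((d, lo, prev + w))
    return runs


def _cluster_runs(runs, band: int):
    """Group diagonal runs whose diagonals are within band and q-ranges near."""
    runs = sorted(runs, key=lambda r: (r[0], r[1]))
    clusters = []
    used = [False] * len(runs)
    for i, (d, lo, hi) in enumerate(runs):
        if used[i]:
            continue
        group = [(d, lo, hi)]
        used[i] = True
        for j in range(i + 1, len(runs)):
            dj, loj, hij = runs[j]
            if dj - d > band:
                break
            if used[j]:
                continue
            glo = min(g[1] for g in group)
            ghi = max(g[2] for g in group)
            if loj <= ghi + band and hij >= glo - band:
                group.append(runs[j])
                used[j] = True
        clusters.append(group)
    return clusters


# ---------------------------------------------------------------------------
# extension


def _ungapped_extend(query: str, subject: str, q0: int, s0: int, length: int, params):
    """X-drop ungapped extension of an exact-ish run; returns hit fields."""
    M, N, X = params.match, params.mismatch, params.xdrop
    # score the core
    score = 0
    matches = 0
    for k in range(length):
        if query[q0 + k] == subject[s0 + k]:
            score += M
            matches += 1
        else:
            score += N
    # extend right
    best, cur = score, score
    best_right = length
    k = length
    while q0 + k < len(query) and s0 + k < len(subject):
        cur += M if query[q0 + k] == subject[s0 + k] else N
        k += 1
        if cur > best:
            best, best_right = cur, k
        if best - cur > X:
            break
    # recount matches over chosen right extension
    for k in range(length, best_right):
        if query[q0 + k] == subject[s0 + k]:
            matches += 1
    score = best
    # extend left
    best, cur = score, score
    best_left = 0
    k = 1
    while q0 - k >= 0 and s0 - k >= 0:
        cur += M if query[q0 - k] == subject[s0 - k] else N
        if cur > best:
            best, best_left = cur, k
        if best - cur > X:
            break
        k += 1
    for k in range(1, best_left + 1):
        if query[q0 - k] == subject[s0 - k]:
            matches += 1
    qs, qe = q0 - best_left, q0 + best_right
    ss = s0 - best_left
    alen = qe - qs
    return qs, qe, ss, ss + alen, alen, matches, best


def _make_aligner(params: AlignParams) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _windowed_dp(query: str, subject: str, qlo, qhi, slo, shi, params):
    """Optimal local alignment inside a window; returns hit fields or None."""
    qseq = query[qlo:qhi]
    sseq = subject[slo:shi]
    if not qseq or not sseq:
        return None
    aligner = _make_aligner(params)
    alns = aligner.align(qseq, sseq)
    if len(alns) == 0:
        return None
    aln = alns[0]
    score = aln.score
    qblocks, sblocks = aln.aligned
    matches = 0
    alen = 0
    prev_q = prev_s = None
    for (qb, qe), (sb, se) in zip(qblocks, sblocks):
        if prev_q is not None:
            alen += (qb - prev_q) + (sb - prev_s)  # gap columns
        for a, b in zip(qseq[qb:qe], sseq[sb:se]):
            if a == b:
                matches += 1
        alen += qe - qb
        prev_q, prev_s = qe, se
    qs = int(qblocks[0][0]) + qlo
    qe = int(qblocks[-1][1]) + qlo
    ss = int(sblocks[0][0]) + slo
    se = int(sblocks[-1][1]) + slo
    return qs, qe, ss, se, alen, matches, float(score)


def _extend_cluster(query: str, subject: str, cluster, params: AlignParams):
    diags = [g[0] for g in cluster]
    qlo = min(g[1] for g in cluster)
    qhi = max(g[2] for g in cluster)
    single_diag = len(set(diags)) == 1
    pad = params.band + 25
    slo = max(0, qlo - max(diags) - pad)
    shi = min(len(subject), qhi - min(diags) + pad)
    wqlo, wqhi = max(0, qlo - pad), min(len(query), qhi + pad)
    area = (wqhi - wqlo) * (shi - slo)
    if single_diag and area > params.max_dp_cells:
        d = diags[0]
        core_len = qhi - qlo
        return _ungapped_extend(query, subject, qlo, qlo - d, core_len, params)
    if area > params.max_dp_cells:
        # too big for DP: fall back to ungapped on the longest run
        d, lo, hi = max(cluster, key=lambda g: g[2] - g[1])
        return _ungapped_extend(query, subject, lo, lo - d, hi - lo, params)
    return _windowed_dp(query, subject, wqlo, wqhi, slo, shi, params)


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits contained in an equal-or-better hit (nested/redundant removal)."""
    hits = sorted(hits, key=lambda h: (-h.score, h.query_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if (
                k.orientation == h.orientation
                and k.query_start <= h.query_start
                and h.query_end <= k.query_end
                and k.subject_start <= h.subject_start
                and h.subject_end <= k.subject_end
                and k.identity >= h.identity - 1e-9
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def min_significant_score(query_len: int, subject_len: int, params: AlignParams) -> float:
    """Smallest score whose E-value clears the cutoff."""
    lam = params.karlin_lambda
    return math.log(params.karlin_k * query_len * subject_len
                    / max(params.evalue_cutoff, 1e-300)) / lam


def seed_and_extend(query: str, subject: str, params: AlignParams | None = None,
                    self_alignment: bool = False) -> list[AlignmentHit]:
    """All local alignments clearing the E-value cutoff, both strands.

    With self_alignment=True the trivial full-length identity diagonal is
    excluded from seeding (the caller gets only off-diagonal / reverse hits).

    On large inputs each diagonal seed run is pre-screened with a cheap
    ungapped X-drop extension; only runs whose ungapped score approaches the
    E-value significance threshold get the windowed gapped DP.  Small inputs
    (m*n below ~1e6) always take the exact windowed-DP path with
    cross-diagonal cluster merging, which keeps the engine score-equivalent
    to full Smith-Waterman there.
    """
    if params is None:
        params = AlignParams()
    if not query or not subject:
        return []
    m, n = len(query), len(subject)
    small = m * n <= 1_000_000
    s_min = min_significant_score(m, n, params)
    hits: list[AlignmentHit] = []
    for strand in "+-":
        sseq = subject if strand == "+" else reverse_complement(subject)
        exclude = self_alignment and strand == "+"
        by_diag = _seed_matches(query, sseq, params.word_size, exclude)
        runs = _diagonal_runs(by_diag, params.word_size)
        if small:
            clusters = _cluster_runs(runs, params.band)
        else:
            screened = []
            for d, lo, hi in runs:
                qs, qe, ss, se, alen, matches, score = _ungapped_extend(
                    query, sseq, lo, lo - d, hi - lo, params
                )
                # gapped refinement can only add a bounded amount; 0.8 margin
                if score >= 0.8 * s_min:
                    screened.append([(d, lo, hi)])
            clusters = screened
        for cluster in clusters:
            res = _extend_cluster(query, sseq, cluster, params)
            if res is None:
                continue
            qs, qe, ss, se, alen, matches, score = res
            if score <= 0:
                continue
            ev = evalue(score, m, n, params)
            if ev > params.evalue_cutoff:
                continue
            if strand == "-":
                ss, se = n - se, n - ss
            if self_alignment and strand == "+" and qs == ss and qe == se:
                continue
            hits.append(
                AlignmentHit(qs, qe, ss, se, strand, alen, matches, score, ev)
            )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.score, h.query_start))
    if params.max_hits is not None:
        hits = hits[: params.max_hits]
    return hits


def filter_hits(hits, min_identity: float, min_coverage: float,
                evalue_cutoff: float, query_len: int) -> list[AlignmentHit]:
    """Keep hits passing identity, query-coverage and E-value thresholds."""
    out = []
    for h in hits:
        if h.identity < min_identity:
            continue
        if h.coverage(query_len) < min_coverage:
            continue
        if h.evalue > evalue_cutoff:
            continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# global pairwise helpers used by downstream stages


def global_align(a: str, b: str, params: AlignParams | None = None):
    """Global alignment of two nucleotide sequences; returns (aligned_a, aligned_b)."""
    if params is None:
        params = AlignParams(match=1, mismatch=-1, gap_open=2, gap_extend=1)
    aligner = _make_aligner(params)
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def global_align_protein(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Global protein alignment with +1/-1 residue scoring and affine gaps."""
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])
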