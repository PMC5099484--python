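"""Repeat landscape scanners: SSRs, tandem repeats, dispersed repeat families.

SSRs are perfect tandem runs of 1-6 nt motifs above per-motif-length copy
thresholds (default 8,4,4,3,3,3).  Tandem repeats (unit >= 7 bp, mismatches
allowed) are found by lag autocorrelation.  Dispersed repeats come from a
gapped self-alignment with the trivial identity hit removed, clustered into
families typed DR (direct), IR (inverted) or DR/IR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, seed_and_extend
from .seqio import Feature, GenomeRecord

DEFAULT_SSR_THRESHOLDS = (8, 4, 4, 3, 3, 3)


# ---------------------------------------------------------------------------
# SSRs


@dataclass
class SSR:
    motif: str  # canonical (lexicographically minimal rotation) unit
    unit_len: int
    copies: int
    start: int
    end: int
    location: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def find_ssrs(record, thresholds=DEFAULT_SSR_THRESHOLDS) -> list[SSR]:
    """Maximal perfect SSR runs, reported once at their smallest true period.

    Runs reportable at several unit lengths surface only at the primitive
    period; overlapping reports are resolved greedily left-to-right (earlier
    start wins, then smaller period).
    """
    seq = record.sequence if isinstance(record, GenomeRecord) else record
    if len(thresholds) != 6:
        raise ValueError("thresholds must have length 6")
    n = len(seq)
    candidates = []
    for p in range(1, 7):
        thr = thresholds[p - 1]
        k = p
        while k < n:
            if seq[k] != seq[k - p]:
                k += 1
                continue
            # maximal stretch of period-p matches starting at k
            a = k
            while k < n and seq[k] == seq[k - p]:
                k += 1
            run_start, run_len = a - p, (k - a) + p
            copies = run_len // p
            unit = seq[run_start : run_start + p]
            if copies >= thr and "N" not in unit and _is_primitive(unit):
                candidates.append(
                    SSR(
                        motif=canonical_rotation(unit),
                        unit_len=p,
                        copies=copies,
                        start=run_start,
                        end=run_start + p * copies,
                    )
                )
    candidates.sort(key=lambda s: (s.start, s.unit_len))
    out: list[SSR] = []
    covered_until = -1
    for c in candidates:
        if c.start > covered_until:
            out.append(c)
            covered_until = c.end - 1
    return out


# ---------------------------------------------------------------------------
# tandem repeats


@dataclass
class TandemRepeat:
    period: int
    copies: float
    identity: float  # %
    consensus: str
    start: int
    end: int
    location: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _consensus_of(region: str, period: int) -> str:
    cols: list[dict] = [dict() for _ in range(period)]
    for i, ch in enumerate(region):
        col = cols[i % period]
        col[ch] = col.get(ch, 0) + 1
    # ties resolved by first copy's base
    out = []
    for j, col in enumerate(cols):
        best = max(col.values())
        winners = [b for b, c in col.items() if c == best]
        out.append(region[j] if region[j] in winners else winners[0])
    return "".join(out)


def find_tandem_repeats(record, min_period: int = 7, max_period: int = 100,
                        min_copies: float = 2.0, min_identity: float = 90.0) -> list[TandemRepeat]:
    """Lag-autocorrelation tandem detector (substitution-only model).

    For each candidate period p the sequence is compared against itself at
    lag p; maximal high-identity stretches become repeat regions.  Periods
    whose unit is itself an SSR motif (minimal period <= 6) are excluded.
    """
    if min_period <= 0 or min_copies < 2 or min_identity <= 0:
        raise ValueError("parameters must be positive (min_copies >= 2)")
    seq = record.sequence if isinstance(record, GenomeRecord) else record
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    results: list[TandemRepeat] = []
    mismatch_penalty = 5.0  # random lag-matches (P=1/4) score negative on average
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = arr[p:] == arr[:-p]
        min_stretch = int(np.ceil((min_copies - 1) * p))
        scores = np.where(eq, 1.0, -mismatch_penalty)
        # maximal positive-scoring segments (Kadane-style with segment cuts);
        # segments start and end on a match, trimming chance flank creep
        m = len(eq)
        k = 0
        while k < m:
            if not eq[k]:
                k += 1
                continue
            a = k
            run = best = 0.0
            best_end = k
            while k < m:
                run += scores[k]
                if run < 0:
                    break
                if run >= best:
                    best, best_end = run, k + 1
                k += 1
            b = best_end
            stretch = b - a
            if stretch >= min_stretch:
                mismatches = int(np.sum(~eq[a:b]))
                region = seq[a : b + p]
                ident = 100.0 * (stretch - mismatches) / stretch
                unit = seq[a : a + p]
                if ident >= min_identity and _min_period_of(unit) > 6:
                    results.append(
                        TandemRepeat(
                            period=p,
                            copies=round(len(region) / p, 2),
                            identity=round(ident, 2),
                            consensus=_consensus_of(region, p),
                            start=a,
                            end=b + p,
                        )
                    )
            k = max(k + 1, b)
    # smallest-period-first, then greedy non-overlap
    results.sort(key=lambda t: (t.period, t.start))
    kept: list[TandemRepeat] = []
    for t in results:
        if all(t.end <= u.start or t.start >= u.end for u in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


def _min_period_of(unit: str) -> int:
    for d in range(1, len(unit) + 1):
        if all(unit[i] == unit[i % d] for i in range(len(unit))):
            return d
    return len(unit)


# ---------------------------------------------------------------------------
# dispersed repeat families


@dataclass
class RepeatFamily:
    family_id: str
    unit_length: int
    identity: float  # %
    copies: list = field(default_factory=list)  # [(start, end, orientation)]
    rtype: str = "DR"  # DR | IR | DR/IR

    @property
    def n_copies(self) -> int:
        return len(self.copies)


def _overlap_frac(a, b) -> float:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if hi <= lo:
        return 0.0
    inter = hi - lo
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def find_dispersed_repeats(record, params: AlignParams | None = None,
                           min_report_len: int = 20) -> list[RepeatFamily]:
    """Self-alignment based dispersed-repeat families, DR/IR typed.

    Circular records are scanned on the doubled sequence with coordinates
    normalized modulo L and duplicate pairs removed.
    """
    if params is None:
        params = AlignParams(evalue_cutoff=1.0)
    if isinstance(record, GenomeRecord):
        seq = record.sequence
        circular = record.topology == "circular"
    else:
        seq, circular = record, False
    L = len(seq)
    scan_seq = seq + seq if circular else seq
    hits = seed_and_extend(scan_seq, scan_seq, params, self_alignment=True)

    pairs = []  # ((qs,qe),(ss,se),orientation,identity,length)
    seen = set()
    for h in hits:
        if h.aligned_length < min_report_len:
            continue
        if h.aligned_length > L:
            continue  # doubled-sequence artifact spanning a full genome copy
        q = (h.query_start % L, h.query_start % L + (h.query_end - h.query_start))
        s = (h.subject_start % L, h.subject_start % L + (h.subject_end - h.subject_start))
        if circular and q[0] == s[0] and q[1] == s[1] and h.orientation == "+":
            continue  # same genomic interval seen through the doubling
        a, b = (q, s) if q <= s else (s, q)
        key = (a, b, h.orientation)
        if key in seen:
            continue
        seen.add(key)
        pairs.append((a, b, h.orientation, h.identity, h.aligned_length))

    # merge intervals with >=80% reciprocal overlap into copy nodes
    intervals: list[list[int]] = []

    def node_of(iv):
        for idx, known in enumerate(intervals):
            if _overlap_frac(iv, known) >= 0.8:
                known[0] = min(known[0], iv[0])
                known[1] = max(known[1], iv[1])
                return idx
        intervals.append([iv[0], iv[1]])
        return len(intervals) - 1

    edges = []
    for a, b, orient, ident, length in pairs:
        na, nb = node_of(a), node_of(b)
        if na != nb:
            edges.append((na, nb, orient, ident, length))

    # connected components with orientation parity
    parent = list(range(len(intervals)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for na, nb, *_ in edges:
        ra, rb = find(na), find(nb)
        if ra != rb:
            parent[ra] = rb

    comp: dict[int, list[int]] = {}
    for idx in range(len(intervals)):
        comp.setdefault(find(idx), []).append(idx)

    families = []
    for members in comp.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda i: intervals[i][0])
        anchor = members[0]
        # orientation of each copy relative to the anchor via BFS over hits
        orient = {anchor: "+"}
        frontier = [anchor]
        adj: dict[int, list[tuple[int, str]]] = {}
        for na, nb, o, _i, _l in edges:
            adj.setdefault(na, []).append((nb, o))
            adj.setdefault(nb, []).append((na, o))
        while frontier:
            cur = frontier.pop()
            for nxt, o in adj.get(cur, []):
                if nxt in orient:
                    continue
                flip = {"+": "-", "-": "+"}
                orient[nxt] = orient[cur] if o == "+" else flip[orient[cur]]
                frontier.append(nxt)
        fam_hits = [e for e in edges if find(e[0]) == find(anchor)]
        best = max(fam_hits, key=lambda e: e[4])
        rel = [orient.get(i, "+") for i in members[1:]]
        if all(o == "+" for o in rel):
            rtype = "DR"
        elif all(o == "-" for o in rel):
            rtype = "IR"
        else:
            rtype = "DR/IR"
        families.append(
            RepeatFamily(
                family_id="",
                unit_length=best[4],
                identity=round(best[3], 2),
                copies=[(intervals[i][0], intervals[i][1], orient.get(i, "+")) for i in members],
                rtype=rtype,
            )
        )
    families.sort(key=lambda f: (-f.unit_length, f.copies[0][0]))
    for i, fam in enumerate(families, 1):
        fam.family_id = f"R{i}"
    return families


# ---------------------------------------------------------------------------
# genomic context


def classify_location(interval: tuple[int, int], record: GenomeRecord) -> str:
    """Context label: gene name, 'gene-intronK', or 'IGS (up, down)'."""
    genes = record.genes()
    if not genes and not any(f.ftype == "intron" for f in record.features):
        return "unannotated"
    lo, hi = interval
    for f in record.features:
        if f.ftype == "intron":
            s, e = f.spans[0]
            if lo >= s and hi <= e:
                idx = f.notes.get("intron_index", 1)
                return f"{f.gene}-intron{idx}"
    for f in genes:
        for s, e in f.spans:
            if lo < e and hi > s:
                return f.gene
        # inside a gap between consecutive spans of the same feature -> intron
        spans = sorted(f.spans)
        for k in range(len(spans) - 1):
            gap_s, gap_e = spans[k][1], spans[k + 1][0]
            if lo >= gap_s and hi <= gap_e:
                return f"{f.gene}-intron{k + 1}"
    # intergenic: nearest flanking genes in circular genome order
    L = len(record.sequence)
    circular = record.topology == "circular"

    def dist_before(f):
        d = lo - f.end
        if d < 0 and circular:
            d += L
        return d if d >= 0 else float("inf")

    def dist_after(f):
        d = f.start - hi
        if d < 0 and circular:
            d += L
        return d if d >= 0 else float("inf")

    up = min(genes, key=dist_before, default=None)
    down = min(genes, key=dist_after, default=None)
    if up is None or down is None:
        return "unannotated"
    return f"IGS ({up.gene}, {down.gene})"


def repeat_length_histogram(families, bin_width: int = 10, origin: int = 20) -> dict:
    """Counts of family unit lengths in fixed-width bins from `origin`."""
    hist: dict[int, int] = {}
    for fam in families:
        length = fam.unit_length if isinstance(fam, RepeatFamily) else int(fam)
        b = origin + bin_width * ((length - origin) // bin_width) if length >= origin else origin - bin_width
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items()))
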