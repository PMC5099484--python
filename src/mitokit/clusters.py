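"""Conserved gene-cluster detection across annotated genomes.

A cluster is a maximal run of >= 2 genes that appear adjacent (no
intervening annotated gene, junction gap <= max_gap) and in the same
relative order (forward or fully reversed) in every supporting genome.
Junction intervals use one signed formula for both gap and overlap cases:
downstream start - upstream end - 1 on 1-based inclusive coordinates
(equivalently start2 - end1 on the internal half-open convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import GenomeRecord


def junction_interval(end1: int, start2: int, one_based: bool = True,
                      wrapped: bool = False, genome_length: int | None = None) -> int:
    """Signed bp between two neighbouring genes (negative = overlap).

    `end1` is the upstream gene's end, `start2` the downstream gene's start.
    With one_based=True both are 1-based inclusive (as printed in genome
    tables); otherwise end1 is the exclusive end of a half-open span.  For a
    junction crossing the circular origin pass wrapped=True together with
    genome_length.
    """
    gap = start2 - end1 - 1 if one_based else start2 - end1
    if wrapped:
        if genome_length is None:
            raise ValueError("wrapped junction needs genome_length")
        gap += genome_length
    return gap


@dataclass
class GeneCluster:
    genes: list[str]
    intervals: list[int]  # signed bp per junction, from the first genome
    support: list[str]  # ids of genomes containing the cluster
    copy_count: int = 1
    strands: list[str] = field(default_factory=list)


def _gene_order(record: GenomeRecord):
    feats = [f for f in record.genes() ]
    feats.sort(key=lambda f: f.start)
    return feats


def _name_sequence(feats):
    return [f.gene.lower() for f in feats]


def _occurrences(feats, record, run, max_gap):
    """Count gap-valid occurrences of `run` (forward or reversed) as a
    consecutive gene subsequence, circular-aware."""
    n = len(feats)
    if n == 0 or len(run) > n:
        return 0
    names = [f.gene.lower() for f in feats]
    circular = record.topology == "circular"
    L = len(record.sequence)
    span = range(n) if circular else range(n - len(run) + 1)
    rev = list(reversed(run))
    hits = 0
    for i in span:
        idx = [(i + k) % n for k in range(len(run))]
        if not circular and any(j < i for j in idx):
            continue
        window = [names[j] for j in idx]
        if window != run and window != rev:
            continue
        ok = True
        for a, b in zip(idx, idx[1:]):
            gap = junction_interval(feats[a].end, feats[b].start, one_based=False,
                                    wrapped=circular and b < a, genome_length=L)
            if gap > max_gap:
                ok = False
                break
        if ok:
            hits += 1
    return hits


def find_clusters(records: list[GenomeRecord], max_gap: int = 2000) -> list[GeneCluster]:
    """Maximal gene runs conserved in every input genome."""
    if len(records) < 2:
        raise ValueError("need at least 2 annotated genomes")
    ref = records[0]
    feats = _gene_order(ref)
    names = _name_sequence(feats)
    n = len(feats)
    if n < 2:
        return []
    circular = ref.topology == "circular"
    L = len(ref.sequence)

    def junction(i, j):
        return junction_interval(feats[i].end, feats[j].start, one_based=False,
                                 wrapped=circular and j < i, genome_length=L)

    def gap_ok(i, j):
        return junction(i, j) <= max_gap

    others = [(r, _gene_order(r)) for r in records[1:]]

    def conserved(run):
        return all(_occurrences(ofeats, r, run, max_gap) >= 1
                   for r, ofeats in others)

    limit = n if circular else n - 1
    clusters: list[GeneCluster] = []
    covered: set[tuple] = set()
    for i in range(limit):
        j = (i + 1) % n
        if not gap_ok(i, j):
            continue
        run_idx = [i, j]
        if not conserved([names[k] for k in run_idx]):
            continue
        # extend right maximally
        while True:
            nxt = (run_idx[-1] + 1) % n
            if nxt == run_idx[0] or not gap_ok(run_idx[-1], nxt):
                break
            cand = run_idx + [nxt]
            if not conserved([names[k] for k in cand]):
                break
            run_idx = cand
        run_names = tuple(names[k] for k in run_idx)
        index_key = frozenset(run_idx)
        if index_key in covered or any(
            run_names == tuple(c[k : k + len(run_names)])
            for c in covered if isinstance(c, tuple)
            for k in range(len(c) - len(run_names) + 1)
        ):
            continue
        covered.add(run_names)
        covered.add(index_key)
        intervals = [junction(a, b) for a, b in zip(run_idx, run_idx[1:])]
        clusters.append(
            GeneCluster(
                genes=[feats[k].gene for k in run_idx],
                intervals=intervals,
                support=[r.id for r in records],
                copy_count=max(1, _occurrences(feats, ref, list(run_names), max_gap)),
                strands=[feats[k].strand for k in run_idx],
            )
        )
    # drop clusters wholly contained in a longer reported cluster
    final = []
    for c in clusters:
        contained = False
        for d in clusters:
            if c is d or len(c.genes) >= len(d.genes):
                continue
            dg = [g.lower() for g in d.genes]
            cg = [g.lower() for g in c.genes]
            for k in range(len(dg) - len(cg) + 1):
                if dg[k : k + len(cg)] == cg:
                    contained = True
                    break
            if contained:
                break
        if not contained:
            final.append(c)
    return final
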