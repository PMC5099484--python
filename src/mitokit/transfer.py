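"""Inter-genomic DNA transfer detection and synteny.

Covers cp->mt gene-fragment and tRNA transfer, mt->nucleus gene/tRNA
transfer (class thresholds: identity >= 80%, E <= 1e-10, coverage >= 50%;
tRNA copies at identity > 90%), long high-identity syntenic blocks, and
coding-SNP counting between corresponding gene copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignParams, AlignmentHit, filter_hits, global_align, seed_and_extend

log = logging.getLogger(__name__)

TRANSFER_THRESHOLDS = {
    "cp->mt gene-fragment": {"min_identity": 80.0, "evalue": 1e-10, "min_coverage": 50.0},
    "cp->mt tRNA": {"min_identity": 80.0, "evalue": 1e-10, "min_coverage": 50.0},
    "mt->nuc gene": {"min_identity": 80.0, "evalue": 1e-10, "min_coverage": 50.0},
    "mt->nuc tRNA": {"min_identity": 90.0, "evalue": 1e-10, "min_coverage": 50.0},
}


@dataclass
class TransferHit:
    source_gene: str
    source_copy: int
    target_start: int
    target_end: int
    strand: str
    identity: float
    coverage: float
    evalue: float
    transfer_class: str


def _default_params() -> AlignParams:
    # W=11 keeps random seed noise negligible at gene-vs-genome scale
    return AlignParams(word_size=11, evalue_cutoff=10.0)


def detect_gene_transfers(source_genes: dict, target_seq: str,
                          transfer_class: str = "mt->nuc gene",
                          params: AlignParams | None = None,
                          thresholds: dict | None = None) -> list[TransferHit]:
    """Per source gene: best passing hit plus non-overlapping secondary hits."""
    if not source_genes:
        raise ValueError("empty source gene set")
    if thresholds is None:
        thresholds = TRANSFER_THRESHOLDS[transfer_class]
    if params is None:
        params = _default_params()
    out: list[TransferHit] = []
    for name, seq in source_genes.items():
        gene, copy = (name if isinstance(name, tuple) else (name, 1))
        hits = seed_and_extend(seq, target_seq, params)
        passing = filter_hits(hits, thresholds["min_identity"],
                              thresholds["min_coverage"], thresholds["evalue"],
                              len(seq))
        passing.sort(key=lambda h: -h.score)
        accepted: list[AlignmentHit] = []
        for h in passing:
            if all(h.subject_end <= a.subject_start or h.subject_start >= a.subject_end
                   for a in accepted):
                accepted.append(h)
        for h in accepted:
            out.append(
                TransferHit(gene, copy, h.subject_start, h.subject_end,
                            h.orientation, round(h.identity, 2),
                            round(h.coverage(len(seq)), 2), h.evalue,
                            transfer_class)
            )
    return out


def classify_trna_origin(mt_trnas: dict, cp_trnas: dict,
                         thresholds: dict | None = None,
                         params: AlignParams | None = None) -> dict:
    """Partition mt tRNAs into 'native' / 'cp-derived' by cp-genome hits."""
    if thresholds is None:
        thresholds = TRANSFER_THRESHOLDS["cp->mt tRNA"]
    if params is None:
        params = AlignParams(word_size=7, evalue_cutoff=10.0)
    result = {}
    for name, seq in mt_trnas.items():
        derived = False
        for cp_seq in cp_trnas.values():
            hits = seed_and_extend(seq, cp_seq, params)
            if filter_hits(hits, thresholds["min_identity"],
                           thresholds["min_coverage"], thresholds["evalue"], len(seq)):
                derived = True
                break
        result[name] = "cp-derived" if derived else "native"
    return result


# ---------------------------------------------------------------------------
# synteny


@dataclass
class SyntenyBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    identity: float
    orientation: str
    genes: list = field(default_factory=list)
    order_conserved: bool = True


def find_synteny_blocks(seq_a: str, seq_b: str, min_len: int = 10_000,
                        min_identity: float = 99.5,
                        params: AlignParams | None = None,
                        record_a=None) -> list[SyntenyBlock]:
    """Chained co-linear local hits merged into maximal blocks.

    `record_a` (optional annotated GenomeRecord for seq_a) fills in carried
    gene content and the order-conservation flag.
    """
    if not seq_a or not seq_b:
        return []
    if params is None:
        # long exact seeds: random collisions vanish at genome scale
        params = AlignParams(word_size=31, evalue_cutoff=1e-6)
    hits = seed_and_extend(seq_a, seq_b, params)
    blocks: list[SyntenyBlock] = []
    hits.sort(key=lambda h: h.query_start)
    used = [False] * len(hits)
    for i, h in enumerate(hits):
        if used[i]:
            continue
        used[i] = True
        qa, qe, sa, se = h.query_start, h.query_end, h.subject_start, h.subject_end
        matches, alen = h.matches, h.aligned_length
        diag = h.query_start - h.subject_start
        for j in range(i + 1, len(hits)):
            g = hits[j]
            if used[j] or g.orientation != h.orientation:
                continue
            if abs((g.query_start - g.subject_start) - diag) > 2000:
                continue
            if g.query_start > qe + 5000:
                continue
            used[j] = True
            qa, qe = min(qa, g.query_start), max(qe, g.query_end)
            sa, se = min(sa, g.subject_start), max(se, g.subject_end)
            matches += g.matches
            alen += g.aligned_length
        identity = 100.0 * matches / alen if alen else 0.0
        length = qe - qa
        if length >= min_len and identity >= min_identity:
            block = SyntenyBlock(qa, qe, sa, se, length, round(identity, 2),
                                 h.orientation)
            if record_a is not None:
                carried = [f for f in record_a.genes()
                           if f.start >= qa and f.end <= qe]
                carried.sort(key=lambda f: f.start)
                block.genes = [(f.gene, f.copy_index) for f in carried]
                block.order_conserved = True  # single co-linear chain by construction
            blocks.append(block)
    blocks.sort(key=lambda b: b.a_start)
    return blocks


# ---------------------------------------------------------------------------
# SNP accounting


@dataclass
class SnpLedger:
    aligned_bp: int = 0
    substitutions: int = 0
    per_gene: dict = field(default_factory=dict)


def count_coding_snps(pairs: dict) -> SnpLedger:
    """Substitution columns over match columns of global gene-pair alignments.

    `pairs` maps gene name -> (seq_a, seq_b).  Indel columns are excluded
    from both tallies; pairs under 50% identity are skipped with a warning.
    """
    ledger = SnpLedger()
    for gene, (a, b) in pairs.items():
        if a == b:
            aligned, snps = len(a), 0
        else:
            aa, bb = global_align(a, b)
            aligned = snps = matches = 0
            for x, y in zip(aa, bb):
                if x == "-" or y == "-":
                    continue
                aligned += 1
                if x == y:
                    matches += 1
                else:
                    snps += 1
            if aligned == 0 or matches / aligned < 0.5:
                log.warning("gene %s: pair unalignable (<50%% identity), skipped", gene)
                continue
        ledger.aligned_bp += aligned
        ledger.substitutions += snps
        ledger.per_gene[gene] = {"aligned_bp": aligned, "snps": snps}
    return ledger
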