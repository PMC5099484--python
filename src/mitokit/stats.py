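"""Annotation-driven genome accounting: composition, codon survey,
intron census, and grouped gene inventory."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import GenomeRecord, extract_sequence

log = logging.getLogger(__name__)

TRANS_SPLICE_GAP = 50_000  # consecutive exons farther apart are called trans-spliced

_STOPS = {"TAA", "TAG", "TGA"}

GENE_CLASSES = [
    ("Complex I (NADH dehydrogenase)", ("nad",)),
    ("Complex II (succinate dehydrogenase)", ("sdh",)),
    ("Complex III (ubiquinol cytochrome c reductase)", ("cob",)),
    ("Complex IV (cytochrome c oxidase)", ("cox",)),
    ("Complex V (ATP synthase)", ("atp",)),
    ("Cytochrome c biogenesis", ("ccm",)),
    ("Ribosomal proteins (SSU)", ("rps",)),
    ("Ribosomal proteins (LSU)", ("rpl",)),
    ("Maturases", ("matr",)),
    ("Transport membrane protein", ("mttb",)),
    ("Ribosomal RNAs", ("rrn",)),
    ("Transfer RNAs", ("trn",)),
]


def _union_size(spans) -> int:
    spans = sorted(spans)
    total = 0
    cur_s = cur_e = None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _base_percents(seq_parts: list[str]) -> dict:
    counts = {b: 0 for b in "ACGT"}
    for part in seq_parts:
        for b in "ACGT":
            counts[b] += part.count(b)
    denom = sum(counts.values())  # N bases excluded from denominators
    if denom == 0:
        return {b: 0.0 for b in "ACGT"} | {"GC": 0.0}
    out = {b: 100.0 * counts[b] / denom for b in "ACGT"}
    out["GC"] = out["C"] + out["G"]
    return out


def _cis_intron_spans(record: GenomeRecord) -> list[tuple[int, int]]:
    spans = [f.spans[0] for f in record.features if f.ftype == "intron"]
    if spans:
        return spans
    # derive from gaps between co-located exons of multi-span CDS features
    for f in record.features:
        if f.ftype != "CDS" or len(f.spans) < 2:
            continue
        ordered = sorted(f.spans)
        for k in range(len(ordered) - 1):
            gap = ordered[k + 1][0] - ordered[k][1]
            if 0 < gap <= TRANS_SPLICE_GAP:
                spans.append((ordered[k][1], ordered[k + 1][0]))
    return spans


@dataclass
class CompositionReport:
    categories: dict = field(default_factory=dict)  # name -> dict(bp, pct, A,C,G,T,GC)

    def __getitem__(self, key):
        return self.categories[key]


def composition_report(record: GenomeRecord) -> CompositionReport:
    """Nucleotide accounting per category; overlaps count once per category
    and once in the coding union; GC is computed over non-N bases."""
    L = len(record.sequence)
    cat_spans = {
        "CDS": [s for f in record.features if f.ftype == "CDS" for s in f.spans],
        "cis-introns": _cis_intron_spans(record),
        "tRNA": [s for f in record.features if f.ftype == "tRNA" for s in f.spans],
        "rRNA": [s for f in record.features if f.ftype == "rRNA" for s in f.spans],
    }
    report = CompositionReport()
    report.categories["genome"] = {
        "bp": L, "pct": 100.0, **_base_percents([record.sequence]),
    }
    all_coding = []
    for name, spans in cat_spans.items():
        bp = _union_size(spans)
        parts = [record.sequence[s:e] for s, e in spans]
        report.categories[name] = {
            "bp": bp, "pct": 100.0 * bp / L, **_base_percents(parts),
        }
        all_coding.extend(spans)
    bp = _union_size(all_coding)
    merged = sorted(all_coding)
    parts = []
    cur_s = cur_e = None
    for s, e in merged:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                parts.append(record.sequence[cur_s:cur_e])
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        parts.append(record.sequence[cur_s:cur_e])
    report.categories["coding"] = {"bp": bp, "pct": 100.0 * bp / L, **_base_percents(parts)}
    report.categories["non-coding"] = {"bp": L - bp, "pct": 100.0 * (L - bp) / L}
    return report


def codon_survey(record: GenomeRecord) -> list[dict]:
    """Start/stop codons of every spliced CDS with anomaly flags."""
    rows = []
    for f in record.features:
        if f.ftype != "CDS":
            continue
        cds = extract_sequence(record, f)
        if len(cds) < 6:
            raise ValueError(f"CDS {f.gene} shorter than 6 nt")
        start, stop = cds[:3], cds[-3:]
        if start == "ATG":
            flag = "normal"
        elif start == "ACG":
            flag = "ACG-start"
        else:
            flag = "unknown-start"
        if stop == "CGA":
            flag = flag + "+CGA-stop" if flag != "normal" else "CGA-stop"
        elif stop not in _STOPS:
            flag = flag + "+unknown-stop" if flag != "normal" else "unknown-stop"
        rows.append(
            {"gene": f.gene, "copy": f.copy_index, "start_codon": start,
             "stop_codon": stop, "flag": flag,
             "editing_note": "C-to-U editing restores UGA" if stop == "CGA" else ""}
        )
    return rows


def intron_census(record: GenomeRecord) -> dict:
    """Per-gene cis/trans-spliced intron counts.

    A junction between consecutive exons is trans when the exons are more
    than TRANS_SPLICE_GAP apart or belong to separately annotated parts of
    the same gene copy (opposite strands / distant loci)."""
    groups: dict[tuple[str, int], list] = {}
    for f in record.features:
        if f.ftype == "CDS":
            groups.setdefault((f.gene.lower(), f.copy_index), []).append(f)
    per_gene: dict[tuple[str, int], dict] = {}
    for key, parts in groups.items():
        cis = trans = 0
        for f in parts:
            ordered = sorted(f.spans)
            for k in range(len(ordered) - 1):
                gap = ordered[k + 1][0] - ordered[k][1]
                if gap > TRANS_SPLICE_GAP:
                    trans += 1
                else:
                    cis += 1
        trans += len(parts) - 1  # junctions between separately annotated parts
        per_gene[key] = {"gene": parts[0].gene, "copy": key[1], "cis": cis, "trans": trans}
    totals = {
        "cis": sum(g["cis"] for g in per_gene.values()),
        "trans": sum(g["trans"] for g in per_gene.values()),
    }
    return {"per_gene": per_gene, "totals": totals}


def gene_content_table(record: GenomeRecord) -> dict:
    """Genes grouped by functional class with '(xN)' copy annotations."""
    seen: dict[tuple[str, str], int] = {}
    for f in record.features:
        if f.ftype not in ("CDS", "tRNA", "rRNA"):
            continue
        key = (f.gene, f.ftype)
        seen[key] = max(seen.get(key, 0), f.copy_index)
    table: dict[str, list[str]] = {}
    for (gene, _ftype), copies in sorted(seen.items()):
        cls = None
        low = gene.lower()
        for cname, prefixes in GENE_CLASSES:
            if any(low.startswith(p) for p in prefixes):
                cls = cname
                break
        if cls is None:
            log.warning("gene %s has no functional class; filed under 'other'", gene)
            cls = "other"
        label = gene if copies == 1 else f"{gene} (x{copies})"
        table.setdefault(cls, []).append(label)
    return table
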