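"""Sequence/annotation I/O and the shared genome data model.

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive conventions of GenBank/GFF3 happens only at format boundaries.
Features on circular records that span the origin are stored as wrapped
span pairs, never as negative or out-of-range coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "intron", "exon", "misc")

_EXON_SUFFIX = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN symbols to N; returns (seq, n_substituted)."""
    up = seq.upper()
    if set(up) <= VALID_BASES:
        return up, 0
    cleaned = []
    n_sub = 0
    for ch in up:
        if ch in VALID_BASES:
            cleaned.append(ch)
        else:
            cleaned.append("N")
            n_sub += 1
    if n_sub:
        log.warning("substituted %d non-ACGTN symbols with N", n_sub)
    return "".join(cleaned), n_sub


def normalize_gene_name(name: str) -> tuple[str, int | None]:
    """Split exon qualifiers off a gene label, case-insensitively.

    'nad1d' -> ('nad1', 4); 'cox2-exon1' -> ('cox2', 1); 'matR' -> ('matR', None).
    """
    name = name.strip()
    low = name.lower()
    if "-exon" in low:
        stem, _, idx = low.rpartition("-exon")
        try:
            return name[: len(stem)], int(idx)
        except ValueError:
            return name, None
    # trailing single letter a-e on a name ending in a digit+letter (nad1d)
    if len(low) > 2 and low[-1] in _EXON_SUFFIX and low[-2].isdigit():
        return name[:-1], _EXON_SUFFIX[low[-1]]
    return name, None


@dataclass
class Feature:
    """One annotated element; multi-exon features carry several spans."""

    gene: str
    ftype: str
    strand: str
    spans: list[tuple[int, int]]
    copy_index: int = 1
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type: {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.spans:
            raise ValueError("feature must have at least one span")
        for s, e in self.spans:
            if not (0 <= s < e):
                raise ValueError(f"invalid span [{s},{e})")
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)

    def key(self) -> tuple[str, int]:
        return (self.gene.lower(), self.copy_index)


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self._validate_features()

    def _validate_features(self):
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.spans:
                if e > L:
                    raise ValueError(
                        f"feature {f.gene} span [{s},{e}) beyond record length {L}"
                    )
        self.features.sort(key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.sequence)

    def add_feature(self, feature: Feature) -> None:
        self.features.append(feature)
        self._validate_features()

    def genes(self, ftypes=("CDS", "tRNA", "rRNA")) -> list[Feature]:
        return [f for f in self.features if f.ftype in ftypes]

    def flip(self) -> "GenomeRecord":
        """Reverse-complement the whole record, remapping all features."""
        L = len(self.sequence)
        flipped = []
        for f in self.features:
            spans = sorted((L - e, L - s) for s, e in f.spans)
            strand = "-" if f.strand == "+" else "+"
            flipped.append(replace(f, spans=spans, strand=strand))
        return GenomeRecord(self.id, reverse_complement(self.sequence),
                            self.topology, flipped)

    def rotate(self, k: int) -> "GenomeRecord":
        """Rotate a circular record so old position k becomes position 0."""
        if self.topology != "circular":
            raise ValueError("can only rotate circular records")
        L = len(self.sequence)
        k %= L
        new_seq = self.sequence[k:] + self.sequence[:k]
        new_feats = []
        for f in self.features:
            spans = []
            for s, e in f.spans:
                ns, ne = (s - k) % L, (e - k) % L
                if ne == 0:
                    ne = L
                if ns < ne:
                    spans.append((ns, ne))
                else:  # span now wraps the new origin
                    spans.append((ns, L))
                    spans.append((0, ne))
            new_feats.append(replace(f, spans=spans))
        return GenomeRecord(self.id, new_seq, self.topology, new_feats)


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords; non-ACGTN bases become N."""
    records = []
    seen = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq, _ = sanitize_sequence(str(rec.seq))
        records.append(GenomeRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    if isinstance(records, GenomeRecord):
        records = [records]
    with open(path, "w") as fh:
        for rec in records:
            topo = " circular" if rec.topology == "circular" else ""
            fh.write(f">{rec.id}{topo}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _biofeature_to_feature(bio_feat, length: int, circular: bool) -> Feature | None:
    ftype = bio_feat.type
    if ftype not in FEATURE_TYPES:
        return None
    quals = bio_feat.qualifiers
    gene = (quals.get("gene") or quals.get("product") or quals.get("locus_tag") or ["?"])[0]
    strand = "-" if bio_feat.location.strand == -1 else "+"
    spans = []
    for part in bio_feat.location.parts:
        s, e = int(part.start), int(part.end)
        if e > length:
            if not circular:
                raise ValueError(
                    f"feature {gene} [{s},{e}) beyond linear record length {length}"
                )
            spans.append((s, length))
            spans.append((0, e - length))
        else:
            spans.append((s, e))
    notes = {}
    if "note" in quals:
        notes["note"] = quals["note"][0]
    return Feature(gene=gene, ftype=ftype, strand=strand, spans=spans, notes=notes)


def read_genbank(path) -> GenomeRecord:
    """Parse a GenBank flat file into a GenomeRecord.

    1-based inclusive locations become 0-based half-open spans; join()
    becomes a multi-span feature; 'circular' in the LOCUS line sets topology.
    Duplicated gene names get incrementing copy_index in file order.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = _BioSeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq:
        raise ValueError(f"GenBank record {rec.id} has no ORIGIN sequence")
    seq, _ = sanitize_sequence(seq)
    circular = rec.annotations.get("topology", "linear") == "circular"
    topology = "circular" if circular else "linear"
    features = []
    copy_counter: dict[tuple[str, str], int] = {}
    for bf in rec.features:
        f = _biofeature_to_feature(bf, len(seq), circular)
        if f is None:
            continue
        key = (f.gene.lower(), f.ftype)
        copy_counter[key] = copy_counter.get(key, 0) + 1
        f.copy_index = copy_counter[key]
        features.append(f)
    return GenomeRecord(rec.id, seq, topology, features)


def extract_sequence(record: GenomeRecord, feature: Feature) -> str:
    """Spliced feature sequence: spans concatenated, revcomped on '-'."""
    L = len(record.sequence)
    parts = []
    for s, e in feature.spans:
        if e > L or s < 0:
            raise ValueError(f"span [{s},{e}) outside record of length {L}")
        parts.append(record.sequence[s:e])
    seq = "".join(parts)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# tabular / annotation writers

_GFF_COLS = "seqid source type start end score strand phase attributes".split()


def write_gff(record: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {len(record)}\n")
        for f in record.features:
            if f.ftype not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {f.ftype}")
            attrs = f"ID={f.gene}.{f.copy_index};gene={f.gene};copy_index={f.copy_index}"
            if "intron_index" in f.notes:
                attrs += f";intron_index={f.notes['intron_index']}"
            for i, (s, e) in enumerate(f.spans):
                part = attrs if len(f.spans) == 1 else f"{attrs};part={i + 1}"
                fh.write(
                    "\t".join(
                        [
                            record.id,
                            "mitokit",
                            f.ftype,
                            str(s + 1),
                            str(e),
                            ".",
                            f.strand,
                            ".",
                            part,
                        ]
                    )
                    + "\n"
                )


def read_gff(path, sequence: str = "N", topology: str = "linear") -> GenomeRecord:
    """Read features back from a GFF3 written by write_gff."""
    feats: dict[tuple[str, str, int], Feature] = {}
    rec_id, rec_len = "gff", None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, rec_id, _, end = line.split()
                rec_len = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = line.split("\t")
            rec_id = seqid
            a = dict(kv.split("=", 1) for kv in attrs.split(";"))
            gene = a.get("gene", a.get("ID", "?"))
            copy_index = int(a.get("copy_index", 1))
            span = (int(start) - 1, int(end))
            notes = {}
            if "intron_index" in a:
                notes["intron_index"] = int(a["intron_index"])
            key = (gene, ftype, copy_index, a.get("intron_index"))
            if key in feats:
                feats[key].spans.append(span)
            else:
                feats[key] = Feature(gene, ftype, strand, [span], copy_index, notes)
    if sequence == "N" and rec_len:
        sequence = "N" * rec_len
    return GenomeRecord(rec_id, sequence, topology, list(feats.values()))


def write_bed(record: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f'track name="{record.id}"\n')
        for f in record.features:
            if f.ftype not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {f.ftype}")
            for s, e in f.spans:
                fh.write(
                    f"{record.id}\t{s}\t{e}\t{f.gene}.{f.copy_index}\t0\t{f.strand}\n"
                )


def write_tsv(rows, path, columns=None) -> None:
    """Write a list of dicts (or a pandas DataFrame) to TSV."""
    import pandas as pd

    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows), columns=columns)
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contig graphs (GFA 1.0 + depth TSV)


@dataclass
class ContigGraph:
    """Contig adjacency graph; nodes carry sequence/depth, edges join ends.

    Edge ends are '5' or '3'. An edge (a, ea, b, eb, support) says the ea end
    of contig a abuts the eb end of contig b in the underlying genome.
    """

    nodes: dict = field(default_factory=dict)  # id -> dict(sequence, depth, length)
    edges: list = field(default_factory=list)  # (a, end_a, b, end_b, support)

    def add_node(self, cid: str, sequence: str, depth: float) -> None:
        if depth < 0:
            raise ValueError("depth must be >= 0")
        self.nodes[cid] = {"sequence": sequence, "depth": float(depth), "length": len(sequence)}

    def add_edge(self, a: str, end_a: str, b: str, end_b: str, support: int = 1) -> None:
        for cid in (a, b):
            if cid not in self.nodes:
                raise ValueError(f"edge references unknown contig {cid}")
        if end_a not in ("5", "3") or end_b not in ("5", "3"):
            raise ValueError("ends must be '5' or '3'")
        self.edges.append((a, end_a, b, end_b, int(support)))

    def copy(self) -> "ContigGraph":
        g = ContigGraph()
        g.nodes = {k: dict(v) for k, v in self.nodes.items()}
        g.edges = list(self.edges)
        return g


def write_gfa(graph: ContigGraph, gfa_path, depth_path=None) -> None:
    with open(gfa_path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for cid in sorted(graph.nodes):
            node = graph.nodes[cid]
            fh.write(f"S\t{cid}\t{node['sequence']}\tDP:f:{node['depth']:.2f}\n")
        for a, ea, b, eb, sup in graph.edges:
            # GFA: '+' means the 3' end of the from-segment joins the 5' end
            # of the to-segment.  Our end-labelled edges map onto orientations.
            oa = "+" if ea == "3" else "-"
            ob = "+" if eb == "5" else "-"
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\tRC:i:{sup}\n")
    if depth_path:
        with open(depth_path, "w") as fh:
            fh.write("contig_id\tdepth\tlength\n")
            for cid in sorted(graph.nodes):
                node = graph.nodes[cid]
                fh.write(f"{cid}\t{node['depth']:.2f}\t{node['length']}\n")


def read_gfa(gfa_path, depth_path=None) -> ContigGraph:
    graph = ContigGraph()
    links = []
    with open(gfa_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                cid, seq = parts[1], parts[2]
                depth = 0.0
                for tag in parts[3:]:
                    if tag.startswith("DP:f:"):
                        depth = float(tag[5:])
                graph.add_node(cid, seq, depth)
            elif parts[0] == "L":
                links.append(parts)
    for parts in links:
        a, oa, b, ob = parts[1], parts[2], parts[3], parts[4]
        sup = 1
        for tag in parts[6:]:
            if tag.startswith("RC:i:"):
                sup = int(tag[5:])
        ea = "3" if oa == "+" else "5"
        eb = "5" if ob == "+" else "3"
        graph.add_edge(a, ea, b, eb, sup)
    if depth_path:
        with open(depth_path) as fh:
            header = fh.readline()
            assert header.startswith("contig_id")
            for line in fh:
                cid, depth, _length = line.rstrip("\n").split("\t")
                if cid in graph.nodes:
                    graph.nodes[cid]["depth"] = float(depth)
    return graph
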