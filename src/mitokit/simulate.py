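"""Synthetic genomes with planted, machine-readable truth.

Every downstream stage is exercised on output of this module: circular
mitochondrial genomes with planted genes, SSRs, tandem and dispersed
repeats; nuclear chromosomes carrying recently transferred blocks; sheared
contig graphs with repeat-induced depth multiplicities; and CDS sets with
planted C-to-U edit sites plus matching reference protein panels.

All randomness flows through one numpy Generator; a fixed SimConfig
(including seed) yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ContigGraph, Feature, GenomeRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

from Bio.Data import CodonTable as _CodonTable

_standard = _CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    GENETIC_CODE[_stop] = "*"

_AA20 = sorted(set(GENETIC_CODE.values()) - {"*"})


def translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    gc_target: float = 0.45
    gene_catalog: list = field(default_factory=list)  # (name, n_codons, exon_split)
    planted_ssrs: list = field(default_factory=list)  # (motif, copies, position|None)
    planted_tandems: list = field(default_factory=list)  # (unit, copies, position|None)
    planted_dispersed: list = field(default_factory=list)  # (length, identity%, 'DR'|'IR', n_copies)
    transfer_blocks: list = field(default_factory=list)  # (mt_start, mt_end, rate)
    edit_sites: list = field(default_factory=list)
    read_depth: float = 30.0
    nuclear_length: int = 200_000

    def __post_init__(self):
        for blk in self.transfer_blocks:
            if blk[2] >= 1 or blk[2] < 0:
                raise ValueError("mutation rate must be in [0,1)")


@dataclass
class TruthTable:
    ssrs: list = field(default_factory=list)
    tandems: list = field(default_factory=list)
    dispersed: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    blocks: list = field(default_factory=list)
    edits: list = field(default_factory=list)
    path: list = field(default_factory=list)
    contigs: dict = field(default_factory=dict)

    def to_rows(self):
        rows = []
        for kind in ("ssrs", "tandems", "genes", "blocks", "edits"):
            for entry in getattr(self, kind):
                rows.append({"kind": kind[:-1], **entry})
        for fam in self.dispersed:
            for i, (s, e, o) in enumerate(fam["copies"], 1):
                rows.append(
                    {"kind": "dispersed", "family": fam["family"], "copy": i,
                     "start": s, "end": e, "orientation": o}
                )
        return rows


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def random_cds(rng: np.random.Generator, n_codons: int,
               start: str = "ATG", stop: str = "TAA") -> str:
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)]
    return start + "".join(body) + stop


def mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """I.i.d. substitutions at `rate`; returns (mutated, n_changes)."""
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), n


class _Allocator:
    """Non-overlapping interval placement over [0, length)."""

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 25):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def _free(self, s: int, e: int) -> bool:
        if s < 0 or e > self.length:
            return False
        for ts, te in self.taken:
            if s < te + self.margin and e + self.margin > ts:
                return False
        return True

    def place(self, size: int, position: int | None = None) -> int:
        if position is not None:
            if not self._free(position, position + size):
                raise ValueError(f"planted element at {position} (+{size}) overlaps or exceeds length")
            self.taken.append((position, position + size))
            return position
        for _ in range(2000):
            s = int(self.rng.integers(0, self.length - size))
            if self._free(s, s + size):
                self.taken.append((s, s + size))
                return s
        raise ValueError("could not place element: genome too crowded")


def _guard_flanks(seq: list, start: int, end: int, period: int, rng) -> None:
    """Break accidental periodic extension of a planted repeat into its flanks."""
    if start - 1 >= 0 and seq[start - 1] == seq[start - 1 + period]:
        alts = [b for b in "ACGT" if b != seq[start - 1 + period]]
        seq[start - 1] = alts[int(rng.integers(0, 3))]
    if end < len(seq) and seq[end] == seq[end - period]:
        alts = [b for b in "ACGT" if b != seq[end - period]]
        seq[end] = alts[int(rng.integers(0, 3))]


def simulate_mitogenome(config: SimConfig) -> tuple[GenomeRecord, TruthTable]:
    rng = np.random.default_rng(config.seed)
    seq = list(random_sequence(rng, config.genome_length, config.gc_target))
    alloc = _Allocator(config.genome_length, rng)
    truth = TruthTable()
    features: list[Feature] = []

    copy_counter: dict[str, int] = {}
    for entry in config.gene_catalog:
        name, n_codons = entry[0], entry[1]
        exon_split = entry[2] if len(entry) > 2 else None
        strand = entry[3] if len(entry) > 3 else ("+" if rng.random() < 0.5 else "-")
        start_codon = entry[4] if len(entry) > 4 else "ATG"
        stop_codon = entry[5] if len(entry) > 5 else "TAA"
        cds = random_cds(rng, n_codons, start_codon, stop_codon)
        if exon_split:
            exon_lens = list(exon_split)
            assert sum(exon_lens) == len(cds)
        else:
            exon_lens = [len(cds)]
        intron_lens = [int(rng.integers(80, 400)) for _ in range(len(exon_lens) - 1)]
        footprint = sum(exon_lens) + sum(intron_lens)
        pos = alloc.place(footprint)
        spans = []
        cursor = pos
        pieces = cds if strand == "+" else reverse_complement(cds)
        # carve exons in genomic order; '-' strand stores revcomp pieces
        exon_order = exon_lens if strand == "+" else exon_lens[::-1]
        off = 0
        for k, el in enumerate(exon_order):
            seq[cursor : cursor + el] = list(pieces[off : off + el])
            spans.append((cursor, cursor + el))
            off += el
            if k < len(intron_lens):
                cursor += el + intron_lens[k]
            else:
                cursor += el
        copy_counter[name.lower()] = copy_counter.get(name.lower(), 0) + 1
        feat = Feature(name, "CDS", strand, spans, copy_index=copy_counter[name.lower()])
        features.append(feat)
        for k in range(len(spans) - 1):
            features.append(
                Feature(name, "intron", strand, [(spans[k][1], spans[k + 1][0])],
                        copy_index=copy_counter[name.lower()],
                        notes={"intron_index": k + 1})
            )
        truth.genes.append(
            {"gene": name, "copy": copy_counter[name.lower()], "start": pos,
             "end": spans[-1][1], "strand": strand, "cds": cds}
        )

    for motif, copies, *rest in config.planted_ssrs:
        position = rest[0] if rest else None
        run = motif * copies
        pos = alloc.place(len(run), position)
        seq[pos : pos + len(run)] = list(run)
        _guard_flanks(seq, pos, pos + len(run), len(motif), rng)
        truth.ssrs.append(
            {"motif": motif, "copies": copies, "start": pos, "end": pos + len(run)}
        )

    for unit, copies, *rest in config.planted_tandems:
        position = rest[0] if rest else None
        run = unit * copies
        pos = alloc.place(len(run), position)
        seq[pos : pos + len(run)] = list(run)
        _guard_flanks(seq, pos, pos + len(run), len(unit), rng)
        truth.tandems.append(
            {"unit": unit, "period": len(unit), "copies": copies,
             "start": pos, "end": pos + len(run)}
        )

    for fam_idx, (length, identity, orientation, n_copies) in enumerate(config.planted_dispersed, 1):
        rate = max(0.0, 1.0 - identity / 100.0)
        src = alloc.place(length)
        unit = "".join(seq[src : src + length])
        copies = [(src, src + length, "+")]
        for _ in range(n_copies - 1):
            pos = alloc.place(length)
            variant, _n = mutate(rng, unit, rate)
            if orientation == "IR":
                variant = reverse_complement(variant)
            seq[pos : pos + length] = list(variant)
            copies.append((pos, pos + length, "+" if orientation == "DR" else "-"))
        copies.sort(key=lambda c: c[0])
        truth.dispersed.append(
            {"family": f"P{fam_idx}", "length": length, "identity": identity,
             "orientation": orientation, "copies": copies}
        )

    record = GenomeRecord("sim_mt", "".join(seq), "circular", features)
    return record, truth


def simulate_nuclear_chromosome(mt_record: GenomeRecord, config: SimConfig
                                ) -> tuple[GenomeRecord, TruthTable]:
    """Nuclear background carrying mt blocks with i.i.d. substitutions."""
    rng = np.random.default_rng(config.seed + 1)
    seq = list(random_sequence(rng, config.nuclear_length, config.gc_target))
    alloc = _Allocator(config.nuclear_length, rng)
    truth = TruthTable()
    for mt_start, mt_end, rate in config.transfer_blocks:
        if rate >= 1:
            raise ValueError("mutation rate must be < 1")
        if not (0 <= mt_start < mt_end <= len(mt_record.sequence)):
            raise ValueError("block interval outside mt record")
        block = mt_record.sequence[mt_start:mt_end]
        mutated, n = mutate(rng, block, rate)
        pos = alloc.place(len(block))
        seq[pos : pos + len(block)] = list(mutated)
        realized_identity = 100.0 * (len(block) - n) / len(block)
        carried = [
            (f.gene, f.copy_index)
            for f in mt_record.genes(("CDS", "tRNA", "rRNA"))
            if f.start >= mt_start and f.end <= mt_end
        ]
        carried.sort(key=lambda g: next(
            f.start for f in mt_record.features if (f.gene, f.copy_index) == g and f.ftype != "intron"
        ))
        truth.blocks.append(
            {"mt_start": mt_start, "mt_end": mt_end,
             "nuc_start": pos, "nuc_end": pos + len(block),
             "identity": realized_identity, "genes": carried}
        )
    return GenomeRecord("sim_chr", "".join(seq), "linear"), truth


# ---------------------------------------------------------------------------
# contig graphs


def simulate_contig_graph(record: GenomeRecord, truth: TruthTable, config: SimConfig,
                          decoys: list | None = None
                          ) -> tuple[ContigGraph, TruthTable]:
    """Shear a circular genome into a contig graph at repeat boundaries.

    Copies of each planted dispersed family collapse onto one repeat contig
    whose depth scales with copy number; unique inter-repeat stretches become
    unique contigs; edges follow true genome adjacency.  `decoys` adds
    unconnected (or weakly connected) off-window contigs:
    [(name, length, depth)].
    """
    rng = np.random.default_rng(config.seed + 2)
    L = len(record.sequence)
    cuts = set()
    repeat_at: dict[int, tuple[str, str]] = {}  # start -> (family_contig_id, orientation)
    fam_seq: dict[str, str] = {}
    for fam in truth.dispersed:
        cid = "repeat_" + fam["family"]
        first = fam["copies"][0]
        fam_seq[cid] = record.sequence[first[0] : first[1]]
        for s, e, orient in fam["copies"]:
            cuts.add(s)
            cuts.add(e)
            repeat_at[s] = (cid, orient)
    cuts = sorted(cuts)
    graph = ContigGraph()
    gtruth = TruthTable()
    base_depth = config.read_depth

    segments: list[tuple[str, str]] = []  # (contig_id, orientation) in genome order
    if not cuts:
        n_pieces = max(3, min(8, L // 5000))
        bounds = sorted(set([0] + list(rng.integers(1, L, size=n_pieces - 1))))
        for i, b in enumerate(bounds):
            nb = bounds[i + 1] if i + 1 < len(bounds) else L
            cid = f"contig{i:05d}"
            graph.add_node(cid, record.sequence[b:nb], _noisy(rng, base_depth))
            segments.append((cid, "+"))
    else:
        uniq_idx = 0
        pos = 0
        boundaries = cuts + [L]
        if cuts[0] != 0:
            boundaries = [0] + boundaries
        for i in range(len(boundaries) - 1):
            s, e = boundaries[i], boundaries[i + 1]
            if s == e:
                continue
            if s in repeat_at and any(s == cs and e == ce for cs, ce, _o in _all_copies(truth)):
                cid, orient = repeat_at[s]
                if cid not in graph.nodes:
                    n_cop = len(next(f for f in truth.dispersed
                                     if "repeat_" + f["family"] == cid)["copies"])
                    graph.add_node(cid, fam_seq[cid], _noisy(rng, base_depth * n_cop))
                segments.append((cid, orient))
            else:
                cid = f"contig{uniq_idx:05d}"
                uniq_idx += 1
                graph.add_node(cid, record.sequence[s:e], _noisy(rng, base_depth))
                segments.append((cid, "+"))
        pos = boundaries[-1]

    # circular adjacency edges; orientation decides which ends meet
    n_seg = len(segments)
    for i in range(n_seg):
        a, oa = segments[i]
        b, ob = segments[(i + 1) % n_seg]
        end_a = "3" if oa == "+" else "5"
        end_b = "5" if ob == "+" else "3"
        graph.add_edge(a, end_a, b, end_b, support=int(rng.integers(5, 20)))

    if decoys:
        candidates = list(graph.nodes)
        for name, length, depth in decoys:
            graph.add_node(name, random_sequence(rng, length, config.gc_target), depth)
            # spurious weak link into the real graph
            target = candidates[int(rng.integers(0, len(candidates)))]
            graph.add_edge(name, "3", target, "5", support=1)

    gtruth.path = segments
    gtruth.contigs = {cid: dict(graph.nodes[cid]) for cid in graph.nodes}
    return graph, gtruth


def _all_copies(truth: TruthTable):
    for fam in truth.dispersed:
        yield from fam["copies"]


def _noisy(rng, depth: float) -> float:
    return float(max(0.5, depth * (1.0 + rng.normal(0, 0.03))))


def simulate_reads(record: GenomeRecord, coverage: float = 20.0,
                   read_length: int = 300, seed: int = 0) -> list[str]:
    """Error-free reads as random windows; circular records wrap."""
    rng = np.random.default_rng(seed)
    L = len(record.sequence)
    n_reads = int(coverage * L / read_length)
    doubled = record.sequence + record.sequence if record.topology == "circular" else record.sequence
    limit = L if record.topology == "circular" else L - read_length
    reads = []
    for _ in range(max(1, n_reads)):
        s = int(rng.integers(0, max(1, limit)))
        reads.append(doubled[s : s + read_length])
    return reads


# ---------------------------------------------------------------------------
# RNA-editing plants


def plant_edits(cds_set: dict[str, str], panel_size: int,
                edit_sites: list | None = None, n_edits_per_gene: int = 3,
                noise: float = 0.0, member_noise_rate: float = 0.3, seed: int = 0,
                position_weights=(0.35, 0.65)):
    """Plant C-positions whose U-edit restores the panel-conserved residue.

    `cds_set` maps gene -> edited ("true" mRNA-sense) CDS.  Returns
    (genomic_cds, panel, truth): genomic CDSs carry C at each planted site
    where the edited transcript has U/T; `noise` is the fraction of panel
    members that receive neutral residue noise (i.i.d. substitutions at
    `member_noise_rate` within those members).
    """
    rng = np.random.default_rng(seed)
    genomic: dict[str, str] = {}
    panel: dict[str, list[str]] = {}
    truth = TruthTable()
    for gene, cds in cds_set.items():
        if len(cds) % 3:
            raise ValueError(f"CDS length of {gene} not a multiple of 3")
        sites = [s for s in (edit_sites or []) if s[0] == gene]
        if not sites:
            sites = _auto_sites(rng, gene, cds, n_edits_per_gene, position_weights)
        arr = list(cds)
        for _gene, codon_idx, codon_pos in sites:
            i = (codon_idx - 1) * 3 + (codon_pos - 1)
            if arr[i] != "T":
                raise ValueError(
                    f"{gene} codon {codon_idx} pos {codon_pos}: edited base is "
                    f"{arr[i]}, cannot plant a C->U edit"
                )
            edited_codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
            unedited = edited_codon[: codon_pos - 1] + "C" + edited_codon[codon_pos:]
            if GENETIC_CODE[unedited] == GENETIC_CODE[edited_codon]:
                raise ValueError(
                    f"{gene} codon {codon_idx} pos {codon_pos}: edit is synonymous"
                )
            arr[i] = "C"
            truth.edits.append(
                {"gene": gene, "codon": codon_idx, "position": codon_pos,
                 "from_aa": GENETIC_CODE[unedited], "to_aa": GENETIC_CODE[edited_codon]}
            )
        genomic[gene] = "".join(arr)
        protein = translate(cds)[:-1] if cds[-3:] in _STOPS else translate(cds)
        members = []
        for m in range(panel_size):
            res = list(protein)
            if noise > 0 and rng.random() < noise:
                hit = rng.random(len(res)) < member_noise_rate
                for i in np.nonzero(hit)[0]:
                    alts = [a for a in _AA20 if a != res[i]]
                    res[i] = alts[int(rng.integers(0, len(alts)))]
            members.append("".join(res))
        panel[gene] = members
    return genomic, panel, truth


def _auto_sites(rng, gene, cds, n_edits, position_weights):
    """Pick codons where a T at position 1 or 2 supports a nonsynonymous C->U plant."""
    candidates = []
    for codon_idx in range(2, len(cds) // 3):  # skip start & stop codons
        codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
        for pos in (1, 2):
            if codon[pos - 1] != "T":
                continue
            unedited = codon[: pos - 1] + "C" + codon[pos:]
            if unedited in _STOPS or GENETIC_CODE[unedited] == GENETIC_CODE[codon]:
                continue
            candidates.append((codon_idx, pos))
    if len(candidates) < n_edits:
        raise ValueError(f"not enough editable positions in {gene}")
    w1, w2 = position_weights
    weights = np.array([w1 if pos == 1 else w2 for _idx, pos in candidates], dtype=float)
    weights /= weights.sum()
    chosen_codons = set()
    sites = []
    order = rng.choice(len(candidates), size=len(candidates), replace=False, p=weights)
    for k in order:
        codon_idx, pos = candidates[k]
        if codon_idx in chosen_codons:
            continue
        chosen_codons.add(codon_idx)
        sites.append((gene, codon_idx, pos))
        if len(sites) == n_edits:
            break
    return sorted(sites)
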