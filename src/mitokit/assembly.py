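"""Organelle genome assembly from a contig graph.

Pipeline: depth-window candidate filtering (with reference-confirmed,
graph-essential rescues), reference selection, edge pruning, circular path
walking with repeat-contig reuse proportional to depth, junction gap
filling from reads, and read-based validation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .align import AlignParams, seed_and_extend
from .seqio import ContigGraph, reverse_complement

log = logging.getLogger(__name__)


@dataclass
class AssemblyConfig:
    depth_window: tuple = (15.0, 50.0)
    min_edge_support: int = 2
    gap_max_mismatches: int = 1
    gap_min_overlap_identity: float = 95.0
    gap_end_window: tuple = (3, 60)
    reference_word_size: int = 15

    def __post_init__(self):
        lo, hi = self.depth_window
        if lo >= hi:
            raise ValueError("depth window low must be < high")
        if self.gap_end_window[0] > self.gap_end_window[1]:
            raise ValueError("end window must be ascending")


@dataclass
class AssemblyPath:
    segments: list  # [(contig_id, orientation)]
    usage: dict  # contig_id -> times used
    junctions: list = field(default_factory=list)  # fill sequence per junction
    sequence: str = ""


def _undirected(graph: ContigGraph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(graph.nodes)
    for a, _ea, b, _eb, sup in graph.edges:
        g.add_edge(a, b, support=sup)
    return g


def filter_by_depth(graph: ContigGraph, window=(15.0, 50.0),
                    reference_confirmed: set | None = None) -> dict:
    """Candidate contigs: depth inside the window, plus out-of-window contigs
    that are reference-confirmed AND bridge otherwise-disconnected in-window
    contigs.  Returns contig_id -> tag."""
    lo, hi = window
    in_window = {c for c, nd in graph.nodes.items() if lo <= nd["depth"] <= hi}
    tags = {c: "in-window" for c in in_window}
    if reference_confirmed:
        g = _undirected(graph)
        base = g.subgraph(in_window)
        base_components = nx.number_connected_components(base) if in_window else 0
        for c in sorted(reference_confirmed - in_window):
            if c not in graph.nodes:
                continue
            with_c = g.subgraph(in_window | {c})
            merged = sum(
                1 for comp in nx.connected_components(with_c) if comp & in_window
            )
            if merged < base_components:
                tags[c] = "ref-essential"
    return tags


def select_by_reference(candidates, graph: ContigGraph, reference_panel: list,
                        params: AlignParams | None = None) -> set:
    """Candidates with at least one alignment hit to any panel genome."""
    if not reference_panel:
        raise ValueError("empty reference panel")
    if params is None:
        params = AlignParams(word_size=15, evalue_cutoff=1e-6)
    kept = set()
    for cid in candidates:
        seq = graph.nodes[cid]["sequence"]
        for ref in reference_panel:
            ref_seq = ref if isinstance(ref, str) else ref.sequence
            if seed_and_extend(seq, ref_seq, params):
                kept.add(cid)
                break
    return kept


def prune_graph(graph: ContigGraph, min_edge_support: int = 2,
                candidates: set | None = None) -> ContigGraph:
    """Drop weak edges and branches into non-candidate contigs."""
    pruned = ContigGraph()
    keep = set(graph.nodes) if candidates is None else set(candidates)
    for cid in keep:
        nd = graph.nodes[cid]
        pruned.add_node(cid, nd["sequence"], nd["depth"])
    for a, ea, b, eb, sup in graph.edges:
        if sup < min_edge_support:
            continue
        if a not in keep or b not in keep:
            continue
        pruned.add_edge(a, ea, b, eb, sup)
    return pruned


def _modal_unique_depth(graph: ContigGraph) -> float:
    """Modal depth of degree-2 contigs (one edge per end) = the 1x baseline."""
    slot_deg = Counter()
    for a, ea, b, eb, _s in graph.edges:
        slot_deg[(a, ea)] += 1
        slot_deg[(b, eb)] += 1
    unique = [
        nd["depth"] for cid, nd in graph.nodes.items()
        if slot_deg[(cid, "5")] == 1 and slot_deg[(cid, "3")] == 1
    ]
    if not unique:
        unique = [nd["depth"] for nd in graph.nodes.values()]
    rounded = Counter(round(d) for d in unique)
    mode = rounded.most_common(1)[0][0]
    close = [d for d in unique if abs(d - mode) <= max(2.0, 0.2 * mode)]
    return sum(close) / len(close) if close else float(mode)


def copy_number(depth: float, base_depth: float) -> int:
    m = depth / base_depth
    frac = m - int(m)
    if abs(frac - 0.5) < 0.05:
        log.warning("ambiguous copy number %.2f; rounding toward 1", m)
        return max(1, int(m))
    return max(1, round(m))


def walk_circular_path(graph: ContigGraph, base_depth: float | None = None) -> AssemblyPath:
    """Closed walk using each contig round(depth / base_depth) times.

    Exhaustive backtracking with memoized dead ends; raises with the
    violating contigs when no closed walk exists."""
    if not graph.nodes:
        raise ValueError("empty graph")
    if base_depth is None:
        base_depth = _modal_unique_depth(graph)
    mult = {cid: copy_number(nd["depth"], base_depth) for cid, nd in graph.nodes.items()}

    adj: dict[tuple, list[tuple]] = {}
    for a, ea, b, eb, _sup in graph.edges:
        adj.setdefault((a, ea), []).append((b, eb))
        adj.setdefault((b, eb), []).append((a, ea))

    start = min((c for c in mult if mult[c] == 1), default=min(mult))
    total_steps = sum(mult.values())
    order = sorted(mult)
    dead: set = set()

    def other(end):
        return "3" if end == "5" else "5"

    path: list[tuple] = []

    def dfs(cid, exit_end, remaining):
        state = (cid, exit_end, tuple(remaining[c] for c in order))
        if state in dead:
            return False
        used = total_steps - sum(remaining.values())
        if used == total_steps:
            # closed iff an edge joins our exit back to the start's entry end
            entry = ("5" if path[0][1] == "+" else "3")
            return (start, entry) in adj.get((cid, exit_end), [])
        for nxt, enter_end in adj.get((cid, exit_end), []):
            if remaining.get(nxt, 0) <= 0:
                continue
            remaining[nxt] -= 1
            orient = "+" if enter_end == "5" else "-"
            path.append((nxt, orient))
            if dfs(nxt, other(enter_end), remaining):
                return True
            path.pop()
            remaining[nxt] += 1
        dead.add(state)
        return False

    remaining = dict(mult)
    remaining[start] -= 1
    path.append((start, "+"))
    if not dfs(start, "3", remaining):
        unused = [c for c in order if remaining.get(c, 0) > 0]
        raise ValueError(
            "no closed walk consistent with contig multiplicities; "
            f"unplaced or conflicting contigs: {unused or order}"
        )
    usage = Counter(cid for cid, _o in path)
    seq_parts = []
    for cid, orient in path:
        s = graph.nodes[cid]["sequence"]
        seq_parts.append(s if orient == "+" else reverse_complement(s))
    return AssemblyPath(segments=path, usage=dict(usage), sequence="".join(seq_parts))


def fill_gaps(path: AssemblyPath, graph: ContigGraph, reads: list[str],
              config: AssemblyConfig | None = None) -> str:
    """Resolve each junction by majority vote of reads spanning both flanks.

    Unresolved junctions are reported and left as N-gaps."""
    if config is None:
        config = AssemblyConfig()
    win = config.gap_end_window[1]
    flank = min(20, win)
    parts = []
    segs = path.segments
    read_pool = reads + [reverse_complement(r) for r in reads]
    for idx, (cid, orient) in enumerate(segs):
        s = graph.nodes[cid]["sequence"]
        parts.append(s if orient == "+" else reverse_complement(s))
        nxt_cid, nxt_orient = segs[(idx + 1) % len(segs)]
        ns = graph.nodes[nxt_cid]["sequence"]
        nxt_seq = ns if nxt_orient == "+" else reverse_complement(ns)
        left = parts[-1][-flank:]
        right = nxt_seq[:flank]
        votes: Counter = Counter()
        for read in read_pool:
            pos = read.find(left)
            if pos < 0:
                continue
            rest = read[pos + len(left) :]
            hit = rest.find(right)
            if 0 <= hit <= win:
                votes[rest[:hit]] += 1
        if votes:
            winner, n_win = votes.most_common(1)[0]
            if len(votes) > 1:
                log.warning(
                    "junction %s->%s: conflicting fills %s; majority chosen",
                    cid, nxt_cid, dict(votes),
                )
            path.junctions.append({"from": cid, "to": nxt_cid, "fill": winner,
                                   "support": n_win})
            parts.append(winner)
        else:
            gap = "N" * 10
            log.warning("junction %s->%s unresolved; N-gap inserted", cid, nxt_cid)
            path.junctions.append({"from": cid, "to": nxt_cid, "fill": gap,
                                   "support": 0})
            parts.append(gap)
    return "".join(parts)


def validate_assembly(sequence: str, reads: list[str], k: int = 31,
                      circular: bool = True) -> dict:
    """Per-position read support and consensus-vs-assembly discrepancies."""
    L = len(sequence)
    genome = sequence + sequence[: max(len(r) for r in reads)] if circular else sequence
    index: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        index.setdefault(genome[i : i + k], []).append(i)
    depth = [0] * L
    mismatch_votes: dict[int, Counter] = {}
    unmapped = 0
    for read in reads:
        placed = False
        for rc in (read, reverse_complement(read)):
            seed = rc[:k]
            for pos in index.get(seed, []):
                window = genome[pos : pos + len(rc)]
                if len(window) < len(rc):
                    continue
                mism = [i for i in range(len(rc)) if rc[i] != window[i]]
                if len(mism) <= max(2, len(rc) // 50):
                    for i in range(len(rc)):
                        depth[(pos + i) % L] += 1
                    for i in mism:
                        mismatch_votes.setdefault((pos + i) % L, Counter())[rc[i]] += 1
                    placed = True
                    break
            if placed:
                break
        if not placed:
            unmapped += 1
    discrepancies = []
    for pos, votes in sorted(mismatch_votes.items()):
        alt, n_alt = votes.most_common(1)[0]
        if n_alt > depth[pos] - n_alt:
            discrepancies.append({"position": pos, "assembly": sequence[pos],
                                  "consensus": alt, "support": n_alt,
                                  "depth": depth[pos]})
    low_support = [i for i, d in enumerate(depth) if d == 0]
    return {"depth": depth, "discrepancies": discrepancies,
            "uncovered_positions": low_support, "unmapped_reads": unmapped}


def assemble(graph: ContigGraph, config: AssemblyConfig | None = None,
             reference_panel: list | None = None,
             reads: list[str] | None = None) -> AssemblyPath:
    """Full pipeline: depth filter -> reference select -> prune -> walk -> fill."""
    if config is None:
        config = AssemblyConfig()
    ref_confirmed = None
    if reference_panel:
        ref_confirmed = select_by_reference(set(graph.nodes), graph, reference_panel)
    tags = filter_by_depth(graph, config.depth_window, ref_confirmed)
    candidates = set(tags)
    if ref_confirmed is not None:
        candidates = {c for c in candidates
                      if c in ref_confirmed or tags[c] == "ref-essential"}
    pruned = prune_graph(graph, config.min_edge_support, candidates)
    path = walk_circular_path(pruned)
    if reads:
        path.sequence = fill_gaps(path, pruned, reads, config)
    return path
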