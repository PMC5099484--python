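"""Conservation-scored C-to-U RNA-editing prediction.

Per codon, every subset of its C positions (up to a cap) is tried as a
U-edited variant; a variant's support is the fraction of informative
reference-panel members whose aligned residue equals the variant's residue.
The best-supported variant is reported when its support clears the cutoff
and beats the unedited codon.  Synonymous candidates can never score above
the unedited variant, so third-position silent edits are structurally
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .align import global_align_protein
from .simulate import GENETIC_CODE


@dataclass
class EditingConfig:
    cutoff: float = 0.6
    max_edits_per_codon: int = 3
    min_panel: int = 3

    def __post_init__(self):
        if not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must be in (0, 1]")


@dataclass
class EditSite:
    gene: str
    codon_index: int  # 1-based
    codon_position: int  # 1, 2 or 3
    cds_position: int  # 0-based offset in the CDS
    unedited_codon: str
    edited_codon: str
    from_aa: str
    to_aa: str
    score: float


def _panel_columns(protein: str, panel: list[str]) -> list[list[str]]:
    """Aligned panel residue per query residue; '-' marks non-informative.

    Panels whose members all match the query length are taken as pre-aligned
    columns; otherwise each member is globally aligned to the query.
    """
    n = len(protein)
    cols: list[list[str]] = [[] for _ in range(n)]
    if all(len(m) == n for m in panel):
        for m in panel:
            for i, r in enumerate(m):
                cols[i].append(r)
        return cols
    for m in panel:
        qa, ma = global_align_protein(protein, m)
        qi = 0
        for qc, mc in zip(qa, ma):
            if qc != "-":
                cols[qi].append(mc)
                qi += 1
    return cols


def predict_edits(cds: str, gene_name: str, panel: list[str],
                  config: EditingConfig | None = None) -> list[EditSite]:
    """C->U edit sites in a CDS supported by reference protein conservation."""
    if config is None:
        config = EditingConfig()
    if len(cds) % 3:
        raise ValueError(f"CDS length of {gene_name} not a multiple of 3")
    if len(panel) < config.min_panel:
        raise ValueError(
            f"reference panel for {gene_name} has {len(panel)} members; "
            f"need >= {config.min_panel}"
        )
    n_codons = len(cds) // 3
    protein_len = n_codons - (1 if cds[-3:] in ("TAA", "TAG", "TGA") else 0)
    protein = "".join(GENETIC_CODE[cds[i * 3 : i * 3 + 3]] for i in range(protein_len))
    cols = _panel_columns(protein, panel)
    sites: list[EditSite] = []
    for ci in range(protein_len):
        codon = cds[ci * 3 : ci * 3 + 3]
        c_positions = [k for k in range(3) if codon[k] == "C"]
        if not c_positions:
            continue
        residues = [r for r in cols[ci] if r not in ("-", "X")]
        if len(residues) < config.min_panel:
            continue

        def support(aa: str) -> float:
            return sum(1 for r in residues if r == aa) / len(residues)

        base_aa = GENETIC_CODE[codon]
        base_support = support(base_aa)
        best = (base_support, 0, (), codon, base_aa)  # support, -n_edits pref via tuple order
        for k in range(1, min(len(c_positions), config.max_edits_per_codon) + 1):
            for subset in combinations(c_positions, k):
                variant = "".join(
                    "T" if j in subset else codon[j] for j in range(3)
                )
                aa = GENETIC_CODE[variant]
                if aa == "*" and ci < protein_len - 1:
                    continue  # premature stops are never conservation-supported
                s = support(aa)
                if s > best[0] + 1e-12 or (abs(s - best[0]) < 1e-12 and k < -best[1]):
                    best = (s, -k, subset, variant, aa)
        s, _negk, subset, variant, aa = best
        if not subset:
            continue
        if s < config.cutoff or s <= base_support:
            continue
        for j in subset:
            sites.append(
                EditSite(
                    gene=gene_name, codon_index=ci + 1, codon_position=j + 1,
                    cds_position=ci * 3 + j, unedited_codon=codon,
                    edited_codon=variant, from_aa=base_aa, to_aa=aa,
                    score=round(s, 4),
                )
            )
    return sites


@dataclass
class EditSummary:
    by_position: dict = field(default_factory=dict)
    by_change: dict = field(default_factory=dict)
    per_gene: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.by_position.values())


def summarize_edits(sites: list[EditSite]) -> EditSummary:
    """Codon-position distribution, amino-acid change table, per-gene counts."""
    summary = EditSummary()
    for s in sites:
        summary.by_position[s.codon_position] = summary.by_position.get(s.codon_position, 0) + 1
        change = f"{s.from_aa}->{s.to_aa}"
        summary.by_change[change] = summary.by_change.get(change, 0) + 1
        summary.per_gene[s.gene] = summary.per_gene.get(s.gene, 0) + 1
        if s.codon_index == 1 and s.unedited_codon == "ACG" and s.edited_codon == "ATG":
            summary.flags.append((s.gene, s.codon_index, "start-codon restoration"))
        if s.to_aa == "*":
            summary.flags.append((s.gene, s.codon_index, "stop-codon creation"))
    return summary
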