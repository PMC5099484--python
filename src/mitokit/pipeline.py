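"""Pipeline orchestration and report generation.

`run_pipeline` drives the stages in dependency order on a config mapping and
writes per-stage TSVs plus a machine-readable JSON of headline numbers;
`make_fixtures` emits the small worked-example fixtures used by the
acceptance suite (printed cluster coordinates, repeat motifs, toy CDS pairs).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import repeats as rep
from . import seqio
from . import simulate as sim
from . import stats as ann
from .align import AlignParams
from .clusters import junction_interval

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "genome_length", "gc_target",
    "gene_catalog", "planted_ssrs", "planted_tandems", "planted_dispersed",
    "read_depth", "ssr_thresholds", "tandem_min_period", "tandem_min_identity",
    "dispersed_min_len", "dispersed_evalue",
}

_DEFAULT_STAGES = ("simulate", "ssr", "tandem", "dispersed", "stats")


def run_pipeline(config: dict) -> dict:
    """Run the requested stages; returns the headline-numbers dict.

    Unknown config keys are rejected; the effective config is echoed into
    the output directory for provenance.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = Path(config.get("out_dir", "mitokit_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", _DEFAULT_STAGES))
    (out / "effective_config.json").write_text(
        json.dumps({**{k: config.get(k) for k in sorted(_KNOWN_KEYS)},
                    "stages": list(stages)}, indent=2, default=str)
    )
    headline: dict = {}
    sim_config = sim.SimConfig(
        seed=int(config.get("seed", 0)),
        genome_length=int(config.get("genome_length", 60000)),
        gc_target=float(config.get("gc_target", 0.45)),
        gene_catalog=list(config.get("gene_catalog", [("nad1", 200), ("cox1", 250)])),
        planted_ssrs=list(config.get("planted_ssrs", [])),
        planted_tandems=list(config.get("planted_tandems", [])),
        planted_dispersed=list(config.get("planted_dispersed", [])),
        read_depth=float(config.get("read_depth", 30.0)),
    )
    record = None
    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            record, truth = sim.simulate_mitogenome(sim_config)
            seqio.write_fasta(record, out / "genome.fasta")
            seqio.write_gff(record, out / "genome.gff3")
            seqio.write_tsv(truth.to_rows(), out / "truth.tsv")
            headline["genome_length"] = len(record)
        elif stage == "ssr":
            record = record or seqio.read_fasta(out / "genome.fasta")[0]
            thresholds = tuple(config.get("ssr_thresholds", rep.DEFAULT_SSR_THRESHOLDS))
            ssrs = rep.find_ssrs(record, thresholds)
            seqio.write_tsv(
                [{"motif": s.motif, "unit_len": s.unit_len, "copies": s.copies,
                  "start": s.start, "end": s.end} for s in ssrs],
                out / "ssrs.tsv",
                columns=["motif", "unit_len", "copies", "start", "end"],
            )
            headline["n_ssrs"] = len(ssrs)
        elif stage == "tandem":
            record = record or seqio.read_fasta(out / "genome.fasta")[0]
            trs = rep.find_tandem_repeats(
                record,
                min_period=int(config.get("tandem_min_period", 7)),
                min_identity=float(config.get("tandem_min_identity", 90.0)),
            )
            seqio.write_tsv(
                [{"period": t.period, "copies": t.copies, "identity": t.identity,
                  "start": t.start, "end": t.end} for t in trs],
                out / "tandems.tsv",
                columns=["period", "copies", "identity", "start", "end"],
            )
            headline["n_tandems"] = len(trs)
        elif stage == "dispersed":
            record = record or seqio.read_fasta(out / "genome.fasta")[0]
            fams = rep.find_dispersed_repeats(
                record,
                AlignParams(evalue_cutoff=float(config.get("dispersed_evalue", 1.0))),
                min_report_len=int(config.get("dispersed_min_len", 20)),
            )
            rows = [
                {"family": f.family_id, "unit_length": f.unit_length,
                 "identity": f.identity, "type": f.rtype, "n_copies": f.n_copies}
                for f in fams
            ]
            seqio.write_tsv(rows, out / "repeat_families.tsv",
                            columns=["family", "unit_length", "identity", "type", "n_copies"])
            headline["n_repeat_families"] = len(fams)
            headline["n_families_gt1kb"] = sum(1 for f in fams if f.unit_length > 1000)
        elif stage == "stats":
            record = record or seqio.read_fasta(out / "genome.fasta")[0]
            comp = ann.composition_report(record)
            seqio.write_tsv(
                [{"category": k, **{kk: round(vv, 4) if isinstance(vv, float) else vv
                                    for kk, vv in v.items()}}
                 for k, v in comp.categories.items()],
                out / "composition.tsv",
            )
            headline["gc_percent"] = round(comp["genome"]["GC"], 2)
        else:
            raise ValueError(f"unknown stage: {stage}")
        log.info("stage %-10s done in %.2fs", stage, time.time() - t0)
    (out / "headline.json").write_text(json.dumps(headline, indent=2))
    return headline


# worked examples printed in the source genome's tables, reused as fixtures
CLUSTER_COORDS = {
    # cluster -> ((gene1 start, gene1 end), (gene2 start, gene2 end)), 1-based
    "cox1-rps10": ((34397, 36529), (36716, 37897)),
    "cob-rps14": ((273866, 275044), (276398, 276700)),
    "sdh4-cox3": ((32397, 32795), (32723, 33520)),
}

TANDEM_UNITS = [
    "TAAGTGAAATAAAAT",
    "TAACAGAAGTTTCAAGAGAAC",
    "TCGGAAAAACAAATGCCATGAAGGACTTAGGAAAGA",
    "GATCGCCGTCAAAGACAGGATTCGAG",
    "TAAGTGAAATAAAAT",
    "CTTGGCTTTCCTTTTTGTCTTGACTCTATGCCTTCCAGCTGT",
]

PENTAMER_SSR = ("TTTTA", 5)  # the IGS(atp4, ccmFc-exon1) pentamer run


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the worked-example fixtures; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    rows = [
        {"cluster": name,
         "gene1_start": c[0][0], "gene1_end": c[0][1],
         "gene2_start": c[1][0], "gene2_end": c[1][1],
         "interval": junction_interval(c[0][1], c[1][0])}
        for name, c in CLUSTER_COORDS.items()
    ]
    seqio.write_tsv(rows, out / "cluster_coords.tsv")
    paths["clusters"] = out / "cluster_coords.tsv"

    rng = sim.np.random.default_rng(seed)
    with open(out / "tandem_units.fasta", "w") as fh:
        for i, unit in enumerate(TANDEM_UNITS, 1):
            flank5 = sim.random_sequence(rng, 500)
            flank3 = sim.random_sequence(rng, 500)
            fh.write(f">tandem_{i} period={len(unit)}\n{flank5}{unit * 2}{flank3}\n")
    paths["tandems"] = out / "tandem_units.fasta"

    motif, copies = PENTAMER_SSR
    flank5 = sim.random_sequence(rng, 1000)
    flank3 = sim.random_sequence(rng, 1000)
    with open(out / "pentamer_ssr.fasta", "w") as fh:
        fh.write(f">pentamer expected_len={len(motif) * copies}\n")
        fh.write(f"{flank5}{motif * copies}{flank3}\n")
    paths["ssr"] = out / "pentamer_ssr.fasta"

    toy_a = "ATGTTTGCTAAGCCCGGGTTACGACATTGGGAT" + "TAA"
    toy_b = "ATGTTCGCTAAGCCCGGATTACGACATTGGGAT" + "TAA"
    with open(out / "toy_cds_pair.fasta", "w") as fh:
        fh.write(f">toyA\n{toy_a}\n>toyB\n{toy_b}\n")
    paths["cds_pair"] = out / "toy_cds_pair.fasta"
    return paths
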