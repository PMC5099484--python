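import numpy as np
import pytest

from mitokit.align import AlignParams
from mitokit.repeats import (
    DEFAULT_SSR_THRESHOLDS,
    classify_location,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_length_histogram,
)
from mitokit.seqio import GenomeRecord, reverse_complement
from mitokit.simulate import SimConfig, random_sequence, simulate_mitogenome


# --------------------------------------------------------------------------
# independent SSR oracle: dumb enumeration over every (start, period) pair


def _unit_is_primitive(unit):
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def ssr_oracle(seq, thresholds=DEFAULT_SSR_THRESHOLDS):
    n = len(seq)
    found = []
    for start in range(n):
        for p in range(1, 7):
            if start + p > n:
                break
            unit = seq[start : start + p]
            if "N" in unit or not _unit_is_primitive(unit):
                continue
            # base-level maximality on the left
            if start > 0 and start - 1 + p < n and seq[start - 1] == seq[start - 1 + p]:
                continue
            # extend right base-by-base under periodicity
            j = start + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            copies = (j - start) // p
            if copies < thresholds[p - 1]:
                continue
            found.append((start, p, copies))
    # greedy left-to-right, smaller period first on ties
    found.sort(key=lambda t: (t[0], t[1]))
    accepted = []
    covered_until = -1
    for start, p, copies in found:
        if start > covered_until:
            accepted.append((start, p, copies))
            covered_until = start + p * copies - 1
    return accepted


class TestSSR:
    def test_planted_pentamer(self):
        rng = np.random.default_rng(42)
        while True:
            flank5, flank3 = random_sequence(rng, 500), random_sequence(rng, 500)
            seq = flank5 + "TTTTA" * 5 + flank3
            background = find_ssrs(flank5 + flank3)
            if not background:
                break
        ssrs = find_ssrs(seq)
        assert len(ssrs) == 1
        s = ssrs[0]
        assert s.unit_len == 5 and s.copies == 5 and s.length == 25

    def test_mononucleotide_threshold_eight(self):
        assert find_ssrs("GC" + "A" * 7 + "GC") == []
        hits = find_ssrs("GC" + "A" * 8 + "GC")
        assert len(hits) == 1 and hits[0].unit_len == 1 and hits[0].copies == 8

    def test_monomer_run_never_reported_as_dimer(self):
        hits = find_ssrs("C" + "A" * 10 + "C")
        assert len(hits) == 1
        assert hits[0].unit_len == 1

    def test_no_overlapping_reports(self):
        rng = np.random.default_rng(1)
        seq = random_sequence(rng, 20000)
        ssrs = find_ssrs(seq)
        for a, b in zip(ssrs, ssrs[1:]):
            assert a.end <= b.start

    def test_length_invariant(self):
        rng = np.random.default_rng(2)
        for s in find_ssrs(random_sequence(rng, 20000)):
            assert s.end - s.start == s.unit_len * s.copies

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich background breeds plenty of candidate runs
        p = [0.35, 0.15, 0.15, 0.35]
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=3000, p=p)])
        got = [(s.start, s.unit_len, s.copies) for s in find_ssrs(seq)]
        assert got == ssr_oracle(seq)

    def test_thresholds_length_check(self):
        with pytest.raises(ValueError):
            find_ssrs("ACGT", thresholds=(8, 4))


class TestTandem:
    def test_table_unit_15mer(self):
        rng = np.random.default_rng(3)
        unit = "TAAGTGAAATAAAAT"
        seq = random_sequence(rng, 400) + unit * 2 + random_sequence(rng, 400)
        trs = [t for t in find_tandem_repeats(seq) if t.period == 15]
        assert len(trs) == 1
        t = trs[0]
        # chance lag-matches in the random flanks may stretch the region by
        # a base or two; period and ~2 copies are the planted signal
        assert t.copies == pytest.approx(2.0, abs=0.15)
        assert t.identity == 100.0
        assert t.consensus == unit

    def test_table_unit_42mer(self):
        rng = np.random.default_rng(4)
        unit = "CTTGGCTTTCCTTTTTGTCTTGACTCTATGCCTTCCAGCTGT"
        seq = random_sequence(rng, 300) + unit * 2 + random_sequence(rng, 300)
        trs = [t for t in find_tandem_repeats(seq) if t.period == 42]
        assert len(trs) == 1
        assert trs[0].copies == pytest.approx(2.0, abs=0.15)

    def test_one_mismatch_variant_identity(self):
        rng = np.random.default_rng(5)
        unit = "GATCGCCGTCAAAGACAGGATTCGAG"  # 26-mer
        variant = "GATCGCCGTCAAGGACAGGATTCGAG"  # one substitution
        assert sum(a != b for a, b in zip(unit, variant)) == 1
        seq = random_sequence(rng, 300) + unit + variant + random_sequence(rng, 300)
        trs = [t for t in find_tandem_repeats(seq) if t.period == 26]
        assert len(trs) == 1
        t = trs[0]
        assert t.copies == pytest.approx(2.0, abs=0.15)
        assert t.identity == pytest.approx(100.0 * 25 / 26, abs=0.5)

    def test_ssr_periods_excluded(self):
        seq = "G" + "AT" * 30 + "C"
        assert all(t.period > 6 for t in find_tandem_repeats(seq))

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_copies=1)


@pytest.fixture(scope="module")
def genome():
    config = SimConfig(
        seed=77,
        genome_length=25_000,
        planted_dispersed=[(2532, 99.64, "DR", 2), (600, 99.0, "IR", 2)],
    )
    return simulate_mitogenome(config)


class TestDispersed:
    def test_planted_dr_family(self, genome):
        record, truth = genome
        fams = find_dispersed_repeats(record, AlignParams(evalue_cutoff=1.0))
        big = [f for f in fams if f.unit_length > 2000]
        assert len(big) == 1
        fam = big[0]
        assert fam.rtype == "DR"
        assert fam.n_copies == 2
        assert fam.identity >= 99.0

    def test_planted_ir_family(self, genome):
        record, truth = genome
        fams = find_dispersed_repeats(record, AlignParams(evalue_cutoff=1.0))
        mid = [f for f in fams if 400 < f.unit_length < 1000]
        assert any(f.rtype == "IR" for f in mid)

    def test_family_labels_sorted_by_length(self, genome):
        record, _ = genome
        fams = find_dispersed_repeats(record, AlignParams(evalue_cutoff=1.0))
        lengths = [f.unit_length for f in fams]
        assert lengths == sorted(lengths, reverse=True)
        assert [f.family_id for f in fams] == [f"R{i}" for i in range(1, len(fams) + 1)]

    def test_random_sequence_chance_families_bounded(self):
        rng = np.random.default_rng(6)
        seq = random_sequence(rng, 10_000)
        fams = find_dispersed_repeats(
            GenomeRecord("r", seq, "linear"), AlignParams(evalue_cutoff=0.01)
        )
        assert len(fams) <= 2

    def test_rotation_invariance(self, genome):
        record, _ = genome
        fams = find_dispersed_repeats(record, AlignParams(evalue_cutoff=1e-3),
                                      min_report_len=100)
        rotated = record.rotate(4000)
        fams_rot = find_dispersed_repeats(rotated, AlignParams(evalue_cutoff=1e-3),
                                          min_report_len=100)
        key = sorted((f.n_copies, f.rtype) for f in fams)
        key_rot = sorted((f.n_copies, f.rtype) for f in fams_rot)
        assert key == key_rot
        lens = sorted(f.unit_length for f in fams)
        lens_rot = sorted(f.unit_length for f in fams_rot)
        for a, b in zip(lens, lens_rot):
            assert abs(a - b) <= 10  # edge wobble from random flank matches


class TestLocation:
    def test_inside_cds(self, toy_record):
        assert classify_location((120, 130), toy_record) == "g1"

    def test_intergenic(self, toy_record):
        label = classify_location((250, 260), toy_record)
        assert label == "IGS (g1, g2)"

    def test_intron(self, toy_record):
        assert classify_location((380, 400), toy_record) == "g2-intron1"

    def test_unannotated(self):
        rec = GenomeRecord("r", "ACGT" * 100)
        assert classify_location((10, 20), rec) == "unannotated"

    def test_origin_spanning_igs_resolves_across_origin(self, toy_record):
        # between rrn5 (ends 1020) and g1 (starts 100), across the origin
        label = classify_location((1990, 1995), toy_record)
        assert label == "IGS (rrn5, g1)"

    def test_rotation_invariant_labels(self, toy_record):
        label = classify_location((250, 260), toy_record)
        rotated = toy_record.rotate(50)
        assert classify_location((200, 210), rotated) == label


class TestHistogram:
    def test_sum_conserves_count(self, planted_genome):
        _config, record, _truth = planted_genome
        fams = find_dispersed_repeats(record, AlignParams(evalue_cutoff=1.0))
        hist = repeat_length_histogram(fams)
        assert sum(hist.values()) == len(fams)

    def test_empty(self):
        assert repeat_length_histogram([]) == {}

    def test_planted_lengths_in_correct_bins(self):
        hist = repeat_length_histogram([25, 33, 1205])
        assert hist[20] == 1 and hist[30] == 1 and hist[1200] == 1
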