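"""Demultiplexing, remnant/adapter checks, quality filter, pool balance."""

import math

import pytest

import middrad as m
from middrad.io import read_fastq

from conftest import sample_reads


def test_demux_roundtrip_is_perfect(roundtrip):
    stats = roundtrip.demux_stats
    assert stats.assigned == stats.raw
    assert stats.unassigned == 0
    # true sample is encoded in the simulated read title
    titles = [t.split(":")[0] for t, _, _ in
              read_fastq(roundtrip.paths["pool1"][0])]
    assert stats.assignments == titles


def test_demux_conservation(roundtrip):
    stats = roundtrip.demux_stats
    assert stats.assigned + stats.unassigned == stats.raw
    assert sum(stats.per_sample.values()) == stats.assigned


def _mini_fixtures(tmp_path, avaii):
    bset = m.BarcodeSet([m.Barcode("AATT"), m.Barcode("CGGC")])
    sheet = m.SampleSheet([("s1", "AATT", "pool1"), ("s2", "CGGC", "pool1")])
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    return bset, sheet, r1, r2


def _write_fastq(path, records):
    path.write_text("".join(f"@{t}\n{s}\n+\n{'I' * len(s)}\n"
                            for t, s in records))


def test_one_substitution_in_barcode_still_assigned(tmp_path, avaii):
    bset, sheet, r1, r2 = _mini_fixtures(tmp_path, avaii)
    insert = "GTCC" + "ACGT" * 30
    _write_fastq(r1, [("read1", "TATT" + insert)])   # AATT with 1 mismatch
    _write_fastq(r2, [("read1", "CGG" + "ACGT" * 30)])
    _, stats = m.demultiplex(r1, r2, sheet, bset, avaii, tol=1)
    assert stats.per_sample["s1"] == 1


def test_equidistant_read_is_unassigned(tmp_path, avaii):
    bset = m.BarcodeSet([m.Barcode("AATT"), m.Barcode("AAGG")])
    sheet = m.SampleSheet([("s1", "AATT", "pool1"), ("s2", "AAGG", "pool1")])
    r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    # AATG is 1 mismatch from both AATT and AAGG
    _write_fastq(r1, [("read1", "AATG" + "GTCC" + "ACGT" * 30)])
    _write_fastq(r2, [("read1", "CGG" + "ACGT" * 30)])
    _, stats = m.demultiplex(r1, r2, sheet, bset, avaii, tol=1)
    assert stats.unassigned == 1


def test_wrong_remnant_blocks_assignment(tmp_path, avaii):
    bset, sheet, r1, r2 = _mini_fixtures(tmp_path, avaii)
    _write_fastq(r1, [("read1", "AATT" + "TTTT" + "ACGT" * 30)])
    _write_fastq(r2, [("read1", "CGG" + "ACGT" * 30)])
    _, stats = m.demultiplex(r1, r2, sheet, bset, avaii, tol=1)
    assert stats.unassigned == 1


def test_raising_tolerance_never_loses_reads(roundtrip, avaii):
    r1, r2 = roundtrip.paths["pool1"]
    assigned = []
    for tol in (0, 1, 2):
        _, stats = m.demultiplex(r1, r2, roundtrip.sheet, roundtrip.bset,
                                 avaii, tol=tol)
        assigned.append(stats.assigned)
    assert assigned == sorted(assigned)


def test_remnant_check_roundtrip(roundtrip, avaii, mspi):
    for sample in roundtrip.sheet.samples():
        assert m.remnant_check(sample_reads(roundtrip, sample, 0), avaii) == 1.0
        assert m.remnant_check(sample_reads(roundtrip, sample, 1), mspi) == 1.0


def test_remnant_check_counts_fraction(avaii):
    good = ["GACC" + "A" * 20] * 95
    bad = ["TTTT" + "A" * 20] * 5
    assert m.remnant_check(good + bad, avaii) == pytest.approx(0.95)
    assert m.remnant_check(bad, avaii) == 0.0


def test_adapter_fraction_mixture():
    adapter = "GTGACTGGAGTTCAGACGTGTGC"
    with_adapter = [("ACGT" * 20) + adapter[:20] for _ in range(20)]
    clean = ["ACGTTGCA" * 15 for _ in range(30)]
    frac = m.adapter_fraction(with_adapter + clean, adapter, min_overlap=10)
    assert frac == pytest.approx(0.40)
    assert m.adapter_fraction(clean, adapter) == 0.0
    with pytest.raises(ValueError):
        m.adapter_fraction(clean, adapter, min_overlap=3)


def test_adapter_fraction_on_simulated_read_through(tmp_path, avaii, mspi):
    from middrad.enzymes import reverse_complement
    from middrad.library_design import build_adapters
    contig = "A" * 30 + "GGTCC" + "T" * 40 + "CCGG" + "A" * 30
    bset = m.BarcodeSet([m.Barcode("ACTGA")])
    sheet = m.SampleSheet([("s", "ACTGA", "pool1")])
    cfg = m.SimConfig(read_length=150, mean_depth=5,
                      depth_dispersion=float("inf"), error_rate=0.0,
                      window=m.SizeWindow(10, 100), seed=3, read_through=True)
    paths, _ = m.simulate_library({"c": contig}, sheet, avaii, mspi, cfg,
                                  tmp_path)
    reads = [s for _, s, _ in read_fastq(paths["pool1"][0])]
    adapter_in_read = reverse_complement(build_adapters("ACTGA", avaii,
                                                        mspi).p2_top)
    # padding after the adapter breaks a 3'-anchored suffix match, so search
    # the known read-through region the way the simulator laid it out
    assert all(adapter_in_read in r for r in reads)


def test_quality_filter_window_rules():
    q40 = chr(40 + 33) * 100
    q2 = chr(2 + 33) * 100
    patched = chr(40 + 33) * 40 + chr(9 + 33) * 15 + chr(40 + 33) * 45
    reads = [("good", "A" * 100, q40), ("bad", "A" * 100, q2),
             ("patched", "A" * 100, patched)]
    kept, dropped = m.quality_filter(reads, m.QCParams())
    assert [t for t, _, _ in kept] == ["good"]
    assert dropped == 2


def test_quality_filter_short_read_uses_whole_mean():
    ok = ("short", "ACGT", chr(30 + 33) * 4)
    kept, dropped = m.quality_filter([ok], m.QCParams())
    assert kept == [ok] and dropped == 0


def test_pool_balance_examples():
    assert m.pool_balance([10, 10, 10, 10]).cv == 0.0
    rep = m.pool_balance([2, 4])
    assert rep.cv == pytest.approx(0.4714)      # sd = sqrt(2), mean = 3
    assert rep.sd == pytest.approx(math.sqrt(2))


def test_pool_balance_scale_invariance():
    counts = [3, 9, 4, 8, 5]
    assert m.pool_balance(counts).cv == m.pool_balance(
        [c * 1000 for c in counts]).cv


def test_pool_balance_needs_two_counts():
    with pytest.raises(ValueError):
        m.pool_balance([5])


@pytest.mark.parametrize("seq, expected", [
    (["GCGC"], 1.0), (["ATAT"], 0.0), (["ACGT"], 0.5),
])
def test_gc_fraction(seq, expected):
    assert m.gc_fraction(seq) == expected


def test_gc_fraction_ignores_ambiguity_codes():
    assert m.gc_fraction(["GCNN"]) == 1.0
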