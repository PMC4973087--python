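"""Stack building, catalog merging, genotyping and Phylip export."""

import io
import random

import pytest

import middrad as m

from conftest import random_dna, sample_reads


def _seq(rng=None, n=140):
    return random_dna(rng or random.Random(0), n)


def test_truncate_reads():
    reads = ["A" * 150, "C" * 140, "G" * 100]
    kept, dropped = m.truncate_reads(reads, 140)
    assert kept == ["A" * 140, "C" * 140]
    assert dropped == 1


def test_single_stack_above_threshold():
    s = _seq()
    report = m.build_stacks([s] * 12, "s", m.ClusterParams(m=10))
    assert len(report.tags) == 1
    tag = report.tags[0]
    assert tag.depth == 12
    assert tag.consensus == s
    assert tag.variant_columns == []
    assert report.conserved()


def test_below_threshold_stack_makes_no_tag():
    report = m.build_stacks([_seq()] * 9, "s", m.ClusterParams(m=10))
    assert report.tags == []
    assert report.below_m_unmerged == 9
    assert report.conserved()


def test_two_deep_stacks_within_m_merge_into_one_tag():
    s = _seq()
    variant = "A" + s[1:] if s[0] != "A" else "C" + s[1:]
    reads = [s] * 12 + [variant] * 11
    report = m.build_stacks(reads, "s", m.ClusterParams(m=10, M=3))
    assert len(report.tags) == 1
    tag = report.tags[0]
    assert tag.depth == 23
    assert tag.consensus == s                  # deeper haplotype wins majority
    assert tag.variant_columns == [0]
    assert set(tag.alleles) == {s, variant}


def test_distant_stacks_stay_separate():
    rng = random.Random(5)
    a, b = _seq(rng), _seq(rng)           # random 140-mers differ everywhere
    report = m.build_stacks([a] * 12 + [b] * 12, "s", m.ClusterParams(m=10))
    assert len(report.tags) == 2


def test_secondary_attaches_to_nearest_primary():
    s = _seq()
    near = s[:5] + ("A" if s[5] != "A" else "C") + s[6:]
    report = m.build_stacks([s] * 15 + [near] * 3, "s",
                            m.ClusterParams(m=10, M=3))
    assert len(report.tags) == 1
    assert report.tags[0].depth == 18
    assert report.conserved()


def test_repetitive_depth_outlier_excluded():
    rng = random.Random(9)
    normals = [_seq(rng) for _ in range(50)]
    monster = _seq(rng)
    reads = []
    for s in normals:
        reads += [s] * 12
    reads += [monster] * 100   # far above mean + 3 sd of primary depths
    report = m.build_stacks(reads, "s", m.ClusterParams(m=10, M=0))
    assert report.repetitive_excluded == 100
    assert len(report.tags) == 50
    assert report.conserved()


def test_catalog_merging_rules():
    base = _seq()
    one_off = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
    six_off = list(base)
    for i in range(6):
        pos = 10 + i * 10
        six_off[pos] = "A" if base[pos] != "A" else "C"
    six_off = "".join(six_off)
    t = lambda s, samp: m.Tag(samp, s, 12, {s: 12})
    params = m.ClusterParams(m=10, n=5)

    same = m.build_catalog({"s1": [t(base, "s1")], "s2": [t(base, "s2")]},
                           params)
    assert len(same) == 1 and same[0].variant_columns == []

    close = m.build_catalog({"s1": [t(base, "s1")], "s2": [t(one_off, "s2")]},
                            params)
    assert len(close) == 1 and close[0].variant_columns == [50]

    far = m.build_catalog({"s1": [t(base, "s1")], "s2": [t(six_off, "s2")]},
                          params)
    assert len(far) == 2


def test_genotyping_two_samples_one_snp():
    base = _seq()
    alt = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
    t = lambda s, samp: m.Tag(samp, s, 12, {s: 12})
    tags = {"s1": [t(base, "s1")], "s2": [t(alt, "s2")]}
    catalog = m.build_catalog(tags, m.ClusterParams())
    matrix = m.match_and_genotype(tags, catalog, m.ClusterParams())
    assert matrix.n_columns == 1
    assert matrix.calls["s1"] == [base[50]]
    assert matrix.calls["s2"] == [alt[50]]


def test_sample_missing_a_locus_gets_n():
    rng = random.Random(2)
    shared = _seq(rng)
    alt = shared[:30] + ("A" if shared[30] != "A" else "C") + shared[31:]
    private = _seq(rng)
    t = lambda s, samp: m.Tag(samp, s, 12, {s: 12})
    tags = {"s1": [t(shared, "s1"), t(private, "s1")], "s2": [t(alt, "s2")]}
    catalog = m.build_catalog(tags, m.ClusterParams())
    matrix = m.match_and_genotype(tags, catalog, m.ClusterParams())
    assert matrix.n_columns == 1
    assert matrix.calls["s2"] == [alt[30]]


def test_heterozygous_tag_iupac_coded():
    base = _seq()
    # within-sample heterozygote: two alleles in one tag
    alt = base[:20] + ("G" if base[20] != "G" else "T") + base[21:]
    het = m.Tag("s1", base, 24, {base: 12, alt: 12})
    hom = m.Tag("s2", base, 12, {base: 12})
    tags = {"s1": [het], "s2": [hom]}
    catalog = m.build_catalog(tags, m.ClusterParams())
    matrix = m.match_and_genotype(tags, catalog, m.ClusterParams())
    assert matrix.n_columns == 1
    code = matrix.calls["s1"][0]
    assert code in "RYSWKM"
    assert matrix.calls["s2"][0] == base[20]


def test_fixed_within_variable_among_filter():
    matrix = m.SNPMatrix(
        samples=["a1", "a2", "b1", "b2"],
        columns=[(1, 0), (1, 1), (2, 0), (2, 1)],
        calls={"a1": list("AGCT"), "a2": list("AGCA"),
               "b1": list("TGCT"), "b2": list("TGCN")})
    from middrad.tag_cluster import filter_fixed_within_variable_among
    groups = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"}
    kept = filter_fixed_within_variable_among(matrix, groups)
    # col0: fixed A vs fixed T -> keep; col1/col2: no between-group
    # difference; col3: polymorphic within spA and N in spB
    assert kept.columns == [(1, 0)]
    assert kept.calls["a1"] == ["A"] and kept.calls["b1"] == ["T"]
    lenient = filter_fixed_within_variable_among(matrix, groups,
                                                 allow_missing=True)
    assert lenient.columns == [(1, 0)]
    with pytest.raises(ValueError, match="without a group"):
        filter_fixed_within_variable_among(matrix, {"a1": "spA"})


def test_phylip_export_and_readback(tmp_path):
    matrix = m.SNPMatrix(
        samples=["alpha", "beta", "gamma"],
        columns=[(1, 5), (1, 9), (2, 0), (2, 7), (3, 3)],
        calls={"alpha": list("ACGTA"), "beta": list("ACGTC"),
               "gamma": list("TCGAA")})
    path = tmp_path / "snps.phy"
    m.export_phylip(matrix, path)
    text = path.read_text()
    assert text.splitlines()[0] == "3 5"
    # independent reader round-trip
    from Bio import AlignIO
    aln = AlignIO.read(io.StringIO(text), "phylip")
    assert {rec.id: str(rec.seq) for rec in aln} == {
        "alpha": "ACGTA", "beta": "ACGTC", "gamma": "TCGAA"}


def test_phylip_rejects_empty_and_duplicates(tmp_path):
    empty = m.SNPMatrix(samples=[], columns=[], calls={})
    with pytest.raises(ValueError):
        m.export_phylip(empty, tmp_path / "x.phy")
    dup = m.SNPMatrix(samples=["a", "a"], columns=[(1, 0)],
                      calls={"a": ["A"]})
    with pytest.raises(ValueError, match="duplicate"):
        m.export_phylip(dup, tmp_path / "y.phy")


def test_roundtrip_tag_counts_equal_manifest(roundtrip):
    """Error-free fixed-depth simulation: one tag per in-window fragment."""
    manifest = roundtrip.manifest
    params = m.ClusterParams(m=10, M=3, n=5, tag_length=140)
    for sample in roundtrip.sheet.samples():
        reads, dropped = m.truncate_reads(sample_reads(roundtrip, sample),
                                          140)
        assert dropped == 0
        report = m.build_stacks(reads, sample, params)
        expected = int((manifest["sample"] == sample).sum())
        assert len(report.tags) == expected
        assert report.conserved()


def test_planted_snps_recovered_exactly(roundtrip):
    """The cross-sample SNP matrix contains exactly the planted columns,
    with the carrier sample differing and the other two agreeing."""
    params = m.ClusterParams(m=10, M=3, n=5, tag_length=140)
    tags = {}
    for sample in roundtrip.sheet.samples():
        reads, _ = m.truncate_reads(sample_reads(roundtrip, sample), 140)
        tags[sample] = m.build_stacks(reads, sample, params).tags
    catalog = m.build_catalog(tags, params)
    matrix = m.match_and_genotype(tags, catalog, params)
    n_planted = sum(len(v) for v in roundtrip.planted.values())
    assert matrix.n_columns == n_planted
    minorities = []
    for col in range(matrix.n_columns):
        calls = {s: matrix.calls[s][col] for s in matrix.samples}
        values = list(calls.values())
        assert "N" not in values
        # exactly one sample (the carrier) differs from the other two
        assert len(set(values)) == 2
        minority = [s for s in calls if values.count(calls[s]) == 1]
        assert len(minority) == 1
        minorities.append(minority[0])
    assert sorted(minorities) == sorted(roundtrip.carrier_of.values())
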