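"""Shared fixtures: enzymes, a seeded end-to-end simulation with planted SNPs."""

from __future__ import annotations

import random
from dataclasses import dataclass

import pytest

import middrad as m
from middrad.io import read_fastq


@pytest.fixture(scope="session")
def avaii() -> m.RestrictionEnzyme:
    return m.get_enzyme("AvaII")


@pytest.fixture(scope="session")
def mspi() -> m.RestrictionEnzyme:
    return m.get_enzyme("MspI")


def brute_force_sites(seq: str, enzyme: m.RestrictionEnzyme) -> list[tuple[int, str]]:
    """Independent site scanner: test every offset against every expansion
    on both strands (collapsing strands for palindromes)."""
    from middrad.enzymes import expand_iupac, reverse_complement

    fwd = expand_iupac(enzyme.recognition)
    rev = {reverse_complement(x) for x in fwd}
    L = len(enzyme.recognition)
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        if window in fwd:
            hits.append((i, "+"))
        if not enzyme.self_rc and window in rev:
            hits.append((i, "-"))
    return hits


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@dataclass
class RoundTrip:
    """Everything produced by the seeded error-free end-to-end run."""

    genome: dict[str, str]
    sheet: m.SampleSheet
    bset: m.BarcodeSet
    config: m.SimConfig
    paths: dict
    manifest: object
    demux_paths: dict
    demux_stats: object
    planted: dict                      # sample -> {(contig, pos): alt}
    carrier_of: dict                   # (contig, pos) -> sample


@pytest.fixture(scope="session")
def roundtrip(tmp_path_factory, avaii, mspi) -> RoundTrip:
    """1-Mb genome, 3 samples, fixed depth 20, no errors, no read-through.

    Fixed (non-dispersed) depth keeps every fragment above the minimum
    stack depth so tag counts can be compared to the manifest exactly.
    Three heterozygote-free variants are planted in distinct in-window
    fragments of one sample each.
    """
    workdir = tmp_path_factory.mktemp("roundtrip")
    genome = m.synth_genome(2, 500_000, gc_fraction=0.44, seed=42)
    bset = m.generate_barcode_set(20, (4, 8), seed=7, enzyme_a=avaii)
    samples = ["bambA", "bambB", "bambC"]
    sheet = m.build_sample_sheet(samples, bset, 1)
    config = m.SimConfig(read_length=150, mean_depth=20,
                         depth_dispersion=float("inf"), error_rate=0.0,
                         window=m.SizeWindow(400, 700), seed=5,
                         read_through=False)
    frag_map = m.double_digest(genome, avaii, mspi)
    targets = [f for frags in frag_map.values() for f in frags
               if f.end_class == "AB" and f.length in config.window]
    assert len(targets) >= 6, "synthetic genome yields too few in-window fragments"
    planted: dict[str, dict] = {s: {} for s in samples}
    carrier_of: dict[tuple, str] = {}
    for i, frag in enumerate(targets[:6]):
        # pick a position well inside the 140-bp read1 footprint
        if frag.left_enzyme == avaii.name:
            pos = frag.start + 60 + i   # A end on the left: read1 is top strand
        else:
            pos = frag.end - 61 - i     # A end on the right: read1 is bottom strand
        ref = genome[frag.contig][pos]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        carrier = samples[i % 3]
        planted[carrier][(frag.contig, pos)] = alt
        carrier_of[(frag.contig, pos)] = carrier
    paths, manifest = m.simulate_library(
        genome, sheet, avaii, mspi, config, workdir / "sim",
        sample_variants=planted)
    r1, r2 = paths["pool1"]
    demux_paths, stats = m.demultiplex(r1, r2, sheet, bset, avaii, tol=1,
                                       out_dir=workdir / "demux")
    return RoundTrip(genome=genome, sheet=sheet, bset=bset, config=config,
                     paths=paths, manifest=manifest, demux_paths=demux_paths,
                     demux_stats=stats, planted=planted, carrier_of=carrier_of)


def sample_reads(rt: RoundTrip, sample: str, mate: int = 0) -> list[str]:
    return [s for _, s, _ in read_fastq(rt.demux_paths[sample][mate])]
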