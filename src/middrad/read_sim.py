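"""Synthetic genomes and MiddRAD paired-end read simulation.

Read anatomy (protocol-B style library on an AvaII+MspI digest):

* R1 = [inline barcode][enzyme-A remnant, e.g. GWCC as present at the
  fragment's A end][insert ...]
* R2 = [enzyme-B remnant, e.g. CGG][insert from the other end ...]

Reads are extracted from the *sticky* fragment — the strand extents
between the top-strand cut on one side and the bottom-strand cut on the
other — so the full remnant appears at the read start whichever end of
the genome interval the A-side cut falls on.

Per-fragment depth is negative-binomial (mean, dispersion) to create the
pool imbalance that coefficient-of-variation analyses need; sequencing
errors are i.i.d. substitutions; when the insert is shorter than the read
and read-through is enabled, the read continues into the reverse
complement of the opposite adapter, the diagnostic signature of an
inadequate size selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .digestion import Fragment, SizeWindow, double_digest
from .enzymes import RestrictionEnzyme, reverse_complement
from .io import FastqWriter, read_fasta, write_fasta
from .library_design import AdapterPair, SampleSheet, build_adapters

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs of one simulated sequencing run."""

    read_length: int = 150          # PE150 by default; PE100 also common
    mean_depth: float = 20.0        # expected read pairs per fragment
    depth_dispersion: float = 10.0  # NB size parameter; larger = tighter
    error_rate: float = 0.0         # per-base substitution probability
    window: SizeWindow = field(default_factory=lambda: SizeWindow(400, 700))
    seed: int = 0
    read_through: bool = True
    base_quality: int = 37          # constant Phred with optional 3' taper
    taper_last: int = 0             # bases at the 3' end tapered down
    taper_to: int = 30

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")


def synth_genome(n_contigs: int, contig_length: int, gc_fraction: float = 0.44,
                 repeat_fraction: float = 0.0, seed: int = 0,
                 repeat_unit: int = 200,
                 path: str | Path | None = None) -> dict[str, str]:
    """Generate a random genome with controllable GC and repeat content.

    Repeats are modelled as copies of one sampled unit pasted into
    unit-aligned blocks (tandem when blocks are adjacent, dispersed
    otherwise) so downstream repeat-tagging behaviour can be exercised;
    use :func:`synth_genome_with_log` to also get the placement log.
    Deterministic for a fixed seed.
    """
    contigs, _ = synth_genome_with_log(n_contigs, contig_length, gc_fraction,
                                       repeat_fraction, seed, repeat_unit)
    if path is not None:
        write_fasta(contigs, path)
    return contigs


def synth_genome_with_log(n_contigs: int, contig_length: int,
                          gc_fraction: float = 0.44,
                          repeat_fraction: float = 0.0, seed: int = 0,
                          repeat_unit: int = 200):
    """Like :func:`synth_genome` but also returns the repeat placement log.

    The log is a list of (contig, start, end) spans covered by repeat-unit
    copies; their total length / genome length approximates
    ``repeat_fraction`` up to block rounding.
    """
    if n_contigs <= 0 or contig_length <= 0:
        raise ValueError("n_contigs and contig_length must be positive")
    if not (0 <= gc_fraction <= 1 and 0 <= repeat_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    contigs: dict[str, str] = {}
    log: list[tuple[str, int, int]] = []
    for i in range(n_contigs):
        name = f"contig{i + 1}"
        arr = rng.choice(_BASES, size=contig_length, p=p)
        if repeat_fraction > 0 and contig_length >= repeat_unit:
            unit_start = int(rng.integers(0, contig_length - repeat_unit + 1))
            unit = arr[unit_start:unit_start + repeat_unit].copy()
            n_blocks = contig_length // repeat_unit
            k = int(round(repeat_fraction * n_blocks))
            blocks = rng.choice(n_blocks, size=min(k, n_blocks), replace=False)
            for b in sorted(blocks):
                s = b * repeat_unit
                arr[s:s + repeat_unit] = unit
                log.append((name, s, s + repeat_unit))
        contigs[name] = "".join(arr)
    return contigs, log


def _depth_draws(rng: np.random.Generator, n: int, mean: float,
                 dispersion: float) -> np.ndarray:
    """Negative-binomial pair counts with the given mean and size parameter."""
    if dispersion <= 0 or not np.isfinite(dispersion):
        return np.full(n, int(round(mean)), dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _mutate(read: list[str], rng: np.random.Generator, rate: float) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(read)) < rate)[0]
    for i in hits:
        cur = read[i]
        alts = [b for b in "ACGT" if b != cur]
        read[i] = alts[int(rng.integers(0, 3))]


def _quality_string(cfg: SimConfig) -> str:
    q = np.full(cfg.read_length, cfg.base_quality)
    if cfg.taper_last > 0:
        n = min(cfg.taper_last, cfg.read_length)
        q[-n:] = np.linspace(cfg.base_quality, cfg.taper_to, n).round()
    return "".join(chr(int(v) + 33) for v in q)


def _sticky_template(seq: str, frag: Fragment, a_on_left: bool) -> tuple[str, str]:
    """(R1 template, R2 template) for one fragment, 5'->3' from each end.

    The top strand of the duplex runs between the two top-strand cuts,
    the bottom strand between the two bottom-strand cuts; reading from
    the right end means reading the bottom strand 5'->3', i.e. the
    reverse complement of the bottom-strand extent.  This reproduces the
    full restriction remnant at the read start at either end.
    """
    from_left = seq[frag.start:frag.end]
    bot_lo = min(frag.left_bottom, frag.right_bottom)
    bot_hi = max(frag.left_bottom, frag.right_bottom)
    from_right = reverse_complement(seq[bot_lo:bot_hi])
    return (from_left, from_right) if a_on_left else (from_right, from_left)


def simulate_library(genome, sheet: SampleSheet, enzyme_a: RestrictionEnzyme,
                     enzyme_b: RestrictionEnzyme, config: SimConfig,
                     out_dir: str | Path,
                     sample_variants: Mapping[str, Mapping[tuple[str, int], str]]
                     | None = None) -> tuple[dict[str, tuple[Path, Path]], pd.DataFrame]:
    """Simulate a MiddRAD sequencing run.

    For every sample, every AB fragment inside the size window receives a
    negative-binomial number of read pairs.  ``sample_variants`` maps a
    sample id to substitutions ``{(contig, genome_pos): alt_base}``; they
    are applied to the extracted fragment sequence, so planted variants
    must not fall on cut sites (the digest is shared across samples).

    Returns ``({pool: (r1_path, r2_path)}, truth_manifest)`` where the
    manifest holds one row per (sample, fragment) with the pair count
    emitted.  Deterministic for a fixed config seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = read_fasta(genome)
    frag_map = double_digest(contigs, enzyme_a, enzyme_b)
    targets: list[Fragment] = [
        f for frags in frag_map.values() for f in frags
        if f.end_class == "AB" and f.length in config.window
    ]
    rng = np.random.default_rng(config.seed)
    qual = _quality_string(config)
    bc_by_sample = {s: b for s, b, _ in sheet.rows}
    adapters: dict[str, AdapterPair] = {
        s: build_adapters(b, enzyme_a, enzyme_b) for s, b in bc_by_sample.items()
    }
    writers: dict[str, tuple[FastqWriter, FastqWriter]] = {}
    for pool in sheet.pools():
        writers[pool] = (FastqWriter(out_dir / f"{pool}_R1.fastq.gz"),
                         FastqWriter(out_dir / f"{pool}_R2.fastq.gz"))
    manifest_rows = []
    if not targets:
        import warnings
        warnings.warn("no AB fragments inside the size window; empty FASTQ written")
    for sid, bc, pool in sheet.rows:
        w1, w2 = writers[pool]
        adapt = adapters[sid]
        depths = _depth_draws(rng, len(targets), config.mean_depth,
                              config.depth_dispersion)
        variants = (sample_variants or {}).get(sid, {})
        for frag, k in zip(targets, depths):
            manifest_rows.append({
                "sample": sid, "pool": pool, "contig": frag.contig,
                "start": frag.start, "end": frag.end, "pairs": int(k),
            })
            if k == 0:
                continue
            seq = contigs[frag.contig]
            if variants:
                lo = min(frag.left_bottom, frag.start)
                hi = max(frag.right_bottom, frag.end)
                local = list(seq[lo:hi])
                touched = False
                for (c, pos), alt in variants.items():
                    if c == frag.contig and lo <= pos < hi:
                        local[pos - lo] = alt
                        touched = True
                if touched:
                    seq = seq[:lo] + "".join(local) + seq[hi:]
            a_on_left = frag.left_enzyme == enzyme_a.name
            t1, t2 = _sticky_template(seq, frag, a_on_left)
            for j in range(int(k)):
                r1 = _assemble_read(bc + t1, adapt.p2_top, config)
                r2 = _assemble_read(t2, adapt.p1_top, config)
                _finalize_pair(r1, r2, rng, config)
                title = (f"{sid}:{frag.contig}:{frag.start}-{frag.end}:{j}")
                w1.write(title + "/1", "".join(r1), qual)
                w2.write(title + "/2", "".join(r2), qual)
    paths = {}
    for pool, (w1, w2) in writers.items():
        w1.close()
        w2.close()
        paths[pool] = (w1.path, w2.path)
    manifest = pd.DataFrame(manifest_rows, columns=[
        "sample", "pool", "contig", "start", "end", "pairs"])
    return paths, manifest


def _concretize(pattern: str) -> str:
    """Fix degenerate adapter positions (mixed-base oligo) to one base."""
    from .enzymes import IUPAC
    return "".join(IUPAC.get(c, "N")[0] for c in pattern)


def _assemble_read(template: str, opposite_adapter_top: str,
                   config: SimConfig) -> list[str]:
    n = config.read_length
    read = template[:n]
    if len(read) < n and config.read_through:
        tail = reverse_complement(_concretize(opposite_adapter_top))
        read += tail[:n - len(read)]
    if len(read) < n:
        read += "A" * (n - len(read))  # off-template dark cycles
    return list(read)


def _finalize_pair(r1: list[str], r2: list[str], rng: np.random.Generator,
                   config: SimConfig) -> None:
    _mutate(r1, rng, config.error_rate)
    _mutate(r2, rng, config.error_rate)
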