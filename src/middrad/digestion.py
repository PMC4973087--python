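"""In silico double digestion: fragments, end classes, size windows, histograms.

Double digestion pools the cut coordinates of the two enzymes per contig,
deduplicates and sorts them, and the intervals between consecutive
coordinates (including contig boundaries) are the fragments.  Fragment
boundaries are TOP-strand cut coordinates; sticky-end overhangs do not
count toward length (errors of at most a few bp per end).  The
bottom-strand coordinate of each bounding cut is retained because the read
simulator needs the physical strand extents to reproduce restriction
remnants at both fragment ends.

Only AB fragments — one end cut by each enzyme — receive both adapters and
amplify in a ddRAD library, so counting defaults to the AB class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enzymes import RestrictionEnzyme, find_sites
from .io import read_fasta

TERMINAL = "TERMINAL"
END_CLASSES = ("AB", "AA", "BB", "TERMINAL")


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length window, e.g. 400-700 bp from a gel cut."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"invalid size window [{self.min_len}, {self.max_len}]")

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


@dataclass(frozen=True)
class Fragment:
    """A double-digest fragment in 0-based half-open top-strand coordinates."""

    contig: str
    start: int
    end: int
    left_enzyme: str   # enzyme name or TERMINAL
    right_enzyme: str  # enzyme name or TERMINAL
    end_class: str
    # bottom-strand coordinates of the bounding cuts (== start/end at
    # contig boundaries); needed to extract sticky-end read templates
    left_bottom: int = -1
    right_bottom: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must precede end")
        if self.left_bottom < 0:
            object.__setattr__(self, "left_bottom", self.start)
        if self.right_bottom < 0:
            object.__setattr__(self, "right_bottom", self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def _classify(left: str, right: str, enz_a: str, enz_b: str) -> str:
    if left == TERMINAL or right == TERMINAL:
        return TERMINAL
    ends = {left, right}
    if ends == {enz_a, enz_b}:
        return "AB"
    return "AA" if ends == {enz_a} else "BB"


def double_digest(genome, enz_a: RestrictionEnzyme,
                  enz_b: RestrictionEnzyme) -> dict[str, list[Fragment]]:
    """Digest a genome (FASTA path or contig dict) with two enzymes.

    Returns fragments per contig, tiling each contig exactly.  Coincident
    cut coordinates from the two enzymes are deduplicated (the
    alphabetically first enzyme name labels the cut).
    """
    if enz_a.name == enz_b.name:
        raise ValueError("the two enzymes must differ")
    contigs = read_fasta(genome)
    out: dict[str, list[Fragment]] = {}
    for name, seq in contigs.items():
        cuts: dict[int, tuple[str, int]] = {}  # top coord -> (enzyme, bottom coord)
        for enz in (enz_a, enz_b):
            for site in find_sites(seq, enz, contig=name):
                pos = site.cut_pos
                if 0 < pos < len(seq):
                    prev = cuts.get(pos)
                    if prev is None or enz.name < prev[0]:
                        cuts[pos] = (enz.name, site.cut_pos_bottom)
        boundaries = [(0, TERMINAL, 0)] + sorted(
            (p, e, b) for p, (e, b) in cuts.items()
        ) + [(len(seq), TERMINAL, len(seq))]
        frags = []
        for (s, left_enz, s_bot), (e, right_enz, e_bot) in zip(boundaries, boundaries[1:]):
            frags.append(Fragment(
                name, s, e, left_enz, right_enz,
                _classify(left_enz, right_enz, enz_a.name, enz_b.name),
                left_bottom=min(max(s_bot, 0), len(seq)),
                right_bottom=min(max(e_bot, 0), len(seq)),
            ))
        out[name] = frags
    return out


def iter_fragments(fragments) -> Iterable[Fragment]:
    """Flatten per-contig fragment dicts; lists pass through."""
    if isinstance(fragments, Mapping):
        for frags in fragments.values():
            yield from frags
    else:
        yield from fragments


def count_fragments(fragments, window: SizeWindow | None = None,
                    classes: Sequence[str] = ("AB",)) -> int:
    """Count fragments by end class within an inclusive length window."""
    cls = set(classes)
    n = 0
    for f in iter_fragments(fragments):
        if f.end_class in cls and (window is None or f.length in window):
            n += 1
    return n


def size_histogram(fragments, bin_width: int = 100, max_bp: int = 1500,
                   classes: Sequence[str] = ("AB",)) -> np.ndarray:
    """Fragment-length histogram: bins of *bin_width* over [0, max_bp) plus overflow.

    Bin i counts lengths in [i*bin_width, (i+1)*bin_width); the final bin
    counts lengths >= max_bp.  Bins sum to the number of counted fragments.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nbins = max_bp // bin_width
    hist = np.zeros(nbins + 1, dtype=int)
    cls = set(classes)
    for f in iter_fragments(fragments):
        if f.end_class not in cls:
            continue
        hist[min(f.length // bin_width, nbins)] += 1
    return hist


def per_chromosome_counts(fragments: Mapping[str, list[Fragment]],
                          window: SizeWindow | None = None,
                          classes: Sequence[str] = ("AB",)) -> dict[str, int]:
    """Per-contig window counts; values sum to the genome-wide count."""
    return {c: count_fragments(frags, window, classes)
            for c, frags in fragments.items()}


@dataclass
class DigestProfile:
    """Per-genome, per-pair digestion summary."""

    genome_id: str
    genome_length: int
    site_counts: dict[str, int]
    class_counts: dict[str, int]
    window: SizeWindow | None
    window_count: int
    histogram: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "genome_id": self.genome_id,
            "genome_length": self.genome_length,
            "site_counts": self.site_counts,
            "class_counts": self.class_counts,
            "window_count": self.window_count,
            "histogram": list(self.histogram),
        }
        if self.window is not None:
            d["window"] = [self.window.min_len, self.window.max_len]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def profile_digest(genome, enz_a: RestrictionEnzyme, enz_b: RestrictionEnzyme,
                   window: SizeWindow | None = None,
                   genome_id: str = "genome") -> DigestProfile:
    """Digest and summarize: site counts, class counts, window count, histogram."""
    contigs = read_fasta(genome)
    frags = double_digest(contigs, enz_a, enz_b)
    site_counts = {
        e.name: sum(len(find_sites(seq, e)) for seq in contigs.values())
        for e in (enz_a, enz_b)
    }
    class_counts = {c: count_fragments(frags, None, (c,)) for c in END_CLASSES}
    return DigestProfile(
        genome_id=genome_id,
        genome_length=sum(len(s) for s in contigs.values()),
        site_counts=site_counts,
        class_counts=class_counts,
        window=window,
        window_count=count_fragments(frags, window, ("AB",)),
        histogram=size_histogram(frags).tolist(),
    )


def write_bed(fragments, path: str | Path) -> None:
    """Write fragments as BED6 (name = leftEnz_rightEnz, score = length)."""
    with open(path, "w") as fh:
        for f in iter_fragments(fragments):
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t"
                     f"{f.left_enzyme}_{f.right_enzyme}\t{f.length}\t+\n")
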