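"""Restriction enzymes with degenerate (IUPAC) recognition sites.

A :class:`RestrictionEnzyme` is a recognition motif over the IUPAC DNA
alphabet plus the two strand-specific cut offsets, measured in bases from
the start of the recognition sequence on the top strand.  For example
AvaII (``G^GWCC``) cuts the top strand after 1 base and the bottom strand
after 4, leaving a 3-nt 5' overhang ``GWC``; the 4-nt remnant retained at
the downstream read start is ``GWCC``.

Coordinates are 0-based and half-open throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; IUPAC codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(pattern: str) -> set[str]:
    """Expand an IUPAC pattern into the set of concrete ACGT strings.

    The result size is the product of per-position degeneracies
    (e.g. ``GGWCC`` -> {GGACC, GGTCC}).

    Raises
    ------
    ValueError
        If the pattern is empty or contains a non-IUPAC character.
    """
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    choices = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
        choices.append(IUPAC[ch])
    return {"".join(p) for p in product(*choices)}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme with possibly degenerate recognition."""

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int
    self_rc: bool = field(init=False)

    def __post_init__(self) -> None:
        expanded = expand_iupac(self.recognition)  # validates alphabet
        n = len(self.recognition)
        if not (0 <= self.cut_offset_top <= n and 0 <= self.cut_offset_bottom <= n):
            raise ValueError(
                f"{self.name}: cut offsets must lie within [0, {n}]"
            )
        object.__setattr__(
            self, "self_rc", expanded == {reverse_complement(s) for s in expanded}
        )

    def __len__(self) -> int:
        return len(self.recognition)

    @property
    def remnant(self) -> str:
        """IUPAC pattern retained at the downstream fragment's read start."""
        return self.recognition[self.cut_offset_top:]

    @property
    def overhang(self) -> str:
        """The single-stranded overhang pattern left by the cut (5' if top<bottom)."""
        lo = min(self.cut_offset_top, self.cut_offset_bottom)
        hi = max(self.cut_offset_top, self.cut_offset_bottom)
        return self.recognition[lo:hi]

    def compiled(self) -> re.Pattern:
        """Regex matching every concrete expansion, with overlap lookahead."""
        alts = "|".join(sorted(expand_iupac(self.recognition)))
        return re.compile(f"(?=(?:{alts}))")


def is_self_rc(enzyme: RestrictionEnzyme) -> bool:
    """True iff the concrete expansions are closed under reverse complement."""
    return enzyme.self_rc


@dataclass(frozen=True)
class CutSite:
    """A located recognition match with its top/bottom-strand cut coordinates."""

    contig: str
    match_start: int
    cut_pos: int           # top-strand cut coordinate
    enzyme: str
    strand: str            # "+" or "-"
    cut_pos_bottom: int = -1

    def __post_init__(self) -> None:
        if self.cut_pos_bottom < 0:
            object.__setattr__(self, "cut_pos_bottom", self.cut_pos)


def find_sites(sequence: str, enzyme: RestrictionEnzyme,
               contig: str = "seq") -> list[CutSite]:
    """Locate all recognition sites of *enzyme* on *sequence*.

    Forward-strand matches are always reported; minus-strand matches are
    added only for non-palindromic (non ``self_rc``) enzymes, since for
    palindromes both orientations are the same site.  Overlapping matches
    are all reported.  Windows containing non-ACGT characters (assembly
    gaps, ambiguity codes) never match.

    Returned sites are sorted by ``match_start`` and carry both the
    top-strand (``cut_pos``) and bottom-strand (``cut_pos_bottom``)
    cut coordinates.
    """
    seq = sequence.upper()
    L = len(enzyme.recognition)
    sites: list[CutSite] = []
    for m in enzyme.compiled().finditer(seq):
        s = m.start()
        sites.append(CutSite(contig, s, s + enzyme.cut_offset_top, enzyme.name,
                             "+", s + enzyme.cut_offset_bottom))
    if not enzyme.self_rc:
        rc_alts = "|".join(
            sorted({reverse_complement(x) for x in expand_iupac(enzyme.recognition)})
        )
        for m in re.finditer(f"(?=(?:{rc_alts}))", seq):
            s = m.start()
            # a minus-strand site: the enzyme's top strand is the genome's
            # bottom strand, so genome-top cut = mirror of the bottom offset
            sites.append(CutSite(contig, s, s + L - enzyme.cut_offset_bottom,
                                 enzyme.name, "-", s + L - enzyme.cut_offset_top))
    sites.sort(key=lambda c: (c.match_start, c.strand))
    return sites


# REBASE-standard offsets; the table ships with the package and can be
# overridden or extended from a TSV of the same shape.
_BUILTIN_ROWS = [
    ("AvaII", "GGWCC", 1, 4),
    ("MspI", "CCGG", 1, 3),
    ("EcoRI", "GAATTC", 1, 5),
    ("PstI", "CTGCAG", 5, 1),
    ("SbfI", "CCTGCAGG", 2, 6),
    ("MluCI", "AATT", 0, 4),
    ("NlaIII", "CATG", 4, 0),
]


def load_enzyme_table(path: str | Path | None = None) -> dict[str, RestrictionEnzyme]:
    """Load enzymes from a TSV (name, recognition, cut_offset_top, cut_offset_bottom).

    Without a path, returns the built-in table.
    """
    table: dict[str, RestrictionEnzyme] = {}
    if path is None:
        try:
            text = (resources.files("middrad") / "data" / "enzymes.tsv").read_text()
        except (FileNotFoundError, ModuleNotFoundError):
            for name, rec, t, b in _BUILTIN_ROWS:
                table[name] = RestrictionEnzyme(name, rec, t, b)
            return table
    else:
        text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, rec, top, bottom = line.split("\t")
        table[name] = RestrictionEnzyme(name, rec, int(top), int(bottom))
    return table


def get_enzyme(name: str, extra: str | Path | None = None) -> RestrictionEnzyme:
    """Fetch an enzyme by name from the built-in table (plus optional user TSV)."""
    table = load_enzyme_table()
    if extra is not None:
        table.update(load_enzyme_table(extra))
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {', '.join(sorted(table))}"
        ) from None


def write_enzyme_table(enzymes: Iterable[RestrictionEnzyme], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\trecognition\tcut_offset_top\tcut_offset_bottom\n")
        for e in enzymes:
            fh.write(f"{e.name}\t{e.recognition}\t{e.cut_offset_top}\t{e.cut_offset_bottom}\n")
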