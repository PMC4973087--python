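"""Variable-length inline barcodes, adapter models and sample sheets.

Barcodes of varying length (4-8 bp) stagger the restriction-site remnant
across sequencing cycles, which keeps per-cycle base composition balanced
on Illumina machines.  Because lengths vary, the barcode is delimited by
the downstream restriction remnant rather than by position, so the set
must be prefix-free; a minimum pairwise edit distance of 2 gives
single-error detection; and no barcode may end in bases that, followed by
the remnant, reconstitute the P1 enzyme's recognition site (such a
junction would be re-cut during ligation-digestion).

The set is generated in multiples of 20 with lengths balanced across the
allowed range, so sub-libraries can reuse the same 20 barcodes with
different pool indexes (20 * n samples).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .enzymes import RestrictionEnzyme, expand_iupac, reverse_complement

_BASES = "ACGT"
# Illumina-compatible placeholder stubs; only length and overhang are normative
_P1_STUB_FULL = "ACACTCTTTCCCTACACGACGAC"
_P2_STUB_FULL = "GTGACTGGAGTTCAGACGTGTGC"


@dataclass(frozen=True)
class Barcode:
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or any(c not in _BASES for c in self.sequence):
            raise ValueError(f"barcode must be non-empty ACGT: {self.sequence!r}")
        if not (4 <= len(self.sequence) <= 8):
            raise ValueError("barcode length must be 4-8 bp")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BarcodeSet:
    barcodes: list[Barcode]
    seed: int | None = None
    min_distance: int = 2

    def __iter__(self):
        return iter(self.barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)

    def sequences(self) -> list[str]:
        return [b.sequence for b in self.barcodes]

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{b.sequence}\n" for b in self.barcodes))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeSet":
        seqs = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls([Barcode(s) for s in seqs])


def _forbidden_suffix(candidate: str, enzyme: RestrictionEnzyme) -> bool:
    """True if candidate's tail + the read-side remnant rebuilds the site.

    The remnant is recognition[t:]; the junction reconstitutes the site
    exactly when the last t bases of the barcode match recognition[:t].
    """
    t = enzyme.cut_offset_top
    if t == 0 or len(candidate) < t:
        return False
    head = enzyme.recognition[:t]
    return candidate[-t:] in expand_iupac(head)


def _violations_pair(a: str, b: str, min_distance: int) -> list[str]:
    out = []
    if a != b and (a.startswith(b) or b.startswith(a)):
        out.append(f"prefix violation: {min(a, b, key=len)} is a prefix of "
                   f"{max(a, b, key=len)}")
    d = edlib.align(a, b, task="distance")["editDistance"]
    if d < min_distance:
        out.append(f"distance violation: d({a},{b}) = {d} < {min_distance}")
    return out


def validate_barcode_set(bset: BarcodeSet, enzyme_a: RestrictionEnzyme,
                         length_range: tuple[int, int] = (4, 8)) -> list[str]:
    """Check every design invariant; returns violations (empty = valid)."""
    seqs = bset.sequences()
    report: list[str] = []
    for i, a in enumerate(seqs):
        if _forbidden_suffix(a, enzyme_a):
            report.append(
                f"site-reconstitution violation: {a} ends with bases that, "
                f"joined to remnant {enzyme_a.remnant}, rebuild "
                f"{enzyme_a.recognition}")
        for b in seqs[i + 1:]:
            report.extend(_violations_pair(a, b, bset.min_distance))
    # length balance: each length class within +/-1 of equal share
    lo, hi = length_range
    classes = list(range(lo, hi + 1))
    per = {c: sum(1 for s in seqs if len(s) == c) for c in classes}
    share = len(seqs) / len(classes)
    for c, n in per.items():
        if abs(n - share) > 1:
            report.append(f"length-balance violation: {n} barcodes of length {c}, "
                          f"expected ~{share:.1f}")
    return report


def generate_barcode_set(count: int, length_range: tuple[int, int] = (4, 8),
                         seed: int = 0,
                         enzyme_a: RestrictionEnzyme | None = None,
                         min_distance: int = 2,
                         max_attempts: int = 200_000) -> BarcodeSet:
    """Greedy rejection search for a constraint-satisfying barcode set.

    ``count`` must be a multiple of 20; lengths are dealt round-robin over
    the allowed range so each class holds an equal (+/-1) share.
    Deterministic for a fixed seed.
    """
    if count <= 0 or count % 20:
        raise ValueError("barcode count must be a positive multiple of 20")
    lo, hi = length_range
    if not (4 <= lo <= hi <= 8):
        raise ValueError("length range must lie within [4, 8]")
    rng = random.Random(seed)
    classes = list(range(lo, hi + 1))
    wanted = [classes[i % len(classes)] for i in range(count)]
    accepted: list[str] = []
    attempts = 0
    for length in wanted:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not satisfy barcode constraints for count={count}, "
                    f"lengths {length_range} after {max_attempts} attempts")
            cand = "".join(rng.choice(_BASES) for _ in range(length))
            if enzyme_a is not None and _forbidden_suffix(cand, enzyme_a):
                continue
            if any(_violations_pair(cand, a, min_distance) for a in accepted):
                continue
            accepted.append(cand)
            break
    return BarcodeSet([Barcode(s) for s in accepted], seed=seed,
                      min_distance=min_distance)


@dataclass(frozen=True)
class AdapterPair:
    """P1/P2 oligo model: [stub][barcode][overhang] for P1, fixed P2."""

    p1_top: str
    p2_top: str
    barcode: str
    overhang_a: str
    overhang_b: str


def build_adapters(barcode: Barcode | str, enzyme_a: RestrictionEnzyme,
                   enzyme_b: RestrictionEnzyme) -> AdapterPair:
    """Assemble the adapter pair for one barcode.

    P1 length contract: len(p1_top) = 20 + len(barcode) (25 bp for the
    canonical 5-bp barcode).  Each adapter ends in the single-stranded
    overhang complementary to its enzyme's sticky end; blunt cutters are
    rejected because ligation requires compatible overhangs.
    """
    bc = barcode.sequence if isinstance(barcode, Barcode) else Barcode(barcode).sequence
    for enz in (enzyme_a, enzyme_b):
        if enz.cut_offset_top == enz.cut_offset_bottom:
            raise ValueError(f"{enz.name} is a blunt cutter; sticky ends required")
    over_a = reverse_complement(enzyme_a.overhang)
    over_b = reverse_complement(enzyme_b.overhang)
    stub1 = _P1_STUB_FULL[:20 - len(over_a)]
    p1 = stub1 + bc + over_a
    assert len(p1) == 20 + len(bc)
    p2 = _P2_STUB_FULL[:20 - len(over_b)] + over_b
    return AdapterPair(p1_top=p1, p2_top=p2, barcode=bc,
                       overhang_a=over_a, overhang_b=over_b)


@dataclass
class SampleSheet:
    """Rows of (sample_id, barcode, pool_index); pairs are unique."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(bc, pool) for _, bc, pool in self.rows]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (barcode, pool_index) pair in sample sheet")

    def __len__(self) -> int:
        return len(self.rows)

    def samples(self) -> list[str]:
        return [s for s, _, _ in self.rows]

    def pools(self) -> list[str]:
        return sorted({p for _, _, p in self.rows})

    def rows_for_pool(self, pool: str) -> list[tuple[str, str, str]]:
        return [r for r in self.rows if r[2] == pool]

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{b}\t{p}\n" for s, b, p in self.rows))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        rows = []
        for ln in Path(path).read_text().splitlines():
            if ln.strip():
                s, b, p = ln.rstrip("\n").split("\t")
                rows.append((s, b, p))
        return cls(rows)


def build_sample_sheet(samples: list[str], bset: BarcodeSet,
                       n_pools: int) -> SampleSheet:
    """Assign samples round-robin to (barcode, pool) pairs.

    Barcodes cycle within pool 1 first, then pool 2, etc.; capacity is
    len(bset) * n_pools and no pair is reused.
    """
    capacity = len(bset) * n_pools
    if len(samples) > capacity:
        raise ValueError(
            f"{len(samples)} samples exceed capacity {capacity} "
            f"({len(bset)} barcodes x {n_pools} pools)")
    seqs = bset.sequences()
    rows = []
    for i, sid in enumerate(samples):
        pool = i // len(seqs) + 1
        rows.append((sid, seqs[i % len(seqs)], f"pool{pool}"))
    return SampleSheet(rows)
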