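"""RAD tag clustering: per-sample stacks, cross-sample catalog, SNP matrix.

A deliberately simple, fully deterministic clustering of truncated read1
sequences, in the spirit of the ustacks/cstacks/sstacks trio but
self-contained and oracle-testable:

* identical reads form exact *stacks*; stacks with depth >= m are
  primaries;
* primaries within <= M Hamming mismatches are merged (single linkage,
  deeper stacks seed first), then sub-threshold stacks attach to the
  nearest merged group within <= M;
* primary stacks with depth > mean + 3 sd of primary depths are flagged
  repetitive and excluded — a simple stand-in for depth-based removal of
  repeat-derived stacks;
* the cross-sample catalog is greedy single linkage over tag consensuses
  at <= n mismatches, in deterministic (sample, consensus) order;
* per-sample calls at a locus's variant columns give the SNP matrix,
  exportable as sequential Phylip.

Distances are Hamming (no gaps); consensuses are column-majority with
lexicographic tie-break; >2-allele columns are IUPAC-coded on export.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_IUPAC_FROM_BASES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def iupac_code(bases: Iterable[str]) -> str:
    key = frozenset(b for b in bases if b in "ACGT")
    return _IUPAC_FROM_BASES.get(key, "N")


@dataclass
class ClusterParams:
    m: int = 10          # minimum stack depth
    M: int = 3           # within-sample merge mismatch limit
    n: int = 5           # across-sample catalog mismatch limit
    tag_length: int = 140

    def __post_init__(self) -> None:
        if self.m < 1 or self.M < 0 or self.n < 0 or self.tag_length < 1:
            raise ValueError("invalid clustering parameters")
        if self.n < self.M:
            import warnings
            warnings.warn("catalog mismatch limit n < within-sample limit M")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def truncate_reads(reads: Iterable[str], tag_length: int = 140
                   ) -> tuple[list[str], int]:
    """Exact-length prefixes; shorter reads are dropped and counted."""
    kept, dropped = [], 0
    for seq in reads:
        if len(seq) >= tag_length:
            kept.append(seq[:tag_length])
        else:
            dropped += 1
    return kept, dropped


@dataclass
class Tag:
    sample: str
    consensus: str
    depth: int
    alleles: dict[str, int] = field(default_factory=dict)  # haplotype -> depth

    @property
    def variant_columns(self) -> list[int]:
        if len(self.alleles) < 2:
            return []
        seqs = list(self.alleles)
        return [i for i in range(len(seqs[0]))
                if len({s[i] for s in seqs}) > 1]


def _consensus(members: Mapping[str, int]) -> str:
    """Depth-weighted column majority; ties to the lexicographically first base."""
    seqs = list(members)
    length = len(seqs[0])
    out = []
    for i in range(length):
        votes: Counter[str] = Counter()
        for s, d in members.items():
            votes[s[i]] += d
        best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


@dataclass
class StackReport:
    tags: list[Tag]
    input_reads: int
    below_m_unmerged: int
    repetitive_excluded: int

    def conserved(self) -> bool:
        return (sum(t.depth for t in self.tags) + self.below_m_unmerged
                + self.repetitive_excluded == self.input_reads)


def build_stacks(reads: Sequence[str], sample: str = "sample",
                 params: ClusterParams | None = None) -> StackReport:
    """Cluster one sample's fixed-length reads into Tags.

    Reads must already be truncated to a common length (see
    :func:`truncate_reads`).
    """
    params = params or ClusterParams()
    if reads and len({len(r) for r in reads}) > 1:
        raise ValueError("reads must share one length; truncate first")
    stacks = Counter(reads)
    primaries = {s: d for s, d in stacks.items() if d >= params.m}
    secondaries = {s: d for s, d in stacks.items() if d < params.m}
    repetitive = 0
    if len(primaries) >= 2:
        depths = list(primaries.values())
        mean = sum(depths) / len(depths)
        var = sum((d - mean) ** 2 for d in depths) / (len(depths) - 1)
        cutoff = mean + 3 * var ** 0.5
        flagged = [s for s, d in primaries.items() if d > cutoff]
        for s in flagged:
            repetitive += primaries.pop(s)
    # single-linkage merge of primaries within M, deepest seeds first
    order = sorted(primaries, key=lambda s: (-primaries[s], s))
    groups: list[dict[str, int]] = []
    for s in order:
        joined = None
        for g in groups:
            if any(_hamming(s, member) <= params.M for member in g):
                if joined is None:
                    g[s] = primaries[s]
                    joined = g
                else:       # s bridges two groups: merge them
                    joined.update(g)
                    g.clear()
        groups = [g for g in groups if g]
        if joined is None:
            groups.append({s: primaries[s]})
    # attach secondaries to the best group (fewest mismatches to any member;
    # ties to the deeper group, then lexicographic consensus)
    unmerged = 0
    for s, d in sorted(secondaries.items()):
        best = None
        for g in groups:
            dist = min(_hamming(s, member) for member in g)
            if dist > params.M:
                continue
            key = (dist, -sum(g.values()), _consensus(g))
            if best is None or key < best[0]:
                best = (key, g)
        if best is None:
            unmerged += d
        else:
            best[1][s] = best[1].get(s, 0) + d
    tags = []
    for g in groups:
        tags.append(Tag(sample=sample, consensus=_consensus(g),
                        depth=sum(g.values()), alleles=dict(sorted(g.items()))))
    tags.sort(key=lambda t: t.consensus)
    return StackReport(tags=tags, input_reads=len(reads),
                       below_m_unmerged=unmerged, repetitive_excluded=repetitive)


@dataclass
class CatalogLocus:
    locus_id: int
    consensus: str
    members: list[Tag] = field(default_factory=list)

    @property
    def variant_columns(self) -> list[int]:
        cols: set[int] = set()
        seqs = [t.consensus for t in self.members]
        for i in range(len(self.consensus)):
            if len({s[i] for s in seqs}) > 1:
                cols.add(i)
        for t in self.members:
            cols.update(t.variant_columns)
        return sorted(cols)


def build_catalog(tags_by_sample: Mapping[str, Sequence[Tag]],
                  params: ClusterParams | None = None) -> list[CatalogLocus]:
    """Greedy single-linkage merge of tag consensuses across samples.

    Tags are processed in (sample name, consensus) order; each joins the
    closest existing locus within <= n mismatches (ties to the earliest
    locus) or founds a new one.  Locus consensus is the unweighted
    column majority of member tag consensuses.
    """
    params = params or ClusterParams()
    loci: list[CatalogLocus] = []
    for sample in sorted(tags_by_sample):
        for tag in sorted(tags_by_sample[sample], key=lambda t: t.consensus):
            best = None
            for locus in loci:
                if len(locus.consensus) != len(tag.consensus):
                    continue
                d = _hamming(tag.consensus, locus.consensus)
                if d <= params.n and (best is None or d < best[0]):
                    best = (d, locus)
            if best is None:
                loci.append(CatalogLocus(len(loci) + 1, tag.consensus, [tag]))
            else:
                locus = best[1]
                locus.members.append(tag)
                locus.consensus = _consensus(
                    Counter(t.consensus for t in locus.members))
    return loci


@dataclass
class SNPMatrix:
    samples: list[str]
    columns: list[tuple[int, int]]          # (locus_id, position)
    calls: dict[str, list[str]]             # sample -> IUPAC codes per column

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def match_and_genotype(tags_by_sample: Mapping[str, Sequence[Tag]],
                       catalog: Sequence[CatalogLocus],
                       params: ClusterParams | None = None) -> SNPMatrix:
    """Assign each sample's tags to catalog loci and call variant columns.

    A tag matches the unique best locus within <= n mismatches; a sample
    without a matching tag at a locus gets the missing code ``N`` at that
    locus's columns.  Heterozygous tags (multiple alleles) are IUPAC-coded.
    """
    params = params or ClusterParams()
    samples = sorted(tags_by_sample)
    var_cols = [(locus.locus_id, pos) for locus in catalog
                for pos in locus.variant_columns]
    calls = {s: ["N"] * len(var_cols) for s in samples}
    col_index = {key: i for i, key in enumerate(var_cols)}
    for s in samples:
        for tag in tags_by_sample[s]:
            best, n_best = None, 0
            for locus in catalog:
                if len(locus.consensus) != len(tag.consensus):
                    continue
                d = _hamming(tag.consensus, locus.consensus)
                if d > params.n:
                    continue
                if best is None or d < best[0]:
                    best, n_best = (d, locus), 1
                elif d == best[0]:
                    n_best += 1
            if best is None or n_best != 1:
                continue
            locus = best[1]
            for pos in locus.variant_columns:
                bases = {h[pos] for h in tag.alleles} or {tag.consensus[pos]}
                calls[s][col_index[(locus.locus_id, pos)]] = iupac_code(bases)
    return SNPMatrix(samples=samples, columns=var_cols, calls=calls)


def filter_fixed_within_variable_among(matrix: SNPMatrix,
                                       groups: Mapping[str, str],
                                       allow_missing: bool = False
                                       ) -> SNPMatrix:
    """Keep columns fixed within each group but variable among groups.

    The diagnostic-marker screen for multi-species panels: a column
    survives if every group (species) is monomorphic for one base and at
    least two groups carry different bases.  Missing calls (``N``) drop a
    column unless ``allow_missing`` is set, in which case a group's state
    is judged on its called samples only.
    """
    unknown = set(matrix.samples) - set(groups)
    if unknown:
        raise ValueError(f"samples without a group: {sorted(unknown)}")
    by_group: dict[str, list[str]] = {}
    for s in matrix.samples:
        by_group.setdefault(groups[s], []).append(s)
    keep: list[int] = []
    for i in range(matrix.n_columns):
        states = []
        ok = True
        for members in by_group.values():
            calls = [matrix.calls[s][i] for s in members]
            if not allow_missing and "N" in calls:
                ok = False
                break
            called = [c for c in calls if c != "N"]
            if not called or len(set(called)) > 1:
                ok = False
                break
            states.append(called[0])
        if ok and len(set(states)) > 1:
            keep.append(i)
    return SNPMatrix(
        samples=matrix.samples,
        columns=[matrix.columns[i] for i in keep],
        calls={s: [matrix.calls[s][i] for i in keep] for s in matrix.samples})


def export_phylip(matrix: SNPMatrix, path: str | Path) -> None:
    """Write the SNP matrix as sequential Phylip (names padded to 10 chars).

    Three or more samples are needed for an informative unrooted tree; a
    warning is emitted below that.
    """
    if matrix.n_columns == 0 or not matrix.samples:
        raise ValueError("empty SNP matrix cannot be exported")
    if len(matrix.samples) != len(set(matrix.samples)):
        raise ValueError("duplicate sample names in SNP matrix")
    if len(matrix.samples) < 3:
        import warnings
        warnings.warn("fewer than 3 samples: unrooted tree will be uninformative")
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.samples)} {matrix.n_columns}\n")
        for s in matrix.samples:
            fh.write(f"{s[:10]:<10}{''.join(matrix.calls[s])}\n")
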