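"""Enzyme-pair screening across genomes and ddRAD summary statistics.

The screen answers the design question "which enzyme pair gives enough —
but not too many — sequenceable fragments on my genome?"  For each
(genome, pair) it reports the total number of AB fragments and the number
inside the size-selection window; across genomes of different sizes the
window count is well described by an ordinary least-squares line on genome
size (Mb), which lets tag yield be predicted for an unsequenced species
from its C-value alone.

Summary metrics follow the standard reduced-representation bookkeeping:

* tags per 100 kb  = tag_count / genome_length * 1e5
* simplification ratio (%) = tag_count * tag_length / genome_length * 100
* mean tag depth   = clean_read_count / tag_count
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .digestion import SizeWindow, count_fragments, double_digest
from .enzymes import RestrictionEnzyme
from .io import read_fasta


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of fragment count on genome size in Mb."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class SummaryMetrics:
    tag_count: int
    tag_length: int
    genome_length: int
    clean_read_count: int
    tags_per_100kb: float
    simplification_ratio: float
    mean_tag_depth: float
    expected_over_observed: float | None = None


def screen_pairs(genomes: Sequence[tuple], pairs: Sequence[tuple],
                 window: SizeWindow) -> pd.DataFrame:
    """Digest every genome with every enzyme pair and tabulate AB counts.

    Parameters
    ----------
    genomes
        Tuples ``(genome_id, fasta_or_dict)`` or ``(genome_id, fasta, size_mb)``.
    pairs
        Tuples ``(RestrictionEnzyme, RestrictionEnzyme)``.

    Returns a DataFrame with one row per (genome, pair): total AB
    fragments, window AB fragments, genome size in Mb, and an ``error``
    column; an unreadable genome is recorded and the screen continues.
    """
    if not genomes or not pairs:
        raise ValueError("need at least one genome and one pair")
    rows = []
    for entry in genomes:
        gid, source = entry[0], entry[1]
        size_mb = entry[2] if len(entry) > 2 else None
        try:
            contigs = read_fasta(source)
        except Exception as e:  # noqa: BLE001 - per-genome errors are data
            for enz_a, enz_b in pairs:
                rows.append({"genome": gid, "pair": f"{enz_a.name}+{enz_b.name}",
                             "total_ab": None, "window_ab": None,
                             "genome_mb": size_mb, "error": str(e)})
            continue
        if size_mb is None:
            size_mb = sum(len(s) for s in contigs.values()) / 1e6
        for enz_a, enz_b in pairs:
            frags = double_digest(contigs, enz_a, enz_b)
            rows.append({
                "genome": gid,
                "pair": f"{enz_a.name}+{enz_b.name}",
                "total_ab": count_fragments(frags, None, ("AB",)),
                "window_ab": count_fragments(frags, window, ("AB",)),
                "genome_mb": size_mb,
                "error": "",
            })
    return pd.DataFrame(rows)


def fit_genome_size_model(rows: pd.DataFrame,
                          response: str = "window_ab") -> RegressionModel:
    """OLS line of fragment count on genome size (Mb) for one enzyme pair."""
    clean = rows.dropna(subset=[response, "genome_mb"])
    x = clean["genome_mb"].to_numpy(float)
    y = clean[response].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 genomes to fit the size model")
    if x.std() == 0:
        raise ValueError("genome sizes have zero variance")
    fit = stats.linregress(x, y)
    r2 = 0.0 if y.std() == 0 else fit.rvalue ** 2
    return RegressionModel(slope=float(fit.slope), intercept=float(fit.intercept),
                           r_squared=_round_half_up(r2, 4))


def predict_tag_count(model: RegressionModel, genome_size_mb: float) -> float:
    """Predicted fragment count for a genome size, floored at zero."""
    return max(0.0, model.slope * genome_size_mb + model.intercept)


def summary_metrics(tag_count: int, tag_length: int, genome_length: int,
                    clean_read_count: int,
                    expected_tag_count: int | None = None) -> SummaryMetrics:
    """Reduced-representation summary for one library (2-decimal reporting)."""
    for label, v in (("tag_count", tag_count), ("tag_length", tag_length),
                     ("genome_length", genome_length),
                     ("clean_read_count", clean_read_count)):
        if v <= 0:
            raise ValueError(f"{label} must be positive, got {v}")
    eo = None
    if expected_tag_count is not None:
        if expected_tag_count <= 0:
            raise ValueError("expected_tag_count must be positive")
        eo = _round_half_up(expected_tag_count / tag_count * 100, 2)
    return SummaryMetrics(
        tag_count=tag_count,
        tag_length=tag_length,
        genome_length=genome_length,
        clean_read_count=clean_read_count,
        tags_per_100kb=_round_half_up(tag_count / genome_length * 1e5, 2),
        simplification_ratio=_round_half_up(
            tag_count * tag_length / genome_length * 100, 2),
        mean_tag_depth=_round_half_up(clean_read_count / tag_count, 2),
        expected_over_observed=eo,
    )


@dataclass(frozen=True)
class ComparisonStats:
    expected: dict[str, int]
    observed: dict[str, int]
    pearson_r: float


def compare_observed_expected(expected: Mapping[str, int],
                              observed: Mapping[str, int]) -> ComparisonStats:
    """Per-chromosome consistency of predicted vs sequenced tag counts.

    Pearson correlation of the paired per-contig vectors, reported to 4
    decimals; contig keys must match exactly.
    """
    if set(expected) != set(observed):
        diff = set(expected) ^ set(observed)
        raise ValueError(f"contig keys differ between vectors: {sorted(diff)}")
    if len(expected) < 3:
        raise ValueError("need at least 3 contigs for a meaningful correlation")
    keys = sorted(expected)
    r = stats.pearsonr([expected[k] for k in keys],
                       [observed[k] for k in keys]).statistic
    return ComparisonStats(dict(expected), dict(observed), _round_half_up(float(r), 4))
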