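"""Co-expression of neighbouring microRNAs as a function of genomic distance."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import pairwise_gap
from .model import ExpressionMatrix, MicroRNALocus


@dataclass(frozen=True)
class DistanceBinSpec:
    """Ordered finite bin edges in nt; the last bin is open-ended.

    Edges ``(e0, e1, ..., ek)`` define bins ``[e0,e1), ..., [e_{k-1},ek),
    [ek, inf)``.
    """

    edges: tuple[int, ...] = (0, 1_000, 10_000, 100_000)

    def __post_init__(self) -> None:
        if len(self.edges) < 1 or self.edges[0] < 0:
            raise ValueError("first bin edge must be >= 0")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        labels = [
            f"[{a},{b})" for a, b in zip(self.edges, self.edges[1:])
        ]
        labels.append(f"[{self.edges[-1]},inf)")
        return labels

    def assign(self, gap: int) -> str:
        if gap < self.edges[0]:
            raise ValueError(f"gap {gap} below the first bin edge")
        idx = int(np.searchsorted(self.edges, gap, side="right")) - 1
        return self.labels[idx]


def pearson_counts(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson r on raw read counts; ``None`` when undefined.

    Undefined (zero variance in either vector, or fewer than 3 samples)
    correlations are excluded from summaries rather than imputed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    if x.size < 3:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return max(-1.0, min(1.0, r))


def neighboring_pairs(
    loci: Iterable[MicroRNALocus],
    all_pairs: bool = False,
) -> list[tuple[MicroRNALocus, MicroRNALocus, int]]:
    """Same-chromosome same-strand locus pairs with their gap.

    By default only consecutive loci along the chromosome are paired
    ("neighboring"); with ``all_pairs=True`` every comparable pair is
    returned.
    """
    groups: dict[tuple[str, str], list[MicroRNALocus]] = {}
    for locus in loci:
        groups.setdefault((locus.chrom, locus.strand), []).append(locus)
    pairs = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda l: (l.start, l.end))
        if all_pairs:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    gap = pairwise_gap(members[i], members[j])
                    assert gap is not None
                    pairs.append((members[i], members[j], gap))
        else:
            for a, b in zip(members, members[1:]):
                gap = pairwise_gap(a, b)
                assert gap is not None
                pairs.append((a, b, gap))
    return pairs


@dataclass
class CorrelationByDistance:
    """Per-bin correlation values and their box-plot summaries."""

    values: dict[str, list[float]]   # bin label -> r values
    summary: pd.DataFrame            # n, median, q1, q3 per bin ("empty" marked)
    n_skipped_missing: int           # pairs dropped: locus absent from matrix
    n_skipped_undefined: int         # pairs dropped: zero-variance counts


def correlation_vs_distance(
    loci: Iterable[MicroRNALocus],
    expr: ExpressionMatrix,
    bins: DistanceBinSpec = DistanceBinSpec(),
    all_pairs: bool = False,
    log1p: bool = False,
) -> CorrelationByDistance:
    """Pearson r between neighbouring loci, stratified by genomic gap."""
    values: dict[str, list[float]] = {label: [] for label in bins.labels}
    n_missing = 0
    n_undef = 0
    for a, b, gap in neighboring_pairs(loci, all_pairs=all_pairs):
        if a.mirna_id not in expr or b.mirna_id not in expr:
            n_missing += 1
            continue
        x = expr.counts(a.mirna_id)
        y = expr.counts(b.mirna_id)
        if log1p:
            x = np.log1p(x)
            y = np.log1p(y)
        r = pearson_counts(x, y)
        if r is None:
            n_undef += 1
            continue
        values[bins.assign(gap)].append(r)

    rows = []
    for label in bins.labels:
        vals = values[label]
        if vals:
            arr = np.array(vals)
            rows.append(
                {
                    "bin": label,
                    "n": len(vals),
                    "median": float(np.median(arr)),
                    "q1": float(np.percentile(arr, 25)),
                    "q3": float(np.percentile(arr, 75)),
                    "empty": False,
                }
            )
        else:
            rows.append(
                {"bin": label, "n": 0, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "empty": True}
            )
    summary = pd.DataFrame(rows).set_index("bin")
    return CorrelationByDistance(values, summary, n_missing, n_undef)
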