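"""Two-point linkage QC for a coded F2 genotype matrix.

For every pair of codominant A/H/B markers the recombination fraction is
estimated by maximum likelihood under the standard F2 model.  The double
heterozygote class mixes parental and recombinant gamete pairs, so the
complete-data recombinant count is latent and the MLE is found by EM.
Linkage is scored as LOD = log10 L(rf_hat) - log10 L(0.5); markers are
grouped by single-linkage transitive closure over pairs exceeding the LOD
threshold, and distances are reported in Haldane centimorgans
(d = -50 ln(1 - 2 rf), no crossover interference).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_CODE_TO_INT = {"A": 0, "H": 1, "B": 2}


@dataclass(frozen=True)
class TwoPointResult:
    marker1: str
    marker2: str
    rf_hat: float
    lod: float
    n_informative: int
    low_information: bool = False

    @property
    def cm(self) -> float:
        return haldane_cm(self.rf_hat) if self.rf_hat < 0.5 else math.inf


@dataclass(frozen=True)
class LinkageGroup:
    group_id: int
    markers: tuple[str, ...]
    chromosome: str | None = None


def segregation_counts(row: Sequence[str]) -> tuple[int, int, int, int]:
    """Tally (nA, nH, nB, nMissing) for one coded matrix row."""
    if len(row) == 0:
        raise ValueError("empty genotype row")
    n_a = sum(1 for c in row if c == "A")
    n_h = sum(1 for c in row if c == "H")
    n_b = sum(1 for c in row if c == "B")
    return n_a, n_h, n_b, len(row) - n_a - n_h - n_b


def _class_probs(r: float) -> np.ndarray:
    """3x3 F2 two-locus genotype class probabilities (coupling phase)."""
    s = 1.0 - r
    return np.array(
        [
            [s * s / 4, r * s / 2, r * r / 4],
            [r * s / 2, (s * s + r * r) / 2, r * s / 2],
            [r * r / 4, r * s / 2, s * s / 4],
        ]
    )


def loglik(table: np.ndarray, r: float) -> float:
    """Multinomial log10-likelihood of a 3x3 table at recombination r."""
    probs = _class_probs(r)
    mask = table > 0
    if (probs[mask] <= 0).any():
        return -math.inf
    return float((table[mask] * np.log10(probs[mask])).sum())


# expected recombinant gametes per class; the double-het entry is latent
_RECOMBINANTS = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)


def estimate_rf_em(
    table: np.ndarray | Sequence[Sequence[int]],
    marker1: str = "m1",
    marker2: str = "m2",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> TwoPointResult:
    """EM maximum-likelihood recombination fraction for an F2 marker pair.

    ``table[i][j]`` counts individuals with genotype i at marker 1 and j
    at marker 2 (0=A, 1=H, 2=B; missing pairs excluded beforehand).  Every
    class contributes a known number of recombinant gametes except the
    double heterozygote, where the posterior weight of the two-recombinant
    configuration is r^2 / (r^2 + (1-r)^2).  The estimate is clipped to
    [0, 0.5] and LOD is evaluated against independence (r = 0.5).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype table")
    if (t < 0).any():
        raise ValueError("negative counts")
    n = t.sum()
    if n == 0:
        return TwoPointResult(marker1, marker2, 0.5, 0.0, 0, True)

    r = 0.25
    fixed = (t * _RECOMBINANTS).sum() - 0.0  # double-het handled separately
    n_hh = t[1, 1]
    for _ in range(max_iter):
        denom = r * r + (1.0 - r) * (1.0 - r)
        w = 2.0 * r * r / denom if denom > 0 else 0.0
        r_new = (fixed + n_hh * w) / (2.0 * n)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    r = min(max(r, 0.0), 0.5)
    lod = loglik(t, r) - loglik(t, 0.5)
    return TwoPointResult(
        marker1, marker2, float(r), max(float(lod), 0.0), int(n), n < 10
    )


def table_from_rows(row1: Sequence[str], row2: Sequence[str]) -> np.ndarray:
    """Cross-tabulate two coded rows, dropping pairs with missing data."""
    t = np.zeros((3, 3))
    for a, b in zip(row1, row2):
        i = _CODE_TO_INT.get(a)
        j = _CODE_TO_INT.get(b)
        if i is not None and j is not None:
            t[i, j] += 1
    return t


def pairwise_analysis(matrix: pd.DataFrame) -> list[TwoPointResult]:
    """Two-point results for every marker pair of a coded matrix."""
    markers = list(matrix.index)
    coded = np.full(matrix.shape, -1, dtype=np.int8)
    vals = matrix.to_numpy()
    for code, k in _CODE_TO_INT.items():
        coded[vals == code] = k
    results = []
    for (i, m1), (j, m2) in itertools.combinations(enumerate(markers), 2):
        a, b = coded[i], coded[j]
        valid = (a >= 0) & (b >= 0)
        t = np.zeros((3, 3))
        np.add.at(t, (a[valid], b[valid]), 1)
        results.append(estimate_rf_em(t, m1, m2))
    return results


def haldane_cm(rf: float) -> float:
    """Haldane map distance d = -50 ln(1 - 2 rf) in centimorgans."""
    if not 0.0 <= rf < 0.5:
        raise ValueError(f"rf must lie in [0, 0.5), got {rf}")
    return -50.0 * math.log1p(-2.0 * rf)


def haldane_rf(cm: float) -> float:
    """Inverse Haldane function: rf = (1 - exp(-d/50)) / 2."""
    if cm < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * -math.expm1(-cm / 50.0)


def group_markers(
    results: Sequence[TwoPointResult],
    lod_threshold: float = 4.0,
    max_rf: float = 0.45,
    chromosome_of: Mapping[str, str] | None = None,
) -> list[LinkageGroup]:
    """Single-linkage grouping over pairs with LOD above the threshold.

    An edge joins two markers when lod > lod_threshold and rf_hat < max_rf
    (the rf guard rejects spurious high-LOD linkage between distorted
    markers).  Groups are numbered by their lexicographically smallest
    member; an optional marker -> chromosome mapping labels each group by
    majority vote of its anchored members.
    """
    markers = sorted({r.marker1 for r in results} | {r.marker2 for r in results})
    parent = {m: m for m in markers}

    def find(m: str) -> str:
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for res in results:
        if res.lod > lod_threshold and res.rf_hat < max_rf:
            ra, rb = find(res.marker1), find(res.marker2)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    members: dict[str, list[str]] = {}
    for m in markers:
        members.setdefault(find(m), []).append(m)

    groups = []
    for gid, root in enumerate(sorted(members), start=1):
        group_markers_ = tuple(sorted(members[root]))
        chrom = None
        if chromosome_of:
            labels = [
                chromosome_of[m] for m in group_markers_ if m in chromosome_of
            ]
            if labels:
                chrom = max(sorted(set(labels)), key=labels.count)
        groups.append(LinkageGroup(gid, group_markers_, chrom))
    return groups


def results_to_frame(results: Sequence[TwoPointResult]) -> pd.DataFrame:
    rows = [
        {
            "marker1": r.marker1, "marker2": r.marker2, "rf": r.rf_hat,
            "cm": r.cm if math.isfinite(r.cm) else math.inf,
            "lod": r.lod, "n": r.n_informative,
            "low_information": r.low_information,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["marker1", "marker2", "rf", "cm", "lod", "n",
                 "low_information"],
    )


__all__ = [
    "LinkageGroup",
    "TwoPointResult",
    "estimate_rf_em",
    "group_markers",
    "haldane_cm",
    "haldane_rf",
    "loglik",
    "pairwise_analysis",
    "results_to_frame",
    "segregation_counts",
    "table_from_rows",
]
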