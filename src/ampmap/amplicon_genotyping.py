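"""Genotype calling on amplicon allele depths and F2 matrix construction.

Each marker's amplicon carries one pre-specified "hotspot" base expected to
hold the designed polymorphism (plus, possibly, additional variant sites
discovered within the amplicon).  Per-sample ref/alt read counts at each
site are turned into genotype calls; replicate parent plants give a
consensus per line; markers are classified by how well the hotspot
recovered the designed polymorphism; F2 calls at the representative site
of each marker are coded A/H/B relative to the parents, and rows failing
the missing-data or 1:2:1 segregation filters are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ampmap.formats import MISSING_CODE, PipelineConfig

REF_HOM = "ref_hom"
HET = "het"
ALT_HOM = "alt_hom"
NO_CALL = "no_call"
UNFIXED = "unfixed"

CALLED = (REF_HOM, HET, ALT_HOM)


@dataclass(frozen=True)
class SiteDepth:
    """Ref/alt read counts for one sample at one amplicon site."""

    sample_id: str
    marker_id: str
    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str
    is_hotspot: bool
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")


def call_genotype(
    ref_count: int, alt_count: int, cfg: PipelineConfig
) -> str:
    """Call one site from ref/alt depths.

    No call below ``min_coverage`` total reads; alt frequency above
    ``hom_cutoff`` percent is alt-homozygous, below ``100 - hom_cutoff``
    ref-homozygous; anything between is heterozygous provided the minor
    allele has at least ``min_count`` reads (otherwise no call).
    """
    total = ref_count + alt_count
    if total < cfg.min_coverage:
        return NO_CALL
    freq = 100.0 * alt_count / total
    if freq > cfg.hom_cutoff:
        return ALT_HOM
    if freq < 100.0 - cfg.hom_cutoff:
        return REF_HOM
    if min(ref_count, alt_count) >= cfg.min_count:
        return HET
    return NO_CALL


def call_genotype_frame(df: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Vectorised genotype calling over a site-depth table."""
    out = df.copy()
    ref = out["ref_count"].to_numpy(dtype=float)
    alt = out["alt_count"].to_numpy(dtype=float)
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, 100.0 * alt / np.maximum(total, 1), 0.0)
    call = np.full(len(out), NO_CALL, dtype=object)
    covered = total >= cfg.min_coverage
    call[covered & (freq > cfg.hom_cutoff)] = ALT_HOM
    call[covered & (freq < 100.0 - cfg.hom_cutoff)] = REF_HOM
    mid = covered & (freq <= cfg.hom_cutoff) & (freq >= 100.0 - cfg.hom_cutoff)
    call[mid & (np.minimum(ref, alt) >= cfg.min_count)] = HET
    out["call"] = call
    return out


def parental_consensus(calls: Sequence[str]) -> str:
    """Consensus across replicate plants of one parental line.

    Unanimity among non-missing calls is required; any disagreement marks
    the site unfixed in that line, and all-missing stays no-call.
    """
    if not calls:
        raise ValueError("no replicate calls")
    informative = {c for c in calls if c != NO_CALL}
    if not informative:
        return NO_CALL
    if len(informative) > 1:
        return UNFIXED
    return informative.pop()


def classify_marker(
    consensus_p1: str, consensus_p2: str, had_any_variant: bool
) -> int:
    """Five-way hotspot validation class.

    1: both parental consensus genotypes fixed and different (the designed
    polymorphism was captured); 2: no variant was ever observed at the
    hotspot (or the fixed parents do not differ); 3: neither parent gave
    enough coverage; 4: exactly one parent is no-call; 5: a parental line
    is not fixed at the hotspot.
    """
    fixed1 = consensus_p1 in CALLED
    fixed2 = consensus_p2 in CALLED
    if fixed1 and fixed2 and consensus_p1 != consensus_p2:
        return 1
    if not had_any_variant:
        return 2
    if consensus_p1 == NO_CALL and consensus_p2 == NO_CALL:
        return 3
    if (consensus_p1 == NO_CALL) != (consensus_p2 == NO_CALL):
        return 4
    if UNFIXED in (consensus_p1, consensus_p2):
        return 5
    # both parents fixed for the same genotype: no inter-parental variant
    return 2


def to_parental_code(
    f2_call: str, consensus_p1: str, consensus_p2: str
) -> str:
    """Recode an F2 call as A (parent-1 homozygote), H, B or missing.

    The parents must be homozygous for different alleles; the code follows
    the parent, not the allele (a parent-1 fixed for the alt allele makes
    alt-homozygous F2 plants "A").
    """
    homs = {REF_HOM, ALT_HOM}
    if (
        consensus_p1 not in homs
        or consensus_p2 not in homs
        or consensus_p1 == consensus_p2
    ):
        raise ValueError(
            "site not convertible: parents must be fixed homozygous for "
            f"different alleles (got {consensus_p1}/{consensus_p2})"
        )
    if f2_call == NO_CALL:
        return MISSING_CODE
    if f2_call == HET:
        return "H"
    if f2_call == consensus_p1:
        return "A"
    if f2_call == consensus_p2:
        return "B"
    raise ValueError(f"unknown genotype call {f2_call!r}")


@dataclass(frozen=True)
class AmpliconSite:
    """Bookkeeping for one site inside one amplicon during selection."""

    marker_id: str
    scaffold: str
    position: int
    is_hotspot: bool
    f1_heterozygous: bool
    missing_fraction: float


def select_representative_site(
    sites: Sequence[AmpliconSite],
) -> AmpliconSite | None:
    """Pick one site per amplicon for map construction.

    Only sites heterozygous in the reference F1 plant qualify (an F2 can
    only segregate where its F1 was heterozygous).  The hotspot is
    preferred; otherwise the qualifying site with the lowest missing
    fraction, ties broken by coordinate.
    """
    candidates = [s for s in sites if s.f1_heterozygous]
    if not candidates:
        return None
    hotspots = [s for s in candidates if s.is_hotspot]
    if hotspots:
        return min(hotspots, key=lambda s: s.position)
    return min(candidates, key=lambda s: (s.missing_fraction, s.position))


# ---------------------------------------------------------------------------
# matrix filters


def segregation_chi2(n_a: int, n_h: int, n_b: int) -> tuple[float, float]:
    """1:2:1 chi-square (df=2) on called genotype counts."""
    n = n_a + n_h + n_b
    if n == 0:
        return 0.0, 1.0
    expected = np.array([0.25, 0.5, 0.25]) * n
    stat = float((((np.array([n_a, n_h, n_b]) - expected) ** 2) / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=2))


def filter_matrix(
    matrix: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with too much missing data or distorted segregation.

    A row is removed when its missing fraction strictly exceeds
    ``max_missing`` or its 1:2:1 chi-square p-value is strictly below
    ``distortion_alpha``.  Returns (filtered matrix, per-row report with
    counts, statistic, p, and the drop reason or 'kept').
    """
    n = matrix.shape[1]
    rows = []
    keep = []
    for marker_id, row in matrix.iterrows():
        vals = row.to_numpy()
        n_a = int((vals == "A").sum())
        n_h = int((vals == "H").sum())
        n_b = int((vals == "B").sum())
        n_missing = n - n_a - n_h - n_b
        miss_frac = n_missing / n if n else 0.0
        stat, p = segregation_chi2(n_a, n_h, n_b)
        if miss_frac > cfg.max_missing:
            reason = "missing"
        elif p < cfg.distortion_alpha:
            reason = "distorted"
        else:
            reason = "kept"
            keep.append(marker_id)
        rows.append(
            {
                "marker_id": marker_id, "n_A": n_a, "n_H": n_h, "n_B": n_b,
                "n_missing": n_missing, "missing_fraction": miss_frac,
                "chi2": stat, "p_value": p, "status": reason,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["marker_id", "n_A", "n_H", "n_B", "n_missing",
                 "missing_fraction", "chi2", "p_value", "status"],
    )
    return matrix.loc[keep], report


# ---------------------------------------------------------------------------
# marker-set refinement


@dataclass(frozen=True)
class MarkerStatus:
    """Summary of one panel marker after a round of population genotyping."""

    marker_id: str
    scaffold: str
    position: int
    marker_class: int
    captured_polymorphism: bool  # any usable inter-parental site in amplicon
    used_in_map: bool            # segregated and entered the linkage map
    missing_fraction: float = 0.0


def refine_marker_set(
    statuses: Sequence[MarkerStatus],
) -> tuple[list[str], dict[str, int]]:
    """Refine a panel after genotyping one population.

    Markers that failed amplification (class 3) or never captured an
    inter-parental polymorphism anywhere in the amplicon are removed.
    When several mapped markers share a scaffold they are redundant for
    mapping and only a representative (lowest missing fraction, tie by
    coordinate) is kept.  Markers that captured a parental polymorphism
    but did not segregate are retained: they may segregate in an F2 from
    a different F1 plant.

    Returns (kept marker ids, report counts).
    """
    usable = [
        s for s in statuses
        if s.marker_class != 3 and s.captured_polymorphism
    ]
    removed_failed = len(statuses) - len(usable)

    mapped = [s for s in usable if s.used_in_map]
    by_scaffold: dict[str, list[MarkerStatus]] = {}
    for s in mapped:
        by_scaffold.setdefault(s.scaffold, []).append(s)
    redundant: set[str] = set()
    for members in by_scaffold.values():
        if len(members) > 1:
            rep = min(members, key=lambda s: (s.missing_fraction, s.position))
            redundant.update(s.marker_id for s in members if s is not rep)

    kept = [s.marker_id for s in usable if s.marker_id not in redundant]
    report = {
        "input": len(statuses),
        "removed_failed_or_uncaptured": removed_failed,
        "removed_redundant_coscaffold": len(redundant),
        "kept_mapped": len({s.marker_id for s in mapped} - redundant),
        "kept_nonsegregating": len([s for s in usable if not s.used_in_map]),
        "kept_total": len(kept),
    }
    return kept, report


# ---------------------------------------------------------------------------
# population-level orchestration


def genotype_population(
    depths: pd.DataFrame,
    parent1_samples: Sequence[str],
    parent2_samples: Sequence[str],
    f1_sample: str,
    f2_samples: Sequence[str],
    cfg: PipelineConfig,
) -> dict:
    """Full genotyping pass: calls, consensus, classes, coded F2 matrix.

    ``depths`` is a site-depth table (see formats.DEPTH_COLUMNS).  Returns
    a dict with the called frame, per-marker hotspot classes, the selected
    representative site per marker, and the A/H/B GenotypeMatrix over
    convertible markers (before filtering).
    """
    called = call_genotype_frame(depths, cfg)
    site_cols = ["marker_id", "scaffold", "position", "ref_allele",
                 "alt_allele", "is_hotspot"]

    def calls_of(samples: Iterable[str]) -> pd.DataFrame:
        return called[called["sample_id"].isin(list(samples))]

    p1 = calls_of(parent1_samples)
    p2 = calls_of(parent2_samples)
    consensus: dict[tuple, tuple[str, str]] = {}
    for key, grp in called.groupby(site_cols, sort=True):
        c1 = parental_consensus(
            [*grp[grp["sample_id"].isin(list(parent1_samples))]["call"]]
        ) if not p1.empty else NO_CALL
        c2 = parental_consensus(
            [*grp[grp["sample_id"].isin(list(parent2_samples))]["call"]]
        ) if not p2.empty else NO_CALL
        consensus[key] = (c1, c2)

    # variant presence per marker hotspot: any called non-reference genotype
    variant_at = {
        key: bool(
            grp["call"].isin([HET, ALT_HOM]).any()
        )
        for key, grp in called.groupby(site_cols, sort=True)
    }

    classes: dict[str, int] = {}
    hotspot_of: dict[str, tuple] = {}
    for key, (c1, c2) in consensus.items():
        marker_id, _, _, _, _, is_hotspot = key
        if is_hotspot:
            hotspot_of[marker_id] = key
            classes[marker_id] = classify_marker(c1, c2, variant_at[key])

    # representative-site selection via F1 heterozygosity
    f1_calls = calls_of([f1_sample]).set_index(site_cols)["call"].to_dict()
    n_f2 = max(len(list(f2_samples)), 1)
    f2_frame = calls_of(f2_samples)
    site_objects: dict[str, list[AmpliconSite]] = {}
    for key in consensus:
        marker_id, scaffold, position, _, _, is_hotspot = key
        c1, c2 = consensus[key]
        convertible = (
            c1 in (REF_HOM, ALT_HOM) and c2 in (REF_HOM, ALT_HOM) and c1 != c2
        )
        if not convertible:
            continue
        sub = f2_frame[
            (f2_frame["marker_id"] == marker_id)
            & (f2_frame["position"] == position)
        ]
        n_called = int((sub["call"] != NO_CALL).sum())
        site_objects.setdefault(marker_id, []).append(
            AmpliconSite(
                marker_id=marker_id,
                scaffold=scaffold,
                position=int(position),
                is_hotspot=bool(is_hotspot),
                f1_heterozygous=f1_calls.get(key) == HET,
                missing_fraction=1.0 - n_called / n_f2,
            )
        )

    representatives = {
        mid: rep
        for mid, sites in site_objects.items()
        if (rep := select_representative_site(sites)) is not None
    }

    # coded F2 matrix over representative sites
    f2_list = list(f2_samples)
    matrix_rows = {}
    for mid, rep in sorted(representatives.items()):
        key = next(
            k for k in consensus
            if k[0] == mid and int(k[2]) == rep.position
        )
        c1, c2 = consensus[key]
        sub = f2_frame[
            (f2_frame["marker_id"] == mid)
            & (f2_frame["position"] == rep.position)
        ].set_index("sample_id")["call"].to_dict()
        matrix_rows[mid] = [
            to_parental_code(sub.get(s, NO_CALL), c1, c2) for s in f2_list
        ]
    matrix = pd.DataFrame.from_dict(
        matrix_rows, orient="index", columns=f2_list
    )
    matrix.index.name = "marker_id"

    return {
        "called": called,
        "consensus": consensus,
        "classes": classes,
        "representatives": representatives,
        "matrix": matrix,
    }


def genotype_concordance(calls1: Mapping, calls2: Mapping) -> float:
    """Fraction of shared keys with identical calls (duplicate-sample QC)."""
    shared = [k for k in calls1 if k in calls2]
    if not shared:
        return float("nan")
    agree = sum(calls1[k] == calls2[k] for k in shared)
    return agree / len(shared)


__all__ = [
    "ALT_HOM",
    "AmpliconSite",
    "CALLED",
    "HET",
    "MarkerStatus",
    "NO_CALL",
    "REF_HOM",
    "SiteDepth",
    "UNFIXED",
    "call_genotype",
    "call_genotype_frame",
    "classify_marker",
    "filter_matrix",
    "genotype_concordance",
    "genotype_population",
    "parental_consensus",
    "refine_marker_set",
    "segregation_chi2",
    "select_representative_site",
    "to_parental_code",
]
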