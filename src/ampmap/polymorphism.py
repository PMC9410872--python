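"""Inter-line polymorphism detection from per-individual variant tables.

Two heterogeneous parental lines are each sequenced as several individuals.
Because outcrossing lines are not fully inbred, a variant must be observed
as a homozygous call in nearly all individuals of a line ("fixed") before
it counts as a line allele; a site is polymorphic between the lines when it
is fixed in one line and no individual of the other line has any called
variant (homozygous or heterozygous) there.

Site keys are ``(unigene_id, position, alt_allele)``: each alt allele at a
multi-allelic position is tracked independently, but the opposite line's
veto applies to the position, whatever allele it carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ampmap.formats import MapAnchor, PipelineConfig

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
NO_CALL = "none"

SiteKey = tuple[str, int, str]


@dataclass(frozen=True)
class VariantObservation:
    """One allele observation for one individual at one unigene position."""

    sample_id: str
    line_id: str
    unigene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    total_depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.total_depth < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_count > self.total_depth:
            raise ValueError("alt_count exceeds total_depth")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")


@dataclass(frozen=True)
class ZygosityCall:
    sample_id: str
    line_id: str
    unigene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    zygosity: str

    @property
    def site_key(self) -> SiteKey:
        return (self.unigene_id, self.position, self.alt_allele)


@dataclass(frozen=True)
class PolymorphicSite:
    """An inter-line polymorphism, optionally lifted onto the genome."""

    unigene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    fixed_line: str
    support: int
    anchor: MapAnchor | None = None
    genome_scaffold: str | None = None
    genome_position: int | None = None
    genome_strand: str | None = None
    drop_reason: str | None = None

    @property
    def site_key(self) -> SiteKey:
        return (self.unigene_id, self.position, self.alt_allele)

    @property
    def category(self) -> str:
        return self.anchor.category if self.anchor else "no_information"


def call_zygosity(
    obs: VariantObservation, cfg: PipelineConfig
) -> ZygosityCall:
    """Apply depth/count/frequency thresholds and the homozygosity cutoff.

    A variant below any of the three detection thresholds is not called at
    all; a detected variant with allele frequency strictly above
    ``hom_cutoff`` percent is homozygous, otherwise heterozygous.
    """
    if obs.total_depth < cfg.min_coverage or obs.alt_count < cfg.min_count:
        zyg = NO_CALL
    else:
        freq = 100.0 * obs.alt_count / obs.total_depth
        if freq < cfg.min_freq:
            zyg = NO_CALL
        elif freq > cfg.hom_cutoff:
            zyg = HOMOZYGOUS
        else:
            zyg = HETEROZYGOUS
    return ZygosityCall(
        obs.sample_id, obs.line_id, obs.unigene_id, obs.position,
        obs.ref_allele, obs.alt_allele, zyg,
    )


def observations_from_table(df: pd.DataFrame) -> list[VariantObservation]:
    return [
        VariantObservation(
            row.sample_id, row.line_id, row.unigene_id, int(row.position),
            row.ref_allele, row.alt_allele, int(row.total_depth),
            int(row.alt_count),
        )
        for row in df.itertuples(index=False)
    ]


def call_all(
    observations: Iterable[VariantObservation], cfg: PipelineConfig
) -> list[ZygosityCall]:
    calls = [call_zygosity(o, cfg) for o in observations]
    return [c for c in calls if c.zygosity != NO_CALL]


def default_min_support(n_individuals: int) -> int:
    """All-but-one rule: with n individuals, require n - 1 homozygous calls."""
    return max(1, n_individuals - 1)


def line_fixed_sites(
    calls: Sequence[ZygosityCall],
    line_id: str,
    n_individuals: int,
    min_support: int | None = None,
) -> dict[SiteKey, tuple[str, int]]:
    """Find sites fixed homozygous within one line.

    A site (unigene, position, alt) is fixed when at least ``min_support``
    individuals of the line carry a homozygous call for the same alt allele.
    Returns ``{site_key: (ref_allele, support)}``.
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals per line")
    if min_support is None:
        min_support = default_min_support(n_individuals)
    foreign = {c.line_id for c in calls} - {line_id}
    if foreign:
        raise ValueError(
            f"calls from lines {sorted(foreign)} mixed into line {line_id}"
        )
    support: dict[SiteKey, set[str]] = {}
    refs: dict[SiteKey, str] = {}
    for c in calls:
        if c.zygosity != HOMOZYGOUS:
            continue
        support.setdefault(c.site_key, set()).add(c.sample_id)
        refs.setdefault(c.site_key, c.ref_allele)
    return {
        key: (refs[key], len(samples))
        for key, samples in support.items()
        if len(samples) >= min_support
    }


def interline_polymorphic_sites(
    fixed_1: Mapping[SiteKey, tuple[str, int]],
    calls_2: Sequence[ZygosityCall],
    fixed_2: Mapping[SiteKey, tuple[str, int]],
    calls_1: Sequence[ZygosityCall],
    line_1: str = "parent1",
    line_2: str = "parent2",
) -> list[PolymorphicSite]:
    """Sites fixed in one line with no called variant in the other line.

    The veto is positional: any called variant (hom or het, any allele) in
    an individual of the opposite line at the same unigene position removes
    the site.  Sites fixed in both lines for the same allele are not
    polymorphic and are excluded.
    """
    called_pos_1 = {(c.unigene_id, c.position) for c in calls_1}
    called_pos_2 = {(c.unigene_id, c.position) for c in calls_2}

    sites: list[PolymorphicSite] = []
    for fixed, other_called, line in (
        (fixed_1, called_pos_2, line_1),
        (fixed_2, called_pos_1, line_2),
    ):
        for (unigene, pos, alt), (ref, supp) in fixed.items():
            if (unigene, pos) in other_called:
                continue
            sites.append(
                PolymorphicSite(unigene, pos, ref, alt, line, supp)
            )
    sites.sort(key=lambda s: (s.unigene_id, s.position, s.alt_allele))
    return sites


def categorize_sites(
    sites: Sequence[PolymorphicSite], anchors: Mapping[str, MapAnchor]
) -> list[PolymorphicSite]:
    """Attach map anchors (anchored / chromosome_only / no_information)."""
    return [
        replace(s, anchor=anchors.get(s.unigene_id)) for s in sites
    ]


def summarize_by_chromosome(
    sites: Sequence[PolymorphicSite],
    marker_ids: Mapping[SiteKey, bool] | None = None,
) -> pd.DataFrame:
    """Per-chromosome counts of polymorphisms, distinct unigenes and markers.

    One row per chromosome per category plus per-category totals, in the
    layout of the panel-design summary table: ``category`` in {anchored,
    chromosome_only, no_information}; no_information sites count under
    chromosome ``.``.  ``marker_ids`` optionally flags the sites that became
    panel markers.
    """
    rows = []
    for s in sites:
        chrom = s.anchor.chromosome if (s.anchor and s.anchor.chromosome) else "."
        rows.append(
            {
                "category": s.category,
                "chromosome": chrom,
                "unigene_id": s.unigene_id,
                "is_marker": bool(marker_ids and marker_ids.get(s.site_key)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["category", "chromosome", "unigene_id", "is_marker"]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["category", "chromosome", "n_polymorphisms",
                     "n_unigenes", "n_markers"]
        )
    grouped = (
        df.groupby(["category", "chromosome"])
        .agg(
            n_polymorphisms=("unigene_id", "size"),
            n_unigenes=("unigene_id", "nunique"),
            n_markers=("is_marker", "sum"),
        )
        .reset_index()
    )
    totals = (
        df.groupby("category")
        .agg(
            n_polymorphisms=("unigene_id", "size"),
            n_unigenes=("unigene_id", "nunique"),
            n_markers=("is_marker", "sum"),
        )
        .reset_index()
    )
    totals.insert(1, "chromosome", "Total")
    out = pd.concat([grouped, totals], ignore_index=True)
    out["n_markers"] = out["n_markers"].astype(int)
    return out.sort_values(["category", "chromosome"]).reset_index(drop=True)


def sites_to_frame(sites: Sequence[PolymorphicSite]) -> pd.DataFrame:
    """Flatten PolymorphicSites to the site-table TSV layout."""
    rows = []
    for s in sites:
        anchor = s.anchor
        rows.append(
            {
                "unigene_id": s.unigene_id,
                "position": s.position,
                "ref_allele": s.ref_allele,
                "alt_allele": s.alt_allele,
                "fixed_line": s.fixed_line,
                "support": s.support,
                "category": s.category,
                "chromosome": (anchor.chromosome if anchor and anchor.chromosome else "."),
                "cm_position": (
                    anchor.cm_position
                    if anchor and anchor.cm_position is not None
                    else math.nan
                ),
                "genome_scaffold": s.genome_scaffold or ".",
                "genome_position": (
                    s.genome_position if s.genome_position is not None else 0
                ),
                "genome_strand": s.genome_strand or ".",
                "drop_reason": s.drop_reason or ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unigene_id", "position", "ref_allele", "alt_allele",
            "fixed_line", "support", "category", "chromosome", "cm_position",
            "genome_scaffold", "genome_position", "genome_strand",
            "drop_reason",
        ],
    )


def sites_from_frame(
    df: pd.DataFrame, anchors: Mapping[str, MapAnchor] | None = None
) -> list[PolymorphicSite]:
    anchors = anchors or {}
    sites = []
    for row in df.itertuples(index=False):
        anchor = anchors.get(row.unigene_id)
        if anchor is None:
            chrom = None if row.chromosome in {".", ""} else str(row.chromosome)
            cm = None if pd.isna(row.cm_position) else float(row.cm_position)
            if chrom is not None:
                anchor = MapAnchor(row.unigene_id, chrom, cm)
        sites.append(
            PolymorphicSite(
                unigene_id=row.unigene_id,
                position=int(row.position),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                fixed_line=row.fixed_line,
                support=int(row.support),
                anchor=anchor,
                genome_scaffold=(
                    None if row.genome_scaffold == "." else row.genome_scaffold
                ),
                genome_position=(
                    None if int(row.genome_position) == 0 else int(row.genome_position)
                ),
                genome_strand=(
                    None if row.genome_strand == "." else row.genome_strand
                ),
                drop_reason=None if row.drop_reason == "." else row.drop_reason,
            )
        )
    return sites


__all__ = [
    "HETEROZYGOUS",
    "HOMOZYGOUS",
    "NO_CALL",
    "PolymorphicSite",
    "VariantObservation",
    "ZygosityCall",
    "call_all",
    "call_zygosity",
    "categorize_sites",
    "default_min_support",
    "interline_polymorphic_sites",
    "line_fixed_sites",
    "observations_from_table",
    "sites_from_frame",
    "sites_to_frame",
    "summarize_by_chromosome",
]
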