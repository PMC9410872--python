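"""Project unigene (transcript) positions onto genome scaffolds.

Transcript-designed primers fail when they straddle intron-exon junctions,
so polymorphic-site positions detected on unigenes are projected through
each unigene's best genomic alignment onto scaffold coordinates, and primer
design then happens on genomic sequence.

Projection is exact or refused: gapped HSPs are only projected through a
per-base trace (see :mod:`ampmap.formats`); a gapped HSP without a trace is
rejected rather than linearly interpolated, because interpolation can place
the primer window on the wrong bases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from ampmap.formats import AlignmentRecord
from ampmap.polymorphism import PolymorphicSite


class ProjectionError(ValueError):
    """A query position cannot be projected through an alignment."""


@dataclass(frozen=True)
class ProjectedPosition:
    scaffold_id: str
    position: int  # 1-based on the subject
    strand: str
    query_id: str


def best_alignment(alignments: Sequence[AlignmentRecord]) -> AlignmentRecord:
    """Best hit for one query: highest bitscore, ties broken by identity,
    then alignment length, then subject id (lexicographic, for determinism).
    """
    if not alignments:
        raise ValueError("no alignments for query")
    return min(
        alignments,
        key=lambda a: (-a.bitscore, -a.pct_identity, -a.aln_len, a.subject_id),
    )


def has_ambiguous_best(alignments: Sequence[AlignmentRecord]) -> bool:
    """True when the top (bitscore, identity, aln_len) is shared by hits on
    more than one subject; the deterministic winner is then flagged."""
    if len(alignments) < 2:
        return False
    top = max((a.bitscore, a.pct_identity, a.aln_len) for a in alignments)
    subjects = {
        a.subject_id
        for a in alignments
        if (a.bitscore, a.pct_identity, a.aln_len) == top
    }
    return len(subjects) > 1


def project_position(aln: AlignmentRecord, qpos: int) -> ProjectedPosition:
    """Map a 1-based query position to the aligned subject base.

    Gapless HSPs use the linear offset; HSPs with a trace are walked base
    by base.  A query base aligned opposite a subject gap ("I" op) has no
    subject coordinate and raises :class:`ProjectionError`, as does a
    gapped HSP without a trace.
    """
    if not aln.qstart <= qpos <= aln.qend:
        raise ProjectionError(
            f"query position {qpos} outside HSP span "
            f"[{aln.qstart}, {aln.qend}] of {aln.query_id}"
        )
    step = 1 if aln.strand == "+" else -1
    if aln.trace is None:
        if not aln.is_gapless:
            raise ProjectionError(
                f"gapped alignment {aln.query_id}/{aln.subject_id} has no "
                "trace; refusing to interpolate"
            )
        offset = qpos - aln.qstart
        return ProjectedPosition(
            aln.subject_id, aln.sstart + step * offset, aln.strand, aln.query_id
        )
    q = aln.qstart
    s = aln.sstart
    for op in aln.trace:
        if op in "MX":
            if q == qpos:
                return ProjectedPosition(
                    aln.subject_id, s, aln.strand, aln.query_id
                )
            q += 1
            s += step
        elif op == "D":  # subject-only base (e.g. intron)
            s += step
        else:  # "I": query-only base, no subject coordinate
            if q == qpos:
                raise ProjectionError(
                    f"query position {qpos} of {aln.query_id} falls in a "
                    "subject gap (unprojectable)"
                )
            q += 1
    raise ProjectionError(
        f"trace of {aln.query_id}/{aln.subject_id} exhausted before "
        f"reaching query position {qpos}"
    )


def lift_sites(
    sites: Sequence[PolymorphicSite],
    alignments: Iterable[AlignmentRecord],
    flank: int = 150,
) -> list[PolymorphicSite]:
    """Project every site through its unigene's best alignment.

    Sites that cannot be projected keep a ``drop_reason``:

    - ``no-alignment``: the unigene has no genomic hit;
    - ``out-of-span``: the site lies outside the best HSP;
    - ``unprojectable``: the site base is absent from the subject;
    - ``gapped-no-trace``: best HSP is gapped but carries no trace;
    - ``near-junction``: the projected base lies within ``flank`` bp of
      either end of the aligned subject span, where a primer window would
      run past the alignment (a proxy for intron-exon junction proximity);
    - ``ambiguous-hit`` (non-fatal flag kept in the reason column when the
      site still projects): equally scoring best hits on several scaffolds.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_query.setdefault(aln.query_id, []).append(aln)

    out: list[PolymorphicSite] = []
    for site in sites:
        alns = by_query.get(site.unigene_id)
        if not alns:
            out.append(replace(site, drop_reason="no-alignment"))
            continue
        best = best_alignment(alns)
        ambiguous = has_ambiguous_best(alns)
        try:
            proj = project_position(best, site.position)
        except ProjectionError as exc:
            reason = (
                "out-of-span" if "outside HSP span" in str(exc)
                else "gapped-no-trace" if "no trace" in str(exc)
                else "unprojectable"
            )
            out.append(replace(site, drop_reason=reason))
            continue
        s_lo, s_hi = sorted((best.sstart, best.send))
        if proj.position - s_lo < flank or s_hi - proj.position < flank:
            out.append(replace(site, drop_reason="near-junction"))
            continue
        out.append(
            replace(
                site,
                genome_scaffold=proj.scaffold_id,
                genome_position=proj.position,
                genome_strand=proj.strand,
                drop_reason="ambiguous-hit" if ambiguous else None,
            )
        )
    return out


def projectable(sites: Sequence[PolymorphicSite]) -> list[PolymorphicSite]:
    """Sites that survived lifting (ambiguous hits are kept, flagged)."""
    return [
        s for s in sites
        if s.genome_scaffold is not None and s.drop_reason in (None, "ambiguous-hit")
    ]


__all__ = [
    "ProjectedPosition",
    "ProjectionError",
    "best_alignment",
    "has_ambiguous_best",
    "lift_sites",
    "project_position",
    "projectable",
]
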