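"""Protein-domain tabulation of mutations (text lollipop track).

Domain intervals and the genomic→codon map are user-supplied configuration:
there is no authoritative hard-coded domain table.  The map is a list of
collinear CDS segments, each mapping a genomic interval onto consecutive
codon numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Set

from .catalog import ConfigError, MutationRecord

__all__ = ["DomainAnnotation", "CdsMap", "DomainCounts", "domain_track", "render_track"]


@dataclass(frozen=True)
class DomainAnnotation:
    name: str
    start_aa: int  # 1-based amino-acid coordinates, inclusive
    end_aa: int

    def __post_init__(self) -> None:
        if self.start_aa > self.end_aa:
            raise ConfigError(f"domain {self.name}: start_aa {self.start_aa} > end_aa {self.end_aa}")


@dataclass(frozen=True)
class CdsMap:
    """Piecewise-linear genomic→codon mapping.

    ``segments`` is a sequence of ``(g_start, g_end, aa_at_start)`` triples:
    genomic positions in ``[g_start, g_end]`` map to codon
    ``aa_at_start + (pos - g_start) // 3``.
    """

    segments: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    def codon_of(self, position: int) -> int | None:
        for g_start, g_end, aa_start in self.segments:
            if g_start <= position <= g_end:
                return aa_start + (position - g_start) // 3
        return None


@dataclass
class DomainCounts:
    name: str
    n_total: int = 0
    n_flagged: int = 0
    n_total_weighted: float = 0.0  # recurrence-weighted
    n_flagged_weighted: float = 0.0


def _check_overlaps(domains: Sequence[DomainAnnotation]) -> None:
    ordered = sorted(domains, key=lambda d: d.start_aa)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_aa <= prev.end_aa:
            raise ConfigError(f"domains {prev.name!r} and {cur.name!r} overlap on one track")


def domain_track(
    records: Sequence[MutationRecord],
    flagged_ids: Set[str],
    domains: Sequence[DomainAnnotation],
    cds_map: CdsMap,
    multiplicity: Mapping[tuple, int] | None = None,
) -> list[DomainCounts]:
    """Per-domain mutation counts, flagged subset and recurrence weights.

    Records whose position the map does not cover land in an ``unmapped``
    bucket; with an empty domain list, everything mapped goes to a single
    ``unannotated`` bucket.  Counts (plus unmapped) always sum to the input
    total.
    """
    _check_overlaps(domains)
    buckets = [DomainCounts(d.name) for d in domains]
    unannotated = DomainCounts("unannotated")
    unmapped = DomainCounts("unmapped")
    for rec in records:
        weight = float(multiplicity.get(rec.key, 1)) if multiplicity else 1.0
        codon = cds_map.codon_of(rec.position)
        if codon is None:
            target = unmapped
        else:
            target = unannotated
            for dom, bucket in zip(domains, buckets):
                if dom.start_aa <= codon <= dom.end_aa:
                    target = bucket
                    break
        target.n_total += 1
        target.n_total_weighted += weight
        if rec.id in flagged_ids:
            target.n_flagged += 1
            target.n_flagged_weighted += weight
    out = list(buckets)
    if not domains or unannotated.n_total:
        out.append(unannotated)
    out.append(unmapped)
    return out


def render_track(counts: Sequence[DomainCounts], width: int = 60) -> str:
    """Plain-text lollipop-style track; glyph run length scales with the
    recurrence-weighted count, '*' marks flagged mass."""
    total = max((c.n_total_weighted for c in counts), default=0.0)
    lines = []
    for c in counts:
        if total > 0:
            n_glyph = int(round(width * c.n_total_weighted / total))
            n_flag = int(round(width * c.n_flagged_weighted / total))
        else:
            n_glyph = n_flag = 0
        bar = "*" * n_flag + "o" * max(n_glyph - n_flag, 0)
        lines.append(f"{c.name:>14s} | {bar:<{width}s} {c.n_total:4d} ({c.n_flagged} flagged)")
    return "\n".join(lines)
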