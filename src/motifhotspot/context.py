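"""Reference sequence loading and flanking-window extraction.

Coordinates are 1-based inclusive throughout, matching VCF/HGVS usage.  A
:class:`ReferenceSequence` stores a gene-region slice together with the
genomic coordinate of its first base, so catalogue positions can be used
directly without re-mapping.  Context windows describe the *pre-mutation*
(reference) genome: the window sequence is taken from the reference, never
from the mutant haplotype.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .catalog import MutationRecord, VariantClass

__all__ = [
    "ReferenceSequence",
    "ContextWindow",
    "WindowSpec",
    "AnchorRule",
    "StrandMode",
    "ReferenceError",
    "load_reference",
    "extract_window",
    "extract_windows",
    "audit_ref_alleles",
    "bed_mask_positions",
]

_VALID = frozenset("ACGTN")


class ReferenceError(Exception):
    """Problems loading or indexing the reference sequence."""


class AnchorRule(enum.Enum):
    #: centre the window on the variant position (SNVs)
    VARIANT_POSITION = "VARIANT_POSITION"
    #: centre on the leftmost affected base of an indel (VCF-style anchor);
    #: identical to VARIANT_POSITION when positions are already left-anchored
    INDEL_LEFT_ANCHOR = "INDEL_LEFT_ANCHOR"


class StrandMode(enum.Enum):
    REFERENCE_ONLY = "REFERENCE_ONLY"
    BOTH_STRANDS = "BOTH_STRANDS"


@dataclass(frozen=True)
class ReferenceSequence:
    contig: str
    offset: int  # 1-based genomic coordinate of bases[0]
    bases: str
    build_label: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ReferenceError("reference sequence is empty")
        if self.offset < 1:
            raise ReferenceError(f"offset must be >= 1, got {self.offset}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        return self.offset + len(self.bases) - 1

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based genomic coordinate."""
        if not self.start <= position <= self.end:
            raise ReferenceError(
                f"position {position} outside reference {self.contig}:{self.start}-{self.end}"
            )
        return self.bases[position - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based genomic slice; both ends must lie inside."""
        if start > end:
            raise ValueError(f"slice start {start} > end {end}")
        self.base_at(start)
        self.base_at(end)
        return self.bases[start - self.offset : end - self.offset + 1]


@dataclass(frozen=True)
class WindowSpec:
    flank: int = 5
    anchor_rule: AnchorRule = AnchorRule.INDEL_LEFT_ANCHOR
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError(f"flank must be >= 1, got {self.flank}")

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1


@dataclass(frozen=True)
class ContextWindow:
    record_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        assert self.end - self.start + 1 == len(self.sequence)


def load_reference(
    path: str | Path,
    contig: str | None = None,
    offset: int = 1,
    build_label: str = "",
) -> ReferenceSequence:
    """Load one contig from a (possibly multi-record) FASTA file.

    Sequence is upper-cased and RNA ``U`` is normalized to ``T``; any other
    character outside ``{A,C,G,T,N}`` raises an error naming its position.
    If ``contig`` is None the file must contain exactly one record.
    """
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise ReferenceError(f"FASTA file not found: {path}")
    try:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:  # Bio raises assorted errors on garbage input
        raise ReferenceError(f"could not parse FASTA {path}: {exc}") from exc
    if not seqs:
        raise ReferenceError(f"FASTA {path} contains no records")
    if contig is None:
        if len(seqs) != 1:
            raise ReferenceError(
                f"FASTA {path} has {len(seqs)} records; specify a contig "
                f"(available: {', '.join(seqs)})"
            )
        contig, raw = next(iter(seqs.items()))
    else:
        if contig not in seqs:
            raise ReferenceError(f"contig {contig!r} not found in {path} (available: {', '.join(seqs)})")
        raw = seqs[contig]
    bases = raw.upper().replace("U", "T")
    bad = next((i for i, ch in enumerate(bases) if ch not in _VALID), None)
    if bad is not None:
        raise ReferenceError(
            f"invalid character {bases[bad]!r} at sequence position {bad + 1} of contig {contig}"
        )
    return ReferenceSequence(contig=contig, offset=offset, bases=bases, build_label=build_label)


def extract_window(
    ref: ReferenceSequence, record: MutationRecord, spec: WindowSpec = WindowSpec()
) -> ContextWindow:
    """Extract the ±flank reference window centred on a mutation.

    The window covers ``[position - flank, position + flank]`` clipped to the
    reference extent; ``truncated`` is set when clipping occurred.  Indels
    are anchored on their leftmost affected base (the catalogue position).
    """
    pos = record.position
    if not ref.start <= pos <= ref.end:
        raise ReferenceError(
            f"record {record.id}: position {pos} outside reference "
            f"{ref.contig}:{ref.start}-{ref.end}"
        )
    lo, hi = pos - spec.flank, pos + spec.flank
    start, end = max(lo, ref.start), min(hi, ref.end)
    return ContextWindow(
        record_id=record.id,
        start=start,
        end=end,
        sequence=ref.slice(start, end),
        truncated=(start != lo or end != hi),
    )


def extract_windows(
    ref: ReferenceSequence, records: Sequence[MutationRecord], spec: WindowSpec = WindowSpec()
) -> list[ContextWindow]:
    return [extract_window(ref, rec, spec) for rec in records]


def bed_mask_positions(path: str | Path, contig: str) -> set[int]:
    """1-based genomic positions covered by a BED file on one contig.

    BED intervals are 0-based half-open; they are converted to the package's
    1-based inclusive convention.  Used to restrict the eligible positions of
    the randomized null (e.g. to exonic/splice-region space matching the
    catalogue's ascertainment).
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise ReferenceError(f"BED file not found: {path}")
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    out: set[int] = set()
    for _, row in bed[bed["chrom"] == contig].iterrows():
        out.update(range(int(row["start"]) + 1, int(row["end"]) + 1))
    return out


def audit_ref_alleles(ref: ReferenceSequence, records: Sequence[MutationRecord]) -> list[str]:
    """Data-integrity gate: ids of SNVs whose catalogue ref allele disagrees
    with the reference base at their position.

    An empty list means the catalogue and the loaded FASTA are mutually
    consistent; pipelines should refuse to proceed otherwise unless
    explicitly overridden.
    """
    mismatches = []
    for rec in records:
        if rec.variant_class is not VariantClass.SNV:
            continue
        if ref.base_at(rec.position) != rec.ref_allele:
            mismatches.append(rec.id)
    return mismatches
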