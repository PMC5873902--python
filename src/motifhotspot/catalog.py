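"""Mutation catalogue I/O, validation, deduplication and filtering.

A catalogue is a flat table with one row per *reported* mutation (so the same
DNA change seen in several patients appears several times).  Downstream
analyses run either on the full catalogue or on the recurrence-collapsed
unique set; both totals are first-class quantities here.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantClass",
    "Annotation",
    "Inheritance",
    "Sex",
    "MutationRecord",
    "CatalogSummary",
    "CatalogError",
    "ConfigError",
    "RecordError",
    "parse_catalog",
    "deduplicate",
    "filter_records",
    "DEFAULT_ANNOTATION_SYNONYMS",
]

_DNA = frozenset("ACGT")


class CatalogError(Exception):
    """Base class for catalogue-level problems."""


class ConfigError(CatalogError):
    """Configuration problem: missing column, unknown enum value, ..."""


class RecordError(CatalogError):
    """One or more rows failed validation; message carries row numbers."""


class VariantClass(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Annotation(enum.Enum):
    SPLICING = "SPLICING"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Inheritance(enum.Enum):
    DE_NOVO = "DE_NOVO"
    RARE_INHERITED = "RARE_INHERITED"
    UNKNOWN = "UNKNOWN"


class Sex(enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"


#: Free-text annotation strings (lower-cased, stripped) mapped onto the fixed
#: vocabulary.  Users may pass an extended mapping to :func:`parse_catalog`.
DEFAULT_ANNOTATION_SYNONYMS: Mapping[str, Annotation] = {
    "splicing": Annotation.SPLICING,
    "splice": Annotation.SPLICING,
    "splice site": Annotation.SPLICING,
    "splice_site": Annotation.SPLICING,
    "splice-site": Annotation.SPLICING,
    "splice_donor": Annotation.SPLICING,
    "splice_acceptor": Annotation.SPLICING,
    "splice_region": Annotation.SPLICING,
    "missense": Annotation.MISSENSE,
    "nonsense": Annotation.NONSENSE,
    "stop_gained": Annotation.NONSENSE,
    "stopgain": Annotation.NONSENSE,
    "frameshift": Annotation.FRAMESHIFT,
    "synonymous": Annotation.SYNONYMOUS,
    "silent": Annotation.SYNONYMOUS,
    "other": Annotation.OTHER,
    "unknown": Annotation.UNKNOWN,
    ".": Annotation.UNKNOWN,
    "": Annotation.UNKNOWN,
}


@dataclass(frozen=True)
class MutationRecord:
    """One catalogued variant.

    ``position`` is the 1-based genomic coordinate of the variant; for indels
    it is the VCF-style left anchor (first affected/anchor base).
    """

    id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    annotation: Annotation = Annotation.UNKNOWN
    inheritance: Inheritance = Inheritance.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or set(allele) - _DNA:
                raise ValueError(f"{name} allele {allele!r} is not a nonempty ACGT string")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical ({self.ref_allele!r}): no-op variant")
        is_snv = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        if is_snv != (self.variant_class is VariantClass.SNV):
            raise ValueError(
                f"variant_class {self.variant_class.value} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """DNA-level identity used for recurrence collapsing."""
        return (self.contig, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class CatalogSummary:
    n_total: int
    n_unique: int
    n_unique_snv: int
    n_unique_indel: int
    n_de_novo: int
    recurrence_multiplicity: Mapping[tuple[str, int, str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_unique == self.n_unique_snv + self.n_unique_indel
        assert self.n_unique <= self.n_total
        assert sum(self.recurrence_multiplicity.values()) == self.n_total


_TSV_COLUMNS = ("id", "contig", "position", "ref", "alt", "class",
                "annotation", "inheritance", "sex", "source")


def _classify(ref: str, alt: str) -> VariantClass:
    return VariantClass.SNV if len(ref) == 1 == len(alt) else VariantClass.INDEL


def _parse_enum(cls, raw: str, synonyms: Mapping[str, object] | None = None):
    token = (raw or "").strip()
    if synonyms is not None:
        mapped = synonyms.get(token.lower())
        if mapped is not None:
            return mapped
    if token in ("", "."):
        return cls.UNKNOWN
    try:
        return cls(token.upper())
    except ValueError:
        raise ValueError(f"unrecognized {cls.__name__} value {raw!r}") from None


def parse_catalog(
    path: str | Path,
    dialect: str = "tsv",
    annotation_synonyms: Mapping[str, Annotation] | None = None,
) -> list[MutationRecord]:
    """Read a mutation catalogue from a TSV table or a VCF file.

    The TSV dialect uses tab-separated columns
    ``id contig position ref alt class annotation inheritance sex source``
    with ``.`` for missing values and 1-based positions.  The VCF dialect is
    standard VCF 4.x with optional INFO keys ``ANNOT``, ``INH`` and ``SEX``;
    the variant class is derived from allele lengths.

    Row order is preserved.  Malformed rows are collected and reported
    together in a :class:`RecordError` naming each offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"catalogue file not found: {path}")
    synonyms = dict(DEFAULT_ANNOTATION_SYNONYMS)
    if annotation_synonyms:
        synonyms.update({k.lower(): v for k, v in annotation_synonyms.items()})
    dialect = dialect.lower()
    if dialect == "tsv":
        return _parse_tsv(path, synonyms)
    if dialect == "vcf":
        return _parse_vcf(path, synonyms)
    raise ConfigError(f"unknown catalogue dialect {dialect!r} (expected 'tsv' or 'vcf')")


def _parse_tsv(path: Path, synonyms: Mapping[str, Annotation]) -> list[MutationRecord]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"empty catalogue file {path}", stacklevel=2)
            return []
        missing = [c for c in _TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ConfigError(f"catalogue {path} is missing required column(s): {', '.join(missing)}")
        records: list[MutationRecord] = []
        errors: list[str] = []
        n_rows = 0
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            n_rows += 1
            try:
                ref = (row["ref"] or "").strip().upper()
                alt = (row["alt"] or "").strip().upper()
                cls_token = (row["class"] or "").strip()
                vclass = _classify(ref, alt) if cls_token in ("", ".") else VariantClass(cls_token.upper())
                if vclass is not _classify(ref, alt):
                    raise ValueError(f"declared class {cls_token} inconsistent with alleles {ref}>{alt}")
                records.append(
                    MutationRecord(
                        id=(row["id"] or "").strip() or f"row{row_no}",
                        contig=(row["contig"] or "").strip(),
                        position=int(row["position"]),
                        ref_allele=ref,
                        alt_allele=alt,
                        variant_class=vclass,
                        annotation=_parse_enum(Annotation, row["annotation"], synonyms),
                        inheritance=_parse_enum(Inheritance, row["inheritance"]),
                        sex=_parse_enum(Sex, row["sex"]),
                        source="" if (row["source"] or ".").strip() == "." else row["source"].strip(),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"line {row_no}: {exc}")
        if errors:
            raise RecordError(f"catalogue {path} has {len(errors)} malformed row(s):\n" + "\n".join(errors))
        if n_rows == 0:
            warnings.warn(f"catalogue {path} contains a header but no data rows", stacklevel=2)
        return records


def _parse_vcf(path: Path, synonyms: Mapping[str, Annotation]) -> list[MutationRecord]:
    import pysam

    records: list[MutationRecord] = []
    errors: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf, start=1):
            try:
                alts = rec.alts or ()
                if len(alts) != 1:
                    raise ValueError(f"expected exactly one ALT allele, got {alts}")
                ref = rec.ref.upper()
                alt = alts[0].upper()
                info = rec.info

                def _info(key: str) -> str:
                    try:  # pysam raises on keys absent from the header
                        val = info.get(key)
                    except (KeyError, ValueError):
                        return ""
                    if val is None:
                        return ""
                    return val[0] if isinstance(val, tuple) else str(val)

                records.append(
                    MutationRecord(
                        id=rec.id or f"var{i}",
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        variant_class=_classify(ref, alt),
                        annotation=_parse_enum(Annotation, _info("ANNOT"), synonyms),
                        inheritance=_parse_enum(Inheritance, _info("INH")),
                        sex=_parse_enum(Sex, _info("SEX")),
                        source=_info("SOURCE"),
                    )
                )
            except ValueError as exc:
                errors.append(f"record {i}: {exc}")
    if errors:
        raise RecordError(f"VCF {path} has {len(errors)} malformed record(s):\n" + "\n".join(errors))
    if not records:
        warnings.warn(f"VCF {path} contains no variant records", stacklevel=2)
    return records


def deduplicate(records: Sequence[MutationRecord]) -> tuple[list[MutationRecord], CatalogSummary]:
    """Collapse recurrent mutations to one representative each.

    Identity is DNA-level: ``(contig, position, ref, alt)``.  The
    representative is the first occurrence in input order.  Returns the
    unique records plus a :class:`CatalogSummary` with both totals and the
    per-key recurrence multiplicities.
    """
    seen: dict[tuple, MutationRecord] = {}
    multiplicity: Counter = Counter()
    for rec in records:
        multiplicity[rec.key] += 1
        seen.setdefault(rec.key, rec)
    unique = list(seen.values())
    n_snv = sum(1 for r in unique if r.variant_class is VariantClass.SNV)
    summary = CatalogSummary(
        n_total=len(records),
        n_unique=len(unique),
        n_unique_snv=n_snv,
        n_unique_indel=len(unique) - n_snv,
        n_de_novo=sum(1 for r in records if r.inheritance is Inheritance.DE_NOVO),
        recurrence_multiplicity=dict(multiplicity),
    )
    return unique, summary


def _coerce(cls, value):
    if value is None or isinstance(value, cls):
        return value
    try:
        return cls(str(value).upper())
    except ValueError:
        raise ConfigError(f"unknown {cls.__name__} value {value!r}") from None


def filter_records(
    records: Iterable[MutationRecord],
    by_class: VariantClass | str | None = None,
    by_annotation: Annotation | str | None = None,
    by_inheritance: Inheritance | str | None = None,
) -> list[MutationRecord]:
    """Stable-order subset matching all provided predicates (conjunction)."""
    by_class = _coerce(VariantClass, by_class)
    by_annotation = _coerce(Annotation, by_annotation)
    by_inheritance = _coerce(Inheritance, by_inheritance)
    out = []
    for rec in records:
        if by_class is not None and rec.variant_class is not by_class:
            continue
        if by_annotation is not None and rec.annotation is not by_annotation:
            continue
        if by_inheritance is not None and rec.inheritance is not by_inheritance:
            continue
        out.append(rec)
    return out
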