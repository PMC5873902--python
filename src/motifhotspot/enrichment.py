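"""Association tests downstream of motif flagging.

The central contrast: are motif-flagged mutations enriched for splice-site
annotation?  The implemented 2x2 layout is the standard disjoint one

                 splicing   non-splicing
    flagged         a            b
    unflagged       c            d

which is the only layout with a valid exact test.  The overlapping-group
fractions sometimes quoted descriptively (flagged-splicing fraction vs the
splicing fraction of the *whole* catalogue) are reported alongside, not
tested.  UNKNOWN annotations count as non-splicing — conservative toward the
enrichment claim — and are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
from scipy import stats

from .catalog import Annotation, Inheritance, MutationRecord, Sex
from .context import ContextWindow, StrandMode
from .motifs import MotifSpec, PermutationConfig, Statistic, observed_statistic

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "SexSummary",
    "InheritanceTable",
    "ControlComparison",
    "build_contingency",
    "fisher_exact",
    "sex_summary",
    "inheritance_summary",
    "compare_control",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # flagged & splicing
    b: int  # flagged & non-splicing
    c: int  # unflagged & splicing
    d: int  # unflagged & non-splicing
    n_unknown_annotation: int = 0  # UNKNOWNs folded into b/d, tallied here

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    p_two_sided: float
    odds_ratio: float  # sample OR (a*d)/(b*c); inf when b*c == 0 and a*d > 0
    odds_ratio_haldane: float  # Haldane–Anscombe: +0.5 to every cell
    flagged_splicing_fraction: float  # a / (a+b)
    overall_splicing_fraction: float  # (a+c) / N


@dataclass(frozen=True)
class SexSummary:
    n_female: int
    n_male: int
    n_unknown: int
    female_fraction_of_known: float | None  # None when no record has known sex


@dataclass(frozen=True)
class InheritanceTable:
    flagged: Mapping[Inheritance, int]
    unflagged: Mapping[Inheritance, int]


@dataclass(frozen=True)
class ControlComparison:
    case_statistic: int
    control_statistic: int
    case_fraction: float
    control_fraction: float
    difference: float  # case_fraction - control_fraction
    p_value: float  # two-sided label-permutation p on |difference|
    n_iterations: int


def build_contingency(
    records: Sequence[MutationRecord], flagged_ids: Set[str]
) -> ContingencyTable2x2:
    """Cross-classify mutations by motif flag and splicing annotation."""
    ids = {r.id for r in records}
    stray = set(flagged_ids) - ids
    if stray:
        raise ValueError(f"flagged ids not present in the records: {sorted(stray)[:5]}")
    a = b = c = d = unknown = 0
    for rec in records:
        flagged = rec.id in flagged_ids
        splicing = rec.annotation is Annotation.SPLICING
        if rec.annotation is Annotation.UNKNOWN:
            unknown += 1
        if flagged and splicing:
            a += 1
        elif flagged:
            b += 1
        elif splicing:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d, n_unknown_annotation=unknown)


def fisher_exact(table: ContingencyTable2x2, mid_p: bool = False) -> EnrichmentResult:
    """Two-sided Fisher exact test on the disjoint 2x2 layout.

    The two-sided p sums hypergeometric point probabilities <= that of the
    observed table (the common convention).  ``mid_p=True`` instead counts
    the observed table's probability class at half weight.
    """
    if table.total < 1:
        raise ValueError("empty contingency table")
    arr = table.as_array()
    if mid_p:
        p = _mid_p(table)
    else:
        _, p = stats.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        sample_or = float("inf") if a * d > 0 else float("nan")
    else:
        sample_or = (a * d) / (b * c)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    n_flagged = a + b
    return EnrichmentResult(
        table=table,
        p_two_sided=float(p),
        odds_ratio=sample_or,
        odds_ratio_haldane=haldane,
        flagged_splicing_fraction=(a / n_flagged) if n_flagged else float("nan"),
        overall_splicing_fraction=(a + c) / table.total,
    )


def _mid_p(table: ContingencyTable2x2) -> float:
    """Two-sided mid-p: tables strictly less probable at full weight, the
    observed probability class at half weight (hypergeometric, fixed margins)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    rel_tol = 1 + 1e-7
    smaller = probs < p_obs / rel_tol
    equal = np.abs(probs - p_obs) <= p_obs * 1e-7
    return float(probs[smaller].sum() + 0.5 * probs[equal].sum())


def sex_summary(records: Sequence[MutationRecord]) -> SexSummary:
    """Counts of reported sex; fraction computed over known-sex records only."""
    nf = sum(1 for r in records if r.sex is Sex.F)
    nm = sum(1 for r in records if r.sex is Sex.M)
    nu = len(records) - nf - nm
    known = nf + nm
    return SexSummary(nf, nm, nu, (nf / known) if known else None)


def inheritance_summary(
    records: Sequence[MutationRecord],
    flagged_ids: Set[str],
    by_annotation: Annotation | None = None,
) -> InheritanceTable:
    """Inheritance-class counts, cross-tabulated against the motif flag.

    With ``by_annotation`` the tabulation is restricted to records carrying
    that annotation (e.g. the flagged *splicing* mutations).
    """
    flagged: dict[Inheritance, int] = {k: 0 for k in Inheritance}
    unflagged: dict[Inheritance, int] = {k: 0 for k in Inheritance}
    for rec in records:
        if by_annotation is not None and rec.annotation is not by_annotation:
            continue
        bucket = flagged if rec.id in flagged_ids else unflagged
        bucket[rec.inheritance] += 1
    return InheritanceTable(flagged=flagged, unflagged=unflagged)


def compare_control(
    case_windows: Sequence[ContextWindow],
    control_windows: Sequence[ContextWindow],
    motif: str,
    config: PermutationConfig = PermutationConfig(),
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY,
) -> ControlComparison:
    """Case-vs-control motif proximity with a label-permutation p-value.

    Both sets get the WINDOWS_WITH_HIT statistic for ``motif``; the p-value
    is two-sided on the absolute difference in flagged fractions under
    random reassignment of the case/control labels (sizes preserved).
    """
    if not case_windows or not control_windows:
        raise ValueError("both case and control window sets must be nonempty")
    spec = MotifSpec(length_l=len(motif), statistic=Statistic.WINDOWS_WITH_HIT)
    case_stat, _ = observed_statistic(case_windows, motif, spec, strand_mode)
    control_stat, _ = observed_statistic(control_windows, motif, spec, strand_mode)
    n_case, n_control = len(case_windows), len(control_windows)
    diff = case_stat / n_case - control_stat / n_control

    # one hit indicator per window; label permutation only needs these
    from .motifs import count_in_window

    hits = np.array(
        [count_in_window(w, motif, strand_mode) > 0 for w in list(case_windows) + list(control_windows)],
        dtype=bool,
    )
    rng = np.random.default_rng(config.seed)
    n_total = n_case + n_control
    count = 0
    for _ in range(config.n_iterations):
        perm = rng.permutation(n_total)
        perm_case = hits[perm[:n_case]].sum() / n_case
        perm_control = hits[perm[n_case:]].sum() / n_control
        if abs(perm_case - perm_control) >= abs(diff) - 1e-12:
            count += 1
    return ControlComparison(
        case_statistic=case_stat,
        control_statistic=control_stat,
        case_fraction=case_stat / n_case,
        control_fraction=control_stat / n_control,
        difference=diff,
        p_value=count / config.n_iterations,
        n_iterations=config.n_iterations,
    )
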