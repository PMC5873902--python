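"""Fixed-length motif counting and the randomized hotspot test.

The question asked here: do catalogued mutations sit unusually close to a
given k-mer?  For every motif of length ``l`` (all 4^l of them) we compute an
observed statistic over the ±flank context windows — by default the number of
windows containing at least one occurrence — and compare it against a null
distribution built from 10,000 randomized draws.  The empirical p-value is
the fraction of null draws whose statistic is greater than or equal to the
observed one, so p can never be exactly zero in spirit: a zero count is
displayed as "< 1/N".

Two null models are provided, both reconstructions of a positional-clustering
null rather than a certified published procedure:

``POSITIONAL_RESAMPLE``
    each iteration draws the same number of mutation positions uniformly
    without replacement from the eligible positions of the reference
    (positions whose full window fits inside the sequence), extracts windows,
    and recomputes the statistic.  This is the default: the hypothesis under
    test is positional clustering near motif copies.

``DINUCLEOTIDE_SHUFFLE``
    each iteration shuffles every observed window preserving its dinucleotide
    composition (Altschul–Erikson Eulerian-path shuffle) and recomputes.
    Sensitivity analysis: keeps the local composition, destroys motif order.

All 4^l motifs are scored against the *same* randomized draws — one
randomization, 4^l statistics — so motif ranks are comparable across motifs.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .context import ContextWindow, ReferenceSequence, StrandMode, WindowSpec

__all__ = [
    "Statistic",
    "NullModel",
    "Correction",
    "MotifSpec",
    "MotifCountTable",
    "PermutationConfig",
    "PermutationResult",
    "enumerate_motifs",
    "reverse_complement",
    "count_in_window",
    "observed_statistic",
    "count_table",
    "run_randomized_test",
    "scan_all_motifs",
    "dinucleotide_shuffle",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


class Statistic(enum.Enum):
    WINDOWS_WITH_HIT = "WINDOWS_WITH_HIT"
    TOTAL_OCCURRENCES = "TOTAL_OCCURRENCES"


class NullModel(enum.Enum):
    POSITIONAL_RESAMPLE = "POSITIONAL_RESAMPLE"
    DINUCLEOTIDE_SHUFFLE = "DINUCLEOTIDE_SHUFFLE"


class Correction(enum.Enum):
    BONFERRONI = "BONFERRONI"
    BH = "BH"
    NONE = "NONE"


@dataclass(frozen=True)
class MotifSpec:
    length_l: int = 3
    statistic: Statistic = Statistic.WINDOWS_WITH_HIT

    def __post_init__(self) -> None:
        if self.length_l < 1:
            raise ValueError(f"motif length must be >= 1, got {self.length_l}")

    @property
    def n_motifs(self) -> int:
        return 4**self.length_l


@dataclass(frozen=True)
class PermutationConfig:
    n_iterations: int = 10_000
    null_model: NullModel = NullModel.POSITIONAL_RESAMPLE
    seed: int = 0
    alpha: float = 0.05
    correction: Correction = Correction.BONFERRONI

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class MotifCountTable:
    """Observed per-motif statistics over a set of context windows."""

    per_motif: Mapping[str, int]
    n_windows: int
    spec: MotifSpec
    windows_flagged: Mapping[str, frozenset[str]]  # motif -> record ids with >= 1 hit


@dataclass
class PermutationResult:
    motif: str
    observed: int
    null_draws: np.ndarray
    p_empirical: float
    p_corrected: float
    significant: bool

    @property
    def n_iterations(self) -> int:
        return len(self.null_draws)

    @property
    def p_display(self) -> str:
        """Publication-style p string: a zero tail count reads "< 1/N"."""
        if self.p_empirical == 0.0:
            return f"< {1.0 / self.n_iterations:g}"
        return f"{self.p_empirical:g}"

    @property
    def p_add_one(self) -> float:
        """(count + 1) / (N + 1) estimator, never exactly zero."""
        count = int(round(self.p_empirical * self.n_iterations))
        return (count + 1) / (self.n_iterations + 1)


def enumerate_motifs(spec: MotifSpec | int = MotifSpec()) -> list[str]:
    """All 4^l motifs of length l in lexicographic order (AAA... first)."""
    l = spec if isinstance(spec, int) else spec.length_l
    return ["".join(p) for p in itertools.product("ACGT", repeat=l)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _match_positions(seq: str, motif: str) -> set[int]:
    l = len(motif)
    return {i for i in range(len(seq) - l + 1) if seq[i : i + l] == motif}


def count_in_window(
    window: ContextWindow | str,
    motif: str,
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY,
) -> int:
    """Overlap-allowed occurrence count of ``motif`` in one window.

    Positions overlapping an ``N`` never match.  Under ``BOTH_STRANDS`` a
    site counts if the forward substring equals the motif or its reverse
    complement; a site matching both (possible only for palindromic motifs)
    counts once.
    """
    seq = window if isinstance(window, str) else window.sequence
    if len(motif) > len(seq):
        warnings.warn(
            f"motif {motif!r} is longer than the window ({len(seq)} bp); count is 0",
            stacklevel=2,
        )
        return 0
    hits = _match_positions(seq, motif)
    if strand_mode is StrandMode.BOTH_STRANDS:
        hits |= _match_positions(seq, reverse_complement(motif))
    return len(hits)


def observed_statistic(
    windows: Sequence[ContextWindow],
    motif: str,
    spec: MotifSpec = MotifSpec(),
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY,
) -> tuple[int, frozenset[str]]:
    """Observed statistic for one motif plus the flagged record ids.

    WINDOWS_WITH_HIT counts windows containing >= 1 occurrence (the
    "mutations near the motif" reading); TOTAL_OCCURRENCES sums occurrence
    counts over windows.
    """
    flagged = []
    total = 0
    for w in windows:
        c = count_in_window(w, motif, strand_mode)
        if c:
            flagged.append(w.record_id)
            total += c
    stat = len(flagged) if spec.statistic is Statistic.WINDOWS_WITH_HIT else total
    return stat, frozenset(flagged)


def count_table(
    windows: Sequence[ContextWindow],
    spec: MotifSpec = MotifSpec(),
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY,
) -> MotifCountTable:
    """Observed statistics for every motif of length l at once."""
    motifs = enumerate_motifs(spec)
    per_motif = {}
    flagged = {}
    for m in motifs:
        per_motif[m], flagged[m] = observed_statistic(windows, m, spec, strand_mode)
    return MotifCountTable(per_motif=per_motif, n_windows=len(windows), spec=spec, windows_flagged=flagged)


# ---------------------------------------------------------------------------
# fast vectorized machinery for the randomized null
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_LUT = np.full(256, 4, dtype=np.int64)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c


def _codes(seq: str) -> np.ndarray:
    return _LUT[_encode(seq)]


def _kmer_ids(codes: np.ndarray, l: int) -> np.ndarray:
    """Base-4 k-mer id at every start position; -1 where an N intrudes."""
    n = len(codes) - l + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(l):
        c = codes[j : j + n]
        ids = ids * 4 + np.where(c < 4, c, 0)
        valid &= c < 4
    ids[~valid] = -1
    return ids


def _revcomp_map(l: int) -> np.ndarray:
    ids = np.arange(4**l)
    out = np.zeros_like(ids)
    rem = ids.copy()
    for _ in range(l):
        out = out * 4 + (3 - rem % 4)
        rem //= 4
    # digits of `ids` are consumed least-significant first, which reverses
    # the k-mer while complementing: exactly reverse complement in base-4
    return out


def _stats_from_id_matrix(
    ids: np.ndarray, n_motifs: int, statistic: Statistic, rc_map: np.ndarray | None
) -> np.ndarray:
    """Per-motif statistic vector from an (n_windows, n_positions) id matrix."""
    n_win = ids.shape[0]
    if statistic is Statistic.WINDOWS_WITH_HIT:
        hit = np.zeros((n_win, n_motifs + 1), dtype=bool)
        rows = np.arange(n_win)[:, None]
        hit[rows, ids] = True
        if rc_map is not None:
            rc_ids = np.where(ids >= 0, rc_map[np.maximum(ids, 0)], -1)
            hit[rows, rc_ids] = True
        return hit[:, :n_motifs].sum(axis=0).astype(np.int64)
    flat = ids.ravel()
    flat = flat[flat >= 0]
    counts = np.bincount(flat, minlength=n_motifs)
    if rc_map is not None:
        rc = np.bincount(rc_map[flat], minlength=n_motifs)
        # a site whose k-mer is its own reverse complement must count once
        palindrome = rc_map[flat] == flat
        dup = np.bincount(flat[palindrome], minlength=n_motifs)
        counts = counts + rc - dup
    return counts.astype(np.int64)


def _observed_vector(
    windows: Sequence[ContextWindow], spec: MotifSpec, strand_mode: StrandMode
) -> np.ndarray:
    """Vector of observed statistics for all motifs (fast path, handles
    ragged/truncated windows)."""
    n_motifs = spec.n_motifs
    rc_map = _revcomp_map(spec.length_l) if strand_mode is StrandMode.BOTH_STRANDS else None
    out = np.zeros(n_motifs, dtype=np.int64)
    for w in windows:
        ids = _kmer_ids(_codes(w.sequence), spec.length_l)
        if len(ids) == 0:
            continue
        out += _stats_from_id_matrix(ids[None, :], n_motifs, spec.statistic, rc_map)
    return out


def _null_matrix(
    ref: ReferenceSequence,
    n_mutations: int,
    windows: Sequence[ContextWindow],
    window_spec: WindowSpec,
    motif_spec: MotifSpec,
    config: PermutationConfig,
    rng: np.random.Generator,
    strand_mode: StrandMode,
    position_sink: list | None = None,
    position_mask: set[int] | None = None,
) -> np.ndarray:
    """(n_iterations, 4^l) matrix of null statistics, one row per draw.

    ``position_sink``, when given, collects the genomic positions sampled at
    each iteration (POSITIONAL_RESAMPLE) so external code can recount the
    draws independently.
    """
    f = window_spec.flank
    l = motif_spec.length_l
    n_motifs = motif_spec.n_motifs
    rc_map = _revcomp_map(l) if strand_mode is StrandMode.BOTH_STRANDS else None
    out = np.empty((config.n_iterations, n_motifs), dtype=np.int64)

    if config.null_model is NullModel.POSITIONAL_RESAMPLE:
        if len(ref) < window_spec.window_length:
            raise ValueError(
                f"reference ({len(ref)} bp) shorter than the window ({window_spec.window_length} bp)"
            )
        K = _kmer_ids(_codes(ref.bases), l)
        # eligible centres: 0-based indices whose full window fits,
        # optionally restricted to a genomic position mask (e.g. from BED)
        eligible = np.arange(f, len(ref) - f)
        if position_mask is not None:
            allowed = np.array(sorted(position_mask), dtype=np.int64) - ref.offset
            eligible = np.intersect1d(eligible, allowed)
        if n_mutations > len(eligible):
            raise ValueError(
                f"cannot draw {n_mutations} positions without replacement from "
                f"{len(eligible)} eligible positions"
            )
        offsets = np.arange(2 * f + 1 - l + 1) - f  # k-mer starts within a window
        for it in range(config.n_iterations):
            centres = rng.choice(eligible, size=n_mutations, replace=False)
            if position_sink is not None:
                position_sink.append((centres + ref.offset).tolist())
            ids = K[centres[:, None] + offsets[None, :]]
            out[it] = _stats_from_id_matrix(ids, n_motifs, motif_spec.statistic, rc_map)
        return out

    # DINUCLEOTIDE_SHUFFLE: permute each observed window, recount
    seqs = [w.sequence for w in windows]
    for it in range(config.n_iterations):
        shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
        if position_sink is not None:
            position_sink.append(list(shuffled))
        acc = np.zeros(n_motifs, dtype=np.int64)
        for s in shuffled:
            ids = _kmer_ids(_codes(s), l)
            if len(ids):
                acc += _stats_from_id_matrix(ids[None, :], n_motifs, motif_spec.statistic, rc_map)
        out[it] = acc
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erikson shuffle: a uniform random sequence with the same
    dinucleotide composition (and first/last base) as ``seq``.

    Works on the multigraph whose edges are the observed dinucleotides; a
    random Eulerian path anchored at the original endpoints is drawn by the
    last-edge arborescence construction.
    """
    if len(seq) <= 2:
        return seq
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # choose a random last edge out of every non-terminal vertex such that
    # the chosen edges form an arborescence toward the terminal vertex
    for _ in range(1000):
        lasts = {}
        for v in vertices:
            if v == last or not edges[v]:
                continue
            lasts[v] = edges[v][rng.integers(len(edges[v]))]
        # connectivity check: every chosen-last vertex must reach `last`
        ok = True
        for v in lasts:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in lasts:
                    ok = False
                    break
                seen.add(cur)
                cur = lasts[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - bounded retries exhausted on adversarial input
        return seq
    shuffled_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v in lasts:
            rest.remove(lasts[v])
        rng.shuffle(rest)
        if v in lasts:
            rest.append(lasts[v])
        shuffled_edges[v] = rest
    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _correct(p_values: np.ndarray, correction: Correction, alpha: float) -> np.ndarray:
    if correction is Correction.NONE or len(p_values) == 1:
        return p_values.copy()
    from statsmodels.stats.multitest import multipletests

    method = {"BONFERRONI": "bonferroni", "BH": "fdr_bh"}[correction.value]
    return multipletests(p_values, alpha=alpha, method=method)[1]


def run_randomized_test(
    ref: ReferenceSequence,
    windows: Sequence[ContextWindow],
    motif: str,
    window_spec: WindowSpec = WindowSpec(),
    config: PermutationConfig = PermutationConfig(),
    motif_spec: MotifSpec | None = None,
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY,
    position_sink: list | None = None,
    position_mask: set[int] | None = None,
) -> PermutationResult:
    """Randomized draw test for a single motif.

    The observed statistic comes from the supplied windows; the null draws
    the same number of mutations under ``config.null_model``.  The empirical
    p-value counts null draws >= observed, divided by the iteration count.
    No multiplicity correction is applied (p_corrected == p_empirical);
    use :func:`scan_all_motifs` for a corrected family of 4^l tests.
    """
    if not windows:
        raise ValueError("need at least one observed window")
    spec = motif_spec or MotifSpec(length_l=len(motif))
    if len(motif) != spec.length_l:
        raise ValueError(f"motif {motif!r} does not match motif length {spec.length_l}")
    rng = np.random.default_rng(config.seed)
    observed, _ = observed_statistic(windows, motif, spec, strand_mode)
    null = _null_matrix(
        ref, len(windows), windows, window_spec, spec, config, rng, strand_mode,
        position_sink, position_mask,
    )
    motif_idx = enumerate_motifs(spec).index(motif)
    draws = null[:, motif_idx]
    p = float(np.count_nonzero(draws >= observed)) / config.n_iterations
    return PermutationResult(
        motif=motif,
        observed=observed,
        null_draws=draws,
        p_empirical=p,
        p_corrected=p,
        significant=p <= config.alpha,
    )


def scan_all_motifs(
    ref: ReferenceSequence,
    windows: Sequence[ContextWindow],
    config: PermutationConfig = PermutationConfig(),
    motif_spec: MotifSpec = MotifSpec(),
    window_spec: WindowSpec = WindowSpec(),
    strand_mode: StrandMode = StrandMode.REFERENCE_ONLY,
    position_mask: set[int] | None = None,
) -> list[PermutationResult]:
    """Randomized test for every motif of length l, sharing one null.

    All 4^l motifs are counted on each randomized draw, so every motif's
    null comes from the same randomization.  Results are sorted by corrected
    p-value, then observed statistic (descending), then motif string.
    """
    if not windows:
        raise ValueError("need at least one observed window")
    motifs = enumerate_motifs(motif_spec)
    rng = np.random.default_rng(config.seed)
    observed = _observed_vector(windows, motif_spec, strand_mode)
    null = _null_matrix(
        ref, len(windows), windows, window_spec, motif_spec, config, rng, strand_mode,
        None, position_mask,
    )
    tail = (null >= observed[None, :]).sum(axis=0)
    p_emp = tail.astype(float) / config.n_iterations
    p_corr = _correct(p_emp, config.correction, config.alpha)
    results = [
        PermutationResult(
            motif=m,
            observed=int(observed[i]),
            null_draws=null[:, i],
            p_empirical=float(p_emp[i]),
            p_corrected=float(p_corr[i]),
            significant=bool(p_corr[i] <= config.alpha),
        )
        for i, m in enumerate(motifs)
    ]
    results.sort(key=lambda r: (r.p_corrected, -r.observed, r.motif))
    return results
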