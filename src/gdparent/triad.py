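"""Triad (mother, father, offspring) enumeration, scoring, and declaration.

For every unordered candidate parent pair the expected-progeny genotype is
built once and compared, via Gower dissimilarity, with every candidate
offspring.  A true trio yields a near-zero dissimilarity (exactly zero
absent genotyping error), while spurious combinations pile up far higher,
so the ordered GD values show a conspicuous gap.  The analysis locates the
largest gap below a pruning ceiling (MaxIdent), checks that the gap itself
is an outlier among adjacent-gap lengths (Dixon test), and then tests each
below-gap triad individually against the nearest above-gap values before
declaring it true.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dixon import dixon_test
from .errors import ConfigurationError
from .genotype import GenotypeMatrix, expected_progeny_states, gower_matrix

log = logging.getLogger(__name__)

MOTHER_KEYS = frozenset({"Mo", "Pa", "All"})
FATHER_KEYS = frozenset({"Fa", "Pa", "All"})
OFFSPRING_KEYS = frozenset({"Off", "All"})


@dataclass(slots=True)
class TriadRecord:
    mother_id: str
    father_id: str
    offspring_id: str
    gd: float
    usable_loci: int
    self_overlap: bool = False
    declared: bool = False
    p_value: float | None = None


@dataclass
class GapResult:
    """Location and significance of the largest adjacent-GD gap."""

    determinable: bool
    threshold: float = float("nan")
    gap_size: float = float("nan")
    gap_p: float = float("nan")
    n_below: int = 0
    n_in_region: int = 0
    search_ceiling: float = float("nan")


@dataclass
class TriadSpace:
    """Candidate triads as (unordered parent pair) x (offspring) grid.

    ``pairs`` holds oriented ``(mother_id, father_id)`` tuples; the full
    triad list is the cross product with ``offspring_ids``, so the grid is
    never materialised unless asked for.
    """

    pairs: list[tuple[str, str]]
    offspring_ids: list[str]

    def __len__(self) -> int:
        return len(self.pairs) * len(self.offspring_ids)

    def triads(self) -> list[tuple[str, str, str]]:
        return [(m, f, k) for (m, f) in self.pairs for k in self.offspring_ids]


def enumerate_triads(ids: list[str], class_keys: list[str]) -> TriadSpace:
    """Enumerate candidate triads from the class roster.

    Mother candidates are Mo/Pa/All, fathers Fa/Pa/All, offspring Off/All.
    Parent pairs are unordered (deduplicated when an individual qualifies
    for both roles) with mother != father; every offspring candidate is
    paired with every parent pair, including the parents themselves
    (flagged as self-overlap downstream), so with all n individuals coded
    All the triad count is exactly n * n(n-1)/2.
    """
    if len(ids) != len(class_keys):
        raise ValueError("ids and class_keys must align")
    mothers = [i for i, k in enumerate(class_keys) if k in MOTHER_KEYS]
    fathers = [i for i, k in enumerate(class_keys) if k in FATHER_KEYS]
    offspring = [i for i, k in enumerate(class_keys) if k in OFFSPRING_KEYS]
    for name, cand in (("mother", mothers), ("father", fathers), ("offspring", offspring)):
        if not cand:
            raise ConfigurationError(
                f"no {name} candidates in roster (classes present: "
                f"{sorted(set(class_keys))})"
            )
    oriented: dict[tuple[int, int], tuple[int, int]] = {}
    for i in mothers:
        for j in fathers:
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            if key not in oriented:
                oriented[key] = (i, j)
    pairs = [(ids[m], ids[f]) for m, f in (oriented[k] for k in sorted(oriented))]
    return TriadSpace(pairs=pairs, offspring_ids=[ids[k] for k in offspring])


@dataclass
class TriadScores:
    """Scored triad grid: GD, usable-locus count, and declaration state.

    Arrays are (n_pairs x n_offspring); ``records()`` materialises the flat
    list of :class:`TriadRecord` (ordering: pair-major).
    """

    pairs: list[tuple[str, str]]
    offspring_ids: list[str]
    gd: np.ndarray
    usable: np.ndarray
    self_overlap: np.ndarray
    declared: np.ndarray = field(default=None)  # type: ignore[assignment]
    p_value: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.declared is None:
            self.declared = np.zeros(self.gd.shape, dtype=bool)
        if self.p_value is None:
            self.p_value = np.full(self.gd.shape, np.nan)

    @property
    def flat_gd(self) -> np.ndarray:
        return self.gd.ravel()

    def records(self) -> list[TriadRecord]:
        out: list[TriadRecord] = []
        gd = self.gd
        usable = self.usable
        overlap = self.self_overlap
        declared = self.declared
        pval = self.p_value
        for p, (m, f) in enumerate(self.pairs):
            for k, off in enumerate(self.offspring_ids):
                pv = pval[p, k]
                out.append(
                    TriadRecord(
                        mother_id=m,
                        father_id=f,
                        offspring_id=off,
                        gd=float(gd[p, k]),
                        usable_loci=int(usable[p, k]),
                        self_overlap=bool(overlap[p, k]),
                        declared=bool(declared[p, k]),
                        p_value=None if np.isnan(pv) else float(pv),
                    )
                )
        return out

    def declared_records(self) -> list[TriadRecord]:
        out = []
        for p, k in zip(*np.nonzero(self.declared)):
            out.append(
                TriadRecord(
                    mother_id=self.pairs[p][0],
                    father_id=self.pairs[p][1],
                    offspring_id=self.offspring_ids[k],
                    gd=float(self.gd[p, k]),
                    usable_loci=int(self.usable[p, k]),
                    self_overlap=bool(self.self_overlap[p, k]),
                    declared=True,
                    p_value=float(self.p_value[p, k]),
                )
            )
        return out


def score_triads(gm: GenotypeMatrix, space: TriadSpace) -> TriadScores:
    """Compute GD between each pair's expected progeny and each offspring.

    Expected progenies are computed once per parent pair and reused across
    all offspring; results are identical to per-triad recomputation.
    """
    pi = np.array([gm.index_of(m) for m, _ in space.pairs], dtype=np.intp)
    pj = np.array([gm.index_of(f) for _, f in space.pairs], dtype=np.intp)
    ko = np.array([gm.index_of(k) for k in space.offspring_ids], dtype=np.intp)
    ep = expected_progeny_states(gm.states[pi], gm.states[pj])
    gd, usable = gower_matrix(ep, gm.states[ko])
    n_undef = int(np.isnan(gd).sum())
    if n_undef:
        log.warning(
            "%d triads have no comparable loci; their GD is undefined and "
            "they are excluded from ranking",
            n_undef,
        )
    overlap = (pi[:, None] == ko[None, :]) | (pj[:, None] == ko[None, :])
    return TriadScores(
        pairs=space.pairs,
        offspring_ids=space.offspring_ids,
        gd=gd,
        usable=usable,
        self_overlap=overlap,
    )


def find_gap(
    gds: np.ndarray,
    max_ident: float = 0.1,
    *,
    seed: int = 0,
    n_mc: int = 10_000,
) -> GapResult:
    """Locate the largest gap between adjacent ordered GD values < MaxIdent.

    The threshold is the midpoint of the widest adjacent gap; its
    significance is the Dixon p-value of that gap being an upper outlier
    among all adjacent-gap lengths in the scanned region.  With fewer than
    three values below the ceiling the gap is undeterminable and the
    analysis declares nothing.  Exact ties for the widest gap resolve to
    the lowest-GD gap (the conservative, smaller declared set).
    """
    g = np.asarray(gds, dtype=np.float64)
    region = np.sort(g[np.isfinite(g) & (g < max_ident)])
    if region.size < 3:
        log.warning(
            "gap undeterminable: only %d GD values below MaxIdent=%g",
            region.size, max_ident,
        )
        return GapResult(
            determinable=False, n_in_region=int(region.size), search_ceiling=max_ident
        )
    diffs = np.diff(region)
    i = int(np.argmax(diffs))  # first (lowest-GD) maximal gap
    gap_size = float(diffs[i])
    threshold = float((region[i] + region[i + 1]) / 2.0)
    if gap_size == 0.0:
        gap_p = 1.0
    elif diffs.size < 3:
        log.warning("only %d adjacent gaps in region; gap significance untestable", diffs.size)
        gap_p = 1.0
    else:
        gap_p = dixon_test(diffs, "max", seed=seed, n_mc=n_mc)
    return GapResult(
        determinable=True,
        threshold=threshold,
        gap_size=gap_size,
        gap_p=gap_p,
        n_below=int(np.count_nonzero(region < threshold)),
        n_in_region=int(region.size),
        search_ceiling=max_ident,
    )


def declare_triads(
    scores: TriadScores,
    gap: GapResult,
    alpha: float = 0.01,
    comparison_sample_size: int = 30,
    *,
    seed: int = 0,
    n_mc: int = 10_000,
) -> list[TriadRecord]:
    """Two-level significance testing of the below-gap triads.

    If the gap itself is not significant (Dixon p > alpha) nothing is
    declared.  Otherwise each below-threshold triad is tested as a lower
    outlier against the ``comparison_sample_size`` smallest GD values above
    the gap (still below MaxIdent); it is declared true iff that Dixon
    p-value is <= alpha.  Self-overlap triads (offspring equal to a parent)
    are scored but never declared.
    """
    scores.declared[:] = False
    if not gap.determinable or not (gap.gap_p <= alpha):
        if gap.determinable:
            log.info("gap not significant (p=%.4g > alpha=%g); nothing declared", gap.gap_p, alpha)
        return []
    gd = scores.gd
    finite = np.isfinite(gd)
    region_mask = finite & (gd < gap.search_ceiling)
    above = np.sort(gd[region_mask & (gd > gap.threshold)])
    if above.size == 0:
        log.warning("no above-gap GD values available for comparison; nothing declared")
        return []
    if above.size < comparison_sample_size:
        log.warning(
            "only %d above-gap values available (requested %d); using all",
            above.size, comparison_sample_size,
        )
    sample = above[:comparison_sample_size]
    below = np.nonzero(region_mask & (gd < gap.threshold))
    for p, k in zip(*below):
        if scores.self_overlap[p, k]:
            continue
        test_set = np.concatenate(([gd[p, k]], sample))
        p_val = dixon_test(test_set, "min", seed=seed, n_mc=n_mc)
        scores.p_value[p, k] = p_val
        if p_val <= alpha:
            scores.declared[p, k] = True
    return scores.declared_records()


@dataclass
class TriadAnalysisResult:
    scores: TriadScores
    gap: GapResult
    declared: list[TriadRecord]


def run_triad_analysis(
    gm: GenotypeMatrix,
    *,
    max_ident: float = 0.1,
    alpha: float = 0.01,
    comparison_sample_size: int = 30,
    seed: int = 0,
    n_mc: int = 10_000,
) -> TriadAnalysisResult:
    """Enumerate, score, gap-test, and declare triads for a population."""
    space = enumerate_triads(gm.ids, gm.class_keys)
    scores = score_triads(gm, space)
    gap = find_gap(scores.flat_gd, max_ident, seed=seed, n_mc=n_mc)
    if gap.determinable:
        declared = declare_triads(
            scores, gap, alpha, comparison_sample_size, seed=seed, n_mc=n_mc
        )
    else:
        declared = []
    log.info(
        "triad analysis: %d triads scored, gap p=%.4g, %d declared",
        len(space), gap.gap_p if gap.determinable else float("nan"), len(declared),
    )
    return TriadAnalysisResult(scores=scores, gap=gap, declared=declared)
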