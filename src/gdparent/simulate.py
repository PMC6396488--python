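"""Pedigree simulator: synthetic populations with known parent-offspring trios.

The generator emulates a germplasm-collection validation design: a panmictic
pool of founders genotyped at bi-allelic SNPs, from which a few parent pairs
are drawn (without replacement, so full-sib confounders exist by
construction) to produce full-sib families of known pedigree.  Defaults
mirror the reference design — 62 founders plus 15 offspring in five
full-sib families of three, 1000 SNPs, ~36.5% expected heterozygosity
(allele frequencies uniform on [0.05, 0.95] under Hardy-Weinberg), 11.8%
missing data, and a 1% per-call genotyping-error rate.

The simulation operates directly on collapsed three-state calls, matching
what the analysis sees regardless of ploidy.  Mendelian transmission is
exact at the call level: two homozygous parents produce a deterministic
offspring state (so with error and missingness off, every true trio has a
Gower dissimilarity of exactly zero), while a heterozygous parent transmits
either allele with equal probability.  Genotyping error moves a call to an
adjacent state (homozygote <-> heterozygote; opposite homozygotes only via
double perturbation, which a single-step model never produces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .genotype import HET, HOM_A, HOM_B, MISSING
from .io import MISSING_TOKEN, RawGenotypeTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of a simulated population.

    ``allele_freq_range`` is the support of the per-locus uniform allele
    frequency; ``remove_parents`` lists ``(family_index, "mother"|"father")``
    pairs to drop from the output table (they remain in the truth, which is
    how absent-parent dyad scenarios are built).  With
    ``generational_labels`` adults are classed Pa and progeny Off instead of
    everyone being All.  The seed fixes all randomness.
    """

    n_founders: int = 62
    n_families: int = 5
    sibs_per_family: int = 3
    n_loci: int = 1000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.118
    error_rate: float = 0.01
    remove_parents: tuple[tuple[int, str], ...] = ()
    generational_labels: bool = False
    seed: int = 0

    def expected_heterozygosity(self) -> float:
        """E[2p(1-p)] for p uniform on the configured range."""
        lo, hi = self.allele_freq_range
        mean_p = (lo + hi) / 2.0
        mean_p2 = (hi - lo) ** 2 / 12.0 + mean_p**2
        return 2.0 * (mean_p - mean_p2)

    def validate(self) -> None:
        if min(self.n_founders, self.n_families, self.sibs_per_family, self.n_loci) < 1:
            raise ConfigurationError("counts must be positive")
        for name, rate in (("missing_rate", self.missing_rate), ("error_rate", self.error_rate)):
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {rate}")
        lo, hi = self.allele_freq_range
        if not 0 < lo <= hi < 1:
            raise ConfigurationError(f"allele_freq_range must satisfy 0 < lo <= hi < 1")
        if 2 * self.n_families > self.n_founders:
            raise ConfigurationError(
                f"{self.n_families} families need {2 * self.n_families} distinct "
                f"founder parents but only {self.n_founders} founders exist"
            )
        for fam, which in self.remove_parents:
            if not 0 <= fam < self.n_families:
                raise ConfigurationError(f"remove_parents references family {fam}")
            if which not in ("mother", "father"):
                raise ConfigurationError(
                    f"remove_parents role must be 'mother' or 'father', got {which!r}"
                )


@dataclass
class SimTruth:
    """Ground-truth pedigree: one (mother, father, offspring) trio per offspring."""

    trios: list[tuple[str, str, str]]
    removed_individuals: list[str] = field(default_factory=list)

    def truth_triad_set(self) -> set[tuple[frozenset, str]]:
        return {(frozenset((m, f)), k) for m, f, k in self.trios}

    def truth_dyad_set(self) -> set[tuple[str, str]]:
        """(parent, offspring) pairs for parents still present in the table."""
        removed = set(self.removed_individuals)
        return {
            (p, k)
            for m, f, k in self.trios
            for p in (m, f)
            if p not in removed
        }


def _transmit(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Allele (0 or 1 copy of the secondary allele) transmitted per locus."""
    out = np.where(states == HOM_B, 1, 0).astype(np.int8)
    het = states == HET
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def simulate_population(cfg: SimConfig) -> tuple[RawGenotypeTable, SimTruth]:
    """Generate a genotype table and its ground-truth pedigree.

    Founders are drawn locus-wise in Hardy-Weinberg proportions; offspring
    arise by Mendelian transmission at the call level; per-call error and
    missingness are applied afterwards.  The same seed yields a
    bit-identical table and truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.allele_freq_range
    L = cfg.n_loci
    freqs = rng.uniform(lo, hi, size=L)

    # Per-locus allele characters (two distinct bases; first is the primary
    # allele, i.e. the one at frequency p).
    base_idx = np.argsort(rng.random((L, 4)), axis=1)[:, :2]
    allele_pairs = _BASES[base_idx]

    # Founder states in HW proportions: P(HOM_A)=p^2, P(HET)=2pq, P(HOM_B)=q^2.
    u = rng.random((cfg.n_founders, L))
    t1 = freqs**2
    t2 = t1 + 2 * freqs * (1 - freqs)
    founders = np.full((cfg.n_founders, L), HOM_B, dtype=np.int8)
    founders[u < t2] = HET
    founders[u < t1] = HOM_A

    founder_ids = [f"F{i + 1:03d}" for i in range(cfg.n_founders)]
    parent_picks = rng.choice(cfg.n_founders, size=2 * cfg.n_families, replace=False)
    mothers = parent_picks[: cfg.n_families]
    fathers = parent_picks[cfg.n_families :]

    trios: list[tuple[str, str, str]] = []
    off_states = []
    off_ids = []
    for fam in range(cfg.n_families):
        mo, fa = founders[mothers[fam]], founders[fathers[fam]]
        for sib in range(cfg.sibs_per_family):
            child = (_transmit(mo, rng) + _transmit(fa, rng)).astype(np.int8)
            off_states.append(child)
            oid = f"Off{fam + 1}_{sib + 1}"
            off_ids.append(oid)
            trios.append((founder_ids[mothers[fam]], founder_ids[fathers[fam]], oid))

    true_states = np.vstack([founders] + [s[None, :] for s in off_states])
    all_ids = founder_ids + off_ids
    n_total = len(all_ids)

    # Genotyping error: adjacent-state perturbation with per-call probability.
    observed = true_states.copy()
    err = rng.random((n_total, L)) < cfg.error_rate
    hom = (true_states == HOM_A) | (true_states == HOM_B)
    het = true_states == HET
    observed[err & hom] = HET
    flip = err & het
    observed[flip] = rng.choice(
        np.array([HOM_A, HOM_B], dtype=np.int8), size=int(flip.sum())
    )
    # Missingness, independent of error.
    observed[rng.random((n_total, L)) < cfg.missing_rate] = MISSING

    removed_ids = []
    for fam, which in cfg.remove_parents:
        idx = mothers[fam] if which == "mother" else fathers[fam]
        removed_ids.append(founder_ids[idx])

    if cfg.generational_labels:
        keys = ["Pa"] * cfg.n_founders + ["Off"] * len(off_ids)
    else:
        keys = ["All"] * n_total

    rows = []
    removed = set(removed_ids)
    for i, ind_id in enumerate(all_ids):
        if ind_id in removed:
            continue
        tokens = []
        for j in range(L):
            s = observed[i, j]
            if s == MISSING:
                tokens.append(MISSING_TOKEN)
            else:
                a0, a1 = allele_pairs[j]
                if s == HOM_A:
                    tokens.append(f"{a0}/{a0}")
                elif s == HOM_B:
                    tokens.append(f"{a1}/{a1}")
                else:
                    tokens.append(f"{a0}/{a1}")
        rows.append((ind_id, keys[i], tokens))

    return (
        RawGenotypeTable(rows=rows),
        SimTruth(trios=trios, removed_individuals=removed_ids),
    )


def remove_one_parent_per_family(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimConfig:
    """Config variant dropping a randomly chosen parent from every family."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    removals = tuple(
        (fam, "mother" if rng.random() < 0.5 else "father")
        for fam in range(cfg.n_families)
    )
    return replace(cfg, remove_parents=removals)


def score_against_truth(declared, truth: SimTruth) -> tuple[int, int, float]:
    """Score declared triads or reported dyads against the simulated pedigree.

    Returns ``(type1, type2, accuracy)`` where type1 counts declared records
    absent from the truth, type2 counts truth relationships left undeclared,
    and accuracy = 100 * declared-true / (true + falsely-declared).
    """
    declared = list(declared)
    if declared and hasattr(declared[0], "mother_id"):
        declared_set = {
            (frozenset((r.mother_id, r.father_id)), r.offspring_id) for r in declared
        }
        truth_set = truth.truth_triad_set()
    elif declared and hasattr(declared[0], "parent_id"):
        declared_set = {(r.parent_id, r.offspring_id) for r in declared}
        truth_set = truth.truth_dyad_set()
    else:  # empty declaration list: compare against the triad truth
        declared_set = set()
        truth_set = truth.truth_triad_set()
    if not truth_set:
        raise ConfigurationError("truth is empty; nothing to score against")
    true_declared = len(declared_set & truth_set)
    type1 = len(declared_set - truth_set)
    type2 = len(truth_set - declared_set)
    accuracy = 100.0 * true_declared / (len(truth_set) + type1)
    return type1, type2, accuracy


def write_truth(truth: SimTruth, path) -> None:
    """Tab-delimited truth file: mother, father, offspring (one trio per line)."""
    with open(path, "w") as handle:
        for m, f, k in truth.trios:
            handle.write(f"{m}\t{f}\t{k}\n")
        for r in truth.removed_individuals:
            handle.write(f"# removed\t{r}\n")
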