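"""Three-state genotype encoding, expected-progeny construction, and the
Gower dissimilarity between genotype-state vectors.

Genotypes at a bi-allelic SNP are collapsed to three states relative to the
locus's (lexicographically ordered) allele pair — primary homozygote,
heterozygote, secondary homozygote — plus a missing state.  The collapse is
ploidy-agnostic: any heterozygous dosage maps to the single heterozygous
state, so tetraploid (or higher) data are handled without a dosage model.

The Gower dissimilarity between two state vectors is

    GD = 1 - (sum_l s_l * w_l) / (sum_l w_l)

with per-locus similarity s_l = 1 when the states are identical, 0.5 when
they differ by one allele (heterozygote vs either homozygote), 0 for
opposite homozygotes, and weight w_l = 1 only when both calls are present.
GD ranges from 0 (identity) to 1 (opposite homozygotes everywhere); loci
missing in either vector carry no weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NoUsableLociError

log = logging.getLogger(__name__)

# State codes.  The numeric spacing is meaningful: |a - b| / 2 equals the
# per-locus dissimilarity 1 - s for any pair of non-missing states.
MISSING: int = -1
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2

MISSING_TOKEN = "-/-"


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of three-state genotype calls.

    ``states`` is an int8 array with values in {-1, 0, 1, 2} (missing,
    primary homozygote, heterozygote, secondary homozygote).  ``alleles``
    holds the ordered allele pair per locus; monomorphic loci carry the
    observed allele twice.
    """

    ids: list[str]
    class_keys: list[str]
    states: np.ndarray
    alleles: list[tuple[str, str]]
    locus_names: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.ids), len(self.alleles)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.alleles)} loci"
            )
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.alleles)

    def index_of(self, ind_id: str) -> int:
        try:
            return self._index[ind_id]
        except KeyError:
            raise KeyError(f"unknown individual ID {ind_id!r}") from None

    def row(self, ind_id: str) -> np.ndarray:
        return self.states[self.index_of(ind_id)]


@dataclass
class ExpectedProgeny:
    """Inferable genotype of any offspring of a given parent pair.

    Defined only at loci where both parents carry non-missing homozygous
    calls: two primary homozygotes yield a primary homozygote, two secondary
    homozygotes a secondary homozygote, and opposite homozygotes force a
    heterozygous offspring.  Everywhere else the state is missing (zero
    weight in the Gower dissimilarity).
    """

    mother_id: str
    father_id: str
    states: np.ndarray


def encode(table, *, drop_monomorphic: bool = False) -> GenotypeMatrix:
    """Encode a :class:`~gdparent.io.RawGenotypeTable` into three-state calls.

    Each locus's allele pair is determined from all genotype tokens observed
    at that locus, ordered lexicographically.  Loci with more than two
    observed alleles or with no non-missing call are dropped with a logged
    warning; with ``drop_monomorphic`` loci showing a single allele are
    dropped as well (by default they are retained — they always match and
    only dilute comparisons).
    """
    rows = table.rows
    if not rows:
        raise NoUsableLociError("empty genotype table")
    n_ind = len(rows)
    n_loci = len(rows[0][2])
    kept_states: list[np.ndarray] = []
    kept_alleles: list[tuple[str, str]] = []
    kept_names: list[str] = []
    n_multi = n_empty = n_mono = 0
    width = max(4, len(str(n_loci)))
    for j in range(n_loci):
        tokens = [row[2][j] for row in rows]
        alleles: set[str] = set()
        for tok in tokens:
            if tok != MISSING_TOKEN:
                a, b = tok.split("/")
                alleles.add(a)
                alleles.add(b)
        name = f"L{j + 1:0{width}d}"
        if len(alleles) == 0:
            n_empty += 1
            log.warning("locus %s dropped: no non-missing calls", name)
            continue
        if len(alleles) > 2:
            n_multi += 1
            log.warning(
                "locus %s dropped: %d observed alleles (%s)",
                name, len(alleles), ",".join(sorted(alleles)),
            )
            continue
        if len(alleles) == 1:
            n_mono += 1
            if drop_monomorphic:
                continue
            a0 = a1 = next(iter(alleles))
        else:
            a0, a1 = sorted(alleles)
        col = np.full(n_ind, MISSING, dtype=np.int8)
        for i, tok in enumerate(tokens):
            if tok == MISSING_TOKEN:
                continue
            x, y = tok.split("/")
            if x == y:
                col[i] = HOM_A if x == a0 else HOM_B
            else:
                col[i] = HET
        kept_states.append(col)
        kept_alleles.append((a0, a1))
        kept_names.append(name)
    if not kept_states:
        raise NoUsableLociError(
            "no usable loci after encoding "
            f"({n_multi} multi-allelic, {n_empty} all-missing)"
        )
    dropped = n_multi + n_empty + (n_mono if drop_monomorphic else 0)
    if dropped:
        log.warning("dropped %d of %d loci during encoding", dropped, n_loci)
    states = np.column_stack(kept_states)
    return GenotypeMatrix(
        ids=[r[0] for r in rows],
        class_keys=[r[1] for r in rows],
        states=states,
        alleles=kept_alleles,
        locus_names=kept_names,
    )


def expected_progeny_states(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """Vector (or matrix) form of the expected-progeny construction."""
    hom_i = (gi == HOM_A) | (gi == HOM_B)
    hom_j = (gj == HOM_A) | (gj == HOM_B)
    ep = np.where(hom_i & hom_j, (gi + gj) // 2, MISSING)
    return ep.astype(np.int8)


def expected_progeny(gm: GenotypeMatrix, mother: str, father: str) -> ExpectedProgeny:
    """Construct the expected progeny of a parent pair.

    Uses only markers homozygous (and called) in both parents; all other
    loci are missing in the result.
    """
    gi = gm.row(mother)
    gj = gm.row(father)
    return ExpectedProgeny(
        mother_id=mother,
        father_id=father,
        states=expected_progeny_states(gi, gj),
    )


def gower_dissimilarity(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Gower dissimilarity between two genotype-state vectors.

    Returns ``(gd, usable_loci)``.  When no locus is comparable (every
    weight zero) the dissimilarity is undefined and returned as ``nan`` —
    never silently 0 — with ``usable_loci == 0``.
    """
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"state vectors must be 1-D and equal length, got {x.shape} vs {y.shape}"
        )
    w = (x != MISSING) & (y != MISSING)
    usable = int(w.sum())
    if usable == 0:
        return float("nan"), 0
    diff = np.abs(x[w].astype(np.int16) - y[w].astype(np.int16))
    gd = float(diff.sum()) / 2.0 / usable
    return gd, usable


def gower_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Gower dissimilarities between two stacks of state vectors.

    ``A`` is (p x L), ``B`` is (k x L); returns ``(gd, usable)`` of shape
    (p x k).  Computed through one-hot indicator matrix products so the
    whole comparison runs as a handful of BLAS calls; entries with zero
    comparable loci are ``nan``.
    """
    A = np.asarray(A, dtype=np.int8)
    B = np.asarray(B, dtype=np.int8)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError(f"incompatible shapes {A.shape} and {B.shape}")
    a0 = (A == HOM_A).astype(np.float32)
    a1 = (A == HET).astype(np.float32)
    a2 = (A == HOM_B).astype(np.float32)
    b0 = (B == HOM_A).astype(np.float32)
    b1 = (B == HET).astype(np.float32)
    b2 = (B == HOM_B).astype(np.float32)
    same = a0 @ b0.T + a1 @ b1.T + a2 @ b2.T
    half = a1 @ (b0 + b2).T + (a0 + a2) @ b1.T
    weight = (a0 + a1 + a2) @ (b0 + b1 + b2).T
    with np.errstate(divide="ignore", invalid="ignore"):
        gd = 1.0 - (same + 0.5 * half) / weight
    gd = gd.astype(np.float64)
    gd[weight == 0] = np.nan
    return gd, weight.astype(np.int64)
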