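"""Single-parent (dyad) inference via the two-stage GDM/GDCV procedure.

When one parent of an offspring is absent from the genotyped population the
triad analysis is inconclusive, but a likely single parent can still be
identified.  For offspring k and candidate parent i:

* stage 1 — GDM, the mean Gower dissimilarity between k and the expected
  progenies of i with every possible co-parent j.  A true parent's EPs are
  (statistically) k's siblings, and an individual is closer to a population
  of its siblings than to random individuals, so the true parent's GDM is a
  low outlier.  Each offspring's GDM set is treated as a normal sample and
  candidates whose normal score falls below the confidence bound are
  flagged.

* stage 2 — GDCV, the standard deviation of those per-co-parent GDs
  re-expressed in units of GD_i|k, the Gower dissimilarity between parent i
  and offspring k over their pairwise-homozygous loci (the analysis uses
  only pairwise-homozygous loci throughout; at such loci a true parent and
  its offspring are identical up to genotyping error, so the denominator is
  near zero for real parents and ~the population homozygous mismatch rate
  otherwise).  Flagged pairs whose GDCV normal score exceeds the upper
  confidence bound are reported; this separates true parents (tiny
  denominator, huge GDCV) from full-sib confounders flagged at stage 1.

The reported cumulative p-value is the product of the stage-1 lower-tail
and stage-2 upper-tail normal probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .genotype import (
    HOM_A,
    HOM_B,
    MISSING,
    GenotypeMatrix,
    expected_progeny,
    expected_progeny_states,
    gower_dissimilarity,
    gower_matrix,
)

log = logging.getLogger(__name__)


@dataclass(slots=True)
class DyadRecord:
    parent_id: str
    offspring_id: str
    gdm: float
    gdm_z: float
    sigma_gd: float
    gd_ik: float
    gdcv: float
    gdcv_z: float
    cumulative_p: float
    stage1_flag: bool
    stage2_flag: bool


def _hom_masked(states: np.ndarray) -> np.ndarray:
    """Copy of a state array with heterozygous calls set to missing."""
    return np.where(
        (states == HOM_A) | (states == HOM_B), states, MISSING
    ).astype(np.int8)


def homozygous_gd(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Gower dissimilarity restricted to loci homozygous in both vectors.

    At such loci the two calls are either identical (s=1) or opposite
    homozygotes (s=0); a parent-offspring pair mismatches only through
    genotyping error, which is what makes this the discriminating
    denominator of the GDCV statistic.
    """
    return gower_dissimilarity(_hom_masked(np.asarray(x)), _hom_masked(np.asarray(y)))


def compute_gdm(
    gm: GenotypeMatrix,
    parent: str,
    offspring: str,
    coparents: list[str],
) -> tuple[float, np.ndarray]:
    """Mean GD between an offspring and the expected progenies of one parent.

    Returns ``(gdm, per_coparent_gds)``; undefined per-co-parent GDs (no
    comparable loci) are dropped from the mean with a warning.
    """
    if not coparents:
        raise ConfigurationError("empty co-parent set")
    if parent in coparents:
        raise ConfigurationError("parent must not appear in its own co-parent set")
    off = gm.row(offspring)
    gds = np.empty(len(coparents))
    for idx, j in enumerate(coparents):
        ep = expected_progeny(gm, parent, j)
        gds[idx], _ = gower_dissimilarity(ep.states, off)
    n_undef = int(np.isnan(gds).sum())
    if n_undef:
        log.warning(
            "%d of %d co-parent GDs undefined for (%s, %s); dropped from mean",
            n_undef, len(coparents), parent, offspring,
        )
    gdm = float(np.nanmean(gds)) if n_undef < len(coparents) else float("nan")
    return gdm, gds


def compute_gdcv(per_coparent_gds: np.ndarray, gd_ik: float) -> tuple[float, float]:
    """Sample standard deviation of the per-co-parent GDs, over GD_i|k.

    The standard deviation uses divisor j - 1.  With fewer than two defined
    values, or a non-positive denominator, the result is undefined (nan)
    and the pair is excluded by the caller.
    """
    gds = np.asarray(per_coparent_gds, dtype=np.float64)
    gds = gds[np.isfinite(gds)]
    if gds.size < 2:
        return float("nan"), float("nan")
    sigma = float(np.std(gds, ddof=1))
    if not (gd_ik > 0):
        log.warning("GD_i|k = %s; GDCV undefined, pair excluded", gd_ik)
        return sigma, float("nan")
    return sigma, sigma / gd_ik


def _zscores(values: np.ndarray) -> np.ndarray:
    """Normal scores of a set: (x - mean) / sd, sample sd (ddof=1)."""
    finite = np.isfinite(values)
    mu = np.mean(values[finite]) if finite.any() else np.nan
    sd = np.std(values[finite], ddof=1) if finite.sum() > 1 else 0.0
    out = np.full_like(values, np.nan, dtype=np.float64)
    if sd > 0:
        out[finite] = (values[finite] - mu) / sd
    return out


def run_dyad(
    gm: GenotypeMatrix,
    offspring_set: list[str],
    parent_candidates: list[str],
    confidence: float = 0.99,
) -> list[DyadRecord]:
    """Two-stage dyad test for each offspring against each candidate parent.

    Returns one record per (candidate parent, offspring) pair with both
    test statistics, their normal scores, and the stage flags; pairs with
    both flags set are the reported likely parent-offspring dyads.  The
    stage-1 (lower) and stage-2 (upper) bounds are the one-sided normal
    quantiles at the given confidence level.  Candidates at zero plain
    Gower distance from the offspring are excluded as duplicate samples.
    """
    if not 0 < confidence < 1:
        raise ConfigurationError(f"confidence must be in (0,1), got {confidence}")
    if len(parent_candidates) < 3:
        raise ConfigurationError(
            f"dyad analysis needs >= 3 candidate parents for meaningful "
            f"normal scores, got {len(parent_candidates)}"
        )
    lower_bound = stats.norm.ppf(1 - confidence)
    upper_bound = stats.norm.ppf(confidence)

    par_idx = np.array([gm.index_of(i) for i in parent_candidates], dtype=np.intp)
    off_idx = np.array([gm.index_of(k) for k in offspring_set], dtype=np.intp)
    m = len(parent_candidates)

    # GD between every unordered candidate-parent pair's EP and every offspring,
    # computed once; per-offspring co-parent sets are views into this grid.
    ia, ib = np.triu_indices(m, k=1)
    ep = expected_progeny_states(gm.states[par_idx[ia]], gm.states[par_idx[ib]])
    pair_gd, _ = gower_matrix(ep, gm.states[off_idx])
    # Plain parent-vs-offspring GD (duplicate-sample screen) and the
    # pairwise-homozygous GD used as the GDCV denominator.
    plain_gd, _ = gower_matrix(gm.states[par_idx], gm.states[off_idx])
    hom_par = _hom_masked(gm.states[par_idx])
    hom_off = _hom_masked(gm.states[off_idx])
    hom_gd, hom_n = gower_matrix(hom_par, hom_off)
    # Half-a-mismatch floor: with no mismatching pairwise-homozygous locus
    # observed the dissimilarity is below the panel's resolution, not zero.
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(hom_n > 0, np.maximum(hom_gd, 0.5 / np.maximum(hom_n, 1)), np.nan)

    records: list[DyadRecord] = []
    grid = np.full((m, m), np.nan)
    for kpos, k in enumerate(offspring_set):
        grid[:] = np.nan
        grid[ia, ib] = pair_gd[:, kpos]
        grid[ib, ia] = pair_gd[:, kpos]
        if k in parent_candidates:
            kp = parent_candidates.index(k)
            grid[kp, :] = np.nan
            grid[:, kp] = np.nan
        gdm = np.full(m, np.nan)
        sigma = np.full(m, np.nan)
        gdcv = np.full(m, np.nan)
        for ipos in range(m):
            row = grid[ipos]
            vals = row[np.isfinite(row)]
            if parent_candidates[ipos] == k or vals.size == 0:
                continue
            if plain_gd[ipos, kpos] == 0:
                log.warning(
                    "candidate %s is at zero Gower distance from offspring %s "
                    "(duplicate sample?); pair excluded", parent_candidates[ipos], k,
                )
                continue
            gdm[ipos] = vals.mean()
            if vals.size >= 2 and np.isfinite(denom[ipos, kpos]):
                sigma[ipos] = np.std(vals, ddof=1)
                gdcv[ipos] = sigma[ipos] / denom[ipos, kpos]
        gdm_z = _zscores(gdm)
        gdcv_z = _zscores(gdcv)
        if not np.isfinite(gdm_z).any():
            log.warning("degenerate GDM set for offspring %s; no pairs flagged", k)
        for ipos, i in enumerate(parent_candidates):
            if i == k or not np.isfinite(gdm[ipos]):
                continue
            z1 = gdm_z[ipos]
            z2 = gdcv_z[ipos]
            s1 = bool(np.isfinite(z1) and z1 < lower_bound)
            s2 = bool(s1 and np.isfinite(z2) and z2 > upper_bound)
            cum_p = float("nan")
            if np.isfinite(z1) and np.isfinite(z2):
                cum_p = float(stats.norm.cdf(z1) * stats.norm.sf(z2))
            records.append(
                DyadRecord(
                    parent_id=i,
                    offspring_id=k,
                    gdm=float(gdm[ipos]),
                    gdm_z=float(z1) if np.isfinite(z1) else float("nan"),
                    sigma_gd=float(sigma[ipos]) if np.isfinite(sigma[ipos]) else float("nan"),
                    gd_ik=float(hom_gd[ipos, kpos]),
                    gdcv=float(gdcv[ipos]) if np.isfinite(gdcv[ipos]) else float("nan"),
                    gdcv_z=float(z2) if np.isfinite(z2) else float("nan"),
                    cumulative_p=cum_p,
                    stage1_flag=s1,
                    stage2_flag=s2,
                )
            )
    n_rep = sum(1 for r in records if r.stage1_flag and r.stage2_flag)
    log.info(
        "dyad analysis: %d offspring x %d candidates, %d pairs reported",
        len(offspring_set), m, n_rep,
    )
    return records


def reported_pairs(records: list[DyadRecord]) -> list[DyadRecord]:
    """Pairs passing both stages — the likely parent-offspring dyads."""
    return [r for r in records if r.stage1_flag and r.stage2_flag]
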