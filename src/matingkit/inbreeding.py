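"""Inbreeding coefficients across generations and the purging statistic.

Three quantities summarise a lineage's inbreeding history:

* ``F`` — the heterozygosity-deficit inbreeding coefficient of a genotyped
  cohort, ``F = 1 - H_obs / H_exp`` with the expected heterozygosity given
  the small-sample correction ``(2n/(2n-1)) * (1 - sum p^2)``; loci are
  combined as a ratio of sums (sum of observed over sum of expected
  heterozygosities) which is far more stable than averaging per-locus
  ratios when families contribute few individuals.
* ``Fe`` — the inbreeding coefficient the progeny cohort would reach at
  equilibrium under a constant multilocus outcrossing rate ``tm``,
  ``Fe = (1 - tm) / (1 + tm)``.
* ``Fe - F`` — the gap between the equilibrium expectation and the realised
  adult value.  Under sustained mixed mating with no selection the two
  coincide; a positive gap indicates selection against inbred individuals
  (purging) between zygote and adult.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING

__all__ = [
    "InbreedingSummary",
    "inbreeding_coefficient",
    "equilibrium_inbreeding",
    "purging_statistic",
]


class UndefinedInbreedingError(ValueError):
    """F cannot be computed (e.g., every locus monomorphic)."""


@dataclass
class InbreedingSummary:
    """F, Fe and their difference for one scope (family or population)."""

    scope_id: str
    F: float
    Fe: float
    n_loci_used: int

    @property
    def diff(self) -> float:
        return purging_statistic(self.Fe, self.F)


def inbreeding_coefficient(genotypes: np.ndarray, min_individuals: int = 2) -> tuple[float, int]:
    """Heterozygosity-deficit F from a genotype array ``(n, n_loci, 2)``.

    Returns ``(F, n_loci_used)``.  Monomorphic loci (and loci with fewer
    than ``min_individuals`` genotyped individuals) carry no information
    about heterozygosity deficit and are excluded; the count of loci that
    did contribute is returned alongside.

    Raises
    ------
    UndefinedInbreedingError
        When no polymorphic locus remains.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 3 or genotypes.shape[2] != 2:
        raise ValueError("genotypes must have shape (n, n_loci, 2)")
    sum_hobs = 0.0
    sum_hexp = 0.0
    n_used = 0
    for j in range(genotypes.shape[1]):
        g = genotypes[:, j, :]
        typed = g[g[:, 0] != MISSING]
        n = typed.shape[0]
        if n < min_individuals:
            continue
        alleles, counts = np.unique(typed.ravel(), return_counts=True)
        if alleles.size < 2:
            continue  # monomorphic
        p = counts / counts.sum()
        hexp = (2 * n / (2 * n - 1)) * (1.0 - np.square(p).sum())
        hobs = float(np.mean(typed[:, 0] != typed[:, 1]))
        sum_hobs += n * hobs
        sum_hexp += n * hexp
        n_used += 1
    if n_used == 0 or sum_hexp == 0.0:
        raise UndefinedInbreedingError("no polymorphic locus with enough individuals")
    return 1.0 - sum_hobs / sum_hexp, n_used


def equilibrium_inbreeding(tm: float | np.ndarray) -> float | np.ndarray:
    """Equilibrium inbreeding Fe = (1 - tm) / (1 + tm) for tm in [0, 1]."""
    tm_arr = np.asarray(tm, dtype=float)
    if np.any((tm_arr < 0) | (tm_arr > 1) | ~np.isfinite(tm_arr)):
        raise ValueError("tm must lie in [0, 1]")
    fe = (1.0 - tm_arr) / (1.0 + tm_arr)
    return float(fe) if np.isscalar(tm) or tm_arr.ndim == 0 else fe


def purging_statistic(Fe: float | np.ndarray, F: float | np.ndarray) -> float | np.ndarray:
    """The purging gap Fe - F (positive when inbred progeny were removed)."""
    Fe_arr, F_arr = np.asarray(Fe, dtype=float), np.asarray(F, dtype=float)
    if not (np.all(np.isfinite(Fe_arr)) and np.all(np.isfinite(F_arr))):
        raise ValueError("Fe and F must be finite")
    d = Fe_arr - F_arr
    return float(d) if d.ndim == 0 else d
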