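"""Mixed-mating model estimation from progeny arrays.

Under the mixed-mating model every offspring in a family is produced by
self-fertilisation of the mother with probability ``s`` or by outcrossing to
a shared population pollen pool with probability ``tm = 1 - s``.  Given the
maternal multilocus genotype and pollen-pool allele frequencies, the
per-offspring likelihood is a two-component mixture

    P(g_i | s) = s * L_self,i + (1 - s) * L_out,i

with ``L_self`` the Mendelian selfing kernel and ``L_out`` the
maternal-gamete x pollen-pool kernel, both multiplied across unlinked loci
(missing loci dropped).  ``s`` is estimated per family by
Expectation-Maximization: the E-step computes the posterior probability that
each offspring is selfed, the M-step sets ``s`` to their mean.  The EM map
monotonically increases the log-likelihood and for this one-parameter
mixture converges to the MLE.

The public surface follows the Model/Results idiom: build a
:class:`MixedMatingModel` from a :class:`~matingkit.io.ProgenyArray` (plus a
:class:`PollenPool`), call :meth:`~MixedMatingModel.fit`, and read the
estimates, bootstrap uncertainty and diagnostics off the returned
:class:`MixedMatingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import MISSING, ProgenyArray

__all__ = [
    "PollenPool",
    "MixedMatingModel",
    "MixedMatingResults",
    "self_offspring_prob",
    "outcross_offspring_prob",
    "build_pollen_pool",
    "infer_maternal_genotype",
    "estimate_population",
]


class EstimationError(RuntimeError):
    """Family cannot be estimated (e.g., no informative offspring)."""


# probability assigned, during maternal-genotype scoring, to an offspring a
# candidate mother cannot have produced (genotyping error / null allele)
_MISMATCH_PENALTY = 1e-6


# ---------------------------------------------------------------------------
# single-locus transmission kernels
# ---------------------------------------------------------------------------


def self_offspring_prob(offspring: tuple[int, int], mother: tuple[int, int]) -> float:
    """Probability of an unordered offspring genotype under selfing.

    Both gametes are independent Mendelian draws from the mother (1/2 each
    allele for a heterozygote).  Returns 0 for genotypes impossible under
    selfing; raises on missing input.
    """
    if MISSING in offspring or MISSING in mother:
        raise ValueError("selfing kernel requires non-missing genotypes")
    m1, m2 = mother
    o1, o2 = offspring
    p = 0.0
    for g1 in (m1, m2):
        for g2 in (m1, m2):
            if (g1, g2) == (o1, o2) or (g1, g2) == (o2, o1):
                p += 0.25
    return p


def outcross_offspring_prob(
    offspring: tuple[int, int],
    mother: tuple[int, int],
    pollen: dict[int, float],
) -> float:
    """Probability of an unordered offspring genotype under outcrossing.

    One gamete is Mendelian from the mother, the other is drawn from the
    pollen-pool allele frequencies.  Returns 0 when the offspring shares no
    allele with the mother.
    """
    if MISSING in offspring or MISSING in mother:
        raise ValueError("outcross kernel requires non-missing genotypes")
    m1, m2 = mother
    o1, o2 = offspring
    maternal = {m1: 0.0, m2: 0.0}
    maternal[m1] += 0.5
    maternal[m2] += 0.5
    if o1 == o2:
        return maternal.get(o1, 0.0) * pollen.get(o1, 0.0)
    return maternal.get(o1, 0.0) * pollen.get(o2, 0.0) + maternal.get(o2, 0.0) * pollen.get(
        o1, 0.0
    )


# ---------------------------------------------------------------------------
# pollen pool
# ---------------------------------------------------------------------------


@dataclass
class PollenPool:
    """Per-locus outcross allele frequencies (the paternal gamete model).

    Frequencies are strictly positive for every allele observed anywhere in
    the population (additive smoothing guarantees this), so an offspring
    carrying a maternal allele always has positive outcross likelihood.
    """

    locus_names: list[str]
    freqs: list[dict[int, float]]

    def __post_init__(self) -> None:
        for name, f in zip(self.locus_names, self.freqs):
            if not f:
                continue  # locus with no population data (failed amplification)
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"locus {name}: pollen frequencies sum to {total}, not 1")
            if any(v <= 0 for v in f.values()):
                raise ValueError(f"locus {name}: non-positive pollen frequency")


def build_pollen_pool(
    arrays: Sequence[ProgenyArray],
    maternal_genotypes: Sequence[np.ndarray],
    smoothing: float = 0.5,
) -> PollenPool:
    """Estimate population pollen-pool allele frequencies.

    Allele counts are pooled from the (provided or inferred) maternal
    genotypes across all families, then ``smoothing`` pseudo-counts are
    added for every distinct allele observed in any mother *or* offspring,
    and the counts renormalised.  The smoothing mass is what keeps every
    offspring allele scorable under outcrossing.
    """
    if not arrays:
        raise ValueError("need at least one progeny array")
    locus_names = arrays[0].locus_names
    n_loci = len(locus_names)
    counts: list[dict[int, float]] = [dict() for _ in range(n_loci)]
    observed: list[set[int]] = [set() for _ in range(n_loci)]
    for arr in arrays:
        for j in range(n_loci):
            alleles = arr.offspring[:, j, :].ravel()
            observed[j].update(int(a) for a in alleles if a != MISSING)
    for geno in maternal_genotypes:
        if geno is None:
            continue
        for j in range(n_loci):
            for a in geno[j]:
                a = int(a)
                if a != MISSING:
                    counts[j][a] = counts[j].get(a, 0.0) + 1.0
                    observed[j].add(a)
    freqs = []
    for j in range(n_loci):
        c = dict(counts[j])
        for a in observed[j]:
            c[a] = c.get(a, 0.0) + smoothing
        total = sum(c.values())
        freqs.append({a: v / total for a, v in sorted(c.items())} if total else {})
    return PollenPool(locus_names=list(locus_names), freqs=freqs)


# ---------------------------------------------------------------------------
# maternal genotype inference
# ---------------------------------------------------------------------------


def infer_maternal_genotype(
    array: ProgenyArray,
    pollen: PollenPool,
    ref_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood maternal genotype per locus from the progeny array.

    Candidates at each locus are all unordered pairs of alleles observed in
    the family or carried by the population pollen pool.  Each candidate is
    scored by the mixed-mating likelihood of the whole offspring set at the
    fixed reference selfing rate ``ref_s`` (neutral between kernels; using
    the family's own estimate would be circular) times a Hardy-Weinberg
    prior from the pollen frequencies.  Ties break toward the higher prior,
    then lexicographic allele order.

    Returns ``(genotype, posterior_weight)`` where the weight is the
    normalised posterior probability of the chosen genotype among the
    candidates (1.0 when a provided maternal genotype bypasses inference).
    If the array already carries a maternal genotype it is used verbatim.

    Loci with no genotyped offspring come back missing with weight ``nan``.
    """
    n_loci = array.n_loci
    if array.maternal is not None:
        return array.maternal.copy(), np.ones(n_loci)
    geno = np.zeros((n_loci, 2), dtype=np.int64)
    weight = np.full(n_loci, np.nan)
    for j in range(n_loci):
        obs = array.offspring[:, j, :]
        typed = obs[obs[:, 0] != MISSING]
        if typed.size == 0:
            continue
        fam_alleles = {int(a) for a in typed.ravel()}
        cand_alleles = sorted(fam_alleles | set(pollen.freqs[j].keys()))
        pf = pollen.freqs[j]
        candidates: list[tuple[tuple[int, int], float, float]] = []
        for a1, a2 in combinations_with_replacement(cand_alleles, 2):
            prior = pf.get(a1, 0.0) ** 2 if a1 == a2 else 2 * pf.get(a1, 0.0) * pf.get(a2, 0.0)
            if prior <= 0.0:
                continue
            logl = np.log(prior)
            for o1, o2 in typed:
                ps = self_offspring_prob((int(o1), int(o2)), (a1, a2))
                po = outcross_offspring_prob((int(o1), int(o2)), (a1, a2), pf)
                mix = ref_s * ps + (1 - ref_s) * po
                # an offspring this candidate cannot produce is scored as a
                # rare genotyping-error event, not dropped — skipping would
                # hand impossible candidates an artificially short product
                logl += np.log(mix) if mix > 0.0 else np.log(_MISMATCH_PENALTY)
            candidates.append(((a1, a2), logl, prior))
        if not candidates:
            continue
        # best score; ties toward higher prior, then lexicographic alleles
        best = min(candidates, key=lambda c: (-c[1], -c[2], c[0]))
        geno[j] = best[0]
        logs = np.array([c[1] for c in candidates])
        norm = np.exp(logs - logs.max())
        weight[j] = float(np.exp(best[1] - logs.max()) / norm.sum())
    return geno, weight


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class MixedMatingModel:
    """Per-family mixed-mating likelihood, fitted by EM.

    Parameters
    ----------
    array : ProgenyArray
        The family's offspring genotypes (and, optionally, the maternal
        genotype; otherwise it is inferred at construction).
    pollen : PollenPool
        Population outcross allele frequencies, held fixed during the fit.
    maternal : ndarray, optional
        Override the maternal multilocus genotype.

    Notes
    -----
    Per-offspring multilocus kernels are pre-computed once; every EM
    iteration (and every bootstrap replicate, which only resamples
    offspring) then costs a handful of vector operations.  An offspring
    locus where both kernels are zero — the offspring carries no maternal
    allele, a genotyping error or unmodelled null allele — is demoted to
    missing for that offspring and counted in ``n_mismatch_loci``.
    """

    def __init__(
        self,
        array: ProgenyArray,
        pollen: PollenPool,
        maternal: np.ndarray | None = None,
    ) -> None:
        self.array = array
        self.pollen = pollen
        if maternal is not None:
            self.maternal = np.asarray(maternal, dtype=np.int64)
        else:
            self.maternal, _ = infer_maternal_genotype(array, pollen)
        self.n_mismatch_loci = 0
        self._prepare()

    def _prepare(self) -> None:
        arr, pollen = self.array, self.pollen
        n, L = arr.n_offspring, arr.n_loci
        log_ls = np.zeros(n)
        log_lo = np.zeros(n)
        informative = np.zeros(n, dtype=bool)
        for i in range(n):
            for j in range(L):
                o = arr.offspring[i, j]
                if o[0] == MISSING:
                    continue
                m = self.maternal[j]
                if m[0] == MISSING:
                    continue
                ps = self_offspring_prob((int(o[0]), int(o[1])), (int(m[0]), int(m[1])))
                po = outcross_offspring_prob(
                    (int(o[0]), int(o[1])), (int(m[0]), int(m[1])), pollen.freqs[j]
                )
                if ps == 0.0 and po == 0.0:
                    self.n_mismatch_loci += 1
                    continue
                log_ls[i] += np.log(ps) if ps > 0 else -np.inf
                log_lo[i] += np.log(po) if po > 0 else -np.inf
                informative[i] = True
        keep = informative
        self.n_offspring_used = int(keep.sum())
        if self.n_offspring_used == 0:
            raise EstimationError(
                f"family {arr.family_id}: no offspring with an informative locus"
            )
        # exp is safe: per-locus kernels are >= smoothing-floor probabilities
        self.L_self = np.exp(log_ls[keep])
        self.L_out = np.exp(log_lo[keep])

    # -- likelihood ---------------------------------------------------------

    def loglike(self, s: float, idx: np.ndarray | None = None) -> float:
        """Observed-data log-likelihood at selfing rate ``s``."""
        ls = self.L_self if idx is None else self.L_self[idx]
        lo = self.L_out if idx is None else self.L_out[idx]
        return self._loglike_arrays(s, ls, lo)

    @staticmethod
    def _loglike_arrays(s: float, ls: np.ndarray, lo: np.ndarray) -> float:
        mix = s * ls + (1.0 - s) * lo
        if np.any(mix <= 0.0):
            return -np.inf
        return float(np.log(mix).sum())

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        s_init: float = 0.5,
        tol: float = 1e-8,
        max_iter: int = 1000,
        _idx: np.ndarray | None = None,
    ) -> "MixedMatingResults":
        """Run EM to the MLE of ``s`` and return a results object.

        ``s`` is clamped to ``[1e-9, 1 - 1e-9]`` during iteration and
        snapped to an exact boundary when within 1e-6 of it at convergence,
        so fully selfing and fully outcrossing families report exact 1/0.
        Convergence is declared on the log-likelihood change (< ``tol``).
        """
        ls = self.L_self if _idx is None else self.L_self[_idx]
        lo = self.L_out if _idx is None else self.L_out[_idx]
        if ls.size == 0:
            raise EstimationError(f"family {self.array.family_id}: empty resample")
        eps = 1e-9
        s = float(np.clip(s_init, eps, 1 - eps))
        prev = -np.inf
        converged = False
        n_iter = 0
        ll_path = []
        for n_iter in range(1, max_iter + 1):
            num = s * ls
            denom = num + (1.0 - s) * lo
            ll = float(np.log(denom).sum())
            ll_path.append(ll)
            z = num / denom
            s_new = float(np.clip(z.mean(), eps, 1 - eps))
            if np.isfinite(prev) and abs(ll - prev) < tol:
                converged = True
                break
            prev = ll
            s = s_new
        # terminal EM convergence is sublinear where the likelihood is
        # flat; a bounded 1-D polish of the same objective sharpens the
        # last digits (kept only when it strictly improves the fit)
        polish = minimize_scalar(
            lambda v: -self._loglike_arrays(v, ls, lo),
            bounds=(eps, 1 - eps),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if polish.success and -polish.fun > self._loglike_arrays(s, ls, lo) + 1e-12:
            s = float(polish.x)
        if s < 1e-6:
            s = 0.0
        elif s > 1 - 1e-6:
            s = 1.0
        ll_final = self.loglike(s, _idx)
        # curvature of the profile log-likelihood; ~0 means the two kernels
        # coincide and s is not identifiable from this family
        h = 1e-5
        s_mid = float(np.clip(s, h, 1 - h))
        curv = (
            self.loglike(s_mid + h, _idx)
            - 2 * self.loglike(s_mid, _idx)
            + self.loglike(s_mid - h, _idx)
        ) / h**2
        return MixedMatingResults(
            model=self,
            family_id=self.array.family_id,
            population_id=self.array.population_id,
            s=s,
            log_likelihood=ll_final,
            n_iterations=n_iter,
            converged=converged,
            identifiable=bool(abs(curv) > 1e-6),
            n_offspring_used=int(ls.size),
            n_mismatch_loci=self.n_mismatch_loci,
            _ll_path=np.asarray(ll_path),
        )


@dataclass
class MixedMatingResults:
    """Fitted mixed-mating estimates for one family.

    ``tm + s == 1`` by construction; bootstrap uncertainty is attached by
    :meth:`bootstrap` (offspring resampled with replacement within the
    family, maternal genotype and pollen pool held fixed).
    """

    model: MixedMatingModel
    family_id: str
    population_id: str
    s: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    identifiable: bool
    n_offspring_used: int
    n_mismatch_loci: int
    bootstrap_se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    _ll_path: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def tm(self) -> float:
        return 1.0 - self.s

    def bootstrap(self, B: int = 1000, seed: int | None = None, max_retries: int = 10) -> "MixedMatingResults":
        """Family-level bootstrap: SE and 2.5/97.5 percentile CI of ``tm``.

        With ``B == 1`` the SE is undefined and left absent.  Replicates
        whose resample has no informative offspring are redrawn (up to
        ``max_retries``) then dropped.
        """
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        n = self.model.L_self.shape[0]
        reps = []
        for _ in range(B):
            for _retry in range(max_retries):
                idx = rng.integers(0, n, size=n)
                try:
                    res = self.model.fit(_idx=idx)
                except EstimationError:
                    continue
                reps.append(res.tm)
                break
        reps_arr = np.asarray(reps)
        if reps_arr.size >= 2:
            self.bootstrap_se = float(reps_arr.std(ddof=1))
            self.ci_low = float(np.percentile(reps_arr, 2.5))
            self.ci_high = float(np.percentile(reps_arr, 97.5))
        self.n_bootstrap = int(reps_arr.size)
        return self

    def summary(self) -> str:
        lines = [
            "Mixed-mating model (EM) — family "
            f"{self.family_id} (population {self.population_id})",
            "-" * 62,
            f"offspring used        {self.n_offspring_used}",
            f"mismatch loci demoted {self.n_mismatch_loci}",
            f"tm (outcrossing)      {self.tm:.4f}",
            f"s  (selfing)          {self.s:.4f}",
        ]
        if self.bootstrap_se is not None:
            lines.append(f"bootstrap SE (tm)     {self.bootstrap_se:.4f}  [B={self.n_bootstrap}]")
            lines.append(f"95% CI (tm)           [{self.ci_low:.4f}, {self.ci_high:.4f}]")
        lines += [
            f"log-likelihood        {self.log_likelihood:.4f}",
            f"EM iterations         {self.n_iterations}"
            + ("" if self.converged else "  (NOT converged)"),
        ]
        if not self.identifiable:
            lines.append("WARNING: flat likelihood — s not identifiable for this family")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "population": self.population_id,
            "family": self.family_id,
            "tm": self.tm,
            "s": self.s,
            "se": self.bootstrap_se if self.bootstrap_se is not None else np.nan,
            "ci_low": self.ci_low if self.ci_low is not None else np.nan,
            "ci_high": self.ci_high if self.ci_high is not None else np.nan,
            "loglik": self.log_likelihood,
            "iters": self.n_iterations,
            "converged": self.converged,
            "n_mismatch_loci": self.n_mismatch_loci,
        }


# ---------------------------------------------------------------------------
# population-level driver
# ---------------------------------------------------------------------------


def estimate_population(
    arrays: Sequence[ProgenyArray],
    bootstrap: int = 0,
    seed: int | None = None,
    smoothing: float = 0.5,
) -> tuple[pd.DataFrame, PollenPool, list[MixedMatingResults]]:
    """Fit every family of one population and tabulate the estimates.

    The pollen pool is built once from all (inferred or provided) maternal
    genotypes and held fixed for every family, keeping families independent
    for the family-level bootstrap.  Families whose population lost a locus
    simply carry that locus as missing; no code path depends on a fixed
    locus count.
    """
    provisional = PollenPool(
        locus_names=list(arrays[0].locus_names),
        freqs=_offspring_frequencies(arrays),
    )
    mothers = [infer_maternal_genotype(a, provisional)[0] if a.maternal is None else a.maternal for a in arrays]
    pollen = build_pollen_pool(arrays, mothers, smoothing=smoothing)
    rng = np.random.default_rng(seed)
    results = []
    for arr, mom in zip(arrays, mothers):
        model = MixedMatingModel(arr, pollen, maternal=mom)
        res = model.fit()
        if bootstrap > 0:
            res.bootstrap(B=bootstrap, seed=int(rng.integers(0, 2**31 - 1)))
        results.append(res)
    df = pd.DataFrame([r.to_row() for r in results])
    return df, pollen, results


def _offspring_frequencies(arrays: Sequence[ProgenyArray]) -> list[dict[int, float]]:
    """Raw offspring allele frequencies, used only to seed maternal inference."""
    n_loci = arrays[0].n_loci
    freqs = []
    for j in range(n_loci):
        counts: dict[int, float] = {}
        for arr in arrays:
            for a in arr.offspring[:, j, :].ravel():
                if a != MISSING:
                    counts[int(a)] = counts.get(int(a), 0.0) + 1.0
        total = sum(counts.values())
        # a locus with no genotyped offspring anywhere (e.g., failed to
        # amplify in this population) simply carries no pollen information
        freqs.append({a: v / total for a, v in sorted(counts.items())} if total else {})
    return freqs
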