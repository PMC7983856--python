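"""Inbreeding depression from paired pollination treatments, and the
primary-selfing correction.

A hand-pollination experiment applies a self and an outcross treatment to
each mother; per-fruit fitness is the product of seed-set (seeds/ovules)
and per-seed mass.  Cumulative inbreeding depression is

    delta = 1 - w_self / w_out

with ``w_self`` / ``w_out`` mean fitness of selfed and outcrossed progeny.
Only mothers with at least one fruit per treatment enter the estimate.

Because selfed zygotes die disproportionately before genotyping, the
selfing rate ``s`` estimated from progeny arrays underestimates selfing at
fertilisation.  The primary selfing rate corrects for that mortality:

    r = s / (1 - delta + s * delta)

``r`` equals ``s`` when delta = 0 and exceeds it otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepressionEstimate",
    "fruit_fitness",
    "estimate_delta",
    "primary_selfing_rate",
    "selfing_from_primary",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class DepressionEstimate:
    population_id: str
    w_self: float
    w_out: float
    n_mothers: int
    level: str  # "fruit" or "mother"

    @property
    def delta(self) -> float:
        return 1.0 - self.w_self / self.w_out


def fruit_fitness(seed_set, seed_mass):
    """Per-fruit fitness: seed-set times per-seed mass."""
    return np.asarray(seed_set, dtype=float) * np.asarray(seed_mass, dtype=float)


def estimate_delta(
    records: pd.DataFrame,
    population: str | None = None,
    level: str = "fruit",
) -> DepressionEstimate:
    """Estimate cumulative inbreeding depression for one population.

    Parameters
    ----------
    records : DataFrame
        Fitness records with columns ``population``, ``mother``,
        ``treatment`` ('self'/'outcross'), ``seed_set``, ``seed_mass``.
    population : str, optional
        Restrict to one population id (required if several are present).
    level : {'fruit', 'mother'}
        ``'fruit'`` (default) averages per-fruit fitness over all fruits of
        the included mothers; ``'mother'`` first averages within mother,
        then across mothers, which weights unbalanced fruit counts equally.

    Mothers lacking either treatment are excluded before averaging.  delta
    may be negative (outbreeding depression) and is reported as-is.
    """
    df = records
    if population is not None:
        df = df[df["population"] == population]
    elif df["population"].nunique() > 1:
        raise ValueError("records span several populations; pass `population`")
    pops = df["population"].unique()
    pop_id = str(pops[0]) if len(pops) else str(population)
    if len(df) == 0:
        raise InsufficientDataError(f"no fitness records for population {population!r}")

    by_mother = df.groupby("mother")["treatment"].agg(lambda t: set(t))
    complete = by_mother[by_mother.apply(lambda s: {"self", "outcross"} <= s)].index
    excluded = sorted(set(by_mother.index) - set(complete))
    if len(complete) == 0:
        raise InsufficientDataError(
            "no mother has at least one fruit per treatment; excluded mothers: "
            + ", ".join(map(str, excluded))
        )
    kept = df[df["mother"].isin(complete)].copy()
    kept["w"] = fruit_fitness(kept["seed_set"], kept["seed_mass"])

    if level == "fruit":
        means = kept.groupby("treatment")["w"].mean()
    elif level == "mother":
        means = kept.groupby(["mother", "treatment"])["w"].mean().groupby("treatment").mean()
    else:
        raise ValueError("level must be 'fruit' or 'mother'")
    w_self, w_out = float(means["self"]), float(means["outcross"])
    if w_out == 0.0:
        raise InsufficientDataError("mean outcross fitness is zero; delta undefined")
    return DepressionEstimate(
        population_id=pop_id,
        w_self=w_self,
        w_out=w_out,
        n_mothers=int(len(complete)),
        level=level,
    )


def primary_selfing_rate(s, delta):
    """Selfing rate at fertilisation: r = s / (1 - delta + s*delta).

    Accepts scalars or arrays; requires s in [0, 1] and delta < 1.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr < 0) | (s_arr > 1) | ~np.isfinite(s_arr)):
        raise ValueError("s must lie in [0, 1]")
    d_arr = np.asarray(delta, dtype=float)
    if np.any(d_arr >= 1) or np.any(~np.isfinite(d_arr)):
        raise ValueError("delta must be finite and < 1")
    r = s_arr / (1.0 - d_arr + s_arr * d_arr)
    return float(r) if r.ndim == 0 else r


def selfing_from_primary(r, delta):
    """Inverse of :func:`primary_selfing_rate`: s = r(1-delta) / (1 - r*delta)."""
    r_arr = np.asarray(r, dtype=float)
    d_arr = np.asarray(delta, dtype=float)
    s = r_arr * (1.0 - d_arr) / (1.0 - r_arr * d_arr)
    return float(s) if s.ndim == 0 else s
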