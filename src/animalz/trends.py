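"""Cohort-level genetic trends from posterior breeding-value draws.

The mean breeding value of all individuals hatched in a given year -- the
cohort mean -- is a linear combination of the latent field, so its
posterior is obtained by averaging within each stored posterior draw and
summarizing across draws.  Differences between cohorts are likewise
computed drawwise (never as differences of summaries), which preserves the
posterior correlation between cohorts that share ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .pedigree_io import Pedigree


def _cohort_members(ped: Pedigree):
    if ped.cohort is None:
        raise ValueError("pedigree has no cohort information")
    ok = ~np.isnan(ped.cohort)
    if not ok.all():
        import warnings
        warnings.warn(f"{int((~ok).sum())} individuals lack a cohort and are "
                      "excluded from trends")
    years = np.unique(ped.cohort[ok]).astype(int)
    return {int(y): np.flatnonzero(ok & (ped.cohort == y)) for y in years}


def _latent_draws(ps: PosteriorSamples, effect: str) -> np.ndarray:
    draws = ps.a_draws if effect == "autosomal" else ps.z_draws
    if draws is None or len(draws) < 2:
        raise ValueError(
            f"no stored {effect} breeding-value draws; refit with "
            "store_latent=True and a latent_thin small enough to keep >= 2 draws")
    return draws


@dataclass(frozen=True)
class CohortTrend:
    """Posterior summaries of cohort-mean breeding values per effect type."""

    table: pd.DataFrame   # year, effect, mean, sd, lower, upper, n

    def for_effect(self, effect: str) -> pd.DataFrame:
        return self.table[self.table["effect"] == effect].reset_index(drop=True)

    def write(self, path, sep="\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def cohort_trends(ps: PosteriorSamples, ped: Pedigree) -> CohortTrend:
    """Posterior mean and 95% CI of cohort-mean autosomal (and sex-linked)
    effects, averaging over ALL pedigree members of each hatch year,
    phenotyped or not."""
    members = _cohort_members(ped)
    rows = []
    effects = ["autosomal"] if ps.z_draws is None else ["autosomal", "zlinked"]
    for effect in effects:
        draws = _latent_draws(ps, effect)          # (n_draws, n_p)
        for year, idx in members.items():
            m = draws[:, idx].mean(axis=1)         # drawwise cohort mean
            rows.append(dict(
                year=year, effect=effect, mean=float(m.mean()),
                sd=float(m.std(ddof=1)),
                lower=float(np.quantile(m, 0.025)),
                upper=float(np.quantile(m, 0.975)), n=len(idx)))
    return CohortTrend(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class CohortDifference:
    """Posterior of the difference in cohort-mean additive effects."""

    year_a: int
    year_b: int
    effect: str
    samples: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if len(self.samples) > 1 else 0.0

    @property
    def ci(self) -> tuple:
        return (float(np.quantile(self.samples, 0.025)),
                float(np.quantile(self.samples, 0.975)))

    @property
    def significant(self) -> bool:
        """95% equal-tailed credible interval excludes zero."""
        lo, hi = self.ci
        return bool(lo > 0.0 or hi < 0.0)

    def __str__(self):
        lo, hi = self.ci
        return (f"{self.effect} cohort {self.year_a} - {self.year_b}: "
                f"mean difference {self.mean:.3f} (SD = {self.sd:.3f}) and "
                f"95% CI ({lo:.3f},{hi:.3f})"
                f"{' [significant]' if self.significant else ''}")


def cohort_difference(ps: PosteriorSamples, ped: Pedigree, year_a: int,
                      year_b: int, effect: str = "autosomal") -> CohortDifference:
    """Drawwise posterior of (cohort-mean in year_a) - (cohort-mean in year_b)."""
    members = _cohort_members(ped)
    for y in (year_a, year_b):
        if y not in members or len(members[y]) == 0:
            raise ValueError(f"cohort {y} is empty or absent")
    draws = _latent_draws(ps, effect)
    diff = draws[:, members[year_a]].mean(axis=1) - \
        draws[:, members[year_b]].mean(axis=1)
    return CohortDifference(year_a=year_a, year_b=year_b, effect=effect,
                            samples=diff)
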