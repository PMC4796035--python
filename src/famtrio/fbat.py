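"""The FBAT statistic over complete trios.

FBAT tests for association between a bi-allelic marker and a dichotomous
offspring phenotype, conditional on the parental genotypes, which makes it
robust to population stratification.  For trio *i* with coded offspring
genotype X_i and coded trait T_i = Y_i - mu,

    U      = sum_i T_i (X_i - E[X_i])
    Var(U) = sum_i T_i^2 Var(X_i)
    Z      = U / sqrt(Var(U))

with expectations taken over the Mendelian offspring distribution given the
parents.  Z is approximately standard normal under the null of no linkage and
no association; a positive Z means the alternate allele was over-transmitted
to affected offspring.  P-values are two-sided normal tail probabilities.

The offset mu in [0, 1] weights affected (T = 1 - mu) against unaffected
(T = -mu) trios; mu = 0 uses affected trios only, mu = 0.5 gives equal and
opposite weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .genetics import Chrom, Model, Trio, trio_score

__all__ = ["coded_trait", "FBAT", "FBATResults", "fbat"]

#: machine epsilon used when formatting vanishingly small p-values
EPS = 2.220446049250313e-16


def coded_trait(affected: bool, mu: float) -> float:
    """Coded trait T = Y - mu with Y = 1 for affected, 0 for unaffected."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"offset mu must lie in [0, 1], got {mu}")
    return (1.0 if affected else 0.0) - mu


def zscore_pvalue(z: float) -> float:
    """Two-sided standard-normal p-value of a z-score (NaN passes through)."""
    if math.isnan(z):
        return math.nan
    return 2.0 * stats.norm.sf(abs(z))


@dataclass
class FBATResults:
    """FBAT fit results for a single marker.

    ``z`` and ``pvalue`` are NaN when no informative trio contributes
    (``var_u == 0``); such markers carry no evidence either way.
    """

    u: float
    var_u: float
    n_trios: int
    n_complete: int
    n_informative: int
    n_excluded_mendel: int
    mu: float
    model: Model
    chrom: Chrom
    z: float = field(init=False)
    pvalue: float = field(init=False)

    def __post_init__(self) -> None:
        if self.var_u > 0:
            self.z = self.u / math.sqrt(self.var_u)
            self.pvalue = zscore_pvalue(self.z)
        else:
            self.z = math.nan
            self.pvalue = math.nan

    @property
    def defined(self) -> bool:
        return self.var_u > 0

    def summary(self) -> str:
        lines = [
            "FBAT results",
            "=" * 40,
            f"model:            {Model(self.model).value}",
            f"chromosome:       {Chrom(self.chrom).value}",
            f"mu (offset):      {self.mu:g}",
            f"trios (total):    {self.n_trios}",
            f"trios (complete): {self.n_complete}",
            f"informative:      {self.n_informative}",
            f"Mendel excluded:  {self.n_excluded_mendel}",
            f"U:                {self.u:.6g}",
            f"Var(U):           {self.var_u:.6g}",
        ]
        if self.defined:
            p = f"<{EPS:.3g}" if self.pvalue < EPS else f"{self.pvalue:.4g}"
            lines += [f"Z:                {self.z:.4f}", f"p-value:          {p}"]
        else:
            lines += ["Z:                undefined (no informative trio)"]
        return "\n".join(lines)


class FBAT:
    """FBAT model for one marker, built from a list of :class:`Trio`.

    Incomplete trios are skipped (they are the business of CIFBAT);
    Mendelian-inconsistent complete trios are excluded and counted rather
    than allowed to corrupt U.

    Parameters
    ----------
    trios : sequence of Trio
    model : genetic model used to code offspring genotypes
    chrom : autosomal or X context (offspring sex is taken from each trio)
    mu : trait offset in [0, 1]
    """

    def __init__(
        self,
        trios,
        model: Model = Model.ADDITIVE,
        chrom: Chrom = Chrom.AUTOSOMAL,
        mu: float = 0.5,
    ) -> None:
        if not 0.0 <= mu <= 1.0:
            raise ValueError(f"offset mu must lie in [0, 1], got {mu}")
        self.trios = list(trios)
        self.model = Model(model)
        self.chrom = Chrom(chrom)
        self.mu = float(mu)

    def fit(self) -> FBATResults:
        u = 0.0
        var_u = 0.0
        n_complete = n_informative = n_excluded = 0
        for t in self.trios:
            if not t.is_complete:
                continue
            try:
                s = trio_score(t, self.model, self.chrom)
            except Exception as err:  # Mendelian inconsistency
                from .genetics import MendelianError

                if isinstance(err, MendelianError):
                    n_excluded += 1
                    continue
                raise
            n_complete += 1
            if s.var_x > 0:
                n_informative += 1
            ti = coded_trait(t.affected, self.mu)
            u += ti * s.x_minus_e
            var_u += ti * ti * s.var_x
        return FBATResults(
            u=u,
            var_u=var_u,
            n_trios=len(self.trios),
            n_complete=n_complete,
            n_informative=n_informative,
            n_excluded_mendel=n_excluded,
            mu=self.mu,
            model=self.model,
            chrom=self.chrom,
        )


def fbat(
    trios,
    model: Model = Model.ADDITIVE,
    chrom: Chrom = Chrom.AUTOSOMAL,
    mu: float = 0.5,
) -> FBATResults:
    """Functional one-shot interface: ``FBAT(trios, ...).fit()``."""
    return FBAT(trios, model=model, chrom=chrom, mu=mu).fit()
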