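"""TDT and robustTDT for trios with affected offspring.

The transmission disequilibrium test (TDT) counts, over heterozygous parents
of affected offspring, transmissions of the alternate allele (b) versus the
reference allele (c) and forms the McNemar statistic

    chi2 = (b - c)^2 / (b + c)      ~ chi-square, 1 df under the null.

Model extensions (dominant / recessive, autosomal and X): a transmission from
a heterozygous parent is counted only when it is *model-informative* — the
two candidate transmitted alleles would produce offspring with different
coded genotypes, given the other parent's realized transmission.  Under the
additive model this reduces to the classical count (every heterozygous-parent
transmission with unambiguous attribution counts; the both-heterozygous,
heterozygous-offspring trio contributes one b and one c).  On the X
chromosome fathers are hemizygous, never heterozygous, so sons count only
maternal transmissions and daughters count maternal transmissions subject to
model-informativeness given the paternal allele.

robustTDT handles incomplete trios without modelling the missingness: each
incomplete trio realizes one (delta-b, delta-c) increment per Mendelian-
consistent completion, and exact lower/upper bounds of the statistic are
taken over the reachable set of totals (dynamic programming over (b, c)
pairs — the statistic is not monotone in b and c separately, so interval
arithmetic on the counts would be loose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from scipy import stats

from .genetics import (
    Chrom,
    MendelianError,
    Model,
    Sex,
    Trio,
    code_genotype,
    enumerate_completions,
    is_mendelian_consistent,
)

__all__ = [
    "TransmissionCounts",
    "TDT",
    "TDTResults",
    "tdt_counts",
    "tdt_statistic",
    "trio_count_options",
    "RobustTDT",
    "RobustTDTResults",
    "robust_tdt",
]


@dataclass(frozen=True)
class TransmissionCounts:
    """Informative transmission tallies: b alternate, c reference."""

    b: int
    c: int

    def __add__(self, other: "TransmissionCounts") -> "TransmissionCounts":
        return TransmissionCounts(self.b + other.b, self.c + other.c)


def _chi2(b: int, c: int) -> float:
    """McNemar statistic; NaN when no informative transmission was seen."""
    n = b + c
    if n == 0:
        return math.nan
    return (b - c) ** 2 / n


def _chi2_pvalue(chi2: float) -> float:
    if math.isnan(chi2):
        return math.nan
    return float(stats.chi2.sf(chi2, df=1))


@lru_cache(maxsize=4096)
def _increment(
    father: int, mother: int, offspring: int, sex: Sex, model: Model, chrom: Chrom
) -> tuple[int, int]:
    """(delta-b, delta-c) of one complete consistent affected trio."""
    code = lambda o: code_genotype(o, model, chrom, sex)  # noqa: E731

    if chrom == Chrom.X:
        if sex == Sex.MALE:
            # sons receive no paternal X; only a heterozygous mother counts
            if mother != 1:
                return (0, 0)
            # alternatives 0/1 always code differently for males (all models)
            return (1, 0) if offspring == 1 else (0, 1)
        # daughter: father transmits his single allele with certainty
        if mother != 1:
            return (0, 0)
        am = offspring - father
        if code(father + 0) == code(father + 1):
            return (0, 0)
        return (1, 0) if am == 1 else (0, 1)

    # autosomal: enumerate transmission assignments consistent with the trio
    def alleles(g: int) -> tuple[int, ...]:
        return ((0,), (0, 1), (1,))[g]

    incs: set[tuple[int, int]] = set()
    for af in alleles(father):
        for am in alleles(mother):
            if af + am != offspring:
                continue
            b = c = 0
            if father == 1 and code(0 + am) != code(1 + am):
                if af == 1:
                    b += 1
                else:
                    c += 1
            if mother == 1 and code(af + 0) != code(af + 1):
                if am == 1:
                    b += 1
                else:
                    c += 1
            incs.add((b, c))
    # all consistent assignments agree for bi-allelic trios (symmetry of the
    # ambiguous het x het -> het case); assert rather than silently pick
    assert len(incs) == 1, (father, mother, offspring, incs)
    return incs.pop()


def tdt_counts(
    trios: Sequence[Trio],
    model: Model = Model.ADDITIVE,
    chrom: Chrom = Chrom.AUTOSOMAL,
) -> TransmissionCounts:
    """Transmission counts (b, c) over complete, consistent, affected trios.

    Unaffected and incomplete trios are ignored; Mendelian-inconsistent trios
    are excluded.
    """
    model, chrom = Model(model), Chrom(chrom)
    b = c = 0
    for t in trios:
        if not t.affected or not t.is_complete:
            continue
        if not is_mendelian_consistent(t, chrom):
            continue
        db, dc = _increment(t.father, t.mother, t.offspring, t.sex, model, chrom)
        b += db
        c += dc
    return TransmissionCounts(b, c)


@dataclass
class TDTResults:
    """TDT fit: counts, McNemar chi-square (1 df) and its upper-tail p-value."""

    counts: TransmissionCounts
    model: Model
    chrom: Chrom

    @property
    def chi2(self) -> float:
        return _chi2(self.counts.b, self.counts.c)

    @property
    def pvalue(self) -> float:
        return _chi2_pvalue(self.chi2)

    @property
    def defined(self) -> bool:
        return self.counts.b + self.counts.c > 0

    def summary(self) -> str:
        lines = [
            "TDT results",
            "=" * 40,
            f"model:        {Model(self.model).value}",
            f"chromosome:   {Chrom(self.chrom).value}",
            f"b (alt transmitted): {self.counts.b}",
            f"c (ref transmitted): {self.counts.c}",
        ]
        if self.defined:
            lines += [f"chi2 (1 df):  {self.chi2:.4f}", f"p-value:      {self.pvalue:.4g}"]
        else:
            lines += ["chi2:         undefined (no informative transmission)"]
        return "\n".join(lines)


def tdt_statistic(counts: TransmissionCounts) -> TDTResults:
    """McNemar statistic from pre-computed counts (model fields unset)."""
    return TDTResults(counts=counts, model=Model.ADDITIVE, chrom=Chrom.AUTOSOMAL)


class TDT:
    """TDT model for one marker over affected trios."""

    def __init__(
        self,
        trios,
        model: Model = Model.ADDITIVE,
        chrom: Chrom = Chrom.AUTOSOMAL,
    ) -> None:
        self.trios = list(trios)
        self.model = Model(model)
        self.chrom = Chrom(chrom)

    def fit(self) -> TDTResults:
        counts = tdt_counts(self.trios, self.model, self.chrom)
        return TDTResults(counts=counts, model=self.model, chrom=self.chrom)


def trio_count_options(
    t: Trio,
    model: Model = Model.ADDITIVE,
    chrom: Chrom = Chrom.AUTOSOMAL,
) -> set[tuple[int, int]]:
    """Distinct (delta-b, delta-c) increments over all completions of ``t``.

    ``t`` must be an affected incomplete trio with at least one consistent
    completion; raises :class:`MendelianError` otherwise.
    """
    if t.is_complete:
        raise ValueError("trio_count_options requires an incomplete trio")
    model, chrom = Model(model), Chrom(chrom)
    opts = {
        _increment(c.father, c.mother, c.offspring, c.sex, model, chrom)
        for c in enumerate_completions(t, chrom)
    }
    return opts


@dataclass
class RobustTDTResults:
    """Exact bounds of the TDT statistic over joint completions.

    ``chi2_lower <= chi2_upper``; both p-values are reported (upper-tail of
    chi-square 1 df at each bound).  Totals with b + c = 0 carry no evidence
    and enter the bounds as chi2 = 0.  ``reachable_count`` is the number of
    distinct (b, c) totals examined.
    """

    chi2_lower: float
    chi2_upper: float
    reachable_count: int
    counts_complete: TransmissionCounts
    n_incomplete: int
    model: Model
    chrom: Chrom

    @property
    def p_lower(self) -> float:
        """P-value at the *upper* chi2 bound (smallest attainable p)."""
        return _chi2_pvalue(self.chi2_upper)

    @property
    def p_upper(self) -> float:
        """P-value at the *lower* chi2 bound (largest attainable p)."""
        return _chi2_pvalue(self.chi2_lower)

    def summary(self) -> str:
        return "\n".join(
            [
                "robustTDT results",
                "=" * 40,
                f"model:            {Model(self.model).value}",
                f"chromosome:       {Chrom(self.chrom).value}",
                f"complete (b, c):  ({self.counts_complete.b}, {self.counts_complete.c})",
                f"incomplete trios: {self.n_incomplete}",
                f"reachable totals: {self.reachable_count}",
                f"chi2 bounds:      [{self.chi2_lower:.4f}, {self.chi2_upper:.4f}]",
                f"p-value bounds:   [{self.p_lower:.4g}, {self.p_upper:.4g}]",
            ]
        )


class RobustTDT:
    """robustTDT model: exact TDT-statistic bounds over genotype completions."""

    def __init__(
        self,
        trios,
        model: Model = Model.ADDITIVE,
        chrom: Chrom = Chrom.AUTOSOMAL,
    ) -> None:
        self.trios = list(trios)
        self.model = Model(model)
        self.chrom = Chrom(chrom)

    def fit(self) -> RobustTDTResults:
        affected = [t for t in self.trios if t.affected]
        complete = [t for t in affected if t.is_complete]
        incomplete = [t for t in affected if not t.is_complete]
        base = tdt_counts(complete, self.model, self.chrom)

        reachable: set[tuple[int, int]] = {(base.b, base.c)}
        n_used = 0
        for t in incomplete:
            try:
                opts = trio_count_options(t, self.model, self.chrom)
            except MendelianError:
                continue
            n_used += 1
            reachable = {(b + db, c + dc) for (b, c) in reachable for (db, dc) in opts}

        chis = [0.0 if b + c == 0 else _chi2(b, c) for b, c in reachable]
        return RobustTDTResults(
            chi2_lower=min(chis),
            chi2_upper=max(chis),
            reachable_count=len(reachable),
            counts_complete=base,
            n_incomplete=n_used,
            model=self.model,
            chrom=self.chrom,
        )


def robust_tdt(
    trios,
    model: Model = Model.ADDITIVE,
    chrom: Chrom = Chrom.AUTOSOMAL,
) -> RobustTDTResults:
    """Functional one-shot interface: ``RobustTDT(trios, ...).fit()``."""
    return RobustTDT(trios, model=model, chrom=chrom).fit()
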