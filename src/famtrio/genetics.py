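"""Genotype coding, Mendelian transmission and trio scoring.

A bi-allelic genotype is stored as the dosage of the non-reference (alternate)
allele: 0, 1 or 2 for autosomal loci and X-chromosome females, 0 or 1 for
hemizygous X-chromosome males.  Missing genotypes are the sentinel
:data:`MISSING` (``-1``).

A *trio* is a father-mother-offspring unit with a dichotomous offspring
phenotype.  Conditional on the parental genotypes, the offspring genotype has
a Mendelian transmission distribution; the trio score is the pair
``(X - E[X], Var(X))`` of the model-coded offspring genotype centred and
scaled by that distribution.  These scores are the building blocks of the
FBAT statistic and of its quantile intervals over randomized completions of
incomplete trios.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import NamedTuple

import numpy as np

__all__ = [
    "MISSING",
    "Model",
    "Chrom",
    "Sex",
    "Trio",
    "TrioScore",
    "MendelianError",
    "offspring_distribution",
    "code_genotype",
    "trio_score",
    "is_informative",
    "is_mendelian_consistent",
    "enumerate_completions",
    "offspring_space",
    "parent_space",
    "score_tables",
]

#: sentinel for a missing genotype
MISSING = -1


class Model(str, enum.Enum):
    """Genetic model used to code the offspring genotype."""

    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class Chrom(str, enum.Enum):
    """Chromosome context: autosomal or X."""

    AUTOSOMAL = "autosomal"
    X = "X"


class Sex(enum.IntEnum):
    """Offspring sex; PED convention (1=male, 2=female)."""

    MALE = 1
    FEMALE = 2


class MendelianError(ValueError):
    """A trio violates Mendelian inheritance (or malformed genotypes)."""


class TrioScore(NamedTuple):
    """The FBAT per-trio score ``(X - E[X], Var(X))``.

    ``var_x == 0`` marks a non-informative trio for the given model.
    """

    x_minus_e: float
    var_x: float


@dataclass(frozen=True)
class Trio:
    """A father-mother-offspring unit at a single bi-allelic marker.

    Genotypes are alternate-allele dosages, ``MISSING`` (-1) when unknown.
    ``sex`` is the offspring sex and only matters on the X chromosome.
    """

    father: int
    mother: int
    offspring: int
    affected: bool = True
    sex: Sex = Sex.FEMALE
    family_id: str = ""

    def __post_init__(self) -> None:
        for role in ("father", "mother", "offspring"):
            g = getattr(self, role)
            if g is None:
                object.__setattr__(self, role, MISSING)

    @property
    def is_complete(self) -> bool:
        return MISSING not in (self.father, self.mother, self.offspring)

    @property
    def n_missing(self) -> int:
        return sum(g == MISSING for g in (self.father, self.mother, self.offspring))


# ---------------------------------------------------------------------------
# genotype spaces and validation
# ---------------------------------------------------------------------------

def parent_space(role: str, chrom: Chrom = Chrom.AUTOSOMAL) -> tuple[int, ...]:
    """Valid genotype dosages for a parent in the given context."""
    if chrom == Chrom.X and role == "father":
        return (0, 1)  # hemizygous
    return (0, 1, 2)


def offspring_space(chrom: Chrom = Chrom.AUTOSOMAL, sex: Sex = Sex.FEMALE) -> tuple[int, ...]:
    """Valid genotype dosages for the offspring in the given context."""
    if chrom == Chrom.X and sex == Sex.MALE:
        return (0, 1)
    return (0, 1, 2)


def _check(g: int, space: tuple[int, ...], who: str) -> None:
    if g != MISSING and g not in space:
        raise ValueError(f"invalid {who} genotype {g!r} for this context (valid: {space})")


def _validate_trio(t: Trio, chrom: Chrom) -> None:
    _check(t.father, parent_space("father", chrom), "father")
    _check(t.mother, parent_space("mother", chrom), "mother")
    _check(t.offspring, offspring_space(chrom, t.sex), "offspring")


def _transmission(g: int) -> dict[int, float]:
    """Transmitted-allele distribution for a diploid parent of dosage ``g``."""
    if g == 0:
        return {0: 1.0}
    if g == 1:
        return {0: 0.5, 1: 0.5}
    if g == 2:
        return {1: 1.0}
    raise ValueError(f"invalid parental dosage {g!r}")


def _allele_options(g: int) -> tuple[int, ...]:
    """Alleles a diploid parent of dosage ``g`` can transmit (missing -> both)."""
    if g == MISSING:
        return (0, 1)
    return tuple(_transmission(g))


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def offspring_distribution(
    father: int,
    mother: int,
    chrom: Chrom = Chrom.AUTOSOMAL,
    sex: Sex = Sex.FEMALE,
) -> dict[int, float]:
    """Mendelian distribution of the offspring genotype given the parents.

    Autosomal: each parent transmits one of its two alleles with probability
    1/2.  X-chromosome sons receive only the maternal transmission;
    X-chromosome daughters receive the father's single X allele with
    probability 1 plus a maternal transmission.
    """
    if father == MISSING or mother == MISSING:
        raise ValueError("offspring_distribution requires non-missing parents")
    _check(father, parent_space("father", chrom), "father")
    _check(mother, parent_space("mother", chrom), "mother")

    mom = _transmission(mother)
    if chrom == Chrom.X:
        if sex == Sex.MALE:
            return dict(mom)
        dist: dict[int, float] = {}
        for b, pb in mom.items():
            dist[father + b] = dist.get(father + b, 0.0) + pb
        return dist
    dad = _transmission(father)
    dist = {}
    for a, pa in dad.items():
        for b, pb in mom.items():
            dist[a + b] = dist.get(a + b, 0.0) + pa * pb
    return dist


def code_genotype(
    g: int,
    model: Model,
    chrom: Chrom = Chrom.AUTOSOMAL,
    sex: Sex = Sex.FEMALE,
) -> float:
    """Model-coded genotype value X.

    ADDITIVE codes the dosage itself; DOMINANT codes carrier status.  Under
    RECESSIVE, autosomal/X-female genotypes code 1 only when homozygous
    alternate, while a hemizygous X-male expresses a recessive allele with a
    single copy, so dosage 1 codes 1.
    """
    if g == MISSING:
        raise ValueError("cannot code a missing genotype")
    _check(g, offspring_space(chrom, sex), "genotype")
    model = Model(model)
    if model == Model.ADDITIVE:
        return float(g)
    if model == Model.DOMINANT:
        return 1.0 if g >= 1 else 0.0
    # recessive
    if chrom == Chrom.X and sex == Sex.MALE:
        return 1.0 if g == 1 else 0.0
    return 1.0 if g == 2 else 0.0


def is_mendelian_consistent(t: Trio, chrom: Chrom = Chrom.AUTOSOMAL) -> bool:
    """True iff some allele assignment to the non-missing members is transmissible.

    A missing member imposes no constraint; a fully missing trio is vacuously
    consistent.
    """
    _validate_trio(t, chrom)
    if t.offspring == MISSING:
        return True
    if chrom == Chrom.X:
        mom = _allele_options(t.mother)
        if t.sex == Sex.MALE:
            return t.offspring in mom
        dads = (0, 1) if t.father == MISSING else (t.father,)
        return any(fa + b == t.offspring for fa in dads for b in mom)
    return any(
        a + b == t.offspring
        for a in _allele_options(t.father)
        for b in _allele_options(t.mother)
    )


def trio_score(
    t: Trio,
    model: Model,
    chrom: Chrom = Chrom.AUTOSOMAL,
) -> TrioScore:
    """Score a complete trio: ``(x(offspring) - E[x], Var(x))``.

    Expectations are over the Mendelian offspring distribution given the
    parents; ``x`` is the model coding.  Raises :class:`MendelianError` for an
    inconsistent trio and :class:`ValueError` for missing members.
    """
    if not t.is_complete:
        raise ValueError(f"trio_score requires a complete trio, got {t}")
    if not is_mendelian_consistent(t, chrom):
        raise MendelianError(f"Mendelian-inconsistent trio {t}")
    dist = offspring_distribution(t.father, t.mother, chrom, t.sex)
    ex = sum(p * code_genotype(g, model, chrom, t.sex) for g, p in dist.items())
    ex2 = sum(p * code_genotype(g, model, chrom, t.sex) ** 2 for g, p in dist.items())
    var = max(ex2 - ex * ex, 0.0)
    return TrioScore(code_genotype(t.offspring, model, chrom, t.sex) - ex, var)


def is_informative(
    father: int,
    mother: int,
    model: Model,
    chrom: Chrom = Chrom.AUTOSOMAL,
    sex: Sex = Sex.FEMALE,
) -> bool:
    """True iff the mating gives the coded offspring genotype positive variance."""
    dist = offspring_distribution(father, mother, chrom, sex)
    codes = [code_genotype(g, model, chrom, sex) for g in dist]
    return max(codes) - min(codes) > 0


def enumerate_completions(t: Trio, chrom: Chrom = Chrom.AUTOSOMAL) -> list[Trio]:
    """All distinct Mendelian-consistent completions of an incomplete trio.

    Every completion agrees with the observed members; non-informative
    completions (both parents homozygous) are included — they contribute a
    (0, 0) score.  Raises :class:`ValueError` if the trio is already complete
    and :class:`MendelianError` if the observed members alone are
    inconsistent.
    """
    if t.is_complete:
        raise ValueError("enumerate_completions requires at least one missing genotype")
    if not is_mendelian_consistent(t, chrom):
        raise MendelianError(f"observed members of {t} are Mendelian-inconsistent")
    spaces = {
        "father": parent_space("father", chrom),
        "mother": parent_space("mother", chrom),
        "offspring": offspring_space(chrom, t.sex),
    }
    missing = [r for r in ("father", "mother", "offspring") if getattr(t, r) == MISSING]
    out: list[Trio] = []
    for combo in itertools.product(*(spaces[r] for r in missing)):
        cand = replace(t, **dict(zip(missing, combo)))
        if is_mendelian_consistent(cand, chrom):
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# vectorised lookup tables (used by the scan/simulation fast paths)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def score_tables(
    model: Model,
    chrom: Chrom = Chrom.AUTOSOMAL,
    sex: Sex = Sex.FEMALE,
):
    """Lookup tables for vectorised trio scoring.

    Returns ``(code, ex, var, cons)`` where ``code[o]`` is the coded offspring
    genotype, ``ex[f, m]`` / ``var[f, m]`` the mean and variance of the coded
    genotype under the Mendelian offspring distribution, and
    ``cons[f, m, o]`` the Mendelian-consistency mask.  Invalid genotype
    combinations for the context hold NaN / False.
    """
    model, chrom, sex = Model(model), Chrom(chrom), Sex(sex)
    code = np.full(3, np.nan)
    for o in offspring_space(chrom, sex):
        code[o] = code_genotype(o, model, chrom, sex)
    ex = np.full((3, 3), np.nan)
    var = np.full((3, 3), np.nan)
    cons = np.zeros((3, 3, 3), dtype=bool)
    for f in parent_space("father", chrom):
        for m in parent_space("mother", chrom):
            dist = offspring_distribution(f, m, chrom, sex)
            e = sum(p * code[g] for g, p in dist.items())
            e2 = sum(p * code[g] ** 2 for g, p in dist.items())
            ex[f, m] = e
            var[f, m] = max(e2 - e * e, 0.0)
            for o in dist:
                cons[f, m, o] = True
    ex.setflags(write=False)
    var.setflags(write=False)
    cons.setflags(write=False)
    code.setflags(write=False)
    return code, ex, var, cons
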