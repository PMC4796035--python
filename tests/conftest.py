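"""Shared fixtures and independent oracles for the test suite.

The oracles here re-derive trio scores, Mendelian consistency and genotype
completions from first principles (explicit enumeration of parental allele
pairs and transmissions) on a code path deliberately separate from the
package's closed-form implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from famtrio.genetics import MISSING, Chrom, Model, Sex

# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def oracle_code(g: int, model: Model, chrom: Chrom, sex: Sex) -> float:
    """Model coding restated literally, independent of the package."""
    if model == Model.ADDITIVE:
        return float(g)
    if model == Model.DOMINANT:
        return float(g >= 1)
    if chrom == Chrom.X and sex == Sex.MALE:
        return float(g == 1)
    return float(g == 2)


def oracle_outcomes(f: int, m: int, chrom: Chrom, sex: Sex) -> list[int]:
    """Equally likely offspring genotypes via explicit transmission listing.

    Autosomal: 4 ordered (paternal, maternal) transmissions.  X sons: the 2
    maternal transmissions.  X daughters: paternal allele is certain, so the
    2 maternal transmissions.
    """
    mo = _ALLELE_PAIRS[m]
    if chrom == Chrom.X:
        if sex == Sex.MALE:
            return [b for b in mo]
        return [f + b for b in mo]
    fa = _ALLELE_PAIRS[f]
    return [a + b for a in fa for b in mo]


def oracle_score(f: int, m: int, o: int, model: Model, chrom: Chrom, sex: Sex):
    """(x - E[x], Var(x)) by averaging the coded outcome list."""
    codes = [oracle_code(g, model, chrom, sex) for g in oracle_outcomes(f, m, chrom, sex)]
    e = float(np.mean(codes))
    v = float(np.mean(np.square(codes)) - e * e)
    return oracle_code(o, model, chrom, sex) - e, max(v, 0.0)


def oracle_member_spaces(chrom: Chrom, sex: Sex):
    father = (0, 1) if chrom == Chrom.X else (0, 1, 2)
    mother = (0, 1, 2)
    off = (0, 1) if (chrom == Chrom.X and sex == Sex.MALE) else (0, 1, 2)
    return father, mother, off


def oracle_completions(f: int, m: int, o: int, chrom: Chrom, sex: Sex):
    """Brute force over the full genotype space with the transmission filter."""
    fs, ms, os_ = oracle_member_spaces(chrom, sex)
    out = []
    for cf, cm, co in itertools.product(fs, ms, os_):
        if f != MISSING and cf != f:
            continue
        if m != MISSING and cm != m:
            continue
        if o != MISSING and co != o:
            continue
        if co in oracle_outcomes(cf, cm, chrom, sex):
            out.append((cf, cm, co))
    return out


CONTEXTS = [
    (Chrom.AUTOSOMAL, Sex.FEMALE),
    (Chrom.X, Sex.FEMALE),
    (Chrom.X, Sex.MALE),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
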