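"""Simulator for nuclear-family genotype and phenotype data.

The generator emulates a two-subpopulation cohort of nuclear families typed
at independent bi-allelic autosomal markers:

* marker frequencies are drawn from a scaled Gamma law, Gamma(2, 2)/35
  (mean ~0.114), clipped away from fixation, with mild Balding-Nichols
  differentiation between the two subpopulations;
* parental genotypes follow Hardy-Weinberg proportions at the family's
  subpopulation frequency; each family has one or two offspring produced by
  Mendelian transmission, with uniform offspring sex;
* disease status follows a log-additive penetrance model
  ``log(pi_ij) = alpha_ij + sum_m beta_m X(G_ijm)`` over a few causative
  markers, where ``beta`` for two causative copies is the log penetrance
  ratio log(f2/f0) and one copy contributes half of it, plus a family-shared
  environmental exposure calibrated so the mean population prevalence hits a
  target (12.5% by default);
* missingness is injected per (individual, marker) genotype entry under
  MCAR, or concentrated 80/20 on a target group (subpopulation, sex, case
  status, or the genotype value itself) for MAR / MNAR scenarios.

Everything is driven by a single :class:`numpy.random.Generator` so runs are
exactly reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .genetics import MISSING

__all__ = [
    "SimConfig",
    "MissingnessSpec",
    "PedigreeSet",
    "SCENARIO_TARGETS",
    "draw_marker_freqs",
    "simulate_families",
    "assign_disease",
    "calibrate_prevalence",
    "measure_prevalence",
    "select_case_control",
    "inject_missingness",
]


@dataclass
class SimConfig:
    """Parameters of the family-genotype simulator.

    Defaults are the study conditions: 4000 families split 1/3 : 2/3 over two
    subpopulations, 300 markers of which 3 are causative, penetrances
    f2 ~ N(0.1, 0.01) and f0 ~ N(0.001, 0.001) (second argument is the sd),
    environmental effect lambda_s = 3, genomic effect lambda_g = 2 (recorded;
    the additive beta coding is fully determined by f0 and f2), marker
    frequencies Gamma(shape=2, scale=2)/35 clipped to [0.001, 0.5].

    ``p_env`` is the family-level probability of the shared environmental
    exposure; leave it None and call :func:`calibrate_prevalence` to set it
    so the mean population prevalence matches ``prevalence_target``.
    """

    n_families: int = 4000
    pop_fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    n_markers: int = 300
    n_causative: int = 3
    offspring_choices: tuple[int, ...] = (1, 2)
    freq_shape: float = 2.0
    freq_scale: float = 2.0
    freq_divisor: float = 35.0
    freq_bounds: tuple[float, float] = (0.001, 0.5)
    fst: float = 0.01
    f2_mean: float = 0.1
    f2_sd: float = 0.01
    f0_mean: float = 0.001
    f0_sd: float = 0.001
    penetrance_floor: float = 1e-5
    lambda_s: float = 3.0
    lambda_g: float = 2.0
    p_env: float | None = None
    prevalence_target: float = 0.125
    cifbat_iterations: int = 100
    alpha: float = 0.05
    fdr: float = 0.10
    mu: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.pop_fractions) - 1.0) > 1e-9:
            raise ValueError("pop_fractions must sum to 1")
        if self.n_causative > self.n_markers:
            raise ValueError("n_causative cannot exceed n_markers")
        lo, hi = self.freq_bounds
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError("freq_bounds must satisfy 0 < lo < hi <= 0.5")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


#: Table of missingness scenarios: (mode, target group the 80% falls on)
SCENARIO_TARGETS: tuple[tuple[str, str], ...] = (
    ("MCAR", "random"),
    ("MAR", "small_pop"),
    ("MAR", "large_pop"),
    ("MAR", "males"),
    ("MAR", "females"),
    ("MNAR", "cases"),
    ("MNAR", "controls"),
    ("MNAR", "heterozygotes"),
    ("MNAR", "homozygotes"),
)

_VALID_TARGETS = {t for _, t in SCENARIO_TARGETS}


@dataclass(frozen=True)
class MissingnessSpec:
    """One missingness scenario: mechanism, target group, entry rate.

    ``split`` is the fraction of missing entries concentrated in the target
    group (0.8 means an 80/20 split); it is ignored under MCAR.
    """

    mode: str = "MCAR"
    target: str = "random"
    rate: float = 0.0
    split: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in {"MCAR", "MAR", "MNAR"}:
            raise ValueError(f"unknown missingness mode {self.mode!r}")
        if self.target not in _VALID_TARGETS:
            raise ValueError(f"unknown missingness target {self.target!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")
        if not 0.5 < self.split <= 1.0:
            raise ValueError("split must lie in (0.5, 1]")


@dataclass
class PedigreeSet:
    """A simulated cohort of nuclear families at independent markers.

    Genotypes are alternate-allele dosage matrices (int8, -1 = missing):
    one row per family for each parent, one row per offspring.  Trio *i* is
    (father of family ``off_family[i]``, mother of the same family,
    offspring *i*).
    """

    config: SimConfig
    freq_base: np.ndarray  # (n_markers,)
    freq_pop: np.ndarray  # (2, n_markers)
    fam_pop: np.ndarray  # (n_families,) 0/1
    father_geno: np.ndarray  # (n_families, n_markers) int8
    mother_geno: np.ndarray  # (n_families, n_markers) int8
    off_geno: np.ndarray  # (n_offspring, n_markers) int8
    off_family: np.ndarray  # (n_offspring,) family index
    off_sex: np.ndarray  # (n_offspring,) 1 male / 2 female
    affected: np.ndarray | None = None  # (n_offspring,) bool
    causative: np.ndarray | None = None  # causative marker indices
    n_pi_clipped: int = 0
    n_missing_spilled: int = 0

    @property
    def n_offspring(self) -> int:
        return self.off_geno.shape[0]

    @property
    def prevalence(self) -> float:
        if self.affected is None:
            raise ValueError("disease status not assigned yet")
        return float(np.mean(self.affected))

    def trio_genotypes(self, trio_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(father, mother, offspring) dosage matrices for the given trios."""
        fams = self.off_family[trio_idx]
        return (
            self.father_geno[fams],
            self.mother_geno[fams],
            self.off_geno[trio_idx],
        )


def draw_marker_freqs(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Base and per-subpopulation alternate-allele frequencies.

    The base frequency per marker comes from Gamma(shape, scale)/divisor,
    clipped to ``freq_bounds``.  Subpopulation frequencies are perturbed from
    the base with a Balding-Nichols Beta draw at differentiation ``fst``
    (fst <= 0 leaves both populations at the base frequency).
    """
    base = rng.gamma(cfg.freq_shape, cfg.freq_scale, size=cfg.n_markers) / cfg.freq_divisor
    base = np.clip(base, *cfg.freq_bounds)
    if cfg.fst <= 0:
        pops = np.vstack([base, base])
    else:
        ratio = (1.0 - cfg.fst) / cfg.fst
        pops = rng.beta(base * ratio, (1.0 - base) * ratio, size=(2, cfg.n_markers))
        pops = np.clip(pops, cfg.freq_bounds[0], 1.0 - cfg.freq_bounds[0])
    return base, pops


def simulate_families(
    cfg: SimConfig,
    rng: np.random.Generator,
    freqs: tuple[np.ndarray, np.ndarray] | None = None,
) -> PedigreeSet:
    """Generate parental genotypes under Hardy-Weinberg and Mendelian offspring.

    Families are assigned to the two subpopulations in the configured
    fractions; each family has 1 or 2 offspring (uniform) of uniform sex.
    """
    base, pops = draw_marker_freqs(cfg, rng) if freqs is None else freqs
    n_fam, n_m = cfg.n_families, cfg.n_markers
    n_pop0 = int(round(cfg.pop_fractions[0] * n_fam))
    fam_pop = np.zeros(n_fam, dtype=np.int8)
    fam_pop[n_pop0:] = 1

    p = pops[fam_pop]  # (n_fam, n_markers)
    father = rng.binomial(2, p).astype(np.int8)
    mother = rng.binomial(2, p).astype(np.int8)

    counts = rng.choice(cfg.offspring_choices, size=n_fam)
    off_family = np.repeat(np.arange(n_fam), counts)
    fo = father[off_family]
    mo = mother[off_family]
    child = rng.binomial(1, fo / 2.0) + rng.binomial(1, mo / 2.0)
    off_sex = rng.integers(1, 3, size=off_family.shape[0]).astype(np.int8)

    return PedigreeSet(
        config=cfg,
        freq_base=base,
        freq_pop=pops,
        fam_pop=fam_pop,
        father_geno=father,
        mother_geno=mother,
        off_geno=child.astype(np.int8),
        off_family=off_family,
        off_sex=off_sex,
    )


def _penetrance_draws(cfg: SimConfig, rng: np.random.Generator, n_fam: int):
    f0 = np.clip(rng.normal(cfg.f0_mean, cfg.f0_sd, n_fam), cfg.penetrance_floor, 1.0)
    f2 = np.clip(rng.normal(cfg.f2_mean, cfg.f2_sd, n_fam), cfg.penetrance_floor, 1.0)
    return f0, f2


def _disease_probability(
    cfg: SimConfig,
    dosage_sum: np.ndarray,
    off_family: np.ndarray,
    f0: np.ndarray,
    f2: np.ndarray,
    exposed: np.ndarray,
) -> np.ndarray:
    """pi per offspring from the log-additive penetrance model (pre-clip).

    The family-shared environmental exposure raises the log baseline by
    log(lambda_s * f2 / f0), i.e. an exposed family's baseline is lambda_s
    times the two-copy penetrance; siblings share the exposure, which is the
    source of within-family phenotype correlation beyond shared genotypes.
    """
    beta2 = np.log(f2 / f0)
    env = np.log(cfg.lambda_s * f2 / f0)
    log_pi = (
        np.log(f0)[off_family]
        + exposed[off_family] * env[off_family]
        + dosage_sum * beta2[off_family] / 2.0
    )
    return np.exp(log_pi)


def assign_disease(
    ped: PedigreeSet,
    rng: np.random.Generator,
    causative: np.ndarray | None = None,
) -> PedigreeSet:
    """Draw affection status for every offspring under the penetrance model.

    Requires ``ped.config.p_env`` to be set (see
    :func:`calibrate_prevalence`).  Probabilities above 1 after
    exponentiation are clipped and counted in ``n_pi_clipped``.
    """
    cfg = ped.config
    if cfg.p_env is None:
        raise ValueError("config.p_env is unset; run calibrate_prevalence first")
    n_fam = cfg.n_families
    if causative is None:
        causative = rng.choice(cfg.n_markers, size=cfg.n_causative, replace=False)
    causative = np.asarray(causative)

    f0, f2 = _penetrance_draws(cfg, rng, n_fam)
    exposed = rng.random(n_fam) < cfg.p_env
    dosage_sum = ped.off_geno[:, causative].sum(axis=1).astype(float)
    pi = _disease_probability(cfg, dosage_sum, ped.off_family, f0, f2, exposed)
    n_clipped = int(np.sum(pi > 1.0))
    pi = np.clip(pi, 0.0, 1.0)
    affected = rng.random(ped.n_offspring) < pi

    ped.affected = affected
    ped.causative = causative
    ped.n_pi_clipped = n_clipped
    return ped


def _probe_rep(cfg: SimConfig, rng: np.random.Generator):
    """One prevalence-probe replicate: causative-marker genotypes + frozen uniforms.

    Only the causative markers influence disease risk, so the probe cohort
    simulates just those; exposure and disease uniforms are drawn once so
    prevalence is an exactly non-decreasing, deterministic function of
    ``p_env`` on the replicate.
    """
    probe_cfg = cfg.replace(n_markers=cfg.n_causative)
    ped = simulate_families(probe_cfg, rng)
    f0, f2 = _penetrance_draws(probe_cfg, rng, probe_cfg.n_families)
    u_exp = rng.random(probe_cfg.n_families)
    u_dis = rng.random(ped.n_offspring)
    dosage = ped.off_geno.sum(axis=1).astype(float)
    return ped.off_family, dosage, f0, f2, u_exp, u_dis


def _probe_prevalence(cfg: SimConfig, rep, p_env: float) -> float:
    off_family, dosage, f0, f2, u_exp, u_dis = rep
    pi = _disease_probability(cfg, dosage, off_family, f0, f2, u_exp < p_env)
    return float(np.mean(u_dis < np.clip(pi, 0.0, 1.0)))


def measure_prevalence(
    cfg: SimConfig,
    rng: np.random.Generator,
    n_reps: int = 200,
) -> float:
    """Mean offspring disease prevalence over fresh simulated cohorts.

    Cross-replicate prevalence is highly variable (the causative-marker
    frequency and penetrance draws differ per cohort), so many replicates
    are needed for a tight mean.
    """
    if cfg.p_env is None:
        raise ValueError("config.p_env is unset; run calibrate_prevalence first")
    vals = [
        _probe_prevalence(cfg, _probe_rep(cfg, rng), cfg.p_env) for _ in range(n_reps)
    ]
    return float(np.mean(vals))


def calibrate_prevalence(
    cfg: SimConfig,
    rng: np.random.Generator,
    target: float | None = None,
    tol: float = 0.005,
    n_reps: int = 200,
) -> float:
    """Bisection on the environmental exposure probability ``p_env``.

    A bank of probe replicates is simulated once with frozen exposure and
    disease uniforms, which makes the mean prevalence an exactly
    non-decreasing function of ``p_env`` and lets plain bisection converge
    despite the Monte-Carlo layer.  The replicate count bounds the probe's
    own sampling error (prevalence varies strongly across cohorts); raise it
    when the downstream check is tighter.  Raises if the target is
    unattainable within ``tol`` at either endpoint.
    """
    target = cfg.prevalence_target if target is None else float(target)
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")

    reps = [_probe_rep(cfg, rng) for _ in range(n_reps)]

    def prevalence(p_env: float) -> float:
        return float(np.mean([_probe_prevalence(cfg, rep, p_env) for rep in reps]))

    lo, hi = 0.0, 1.0
    p_lo, p_hi = prevalence(lo), prevalence(hi)
    if p_lo > target + tol:
        raise ValueError(
            f"target prevalence {target:.3f} below the purely genetic floor {p_lo:.3f}"
        )
    if p_hi < target - tol:
        raise ValueError(
            f"target prevalence {target:.3f} above the achievable ceiling {p_hi:.3f}"
        )
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    p_env = 0.5 * (lo + hi)
    achieved = prevalence(p_env)
    if abs(achieved - target) > tol:
        raise ValueError(
            f"calibration stalled at prevalence {achieved:.4f} for target {target:.4f}"
        )
    return p_env


def select_case_control(
    ped: PedigreeSet,
    rng: np.random.Generator,
    allow_trim: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Case and control trio indices (indices into offspring).

    Every affected-offspring trio is a case; an equal number of
    unaffected-offspring trios is drawn uniformly without replacement from
    the remainder.  With ``allow_trim`` the larger side is subsampled
    instead of raising when controls run short (useful for null phenotypes
    near 50% prevalence).
    """
    if ped.affected is None:
        raise ValueError("disease status not assigned yet")
    cases = np.flatnonzero(ped.affected)
    pool = np.flatnonzero(~ped.affected)
    if len(pool) < len(cases):
        if not allow_trim:
            raise ValueError(
                f"only {len(pool)} unaffected trios available for {len(cases)} cases"
            )
        cases = rng.choice(cases, size=len(pool), replace=False)
    controls = rng.choice(pool, size=len(cases), replace=False)
    return np.sort(cases), np.sort(controls)


def _selection_rows(ped: PedigreeSet, case_idx: np.ndarray, control_idx: np.ndarray):
    """Unique individuals touched by the selected trios.

    Returns ``(kinds, indices, sex, pop, is_case, is_control)`` — parents are
    deduplicated per family.  Disease status is a property of the phenotyped
    offspring only: parents are neither cases nor controls (they fall in the
    20% complement when missingness is concentrated on disease status).
    """
    sel_off = np.concatenate([case_idx, control_idx])
    is_case_off = np.zeros(len(sel_off), dtype=bool)
    is_case_off[: len(case_idx)] = True

    uniq_fams = np.unique(ped.off_family[sel_off])
    n_par = len(uniq_fams)
    kinds = np.concatenate(
        [
            np.zeros(n_par, dtype=np.int8),  # 0 = father
            np.ones(n_par, dtype=np.int8),  # 1 = mother
            np.full(len(sel_off), 2, dtype=np.int8),  # 2 = offspring
        ]
    )
    indices = np.concatenate([uniq_fams, uniq_fams, sel_off])
    sex = np.concatenate(
        [
            np.ones(n_par, dtype=np.int8),
            np.full(n_par, 2, dtype=np.int8),
            ped.off_sex[sel_off],
        ]
    )
    pop = np.concatenate(
        [ped.fam_pop[uniq_fams], ped.fam_pop[uniq_fams], ped.fam_pop[ped.off_family[sel_off]]]
    )
    pad = np.zeros(2 * n_par, dtype=bool)
    is_case = np.concatenate([pad, is_case_off])
    is_control = np.concatenate([pad, ~is_case_off])
    return kinds, indices, sex, pop, is_case, is_control


def inject_missingness(
    ped: PedigreeSet,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    spec: MissingnessSpec,
    rng: np.random.Generator,
) -> PedigreeSet:
    """Blank out genotype entries of the selected individuals.

    Per marker, a fraction ``spec.rate`` of the selected individuals'
    entries is set to missing.  Under MCAR entries are chosen uniformly;
    otherwise ``spec.split`` of them fall inside the target group and the
    rest outside, spilling to the other group (and counted in
    ``n_missing_spilled``) when a group is too small.  Returns a new
    :class:`PedigreeSet` with copied genotype matrices; the input is left
    untouched.
    """
    out = dataclasses.replace(
        ped,
        father_geno=ped.father_geno.copy(),
        mother_geno=ped.mother_geno.copy(),
        off_geno=ped.off_geno.copy(),
    )
    if spec.rate <= 0.0:
        return out

    kinds, indices, sex, pop, is_case, is_control = _selection_rows(ped, case_idx, control_idx)
    n_sel = len(kinds)
    geno = np.empty((n_sel, ped.config.n_markers), dtype=np.int8)
    for kind, mat in ((0, ped.father_geno), (1, ped.mother_geno), (2, ped.off_geno)):
        mask = kinds == kind
        geno[mask] = mat[indices[mask]]

    # disease status exists only for phenotyped offspring, so case/control
    # targeting draws from offspring entries alone (80% one status, 20% the
    # other); every other scenario draws from all selected individuals
    eligible = np.ones(n_sel, dtype=bool)
    if spec.mode == "MCAR" or spec.target == "random":
        group = None
    elif spec.target == "small_pop":
        group = pop == 0
    elif spec.target == "large_pop":
        group = pop == 1
    elif spec.target == "males":
        group = sex == 1
    elif spec.target == "females":
        group = sex == 2
    elif spec.target == "cases":
        group = is_case
        eligible = kinds == 2
    elif spec.target == "controls":
        group = is_control
        eligible = kinds == 2
    else:
        group = spec.target  # per-marker genotype targets handled below

    n_spilled = 0
    k = int(round(spec.rate * n_sel))
    all_rows = np.arange(n_sel)
    miss = np.zeros((n_sel, ped.config.n_markers), dtype=bool)
    for j in range(ped.config.n_markers):
        if k == 0:
            break
        if group is None:
            rows = rng.choice(n_sel, size=k, replace=False)
        else:
            if isinstance(group, str):
                tgt = geno[:, j] == (1 if group == "heterozygotes" else 2)
            else:
                tgt = group
            t_rows = all_rows[tgt & eligible]
            o_rows = all_rows[~tgt & eligible]
            k_t = int(round(spec.split * k))
            k_o = k - k_t
            if k_t > len(t_rows):  # target too small: spill outward
                n_spilled += k_t - len(t_rows)
                k_o += k_t - len(t_rows)
                k_t = len(t_rows)
            if k_o > len(o_rows):  # complement too small: spill inward
                n_spilled += k_o - len(o_rows)
                k_t = min(k_t + (k_o - len(o_rows)), len(t_rows))
                k_o = len(o_rows)
            picks = []
            if k_t:
                picks.append(rng.choice(t_rows, size=k_t, replace=False))
            if k_o:
                picks.append(rng.choice(o_rows, size=k_o, replace=False))
            rows = np.concatenate(picks) if picks else np.empty(0, dtype=int)
        miss[rows, j] = True

    for kind, mat in ((0, out.father_geno), (1, out.mother_geno), (2, out.off_geno)):
        sel = kinds == kind
        rows = indices[sel]
        sub = mat[rows]
        sub[miss[sel]] = MISSING
        mat[rows] = sub

    out.n_missing_spilled = n_spilled
    return out
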