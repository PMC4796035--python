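"""Marker scans, BH-FDR calling, and the FBAT-vs-CIFBAT evaluation harness.

This module is the engine behind the simulation study: it runs FBAT and
CIFBAT across all markers of a (simulated or real) trio dataset using
vectorised dosage matrices, applies Benjamini-Hochberg FDR control to the
FBAT p-values, transfers the BH-derived p-value threshold to the CIFBAT
quantile intervals, and scores both call sets against a known causative
marker set (recall, precision, specificity, NPV, F-measure).
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from scipy import stats

from .cifbat import completion_scores
from .genetics import Chrom, MendelianError, Model, Sex, score_tables
from .simulation import (
    MissingnessSpec,
    PedigreeSet,
    SimConfig,
    assign_disease,
    calibrate_prevalence,
    inject_missingness,
    select_case_control,
    simulate_families,
)

__all__ = [
    "bh_fdr",
    "confusion_metrics",
    "marker_scan",
    "evaluate_run",
    "run_scenario",
    "null_scenario",
    "summarize_runs",
]


def bh_fdr(pvalues, q: float = 0.10) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns a boolean rejection array aligned with the input (NaN p-values
    are never rejected and do not count toward m) and the step-up p-value
    threshold: the largest p(i) with p(i) <= q*i/m, or 0.0 when nothing is
    rejected.  The threshold is what the CIFBAT interval rule consumes.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    m = int(valid.sum())
    reject = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return reject, 0.0
    pv = p[valid]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return reject, 0.0
    kmax = passing[-1]
    threshold = float(ranked[kmax])
    reject[valid] = pv <= threshold
    return reject, threshold


def confusion_metrics(calls: np.ndarray, truth: np.ndarray) -> dict:
    """Recall, precision, specificity, NPV and F-measure from call/truth masks.

    Undefined ratios (empty denominator) are reported as 0.0 with a
    ``*_defined`` flag so aggregation never silently divides by zero.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))

    def ratio(num: int, den: int) -> tuple[float, bool]:
        return (num / den, True) if den else (0.0, False)

    recall, recall_def = ratio(tp, tp + fn)
    precision, precision_def = ratio(tp, tp + fp)
    specificity, _ = ratio(tn, tn + fp)
    npv, _ = ratio(tn, tn + fn)
    f = 2 * recall * precision / (recall + precision) if recall + precision > 0 else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "recall": recall,
        "precision": precision,
        "specificity": specificity,
        "npv": npv,
        "f_measure": f,
        "recall_defined": recall_def,
        "precision_defined": precision_def,
    }


def _pattern_tables(model: Model, chrom: Chrom, sex: Sex):
    """Per-pattern completion scores packed for vectorised sampling.

    A pattern id encodes (father, mother, offspring) with -1 for missing as
    pid = (f+1)*16 + (m+1)*4 + (o+1).  For each incomplete, admissible
    pattern the tables hold its completion count and padded score arrays;
    ``valid[pid]`` is False for complete patterns and for observed members
    that are already inconsistent (such trios are excluded from sampling).
    """
    key = (Model(model), Chrom(chrom), Sex(sex))
    cached = _pattern_tables._cache.get(key)
    if cached is not None:
        return cached
    kmax = 15  # fully missing autosomal trio has 15 completions
    n_comp = np.zeros(64, dtype=np.intp)
    comp_xme = np.zeros((64, kmax))
    comp_var = np.zeros((64, kmax))
    valid = np.zeros(64, dtype=bool)
    for f in (-1, 0, 1, 2):
        for m in (-1, 0, 1, 2):
            for o in (-1, 0, 1, 2):
                if f >= 0 and m >= 0 and o >= 0:
                    continue
                pid = (f + 1) * 16 + (m + 1) * 4 + (o + 1)
                try:
                    xme, var = completion_scores(f, m, o, key[2], key[0], key[1])
                except (MendelianError, ValueError):
                    continue
                k = xme.shape[0]
                n_comp[pid] = k
                comp_xme[pid, :k] = xme
                comp_var[pid, :k] = var
                valid[pid] = True
    _pattern_tables._cache[key] = (n_comp, comp_xme, comp_var, valid)
    return _pattern_tables._cache[key]


_pattern_tables._cache = {}


def marker_scan(
    fathers: np.ndarray,
    mothers: np.ndarray,
    offspring: np.ndarray,
    affected: np.ndarray,
    model: Model = Model.ADDITIVE,
    mu: float = 0.5,
    n_iterations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """FBAT + CIFBAT across all markers of an autosomal trio dataset.

    ``fathers``/``mothers``/``offspring`` are (n_trios, n_markers) dosage
    matrices with -1 for missing.  Complete consistent trios feed the FBAT
    statistic; incomplete admissible trios feed the CIFBAT quantile interval
    (``n_iterations`` randomized completions, linear-interpolation empirical
    quantiles).  Each marker uses an independent substream derived from
    ``(seed, marker index)`` so results do not depend on evaluation order.
    """
    model = Model(model)
    code, ex, var, cons = score_tables(model, Chrom.AUTOSOMAL, Sex.FEMALE)
    F, M, O = (np.asarray(a) for a in (fathers, mothers, offspring))
    observed = (F >= 0) & (M >= 0) & (O >= 0)
    Fc, Mc, Oc = (np.where(a >= 0, a, 0) for a in (F, M, O))
    consistent = cons[Fc, Mc, Oc] & observed
    n_mendel = (observed & ~cons[Fc, Mc, Oc]).sum(axis=0)

    T = np.where(np.asarray(affected, dtype=bool), 1.0 - mu, -mu)
    xme = code[Oc] - ex[Fc, Mc]
    vx = var[Fc, Mc]
    u = np.einsum("t,tm->m", T, np.where(consistent, xme, 0.0))
    var_u = np.einsum("t,tm->m", T * T, np.where(consistent, vx, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var_u > 0, u / np.sqrt(var_u), np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    n_complete = consistent.sum(axis=0)
    n_informative = (consistent & (vx > 0)).sum(axis=0)

    n_comp, comp_xme, comp_var, valid = _pattern_tables(model, Chrom.AUTOSOMAL, Sex.FEMALE)
    pid = (F + 1) * 16 + (M + 1) * 4 + (O + 1)
    incomplete = ~observed

    n_markers = F.shape[1]
    z_lo = np.empty(n_markers)
    z_hi = np.empty(n_markers)
    z_med = np.empty(n_markers)
    n_inc = np.zeros(n_markers, dtype=int)
    qs = (alpha / 2.0, 0.5, 1.0 - alpha / 2.0)
    for j in range(n_markers):
        rows = np.flatnonzero(incomplete[:, j])
        pj = pid[rows, j]
        ok = valid[pj]
        rows, pj = rows[ok], pj[ok]
        d = rows.size
        n_inc[j] = d
        if d == 0:
            zz = z[j] if not math.isnan(z[j]) else 0.0
            z_lo[j] = z_hi[j] = z_med[j] = zz
            continue
        rng = np.random.default_rng([seed, j])
        draws = (rng.random((n_iterations, d)) * n_comp[pj]).astype(np.intp)
        cols = np.arange(d)
        xme_d = comp_xme[pj][cols, draws]
        var_d = comp_var[pj][cols, draws]
        t_d = T[rows]
        u_r = u[j] + xme_d @ t_d
        v_r = var_u[j] + var_d @ (t_d * t_d)
        with np.errstate(invalid="ignore", divide="ignore"):
            z_r = np.where(v_r > 0, u_r / np.sqrt(v_r), 0.0)
        z_lo[j], z_med[j], z_hi[j] = np.quantile(z_r, qs, method="linear")

    p_at_lo = 2.0 * stats.norm.sf(np.abs(z_lo))
    p_at_hi = 2.0 * stats.norm.sf(np.abs(z_hi))
    return pd.DataFrame(
        {
            "z": z,
            "pvalue": pvals,
            "n_complete": n_complete,
            "n_informative": n_informative,
            "n_mendel_excluded": n_mendel,
            "n_incomplete": n_inc,
            "z_lo": z_lo,
            "z_median": z_med,
            "z_hi": z_hi,
            "p_at_lo": p_at_lo,
            "p_at_hi": p_at_hi,
        }
    )


def interval_below(scan: pd.DataFrame, p_threshold: float) -> np.ndarray:
    """Markers whose entire CIFBAT p-value spread lies below the threshold."""
    same_side = (scan["z_lo"] > 0) & (scan["z_hi"] > 0) | (scan["z_lo"] < 0) & (
        scan["z_hi"] < 0
    )
    return (
        same_side & (scan["p_at_lo"] < p_threshold) & (scan["p_at_hi"] < p_threshold)
    ).to_numpy()


def evaluate_run(
    scan: pd.DataFrame,
    causative: np.ndarray,
    q: float = 0.10,
) -> dict:
    """Score FBAT and CIFBAT calls of one run against the causative set.

    FBAT calls are BH rejections at FDR ``q``; CIFBAT calls are the markers
    whose quantile interval is entirely below the BH-derived p-value
    threshold.
    """
    n_markers = len(scan)
    truth = np.zeros(n_markers, dtype=bool)
    truth[np.asarray(causative)] = True
    fbat_calls, threshold = bh_fdr(scan["pvalue"].to_numpy(), q)
    cifbat_calls = (
        interval_below(scan, threshold) if threshold > 0 else np.zeros(n_markers, dtype=bool)
    )
    out = {"p_threshold": threshold}
    for name, calls in (("fbat", fbat_calls), ("cifbat", cifbat_calls)):
        for key, val in confusion_metrics(calls, truth).items():
            out[f"{name}_{key}"] = val
    return out


def summarize_runs(df: pd.DataFrame) -> dict:
    """Aggregate per-run metrics into one row per scenario cell.

    Recall averages over all runs; precision averages over runs that made at
    least one call (a run with zero calls has no precision, and counting it
    as 0 would punish abstention); the F-measure is the harmonic mean of the
    aggregated recall and precision columns.
    """
    out = {"n_runs": len(df)}
    for alg in ("fbat", "cifbat"):
        recall = float(df[f"{alg}_recall"].mean())
        defined = df[df[f"{alg}_precision_defined"]]
        precision = float(defined[f"{alg}_precision"].mean()) if len(defined) else 0.0
        f = 2 * recall * precision / (recall + precision) if recall + precision > 0 else 0.0
        out[f"{alg}_recall"] = recall
        out[f"{alg}_precision"] = precision
        out[f"{alg}_f_measure"] = f
        out[f"{alg}_specificity"] = float(df[f"{alg}_specificity"].mean())
        out[f"{alg}_npv"] = float(df[f"{alg}_npv"].mean())
        out[f"{alg}_runs_with_calls"] = int(df[f"{alg}_precision_defined"].sum())
    return out


def _single_run(
    cfg: SimConfig,
    mspec: MissingnessSpec,
    rng: np.random.Generator,
    scan_seed: int,
    null_phenotype: bool,
) -> tuple[pd.DataFrame, PedigreeSet, np.ndarray, np.ndarray]:
    ped = simulate_families(cfg, rng)
    if null_phenotype:
        ped.affected = rng.random(ped.n_offspring) < 0.5
        ped.causative = np.empty(0, dtype=int)
    else:
        assign_disease(ped, rng)
    cases, controls = select_case_control(ped, rng, allow_trim=null_phenotype)
    ped_miss = inject_missingness(ped, cases, controls, mspec, rng)
    trios = np.concatenate([cases, controls])
    F, M, O = ped_miss.trio_genotypes(trios)
    aff = ped_miss.affected[trios]
    scan = marker_scan(
        F,
        M,
        O,
        aff,
        model=Model.ADDITIVE,
        mu=cfg.mu,
        n_iterations=cfg.cifbat_iterations,
        alpha=cfg.alpha,
        seed=scan_seed,
    )
    return scan, ped, cases, controls


def run_scenario(
    cfg: SimConfig,
    mspec: MissingnessSpec,
    n_runs: int,
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Repeat simulate -> inject -> FBAT/CIFBAT -> evaluate for one scenario.

    Returns one row of metrics per run; aggregate with mean/sem.  The
    configuration must carry a calibrated ``p_env`` (calibrated here once if
    absent).  ``seed`` drives every source of randomness; per-run substreams
    come from ``(seed, run index)``.
    """
    if cfg.p_env is None:
        cfg = cfg.replace(p_env=calibrate_prevalence(cfg, np.random.default_rng([seed, 10**6])))
    rows = []
    for r in range(n_runs):
        rng = np.random.default_rng([seed, r])
        scan, ped, cases, _ = _single_run(cfg, mspec, rng, scan_seed=(seed * 100003 + r) % 2**31, null_phenotype=False)
        row = evaluate_run(scan, ped.causative, cfg.fdr)
        row.update(
            run=r,
            prevalence=ped.prevalence,
            n_cases=len(cases),
            mode=mspec.mode,
            target=mspec.target,
            rate=mspec.rate,
        )
        rows.append(row)
        if progress:
            print(f"run {r + 1}/{n_runs} done", flush=True)
    df = pd.DataFrame(rows)
    df.attrs["p_env"] = cfg.p_env
    return df


def null_scenario(
    cfg: SimConfig,
    rates: tuple[float, ...],
    n_runs: int,
    seed: int = 0,
    p_cut: float = 0.1,
) -> pd.DataFrame:
    """Null-phenotype MCAR study: FBAT false-positive rate and interval fractions.

    Phenotypes are uniformly random coin flips; for each MCAR rate the run
    records the fraction of markers with FBAT p below ``p_cut`` (no FDR
    correction), the fraction of CIFBAT quantile intervals lying entirely
    below ``p_cut``, and the count of markers significant under the
    BH-at-``cfg.fdr`` CIFBAT procedure.
    """
    rows = []
    for r in range(n_runs):
        for i, rate in enumerate(rates):
            rng = np.random.default_rng([seed, r, i])
            mspec = MissingnessSpec(mode="MCAR", target="random", rate=rate)
            scan, ped, *_ = _single_run(
                cfg, mspec, rng, scan_seed=(seed * 100003 + r * 17 + i) % 2**31, null_phenotype=True
            )
            valid = ~scan["pvalue"].isna()
            frac_p = float((scan.loc[valid, "pvalue"] < p_cut).mean())
            frac_int = float(interval_below(scan, p_cut).mean())
            _, threshold = bh_fdr(scan["pvalue"].to_numpy(), cfg.fdr)
            n_bh_cifbat = (
                int(interval_below(scan, threshold).sum()) if threshold > 0 else 0
            )
            rows.append(
                {
                    "run": r,
                    "rate": rate,
                    "frac_fbat_p_below": frac_p,
                    "frac_interval_below": frac_int,
                    "n_cifbat_bh_significant": n_bh_cifbat,
                }
            )
    return pd.DataFrame(rows)
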