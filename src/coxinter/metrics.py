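"""Monte-Carlo performance measures for one simulation condition.

Replicate-level fit results are aggregated into the standard simulation-study
measures: bias (absolute, or relative in % when the true coefficient is
nonzero), the relative % error of the model standard error
``100*(ModSE/EmpSE - 1)`` with ``ModSE = sqrt(mean variance estimate)`` and
``EmpSE`` the across-replicate SD of the estimates, coverage of 95% Wald and
profile-likelihood intervals, and the rejection rate of the zero-coefficient
test (type I error under the null, power otherwise).

Two summary modes mirror the study's primary and sensitivity analyses:

* ``converged_only`` — denominators are the eligible replicates whose fit
  converged (``N_c``); PL coverage additionally requires both profile bounds
  to have converged, and PL power requires a computable likelihood-ratio
  statistic at zero;
* ``sensitivity`` — non-converged fits are counted as covering the truth and
  not rejecting the null, with denominator ``N_eligible``.

Ineligible replicates (more than one empty marker-treatment event cell) are
excluded from every denominator in both modes.  Every rate carries a binomial
Monte-Carlo standard error and the SE-ratio carries a jackknife one, so
downstream comparisons can use principled tolerances.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "bias",
    "relative_bias",
    "rel_se_error",
    "coverage",
    "rejection_rate",
    "summarize",
    "SUMMARY_COLUMNS",
]


def bias(estimates, truth: float) -> float:
    """Mean estimate minus the true value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("bias requires at least one estimate")
    return float(np.mean(estimates) - truth)


def relative_bias(estimates, truth: float) -> float:
    """Mean of ``(estimate - truth)/|truth|`` in percent; undefined at truth 0."""
    if truth == 0.0:
        raise ValueError("relative bias is undefined when the true value is 0")
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("relative bias requires at least one estimate")
    return float(np.mean((estimates - truth) / abs(truth)) * 100.0)


def _modse_empse(variances, estimates) -> tuple[float, float]:
    variances = np.asarray(variances, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    modse = math.sqrt(float(np.mean(variances)))
    empse = float(np.std(estimates, ddof=1))
    return modse, empse


def rel_se_error(variances, estimates) -> float:
    """Relative % error of the model SE: ``100*(ModSE/EmpSE - 1)``."""
    variances = np.asarray(variances, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2 or variances.size != estimates.size:
        raise ValueError("need >= 2 paired (variance, estimate) values")
    if np.any(variances < 0.0):
        raise ValueError("variance estimates must be nonnegative")
    modse, empse = _modse_empse(variances, estimates)
    if empse == 0.0:
        raise ValueError("empirical SE is zero; relative SE error undefined")
    return 100.0 * (modse / empse - 1.0)


def _jackknife_se_ratio(variances, estimates) -> float:
    """Jackknife MC standard error of ``100*(ModSE/EmpSE - 1)``."""
    v = np.asarray(variances, dtype=float)
    b = np.asarray(estimates, dtype=float)
    m = b.size
    if m < 3:
        return math.nan
    sv, s1, s2 = v.sum(), b.sum(), (b * b).sum()
    mod_i = np.sqrt((sv - v) / (m - 1))
    mean_i = (s1 - b) / (m - 1)
    ss_i = s2 - b * b - (m - 1) * mean_i**2
    emp_i = np.sqrt(np.maximum(ss_i, 0.0) / (m - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_i = 100.0 * (mod_i / emp_i - 1.0)
    r_i = r_i[np.isfinite(r_i)]
    if r_i.size < 3:
        return math.nan
    return float(np.sqrt((r_i.size - 1) / r_i.size * np.sum((r_i - r_i.mean()) ** 2)))


def coverage(intervals, truth: float) -> float:
    """Percent of closed intervals ``(lo, hi)`` containing the truth."""
    arr = np.asarray(intervals, dtype=float)
    if arr.size == 0:
        raise ValueError("coverage requires at least one interval")
    lo, hi = arr[:, 0], arr[:, 1]
    return float(np.mean((lo <= truth) & (truth <= hi)) * 100.0)


def rejection_rate(p_values, alpha: float = 0.05) -> float:
    """Percent of p-values at or below alpha (``p = alpha`` rejects)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("rejection rate requires at least one p-value")
    return float(np.mean(p <= alpha) * 100.0)


def _rate(numer: int, denom: int) -> tuple[float, float]:
    """Percent and its binomial MC standard error; NaN on empty denominator."""
    if denom == 0:
        return math.nan, math.nan
    p = numer / denom
    return 100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / denom)


#: stable column order of the summary table
SUMMARY_COLUMNS = [
    "method", "coefficient", "mode", "truth",
    "n_generated", "n_eligible", "n_converged",
    "bias", "mcse_bias", "relative_bias_pct", "mcse_relative_bias_pct",
    "modse", "empse", "rel_se_error_pct", "mcse_rel_se_error_pct",
    "coverage_wald_pct", "mcse_coverage_wald_pct",
    "coverage_pl_pct", "mcse_coverage_pl_pct",
    "reject_wald_pct", "mcse_reject_wald_pct",
    "reject_pl_pct", "mcse_reject_pl_pct",
    "rate_label",
    "n_pl_lo_converged", "n_pl_hi_converged", "n_pl_interval", "n_lr",
]

_COEF_FIELDS = {
    # coefficient -> (fit prefix, estimate column suffix, variance suffix)
    "beta_I": ("", "beta_I", "var_I"),
    "beta_TM_low": ("sub_", "beta_low", "var_low"),
    "beta_TM_high": ("sub_", "beta_high", "var_high"),
}


def summarize(replicates: pd.DataFrame, truths: dict[str, float],
              alpha: float = 0.05, methods=("mple", "firth"),
              modes=("converged_only", "sensitivity"),
              scenario=None) -> pd.DataFrame:
    """Aggregate per-replicate fit records into performance measures.

    ``replicates`` is the table produced by :func:`coxinter.runner.run_scenario`
    (one row per generated dataset).  Undefined measures (empty denominators,
    relative bias at truth 0) are reported as NaN, never silently as zero.
    """
    rows = []
    n_generated = len(replicates)
    elig = replicates["eligible"].to_numpy(dtype=bool)
    n_eligible = int(elig.sum())

    for method in methods:
        for coef, (prefix, est_col, var_col) in _COEF_FIELDS.items():
            conv_col = f"{method}_{prefix}conv"
            est_name = f"{method}_{est_col}"
            if conv_col not in replicates.columns or est_name not in replicates.columns:
                continue
            truth = truths[coef]
            conv = replicates[conv_col].to_numpy(dtype=bool) & elig
            n_conv = int(conv.sum())
            est = replicates[est_name].to_numpy(dtype=float)[conv]
            var = replicates[f"{method}_{var_col}"].to_numpy(dtype=float)[conv]

            base = {
                "method": method, "coefficient": coef, "truth": truth,
                "n_generated": n_generated, "n_eligible": n_eligible,
                "n_converged": n_conv,
                "rate_label": "type_I_error" if truth == 0.0 else "power",
            }
            est_stats = {k: math.nan for k in (
                "bias", "mcse_bias", "relative_bias_pct",
                "mcse_relative_bias_pct", "modse", "empse",
                "rel_se_error_pct", "mcse_rel_se_error_pct")}
            if n_conv >= 2:
                modse, empse = _modse_empse(var, est)
                est_stats["bias"] = bias(est, truth)
                est_stats["mcse_bias"] = empse / math.sqrt(n_conv)
                if truth != 0.0:
                    est_stats["relative_bias_pct"] = relative_bias(est, truth)
                    est_stats["mcse_relative_bias_pct"] = (
                        100.0 * empse / abs(truth) / math.sqrt(n_conv)
                    )
                est_stats["modse"] = modse
                est_stats["empse"] = empse
                if empse > 0.0:
                    est_stats["rel_se_error_pct"] = rel_se_error(var, est)
                    est_stats["mcse_rel_se_error_pct"] = _jackknife_se_ratio(var, est)

            has_iv = f"{method}_wald_lo" in replicates.columns and coef == "beta_I"
            for mode in modes:
                row = dict(base)
                row["mode"] = mode
                row.update(est_stats)
                for k in ("coverage_wald_pct", "mcse_coverage_wald_pct",
                          "coverage_pl_pct", "mcse_coverage_pl_pct",
                          "reject_wald_pct", "mcse_reject_wald_pct",
                          "reject_pl_pct", "mcse_reject_pl_pct"):
                    row[k] = math.nan
                row["n_pl_lo_converged"] = row["n_pl_hi_converged"] = 0
                row["n_pl_interval"] = row["n_lr"] = 0
                if has_iv:
                    _interval_rates(row, replicates, method, conv, elig,
                                    truth, alpha, mode)
                rows.append(row)

    df = pd.DataFrame(rows)
    if scenario is not None:
        for k in ("n", "p_M", "p_T", "p_e", "p_c", "t_end",
                  "OR_MT", "HR_M", "HR_T", "HR_I", "master_seed"):
            df[k] = getattr(scenario, k)
        df["scenario_key"] = scenario.key
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def _interval_rates(row, replicates, method, conv, elig, truth, alpha, mode):
    get = lambda c: replicates[c].to_numpy(dtype=float)
    getb = lambda c: replicates[c].to_numpy(dtype=bool)

    wald_lo, wald_hi = get(f"{method}_wald_lo"), get(f"{method}_wald_hi")
    wald_p = get(f"{method}_wald_p")
    wald_cov = conv & (wald_lo <= truth) & (truth <= wald_hi)
    wald_rej = conv & (wald_p <= alpha)

    has_pl = f"{method}_pl_lo" in replicates.columns
    has_lr = f"{method}_lr_p" in replicates.columns
    if has_pl:
        pl_lo_c = getb(f"{method}_pl_lo_conv") & conv
        pl_hi_c = getb(f"{method}_pl_hi_conv") & conv
        pl_both = pl_lo_c & pl_hi_c
        pl_lo, pl_hi = get(f"{method}_pl_lo"), get(f"{method}_pl_hi")
        pl_cov = pl_both & (pl_lo <= truth) & (truth <= pl_hi)
        row["n_pl_lo_converged"] = int(pl_lo_c.sum())
        row["n_pl_hi_converged"] = int(pl_hi_c.sum())
        row["n_pl_interval"] = int(pl_both.sum())
    if has_lr:
        lr_ok = getb(f"{method}_lr_ok") & conv
        lr_p = get(f"{method}_lr_p")
        lr_rej = lr_ok & (lr_p <= alpha)
        row["n_lr"] = int(lr_ok.sum())

    n_elig = int(elig.sum())
    n_conv = int(conv.sum())
    if mode == "converged_only":
        row["coverage_wald_pct"], row["mcse_coverage_wald_pct"] = _rate(
            int(wald_cov.sum()), n_conv)
        row["reject_wald_pct"], row["mcse_reject_wald_pct"] = _rate(
            int(wald_rej.sum()), n_conv)
        if has_pl:
            row["coverage_pl_pct"], row["mcse_coverage_pl_pct"] = _rate(
                int(pl_cov.sum()), row["n_pl_interval"])
        if has_lr:
            row["reject_pl_pct"], row["mcse_reject_pl_pct"] = _rate(
                int(lr_rej.sum()), row["n_lr"])
    else:  # sensitivity: non-converged cover and do not reject
        row["coverage_wald_pct"], row["mcse_coverage_wald_pct"] = _rate(
            int(wald_cov.sum()) + (n_elig - n_conv), n_elig)
        row["reject_wald_pct"], row["mcse_reject_wald_pct"] = _rate(
            int(wald_rej.sum()), n_elig)
        if has_pl:
            row["coverage_pl_pct"], row["mcse_coverage_pl_pct"] = _rate(
                int(pl_cov.sum()) + (n_elig - row["n_pl_interval"]), n_elig)
        if has_lr:
            row["reject_pl_pct"], row["mcse_reject_pl_pct"] = _rate(
                int(lr_rej.sum()), n_elig)
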