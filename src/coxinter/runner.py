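"""Scenario orchestration: replicate loops, summaries, power, table replicas.

The runner owns the generate -> screen -> fit -> summarize pipeline for one
scenario and the desk-scale reproduction of the published result tables.
Replicates are generated from dedicated seed substreams, so results are
independent of execution order and bit-identical across runs for a fixed
manifest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .coxcore import (
    BETA_I, BETA_TM_HIGH, BETA_TM_LOW, SolverSettings, fit, interval_estimate,
    prepare,
)
from .datagen import assemble, eligibility
from .metrics import summarize
from .reference_tables import (
    COLUMNS, REFERENCE, REFERENCE_N, TABLE_NS, TABLE_SCENARIOS, table_scenario,
)
from .scenarios import Scenario

__all__ = [
    "RunManifest",
    "run_scenario",
    "power",
    "replicate_table",
]

logger = logging.getLogger("coxinter")


@dataclass
class RunManifest:
    """Everything that determines one run's outputs bit-for-bit."""

    scenario_keys: list[str]
    reps: int
    settings: SolverSettings
    alpha: float
    mode: str
    master_seed: int
    out_dir: str = ""
    version: str = field(default=__version__)

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2, sort_keys=True)


def _empty_summary(scenario: Scenario) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"method": m, "coefficient": c, "mode": mode, "n_generated": 0,
          "n_eligible": 0, "n_converged": 0}
         for m in ("mple", "firth") for c in ("beta_I",)
         for mode in ("converged_only", "sensitivity")]
    )
    df["scenario_key"] = scenario.key
    return df


def run_scenario(
    scenario: Scenario,
    reps: int | None = None,
    settings: SolverSettings | None = None,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("mple", "firth"),
    subgroup: bool = True,
    pl_intervals: bool = True,
    lr_tests: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one scenario for ``reps`` replicates (default ``scenario.N``).

    Returns ``(summary, replicates)``: the performance-measure table in both
    summary modes and the per-replicate audit records.  ``pl_intervals`` /
    ``lr_tests`` / ``subgroup`` switch off the profile-likelihood interval
    search, likelihood-ratio tests and subgroup-parametrization fits for
    lean runs that only need a subset of the measures.
    """
    settings = settings or SolverSettings()
    reps = scenario.N if reps is None else int(reps)
    records: list[dict] = []
    n_inelig = 0
    n_nonconv = {m: 0 for m in methods}
    for r in range(reps):
        ds = assemble(scenario, r)
        row: dict = {"replicate": r, "eligible": eligibility(ds)}
        if not row["eligible"]:
            n_inelig += 1
            for m in methods:
                row[f"{m}_conv"] = False
                if subgroup:
                    row[f"{m}_sub_conv"] = False
            records.append(row)
            continue
        pd_int = prepare(ds, "interaction")
        pd_sub = prepare(ds, "subgroup") if subgroup else None
        for m in methods:
            res = fit(pd_int, "interaction", m, settings)
            row[f"{m}_conv"] = res.converged
            row[f"{m}_iters"] = res.iterations
            if not res.converged:
                n_nonconv[m] += 1
            row[f"{m}_beta_I"] = res.coefficients[BETA_I] if res.converged else math.nan
            row[f"{m}_var_I"] = res.covariance[BETA_I, BETA_I] if res.converged else math.nan
            iv = interval_estimate(pd_int, res, BETA_I, alpha, settings,
                                   pl=pl_intervals, lr=lr_tests)
            row[f"{m}_wald_lo"] = iv.wald_lo
            row[f"{m}_wald_hi"] = iv.wald_hi
            row[f"{m}_wald_p"] = iv.wald_p
            if pl_intervals:
                row[f"{m}_pl_lo"] = iv.pl_lo
                row[f"{m}_pl_hi"] = iv.pl_hi
                row[f"{m}_pl_lo_conv"] = iv.pl_lo_converged
                row[f"{m}_pl_hi_conv"] = iv.pl_hi_converged
            if lr_tests:
                row[f"{m}_lr_p"] = iv.lr_p
                row[f"{m}_lr_ok"] = iv.lr_ok
            if subgroup:
                res_s = fit(pd_sub, "subgroup", m, settings)
                row[f"{m}_sub_conv"] = res_s.converged
                row[f"{m}_beta_low"] = (
                    res_s.coefficients[BETA_TM_LOW] if res_s.converged else math.nan)
                row[f"{m}_var_low"] = (
                    res_s.covariance[BETA_TM_LOW, BETA_TM_LOW]
                    if res_s.converged else math.nan)
                row[f"{m}_beta_high"] = (
                    res_s.coefficients[BETA_TM_HIGH] if res_s.converged else math.nan)
                row[f"{m}_var_high"] = (
                    res_s.covariance[BETA_TM_HIGH, BETA_TM_HIGH]
                    if res_s.converged else math.nan)
        records.append(row)

    replicates = pd.DataFrame(records)
    # guarantee a stable schema even when no replicate was fitted
    expected: list[str] = ["replicate", "eligible"]
    for m in methods:
        expected += [f"{m}_conv", f"{m}_iters", f"{m}_beta_I", f"{m}_var_I",
                     f"{m}_wald_lo", f"{m}_wald_hi", f"{m}_wald_p"]
        if pl_intervals:
            expected += [f"{m}_pl_lo", f"{m}_pl_hi",
                         f"{m}_pl_lo_conv", f"{m}_pl_hi_conv"]
        if lr_tests:
            expected += [f"{m}_lr_p", f"{m}_lr_ok"]
        if subgroup:
            expected += [f"{m}_sub_conv", f"{m}_beta_low", f"{m}_var_low",
                         f"{m}_beta_high", f"{m}_var_high"]
    for col in expected:
        if col not in replicates.columns:
            default = False if col.endswith(("_conv", "_ok", "eligible")) else math.nan
            replicates[col] = default
    if reps == 0:
        logger.info("scenario %s: 0 replicates requested", scenario.key)
        return _empty_summary(scenario), replicates

    summary = summarize(replicates, scenario.truths(), alpha=alpha,
                        methods=methods, scenario=scenario)
    logger.info(
        "scenario %s: reps=%d ineligible=%d non-converged=%s",
        scenario.key, reps, n_inelig,
        {m: n_nonconv[m] for m in methods},
    )
    return summary, replicates


def power(
    scenario: Scenario,
    reps: int | None = None,
    alpha: float = 0.05,
    method: str = "mple",
    ci_method: str = "wald",
    settings: SolverSettings | None = None,
) -> dict:
    """Simulation-based power of the interaction test.

    Rejection rate of the ``beta_I = 0`` test over eligible, converged
    replicates (under the null scenario ``HR_I = 1`` this estimates the type I
    error).  ``ci_method`` selects the Wald test or the (penalized)
    likelihood-ratio test underlying the profile-likelihood CI.  The estimate
    comes with a binomial Monte-Carlo 95% interval, degenerate (and flagged)
    when fewer than two usable replicates exist.
    """
    if ci_method not in ("wald", "pl"):
        raise ValueError("ci_method must be 'wald' or 'pl'")
    _, replicates = run_scenario(
        scenario, reps=reps, settings=settings, alpha=alpha, methods=(method,),
        subgroup=False, pl_intervals=False, lr_tests=(ci_method == "pl"),
    )
    elig = replicates["eligible"].to_numpy(dtype=bool)
    conv = replicates.get(f"{method}_conv")
    conv = conv.to_numpy(dtype=bool) & elig if conv is not None else elig & False
    if ci_method == "wald":
        usable = conv
        pvals = replicates.get(f"{method}_wald_p")
    else:
        ok = replicates.get(f"{method}_lr_ok")
        usable = conv & (ok.to_numpy(dtype=bool) if ok is not None else False)
        pvals = replicates.get(f"{method}_lr_p")
    n_used = int(usable.sum())
    if n_used == 0:
        est = math.nan
        mc_se = math.nan
    else:
        p = pvals.to_numpy(dtype=float)[usable]
        est = float(np.mean(p <= alpha) * 100.0)
        mc_se = 100.0 * math.sqrt((est / 100.0) * (1.0 - est / 100.0) / n_used)
    degenerate = n_used < 2 or est in (0.0, 100.0)
    return {
        "power_pct": est,
        "mc_se_pct": mc_se,
        "mc_lo_pct": max(est - 1.96 * mc_se, 0.0) if n_used else math.nan,
        "mc_hi_pct": min(est + 1.96 * mc_se, 100.0) if n_used else math.nan,
        "n_used": n_used,
        "n_eligible": int(elig.sum()),
        "n_generated": len(replicates),
        "alpha": alpha,
        "method": method,
        "ci_method": ci_method,
        "degenerate_mc_interval": bool(degenerate),
    }


def _rate_se(pct: float, n: float) -> float:
    """Binomial SE of a percentage, floored near the 0/100 boundary.

    The floor ``p(1-p) >= 1/(4n)`` keeps comparison tolerances positive for
    cells where the observed rate sits on the boundary.
    """
    if n <= 0:
        return math.nan
    p = min(max(pct / 100.0, 0.0), 1.0)
    return 100.0 * math.sqrt(max(p * (1.0 - p), 0.25 / n) / n)


_CELL_MEASURES = {
    # reference column -> (summary column, mc-se column)
    "bias_low": ("bias", "mcse_bias"),
    "relse_low": ("rel_se_error_pct", "mcse_rel_se_error_pct"),
    "bias_high": ("bias", "mcse_bias"),
    "relse_high": ("rel_se_error_pct", "mcse_rel_se_error_pct"),
    "relbias_I": ("relative_bias_pct", "mcse_relative_bias_pct"),
    "relse_I": ("rel_se_error_pct", "mcse_rel_se_error_pct"),
    "cov_wald": ("coverage_wald_pct", "mcse_coverage_wald_pct"),
    "cov_pl": ("coverage_pl_pct", "mcse_coverage_pl_pct"),
    "power_wald": ("reject_wald_pct", "mcse_reject_wald_pct"),
    "power_pl": ("reject_pl_pct", "mcse_reject_pl_pct"),
}

_CELL_COEF = {
    "bias_low": "beta_TM_low", "relse_low": "beta_TM_low",
    "bias_high": "beta_TM_high", "relse_high": "beta_TM_high",
}


def replicate_table(table_id: str, reps: int = 2000,
                    master_seed: int = 20240620,
                    settings: SolverSettings | None = None,
                    ns: tuple[int, ...] = TABLE_NS) -> pd.DataFrame:
    """Re-run one published table at desk scale and compare cell by cell.

    Runs every (block, n) scenario of table ``t3``/``t4``/``t5`` for ``reps``
    replicates and returns a long table with the recomputed value, the
    published value, and the Monte-Carlo tolerance
    ``3 * sqrt(se_recomputed^2 + se_published^2)`` for each cell.  ``N_c`` is
    compared on the converged *fraction* so reduced-replicate runs remain
    comparable.
    """
    if table_id not in REFERENCE:
        raise ValueError(f"unknown table id {table_id!r}; use one of {sorted(REFERENCE)}")
    spec = TABLE_SCENARIOS[table_id]
    ref = REFERENCE[table_id]
    out = []
    for block_value in spec["block_values"]:
        for n in ns:
            scenario = table_scenario(table_id, block_value, n,
                                      N=reps, master_seed=master_seed)
            summary, _ = run_scenario(scenario, reps=reps, settings=settings)
            summary = summary[summary["mode"] == "converged_only"]
            for method in ("mple", "firth"):
                printed = dict(zip(COLUMNS, ref[(block_value, method, n)]))
                sub = summary[summary["method"] == method].set_index("coefficient")
                for col, (mcol, secol) in _CELL_MEASURES.items():
                    coef = _CELL_COEF.get(col, "beta_I")
                    value = float(sub.loc[coef, mcol])
                    se_ours = float(sub.loc[coef, secol])
                    se_pub = _published_se(col, printed, coef, sub)
                    out.append({
                        "table": table_id, spec["block_key"]: block_value,
                        "n": n, "method": method, "measure": col,
                        "computed": value, "published": printed[col],
                        "mc_tolerance": 3.0 * math.hypot(
                            se_ours if np.isfinite(se_ours) else 0.0,
                            se_pub if np.isfinite(se_pub) else 0.0),
                        "reps": reps,
                    })
                # converged fraction (published count is out of REFERENCE_N)
                n_conv = int(sub.loc["beta_I", "n_converged"])
                frac = 100.0 * n_conv / reps
                frac_pub = 100.0 * printed["N_c"] / REFERENCE_N
                se_ours = _rate_se(frac, reps)
                se_pub = _rate_se(frac_pub, REFERENCE_N)
                out.append({
                    "table": table_id, spec["block_key"]: block_value,
                    "n": n, "method": method, "measure": "converged_pct",
                    "computed": frac, "published": frac_pub,
                    "mc_tolerance": 3.0 * math.hypot(se_ours, se_pub),
                    "reps": reps,
                })
    return pd.DataFrame(out)


def _published_se(col: str, printed: dict, coef: str, sub: pd.DataFrame) -> float:
    """Approximate MC standard error of a published cell at N_c replicates.

    Uses this run's spread estimates (EmpSE, jackknife) rescaled to the
    published converged count — the published table prints no uncertainties.
    """
    n_pub = printed["N_c"]
    if n_pub <= 1:
        return math.nan
    if col in ("cov_wald", "cov_pl", "power_wald", "power_pl"):
        return _rate_se(printed[col], n_pub)
    n_ours = float(sub.loc[coef, "n_converged"])
    se_map = {"bias_low": "mcse_bias", "bias_high": "mcse_bias",
              "relbias_I": "mcse_relative_bias_pct"}
    secol = se_map.get(col, "mcse_rel_se_error_pct")
    se_ours = float(sub.loc[coef, secol])
    if not np.isfinite(se_ours) or n_ours < 2:
        return math.nan
    return se_ours * math.sqrt(n_ours / n_pub)
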