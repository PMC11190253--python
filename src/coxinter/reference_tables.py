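"""Published full-scale Monte-Carlo results used for side-by-side comparison.

Each entry is one summary cell of the original N = 10000-replicate study, for
the standard Cox model ("mple") and the Firth-corrected model ("firth").
Row keys are ``(block_value, method, n)`` where the block value is the factor
varied within the table (``HR_M`` for t3, ``p_M`` for t4, ``OR_MT`` for t5).

Column meanings (per row tuple, in order):
  bias_low      absolute bias of beta_TM_low (treatment effect, low marker)
  relse_low     relative % error of SE(beta_TM_low)
  bias_high     absolute bias of beta_TM_high (treatment effect, high marker)
  relse_high    relative % error of SE(beta_TM_high)
  relbias_I     relative % bias of the interaction coefficient
  relse_I       relative % error of SE(beta_I)
  cov_wald      Wald 95% CI coverage (%)
  cov_pl        profile-likelihood 95% CI coverage (%)
  power_wald    Wald power (%) of the interaction test at alpha = 0.05
  power_pl      profile-likelihood power (%)
  N_c           number of eligible replicates with a converged fit
"""

from __future__ import annotations

from .scenarios import Scenario

__all__ = ["REFERENCE_N", "TABLE_SCENARIOS", "REFERENCE", "COLUMNS", "table_scenario"]

REFERENCE_N = 10000

COLUMNS = (
    "bias_low", "relse_low", "bias_high", "relse_high", "relbias_I",
    "relse_I", "cov_wald", "cov_pl", "power_wald", "power_pl", "N_c",
)

#: per table: the factor swept across blocks and the fixed parameters
TABLE_SCENARIOS = {
    "t3": {
        "block_key": "HR_M",
        "block_values": (0.6, 1.0, 3.0),
        "fixed": dict(p_M=0.25, p_T=0.5, p_e=0.2, p_c=0.2, t_end=5.0,
                      OR_MT=1.0, HR_T=1.0, HR_I=0.25),
    },
    "t4": {
        "block_key": "p_M",
        "block_values": (0.25, 0.5, 0.75),
        "fixed": dict(p_T=0.5, p_e=0.2, p_c=0.2, t_end=5.0,
                      OR_MT=0.5, HR_M=0.8, HR_T=1.0, HR_I=0.75),
    },
    "t5": {
        "block_key": "OR_MT",
        "block_values": (0.5, 1.0, 2.0),
        "fixed": dict(p_M=0.5, p_T=0.5, p_e=0.2, p_c=0.2, t_end=5.0,
                      HR_M=1.0, HR_T=1.0, HR_I=0.5),
    },
}

TABLE_NS = (200, 400, 600)

_T3 = {
    (0.6, "mple", 200): (0.0, -1.2, 0.6, 60.2, 46.5, 45.7, 96.6, 96.6, 2.5, 5.0, 4912),
    (0.6, "mple", 400): (0.0, -1.2, 0.2, 35.3, 16.4, 31.0, 96.8, 96.9, 12.6, 23.1, 7671),
    (0.6, "mple", 600): (0.0, -0.7, 0.0, 22.8, 1.6, 21.2, 97.2, 97.3, 33.0, 46.0, 8895),
    (0.6, "firth", 200): (0.0, 3.6, 0.3, 42.8, 19.0, 37.3, 97.6, 96.7, 2.4, 11.3, 9703),
    (0.6, "firth", 400): (0.0, 0.8, 0.1, 22.8, 5.2, 21.1, 96.9, 96.8, 12.2, 29.3, 9995),
    (0.6, "firth", 600): (0.0, 1.2, 0.0, 12.7, 0.5, 12.3, 97.0, 96.6, 31.6, 46.6, 10000),
    (1.0, "mple", 200): (0.0, -1.1, 0.3, 39.3, 23.9, 30.0, 96.6, 96.7, 8.5, 15.2, 6950),
    (1.0, "mple", 400): (0.0, -1.4, 0.0, 19.4, 0.0, 16.8, 97.2, 97.1, 35.6, 46.3, 9129),
    (1.0, "mple", 600): (0.0, -0.6, -0.1, 6.9, -5.7, 6.5, 96.8, 96.0, 61.6, 68.1, 9750),
    (1.0, "firth", 200): (0.0, 3.2, 0.1, 28.3, 8.6, 24.8, 97.2, 96.6, 7.5, 21.5, 9969),
    (1.0, "firth", 400): (0.0, 0.6, 0.0, 11.0, 0.8, 9.9, 97.0, 96.1, 33.7, 46.5, 9999),
    (1.0, "firth", 600): (0.0, 1.1, 0.0, 4.3, -0.5, 4.2, 96.5, 95.3, 59.3, 65.8, 10000),
    (3.0, "mple", 200): (0.0, -1.9, -0.1, 7.8, -4.2, 4.8, 96.4, 95.6, 44.7, 50.2, 9724),
    (3.0, "mple", 400): (0.0, -1.7, 0.0, -2.4, -3.7, -2.1, 95.5, 94.7, 79.4, 81.0, 9991),
    (3.0, "mple", 600): (0.0, -0.5, 0.0, -1.2, -3.2, -0.4, 95.7, 95.1, 93.8, 94.3, 10000),
    (3.0, "firth", 200): (0.0, 2.5, 0.0, 6.5, 0.7, 5.2, 96.6, 95.1, 41.5, 48.8, 10000),
    (3.0, "firth", 400): (0.0, 0.2, 0.0, 1.0, 0.4, 0.9, 95.7, 94.9, 77.5, 80.0, 10000),
    (3.0, "firth", 600): (0.0, 0.8, 0.0, 1.8, -0.5, 2.2, 96.1, 95.5, 93.3, 94.0, 10000),
}

_T4 = {
    (0.25, "mple", 200): (0.0, -2.7, 0.1, 20.4, 33.8, 15.0, 97.2, 96.6, 1.8, 3.2, 8692),
    (0.25, "mple", 400): (0.0, -1.5, 0.0, 2.3, -15.7, 2.3, 96.8, 95.3, 3.8, 6.6, 9855),
    (0.25, "mple", 600): (0.0, -0.2, 0.0, -2.8, -18.4, -2.0, 95.9, 94.6, 6.2, 8.8, 9978),
    (0.25, "firth", 200): (0.0, 3.0, 0.0, 14.0, 11.2, 12.2, 97.6, 96.0, 1.4, 4.2, 9946),
    (0.25, "firth", 400): (0.0, 0.9, 0.0, 3.1, 3.4, 3.3, 97.0, 95.5, 3.1, 6.0, 9999),
    (0.25, "firth", 600): (0.0, 1.3, 0.0, -0.1, -0.8, 0.7, 96.3, 95.1, 5.0, 7.4, 10000),
    (0.5, "mple", 200): (0.0, -1.4, 0.0, -1.4, -20.3, -1.7, 95.9, 94.7, 4.9, 7.1, 9900),
    (0.5, "mple", 400): (0.0, -3.0, 0.0, -2.6, -11.9, -3.1, 95.0, 94.5, 7.9, 9.2, 9999),
    (0.5, "mple", 600): (0.0, -1.3, 0.0, -2.4, -8.2, -2.0, 94.9, 94.5, 10.2, 11.1, 10000),
    (0.5, "firth", 200): (0.0, 4.9, 0.0, 2.7, 2.9, 3.6, 96.8, 95.1, 3.5, 6.0, 9998),
    (0.5, "firth", 400): (0.0, -0.1, 0.0, 1.4, 1.7, 0.5, 95.7, 94.7, 6.3, 7.9, 10000),
    (0.5, "firth", 600): (0.0, 0.7, 0.0, 0.2, 0.5, 0.3, 95.3, 94.9, 8.7, 10.1, 10000),
    (0.75, "mple", 200): (0.0, 5.2, 0.0, -1.5, 0.6, 6.6, 97.2, 96.2, 2.7, 4.6, 9477),
    (0.75, "mple", 400): (0.0, -2.2, 0.0, -0.8, -8.2, -0.5, 95.7, 95.0, 5.9, 7.6, 9911),
    (0.75, "mple", 600): (0.0, -2.3, 0.0, -0.8, -9.6, -1.8, 95.4, 94.9, 8.8, 10.1, 9984),
    (0.75, "firth", 200): (0.0, 6.3, 0.0, 5.5, 20.7, 10.9, 97.6, 96.3, 2.1, 4.0, 9792),
    (0.75, "firth", 400): (0.0, 1.7, 0.0, 2.3, 6.7, 3.0, 96.3, 95.3, 4.9, 6.6, 9947),
    (0.75, "firth", 600): (0.0, 0.6, 0.0, 1.2, 1.1, 0.9, 95.9, 95.2, 7.5, 9.1, 9988),
}

_T5 = {
    (0.5, "mple", 200): (0.0, -1.5, -0.1, 3.3, -10.7, 1.1, 96.4, 95.3, 10.9, 15.2, 9792),
    (0.5, "mple", 400): (0.0, -3.0, 0.0, -2.0, -7.2, -2.6, 95.2, 94.3, 23.8, 26.7, 9994),
    (0.5, "mple", 600): (0.0, -1.3, 0.0, -3.1, -5.2, -2.5, 94.9, 94.4, 34.6, 36.9, 10000),
    (0.5, "firth", 200): (0.0, 4.8, 0.0, 4.4, 1.0, 4.2, 96.9, 95.3, 8.1, 13.4, 10000),
    (0.5, "firth", 400): (0.0, -0.2, 0.0, 1.8, 0.9, 0.8, 95.7, 94.8, 20.3, 24.1, 10000),
    (0.5, "firth", 600): (0.0, 0.6, 0.0, -0.1, 0.1, 0.1, 95.6, 94.8, 31.6, 34.5, 10000),
    (1.0, "mple", 200): (0.0, -1.4, -0.1, -0.1, -7.4, -0.4, 96.6, 95.1, 13.0, 16.0, 9907),
    (1.0, "mple", 400): (0.0, -2.8, 0.0, -1.7, -4.2, -2.5, 95.4, 94.6, 25.9, 27.4, 9999),
    (1.0, "mple", 600): (0.0, -0.9, 0.0, -0.9, -2.7, -1.0, 95.1, 94.7, 36.9, 37.9, 10000),
    (1.0, "firth", 200): (0.0, 5.0, 0.0, 4.0, -1.0, 4.5, 97.3, 95.5, 10.6, 14.8, 9998),
    (1.0, "firth", 400): (0.0, 0.0, 0.0, 2.3, -0.1, 1.0, 96.0, 95.2, 24.0, 26.3, 9999),
    (1.0, "firth", 600): (0.0, 1.0, 0.0, 1.7, -0.1, 1.2, 95.6, 95.1, 35.2, 37.0, 10000),
    (2.0, "mple", 200): (0.0, -1.1, 0.0, -0.7, -0.5, -0.5, 96.3, 95.1, 13.2, 14.6, 9901),
    (2.0, "mple", 400): (0.0, -3.2, 0.0, -1.5, -0.4, -2.1, 95.4, 94.9, 26.2, 26.5, 9979),
    (2.0, "mple", 600): (0.0, -1.3, 0.0, -0.6, -0.5, -0.7, 95.2, 94.9, 36.6, 36.7, 9990),
    (2.0, "firth", 200): (0.0, 5.2, 0.0, 4.8, -0.6, 5.4, 97.2, 95.7, 11.8, 14.7, 9954),
    (2.0, "firth", 400): (0.0, -0.2, 0.0, 2.2, -0.1, 1.3, 96.1, 95.2, 25.6, 27.0, 9980),
    (2.0, "firth", 600): (0.0, 0.6, 0.0, 1.8, -0.3, 1.5, 95.8, 95.2, 36.2, 37.3, 9990),
}

REFERENCE = {"t3": _T3, "t4": _T4, "t5": _T5}


def table_scenario(table_id: str, block_value: float, n: int,
                   N: int = REFERENCE_N, master_seed: int = 20240620) -> Scenario:
    """Scenario for one cell block of a reference table."""
    spec = TABLE_SCENARIOS[table_id]
    params = dict(spec["fixed"])
    params[spec["block_key"]] = block_value
    return Scenario(n=n, N=N, master_seed=master_seed, **params)
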