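"""Synthetic survival data for one replicate of a simulation condition.

Each subject is assigned to one of four (marker, treatment) cells by a
multinomial draw, then receives a latent exponential event time under the
proportional-hazards model ``rate = lambda_e * exp(bM*M + bT*T + bI*M*T)`` and
a latent non-differential exponential censoring time (rate ``lambda_c``,
independent of M and T).  Follow-up ends administratively at ``t_end``: the
observed record is ``(t_e, event=1)`` if ``t_e <= min(t_c, t_end)`` and
``(min(t_c, t_end), event=0)`` otherwise.

Reproducibility contract: the dataset for a given ``(master_seed,
scenario.key, replicate_index)`` is bit-identical across runs and processes.
Each replicate owns a dedicated PCG64 stream seeded from
``SeedSequence((master_seed, scenario.key_hash, replicate_index))``, so
replicates can be generated in any order and individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import CellProbabilities, Scenario

__all__ = [
    "SurvivalDataset",
    "replicate_rng",
    "draw_cells",
    "event_time",
    "censoring_time",
    "assemble",
    "eligibility",
]


@dataclass
class SurvivalDataset:
    """Per-subject records of one simulated replicate.

    ``M``/``T`` are 0/1 indicators, ``time`` the observed follow-up in years,
    ``event`` 1 for an observed event and 0 for (random or administrative)
    censoring.  ``events_per_cell[m, t]`` counts events in each cell.
    """

    M: np.ndarray
    T: np.ndarray
    time: np.ndarray
    event: np.ndarray
    scenario_key: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        counts = np.zeros((2, 2), dtype=np.int64)
        np.add.at(counts, (self.M, self.T), self.event)
        self.events_per_cell = counts

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self):
        """Delimited-text-friendly view (columns M, T, time, event)."""
        import pandas as pd

        return pd.DataFrame(
            {"M": self.M, "T": self.T, "time": self.time, "event": self.event}
        )


def replicate_rng(scenario: Scenario, replicate_index: int) -> np.random.Generator:
    """Dedicated random stream for one (scenario, replicate) pair."""
    if replicate_index < 0:
        raise ValueError("replicate_index must be nonnegative")
    seq = np.random.SeedSequence(
        (int(scenario.master_seed), scenario.key_hash, int(replicate_index))
    )
    return np.random.default_rng(seq)


def _open_uniform(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform draws on the open interval (0, 1).

    ``Generator.random`` yields [0, 1); mapping u -> 1 - u gives (0, 1], and
    the (probability ~2^-53) endpoint u = 1 is resampled so that -log(u) is
    finite and strictly positive, keeping all generated times positive.
    """
    u = 1.0 - rng.random(size)
    bad = u >= 1.0
    while bad.any():
        u[bad] = 1.0 - rng.random(int(bad.sum()))
        bad = u >= 1.0
    return u


def draw_cells(
    n: int, probs: CellProbabilities, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n independent multinomial cell assignments, in draw order.

    Returns (M, T) indicator arrays.  Cell order for the inverse-CDF lookup is
    (0,0), (1,0), (0,1), (1,1).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    p = np.asarray(probs.as_tuple(), dtype=float)
    edges = np.cumsum(p)
    edges[-1] = 1.0  # guard against rounding
    idx = np.searchsorted(edges, rng.random(n), side="right")
    m = np.array([0, 1, 0, 1], dtype=np.int64)[idx]
    t = np.array([0, 0, 1, 1], dtype=np.int64)[idx]
    return m, t


def event_time(M, T, lambda_e: float, beta_M: float, beta_T: float,
               beta_I: float, u) -> np.ndarray:
    """Inverse-transform exponential event time(s).

    ``t_e = -log(u) / (lambda_e * exp(bM*M + bT*T + bI*M*T))`` with u drawn
    uniformly on (0, 1).
    """
    if lambda_e <= 0.0:
        raise ValueError("lambda_e must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    rate = lambda_e * np.exp(beta_M * M + beta_T * T + beta_I * M * T)
    return -np.log(u) / rate


def censoring_time(lambda_c: float, u) -> np.ndarray:
    """Non-differential censoring time; +inf when the rate is zero."""
    if lambda_c < 0.0:
        raise ValueError("lambda_c must be nonnegative")
    u = np.asarray(u, dtype=float)
    if lambda_c == 0.0:
        return np.full(u.shape, np.inf)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    return -np.log(u) / lambda_c


def assemble(
    scenario: Scenario,
    replicate_index: int = 0,
    rng: np.random.Generator | None = None,
) -> SurvivalDataset:
    """Generate one replicate dataset from a scenario.

    Draw order within the replicate stream is fixed (cells, then event
    uniforms, then censoring uniforms) so datasets are reproducible.
    """
    if rng is None:
        rng = replicate_rng(scenario, replicate_index)
    probs = scenario.cells()
    m, t = draw_cells(scenario.n, probs, rng)
    u_e = _open_uniform(rng, scenario.n)
    t_e = event_time(
        m, t, scenario.lambda_e, scenario.beta_M, scenario.beta_T,
        scenario.beta_I, u_e,
    )
    lambda_c = scenario.lambda_c
    if lambda_c > 0.0:
        u_c = _open_uniform(rng, scenario.n)
        t_c = censoring_time(lambda_c, u_c)
    else:
        t_c = np.full(scenario.n, np.inf)

    horizon = np.minimum(t_c, scenario.t_end)
    event = (t_e <= horizon).astype(np.int64)
    time = np.where(event == 1, t_e, horizon)
    return SurvivalDataset(
        M=m, T=t, time=time, event=event,
        scenario_key=scenario.key, replicate_index=replicate_index,
    )


def eligibility(ds: SurvivalDataset) -> bool:
    """A replicate is usable iff at most one (M,T) cell has zero events."""
    return int((ds.events_per_cell == 0).sum()) <= 1
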