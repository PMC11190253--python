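"""Simulation conditions for biomarker-treatment interaction studies.

A :class:`Scenario` bundles everything needed to generate one batch of
synthetic survival datasets: the study size ``n``, the marginal prevalences of
the high-marker group (``p_M``) and the experimental treatment (``p_T``), the
odds ratio ``OR_MT`` linking them, the baseline cumulative event incidence
``p_e`` and random-censoring fraction ``p_c`` by the administrative horizon
``t_end``, and the three generating hazard ratios ``HR_M`` (marker effect
under standard treatment), ``HR_T`` (treatment effect at low marker level) and
``HR_I`` (the marker-treatment interaction).

The module also provides the full factorial grid of conditions evaluated in
the simulation study (:func:`table1_grid`) and five presets derived from
published breast-cancer studies (:func:`study_presets`).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = [
    "Scenario",
    "CellProbabilities",
    "cell_probabilities",
    "rate_from_incidence",
    "table1_grid",
    "study_presets",
    "load_scenarios",
    "dump_scenario",
]


@dataclass(frozen=True)
class CellProbabilities:
    """Multinomial probabilities of the four (marker, treatment) cells.

    ``p_mt`` is the probability of marker level ``m`` and treatment arm ``t``;
    the four cells sum to one, the margins reproduce ``p_M`` and ``p_T``, and
    the cross-product ratio reproduces ``OR_MT``.
    """

    p_00: float
    p_10: float
    p_01: float
    p_11: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_00, self.p_10, self.p_01, self.p_11)

    @property
    def p_M(self) -> float:
        return self.p_10 + self.p_11

    @property
    def p_T(self) -> float:
        return self.p_01 + self.p_11

    @property
    def odds_ratio(self) -> float:
        return (self.p_11 * self.p_00) / (self.p_10 * self.p_01)


def cell_probabilities(p_M: float, p_T: float, OR_MT: float) -> CellProbabilities:
    """Unique 2x2 cell distribution with given margins and odds ratio.

    Uses the Plackett construction: for ``OR_MT != 1`` the joint probability
    ``p_11`` is the admissible root of the quadratic

        OR_MT * (p_M - p_11) * (p_T - p_11) = p_11 * (1 - p_M - p_T + p_11),

    namely ``p_11 = [S - sqrt(S^2 - 4*t*(t-1)*p_M*p_T)] / (2*(t-1))`` with
    ``t = OR_MT`` and ``S = 1 + (p_M + p_T)*(t - 1)``.  For ``OR_MT = 1`` the
    independence table ``p_11 = p_M * p_T`` is returned.
    """
    if not (0.0 < p_M < 1.0 and 0.0 < p_T < 1.0):
        raise ValueError(f"margins must lie strictly in (0,1); got p_M={p_M}, p_T={p_T}")
    if OR_MT <= 0.0:
        raise ValueError(f"OR_MT must be positive; got {OR_MT}")

    theta = float(OR_MT)
    if theta == 1.0:
        p_11 = p_M * p_T
    else:
        s = 1.0 + (p_M + p_T) * (theta - 1.0)
        disc = s * s - 4.0 * theta * (theta - 1.0) * p_M * p_T
        if disc < 0.0:  # cannot occur for valid margins/odds ratio
            raise ArithmeticError("negative discriminant in Plackett root")
        p_11 = (s - math.sqrt(disc)) / (2.0 * (theta - 1.0))

    cells = CellProbabilities(
        p_00=1.0 - p_M - p_T + p_11,
        p_10=p_M - p_11,
        p_01=p_T - p_11,
        p_11=p_11,
    )
    if min(cells.as_tuple()) < -1e-12:
        raise ArithmeticError(f"inadmissible cell table {cells} for ({p_M}, {p_T}, {OR_MT})")
    return cells


def rate_from_incidence(p: float, t_end: float) -> float:
    """Exponential rate giving cumulative incidence ``p`` by time ``t_end``.

    Solves ``1 - exp(-rate * t_end) = p``; ``p = 0`` maps to rate 0, which
    callers interpret as "no random censoring" (censoring time +inf).
    """
    if not (0.0 <= p < 1.0):
        raise ValueError(f"incidence must lie in [0,1); got {p}")
    if t_end <= 0.0:
        raise ValueError(f"t_end must be positive; got {t_end}")
    return -math.log1p(-p) / t_end


@dataclass(frozen=True)
class Scenario:
    """Full parameter set of one simulation condition."""

    n: int
    p_M: float
    p_T: float
    p_e: float
    p_c: float
    t_end: float
    OR_MT: float
    HR_M: float
    HR_T: float
    HR_I: float
    N: int = 10000
    master_seed: int = 20240620
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if not (0.0 < self.p_M < 1.0):
            raise ValueError("p_M must lie strictly in (0,1)")
        if not (0.0 < self.p_T < 1.0):
            raise ValueError("p_T must lie strictly in (0,1)")
        if not (0.0 <= self.p_e < 1.0):
            raise ValueError("p_e must lie in [0,1)")
        if not (0.0 <= self.p_c < 1.0):
            raise ValueError("p_c must lie in [0,1)")
        if self.t_end <= 0.0:
            raise ValueError("t_end must be positive")
        for ratio_name in ("OR_MT", "HR_M", "HR_T", "HR_I"):
            value = getattr(self, ratio_name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"{ratio_name} must be a finite positive ratio")

    # -- derived quantities -------------------------------------------------

    @property
    def beta_M(self) -> float:
        return math.log(self.HR_M)

    @property
    def beta_T(self) -> float:
        return math.log(self.HR_T)

    @property
    def beta_I(self) -> float:
        return math.log(self.HR_I)

    @property
    def HR_TM_low(self) -> float:
        """Treatment hazard ratio in the low-marker subgroup."""
        return self.HR_T

    @property
    def HR_TM_high(self) -> float:
        """Treatment hazard ratio in the high-marker subgroup."""
        return self.HR_T * self.HR_I

    @property
    def lambda_e(self) -> float:
        """Baseline event rate calibrated so S(t_end) = 1 - p_e."""
        return rate_from_incidence(self.p_e, self.t_end)

    @property
    def lambda_c(self) -> float:
        """Random-censoring rate; 0 means administrative censoring only."""
        return rate_from_incidence(self.p_c, self.t_end)

    def cells(self) -> CellProbabilities:
        return cell_probabilities(self.p_M, self.p_T, self.OR_MT)

    def truths(self) -> dict[str, float]:
        """True log-hazard-ratio values of the estimable coefficients."""
        return {
            "beta_M": self.beta_M,
            "beta_T": self.beta_T,
            "beta_I": self.beta_I,
            "beta_TM_low": math.log(self.HR_TM_low),
            "beta_TM_high": math.log(self.HR_TM_high),
        }

    @property
    def key(self) -> str:
        """Canonical identity string (all parameters, fixed order)."""
        return (
            f"n={self.n}|p_M={self.p_M:g}|p_T={self.p_T:g}|p_e={self.p_e:g}"
            f"|p_c={self.p_c:g}|t_end={self.t_end:g}|OR_MT={self.OR_MT:g}"
            f"|HR_M={self.HR_M:g}|HR_T={self.HR_T:g}|HR_I={self.HR_I:g}"
            f"|N={self.N}|seed={self.master_seed}"
        )

    @property
    def key_hash(self) -> int:
        """Stable 32-bit hash of the identity string (seed-stream component)."""
        digest = hashlib.sha256(self.key.encode("utf-8")).digest()
        return int.from_bytes(digest[:4], "little")

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


_SCENARIO_KEYS = [f.name for f in fields(Scenario)]


# -- condition catalogues ---------------------------------------------------

#: factor levels of the full simulation grid
GRID_LEVELS = {
    "n": (200, 300, 400, 500, 600, 800, 1000),
    "p_M": (0.25, 0.5, 0.75),
    "p_c": (0.2, 0.5),
    "OR_MT": (0.5, 1.0, 2.0),
    "HR_M": (0.6, 0.8, 1.0, 3.0, 6.0),
    "HR_I": (0.25, 0.5, 0.75, 1.0),
}

GRID_FIXED = {"N": 10000, "p_T": 0.5, "p_e": 0.2, "t_end": 5.0, "HR_T": 1.0}


def table1_grid(master_seed: int = 20240620) -> list[Scenario]:
    """Full cross of the simulation-grid factor levels (2520 scenarios)."""
    out = []
    for n in GRID_LEVELS["n"]:
        for p_M in GRID_LEVELS["p_M"]:
            for p_c in GRID_LEVELS["p_c"]:
                for OR_MT in GRID_LEVELS["OR_MT"]:
                    for HR_M in GRID_LEVELS["HR_M"]:
                        for HR_I in GRID_LEVELS["HR_I"]:
                            out.append(
                                Scenario(
                                    n=n, p_M=p_M, p_c=p_c, OR_MT=OR_MT,
                                    HR_M=HR_M, HR_I=HR_I,
                                    master_seed=master_seed, **GRID_FIXED,
                                )
                            )
    return out


def study_presets(N: int = 10000, master_seed: int = 20240620) -> dict[str, Scenario]:
    """Scenario presets derived from five published breast-cancer studies.

    Parameters were extracted from the original cohorts with follow-up
    truncated at 5 years and no covariate adjustment; ``p_c = 0`` presets
    carry a zero random-censoring rate (administrative censoring only).
    """
    rows = {
        # name: (n, p_M, p_T, p_e, p_c, OR_MT, HR_M, HR_T, HR_I)
        "deBoo": (129, 0.53, 0.47, 0.38, 0.00, 0.92, 0.67, 0.23, 1.95),
        "Knauer": (541, 0.53, 0.42, 0.03, 0.88, 2.34, 6.60, 0.56, 0.37),
        "Kok": (239, 0.52, 0.49, 0.40, 0.00, 1.48, 0.86, 0.83, 0.63),
        "Schouten": (117, 0.14, 0.59, 0.34, 0.65, 1.70, 5.39, 0.87, 0.08),
        "Vollebergh": (230, 0.18, 0.49, 0.38, 0.00, 0.79, 3.51, 0.68, 0.24),
    }
    presets = {}
    for name, (n, p_M, p_T, p_e, p_c, OR_MT, HR_M, HR_T, HR_I) in rows.items():
        presets[name] = Scenario(
            n=n, p_M=p_M, p_T=p_T, p_e=p_e, p_c=p_c, t_end=5.0,
            OR_MT=OR_MT, HR_M=HR_M, HR_T=HR_T, HR_I=HR_I,
            N=N, master_seed=master_seed, name=name,
        )
    return presets


# -- plain-text config I/O --------------------------------------------------

def _scenarios_from_mapping(doc: dict) -> list[Scenario]:
    doc = {k: v for k, v in doc.items() if k in _SCENARIO_KEYS}
    listy = {k: v for k, v in doc.items() if isinstance(v, (list, tuple))}
    if not listy:
        return [Scenario(**doc)]
    # grid specification: cross all list-valued keys
    out = [dict(doc)]
    for k, values in listy.items():
        out = [{**d, k: v} for d in out for v in values]
    return [Scenario(**d) for d in out]


def load_scenarios(path) -> list[Scenario]:
    """Read scenarios from a YAML ``key: value`` config.

    Each document describes one scenario; list-valued keys are crossed into a
    grid.  Keys are exactly the :class:`Scenario` field names.
    """
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    out: list[Scenario] = []
    for doc in docs:
        if doc is None:
            continue
        out.extend(_scenarios_from_mapping(doc))
    return out


def dump_scenario(scenario: Scenario, path) -> None:
    doc = {k: getattr(scenario, k) for k in _SCENARIO_KEYS}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
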