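"""Rank the simulation's stochastic inputs by their influence on the EDI.

For each stochastic input captured during the simulation (tissue
concentrations, and the mass-fraction ratios when they are stochastic) the
analysis computes a correlation coefficient against the per-iteration EDI
and sorts inputs by absolute influence — the tornado-chart view standard in
probabilistic exposure assessment.

Methods: Spearman rank correlation (default, robust to the monotone
transforms in the model), Pearson product–moment, and a normalised
contribution-to-variance (squared rank correlations rescaled to sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exposure import simulate_draws
from .io import ExposureScenario

__all__ = ["SensitivityResult", "sensitivity_analysis", "sensitivity_to_dataframe"]

Method = Literal["spearman_rank", "pearson", "contribution_to_variance"]


@dataclass(frozen=True)
class SensitivityResult:
    population: str
    method: Method
    # (input name, coefficient), sorted descending by |coefficient|
    coefficients: tuple[tuple[str, float], ...]


def _coefficients(
    inputs: dict[str, np.ndarray], edi: np.ndarray, method: Method
) -> tuple[tuple[str, float], ...]:
    if method == "spearman_rank":
        raw = {k: float(sps.spearmanr(v, edi).statistic) for k, v in inputs.items()}
    elif method == "pearson":
        raw = {k: float(sps.pearsonr(v, edi).statistic) for k, v in inputs.items()}
    elif method == "contribution_to_variance":
        rho = {k: float(sps.spearmanr(v, edi).statistic) for k, v in inputs.items()}
        total = sum(r**2 for r in rho.values())
        raw = {k: (r**2 / total if total > 0 else 0.0) for k, r in rho.items()}
    else:
        raise ValueError(f"unknown method {method!r}")
    return tuple(sorted(raw.items(), key=lambda item: abs(item[1]), reverse=True))


def sensitivity_analysis(
    scenario: ExposureScenario, method: Method = "spearman_rank"
) -> dict[str, SensitivityResult]:
    """Correlation of every stochastic input with the EDI, per population.

    Re-runs the simulation capturing the per-iteration input draws.  Raises
    when every input is degenerate (no variance to attribute).
    """
    base, inputs = simulate_draws(scenario)
    if not inputs:
        raise ValueError("no stochastic inputs: nothing to attribute variance to")
    results: dict[str, SensitivityResult] = {}
    for population, bw in scenario.bw.items():
        edi = base / bw
        results[population] = SensitivityResult(
            population=population,
            method=method,
            coefficients=_coefficients(inputs, edi, method),
        )
    return results


def sensitivity_to_dataframe(results: dict[str, SensitivityResult]) -> pd.DataFrame:
    """Tornado-style long table: population, input, coefficient, rank."""
    rows = []
    for r in results.values():
        for rank, (name, coefficient) in enumerate(r.coefficients, start=1):
            rows.append(
                {
                    "population": r.population,
                    "input": name,
                    "method": r.method,
                    "coefficient": coefficient,
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)
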