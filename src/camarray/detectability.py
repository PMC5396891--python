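"""Survey and season detection probability estimators.

Survey detectability p is the fraction of detected (site, replicate) cells,
p = sum(P) / (N k), under the assumption that the species is present at
every site (occupancy fixed at 1, so zeros are detection failures, not
absences). Season detectability p* = 1 - (1 - p)^k is the probability of
at least one detection across the k replicates of a season, assuming
replicate independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from camarray.subsampling import ReplicateDetectionMatrix

__all__ = [
    "SurveyDetectionEstimate",
    "SeasonDetectionEstimate",
    "survey_detection_probability",
    "season_detection_probability",
    "summarize_by_array_size",
]


@dataclass(frozen=True)
class SurveyDetectionEstimate:
    """Estimated per-replicate (survey) detection probability for one draw."""

    p: float
    n_sites: int
    n_replicates: int
    array_size: int
    species_id: str


@dataclass(frozen=True)
class SeasonDetectionEstimate:
    """Cumulative season-long detection probability derived from (p, k)."""

    p_star: float
    p: float
    n_replicates: int


def survey_detection_probability(matrix: ReplicateDetectionMatrix) -> SurveyDetectionEstimate:
    """Exact ratio of detected cells to total cells of a replicate matrix."""
    values = np.asarray(matrix.values)
    if values.size == 0:
        raise ValueError("empty replicate matrix")
    if not np.isin(values, (0, 1)).all():
        raise ValueError("replicate matrix cells must be 0/1")
    n, k = values.shape
    return SurveyDetectionEstimate(
        p=float(values.sum()) / (n * k),
        n_sites=n,
        n_replicates=k,
        array_size=matrix.draw.array_size,
        species_id=matrix.species_id,
    )


def season_detection_probability(p: float, k: int) -> SeasonDetectionEstimate:
    """Probability of >= 1 detection over k independent replicates, 1 - (1-p)^k."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    return SeasonDetectionEstimate(p_star=1.0 - (1.0 - p) ** int(k), p=p, n_replicates=int(k))


def summarize_by_array_size(
    mc_results: pd.DataFrame,
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Per (species, array size) distribution summary of per-draw p values.

    Mirrors the per-design boxplot view of the Monte Carlo output: mean and
    selected quantiles of survey detectability across iterations.
    """
    rows = []
    for (species, m), grp in mc_results.groupby(["species_id", "array_size"], sort=True):
        p = grp["p"].to_numpy()
        row = {
            "species_id": species,
            "array_size": m,
            "n_draws": len(p),
            "p_mean": p.mean(),
        }
        for q in quantiles:
            row[f"p_q{int(round(q * 100)):02d}"] = float(np.quantile(p, q))
        rows.append(row)
    return pd.DataFrame(rows)
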