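"""Pairwise comparison of survey detectability across array sizes.

All-pairs mean contrasts with familywise error control in the spirit of the
robust Tukey-type procedures used for non-normal, heteroscedastic data:

``max_t_robust``
    Welch-type contrasts with heteroscedasticity-consistent standard errors
    (per-group sample variances, no pooling) and a single-step adjustment
    over the joint null distribution of all contrasts. The joint
    equicoordinate probability is evaluated by a seeded parametric
    simulation of the group-mean vector (default 20,000 draws); with two
    groups the exact two-sided normal p-value is used. The normal reference
    is appropriate for the intended inputs — thousands of Monte Carlo
    iterations per group.

``permutation``
    Max-|t| permutation null: group labels are permuted jointly and every
    contrast is compared against the permutation distribution of the
    maximum absolute statistic, which controls the familywise error without
    distributional assumptions (but assumes exchangeability across groups).

A caveat recorded in the result: Monte Carlo iterations are treated as
independent observations although draws resample one underlying year of
data, so p-values are anti-conservative to an unquantified degree.

The compact letter display is built by insertion-absorption: groups share a
letter iff their pairwise adjusted p-value is at or above alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAIR_COLUMNS",
    "ComparisonResult",
    "compare_array_sizes",
    "letter_display",
]

PAIR_COLUMNS = ["m_i", "m_j", "diff", "se", "stat", "p_raw", "p_adj"]

INDEPENDENCE_CAVEAT = (
    "Monte Carlo iterations are treated as independent observations although "
    "they resample a single underlying year of data; p-values do not account "
    "for this dependence."
)


@dataclass
class ComparisonResult:
    """All-pairs comparison of per-draw survey detectability between array sizes."""

    pairs: pd.DataFrame  # columns PAIR_COLUMNS
    groups: dict[int, str]  # compact letter display, array size -> letters
    alpha: float
    method: str
    species_id: str | None = None
    notes: tuple[str, ...] = (INDEPENDENCE_CAVEAT,)


def _group_stats(samples: Mapping[int, np.ndarray]) -> tuple[list[int], np.ndarray, np.ndarray, np.ndarray]:
    keys = sorted(samples)
    means = np.array([np.mean(samples[g]) for g in keys])
    var = np.array([np.var(samples[g], ddof=1) for g in keys])
    n = np.array([len(samples[g]) for g in keys], dtype=float)
    return keys, means, var, n


def _welch_stats(means, var, n, pairs_idx):
    diffs = np.array([means[i] - means[j] for i, j in pairs_idx])
    ses = np.array([np.sqrt(var[i] / n[i] + var[j] / n[j]) for i, j in pairs_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ses > 0, diffs / np.where(ses > 0, ses, 1.0), np.where(diffs == 0, 0.0, np.inf))
    return diffs, ses, t


def compare_array_sizes(
    samples: Mapping[int, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    method: str = "max_t_robust",
    n_draws: int = 20_000,
    n_permutations: int = 5000,
    seed: int = 0,
    species_id: str | None = None,
) -> ComparisonResult:
    """Test all pairwise mean differences of per-draw detectability.

    ``samples`` maps array size to the vector of per-iteration survey
    detection probabilities. Returns adjusted p-values controlling the
    familywise error at level ``alpha`` and the matching compact letter
    display. Deterministic for a fixed ``seed``.
    """
    if method not in ("max_t_robust", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    if any(v.size < 2 for v in samples.values()):
        raise ValueError("each group needs at least 2 observations")

    keys, means, var, n = _group_stats(samples)
    pairs_idx = list(itertools.combinations(range(len(keys)), 2))
    diffs, ses, t = _welch_stats(means, var, n, pairs_idx)
    abs_t = np.abs(t)
    finite = np.isfinite(abs_t)
    p_raw = np.where(
        ses > 0,
        2.0 * stats.norm.sf(np.where(finite, abs_t, 0.0)),
        np.where(diffs == 0, 1.0, 0.0),
    )

    rng = np.random.default_rng(seed)
    if method == "max_t_robust":
        if len(keys) == 2:
            p_adj = p_raw.copy()
        else:
            sd_mean = np.sqrt(var / n)
            z = rng.standard_normal((n_draws, len(keys))) * sd_mean
            valid = ses > 0
            if valid.any():
                tnull = np.stack(
                    [(z[:, i] - z[:, j]) / ses[l]
                     for l, (i, j) in enumerate(pairs_idx) if valid[l]],
                    axis=1,
                )
                max_t = np.abs(tnull).max(axis=1)
                p_adj = np.empty_like(p_raw)
                vi = 0
                for l in range(len(pairs_idx)):
                    if valid[l]:
                        if np.isfinite(abs_t[l]):
                            p_adj[l] = (1 + np.sum(max_t >= abs_t[l])) / (n_draws + 1)
                        else:
                            p_adj[l] = 0.0
                        vi += 1
                    else:
                        p_adj[l] = 1.0 if diffs[l] == 0 else 0.0
            else:
                p_adj = np.where(diffs == 0, 1.0, 0.0)
    else:
        pooled = np.concatenate([samples[g] for g in keys])
        sizes = [len(samples[g]) for g in keys]
        edges = np.cumsum([0] + sizes)
        obs_max = np.nanmax(np.where(np.isfinite(abs_t), abs_t, 0.0))
        max_null = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = pooled[rng.permutation(pooled.size)]
            gm = np.array([perm[edges[i]:edges[i + 1]].mean() for i in range(len(keys))])
            gv = np.array([perm[edges[i]:edges[i + 1]].var(ddof=1) for i in range(len(keys))])
            _, pses, pt = _welch_stats(gm, gv, n, pairs_idx)
            with np.errstate(invalid="ignore"):
                vals = np.abs(pt)
            max_null[b] = np.nanmax(np.where(np.isfinite(vals), vals, 0.0))
        p_adj = np.array(
            [
                (1 + np.sum(max_null >= abs_t[l])) / (n_permutations + 1)
                if np.isfinite(abs_t[l]) and ses[l] > 0
                else (1.0 if diffs[l] == 0 else 0.0)
                for l in range(len(pairs_idx))
            ]
        )
        del obs_max

    # single-step adjustment can never fall below the unadjusted p-value
    p_adj = np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)

    pairs = pd.DataFrame(
        {
            "m_i": [keys[i] for i, _ in pairs_idx],
            "m_j": [keys[j] for _, j in pairs_idx],
            "diff": diffs,
            "se": ses,
            "stat": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )[PAIR_COLUMNS]
    groups = letter_display(pairs, alpha)
    return ComparisonResult(
        pairs=pairs, groups=groups, alpha=alpha, method=method, species_id=species_id
    )


def letter_display(pairs: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from a complete pairwise adjusted-p table.

    Insertion-absorption construction: start from one letter containing all
    groups; for every significant pair split each letter containing both
    members, then absorb letters that became subsets of others. Two groups
    share a letter iff their adjusted p-value is >= alpha.
    """
    required = {"m_i", "m_j", "p_adj"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs table must have columns {sorted(required)}")
    members = sorted(set(pairs["m_i"]) | set(pairs["m_j"]))
    seen = {frozenset((a, b)) for a, b in zip(pairs["m_i"], pairs["m_j"])}
    expected = {frozenset(c) for c in itertools.combinations(members, 2)}
    if seen != expected:
        raise ValueError("pairs table must contain every unordered pair exactly once")

    letters: list[set] = [set(members)]
    for _, row in pairs.iterrows():
        if row["p_adj"] >= alpha:
            continue
        a, b = row["m_i"], row["m_j"]
        new: list[set] = []
        for letter in letters:
            if a in letter and b in letter:
                new.append(letter - {a})
                new.append(letter - {b})
            else:
                new.append(letter)
        # absorb subsets
        new = [s for s in new if s]
        letters = [
            s for i, s in enumerate(new)
            if not any(s < o or (s == o and i > j) for j, o in enumerate(new))
        ]
    letters.sort(key=lambda s: (min(s), -len(s)))
    assignment: dict = {g: "" for g in members}
    for idx, letter in enumerate(letters):
        ch = chr(ord("a") + idx) if idx < 26 else f"({idx})"
        for g in sorted(letter):
            assignment[g] += ch
    return assignment
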