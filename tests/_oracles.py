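"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: deduplication is done
by union-find over all event pairs, replicate extraction by triple-loop
enumeration over (site, replicate, day), curve fitting by dense grid search,
and the compact letter display by exhaustive search over letter families.
"""

import itertools

import numpy as np
import pandas as pd


def dedup_union_find(events: pd.DataFrame, window_minutes: float) -> pd.DataFrame:
    """O(n^2) chain construction: connected components of the pairwise
    within-window graph per (site, species)."""
    records = []
    for (site, sp), grp in events.groupby(["site_id", "species_id"]):
        ts = grp["timestamp"].to_numpy()
        cams = grp["camera_id"].to_numpy()
        n = len(ts)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                gap = abs((ts[j] - ts[i]) / np.timedelta64(1, "m"))
                if gap < window_minutes:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        for idx in comps.values():
            t = ts[idx]
            records.append(
                (site, sp, t.min(), t.max(), tuple(sorted(set(cams[idx]))))
            )
    out = pd.DataFrame(
        records,
        columns=["site_id", "species_id", "timestamp_first", "timestamp_last",
                 "contributing_cameras"],
    )
    return out.sort_values(
        ["timestamp_first", "site_id", "species_id"], kind="mergesort"
    ).reset_index(drop=True)


def replicate_matrix_enumeration(
    events: pd.DataFrame, draw, species_id: str, year_start, window_minutes: float = 30.0
) -> np.ndarray:
    """Enumerate every (site, replicate, day) cell, scanning oracle-dedup chains."""
    sp_events = events[events["species_id"] == species_id]
    sites = sorted(draw.selected_cameras)
    k, L = draw.n_replicates, draw.replicate_length
    out = np.zeros((len(sites), k), dtype=np.int8)
    for i, site in enumerate(sites):
        sel = set(draw.selected_cameras[site])
        sub = sp_events[(sp_events["site_id"] == site) & sp_events["camera_id"].isin(sel)]
        chains = dedup_union_find(sub, window_minutes)
        chain_days = {
            (pd.Timestamp(t).normalize() - pd.Timestamp(year_start)).days + 1
            for t in chains["timestamp_first"]
        }
        for j in range(k):
            for offset in range(L):
                day = (draw.season_start - 1 + j * L + offset) % 365 + 1
                if day in chain_days:
                    out[i, j] = 1
                    break
    return out


def grid_search_rss(S: np.ndarray, y: np.ndarray, A_grid: np.ndarray, R_grid: np.ndarray):
    """Dense RSS minimization over an (A, R) grid."""
    best = (np.inf, None, None)
    for A in A_grid:
        pred = A * (1.0 - np.exp(-np.outer(R_grid, S)))
        rss = ((pred - y) ** 2).sum(axis=1)
        b = int(np.argmin(rss))
        if rss[b] < best[0]:
            best = (float(rss[b]), float(A), float(R_grid[b]))
    return best  # (rss, A, R)


def exhaustive_letter_search(groups, significant_pairs):
    """Smallest family of letters (subsets of groups) such that no significant
    pair shares a letter and every non-significant pair shares at least one."""
    groups = sorted(groups)
    sig = {frozenset(p) for p in significant_pairs}
    nonsig = [
        frozenset(p)
        for p in itertools.combinations(groups, 2)
        if frozenset(p) not in sig
    ]
    subsets = [
        frozenset(c)
        for r in range(1, len(groups) + 1)
        for c in itertools.combinations(groups, r)
        if not any(s <= frozenset(c) for s in sig)
    ]
    for size in range(1, len(groups) + 1):
        for family in itertools.combinations(subsets, size):
            covered_groups = set().union(*family)
            if covered_groups != set(groups):
                continue
            if all(any(pair <= letter for letter in family) for pair in nonsig):
                return size
    raise AssertionError("no valid letter family found")
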