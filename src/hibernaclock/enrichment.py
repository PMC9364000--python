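"""Functional-element permutation enrichment and gene-set overlap tests.

The permutation test follows the eFORGE design: the DMP probe set is thinned
so that no two retained sites lie within a proximity window (1 kb by
default, guarding against clustered, correlated CpGs), its overlap with each
functional-element map (cell line × histone mark or chromatin state) is
counted, and the same-size overlap distribution is built from random thinned
draws out of the array background.  Sampling is uniform over the background;
empirical p-values use the add-one convention
``p = (1 + #{perm >= obs}) / (1 + n_perm)`` and are BY-adjusted across maps.

Gene-level analysis assigns each gene a direction by majority vote of its
winter-up vs winter-down DMPs, and overlap with curated gene sets (innate
immunity, longevity) is tested on a 2×2 table over the gene background with
either the Pearson chi-square (no continuity correction) or Fisher's exact
test built on the hypergeometric distribution.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hibernaclock.dmp import by_fdr


def thin_probes(probe_ids, positions: pd.DataFrame,
                proximity_bp: int = 1000) -> list[str]:
    """Greedy proximity thinning: keep at most one site per window.

    Probes are scanned left-to-right by (scaffold, position); a probe is
    dropped if a kept probe on the same scaffold lies within ``proximity_bp``.
    Deterministic for a fixed input order of coordinates.
    """
    pos = positions.set_index("probe_id")
    sub = pos.loc[list(probe_ids)].sort_values(["scaffold", "pos"])
    kept: list[str] = []
    last_sc, last_pos = None, None
    for pid, row in sub.iterrows():
        if row["scaffold"] != last_sc or row["pos"] - last_pos > proximity_bp:
            kept.append(pid)
            last_sc, last_pos = row["scaffold"], row["pos"]
    return kept


def _random_thinned_set(bg_ids: np.ndarray, scaffolds: np.ndarray,
                        coords: np.ndarray, size: int, proximity_bp: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a random thinned subset of the background of a given size.

    Background probes are visited in random order; a probe is kept unless a
    previously kept probe on the same scaffold is within the proximity
    window.  Stops once ``size`` probes are kept.
    """
    order = rng.permutation(len(bg_ids))
    kept_idx: list[int] = []
    kept_positions: dict[int, list[int]] = {}
    for i in order:
        sc, c = scaffolds[i], coords[i]
        lst = kept_positions.setdefault(sc, [])
        j = bisect_left(lst, c)
        if (j > 0 and c - lst[j - 1] <= proximity_bp) or \
           (j < len(lst) and lst[j] - c <= proximity_bp):
            continue
        insort(lst, c)
        kept_idx.append(i)
        if len(kept_idx) == size:
            break
    return bg_ids[np.array(kept_idx, dtype=int)]


def permutation_enrichment(
    test_set,
    background,
    maps: dict[str, set[str]],
    positions: pd.DataFrame,
    n_perm: int = 1000,
    proximity_bp: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of a probe set against element maps.

    Parameters
    ----------
    test_set, background
        Probe-id collections with ``test_set ⊆ background``.
    maps
        Map name -> set of labelled probe ids (subset of the background).
    positions
        ``probe_id, scaffold, pos`` table covering the background, used for
        proximity thinning.

    Returns one row per map: observed overlap of the thinned test set,
    permutation mean and SD, z-score, add-one empirical p and BY-adjusted p.
    """
    test_set = list(dict.fromkeys(test_set))
    background = list(dict.fromkeys(background))
    bg = set(background)
    if not set(test_set) <= bg:
        raise ValueError("test set must be a subset of the background")
    if len(background) < len(test_set):
        raise ValueError("background smaller than test set")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")

    thinned = thin_probes(test_set, positions, proximity_bp)
    size = len(thinned)
    thinned_set = set(thinned)

    pos = positions.set_index("probe_id").loc[background]
    bg_ids = np.array(background)
    sc_codes = pd.factorize(pos["scaffold"])[0]
    coords = pos["pos"].to_numpy(int)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    map_names = list(maps)
    observed = np.array([len(thinned_set & set(maps[m])) for m in map_names])
    perm_overlaps = np.empty((n_perm, len(map_names)), dtype=int)
    map_sets = [set(maps[m]) for m in map_names]
    for t in range(n_perm):
        draw = set(_random_thinned_set(bg_ids, sc_codes, coords, size,
                                       proximity_bp, rng))
        for k, ms in enumerate(map_sets):
            perm_overlaps[t, k] = len(draw & ms)

    mean = perm_overlaps.mean(axis=0)
    sd = perm_overlaps.std(axis=0, ddof=1)
    z = np.where(sd > 0, (observed - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    p_emp = (1.0 + (perm_overlaps >= observed[None, :]).sum(axis=0)) / (1.0 + n_perm)
    out = pd.DataFrame({
        "map": map_names,
        "observed": observed,
        "perm_mean": mean,
        "perm_sd": sd,
        "z": z,
        "p_emp": p_emp,
        "n_test_thinned": size,
    })
    out["p_by"] = by_fdr(out["p_emp"].to_numpy())
    return out.sort_values("p_emp", kind="mergesort").reset_index(drop=True)


def assign_gene_directions(dmp_table: pd.DataFrame,
                           probe_annotation: pd.DataFrame) -> pd.DataFrame:
    """Majority-rule direction per gene from its DMPs' direction calls.

    A gene is winter-up if more of its DMPs are winter-up than winter-down,
    winter-down in the reverse case, and ``none`` on a tie.  Only probes
    called as DMPs contribute.
    """
    annot = probe_annotation.set_index("probe_id")["nearest_gene"]
    dmps = dmp_table[dmp_table["direction"] != "none"].copy()
    dmps["gene"] = dmps["probe_id"].map(annot)
    dmps = dmps.dropna(subset=["gene"])
    rows = []
    for gene, grp in dmps.groupby("gene", sort=True):
        up = int((grp["direction"] == "winter-up").sum())
        down = int((grp["direction"] == "winter-down").sum())
        direction = "winter-up" if up > down else (
            "winter-down" if down > up else "none")
        rows.append({"gene": gene, "n_winter_up_dmps": up,
                     "n_winter_down_dmps": down, "direction": direction})
    return pd.DataFrame(rows, columns=["gene", "n_winter_up_dmps",
                                       "n_winter_down_dmps", "direction"])


@dataclass
class ContingencyTable:
    """2×2 membership table over a gene background."""

    a: int   # in both sets
    b: int   # set2 only
    c: int   # set1 only
    d: int   # neither

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def overlap_test(set1, set2, background, method: str = "chi_sq"
                 ) -> tuple[ContingencyTable, float, float]:
    """Test association of two gene sets over a background universe.

    ``set1`` indexes the rows (e.g. hibernation genes) and ``set2`` the
    columns (e.g. an immunity list); ``a`` counts genes in both.  ``chi_sq``
    is the Pearson statistic without continuity correction; ``fisher`` is
    the two-sided exact test (statistic reported is the overlap count).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    s1, s2 = set(set1) & bg, set(set2) & bg
    if set(set1) - bg or set(set2) - bg:
        raise ValueError("gene sets must be subsets of the background")
    a = len(s1 & s2)
    b = len(s2 - s1)
    c = len(s1 - s2)
    d = len(bg) - a - b - c
    table = ContingencyTable(a, b, c, d)
    if method == "chi_sq":
        stat, p, *_ = stats.chi2_contingency(table.as_array(), correction=False)
        return table, float(stat), float(p)
    if method == "fisher":
        p = hypergeometric_p(a, len(s1), len(s2), len(bg))
        return table, float(a), p
    raise ValueError(f"unknown method {method!r}")


def hypergeometric_p(a: int, set1_size: int, set2_size: int,
                     background_size: int) -> float:
    """Two-sided Fisher exact p for an overlap of ``a`` between two sets.

    Sums the hypergeometric probabilities of all tables (with the same
    margins) whose probability does not exceed that of the observed table —
    the standard two-sided convention for Fisher's exact test.
    """
    if not (0 <= set1_size <= background_size
            and 0 <= set2_size <= background_size):
        raise ValueError("inconsistent margins")
    lo = max(0, set1_size + set2_size - background_size)
    hi = min(set1_size, set2_size)
    if not lo <= a <= hi:
        raise ValueError("overlap incompatible with margins")
    k = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(k, background_size, set1_size, set2_size)
    p_obs = stats.hypergeom.pmf(a, background_size, set1_size, set2_size)
    # relative tolerance guards against float noise when excluding tables
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
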