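"""Probe genomic annotation: nearest TSS, region class, and region tests.

Each array probe maps to a scaffold coordinate (0-based).  Its nearest gene
is the gene with the closest TSS on the same scaffold (ties broken toward
the lexicographically smaller gene id), its TSS distance is signed and
strand-aware (negative = upstream of the TSS in the gene's orientation),
and its region class is one of six mutually exclusive labels assigned by
precedence:

    promoter > 5'UTR > 3'UTR > exon > intron > intergenic

with promoter defined as the closed window [-10 kb, +1 kb] around the
nearest TSS.  Containment (UTR/exon/intron) is evaluated against the
nearest gene's model; a probe inside the gene body but outside any
exon/UTR interval is intronic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PROMOTER_UPSTREAM = 10_000
PROMOTER_DOWNSTREAM = 1_000
REGION_ORDER = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic")


@dataclass
class GenomeAnnotation:
    """Scaffold lengths, gene models and (optionally) probe placements."""

    scaffolds: dict[str, int]
    genes: pd.DataFrame       # gene_id, scaffold, strand, start, end, tss
    features: pd.DataFrame    # gene_id, feature in {exon, utr5, utr3}, start, end
    probes: pd.DataFrame      # probe_id, scaffold, pos

    def __post_init__(self) -> None:
        for _, g in self.genes.iterrows():
            L = self.scaffolds.get(g["scaffold"])
            if L is not None and not (0 <= g["start"] < g["end"] <= L):
                raise ValueError(
                    f"gene {g['gene_id']} outside scaffold bounds")


def annotate_probes(annotation: GenomeAnnotation,
                    probes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign nearest gene, signed TSS distance and region class per probe.

    Parameters
    ----------
    probes
        Data frame with ``probe_id``, ``scaffold``, ``pos``; defaults to the
        annotation's own probe placements.

    Returns one row per probe: ``probe_id, scaffold, pos, nearest_gene,
    tss_distance, region``.  Probes on scaffolds without genes are
    intergenic with no nearest gene (distance NaN).
    """
    if probes is None:
        probes = annotation.probes
    genes = annotation.genes
    feats = annotation.features.set_index("gene_id")

    # per-scaffold sorted TSS arrays for nearest-neighbour lookup
    per_scaffold: dict[str, pd.DataFrame] = {
        sc: grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for sc, grp in genes.groupby("scaffold")}

    rows = []
    for _, pr in probes.iterrows():
        sc, pos = pr["scaffold"], int(pr["pos"])
        if sc not in annotation.scaffolds:
            raise KeyError(f"probe {pr['probe_id']} on unknown scaffold {sc}")
        g = per_scaffold.get(sc)
        if g is None or g.empty:
            rows.append((pr["probe_id"], sc, pos, None, np.nan, "intergenic"))
            continue
        tss = g["tss"].to_numpy(int)
        i = int(np.searchsorted(tss, pos))
        candidates = [j for j in (i - 1, i, i + 1) if 0 <= j < len(g)]
        # nearest by absolute distance, ties toward smaller gene id
        best = min(candidates,
                   key=lambda j: (abs(tss[j] - pos), g.loc[j, "gene_id"]))
        gene = g.loc[best]
        signed = (pos - gene["tss"]) if gene["strand"] == "+" \
            else (gene["tss"] - pos)
        region = _classify(pos, int(signed), gene, feats)
        rows.append((pr["probe_id"], sc, pos, gene["gene_id"], int(signed),
                     region))
    return pd.DataFrame(rows, columns=["probe_id", "scaffold", "pos",
                                       "nearest_gene", "tss_distance",
                                       "region"])


def _classify(pos: int, signed: int, gene: pd.Series,
              feats: pd.DataFrame) -> str:
    if -PROMOTER_UPSTREAM <= signed <= PROMOTER_DOWNSTREAM:
        return "promoter"
    f = feats.loc[[gene["gene_id"]]]
    for label, feature in (("utr5", "utr5"), ("utr3", "utr3")):
        sub = f[f["feature"] == feature]
        if ((sub["start"] <= pos) & (pos < sub["end"])).any():
            return label
    ex = f[f["feature"] == "exon"]
    if ((ex["start"] <= pos) & (pos < ex["end"])).any():
        return "exon"
    if gene["start"] <= pos < gene["end"]:
        return "intron"
    return "intergenic"


def per_region_chi_square(observed: float, expected: float) -> float:
    """Single-cell deviation statistic (O − E)² / E, df = 1."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return (observed - expected) ** 2 / expected


def region_enrichment(dmp_probe_ids, probe_annotation: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict]:
    """Test whether DMPs are distributed across region classes as the array is.

    Expected counts are proportional to the background (all annotated
    probes) region frequencies.  Each region gets the single-cell statistic
    (O − E)²/E with a df = 1 p-value and a direction of deviation; the
    omnibus statistic is their sum with df = #regions − 1.
    """
    dmp_ids = set(dmp_probe_ids)
    annot = probe_annotation
    background = annot["region"].value_counts()
    dmp_regions = annot.loc[annot["probe_id"].isin(dmp_ids), "region"]
    n_dmps = len(dmp_regions)
    observed = dmp_regions.value_counts()

    rows = []
    for region in REGION_ORDER:
        nb = int(background.get(region, 0))
        if nb == 0:
            continue
        O = int(observed.get(region, 0))
        E = n_dmps * nb / int(background.sum())
        chi = per_region_chi_square(O, E) if E > 0 else 0.0
        rows.append({"region": region, "observed": O, "expected": E,
                     "ratio": O / E if E > 0 else np.nan,
                     "chi_sq": chi, "p": float(stats.chi2.sf(chi, 1)),
                     "direction": "enriched" if O > E else
                                  ("depleted" if O < E else "none")})
    table = pd.DataFrame(rows)
    omnibus_chi = float(table["chi_sq"].sum())
    df = max(len(table) - 1, 1)
    omnibus = {"chi_sq": omnibus_chi, "df": df,
               "p": float(stats.chi2.sf(omnibus_chi, df)),
               "n_dmps": n_dmps}
    return table, omnibus


def tss_distance_comparison(group_a, group_b,
                            probe_annotation: pd.DataFrame) -> dict:
    """Two-sample Student's t-test on absolute TSS distances (bp).

    Returns means with standard errors per group plus the pooled-variance t
    statistic and two-sided p.
    """
    annot = probe_annotation.set_index("probe_id")
    da = annot.loc[list(group_a), "tss_distance"].abs().dropna().to_numpy(float)
    db = annot.loc[list(group_b), "tss_distance"].abs().dropna().to_numpy(float)
    if len(da) < 2 or len(db) < 2:
        raise ValueError("each group needs >= 2 probes with TSS distances")
    t, p = stats.ttest_ind(da, db, equal_var=True)
    return {"mean_a": float(da.mean()),
            "se_a": float(da.std(ddof=1) / np.sqrt(len(da))),
            "mean_b": float(db.mean()),
            "se_b": float(db.std(ddof=1) / np.sqrt(len(db))),
            "t": float(t), "p": float(p),
            "n_a": len(da), "n_b": len(db)}


def scaffold_coverage(dmp_probe_ids, annotation: GenomeAnnotation,
                      probe_annotation: pd.DataFrame | None = None
                      ) -> tuple[int, int]:
    """(number of scaffolds holding >= 1 DMP, total scaffold count)."""
    probes = probe_annotation if probe_annotation is not None \
        else annotation.probes
    hit = probes.loc[probes["probe_id"].isin(set(dmp_probe_ids)), "scaffold"]
    return int(hit.nunique()), len(annotation.scaffolds)
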