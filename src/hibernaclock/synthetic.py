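"""Synthetic DNA-methylation cohorts with planted age and hibernation effects.

The generator emulates a captive colony of a hibernating bat species sampled
in winter (hibernation) and summer (active season): most individuals
contribute one sample per season, ages span roughly the first decade of life,
and a subset of wild-caught animals have only minimum ages.  The beta-value
matrix carries three planted signal layers on top of truncated-Gaussian
noise:

* *clock sites* drift linearly with age, and additionally shift in winter so
  that the epigenetic age read off them is a fixed number of years younger
  during hibernation;
* *DMP sites* carry an additive seasonal offset (positive = more methylated
  in winter, "winter-up") with a configurable winter-up excess;
* all remaining sites are age- and season-free noise.

A :class:`SyntheticTruth` records every planted quantity so downstream
stages can be scored for parameter recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic")

WINTER_MONTH_OFFSET = 5.0 / 12.0  # summer sample taken ~5 months after winter


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is inconsistent."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: 20 individuals aged
    0.7–10.1 years, 30% wild-caught with minimum ages, 75% sampled in both
    seasons, a 77.5% winter-up excess among differentially methylated
    positions, and a planted epigenetic-age deceleration of 0.77 years
    during hibernation.

    Units: effect and noise scales are in beta units (proportion methylated);
    ``age_slope_sd`` is beta units per year; ``seasonal_age_offset`` is years.
    """

    n_individuals: int = 20
    frac_wild: float = 0.3
    frac_paired: float = 0.75
    age_range: tuple[float, float] = (0.7, 10.1)
    n_probes: int = 2000
    n_clock_sites: int = 50
    n_dmp_sites: int = 100
    frac_winter_up: float = 0.775
    dmp_effect_mean: float = 0.10
    dmp_effect_sd: float = 0.02
    noise_sd: float = 0.02
    individual_sd: float = 0.01
    age_slope_sd: float = 0.01
    seasonal_age_offset: float = 0.77
    missing_rate: float = 0.0
    n_scaffolds: int = 30
    genes_per_scaffold: int = 5
    immunity_set_size: int = 40
    longevity_set_size: int = 25
    immunity_overlap_frac: float = 0.5
    longevity_overlap_frac: float = 0.5
    n_element_maps: int = 10
    element_background_frac: float = 0.05
    element_planted_frac: float = 0.5
    seed: int = 0
    # probe-level biology (baselines, age slopes, planted effects, genome,
    # gene sets, element maps) is keyed separately so that disjoint cohorts
    # can share one array; defaults to `seed`
    probe_seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("need at least 2 individuals")
        for name in ("frac_wild", "frac_paired", "frac_winter_up",
                     "missing_rate", "immunity_overlap_frac",
                     "longevity_overlap_frac", "element_background_frac",
                     "element_planted_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.n_clock_sites + self.n_dmp_sites > self.n_probes:
            raise ConfigurationError(
                "n_clock_sites + n_dmp_sites exceeds n_probes")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise ConfigurationError("noise scales must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        if self.n_scaffolds < 1:
            raise ConfigurationError("need at least one scaffold")
        if self.genes_per_scaffold < 1:
            raise ConfigurationError(
                "genes_per_scaffold must be >= 1 so every genomic region "
                "class can be represented")

    # Deterministic per-component generators so each artefact (cohort, betas,
    # genome, gene sets, element maps) is reproducible independently.
    def rng(self, component: str) -> np.random.Generator:
        salt = {"cohort": 1, "betas": 2, "genome": 3,
                "genesets": 4, "elements": 5, "probe_params": 6}[component]
        base = self.seed if component in ("cohort", "betas") else \
            (self.probe_seed if self.probe_seed is not None else self.seed)
        return np.random.default_rng(np.random.SeedSequence([base, salt]))

    def probe_ids(self) -> list[str]:
        return [f"cg{i:06d}" for i in range(self.n_probes)]

    def clock_site_ids(self) -> list[str]:
        return self.probe_ids()[: self.n_clock_sites]

    def dmp_site_ids(self) -> list[str]:
        return self.probe_ids()[
            self.n_clock_sites: self.n_clock_sites + self.n_dmp_sites]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of all planted effects, for parameter-recovery scoring."""

    clock_site_ids: list[str]
    clock_slopes: pd.Series                 # beta units / year, per clock site
    dmp_sites: pd.DataFrame                 # probe_id, true_effect, true_direction
    true_ages: pd.Series                    # per individual, at winter sampling
    sample_true_ages: pd.Series             # per sample, at collection
    planted_seasonal_offset: float          # years
    n_clipped: int = 0


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a sample sheet for a paired winter/summer cohort.

    Each individual contributes one winter and one summer sample when paired,
    otherwise a single summer sample.  Wild-born individuals carry a
    minimum-age flag: their recorded age is the true age minus a positive
    censoring offset (animals caught as adults of unknown exact age).

    Returns a data frame with one row per sample: ``sample_id``,
    ``individual_id``, ``season`` (winter/summer), ``birthplace``
    (captive/wild), ``age_years`` (recorded; a lower bound when
    ``age_is_minimum``), ``age_true_years`` and ``collection_date``.
    """
    config.validate()
    rng = config.rng("cohort")
    n = config.n_individuals
    n_wild = int(round(config.frac_wild * n))
    n_paired = int(round(config.frac_paired * n))

    lo, hi = config.age_range
    base_age = rng.uniform(lo, hi, size=n)          # true age at winter sampling
    is_wild = np.zeros(n, dtype=bool)
    is_wild[rng.choice(n, size=n_wild, replace=False)] = True
    # Censoring offset for wild-caught animals: known alive for this many
    # years less than their true age.
    censor = rng.uniform(0.5, 2.0, size=n)
    is_paired = np.zeros(n, dtype=bool)
    is_paired[rng.choice(n, size=n_paired, replace=False)] = True

    rows = []
    for i in range(n):
        ind = f"bat{i:03d}"
        birthplace = "wild" if is_wild[i] else "captive"
        seasons = ["winter", "summer"] if is_paired[i] else ["summer"]
        for season in seasons:
            age_true = base_age[i] + (WINTER_MONTH_OFFSET if season == "summer" else 0.0)
            recorded = age_true - censor[i] if is_wild[i] else age_true
            recorded = max(recorded, 0.1)
            rows.append({
                "sample_id": f"{ind}_{season[0].upper()}",
                "individual_id": ind,
                "season": season,
                "birthplace": birthplace,
                "age_years": round(recorded, 4),
                "age_is_minimum": bool(is_wild[i]),
                "age_true_years": round(age_true, 4),
                "collection_date": "2020-02-15" if season == "winter" else "2020-07-15",
            })
    return pd.DataFrame(rows)


def _planted_directions(config: SyntheticConfig) -> np.ndarray:
    n_up = int(round(config.frac_winter_up * config.n_dmp_sites))
    return np.concatenate([np.ones(n_up), -np.ones(config.n_dmp_sites - n_up)])


def generate_beta_matrix(
    cohort: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a probes × samples beta matrix with planted structure.

    Clock sites: ``beta = baseline + slope * age_true``, minus
    ``slope * seasonal_age_offset`` in winter, so the epigenetic age read off
    these sites is exactly ``seasonal_age_offset`` years younger during
    hibernation.  DMP sites: additive ``±effect`` in winter, sign per planted
    direction with a ``frac_winter_up`` excess of winter-up sites.  Remaining
    sites are pure noise.  All values are clipped to [0, 1]; a warning is
    logged if clipping touches more than 10% of entries.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    config.validate()
    rng = config.rng("betas")
    probe_ids = config.probe_ids()
    n_probes, n_samples = config.n_probes, len(cohort)
    n_clock, n_dmp = config.n_clock_sites, config.n_dmp_sites

    ages = cohort["age_true_years"].to_numpy(float)
    winter = (cohort["season"] == "winter").to_numpy()
    individuals = cohort["individual_id"].to_numpy()
    uniq_ind, ind_index = np.unique(individuals, return_inverse=True)

    prng = config.rng("probe_params")
    baseline = prng.uniform(0.15, 0.85, size=n_probes)
    slopes = prng.normal(0.0, config.age_slope_sd, size=n_clock)
    directions = _planted_directions(config)
    effects = np.abs(prng.normal(config.dmp_effect_mean, config.dmp_effect_sd,
                                 size=n_dmp)) * directions

    values = np.tile(baseline[:, None], (1, n_samples))
    # clock layer: age trend plus winter rejuvenation by seasonal_age_offset
    effective_age = ages[None, :] - config.seasonal_age_offset * winter[None, :]
    values[:n_clock] += slopes[:, None] * effective_age
    # DMP layer: additive seasonal offset
    values[n_clock:n_clock + n_dmp] += effects[:, None] * winter[None, :]
    # within-individual correlation: per probe × individual random intercept
    if config.individual_sd > 0:
        u = rng.normal(0.0, config.individual_sd, size=(n_probes, len(uniq_ind)))
        values += u[:, ind_index]
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    n_clipped = int(np.sum((values < 0) | (values > 1)))
    if n_clipped > 0.10 * values.size:
        msg = (f"{n_clipped}/{values.size} beta values hit the [0,1] clipping "
               "bounds; planted effects are likely too large")
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    values = np.clip(values, 0.0, 1.0)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    betas = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                         columns=cohort["sample_id"].to_list())

    dmp_ids = config.dmp_site_ids()
    truth = SyntheticTruth(
        clock_site_ids=config.clock_site_ids(),
        clock_slopes=pd.Series(slopes, index=config.clock_site_ids(), name="slope"),
        dmp_sites=pd.DataFrame({
            "probe_id": dmp_ids,
            "true_effect": effects,
            "true_direction": np.where(directions > 0, "winter-up", "winter-down"),
        }),
        true_ages=pd.Series(
            cohort.drop_duplicates("individual_id")
                  .set_index("individual_id")["age_true_years"]
            - np.where(cohort.drop_duplicates("individual_id")["season"].to_numpy()
                       == "summer", WINTER_MONTH_OFFSET, 0.0),
            name="age_true_years"),
        sample_true_ages=cohort.set_index("sample_id")["age_true_years"].astype(float),
        planted_seasonal_offset=config.seasonal_age_offset,
        n_clipped=n_clipped,
    )
    return betas, truth


# ---------------------------------------------------------------------------
# toy genome


def generate_genome_annotation(config: SyntheticConfig):
    """Build a toy genome: scaffolds, gene models and probe placements.

    Genes get a strand, TSS, 2–4 exons and terminal UTRs.  Probes are placed
    so that every region class (promoter, 5'UTR, exon, intron, 3'UTR,
    intergenic) is represented, and planted DMP probes land inside or just
    upstream of genes spread across scaffolds so that gene-level direction
    calls and scaffold coverage have a known truth.  Coordinates are 0-based,
    half-open.
    """
    from hibernaclock.annotation import GenomeAnnotation

    config.validate()
    rng = config.rng("genome")
    scaffold_names = [f"scaffold_{i:04d}" for i in range(config.n_scaffolds)]

    gene_rows, feature_rows = [], []
    gene_counter = 0
    scaffold_lengths = {}
    for sc in scaffold_names:
        cursor = int(rng.integers(20_000, 60_000))
        for _ in range(config.genes_per_scaffold):
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(150, 1200, size=n_exons)
            # the first transcribed exon is long so part of its 5'UTR can
            # fall beyond the +1 kb promoter window
            if strand == "+":
                exon_lens[0] = int(rng.integers(1700, 2600))
            else:
                exon_lens[-1] = int(rng.integers(1700, 2600))
            intron_lens = rng.integers(800, 8000, size=n_exons - 1)
            start = cursor
            pos = start
            exons = []
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            end = exons[-1][1]
            gene_id = f"gene{gene_counter:05d}"
            gene_counter += 1
            tss = start if strand == "+" else end - 1
            gene_rows.append({"gene_id": gene_id, "scaffold": sc,
                              "strand": strand, "start": start, "end": end,
                              "tss": tss})
            # terminal UTRs occupy part of the first/last transcribed exon
            first, last = exons[0], exons[-1]
            if strand == "+":
                utr_len5 = min(1500, first[1] - first[0] - 100)
                utr_len3 = min(100, last[1] - last[0] - 1)
                utr5 = (first[0], first[0] + utr_len5)
                utr3 = (last[1] - utr_len3, last[1])
            else:
                utr_len5 = min(1500, last[1] - last[0] - 100)
                utr_len3 = min(100, first[1] - first[0] - 1)
                utr5 = (last[1] - utr_len5, last[1])
                utr3 = (first[0], first[0] + utr_len3)
            for s, e in exons:
                feature_rows.append({"gene_id": gene_id, "feature": "exon",
                                     "start": s, "end": e})
            feature_rows.append({"gene_id": gene_id, "feature": "utr5",
                                 "start": utr5[0], "end": utr5[1]})
            feature_rows.append({"gene_id": gene_id, "feature": "utr3",
                                 "start": utr3[0], "end": utr3[1]})
            cursor = end + int(rng.integers(30_000, 120_000))
        scaffold_lengths[sc] = cursor + int(rng.integers(20_000, 60_000))

    genes = pd.DataFrame(gene_rows)
    features = pd.DataFrame(feature_rows)

    probes = _place_probes(config, genes, features, scaffold_lengths, rng)
    return GenomeAnnotation(scaffolds=scaffold_lengths, genes=genes,
                            features=features, probes=probes)


def _place_probes(config, genes, features, scaffold_lengths, rng):
    """Assign each probe id a scaffold and coordinate.

    The first six probes cover the six region classes of the first gene.
    Planted DMP probes are placed in/near genes cycling across scaffolds;
    the rest are scattered uniformly.
    """
    probe_ids = config.probe_ids()
    n_clock, n_dmp = config.n_clock_sites, config.n_dmp_sites
    dmp_ids = set(config.dmp_site_ids())
    placements: dict[str, tuple[str, int]] = {}

    # guarantee one probe per region class: classify candidate positions
    # around the first scaffold's genes and keep the first hit per class
    from hibernaclock.annotation import GenomeAnnotation, annotate_probes

    sc0 = genes.iloc[0]["scaffold"]
    candidates = []
    for _, g in genes[genes["scaffold"] == sc0].iterrows():
        f = features[features["gene_id"] == g["gene_id"]]
        shift = 500 if g["strand"] == "-" else -500
        candidates.append(int(g["tss"] + shift))
        for _, row in f.iterrows():
            candidates.extend([int(row["start"]) + 10, int(row["end"]) - 10,
                               int(row["end"]) + 400])
        candidates.append(int(g["end"] + 15_000))
    candidates.append(int(scaffold_lengths[sc0] - 1000))
    candidates = sorted({c for c in candidates
                         if 0 <= c < scaffold_lengths[sc0]})
    probe_table = pd.DataFrame({
        "probe_id": [f"cand{i}" for i in range(len(candidates))],
        "scaffold": sc0, "pos": candidates})
    toy = GenomeAnnotation(scaffolds=scaffold_lengths, genes=genes,
                           features=features,
                           probes=pd.DataFrame(columns=["probe_id",
                                                        "scaffold", "pos"]))
    classified = annotate_probes(toy, probe_table)
    anchor_positions = []
    from hibernaclock.synthetic import REGIONS
    for region in REGIONS:
        hits = classified[classified["region"] == region]
        if not hits.empty:
            anchor_positions.append(int(hits.iloc[0]["pos"]))
    anchor_ids = probe_ids[config.n_clock_sites + config.n_dmp_sites:
                           config.n_clock_sites + config.n_dmp_sites
                           + len(anchor_positions)]
    for pid, pos in zip(anchor_ids, anchor_positions):
        placements[pid] = (sc0, pos)

    genes_by_row = genes.reset_index(drop=True)
    n_genes = len(genes_by_row)
    dmp_list = config.dmp_site_ids()
    for k, pid in enumerate(dmp_list):
        g = genes_by_row.iloc[k % n_genes]
        # alternate between gene body and promoter-proximal placement
        if k % 2 == 0:
            pos = int(rng.integers(g["start"], g["end"]))
        else:
            pos = int(g["tss"] - rng.integers(0, 5000)) if g["strand"] == "+" \
                else int(g["tss"] + rng.integers(0, 5000))
            pos = max(0, min(pos, scaffold_lengths[g["scaffold"]] - 1))
        placements[pid] = (g["scaffold"], pos)

    scaffold_names = list(scaffold_lengths)
    for pid in probe_ids:
        if pid in placements:
            continue
        sc = scaffold_names[int(rng.integers(0, len(scaffold_names)))]
        placements[pid] = (sc, int(rng.integers(0, scaffold_lengths[sc])))

    out = pd.DataFrame(
        {"probe_id": probe_ids,
         "scaffold": [placements[p][0] for p in probe_ids],
         "pos": [placements[p][1] for p in probe_ids]})
    out["is_dmp_site"] = out["probe_id"].isin(dmp_ids)
    return out


# ---------------------------------------------------------------------------
# gene sets and element maps


def generate_gene_sets(annotation, config: SyntheticConfig) -> dict[str, list[str]]:
    """Build background, immunity-like and longevity-like gene sets.

    The background is every annotated gene.  The immunity/longevity sets have
    configured sizes and draw a configured fraction of their members from
    genes nearest planted DMP probes (controlled true enrichment); the
    remainder is sampled from non-DMP genes.
    """
    from hibernaclock.annotation import annotate_probes

    config.validate()
    genes = list(annotation.genes["gene_id"])
    if len(genes) < 2:
        raise ConfigurationError("annotation must contain at least 2 genes")
    rng = config.rng("genesets")

    dmp_probe_ids = set(config.dmp_site_ids())
    probe_annot = annotate_probes(
        annotation, annotation.probes[annotation.probes["probe_id"].isin(dmp_probe_ids)])
    dmp_genes = sorted(set(probe_annot["nearest_gene"].dropna()))
    other_genes = sorted(set(genes) - set(dmp_genes))

    sets: dict[str, list[str]] = {"background": sorted(genes)}
    for name, size, frac in (
            ("immunity", config.immunity_set_size, config.immunity_overlap_frac),
            ("longevity", config.longevity_set_size, config.longevity_overlap_frac)):
        if size > len(genes):
            raise ConfigurationError(
                f"{name} set size {size} exceeds number of genes {len(genes)}")
        n_from_dmp = min(int(round(frac * size)), len(dmp_genes))
        chosen = list(rng.choice(dmp_genes, size=n_from_dmp, replace=False)) \
            if n_from_dmp else []
        n_rest = size - n_from_dmp
        pool = other_genes if frac == 0.0 else sorted(set(genes) - set(chosen))
        chosen += list(rng.choice(pool, size=n_rest, replace=False))
        sets[name] = sorted(chosen)
    return sets


def generate_element_maps(annotation, config: SyntheticConfig) -> dict[str, set[str]]:
    """Build synthetic functional-element maps (probe-id label sets).

    Emulates cell-line × mark/state maps: each null map labels a uniform
    ``element_background_frac`` of array probes; the map named
    ``planted_enhancer`` additionally covers ``element_planted_frac`` of the
    planted DMP probes, giving a known truly-enriched element.
    """
    config.validate()
    rng = config.rng("elements")
    probe_ids = np.array(annotation.probes["probe_id"])
    dmp_ids = np.array(config.dmp_site_ids())
    maps: dict[str, set[str]] = {}
    for k in range(config.n_element_maps):
        n_lab = int(round(config.element_background_frac * len(probe_ids)))
        maps[f"cellline{k:02d}_state"] = set(
            rng.choice(probe_ids, size=n_lab, replace=False))
    n_bg = int(round(config.element_background_frac * len(probe_ids)))
    n_planted = int(round(config.element_planted_frac * len(dmp_ids)))
    planted = set(rng.choice(probe_ids, size=n_bg, replace=False))
    planted |= set(rng.choice(dmp_ids, size=n_planted, replace=False))
    maps["planted_enhancer"] = planted
    return maps
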