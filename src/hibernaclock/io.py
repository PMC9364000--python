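"""Readers and writers for the pipeline's plain-text interchange formats.

Formats follow common array-methylation conventions: the beta matrix is a
CSV with probes as rows and sample ids as the header row (a GEO-series-like
layout); probe placements are BED-like TSVs (0-based, half-open); gene
models a GFF3-like TSV; gene sets GMT; configs YAML.  All writers use fixed
float formatting so a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FMT = "%.6g"


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, float_format=FLOAT_FMT, index_label="probe_id")


def read_beta_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="probe_id")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"age_is_minimum": bool})


def write_probe_bed(probes: pd.DataFrame, path) -> None:
    """BED-like: scaffold, start, end (start+1), probe_id."""
    bed = pd.DataFrame({
        "scaffold": probes["scaffold"],
        "start": probes["pos"].astype(int),
        "end": probes["pos"].astype(int) + 1,
        "probe_id": probes["probe_id"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_probe_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["scaffold", "start", "end", "probe_id"])
    return pd.DataFrame({"probe_id": bed["probe_id"],
                         "scaffold": bed["scaffold"],
                         "pos": bed["start"].astype(int)})


def write_gene_models(annotation, path) -> None:
    """GFF3-like TSV: one row per gene and per feature interval."""
    rows = []
    for _, g in annotation.genes.iterrows():
        rows.append((g["scaffold"], "gene", int(g["start"]), int(g["end"]),
                     g["strand"], g["gene_id"]))
    gene_info = annotation.genes.set_index("gene_id")
    for _, f in annotation.features.iterrows():
        g = gene_info.loc[f["gene_id"]]
        rows.append((g["scaffold"], f["feature"], int(f["start"]),
                     int(f["end"]), g["strand"], f["gene_id"]))
    df = pd.DataFrame(rows, columns=["scaffold", "feature", "start", "end",
                                     "strand", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path, scaffolds: dict[str, int] | None = None):
    from hibernaclock.annotation import GenomeAnnotation

    df = pd.read_csv(path, sep="\t")
    genes = df[df["feature"] == "gene"].copy()
    genes["tss"] = genes.apply(
        lambda g: g["start"] if g["strand"] == "+" else g["end"] - 1, axis=1)
    genes = genes[["gene_id", "scaffold", "strand", "start", "end", "tss"]]
    features = df[df["feature"] != "gene"][["gene_id", "feature", "start", "end"]]
    if scaffolds is None:
        scaffolds = {sc: int(df[df["scaffold"] == sc]["end"].max()) + 10_000
                     for sc in df["scaffold"].unique()}
    return GenomeAnnotation(scaffolds=scaffolds,
                            genes=genes.reset_index(drop=True),
                            features=features.reset_index(drop=True),
                            probes=pd.DataFrame(
                                columns=["probe_id", "scaffold", "pos"]))


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            members = "\t".join(gene_sets[name])
            fh.write(f"{name}\tsynthetic\t{members}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_element_maps(maps: dict[str, set[str]], path) -> None:
    """Element maps as a two-column TSV: map name, labelled probe id."""
    with open(path, "w") as fh:
        for name in sorted(maps):
            for pid in sorted(maps[name]):
                fh.write(f"{name}\t{pid}\n")


def read_element_maps(path) -> dict[str, set[str]]:
    maps: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            name, pid = line.rstrip("\n").split("\t")
            maps.setdefault(name, set()).add(pid)
    return maps


def write_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path):
    from hibernaclock.synthetic import SyntheticConfig

    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["age_range"] = tuple(d["age_range"])
    return SyntheticConfig(**d)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
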