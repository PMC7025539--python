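"""Packaged reference tables: parental map statistics, diagnostic genotype
classes and the amplicon haplotype catalog."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .linkmap import MapSummary
from .stshap import HaplotypeCatalog, load_catalog

_CHECKSUMS = {
    "map_statistics.tsv":
        "b3e8efa1dce6467dc2b7145c753b8a71792ad34a11c6e84e3c5166594a5e2aec",
    "diagnostic_genotypes.tsv":
        "eb01f0ae580342a228e6eece54c442dc4cd0cbd1077ed1ffffad0f764996cb04",
    "haplotype_catalog.tsv":
        "c2b8ebee8cafb31cb7a344af8f600adeee823171503e0cd0a57e6ccb270b7ea2",
}


def _data_path(name: str):
    return resources.files("olivemap.data") / name


def _verify(name: str) -> None:
    with resources.as_file(_data_path(name)) as p:
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"checksum mismatch for packaged table {name}")


def load_map_statistics() -> pd.DataFrame:
    """Per-parent, per-chromosome marker/length/bin statistics.

    Rows with ``chrom == 'total'`` carry the published totals.  Note the
    published male per-chromosome lengths sum to 100 cM more than the
    published male total; both are kept as printed.
    """
    _verify("map_statistics.tsv")
    with resources.as_file(_data_path("map_statistics.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_diagnostic_genotypes() -> pd.DataFrame:
    """The 11 diagnostic genotype classes with their haplotype combinations."""
    _verify("diagnostic_genotypes.tsv")
    with resources.as_file(_data_path("diagnostic_genotypes.tsv")) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def load_haplotype_catalog() -> HaplotypeCatalog:
    _verify("haplotype_catalog.tsv")
    return load_catalog()


@dataclass(frozen=True)
class TableFixtures:
    map_statistics: pd.DataFrame
    diagnostic_genotypes: pd.DataFrame
    haplotype_catalog: HaplotypeCatalog


def load_table_fixtures() -> TableFixtures:
    """All packaged tables as typed structures (checksum-verified)."""
    return TableFixtures(map_statistics=load_map_statistics(),
                         diagnostic_genotypes=load_diagnostic_genotypes(),
                         haplotype_catalog=load_haplotype_catalog())


def map_summary_from_table(parent: str) -> MapSummary:
    """A :class:`MapSummary` built from the packaged map-statistics table,
    interchangeable with summaries of maps built in-package."""
    df = load_map_statistics()
    sub = df[df["parent"] == parent]
    if sub.empty:
        raise ValueError(f"unknown parent {parent!r}")
    totals_row = sub[sub["chrom"] == "total"]
    per_group = sub[sub["chrom"] != "total"].rename(columns={"chrom": "lg"})[
        ["lg", "n_markers", "length_cM", "n_bins"]].reset_index(drop=True)
    totals = None
    if not totals_row.empty:
        r = totals_row.iloc[0]
        totals = {"n_markers": int(r["n_markers"]),
                  "length_cM": float(r["length_cM"]),
                  "n_bins": int(r["n_bins"])}
    return MapSummary(parent=parent, per_group=per_group,
                      published_totals=totals)
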