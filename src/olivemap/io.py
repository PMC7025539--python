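"""File formats, configuration and the end-to-end pipeline.

Formats are deliberately plain text: genotype matrices and maps as TSV,
phenotypes and reports as CSV, ground truth as JSON.  Every writer prepends a
provenance header (``#`` lines: package version, seed, parameters) that all
readers skip, and every writer/reader pair round-trips.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genocall import (CallingThresholds, GenotypeMatrix, VALIDATED,
                       build_genotype_matrix, call_read_matrix, check_parentage)
from .linkmap import (GeneticBin, GeneticMap, LinkageGroup, MappingParams,
                      build_parent_map, distortion_scan, map_stats)
from .simcross import (CrossConfig, ReadCountMatrix, simulate_cross,
                       simulate_reads)
from .stshap import classify_dsi, genotype_from_diagnostics, load_catalog
from .tables import load_diagnostic_genotypes
from .traitmap import map_trait, segregation_test, usable_phenotypes

logger = logging.getLogger(__name__)


def _provenance_lines(seed: int | None = None, **params) -> list[str]:
    lines = [f"# olivemap {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in params.items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_with_header(path: Path, frame: pd.DataFrame, sep: str,
                       index: bool, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        frame.to_csv(fh, sep=sep, index=index)


# ---------------------------------------------------------------------------
# Genotype matrix TSV
# ---------------------------------------------------------------------------

def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path,
                       seed: int | None = None) -> None:
    """One row per marker: id, mother, father, seg_class, offspring calls."""
    df = pd.concat(
        [gm.mother.rename("mother"), gm.father.rename("father"),
         gm.seg_class.rename("seg_class"), gm.calls], axis=1)
    df.index.name = "marker"
    _write_with_header(Path(path), df, "\t", True, _provenance_lines(seed))


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="marker",
                     dtype=str, keep_default_na=False)
    df.index.name = None
    return GenotypeMatrix(
        calls=df.drop(columns=["mother", "father", "seg_class"]),
        mother=df["mother"], father=df["father"], seg_class=df["seg_class"])


# ---------------------------------------------------------------------------
# Read counts / phenotypes / truth
# ---------------------------------------------------------------------------

def write_read_counts_tsv(rc: ReadCountMatrix, path: str | Path,
                          seed: int | None = None) -> None:
    _write_with_header(Path(path), rc.to_long_frame(), "\t", False,
                       _provenance_lines(seed))


def read_read_counts_tsv(path: str | Path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker": str,
                     "individual": str, "allele": str, "count": int})
    return ReadCountMatrix.from_long_frame(df)


def write_phenotypes_csv(phenotypes: pd.Series, path: str | Path,
                         seed: int | None = None) -> None:
    df = phenotypes.rename("phenotype").to_frame()
    df.index.name = "individual"
    _write_with_header(Path(path), df, ",", True, _provenance_lines(seed))


def read_phenotypes_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, comment="#", index_col="individual", dtype=str,
                     keep_default_na=False)
    return df["phenotype"]


def write_truth_json(population, path: str | Path, error_log=None) -> None:
    payload = {
        "contaminants": sorted(population.contaminant[population.contaminant]
                               .index.tolist()),
        "phenotypes": population.phenotypes.to_dict(),
        "dsi_maternal_allele": population.dsi_maternal_allele.to_dict(),
        "crossovers": population.crossovers,
        "injected_errors": ([] if error_log is None
                            else error_log.to_dict(orient="records")),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Map TSV
# ---------------------------------------------------------------------------

def write_map_tsv(gmap: GeneticMap, path: str | Path,
                  seed: int | None = None) -> None:
    rows = []
    for g in gmap.groups:
        for bi, b in enumerate(g.bins):
            rows.append((g.lg_id, bi, round(b.position_cM, 4),
                         b.representative, ",".join(b.markers)))
    df = pd.DataFrame(rows, columns=["lg", "bin_index", "position_cM",
                                     "representative", "markers"])
    _write_with_header(Path(path), df, "\t", False,
                       _provenance_lines(seed, parent=gmap.parent))


def read_map_tsv(path: str | Path) -> GeneticMap:
    """Rebuild map structure (without patterns) from a map TSV."""
    parent = "unknown"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# parent:"):
                parent = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    groups = []
    for lg_id, sub in df.groupby("lg"):
        sub = sub.sort_values("bin_index")
        bins = [GeneticBin(representative=r["representative"],
                           markers=str(r["markers"]).split(","),
                           position_cM=float(r["position_cM"]))
                for _, r in sub.iterrows()]
        groups.append(LinkageGroup(lg_id=int(lg_id), bins=bins))
    groups.sort(key=lambda g: g.lg_id)
    return GeneticMap(parent=parent, groups=groups)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Stage parameter blocks for the end-to-end pipeline."""

    cross: CrossConfig = field(default_factory=CrossConfig)
    calling: CallingThresholds = field(default_factory=CallingThresholds)
    mapping: MappingParams = field(default_factory=MappingParams)
    max_parentage_mismatches: int = 1
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, sub_cls in (("cross", CrossConfig),
                              ("calling", CallingThresholds),
                              ("mapping", MappingParams)):
            block = dict(raw.get(name, {}))
            sub_known = {f.name for f in dataclasses.fields(sub_cls)}
            sub_unknown = set(block) - sub_known
            if sub_unknown:
                raise ValueError(
                    f"unknown keys in config block {name!r}: {sorted(sub_unknown)}")
            kwargs[name] = sub_cls(**block)
        for name in ("max_parentage_mismatches", "seed", "verbosity"):
            if name in raw:
                kwargs[name] = raw[name]
        if "seed" in raw and "seed" not in raw.get("cross", {}):
            kwargs["cross"] = dataclasses.replace(kwargs["cross"],
                                                  seed=int(raw["seed"]))
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """simulate -> call -> check-parents -> map -> trait-map -> classify.

    Writes each stage's artifacts under ``out_dir`` and returns the in-memory
    results.  Idempotent for a fixed seed.  A stage failure aborts with the
    stage name in the exception.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    results: dict = {}
    stage = "simulate"
    try:
        genome, pop = simulate_cross(config.cross)
        reads, err_log = simulate_reads(genome, pop, config.cross)
        write_genotype_tsv(pop.genotypes, out / "true_genotypes.tsv", seed)
        write_read_counts_tsv(reads, out / "read_counts.tsv", seed)
        write_phenotypes_csv(pop.phenotypes, out / "phenotypes.csv", seed)
        write_truth_json(pop, out / "truth.json", err_log)
        logger.info("simulate: %d markers, %d offspring (%d contaminants)",
                    len(genome.markers), len(pop.individuals),
                    int(pop.contaminant.sum()))
        results["population"] = pop

        stage = "call"
        call_table = call_read_matrix(reads, config.calling)
        gm, exclusions = build_genotype_matrix(call_table,
                                               mother_id="mother",
                                               father_id="father",
                                               thresholds=config.calling)
        logger.info("call: %d/%d markers retained", len(gm.marker_ids),
                    len(call_table))
        if not gm.marker_ids:
            raise ValueError("no markers retained by the calling thresholds")
        results["genotypes"] = gm
        results["marker_exclusions"] = exclusions

        stage = "check-parents"
        parentage = check_parentage(pop.parentage_genotypes,
                                    genome.parentage_mother,
                                    genome.parentage_father,
                                    config.max_parentage_mismatches)
        parentage.to_csv(out / "parentage.csv")
        validated = [i for i in pop.individuals
                     if parentage.loc[i, "status"] == VALIDATED]
        logger.info("check-parents: %d/%d validated", len(validated),
                    len(pop.individuals))
        gm = gm.subset_individuals([i for i in gm.individuals
                                    if i in set(validated)])
        results["parentage"] = parentage

        stage = "map"
        maps = {}
        for parent in ("mother", "father"):
            gmap, removals = build_parent_map(gm, parent, config.mapping)
            write_map_tsv(gmap, out / f"map_{parent}.tsv", seed)
            stats = map_stats(gmap)
            logger.info("map[%s]: %d markers, %d bins, %.1f cM", parent,
                        stats.total_markers, stats.total_bins,
                        stats.total_length)
            maps[parent] = gmap
        results["maps"] = maps
        distortion = distortion_scan(gm, config.mapping)
        distortion.to_csv(out / "distortion.csv")
        results["distortion"] = distortion

        stage = "trait-map"
        phenos = pop.phenotypes[validated]
        chi2, p, ok = segregation_test(phenos)
        report = map_trait(phenos, maps["mother"], config.mapping)
        payload = {
            "segregation_chi2": round(chi2, 4), "segregation_p": round(p, 6),
            "consistent_1to1": bool(ok), "lg": report.lg_id,
            "trait_position_cM": report.trait_position_cM,
            "co_segregating": report.co_segregating,
            "interval_cM": report.interval_cM,
            "upper_flank": dataclasses.asdict(report.upper_flank),
            "lower_flank": dataclasses.asdict(report.lower_flank),
            "n_phenotyped": report.n_phenotyped,
            "unlinked": report.unlinked,
        }
        (out / "trait_interval.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
        results["trait_report"] = report

        stage = "classify"
        catalog = load_catalog()
        rows = []
        for _, r in load_diagnostic_genotypes().iterrows():
            geno = genotype_from_diagnostics(r["geno63"], r["geno283"])
            cls = classify_dsi(geno, catalog)
            rows.append((r["combination"], r["geno63"], r["geno283"],
                         cls.group,
                         ";".join("/".join(p) for p in cls.consistent_pairs)))
        cls_df = pd.DataFrame(rows, columns=["combination", "geno63",
                                             "geno283", "group", "pairs"])
        _write_with_header(out / "classification.csv", cls_df, ",", False,
                           _provenance_lines(seed))
        results["classification"] = cls_df
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
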