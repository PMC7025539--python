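"""Mendelian trait-locus localisation by co-segregation on a parental map.

A binary phenotype segregating 1:1 from one parent is encoded as a testcross
pseudo-marker and compared with every genetic bin of that parent's map.  The
locus is placed at the bin(s) with zero recombinants among phenotyped,
genotyped individuals; its interval is delimited by the nearest flanking bins
showing at least one recombinant, with the supporting recombinant individuals
reported per border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linkmap import GeneticMap, MappingParams

G1 = "G1"
G2 = "G2"
UNKNOWN = "unknown"

PHENOTYPE_VALUES = (G1, G2, UNKNOWN)


def usable_phenotypes(phenotypes: pd.Series) -> pd.Series:
    """Drop discarded/unknown individuals before any computation."""
    return phenotypes[phenotypes.isin([G1, G2])]


def segregation_test(phenotypes: pd.Series, alpha: float = 0.05,
                     ) -> tuple[float, float, bool]:
    """Goodness-of-fit of G1:G2 counts against 1:1.

    Returns (chi2, p, consistent) with chi2 = (a-b)^2/(a+b) on 1 df.
    """
    usable = usable_phenotypes(phenotypes)
    a = int((usable == G1).sum())
    b = int((usable == G2).sum())
    if a + b == 0:
        raise ValueError("no phenotyped individuals")
    chi2 = (a - b) ** 2 / (a + b)
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, p, p >= alpha


@dataclass
class FlankSupport:
    bin_id: str | None
    position_cM: float | None
    n_recombinants: int
    recombinant_ids: list[str] = field(default_factory=list)

    @property
    def open_ended(self) -> bool:
        return self.bin_id is None


@dataclass
class TraitIntervalReport:
    lg_id: int | None
    trait_position_cM: float | None
    co_segregating: list[str]  # bin representatives with zero recombinants
    min_recombinants: int
    upper_flank: FlankSupport
    lower_flank: FlankSupport
    interval_cM: float | None
    n_phenotyped: int
    recombinant_ids: list[str]
    s_phase: int | None  # pattern value transmitted with G1 at the trait bin
    unlinked: bool = False
    per_bin: pd.DataFrame | None = None

    @property
    def linked(self) -> bool:
        return not self.unlinked


def _recombinants(trait: np.ndarray, pattern: np.ndarray,
                  individuals: list[str]) -> tuple[int, list[str], int, int]:
    """(count, ids, n informative, phase) for the better of the two phases."""
    mask = (trait >= 0) & (pattern >= 0)
    n = int(mask.sum())
    if n == 0:
        return 0, [], 0, 1
    mism = (trait != pattern) & mask
    match = (trait == pattern) & mask
    if int(mism.sum()) <= int(match.sum()):
        rec_mask, phase = mism, 1  # G1 in phase with pattern value 1
    else:
        rec_mask, phase = match, 0
    ids = [individuals[i] for i in np.nonzero(rec_mask)[0]]
    return len(ids), ids, n, phase


def map_trait(phenotypes: pd.Series, gmap: GeneticMap,
              params: MappingParams | None = None,
              max_unlinked_fraction: float = 0.20) -> TraitIntervalReport:
    """Place a binary trait on ``gmap`` by recombinant counting.

    Individuals with unknown phenotype or missing genotype at a bin are
    skipped for that bin.  If no bin shows a recombinant fraction below
    ``max_unlinked_fraction`` the trait is reported unlinked (not an error).
    """
    params = params or MappingParams()
    usable = usable_phenotypes(phenotypes)
    if len(usable) < 2:
        raise ValueError("need at least two phenotyped individuals")
    individuals = gmap.individuals
    trait = np.full(len(individuals), -1, dtype=np.int8)
    for i, ind in enumerate(individuals):
        if ind in usable.index:
            trait[i] = 1 if usable[ind] == G1 else 0

    records = []
    for g in gmap.groups:
        for bi, b in enumerate(g.bins):
            n_rec, ids, n_inf, phase = _recombinants(trait, b.pattern, individuals)
            frac = n_rec / n_inf if n_inf else 1.0
            records.append((g.lg_id, bi, b.representative, b.position_cM,
                            n_rec, n_inf, frac, phase, ids))
    per_bin = pd.DataFrame(records, columns=[
        "lg", "bin_index", "bin", "position_cM", "n_recombinants",
        "n_informative", "recomb_fraction", "phase", "recombinant_ids"])
    n_phenotyped = int((trait >= 0).sum())

    informative = per_bin[per_bin["n_informative"] > 0]
    if informative.empty or informative["recomb_fraction"].min() >= max_unlinked_fraction:
        return TraitIntervalReport(
            lg_id=None, trait_position_cM=None, co_segregating=[],
            min_recombinants=0,
            upper_flank=FlankSupport(None, None, 0),
            lower_flank=FlankSupport(None, None, 0),
            interval_cM=None, n_phenotyped=n_phenotyped, recombinant_ids=[],
            s_phase=None, unlinked=True, per_bin=per_bin)

    best = informative.loc[informative["recomb_fraction"].idxmin()]
    lg_id = int(best["lg"])
    lg_bins = per_bin[per_bin["lg"] == lg_id].sort_values("bin_index")
    counts = lg_bins["n_recombinants"].to_numpy()
    inf_counts = lg_bins["n_informative"].to_numpy()
    min_rec = int(best["n_recombinants"])
    zero_idx = np.nonzero((counts == min_rec) & (inf_counts > 0))[0]
    # contiguous hull of the minimal-recombinant bins
    lo, hi = int(zero_idx.min()), int(zero_idx.max())
    co_seg = (list(lg_bins["bin"].to_numpy()[zero_idx]) if min_rec == 0 else [])

    def flank(direction: int) -> FlankSupport:
        idx = lo - 1 if direction < 0 else hi + 1
        while 0 <= idx < len(lg_bins):
            row = lg_bins.iloc[idx]
            if row["n_informative"] > 0 and row["n_recombinants"] > min_rec:
                return FlankSupport(row["bin"], float(row["position_cM"]),
                                    int(row["n_recombinants"]),
                                    list(row["recombinant_ids"]))
            idx += direction
        return FlankSupport(None, None, 0)

    upper, lower = flank(-1), flank(+1)
    interval = None
    if upper.position_cM is not None and lower.position_cM is not None:
        interval = abs(lower.position_cM - upper.position_cM)
    positions = lg_bins["position_cM"].to_numpy()
    trait_pos = float(np.mean(positions[lo:hi + 1]))
    rec_ids = sorted({i for ids in lg_bins["recombinant_ids"].iloc[lo:hi + 1]
                      for i in ids})
    s_phase = int(lg_bins["phase"].iloc[lo])
    return TraitIntervalReport(
        lg_id=lg_id, trait_position_cM=trait_pos, co_segregating=co_seg,
        min_recombinants=min_rec, upper_flank=upper, lower_flank=lower,
        interval_cM=interval, n_phenotyped=n_phenotyped,
        recombinant_ids=rec_ids, s_phase=s_phase, per_bin=per_bin)


def flank_support(report: TraitIntervalReport) -> pd.DataFrame:
    """Border-evidence table: recombinant counts and individuals per flank."""
    if report.unlinked:
        raise ValueError("trait is unlinked; no flanks to report")
    rows = []
    for name, fl in (("upper", report.upper_flank), ("lower", report.lower_flank)):
        rows.append((name, fl.bin_id if fl.bin_id is not None else "open",
                     fl.position_cM, fl.n_recombinants,
                     ",".join(fl.recombinant_ids)))
    return pd.DataFrame(rows, columns=["flank", "bin", "position_cM",
                                       "n_recombinants", "recombinant_ids"])


def render_recombinants(report: TraitIntervalReport, gmap: GeneticMap,
                        phenotypes: pd.Series, window: int = 5) -> str:
    """Text diagram of recombinant chromosomes around the trait interval.

    One column per recombinant individual; '#' marks the allele in phase with
    G1 (the dominant determinant), '.' the alternative, ' ' missing.
    """
    if report.unlinked or report.lg_id is None:
        return "trait unlinked; nothing to render"
    lg = next(g for g in gmap.groups if g.lg_id == report.lg_id)
    lg_bins = report.per_bin[report.per_bin["lg"] == report.lg_id]
    focus = [b for b in (report.upper_flank.bin_id, report.lower_flank.bin_id,
                         *report.co_segregating) if b is not None]
    idx = [i for i, b in enumerate(lg.bins) if b.representative in focus]
    lo = max(0, min(idx) - window) if idx else 0
    hi = min(len(lg.bins), max(idx) + window + 1) if idx else len(lg.bins)
    inds = report.recombinant_ids + \
        [i for f in (report.upper_flank, report.lower_flank)
         for i in f.recombinant_ids]
    inds = sorted(dict.fromkeys(inds))
    individuals = gmap.individuals
    phase_by_bin = dict(zip(lg_bins["bin"], lg_bins["phase"]))
    lines = [f"LG {report.lg_id}: recombinant chromosomes "
             f"({len(inds)} individuals)"]
    header = " " * 30 + " ".join(f"{i[:8]:>8}" for i in inds)
    lines.append(header)
    for b in lg.bins[lo:hi]:
        cells = []
        for ind in inds:
            v = b.pattern[individuals.index(ind)]
            if v < 0:
                cells.append(" " * 8)
            else:
                in_phase = v == phase_by_bin.get(b.representative, 1)
                cells.append(f"{'#' if in_phase else '.':>8}")
        tag = "*" if b.representative in report.co_segregating else " "
        lines.append(f"{b.representative:>20} {b.position_cM:7.2f}{tag} "
                     + " ".join(cells))
    return "\n".join(lines)
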