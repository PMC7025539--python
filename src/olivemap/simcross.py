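"""Synthetic F1 pseudo-testcross populations with a diallelic SI locus.

Meioses follow a Poisson (no-interference) crossover model on the genetic
scale: per chromosome the crossover count is Poisson with mean equal to the
sex-specific genetic length in Morgans, breakpoints are uniform, and a gamete
switches between the parent's two phased haplotypes at every breakpoint.  A
dominant-S incompatibility locus (mother Ss, father ss) is transmitted like
any other locus, so offspring phenotypes segregate 1:1 (G1 carries S).

Contaminant (non-true-to-type) offspring are produced as female parent x an
unrelated random pollen donor, so they are detectable only through paternal
alleles at the multi-allelic parentage markers, mirroring open pollination.
All randomness flows from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genocall import (FULLY_INFORMATIVE, GenotypeMatrix, MATERNAL_TC,
                       MISSING, PATERNAL_TC)

DONOR_ALLELE_POOL = [str(i) for i in range(1, 11)]
MOTHER_P_ALLELES = ("1", "2")
FATHER_P_ALLELES = ("3", "4")


@dataclass
class CrossConfig:
    """Parameters of a simulated biparental cross."""

    n_chromosomes: int = 23
    female_chrom_lengths: Sequence[float] | None = None  # cM
    male_chrom_lengths: Sequence[float] | None = None  # cM
    heterochiasmy_ratio: float = 1.6  # female/male map-length ratio
    markers_per_chromosome: int = 60
    seg_class_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    dsi_chromosome: int = 18  # 1-based
    dsi_position: float | None = None  # cM on the female scale
    n_offspring: int = 229
    contaminant_fraction: float = 0.05
    genotyping_error_rate: float = 0.005
    mean_depth: float = 40.0
    depth_dispersion: float = 2.0
    seq_error: float = 0.01
    n_parentage_markers: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.markers_per_chromosome < 1:
            raise ValueError("need at least one marker per chromosome")
        if self.n_offspring < 1:
            raise ValueError("need at least one offspring")
        if self.heterochiasmy_ratio <= 0:
            raise ValueError("heterochiasmy_ratio must be > 0")
        if self.female_chrom_lengths is None:
            self.female_chrom_lengths = [120.0] * self.n_chromosomes
        self.female_chrom_lengths = [float(x) for x in self.female_chrom_lengths]
        if len(self.female_chrom_lengths) != self.n_chromosomes:
            raise ValueError("female_chrom_lengths length mismatch")
        if self.male_chrom_lengths is None:
            self.male_chrom_lengths = [x / self.heterochiasmy_ratio
                                       for x in self.female_chrom_lengths]
        self.male_chrom_lengths = [float(x) for x in self.male_chrom_lengths]
        if len(self.male_chrom_lengths) != self.n_chromosomes:
            raise ValueError("male_chrom_lengths length mismatch")
        if any(x <= 0 for x in self.female_chrom_lengths + self.male_chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if abs(sum(self.seg_class_mix) - 1.0) > 1e-9:
            raise ValueError("seg_class_mix must sum to 1")
        if any(p < 0 or p > 1 for p in self.seg_class_mix):
            raise ValueError("seg_class_mix proportions must lie in [0,1]")
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError("contaminant_fraction must lie in [0,1)")
        if not (1 <= self.dsi_chromosome <= self.n_chromosomes):
            raise ValueError("dsi_chromosome out of range")
        L = self.female_chrom_lengths[self.dsi_chromosome - 1]
        if self.dsi_position is None:
            self.dsi_position = L / 2.0
        if not (0.0 <= self.dsi_position <= L):
            raise ValueError("dsi_position outside its chromosome")
        for name in ("genotyping_error_rate", "seq_error"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth >= 0 and depth_dispersion > 0 required")

    @property
    def n_total_offspring(self) -> int:
        """Offspring drawn, including contaminants, so that n_offspring remain."""
        return int(round(self.n_offspring / (1.0 - self.contaminant_fraction)))

    @property
    def n_contaminants(self) -> int:
        return self.n_total_offspring - self.n_offspring


@dataclass
class MarkerDef:
    """One simulated marker with its phased parental alleles."""

    marker_id: str
    chrom: int  # 1-based
    pos_female: float  # cM on the female map
    pos_male: float  # cM on the male map
    seg_class: str
    mother_haps: tuple[str, str]
    father_haps: tuple[str, str]

    @property
    def alphabet(self) -> list[str]:
        return sorted(set(self.mother_haps) | set(self.father_haps))


@dataclass
class ParentalGenome:
    """Phased parental haplotypes over all simulated markers."""

    markers: list[MarkerDef]
    dsi_chromosome: int
    dsi_position: float
    mother_dsi_haps: tuple[str, str]  # phased ('S','s') or ('s','S')
    father_dsi_haps: tuple[str, str] = ("s", "s")
    parentage_mother: dict[str, str] = field(default_factory=dict)
    parentage_father: dict[str, str] = field(default_factory=dict)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def markers_on(self, chrom: int) -> list[MarkerDef]:
        return [m for m in self.markers if m.chrom == chrom]


@dataclass
class SimulatedPopulation:
    """Ground truth for a simulated cross."""

    individuals: list[str]
    contaminant: pd.Series  # bool per offspring
    genotypes: GenotypeMatrix  # true calls
    phenotypes: pd.Series  # 'G1' / 'G2'
    dsi_maternal_allele: pd.Series  # 'S' / 's' transmitted by the mother
    maternal_origin: pd.DataFrame  # markers x offspring, 0/1 mother haplotype
    paternal_origin: pd.DataFrame  # markers x offspring, 0/1, -1 for contaminants
    crossovers: dict  # individual -> {"maternal"/"paternal": {chrom: [cM, ...]}}
    parentage_genotypes: pd.DataFrame  # offspring x parentage markers, "a/b"

    @property
    def true_to_type_ids(self) -> list[str]:
        return [i for i in self.individuals if not self.contaminant[i]]


@dataclass
class ReadCountMatrix:
    """Per-marker, per-individual allele read counts."""

    individuals: list[str]
    alleles: dict[str, list[str]]  # marker -> allele alphabet
    counts: dict[str, np.ndarray]  # marker -> (n_individuals x n_alleles)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.counts)

    def cell(self, marker_id: str, individual: str) -> dict[str, int]:
        i = self.individuals.index(individual)
        return dict(zip(self.alleles[marker_id],
                        (int(x) for x in self.counts[marker_id][i])))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for mid in self.counts:
            arr = self.counts[mid]
            for i, ind in enumerate(self.individuals):
                for j, allele in enumerate(self.alleles[mid]):
                    rows.append((mid, ind, allele, int(arr[i, j])))
        return pd.DataFrame(rows, columns=["marker", "individual", "allele", "count"])

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "ReadCountMatrix":
        individuals = list(dict.fromkeys(df["individual"]))
        ind_idx = {x: i for i, x in enumerate(individuals)}
        alleles: dict[str, list[str]] = {}
        counts: dict[str, np.ndarray] = {}
        for mid, grp in df.groupby("marker", sort=False):
            al = list(dict.fromkeys(grp["allele"]))
            arr = np.zeros((len(individuals), len(al)), dtype=np.int64)
            aidx = {a: j for j, a in enumerate(al)}
            for _, r in grp.iterrows():
                arr[ind_idx[r["individual"]], aidx[r["allele"]]] = r["count"]
            alleles[str(mid)] = al
            counts[str(mid)] = arr
        return cls(individuals, alleles, counts)


def _draw_parental_genome(config: CrossConfig, rng: np.random.Generator) -> ParentalGenome:
    markers: list[MarkerDef] = []
    classes = np.array([MATERNAL_TC, PATERNAL_TC, FULLY_INFORMATIVE])
    for c in range(1, config.n_chromosomes + 1):
        Lf = config.female_chrom_lengths[c - 1]
        Lm = config.male_chrom_lengths[c - 1]
        m = config.markers_per_chromosome
        pos_f = np.linspace(0.0, Lf, m) if m > 1 else np.array([Lf / 2.0])
        seg = rng.choice(classes, size=m, p=list(config.seg_class_mix))
        for k in range(m):
            mother: tuple[str, str]
            father: tuple[str, str]
            if seg[k] == MATERNAL_TC:
                mother = ("A", "B") if rng.integers(2) == 0 else ("B", "A")
                hom = "A" if rng.integers(2) == 0 else "B"
                father = (hom, hom)
            elif seg[k] == PATERNAL_TC:
                hom = "A" if rng.integers(2) == 0 else "B"
                mother = (hom, hom)
                father = ("A", "B") if rng.integers(2) == 0 else ("B", "A")
            else:
                mother = ("A", "B") if rng.integers(2) == 0 else ("B", "A")
                father = ("C", "D") if rng.integers(2) == 0 else ("D", "C")
            markers.append(MarkerDef(
                marker_id=f"c{c:02d}m{k:03d}", chrom=c,
                pos_female=float(pos_f[k]), pos_male=float(pos_f[k] * Lm / Lf),
                seg_class=str(seg[k]), mother_haps=mother, father_haps=father))
    mother_dsi = ("S", "s") if rng.integers(2) == 0 else ("s", "S")
    p_mother = {f"ssr{k:02d}": "/".join(MOTHER_P_ALLELES)
                for k in range(config.n_parentage_markers)}
    p_father = {f"ssr{k:02d}": "/".join(FATHER_P_ALLELES)
                for k in range(config.n_parentage_markers)}
    return ParentalGenome(markers=markers, dsi_chromosome=config.dsi_chromosome,
                          dsi_position=float(config.dsi_position),
                          mother_dsi_haps=mother_dsi,
                          parentage_mother=p_mother, parentage_father=p_father)


def _gamete_origin(rng: np.random.Generator, length_cM: float,
                   positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype-of-origin (0/1) at each position for one meiosis.

    Crossover count ~ Poisson(length/100), breakpoints uniform, no
    interference; the starting haplotype is a fair coin.
    """
    n_co = rng.poisson(length_cM / 100.0)
    breakpoints = np.sort(rng.uniform(0.0, length_cM, size=n_co))
    start = int(rng.integers(2))
    origin = (start + np.searchsorted(breakpoints, positions, side="right")) % 2
    return origin.astype(np.int8), breakpoints


def _pair_code(a: str, b: str) -> str:
    pair = "".join(sorted((a, b)))
    if set(pair) <= {"A", "B"}:
        return {"AA": "A", "BB": "B"}.get(pair, "H")
    return pair


def simulate_cross(config: CrossConfig) -> tuple[ParentalGenome, SimulatedPopulation]:
    """Simulate a full-sib family (plus contaminants) with complete ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    genome = _draw_parental_genome(config, rng)

    n_total = config.n_total_offspring
    n_cont = config.n_contaminants
    ids = [f"off{i:03d}" for i in range(n_total)]
    cont_idx = set(rng.choice(n_total, size=n_cont, replace=False).tolist())
    contaminant = pd.Series([i in cont_idx for i in range(n_total)], index=ids)

    marker_ids = genome.marker_ids
    by_chrom = {c: genome.markers_on(c) for c in range(1, config.n_chromosomes + 1)}
    mat_origin = np.full((len(marker_ids), n_total), -1, dtype=np.int8)
    pat_origin = np.full((len(marker_ids), n_total), -1, dtype=np.int8)
    calls = np.empty((len(marker_ids), n_total), dtype=object)
    row_of = {mid: i for i, mid in enumerate(marker_ids)}

    dsi_allele = []
    crossovers: dict[str, dict] = {}
    pmarkers = sorted(genome.parentage_mother)
    pgeno = np.empty((n_total, len(pmarkers)), dtype=object)

    for i, oid in enumerate(ids):
        is_cont = i in cont_idx
        co_log = {"maternal": {}, "paternal": {}}
        for c in range(1, config.n_chromosomes + 1):
            mks = by_chrom[c]
            pos_f = np.array([m.pos_female for m in mks])
            pos_m = np.array([m.pos_male for m in mks])
            Lf = config.female_chrom_lengths[c - 1]
            Lm = config.male_chrom_lengths[c - 1]
            dsi_here = c == genome.dsi_chromosome
            eval_f = np.append(pos_f, genome.dsi_position) if dsi_here else pos_f
            origin_f, bps_f = _gamete_origin(rng, Lf, eval_f)
            co_log["maternal"][c] = [float(x) for x in bps_f]
            if dsi_here:
                dsi_origin = int(origin_f[-1])
                origin_f = origin_f[:-1]
                dsi_allele.append(genome.mother_dsi_haps[dsi_origin])
            if is_cont:
                # unrelated pollen donor: unlinked random alleles
                pat_alleles = []
                for m in mks:
                    donor_pool = sorted(set(m.father_haps))
                    pat_alleles.append(str(rng.choice(donor_pool)))
                origin_m = None
            else:
                origin_m, bps_m = _gamete_origin(rng, Lm, pos_m)
                co_log["paternal"][c] = [float(x) for x in bps_m]
                pat_alleles = [m.father_haps[origin_m[k]] for k, m in enumerate(mks)]
            for k, m in enumerate(mks):
                r = row_of[m.marker_id]
                mat_a = m.mother_haps[origin_f[k]]
                mat_origin[r, i] = origin_f[k]
                if origin_m is not None:
                    pat_origin[r, i] = origin_m[k]
                calls[r, i] = _pair_code(mat_a, pat_alleles[k])
        crossovers[oid] = co_log
        for j, pm in enumerate(pmarkers):
            mat_p = str(rng.choice(MOTHER_P_ALLELES))
            if is_cont:
                pat_p = str(rng.choice(DONOR_ALLELE_POOL))
            else:
                pat_p = str(rng.choice(FATHER_P_ALLELES))
            pgeno[i, j] = f"{mat_p}/{pat_p}"

    mother_calls = pd.Series({m.marker_id: _pair_code(*m.mother_haps)
                              for m in genome.markers})
    father_calls = pd.Series({m.marker_id: _pair_code(*m.father_haps)
                              for m in genome.markers})
    seg = pd.Series({m.marker_id: m.seg_class for m in genome.markers})
    gm = GenotypeMatrix(
        calls=pd.DataFrame(calls, index=marker_ids, columns=ids),
        mother=mother_calls.loc[marker_ids],
        father=father_calls.loc[marker_ids],
        seg_class=seg.loc[marker_ids])
    pop = SimulatedPopulation(
        individuals=ids,
        contaminant=contaminant,
        genotypes=gm,
        phenotypes=pd.Series(["G1" if a == "S" else "G2" for a in dsi_allele],
                             index=ids),
        dsi_maternal_allele=pd.Series(dsi_allele, index=ids),
        maternal_origin=pd.DataFrame(mat_origin, index=marker_ids, columns=ids),
        paternal_origin=pd.DataFrame(pat_origin, index=marker_ids, columns=ids),
        crossovers=crossovers,
        parentage_genotypes=pd.DataFrame(pgeno, index=ids, columns=pmarkers))
    return genome, pop


def simulate_reads(genome: ParentalGenome, population: SimulatedPopulation,
                   config: CrossConfig,
                   ) -> tuple[ReadCountMatrix, pd.DataFrame]:
    """Simulate allele read counts for parents and offspring.

    Depth per cell is negative binomial (``mean_depth``, ``depth_dispersion``);
    reads sample the cell's two alleles evenly and are miscalled to another
    allele of the marker's alphabet with probability ``seq_error``.  With
    probability ``genotyping_error_rate`` an offspring cell's generating
    genotype is swapped for a different one and the swap is logged.
    Deterministic for a fixed ``config.seed`` (uses a stream independent of
    :func:`simulate_cross`).
    """
    rng = np.random.default_rng([config.seed, 1])
    individuals = ["mother", "father"] + population.individuals
    gm = population.genotypes
    alleles: dict[str, list[str]] = {}
    counts: dict[str, np.ndarray] = {}
    err_log = []
    k = config.depth_dispersion
    p_nb = k / (k + config.mean_depth) if config.mean_depth > 0 else 1.0

    def genotype_space(alphabet: list[str]) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(alphabet):
            for b in alphabet[i:]:
                out.append((a, b))
        return out

    def decode(call: str, alphabet: list[str]) -> tuple[str, str]:
        if call == "A":
            return ("A", "A")
        if call == "B":
            return ("B", "B")
        if call == "H":
            return ("A", "B")
        return (call[0], call[1])

    for m in genome.markers:
        al = m.alphabet
        space = genotype_space(al)
        arr = np.zeros((len(individuals), len(al)), dtype=np.int64)
        aidx = {a: j for j, a in enumerate(al)}
        true_pairs = [decode(gm.mother[m.marker_id], al),
                      decode(gm.father[m.marker_id], al)]
        for oid in population.individuals:
            true_pairs.append(decode(gm.calls.at[m.marker_id, oid], al))
        depths = rng.negative_binomial(k, p_nb, size=len(individuals)) \
            if config.mean_depth > 0 else np.zeros(len(individuals), dtype=np.int64)
        swap = rng.random(len(individuals)) < config.genotyping_error_rate
        for i, ind in enumerate(individuals):
            pair = true_pairs[i]
            if swap[i] and i >= 2:  # parents assumed deeply re-genotyped
                others = [g for g in space if g != tuple(sorted(pair))]
                new = others[int(rng.integers(len(others)))]
                err_log.append((m.marker_id, ind, "".join(sorted(pair)),
                                "".join(new)))
                pair = new
            d = int(depths[i])
            if d == 0:
                continue
            n_first = int(rng.binomial(d, 0.5)) if pair[0] != pair[1] else d
            for allele, n_reads in ((pair[0], n_first), (pair[1], d - n_first)):
                if n_reads == 0:
                    continue
                n_err = int(rng.binomial(n_reads, config.seq_error))
                arr[i, aidx[allele]] += n_reads - n_err
                if n_err:
                    targets = [a for a in al if a != allele]
                    if targets:
                        split = rng.multinomial(n_err,
                                                [1 / len(targets)] * len(targets))
                        for t, n_t in zip(targets, split):
                            arr[i, aidx[t]] += int(n_t)
                    else:
                        arr[i, aidx[allele]] += n_err
        alleles[m.marker_id] = al
        counts[m.marker_id] = arr
    log = pd.DataFrame(err_log, columns=["marker", "individual",
                                         "true_genotype", "generated_genotype"])
    return ReadCountMatrix(individuals, alleles, counts), log
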