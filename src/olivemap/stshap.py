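"""Sequence-tagged-site haplotype catalog and incompatibility-group classifier.

A 476-bp amplicon carries 14 variant positions (12 substitutions, 2 small
indels) distinguishing five haplotypes: two dominant ones conferring the G1
incompatibility group and three recessive ones.  Two diagnostic positions
(63 and 283, counted 1-based from the first base of the forward primer) are
sufficient to call G1 vs G2.  Classification enumerates all unordered
haplotype pairs consistent with an observed diploid genotype and applies the
dominance rule; genotypes fitting no catalog pair are reported inconsistent
with a novel-haplotype flag, never force-fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement

import pandas as pd
from Bio import Align
from Bio.Data.IUPACData import ambiguous_dna_values

AMPLICON_LENGTH = 476
FORWARD_PRIMER = "TTTTGGGTGCGAATTGTCCA"
REVERSE_PRIMER = "AGGCCACTGTATTTCTAACTCG"

DIAGNOSTIC_POSITIONS = (63, 283)
GAP = "-"

GROUP_G1 = "G1"
GROUP_G2 = "G2"
GROUP_AMBIGUOUS = "ambiguous"
GROUP_INCONSISTENT = "inconsistent"

# Genotype: position -> sorted allele pair, or None / absent when missing.
Genotype = dict[int, tuple[str, str]]


@dataclass(frozen=True)
class HaplotypeCatalog:
    """The amplicon haplotype table: alleles per haplotype per position."""

    positions: tuple[int, ...]
    alleles: pd.DataFrame  # haplotypes x positions
    dominant: frozenset[str]
    accessions: dict[str, str] = field(default_factory=dict)
    indel_lengths: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.alleles.columns) != list(self.positions):
            raise ValueError("allele table columns must equal positions")
        if self.alleles.isna().any().any():
            raise ValueError("every haplotype must be specified at all positions")

    @property
    def haplotypes(self) -> list[str]:
        return list(self.alleles.index)

    @property
    def indel_positions(self) -> list[int]:
        """Positions where at least one haplotype carries a deletion."""
        return [p for p in self.positions
                if (self.alleles[p] == GAP).any()]

    @property
    def substitution_positions(self) -> list[int]:
        return [p for p in self.positions if p not in self.indel_positions]

    def allele(self, haplotype: str, position: int) -> str:
        return str(self.alleles.at[haplotype, position])

    def polymorphic_positions(self, haplotypes: list[str] | None = None,
                              include_indels: bool = True) -> list[int]:
        """Positions segregating within the given haplotype subset."""
        sub = self.alleles.loc[haplotypes] if haplotypes else self.alleles
        poly = [p for p in self.positions if sub[p].nunique() > 1]
        if not include_indels:
            poly = [p for p in poly if p not in self.indel_positions]
        return poly

    def pair_genotype(self, h1: str, h2: str) -> Genotype:
        """The diploid genotype implied by an unordered haplotype pair."""
        return {p: tuple(sorted((self.allele(h1, p), self.allele(h2, p))))
                for p in self.positions}


def load_catalog() -> HaplotypeCatalog:
    """Load the packaged five-haplotype catalog."""
    path = resources.files("olivemap.data") / "haplotype_catalog.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    df = df.set_index("haplotype")
    accessions = df["accession"].to_dict()
    dominant = frozenset(df.index[df["dominant"] == "yes"])
    alleles = df.drop(columns=["accession", "dominant"])
    alleles.columns = [int(c) for c in alleles.columns]
    positions = tuple(alleles.columns)
    indel_lengths = {}
    for p in positions:
        non_gap = [a for a in alleles[p] if a != GAP]
        if (alleles[p] == GAP).any():
            indel_lengths[p] = max(len(a) for a in non_gap)
    return HaplotypeCatalog(positions=positions, alleles=alleles,
                            dominant=dominant, accessions=accessions,
                            indel_lengths=indel_lengths)


# ---------------------------------------------------------------------------
# Reference frame and sequence construction
# ---------------------------------------------------------------------------

def _reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def _slot_length(catalog: HaplotypeCatalog, position: int) -> int:
    return catalog.indel_lengths.get(position, 1)


def build_reference(catalog: HaplotypeCatalog,
                    backbone_haplotype: str | None = None) -> str:
    """The amplicon reference frame: forward primer at position 1, reverse
    primer (reverse-complemented) at the 3' end, catalog alleles of the
    backbone haplotype at the variant positions and a fixed arbitrary filler
    elsewhere."""
    if backbone_haplotype is None:
        backbone_haplotype = sorted(catalog.dominant)[0]
    filler = "ACGT"
    seq = [filler[i % 4] for i in range(AMPLICON_LENGTH)]
    seq[:len(FORWARD_PRIMER)] = list(FORWARD_PRIMER)
    rc = _reverse_complement(REVERSE_PRIMER)
    seq[-len(rc):] = list(rc)
    for p in catalog.positions:
        allele = catalog.allele(backbone_haplotype, p)
        if allele == GAP:
            raise ValueError("backbone haplotype may not carry deletions")
        for k, base in enumerate(allele):
            seq[p - 1 + k] = base
    # keep indel flanks free of bases identical to the indel content so a
    # deletion cannot drift outside its variant block during alignment;
    # the block extends over catalog positions adjacent to the indel slot
    for p, ln in catalog.indel_lengths.items():
        start, end = p, p + ln - 1  # 1-based block bounds
        while start - 1 in catalog.positions:
            start -= 1
        while end + 1 in catalog.positions:
            end += 1
        content = set("".join(seq[start - 1:end]))
        for flank in (start - 2, end):  # 0-based indices just outside the block
            if 0 <= flank < AMPLICON_LENGTH and flank + 1 not in catalog.positions:
                if seq[flank] in content:
                    seq[flank] = next(b for b in "ACGT" if b not in content)
    return "".join(seq)


def build_haplotype_sequence(catalog: HaplotypeCatalog, haplotype: str) -> str:
    """Full amplicon sequence of one catalog haplotype over the fixed backbone."""
    ref = build_reference(catalog)
    out = []
    cursor = 0
    for p in sorted(catalog.positions):
        ln = _slot_length(catalog, p)
        out.append(ref[cursor:p - 1])
        allele = catalog.allele(haplotype, p)
        if allele != GAP:
            out.append(allele)
        cursor = p - 1 + ln
    out.append(ref[cursor:])
    return "".join(out)


def _expand_ambiguity(base: str) -> tuple[str, ...]:
    values = ambiguous_dna_values.get(base.upper())
    if values is None:
        return ()
    return tuple(sorted(values))


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -1
    al.open_gap_score = -4
    al.extend_gap_score = -1
    try:  # biopython >= 1.88 naming
        al.end_insertion_score = 0
        al.end_deletion_score = 0
    except AttributeError:  # pragma: no cover - older biopython
        al.target_end_gap_score = 0
        al.query_end_gap_score = 0
    return al


def _read_alleles(sequence: str, catalog: HaplotypeCatalog,
                  reference: str) -> dict[int, str]:
    """Per-position allele string of one (haploid or consensus) sequence.

    The sequence is anchored at the forward primer, globally aligned to the
    reference frame and read off at every catalog position; bases aligned to
    gaps inside an indel slot yield the deletion allele.
    """
    seq = sequence.upper().replace("U", "T")
    start = seq.find(FORWARD_PRIMER)
    if start < 0:
        rc = _reverse_complement(seq) if set(seq) <= set("ACGT") else None
        if rc is not None and rc.find(FORWARD_PRIMER) >= 0:
            seq = rc
            start = seq.find(FORWARD_PRIMER)
        else:
            raise ValueError("frame not found: forward primer absent")
    seq = seq[start:]
    max_indel = sum(catalog.indel_lengths.values())
    if abs(len(seq) - AMPLICON_LENGTH) > max_indel + 10:
        warnings.warn(f"sequence length {len(seq)} inconsistent with "
                      f"{AMPLICON_LENGTH} bp amplicon", stacklevel=2)
    alignment = _aligner().align(reference, seq)[0]
    # map reference coordinates to query bases
    ref_to_query: dict[int, str] = {}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            ref_to_query[t0 + k] = seq[q0 + k]
    out: dict[int, str] = {}
    for p in catalog.positions:
        ln = _slot_length(catalog, p)
        bases = [ref_to_query.get(p - 1 + k) for k in range(ln)]
        if all(b is None for b in bases):
            out[p] = GAP
        elif any(b is None for b in bases):
            out[p] = GAP  # partial deletion of the slot: treat as deletion
        else:
            out[p] = "".join(bases)
    # gap placement is ambiguous when an indel slot borders a substitution
    # position: re-assign the gap to the indel slot
    for q, ln in catalog.indel_lengths.items():
        for p in catalog.positions:
            if p in catalog.indel_lengths:
                continue
            adjacent = (p + 1 == q) or (q - 1 + ln == p - 1)
            if adjacent and out.get(p) == GAP and out.get(q, GAP) != GAP:
                out[p] = out[q][0] if len(out[q]) == 1 else out[q]
                out[q] = GAP
    return out


@dataclass
class AmpliconGenotype:
    """Diploid allele pairs at the catalog positions (missing = absent key)."""

    alleles: Genotype
    phased: bool = False

    def at(self, position: int) -> tuple[str, str] | None:
        return self.alleles.get(position)


def genotype_from_diagnostics(geno63: str, geno283: str) -> AmpliconGenotype:
    """Build a genotype from the two diagnostic allele pairs, e.g. 'TG', 'CT'."""
    alleles: Genotype = {}
    for pos, g in zip(DIAGNOSTIC_POSITIONS, (geno63, geno283)):
        g = g.strip()
        if len(g) != 2:
            raise ValueError(f"diagnostic genotype must be two alleles, got {g!r}")
        alleles[pos] = tuple(sorted(g.upper()))
    return AmpliconGenotype(alleles=alleles)


def extract_amplicon_genotype(sequences: list[str],
                              catalog: HaplotypeCatalog | None = None,
                              ) -> AmpliconGenotype:
    """Genotype at the 14 catalog positions from amplicon sequence(s).

    Accepts one unphased consensus (IUPAC ambiguity codes expand to diploid
    pairs) or two cloned haplotype reads (each contributes one allele).
    """
    catalog = catalog or load_catalog()
    reference = build_reference(catalog)
    if not 1 <= len(sequences) <= 2:
        raise ValueError("provide one consensus or two cloned sequences")
    if len(sequences) == 2:
        reads = [_read_alleles(s, catalog, reference) for s in sequences]
        alleles: Genotype = {}
        for p in catalog.positions:
            a, b = reads[0].get(p), reads[1].get(p)
            if a is None or b is None:
                continue
            alleles[p] = tuple(sorted((a, b)))
        return AmpliconGenotype(alleles=alleles, phased=True)
    read = _read_alleles(sequences[0], catalog, reference)
    alleles = {}
    for p, a in read.items():
        if len(a) == 1 and a != GAP and a not in "ACGT":
            expanded = _expand_ambiguity(a)
            if len(expanded) == 2:
                alleles[p] = expanded
            elif len(expanded) == 1:
                alleles[p] = (expanded[0], expanded[0])
            # higher ambiguity: leave missing
        else:
            alleles[p] = (a, a)
    return AmpliconGenotype(alleles=alleles, phased=False)


# ---------------------------------------------------------------------------
# Phase resolution and classification
# ---------------------------------------------------------------------------

def resolve_haplotypes(genotype: AmpliconGenotype,
                       catalog: HaplotypeCatalog | None = None,
                       ) -> list[tuple[str, str]]:
    """All unordered catalog pairs (with repetition) whose position-wise
    allele multisets match the genotype at every non-missing position."""
    catalog = catalog or load_catalog()
    pairs = []
    for h1, h2 in combinations_with_replacement(catalog.haplotypes, 2):
        ok = True
        for p, observed in genotype.alleles.items():
            if observed is None or p not in catalog.positions:
                continue
            expected = tuple(sorted((catalog.allele(h1, p),
                                     catalog.allele(h2, p))))
            if tuple(sorted(observed)) != expected:
                ok = False
                break
        if ok:
            pairs.append(tuple(sorted((h1, h2))))
    return sorted(set(pairs))


@dataclass(frozen=True)
class DSIClassification:
    group: str
    consistent_pairs: tuple[tuple[str, str], ...]
    novel_haplotype: bool = False
    homozygous_or_null: bool = False


def classify_dsi(genotype: AmpliconGenotype,
                 catalog: HaplotypeCatalog | None = None) -> DSIClassification:
    """Incompatibility group from the haplotype pairs consistent with a
    genotype.

    G1 iff every consistent pair contains a dominant haplotype, G2 iff none
    does, ambiguous when pairs disagree, inconsistent (novel flag) when no
    catalog pair fits.  Pairs made only of dominant haplotypes additionally
    carry the homozygous-or-null annotation.
    """
    catalog = catalog or load_catalog()
    pairs = resolve_haplotypes(genotype, catalog)
    if not pairs:
        return DSIClassification(GROUP_INCONSISTENT, (), novel_haplotype=True)
    has_dom = [bool(set(p) & catalog.dominant) for p in pairs]
    if all(has_dom):
        hom_null = all(set(p) <= catalog.dominant for p in pairs)
        return DSIClassification(GROUP_G1, tuple(pairs),
                                 homozygous_or_null=hom_null)
    if not any(has_dom):
        return DSIClassification(GROUP_G2, tuple(pairs))
    return DSIClassification(GROUP_AMBIGUOUS, tuple(pairs))


@dataclass
class CrossCheckResult:
    per_offspring: pd.DataFrame  # combination, group, valid
    combination_counts: dict[tuple[str, str], int]
    group_counts: dict[str, int]
    flagged: list[str]


def verify_cross_haplotypes(parent1_pair: tuple[str, str],
                            parent2_pair: tuple[str, str],
                            offspring: dict[str, AmpliconGenotype],
                            catalog: HaplotypeCatalog | None = None,
                            ) -> CrossCheckResult:
    """Check transmission of four parental haplotypes in a cross.

    Every offspring must be consistent with one haplotype from each parent;
    offspring fitting no parental combination are flagged.
    """
    catalog = catalog or load_catalog()
    expected = sorted({tuple(sorted((a, b)))
                       for a in parent1_pair for b in parent2_pair})
    combo_counts = {c: 0 for c in expected}
    group_counts = {GROUP_G1: 0, GROUP_G2: 0}
    rows, flagged = [], []
    for oid in sorted(offspring):
        pairs = resolve_haplotypes(offspring[oid], catalog)
        fitting = [p for p in pairs if p in expected]
        cls = classify_dsi(offspring[oid], catalog)
        if not fitting:
            flagged.append(oid)
            rows.append((oid, None, cls.group, False))
            continue
        combo = fitting[0] if len(fitting) == 1 else None
        if combo is not None:
            combo_counts[combo] += 1
        if cls.group in group_counts:
            group_counts[cls.group] += 1
        rows.append((oid, combo, cls.group, True))
    per = pd.DataFrame(rows, columns=["individual", "combination", "group",
                                      "valid"]).set_index("individual")
    return CrossCheckResult(per_offspring=per, combination_counts=combo_counts,
                            group_counts=group_counts, flagged=flagged)
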