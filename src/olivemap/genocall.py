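"""Genotype calling from allele read counts and offspring validation.

Calls are threshold-based: a cell is callable once its total read depth
reaches ``min_coverage``; heterozygotes are recognised whenever the reference
read fraction falls inside the symmetric ``[het_ratio_low, het_ratio_high]``
window (boundaries inclusive).  Loci are retained only when called in more
than ``min_called_progeny`` offspring.  Parentage validation re-implements
likelihood-free Mendelian exclusion counting on multi-allelic markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Biallelic call codes (also used in the genotype-matrix TSV dialect).
HOM_REF = "A"
HET = "H"
HOM_ALT = "B"
MISSING = "-"

# Segregation classes.
MATERNAL_TC = "maternal_testcross"
PATERNAL_TC = "paternal_testcross"
FULLY_INFORMATIVE = "fully_informative"
UNINFORMATIVE = "uninformative"

SEG_CLASSES = (MATERNAL_TC, PATERNAL_TC, FULLY_INFORMATIVE, UNINFORMATIVE)


@dataclass(frozen=True)
class CallingThresholds:
    """Read-count filters applied when converting counts to genotype calls."""

    min_coverage: int = 8
    het_ratio_low: float = 0.15
    het_ratio_high: float = 0.85
    min_called_progeny: int = 150

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0.0 < self.het_ratio_low < self.het_ratio_high < 1.0):
            raise ValueError("require 0 < het_ratio_low < het_ratio_high < 1")
        if self.min_called_progeny < 0:
            raise ValueError("min_called_progeny must be >= 0")


@dataclass
class GenotypeMatrix:
    """Markers x individuals call matrix with parental calls and segregation classes.

    ``calls`` is indexed by marker id with one column per offspring; values are
    the biallelic codes ``A``/``H``/``B``/``-`` or, for markers with four
    distinguishable alleles (ABxCD), sorted two-letter allele pairs such as
    ``AC``.  ``mother``/``father`` hold the parental calls and ``seg_class``
    the per-marker segregation class.
    """

    calls: pd.DataFrame
    mother: pd.Series
    father: pd.Series
    seg_class: pd.Series

    def __post_init__(self) -> None:
        idx = self.calls.index
        for name, series in (("mother", self.mother), ("father", self.father),
                             ("seg_class", self.seg_class)):
            if not series.index.equals(idx):
                raise ValueError(f"{name} index does not match calls index")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)

    def subset_individuals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[:, list(keep)].copy(),
                              self.mother.copy(), self.father.copy(),
                              self.seg_class.copy())

    def subset_markers(self, keep: Sequence[str]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(self.calls.loc[keep].copy(),
                              self.mother.loc[keep].copy(),
                              self.father.loc[keep].copy(),
                              self.seg_class.loc[keep].copy())


def call_genotype(ref_count: int, alt_count: int,
                  thresholds: CallingThresholds | None = None) -> str:
    """Call a biallelic genotype from reference/alternate read counts.

    Returns ``-`` below ``min_coverage``; otherwise the reference read
    fraction decides: inside the het window (inclusive) -> ``H``, above ->
    ``A`` (hom ref), below -> ``B`` (hom alt).
    """
    thr = thresholds or CallingThresholds()
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total < thr.min_coverage:
        return MISSING
    f = ref_count / total
    if thr.het_ratio_low <= f <= thr.het_ratio_high:
        return HET
    return HOM_REF if f > thr.het_ratio_high else HOM_ALT


def call_alleles(counts: Mapping[str, int],
                 thresholds: CallingThresholds | None = None) -> str:
    """Multi-allelic generalisation of :func:`call_genotype`.

    An allele is deemed present when its read fraction is at least
    ``het_ratio_low``; with exactly one or two present alleles the call is the
    sorted allele pair (``XX`` for homozygotes), anything else is missing.
    For two alleles this reduces exactly to the biallelic rule.
    """
    thr = thresholds or CallingThresholds()
    total = sum(counts.values())
    if total < thr.min_coverage:
        return MISSING
    present = [a for a, c in sorted(counts.items()) if c / total >= thr.het_ratio_low]
    if len(present) == 1:
        return present[0] * 2
    if len(present) == 2:
        return "".join(sorted(present))
    return MISSING


def retain_locus(calls: Iterable[str],
                 thresholds: CallingThresholds | None = None) -> bool:
    """True iff the number of non-missing progeny calls strictly exceeds
    ``min_called_progeny``."""
    thr = thresholds or CallingThresholds()
    n_called = sum(1 for c in calls if c != MISSING)
    return n_called > thr.min_called_progeny


def _is_het(call: str) -> bool:
    if call == HET:
        return True
    return len(call) == 2 and call[0] != call[1]


def _is_hom(call: str) -> bool:
    if call in (HOM_REF, HOM_ALT):
        return True
    return len(call) == 2 and call[0] == call[1]


def classify_segregation(mother_call: str, father_call: str) -> str:
    """Segregation class from the two parental calls.

    het x hom -> maternal testcross, hom x het -> paternal testcross,
    het x het -> fully informative, hom x hom -> uninformative.  A missing
    parental call is an error (the marker must be excluded upstream).
    """
    if mother_call == MISSING or father_call == MISSING:
        raise ValueError("parental call missing; marker cannot be classified")
    mh, fh = _is_het(mother_call), _is_het(father_call)
    if mh and fh:
        return FULLY_INFORMATIVE
    if mh:
        return MATERNAL_TC
    if fh:
        return PATERNAL_TC
    return UNINFORMATIVE


def pair_to_biallelic(call: str) -> str:
    """Normalise an ``AA``/``AB``/``BB`` pair over the {A,B} alphabet to the
    single-letter biallelic codes; other strings pass through unchanged."""
    if len(call) == 2 and set(call) <= {"A", "B"}:
        if call == "AA":
            return HOM_REF
        if call == "BB":
            return HOM_ALT
        return HET
    return call


def build_genotype_matrix(call_table: pd.DataFrame, mother_id: str = "mother",
                          father_id: str = "father",
                          thresholds: CallingThresholds | None = None,
                          ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Assemble a :class:`GenotypeMatrix` from a table of per-individual calls.

    ``call_table`` has one row per marker and one column per individual
    (parents included).  Markers with a missing parental call or called in too
    few progeny are dropped; the second return value logs every exclusion with
    its reason.
    """
    thr = thresholds or CallingThresholds()
    offspring_cols = [c for c in call_table.columns if c not in (mother_id, father_id)]
    kept_rows, exclusions = [], []
    for mid, row in call_table.iterrows():
        mother = pair_to_biallelic(row[mother_id])
        father = pair_to_biallelic(row[father_id])
        if mother == MISSING or father == MISSING:
            exclusions.append((mid, "missing_parental_call"))
            continue
        progeny = row[offspring_cols]
        if not retain_locus(progeny, thr):
            exclusions.append((mid, "insufficient_progeny_calls"))
            continue
        seg = classify_segregation(mother, father)
        kept_rows.append((mid, mother, father, seg, progeny))
    if kept_rows:
        ids = [r[0] for r in kept_rows]
        calls = pd.DataFrame([r[4] for r in kept_rows], index=ids)
        gm = GenotypeMatrix(
            calls=calls,
            mother=pd.Series([r[1] for r in kept_rows], index=ids),
            father=pd.Series([r[2] for r in kept_rows], index=ids),
            seg_class=pd.Series([r[3] for r in kept_rows], index=ids),
        )
    else:
        empty = pd.Series(dtype=object)
        gm = GenotypeMatrix(pd.DataFrame(columns=offspring_cols), empty, empty, empty)
    log = pd.DataFrame(exclusions, columns=["marker", "reason"])
    for mid, reason in exclusions:
        logger.info("marker %s excluded: %s", mid, reason)
    return gm, log


def call_read_matrix(read_counts, thresholds: CallingThresholds | None = None,
                     ) -> pd.DataFrame:
    """Call every cell of a :class:`~olivemap.simcross.ReadCountMatrix`.

    Returns a marker x individual table of biallelic codes / allele pairs
    ready for :func:`build_genotype_matrix`.
    """
    thr = thresholds or CallingThresholds()
    rows = {}
    for mid in read_counts.marker_ids:
        alleles = read_counts.alleles[mid]
        arr = read_counts.counts[mid]
        calls = []
        for i in range(arr.shape[0]):
            counts = dict(zip(alleles, (int(x) for x in arr[i])))
            if set(alleles) <= {"A", "B"}:
                call = call_genotype(counts.get("A", 0), counts.get("B", 0), thr)
            else:
                call = call_alleles(counts, thr)
            calls.append(call)
        rows[mid] = calls
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=read_counts.individuals)


# ---------------------------------------------------------------------------
# Parentage validation
# ---------------------------------------------------------------------------

VALIDATED = "validated"
EXCLUDED = "excluded"
UNRESOLVABLE = "unresolvable"


def _split_alleles(genotype: str) -> tuple[str, str] | None:
    if not genotype or genotype == MISSING:
        return None
    if "/" in genotype:
        a, b = genotype.split("/", 1)
    elif len(genotype) == 2:
        a, b = genotype[0], genotype[1]
    else:
        return None
    if a in ("", MISSING) or b in ("", MISSING):
        return None
    return a, b


def _mendelian_consistent(off: tuple[str, str], mother: tuple[str, str],
                          father: tuple[str, str]) -> bool:
    a, b = off
    return ((a in mother and b in father) or (b in mother and a in father))


def check_parentage(offspring_genotypes: pd.DataFrame,
                    mother_genotypes: Mapping[str, str],
                    father_genotypes: Mapping[str, str],
                    max_mismatches: int = 1) -> pd.DataFrame:
    """Mendelian-exclusion parentage check on multi-allelic markers.

    ``offspring_genotypes`` holds one row per offspring and one column per
    parentage marker, with genotypes encoded ``"a/b"``.  An offspring is
    excluded when more than ``max_mismatches`` markers carry an allele that
    cannot have come from the declared father once one maternal allele is
    assigned.  Offspring missing more than half their markers are flagged
    unresolvable instead of being silently validated.

    Returns a frame with columns ``n_checked``, ``n_mismatch``, ``status``.
    """
    markers = [m for m in offspring_genotypes.columns]
    mother = {m: _split_alleles(str(mother_genotypes[m])) for m in markers}
    father = {m: _split_alleles(str(father_genotypes[m])) for m in markers}
    records = []
    for oid, row in offspring_genotypes.iterrows():
        n_checked = 0
        n_mismatch = 0
        for m in markers:
            if mother[m] is None or father[m] is None:
                continue
            off = _split_alleles(str(row[m]))
            if off is None:
                continue
            n_checked += 1
            if not _mendelian_consistent(off, mother[m], father[m]):
                n_mismatch += 1
        if len(markers) and n_checked < 0.5 * len(markers):
            status = UNRESOLVABLE
        elif n_mismatch > max_mismatches:
            status = EXCLUDED
        else:
            status = VALIDATED
        records.append((oid, n_checked, n_mismatch, status))
    return pd.DataFrame(records, columns=["individual", "n_checked",
                                          "n_mismatch", "status"]
                        ).set_index("individual")
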