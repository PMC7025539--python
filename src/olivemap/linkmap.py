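"""Per-parent linkage-map construction for pseudo-testcross populations.

The pipeline per parent: extract binary transmission patterns for markers
informative in that parent, estimate pairwise recombination fractions and LOD
scores, group by single-linkage transitive closure (LOD > lod_min and
r <= rf_max), collapse zero-recombinant markers into genetic bins, order bins
with a minimum-spanning-tree seeded linearization refined by 2-opt, scrub
isolated genotyping errors with a neighbour-consensus smoother, and convert
adjacent recombination fractions to cM with the Kosambi function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genocall import (FULLY_INFORMATIVE, GenotypeMatrix, HET, HOM_ALT,
                       HOM_REF, MATERNAL_TC, MISSING, PATERNAL_TC)

logger = logging.getLogger(__name__)

MIN_INFORMATIVE_PAIRS = 10


@dataclass(frozen=True)
class MappingParams:
    """Thresholds controlling grouping, smoothing and distortion testing."""

    lod_min: float = 10.0
    rf_max: float = 0.20
    distortion_alpha: float = 0.05
    smooth_neighbors: int = 5
    smooth_threshold: float = 0.50
    smooth_tighten: float = 0.05  # threshold lowered by this much per iteration
    smooth_max_iter: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.rf_max <= 0.5):
            raise ValueError("rf_max must lie in (0, 0.5]")
        if not (0.0 < self.distortion_alpha < 1.0):
            raise ValueError("distortion_alpha must lie in (0, 1)")
        if self.smooth_neighbors < 1 or self.smooth_max_iter < 0:
            raise ValueError("invalid smoothing parameters")


@dataclass(frozen=True)
class TwoPointEstimate:
    r: float
    lod: float
    phase: str  # 'coupling' | 'repulsion'
    n_informative: int

    @property
    def reliable(self) -> bool:
        return self.n_informative >= MIN_INFORMATIVE_PAIRS


@dataclass
class GeneticBin:
    """A map position: all markers sharing one segregation pattern."""

    representative: str
    markers: list[str]
    position_cM: float = 0.0
    pattern: np.ndarray | None = None  # int8 over individuals, -1 = missing


@dataclass
class LinkageGroup:
    lg_id: int
    bins: list[GeneticBin]

    @property
    def n_markers(self) -> int:
        return sum(len(b.markers) for b in self.bins)

    @property
    def length_cM(self) -> float:
        return self.bins[-1].position_cM if self.bins else 0.0


@dataclass
class GeneticMap:
    parent: str
    groups: list[LinkageGroup]
    singletons: list[str] = field(default_factory=list)
    individuals: list[str] = field(default_factory=list)

    @property
    def total_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_bins(self) -> int:
        return sum(len(g.bins) for g in self.groups)

    @property
    def total_length(self) -> float:
        return sum(g.length_cM for g in self.groups)

    def marker_positions(self) -> dict[str, tuple[int, float]]:
        """marker id -> (lg_id, position cM)."""
        out: dict[str, tuple[int, float]] = {}
        for g in self.groups:
            for b in g.bins:
                for mid in b.markers:
                    out[mid] = (g.lg_id, b.position_cM)
        return out


# ---------------------------------------------------------------------------
# Pattern extraction
# ---------------------------------------------------------------------------

def parental_patterns(gm: GenotypeMatrix, parent: str) -> pd.DataFrame:
    """Binary transmission patterns for markers informative in ``parent``.

    Rows are pattern ids (the marker id, suffixed ``:m``/``:p`` for the
    maternal/paternal side of a fully informative ABxCD marker), columns the
    offspring; values are int8 0/1 for the two parental alleles, -1 missing.
    Pure testcross markers keep their marker id unchanged.
    """
    if parent not in ("mother", "father"):
        raise ValueError("parent must be 'mother' or 'father'")
    want_tc = MATERNAL_TC if parent == "mother" else PATERNAL_TC
    rows: dict[str, np.ndarray] = {}
    for mid in gm.marker_ids:
        seg = gm.seg_class[mid]
        calls = gm.calls.loc[mid]
        if seg == want_tc:
            hom = gm.father[mid] if parent == "mother" else gm.mother[mid]
            pat = np.full(len(calls), -1, dtype=np.int8)
            if hom == HOM_REF:  # informative parent transmitted ref->0, alt->1
                pat[(calls == HOM_REF).to_numpy()] = 0
                pat[(calls == HET).to_numpy()] = 1
            else:
                pat[(calls == HET).to_numpy()] = 0
                pat[(calls == HOM_ALT).to_numpy()] = 1
            rows[mid] = pat
        elif seg == FULLY_INFORMATIVE:
            par_call = gm.mother[mid] if parent == "mother" else gm.father[mid]
            # the het parent's two alleles ('H' is the biallelic A/B het)
            a0, a1 = ("A", "B") if par_call == HET else (par_call[0], par_call[1])
            expand = {HOM_REF: "AA", HET: "AB", HOM_ALT: "BB"}
            pat = np.full(len(calls), -1, dtype=np.int8)
            arr = calls.to_numpy()
            for i, c in enumerate(arr):
                if not isinstance(c, str):
                    continue
                c = expand.get(c, c)
                if len(c) != 2:
                    continue
                # transmitted allele is resolvable only when exactly one of
                # the parent's alleles is present (het x het 'H' stays -1)
                if a0 in c and a1 not in c:
                    pat[i] = 0
                elif a1 in c and a0 not in c:
                    pat[i] = 1
            suffix = ":m" if parent == "mother" else ":p"
            rows[mid + suffix] = pat
    df = pd.DataFrame(rows, index=gm.individuals).T
    return df.astype(np.int8)


def base_marker_id(pattern_id: str) -> str:
    """Strip the ABxCD decomposition suffix from a pattern id."""
    return pattern_id[:-2] if pattern_id.endswith((":m", ":p")) else pattern_id


# ---------------------------------------------------------------------------
# Two-point estimation
# ---------------------------------------------------------------------------

def _pairwise_counts(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise informative counts N and coupling mismatch counts R."""
    one = (P == 1).astype(np.float32)
    zero = (P == 0).astype(np.float32)
    valid = one + zero
    N = valid @ valid.T
    R = one @ zero.T + zero @ one.T
    return N.astype(np.int64), R.astype(np.int64)


def _lod_from_counts(n: np.ndarray, rec: np.ndarray) -> np.ndarray:
    """LOD of linkage for ``rec`` recombinants among ``n`` meioses."""
    n = np.asarray(n, dtype=np.float64)
    rec = np.asarray(rec, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, rec / np.maximum(n, 1), 0.5)
        lod = ((n - rec) * np.log10(np.maximum(2 * (1 - r), 1e-300))
               + rec * np.log10(np.maximum(2 * r, 1e-300)))
        lod = np.where(rec == 0, n * math.log10(2.0), lod)
    return np.maximum(lod, 0.0)


def pairwise_rf_lod(calls_a: Sequence[int], calls_b: Sequence[int]) -> TwoPointEstimate:
    """Two-point recombination estimate between two binary testcross patterns.

    Missing observations (``-1``) are dropped pairwise.  The phase (coupling
    or repulsion) minimising the recombinant count is chosen and r and LOD are
    computed under it; with fewer than 10 complete pairs the estimate is
    flagged unreliable (``reliable`` property) and must not enter grouping.
    """
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("patterns differ in length")
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        return TwoPointEstimate(0.5, 0.0, "coupling", 0)
    mism = int((a[mask] != b[mask]).sum())
    phase = "coupling" if mism <= n - mism else "repulsion"
    rec = min(mism, n - mism)
    r = rec / n
    lod = float(_lod_from_counts(np.array([n]), np.array([rec]))[0])
    return TwoPointEstimate(r, lod, phase, n)


def pairwise_tables(P: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised all-pairs (N, recombinants, r, LOD) under the better phase."""
    N, R = _pairwise_counts(P)
    rec = np.minimum(R, N - R)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, rec / np.maximum(N, 1), 0.5)
    lod = _lod_from_counts(N, rec)
    return N, rec, r, lod


# ---------------------------------------------------------------------------
# Grouping and binning
# ---------------------------------------------------------------------------

def group_markers(pattern_ids: Sequence[str], P: np.ndarray,
                  params: MappingParams | None = None,
                  ) -> tuple[list[list[str]], list[str]]:
    """Single-linkage transitive closure over qualifying two-point edges.

    Returns (groups sorted by decreasing size, singletons).  Edges require
    LOD > ``lod_min``, r <= ``rf_max`` and at least 10 complete pairs.
    """
    params = params or MappingParams()
    ids = list(pattern_ids)
    if not ids:
        return [], []
    N, rec, r, lod = pairwise_tables(P)
    adj = (lod > params.lod_min) & (r <= params.rf_max) & (N >= MIN_INFORMATIVE_PAIRS)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for mid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(mid)
    out = [sorted(v) for v in groups.values() if len(v) > 1]
    out.sort(key=lambda g: (-len(g), g[0]))
    singletons = sorted(v[0] for v in groups.values() if len(v) == 1)
    return out, singletons


def _align_to(reference: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Flip ``pattern`` if that reduces mismatches against ``reference``."""
    mask = (reference >= 0) & (pattern >= 0)
    if mask.sum() == 0:
        return pattern
    mism = int((reference[mask] != pattern[mask]).sum())
    if mism > mask.sum() - mism:
        flipped = pattern.copy()
        flipped[pattern >= 0] = 1 - flipped[pattern >= 0]
        return flipped
    return pattern


def collapse_bins(pattern_ids: Sequence[str], P: np.ndarray,
                  min_overlap: int = MIN_INFORMATIVE_PAIRS) -> list[GeneticBin]:
    """Merge markers with zero phase-resolved recombinants into genetic bins.

    Bin representative = member with fewest missing calls (ties broken
    lexicographically by id); the bin pattern is a phase-aligned consensus
    with missing cells filled by majority vote over members.
    """
    ids = list(pattern_ids)
    if not ids:
        return []
    N, rec, _, _ = pairwise_tables(P)
    adj = (rec == 0) & (N >= min_overlap)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    bins: list[GeneticBin] = []
    for lab in sorted(set(labels)):
        member_idx = [i for i, l in enumerate(labels) if l == lab]
        members = sorted(ids[i] for i in member_idx)
        missing_counts = {ids[i]: int((P[i] < 0).sum()) for i in member_idx}
        rep = min(members, key=lambda m: (missing_counts[m], m))
        rep_idx = ids.index(rep)
        ref = P[rep_idx].copy()
        votes1 = np.zeros(P.shape[1])
        votes0 = np.zeros(P.shape[1])
        for i in member_idx:
            aligned = _align_to(ref, P[i])
            votes1 += aligned == 1
            votes0 += aligned == 0
        consensus = np.full(P.shape[1], -1, dtype=np.int8)
        consensus[votes1 > votes0] = 1
        consensus[votes0 > votes1] = 0
        bins.append(GeneticBin(representative=rep, markers=members,
                               pattern=consensus))
    bins.sort(key=lambda b: b.representative)
    return bins


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

def _adjacent_objective(order: Sequence[int], rec: np.ndarray) -> int:
    return int(sum(rec[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _two_opt(order: list[int], rec: np.ndarray) -> list[int]:
    """Segment-reversal + single-bin relocation refinement; objective is the
    total adjacent recombinant count and never increases."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                left = rec[order[i - 1], order[j]] if i > 0 else 0
                right = rec[order[i], order[j + 1]] if j < n - 1 else 0
                old_l = rec[order[i - 1], order[i]] if i > 0 else 0
                old_r = rec[order[j], order[j + 1]] if j < n - 1 else 0
                if left + right < old_l + old_r:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
        # or-opt: relocate single bins
        base = _adjacent_objective(order, rec)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                cand = order[:i] + order[i + 1:]
                cand.insert(j if j < i else j, order[i])
                if _adjacent_objective(cand, rec) < base:
                    order = cand
                    base = _adjacent_objective(order, rec)
                    improved = True
    return order


def order_markers(bins: list[GeneticBin],
                  params: MappingParams | None = None) -> list[GeneticBin]:
    """Order bins by an MST-seeded linearization refined by 2-opt.

    A complete graph on bins weighted by pairwise r is reduced to its minimum
    spanning tree; the tree's longest (weighted) path seeds the order and the
    remaining bins are inserted at the adjacent position that adds the fewest
    recombinants.  Orientation is canonical: first bin id < last bin id.
    Raises if the reliable-estimate graph is disconnected.
    """
    if len(bins) <= 1:
        return list(bins)
    P = np.stack([b.pattern for b in bins])
    N, rec, r, _ = pairwise_tables(P)
    reliable = N >= MIN_INFORMATIVE_PAIRS
    np.fill_diagonal(reliable, False)
    n_comp, labels = connected_components(csr_matrix(reliable), directed=False)
    if n_comp > 1:
        subsets = {}
        for b, lab in zip(bins, labels):
            subsets.setdefault(int(lab), []).append(b.representative)
        raise ValueError(f"estimate graph disconnected; unlinked bin subsets: "
                         f"{sorted(subsets.values())}")
    G = nx.Graph()
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            G.add_edge(i, j, weight=float(r[i, j]))
    mst = nx.minimum_spanning_tree(G)
    # longest weighted path in the tree via double sweep
    lengths = nx.single_source_dijkstra_path_length(mst, 0)
    u = max(lengths, key=lambda k: (lengths[k], bins[k].representative))
    lengths_u, paths_u = nx.single_source_dijkstra(mst, u)
    v = max(lengths_u, key=lambda k: (lengths_u[k], bins[k].representative))
    order = list(paths_u[v])
    remaining = sorted(set(range(len(bins))) - set(order),
                       key=lambda i: bins[i].representative)
    for x in remaining:
        best_cost, best_pos = None, 0
        for pos in range(len(order) + 1):
            cost = 0
            if pos > 0:
                cost += rec[order[pos - 1], x]
            if pos < len(order):
                cost += rec[x, order[pos]]
            if 0 < pos < len(order):
                cost -= rec[order[pos - 1], order[pos]]
            if best_cost is None or cost < best_cost:
                best_cost, best_pos = cost, pos
        order.insert(best_pos, x)
    order = _two_opt(order, rec)
    if bins[order[0]].representative > bins[order[-1]].representative:
        order.reverse()
    return [bins[i] for i in order]


# ---------------------------------------------------------------------------
# Error smoothing
# ---------------------------------------------------------------------------

def _orient_group(patterns: list[np.ndarray]) -> list[np.ndarray]:
    """Phase-align an ordered list of patterns sequentially."""
    out = [patterns[0].copy()]
    for p in patterns[1:]:
        out.append(_align_to(out[-1], p))
    return out


def _smooth_scores(Q: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Per-datapoint support: the better of the two flanking-side weighted
    agreement fractions, neighbour weights halving with rank.

    A genuine call sits on at least one intact haplotype segment, so its own
    side supports it fully; an isolated error is contradicted on both sides.
    Cells with no informative neighbour on either side score 1 (kept).
    """
    m, n = Q.shape
    valid = Q >= 0
    agree_l = np.zeros((m, n))
    tot_l = np.zeros((m, n))
    agree_r = np.zeros((m, n))
    tot_r = np.zeros((m, n))
    for k in range(1, n_neighbors + 1):
        w = 2.0 ** (-(k - 1))
        if k < m:
            nb = Q[:-k]
            both = valid[k:] & (nb >= 0)
            agree_l[k:] += w * (both & (nb == Q[k:]))
            tot_l[k:] += w * both
            nb = Q[k:]
            both = valid[:-k] & (nb >= 0)
            agree_r[:-k] += w * (both & (nb == Q[:-k]))
            tot_r[:-k] += w * both
    with np.errstate(invalid="ignore", divide="ignore"):
        s_l = np.where(tot_l > 0, agree_l / np.maximum(tot_l, 1e-12), np.nan)
        s_r = np.where(tot_r > 0, agree_r / np.maximum(tot_r, 1e-12), np.nan)
    score = np.fmax(s_l, s_r)  # ignores NaN sides
    score = np.where(np.isnan(score), 1.0, score)
    score[~valid] = 1.0
    return score


def smooth_correct(ordered_ids: list[str], patterns: pd.DataFrame,
                   params: MappingParams | None = None,
                   ) -> tuple[pd.DataFrame, list[tuple[str, str]], list[str]]:
    """Remove datapoints inconsistent with their flanking haplotype context.

    Works on one ordered linkage group of marker patterns.  Each iteration
    scores every call with :func:`_smooth_scores`, sets calls scoring below
    the (iteratively tightened) threshold to missing — never flips them —
    re-bins, re-orders, and stops when an iteration removes nothing or
    ``smooth_max_iter`` is reached.

    Returns (cleaned patterns, removal log of (marker, individual), final
    marker order).
    """
    params = params or MappingParams()
    cleaned = patterns.copy()
    removals: list[tuple[str, str]] = []
    order = list(ordered_ids)
    threshold = params.smooth_threshold
    for _ in range(params.smooth_max_iter):
        Q = np.stack([cleaned.loc[m].to_numpy() for m in order])
        Q = np.stack(_orient_group([q for q in Q]))
        scores = _smooth_scores(Q, params.smooth_neighbors)
        bad = (Q >= 0) & (scores < threshold)
        # only remove local score minima: a cell contradicted by a worse
        # neighbouring cell of the same individual is that cell's victim and
        # is re-scored after the culprit is gone
        for i, j in zip(*np.nonzero(bad)):
            lo = max(0, i - params.smooth_neighbors)
            hi = min(Q.shape[0], i + params.smooth_neighbors + 1)
            window = scores[lo:hi, j][bad[lo:hi, j]]
            if window.size and scores[i, j] > window.min():
                bad[i, j] = False
        if not bad.any():
            break
        inds = list(patterns.columns)
        for i, j in zip(*np.nonzero(bad)):
            cleaned.loc[order[i], inds[j]] = -1
            removals.append((order[i], inds[j]))
        bins = collapse_bins(order, np.stack([cleaned.loc[m].to_numpy()
                                              for m in order]))
        try:
            ordered_bins = order_markers(bins, params)
        except ValueError:
            ordered_bins = bins
        order = [m for b in ordered_bins for m in b.markers]
        # successive passes are stricter about what counts as an error
        threshold = max(threshold - params.smooth_tighten, 0.0)
    return cleaned, removals, order


def apply_removals(gm: GenotypeMatrix, removals: list[tuple[str, str]]) -> GenotypeMatrix:
    """Return a copy of ``gm`` with the logged datapoints set to missing."""
    calls = gm.calls.copy()
    for pid, ind in removals:
        calls.loc[base_marker_id(pid), ind] = MISSING
    return GenotypeMatrix(calls, gm.mother.copy(), gm.father.copy(),
                          gm.seg_class.copy())


# ---------------------------------------------------------------------------
# Map distances
# ---------------------------------------------------------------------------

def kosambi_cM(r: float) -> float:
    """Kosambi map distance in cM: 25 * ln((1+2r)/(1-2r)).

    The quarter-log form yields Morgans; positions are stored in cM.
    """
    if not (0.0 <= r < 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cM: float) -> float:
    """Inverse of :func:`kosambi_cM` (closed form, r = tanh(2d)/2)."""
    if d_cM < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * math.tanh(2.0 * d_cM / 100.0)


def map_distances(ordered_bins: list[GeneticBin]) -> list[GeneticBin]:
    """Assign cumulative Kosambi cM positions from adjacent recombination
    fractions; the first bin sits at 0."""
    pos = 0.0
    for i, b in enumerate(ordered_bins):
        if i > 0:
            est = pairwise_rf_lod(ordered_bins[i - 1].pattern, b.pattern)
            r = min(est.r, 0.4999999)
            pos += kosambi_cM(r)
        b.position_cM = pos
    return ordered_bins


# ---------------------------------------------------------------------------
# Full per-parent build
# ---------------------------------------------------------------------------

def build_parent_map(gm: GenotypeMatrix, parent: str,
                     params: MappingParams | None = None,
                     smooth: bool = True,
                     ) -> tuple[GeneticMap, list[tuple[str, str]]]:
    """Run the full grouping/binning/ordering/smoothing/distance pipeline.

    Returns the map and the smoothing removal log (pattern id, individual).
    """
    params = params or MappingParams()
    patterns = parental_patterns(gm, parent)
    ids = list(patterns.index)
    P = patterns.to_numpy()
    groups, singletons = group_markers(ids, P, params)
    lgs: list[LinkageGroup] = []
    all_removals: list[tuple[str, str]] = []
    cleaned_all = patterns.copy()
    for gi, member_ids in enumerate(groups):
        sub = patterns.loc[member_ids]
        bins = collapse_bins(member_ids, sub.to_numpy())
        ordered = order_markers(bins, params)
        if smooth:
            order_ids = [m for b in ordered for m in b.markers]
            cleaned, removals, order_ids = smooth_correct(order_ids, sub, params)
            all_removals.extend(removals)
            cleaned_all.loc[member_ids] = cleaned
            bins = collapse_bins(order_ids,
                                 np.stack([cleaned.loc[m].to_numpy()
                                           for m in order_ids]))
            ordered = order_markers(bins, params)
        ordered = map_distances(ordered)
        lgs.append(LinkageGroup(lg_id=0, bins=ordered))
    lgs.sort(key=lambda g: (-g.n_markers, g.bins[0].representative if g.bins else ""))
    for i, g in enumerate(lgs):
        g.lg_id = i + 1
    return (GeneticMap(parent=parent, groups=lgs, singletons=singletons,
                       individuals=list(patterns.columns)), all_removals)


# ---------------------------------------------------------------------------
# Distortion scan
# ---------------------------------------------------------------------------

def distortion_scan(gm: GenotypeMatrix, params: MappingParams | None = None,
                    bonferroni: bool = False) -> pd.DataFrame:
    """Chi-square segregation-distortion test per retained marker.

    Testcross markers are tested against 1:1 with (a-b)^2/(a+b) on 1 df;
    ABxCD markers against 1:1:1:1 (3 df) and shared biallelic het x het
    against 1:2:1 (2 df).  ``flagged`` marks p below ``distortion_alpha``
    (optionally Bonferroni-corrected across markers).
    """
    params = params or MappingParams()
    rows = []
    for mid in gm.marker_ids:
        seg = gm.seg_class[mid]
        calls = gm.calls.loc[mid]
        counts = calls[calls != MISSING].value_counts()
        if seg in (MATERNAL_TC, PATERNAL_TC):
            hom = gm.father[mid] if seg == MATERNAL_TC else gm.mother[mid]
            classes = [HOM_REF, HET] if hom == HOM_REF else [HET, HOM_ALT]
            a, b = (int(counts.get(c, 0)) for c in classes)
            total = a + b
            chi2 = (a - b) ** 2 / total if total else 0.0
            df = 1
        elif seg == FULLY_INFORMATIVE:
            par = gm.mother[mid]
            if par == HET:  # biallelic het x het, expect 1:2:1
                obs = [int(counts.get(c, 0)) for c in (HOM_REF, HET, HOM_ALT)]
                total = sum(obs)
                exp = [total / 4, total / 2, total / 4]
                chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp)) if total else 0.0
                df = 2
            else:  # ABxCD, expect 1:1:1:1
                classes = sorted({"".join(sorted((x, y)))
                                  for x in gm.mother[mid] for y in gm.father[mid]})
                obs = [int(counts.get(c, 0)) for c in classes]
                total = sum(obs)
                exp_v = total / len(classes) if total else 0
                chi2 = (sum((o - exp_v) ** 2 / exp_v for o in obs)
                        if total else 0.0)
                df = len(classes) - 1
        else:
            continue
        p = float(stats.chi2.sf(chi2, df)) if total else 1.0
        rows.append((mid, seg, chi2, df, p))
    out = pd.DataFrame(rows, columns=["marker", "seg_class", "chi2", "df", "p"]
                       ).set_index("marker")
    alpha = params.distortion_alpha / max(len(out), 1) if bonferroni \
        else params.distortion_alpha
    out["flagged"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# Cross-parent synteny
# ---------------------------------------------------------------------------

@dataclass
class InversionSegment:
    lg_a: int
    lg_b: int
    anchors: list[str]
    extent_a: tuple[float, float]
    extent_b: tuple[float, float]

    @property
    def span_a(self) -> float:
        return self.extent_a[1] - self.extent_a[0]

    @property
    def span_b(self) -> float:
        return abs(self.extent_b[1] - self.extent_b[0])


@dataclass
class SyntenyReport:
    anchors: list[str]
    lg_pairs: dict[int, int]  # map A LG -> map B LG (majority pairing)
    order_correlation: dict[int, float]  # per map-A LG, Spearman rho
    inversions: list[InversionSegment]
    translocations: list[str]
    unalignable: list[int]


def compare_maps(map_a: GeneticMap, map_b: GeneticMap,
                 min_anchor_run: int = 2) -> SyntenyReport:
    """Align two parental maps through shared fully-informative anchors.

    Linkage groups are paired by anchor majority; within each pair, maximal
    strictly-decreasing runs of at least ``min_anchor_run`` anchors (ordered
    by map A, positions compared in map B after orienting map B's LG to a
    positive trend) are reported as inversion candidates with cM extents.
    Anchors voting against the majority pairing are translocation candidates.
    """
    pos_a = {base_marker_id(m): v for m, v in map_a.marker_positions().items()}
    pos_b = {base_marker_id(m): v for m, v in map_b.marker_positions().items()}
    anchors = sorted(set(pos_a) & set(pos_b))
    votes: dict[int, dict[int, int]] = {}
    for m in anchors:
        la, lb = pos_a[m][0], pos_b[m][0]
        votes.setdefault(la, {}).setdefault(lb, 0)
        votes[la][lb] += 1
    lg_pairs = {la: max(v, key=lambda k: (v[k], -k)) for la, v in votes.items()}
    translocations = [m for m in anchors
                      if pos_b[m][0] != lg_pairs.get(pos_a[m][0])]
    inversions: list[InversionSegment] = []
    correlations: dict[int, float] = {}
    unalignable: list[int] = []
    for la, lb in sorted(lg_pairs.items()):
        shared = [m for m in anchors
                  if pos_a[m][0] == la and pos_b[m][0] == lb]
        if len(shared) < 2:
            unalignable.append(la)
            continue
        shared.sort(key=lambda m: (pos_a[m][1], m))
        xa = np.array([pos_a[m][1] for m in shared])
        xb = np.array([pos_b[m][1] for m in shared])
        rho = float(stats.spearmanr(xa, xb).statistic) if len(shared) > 2 else 1.0
        correlations[la] = rho
        if rho < 0:  # orient map B's group to a positive overall trend
            xb = -xb
        # maximal strictly decreasing runs in map-B order
        i = 0
        while i < len(shared) - 1:
            j = i
            while j + 1 < len(shared) and xb[j + 1] < xb[j]:
                j += 1
            if j - i + 1 >= min_anchor_run:
                seg = shared[i:j + 1]
                ext_b = (float(min(pos_b[m][1] for m in seg)),
                         float(max(pos_b[m][1] for m in seg)))
                inversions.append(InversionSegment(
                    lg_a=la, lg_b=lb, anchors=seg,
                    extent_a=(float(xa[i]), float(xa[j])), extent_b=ext_b))
            i = max(j, i + 1)
    return SyntenyReport(anchors=anchors, lg_pairs=lg_pairs,
                         order_correlation=correlations, inversions=inversions,
                         translocations=sorted(translocations),
                         unalignable=unalignable)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class MapSummary:
    """Per-linkage-group statistics plus totals, Table-style.

    ``published_totals`` overrides the column sums when a source table
    carries an explicit Total row (the two can disagree in published data).
    """

    parent: str
    per_group: pd.DataFrame  # columns lg, n_markers, length_cM, n_bins
    published_totals: dict | None = None

    def _total(self, column: str):
        if self.published_totals is not None:
            return self.published_totals[column]
        return self.per_group[column].sum()

    @property
    def total_markers(self) -> int:
        return int(self._total("n_markers"))

    @property
    def total_length(self) -> float:
        return float(self._total("length_cM"))

    @property
    def total_bins(self) -> int:
        return int(self._total("n_bins"))

    @property
    def mean_bin_spacing(self) -> float:
        """Total length / total bins, rounded to 2 decimals for reporting."""
        if self.total_bins == 0:
            return 0.0
        return round(self.total_length / self.total_bins, 2)


def map_stats(gmap: GeneticMap) -> MapSummary:
    """Summarise a built map: per-LG marker count, cM length, bin count."""
    rows = [(g.lg_id, g.n_markers, g.length_cM, len(g.bins))
            for g in gmap.groups]
    df = pd.DataFrame(rows, columns=["lg", "n_markers", "length_cM", "n_bins"])
    return MapSummary(parent=gmap.parent, per_group=df)
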