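"""Haley-Knott interval mapping for RIL populations with permutation thresholds.

The scan regresses per-line trait means on the expected QTL genotype at a
grid of pseudo-positions along the genetic map.  Expected genotypes are
conditional P(AA) values given the nearest informative flanking markers,
using Haldane recombination fractions r = (1 - exp(-2d/100)) / 2 and the
selfed-RIL expansion R = 2r / (1 + 2r) (two observable genotype classes,
fully inbred lines).  Evidence is summarized as LOD = (n/2) log10(RSS0/RSS1).
Genome-wide significance comes from permuting line means across lines and
taking an empirical quantile of the per-permutation maximum LOD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phenostat import LineMeans

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "GenotypeProbs",
    "QTLScan",
    "PermutationThreshold",
    "QTLPeak",
    "haldane_r",
    "ril_expansion",
    "conditional_genotype_probs",
    "interval_mapping_scan",
    "permutation_threshold",
    "call_qtl_peaks",
]

logger = logging.getLogger(__name__)

#: RSS floor factor guarding LOD against a perfect fit (RSS1 = 0).
RSS_FLOOR = 1e-12


def haldane_r(d_cM) -> np.ndarray:
    """Haldane map function: distance in cM -> recombination fraction (no interference)."""
    d = np.asarray(d_cM, dtype=np.float64)
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def ril_expansion(r) -> np.ndarray:
    """Observable recombination fraction between selfed-RIL genotypes: R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=np.float64)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers: parallel tuples of name, chromosome, and position (cM).

    Positions must be non-decreasing within a chromosome and marker names
    unique; chromosome blocks must be contiguous in the given order.
    """

    names: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_cM: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.chromosomes) == len(self.positions_cM) == n) or n == 0:
            raise ValueError("map fields must be equal-length and non-empty")
        if len(set(self.names)) != n:
            raise ValueError("marker names must be unique")
        seen: set[str] = set()
        prev_chrom = None
        prev_pos = -np.inf
        for chrom, pos in zip(self.chromosomes, self.positions_cM):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise ValueError(f"chromosome {chrom!r} markers are not contiguous")
                seen.add(chrom)
                prev_chrom, prev_pos = chrom, -np.inf
            if pos < prev_pos:
                raise ValueError(f"positions must be non-decreasing within chromosome {chrom!r}")
            if pos < 0:
                raise ValueError("positions must be >= 0 cM")
            prev_pos = pos

    @property
    def n_markers(self) -> int:
        return len(self.names)

    def chromosome_order(self) -> list[str]:
        return list(dict.fromkeys(self.chromosomes))


@dataclass(frozen=True)
class GenotypeMatrix:
    """Line x marker calls: 1.0 = AA, 0.0 = BB, NaN = missing (fully inbred RILs)."""

    line_ids: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.float64)
        if calls.ndim != 2 or calls.shape[0] != len(self.line_ids):
            raise ValueError("calls must be a 2-D lines x markers array")
        valid = np.isnan(calls) | (calls == 0.0) | (calls == 1.0)
        if not valid.all():
            raise ValueError("genotype calls must be 0, 1 or NaN")
        object.__setattr__(self, "calls", calls)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass(frozen=True)
class GenotypeProbs:
    """Conditional P(AA) per line at each pseudo-position of the scan grid."""

    line_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_cM: np.ndarray
    p_aa: np.ndarray  # n_lines x n_positions


@dataclass(frozen=True)
class QTLScan:
    """Per-position LOD profile for one trait."""

    trait: str
    chromosomes: tuple[str, ...]
    positions_cM: np.ndarray
    lod: np.ndarray
    n_lines: int


@dataclass(frozen=True)
class PermutationThreshold:
    """Genome-wide empirical LOD threshold from phenotype permutations."""

    alpha: float
    n_perm: int
    threshold_lod: float
    seed: int


@dataclass(frozen=True)
class QTLPeak:
    """A called QTL: peak location, LOD, LOD-drop support interval, additive effect."""

    trait: str
    chromosome: str
    peak_cM: float
    peak_lod: float
    support_interval_cM: tuple[float, float]
    effect: float


def _nearest_informative(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per line/marker, index of the nearest non-missing marker at-or-left / at-or-right.

    Returns (left_idx, right_idx), each n x M with -1 where none exists.
    """
    n, m = calls.shape
    informative = ~np.isnan(calls)
    idx = np.where(informative, np.arange(m)[None, :], -1)
    left = np.maximum.accumulate(idx, axis=1)
    ridx = np.where(informative, np.arange(m)[None, :], m)
    right = np.minimum.accumulate(ridx[:, ::-1], axis=1)[:, ::-1]
    right = np.where(right == m, -1, right)
    return left, right


def conditional_genotype_probs(gmap: GeneticMap, geno: GenotypeMatrix, step_cM: float = 1.0) -> GenotypeProbs:
    """Conditional P(AA) for every line at a step_cM grid plus all marker positions.

    At each pseudo-position the nearest informative flanking markers condition
    the genotype through the RIL Markov chain: transition probability between
    same (different) genotypes over distance d is 1-R(d) (R(d)) with R the
    RIL-expanded Haldane fraction.  Lines with no informative marker on a
    chromosome get P(AA) = 0.5.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be > 0")
    mpos_all = np.asarray(gmap.positions_cM, dtype=np.float64)
    chroms_all = np.asarray(gmap.chromosomes, dtype=object)
    n = geno.n_lines
    if geno.calls.shape[1] != gmap.n_markers:
        raise ValueError("genotype matrix width must match the map")

    out_chrom: list[str] = []
    out_pos: list[float] = []
    out_p: list[np.ndarray] = []
    for chrom in gmap.chromosome_order():
        sel = np.flatnonzero(chroms_all == chrom)
        if sel.size == 0:
            logger.warning("chromosome %s has no markers; skipped", chrom)
            continue
        mpos = mpos_all[sel]
        calls = geno.calls[:, sel]
        grid = np.arange(mpos[0], mpos[-1] + step_cM / 2.0, step_cM)
        qpos = np.union1d(np.round(grid, 9), np.round(mpos, 9))
        left_idx, right_idx = _nearest_informative(calls)

        for q in qpos:
            jl = int(np.searchsorted(mpos, q, side="right")) - 1
            jr = int(np.searchsorted(mpos, q, side="left"))
            jr = min(jr, mpos.size - 1)
            li = left_idx[:, jl] if jl >= 0 else np.full(n, -1)
            ri = right_idx[:, jr]
            has_l = li >= 0
            has_r = ri >= 0

            rl = ril_expansion(haldane_r(q - mpos[np.where(has_l, li, 0)]))
            rr = ril_expansion(haldane_r(mpos[np.where(has_r, ri, 0)] - q))
            gl = calls[np.arange(n), np.where(has_l, li, 0)]
            gr = calls[np.arange(n), np.where(has_r, ri, 0)]

            # transition weights toward AA / BB from each informative flank
            wl_aa = np.where(has_l, np.where(gl == 1.0, 1.0 - rl, rl), 0.5)
            wl_bb = np.where(has_l, np.where(gl == 0.0, 1.0 - rl, rl), 0.5)
            wr_aa = np.where(has_r, np.where(gr == 1.0, 1.0 - rr, rr), 0.5)
            wr_bb = np.where(has_r, np.where(gr == 0.0, 1.0 - rr, rr), 0.5)
            num_aa = wl_aa * wr_aa
            num_bb = wl_bb * wr_bb
            p = num_aa / (num_aa + num_bb)

            out_chrom.append(chrom)
            out_pos.append(float(q))
            out_p.append(p)

    return GenotypeProbs(
        line_ids=tuple(geno.line_ids),
        chromosomes=tuple(out_chrom),
        positions_cM=np.asarray(out_pos),
        p_aa=np.column_stack(out_p) if out_p else np.empty((n, 0)),
    )


def _lod_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD for every (position, phenotype) pair of a single-QTL regression scan.

    x is n x P expected genotypes, y is n x K phenotype vectors.  Uses the
    closed form RSS1 = Syy - Sxy^2/Sxx of simple regression, so the whole
    permutation stack is two matrix products.  Monomorphic positions
    (Sxx ~ 0) score LOD 0; RSS1 is floored at RSS_FLOOR * RSS0.
    """
    n = x.shape[0]
    xc = x - x.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", xc, xc)
    syy = np.einsum("ij,ij->j", yc, yc)
    sxy = xc.T @ yc  # P x K
    informative = sxx > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        rss1 = syy[None, :] - np.where(informative, 1.0, np.nan)[:, None] * sxy**2 / np.where(informative, sxx, 1.0)[:, None]
    rss0 = np.broadcast_to(syy[None, :], rss1.shape)
    rss1 = np.maximum(rss1, RSS_FLOOR * rss0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((rss1 > 0) & ~np.isnan(rss1), rss0 / np.where(rss1 > 0, rss1, 1.0), 1.0)
        lod = (n / 2.0) * np.log10(ratio)
    return np.maximum(np.nan_to_num(lod, nan=0.0), 0.0)


def _align_means(probs: GenotypeProbs, line_means: list[LineMeans], trait: str) -> tuple[np.ndarray, np.ndarray]:
    by_line = {m.line_id: m.lsmean for m in line_means if m.trait == trait}
    if not by_line:
        raise ValueError(f"no line means for trait {trait!r}")
    keep = [i for i, lid in enumerate(probs.line_ids) if lid in by_line and np.isfinite(by_line[lid])]
    if len(keep) < 10:
        raise ValueError(f"need >= 10 informative lines, have {len(keep)}")
    y = np.array([by_line[probs.line_ids[i]] for i in keep])
    return probs.p_aa[keep, :], y


def interval_mapping_scan(probs: GenotypeProbs, line_means: list[LineMeans], trait: str) -> QTLScan:
    """Genome scan: regress line means on expected genotype at every pseudo-position.

    The genotype regressor is coded 2*P(AA) - 1 so the fitted slope is the
    additive effect (half the difference between homozygote means).
    """
    x, y = _align_means(probs, line_means, trait)
    lod = _lod_matrix(2.0 * x - 1.0, y[:, None])[:, 0]
    n_mono = int(np.sum((2.0 * x - 1.0).std(axis=0) <= 1e-7))
    if n_mono:
        logger.warning("%d monomorphic position(s) scored LOD 0", n_mono)
    return QTLScan(
        trait=trait,
        chromosomes=probs.chromosomes,
        positions_cM=probs.positions_cM.copy(),
        lod=lod,
        n_lines=x.shape[0],
    )


def permutation_threshold(
    probs: GenotypeProbs,
    line_means: list[LineMeans],
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationThreshold:
    """Genome-wide LOD threshold: (1-alpha) quantile of max LOD over permutations.

    Line means are shuffled across lines n_perm times; each shuffle is
    rescanned and its genome-wide maximum recorded.  The threshold is the
    empirical (1-alpha) quantile with type-7 (linear) interpolation,
    reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    x, y = _align_means(probs, line_means, trait)
    rng = np.random.default_rng(seed)
    n = y.size
    perm_y = np.empty((n, n_perm))
    for k in range(n_perm):
        perm_y[:, k] = y[rng.permutation(n)]
    max_lod = _lod_matrix(2.0 * x - 1.0, perm_y).max(axis=0)
    thr = float(np.quantile(max_lod, 1.0 - alpha, method="linear"))
    return PermutationThreshold(alpha=alpha, n_perm=n_perm, threshold_lod=thr, seed=seed)


def _estimate_effect(x_col: np.ndarray, y: np.ndarray) -> float:
    xc = x_col - x_col.mean()
    sxx = float(xc @ xc)
    if sxx <= 1e-12:
        return 0.0
    return float(xc @ (y - y.mean()) / sxx)


def call_qtl_peaks(
    scan: QTLScan,
    thr: PermutationThreshold,
    drop_lod: float = 1.5,
    probs: GenotypeProbs | None = None,
    line_means: list[LineMeans] | None = None,
    min_separation_cM: float = 30.0,
) -> list[QTLPeak]:
    """Call QTL peaks: per-chromosome local maxima above the threshold.

    A peak's support interval is the contiguous run of positions within
    drop_lod of the peak LOD.  Candidate maxima whose support interval
    overlaps an already claimed one, or that lie within min_separation_cM of
    a claimed peak, are merged into it: a strong QTL's linkage shadow can
    lift shoulder maxima above a genome-wide threshold tens of cM away
    (RIL genotype correlation 1-2R is still ~0.25 at 30 cM).  When probs and
    line_means are supplied the additive effect (slope on the -1/+1 genotype
    axis) is estimated at each peak, else reported as NaN.
    """
    chroms = np.asarray(scan.chromosomes, dtype=object)
    peaks: list[QTLPeak] = []
    x = y = None
    if probs is not None and line_means is not None:
        x, y = _align_means(probs, line_means, scan.trait)
    for chrom in dict.fromkeys(scan.chromosomes):
        sel = np.flatnonzero(chroms == chrom)
        lod = scan.lod[sel]
        pos = scan.positions_cM[sel]
        above = lod >= thr.threshold_lod
        # candidates are local maxima of the profile (plateaus count once)
        higher_left = np.empty(lod.size, dtype=bool)
        higher_left[0] = True
        higher_left[1:] = lod[1:] >= lod[:-1]
        higher_right = np.empty(lod.size, dtype=bool)
        higher_right[-1] = True
        higher_right[:-1] = lod[:-1] > lod[1:]
        local_max = above & higher_left & higher_right
        claimed: list[tuple[int, int, float]] = []
        order = sorted(np.flatnonzero(local_max), key=lambda j: -lod[j])
        for i in order:
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - drop_lod:
                lo -= 1
            hi = i
            while hi < lod.size - 1 and lod[hi + 1] >= lod[i] - drop_lod:
                hi += 1
            # a candidate whose support interval overlaps an already claimed
            # one, or that sits within the separation radius of a claimed
            # peak, is the same QTL's shoulder: merge it into that peak
            if any(lo <= c_hi and hi >= c_lo for c_lo, c_hi, _ in claimed):
                continue
            if any(abs(pos[i] - c_pos) < min_separation_cM for _, _, c_pos in claimed):
                continue
            claimed.append((lo, hi, float(pos[i])))
            effect = float("nan")
            if x is not None and y is not None:
                effect = _estimate_effect(2.0 * x[:, sel[i]] - 1.0, y)
            peaks.append(
                QTLPeak(
                    trait=scan.trait,
                    chromosome=str(chrom),
                    peak_cM=float(pos[i]),
                    peak_lod=float(lod[i]),
                    support_interval_cM=(float(pos[lo]), float(pos[hi])),
                    effect=effect,
                )
            )
    peaks.sort(key=lambda p: (str(p.chromosome), p.peak_cM))
    return peaks
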