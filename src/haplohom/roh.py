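"""Runs of homozygosity (ROH) between paired haplotypes.

Two phased haplotypes are treated as a pseudo-diploid: a site is
heterozygous when their alleles differ.  A run of homozygosity is a maximal
stretch of consecutive panel sites containing at most a bounded number of
heterozygous sites (default 1, PLINK-style), spanning at least a minimum
physical length (default 10 kb) and a minimum number of sites.  Long
abundant ROH indicate recent shared ancestry or inbreeding; plotting total
ROH coverage against whole-chromosome homozygosity separates recent
inbreeding from old, population-level loss of diversity.

Detection here is an exact maximal-run scan rather than PLINK's windowed
heuristic: every candidate run is bounded by the heterozygous sites that
would push it over the allowance, so no reported run can be extended in
either direction.  Overlapping candidates (which share an allowed
heterozygous site) are resolved greedily left to right.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PanelError


@dataclass
class ROHParams:
    min_length_bp: int = 10_000
    max_het_per_run: int = 1
    min_sites_per_run: int = 25

    def __post_init__(self) -> None:
        if self.min_length_bp < 1 or self.min_sites_per_run < 1:
            raise PanelError("ROH length/site minima must be positive")
        if self.max_het_per_run < 0:
            raise PanelError("max_het_per_run must be >= 0")


@dataclass
class ROHSegment:
    """One run, in 1-based inclusive coordinates of its first/last site."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_sites: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def detect_roh(
    h1: np.ndarray,
    h2: np.ndarray,
    positions: np.ndarray,
    params: ROHParams,
    chromosome: str = "",
) -> list[ROHSegment]:
    """All qualifying maximal runs of homozygosity for one haplotype pair.

    Candidate runs are the maximal windows containing <= ``max_het_per_run``
    heterozygous sites.  Consecutive candidates overlap (they share allowed
    heterozygous sites or the homozygous stretch between two); segments are
    made disjoint greedily left to right, truncating each candidate to start
    after the previously accepted segment, so the shared region always
    belongs to the leftmost-starting maximal run.  Length and site-count
    minima are applied after truncation.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    positions = np.asarray(positions, dtype=np.int64)
    if not (h1.shape == h2.shape == positions.shape):
        raise PanelError("haplotypes and positions must be aligned")
    if positions.size and np.any(np.diff(positions) <= 0):
        raise PanelError("positions must be strictly increasing")
    L = positions.size
    if L == 0:
        return []

    het_idx = np.flatnonzero(h1 != h2)
    k = params.max_het_per_run
    # sentinels: virtual blocking hets just outside the panel
    q = np.concatenate(([-1], het_idx, [L]))
    m = het_idx.size
    segments: list[ROHSegment] = []
    last_end = -1
    for t in range(max(m - k, 0) + 1):
        start = max(int(q[t]) + 1, last_end + 1)
        end = int(q[min(t + k + 1, m + 1)]) - 1
        if end < start or end <= last_end:
            continue
        n_sites = end - start + 1
        span = int(positions[end] - positions[start] + 1)
        n_het = int(np.searchsorted(het_idx, end, side="right")
                    - np.searchsorted(het_idx, start))
        if n_sites < params.min_sites_per_run or span < params.min_length_bp:
            continue
        segments.append(
            ROHSegment(chromosome, int(positions[start]), int(positions[end]), n_sites, n_het)
        )
        last_end = end
    return segments


def roh_coverage(segments: list[ROHSegment], chromosome_span_bp: int) -> float:
    """Fraction of the chromosome span covered by non-overlapping ROH."""
    if chromosome_span_bp < 1:
        raise PanelError("chromosome span must be positive")
    ordered = sorted(segments, key=lambda s: s.start_bp)
    prev_end = -1
    total = 0
    for s in ordered:
        if s.start_bp <= prev_end:
            raise PanelError(
                f"overlapping ROH segments at {s.chromosome}:{s.start_bp}"
            )
        total += s.length_bp
        prev_end = s.end_bp
    return total / chromosome_span_bp


def pair_roh_coverages(
    m,  # HaplotypeMatrix
    pairs: pd.DataFrame,
    params: ROHParams,
    span_bp: int | None = None,
) -> np.ndarray:
    """Total ROH coverage for every pair row of a pair-homozygosity table."""
    if span_bp is None:
        span_bp = int(m.positions[-1] - m.positions[0] + 1)
    row = {h: i for i, h in enumerate(m.haplotype_ids)}
    out = np.empty(len(pairs))
    for i, (a, b) in enumerate(zip(pairs["hap_id_1"], pairs["hap_id_2"])):
        segs = detect_roh(
            m.alleles[row[a]], m.alleles[row[b]], m.positions, params, m.chromosome
        )
        out[i] = roh_coverage(segs, span_bp)
    return out


@dataclass
class ClassFit:
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    mean_homozygosity: float
    mean_coverage: float
    mean_residual: float  # residual from the pooled fit


@dataclass
class RohHomFit:
    """Per-group-pair regression of homozygosity on ROH coverage."""

    fits: dict[str, ClassFit]
    pooled_slope: float
    pooled_intercept: float

    def residual_difference(self, class_a: str, class_b: str) -> float:
        """Mean pooled-fit residual of ``class_a`` minus that of ``class_b``.

        Positive means class_a pairs are more homozygous than class_b pairs
        at equal ROH coverage — the diagnostic that separates old
        population-level homozygosity from recent inbreeding.
        """
        return self.fits[class_a].mean_residual - self.fits[class_b].mean_residual


def homozygosity_vs_roh(table: pd.DataFrame, coverages: np.ndarray) -> RohHomFit:
    """Fit homozygosity ~ ROH coverage per group combination.

    ``coverages`` must align row-wise with ``table``.  Each class (unordered
    group pair, e.g. ``EuropeanWild x EuropeanWild``) gets its own
    least-squares line; residuals from a pooled all-class fit support the
    equal-coverage comparison via :meth:`RohHomFit.residual_difference`.
    """
    coverages = np.asarray(coverages, dtype=float)
    if len(coverages) != len(table):
        raise PanelError("coverages not aligned with pair table")
    y = table["homozygosity"].to_numpy(float)
    labels = np.array(
        [" x ".join(sorted((g1, g2))) for g1, g2 in zip(table["group_1"], table["group_2"])]
    )
    if np.ptp(coverages) > 0:
        pooled_slope, pooled_intercept = np.polyfit(coverages, y, 1)
    else:
        pooled_slope, pooled_intercept = 0.0, float(y.mean())
    pooled_resid = y - (pooled_slope * coverages + pooled_intercept)

    fits: dict[str, ClassFit] = {}
    for lab in np.unique(labels):
        sel = labels == lab
        if sel.sum() < 3:
            raise PanelError(f"class {lab!r} has fewer than 3 pairs")
        x_c, y_c = coverages[sel], y[sel]
        if np.ptp(x_c) > 0:
            res = stats.linregress(x_c, y_c)
            slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        else:
            slope, intercept, r2 = 0.0, float(y_c.mean()), 1.0 if np.ptp(y_c) == 0 else 0.0
        fits[lab] = ClassFit(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(r2),
            n_pairs=int(sel.sum()),
            mean_homozygosity=float(y_c.mean()),
            mean_coverage=float(x_c.mean()),
            mean_residual=float(pooled_resid[sel].mean()),
        )
    return RohHomFit(fits, float(pooled_slope), float(pooled_intercept))


def write_bed(segments: list[ROHSegment], path: str | Path) -> Path:
    """BED export: 0-based half-open intervals, with site and het counts."""
    lines = [
        f"{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{s.n_sites}\t{s.n_het}"
        for s in segments
    ]
    p = Path(path)
    p.write_text("\n".join(lines) + ("\n" if lines else ""))
    return p
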