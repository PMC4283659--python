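"""Pairwise haplotype homozygosity and its pooled distributions.

Haplotype homozygosity between two phased haplotypes is the proportion of
panel sites at which they carry the same allele — one minus the normalized
Hamming distance, with the *full* retained panel (monomorphic sites
included) as the denominator.  Pairing every combination of two haplotypes
in a dataset and pooling by population group yields distributions whose
locations separate demographic histories: a bottlenecked wild group shows
high within-group homozygosity, deeply diverged continental clades show low
between-group homozygosity, and an admixed group sits in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GroupAssignment, HaplotypeMatrix, PanelError

#: Column schema of the pair-homozygosity table.
PAIR_COLUMNS = [
    "hap_id_1",
    "hap_id_2",
    "individual_1",
    "individual_2",
    "group_1",
    "group_2",
    "chromosome",
    "n_sites",
    "homozygosity",
]


def pair_homozygosity(h1: np.ndarray, h2: np.ndarray) -> float:
    """Proportion of sites at which two haplotypes carry the same allele.

    Symmetric in its arguments; 1.0 for identical haplotypes, 0.0 for
    complementary ones.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape or h1.ndim != 1:
        raise PanelError(f"haplotype length mismatch: {h1.shape} vs {h2.shape}")
    if h1.size == 0:
        raise PanelError("haplotypes must contain at least one site")
    return float(np.mean(h1 == h2))


def pairwise_homozygosity_matrix(
    a: np.ndarray, b: np.ndarray | None = None
) -> np.ndarray:
    """Homozygosity between every row of ``a`` and every row of ``b``.

    Computed through a single matrix product on +/-1 recoded alleles:
    for binary vectors, agreements − disagreements = s_a · s_b with
    s = 2x − 1, so matches = (s_a · s_b + L) / 2.
    """
    sa = a.astype(np.float32) * 2 - 1
    sb = sa if b is None else b.astype(np.float32) * 2 - 1
    L = a.shape[1]
    # the +/-1 dot products are integers below 2**24, hence exact in float32;
    # divide in float64 so the proportions are exact too
    return ((sa @ sb.T).astype(np.float64) + L) / (2 * L)


def all_pairs(
    m: HaplotypeMatrix,
    groups: GroupAssignment,
    within: str | None = None,
    between: tuple[str, str] | None = None,
    include_within_individual: bool = True,
) -> pd.DataFrame:
    """Homozygosity for every unordered pair of haplotypes in scope.

    Scope is one of: all pairs within a group (``within``), all cross pairs
    between two disjoint groups (``between``), or — with neither — every
    pair in the panel.  Each unordered pair appears once with
    ``hap_id_1 < hap_id_2`` lexicographically.  Pairs of the two haplotypes
    of one individual are included by default and can be excluded to study
    between-individual variation only.
    """
    if within is not None and between is not None:
        raise PanelError("pass at most one of within= and between=")
    groups.validate_against(m)
    panel_ids = set(m.haplotype_ids)

    def group_ids(g: str) -> list[str]:
        ids = [h for h in groups.haplotypes_in(g) if h in panel_ids]
        if not ids:
            raise PanelError(f"group {g!r} has no haplotypes in this panel")
        return ids

    if between is not None:
        g1, g2 = between
        ids1, ids2 = group_ids(g1), group_ids(g2)
        if set(ids1) & set(ids2):
            raise PanelError(f"groups {g1!r} and {g2!r} share haplotypes")
        pairs = [tuple(sorted((a, b))) for a in ids1 for b in ids2]
    else:
        ids = sorted(panel_ids) if within is None else group_ids(within)
        pairs = list(combinations(ids, 2))

    if not include_within_individual:
        pairs = [
            (a, b)
            for a, b in pairs
            if groups.individual_of(a) != groups.individual_of(b)
        ]
    pairs.sort()

    row_of = {h: i for i, h in enumerate(m.haplotype_ids)}
    used = sorted({h for p in pairs for h in p}, key=row_of.get)
    sub_index = {h: i for i, h in enumerate(used)}
    hom = pairwise_homozygosity_matrix(m.alleles[[row_of[h] for h in used]])

    i1 = [sub_index[a] for a, _ in pairs]
    i2 = [sub_index[b] for _, b in pairs]
    return pd.DataFrame(
        {
            "hap_id_1": [a for a, _ in pairs],
            "hap_id_2": [b for _, b in pairs],
            "individual_1": [groups.individual_of(a) for a, _ in pairs],
            "individual_2": [groups.individual_of(b) for _, b in pairs],
            "group_1": [groups.group_of(a) for a, _ in pairs],
            "group_2": [groups.group_of(b) for _, b in pairs],
            "chromosome": m.chromosome,
            "n_sites": m.n_sites,
            "homozygosity": hom[i1, i2].astype(float),
        },
        columns=PAIR_COLUMNS,
    )


@dataclass
class DistributionSummary:
    """Location/shape summary of a pooled pair-homozygosity distribution."""

    label: str
    n_pairs: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "label": self.label,
            "n_pairs": self.n_pairs,
            "mean": self.mean,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": self.min,
            "max": self.max,
            "bin_edges": np.round(self.bin_edges, 10).tolist(),
            "bin_counts": self.bin_counts.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def summarize(
    table: pd.DataFrame,
    label: str = "",
    bin_width: float = 0.002,
    bin_range: tuple[float, float] = (0.7, 1.0),
) -> DistributionSummary:
    """Summary statistics and a fixed-width histogram of pooled pairs.

    The default 0.002-wide bins on [0.7, 1.0] resolve the distribution peaks
    of interest (outgroup pairs near 0.72, within-European pairs near 0.94);
    the range is widened automatically if the data fall outside it.
    """
    if table.empty:
        raise PanelError("cannot summarize an empty pair table")
    x = table["homozygosity"].to_numpy(float)
    lo = min(bin_range[0], np.floor(x.min() / bin_width) * bin_width)
    hi = max(bin_range[1], np.ceil(x.max() / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if not label:
        gp = sorted({tuple(sorted(t)) for t in zip(table["group_1"], table["group_2"])})
        label = ";".join("x".join(t) for t in gp)
    return DistributionSummary(
        label=label,
        n_pairs=len(x),
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(x.min()),
        max=float(x.max()),
        bin_edges=edges,
        bin_counts=counts,
    )


@dataclass
class ChromosomeCorrelation:
    """Cross-chromosome consistency of per-pair homozygosities."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n_pairs: int
    outlier_pairs: pd.DataFrame = field(repr=False)
    flagged_individuals: list[str] = field(default_factory=list)


def chromosome_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    outlier_sd: float = 3.0,
    flag_fraction: float = 0.9,
) -> ChromosomeCorrelation:
    """Pearson correlation of pair homozygosities on two chromosomes.

    Pairs are matched on their unordered haplotype ids.  Outlier pairs are
    those whose residual from the least-squares line exceeds ``outlier_sd``
    residual standard deviations — the analogue of the off-diagonal "clouds"
    that betray chromosome-specific introgression.  An individual is flagged
    when more than ``flag_fraction`` of its matched pairs are outliers.
    """
    key = ["hap_id_1", "hap_id_2"]
    merged = table_a.merge(table_b, on=key, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise PanelError(
            f"only {len(merged)} matched pairs; need at least 3 for a correlation"
        )
    x = merged["homozygosity_a"].to_numpy(float)
    y = merged["homozygosity_b"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # degenerate: identical values on one axis
        r, p, slope, intercept = 1.0, 0.0, 1.0, 0.0
        resid = y - x
    else:
        r, p = stats.pearsonr(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
    sd = resid.std()
    is_outlier = np.abs(resid) > outlier_sd * sd if sd > 0 else np.zeros(len(resid), bool)
    outliers = merged.loc[is_outlier, key + ["homozygosity_a", "homozygosity_b"]].copy()
    outliers["residual"] = resid[is_outlier]

    flagged = []
    inds = pd.concat(
        [
            merged.assign(ind=merged["individual_1_a"], out=is_outlier),
            merged.assign(ind=merged["individual_2_a"], out=is_outlier),
        ]
    )
    for ind, sub in inds.groupby("ind"):
        if sub["out"].mean() > flag_fraction:
            flagged.append(str(ind))
    return ChromosomeCorrelation(
        r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
        n_pairs=len(merged),
        outlier_pairs=outliers.reset_index(drop=True),
        flagged_individuals=sorted(flagged),
    )


def write_pair_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a pair table as TSV with fixed float formatting (reproducible bytes)."""
    p = Path(path)
    table.to_csv(p, sep="\t", index=False, float_format="%.8f")
    return p
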