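"""Chimeric haplotypes and grid-search introgression estimation.

A chimeric haplotype carries a fraction ``f`` of donor-group alleles on a
recipient-group background, emulating a genome introgressed by
hybridization and backcrossing.  Pairing chimeras against a reference group
yields a homozygosity distribution whose mean is, in expectation, the
linear mixture

    E[H(chimera(f), ref)] = (1 - f) E[H(recipient, ref)] + f E[H(donor, ref)]

regardless of whether the replaced sites are contiguous blocks or scattered
singletons.  Matching this family of distributions against the observed
distribution of a putatively admixed group versus the recipient group gives
a simple, assumption-light estimator of the admixture fraction
(:func:`estimate_admixture_fraction`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .homozygosity import PAIR_COLUMNS, pairwise_homozygosity_matrix
from .io_formats import GroupAssignment, HaplotypeMatrix, PanelError

MODES = ("contiguous_blocks", "random_sites")


@dataclass(frozen=True)
class ChimeraSpec:
    """Recipe for replacing a fraction ``f`` of a recipient's alleles.

    The replaced-site set is a deterministic function of
    ``(f, mode, n_blocks, seed, L)`` and is therefore shared by all
    recipient x donor pairs built from one spec; the pooled mean of the
    resulting distribution does not depend on which sites were chosen.
    ``round(f * L)`` uses round-half-to-even.
    """

    f: float
    mode: str = "contiguous_blocks"
    n_blocks: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise PanelError(f"replacement fraction f={self.f} outside [0, 1]")
        if self.mode not in MODES:
            raise PanelError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_blocks < 1:
            raise PanelError("n_blocks must be >= 1")

    def n_replaced(self, n_sites: int) -> int:
        return int(round(self.f * n_sites))

    def replaced_sites(self, n_sites: int) -> np.ndarray:
        """Sorted indices of the sites taken from the donor."""
        k = self.n_replaced(n_sites)
        if k == 0:
            return np.empty(0, dtype=np.int64)
        if k >= n_sites:
            return np.arange(n_sites, dtype=np.int64)
        rng = np.random.default_rng([self.seed, k, n_sites, MODES.index(self.mode)])
        if self.mode == "random_sites":
            return np.sort(rng.choice(n_sites, size=k, replace=False))
        # contiguous_blocks: n_blocks disjoint runs with sizes as equal as
        # possible, placed by distributing the leftover sites into the
        # n_blocks + 1 gaps around them.
        nb = min(self.n_blocks, k)
        sizes = np.full(nb, k // nb, dtype=np.int64)
        sizes[: k % nb] += 1
        gaps = rng.multinomial(n_sites - k, np.full(nb + 1, 1.0 / (nb + 1)))
        idx: list[np.ndarray] = []
        start = 0
        for g, s in zip(gaps[:-1], sizes):
            start += int(g)
            idx.append(np.arange(start, start + s))
            start += int(s)
        return np.concatenate(idx)


def make_chimera(
    recipient: np.ndarray, donor: np.ndarray, spec: ChimeraSpec
) -> np.ndarray:
    """One chimeric haplotype: donor alleles at the spec's replaced sites."""
    recipient = np.asarray(recipient)
    donor = np.asarray(donor)
    if recipient.shape != donor.shape or recipient.ndim != 1:
        raise PanelError("recipient and donor must be equal-length vectors")
    out = recipient.copy()
    idx = spec.replaced_sites(recipient.size)
    out[idx] = donor[idx]
    return out


@dataclass
class ChimeraPanel:
    """All recipient x donor chimeras for one spec.

    ``alleles`` has one row per (recipient, donor) ordered pair; ``records``
    holds the matching (recipient_id, donor_id) annotations.
    """

    alleles: np.ndarray
    records: list[tuple[str, str]]
    spec: ChimeraSpec

    @property
    def ids(self) -> list[str]:
        return [f"chimera({r}|{d})" for r, d in self.records]


def build_chimera_panel(
    m: HaplotypeMatrix,
    groups: GroupAssignment,
    recipient_group: str,
    donor_group: str,
    spec: ChimeraSpec,
) -> ChimeraPanel:
    """Construct chimeras for every recipient x donor haplotype pair."""
    rec_ids = groups.haplotypes_in(recipient_group)
    don_ids = groups.haplotypes_in(donor_group)
    row = {h: i for i, h in enumerate(m.haplotype_ids)}
    R = m.alleles[[row[h] for h in rec_ids]]
    D = m.alleles[[row[h] for h in don_ids]]
    idx = spec.replaced_sites(m.n_sites)
    n_r, n_d = len(rec_ids), len(don_ids)
    C = np.repeat(R, n_d, axis=0)
    C[:, idx] = np.tile(D, (n_r, 1))[:, idx]
    records = [(r, d) for r in rec_ids for d in don_ids]
    return ChimeraPanel(C, records, spec)


def chimera_distribution(
    m: HaplotypeMatrix,
    groups: GroupAssignment,
    recipient_group: str,
    donor_group: str,
    reference_group: str,
    spec: ChimeraSpec,
) -> pd.DataFrame:
    """Pair every chimera with every reference-group haplotype.

    The chimera's own recipient haplotype is excluded from the reference set
    (a chimera against its own backbone is trivially near-identical); the
    recipient individual's other haplotype is retained.
    """
    panel = build_chimera_panel(m, groups, recipient_group, donor_group, spec)
    ref_ids = groups.haplotypes_in(reference_group)
    row = {h: i for i, h in enumerate(m.haplotype_ids)}
    W = m.alleles[[row[h] for h in ref_ids]]
    hom = pairwise_homozygosity_matrix(panel.alleles, W).astype(float)
    chim_ids = panel.ids
    rows: dict[str, list] = {c: [] for c in PAIR_COLUMNS}
    for i, (rec, don) in enumerate(panel.records):
        for j, ref in enumerate(ref_ids):
            if ref == rec:
                continue
            rows["hap_id_1"].append(chim_ids[i])
            rows["hap_id_2"].append(ref)
            rows["individual_1"].append(f"{rec}|{don}")
            rows["individual_2"].append(groups.individual_of(ref))
            rows["group_1"].append("Chimera")
            rows["group_2"].append(reference_group)
            rows["chromosome"].append(m.chromosome)
            rows["n_sites"].append(m.n_sites)
            rows["homozygosity"].append(hom[i, j])
    if not rows["homozygosity"]:
        raise PanelError(
            f"reference group {reference_group!r} empty after excluding recipients"
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _chimera_mean(
    m: HaplotypeMatrix,
    groups: GroupAssignment,
    recipient_group: str,
    donor_group: str,
    reference_group: str,
    spec: ChimeraSpec,
) -> tuple[float, np.ndarray]:
    """Pooled mean (and flat values) of the chimera-vs-reference distribution."""
    panel = build_chimera_panel(m, groups, recipient_group, donor_group, spec)
    ref_ids = groups.haplotypes_in(reference_group)
    row = {h: i for i, h in enumerate(m.haplotype_ids)}
    W = m.alleles[[row[h] for h in ref_ids]]
    hom = pairwise_homozygosity_matrix(panel.alleles, W).astype(float)
    keep = np.ones(hom.shape, dtype=bool)
    ref_col = {h: j for j, h in enumerate(ref_ids)}
    for i, (rec, _don) in enumerate(panel.records):
        if rec in ref_col:
            keep[i, ref_col[rec]] = False
    vals = hom[keep]
    if vals.size == 0:
        raise PanelError(
            f"reference group {reference_group!r} empty after excluding recipients"
        )
    return float(vals.mean()), vals


@dataclass
class AdmixtureEstimate:
    """Result of the grid-search distribution-matching estimator."""

    f_hat: float
    grid: np.ndarray
    objective: np.ndarray
    target_mean: float
    objective_kind: str
    n_target_pairs: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "f_hat": self.f_hat,
            "objective_kind": self.objective_kind,
            "target_mean": self.target_mean,
            "n_target_pairs": self.n_target_pairs,
            "grid": np.round(self.grid, 10).tolist(),
            "objective": np.round(self.objective, 10).tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def estimate_admixture_fraction(
    m: HaplotypeMatrix,
    groups: GroupAssignment,
    recipient_group: str,
    donor_group: str,
    target_group: str,
    grid: np.ndarray | None = None,
    spec_template: ChimeraSpec | None = None,
    objective: str = "mean",
) -> AdmixtureEstimate:
    """Estimate the donor-allele fraction carried by ``target_group``.

    For every grid value ``f``, chimeras (donor on recipient background) are
    paired against the recipient group and the resulting distribution is
    compared with the observed target-vs-recipient distribution; ``f_hat``
    minimizes the discrepancy.  ``objective='mean'`` compares distribution
    means (the default — the mixture identity makes the mean a sufficient
    location statistic); ``objective='wasserstein'`` compares whole
    distributions by 1-Wasserstein distance.  Ties resolve to the smallest
    grid value.
    """
    from .homozygosity import all_pairs  # local import to avoid cycle at module load

    if grid is None:
        grid = np.round(np.arange(0.0, 0.5001, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise PanelError("grid must be non-empty with values in [0, 1]")
    if objective not in ("mean", "wasserstein"):
        raise PanelError(f"unknown objective {objective!r}")
    if spec_template is None:
        spec_template = ChimeraSpec(f=0.0)

    if target_group == recipient_group:
        target = all_pairs(m, groups, within=target_group)
    else:
        target = all_pairs(m, groups, between=(target_group, recipient_group))
    if target.empty:
        raise PanelError("empty target distribution")
    tvals = target["homozygosity"].to_numpy(float)
    tmean = float(tvals.mean())

    obj = np.empty(grid.size)
    for k, f in enumerate(grid):
        spec = replace(spec_template, f=float(f))
        mean_f, vals_f = _chimera_mean(
            m, groups, recipient_group, donor_group, recipient_group, spec
        )
        if objective == "mean":
            obj[k] = abs(mean_f - tmean)
        else:
            obj[k] = wasserstein_distance(vals_f, tvals)
    k_best = int(np.argmin(obj))
    return AdmixtureEstimate(
        f_hat=float(grid[k_best]),
        grid=grid,
        objective=obj,
        target_mean=tmean,
        objective_kind=objective,
        n_target_pairs=len(target),
    )
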