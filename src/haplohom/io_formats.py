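"""Phased haplotype panel I/O and site filtering.

The analysis unit throughout the package is a :class:`HaplotypeMatrix` — an
``H x L`` matrix of phased binary alleles for one chromosome, one row per
haplotype.  Every diploid individual contributes two rows, named
``<individual>_A`` and ``<individual>_B``.  Haplotypes are grouped into
populations (e.g. European wild boar vs. Asian commercial breeds) through a
:class:`GroupAssignment`.

Panels are read from phased VCF with :func:`read_phased_vcf`, which also
returns a :class:`SiteMask` describing missingness and per-site variant
class, and are reduced to the analysis-ready biallelic SNP panel with
:func:`filter_sites`: indels are dropped, multi-allelic sites are dropped,
and sites must be called in more than a threshold fraction of individuals
both overall and within every population group (strict ``>``, default 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

#: Canonical population groups used in the pig chromosome-1 analysis.
CANONICAL_GROUPS = (
    "Outgroup",
    "EuropeanLocal",
    "EuropeanIberian",
    "EuropeanCommercial",
    "EuropeanWild",
    "AsianCommercial",
    "AsianLocal",
    "AsianWild",
)

HAPLOTYPE_SUFFIXES = ("_A", "_B")


class PanelError(ValueError):
    """Raised for malformed panels, group maps, or VCF inputs."""


@dataclass
class HaplotypeMatrix:
    """Phased binary alleles for ``H`` haplotypes at ``L`` sites.

    Parameters
    ----------
    chromosome : str
        Chromosome label all sites belong to.
    positions : ndarray of int
        1-based bp coordinates, strictly increasing, length ``L``.
    alleles : ndarray of int8, shape (H, L)
        0 = reference allele, 1 = alternative.  Immediately after reading an
        unfiltered VCF, entries may exceed 1 (multi-allelic sites) or be 0 at
        masked positions; :meth:`validate` enforces the strict {0,1} /
        no-missing invariant that holds for filtered panels.
    haplotype_ids : list of str
        ``<individual>_A`` / ``<individual>_B`` identifiers, length ``H``.
    """

    chromosome: str
    positions: np.ndarray
    alleles: np.ndarray
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D (H x L) matrix")
        if self.alleles.shape != (len(self.haplotype_ids), len(self.positions)):
            raise PanelError(
                f"shape mismatch: alleles {self.alleles.shape}, "
                f"{len(self.haplotype_ids)} ids, {len(self.positions)} positions"
            )
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise PanelError("positions must be strictly increasing")
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            raise PanelError("duplicate haplotype ids")

    # -- basic accessors -------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def individuals(self) -> list[str]:
        """Individual ids in order of first appearance."""
        seen: dict[str, None] = {}
        for hap in self.haplotype_ids:
            seen.setdefault(individual_of_haplotype(hap), None)
        return list(seen)

    def row(self, haplotype_id: str) -> np.ndarray:
        return self.alleles[self.haplotype_ids.index(haplotype_id)]

    def subset_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.chromosome,
            self.positions[index],
            self.alleles[:, index],
            list(self.haplotype_ids),
        )

    def subset_haplotypes(self, ids: list[str]) -> "HaplotypeMatrix":
        rows = [self.haplotype_ids.index(h) for h in ids]
        return HaplotypeMatrix(
            self.chromosome, self.positions.copy(), self.alleles[rows], list(ids)
        )

    def validate(self) -> None:
        """Enforce the filtered-panel invariant: all alleles in {0, 1}."""
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise PanelError(f"{int(bad.sum())} alleles outside {{0,1}}")
        if self.n_haplotypes % 2:
            raise PanelError("odd number of haplotypes: individuals must be diploid")


def individual_of_haplotype(haplotype_id: str) -> str:
    for suf in HAPLOTYPE_SUFFIXES:
        if haplotype_id.endswith(suf):
            return haplotype_id[: -len(suf)]
    raise PanelError(f"haplotype id {haplotype_id!r} lacks an _A/_B suffix")


@dataclass
class GroupAssignment:
    """Mapping from haplotype id to (population group, source individual)."""

    group_by_haplotype: dict[str, str]
    individual_by_haplotype: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.group_by_haplotype) != set(self.individual_by_haplotype):
            raise PanelError("group and individual maps cover different haplotypes")
        per_ind: dict[str, str] = {}
        for hap, grp in self.group_by_haplotype.items():
            ind = self.individual_by_haplotype[hap]
            if per_ind.setdefault(ind, grp) != grp:
                raise PanelError(
                    f"individual {ind!r} assigned to multiple groups"
                )

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "GroupAssignment":
        """Build from ``haplotype_id -> group``; individuals from id suffixes."""
        return cls(
            dict(pairs),
            {h: individual_of_haplotype(h) for h in pairs},
        )

    def group_of(self, haplotype_id: str) -> str:
        try:
            return self.group_by_haplotype[haplotype_id]
        except KeyError:
            raise PanelError(f"haplotype {haplotype_id!r} has no group") from None

    def individual_of(self, haplotype_id: str) -> str:
        return self.individual_by_haplotype[haplotype_id]

    def haplotypes_in(self, group: str) -> list[str]:
        ids = sorted(h for h, g in self.group_by_haplotype.items() if g == group)
        if not ids:
            raise PanelError(f"unknown or empty group {group!r}")
        return ids

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_by_haplotype.values()))

    def validate_against(self, m: HaplotypeMatrix) -> None:
        missing = [h for h in m.haplotype_ids if h not in self.group_by_haplotype]
        if missing:
            raise PanelError(f"haplotypes without group assignment: {missing}")

    # -- TSV interchange (haplotype_id, individual_id, group) ------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupAssignment":
        groups: dict[str, str] = {}
        inds: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PanelError(f"group map line needs 3 columns: {line!r}")
            hap, ind, grp = fields
            groups[hap] = grp
            inds[hap] = ind
        return cls(groups, inds)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["#haplotype_id\tindividual_id\tgroup"]
        for hap in sorted(self.group_by_haplotype):
            lines.append(
                f"{hap}\t{self.individual_by_haplotype[hap]}\t{self.group_by_haplotype[hap]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SiteMask:
    """Per-site/per-haplotype missingness and variant class for a raw panel."""

    missing: np.ndarray  # (H, L) bool — allele not confidently phased/called
    is_indel: np.ndarray  # (L,) bool
    is_multiallelic: np.ndarray  # (L,) bool

    def subset_sites(self, index: np.ndarray) -> "SiteMask":
        return SiteMask(
            self.missing[:, index], self.is_indel[index], self.is_multiallelic[index]
        )


@dataclass
class FilterParams:
    """Site-retention rules for building the analysis panel.

    Call-rate thresholds are strict (a site must be called in *more than*
    the given fraction of individuals) and are applied per individual: a
    genotype counts as called only when both alleles are present and phased.
    """

    min_call_rate_overall: float = 0.8
    min_call_rate_per_group: float = 0.8
    biallelic_only: bool = True
    missing_policy: str = "error"  # or "major_allele_fill"

    def __post_init__(self) -> None:
        for v in (self.min_call_rate_overall, self.min_call_rate_per_group):
            if not 0 < v <= 1:
                raise PanelError("call-rate thresholds must be in (0, 1]")
        if self.missing_policy not in ("error", "major_allele_fill"):
            raise PanelError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class FilterReport:
    """Sites removed per rule, in application order."""

    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def to_tsv(self, path: str | Path) -> None:
        lines = ["#rule\tsites_removed"]
        lines += [f"{rule}\t{n}" for rule, n in self.counts.items()]
        lines.append(f"retained\t{self.n_output}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path, groups: GroupAssignment
) -> list[tuple[HaplotypeMatrix, SiteMask]]:
    """Read a sorted phased VCF into one (matrix, mask) pair per chromosome.

    Genotypes must be diploid.  Unphased heterozygous and half-missing
    genotypes are recorded in the missingness mask rather than dropped;
    unphased homozygous calls are accepted as-is since phase carries no
    information for them.

    Raises
    ------
    PanelError
        If a VCF sample has no group assignment, or a genotype is not diploid.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    known = set(groups.individual_by_haplotype.values())
    offenders = [s for s in samples if s not in known]
    if offenders:
        raise PanelError(f"VCF samples absent from group assignment: {offenders}")

    hap_ids = [f"{s}{suf}" for s in samples for suf in HAPLOTYPE_SUFFIXES]
    per_chrom: dict[str, dict[str, list]] = {}
    for v in vcf:
        store = per_chrom.setdefault(
            v.CHROM, {"pos": [], "cols": [], "miss": [], "indel": [], "multi": []}
        )
        alts = [a for a in (v.ALT or [])]
        is_indel = len(v.REF) != 1 or any(
            len(a) != 1 or a.startswith("<") or a == "*" for a in alts
        )
        col = np.zeros(2 * len(samples), dtype=np.int8)
        miss = np.zeros(2 * len(samples), dtype=bool)
        for i, gt in enumerate(v.genotypes):
            if len(gt) != 3:
                raise PanelError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            a0, a1, phased = gt
            if a0 < 0 or a1 < 0:
                miss[2 * i] = miss[2 * i + 1] = True
                col[2 * i] = max(a0, 0)
                col[2 * i + 1] = max(a1, 0)
            elif not phased and a0 != a1:
                # heterozygous without phase: haplotype assignment unknown
                miss[2 * i] = miss[2 * i + 1] = True
            else:
                col[2 * i], col[2 * i + 1] = a0, a1
        store["pos"].append(v.POS)
        store["cols"].append(col)
        store["miss"].append(miss)
        store["indel"].append(is_indel)
        store["multi"].append(len(alts) > 1)

    out = []
    for chrom, store in per_chrom.items():
        L = len(store["pos"])
        alleles = (
            np.stack(store["cols"], axis=1) if L else np.zeros((len(hap_ids), 0), np.int8)
        )
        missing = (
            np.stack(store["miss"], axis=1) if L else np.zeros((len(hap_ids), 0), bool)
        )
        m = HaplotypeMatrix(chrom, np.array(store["pos"], np.int64), alleles, hap_ids)
        mask = SiteMask(missing, np.array(store["indel"], bool), np.array(store["multi"], bool))
        out.append((m, mask))
    return out


def read_single_chromosome(
    path: str | Path, groups: GroupAssignment
) -> tuple[HaplotypeMatrix, SiteMask]:
    """Read a VCF expected to hold exactly one chromosome."""
    panels = read_phased_vcf(path, groups)
    if len(panels) != 1:
        raise PanelError(
            f"expected a single chromosome, found {len(panels)}: "
            f"{[m.chromosome for m, _ in panels]}"
        )
    return panels[0]


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def filter_sites(
    m: HaplotypeMatrix,
    mask: SiteMask,
    params: FilterParams,
    groups: GroupAssignment,
) -> tuple[HaplotypeMatrix, FilterReport]:
    """Reduce a raw panel to the analysis-ready biallelic SNP panel.

    Rules are applied in order — indel removal, multi-allelic removal,
    overall call rate, per-group call rate — and a site removed by one rule
    is not counted again by later ones.  Residual missing alleles in
    retained sites are handled per ``params.missing_policy``.
    """
    groups.validate_against(m)
    if mask.missing.shape != m.alleles.shape:
        raise PanelError("missingness mask not aligned with matrix")

    inds = m.individuals
    ind_rows = {
        ind: [m.haplotype_ids.index(ind + s) for s in HAPLOTYPE_SUFFIXES]
        for ind in inds
    }
    # genotype called <=> both alleles unmasked
    called = np.stack(
        [~mask.missing[rows[0]] & ~mask.missing[rows[1]] for rows in ind_rows.values()]
    )  # (N_ind, L)

    keep = np.ones(m.n_sites, dtype=bool)
    report = FilterReport(n_input=m.n_sites)

    def apply(rule: str, bad: np.ndarray) -> None:
        removed = bad & keep
        report.counts[rule] = int(removed.sum())
        keep[removed] = False

    apply("indel", mask.is_indel)
    if params.biallelic_only:
        apply("multiallelic", mask.is_multiallelic | (m.alleles > 1).any(axis=0))
    else:
        report.counts["multiallelic"] = 0
    apply("overall_call_rate", called.mean(axis=0) <= params.min_call_rate_overall)

    group_bad = np.zeros(m.n_sites, dtype=bool)
    ind_list = list(ind_rows)
    for grp in groups.groups:
        sel = [i for i, ind in enumerate(ind_list) if _group_of_individual(groups, ind) == grp]
        if sel:
            group_bad |= called[sel].mean(axis=0) <= params.min_call_rate_per_group
    apply("group_call_rate", group_bad)

    idx = np.flatnonzero(keep)
    out = m.subset_sites(idx)
    out_missing = mask.missing[:, idx]
    if out_missing.any():
        if params.missing_policy == "error":
            sites = m.positions[idx][out_missing.any(axis=0)]
            raise PanelError(
                f"residual missing alleles at {len(sites)} retained sites "
                f"(first few positions: {sites[:5].tolist()}); re-run with "
                "missing_policy='major_allele_fill' or impute upstream"
            )
        _fill_major_allele(out, out_missing, groups)
    report.n_output = out.n_sites
    out.validate()
    return out, report


def _group_of_individual(groups: GroupAssignment, individual: str) -> str:
    for hap, ind in groups.individual_by_haplotype.items():
        if ind == individual:
            return groups.group_by_haplotype[hap]
    raise PanelError(f"individual {individual!r} has no group")


def _fill_major_allele(
    m: HaplotypeMatrix, missing: np.ndarray, groups: GroupAssignment
) -> None:
    """Replace masked alleles with the group-major allele (ties -> 0)."""
    warnings.warn(
        "filling missing alleles with group-major allele; the source study "
        "imputed with Beagle, which this fill does not emulate",
        stacklevel=3,
    )
    hap_groups = np.array([groups.group_of(h) for h in m.haplotype_ids])
    for grp in np.unique(hap_groups):
        rows = np.flatnonzero(hap_groups == grp)
        sub_missing = missing[rows]
        if not sub_missing.any():
            continue
        sub = m.alleles[rows].astype(float)
        sub[sub_missing] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN columns
            grp_mean = np.nanmean(sub, axis=0)
        major = (np.nan_to_num(grp_mean) > 0.5).astype(np.int8)
        for r in rows:
            cols = np.flatnonzero(missing[r])
            m.alleles[r, cols] = major[cols]


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

def write_phased_vcf(
    m: HaplotypeMatrix, groups: GroupAssignment, path: str | Path
) -> Path:
    """Write a filtered panel as a minimal phased VCF 4.2 file.

    Alleles are abstract (REF written as ``A``, ALT as ``C``); the round trip
    ``read_phased_vcf(write_phased_vcf(m))`` reproduces the matrix exactly.
    """
    m.validate()
    groups.validate_against(m)
    inds = m.individuals
    rows = {
        ind: tuple(m.haplotype_ids.index(ind + s) for s in HAPLOTYPE_SUFFIXES)
        for ind in inds
    }
    length = int(m.positions[-1]) if m.n_sites else 1
    lines = [
        "##fileformat=VCFv4.2",
        "##source=haplohom",
        f"##contig=<ID={m.chromosome},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds),
    ]
    for j in range(m.n_sites):
        gts = "\t".join(
            f"{m.alleles[a, j]}|{m.alleles[b, j]}" for a, b in rows.values()
        )
        lines.append(
            f"{m.chromosome}\t{m.positions[j]}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}"
        )
    p = Path(path)
    p.write_text("\n".join(lines) + "\n")
    return p
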