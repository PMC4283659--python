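"""Calibrated synthetic phased-haplotype panels.

The generator emulates the statistical structure the homozygosity analyses
assume: a set of populations drifting independently from one ancestral
allele-frequency pool (Balding–Nichols model), among them a strongly
bottlenecked European wild group and more diverse Asian groups; an admixed
"commercial" group whose haplotypes carry a known fraction ``true_f`` of
donor-population alleles on a wild-population background; an optional
deeply diverged outgroup; and optional inbred individuals whose two
haplotypes share long identical segments (long ROH).

Under Balding–Nichols with drift coefficient ``F`` around an ancestral
frequency p̄ with E[p̄(1−p̄)] = θ, expected pair homozygosity has closed
forms::

    within one population       1 − 2(1−F)θ
    between two populations     1 − 2θ           (F-independent)

so the generator can be calibrated exactly to target group-level means by
inverting these expressions (:func:`calibrate`): θ from the between-clade
target, one F per group from its within-group target.  The admixed group's
expectations are the ``f``-weighted mixtures of its source populations'.

Ancestral frequencies are drawn from a symmetric Beta(a, a) with
``a = 2θ / (1 − 4θ)``, which gives E[p̄(1−p̄)] = θ exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chimera import ChimeraSpec, make_chimera
from .io_formats import (
    CANONICAL_GROUPS,
    GroupAssignment,
    HaplotypeMatrix,
    PanelError,
    write_phased_vcf,
)

#: Short per-group prefixes used in synthetic haplotype ids.
GROUP_CODES = {
    "Outgroup": "OUT",
    "EuropeanLocal": "EUL",
    "EuropeanIberian": "EUI",
    "EuropeanCommercial": "EUC",
    "EuropeanWild": "EUW",
    "AsianCommercial": "ASC",
    "AsianLocal": "ASL",
    "AsianWild": "ASW",
}


@dataclass
class CalibrationTargets:
    """Group-level expected homozygosities the generator must reproduce."""

    within_group: dict[str, float]
    between_clade: float = 0.825

    def __post_init__(self) -> None:
        vals = [self.between_clade, *self.within_group.values()]
        if any(not 0.5 < v < 1.0 for v in vals):
            raise PanelError("calibration targets must lie in (0.5, 1.0)")
        if any(v < self.between_clade for v in self.within_group.values()):
            raise PanelError(
                "within-group targets must be >= the between-clade target"
            )


#: Printed group means the default generator is calibrated to: within
#: European wild 0.941, within Asian wild 0.84 (reused for the other Asian
#: groups, whose within-group means are not printed), between clades 0.825.
DEFAULT_TARGETS = CalibrationTargets(
    within_group={
        "EuropeanWild": 0.941,
        "AsianWild": 0.84,
        "AsianCommercial": 0.84,
        "AsianLocal": 0.84,
    },
    between_clade=0.825,
)

DEFAULT_SAMPLE_SIZES = {
    "EuropeanWild": 40,
    "AsianCommercial": 40,
    "EuropeanCommercial": 40,
    "AsianWild": 20,
    "Outgroup": 4,
}


def _drift_from_within(theta: float, within: float) -> float:
    return 1.0 - (1.0 - within) / (2.0 * theta)


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic panel.

    ``seed`` is mandatory; every stochastic step derives its own generator
    deterministically from (seed, purpose token), so panels are reproducible
    and individual groups are insensitive to the sizes of others.
    """

    seed: int
    L: int = 50_000
    position_step: int = 600
    theta_anc: float = 0.0875
    F_by_population: dict[str, float] = field(default_factory=dict)
    sample_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    true_f: float = 0.20
    admixed_group: str = "EuropeanCommercial"
    recipient_population: str = "EuropeanWild"
    donor_population: str = "AsianCommercial"
    ld_block_sites: int = 0
    block_redraw_prob: float = 0.5
    inbred_pairs: list[tuple[str, float]] = field(default_factory=list)
    outgroup_divergence: float = 0.3
    chimera_n_blocks: int = 10
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_anc <= 0.25:
            raise PanelError("theta_anc must be in (0, 0.25]")
        if not self.F_by_population:
            t = self.theta_anc
            self.F_by_population = {
                g: _drift_from_within(t, w)
                for g, w in DEFAULT_TARGETS.within_group.items()
            }
            self.F_by_population["Outgroup"] = 0.2
        for g, F in self.F_by_population.items():
            if not 0.0 <= F < 1.0:
                raise PanelError(f"drift coefficient for {g!r} must be in [0, 1)")
        if not 0.0 <= self.true_f <= 1.0:
            raise PanelError("true_f must be in [0, 1]")
        if not 0.0 <= self.outgroup_divergence < 1.0:
            raise PanelError("outgroup_divergence must be in [0, 1)")
        for g, n in self.sample_sizes.items():
            if n < 0:
                raise PanelError(f"negative sample size for {g!r}")
            if n % 2:
                raise PanelError(f"sample size for {g!r} must be even (diploids)")
        if self.L < 1 or self.position_step < 1:
            raise PanelError("L and position_step must be positive")

    def rng(self, *tokens) -> np.random.Generator:
        """Deterministic sub-generator for one named purpose.

        The chromosome label is part of the stream identity, so the same
        seed yields independent sites (but the same individuals) on
        different chromosomes.
        """
        h = zlib.crc32("|".join(map(str, (self.chromosome, *tokens))).encode())
        return np.random.default_rng([int(self.seed), int(h)])


def calibrate(
    targets: CalibrationTargets = DEFAULT_TARGETS, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Invert the closed-form homozygosities into a generator config.

    θ comes from the between-clade target and one drift coefficient per
    group from its within-group target, so
    ``expected_homozygosity(calibrate(t)) == t`` exactly.
    """
    theta = (1.0 - targets.between_clade) / 2.0
    F = {g: _drift_from_within(theta, w) for g, w in targets.within_group.items()}
    F.setdefault("Outgroup", 0.2)
    F.update(overrides.pop("F_by_population", {}))
    return GeneratorConfig(
        seed=seed, theta_anc=theta, F_by_population=F, **overrides
    )


# ---------------------------------------------------------------------------
# Frequency and haplotype sampling
# ---------------------------------------------------------------------------

def sample_ancestral_frequencies(
    theta_anc: float, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-site ancestral frequencies p̄ with E[p̄(1−p̄)] = theta_anc."""
    if not 0.0 < theta_anc <= 0.25:
        raise PanelError("theta_anc must be in (0, 0.25]")
    if theta_anc == 0.25:
        return np.full(L, 0.5)
    a = 2.0 * theta_anc / (1.0 - 4.0 * theta_anc)
    return rng.beta(a, a, size=L)


def drift_frequencies(
    p_bar: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding–Nichols daughter-population frequencies around p̄."""
    if F >= 1.0:
        raise PanelError("drift coefficient F must be < 1")
    if F == 0.0:
        return np.asarray(p_bar, dtype=float).copy()
    p_bar = np.asarray(p_bar, dtype=float)
    ratio = (1.0 - F) / F
    interior = (p_bar > 0.0) & (p_bar < 1.0)
    out = p_bar.copy()  # fixed sites stay fixed
    out[interior] = rng.beta(p_bar[interior] * ratio, (1.0 - p_bar[interior]) * ratio)
    return out


def sample_population_frequencies(
    theta_anc: float, F: float, L: int, seed: int
) -> np.ndarray:
    """Draw ancestral frequencies, then drift them into one population."""
    rng = np.random.default_rng(seed)
    return drift_frequencies(sample_ancestral_frequencies(theta_anc, L, rng), F, rng)


def sample_haplotypes(
    freqs: np.ndarray,
    n: int,
    ld_block_sites: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    block_redraw_prob: float = 0.5,
) -> np.ndarray:
    """``n`` haplotypes from per-site frequencies, optionally with block LD.

    With ``ld_block_sites == 0`` every site of every haplotype is an
    independent Bernoulli draw.  Otherwise each new haplotype is assembled
    block by block: with probability ``block_redraw_prob`` a block is drawn
    fresh from the frequencies, else it is copied from a uniformly chosen
    earlier haplotype — inducing linkage disequilibrium while preserving the
    per-site frequencies in expectation.
    """
    if n < 1:
        raise PanelError("need n >= 1 haplotypes")
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    L = freqs.size
    if ld_block_sites <= 0:
        return (rng.random((n, L)) < freqs).astype(np.int8)
    haps = np.empty((n, L), dtype=np.int8)
    haps[0] = (rng.random(L) < freqs).astype(np.int8)
    starts = np.arange(0, L, ld_block_sites)
    for i in range(1, n):
        fresh = (rng.random(L) < freqs).astype(np.int8)
        redraw = rng.random(starts.size) < block_redraw_prob
        sources = rng.integers(0, i, size=starts.size)
        hap = np.empty(L, dtype=np.int8)
        for b, s in enumerate(starts):
            sl = slice(s, min(s + ld_block_sites, L))
            hap[sl] = fresh[sl] if redraw[b] else haps[sources[b], sl]
        haps[i] = hap
    return haps


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------

def expected_homozygosity(
    config: GeneratorConfig, group_a: str, group_b: str
) -> float:
    """Closed-form expected pair homozygosity between two groups.

    Within a population: ``1 − 2(1−F)θ``.  Between two distinct populations
    drifting from the shared ancestor: ``1 − 2θ``.  Outgroup pairs mix in a
    fraction ``outgroup_divergence`` of sites with independently redrawn
    ancestral frequency (expected agreement 1/2).  The admixed group's
    expectations are ``true_f``-weighted mixtures of its sources' — the
    within-admixed value treats the two haplotypes' replaced-site sets as
    independent, which holds approximately for randomly placed blocks.
    """
    theta = config.theta_anc
    between = 1.0 - 2.0 * theta

    def known(g: str) -> None:
        if g not in GROUP_CODES:
            raise PanelError(f"undefined group {g!r}")
        if g != config.admixed_group and g != "Outgroup" and g not in config.F_by_population:
            raise PanelError(f"no drift coefficient configured for {g!r}")

    known(group_a)
    known(group_b)

    def within(g: str) -> float:
        return 1.0 - 2.0 * (1.0 - config.F_by_population[g]) * theta

    def outgroup_cross() -> float:
        m = config.outgroup_divergence
        return (1.0 - m) * between + m * 0.5

    f = config.true_f
    adx, rec, don = (
        config.admixed_group,
        config.recipient_population,
        config.donor_population,
    )

    def vs_admixed(other: str) -> float:
        # mixture over which source contributed the admixed allele
        part_rec = within(rec) if other == rec else _plain(rec, other)
        part_don = within(don) if other == don else _plain(don, other)
        return (1.0 - f) * part_rec + f * part_don

    def _plain(g1: str, g2: str) -> float:
        if "Outgroup" in (g1, g2) and g1 != g2:
            return outgroup_cross()
        return within(g1) if g1 == g2 else between

    if group_a == adx and group_b == adx:
        return (
            (1.0 - f) ** 2 * within(rec)
            + 2.0 * f * (1.0 - f) * between
            + f**2 * within(don)
        )
    if group_a == adx:
        return vs_admixed(group_b)
    if group_b == adx:
        return vs_admixed(group_a)
    return _plain(group_a, group_b)


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def build_panel(
    config: GeneratorConfig,
) -> tuple[HaplotypeMatrix, GroupAssignment, dict]:
    """Generate a phased multi-group panel plus its ground-truth record.

    Non-admixed groups are sampled from their Balding–Nichols population
    frequencies.  The admixed group's haplotypes are chimeras of fresh
    recipient-population haplotypes with fresh donor-population haplotypes
    at fraction ``true_f`` (contiguous blocks, one sub-seeded replaced-site
    set per haplotype).  Inbred individuals are made by copying a contiguous
    shared segment between an individual's two haplotypes.
    """
    L = config.L
    positions = 1 + np.arange(L, dtype=np.int64) * config.position_step
    p_bar = sample_ancestral_frequencies(config.theta_anc, L, config.rng("ancestral"))

    active = [
        g for g in CANONICAL_GROUPS if config.sample_sizes.get(g, 0) > 0
    ]
    needs_sources = config.admixed_group in active
    freq_groups = {g for g in active if g != config.admixed_group}
    if needs_sources:
        if config.sample_sizes.get(config.donor_population, 0) == 0 and (
            config.donor_population not in config.F_by_population
        ):
            raise PanelError(
                f"admixed group {config.admixed_group!r} requested but donor "
                f"population {config.donor_population!r} is undefined"
            )
        freq_groups |= {config.recipient_population, config.donor_population}

    freqs: dict[str, np.ndarray] = {}
    for g in sorted(freq_groups):
        if g not in config.F_by_population:
            raise PanelError(f"no drift coefficient configured for {g!r}")
        rng = config.rng("freqs", g)
        anc = p_bar
        if g == "Outgroup":
            redrawn = sample_ancestral_frequencies(config.theta_anc, L, rng)
            anc = np.where(
                rng.random(L) < config.outgroup_divergence, redrawn, p_bar
            )
        freqs[g] = drift_frequencies(anc, config.F_by_population[g], rng)

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    group_of: dict[str, str] = {}
    for g in active:
        n = config.sample_sizes[g]
        if g == config.admixed_group:
            rng = config.rng("admixed")
            rec = sample_haplotypes(
                freqs[config.recipient_population], n, config.ld_block_sites,
                rng=rng, block_redraw_prob=config.block_redraw_prob,
            )
            don = sample_haplotypes(
                freqs[config.donor_population], n, config.ld_block_sites,
                rng=rng, block_redraw_prob=config.block_redraw_prob,
            )
            haps = np.stack(
                [
                    make_chimera(
                        rec[i],
                        don[i],
                        ChimeraSpec(
                            f=config.true_f,
                            mode="contiguous_blocks",
                            n_blocks=config.chimera_n_blocks,
                            seed=int(config.rng("chimera", g, i).integers(2**31)),
                        ),
                    )
                    for i in range(n)
                ]
            )
        else:
            haps = sample_haplotypes(
                freqs[g], n, config.ld_block_sites,
                rng=config.rng("haps", g),
                block_redraw_prob=config.block_redraw_prob,
            )
        code = GROUP_CODES[g]
        for i in range(n):
            hap_id = f"{code}{i // 2 + 1:02d}_{'AB'[i % 2]}"
            ids.append(hap_id)
            group_of[hap_id] = g
        blocks.append(haps)

    alleles = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, L), np.int8)
    m = HaplotypeMatrix(config.chromosome, positions, alleles, ids)
    ga = GroupAssignment.from_pairs(group_of)

    inbred_truth = []
    for grp, shared in config.inbred_pairs:
        if not 0.0 <= shared <= 1.0:
            raise PanelError("inbred shared fraction must be in [0, 1]")
        ind = _first_uninbred_individual(ga, grp, {r["individual"] for r in inbred_truth})
        rng = config.rng("inbred", grp, ind)
        n_shared = int(round(shared * L))
        start = int(rng.integers(0, L - n_shared + 1)) if n_shared < L else 0
        a = ids.index(ind + "_A")
        b = ids.index(ind + "_B")
        m.alleles[b, start : start + n_shared] = m.alleles[a, start : start + n_shared]
        inbred_truth.append(
            {"individual": ind, "group": grp, "shared_fraction": shared, "start": start}
        )

    truth = {
        "seed": config.seed,
        "theta_anc": config.theta_anc,
        "F_by_population": dict(config.F_by_population),
        "sample_sizes": {g: config.sample_sizes[g] for g in active},
        "true_f": config.true_f,
        "admixed_group": config.admixed_group,
        "recipient_population": config.recipient_population,
        "donor_population": config.donor_population,
        "ld_block_sites": config.ld_block_sites,
        "outgroup_divergence": config.outgroup_divergence,
        "inbred": inbred_truth,
        "L": L,
        "chromosome": config.chromosome,
    }
    return m, ga, truth


def _first_uninbred_individual(
    ga: GroupAssignment, group: str, taken: set[str]
) -> str:
    for hap in ga.haplotypes_in(group):
        ind = ga.individual_of(hap)
        if ind not in taken:
            return ind
    raise PanelError(f"no individual left in {group!r} to make inbred")


def write_panel(
    m: HaplotypeMatrix,
    ga: GroupAssignment,
    truth: dict,
    out_dir: str | Path,
    prefix: str = "panel",
) -> dict[str, Path]:
    """Write VCF + group-map TSV + truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / f"{prefix}.vcf",
        "groups": out / f"{prefix}.groups.tsv",
        "truth": out / f"{prefix}.truth.json",
    }
    write_phased_vcf(m, ga, paths["vcf"])
    ga.to_tsv(paths["groups"])
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths
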