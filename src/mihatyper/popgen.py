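"""Mismatch probabilities and mismatch-count distributions under HWE.

Per locus, let p be the immunogenic-allele frequency and q = 1 - p.
Under Hardy-Weinberg equilibrium a random individual carries at least
one immunogenic allele with probability 1 - q^2 and is homozygous
non-immunogenic with probability q^2.  For an unrelated donor-recipient
pair the two genotypes are independent, so

    P_mm(unrelated) = (1 - q^2) * q^2,

with analytic maximum 1/4 at q^2 = 1/2.  Sibling pairs share parents:
conditional on the (HWE-distributed) parental genotypes the two
children are independent Mendelian draws, giving

    P_mm(sibling) = E[ h (1 - h) ],   h = (1 - g1/2)(1 - g2/2),

where g1, g2 are the parents' immunogenic-allele dosages.  Sharing
makes donor and recipient positively correlated, so the sibling
probability never exceeds the unrelated one.

Across the panel, per-locus mismatch indicators are treated as
independent Bernoulli variables; the number of mismatched loci K then
follows a Poisson-binomial distribution, computed exactly by sequential
convolution or empirically by seeded Monte-Carlo simulation (including
a genotype-level simulator that draws parents and children explicitly
and applies the same GvH rule as the pair reports).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError
from .panel import FrequencyTable, PanelDefinition

_SIM_CHUNK = 250_000  # iterations per vectorized chunk, bounds memory


def _check_prob(p: float, what: str = "frequency") -> None:
    if not 0.0 <= p <= 1.0:
        raise InputError(f"{what} {p} outside [0, 1]")


def pmm_unrelated(p_imm: float) -> float:
    """Per-locus mismatch probability for an unrelated pair: (1-q^2) q^2."""
    _check_prob(p_imm)
    q2 = (1.0 - p_imm) ** 2
    return (1.0 - q2) * q2


def pmm_sibling(p_imm: float) -> float:
    """Per-locus mismatch probability for a sibling pair.

    Exact enumeration over the 3 x 3 HWE parental genotype pairs; both
    children segregate independently given the parents.
    """
    _check_prob(p_imm)
    p = p_imm
    q = 1.0 - p
    dosage_prob = (q * q, 2.0 * p * q, p * p)  # parent carries 0, 1, 2 copies
    total = 0.0
    for g1 in range(3):
        for g2 in range(3):
            # h = P(child homozygous non-immunogenic | parents)
            h = (1.0 - g1 / 2.0) * (1.0 - g2 / 2.0)
            total += dosage_prob[g1] * dosage_prob[g2] * h * (1.0 - h)
    return total


@dataclass(frozen=True)
class MismatchProbability:
    """Per-locus mismatch probabilities for both pair kinds."""

    locus: str
    p_imm: float
    pmm_unrelated: float
    pmm_sibling: float


def per_locus_probabilities(
    freqs: FrequencyTable, panel: PanelDefinition
) -> list[MismatchProbability]:
    """Tabulate unrelated and sibling mismatch probabilities per panel locus."""
    out = []
    for name, p in zip(panel.locus_names, freqs.for_panel(panel)):
        out.append(
            MismatchProbability(
                locus=name,
                p_imm=p,
                pmm_unrelated=pmm_unrelated(p),
                pmm_sibling=pmm_sibling(p),
            )
        )
    return out


class Provenance(enum.Enum):
    EXACT_DP = "exact_dp"
    MONTE_CARLO = "monte_carlo"


@dataclass(frozen=True)
class CountDistribution:
    """Distribution of the number of mismatched loci K over 0..L."""

    pmf: np.ndarray
    provenance: Provenance
    n_iter: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if pmf.ndim != 1 or pmf.size == 0:
            raise InputError("count distribution must be a non-empty vector")
        if (pmf < 0).any() or abs(pmf.sum() - 1.0) > 1e-9:
            raise InputError("count distribution must be a probability vector")

    @property
    def n_loci(self) -> int:
        return self.pmf.size - 1

    @property
    def mean(self) -> float:
        return float(np.arange(self.pmf.size) @ self.pmf)

    @property
    def mode(self) -> int:
        """Most probable count; ties broken toward the smaller count."""
        return int(np.argmax(self.pmf))

    def p_at_least(self, k: int) -> float:
        return float(self.pmf[k:].sum())


def mismatch_distribution_exact(pmms: Sequence[float]) -> CountDistribution:
    """Poisson-binomial distribution of K by sequential convolution.

    Exact dynamic programming over independent per-locus Bernoulli
    indicators; O(L^2) and numerically exact at panel scale.
    """
    if len(pmms) == 0:
        raise InputError("no per-locus probabilities given")
    for p in pmms:
        _check_prob(p, "mismatch probability")
    pmf = np.array([1.0])
    for p in pmms:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return CountDistribution(pmf=pmf, provenance=Provenance.EXACT_DP)


def mismatch_distribution_simulated(
    pmms: Sequence[float], n_iter: int, seed: int
) -> CountDistribution:
    """Empirical distribution of K from seeded Bernoulli sampling.

    Retained alongside the exact method both for fidelity to
    simulation-based workflows and as an independent cross-check;
    reproducible under a fixed seed.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    for p in pmms:
        _check_prob(p, "mismatch probability")
    rng = np.random.default_rng(seed)
    probs = np.asarray(pmms, dtype=float)
    counts = np.zeros(len(pmms) + 1, dtype=np.int64)
    done = 0
    while done < n_iter:
        m = min(_SIM_CHUNK, n_iter - done)
        k = (rng.random((m, probs.size)) < probs).sum(axis=1)
        counts += np.bincount(k, minlength=probs.size + 1)
        done += m
    return CountDistribution(
        pmf=counts / n_iter,
        provenance=Provenance.MONTE_CARLO,
        n_iter=n_iter,
        seed=seed,
    )


def _simulate_locus_mismatches(
    p: float, n: int, rng: np.random.Generator, related: bool
) -> np.ndarray:
    """Boolean mismatch indicators for n pairs at one locus.

    Genotype-level mechanism: draw genotypes as immunogenic-allele
    dosages under HWE; siblings are generated by drawing two parents and
    segregating one allele from each parent per child.  A pair is
    mismatched when the recipient's dosage is >= 1 and the donor's is 0
    — the same GvH rule the pair reports apply.
    """
    if related:
        g_parent1 = rng.binomial(2, p, size=n)
        g_parent2 = rng.binomial(2, p, size=n)
        recipient = rng.binomial(1, g_parent1 / 2.0) + rng.binomial(1, g_parent2 / 2.0)
        donor = rng.binomial(1, g_parent1 / 2.0) + rng.binomial(1, g_parent2 / 2.0)
    else:
        recipient = rng.binomial(2, p, size=n)
        donor = rng.binomial(2, p, size=n)
    return (recipient >= 1) & (donor == 0)


def genotype_pair_simulator(
    freqs: FrequencyTable,
    panel: PanelDefinition,
    n_iter: int,
    seed: int,
    related: bool = True,
) -> tuple[CountDistribution, dict[str, float]]:
    """Simulate donor-recipient pairs genotype by genotype.

    Returns the empirical mismatch-count distribution together with the
    per-locus empirical mismatch rates (useful for cross-checking the
    closed-form probabilities).  ``related=True`` simulates siblings via
    shared parents; ``related=False`` draws two independent HWE
    genotypes per locus.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    probs = freqs.for_panel(panel)
    rng = np.random.default_rng(seed)
    n_loci = len(probs)
    counts = np.zeros(n_loci + 1, dtype=np.int64)
    locus_hits = np.zeros(n_loci, dtype=np.int64)
    done = 0
    while done < n_iter:
        m = min(_SIM_CHUNK, n_iter - done)
        mism = np.empty((m, n_loci), dtype=bool)
        for j, p in enumerate(probs):
            mism[:, j] = _simulate_locus_mismatches(p, m, rng, related)
        counts += np.bincount(mism.sum(axis=1), minlength=n_loci + 1)
        locus_hits += mism.sum(axis=0)
        done += m
    dist = CountDistribution(
        pmf=counts / n_iter,
        provenance=Provenance.MONTE_CARLO,
        n_iter=n_iter,
        seed=seed,
    )
    rates = {
        name: locus_hits[j] / n_iter for j, name in enumerate(panel.locus_names)
    }
    return dist, rates


def sibling_pair_simulator(
    freqs: FrequencyTable, panel: PanelDefinition, n_iter: int, seed: int
) -> tuple[CountDistribution, dict[str, float]]:
    """Genotype-level sibling-pair simulation (see genotype_pair_simulator)."""
    return genotype_pair_simulator(freqs, panel, n_iter, seed, related=True)


@dataclass(frozen=True)
class DistributionSummary:
    mode: int
    p_mode: float
    mean: float
    p_at_least_one: float

    @property
    def p_mode_percent(self) -> float:
        return 100.0 * self.p_mode

    @property
    def p_at_least_one_percent(self) -> float:
        return 100.0 * self.p_at_least_one


def summarize(dist: CountDistribution) -> DistributionSummary:
    """Headline numbers of a mismatch-count distribution."""
    return DistributionSummary(
        mode=dist.mode,
        p_mode=float(dist.pmf[dist.mode]),
        mean=dist.mean,
        p_at_least_one=dist.p_at_least(1),
    )
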