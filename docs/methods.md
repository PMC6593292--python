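# Methods

## Assay model

The panel genotypes 20 HLA-A\*02:01-restricted MiHAs: 19 non-synonymous
SNPs plus the UGT2B17 whole-gene deletion polymorphism. Loci are pooled
into 5 multiplex panels of 4, one hydrolysis-probe color channel per
locus (FAM, HEX, ROX, Cy5 → channels 1–4), with a beta-2-microglobulin
(B2M) internal amplification control on channel 5 (Cy5.5) of every
reaction. Each sample × panel combination is run in two wells that
differ only in their allele-specific primers (ASPs): one mix carries the
ASPs matching the reference SNP alleles, the other the alternative
alleles. The deletion locus and B2M use identical oligos in both wells.

Allele-specific priming is discriminative, not absolute: on a
mismatched template the ASP still extends eventually, just several
cycles later. The calling procedure therefore combines a positivity
threshold with a relative-lead rule.

## Calling procedure

Thresholds (all overridable via `CallingConfig` / CLI flags):

| parameter | default | unit | role |
| --- | --- | --- | --- |
| `positivity_cq` | 30.0 | cycles | reaction positive iff Cq < 30 |
| `hom_delta_cq` | 2.0 | cycles | lead that overrides het → homozygous |
| `control_delta_cq` | 1.5 | cycles | max B2M disagreement between paired wells |
| `min_rfu` | 300.0 | RFU | end-point fluorescence floor per readout |
| `max_cycles` | 40 | cycles | run length; later Cqs are input errors |

Order of evaluation per sample and panel: (1) each readout is
classified positive / negative / invalid — the RFU floor is checked
first and wins over any Cq; (2) the B2M gate passes iff both control
wells recorded a Cq, neither is invalid, and |ΔCq| < 1.5 (exactly 1.5
fails; the gate demands agreement, not positivity — a deliberate
reading, flagged for review, since only the agreement requirement is
specified for the control); (3) each SNP locus is called from its
REF/ALT reaction pair as in the README; both-positive with ΔCq exactly
2.0 counts as homozygous ("two or more cycles ahead"). Both-negative at
a SNP locus is a flagged no-call, never a genotype — only at the
deletion locus is double-negative informative (homozygous deletion).
Discordant deletion-locus replicates (one positive, one negative) are
called *present* with a `replicate_discordant` flag: a specific
amplification is positive evidence of the gene, and the conservative
direction for mismatch calling.

A control-gate failure voids only the four loci of its own panel, since
every panel pair carries its own B2M set. Calls are deterministic
functions of the input records.

The ΔCq override is intentionally redundant with the one-positive rule
when the lagging reaction falls beyond the positivity threshold; it
matters precisely when ASP cross-reaction crosses before 30 cycles.

## Mismatch rule

GvH-direction mismatch at a locus: the recipient carries ≥ 1 copy of
the in-vivo-immunogenic allele and the donor is homozygous for the
alternative allele; for the deletion locus, recipient gene-positive and
donor homozygous deleted. Any no-call on either side makes the locus
indeterminate: it is listed, warned about in the report footer, and
never counted in the total. Several panel loci may be immunogenic in
both directions (co-dominant); reverse-direction candidates (donor
carries the alternative allele, recipient homozygous immunogenic) are
reported as annotations only and never counted.

In the packaged 13-pair validation table the first-listed subject of
each pair is treated as the recipient. The source table does not label
roles explicitly; this orientation is the one that reproduces its
printed per-pair totals (verified by hand before being frozen into the
fixture test) and is surfaced here deliberately.

The "N/O" entry at the deletion locus of one validation donor is parsed
as "No" (homozygous deletion) with a `parsed_warning` flag — treated as
a typographic variant of "No"; the alternative reading "not obtained"
cannot be excluded, hence the warning rather than silent acceptance.

## Population statistics

With immunogenic-allele frequency *p* and *q* = 1 − *p*, Hardy–Weinberg
genotype probabilities give

* unrelated pairs: `P_mm = (1 − q²) · q²` — recipient carries the
  allele, independent donor homozygous for the alternative. The maximum
  is 1/4 at q² = 1/2 (p ≈ 0.293).
* sibling pairs: `P_mm = E[h(1 − h)]` with
  `h = (1 − g₁/2)(1 − g₂/2)`, the probability that a child of parents
  with immunogenic-allele dosages g₁, g₂ is homozygous non-immunogenic;
  the expectation runs over the 3 × 3 HWE parental genotype table and
  the two children are independent given the parents (this enumeration
  is equivalent to conditioning on 0/1/2 shared haplotypes identical by
  descent). At p = 0.5 this gives exactly 7/64 = 0.109375. Shared
  parentage correlates the siblings' genotypes, so the sibling
  probability never exceeds the unrelated one.

Across the panel, per-locus mismatch indicators are modeled as
independent Bernoulli draws — including the three co-located pairs of
loci on chromosomes 6, 11, 12 and 17, for which no linkage model is
applied because the published per-locus probabilities are marginal.
The mismatch count K then follows a Poisson-binomial distribution,
computed exactly by sequential convolution (O(L²), numerically exact at
L = 20; validated in tests against full 2^L enumeration up to L = 12
and against an independent library implementation). A seeded
Monte-Carlo path (Bernoulli sampling, and a genotype-level simulator
that draws parents and children explicitly and applies the same GvH
rule as the pair reports) is retained both for fidelity to
simulation-based workflows and as a cross-check; the default iteration
count of 10⁶ puts every bin within Monte-Carlo error of the exact
distribution while keeping runs in the seconds range. Distribution
modes are reported with ties broken toward the smaller count, for
determinism.

### Frequency inputs

Per-locus immunogenic-allele frequencies are user-supplied
(two-column TSV). The shipped demo table
(`data/european_freqs_synthetic.tsv`) is a **synthetic reconstruction**:
it inverts the panel's published unrelated mismatch probabilities
through `(1 − q²)q²`, taking the minor-immunogenic root of the
quadratic in q². That root reproduces the expected rare-allele
frequency at the panel's rarest locus (TRIM22, p ≈ 0.0097) and, pushed
through the sibling model and the exact count distribution, yields the
expected related-pair mode of 2 at 28.8% — but it is a demo fixture,
not an authoritative population reference.

## Synthetic data generator

`NoiseConfig` defaults describe a clean assay run:

| parameter | default | rationale |
| --- | --- | --- |
| `base_cq` | 24.0 cycles | specific reaction on ~80 ng genomic DNA |
| `cq_sd` | 0.3 cycles | replicate scatter |
| `het_shift` | 1.0 cycle | heterozygotes carry half the template per allele; one doubling ≈ one cycle |
| `nonspecific_delta_cq` | 4.9 cycles | allele-discrimination margin of a well-designed ASP; reactions pushed past `max_cycles` lose their crossing |
| `b2m_cq` | 21.0 cycles | abundant single-copy control target |
| `plateau_rfu_mean/sd` | 1500 / 200 RFU | bright end-point plateaus |
| artifact rates | 0 | opt-in failure injection |

Artifacts: *evaporation* delays one well of a pair (B2M and co-resident
targets) by 3.0 cycles, which trips the 1.5-cycle control gate;
*low RFU* crushes a single readout's plateau below the 300-RFU floor;
*dropout* is modeled as whole-well failure — every channel of the well,
B2M included, loses its crossing. The per-channel alternative was
rejected deliberately: dropping only the specific reaction would leave
the non-specific signal positive and silently flip the genotype,
whereas whole-well failure (missing mix, bad seal — the typical
physical cause) is always caught by the control gate. Under this model
every injected artifact surfaces as a flagged no-call, never a silent
miscall, which the test suite asserts across artifact classes.

What the generator does **not** emulate: amplification-curve kinetics
(no sigmoid model — only Cq and end-point RFU are produced), channel
cross-talk, primer-dimer artifacts, probe degradation, template
titration effects, and interfering rare SNPs in primer binding sites
(a known real-world failure mode of ASP-based assays). Passing tests on
synthetic plates therefore demonstrate that the calling logic inverts
the documented signal model, not that the assay is robust to every
laboratory failure mode.

Noise note: the two B2M control readouts of a pair are drawn
independently with `cq_sd` scatter, so their difference has standard
deviation `cq_sd·√2` ≈ 0.42 cycles and a ~4·10⁻⁴ chance per panel of
tripping the 1.5-cycle gate even without artifacts. That is a voided
panel, not an error; recovery tests accordingly assert 100% accuracy on
called loci plus a ≥ 99.5% call rate under default noise (and exact
recovery in the noise-free setting).

## Problem sizes and tolerances

Exact quantities (pair totals, Poisson-binomial pmf) are asserted to
printed precision or 10⁻¹² where analytically exact. Monte-Carlo
agreement is asserted bin-wise / rate-wise within 3 standard errors at
10⁶ iterations. Simulation-based tests use fixed seeds throughout;
recovery sweeps use 200 samples and pair-rate checks 3000 pairs, sizes
at which the binomial standard errors are comfortably inside the
asserted bounds.

## Known limitations

* The mismatch total is a count, not a clinical risk score; no
  GvHD/GvL interpretation, hematopoietic-expression filtering, or HLA
  typing verification is attempted.
* Cq values are taken as given from the instrument export; no
  baseline/threshold computation, curve-shape QC (beyond the B2M ΔCq
  gate), or melting analysis.
* Population statistics assume HWE, locus independence, and
  HLA-A\*02:01-positive pairs; no linkage disequilibrium or population
  structure corrections.
* The sibling model covers full siblings only (shared parents); other
  relatedness degrees would need their own kinship enumeration.
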