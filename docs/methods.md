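# Methods

## The genetic model

The *Se* locus of Asian rice lies inside a large presence-absence variation
(PAV). PAV-carrying haplotypes hold two adjacent genes: a **sporophytic
pollen killer** and a **gametophytic protector**. The killer is expressed by
the diploid parent and attacks gametes indiscriminately; the protector
rescues only the gametes that themselves carry it. A heterozygote between a
PAV-present haplotype ("E", killer + protector) and the PAV-absent japonica
haplotype ("T") therefore aborts its T-bearing pollen: the killer is active
in the sporophyte, and T gametes carry no protector.

`selocus.transmission` formalises this as follows. A genotype is a pair of
Se allele profiles (two independent booleans: functional killer, functional
protector) plus any unlinked transgene loci (gene ∈ {killer, protector},
dosage ∈ {0,1,2}, penetrance ∈ [0,1]). Gamete classes are enumerated by
independent Mendelian segregation (½ per heterozygous locus; transgenes are
strictly unlinked to Se and to each other). Each gamete's survival is

    viability = 1 − k_sex · A · (1 − P)

where `A` is the sporophyte's killer activity (1 if any Se allele carries a
functional killer, otherwise the largest penetrance among killer transgenes
present), `P` is the gamete's protection (1 if its Se allele carries a
functional protector, otherwise `1 − Π(1 − penetrance)` over carried
protector-transgene copies), and `k_sex` is the sex-specific killing
efficiency: `km` for pollen, `kf` for ovules. Defaults are **km = 1**
(complete male killing — no T transmission through T/E pollen) and
**kf = 0** (female distortion is milder and is left to be estimated from
data). The surviving-viability mass of the male pool is the predicted
pollen fertility: 0.50 for T/E, 0.75 for T/E with one hemizygous protector
transgene (the `(T,G)`, `(E,G)`, `(E,−)` classes survive out of four), 1.0
whenever the killer is inactive or every gamete is protected. A pool whose
mass is exactly zero raises `CompleteSterilityError` rather than returning
an empty distribution, so downstream crosses cannot silently renormalise.

Offspring distributions are the outer product of the female and male pools,
merged under canonical class keys: allele pairs joined in reverse
lexicographic order (the conventional `T/E`, never `E/T`) and transgene
genotypes rendered `G/G`, `G/-`, `-/-` in symbol order. Two useful
consequences, both tested: swapping the parents while swapping km↔kf leaves
the distribution unchanged, and km = kf = 0 reduces exactly to a Punnett
square (checked against an independent exact-fraction enumeration).

Female killing is modelled with the same protector logic as male killing
(kf applied to unprotected megagametophytes). Whether real ovule abortion
requires protector absence in the megagametophyte or tracks the T allele
itself is not established; for the crosses handled here (the female parent
heterozygous, the male tester homozygous protected) the two readings give
identical class probabilities, so the choice is untestable at this scope
and is flagged as a modelling assumption.

## Fertility phenotyping

Pollen fertility is measured as the stained fraction of ≥200 grains. In
segregating populations the distribution is bimodal — semi-sterile
heterozygotes near 50%, fertile homozygotes near 95% — with a valley in the
70–80% band. `selocus.fertility` applies the threshold rule with strict
inequalities: fraction < 0.70 → semi-sterile, > 0.80 → fertile, the closed
band (including its endpoints) → ambiguous. Ambiguous plants are excluded
from segregation-ratio tests (the band is genuinely unassigned under the
threshold rule) and the exclusion is logged. Histograms use right-open bins
partitioning [0,1] (the last bin closed so 1.0 is counted).

## Inference

`chisq_gof` is the plain Pearson statistic Σ(O−E)²/E with E = n·p, no
continuity correction (the standard choice for multi-class segregation
tables; whether the original analyses corrected is unstated, so this is an
explicit assumption). Zero-probability classes are excluded from the
statistic and from df = (#classes with p>0) − 1 − (#fitted parameters).
Critical values invert the chi-square survival function numerically
(regularized incomplete gamma under the hood): 3.84 at (df 1, α 0.05),
14.067 at (df 7, α 0.05).

`fit_transmission_params` maximises the joint multinomial log-likelihood of
one or more observed cross tables over the free subset of {km, kf}, with
the fixed parameter taken from each dataset's `base_params`. One free
parameter: dense grid (step 0.001) plus a bounded golden-section polish
around the best grid point. Two free: 0.02 joint grid plus four rounds of
coordinate-wise golden-section refinement. 95% confidence intervals come
from the profile likelihood (drop of 1.92 log units), with linear
interpolation between grid points for the crossing; for the joint fit the
profiles are at coarse-grid resolution. Boundary estimates (0 or 1) are
reported as-is with one-sided intervals. A parameter whose profile is flat
over the whole grid (e.g. km from a cross whose male parent produces only
protected gametes) is flagged non-identifiable with CI [0,1]. The canonical
worked example: a T/E female × E/E tester produces T/E and E/E offspring in
proportions (1−kf) : 1, so observed counts 54:74 give k̂f = 1 − 54/74 =
10/37 ≈ 0.270, and the closed form is matched by the numeric fit to <1e−4.

`lrt_distortion` compares the fitted model to the Mendelian null
(km = kf = 0); because the null sits on the boundary of the parameter
space, the chi-square(df = #freed) reference is conservative. Multiple
testing is out of scope (single planned tests).

## Haplotype typing

Typing mirrors the bench assays on sequence alone:

* **PAV presence** — in-silico PCR: both strand assignments of the primer
  pair are scanned for exact convergent matches within a product-length
  bound; an empty product list is the PAV-absent call. Primer matching is
  exact by default (a max-mismatch option exists); intervals are 0-based
  half-open on the forward strand, and the assay is strand-invariant and
  position-covariant by construction (both properties tested).
* **ORF integrity** — each CDS is located by an exact flanking anchor
  k-mer, extracted at the reference CDS length, and translated with the
  standard code stopping at the first stop codon. A product matching the
  reference length (596 aa killer, 523 aa protector) is full-length;
  shorter (premature stop) is truncated; a missing anchor is absent.
* **Promoter deletion** — the 369-bp promoter marker is flanked by two
  anchor k-mers; flanks separated by exactly the marker length → intact,
  directly adjacent → promoter-deleted, anything else is an error.

Anchor-based detection is exact-match and therefore adequate only for the
synthetic data this package generates; divergent real genomes would need
alignment-based anchoring. This is a stated limitation, not a fallback.

Type assignment is a total, ordered, first-match-wins rule table (shipped
default, user-overridable via simple field-match config): no PAV → noPAV;
African-complex lineage → Type 4; *O. meridionalis* → Type 5; full-length
killer → Type 1; intact protector → Type 3 (the neutral allele: no killing
in any cross); everything else (promoter-deleted or truncated protector
with a dead killer) → Type 2. Lineage is metadata, not inferred from
sequence, because Types 4 and 5 are defined by species, not by sequence
features. Cross-compatibility prediction reduces each call to an allele
profile — killer = full-length ORF3; protector = intact **or**
promoter-deleted ORF4 (the deletion lowers expression, but its protection
is treated as sufficient by default and the set is configurable) — and
returns the F1's predicted pollen fertility: Type1 × noPAV → 0.50,
Type3 × noPAV → 1.0.

## Synthetic data

`selocus.synth` generates every input with known truth labels.

**Reference locus.** Layout: spacer — ORF1 analogue (250 aa) — spacer —
[PAV insert: spacer — killer CDS (1791 nt = 596 aa + stop) — spacer —
promoter (120 nt + 369-nt marker + 80 nt) — protector CDS (1572 nt =
523 aa + stop) — spacer] — spacer — ORF2 analogue (466 aa) — spacer.
Spacer lengths are the real-scale inter-feature distances (mapped region
~13 kb, insert ~28 kb) multiplied by `scale` (default 0.1, giving a ~9.6 kb
locus); feature lengths are absolute so every measured quantity survives
scaling. Background is i.i.d. uniform {A,C,G,T} — no repeat structure,
which is sufficient for exact-match primers/anchors; uniqueness of every
anchor and primer site (and their absence from the PAV-deleted sequence)
is verified at build time, with a deterministic seeded retry if a collision
ever occurs. A scale that shrinks any spacer below the room needed for
anchors raises an error. Same seed ⇒ byte-identical sequence.

**Variants.** PAV absence (excise the insert, join the flanks), a stop
codon substituted at any killer codon k (truncating the product to k−1 aa;
k=101 reproduces the 100-aa N-terminal landmark), and excision of exactly
the 369-nt promoter marker. Per-type recipes use distinct stop positions to
mimic independent truncation haplotypes.

**Panels.** Per-taxon composition either exact (counts) or sampled
(frequency vector, seeded multinomial). The default panel emulates the
published *Oryza* survey: japonica 132/148 no-PAV with the PAV minority
split 10 Type-2 : 6 Type-1; indica 22 no-PAV / 74 Type-1 / 140 Type-2 of
236; wild Asian taxa carrying all of Types 1–3; African-complex taxa all
Type 4; *O. meridionalis* all Type 5. Only the headline counts are reported
values; the remaining splits are plausible round numbers chosen once.

**Cross progeny** are single seeded multinomial draws from a model
distribution. **Fertility records** are beta-binomial: per plant, a class
(default fertile/semi-sterile 1:1), a true fertility ~
Beta(mean·c, (1−mean)·c) with concentration c = 1/dispersion (dispersion 0
degenerates to the mean), and an observed fraction Binomial(n_pollen,
true)/n_pollen. Defaults — means 0.95/0.50, dispersion 0.02, 200 grains,
279 plants — give class standard deviations of roughly 0.03 and 0.08, so
the 70–80% band is nearly empty in expectation and the histogram valley
falls inside it in well over 90% of seeds.

What the generator deliberately does not emulate: sequence divergence and
repeats (so anchor/primer matching is noise-free), measurement error in
genotype calls, linkage between the transgene and Se, within-locus
recombination, and real per-plant fertility dispersion (not printed
anywhere; the default is calibrated only to the qualitative bimodality).
Passing round-trip tests therefore demonstrate internal consistency of the
calculus and the assays on clean data, not robustness to real-genome noise.

## Problem sizes and numerical choices

The shipped tests use the study-scale numbers where they are stated —
279-plant fertility populations, 240 F2 progeny, 10,000-progeny recovery
replicates (100 seeds), 200-seed phenotyping replicates, the full
~786-accession default panel — and the default 0.1-scale locus. Gamete and
offspring probability sums are enforced to 1e−9 (checked in tests at
1e−12); the SF inversion is accurate to <1e−10; MLE grids are as above.
Ties in the canonical key order are impossible because labels within a
genotype are unique.

## Known limitations

* Exact-match primers/anchors restrict typing to synthetic or
  near-reference sequences.
* Spikelet fertility is not predicted from kf; the female effect exists in
  the model only at gamete transmission.
* The profile-likelihood CI of a joint (km, kf) fit is coarse-grid.
* Chi-square LRT p-values at the Mendelian boundary are conservative.
* Multi-allelic Se series and linked modifiers are out of scope.
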