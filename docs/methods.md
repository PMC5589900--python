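# Methods

## The model

An imprinted differentially methylated region (DMR) carries a
germline-established methylation mark on exactly one parental allele, so
normal diploid tissue reads out an average beta value near 0.5. Somatic
copy-number aberrations (CNAs) move that value deterministically. With an
allele-specific copy state of `t` total copies and `m` copies of the minor
(less abundant) parental allele, only two methylation fractions are
consistent with the copy state:

```
minor methylation value  mm = m / t
predicted beta ∈ { mm, 1 − mm }
```

Which branch applies depends on which parental allele carries the germline
methylation. The observed array value resolves it: if the observed DMR
average is below 0.5 the methylated allele is taken to be the minor one
(prediction `mm`); above 0.5, the major one (prediction `1 − mm`). An
observed value of exactly 0.5 is a tie and resolves to the `1 − mm` branch
(logged); for `mm = 0.5` both branches coincide. Equivalently, the rule picks
whichever of `{mm, 1 − mm}` is nearer to the observed value — the test suite
proves this equivalence by exhaustive enumeration over `t = 1..14`,
`m = 0..⌊t/2⌋`, and an observed grid of step 0.01.

A locus with `t = 0` (homozygous deletion) has no prediction; it is flagged
not-evaluable and excluded from epimutation denominators.

### Epimutation calling

A (sample, DMR) pair is called **CNA-independent** — an epimutation
candidate — when the observed DMR average deviates from the CNA-predicted
value by strictly more than 3 standard deviations of the normal-tissue
controls (the per-region cross-control s.d. of DMR averages, ddof = 1,
requiring ≥ 2 controls). The band is centered on the per-sample predicted
value; its width comes from the control s.d. When that s.d. is exactly zero,
any deviation larger than an absolute guard of 1e-9 is independent — the
guard absorbs accumulated floating-point rounding (probe averaging and the
`1 − mm` complement each cost up to an ulp) without masking any real signal.

Absolute methylation states are assigned separately and are deliberately
CNA-unaware: beta > 0.8 is hypermethylated, < 0.2 hypomethylated (strict);
otherwise a shift of at least ±0.2 beta from the control mean is an
intermediate gain/loss; else normal. Copy-altered loci can therefore be
"hypermethylated" in the absolute sense while being entirely CNA-consistent;
the `cna_independent` flag, not the state, is the epimutation call.

### Copy-neutral LOH and parent of origin

Copy-neutral loss of heterozygosity (cnnLOH) is `t ≥ 2, m = 0`: one parental
allele lost, the other present in two or more copies. All copies then share
one parent, so an imprinted DMR reads out near 0 or 1, and the observed value
identifies the retained parent: beta > 0.8 means the retained allele carries
the germline mark (the annotated methylated parent), beta < 0.2 the other
parent, anything between is ambiguous. The 0.8/0.2 bands are reused from the
state classifier for internal consistency.

A consequence worth stating plainly: at any locus with `m = 0` (cnnLOH or
hemizygous), a *complete* methylation swing — an epimutation methylating or
demethylating every copy — produces exactly the beta profile of the opposite
retained parent. Given only average beta and the copy state, such events are
unidentifiable in principle, by any method. The recovery tests therefore
measure hyper/hypo sensitivity over loci retaining both alleles (`m ≥ 1`);
the simulator still injects the unidentifiable ones, and they depress the
recovered cohort frequency accordingly.

### Locus copy states

Segments overlap a region if they share at least 1 bp. When a region is
split across segments, the segment covering the most of it supplies the copy
state (ties toward higher total copy number); uncovered regions default to
an assumed 2:1 diploid state, flagged `assumed`. Baseline ploidy per sample
is the length-weighted median total copy number, rounded half-up (minimum
1) — the median resists focal amplification outliers — and each state also
reports `total / baseline` for hyperploid interpretation. A segment is
**internal** when its nearest anchor (telomere or centromere interval) is
strictly more than 1 Mb away; otherwise it takes the nearer anchor's class,
ties to the telomere.

### Genome-context hypermethylation

CIMP promoter islands, bivalent domains and DNA-methylation valleys are
scored only where controls are uniformly unmethylated (control mean < 0.2).
Severity per (sample, region): highly (> 0.75 beta), mildly (> 0.5), lowly
(≥ control mean + 0.2, the ≥ being a documented convention), else
unaffected. The per-sample burden score is `3·highly + 2·mildly + 1·lowly` —
an explicit severity-weighted convention, configurable. Burdens are
correlated pairwise (and against the count of non-normal imprinted states)
with Pearson's r when both vectors pass Shapiro–Wilk at α = 0.05, otherwise
Spearman's rank.

## The synthetic cohort generator

The generator emulates a cell-line cohort measured on a beta-value array
with matched allele-specific copy-number calls. Defaults are the conditions
of a breast-cancer cell-line study: 51 tumor lines, 19 normal controls, 37
imprinted DMRs (18 probes each, ≈ 661 DMR probes), 30 CIMP / 442 bivalent /
166 DMV context regions (4 probes each), amplification up to 14 total
copies, purity 1.

Per (tumor, DMR), a copy state is drawn: cnnLOH with probability 0.08
(total 2–4, minor 0), otherwise a CNA with probability 0.40 (total from a
prior concentrated on 1–4 with a geometric tail to 14; minor uniform on
`0..⌊t/2⌋`), else 2:1. The minor allele's parent is uniform, so both 75:25
and 25:75 outcomes occur. Each copy carries its parent's germline
methylation state; the noise-free locus beta is exactly
`methylated copies / total copies`.

Epimutations hit each (tumor, DMR) with probability 0.176 (the headline
cohort frequency the defaults emulate); the kind is drawn from weights
hyper 0.5 / hypo 0.3 / intermediate 0.2 restricted to kinds that actually
change the per-copy pattern — a "hyper" event at an already fully methylated
locus would be a no-op and is not an event. Hyper methylates every copy,
hypo demethylates every copy, intermediate flips exactly one copy chosen
uniformly (so at 2:1 the locus jumps to 0 or 1, at 4:1 it shifts by 0.25).

Probe values are the locus beta plus heteroscedastic Gaussian noise with
s.d. `noise_sd · 2·√(β(1−β))` (0.02 at beta 0.5, vanishing at the
extremes), clipped to [0, 1]. This mirrors the variance profile of real
beta values — maximal at intermediate methylation, near zero at the
boundaries — and keeps probes unbiased at 0/1, where additive homoscedastic
noise would be clipped asymmetrically and drag the mean off the true
fraction. Homozygously deleted loci emit the contaminating-normal 0.5
signal (no DNA of their own), so a single sample's deletion cannot knock a
probe out cohort-wide through the missing-value QC rule.

Tumor purity below 1 dilutes every beta linearly toward the matched normal
profile (`p·β_tumor + (1−p)·β_normal`); cell lines use purity 1, and
primary-tumor settings are simulated by lowering `purity_mean` (e.g., the
0.722 ± 0.205 typical of breast carcinoma resections). Genome-context
hypermethylation is driven by one per-tumor latent factor (each eligible
region methylated to U(0.25, 0.95) with probability equal to the factor),
while imprinted epimutations are drawn independently of it — so context
burdens correlate strongly across classes and not at all with imprinted
defects. RRBS-style site tables draw Poisson coverage (mean 30, zero-
coverage sites dropped) and binomial methylated counts at the true site
fraction.

Randomness is one `numpy` Generator stream per (seed, role, sample, region),
with tumor indices offset from normal indices, so adding samples or regions
never perturbs existing draws and identical seeds are bit-reproducible.

What the generator does **not** model — and hence what passing tests do not
show about real data: probe-specific biases and cross-reactivity, bisulphite
conversion failure, segmentation error in the copy-number input, subclonal
copy-number or methylation mosaicism, correlated probes within a region
beyond the shared locus mean, and genuine biological coupling between
genome-context hypermethylation and imprinted epimutations.

## Numerical and design choices

* Strict inequalities at every stated boundary (0.8/0.2, ±3 s.d., > 10% of
  samples, > 1 Mb), matching the rules' wording; exactly-at-boundary values
  fall on the conservative side.
* Intervals are 0-based half-open internally; SEG-like tables (1-based
  inclusive) are converted on read. Overlap is plain interval arithmetic on
  validated non-overlapping per-sample segments.
* The per-cohort epimutation frequency is reported both as independent
  calls / evaluable (sample, DMR) pairs and as mean affected DMRs per
  sample, since cohort percentages can be expressed either way.
* Probe QC order: detection filter, then missing values, then SNP
  proximity, then sex chromosomes; counts reconcile exactly with the input.
* R² comes from ordinary least squares with intercept
  (`scipy.stats.linregress`); a constant predictor reports R² = 0 with a
  degeneracy flag, a constant response reports 1 (zero residuals).
* Problem sizes in the cohort-scale tests — 200–500 tumors × 37 DMRs, 300
  tumors for the context-correlation cohort — are chosen so binomial
  tolerances on recovered rates are tight while a full suite run stays in
  the tens of seconds.

## Known limitations

* The branch rule conditions on the observed value, so it can never flag a
  locus whose observed beta sits at the *other* CNA-consistent branch; this
  is inherent to the method, not the implementation.
* Epimutation frequencies are biased downward by unidentifiable events at
  LOH loci and upward by the false-positive floor of the ±3·estimated-s.d.
  rule (with 10 controls the tumor/control deviation ratio is t-distributed
  with 9 d.f., so the per-pair false-positive rate is ≈ 1.5% at mid-range
  loci rather than the nominal 0.27%). More controls narrow this floor.
* Split DMRs take the largest-overlap segment's state rather than an
  average; the fraction of split DMRs is visible in the state table.
* CNA size summaries average over segments (not over samples); noted in the
  output metadata.
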