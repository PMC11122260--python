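# Methods

## Broad copy-number aberration calling

Input segments carry a total copy-number state in {−2, −1, 0, +1, +2}
relative to diploid, with an optional minor-allele copy number. For
every chromosome arm (from a UCSC-style cytoband file; an arm is the
contiguous union of its p or q bands) the caller computes the fraction
of arm *base pairs* covered by gained (state > 0), lost (state < 0) and
copy-neutral-LOH (state 0, minor allele 0) segments, by exact integer
arithmetic on clipped intervals. An arm is broad-gained when its gain
fraction strictly exceeds the broad threshold (default 0.25 — "more
than 25%" is a strict inequality, so an arm exactly 25% altered is
focal). Fractions are territorial (base pairs), not gene counts: the
definition of a broad event is about how much of the arm is affected,
and a per-gene count of the same segments displays the same
information. Gain and loss fractions are computed independently; in
the rare case both exceed the threshold on one arm, precedence is
gain > loss > CN-LOH and the conflict is logged.

Two arms broad in the same direction merge into one whole-chromosome
('w') entry of the virtual karyotype; a chromosome defined with only a
q arm (acrocentric convention) reports scope 'q' as its
whole-chromosome equivalent. The aneuploidy index counts broadly
gained or lost *arms* — a 'w' event on a two-arm chromosome counts 2,
on a single-arm chromosome 1 — and CN-LOH is listed in the karyotype
but excluded from the index, which is defined by the counting of gains
and losses. CN-LOH detection requires an explicit minor-allele copy
number of 0 at total state 0; segment files without that column simply
never produce CN-LOH calls (genotype-based LOH inference is out of
scope). Sex chromosomes are treated like autosomes. Internally all
coordinates are 0-based half-open; SEG-like input is declared 1-based
inclusive and converted on read, and "chr20"/"20" are normalized to one
name space.

## Stratification

A target aberration is a (chromosome, scope set, direction) triple,
e.g. `20:q,w:gain`. Tumors with a matching broad entry form the
Selected group; tumors with *no* broad entry of any direction
(gain, loss or CN-LOH) on the target chromosome form the Control
group; tumors with a non-matching broad event there are excluded from
both. Focal events never disqualify a Control — the design is defined
at the broad-aberration level, so a focal gain on the chosen chromosome
is treated as absence of the aberration. CN-LOH on the target
chromosome disqualifies Control membership (it is an aberration) but
never grants Selected. An empty Selected or Control group is a flagged,
degenerate design: FC2 is then undefined and reported as such.

## Fold-change indices and classes

Group means are arithmetic means of log2 values (RMA-scale), computed
per group and only then exponentiated — not means of linear values.
The signed linear fold change is +2^(study−control) when the study
mean is larger, −2^(control−study) when smaller, and +1.0 at exact
equality (the two-branch formula is silent there; +1 keeps the
|FC| ≥ 1 invariant and a well-defined sign). Because FC2, FC3 and FC4
derive from the same three group means, their unsigned ratios satisfy
ratio4 = ratio2 · ratio3 up to floating-point rounding — the package
treats this as a testable identity, not an approximation.

All classification cut-offs are strict: UpT needs FC3 > 1.5 and
FC4 > 1.5; OverT needs FC2 > 1.3; Over-UpT needs FC2 > 1.3 and
FC3 > 1.5, with label precedence Over-UpT > UpT > OverT > none.
Boundary values (FC3 exactly 1.5) fail. Negative fold changes never
pass any cut-off. No FC1 cut-off exists; FC1 is computed and reported
but unused in classification. Whether Over-UpT should additionally
require FC4 > 1.5 (making it a strict subset of UpT) is a genuinely
open reading; the literal two-condition filter is the default and a
`require_upt` switch enables the subset reading. ANOVA (one-way,
fixed-effects, across the normal/Control/Selected groups) and
Benjamini–Hochberg FDR are annotations: class membership is defined by
the fold-change thresholds alone, and an optional `fdr_filter` flag
demotes non-significant transcripts when a significance-gated list is
wanted. A biotype allow-list (e.g. lncRNA-only) can restrict the
classified universe before any statistic is computed. qPCR validation
data are summarized as 1/ΔCt with the ΔCt normalized against a
reference gene such as ACTB; ΔCt = 0 is an error and negative ΔCt is
returned with a warning.

## ceRNA screen

Candidate pairs (lncRNA, partner, partner kind) are an input file;
target prediction is out of scope. Pearson's r with a two-sided
t-transform p-value (n − 2 df) is computed across tumor samples by
default — the scatter analyses this mirrors are across cancer samples;
a flag includes normals. A pri-miRNA partner significantly negatively
correlated is *sponge-consistent*; a marker partner significantly
positively correlated is *proliferation-consistent*; a significant
wrong-sign correlation is *inconsistent*; non-significance (α = 0.05)
is *indeterminate*. Zero-variance series and unresolvable ids yield
indeterminate/error rows rather than aborting the screen. Correlations
are between transcript-level values, with pri-miRNA transcripts
standing in for mature miRNAs.

## Synthetic cohorts

For sample *s* and transcript *t*,

    x_ts = μ_t + β_t·I(tumor) + γ_t·log2(c_ts/2) + ε,  ε ~ N(0, σ²)

where c_ts is the local copy number implied by the sample's segments.
Selected tumors carry one broad segment of copy number *c* over the
target region; Controls and Normals are diploid everywhere. The dosage
term makes the population FC2 of an on-target transcript analytically
(c/2)^γ — γ = 1 is proportional dosage, γ = 0 insensitivity — and the
population FC3 is 2^β, so every simulated transcript has a closed-form
intended class recorded in the truth table. Sponge partners are affine
in their lncRNA's realized values, m = μ_m + β_m·I(tumor) −
κ·(x_lnc − x̄_lnc) + ε with κ ≥ 0 (positive coupling for markers),
which fixes the sign of the induced correlation; their truth-table
fold changes follow in closed form from the lncRNA's group means.

Defaults mirror the scale of the HTA-style colorectal cohort the
analysis is designed for: 26 normal mucosae and 46 tumors (23
Selected, 23 Control), a 20q trisomy (c = 3), baselines of 6.0 log2
units (a mid-range RMA intensity), cancer effect β = 1 (2-fold),
proportional dosage γ = 1 on ten target lncRNAs, Gaussian log2 noise
σ = 0.3 (a typical between-sample SD for array data), and one κ = 0.8
pri-miRNA plus one marker coupling. The toy genome has four two-arm
chromosomes named 7, 8, 13 and 20 with 200 transcripts, so a full
pipeline run takes seconds. One integer seed drives everything;
per-stage substreams are spawned from it deterministically, and equal
seeds give byte-identical outputs.

What the generator does *not* emulate — and what passing tests
therefore do not show about real data: probe-level summarization and
normalization artifacts, heteroscedastic or heavy-tailed noise,
correlated expression blocks beyond the explicit couplings, focal
events and realistic breakpoints, subclonality, or tumor purity. The
generator validates the pipeline's logic and statistical behavior
under its stated model, not array physics.

## Numerical choices and problem sizes

Fraction arithmetic is exact integer base-pair counting. Fold-change
identities are checked to 1e-12 absolute on ratios of order 10.
The truth-recovery check runs at σ = 0, where class labels are exact
because every population fold change sits far from the thresholds.
Parameter-recovery and sponge-recovery checks use 100 samples per
group over 20 seeds, and ANOVA calibration uses 1,000 null
simulations of three 10-sample groups — sizes at which the acceptance
script completes in seconds while the binomial noise of the measured
rates stays well inside the asserted bands.

## Known limitations

Segmentation from raw intensities, allele-specific copy-number
estimation, paired-sample designs, batch correction, survival
covariates and miRNA target prediction are all out of scope; the
package consumes segments, normalized expression and interaction
pairs as inputs. Control groups exclude tumors with any broad event
on the target chromosome but not tumors with focal events there — a
documented reading of an under-specified rule, configurable only by
editing the karyotype upstream.
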