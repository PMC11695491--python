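# Methods

This note documents the models and procedures implemented in
`edascreen`, the defaults chosen where the underlying screening
workflow leaves them open, and what the synthetic-data experiments do
and do not demonstrate.

## Exact-mass arithmetic (`chemmass`)

Formulas are Hill-notation element/count maps over
{C, H, N, O, S, Cl, Br, F, P, Na, K}; monoisotopic mass is the sum of
most-abundant-isotope masses (IUPAC, ≥ 6 decimals).  Only singly
charged positive-mode adducts are modelled; the [M+H]⁺ offset is the
proton mass 1.007276 Da (electron mass accounted for), which reproduces
reference MW ↔ m/z differences to ≤ 0.05 mDa.  ppm errors are signed as
(measured − theoretical)/theoretical, the usual non-target screening
convention.  Isotope fine structure, multiple charging and negative
mode are out of scope.

Reported percentages and decile sizes use round-half-up (ties away
from zero): it is the unique simple rule consistent with the published
candidate-count/decile pairs this package reproduces (1085→109,
311→31, 356→36, 1283→128).  Printed percentages in such tables are not
always internally consistent at the last decimal; the package applies
its single documented rule and keeps raw ratios in machine output.

## Feature model (`feature_model`)

Feature tables are long-format delimited text (one row per
feature × injection) plus a sample manifest; MS2 spectra travel as MGF
with the feature id in TITLE.  Areas are stored per injection
replicate, unaveraged, each carrying a gap-fill flag: a gap-filled
value was imputed during alignment and is never treated as a genuine
detection.  Replicate aggregation is the arithmetic mean over
present-and-qualifying replicates.

Cross-table merging links features with |Δmass| ≤ 2 ppm (relative to
the pair's mean mass) and |Δrt| ≤ 0.2 min and takes connected
components; representatives use area-weighted mean mass/rt, which is
stable under replicate noise.  The rt tolerance is a package choice —
vendor alignment tools do not publish theirs — set narrow relative to a
~27-min gradient.  If two members of one cluster carry areas in the
same injection they are treated as split parts of one peak (areas add;
a genuine detection on either side keeps the merged value genuine).

## Filter cascade (`prioritize`)

Defaults: abundance threshold 1×10⁶ (strict >), recovery window
[0.10, 0.75] (inclusive bounds — the window is stated without
inclusivity; boundary cases are configuration-sensitive and tested),
blank factor 10 (strict >), suspect tolerance 2 ppm.  Decisions the
workflow leaves open, resolved as package defaults:

- "Detected" in a plate blank means any genuine peak, of any size.
- "Detected" in an off-zone fraction additionally requires exceeding
  the abundance threshold (configurable, `offzone_use_threshold`);
  threshold-free off-zone exclusion would be dominated by
  imputation-level noise.
- All four rules are evaluated for every feature, so the audit trail is
  complete and the conjunction is manifestly order-independent.

Workflow accounting (`percent_reduction`) reports the percent of parent
features removed, to one decimal.

## In-source grouping (`insource`)

Defaults rt_tol = 0.05 min, mz_tol = 0.005 Da, min_shared = 2.  The
evidence types are (a) ≥ min_shared shared MS2 fragments under greedy
closest-first one-to-one matching and (b) a feature's [M+H]⁺ occurring
as a fragment in a co-eluting higher-mass feature's MS2.  Greedy
matching equals the maximum bipartite matching whenever within-spectrum
peak spacing exceeds twice the tolerance — the regime of centroided
MS2 — and that is the regime the tests construct.  Groups are connected
components (transitive closure accepted); the highest-mass member
represents the group as the plausible intact ion.  Downstream modelling
still treats features independently; groups annotate the report.

## Genotoxicity models (`genotox`)

DT40 DNA-damage activity is derived from AC50 ratios: a chemical is
active when wild-type AC50 / repair-deficient-mutant AC50 ≥ 2 for at
least one mutant line.  The 2-fold default is a package choice (no
numeric cutoff is published for this construction); chemicals missing
either the mutant or the wild-type AC50 are conservatively inactive.

Per endpoint, an XGBoost classifier (200 trees, depth 3, learning rate
0.2, histogram method, single thread) is trained on fingerprint bits
with a stratified 0.85/0.15 split and positive-class weight
n_inactive/n_active (endpoint priors are ~8–12% active).  No
hyperparameter search: fixed shallow settings keep runs desk-scale and
bit-for-bit reproducible from the seed.  Held-out metrics are balanced
accuracy, sensitivity, specificity.  Model artifacts serialize to a
self-describing JSON (schema version, fingerprint length, seed,
metrics, booster) and reload to identical predictions.

A feature is called potentially genotoxic when max endpoint
probability > 0.5 (strict).  Fingerprints are consumed as inputs (or
simulated); predicting fingerprints from MS2 spectra is an upstream
tool's job, not re-implemented here.

## Candidate statistics (`candidates`)

Candidate structures are ranked by Tanimoto (Jaccard) similarity over
fingerprint bits, ties broken by structure id.  Tanimoto is a
documented stand-in for proprietary spectral-library scores; every
downstream statistic depends only on the rank order, so any strictly
monotone rescoring leaves results unchanged.  Per feature the report
carries total and top-decile predicted-genotoxic counts and
percentages; the final priority order is
(any-endpoint call desc, top-decile share desc, overall share desc,
parent area desc, feature id) — a total, deterministic key.

## Synthetic studies (`synthsim`)

The generator emulates a one-dimensional mock study: 1695 matrix
features with log₁₀-normal parent areas (μ = 6.8, σ = 0.6, so a
realistic minority sits below the 1×10⁶ threshold), four zones, 150
blank-only background features, triplicate injections with 10%
multiplicative log-normal noise, gap-filled entries emitted with
probability 0.5 where a feature is absent from an injection, in-source
clusters sharing retention time (± 0.02 min) and planted fragment ions
(85.0283, 99.0440, 127.0389), and two spiked genotoxicants: an
isothiazolinone biocide at 38% recovery (manual-scrape-like) and a
nitroquinoline positive control at 10% (interface-like).  Zone
recoveries are Beta-distributed per elution method with means 0.10
(interface) and 0.38 (manual).  Endpoint datasets default to the
Tox21-scale priors 723/5953 and 257/3057.

Endpoint simulation plants an OR rule over designated fingerprint bits
and flips labels with probability ε (default 0.05).  The pre-noise rule
prevalence is calibrated to r = (af − ε)/(1 − 2ε) so the emitted class
prior equals the requested active fraction in expectation; this
requires af > ε.

**Classifier validation design.**  The parameter-recovery experiment
uses n = 2000 chemicals, an OR-of-3-bits rule, ε = 0.05 and a balanced
prior (active fraction 0.5), the standard design for method
validation.  Because held-out balanced accuracy is measured against
*noisy* labels, noise imposes an analytic ceiling
BA* = ½·[π(1−ε)/(π(1−ε)+(1−π)ε) + (1−π)(1−ε)/((1−π)(1−ε)+πε)]
with π the pre-noise prevalence: ≈ 0.95 for the balanced design
(observed ≈ 0.93–0.95 across seeds), but only ≈ 0.86 at a 12% prior —
a skewed prior would make high-accuracy recovery unattainable by
construction, not by model failure.

**What the synthetic experiments show** — that the cascade, grouping,
matching and modelling operations are implemented correctly against
independent oracles and recover planted truth under the stated noise
model.  **What they do not show** — performance on real instrument
data: the generator has no chromatographic peak shapes, mass-accuracy
drift, correlated matrix interferences, retention-dependent ionization,
assay dose–response, or realistic fingerprint bit correlations
(bits are independent Bernoulli draws).  Candidate structures are
simulated for spiked and in-source-cluster features only; ranking real
zones requires externally supplied fingerprints and candidate lists.

## Problem sizes and determinism

Default test-suite experiments use studies of ~1850 features, 1000-table
filter-cascade randomizations, 1000 random link graphs (≤ 15 nodes),
100-seed spike-recall replications and 5–20 seeded classifier fits —
sizes chosen so the whole suite runs in a couple of minutes on one CPU.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; study directories written twice from the
same seed are byte-identical.

## Known limitations

- Only [M+H]⁺, single charge; no adduct/isotopologue networking.
- The blank rule compares against the maximum single blank peak, not a
  blank distribution.
- Merging does not re-cluster representatives, so chain-merged clusters
  can in principle leave two representatives within tolerance.
- DT40 ratio handling of one-line-only chemicals is conservative
  (inactive) and configurable only through the rule threshold.
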