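# Methods

## The screen and its readout

The pipeline models a high-content RNAi screen for kinases that repress
myoblast differentiation. A 571-gene mouse kinase siRNA library is arrayed
across two 384-well plates; each library plate is run in triplicate under
two arms — vehicle, and a CDK4/6-inhibitor sensitizer — giving 12 physical
plates. Each physical plate carries 32 growth-medium (GM) negative-control
wells, 32 differentiation-medium-plus-insulin (DM+I) positive-control
wells, 32 or 37 other control wells (mock transfection, universal control
siRNA, and a Kif11 knockdown-efficacy control), and 288 or 283 experimental
wells (288 + 283 = 571). Four sites are imaged per well; the readout per
site is the total nuclei count and the Myogenin-positive nuclei count.

A well is summarized by (i) its per-site Myogenin-positive fractions, (ii)
the pooled Myogenin-positive percentage, 100 × Σ positives / Σ totals over
sites, and (iii) the mean nuclei count per site. The pooled percentage
weights sites by cell content, which is less noisy for sparse wells; the
raw per-site fractions are kept because they are the sampling unit of the
per-well test. Sites with zero nuclei are excluded from fractions; wells
with no nuclei anywhere are flagged unsummarizable and excluded downstream
with a log entry.

## Hit calling

Per well, two criteria:

* **Myogenin criterion** — one-sided pooled-variance Student's *t* test of
  the well's site fractions against the pooled site fractions of the GM
  wells on the same physical plate, significant at α = 0.05 for an
  increase. No multiple-testing correction is applied across the library
  (a Benjamini–Hochberg option exists but is off by default), matching
  standard primary-screen practice of controlling errors through
  replication instead.
* **Cell-number criterion** — two dialects, selectable per run:
  `methods` (default): well mean nuclei ≤ median(GM reference) − 1 × MAD;
  `results`: well mean nuclei ≤ median(DM+I reference) + 1 × MAD, i.e. the
  count has fallen to within one MAD of the differentiated-control level.
  Both use the raw, unscaled MAD of reference well means. The two dialects
  encode two non-equivalent published phrasings of the same rule; the
  discrepancy is surfaced as configuration rather than silently resolved.

A well is positive when both criteria hold (Myogenin alone in the
sensitizer arm — the CDK4/6 inhibitor suppresses cell number in every well,
so a knockdown-attributable depletion cannot be read there). A kinase is a
hit with ≥ 2 of 3 positive replicate wells in the vehicle arm and 3 of 3 in
the sensitizer arm.

The per-kinase robust Z-score — the kinase's mean Myogenin percentage
centered and scaled by the median and 1.4826 × MAD of the per-kinase means
on the same library plate and arm (GM-referenced scaling is available as a
switch) — is reported alongside every call but never gates hit status: hits
are defined by the *t*-test/MAD rules, and the Z-score serves as an effect
magnitude. The 1.4826 factor (normal-consistency scaling) is applied only
inside robust Z-scores; the cell-number threshold uses the raw MAD.

Degenerate cases are given exact conventions: if both *t*-test samples are
constant, *p* := 1 when equal and *p* := 0 in the favorable direction
(the guard tests exact constancy, not estimated variance — near-constant
samples otherwise yield catastrophic-cancellation variances around 1e−35
and a spurious *t*); a zero reference MAD raises a degenerate-scale error
rather than dividing by zero; wells with fewer than two usable site
fractions are scored not-positive and logged.

## Assay-window QC

Plate quality is the Z'-factor between DM+I and GM control wells on the
pooled Myogenin percentage: 1 − 3(s₊ + s₋)/|m₊ − m₋| with sample (n−1)
standard deviations, chosen because control groups are small (32 wells).
Control scoring applies the full per-well hit criteria to the control
wells themselves (GM wells leave-one-out against their plate-mates),
reporting the fraction of positive controls that score and of negative
controls that score, per arm.

## Network classification

Hit kinases are mapped onto an undirected protein-interaction graph built
from two-column tab-separated edge lists (HPRD/BioGRID-style exports;
extra columns ignored, headers auto-detected, symbols uppercased, self-
loops and duplicate edges dropped with counts logged, per-edge source
provenance retained). Mouse-to-human symbol mapping defaults to uppercase
transliteration plus a small override table (e.g. Myod → MYOD1).

For each (kinase, MRF) pair — MRFs being MYOD1, MYOG, MYF5, MYF6, MEF2A,
MEF2C, MEF2D — the label is *direct* if the edge exists, else *semi-direct*
if the two share at least one intermediary neighbor that is itself neither
a query kinase nor an MRF (intermediaries form a distinct tier of the
network maps; a switch permits kinase/MRF intermediaries), else
*unconnected*. A pair counts once regardless of how many intermediaries
join it; all intermediaries are recorded. A kinase's summary label is its
strongest pairwise connection. Kinases with no edges at all are flagged so
downstream maps can exclude them. Summary rankings (kinases by MRFs
reached, MRFs by kinases connected, intermediaries by distinct MRFs
linked) break ties by count descending then symbol ascending. Direction
annotations in source databases (bait/prey) are discarded; interactions
are treated symmetrically.

## Enrichment

Gene sets come from GMT files. The background is the screened library, not
the genome: membership is intersected with the library before counting, so
`K` counts only screened genes out of `N` = 571. With `m` hits of which
`k` are in the set, *p* = P(X ≥ k) for X ~ Binomial(m, K/N) (one-sided,
enrichment only; a hypergeometric variant is provided but off by default)
and fold enrichment = (k/m)/(K/N). BH adjustment runs over all sets with
K ≥ 1 in the collection; the report filters at unadjusted *p* < 0.05 with
q-values alongside, both thresholds configurable.

## The synthetic-data generator

`simulate_screen` emulates the screen's design and assumed statistics:

* **Total nuclei per site** ~ negative binomial with mean 250 in GM
  (dispersion 10, so variance ≈ mean + mean²/10) — overdispersed counts
  are the conservative choice for imaging-based cell counts.
* **Myogenin-positive nuclei per site** ~ beta-binomial: each site draws a
  latent fraction from a Beta with mean given by the well's condition and
  intra-class correlation 0.01, then a binomial count. Baseline fraction
  0.02 in GM, 0.40 in DM+I. Effects compose on the logit scale —
  knockdown odds multipliers and the sensitizer shift add as log-odds — so
  composed fractions stay in (0, 1).
* **Arm and role effects**: the sensitizer halves expected nuclei in every
  well and, by default, adds no Myogenin shift of its own
  (sensitizer_myog_shift = 1.0 — the screen cannot detect the small
  increase the drug alone produces); DM+I wells run at half proliferation;
  Kif11 control wells at 0.3× (a lethal knockdown used as transfection
  control). Planted hits apply their odds/proliferation multipliers only
  in their own experimental wells.
* Overdispersion acts **per site**: each imaged field draws its own latent
  fraction. A shared well-level latent component (sites of one well
  correlated) is deliberately not the default: it would make any
  site-level test of the well mean strongly anticonservative (measured
  false-positive rate ≈ 0.17 at these settings) and is not identifiable
  from the published design. Plate-position effects (row/column gradients,
  edge effects) are off by default but hooks exist (additive logit/log
  offsets per row and column); the analysis normalizes per plate only, so
  simulated spatial structure would degrade it realistically.

Fractions and counts are configuration choices of the generator, not
measured values — the screen's absolute control behavior is published only
graphically. Gene symbols in the default library are synthetic
placeholders (`KIN001`…), since the library's identity adds nothing to
the statistics. The generator does not simulate images, segmentation
error, or transfection-efficiency gradients; recovery results on synthetic
screens therefore bound what the statistics can do under the assumed noise
model, not under real imaging artifacts.

Ground truth marks a gene as a planted hit only when its differentiation
odds multiplier differs from 1; purely anti-proliferative plants are
recorded with their parameters but are not expected calls.

## Calibration of the per-well test: a known limitation

Under the generator's default noise model the one-sided Student *t* on
four site fractions is mildly anticonservative: site fractions at a 2%
baseline are right-skewed (beta-binomial with ~5 positive nuclei per
site), and the mean of four skewed values has a heavier right tail than
normal theory assumes. Direct Monte Carlo of the isolated test (4 site
fractions vs. 128 pooled GM site fractions, 30,000 replicates) gives a
true false-positive rate of ≈ 0.065 at nominal α = 0.05 (≈ 0.055 with the
beta overdispersion removed); full null-screen simulations average ≈ 0.059
per well with plate-to-plate spread from shared GM references. Wells with
depleted cell counts are hit hardest, because fewer nuclei per site mean
noisier fractions while the pooled variance is dominated by the healthier
reference wells. The procedure tolerates this by design: conjunction with
the cell-number criterion (null pass rate ≈ 0.26) and the 2-of-3 replicate
rule push the per-gene false-call probability to ~10⁻³, and null-screen
simulations at full scale typically call zero hits. But the per-*well*
Myogenin criterion alone should not be treated as an exact α-level test,
and a single screen planting ~10 purely anti-proliferative genes has a
~10% chance that one of them leaks through two replicate-well false
positives. These are properties of the published procedure on realistic
data, not implementation artifacts.

## Problem sizes

Unit tests run on a reduced single-plate layout (8 GM + 8 DM+I + 4 other
controls + 20 experimental wells) where distributional properties do not
need full scale; acceptance-style checks use the full 571-gene,
two-plate, two-arm, triplicate design (4,608 wells, 18,432 sites per
screen), three seeds for null-screen behavior and a four-point effect-size
grid for recovery monotonicity. Scalar estimators are verified against
brute-force definitions on ≥ 1,000 randomized cases each, and the
semi-direct classifier against exhaustive two-hop enumeration on 500
random graphs of up to 50 nodes.
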