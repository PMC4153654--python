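# Methods

## The measurement model

The pipeline analyses a three-channel stable-isotope dimethyl labeling
experiment. Three biological conditions are digested, labeled with light,
medium (+4 Da) and heavy (+8 Da) dimethyl on peptide N-termini and lysines,
mixed, enriched for phosphotyrosine peptides, and measured in one LC-MS run.
In the intended design the light channel carries the wild-type reference
(WT), medium a Noonan-syndrome-type activating Shp2 perturbation (NS), and
heavy a LEOPARD-syndrome-type catalytically impaired Shp2 perturbation (LS);
nothing in the code depends on that biology beyond the channel naming
(`medium/light` = NS/WT, `heavy/light` = LS/WT).

For PSM (peptide-spectrum match) `i` and channel `c ∈ {medium, heavy}` the
observed quantity is modeled as

    q_ic = q_i,light · m_c · 2^(Δ_s(i)) · ε_ic

where `m_c` is the channel's total mixing factor (the conditions were not
mixed 1:1:1 — the defaults emulate medium/light = 1.38 and heavy/light =
2.35), `Δ_s` is the true Log2 phosphorylation change of the site the PSM
measures (0 for every non-phosphopeptide), and `ε` is multiplicative
lognormal noise (normal on the Log2 scale). The analysis removes `m_c` by
dividing every ratio by the **median ratio of all non-phosphopeptide PSMs**
in that channel: unmodified peptides are assumed to be unaffected by the
perturbations, so their median ratio estimates the mixing factor. After this
step the median non-phosphopeptide Log2 ratio is exactly zero per channel,
and rescaling any channel by a constant cancels identically — both
properties are asserted in the test suite rather than merely assumed.

## Stage by stage

1. **Reading** (`psm_io`). PSM rows come from delimited search-engine
   exports (Proteome-Discoverer-1.3-style headers by default, remappable in
   config). Either per-channel abundances or precomputed channel/light
   ratios are accepted; ratio columns win when both are present, because a
   vendor-computed ratio may use feature pairing the abundances alone cannot
   reproduce. A decimal-comma mode exists because published tables in this
   field print `−1,91`. Missing and non-positive quantities collapse to a
   single missing state.
2. **Filtering** (`filtering`). Four rules in fixed order — |mass error| ≤
   10 ppm, ion score ≥ 20, length ≥ 6, rank = 1 — with first-failing-rule
   attribution, all inclusive ("at least", "minimum", "±" readings).
   Decoy matches flow through the rules and the surviving decoy/target count
   estimates the peptide FDR. The estimator is the plain ratio `d/t`, not
   `2d/(t+d)`; with the defaults it lands well under 1% on simulated data.
   An FDR above `max_fdr` produces a warning, not a failure, because the
   score threshold is not the filter that defines the accepted set here;
   `threshold_for_fdr` is available as an explicit re-thresholding step.
3. **Localization** (`localization`). Site probabilities (phosphoRS-style
   percentages per candidate S/T/Y) are **inputs**; the resolver never
   invents or renormalizes them. A moiety is localized when its best
   candidate reaches the cutoff (default 75%, inclusive — the inclusive
   reading is a choice, exposed as `localization.inclusive`, since "above
   75%" and "a 75% cut-off" pull in opposite directions). A tie at the top
   leaves the site ambiguous rather than picking an arbitrary winner.
4. **Quantification** (`quantification`). Normalized ratios are averaged
   arithmetically within each (accession, peptide, resolved-site-set) group
   and the Log2 of the mean is reported (`quantification.aggregate =
   median` switches the centre). When a peptide has both localized and
   ambiguous evidence, only the localized PSMs are used; when nothing
   reaches the cutoff, all PSMs pool into one ambiguous group.
   Normalization happens before averaging; the two orders are
   scale-equivalent, so this is a documentation choice, not a numerical one.
   Significance is |Log2| strictly greater than 1 per channel; exactly 1.0
   is not significant, and a missing channel is never significant.
5. **Classification** (`classification`). The two significance calls and
   signs define nine total labels: the four significant corners
   (`substrate_model` = NS down & LS up, `downstream_model` = NS up & LS
   down, `shared_up`, `shared_down`), four single-channel labels, and
   `unchanged`. The single-channel and unchanged labels are an extension so
   the classifier is total; the biological reading attaches only to the
   corners.
6. **Annotation** (`annotation`). Peptides are located on their source
   proteins by exact substring search (tryptic peptides are exact
   subsequences of their parent, so this matches what a BLAST of the peptide
   returns for exact hits). Site coordinates transfer to the paired human
   ortholog through a global Needleman–Wunsch alignment (BLOSUM62, gap open
   11 / extend 1 — conventional protein-alignment defaults, configurable);
   a site aligned opposite a gap stays in the results with an empty human
   column. The "most commonly observed site" lookup for ambiguous peptides
   is an offline two-column table supplied by the user, keeping the pipeline
   hermetic; rows annotated this way are marked `ambiguous-but-annotated`
   because the localization evidence itself has not improved.

## The synthetic-data generator

`synthetic_data.simulate` draws datasets with the structure above: random
tryptic proteins (uniform segments between K/R terminators), a large excess
of non-phosphopeptides including three abundant contaminant analogs
(actin/keratin/vitellogenin-like), a minority of phosphosites biased toward
tyrosine, per-site true Log2 effects (default: 80% null, 20% with |Log2| in
[1.2, 2.5]), lognormal ratio noise (σ = 0.25 Log2 by default), decoys as
reversed sequences with a score distribution shifted down to ~12 vs ~45 for
targets, a 20% ambiguous-localization fraction, 10% randomly missing
channels, and mixing factors 1.38 / 2.35. Human "orthologs" are derived from
source proteins by seeded point substitutions (3%) and short indels whose
positions are bookkept, so the true source→human coordinate of every site is
known. Indel boundaries are constrained to differ from their flanking
residues so the optimal alignment's gap placement is unique and mapping
accuracy is a meaningful 0/1 outcome.

Default problem sizes (40 proteins, 600 non-phospho PSMs, 69 sites × 4
PSMs) keep a full generate-analyze-score cycle around a second; the
recovery benchmark uses 200 sites × 8 PSMs with effects
{−2, −1.5, 0, 1.5, 2}. Everything is driven by one `numpy` Generator seed
and identical configs produce byte-identical files.

What the generator does **not** emulate: spectra (probabilities and scores
are drawn, not computed from peaks), retention-time feature pairing, isotope
impurity between channels, interference/ratio compression from co-eluting
peptides, protein-level abundance correlation, and missed cleavages. Passing
the recovery tests therefore shows the *arithmetic* of the pipeline is
right under its own model, not that real instrument data would behave this
well — in particular, ratio compression in real data biases |Log2| toward 0
in ways no amount of synthetic testing here can reveal.

A second, fully hand-specified 50-PSM fixture (`make_toy_fixture`) contains
one exemplar of every edge case (decoy passing all rules, ambiguous site,
missing channel, shared peptide, contaminant, one rejection per filter
rule). Its quantities are exact products `light · mixing · 2^effect`, so the
expected results table is analytic and committed as a golden file.

## Numerical choices and degenerate inputs

- Missing channels: a ratio is missing when its numerator or denominator is
  absent; the light (reference) channel is the common denominator, so a PSM
  without light has no usable ratios even when two channels are present.
- Medians use `statistics.median` (mean of the two middle elements for even
  counts); the median-zero invariant is exact because the median normalized
  ratio is the median raw ratio divided by itself.
- Normalization refuses to run on fewer than `min_nonphospho` (default 10)
  non-phosphopeptide PSMs; lowering the threshold must be explicit.
- Result ordering is total and deterministic: descending NS/WT Log2,
  missing last, ties by accession then peptide, so identical inputs give
  byte-identical outputs.
- Peptides mapping to several accessions produce one coordinate per
  accession (`Y19; Y19`); several moieties on one peptide are joined within
  an accession (`Y55, Y57`).
- An empty PSM table yields a header-only results file and a zero summary,
  not an error.

## Known limitations

- FDR is peptide-spectrum-level only; no protein-level FDR, no
  Percolator-style rescoring.
- The BLAST and PhosphoSitePlus steps of a real annotation workflow are
  replaced by exact substring search and an offline site table; inexact
  homology hits are out of scope.
- No isotope-impurity correction and no spectrum-level processing; vendor
  raw files are not read.
- Quadrant labels are reported without any downstream biological
  interpretation.
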