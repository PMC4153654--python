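# phosphoquant

Quantitative analysis of **three-channel stable-isotope dimethyl labeling
phosphoproteomics** experiments — the design in which a wild-type reference
(light channel) is compared against two perturbed conditions (medium and
heavy channels) in a single LC-MS run, typically after phosphotyrosine
peptide immunoprecipitation. The motivating use case is comparing zebrafish
embryos expressing wild-type Shp2 (WT, light) against Noonan-syndrome
(NS, medium) and LEOPARD-syndrome (LS, heavy) Shp2 mutants, but any triplex
dimethyl experiment with a light reference fits.

For a PSM measuring site *s*, the channel quantities follow

    q_c = q_light · m_c · 2^Δs · ε      (c = medium, heavy)

with `m_c` the channel mixing factor, `Δs` the true Log2 phosphorylation
change, and `ε` lognormal noise. The pipeline:

1. reads Proteome-Discoverer-style PSM export tables and FASTA files;
2. filters PSMs (|Δm| ≤ 10 ppm, ion score ≥ 20, length ≥ 6, rank 1) with
   target–decoy FDR estimation;
3. resolves phosphosite localization at a 75% probability cutoff
   (phosphoRS-style probabilities are inputs), keeping sub-cutoff sites as
   "ambiguous";
4. divides every channel/light ratio by the **median ratio of all
   non-phosphopeptides** (removes `m_c`), averages normalized ratios per
   unique phosphopeptide/site, and reports Log2 NS/WT and LS/WT;
5. calls |Log2| > 1 significant and classifies each site into biological
   quadrants (`substrate_model` = NS down & LS up, `downstream_model` =
   NS up & LS down, `shared_up`/`shared_down`, single-channel labels,
   `unchanged`);
6. maps site coordinates onto human orthologs by global pairwise alignment
   (BLOSUM62, gap 11/1), e.g. a zebrafish Fer autophosphorylation site Y716
   landing on human FER Y714.

A seeded synthetic-data generator (`phosphoquant.simulate`) emits PSM
tables, FASTA pairs with known site offsets, and a ground-truth sidecar, so
the whole pipeline is testable without any external download. See
`docs/methods.md` for the model, assumptions and design choices.

## Worked example

Generate a small dataset and run the pipeline:

```sh
phosphoquant simulate --seed 4 --out demo/          # writes psms.tsv, FASTAs, truth.json
phosphoquant run --psms demo/psms.tsv --proteome demo/source.fasta \
    --human demo/human.fasta --pairs demo/ortholog_pairs.tsv \
    --out demo/results.tsv
```

The same command on the repository's hand-built 50-PSM fixture
(`tests/data/toy_*`, adding `--known-sites tests/data/toy_known_sites.tsv`)
prints this summary:

```json
{
 "filter": {
  "estimated_fdr": 0.022222222222222223,
  "n_accepted": 45,
  "n_input": 50
 },
 "n_ambiguous_sites": 1,
 "n_localized_ptyr_sites": 5,
 "n_quantified_sites": 6,
 "n_significant_ls": 3,
 "n_significant_ns": 5,
 "normalization": {
  "median_heavy_over_light": 2.35,
  "median_medium_over_light": 1.38,
  "n_nonphospho_used": 37
 },
 "quadrant_counts": {
  "downstream_model": 0,
  "ls_only_down": 0,
  "ls_only_up": 1,
  "ns_only_down": 1,
  "ns_only_up": 2,
  "shared_down": 1,
  "shared_up": 1,
  "substrate_model": 0,
  "unchanged": 0
 }
}
```

(The logged warning about the 2.2% estimated FDR is the fixture's
filter-passing decoy: 1 decoy against 45 accepted targets.)

and this results table (abridged — the file also carries `significant_ns`,
`significant_ls` and `n_psms` columns):

```
protein                       accession    peptide          site_source  site_human  log2_ns_wt  log2_ls_wt  quadrant
receptor B-like               PROTB        MEGVV(pY)ADLR    Y26          Y29         2.95        1.77        shared_up
kinase A-like                 PROTA        DDSA(pY)LQGK     Y23          Y21         1.50        0.40        ns_only_up
kinase A-like                 PROTA        NQSE(pY)FDTK     Y32                      1.20                    ns_only_up
kinase C-like; kinase D-like  PROTC;PROTD  GGE(pY)TVVMK     Y5; Y12      Y5; Y11     0.00        1.92        ls_only_up
receptor B-like               PROTB        TSPLYQDEK        Y16          Y19         -1.18       -0.48       ns_only_down
kinase A-like                 PROTA        SAMPD(pY)INK     Y15          Y13         -1.91       -1.47       shared_down
```

Reading the rows: the normalization factors recovered the 1.38/2.35 channel
mixing exactly, so the Log2 columns are true phosphorylation changes.
`(pY)` marks a localized phosphotyrosine; `TSPLYQDEK` carries no mark
because no candidate reached 75% — its coordinate (Y16) comes from the
offline known-site table. `Y5; Y12` is one shared peptide reported per
paralog, and the row with an empty LS column had a missing heavy channel.
The last row — down more than 3.7-fold in NS and 2.8-fold in LS — is the
kind of shared-decrease site (a Fer-kinase analog in the fixture) that the
quadrant view is designed to surface.

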