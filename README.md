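# eladkit

Toolkit for calling and analysing **euchromatin lamin B1-associated
domains (eLADs)** — megabase-scale clusters of lamin B1 ChIP-seq sites
that sit in *active*, gene-rich chromatin, unlike the classical
heterochromatic lamina-associated domains (cLADs) — and for relating
them to genome architecture (Hi-C A/B compartments and TAD borders)
across experimental conditions such as a TGF-β-induced
epithelial-to-mesenchymal transition time course.

It is aimed at computational epigenomics users who have binned ChIP/IgG
coverage, expression tables, and cis Hi-C matrices, and who want a
transparent, fully testable pipeline rather than a chain of opaque
external callers. A first-class synthetic-data module generates genomes
with planted eLADs, cLADs, compartments and TADs, so every stage of the
analysis can be validated against known ground truth without any
download.

## What it computes

- **Lamin B1+ sites** (`eladkit.signal.call_sites`): per 1-kb bin, a
  one-sided Poisson test of the ChIP count *x<sub>i</sub>* against
  λ<sub>i</sub> = max(scaled control, scaled local control mean,
  pseudocount), Benjamini–Hochberg corrected; adjacent significant bins
  merge into peaks, kept if their aggregate fold enrichment ≥ 2.
- **eLADs** (`eladkit.domains.call_elads`): single-linkage chaining of
  peaks with inter-peak gap ≤ 100 kb; clusters with ≥ 3 sites become
  domains spanning first-peak start to last-peak end. Summaries report
  domain count, mean size and genome coverage.
- **A/B compartments** (`eladkit.hic.compartment_pc1`): leading
  eigenvector of the Pearson correlation of the distance-normalized
  (observed/expected) balanced contact matrix at 100 kb, sign-oriented
  so that A (PC1 > 0) is the gene-dense state; per-bin compartment
  changes between conditions.
- **TAD borders** (`eladkit.hic.insulation`, `call_borders`): insulation
  score = log2 of the mean contact in a 5×5-bin square straddling each
  40-kb bin over the chromosome mean; borders are prominence-filtered
  local minima with strength normalized to [0, 10] per chromosome;
  border conservation and per-border lamin B1 peak occupancy.
- **Integration statistics** (`eladkit.stats`): feature × landmark 2×2
  contingency tables with natural-log odds (Haldane–Anscombe-corrected
  only at zero cells) and two-sided Fisher exact p; binomial or
  permutation tests for peak enrichment at TAD borders; exact set
  algebra for target-gene dynamics across time points; FRAP
  double-normalization
  `[(ROI_b−ROI_bg)/(ROI_nb−ROI_bg)] / [(pbROI_b−pbROI_bg)/(pbROI_nb−pbROI_bg)]`.

## Worked example

Run the full synthetic pipeline (one 20-Mb chromosome, 16 planted eLADs
of mean 0.34 Mb, three conditions, 10⁶ reads per track):

```sh
eladkit run --seed 1 --outdir out/
```

`out/report.json` from that exact command contains, among others:

```
call_sites   n_peaks: untreated 586, tgfb_8h 577, tgfb_24h 580
elads        untreated: 16 domains, mean 308,688 bp, coverage 24.7%
             tgfb_8h:   16 domains, mean 328,750 bp, coverage 26.3%
             tgfb_24h:  16 domains, mean 337,125 bp, coverage 27.0%
dynamics     79 of 404 target genes (20%) keep lamin B1 in all three
             conditions; 80% change
compartments tgfb_8h vs untreated: 30 bins A→B, 0 B→A (seed-1 world
             plants 30 one-way flips at 8 h)
borders      26/25/23 borders; 84.6% conserved across conditions
integrate    eLADs in A compartment: log-odds +2.14 (p ≈ 2.4e-10);
             cLADs in B compartment: log-odds +4.82
```

Reading it: the domain caller recovers all 16 planted eLADs per
condition with mean sizes near the configured 0.34 Mb; only a fifth of
target genes keep lamin B1 across the time course because the simulator
retains just 28% of domains between conditions; and eLADs are strongly
enriched in the A compartment while cLADs sit in B, matching the
structure the generator plants.

Each stage is also exposed separately (`eladkit simulate`, `call-sites`,
`call-elads`, `compartments`, `tads`, `frap`) on bedGraph / BED / dense
matrix text files; see `eladkit --help`.

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch —
simulating the synthetic world from the given seed, calling sites and
eLADs in all three conditions, computing compartments, borders and the
integration statistics — validates the resulting report against the
expected schema, and writes the acceptance JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic world
and its defaults, numerical choices, and known limitations.
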