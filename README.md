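# chronocell

Single-cell transcriptomics of *Chlamydomonas reinhardtii* batch
cultures shows that even under constant light, individual cells occupy
different points of a ~24-h diurnal program, and that this hidden
heterogeneity — not just nutrient state — dominates cell-to-cell
variation. `chronocell` is a tested, reusable Python implementation of
that analysis style for droplet scRNA-seq count data:

- **module scores** with expression-bin-matched random control genes,
  the workhorse statistic for reading a gene program (iron or nitrogen
  deficiency, cell division, photosynthesis, ribosome biogenesis, ...)
  in single cells at shallow coverage;
- **nutritional-state classification** from those scores, including a
  Gaussian-mixture bimodality diagnostic (Ashman's D) for mixed
  populations and the fraction of cells with a positive cell-division
  score;
- a **molecular timetable**: non-overlapping diurnal phase-bin gene
  sets built from a gene → peak-phase table (half-hour grid, dawn = 0),
  scored per cell, and inverted into a per-cell internal-time estimate
  on the 24-h circle;
- **circular pseudo-time** ordering of cells around the diurnal cycle,
  anchored so the cell-division signature sits at 12–14 h;
- a **phase-shift permutation test** for clock delays between
  conditions (e.g. iron-starved vs replete cultures);
- Wilcoxon rank-sum + Benjamini–Hochberg **differential expression**;
- a **negative-binomial simulator** with full latent truth (per-cell
  phases, condition regulons, division states, gene peak phases) so
  every stage is testable without any data download.

## The core statistic

For a gene set $S$ and log-normalized expression $x_{cg}$, all genes
are ranked into $B$ equal-frequency bins by mean expression; each
member $g \in S$ draws $n_{\mathrm{ctrl}}$ control genes from its own
bin (excluding $S$), pooled into $C$. The module score of cell $c$ is

$$m_c = \frac{1}{|S|}\sum_{g \in S} x_{cg} \;-\; \frac{1}{|C|}\sum_{g \in C} x_{cg},$$

i.e. enrichment of the program over expression-matched background.
Scoring the 13 phase bins (centers 0, 2, …, 24 h) gives each cell a
score profile around the clock; its phase is read off by a signed
first-harmonic projection of that profile, recentered across cells by
a least-squares circle fit (see `docs/methods.md` for why the
recentering matters in phase-crowded populations).

## Worked example

`examples/03_iron_phase_delay.py` injects a 2-h clock delay into a
simulated iron-starved sample and recovers it from a single snapshot:

```
estimated shift Fe- minus Fe+: +1.98 h (injected: +2.00 h)
permutation p-value: 0.000999 (1000 permutations)
group circular means: Fe+ 6.02 h, Fe- 8.00 h
```

The per-cell phase calls behind that estimate are accurate to a
fraction of an hour (`examples/02_molecular_timetable.py`):

```
cells called: 2000/2000
circular MAE vs hidden truth: 0.31 h
dawn (0 h) vs cycle-end (24 h) column correlation: 0.77
```

The other examples cover module scoring / bimodality
(`01_module_scores.py`) and the full pipeline with its run report
(`04_full_pipeline.py`). A thin CLI wraps the same library calls:

```bash
chronocell run-all --demo --seed 0 --out pipeline_out
chronocell simulate --out simdir --n-cells 500 --seed 1
chronocell phase --counts simdir --phase-table simdir/phase_table.tsv \
    --out calls.tsv --compare Fe+ Fe-
```

All pipeline artifacts are plain TSV/MatrixMarket files, and a rerun
with the same seed reproduces them byte for byte.

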