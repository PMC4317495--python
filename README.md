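# adhesiomics

Quantitative analysis of integrin activation state-dependent adhesion
complexes. Integrins switch between active (ligand-competent) and inactive
conformations, and the protein complexes that assemble around each state can
be isolated with conformation-specific antibodies and profiled by mass
spectrometry. This package implements the downstream analysis of such
experiments as a tested, reusable library:

* **Spectral-count quantification** (`adhesiomics.quantify`) — normalized
  spectral counts `NSC_is = SpC_is / (T_s · M_i)` (spectral count over the
  run's total spectra `T_s` and the protein's molecular weight `M_i`),
  technical replicates summed within biological isolations, fold enrichment
  `mean NSC_active / mean NSC_inactive` with `U` sentinels for single-state
  detection, a calibrated G-test differential flag at 5% FDR, and the
  presence-Venn / +TIP / adhesome summary statistics.
* **Profile clustering** (`adhesiomics.clustering`) — complete-linkage
  agglomeration under the uncentred Pearson similarity
  `r = Σxy / √(Σx²·Σy²)`, cluster extraction at a similarity threshold
  (`r ≥ 0.80`), and labelling of clusters as active / inactive / unenriched
  from median log₂ fold change.
* **Interactome analysis** (`adhesiomics.network`) — merged simple
  undirected interaction graphs (self-interactions excluded), breadth-first
  hop distances from a seed integrin (ITGB1), functional-class summaries and
  neighbourhood-intersection candidate nomination.
* **Overrepresentation statistics** (`adhesiomics.enrichment`) —
  hypergeometric (Fisher) and EASE p-values, Bonferroni correction, the
  keyword filter (fold enrichment ≥ 1.5, Bonferroni P < 0.05, EASE < 0.05,
  ≥ 2 proteins), a 100-randomization false discovery rate, and the
  log₂-fold-change functional enrichment map over 5–500-protein terms.
* **Cortical microtubule dynamics** (`adhesiomics.cortical`) — 5 × 2 μm
  peripheral counting boxes tiling the cell edge, rolling-ball-filtered
  micropattern patch intensities, per-frame tip-to-edge distances, residence
  lifetimes within 2 μm of the periphery at a 10 s frame interval,
  displacement summaries and ≥ 40 μm² signal-area fractions.
* **Synthetic data** (`adhesiomics.synthetic`) — generators for every input
  above: over-dispersed counts with planted enrichment classes, scale-free
  interactomes, annotation collections with planted terms, two-state tip
  trajectories with regime-dependent cortical dwell, and micropattern
  images (2 μm patches on a 9 μm square lattice).

## Worked example

`examples/cortical_residence.py` simulates microtubule tips in a 20 μm
circular cell under stimulatory (mean cortical dwell 6 frames) and
inhibitory (2 frames) integrin signalling and measures residence within
2 μm of the edge:

```
stimulatory: median residence 110 s, mean 119 s
inhibitory: median residence 30 s, mean 35 s
one-sided rank test stimulatory > inhibitory: P = 1.76e-31

32 peripheral boxes on a 40 um square cell; microtubule density 0.50 +/- 0.71 per box
```

Microtubules under stimulatory signalling remain several times longer at
the cortex — the planted regime difference is recovered from the simulated
trajectories by the same distance/residence operations applied to real
tracks. The other scripts in `examples/` walk through quantification,
clustering, hop analysis and the enrichment map in the same style.

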