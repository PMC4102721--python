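# homoeopool

Building BAC contigs for homoeologous regions of an allopolyploid genome
from intergenomic-SNP screens of multidimensional clone pools.

In an allopolyploid (AACC) genome every region exists in two homoeologous
copies a few percent diverged. SNPs that differentiate the A and C
(sub)genomes — *intergenomic* SNPs — both identify homoeologous clones
and tell the copies apart, which makes them ideal markers for screening a
pooled BAC library. This package implements that workflow end to end for
people developing or evaluating pooled-library screening designs:

- **discovery** of assay sites from progenitor-genome alignments (HSP
  suitability filters with off-target exclusion, conservative
  survey-sequence contig assembly, per-column flank/clearance rules,
  verification of candidate sites in the amphidiploid);
- **calling** of per-pool two-colour genotyping signals by thresholds
  (normalised R >= 0.2; Theta <= 0.05 / >= 0.95 for the alternative
  nucleotides, intermediate = both);
- **deconvolution** of positive pools into putative clone coordinates —
  a coordinate is reported for a nucleotide iff all seven of its pools
  are positive for it (group testing), with an exhaustive per-coordinate
  oracle kept alongside the optimised decoder;
- **subgenome assignment** of assay nucleotides (evidence categories
  1–5, with clone-based inference for the pending categories) and of
  clones (consensus with conflict reporting);
- **selection, validation and contig building**: rule-based clone
  selection, oracle (amplicon) validation, contigs as connected
  components under shared confirmed markers, false-negative recovery by
  fixed-point refinement, and contig bridging/extension;
- a **synthetic-data generator** producing every input with ground truth
  retained: diverged progenitor regions, the amphidiploid, a 10x
  82,944-clone library, the seven-dimension pooling design, noisy
  R/Theta signals, reference-panel evidence and a validation oracle.

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_build_contigs.py` (a 1,152-clone library, 100 kbp
regions, 20 assays, default noise) prints:

```
selected clones: 977 of 1119 putative
false-positive scores among selected: 5391
recovered false-negative scores: 52
contigs: A 2 (true 2), C 1 (true 1)
tiling recall: 99.7%

markers: a01 a02 a03 a04 a05 a06 a07 a08 a09 a10 a11 a12 a13 a14 ...
[A-1] markers 0-13, 23 clones
     736 #...................
     387 #-#.................
    1074 #-#.................
     185 ..####..............
...
```

Most putative coordinates are *shadows* — coordinates whose seven pools
are all covered by the union of true positives — which is why far more
scores are decoded than are true, why validation discards thousands of
false-positive scores, and why the final contigs nevertheless recover
99.7% of the true clone/marker tiling with the true number of contigs
per subgenome. In the diagram each `#` is a confirmed marker of a clone
and `-` an interior marker of its span without confirmation.

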