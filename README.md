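# eqtlcross

Genome-wide eQTL linkage analysis for F2 line crosses.

`eqtlcross` is for quantitative geneticists analyzing expression data
from a cross between two lines assumed fixed for alternative QTL alleles
(the motivating design is a three-generation Duroc x Pietrain pig
population: purebred F0 grandparents, F1 parents, genotyped F2 offspring
profiled on two-color microarrays with a litter-extreme selective
phenotyping scheme). It covers the full analysis path:

1. **Synthetic cross simulation** — pedigree, microsatellite-like
   genotypes with recombination, selective-phenotyping array design with
   balanced dyes, expression and phenotype data with known ground truth.
2. **Breed-of-origin probabilities** — for every F2 and scan position,
   the posterior (pDD, pDP, pPP) over homolog origins from
   three-generation marker data, and the additive line-cross coefficient
   `c_a = pDD - pPP`.
3. **Two-color normalization** — within-print-tip loess location
   normalization plus MAD scale normalization, no background correction.
4. **Mixed-model scan** — per transcript,
   `Y = mu + Dye + Sex + growth_group + c_a·a + Array + Litter + e`
   with REML variance components estimated once under the null and a GLS
   t-test of the additive effect `a` at every position (every marker and
   k = 11 inter-marker points; 124 markers in 19 linkage groups give
   1,279 positions, and with a 20,400-probe manifest over 26 million
   planned tests).
5. **Significance** — Storey q-values across all trait x position
   tests, linkage-peak calling from contiguous significant runs, hotspot
   counts against the `n_traits x alpha` null expectation.
6. **Annotation** — probe positioning from alignment records (<= 3
   mismatches, multi-hits discarded) and local / distant / unpositioned
   eQTL classification.
7. **Co-localization** — 5 cM regions around eQTL and pQTL peaks,
   overlap detection, and the uniform-center overlap probability
   `p = 2d/G - (d/G)^2` on a 3,000 cM genome, with a Monte-Carlo null.

The scan is exposed scikit-learn style (`EQTLScanner.fit`,
`TwoColorNormalizer.transform`, `get_params`/`set_params`, fitted
attributes with trailing underscores) so it composes with sklearn
tooling; module-level functions wrap the same machinery.

## Worked example

```python
from eqtlcross.io import SimulationConfig
from eqtlcross.pipeline import run_pipeline

cfg = SimulationConfig(seed=1)          # 44 litters, 176 F2, 500 probes
res = run_pipeline(cfg, "out/", k_intermediate=1)
peaks = res["peaks"]
print(len(peaks), (peaks["classification"] == "local").sum())
```

This simulates the full study (10% of probes carry an eQTL of additive
effect 0.5 on log2 scale, residual variance 1), scans all 500 transcripts
at 247 grid positions, and prints

```
samples: 176  probes: 500  grid positions: 247
peaks: 43 | local: 21  distant: 22
      trait chromosome  peak_cM       peak_p   peak_q       h2 breed_overexpressed classification
probe_00014          3     24.0 1.458789e-05 0.031102 0.097290               Duroc        distant
probe_00022          7     12.0 8.797758e-07 0.004112 0.113445            Pietrain        distant
probe_00026         11      0.0 6.646840e-09 0.000162 0.152807               Duroc          local
```

Each row is one collapsed linkage peak: its chromosome and cM position,
the peak p- and q-value, the fraction of variance `h2` attributed to the
eQTL, which breed's allele is over-expressed (the sign of `a`), and
whether the peak lies on the probe's own chromosome (local, putatively
cis-acting) or elsewhere (distant, trans-acting). At the exploratory
threshold P < 1e-4 roughly `500 probes x 247 positions x 1e-4 ≈ 12`
false-positive tests are expected, so a minority of the distant peaks
here are noise — mirroring why the confirmatory tier P < 3.5e-6 exists.

All outputs are written as TSV/BED/JSON under `out/`
(`scan_profiles.tsv`, `peaks.tsv`, `hotspots.tsv`, `overlaps.tsv`, ...).
The same stages are scriptable from the shell:

```bash
eqtlcross simulate --seed 1 --out out/
eqtlcross scan --expr out/expression.tsv --design out/design.tsv \
               --coef out/ca_matrix.tsv --out profiles.tsv
eqtlcross colocalize --eqtl out/peaks.tsv --pqtl out/pqtl_peaks.tsv \
                     --map out/map.tsv --out regions.tsv
```

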