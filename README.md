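# refstab — reference-gene validation for RT-qPCR

Relative quantification by RT-qPCR stands or falls with its normalization:
target-gene expression is reported relative to "housekeeping" reference
genes that are assumed constant across every sample and condition. That
assumption is routinely violated — classic references such as GAPDH or 18S
rRNA shift under injury, disease or treatment — so candidate reference genes
must be validated on the actual study design before they are trusted.
`refstab` implements the complete geNorm-style validation workflow for
anyone running multi-condition qPCR panels (the built-in simulator emulates
a longitudinal nerve-injury study: 7 candidate genes, 7 timepoint groups of
3 subjects, triplicate wells), and works equally on any gene × sample Cq
table.

## The statistics

Starting from well-level quantification cycles Cq, with per-gene
amplification efficiency *E* (estimated from serial dilutions via the slope
of Cq against log₁₀ template amount, *E* = 10^(−1/slope) − 1):

- **Relative quantity**: per gene, Cq values are rescaled to the gene's
  lowest Cq (internal control) and linearized,
  RQ = (1+E)^(Cq_anchor − Cq_sample); technical replicates are averaged
  arithmetically.
- **M-value** (expression stability): for gene *j*,
  M_j = mean over k≠j of SD_samples( log₂ RQ_j/RQ_k ), using the n−1
  standard deviation. Stable genes have low M; the heterogeneous-panel gate
  is M < 1.0.
- **CV**: σ/μ of a gene's relative quantities; second gate, CV < 50%
  (homogeneous panels: M < 0.5, CV < 25%). A gene is validated only if both
  gates pass.
- **Stepwise ranking**: the highest-M gene is eliminated and M recomputed
  until two genes remain; those two are reported as a tied best pair.
- **Pairwise variation** V(n, n+1) = SD_samples( log₂ NF_n/NF_{n+1} ), where
  NF_n is the geometric mean of the n most stable genes' RQs. The smallest n
  with V < 0.15 is the number of reference genes needed; V(2,3) < 0.15 means
  any validated pair suffices.

## Worked example

```python
import refstab as rs

table, efficiencies, truth = rs.simulate(
    rs.default_study_config(seed=1, unstable_gene="GAPDH")
)
filtered, qc_log = rs.qc_filter(table)              # Cq <= 30, 0.5-cycle spread
rq = rs.to_relative_quantities(filtered, efficiencies)

trace = rs.rank_genes(rq)
vseries = rs.pairwise_variation_series(rq, trace, threshold=0.15)
print("eliminated (worst first):", " -> ".join(trace.eliminated))
print("recommended pair:", " + ".join(trace.final_pair))
print("V(2,3) = %.4f, recommended n = %d" % (vseries.entries[0][1], vseries.recommended_n))
```

prints

```
eliminated (worst first): GAPDH -> RPL29 -> RPL13a -> 18S -> HMBS
recommended pair: Actb + HPRT1
V(2,3) = 0.0510, recommended n = 2
```

GAPDH was simulated with a condition-dependent expression drift ramping to
1.5 cycles, and the stepwise ranking eliminates it first; the remaining
panel is so coherent that V(2,3) sits far below the 0.15 threshold — two
reference genes are enough. The `examples/` directory holds one short
script per capability (simulation, QC + relative quantities, stability
gates, ranking + minimal gene count, efficiency fitting), each printing and
explaining its numbers.

The same pipeline is available from the shell:

```sh
refstab simulate --out data/ --seed 1
refstab analyze --cq data/cq_long.csv --eff data/efficiencies.csv --out results/
refstab efficiency --series dilutions.csv
```

`analyze` writes the QC log, RQ matrix, stability report, ranking trace,
V series and a markdown summary.

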