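# Methods

## Model and procedure

`refstab` validates candidate RT-qPCR reference genes in five stages.

**1. Quality control.** Well-level Cq values above a ceiling (default 30
cycles, the upper end of the trusted quantification range for a
SYBR-green assay) are removed. Within each (sample, gene) triplicate, if
the replicate range exceeds a spread tolerance (default 0.5 cycles) the
replicate farthest from the group median is removed, iteratively, until the
range is within tolerance or one replicate remains. This rule is
deterministic and order-independent; the tolerance is a package decision —
instrument software flags "doubtful curves" qualitatively, and 0.5 cycles
is the widest spread a clean triplicate plausibly shows. On a tie in
distance from the median the higher Cq (weaker signal) is dropped. A group
can only be emptied by the Cq ceiling; that raises an error naming the
group. Samples left without a complete gene set are dropped with a warning
(configurable to a hard error), because every downstream statistic needs a
full gene × sample grid.

**2. Relative quantification.** Per gene g the anchor A_g is the minimum
Cq over all of g's wells; each well contributes
RQ = (1+E_g)^(A_g − Cq). Per (sample, gene) the replicate RQs are averaged
arithmetically. Averaging Cq before linearization (geometric-mean
behaviour) is available via `replicate_average="cq"` but off by default.
The anchor choice (minimum well vs minimum sample mean) is immaterial for
every ratio-based statistic downstream — both differ by a per-gene constant
that cancels — so the well-level minimum is used; it also guarantees
RQ ∈ (0, 1]. Efficiencies are per gene *and per tissue dataset*; a run
analyzes one tissue at a time. No inter-run calibration is applied: under a
sample-maximization plate layout (all samples of one gene in one run) run
effects are gene-constant and cancel in ratios.

**3. Stability gates.** M_j is the mean over other genes k of the n−1
standard deviation across samples of log₂(RQ_j/RQ_k); CV_j is σ/μ of gene
j's RQ row. Log base 2 is fixed (the geNorm convention); changing the base
rescales every M uniformly and would make M-values incomparable with the
published cut-offs. Cut-offs are strict inequalities: M < 1.0 and CV < 0.50
for heterogeneous panels (samples pooled across all conditions), M < 0.5
and CV < 0.25 for homogeneous ones. CV is computed on relative quantities,
not on normalized quantities (a config flag exists for the latter
convention). Both gates must pass for validation — a gene that co-varies
with the panel can carry a deceptively good M while swinging widely on its
own, which only CV catches.

**4. Ranking.** Stepwise elimination of the argmax-M gene with
recomputation at each step, down to a final pair. The last two genes have
identical M by construction (one shared ratio), so they are reported tied;
`full_order` lists the tied pair (alphabetical) first, then the eliminated
genes in reverse order. Exact M ties are broken by eliminating the
lexicographically last label, and the tie is flagged in the trace. An
optional per-condition ranking produces one trace per group.

**5. Minimal number of reference genes.** NF_n is the per-sample geometric
mean of the top-n genes' RQs, genes added in `full_order`. V(n, n+1) is the
n−1 SD across samples of log₂(NF_n/NF_{n+1}), for n = 2 … G−1;
`recommended_n` is the smallest n with V below the threshold (default
0.15), or G if none. `worst_pair_check` repeats V(2,3) using the *least*
stable validated genes: if even that pairing stays below threshold, any
validated pair is a safe normalizer. The check needs at least three
validated genes — the statistic compares the worst pair's NF with the NF
after adding a third gene — so it raises below that, including the
borderline two-gene case.

## Synthetic data

The generator emulates a longitudinal nerve-injury validation study: 7
candidate genes (18S, Actb, GAPDH, HMBS, HPRT1, RPL13a, RPL29), 7 condition
groups (naive plus post-surgery days 2–21) of 3 subjects, triplicate wells.
Noise is additive on the Cq (log-expression) scale:

    Cq = baseline_g + S_j + effect_g(condition) + N(0, σ_bio,g) + N(0, σ_tech)

with defaults σ_tech = 0.1 and σ_bio = 0.2 cycles — consistent with
triplicates that pass a 0.5-cycle spread filter — and a subject-wide
template-content shift S_j ~ N(0, 0.15 cycles) common to all genes.
Efficiencies (0.70–0.89) match a realistic validated primer panel;
baselines sit in the 15–25 Cq range (rRNA most abundant) so stable genes
never trip the 30-cycle ceiling. Condition effects are deterministic
per-condition shifts (fixed effects); the stock instability is a linear
ramp from 0 to 1.5 cycles over the post-surgery days, and a gene is labelled
unstable iff any effect is nonzero.

What this does and does not show: content shifts cancel from M but inflate
CV, exactly as in real data, and injected instabilities are recovered by
the ranking; but real assays add non-Gaussian tails, inhibitor-dependent
efficiency drift, inter-plate effects and pipetting outliers that the
Gaussian Cq model does not emulate. Passing the simulation-based tests
demonstrates the statistics and their sensitivity, not assay robustness.

## Numerical choices

- n−1 (sample) standard deviation everywhere, matching the original geNorm
  implementation; `ddof` is exposed for sensitivity checks.
- Efficiency fits use ordinary least squares of Cq on log₁₀ relative
  template amount (amount = 1/dilution factor); a nonnegative slope is
  rejected as unphysical. Noiseless series invert to machine precision.
- Efficiency files accept percent or fraction scales; auto-detection treats
  values above 1.5 as percent (no plausible fraction exceeds 1.1, no
  plausible percent is below 50). Valid range (0, 1.1]: slightly
  super-unity values arise from regression noise and are tolerated.
- Report files round floats to 6 significant digits; pass/fail decisions
  are made before rounding and are stable under it (tested).
- Degenerate inputs: zero-noise simulations yield exactly M = CV = 0; a
  two-gene panel has M_A = M_B = V(A,B); ranking requires ≥ 3 genes.

## Problem sizes

Simulation-based checks (unstable-gene recovery, all-stable validation
rate, efficiency recovery under noise) use 100 seeded runs of the
study-shaped design each, the package's standard batch for rate estimates;
each run is a full pipeline pass over 441 wells.

## Known limitations

- No inter-run calibrator handling; data from sample-maximized layouts (or
  already calibrated exports) are assumed.
- No melting-curve, no-template or no-RT control analytics; these remain
  upstream flags.
- No alternative stability statistics (NormFinder, BestKeeper) and no
  bootstrap uncertainty on ranks.
- The final ranked pair is inherently undiscriminated; an optional CV sort
  is display-only.
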