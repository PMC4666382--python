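# Methods

## The blocking model

A blocker hairpin anneals a targeted miRNA's 5′ prefix to its
single-stranded overhang so that the miRNA's 5′ phosphate abuts the
hairpin's free 3′-OH as a nick in a DNA:RNA hybrid. T4 DNA Ligase seals
that nick only under restrictive geometric conditions, and the whole
off-target model reduces to three sequence rules applied at the
junction:

1. **Nick-pair rule.** The base pair at the nick (species position 1
   against the overhang's 3′-most base) must be Watson–Crick. A
   mismatch there is never sealed, regardless of downstream similarity
   → class `ESCAPE`.
2. **Contiguity rule.** From the junction inward, the species must run
   contiguously complementary to the overhang for at least
   `full_block_min` bases for full blocking (`BLOCKED`), or at least
   `partial_min` bases for partial blocking (`PARTIAL`). Matching is
   strict Watson–Crick; G:U wobble is not credited.
3. **Register rule.** Only two annealing registers are productive:
   register 0 (sealable nick) and register +1 (one-base gap, sealed
   inefficiently → at most `PARTIAL`). A 5′ extension creates an
   unligatable flap, and shifts of two or more bases leave no junction
   (`NONE`). Ties prefer register 0.

Because the overhang is constructed as the exact reverse complement of
the target's first *k* bases, "complementary to the overhang from the
junction" is equivalent to "identical to the target's 5′ prefix", and
the classifier is implemented on that identity. The test suite checks
it against an independent brute-force oracle that enumerates registers
over the physical overhang with an explicit base-pairing table.

Each class maps to a ligation efficiency — the fraction of that
species' molecules covalently capped — via a configurable map. This is
the only place the model leaves pure sequence logic; efficiencies are
model parameters, not measurements.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `overhang_length` (*k*) | 12 | nt | the validated overhang size; configurable 8–16 with a warning outside 10–14, since only 12 has been demonstrated |
| `stem` / `loop` | `GCAGCCTG` / `GAAA` | — | any self-complementary stem works mechanistically; an 8-bp GC-balanced stem plus a stable GAAA tetraloop is a conventional, orderable choice. `check_design` guards against overhang–stem cross-pairing (≥ 6 contiguous bases) and overhang self-dimerization |
| `full_block_min` | 8 | nt | calibrated to the observed family behaviour: 9-base 5′ identities are fully blocked while a 7-base identity is only partially reduced |
| `partial_min` | 6 | nt | lower edge of the partial regime; a 7-base match classifies `PARTIAL`, shorter similarity is ignored |
| efficiency `BLOCKED` | 0.995 | fraction | the smallest round value for which a species at 60% of input reads falls below 1% of the post-blocking library: residual fraction is (1−e)f/(1−ef), and e must exceed ≈0.9934 at f = 0.6 |
| efficiency `PARTIAL` | 0.5 | fraction | "moderate fold-change" regime of gap/short-match junctions; a knob, not an estimate |
| efficiency `ESCAPE`/`NONE` | 0.0 | fraction | unsealed junctions leave the species untouched |
| analysis `depth` | 6 000 000 | reads | the common down-sampling depth used for library comparisons |
| detection `threshold` | 10 | counts | the conventional detection cutoff |
| fold-change pseudocount | 0.5 | counts | symmetric, standard; keeps log2 ratios finite at zero counts |

Oligo rendering uses the DNA alphabet (ligation happens on a DNA:RNA
hybrid; all matching logic runs in normalized RNA). The overhang Tm is
a Wallace-rule approximation (2·AT + 4·GC) and is informational only —
there is no thermodynamic acceptance criterion.

The 3′-blocking geometry (3′ overhang, 5′ phosphate, 3′ C3 spacer) is
constructed and rendered but deprecated: it costs roughly five-fold in
final library yield and 3′ ends of miRNAs are far more length-variable
than 5′ ends, so its off-target classification is deliberately not
implemented (`align_junction` raises with the rationale).

## Count operations

- **Down-sampling** draws reads without replacement (multivariate
  hypergeometric, numpy `marginals` method): reads are physical
  objects. A multinomial (with-replacement) mode exists for very large
  depths; it is off by default. A deterministic mode
  (largest-remainder rounding of expectations) supports exact tests.
- **Replicate averaging** is the count-preserving three-step
  procedure: down-sample both replicates to a common total, sum per
  species, down-sample the sum back to that total. The common total
  defaults to the smaller library total — the only value always
  feasible without replacement. Averaging a replicate with zero total
  is rejected.
- **In-silico blocking** thins each called species binomially with
  survival probability 1 − efficiency, matching the physical picture of
  independent per-molecule capping.
- **Detection gain** pairs samples present in both conditions, averages
  replicates within a condition, down-samples both sides to a common
  depth, and reports the per-threshold difference in species with
  count ≥ threshold (blocked − unblocked). Antisymmetric under
  swapping conditions.
- **Dispersion** is the method-of-moments solution of
  var = mean + α·mean², clamped at zero, computed per species across
  replicate libraries. It is a reproducibility descriptor, explicitly
  **not** a DESeq2-style shrunken/likelihood estimate, and output is
  labelled accordingly.
- **Fold-change concordance**: for every sample pair, per-species
  log2((a+0.5)/(b+0.5)) within each condition on depth-matched counts,
  filtered to species whose pair-mean count exceeds `base_mean_min`
  (default 10) in both conditions, then Spearman rho between the two
  conditions' fold-change vectors. Differential-expression testing
  (LRT, FDR) is out of scope.

## Synthetic cohorts

`simulate.simulate_cohort` emulates the statistical shape of plasma
miRNA libraries, not their biology:

- a log-normal abundance tail (default sdlog 2.0) reproduces the
  many-low/few-high scatter of real libraries;
- one dominant species (default hsa-miR-16-5p at 40%, the middle of the
  observed 20–60% range) with ±5 percentage points of uniform
  sample-to-sample jitter — a mechanism-free stand-in for hemolysis
  variation;
- replicate noise via gamma-perturbed proportions (variance α·p²,
  α = `nb_dispersion`, default 0.01) followed by a multinomial draw of
  exactly `depth` reads. Marginals are negative-binomial-like while
  every library sums exactly to the configured depth; at α = 0 the draw
  is a plain multinomial at the true proportions.

Defaults mirror the five-sample, two-replicates-per-condition plasma
design; tests and the acceptance script scale depth to 10⁴–10⁵ reads
and a few hundred species so the whole suite runs in seconds.

What the generator does **not** model: ligation sequence bias, isomiR
read-level structure, non-miRNA contaminant species, hemolysis
covariates, or any correlation between abundance and blockability.
Passing tests on synthetic cohorts therefore demonstrate the counting
machinery and the depletion arithmetic, not wet-lab efficacy on real
plasma.

5′-isomiR effects are handled separately: `simulate_isomir_table`
expands a species into weighted offset isoforms, `isoform_adjust`
re-classifies a junction call per offset (+1 → gap register, −1 → flap,
|offset| ≥ 2 → no junction), and `isoform_weighted_survival` gives the
aggregate surviving fraction of a mixed isomiR population.

## Numerical and design choices

- All stochastic functions accept either an integer seed or a numpy
  `Generator`; runs are bit-reproducible for a fixed seed. The CLI
  serializes the effective configuration next to every output.
- Classification is invariant under U/T input representation; all
  sequences are normalized to RNA on read.
- Multi-blocker reactions use union semantics — per species the
  maximum efficiency across blockers, no interaction term — matching
  the observed independence of combined blockers. A cross-check flags
  blocker pairs whose overhangs are mutually complementary over ≥ 8
  contiguous bases, which would titrate each other in solution.
- For a 7-base prefix match the register-0 partial call and a gap
  register are experimentally indistinguishable; the classifier prefers
  register 0 and records the ambiguity in the call's `note` field.
- Degenerate inputs are rejected loudly: down-sampling deeper than the
  library total, averaging against an empty replicate, efficiencies
  outside [0, 1], mismatched species sets, negative or non-integer
  counts (with coordinates).

## Known limitations

- Blocking efficiencies are class-level constants, not per-species
  thermodynamic predictions; concentration dose-response is not
  modelled (efficiency is the only knob).
- The classifier scans only the supplied mature sequences; species
  whose reads derive from precursor stem-loop regions (e.g. the
  hsa-miR-451b case) are caught only if that read region is supplied as
  an extra record.
- Dispersion and fold-change statistics are deliberate simplifications;
  they are comparable between conditions within this toolkit but not
  numerically comparable to DESeq2 output.
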