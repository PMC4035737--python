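# Methods

## Model

The predictor treats membrane insertion as a purely local, compositional
property: a 20-value amino-acid scale h(·) assigns each residue an
insertion propensity, and a candidate helix is scored by the arithmetic
mean of h over a fixed window of n = 23 residues (the typical span of a
membrane-crossing α-helix). The per-sequence statistic is the maximum
window mean (the *PMI value*). Two strict thresholds drive all
decisions: τ_first = 2.7 separates signal peptides from signal anchors
and admits the first TM segment; τ_next = 2.1 admits every subsequent
segment. "Exceeds" is implemented as a strict `>`: a score exactly at
the threshold is classified SP (not inserted). Both thresholds, the
window length, the inter-segment gap (2 residues) and the N-terminal
limit for the membrane call (140 residues) are exposed as parameters;
the defaults are the published operating point.

Assumptions worth stating: insertion propensity is additive and
position-independent within the window; segment length is fixed at n
(the scan never extends or trims a segment); and segments interact only
through the greedy left-to-right order and the minimum gap. These are
deliberate simplifications — families whose helices cooperate during
insertion (e.g. GPCRs) violate them and are out of scope.

## Topography scan

The scan walks window start positions 1..L−n+1. The first window with
mean > τ_first becomes segment 1 (residues [i, i+n−1]); the scan resumes
at start = end + gap + 1 and switches to τ_next. The first-segment scan
can optionally be truncated at the N-terminal limit (`limit_scan`); by
default the limit applies only to the membrane/non-membrane call, since
it models SRP engagement of the nascent chain, not helix insertion per
se. Sequences shorter than n are scored as a single whole-sequence
window with a warning rather than dropped; non-canonical letters score
0.0 (near the neutral region of both built-in scales) with a warning.

## Discrimination and AUC

TM is the positive class. AUC is computed as the Mann–Whitney
concordance probability via midranks, which is exact under ties —
preferable to trapezoidal integration of a sampled curve. ROC curve
*points* for export are taken from scikit-learn's `roc_curve`; a test
cross-checks the rank AUC against `roc_auc_score` and against a
brute-force pairwise count.

## Scale learning

Grouped steepest-ascent local search over the 20 scale values, starting
from the Kyte–Doolittle (1982) index (the standard published table; the
transcription was cross-checked by summing to −9.8). Groups
G1 = {F,L,I,V,Y,W}, G2 = {A,T,D,E,R,G,H}, G3 = {C,K,S,M,N,P,Q} are
optimized in order; for each step size δ in the schedule
[3, 2, 1, 0.5, 0.25, 0.1] the full neighborhood — all 3^|G| − 1
combinations of {unchanged, +δ, −δ}, identity excluded — is evaluated
and the best neighbor replaces the current scale only on a strict AUC
improvement, so the accepted-move trace is strictly increasing and the
search terminates. Ties among equal-best neighbors are broken by
enumeration order (alphabetical residues; per residue unchanged < −δ <
+δ), making the whole procedure deterministic with no random state. The
identity combination is excluded because it is the current solution;
including it would mask termination. Groups larger than 7 residues fall
back to single-coordinate moves (2·|G| neighbors) with a warning, since
3^|G| blows up. An optional `recycle` mode repeats the G1→G2→G3 pass
until a full pass accepts no move; the default is a single pass. A
`max_steps_per_phase` cap (500) guards against pathological inputs and
raises with the trace attached.

Neighbor evaluation is vectorized: each training sequence is reduced
once to a per-window residue-count matrix, so a window mean is
`counts · h / n`, the per-example score a segmented maximum, and each
neighbor costs one small matrix-vector product plus a ranking. A
dual-route test asserts the fast path reproduces the direct
window-scoring path's example scores to 1e-9. (The two paths can order
*exactly tied* examples differently at float precision, which shifts an
AUC by ~1e-5 on large tied datasets; the trace is therefore computed
consistently on the fast path.)

## Synthetic data

The generator emulates the *structure* of curated SP/TM training data,
not its full biological richness:

* TM examples: a hydrophobic core of 19–25 residues (I/L/F/V-rich, with
  some aromatic W/Y) flanked by 10 background residues per side, core
  coordinates recorded as ground truth.
* SP examples: at most 60 residues — n-region (1–5 residues, ≥1 K/R),
  h-region of 6–12 L/A/V-rich residues (critically *shorter* than the
  23-residue window, so its maximum window necessarily mixes in polar
  context), then polar c-region/filler.
* Topography proteins: background loops of 25–45 residues alternating
  with 23-residue TM cores.

The background is polar-enriched (D/E/K/R/N/Q/S/T/G/P/H at 0.068 each).
All compositions are overridable and validated to sum to 1. Randomness
flows through an explicit seeded `numpy` Generator.

What passing tests on this data do and do not show: the synthetic
classes are separable by construction (the h-region/window-length
mismatch mirrors the real compositional bias), so near-perfect AUCs here
validate the *machinery* — scoring, ranking, search — not real-world
accuracy. Real signal peptides have cleavage-site motifs, length and
composition variation, and annotation noise that the generator does not
model; published benchmark AUCs (≈0.80–0.93) are the realistic range.
The inverted-hydropathy fixture used in optimizer tests swaps the class
compositions but keeps within-class variance, so the initial
Kyte–Doolittle score distributions overlap; a fixture with a clean gap
between fully inverted classes would pin the AUC to exactly 0, a plateau
from which no single steepest-ascent move can escape, and would test
nothing about the search.

## Numerical choices

* Window means are computed per window over a strided view (pairwise
  summation), not by a running sum: identical windows then score
  bit-identically, so the "first window attaining the maximum" and
  threshold ties are exact. An O(L·n) pass is negligible at protein
  scale.
* Scale files store floats via `repr` for exact round-trips.
* Degenerate benchmark ratios (no predicted or no annotated segments)
  report 100% with a warning, keeping the raw TP/FP/FN counts available.
* Segment matching is one-to-one and greedy in sequence order with a
  minimum-overlap criterion (default 5 residues; the published
  benchmarks do not state theirs, so it is configurable).
* "Specificity" in the topography benchmark is segment-level precision
  TP/(TP+FP), the convention of TM-helix benchmark servers — not the
  true-negative rate.

## Problem sizes

The acceptance script trains on 305 TM + 700 SP synthetic examples and
evaluates on 130 TM + 300 SP (the shape of the original
training/test split), benchmarks topography on 120 annotated synthetic
proteins with 0–4 segments each, and completes in well under a minute on
one CPU; the full optimizer run accepts on the order of 10 moves.

## Known limitations

* No in/out topology, positive-inside rule, re-entrant or
  non-canonical helices; fixed 23-residue segments only.
* The learned scale is schedule- and path-dependent: re-running the
  search does not reproduce the published PMIscale values bit-for-bit,
  and the package does not attempt to.
* The published benchmark datasets are not bundled; the corresponding
  quantitative tests require a manual conversion step (see
  `tests/test_acceptance.py`).
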