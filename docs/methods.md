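# Methods

## The prediction problem

Trapped ion mobility mass spectrometry measures, for every peptide ion, an
inverse reduced mobility 1/K0 that kinetic theory converts into a collisional
cross-section (CCS, Å²) — the effective area the ion presents to collisions
with the drift gas. CCS is a reproducible physicochemical property of an
ion's gas-phase conformation, so an accurate in-silico predictor of peptide
CCS can be matched against the measured value to support or refute a
peptide-spectrum match. `ccspred` implements such a predictor together with
the preprocessing a real identification table needs before it can serve as
training data, and the feature computation that feeds predictions back into
percolator rescoring.

## Two-stage model

CCS grows with ion mass roughly as a square root within a charge state, and
the per-charge curves are well separated. The predictor therefore decomposes

    ccs_final(mz, c, s) = ccs_init(mz, c) + M(s, c, θ)

* **Baseline** `ccs_init(mz, c) = w_c·√mz + b_c`, fit separately per charge
  state c by closed-form linear least squares on the transformed regressor
  √mz (the model is linear in its parameters, so a generic curve search adds
  nothing but nondeterminism). Charges above `max_charge` (default 4) are
  excluded from fitting and prediction: higher charge states are too sparse
  to calibrate and downstream rescoring drops them too.
* **Residual network** M: a token embedding (default 128-dimensional) over a
  closed vocabulary of 30 tokens (20 amino acids; phospho-S/T/Y,
  carbamidomethyl-C, cysteinyl-C, oxidized M; plain and acetylated start
  tokens; end; padding), two bidirectional gated recurrent layers (128 units
  per direction), and a dense head (128 → 64 → 1) that receives the final
  recurrent state concatenated with a `max_charge`-way charge indicator.
  Dropout (rate 0.2) sits between the two dense layers. With defaults this
  is 540,161 trainable weights; the closed-form per-layer accounting is part
  of the test suite. The baseline parameters are carried by the model but
  are not registered with the optimizer — they are frozen by construction,
  and a test refits them to prove training never moved them.

The GRU uses the double-bias ("reset-after") gate parameterization, so each
direction of a layer holds 3·(in·u + u² + 2u) weights. The network is
implemented directly in NumPy (float64) with hand-written backpropagation
through time; the gradients of every layer are validated against central
finite differences in the test suite. Padded positions carry the previous
hidden state through unchanged, which makes predictions exactly invariant to
the amount of padding — asserted as a test property.

### Training procedure

Adam (initial learning rate 1e−3), mean absolute error objective, batch size
128. After each epoch the MAE on the full validation set is computed; after
three epochs without improvement the learning rate drops by a factor of ten,
and after three further non-improving epochs training stops. The weights of
the best validation epoch are restored at the end. MAE rather than MSE keeps
the objective on the same Å² scale as the reported errors and is robust to
the occasional mis-aggregated feature.

## Preprocessing

**Mobility conversion.** 1/K0 (Vs/cm²) is converted to CCS with the
Mason–Schamp relation, Ω = 3ze/(16·N0) · √(2π/(μ·k_B·T)) · 1/K0, with μ the
ion/gas reduced mass. Defaults are nitrogen drift gas (28.013 Da) at 305 K —
the timsTOF convention — overridable via `MobilityConstants`. The
implementation is checked against a frozen constant-by-constant hand
evaluation and is exactly invertible (`ccs_to_k0`).

**Deduplication and multimodality.** Identical (sequence, charge, CCS)
instances merge with summed occurrences. Within a (sequence, charge) group,
the main feature is the instance with the highest occurrence (ties broken
toward the lower CCS for determinism); σ is the occurrence-weighted
population standard deviation of all CCS instances in the group, computed
once on the full group. Instances within 2σ of the main feature fuse into an
occurrence-weighted mean — their spread is attributed to measurement
inaccuracy — while instances outside the boundary indicate additional
gas-phase conformers: they are counted as extra modes (re-clustering the
leftovers by the same rule) and dropped, because a regression trained on a
multimodal target would otherwise converge to the mode mean. The dropped
occurrence mass is retained on the aggregated record. The ≤ comparison on
the 2σ boundary carries a ~1e−12 relative guard: an equal-occurrence pair
sits mathematically exactly on the boundary (σ is half the gap) and must
fuse regardless of floating-point representation noise.

**Alignment.** Instruments and processing pipelines leave a small additive
offset between datasets. The shift is the unweighted mean of per-key CCS
differences over (sequence, charge) pairs present in both datasets
(occurrence-weighted variant behind a flag), applied to every target CCS.
Alignment is idempotent and exact for a constant offset.

## Tokenization and masses

MaxQuant-style `_(ac)M(ox)AAK_` and PEAKS-style bracketed mass deltas
(`S(+79.97)`) both map onto the same canonical token string
(`<START-ac> M-ox A A K <END>`). The vocabulary is closed: unknown
modifications raise a tokenization error naming the offending span, and
table readers skip and count such rows rather than guessing. Monoisotopic
residue masses come from pyteomics; modification deltas (phospho +79.96633,
acetyl +42.01057, carbamidomethyl +57.02146, oxidation +15.99491,
cysteinylation +119.00410 Da) are pinned constants.

## Scalar descriptors

Nine per-amino-acid scales — Zamyatnin residue volume, Grantham polarity,
Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, a percent-exposed-
residues scale, Chothia accessible surface area, Rose folded-state
accessible surface area, Bhaskaran–Ponnuswamy local flexibility, and
standard side-chain pK values — ship as a versioned CSV data file. A
sequence's descriptor is the sum of per-residue values divided by the
residue count; modified residues use their base amino acid's value (the
published scales cover only the 20 canonical residues). These composition-
only descriptors support correlation analyses of the learned residuals.

## Rescoring features

For a PSM with observed CCS o and predicted CCS p, the five features are
(o, p, o−p, |o−p|, 100·(o−p)/o). The plain error stays signed — systematic
over- and under-prediction are different evidence. Rows with charge > 4 are
removed from the rescoring input (the predictor is not trained for them) and
counted, as are PSMs without a matching prediction; untouched PIN columns
are preserved byte-for-byte, and re-augmenting an already augmented PIN is
refused via duplicate-column detection.

## Synthetic data: what it emulates and what it does not

The generator draws sequences uniformly over the residue vocabulary
(lengths 7–30), charges from {1: 0.10, 2: 0.50, 3: 0.30, 4: 0.10}, and
computes

    ccs = w_c·√mz + b_c + Σ_token effect(token) + N(0, σ)

with per-charge curves (w, b) = (14, 80), (17, 40), (21, 15), (25, 0) for
charges 1–4 — slopes growing with charge as on timsTOF tryptic data, placing
doubly charged ions near 400–550 Å² — and measurement noise σ = 5 Å²
(roughly 1% of a typical CCS). Token effects are additive in composition,
deliberately learnable by the recurrent model and analyzable by the additive
descriptors: bulky aromatics positive (+3…4 Å²), glycine/proline negative,
and the phospho tokens −25 Å². The phospho magnitude is chosen so that the
*net* observed difference between a phosphopeptide and its unmodified
counterpart — the −25 Å² sequence effect plus the ≈+13…15 Å² baseline
increase from the +80 Da mass at charges 2–4 — lands in the few-percent net
decrease reported for real phosphopeptides. Occurrence counts are uniform
on 2–12; a configurable fraction of features receives a second conformer at
+30 Å² separation with occurrence a fraction (default 0.3) of the main
mode's, so the main-feature rule is exercised non-trivially.

What the generator does **not** emulate: realistic amino-acid usage or
tryptic termini, positional (non-additive) sequence effects, charge-dependent
modification effects, intensity distributions, retention time, or
heteroscedastic noise. Passing tests therefore demonstrate that the
machinery recovers the structure it assumes — square-root baselines, additive
sequence residuals, occurrence-weighted modality — not that the shipped
configuration reaches any particular accuracy on real instrument data, which
requires training on real identification tables.

## Numerical choices and problem sizes

* All model arithmetic is float64; weight init is Glorot-uniform from a
  seeded generator; shuffling and dropout share the training seed, so a
  fixed seed reproduces training histories bit-for-bit.
* Exercised problem sizes: 5,000 ions for baseline recovery, multimodality
  recovery and training; a reduced model (embedding 32, GRU 32/32) and at
  most 20 epochs for the training checks, which recovers the residual
  structure on this data while keeping a single-CPU run in the order of a
  minute. The full-size default configuration differs only in widths.
* Aggregation ties (equal occurrence) break to the lower CCS; alignment with
  zero shared keys is an error rather than a zero shift; empty input tables
  produce an empty dataset plus a warning, not an exception.

## Known limitations

* The vocabulary is closed at 30 tokens; new modifications require a
  vocabulary release, because the embedding table's shape is part of the
  trained weights.
* Only an additive, dataset-level alignment is provided (no per-charge or
  nonlinear alignment).
* The NumPy training loop is single-threaded apart from BLAS; it is sized
  for the desk-scale datasets above, not for training on hundreds of
  thousands of peptides.
* Multimodality handling keeps only the main conformer; secondary modes are
  counted and their occurrence mass logged, but not emitted as records.
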