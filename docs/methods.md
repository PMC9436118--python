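# Methods

## The method in brief

AlphaFold2-class predictors read residue–residue co-evolution out of a
multiple sequence alignment (MSA) and fold toward the conformation that
co-evolution supports most strongly. When a protein populates several
conformations, the MSA encodes contacts from more than one of them; the
predictor usually returns only the dominant state. This package perturbs
that balance deliberately: it identifies the residues that mediate a chosen
interaction surface in an initial predicted model, substitutes them with
alanine *across every sequence of the MSA* (erasing that surface's
co-evolution signal while leaving the rest intact), and hands the edited
alignment back to the predictor. Repeating this for a window sliding along
the sequence produces an ensemble of models that samples alternate
conformations, which are then quality-filtered and summarized by coordinate
PCA.

The package orchestrates everything around the folding step. Folding itself
is behind a backend contract: a `colabfold_batch` adapter for real use, and
a deterministic mock backend for testing.

## Pipeline stages and their parameters

**Scan region.** Predicted models carry per-residue pLDDT (0–100 confidence)
in the PDB B-factor column. Both termini are truncated where pLDDT falls
below the mean over all residues; internal dips are kept. Only ends are
trimmed because terminal tails are the typical low-confidence artifact,
while internal flexible segments are part of the conformational signal.

**Window scan.** The region is tiled with non-overlapping windows of
`window_length` (default 11 residues, matched to the length scale of
transmembrane helices and domain edges; stride defaults to the window
length, and the final window is re-anchored at `end − window + 1` so no
residue is left uncovered). For each window, every residue pair with one
member inside the window and one outside is a contact when their closest
heavy atoms (all elements, side chains included, hydrogens ignored) lie
within `contact_cutoff` (default 4.0 Å — wide enough to cover polar, ionic
and water-mediated interactions). Partners within `sequence_exclusion`
residues of the window (default 4) are omitted so that local secondary
structure is not attacked. Both pair members enter the mutation set by
default (`mutate_side="both"`); window-only and partners-only variants are
available, since either reading of "mutate the interacting pairs" is
defensible.

**Targeted mode.** Instead of scanning, the user may supply two residue
groups (e.g. the N- and C-terminal halves of a transporter); the mutation
set is every residue participating in an inter-group contact within the
cutoff. An explicit residue list is also accepted verbatim.

**MSA mutagenesis.** a3m semantics: the query row is uppercase and gapless;
in every other row an uppercase letter or `-` occupies one match column per
query position, and lowercase letters (or `.`) are insertions with no query
equivalent. Mutation replaces the selected match columns with alanine in
every row, including the query (the mutant sequence is what gets folded),
except where the column holds a gap, which is untouched. Insertions are
never edited. Everything outside the selected columns round-trips
byte-identically. Alanine is the default because it is the least disruptive
residue for secondary structure; the substituted letter is configurable.

**Folding plan.** Each alignment (every mutated one plus the unmodified
original) is folded `runs_per_set` times (default 3) with a distinct random
seed per run, `models_per_run` models each (default 5): 15 models per set.
A campaign of *k* sets therefore expects `(k+1) × 15` models. Runs are
materialized on disk with a manifest; completed runs are skipped on resume
and individual failures are recorded without aborting the campaign.
Templates are always disabled in the adapter so the predictor is free to
build intermediates that no deposited structure shows.

**Set-level quality filter.** Misfolding caused by aggressive surface
removal shows up set-wide, so filtering operates on whole sets. Per-model
quality scores (MolProbity scores read from CSV, or the built-in clash
proxy) are pooled; with pooled median *M* and sample standard deviation *S*
(ddof = 1), any set whose mean score exceeds *M + S* is discarded.
Standard-error-of-mean semantics are available behind a flag for users who
read "standard deviation of the mean" that way; the default follows the
plain pooled-SD reading, which keeps the threshold independent of the pool
size. The relative score `(MP − MPmin)/MPmin` is reported for coloring
landscape plots.

**Clash proxy.** A clashscore-style count of van-der-Waals overlaps
(heavy-atom pairs from non-adjacent residues closer than
`r_i + r_j − 0.4 Å`, per 1000 atoms). It is *not* MolProbity — no
Ramachandran, rotamer or CaBLAM terms — and exists so the pipeline runs
without external scorers; the CSV reader is the intended production route.

**Ensemble metrics.** Superposition is least-squares on Cα (Kabsch, proper
rotations only). RMSF is computed about an iteratively refined mean: all
models are superposed on the first, averaged, re-superposed on the mean,
iterated until the mean moves < 1e-4 Å (max 100 rounds). TM-score uses the
fixed residue correspondence appropriate for same-sequence comparisons:

    TM = (1/L) Σ_i 1 / (1 + (d_i/d0(L))²),   d0(L) = 1.24·(L−15)^⅓ − 1.8

normalized by the reference length L (both normalizations are exposed; the
score is asymmetric), with d0 floored at 0.5 Å for short chains. The
maximization over superpositions seeds Kabsch fits from contiguous fragments
at halving lengths and refines each by the standard iterative distance
cutoff until the in-cutoff residue set is stable. Correspondence with
experimental structures is built by author-residue-number intersection, with
region exclusion supported (e.g. dropping a helix unraveled by crystal
contacts).

**PCA and outlier pruning.** PCA is an SVD of superposed Cα deviations from
the iterative mean; eigenvalues are coordinate variances (ddof = 0 about
that mean), their sum equals the total variance (checked to 1e-6 relative),
components are orthonormal with signs fixed so each component's
largest-magnitude entry is positive. Experimental references are superposed
onto the same mean and projected but excluded from the covariance by
default, so the landscape is model-derived and the references are guests on
it. The manual "remove apparent outliers, repeat" loop is automated: models
whose per-axis median/MAD-standardized (PC1, PC2) distance exceeds `k`
(default 3.5) are removed, the PCA refit from the retained coordinates
(including a fresh iterative mean), and the loop runs to a fixed point.
Manual exclusion lists are honored; removing every model is an error.

## The synthetic data generators

**Hinge toy.** Two antiparallel 20-residue arms (idealized backbone N, CA,
C, O at 3.8 Å Cα spacing plus a Cβ stub) joined by a 3-residue linker. In
the closed state alternating Cβ stubs on the two arms face each other 3.2 Å
apart — a genuine heavy-atom contact interface with no steric clashes —
and the interface disappears as arm B rotates open about the hinge (mode 1,
angle θ). An optional second mode sweeps arm B laterally about the
orthogonal axis (mode 2, angle φ), giving displacement fields in orthogonal
coordinate planes so the two modes remain orthogonal after superposition.
Models draw angles uniformly from (15°, 45°) and (−20°, 20°) by default and
add isotropic Gaussian noise (default 0.3 Å) to every atom. pLDDT is 88 in
the arms, 70 in the linker and 50 at the two terminal residues, so the scan
region genuinely truncates.

What the toy does **not** emulate: real side-chain packing, secondary
structure, or any sequence–structure relationship; its "misfolding" is a
score label, not a geometry. Tests passing on the toy demonstrate the
bookkeeping, geometry and statistics of the pipeline, not predictor
behavior on real proteins.

**Mock folding backend.** Returns hinge-toy models whose mean opening angle
is the generator's base angle plus `shift_degrees` (default 25°) times the
fraction of interface positions alanized in the submitted a3m's query row,
with 2° Gaussian jitter — a deterministic function of the file bytes and
run seed. This gives the end-to-end test a programmed causal link between
MSA mutagenesis and conformational output whose recovery can be asserted
quantitatively.

**Synthetic a3m / score tables.** Alignments with controllable per-column
gap probability, identity and lowercase insertion rate (match-column
conservation holds by construction); Gaussian per-set score tables with
optional upward-shifted outlier sets, defaulting to the 1.6–1.9 score range
typical of mostly-well-folded predicted models.

## Numerical choices and benchmark conditions

- Altlocs collapse to the highest-occupancy conformer; hydrogens are
  dropped on read; distances are therefore deterministic.
- Superposition refuses collinear point sets (rotation ill-defined) and
  never returns reflections.
- TM-score demands ≥ 15 correspondence pairs (the d0 formula's domain).
- The two-mode PCA recovery benchmark runs at 100 models and 0.3 Å noise.
  The recovery targets are computed from the generator itself: the mode
  subspace from central-difference tangent fields at the realized mean
  angles, and the per-mode generated variance from the essential-dynamics
  linearization (tangent-field norm² × realized angle variance). Two caveats
  are inherent to rigid rotations seen through least-squares superposition:
  the quadratic (1 − cos) component of a rotation is real variance that PCA
  assigns beyond the top components, and the PC2 direction carries a
  finite-sample error that scales like √(d·λ_noise/(n·λ₂)) across the ~3L
  noise directions. At the benchmark conditions the subspace angle is
  typically ~6–8° and the share mismatch a few percent, with occasional
  seeds reaching ~20% share error through quadratic leakage; the seeded
  tests pin representative conditions.
- The end-to-end mock campaign samples near-closed conformations
  (θ ∈ (1°, 5°)) because the toy's contact interface only exists near
  closure; the scanned model is the most closed of the five initial models
  (their pLDDTs tie in the toy, and the choice of initial model is exposed
  to the user in general). Its filter stage consumes externally supplied
  scores: in the toy, clash counts are confounded with hinge angle by
  construction, which would let the set filter discard sets for geometry
  rather than quality.
- The adenylate kinase open/closed benchmark (1AKE vs 4AKE chains A,
  ~7.2 Å Cα RMSD, TM ≈ 0.68) runs whenever the two PDB entries are
  available locally or downloadable; coordinates are not bundled with the
  package.

## Known limitations

- The ColabFold adapter relies on the installed `colabfold_batch` honoring
  `--random-seed`; without it, repeated runs of one MSA do not vary.
- TM-score here never searches alignments; comparing proteins of different
  sequence is out of scope.
- The clash proxy is a coarse stand-in for full geometry validation and
  should not be compared numerically against MolProbity scores.
- Set filtering assumes scores are comparable across sets (same scorer,
  same protein); mixing scorers invalidates the pooled threshold.
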