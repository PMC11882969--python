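# Methods

This note records the models, conventions and design choices behind
`cb1triage`, what the synthetic-data generators do and do not emulate, and
the numerical details a user would otherwise have to read out of the code.

## Hit triage

Fingerprints are radius-2 extended-connectivity circular fingerprints
(diameter 4 bonds, "ECFP4") folded to 2048 bits, without chirality — the
community-standard realization via RDKit's Morgan generator. Tanimoto
similarity is `|A∧B|/|A∨B|`, defined as 0 when both bitsets are empty.
cLogP is the RDKit Crippen estimator; because property thresholds are
estimator-dependent, every record carries the estimator name
(`rdkit-crippen`), and scores derived from cLogP (LLE, CNS MPO) should only
be compared within one estimator.

Clustering is *single-pass leader clustering* over the score-ranked list:
each molecule joins the first existing leader with Tc ≥ 0.5, else founds a
new cluster. Because the input is ranked, the leader is by construction the
best-scoring member (the cluster representative). Two properties follow and
are asserted in tests: every non-leader has Tc ≥ threshold to its leader,
and appending duplicates at the end never changes earlier assignments.
One property deliberately does **not** hold and is not asserted: leaders are
not guaranteed pairwise-dissimilar (a molecule similar to two leaders joins
the first). Sorting is the caller's contract; unsorted input is an error
rather than silently resorted, so ranking bugs surface.

The novelty filter removes candidates whose *maximum* Tc against the known
CB1R/CB2R ligand set is ≥ 0.36. The literature around this campaign quotes
both "retained below 0.38" and "excluded at ≥ 0.36"; the methods-level rule
(0.36 exclusion) is the default here and the threshold is configurable. An
empty reference set is an error, distinct from "keep everything".

Property windows (350–500 Da, cLogP 3–5) are inclusive at both ends. The
funnel applies, in order: top-N by score → leader clustering → cluster
representatives → novelty filter → polar-contact filter, and reports
per-stage survivor counts, which can only decrease. The visual-inspection
step of a real campaign is represented by the manual-review CSV export, not
automated.

## Pose analysis

The polar-contact filter passes a pose iff at least one polar ligand atom
(N or O by default; halogens excluded, configurable) lies within the contact
cutoff of at least one binding-site anchor atom. The default cutoff is 3.5 Å
heavy-atom-to-heavy-atom, a conventional hydrogen-bond distance; anchors
default to the side-chain polar atoms of the Ser/Thr/His triad lining the
orthosteric site (Ser OG, Thr OG1, His ND1+NE2), harvested from a PDB file
by residue number. An apolar ligand *fails* the filter with an explicit
reason; it does not raise, because that is a legitimate triage outcome.

The symmetry-corrected RMSD treats atoms of the same element as
interchangeable: for each element class, the optimal one-to-one assignment
between the two poses is found by solving a linear assignment problem with
squared-distance costs, and the RMSD is taken over all assigned pairs.
Assignment classes are element symbols only — no bond-topology automorphism
analysis — which matches the granularity of the established docking-suite
implementation of this idea and is exactly checkable against a brute-force
permutation oracle (tests enumerate all within-element permutations on
≤ 8-atom instances and require equality to 1e-10 Å). No superposition is
performed inside the RMSD: poses must already share a frame. For comparing
poses solved in different frames, a separate least-squares (Kabsch)
receptor-frame alignment on matched reference atoms (e.g. Cα of selected
residues) is provided. Hydrogens are ignored throughout, since experimental
models rarely place them reliably.

## Pharmacology

4PL fits run on log10 concentration with the parameterization
(baseline, Emax, log10 EC50, Hill). Initialization: Hill = 1, EC50 at the
geometric mid-concentration, plateaus at the data extremes; plateau bounds
are the data range padded by one span; EC50 is allowed 3 decades beyond the
tested range, and fits are to pooled replicate points by default (replicate
means are selectable). Standard errors come from the curve_fit covariance;
the EC50 confidence interval is formed on the log scale. Flat data, failed
optimization or a singular covariance yield `converged=False` with the
parameters absent — never a silently extrapolated number. On 200 seeded
synthetic curves (5 % noise, 3 replicates, 8 concentrations) the median
|log10(fitted/true EC50)| is ~0.04 and the 95 % CI covers the truth in
≥ 90 % of runs (both asserted).

Hit calling is strict: displacement must exceed 50 %; exactly 50 % is not a
hit. Values outside [−50, 150] % are flagged suspect but still classified.
Logs in the bias arithmetic are base 10 (the Δlog/10^Δlog convention). ΔΔG
uses R = 1.987×10⁻³ kcal/(mol·K) at a default 298.15 K; between 298 and
310 K the headline SAR anchor rounds identically, so the temperature choice
is not load-bearing. Cheng–Prusoff is the Ki conversion, with the
radioligand concentration defaulting to 0.75 nM and Kd supplied per batch.

The CNS MPO score hard-codes the published desirability knots: decreasing
ramps for cLogP (1 at ≤ 3 → 0 at ≥ 5), cLogD (2→4), MW (360→500), HBD
(0.5→3.5) and pKa (8→10), and a TPSA hump (0 at ≤ 20, 1 on 40–90, 0 at
≥ 120); the score is the sum of the six transforms. Descriptor provenance
must be stored with the score: different cLogP/cLogD/pKa engines shift MPO
by several tenths, which is why the demo labels its cLogD ≈ cLogP and fixed
pKa inputs as synthetic stand-ins.

The plate percent-activity equation is implemented verbatim with its
printed denominator (reference max minus reference RLU); because that form
is unusual, an alternate "max minus vehicle" denominator is selectable
rather than guessing intent. uBRET is the affine standardization
`(ratio − A)/(B − A) × 10,000` between negative- and positive-control
transfections; it is invariant under any common affine recalibration of the
raw ratios (property-tested).

## PK / ADME

NCA uses the linear trapezoid. On a convex decaying curve the chords lie
*above* the curve, so the trapezoid slightly overestimates the integral over
the sampled window; the error vanishes quadratically as sampling densifies
(asserted on refined grids), and the extrapolated AUC∞ converges to the
one-compartment closed form `dose/(V/F·ke)`. The log-linear down-slope
variant is deliberately not implemented — linear is the simplest defensible
default and the difference is absorbed in the documented tolerance. λz uses
the last 3 quantifiable points by default; a best-adjusted-R² tail search is
selectable. Fewer than 3 usable terminal points or a non-negative slope
leaves λz/T½/AUC∞ explicitly unestimable while AUC_last is still returned.

LLOQ handling is purpose-dependent: below-LLOQ values are zero for AUC (no
exposure contribution) and missing for T½ (a censored value would bias the
terminal regression). Brain profiles are treated identically to plasma with
ng/g units; no partition-coefficient modeling is attempted. Intrinsic
clearance is kel normalized to the 0.42 mg/mL incubation protein
concentration, reported in µL/min/mg. Papp is `(dQ/dt)/(A·C0)` from the
linear receiver-accumulation phase, and the efflux ratio is
Papp(B→A)/Papp(A→B), undefined (with status) when A→B is zero.

## Behavior

Significance flags are inputs, not recomputed: the primary behavioral
statistics (ANOVA with post-hoc corrections) are standard and out of scope
here. The therapeutic window is min side-effect dose / min analgesic dose.
When a side-effect assay never reaches significance up to the top tested
dose, the window is a *lower bound* (top tested / min analgesic), typed
distinctly from point estimates. For a side effect that shows only a
non-significant trend, the shipped example table counts the trend dose as
the minimal side-effect dose (the conservative convention, with the assay
named `catalepsy_trend` to make the semantics visible); bound semantics are
available by flagging the row non-significant instead. The window matrix
crosses every analgesic assay with every side-effect assay so any summary
pair can be recovered without guessing.

## Synthetic data

Generators are pure functions of their specs; the same spec yields
byte-identical output, and planted truth is always returned alongside the
data.

The library generator builds molecules from a frozen, versioned fragment
grammar: 17 novel scaffolds, 4 "known ligand"-like reference scaffolds
(aminoalkylindole-, arylpyrazole-, biphenyl-resorcinol- and eicosanoid-like
cores), and 40 aromatic substituents, combined at up to two sites. The
scaffold set was *selected*, not sampled: candidates were screened so that
(a) each scaffold supplies hundreds of property-window members that remain
pairwise Tc ≥ 0.5 — membership is admitted greedily with that invariant
enforced at build time — and (b) members of different scaffolds stay below
Tc 0.34, a margin under the 0.36 novelty cutoff. Requests the grammar
cannot honor (more clusters than scaffolds, cluster sizes beyond capacity,
fraction/cluster combinations leaving an empty pool) raise, rather than
silently relaxing the similarity structure. Cluster sizes are allocated by
water-filling (as even as capacities allow). Docking scores are drawn
i.i.d. normal (−35 ± 4 by default), independent of cluster membership, so
rankings interleave clusters; reference ligands are the lead members of the
reference scaffolds. Generation re-verifies the novelty margins exhaustively
against the reference ligands and across cluster leads.

What the generator does *not* emulate: real chemical-library property
distributions beyond the MW/cLogP windows, synthesizability, conformer
energetics, or the long-tailed cluster-size structure of a real 300k-molecule
triage. Passing the planted-recovery tests therefore demonstrates that the
funnel's logic is exact on data satisfying its stated similarity structure —
not that a real campaign's clustering is unambiguous.

Pose generation plants one polar atom inside the contact cutoff for the
planted fraction and keeps all polar atoms at least 1.1× the cutoff away
for the rest; curves add i.i.d. Gaussian noise on the percent scale (the
default 8 concentrations span 1 fM–10 µM); PK profiles follow the
one-compartment extravascular closed form
`C(t) = (D·ka)/(V/F·(ka−ke))·(e^{−ke t} − e^{−ka t})` (bolus mode:
`C = D/(V/F)·e^{−ke t}`), with optional multiplicative lognormal noise and
`ka = ke` rejected as degenerate. The default sampling grid is the
9-point 5 min–24 h design typical of rodent PK studies.

## Problem sizes and runtime

Test and acceptance runs are sized for a laptop: the planted-recovery
funnel runs on a 10,000-molecule library (15 clusters, 10 % known-like),
curve-recovery suites use 200 seeded curves, and RMSD oracle checks use
≤ 8-atom instances where exhaustive permutation is exact. These sizes were
chosen as the smallest at which the claimed properties are non-trivial;
every operation scales to campaign-size inputs linearly in molecules (the
leader pass is O(n·clusters)).

## Known limitations

- Leader clustering reproduces the funnel's *procedure*; the real
  campaign's cluster count on its own data depends on input order and
  threshold details that a re-implementation cannot pin down exactly.
- The MPO score is only as comparable as its descriptor engines; no pKa or
  logD estimator ships here.
- NCA implements the linear trapezoid only; commercial tools mixing
  log-linear down-slopes will differ slightly on sparse decaying tails.
- The CLI's `triage` path reads whole libraries into memory; campaign-scale
  (10⁸-molecule) score tables would need a streaming front end.
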