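# Methods

This note records the model implemented by `ededock`, the assumptions behind
it, every tunable parameter with its default and units, what the synthetic
data generator does and does not emulate, and the numerical and design
choices that affect results.

## 1. Model

### 1.1 Pocket definition

Given a reference receptor–ligand complex, a residue belongs to the binding
pocket if **any of its side-chain heavy atoms** lies within `contact_cutoff`
(default **3.0 Å**) of **any ligand heavy atom**. Backbone atoms (N, CA, C,
O, and backbone hydrogens) are excluded from the contact test so that the
pocket reflects side-chain engagement; glycine, which has no side-chain
heavy atom, falls back to its CA. Hydrogens are ignored on both sides. The
pocket is fixed from the reference complex and held constant across the
trajectory.

### 1.2 Featurization

Each trajectory frame is rigidly superposed onto the reference structure
using the Kabsch (SVD) algorithm on Cα atoms of residues within
`align_range` (inclusive residue-number bounds; residues are matched between
frame topology and reference by chain and residue number). After
superposition, the feature vector of a frame is the concatenation of the
**mass-weighted heavy-atom centers of mass** of the pocket residues — a
3·m-dimensional vector for m pocket residues. Atomic masses come from a
standard-element table; elements missing from PDB columns are inferred from
atom names.

Assumption: a rigid-body fit on a stable structural core removes global
translation/rotation, so residual COM displacement reflects internal pocket
motion. This fails if the alignment region itself is flexible.

### 1.3 Essential dynamics

PCA is applied to the feature matrix (frames × features) with the unbiased
(F−1) covariance normalization. The number of retained components is the
smallest number whose cumulative explained variance reaches
`variance_threshold` (default **0.90**), capped at `max_pcs` (default
**15**). Component signs follow a deterministic convention: the
largest-magnitude loading of each component is made positive, so results do
not depend on SVD sign ambiguity.

### 1.4 Conformational selection

K-means (k-means++ initialization, `n_init` = 10 restarts, default
`n_clusters` = **4**) clusters the frames in the retained PC space. Cluster
labels are renumbered by **descending population** (ties broken by original
label), so state 1 is always the most populated. Populations are occupancy
fractions `P_i = N_i / F`. Conformational free energies are defined relative
to state 1, in units of kT:

    ΔG_conf(1,i) = −ln(P_i / P_1),   so ΔG_conf(1,1) = 0 and ΔG_conf ≥ 0.

The representative of each state is the member frame nearest (Euclidean, in
PC space by default; Cartesian feature space optionally) to the cluster
center; distance ties resolve to the lowest frame index. Representatives are
written as single-model PDB files annotated with their source frame index.

Assumption: occupancy free energies require the trajectory to be
equilibrium-sampled; populations from a biased or short trajectory give
biased ΔG_conf.

### 1.5 Ensemble binding score

With per-conformation docking scores ΔG_bind(1,i) in kcal/mol and kT = R·T
(R = 1.9872041×10⁻³ kcal·mol⁻¹·K⁻¹; default T = **300 K**, kT ≈ 0.59616
kcal/mol):

    ΔG_bind = kT · ln [ Σ_i e^(−ΔG_conf(1,i)) / Σ_i e^(−ΔG_conf(1,i) − ΔG_bind(1,i)/kT) ]

The numerator is the unbound-receptor partition sum over conformations; the
denominator additionally Boltzmann-weights each conformation by the docking
energy. ΔG_conf enters directly in kT units; ΔG_bind is converted by
division by kT. Per-conformation contributions (each term of the
denominator, normalized) are reported alongside the score so dominant
conformations can be identified.

Limits and properties (all verified by tests):

- n = 1 → the raw docking score, exactly.
- All ΔG_conf = 0 → kT·ln( n / Σ e^(−ΔG_bind,i/kT) ) (equal weighting).
- min_i ΔG_bind,i ≤ ΔG_bind ≤ max_i ΔG_bind,i, strictly monotone in every
  per-conformation score.
- A state with ΔG_conf = 20 kT shifts the score by < 10⁻⁶ kcal/mol even if
  it docks as well as the best existing state — rare states cannot dominate.

**Missing poses.** If a compound failed to dock in some conformations, those
terms are dropped from the bound (denominator) sum only; the unbound sum
keeps all states. This treats "no pose" as "no binding in that
conformation", which penalizes the compound rather than silently renormalizing.
A compound with no poses at all is an error.

### 1.6 Triage and evaluation

Compounds are ranked by ascending ensemble score; ranks are assigned stably
(ties by input order). A compound passes triage if its score is ≤
`triage_cutoff` (default **−9.0 kcal/mol**). When activity labels are
supplied, the screen is evaluated by the confusion matrix and accuracy,
false-negative rate, and false-positive rate; rates whose denominator is
zero are reported as null, never as 0 or NaN. By default the label classes
`strong` and `medium` count as active.

## 2. Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `contact_cutoff` | 3.0 | Å | side-chain heavy atom ↔ ligand heavy atom |
| `align_range` | required | residue numbers | inclusive Cα superposition range |
| `com_mode` | `residue` | — | whole-residue heavy-atom COM (see §4) |
| `variance_threshold` | 0.90 | fraction | cumulative explained variance |
| `max_pcs` | 15 | count | cap on retained components |
| `n_clusters` (k) | 4 | count | inertia-vs-k report aids choosing k |
| `n_init` | 10 | count | K-means restarts |
| `random_state` / `seed` | 0 | — | controls K-means only; pipeline is otherwise deterministic |
| `temperature` | 300.0 | K | sets kT |
| `triage_cutoff` | −9.0 | kcal/mol | pass if score ≤ cutoff |

## 3. Synthetic data generator

The generator exists so that every stage can be validated against exact
ground truth.

**What it emulates.** (a) Toy receptor–ligand complexes in which the minimum
side-chain–ligand heavy-atom distance of each residue is *exactly* a
requested value, by construction (the contacting atom is placed at distance
d along a direction u from the ligand atom maximizing the projection onto u,
which provably attains the minimum). These make the pocket rule testable
atom-for-atom. (b) Multi-state pocket trajectories: m two-atom pocket
residues whose CA/CB midpoint — and therefore, the two atoms being both
carbon, the mass-weighted COM — *equals* a point sampled as
state-center + Gaussian fluctuation (σ default 0.25 Å), plus a rigid
8-residue glycine core for superposition; states are drawn i.i.d. per frame
from the specified populations. Optional per-frame random rigid transforms
exercise the superposition. The default study preset has 4 states with
populations 0.5/0.3/0.15/0.05, 12 pocket residues, and state centers ≥ 20 σ
apart so clustering is unambiguous. (c) Docking score tables generated from
per-state true binding energies with Gaussian noise and missing-at-random
poses, together with the implied true ensemble scores and ΔG_conf.

**What it does not emulate.** Real protein geometry, bonded structure,
solvent, or force-field physics; temporal correlation (frames are i.i.d., so
there is no kinetics and no autocorrelation); anharmonic or multimodal
within-state fluctuations; docking-scoring-function bias (noise is unbiased
Gaussian); pose geometry (scores are numbers, not poses). Conclusions about
sampling convergence on real MD data do not follow from it.

## 4. Numerical and design choices

- **Log-sum-exp.** Both partition sums are evaluated with
  `scipy.special.logsumexp`; no raw exponentials of score/kT ratios are ever
  summed, so scores of −20 kcal/mol (≈ e³³) cannot overflow.
- **Kabsch with reflection guard.** The rotation uses SVD with the
  determinant-corrected last singular vector, guaranteeing a proper
  rotation. It is cross-validated against an independent quaternion
  (QCP-style) superposition to 10⁻⁸ Å RMSD agreement.
- **Deterministic everywhere.** PCA sign convention, population-ordered
  cluster relabeling, lowest-index tie-breaks for representatives, stable
  ranking, sorted-key YAML/JSON without timestamps: rerunning the pipeline
  with the same seed is byte-identical.
- **Whole-residue COM** (default) rather than side-chain-only COM: the
  backbone contributes to pocket shape, and glycine needs no special case in
  featurization. Side-chain-only contact *selection* plus whole-residue
  *featurization* is a deliberate asymmetry — selection asks "does the side
  chain engage the ligand?", featurization asks "where is the residue?". A
  `com_mode` switch leaves the alternative open.
- **ΔG_conf from occupancies, in kT.** Keeping ΔG_conf dimensionless (kT
  units) in the score avoids a double unit conversion and makes the
  equal-population limit exact; docking scores are converted once, by /kT.
- **Unbiased covariance (F−1)** in PCA, matching the estimator convention of
  the underlying library and the eigenvalue-recovery tests.
- **k is not auto-selected.** An inertia-vs-k table is emitted to aid the
  elbow heuristic, but the choice of k is the user's; automatic selection
  would hide a decision that materially changes ΔG_conf.

## 5. Limitations

- Occupancy-based ΔG_conf inherits all sampling error of the input
  trajectory; no reweighting for enhanced-sampling data is provided.
- The pocket is fixed from a single reference complex; cryptic pockets that
  only open during the trajectory are not detected.
- K-means assumes roughly isotropic clusters in PC space; strongly
  anisotropic or hierarchical state structure may be split or merged.
- The ensemble score combines docking scores as if they were free energies
  on a common scale; systematic scoring-function error is passed through,
  not corrected.
- Evaluation metrics assume binary activity after class mapping; potency
  regression is out of scope.
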