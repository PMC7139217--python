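# Methods

This note documents the models and numerical choices behind densedock: what
each stage computes, the parameters that matter, what the synthetic scenes
do and do not emulate, and the limitations a user should know about.

## Coordinate and grid conventions

All coordinates are Å, right-handed. Density grids use 0-based voxel
indexing with axis 0 along x; the physical position of voxel (i, j, k) is
`origin + (i, j, k)·voxel_size`. On reading MRC/CCP4 files the axes are
normalized to x, y, z regardless of the stored MAPC/MAPR/MAPS permutation.
Two origin dialects circulate in deposited maps; the reader uses the ORIGIN
header record when any component is nonzero and falls back to
`nstart × voxel_size` otherwise, which covers both conventions
deterministically. Non-orthogonal cells are rejected. In PDB models,
alternate locations resolve to the highest-occupancy conformer (ties: first
in file); missing element columns fall back to matching the leading letters
of the atom name against a fixed element table, which can misassign exotic
names — a warning is logged when the fallback cannot decide.

## Density simulation

Model-to-map scores compare the experimental map with a simulated one. Each
heavy atom contributes an isotropic Gaussian `w·exp(−r²/2σ²)` with
σ = `sigma_coeff · resolution` and weight w = atomic number (or 1 under
uniform weighting), truncated at `cutoff·σ` (default 4σ; the analytic mass
`Σ Z·(2πσ²)^{3/2}` is then captured to well under 1%). The default
`sigma_coeff = 0.356` is the convention in which the Gaussian's Fourier
transform falls to half its peak at spatial frequency 1/resolution; 0.425
(real-space half-height convention) is exposed for cross-checking against
other simulation tools, and every score report records the coefficient used.
Hydrogens are ignored by default — deposited models at ~4 Å rarely carry
meaningful hydrogen positions. B-factor-dependent per-atom widths are
deliberately out of scope.

## Difference mapping

Two reconstructions of the same specimen differ in overall amplitude
falloff, so naive subtraction leaves shell-dependent residuals. The
reference map B is therefore scaled to the target A in Fourier space: within
each radial shell, B's amplitudes are multiplied by a single factor that
equates the shell's power to A's; phases are untouched, and the DC term is
matched separately so the means agree. The default shell width,
1/(10·box length) Å⁻¹, is finer than the 1/L Fourier sampling, i.e.
effectively per-radius matching; shells where B has zero power keep factor 1.
With a single shell the operation reduces exactly to global mean/std
matching, which serves as the degenerate fallback. The difference map is
`A − scaled(B)`; its positive clamp localizes features present only in A.

Peaks are connected components (26-connectivity) of voxels above
`mean + kσ` of the whole difference grid — a solvent mask would be less
reproducible and is not needed at synthetic-scene contrast. The display
threshold for difference density is inherently a choice; the default k = 3
is exposed in the configuration, and peak counts are monotonically
non-increasing in k. Peak centroids are density-weighted; sorting is by
maximum value, then volume, then lexicographic centroid so that reports are
stable under voxel-order permutations.

## CCC and SMOC

CCC is the Pearson correlation between experimental and simulated density
over a voxel mask. The default mask is *model proximity* — voxels within
`max(2.5 Å, resolution/2)` of any probe atom — because local fit is what
distinguishes candidate ligand poses; a whole-map CCC is dominated by the
receptor (in the motivating application, by tubulin). `sim-contour` and
`whole-map` masks are available. Masks under 30 voxels yield a score flagged
unreliable (still returned). The vectorized computation is checked in the
test suite against a per-voxel Pearson loop to 1e-10.

SMOC profiles local fit: for each residue, the CCC over the mask of a
sliding window of residues centred on it (default 9, truncated at chain
ends), with the simulated map computed once from the whole model. Windows
must be odd; residues wholly outside the map are skipped with a warning.
The profile depends only on residue order, not numbering, and a wider
window trades spatial localization for a smoother profile.

## Pose analysis

Docking poses against a fixed receptor share the receptor frame, so RMSD is
computed **without superposition** — superposing would hide exactly the
translational differences that distinguish binding sites. With symmetry
handling on (the default), the RMSD is minimized over automorphisms of the
element-colored bond graph (bonds inferred from covalent radii + 0.45 Å
slack when connectivity is absent), enumeration capped at 10,000 mappings
with a warning fallback to the identity mapping. Whether redundancy
grouping in the original protocols considered ligand symmetry is not
documented; both modes are provided.

Redundancy grouping is greedy, best score first: poses are visited in score
order (orientation declared per engine; mixing orientations in one set is an
error) and join the first representative within the threshold (default
2 Å), else found a new group. This matches the "represented by the
conformation with the best score" semantics and guarantees (i) no two
representatives within the threshold, (ii) every pose within the threshold
of its representative — both verified against exhaustive checks. When
scores are absent, input order is used with a warning. Unique conformations
are clustered into candidate sites by single-linkage on centroids (default
cutoff 5 Å, a choice exposed in config).

Cross-engine consensus keeps a pose iff every other engine contains a pose
within the threshold; the union is deduplicated at the same threshold in
lexicographic pose-id order, making the result invariant to engine
relabeling. Scores are never compared across engines; where a pooled
ordering is unavoidable (merging blind runs from different engines) raw
scores are first replaced by within-engine ranks.

## The two-stage protocol

`run_protocol` executes: difference map → difference peaks → merge blind
runs (dedup at 2 Å) → centroid clustering → site identification → stage-1
cross-engine consensus restricted to the top site (default radius 12 Å) →
CCC ranking; then optionally stage-2 consensus within a tight radius
(default 6 Å) around the stage-1 winner, when focused pose sets are
supplied. Site identification links evidence items (dock clusters,
difference peaks, pockets; pocket lists are consumed as plain centers from
an external predictor) whose centers lie within `match_radius` (default
5 Å, a choice — the protocols this mirrors do not state one); a candidate
with all three kinds is a consensus site and always outranks partial ones.
The best pose maximizes the average of full-map and difference-map CCC;
ties break on the higher full-map CCC (the full map is better determined
than a difference map), then pose id. The report distinguishes the
stage-1 consensus count from the post-stage-2 count rather than conflating
them, and lists every threshold used.

Degenerate inputs are defined rather than fatal: empty cross-engine
consensus falls back to ranking per-engine unique representatives near the
top site, flagged `empty-consensus-fallback`; a pose outside the map is
flagged and ranked last; absent stage-2 files leave the report in
"stage-1 only" mode. Intermediate model-refinement steps that external
tools would perform (rigid re-fitting, sidechain refinement) are
represented only as the PDB read/write exchange points, not implemented.
The pipeline never invokes docking binaries; pose files are inputs, which
keeps the artifact self-contained and deterministic — given fixed inputs
and configuration there is no unseeded randomness anywhere.

## Kinetics

`fit_michaelis_menten` fits `v = Vmax·S/(K+S)` by bounded nonlinear least
squares (initialization Vmax₀ = max rate, K₀ = interpolated half-max
concentration); `fit_ic50` fits `y = a/(1+(x/b)^c)` with all three
parameters free (c₀ = 1) — whether published fits of this form constrained
a or c is typically unstated, so the default leaves them free. Zero
concentrations are handled on the linear axis (the model value at x = 0 is
exactly a). Parameter standard errors come from the fit covariance; R² is
1 − RSS/TSS. Fits are scale-equivariant in concentration, all-zero rates or
flat activities fail fast with diagnostics, and optimizer tolerances are
tightened (1e-14) so noise-free recovery is exact to ~1e-6 relative.
No replicate weighting is applied by default, matching the common practice
of fitting condition means.

## Synthetic scenes

`make_scene` emulates the statistical structure the analysis assumes — not
cryo-EM image formation. The receptor is an abstract pair of idealized
30-residue helices (5 heavy atoms per residue, axes 14 Å apart) whose cleft
holds a rigid 20-heavy-atom biaryl-like fragment (two six-rings, a CF₃-like
group, a short amide-like tail — enough symmetry to exercise automorphism
handling). Both maps are simulated on one shared grid; each receives
independent white Gaussian voxel noise of standard deviation
`noise_sigma × (noise-free ligand peak height)` — a single interpretable
SNR knob. With `conformational_change` on, four residues at the far end of
one helix are displaced 4 Å between the states, producing the additional
difference peaks that receptor loops cause in real paired reconstructions.
Default conditions are 4 Å resolution, 1 Å voxels, `noise_sigma = 0.1`.

`make_engine_outputs` plants one pose perturbed ≤ 1 Å from truth in each
engine plus rigid decoys rejection-sampled to a symmetry-corrected RMSD to
truth within `decoy_range` (default 5–20 Å; a lower bound under 2 Å warns
because decoys could alias the native cluster). Scores are drawn from
per-engine distributions (negative-energy-like for the lower-is-better
engine, fitness-like for the others) and the near-native pose is pinned
just past the median — strictly worse than the better half — so score-only
ranking never places it first. Titration tables use a linear activator
series 0–4·K for the activation model (concentrated around K, where K is
identifiable) and a log series spanning two decades either side of the IC50
for inhibition, with multiplicative Gaussian noise.

All generators are pure functions of (parameters, seed): the same seed
reproduces maps bit-for-bit.

What passing tests on these scenes show: that the pipeline's evidence
linking, consensus logic and density ranking recover a planted ligand under
honest noise and decoy conditions, with every stage checked against
independent oracles. What they do not show: robustness to CTF artefacts,
local resolution gradients, solvent/detergent density, receptor flexibility
beyond a rigid loop shift, or scoring-function biases of real docking
engines — real reconstructions and real pose sets remain the domain of the
file-based interfaces.

## Known limitations

- Amplitude scaling assumes both maps are already aligned on a congruent
  grid; misaligned maps are only trilinearly resampled, not registered.
- The Gaussian density model ignores electron scattering form factors and
  B-factors; simulated and experimental absolute scales differ (harmless to
  Pearson-based scores).
- Bond inference by distance can over-connect distorted geometries, which
  changes the automorphism group used for symmetric RMSD; connectivity from
  SDF input is not currently propagated into the RMSD step.
- Peak statistics use the whole grid rather than a solvent mask, so very
  crowded difference maps shift the effective threshold.
- The PDBQT reader is deliberately minimal (coordinates + Vina score
  remark); charges and atom-type semantics are ignored.
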