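# Methods

## Disulfide design scan

A candidate disulfide between residues *i* and *j* is modeled from
backbone geometry alone. Each residue contributes its Cβ (an ideal Cβ is
constructed from N/CA/C with CA–CB 1.53 Å, N–CA–CB 110.4° and
L-amino-acid chirality when absent, e.g. for glycine); Sγ is placed at
Cβ–Sγ 1.81 Å and CA–Cβ–Sγ 114° for every χ1 on a grid (default step 10°,
configurable down to 1°). Every (χ1ᵢ, χ1ⱼ) combination is scored with a
harmonic strain energy

E = k_d (d_SS − 2.02)² + k_a [(θᵢ − 104.15)² + (θⱼ − 104.15)²]
  + k_x Δ(χ_SS, ±87)² + k_x Δ(χ1ᵢ, rot)² + k_x Δ(χ1ⱼ, rot)²

with k_d = 100 kcal/mol/Å², k_a = 0.02 kcal/mol/deg²,
k_x = 0.005 kcal/mol/deg². Δ(·,·) is the wrapped deviation from the
nearest ideal value (χ_SS about +87° or −87°; χ1 about the staggered
rotamers −60/60/180°). The functional is zero at ideal geometry and
strictly quadratic in each deviation, which makes it directly testable
(mirror symmetry in χ_SS, quadrupling under doubled deviations, exhaustive
grid-search equivalence). χ2-type terms are deliberately omitted: given
χ1, the scored terms already determine the Sγ placement quality, and a χ2
penalty would only rescale the ranking. The constants are chosen so that
a geometrically perfect disulfide scores ≈ 0 and typical native disulfide
geometries score below the 10 kcal/mol acceptance cutoff.

Pair enumeration is bounded by Cβ–Cβ ≤ 5 Å and sequence separation ≥ 3
within a chain (standard disulfide geometry bounds). Candidates whose
residues approach a protected site (any atom to any site atom) closer
than the exclusion radius (default 10 Å, e.g. around the FAD cofactor)
are discarded; the survivors are ranked by ascending strain energy with a
lexicographic (chain, residue) tie-break. Existing cysteines participate
like any other residue, contributing their real Cβ.

## Elastic-network Brownian simulator

The screening statistic only needs trajectories with correct *fluctuation
statistics*, not correct kinetics. The simulator therefore uses a Cα
elastic network: beads at Cα positions, springs (default
k = 1 kcal/mol/Å²) between all pairs within a cutoff (default 8 Å), rest
lengths equal to the input distances. The force is the linearized network
force **F** = −H(**x** − **x₀**), with H the standard anisotropic-network
Hessian, integrated by overdamped Euler–Maruyama:

x ← x − (dt/γ) H (x − x₀) + √(2 k_B T dt/γ) · P ξ

with k_B = 0.0019872 kcal/mol/K and γ the friction (1/time; time units
are opaque — only stationary statistics are consumed downstream). The
projector P removes the Hessian's rigid-body null modes from the noise:
at finite amplitude a *linearized* rotation mode is not a rotation but a
shear-like deformation, and exciting it corrupts the sampled fluctuations
in a way no rigid-body superposition can undo. With the projection, the
sampled per-bead mean-square fluctuation converges to the closed form

MSF_i = k_B·T · tr[(H⁺)ᵢᵢ]

(pseudo-inverse with the six rigid modes removed), which serves as the
module's analytic oracle; agreement is within ~8% per bead at 2×10⁵ steps
for 50-bead networks. MSF ∝ T holds exactly, so avg-RMSF grows as √T and
the fitted λ is strictly positive for any connected network.

Stability is enforced as dt < γ/λ_max(H) using the true largest Hessian
eigenvalue (a per-spring bound would underestimate stiff, highly
coordinated modes). More than six zero modes raises an error — the
network is disconnected or mechanically floppy (e.g. a collinear chain,
which has no transverse stiffness under directional springs).

Engineered disulfides are modeled as one extra spring (default
k_ss = 10 kcal/mol/Å²) at the current bead distance. Because a harmonic
crosslink restrains motion only along its bond axis, placement matters;
`suggest_crosslink` picks the bead pair maximizing the equilibrium
variance of the relative displacement projected on the connecting line,
Var[(uᵢ−uⱼ)·ê], computed from the covariance k_B·T·H⁺ — the motion a
spring actually removes. Adding a crosslink can only lower (never raise)
any bead's MSF (eigenvalue interlacing), which is asserted as a property
test.

### Synthetic test proteins

`compact_cluster(n)` is a jittered cubic-lattice blob at Cα-like spacing
(3.8 Å), trimmed to a roughly spherical shape — densely connected and
stiff, with fluctuation amplitudes in the sub-Å regime of folded
proteins. `mobile_loop_protein()` adds an 8-bead loop arcing 7 Å out of
the surface between two anchor beads: anchored at both ends (no zero
modes) but several-fold more mobile than the core, mimicking a flexible
solvent-exposed loop — the natural target for stabilizing crosslinks.
Elongated filaments are deliberately not used as fixtures: under
directional springs their transverse modes are near-zero and their
fluctuations exceed the structure size, outside any harmonic model's
validity. These generators emulate the *statistical structure* the screen
assumes (fluctuations growing with temperature, crosslinks damping them);
they do not emulate anharmonicity, solvent, side-chain packing or
unfolding, so passing tests validate the screening machinery, not
all-atom force-field behavior.

## Trajectory screening

Per trajectory: the first fraction of frames is discarded (default 0.2,
mirroring the exclusion of the equilibration segment from a production
run), frames are superposed by the Kabsch algorithm onto an iterated mean
structure (two passes: align to the first retained frame, re-align to the
mean), and RMSF_i = √⟨|xᵢ − ⟨xᵢ⟩|²⟩ is computed per Cα. avg-RMSF averages
the profile over an inclusive residue window (e.g. 10–437 for a 438-residue
chain, excluding mobile termini). λ, its intercept and R² (squared Pearson
correlation) come from ordinary least squares of avg-RMSF on temperature;
a perfectly flat response has undefined R², reported as 0 with a
degeneracy flag.

Regression points: with one trajectory per temperature the retained
frames are split into `n_blocks` contiguous blocks (default 3), each
contributing one avg-RMSF point, giving the slope-comparison test its
degrees of freedom; explicit replicate trajectories contribute one point
each. The variant-vs-reference p-value is the two-sided equality-of-slopes
t-test with pooled residual variance, df = n₁+n₂−4 (the published
screening table does not name its procedure; this is the standard choice
and its type-I error is verified by simulation at α = 0.05). Residual
variance at machine-rounding level is treated as an exact fit (identical
lines → p = 1; distinct exact lines → p = 0 with a warning).

Decision rule: `rejected_fit` if R² < 0.80 regardless of slope (the
threshold separates the published rejected-for-fit case, R² ≈ 0.43, from
the weakest retained fit, R² ≈ 0.89, with margin on both sides);
`rejected_slope` if λ > λ_ref strictly; otherwise `selected` — so a
variant identical to the reference sits on the boundary and is selected.

Sampling caveat: at desk scale, λ from a Brownian trajectory carries
10–15% sampling error, dominated by the slowest loop mode's relaxation
time relative to trajectory length. The end-to-end demo therefore
compares a reference against a variant whose mobile loop is stapled by
four optimally placed crosslinks (analytic λ reduction ≈ 14%), simulates
both with a common random-number stream (paired noise cancels much of the
sampling error in the comparison) and fits λ on whole-trajectory points
(`n_blocks = 1`). The single-crosslink λ decrease is asserted through the
exact analytic oracle, where it is deterministic. Simulation lengths
throughout the test-suite (10⁵–3×10⁵ steps, 10–50 beads) were chosen by
this signal-to-noise analysis.

## Tunnel bottleneck

A clearance grid over the padded bounding box (default spacing 0.5 Å,
padding 5 Å) stores per voxel the exact distance to the nearest atom
surface, min_i(‖x − xᵢ‖ − vdWᵢ), capped at `max_probe` (default 4 Å) so
that open solvent does not dominate the path search — a grid-level
approximation of the shell parameters Voronoi tunnel software uses to
define the protein surface. Van der Waals radii come from a fixed
Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80 Å, …; unknown elements
1.5 Å with a logged warning).

The widest access path from the start atom (e.g. flavin N5; the atom
itself is not an obstacle, and a buried start hops to the best free voxel
within 3 Å, as tunnel tools do) to the box boundary is the maximin path
over 6-connected positive-clearance voxels, computed by bottleneck
Dijkstra with a deterministic lexicographic tie-break. The maximin value
is unique even when paths are not; equivalence with a
threshold-connectivity oracle is asserted on small random grids. Over a
trajectory, per-frame bottlenecks are summarized as mean ± sample SD;
frames with a fully buried start are skipped with a log message. The
probe radius (default 1.4 Å, roughly a water/small-sugar probe) is a
reporting floor (`passes_probe`), not a passability constraint. Only the
single widest tunnel is reported; tunnel clustering and multi-tunnel
output are out of scope.

## Assay fitting

Michaelis–Menten and Boltzmann models are fitted by Levenberg–Marquardt
nonlinear least squares on pooled replicate points (not means), so
standard errors from the fit covariance reflect replicate scatter.
Deterministic initializers: Vmax ← max rate, Km ← substrate level nearest
half-max; A_top/A_bottom ← max/min activity, T50 ← temperature nearest
half-range, s ← 3 °C. Temperatures are °C end-to-end. Flags instead of
silent failure: Km > 50× the largest substrate level → unidentifiable;
monotone-increasing activity → no inactivation; T50 outside the data
range → extrapolated. kcat = Vmax/[E] and kcat/Km are computed from the
unrounded estimates, so the reported ratio is exactly kcat ÷ Km.
ΔT50 between two fits carries the quadrature-propagated SE.

The synthetic generator draws replicates (default 3) on the published
designs — substrate 0.05–2 mM, temperature 25–100 °C in 5 °C steps — as
curve value plus Gaussian noise with SD equal to a fraction of the local
curve value, truncated at zero; this is the simplest noise model
consistent with assay error bars that grow with signal. With 3% noise the
Boltzmann fit recovers a mid-range T50 to within ~0.1 °C; with 5% noise
the Michaelis–Menten fit recovers Km well within its published
uncertainty. Whether published ± values are replicate SDs or pooled-fit
SEs is generally ambiguous; the toolkit reports the pooled-fit SE and
leaves replicate-wise refitting to the user.

## I/O conventions

PDB (and mmCIF) parsing and writing are delegated to biotite; multi-model
PDB is the trajectory interchange dialect (a DCD adapter was considered
and omitted — users with binary trajectories can convert via mdtraj or
MDAnalysis). Author residue numbering is preserved exactly; alternate
locations resolve to the highest-occupancy conformer. Malformed records
are reported with their line number; models with inconsistent atom counts
abort trajectory assembly with the offending model indices. Selections
are a small conjunctive grammar (`name`, `resid` ranges, `chain`,
`resname`, `hetatm`/`protein`, `not`) resolving to sorted atom indices.

## Known limitations

- The elastic network is harmonic by construction: no unfolding, no
  anharmonic loop dynamics, no solvent friction heterogeneity. λ values
  from toy networks are commensurate with (but not comparable to)
  all-atom values.
- The strain-energy constants are a documented choice, not a fit to a
  disulfide database; rankings are meaningful, absolute energies are not.
- The grid tunnel reports a single widest path; branched or multiple
  tunnels are not resolved, and absolute bottleneck radii depend on the
  vdW table and `max_probe`.
- The equality-of-slopes test assumes independent Gaussian residuals;
  block-derived points from one trajectory are only approximately
  independent.
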