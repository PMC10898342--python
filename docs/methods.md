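# Methods

## The quantity being estimated

Each residue is coarse-grained to its Cα atom.  Over a trajectory of F
frames the fluctuation of residue *i* is ΔR_i(t) = R_i(t) − ⟨R_i⟩, and the
mutual information between residues *i* and *j* is the MI of the two
3-dimensional random vectors ΔR_i and ΔR_j,

    I(ΔR_i, ΔR_j) = ⟨ ln p(ΔR_i, ΔR_j) − ln p(ΔR_i) − ln p(ΔR_j) ⟩ ,

in nats.  I quantifies how much knowing one residue's instantaneous
displacement reduces the uncertainty about the other's — the currency of
dynamic allostery.  The five estimators differ in what they assume about
the joint distribution p.

## Estimators

**Exact anisotropic (histogram plug-in).**  Each of the six Cartesian
components is divided into g equal-width intervals over its per-pair
[min, max] range, and I = H₃(i) + H₃(j) − H₆(i,j) is evaluated from the
empirical cell frequencies.  Marginal and joint histograms share the same
per-axis edges; this makes the entropy decomposition *identical* (to
floating-point roundoff, asserted at 1e-12 in the tests) to the direct
sample average of ln[p̂(joint)/(p̂_i p̂_j)].  Empty cells contribute nothing;
no pseudocounts or bias corrections are applied.  Joint cells are stored
sparsely (a 64-bit key per occupied cell), so memory scales with the number
of frames, never with g⁶; g is capped at 40.  The pair order is
canonicalized internally so that I(i,j) and I(j,i) are bit-identical.

**Exact isotropic.**  The same plug-in recipe applied to the 2D joint
histogram of magnitudes |ΔR_i|, |ΔR_j|.  Directional (anisotropic)
information is discarded by construction, so this estimator is blind to
correlations that only show up in orientation.

**Multivariate Gaussian (linearized MI).**  If p is modelled as a zero-mean
6D Gaussian with covariance ⟨ΔRΔRᵀ⟩, MI reduces to
−½ ln[det C₆ / (det C₃ᵢ · det C₃ⱼ)].  Covariances are normalized by F (not
F−1); the choice cancels in every ratio.  Log-determinants are computed via
symmetric eigendecomposition, never raw determinants.  Non-negativity is
guaranteed by Fischer's inequality for PSD matrices.

**Isotropic Gaussian.**  Dropping the orthogonal-axis (off-diagonal) terms
of C₆ leaves only scalar dot products: I = −½ ln[1 − ⟨ΔR_i·ΔR_j⟩² /
(⟨ΔR_i²⟩⟨ΔR_j²⟩)].  Note that for perfectly isotropic pairs (per-axis
covariance blocks proportional to the identity) the multivariate form
factorizes into three identical axis blocks, so I_multi = 3·I_iso exactly —
the two Gaussian estimators deliberately measure different things and are
not interchangeable.

**GNM.**  The Kirchhoff matrix Γ of the Cα contact graph (Γ_ij = −1 when
R_ij ≤ r_c) is eigendecomposed; cross-correlations are the spectral sum
Σ λ_m⁻¹ u_m u_mᵀ over a subset of nonzero modes ("1-all" = all N−1 modes =
the Moore–Penrose pseudoinverse; "2-all" etc. drop the slowest motions).
The physical prefactor 3k_BT/γ cancels in the isotropic-Gaussian MI ratio,
so GNM MI needs no temperature or spring constant.  An eigenvalue below
1e-8 of the largest is the rigid-body zero mode; two or more such
eigenvalues mean a disconnected contact graph, which is a hard error
(advice: increase r_c).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| grid size g | selected | intervals per axis for histogram MI; chosen by the RMSD rule below |
| grid candidates | 4,6,8,10,12,16,20,24,32 | candidate g values for selection; no canonical list exists, this spans the usable range for 10³–10⁵ frames |
| r_c | 7.3 Å | GNM contact cutoff; the community-standard Cα value. Always explicit in the CLI and recorded in output metadata |
| segments per length | min(10, ⌊F/length⌋) | segment-averaging count; non-overlapping whenever they fit, evenly spread overlap otherwise |
| singular threshold | 1e-10 (relative) | smallest/largest eigenvalue ratio below which a covariance block is flagged degenerate instead of producing ±inf |
| superposition | on for PDB/DCD/XTC | iterated least-squares fit to the mean structure, to numerical convergence; rigid-body motion otherwise dominates every covariance. Off for the plain-matrix container (assumed pre-aligned), `--no-superpose` for MD inputs aligned upstream |

**Grid-size selection.**  For each candidate g the exact-anisotropic MI
profile over the requested pairs is computed and compared by RMSD to the
multivariate-Gaussian profile of the same trajectory; the minimizing g wins,
ties going to the smaller g.  Small grids miss structure, large grids
overfit sparse cells (plug-in bias grows roughly with occupied-cell count /
2F); the Gaussian profile anchors the trade-off.  The full (g, RMSD) table
is always returned for audit.

**Convergence protocol.**  Segments of a given length are cut at evenly
spaced offsets, fluctuations are recomputed within each segment (each
segment sees its own mean structure, exactly as an independent short
simulation would), per-pair MI is averaged arithmetically over segments,
and the anchor residue's MI profile is compared to the reference by RMSD
and Pearson r.  The diagonal/self term is excluded from both.  Degenerate
pairs are averaged over their valid segments and excluded pairwise from the
comparisons.  One caveat discovered while validating the protocol: once the
segments of a given length tile the whole parent trajectory, longer
segments no longer add data — they only trade bias (which shrinks) against
averaging (which is lost), so Pearson r saturates and its differences
between the largest lengths are pure noise.

## The synthetic ground truth

`synthetic_data` provides the data every estimator is validated against:

* **Gaussian trajectories** — i.i.d. frames from a prescribed 3N×3N
  covariance via symmetric eigenvalue factorization (PSD covariances with
  zero modes, e.g. GNM embeddings, are sampled exactly on their support).
  The analytic Gaussian MI of the generating covariance is the oracle.
* **Toy structures** — collinear chain (3.8 Å spacing; the 3-bead case is
  fully hand-checkable: eigenvalues {0, 1, 3}, end-pair MI = −½ ln 0.36),
  ideal α-helix (rise 1.5 Å, 100° twist, radius 2.3 Å), and a two-domain
  cluster pair whose slowest GNM mode is anti-correlated across domains.
* **Multi-well fixture** — one designated residue pair where a hidden
  two-state well variable is encoded in the *product* of residue i's two
  displacement signs (an XOR construction): every linear cross-covariance
  entry is zero in expectation, yet the joint distribution carries ≈ ln 2
  nats.  Covariance-based MI sees nothing; the 6D histogram sees the
  coupling.  Two literally displaced wells cannot have this property — if
  both residues move between two wells, the cross-covariance contains
  w_i w_jᵀ ≠ 0 — hence the four-well/XOR design.  Setting the well offset
  to zero collapses the fixture to the purely Gaussian case.

What the synthetic data does **not** emulate: temporal autocorrelation
(frames are i.i.d., real MD frames are not — effective sample sizes in real
trajectories are smaller than the frame count), anharmonic multi-basin
dynamics beyond the single designated pair, solvent effects, and any
specific protein's fluctuation spectrum.  Passing tests therefore establish
the *estimators'* correctness and statistical behavior, not how long any
particular real trajectory must be.

## Numerical choices

* Natural logarithms throughout; `--bits` divides by ln 2 at output only.
* Histogram ranges are per-pair [min, max] with the top edge inclusive;
  a zero-width axis collapses to one occupied bin (entropy contribution 0).
* Degenerate results (singular blocks, |normalized correlation| ≥ 1, MI of
  a residue with itself) are flags/NaN sentinels, never ±inf, so full maps
  stay writable; TSV writers emit the token `inf`.
* Superposition iterates fit-to-mean starting *from the current mean*
  (starting from frame 0 would break idempotence) until the mean moves
  < 1e-12 Å RMSD (cap 500 iterations).
* Grid-size ties and the tie between equal RMSDs go to the smaller g —
  fewer cells, less overfitting.
* `plan_segments` rounds evenly spaced offsets and falls back to exact
  tiling if rounding would re-introduce overlap among nominally disjoint
  segments.

## Problem sizes used in validation

The statistical tests run at the sizes where their guarantees are meaningful
on a single CPU: 10⁵ frames for closed-form recovery (10 seeds), sample
sizes 10³/10⁴/10⁵ for the histogram-bias sweep (grid selected once on the
full-length trajectory, then held fixed while n grows — the consistency
statement is about the estimator at its selected grid), 6-residue systems
for convergence curves, and N ≤ 50 random structures for the GNM spectral
identities.

## Known limitations

* The 6D histogram estimator needs on the order of g⁶ well-populated cells;
  below ~10⁴ frames its plug-in bias is large (the bias sweep above
  measures it directly), which is precisely why the grid-selection rule
  exists.
* GNM MI inherits every GNM assumption: isotropic harmonic springs, a
  single structure, topology-only force constants.  Terminal residues have
  exaggerated slow-mode amplitudes, which inflates end-to-end MI — visible
  already in the 3-bead chain, where the end pair has the largest MI.
* No autocorrelation-time or statistical-inefficiency correction is
  applied; segment averaging addresses sampling noise, not sample
  dependence.
* The isotropic estimators (exact and Gaussian) are blind to purely
  orientational correlations by design.
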