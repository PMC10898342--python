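# dyncorr

Mutual information between residue fluctuations in proteins, five ways.

Correlated thermal fluctuations let distant protein sites exchange
information without any visible conformational change — the basis of dynamic
allostery.  `dyncorr` quantifies this exchange as the mutual information (MI)
between the Cα fluctuation vectors of residue pairs, estimated from
molecular-dynamics trajectories or, at the coarsest level, from a single
crystal structure.  It is aimed at people who run or analyze MD simulations
and want to know (a) which residue pairs share dynamic information and
(b) whether their trajectory is long enough for that answer to be trusted.

## The estimators

Write ΔR_i(t) = R_i(t) − ⟨R_i⟩ for the Cα displacement of residue *i* and
stack a pair into the 6-vector ΔR = col(ΔX_i, ΔY_i, ΔZ_i, ΔX_j, ΔY_j, ΔZ_j).
All MI values are in nats (natural logarithm).

| estimator | definition |
|---|---|
| exact anisotropic | plug-in MI of the empirical 6D joint histogram: I = H(ΔR_i) + H(ΔR_j) − H(ΔR_i, ΔR_j), each Cartesian component binned separately |
| exact isotropic | same plug-in recipe on the 2D histogram of magnitudes \|ΔR_i\|, \|ΔR_j\| |
| multivariate Gaussian | I = −½ ln [ det⟨ΔRΔRᵀ⟩ / (det⟨ΔR_iΔR_iᵀ⟩ · det⟨ΔR_jΔR_jᵀ⟩) ] (linearized MI) |
| isotropic Gaussian | I = −½ ln [ 1 − ⟨ΔR_i·ΔR_j⟩² / (⟨ΔR_i²⟩⟨ΔR_j²⟩) ] |
| GNM | isotropic Gaussian form fed with cross-correlations from the pseudoinverse of the Kirchhoff contact matrix Γ (Γ_ij = −1 for contacts within r_c); mode subsets "1-all", "2-all", … dissect timescales |

Two diagnostics support the estimators: a **grid-size selection** rule for the
histogram estimators (choose the per-axis bin count whose exact-anisotropic
MI profile has minimal RMSD to the multivariate-Gaussian profile of the same
data) and a **convergence protocol** (cut segments of increasing length from
a long trajectory, average MI over segments, and track RMSD and Pearson r of
the resulting MI profiles against a reference).

## Worked example

Generate a synthetic Gaussian trajectory with known ground truth, estimate
MI, and check the histogram estimator against the closed form:

```python
import numpy as np
from dyncorr import (
    sample_gaussian_trajectory, pair_covariance, multivariate_gaussian_mi,
    exact_anisotropic_mi, select_grid_size,
)
from dyncorr.synthetic_data import make_single_rho_spec

# two residues, correlation 0.5 between their x axes: true MI = -1/2 ln(1-0.25)
spec = make_single_rho_spec(0.5, seed=1)
fluct = sample_gaussian_trajectory(spec, 100_000)

gauss = multivariate_gaussian_mi(pair_covariance(fluct, 0, 1))
grid = select_grid_size(fluct, pairs=[(0, 1)]).chosen
exact = exact_anisotropic_mi(fluct, 0, 1, grid)
print(f"true     {-0.5 * np.log(0.75):.4f} nats")
print(f"gaussian {gauss.value:.4f} nats")
print(f"exact    {exact.value:.4f} nats  (grid {grid.n_bins})")
```

```
true     0.1438 nats
gaussian 0.1489 nats
exact    0.1409 nats  (grid 6)
```

Both estimators recover the analytic value; the Gaussian one from 36
covariance entries, the histogram one from ~10⁵-cell occupancies at the
selected grid.  The same machinery runs from the shell:

```sh
dyncorr synth --kind gaussian --n-residues 6 --n-frames 100000 --seed 7 --out traj.tsv
dyncorr mi --traj traj.tsv --method gauss-multi --map --out map.tsv
dyncorr gnm --pdb structure.pdb --cutoff 7.3 --modes 1-all --out gnm_map.tsv
dyncorr converge --traj traj.tsv --lengths 1000,10000,100000 \
    --estimator gauss-multi --anchor 1 --out curve.tsv
dyncorr gridsearch --traj traj.tsv --out grids.tsv
```

For the 3-residue collinear chain (a hand-checkable GNM case), `dyncorr gnm
--cutoff 4 --modes 1-all` reports MI(1,3) = 0.5108 nats — the end beads are
strongly anti-correlated through the single slow mode, and −½ ln(1 − 0.8²)
= 0.5108 follows directly from the pseudoinverse of Γ.

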