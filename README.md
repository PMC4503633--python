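# confent

Distance-based configurational entropy of molecular ensembles.

`confent` estimates the entropy of conformational, translational and
rotational distributions directly from the distances between samples — the
k-nearest-neighbor approach — rather than from histograms or from the
quasi-harmonic (covariance) approximation. It is aimed at structural
bioinformatics and molecular-modelling work where the quantities of interest
are the conformational entropy of protein folding (per residue, from torsion
angles) and the rototranslational entropy lost when a ligand binds a receptor
or a protein adsorbs on a surface.

## The estimator

For *n* samples of an *s*-dimensional variable with density *p*, let
*R*<sub>*i*,*k*</sub> be the distance of sample *i* from its *k*-th nearest
neighbor. The unbiased nearest-neighbor estimator of the differential entropy
(in units of k<sub>B</sub>, natural logarithm) is

    S_k(n) = (s/n) Σ_i log R_{i,k} + log( n π^{s/2} / Γ(s/2 + 1) )
             − L_{k−1} + γ

with γ Euler's constant and L_0 = 0, L_j = Σ_{i≤j} 1/i. The middle term is
log(*n* · V₁) with V₁ the unit-ball volume, so on spaces with a non-Euclidean
ball law the estimator generalises to
S = (1/n) Σ log(n · V(R_{i,k})) − L_{k−1} + γ with V the ball-volume law of
the space. Three sample spaces are built in:

- **torus** — torsion angles with periodicities Θᵢ, circular per-angle
  distances combined in quadrature; uniform reference entropy Σ log Θᵢ;
- **Euclidean** — translation vectors in Å; the 1 M standard state
  (1660 Å³ per molecule) is the translational reference;
- **rotation group** — 3×3 matrices with distance
  d = arccos[(Tr(R₂⁻¹R₁) − 1)/2] and Haar ball volume 4π(d − sin d);
  uniform reference log 4π².

Comparators included: a binned (histogram) estimator for translations
(0.133 Å bins) and rotations (equal-Haar-measure axis/angle bins), and the
classical quasi-harmonic entropy change ½ log(det Σ_B / det Σ_A).

## Worked example

The restricted-rotor toy shows why nearest-neighbor beats quasi-harmonic
analysis for bounded, curved supports. A bond angle free on the full circle
is restricted to a window Δθ = π/3; the true entropy change is
log(Δθ/2π) = −1.79 k_B:

```sh
$ confent rotor-demo --dtheta 1.0472 --n 100 --replicates 2000 --seed 7
exact dS               -1.7918 kB
quasi-harmonic dS      -3.7476 kB
QH/exact ratio          2.0916
NN RMS error              8.05 % (n=100, replicates=2000)
```

The quasi-harmonic change, computed from the analytic covariance of the
end-atom coordinates (cos θ, sin θ), overshoots the true loss by a factor of
two; the nearest-neighbor estimate from only 100 samples per replicate is
unbiased with a purely statistical RMS error of a few percent.

From Python, entropies carry their provenance:

```python
>>> from confent import entropy_knn, relative_to_uniform
>>> from confent.synthetic import DensitySpec, sample
>>> s = sample(DensitySpec("vonmises", mu=(0.0, 0.0), kappa=(8.0, 8.0)), 300, seed=1)
>>> est = entropy_knn(s)                      # two torsion angles, 300 snapshots
>>> print(est)
S = 0.7780 kB (k=1, n=300, s=2, <R_k>=0.04865)
>>> print(relative_to_uniform(est, s.space))
S = -2.8977 kB relative to uniform-torus (k=1, n=300, s=2, <R_k>=0.04865)
```

(The exact entropy of this two-angle von Mises density is 0.828 k_B, i.e.
−2.85 k_B relative to uniform; the estimate is within one standard error.)

Other subcommands: `torsion-entropy` and `folding-entropy` (per-residue
entropies from a multi-model PDB or an angle table, with unfolded-state
reference subtraction and contact-cluster sums), `rototrans-entropy`
(ligand-pose extraction and binding entropy vs the 1 M / uniform-rotation
standard states), `hist-entropy`, `profile`, and `synth` (synthetic
fixtures with ground-truth sidecars).

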