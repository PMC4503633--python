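# Methods

## The estimator and its assumptions

All entropies are differential entropies −∫ p log p in units of k_B
(natural logarithm). The core estimator is the unbiased k-nearest-neighbor
form: each sample's local density is inferred from the volume of the metric
ball reaching its k-th neighbor, and the bias of the plug-in average is
removed exactly by the −L_{k−1} + γ correction. Two assumptions matter in
practice:

1. **The ball-volume law must hold at the neighbor scale.** On a torus the
   Euclidean (hypersphere) law is exact only up to half the smallest
   periodicity; on the rotation group the Haar law 4π(r − sin r) is exact
   everywhere up to the group diameter π. Estimates whose mean neighbor
   distance exceeds these ranges carry an `uncorrected-volume` warning
   rather than an attempted correction (exact finite-periodicity volumes
   are out of scope).
2. **Absolute values depend on the distance unit**; only differences with
   respect to a reference (or between states) are unit-free. References
   provided: Σ log Θᵢ (uniform torsion angles), log 4π² (uniform
   rotations), log 1660 Å³ (the 1 M translational standard state,
   10²⁷/N_Av computed at run time, 1660.54 Å³), and caller-supplied
   volumes for 1-D spaces, which have no universal standard state.

`k` defaults to 1. Larger k trades variance for resolution: the mean k-th
neighbor distance is the length scale at which the density is probed, which
is why the entropy-vs-k profile rises on multimodal data once the probing
scale crosses between modes (and why the profile, not k itself, is the
meaningful abscissa).

Duplicate samples carry no volume information and would send log R to −∞;
duplicates beyond the first occurrence are dropped with a warning and the
estimate recomputed on the remainder. Neighbor search is brute force over
the exact metric (chunked, never materialising the full n² matrix), with a
KD-tree fast path for Euclidean/line spaces only; the two paths agree
exactly and are cross-checked in the tests. The arccos argument of the
rotation metric is clamped to [−1, 1]; rotation ball volumes are floored at
the smallest positive float because r − sin r underflows for near-duplicate
rotations.

## Torsional pipeline

Entropies are computed residue by residue on the joint torus of the
residue's rotatable torsions: backbone φ, ψ; sidechain heavy-atom χ angles;
and torsions ending in a polar hydrogen (Ser/Thr hydroxyl, Cys thiol, Tyr
hydroxyl, Trp indole N–H). Proline rings, aromatic rings, amide and
guanidinium planes are rigid; threefold methyl/amino rotors are excluded
because their conformational distribution is assumed unchanged by the
processes studied, so they cancel in any entropy difference. The resulting
internal counts are ALA/GLY/PRO 2, VAL 3, ILE/LEU/SER/THR/CYS/ASP/ASN/HIS/
PHE 4, MET/GLU/GLN/TYR/TRP 5, LYS/ARG 6; disulfide-bridged cysteines
(SG–SG < 2.5 Å) reduce to φ, ψ, χ1. The Trp count includes the indole N–H
torsion: its four-atom definition (CG-CD1-NE1-HE1) satisfies the
three-heavy-atoms-plus-polar-hydrogen rule even though the ring itself is
rigid, and it is what brings tryptophan to five torsions.

Terminal residues lose φ (N-terminal) or ψ (C-terminal). Inter-residue
correlations are neglected by design — the per-residue factorisation is the
model — and the φ_i/ψ_{i−1} mutual-information helper exists precisely to
quantify that neglect on any given ensemble.

The packaged unfolded-state reference table gives the entropy of each
amino-acid type (relative to uniform angles) in unfolded-like conformations,
with N-/C-terminal variants; subtracting it from a folded-ensemble entropy
yields the per-residue conformational entropy of folding. Contact clusters
(any interatomic distance < 1 Å + sum of Bondi van der Waals radii, self
included) sum folding entropies into an estimate for the local opening
reaction around each residue. The table's secondary-structure and
hydrogen-bond filters belong to its construction and are not recomputed
here.

## Rototranslational pipeline

A snapshot's ligand pose is reduced to (R, t): frame atoms of the receptor
are superposed onto a reference snapshot by least-squares (Kabsch, proper
rotations only, degenerate point sets rejected), then the reference triad
of ligand atoms (default: central-residue N, CA, C — chosen by ranking
candidate triads by post-fit fluctuation, most rigid first) is superposed
onto the aligned snapshot triad. The translation recorded is the
displacement of the triad centroid, which keeps the translation sample
independent of the rotation sample. Rotational and translational entropies
are then estimated independently — an explicit simplification that can
underestimate the loss when the two are correlated — and referenced to the
uniform-rotation and 1 M standard states; −TΔS is reported at 300 K
(k_B·T·N_Av = 0.596 kcal/mol).

For surface-bound molecules the translational state is the height above
the plane (1-D estimator, caller-supplied reference length) and the
rotational entropy gains +log 2π because spin about the surface normal
remains free in the bound state.

## Histogram comparators

Translations are binned on a cubic grid of width 0.133 Å anchored at the
per-axis sample minimum (translation invariant, and flush with data whose
support spans a whole number of bins, which a centroid anchor is not).

Rotations are converted to an axis (azimuth φ, polar ψ) and a signed angle
θ. The canonical representative fixes the axis to the upper hemisphere
(ties: positive x, then y) and signs θ accordingly; θ is restricted to
[−π/2, π/2] and samples with a larger rotation angle are left unbinned
(flagged) while still counting in the normalisation. Bins are equal-measure:
φ uniform, ψ uniform in cos ψ, θ in equal increments of ∫(1 − cos θ).
Because the canonical axis occupies only the upper hemisphere, a ψ-bin's
Haar weight is the overlap of its cos range with [0, 1]; each occupied bin
contributes p̂ᵢ (log Vᵢ − log p̂ᵢ) with Vᵢ its true Haar fraction of the
full group. This construction makes the estimate an honest relative entropy
against uniform rotations: Haar input reads 0, a uniform cap of angle π/2
reads log((π/2 − 1)/π), and a point mass reads log(f/5000) with
f = (π/2 − 1)/π under the default 10 × 10 × 100 binning.

Both comparators are only meaningful when the ensemble spread is
commensurate with the bin scale: much tighter ensembles hit the resolution
floor (entropy overestimated), much broader ones undersample (more occupied
bins than samples, entropy underestimated). The nearest-neighbor estimator
has no such window, which is the practical argument for it.

## Quasi-harmonic comparator and the rotor toy

Entropy changes only: ΔS = ½ log(det Σ_B / det Σ_A), exact for Gaussian
fluctuations and for range restrictions of a 1-D uniform variable.
The restricted-rotor toy (end atom on a unit circle, angle uniform on a
window Δθ centred at 0 — the toy is rotation invariant, so the centring is
immaterial) uses analytic covariances of (cos θ, sin θ). At Δθ = π/3 the
quasi-harmonic change overshoots the exact log(Δθ/2π) by the factor 2.0916;
the overshoot holds for all Δθ up to at least a half circle and reverses
only as Δθ → 2π where both changes vanish. The nearest-neighbor benchmark
draws n = 100 angles per replicate, estimates the restricted entropy with
k = 1, forms the change against the exact free entropy log 2π, and reports
the RMS deviation from the exact change over 2000 replicates as a percent
of |ΔS| — this denominator is a documented choice, since "percent error"
for an entropy change admits several readings. Under this definition the
error is ≈ 8% (the estimator's asymptotic standard deviation is
√(ψ′(1)/n) = 0.128 k_B, i.e. 7.2% of |ΔS|, plus finite-sample effects);
a ~5% figure would correspond to k = 2–3 or n ≈ 250 under the same
definition.

## Synthetic data

The generator module covers every input class with known ground truth:
uniform intervals and tori, von Mises rotamers and mixtures, Gaussians,
exactly-Haar rotations (normalised 4-D Gaussian quaternions) and
cap-restricted rotations (rejection). `numeric_entropy_oracle` supplies the
matching −∫ p log p by closed form or adaptive quadrature, independent of
any estimator. Idealised polypeptide backbones are built from prescribed
φ/ψ by natural-extension placement with standard bond geometry and trans
peptide bonds. The toy complex plants a rigid, asymmetric receptor frame
and a ligand triad with Gaussian centroid translations and cap-uniform
rotations, wraps every snapshot in a random global rigid motion, and keeps
the ground truth for end-to-end recovery tests.

The bound-ensemble panel used for the nearest-neighbor/histogram
cross-check draws translational σ in 0.10–0.18 Å and a mean pose angle in
0.85–1.25 rad with rotational spread tied to it (0.20 + 0.20·(θ₀ − 0.85)),
i.e. inside the comparator validity window described above. What these
synthetic ensembles do *not* emulate: anisotropic and correlated
fluctuations, multimodal binding poses, slow conformational drift, or any
coupling between internal and external degrees of freedom — so passing
tests demonstrate estimator correctness on controlled densities, not
fidelity to any particular molecular system.

## Problem sizes and tolerances

Torsional examples use 300 snapshots (and 150-snapshot halves for the
stability check); rototranslational ensembles use 1000–2000 snapshots;
oracle-equivalence checks run at n = 10⁴ with a tolerance of three
conservative standard errors (3 · 3/√n, bounding the per-sample standard
deviation of the k = 1 estimator across the densities used); uniform-input
histogram checks use 10⁵–10⁶ rotations so that bin-occupancy bias
(≈ N_bins/2n) stays below the 0.05 k_B tolerance. Deterministic quantities
(ball volumes, references, the quasi-harmonic ratio, table arithmetic) are
asserted to ~1e-3 or tighter.

## Known limitations

- No finite-periodicity volume corrections: wide torsional distributions
  (neighbor distances beyond half a periodicity) are flagged, not fixed.
- Per-residue factorisation ignores inter-residue correlations; the MI
  helper measures, but does not remove, the approximation.
- Rotational/translational independence in the binding pipeline.
- The rotational histogram cannot represent rotations with angle > π/2;
  they are excluded from the bins (and flagged), matching its reference
  construction.
- The 1-D (surface) translational standard state is a free parameter; no
  convention is imposed.
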