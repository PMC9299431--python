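# Methods

This note documents the models and procedures implemented in voxsite, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not
establish.

## Active-site voxelization

A cubic box (default edge 20 Å) is centred on the unweighted mean of the
side-chain heavy atoms of the user-named catalytic residues and divided into
voxels (default edge 1 Å, so a 20×20×20 grid). Only side-chain heavy atoms
of standard residues are deposited: backbone atoms (`N, CA, C, O, OXT` and
their hydrogens) are excluded so that a classifier trained on the grids
cannot key on backbone geometry, and CB is treated as side chain so that
alanine retains one informative atom. Hydrogens are parsed but never
featurized; no protonation is added.

Each deposited atom contributes a 13-feature vector, all features in [0, 1]:

| channel | meaning |
|---|---|
| 1–4 | element one-hot: C, N, O, S |
| 5 | aromatic-ring atom |
| 6 | aliphatic hydrophobic atom |
| 7 | H-bond donor heavy atom |
| 8 | H-bond acceptor heavy atom |
| 9 | positively ionizable group member |
| 10 | negatively ionizable group member |
| 11 | amide side-chain atom |
| 12 | hydroxyl / thiol atom |
| 13 | residue-type ordinal / 20 |

Channel 13 makes the per-residue multiset of vectors injective over the 20
standard residues (verified exhaustively in the tests), so chemically
analogous residues such as Asp and Glu are encoded differently.

Voxel intervals are half-open `[lo, hi)`. When two atoms fall into one voxel
the atom nearest the voxel centre wins and a warning is logged; the
idealized one-atom-per-1 Å-voxel premise holds for most real side-chain
packing but is not guaranteed. After deposition every channel is convolved
with a truncated Gaussian (default σ = 1 Å, truncation radius 3σ), with the
discrete kernel normalized to unit mass so channel totals are preserved for
atoms at least the truncation radius from every box face. Whether distinct
atom classes should receive distinct kernel widths is ambiguous; a uniform
per-channel σ is used and exposed in `SmearingConfig`.

Rotations for augmentation and for scan-time prediction are drawn uniformly
from SO(3) by the normalized-quaternion method and applied about the box
centre, so no atom within a sphere of radius box_edge/2 of the centre ever
leaves the box under rotation.

Datasets are split 0.7 : 0.15 : 0.15 (train : test : validation) **at the
structure level before augmentation** — rotated copies inherit their source
structure's split — so augmentation can never leak a structure across
partitions. Split sizes use the largest-remainder rule with ties broken in
train, test, validation order; membership is a seeded shuffle.

## Classifier

The networks are implemented in numpy (forward and backward passes written
out; Adam with global-norm gradient clipping at 5; softmax cross-entropy).
This keeps the package free of a deep-learning-framework dependency and
deterministic given a seed and a fixed BLAS thread count; bitwise
reproducibility across BLAS builds is not guaranteed for float32 matmuls.

`tiny3d` (default): average-pool the grid by 4 (20³ → 5³), a 3³ stem
convolution with batch norm, three residual blocks (conv–BN–ReLU–conv–BN
plus identity skip) at width 16, global average pooling, and — concatenated
with the CNN features — the *global channel means of the raw input grid*,
batch-normalized, feeding a zero-initialized softmax head. The global
composition branch reflects what the voxel representation makes true by
construction: family identity is largely carried by the overall channel
composition near the site, while the convolutional branch contributes
geometry-sensitive features. Because the head is zero-initialized, an
untrained model predicts the uniform distribution.

`resnet50_3d` keeps the canonical [3, 4, 6, 3] bottleneck-block layout of
ResNet-50 translated to 3D, at configurable (desk-scale, default 16) base
width. It is provided for architectural fidelity; the tests train `tiny3d`,
since a 50-layer 3D network is GPU-scale and adds nothing to the synthetic
benchmark.

Inputs are scaled per channel by 1/RMS (computed on up to 257 training
grids), floored at 0.1× the global RMS so sparse-but-informative channels
are boosted by at most 10× relative to dense ones; unbounded per-channel
standardization destabilized training on sparse grids.

Training defaults: Adam lr 3×10⁻³, batch 16, up to 30 epochs, early stopping
on validation accuracy (patience 8), stop immediately when validation
reaches 1.0, restore the best-validation weights (and batch-norm running
statistics). Inverse-frequency class weights are available but off by
default. Training indexes the grid array batch-by-batch and never
materializes whole partitions, keeping the 3×30×50 benchmark under ~2.5 GB.

## Alanine scan

Mutation is side-chain truncation to CB with relabelling to ALA. A
rebuild-based mutation would differ only in backbone and hydrogen placement,
which the featurizer ignores, so truncation is feature-equivalent and needs
no external tool. Gly and Ala targets return a skip signal.

A mutant is scored by `n_predictions` (default 1000) independent
featurize-and-predict passes under uniform rotations:
`S = p_true − max_{c≠true} p_c ∈ [−1, 1]`. For two classes this reduces
exactly to `S = 2·p_true − 1`. The Monte-Carlo standard error of S scales as
`n_predictions^(−1/2)` (property-tested); at n = 100 it is ≈0.05 for a
maximally uncertain classifier, which is why the acceptance benchmark can
use 100 predictions per mutant instead of 1000 without affecting rank-1
identification of the planted residue — the planted score gap is more than
an order of magnitude larger.

The iterative protocol scans every non-frozen residue with a side-chain
heavy atom inside the box, on top of the already-accumulated ("frozen")
mutations; after each iteration all residues whose score drop relative to
the current-background wild type is ≥ δ (default 0.5) are frozen, and the
loop stops at `max_iterations` (default 4) or when no residue passes. The
accumulation criterion is an explicit stand-in: the field's iterative
protocols do not state a numeric rule. A consequence worth knowing: if two
residues *redundantly* determine the class, a well-trained classifier keeps
classifying either single mutant correctly, so neither can ever pass δ —
sequential accumulation requires non-redundant evidence, and the benchmark
plants exactly one discriminative residue per family.

## Electrostatics

Potentials and fields are bare vacuum Coulomb sums (no dielectric, cutoff,
or periodicity): `V(r) = k_C Σ q_i/|r−r_i|`, `E(r) = k_C Σ q_i(r−r_i)/|r−r_i|³`,
with `k_C = e²N_A/(4πε₀·10³·10⁻¹⁰) ≈ 1389.35 kJ·mol⁻¹·Å·e⁻²` from CODATA
2018 constants. Unit systems: kJ·mol⁻¹·e⁻¹ (fields per Å) and atomic units
(hartree·e⁻¹, fields per bohr); conversions round-trip to 1e−12.

Bond projections report `E·u` at the two bond atoms, the corresponding force
components `qE·u`, and a net attraction `A = F_from·u − F_to·u` with `u`
pointing from the first atom to the second. The sign convention (A > 0
compresses the bond) is this package's own documented choice; the figure
convention in the source literature is not stated.

Counterion placement is greedy on a regular grid (default 0.5 Å) over the
solute bounding box padded by `min_solute_dist + 5 Å`: admissible points lie
≥ 10.5 Å from every solute atom and ≥ 5 Å from every placed ion; each ion
goes to the most negative potential ("optimal electrostatic position" read
as most negative, appropriate for a cation), ties broken deterministically
by grid order. Already-placed ions contribute to the potential for
subsequent placements by default (physically sensible and prevents
clustering); a flag disables this. `n_ions="neutralize"` places
`round(−net/ion_charge)` ions.

## Kinetics

Eyring conversions use transmission coefficient 1 and CODATA 2018 constants
(k_B = 1.380649×10⁻²³ J·K⁻¹, h = 6.62607015×10⁻³⁴ J·s,
R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹): `ΔG‡ = RT·ln(k_B·T/(h·k))` and its
inverse. Temperatures are always caller-supplied (a 294 K measurement and a
300 K simulation must never be conflated). Note that a rate/barrier pair
printed at 0.1 kcal·mol⁻¹ precision constrains the inverse rate only to
±exp(0.05/RT) ≈ ±9%.

Michaelis–Menten fits use scipy nonlinear least squares on
`v = k_cat·E·S/(K_M+S)` with the initialization Vmax₀ = max rate and
K_M₀ = concentration nearest half-max; standard errors come from the local
curvature, and the error on k_cat/K_M is propagated including the parameter
covariance. At least four distinct concentrations and a nonzero signal are
required.

## Synthetic data

The generator emulates small labelled enzyme families whose class identity
is carried by side-chain composition near a catalytic triad, at desk scale:
16 residues on a ring of radius 9 Å with side chains pointing inward
(idealized pseudo-atom geometry, deliberately not rotamer-accurate — the
featurizer consumes only identities and positions), a Ser–His–Asp triad at
fixed positions, and per-family *motif* residues at designated positions.
The default benchmark is 3 families × 30 structures differing at one motif
position (TRP / LYS / GLU — disjoint feature channels), jitter σ = 0.25 Å of
i.i.d. Gaussian coordinate noise per atom, mirroring a three-family
serine-hydrolase setup at desk scale. With jitter ≤ 0.3 Å the unrotated
grids are perfectly separable by nearest centroid (tested), so a
classification failure indicts the model, not the data.

Charged test systems (point, dipole, random cloud) and Michaelis–Menten
rate tables (default: k_cat = 18.54×10⁻³ s⁻¹, K_M = 0.182 mM,
[E] = 3.6×10⁻⁷ M, eight concentrations 10 µM–3 mM, 5% relative Gaussian
noise) are generated with declared ground truth and fixed seeds.

What a green benchmark does **not** establish: performance on real,
redundant, conformationally diverse PDB families; robustness of the
13-feature encoding choices against alternative definitions; or any claim
about absolute electrostatic magnitudes in a real protein environment,
which depend on simulation-derived charge sets this package does not
compute.

## Known limitations

- The voxel collision rule (keep nearest to voxel centre) discards atoms in
  densely packed real sites; the log reports how many.
- The numpy networks are CPU-bound; `resnet50_3d` at realistic widths is
  impractical without an accelerator framework.
- PQR parsing accepts the common whitespace dialect only; mmCIF,
  assemblies, altloc ensembles beyond first-kept, and residue renumbering
  are out of scope.
- The greedy ion placer evaluates the full admissible grid each step;
  systems much larger than a few thousand atoms will want a coarser grid.
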