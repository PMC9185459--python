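# Methods

## Physical model

The package treats 2D transverse-magnetic scattering from non-magnetic
dielectric objects immersed in a homogeneous background of relative
permittivity `eps_rb` (default 10) and conductivity `sigma_b` (default
lossless). Scatterers inside the square domain of interest D are
described by the complex contrast

    chi(r) = (eps_r(r) - eps_rb) / eps_rb - j (sigma(r) - sigma_b) / (omega eps_b),

which is identically zero outside the scatterer support. Two coupled
integral equations govern the fields, with the e^{j omega t} time
convention and the 2D free-space Green function
g(r, r') = -(j/4) H0^(2)(k_b |r - r'|):

* the **state equation** — the total field inside D equals the incident
  field plus re-radiation by the induced contrast currents
  J = chi * E_t;
* the **data equation** — the scattered field at external receivers is
  the radiation of those currents.

Note on the contrast definition: with a non-unit background the
numerator of the real part must be `eps_r - eps_rb`; any constant-offset
variant would give the background itself a nonzero contrast and the
state/data equations would not vanish outside the scatterer.

## Discretisation

D is divided into M x M square pixels (row-major enumeration, x fastest,
origin at the domain centre). Pulse-basis point matching with an
equal-area circular cell of radius `a = sqrt(dx*dy/pi)` gives the
closed-form matrix elements

    g_mn = -(j/2) pi k_b a J1(k_b a) H0^(2)(k_b |r_m - r_n|),  m != n
    g_nn = -(j/2) [pi k_b a H1^(2)(k_b a) - 2j],

the classical equivalent-circle pair: the off-diagonal form is the exact
integral of the continuous kernel over the equal-area circle (addition
theorem), the diagonal its self-cell counterpart. The radius must carry
the square root — `dx*dy/pi` alone has units of area and is dimensionally
inconsistent as a Hankel argument. A unit-test oracle checks both forms
against adaptive quadrature of the continuous kernel on electrically
small cells; the approximation degrades for cells larger than about a
tenth of a wavelength, which bounds sensible grid choices.

The state equation `(I - G_D diag(chi)) E_t = E_i` is solved by dense LU
for N <= 1200 pixels and otherwise by a matrix-free Krylov method
(BiCGStab with GMRES fallback, relative tolerance 1e-8) whose G_D
matvec exploits the block-Toeplitz structure of the kernel via 2D FFTs
on a doubled grid. Incident fields are unit-amplitude line sources,
E_i = H0^(2)(k_b |r - r_p|); amplitude consistency between simulation
and inversion makes the absolute source strength immaterial.

Data are always simulated on a grid finer than the inversion grid
(150 x 150 versus 64 x 64 at full scale) to avoid the inverse crime; the
generator warns if the two coincide.

## Inversion

The Born iterative method alternates (a) a total-field solve with the
current contrast and (b) a linearised contrast update. Each update is
the convex program

    min_{d, chi}  sum_m |d_m|^2 + lambda ||grad chi||^2
    s.t.  d_m + sum_n g_mn chi_n E^t_n = E~s_m   (all receivers, sources,
                                                  frequencies)
          chi in box bounds,

with a single contrast vector shared across the stacked incidences.
Since QP machinery operates on real quantities, the complex misfit is
rearranged into real and imaginary parts: the Hermitian data Gram
H = sum B^H B becomes the symmetric block form [[Re H, -Im H], [Im H,
Re H]] acting on z = [Re chi; Im chi]. The slack variables d are
eliminated analytically (the equalities fix d at the residual), leaving
a box-constrained strictly convex quadratic with a unique global
minimum. It is solved by a compiled bound-constrained quasi-Newton
descent followed by exact Newton polish on the identified active set;
every update is verified post hoc by a scaled KKT residual <= 1e-6.

Choices that the problem statement leaves open, fixed here:

* **Tikhonov weight** `lambda`: default `1e-2 x trace(H) / trace(R)`
  where R is the Gram of forward first differences (zero-flux boundary).
  The trace ratio makes the default scale-free across grid sizes and
  data magnitudes; it is overridable per run.
* **Box bounds**: Re chi from the tissue permittivity range [2.5, 67];
  Im chi in [-(sigma_max - sigma_b)/(omega_ref eps_b), 0] with
  sigma_max = 4 S/m, a loose physical cap.
* **Frequency-independent contrast**: one chi is fitted to all
  frequencies. Its real part is physically frequency-independent; the
  imaginary part absorbs a conductivity scaled at the mid-band reference
  frequency, which also converts the final chi back to (eps_r, sigma)
  maps. For the lossless circular phantom this is exact; for lossy
  phantoms it is a deliberate model reduction.
* **Initial guesses**: `born_zero` (first-Born update from the sources of
  the highest — best-resolved — frequency), `multi_freq_source` (the same
  update jointly over all sources and frequencies), and `constant_min`
  (uniform chi at the minimum permittivity, used for the breast sweep).
* **Stopping**: a fixed iteration budget (10 for the circular protocol,
  5 for the breast sweep), matching the study design; no adaptive rule.
* **Degenerate inputs**: an all-zero dataset returns the regularised
  minimum (zero contrast) rather than erroring; a singular forward solve
  mid-iteration aborts with the partial iterate preserved.

The per-iteration record keeps every contrast iterate and the data
residual `||E~s - Es(chi_k)|| / ||E~s||` computed with a full forward
solve, so residual monotonicity can be audited after the fact.

## Refinement network

A small U-Net regresses reconstructed permittivity maps onto
ground-truth maps. Contracting path: per level, two 3x3 convolutions
each with batch normalization and ReLU, then 2x2 max pooling (stride 2)
with channel doubling. Expanding path: nearest-neighbour upsampling,
a 2x2 convolution halving the channels, concatenation with the
corresponding contracting feature map, then two 3x3 convolutions with
ReLU. A final 1x1 convolution projects to the single-channel map.
The layers and backpropagation are implemented directly on numpy
arrays (im2col convolutions), with an Adam optimizer; gradient
correctness is tested against finite differences.

Training details (unstated in the study design, fixed here): maps are
normalised to [0, 1] by the (2.5, 67) range and de-normalised (and
clipped) on output; squared-error loss; 90/10 train/validation split by
seeded shuffle with a floor rule (108 pairs -> 97/11); no augmentation.
Defaults: depth 4 with 16 base channels for 64 x 64 maps; depth 3 for
the desk-scale 24 x 24 maps. Only permittivity is refined; conductivity
is regenerated from the refined map through the linear tissue model
sigma = 0.019 eps_r - 0.047 (floored at zero, which only engages below
eps_r ~ 2.47, just under the tissue range).

## Synthetic breast phantoms

The four-class generator emulates 2D slices of MRI-derived anatomies:
a slightly eccentric breast outline of 6 cm radius, a 2 mm skin ring
(eps_r 36), a fatty interior (eps_r 5.5 +- 10% smooth heterogeneity),
and a fibroglandular compartment (eps_r 42 +- 10%) obtained by
thresholding a smooth Gaussian random field, biased toward the breast
centre, at the class area fraction (10 / 25 / 45 / 65% of the interior
for classes 1-4). Tumors (eps_r 62) of 3, 5 or 8 mm diameter are
implanted at nine fixed positions: (0, 0), (0, +-1.9), (+-1.9, 0),
(+-1.9, +-1.9) cm. All random structure is built from random Fourier
features — continuous functions of position — so one seed renders
consistently at any grid resolution, and one anatomy per (class, seed)
is shared across all tumor placements, as for repeated acquisitions of
one patient. Conductivity follows the linear tissue model inside the
breast and equals the background outside.

What the generator does *not* emulate: true anatomical texture and
ductal structure, dispersive (frequency-dependent) tissue properties,
skin thickness variation, and inter-patient variability beyond the
random field. Consequently, passing the sweep shows that the chain
recovers layered piecewise-smooth dielectric structure of the right
scale and class ordering — not that it would meet clinical accuracy on
real breasts.

## Problem sizes and protocols

Two canonical protocols are shipped (`mwtomo.presets`):

* **Circular validation**: 18 x 18 cm domain, 150 x 150 simulation grid,
  18 sources and 30 sampling positions on a 10 cm ring, 15 equispaced
  frequencies from 600 kHz to 600 MHz, 10 BIM iterations. The package's
  standard check inverts on 32 x 32 (the full 64 x 64 inversion is a
  configuration change away and roughly 8x slower per update).
* **Breast sweep (desk scale)**: 64 x 64 simulation grid, 24 x 24
  inversion grid, 8 sources, 18 receivers, 5 frequencies, 5 iterations
  with the `constant_min` start, followed by refiner training (depth 3,
  16 base channels, 150 epochs, learning rate 1e-3, batch 16). The
  full-scale protocol (150 x 150 / 64 x 64, 18 sources, 15 frequencies)
  is expressed by the same configuration schema.

At the desk scale a 24 x 24 pixel spans 7.5 mm, so the implanted tumors
are at or below one pixel; they are retained for protocol fidelity, but
the sweep's error metric is dominated by the skin/fat/gland anatomy.
Tumor-scale localisation requires the full 64 x 64 inversion grid.

## Numerical edge cases

* Grids require at least 2 pixels per side and positive extent; sources
  must not coincide with pixel centres (singular Hankel argument).
* Receivers may lie inside the square domain (the 10 cm ring crosses
  the 18 cm square's corners) — the sampled cells must simply carry zero
  contrast; exact coincidence with a pixel centre is rejected.
* The QP Hessian is regularised by a relative ridge of 1e-13 x mean
  diagonal for Cholesky; singular (rank-deficient, lambda = 0) systems
  fall back to a pseudo-inverse solve returning the minimum-norm
  minimiser.
* Relative-error reports reject all-zero truth maps (undefined ratio).
* Dataset noise, when requested, is complex white Gaussian calibrated
  to a per-frequency SNR and recorded (type, level, seed) in the
  dataset's metadata; the default is noiseless.

## Known limitations

* The Born-type linearisation saturates on very strong scatterers; the
  circular model (chi = 3 outer shell) reconstructs structure but not
  exact values — that is the gap the refinement network closes on the
  phantom families it was trained on.
* A single shared contrast across frequencies biases the imaginary part
  for strongly dispersive loss profiles.
* The refiner is a per-protocol model: a checkpoint trained at one grid
  size and phantom family does not transfer to another without
  retraining.
* 3D propagation, near-field antenna models and matching media other
  than a homogeneous background are out of scope.
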