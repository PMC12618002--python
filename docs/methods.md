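# Methods

## The model

`vqfold` implements a two-stage generative model over protein backbones
(the N, CA, C, O atoms of each residue).

**Stage 1 — vector-quantized auto-encoder.** An SE(3)-invariant encoder maps
a backbone to one continuous latent vector per residue (d = 16 by default).
Each residue becomes a node in a k-nearest-neighbor graph (k = 30 by CA-CA
distance); node features are the CA→N, CA→C and virtual-CB unit directions
expressed in the residue's own rigid frame, and edge features are the
one-hot signed sequence separation (clipped at ±32, with a dedicated
cross-chain class), a 16-bin Gaussian RBF of the CA-CA distance over
2-22 Å, the inter-residue direction in the source frame, and the relative
orientation as a w ≥ 0 quaternion. Because every feature is frame-local,
any rigid motion of the input leaves the latents numerically unchanged
(verified to 1e-4). Message-passing layers aggregate neighbor messages;
a final linear layer emits the latents.

Each latent row is snapped to the nearest row (squared Euclidean distance,
ties to the smaller index) of a learned codebook of K vectors (K = 8192 by
default; the miniature benchmarks use K = 64). The total training loss for
a backbone x is

    L(x) = L_D(x, D(e)) + ||sg(E(x)) − e||² + β ||sg(e) − E(x)||²,

with β = 0.25 and `sg` the stop-gradient operator: the middle term moves
only the codebook, the last only the encoder, and reconstruction gradients
reach the encoder through the straight-through estimator (forward value =
quantized latents, gradient passed through unchanged). Dead codebook rows
(unused for 1000 steps) are re-seeded from a current encoder output. The
codebook is initialized from the per-dimension mean/std of the first
encoded batch.

**Decoder.** The quantized latent array passes through self-attention
blocks (sinusoidal position encoding) and three per-residue heads that
predict (i) a relative rigid-frame update with respect to the previous
residue — a rotation via Gram-Schmidt around an ideal-helix bias, and a
translation in the previous frame — (ii) small deviations of the four
backbone atoms from ideal local geometry, and (iii) a token-conditioned
global coordinate correction. The chain of frames is composed by an
inclusive parallel prefix scan over affine transforms, so the network works
with local, near-unit-scale quantities, and an untrained decoder emits an
ideal helix rather than an arbitrary point cloud. Decoding is a
deterministic pure function of the latents; combined with the invariant
encoder, reconstructions of rigidly moved inputs superpose exactly.

**Reconstruction loss L_D.** Three SE(3)-invariant terms:

1. frame-aligned point error: all present backbone atoms expressed in every
   residue frame of each structure (its own frames for each side), the
   per-pair distance clamped at 10 Å and normalized; 10 % of the term is
   left unclamped so grossly misplaced and mirror-image geometry still
   receives a gradient;
2. a CA-CA distance-map term over target pairs closer than 20 Å, with the
   per-pair squared error clamped at (5 Å)² and normalized to [0, 1] so that
   badly misplaced pairs cannot drown every other gradient;
3. multiscale relative-frame consistency: the rotation and translation of
   residue i+s in the frame of residue i, compared to the target at
   separations s ∈ {1, 2, 4, 8, 16}; this well-conditioned local term is
   what makes the composed-chain decoder trainable, and the medium
   separations suppress orientation drift along the chain.

**Training** has two phases, following the crop schedule of the original
recipe: phase 1 trains encoder, codebook and decoder on contiguous random
crops of length min(L, 256); phase 2 freezes encoder and codebook and
fine-tunes the decoder on crops of min(L, 640). Optimization is Adam with
cosine learning-rate decay (floor 5 %), global gradient-norm clipping
(1.0), batch-averaged loss (default batch 3-8 structures per step), and a
smaller learning rate and tighter clip for the encoder (5e-4 / 0.5 versus
2e-3 / 1.0): a fast-moving encoder makes the decoder chase moving latents
and destabilizes joint training at small scale. Everything is a
deterministic function of the config seed.

**Stage 2 — latent-space diffusion.** A DDPM over the quantized latent
arrays: forward noising `z_t = √ᾱ_t z₀ + √(1−ᾱ_t) ε` along a linear beta
schedule (T = 400, β from 1e-4 to 0.02 by default). The denoiser is a
transformer over residue tokens with a sinusoidal timestep embedding; it
predicts the clean latent array (x₀ parameterization), trained by masked
MSE against the native latents. Latents are standardized per dimension
(statistics from the training set, stored in the model) so the unit-noise
assumption holds. Ancestral sampling applies the standard posterior mean
with posterior variance noise (none at t = 1); sampled rows can be snapped
onto the codebook before decoding. When a protocol shortens the schedule
(e.g. T = 50 for speed), the beta endpoints are scaled by 400/T so the
terminal ᾱ, and hence the validity of starting from N(0, I), is preserved.

**Sequence conditioning.** The unconditional denoiser is fine-tuned with
multi-head cross-attention inserted after self-attention in every block
(queries: latent tokens; keys/values: a per-residue sequence embedding).
The bundled embedder is a learned per-residue-type table plus sinusoidal
positions behind a small interface; a pretrained protein language model can
be plugged in through the same interface. Cross-attention output
projections are initialized near zero so fine-tuning starts at the
unconditional function; condition dropout (default 0.1) retains the
unconditional mode. With dropout 1.0 the fine-tuning trajectory is
bit-identical to continued unconditional training, which is tested.

## Ensemble analysis

* **RMSF**: members are iteratively superposed onto the running mean
  structure using the TM-score-optimal transform. An equal-weight
  least-squares fit was rejected: for two-state hinge ensembles the
  large-displacement arm dominates the quadratic objective and the
  alignment splits the difference between arms, smearing fluctuation over
  the rigid core (measured: correlation with the true displacement profile
  drops from 0.998 to ~0.3).
* **Displacement profiles** superpose one structure onto the other with the
  TM-optimal transform and average over backbone atoms per residue.
* **TM-score** uses the standard d0(L) with a 0.5 Å floor for L ≤ 21 and a
  fragment-seeded iterative superposition search (fragments of length L,
  L/2, L/4; pairs with d < d0 kept, threshold relaxed when fewer than three
  survive; 20 iterations), under sequential residue correspondence.
  recRMSD superposes on CA with the TM-optimal transform and reports the
  RMSD over all present backbone atoms.
* **Secondary structure** is assigned from CA geometry only (P-SEA style):
  helix when the CA(i)-CA(i+3) distance lies in 4.5-5.9 Å and the CA
  pseudo-dihedral in 25-80° for two consecutive windows; strand when the
  CA(i)-CA(i+2) distances lie in 5.7-7.3 Å with |pseudo-dihedral| ≥ 150°;
  otherwise coil. Thresholds live in `SecondaryStructureConfig`.
* **Domains** by recursive spectral bipartition (Fiedler vector) of the
  8 Å CA contact graph, accepting splits that improve Newman modularity
  with parts of ≥ 40 residues.
* **2-D embeddings** (conformation sets and codebook rows) use seeded t-SNE
  on precomputed CA-RMSD matrices; clusters come from DBSCAN with a radius
  of half the median pairwise RMSD.

## Synthetic data

The generators stand in for curated structure databases at desk scale.
Secondary-structure strings are drawn from a run-length grammar (geometric
run lengths, means H: 8, E: 5, C: 4 — matching typical helix/strand/loop
lengths in globular proteins); backbones are built with ideal bond geometry
(N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, ω = 180°, helix φ/ψ = −57/−47,
strand −120/+120, coil torsions uniform) and perturbed with isotropic
Gaussian jitter (σ = 0.2 Å). Sequences are read off the secondary structure
through a fixed three-letter code (helix→A, strand→V, coil→G) with a
configurable mislabeling rate, giving conditional models a learnable
sequence→structure signal. The two-state generator rotates the C-terminal
segment rigidly about an axis through a hinge residue, yielding ensembles
whose residue-wise displacement profile is known exactly.

What these toys do **not** emulate: real Ramachandran statistics, side
chains, packing quality, sequence redundancy, or the diversity of natural
folds. Passing the scaled-down benchmarks therefore demonstrates that the
mechanism (invariant encoding → quantization → latent diffusion →
decoding → ensemble statistics) works end to end and recovers known ground
truth; it does not demonstrate PDB-scale reconstruction or prediction
accuracy.

## Benchmark protocols and problem sizes

`vqfold.protocols` fixes three end-to-end experiments (each a pure function
of its seed); the test suite and `scripts/acceptance.py` run exactly these:

* **Reconstruction**: K = 64, d = 16 model trained 2000 + 500 steps (batch
  8) on 50 toy backbones of 40-64 residues; recRMSD reported on the
  training set and on 10 held-out draws from the same generator.
* **Mixture recovery**: DDPM (T = 50, time-compressed betas) trained on a
  two-component latent distribution (mixing weight 0.65); 2000 samples are
  classified by nearest component mean and the recovered proportion is
  compared with the training proportion.
* **Hinge conditional sampling**: a 44-residue helix-hinge-strand construct
  with a 55° hinge rotation, 30 jittered members per state sharing one
  sequence; miniature auto-encoder (1500 steps), unconditional DDPM (400
  steps), conditional fine-tuning (2000 steps), 40 conditioned samples
  decoded; the ensemble RMSF is correlated with the exact displacement
  profile.

## Numerical choices and degenerate inputs

* All trainable components run on a small reverse-mode autodiff engine over
  numpy float64 arrays; determinism follows from seeded `numpy.random`
  Generators and pure-function training loops.
* Collinear N/CA/C triples make the residue frame undefined and raise a
  geometry error; chains shorter than 5 residues are assigned all-coil;
  TM-score requires equal lengths (sequence-independent alignment is out of
  scope).
* Quantization ties resolve to the smallest codebook index; the
  straight-through estimator returns the quantized values exactly.
* The schedule identities (ᾱ_t as running product, closed-form posterior
  variance) hold to 1e-12 and are tested; an oracle denoiser run backward
  from a noiseless forward pass recovers the input exactly.

## Known limitations

* Trained quality at the miniature scale is optimization-limited: the
  5-structure overfit reaches sub-Ångström reconstructions, but at 50
  structures the prescribed 2000 + 500 steps leave the model underfit
  (~10 Å mean training recRMSD, loss still decreasing), and held-out
  reconstruction is further limited by K = 64 quantization of random coil
  torsions, whose nearest-code substitution is amplified by the chain lever
  arm. Reconstruction accuracy is expected to improve with codebook size,
  consistent with the published behavior of the original model.
* The decoder anchors its canonical pose at the first residue; outputs are
  compared only through SE(3)-invariant metrics.
* The TM-score search is an approximation of the reference dynamic
  programming implementation, adequate for same-sequence comparisons; the
  clash counter (non-bonded backbone atoms under 2.5 Å at sequence
  separation ≥ 2) is a simple stand-in for unpublished quality metrics.
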