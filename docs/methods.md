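# Methods

## The sequence model

`SequenceRBM` implements a compositional Restricted Boltzmann Machine over
aligned peptide fragments. A sequence S = (s₁…s_N), sᵢ in the 21-symbol
alphabet (20 residues + the alignment gap, which is treated as an ordinary
symbol everywhere), has probability

    P(S) = Z⁻¹ exp[ Σᵢ gᵢ(sᵢ) + Σ_μ Γ_μ(I_μ(S)) ],   I_μ(S) = Σᵢ w_iμ(sᵢ).

The fields g capture per-column residue preferences; each hidden unit's
weight slice w_·μ is a sequence motif and I_μ its matching score. The
hidden-unit potential is the double rectified linear unit (dReLU)

    Γ(I) = log[ Φ((−I+θ⁺)/√γ⁺)/√γ⁺ + Φ((I−θ⁻)/√γ⁻)/√γ⁻ ],
    Φ(x) = exp(x²/2)·√(π/2)·erfc(x/√2),

the cumulant generating function of a piecewise-Gaussian hidden variable
with separate curvatures γ± > 0 and thresholds θ± on the two branches.
Γ is strictly convex; Γ′(I) and Γ″(I) are the mean and variance of the
conditional p(h | I), a two-branch truncated-Gaussian mixture. All branch
bookkeeping is done in log space (`scipy.special.log_ndtr`), and the
conditional is sampled by inverting the survival function
(`scipy.special.ndtri_exp`), which stays exact arbitrarily far into either
tail; outputs are finite for |I| up to at least 10³. With θ± = 0 and equal
curvatures the potential is exactly quadratic, Γ(I) = I²/2γ + ½log(2π/γ),
and the model reduces to a Potts model with low-rank couplings
J_ij(a,b) = Σ_μ w_iμ(a)w_jμ(b)/γ — the closed form used as an enumeration
oracle in the tests.

### Training

Persistent contrastive divergence maximizes the reweighted data
log-likelihood minus two penalties: an L1² motif-sparsity term
(λ₁₂/2)·Σ_μ(Σ_{i,a}|w_iμ(a)|)² and a field L2 term of strength 10⁻²·λ₁₂.
Gradients for the dReLU shape parameters use the analytic branch moments
(∂Γ/∂θ⁺ = −p⁺E[h|+], ∂Γ/∂γ⁺ = −p⁺E[h²|+]/2, mirrored for the negative
branch); γ± are projected to ≥ 0.05 after each step. The optimizer is ADAM
with β₁ = 0, β₂ = 0.99, ε = 10⁻³, learning rate 10⁻³ held constant for the
first half of training and decayed exponentially to 10⁻⁵ over the second
half; minibatches of 100 are drawn with probability proportional to the
sequence weights, and the model expectation comes from 100 persistent Gibbs
chains advanced a fixed number of full alternate-Gibbs sweeps per update
(default 20). These defaults suit production-size alignments (~2·10³
records, 2·10⁴ updates); the tests and the acceptance script pass smaller
explicit sizes (≈400–2500 updates, 5 sweeps, 30–100 chains), which the
bundled synthetic problems comfortably converge under.

Two numerical choices differ from the most conservative textbook setup and
matter in practice:

* **Weight initialization.** Zero weights are a saddle point of the
  penalized likelihood: once the fields match the data marginals, the
  weight gradient vanishes at w = 0 while the L1² penalty gradient scales
  with Σ|w|, so an initialization that is too small decays to the saddle
  before any covariance eigendirection can grow. Weights start at
  N(0, (0.3/√N)²) (exposed as `weight_init_scale`); with this scale the
  planted-coupling benchmarks recover reliably across seeds.
* **Sparsity strength at small scale.** The L1² penalty acts as an
  eigenvalue threshold on the data covariance. Production alignments carry
  enough block structure to support λ₁₂ up to ~0.25 (the estimator
  default); the desk-scale synthetic benchmarks use λ₁₂ = 0.01 so that a
  single planted coupling clears the threshold. The refinement filter model
  always uses λ₁₂ = 10⁻² with 10 hidden units.

### Partition function, likelihood, entropy

`estimate_log_partition` runs annealed importance sampling from the
fields-only base model (closed-form log Z₀ = Σᵢ log Σₐ exp gᵢ(a) + Σ_μ Γ_μ(0))
along a path that scales only the weight tensor, βw with β on a linear grid
(default 10⁴ points, 10 repeats). Chains start as exact softmax(g) samples;
the estimate is the log-mean of the importance weights and the quoted
standard error is the spread over repeats. Scaling only the weights keeps
every intermediate distribution exactly sampleable by the same Gibbs kernel
and makes the β = 0 end exact; interpolating the fields as well would give
another valid path but no simpler base.

Normalized likelihoods are unnormalized scores minus log Z; the per-site
variant divides by N. Model entropy is estimated as
H = log Z − ⟨unnormalized log P⟩ over model samples and reported as a
base-10 exponent ("the model spans 10^H sequences"); for the factorized
PSSM the column entropies are summed exactly instead, and low temperature
is applied by exponent-tilting each column. Low-temperature RBM sampling
scales g and w by β (default β = 2) and leaves the dReLU shape parameters
untouched.

### Interpretation

Mutational landscapes Δlog P(i, a) are computed from the energy difference
directly (Z cancels). Effective epistatic couplings are
J_ij(a,b) = Σ_μ w_iμ(a) w_jμ(b) ⟨Γ″_μ(I_μ)⟩_data, summarized per pair by
the Frobenius norm in the zero-sum gauge with the diagonal excluded. Motif
sparsity is the participation fraction
p_μ = (Σ_{i,a} w²)² / (N·Σᵢ(Σₐ w²)²), 1/N for a single-site motif, 1 for a
uniformly spread one. Model selection (`select_rbm`) grid-searches
(M, λ₁₂) with a cluster-aware split and picks the best held-out per-site
likelihood subject to a mean-participation cap (default 0.5) — a
reproducible proxy for an accuracy/interpretability compromise — then
retrains on the full alignment.

## Alignment handling

Sequence weights are 1/|{s′ : Hamming(s, s′) ≤ 1}|, gaps counted as a 21st
symbol, distances unnormalized; the neighbour rule is interpreted as "at
most one differing position" and the radius is exposed. Clustering is
single linkage on Hamming distances (`scipy.cluster.hierarchy`); the
train/validation split assigns whole clusters (cut at 2) 80/20 so any
cross-split pair differs in ≥ 3 columns. Cluster representatives are the
highest-scoring members, ties to the lexicographically smallest id.

The interolog filter computes pairwise identities excluding double-gap
columns (gap-vs-residue is a mismatch), correlates each candidate's
identity profile to the seeds across the three complex components, and
keeps candidates whose mean correlation R_l reaches the minimum seed score.
Seeds are scored leave-one-out so that threshold is well defined, which
requires ≥ 4 seed triplets; per organism, the enzyme-copy pair maximizing
the mean R_l is retained before thresholding. Fragment extraction takes a
1-based inclusive window (default −10…+16 columns around the motif anchor),
keeps insertions, drops fully-gapped rows and clips out-of-bounds windows,
with warnings.

Refinement Z-normalizes the filter model's unnormalized log-likelihood
(Z is constant across records and cancels) and discards records below
Z = −0.3, aborting if that would remove > 90%. The report carries six
equal-width likelihood bins with per-bin profiles, and the raw
location/scale behind the Z transform: re-running refinement with those
statistics (and the same model) anchors the cutoff to a fixed likelihood
threshold, under which the operation is idempotent. Re-normalizing per run
instead would always cut a fixed quantile (~Φ(−0.3) ≈ 38%) of a clean
unimodal distribution — the anchored semantics is the meaningful one for
repeated passes.

## Screening analytics

* **Pose cost.** Coverage + 0.05·NumAtomContacts + 0.05·Extension over
  heavy atoms, strict 4 Å center-center contacts, Extension the terminal
  Cα–Cα distance; clashes (< 2 Å) are resolved by rigid 0.5 Å translations
  along the receptor→peptide centroid direction. PDB input ignores
  hydrogens, waters and hetero records.
* **Chip normalization.** Per repeat, the log of each ROI's mean
  fluorescence is fitted on non-border spots with a full 6-term quadratic
  in (row, col) by iteratively-reweighted least squares (Huber weights, so
  genuine hits do not drag the surface); residuals are averaged over the
  two ROIs per peptide, Z-normalized over interior peptides, and averaged
  over repeats. Border peptides (outermost ring, elevated by marker
  over-splash) keep a score but are flagged and excluded from hit calling.
  A rook-neighbour lag-1 autocorrelation of residuals above 0.2 triggers an
  over-splash warning. A numerically degenerate scan (residual scale
  < 10⁻⁹) defines all Z as 0.
* **IC50.** Least squares on f([I]) = f_min + (f_max−f_min)/(1+[I]/IC50);
  the verdict is "no binding" (not an exception) when the fit fails, the
  fitted span is under 3 residual SDs, or IC50 exceeds the largest tested
  concentration. Bound fraction is (P − f_min)/(f_max − f_min) with
  endpoints from the fit.
* **Surrogate.** One-hot LASSO with the penalty chosen by K-fold
  cross-validated Pearson r; predictions are exactly coefficient·one-hot +
  intercept, and a permutation p-value is available for null checks.

## Synthetic data: what it emulates and what it does not

The generators in `pepfunnel.synthetic` reproduce the statistical structure
each stage assumes: gene-specific conserved sub-motifs with bounded column
support (a preferred residue, a few alternates, a small rare-residue floor,
2% gaps), optional planted pairwise couplings (two joint letter pairs at a
chosen column pair), motif-free outlier records; triplets evolved along a
shared chain phylogeny with decoys breaking the substrate's co-divergence;
chip scans with a quadratic log-baseline, duplicate ROIs, repeats and
planted hits; and single-site competition curves with proportional noise.
`make_demo_mfa`/`make_demo_substrates` are deterministic stand-ins for the
curated reference datasets, matched to their printed summary statistics
(1886 × 16; 67 substrates, 38 yeast + 29 human; strong conservation only at
the P/I₁/I₂ motif positions; independent-model entropy ≈ 10^17.3).

What passing on these fixtures does **not** show: real fragment alignments
carry phylogenetic correlation between records, alignment errors beyond
uniform noise, and per-gene likelihood offsets far larger than the two-gene
fixtures used for outlier recovery; real chips have non-polynomial
artefacts; real binding curves deviate from single-site behaviour at high
concentration. The benchmarks demonstrate correctness of the machinery at
its operating point, not field performance. Outcomes that depend on
external engines or wet-lab data — mutational-scan correlations, docking
energies and their r = 0.89 surrogate, chip fluorescence of the real panel,
Table-1 IC50s, the 7/10 binder rate — are reference points only and are not
recomputed here.

## Degenerate inputs and tie-breaking

Empty alignments, ragged records, illegal symbols, duplicate ids, single
clusters at the split cut, constant regression responses, all-border chips
and sub-5-point titrations raise typed errors. Score ties in cluster
representatives and enzyme-copy selection break to the lexicographically
smallest id; the kept set of the interolog filter is monotone in R_l by
construction. All stochastic components take explicit seeds; the pipeline
derives per-stage seeds from one root seed by hashing, and its manifest
records a content hash of every artifact.
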