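# Methods

## Scientific setting

The RNA polymerase II trigger loop (TL, Rpb1 residues 1076–1106 in
*S. cerevisiae*) is a mobile active-site element that closes over the
incoming NTP and, together with the adjacent bridge helix (BH), controls
catalysis and fidelity. Deep mutational scanning of the TL yields, for
every mutant, log2 allele-frequency fitness scores under 21 growth
conditions × 3 replicates. Classical analyses bin mutants into discrete
classes — gain of function (GOF), loss of function (LOF), lethal, or
wild-type-like — but the underlying biology is graded. This package
models phenotype as a real continuum anchored at the class values
GOF = +1, LOF = −1, lethal = −2, WT/indeterminate = 0, and asks three
questions: (i) can the continuum phenotype be read out of the fitness
profile, (ii) can it be predicted from the 31-residue TL sequence alone,
and (iii) do MD-derived inter-residue distances organise mutants into
mechanistically interpretable groups?

## Phenotype continuum and class bands

`encode_phenotype_class` maps the four classes to their anchors;
`classify_phenotype_value` inverts the map with band edges at −1.5
(lethal, inclusive), −0.5 and +0.5. Only the lethal cutoff is anchored
by convention in the field; the symmetric ±0.5 edges around 0 are this
package's choice (configurable via `PhenotypeBands`) and are consistent
with the ±1 class anchors.

## Networks and training

All models are small feed-forward networks trained with Adam. Because
the architectures, losses and training protocol are the substance of the
package, they are implemented directly on a compact reverse-mode
autodiff core (`polphen.nn.autodiff`, ~300 lines, numpy only) rather
than through an external deep-learning framework; gradient correctness
is fuzz-tested against central finite differences at 1e-6 tolerance.

Geometries:

* **fitness net** — 63 → 256 → 128 → 64 → 1, ReLU hidden layers;
* **sequence net** — input 31×21 one-hot (20 amino acids + a dedicated
  protonated-histidine channel; H1085 is protonated by default). Three
  dense layers act position-wise (31×128, 31×64, 31×32), sharing weights
  across positions; the 31×32 activation is flattened to 992, passed
  through a 32-node layer, then a single output;
* **MD net** — 62 → 128 → 64 → 32 → 1, or 62 → 128 → 64 → attention →
  1 when the attention variant is selected.

Self-attention treats the units of the hidden vector as tokens with
scalar values; the hidden activation itself serves as query, key and
value. Similarities are plain dot products by default (a 1/√d-scaled
variant is available), row-softmaxed into weights that sum to one, and
applied to the values. A constant hidden vector is a fixed point.

Training defaults follow the standard protocol: learning rate 1e-4
(1e-5 for sequence models), batch size 4, checkpoints every 500 epochs
up to 20,000. With the moment-KL loss active the whole training set is
one batch, since the KL term compares the Gaussian moment summaries
(mean, SD) of labels and predictions over the batch:

KL = ½[(σ_T/σ_P)² + (μ_T−μ_P)²/σ_P² − 1 + ln(σ_P²/σ_T²)],

added 1:1 to the MSE. A variance floor of 1e-12 guards the
differentiable form against zero-variance prediction batches at
initialisation; the `MomentPair` API enforces strictly positive SDs.

Model selection and ensembling: mutants are split into random train/test
sets (100/35 in the full protocol, ten splits, ten replicate models per
split). The checkpoint maximising R² − |slope − 1| on the split's test
set is kept (R² is the squared Pearson correlation of predictions vs
labels; slope/intercept come from least-squares regression of
predictions on labels); ties go to the earliest epoch. The final
predictor is the arithmetic mean over the per-split winners. Fitness and
MD features are z-scored per feature on the training rows and the same
transform is applied at prediction time; one-hot input is left raw.

Transfer combinations freeze a pre-trained branch: *feed-last* adds a
zero-initialised projection of the new branch's hidden activation into
the pre-trained last hidden layer (so an untrained branch reproduces the
pre-trained outputs exactly); *concat-last* concatenates the two last
hidden layers under a fresh output layer.

## Variational autoencoders

The fitness VAE uses 256/128/64 encoder and mirrored decoder on the 63
fitness features; the distance VAE uses 128/64/32 with a self-attention
layer after the 32-node layer on both the encoder and decoder side. The
posterior is diagonal-Gaussian (mean and log-variance heads, latent
dimension 2 by default, 3 supported); training samples via the
reparameterisation trick and minimises reconstruction error plus the
closed-form standard-normal prior KL. Reconstruction error is summed
over features before batch-averaging (per-feature MSE times the feature
count), which keeps it on a comparable scale to the KL term for 62–63
features; plain per-element MSE is available. Latent projection uses the
posterior mean (no sampling).

Four numerical choices matter for the distance VAE; all were settled on
synthetic validation data with known mechanisms, the same way learning
rates are normally screened:

* **scaled attention similarities** (1/√d) are the default inside the
  VAE. Unscaled dot products of the 32-wide ReLU activation saturate the
  softmax early in training and frequently trap the optimiser in
  poorly-reconstructing minima;
* **KL warm-up** — the prior-KL weight ramps linearly from 0 to 1 over
  the first 1,000 epochs (the converged objective is the standard one).
  Without a long near-autoencoder phase the regulariser freezes latent
  directions before the encoder has learned them and the decoder
  reproduces only part of the structured variation;
* **restarts** — as with k-means, several VAEs (default 4) are trained
  from different initialisations and the one with the lowest final
  training loss is kept. Restarts whose decoder misses a structured
  feature group converge to visibly higher loss (~2–3 units), so the
  selection favours complete models without ever consulting labels;
* **training length** — 1,200 epochs: most of the budget is the warm-up
  phase, and training stops shortly after the full objective engages.
  Training far beyond that lets the latent space absorb within-group
  noise: one group elongates along a latent axis (the objective
  genuinely prefers encoding residual noise once the signal is
  exhausted), which degrades the Euclidean k-means partition while
  leaving the decoded centroid profiles unchanged.

The latent cloud is grouped by k-means (fixed seed, 10 restarts,
inertia-best). Clusters are relabelled in descending order of mean
phenotype, so cluster I is always the most GOF-like; this makes cluster
indices a deterministic function of the fitted model and removes label
permutation flakiness. Decoding a latent point de-standardises the
decoder output back to Å; Δdistance is the decoded profile minus the WT
reference per feature.

## Structural features

Distance features are minimum inter-residue distances over heavy atoms
(hydrogen exclusion is configurable; the convention is not fixed in the
field). The 62-pair catalog spans five categories — TL–TL, TL–BH,
BH–BH, TL–GTP and GTP–other (Mg²⁺, terminal RNA, templating DNA) — with
the literature-named pairs built in and the remainder systematic
near-neighbour pairs; a study-specific catalog can be supplied as YAML or CSV.
Per-pair series are restricted to a frame window (default the last half
of each trajectory, matching the discard-equilibration convention) and
replicate-pooled averages are computed over the concatenation of all
replicates' retained frames, not as a mean of per-replicate means.

Pocket analyses use the nine-residue hydrophobic pocket (I837, L841,
A1076, M1079, G1097, L1101, V1352, V1355, I1356): contacts count
residue pairs with minimum distance ≤ 6 Å (boundary inclusive), and
solvent-accessible surface area uses Shrake–Rupley sphere sampling with
960 quasi-uniform points per atom, a 1.4 Å probe, element van der Waals
radii, and all atoms of the frame as occluders. Backbone φ/ψ dihedrals
use the standard four-point signed construction in (−180°, 180°];
superposition RMSD uses the Kabsch SVD solution with reflection guard.
Structure and trajectory I/O (PDB topology, DCD/XTC frames) goes through
mdtraj; coordinates are assumed re-imaged (no periodic minimum-image
handling).

## Synthetic study conditions

The generators in `polphen.synth` define the conditions under which the
pipeline is validated; all emit ground truth and are seed-deterministic.

* **Fitness matrices** — 135 single mutants; true phenotypes are drawn
  at class anchor + N(0, 0.2) with class proportions GOF 0.20 / LOF
  0.35 / lethal 0.25 / WT 0.20, or planted externally (e.g. from the
  additive sequence effects below). Each of the 21 conditions responds
  linearly, f = a_c·p + b_c, with fixed sign-discordant slopes so hyper-
  and hypoactive mutants are separable — emulating how conditions such
  as MPA and Mn discriminate GOF from LOF. Replicate noise σ = 0.1
  fitness units and 5% missingness are the defaults.
* **Sequence effects** — a mutant's phenotype is the sum of a position
  effect (SD 0.6) and a substituted-residue effect shared across
  positions (SD 0.5). The shared residue effect is what makes held-out
  substitutions predictable; purely idiosyncratic per-(position, residue)
  effects would be unlearnable by construction.
* **Distance tables** — a deterministic WT baseline in the 2–12 Å
  close-contact range; three planted mechanisms: lethal and half of the
  LOF mutants inflate every TL–GTP distance by 2 Å (direct active-site
  distortion), the other half of the LOF mutants inflate every TL–BH
  distance by 2 Å (bridge-helix decoupling), GOF/WT keep the tight
  baseline. Per-feature Gaussian noise σ_d = 0.3 Å.

What the synthetic conditions do **not** emulate: condition-specific
nonlinearity and epistasis in real fitness data, correlated replicate
noise, within-mechanism heterogeneity of real distance profiles, and
the far weaker coupling between real MD averages and phenotype (the
planted mechanisms are cleanly separable by design). Passing the
recovery tests therefore demonstrates that the pipeline's machinery is
correct and well-calibrated, not that real data are this predictable.
The default WT 31-mer is an arbitrary fixed sequence whose residue
identities match the mutants discussed in the literature; the true Rpb1
sequence must be supplied for real-data runs.

## Problem sizes and reduced protocols

The validation and acceptance runs scale the full protocol down: the
fitness net trains 1,000 epochs (checkpoints every 100); the sequence
ensemble uses 3 splits × 1 replicate at 2,000 epochs; the distance VAE
uses 4 restarts × 1,200 epochs. These sizes recover the planted
structure with margin (held-out R² ≈ 0.99 for the fitness net, ensemble
R² ≈ 0.9 for sequences, ARI ≈ 1.0 for mechanisms) while keeping a full
pipeline run to minutes on one CPU. The full 10-split × 10-replicate ×
20,000-epoch protocol is available through the same APIs.

## Known limitations

* The attention-token semantics for a flat hidden vector (units as
  tokens with scalar values) is one consistent reading of an
  underspecified construction; alternatives (e.g. learned projections)
  would change the operator.
* The exact functional form of "best R² and slope combination" for
  checkpoint selection is not standardised; R² − |slope − 1| is adopted
  and configurable.
* Whether the per-position landscape "Mean" row excludes lethal cells
  is unspecified; all predicted cells are included.
* Real MD observables (SASA, dihedrals) are computed from single frames
  here; trajectory-level distributions beyond pooled means are left to
  the caller.
* Double-mutant site-distance analysis requires a user-supplied WT
  structure; without one, only the sequence-side additivity analysis is
  produced.
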