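# Methods

## The problem being modelled

Iterative affinity selection (biopanning) of a displayed peptide library
interleaves four physical steps per round: capture on an immobilized
target, washing, elution, and amplification in a bacterial host. Deep
sequencing of the eluted pool after each round turns the experiment into a
count time-series per peptide. Two confounds corrupt the naive reading
"most abundant = best binder": clones that bind the immobilization resin
rather than the target, and clones with a growth advantage during
amplification. The package's analytics encode the standard experimental
countermeasure — run several strategies in parallel with different or
alternating immobilization chemistries and trust only peptides that
enrich in all of them — and the simulator generates data in which that
countermeasure provably works, so every analytic is testable against
planted ground truth.

## Selection model

Per clone *i* with latent dissociation constant K_D,i (molar, infinite for
non-binders), resin stickiness σ_i,ρ ∈ [0,1) per resin ρ, and growth
fitness g_i, one round with target amount T_r, W_r washes and an optional
negative-selection step updates relative abundances a_i by

    theta_i = T_r / (T_r + K_D,i)                       (occupancy)
    pass_i  = (1 - sigma_i)^k_neg   if negative selection, else 1
    c_i     = 1 - (1 - theta_i)(1 - sigma_i)(1 - c0)    (capture)
    q_i     = q_ns + (1 - q_ns) max(theta_i, sigma_i)   (per-wash retention)
    e_i     = a_i pass_i c_i q_i^{W_r}                  (eluted weight)
    a'_i    ∝ e_i g_i exp(eta_i),  eta ~ N(0, tau)      (amplification)

Mass is conserved clone-wise before renormalization (e_i ≤ a_i), eluted
weight is monotone non-increasing in K_D, and with τ = 0 the iteration is
exactly reproducible by closed form — all three are asserted as tests.

### Parameter choices and their rationale

- **Target amount → concentration** (`target_scale`, default 1e-5 M/μg).
  Selections specify μg of immobilized protein, not an effective
  concentration. 10 μg of a ~21 kDa target in ~1 mL is ~0.5 μM nominal;
  phage display is multivalent (several peptide copies per particle), and
  avidity raises apparent occupancy by one to two orders of magnitude.
  The default maps 10 μg to 10 μM *effective*, which makes occupancy
  saturating in early rounds for all binders in the 50 nM – 5 μM window.
  That matches the observed phenomenology of such campaigns: binders
  spanning a ~40-fold K_D range all reach top ranks, discrimination
  happening mostly in the late, low-target rounds.
- **Wash retention floor** (`q_ns = 0.9` per wash). Washes remove
  nonspecific phage incompletely (tube walls, bead crevices); eight to ten
  washes at 0.9 retain ~35–43% of background, giving per-round
  binder-over-background enrichment of ~100–300× — the regime in which
  four rounds produce final pools whose top handful of peptides carry
  60–95% of reads, as real campaigns report.
- **Negative-selection strength** (`k_neg = 0.2`). Pre-incubation with
  unloaded beads depletes resin binders sub-linearly: the depletion beads
  saturate, and the stickiest clones are exactly the ones that saturate
  them. A sub-unity exponent inside (1−σ)^k_neg keeps strongly sticky
  clones viable enough to dominate a single-resin selection (the observed
  parasite phenomenon) while alternation still removes them.
- **Stickiness** is drawn per resin independently (prevalence 2%,
  Beta(2,5)), plus a few planted strong parasites (σ 0.9–0.97 on one
  resin). Independence across resins is deliberate: it is precisely the
  assumption under which alternating chemistries decorrelate parasite
  enrichment.
- **Abundance and noise.** Naive abundances are log-normal (σ = 1.0),
  reflecting transformation and expression bottlenecks; amplification
  noise is log-normal with τ = 0.2 per round; growth fitness is log-normal
  with σ = 0.1. These keep stochastic rank shuffling visible at sequencing
  depth without drowning the selection signal.
- **Sequencing** is multinomial at the configured depth with
  substitution-only errors (default 1e-3/base, Illumina-like).
  Substitution-only keeps flank-anchored extraction exact; indel handling
  would buy realism the downstream analytics do not need at amplicon
  lengths of ~40 nt.

### What the simulator does and does not emulate

It reproduces the *selection logic*: differential enrichment by affinity,
resin-specific parasitism, growth bias, multinomial sampling noise, and
per-base sequencing error, under configurable stringency schedules. It
does not model PCR chimeras or indels, phage interference, suppression
efficiency at the ribosome, bead capacity limits beyond the sub-linear
negative-selection exponent, or paired-end read structure (single reads
suffice for ≤45 nt variable regions). Passing recovery tests therefore
demonstrates that the analytics draw correct conclusions *when the
experiment behaves according to this model*, not that any particular real
campaign did.

## Library decoding

Degenerate codons expand by IUPAC letter product (NNK → 32 codons covering
all 20 residues plus amber). Translation applies suppression overrides
before stop rejection, because amber suppression is the design principle
of the AcrK library; an unsuppressed in-frame stop rejects the read with
reason `stop`. Peptides are token *sequences*: canonical residues are
single letters, non-canonical residues are multi-character tokens
parenthesized in serialized form. Peptide positions are 1-based; DNA
intervals are 0-based half-open. The 12-mer scaffold is fixed as
C + 12×NNK + C (positions 1 and 14 cysteine), consistent with every
published hit from that library; whether anything N-terminal of the lead
cysteine is displayed is unknowable from sequence alone, so position 1 is
the cysteine by convention. Constant flanking DNA is user configuration
(primers are instrument-specific); the defaults are arbitrary 15-mers used
by the simulator.

## Enrichment analytics

- **Enrichment ratio**: (f_r + p)/(f_{r−1} + p) with p = 0.5/total_{r−1}, a
  Jeffreys-style pseudo-count that keeps de-novo appearances finite. No
  significance model is attached; the ratio is a descriptive statistic.
- **Overlap fractions** are read-weighted by default (region reads over
  pooled reads of all contributing samples); a unique-sequence weighting
  is one switch away, since published "fraction of the pool" figures are
  ambiguous between the two.
- **Consensus ranking** uses competition ranking ("1224") within each
  strategy for order-independence; the consensus rank is the maximum
  (worst) per-strategy rank. Candidates must exceed 0.1% final-round
  frequency in at least one strategy; a candidate below threshold in any
  strategy is flagged `strategy_restricted` rather than silently dropped,
  because those clones are the parasite signal, not noise. Ties break by
  mean frequency, then lexicographically.

## Descriptors and embedding

GRAVY uses the Kyte–Doolittle scale; net charge is a
Henderson–Hasselbalch sum over ionizable side chains with an EMBOSS-style
pKa set (termini optional, off by default — displayed and cyclized
peptides typically lack free termini); the aliphatic index follows Ikai's
mole-fraction formula. AcrK defaults: hydropathy −3.9 (lysine-like side
chain length), no ionizable side chain (acylation caps the ε-amine),
aliphatic weight 0 — all user-overridable in the ScaleSet. "Sequence" as
a feature is the monomer-frequency vector rather than positional one-hot,
since pools mix scaffolds and lengths.

Embedding z-scores the descriptor matrix (zero-variance columns dropped
and recorded), then UMAP (n_neighbors 15, min_dist 0.1, fixed random
state) or a deterministic PCA projection, then DBSCAN (eps 0.5,
min_samples 5) on the embedded coordinates. The UMAP hyperparameters are
package defaults, not a reproduction of any published figure's unstated
settings. Degenerate inputs (all peptides identical in feature space)
return a single cluster at the origin rather than erroring.

## Kinetics

The 1:1 model is closed-form (no ODE integration; mass-transport
limitation is out of scope, as in standard instrument software).
Global fitting shares one (k_on, k_off, R_max) across traces — per-trace
baseline offsets are the only nuisance parameters; per-trace R_max is
deliberately not fitted by default, matching the strictest reading of a
global 1:1 fit. Parameters are optimized in log space by
Levenberg–Marquardt from multi-start seeds (a k_obs linearization
estimate plus a log-spaced grid; the three cheapest-cost starts are
refined). Standard errors come from the Jacobian at the optimum via the
delta method; non-convergence is flagged on the result object.
Least squares is unweighted across phases.

Alanine-scan fold classes are exhaustive over positive folds: >9
essential, (4, 9] intermediate, [2, 4] mild, <2 neutral. The
"intermediate" band is named explicitly rather than leaving a gap between
the conventional "mild" and "essential" labels, so classification is
total and boundary behavior (9 → intermediate, 4 and 2 → mild) is
testable. Missing variant measurements are flagged `not-determined`.

## Numerical and testing choices

Problem sizes in the test and acceptance runs are scaled to the analysis:
recovery statistics use 20 campaigns of 10⁴ clones at depth 10⁵ in
counts mode (sequencing-string emission is exercised separately at
smaller depth, where the ε = 0 round-trip is checked exactly);
translation and Venn oracles use 10³ draws and 200 random triples;
kinetic recovery uses 20 seeded five-concentration sets at 1–2% noise.
All randomness flows from one seeded generator with documented stream
order, making simulator outputs byte-reproducible. The noise-free
simulator path is asserted against an independently coded closed-form
iteration at 1e-12.

Known limitations: enrichment ratios carry no significance model; flank
matching tolerates at most one substitution and no indels; the consensus
threshold (0.1%) is a convention, and campaigns with shallow sequencing
may need it lowered; UMAP determinism holds per installed library version,
so the PCA projection is the cross-version reproducible path.
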