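# Methods

This note records the statistical model, the estimators, the numerical
choices, and the limits of what the packaged synthetic experiments can show.

## Observation model

Two observation streams summarize a protein chain:

* **Backbone.** For residue *i* with four intact virtual Cα bonds around it,
  the trimer (s_{i-1}, s_i, s_{i+1}) and the virtual-dihedral pair
  (γ_{i-1}, γ_i), where γ_j is the torsion of Cα_{j-1}..Cα_{j+2} about the
  virtual bond Cα_j–Cα_{j+1} (IUPAC sign convention, stored on [0, 2π) so
  the packaged Voronoi seeds, which span 0.0–6.1 rad, apply directly). A
  chain of length L with no breaks yields L − 4 observations. A virtual
  bond whose length falls outside [2.8, 4.2] Å is treated as a chain break
  and windows crossing it are skipped; this range accepts both trans and
  cis peptides while rejecting gap artifacts. Trimers containing an unknown
  residue ('X') are dropped.
* **Contacts.** Every unordered residue pair at sequence separation ≥ 5
  whose nearest heavy-atom approach is ≤ 12 Å contributes one stored
  contact (hydrogens excluded; X-ray structures mostly lack them). Each
  stored contact belongs to the environment of *both* endpoint residues, so
  it enters the per-residue double sum twice. Alternate locations resolve
  to the highest-occupancy conformer (ties: first).

## Estimators

With counts N over a dataset of n_d backbone observations (n_c stored
contacts), the per-residue mutual information is estimated as

    I = (1/n_d) Σ_obs [ ln f(c|s) − ln f(c) ].

Frequencies are regularized in two ways:

* **Leave-one-out** (default on): each observation is removed from the
  joint count, the conditional total, the marginal count, and the grand
  total before its own contribution is computed:
  f(c|s) = (N(c,s) − 1 + λ·b(c)) / (N(s) − 1 + λ),
  f(c) = (N(c) − 1 + λ/K) / (n − 1 + λ), where b(c) = N(c)/n is the
  marginal background and K the number of structural states. Without this
  correction a fine discretization can memorize each observation and report
  spurious information.
* **Background mixture** λ (default 1.0, one pseudo-observation): the
  simplest convex mixture that keeps every log argument positive under
  leave-one-out and vanishes as counts grow. λ = 0 with leave-one-out off
  recovers the plug-in estimator.

The four estimators: I_bb conditions on the reduced trimer; I_bb,norm
averages each full-alphabet trimer's mean per-occurrence log-ratio over all
8000 trimers (unobserved trimers contribute 0; the divisor is 8000
unconditionally), so letter-frequency bias is removed; I_c conditions on
the reduced unordered pair with the bin marginal; I_total = I_bb + α·I_c
with α = 1 by default — reduced-alphabet optimization is empirically stable
across α ∈ [0.05, 20] on planted data where backbone and contact signals
share the same letter grouping, because both terms then rank rules
identically.

All four estimators are validated to 1e-9 against independent
per-observation dictionary-loop oracles (`tests/oracles.py`).

## Structural descriptors and their optimization

* **Backbone**: a Voronoi partition of the (γ_{i-1}, γ_i) plane. Candidate
  seeds live on a 0.1-rad grid, 62 × 62 = 3844 points covering [0, 6.1]².
  Assignment is nearest-seed under the Euclidean metric by default (ties:
  lowest seed index); a toroidal metric is available behind a flag since the
  space is periodic, but the non-periodic metric is the package's reference
  behavior and matches the frame of the packaged seeds. A 16-seed partition
  fit to a large non-redundant X-ray set ships as the package default.
* **Contacts**: m equal-width, left-open right-closed bins on (0, d_max];
  d_max ≤ 12 Å. The canonical setting d_max = 10 Å, m = 50 is used by the
  analysis drivers.

Both resolutions are selected by maximizing leave-one-out MI. The seed
search is a restart hill climb: proposals either replace 1–3 random seeds
with random grid points or displace 1–3 seeds to neighboring grid points
(equal probability; for k > 20 up to ⌈k/8⌉ seeds move); only strict
improvements are accepted; a restart stops after `patience` consecutive
rejections (default 10,000) and the best of `restarts` (default 20)
restarts is kept, its objective recomputed through the estimator module
with central-residue conditioning (the seed search conditions on the
central letter only, which keeps the conditional tables populated during
optimization). The (d_max, m) grid is searched exhaustively; contacts
beyond a candidate d_max are excluded from numerator and denominator counts
alike. On planted data the leave-one-out objective rises to a peak at the
planted resolution and falls beyond it — over-fine descriptors are
penalized exactly as intended — while the plug-in objective is
non-decreasing under genuine refinement (both behaviors are asserted in the
test suite).

## Rule search and alphabet survey

A substitution rule for an n-letter alphabet assigns each of the 20 − n
excluded letters to a member (n^(20−n) rules). The hill climb reassigns a
uniform-random 1–3 excluded letters to uniform-random members per proposal,
accepts strict improvements, stops a restart after `patience` consecutive
rejections, and keeps the best of `restarts` restarts; ties break toward
the lexicographically smaller rule string so results are reproducible.
Exhaustive enumeration (refused above a configurable budget, default 10^6
rules) provides the ground-truth optimum for small spaces; on the packaged
planted conditions the hill climb with default settings attains it for
100/100 random 17-letter alphabets.

Rule evaluation is the hot path: the evaluator precomputes per-bucket count
arrays over the distinct (full trimer, cell) and (pair, bin) combinations;
one rule evaluation is then two bincounts and two log passes over those
buckets, with the rule-independent marginal terms folded into constants and
results memoized per rule image (memoization only avoids recomputing a
revisited rule and cannot alter a search trajectory). Surveys derive each
alphabet's RNG seed from the master seed and the alphabet's canonical
string, so results are independent of evaluation order and worker count.

Ranking convention: rank = 1 + (number of alphabets with strictly greater
objective); percentile = (1 − n_better/N) × 100, reported to two decimals
(three where a third is meaningful).

## Threading

The regularized, no-leave-one-out propensities (self-exclusion is
inapplicable when scoring foreign sequences) are Boltzmann-inverted into
ΔU = −kT ln p(C|S)/p(C) tables over (trimer, cell) and (pair, bin), kT = 1
so energies are in kT units. Structural states never observed in the
fitting data carry no propensity signal and score 0. Gapless threading
keeps the structure-derived cells and bins fixed and varies only the
mounted sequence; the discrimination measure is the gap
ΔU_native − ⟨ΔU_shuffled⟩ over composition-preserving whole-chain
permutations (default 500; the decoy-mean standard error shrinks as
1/√n_shuffles). Per-alphabet threading surveys refit the potential on the
rule-rewritten dataset rather than remapping full-alphabet tables,
mirroring the MI pipeline, and report per-residue means per record (the
alternative, per-protein averaging, weights long chains less; per-residue
is the package's reporting convention). With plug-in (λ = 0, leave-one-out
off) tables fit on a single record, the native energy equals
−kT·n_d·(I_bb + I_c) exactly — a cross-module identity asserted in the
tests.

## Synthetic generator

The generator plants a configurable sequence → structure coupling: letters
are partitioned into g groups; the backbone dihedral pair of a residue is a
categorical draw over K basin centers (per central-residue group) plus
isotropic wrapped Gaussian noise σ; contact distances are truncated normals
on (2, 12] Å with group-pair-dependent means; contacts appear at a fixed
rate per residue. Defaults: four physicochemical groups (hydrophobic
ACFILMVWY, polar HNQST, charged DEKR, special GP), helix-like (0.87, 0.87),
strand-like (3.3, 3.3), polyproline-like (5.0, 5.0) and diffuse (1.9, 4.7)
basins with σ = 0.25 rad, contact means spread over 4.5–9.5 Å with
τ = 1.0 Å, one stored contact per residue, chain lengths 50–300. These
defaults give roughly equal backbone and contact observation counts at
a given residue budget.

Coordinate output builds Cα traces by natural extension (bond 3.8 Å,
state-dependent bond angle, torsion = the sampled basin value plus noise),
with one pseudo side-chain atom 1.5 Å off each Cα so nearest-atom-approach
distances are nondegenerate; PDB files round-trip through the reader with
~1e-3 rad angular quantization from the 3-decimal coordinate format. A
"redundant pairs" variant couples each of 10 member letters to one excluded
partner sharing its basin and contact profile, making the member set (and
every other one-letter-per-pair transversal) exactly information-optimal —
the construction behind the planted-recovery tests.

What the generator does *not* emulate: excluded volume, side-chain packing,
real fold topology, secondary-structure segment statistics, or database
redundancy. Note also an asymmetry between the two output modes: the
observation sampler draws contact distances directly from the planted
group-pair distributions, whereas the coordinate builder derives contacts
from the constructed 3D geometry, so coordinate corpora carry only the
backbone-mediated part of the contact signal (their leave-one-out contact
MI sits near zero, and the descriptor drivers report exactly that). Passing
tests therefore demonstrate the correctness and calibration of the
estimators and searches, not claims about real proteins.

## Problem sizes and determinism

The packaged experiments run at desk scale: ~20,000 observations for the
rule-search agreement study (100 alphabets of size 17, whose 4,913-rule
spaces are exhaustively enumerable), ~6,000 for planted-alphabet recovery
(1,000 sampled alphabets + the planted one), ~3,000 for the
resolution-scan behavior, and 20–60 chains for threading. Every random
draw flows from an explicit seed (`numpy.random.default_rng`); fixed seeds
give bit-identical outputs, including written PDB files and pipeline TSVs.

## Known limitations

* The Euclidean (non-periodic) seed metric slightly distorts neighborhoods
  across the 0/2π wrap; the toroidal flag exists but is not the default.
* The contact term treats contacts as independent given the pair identity;
  cooperative effects are out of scope, which is also why no
  composition-normalized variant of I_c is offered.
* MI confidence intervals are not provided; the leave-one-out estimator's
  small-sample bias is negative (independence tests bound |MI| by
  3/√n rather than asserting zero).
* Threading uses gapless mounting without relaxation; destabilizing
  substitutions are penalized only through the propensity tables.
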