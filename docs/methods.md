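# Methods

This note documents the models and procedures implemented in
`analogscope`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open.

## Neighborhood scores

An analog series (AS) is a core scaffold with labeled substitution
sites plus existing analogs (EAs) carrying one substituent (or H) per
site and a pIC50 potency. Virtual analogs (VAs) — enumerated,
Free-Wilson or sampled — serve as a probe population for the space the
series *could* occupy.

EAs and a VA sample are embedded in a descriptor space and z-scored;
each EA's neighborhood (NBH) is the closed ball of radius *r* in the
standardized space. Closed-ball membership (distance ≤ r) makes
boundary behavior deterministic. Four scores follow:

- **C (coverage)** — fraction of VAs inside at least one NBH.
- **D (density)** — 1 − 1/d̄ with d̄ the mean NBH multiplicity over
  *covered* VAs. Read this way d̄ ≥ 1 always, so D ∈ [0, 1). The
  alternative literal reading (overlapping-NBH count over total covered
  VAs) can fall below 1 and would make D negative; it is not used.
- **S (saturation)** — harmonic mean 2CD/(C+D); 0 when C + D = 0.
- **P (progression)** — for each VA contained in the NBHs of mᵢ ≥ 2
  EAs, the mean absolute pairwise potency difference of those EAs,
  averaged with weights 1/mᵢ. VAs with mᵢ ≤ 1 carry no overlap
  information (weight 0). P is invariant under shifting all potencies
  and scales linearly with them; its units are pIC50 log units.

Degenerate cases: D = 0 when no VA is covered; P = 0 when no VA has
mᵢ ≥ 2. Both are the semantic floor ("no overlap information"), not
errors.

### Parameters

| parameter | default | meaning |
|---|---|---|
| descriptor set | MW, logP, HBD, HBA, TPSA, rotatable bonds, aromatic rings | the chemical reference space; fully configurable via a registry |
| radius *r* | no universal default; calibrate | NBH radius in z-scored distance units |
| n_resamples × sample_size | 10 × 1000 | independent VA subsamples per score report |
| target_quantile | 0.05 | for radius calibration: quantile of all EA–VA distances |

The seven default descriptors are a standard lead-optimization set;
nothing in the scoring depends on this particular choice and the report
always echoes the descriptor list, the radius, the sample sizes and the
seed so runs are comparable. Standardization is fitted on the union of
EAs and the VA sample of the same scoring run (EAs and VAs are judged
in one shared space; fitting on either side alone would let one
population dictate the metric). Constant descriptor dimensions get
scale 1 — they carry no distance information and forcing unit scale
keeps the transform invertible. Score sd is the sample sd (ddof 1)
over resamples. VAs whose canonical SMILES equals an EA are removed
from the pool before sampling: design routes that reproduce training
analogs would otherwise inflate coverage trivially.

Radius calibration returns a quantile of all EA–VA standardized
distances, which is monotone in the quantile and gives C → 1 as q → 1.
In practice a small quantile (0.05) yields radii that neither cover
everything nor nothing; the radius is always reported rather than
hidden.

## Series representation and fragmentation

Cores are SMILES with mapped attachment dummies (`[*:1]`…); substituents
are single-attachment fragments (`*C`, `*OC`…) with `[H]` as the
explicit placeholder for an unsubstituted site. Assembly uses RDKit's
`molzip`; every stored decomposition must reassemble to the analog's
canonical SMILES (validated, not assumed).

Fragmentation cuts acyclic single bonds matched by a configurable rule
set (shipped default: amide, ester, amine, ether, sulfonamide,
aryl–alkyl disconnections as SMARTS on the two bonded atoms). A
decomposition is kept when exactly one fragment — the core — touches
every cut and holds at least half the molecule's heavy atoms, and each
substituent has one attachment and at most 13 heavy atoms. Series
extraction counts core support over all compounds' decompositions,
picks the best-supported core (ties: larger core, then lexicographic
SMILES), then assigns *all* remaining compounds by R-group
decomposition restricted to the labeled sites — this second step is
what captures analogs carrying H at a site, which have no bond to cut
there. Compounds join at most one series; the loop repeats on the
remainder and drops series below `min_size`.

## Enumeration

Close-in and diverse enumeration differ only in the substituent pool
(series-derived vs external). Each draw independently sets every site
to H — with probability equal to the fraction of EAs carrying H at that
site, the one series statistic directly interpretable as a substitution
probability — or to a uniform pool fragment (draws are independent
across sites, with replacement). Products outside the EA heavy-atom
range, duplicating an earlier product, or equal to an EA are rejected;
rejection sampling is bounded at 100 draws per requested VA so tiny
combinatorial spaces terminate with a logged shortfall instead of
hanging.

## Free-Wilson quartets

Within a series, matched molecular pairs (MMPs) are computed
positionally — two analogs differing at exactly one site — which inside
a decomposed series is equivalent to and less ambiguous than generic
single-cut MMP detection. The MMP network (NetworkX graph, edges
labeled by site) supports quartet enumeration: for each reference
analog and unordered site pair (s₁ < s₂), every combination of an MMP
partner at s₁ with one at s₂ closes a double-exchange cycle exactly
once. The target combines both exchanges; if it exists among EAs the
quartet is closed by an existing analog, otherwise the target is a
Free-Wilson VA. Under substituent additivity
pot(target) = pot(x) + pot(y) − pot(ref); multiple quartets sharing a
target are aggregated by unweighted mean and sample sd (no weighting
scheme is better motivated at this granularity, and the sd itself is
the useful non-additivity signal). "Membership in a Free-Wilson
neighborhood" counts an analog appearing in any quartet role; the
count of analogs appearing specifically as predicted targets is exposed
separately.

## Global potency models

Fingerprints are folded 2048-bit Morgan fingerprints of radius 2 (bond
diameter 4). The Tanimoto kernel |a∧b|/|a∨b| is positive semi-definite
on binary vectors; all-zero pairs get similarity 0 with a warning. SVR
uses the precomputed kernel; ridge regression uses the raw bit vectors.
Training is three-fold double cross-validation: the inner folds select
hyper-parameters (SVR grid C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.1, 0.5};
ridge α ∈ {0.01, 0.1, 1, 10, 100} — conventional ranges, configurable),
the outer folds estimate generalization, and the final model is refit
on everything with the most frequently winning parameters. R² is the
coefficient of determination (not squared Pearson correlation); MAE is
in pIC50 units. The series-splitting helper reproduces the intended
training protocol — background actives plus half the series, the other
half held out — stratifying the 50/50 split by potency quartile so
neither half gets a degenerate potency range.

## Generative model

The SMILES language model is a token-level stacked LSTM (embedding →
LSTM layers → softmax), implemented in NumPy with full backpropagation
through time and Adam (gradient-norm clipping at 5). The tokenizer
keeps multi-character atom symbols, bracket atoms and two-digit ring
closures as single tokens; ring-closure digits 1–6 are always in the
vocabulary because SMILES randomization can introduce digits beyond
those seen in canonical training strings. The learning rate decays
exponentially (factor 0.9) when held-out cross-entropy fails to improve
for 3 epochs.

Desk-scale defaults: embedding 64, 2 LSTM layers of width 128, max
sequence 128 tokens, batch 32, pretraining learning rate 3e-3. These
train on a few hundred corpus strings in well under a minute per run;
wider/deeper settings are plain configuration. Pretraining holds out
10% of the corpus to monitor convergence and warns if the loss does not
decrease.

Transfer learning clones the prior, resets the optimizer state, and
fine-tunes on the series' analogs; each epoch trains on 10 passes over
the analog strings (a ~30-compound series provides too few gradient
steps per epoch otherwise) and then draws a fixed sample scored into
per-epoch metrics: sampled, valid (RDKit-parseable), unique (canonical
SMILES), core-containing, and reproduced analogs (distinct EAs among
the epoch's sample). "Contains the core" is a substructure match of
the core skeleton with the attachment dummies removed, so analogs
carrying H at a site still count — the stricter wildcard-per-site
reading would exclude part of the series itself. A lower fine-tuning
rate (1e-3) is recommended.

SMILES-randomization augmentation is implemented but off by default:
at desk scale, with a weak prior and ~30 fine-tuning molecules,
augmentation turns fine-tuning into an effectively unbounded string-
modeling task, validity collapses and no focusing occurs, whereas
canonical-string fine-tuning reproduces the expected focusing behavior
(rising core-containing fraction, analogs reproduced, falling
uniqueness). With a large pretrained prior the balance reverses, and
the flag is there to enable it.

Per-compound sampling frequency counts the number of *distinct epochs*
in which a compound appeared; several draws within one epoch count
once.

## Synthetic data

The generator emulates the data regime the diagnostics assume: a core
with 2–4 aromatic-carbon attachment sites from a shipped core library,
per-site substituent alphabets drawn from a fragment library, and
potencies

  pIC50 = base + Σ effect(site, substituent) + Σ interaction(site pair,
  substituent pair) + N(0, noise_sd)

with per-substituent effects ~ N(0, effect_sd), hydrogen as the
zero-effect reference, and optional pairwise interaction terms
~ N(0, interaction_sd) as the controllable non-additivity. Defaults
(base 6.0, effect sd 0.5 log units, 30 EAs on a 3-site core with 6
substituents per site plus H, no noise) give a realistic mid-size
series with potencies spanning roughly 4–8 pIC50. All randomness flows
from one spec seed through a documented `SeedSequence` split; the same
spec is byte-identical.

Every substituent in the fragment library attaches through an sp3
carbon, so the default aryl–alkyl fragmentation rule cleaves every
substitution site and series extraction can be validated against the
generator's membership ground truth. This is a deliberate
simplification: real series mix attachment chemistries (aryl ethers,
anilines, halides on the ring), which fragment inconsistently across
rules — the extraction code handles such inputs but cannot then be
oracle-checked. Other realism gaps: no assay noise structure beyond
i.i.d. Gaussian, no activity cliffs from 3D effects, no inactive
compounds, and corpus molecules for pretraining are deliberately
simple. Passing tests therefore demonstrate correctness of the
machinery and its response to constructed SAR, not performance on any
particular experimental series.

VA pool strategies with known coverage geometry: `recombination`
(close-in products populating EA-proximal space), `copy` (EA
duplicates — full coverage at any positive radius), `remote` (long
alkyl chains far outside the EA descriptor range — zero coverage).

## Stage classification

The stage label is a pure 2×2 function of (S, P) with configurable
thresholds (defaults S ≥ 0.5 saturated, P ≥ 0.8 progression-active):
saturated + flat → late; saturated + active → mid; unsaturated +
active → early_mid; unsaturated + flat → early; S = 0 is always
"early". The label is monotone in S at fixed P. The published
analyses classify series only *relative* to each other, so the numeric
thresholds are a pragmatic formalization — they are printed with every
assessment and are configuration, not doctrine. Strategy
recommendation maps late stages to conservative routes (Free-Wilson,
close-in) and early stages to explorative ones (diverse, sampled);
the mapping is a configurable table.

## Numerical conventions

- Canonical SMILES (RDKit) is the identity key for all uniqueness and
  overlap computations.
- Distances are Euclidean in z-scored descriptor space (population sd;
  constant dimensions → scale 1).
- Sample sd (ddof 1) everywhere a spread over resamples or quartets is
  reported; a single observation reports sd 0.
- Ranking of predicted populations is stable descending with canonical
  SMILES as tie-break.
- PCA uses the full SVD solver; rank-deficient input returns fewer
  components with a warning.

## Problem sizes

The test suite and examples run at desk scale: series of 25–120
analogs, VA pools of 150–3200, corpora of 600 strings, 20 pretraining
and 15 fine-tuning epochs with 256 samples per epoch, and oracle checks
up to 1000 × 10000 points. These sizes were chosen so the full suite
completes in a few minutes while every statistical check retains a
comfortable margin.

## Known limitations

- Series extraction greedily assigns each compound to the
  best-supported core; a compound fitting several series goes to the
  first (logged), and exact tie-handling between equally supported
  cores is lexicographic rather than chemistry-aware.
- The quartet-local Free-Wilson treatment deliberately does not fit the
  classical global Free-Wilson regression matrix.
- The generative module is a desk-scale instrument for studying the
  transfer-learning dynamics, not a production molecule generator; its
  prior is only as broad as the corpus it is given.
- Potency aggregation across repeated measurements is out of scope:
  inputs must provide one pIC50 per compound.
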