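# analogscope

Saturation diagnostics and virtual-analog design for lead-optimization
analog series.

Medicinal-chemistry optimization revolves around analog series (AS): sets
of compounds sharing a core scaffold and differing at a few substitution
sites. Two questions dominate: *is the series chemically saturated* — has
its local chemical space been explored enough that further analogs are
unlikely to help — and *is the structure–activity relationship (SAR) still
progressing*? `analogscope` answers both by surrounding a series with
virtual analogs (VAs) and measuring how the existing analogs (EAs) cover
the resulting series-centric chemical space, then uses the same VA
machinery to propose and prioritize candidate analogs.

## The diagnostics

EAs and a random sample of VAs are projected into a z-scored
physicochemical descriptor space (default: MW, logP, HBD, HBA, TPSA,
rotatable bonds, aromatic rings). Each EA defines a neighborhood (NBH),
the closed ball of radius *r*. With VA<sub>NBH</sub> the number of VAs in
any NBH and VA<sub>all</sub> the sample size:

- **Coverage**  C = VA<sub>NBH</sub> / VA<sub>all</sub>
- **Density**  D = 1 − 1/d̄, with d̄ the mean number of NBHs containing a
  covered VA (NBH overlap)
- **Saturation**  S = 2CD / (C + D), the harmonic mean
- **Progression**  P = Σᵢ wᵢ Δ̄ᵢ / Σᵢ wᵢ, where for each VA *i* inside the
  NBHs of mᵢ ≥ 2 EAs, Δ̄ᵢ is the mean pairwise |pIC50| difference of those
  EAs and wᵢ = 1/mᵢ (wᵢ = 0 for mᵢ = 1)

High S with low P marks a saturated, SAR-flat late-stage series; low S
with high P marks an early series that still responds strongly to small
modifications. Scores are reported as mean ± sd over seeded VA resamples
(default 10 × 1000).

## Design strategies and prediction

- **Close-in / diverse enumeration** — decorate the core's sites with
  series-observed or external substituents (site-wise H probability taken
  from the series, VA size restricted to the EA heavy-atom range).
- **Free-Wilson (FW) analogs** — matched molecular pairs are organized in
  a network; each quartet (ref, x, y, target) closing a double substituent
  exchange yields the local additivity prediction
  pot(target) = pot(x) + pot(y) − pot(ref). Targets absent from the
  series are FW virtual analogs.
- **Generative sampling** — a token-level LSTM SMILES language model
  (NumPy implementation) pretrained on a corpus and fine-tuned on the
  series, with per-epoch valid/unique/core-containing/reproduced-analog
  sampling statistics.
- **Global models** — SVR with a Tanimoto kernel on folded 2048-bit ECFP4
  fingerprints (or ridge regression), trained by three-fold double
  cross-validation.

A synthetic-data generator (`analogscope.synthetic`) builds valence-correct
series with a known potency decomposition (base + per-substituent effects
+ optional pairwise interactions + Gaussian noise), so every pipeline
stage can be validated against ground truth.

## Worked example

`examples/01_diagnostic_scoring.py` scores a synthetic 40-analog,
3-site series against 400 close-in virtual analogs:

```
series core: O=C(Nc1ccc([*:3])cc1)c1ccc([*:1])cc1[*:2]
40 existing analogs, 3 substitution sites
virtual-analog pool: 400 unique close-in analogs
calibrated neighborhood radius: 1.102 (5% distance quantile)
C=0.67 (±0.02)  D=0.67 (±0.01)  S=0.67 (±0.01)  P=0.71 (±0.01)
stage: late — S=0.67 (>= 0.5), P=0.71 (< 0.8): saturated chemical space with flat SAR progression
recommended design strategies (best first): ('fw', 'close_in', 'sampled', 'diverse')
```

Two thirds of the sampled virtual analogs fall inside existing-analog
neighborhoods (C), those neighborhoods overlap strongly (D), so saturation
is high; the modest potency spread inside overlapping neighborhoods (P,
in pIC50 log units) indicates flat SAR — together a late-stage call, for
which conservative Free-Wilson analogs are ranked first. The other
examples cover enumeration overlap (`02`), exact Free-Wilson recovery on
an additive series (`03`), global-model training and ranking (`04`) and
generative transfer learning (`05`).

A thin CLI mirrors the library: `analogscope simulate | score | design |
fw | predict | sample | overlap` (every stochastic subcommand requires
`--seed`).

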