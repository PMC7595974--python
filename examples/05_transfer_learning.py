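"""Generative analog sampling: pretrain a SMILES model, fine-tune on a
series, watch the sampling focus onto series-centric chemical space.

Runs in about a minute at the desk-scale configuration.
"""

from analogscope.generative import (
    GenerativeConfig,
    collect_sampled_vas,
    pretrain,
    transfer_learn,
)
from analogscope.synthetic import (
    SeriesGeneratorSpec,
    generate_corpus,
    generate_series,
)

corpus = generate_corpus(600, complexity="varied", seed=3)
prior, history = pretrain(corpus, GenerativeConfig(epochs=20, seed=0))
print(
    f"prior trained on {len(corpus)} strings: held-out cross-entropy "
    f"{history[0]['val_loss']:.2f} -> {history[-1]['val_loss']:.2f} nats/token"
)

synth = generate_series(
    SeriesGeneratorSpec(
        n_sites=3, substituents_per_site=6, n_eas=30, noise_sd=0.2, seed=7
    )
)
cfg = GenerativeConfig(epochs=15, sample_per_epoch=256, learning_rate=1e-3, seed=5)
model, metrics, samples = transfer_learn(prior, synth.series, cfg)

print("epoch  valid  unique  with_core  reproduced_analogs")
for m in metrics:
    print(
        f"{m.epoch:>5}  {m.n_valid:>5}  {m.n_unique:>6}  "
        f"{m.n_with_core:>9}  {m.n_reproduced_eas:>18}"
    )

counts, reproduced = collect_sampled_vas(samples, synth.series)
multi = sum(1 for c in counts.values() if c > 1)
print(
    f"\n{len(counts)} unique sampled compounds over {len(samples)} epochs; "
    f"{len(reproduced)} reproduce existing analogs; "
    f"{multi} were sampled in more than one epoch"
)
print(
    "The rising with_core column is the focusing signal: the fine-tuned "
    "model increasingly samples compounds built on the series scaffold, "
    "while reproduced analogs confirm it has locked onto the series."
)
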