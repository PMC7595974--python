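"""A compact SMILES language model with transfer learning onto a series.

The model is a character/token-level stacked LSTM implemented directly
in NumPy (embedding -> LSTM layers -> softmax over the token
vocabulary), trained by truncated-none BPTT with Adam and an
exponentially decaying learning rate gated by patience on held-out
loss.  It is pre-trained on a broad corpus of SMILES ("prior") and then
fine-tuned on the existing analogs of one series; after every
fine-tuning epoch a fixed number of strings is sampled and scored into
:class:`EpochMetrics` (valid / unique / core-containing / reproduced
analogs), which trace how sampling focuses onto series-centric space.

The default configuration is desk scale: it trains in minutes on a few
hundred corpus strings.  Larger architectures (more layers, wider
hidden state, longer sequences) are plain configuration.
"""

from __future__ import annotations

import copy
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from .series import AnalogSeries

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")

PAD, START, END = "<pad>", "<s>", "</s>"


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; multi-character atom symbols
    (two-letter elements, bracket atoms, two-digit ring closures) are
    single tokens.  Concatenating the tokens restores the string."""
    tokens = _TOKEN_RE.findall(smiles)
    assert "".join(tokens) == smiles
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def encode(self, smiles: str) -> list[int]:
        idx = self.index
        try:
            body = [idx[t] for t in tokenize(smiles)]
        except KeyError as exc:
            raise ValueError(f"out-of-vocabulary token {exc.args[0]!r} in {smiles!r}")
        return [idx[START]] + body + [idx[END]]

    def decode(self, ids: Sequence[int]) -> str:
        specials = {self.index[PAD], self.index[START], self.index[END]}
        return "".join(self.tokens[i] for i in ids if i not in specials)


def build_vocabulary(corpus: Sequence[str]) -> Vocabulary:
    """Token set of a corpus plus pad/start/end; invalid SMILES are
    rejected with a logged diagnostic."""
    seen: set[str] = set()
    n_ok = 0
    for smi in corpus:
        if Chem.MolFromSmiles(smi) is None:
            logger.warning("rejecting invalid SMILES from corpus: %r", smi)
            continue
        seen.update(tokenize(smi))
        n_ok += 1
    if n_ok == 0:
        raise ValueError("no valid SMILES in corpus")
    # ring-closure digits are the one token class SMILES randomization
    # can introduce beyond the canonical forms; always reserve them
    seen.update("123456")
    return Vocabulary((PAD, START, END) + tuple(sorted(seen)))


@dataclass
class GenerativeConfig:
    """Desk-scale defaults; every size is plain configuration."""

    embedding_size: int = 64
    hidden_size: int = 128
    n_layers: int = 2
    max_sequence_length: int = 128
    epochs: int = 15
    sample_per_epoch: int = 256
    passes_per_epoch: int = 10
    learning_rate: float = 3e-3
    lr_decay: float = 0.9
    patience: int = 3
    batch_size: int = 32
    augmentation: bool = False
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embedding_size", "hidden_size", "n_layers",
                     "max_sequence_length", "epochs", "sample_per_epoch",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class SmilesLSTM:
    """Stacked-LSTM next-token model over a SMILES vocabulary."""

    def __init__(self, vocab: Vocabulary, config: GenerativeConfig, rng: np.random.Generator):
        self.vocab = vocab
        self.config = config
        v, e, h = vocab.size, config.embedding_size, config.hidden_size
        def init(shape, scale):
            return rng.normal(0.0, scale, size=shape)
        self.params: dict[str, np.ndarray] = {"E": init((v, e), 0.1)}
        for l in range(config.n_layers):
            d_in = e if l == 0 else h
            self.params[f"W{l}"] = init((d_in + h, 4 * h), 1.0 / np.sqrt(d_in + h))
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
        self.params["Wo"] = init((h, v), 1.0 / np.sqrt(h))
        self.params["bo"] = np.zeros(v)
        self._adam_m = {k: np.zeros_like(p) for k, p in self.params.items()}
        self._adam_v = {k: np.zeros_like(p) for k, p in self.params.items()}
        self._adam_t = 0

    def clone(self) -> "SmilesLSTM":
        return copy.deepcopy(self)

    # ---------------- forward / backward ----------------

    def _forward(self, batch: np.ndarray):
        """batch: (B, T) int ids padded with PAD. Returns logits and cache."""
        cfg = self.config
        p = self.params
        b_sz, t_len = batch.shape
        h_dim = cfg.hidden_size
        x = p["E"][batch]  # (B, T, E)
        hs, cs, gates, inputs = [], [], [], []
        layer_in = x
        for l in range(cfg.n_layers):
            h = np.zeros((b_sz, h_dim))
            c = np.zeros((b_sz, h_dim))
            h_seq = np.empty((b_sz, t_len, h_dim))
            c_seq = np.empty((b_sz, t_len, h_dim))
            g_seq = np.empty((b_sz, t_len, 4 * h_dim))
            for t in range(t_len):
                z = np.hstack([layer_in[:, t], h]) @ p[f"W{l}"] + p[f"b{l}"]
                i = _sigmoid(z[:, :h_dim])
                f = _sigmoid(z[:, h_dim : 2 * h_dim])
                g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
                o = _sigmoid(z[:, 3 * h_dim :])
                c = f * c + i * g
                h = o * np.tanh(c)
                h_seq[:, t] = h
                c_seq[:, t] = c
                g_seq[:, t] = np.hstack([i, f, g, o])
            inputs.append(layer_in)
            hs.append(h_seq)
            cs.append(c_seq)
            gates.append(g_seq)
            layer_in = h_seq
        logits = layer_in @ p["Wo"] + p["bo"]
        return logits, (inputs, hs, cs, gates)

    def loss_and_grads(self, batch: np.ndarray):
        """Masked next-token cross-entropy and parameter gradients."""
        cfg = self.config
        p = self.params
        pad = self.vocab.index[PAD]
        inp = batch[:, :-1]
        tgt = batch[:, 1:]
        mask = (tgt != pad).astype(float)
        logits, cache = self._forward(inp)
        shifted = logits - logits.max(axis=-1, keepdims=True)
        exps = np.exp(shifted)
        probs = exps / exps.sum(axis=-1, keepdims=True)
        b_sz, t_len = tgt.shape
        n_tok = mask.sum()
        ll = -np.log(probs[np.arange(b_sz)[:, None], np.arange(t_len)[None, :], tgt] + 1e-12)
        loss = float((ll * mask).sum() / n_tok)

        dlogits = probs.copy()
        dlogits[np.arange(b_sz)[:, None], np.arange(t_len)[None, :], tgt] -= 1.0
        dlogits *= (mask / n_tok)[:, :, None]

        inputs, hs, cs, gates = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        top_h = hs[-1]
        grads["Wo"] = np.einsum("bth,btv->hv", top_h, dlogits)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dlayer = dlogits @ p["Wo"].T  # gradient wrt top layer h sequence
        h_dim = cfg.hidden_size
        for l in range(cfg.n_layers - 1, -1, -1):
            w = p[f"W{l}"]
            d_in = w.shape[0] - h_dim
            dx_seq = np.zeros((b_sz, t_len, d_in))
            dh_next = np.zeros((b_sz, h_dim))
            dc_next = np.zeros((b_sz, h_dim))
            dw = np.zeros_like(w)
            db = np.zeros_like(p[f"b{l}"])
            for t in range(t_len - 1, -1, -1):
                dh = dlayer[:, t] + dh_next
                g = gates[l][:, t]
                i, f, gg, o = (
                    g[:, :h_dim],
                    g[:, h_dim : 2 * h_dim],
                    g[:, 2 * h_dim : 3 * h_dim],
                    g[:, 3 * h_dim :],
                )
                c = cs[l][:, t]
                c_prev = cs[l][:, t - 1] if t > 0 else np.zeros_like(c)
                h_prev = hs[l][:, t - 1] if t > 0 else np.zeros((b_sz, h_dim))
                tanh_c = np.tanh(c)
                do = dh * tanh_c
                dc = dc_next + dh * o * (1 - tanh_c**2)
                di = dc * gg
                df = dc * c_prev
                dg = dc * i
                dz = np.hstack(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - gg**2),
                        do * o * (1 - o),
                    ]
                )
                xh = np.hstack([inputs[l][:, t], h_prev])
                dw += xh.T @ dz
                db += dz.sum(axis=0)
                dxh = dz @ w.T
                dx_seq[:, t] = dxh[:, :d_in]
                dh_next = dxh[:, d_in:]
                dc_next = dc * f
            grads[f"W{l}"] = dw
            grads[f"b{l}"] = db
            dlayer = dx_seq
        # dlayer now holds gradient wrt embeddings
        np.add.at(grads["E"], inp, dlayer)
        return loss, grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                   clip: float = 5.0) -> None:
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, clip / (norm + 1e-12))
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g * scale
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1**t)
            v_hat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # ---------------- training ----------------

    def _encode_batch(self, smiles: Sequence[str]) -> np.ndarray:
        pad = self.vocab.index[PAD]
        enc = [self.vocab.encode(s)[: self.config.max_sequence_length] for s in smiles]
        t_len = max(len(e) for e in enc)
        out = np.full((len(enc), t_len), pad, dtype=np.int64)
        for i, e in enumerate(enc):
            out[i, : len(e)] = e
        return out

    def evaluate_loss(self, smiles: Sequence[str]) -> float:
        total, n = 0.0, 0
        for start in range(0, len(smiles), self.config.batch_size):
            batch = self._encode_batch(smiles[start : start + self.config.batch_size])
            loss, _ = self.loss_and_grads(batch)
            total += loss * len(batch)
            n += len(batch)
        return total / n

    def fit(
        self,
        train: Sequence[str],
        held_out: Sequence[str],
        epochs: int,
        rng: np.random.Generator,
        augment_fn=None,
    ) -> list[dict]:
        """Adam training with exponential lr decay under patience on
        held-out loss.  Returns per-epoch loss history."""
        cfg = self.config
        lr = cfg.learning_rate
        best = np.inf
        stall = 0
        history = []
        for epoch in range(1, epochs + 1):
            strings = list(train)
            if augment_fn is not None:
                strings = [augment_fn(s, rng) for s in strings]
            order = rng.permutation(len(strings))
            total, n = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = self._encode_batch([strings[i] for i in idx])
                loss, grads = self.loss_and_grads(batch)
                self._adam_step(grads, lr)
                total += loss * len(idx)
                n += len(idx)
            val = self.evaluate_loss(held_out) if held_out else total / n
            history.append({"epoch": epoch, "train_loss": total / n, "val_loss": val, "lr": lr})
            if val < best - 1e-4:
                best = val
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    lr *= cfg.lr_decay
                    stall = 0
        return history

    # ---------------- sampling ----------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        temperature: Optional[float] = None,
    ) -> list[str]:
        """Draw n strings token by token; temperature 0 means argmax."""
        cfg = self.config
        p = self.params
        temp = cfg.temperature if temperature is None else temperature
        v = self.vocab
        start, end, pad = v.index[START], v.index[END], v.index[PAD]
        h_dim = cfg.hidden_size
        hs = [np.zeros((n, h_dim)) for _ in range(cfg.n_layers)]
        cs = [np.zeros((n, h_dim)) for _ in range(cfg.n_layers)]
        tokens = np.full(n, start, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        out_ids = np.full((n, cfg.max_sequence_length), pad, dtype=np.int64)
        for t in range(cfg.max_sequence_length):
            x = p["E"][tokens]
            for l in range(cfg.n_layers):
                z = np.hstack([x, hs[l]]) @ p[f"W{l}"] + p[f"b{l}"]
                i = _sigmoid(z[:, :h_dim])
                f = _sigmoid(z[:, h_dim : 2 * h_dim])
                g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
                o = _sigmoid(z[:, 3 * h_dim :])
                cs[l] = np.where(alive[:, None], f * cs[l] + i * g, cs[l])
                hs[l] = np.where(alive[:, None], o * np.tanh(cs[l]), hs[l])
                x = hs[l]
            logits = x @ p["Wo"] + p["bo"]
            if temp <= 1e-6:
                nxt = logits.argmax(axis=1)
            else:
                shifted = logits / temp
                shifted -= shifted.max(axis=1, keepdims=True)
                probs = np.exp(shifted)
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random((n, 1))
                nxt = (probs.cumsum(axis=1) < u).sum(axis=1)
            nxt = np.where(alive, nxt, pad)
            out_ids[:, t] = np.where(nxt == end, pad, nxt)
            alive &= nxt != end
            tokens = np.where(alive, nxt, pad)
            if not alive.any():
                break
        return [v.decode(row) for row in out_ids]


def pretrain(
    corpus: Sequence[str],
    config: Optional[GenerativeConfig] = None,
    epochs: Optional[int] = None,
) -> tuple[SmilesLSTM, list[dict]]:
    """Train a prior model on a SMILES corpus.

    10% of the corpus is held out to monitor next-token cross-entropy;
    a non-decreasing loss over the run raises a convergence warning.
    """
    config = config or GenerativeConfig()
    if len(corpus) < 500:
        warnings.warn(
            f"corpus of {len(corpus)} strings is small even at desk scale",
            stacklevel=2,
        )
    vocab = build_vocabulary(corpus)
    valid = [s for s in corpus if Chem.MolFromSmiles(s) is not None]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(valid))
    n_held = max(1, len(valid) // 10)
    held = [valid[i] for i in order[:n_held]]
    train = [valid[i] for i in order[n_held:]]
    model = SmilesLSTM(vocab, config, rng)
    history = model.fit(train, held, epochs or config.epochs, rng)
    if history and history[-1]["train_loss"] >= history[0]["train_loss"]:
        warnings.warn("pretraining loss did not decrease", stacklevel=2)
    return model, history


@dataclass
class EpochMetrics:
    """Sampling statistics after one fine-tuning epoch."""

    epoch: int
    n_sampled: int
    n_valid: int
    n_unique: int
    n_with_core: int
    n_reproduced_eas: int

    def check(self, n_eas: int) -> None:
        ok = (
            self.n_with_core <= self.n_valid <= self.n_sampled
            and self.n_unique <= self.n_valid
            and self.n_reproduced_eas <= n_eas
        )
        if not ok:
            raise AssertionError(f"inconsistent epoch metrics: {self}")


def core_query(series: AnalogSeries) -> Chem.Mol:
    """Substructure query for 'contains the series core': the core
    skeleton with attachment dummies removed, so both substituted and
    H-bearing sites match."""
    rw = Chem.RWMol(series.core.mol)
    for atom in sorted(
        (a for a in rw.GetAtoms() if a.GetAtomicNum() == 0),
        key=lambda a: -a.GetIdx(),
    ):
        rw.RemoveAtom(atom.GetIdx())
    q = rw.GetMol()
    Chem.SanitizeMol(q)
    return q


def score_sample(
    sample: Sequence[str], series: AnalogSeries, epoch: int
) -> tuple[EpochMetrics, list[str]]:
    """Score one epoch's sample; returns metrics and the canonical
    SMILES of its valid molecules."""
    query = core_query(series)
    ea_smiles = series.ea_smiles
    canon: list[str] = []
    n_core = 0
    reproduced: set[str] = set()
    for smi in sample:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        c = Chem.MolToSmiles(mol)
        canon.append(c)
        if mol.HasSubstructMatch(query):
            n_core += 1
        if c in ea_smiles:
            reproduced.add(c)
    metrics = EpochMetrics(
        epoch=epoch,
        n_sampled=len(sample),
        n_valid=len(canon),
        n_unique=len(set(canon)),
        n_with_core=n_core,
        n_reproduced_eas=len(reproduced),
    )
    metrics.check(series.n_analogs)
    return metrics, canon


def randomized_smiles(smiles: str, rng: np.random.Generator) -> str:
    """A random (non-canonical) SMILES of the same molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    variants = Chem.MolToRandomSmilesVect(mol, 1, int(rng.integers(2**31)))
    return variants[0] if variants else smiles


def transfer_learn(
    prior: SmilesLSTM,
    series: AnalogSeries,
    config: Optional[GenerativeConfig] = None,
) -> tuple[SmilesLSTM, list[EpochMetrics], list[list[str]]]:
    """Fine-tune a prior on the series' analogs, sampling every epoch.

    Every analog must tokenize under the prior vocabulary (an
    out-of-vocabulary token raises, naming the token).  When
    augmentation is enabled each epoch trains on freshly randomized
    SMILES of the analogs.  Returns the fine-tuned model, per-epoch
    metrics and the raw per-epoch samples.  Deterministic given
    ``config.seed``.
    """
    config = config or prior.config
    eas = [r.smiles for r in series.analogs]
    for smi in eas:
        prior.vocab.encode(smi)  # raises naming the offending token
    model = prior.clone()
    model.config = config
    # fresh optimizer state: fine-tuning is a new optimization problem
    model._adam_m = {k: np.zeros_like(p) for k, p in model.params.items()}
    model._adam_v = {k: np.zeros_like(p) for k, p in model.params.items()}
    model._adam_t = 0
    rng = np.random.default_rng(config.seed)
    augment = randomized_smiles if config.augmentation else None
    metrics: list[EpochMetrics] = []
    samples: list[list[str]] = []
    # several augmented passes per epoch so small series still provide
    # enough gradient steps to focus the model
    train_strings = eas * config.passes_per_epoch
    for epoch in range(1, config.epochs + 1):
        model.fit(train_strings, [], epochs=1, rng=rng, augment_fn=augment)
        sample = model.sample(config.sample_per_epoch, rng)
        m, _ = score_sample(sample, series, epoch)
        metrics.append(m)
        samples.append(sample)
    return model, metrics, samples


def collect_sampled_vas(
    samples: Sequence[Sequence[str]], series: AnalogSeries
) -> tuple[dict[str, int], set[str]]:
    """Unique sampled population with per-compound epoch frequency.

    Frequency counts the number of distinct epochs in which a compound
    appeared (several draws within one epoch count once).  Returns
    (canonical SMILES -> epoch count, subset that reproduces analogs).
    """
    freq: dict[str, set[int]] = {}
    for epoch, sample in enumerate(samples, start=1):
        epoch_canon: set[str] = set()
        for smi in sample:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            epoch_canon.add(Chem.MolToSmiles(mol))
        for c in epoch_canon:
            freq.setdefault(c, set()).add(epoch)
    counts = {c: len(e) for c, e in freq.items()}
    reproduced = set(counts) & series.ea_smiles
    return counts, reproduced
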