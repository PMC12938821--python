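"""A miniature trainable character-level SMILES variational autoencoder.

Molecules are tokenized (multi-character element tokens kept atomic),
one-hot encoded to a fixed maximum length and mapped by an MLP encoder to a
continuous latent space (posterior mean used for deterministic encoding).
Decoding samples each sequence position from a temperature-scaled softmax,
and the decode-retry protocol re-samples up to a configurable attempt budget
until a valid, long-enough molecule emerges.

Any object exposing ``encode(mol) -> vector`` and ``sample_smiles(z, rng,
temperature) -> str`` satisfies the embedding contract used by the rest of
the package, so external encoders can substitute for the built-in VAE.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chemstore import CanonicalMolecule, ParseError, standardize_molecule

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|@@|[BCNOFPSIbcnops]|[0-9]|%[0-9]{2}|[=#\-\+\\/\(\)\.@])"
)

PAD, EOS = "<pad>", "<eos>"


class TokenizationError(ValueError):
    pass


def tokenize_smiles(smiles: str) -> List[str]:
    """Split a SMILES string into tokens; two-character elements stay atomic."""
    tokens, pos = [], 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(f"untokenizable character {smiles[pos]!r} in {smiles!r}")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token list with specials; lossless on its building corpus."""

    tokens: Tuple[str, ...]
    max_length: int

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise TokenizationError(f"out-of-vocabulary token {token!r}") from None

    def encode(self, smiles: str) -> np.ndarray:
        """Token index sequence padded to max_length (EOS-terminated)."""
        toks = tokenize_smiles(smiles)
        if len(toks) + 1 > self.max_length:
            raise TokenizationError(f"SMILES longer than max_length: {smiles!r}")
        idx = [self.index(t) for t in toks] + [self.tokens.index(EOS)]
        idx += [self.tokens.index(PAD)] * (self.max_length - len(idx))
        return np.array(idx, dtype=np.int64)

    def decode(self, indices: Sequence[int]) -> str:
        out = []
        pad_i, eos_i = self.tokens.index(PAD), self.tokens.index(EOS)
        for i in indices:
            if i in (pad_i, eos_i):
                break
            out.append(self.tokens[i])
        return "".join(out)


def build_vocabulary(corpus: Sequence[str], max_length: int = 64) -> TokenVocabulary:
    """Build a vocabulary covering every corpus string losslessly.

    Strings whose token count (plus EOS) exceeds ``max_length`` are rejected.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    seen = set()
    for s in corpus:
        toks = tokenize_smiles(s)
        if len(toks) + 1 > max_length:
            raise TokenizationError(f"corpus string exceeds max_length: {s!r}")
        seen.update(toks)
    tokens = (PAD, EOS, *sorted(seen))
    vocab = TokenVocabulary(tokens=tokens, max_length=max_length)
    for s in corpus:  # round-trip invariant
        assert vocab.decode(vocab.encode(s)) == s
    return vocab


@dataclass
class VaeConfig:
    latent_dim: int = 196
    hidden_dim: int = 256
    epochs: int = 1500
    batch_size: int = 64
    learning_rate: float = 1e-3
    kl_weight: float = 0.05
    kl_warmup_epochs: int = 200
    seed: int = 0


@dataclass
class DecodePolicy:
    """Decode-retry budget and the post-decode length filter."""

    max_attempts: int = 500
    temperature: float = 1.0
    min_smiles_length: int = 10
    seed: int = 0
    jitter_sd: float = 0.0  # optional per-attempt latent perturbation


def length_filter(smiles: str, min_len: int = 10) -> bool:
    """True iff the SMILES character length is >= ``min_len`` (strict < discard)."""
    return len(smiles) >= min_len


class VaeModel:
    """MLP variational autoencoder over one-hot SMILES sequences.

    ``encode`` returns the (deterministic) posterior mean; ``sample_smiles``
    draws every position independently from the temperature-scaled decoder
    softmax at a fixed latent point.
    """

    def __init__(self, vocab: TokenVocabulary, config: VaeConfig):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, V, H, d = vocab.max_length, vocab.size, config.hidden_dim, config.latent_dim
        D = L * V

        def init(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        self.params = {
            "W1": init((D, H), D), "b1": np.zeros(H),
            "Wm": init((H, d), H), "bm": np.zeros(d),
            "Wv": init((H, d), H), "bv": np.zeros(d),
            "W2": init((d, H), d), "b2": np.zeros(H),
            "W3": init((H, D), H), "b3": np.zeros(D),
        }
        self.training_log: List[dict] = []

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    # -- forward pieces ----------------------------------------------------
    def _onehot(self, idx: np.ndarray) -> np.ndarray:
        L, V = self.vocab.max_length, self.vocab.size
        x = np.zeros((idx.shape[0], L, V))
        rows = np.arange(idx.shape[0])[:, None]
        x[rows, np.arange(L)[None, :], idx] = 1.0
        return x.reshape(idx.shape[0], L * V)

    def _encode_batch(self, x: np.ndarray):
        p = self.params
        h1 = np.tanh(x @ p["W1"] + p["b1"])
        return h1, h1 @ p["Wm"] + p["bm"], h1 @ p["Wv"] + p["bv"]

    def _decode_logits(self, z: np.ndarray):
        p = self.params
        h2 = np.tanh(z @ p["W2"] + p["b2"])
        return h2, (h2 @ p["W3"] + p["b3"]).reshape(z.shape[0], self.vocab.max_length, self.vocab.size)

    # -- public API --------------------------------------------------------
    def encode_smiles(self, smiles: str) -> np.ndarray:
        idx = self.vocab.encode(smiles)[None, :]
        _, mu, _ = self._encode_batch(self._onehot(idx))
        return mu[0]

    def encode(self, mol: CanonicalMolecule) -> np.ndarray:
        """Deterministic posterior-mean embedding of a molecule."""
        return self.encode_smiles(mol.smiles)

    def sample_smiles(self, z: np.ndarray, rng: np.random.Generator, temperature: float = 1.0) -> str:
        if z.shape != (self.latent_dim,):
            raise ValueError(f"latent dimension mismatch: {z.shape} vs {self.latent_dim}")
        _, logits = self._decode_logits(z[None, :])
        logits = logits[0] / max(temperature, 1e-8)
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        # vectorized inverse-CDF draw per position
        cdf = np.cumsum(probs, axis=1)
        u = rng.random((self.vocab.max_length, 1))
        idx = (cdf < u).sum(axis=1)
        return self.vocab.decode(idx)

    def greedy_smiles(self, z: np.ndarray) -> str:
        _, logits = self._decode_logits(z[None, :])
        return self.vocab.decode(np.argmax(logits[0], axis=1))

    # -- training ----------------------------------------------------------
    def fit(self, corpus_smiles: Sequence[str]) -> "VaeModel":
        """Train with Adam on cross-entropy + KL (linear KL warm-up)."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        idx_all = np.stack([self.vocab.encode(s) for s in corpus_smiles])
        n = idx_all.shape[0]
        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        for epoch in range(cfg.epochs):
            beta = cfg.kl_weight * min(1.0, (epoch + 1) / max(cfg.kl_warmup_epochs, 1))
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                batch = idx_all[order[start:start + cfg.batch_size]]
                t += 1
                loss = self._adam_step(batch, beta, rng, m_state, v_state, t)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                losses.append(loss)
            self.training_log.append({"epoch": epoch, "loss": float(np.mean(losses)), "beta": beta})
        return self

    def _adam_step(self, batch_idx, beta, rng, m_state, v_state, t):
        p = self.params
        B, L, V = batch_idx.shape[0], self.vocab.max_length, self.vocab.size
        x = self._onehot(batch_idx)
        h1, mu, lv = self._encode_batch(x)
        lv = np.clip(lv, -10, 10)
        std = np.exp(0.5 * lv)
        eps = rng.standard_normal(mu.shape)
        z = mu + std * eps
        h2, logits = self._decode_logits(z)
        logits = logits.reshape(B, L, V)
        logits -= logits.max(axis=2, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=2, keepdims=True)
        rows, cols = np.arange(B)[:, None], np.arange(L)[None, :]
        ce = -np.log(probs[rows, cols, batch_idx] + 1e-12).sum(axis=1)
        kl = -0.5 * (1 + lv - mu**2 - np.exp(lv)).sum(axis=1)
        loss = float(np.mean(ce + beta * kl))

        dlogits = probs.copy()
        dlogits[rows, cols, batch_idx] -= 1.0
        dlogits = dlogits.reshape(B, L * V) / B
        grads = {}
        grads["W3"] = h2.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dh2 = (dlogits @ p["W3"].T) * (1 - h2**2)
        grads["W2"] = z.T @ dh2
        grads["b2"] = dh2.sum(axis=0)
        dz = dh2 @ p["W2"].T
        dmu = dz + beta * mu / B
        dlv = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(lv) - 1) / B
        dh1 = (dmu @ p["Wm"].T + dlv @ p["Wv"].T) * (1 - h1**2)
        grads["Wm"] = h1.T @ dmu
        grads["bm"] = dmu.sum(axis=0)
        grads["Wv"] = h1.T @ dlv
        grads["bv"] = dlv.sum(axis=0)
        grads["W1"] = x.T @ dh1
        grads["b1"] = dh1.sum(axis=0)

        lr, b1m, b2m, eps_a = self.config.learning_rate, 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m_state[k] = b1m * m_state[k] + (1 - b1m) * g
            v_state[k] = b2m * v_state[k] + (1 - b2m) * g**2
            mhat = m_state[k] / (1 - b1m**t)
            vhat = v_state[k] / (1 - b2m**t)
            p[k] -= lr * mhat / (np.sqrt(vhat) + eps_a)
        return loss

    def reconstruction_accuracy(self, corpus_smiles: Sequence[str]) -> float:
        """Fraction of corpus strings exactly recovered by greedy decoding."""
        hits = sum(1 for s in corpus_smiles if self.greedy_smiles(self.encode_smiles(s)) == s)
        return hits / len(corpus_smiles)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "tokens": list(self.vocab.tokens),
            "max_length": self.vocab.max_length,
            "config": self.config.__dict__,
        }
        np.savez(path, meta=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "VaeModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        vocab = TokenVocabulary(tokens=tuple(meta["tokens"]), max_length=meta["max_length"])
        model = cls(vocab, VaeConfig(**meta["config"]))
        for k in model.params:
            model.params[k] = data[k]
        return model


def train_vae(corpus: Sequence[CanonicalMolecule], config: Optional[VaeConfig] = None,
              max_length: int = 64) -> VaeModel:
    """Build a vocabulary on a standardized corpus and train the VAE."""
    config = config or VaeConfig()
    smiles = [m.smiles for m in corpus]
    vocab = build_vocabulary(smiles, max_length=max_length)
    return VaeModel(vocab, config).fit(smiles)


def decode_with_retries(model, z: np.ndarray, policy: DecodePolicy = DecodePolicy()):
    """Stochastically decode a latent vector with a retry budget.

    Returns ``(molecule, attempts)`` where ``molecule`` is the first decoded
    string that parses as a valid molecule and whose canonical SMILES passes
    the length filter, standardized to a :class:`CanonicalMolecule`; or
    ``(None, attempts)`` if every attempt fails.
    """
    rng = np.random.default_rng(policy.seed)
    attempts = 0
    for _ in range(policy.max_attempts):
        attempts += 1
        zt = z if policy.jitter_sd == 0 else z + rng.normal(0, policy.jitter_sd, size=z.shape)
        s = model.sample_smiles(zt, rng, temperature=policy.temperature)
        if not s:
            continue
        try:
            mol = standardize_molecule(s)
        except (ParseError, ValueError):
            continue
        if length_filter(mol.smiles, policy.min_smiles_length):
            return mol, attempts
    return None, attempts
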