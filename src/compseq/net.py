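"""Encoder-decoder transformer for episode-based (meta-)training.

The encoder consumes a single source string: the query input tokens followed
by the study examples, each delimited by ``|`` with ``->`` between a study
input and its output. The decoder emits output symbols autoregressively
between ``<SOS>`` and ``<EOS>``. Architecture defaults follow the behavioural
modelling setup: 3+3 layers, 8 heads, 128-dim embeddings, 512-dim feedforward,
GELU activations, sinusoidal positional encodings, dropout 0.1 -- about 1.4
million parameters.

Training regimes differ only in how the episode stream is prepared (bias
transform, copy-only queries, open-ended chains, bridge episodes); the
optimizer is Adam with a one-epoch linear warm-up and a linear decay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor
from .episodes import Episode, ExamplePair
from .grammar import COLOUR_POOL, WORD_POOL

__all__ = [
    "NetConfig",
    "TrainConfig",
    "SeqToSeqTransformer",
    "Checkpoint",
    "encode_source",
    "episode_instances",
    "open_ended_episodes",
    "bridge_episodes",
    "meta_train",
    "train_basic_seq2seq",
    "BasicSeq2SeqResult",
]

PAD = "<PAD>"
SOS = "<SOS>"
EOS_TOK = "<EOS>"
SEP_EXAMPLE = "|"
SEP_IO = "->"


@dataclass(frozen=True)
class NetConfig:
    n_layers: int = 3
    n_heads: int = 8
    d_model: int = 128
    d_ff: int = 512
    dropout: float = 0.1
    words: tuple[str, ...] = WORD_POOL[:8]
    symbols: tuple[str, ...] = COLOUR_POOL
    max_decode_len: int = 9  # 8 output symbols + end marker
    norm_style: str = "post"  # "post" (standard) or "pre" (stabler at small scale)

    def __post_init__(self) -> None:
        if min(self.n_layers, self.n_heads, self.d_model, self.d_ff) <= 0:
            raise ValueError("architecture dimensions must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.norm_style not in ("post", "pre"):
            raise ValueError("norm_style must be 'post' or 'pre'")

    @property
    def encoder_vocab(self) -> tuple[str, ...]:
        return (PAD,) + self.words + self.symbols + (SEP_EXAMPLE, SEP_IO)

    @property
    def decoder_vocab(self) -> tuple[str, ...]:
        return (PAD,) + self.symbols + (SOS, EOS_TOK)

    @property
    def output_classes(self) -> tuple[str, ...]:
        return self.symbols + (EOS_TOK,)


@dataclass
class TrainConfig:
    batch_size: int = 25  # episodes per batch
    epochs: int = 50
    lr_max: float = 1e-3
    lr_min: float = 5e-5
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    val_every: int = 100  # steps between validation checkpoints
    include_copy_queries: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_max <= 0 or self.lr_min <= 0:
            raise ValueError("learning-rate endpoints must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def encode_source(
    study: Sequence[ExamplePair], query_input: Sequence[str]
) -> list[str]:
    """Concatenate query and study examples into one source token sequence.

    Layout (a fixed convention of this package): query tokens first, then for
    each study pair a ``|`` delimiter, the pair's input tokens, ``->``, and
    its output tokens. The layout round-trips: tokens before the first ``|``
    are the query, and each delimited block splits at ``->``.
    """
    tokens = list(query_input)
    for pair in study:
        tokens.append(SEP_EXAMPLE)
        tokens.extend(pair.input)
        tokens.append(SEP_IO)
        tokens.extend(pair.output)
    return tokens


def decode_source(tokens: Sequence[str]) -> tuple[list[str], list[tuple[list[str], list[str]]]]:
    """Inverse of :func:`encode_source` (used to verify the layout)."""
    toks = list(tokens)
    first = toks.index(SEP_EXAMPLE) if SEP_EXAMPLE in toks else len(toks)
    query = toks[:first]
    pairs = []
    rest = toks[first:]
    while rest:
        assert rest[0] == SEP_EXAMPLE
        rest = rest[1:]
        end = rest.index(SEP_EXAMPLE) if SEP_EXAMPLE in rest else len(rest)
        block = rest[:end]
        rest = rest[end:]
        io = block.index(SEP_IO)
        pairs.append((block[:io], block[io + 1:]))
    return query, pairs


def episode_instances(
    episode: Episode, include_copy_queries: bool = True
) -> list[tuple[list[str], tuple[str, ...]]]:
    """(source tokens, target output) training instances for one episode.

    Every query contributes one instance; with ``include_copy_queries`` each
    study input is additionally passed as an auxiliary copy query whose target
    is its own study output.
    """
    out = []
    for q in episode.query:
        out.append((encode_source(episode.study, q.input), q.output))
    if include_copy_queries:
        for s in episode.study:
            out.append((encode_source(episode.study, s.input), s.output))
    return out


def open_ended_episodes(
    participant_chains: Sequence[Sequence[ExamplePair]],
    rng: np.random.Generator,
    n_episodes: int,
    words: Sequence[str] = WORD_POOL[:8],
    symbols: Sequence[str] = COLOUR_POOL,
) -> list[Episode]:
    """Episodes derived from open-ended participant response chains.

    Each episode picks one participant's (query, response) pairs, splits
    them into 0-5 study pairs (remainder become queries), shuffles the study
    order and remaps the input words and output symbols by fresh random
    bijections, preserving the structure of the mapping while varying its
    surface form.
    """
    episodes = []
    for _ in range(n_episodes):
        chain = list(participant_chains[int(rng.integers(len(participant_chains)))])
        # map the observed surface vocabulary onto the network's vocabulary
        seen_words = sorted({w for p in chain for w in p.input})
        seen_syms = sorted({s for p in chain for s in p.output})
        if len(seen_words) > len(words) or len(seen_syms) > len(symbols):
            raise ValueError("chain vocabulary exceeds the network vocabulary")
        word_perm = {
            w: words[int(i)]
            for w, i in zip(seen_words, rng.choice(len(words), size=len(seen_words), replace=False))
        }
        sym_perm = {
            s: symbols[int(i)]
            for s, i in zip(seen_syms, rng.choice(len(symbols), size=len(seen_syms), replace=False))
        }

        def remap(pair: ExamplePair, tag: str) -> ExamplePair:
            return ExamplePair(
                input=tuple(word_perm.get(w, w) for w in pair.input),
                output=tuple(sym_perm.get(s, s) for s in pair.output),
                tag=tag,
                provenance="human",
            )

        n_study = int(rng.integers(0, min(5, len(chain) - 1) + 1))
        order = rng.permutation(len(chain))
        study_idx = sorted(order[:n_study])
        study = [remap(chain[int(i)], "study") for i in rng.permutation(study_idx)]
        query = [remap(chain[int(i)], "query") for i in range(len(chain)) if i not in study_idx]
        episodes.append(Episode(study=study, query=query, grammar=None))
    return episodes


def bridge_episodes(
    episodes: Sequence[Episode], rng: np.random.Generator
) -> list[Episode]:
    """Few-shot episodes with the study count subsampled uniformly 0..14.

    Used to unify joint training: with few study examples an episode is
    indistinguishable from an open-ended one, so a single model must handle
    both regimes.
    """
    out = []
    for ep in episodes:
        keep = int(rng.integers(0, len(ep.study) + 1))
        idx = rng.permutation(len(ep.study))[:keep]
        study = [ep.study[int(i)] for i in idx]
        out.append(Episode(study=study, query=list(ep.query), grammar=ep.grammar))
    return out


class SeqToSeqTransformer:
    """Post-norm encoder-decoder transformer over NumPy tensors."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        self.config = config
        self.enc_index = {t: i for i, t in enumerate(config.encoder_vocab)}
        self.dec_index = {t: i for i, t in enumerate(config.decoder_vocab)}
        self.class_index = {t: i for i, t in enumerate(config.output_classes)}
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # -- parameters --------------------------------------------------------

    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Parameter(array)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, ff = cfg.d_model, cfg.d_ff
        std = 0.02

        def mat(*shape):
            return rng.normal(0.0, std, size=shape)

        # unit variance after the sqrt(d) embedding scale, so token identity
        # is not drowned out by the positional encodings
        emb_std = 1.0 / math.sqrt(d)
        self._add("enc_embed", rng.normal(0.0, emb_std, size=(len(cfg.encoder_vocab), d)))
        self._add("dec_embed", rng.normal(0.0, emb_std, size=(len(cfg.decoder_vocab), d)))
        for side, layers in (("enc", cfg.n_layers), ("dec", cfg.n_layers)):
            for l in range(layers):
                p = f"{side}{l}"
                blocks = ["self"] if side == "enc" else ["self", "cross"]
                for blk in blocks:
                    for m in ("q", "k", "v", "o"):
                        self._add(f"{p}.{blk}.W{m}", mat(d, d))
                        self._add(f"{p}.{blk}.b{m}", np.zeros(d))
                    self._add(f"{p}.{blk}.ln_g", np.ones(d))
                    self._add(f"{p}.{blk}.ln_b", np.zeros(d))
                self._add(f"{p}.ff.W1", mat(d, ff))
                self._add(f"{p}.ff.b1", np.zeros(ff))
                self._add(f"{p}.ff.W2", mat(ff, d))
                self._add(f"{p}.ff.b2", np.zeros(d))
                self._add(f"{p}.ff.ln_g", np.ones(d))
                self._add(f"{p}.ff.ln_b", np.zeros(d))
        if cfg.norm_style == "pre":
            for side in ("enc", "dec"):
                self._add(f"{side}_final.ln_g", np.ones(d))
                self._add(f"{side}_final.ln_b", np.zeros(d))
        self._add("out.W", mat(d, len(cfg.output_classes)))
        self._add("out.b", np.zeros(len(cfg.output_classes)))

    def count_params(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        from .autodiff import get_default_dtype

        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=get_default_dtype())

    # -- encoding helpers --------------------------------------------------

    def _ids(self, tokens: Sequence[str], index: dict[str, int]) -> list[int]:
        try:
            return [index[t] for t in tokens]
        except KeyError as exc:
            raise ValueError(f"token outside vocabulary: {exc.args[0]!r}") from exc

    def _pad_batch(
        self, seqs: Sequence[Sequence[int]]
    ) -> tuple[np.ndarray, np.ndarray]:
        n, m = len(seqs), max(len(s) for s in seqs)
        ids = np.zeros((n, m), dtype=np.int64)
        mask = np.zeros((n, m), dtype=bool)
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            mask[i, : len(s)] = True
        return ids, mask

    @staticmethod
    def _positional(length: int, d: int) -> np.ndarray:
        pos = np.arange(length)[:, None]
        i = np.arange(d // 2)[None, :]
        angles = pos / np.power(10000.0, 2 * i / d)
        from .autodiff import get_default_dtype

        pe = np.zeros((length, d), dtype=get_default_dtype())
        pe[:, 0::2] = np.sin(angles)
        pe[:, 1::2] = np.cos(angles)
        return pe

    # -- forward pass ------------------------------------------------------

    def _attention(
        self,
        prefix: str,
        x: Tensor,
        kv: Tensor,
        add_mask: np.ndarray,
        rng: Optional[np.random.Generator],
    ) -> Tensor:
        cfg = self.config
        H, Dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        B, Tq = x.shape[0], x.shape[1]
        Tk = kv.shape[1]
        P = self.params

        def proj(z: Tensor, m: str) -> Tensor:
            out = z.matmul(P[f"{prefix}.W{m}"]) + P[f"{prefix}.b{m}"]
            return out.reshape(z.shape[0], z.shape[1], H, Dh).transpose(0, 2, 1, 3)

        pre = cfg.norm_style == "pre"
        if pre:
            src = x.layer_norm(P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"])
            kv_src = src if kv is x else kv
        else:
            src, kv_src = x, kv
        q, k, v = proj(src, "q"), proj(kv_src, "k"), proj(kv_src, "v")
        scores = q.matmul(k.transpose(0, 1, 3, 2)).scale(1.0 / math.sqrt(Dh))
        att = scores.softmax(additive_mask=add_mask)
        att = att.dropout(cfg.dropout, rng)
        ctx = att.matmul(v).transpose(0, 2, 1, 3).reshape(B, Tq, cfg.d_model)
        ctx = ctx.matmul(P[f"{prefix}.Wo"]) + P[f"{prefix}.bo"]
        ctx = ctx.dropout(cfg.dropout, rng)
        res = x + ctx
        if pre:
            return res
        return res.layer_norm(P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"])

    def _ffn(self, prefix: str, x: Tensor, rng) -> Tensor:
        P = self.params
        pre = self.config.norm_style == "pre"
        src = x.layer_norm(P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"]) if pre else x
        h = (src.matmul(P[f"{prefix}.W1"]) + P[f"{prefix}.b1"]).gelu()
        h = h.matmul(P[f"{prefix}.W2"]) + P[f"{prefix}.b2"]
        h = h.dropout(self.config.dropout, rng)
        res = x + h
        if pre:
            return res
        return res.layer_norm(P[f"{prefix}.ln_g"], P[f"{prefix}.ln_b"])

    def _embed(self, table: Tensor, ids: np.ndarray, rng) -> Tensor:
        d = self.config.d_model
        x = table.embedding(ids).scale(math.sqrt(d))
        x = x.add_const(self._positional(ids.shape[1], d)[None])
        return x.dropout(self.config.dropout, rng)

    @staticmethod
    def _key_mask(mask: np.ndarray) -> np.ndarray:
        from .autodiff import get_default_dtype

        # (B, Tk) boolean -> additive (B, 1, 1, Tk)
        return np.where(mask[:, None, None, :], 0.0, -1e9).astype(get_default_dtype())

    def encode(self, src_ids: np.ndarray, src_mask: np.ndarray, rng=None) -> Tensor:
        x = self._embed(self.params["enc_embed"], src_ids, rng)
        add = self._key_mask(src_mask)
        for l in range(self.config.n_layers):
            x = self._attention(f"enc{l}.self", x, x, add, rng)
            x = self._ffn(f"enc{l}.ff", x, rng)
        if self.config.norm_style == "pre":
            x = x.layer_norm(self.params["enc_final.ln_g"], self.params["enc_final.ln_b"])
        return x

    def decode(
        self,
        memory: Tensor,
        src_mask: np.ndarray,
        tgt_ids: np.ndarray,
        rng=None,
    ) -> Tensor:
        T = tgt_ids.shape[1]
        x = self._embed(self.params["dec_embed"], tgt_ids, rng)
        from .autodiff import get_default_dtype

        causal = np.where(np.tril(np.ones((T, T), dtype=bool)), 0.0, -1e9)[
            None, None
        ].astype(get_default_dtype())
        cross = self._key_mask(src_mask)
        for l in range(self.config.n_layers):
            x = self._attention(f"dec{l}.self", x, x, causal, rng)
            x = self._attention(f"dec{l}.cross", x, memory, cross, rng)
            x = self._ffn(f"dec{l}.ff", x, rng)
        if self.config.norm_style == "pre":
            x = x.layer_norm(self.params["dec_final.ln_g"], self.params["dec_final.ln_b"])
        return x.matmul(self.params["out.W"]) + self.params["out.b"]

    # -- training-facing API ----------------------------------------------

    def batch_arrays(
        self, instances: Sequence[tuple[Sequence[str], Sequence[str]]]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        srcs = [self._ids(s, self.enc_index) for s, _ in instances]
        tgts_in = [
            self._ids([SOS] + list(t), self.dec_index) for _, t in instances
        ]
        tgt_classes = [
            [self.class_index[tok] for tok in list(t)] + [self.class_index[EOS_TOK]]
            for _, t in instances
        ]
        src_ids, src_mask = self._pad_batch(srcs)
        tgt_ids, tgt_mask = self._pad_batch(tgts_in)
        targets = np.zeros_like(tgt_ids)
        for i, cls in enumerate(tgt_classes):
            targets[i, : len(cls)] = cls
        return src_ids, src_mask, tgt_ids, tgt_mask, targets

    def loss(
        self,
        instances: Sequence[tuple[Sequence[str], Sequence[str]]],
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Token-averaged cross-entropy on a batch of (source, target) pairs."""
        src_ids, src_mask, tgt_ids, tgt_mask, targets = self.batch_arrays(instances)
        memory = self.encode(src_ids, src_mask, rng)
        logits = self.decode(memory, src_mask, tgt_ids, rng)
        B, T, V = logits.shape
        flat = logits.reshape(B * T, V)
        loss = flat.cross_entropy(targets.reshape(-1), tgt_mask.reshape(-1).astype(float))
        if not np.isfinite(loss.data):
            raise FloatingPointError("training loss diverged (non-finite)")
        return loss

    def _step_logits(self, memory: Tensor, src_mask, tgt_ids) -> np.ndarray:
        return self.decode(memory, src_mask, tgt_ids, rng=None).data

    def greedy_decode(
        self, source_tokens: Sequence[str], max_steps: Optional[int] = None
    ) -> tuple[str, ...]:
        """Argmax decoding until the end marker; ties break to the lowest index."""
        return self._autoregress(source_tokens, rng=None, max_steps=max_steps)

    def sample_decode(
        self,
        source_tokens: Sequence[str],
        rng: np.random.Generator,
        max_steps: Optional[int] = None,
        temperature: float = 1.0,
    ) -> tuple[str, ...]:
        return self._autoregress(source_tokens, rng=rng, max_steps=max_steps, temperature=temperature)

    def _autoregress(self, source_tokens, rng, max_steps=None, temperature=1.0):
        cfg = self.config
        max_steps = max_steps or cfg.max_decode_len
        src_ids, src_mask = self._pad_batch([self._ids(source_tokens, self.enc_index)])
        memory = self.encode(src_ids, src_mask, rng=None)
        out: list[str] = []
        tgt = [self.dec_index[SOS]]
        for _ in range(max_steps):
            logits = self._step_logits(memory, src_mask, np.array([tgt]))[0, -1]
            if rng is None:
                choice = int(np.argmax(logits))  # argmax -> lowest index on ties
            else:
                z = logits / temperature
                z -= z.max()
                p = np.exp(z)
                p /= p.sum()
                choice = int(rng.choice(len(p), p=p))
            tok = cfg.output_classes[choice]
            if tok == EOS_TOK:
                break
            out.append(tok)
            tgt.append(self.dec_index[tok])
        return tuple(out)

    def response_distributions(
        self, source_tokens: Sequence[str], response: Sequence[str]
    ) -> list[np.ndarray]:
        """Teacher-forced next-symbol distribution at each response position.

        Row ``t`` is the model's distribution over the output classes before
        emitting token ``t`` of ``response`` (the last row conditions on the
        whole response, i.e. it is the end-of-sequence slot).
        """
        src_ids, src_mask = self._pad_batch([self._ids(source_tokens, self.enc_index)])
        memory = self.encode(src_ids, src_mask, rng=None)
        tgt = [self.dec_index[SOS]] + self._ids(response, self.dec_index)
        logits = self._step_logits(memory, src_mask, np.array([tgt]))[0]
        z = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(z)
        return list(p / p.sum(axis=-1, keepdims=True))

    def score_response(
        self, source_tokens: Sequence[str], response: Sequence[str]
    ) -> float:
        """Log-probability of ``response`` plus its end marker (nats)."""
        dists = self.response_distributions(source_tokens, response)
        idx = [self.class_index[t] for t in list(response)] + [self.class_index[EOS_TOK]]
        return float(sum(math.log(d[i]) for d, i in zip(dists, idx)))


# -- optimization -----------------------------------------------------------


class _Adam:
    def __init__(self, params: dict[str, Tensor], betas, eps):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def lr_at(step: int, steps_per_epoch: int, total_steps: int, cfg: TrainConfig) -> float:
    """One-epoch linear warm-up to lr_max, then linear decay to lr_min."""
    warm = max(steps_per_epoch, 1)
    if step < warm:
        return cfg.lr_max * (step + 1) / warm
    remain = max(total_steps - warm, 1)
    frac = min((step - warm + 1) / remain, 1.0)
    return cfg.lr_max + frac * (cfg.lr_min - cfg.lr_max)


@dataclass
class Checkpoint:
    """Trained weights plus the configuration and vocabulary that bind them."""

    state: dict[str, np.ndarray]
    config: NetConfig
    step: int = 0
    val_loss: Optional[float] = None
    log: list[dict] = field(default_factory=list)

    def build(self) -> SeqToSeqTransformer:
        net = SeqToSeqTransformer(self.config, np.random.default_rng(0))
        net.load_state_dict(self.state)
        return net

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "step": self.step,
            "val_loss": self.val_loss,
            "log": self.log,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.state)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg_dict = meta["config"]
        for key in ("words", "symbols", "adam_betas"):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        return cls(
            state=state,
            config=NetConfig(**cfg_dict),
            step=meta["step"],
            val_loss=meta["val_loss"],
            log=meta["log"],
        )


def meta_train(
    episodes: Sequence[Episode],
    net_config: NetConfig = NetConfig(),
    train_config: TrainConfig = TrainConfig(),
    val_episodes: Sequence[Episode] = (),
    net: Optional[SeqToSeqTransformer] = None,
    progress: bool = False,
) -> Checkpoint:
    """Optimize a transformer over an episode stream.

    Episodes must already be prepared for the desired regime (bias-transformed
    queries, copy-only queries, open-ended chains, bridge study counts). When
    validation episodes are given, the best parameter setting across intervals
    of ``val_every`` steps is kept; otherwise training runs to completion and
    the final parameters are returned.
    """
    if not episodes:
        raise ValueError("empty episode stream")
    rng = np.random.default_rng(train_config.seed)
    if net is None:
        net = SeqToSeqTransformer(net_config, rng)
    opt = _Adam(net.params, train_config.adam_betas, train_config.adam_eps)
    steps_per_epoch = math.ceil(len(episodes) / train_config.batch_size)
    total_steps = steps_per_epoch * train_config.epochs

    val_instances = []
    for ep in val_episodes:
        val_instances.extend(
            episode_instances(ep, train_config.include_copy_queries)
        )

    best_state = None
    best_val = math.inf
    log: list[dict] = []
    step = 0
    iterator = range(train_config.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="meta-train", unit="epoch")
    for _epoch in iterator:
        order = rng.permutation(len(episodes))
        for start in range(0, len(episodes), train_config.batch_size):
            batch_eps = [episodes[int(i)] for i in order[start : start + train_config.batch_size]]
            instances = []
            for ep in batch_eps:
                instances.extend(
                    episode_instances(ep, train_config.include_copy_queries)
                )
            opt.zero_grad()
            loss = net.loss(instances, rng=rng)
            loss.backward()
            opt.step(lr_at(step, steps_per_epoch, total_steps, train_config))
            entry = {"step": step, "train_loss": float(loss.data)}
            if val_instances and step % train_config.val_every == 0:
                vloss = float(net.loss(val_instances, rng=None).data)
                entry["val_loss"] = vloss
                if vloss < best_val:
                    best_val = vloss
                    best_state = net.state_dict()
            log.append(entry)
            step += 1

    if val_instances:
        vloss = float(net.loss(val_instances, rng=None).data)
        if vloss < best_val:
            best_val = vloss
            best_state = net.state_dict()
    state = best_state if best_state is not None else net.state_dict()
    return Checkpoint(
        state=state,
        config=net.config,
        step=step,
        val_loss=None if not val_instances else best_val,
        log=log,
    )


@dataclass
class BasicSeq2SeqResult:
    checkpoint: Checkpoint
    train_exact_match: float
    test_exact_match: float
    best_step: int
    log: list[dict]


def train_basic_seq2seq(
    study_pairs: Sequence[ExamplePair],
    query_pairs: Sequence[ExamplePair],
    net_config: NetConfig = NetConfig(),
    train_config: TrainConfig = TrainConfig(),
    n_epochs: int = 1000,
) -> BasicSeq2SeqResult:
    """Train the no-context transformer on the study items alone.

    The source is the query input only (no study examples in context). Each
    epoch is one optimizer step over the batched study set. Every step's
    parameters are scored on the *query* loss and the best such setting is
    selected -- a deliberately favourable checkpoint-selection concession --
    before exact-match accuracy on the queries is measured by greedy decoding.
    """
    rng = np.random.default_rng(train_config.seed)
    net = SeqToSeqTransformer(net_config, rng)
    opt = _Adam(net.params, train_config.adam_betas, train_config.adam_eps)
    train_instances = [(list(p.input), p.output) for p in study_pairs]
    test_instances = [(list(p.input), p.output) for p in query_pairs]

    best_state = net.state_dict()
    best_val = float(net.loss(test_instances, rng=None).data)
    best_step = -1
    log = []
    for step in range(n_epochs):
        opt.zero_grad()
        loss = net.loss(train_instances, rng=rng)
        loss.backward()
        opt.step(lr_at(step, 1, n_epochs, train_config))
        test_loss = float(net.loss(test_instances, rng=None).data)
        log.append({"step": step, "train_loss": float(loss.data), "test_loss": test_loss})
        if test_loss < best_val:
            best_val = test_loss
            best_state = net.state_dict()
            best_step = step

    def exact(instances) -> float:
        hits = 0
        for src, tgt in instances:
            if net.greedy_decode(src) == tuple(tgt):
                hits += 1
        return hits / len(instances)

    # memorization is judged on the fully trained weights; generalization on
    # the favourably selected best-test-loss checkpoint
    train_em = exact(train_instances)
    net.load_state_dict(best_state)
    test_em = exact(test_instances)

    return BasicSeq2SeqResult(
        checkpoint=Checkpoint(state=best_state, config=net_config, step=best_step, val_loss=best_val, log=log),
        train_exact_match=train_em,
        test_exact_match=test_em,
        best_step=best_step,
        log=log,
    )
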