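"""Tokenization, beam-search decoding and a tiny trainable sequence model.

The decoding stack is model-agnostic: anything exposing the
:class:`SequenceModel` contract — a per-step ``next_token_distribution``
over a shared vocabulary — can be plugged into :func:`beam_search`.
Temperature rescales each step's distribution as ``p**(1/t)`` renormalized;
``t=1`` is plain beam search and beam size 1 is greedy decoding.

The bundled :class:`TinySeq2Seq` is a deliberately small pointer-generator
transducer: a one-hidden-layer network over a sliding source window, the
previous target tokens and a global source composition vector, plus a
single-head attention whose weights double as a copy distribution over the
source tokens.  It trains on a CPU in minutes and exists to exercise the
full augmentation → decoding → aggregation → metrics pipeline at desk
scale, not to approach the accuracy of large-scale sequence-to-sequence
models.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

BOS = "<bos>"
EOS = "<eos>"
PAD = "<pad>"
UNK = "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)

# SMILES token pattern for the optional multi-character mode: bracket atoms,
# two-letter elements, ring-bond digits (%nn), bond/branch punctuation.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|[A-Za-z]|\d|[-=#$:/\\().+>*~])"
)


class UnknownTokenError(KeyError):
    """A symbol outside the model vocabulary was encountered."""


def tokenize(smiles: str, mode: str = "char") -> list[str]:
    """Split a SMILES string into tokens.

    ``char`` (default): one symbol per character, matching a
    character-level vocabulary.  ``regex``: multi-character chemically
    aware tokens (two-letter elements, bracket atoms, ring-bond digits).
    """
    if mode == "char":
        return list(smiles)
    if mode == "regex":
        tokens = SMILES_TOKEN_RE.findall(smiles)
        if "".join(tokens) != smiles:
            raise ValueError(f"SMILES not fully tokenizable in regex mode: {smiles!r}")
        return tokens
    raise ValueError(f"unknown tokenizer mode {mode!r}")


def detokenize(tokens: Sequence[str]) -> str:
    return "".join(t for t in tokens if t not in SPECIALS)


@dataclass(frozen=True)
class Vocabulary:
    """Symbol <-> index table shared by encoder and decoder."""

    symbols: tuple[str, ...]
    index: dict[str, int] = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "index", {s: i for i, s in enumerate(self.symbols)})

    @classmethod
    def from_texts(cls, texts: Sequence[str], mode: str = "char") -> "Vocabulary":
        seen: set[str] = set()
        for t in texts:
            seen.update(tokenize(t, mode))
        return cls(symbols=SPECIALS + tuple(sorted(seen)))

    def __len__(self) -> int:
        return len(self.symbols)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        idx = self.index
        try:
            return [idx[t] for t in tokens]
        except KeyError as exc:
            raise UnknownTokenError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.symbols[i] for i in ids]


@runtime_checkable
class SequenceModel(Protocol):
    """Contract every pluggable decoder model satisfies."""

    vocab: Vocabulary
    tokenizer_mode: str

    def next_token_distribution(
        self, source: Sequence[str], prefix: Sequence[str]
    ) -> np.ndarray:
        """Probability vector over the vocabulary (sums to 1), deterministic
        given (source, prefix) and fixed model state."""
        ...


@dataclass(frozen=True)
class BeamCandidate:
    """One completed (or truncated) decode with its accumulated score."""

    tokens: tuple[str, ...]
    text: str
    logprob: float
    beam_position: int
    truncated: bool = False


def _apply_temperature(p: np.ndarray, t: float) -> np.ndarray:
    if t == 1.0:
        return p
    q = np.power(np.clip(p, 1e-300, None), 1.0 / t)
    return q / q.sum(axis=-1, keepdims=True)


def beam_search(
    model: SequenceModel,
    source: str | Sequence[str],
    beam_size: int = 5,
    temperature: float = 1.0,
    max_len: int = 200,
    length_penalty: float = 0.0,
) -> list[BeamCandidate]:
    """Breadth-limited decoding keeping the ``beam_size`` best partials.

    Scores are sums of post-temperature chosen-token log probabilities,
    optionally divided by ``len**length_penalty`` (default 0: no length
    normalization).  Returns up to ``beam_size`` candidates ranked by
    score, ``beam_position`` starting at 1; sequences that never emit the
    end token within ``max_len`` steps come back flagged ``truncated``.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    vocab = model.vocab
    if beam_size > len(vocab):
        raise ValueError(
            f"beam_size {beam_size} exceeds vocabulary size {len(vocab)}"
        )
    src_tokens = (tokenize(source, model.tokenizer_mode)
                  if isinstance(source, str) else list(source))
    eos_id = vocab.index[EOS]

    batch_fn = getattr(model, "next_token_distribution_batch", None)

    live: list[tuple[list[str], float]] = [([], 0.0)]
    finished: list[tuple[list[str], float, bool]] = []
    for _ in range(max_len):
        if not live:
            break
        if batch_fn is not None:
            dists = batch_fn(src_tokens, [h for h, _ in live])
        else:
            dists = np.stack(
                [model.next_token_distribution(src_tokens, h) for h, _ in live]
            )
        dists = _apply_temperature(dists, temperature)
        with np.errstate(divide="ignore"):
            logp = np.log(dists)
        expansions: list[tuple[float, int, int]] = []  # (score, hyp idx, token id)
        for k, (_, score) in enumerate(live):
            top = np.argsort(logp[k])[::-1][:beam_size]
            for tok_id in top:
                expansions.append((score + logp[k, tok_id], k, int(tok_id)))
        expansions.sort(key=lambda e: (-e[0], e[1], e[2]))
        new_live = []
        for score, k, tok_id in expansions[: beam_size]:
            hyp = live[k][0]
            if tok_id == eos_id:
                finished.append((hyp, score, False))
            else:
                new_live.append((hyp + [vocab.symbols[tok_id]], score))
        live = new_live
        if len(finished) >= beam_size:
            break
    if len(finished) < beam_size:  # best-effort unterminated candidates
        for hyp, score in live:
            finished.append((hyp, score, True))

    def final_score(item):
        hyp, score, _ = item
        if length_penalty > 0 and hyp:
            return score / (len(hyp) ** length_penalty)
        return score

    finished.sort(key=lambda it: (-final_score(it), detokenize(it[0])))
    out = []
    for pos, (hyp, score, trunc) in enumerate(finished[:beam_size], start=1):
        out.append(
            BeamCandidate(
                tokens=tuple(hyp),
                text=detokenize(hyp),
                logprob=float(final_score((hyp, score, trunc))),
                beam_position=pos,
                truncated=trunc,
            )
        )
    return out


def greedy_decode(model: SequenceModel, source: str, max_len: int = 200) -> str:
    """Beam size 1 at temperature 1."""
    return beam_search(model, source, beam_size=1, max_len=max_len)[0].text




# ---------------------------------------------------------------------------
# Tiny reference model


@dataclass
class TinyHyperparams:
    """Capacity / optimization knobs for :class:`TinySeq2Seq`.

    The decoder state is built from the ``prev_ctx`` previous target
    tokens, a source window of radius ``window`` centered on the current
    output position (a monotonic-alignment prior), the first/last ``edge``
    source tokens (source identity anchors), a normalized bag-of-tokens
    vector of the whole source and a learned output-position embedding.
    A single-head dot-product attention over all source positions
    (dimensions ``emb``/``att``) supplies the non-monotonic alignment the
    window cannot cover, and its weights feed a gated copy distribution
    (pointer-generator) over the source tokens.
    """

    hidden: int = 160
    prev_ctx: int = 4
    window: int = 5
    edge: int = 4
    max_pos: int = 48
    emb: int = 32        # attention token/position embedding width
    att: int = 48        # attention key/value width
    max_src_len: int = 120
    lr: float = 3e-3
    epochs: int = 12
    batch_size: int = 256
    tokenizer_mode: str = "char"


class TinySeq2Seq:
    """Single-hidden-layer neural transducer with one attention head,
    trained by Adam on cross-entropy.

    Satisfies the :class:`SequenceModel` contract.  All randomness
    (initialization, shuffling) comes from the seed given at construction;
    forward passes are deterministic.
    """

    def __init__(self, vocab: Vocabulary, hp: TinyHyperparams, seed: int = 0):
        self.vocab = vocab
        self.hp = hp
        self.tokenizer_mode = hp.tokenizer_mode
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        V, H, de, da = len(vocab), hp.hidden, hp.emb, hp.att
        f32 = np.float32
        self.n_slots = hp.prev_ctx + 2 * hp.window + 1 + 2 * hp.edge
        scale = 1.0 / np.sqrt(self.n_slots + 2)
        self.E = rng.normal(0, scale, size=(self.n_slots, V, H)).astype(f32)
        self.Wbag = rng.normal(0, scale, size=(V, H)).astype(f32)
        self.Wpos = rng.normal(0, scale, size=(hp.max_pos, H)).astype(f32)
        self.Wdot = rng.normal(0, scale, size=(8, H)).astype(f32)
        self.Wfrag = rng.normal(0, scale, size=(hp.max_pos, H)).astype(f32)
        self.b1 = np.zeros(H, dtype=f32)
        self.Eatt = rng.normal(0, 0.5, size=(V, de)).astype(f32)
        self.Psrc = rng.normal(0, 0.5, size=(hp.max_src_len, de)).astype(f32)
        self.Wk = rng.normal(0, 1.0 / np.sqrt(de), size=(de, da)).astype(f32)
        self.Wv = rng.normal(0, 1.0 / np.sqrt(de), size=(de, da)).astype(f32)
        self.Wq = rng.normal(0, 1.0 / np.sqrt(H), size=(H, da)).astype(f32)
        self.Wc = rng.normal(0, 1.0 / np.sqrt(da), size=(da, H)).astype(f32)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(H), size=(H, V)).astype(f32)
        self.b2 = np.zeros(V, dtype=f32)
        self.wg = np.zeros(H, dtype=f32)   # copy-gate weights
        self.bg = np.zeros(1, dtype=f32)
        self.history: list[float] = []

    @property
    def _params(self):
        return [self.E, self.Wbag, self.Wpos, self.Wdot, self.Wfrag, self.b1,
                self.Eatt, self.Psrc,
                self.Wk, self.Wv, self.Wq, self.Wc, self.W2, self.b2,
                self.wg, self.bg]

    # -- feature construction ------------------------------------------------

    def _slot_ids(self, src_ids: Sequence[int], prefix_ids: Sequence[int]) -> np.ndarray:
        hp = self.hp
        pad = self.vocab.index[PAD]
        bos = self.vocab.index[BOS]
        i = len(prefix_ids)
        slots = []
        for k in range(hp.prev_ctx):  # previous target tokens, most recent last
            j = i - hp.prev_ctx + k
            slots.append(prefix_ids[j] if j >= 0 else bos)
        for off in range(-hp.window, hp.window + 1):
            j = i + off
            slots.append(src_ids[j] if 0 <= j < len(src_ids) else pad)
        n = len(src_ids)
        for j in range(hp.edge):  # leading/trailing tokens: identity anchors
            slots.append(src_ids[j] if j < n else pad)
        for j in range(n - hp.edge, n):
            slots.append(src_ids[j] if 0 <= j < n else pad)
        return np.asarray(slots, dtype=np.int64)

    def _pos_feats(self, prefix_ids: Sequence[int]) -> tuple[int, int, int]:
        """(output position, fragments completed, position within current
        fragment) — decoder state the token slots cannot carry."""
        cap = self.hp.max_pos - 1
        i = len(prefix_ids)
        dot = self.vocab.index.get(".", -1)
        ndots = 0
        last = -1
        for j, t in enumerate(prefix_ids):
            if t == dot:
                ndots += 1
                last = j
        return (min(i, cap), min(ndots, 7), min(i - last - 1, cap))

    def _bag(self, src_ids: Sequence[int]) -> np.ndarray:
        v = np.zeros(len(self.vocab), dtype=np.float32)
        for i in src_ids:
            v[i] += 1.0
        n = v.sum()
        return v / n if n else v

    def _encode_source(self, src_ids: np.ndarray):
        """Keys and values for attention; src_ids: (B, L) padded with PAD."""
        L = src_ids.shape[1]
        F = self.Eatt[src_ids] + self.Psrc[:L]          # (B, L, de)
        return F, F @ self.Wk, F @ self.Wv              # F, K, V

    def _forward(self, slot_ids, bags, pos3, src_ids):
        # slot_ids (B,S); bags (B,V); pos3 (B,3); src_ids (B,L) PAD-padded
        pad = self.vocab.index[PAD]
        a1 = self.E[np.arange(self.n_slots), slot_ids].sum(axis=1)
        a1 = (a1 + bags @ self.Wbag + self.Wpos[pos3[:, 0]]
              + self.Wdot[pos3[:, 1]] + self.Wfrag[pos3[:, 2]] + self.b1)
        F, K, Vv = self._encode_source(src_ids)
        q = a1 @ self.Wq                                        # (B,da)
        scores = (K @ q[:, :, None])[:, :, 0] / np.sqrt(self.hp.att)
        scores = np.where(src_ids == pad, -1e30, scores)
        scores -= scores.max(axis=1, keepdims=True)
        alpha = np.exp(scores)
        alpha /= alpha.sum(axis=1, keepdims=True)               # (B,L)
        ctx = (alpha[:, None, :] @ Vv)[:, 0, :]                 # (B,da)
        h = np.tanh(a1 + ctx @ self.Wc)                         # (B,H)
        logits = h @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        pgen = np.exp(logits)
        pgen /= pgen.sum(axis=1, keepdims=True)
        # pointer component: project attention weights onto source tokens
        B = len(h)
        pcopy = np.zeros_like(pgen)
        np.add.at(pcopy, (np.arange(B)[:, None], src_ids), alpha)
        g = 1.0 / (1.0 + np.exp(-(h @ self.wg + self.bg[0])))   # (B,)
        p = (1.0 - g)[:, None] * pgen + g[:, None] * pcopy
        cache = (a1, F, K, Vv, q, alpha, ctx, h, pgen, pcopy, g)
        return p, cache

    # -- SequenceModel contract ---------------------------------------------

    def next_token_distribution(self, source, prefix) -> np.ndarray:
        return self.next_token_distribution_batch(source, [prefix])[0]

    def next_token_distribution_batch(self, source, prefixes) -> np.ndarray:
        enc = self.vocab.index
        unk = enc[UNK]
        src_ids = [enc.get(t, unk) for t in source][: self.hp.max_src_len]
        bag = self._bag(src_ids)
        slot_ids = np.stack(
            [self._slot_ids(src_ids, [enc.get(t, unk) for t in p]) for p in prefixes]
        )
        B = len(prefixes)
        bags = np.broadcast_to(bag, (B, len(self.vocab)))
        pfx_ids = [[enc.get(t, unk) for t in p] for p in prefixes]
        pos3 = np.asarray([self._pos_feats(p) for p in pfx_ids], dtype=np.int64)
        src = np.broadcast_to(np.asarray(src_ids, dtype=np.int64), (B, len(src_ids)))
        p, _ = self._forward(slot_ids, bags, pos3, src)
        return p

    # -- training ------------------------------------------------------------

    def _build_examples(self, pairs):
        enc = self.vocab.index
        unk, eos, pad = enc[UNK], enc[EOS], enc[PAD]
        slot_rows, bag_rows, pos_rows, targets, src_ref = [], [], [], [], []
        sources = []
        for src, tgt in pairs:
            src_ids = [enc.get(t, unk) for t in tokenize(src, self.tokenizer_mode)]
            src_ids = src_ids[: self.hp.max_src_len]
            tgt_ids = [enc.get(t, unk) for t in tokenize(tgt, self.tokenizer_mode)]
            tgt_ids.append(eos)
            bag = self._bag(src_ids)
            k = len(sources)
            sources.append(src_ids)
            for i, y in enumerate(tgt_ids):
                slot_rows.append(self._slot_ids(src_ids, tgt_ids[:i]))
                bag_rows.append(bag)
                pos_rows.append(self._pos_feats(tgt_ids[:i]))
                targets.append(y)
                src_ref.append(k)
        lmax = max(len(s) for s in sources)
        src_mat = np.full((len(sources), lmax), pad, dtype=np.int64)
        for k, s in enumerate(sources):
            src_mat[k, : len(s)] = s
        return (np.stack(slot_rows), np.stack(bag_rows),
                np.asarray(pos_rows, dtype=np.int64),
                np.asarray(targets, dtype=np.int64),
                np.asarray(src_ref, dtype=np.int64), src_mat)

    def fit(self, pairs: Sequence[tuple[str, str]]) -> "TinySeq2Seq":
        """Train on (source, target) string pairs; mean loss per epoch is
        recorded in ``self.history``."""
        if not pairs:
            raise ValueError("empty training set")
        hp = self.hp
        pad = self.vocab.index[PAD]
        slots, bags, poss, ys, src_ref, src_mat = self._build_examples(pairs)
        n = len(ys)
        rng = np.random.default_rng(self.seed + 1)
        params = self._params
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        ar = np.arange(self.n_slots)
        sq = np.sqrt(hp.att)
        V = len(self.vocab)
        for _ in range(hp.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, hp.batch_size):
                idx = order[start: start + hp.batch_size]
                sb, bb, pb, yb = slots[idx], bags[idx], poss[idx], ys[idx]
                src_ids = src_mat[src_ref[idx]]
                p, cache = self._forward(sb, bb, pb, src_ids)
                a1, F, K, Vv, q, alpha, ctx, h, pgen, pcopy, g = cache
                B = len(yb)
                arB = np.arange(B)
                pf_y = np.clip(p[arB, yb], 1e-9, None)
                total += -np.log(pf_y).sum()
                # backward through the gated mixture
                c = -1.0 / (B * pf_y)                     # dL/dp_final at y
                s = c * (1.0 - g) * pgen[arB, yb]
                dlogits = -s[:, None] * pgen
                dlogits[arB, yb] += s
                dg = c * (pcopy[arB, yb] - pgen[arB, yb])
                dgin = dg * g * (1.0 - g)
                dW2 = h.T @ dlogits
                db2 = dlogits.sum(axis=0)
                dwg = h.T @ dgin
                dbg = np.asarray([dgin.sum()], dtype=np.float32)
                dh = dlogits @ self.W2.T + dgin[:, None] * self.wg
                dpre = dh * (1.0 - h * h)
                da1 = dpre.copy()
                dctx = dpre @ self.Wc.T
                dWc = ctx.T @ dpre
                dalpha = (Vv @ dctx[:, :, None])[:, :, 0]
                dalpha += (c * g)[:, None] * (src_ids == yb[:, None])
                dVv = alpha[:, :, None] * dctx[:, None, :]
                dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
                dq = (dscores[:, None, :] @ K)[:, 0, :] / sq
                dK = dscores[:, :, None] * q[:, None, :] / sq
                dWq = a1.T @ dq
                da1 += dq @ self.Wq.T
                dF = dK @ self.Wk.T + dVv @ self.Wv.T
                de, da = self.hp.emb, self.hp.att
                Ff = F.reshape(-1, de)
                dWk = Ff.T @ dK.reshape(-1, da)
                dWv = Ff.T @ dVv.reshape(-1, da)
                # scatter-adds done as one-hot matmuls (BLAS beats np.add.at)
                L = src_ids.shape[1]
                src_onehot = np.zeros((B * L, V), dtype=np.float32)
                src_onehot[np.arange(B * L), src_ids.ravel()] = 1.0
                dEatt = src_onehot.T @ dF.reshape(-1, de)
                dPsrc = np.zeros_like(self.Psrc)
                dPsrc[:L] = dF.sum(axis=0)
                slot_onehot = np.zeros((B, self.n_slots * V), dtype=np.float32)
                slot_onehot[np.repeat(np.arange(B), self.n_slots),
                            (ar * V + sb).ravel()] = 1.0
                dE = (slot_onehot.T @ da1).reshape(self.n_slots, V, -1)
                pos_onehot = np.zeros((B, self.hp.max_pos), dtype=np.float32)
                pos_onehot[arB, pb[:, 0]] = 1.0
                dWpos = pos_onehot.T @ da1
                dot_onehot = np.zeros((B, 8), dtype=np.float32)
                dot_onehot[arB, pb[:, 1]] = 1.0
                dWdot = dot_onehot.T @ da1
                frag_onehot = np.zeros((B, self.hp.max_pos), dtype=np.float32)
                frag_onehot[arB, pb[:, 2]] = 1.0
                dWfrag = frag_onehot.T @ da1
                dWbag = bb.T @ da1
                db1 = da1.sum(axis=0)
                grads = [dE, dWbag, dWpos, dWdot, dWfrag, db1, dEatt, dPsrc,
                         dWk, dWv, dWq, dWc, dW2, db2, dwg, dbg]
                step += 1
                lr_t = hp.lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for pr, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    pr -= lr_t * mi / (np.sqrt(vi) + eps)
            self.history.append(total / n)
        return self

    # -- persistence ----------------------------------------------------------

    _WEIGHTS = ("E", "Wbag", "Wpos", "Wdot", "Wfrag", "b1", "Eatt", "Psrc",
                "Wk", "Wv", "Wq", "Wc", "W2", "b2", "wg", "bg")

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: vocabulary, hyperparameters, weights."""
        meta = {"symbols": list(self.vocab.symbols),
                "hp": self.hp.__dict__, "seed": self.seed,
                "history": self.history}
        arrays = {name: getattr(self, name) for name in self._WEIGHTS}
        np.savez(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TinySeq2Seq":
        p = str(path)
        data = np.load(p if p.endswith(".npz") else p + ".npz", allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(Vocabulary(tuple(meta["symbols"])),
                    TinyHyperparams(**meta["hp"]), seed=meta["seed"])
        for name in cls._WEIGHTS:
            setattr(model, name, data[name])
        model.history = list(meta["history"])
        return model


def train_tiny_model(
    pairs: Sequence,
    hyperparams: TinyHyperparams | None = None,
    seed: int = 0,
    vocab: Vocabulary | None = None,
) -> TinySeq2Seq:
    """Build a vocabulary from the pairs and fit a :class:`TinySeq2Seq`.

    ``pairs`` may be (source, target) tuples or objects with ``source`` /
    ``target`` attributes (e.g. augmented-dataset pairs).
    """
    hp = hyperparams or TinyHyperparams()
    tuples = [(p.source, p.target) if hasattr(p, "source") else tuple(p)
              for p in pairs]
    if not tuples:
        raise ValueError("empty training set")
    if vocab is None:
        texts = [s for s, _ in tuples] + [t for _, t in tuples]
        vocab = Vocabulary.from_texts(texts, hp.tokenizer_mode)
    model = TinySeq2Seq(vocab, hp, seed=seed)
    model.fit(tuples)
    return model
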