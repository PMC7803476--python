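"""Neural sequence labeler for family-member and observation entities.

The main architecture is an attention-based BiLSTM-CRF: token embeddings
(optionally concatenated with an external-annotation feature channel) pass
through dropout, a bidirectional LSTM, multi-head self-attention with a
residual connection and layer normalization, a linear projection to
emission scores, and a linear-chain CRF decoded with Viterbi.  A simple
linear-softmax classifier over the embeddings serves as the baseline
architecture.  An optional entity-discovery head adds a per-token binary
"is this token part of any entity" objective whose loss is linearly
combined with the tagging loss.

Tags follow the BIO scheme over two entity classes: observations (Obs) and
patient family members (PFM).  When the wordpiece tokenizer is used, a
reconstruction step promotes partially tagged words to whole-word entities
before spans are emitted.

Training uses Adam with early stopping on validation span F1; each epoch
draws a fixed number of random batches from the training partition, and
static embeddings may be fine-tuned for the first few epochs and then
frozen.  All randomness flows from the config seed, so runs are exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.model_selection import KFold

from famhx.autodiff import Adam, Tensor, bce_with_logits, concat
from famhx.docmodel import Document, FamilyMemberMention, ObservationMention, Sentence, Token
from famhx.kinship import default_lexicon, normalize_mention
from famhx.observation import DiseaseDictionary, annotate_dictionary
from famhx.preprocess import (
    TAGSET,
    WordpieceVocab,
    bio_to_spans,
    spans_to_bio,
    split_sentences,
    tokenize_subwords,
    tokenize_words,
)

TAG2ID = {tag: i for i, tag in enumerate(TAGSET)}
UNK = "<unk>"


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the published training setup."""

    embed_dim: int = 200
    hidden: int = 256
    heads: int = 2
    dropout: float = 0.5
    lr: float = 0.001
    batch: int = 32
    epochs: int = 100
    iters_per_epoch: int = 100
    patience: int = 5
    embed_train_epochs: int = 2
    use_crf: bool = True
    use_ed_head: bool = False
    ed_weight: float = 0.5
    use_external_features: bool = False
    arch: str = "bilstm_attn"  # "bilstm_attn" | "linear"
    tokenizer: str = "word"  # "word" | "subword"
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("bilstm_attn", "linear"):
            raise ValueError(f"unknown arch: {self.arch!r}")
        if self.use_ed_head and not 0.0 < self.ed_weight < 1.0:
            raise ValueError("ed_weight must lie in (0, 1) when the ED head is on")
        if (2 * self.hidden) % self.heads:
            raise ValueError("2*hidden must be divisible by the number of heads")


@dataclass
class LabeledSentence:
    """One training example: tokens, gold BIO tags, optional features."""

    tokens: list[Token]
    tags: list[str]
    features: Optional[np.ndarray] = None


# --- external-annotation feature channel ----------------------------------


def encode_external_features(
    tokens: Sequence[Token], annotations: Sequence[Tuple[int, int]]
) -> np.ndarray:
    """Per-token 0/1/2 coding of external annotation spans, normalized.

    0 = token not covered by any annotation, 1 = first covered token of an
    annotation, 2 = following covered tokens; normalization divides by 2,
    adding one feature dimension to the embeddings.
    """
    raw = np.zeros(len(tokens), dtype=np.float64)
    for start, end in annotations:
        covered = [i for i, t in enumerate(tokens) if t.start < end and start < t.end]
        for rank, i in enumerate(covered):
            raw[i] = 1.0 if rank == 0 else 2.0
    return raw / 2.0


# --- CRF ------------------------------------------------------------------


def crf_nll(
    emissions: Tensor,
    gold_tags: Sequence[int],
    transitions: Tensor,
    start: Tensor,
    end: Tensor,
) -> Tensor:
    """Negative log-likelihood of a tag path under a linear-chain CRF.

    The partition function is computed with the forward algorithm in log
    space; the result is ``log Z - score(gold path)``, always >= 0 up to
    rounding.
    """
    n = emissions.shape[0]
    tags = np.asarray(gold_tags, dtype=np.intp)
    if n != len(tags):
        raise ValueError("emissions and gold tags must have equal length")
    gold = start[tags[0]] + emissions[np.arange(n), tags].sum() + end[tags[-1]]
    if n > 1:
        gold = gold + transitions[tags[:-1], tags[1:]].sum()
    alpha = start + emissions[0]
    for t in range(1, n):
        alpha = (
            alpha.reshape(-1, 1) + transitions + emissions[t].reshape(1, -1)
        ).logsumexp(axis=0)
    log_z = (alpha + end).logsumexp(axis=0)
    nll = log_z - gold
    if np.isnan(nll.data):
        raise FloatingPointError("CRF loss is NaN")
    return nll


def crf_log_partition(
    emissions: np.ndarray, transitions: np.ndarray, start: np.ndarray, end: np.ndarray
) -> float:
    """log Z as a plain number (used by tests and diagnostics)."""
    return float(
        crf_nll(
            Tensor(emissions), [0] * len(emissions), Tensor(transitions),
            Tensor(start), Tensor(end),
        ).data
        + _path_score(emissions, [0] * len(emissions), transitions, start, end)
    )


def _path_score(emissions, tags, transitions, start, end) -> float:
    score = start[tags[0]] + end[tags[-1]]
    score += sum(emissions[i, t] for i, t in enumerate(tags))
    score += sum(transitions[a, b] for a, b in zip(tags[:-1], tags[1:]))
    return float(score)


def viterbi_decode(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> list[int]:
    """Max-score tag path; ties break toward the lower tag index."""
    n, t = emissions.shape
    if n == 0:
        return []
    delta = start + emissions[0]
    backptr = np.zeros((n, t), dtype=np.intp)
    for i in range(1, n):
        scores = delta[:, None] + transitions + emissions[i][None, :]
        backptr[i] = scores.argmax(axis=0)  # argmax picks the first (lowest) index
        delta = scores[backptr[i], np.arange(t)]
    final = delta + end
    best = int(final.argmax())
    path = [best]
    for i in range(n - 1, 0, -1):
        best = int(backptr[i, best])
        path.append(best)
    return path[::-1]


# --- auxiliary losses -----------------------------------------------------


def ed_loss(token_logits: Tensor, gold_tags: Sequence[int]) -> Tensor:
    """Entity-discovery loss: binary cross-entropy of "token is part of an
    entity" (any non-O tag) against per-token logits."""
    targets = np.asarray([0.0 if t == TAG2ID["O"] else 1.0 for t in gold_tags])
    return bce_with_logits(token_logits, targets)


def total_loss(
    ner: Tensor, ed: Optional[Tensor], alpha: float, ed_enabled: bool
) -> Tensor:
    """Linear combination alpha*ner + (1-alpha)*ed; just ner when the
    entity-discovery head is disabled."""
    if not ed_enabled or ed is None:
        return ner
    return ner * alpha + ed * (1.0 - alpha)


# --- reconstruction -------------------------------------------------------


def reconstruct_entities(tokens: Sequence[Token], tags: Sequence[str]) -> list[str]:
    """Promote partially tagged words to whole-word entities.

    For every word where at least one subword piece carries an entity class,
    all of its pieces receive that class (majority vote across pieces, ties
    to the earliest tagged piece).  B/I prefixes are then rebuilt at the
    word level, yielding valid BIO.  Idempotent, and never shortens an
    entity.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must have equal length")
    groups: dict[int, list[int]] = {}
    for i, tok in enumerate(tokens):
        groups.setdefault(tok.word_index, []).append(i)
    word_class: dict[int, Optional[str]] = {}
    for word, indices in groups.items():
        classes = [tags[i][2:] for i in indices if tags[i] != "O"]
        if not classes:
            word_class[word] = None
            continue
        counts = Counter(classes)
        top = max(counts.values())
        word_class[word] = next(c for c in classes if counts[c] == top)
    out = ["O"] * len(tags)
    prev_word: Optional[int] = None
    for i, tok in enumerate(tokens):
        cls = word_class[tok.word_index]
        if cls is None:
            prev_word = tok.word_index
            continue
        word_initial = tok.word_index != prev_word
        entity_initial = word_initial and (
            prev_word is None or word_class.get(prev_word) != cls
        )
        out[i] = ("B-" if entity_initial else "I-") + cls
        prev_word = tok.word_index
    return out


# --- the model ------------------------------------------------------------


class NERModel:
    """Attention-BiLSTM-CRF (or linear-softmax baseline) with its vocab."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: dict[str, int],
        rng: Optional[np.random.Generator] = None,
        subword_vocab: Optional[WordpieceVocab] = None,
        external_annotator: Optional[DiseaseDictionary] = None,
    ):
        self.config = config
        self.vocab = vocab
        self.subword_vocab = subword_vocab
        self.external_annotator = external_annotator
        rng = rng or np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # parameter bookkeeping ------------------------------------------------

    def _param(self, name: str, shape, rng, scale=None) -> Tensor:
        scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
        t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
        self.params[name] = t
        return t

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        n_tags = len(TAGSET)
        d_in = cfg.embed_dim + (1 if cfg.use_external_features else 0)
        self._param("embed", (len(self.vocab), cfg.embed_dim), rng, scale=0.1)
        if cfg.arch == "bilstm_attn":
            h = cfg.hidden
            for direction in ("fwd", "bwd"):
                self._param(f"lstm_{direction}_wih", (d_in, 4 * h), rng)
                self._param(f"lstm_{direction}_whh", (h, 4 * h), rng)
                self.params[f"lstm_{direction}_b"] = Tensor(
                    np.zeros((1, 4 * h)), requires_grad=True
                )
            d_model = 2 * h
            d_head = d_model // cfg.heads
            for head in range(cfg.heads):
                for mat in ("wq", "wk", "wv"):
                    self._param(f"attn{head}_{mat}", (d_model, d_head), rng)
            self._param("attn_wo", (d_model, d_model), rng)
            self.params["ln_gamma"] = Tensor(np.ones(d_model), requires_grad=True)
            self.params["ln_beta"] = Tensor(np.zeros(d_model), requires_grad=True)
            self._param("proj_w", (d_model, n_tags), rng)
            d_state = d_model
        else:
            self._param("proj_w", (d_in, n_tags), rng)
            d_state = d_in
        self.params["proj_b"] = Tensor(np.zeros(n_tags), requires_grad=True)
        if cfg.use_crf:
            self.params["crf_trans"] = Tensor(
                rng.normal(0.0, 0.1, size=(n_tags, n_tags)), requires_grad=True
            )
            self.params["crf_start"] = Tensor(
                rng.normal(0.0, 0.1, size=n_tags), requires_grad=True
            )
            self.params["crf_end"] = Tensor(
                rng.normal(0.0, 0.1, size=n_tags), requires_grad=True
            )
        if cfg.use_ed_head:
            self._param("ed_w", (d_state, 1), rng)
            self.params["ed_b"] = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # encoding -------------------------------------------------------------

    def token_ids(self, tokens: Sequence[Token]) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.asarray(
            [self.vocab.get(t.surface.lower(), unk) for t in tokens], dtype=np.intp
        )

    def forward(
        self,
        tokens: Sequence[Token],
        features: Optional[np.ndarray] = None,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[Tensor, Optional[Tensor]]:
        """Emission scores (n_tokens x n_tags) and optional entity-discovery
        logits.  Dropout applies only in training mode, so inference is
        deterministic given fixed weights."""
        cfg = self.config
        n = len(tokens)
        if n == 0:
            return Tensor(np.zeros((0, len(TAGSET)))), None
        x = self.params["embed"][self.token_ids(tokens)]
        if cfg.use_external_features:
            if features is None:
                features = np.zeros(n)
            if len(features) != n:
                raise ValueError("feature channel length mismatch")
            x = concat([x, Tensor(np.asarray(features).reshape(n, 1))], axis=1)
        if train and cfg.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an RNG for dropout")
            keep = 1.0 - cfg.dropout
            mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
            x = x * Tensor(mask)

        if cfg.arch == "linear":
            states = x
        else:
            fwd = self._lstm(x, "fwd", reverse=False)
            bwd = self._lstm(x, "bwd", reverse=True)
            h2 = concat([fwd, bwd], axis=1)
            states = self._attention(h2)
        emissions = states @ self.params["proj_w"] + self.params["proj_b"]
        ed_logits = None
        if cfg.use_ed_head:
            ed_logits = (states @ self.params["ed_w"] + self.params["ed_b"]).reshape(n)
        return emissions, ed_logits

    def _lstm(self, x: Tensor, direction: str, reverse: bool) -> Tensor:
        h_size = self.config.hidden
        wih = self.params[f"lstm_{direction}_wih"]
        whh = self.params[f"lstm_{direction}_whh"]
        b = self.params[f"lstm_{direction}_b"]
        n = x.shape[0]
        h = Tensor(np.zeros((1, h_size)))
        c = Tensor(np.zeros((1, h_size)))
        order = range(n - 1, -1, -1) if reverse else range(n)
        outputs: list[Optional[Tensor]] = [None] * n
        for t in order:
            z = x[t : t + 1] @ wih + h @ whh + b
            i_gate = z[:, 0 * h_size : 1 * h_size].sigmoid()
            f_gate = z[:, 1 * h_size : 2 * h_size].sigmoid()
            o_gate = z[:, 2 * h_size : 3 * h_size].sigmoid()
            g = z[:, 3 * h_size : 4 * h_size].tanh()
            c = f_gate * c + i_gate * g
            h = o_gate * c.tanh()
            outputs[t] = h
        return concat([o for o in outputs if o is not None], axis=0)

    def _attention(self, h2: Tensor) -> Tensor:
        cfg = self.config
        d_model = 2 * cfg.hidden
        d_head = d_model // cfg.heads
        heads = []
        for head in range(cfg.heads):
            q = h2 @ self.params[f"attn{head}_wq"]
            k = h2 @ self.params[f"attn{head}_wk"]
            v = h2 @ self.params[f"attn{head}_wv"]
            scores = (q @ k.T) * (1.0 / np.sqrt(d_head))
            heads.append(scores.softmax(axis=1) @ v)
        mixed = concat(heads, axis=1) @ self.params["attn_wo"]
        res = mixed + h2  # residual connection around the attention block
        mu = res.mean(axis=1, keepdims=True)
        var = ((res - mu) ** 2.0).mean(axis=1, keepdims=True)
        normed = (res - mu) * ((var + 1e-6) ** -0.5)
        return normed * self.params["ln_gamma"] + self.params["ln_beta"]

    # losses and decoding ----------------------------------------------------

    def sentence_loss(
        self,
        sent: LabeledSentence,
        train: bool,
        rng: Optional[np.random.Generator],
    ) -> Tensor:
        cfg = self.config
        emissions, ed_logits = self.forward(sent.tokens, sent.features, train, rng)
        tag_ids = [TAG2ID[t] for t in sent.tags]
        if cfg.use_crf:
            ner = crf_nll(
                emissions,
                tag_ids,
                self.params["crf_trans"],
                self.params["crf_start"],
                self.params["crf_end"],
            ) * (1.0 / max(len(tag_ids), 1))
        else:
            log_probs = emissions - emissions.logsumexp(axis=1, keepdims=True)
            ner = -log_probs[np.arange(len(tag_ids)), tag_ids].mean()
        ed = ed_loss(ed_logits, tag_ids) if ed_logits is not None else None
        return total_loss(ner, ed, cfg.ed_weight, cfg.use_ed_head)

    def decode(
        self, tokens: Sequence[Token], features: Optional[np.ndarray] = None
    ) -> list[str]:
        if not tokens:
            return []
        emissions, _ = self.forward(tokens, features, train=False)
        if self.config.use_crf:
            path = viterbi_decode(
                emissions.data,
                self.params["crf_trans"].data,
                self.params["crf_start"].data,
                self.params["crf_end"].data,
            )
        else:
            path = emissions.data.argmax(axis=1).tolist()
        return [TAGSET[i] for i in path]

    # persistence ------------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "vocab": self.vocab,
            "weights": {k: v.data.tolist() for k, v in self.params.items()},
            "subword_vocab": sorted(self.subword_vocab.pieces)
            if self.subword_vocab
            else None,
            "external_terms": sorted(self.external_annotator.terms)
            if self.external_annotator
            else None,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "NERModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        config = ModelConfig(**payload["config"])
        model = cls(
            config,
            payload["vocab"],
            subword_vocab=WordpieceVocab(payload["subword_vocab"])
            if payload.get("subword_vocab")
            else None,
            external_annotator=DiseaseDictionary.from_terms(payload["external_terms"])
            if payload.get("external_terms")
            else None,
        )
        for name, values in payload["weights"].items():
            model.params[name].data = np.asarray(values, dtype=np.float64)
        return model


# --- training -------------------------------------------------------------


def build_vocab(corpus: Sequence[LabeledSentence]) -> dict[str, int]:
    counts = Counter(
        tok.surface.lower() for sent in corpus for tok in sent.tokens
    )
    vocab = {UNK: 0}
    for word, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        vocab[word] = len(vocab)
    return vocab


def span_prf(model: NERModel, data: Sequence[LabeledSentence]) -> dict:
    """Span-level precision/recall/F1 (exact span + class), per class and
    micro-averaged, with wordpiece reconstruction applied when relevant."""
    counts = {cls: [0, 0, 0] for cls in ("Obs", "PFM")}  # tp, fp, fn
    for sent in data:
        pred_tags = model.decode(sent.tokens, sent.features)
        if model.config.tokenizer == "subword":
            pred_tags = reconstruct_entities(sent.tokens, pred_tags)
        pred = set(bio_to_spans(sent.tokens, pred_tags))
        gold = set(bio_to_spans(sent.tokens, sent.tags))
        for cls in counts:
            p = {s for s in pred if s[1] == cls}
            g = {s for s in gold if s[1] == cls}
            counts[cls][0] += len(p & g)
            counts[cls][1] += len(p - g)
            counts[cls][2] += len(g - p)

    def prf(tp, fp, fn):
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return {"precision": precision, "recall": recall, "f1": f1}

    report = {cls: prf(*counts[cls]) for cls in counts}
    totals = [sum(c[i] for c in counts.values()) for i in range(3)]
    report["overall"] = prf(*totals)
    return report


def train_model(
    train_set: Sequence[LabeledSentence],
    val_set: Sequence[LabeledSentence],
    config: ModelConfig,
    seed_offset: int = 0,
    external_annotator: Optional[DiseaseDictionary] = None,
    subword_vocab: Optional[WordpieceVocab] = None,
) -> Tuple[NERModel, list[dict]]:
    """Train one model with early stopping on validation span F1.

    Each epoch runs ``iters_per_epoch`` random batches of ``batch``
    sentences sampled from the training partition; the embedding table is
    trainable for the first ``embed_train_epochs`` epochs and then frozen.
    Returns the best model (by validation F1) and the epoch history.
    """
    if not train_set:
        raise ValueError(
            "training partition is empty; generate a larger corpus or "
            "reduce the number of folds"
        )
    seed = (config.seed + seed_offset) % (2**31)
    rng = np.random.default_rng(seed)
    model = NERModel(
        config,
        build_vocab(train_set),
        rng=rng,
        subword_vocab=subword_vocab,
        external_annotator=external_annotator,
    )
    optimizer = Adam(model.parameters(), lr=config.lr)
    best_f1 = -1.0
    best_weights: Optional[dict[str, np.ndarray]] = None
    bad_epochs = 0
    history: list[dict] = []
    for epoch in range(config.epochs):
        frozen = (
            [model.params["embed"]] if epoch >= config.embed_train_epochs else []
        )
        for _ in range(config.iters_per_epoch):
            idx = rng.integers(0, len(train_set), size=min(config.batch, len(train_set)))
            optimizer.zero_grad()
            losses = [
                model.sentence_loss(train_set[i], train=True, rng=rng)
                for i in idx
                if train_set[i].tokens
            ]
            if not losses:
                continue
            batch_loss = losses[0]
            for loss in losses[1:]:
                batch_loss = batch_loss + loss
            batch_loss = batch_loss * (1.0 / len(losses))
            batch_loss.backward()
            optimizer.step(frozen=frozen)
        metrics = span_prf(model, val_set)
        history.append({"epoch": epoch, **{k: v["f1"] for k, v in metrics.items()}})
        f1 = metrics["overall"]["f1"]
        if f1 > best_f1:
            best_f1 = f1
            best_weights = {k: v.data.copy() for k, v in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best_weights is not None:
        for name, values in best_weights.items():
            model.params[name].data = values
    return model, history


def train_cv(
    corpus: Sequence[LabeledSentence],
    config: ModelConfig,
    external_annotator: Optional[DiseaseDictionary] = None,
    subword_vocab: Optional[WordpieceVocab] = None,
) -> Tuple[list[NERModel], list[dict]]:
    """K-fold cross-validation (5 folds by default); returns the per-fold
    models and their validation metrics."""
    if len(corpus) < config.folds:
        raise ValueError(
            f"corpus of {len(corpus)} sentences cannot be split into "
            f"{config.folds} folds; generate more data"
        )
    splitter = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    models: list[NERModel] = []
    reports: list[dict] = []
    items = list(corpus)
    for fold, (train_idx, val_idx) in enumerate(splitter.split(items)):
        train_set = [items[i] for i in train_idx]
        val_set = [items[i] for i in val_idx]
        model, _history = train_model(
            train_set,
            val_set,
            config,
            seed_offset=fold + 1,
            external_annotator=external_annotator,
            subword_vocab=subword_vocab,
        )
        metrics = span_prf(model, val_set)
        metrics["fold"] = fold
        models.append(model)
        reports.append(metrics)
    return models, reports


# --- corpus labeling and prediction ---------------------------------------


def make_labeled_sentences(
    docs: Sequence[Document],
    dictionary: Optional[DiseaseDictionary] = None,
    config: Optional[ModelConfig] = None,
    subword_vocab: Optional[WordpieceVocab] = None,
) -> list[LabeledSentence]:
    """Derive token-level BIO training data from notes.

    Observation spans come from dictionary matching and family-member spans
    from the kinship lexicon (side modifiers included in the span).  On
    template-generated synthetic notes, where every disease term is in the
    dictionary, this labeling is exact.
    """
    dictionary = dictionary or DiseaseDictionary.default()
    config = config or ModelConfig()
    lexicon = default_lexicon()
    out: list[LabeledSentence] = []
    for doc in docs:
        for sentence in split_sentences(doc):
            if config.tokenizer == "subword":
                vocab = subword_vocab or WordpieceVocab.default()
                tokens = tokenize_subwords(sentence, vocab)
            else:
                tokens = tokenize_words(sentence)
            entities: list[Tuple[Tuple[int, int], str]] = []
            obs_spans = []
            for obs in annotate_dictionary(sentence, dictionary):
                entities.append(((obs.span[1], obs.span[2]), "Obs"))
                obs_spans.append((obs.span[1], obs.span[2]))
            entities.extend(
                (span, "PFM") for span in _relative_spans(sentence, lexicon)
            )
            tags = spans_to_bio(tokens, entities)
            features = None
            if config.use_external_features:
                features = encode_external_features(tokens, obs_spans)
            out.append(LabeledSentence(tokens=tokens, tags=tags, features=features))
    return out


def _relative_spans(sentence: Sentence, lexicon) -> list[Tuple[int, int]]:
    tokens = [
        t for t in tokenize_words(sentence) if any(c.isalnum() for c in t.surface)
    ]
    words = [t.surface.lower() for t in tokens]
    spans = []
    i = 0
    while i < len(words):
        start_i = i
        j = i
        if words[j] in ("maternal", "paternal") and j + 1 < len(words):
            j += 1
        matched_end = None
        for width in range(min(lexicon.max_words, len(words) - j), 0, -1):
            entry = lexicon.lookup(" ".join(words[j : j + width]))
            if entry is not None and entry[0] != "Partner":
                matched_end = j + width
                break
        if matched_end is None:
            i += 1
            continue
        # start_i == j unless a side modifier was absorbed into the span
        spans.append((tokens[start_i].start, tokens[matched_end - 1].end))
        i = matched_end
    return spans


def predict_entities(
    doc: Document, model: NERModel
) -> Tuple[list[FamilyMemberMention], list[ObservationMention]]:
    """End-to-end entity prediction for one note: tokenize, decode,
    reconstruct, convert spans to mention objects."""
    members: list[FamilyMemberMention] = []
    observations: list[ObservationMention] = []
    for sentence in split_sentences(doc):
        for span, cls, text in _predict_sentence_spans(model, sentence):
            if cls == "Obs":
                observations.append(
                    ObservationMention(
                        text=text.lower(), span=(sentence.index, span[0], span[1])
                    )
                )
            else:
                normalized = normalize_mention(text.lower())
                if normalized is not None:
                    relation, side = normalized
                    members.append(
                        FamilyMemberMention(
                            relation=relation,
                            side=side,
                            span=(sentence.index, span[0], span[1]),
                        )
                    )
    return members, observations


def predict_observations(
    model: NERModel, sentences: Sequence[Sentence]
) -> list[list[ObservationMention]]:
    """Per-sentence observation mentions (the hybrid pipeline's DL module)."""
    out = []
    for sentence in sentences:
        obs = [
            ObservationMention(text=text.lower(), span=(sentence.index, span[0], span[1]))
            for span, cls, text in _predict_sentence_spans(model, sentence)
            if cls == "Obs"
        ]
        out.append(obs)
    return out


def _predict_sentence_spans(model: NERModel, sentence: Sentence):
    if model.config.tokenizer == "subword":
        vocab = model.subword_vocab or WordpieceVocab.default()
        tokens = tokenize_subwords(sentence, vocab)
    else:
        tokens = tokenize_words(sentence)
    if not tokens:
        return []
    features = None
    if model.config.use_external_features:
        annotator = model.external_annotator or DiseaseDictionary.default()
        spans = [
            (o.span[1], o.span[2]) for o in annotate_dictionary(sentence, annotator)
        ]
        features = encode_external_features(tokens, spans)
    tags = model.decode(tokens, features)
    if model.config.tokenizer == "subword":
        tags = reconstruct_entities(tokens, tags)
    results = []
    for (start, end), cls in bio_to_spans(tokens, tags):
        results.append(((start, end), cls, sentence.text[start:end]))
    return results
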