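"""Synthetic labeled binary corpora with planted informative features.

Emulates the structure of a class-imbalanced social-media document-term
matrix: each document has a binary label (default positive fraction 0.831,
matching a roughly 81/19 depressive / non-depressive imbalance), a small
planted subset of columns carries the class signal (present with
probability ``p_pos`` in class 1 and ``p_neg`` in class 0), and the
remaining columns are class-independent background noise at rate
``q_background``.  The generator returns the ground-truth informative mask
so feature-selection quality is directly measurable, and can render each
row as a pseudo-text whose tokens survive the default preprocessing, so the
full corpus -> DTM pipeline is exercisable without any real data.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .text_pipeline import DocumentTermMatrix, LabeledCorpus

__all__ = ["SynthSpec", "make_vocabulary", "generate_dtm", "generate_corpus"]


@dataclass(frozen=True)
class SynthSpec:
    n_docs: int = 400
    vocab_size: int = 80
    n_informative: int = 10
    positive_fraction: float = 0.831  # ~ 3937 / 4737
    p_pos: float = 0.9
    p_neg: float = 0.1
    q_background: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 2 or self.vocab_size < 1:
            raise ValueError("need n_docs >= 2 and vocab_size >= 1")
        if not 0 <= self.n_informative <= self.vocab_size:
            raise ValueError("n_informative must lie in [0, vocab_size]")
        for name in ("positive_fraction", "p_pos", "p_neg", "q_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.p_neg < self.p_pos:
            raise ValueError("need p_neg < p_pos so the planted signal exists")


def make_vocabulary(size: int) -> list[str]:
    """Fixed-width alphabetic pseudo-words, lexicographically ordered.

    Tokens are >= 4 lowercase letters with a 'v' prefix, so they pass the
    default preprocessing (alphabetic, length >= 2, no stopword collision)
    and their lexicographic order equals their index order.
    """
    letters = string.ascii_lowercase
    width = max(3, int(np.ceil(np.log(max(size, 2)) / np.log(26))))
    vocab = []
    for i in range(size):
        digits = []
        x = i
        for _ in range(width):
            x, r = divmod(x, 26)
            digits.append(letters[r])
        vocab.append("v" + "".join(reversed(digits)))
    return vocab


def generate_dtm(spec: SynthSpec) -> tuple[DocumentTermMatrix, np.ndarray]:
    """Sample one planted-feature DTM; returns (dtm, truth mask).

    Class counts are the rounded split of n_docs by positive_fraction;
    labels are shuffled.  The informative columns are a random subset of the
    vocabulary; the boolean truth mask marks them.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_docs * spec.positive_fraction))
    n_pos = min(max(n_pos, 1), spec.n_docs - 1)
    labels = np.zeros(spec.n_docs, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    truth = np.zeros(spec.vocab_size, dtype=bool)
    truth[rng.choice(spec.vocab_size, size=spec.n_informative, replace=False)] = True

    p = np.tile(spec.q_background, (spec.n_docs, spec.vocab_size))
    p[:, truth] = np.where(labels[:, None] == 1, spec.p_pos, spec.p_neg)
    matrix = (rng.random((spec.n_docs, spec.vocab_size)) < p).astype(np.uint8)

    dtm = DocumentTermMatrix(matrix, make_vocabulary(spec.vocab_size), labels)
    return dtm, truth


def generate_corpus(spec: SynthSpec, words_per_doc: int | None = None) -> LabeledCorpus:
    """Render the synthetic DTM rows as pseudo-texts.

    Each document contains exactly the vocabulary tokens present in its row
    (binary presence is preserved); if ``words_per_doc`` exceeds a row's
    token count the tokens are repeated cyclically to pad the text.
    Building a DTM from this corpus with min_df=1 recovers the planted
    matrix up to column ordering.
    """
    dtm, _ = generate_dtm(spec)
    vocab = np.array(dtm.vocabulary)
    texts = []
    for row in dtm.matrix:
        tokens = vocab[row.astype(bool)].tolist()
        if words_per_doc is not None and tokens:
            reps = -(-words_per_doc // len(tokens))
            tokens = (tokens * reps)[:words_per_doc]
        texts.append(" ".join(tokens))
    return LabeledCorpus(texts, dtm.labels.copy())
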