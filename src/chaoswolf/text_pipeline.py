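"""Corpus ingestion: preprocessing, binary document-term matrix, splitting.

Documents are lowercased, stripped of URLs / user handles / digits /
punctuation, whitespace-tokenized, filtered against a bundled English
stopword list and a minimum token length, and tabulated into a binary
presence matrix (entry 1 iff the term occurs in the document).  The
vocabulary is lexicographically ordered and terms must appear in at least
``min_df`` documents.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import train_test_split

__all__ = [
    "ENGLISH_STOPWORDS",
    "LabeledCorpus",
    "DocumentTermMatrix",
    "preprocess",
    "build_dtm",
    "split",
    "read_corpus",
    "write_corpus",
    "write_dtm",
    "read_dtm",
]

# The classic English stopword list used throughout IR/text-mining work.
ENGLISH_STOPWORDS = frozenset("""
a about above after again against all am an and any are aren't as at be
because been before being below between both but by can't cannot could
couldn't did didn't do does doesn't doing don't down during each few for
from further had hadn't has hasn't have haven't having he he'd he'll he's
her here here's hers herself him himself his how how's i i'd i'll i'm i've
if in into is isn't it it's its itself let's me more most mustn't my myself
no nor not of off on once only or other ought our ours ourselves out over
own same shan't she she'd she'll she's should shouldn't so some such than
that that's the their theirs them themselves then there there's these they
they'd they'll they're they've this those through to too under until up
very was wasn't we we'd we'll we're we've were weren't what what's when
when's where where's which while who who's whom why why's with won't would
wouldn't you you'd you'll you're you've your yours yourself yourselves
""".split())

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_HANDLE_RE = re.compile(r"@\w+")
_NON_ALPHA_RE = re.compile(r"[^a-z']+")


def preprocess(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    min_len: int = 2,
) -> list[str]:
    """Deterministic tokenization of one document.

    lowercase -> strip URLs, @handles, digits and punctuation -> whitespace
    tokenize -> drop stopwords -> drop tokens shorter than ``min_len``.
    """
    if stopwords is None:
        stopwords = ENGLISH_STOPWORDS
    s = text.lower()
    s = _URL_RE.sub(" ", s)
    s = _HANDLE_RE.sub(" ", s)
    s = _NON_ALPHA_RE.sub(" ", s)
    tokens = []
    for tok in s.split():
        tok = tok.strip("'")
        if len(tok) >= min_len and tok not in stopwords:
            tokens.append(tok)
    return tokens


@dataclass
class LabeledCorpus:
    """Ordered labeled documents; label 1 = depressive, 0 = non-depressive."""

    texts: list[str]
    labels: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.ids:
            self.ids = list(range(len(self.texts)))
        if len(self.texts) != len(self.labels) or len(self.texts) != len(self.ids):
            raise ValueError("texts, labels and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("document ids must be unique")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.texts)


@dataclass
class DocumentTermMatrix:
    """Binary documents x terms presence matrix with labels."""

    matrix: np.ndarray  # shape (n_docs, n_terms), entries in {0, 1}
    vocabulary: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.shape != (len(self.labels), len(self.vocabulary)):
            raise ValueError("matrix shape must be (len(labels), len(vocabulary))")

    @property
    def n_docs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]


def build_dtm(
    corpus: LabeledCorpus,
    min_df: int = 2,
    stopwords: frozenset[str] | None = None,
    min_len: int = 2,
) -> DocumentTermMatrix:
    """Tabulate the corpus into a binary presence matrix.

    The vocabulary is the lexicographically sorted set of tokens occurring
    in at least ``min_df`` documents.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    vectorizer = CountVectorizer(
        analyzer=lambda doc: preprocess(doc, stopwords=stopwords, min_len=min_len),
        min_df=min_df,
        binary=True,
    )
    try:
        matrix = vectorizer.fit_transform(corpus.texts)
    except ValueError as exc:
        raise ValueError(
            f"no term appears in at least min_df={min_df} documents; lower min_df"
        ) from exc
    vocab = vectorizer.get_feature_names_out().tolist()
    return DocumentTermMatrix(matrix.toarray(), vocab, corpus.labels.copy())


def split(
    dtm: DocumentTermMatrix,
    train_fraction: float = 0.8,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[DocumentTermMatrix, DocumentTermMatrix]:
    """Disjoint, exhaustive train/test row partition (stratified by default)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    idx = np.arange(dtm.n_docs)
    strat = dtm.labels if stratified else None
    try:
        train_idx, test_idx = train_test_split(
            idx, train_size=train_fraction, stratify=strat, random_state=seed
        )
    except ValueError as exc:
        raise ValueError(f"stratified split failed: {exc}") from exc
    mk = lambda rows: DocumentTermMatrix(
        dtm.matrix[rows], list(dtm.vocabulary), dtm.labels[rows]
    )
    return mk(np.sort(train_idx)), mk(np.sort(test_idx))


_LABEL_MAP = {
    "0": 0, "1": 1,
    "non-depressive": 0, "nondepressive": 0, "non_depressive": 0,
    "depressive": 1, "depressed": 1,
}


def read_corpus(path: str | Path) -> LabeledCorpus:
    """Read a delimited corpus with ``text`` and ``label`` columns.

    Labels may be 0/1 or the strings "depressive" / "non-depressive".
    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"text", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    labels = []
    bad = []
    for i, raw in enumerate(df["label"]):
        key = str(raw).strip().lower()
        if key in _LABEL_MAP:
            labels.append(_LABEL_MAP[key])
        else:
            bad.append((i + 2, raw))  # +2: header line + 1-based indexing
    if bad:
        detail = ", ".join(f"line {ln}: {val!r}" for ln, val in bad[:10])
        raise ValueError(f"{path}: unknown label value(s) — {detail}")
    ids = df["id"].tolist() if "id" in df.columns else list(range(len(df)))
    return LabeledCorpus(df["text"].tolist(), np.array(labels), ids)


def write_corpus(corpus: LabeledCorpus, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        {"id": corpus.ids, "text": corpus.texts, "label": corpus.labels}
    ).to_csv(path, sep=sep, index=False)


def write_dtm(
    dtm: DocumentTermMatrix,
    out_dir: str | Path,
    fmt: str = "tsv",
    provenance: dict | None = None,
) -> Path:
    """Persist a DTM under ``out_dir``.

    ``fmt='tsv'`` writes a dense TSV with a vocabulary header and a leading
    ``label`` column; ``fmt='mtx'`` writes a sparse MatrixMarket file plus
    ``vocabulary.txt`` and ``labels.txt`` sidecars.  A ``provenance.json``
    records options and counts in either case.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df = pd.DataFrame(dtm.matrix, columns=dtm.vocabulary)
        df.insert(0, "label", dtm.labels)
        df.to_csv(out_dir / "dtm.tsv", sep="\t", index=False)
    elif fmt == "mtx":
        mmwrite(out_dir / "dtm.mtx", csr_matrix(dtm.matrix))
        (out_dir / "vocabulary.txt").write_text("\n".join(dtm.vocabulary) + "\n")
        (out_dir / "labels.txt").write_text("\n".join(map(str, dtm.labels)) + "\n")
    else:
        raise ValueError(f"unknown DTM format {fmt!r}")
    meta = {"format": fmt, "n_docs": dtm.n_docs, "n_terms": dtm.n_terms}
    if provenance:
        meta.update(provenance)
    (out_dir / "provenance.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out_dir


def read_dtm(out_dir: str | Path, fmt: str | None = None) -> DocumentTermMatrix:
    """Read a DTM previously written by :func:`write_dtm` (round-trip identity)."""
    out_dir = Path(out_dir)
    if fmt is None:
        fmt = "tsv" if (out_dir / "dtm.tsv").exists() else "mtx"
    if fmt == "tsv":
        df = pd.read_csv(out_dir / "dtm.tsv", sep="\t")
        labels = df.pop("label").to_numpy()
        return DocumentTermMatrix(df.to_numpy(), df.columns.tolist(), labels)
    matrix = np.asarray(mmread(out_dir / "dtm.mtx").todense())
    vocab = (out_dir / "vocabulary.txt").read_text().splitlines()
    labels = np.array([int(x) for x in (out_dir / "labels.txt").read_text().split()])
    return DocumentTermMatrix(matrix, vocab, labels)
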