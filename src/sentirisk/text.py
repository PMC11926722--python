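"""Lexicon-based sentiment pipeline: raw documents to weekly count panels.

The chain is: clean the raw text (URLs, handles, hashtag markers, HTML,
digits, punctuation out; lowercase; whitespace collapsed), tokenize and
drop stopwords, label each document negative / positive / neutral by a
majority vote of lexicon matches, then aggregate labelled documents into
the region x week :class:`~sentirisk.panel.SentimentPanel` of negative
(``ntw``) and total (``ttw``) counts.

The scorer is deliberately pluggable: the statistics downstream only see
per-document labels, so output from any external classifier (e.g. a
trained sentiment model) can be injected as pre-labelled documents.
Lexicon terms ending in ``*`` match as word-stem prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as dt
import json
import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import SentimentPanel, week_index
from .regions import RegionGraph

__all__ = [
    "Document",
    "Lexicon",
    "clean_text",
    "tokenize_and_filter",
    "score_sentiment",
    "aggregate_panel",
    "LexiconSentimentClassifier",
    "default_lexicon",
]

logger = logging.getLogger(__name__)

NEGATIVE, POSITIVE, NEUTRAL = "negative", "positive", "neutral"


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    timestamp: dt.datetime
    region: str
    label: str | None = None


@dataclass(frozen=True)
class Lexicon:
    """Three pairwise-disjoint lowercase term sets.

    A term ending in ``*`` is a stem and matches any token having it as
    a prefix (after the ``*`` is stripped).
    """

    negative_terms: frozenset[str]
    positive_terms: frozenset[str]
    stopwords: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for name in ("negative_terms", "positive_terms", "stopwords"):
            terms = frozenset(getattr(self, name))
            for t in terms:
                if t != t.lower() or any(ch.isspace() for ch in t):
                    raise ValueError(
                        f"lexicon entry {t!r} must be lowercase, no whitespace"
                    )
            object.__setattr__(self, name, terms)
        pairs = [
            (self.negative_terms, self.positive_terms),
            (self.negative_terms, self.stopwords),
            (self.positive_terms, self.stopwords),
        ]
        if any(a & b for a, b in pairs):
            raise ValueError("lexicon term sets must be pairwise disjoint")

    @classmethod
    def from_csv(cls, path) -> "Lexicon":
        """3-column CSV ``term,class`` with class in {negative,positive,stopword}."""
        df = pd.read_csv(path, dtype=str)
        groups: dict[str, set[str]] = {
            "negative": set(), "positive": set(), "stopword": set()
        }
        for term, klass in zip(df["term"], df["class"]):
            if klass not in groups:
                raise ValueError(f"unknown lexicon class {klass!r}")
            groups[klass].add(term)
        return cls(
            frozenset(groups["negative"]),
            frozenset(groups["positive"]),
            frozenset(groups["stopword"]),
        )


# Small transparent German emotion lexicon used as the default scorer.
_DEFAULT_NEGATIVE = (
    "angst", "wut", "trauer", "traurig", "schlecht", "schlimm", "furchtbar",
    "schrecklich", "katastrophe", "verlust", "zerstört", "zerstörung",
    "gefahr", "gefährlich", "panik", "sorge", "sorgen", "verzweifelt",
    "verzweiflung", "hass", "ärger", "ärgerlich", "krise", "leid", "opfer",
    "tot", "tote", "sterben", "kaputt", "elend", "horror", "alptraum",
    "erschöpft", "hilflos", "bedrohung", "notstand", "chaos", "schaden",
    "schmerz", "weinen",
)
_DEFAULT_POSITIVE = (
    "gut", "schön", "toll", "super", "freude", "glücklich", "glück",
    "liebe", "lachen", "großartig", "wunderbar", "herrlich", "dankbar",
    "danke", "hoffnung", "zuversicht", "froh", "begeistert", "spaß",
    "genial", "perfekt", "fantastisch", "erleichtert", "sicher", "ruhig",
    "zufrieden", "optimistisch", "stark", "mutig", "gewonnen",
)
_DEFAULT_STOPWORDS = (
    "der", "die", "das", "ein", "eine", "und", "oder", "aber", "ist",
    "sind", "war", "waren", "ich", "du", "er", "sie", "es", "wir", "ihr",
    "in", "im", "an", "am", "auf", "mit", "von", "zu", "für", "bei",
    "nicht", "kein", "auch", "noch", "schon", "nur", "den", "dem", "des",
)


def default_lexicon() -> Lexicon:
    return Lexicon(
        frozenset(_DEFAULT_NEGATIVE),
        frozenset(_DEFAULT_POSITIVE),
        frozenset(_DEFAULT_STOPWORDS),
    )


_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_HANDLE_RE = re.compile(r"@\w+")
_HTML_RE = re.compile(r"<[^>]*>")
# letter runs (incl. umlauts/ss and other unicode letters); everything
# else -- punctuation, symbols, digits, the bare '#' marker -- separates
_KEEP_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def clean_text(raw: str, drop_hashtag_words: bool = False) -> str:
    """Normalize a raw document to lowercase letter-only tokens.

    Removes URLs, @-handles, HTML tags, digits, punctuation and symbols;
    hashtags lose the ``#`` marker but keep the bare word unless
    ``drop_hashtag_words`` is set.  Whitespace runs collapse to single
    spaces.  Idempotent.
    """
    if not isinstance(raw, str):
        raise TypeError("clean_text expects a string")
    s = _URL_RE.sub(" ", raw)
    s = _HTML_RE.sub(" ", s)
    s = _HANDLE_RE.sub(" ", s)
    if drop_hashtag_words:
        s = re.sub(r"#\w+", " ", s)
    s = s.lower()
    words = _KEEP_RE.findall(s)
    return " ".join(words)


def tokenize_and_filter(cleaned: str, lexicon: Lexicon) -> list[str]:
    """Whitespace tokenization with stopword removal, order preserved."""
    return [tok for tok in cleaned.split() if tok not in lexicon.stopwords]


def _build_matcher(terms: Iterable[str]):
    exact = {t for t in terms if not t.endswith("*")}
    stems = tuple(t[:-1] for t in terms if t.endswith("*") and len(t) > 1)

    def match(token: str) -> bool:
        return token in exact or any(token.startswith(s) for s in stems)

    return match


def score_sentiment(tokens: Sequence[str], lexicon: Lexicon) -> str:
    """Majority label from lexicon matches; ties (incl. 0-0) are neutral."""
    neg = _build_matcher(lexicon.negative_terms)
    pos = _build_matcher(lexicon.positive_terms)
    n_neg = sum(1 for t in tokens if neg(t))
    n_pos = sum(1 for t in tokens if pos(t))
    if n_neg > n_pos:
        return NEGATIVE
    if n_pos > n_neg:
        return POSITIVE
    return NEUTRAL


def aggregate_panel(
    docs: Iterable[Document],
    graph: RegionGraph,
    week_origin: dt.date,
    n_weeks: int,
) -> SentimentPanel:
    """Count labelled documents into the region x week panel.

    ``ttw`` counts all unique in-window documents per cell, ``ntw`` the
    negative-labelled ones.  Duplicate ``doc_id`` values count once
    (first occurrence wins); out-of-window timestamps are skipped with a
    logged count; an unknown region is an error.
    """
    region_index = {r: i for i, r in enumerate(graph.region_ids)}
    ntw = np.zeros((graph.n_regions, n_weeks), np.int64)
    ttw = np.zeros((graph.n_regions, n_weeks), np.int64)
    seen: set[str] = set()
    skipped = 0
    for doc in docs:
        if doc.label is None:
            raise ValueError(f"document {doc.doc_id} carries no label")
        if doc.doc_id in seen:
            continue
        seen.add(doc.doc_id)
        if doc.region not in region_index:
            raise KeyError(f"unknown region {doc.region!r}")
        t = week_index(doc.timestamp, week_origin)
        if not 0 <= t < n_weeks:
            skipped += 1
            continue
        i = region_index[doc.region]
        ttw[i, t] += 1
        if doc.label == NEGATIVE:
            ntw[i, t] += 1
    if skipped:
        logger.warning("aggregate_panel skipped %d out-of-window documents",
                       skipped)
    week_starts = tuple(
        week_origin + dt.timedelta(days=7 * t) for t in range(n_weeks)
    )
    return SentimentPanel(graph.region_ids, week_starts, ntw, ttw)


class LexiconSentimentClassifier(BaseEstimator):
    """Sklearn-style wrapper around the lexicon scorer.

    ``fit`` validates and freezes the lexicon (no learning happens);
    ``predict`` maps raw texts to {negative, positive, neutral}.

    Parameters
    ----------
    lexicon
        A :class:`Lexicon`; None selects the built-in German default.
    drop_hashtag_words
        Drop whole hashtag words instead of only the ``#`` marker.
    """

    def __init__(self, lexicon: Lexicon | None = None,
                 drop_hashtag_words: bool = False):
        self.lexicon = lexicon
        self.drop_hashtag_words = drop_hashtag_words

    def fit(self, X=None, y=None):
        self.lexicon_ = self.lexicon or default_lexicon()
        return self

    def predict(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "lexicon_"):
            self.fit()
        out = []
        for text in X:
            cleaned = clean_text(text, self.drop_hashtag_words)
            tokens = tokenize_and_filter(cleaned, self.lexicon_)
            out.append(score_sentiment(tokens, self.lexicon_))
        return np.asarray(out, dtype=object)

    def label_documents(self, docs: Iterable[Document]) -> list[Document]:
        """Return copies of ``docs`` with labels filled in (existing kept)."""
        if not hasattr(self, "lexicon_"):
            self.fit()
        labelled = []
        for doc in docs:
            if doc.label is not None:
                labelled.append(doc)
                continue
            label = self.predict([doc.text])[0]
            labelled.append(
                Document(doc.doc_id, doc.text, doc.timestamp, doc.region, label)
            )
        return labelled


def read_documents(path) -> list[Document]:
    """Read documents from newline-delimited JSON or CSV.

    Required fields: ``doc_id, text, timestamp, region``; optional
    ``label``.
    """
    path = str(path)
    records: list[dict]
    if path.endswith((".jsonl", ".ndjson", ".json")):
        with open(path) as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    else:
        records = pd.read_csv(path, dtype={"doc_id": str, "region": str}) \
            .to_dict("records")
    docs = []
    for rec in records:
        ts = rec["timestamp"]
        if not isinstance(ts, dt.datetime):
            ts = dt.datetime.fromisoformat(str(ts))
        docs.append(
            Document(
                str(rec["doc_id"]), str(rec["text"]), ts, str(rec["region"]),
                rec.get("label") if rec.get("label") else None,
            )
        )
    return docs
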