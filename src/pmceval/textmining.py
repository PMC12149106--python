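"""Text-feature extraction: segmentation, term ranking, co-occurrence nets.

Mirrors the text-mining stage of quantitative policy content analysis:
policy documents are segmented into terms, stopwords are dropped,
high-frequency terms are ranked, and an undirected weighted term graph
records how often term pairs co-occur within a window (a sentence, the
whole document, or a sliding token window).

Counting convention: a pair counts once per window regardless of how
many times either term repeats inside it.  Weights are therefore
"number of windows containing both terms", the standard convention for
semantic co-occurrence maps.

Segmentation is pluggable.  Three strategies are registered:

``whitespace``
    Split on whitespace; trailing/leading punctuation stripped.  Suits
    Latin-script and pre-tokenized text.
``ngram``
    Overlapping character n-grams (default n=2) over non-space runs —
    a dictionary-free baseline for unsegmented Chinese text.
``dictionary``
    Forward maximum matching against a user-supplied lexicon: at each
    position the longest lexicon word is taken, unmatched characters
    pass through as single tokens.  A transparent, deterministic
    segmenter for Chinese policy prose.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "SENTENCE_DELIMITERS",
    "TokenizedCorpus",
    "TermFrequencyTable",
    "load_default_stopwords",
    "tokenize_corpus",
    "term_frequencies",
    "cooccurrence_network",
    "network_centrality",
    "write_network",
    "register_segmenter",
]

#: Sentence-final punctuation, Chinese and Latin.
SENTENCE_DELIMITERS = "。！？.!?"

_PUNCT = set(string.punctuation) | set("。！？，、；：「」『』（）《》【】“”‘’…—")


# ---------------------------------------------------------------------------
# segmenters
# ---------------------------------------------------------------------------

def _segment_whitespace(sentence: str) -> list[str]:
    tokens = []
    for raw in sentence.split():
        tok = raw.strip("".join(_PUNCT & set(raw)))
        if tok:
            tokens.append(tok)
    return tokens


def _segment_ngram(sentence: str, n: int = 2) -> list[str]:
    tokens: list[str] = []
    for run in sentence.split():
        run = "".join(ch for ch in run if ch not in _PUNCT)
        if not run:
            continue
        if len(run) <= n:
            tokens.append(run)
        else:
            tokens.extend(run[i : i + n] for i in range(len(run) - n + 1))
    return tokens


def _segment_dictionary(sentence: str, lexicon: Iterable[str] = ()) -> list[str]:
    """Greedy forward maximum matching against ``lexicon``."""
    words = set(lexicon)
    if not words:
        raise ValueError("dictionary segmenter requires a non-empty lexicon")
    max_len = max(len(w) for w in words)
    tokens: list[str] = []
    for run in sentence.split():
        i = 0
        while i < len(run):
            if run[i] in _PUNCT:
                i += 1
                continue
            for L in range(min(max_len, len(run) - i), 0, -1):
                cand = run[i : i + L]
                if L == 1 or cand in words:
                    tokens.append(cand)
                    i += L
                    break
    return tokens


_SEGMENTERS: dict[str, Callable[..., list[str]]] = {
    "whitespace": _segment_whitespace,
    "ngram": _segment_ngram,
    "dictionary": _segment_dictionary,
}


def register_segmenter(name: str, fn: Callable[..., list[str]]) -> None:
    """Register a custom segmentation strategy under ``name``."""
    _SEGMENTERS[name] = fn


# ---------------------------------------------------------------------------
# corpus containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenizedCorpus:
    """Segmented documents with sentence structure retained.

    ``sentences`` maps policy_id to a list of sentences, each an ordered
    token list with stopwords already removed.
    """

    sentences: Mapping[str, tuple[tuple[str, ...], ...]]
    segmenter: str
    stopwords: frozenset[str]

    @property
    def documents(self) -> dict[str, list[str]]:
        """Flattened token stream per document."""
        return {
            pid: [t for sent in sents for t in sent]
            for pid, sents in self.sentences.items()
        }

    @property
    def total_tokens(self) -> int:
        return sum(len(toks) for toks in self.documents.values())


@dataclass(frozen=True)
class TermFrequencyTable:
    """Ranked high-frequency terms: (term, count, document frequency)."""

    entries: tuple[tuple[str, int, int], ...]
    total_tokens: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.entries), columns=["term", "count", "document_frequency"]
        )

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")


def load_default_stopwords() -> frozenset[str]:
    """The packaged default stopword list (editable; see data/stopwords.txt)."""
    text = resources.files("pmceval.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def tokenize_corpus(
    texts: Mapping[str, str],
    segmenter: str = "whitespace",
    stopwords: Optional[Iterable[str]] = None,
    **segmenter_kwargs,
) -> TokenizedCorpus:
    """Segment documents into sentence-structured token streams.

    Sentences are split on Chinese and Latin sentence-final punctuation
    before segmentation; stopwords are removed after segmentation.
    """
    if segmenter not in _SEGMENTERS:
        raise ValueError(
            f"unknown segmenter {segmenter!r}; registered: {sorted(_SEGMENTERS)}"
        )
    seg = _SEGMENTERS[segmenter]
    sw = frozenset(stopwords) if stopwords is not None else frozenset()
    out: dict[str, tuple[tuple[str, ...], ...]] = {}
    for pid, text in texts.items():
        sents = []
        for raw_sentence in _split_sentences(text):
            toks = tuple(t for t in seg(raw_sentence, **segmenter_kwargs) if t not in sw)
            if toks:
                sents.append(toks)
        out[pid] = tuple(sents)
    return TokenizedCorpus(sentences=out, segmenter=segmenter, stopwords=sw)


def _split_sentences(text: str) -> list[str]:
    sentences, buf = [], []
    for ch in text:
        if ch in SENTENCE_DELIMITERS:
            if buf:
                sentences.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        sentences.append("".join(buf))
    return [s for s in sentences if s.strip()]


# ---------------------------------------------------------------------------
# frequencies and networks
# ---------------------------------------------------------------------------

def term_frequencies(corpus: TokenizedCorpus, top_k: int = 50) -> TermFrequencyTable:
    """Top-``top_k`` terms by corpus count, ties broken lexicographically."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: dict[str, int] = {}
    docfreq: dict[str, int] = {}
    total = 0
    for pid, toks in corpus.documents.items():
        total += len(toks)
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
        for t in set(toks):
            docfreq[t] = docfreq.get(t, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    entries = tuple((t, c, docfreq[t]) for t, c in ranked)
    return TermFrequencyTable(entries=entries, total_tokens=total)


def _windows(corpus: TokenizedCorpus, window) -> Iterable[Sequence[str]]:
    if window == "sentence":
        for sents in corpus.sentences.values():
            yield from sents
    elif window == "document":
        yield from corpus.documents.values()
    elif isinstance(window, int) or (isinstance(window, str) and window.startswith("sliding")):
        k = window if isinstance(window, int) else int(window.split(":", 1)[1])
        if k < 2:
            raise ValueError("sliding window size must be >= 2")
        for toks in corpus.documents.values():
            if len(toks) <= k:
                if toks:
                    yield toks
            else:
                for i in range(len(toks) - k + 1):
                    yield toks[i : i + k]
    else:
        raise ValueError(
            f"unknown window {window!r}; use 'sentence', 'document', an int, or 'sliding:k'"
        )


def cooccurrence_network(
    corpus: TokenizedCorpus,
    window="sentence",
    min_edge_weight: int = 2,
) -> nx.Graph:
    """Build the undirected weighted term co-occurrence graph.

    ``weight(a, b)`` is the number of windows containing both ``a`` and
    ``b`` (each window counts a pair at most once; no self-loops).
    Edges lighter than ``min_edge_weight`` are dropped, then isolated
    nodes are dropped.  Node attribute ``frequency`` is the corpus term
    count.
    """
    if min_edge_weight < 1:
        raise ValueError("min_edge_weight must be >= 1")
    freq: dict[str, int] = {}
    for toks in corpus.documents.values():
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    weights: dict[tuple[str, str], int] = {}
    for win in _windows(corpus, window):
        uniq = sorted(set(win))
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                weights[(a, b)] = weights.get((a, b), 0) + 1
    G = nx.Graph()
    for (a, b), w in weights.items():
        if w >= min_edge_weight:
            G.add_edge(a, b, weight=w)
    for node in G.nodes:
        G.nodes[node]["frequency"] = freq[node]
    return G


def network_centrality(network: nx.Graph) -> pd.DataFrame:
    """Degree and weighted degree per term, sorted by weighted degree.

    Distinguishes core terms (high weighted degree) from terms at the
    edge of the semantic map.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    rows = [
        {
            "term": n,
            "degree": network.degree(n),
            "weighted_degree": int(network.degree(n, weight="weight")),
        }
        for n in network.nodes
    ]
    df = pd.DataFrame(rows).sort_values(
        ["weighted_degree", "term"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def write_network(network: nx.Graph, path: Union[str, Path]) -> None:
    """Export the graph as GraphML (.graphml) or a weighted edge list CSV."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(network, path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as f:
            w = csv.writer(f)
            w.writerow(["source", "target", "weight"])
            for a, b, d in network.edges(data=True):
                w.writerow([a, b, d["weight"]])
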