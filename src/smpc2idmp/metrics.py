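"""Similarity metrics, record comparison and factor analysis.

Extractions are scored against gold records with a battery of complementary
metrics, each normalized to [0, 1]:

* exact match (dates compared as parsed dates, lists as sets),
* Jaccard similarity over token sets,
* ANLS — average normalized Levenshtein similarity,
  ``1 - d(a, b) / max(|a|, |b|)``,
* TF-IDF cosine similarity,
* BLEU (n-gram precision with smoothing for short fields), ROUGE-L F1 and
  METEOR (unigram F-mean with a fragmentation penalty; exact + light-stem
  matching),
* an embedding-based semantic score (greedy token-matching F1 when the
  encoder provides token vectors, pooled cosine otherwise).

Fields whose values are default-equivalent (an empty storage precaution vs.
the standard "no special storage conditions" phrase; an empty shelf life vs.
a standard value) receive full similarity on every metric.  Factor effects
across benchmark configurations are assessed with the Kruskal-Wallis rank
test (tie-corrected H, chi-square p), appropriate for the strongly bimodal,
non-normal score distributions this task produces.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Any, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

from .idmp_model import FieldSpec, field_registry, get_path
from .normalize import (
    DEFAULT_RULES,
    NormalizationRules,
    canonicalize_default,
    parse_date_value,
)
from .retrieval import EmbeddingBackend, get_embedding_backend

__all__ = [
    "METRIC_NAMES",
    "FieldScore",
    "EvaluationReport",
    "exact_match_score",
    "jaccard_score",
    "anls_score",
    "tfidf_cosine_score",
    "lexical_overlap_scores",
    "semantic_score",
    "match_list_items",
    "compare_records",
    "kruskal_wallis",
    "aggregate_report",
    "CorpusStats",
]

METRIC_NAMES = (
    "exact_match",
    "jaccard",
    "anls",
    "tfidf_cosine",
    "bleu",
    "rouge",
    "meteor",
    "semantic",
)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def _tokens(text: str) -> list[str]:
    """Lowercase Unicode word tokens; digits kept, punctuation dropped."""
    return _TOKEN_RE.findall(text.lower())


def _as_text(value: Any) -> str:
    """Canonical text rendering of a field value for string metrics.

    Lists render as their sorted elements joined with ", " so that string
    metrics inherit order-invariance; nested records render their leaf values.
    """
    if isinstance(value, str):
        return value
    if isinstance(value, list):
        return ", ".join(sorted(_as_text(v) for v in value))
    if isinstance(value, dict):
        return ", ".join(_as_text(value[k]) for k in sorted(value))
    return str(value)


# --- scalar metrics ---------------------------------------------------------

def exact_match_score(pred: Any, gold: Any) -> float:
    """1 iff the canonical forms are equal; dates as parsed dates, lists as
    (multiset-insensitive) sets."""
    if isinstance(pred, list) and isinstance(gold, list):
        return float(
            {_as_text(v) for v in pred} == {_as_text(v) for v in gold}
        )
    if isinstance(pred, str) and isinstance(gold, str):
        dp, dg = parse_date_value(pred), parse_date_value(gold)
        if dp is not None and dg is not None:
            return float(dp == dg)
        return float(pred.strip() == gold.strip())
    return float(_as_text(pred) == _as_text(gold))


def jaccard_score(pred: Any, gold: Any) -> float:
    """|A ∩ B| / |A ∪ B| over token sets (element sets for lists); two empty
    values are identical (score 1)."""
    if isinstance(pred, list) and isinstance(gold, list):
        a = {_as_text(v).strip().lower() for v in pred}
        b = {_as_text(v).strip().lower() for v in gold}
    else:
        a, b = set(_tokens(_as_text(pred))), set(_tokens(_as_text(gold)))
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def anls_score(pred: Any, gold: Any) -> float:
    """Normalized Levenshtein similarity: 1 - d / max(len); both empty -> 1."""
    a, b = _as_text(pred), _as_text(gold)
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    distance = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - distance / max(len(a), len(b))


class CorpusStats:
    """TF-IDF vocabulary/IDF statistics fitted once over a text collection."""

    def __init__(self, texts: Sequence[str]):
        texts = [t for t in texts if t.strip()]
        self.vectorizer: TfidfVectorizer | None = None
        if texts:
            self.vectorizer = TfidfVectorizer(token_pattern=r"(?u)\w+")
            try:
                self.vectorizer.fit(texts)
            except ValueError:  # vocabulary empty (e.g. punctuation only)
                self.vectorizer = None


def tfidf_cosine_score(
    pred: Any, gold: Any, corpus_stats: CorpusStats | None = None
) -> float:
    """Cosine of TF-IDF vectors, clipped to [0, 1]; both empty -> 1, one
    empty -> 0."""
    a, b = _as_text(pred), _as_text(gold)
    if not a.strip() and not b.strip():
        return 1.0
    if not a.strip() or not b.strip():
        return 0.0
    vectorizer = corpus_stats.vectorizer if corpus_stats else None
    try:
        if vectorizer is None:
            vectorizer = TfidfVectorizer(token_pattern=r"(?u)\w+").fit([a, b])
        mat = vectorizer.transform([a, b])
    except ValueError:
        return 0.0
    score = float(cosine_similarity(mat[0], mat[1])[0, 0])
    return min(1.0, max(0.0, score))


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _bleu(pred_tokens: list[str], gold_tokens: list[str], max_n: int = 4) -> float:
    """BLEU with add-one smoothing on higher-order n-grams so that short
    field values do not vanish to zero."""
    if not pred_tokens or not gold_tokens:
        return 1.0 if pred_tokens == gold_tokens else 0.0
    log_sum = 0.0
    for n in range(1, max_n + 1):
        pred_ngrams = _ngrams(pred_tokens, n)
        gold_ngrams = _ngrams(gold_tokens, n)
        overlap = sum((pred_ngrams & gold_ngrams).values())
        total = sum(pred_ngrams.values())
        if n == 1:
            if overlap == 0:
                return 0.0
            p_n = overlap / total
        else:
            p_n = (overlap + 1.0) / (total + 1.0) if total else 1.0
        log_sum += math.log(p_n)
    precision = math.exp(log_sum / max_n)
    bp = 1.0 if len(pred_tokens) >= len(gold_tokens) else math.exp(
        1.0 - len(gold_tokens) / len(pred_tokens)
    )
    return bp * precision


def _lcs_len(a: list[str], b: list[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def _rouge_l(pred_tokens: list[str], gold_tokens: list[str]) -> float:
    if not pred_tokens and not gold_tokens:
        return 1.0
    if not pred_tokens or not gold_tokens:
        return 0.0
    lcs = _lcs_len(pred_tokens, gold_tokens)
    if lcs == 0:
        return 0.0
    precision = lcs / len(pred_tokens)
    recall = lcs / len(gold_tokens)
    return 2 * precision * recall / (precision + recall)


_SUFFIXES = ("ational", "iveness", "fulness", "ation", "izer", "ing", "ely",
             "es", "ed", "ly", "s")


def _stem(token: str) -> str:
    """Light suffix-stripping stemmer (no external lexicon)."""
    for suffix in _SUFFIXES:
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)]
    return token


def _meteor(pred_tokens: list[str], gold_tokens: list[str]) -> float:
    """Unigram METEOR: exact then stem matching, F-mean weighted toward
    recall, times a fragmentation penalty."""
    if not pred_tokens and not gold_tokens:
        return 1.0
    if not pred_tokens or not gold_tokens:
        return 0.0
    gold_free = list(range(len(gold_tokens)))
    alignment: list[tuple[int, int]] = []  # (pred_idx, gold_idx)
    for stage in ("exact", "stem"):
        for i, tok in enumerate(pred_tokens):
            if any(i == pi for pi, _ in alignment):
                continue
            key = tok if stage == "exact" else _stem(tok)
            for j in list(gold_free):
                gtok = gold_tokens[j] if stage == "exact" else _stem(gold_tokens[j])
                if key == gtok:
                    alignment.append((i, j))
                    gold_free.remove(j)
                    break
    matches = len(alignment)
    if matches == 0:
        return 0.0
    precision = matches / len(pred_tokens)
    recall = matches / len(gold_tokens)
    f_mean = 10 * precision * recall / (recall + 9 * precision)
    # chunks: maximal runs contiguous in both sequences
    alignment.sort()
    chunks = 1
    for (pi, gi), (pj, gj) in zip(alignment, alignment[1:]):
        if pj != pi + 1 or gj != gi + 1:
            chunks += 1
    # a single contiguous chunk is unfragmented: no penalty, so identical
    # inputs score exactly 1
    penalty = 0.0 if chunks == 1 else 0.5 * (chunks / matches) ** 3
    return f_mean * (1.0 - penalty)


def lexical_overlap_scores(pred: Any, gold: Any) -> dict[str, float]:
    """BLEU, ROUGE-L F1 and METEOR on tokenized values; all in [0, 1]."""
    pt, gt = _tokens(_as_text(pred)), _tokens(_as_text(gold))
    return {
        "bleu": min(1.0, max(0.0, _bleu(pt, gt))),
        "rouge": min(1.0, max(0.0, _rouge_l(pt, gt))),
        "meteor": min(1.0, max(0.0, _meteor(pt, gt))),
    }


def semantic_score(
    pred: Any, gold: Any, encoder: EmbeddingBackend | None = None
) -> float:
    """Embedding-based similarity in [0, 1].

    When the encoder exposes ``embed_tokens`` the score is a greedy
    token-matching F1 over token vectors (BERTScore-style); otherwise the
    cosine of pooled text vectors, mapped from [-1, 1] to [0, 1] by clipping.
    """
    a, b = _as_text(pred), _as_text(gold)
    if not a.strip() and not b.strip():
        return 1.0
    if not a.strip() or not b.strip():
        return 0.0
    if a == b:  # identity law holds exactly despite float cosine rounding
        return 1.0
    encoder = encoder or get_embedding_backend("hashed-bow")
    embed_tokens = getattr(encoder, "embed_tokens", None)
    if callable(embed_tokens):
        va, vb = embed_tokens(a), embed_tokens(b)
        if len(va) == 0 or len(vb) == 0:
            return 0.0
        sims = cosine_similarity(np.asarray(va), np.asarray(vb))
        recall = float(np.mean(np.max(sims, axis=0)))
        precision = float(np.mean(np.max(sims, axis=1)))
        if precision + recall <= 0:
            return 0.0
        return min(1.0, max(0.0, 2 * precision * recall / (precision + recall)))
    vecs = np.asarray(encoder.embed([a, b]), dtype=np.float64)
    norms = np.linalg.norm(vecs, axis=1)
    if norms[0] == 0 or norms[1] == 0:
        return 0.0
    return min(1.0, max(0.0, float(vecs[0] @ vecs[1] / (norms[0] * norms[1]))))


# --- list-of-records matching ----------------------------------------------

def match_list_items(
    pred_list: list[dict], gold_list: list[dict], key: str
) -> tuple[list[tuple[dict, dict]], list[dict], list[dict]]:
    """Pair list items by normalized equality of a key field.

    Order-insensitive; each item used at most once; items missing the key go
    to the unmatched side.  Returns (pairs, unmatched_pred, unmatched_gold).
    """
    def norm(item: dict) -> str | None:
        value = item.get(key)
        return _as_text(value).strip().lower() if value is not None else None

    pairs: list[tuple[dict, dict]] = []
    unmatched_pred: list[dict] = []
    gold_pool = list(gold_list)
    for item in pred_list:
        k = norm(item)
        match = None
        if k is not None:
            for candidate in gold_pool:
                if norm(candidate) == k:
                    match = candidate
                    break
        if match is not None:
            pairs.append((item, match))
            gold_pool.remove(match)
        else:
            unmatched_pred.append(item)
    return pairs, unmatched_pred, gold_pool


# --- record comparison ------------------------------------------------------

@dataclass(frozen=True)
class FieldScore:
    field_id: str
    metric: str
    value: float


@dataclass
class EvaluationReport:
    """Per-field x per-metric scores in long format plus aggregates."""

    scores: pd.DataFrame  # columns: doc_id, field_id, section, metric, value [+ factors]
    test_results: pd.DataFrame | None = None  # columns: factor, metric, H, p

    def section_means(self) -> pd.DataFrame:
        return (
            self.scores.groupby(["section", "metric"])["value"].mean().unstack()
        )

    def overall_means(self) -> pd.Series:
        return self.scores.groupby("metric")["value"].mean()


def _scalar_scores(
    pred: Any,
    gold: Any,
    metrics: Sequence[str],
    corpus_stats: CorpusStats | None,
    encoder: EmbeddingBackend | None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for metric in metrics:
        if metric == "exact_match":
            out[metric] = exact_match_score(pred, gold)
        elif metric == "jaccard":
            out[metric] = jaccard_score(pred, gold)
        elif metric == "anls":
            out[metric] = anls_score(pred, gold)
        elif metric == "tfidf_cosine":
            out[metric] = tfidf_cosine_score(pred, gold, corpus_stats)
        elif metric in ("bleu", "rouge", "meteor"):
            if metric not in out:
                out.update(
                    (k, v) for k, v in lexical_overlap_scores(pred, gold).items()
                    if k in metrics
                )
        elif metric == "semantic":
            out[metric] = semantic_score(pred, gold, encoder)
    return out


def _canonical_for_scoring(
    spec: FieldSpec, value: Any, rules: NormalizationRules
) -> Any:
    """Apply default/shelf-life equivalence classes before scoring."""
    if isinstance(value, str) and spec.value_kind == "scalar-text":
        return canonicalize_default(spec.path, value, rules)
    return value


def compare_records(
    pred: dict,
    gold: dict,
    metrics: Sequence[str] = METRIC_NAMES,
    rules: NormalizationRules = DEFAULT_RULES,
    corpus_stats: CorpusStats | None = None,
    encoder: EmbeddingBackend | None = None,
    doc_id: str = "",
) -> EvaluationReport:
    """Score every registry field of a (normalized) prediction against gold.

    List-of-records fields are matched on their key field first; matched
    pairs are scored leaf-wise and averaged, unmatched items score 0.
    Default-equivalent pairs receive full scores on every metric.
    """
    rows: list[dict] = []
    for spec in field_registry():
        if spec.field_id == "package_component_component":
            scores = _component_scores(pred, gold, metrics, corpus_stats, encoder)
        else:
            pv = _field_value(pred, spec)
            gv = _field_value(gold, spec)
            pv = _canonical_for_scoring(spec, pv, rules)
            gv = _canonical_for_scoring(spec, gv, rules)
            scores = _scalar_scores(pv, gv, metrics, corpus_stats, encoder)
        for metric, value in scores.items():
            rows.append(
                {
                    "doc_id": doc_id,
                    "field_id": spec.field_id,
                    "section": spec.section,
                    "metric": metric,
                    "value": float(value),
                }
            )
    return EvaluationReport(pd.DataFrame(rows))


def _field_value(record: dict, spec: FieldSpec) -> Any:
    if "[]" not in spec.path:
        return get_path(record, spec.path)
    list_path, _, tail = spec.path.partition("[]")
    tail = tail.lstrip(".")
    items = get_path(record, list_path, default=[])
    if not isinstance(items, list):
        return []
    if spec.field_id.startswith("active_"):
        # single composition entry by convention
        return get_path(record, f"{list_path}[0].{tail}") if items else ""
    if not tail:  # the list-of-records field owns whole entries
        return list(items)
    return [get_path(record, f"{list_path}[{i}].{tail}") for i in range(len(items))]


_COMPONENT_PATH = (
    "packaged_medicinal_product.package.package_composition.package_component"
)


def _component_scores(
    pred: dict,
    gold: dict,
    metrics: Sequence[str],
    corpus_stats: CorpusStats | None,
    encoder: EmbeddingBackend | None,
) -> dict[str, float]:
    """Score packaging components: match on the component key, average the
    per-pair leaf scores, count unmatched items as 0."""
    pred_items = get_path(pred, _COMPONENT_PATH, default=[]) or []
    gold_items = get_path(gold, _COMPONENT_PATH, default=[]) or []
    if not pred_items and not gold_items:
        return {m: 1.0 for m in metrics}
    pairs, unmatched_pred, unmatched_gold = match_list_items(
        pred_items, gold_items, key="component"
    )
    n_units = len(pairs) + len(unmatched_pred) + len(unmatched_gold)
    totals = {m: 0.0 for m in metrics}
    for p_item, g_item in pairs:
        leaf_scores = [
            _scalar_scores(
                str(p_item.get(leaf, "")), str(g_item.get(leaf, "")),
                metrics, corpus_stats, encoder,
            )
            for leaf in ("component", "material")
        ]
        for m in metrics:
            totals[m] += sum(s[m] for s in leaf_scores) / len(leaf_scores)
    out = {m: totals[m] / n_units for m in metrics}
    if "exact_match" in out:
        # exact match stays an indicator: 1 iff every item pairs up and
        # every paired leaf matches exactly
        out["exact_match"] = float(
            not unmatched_pred and not unmatched_gold
            and totals["exact_match"] == len(pairs)
        )
    return out


# --- statistics -------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Kruskal-Wallis rank test across >= 2 non-empty groups.

    Returns the tie-corrected H statistic and the chi-square p-value with
    (k - 1) degrees of freedom; fully tied data yields H = 0, p = 1 by
    convention.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis groups must be non-empty")
    flat = [x for g in groups for x in g]
    if all(x == flat[0] for x in flat):
        return {"H": 0.0, "p": 1.0}
    result = stats.kruskal(*groups)
    return {"H": float(result.statistic), "p": float(result.pvalue)}


def aggregate_report(
    reports: Sequence[EvaluationReport],
    group_by: Sequence[str] = (),
) -> EvaluationReport:
    """Pool scored reports and compute factor-level aggregates.

    Each input report's ``scores`` frame may carry configuration factor
    columns (llm, prompt, embedding, retrieval, ...).  The pooled report's
    aggregates are means per metric per section and per factor level, and a
    Kruskal-Wallis test per (factor, metric) across the factor's levels.
    """
    if not reports:
        raise ValueError("aggregate_report needs at least one report")
    pooled = pd.concat([r.scores for r in reports], ignore_index=True)
    tests: list[dict] = []
    for factor in group_by:
        if factor not in pooled.columns:
            raise KeyError(f"factor column {factor!r} missing from scores")
        for metric in pooled["metric"].unique():
            sub = pooled[pooled["metric"] == metric]
            groups = [
                grp["value"].to_list() for _, grp in sub.groupby(factor)
            ]
            if len(groups) >= 2 and all(groups):
                result = kruskal_wallis(groups)
                tests.append(
                    {"factor": factor, "metric": metric,
                     "H": result["H"], "p": result["p"]}
                )
    test_df = pd.DataFrame(tests) if tests else None
    return EvaluationReport(pooled, test_df)
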