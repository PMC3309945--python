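"""Hit counts and top-k citation lists for rendered queries.

Two providers satisfy the same contract (``count`` and ``top_k`` over a
query string): :class:`LocalProvider`, which evaluates Boolean queries
against an in-memory citation corpus with PubMed-like field semantics,
and :class:`EutilsProvider`, a thin NCBI esearch client (network,
never exercised in CI).
"""

from __future__ import annotations

import json
import re
import time
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from .query_builder import And, BooleanQuery, Clause, Node, Not, Or, parse_query

__all__ = [
    "SUBSETS",
    "Citation",
    "local_eval",
    "LocalProvider",
    "EutilsProvider",
    "count",
    "top_k",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_corpus_pubmed_xml",
]

SUBSETS = ("MEDLINE", "OldMedline", "premedline")

_WORD = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class Citation:
    """One PubMed-like citation record."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_terms: tuple[str, ...] = ()
    subsets: frozenset[str] = frozenset()
    pub_date: date = date(2011, 1, 1)

    def __post_init__(self) -> None:
        unknown = set(self.subsets) - set(SUBSETS)
        if unknown:
            raise ValueError(f"pmid {self.pmid}: unknown subsets {sorted(unknown)}")
        if "MEDLINE" in self.subsets and "premedline" in self.subsets:
            raise ValueError(f"pmid {self.pmid}: MEDLINE and premedline are mutually exclusive")


def _tokens(text: str) -> list[str]:
    return _WORD.findall(text.lower())


def _contains_phrase(text_tokens: Sequence[str], phrase_tokens: Sequence[str]) -> bool:
    """Word-boundary, punctuation-insensitive contiguous token match."""
    n, m = len(text_tokens), len(phrase_tokens)
    if m == 0 or m > n:
        return False
    first = phrase_tokens[0]
    for i in range(n - m + 1):
        if text_tokens[i] == first and list(text_tokens[i : i + m]) == list(phrase_tokens):
            return True
    return False


class _IndexedCorpus:
    """Pre-tokenized corpus, reused across clause evaluations."""

    def __init__(self, citations: Sequence[Citation]):
        pmids = [c.pmid for c in citations]
        if len(set(pmids)) != len(pmids):
            raise ValueError("duplicate pmids in corpus")
        self.citations = list(citations)
        self.tiab_tokens = [_tokens(c.title) + ["\x00"] + _tokens(c.abstract) for c in citations]
        # the \x00 sentinel blocks phrases from spanning the title/abstract boundary
        self.mesh_norm = [frozenset(t.lower() for t in c.mesh_terms) for c in citations]

    def all_pmids(self) -> set[str]:
        return {c.pmid for c in self.citations}

    def eval_clause(self, clause: Clause) -> set[str]:
        if clause.field_tag == "SB":
            wanted = clause.phrase.lower()
            return {
                c.pmid
                for c in self.citations
                if any(s.lower() == wanted for s in c.subsets)
            }
        phrase_tokens = _tokens(clause.phrase)
        out: set[str] = set()
        for c, tiab, mesh in zip(self.citations, self.tiab_tokens, self.mesh_norm):
            if clause.field_tag in ("MeSH Terms", "All Fields"):
                if clause.phrase.lower() in mesh:
                    out.add(c.pmid)
                    continue
                if clause.field_tag == "MeSH Terms":
                    continue
            if _contains_phrase(tiab, phrase_tokens):
                out.add(c.pmid)
        return out


def _eval_node(corpus: _IndexedCorpus, node: Node) -> set[str]:
    if isinstance(node, Clause):
        return corpus.eval_clause(node)
    if isinstance(node, And):
        result: Optional[set[str]] = None
        for child in node.children:
            hit = _eval_node(corpus, child)
            result = hit if result is None else result & hit
        return result or set()
    if isinstance(node, Or):
        result = set()
        for child in node.children:
            result |= _eval_node(corpus, child)
        return result
    if isinstance(node, Not):
        return _eval_node(corpus, node.left) - _eval_node(corpus, node.right)
    raise TypeError(f"not a query node: {node!r}")


def local_eval(
    corpus: Union[Sequence[Citation], "_IndexedCorpus"], query: Union[BooleanQuery, Node]
) -> set[str]:
    """Evaluate a Boolean query against a citation corpus; returns pmids.

    Field semantics: [MeSH Terms] is exact case-insensitive membership in
    the citation's headings; [TIAB] is a word-boundary phrase match over
    title or abstract; [All Fields] is either of those; [SB] is subset
    membership; AND/OR/NOT are intersection/union/difference.
    """
    if not isinstance(corpus, _IndexedCorpus):
        corpus = _IndexedCorpus(corpus)
    node = query.root if isinstance(query, BooleanQuery) else query
    return _eval_node(corpus, node)


def _sort_key(citation: Citation) -> tuple:
    pmid_key = int(citation.pmid) if citation.pmid.isdigit() else citation.pmid
    return (citation.pub_date, pmid_key)


class LocalProvider:
    """Count/top-k provider over a fixture corpus.

    Query strings are parsed back to ASTs with
    :func:`pubmed_expand.query_builder.parse_query`, so anything render()
    emits is accepted.
    """

    def __init__(self, corpus: Sequence[Citation]):
        self._corpus = _IndexedCorpus(corpus)
        self._by_pmid = {c.pmid: c for c in corpus}

    def _matches(self, query: Union[str, BooleanQuery, Node]) -> list[Citation]:
        if isinstance(query, str):
            query = parse_query(query)
        pmids = local_eval(self._corpus, query)
        hits = [self._by_pmid[p] for p in pmids]
        hits.sort(key=_sort_key, reverse=True)  # date-descending, then pmid-descending
        return hits

    def count(self, query: Union[str, BooleanQuery, Node]) -> int:
        return len(self._matches(query))

    def top_k(self, query: Union[str, BooleanQuery, Node], k: int) -> list[str]:
        if k < 1:
            raise ValueError("k must be >= 1")
        return [c.pmid for c in self._matches(query)[:k]]

    def top_all(self, query: Union[str, BooleanQuery, Node]) -> list[str]:
        return [c.pmid for c in self._matches(query)]


class RetrievalError(RuntimeError):
    """Provider failure after retries."""


class EutilsProvider:
    """NCBI E-utilities esearch client honoring the usage policy.

    Requests are spaced >= ``min_interval`` seconds apart and retried
    up to ``retries`` times with doubling backoff.  Responses may be
    cached on disk keyed by query hash and date, for reproducibility.
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

    def __init__(
        self,
        email: Optional[str] = None,
        api_key: Optional[str] = None,
        retries: int = 3,
        min_interval: float = 0.34,
        cache_dir: Optional[Union[str, Path]] = None,
    ):
        self.email = email
        self.api_key = api_key
        self.retries = retries
        self.min_interval = min_interval
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self._last_request = 0.0

    def _cache_path(self, query: str, retmax: int) -> Optional[Path]:
        if self.cache_dir is None:
            return None
        import hashlib

        digest = hashlib.sha256(f"{query}|{retmax}".encode()).hexdigest()[:24]
        return self.cache_dir / f"esearch-{date.today().isoformat()}-{digest}.json"

    def _fetch(self, query: str, retmax: int) -> dict:
        cache = self._cache_path(query, retmax)
        if cache is not None and cache.exists():
            return json.loads(cache.read_text())
        params = {
            "db": "pubmed",
            "term": query,
            "retmode": "json",
            "retmax": str(retmax),
            "sort": "most+recent",
        }
        if self.email:
            params["email"] = self.email
        if self.api_key:
            params["api_key"] = self.api_key
        url = f"{self.BASE}?{urllib.parse.urlencode(params)}"
        delay = 1.0
        last_error: Optional[Exception] = None
        for _ in range(self.retries):
            wait = self.min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            try:
                self._last_request = time.monotonic()
                with urllib.request.urlopen(url, timeout=30) as resp:
                    payload = json.loads(resp.read().decode())
                result = payload["esearchresult"]
                if cache is not None:
                    cache.parent.mkdir(parents=True, exist_ok=True)
                    cache.write_text(json.dumps(result))
                return result
            except KeyError as exc:
                raise RetrievalError(f"malformed esearch response: missing {exc}") from exc
            except Exception as exc:  # noqa: BLE001 - network errors are retryable
                last_error = exc
                time.sleep(delay)
                delay *= 2
        raise RetrievalError(f"esearch failed after {self.retries} attempts: {last_error}")

    def count(self, query: str) -> int:
        return int(self._fetch(query, retmax=0)["count"])

    def top_k(self, query: str, k: int) -> list[str]:
        if k < 1:
            raise ValueError("k must be >= 1")
        return list(self._fetch(query, retmax=k)["idlist"])[:k]


def count(provider, query: Union[str, BooleanQuery]) -> int:
    """Hit count for a query via any provider."""
    if isinstance(query, BooleanQuery) and not isinstance(provider, LocalProvider):
        query = query.render()
    return provider.count(query)


def top_k(provider, query: Union[str, BooleanQuery], k: int) -> list[str]:
    """Top-k pmids (date-descending, larger pmid first on ties)."""
    if isinstance(query, BooleanQuery) and not isinstance(provider, LocalProvider):
        query = query.render()
    return provider.top_k(query, k)


# --- corpus I/O ---------------------------------------------------------


def _citation_to_dict(c: Citation) -> dict:
    return {
        "pmid": c.pmid,
        "title": c.title,
        "abstract": c.abstract,
        "mesh_terms": list(c.mesh_terms),
        "subsets": sorted(c.subsets),
        "pub_date": c.pub_date.isoformat(),
    }


def _citation_from_dict(d: dict) -> Citation:
    return Citation(
        pmid=str(d["pmid"]),
        title=d.get("title", ""),
        abstract=d.get("abstract", ""),
        mesh_terms=tuple(d.get("mesh_terms", ())),
        subsets=frozenset(d.get("subsets", ())),
        pub_date=date.fromisoformat(d["pub_date"]),
    )


def write_corpus_jsonl(citations: Iterable[Citation], stream: IO[str]) -> None:
    for c in citations:
        stream.write(json.dumps(_citation_to_dict(c), sort_keys=True) + "\n")


def read_corpus_jsonl(stream: Union[IO[str], str]) -> list[Citation]:
    """Read a JSON-lines corpus (one citation object per line)."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    out = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            out.append(_citation_from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ValueError(f"corpus line {lineno}: {exc}") from exc
    return out


_STATUS_SUBSET = {
    "MEDLINE": "MEDLINE",
    "OLDMEDLINE": "OldMedline",
    "PubMed-not-MEDLINE": frozenset(),
    "In-Process": "premedline",
    "In-Data-Review": "premedline",
    "Publisher": "premedline",
}


def read_corpus_pubmed_xml(stream: Union[IO[str], str]) -> list[Citation]:
    """Read a PubmedArticle XML subset: PMID, title, abstract, headings, date.

    The MedlineCitation Status attribute maps to the subset flag
    (MEDLINE, OldMedline, or premedline for in-process/publisher records).
    """
    root = ET.fromstring(stream if isinstance(stream, str) else stream.read())
    out = []
    for article in root.iter("PubmedArticle"):
        mc = article.find("MedlineCitation")
        if mc is None:
            raise ValueError("PubmedArticle without MedlineCitation")
        pmid = mc.findtext("PMID", "").strip()
        title = mc.findtext("Article/ArticleTitle", "") or ""
        abstract = " ".join(
            (t.text or "") for t in mc.iterfind("Article/Abstract/AbstractText")
        )
        mesh = tuple(
            (h.findtext("DescriptorName") or "").strip()
            for h in mc.iterfind("MeshHeadingList/MeshHeading")
        )
        status = mc.get("Status", "")
        mapped = _STATUS_SUBSET.get(status, frozenset())
        subsets = frozenset() if not mapped else frozenset([mapped] if isinstance(mapped, str) else mapped)
        year = int(mc.findtext("Article/Journal/JournalIssue/PubDate/Year", "2011") or 2011)
        month = int(mc.findtext("Article/Journal/JournalIssue/PubDate/Month", "1") or 1)
        day = int(mc.findtext("Article/Journal/JournalIssue/PubDate/Day", "1") or 1)
        out.append(
            Citation(
                pmid=pmid,
                title=title,
                abstract=abstract,
                mesh_terms=tuple(m for m in mesh if m),
                subsets=subsets,
                pub_date=date(year, month, day),
            )
        )
    return out
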