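"""Ontology lexicon: labels + exact synonyms, token vocabulary and 3-mer index.

Reads OBO 1.4 flat files and OBO-graph JSON. Only labels and exact synonyms
are indexed by default; alt_ids resolve to primary IDs; an optional root
filter restricts the lexicon to the is_a descendants of one concept.
"""

from __future__ import annotations

import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from tblat.errors import OntologyFormatError
from tblat.kmers import kmers
from tblat.textprep import StopWordList, content_tokens, default_stopwords

__all__ = ["OntologyLexicon", "load_ontology", "candidates_for", "toy_ontology_path"]

#: Lexicon tokens keep length-3 words (e.g. "hip") — they are matchable
#: exactly even though they are below the corpus cleansing floor of 4.
LEXICON_MIN_TOKEN_LEN = 3


@dataclass
class ConceptPhrase:
    """One label or synonym of a concept, as a content-token multiset."""

    text: str
    tokens: tuple[str, ...]  # sorted content tokens (multiset as sorted tuple)

    @property
    def counter(self) -> Counter:
        return Counter(self.tokens)


@dataclass
class OntologyLexicon:
    concepts: dict[str, list[ConceptPhrase]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)  # concept id -> primary label
    alt_ids: dict[str, str] = field(default_factory=dict)  # retired id -> primary id
    token_index: dict[str, set[str]] = field(default_factory=dict)
    trigram_index: dict[str, set[str]] = field(default_factory=dict)
    root_filter: str | None = None

    def resolve_id(self, concept_id: str) -> str:
        """Map a possibly retired ID to its primary ID."""
        return self.alt_ids.get(concept_id, concept_id)

    @property
    def vocabulary(self) -> set[str]:
        return set(self.token_index)

    def __contains__(self, concept_id: str) -> bool:
        return self.resolve_id(concept_id) in self.concepts


_OBO_TAG_RE = re.compile(r"^([\w-]+):\s*(.*?)\s*(?:(?<!\\)!.*)?$")
_SYNONYM_RE = re.compile(r'^"(.*)"\s+(\w+)')


def _parse_obo(path: Path) -> tuple[dict, dict, dict, dict]:
    """Minimal OBO 1.4 reader: id, name, synonym scope, is_a, alt_id, obsolete."""
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = defaultdict(list)
    parents: dict[str, set[str]] = defaultdict(set)
    alt_ids: dict[str, str] = {}
    current: str | None = None
    in_term = False
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
            current = None
            continue
        if not in_term or not line:
            continue
        m = _OBO_TAG_RE.match(line)
        if not m:
            continue
        tag, value = m.group(1), m.group(2)
        if tag == "id":
            current = value
        elif current is None:
            continue
        elif tag == "name":
            names[current] = value
        elif tag == "alt_id":
            alt_ids[value] = current
        elif tag == "is_a":
            parents[current].add(value.split("!")[0].strip())
        elif tag == "synonym":
            sm = _SYNONYM_RE.match(value)
            if sm and sm.group(2) == "EXACT":
                synonyms[current].append(sm.group(1))
        elif tag == "is_obsolete" and value.lower() == "true":
            names.pop(current, None)
    return names, dict(synonyms), dict(parents), alt_ids


def _parse_obograph(path: Path) -> tuple[dict, dict, dict, dict]:
    """OBO-graph JSON reader (nodes/edges of the first graph)."""
    doc = json.loads(path.read_text(encoding="utf-8"))
    try:
        graph = doc["graphs"][0]
    except (KeyError, IndexError, TypeError):
        raise OntologyFormatError(f"{path}: not an OBO-graph JSON document")
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = defaultdict(list)
    parents: dict[str, set[str]] = defaultdict(set)
    alt_ids: dict[str, str] = {}

    def _curie(iri: str) -> str:
        frag = iri.rsplit("/", 1)[-1]
        return frag.replace("_", ":", 1) if "_" in frag else frag

    for node in graph.get("nodes", []):
        if node.get("type") not in (None, "CLASS"):
            continue
        nid = _curie(node["id"])
        meta = node.get("meta", {}) or {}
        if meta.get("deprecated"):
            continue
        if "lbl" in node:
            names[nid] = node["lbl"]
        for syn in meta.get("synonyms", []):
            if syn.get("pred") == "hasExactSynonym":
                synonyms[nid].append(syn["val"])
        for bpv in meta.get("basicPropertyValues", []):
            if bpv.get("pred", "").endswith("hasAlternativeId"):
                alt_ids[_curie(bpv["val"])] = nid
    for edge in graph.get("edges", []):
        if edge.get("pred") == "is_a":
            parents[_curie(edge["sub"])].add(_curie(edge["obj"]))
    return names, dict(synonyms), dict(parents), alt_ids


def _descendants(root: str, parents: dict[str, set[str]]) -> set[str]:
    children: dict[str, set[str]] = defaultdict(set)
    for child, pars in parents.items():
        for p in pars:
            children[p].add(child)
    seen: set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for c in children.get(node, ()):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return seen


def load_ontology(
    path: str | Path,
    root_filter: str | None = None,
    stoplist: StopWordList | None = None,
    min_token_len: int = LEXICON_MIN_TOKEN_LEN,
) -> OntologyLexicon:
    """Build an :class:`OntologyLexicon` from an OBO or OBO-graph JSON file.

    Labels and exact synonyms are normalized with the standard text pipeline
    (default stop-word list unless one is given); with ``root_filter`` set,
    only strict is_a descendants of that concept are kept.
    """
    path = Path(path)
    if stoplist is None:
        stoplist = default_stopwords()
    text_head = path.read_text(encoding="utf-8", errors="replace")[:200].lstrip()
    if path.suffix == ".json" or text_head.startswith("{"):
        names, synonyms, parents, alt_ids = _parse_obograph(path)
    elif path.suffix == ".obo" or "format-version" in text_head or "[Term]" in text_head:
        names, synonyms, parents, alt_ids = _parse_obo(path)
    else:
        raise OntologyFormatError(f"{path}: unrecognized ontology format")
    if not names:
        raise OntologyFormatError(f"{path}: no ontology terms found")

    keep = set(names)
    if root_filter is not None:
        if root_filter not in names:
            raise OntologyFormatError(f"root filter {root_filter!r} not in ontology")
        keep = _descendants(root_filter, parents) & keep

    lex = OntologyLexicon(root_filter=root_filter, alt_ids=alt_ids)
    for cid in sorted(keep):
        phrases: list[ConceptPhrase] = []
        for phrase_text in [names[cid], *synonyms.get(cid, [])]:
            toks = tuple(
                sorted(
                    t.surface
                    for t in content_tokens(phrase_text, stoplist, min_len=min_token_len)
                )
            )
            if toks:
                phrases.append(ConceptPhrase(phrase_text, toks))
        if not phrases:
            continue
        lex.concepts[cid] = phrases
        lex.labels[cid] = names[cid]
        for phrase in phrases:
            for tok in phrase.tokens:
                lex.token_index.setdefault(tok, set()).add(cid)
    for tok in lex.token_index:
        for km in kmers(tok).kmers:
            lex.trigram_index.setdefault(km, set()).add(tok)
    return lex


def default_min_shared(query: str) -> int:
    """Seeding floor: 1 shared 3-mer for short queries (<= 4 3-mers), else 2."""
    return 1 if len(query) - 2 <= 4 else 2


def candidates_for(
    query_token: str, lex: OntologyLexicon, min_shared: int | None = None
) -> list[str]:
    """Ontology tokens sharing >= ``min_shared`` distinct 3-mers with the query.

    Ranked by shared-3-mer count descending (ties alphabetical, for
    determinism). ``min_shared=None`` applies the length-adaptive default.
    """
    if min_shared is None:
        min_shared = default_min_shared(query_token)
    shared: Counter = Counter()
    for km in set(kmers(query_token).kmers):
        for tok in lex.trigram_index.get(km, ()):
            shared[tok] += 1
    ranked = [tok for tok, n in shared.items() if n >= min_shared]
    ranked.sort(key=lambda tok: (-shared[tok], tok))
    return ranked


def toy_ontology_path() -> Path:
    """Path of the small OBO fixture shipped with the package."""
    with resources.as_file(resources.files("tblat.data").joinpath("toy.obo")) as p:
        return Path(p)
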