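"""Grounding: mapping textual spans to CURIEs via local lexicons, under constraints.

Every leaf of an extracted instance tree that corresponds to a named
entity is grounded — looked up against one or more lexicons (label/synonym
→ CURIE tables), optionally normalized to a required identifier prefix via
a single-hop mapping table, and then validated against the class's
identifier-prefix constraints (IDSpaces) and value set.  A span that
survives no candidate becomes a :class:`Placeholder` (rendered with RDF
blank-node syntax), never an error.

Matching is whole-span lookup: the value parsed from a completion is
treated as one entity mention.  Before giving up, a longest-prefix
fallback drops a trailing parenthetical and then trailing tokens; such
partial matches are recorded so evaluation can score them as incorrect
span parses.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .schema_model import ClassDefinition, ValueSetSpec

CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_.]*):(\S+)$")


class InvalidIdentifierError(ValueError):
    """The given string is not a well-formed CURIE."""


class UnresolvedRootError(KeyError):
    """An intensional value-set root is absent from the ontology graph."""


def curie_prefix(curie: str) -> str:
    m = CURIE_RE.match(curie)
    if m is None:
        raise InvalidIdentifierError(f"not a CURIE: {curie!r}")
    return m.group(1)


def is_valid_curie(curie: str, require_upper: bool = True) -> bool:
    m = CURIE_RE.match(curie)
    if m is None:
        return False
    return not require_upper or m.group(1) == m.group(1).upper()


_TERMINAL_PUNCT = ".,;:!?"


def normalize_label(text: str) -> str:
    """Canonical form for lexical matching: NFKC, case-fold, collapse whitespace, strip terminal punctuation."""
    text = unicodedata.normalize("NFKC", text)
    text = re.sub(r"\s+", " ", text).strip()
    text = text.rstrip(_TERMINAL_PUNCT).rstrip()
    return text.casefold()


@dataclass(frozen=True)
class LexiconEntry:
    label: str
    curie: str
    source_prefix: str
    priority: int = 1
    is_preferred_label: bool = True


@dataclass(frozen=True)
class GroundedRef:
    """A successful grounding: a CURIE plus the matched label and source span.

    ``matched_span`` is the (possibly truncated) portion of the original
    span that actually matched; when it differs from ``original_span`` the
    grounding used the longest-prefix fallback.
    """

    curie: str
    matched_label: str
    original_span: str
    source_prefix: str
    match_kind: str = "exact"  # exact | normalized
    matched_span: str = ""

    @property
    def whole_span(self) -> bool:
        span = self.matched_span or self.original_span
        return normalize_label(span) == normalize_label(self.original_span)


@dataclass(frozen=True)
class Placeholder:
    """A locally scoped stand-in for a span that could not be grounded.

    Rendered with RDF blank-node syntax (``_:Label``).
    """

    label: str
    span: str


def placeholder_label(span: str) -> str:
    words = re.findall(r"[A-Za-z0-9]+", span)
    label = "".join(w[:1].upper() + w[1:] for w in words)
    return label or "Unknown"


class Lexicon:
    """A label/synonym → CURIE table, the offline stand-in for ontology annotators."""

    def __init__(
        self,
        entries: Iterable[LexiconEntry] = (),
        normalization_policy: str = "default",
    ):
        self.normalization_policy = normalization_policy
        self.entries: list[LexiconEntry] = []
        self._index: dict[str, list[LexiconEntry]] = {}
        self._best: dict[tuple[str, str], LexiconEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: LexiconEntry) -> None:
        key = (normalize_label(entry.label), entry.curie)
        existing = self._best.get(key)
        # duplicates collapse to the best (lowest-number) priority
        if existing is not None and existing.priority <= entry.priority:
            return
        if existing is not None:
            self.entries.remove(existing)
            self._index[key[0]].remove(existing)
        self._best[key] = entry
        self.entries.append(entry)
        self._index.setdefault(key[0], []).append(entry)

    def lookup(self, span: str) -> list[LexiconEntry]:
        return list(self._index.get(normalize_label(span), ()))

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(
    source: Union[str, Iterable[Sequence[str]]],
    *,
    warnings: Optional[list[str]] = None,
) -> Lexicon:
    """Build a :class:`Lexicon` from a TSV term file or an iterable of rows.

    Columns: curie, label, synonym-flag (``synonym``/``label``, optional),
    priority (integer, optional, lower = higher priority).  Rows with a
    malformed CURIE (including lower-case prefixes) are rejected with a
    warning rather than aborting the load.
    """
    if isinstance(source, str):
        rows: Iterable[Sequence[str]] = csv.reader(io.StringIO(source), delimiter="\t")
    else:
        rows = source
    lexicon = Lexicon()
    for i, row in enumerate(rows, start=1):
        row = [c.strip() for c in row]
        if not row or not any(row) or row[0].startswith("#"):
            continue
        if len(row) < 2:
            if warnings is not None:
                warnings.append(f"row {i}: expected at least (curie, label)")
            continue
        curie, label = row[0], row[1]
        if not is_valid_curie(curie):
            if warnings is not None:
                warnings.append(f"row {i}: malformed CURIE {curie!r}")
            continue
        flag = row[2].casefold() if len(row) > 2 and row[2] else "label"
        try:
            priority = int(row[3]) if len(row) > 3 and row[3] else 1
        except ValueError:
            priority = 1
        lexicon.add(
            LexiconEntry(
                label=label,
                curie=curie,
                source_prefix=curie_prefix(curie),
                priority=priority,
                is_preferred_label=flag != "synonym",
            )
        )
    return lexicon


def load_lexicon(path: str, *, warnings: Optional[list[str]] = None) -> Lexicon:
    with open(path, encoding="utf-8") as fh:
        return build_lexicon(fh.read(), warnings=warnings)


class MappingTable:
    """Single-hop CURIE → CURIE mappings (e.g. CHEBI chemicals to their MeSH partners)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._map: dict[str, list[str]] = {}
        for from_curie, to_curie in pairs:
            self._map.setdefault(from_curie, []).append(to_curie)

    @classmethod
    def from_tsv(cls, text: str) -> "MappingTable":
        pairs = []
        for row in csv.reader(io.StringIO(text), delimiter="\t"):
            row = [c.strip() for c in row]
            if len(row) >= 2 and row[0] and not row[0].startswith("#"):
                pairs.append((row[0], row[1]))
        return cls(pairs)

    @classmethod
    def load(cls, path: str) -> "MappingTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_tsv(fh.read())

    def targets(self, curie: str) -> list[str]:
        return list(self._map.get(curie, ()))


def normalize_identifier(
    curie: str,
    target_prefixes: Sequence[str],
    mapping: Optional[MappingTable] = None,
) -> Optional[str]:
    """Map a CURIE into an allowed prefix; identity if already allowed, ``None`` if unmappable."""
    prefix = curie_prefix(curie)
    if not target_prefixes or prefix in target_prefixes:
        return curie
    if mapping is not None:
        candidates = sorted(
            t for t in mapping.targets(curie) if curie_prefix(t) in target_prefixes
        )
        if candidates:
            return candidates[0]
    return None


_TRAILING_PAREN = re.compile(r"\s*\([^()]*\)\s*$")


def _fallback_attempts(span: str) -> list[str]:
    """The whole span, then without a trailing parenthetical, then dropping trailing tokens."""
    attempts = [span]
    stripped = _TRAILING_PAREN.sub("", span)
    if stripped and stripped != span:
        attempts.append(stripped)
    tokens = attempts[-1].split()
    while len(tokens) > 1:
        tokens = tokens[:-1]
        candidate = " ".join(tokens)
        if candidate not in attempts:
            attempts.append(candidate)
    return attempts


def ground_span(
    span: str,
    class_def: ClassDefinition,
    lexicons: Sequence[Lexicon],
    mapping: Optional[MappingTable] = None,
    value_set: Optional[frozenset] = None,
    *,
    log: Optional[list[str]] = None,
) -> Union[GroundedRef, Placeholder]:
    """Ground one span against ordered lexicons under the class's constraints.

    Candidates from all lexicons are gathered by normalized lookup,
    normalized via the mapping table when the class requires specific
    prefixes, then filtered by IDSpaces and (when present) the resolved
    value set; both constraints apply when both are set.  Ties break on
    (exact match over normalized, lexicon order, priority, lexicographically
    smallest CURIE), making grounding deterministic for a fixed lexicon
    order.  Failure yields a :class:`Placeholder`.
    """
    id_spaces = list(class_def.id_spaces)
    allowed = value_set
    if allowed is None and class_def.value_set is not None and class_def.value_set.extensional:
        allowed = frozenset(class_def.value_set.extensional)

    for attempt in _fallback_attempts(span):
        candidates: list[tuple[tuple, GroundedRef]] = []
        for lex_idx, lexicon in enumerate(lexicons):
            for entry in lexicon.lookup(attempt):
                curie = entry.curie
                if id_spaces:
                    normalized = normalize_identifier(curie, id_spaces, mapping)
                    if normalized is None:
                        continue
                    curie = normalized
                if allowed is not None and curie not in allowed:
                    continue
                exact = entry.label == attempt
                ref = GroundedRef(
                    curie=curie,
                    matched_label=entry.label,
                    original_span=span,
                    source_prefix=curie_prefix(curie),
                    match_kind="exact" if exact else "normalized",
                    matched_span=attempt,
                )
                candidates.append(((0 if exact else 1, lex_idx, entry.priority, curie), ref))
        if candidates:
            candidates.sort(key=lambda pair: pair[0])
            best = candidates[0][1]
            if attempt != span and log is not None:
                log.append(f"partial-span grounding: {span!r} matched as {attempt!r}")
            return best
    return Placeholder(label=placeholder_label(span), span=span)


def resolve_value_set(
    spec: ValueSetSpec,
    edges: Optional[Iterable[tuple[str, str]]] = None,
) -> frozenset:
    """Resolve a value set to its explicit CURIE extension.

    Extensional sets are returned as given.  Intensional sets are resolved
    against a (child, parent) edge table: all reflexive-transitive
    descendants of the included roots, minus all descendants of the
    excluded roots.
    """
    if spec.extensional is not None:
        return frozenset(spec.extensional)
    intension = spec.intensional or {}
    include = list(intension.get("include", ()))
    exclude = list(intension.get("exclude", ()))
    children: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for child, parent in edges or ():
        children.setdefault(parent, []).append(child)
        nodes.add(child)
        nodes.add(parent)

    def descendants(root: str) -> set[str]:
        if root not in nodes:
            raise UnresolvedRootError(f"root {root!r} absent from ontology graph")
        seen = {root}
        stack = [root]
        while stack:
            node = stack.pop()
            for c in children.get(node, ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    included: set[str] = set()
    for root in include:
        included |= descendants(root)
    for root in exclude:
        included -= descendants(root)
    return frozenset(included)


def load_ontology_edges(path: str) -> list[tuple[str, str]]:
    """Read a (child, parent) CURIE edge table from TSV."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            row = [c.strip() for c in row]
            if len(row) >= 2 and row[0] and not row[0].startswith("#"):
                edges.append((row[0], row[1]))
    return edges


@dataclass
class Grounder:
    """Bundle of lexicons, mapping table, and ontology edges used during extraction."""

    lexicons: list[Lexicon] = field(default_factory=list)
    mapping: Optional[MappingTable] = None
    ontology_edges: list[tuple[str, str]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    _value_set_cache: dict[str, frozenset] = field(default_factory=dict)

    def resolve(self, spec: ValueSetSpec) -> frozenset:
        if spec.name not in self._value_set_cache:
            self._value_set_cache[spec.name] = resolve_value_set(spec, self.ontology_edges)
        return self._value_set_cache[spec.name]

    def ground(
        self, span: str, class_def: ClassDefinition, value_set_spec: Optional[ValueSetSpec] = None
    ) -> Union[GroundedRef, Placeholder]:
        value_set = None
        spec = value_set_spec or class_def.value_set
        if spec is not None:
            value_set = self.resolve(spec)
        return ground_span(
            span,
            class_def,
            self.lexicons,
            mapping=self.mapping,
            value_set=value_set,
            log=self.log,
        )
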