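"""MeSH and UMLS concept-table parsing, and the terminology index.

The index answers, for any MeSH descriptor: preferred term, entry terms,
direct hierarchy children ("sons"), and the deduplicated list of synonyms
contributed by other source vocabularies sharing a UMLS concept (CUI).
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_SOURCES",
    "MeshDescriptor",
    "ConceptAtom",
    "TerminologyIndex",
    "DescriptorFeatures",
    "ParseError",
    "parse_mesh",
    "serialize_mesh_tabular",
    "parse_mrconso",
    "mesh_cui_map_from_atoms",
    "build_index",
    "sons_of",
    "normalize_spelling",
    "umls_synonyms",
    "descriptor_features",
]

#: Source vocabularies admitted as UMLS-synonym contributors by default.
DEFAULT_SOURCES = frozenset(
    {
        "SNOMEDCT",
        "SNOMEDINTL",
        "ICD10",
        "WHOART",
        "ICF",
        "ICPC2",
        "LNC",
        "MDR",
        "FMA",
        "MEDLINEPLUS",
    }
)

# MRCONSO.RRF column indices (pipe-delimited, 18 columns).
_MRCONSO_CUI = 0
_MRCONSO_LAT = 1
_MRCONSO_SAB = 11
_MRCONSO_TTY = 12
_MRCONSO_STR = 14
_MRCONSO_SUPPRESS = 16
_MRCONSO_MIN_COLS = _MRCONSO_SUPPRESS + 1

_WS = re.compile(r"\s+")


class ParseError(ValueError):
    """Malformed terminology input."""


def normalize_spelling(term: str) -> str:
    """Canonical spelling used for duplicate detection.

    Lowercases, collapses internal whitespace runs to single spaces and
    strips the ends.  Punctuation is retained, so ``"Kidney Failure"`` and
    ``"Kidney-Failure"`` stay distinct.  Idempotent.
    """
    return _WS.sub(" ", term).strip().lower()


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH heading: identifier, preferred term, entry terms, tree codes."""

    ui: str
    preferred_term: str
    entry_terms: tuple[str, ...] = ()
    tree_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.preferred_term:
            raise ValueError(f"descriptor {self.ui!r}: empty preferred term")
        pref = normalize_spelling(self.preferred_term)
        for t in self.entry_terms:
            if normalize_spelling(t) == pref:
                raise ValueError(
                    f"descriptor {self.ui!r}: entry term {t!r} duplicates the preferred term"
                )
        if len(set(self.tree_numbers)) != len(self.tree_numbers):
            raise ValueError(f"descriptor {self.ui!r}: duplicate tree numbers")


@dataclass(frozen=True)
class ConceptAtom:
    """One term string from one source vocabulary under one CUI."""

    cui: str
    source: str
    term: str
    language: str = "ENG"

    def __post_init__(self) -> None:
        if not self.cui or not self.term:
            raise ValueError("ConceptAtom requires a non-empty cui and term")


@dataclass(frozen=True)
class DescriptorFeatures:
    """Per-descriptor factors recorded for the correlation analysis."""

    ui: str
    n_sons: int
    n_mesh_synonyms: int
    n_umls_synonyms: int

    def __post_init__(self) -> None:
        if min(self.n_sons, self.n_mesh_synonyms, self.n_umls_synonyms) < 0:
            raise ValueError("feature counts must be non-negative")


@dataclass
class TerminologyIndex:
    descriptors: dict[str, MeshDescriptor]
    atoms: list[ConceptAtom]  # original row order; fixes synonym ordering
    atoms_by_cui: dict[str, list[ConceptAtom]]
    cuis_by_ui: dict[str, frozenset[str]]
    ui_by_tree: dict[str, str] = field(default_factory=dict)

    def descriptor(self, ui: str) -> MeshDescriptor:
        try:
            return self.descriptors[ui]
        except KeyError:
            raise KeyError(f"unknown descriptor ui {ui!r}") from None


def _as_text_stream(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_mesh(stream: IO[str] | str, dialect: str = "tabular") -> list[MeshDescriptor]:
    """Parse MeSH descriptor records from ``stream``.

    ``dialect`` is ``"tabular"`` (TSV: ui, preferred_term, entry_terms
    semicolon-joined, tree_numbers semicolon-joined) or ``"xml"`` (the
    DescriptorRecordSet subset of the NLM MeSH XML format).  Entry-term
    order is preserved; a duplicated descriptor UI is an error.
    """
    if dialect == "tabular":
        descriptors = _parse_mesh_tabular(_as_text_stream(stream))
    elif dialect == "xml":
        descriptors = _parse_mesh_xml(_as_text_stream(stream))
    else:
        raise ValueError(f"unknown MeSH dialect {dialect!r}")

    seen: set[str] = set()
    for d in descriptors:
        if d.ui in seen:
            raise ParseError(f"duplicate descriptor ui {d.ui!r}")
        seen.add(d.ui)
    return descriptors


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(part for part in (p.strip() for p in cell.split(";")) if part)


def _parse_mesh_tabular(stream: IO[str]) -> list[MeshDescriptor]:
    out: list[MeshDescriptor] = []
    for ordinal, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ParseError(
                f"tabular MeSH record {ordinal}: expected 4 tab-separated columns, got {len(cols)}"
            )
        ui, preferred, entries, trees = cols
        if not ui or not preferred:
            raise ParseError(f"tabular MeSH record {ordinal}: empty ui or preferred term")
        try:
            out.append(
                MeshDescriptor(
                    ui=ui,
                    preferred_term=preferred,
                    entry_terms=_split_multi(entries),
                    tree_numbers=_split_multi(trees),
                )
            )
        except ValueError as exc:
            raise ParseError(f"tabular MeSH record {ordinal}: {exc}") from exc
    return out


def _parse_mesh_xml(stream: IO[str]) -> list[MeshDescriptor]:
    try:
        root = ET.parse(stream).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"malformed MeSH XML: {exc}") from exc
    out: list[MeshDescriptor] = []
    for ordinal, rec in enumerate(root.iter("DescriptorRecord"), start=1):
        ui = rec.findtext("DescriptorUI", "").strip()
        preferred = rec.findtext("DescriptorName/String", "").strip()
        if not ui or not preferred:
            raise ParseError(f"MeSH XML record {ordinal}: missing DescriptorUI or DescriptorName")
        pref_norm = normalize_spelling(preferred)
        entry_terms: list[str] = []
        seen_terms = {pref_norm}
        for term in rec.iterfind("ConceptList/Concept/TermList/Term/String"):
            text = (term.text or "").strip()
            norm = normalize_spelling(text)
            if text and norm not in seen_terms:
                entry_terms.append(text)
                seen_terms.add(norm)
        trees = [
            (t.text or "").strip()
            for t in rec.iterfind("TreeNumberList/TreeNumber")
            if (t.text or "").strip()
        ]
        try:
            out.append(
                MeshDescriptor(
                    ui=ui,
                    preferred_term=preferred,
                    entry_terms=tuple(entry_terms),
                    tree_numbers=tuple(trees),
                )
            )
        except ValueError as exc:
            raise ParseError(f"MeSH XML record {ordinal}: {exc}") from exc
    return out


def serialize_mesh_tabular(descriptors: Iterable[MeshDescriptor]) -> str:
    """Inverse of the tabular dialect of :func:`parse_mesh`."""
    lines = []
    for d in descriptors:
        lines.append(
            "\t".join(
                [d.ui, d.preferred_term, ";".join(d.entry_terms), ";".join(d.tree_numbers)]
            )
        )
    return "".join(line + "\n" for line in lines)


def parse_mrconso(
    stream: IO[str] | str,
    source_filter: Iterable[str] = DEFAULT_SOURCES,
    language: str = "ENG",
) -> list[ConceptAtom]:
    """Read concept atoms from a pipe-delimited MRCONSO-layout stream.

    Keeps rows whose SAB is in ``source_filter``, whose LAT equals
    ``language`` and which are not suppressed (SUPPRESS in {N, empty}).
    Row order is preserved (it later fixes synonym ordering).
    """
    wanted = set(source_filter)
    atoms: list[ConceptAtom] = []
    for lineno, raw in enumerate(_as_text_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("|")
        if len(cols) < _MRCONSO_MIN_COLS:
            raise ParseError(
                f"MRCONSO line {lineno}: expected at least {_MRCONSO_MIN_COLS} columns, got {len(cols)}"
            )
        if cols[_MRCONSO_LAT] != language:
            continue
        if cols[_MRCONSO_SAB] not in wanted:
            continue
        if cols[_MRCONSO_SUPPRESS] not in ("N", ""):
            continue
        atoms.append(
            ConceptAtom(
                cui=cols[_MRCONSO_CUI],
                source=cols[_MRCONSO_SAB],
                term=cols[_MRCONSO_STR],
                language=cols[_MRCONSO_LAT],
            )
        )
    return atoms


def mesh_cui_map_from_atoms(
    stream: IO[str] | str, mesh_source: str = "MSH", language: str = "ENG"
) -> dict[str, set[str]]:
    """Derive a descriptor-ui -> CUIs map from MeSH-sourced MRCONSO rows.

    Uses the SDUI column (index 10) of rows whose SAB is ``mesh_source``.
    """
    mapping: dict[str, set[str]] = {}
    for lineno, raw in enumerate(_as_text_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("|")
        if len(cols) < _MRCONSO_MIN_COLS:
            raise ParseError(
                f"MRCONSO line {lineno}: expected at least {_MRCONSO_MIN_COLS} columns, got {len(cols)}"
            )
        if cols[_MRCONSO_LAT] != language or cols[_MRCONSO_SAB] != mesh_source:
            continue
        sdui = cols[10]
        if sdui:
            mapping.setdefault(sdui, set()).add(cols[_MRCONSO_CUI])
    return mapping


def build_index(
    descriptors: Sequence[MeshDescriptor],
    atoms: Sequence[ConceptAtom],
    mesh_cui_map: Mapping[str, Iterable[str]],
) -> TerminologyIndex:
    """Assemble the terminology index.

    ``mesh_cui_map`` associates descriptor UIs with the CUIs whose atoms
    supply UMLS synonyms.  Descriptors without a mapping are allowed
    (they simply have no UMLS synonyms); a mapping that names an unknown
    ui, or a cui with no atoms, is an error.
    """
    by_ui: dict[str, MeshDescriptor] = {}
    for d in descriptors:
        if d.ui in by_ui:
            raise ValueError(f"duplicate descriptor ui {d.ui!r}")
        by_ui[d.ui] = d

    atoms_by_cui: dict[str, list[ConceptAtom]] = {}
    for atom in atoms:
        atoms_by_cui.setdefault(atom.cui, []).append(atom)

    cuis_by_ui: dict[str, frozenset[str]] = {}
    for ui, cuis in mesh_cui_map.items():
        if ui not in by_ui:
            raise ValueError(f"mapping references unknown descriptor ui {ui!r}")
        cuis = frozenset(cuis)
        for cui in cuis:
            if cui not in atoms_by_cui:
                raise ValueError(f"mapping references cui {cui!r} with no atoms")
        cuis_by_ui[ui] = cuis
    for ui in by_ui:
        cuis_by_ui.setdefault(ui, frozenset())

    ui_by_tree: dict[str, str] = {}
    for d in by_ui.values():
        for tree in d.tree_numbers:
            if tree in ui_by_tree and ui_by_tree[tree] != d.ui:
                raise ValueError(f"tree number {tree!r} assigned to two descriptors")
            ui_by_tree[tree] = d.ui

    return TerminologyIndex(
        descriptors=by_ui,
        atoms=list(atoms),
        atoms_by_cui=atoms_by_cui,
        cuis_by_ui=cuis_by_ui,
        ui_by_tree=ui_by_tree,
    )


def _parent_tree(tree: str) -> str | None:
    head, _, tail = tree.rpartition(".")
    return head if tail and head else None


def sons_of(index: TerminologyIndex, ui: str) -> list[MeshDescriptor]:
    """Direct hierarchy children: descriptors one tree segment deeper."""
    parent = index.descriptor(ui)
    parent_trees = set(parent.tree_numbers)
    sons: list[MeshDescriptor] = []
    seen: set[str] = set()
    for d in index.descriptors.values():
        if d.ui == ui or d.ui in seen:
            continue
        if any(_parent_tree(t) in parent_trees for t in d.tree_numbers):
            sons.append(d)
            seen.add(d.ui)
    return sons


def umls_synonyms(index: TerminologyIndex, ui: str, drop_nos: bool = False) -> list[str]:
    """Deduplicated UMLS synonyms of a descriptor, in atom (row) order.

    Every atom term under the descriptor's CUIs is returned once, unless
    its normalized spelling equals the preferred term, an entry term, or
    an earlier synonym.  With ``drop_nos``, terms whose raw form ends in
    ``", NOS"`` (case-insensitive) are skipped too.
    """
    descriptor = index.descriptor(ui)
    taken = {normalize_spelling(descriptor.preferred_term)}
    taken.update(normalize_spelling(t) for t in descriptor.entry_terms)

    cuis = index.cuis_by_ui.get(ui, frozenset())
    out: list[str] = []
    for atom in index.atoms:
        if atom.cui not in cuis:
            continue
        if drop_nos and atom.term.lower().rstrip().endswith(", nos"):
            continue
        norm = normalize_spelling(atom.term)
        if norm in taken:
            continue
        taken.add(norm)
        out.append(atom.term)
    return out


def descriptor_features(index: TerminologyIndex, ui: str) -> DescriptorFeatures:
    """Son count, entry-term count and UMLS-synonym count for ``ui``."""
    descriptor = index.descriptor(ui)
    return DescriptorFeatures(
        ui=ui,
        n_sons=len(sons_of(index, ui)),
        n_mesh_synonyms=len(descriptor.entry_terms),
        n_umls_synonyms=len(umls_synonyms(index, ui, drop_nos=False)),
    )
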