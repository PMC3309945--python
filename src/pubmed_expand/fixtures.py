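"""Self-contained synthetic inputs for every other module.

Generates a mini MeSH (tabular dialect) plus a matching MRCONSO-layout
concept table, citation corpora whose q3/q4/q5 hit counts are known by
construction, and rater judgment tables with tunable agreement.  All
outputs are deterministic functions of the seed.

The well-known "Myocardial Infarction" descriptor — preferred term,
entry-term family, the "Heart attack" cross-vocabulary synonym and the
", NOS" variant — is always embedded verbatim, so the canonical query
strings can be reproduced from generated data alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .query_builder import build_all
from .terminology import (
    DEFAULT_SOURCES,
    TerminologyIndex,
    build_index,
    mesh_cui_map_from_atoms,
    parse_mesh,
    parse_mrconso,
    umls_synonyms,
)

__all__ = [
    "MI_UI",
    "FixtureConfig",
    "TerminologyFixture",
    "CorpusFixture",
    "gen_terminology",
    "index_from_fixture",
    "gen_corpus",
    "gen_judgments",
    "expected_kappa",
]

#: Descriptor UI of the embedded Myocardial Infarction record.
MI_UI = "D009203"
_MI_CUI = "C0027051"
_MI_PREFERRED = "Myocardial Infarction"
_MI_ENTRY_TERMS = (
    "Infarct, Myocardial",
    "Infarction, Myocardial",
    "Myocardial Infarcts",
    "Myocardial Infarct",
    "Infarcts, Myocardial",
    "Myocardial Infarctions",
    "Infarctions, Myocardial",
)
_MI_TREE = "C14.280.647.500"

_CATEGORIES = ("bad", "partial", "full")

# Filler vocabulary for generated titles/abstracts.  Deliberately
# disjoint from every token of every generated or embedded term, so
# filler text can never create an accidental phrase match.
_FILLER = (
    "the", "of", "with", "cohort", "randomized", "trial", "outcomes",
    "baseline", "followup", "analysis", "between", "groups", "observed",
    "measured", "results", "clinical", "study", "patients", "treatment",
    "effect", "during", "reported", "registry", "survey",
)
_RESERVED_TOKENS = frozenset(_FILLER) | {
    "myocardial", "infarction", "infarct", "infarcts", "infarctions",
    "heart", "attack", "nos",
}

_SYLLABLES = (
    "ba", "do", "fi", "gu", "ke", "lo", "mu", "ni",
    "pa", "re", "su", "ta", "vo", "wi", "za", "xe",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the generators; a fixed seed gives byte-identical output."""

    n_descriptors: int = 8
    synonyms_per_descriptor: tuple[int, int] = (0, 4)  # inclusive range
    n_citations: int = 200
    premedline_fraction: float = 0.5
    oldmedline_fraction: float = 0.05
    synonym_hit_rate: float = 0.3
    rater_agreement: float = 0.8
    n_raters: int = 4
    n_judgment_rows: int = 100
    latent_dist: tuple[float, float, float] = (0.3, 0.3, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("premedline_fraction", "oldmedline_fraction", "synonym_hit_rate", "rater_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.premedline_fraction + self.oldmedline_fraction > 1.0:
            raise ValueError("premedline_fraction + oldmedline_fraction must not exceed 1")
        if abs(sum(self.latent_dist) - 1.0) > 1e-9:
            raise ValueError("latent_dist must sum to 1")
        lo, hi = self.synonyms_per_descriptor
        if lo < 0 or hi < lo:
            raise ValueError("synonyms_per_descriptor must be a non-negative (lo, hi) range")

    @classmethod
    def from_file(cls, path: str | Path) -> "FixtureConfig":
        """Read a key=value config file mirroring the field names."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("synonyms_per_descriptor", "latent_dist"):
                kwargs[key] = tuple(float(v) if "." in v else int(v) for v in value.split(","))
            elif key in ("n_descriptors", "n_citations", "n_raters", "n_judgment_rows", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        if "latent_dist" in kwargs:
            kwargs["latent_dist"] = tuple(float(v) for v in kwargs["latent_dist"])
        return cls(**kwargs)


@dataclass(frozen=True)
class TerminologyFixture:
    mesh_tsv: str
    mrconso: str
    mapping: dict[str, set[str]] = field(hash=False)


@dataclass(frozen=True)
class CorpusFixture:
    jsonl: str
    manifest: dict = field(hash=False)


def _word_factory(rng: np.random.Generator):
    used: set[str] = set(_RESERVED_TOKENS)

    def fresh_word() -> str:
        while True:
            word = "".join(rng.choice(_SYLLABLES) for _ in range(3))
            if word not in used:
                used.add(word)
                return word

    return fresh_word


def _mrconso_row(cui: str, sab: str, tty: str, term: str, sdui: str = "", suppress: str = "N") -> str:
    # CUI|LAT|TS|LUI|STT|SUI|ISPREF|AUI|SAUI|SCUI|SDUI|SAB|TTY|CODE|STR|SRL|SUPPRESS|CVF
    fields = [
        cui, "ENG", "P", "L0000000", "PF", "S0000000", "Y", "A0000000",
        "", "", sdui, sab, tty, "NOCODE", term, "0", suppress, "",
    ]
    return "|".join(fields) + "|"


def gen_terminology(config: FixtureConfig) -> TerminologyFixture:
    """Mini-MeSH (tabular) plus mini-MRCONSO with a derivable ui->cui map.

    Every generated term is a two-word phrase whose words occur nowhere
    else, so no term can occur inside another; the embedded Myocardial
    Infarction record is the only descriptor with overlapping spellings.
    A suppressed row and a non-English row are planted to exercise the
    MRCONSO filters.
    """
    rng = np.random.default_rng(config.seed)
    fresh_word = _word_factory(rng)
    sources = sorted(DEFAULT_SOURCES)

    mesh_rows: list[str] = []
    mrconso_rows: list[str] = []

    # -- the embedded canonical descriptor --------------------------------
    mesh_rows.append(
        "\t".join([MI_UI, _MI_PREFERRED, ";".join(_MI_ENTRY_TERMS), _MI_TREE])
    )
    mrconso_rows.append(_mrconso_row(_MI_CUI, "MSH", "MH", _MI_PREFERRED, sdui=MI_UI))
    for entry in _MI_ENTRY_TERMS:
        mrconso_rows.append(_mrconso_row(_MI_CUI, "MSH", "ET", entry, sdui=MI_UI))
    mrconso_rows.append(_mrconso_row(_MI_CUI, "WHOART", "PT", "Myocardial infarction"))
    mrconso_rows.append(_mrconso_row(_MI_CUI, "WHOART", "PT", "Heart attack"))
    mrconso_rows.append(_mrconso_row(_MI_CUI, "SNOMEDCT", "PT", "Myocardial infarction, NOS"))
    # planted filter fodder: suppressed and non-English duplicates
    mrconso_rows.append(_mrconso_row(_MI_CUI, "MDR", "LLT", "Cardiac rupture event", suppress="Y"))
    mrconso_rows.append(
        _mrconso_row(_MI_CUI, "WHOART", "PT", "Infarctus du myocarde").replace("|ENG|", "|FRE|")
    )

    # -- randomized descriptors -------------------------------------------
    trees: list[str] = []
    for i in range(config.n_descriptors):
        ui = f"D9{i:05d}"
        cui = f"C9{i:06d}"
        preferred = f"{fresh_word()} {fresh_word()}".title()
        n_entries = int(rng.integers(0, 4))
        entries = [f"{fresh_word()} {fresh_word()}".title() for _ in range(n_entries)]
        lo, hi = config.synonyms_per_descriptor
        n_syn = int(rng.integers(lo, hi + 1))
        synonyms = [f"{fresh_word()} {fresh_word()}".title() for _ in range(n_syn)]

        if trees and rng.random() < 0.6:
            parent = trees[int(rng.integers(0, len(trees)))]
            tree = f"{parent}.{500 + i}"
        else:
            tree = f"C{60 + i:02d}"
        trees.append(tree)

        mesh_rows.append("\t".join([ui, preferred, ";".join(entries), tree]))
        # the last descriptor is left unmapped (no MRCONSO presence)
        if i == config.n_descriptors - 1:
            continue
        mrconso_rows.append(_mrconso_row(cui, "MSH", "MH", preferred, sdui=ui))
        for entry in entries:
            mrconso_rows.append(_mrconso_row(cui, "MSH", "ET", entry, sdui=ui))
        for syn in synonyms:
            sab = sources[int(rng.integers(0, len(sources)))]
            mrconso_rows.append(_mrconso_row(cui, sab, "PT", syn))
        if rng.random() < 0.5:  # same-spelling duplicate, must dedup away
            mrconso_rows.append(_mrconso_row(cui, "MDR", "LLT", preferred.lower()))

    mesh_tsv = "".join(r + "\n" for r in mesh_rows)
    mrconso = "".join(r + "\n" for r in mrconso_rows)
    mapping = mesh_cui_map_from_atoms(mrconso)
    return TerminologyFixture(mesh_tsv=mesh_tsv, mrconso=mrconso, mapping=mapping)


def index_from_fixture(fixture: TerminologyFixture) -> TerminologyIndex:
    """Parse a generated terminology fixture into a TerminologyIndex."""
    descriptors = parse_mesh(StringIO(fixture.mesh_tsv), dialect="tabular")
    atoms = parse_mrconso(StringIO(fixture.mrconso), source_filter=DEFAULT_SOURCES | {"MSH"})
    return build_index(descriptors, atoms, fixture.mapping)


def _phrase_tokens(term: str) -> tuple[str, ...]:
    import re

    return tuple(re.findall(r"[a-z0-9]+", term.lower()))


def _contains(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    n, m = len(haystack), len(needle)
    return any(tuple(haystack[i : i + m]) == tuple(needle) for i in range(n - m + 1))


def _safe_synonyms(index: TerminologyIndex, ui: str) -> list[str]:
    """Synonyms that do not contain the preferred/entry token sequences.

    Embedding one of these in a citation makes it a q4-only (hence q5)
    hit; a synonym like "myocardial infarction, nos" would also trip the
    q3 phrase clauses and is therefore unusable for that purpose.
    """
    d = index.descriptor(ui)
    blocked = [_phrase_tokens(d.preferred_term)] + [_phrase_tokens(t) for t in d.entry_terms]
    safe = []
    for syn in umls_synonyms(index, ui, drop_nos=False):
        tokens = _phrase_tokens(syn)
        if not any(_contains(tokens, b) for b in blocked):
            safe.append(syn)
    return safe


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    return [_FILLER[int(rng.integers(0, len(_FILLER)))] for _ in range(n)]


def _sentence(rng: np.random.Generator, phrase: Optional[str]) -> str:
    words = _filler(rng, int(rng.integers(4, 9)))
    if phrase is not None:
        pos = int(rng.integers(0, len(words) + 1))
        words[pos:pos] = [phrase.lower()]
    text = " ".join(words)
    return text[0].upper() + text[1:] + "."


def gen_corpus(config: FixtureConfig, index: TerminologyIndex) -> CorpusFixture:
    """Citation corpus whose per-descriptor q3/q4/q5 counts are known.

    MEDLINE-stratum citations carry the descriptor heading and filler
    text; OldMedline citations embed a preferred/entry phrase (they hit
    q3's title/abstract block but are excluded from q4's); premedline
    citations embed, per the configured rates, either a q5-safe synonym,
    a preferred/entry phrase, or nothing.  The manifest records the
    resulting counts, derived purely from these construction choices.
    """
    rng = np.random.default_rng(config.seed + 1)
    uis = list(index.descriptors)
    safe = {ui: _safe_synonyms(index, ui) for ui in uis}
    counts = {ui: {"q3": 0, "q4": 0, "q5": 0} for ui in uis}
    strata = {"MEDLINE": 0, "OldMedline": 0, "premedline": 0}

    lines: list[str] = []
    base_date = date(2010, 1, 1)
    for j in range(config.n_citations):
        ui = uis[int(rng.integers(0, len(uis)))]
        d = index.descriptor(ui)
        pmid = str(21_000_000 + j)
        pub = base_date + timedelta(days=int(rng.integers(0, 730)))
        mesh_terms: tuple[str, ...] = ()
        phrase: Optional[str] = None

        u = rng.random()
        if u < config.premedline_fraction:
            stratum = "premedline"
            r = rng.random()
            if r < config.synonym_hit_rate and safe[ui]:
                phrase = safe[ui][int(rng.integers(0, len(safe[ui])))]
                counts[ui]["q4"] += 1
                counts[ui]["q5"] += 1
            elif r < config.synonym_hit_rate + 0.5 * (1 - config.synonym_hit_rate):
                pool = [d.preferred_term, *d.entry_terms]
                phrase = pool[int(rng.integers(0, len(pool)))]
                counts[ui]["q3"] += 1
                counts[ui]["q4"] += 1
        elif u < config.premedline_fraction + config.oldmedline_fraction:
            stratum = "OldMedline"
            pool = [d.preferred_term, *d.entry_terms]
            phrase = pool[int(rng.integers(0, len(pool)))]
            counts[ui]["q3"] += 1  # q3 excludes only MEDLINE[SB]; q4 excludes this stratum
        else:
            stratum = "MEDLINE"
            mesh_terms = (d.preferred_term,)
            counts[ui]["q3"] += 1
            counts[ui]["q4"] += 1
        strata[stratum] += 1

        in_title = phrase is not None and rng.random() < 0.5
        title = _sentence(rng, phrase if in_title else None)
        abstract = " ".join(
            [_sentence(rng, phrase if (phrase is not None and not in_title) else None)]
            + [_sentence(rng, None) for _ in range(int(rng.integers(1, 3)))]
        )
        record = {
            "pmid": pmid,
            "title": title,
            "abstract": abstract,
            "mesh_terms": list(mesh_terms),
            "subsets": [stratum],
            "pub_date": pub.isoformat(),
        }
        lines.append(json.dumps(record, sort_keys=True))

    manifest = {
        "n_citations": config.n_citations,
        "strata": strata,
        "per_descriptor": counts,
    }
    return CorpusFixture(jsonl="".join(line + "\n" for line in lines), manifest=manifest)


def gen_judgments(config: FixtureConfig) -> str:
    """Long-format judgments CSV with tunable inter-rater agreement.

    Each row draws a latent category from ``latent_dist``; each rater
    reports it with probability ``rater_agreement`` and otherwise picks
    one of the two other categories uniformly.
    """
    rng = np.random.default_rng(config.seed + 2)
    alpha = config.rater_agreement
    raters = [f"rater{r + 1}" for r in range(config.n_raters)]
    lines = ["term,rank,pmid,rater,rating"]
    for i in range(config.n_judgment_rows):
        term = f"term{i // 20 + 1}"
        rank = i % 20 + 1
        pmid = str(22_000_000 + i)
        latent = int(rng.choice(3, p=list(config.latent_dist)))
        for rater in raters:
            if rng.random() < alpha:
                cat = latent
            else:
                others = [c for c in range(3) if c != latent]
                cat = others[int(rng.integers(0, 2))]
            lines.append(f"{term},{rank},{pmid},{rater},{_CATEGORIES[cat]}")
    return "".join(line + "\n" for line in lines)


def expected_kappa(alpha: float, latent_dist: Sequence[float] = (0.3, 0.3, 0.4)) -> float:
    """Population kappa induced by the judgment noise model.

    Two raters agree when both report the latent category (alpha^2) or
    both err to the same one of the two alternatives ((1-alpha)^2 / 2);
    chance agreement comes from the marginal category probabilities
    p_j = alpha*pi_j + (1-alpha)*(1-pi_j)/2.
    """
    pi = np.asarray(latent_dist, dtype=float)
    p_o = alpha**2 + (1 - alpha) ** 2 / 2.0
    p_j = alpha * pi + (1 - alpha) * (1 - pi) / 2.0
    p_e = float(np.square(p_j).sum())
    return (p_o - p_e) / (1.0 - p_e)


def build_canonical_queries(drop_nos: bool = False, seed: int = 0) -> dict[str, str]:
    """Rendered q1..q5 for the embedded Myocardial Infarction descriptor.

    q1/q3/q4/q5 come from mapping the preferred term; q2 from mapping the
    "Myocardial Infarct" entry term, as a user would type it.
    """
    fixture = gen_terminology(FixtureConfig(seed=seed))
    index = index_from_fixture(fixture)
    queries = build_all(index, _MI_PREFERRED, drop_nos=drop_nos)
    queries["q2"] = build_all(index, "Myocardial Infarct", drop_nos=drop_nos)["q2"]
    return {label: q.render() for label, q in sorted(queries.items())}
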