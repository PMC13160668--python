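"""Bibliographic record ingest, filtering, keyword normalization, and descriptive stats.

The canonical in-memory corpus is a list of :class:`BibRecord`; the canonical
on-disk form is JSON Lines with one record per line. PubMed MEDLINE exports
(``.nbib``/``.txt``) and CSV files are converted on ingest.
"""

from __future__ import annotations

import csv
import datetime
import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "BibRecord",
    "NormalizationRules",
    "CountsLog",
    "ParseReport",
    "parse_records",
    "write_jsonl",
    "filter_complete",
    "normalize_keywords",
    "corpus_stats",
    "extract_country",
]

_YEAR_RE = re.compile(r"\b(\d{4})\b")


@dataclass
class BibRecord:
    """One publication's metadata.

    ``year`` is ``None`` when no 4-digit year could be extracted from the
    publication-date field; such records are excluded by :func:`filter_complete`.
    ``rcr`` is the relative citation ratio, a field- and time-normalized
    citation metric used only for post-hoc external validation downstream.
    """

    record_id: str
    title: str = ""
    abstract: str = ""
    year: Optional[int] = None
    journal: str = ""
    author_keywords: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    affiliations: list[str] = field(default_factory=list)
    country: Optional[str] = None
    rcr: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BibRecord":
        known = {f: d.get(f) for f in cls.__dataclass_fields__ if f in d}
        rec = cls(**known)
        rec.author_keywords = list(rec.author_keywords or [])
        rec.mesh_terms = list(rec.mesh_terms or [])
        rec.affiliations = list(rec.affiliations or [])
        if rec.year is not None:
            rec.year = int(rec.year)
        if rec.rcr is not None:
            rec.rcr = float(rec.rcr)
            if rec.rcr < 0:
                raise ValueError(f"negative RCR for record {rec.record_id}")
        return rec


@dataclass
class ParseReport:
    n_parsed: int = 0
    skipped: list[str] = field(default_factory=list)
    missing_year: list[str] = field(default_factory=list)
    missing_abstract: list[str] = field(default_factory=list)


@dataclass
class CountsLog:
    """PRISMA-style numeric counts for the identification/retention flow."""

    n_retrieved: int
    n_missing_abstract_or_keywords: int
    n_retained: int
    query_text: str = ""
    timestamps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_retained != self.n_retrieved - self.n_missing_abstract_or_keywords:
            raise ValueError("counts log arithmetic identity violated")

    def write(self, path: str | Path) -> None:
        lines = [
            f"retrieved: {self.n_retrieved}",
            f"excluded (missing abstract/keywords/year-out-of-window): "
            f"{self.n_missing_abstract_or_keywords}",
            f"retained: {self.n_retained}",
            f"query: {self.query_text}",
        ] + [f"timestamp: {t}" for t in self.timestamps]
        Path(path).write_text("\n".join(lines) + "\n")


def _check_map(name: str, mapping: dict[str, str]) -> dict[str, str]:
    """Lowercase a normalization map and reject cycles / non-idempotence."""
    m = {k.strip().lower(): v.strip().lower() for k, v in mapping.items()}
    for k, v in m.items():
        if v in m and m[v] != v:
            raise ValueError(
                f"{name} is not idempotent: {k!r} -> {v!r} -> {m[v]!r}"
            )
    return m


@dataclass
class NormalizationRules:
    """User-editable keyword standardization tables.

    Each map must be idempotent (applying it twice changes nothing); a chain
    a->b with b->c (c != b) is rejected at construction, which also rules out
    cycles a->b, b->a.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    abbreviation_map: dict[str, str] = field(default_factory=dict)
    mesh_entry_map: dict[str, str] = field(default_factory=dict)
    plural_folding: bool = True

    def __post_init__(self) -> None:
        self.synonym_map = _check_map("synonym_map", self.synonym_map)
        self.abbreviation_map = _check_map("abbreviation_map", self.abbreviation_map)
        self.mesh_entry_map = _check_map("mesh_entry_map", self.mesh_entry_map)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationRules":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            synonym_map=data.get("synonym_map", {}) or {},
            abbreviation_map=data.get("abbreviation_map", {}) or {},
            mesh_entry_map=data.get("mesh_entry_map", {}) or {},
            plural_folding=bool(data.get("plural_folding", True)),
        )


# ---------------------------------------------------------------------------
# parsing


def _extract_year(date_field: str) -> Optional[int]:
    m = _YEAR_RE.search(date_field or "")
    return int(m.group(1)) if m else None


def _parse_medline(path: Path, report: ParseReport) -> list[BibRecord]:
    from Bio import Medline

    corpus: list[BibRecord] = []
    with open(path, encoding="utf-8") as fh:
        for entry in Medline.parse(fh):
            pmid = entry.get("PMID")
            if not pmid:
                report.skipped.append("record without PMID")
                continue
            year = _extract_year(entry.get("DP", ""))
            rec = BibRecord(
                record_id=str(pmid),
                title=(entry.get("TI") or "").strip(),
                abstract=(entry.get("AB") or "").strip(),
                year=year,
                journal=(entry.get("JT") or entry.get("TA") or "").strip(),
                author_keywords=list(entry.get("OT", [])),
                mesh_terms=list(entry.get("MH", [])),
                affiliations=list(entry.get("AD", [])),
            )
            if year is None:
                report.missing_year.append(rec.record_id)
            if not rec.abstract:
                report.missing_abstract.append(rec.record_id)
            corpus.append(rec)
    return corpus


def _split_list(raw: str) -> list[str]:
    return [p.strip() for p in re.split(r"[;|]", raw or "") if p.strip()]


def _parse_csv(path: Path, report: ParseReport) -> list[BibRecord]:
    corpus: list[BibRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            rid = (row.get("record_id") or row.get("pmid") or "").strip()
            if not rid:
                report.skipped.append(f"csv row {i + 1}: no record_id")
                continue
            year = _extract_year(str(row.get("year", "")))
            rec = BibRecord(
                record_id=rid,
                title=(row.get("title") or "").strip(),
                abstract=(row.get("abstract") or "").strip(),
                year=year,
                journal=(row.get("journal") or "").strip(),
                author_keywords=_split_list(row.get("author_keywords", "")),
                mesh_terms=_split_list(row.get("mesh_terms", "")),
                affiliations=_split_list(row.get("affiliations", "")),
                country=(row.get("country") or None),
                rcr=float(row["rcr"]) if row.get("rcr") not in (None, "") else None,
            )
            if year is None:
                report.missing_year.append(rid)
            corpus.append(rec)
    return corpus


def _parse_jsonl(path: Path, report: ParseReport) -> list[BibRecord]:
    corpus: list[BibRecord] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = BibRecord.from_dict(json.loads(line))
            except (json.JSONDecodeError, TypeError, ValueError) as exc:
                report.skipped.append(f"jsonl line {i + 1}: {exc}")
                continue
            if rec.year is None:
                report.missing_year.append(rec.record_id)
            corpus.append(rec)
    return corpus


def parse_records(
    path: str | Path, format: str = "jsonl"
) -> tuple[list[BibRecord], ParseReport]:
    """Read bibliographic records from ``path``.

    ``format`` is one of ``medline`` (PubMed ``.nbib``/``.txt`` export),
    ``csv``, or ``jsonl`` (the canonical schema). Malformed records are
    skipped with an entry in the parse report, never dropped silently.
    An unreadable file raises ``OSError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ParseReport()
    parsers = {"medline": _parse_medline, "csv": _parse_csv, "jsonl": _parse_jsonl}
    if format not in parsers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(parsers)}")
    corpus = parsers[format](path, report)
    ids = [r.record_id for r in corpus]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record_id(s) in corpus: {dupes[:5]}")
    report.n_parsed = len(corpus)
    return corpus, report


def write_jsonl(corpus: Iterable[BibRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# filtering


def filter_complete(
    corpus: list[BibRecord],
    window: tuple[int, int],
    query_text: str = "",
) -> tuple[list[BibRecord], CountsLog]:
    """Retain records with a non-empty abstract, non-empty author keywords,
    and a known year inside the inclusive ``window``; return the retained
    corpus and a PRISMA-style counts log."""
    start, end = window
    if start > end:
        raise ValueError(f"inverted year window {window}")
    retained = [
        r
        for r in corpus
        if r.abstract.strip()
        and any(k.strip() for k in r.author_keywords)
        and r.year is not None
        and start <= r.year <= end
    ]
    log = CountsLog(
        n_retrieved=len(corpus),
        n_missing_abstract_or_keywords=len(corpus) - len(retained),
        n_retained=len(retained),
        query_text=query_text,
        timestamps=[datetime.datetime.now(datetime.timezone.utc).isoformat()],
    )
    return retained, log


# ---------------------------------------------------------------------------
# keyword normalization


def _apply_maps(kw: str, rules: NormalizationRules) -> str:
    kw = rules.abbreviation_map.get(kw, kw)
    kw = rules.synonym_map.get(kw, kw)
    kw = rules.mesh_entry_map.get(kw, kw)
    return kw


def normalize_keywords(
    corpus: list[BibRecord], rules: Optional[NormalizationRules] = None
) -> list[BibRecord]:
    """Standardize author keywords: lowercase, trim, expand abbreviations,
    map synonyms and MeSH entry terms, fold plurals, deduplicate per record.

    Plural folding is conservative: a trailing ``s``/``es`` is stripped only
    when the singular form is attested elsewhere (in the corpus vocabulary
    after mapping, or as a map target), so isolated terms like "measles" are
    left alone. The operation is idempotent.
    """
    rules = rules or NormalizationRules()

    def base(kw: str) -> str:
        kw = re.sub(r"\s+", " ", kw.strip().lower())
        return _apply_maps(kw, rules)

    vocab = {base(k) for r in corpus for k in r.author_keywords if k.strip()}
    attested = vocab | set(rules.synonym_map.values()) | set(
        rules.abbreviation_map.values()
    ) | set(rules.mesh_entry_map.values())

    def fold(kw: str) -> str:
        if not rules.plural_folding:
            return kw
        if kw.endswith("s") and kw[:-1] in attested:
            return kw[:-1]
        if kw.endswith("es") and kw[:-2] in attested:
            return kw[:-2]
        return kw

    out = []
    for rec in corpus:
        seen: dict[str, None] = {}
        for kw in rec.author_keywords:
            if not kw.strip():
                continue
            k = _apply_maps(fold(base(kw)), rules)
            if k:
                seen.setdefault(k)
        new = BibRecord.from_dict(rec.to_dict())
        new.author_keywords = list(seen)
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# descriptive statistics


def _country_list() -> set[str]:
    text = resources.files("themescape.data").joinpath("countries.txt").read_text()
    return {line.strip().lower() for line in text.splitlines() if line.strip()}


def extract_country(affiliation: str, countries: Optional[set[str]] = None) -> str:
    """Heuristic country from the last comma-separated token of an affiliation,
    matched case-insensitively against the bundled country-name list."""
    if not affiliation:
        return "unknown"
    countries = countries or _country_list()
    token = affiliation.rsplit(",", 1)[-1].strip().rstrip(".").strip()
    token = re.sub(r"\s+", " ", token)
    return token if token.lower() in countries else "unknown"


def _top_table(values: list[str], top_n: int, n_total: int) -> pd.DataFrame:
    s = pd.Series([v for v in values if v], dtype=object)
    if s.empty:
        return pd.DataFrame(columns=["value", "n", "pct"])
    counts = s.value_counts()
    counts = counts.iloc[: top_n]
    return pd.DataFrame(
        {
            "value": counts.index,
            "n": counts.values,
            "pct": [round(100.0 * c / n_total, 1) for c in counts.values],
        }
    )


def corpus_stats(
    corpus: list[BibRecord],
    top_n: int = 10,
    window: Optional[tuple[int, int]] = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive tables: annual counts over the full window (zero-filled)
    plus top-N countries, affiliations, journals, and keywords with
    percentages of the retained total, rounded to one decimal."""
    n = len(corpus)
    if n == 0:
        return {
            k: pd.DataFrame()
            for k in ("annual_counts", "countries", "affiliations", "journals", "keywords")
        }
    years = [r.year for r in corpus if r.year is not None]
    lo, hi = window if window else (min(years), max(years))
    annual = pd.DataFrame(
        {
            "year": list(range(lo, hi + 1)),
            "n": [sum(1 for y in years if y == yy) for yy in range(lo, hi + 1)],
        }
    )
    countries = _country_list()
    ctry = [
        r.country or (extract_country(r.affiliations[0], countries) if r.affiliations else "unknown")
        for r in corpus
    ]
    return {
        "annual_counts": annual,
        "countries": _top_table([c for c in ctry if c != "unknown"], top_n, n),
        "affiliations": _top_table(
            [r.affiliations[0] for r in corpus if r.affiliations], top_n, n
        ),
        "journals": _top_table([r.journal for r in corpus], top_n, n),
        "keywords": _top_table(
            [k for r in corpus for k in dict.fromkeys(r.author_keywords)], top_n, n
        ),
    }
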