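"""Compiled cytogenetic records of fungus-farming ants.

A record is one row of a compilation table in the style of the Ant
Chromosome Database: taxon, diploid/haploid chromosome count, haploid
genome size (1C, pg), provenance, a karyotype formula string such as
``"12 m + 6 sm + 4 a"`` and a five-position heterochromatin C-band code
(centromeric, pericentromeric, interstitial, short arm, long arm — each
positive, negative or unknown).

The packaged reference table (``data/attina_records.tsv``) transcribes
the published compilation for the subtribe Attina (61 records across 12
genera, including the five karyotypes newly described alongside it).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FormulaParseError",
    "HeterochromatinPattern",
    "CytogeneticRecord",
    "RecordSummary",
    "parse_formula",
    "format_formula",
    "validate_record",
    "summarize_records",
    "band_richness",
    "band_richness_by_threshold",
    "gs_exceptions",
    "normalize_taxon",
    "read_records",
    "write_records",
    "load_reference_records",
    "records_to_traits",
]

MORPHOLOGY_LABELS = ("m", "sm", "st", "t", "a")

#: Known misspellings in published compilations, normalized on input.
TAXON_SYNONYMS = {
    "Serycomyrmex": "Sericomyrmex",
    "Myrmicocripta": "Myrmicocrypta",
    "Mycetomollerius": "Mycetomoellerius",
}

BAND_POSITIONS = ("C", "PC", "IN", "SA", "LA")

_MORPHOSPECIES_RE = re.compile(r"^sp\.?(\s*\d+|\d*)$", re.IGNORECASE)


class FormulaParseError(ValueError):
    """A karyotype formula string could not be parsed."""


def parse_formula(text: str) -> Counter:
    """Parse ``"12 m + 6 sm + 4 a"`` into morphology counts.

    Terms are ``<int> <label>`` joined by ``+``; whitespace is free and
    duplicate labels are summed. Raises FormulaParseError with the
    offending token otherwise.
    """
    if text is None or not str(text).strip():
        raise FormulaParseError("empty formula string")
    counts: Counter = Counter()
    for term in str(text).split("+"):
        term = term.strip()
        if not term:
            raise FormulaParseError(f"empty term in formula {text!r}")
        match = re.fullmatch(r"(\d+)\s*([A-Za-z]+)", term)
        if not match:
            raise FormulaParseError(f"malformed term {term!r} in formula {text!r}")
        count, label = int(match.group(1)), match.group(2)
        if label not in MORPHOLOGY_LABELS:
            raise FormulaParseError(f"unknown morphology label {label!r} in {term!r}")
        counts[label] += count
    return counts


def format_formula(formula: Mapping[str, int]) -> str:
    """Canonical formula string: labels in order m, sm, st, t, a."""
    parts = [
        f"{formula[label]} {label}"
        for label in MORPHOLOGY_LABELS
        if formula.get(label)
    ]
    if not parts:
        raise FormulaParseError("formula has no positive counts")
    return " + ".join(parts)


@dataclass(frozen=True)
class HeterochromatinPattern:
    """C-band presence at the five coded positions (None = unknown)."""

    c: Optional[bool] = None
    pc: Optional[bool] = None
    interstitial: Optional[bool] = None
    short_arm: Optional[bool] = None
    long_arm: Optional[bool] = None

    def positions(self) -> tuple[Optional[bool], ...]:
        return (self.c, self.pc, self.interstitial, self.short_arm, self.long_arm)

    @property
    def is_known(self) -> bool:
        return any(p is not None for p in self.positions())


def band_richness(pattern: HeterochromatinPattern) -> int:
    """Number of positions with a positive heterochromatin block."""
    return sum(1 for p in pattern.positions() if p is True)


def normalize_taxon(name: str) -> str:
    """Normalize a taxon name: strip markup, collapse whitespace,
    capitalize the genus, and apply the packaged synonym map."""
    name = re.sub(r"[*_]", "", str(name))
    parts = name.split()
    if not parts:
        raise ValueError("empty taxon name")
    genus = parts[0].capitalize()
    genus = TAXON_SYNONYMS.get(genus, genus)
    rest = [p.lower() if not _MORPHOSPECIES_RE.match(p) else p.lower() for p in parts[1:]]
    return " ".join([genus, *rest])


@dataclass(frozen=True)
class CytogeneticRecord:
    """One compiled cytogenetic record (one table row)."""

    taxon: str
    diploid_number: Optional[int] = None
    haploid_number: Optional[int] = None
    genome_size_1c: Optional[float] = None
    locality: Optional[str] = None
    country: Optional[str] = None
    formula: Optional[Counter] = None
    pattern: Optional[HeterochromatinPattern] = None
    source: str = ""
    is_new_report: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon", normalize_taxon(self.taxon))
        if self.diploid_number is None and self.haploid_number is None:
            raise ValueError(f"{self.taxon}: neither 2n nor n present")
        if (
            self.diploid_number is not None
            and self.haploid_number is not None
            and self.diploid_number != 2 * self.haploid_number
        ):
            raise ValueError(
                f"{self.taxon}: 2n={self.diploid_number} inconsistent with n={self.haploid_number}"
            )
        if self.genome_size_1c is not None and not self.genome_size_1c > 0:
            raise ValueError(f"{self.taxon}: non-positive genome size")

    @property
    def genus(self) -> str:
        return self.taxon.split()[0]

    @property
    def epithet(self) -> str:
        return " ".join(self.taxon.split()[1:])

    @property
    def is_unidentified(self) -> bool:
        """True for morphospecies records ("sp.", "sp.1", "sp. 2", ...)."""
        return bool(_MORPHOSPECIES_RE.match(self.epithet.split()[0])) if self.epithet else False

    @property
    def effective_haploid(self) -> int:
        """n, taken directly or as 2n/2 (rounded down for odd 2n)."""
        if self.haploid_number is not None:
            return self.haploid_number
        return self.diploid_number // 2

    @property
    def effective_diploid(self) -> int:
        if self.diploid_number is not None:
            return self.diploid_number
        return 2 * self.haploid_number


def validate_record(record: CytogeneticRecord) -> str:
    """Check the karyotype formula against the chromosome count.

    Published compilations mix diploid and haploid formula conventions,
    so the status distinguishes them: ``diploid_consistent`` when the
    formula sums to 2n, ``haploid_consistent`` when it sums to n,
    ``inconsistent`` otherwise and ``no_formula`` when absent.
    """
    if record.formula is None:
        return "no_formula"
    total = sum(record.formula.values())
    two_n = record.effective_diploid
    if total == two_n:
        return "diploid_consistent"
    if 2 * total == two_n:
        return "haploid_consistent"
    return "inconsistent"


@dataclass(frozen=True)
class RecordSummary:
    """Descriptive statistics over a set of records."""

    record_count: int
    unidentified_count: int
    taxa_with_gs_count: int
    min_haploid: int
    max_haploid: int
    mean_gs: Optional[float]
    sd_gs: Optional[float]
    haploid_frequency: dict[int, int]
    genus_haploid_sets: dict[str, set[int]]
    distinct_taxon_karyotype_count: int
    new_report_count: int


def summarize_records(records: Sequence[CytogeneticRecord]) -> RecordSummary:
    """Summarize a record compilation.

    Counting rules: "unidentified" counts *records* whose epithet is a
    morphospecies label; "taxa with genome size" counts *distinct taxon
    names* carrying a non-missing 1C value (subspecies and morphospecies
    labels are distinct taxa, repeated populations of one taxon count
    once); the genome-size mean/SD average each non-missing record-level
    value once, without deduplication.
    """
    if not records:
        raise ValueError("empty record list")
    haploids = [r.effective_haploid for r in records]
    gs_values = [r.genome_size_1c for r in records if r.genome_size_1c is not None]
    mean_gs = sd_gs = None
    if gs_values:
        mean_gs = sum(gs_values) / len(gs_values)
        if len(gs_values) > 1:
            var = sum((v - mean_gs) ** 2 for v in gs_values) / (len(gs_values) - 1)
            sd_gs = var**0.5
        else:
            sd_gs = 0.0
    genus_sets: dict[str, set[int]] = {}
    for r in records:
        genus_sets.setdefault(r.genus, set()).add(r.effective_haploid)
    karyo_keys = {
        (r.taxon, format_formula(r.formula) if r.formula else f"2n={r.effective_diploid}")
        for r in records
    }
    return RecordSummary(
        record_count=len(records),
        unidentified_count=sum(r.is_unidentified for r in records),
        taxa_with_gs_count=len({r.taxon for r in records if r.genome_size_1c is not None}),
        min_haploid=min(haploids),
        max_haploid=max(haploids),
        mean_gs=mean_gs,
        sd_gs=sd_gs,
        haploid_frequency=dict(sorted(Counter(haploids).items())),
        genus_haploid_sets=genus_sets,
        distinct_taxon_karyotype_count=len(karyo_keys),
        new_report_count=sum(r.is_new_report for r in records),
    )


@dataclass(frozen=True)
class BandRichnessGroup:
    size: int
    mean_richness: Optional[float]
    beyond_centromere_count: int


@dataclass(frozen=True)
class BandRichnessComparison:
    n_threshold: int
    low: BandRichnessGroup   # records with n <= threshold
    high: BandRichnessGroup  # records with n > threshold


def band_richness_by_threshold(
    records: Sequence[CytogeneticRecord], n_threshold: int = 15
) -> BandRichnessComparison:
    """Compare heterochromatin band richness below/above a haploid count.

    Only records with a known C-band pattern enter the comparison; blank
    patterns are unknown and excluded. ``beyond_centromere_count`` counts
    records with a positive block at any non-centromeric position. The
    comparison is descriptive (no hypothesis test is attached).
    """

    def group(recs: list[CytogeneticRecord]) -> BandRichnessGroup:
        richness = [band_richness(r.pattern) for r in recs]
        return BandRichnessGroup(
            size=len(recs),
            mean_richness=sum(richness) / len(richness) if richness else None,
            beyond_centromere_count=sum(
                1
                for r in recs
                if any(p is True for p in r.pattern.positions()[1:])
            ),
        )

    usable = [r for r in records if r.pattern is not None and r.pattern.is_known]
    low = [r for r in usable if r.effective_haploid <= n_threshold]
    high = [r for r in usable if r.effective_haploid > n_threshold]
    return BandRichnessComparison(n_threshold=n_threshold, low=group(low), high=group(high))


def gs_exceptions(
    records: Sequence[CytogeneticRecord], threshold: float = 0.50
) -> list[CytogeneticRecord]:
    """Records whose 1C genome size is at or above the threshold,
    sorted by genome size descending."""
    flagged = [
        r
        for r in records
        if r.genome_size_1c is not None and r.genome_size_1c >= threshold
    ]
    return sorted(flagged, key=lambda r: -r.genome_size_1c)


# ---------------------------------------------------------------------------
# I/O

RECORD_COLUMNS = (
    "taxon",
    "diploid_2n",
    "haploid_n",
    "gs_1c_pg",
    "locality",
    "country",
    "karyotype",
    "karyotype_alt",
    "hc_C",
    "hc_PC",
    "hc_IN",
    "hc_SA",
    "hc_LA",
    "reference",
    "new_report",
)

_BAND_MAP = {"+": True, "-": False, "–": False}


def _parse_band(cell) -> Optional[bool]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    token = str(cell).strip()
    if token not in _BAND_MAP:
        raise ValueError(f"unrecognized band code {token!r}")
    return _BAND_MAP[token]


def _opt_int(cell) -> Optional[int]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() in ("", "-"):
        return None
    return int(float(cell))


def _opt_float(cell) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() in ("", "-"):
        return None
    return float(cell)


def _opt_str(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    return str(cell).strip()


def read_records(path_or_buffer) -> list[CytogeneticRecord]:
    """Read a record table TSV (UTF-8, fixed column names) into records."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - {"karyotype_alt"} - set(df.columns)
    if missing:
        raise ValueError(f"record table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        formula_text = _opt_str(row.karyotype)
        pattern = HeterochromatinPattern(
            c=_parse_band(row.hc_C),
            pc=_parse_band(row.hc_PC),
            interstitial=_parse_band(row.hc_IN),
            short_arm=_parse_band(row.hc_SA),
            long_arm=_parse_band(row.hc_LA),
        )
        records.append(
            CytogeneticRecord(
                taxon=row.taxon,
                diploid_number=_opt_int(row.diploid_2n),
                haploid_number=_opt_int(row.haploid_n),
                genome_size_1c=_opt_float(row.gs_1c_pg),
                locality=_opt_str(row.locality),
                country=_opt_str(row.country),
                formula=parse_formula(formula_text) if formula_text else None,
                pattern=pattern if pattern.is_known else None,
                source=_opt_str(row.reference) or "",
                is_new_report=str(row.new_report).strip().lower() in ("1", "true", "yes"),
            )
        )
    return records


def write_records(records: Sequence[CytogeneticRecord], path: str | Path) -> None:
    """Write records back out in the fixed TSV schema."""

    def band_cell(value: Optional[bool]) -> str:
        return "" if value is None else ("+" if value else "-")

    rows = []
    for r in records:
        pattern = r.pattern or HeterochromatinPattern()
        rows.append(
            {
                "taxon": r.taxon,
                "diploid_2n": "" if r.diploid_number is None else r.diploid_number,
                "haploid_n": "" if r.haploid_number is None else r.haploid_number,
                "gs_1c_pg": "" if r.genome_size_1c is None else r.genome_size_1c,
                "locality": r.locality or "",
                "country": r.country or "",
                "karyotype": format_formula(r.formula) if r.formula else "",
                "karyotype_alt": "",
                "hc_C": band_cell(pattern.c),
                "hc_PC": band_cell(pattern.pc),
                "hc_IN": band_cell(pattern.interstitial),
                "hc_SA": band_cell(pattern.short_arm),
                "hc_LA": band_cell(pattern.long_arm),
                "reference": r.source,
                "new_report": int(r.is_new_report),
            }
        )
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_reference_records() -> list[CytogeneticRecord]:
    """Load the packaged Attina compilation table (61 records)."""
    ref = resources.files("attakaryo.data").joinpath("attina_records.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_records(fh)


def records_to_traits(
    records: Sequence[CytogeneticRecord],
) -> dict[str, tuple[Optional[int], Optional[float]]]:
    """Reconcile records into one (haploid n, genome size) pair per taxon.

    Taxa with multiple records keep the haploid number of the newest
    primary count (records flagged as new reports take precedence over
    older compilation rows, which matters where a re-count superseded a
    published number), and the first non-missing genome size in table
    order.
    """
    traits: dict[str, dict] = {}
    for r in records:
        entry = traits.setdefault(
            r.taxon, {"n": None, "n_is_new": False, "gs": None}
        )
        if entry["n"] is None or (r.is_new_report and not entry["n_is_new"]):
            entry["n"] = r.effective_haploid
            entry["n_is_new"] = r.is_new_report
        if entry["gs"] is None and r.genome_size_1c is not None:
            entry["gs"] = r.genome_size_1c
    return {taxon: (e["n"], e["gs"]) for taxon, e in traits.items()}
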