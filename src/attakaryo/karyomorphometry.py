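"""Karyomorphometric analysis of metaphase chromosome measurements.

Implements the standard workflow used in ant cytogenetics: per-chromosome
arm lengths measured on spread metaphases (µm) are aggregated across
spreads into mean ± SD statistics for total length (TL), long arm (L),
short arm (S), relative length (RL, percent of the karyotype length) and
arm ratio (r = L/S), chromosomes are classified into the Levan centromere
morphology classes (m, sm, st, t), and the whole complement is summarized
as a karyotype formula with fundamental number (FN, total arm count) and
karyotype length (KL, µm).

Homologues are paired by size rank within each spread (total length
descending, consecutive entries paired), which is the standard manual
practice when no banding information identifies homologues. Morphology is
assigned per homologue *pair* from the mean arm ratio of the larger
(first-ranked) homologue, and both homologues inherit the pair class; the
two measured copies of one chromosome are a single biological entity and
classifying them independently would let measurement noise split a pair
across classes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ArmMeasurement",
    "MetaphaseSpread",
    "ChromosomeProfile",
    "KaryotypeSummary",
    "HeteromorphismEvidence",
    "InvalidMeasurementError",
    "InconsistentSpreadsError",
    "arm_ratio",
    "classify_levan",
    "relative_length",
    "aggregate_spreads",
    "summarize_karyotype",
    "fundamental_number",
    "detect_heteromorphism",
    "read_measurements",
    "write_profile_table",
]

#: Levan morphology classes in order of decreasing centromere centrality.
MORPHOLOGY_ORDER = ("m", "sm", "st", "t")

#: Arm-ratio cutoffs: r in [1, 1.7) -> m, [1.7, 3) -> sm, [3, 7) -> st,
#: [7, inf) -> t. Boundaries are closed on the larger-class side.
LEVAN_CUTOFFS = ((1.7, "m"), (3.0, "sm"), (7.0, "st"))

MORPHOLOGY_NAMES = {
    "m": "Metacentric",
    "sm": "Submetacentric",
    "st": "Subtelocentric",
    "t": "Telocentric",
}


class InvalidMeasurementError(ValueError):
    """A chromosome arm length is missing, non-positive, or non-finite."""


class InconsistentSpreadsError(ValueError):
    """Spreads in one aggregation do not share a chromosome count."""

    def __init__(self, counts: Mapping[str, int]):
        self.counts = dict(counts)
        super().__init__(
            "spreads disagree in chromosome count: "
            + ", ".join(f"{sid}={n}" for sid, n in self.counts.items())
        )


def _check_positive(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InvalidMeasurementError(f"{what} must be a positive finite length, got {value!r}")
    return value


@dataclass(frozen=True)
class ArmMeasurement:
    """One chromosome's long/short arm lengths in µm.

    Orientation is normalized on construction: the larger of the two
    values is always stored as ``long_arm``.
    """

    long_arm: float
    short_arm: float

    def __post_init__(self) -> None:
        long_arm = _check_positive(self.long_arm, "long_arm")
        short_arm = _check_positive(self.short_arm, "short_arm")
        if short_arm > long_arm:
            long_arm, short_arm = short_arm, long_arm
        object.__setattr__(self, "long_arm", long_arm)
        object.__setattr__(self, "short_arm", short_arm)

    @property
    def total_length(self) -> float:
        return self.long_arm + self.short_arm

    @property
    def arm_ratio(self) -> float:
        return self.long_arm / self.short_arm


@dataclass(frozen=True)
class MetaphaseSpread:
    """All chromosome measurements of a single metaphase."""

    spread_id: str
    measurements: tuple[ArmMeasurement, ...]

    def __post_init__(self) -> None:
        measurements = tuple(self.measurements)
        if not measurements:
            raise InvalidMeasurementError(f"spread {self.spread_id!r} has no measurements")
        object.__setattr__(self, "measurements", measurements)

    def __len__(self) -> int:
        return len(self.measurements)

    def total_length(self) -> float:
        return sum(m.total_length for m in self.measurements)


@dataclass(frozen=True)
class ChromosomeProfile:
    """Aggregated per-chromosome statistics across spreads.

    ``rank`` is the 1-based display position in the karyotype table;
    ``pair_index`` identifies the homologue pair and ``homologue`` is 0
    for the larger and 1 for the smaller homologue (always 0 for haploid
    complements). Lengths are µm, RL is percent, r is dimensionless.
    """

    rank: int
    pair_index: int
    homologue: int
    mean_TL: float
    sd_TL: float
    mean_L: float
    sd_L: float
    mean_S: float
    sd_S: float
    mean_RL: float
    sd_RL: float
    mean_r: float
    sd_r: float
    morphology: str

    @property
    def label(self) -> str:
        """Table label: pair index, parenthesized for the second homologue."""
        return f"({self.pair_index})" if self.homologue else f"{self.pair_index}"


@dataclass(frozen=True)
class HeteromorphismEvidence:
    """Per-pair evidence of heteromorphism between homologues."""

    pair_index: int
    flagged: bool
    class_mismatch_fraction: float
    mean_tl_ratio: float
    per_spread: tuple[dict, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class KaryotypeSummary:
    """Complement-level summary: 2n (or n), formula, FN, KL, profiles."""

    diploid_number: int
    formula: Counter
    fundamental_number: int
    karyotype_length: float
    profiles: tuple[ChromosomeProfile, ...]
    heteromorphic_pairs: tuple[int, ...] = ()
    ploidy: str = "diploid"

    @property
    def formula_string(self) -> str:
        from .records import format_formula

        return format_formula(self.formula)


def arm_ratio(long_arm: float, short_arm: float) -> float:
    """Arm ratio r = L/S after orientation normalization; always >= 1."""
    return ArmMeasurement(long_arm, short_arm).arm_ratio


def classify_levan(r: float) -> str:
    """Classify a chromosome by arm ratio into m, sm, st or t.

    Cutoffs follow Levan's nomenclature with half-open intervals closed
    on the larger-class side: [1, 1.7) m, [1.7, 3) sm, [3, 7) st,
    [7, inf) t.
    """
    r = float(r)
    if not math.isfinite(r) or r < 1.0:
        raise InvalidMeasurementError(f"arm ratio must be >= 1, got {r!r}")
    for cutoff, label in LEVAN_CUTOFFS:
        if r < cutoff:
            return label
    return "t"


def relative_length(tl_i: float, tl_all: Sequence[float]) -> float:
    """Percent contribution of one chromosome to the spread's total length."""
    tl_i = _check_positive(tl_i, "tl_i")
    if not tl_all:
        raise InvalidMeasurementError("tl_all is empty")
    totals = [_check_positive(t, "total length") for t in tl_all]
    if not any(math.isclose(tl_i, t, rel_tol=1e-12) for t in totals):
        raise InvalidMeasurementError("tl_i is not among tl_all")
    return tl_i * 100.0 / sum(totals)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1); SD of a single value is 0."""
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def _ranked(spread: MetaphaseSpread) -> list[ArmMeasurement]:
    return sorted(spread.measurements, key=lambda m: m.total_length, reverse=True)


def aggregate_spreads(
    spreads: Sequence[MetaphaseSpread],
    ploidy: str = "diploid",
) -> list[ChromosomeProfile]:
    """Aggregate measurements across spreads into chromosome profiles.

    Within each spread chromosomes are ranked by total length descending;
    for diploid complements consecutive ranks are paired as homologues.
    Per rank, TL, L, S, r and RL are averaged across spreads (r and RL
    computed per spread, then averaged). Morphology is assigned per pair
    from the first homologue's mean r; profiles are returned in the table
    display order (classes grouped m < sm < st < t, size-descending
    within class).
    """
    if not spreads:
        raise InvalidMeasurementError("need at least one spread")
    if ploidy not in ("diploid", "haploid"):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    counts = {s.spread_id: len(s) for s in spreads}
    if len(set(counts.values())) != 1:
        raise InconsistentSpreadsError(counts)
    n_chrom = len(spreads[0])
    if ploidy == "diploid" and n_chrom % 2:
        raise InconsistentSpreadsError(counts)

    per_rank: list[dict[str, list[float]]] = [
        {"TL": [], "L": [], "S": [], "r": [], "RL": []} for _ in range(n_chrom)
    ]
    for spread in spreads:
        ranked = _ranked(spread)
        total = sum(m.total_length for m in ranked)
        for i, m in enumerate(ranked):
            per_rank[i]["TL"].append(m.total_length)
            per_rank[i]["L"].append(m.long_arm)
            per_rank[i]["S"].append(m.short_arm)
            per_rank[i]["r"].append(m.arm_ratio)
            per_rank[i]["RL"].append(m.total_length * 100.0 / total)

    stats = []
    for values in per_rank:
        row = {}
        for key, vals in values.items():
            row[f"mean_{key}"], row[f"sd_{key}"] = _mean_sd(vals)
        stats.append(row)

    pair_size = 2 if ploidy == "diploid" else 1
    pairs = []
    for k in range(n_chrom // pair_size):
        members = stats[k * pair_size : (k + 1) * pair_size]
        morphology = classify_levan(members[0]["mean_r"])
        pairs.append((morphology, members))

    class_order = {label: i for i, label in enumerate(MORPHOLOGY_ORDER)}
    pairs.sort(key=lambda p: (class_order[p[0]], -p[1][0]["mean_TL"]))

    profiles: list[ChromosomeProfile] = []
    rank = 0
    for pair_index, (morphology, members) in enumerate(pairs, start=1):
        for homologue, row in enumerate(members):
            rank += 1
            profiles.append(
                ChromosomeProfile(
                    rank=rank,
                    pair_index=pair_index,
                    homologue=homologue,
                    morphology=morphology,
                    **row,
                )
            )
    return profiles


def fundamental_number(formula: Mapping[str, int]) -> int:
    """Total arm count: two per biarmed (m/sm/st), one per t/a chromosome."""
    known = {"m", "sm", "st", "t", "a"}
    unknown = set(formula) - known
    if unknown:
        raise ValueError(f"unknown morphology labels: {sorted(unknown)}")
    for label, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for {label!r}")
    biarmed = sum(formula.get(k, 0) for k in ("m", "sm", "st"))
    uniarmed = sum(formula.get(k, 0) for k in ("t", "a"))
    return 2 * biarmed + uniarmed


def detect_heteromorphism(
    spreads: Sequence[MetaphaseSpread],
    pair_index: int,
    class_fraction: float = 0.5,
    tl_ratio_threshold: float = 1.25,
) -> HeteromorphismEvidence:
    """Flag a homologue pair as heteromorphic (size/morphology polymorphism).

    ``pair_index`` is 1-based in size-rank order (TL-descending pairing,
    the ranking aggregate_spreads uses internally). The pair is flagged
    when the two homologues fall in different Levan classes in at least
    ``class_fraction`` of spreads, or when the ratio of their mean total
    lengths exceeds ``tl_ratio_threshold``.
    """
    if not spreads:
        raise InvalidMeasurementError("need at least one spread")
    n_pairs = len(spreads[0]) // 2
    if not 1 <= pair_index <= n_pairs:
        raise ValueError(f"pair_index {pair_index} out of range 1..{n_pairs}")

    evidence = []
    mismatches = 0
    tl_a: list[float] = []
    tl_b: list[float] = []
    for spread in spreads:
        ranked = _ranked(spread)
        a, b = ranked[2 * (pair_index - 1)], ranked[2 * pair_index - 1]
        cls_a, cls_b = classify_levan(a.arm_ratio), classify_levan(b.arm_ratio)
        mismatch = cls_a != cls_b
        mismatches += mismatch
        tl_a.append(a.total_length)
        tl_b.append(b.total_length)
        evidence.append(
            {
                "spread_id": spread.spread_id,
                "class_a": cls_a,
                "class_b": cls_b,
                "tl_a": a.total_length,
                "tl_b": b.total_length,
                "mismatch": mismatch,
            }
        )
    frac = mismatches / len(spreads)
    mean_a, _ = _mean_sd(tl_a)
    mean_b, _ = _mean_sd(tl_b)
    ratio = max(mean_a, mean_b) / min(mean_a, mean_b)
    flagged = frac >= class_fraction or ratio > tl_ratio_threshold
    return HeteromorphismEvidence(
        pair_index=pair_index,
        flagged=flagged,
        class_mismatch_fraction=frac,
        mean_tl_ratio=ratio,
        per_spread=tuple(evidence),
    )


def summarize_karyotype(
    profiles: Sequence[ChromosomeProfile],
    spreads: Sequence[MetaphaseSpread] | None = None,
    ploidy: str = "diploid",
    class_fraction: float = 0.5,
    tl_ratio_threshold: float = 1.25,
) -> KaryotypeSummary:
    """Summarize profiles into 2n (or n), formula, FN, KL.

    When the underlying spreads are supplied, every homologue pair is
    additionally screened for heteromorphism and flagged pairs are
    reported by display-order pair index.
    """
    if not profiles:
        raise InvalidMeasurementError("empty profile list")
    formula = Counter(p.morphology for p in profiles)
    kl = sum(p.mean_TL for p in profiles)
    heteromorphic: tuple[int, ...] = ()
    if spreads is not None and ploidy == "diploid":
        # detect on size-rank pairs, then map to display pair indices via TL
        n_pairs = len(profiles) // 2
        flagged_sizerank = [
            k
            for k in range(1, n_pairs + 1)
            if detect_heteromorphism(
                spreads, k, class_fraction, tl_ratio_threshold
            ).flagged
        ]
        if flagged_sizerank:
            first_by_size = sorted(
                (p for p in profiles if p.homologue == 0),
                key=lambda p: p.mean_TL,
                reverse=True,
            )
            heteromorphic = tuple(
                sorted(first_by_size[k - 1].pair_index for k in flagged_sizerank)
            )
    return KaryotypeSummary(
        diploid_number=len(profiles),
        formula=formula,
        fundamental_number=fundamental_number(formula),
        karyotype_length=kl,
        profiles=tuple(profiles),
        heteromorphic_pairs=heteromorphic,
        ploidy=ploidy,
    )


# ---------------------------------------------------------------------------
# I/O

MEASUREMENT_COLUMNS = ("spread_id", "chromosome_index", "long_um", "short_um")


def read_measurements(path: str | Path) -> list[MetaphaseSpread]:
    """Read a measurement table (CSV or TSV) into spreads.

    Required columns: spread_id, chromosome_index, long_um, short_um.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spreads = []
    for sid, group in df.groupby("spread_id", sort=False):
        group = group.sort_values("chromosome_index")
        spreads.append(
            MetaphaseSpread(
                spread_id=str(sid),
                measurements=tuple(
                    ArmMeasurement(row.long_um, row.short_um)
                    for row in group.itertuples()
                ),
            )
        )
    return spreads


def _fmt(mean: float, sd: float, ndigits: int) -> str:
    return f"{round(mean, ndigits):.{ndigits}f} ± {round(sd, ndigits):.{ndigits}f}"


def write_profile_table(
    summary: KaryotypeSummary, path: str | Path, ndigits: int = 2
) -> None:
    """Write a karyotype table in the conventional layout.

    One row per chromosome ("mean ± sd" cells for TL, L, S, RL, r plus
    the Classification), followed by a summary block (KL, 2n or n, the
    karyotype formula and FN). Rounding is half-to-even.
    """
    rows = []
    for p in summary.profiles:
        rows.append(
            {
                "Chromosome": p.label,
                "TL": _fmt(p.mean_TL, p.sd_TL, ndigits),
                "L": _fmt(p.mean_L, p.sd_L, ndigits),
                "S": _fmt(p.mean_S, p.sd_S, ndigits),
                "RL": _fmt(p.mean_RL, p.sd_RL, ndigits),
                "r": _fmt(p.mean_r, p.sd_r, ndigits),
                "Classification": MORPHOLOGY_NAMES[p.morphology],
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(f"KL\t{round(summary.karyotype_length, ndigits):.{ndigits}f}\n")
        n_label = "2n" if summary.ploidy == "diploid" else "n"
        fh.write(f"{n_label}\t{summary.diploid_number}\n")
        fh.write(f"2K\t{summary.formula_string}\n")
        fh.write(f"FN\t{summary.fundamental_number}\n")
        if summary.heteromorphic_pairs:
            pairs = ", ".join(str(i) for i in summary.heteromorphic_pairs)
            fh.write(f"heteromorphic pairs\t{pairs}\n")
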