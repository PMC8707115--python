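"""Synthetic data generators mirroring the statistical structure of the
real inputs.

Three generators cover the three data layers of the pipeline:

* noisy metaphase spreads around a known true karyotype — spread-to-spread
  chromosome condensation is a shared log-normal factor (condensation
  varies jointly within a metaphase), and each arm carries independent
  multiplicative Gaussian measurement noise;
* chromosome-number evolution along a time-calibrated tree as a
  continuous-time fission/fusion process (fission n -> n+1, fusion
  n -> n-1, constant rates per Myr), with a reflecting lower bound and an
  optional upper cap embodying the hypothesis that karyotypes cannot
  grow without limit;
* genome-size evolution as Brownian motion around a root value (default
  0.38 pg, the compilation mean for fungus-farming ants), optionally
  adding a fixed jump per fission event to emulate heterochromatin-driven
  genome growth.

Every generator is a pure function of its inputs and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import dendropy

from .karyomorphometry import ArmMeasurement, MetaphaseSpread

__all__ = [
    "TrueKaryotype",
    "EvolModel",
    "FissionFusionEvent",
    "FixtureTableSpec",
    "simulate_spreads",
    "simulate_chromosome_evolution",
    "simulate_gs",
    "make_fixture_tables",
]


@dataclass(frozen=True)
class TrueKaryotype:
    """Ground-truth karyotype: per-pair (total length µm, arm ratio >= 1)."""

    pairs: tuple[tuple[float, float], ...]
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("karyotype needs at least one chromosome pair")
        if self.ploidy not in ("diploid", "haploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        for tl, r in self.pairs:
            if not tl > 0:
                raise ValueError("total length must be positive")
            if not r >= 1:
                raise ValueError("arm ratio must be >= 1")
        object.__setattr__(self, "pairs", tuple((float(t), float(r)) for t, r in self.pairs))

    def arms(self) -> list[tuple[float, float]]:
        """True (long, short) arm lengths per pair."""
        return [(tl * r / (1 + r), tl / (1 + r)) for tl, r in self.pairs]


@dataclass(frozen=True)
class EvolModel:
    """Parameters of the karyotype/genome-size evolution model.

    Rates are events per Myr; ``gs_sigma`` is the Brownian step SD in
    pg per sqrt(Myr); ``gs_fission_jump`` adds that many pg per fission
    when an event log is supplied to simulate_gs.
    """

    fission_rate: float = 0.05
    fusion_rate: float = 0.05
    n_min: int = 1
    n_cap: Optional[int] = None
    gs_root: float = 0.38
    gs_sigma: float = 0.02
    gs_fission_jump: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fission_rate < 0 or self.fusion_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.n_cap is not None and self.n_cap < self.n_min:
            raise ValueError("n_cap must be >= n_min")
        if not self.gs_root > 0:
            raise ValueError("gs_root must be positive")
        if self.gs_sigma < 0:
            raise ValueError("gs_sigma must be non-negative")


def simulate_spreads(
    truth: TrueKaryotype,
    n_spreads: int,
    condensation_sd: float = 0.10,
    arm_noise_sd: float = 0.02,
    seed: int = 0,
) -> list[MetaphaseSpread]:
    """Simulate measured metaphase spreads around a true karyotype.

    Per spread j a condensation factor c_j ~ exp(N(0, condensation_sd))
    (median 1) scales every chromosome; each arm additionally gets
    independent multiplicative noise (1 + e), e ~ N(0, arm_noise_sd),
    truncated so lengths stay positive. Homologues are duplicated for
    diploid karyotypes. Deterministic for a fixed seed.
    """
    if n_spreads < 1:
        raise ValueError("n_spreads must be >= 1")
    if condensation_sd < 0 or arm_noise_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    copies = 2 if truth.ploidy == "diploid" else 1
    arms = truth.arms()
    spreads = []
    for j in range(n_spreads):
        c = float(np.exp(rng.normal(0.0, condensation_sd))) if condensation_sd else 1.0
        measurements = []
        for long_true, short_true in arms:
            for _ in range(copies):
                noise = rng.normal(0.0, arm_noise_sd, size=2) if arm_noise_sd else (0.0, 0.0)
                long_obs = long_true * c * max(1.0 + noise[0], 1e-6)
                short_obs = short_true * c * max(1.0 + noise[1], 1e-6)
                measurements.append(ArmMeasurement(long_obs, short_obs))
        spreads.append(MetaphaseSpread(spread_id=f"spread_{j + 1}", measurements=tuple(measurements)))
    return spreads


@dataclass(frozen=True)
class FissionFusionEvent:
    branch_head: str  # label or oid of the node below the branch
    time: float       # time since the branch's start, Myr
    event: str        # "fission" or "fusion"
    n_after: int


def _branch_key(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return f"node_{id(node) & 0xFFFFFF}" if node.label is None else node.label


def simulate_chromosome_evolution(
    tree: dendropy.Tree,
    model: EvolModel,
    root_n: int,
    seed: int = 0,
) -> tuple[dict[str, int], list[FissionFusionEvent]]:
    """Evolve a haploid chromosome number along a tree by fission/fusion.

    Along each branch a continuous-time chain steps n -> n+1 at the
    fission rate and n -> n-1 at the fusion rate (Gillespie sampling).
    Fusions are suppressed at ``n_min`` (reflecting bound); fissions are
    suppressed at ``n_cap`` when set (truncation). Returns tip states
    keyed by tip label plus the full event log.
    """
    if root_n < model.n_min:
        raise ValueError("root_n below n_min")
    if model.n_cap is not None and root_n > model.n_cap:
        raise ValueError("root_n above n_cap")
    rng = np.random.default_rng(seed)
    tips: dict[str, int] = {}
    log: list[FissionFusionEvent] = []
    states = {id(tree.seed_node): root_n}
    # enumerate branches deterministically in preorder
    branch_index = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        branch_index += 1
        n = states[id(node.parent_node)]
        length = node.edge.length or 0.0
        key = _branch_key(node)
        t = 0.0
        while True:
            fission = model.fission_rate if (model.n_cap is None or n < model.n_cap) else 0.0
            fusion = model.fusion_rate if n > model.n_min else 0.0
            total = fission + fusion
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= length:
                break
            if rng.random() < fission / total:
                n += 1
                event = "fission"
            else:
                n -= 1
                event = "fusion"
            log.append(FissionFusionEvent(branch_head=key, time=t, event=event, n_after=n))
        states[id(node)] = n
        if node.is_leaf():
            tips[node.taxon.label] = n
    return tips, log


def simulate_gs(
    tree: dendropy.Tree,
    model: EvolModel,
    seed: int = 0,
    event_log: Optional[Sequence[FissionFusionEvent]] = None,
    floor: float = 0.01,
) -> dict[str, float]:
    """Evolve genome size along a tree as Brownian motion.

    Each branch adds a N(0, gs_sigma^2 * length) increment to the parent
    value, floored at ``floor`` pg. When ``gs_fission_jump`` is set and an
    event log from simulate_chromosome_evolution is supplied, every
    fission on a branch adds the jump (heterochromatin gain after
    centric fission). Returns tip genome sizes keyed by tip label.
    """
    rng = np.random.default_rng(seed)
    jumps: dict[str, int] = {}
    if event_log is not None:
        for ev in event_log:
            if ev.event == "fission":
                jumps[ev.branch_head] = jumps.get(ev.branch_head, 0) + 1
    values = {id(tree.seed_node): model.gs_root}
    tips: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = values[id(node.parent_node)]
        length = node.edge.length or 0.0
        step = rng.normal(0.0, model.gs_sigma * np.sqrt(length)) if model.gs_sigma and length else 0.0
        value = parent + step
        if model.gs_fission_jump is not None:
            value += model.gs_fission_jump * jumps.get(_branch_key(node), 0)
        value = max(value, floor)
        values[id(node)] = value
        if node.is_leaf():
            tips[node.taxon.label] = value
    return tips


# ---------------------------------------------------------------------------
# Synthetic record tables


@dataclass(frozen=True)
class FixtureTableSpec:
    """Composition of a synthetic cytogenetic record table.

    ``genus_sizes`` maps genus name -> number of records; ``genus_haploid``
    maps genus -> candidate haploid numbers drawn uniformly. Genome sizes
    are N(gs_mean, gs_sd) truncated positive and present with probability
    ``gs_fraction``; a record is a morphospecies ("sp.") with probability
    ``unidentified_fraction`` and carries a random C-band pattern with
    probability ``pattern_fraction``.
    """

    genus_sizes: dict[str, int]
    genus_haploid: dict[str, tuple[int, ...]]
    gs_mean: float = 0.38
    gs_sd: float = 0.05
    gs_fraction: float = 0.6
    unidentified_fraction: float = 0.15
    pattern_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.genus_sizes:
            raise ValueError("at least one genus required")
        missing = set(self.genus_sizes) - set(self.genus_haploid)
        if missing:
            raise ValueError(f"no haploid choices for genera {sorted(missing)}")


_EPITHETS = (
    "aurata", "brevis", "cristata", "dubia", "elegans", "fulva", "gracilis",
    "humilis", "incerta", "jucunda", "laevis", "minor", "nitida", "obscura",
    "pallida", "quadrata", "rustica", "subtilis", "tenuis", "varia",
)


def make_fixture_tables(
    spec: FixtureTableSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic record table plus its ground-truth ledger.

    Returns a DataFrame in the record-table TSV schema and a ledger of
    the summary statistics the records module should recover exactly
    (record/unidentified/GS-taxon counts, haploid range, mean GS).
    Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ledger = {
        "record_count": 0,
        "unidentified_count": 0,
        "taxa_with_gs": set(),
        "haploids": [],
        "gs_values": [],
        "pattern_count": 0,
    }
    for genus in sorted(spec.genus_sizes):
        size = spec.genus_sizes[genus]
        choices = spec.genus_haploid[genus]
        sp_counter = 0
        for i in range(size):
            unidentified = bool(rng.random() < spec.unidentified_fraction)
            if unidentified:
                sp_counter += 1
                taxon = f"{genus} sp.{sp_counter}"
            else:
                taxon = f"{genus} {_EPITHETS[i % len(_EPITHETS)]}"
            n = int(choices[rng.integers(len(choices))])
            gs = None
            if rng.random() < spec.gs_fraction:
                gs = abs(float(rng.normal(spec.gs_mean, spec.gs_sd)))
                gs = max(round(gs, 3), 0.001)
            n_m = 2 * int(rng.integers(1, n + 1))
            n_sm = 2 * n - n_m
            karyotype = f"{n_m} m + {n_sm} sm" if n_sm else f"{n_m} m"
            has_pattern = bool(rng.random() < spec.pattern_fraction)
            bands = (
                ["+"] + [("+" if rng.random() < 0.3 else "-") for _ in range(4)]
                if has_pattern
                else [""] * 5
            )
            rows.append(
                {
                    "taxon": taxon,
                    "diploid_2n": 2 * n,
                    "haploid_n": n,
                    "gs_1c_pg": "" if gs is None else gs,
                    "locality": "",
                    "country": "Synthetica",
                    "karyotype": karyotype,
                    "karyotype_alt": "",
                    "hc_C": bands[0],
                    "hc_PC": bands[1],
                    "hc_IN": bands[2],
                    "hc_SA": bands[3],
                    "hc_LA": bands[4],
                    "reference": "synthetic",
                    "new_report": 0,
                }
            )
            ledger["record_count"] += 1
            ledger["unidentified_count"] += unidentified
            ledger["haploids"].append(n)
            if gs is not None:
                ledger["taxa_with_gs"].add(taxon)
                ledger["gs_values"].append(gs)
            ledger["pattern_count"] += has_pattern
    df = pd.DataFrame(rows)
    ledger["taxa_with_gs_count"] = len(ledger.pop("taxa_with_gs"))
    ledger["min_haploid"] = min(ledger["haploids"])
    ledger["max_haploid"] = max(ledger["haploids"])
    gs_values = ledger.pop("gs_values")
    ledger["mean_gs"] = sum(gs_values) / len(gs_values) if gs_values else None
    return df, ledger
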