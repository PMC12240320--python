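"""Consensus-interface contact classification and binding-energy summaries.

A consensus template lists interface positions of the RhoGAP family grid
(conserved / variable regions) together with the RhoA residues each position
contacts. Observed contacts from a trajectory are classified through an
externally supplied alignment map: *matched* when the GAP residue maps to a
template position whose RhoA set contains the observed partner, *unmatched*
when it maps but the partner differs, *unmapped* otherwise. Binding-energy
tables are consumed as printed values (never computed here) and summarized
as percentage ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .contacts import PersistenceRecord

__all__ = [
    "ConsensusTemplate",
    "AlignmentMap",
    "EnergyTable",
    "ContactClassification",
    "classify_contacts",
    "energy_ratio",
    "tier_threshold_ns",
]

GAP_REGION_LABELS = frozenset({"conserved", "variable1", "variable2", "other"})


@dataclass(frozen=True)
class ConsensusTemplate:
    """Interface positions: id -> (region label, contacted RhoA residues)."""

    positions: tuple[tuple[str, str, frozenset[int]], ...]

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.positions]
        if len(ids) != len(set(ids)):
            raise ValueError("template position ids must be unique")
        for _, label, _ in self.positions:
            if label not in GAP_REGION_LABELS:
                raise ValueError(f"unknown gap_region label {label!r}")

    def rhoa_set(self, position: str) -> frozenset[int]:
        for pid, _, rset in self.positions:
            if pid == position:
                return rset
        raise KeyError(position)

    @classmethod
    def from_tsv(cls, path) -> "ConsensusTemplate":
        df = pd.read_csv(path, sep="\t", dtype=str)
        rows = []
        for _, r in df.iterrows():
            rhoa = frozenset(
                int(x) for x in str(r["rhoa_residues"]).split(",") if x.strip()
            )
            rows.append((str(r["position"]), str(r["label"]), rhoa))
        return cls(positions=tuple(rows))


@dataclass(frozen=True)
class AlignmentMap:
    """Injective map between query residues (chain, resseq) and template
    position ids; unmapped residues are simply absent."""

    pairs: tuple[tuple[tuple[str, int], str], ...]

    def __post_init__(self) -> None:
        q = [p[0] for p in self.pairs]
        t = [p[1] for p in self.pairs]
        if len(q) != len(set(q)) or len(t) != len(set(t)):
            raise ValueError("alignment map must be injective in both directions")

    def position_of(self, residue: tuple[str, int]) -> str | None:
        for q, t in self.pairs:
            if q == residue:
                return t
        return None

    @classmethod
    def from_tsv(cls, path) -> "AlignmentMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        pairs = tuple(
            ((str(r["chain"]), int(r["resseq"])), str(r["position"]))
            for _, r in df.iterrows()
        )
        return cls(pairs=pairs)


@dataclass(frozen=True)
class EnergyTable:
    """Printed binding free energies: complex label -> dG (kcal/mol)."""

    rows: Mapping[str, float]

    @classmethod
    def from_tsv(cls, path) -> "EnergyTable":
        df = pd.read_csv(path, sep="\t")
        return cls(rows=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))


@dataclass
class ContactClassification:
    """Per-record status plus counts per (tier, status)."""

    statuses: list[str]  # aligned with the input record list
    counts: dict[tuple[str, str], int]


def classify_contacts(
    records: Iterable[PersistenceRecord],
    amap: AlignmentMap,
    template: ConsensusTemplate,
) -> ContactClassification:
    """Classify each observed GAP-RhoA contact against the consensus grid.

    ``res_a`` of each record is the GAP-side residue, ``res_b`` the RhoA
    partner. The three statuses partition the records exactly.
    """
    statuses: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        pos = amap.position_of((rec.res_a[0], rec.res_a[1]))
        if pos is None:
            status = "unmapped"
        elif rec.res_b[1] in template.rhoa_set(pos):
            status = "matched"
        else:
            status = "unmatched"
        statuses.append(status)
        counts[(rec.tier, status)] = counts.get((rec.tier, status), 0) + 1
    return ContactClassification(statuses=statuses, counts=counts)


def energy_ratio(table: EnergyTable, numerator: str, denominator: str) -> float:
    """Percentage ratio of two binding free energies, one-decimal rounded.

    Both values in a typical table are negative, so the signs cancel and the
    ratio equals the ratio of magnitudes; mixed-sign inputs raise a warning
    because the percentage is then not a magnitude comparison.
    """
    try:
        num = table.rows[numerator]
        den = table.rows[denominator]
    except KeyError as exc:
        raise KeyError(f"label {exc.args[0]!r} not in energy table") from None
    if den == 0:
        raise ZeroDivisionError("denominator energy is zero")
    if (num < 0) != (den < 0):
        warnings.warn("energy ratio of mixed-sign values is not a magnitude ratio")
    return round(100.0 * num / den, 1)


def tier_threshold_ns(total_ns: float, fraction: float) -> float:
    """Duration corresponding to an occupancy-fraction tier edge.

    For a 2 us trajectory the 5%, 1% and 0.1% edges are 100, 20 and 2 ns.
    """
    if not total_ns > 0:
        raise ValueError("total_ns must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return total_ns * fraction
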