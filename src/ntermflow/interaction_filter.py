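"""Stringent filtering of AP-MS pull-down candidates.

The stringent rule: a protein is a strong candidate interactor iff it is
identified (non-missing LFQ intensity) in EVERY bait replicate, in NO
control pull-down, and carries a chloroplast annotation.  A relaxed rule
admits proteins seen in at least one bait replicate and no control,
flagged as single-replicate evidence.  Stringent candidates are always a
subset of relaxed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class PulldownRecord:
    """One protein group across bait replicates and control pull-downs.

    ``bait_intensities`` / ``control_intensities`` hold log2 LFQ values
    with NaN for "not identified"; presence flags are derived from
    non-missing intensities.
    """

    accession: str
    bait_intensities: Sequence[float]
    control_intensities: Sequence[float]
    chloroplast_annotated: bool = False
    unique_peptides: int = 1
    coverage_pct: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.bait_intensities) == 0:
            raise ValueError(f"{self.accession}: record has zero bait replicates")
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError(f"{self.accession}: coverage {self.coverage_pct} outside [0, 100]")

    @property
    def bait_present(self) -> list[bool]:
        return [np.isfinite(v) for v in np.asarray(self.bait_intensities, dtype=float)]

    @property
    def control_present(self) -> list[bool]:
        return [np.isfinite(v) for v in np.asarray(self.control_intensities, dtype=float)]

    @property
    def max_bait_intensity(self) -> float:
        arr = np.asarray(self.bait_intensities, dtype=float)
        finite = arr[np.isfinite(arr)]
        return float(finite.max()) if finite.size else -np.inf


def _validate(records: Sequence[PulldownRecord]) -> None:
    if records and len(records[0].bait_intensities) < 2:
        raise ValueError("need >= 2 bait replicates")
    if records and len(records[0].control_intensities) < 1:
        raise ValueError("need >= 1 control pull-down")


def stringent_subset(
    records: Sequence[PulldownRecord], min_unique_peptides: int = 1
) -> list[PulldownRecord]:
    """Strong candidate interactors.

    Keep iff present in ALL bait replicates AND absent from ALL controls
    AND chloroplast-annotated (AND at least ``min_unique_peptides`` unique
    peptides).  Output sorted by maximum bait intensity, descending.
    """
    _validate(records)
    kept = [
        r
        for r in records
        if all(r.bait_present)
        and not any(r.control_present)
        and r.chloroplast_annotated
        and r.unique_peptides >= min_unique_peptides
    ]
    return sorted(kept, key=lambda r: (-r.max_bait_intensity, r.accession))


def relaxed_subset(
    records: Sequence[PulldownRecord], min_unique_peptides: int = 1
) -> list[PulldownRecord]:
    """Secondary candidates: >= 1 bait replicate, no control, chloroplast.

    A superset of the stringent candidates; proteins seen in only some
    bait replicates carry single-replicate evidence (inspect
    ``bait_present`` to distinguish them).
    """
    _validate(records)
    kept = [
        r
        for r in records
        if any(r.bait_present)
        and not any(r.control_present)
        and r.chloroplast_annotated
        and r.unique_peptides >= min_unique_peptides
    ]
    return sorted(kept, key=lambda r: (-r.max_bait_intensity, r.accession))


def candidates_table(records: Iterable[PulldownRecord]) -> pd.DataFrame:
    """Candidate list in the style of a stringent-subset results table."""
    rows = []
    for r in records:
        rec = {
            "accession": r.accession,
            "name": r.name,
            "unique_peptides": r.unique_peptides,
            "coverage_pct": r.coverage_pct,
        }
        for i, v in enumerate(r.bait_intensities, start=1):
            rec[f"log2_LFQ_rep{i}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)


def records_from_tables(
    bait_tables: Sequence[pd.DataFrame],
    control_tables: Sequence[pd.DataFrame],
    chloroplast: Optional[set[str]] = None,
) -> list[PulldownRecord]:
    """Assemble pull-down records from per-experiment protein tables.

    Each table needs an ``accession`` column and an ``intensity`` column;
    optional ``unique_peptides``, ``coverage_pct``, ``chloroplast`` and
    ``name`` columns are carried through (chloroplast annotation may come
    from the tables or from the ``chloroplast`` accession set).
    """
    accs: dict[str, dict] = {}

    def intensity_of(tab: pd.DataFrame, acc: str) -> float:
        hit = tab.loc[tab["accession"] == acc]
        if hit.empty:
            return np.nan
        v = float(hit["intensity"].iloc[0])
        return v if v > 0 else np.nan

    for tab in list(bait_tables) + list(control_tables):
        for _, row in tab.iterrows():
            meta = accs.setdefault(row["accession"], {})
            if "chloroplast" in row and not pd.isna(row["chloroplast"]):
                meta["chloroplast"] = bool(row["chloroplast"])
            if "unique_peptides" in row and not pd.isna(row["unique_peptides"]):
                meta["unique_peptides"] = max(
                    int(row["unique_peptides"]), meta.get("unique_peptides", 0)
                )
            if "coverage_pct" in row and not pd.isna(row["coverage_pct"]):
                meta["coverage_pct"] = max(
                    float(row["coverage_pct"]), meta.get("coverage_pct", 0.0)
                )
            if "name" in row and isinstance(row.get("name"), str):
                meta["name"] = row["name"]
    records = []
    for acc, meta in sorted(accs.items()):
        records.append(
            PulldownRecord(
                accession=acc,
                bait_intensities=[intensity_of(t, acc) for t in bait_tables],
                control_intensities=[intensity_of(t, acc) for t in control_tables],
                chloroplast_annotated=meta.get(
                    "chloroplast", acc in chloroplast if chloroplast else False
                ),
                unique_peptides=meta.get("unique_peptides", 1),
                coverage_pct=meta.get("coverage_pct", 0.0),
                name=meta.get("name", ""),
            )
        )
    return records
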