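"""Positional annotation of protein N-termini and modification mass accounting.

An identified N-terminal peptide is mapped onto its parent protein and
classified by where it starts:

* ``POS1`` — translation start site with intact initiator Met (start 1);
* ``POS2`` — start site after initiator-Met excision (start 2, residue 1
  is Met);
* ``CLEAVAGE_WINDOW`` — within ``W`` residues (two-sided, inclusive) of the
  predicted mature N-terminus after signal- or transit-peptide cleavage;
* ``UNANNOTATED`` — anywhere else (internal proteolysis, alternative
  starts, degradation intermediates).

POS1/POS2/CLEAVAGE_WINDOW termini are "expected"; the precedence order is
POS1 > POS2 > CLEAVAGE_WINDOW, since direct start-site evidence outranks a
prediction window.

The module also books the monoisotopic mass shifts of the N-terminal
chemistry used in dimethylation-based terminal enrichment: light and heavy
reductive dimethylation, endogenous N-terminal acetylation, and pyroGlu
formation from Glu or Gln.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ntermflow.io_formats import AnalysisConfig, Compartment, ProteinEntry

# IUPAC 2021 monoisotopic atomic masses (Da).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,  # 2H
    "C": 12.0,
    "13C": 13.00335483507,
    "N": 14.00307400443,
    "15N": 15.00010889888,
    "O": 15.99491461957,
    "S": 31.97207117354,
}


class NTermMod(str, enum.Enum):
    """N-terminal modification state of an identified peptide."""

    FREE_DIMETHYLATED = "free_dimethylated"
    ACETYLATED = "acetylated"
    PYROGLU_E = "pyroGlu_E"
    PYROGLU_Q = "pyroGlu_Q"


class Category(str, enum.Enum):
    POS1 = "POS1"
    POS2 = "POS2"
    CLEAVAGE_WINDOW = "CLEAVAGE_WINDOW"
    UNANNOTATED = "UNANNOTATED"


class WindowKind(str, enum.Enum):
    SP = "SP"
    TP_PLASTID = "TP_plastid"
    TP_MITO = "TP_mito"
    PROPEPTIDE = "propeptide"
    NONE = "none"


_COMPARTMENT_WINDOW = {
    Compartment.PLASTID: WindowKind.TP_PLASTID,
    Compartment.MITOCHONDRION: WindowKind.TP_MITO,
    Compartment.SECRETORY: WindowKind.SP,
    Compartment.OTHER: WindowKind.NONE,
}


@dataclass(frozen=True)
class ModificationSpec:
    """A chemical modification as a signed elemental composition delta."""

    name: str
    delta: Mapping[str, int]

    def mass_shift(self) -> float:
        return mass_shift(self)


def mass_shift(mod: ModificationSpec) -> float:
    """Signed monoisotopic mass shift of ``mod`` in Da, to 6 decimals.

    Computed as the dot product of the elemental delta with monoisotopic
    atomic masses; unknown element symbols raise ``KeyError``.
    """
    total = 0.0
    for element, count in mod.delta.items():
        if element not in MONOISOTOPIC_MASS:
            raise KeyError(f"unknown element symbol {element!r}")
        total += count * MONOISOTOPIC_MASS[element]
    return round(total, 6)


#: The modifications of the dimethylation labeling scheme.  Light dimethyl
#: adds two CH2 to a primary amine; heavy dimethyl replaces the two amine
#: hydrogens with two 13CD3 groups; acetylation adds C2H2O; pyroGlu
#: formation loses H2O (from Glu) or NH3 (from Gln).
MODIFICATIONS: Mapping[str, ModificationSpec] = {
    "dimethyl_light": ModificationSpec("dimethyl_light", {"C": 2, "H": 4}),
    "dimethyl_heavy": ModificationSpec("dimethyl_heavy", {"13C": 2, "D": 6, "H": -2}),
    "acetyl": ModificationSpec("acetyl", {"C": 2, "H": 2, "O": 1}),
    "pyroglu_E": ModificationSpec("pyroglu_E", {"H": -2, "O": -1}),
    "pyroglu_Q": ModificationSpec("pyroglu_Q", {"N": -1, "H": -3}),
}


@dataclass
class NTermPeptide:
    """An identified N-terminal peptide.

    ``channel_intensities`` maps sample name (``<genotype>_<replicate>``)
    to intensity; absent samples mean not quantified.
    """

    peptide_seq: str
    accession: str
    start_pos: int
    nterm_mod: NTermMod
    channel_intensities: dict[str, float] = field(default_factory=dict)
    terminus_id: Optional[str] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.nterm_mod is NTermMod.PYROGLU_E and self.peptide_seq[:1] != "E":
            raise ValueError("pyroGlu_E requires first residue E")
        if self.nterm_mod is NTermMod.PYROGLU_Q and self.peptide_seq[:1] != "Q":
            raise ValueError("pyroGlu_Q requires first residue Q")
        if self.terminus_id is None:
            self.terminus_id = f"{self.accession}@{self.start_pos}"

    def validate_against(self, protein: ProteinEntry) -> None:
        sub = protein.sequence[self.start_pos - 1 : self.start_pos - 1 + len(self.peptide_seq)]
        if sub != self.peptide_seq:
            raise ValueError(
                f"peptide {self.peptide_seq!r} does not match {protein.accession} "
                f"at position {self.start_pos}"
            )

    @property
    def acetylated(self) -> bool:
        return self.nterm_mod is NTermMod.ACETYLATED

    @property
    def has_lys(self) -> bool:
        """Whether the peptide carries a Lys whose side chain takes the label."""
        return "K" in self.peptide_seq


@dataclass(frozen=True)
class TerminusAnnotation:
    """Positional classification of one observed N-terminus."""

    category: Category
    window_kind: WindowKind
    offset: Optional[int]  # observed_start - (cleavage_pos + 1)
    expected: bool
    acetylated: bool
    note: str = ""

    def __post_init__(self) -> None:
        assert self.expected == (self.category is not Category.UNANNOTATED)


def map_peptide(
    peptide_seq: str, proteome: Mapping[str, str]
) -> list[tuple[str, int]]:
    """All exact substring occurrences of ``peptide_seq`` in the proteome.

    Returns ``(accession, 1-based start)`` pairs sorted by accession then
    position; overlapping occurrences are all reported.
    """
    hits: list[tuple[str, int]] = []
    for acc in sorted(proteome):
        seq = proteome[acc]
        start = seq.find(peptide_seq)
        while start != -1:
            hits.append((acc, start + 1))
            start = seq.find(peptide_seq, start + 1)
    return hits


def classify_terminus(
    start_pos: int,
    protein: ProteinEntry,
    cfg: AnalysisConfig,
    acetylated: bool = False,
    propeptide_sites: Sequence[int] = (),
) -> TerminusAnnotation:
    """Classify an observed N-terminus by the positional rules.

    Precedence: POS1 > POS2 > CLEAVAGE_WINDOW > UNANNOTATED.  The signed
    offset to the predicted mature N-terminus (``cleavage_pos + 1``) is
    reported whenever the protein has a predicted cleavage site, regardless
    of category.  ``propeptide_sites`` optionally supplies additional
    maturation-site positions (last residue of the propeptide, from any
    external annotation source) honoured under the same window rule after
    the presequence window.
    """
    if not 1 <= start_pos <= len(protein.sequence):
        raise ValueError(
            f"start_pos {start_pos} outside protein {protein.accession} "
            f"(length {len(protein.sequence)})"
        )
    offset: Optional[int] = None
    if protein.cleavage_pos is not None:
        offset = start_pos - (protein.cleavage_pos + 1)

    if start_pos == 1:
        return TerminusAnnotation(Category.POS1, WindowKind.NONE, offset, True, acetylated)
    if start_pos == 2 and protein.sequence[0] == "M":
        return TerminusAnnotation(Category.POS2, WindowKind.NONE, offset, True, acetylated)
    if offset is not None and abs(offset) <= cfg.window_W:
        kind = _COMPARTMENT_WINDOW[protein.compartment]
        return TerminusAnnotation(Category.CLEAVAGE_WINDOW, kind, offset, True, acetylated)
    for site in propeptide_sites:
        if abs(start_pos - (site + 1)) <= cfg.window_W:
            return TerminusAnnotation(
                Category.CLEAVAGE_WINDOW, WindowKind.PROPEPTIDE, offset, True, acetylated,
                note=f"propeptide site {site}",
            )
    return TerminusAnnotation(Category.UNANNOTATED, WindowKind.NONE, offset, False, acetylated)


def annotate_peptides(
    peptides: Iterable[NTermPeptide],
    proteome: Mapping[str, ProteinEntry],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Annotate a collection of N-terminal peptides.

    Peptides matching multiple proteins are assigned to the
    lexicographically smallest accession and flagged ambiguous.  Returns
    one row per peptide with columns: terminus_id, accession, start,
    category, window_kind, offset, expected, acetylated, ambiguous,
    has_lys.
    """
    sequences = {acc: p.sequence for acc, p in proteome.items()}
    rows = []
    for pep in peptides:
        acc, start, ambiguous = pep.accession, pep.start_pos, pep.ambiguous
        if acc not in proteome:
            hits = map_peptide(pep.peptide_seq, sequences)
            if not hits:
                raise KeyError(f"peptide {pep.peptide_seq!r} maps to no protein")
            acc, start = hits[0]
            ambiguous = len({a for a, _ in hits}) > 1
        ann = classify_terminus(start, proteome[acc], cfg, acetylated=pep.acetylated)
        rows.append(
            {
                "terminus_id": pep.terminus_id,
                "accession": acc,
                "start": start,
                "category": ann.category.value,
                "window_kind": ann.window_kind.value,
                "offset": ann.offset,
                "expected": ann.expected,
                "acetylated": ann.acetylated,
                "ambiguous": ambiguous,
                "has_lys": pep.has_lys,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "terminus_id", "accession", "start", "category", "window_kind",
            "offset", "expected", "acetylated", "ambiguous", "has_lys",
        ],
    )
    return df.set_index("terminus_id")


def offset_histogram(annotations: pd.DataFrame, window_W: int = 5) -> pd.DataFrame:
    """Histogram of signed offsets to the predicted cleavage site.

    Counts every annotation row with a defined offset; ``in_window`` flags
    offsets inside the two-sided acceptance window.  Counts sum to the
    number of rows with a defined offset.
    """
    with_offset = annotations.dropna(subset=["offset"])
    counts = Counter(int(o) for o in with_offset["offset"])
    rows = [
        {"offset": off, "count": n, "in_window": abs(off) <= window_W}
        for off, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["offset", "count", "in_window"])


def detect_precursors(
    annotations: pd.DataFrame,
    proteome: Mapping[str, ProteinEntry],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Candidate intact precursor proteins.

    On presequence-bearing proteins, a terminus starting well upstream of
    the predicted cleavage site (``start <= cleavage_pos - W``, which
    includes POS1/POS2) indicates an unprocessed full-length precursor.
    ``quantifiable_via_lys`` flags whether the peptide carries a Lys whose
    labeled side chain permits channel-based quantification even when the
    alpha-amine is acetylated.
    """
    rows = []
    for terminus_id, row in annotations.iterrows():
        protein = proteome[row["accession"]]
        if protein.cleavage_pos is None:
            continue
        if row["start"] <= protein.cleavage_pos - cfg.window_W:
            rows.append(
                {
                    "terminus_id": terminus_id,
                    "accession": row["accession"],
                    "start": row["start"],
                    "category": row["category"],
                    "acetylated": row["acetylated"],
                    "quantifiable_via_lys": bool(row.get("has_lys", False)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["terminus_id", "accession", "start", "category", "acetylated",
                 "quantifiable_via_lys"],
    )


def tally_categories(
    annotations: pd.DataFrame, include_ambiguous: bool = False
) -> pd.DataFrame:
    """Counts of acetylated vs dimethylated termini per positional category.

    The partition is exhaustive and disjoint: each terminus counts exactly
    once and the grand total equals the number of (retained) input rows.
    Ambiguously mapped termini are excluded by default.
    """
    df = (
        annotations
        if include_ambiguous
        else annotations[~annotations["ambiguous"].astype(bool)]
    )
    order = [c.value for c in Category]
    tally = pd.DataFrame(0, index=order, columns=["acetylated", "dimethylated", "total"])
    for cat in order:
        sub = df[df["category"] == cat]
        n_ac = int(sub["acetylated"].sum())
        tally.loc[cat] = [n_ac, len(sub) - n_ac, len(sub)]
    tally.index.name = "category"
    return tally
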