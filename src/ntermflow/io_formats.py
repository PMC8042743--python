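"""Readers and writers for the external formats and the shared configuration.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout: position 1 is the
  initiator methionine.
* ``cleavage_pos`` denotes the *last* residue of a predicted transit or
  signal peptide; the mature N-terminus is ``cleavage_pos + 1``.  This
  matches how TargetP reports cleavage-site positions (presequence length).
* In quantification TSVs an empty cell or a literal ``0`` means "not
  quantified"; literal NaN text is rejected.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class Compartment(str, enum.Enum):
    """Predicted sub-cellular destination of a protein."""

    PLASTID = "plastid"
    MITOCHONDRION = "mitochondrion"
    SECRETORY = "secretory"
    OTHER = "other"


#: TargetP-2.0 class labels mapped onto compartments.
TARGETP_CLASSES: Mapping[str, Compartment] = {
    "cTP": Compartment.PLASTID,
    "mTP": Compartment.MITOCHONDRION,
    "SP": Compartment.SECRETORY,
    "noTP": Compartment.OTHER,
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinEntry:
    """One database protein with localization prediction.

    Parameters
    ----------
    accession : str
        Identifier (FASTA header token before the first whitespace).
    sequence : str
        Amino-acid sequence, uppercase, canonical 20 letters.
    compartment : Compartment
        Predicted destination; defaults to OTHER when no prediction exists.
    cleavage_pos : int or None
        1-based position of the last residue of the predicted transit or
        signal peptide, or ``None`` when no presequence is predicted.
    plastid_encoded : bool
        True for proteins encoded on the plastid genome, which carry no
        transit peptide.
    """

    accession: str
    sequence: str
    compartment: Compartment = Compartment.OTHER
    cleavage_pos: Optional[int] = None
    plastid_encoded: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.cleavage_pos is not None:
            if not 1 <= self.cleavage_pos < len(self.sequence):
                raise ValueError(
                    f"{self.accession}: cleavage_pos {self.cleavage_pos} outside "
                    f"[1, {len(self.sequence) - 1}]"
                )
            if self.plastid_encoded:
                raise ValueError(
                    f"{self.accession}: plastid-encoded protein cannot have a "
                    "transit-peptide cleavage position"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mature_start(self) -> Optional[int]:
        """1-based start of the predicted mature protein, if any."""
        return None if self.cleavage_pos is None else self.cleavage_pos + 1


@dataclass
class AnalysisConfig:
    """Shared analysis thresholds.

    Attributes
    ----------
    window_W : int
        Half-width, in residues, of the cleavage-site acceptance window
        ("within five amino acids"): an observed start within ``W`` of the
        predicted mature N-terminus counts as an expected cleavage product.
    alpha : float
        Per-test p-value threshold (moderated t, Tukey, pairwise t).
    fdr_q : float
        Benjamini-Hochberg FDR threshold for the proteome ANOVA.
    log2fc_tau : float
        Absolute log2 fold-change threshold; 0.58 corresponds to a 50%
        change in abundance.
    min_quant_reps : int
        Minimum replicates with a present value per group for a feature to
        be quantifiable.
    n_clusters_k : int
        Number of clusters cut from the hierarchical tree.
    impute_width : float
        Width of the imputation Gaussian as a fraction of the per-sample SD.
    impute_downshift : float
        Downshift of the imputation Gaussian mean, in per-sample SDs.
    rng_seed : int
        Master seed for all stochastic stages.
    """

    window_W: int = 5
    alpha: float = 0.05
    fdr_q: float = 0.05
    log2fc_tau: float = 0.58
    min_quant_reps: int = 2
    n_clusters_k: int = 7
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_q", "log2fc_tau", "impute_width", "impute_downshift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.window_W < 0:
            raise ValueError("window_W must be >= 0")
        if self.min_quant_reps < 1:
            raise ValueError("min_quant_reps must be >= 1")
        if self.n_clusters_k < 1:
            raise ValueError("n_clusters_k must be >= 1")

    _INT_FIELDS = ("window_W", "min_quant_reps", "n_clusters_k", "rng_seed")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key = value`` text config; unknown keys are errors."""
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = int(value) if key in cls._INT_FIELDS else float(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class QuantTable:
    """Intensity matrix with an explicit sample design.

    ``data`` is a DataFrame indexed by feature identifier (protein
    accession or terminus id) whose columns are ``<genotype>_<replicate>``;
    missing values are NaN.  ``design`` maps each column to its
    ``(genotype, replicate)`` pair.
    """

    data: pd.DataFrame
    design: pd.DataFrame  # columns: sample, genotype, replicate

    def __post_init__(self) -> None:
        if self.design["sample"].duplicated().any():
            raise ValueError("duplicate sample columns in design")
        missing = set(self.design["sample"]) - set(self.data.columns)
        if missing:
            raise FormatError(f"design references absent columns: {sorted(missing)}")
        values = self.data[list(self.design["sample"])].to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("intensities must be finite when present")

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.design["genotype"]))

    def columns_for(self, genotype: str) -> list[str]:
        sel = self.design.loc[self.design["genotype"] == genotype, "sample"]
        if sel.empty:
            raise KeyError(f"unknown genotype {genotype!r}")
        return list(sel)

    def matrix(self) -> pd.DataFrame:
        """Intensity columns in design order."""
        return self.data[list(self.design["sample"])]


def design_from_columns(columns: Sequence[str]) -> pd.DataFrame:
    """Infer a ``(genotype, replicate)`` design from ``<genotype>_<rep>`` names."""
    rows = []
    for col in columns:
        m = re.fullmatch(r"(.+)_([^_]+)", col)
        if not m:
            raise FormatError(f"cannot parse sample column {col!r} as <genotype>_<replicate>")
        rows.append({"sample": col, "genotype": m.group(1), "replicate": m.group(2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA into :class:`ProteinEntry` records.

    The accession is the header token before the first whitespace; sequences
    are uppercased with a single trailing ``*`` (stop) stripped.
    """
    path = Path(path)
    # Pre-scan for records with no header line: sequence text before any '>'.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}:{lineno}: sequence data before first header")
                break
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        entries.append(ProteinEntry(accession=record.id, sequence=seq))
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description="") for e in entries
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# TargetP-like localization table
# ---------------------------------------------------------------------------

def read_targetp_table(
    path: str | Path,
    sequences: Optional[Mapping[str, str]] = None,
) -> dict[str, tuple[Compartment, Optional[int]]]:
    """Read a TargetP-2.0-like TSV of per-protein localization predictions.

    Expected columns (tab-separated, with header): accession, predicted
    class (``cTP``/``mTP``/``SP``/``noTP``), cleavage-site position (empty
    or ``-`` when no presequence is predicted).  Unknown class labels map
    to ``other`` with a warning.  When ``sequences`` is given, cleavage
    positions are validated against sequence length.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 tab-separated columns")
    acc_col, class_col, cs_col = df.columns[:3]
    if df[acc_col].duplicated().any():
        dupes = df.loc[df[acc_col].duplicated(), acc_col].tolist()
        raise FormatError(f"{path}: duplicated accession(s) {dupes}")
    out: dict[str, tuple[Compartment, Optional[int]]] = {}
    for _, row in df.iterrows():
        acc = row[acc_col]
        label = row[class_col]
        if label in TARGETP_CLASSES:
            comp = TARGETP_CLASSES[label]
        else:
            logger.warning("unknown localization class %r for %s; mapped to 'other'", label, acc)
            comp = Compartment.OTHER
        raw_cs = row[cs_col]
        if raw_cs is None or (isinstance(raw_cs, float) and np.isnan(raw_cs)) or str(raw_cs).strip() in ("", "-", "—"):
            cs: Optional[int] = None
        else:
            cs = int(raw_cs)
            if cs < 1:
                raise FormatError(f"{path}: {acc}: cleavage position {cs} out of range")
            if sequences is not None and acc in sequences and cs >= len(sequences[acc]):
                raise FormatError(
                    f"{path}: {acc}: cleavage position {cs} >= sequence length "
                    f"{len(sequences[acc])}"
                )
        out[acc] = (comp, cs)
    return out


def write_targetp_table(
    predictions: Mapping[str, tuple[Compartment, Optional[int]]], path: str | Path
) -> None:
    inv = {v: k for k, v in TARGETP_CLASSES.items()}
    rows = [
        {
            "accession": acc,
            "prediction": inv[comp],
            "cleavage_site": "" if cs is None else cs,
        }
        for acc, (comp, cs) in predictions.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_predictions(
    entries: Iterable[ProteinEntry],
    predictions: Mapping[str, tuple[Compartment, Optional[int]]],
    plastid_encoded: Iterable[str] = (),
) -> list[ProteinEntry]:
    """Combine bare FASTA entries with localization predictions."""
    encoded = set(plastid_encoded)
    out = []
    for e in entries:
        comp, cs = predictions.get(e.accession, (Compartment.OTHER, None))
        if e.accession in encoded:
            out.append(
                ProteinEntry(e.accession, e.sequence, Compartment.PLASTID, None, True)
            )
        else:
            out.append(ProteinEntry(e.accession, e.sequence, comp, cs))
    return out


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

def read_quant_table(
    path: str | Path,
    design: Optional[pd.DataFrame] = None,
    id_column: Optional[str] = None,
) -> QuantTable:
    """Read a simplified MaxQuant-like quantification TSV.

    One row per protein or peptide; intensity columns are named
    ``<genotype>_<replicate>``.  Zero or empty cells become missing (zero
    intensity means "not quantified").  Non-intensity columns are kept as
    annotation.  When ``design`` is given, all its sample columns must be
    present; otherwise the design is inferred from the column names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column is None:
        id_column = df.columns[0]
    df = df.set_index(id_column)
    df = df.replace("", np.nan).infer_objects(copy=False)
    if design is None:
        # inferred sample columns are <genotype>_<replicate number>;
        # annotation columns (sequences, names) do not match
        candidates = [c for c in df.columns if re.fullmatch(r".+_\d+", c)]
        design = design_from_columns(candidates)
    else:
        absent = set(design["sample"]) - set(df.columns)
        if absent:
            raise FormatError(f"{path}: design columns missing from file: {sorted(absent)}")
    sample_cols = list(design["sample"])
    for col in sample_cols:
        raw = df[col]
        present = raw.notna()
        if raw[present].astype(str).str.strip().str.lower().isin(["nan"]).any():
            raise FormatError(f"{path}: literal NaN text in column {col!r}; use empty or 0")
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & present
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"{path}: non-numeric intensity at row {row!r}, column {col!r}")
        parsed = parsed.mask(parsed == 0.0)  # zero intensity = not quantified
        if (parsed < 0).any():
            row = parsed.index[parsed < 0][0]
            raise FormatError(f"{path}: negative intensity at row {row!r}, column {col!r}")
        df[col] = parsed
    for c in (c for c in df.columns if c not in sample_cols):
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return QuantTable(data=df, design=design.reset_index(drop=True))


def write_quant_table(table: QuantTable, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a quantification table; missing values become empty cells."""
    table.data.to_csv(path, sep="\t", float_format=float_format, na_rep="")
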