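"""Synthetic proteome, terminome, proteome-quant and pull-down experiments.

The generators emulate the structure of a three-genotype (wild type, a
knock-down line and an overexpressor line) seedling experiment with four
biological replicates:

* a toy protein database with per-protein compartment predictions and
  transit/signal-peptide cleavage sites;
* an N-terminome of ~1,300 terminal peptides spanning the positional
  categories (start sites with intact or excised initiator Met, cleavage-
  site windows with ragged +/-2 offsets, internal proteolysis), with
  category-specific N-terminal acetylation frequencies (0.89 at position 1,
  0.78 at position 2, 0.27 for mature plastid termini, 0 for signal-
  peptide-processed termini);
* a label-free proteome of ~3,000 proteins with genotype effects and
  missing-not-at-random dropout (missingness increases as intensity
  decreases, via a logistic link);
* bait/control co-immunoprecipitation tables with a known interactor set.

Every generator is a pure function of its parameters and seed; ground
truth is returned alongside each simulated table so downstream stages can
be tested for exact recovery.

In the dimethylation labeling scheme only free primary amines take the
isotopic label, so an endogenously acetylated N-terminal peptide is
quantifiable across channels only through the side chain of an internal
Lys.  The simulator draws real peptide sequences from the toy proteome and
derives Lys content from them; acetylated termini without Lys are emitted
as identified-but-not-quantified (all intensities missing).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ntermflow.io_formats import Compartment, ProteinEntry, QuantTable, design_from_columns
from ntermflow.terminome_annotation import Category

GENOTYPES = ("wt", "mi", "ox")

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def operation_rng(seed: int, operation: str) -> np.random.Generator:
    """Independent RNG stream per operation, derived from the master seed."""
    sub = (int(seed) ^ zlib.crc32(operation.encode())) % (2**31)
    return np.random.default_rng(sub)


@dataclass
class SimParams:
    """Knobs of all generators, with defaults matching the study's scale.

    Intensity parameters are on the log2 scale (label-free MS1 intensities
    span roughly 2^20-2^30); ``rep_sigma`` is the replicate-to-replicate
    log2 noise.  ``category_weights`` gives the terminome category mixture;
    ``acetylation_probs`` the per-category endogenous N-terminal
    acetylation frequencies; ``offset_weights`` the ragged-cleavage offset
    distribution over residues -2..+2.
    """

    # proteome database
    n_proteins: int = 3000
    frac_plastid_tp: float = 0.20
    frac_mito_tp: float = 0.10
    frac_sp: float = 0.10
    frac_plastid_encoded: float = 0.02
    min_length: int = 120
    max_length: int = 600
    cleavage_min: int = 30
    cleavage_max: int = 80

    # terminome
    n_termini: int = 1300
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "POS1": 0.18,
            "POS2": 0.33,
            "TP_plastid": 0.14,
            "TP_mito": 0.04,
            "SP": 0.04,
            "internal": 0.27,
        }
    )
    acetylation_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "POS1": 0.89,
            "POS2": 0.78,
            "TP_plastid": 0.27,
            "TP_mito": 0.05,
            "SP": 0.0,
            "internal": 0.125,
        }
    )
    offset_weights: Mapping[int, float] = field(
        default_factory=lambda: {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}
    )
    peptide_min_len: int = 8
    peptide_max_len: int = 25
    term_effect_frac: float = 0.10
    term_effect_log2: float = 1.0
    term_missingness: float = 0.10

    # quantitative proteome
    log2_loc: float = 23.0
    log2_scale: float = 2.0
    rep_sigma: float = 0.25
    effect_frac: float = 0.45
    effect_log2_min: float = 0.58
    effect_log2_max: float = 2.0
    missingness: float = 0.10
    miss_logit_slope: float = 0.8  # per log2 unit, steeper = more MNAR
    n_replicates: int = 4

    # co-immunoprecipitation
    n_true_interactors: int = 8
    n_background: int = 100
    n_bait_reps: int = 2
    n_controls: int = 2
    bg_presence_prob: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be > 0")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category weights must sum to 1, got {total}")
        for k, p in self.acetylation_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"acetylation probability for {k} outside [0, 1]")
        if not 0.0 <= self.effect_frac <= 1.0:
            raise ValueError("effect_frac must be in [0, 1]")
        total_off = sum(self.offset_weights.values())
        if abs(total_off - 1.0) > 1e-9:
            raise ValueError("offset weights must sum to 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment (a table per aspect)."""

    termini: Optional[pd.DataFrame] = None  # terminome truth
    proteins: Optional[pd.DataFrame] = None  # proteome-quant truth
    interactors: Optional[set] = None  # coip truth


# ---------------------------------------------------------------------------
# toy proteome
# ---------------------------------------------------------------------------

def generate_proteome(params: SimParams) -> list[ProteinEntry]:
    """A toy protein database with localization predictions.

    Sequences are i.i.d. uniform over the 20 canonical amino acids with
    position 1 fixed to Met.  Presequence-bearing fractions (plastid TP,
    mitochondrial TP, secretory SP) get a cleavage position drawn uniform
    in [cleavage_min, cleavage_max]; a small fraction is plastid-encoded
    (chloroplast annotation, no transit peptide).  Deterministic for a
    given seed.
    """
    rng = operation_rng(params.seed, "generate_proteome")
    n = params.n_proteins
    n_ptp = round(n * params.frac_plastid_tp)
    n_mtp = round(n * params.frac_mito_tp)
    n_sp = round(n * params.frac_sp)
    n_enc = round(n * params.frac_plastid_encoded)
    if n_ptp + n_mtp + n_sp + n_enc > n:
        raise ValueError("compartment fractions exceed 1")
    kinds = (
        [("plastid_tp")] * n_ptp
        + ["mito_tp"] * n_mtp
        + ["sp"] * n_sp
        + ["plastid_encoded"] * n_enc
    )
    kinds += ["other"] * (n - len(kinds))

    lengths = rng.integers(params.min_length, params.max_length + 1, size=n)
    entries = []
    width = len(str(n))
    for i, (kind, length) in enumerate(zip(kinds, lengths), start=1):
        seq = "M" + "".join(rng.choice(AA, size=int(length) - 1))
        acc = f"SYN{i:0{width}d}"
        if kind in ("plastid_tp", "mito_tp", "sp"):
            cs = int(rng.integers(params.cleavage_min, params.cleavage_max + 1))
            comp = {
                "plastid_tp": Compartment.PLASTID,
                "mito_tp": Compartment.MITOCHONDRION,
                "sp": Compartment.SECRETORY,
            }[kind]
            entries.append(ProteinEntry(acc, seq, comp, cs))
        elif kind == "plastid_encoded":
            entries.append(ProteinEntry(acc, seq, Compartment.PLASTID, None, True))
        else:
            entries.append(ProteinEntry(acc, seq, Compartment.OTHER, None))
    return entries


# ---------------------------------------------------------------------------
# terminome
# ---------------------------------------------------------------------------

_CATEGORY_TRUTH = {
    "POS1": Category.POS1.value,
    "POS2": Category.POS2.value,
    "TP_plastid": Category.CLEAVAGE_WINDOW.value,
    "TP_mito": Category.CLEAVAGE_WINDOW.value,
    "SP": Category.CLEAVAGE_WINDOW.value,
    "internal": Category.UNANNOTATED.value,
}

_WINDOW_COMPARTMENT = {
    "TP_plastid": Compartment.PLASTID,
    "TP_mito": Compartment.MITOCHONDRION,
    "SP": Compartment.SECRETORY,
}


def _sample_columns(params: SimParams) -> list[str]:
    return [f"{g}_{r}" for g in GENOTYPES for r in range(1, params.n_replicates + 1)]


def simulate_terminome(
    proteome: Sequence[ProteinEntry], params: SimParams, window_W: int = 5
) -> tuple[QuantTable, SimTruth]:
    """Simulate identified N-terminal peptides with per-channel intensities.

    Start positions follow the true category (POS1 -> 1, POS2 -> 2,
    cleavage windows -> predicted mature start plus a ragged offset,
    internal -> a position outside every expected region).  Acetylation is
    drawn per category; acetylated termini lacking an internal Lys carry
    no quantifiable label and get all-missing intensities.  A fraction of
    termini carries a genotype effect (higher in the overexpressor,
    flagged in the returned truth).
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = operation_rng(params.seed, "simulate_terminome")
    by_kind: dict[str, list[ProteinEntry]] = {"any": [], "TP_plastid": [], "TP_mito": [], "SP": []}
    for p in proteome:
        by_kind["any"].append(p)
        if p.cleavage_pos is not None:
            if p.compartment is Compartment.PLASTID:
                by_kind["TP_plastid"].append(p)
            elif p.compartment is Compartment.MITOCHONDRION:
                by_kind["TP_mito"].append(p)
            elif p.compartment is Compartment.SECRETORY:
                by_kind["SP"].append(p)

    cats = list(params.category_weights)
    weights = np.array([params.category_weights[c] for c in cats])
    offsets = np.array(sorted(params.offset_weights))
    off_w = np.array([params.offset_weights[o] for o in offsets])
    cols = _sample_columns(params)
    geno_of_col = [c.rsplit("_", 1)[0] for c in cols]

    rows, truth_rows = [], []
    used: set[tuple[str, int]] = set()
    for i in range(params.n_termini):
        for _attempt in range(200):
            cat = cats[rng.choice(len(cats), p=weights)]
            pool = by_kind[cat] if cat in _WINDOW_COMPARTMENT else by_kind["any"]
            if not pool:
                raise RuntimeError(f"no protein compatible with category {cat}")
            protein = pool[rng.integers(len(pool))]
            offset = 0
            if cat == "POS1":
                start = 1
            elif cat == "POS2":
                start = 2
            elif cat in _WINDOW_COMPARTMENT:
                offset = int(offsets[rng.choice(len(offsets), p=off_w)])
                start = protein.cleavage_pos + 1 + offset
            else:  # internal: outside positions 1/2 and any cleavage window
                lo = 3
                hi = len(protein.sequence) - params.peptide_min_len
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                if protein.cleavage_pos is not None and (
                    abs(start - (protein.cleavage_pos + 1)) <= window_W
                ):
                    continue
            if (protein.accession, start) in used:
                continue
            used.add((protein.accession, start))
            break
        else:
            raise RuntimeError("could not place terminus; proteome too small")

        pep_len = int(rng.integers(params.peptide_min_len, params.peptide_max_len + 1))
        pep_len = min(pep_len, len(protein.sequence) - start + 1)
        pep_seq = protein.sequence[start - 1 : start - 1 + pep_len]
        acetylated = bool(rng.random() < params.acetylation_probs[cat])
        has_lys = "K" in pep_seq
        quantifiable = (not acetylated) or has_lys

        has_effect = bool(rng.random() < params.term_effect_frac)
        mult = {g: 1.0 for g in GENOTYPES}
        if has_effect:
            mult["ox"] = 2.0 ** params.term_effect_log2
        base = rng.normal(params.log2_loc, params.log2_scale)
        terminus_id = f"{protein.accession}@{start}"
        intensities: dict[str, float] = {}
        if quantifiable:
            for col, g in zip(cols, geno_of_col):
                if rng.random() < params.term_missingness:
                    intensities[col] = np.nan
                else:
                    log2v = base + np.log2(mult[g]) + rng.normal(0.0, params.rep_sigma)
                    intensities[col] = 2.0**log2v
        else:
            intensities = {col: np.nan for col in cols}

        rows.append({"terminus_id": terminus_id, "peptide_seq": pep_seq, **intensities})
        truth_rows.append(
            {
                "terminus_id": terminus_id,
                "accession": protein.accession,
                "start": start,
                "category": _CATEGORY_TRUTH[cat],
                "window_kind": cat if cat in _WINDOW_COMPARTMENT else "none",
                "offset": (
                    start - (protein.cleavage_pos + 1)
                    if protein.cleavage_pos is not None
                    else np.nan
                ),
                "acetylated": acetylated,
                "has_lys": has_lys,
                "quantifiable": quantifiable,
                "effect": has_effect,
                **{f"mult_{g}": mult[g] for g in GENOTYPES},
            }
        )

    data = pd.DataFrame(rows).set_index("terminus_id")
    table = QuantTable(data=data, design=design_from_columns(cols))
    truth = SimTruth(termini=pd.DataFrame(truth_rows).set_index("terminus_id"))
    return table, truth


# ---------------------------------------------------------------------------
# quantitative proteome
# ---------------------------------------------------------------------------

def simulate_proteome_quant(
    proteome: Sequence[ProteinEntry], params: SimParams
) -> tuple[QuantTable, SimTruth]:
    """Simulate a label-free proteome quantification table.

    Per-protein log-normal intensities over 3 genotypes x n replicates; a
    fraction ``effect_frac`` of proteins carries a genotype effect, split
    evenly between up-in-overexpressor and up-in-knock-down classes, with
    |log2 effect| uniform in [effect_log2_min, effect_log2_max].
    Missingness is not-at-random: the per-cell dropout probability follows
    a logistic link decreasing with log2 intensity, rescaled so the
    expected overall missing fraction equals ``missingness``.
    """
    if not 0.0 <= params.effect_frac <= 1.0:
        raise ValueError("effect fraction outside [0, 1]")
    rng = operation_rng(params.seed, "simulate_proteome_quant")
    n = len(proteome)
    cols = _sample_columns(params)
    geno_idx = np.array([GENOTYPES.index(c.rsplit("_", 1)[0]) for c in cols])

    classes = np.array(["null"] * n, dtype=object)
    n_eff = round(n * params.effect_frac)
    eff_idx = rng.choice(n, size=n_eff, replace=False)
    half = n_eff // 2
    classes[eff_idx[:half]] = "up_in_ox"
    classes[eff_idx[half:]] = "up_in_mi"

    base = rng.normal(params.log2_loc, params.log2_scale, size=n)
    eff_size = rng.uniform(params.effect_log2_min, params.effect_log2_max, size=n)
    log2_mult = np.zeros((n, len(GENOTYPES)))
    log2_mult[classes == "up_in_ox", GENOTYPES.index("ox")] = eff_size[classes == "up_in_ox"]
    log2_mult[classes == "up_in_mi", GENOTYPES.index("mi")] = eff_size[classes == "up_in_mi"]

    log2_int = (
        base[:, None]
        + log2_mult[:, geno_idx]
        + rng.normal(0.0, params.rep_sigma, size=(n, len(cols)))
    )

    if params.missingness > 0:
        # logistic MNAR weight, rescaled to the target overall rate
        from scipy.special import expit

        w = expit(-params.miss_logit_slope * (log2_int - params.log2_loc))
        p_miss = np.clip(params.missingness * w / w.mean(), 0.0, 1.0)
        miss = rng.random(size=log2_int.shape) < p_miss
    else:
        miss = np.zeros_like(log2_int, dtype=bool)

    values = 2.0**log2_int
    values[miss] = np.nan
    accs = [p.accession for p in proteome]
    data = pd.DataFrame(values, index=pd.Index(accs, name="accession"), columns=cols)
    # iBAQ proxy: mean intensity per genotype (absolute-abundance stand-in)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-missing genotypes
        for g in GENOTYPES:
            gcols = [c for c in cols if c.rsplit("_", 1)[0] == g]
            data[f"iBAQ_{g}"] = np.nanmean(
                values[:, [cols.index(c) for c in gcols]], axis=1
            )
    table = QuantTable(data=data, design=design_from_columns(cols))
    truth = SimTruth(
        proteins=pd.DataFrame(
            {
                "accession": accs,
                "diff_class": classes,
                "log2_effect": np.where(classes == "null", 0.0, eff_size),
                "base_log2": base,
            }
        ).set_index("accession")
    )
    return table, truth


# ---------------------------------------------------------------------------
# co-immunoprecipitation
# ---------------------------------------------------------------------------

def simulate_coip(
    proteome: Sequence[ProteinEntry], params: SimParams
):
    """Simulate bait/control pull-down records with a known interactor set.

    True interactors are chloroplast proteins present in every bait
    replicate and absent from all controls; background proteins appear
    sporadically in any sample with probability ``bg_presence_prob``.
    Returns ``(records, truth)`` where ``truth.interactors`` is the true
    accession set.
    """
    from ntermflow.interaction_filter import PulldownRecord

    rng = operation_rng(params.seed, "simulate_coip")
    chloro = [p for p in proteome if p.compartment is Compartment.PLASTID]
    if len(chloro) < params.n_true_interactors:
        raise ValueError("not enough chloroplast proteins for the interactor set")
    pick = rng.choice(len(chloro), size=params.n_true_interactors, replace=False)
    true_set = {chloro[i].accession for i in pick}
    others = [p for p in proteome if p.accession not in true_set]
    n_bg = min(params.n_background, len(others))
    bg_pick = rng.choice(len(others), size=n_bg, replace=False)

    records = []
    for p in (chloro[i] for i in pick):
        bait = 20.0 + rng.normal(0.0, 1.0, size=params.n_bait_reps)
        records.append(
            PulldownRecord(
                accession=p.accession,
                bait_intensities=list(bait),
                control_intensities=[np.nan] * params.n_controls,
                chloroplast_annotated=True,
                unique_peptides=int(rng.integers(2, 30)),
                coverage_pct=float(rng.uniform(5, 80)),
            )
        )
    for p in (others[i] for i in bg_pick):
        bait = [
            20.0 + rng.normal(0.0, 1.0) if rng.random() < params.bg_presence_prob else np.nan
            for _ in range(params.n_bait_reps)
        ]
        ctrl = [
            18.0 + rng.normal(0.0, 1.0) if rng.random() < params.bg_presence_prob else np.nan
            for _ in range(params.n_controls)
        ]
        records.append(
            PulldownRecord(
                accession=p.accession,
                bait_intensities=bait,
                control_intensities=ctrl,
                chloroplast_annotated=p.compartment is Compartment.PLASTID,
                unique_peptides=int(rng.integers(1, 10)),
                coverage_pct=float(rng.uniform(1, 40)),
            )
        )
    return records, SimTruth(interactors=true_set)
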