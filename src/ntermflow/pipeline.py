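"""End-to-end orchestration: simulate -> annotate -> terminome differential
-> proteome differential -> clustering -> pull-down filter, with a run
manifest that fully determines a rerun of the deterministic stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import ntermflow
from ntermflow.io_formats import (
    AnalysisConfig,
    ProteinEntry,
    write_fasta,
    write_quant_table,
    write_targetp_table,
)
from ntermflow import interaction_filter, proteome_stats, synthetic_data, terminome_stats
from ntermflow.synthetic_data import SimParams
from ntermflow.terminome_annotation import NTermMod, NTermPeptide, annotate_peptides, offset_histogram, tally_categories

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """What went into a run: config, input checksums, seed, versions."""

    config: dict
    sim_params: dict
    seed: int
    package_version: str = ntermflow.__version__
    input_checksums: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _peptides_from_sim(table, truth) -> list[NTermPeptide]:
    peps = []
    for tid, row in table.data.iterrows():
        tr = truth.termini.loc[tid]
        intensities = {
            c: float(row[c]) for c in table.design["sample"] if np.isfinite(row[c])
        }
        peps.append(
            NTermPeptide(
                peptide_seq=row["peptide_seq"],
                accession=tr["accession"],
                start_pos=int(tr["start"]),
                nterm_mod=NTermMod.ACETYLATED if tr["acetylated"] else NTermMod.FREE_DIMETHYLATED,
                channel_intensities=intensities,
                terminus_id=tid,
            )
        )
    return peps


def run_pipeline(
    cfg: AnalysisConfig,
    out_dir: str | Path,
    sim_params: Optional[SimParams] = None,
) -> RunManifest:
    """Run every stage on a freshly simulated dataset and write the report.

    Outputs under ``out_dir``: proteome FASTA + localization TSV, terminome
    and proteome quant TSVs with ground truth, annotation table, category
    tallies, offset histogram, volcano tables per genotype pair, ANOVA/
    Tukey/cluster results, cluster profiles, candidate interactors, and
    ``manifest.json``.  Any stage failure raises :class:`StageError` naming
    the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = sim_params or SimParams(seed=cfg.rng_seed)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        sim_params={
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(params).items()
        },
        seed=cfg.rng_seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    header = f"# ntermflow {ntermflow.__version__} seed={cfg.rng_seed}\n"

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        proteome = synthetic_data.generate_proteome(params)
        by_acc = {p.accession: p for p in proteome}
        write_fasta(proteome, out / "proteome.fasta")
        write_targetp_table(
            {p.accession: (p.compartment, p.cleavage_pos) for p in proteome},
            out / "localization.tsv",
        )
        term_table, term_truth = synthetic_data.simulate_terminome(
            proteome, params, window_W=cfg.window_W
        )
        prot_table, prot_truth = synthetic_data.simulate_proteome_quant(proteome, params)
        write_quant_table(term_table, out / "terminome_quant.tsv")
        write_quant_table(prot_table, out / "proteome_quant.tsv")
        term_truth.termini.to_csv(out / "terminome_truth.tsv", sep="\t")
        prot_truth.proteins.to_csv(out / "proteome_truth.tsv", sep="\t")
        for f in ("proteome.fasta", "localization.tsv", "terminome_quant.tsv", "proteome_quant.tsv"):
            manifest.input_checksums[f] = _checksum(out / f)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        stage("annotate")
        peptides = _peptides_from_sim(term_table, term_truth)
        annotations = annotate_peptides(peptides, by_acc, cfg)
        with open(out / "annotations.tsv", "w") as fh:
            fh.write(header)
            annotations.to_csv(fh, sep="\t")
        tally = tally_categories(annotations)
        tally.to_csv(out / "category_tally.tsv", sep="\t")
        plastid_rows = annotations[
            annotations["accession"].map(
                lambda a: by_acc[a].compartment.value == "plastid"
                and by_acc[a].cleavage_pos is not None
            )
        ]
        offset_histogram(plastid_rows, cfg.window_W).to_csv(
            out / "offset_histogram.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    try:
        stage("term-diff")
        plastid_flag = annotations["accession"].map(
            lambda a: by_acc[a].compartment.value == "plastid"
        )
        summary_lines = []
        for a, b in (("ox", "mi"), ("wt", "mi"), ("ox", "wt")):
            res = terminome_stats.moderated_t_table(term_table, a, b, cfg)
            res = terminome_stats.significance_filter(res, cfg)
            volcano = terminome_stats.volcano_table(res, plastid_flag)
            with open(out / f"volcano_{a}_vs_{b}.tsv", "w") as fh:
                fh.write(header)
                volcano.to_csv(fh, sep="\t")
            summary_lines.append(
                f"{a} vs {b}: {res.attrs['n_up']} up, {res.attrs['n_down']} down"
            )
        (out / "term_diff_summary.txt").write_text("\n".join(summary_lines) + "\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("term-diff", exc) from exc

    try:
        stage("prot-diff")
        results = proteome_stats.run_proteome_pipeline(prot_table, cfg, seed=cfg.rng_seed)
        with open(out / "proteome_results.tsv", "w") as fh:
            fh.write(header)
            results.to_frame().to_csv(fh, sep="\t")
        results.cluster_profiles.to_csv(out / "cluster_profiles.tsv", sep="\t")
        pca, evr = proteome_stats.pca_coordinates(
            results.completed, results.anova.index[results.anova["significant"]]
        )
        pca.to_csv(out / "pca_scores.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError("prot-diff", exc) from exc

    try:
        stage("coip")
        records, coip_truth = synthetic_data.simulate_coip(proteome, params)
        kept = interaction_filter.stringent_subset(records)
        with open(out / "candidate_interactors.tsv", "w") as fh:
            fh.write(header)
            interaction_filter.candidates_table(kept).to_csv(fh, sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("coip", exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
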