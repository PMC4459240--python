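"""End-to-end analysis pipeline: read -> QC -> drop -> impute -> shape PCA
-> ratio spectra -> ratio extraction -> report -> identification key.

``run_all`` executes the stages deterministically for a given seed and
writes TSV outputs with commented headers recording the parameters, so a
re-run with identical inputs reproduces byte-identical numbers.  Any stage
failure aborts with the stage name; files written by the failed run are
removed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .measurement_data import (MeasurementTable, correlation_qc,
                               drop_variables, impute_missing,
                               read_measurement_table)
from .core import (allometry_ratio_spectrum, pca_ratio_spectrum,
                   shape_decompose, shape_pca, variance_explained)
from .ratio_extractor import GroupComparison, table2_report
from .taxon_key import classify_table

__all__ = ["PipelineConfig", "StageError", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_csv: str
    out_dir: str
    qc_threshold: float = 0.5
    drop: list[str] = field(default_factory=list)  # force-dropped variables
    drop_flagged: bool = True
    comparisons: list[tuple] = field(default_factory=list)  # (side1, side2)
    n_ratios: int = 2
    n_boot: int = 1000
    level: float = 0.68
    spectrum_pcs: list[int] = field(default_factory=lambda: [1])
    run_key: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["comparisons"] = [tuple(c) for c in raw.get("comparisons", [])]
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(path: Path, text: str, written: list[Path]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    written.append(path)


def _frame_tsv(df: pd.DataFrame, header: str) -> str:
    return f"# {header}\n" + df.to_csv(sep="\t", float_format="%.10g")


def run_all(config: PipelineConfig,
            table: MeasurementTable | None = None) -> dict:
    """Run the full analysis; returns a dict of in-memory results.

    *table* may be supplied directly to skip the read stage (e.g. a
    simulated table); otherwise ``config.input_csv`` is read.
    """
    out = Path(config.out_dir)
    written: list[Path] = []
    results: dict = {}
    log_lines = [
        f"mra {__version__} | python {sys.version.split()[0]} | "
        f"numpy {np.__version__} | pandas {pd.__version__}",
        f"seed={config.seed} qc_threshold={config.qc_threshold} "
        f"n_ratios={config.n_ratios} n_boot={config.n_boot} "
        f"level={config.level} drop={config.drop}",
    ]

    stage = "read"
    try:
        if table is None:
            table = read_measurement_table(config.input_csv)
        log_lines.append(f"read: {table.n_specimens} specimens x "
                         f"{len(table.columns)} characters")

        stage = "qc"
        qc = correlation_qc(table, config.qc_threshold)
        results["qc"] = qc
        _write(out / "qc.tsv", qc.to_tsv(), written)
        log_lines.append(f"qc: flagged {qc.flagged_variables}")

        stage = "drop"
        to_drop = list(dict.fromkeys(
            (qc.flagged_variables if config.drop_flagged else []) + config.drop))
        to_drop = [v for v in to_drop if v in table.columns]
        table = drop_variables(table, to_drop)
        log_lines.append(f"drop: removed {to_drop}, "
                         f"{len(table.columns)} characters remain")

        stage = "impute"
        table, imp_log = impute_missing(table, seed=config.seed)
        results["imputation"] = imp_log
        _write(out / "imputation_log.tsv", imp_log.to_tsv(), written)
        log_lines.append(f"impute: {imp_log.n_imputed_cells} cells "
                         f"(converged={imp_log.converged})")

        stage = "shape_pca"
        shape = shape_decompose(table)
        pca = shape_pca(shape)
        results["shape"] = shape
        results["pca"] = pca
        scores = pca.scores.copy()
        scores.insert(0, "isosize", shape.isosize)
        scores.insert(0, "group", shape.group)
        _write(out / "shape_scores.tsv",
               _frame_tsv(scores, f"shape PCA scores, seed={config.seed}"),
               written)
        ve2 = variance_explained(pca, min(2, len(pca.eigenvalues)))
        log_lines.append(f"shape_pca: PC1+PC2 variance fraction {ve2:.3f}")

        stage = "spectra"
        spectra = {}
        for pc in config.spectrum_pcs:
            sp = pca_ratio_spectrum(pca, pc, shape, n_boot=config.n_boot,
                                    level=config.level, seed=config.seed)
            spectra[f"PC{pc}"] = sp
            _write(out / "spectra" / f"pca_ratio_spectrum_PC{pc}.tsv",
                   _frame_tsv(sp.to_frame(),
                              f"PCA ratio spectrum PC{pc}, n_boot={sp.n_boot}, "
                              f"level={sp.level}, stratified={sp.stratified}, "
                              f"seed={config.seed}"),
                   written)
        asp = allometry_ratio_spectrum(shape, n_boot=config.n_boot,
                                       level=config.level, seed=config.seed)
        spectra["allometry"] = asp
        _write(out / "spectra" / "allometry_ratio_spectrum.tsv",
               _frame_tsv(asp.to_frame(),
                          f"allometry ratio spectrum, n_boot={asp.n_boot}, "
                          f"level={asp.level}, stratified={asp.stratified}, "
                          f"seed={config.seed}"),
               written)
        results["spectra"] = spectra

        if not config.comparisons:
            log_lines.append("no comparisons configured; "
                             "stopping after spectra")
            _write(out / "run_log.txt", "\n".join(log_lines) + "\n", written)
            return results

        stage = "extract"
        comps = [GroupComparison.from_table(table, s1, s2)
                 for s1, s2 in config.comparisons]
        report = table2_report(table, comps, n_ratios=config.n_ratios)
        results["report"] = report
        _write(out / "table2_report.tsv",
               _frame_tsv(report.set_index("comparison"),
                          f"best-ratio report, seed={config.seed}"),
               written)
        log_lines.append(f"extract: {len(report)} ratio rows for "
                         f"{len(comps)} comparisons")

        if config.run_key:
            stage = "key"
            key_df = classify_table(table)
            results["key"] = key_df
            _write(out / "key_results.tsv",
                   _frame_tsv(key_df, f"key classification, seed={config.seed}"),
                   written)
            counts = key_df["label"].value_counts().to_dict()
            log_lines.append(f"key: {counts}")

        _write(out / "run_log.txt", "\n".join(log_lines) + "\n", written)
        return results
    except StageError:
        raise
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(stage, exc) from exc
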