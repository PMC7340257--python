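"""End-to-end orchestration of the screen scoring pipeline.

``run_screen`` wires the stages together: read library + measurements,
quantify per-pair fold changes, assemble the protein x metabolite matrix,
apply the PC correction and robust-null scoring, and write results,
correction report and a run log capturing every parameter.  Given the same
inputs and configuration the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import quant, stats

__all__ = ["RunConfig", "run_screen", "matrix_from_fold_changes"]

logger = logging.getLogger("midaskit")

RESULT_COLUMNS = [
    "protein_id",
    "metabolite_id",
    "log2fc",
    "corrected_log2fc",
    "z",
    "p",
    "q",
    "significant",
]


@dataclasses.dataclass
class RunConfig:
    """Parameters of one pipeline run (YAML-loadable)."""

    library_path: str
    measurements_path: str
    out_dir: str
    k_components: int = stats.DEFAULT_K_COMPONENTS
    lambda_: float = 0.5
    p_thresh: float = stats.DEFAULT_P_THRESHOLD
    q_thresh: float = stats.DEFAULT_Q_THRESHOLD
    outlier_cutoff: float = quant.DEFAULT_OUTLIER_CUTOFF
    floor: float | None = None
    min_null_n: int = stats.DEFAULT_MIN_NULL_N
    blank_subtract: bool = False
    make_volcano: bool = False
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.p_thresh < 1) or not (0 < self.q_thresh < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.k_components < 0:
            raise ValueError("k_components must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def matrix_from_fold_changes(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Pivot the per-pair table to a protein x metabolite mean-log2fc matrix."""
    return fold_changes.pivot(
        index="protein_id", columns="metabolite_id", values="mean_log2fc"
    )


def run_screen(config: RunConfig) -> pd.DataFrame:
    """Run the full scoring pipeline and write outputs to ``out_dir``.

    Writes ``results.tsv`` (one row per pair, ranked by |z|),
    ``fold_changes.tsv``, ``correction_report.json`` and ``run.log``.
    Returns the results frame.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, str(config.verbosity).upper(), logging.INFO))
    try:
        logger.info("run parameters: %s", json.dumps(dataclasses.asdict(config)))

        library = mio.read_library(config.library_path)
        logger.info("library: %d metabolites in %d pools", len(library), library.n_pools)
        table = mio.read_measurements(config.measurements_path)
        logger.info("measurements: %d injections", len(table))

        fc = quant.fold_change_table(
            table,
            floor=config.floor,
            outlier_cutoff=config.outlier_cutoff,
            blank_subtract=config.blank_subtract,
        )
        removed = int(fc["outlier_removed"].sum())
        logger.info(
            "fold changes: %d pairs, %d outlier replicate(s) removed (%.3f%% of values)",
            len(fc),
            removed,
            100.0 * removed / max(fc[[c for c in fc.columns if c.startswith("log2fc_rep")]].size, 1),
        )

        matrix = matrix_from_fold_changes(fc)
        results, corrected, report = stats.score_screen(
            matrix,
            k_components=config.k_components,
            min_null_n=config.min_null_n,
            lambda_=config.lambda_,
            p_thresh=config.p_thresh,
            q_thresh=config.q_thresh,
        )
        logger.info(
            "PC correction: removed %d component(s), %.1f%% of variance",
            report.k_removed,
            100.0 * report.variance_fraction_removed,
        )
        logger.info("significant calls: %d", int(results["significant"].sum()))

        fc.to_csv(out_dir / "fold_changes.tsv", sep="\t", index=False)
        results[RESULT_COLUMNS].to_csv(out_dir / "results.tsv", sep="\t", index=False)
        (out_dir / "correction_report.json").write_text(
            json.dumps(
                {
                    "k_removed": report.k_removed,
                    "variance_fraction_removed": report.variance_fraction_removed,
                    "singular_values": list(map(float, report.singular_values)),
                },
                indent=2,
            )
        )
        if config.make_volcano:
            stats.plot_volcano(results, path=out_dir / "volcano.png")
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
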