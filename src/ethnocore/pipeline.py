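"""End-to-end orchestration: free lists in, comparison report out.

``run_comparison`` executes the full analysis for a two-group dataset:
read -> canonicalize -> salience -> null-model threshold -> core/satellite
classification per group -> core-union composition matrix -> Jaccard ->
PERMANOVA + dispersion homogeneity + PCoA.  ``run_matrix_comparison``
enters at a pre-built presence/absence matrix and runs only the
comparison stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .comparison import (
    CompositionMatrix,
    DispersionResult,
    PcoaResult,
    PermanovaResult,
    betadisper,
    build_core_matrix,
    jaccard_distances,
    pcoa,
    permanova,
    plot_ordination,
    read_matrix_csv,
)
from .freelists import (
    FreeListDataset,
    canonicalize_items,
    read_freelists,
    read_synonym_map,
    summarize,
)
from .salience import (
    NullModelConfig,
    SalienceTable,
    classify_core,
    compute_salience,
    null_salience_distribution,
    salience_pvalues,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_comparison", "run_matrix_comparison"]

log = logging.getLogger("ethnocore")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a full two-group comparison run.

    ``seed`` is the master seed; the null model and the permutation tests
    draw from deterministically derived substreams so each stage can be
    rerun independently with identical results.
    """

    input_path: str | None = None
    synonym_map_path: str | None = None
    groups: tuple[str, str] | None = None  # default: the two groups in the file
    n_null_runs: int = 1000
    alpha: float = 0.05
    length_model: str = "resample_observed"
    n_permutations: int = 999
    seed: int = 0
    output_dir: str | None = None
    plot_format: str = "svg"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw and raw["groups"] is not None:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    def as_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "synonym_map_path": self.synonym_map_path,
            "groups": list(self.groups) if self.groups else None,
            "n_null_runs": self.n_null_runs,
            "alpha": self.alpha,
            "length_model": self.length_model,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "plot_format": self.plot_format,
        }


@dataclass
class AnalysisReport:
    """Everything a run produced, reproducible from config + inputs."""

    config: dict
    salience_tables: dict[str, SalienceTable]
    core_sizes: dict[str, int]
    core_union: list[str]
    dropped_rows: list[str]
    n_rows: int
    permanova: PermanovaResult
    dispersion: DispersionResult
    pcoa: PcoaResult
    version: str = field(default="")

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "core_sizes": self.core_sizes,
            "core_union": self.core_union,
            "cores": {
                g: t.core_items for g, t in self.salience_tables.items()
            } if self.salience_tables else {},
            "composition": {
                "n_rows": self.n_rows,
                "dropped_rows": self.dropped_rows,
            },
            "permanova": self.permanova.as_dict(),
            "dispersion": {
                "f_statistic": self.dispersion.f_statistic,
                "p_perm": self.dispersion.p_perm,
                "group_mean_dispersion": {
                    str(k): float(v) for k, v in self.dispersion.group_means.items()
                },
                "n_permutations": self.dispersion.n_permutations,
            },
            "pcoa": {
                "eigenvalues": [float(v) for v in self.pcoa.eigenvalues],
                "proportion_explained": [
                    float(v) for v in self.pcoa.proportion_explained
                ],
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True, ensure_ascii=False)

    def to_markdown(self) -> str:
        pr = self.permanova
        lines = [
            "# Structural-core comparison report",
            "",
            f"Core sizes: {self.core_sizes}",
            f"Core union ({len(self.core_union)} plants): {', '.join(self.core_union)}",
            f"Rows compared: {self.n_rows} (dropped all-zero: {len(self.dropped_rows)})",
            "",
            "## PERMANOVA",
            "",
            "| Source | df | SS | MS | pseudo-F | R2 | p |",
            "|---|---|---|---|---|---|---|",
            f"| between | {pr.df_between} | {pr.ss_between:.4f} | {pr.ms_between:.5f} "
            f"| {pr.pseudo_f:.3f} | {pr.r_squared:.5f} | {pr.p_perm:.3f} |",
            f"| residuals | {pr.df_within} | {pr.ss_within:.4f} | {pr.ms_within:.5f} "
            f"| | {1 - pr.r_squared:.5f} | |",
            f"| total | {pr.df_between + pr.df_within} | {pr.ss_total:.4f} | | | 1 | |",
            "",
            "## Dispersion homogeneity",
            "",
            f"F = {self.dispersion.f_statistic:.4f}, p = {self.dispersion.p_perm:.3f}",
            "",
        ]
        return "\n".join(lines)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    null_ss, perm_ss, disp_ss = ss.spawn(3)
    to_int = lambda s: int(s.generate_state(1)[0] % (2**31))
    return {
        "null_model": to_int(null_ss),
        "permanova": to_int(perm_ss),
        "betadisper": to_int(disp_ss),
    }


def _classify_group(
    dataset: FreeListDataset, cfg: AnalysisConfig, null_seed: int
) -> SalienceTable:
    summary = summarize(dataset)
    observed = compute_salience(dataset)
    null = null_salience_distribution(
        summary,
        NullModelConfig(
            n_runs=cfg.n_null_runs,
            alpha=cfg.alpha,
            seed=null_seed,
            length_model=cfg.length_model,
        ),
    )
    return classify_core(salience_pvalues(observed, null), alpha=cfg.alpha)


def run_comparison(
    config: AnalysisConfig,
    dataset: FreeListDataset | None = None,
) -> AnalysisReport:
    """Full two-group analysis; ``dataset`` may be passed in-memory instead
    of via ``config.input_path``."""
    if dataset is None:
        if config.input_path is None:
            raise ValueError("either a dataset or config.input_path is required")
        dataset = read_freelists(config.input_path)
    synonym_map = (
        read_synonym_map(config.synonym_map_path) if config.synonym_map_path else None
    )
    dataset = canonicalize_items(dataset, synonym_map)
    groups = list(config.groups) if config.groups else dataset.groups
    if len(groups) != 2:
        raise ValueError(f"two groups required, found {groups}")
    seeds = _stage_seeds(config.seed)

    tables: dict[str, SalienceTable] = {}
    for g in groups:
        sub = dataset.subset_group(g)
        log.info("group %s: %d informants, %d items", g, sub.n_informants, sub.n_items)
        tables[g] = _classify_group(sub, config, seeds["null_model"])
        log.info("group %s: core size %d", g, tables[g].core_size)

    core_union = sorted(set(tables[groups[0]].core_items) | set(tables[groups[1]].core_items))
    if not core_union:
        raise ValueError("empty structural core in both groups: nothing to compare")
    matrix = build_core_matrix(
        [dataset.subset_group(g) for g in groups], core_union
    )
    log.info(
        "composition matrix: %d rows x %d plants (%d dropped)",
        matrix.data.shape[0], matrix.data.shape[1], len(matrix.dropped_rows),
    )
    report = _compare(matrix, config, seeds)
    report.salience_tables = tables
    report.core_sizes = {g: tables[g].core_size for g in groups}
    report.core_union = core_union
    _write_outputs(report, matrix, config)
    return report


def run_matrix_comparison(
    matrix_path=None,
    labels_column: str = "group",
    config: AnalysisConfig | None = None,
    matrix: CompositionMatrix | None = None,
) -> AnalysisReport:
    """Comparison stages only, from a pre-built binary matrix CSV."""
    config = config or AnalysisConfig()
    if matrix is None:
        matrix = read_matrix_csv(matrix_path, group_column=labels_column)
    seeds = _stage_seeds(config.seed)
    report = _compare(matrix, config, seeds)
    _write_outputs(report, matrix, config)
    return report


def _compare(matrix: CompositionMatrix, config: AnalysisConfig, seeds) -> AnalysisReport:
    dist = jaccard_distances(matrix)
    perm = permanova(
        dist, matrix.groups, n_permutations=config.n_permutations, seed=seeds["permanova"]
    )
    disp = betadisper(
        dist, matrix.groups, n_permutations=config.n_permutations, seed=seeds["betadisper"]
    )
    ord_res = pcoa(dist)
    return AnalysisReport(
        config=config.as_dict(),
        salience_tables={},
        core_sizes={},
        core_union=list(matrix.data.columns),
        dropped_rows=matrix.dropped_rows,
        n_rows=matrix.data.shape[0],
        permanova=perm,
        dispersion=disp,
        pcoa=ord_res,
        version=__version__,
    )


def _write_outputs(report: AnalysisReport, matrix: CompositionMatrix, config: AnalysisConfig):
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
    (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
    matrix.to_csv(out / "composition_matrix.csv")
    for g, table in report.salience_tables.items():
        safe = str(g).replace("/", "_").replace(" ", "_")
        with open(out / f"salience_{safe}.tsv", "w", encoding="utf-8") as fh:
            table.to_tsv(fh)
    if report.pcoa.coordinates.shape[1] >= 1:
        plot_ordination(
            report.pcoa, matrix.groups, out / f"ordination.{config.plot_format}"
        )
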