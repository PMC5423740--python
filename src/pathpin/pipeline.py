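"""End-to-end orchestration: read -> preprocess -> activity/seed -> PIN ->
reduce -> greedy selection, with artifacts and stage-labelled errors."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import activity as activity_mod
from . import pin as pin_mod
from . import preprocess, selection
from .data_io import (
    ExpressionStudy,
    PathwayCollection,
    PPINetwork,
    read_expression_tsv,
    read_gmt,
    read_ppi_tsv,
    write_network_tsv,
    write_results_json,
)
from .synthetic import SyntheticConfig, generate_inputs, write_synthetic_inputs

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class AnalysisParams:
    """All analysis knobs, independent of where the inputs come from."""

    min_genes: int = 5
    ppi_confidence_threshold: float = 0.2
    deg_alpha: float = 0.05
    fdr: bool = False
    pcc_edge_threshold: float = 0.8
    top_fraction: float = 0.05
    weight_condition: str = "disease"
    criterion2_condition: str = "max"
    seed_statistic: str = "pooled_t"
    n_folds: int = 5
    n_repeats: int = 100
    base_seed: int = 0
    svm_c: float = 1.0
    min_improvement: float = 1e-6
    no_leakage: bool = False

    def cv_config(self) -> selection.CVConfig:
        return selection.CVConfig(
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            base_seed=self.base_seed,
            svm_c=self.svm_c,
            min_improvement=self.min_improvement,
        )


@dataclass
class PipelineConfig:
    expression_path: str
    gmt_path: str
    ppi_path: str
    out_dir: str
    labels_path: str | None = None
    label_row_name: str | None = None
    probe_map_path: str | None = None
    score_scale: str = "string1000"
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        if self.labels_path is None and self.label_row_name is None:
            raise ValueError("provide labels_path or label_row_name")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        param_fields = {f.name for f in dataclasses.fields(AnalysisParams)}
        raw_params = payload.pop("params", {})
        for key in list(payload):
            if key in param_fields:
                raw_params[key] = payload.pop(key)
        return cls(params=AnalysisParams(**raw_params), **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload

    def echo_dict(self) -> dict:
        """Analysis settings only — no filesystem paths, so two runs of the
        same analysis echo identical configuration."""
        return {
            "params": dataclasses.asdict(self.params),
            "score_scale": self.score_scale,
        }


@dataclass
class PipelineResult:
    """All intermediates of one run, for inspection or resuming."""

    inputs: preprocess.TargetedInputs
    degs: pd.DataFrame
    corr: pd.DataFrame
    activity: activity_mod.ActivityMatrix
    seed: activity_mod.SeedResult
    pin_full: "pin_mod.nx.Graph"
    pin_reduced: "pin_mod.nx.Graph"
    selection: selection.SelectionResult


def run_core(
    study: ExpressionStudy,
    pathways: PathwayCollection,
    ppi: PPINetwork,
    params: AnalysisParams | None = None,
    probe_to_gene: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    params = params or AnalysisParams()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-labelled with stage name
            raise StageError(name, exc) from exc

    inputs = stage(
        "preprocess",
        preprocess.prepare_inputs,
        study,
        pathways,
        ppi,
        min_genes=params.min_genes,
        ppi_confidence_threshold=params.ppi_confidence_threshold,
        probe_to_gene=probe_to_gene,
    )
    act = stage("activity", activity_mod.compute_activity_matrix, inputs)
    seed = stage(
        "seed",
        activity_mod.select_seed,
        act,
        inputs.study.labels,
        statistic=params.seed_statistic,
    )
    degs = stage(
        "differential_expression",
        pin_mod.differential_expression,
        inputs.study,
        alpha=params.deg_alpha,
        fdr=params.fdr,
    )
    corr = stage("pairwise_pcc", pin_mod.pairwise_pcc, inputs.study, inputs.targeted_ppi)
    pin_full = stage(
        "build_pin",
        pin_mod.build_pin,
        inputs,
        degs,
        corr,
        pcc_threshold=params.pcc_edge_threshold,
        weight_condition=params.weight_condition,
        criterion2_condition=params.criterion2_condition,
    )
    pin_reduced = stage(
        "reduce_pin", pin_mod.reduce_top_fraction, pin_full, params.top_fraction
    )
    refitter_factory = None
    if params.no_leakage:
        refitter_factory = lambda ids: activity_mod.make_fold_refitter(inputs, ids)
    result = stage(
        "greedy_select",
        selection.greedy_select,
        seed,
        pin_reduced,
        act,
        inputs.study.labels,
        params.cv_config(),
        refitter_factory,
    )
    logger.info(
        "pipeline: %d genes, %d pathways, %d DEGs, %d PIN edges, %d kept, "
        "%d selected pathways",
        len(inputs.study.matrix()),
        len(inputs.informative_pathways),
        int(degs["is_deg"].sum()),
        pin_full.number_of_edges(),
        pin_reduced.number_of_edges(),
        result.n_pathways,
    )
    return PipelineResult(
        inputs=inputs,
        degs=degs,
        corr=corr,
        activity=act,
        seed=seed,
        pin_full=pin_full,
        pin_reduced=pin_reduced,
        selection=result,
    )


def _write_artifacts(
    config: PipelineConfig, result: PipelineResult, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.degs.to_csv(out / "deg_table.tsv", sep="\t", index_label="gene")
    result.activity.scores.to_csv(
        out / "activity_matrix.tsv", sep="\t", index_label="pathway_id"
    )
    result.seed.per_pathway_statistics.to_csv(
        out / "seed_statistics.tsv", sep="\t"
    )
    result.corr.to_csv(out / "ppi_correlations.tsv", sep="\t")
    pathways = result.inputs.informative_pathways
    write_network_tsv(result.pin_full, pathways, out / "pin_full.tsv")
    write_network_tsv(result.pin_reduced, pathways, out / "pin_reduced.tsv")
    rows = []
    for order, pid in enumerate(result.selection.selected_ids):
        pathway = pathways.by_id[pid]
        rows.append(
            {
                "id": pid,
                "name": pathway.name,
                "n_genes": len(pathway),
                "order_added": order,
                "auc_after_adding": result.selection.auc_trace[order],
            }
        )
    pd.DataFrame(rows).to_csv(out / "selected_pathways.tsv", sep="\t", index=False)
    write_results_json(
        result.selection, out / "result.json", config=config.echo_dict()
    )


def run_pipeline(config: PipelineConfig) -> selection.SelectionResult:
    """File-based pipeline: read inputs, run the analysis, write artifacts."""
    try:
        study = read_expression_tsv(
            config.expression_path,
            label_row_name=config.label_row_name,
            labels_path=config.labels_path,
        )
        pathways = read_gmt(config.gmt_path)
        ppi = read_ppi_tsv(config.ppi_path, score_scale=config.score_scale)
        probe_map = None
        if config.probe_map_path:
            table = pd.read_csv(config.probe_map_path, sep="\t", dtype=str)
            probe_map = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("read_inputs", exc) from exc
    result = run_core(
        study, pathways, ppi, params=config.params, probe_to_gene=probe_map
    )
    _write_artifacts(config, result, Path(config.out_dir))
    return result.selection


def run_synth(config: SyntheticConfig, out_dir: str | Path) -> list[Path]:
    """Generate a synthetic study and write its five input/ground-truth files."""
    inputs = generate_inputs(config)
    return write_synthetic_inputs(inputs, out_dir)
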