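"""End-to-end orchestration: simulate (optional) -> preprocess ->
differential expression per dataset -> surfaceome filter -> evidence
matrix -> scoring -> report.

A run is configured by a single YAML file (or a PipelineConfig built in
code); outputs are written as TSV/JSON under the output directory and
summarized in a machine-readable RunReport.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from surfscore import diffexp, evidence, preprocess, surfaceome, synthetic
from surfscore.errors import StageError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # either a simulation block...
    simulation: synthetic.SimulationConfig | None = None
    # ...or explicit input paths
    expression: list[dict] = field(default_factory=list)  # {expr, meta, dataset_id}
    proteomics: str | None = None
    catalog: str | None = None
    # stage options
    normalize: bool = True
    stat: str = "ordinary"  # or "moderated"
    p_max: float = 0.05
    lfc_min: float = 1.5
    use_adjusted: bool = False
    min_score: int = 5
    require_prerequisite: bool = True
    outdir: str = "surfscore_out"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None and not self.expression:
            raise ValidationError(
                "config: provide either a simulation block or expression inputs"
            )
        if self.p_max <= 0 or self.lfc_min <= 0 or self.min_score <= 0:
            raise ValidationError("config: thresholds must be positive")
        if self.stat not in ("ordinary", "moderated"):
            raise ValidationError(f"stat: unknown statistic {self.stat!r}")
        if self.simulation is None and (self.proteomics is None or self.catalog is None):
            raise ValidationError(
                "config: real-input runs need proteomics and catalog paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        sim = data.pop("simulation", None)
        if sim is not None:
            sim = synthetic.SimulationConfig(**sim)
        return cls(simulation=sim, **data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage counts plus provenance for one pipeline run."""

    datasets: dict[str, dict]
    per_channel: dict[str, int]
    universe_size: int
    prerequisite_count: int
    candidate_count: int
    top_candidates: list[dict]
    venn_genomic: dict[str, int]
    config_hash: str
    seed: int | None
    started: float
    elapsed_seconds: float

    def __post_init__(self) -> None:
        for dataset_id, counts in self.datasets.items():
            if not (
                counts["surface_upregulated"] <= counts["upregulated"] <= counts["tested"]
            ):
                raise ValidationError(
                    f"report: inconsistent counts for dataset {dataset_id}"
                )
        if self.candidate_count > self.universe_size:
            raise ValidationError("report: candidates exceed universe")

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _load_proteomic_runs(path: str | Path) -> list[evidence.ProteomicRun]:
    frame = pd.read_csv(path, sep="\t")
    required = {"protein_id", "gene_symbol", "cell_line", "method"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    runs = []
    for (line, method), grp in frame.groupby(["cell_line", "method"], sort=False):
        proteins = frozenset(
            surfaceome.canonicalize(s) for s in grp["gene_symbol"].astype(str)
        )
        runs.append(
            evidence.ProteomicRun(cell_line=str(line), method=str(method), proteins=proteins)
        )
    return runs


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all outputs under config.outdir.

    Deterministic given the config (and its seed); any stage failure is
    re-raised as StageError naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    started = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: inputs (simulate or load) ---
    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = synthetic.SimulationConfig(**{**sim.to_dict(), "seed": config.seed})
            inputs_dir = outdir / "inputs"
            synthetic.write_all_inputs(sim, inputs_dir)
            catalog, truth = synthetic.generate_surfaceome_catalog(sim)
            matrices = [
                synthetic.simulate_expression_dataset(sim, d, truth)
                for d in range(sim.n_genomic_datasets)
            ]
            proteomic_runs = synthetic.simulate_all_proteomic_runs(sim, truth)
        else:
            catalog = surfaceome.read_catalog(config.catalog)
            matrices = [
                preprocess.read_expression_tsv(
                    spec["expr"], spec["meta"], spec.get("dataset_id", "")
                )
                for spec in config.expression
            ]
            proteomic_runs = _load_proteomic_runs(config.proteomics)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, str(exc)) from exc

    # --- stage: preprocess + differential expression + surface filter ---
    dataset_counts: dict[str, dict] = {}
    genomic_sets: list[tuple[str, set[str]]] = []
    for matrix in matrices:
        stage = f"diffexp:{matrix.dataset_id}"
        try:
            t0 = time.time()
            matrix = preprocess.collapse_duplicate_genes(matrix)
            if config.normalize:
                matrix = preprocess.quantile_normalize(matrix)
            if config.stat == "moderated":
                result = diffexp.moderated_t(matrix)
            else:
                result = diffexp.ordinary_t(matrix)
            result.q = diffexp.bh_adjust(result.p)
            result.write_tsv(outdir / f"de_{matrix.dataset_id}.tsv")
            upregulated = diffexp.select_upregulated(
                result,
                p_max=config.p_max,
                lfc_min=config.lfc_min,
                use_adjusted=config.use_adjusted,
            )
            surface_up = surfaceome.filter_surface(upregulated, catalog)
            genomic_sets.append((matrix.dataset_id, surface_up))
            dataset_counts[matrix.dataset_id] = {
                "tested": matrix.n_genes,
                "upregulated": len(upregulated),
                "surface_upregulated": len(surface_up),
            }
            logger.info(
                "dataset %s: %d tested, %d up, %d surface-up (%.2fs)",
                matrix.dataset_id,
                matrix.n_genes,
                len(upregulated),
                len(surface_up),
                time.time() - t0,
            )
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, str(exc)) from exc

    # --- stage: surface-filter proteomic lists, evidence, scoring ---
    stage = "evidence"
    try:
        filtered_runs = [
            evidence.ProteomicRun(
                cell_line=r.cell_line,
                method=r.method,
                proteins=frozenset(surfaceome.filter_surface(set(r.proteins), catalog)),
            )
            for r in proteomic_runs
        ]
        matrix_ev = evidence.build_evidence_matrix(genomic_sets, filtered_runs)
        all_scores = evidence.score_all(matrix_ev)
        candidates = evidence.score_candidates(
            matrix_ev,
            min_score=config.min_score,
            require_prerequisite=config.require_prerequisite,
        )
        evidence.write_candidates_tsv(candidates, outdir / "candidates.tsv")
        venn = evidence.venn_counts([s for _, s in genomic_sets]) if len(genomic_sets) >= 2 else {}
        evidence.write_venn_json(venn, outdir / "venn.json")
        channel_report = evidence.channel_presence_report(matrix_ev)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    report = RunReport(
        datasets=dataset_counts,
        per_channel=channel_report["per_channel"],
        universe_size=len(matrix_ev.proteins),
        prerequisite_count=sum(c.passes_prerequisite for c in all_scores),
        candidate_count=len(candidates),
        top_candidates=evidence.candidates_to_frame(candidates[:20]).to_dict("records"),
        venn_genomic=venn,
        config_hash=config.config_hash(),
        seed=config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
        started=started,
        elapsed_seconds=time.time() - started,
    )
    report.write_json(outdir / "report.json")
    return report
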