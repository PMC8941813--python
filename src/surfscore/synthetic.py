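"""Seeded synthetic inputs for end-to-end pipeline testing.

Generates, with full determinism per seed:

* a surfaceome catalog with ground-truth surface labels,
* tumor/normal log2-intensity expression datasets with planted
  upregulated genes (true surface targets plus non-surface decoys at the
  same effect size, so the surface filter has something to remove),
* proteomic presence lists per (cell line, method) with
  abundance-dependent logistic detection and non-surface contamination.

Baseline per-gene means are Normal(7, 1) in log2 units; the standardized
baseline mean doubles as the latent abundance driving proteomic
detection, coupling the two omics layers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from surfscore.errors import ValidationError
from surfscore.evidence import ProteomicRun
from surfscore.preprocess import ExpressionMatrix, write_expression_tsv
from surfscore.surfaceome import SurfaceomeCatalog

DEFAULT_CELL_LINES = ("CL1", "CL2", "CL3")
DEFAULT_METHODS = ("membrane_enrichment", "biotinylation")

# sub-stream tags so the catalog, each expression dataset, and each
# proteomic run draw from disjoint reproducible streams
_STREAM_CATALOG = 0
_STREAM_EXPRESSION = 1
_STREAM_PROTEOMIC = 2


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design."""

    n_genes: int = 1000
    surface_fraction: float = 0.2
    n_planted: int = 20
    effect_delta: float = 3.0
    sigma: float = 1.0
    n_tumor: int = 10
    n_normal: int = 10
    n_genomic_datasets: int = 3
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    methods: tuple[str, ...] = DEFAULT_METHODS
    detect_slope: float = 2.0
    detect_intercept: float = 1.0
    contamination_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_lines = tuple(self.cell_lines)
        self.methods = tuple(self.methods)
        for name in ("n_genes", "n_planted", "n_tumor", "n_normal", "n_genomic_datasets"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name}: must be >= 1")
        if not 0 < self.surface_fraction < 1:
            raise ValidationError("surface_fraction: must lie in (0, 1)")
        if self.n_planted > math.floor(self.n_genes * self.surface_fraction):
            raise ValidationError(
                "n_planted: cannot exceed floor(n_genes * surface_fraction)"
            )
        if not self.sigma > 0:
            raise ValidationError("sigma: must be > 0")
        if not 0 <= self.contamination_rate <= 1:
            raise ValidationError("contamination_rate: must lie in [0, 1]")
        if not self.cell_lines or not self.methods:
            raise ValidationError("cell_lines/methods: must be non-empty")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValidationError("cell_lines: labels must be unique")
        if len(set(self.methods)) != len(self.methods):
            raise ValidationError("methods: labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        d["methods"] = list(self.methods)
        return d


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    surface_genes: frozenset[str]
    planted_targets: frozenset[str]
    decoy_targets: frozenset[str]
    abundance: dict[str, float]
    baseline_mean: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.planted_targets <= self.surface_genes:
            raise ValidationError("planted_targets: must be a subset of surface_genes")
        if self.decoy_targets & self.surface_genes:
            raise ValidationError("decoy_targets: must be disjoint from surface_genes")
        if not all(math.isfinite(v) for v in self.abundance.values()):
            raise ValidationError("abundance: values must be finite")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "surface_genes": sorted(self.surface_genes),
            "planted_targets": sorted(self.planted_targets),
            "decoy_targets": sorted(self.decoy_targets),
            "abundance": {g: self.abundance[g] for g in sorted(self.abundance)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_surfaceome_catalog(
    config: SimulationConfig,
) -> tuple[SurfaceomeCatalog, GroundTruth]:
    """Catalog of round(n_genes * surface_fraction) surface entries plus
    the full ground truth (surface labels, planted targets, decoys,
    latent abundances). Deterministic per (config, seed)."""
    rng = np.random.default_rng([config.seed, _STREAM_CATALOG])
    genes = _gene_ids(config.n_genes)
    n_surface = round(config.n_genes * config.surface_fraction)
    perm = rng.permutation(config.n_genes)
    surface_idx = np.sort(perm[:n_surface])
    non_surface_idx = np.sort(perm[n_surface:])
    surface_genes = [genes[i] for i in surface_idx]

    planted = sorted(rng.choice(surface_genes, size=config.n_planted, replace=False))
    n_decoys = min(config.n_planted, len(non_surface_idx))
    decoy_pool = [genes[i] for i in non_surface_idx]
    decoys = sorted(rng.choice(decoy_pool, size=n_decoys, replace=False)) if n_decoys else []

    mu = rng.normal(loc=7.0, scale=1.0, size=config.n_genes)
    std = mu.std()
    abundance = (mu - mu.mean()) / (std if std > 0 else 1.0)

    width = max(5, len(str(config.n_genes)))
    entries = [(f"ACC{i + 1:0{width}d}", genes[i]) for i in surface_idx]
    catalog = SurfaceomeCatalog(entries)
    truth = GroundTruth(
        surface_genes=frozenset(surface_genes),
        planted_targets=frozenset(planted),
        decoy_targets=frozenset(decoys),
        abundance=dict(zip(genes, abundance.tolist())),
        baseline_mean=dict(zip(genes, mu.tolist())),
    )
    return catalog, truth


def simulate_expression_dataset(
    config: SimulationConfig,
    dataset_index: int,
    truth: GroundTruth | None = None,
) -> ExpressionMatrix:
    """One tumor-vs-normal log2-intensity dataset.

    value[g, s] ~ Normal(mu_g + delta * planted_g * tumor_s, sigma^2)
    where planted covers both true surface targets and non-surface
    decoys. The noise stream is keyed on ``seed + dataset_index`` so each
    dataset is reproducible in isolation.
    """
    if not 0 <= dataset_index < config.n_genomic_datasets:
        raise ValidationError(
            f"dataset_index: must lie in [0, {config.n_genomic_datasets})"
        )
    if config.n_tumor < 2 or config.n_normal < 2:
        raise ValidationError("n_tumor/n_normal: need >= 2 samples per group")
    if truth is None:
        _, truth = generate_surfaceome_catalog(config)
    genes = _gene_ids(config.n_genes)
    mu = np.array([truth.baseline_mean[g] for g in genes])
    shifted = np.array(
        [g in truth.planted_targets or g in truth.decoy_targets for g in genes]
    )
    rng = np.random.default_rng([config.seed + dataset_index, _STREAM_EXPRESSION])
    n_samples = config.n_tumor + config.n_normal
    noise = rng.normal(scale=config.sigma, size=(config.n_genes, n_samples))
    values = mu[:, None] + noise
    values[shifted, : config.n_tumor] += config.effect_delta
    dataset_id = f"DS{dataset_index + 1}"
    sample_ids = [f"{dataset_id}_T{i + 1}" for i in range(config.n_tumor)] + [
        f"{dataset_id}_N{i + 1}" for i in range(config.n_normal)
    ]
    groups = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    return ExpressionMatrix(
        values=values,
        gene_ids=genes,
        sample_ids=sample_ids,
        groups=groups,
        dataset_id=dataset_id,
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def simulate_proteomic_run(
    config: SimulationConfig,
    cell_line: str,
    method: str,
    truth: GroundTruth,
) -> ProteomicRun:
    """Presence list for one (cell line, method) channel.

    Surface proteins are detected with probability
    logistic(intercept + slope * abundance); non-surface proteins leak in
    with probability ``contamination_rate``.
    """
    if cell_line not in config.cell_lines:
        raise ValidationError(f"cell_line: unknown label {cell_line!r}")
    if method not in config.methods:
        raise ValidationError(f"method: unknown label {method!r}")
    line_idx = config.cell_lines.index(cell_line)
    method_idx = config.methods.index(method)
    rng = np.random.default_rng(
        [config.seed, _STREAM_PROTEOMIC, line_idx, method_idx]
    )
    genes = sorted(truth.abundance)
    abundance = np.array([truth.abundance[g] for g in genes])
    is_surface = np.array([g in truth.surface_genes for g in genes])
    p_detect = _logistic(config.detect_intercept + config.detect_slope * abundance)
    draws = rng.random(len(genes))
    detected = np.where(
        is_surface, draws < p_detect, draws < config.contamination_rate
    )
    proteins = frozenset(g for g, d in zip(genes, detected) if d)
    return ProteomicRun(cell_line=cell_line, method=method, proteins=proteins)


def simulate_all_proteomic_runs(
    config: SimulationConfig, truth: GroundTruth
) -> list[ProteomicRun]:
    """All cell_line x method channels in the configured order."""
    return [
        simulate_proteomic_run(config, line, method, truth)
        for line in config.cell_lines
        for method in config.methods
    ]


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_catalog_tsv(catalog: SurfaceomeCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tgene_symbol\n")
        for accession, symbol in catalog.entries:
            fh.write(f"{accession}\t{symbol}\n")


def write_proteomic_tsv(
    runs: list[ProteomicRun], catalog: SurfaceomeCatalog, path: str | Path
) -> None:
    rows = []
    for run in runs:
        for protein in sorted(run.proteins):
            accession = catalog.symbol_to_accession.get(protein, protein)
            rows.append((accession, protein, run.cell_line, run.method))
    frame = pd.DataFrame(rows, columns=["protein_id", "gene_symbol", "cell_line", "method"])
    frame.to_csv(path, sep="\t", index=False)


def write_all_inputs(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input and write the standard TSV/JSON
    dialects consumed by the pipeline. Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, truth = generate_surfaceome_catalog(config)
    paths: dict[str, Path] = {}

    paths["catalog"] = outdir / "catalog.tsv"
    write_catalog_tsv(catalog, paths["catalog"])
    paths["ground_truth"] = outdir / "ground_truth.json"
    truth.write_json(paths["ground_truth"])

    for d in range(config.n_genomic_datasets):
        matrix = simulate_expression_dataset(config, d, truth)
        expr = outdir / f"expression_{matrix.dataset_id}.tsv"
        meta = outdir / f"metadata_{matrix.dataset_id}.tsv"
        write_expression_tsv(matrix, expr, meta)
        paths[f"expression_{matrix.dataset_id}"] = expr
        paths[f"metadata_{matrix.dataset_id}"] = meta

    runs = simulate_all_proteomic_runs(config, truth)
    paths["proteomics"] = outdir / "proteomics.tsv"
    write_proteomic_tsv(runs, catalog, paths["proteomics"])
    return paths
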