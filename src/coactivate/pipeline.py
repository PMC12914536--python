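"""Reproducible pipeline runs: ingest -> normalize -> annotate -> subset
-> score -> correlate/stratify, with a manifest of provenance.

A :class:`RunConfig` fully describes a run; :func:`run_pipeline` executes
the requested analyses fail-fast, writes result records (JSON/TSV) into
the output directory together with the verbatim config, and returns a
:class:`RunManifest` with per-stage logs and output checksums.  Presets
package the figure-level analyses of the co-activation study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import annotate_cells, call_angiogenic, select_endothelial
from .coactivation import (
    contrast_across_strata,
    high_low_gene_contrast,
    spearman_coactivation,
    stratify_by_score,
)
from .datamodel import ExpressionMatrix, ValidationError
from .io import (
    default_marker_panel,
    default_signature,
    read_marker_panel,
    read_matrix,
    read_signatures,
)
from .preprocess import normalize
from .scoring import ks_enrichment, score_signature, summarize_by_group

ANALYSES = ("coactivation", "stratification", "high_low", "group_summary", "enrichment")


class PipelineError(ValidationError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str | None = None  # None => simulate from synthetic_config
    input_format: str = "mtx_dir"
    species: str = "mouse"
    synthetic_config: dict | None = None
    signature_file: str | None = None  # None => packaged defaults
    signature_x: str = "cGAS-STING"
    signature_y: str = "Angiogenesis"
    marker_panel_file: str | None = None  # None => packaged retinal panel
    subset_label: str | None = "EC"  # None => all cells
    analyses: tuple[str, ...] = ("coactivation",)
    group_by: str = "stage"  # cell_meta column for group_summary/enrichment
    high_low_stratifier: str = "Sting1"  # gene symbol or signature name
    high_low_targets: tuple[str, ...] = ("Kdr", "Flt1")
    p_method: str = "auto"
    n_permutations: int = 10_000
    seed: int = 0
    out_dir: str = "run_out"
    note: str = ""

    def validate(self, require_input: bool = True) -> None:
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValidationError(f"unknown analysis {a!r}; choose from {ANALYSES}")
        if require_input and self.input_path is None and self.synthetic_config is None:
            raise ValidationError("either input_path or synthetic_config is required")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValidationError(f"input path does not exist: {self.input_path}")
        if self.signature_file is not None and not Path(self.signature_file).exists():
            raise ValidationError(f"signature file not found: {self.signature_file}")
        if (
            self.marker_panel_file is not None
            and not Path(self.marker_panel_file).exists()
        ):
            raise ValidationError(f"marker panel not found: {self.marker_panel_file}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        for key in ("analyses", "high_low_targets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    """Provenance record of one run."""

    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_signatures(cfg: RunConfig):
    if cfg.signature_file is None:
        sig_x = default_signature(cfg.signature_x, species=cfg.species)
        sig_y = default_signature(cfg.signature_y, species=cfg.species)
    else:
        sigs = {s.name: s for s in read_signatures(cfg.signature_file, cfg.species)}
        for name in (cfg.signature_x, cfg.signature_y):
            if name not in sigs:
                raise ValidationError(f"signature {name!r} not in {cfg.signature_file}")
        sig_x, sig_y = sigs[cfg.signature_x], sigs[cfg.signature_y]
    return sig_x, sig_y


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute a configured run; fail-fast, all outputs carry provenance."""
    t0 = time.time()
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    manifest = RunManifest(config=dataclasses.asdict(cfg), version=__version__)

    def log(stage: str, **info) -> None:
        manifest.stages.append({"stage": stage, **info})

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # fail-fast with stage context
            raise PipelineError(stage, exc) from exc

    # ingest
    def ingest():
        if cfg.input_path is not None:
            return read_matrix(cfg.input_path, cfg.input_format, species=cfg.species)
        from .synthetic import SyntheticConfig, simulate_dataset

        scfg = SyntheticConfig(**{**cfg.synthetic_config, "seed": cfg.seed})
        matrix, _ = simulate_dataset(scfg)
        return matrix

    matrix = run_stage("ingest", ingest)
    log("ingest", n_cells=matrix.n_cells, n_genes=matrix.n_genes)

    matrix = run_stage("normalize", lambda: normalize(matrix))
    log("normalize", target_sum=matrix.norm_config.target_sum)

    sig_x, sig_y = run_stage("signatures", lambda: _load_signatures(cfg))

    panel = (
        default_marker_panel()
        if cfg.marker_panel_file is None
        else read_marker_panel(cfg.marker_panel_file)
    )
    annotation = run_stage("annotate", lambda: annotate_cells(matrix, panel))
    log("annotate", **{k: int(v) for k, v in annotation.counts().items()})

    full = matrix
    if cfg.subset_label is not None:
        matrix = run_stage(
            "subset", lambda: select_endothelial(full, annotation, cfg.subset_label)
        )
    log("subset", label=cfg.subset_label, n_cells=matrix.n_cells)

    sx = run_stage("score", lambda: score_signature(matrix, sig_x))
    sy = run_stage("score", lambda: score_signature(matrix, sig_y))
    scores = pd.concat([sx.to_frame(), sy.to_frame()])
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    log("score", coverage_x=sx.coverage, coverage_y=sy.coverage)

    results: dict = {}
    if "coactivation" in cfg.analyses:
        def coact():
            r = spearman_coactivation(
                sx, sy, p_method=cfg.p_method, seed=cfg.seed,
                n_permutations=cfg.n_permutations,
                subset=cfg.subset_label or "all",
            )
            return r.to_dict()

        results["coactivation"] = run_stage("coactivation", coact)

    if "stratification" in cfg.analyses:
        def strat():
            s = stratify_by_score(sx, k=3)
            c = contrast_across_strata(s, sy)
            s.group_labels.to_frame().to_csv(out / "strata.tsv", sep="\t")
            return {
                "stratifier": s.stratifier,
                "boundaries": list(s.boundaries),
                "contrasts": c.table.to_dict(orient="records"),
                "trend_statistic": c.trend_statistic,
                "trend_null_mean": c.trend_null_mean,
                "trend_p": c.trend_p,
            }

        results["stratification"] = run_stage("stratification", strat)

    if "high_low" in cfg.analyses:
        def high_low():
            strat = cfg.high_low_stratifier
            if strat in (sig_x.name, sig_y.name):
                strat = sig_x if strat == sig_x.name else sig_y
            return [
                dataclasses.asdict(
                    high_low_gene_contrast(matrix, strat, target, mode="halves")
                )
                for target in cfg.high_low_targets
            ]

        results["high_low"] = run_stage("high_low", high_low)

    if "group_summary" in cfg.analyses:
        def summary():
            if cfg.group_by not in matrix.cell_meta.columns:
                raise ValidationError(f"no {cfg.group_by!r} column in cell metadata")
            groups = matrix.cell_meta[cfg.group_by].to_numpy()
            table = summarize_by_group(sx, groups)
            table["signature"] = sx.signature_name
            table_y = summarize_by_group(sy, groups)
            table_y["signature"] = sy.signature_name
            both = pd.concat([table, table_y])
            both.to_csv(out / "group_summary.tsv", sep="\t", index=False)
            return both.to_dict(orient="records")

        results["group_summary"] = run_stage("group_summary", summary)

    if "enrichment" in cfg.analyses:
        def enrich():
            # score distribution of the subset vs the remaining cells
            sx_full = score_signature(full, sig_x)
            in_subset = full.cell_ids.isin(matrix.cell_ids)
            r = ks_enrichment(sx_full.values[in_subset], sx_full.values[~in_subset])
            return {
                "signature": sig_x.name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
            }

        results["enrichment"] = run_stage("enrichment", enrich)

    (out / "results.json").write_text(
        json.dumps(results, indent=2, default=float)
    )
    for f in sorted(out.iterdir()):
        if f.is_file():
            manifest.checksums[f.name] = _sha256(f)
    manifest.wall_time_s = time.time() - t0
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESETS = {
    "fvm_coactivation": dict(
        note="Pathological co-activation in fibrovascular-membrane ECs; also "
        "the bulk mode (sample-level scores) with subset_label=None.",
        analyses=("coactivation", "enrichment"),
        subset_label="EC",
        p_method="auto",
    ),
    "developmental_stages": dict(
        note="Stage-wise co-activation and score summaries across postnatal "
        "development (per-stage Spearman, cell counts normalized to the "
        "largest stage).",
        analyses=("coactivation", "group_summary"),
        subset_label="EC",
        group_by="stage",
    ),
    "cross_species": dict(
        note="Conserved EC co-activation in adult retinas; set species to "
        "human/pig/macaque so signature symbols are harmonized per species.",
        analyses=("coactivation",),
        subset_label="EC",
        species="human",
    ),
    "stratification_p6": dict(
        note="Stratify ECs into low/mid/high tertiles of cGAS-STING activity "
        "and contrast angiogenesis scores across strata; includes the "
        "Sting1-high vs -low Kdr/Flt1 contrasts.",
        analyses=("stratification", "high_low"),
        subset_label="EC",
        high_low_stratifier="Sting1",
        high_low_targets=("Kdr", "Flt1"),
    ),
}


def preset(name: str) -> RunConfig:
    """A filled RunConfig template for one of the study-level analyses."""
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    return RunConfig(**_PRESETS[name])


def available_presets() -> list[str]:
    return sorted(_PRESETS)
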