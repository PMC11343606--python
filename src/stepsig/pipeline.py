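"""End-to-end orchestration: derive a signature, threshold, score, classify.

Stages run in order: data (load or simulate) -> TPM/log -> differential
expression (skipped when a signature is supplied) -> step thresholds ->
normalization -> composite scoring -> classification -> optional survival.
Every run writes a manifest (config hash, seed, package versions) that is
sufficient to regenerate the outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, diffexpr, io, signature, stepminer
from .errors import ConfigurationError, PipelineError, StepSigError, ZeroEventsError
from .synthetic import CASE_ARM, SyntheticConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds, and the synthetic block for one pipeline run."""

    out_dir: str = "stepsig_out"
    matrix: str | None = None  # log2(TPM+1) matrix, or counts (see `counts`)
    counts: bool = False
    gene_lengths: str | None = None
    metadata: str | None = None
    signature_file: str | None = None
    gene_sets: str | None = None
    group_column: str = "group"
    test_group: str = CASE_ARM
    p_cut: float = 0.05
    fc_cut: float = 2.0
    dof: int = stepminer.DEFAULT_DOF
    use_adjusted: bool = False
    run_survival: bool = False
    seed: int = 0
    synthetic: SyntheticConfig | None = None

    def validate(self) -> "PipelineConfig":
        if self.synthetic is None and self.matrix is None:
            raise ConfigurationError("either 'matrix' or a 'synthetic' block is required")
        if self.synthetic is not None and self.matrix is not None:
            raise ConfigurationError("'matrix' and 'synthetic' are mutually exclusive")
        if self.counts and self.gene_lengths is None:
            raise ConfigurationError("'gene_lengths' is required when matrix holds counts")
        if not 0 < self.p_cut <= 1:
            raise ConfigurationError(f"p_cut must be in (0, 1], got {self.p_cut}")
        if self.fc_cut < 1:
            raise ConfigurationError(f"fc_cut must be >= 1, got {self.fc_cut}")
        if self.dof < 2:
            raise ConfigurationError(f"dof must be >= 2, got {self.dof}")
        for attr in ("matrix", "gene_lengths", "metadata", "signature_file", "gene_sets"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} path does not exist: {p}")
        if self.synthetic is not None:
            self.synthetic.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        if syn is not None:
            if "gene_length_range" in syn:
                syn["gene_length_range"] = tuple(syn["gene_length_range"])
            try:
                cfg.synthetic = SyntheticConfig(**syn)
            except TypeError as exc:
                raise ConfigurationError(f"synthetic block: {exc}") from exc
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
            d["synthetic"]["gene_length_range"] = list(
                d["synthetic"]["gene_length_range"]
            )
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    signature: list[str]
    scores: pd.DataFrame
    auc: float | None
    manifest: dict
    deg: pd.DataFrame | None = None
    survival: dict | None = field(default=None)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StepSigError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write all outputs plus a manifest."""
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "stepsig",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.to_dict(),
        "stages": [],
        "outputs": {},
        "complete": False,
    }

    def record(stage: str, fname: str | None = None):
        manifest["stages"].append(stage)
        if fname:
            manifest["outputs"][stage] = manifest["outputs"].get(stage, []) + [fname]

    try:
        # --- data -----------------------------------------------------
        if cfg.synthetic is not None:
            syn = cfg.synthetic
            if syn.seed != cfg.seed:
                syn = SyntheticConfig(**{**asdict(syn), "seed": cfg.seed})
            coh = simulate_cohort(syn)
            io.write_matrix(coh.counts, out / "counts.tsv")
            coh.gene_lengths.to_frame().to_csv(out / "gene_lengths.tsv", sep="\t")
            coh.metadata.to_csv(out / "metadata.tsv", sep="\t")
            io.write_signature(coh.truth.signature_genes, out / "truth_signature.txt")
            counts, lengths, metadata = coh.counts, coh.gene_lengths, coh.metadata
            logexpr = diffexpr.log_transform(diffexpr.tpm(counts, lengths))
            record("simulate", "counts.tsv")
        else:
            mat = io.read_expression_matrix(cfg.matrix, counts=cfg.counts)
            metadata = io.read_metadata(cfg.metadata) if cfg.metadata else None
            if cfg.counts:
                lengths = io.read_gene_lengths(cfg.gene_lengths)
                logexpr = diffexpr.log_transform(diffexpr.tpm(mat, lengths))
            else:
                logexpr = mat
            record("load")

        groups = None
        if metadata is not None and cfg.group_column in metadata.columns:
            groups = metadata.loc[logexpr.columns, cfg.group_column]

        # --- signature derivation ------------------------------------
        deg = None
        if cfg.signature_file is not None:
            sig = io.read_signature(cfg.signature_file)
            record("signature_supplied")
        else:
            if groups is None:
                raise ConfigurationError(
                    "deriving a signature needs metadata with a group column"
                )
            deg = _stage("deg")(diffexpr.differential_expression)(
                logexpr,
                groups,
                cfg.test_group,
                p_cut=cfg.p_cut,
                fc_cut=cfg.fc_cut,
                use_adjusted=cfg.use_adjusted,
            )
            header = (
                f"# p_cut={cfg.p_cut} fc_cut={cfg.fc_cut} "
                f"use_adjusted={cfg.use_adjusted} test_group={cfg.test_group}\n"
            )
            with open(out / "deg.tsv", "w") as fh:
                fh.write(header)
                deg.to_csv(fh, sep="\t", index_label="gene_id")
            sig = diffexpr.up_signature(deg)
            io.write_signature(sig, out / "signature.txt")
            record("deg", "deg.tsv")
            if not sig:
                raise PipelineError(
                    "deg", StepSigError("no gene passed the selection filters")
                )

        # --- thresholds, normalization, scoring ----------------------
        fits = _stage("threshold")(stepminer.fit_matrix)(logexpr, dof=cfg.dof)
        fits.to_csv(out / "step_fits.tsv", sep="\t")
        record("threshold", "step_fits.tsv")

        norm = _stage("normalize")(signature.normalize_expression)(logexpr, fits)
        score_table = _stage("score")(signature.composite_score)(norm, sig)
        scores = score_table.table.copy()
        if groups is not None:
            scores["group"] = groups
        scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")
        record("score", "scores.tsv")

        # --- classification ------------------------------------------
        auc = None
        report: dict = {"signature_size": len(score_table.signature)}
        if groups is not None and groups.nunique() == 2:
            auc = signature.roc_auc(
                score_table.scores, groups, positive=cfg.test_group
            )
            comp = signature.group_compare(score_table.scores, groups)
            report["auc"] = auc
            report["positive_class"] = cfg.test_group
            report["welch"] = comp.to_dict(orient="records")
            record("classify")

        # --- survival -------------------------------------------------
        surv_report = None
        if (
            cfg.run_survival
            and metadata is not None
            and {"time", "event"} <= set(metadata.columns)
        ):
            strata = cohort.stratify_by_metagene(logexpr, sig)
            table = pd.DataFrame(
                {
                    "time": metadata.loc[strata.stratum.index, "time"],
                    "event": metadata.loc[strata.stratum.index, "event"].astype(bool),
                    "stratum": strata.stratum,
                }
            )
            try:
                km = _stage("survival")(cohort.km_logrank)(table)
                surv_report = {"logrank_statistic": km.statistic, "p": km.p}
                for name, curve in km.curves.items():
                    fname = f"km_{name}.tsv"
                    curve.to_csv(out / fname, sep="\t", index=False)
                    record("survival", fname)
            except ZeroEventsError as exc:
                surv_report = {"error": str(exc)}
                record("survival")
            report["survival"] = surv_report

        manifest["complete"] = True
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2, default=float))
        record("report", "report.json")
        return PipelineResult(
            out_dir=out,
            signature=list(sig),
            scores=scores,
            auc=auc,
            manifest=manifest,
            deg=deg,
            survival=surv_report,
        )
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
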