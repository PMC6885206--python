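"""TSV/YAML readers and writers, pipeline configuration, run manifests.

TSV is the interchange format throughout: expression as genes x samples
with the gene id in the first column and sample ids in the header
(GCT accepted read-only by skipping its two preamble lines), survival as
``sample  time  event  covariates...``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, SurvivalTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "write_cohort",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_expression(path, na_policy="error", batch=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (or GCT) into an :class:`ExpressionMatrix`.

    ``na_policy`` is ``"error"`` (any missing cell aborts) or
    ``"drop_gene"`` (rows with missing cells are removed; count logged).
    """
    path = Path(path)
    skiprows = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#1.2"):
            skiprows = 2  # GCT preamble: version line + dimensions line
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows)
    if skiprows and "Description" in df.columns:
        df = df.drop(columns=["Description"])
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        lines = [i + 2 + skiprows for i, g in enumerate(df.index) if g in set(dup)]
        raise ValueError(f"duplicate gene ids {dup} (lines {lines})")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if df.isna().any().any():
        if na_policy == "drop_gene":
            bad = df.index[df.isna().any(axis=1)]
            logger.info("dropped %d genes with missing values", len(bad))
            df = df.drop(index=bad)
        else:
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in genes {bad[:5]} (na_policy=error)")
    return ExpressionMatrix(df, batch=batch, metadata={"path": str(path)})


def write_expression(expr, path) -> None:
    frame = expr.values if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    frame.to_csv(path, sep="\t", index_label="gene")


def read_survival(path, time_unit=None) -> SurvivalTable:
    """Read ``sample  time  event  covariates...`` TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {"path": str(path)}
    if time_unit:
        meta["time_unit"] = time_unit
    return SurvivalTable(df, metadata=meta)


def write_survival(surv, path) -> None:
    df = surv.data if isinstance(surv, SurvivalTable) else pd.DataFrame(surv)
    df.to_csv(path, sep="\t", index_label="sample")


def write_cohort(cohort, out_dir) -> dict:
    """Write a synthetic cohort (expression/survival/truth TSVs); returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "survival": out / "survival.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    write_expression(cohort.expression, paths["expression"])
    write_survival(cohort.survival, paths["survival"])
    truth = pd.DataFrame({"true_label": cohort.true_labels})
    truth.to_csv(paths["truth"], sep="\t", index_label="sample")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cohort.true_params["config"], fh)
    return {k: str(v) for k, v in paths.items()}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full discovery-and-transfer run."""

    train_expression: str = ""
    train_survival: str = ""
    valid_expression: str = ""
    valid_survival: str = ""
    probe_map: str = ""
    out_dir: str = "run"
    q_threshold: float = 0.05
    min_cluster: int = 3
    ties: str = "efron"
    combat_mode: str = "joint"  # joint | reference | none
    borderline_band: tuple = (0.4, 0.6)
    covariates: list = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        cfg.borderline_band = tuple(cfg.borderline_band)
        return cfg

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["borderline_band"] = list(self.borderline_band)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    def digest(self) -> str:
        payload = asdict(self)
        payload["borderline_band"] = list(self.borderline_band)
        payload.pop("out_dir")  # where results land is not part of the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute collapse -> screen -> fit -> [combat ->] transfer -> report.

    Writes every artifact plus a manifest (config hash, package version,
    sha256 of each numeric output) into ``config.out_dir`` and returns
    that directory.  Any stage failure aborts with the stage name; the
    artifacts written so far are left in place for debugging.
    """
    from . import __version__
    from .combat import combat_adjust
    from .screen import GeneScreen, collapse_probes
    from .signature import ClusterSignature, apply_signature
    from .survival import fit_cox, km_estimate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    manifest = {"config_sha256": config.digest(), "version": __version__,
                "outputs": {}, "stages": []}

    def _save(name, writer, *args):
        path = out / name
        writer(*args, path)
        manifest["outputs"][name] = _sha256(path)
        return path

    try:
        train_expr = read_expression(config.train_expression)
        train_surv = read_survival(config.train_survival)
        if config.probe_map:
            pm = pd.read_csv(config.probe_map, sep="\t")
            stage = "collapse_probes"
            train_expr = collapse_probes(train_expr, pm)
        manifest["stages"].append("load")

        stage = "screen"
        screen = GeneScreen(q_threshold=config.q_threshold,
                            min_cluster=config.min_cluster,
                            ties=config.ties).fit(train_expr, train_surv)
        _save("screen_report.tsv",
              lambda df, p: df.to_csv(p, sep="\t"), screen.results_)
        (out / "selected_genes.txt").write_text(
            "\n".join(screen.selected_genes_) + "\n")
        manifest["outputs"]["selected_genes.txt"] = _sha256(out / "selected_genes.txt")
        manifest["stages"].append("screen")
        if len(screen.selected_genes_) < 2:
            manifest["status"] = "no genes selected"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            logger.warning("no genes selected at q < %s; stopping cleanly",
                           config.q_threshold)
            return out

        stage = "fit_signature"
        sig = ClusterSignature(borderline_band=config.borderline_band,
                               ties=config.ties).fit(
            train_expr.subset_genes(screen.selected_genes_), train_surv)
        sig.save_json(out / "signature.json")
        manifest["outputs"]["signature.json"] = _sha256(out / "signature.json")
        train_assign = apply_signature(sig, train_expr)
        _save("train_assignments.tsv",
              lambda df, p: df.to_csv(p, sep="\t"), train_assign)
        manifest["stages"].append("fit_signature")

        if config.valid_expression:
            stage = "batch_adjust"
            valid_expr = read_expression(config.valid_expression)
            if config.combat_mode != "none":
                # adjust over the full shared gene set (EB priors are
                # moment-matched across genes), then restrict to the signature
                shared = train_expr.values.index.intersection(
                    valid_expr.values.index)
                missing = sorted(set(sig.genes_) - set(shared))
                if missing:
                    raise KeyError(f"signature genes missing in validation: {missing}")
                joint = pd.concat(
                    [train_expr.values.loc[shared],
                     valid_expr.values.loc[shared]], axis=1)
                batch = ["train"] * train_expr.n_samples + \
                        ["validation"] * valid_expr.n_samples
                ref = "train" if config.combat_mode == "reference" else None
                adjusted, _ = combat_adjust(joint, batch, reference_batch=ref)
                valid_for_pred = adjusted.loc[sig.genes_, valid_expr.sample_ids]
            else:
                valid_for_pred = valid_expr.values.loc[sig.genes_]
            manifest["stages"].append("batch_adjust")

            stage = "apply_signature"
            valid_assign = apply_signature(sig, valid_for_pred)
            _save("valid_assignments.tsv",
                  lambda df, p: df.to_csv(p, sep="\t"), valid_assign)
            if config.valid_survival:
                valid_surv = read_survival(config.valid_survival)
                shared = [s for s in valid_assign.index
                          if s in set(valid_surv.sample_ids)]
                labels = valid_assign.loc[shared, "adverse"].to_numpy(float)
                vs = valid_surv.subset(shared)
                cox = fit_cox(vs, labels[:, None], ties=config.ties)
                _save("valid_cox.tsv",
                      lambda df, p: df.to_csv(p, sep="\t"), cox.summary())
                km = km_estimate(vs, labels.astype(int))
                for g, tab in km.items():
                    _save(f"valid_km_group{int(g)}.tsv",
                          lambda df, p: df.to_csv(p, sep="\t", index=False), tab)
            manifest["stages"].append("apply_signature")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
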