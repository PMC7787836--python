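"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular formats are plain TSV with a header row.  Expression matrices are
genes x samples with the gene symbol in the first column; duplicate gene rows
(several probes mapping to one gene) are collapsed to their median value.
Gene symbols match case-sensitively after whitespace stripping.  Sample
alignment between the expression matrix and the label/platform tables is by
ID intersection, and any dropped IDs are reported explicitly — silent
reindexing is forbidden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import evaluate_all, fit_baseline
from .model import GenePairClassifier

logger = logging.getLogger("pairdx")

__all__ = [
    "read_expression",
    "read_roster",
    "read_labels",
    "read_platforms",
    "align_samples",
    "write_report",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

_LABEL_MAP = {"0": 0, "1": 1, "benign": 0, "malignant": 1}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def read_expression(path) -> pd.DataFrame:
    """Parse a genes x samples expression TSV.

    Duplicate gene rows are collapsed to the per-sample median.  Non-numeric
    cells raise with row/column context.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"empty or malformed expression file: {path}") from e
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"expression file has no data: {path}")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        vals = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric expression value {df[col][bad].iloc[0]!r} "
                    f"at gene {gene!r}, sample {col!r} in {path}"
                ) from None
        raise
    if vals.isna().any().any():
        raise ValueError(f"missing expression values in {path}")
    if vals.index.has_duplicates:
        n_dup = int(vals.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows to median in %s", n_dup, path)
        vals = vals.groupby(level=0, sort=False).median()
    return vals


def read_roster(path) -> list[str]:
    """One gene symbol per line; duplicates are an error."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not genes:
        raise ValueError(f"empty gene roster: {path}")
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate symbols in roster {path}: {dupes[:5]}")
    return genes


def _read_two_column(path, value_name: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, {value_name})")
    s = pd.Series(
        df.iloc[:, 1].astype(str).str.strip().values,
        index=df.iloc[:, 0].astype(str).str.strip(),
        name=value_name,
    )
    if s.index.has_duplicates:
        dupes = s.index[s.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dupes[:5]}")
    return s


def read_labels(path) -> pd.Series:
    """Sample -> 0/1 labels; accepts 0/1 or benign/malignant (case-insensitive)."""
    s = _read_two_column(path, "label")
    lowered = s.str.lower()
    bad = ~lowered.isin(_LABEL_MAP)
    if bad.any():
        raise ValueError(
            f"{path}: labels must be 0/1 or benign/malignant, got {sorted(s[bad].unique())[:5]}"
        )
    return lowered.map(_LABEL_MAP).astype(int)


def read_platforms(path) -> pd.Series:
    return _read_two_column(path, "platform")


def align_samples(expr: pd.DataFrame, table: pd.Series) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Intersect expression samples with a per-sample table, reporting drops."""
    common = [s for s in expr.columns if s in table.index]
    dropped = sorted(set(expr.columns).symmetric_difference(table.index))
    if not common:
        raise ValueError("no overlapping sample IDs between expression and annotation")
    if dropped:
        logger.warning("dropping %d unmatched sample IDs: %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    return expr[common], table.loc[common], dropped


def write_report(report, path) -> Path:
    """Write a diagnostic report (or dict of them) as a Table 3-style TSV."""
    path = Path(path)
    if hasattr(report, "summary"):
        report = {"model": report}
    frames = []
    for name, rep in report.items():
        df = rep.summary().reset_index()
        df.insert(0, "model", name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


@dataclass
class RunConfig:
    """Everything needed to re-execute an end-to-end run bit-identically."""

    expression: str
    labels: str
    out_dir: str
    roster: str | None = None
    platforms: str | None = None
    test_expression: str | None = None
    test_labels: str | None = None
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    signed_r: bool = False
    hidden_dims: tuple[int, ...] = (20, 20, 20)
    corruption: float = 0.5
    sparsity_target: float = 0.1
    sparsity_weight: float = 0.1
    epochs_pretrain: int = 100
    epochs_finetune: int = 200
    learning_rate: float = 0.1
    batch_size: int = 32
    val_fraction: float = 0.20
    patience: int = 10
    baselines: tuple[str, ...] = ()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.hidden_dims = tuple(cfg.hidden_dims)
        cfg.baselines = tuple(cfg.baselines)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        d["baselines"] = list(self.baselines)
        return d


def _versions() -> dict[str, str]:
    import sklearn

    from . import __version__

    return {
        "pairdx": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(config: RunConfig) -> Path:
    """featurize -> select -> pretrain -> finetune -> evaluate, into a run directory.

    Writes retained pairs, the serialized model, per-epoch training logs, a
    report TSV, and a manifest (config + seed + versions) sufficient to
    reproduce the run bit-identically.  Stage failures abort with the stage
    name; the manifest records which stages completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    stages_done: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                r = fn()
            except Exception as e:
                _write_manifest(out, config, stages_done, failed=name)
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            stages_done.append(name)
            logger.info("stage %s complete", name)
            return r

        return deco

    try:
        @stage("read")
        def _read():
            expr = read_expression(config.expression)
            roster = read_roster(config.roster) if config.roster else list(expr.index)
            return expr, roster

        expr, roster = _read

        @stage("select")
        def _select():
            labels = read_labels(config.labels)
            expr_a, labels_a, _ = align_samples(expr, labels)
            model = GenePairClassifier.from_expression(
                expr_a,
                labels_a.to_numpy(),
                roster=roster,
                r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
                signed_r=config.signed_r,
                hidden_dims=config.hidden_dims,
                corruption=config.corruption,
                sparsity_target=config.sparsity_target,
                sparsity_weight=config.sparsity_weight,
            )
            model.retained_pairs.assign(
                r=[model.filter_result.r[k] for k in model.filter_result.retained],
                p=[model.filter_result.p[k] for k in model.filter_result.retained],
            ).to_csv(out / "retained_pairs.tsv", sep="\t", index=False)
            return model, expr_a, labels_a

        model, expr_a, labels_a = _select

        @stage("train")
        def _train():
            res = model.fit(
                epochs_pretrain=config.epochs_pretrain,
                epochs_finetune=config.epochs_finetune,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                val_fraction=config.val_fraction,
                patience=config.patience,
                seed=config.seed,
            )
            res.save(out / "model.npz")
            pd.DataFrame(
                {
                    "epoch": range(len(res.training_log["train_loss"])),
                    "train_loss": res.training_log["train_loss"],
                    "val_loss": res.training_log["val_loss"],
                }
            ).to_csv(out / "training_log.tsv", sep="\t", index=False)
            return res

        res = _train

        @stage("evaluate")
        def _evaluate():
            if config.test_expression and config.test_labels:
                t_expr = read_expression(config.test_expression)
                t_labels = read_labels(config.test_labels)
                t_expr, t_labels, _ = align_samples(t_expr, t_labels)
                X_eval = res.featurize_expression(t_expr)
                y_eval = t_labels.to_numpy()
            else:
                logger.warning("no test set configured; reporting training-set (resubstitution) metrics")
                X_eval, y_eval = model.exog, model.endog
            reports = {"sdsae": res.evaluate(X_eval, y_eval)}
            if config.baselines:
                fitted = {
                    name: fit_baseline(name, model.exog, model.endog, seed=config.seed)
                    for name in config.baselines
                }
                reports.update(evaluate_all(fitted, X_eval, y_eval))
            write_report(reports, out / "report.tsv")
            return reports

        _evaluate
        _write_manifest(out, config, stages_done)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_manifest(out: Path, config: RunConfig, stages_done: list[str], failed: str | None = None):
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": _versions(),
        "stages_completed": stages_done,
    }
    if failed:
        manifest["failed_stage"] = failed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
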