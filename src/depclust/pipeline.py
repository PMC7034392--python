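"""End-to-end pipeline: filter -> cluster -> norms -> agreement -> CV ->
robustness -> validity, driven by a single config and master seed.

Every stochastic stage receives its own seed derived deterministically
from the master seed (via ``numpy.random.SeedSequence`` spawning), so one
integer reproduces the whole report bundle. Artifacts are written per
stage (JSON for machines, CSV/markdown for humans) plus a consolidated
``summary.json`` / ``summary.md``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, cluster, dataio, evaluate, norms, synthgen, validity

logger = logging.getLogger("depclust")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, cause: Exception, hint: str = ""):
        self.stage = stage
        msg = f"stage {stage!r} failed: {cause}"
        if hint:
            msg += f" ({hint})"
        super().__init__(msg)


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run.

    Exactly one of ``input_csv`` (a survey CSV plus ``schema``) or
    ``synthetic`` (a ready-made recipe name, ``paper_like`` or
    ``well_separated``) supplies the data.
    """

    input_csv: str | None = None
    schema: dataio.SurveySchema | None = None
    synthetic: str | None = "paper_like"
    n_respondents: int = 8000

    iqr_multiplier: float | None = 1.5   # None disables the screen
    k: int = 4

    cv_folds: int = 10
    balanced: bool = True                # also run under-sampled CV
    robustness_reps: int = 200
    train_fraction: float = 0.7
    learning_curve_sizes: tuple = (0.1, 0.25, 0.5, 0.75, 1.0)
    learning_curve_splits: int = 3

    outdir: str = "depclust_report"
    seed: int = 0

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input source required: input_csv or synthetic"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "schema" in raw and raw["schema"] is not None:
            sch = raw["schema"]
            sch["item_cols"] = tuple(sch.get("item_cols", ()))
            sch["demographic_cols"] = tuple(sch.get("demographic_cols", ()))
            sch["correlate_cols"] = tuple(sch.get("correlate_cols", ()))
            raw["schema"] = dataio.SurveySchema(**sch)
        if "learning_curve_sizes" in raw:
            raw["learning_curve_sizes"] = tuple(raw["learning_curve_sizes"])
        return cls(**raw)


def _stage_seeds(master_seed: int, names) -> dict:
    children = np.random.SeedSequence(int(master_seed)).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the consolidated summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    seeds = _stage_seeds(
        config.seed,
        ["simulate", "crossval", "undersample", "robustness", "learning_curve"],
    )
    summary: dict = {"config": {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(config).items()
    }, "stage_seeds": seeds}
    logger.info("master seed %d; stage seeds %s", config.seed, seeds)

    try:
        # ---- input -------------------------------------------------------
        if config.synthetic is not None:
            spec = synthgen.default_bdi13_spec(
                config.synthetic,
                n_respondents=config.n_respondents,
                seed=seeds["simulate"],
            )
            dataset = synthgen.generate_dataset(spec)
            dataset.to_csv(outdir / "dataset.csv")
            table = dataset.to_survey_table()
            schema = dataset.schema()
        else:
            schema = config.schema or dataio.SurveySchema()
            table = dataio.read_survey(config.input_csv, schema)
        summary["n_input"] = table.n
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("input", exc, "check the CSV and schema") from exc

    try:
        # ---- careless-response screen -----------------------------------
        if config.iqr_multiplier is not None:
            table, filter_report = dataio.iqr_filter(table, config.iqr_multiplier)
            filter_report.to_json(outdir / "filter_report.json")
            summary["filter"] = {
                k: v for k, v in filter_report.to_dict().items()
                if k != "removed_ids"
            }
            logger.info("IQR screen removed %d of %d",
                        filter_report.n_removed, filter_report.n_input)
        else:
            summary["filter"] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("filter", exc, "try --no-filter") from exc

    matrix = table.responses
    totals = dataio.total_scores(matrix)
    level_names = cluster.DEFAULT_LEVEL_NAMES if config.k == 4 else tuple(
        f"level_{i}" for i in range(config.k)
    )

    try:
        # ---- clustering constructor -------------------------------------
        model = cluster.kmeans_fit(matrix, cluster.maxmin_init(matrix, config.k))
        model.to_json(outdir / "cluster_model.json")
        cluster_sev = cluster.severity_labels(model)
        csum = cluster.summarize_clusters(model, matrix, level_names)
        pd.DataFrame(csum.to_records()).to_csv(outdir / "cluster_summary.csv",
                                               index=False)
        summary["clustering"] = {
            "n_iterations": model.n_iterations,
            "converged": model.converged,
            "sse": model.sse,
            "center_totals": sorted(model.center_totals.tolist()),
            "levels": csum.to_records(),
        }
        logger.info("k-means converged=%s after %d iterations",
                    model.converged, model.n_iterations)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("cluster", exc) from exc

    try:
        # ---- norm labelings ---------------------------------------------
        criteria = norms.builtin_criteria()
        labelings = {"clustering": cluster_sev}
        for crit in criteria:
            labelings[crit.name] = norms.classify_by_norm(totals, crit)
        out_df = pd.read_csv(outdir / "dataset.csv") if config.synthetic \
            else pd.read_csv(config.input_csv)
        keep = np.isin(out_df[schema.id_col if config.input_csv else "id"].to_numpy(),
                       table.ids)
        out_df = out_df.loc[keep].reset_index(drop=True)
        out_df["severity_level"] = [level_names[i] for i in cluster_sev]
        out_df.to_csv(outdir / "labeled.csv", index=False)
        summary["criteria"] = {c.name: c.describe()["levels"] for c in criteria}
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("classify-norm", exc) from exc

    try:
        # ---- correspondence ---------------------------------------------
        summary["agreement"] = {}
        for crit in criteria:
            cm = agreement.cross_tabulate(
                [level_names[i] for i in cluster_sev],
                [level_names[i] for i in labelings[crit.name]],
                level_names=level_names,
            )
            cm.to_dataframe().to_csv(outdir / f"confusion_{crit.name}.csv")
            (outdir / f"confusion_{crit.name}.md").write_text(
                cm.to_markdown() + "\n"
            )
            kappa = agreement.cohen_kappa(cm)
            summary["agreement"][crit.name] = {"kappa": kappa}
            logger.info("kappa clustering vs %s = %.3f", crit.name, kappa)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("compare", exc) from exc

    try:
        # ---- cross-validated model performance --------------------------
        summary["crossval"] = {}
        for method, labels in labelings.items():
            runs = {"imbalanced": (matrix, labels)}
            if config.balanced:
                bal_m, bal_y, _ = evaluate.undersample(
                    matrix, labels, seed=seeds["undersample"]
                )
                runs["balanced"] = (bal_m, bal_y)
            summary["crossval"][method] = {}
            for balance, (mx, ys) in runs.items():
                counts = np.bincount(np.asarray(ys), minlength=config.k)
                if counts.min() < config.cv_folds:
                    summary["crossval"][method][balance] = {
                        "skipped": f"smallest class has {int(counts.min())} "
                                   f"members, fewer than {config.cv_folds} folds"
                    }
                    logger.warning("crossval %s/%s skipped: class too small",
                                   method, balance)
                    continue
                report = evaluate.crossval(mx, ys, folds=config.cv_folds,
                                           seed=seeds["crossval"])
                d = report.to_dict()
                d.pop("per_fold")
                d["sensitivity"] = {
                    level_names[int(kk)]: vv for kk, vv in d["sensitivity"].items()
                }
                _dump_json(d, outdir / f"cv_{method}_{balance}.json")
                summary["crossval"][method][balance] = d
                curve = evaluate.learning_curve(
                    mx, ys,
                    train_sizes=config.learning_curve_sizes,
                    folds=config.learning_curve_splits,
                    seed=seeds["learning_curve"],
                )
                curve.to_csv(outdir / f"learning_curve_{method}_{balance}.csv",
                             index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("crossval", exc,
                                 "reduce --folds for small samples") from exc

    try:
        # ---- resampling robustness --------------------------------------
        if config.robustness_reps > 0:
            rob = evaluate.robustness(
                matrix, k=config.k,
                train_fraction=config.train_fraction,
                reps=config.robustness_reps,
                seed=seeds["robustness"],
            )
            _dump_json(rob.to_dict(), outdir / "robustness.json")
            summary["robustness"] = {
                "reps": rob.reps, "ari_mean": rob.ari_mean,
                "ari_sd": rob.ari_sd, "n_failed": rob.n_failed,
            }
            logger.info("robustness ARI %.3f (SD %.3f, %d reps)",
                        rob.ari_mean, rob.ari_sd, rob.reps)
        else:
            summary["robustness"] = {"skipped": True}
            logger.info("robustness stage skipped (reps=0)")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("robustness", exc) from exc

    try:
        # ---- convergent validity ----------------------------------------
        has_cols = (table.demographics is not None) or (table.correlates is not None)
        if has_cols:
            summary["validity"] = {}
            for method, labels in labelings.items():
                rep = validity.validity_battery(table, labels)
                _dump_json(rep.to_dict(), outdir / f"validity_{method}.json")
                if rep.correlate:
                    rep.level_means_table().to_csv(
                        outdir / f"level_means_{method}.csv"
                    )
                summary["validity"][method] = {
                    "chi2": {n: r["chi2"] for n, r in rep.demographic.items()},
                    "eta_squared": {
                        n: r["eta_squared"] for n, r in rep.correlate.items()
                    },
                }
        else:
            summary["validity"] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("validity", exc,
                                 "check demographic/correlate columns") from exc

    _dump_json(summary, outdir / "summary.json")
    (outdir / "summary.md").write_text(_render_markdown(summary, level_names))
    logger.removeHandler(log_handler)
    log_handler.close()
    return summary


def _render_markdown(summary: dict, level_names) -> str:
    lines = ["# depclust pipeline report", ""]
    if "filter" in summary and not summary["filter"].get("skipped"):
        f = summary["filter"]
        lines += [
            "## Careless-response screen",
            f"- input {f['n_input']}, removed {f['n_removed']}, "
            f"retained {f['n_retained']} "
            f"(fences [{f['lower_fence']:.2f}, {f['upper_fence']:.2f}])",
            "",
        ]
    if "clustering" in summary:
        c = summary["clustering"]
        lines += ["## Clustering-based classification",
                  f"- converged: {c['converged']} after {c['n_iterations']} iterations",
                  f"- center total scores: "
                  + ", ".join(f"{t:.2f}" for t in c["center_totals"]), ""]
        lines.append("| level | n | center total | score range |")
        lines.append("|---|---|---|---|")
        for rec in c["levels"]:
            rng = (f"{rec['score_min']}-{rec['score_max']}"
                   if rec["score_min"] is not None else "-")
            lines.append(f"| {rec['level']} | {rec['n']} | "
                         f"{rec['center_total']:.2f} | {rng} |")
        lines.append("")
    if "agreement" in summary:
        lines += ["## Correspondence with norm-based classifications"]
        for name, rec in summary["agreement"].items():
            lines.append(f"- kappa vs {name}: {rec['kappa']:.3f}")
        lines.append("")
    if "robustness" in summary and not summary["robustness"].get("skipped"):
        r = summary["robustness"]
        lines += ["## Resampling robustness",
                  f"- mean ARI {r['ari_mean']:.3f} (SD {r['ari_sd']:.3f}) "
                  f"over {r['reps']} replicates", ""]
    elif summary.get("robustness", {}).get("skipped"):
        lines += ["## Resampling robustness", "- skipped (reps=0)", ""]
    if "crossval" in summary:
        lines += ["## Cross-validated model performance",
                  "| method | data | accuracy | macro AUC |", "|---|---|---|---|"]
        for method, recs in summary["crossval"].items():
            for balance, d in recs.items():
                if "skipped" in d:
                    lines.append(f"| {method} | {balance} | skipped | skipped |")
                else:
                    lines.append(f"| {method} | {balance} | "
                                 f"{d['accuracy']:.3f} | {d['auc_macro']:.3f} |")
        lines.append("")
    if "validity" in summary and not summary["validity"].get("skipped"):
        lines += ["## Convergent validity (eta-squared per correlate)"]
        for method, rec in summary["validity"].items():
            etas = ", ".join(f"{n}={v:.2f}" for n, v in rec["eta_squared"].items())
            lines.append(f"- {method}: {etas}")
        lines.append("")
    return "\n".join(lines)
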