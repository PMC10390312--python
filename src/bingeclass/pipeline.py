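"""End-to-end pipeline: simulate/ingest -> derive -> classify -> validate -> apt.

``run_pipeline`` executes the stages in order and writes an artifact
bundle: group assignments, fitted/frozen model coefficients (JSON),
internal concordance, external group means, per-respondent demand table,
and a log recording the seed, config hash and per-stage row accounting
(including screening exclusions).  Reruns with an identical config
reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import apt as apt_mod
from .clustering import KMeansGroupDeriver, cluster_means, elbow_select_k
from .cohort import default_profiles, generate_apt_curve, generate_cohort
from .io import PipelineConfig, read_apt_long, read_cohort, write_table
from .ppom import fit_ppom, published_classifier, select_items
from .survey import ITEM_FIELDS, RETAINED_ITEMS
from .validate import composition_by, concordance, external_group_means


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _fit_demand_table(curves: dict, config: PipelineConfig) -> tuple[pd.DataFrame, int]:
    rows, excluded = [], 0
    for rid, arr in curves.items():
        curve = apt_mod.DemandCurve(tuple(arr[:, 0]), tuple(arr[:, 1]))
        report = apt_mod.screen_curve(
            curve,
            trend_threshold=config.trend_threshold,
            bounce_threshold=config.bounce_threshold,
        )
        row = {
            "id": rid,
            "screen_pass": report.passed,
            "trend_stat": report.trend_stat,
            "bounce_ratio": report.bounce_ratio,
            "reversal_count": report.reversal_count,
        }
        if report.passed:
            try:
                fit = apt_mod.fit_exponentiated_demand(curve)
                row.update(
                    intensity=fit.intensity, omax=fit.omax, pmax=fit.pmax,
                    breakpoint1=fit.breakpoint1, breakpoint0=fit.breakpoint0,
                    q0=fit.q0, alpha=fit.alpha, ev=fit.ev, converged=fit.converged,
                )
            except ValueError:
                row["converged"] = False
        else:
            excluded += 1
        rows.append(row)
    return pd.DataFrame(rows), excluded


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return artifact paths and in-memory results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed}", f"config_hash={config.hash()}"]
    artifacts: dict = {"log": out / "pipeline.log"}

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def fail(stage: str, exc: Exception):
        log(stage, f"FAILED: {exc}")
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: cohort -------------------------------------------------
    try:
        if config.input_csv:
            cohort = read_cohort(config.input_csv, config.column_mapping,
                                 config.percent_scale)
            log("cohort", f"read {len(cohort)} validated rows from {config.input_csv}")
        else:
            cohort, true_labels = generate_cohort(n=config.n, seed=config.seed)
            write_table(out / "cohort.csv", cohort)
            write_table(out / "true_labels.csv",
                        pd.DataFrame({"id": cohort["id"], "group": true_labels}))
            log("cohort", f"simulated {len(cohort)} rows (default profiles)")
    except StageError:
        raise
    except Exception as exc:
        fail("cohort", exc)

    items = cohort[list(ITEM_FIELDS)].to_numpy(float)

    # --- stage: derive (K-means + elbow + PPOM refit) -------------------
    try:
        if config.n_clusters is None:
            k, curve = elbow_select_k(items, config.k_range, seed=config.seed,
                                      n_restarts=max(5, config.n_restarts // 2))
            write_table(out / "wcss_curve.csv", curve)
            log("derive", f"elbow selected K={k} over {list(config.k_range)}")
        else:
            k = config.n_clusters
        deriver = KMeansGroupDeriver(
            n_clusters=k, n_restarts=config.n_restarts, random_state=config.seed
        ).fit(items)
        gold = deriver.labels_
        means = cluster_means(gold, items)
        write_table(out / "centroids.csv",
                    pd.DataFrame(deriver.cluster_centers_, columns=list(ITEM_FIELDS)))
        write_table(out / "cluster_means.csv", means, index=True)

        retained, trail = select_items(
            cohort[list(ITEM_FIELDS)], gold, alpha_level=config.alpha_level,
            corr_threshold=config.corr_threshold,
        )
        log("derive", f"retained items: {retained}")
        fitted = fit_ppom(cohort[retained], gold, predictors=retained)
        (out / "ppom_fit.json").write_text(json.dumps(
            {"config_hash": config.hash(), "seed": config.seed, **fitted.to_dict()},
            indent=2))
        log("derive", f"PPOM converged={fitted.converged_} loglik={fitted.loglik_:.3f}")
        artifacts["fit_json"] = out / "ppom_fit.json"
    except StageError:
        raise
    except Exception as exc:
        fail("derive", exc)

    # --- stage: classify (frozen published equations) -------------------
    try:
        frozen = published_classifier(config.coefficient_set)
        probs = frozen.predict_proba(cohort[list(RETAINED_ITEMS)])
        predicted = frozen.predict(cohort[list(RETAINED_ITEMS)])
        assignments = pd.DataFrame({
            "id": cohort["id"], "kmeans_group": gold, "ppom_group": predicted,
        })
        for g in range(1, 5):
            assignments[f"p_group{g}"] = probs[:, g - 1]
        write_table(out / "assignments.csv", assignments)
        artifacts["assignments"] = out / "assignments.csv"
        log("classify", f"classified {len(predicted)} rows "
                        f"({config.coefficient_set})")
    except StageError:
        raise
    except Exception as exc:
        fail("classify", exc)

    # --- stage: validate -------------------------------------------------
    try:
        # internal validation: gold K-means groups vs the refit model's
        # predictions on the same sample
        internal_pred = fitted.predict(cohort[retained])
        table = concordance(gold, internal_pred, n_groups=max(4, k))
        conc = table.counts.copy()
        conc["error_pct"] = table.row_errors_pct
        write_table(out / "concordance.csv", conc, index=True)
        artifacts["concordance"] = out / "concordance.csv"
        log("validate", f"overall misclassification {table.overall_error_pct}%")

        group_means = external_group_means(cohort, frozen)
        write_table(out / "group_means.csv", group_means, index=True)
        artifacts["group_means"] = out / "group_means.csv"

        if "gender" in cohort.columns:
            comp = composition_by(predicted, cohort["gender"])
            write_table(out / "composition.csv",
                        comp["share_of_attribute"].round(2), index=True)
    except StageError:
        raise
    except Exception as exc:
        fail("validate", exc)

    # --- stage: apt -------------------------------------------------------
    try:
        if config.apt_csv:
            curves = read_apt_long(config.apt_csv)
        elif config.simulate_apt and config.input_csv is None:
            profiles = {p.index: p for p in default_profiles()}
            curves = {}
            for i, (rid, g) in enumerate(zip(cohort["id"], true_labels)):
                prof = profiles[int(g)]
                c = generate_apt_curve(
                    prof.q0, prof.alpha, config.prices,
                    noise_sd=config.apt_noise_sd,
                    seed=(config.seed * 100003 + i) % (2**31),
                )
                curves[rid] = np.column_stack([c.p, c.q])
        else:
            curves = {}
        if curves:
            demand, excluded = _fit_demand_table(curves, config)
            write_table(out / "demand.csv", demand)
            artifacts["demand"] = out / "demand.csv"
            log("apt", f"{len(curves)} curves in, {excluded} excluded by "
                       f"screening, {len(curves) - excluded} fitted")
    except StageError:
        raise
    except Exception as exc:
        fail("apt", exc)

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return {
        "artifacts": artifacts,
        "elbow_k": k,
        "concordance": table,
        "fitted": fitted,
        "retained": retained,
        "log": log_lines,
    }
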