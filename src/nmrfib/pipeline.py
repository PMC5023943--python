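"""End-to-end pipeline: simulate/load -> preprocess -> model -> screen ->
fibrosis index -> correlate, as one reproducible run.

Every stage writes its tables under the run directory; the JSON report only
echoes numbers that exist in stage output files. A stage failure leaves a
``FAILED`` marker naming the stage and re-raises.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignments import default_assignments
from .chemometrics import fit_oplsda, fit_plsda, permutation_test, splot, vip, \
    coefficients
from .correlation import correlate, correlation_matrix, sign_concordance
from .fibrosis import fibrosis_index_from_samples
from .io import read_endpoints, read_spectra, write_bucket_table, write_endpoints, \
    write_spectra
from .preprocess import BucketingSpec, build_matrix, quantify_metabolites
from .reference import load_reference_tables
from .screening import ScreeningCuts, group_compare, metabolite_criteria, screen
from .simulate import SimulationConfig, simulate_dataset


@dataclass
class ModelSettings:
    method: str = "oplsda"  # "oplsda" | "plsda"
    groups: tuple[str, str] = ("A", "C")
    n_ortho: int = 1
    n_components: int = 2  # used by plsda
    scaling: str = "uv"
    k_folds: int = 7
    n_permutations: int = 200


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    With ``spectra_dir``/``metadata_path``/``endpoints_path`` unset, the run
    starts from the synthetic-data generator under ``simulation``.
    """

    out_dir: str = "nmrfib_run"
    seed: int = 17
    spectra_dir: str | None = None
    metadata_path: str | None = None
    endpoints_path: str | None = None
    simulation: SimulationConfig | None = None
    bucketing: BucketingSpec = field(default_factory=BucketingSpec)
    model: ModelSettings = field(default_factory=ModelSettings)
    cuts: ScreeningCuts = field(default_factory=ScreeningCuts)
    join: str = "left"
    report_version: str = "1"


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    problems = []
    try:
        if config.bucketing.width <= 0:
            problems.append("bucketing.width must be > 0")
    except Exception as exc:  # spec objects raise on construction too
        problems.append(f"bucketing: {exc}")
    if len(set(config.model.groups)) != 2:
        problems.append("model.groups needs 2 classes")
    if config.model.method not in ("oplsda", "plsda"):
        problems.append(f"model.method unknown: {config.model.method!r}")
    if config.model.n_permutations > 0 and config.seed is None:
        problems.append("seed required when permutations are requested")
    if config.join not in ("left", "both"):
        problems.append(f"join must be 'left' or 'both', got {config.join!r}")
    external = [config.spectra_dir, config.metadata_path, config.endpoints_path]
    if any(p is not None for p in external):
        if not all(p is not None for p in external):
            problems.append("spectra_dir, metadata_path and endpoints_path must "
                            "be given together")
        else:
            for p in external:
                if not os.path.exists(p):
                    problems.append(f"input path does not exist: {p}")
    return problems


def _write_json(path: str, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _config_echo(config: RunConfig) -> dict:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        return o

    return {k: enc(v) for k, v in dataclasses.asdict(config).items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the JSON-serialisable run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    from . import __version__ as _pkg_version  # deferred: avoids import cycle

    report: dict = {"software": {"name": "nmrfib", "version": _pkg_version},
                    "report_version": config.report_version,
                    "config": _config_echo(config), "stages": {}}
    stage = "setup"
    try:
        assignments = default_assignments()

        stage = "simulate" if config.spectra_dir is None else "load"
        if config.spectra_dir is None:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            spectra, meta, conc, endpoints = simulate_dataset(sim, assignments)
            write_spectra(spectra, os.path.join(config.out_dir, "spectra"),
                          os.path.join(config.out_dir, "metadata.tsv"))
            write_endpoints(endpoints, os.path.join(config.out_dir, "endpoints.tsv"))
        else:
            spectra = read_spectra(config.spectra_dir, config.metadata_path)
            endpoints = read_endpoints(config.endpoints_path)
            meta = pd.DataFrame(
                {"animal_id": [s.animal_id for s in spectra],
                 "group": [s.group for s in spectra],
                 "tissue_weight_g": [s.tissue_weight for s in spectra]},
                index=pd.Index([s.sample_id for s in spectra], name="sample_id"))
        report["stages"][stage] = {"n_samples": len(spectra),
                                   "n_animals": int(meta["animal_id"].nunique())}

        stage = "preprocess"
        table = build_matrix(spectra, config.bucketing)
        write_bucket_table(table, os.path.join(config.out_dir, "buckets.tsv"))
        contents = quantify_metabolites(spectra, assignments)
        contents.to_csv(os.path.join(config.out_dir, "contents.tsv"), sep="\t")
        report["stages"]["preprocess"] = {
            "n_buckets_raw": config.bucketing.n_raw,
            "n_buckets": int(table.bucket_left_edges.size),
            "n_buckets_excluded": config.bucketing.n_raw
            - int(table.bucket_left_edges.size),
            "normalized": table.normalized,
        }

        stage = "model"
        ms = config.model
        in_model = np.isin(table.groups, ms.groups)
        X = table.values[in_model]
        y_groups = [g for g, m in zip(table.groups, in_model) if m]
        if ms.method == "oplsda":
            model = fit_oplsda(X, y_groups, n_ortho=ms.n_ortho, scaling=ms.scaling,
                               k_folds=ms.k_folds, seed=config.seed)
            settings = {"method": "oplsda", "n_ortho": ms.n_ortho,
                        "scaling": ms.scaling}
        else:
            model = fit_plsda(X, y_groups, n_components=ms.n_components,
                              scaling=ms.scaling, k_folds=ms.k_folds,
                              seed=config.seed)
            settings = {"method": "plsda", "n_components": ms.n_components,
                        "scaling": ms.scaling}
        sp = splot(model, X)
        sp.insert(0, "bucket", table.bucket_left_edges)
        sp.to_csv(os.path.join(config.out_dir, "splot.tsv"), sep="\t", index=False)
        pd.DataFrame({"bucket": table.bucket_left_edges, "vip": vip(model),
                      "coefficient": np.ravel(coefficients(model))}).to_csv(
            os.path.join(config.out_dir, "vip.tsv"), sep="\t", index=False)
        sample_ids = [s for s, m in zip(table.sample_ids, in_model) if m]
        pd.DataFrame(model.scores, index=sample_ids).to_csv(
            os.path.join(config.out_dir, "scores.tsv"), sep="\t")
        validation = permutation_test(X, y_groups, settings,
                                      n_permutations=ms.n_permutations,
                                      k_folds=ms.k_folds, seed=config.seed)
        _write_json(os.path.join(config.out_dir, "validation.json"), {
            "n_permutations": validation.n_permutations,
            "original_r2": validation.original_r2,
            "original_q2": validation.original_q2,
            "q2_intercept": validation.q2_intercept,
            "passed": validation.passed,
            "cv_anova_F": validation.cv_anova_F,
            "cv_anova_p": validation.cv_anova_p,
        })
        report["stages"]["model"] = {
            "method": ms.method, "groups": list(ms.groups),
            "r2y": model.r2y, "q2": model.q2,
            "r2x_per_component": [float(v) for v in model.r2x_per_component],
            "validation_passed": validation.passed,
            "cv_anova_p": validation.cv_anova_p,
        }

        stage = "screen"
        comparison = group_compare(contents, table.groups)
        criteria = metabolite_criteria(model, sp, table.bucket_left_edges,
                                       table.bucket_width, assignments)
        records = screen(criteria, comparison, config.cuts)
        screening_df = pd.DataFrame([dataclasses.asdict(r) for r in records]
                                    ).drop(columns=["mean_by_group"])
        with open(os.path.join(config.out_dir, "screening.tsv"), "w") as fh:
            fh.write(f"# cuts: vip>={config.cuts.vip} |pcorr|>={config.cuts.pcorr} "
                     f"p<{config.cuts.alpha}\n")
            screening_df.to_csv(fh, sep="\t", index=False)
        report["stages"]["screen"] = {
            "n_selected": int(sum(r.selected for r in records)),
            "selected": [r.metabolite for r in records if r.selected],
            "directions": {r.metabolite: r.direction for r in records},
        }

        stage = "adf"
        fib = fibrosis_index_from_samples(contents, table.groups)
        _write_json(os.path.join(config.out_dir, "adf.json"), {
            "adf_percent": fib.adf_percent, "n_used": fib.n_used,
            "excluded": fib.excluded,
            "alpha": fib.per_metabolite["alpha"].to_dict(),
        })
        report["stages"]["adf"] = {"adf_percent": fib.adf_percent,
                                   "n_used": fib.n_used}

        stage = "correlate"
        corr = correlate(contents, endpoints, meta, join=config.join)
        corr.to_csv(os.path.join(config.out_dir, "correlations.tsv"),
                    sep="\t", index=False)
        _, ref_corr = load_reference_tables()
        concord = sign_concordance(correlation_matrix(corr), ref_corr)
        report["stages"]["correlate"] = {"n_pairs": len(corr),
                                         "sign_concordance": concord}
    except Exception as exc:
        with open(os.path.join(config.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(os.path.join(config.out_dir, "report.json"), report)
    return report
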