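"""End-to-end orchestration: featurize → reduce → cluster/sweep → evaluate.

With family labels available, the cluster number K is swept over 6
values between N (the number of known families) and 2N and the most
accurate K wins. Without labels — or with an explicit ``sweep.K_list``
— clustering runs at the given K values and, absent labels, only the
novel-family typing against the UNCLASSIFIED sentinel is reported.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io
from .clustering import Clustering, SweepPlan, kmeans_cityblock, plan_sweep, run_sweep
from .config import feature_spec, make_config, reducer_spec
from .evaluation import EvaluationReport, evaluate, typing_report
from .features import featurize
from .reduction import reduce_features

logger = logging.getLogger(__name__)


def load_dataset(cfg: dict) -> io.Dataset:
    """Read the FASTA and apply family labels from TSV or miFam file."""
    paths = cfg["paths"]
    if not paths["fasta"]:
        raise ValueError("config paths.fasta is required")
    records = io.read_fasta(paths["fasta"])
    dataset = io.Dataset(records)
    if paths["labels"]:
        dataset = dataset.with_labels(io.read_family_table(paths["labels"]))
    elif paths["mifam"]:
        dataset = dataset.with_labels(io.read_mifam(paths["mifam"]))
    return dataset


def run_pipeline(
    config: dict | None = None,
) -> tuple[EvaluationReport, Clustering, dict[str, Path]]:
    """Run the four-stage pipeline and write report + assignments.

    ``config`` holds partial overrides of the defaults (see
    :mod:`mirnaclust.config`). Returns the evaluation report of the best
    K, its clustering, and the paths of the written artifacts.
    """
    cfg = config if _is_full(config or {}) else make_config(config)
    dataset = load_dataset(cfg)
    report, clustering = run_pipeline_on(dataset, cfg)

    out_dir = Path(cfg["paths"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out_dir / "report.json",
        "assignments": out_dir / "assignments.tsv",
    }
    report.params["config"] = _jsonable(cfg)  # provenance
    io.write_report(report, paths["report"])
    io.write_assignments(clustering, dataset, report, paths["assignments"])
    return report, clustering, paths


def _is_full(cfg: dict) -> bool:
    from .config import DEFAULTS

    return set(cfg) == set(DEFAULTS)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline_on(
    dataset: io.Dataset, cfg: dict
) -> tuple[EvaluationReport, Clustering]:
    """The compute stages on an in-memory dataset (no file output)."""
    seed = int(cfg["seed"])
    km = cfg["kmeans"]
    ev = cfg["evaluation"]
    logger.info("pipeline seed=%d, %d records, %d known families",
                seed, len(dataset), dataset.n_families)

    fm = featurize(dataset.records, feature_spec(cfg))
    logger.info("featurized: %d x %d", fm.values.shape[0], fm.values.shape[1])
    rm = reduce_features(fm, reducer_spec(cfg))
    logger.info("reduced via %s to %d columns", rm.spec.method, rm.values.shape[1])

    labels = [r.family for r in dataset.records]
    k_list = cfg["sweep"]["K_list"]
    labeled = dataset.n_families > 0

    if labeled and cfg["sweep"]["enabled"]:
        plan = (
            SweepPlan(tuple(sorted(set(int(k) for k in k_list))))
            if k_list
            else plan_sweep(dataset.n_families)
        )
        best_K, results = run_sweep(
            rm.values, plan, labels,
            n_restarts=int(km["restarts"]), seed=seed,
            max_iter=int(km["max_iter"]), tol=float(km["tol"]),
            centroid=km["centroid"],
            min_cluster_size=int(ev["min_cluster_size"]),
            vote_fraction=float(ev["vote_fraction"]),
            ids=dataset.ids,
        )
        clustering, report = results[best_K]
        logger.info("sweep over K=%s: best K=%d accuracy=%.4f",
                    list(plan.values), best_K, report.accuracy)
    else:
        if not k_list:
            raise ValueError(
                "without family labels (or with sweep disabled) an explicit "
                "sweep.K_list is required"
            )
        best = None
        for K in sorted(set(int(k) for k in k_list)):
            clustering = kmeans_cityblock(
                rm.values, K, n_restarts=int(km["restarts"]), seed=seed + K,
                max_iter=int(km["max_iter"]), tol=float(km["tol"]),
                centroid=km["centroid"],
            )
            if labeled:
                report = evaluate(
                    clustering, labels,
                    min_cluster_size=int(ev["min_cluster_size"]),
                    vote_fraction=float(ev["vote_fraction"]),
                    ids=dataset.ids,
                )
                key = report.accuracy
            else:
                report = typing_report(
                    clustering, labels,
                    min_cluster_size=int(ev["min_cluster_size"]),
                    vote_fraction=float(ev["vote_fraction"]),
                )
                key = -clustering.objective
            if best is None or key > best[0]:
                best = (key, clustering, report)
        _, clustering, report = best

    return report, clustering
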