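"""End-to-end analysis pipeline.

Order of stages: (optional) cohort simulation → subject connectomes
(functional Fisher-Z Pearson with optional age/sex edge regression;
structural symmetric-KL) → diffusion-map gradients → Procrustes
alignment to the control-group template → gradient spans and ROI/network
group statistics with FDR → SVM classification on network gradient
features → covariate-controlled correlation of gradient change with
clinical change. ``run_pipeline`` adds file IO and a checksummed
manifest around ``analyze_cohort``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ngio
from .connectomes import (
    ConnectivityMatrix,
    functional_connectome,
    regress_confounds,
    structural_connectome,
)
from .gradients import (
    GradientSet,
    cosine_affinity,
    diffusion_map,
    gradient_span,
    orient_reference,
    procrustes_align,
    sparsify_rows,
)
from .stats import (
    NetworkPartition,
    SubjectRecord,
    classify,
    delta_clinical,
    delta_features,
    network_scores,
    partial_correlation,
    roiwise_compare,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["PipelineParams", "RunConfig", "analyze_cohort", "run_pipeline", "embed_connectome"]

log = logging.getLogger("neurograd")


@dataclass
class PipelineParams:
    """Tunable parameters of the gradient pipeline."""

    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    sparsity_keep: float = 0.10
    grid_points: int = 256
    density_floor: float = 1e-12
    q: float = 0.05
    cv_folds: int = 5
    seed: int = 0
    align_iter: int = 10
    regress_functional_confounds: bool = True
    regress_structural_confounds: bool = False
    invert_kl: bool = False  # use (max - KL) profiles before cosine affinity

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 < self.sparsity_keep <= 1:
            raise ValueError("sparsity_keep must be in (0, 1]")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.n_components < 1 or self.cv_folds < 2:
            raise ValueError("n_components >= 1 and cv_folds >= 2 required")


@dataclass
class RunConfig:
    """File-level configuration for a full reproducible run."""

    output_dir: str
    simulate: CohortConfig | None = None
    data_dir: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    write_inputs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = CohortConfig(**raw["simulate"]) if raw.get("simulate") is not None else None
        params = PipelineParams(**raw.get("params", {}))
        cfg = cls(
            output_dir=raw["output_dir"],
            simulate=sim,
            data_dir=raw.get("data_dir"),
            params=params,
            write_inputs=bool(raw.get("write_inputs", False)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and self.data_dir is None:
            raise ValueError("config needs either a simulate block or a data_dir")
        if self.data_dir is not None:
            d = Path(self.data_dir)
            for required in ("metadata.tsv", "partition.tsv"):
                if not (d / required).exists():
                    raise ValueError(f"missing required input file: {d / required}")


# ---------------------------------------------------------------------------
# Embedding of a single connectome
# ---------------------------------------------------------------------------

def embed_connectome(
    cm: ConnectivityMatrix,
    params: PipelineParams,
) -> GradientSet:
    """Sparsify → cosine affinity → diffusion map for one connectome.

    If the affinity graph at the requested sparsity is disconnected (a
    tail event for clean, strongly modular matrices), the row
    sparsification is progressively relaxed (keep fraction x 1.5) until
    the graph is connected; the relaxation is logged. The embedding
    itself refuses disconnected graphs.
    """
    values = cm.values
    if cm.kind == "structural_kl" and params.invert_kl:
        values = values.max() - values
        np.fill_diagonal(values, 0.0)
    keep = params.sparsity_keep
    while True:
        rows = sparsify_rows(values, keep)
        aff = cosine_affinity(rows, keep, source_kind=cm.kind, roi_ids=cm.roi_ids)
        try:
            return diffusion_map(
                aff,
                alpha=params.alpha,
                diffusion_time=params.diffusion_time,
                n_components=params.n_components,
                roi_ids=cm.roi_ids,
                subject_id=cm.subject_id,
                session=cm.session,
            )
        except ValueError as e:
            if "disconnected" not in str(e) or keep >= 1.0:
                raise
            keep = min(1.0, keep * 1.5)
            log.info(
                "affinity disconnected for %s/%s; relaxing sparsity to keep=%.3f",
                cm.subject_id, cm.session, keep,
            )


def _group_mean_matrix(mats: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    values = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix(values, mats[0].kind, mats[0].roi_ids, "group-mean", "")


# ---------------------------------------------------------------------------
# Cohort loading (the file-based twin of the synthetic generator)
# ---------------------------------------------------------------------------

def load_cohort(data_dir: str | Path) -> SyntheticCohort:
    d = Path(data_dir)
    subjects = ngio.read_metadata_tsv(d / "metadata.tsv")
    partition = ngio.read_partition_tsv(d / "partition.tsv")
    timeseries = {}
    vertex_areas = {}
    for s in subjects:
        sessions = ("control",) if s.group == "control" else ("pre", "post")
        for session in sessions:
            ts_path = d / f"{s.subject_id}_{session}_timeseries.tsv"
            va_path = d / f"{s.subject_id}_{session}_vertex_areas.tsv"
            for p in (ts_path, va_path):
                if not p.exists():
                    raise ValueError(f"missing input file for {s.subject_id}/{session}: {p.name}")
            timeseries[(s.subject_id, session)] = ngio.read_timeseries_tsv(
                ts_path, s.subject_id, session
            )
            vertex_areas[(s.subject_id, session)] = ngio.read_vertex_areas_tsv(
                va_path, s.subject_id, session
            )
    truth_path = d / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticCohort(
        subjects=subjects,
        timeseries=timeseries,
        vertex_areas=vertex_areas,
        partition=partition,
        truth=truth,
        config=None,  # unknown for externally supplied data
    )


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def _session_keys(cohort: SyntheticCohort) -> list[tuple[str, str]]:
    keys = []
    for s in cohort.subjects:
        if s.group == "control":
            keys.append((s.subject_id, "control"))
        else:
            keys.extend([(s.subject_id, "pre"), (s.subject_id, "post")])
    return keys


def compute_gradients(
    cohort: SyntheticCohort,
    params: PipelineParams,
    kind: str,
) -> dict:
    """Connectomes → template → aligned per-session gradients for one kind.

    The group template is the embedding of the control-group mean
    connectome, oriented so the gradient runs primary → association;
    individual embeddings are then iteratively Procrustes-rotated onto
    it. Returns a dict with the template, the aligned GradientSets per
    session key, and the alignment diagnostics.
    """
    keys = _session_keys(cohort)
    demo = {s.subject_id: s for s in cohort.subjects}
    if kind == "functional":
        mats = [functional_connectome(cohort.timeseries[k]) for k in keys]
        if params.regress_functional_confounds and len(keys) >= 3:
            mats = regress_confounds(
                mats,
                age=[demo[k[0]].age for k in keys],
                sex=[demo[k[0]].sex for k in keys],
            )
    elif kind == "structural_kl":
        mats = [
            structural_connectome(
                cohort.vertex_areas[k],
                n_points=params.grid_points,
                floor=params.density_floor,
            )
            for k in keys
        ]
        if params.regress_structural_confounds and len(keys) >= 3:
            mats = regress_confounds(
                mats,
                age=[demo[k[0]].age for k in keys],
                sex=[demo[k[0]].sex for k in keys],
            )
    else:
        raise ValueError(f"unknown connectome kind {kind!r}")

    control_idx = [i for i, k in enumerate(keys) if k[1] == "control"]
    template_source = control_idx if control_idx else list(range(len(keys)))
    mean_cm = _group_mean_matrix([mats[i] for i in template_source])
    template = embed_connectome(mean_cm, params)
    roi_networks = cohort.partition.networks_for(mats[0].roi_ids)
    high = "DMN" if "DMN" in cohort.partition.labels else cohort.partition.labels[-1]
    low = "VIS" if "VIS" in cohort.partition.labels else cohort.partition.labels[0]
    template = orient_reference(template, roi_networks, high_network=high, low_network=low)

    sets = [embed_connectome(m, params) for m in mats]
    aligned, align_info = procrustes_align(
        sets, reference=template.scores, n_iter=params.align_iter
    )
    return {
        "keys": keys,
        "connectomes": mats,
        "template": template,
        "gradients": dict(zip(keys, aligned)),
        "alignment": align_info,
    }


def analyze_cohort(
    cohort: SyntheticCohort,
    params: PipelineParams | None = None,
) -> dict:
    """Run the full gradient analysis on an in-memory cohort.

    Returns a results dict with per-session aligned gradients, span and
    ROI/network statistics, classifier reports and treatment
    correlations for both connectome kinds.
    """
    params = params or PipelineParams()
    results: dict = {"params": params}
    part = cohort.partition
    patients = [s for s in cohort.subjects if s.group == "patient"]
    controls = [s for s in cohort.subjects if s.group == "control"]

    for kind, tag in (("functional", "FCG1"), ("structural_kl", "STG1")):
        grad = compute_gradients(cohort, params, kind)
        results[kind] = grad
        gsets = grad["gradients"]

        # per-session principal-gradient span and network scores
        rows = []
        net_rows = []
        for (sid, session), gs in gsets.items():
            group = "control" if session == "control" else "patient"
            rows.append(
                {
                    "subject_id": sid,
                    "session": session,
                    "group": group,
                    "span": gradient_span(gs.scores[:, 0]),
                }
            )
            scores = network_scores(gs, part, component=0)
            net_rows.append({"subject_id": sid, "session": session, **scores.to_dict()})
        span_df = pd.DataFrame(rows)
        net_df = pd.DataFrame(net_rows)
        results[f"span_{tag}"] = span_df
        results[f"network_scores_{tag}"] = net_df

        # span comparisons: control vs pre (independent), pre vs post (paired)
        span_control = span_df.query("session == 'control'")["span"].to_numpy()
        span_pre = span_df.query("session == 'pre'")["span"].to_numpy()
        span_post = span_df.query("session == 'post'")["span"].to_numpy()
        span_stats = {}
        if len(span_control) >= 3 and len(span_pre) >= 3:
            r = roiwise_compare(
                span_control[:, None], span_pre[:, None], paired=False,
                q=params.q, unit_ids=["span"],
            )
            span_stats["control_vs_pre"] = r.table.iloc[0].to_dict()
            r = roiwise_compare(
                span_control[:, None], span_post[:, None], paired=False,
                q=params.q, unit_ids=["span"],
            )
            span_stats["control_vs_post"] = r.table.iloc[0].to_dict()
        if len(span_pre) >= 3 and len(span_pre) == len(span_post):
            r = roiwise_compare(
                span_pre[:, None], span_post[:, None], paired=True,
                q=params.q, unit_ids=["span"],
            )
            span_stats["pre_vs_post"] = r.table.iloc[0].to_dict()
        results[f"span_stats_{tag}"] = span_stats

        # ROI-wise comparisons on the principal gradient
        roi_ids = list(gsets[next(iter(gsets))].roi_ids)
        g1 = {k: gs.scores[:, 0] for k, gs in gsets.items()}
        ctrl_mat = np.array([g1[(s.subject_id, "control")] for s in controls])
        pre_mat = np.array([g1[(s.subject_id, "pre")] for s in patients])
        post_mat = np.array([g1[(s.subject_id, "post")] for s in patients])
        if len(controls) >= 3 and len(patients) >= 3:
            results[f"roi_stats_control_vs_pre_{tag}"] = roiwise_compare(
                ctrl_mat, pre_mat, paired=False, q=params.q, unit_ids=roi_ids
            )
            results[f"roi_stats_pre_vs_post_{tag}"] = roiwise_compare(
                pre_mat, post_mat, paired=True, q=params.q, unit_ids=roi_ids
            )

    # --- classification: control vs patient-pre on network gradient scores
    fcg = results["network_scores_FCG1"]
    stg = results["network_scores_STG1"]
    mask = fcg["session"].isin(["control", "pre"])
    fcg_X = fcg.loc[mask].set_index("subject_id")[list(part.labels)]
    stg_X = stg.loc[stg["session"].isin(["control", "pre"])].set_index("subject_id")[
        list(part.labels)
    ]
    stg_X = stg_X.loc[fcg_X.index]
    labels01 = (fcg.loc[mask, "session"] == "pre").astype(int).to_numpy()
    feature_sets = {
        "FCG1": fcg_X.to_numpy(),
        "STG1": stg_X.to_numpy(),
        "combined": np.hstack([fcg_X.to_numpy(), stg_X.to_numpy()]),
    }
    results["classification"] = {
        name: classify(
            pd.DataFrame(X), labels01, feature_set=name,
            n_folds=params.cv_folds, seed=params.seed,
        )
        for name, X in feature_sets.items()
    }

    # --- treatment correlations: per-network ΔGradient vs ΔUPDRS-III
    if len(patients) > 4 and all(p.updrs3_pre is not None for p in patients):
        corr_tables = {}
        for kind, tag in (("functional", "FCG1"), ("structural_kl", "STG1")):
            gsets = results[kind]["gradients"]
            rows = []
            for net in part.labels:
                x, y, ages, sexes = [], [], [], []
                for p in patients:
                    d = delta_features(
                        gsets[(p.subject_id, "pre")], gsets[(p.subject_id, "post")],
                        part, component=0,
                    )
                    x.append(d[net])
                    y.append(delta_clinical(p))
                    ages.append(p.age)
                    sexes.append(p.sex)
                res = partial_correlation(
                    x, y, covariates=np.column_stack([ages, sexes]), network=net
                )
                rows.append(
                    {"network": net, "r": res.r, "p": res.p, "n": res.n,
                     "covariates": ",".join(res.covariates)}
                )
            corr_tables[tag] = pd.DataFrame(rows)
        results["treatment_correlations"] = corr_tables
    return results


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> ngio.FileManifest:
    """Execute the configured run and write all artifacts plus a manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = ngio.FileManifest(root=str(outdir))

    stage = "simulate"
    try:
        if config.simulate is not None:
            log.info("simulating cohort (seed=%d)", config.simulate.seed)
            cohort = generate_cohort(config.simulate)
            if config.write_inputs:
                for p in ngio.write_cohort(cohort, outdir / "inputs"):
                    manifest.add(p, "tsv/json", "simulate")
        else:
            cohort = load_cohort(config.data_dir)

        stage = "analysis"
        results = analyze_cohort(cohort, config.params)

        stage = "write"
        for kind, tag in (("functional", "FCG1"), ("structural_kl", "STG1")):
            p = outdir / f"template_{tag}.tsv"
            ngio.write_gradients(
                results[kind]["template"], p, outdir / f"template_{tag}.json"
            )
            manifest.add(p, "gradients-tsv", "embedding")
            manifest.add(outdir / f"template_{tag}.json", "json", "embedding")

            p = outdir / f"span_{tag}.tsv"
            results[f"span_{tag}"].to_csv(p, sep="\t", index=False)
            manifest.add(p, "tsv", "stats")

            p = outdir / f"network_scores_{tag}.tsv"
            results[f"network_scores_{tag}"].to_csv(p, sep="\t", index=False)
            manifest.add(p, "tsv", "stats")

            p = outdir / f"span_stats_{tag}.json"
            p.write_text(json.dumps(results[f"span_stats_{tag}"], indent=2, default=float))
            manifest.add(p, "json", "stats")

            for comparison in ("control_vs_pre", "pre_vs_post"):
                key = f"roi_stats_{comparison}_{tag}"
                if key in results:
                    p = outdir / f"{key}.tsv"
                    results[key].table.to_csv(p, sep="\t", index=False)
                    manifest.add(p, "tsv", "stats")

        reports = results.get("classification", {})
        if reports:
            payload = {
                name: {
                    "feature_set": r.feature_set,
                    "accuracy": r.accuracy,
                    "auc": r.auc,
                    "cv_scheme": r.cv_scheme,
                }
                for name, r in reports.items()
            }
            p = outdir / "classification.json"
            p.write_text(json.dumps(payload, indent=2))
            manifest.add(p, "json", "classify")
            for name, r in reports.items():
                p = outdir / f"roc_{name}.tsv"
                pd.DataFrame(r.roc_points, columns=["fpr", "tpr"]).to_csv(
                    p, sep="\t", index=False
                )
                manifest.add(p, "tsv", "classify")

        if "treatment_correlations" in results:
            for tag, table in results["treatment_correlations"].items():
                p = outdir / f"treatment_correlations_{tag}.tsv"
                table.to_csv(p, sep="\t", index=False)
                manifest.add(p, "tsv", "correlate")

        p = outdir / "run_params.json"
        payload = dataclasses.asdict(config.params)
        if config.simulate is not None:
            payload["simulate"] = dataclasses.asdict(config.simulate)
        p.write_text(json.dumps(payload, indent=2))
        manifest.add(p, "json", "config")
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest.write(outdir / "manifest.json")
    return manifest
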