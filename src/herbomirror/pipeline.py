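"""End-to-end orchestration of the chemometric and transcriptomic runs.

``run_chemometrics`` goes from a synthetic chromatogram design through
correction, peak detection, alignment, ratio (or raw-height) features,
PCA and k-means grouping, scored against the planted group labels.
``run_transcriptomics`` goes from synthetic probe arrays through the RMA
stages, eigengene/entropy analysis, per-array and condition-mean PCA
grouping, and moderated-t contrasts with Bonferroni selection.
``concordance`` quantifies agreement between the chemical and
transcriptomic groupings — the headline claim that the treated
organism's transcriptome mirrors the chemical fingerprint.

Configuration is a single validated document; unknown keys are rejected
and every random stage derives from the explicit top-level seed. Runs
are deterministic given the config, and every artifact can be written as
TSV/JSON next to a manifest echoing all parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy.optimize import linear_sum_assignment

from . import io as hio
from .chemometrics import (
    ClusterResult,
    FeatureMatrix,
    PCAModel,
    adjusted_rand,
    cluster_scores,
    pca,
    ratio_transform,
)
from .chrom import (
    AlignedPeakMatrix,
    align_peaks,
    correct_baseline,
    detect_peaks,
    estimate_noise,
    smooth,
)
from .de import (
    ContrastSpec,
    ModeratedStats,
    bonferroni_select,
    design_from_conditions,
    ebayes_moderate,
    fit_lm,
)
from .eigengenes import EntropySummary, eigen_fractions, svd_decompose
from .exprproc import (
    ExpressionMatrix,
    background_correct,
    quantile_normalize,
    summarize_medianpolish,
)
from .synth import ExprDesign, GroundTruth, SyntheticDesign, generate_chromatograms, generate_probe_arrays

__all__ = [
    "ChromStageConfig",
    "ChemStageConfig",
    "EigenStageConfig",
    "DEStageConfig",
    "RunConfig",
    "ChemArtifacts",
    "ExprArtifacts",
    "ConcordanceReport",
    "run_chemometrics",
    "run_transcriptomics",
    "concordance",
    "run_all",
    "match_labels",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChromStageConfig(_Strict):
    smooth_window: int = 5
    baseline_fraction: float = 0.10
    snr_min: float = 3.0
    min_separation: float = 0.1
    rt_tol: float = 0.2


class ChemStageConfig(_Strict):
    feature_kind: str = "peak_ratios"  # or "peak_heights"
    log_ratios: bool = True
    k: int = 3
    n_pc: int = 2
    restarts: int = 100


class EigenStageConfig(_Strict):
    exclude: list[int] = [0]


class DEStageConfig(_Strict):
    alpha: float = 0.05
    exclude_arrays: list[str] = []


class RunConfig(_Strict):
    """One document configuring every stage; seeds are explicit."""

    seed: int = 0
    synth_chrom: dict = {}
    synth_expr: dict = {}
    dilution: dict[str, float] = {}
    chrom: ChromStageConfig = ChromStageConfig()
    chem: ChemStageConfig = ChemStageConfig()
    eigen: EigenStageConfig = EigenStageConfig()
    de: DEStageConfig = DEStageConfig()
    group_condition_map: dict[str, str] = {
        "group0": "usa",
        "group1": "china_europe",
        "group2": "india",
    }


@dataclass
class ChemArtifacts:
    peak_matrix: AlignedPeakMatrix
    features: FeatureMatrix
    pca_model: PCAModel
    clusters: ClusterResult
    truth: GroundTruth
    ari_truth: float
    manifest: dict


@dataclass
class ExprArtifacts:
    expression: ExpressionMatrix
    entropy: EntropySummary
    de_results: dict[str, tuple[ModeratedStats, list[str]]]
    array_clusters: ClusterResult
    mean_clusters: ClusterResult
    mean_conditions: list[str]
    truth: GroundTruth
    manifest: dict


@dataclass
class ConcordanceReport:
    ids: list[str]
    chem_labels: np.ndarray
    expr_labels: np.ndarray
    ari_chem_expr: float
    ari_chem_truth: float | None
    ari_expr_truth: float | None
    flagged: list[str]


def run_chemometrics(cfg: RunConfig, out_dir: str | Path | None = None) -> ChemArtifacts:
    """Simulate, correct, detect, align, featurize, project and group."""
    design = SyntheticDesign(seed=cfg.seed, **cfg.synth_chrom)
    chroms, truth = generate_chromatograms(design)
    if cfg.dilution:
        chroms = [
            c.replace_intensity(c.intensity * cfg.dilution.get(c.sample_id, 1.0))
            for c in chroms
        ]
    peaklists = {}
    for c in chroms:
        # noise must be estimated before smoothing: the difference-based
        # estimator assumes uncorrelated noise
        noise = estimate_noise(c.intensity)
        corrected = correct_baseline(
            smooth(c, cfg.chrom.smooth_window), cfg.chrom.baseline_fraction
        )
        peaklists[c.sample_id] = detect_peaks(
            corrected, cfg.chrom.snr_min, cfg.chrom.min_separation, noise=noise
        )
    matrix = align_peaks(peaklists, cfg.chrom.rt_tol, technique="synthetic")
    if cfg.chem.feature_kind == "peak_ratios":
        features = ratio_transform(matrix, log_scale=cfg.chem.log_ratios)
    elif cfg.chem.feature_kind == "peak_heights":
        features = FeatureMatrix(
            matrix.heights,
            [f"rt_{t:.4f}" for t in matrix.consensus_rt],
            list(matrix.sample_ids),
            kind="peak_heights",
        )
    else:
        raise ValueError(f"unknown feature kind {cfg.chem.feature_kind!r}")
    model = pca(features)
    clusters = cluster_scores(
        model, k=cfg.chem.k, n_pc=cfg.chem.n_pc, restarts=cfg.chem.restarts, seed=cfg.seed
    )
    ari = adjusted_rand(truth.sample_labels, clusters.labels)
    manifest = {
        "stage": "chemometrics",
        "seed": cfg.seed,
        "chrom": cfg.chrom.model_dump(),
        "chem": cfg.chem.model_dump(),
        "dilution": cfg.dilution,
        "n_samples": len(chroms),
        "n_consensus_peaks": matrix.n_peaks,
        "per_sample_peak_counts": {sid: len(pl) for sid, pl in peaklists.items()},
        "explained_fraction_pc12": [float(f) for f in model.explained_fraction[:2]],
        "ari_truth": ari,
    }
    art = ChemArtifacts(matrix, features, model, clusters, truth, ari, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_peak_matrix(matrix, out / "peak_matrix.tsv")
        hio.write_json(manifest, out / "chem_manifest.json")
        hio.write_json(
            {"labels": clusters.labels.tolist(), "truth": truth.sample_labels},
            out / "chem_labels.json",
        )
    return art


def _condition_means(e: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    if e.condition is None:
        raise ValueError("expression matrix lacks condition annotations")
    levels: list[str] = []
    for c in e.condition:
        if c not in levels:
            levels.append(c)
    cols = np.stack(
        [e.values[:, [i for i, c in enumerate(e.condition) if c == lvl]].mean(axis=1)
         for lvl in levels],
        axis=1,
    )
    return cols, levels


def _expression_pca_clusters(
    values_t: np.ndarray, ids: list[str], k: int, seed: int, restarts: int = 100
) -> tuple[PCAModel, ClusterResult]:
    fm = FeatureMatrix(
        values_t, [f"g{i}" for i in range(values_t.shape[1])], ids, kind="expression_means"
    )
    model = pca(fm)
    return model, cluster_scores(model, k=k, n_pc=2, restarts=restarts, seed=seed)


def run_transcriptomics(cfg: RunConfig, out_dir: str | Path | None = None) -> ExprArtifacts:
    """RMA preprocessing, eigengene summary, grouping and moderated contrasts."""
    design = ExprDesign(seed=cfg.seed, **cfg.synth_expr)
    probes, pmap, truth = generate_probe_arrays(design)
    expr = summarize_medianpolish(quantile_normalize(background_correct(probes)), pmap)

    decomp = svd_decompose(expr)
    entropy = eigen_fractions(decomp, exclude=tuple(cfg.eigen.exclude))

    n_cond = len(design.arrays_per_condition)
    _, array_clusters = _expression_pca_clusters(
        expr.values.T, list(expr.array_ids), k=n_cond, seed=cfg.seed
    )
    means, levels = _condition_means(expr)
    _, mean_clusters = _expression_pca_clusters(means.T, levels, k=n_cond, seed=cfg.seed)

    # moderated contrasts on the configured arrays
    keep = [i for i, a in enumerate(expr.array_ids) if a not in set(cfg.de.exclude_arrays)]
    sub = ExpressionMatrix(
        expr.values[:, keep],
        expr.probeset_ids,
        [expr.array_ids[i] for i in keep],
        [expr.condition[i] for i in keep] if expr.condition else None,
    )
    dm = design_from_conditions(sub.condition, baseline=design.control_condition)
    treated = [n for n in dm.names if n != "(intercept)"]
    contrasts = {"control_vs_all": np.array([0.0] + [1.0 / len(treated)] * len(treated))}
    for j, cond in enumerate(treated):
        w = np.zeros(len(dm.names))
        w[1 + j] = 1.0
        contrasts[f"control_vs_{cond}"] = w
    de_results: dict[str, tuple[ModeratedStats, list[str]]] = {}
    for name, w in contrasts.items():
        fit = fit_lm(sub, dm, ContrastSpec(name, w))
        stats = ebayes_moderate(fit)
        selected, _ = bonferroni_select(stats, alpha=cfg.de.alpha)
        de_results[name] = (stats, selected)

    manifest = {
        "stage": "transcriptomics",
        "seed": cfg.seed,
        "eigen": cfg.eigen.model_dump(),
        "de": cfg.de.model_dump(),
        "n_probesets": len(expr.probeset_ids),
        "n_arrays": len(expr.array_ids),
        "entropy_d": entropy.entropy_d,
        "selected_counts": {k: len(v[1]) for k, v in de_results.items()},
        "bonferroni_m": len(expr.probeset_ids),
    }
    art = ExprArtifacts(
        expr, entropy, de_results, array_clusters, mean_clusters, levels, truth, manifest
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_expression(expr, out / "expression.tsv")
        hio.write_json(manifest, out / "expr_manifest.json")
    return art


def match_labels(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to best match ``reference`` (Hungarian matching)."""
    reference = np.asarray(reference)
    labels = np.asarray(labels)
    ref_levels = np.unique(reference)
    lab_levels = np.unique(labels)
    cont = np.zeros((lab_levels.size, ref_levels.size))
    for i, a in enumerate(lab_levels):
        for j, b in enumerate(ref_levels):
            cont[i, j] = np.sum((labels == a) & (reference == b))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {lab_levels[r]: ref_levels[c] for r, c in zip(rows, cols)}
    return np.array([mapping.get(l, l) for l in labels])


def concordance(
    chem_labels,
    expr_labels,
    truth_labels=None,
    ids: list[str] | None = None,
) -> ConcordanceReport:
    """Agreement between chemical and transcriptomic groupings.

    Labels are compared by ARI (label-name independent); items whose
    transcriptomic assignment disagrees with the chemical one after
    optimal label matching are flagged.
    """
    chem = np.asarray(chem_labels)
    expr = np.asarray(expr_labels)
    if chem.size != expr.size:
        raise ValueError("label vectors must align on the same items")
    if ids is None:
        ids = [str(i) for i in range(chem.size)]
    matched = match_labels(chem, expr)
    flagged = [ids[i] for i in range(chem.size) if matched[i] != chem[i]]
    return ConcordanceReport(
        ids=list(ids),
        chem_labels=chem,
        expr_labels=expr,
        ari_chem_expr=adjusted_rand(chem, expr),
        ari_chem_truth=None if truth_labels is None else adjusted_rand(chem, truth_labels),
        ari_expr_truth=None if truth_labels is None else adjusted_rand(expr, truth_labels),
        flagged=flagged,
    )


def run_all(cfg: RunConfig, out_dir: str | Path | None = None):
    """Both runs plus cross-fingerprint concordance over the extract samples.

    The transcriptomic grouping of each treated condition (condition-mean
    clusters, control excluded) is propagated to the chemometric samples
    of the matching group via ``cfg.group_condition_map`` so both label
    vectors align on the extract samples.
    """
    chem = run_chemometrics(cfg, out_dir=out_dir)
    expr = run_transcriptomics(cfg, out_dir=out_dir)
    design = SyntheticDesign(seed=cfg.seed, **cfg.synth_chrom)
    cond_label = dict(zip(expr.mean_conditions, expr.mean_clusters.labels))
    expr_per_sample = []
    for g in chem.truth.sample_labels:
        gname = design.group_names[g]
        cond = cfg.group_condition_map.get(gname)
        if cond is None or cond not in cond_label:
            raise ValueError(f"no condition mapped for chem group {gname!r}")
        expr_per_sample.append(cond_label[cond])
    ids = [f"S{i + 1:02d}" for i in range(len(chem.truth.sample_labels))]
    report = concordance(
        chem.clusters.labels, expr_per_sample, chem.truth.sample_labels, ids
    )
    if out_dir is not None:
        hio.write_json(
            {
                "ari_chem_expr": report.ari_chem_expr,
                "ari_chem_truth": report.ari_chem_truth,
                "ari_expr_truth": report.ari_expr_truth,
                "flagged": report.flagged,
            },
            Path(out_dir) / "concordance.json",
        )
    return chem, expr, report
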