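"""End-to-end experiment: preprocess -> cluster -> extract -> filter ->
select -> fit -> evaluate, for every phase x region plus the clinical model.

Center 1 is the training cohort. The "validation" split is the pooled
out-of-fold prediction set of the seeded 5-fold CV on center 1 (no separate
internal hold-out); the final model is refit on all of center 1
(oversampled) and its Youden threshold is carried unchanged to validation
and the center-2 external test. Eight radiomics models (2 phases x
{subregion 1..3, whole tumor}) plus one clinical-covariate model yield a
nine-row report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureExtractor, jitter_mask, redundancy_filter, stability_filter
from .habitat import cluster_subregions
from .model_eval import EvaluationReport, evaluate, fit_lr, oversample, shap_linear
from .preprocess import resample_isotropic, rescale_unit, znormalize
from .rfa_select import _as_labels, cv_auc, make_folds, rfa
from .synthetic_cohort import CohortManifest, PhantomCase
from .volume import ImageVolume, TumorMask, load_mask, load_nifti

log = logging.getLogger("gisthabitat")

PHASES = ("unenhanced", "venous")
REGIONS = ("sub1", "sub2", "sub3", "whole")
CLINICAL_CONTINUOUS = ("age", "bmi", "cea", "afp", "ca199", "ca125", "size_cm")


@dataclass
class ExperimentConfig:
    seed: int = 0
    folds: int = 5
    n_boot: int = 2000
    cluster_count: int = 3
    tol: float = 0.001
    families: tuple[str, ...] = ("firstorder", "shape", "glcm", "gldm", "glrlm", "glszm")
    filters: tuple[str, ...] = ("wavelet", "log", "lbp")
    phases: tuple[str, ...] = PHASES
    regions: tuple[str, ...] = REGIONS
    stability: bool = True
    stability_threshold: float = 0.75
    rho_threshold: float = 0.9
    include_clinical: bool = True
    max_features: int | None = None

    @classmethod
    def reduced(cls, **kw) -> "ExperimentConfig":
        """First-order + shape bank, no filtered images: the fast profile
        for cohort-scale runs."""
        base = dict(families=("firstorder", "shape"), filters=(), stability=False)
        base.update(kw)
        return cls(**base)


def preprocess_case(case: PhantomCase, phases=PHASES):
    """Load or regenerate a case and return per-phase (image, mask, rescaled)."""
    if case.path_unenhanced:
        vols = {
            "unenhanced": load_nifti(case.path_unenhanced),
            "venous": load_nifti(case.path_venous),
        }
        mask = load_mask(case.path_mask)
    else:
        unenh, venous, mask, _ = case.generate(tuple(phases))
        vols = {"unenhanced": unenh, "venous": venous}
    out = {}
    for phase in phases:
        img = znormalize(vols[phase])
        img_rs, mask_rs = resample_isotropic(img, mask)
        out[phase] = (img_rs, mask_rs, rescale_unit(img_rs, mask_rs))
    return out


def case_region_masks(image_rescaled: ImageVolume, mask: TumorMask, n: int, regions):
    """Region masks for one phase: habitat subregions plus the whole tumor."""
    label_map = cluster_subregions(image_rescaled, mask, n)
    out = {}
    for region in regions:
        if region == "whole":
            out[region] = np.asarray(mask.voxels, bool)
        else:
            out[region] = label_map.region_mask(int(region[3:]))
    return out


def extract_cohort_tables(
    manifest: CohortManifest,
    config: ExperimentConfig,
    jitter_seed: int | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Feature tables for every (phase, region); rows indexed by case_id.

    With ``jitter_seed`` set, extraction runs on morphologically jittered
    masks instead (used to build the perturbed tables for the stability
    filter).
    """
    extractor = FeatureExtractor(families=config.families, filters=config.filters)
    rows: dict[tuple[str, str], dict] = {
        (p, r): {} for p in config.phases for r in config.regions
    }
    for k, case in enumerate(manifest.cases):
        per_phase = preprocess_case(case, config.phases)
        for phase in config.phases:
            img, mask, rescaled = per_phase[phase]
            if jitter_seed is not None:
                jit = jitter_mask(mask.voxels, seed=jitter_seed + 7919 * k)
                mask = TumorMask(jit, mask.spacing_mm, mask.origin)
                rescaled = rescale_unit(img, mask)
            regions = case_region_masks(rescaled, mask, config.cluster_count, config.regions)
            for region, reg_mask in regions.items():
                rows[(phase, region)][case.case_id] = extractor.extract(img, reg_mask)
    tables = {}
    for key, data in rows.items():
        df = pd.DataFrame.from_dict(data, orient="index")
        df.attrs["phase"], df.attrs["region"] = key
        tables[key] = df
    return tables


def clinical_matrix(manifest: CohortManifest) -> pd.DataFrame:
    """Clinical covariates as a numeric design matrix (location one-hot)."""
    frame = manifest.to_frame().set_index("case_id")
    x = frame[list(CLINICAL_CONTINUOUS)].astype(float).copy()
    x["sex_male"] = (frame["sex"] == "M").astype(float)
    for loc in ("cardia", "fundus", "body", "antrum"):
        x[f"location_{loc}"] = (frame["location"] == loc).astype(float)
    return x


@dataclass
class ModelResult:
    name: str
    selected: list[str]
    reports: dict[str, EvaluationReport]   # train / validation / test
    model: object = None
    error: str = ""
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None


@dataclass
class ExperimentBundle:
    table: pd.DataFrame
    results: dict[str, ModelResult]
    shap_model: str = ""
    shap_ranking: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir, plots: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "model_performance.csv", index=False)
        meta = {
            "shap_model": self.shap_model,
            "shap_ranking": self.shap_ranking,
            "selected": {k: v.selected for k, v in self.results.items() if not v.error},
            "errors": self.errors,
        }
        (out / "experiment.json").write_text(json.dumps(meta, indent=2))
        if plots:
            _write_plots(self, out)


def fit_and_eval(
    table: pd.DataFrame,
    labels: np.ndarray,
    is_train: np.ndarray,
    seed: int,
    folds: int = 5,
    n_boot: int = 2000,
    tol: float = 0.001,
    rho_threshold: float = 0.9,
    stability_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    stability_threshold: float = 0.75,
    max_features: int | None = None,
    select: bool = True,
) -> ModelResult:
    """Filter + select + fit on the training rows, evaluate all three splits.

    Cases with missing features (undersized subregions) are excluded from
    this model and logged.
    """
    y = _as_labels(labels)
    keep = ~table.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%d case(s) excluded for missing features", n_dropped)
    tab, y, tr = table.loc[keep], y[keep], np.asarray(is_train)[keep]

    train_tab, train_y = tab.loc[tr], y[tr]
    feats = list(tab.columns)
    if stability_tables is not None:
        ref, pert = stability_tables
        ref, pert = ref.loc[keep].loc[tr], pert.loc[keep].loc[tr]
        ok = (~ref.isna().any(axis=1) & ~pert.isna().any(axis=1)).to_numpy()
        feats = stability_filter(ref.loc[ok, feats], pert.loc[ok, feats], stability_threshold)
    feats = redundancy_filter(train_tab[feats], rho_threshold)
    if select:
        selection = rfa(train_tab[feats], train_y, folds=folds, tol=tol, seed=seed,
                        max_features=max_features)
        selected = selection.selected or feats[:1]
    else:
        selected = feats

    # final model: oversampled full training cohort, Youden threshold
    os_idx = oversample(np.arange(len(train_y)), train_y, seed=seed)
    model = fit_lr(train_tab[selected], train_y, sample_indices=os_idx)

    # pooled out-of-fold predictions on the training cohort = validation
    oof = np.empty(len(train_y))
    for f, (tr_idx, te_idx) in enumerate(make_folds(train_y, folds, seed)):
        os_f = oversample(tr_idx, train_y, seed=seed * 1000 + f)
        m = fit_lr(train_tab[selected].iloc[os_f], train_y[os_f])
        oof[te_idx] = m.predict_proba(train_tab[selected].iloc[te_idx])

    reports = {
        "train": evaluate(model, train_tab[selected], train_y, n_boot=n_boot, seed=seed),
        "validation": evaluate(oof, labels=train_y, n_boot=n_boot, seed=seed,
                               threshold=model.threshold),
        "test": evaluate(model, tab.loc[~tr, selected], y[~tr], n_boot=n_boot, seed=seed),
    }
    return ModelResult(
        "", selected, reports, model,
        test_scores=model.predict_proba(tab.loc[~tr, selected]),
        test_labels=y[~tr],
    )


def run_experiment(manifest: CohortManifest, config: ExperimentConfig | None = None,
                   out_dir=None, plots: bool = False) -> ExperimentBundle:
    """Fit and evaluate the eight radiomics models plus the clinical model."""
    config = config or ExperimentConfig()
    labels = manifest.labels
    is_train = np.array([c.center == 1 for c in manifest.cases])

    tables = extract_cohort_tables(manifest, config)
    perturbed = (
        extract_cohort_tables(manifest, config, jitter_seed=config.seed + 1)
        if config.stability
        else None
    )

    results: dict[str, ModelResult] = {}
    errors: dict[str, str] = {}
    model_keys = [("clinical", None)] if config.include_clinical else []
    model_keys += [(f"{p}_{r}", (p, r)) for p in config.phases for r in config.regions]

    for name, key in model_keys:
        try:
            if key is None:
                res = fit_and_eval(
                    clinical_matrix(manifest), labels, is_train, seed=config.seed,
                    folds=config.folds, n_boot=config.n_boot, tol=config.tol,
                    rho_threshold=config.rho_threshold, select=False,
                )
            else:
                res = fit_and_eval(
                    tables[key], labels, is_train, seed=config.seed,
                    folds=config.folds, n_boot=config.n_boot, tol=config.tol,
                    rho_threshold=config.rho_threshold,
                    stability_tables=(tables[key], perturbed[key]) if perturbed else None,
                    stability_threshold=config.stability_threshold,
                    max_features=config.max_features,
                )
            res.name = name
            results[name] = res
        except Exception as exc:
            log.warning("model %s failed: %s", name, exc)
            errors[name] = f"{type(exc).__name__}: {exc}"
            results[name] = ModelResult(name, [], {}, error=str(exc))

    rows = []
    for name, res in results.items():
        row = {"model": name}
        for split in ("train", "validation", "test"):
            if res.error or split not in res.reports:
                row.update({f"{split}_{c}": np.nan for c in
                            ("AUC", "CI_low", "CI_high", "ACC", "SEN", "SPE", "TPR", "FPR")})
            else:
                row.update({f"{split}_{k}": round(v, 6) if np.isfinite(v) else np.nan
                            for k, v in res.reports[split].row().items()})
        rows.append(row)
    table = pd.DataFrame(rows)

    # SHAP on the best unenhanced subregion model (by validation AUC)
    shap_model, shap_ranking = "", []
    candidates = [
        (res.reports["validation"].auc, name)
        for name, res in results.items()
        if name.startswith("unenhanced_sub") and not res.error and res.reports
    ]
    if candidates:
        _, shap_model = max(candidates)
        res = results[shap_model]
        phase_region = ("unenhanced", shap_model.split("_")[1])
        tab = tables[phase_region]
        keep = ~tab.isna().any(axis=1).to_numpy()
        train_rows = tab.loc[keep & is_train, res.selected]
        shap_ranking = shap_linear(res.model, train_rows).ranking

    bundle = ExperimentBundle(table, results, shap_model, shap_ranking, errors)
    if out_dir is not None:
        bundle.write(out_dir, plots=plots)
    return bundle


def planted_signal_run(seed: int, n_boot: int = 200) -> dict:
    """One replicate of the planted-signal recovery check.

    Generates a default 368-case cohort, fits the unenhanced subregion-3
    and whole-tumor models with the reduced (first-order + shape) bank, and
    reports their external-test AUCs plus the subregion-3 model's global
    attribution ranking. The venous phase (attenuated signal) is not needed
    for this comparison and is skipped for speed.
    """
    from .synthetic_cohort import build_cohort

    config = ExperimentConfig.reduced(
        seed=seed, n_boot=n_boot, phases=("unenhanced",), regions=("sub3", "whole"),
    )
    manifest = build_cohort(seed=seed)
    labels = manifest.labels
    is_train = np.array([c.center == 1 for c in manifest.cases])
    tables = extract_cohort_tables(manifest, config)

    out: dict = {"seed": seed}
    for region in ("sub3", "whole"):
        res = fit_and_eval(
            tables[("unenhanced", region)], labels, is_train,
            seed=config.seed, folds=config.folds, n_boot=config.n_boot,
            tol=config.tol, rho_threshold=config.rho_threshold,
        )
        out[f"auc_{region}"] = res.reports["test"].auc
        if region == "sub3":
            tab = tables[("unenhanced", "sub3")]
            keep = ~tab.isna().any(axis=1).to_numpy()
            ranking = shap_linear(
                res.model, tab.loc[keep & is_train, res.selected]
            ).ranking
            out["shap_ranking"] = ranking
            out["skewness_in_top3"] = any("Skewness" in f for f in ranking[:3])
    out["sub3_ge_whole"] = out["auc_sub3"] >= out["auc_whole"]
    return out


def _write_plots(bundle: ExperimentBundle, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for curve, fname, xlab, ylab in (
        ("roc", "roc_curves.png", "1 - specificity", "sensitivity"),
        ("pr", "pr_curves.png", "recall", "precision"),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, res in bundle.results.items():
            if res.error or "test" not in res.reports:
                continue
            x, y = getattr(res.reports["test"], curve)
            ax.plot(x, y, label=f"{name} (AUC {res.reports['test'].auc:.3f})", lw=1)
        if curve == "roc":
            ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        ax.legend(fontsize=5)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=150)
        plt.close(fig)

    # decision curves on the external test split
    from .model_eval import decision_curve

    fig, ax = plt.subplots(figsize=(5, 4))
    drew_refs = False
    for name, res in bundle.results.items():
        if res.error or res.test_scores is None:
            continue
        dca = decision_curve(res.test_scores, labels=res.test_labels)
        if not drew_refs:
            ax.plot(dca.thresholds, dca.net_benefit_all, "k--", lw=0.7, label="treat all")
            ax.plot(dca.thresholds, dca.net_benefit_none, "k-", lw=0.7, label="treat none")
            drew_refs = True
        ax.plot(dca.thresholds, dca.net_benefit_model, lw=1, label=name)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(-0.05, None)
    ax.legend(fontsize=5)
    fig.tight_layout()
    fig.savefig(out / "dca_curves.png", dpi=150)
    plt.close(fig)
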