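"""End-to-end pipeline: generate -> split -> train -> fuse -> simulate.

Mirrors the flow of the underlying study: PROMs and wound images are
modelled separately on a patient-grouped, outcome-stratified 4:1 split,
combined by late fusion, and the fused per-response risks drive the
implementation-strategy simulation and its threshold sensitivity
analysis. Every seed is explicit in the run configuration; reruns with
the same configuration reproduce identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import auc, benchmark_report, grouped_stratified_split
from .fusion import fit_fusion_head, fuse_responses
from .image import WoundCnnClassifier
from .pathway import (
    StaffingModel,
    Strategy,
    evaluate_pathway,
    pathway_report,
    threshold_sweep,
)
from .preprocessing import PromEncoder
from .synth import Cohort, SyntheticConfig, generate_cohort, read_cohort
from .tabular import TabularRiskClassifier


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (all seeds explicit)."""

    out_dir: str = "runs/demo"
    data_dir: str | None = None  # read an existing cohort instead of generating
    n_patients: int = 150
    image_size: int = 64
    data_seed: int = 1
    split_seed: int = 2
    model_seed: int = 3
    use_images: bool = True
    outcome: str = "ssi48"
    fusion_kind: str = "logistic_stack"
    threshold: float = 0.2
    sweep_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 21), 3))
    staffing: dict = field(default_factory=dict)
    synthetic_overrides: dict = field(default_factory=dict)
    mlp_overrides: dict = field(default_factory=dict)
    cnn_overrides: dict = field(default_factory=dict)
    overwrite: bool = False
    make_plot: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweep_grid"] = [float(x) for x in self.sweep_grid]
        return d


def _load_or_generate(config: RunConfig) -> Cohort:
    if config.data_dir is not None:
        return read_cohort(config.data_dir)
    synth_cfg = SyntheticConfig(
        n_patients=config.n_patients,
        image_size=config.image_size,
        seed=config.data_seed,
        **config.synthetic_overrides,
    )
    return generate_cohort(synth_cfg)


def _render_pixels(cohort: Cohort, image_ids) -> np.ndarray:
    return np.stack([cohort.render_image(i).pixels for i in image_ids])


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline; returns paths and key results.

    Writes under ``config.out_dir``: the cohort files, the prediction
    table, a Table-3-style pathway summary, the raw per-strategy rows,
    the threshold-sweep table (and plot), an AUC benchmark table, the
    trained model bundles and a config echo.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    cohort = _load_or_generate(config)
    responses = cohort.responses
    y_all = responses["ssi48"].to_numpy()

    plan = grouped_stratified_split(responses, test_fraction=0.2, seed=config.split_seed)
    in_test = responses["response_id"].isin(plan.test_ids).to_numpy()
    train, test = responses[~in_test], responses[in_test]

    encoder = PromEncoder().fit(train)
    X_train, X_test, X_all = encoder.transform(train), encoder.transform(test), encoder.transform(responses)
    y_train, y_test = train["ssi48"].to_numpy(), test["ssi48"].to_numpy()

    mlp = TabularRiskClassifier(kind="mlp", random_state=config.model_seed, **config.mlp_overrides).fit(
        X_train, y_train
    )
    logistic = TabularRiskClassifier(kind="logistic").fit(X_train, y_train)
    p_proms_all = mlp.predict_proba(X_all)[:, 1]

    records = [
        {"model": "mlp_proms", "dataset": "test", "outcome": "ssi48",
         "scores": mlp.predict_proba(X_test)[:, 1], "labels": y_test},
        {"model": "logistic_proms", "dataset": "test", "outcome": "ssi48",
         "scores": logistic.predict_proba(X_test)[:, 1], "labels": y_test},
    ]

    p_images_by_response: dict[str, list[float]] = {}
    cnn = None
    head = None
    if config.use_images and len(cohort.images):
        images = cohort.images.merge(
            responses[["response_id", "ssi48"]], on="response_id", how="left"
        )
        img_train = images[images["response_id"].isin(plan.train_ids)]
        img_test = images[images["response_id"].isin(plan.test_ids)]
        X_img_train = _render_pixels(cohort, img_train["image_id"])
        cnn = WoundCnnClassifier(random_state=config.model_seed, **config.cnn_overrides).fit(
            X_img_train, img_train["ssi48"].to_numpy()
        )
        p_img_train = cnn.predict_proba(X_img_train)[:, 1]
        if len(img_test):
            X_img_test = _render_pixels(cohort, img_test["image_id"])
            p_img_test = cnn.predict_proba(X_img_test)[:, 1]
            records.append(
                {"model": "cnn_images", "dataset": "test", "outcome": "ssi48",
                 "scores": p_img_test, "labels": img_test["ssi48"].to_numpy()}
            )
        else:
            p_img_test = np.empty(0)

        # fusion head trained on per-image pairs from the training split
        rid_to_row = {rid: i for i, rid in enumerate(responses["response_id"])}
        pt_train_pairs = p_proms_all[[rid_to_row[r] for r in img_train["response_id"]]]
        head = fit_fusion_head(
            pt_train_pairs, p_img_train, img_train["ssi48"].to_numpy(),
            kind=config.fusion_kind, seed=config.model_seed,
        )
        for rid, p in zip(img_train["response_id"], p_img_train):
            p_images_by_response.setdefault(rid, []).append(float(p))
        for rid, p in zip(img_test["response_id"], p_img_test):
            p_images_by_response.setdefault(rid, []).append(float(p))
    else:
        from .fusion import AverageFusion

        head = AverageFusion()

    predictions = fuse_responses(
        responses["response_id"], p_proms_all, p_images_by_response, head
    )
    predictions.to_csv(out / "predictions.csv", index=False)
    p_fused = predictions["p_fused"].to_numpy()

    fused_test = p_fused[in_test]
    if np.unique(y_test).size == 2:
        records.append(
            {"model": "multimodal_fused", "dataset": "test", "outcome": "ssi48",
             "scores": fused_test, "labels": y_test}
        )
    benchmarks = benchmark_report(records)
    benchmarks.to_csv(out / "benchmarks.csv", index=False)

    staffing_model = StaffingModel(
        study_patients=config.staffing.get("study_patients", cohort.config.n_patients),
        **{k: v for k, v in config.staffing.items() if k != "study_patients"},
    )
    baseline = len(responses)
    outcomes = [
        evaluate_pathway(responses, p_fused, Strategy("full_clinical"), staffing_model, baseline),
        evaluate_pathway(responses, p_fused, Strategy("hybrid", config.threshold), staffing_model, baseline),
        evaluate_pathway(responses, p_fused, Strategy("full_auto", config.threshold), staffing_model, baseline),
    ]
    pd.DataFrame([o.to_row() for o in outcomes]).to_csv(out / "pathway_raw.csv", index=False)
    pathway_report(outcomes).to_csv(out / "pathway_summary.csv", index=False)

    sweeps = {}
    for kind in ("hybrid", "full_auto"):
        sw = threshold_sweep(responses, p_fused, kind, config.sweep_grid, staffing_model, baseline)
        sw.insert(0, "strategy_kind", kind)
        sweeps[kind] = sw
    sweep_table = pd.concat(sweeps.values(), ignore_index=True)
    sweep_table.to_csv(out / "threshold_sweep.csv", index=False)
    if config.make_plot:
        _plot_sweep(sweep_table, out / "threshold_sweep.png")

    # model bundles
    mlp.save(out / "model_mlp.npz")
    logistic.save(out / "model_logistic.npz")
    if cnn is not None:
        cnn.save(out / "model_cnn.npz")

    return {
        "out_dir": out,
        "cohort": cohort,
        "split": plan,
        "predictions": predictions,
        "benchmarks": benchmarks,
        "outcomes": outcomes,
        "sweep": sweep_table,
        "models": {"mlp": mlp, "logistic": logistic, "cnn": cnn, "fusion_head": head},
    }


def _plot_sweep(sweep_table: pd.DataFrame, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for kind, df in sweep_table.groupby("strategy_kind"):
        axes[0].plot(df["threshold"], 100 * df["failure_rate"].astype(float), label=kind)
        axes[1].plot(df["threshold"], df["fte_per_caseload"], label=kind)
    axes[0].set_xlabel("rule-out threshold")
    axes[0].set_ylabel("failure rate, % (1 - NPV)")
    axes[1].set_xlabel("rule-out threshold")
    axes[1].set_ylabel("annual FTE / 1000-patient caseload")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
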