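"""End-to-end experiment driver: simulate -> preprocess -> XRT + CNN -> evaluate.

Ties every stage together under a single, fully seeded configuration, producing
the calibration models, the trained CNN, the metric reports for both predictors
on the identical calibration/test split, and the PCA comparison.  All artifacts
can be written to a run directory (TIFFs, CSVs, JSON models, a text log of every
seed and derived quantity).
"""

from __future__ import annotations

import configparser
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from . import evaluation as ev
from . import phantom as ph
from . import pipeline as pl
from . import xrt as xrt_mod

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: simulator scale, pipeline tunables, CNN recipe, split.

    The default is a desk-scale run (reduced detector, 100 projections = 400
    pods, width-reduced CNN) that exercises the full method on one CPU; the
    full-scale acquisition geometry remains available via ``full_scale=True``.
    Every stochastic stage derives its seed from ``seed``.
    """

    seed: int = 0
    n_projections: int = 100
    full_scale: bool = False
    noise: bool = True
    label_threshold_relative: float | None = 0.75
    label_threshold: float = 5250.0
    i0_region_shape: tuple[int, int] = (8, 8)
    otsu_offset: float = 50.0
    erosion_size: int = 5
    dilation_size: int = 9
    test_fraction: float = 0.10
    validation_fraction: float = 0.20
    cnn_epochs: int = 30
    cnn_enabled: bool = True
    out_dir: str | None = None

    def scan_config(self) -> ph.ScanConfig:
        if self.full_scale:
            return ph.ScanConfig(rng_seed=self.seed, noise=self.noise)
        return ph.desk_config(seed=self.seed, noise=self.noise)

    def pipeline_params(self) -> pl.PipelineParams:
        return pl.PipelineParams(
            label_threshold=self.label_threshold,
            label_threshold_relative=self.label_threshold_relative,
            i0_region_shape=self.i0_region_shape,
        )

    def cnn_spec(self) -> cnn_mod.CNNSpec:
        if self.full_scale:
            return cnn_mod.default_spec(rng_seed=self.seed, epochs=self.cnn_epochs)
        return cnn_mod.desk_spec(seed=self.seed, epochs=self.cnn_epochs)

    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["experiment"] = {k: repr(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        cp = configparser.ConfigParser()
        cp.read(path)
        import ast

        kwargs = {k: ast.literal_eval(v) for k, v in cp["experiment"].items()}
        return cls(**kwargs)


@dataclass
class ExperimentResult:
    manifest: pd.DataFrame
    split: ev.SplitPlan
    predictions: pd.DataFrame  # per pod: truth, xrt and cnn predictions, split
    reports: list[ev.MetricsReport]
    pca: dict[str, tuple[np.ndarray, pd.DataFrame]]  # trait -> (evr, loadings)
    calibrations: dict[str, xrt_mod.CalibrationModel]
    cnn_model: cnn_mod.TrainedModel | None
    provenance: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def report_frame(self) -> pd.DataFrame:
        return ev.reports_to_frame(self.reports)


def _xrt_stage(processed, config: ExperimentConfig):
    integrals = {}
    for pod in processed:
        mask = xrt_mod.segment_kernel(
            pod.filled,
            offset=config.otsu_offset,
            erosion_size=config.erosion_size,
            dilation_size=config.dilation_size,
        )
        integrals[pod.pod_id] = (
            xrt_mod.integrate_masked(pod.vb, mask, invert=False),
            xrt_mod.integrate_masked(pod.vb, mask, invert=True),
        )
    return integrals


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the complete synthetic study; see module docstring.

    Raises RuntimeError naming the stage and pod context on failure.
    """
    log: list[str] = [f"seed={config.seed}", f"n_projections={config.n_projections}"]
    t0 = time.time()

    scan_cfg = config.scan_config()
    layout = ph.HolderLayout.from_detector(scan_cfg.detector_shape)
    try:
        projections, blanks, records = ph.simulate_batch(
            config.n_projections, scan_cfg, layout
        )
    except Exception as exc:  # pragma: no cover - stage context
        raise RuntimeError(f"stage=simulate: {exc}") from exc
    manifest = ph.records_to_frame(records)
    log.append(f"simulated {len(projections)} projections, {len(records)} pods")

    try:
        processed, provenance = pl.preprocess(
            projections, blanks, layout, config.pipeline_params()
        )
    except Exception as exc:
        raise RuntimeError(f"stage=preprocess: {exc}") from exc
    log.append(f"preprocessed {len(processed)} pods")

    pod_ids = [p.pod_id for p in processed]
    split = ev.split_dataset(
        pod_ids,
        test_fraction=config.test_fraction,
        validation_fraction=config.validation_fraction,
        seed=config.seed,
    )
    truth = manifest.set_index("pod_id")
    y = np.stack(
        [
            truth.loc[pod_ids, "kernel_weight_g"].to_numpy(),
            truth.loc[pod_ids, "shell_weight_g"].to_numpy(),
        ],
        axis=1,
    )
    idx = {p: i for i, p in enumerate(pod_ids)}
    cal_idx = np.array([idx[p] for p in split.calibration])
    test_idx = np.array([idx[p] for p in split.test])
    train_idx = np.array([idx[p] for p in split.train])
    val_idx = np.array([idx[p] for p in split.validation])

    # ---------------- XRT pathway
    try:
        integrals = _xrt_stage(processed, config)
    except Exception as exc:
        raise RuntimeError(f"stage=xrt-segmentation: {exc}") from exc
    k_int = np.array([integrals[p][0] for p in pod_ids])
    s_int = np.array([integrals[p][1] for p in pod_ids])
    calibrations = {
        "kernel": xrt_mod.fit_calibration(k_int[cal_idx], y[cal_idx, 0], "kernel"),
        "shell": xrt_mod.fit_calibration(s_int[cal_idx], y[cal_idx, 1], "shell"),
    }
    xrt_pred = np.stack(
        [
            calibrations["kernel"].predict(k_int),
            calibrations["shell"].predict(s_int),
        ],
        axis=1,
    )
    log.append(
        "xrt calibration: kernel slope=%.4g intercept=%.4g; shell slope=%.4g intercept=%.4g"
        % (
            calibrations["kernel"].slope,
            calibrations["kernel"].intercept,
            calibrations["shell"].slope,
            calibrations["shell"].intercept,
        )
    )

    # ---------------- CNN pathway
    cnn_model = None
    cnn_pred = np.full_like(xrt_pred, np.nan)
    if config.cnn_enabled:
        spec = config.cnn_spec()
        try:
            x_all = cnn_mod.images_to_input([p.vb.pixels for p in processed], spec.input_size)
            weights = cnn_mod.compute_sample_weights(
                y[train_idx], n_bins=min(20, len(train_idx))
            )
            net = cnn_mod.build_network(spec)
            cnn_model = cnn_mod.train(
                net,
                x_all[train_idx],
                y[train_idx],
                sample_weights=weights,
                val_images=x_all[val_idx],
                val_targets=y[val_idx],
            )
            cnn_pred = cnn_mod.predict_weights_cnn(net, x_all)
        except Exception as exc:
            raise RuntimeError(f"stage=cnn: {exc}") from exc
        log.append(f"cnn trained {spec.epochs} epochs, input {spec.input_size}")

    # ---------------- evaluation
    predictions = pd.DataFrame(
        {
            "pod_id": pod_ids,
            "kernel_weight_g": y[:, 0],
            "shell_weight_g": y[:, 1],
            "xrt_kernel_g": xrt_pred[:, 0],
            "xrt_shell_g": xrt_pred[:, 1],
            "cnn_kernel_g": cnn_pred[:, 0],
            "cnn_shell_g": cnn_pred[:, 1],
            "kernel_integral": k_int,
            "shell_integral": s_int,
        }
    )
    predictions["split"] = [split.assignment(p)[0] for p in pod_ids]

    reports = []
    pred_cols = {"XRT": ("xrt_kernel_g", "xrt_shell_g")}
    if config.cnn_enabled:
        pred_cols["CNN"] = ("cnn_kernel_g", "cnn_shell_g")
    for predictor, (ck, cs) in pred_cols.items():
        for trait, pcol, tcol in (
            ("kernel", ck, "kernel_weight_g"),
            ("shell", cs, "shell_weight_g"),
        ):
            for split_name, sel in (("calibration", cal_idx), ("test", test_idx)):
                reports.append(
                    ev.compute_metrics(
                        predictions[pcol].to_numpy()[sel],
                        predictions[tcol].to_numpy()[sel],
                        predictor=predictor,
                        trait=trait,
                        split=split_name,
                    )
                )

    pca = {}
    if config.cnn_enabled:
        for trait, cols in (
            ("kernel", ["kernel_weight_g", "xrt_kernel_g", "cnn_kernel_g"]),
            ("shell", ["shell_weight_g", "xrt_shell_g", "cnn_shell_g"]),
        ):
            tab = predictions.iloc[test_idx][cols]
            tab.columns = [f"Obs_{trait[0].upper()}W", f"XRT_{trait[0].upper()}W", f"CNN_{trait[0].upper()}W"]
            evr, loadings, _ = ev.pca_compare(tab)
            pca[trait] = (evr, loadings)
            log.append(f"pca {trait}: PC1 {evr[0] * 100:.2f}%")

    log.append(f"total {time.time() - t0:.1f}s")
    result = ExperimentResult(
        manifest=manifest,
        split=split,
        predictions=predictions,
        reports=reports,
        pca=pca,
        calibrations=calibrations,
        cnn_model=cnn_model,
        provenance=provenance,
        log=log,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: ExperimentResult, config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "experiment_config.txt")
    result.manifest.to_csv(out / "manifest.csv", index=False)
    result.predictions.to_csv(out / "predictions.csv", index=False)
    result.split.to_frame().to_csv(out / "split_plan.csv", index=False)
    result.report_frame().to_csv(out / "metrics.csv", index=False)
    result.provenance.to_csv(out / "provenance.csv", index=False)
    for trait, model in result.calibrations.items():
        model.to_json(out / f"calibration_{trait}.json")
    if result.cnn_model is not None:
        result.cnn_model.history.to_csv(out / "cnn_history.csv", index=False)
    if result.pca:
        for trait in result.pca:
            cols = {
                "kernel": ["kernel_weight_g", "xrt_kernel_g", "cnn_kernel_g"],
                "shell": ["shell_weight_g", "xrt_shell_g", "cnn_shell_g"],
            }[trait]
            test = result.predictions[result.predictions["split"] == "test"]
            ev.plot_pca_biplot(test[cols], out / f"pca_{trait}.png")
    (out / "run.log").write_text("\n".join(result.log) + "\n")
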