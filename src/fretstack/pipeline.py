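"""End-to-end orchestration: background -> ratio -> bleach.

Each stage is optional (background subtraction runs happily on a single
stack; ratio needs both channels; bleach needs the ratio or at least one
processed channel).  Frames are the unit of parallelism and are processed
independently, so outputs are bit-identical for any worker count.  A run
writes corrected TIFF stacks, one HDF5 artifact file, a metrics CSV, a
plain-text log and a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .background import process_stack_background
from .bleach import BleachModel, fit_bleach, correct_ratio_stack
from .core_io import ImageStack, RunConfig, read_stack, setup_run_logger, write_h5, write_stack
from .metrics import (
    FrameMetrics,
    compute_frame_metrics,
    foreground_median,
    metrics_to_dataframe,
)
from .ratio import (
    FLAG_REGISTRATION_WARN,
    RatioFrame,
    RigidTransform,
    apply_rigid_transform,
    bilateral_smooth,
    compute_ratio,
    estimate_rigid_transform,
    otsu_threshold,
    remove_boundary_singularities,
    robust_rescale,
)


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: RunConfig
    donor: ImageStack | None = None
    acceptor: ImageStack | None = None
    corrected: dict[str, ImageStack] = field(default_factory=dict)
    background_results: dict[str, list] = field(default_factory=dict)
    transform: RigidTransform | None = None
    ratio_frames: list[RatioFrame] = field(default_factory=list)
    ratio_stack: np.ndarray | None = None          # float, post bleach if enabled
    ratio_display: np.ndarray | None = None        # uint8
    bleach_models: dict[str, BleachModel] = field(default_factory=dict)
    metrics: list[FrameMetrics] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def frame_ids(self) -> np.ndarray:
        stack = self.donor if self.donor is not None else self.acceptor
        return stack.frame_ids


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig) -> tuple[ImageStack | None, ImageStack | None]:
    intervals = config.selected_intervals()
    donor = acceptor = None
    if config.donor_path:
        donor = read_stack(
            config.donor_path, intervals, bit_depth=config.bit_depth_override,
            channel_label="donor",
        )
    if config.acceptor_path:
        acceptor = read_stack(
            config.acceptor_path, intervals, bit_depth=config.bit_depth_override,
            channel_label="acceptor",
        )
    if donor is None and acceptor is None:
        raise ValueError("no input stack configured: set donor and/or acceptor")
    if donor is not None and acceptor is not None and donor.frames.shape != acceptor.frames.shape:
        raise ValueError("donor and acceptor stacks differ in shape or frame count")
    return donor, acceptor


def run_pipeline(
    config: RunConfig,
    stacks: tuple[ImageStack | None, ImageStack | None] | None = None,
    n_jobs: int | None = None,
    write_outputs: bool = True,
    verbose: bool = False,
) -> RunResult:
    """Execute the enabled stages and (optionally) write all outputs.

    Parameters
    ----------
    config : RunConfig
        Fully resolved configuration.
    stacks : (donor, acceptor), optional
        Pre-loaded stacks; bypasses reading ``config.donor_path`` /
        ``acceptor_path`` (useful for library use and testing).
    n_jobs : int, optional
        Worker count for per-frame parallel sections (default from config);
        results are independent of this value.
    write_outputs : bool
        When False nothing is written to disk and the result is returned
        in memory only.
    """
    t_start = datetime.datetime.now().isoformat(timespec="seconds")
    n_jobs = config.n_jobs if n_jobs is None else n_jobs
    out_dir = Path(config.output_dir)
    logger = setup_run_logger(out_dir, verbose=verbose) if write_outputs else None
    if logger:
        logger.info("fretstack %s modules=%s", __version__, ",".join(config.modules_enabled))
        logger.info("config: %s", config.snapshot())

    donor, acceptor = stacks if stacks is not None else _load_inputs(config)
    result = RunResult(config=config, donor=donor, acceptor=acceptor)
    modules = config.modules_enabled
    if "ratio" in modules and (donor is None or acceptor is None):
        missing = "donor" if donor is None else "acceptor"
        raise ValueError(f"ratio module needs both channels; missing: {missing}")

    channels = {name: s for name, s in (("donor", donor), ("acceptor", acceptor)) if s is not None}

    # --- background subtraction -------------------------------------------
    if "background" in modules:
        for name, stack in channels.items():
            corrected, frame_results = process_stack_background(
                stack, config, n_jobs=n_jobs, logger=logger
            )
            result.corrected[name] = corrected
            result.background_results[name] = frame_results
    else:
        result.corrected = dict(channels)
        result.background_results = {name: [] for name in channels}

    for name, stack in result.corrected.items():
        frame_results = result.background_results[name]
        for i in range(stack.n_frames):
            fr = frame_results[i] if frame_results else None
            result.metrics.append(
                compute_frame_metrics(
                    stack.frames[i],
                    stack.bit_depth,
                    int(stack.frame_ids[i]),
                    channel=name,
                    n_clusters=fr.n_clusters if fr else 0,
                    n_background_tiles=fr.n_background_tiles if fr else 0,
                    flags=fr.flags if fr else (),
                )
            )

    # --- ratio construction ------------------------------------------------
    if "ratio" in modules:
        _run_ratio_stage(result, config, logger)

    # --- photobleaching correction -----------------------------------------
    if "bleach" in modules:
        _run_bleach_stage(result, config, logger)

    if write_outputs:
        _write_outputs(result, out_dir, logger)
        result.manifest = _build_manifest(result, t_start)
        with open(out_dir / "manifest.json", "w") as f:
            json.dump(result.manifest, f, indent=2, sort_keys=True)
        if logger:
            logger.info("run complete")
    return result


def _failed_frames(result: RunResult, channel: str) -> set[int]:
    return {
        fr.frame_id for fr in result.background_results.get(channel, []) if fr.failed
    }


def _run_ratio_stage(result: RunResult, config: RunConfig, logger) -> None:
    donor = result.corrected["donor"]
    acceptor = result.corrected["acceptor"]
    sigma_range = config.bilateral_sigma_range_frac * donor.max_value
    p_lo, p_hi = config.rescale_percentiles

    transform = RigidTransform()
    if config.registration_enabled and not config.register_per_frame:
        transform = estimate_rigid_transform(
            donor.frames[0].astype(np.float64), acceptor.frames[0].astype(np.float64)
        )
        if logger:
            logger.info(
                "registration dx=%.3f dy=%.3f theta=%.4f deg converged=%s",
                transform.dx, transform.dy, math.degrees(transform.theta), transform.converged,
            )
    result.transform = transform

    ratio_frames: list[RatioFrame] = []
    displays = []
    for i in range(donor.n_frames):
        fid = int(donor.frame_ids[i])
        d = donor.frames[i].astype(np.float64)
        a = acceptor.frames[i].astype(np.float64)
        flags: set[str] = set()
        if config.registration_enabled:
            t = transform
            if config.register_per_frame:
                t = estimate_rigid_transform(d, a)
            if not t.converged:
                flags.add(FLAG_REGISTRATION_WARN)
            if not t.is_identity():
                a = apply_rigid_transform(a, t)
        d_s = bilateral_smooth(d, config.bilateral_sigma_space, sigma_range)
        a_s = bilateral_smooth(a, config.bilateral_sigma_space, sigma_range)
        _, mask_d = otsu_threshold(np.rint(d_s).astype(np.int64))
        _, mask_a = otsu_threshold(np.rint(a_s).astype(np.int64))
        mask_d = remove_boundary_singularities(mask_d, config.boundary_area_frac)
        mask_a = remove_boundary_singularities(mask_a, config.boundary_area_frac)
        rf = compute_ratio(a_s, d_s, mask_d & mask_a)
        display, rflags = robust_rescale(rf.ratio, rf.mask, p_lo, p_hi)
        rf.display = display
        rf.flags = rf.flags | flags | rflags
        ratio_frames.append(rf)
        displays.append(display)
        if logger:
            logger.info(
                "ratio frame=%d fg_px=%d donor_zero=%d flags=%s",
                fid, int(rf.mask.sum()), rf.n_donor_zero, ",".join(sorted(rf.flags)) or "-",
            )
        for m in result.metrics:
            if m.frame_id == fid and rf.flags:
                m.flags = m.flags | rf.flags
    result.ratio_frames = ratio_frames
    result.ratio_stack = np.stack([rf.ratio for rf in ratio_frames])
    result.ratio_display = np.stack(displays)


def _run_bleach_stage(result: RunResult, config: RunConfig, logger) -> None:
    frame_ids = result.frame_ids
    if config.bleach_fit_range is None:
        fit_range = (int(frame_ids[0]), int(frame_ids[-1]))
    else:
        fit_range = config.bleach_fit_range
        if not (frame_ids[0] <= fit_range[0] and fit_range[1] <= frame_ids[-1]):
            raise ValueError(
                f"bleach_range {fit_range} outside processed frames "
                f"{int(frame_ids[0])}-{int(frame_ids[-1])}"
            )

    for name in config.bleach_channels:
        stack = result.corrected.get(name)
        if stack is None:
            continue
        failed = _failed_frames(result, name)
        sel = np.array([fid not in failed for fid in stack.frame_ids])
        medians = np.array([foreground_median(f) for f in stack.frames])
        model = fit_bleach(
            medians[sel],
            fit_range,
            model_kind=config.bleach_model,
            ridge_lambda=config.ridge_lambda,
            frame_ids=stack.frame_ids[sel],
        )
        # re-express factors on the full frame axis (failed frames get the
        # model's factor too; they were only excluded from the fit)
        full = fit_factors_on(model, stack.frame_ids)
        result.bleach_models[name] = full
        if logger:
            logger.info(
                "bleach channel=%s model=%s params=(%.6g, %.6g) range=%d-%d",
                name, full.model_kind, *full.params, *full.fit_range,
            )

    if result.ratio_stack is not None:
        result.ratio_stack = correct_ratio_stack(
            result.ratio_stack,
            result.bleach_models.get("donor"),
            result.bleach_models.get("acceptor"),
        )
        displays = []
        p_lo, p_hi = config.rescale_percentiles
        for i, rf in enumerate(result.ratio_frames):
            disp, _ = robust_rescale(result.ratio_stack[i], rf.mask, p_lo, p_hi)
            displays.append(disp)
        result.ratio_display = np.stack(displays)


def fit_factors_on(model: BleachModel, frame_ids: np.ndarray) -> BleachModel:
    """Same fitted trend, correction factors re-evaluated on ``frame_ids``."""
    frame_ids = np.asarray(frame_ids)
    pred = model.predict(frame_ids.astype(np.float64))
    onset = model.onset
    m_onset = float(model.predict(float(onset)))
    factors = np.ones(len(frame_ids))
    after = frame_ids >= onset
    factors[after] = m_onset / pred[after]
    return BleachModel(
        model_kind=model.model_kind,
        params=model.params,
        fit_range=model.fit_range,
        frame_ids=frame_ids.copy(),
        factors=factors,
    )


def _write_outputs(result: RunResult, out_dir: Path, logger) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, np.ndarray] = {}
    for name, stack in result.corrected.items():
        write_stack(stack, out_dir / f"corrected_{name}.tif")
        artifacts[f"corrected/{name}"] = stack.frames
    if result.ratio_stack is not None:
        artifacts["ratio"] = result.ratio_stack
        import tifffile

        tifffile.imwrite(
            str(out_dir / "ratio_display.tif"), result.ratio_display, photometric="minisblack"
        )
    for name, model in result.bleach_models.items():
        artifacts[f"bleach/factors_{name}"] = model.factors
        artifacts[f"bleach/params_{name}"] = np.array(model.params)
    df = metrics_to_dataframe(result.metrics)
    df.to_csv(out_dir / "metrics.csv", index=False)
    artifacts["metrics/foreground_pct"] = df["foreground_pct"].to_numpy()
    artifacts["metrics/median_over_bitdepth"] = df["median_over_bitdepth"].to_numpy()
    write_h5(artifacts, out_dir / "run.h5", frame_ids=result.frame_ids, config=result.config)


def _build_manifest(result: RunResult, t_start: str) -> dict:
    config = result.config
    inputs = {}
    for label, p in (("donor", config.donor_path), ("acceptor", config.acceptor_path)):
        if p and Path(p).exists():
            inputs[label] = {"path": str(p), "sha256": _sha256(Path(p))}
    per_frame_eps = {
        str(int(fid)): config.eps_for_frame(int(fid)) for fid in result.frame_ids
    }
    return {
        "software": {"name": "fretstack", "version": __version__},
        "config": json.loads(config.snapshot()),
        "inputs": inputs,
        "modules": list(config.modules_enabled),
        "per_frame_eps": per_frame_eps,
        "started": t_start,
        "finished": datetime.datetime.now().isoformat(timespec="seconds"),
    }
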