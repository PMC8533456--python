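"""Configuration-driven end-to-end runs.

``run_pipeline`` executes simulate -> preprocess -> features -> smooth ->
select -> classify -> report from a single :class:`RunConfig`, writing
every intermediate product (recording container, epoch container,
feature CSVs, selection JSON, CV report JSON, topography CSV) plus a run
log with stage timings and record counts into the output directory.  The
run seed fans out into per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, in fixed stage order, so a
stage can be re-run in isolation and a re-run with the same config
reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .classify import SVMSpec, cross_validate, default_grid
from .containers import EpochSet, FeatureMatrix, Recording
from .features import asymmetry_features, class_topography, default_bands
from .montage import make_montage
from .preprocess import filter_resample, reject_epochs, segment_epochs
from .smoothing import smooth_feature_matrix
from .synth import ParadigmConfig, default_signatures, simulate_session

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "preprocess", "features", "smooth", "select", "train")


@dataclass
class RunConfig:
    """Everything one end-to-end run depends on.

    The config validates on construction and is serialized verbatim into
    the output directory so a bundle is self-describing.
    """

    seed: int = 0
    out_dir: str = "eegsq_run"
    # paradigm / simulation
    n_sounds_per_class: int = 3
    n_repetitions: int = 27
    stimulus_duration: float = 5.0
    epoch_duration: float = 1.0
    raw_rate: float = 1000.0
    gap_duration: float = 1.0
    noise_level: float = 1.0
    background_amp: float = 2.0
    n_channels: int = 62
    channels: tuple[str, ...] | None = None  # explicit toy layout overriding n_channels
    # preprocessing
    band_low: float = 0.1
    band_high: float = 100.0
    notch: float = 50.0
    target_rate: float = 200.0
    reject_ptp: float | None = None  # microvolts; None disables rejection
    # features
    bases: tuple[str, ...] = ("DE",)
    modes: tuple[str, ...] = ("DASM",)
    # smoothing / selection / classifier
    smoothing: str | None = None  # None, 'fixed' or 'em'
    smoothing_ratio: float = 0.01
    selection: str | None = None  # None, 'mrmr' or 'pca'
    n_selected: int | None = None
    classifier: str = "svm"
    use_grid: bool = True
    svm_c: float = 1.0
    svm_gamma: float = 0.1
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.classifier not in {"svm", "lda"}:
            raise ValueError("classifier must be 'svm' or 'lda'")
        if self.smoothing not in {None, "fixed", "em"}:
            raise ValueError("smoothing must be None, 'fixed' or 'em'")
        if self.selection not in {None, "mrmr", "pca"}:
            raise ValueError("selection must be None, 'mrmr' or 'pca'")
        if self.selection is not None and not self.n_selected:
            raise ValueError("selection requires n_selected")
        bad = set(self.bases) - {"PSD", "Hjorth", "DE"}
        if bad:
            raise ValueError(f"unknown bases {sorted(bad)}")
        bad = set(self.modes) - {"DASM", "RASM"}
        if bad:
            raise ValueError(f"unknown modes {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("bases", "modes", "channels"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bases"] = list(d["bases"])
        d["modes"] = list(d["modes"])
        if d["channels"] is not None:
            d["channels"] = list(d["channels"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed for a named stage (fixed spawn order)."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        idx = _STAGES.index(stage)
        return int(children[idx].generate_state(1)[0] % (2**31))


def _stage(log: list, name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
    return result


def stage_simulate(cfg: RunConfig) -> Recording:
    if cfg.channels is not None:
        montage = make_montage(channels=cfg.channels)
    else:
        montage = make_montage(cfg.n_channels)
    paradigm = ParadigmConfig(
        n_sounds_per_class=cfg.n_sounds_per_class,
        n_repetitions=cfg.n_repetitions,
        stimulus_duration=cfg.stimulus_duration,
        epoch_duration=cfg.epoch_duration,
        raw_rate=cfg.raw_rate,
        gap_duration=cfg.gap_duration,
        seed=cfg.stage_seed("simulate"),
    )
    return simulate_session(
        montage,
        paradigm,
        default_signatures(),
        noise_level=cfg.noise_level,
        background_amp=cfg.background_amp,
    )


def stage_preprocess(cfg: RunConfig, rec: Recording) -> EpochSet:
    filtered = filter_resample(
        rec, low=cfg.band_low, high=cfg.band_high, notch=cfg.notch, target_rate=cfg.target_rate
    )
    es = segment_epochs(
        filtered, epoch_duration=cfg.epoch_duration, stimulus_duration=cfg.stimulus_duration
    )
    if cfg.reject_ptp is not None:
        es, _ = reject_epochs(es, cfg.reject_ptp)
    return es


def stage_features(cfg: RunConfig, es: EpochSet) -> FeatureMatrix:
    return asymmetry_features(es, default_bands(), bases=set(cfg.bases), modes=set(cfg.modes))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a dict with the epoch count, feature dimensionality and the
    cross-validation report; everything is also written under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    log: list[dict] = []

    rec = _stage(log, "simulate", stage_simulate, cfg)
    eio.save_recording(rec, out / "recording")
    log[-1]["n_events"] = len(rec.events)

    es = _stage(log, "preprocess", stage_preprocess, cfg, rec)
    eio.save_epochs(es, out / "epochs")
    log[-1]["n_epochs"] = es.n_epochs

    fm = _stage(log, "features", stage_features, cfg, es)
    eio.save_features(fm, out / "features.csv")
    log[-1]["n_features"] = fm.n_features

    topo = _stage(log, "topography", class_topography, es, default_bands())
    topo.to_csv(out / "topography.csv", index=False)

    if cfg.smoothing is not None:
        smoothed = _stage(
            log, "smooth", smooth_feature_matrix, fm, mode=cfg.smoothing, ratio=cfg.smoothing_ratio
        )
        eio.save_features(smoothed, out / "features_smoothed.csv")

    if cfg.selection == "mrmr":
        from .selection import Discretizer, mrmr_rank

        disc = Discretizer().fit(fm.values)
        sel = _stage(log, "select", mrmr_rank, disc.transform(fm.values), fm.labels, cfg.n_selected)
        (out / "selection.json").write_text(
            json.dumps(
                {
                    "method": sel.method,
                    "ranked_indices": list(sel.ranked_indices),
                    "phi_scores": list(sel.phi_scores),
                },
                indent=1,
            )
        )

    spec = SVMSpec(
        C=cfg.svm_c, gamma=cfg.svm_gamma, grid=default_grid() if cfg.use_grid else None
    )
    report = _stage(
        log,
        "train",
        cross_validate,
        fm,
        classifier=cfg.classifier,
        spec=spec,
        seed=cfg.stage_seed("train"),
        n_folds=cfg.n_folds,
        smoothing=cfg.smoothing,
        smoothing_ratio=cfg.smoothing_ratio,
        selection=cfg.selection,
        n_selected=cfg.n_selected,
    )
    (out / "cv_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    bundle = {
        "n_events": len(rec.events),
        "n_epochs": es.n_epochs,
        "n_features": fm.n_features,
        "cv_report": report.to_dict(),
        "log": log,
    }
    (out / "run_log.json").write_text(json.dumps(bundle["log"], indent=1))
    return bundle
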