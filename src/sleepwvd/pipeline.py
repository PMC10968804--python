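"""Train / score / evaluate orchestration over nights on disk.

Thin glue over the library: reads EDF + hypnogram pairs, extracts WVD band
energies once per night, trains (t1, t2) by PSO against technician labels,
stages nights, and pools agreement reports.  Configuration is a YAML/JSON
mapping validated against :class:`RunConfig`; unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .signal_io import (EpochedRecording, Hypnogram, read_hypnogram,
                        read_psg_edf)
from .wvd import BandDefinition, DEFAULT_BANDS, band_energies_per_second
from .features import DEFAULT_TM, FeatureSeries, Thresholds, compute_features
from .staging import stage_night
from .pso import PsoConfig, PsoResult, fitness_accuracy, pso_optimize
from .metrics import evaluate_pairs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "extract_night_features", "train_thresholds",
           "score_night", "evaluate_nights", "load_config",
           "save_thresholds", "load_thresholds"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a pipeline run."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    tm: float = DEFAULT_TM
    active_channel: str = "C3"
    reference_channel: str | None = "M2"
    pso: PsoConfig = field(default_factory=PsoConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"bands", "tm", "active_channel", "reference_channel", "pso", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; accepted: {sorted(known)}")
        kwargs: dict = {}
        if "bands" in raw:
            kwargs["bands"] = tuple(
                BandDefinition(b["name"], float(b["f_lo"]), float(b["f_hi"]))
                for b in raw["bands"]
            )
        if "pso" in raw:
            pso_raw = dict(raw["pso"])
            if "bounds" in pso_raw:
                pso_raw["bounds"] = tuple(tuple(map(float, b)) for b in pso_raw["bounds"])
            unknown = set(pso_raw) - set(PsoConfig.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown pso config keys: {sorted(unknown)}")
            kwargs["pso"] = PsoConfig(**pso_raw)
        for key in ("tm", "seed", "active_channel", "reference_channel"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.from_dict(raw)
    logger.info("effective config: %s", cfg)
    return cfg


def _read_night(edf_path: str | Path, cfg: RunConfig) -> EpochedRecording:
    try:
        return read_psg_edf(edf_path, cfg.active_channel, cfg.reference_channel)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise type(exc)(f"{edf_path}: {exc}") from exc


def extract_night_features(rec: EpochedRecording, cfg: RunConfig) -> FeatureSeries:
    energies = band_energies_per_second(rec, cfg.bands)
    return compute_features(energies)


def train_thresholds(
    training: list[tuple[str | Path, str | Path]], cfg: RunConfig
) -> tuple[Thresholds, PsoResult]:
    """PSO-optimize (t1, t2) on labeled nights; features extracted once.

    ``training`` is a list of (EDF path, hypnogram CSV path) pairs.
    """
    if not training:
        raise ValueError("training set is empty")
    nights: list[tuple[FeatureSeries, Hypnogram]] = []
    for edf_path, hyp_path in training:
        rec = _read_night(edf_path, cfg)
        truth = read_hypnogram(hyp_path)
        if len(truth) != rec.n_epochs:
            raise ValueError(
                f"{hyp_path}: {len(truth)} epochs but {edf_path} has {rec.n_epochs}"
            )
        nights.append((extract_night_features(rec, cfg), truth))
        logger.info("loaded %s: %d epochs", edf_path, rec.n_epochs)
    result = pso_optimize(lambda pos: fitness_accuracy(pos, nights, tm=cfg.tm),
                          cfg.pso)
    th = Thresholds(t1=result.best_position[0], t2=result.best_position[1], tm=cfg.tm)
    logger.info("trained thresholds t1=%.3e t2=%.3e (fitness %.4f)",
                th.t1, th.t2, result.best_fitness)
    return th, result


def score_night(edf_path: str | Path, th: Thresholds, cfg: RunConfig) -> Hypnogram:
    """Stage one night on disk into {WAKE, N3, OTHER}."""
    rec = _read_night(edf_path, cfg)
    features = extract_night_features(rec, cfg)
    pred = stage_night(features, th)
    counts = {s: pred.labels.count(s) for s in ("WAKE", "N3", "OTHER")}
    logger.info("scored %s: %s", edf_path, counts)
    return pred


def evaluate_nights(scored: list[tuple[Hypnogram, Hypnogram]]) -> dict:
    """Pooled agreement report over (predicted, truth) pairs."""
    return evaluate_pairs(scored)


def save_thresholds(th: Thresholds, path: str | Path,
                    result: PsoResult | None = None) -> None:
    payload = {"tm": th.tm, "t1": th.t1, "t2": th.t2}
    if result is not None:
        payload["seed"] = result.seed
        payload["fitness"] = result.best_fitness
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_thresholds(path: str | Path) -> Thresholds:
    with open(path) as fh:
        raw = json.load(fh)
    return Thresholds(t1=float(raw["t1"]), t2=float(raw["t2"]),
                      tm=float(raw.get("tm", DEFAULT_TM)))
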