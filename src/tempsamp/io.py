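"""Trial-log formats, run configuration, and the staged analysis workflow.

Trial logs are plain delimited text (one row per trial: accuracy, staircase
level, the 24 SNR values and the 11 amplitude/phase pairs that built them);
dense arrays (Z images, time-frequency maps) are written as ``.npz``
containers with JSON metadata sidecars.  Every artifact is stamped with the
configuration hash and the seeds in play, and each stage draws its
randomness from a seed derived from the master seed and a fixed per-stage
constant, so reruns are reproducible stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classification import (
    ClassificationImage,
    bootstrap_z,
    contrast_classification_image,
    group_pipeline,
    raw_classification_image,
)
from .observers import ExperimentLog, make_class_library, simulate_dataset
from .sampling import BasisSpec
from .spectra import ci_power_phase, decode_loo

__all__ = ["RunConfig", "read_trial_log", "write_trial_log", "run_pipeline"]

#: per-stage seed-derivation constants (SeedSequence([master, constant]))
STAGE_SEEDS = {"simulate": 0, "analyze": 1, "contrast": 2, "decode": 3}
STAGES = ("simulate", "analyze", "contrast", "decode", "report")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, with the study's defaults."""

    frequencies: tuple[float, ...] = tuple(float(f) for f in range(5, 60, 5))
    duration: float = 0.200
    refresh_rate: float = 120.0
    sum_target: float = 6.0
    sum_tol: float = 0.05
    n_classes: int = 4
    observers_per_class: int = 12
    n_trials: int = 1200
    accuracy_target: float = 0.5
    gain: float = 6.0
    phase_jitter: float = float(2.0 * np.pi)
    noise_level: int = 64
    n_boot: int = 1000
    n_cycles: float = 3.0
    fwhm_time: float = 0.6
    fwhm_tf: float = 1.5
    alpha: float = 0.05
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 0.5):
            raise ValueError("alpha must lie in (0, 0.5]")
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))

    @property
    def basis(self) -> BasisSpec:
        return BasisSpec(self.frequencies, self.duration, self.refresh_rate)

    def fwhm(self, domain: str) -> float:
        return self.fwhm_tf if domain == "tf" else self.fwhm_time

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, STAGE_SEEDS[stage]]))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if "frequencies" in raw:
            raw["frequencies"] = tuple(float(f) for f in raw["frequencies"])
        return cls(**raw)


def _snr_cols(n: int) -> list[str]:
    return [f"snr_{i:02d}" for i in range(n)]


def _basis_cols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:02d}" for i in range(n)]


def write_trial_log(log: ExperimentLog, path: str | Path) -> None:
    """Serialize a trial log losslessly to delimited text."""
    n_frames = log.spec.n_frames
    n_freq = len(log.spec.frequencies)
    df = pd.DataFrame(
        {
            "participant": log.participant_id,
            "stimulus_class": log.stimulus_class,
            "trial": np.arange(1, log.n_trials + 1),
            "accuracy": log.accuracy,
            "noise_level": log.noise_level,
        }
    )
    df[_snr_cols(n_frames)] = log.values
    df[_basis_cols("amp", n_freq)] = log.amplitudes
    df[_basis_cols("phase", n_freq)] = log.phases
    df.to_csv(path, index=False)


def read_trial_log(path: str | Path, spec: BasisSpec | None = None) -> ExperimentLog:
    """Parse and validate a trial log; errors name the offending column/row."""
    spec = spec or BasisSpec()
    df = pd.read_csv(path, float_precision="round_trip")
    required = (
        ["participant", "stimulus_class", "trial", "accuracy", "noise_level"]
        + _snr_cols(spec.n_frames)
        + _basis_cols("amp", len(spec.frequencies))
        + _basis_cols("phase", len(spec.frequencies))
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing columns {missing}")
    acc = df["accuracy"].to_numpy()
    bad = np.flatnonzero(~np.isin(acc, (0, 1)))
    if bad.size:
        raise ValueError(
            f"non-binary accuracy value {acc[bad[0]]!r} in row {bad[0] + 1} of {path}"
        )
    snr = df[_snr_cols(spec.n_frames)].to_numpy()
    oob = np.argwhere((snr < -1e-9) | (snr > 0.5 + 1e-9))
    if oob.size:
        r, c = oob[0]
        raise ValueError(
            f"SNR outside [0, 0.5] in row {r + 1}, column {_snr_cols(spec.n_frames)[c]} of {path}"
        )
    return ExperimentLog(
        participant_id=str(df["participant"].iloc[0]),
        stimulus_class=str(df["stimulus_class"].iloc[0]),
        values=snr,
        amplitudes=df[_basis_cols("amp", len(spec.frequencies))].to_numpy(),
        phases=df[_basis_cols("phase", len(spec.frequencies))].to_numpy(),
        accuracy=acc.astype(np.int8),
        noise_level=df["noise_level"].to_numpy(),
        spec=spec,
    )


def _stamp(out: Path, stage: str, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"stage": stage, "config_hash": config.config_hash(), "seed": config.seed,
               "config": config.to_dict()}
    if extra:
        payload.update(extra)
    (out / f"{stage}_runlog.json").write_text(json.dumps(payload, indent=2))


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the '{stage}' stage before '{needed_by}'"
        )


def _load_logs(out: Path, config: RunConfig) -> list[ExperimentLog]:
    log_dir = out / "logs"
    _require(log_dir, "simulate", "analyze")
    return [read_trial_log(p, config.basis) for p in sorted(log_dir.glob("*.csv"))]


def _save_group(out: Path, name: str, res) -> None:
    np.savez(out / f"{name}.npz", values=res.values, mask=res.mask)
    meta = {
        "domain": res.domain,
        "z_crit": res.z_crit,
        "alpha": res.alpha,
        "fwhm": res.fwhm,
        "n_images": res.n_images,
        "n_significant_pos": int(np.sum(res.mask > 0)),
        "n_significant_neg": int(np.sum(res.mask < 0)),
    }
    (out / f"{name}.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(np.atleast_2d(res.mask)).to_csv(out / f"{name}_mask.csv", index=False)


def run_pipeline(config: RunConfig, command: str, out_dir: str | Path) -> Path:
    """Run one workflow stage; returns the output directory.

    simulate -> trial logs for the synthetic class library; analyze ->
    per-participant classification images in the three domains plus group
    results; contrast -> pairwise class contrasts; decode -> class decoding
    from classification-image power spectra; report -> plain-text summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if command not in STAGES:
        raise ValueError(f"command must be one of {STAGES}")

    if command == "simulate":
        rng = config.stage_rng("simulate")
        library = make_class_library(
            n_classes=config.n_classes,
            observers_per_class=config.observers_per_class,
            phase_jitter=config.phase_jitter,
            rng=rng,
            gain=config.gain,
            spec=config.basis,
        )
        log_dir = out / "logs"
        log_dir.mkdir(exist_ok=True)
        for model in library:
            log = simulate_dataset(
                model,
                n_trials=config.n_trials,
                spec=config.basis,
                rng=rng,
                calibrate_to=config.accuracy_target,
                noise_level=config.noise_level,
            )
            write_trial_log(log, log_dir / f"{model.participant_id}.csv")
        _stamp(out, "simulate", config, {"n_observers": len(library)})

    elif command == "analyze":
        rng = config.stage_rng("analyze")
        logs = _load_logs(out, config)
        ana = out / "analysis"
        ana.mkdir(exist_ok=True)
        by_class: dict[str, dict[str, list]] = {}
        for log in logs:
            for domain in ("time", "fourier", "tf"):
                raw = raw_classification_image(log, domain, config.n_cycles)
                zci = bootstrap_z(log, domain, config.n_boot, rng, config.n_cycles)
                np.savez(
                    ana / f"{log.participant_id}_{domain}.npz",
                    raw=raw.values,
                    z=zci.values,
                )
                (ana / f"{log.participant_id}_{domain}.json").write_text(
                    json.dumps(zci.meta, indent=2)
                )
                by_class.setdefault(log.stimulus_class, {}).setdefault(domain, []).append(zci)
        for cls, domains in by_class.items():
            for domain, cis in domains.items():
                res = group_pipeline(cis, fwhm=config.fwhm(domain), alpha=config.alpha)
                _save_group(ana, f"group_{cls}_{domain}", res)
        _stamp(out, "analyze", config, {"n_logs": len(logs)})

    elif command == "contrast":
        rng = config.stage_rng("contrast")
        _require(out / "analysis", "analyze", "contrast")
        logs = _load_logs(out, config)
        ana = out / "analysis"
        con = out / "contrasts"
        con.mkdir(exist_ok=True)
        classes = sorted({log.stimulus_class for log in logs})
        for domain in ("time", "tf"):
            groups = {
                cls: [
                    _load_z(ana, log.participant_id, domain, config)
                    for log in logs
                    if log.stimulus_class == cls
                ]
                for cls in classes
            }
            for a, b in itertools.combinations(classes, 2):
                res = contrast_classification_image(
                    groups[a], groups[b],
                    fwhm=config.fwhm(domain), alpha=config.alpha,
                    rng=rng, n_boot=config.n_boot,
                )
                _save_group(con, f"contrast_{a}_vs_{b}_{domain}", res)
        _stamp(out, "contrast", config)

    elif command == "decode":
        _require(out / "analysis", "analyze", "decode")
        logs = _load_logs(out, config)
        ana = out / "analysis"
        results = {}
        for domain, source in (("time", "raw"), ("tf", "z")):
            feats, labels = [], []
            for log in logs:
                with np.load(ana / f"{log.participant_id}_{domain}.npz") as npz:
                    arr = npz[source]
                ci = ClassificationImage(domain, arr, scale="raw")
                feats.append(ci_power_phase(ci).power.ravel())
                labels.append(log.stimulus_class)
            res = decode_loo(np.array(feats), np.array(labels), C=config.svm_c)
            results[domain] = {
                "accuracy": res.accuracy,
                "chance": 1.0 / len(res.classes),
                "classes": list(res.classes),
                "confusion": res.confusion.tolist(),
                "chi2": res.chi2,
                "df": res.df,
                "p_value": res.p_value,
            }
        (out / "decoding.json").write_text(json.dumps(results, indent=2))
        _stamp(out, "decode", config)

    elif command == "report":
        _require(out / "analysis", "analyze", "report")
        lines = [f"tempsamp run report  (config {config.config_hash()}, seed {config.seed})", ""]
        for p in sorted((out / "analysis").glob("group_*.json")):
            meta = json.loads(p.read_text())
            lines.append(
                f"{p.stem}: domain={meta['domain']} z_crit={meta['z_crit']:.3f} "
                f"+points={meta['n_significant_pos']} -points={meta['n_significant_neg']}"
            )
        dec = out / "decoding.json"
        if dec.exists():
            lines.append("")
            for domain, res in json.loads(dec.read_text()).items():
                lines.append(
                    f"decoding[{domain}]: accuracy={res['accuracy']:.3f} "
                    f"(chance {res['chance']:.3f}), chi2({res['df']})={res['chi2']:.1f}, "
                    f"p={res['p_value']:.2e}"
                )
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        _stamp(out, "report", config)

    return out


def _load_z(ana: Path, participant: str, domain: str, config: RunConfig) -> ClassificationImage:
    path = ana / f"{participant}_{domain}.npz"
    _require(path, "analyze", "contrast")
    with np.load(path) as npz:
        z = npz["z"]
    return ClassificationImage(domain, z, scale="z", meta={"n_boot": config.n_boot})
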