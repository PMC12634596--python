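"""Plain-text persistence of synthetic datasets and analysis tables.

Per-trial EMG is a delimited text matrix (one row per sample, one column
per muscle, header row of muscle labels); the manifest is a JSON file
listing participants (with MVC values and ground truth) and trials.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import (Dataset, GroundTruth, ParticipantData, SimulationConfig,
                       TrialRecording)

__all__ = ["write_dataset", "read_dataset"]


def _truth_to_json(t: GroundTruth) -> dict:
    return {
        "W_true": t.W_true.tolist(),
        "preferred_directions": t.preferred_directions.tolist(),
        "drive_band_assignment": [list(b) for b in t.drive_band_assignment],
        "shared_bands": list(t.shared_bands),
        "dominant_synergy": t.dominant_synergy.tolist(),
        "mvc": t.mvc.tolist(),
        "seed": t.seed,
    }


def _truth_from_json(d: dict) -> GroundTruth:
    return GroundTruth(
        W_true=np.array(d["W_true"], float),
        preferred_directions=np.array(d["preferred_directions"], float),
        drive_band_assignment=tuple(tuple(b) for b in d["drive_band_assignment"]),
        shared_bands=tuple(d["shared_bands"]),
        dominant_synergy=np.array(d["dominant_synergy"], int),
        mvc=np.array(d["mvc"], float),
        seed=int(d["seed"]),
    )


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  fmt: str = "%.6e") -> Path:
    """Write per-trial EMG matrices and a JSON manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    manifest = {
        "config": {
            "n_participants": cfg.n_participants,
            "n_muscles": cfg.n_muscles,
            "n_synergies": cfg.n_synergies,
            "directions": cfg.directions.tolist(),
            "n_repetitions": cfg.n_repetitions,
            "fs": cfg.fs,
            "rest_duration": cfg.rest_duration,
            "hold_duration": cfg.hold_duration,
            "drive_bands": [list(b) for b in cfg.drive_bands],
            "drive_gain": cfg.drive_gain,
            "noise_gain": cfg.noise_gain,
            "shared_bands": list(cfg.shared_bands),
            "seed": cfg.seed,
        },
        "muscles": list(cfg.muscle_names),
        "seed": cfg.seed,
        "participants": [],
        "trials": [],
    }
    header = "\t".join(cfg.muscle_names)
    for part in dataset.participants:
        manifest["participants"].append({
            "id": part.participant_id,
            "mvc": {m: float(v) for m, v in zip(part.muscles, part.ground_truth.mvc)},
            "ground_truth": _truth_to_json(part.ground_truth),
        })
        pdir = out / f"participant_{part.participant_id:02d}"
        pdir.mkdir(exist_ok=True)
        for trial in part.trials:
            fname = pdir / f"trial_{trial.trial_id:04d}.tsv"
            try:
                np.savetxt(fname, trial.emg, fmt=fmt, delimiter="\t",
                           header=header, comments="")
            except OSError as exc:
                raise OSError(f"failed to write trial file {fname}: {exc}") from exc
            manifest["trials"].append({
                "participant_id": trial.participant_id,
                "trial_id": trial.trial_id,
                "file": str(fname.relative_to(out)),
                "direction": trial.direction.tolist(),
                "direction_index": trial.direction_index,
                "repetition": trial.repetition,
                "phase_bounds": list(trial.phase_bounds),
            })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def read_dataset(data_dir: str | Path) -> Dataset:
    """Load a dataset written by :func:`write_dataset`."""
    root = Path(data_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    c = manifest["config"]
    config = SimulationConfig(
        n_participants=c["n_participants"], n_muscles=c["n_muscles"],
        n_synergies=c["n_synergies"], directions=np.array(c["directions"]),
        n_repetitions=c["n_repetitions"], fs=c["fs"],
        rest_duration=c["rest_duration"], hold_duration=c["hold_duration"],
        drive_bands=tuple(tuple(b) for b in c["drive_bands"]),
        drive_gain=c["drive_gain"], noise_gain=c["noise_gain"],
        shared_bands=tuple(c["shared_bands"]), seed=c["seed"],
        muscles=tuple(manifest["muscles"]))
    parts = {}
    for p in manifest["participants"]:
        parts[p["id"]] = ParticipantData(
            participant_id=p["id"], trials=[],
            ground_truth=_truth_from_json(p["ground_truth"]),
            muscles=tuple(manifest["muscles"]), fs=c["fs"])
    for t in manifest["trials"]:
        emg = np.loadtxt(root / t["file"], delimiter="\t", skiprows=1, ndmin=2)
        parts[t["participant_id"]].trials.append(TrialRecording(
            participant_id=t["participant_id"], trial_id=t["trial_id"],
            direction=np.array(t["direction"], float),
            repetition=t["repetition"], emg=emg,
            phase_bounds=tuple(t["phase_bounds"]), fs=c["fs"],
            direction_index=t.get("direction_index", -1)))
    return Dataset(config=config,
                   participants=[parts[k] for k in sorted(parts)])
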