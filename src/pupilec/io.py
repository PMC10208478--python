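"""Portable readers/writers for events, arrays, and run bundles.

Event tables follow the BIDS events.tsv dialect (onset/duration in seconds
from run start, missing response times encoded "n/a").  Array containers are
either HDF5 or TSV with a JSON sidecar carrying sampling rate and channel/ROI
names, so every modality round-trips losslessly through plain files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_events",
    "write_events",
    "read_array",
    "write_array",
    "read_eeg",
    "RunBundle",
    "write_cohort",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "response_time"]


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events TSV; onsets are sorted ascending on read."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("onset", "duration"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in {col!r}")
    if not df["onset"].is_monotonic_increasing:
        logger.info("%s: onsets were unsorted; sorting ascending", path)
        df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    return df[EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="n/a",
               float_format="%.6f")


def write_array(path: str | Path, array: np.ndarray, fs: float,
                names: list[str] | None = None, units: str = "a.u.") -> None:
    """Write a 2-d array container (HDF5 or TSV) with a JSON sidecar."""
    path = Path(path)
    array = np.atleast_2d(np.asarray(array, dtype=float))
    sidecar = {"fs": float(fs), "units": units,
               "names": list(names) if names is not None
               else [f"s{i}" for i in range(array.shape[0])],
               "shape": list(array.shape)}
    if len(sidecar["names"]) != array.shape[0]:
        raise ValueError("one name per row required")
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=array)
            f.attrs["sidecar"] = json.dumps(sidecar)
    else:
        np.savetxt(path, array.T, delimiter="\t", fmt="%.17g",
                   header="\t".join(sidecar["names"]), comments="")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_array(path: str | Path):
    """Read an array container; returns (array, sidecar) after validation."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for field_ in ("fs", "names", "shape"):
        if field_ not in sidecar:
            raise ValueError(f"{sidecar_path}: sidecar missing field {field_!r}")
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as f:
            array = np.asarray(f["data"])
    else:
        array = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2).T
    if list(array.shape) != list(sidecar["shape"]):
        raise ValueError(f"{path}: array shape {array.shape} does not match "
                         f"sidecar shape {sidecar['shape']}")
    return array, sidecar


def read_eeg(path: str | Path, drop: tuple[str, ...] = ("ECG",)):
    """Read an EEG container, dropping non-scalp channels by default.

    Acquisition montages commonly carry one ECG electrode alongside the
    scalp channels (e.g., 63 cap + 1 ECG); channels named in ``drop`` are
    excluded on load.  Returns (samples x channels array, channel names, fs).
    """
    array, sidecar = read_array(path)
    names = list(sidecar["names"])
    keep = [i for i, name in enumerate(names) if name not in drop]
    if len(keep) < len(names):
        logger.info("%s: dropped channel(s) %s on load", path,
                    [n for n in names if n in drop])
    return array[keep].T, [names[i] for i in keep], float(sidecar["fs"])


@dataclass
class RunBundle:
    """Paths and identifiers for one run of one subject."""

    subject_id: str
    run_id: str
    events_path: Path
    eeg_path: Path
    pupil_path: Path
    bold_path: Path
    nuisance_path: Path
    seed: int | None = None

    def validate(self) -> None:
        for name in ("events_path", "eeg_path", "pupil_path", "bold_path",
                     "nuisance_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(
                    f"{self.subject_id}/{self.run_id}: missing {name.replace('_path', '')} "
                    f"file {p}")

    def load(self) -> dict:
        self.validate()
        eeg, eeg_meta = read_array(self.eeg_path)
        pupil, pupil_meta = read_array(self.pupil_path)
        bold, bold_meta = read_array(self.bold_path)
        return {
            "events": read_events(self.events_path),
            "eeg": eeg.T, "eeg_fs": eeg_meta["fs"],
            "pupil": pupil[0], "pupil_fs": pupil_meta["fs"],
            "bold": bold, "bold_meta": bold_meta,
            "nuisance": pd.read_csv(self.nuisance_path, sep="\t"),
        }


def write_cohort(cohort, outdir: str | Path) -> list[RunBundle]:
    """Serialize a synthetic cohort to per-run bundles under ``outdir``."""
    outdir = Path(outdir)
    bundles = []
    for subject in cohort.subjects:
        for r, run in enumerate(subject.runs, start=1):
            d = outdir / subject.subject_id / f"run-{r:02d}"
            d.mkdir(parents=True, exist_ok=True)
            write_events(run.events, d / "events.tsv")
            write_array(d / "eeg.tsv", run.eeg.T, fs=run.eeg_fs)
            write_array(d / "pupil.tsv", run.pupil.diameter[None, :],
                        fs=run.pupil.fs, names=["diameter"])
            tr = 2.1
            write_array(d / "bold.tsv", run.bold, fs=1.0 / tr,
                        names=[f"roi_{i}" for i in range(run.bold.shape[0])])
            run.nuisance.to_csv(d / "nuisance.tsv", sep="\t", index=False)
            bundles.append(RunBundle(
                subject_id=subject.subject_id, run_id=f"run-{r:02d}",
                events_path=d / "events.tsv", eeg_path=d / "eeg.tsv",
                pupil_path=d / "pupil.tsv", bold_path=d / "bold.tsv",
                nuisance_path=d / "nuisance.tsv", seed=run.seed))
    return bundles
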