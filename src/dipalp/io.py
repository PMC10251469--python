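"""Configuration, logging, and on-disk formats binding the pipeline stages.

Recordings are stored one file per (probe point, pressure): a delimited
time-series (``time_s, force_N, strain``) plus a JSON sidecar holding the
metadata and the generator's ground truth.  A cohort is indexed by a
delimited manifest (one row per recording).  A single-archive HDF5 layout
(one group per recording) is supported for round-tripping.  Run
configuration is a single YAML file validated before any stage runs and
re-serialised into every output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .classify import CVConfig
from .mechanics import ProbeGeometry
from .simulate import (
    ActuationProtocol,
    BlockTruth,
    CohortConfig,
    RawRecording,
    RecordingMeta,
)

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["patient_id", "point_id", "zone", "label", "pressure",
                    "frequency_schedule", "path"]


@dataclass(frozen=True)
class ExtractionConfig:
    detrend_periods: int = 3
    discard_periods: int = 1


@dataclass
class RunConfig:
    """One configuration drives all pipeline stages.

    ``seed`` overrides the cohort and cross-validation seeds on
    :meth:`resolve`, so a single integer reproduces the full pipeline.
    """

    seed: int = 0
    outdir: str = "runs/dipalp"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def resolve(self) -> "RunConfig":
        cohort = dataclasses.replace(self.cohort, seed=self.seed)
        cv = dataclasses.replace(self.cv, seed=self.seed + 1)
        return dataclasses.replace(self, cohort=cohort, cv=cv)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["points_per_patient"] = list(self.cohort.points_per_patient)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(section: str, klass, payload: dict):
            known = {f.name: f for f in dataclasses.fields(klass)}
            unknown = sorted(set(payload) - set(known))
            if unknown:
                raise ValueError(
                    f"unknown configuration key(s) {', '.join(f'{section}.{k}' for k in unknown)}"
                )
            return klass(**payload)

        if not isinstance(data, dict):
            raise ValueError("configuration must be a mapping")
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - top)
        if unknown:
            raise ValueError(f"unknown configuration key(s) {', '.join(unknown)}")
        kwargs: dict = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "outdir" in data:
            kwargs["outdir"] = str(data["outdir"])
        if "cohort" in data:
            payload = dict(data["cohort"])
            if "points_per_patient" in payload:
                payload["points_per_patient"] = tuple(payload["points_per_patient"])
            kwargs["cohort"] = build("cohort", CohortConfig, payload)
        if "geometry" in data:
            kwargs["geometry"] = build("geometry", ProbeGeometry, dict(data["geometry"]))
        if "extraction" in data:
            kwargs["extraction"] = build("extraction", ExtractionConfig,
                                         dict(data["extraction"]))
        if "cv" in data:
            kwargs["cv"] = build("cv", CVConfig, dict(data["cv"]))
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Recording serialisation
# ---------------------------------------------------------------------------

def _meta_payload(rec: RawRecording) -> dict:
    proto = dataclasses.asdict(rec.meta.protocol)
    proto["frequencies"] = list(rec.meta.protocol.frequencies)
    return {
        "patient_id": rec.meta.patient_id,
        "point_id": rec.meta.point_id,
        "zone": rec.meta.zone,
        "label": rec.meta.label,
        "pressure": rec.meta.pressure,
        "protocol": proto,
        "truth": [dataclasses.asdict(t) for t in rec.truth],
    }


def _meta_from_payload(payload: dict) -> tuple[RecordingMeta, tuple[BlockTruth, ...]]:
    proto = dict(payload["protocol"])
    proto["frequencies"] = tuple(proto["frequencies"])
    meta = RecordingMeta(patient_id=payload["patient_id"],
                         point_id=payload["point_id"], zone=payload["zone"],
                         label=payload["label"], pressure=payload["pressure"],
                         protocol=ActuationProtocol(**proto))
    truth = tuple(BlockTruth(**t) for t in payload.get("truth", []))
    return meta, truth


def recording_basename(rec: RawRecording) -> str:
    return f"{rec.meta.point_id}_{rec.meta.pressure}"


def write_recording(rec: RawRecording, directory: str | Path) -> Path:
    """Write one recording as CSV + JSON sidecar; returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = recording_basename(rec)
    csv_path = directory / f"{base}.csv"
    pd.DataFrame({"time_s": rec.time, "force_N": rec.force,
                  "strain": rec.strain}).to_csv(csv_path, index=False,
                                                float_format="%.9g")
    with open(directory / f"{base}.json", "w") as fh:
        json.dump(_meta_payload(rec), fh, indent=1)
    return csv_path


def read_recording(csv_path: str | Path) -> RawRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("time_s", "force_N", "strain"):
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing column {col!r}")
    with open(csv_path.with_suffix(".json")) as fh:
        meta, truth = _meta_from_payload(json.load(fh))
    return RawRecording(time=df["time_s"].to_numpy(),
                        force=df["force_N"].to_numpy(),
                        strain=df["strain"].to_numpy(), meta=meta, truth=truth)


def write_manifest(recordings: list[RawRecording], directory: str | Path,
                   paths: list[Path] | None = None) -> Path:
    directory = Path(directory)
    rows = []
    for i, rec in enumerate(recordings):
        path = paths[i] if paths else directory / "recordings" / f"{recording_basename(rec)}.csv"
        rows.append({
            "patient_id": rec.meta.patient_id, "point_id": rec.meta.point_id,
            "zone": rec.meta.zone, "label": rec.meta.label,
            "pressure": rec.meta.pressure,
            "frequency_schedule": ";".join(f"{f:g}" for f in rec.meta.protocol.frequencies),
            "path": str(Path(path).relative_to(directory)),
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    return df


def iter_manifest_recordings(manifest_path: str | Path):
    """Yield (row, recording-or-None, error) for each manifest entry."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    for _, row in df.iterrows():
        path = manifest_path.parent / row["path"]
        try:
            yield row, read_recording(path), None
        except Exception as err:  # unreadable/corrupt entries are skippable
            yield row, None, err


# ---------------------------------------------------------------------------
# Single-archive (HDF5) container
# ---------------------------------------------------------------------------

def write_cohort_archive(recordings: list[RawRecording], path: str | Path) -> None:
    """Hierarchical archive: one group per recording with channel datasets."""
    with h5py.File(path, "w") as h5:
        for i, rec in enumerate(recordings):
            grp = h5.create_group(f"{i:04d}_{recording_basename(rec)}")
            grp.create_dataset("time_s", data=rec.time)
            grp.create_dataset("force_N", data=rec.force)
            grp.create_dataset("strain", data=rec.strain)
            grp.attrs["meta"] = json.dumps(_meta_payload(rec))


def read_cohort_archive(path: str | Path) -> list[RawRecording]:
    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5):
            grp = h5[name]
            meta, truth = _meta_from_payload(json.loads(grp.attrs["meta"]))
            out.append(RawRecording(time=grp["time_s"][:], force=grp["force_N"][:],
                                    strain=grp["strain"][:], meta=meta,
                                    truth=truth))
    return out


def setup_run_logging(outdir: str | Path) -> Path:
    """Attach a file handler writing the run log into the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("dipalp")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return log_path
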