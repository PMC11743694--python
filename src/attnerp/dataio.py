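"""Read/write the on-disk dataset layout.

The layout is BIDS-flavoured::

    root/
      sub-01/eeg/sub-01_task-P1_eeg.npz        raw recording (array container)
      sub-01/eeg/sub-01_task-P1_eeg.json       sidecar: sampling rate, units
      sub-01/eeg/sub-01_task-P1_channels.tsv   name / group / x / y
      sub-01/eeg/sub-01_task-P1_events.tsv     onset / duration / trial_type /
                                               stream / trial
      sub-01/eeg/sub-01_task-P1_sim.json       simulation config (optional)

The recording container is a documented NumPy ``.npz`` holding a float32
``samples`` array (channels x time, microvolts); all metadata lives in the
plain-text sidecars.  Event files are UTF-8 tab-separated with a header
row and decimal points.  Real recordings in the same layout flow through
identical code paths as synthetic ones.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONDITIONS, ContinuousRecording, EventTable, ValidationError
from .simulate import SimulationConfig


class ParseError(ValueError):
    """Raised when an on-disk file cannot be read or validated."""


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _sidecar_paths(npz_path: Path) -> dict[str, Path]:
    stem = npz_path.name
    if stem.endswith("_eeg.npz"):
        base = stem[: -len("_eeg.npz")]
    else:
        base = npz_path.stem
    d = npz_path.parent
    return {
        "json": d / f"{base}_eeg.json",
        "channels": d / f"{base}_channels.tsv",
        "events": d / f"{base}_events.tsv",
        "sim": d / f"{base}_sim.json",
    }


def write_recording(path: str | Path, rec: ContinuousRecording) -> Path:
    """Write a recording and its sidecars; returns the container path."""
    path = Path(path)
    if not path.name.endswith("_eeg.npz"):
        raise ParseError(f"recording container must end in '_eeg.npz': {path.name}")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, samples=rec.samples.astype(np.float32))
    side = _sidecar_paths(path)
    side["json"].write_text(
        json.dumps(
            {"SamplingFrequency": rec.sampling_rate, "Units": "uV",
             "EEGChannelCount": rec.n_channels},
            indent=2,
        )
    )
    rows = []
    for c in rec.channel_labels:
        x, y = rec.montage2d.get(c, (np.nan, np.nan))
        rows.append((c, rec.channel_groups[c], x, y))
    pd.DataFrame(rows, columns=["name", "group", "x", "y"]).to_csv(
        side["channels"], sep="\t", index=False
    )
    return path


def read_recording(path: str | Path) -> ContinuousRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`ParseError` (naming the file) for unknown containers,
    missing sampling-rate metadata or inconsistent channel tables.
    """
    path = Path(path)
    if path.suffix != ".npz":
        raise ParseError(f"unsupported recording container: {path}")
    if not path.exists():
        raise ParseError(f"no such recording: {path}")
    side = _sidecar_paths(path)
    if not side["json"].exists():
        raise ParseError(f"missing sampling-rate sidecar for {path}")
    meta = json.loads(side["json"].read_text())
    if "SamplingFrequency" not in meta:
        raise ParseError(f"no sampling rate in {side['json']}")
    if meta.get("Units", "uV") not in ("uV", "µV", "microvolts"):
        raise ParseError(f"ambiguous units {meta.get('Units')!r} in {side['json']}")
    if not side["channels"].exists():
        raise ParseError(f"missing channels table for {path}")
    ch = pd.read_csv(side["channels"], sep="\t")
    with np.load(path) as z:
        samples = np.asarray(z["samples"], dtype=float)
    if samples.shape[0] != len(ch):
        raise ParseError(
            f"{path}: {samples.shape[0]} data rows vs {len(ch)} channel rows"
        )
    labels = ch["name"].astype(str).tolist()
    groups = dict(zip(labels, ch["group"].astype(str)))
    montage = {
        str(r["name"]): (float(r["x"]), float(r["y"]))
        for _, r in ch.iterrows()
        if np.isfinite(r["x"]) and np.isfinite(r["y"])
    }
    try:
        return ContinuousRecording(
            samples, float(meta["SamplingFrequency"]), labels, groups, montage
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def write_events(path: str | Path, events: EventTable) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.df.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path, recording_duration: float | None = None) -> EventTable:
    """Read and validate an events.tsv file.

    Validation failures report the 0-based data row number.  When
    ``recording_duration`` (seconds) is given, onsets beyond it are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such events file: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["onset", "duration", "trial_type", "stream", "trial"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for i, cond in enumerate(df["trial_type"]):
        if cond not in CONDITIONS:
            raise ParseError(f"{path}: row {i}: unknown condition {cond!r}")
    onsets = df["onset"].to_numpy(float)
    if np.any(np.diff(onsets) < 0):
        row = int(np.flatnonzero(np.diff(onsets) < 0)[0] + 1)
        raise ParseError(f"{path}: row {row}: onsets out of order")
    if recording_duration is not None:
        beyond = np.flatnonzero(onsets > recording_duration)
        if beyond.size:
            raise ParseError(
                f"{path}: row {int(beyond[0])}: onset "
                f"{onsets[beyond[0]]:.3f} s beyond recording end "
                f"({recording_duration:.3f} s)"
            )
    try:
        return EventTable(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# simulation config sidecar
# ---------------------------------------------------------------------------

def write_sim_config(path: str | Path, config: SimulationConfig) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dataclasses.asdict(config), indent=2, default=list))
    return path


def read_sim_config(path: str | Path) -> SimulationConfig:
    d = json.loads(Path(path).read_text())
    for key in ("target_range", "gap_range", "dense_gap_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


# ---------------------------------------------------------------------------
# dataset layout
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"sub-(?P<sub>[^_]+)_task-(?P<task>[^_]+)_eeg\.npz$")


@dataclass
class DatasetLayout:
    """Index of a dataset directory: (subject, paradigm) -> file paths."""

    root: Path
    entries: dict[tuple[str, str], dict[str, Path]]

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.entries})

    @property
    def paradigms(self) -> list[str]:
        return sorted({p for _, p in self.entries})

    @classmethod
    def scan(cls, root: str | Path) -> "DatasetLayout":
        root = Path(root)
        if not root.is_dir():
            raise ParseError(f"no such dataset directory: {root}")
        entries = {}
        for npz in sorted(root.glob("sub-*/eeg/*_eeg.npz")):
            m = _SUB_RE.search(npz.name)
            if not m:
                continue
            side = _sidecar_paths(npz)
            entries[(f"sub-{m['sub']}", m["task"])] = {
                "recording": npz, **side
            }
        return cls(root, entries)

    def validate(self) -> None:
        """Check every referenced file exists, parses, and is consistent."""
        if not self.entries:
            raise ParseError(f"no recordings found under {self.root}")
        for (sub, task), paths in self.entries.items():
            rec = read_recording(paths["recording"])
            read_events(paths["events"], recording_duration=rec.duration)

    def load(self, subject: str, paradigm: str) -> tuple[ContinuousRecording, EventTable]:
        try:
            paths = self.entries[(subject, paradigm)]
        except KeyError:
            raise ParseError(
                f"no recording for {subject!r} / {paradigm!r} under {self.root}"
            ) from None
        rec = read_recording(paths["recording"])
        events = read_events(paths["events"], recording_duration=rec.duration)
        return rec, events


def write_subject(
    root: str | Path,
    subject: str,
    paradigm: str,
    rec: ContinuousRecording,
    events: EventTable,
    config: SimulationConfig | None = None,
) -> Path:
    """Write one (subject, paradigm) entry into the layout; returns npz path."""
    root = Path(root)
    d = root / subject / "eeg"
    base = d / f"{subject}_task-{paradigm}_eeg.npz"
    write_recording(base, rec)
    side = _sidecar_paths(base)
    write_events(side["events"], events)
    if config is not None:
        write_sim_config(side["sim"], config)
    return base


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def write_epochs(path: str | Path, epochs) -> Path:
    """Serialize an EpochSet: arrays in .npz, metadata in JSON/TSV sidecars."""
    from .core import EpochSet

    path = Path(path)
    if not path.name.endswith("_epochs.npz"):
        raise ParseError(f"epoch container must end in '_epochs.npz': {path.name}")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        data=epochs.data.astype(np.float32),
        times_ms=epochs.times_ms,
    )
    base = path.name[: -len("_epochs.npz")]
    meta = {
        "sampling_rate": epochs.sampling_rate,
        "channel_labels": epochs.channel_labels,
        "channel_groups": epochs.channel_groups,
        "montage2d": {k: list(v) for k, v in epochs.montage2d.items()},
        "conditions": [str(c) for c in epochs.conditions],
    }
    (path.parent / f"{base}_epochs.json").write_text(json.dumps(meta))
    if epochs.events is not None:
        epochs.events.to_csv(
            path.parent / f"{base}_epochevents.tsv", sep="\t", index=False
        )
    return path


def read_epochs(path: str | Path):
    from .core import EpochSet

    path = Path(path)
    base = path.name[: -len("_epochs.npz")]
    meta_path = path.parent / f"{base}_epochs.json"
    if not path.exists() or not meta_path.exists():
        raise ParseError(f"missing epoch container or sidecar for {path}")
    meta = json.loads(meta_path.read_text())
    with np.load(path) as z:
        data = np.asarray(z["data"], float)
        times = np.asarray(z["times_ms"], float)
    ev_path = path.parent / f"{base}_epochevents.tsv"
    events = pd.read_csv(ev_path, sep="\t") if ev_path.exists() else None
    return EpochSet(
        data,
        times,
        float(meta["sampling_rate"]),
        list(meta["channel_labels"]),
        dict(meta["channel_groups"]),
        np.asarray(meta["conditions"], object),
        {k: tuple(v) for k, v in meta["montage2d"].items()},
        events,
    )


# ---------------------------------------------------------------------------
# result tables and filter sidecars
# ---------------------------------------------------------------------------

def write_table(path: str | Path, df: pd.DataFrame, metadata: dict | None = None) -> Path:
    """Tab-separated table with '# key: value' metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, meta


def write_filter(path: str | Path, result) -> Path:
    """Serialize a fitted spatial filter with its training provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "w": list(map(float, result.w)),
        "eigenvalue": result.eigenvalue,
        "shrinkage": result.shrinkage,
        "channel_labels": result.channel_labels,
        "trained_on": list(result.trained_on),
        "ear": result.ear,
        "degenerate_target": result.degenerate_target,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_filter(path: str | Path):
    from .spatialfilter import MaxSNRFilterResult

    d = json.loads(Path(path).read_text())
    C = len(d["w"])
    return MaxSNRFilterResult(
        w=np.asarray(d["w"], float),
        eigenvalue=float(d["eigenvalue"]),
        R_T=np.full((C, C), np.nan),
        R_N=np.full((C, C), np.nan),
        shrinkage=float(d["shrinkage"]),
        channel_labels=d["channel_labels"],
        trained_on=tuple(d["trained_on"]),
        ear=d["ear"],
        degenerate_target=bool(d["degenerate_target"]),
    )
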