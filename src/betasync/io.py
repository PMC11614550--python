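"""Dataset containers, on-disk layout, band-limiting and segmentation.

Layout of one dataset directory (one (subject, week, state) segment):

    lfp.h5            one float32 dataset per channel, attrs: fs, region,
                      channel_id; file attr: fs
    spikes.csv        columns unit_id, region, spike_time_s
    waveforms.h5      one dataset per unit_id (template at 30 kHz), attr fs
    epochs.csv        columns state, start_s, end_s
    manifest.json     subject / week / state / fs and schema version
    ground_truth.json simulator ground truth (absent for real data)

Analysis-side contracts: LFP is band-limited to 0.1-250 Hz and carried at
1 kHz; analyses run on exactly 60-s segments, one per behavioural state,
with at least four electrodes per region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._filters import apply_mask, raised_cosine_lowpass_mask

MOTOR_CORTEX = "motor_cortex"
STRIATUM = "striatum"
REGIONS = (MOTOR_CORTEX, STRIATUM)

ANALYSIS_FS = 1000.0
SEGMENT_S = 60.0
MIN_ELECTRODES_PER_REGION = 4

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when an on-disk dataset violates the documented layout."""


@dataclass
class Recording:
    """Multi-channel continuous signal.

    samples: (n_channels, n_samples); channels: list of (channel_id, region).
    """

    samples: np.ndarray
    fs: float
    channels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_samples)")
        for cid, region in self.channels:
            if region not in REGIONS:
                raise SchemaError(f"channel {cid!r} has unknown region {region!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def region_indices(self, region: str) -> list[int]:
        return [i for i, (_, r) in enumerate(self.channels) if r == region]


@dataclass
class SpikeTrain:
    """A sorted unit: spike times plus a high-rate waveform template."""

    unit_id: str
    region: str
    spike_times_s: np.ndarray
    waveform_template: np.ndarray | None = None
    waveform_fs: float = 30000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be strictly increasing")
        self.spike_times_s = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass
class EpochSet:
    """Behavioural-state epochs: list of (state, start_s, end_s)."""

    epochs: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        by_state: dict[str, list[tuple[float, float]]] = {}
        for state, start, end in self.epochs:
            if not start < end:
                raise ValueError(f"epoch ({state}, {start}, {end}): start must precede end")
            by_state.setdefault(state, []).append((start, end))
        for state, ivals in by_state.items():
            ivals.sort()
            for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {state!r} epochs")

    def for_state(self, state: str) -> list[tuple[float, float]]:
        return sorted((s, e) for st, s, e in self.epochs if st == state)

    @property
    def states(self) -> list[str]:
        seen = []
        for st, _, _ in self.epochs:
            if st not in seen:
                seen.append(st)
        return seen


@dataclass
class Segment:
    """Exactly 60 s of band-limited recording in one behavioural state."""

    recording: Recording
    state: str
    start_s: float
    subject: str = ""
    week: int | None = None
    spikes: list[SpikeTrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_expected = int(round(SEGMENT_S * self.recording.fs))
        if self.recording.samples.shape[1] != n_expected:
            raise ValueError("segment must be exactly 60 s at the analysis rate")
        for region in REGIONS:
            n = len(self.recording.region_indices(region))
            if n < MIN_ELECTRODES_PER_REGION:
                raise ValueError(
                    f"segment has {n} {region} electrodes; "
                    f"at least {MIN_ELECTRODES_PER_REGION} required"
                )


# ---------------------------------------------------------------------------
# on-disk layout


def write_dataset(
    path: str | Path,
    recording: Recording,
    spikes: list[SpikeTrain] | None = None,
    epochs: EpochSet | None = None,
    ground_truth: dict | None = None,
    manifest: dict | None = None,
) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "lfp.h5", "w") as f:
        f.attrs["fs"] = recording.fs
        for i, (cid, region) in enumerate(recording.channels):
            d = f.create_dataset(cid, data=recording.samples[i].astype(np.float32))
            d.attrs["fs"] = recording.fs
            d.attrs["region"] = region
            d.attrs["channel_id"] = cid
    spikes = spikes or []
    pd.DataFrame(
        [
            {"unit_id": u.unit_id, "region": u.region, "spike_time_s": t}
            for u in spikes
            for t in u.spike_times_s
        ],
        columns=["unit_id", "region", "spike_time_s"],
    ).to_csv(path / "spikes.csv", index=False)
    with h5py.File(path / "waveforms.h5", "w") as f:
        for u in spikes:
            if u.waveform_template is not None:
                d = f.create_dataset(u.unit_id, data=u.waveform_template.astype(np.float32))
                d.attrs["fs"] = u.waveform_fs
                d.attrs["region"] = u.region
    if epochs is not None:
        pd.DataFrame(
            [{"state": s, "start_s": a, "end_s": b} for s, a, b in epochs.epochs]
        ).to_csv(path / "epochs.csv", index=False)
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    full_manifest = {"schema_version": SCHEMA_VERSION, "fs": recording.fs}
    full_manifest.update(manifest or {})
    (path / "manifest.json").write_text(json.dumps(full_manifest, indent=1))
    return path


def read_dataset(path: str | Path) -> tuple[Recording, list[SpikeTrain], EpochSet | None]:
    """Read one dataset directory; lossless round-trip for float32 payloads."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    channels: list[tuple[str, str]] = []
    arrays = []
    with h5py.File(path / "lfp.h5", "r") as f:
        fs = float(f.attrs["fs"])
        if "fs" in manifest and float(manifest["fs"]) != fs:
            raise SchemaError(
                f"fs mismatch: manifest says {manifest['fs']}, container says {fs}"
            )
        for cid in sorted(f.keys()):
            d = f[cid]
            if "region" not in d.attrs:
                raise SchemaError(f"channel {cid!r} missing region label")
            channels.append((cid, str(d.attrs["region"])))
            arrays.append(np.asarray(d[...], dtype=np.float32))
    recording = Recording(samples=np.vstack(arrays), fs=fs, channels=channels)

    spikes: list[SpikeTrain] = []
    spikes_csv = path / "spikes.csv"
    if spikes_csv.exists():
        df = pd.read_csv(spikes_csv)
        templates: dict[str, tuple[np.ndarray, float, str]] = {}
        wf_path = path / "waveforms.h5"
        if wf_path.exists():
            with h5py.File(wf_path, "r") as f:
                for uid in f.keys():
                    d = f[uid]
                    templates[uid] = (
                        np.asarray(d[...], dtype=float),
                        float(d.attrs.get("fs", 30000.0)),
                        str(d.attrs.get("region", "")),
                    )
        if len(df):
            for uid, g in df.groupby("unit_id", sort=True):
                tpl, wf_fs, _ = templates.get(str(uid), (None, 30000.0, ""))
                spikes.append(
                    SpikeTrain(
                        unit_id=str(uid),
                        region=str(g["region"].iloc[0]),
                        spike_times_s=np.sort(g["spike_time_s"].to_numpy(float)),
                        waveform_template=tpl,
                        waveform_fs=wf_fs,
                    )
                )

    epochs = None
    epochs_csv = path / "epochs.csv"
    if epochs_csv.exists():
        df = pd.read_csv(epochs_csv)
        epochs = EpochSet(
            [(str(r.state), float(r.start_s), float(r.end_s)) for r in df.itertuples()]
        )
    return recording, spikes, epochs


def read_ground_truth(path: str | Path) -> dict | None:
    p = Path(path) / "ground_truth.json"
    return json.loads(p.read_text()) if p.exists() else None


# ---------------------------------------------------------------------------
# band-limiting and segmentation


def lfp_bandlimit(raw: Recording, fs_out: float = ANALYSIS_FS) -> Recording:
    """Limit a wideband recording to the LFP range and decimate to 1 kHz.

    Zero-phase low-pass at 250 Hz (raised-cosine roll-off, fully attenuated
    by 275 Hz) followed by integer downsampling.  DC is removed, standing in
    for the 0.1 Hz acquisition high-pass corner, which is below the spectral
    resolution of 60-s band analyses.  Zero phase preserves spike-LFP timing.
    """
    if raw.fs < fs_out:
        raise ValueError(f"input fs {raw.fs} must be >= {fs_out}")
    q = raw.fs / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"input fs {raw.fs} must be an integer multiple of {fs_out}")
    q = int(round(q))
    filtered = apply_mask(
        raw.samples, raw.fs, raised_cosine_lowpass_mask, cutoff_hz=250.0, transition_hz=25.0
    )
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    out = filtered[:, ::q]
    return Recording(samples=out, fs=fs_out, channels=list(raw.channels))


def assemble_segments(
    recording: Recording,
    epochs: EpochSet,
    spikes: list[SpikeTrain] | None = None,
    subject: str = "",
    week: int | None = None,
) -> list[Segment]:
    """One 60-s segment per behavioural state.

    The segment is cut from the earliest epoch of that state that is at
    least 60 s long ([start, start + 60) half-open).  States with no
    qualifying epoch are skipped with a warning.  Spike times are re-based
    to the segment start and clipped to it.
    """
    segments: list[Segment] = []
    for state in epochs.states:
        chosen = None
        for start, end in epochs.for_state(state):
            if end - start >= SEGMENT_S:
                chosen = start
                break
        if chosen is None:
            warnings.warn(
                f"no {state!r} epoch of at least {SEGMENT_S:.0f} s; state skipped",
                stacklevel=2,
            )
            continue
        i0 = int(round(chosen * recording.fs))
        i1 = i0 + int(round(SEGMENT_S * recording.fs))
        sliced = Recording(
            samples=recording.samples[:, i0:i1],
            fs=recording.fs,
            channels=list(recording.channels),
        )
        seg_spikes = []
        for u in spikes or []:
            t = u.spike_times_s
            keep = t[(t >= chosen) & (t < chosen + SEGMENT_S)] - chosen
            seg_spikes.append(
                SpikeTrain(
                    unit_id=u.unit_id,
                    region=u.region,
                    spike_times_s=keep,
                    waveform_template=u.waveform_template,
                    waveform_fs=u.waveform_fs,
                )
            )
        segments.append(
            Segment(
                recording=sliced,
                state=state,
                start_s=chosen,
                subject=subject,
                week=week,
                spikes=seg_spikes,
            )
        )
    return segments
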