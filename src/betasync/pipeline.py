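"""End-to-end orchestration: simulate/read -> preprocess -> spectral /
coherence / spike-field / unit metrics -> group statistics.

Every run is fully determined by (config, master seed); artefacts are plain
CSV/JSON files whose headers are fixed, and the run manifest records the
config hash and seed so each number is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .bands import DEFAULT_BANDS, BandTable
from .coherence import region_pair_coherence
from .io import (
    ANALYSIS_FS,
    MOTOR_CORTEX,
    REGIONS,
    STRIATUM,
    Segment,
    assemble_segments,
    lfp_bandlimit,
    read_dataset,
)
from .spectral import DEFAULT_WELCH, WelchSettings, band_power, peak_frequency, welch_psd
from .spikefield import (
    instantaneous_phase,
    phase_locked_summary,
    rayleigh_test,
    select_target_channel,
    spike_phases,
    stwa_shuffle_ratio,
)
from .stats import chi_square_2x2, compare_groups
from .units import classify_unit, refractory_check, trough_to_peak, UnitFeatures

log = logging.getLogger("betasync")


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable and hashed into the manifest."""

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    data_dir: str | None = None  # read datasets from disk instead of simulating
    bands: BandTable = field(default_factory=BandTable)
    analysis_band: str = "high_beta"
    welch: WelchSettings = field(default_factory=WelchSettings)
    subsample_n: int = 40
    n_shuffle: int = 20
    window_ms: float = 100.0
    alpha: float = 0.05
    ttp_threshold_ms: float = 0.30
    rate_ceiling_hz: float = 20.0
    seed: int = 0

    def config_hash(self) -> str:
        def stringify(o):
            if isinstance(o, dict):
                return {str(k): stringify(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [stringify(v) for v in o]
            return o

        blob = json.dumps(stringify(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    band_power: pd.DataFrame
    coherence: pd.DataFrame
    spikefield: pd.DataFrame
    units: pd.DataFrame
    stats: dict
    manifest: dict


def make_demo_config(scale: str = "smoke", seed: int = 0) -> PipelineConfig:
    """Preset configurations: ``smoke`` is a minutes-scale demonstration,
    ``full`` the cohort used for the recovery experiments."""
    if scale == "smoke":
        cohort = synth.CohortConfig(weeks=(2,), n_subjects_per_group=2)
    elif scale == "full":
        cohort = synth.CohortConfig(weeks=(2, 4), n_subjects_per_group=8)
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'smoke' or 'full'")
    return PipelineConfig(cohort=cohort, seed=seed)


def _iter_segments(config: PipelineConfig):
    if config.data_dir is not None:
        root = Path(config.data_dir)
        manifest_path = root / "cohort_manifest.json"
        entries = (
            json.loads(manifest_path.read_text())
            if manifest_path.exists()
            else [{"path": p.name} for p in sorted(root.iterdir()) if p.is_dir()]
        )
        for entry in entries:
            recording, spikes, epochs = read_dataset(root / entry["path"])
            if recording.fs != ANALYSIS_FS:
                recording = lfp_bandlimit(recording)
            meta = json.loads((root / entry["path"] / "manifest.json").read_text())
            meta.setdefault("group", entry.get("group", meta.get("subject", "")))
            segs = assemble_segments(
                recording,
                epochs,
                spikes=spikes,
                subject=meta.get("subject", entry["path"]),
                week=meta.get("week"),
            )
            for seg in segs:
                yield {**meta, "state": seg.state}, seg
    else:
        for meta, segment, _truth in synth.iter_cohort_segments(config.cohort, config.seed):
            yield meta, segment


def _segment_spectral_rows(config: PipelineConfig, meta: dict, segment: Segment):
    rows = []
    rec = segment.recording
    for i, (cid, region) in enumerate(rec.channels):
        psd = welch_psd(rec.samples[i], rec.fs, config.welch)
        total = float(np.trapezoid(psd.power, psd.frequencies))
        for name, band in config.bands.items():
            p = band_power(psd, band)
            rows.append(
                {
                    "subject": meta["subject"],
                    "group": meta["group"],
                    "week": meta["week"],
                    "state": meta["state"],
                    "region": region,
                    "channel": cid,
                    "band": name,
                    "power": p,
                    "relative_power": p / total if total > 0 else np.nan,
                    "peak_hz": peak_frequency(psd, band),
                    "n_windows": psd.n_windows,
                }
            )
    return rows


def _segment_spikefield_rows(config: PipelineConfig, meta: dict, segment: Segment, seed_seq):
    rows = []
    band = config.bands[config.analysis_band]
    rec = segment.recording
    targets = {}
    phases = {}
    for region in REGIONS:
        ti = select_target_channel(segment, region, band)
        targets[region] = ti
        phases[region] = instantaneous_phase(rec.samples[ti], rec.fs, band)
    children = seed_seq.spawn(max(len(segment.spikes), 1) * 2)
    it = iter(children)
    for unit in segment.spikes:
        for region in REGIONS:
            child = next(it) if segment.spikes else None
            rng = np.random.default_rng(child)
            angles, _ = spike_phases(unit.spike_times_s, phases[region], rec.fs)
            pl = rayleigh_test(
                angles, config.subsample_n, rng, unit_id=unit.unit_id, target_region=region
            )
            row = {
                "subject": meta["subject"],
                "group": meta["group"],
                "week": meta["week"],
                "state": meta["state"],
                "unit_id": unit.unit_id,
                "target_region": region,
                "target_channel": rec.channels[targets[region]][0],
                "n_spikes": unit.n_spikes,
                "r": pl.r,
                "z": pl.z,
                "p": pl.p,
                "preferred_phase": pl.preferred_phase,
                "locked": pl.locked,
                "excluded": pl.excluded,
                "exclusion_reason": pl.exclusion_reason,
            }
            if not pl.excluded:
                try:
                    sr = stwa_shuffle_ratio(
                        unit,
                        rec.samples[targets[region]],
                        rec.fs,
                        band,
                        config.window_ms,
                        config.n_shuffle,
                        rng,
                        target_region=region,
                    )
                    row.update(
                        peak_to_trough=sr.peak_to_trough,
                        shuffle_mean=float(np.mean(sr.shuffle_magnitudes)),
                        ratio=sr.ratio,
                    )
                except ZeroDivisionError:
                    row.update(peak_to_trough=np.nan, shuffle_mean=np.nan, ratio=np.nan)
                    row["exclusion_reason"] = "degenerate-ratio"
            else:
                row.update(peak_to_trough=np.nan, shuffle_mean=np.nan, ratio=np.nan)
            rows.append(row)
    return rows


def _segment_unit_rows(config: PipelineConfig, meta: dict, segment: Segment):
    rows = []
    for unit in segment.spikes:
        rate = unit.n_spikes / segment.recording.duration_s
        frac, ok = refractory_check(unit.spike_times_s)
        ttp = np.nan
        cls = ""
        if unit.waveform_template is not None:
            try:
                ttp = trough_to_peak(unit.waveform_template, unit.waveform_fs)
                cls = classify_unit(
                    UnitFeatures(unit.unit_id, ttp, rate),
                    config.ttp_threshold_ms,
                    config.rate_ceiling_hz,
                )
            except ValueError:
                cls = "invalid_waveform"
        rows.append(
            {
                "subject": meta["subject"],
                "group": meta["group"],
                "week": meta["week"],
                "state": meta["state"],
                "unit_id": unit.unit_id,
                "region": unit.region,
                "trough_to_peak_ms": ttp,
                "rate_hz": rate,
                "class": cls,
                "violation_fraction": frac,
                "refractory_pass": ok,
            }
        )
    return rows


def _group_stats(config: PipelineConfig, bp: pd.DataFrame, coh: pd.DataFrame, sf: pd.DataFrame) -> dict:
    """ANOVAs on rest-state high-beta power and coherence, plus the locked
    proportion chi-square; rest epochs carry the biomarker comparison."""
    out: dict = {"alpha": config.alpha}
    band = config.analysis_band
    rest_bp = bp[(bp["band"] == band) & (bp["state"] == "rest")]
    for region in REGIONS:
        sub = (
            rest_bp[rest_bp["region"] == region]
            .groupby(["group", "subject"], observed=True)["power"]
            .mean()
            .reset_index()
        )
        groups = {g: d["power"].to_numpy() for g, d in sub.groupby("group", observed=True)}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            res = compare_groups(groups)
            out[f"power_{region}"] = {
                "test": res.test,
                "statistic": res.statistic,
                "df": list(res.df),
                "p": res.p,
                "posthoc": [
                    {"pair": list(r["pair"]), "p_adjusted": r["p_adjusted"]} for r in res.posthoc
                ],
            }
    rest_coh = coh[(coh["state"] == "rest") & coh["is_summary"]]
    groups = {
        g: d.groupby("subject", observed=True)["band_mean"].mean().to_numpy()
        for g, d in rest_coh.groupby("group", observed=True)
    }
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        res = compare_groups(groups)
        out["coherence"] = {
            "test": res.test,
            "statistic": res.statistic,
            "df": list(res.df),
            "p": res.p,
        }
    tested = sf[(sf["state"] == "rest") & (~sf["excluded"])]
    if len(tested):
        from types import SimpleNamespace

        by_group = {
            g: [SimpleNamespace(locked=bool(l), excluded=False) for l in d["locked"]]
            for g, d in tested.groupby("group", observed=True)
        }
        summary = phase_locked_summary(by_group)
        out["locked_proportions"] = summary
        names = list(summary)
        if len(names) >= 2:
            a, b = names[0], names[1]
            try:
                chi = chi_square_2x2(
                    summary[a]["n_locked"],
                    summary[a]["n_tested"],
                    summary[b]["n_locked"],
                    summary[b]["n_tested"],
                )
                out["locked_chi_square"] = {
                    "groups": [a, b],
                    "statistic": chi.statistic,
                    "df": list(chi.df),
                    "p": chi.p,
                }
            except ValueError as exc:
                out["locked_chi_square"] = {"error": str(exc)}
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute every stage over the cohort and return (and optionally
    write) the report bundle.  Per-segment failures are logged and the
    segment skipped; the run continues."""
    bp_rows: list[dict] = []
    coh_rows: list[dict] = []
    sf_rows: list[dict] = []
    unit_rows: list[dict] = []
    master = np.random.SeedSequence([config.seed, 0xB5])
    band = config.bands[config.analysis_band]
    n_failed = 0
    for meta, segment in _iter_segments(config):
        try:
            bp_rows.extend(_segment_spectral_rows(config, meta, segment))
            summary, pairs = region_pair_coherence(segment, band, config.welch)
            for r in pairs.to_dict("records"):
                coh_rows.append(
                    {
                        "subject": meta["subject"],
                        "group": meta["group"],
                        "week": meta["week"],
                        "state": meta["state"],
                        **r,
                        "is_summary": False,
                    }
                )
            coh_rows.append(
                {
                    "subject": meta["subject"],
                    "group": meta["group"],
                    "week": meta["week"],
                    "state": meta["state"],
                    "pair_id": "summary",
                    "band_mean": summary,
                    "n_windows": int(pairs["n_windows"].iloc[0]),
                    "is_summary": True,
                }
            )
            seg_seed = master.spawn(1)[0]
            sf_rows.extend(_segment_spikefield_rows(config, meta, segment, seg_seed))
            unit_rows.extend(_segment_unit_rows(config, meta, segment))
        except Exception:
            n_failed += 1
            log.exception(
                "segment failed: subject=%s week=%s state=%s",
                meta.get("subject"),
                meta.get("week"),
                meta.get("state"),
            )
    bp = pd.DataFrame(bp_rows)
    coh = pd.DataFrame(coh_rows)
    sf = pd.DataFrame(sf_rows)
    units = pd.DataFrame(unit_rows)
    stats = _group_stats(config, bp, coh, sf) if len(bp) else {}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_segments_failed": n_failed,
        "n_units_excluded": int(sf["excluded"].sum()) if len(sf) else 0,
        "software": "betasync 0.1.0",
    }
    bundle = ReportBundle(bp, coh, sf, units, stats, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bp.to_csv(out / "band_power.csv", index=False)
        coh.to_csv(out / "coherence.csv", index=False)
        sf.to_csv(out / "spikefield.csv", index=False)
        units.to_csv(out / "units.csv", index=False)
        (out / "stats.json").write_text(json.dumps(stats, indent=1, default=float))
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle
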