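"""End-to-end orchestration: simulate or ingest, preprocess, classify, compare.

A run is described by one plain-text (YAML) configuration and one root
seed; every random stage draws a named substream of that seed, so a run
is reproducible bit for bit and each artifact records the configuration
hash and seed it came from.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, classify, io, phase_plane, preprocess, stats, synthetic
from .core import AngleSeries, substream

log = logging.getLogger("trisync")

#: Classes whose occurrence the group comparison aggregates.
FAMILIES = ("R", "PA", "PI")


@dataclass
class RunConfig:
    """Configuration of one trial run or one group comparison."""

    seed: int = 0
    out_dir: str | None = None
    # trial input: either a simulation spec or paths
    pattern: dict[str, Any] = field(default_factory=dict)
    angles_csv: str | None = None
    tracks_csv: str | None = None
    control_points_csv: str | None = None
    # stage parameters
    noise_sd: float = 0.0
    filter: dict[str, Any] = field(default_factory=dict)
    classifier: dict[str, Any] = field(default_factory=dict)
    density_bins: int = 60
    min_segment_duration: float | None = None
    # group comparison
    groups: dict[str, Any] = field(default_factory=dict)
    n_permutations: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict[str, Any]:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
    }


def _simulate_trial(config: RunConfig, trial_seed: int) -> AngleSeries:
    """One synthetic trial; optional position noise goes through tracks."""
    spec_kwargs = dict(config.pattern)
    spec_kwargs.setdefault("label", "R")
    spec = synthetic.PatternSpec(seed=trial_seed, **spec_kwargs)
    series = synthetic.generate(spec)
    if config.noise_sd > 0:
        tracks = synthetic.angles_to_tracks(
            series, noise_sd=config.noise_sd, seed=trial_seed
        )
        # synthetic tracks carry the oscillation band on both axes, so the
        # smoothing filter must pass it (unlike the slow-translation
        # defaults appropriate for real recordings)
        filt = config.filter or {"cutoff_x": 2.0, "cutoff_y": 2.0}
        tracks = preprocess.lowpass(tracks, preprocess.FilterSpec(**filt))
        series = preprocess.extract_angles(tracks)
    return series


def _load_trial(config: RunConfig) -> AngleSeries:
    if config.angles_csv:
        return io.read_angles_csv(config.angles_csv)
    tracks = io.read_tracks_csv(config.tracks_csv)
    if config.control_points_csv:
        cps = io.read_control_points_csv(config.control_points_csv)
        h = preprocess.fit_dlt(cps)
        tracks = replace(tracks, positions=preprocess.map_to_world(h, tracks.positions))
    tracks = preprocess.lowpass(tracks, preprocess.FilterSpec(**config.filter))
    return preprocess.extract_angles(tracks)


def analyze_series(series: AngleSeries, config: RunConfig) -> dict[str, Any]:
    """Classify one angle series and summarize its pattern frequencies."""
    segments = preprocess.apply_exclusion(series, config.min_segment_duration)
    valid_duration = sum(s.duration for s in segments)
    labelled = [classify.classify_triple(s, **config.classifier) for s in segments]
    durations = {label: 0.0 for label in classify.TRIPLE_LABELS}
    all_segments = []
    for lab in labelled:
        for label, d in lab.label_durations().items():
            durations[label] += d
        all_segments.extend(lab.segments)
    freq = {
        label: (100.0 * d / valid_duration if valid_duration else 0.0)
        for label, d in durations.items()
    }
    family_freq = {
        "R": freq["R"],
        "PA": freq["PA1"] + freq["PA2"],
        "PI": freq["PI1"] + freq["PI2"],
    }
    return {
        "frequencies": freq,
        "family_frequencies": family_freq,
        "segments": all_segments,
        "labelled": labelled,
        "series": series,
        "valid_duration": valid_duration,
    }


def run_trial(config: RunConfig) -> dict[str, Any]:
    """Execute the full chain on one trial and optionally write artifacts."""
    if config.angles_csv or config.tracks_csv:
        series = _load_trial(config)
    else:
        series = _simulate_trial(config, config.seed)
    result = analyze_series(series, config)
    traj = phase_plane.embed(series)
    grid = phase_plane.occupancy_density(traj, bins=config.density_bins)
    dominant = max(result["family_frequencies"], key=result["family_frequencies"].get)
    report = {
        "provenance": _provenance(config),
        "frequencies": result["frequencies"],
        "family_frequencies": result["family_frequencies"],
        "dominant_family": dominant,
        "valid_duration_s": result["valid_duration"],
        "n_segments": len(result["segments"]),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_angles_csv(out / "angles.csv", series)
        merged = classify.PatternLabelSegments(
            intervals=[], segments=result["segments"]
        )
        io.write_labels_csv(out / "labels.csv", merged)
        io.write_frequencies_csv(
            out / "freq.csv",
            [{"trial": 0, "label": k, "percent": v} for k, v in result["frequencies"].items()],
        )
        io.write_density_csv(out / "density.csv", grid)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _group_trials(
    name: str, group_cfg: dict[str, Any], config: RunConfig
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Simulate and analyze all trials of one group.

    Group config keys: ``pattern`` (spec kwargs), ``n_trials``,
    ``n_subgroups``, optional ``jitter`` (fractional amplitude/frequency
    spread across trials) and ``noise_sd``.
    """
    n_trials = int(group_cfg.get("n_trials", 8))
    n_subgroups = int(group_cfg.get("n_subgroups", 4))
    if n_trials < 2:
        raise ValueError(f"group {name!r} needs at least 2 trials")
    jitter = float(group_cfg.get("jitter", 0.1))
    noise_sd = float(group_cfg.get("noise_sd", config.noise_sd))
    base = dict(group_cfg.get("pattern", {}))
    base.setdefault("label", "R")
    rows, freqs = [], []
    rng = substream(config.seed, "group", name)
    for trial in range(n_trials):
        kwargs = dict(base)
        scale = 1.0 + jitter * rng.uniform(-1.0, 1.0)
        kwargs["amplitude"] = kwargs.get("amplitude", 0.3) * scale
        kwargs["frequency"] = kwargs.get("frequency", 0.5) * (
            1.0 + jitter * rng.uniform(-1.0, 1.0)
        )
        kwargs["phase0"] = float(rng.uniform(0.0, 2.0 * np.pi))
        trial_seed = int(rng.integers(2**31 - 1))
        trial_cfg = replace(
            config, pattern=kwargs, noise_sd=noise_sd, out_dir=None
        )
        series = _simulate_trial(trial_cfg, trial_seed)
        result = analyze_series(series, config)
        fam = result["family_frequencies"]
        freqs.append([fam[f] for f in FAMILIES])
        rows.append(
            {
                "group": name,
                "trial": trial,
                "subgroup": trial % n_subgroups,
                **{f: fam[f] for f in FAMILIES},
            }
        )
    subgroups = np.array([r["subgroup"] for r in rows])
    return np.array(freqs), subgroups, rows


def run_group_comparison(config: RunConfig) -> dict[str, Any]:
    """Simulate two groups, classify every trial, and run both tests."""
    if set(config.groups) != {"a", "b"}:
        raise ValueError("groups config must define exactly groups 'a' and 'b'")
    freq_a, sub_a, rows_a = _group_trials("a", config.groups["a"], config)
    freq_b, sub_b, rows_b = _group_trials("b", config.groups["b"], config)
    res_trials = stats.perm_test_trials(
        freq_a, freq_b, config.n_permutations, seed=config.seed
    )
    res_sub = stats.perm_test_subgroups(
        freq_a, sub_a, freq_b, sub_b, config.n_permutations, seed=config.seed
    )
    report = {
        "provenance": _provenance(config),
        "trials": rows_a + rows_b,
        "group_means": {
            "a": dict(zip(FAMILIES, freq_a.mean(axis=0))),
            "b": dict(zip(FAMILIES, freq_b.mean(axis=0))),
        },
        "perm_test_trials": {
            "statistic": res_trials.statistic,
            "p_value": res_trials.p_value,
            "method": res_trials.method,
            "n_permutations": res_trials.n_permutations,
        },
        "perm_test_subgroups": {
            "statistic": res_sub.statistic,
            "p_value": res_sub.p_value,
            "method": res_sub.method,
            "n_permutations": res_sub.n_permutations,
        },
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_frequencies_csv(out / "freq.csv", rows_a + rows_b)
        with open(out / "comparison.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
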