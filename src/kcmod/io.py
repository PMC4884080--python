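"""Serialization, configuration and the end-to-end pipeline.

Everything the pipeline writes is deterministic given (config, seed): no
timestamps or absolute paths appear in any output, and the run manifest
records the master seed plus a SHA-256 of every written file, so two runs
with the same configuration produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocols import ClassifierConfig, EphysProtocol, LIGHT, ODOR
from .synth import (
    CellProfile,
    EphysDataset,
    StimulusResponse,
    TrialRecording,
    generate_population,
    study_design,
)
from .ephys import ResponseCall, ResponseCategory, classify_population, detect_spikes
from .contingency import build_table, collapse_table, exact_test
from .behavior import (
    generate_arena_experiment,
    learning_index,
    signed_preference,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "write_dataset",
    "read_dataset",
    "write_calls",
    "read_calls",
    "run_pipeline",
    "simulate_and_classify",
]


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """All protocol constants and pipeline options in one serializable bag."""

    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    n_gamma_d: int = 12
    n_alpha_beta: int = 11
    n_light_stimuli: int = 2
    n_odor_stimuli: int = 5
    n_trials: int = 6
    noise_sd_mv: float = 1.0
    arena_n_flies: int = 40
    arena_bias: float = 0.3
    arena_n_frames: int = 90
    arena_frame_rate_hz: float = 1.0
    olfactory_duration_s: float = 120.0
    olfactory_window_s: float = 10.0
    n_arena_experiments: int = 8
    master_seed: int = 0
    persist_traces: bool = False

    def __post_init__(self) -> None:
        for name in (
            "n_gamma_d", "n_alpha_beta", "n_light_stimuli", "n_odor_stimuli",
            "n_trials", "arena_n_flies", "arena_n_frames", "n_arena_experiments",
        ):
            if getattr(self, name) < 0 or (name == "n_trials" and self.n_trials < 1):
                raise ValueError(f"{name} must be non-negative (n_trials >= 1)")
        if not 0 <= self.arena_bias <= 1:
            raise ValueError("arena_bias must be in [0, 1]")
        if self.noise_sd_mv <= 0:
            raise ValueError("noise_sd_mv must be positive")
        if self.olfactory_window_s <= 0 or self.olfactory_window_s > self.olfactory_duration_s:
            raise ValueError("olfactory window must be positive and fit in the test")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"] = self.classifier.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "classifier" in d:
            d["classifier"] = ClassifierConfig.from_dict(d["classifier"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# dataset serialization


def write_dataset(dataset: EphysDataset, directory, fmt: str = "hdf5") -> None:
    """Write trials + metadata + ground truth under ``directory``.

    ``fmt`` is 'hdf5' (one array per trial in trials.h5) or 'csv'
    (long-format trials.csv; intended for small datasets only).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: List[dict] = []
    truth: List[dict] = []
    for i, tr in enumerate(dataset.trials):
        meta.append(
            {
                "key": f"trial_{i:05d}",
                "cell_id": tr.cell_id,
                "cell_type": tr.cell_type,
                "stimulus_id": tr.stimulus_id,
                "modality": tr.modality,
                "trial_index": tr.trial_index,
                "protocol": tr.protocol.to_dict(),
            }
        )
        truth.append(
            {
                "key": f"trial_{i:05d}",
                "spike_times_s": [float(t) for t in tr.true_spike_times_s],
                "epsp_peak_mv": tr.true_event_peaks_mv[0],
                "ipsp_peak_mv": tr.true_event_peaks_mv[1],
            }
        )
    if fmt == "hdf5":
        with h5py.File(directory / "trials.h5", "w", track_order=False) as f:
            for i, tr in enumerate(dataset.trials):
                f.create_dataset(
                    f"trial_{i:05d}", data=tr.voltage_mv, track_times=False
                )
    elif fmt == "csv":
        frames = []
        for i, tr in enumerate(dataset.trials):
            frames.append(
                pd.DataFrame(
                    {
                        "key": f"trial_{i:05d}",
                        "sample_index": np.arange(len(tr.voltage_mv)),
                        "voltage_mv": tr.voltage_mv,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(directory / "trials.csv", index=False)
    else:
        raise ValueError("fmt must be 'hdf5' or 'csv'")
    (directory / "metadata.json").write_text(json.dumps({"format": fmt, "trials": meta}, indent=1))
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))


def read_dataset(directory) -> EphysDataset:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    truth_list = json.loads((directory / "truth.json").read_text())
    truth = {t["key"]: t for t in truth_list}
    fmt = meta["format"]
    voltages: Dict[str, np.ndarray] = {}
    if fmt == "hdf5":
        with h5py.File(directory / "trials.h5", "r") as f:
            for k in f:
                voltages[k] = f[k][...]
    else:
        df = pd.read_csv(directory / "trials.csv")
        for k, grp in df.groupby("key"):
            # traces are stored single-precision; the text round-trip is exact
            # once cast back to float32
            voltages[k] = (
                grp.sort_values("sample_index")["voltage_mv"].to_numpy().astype(np.float32)
            )
    trials = []
    for m in meta["trials"]:
        t = truth[m["key"]]
        trials.append(
            TrialRecording(
                cell_id=m["cell_id"],
                cell_type=m["cell_type"],
                stimulus_id=m["stimulus_id"],
                modality=m["modality"],
                trial_index=m["trial_index"],
                voltage_mv=voltages[m["key"]],
                protocol=EphysProtocol.from_dict(m["protocol"]),
                true_spike_times_s=np.asarray(t["spike_times_s"], dtype=float),
                true_event_peaks_mv=(t["epsp_peak_mv"], t["ipsp_peak_mv"]),
            )
        )
    return EphysDataset(trials)


def write_calls(calls: Sequence[ResponseCall], path) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "cell_type": [c.cell_type for c in calls],
            "stimulus_id": [c.stimulus_id for c in calls],
            "modality": [c.modality for c in calls],
            "category": [c.category.value for c in calls],
            "peak_mv": [c.peak_amplitude_mv for c in calls],
            "z": [c.z_score for c in calls],
            "n_trials": [c.n_trials for c in calls],
            "evoked_spikes": [c.evoked_spike_count for c in calls],
            "baseline_spikes": [c.baseline_spike_count for c in calls],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_calls(path) -> List[ResponseCall]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ResponseCall(
            cell_id=r.cell_id,
            cell_type=r.cell_type,
            stimulus_id=r.stimulus_id,
            modality=r.modality,
            category=ResponseCategory(r.category),
            peak_amplitude_mv=float(r.peak_mv),
            z_score=float(r.z),
            n_trials=int(r.n_trials),
            evoked_spike_count=int(r.evoked_spikes),
            baseline_spike_count=int(r.baseline_spikes),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# pipeline


def simulate_and_classify(
    profiles: Sequence[CellProfile],
    stimuli: Dict[str, EphysProtocol],
    config: ClassifierConfig,
    n_trials: int = 6,
    seed=0,
) -> List[ResponseCall]:
    """Generate and classify pair by pair without holding all traces.

    Statistically identical to ``classify_population(generate_population(...))``
    (same seed substreams) but with memory bounded by one pair's trials —
    the right entry point for replicate simulations.
    """
    from .synth import generate_pair_trials
    from .ephys import classify_pair

    for p in profiles:
        for s in stimuli:
            p.response_for(s)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    keys = [(p, s) for p in profiles for s in sorted(stimuli)]
    calls = []
    for (p, s), child in zip(keys, ss.spawn(max(len(keys), 1))):
        trials = generate_pair_trials(p, s, stimuli[s], n_trials, child)
        calls.append(classify_pair(trials, config))
    return calls


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """simulate -> classify -> tabulate -> exact test, plus the arena branch.

    Writes calls.csv, spikes.csv, contingency.json, li.csv,
    behavior_summary.json and manifest.json under ``out_dir`` and returns the
    manifest.  All randomness flows from ``config.master_seed`` via named
    substreams, so identical configs yield identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.master_seed)
    ss_ephys, ss_arena = root.spawn(2)

    # --- ephys branch -----------------------------------------------------
    profiles, stimuli = study_design(
        config.n_gamma_d,
        config.n_alpha_beta,
        config.n_light_stimuli,
        config.n_odor_stimuli,
        config.noise_sd_mv,
    )
    dataset = generate_population(profiles, stimuli, config.n_trials, ss_ephys)
    if config.persist_traces:
        write_dataset(dataset, out / "ephys_data", fmt="hdf5")
    calls = classify_population(dataset, config.classifier)
    write_calls(calls, out / "calls.csv")

    spikes_rows = []
    for tr in dataset.trials:
        train = detect_spikes(tr, config.classifier)
        for t in train.spike_times_s:
            spikes_rows.append((tr.cell_id, tr.stimulus_id, tr.trial_index, t))
    pd.DataFrame(
        spikes_rows, columns=["cell_id", "stimulus_id", "trial_index", "spike_time_s"]
    ).to_csv(out / "spikes.csv", index=False)

    contingency: Dict[str, dict] = {}
    for modality in ("light", "odor"):
        sub = [c for c in calls if c.modality == modality]
        if not sub:
            continue
        table = build_table(sub, row_order=["gamma_d", "alpha_beta"])
        res_full = exact_test(table)
        collapsed = collapse_table(table)
        res_coll = exact_test(collapsed)
        contingency[modality] = {
            "table": table.to_dict(),
            "p_full": res_full.p_value,
            "n_tables_full": res_full.n_tables_enumerated,
            "collapsed_table": collapsed.to_dict(),
            "p_collapsed": res_coll.p_value,
            "method": res_full.method,
        }
    (out / "contingency.json").write_text(json.dumps(contingency, indent=1))

    # --- behavior branch --------------------------------------------------
    li_rows = []
    pooled = []
    for i, child in enumerate(ss_arena.spawn(config.n_arena_experiments)):
        g1, g2 = generate_arena_experiment(
            n_flies=config.arena_n_flies,
            bias=config.arena_bias,
            n_frames=config.arena_n_frames,
            seed=child,
        )
        res = learning_index(signed_preference(g1), signed_preference(g2))
        pooled.append(res.pooled_li)
        for f, v in enumerate(res.li_per_frame):
            li_rows.append((i, f, v))
    pd.DataFrame(li_rows, columns=["experiment", "frame", "li"]).to_csv(
        out / "li.csv", index=False
    )
    behavior_summary = {
        "n_experiments": config.n_arena_experiments,
        "bias": config.arena_bias,
        "pooled_li_mean": float(np.mean(pooled)) if pooled else None,
        "pooled_li_sd": float(np.std(pooled, ddof=1)) if len(pooled) > 1 else None,
        "pooled_li": pooled,
    }
    (out / "behavior_summary.json").write_text(json.dumps(behavior_summary, indent=1))

    # --- manifest ---------------------------------------------------------
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
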