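"""Config-driven end-to-end runs with a checksummed artifact manifest.

A run executes simulate -> preprocess -> detect-windows -> score-trials ->
stats in dependency order, writing every artifact under the configured
output directory and recording path, sha256 and the seed chain in
``manifest.json``.  A stage failure halts the run with a stage-named error;
artifacts written before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomy, behavior, io, photometry, synth

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    duration_s: float = 900.0
    fs: float = 1017.25
    n_mice: int = 3
    bin_s: float = 0.3
    analysis_span_s: tuple[float, float] = (0.0, 3.9)
    alpha: float = 0.05
    n_perm: int = 5000
    inputs: dict | None = None  # optional pre-existing input paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.read_yaml(path) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analysis_span_s" in raw:
            raw["analysis_span_s"] = tuple(raw["analysis_span_s"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_span_s"] = list(d["analysis_span_s"])
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    if config.inputs:
        for name, p in config.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input {name!r} not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash only analysis-relevant fields so equal analyses in different
    # output directories are byte-comparable
    hashable = {k: v for k, v in config.to_dict().items() if k not in ("outdir",)}
    chash = io.config_hash(hashable)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "artifacts": {},
        "stages": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": io.file_checksum(path),
        }

    state: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"].append(name)
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                _write_manifest(outdir, manifest)
                raise StageError(name, e) from e

        return deco

    @stage("simulate")
    def _simulate():
        sessions = []
        for m in range(config.n_mice):
            cfg = synth.SimulationConfig(
                seed=config.seed * 1000 + m,
                duration_s=config.duration_s,
                fs=config.fs,
            )
            trials = synth.generate_trial_schedule(cfg)
            session, truth = synth.generate_photometry_session(cfg, trials)
            hyp, eeg_tr, emg_tr = synth.generate_sleep_records(cfg)
            spath = outdir / f"session_m{m}.h5"
            io.write_session(
                spath, session, eeg=eeg_tr, emg=emg_tr,
                attrs={"config_hash": chash, "seed": cfg.seed},
            )
            trials["baseline_state"] = "NREM"
            trials["outcome"] = truth.trial_outcomes
            trials["mouse"] = f"m{m}"
            tpath = outdir / f"trials_m{m}.csv"
            io.write_table(tpath, trials)
            hpath = outdir / f"hypnogram_m{m}.csv"
            io.write_table(hpath, hyp)
            io.write_yaml(
                outdir / f"truth_m{m}.yaml",
                {
                    "true_windows": [list(w) for w in truth.true_windows],
                    "trial_outcomes": truth.trial_outcomes,
                },
            )
            record(f"session_m{m}", spath)
            record(f"trials_m{m}", tpath)
            record(f"hypnogram_m{m}", hpath)
            record(f"truth_m{m}", outdir / f"truth_m{m}.yaml")
            sessions.append((cfg, session, trials, truth, hyp))
        counts, _ = synth.generate_cell_counts(
            {"PRN": 8, "BF": 7}, missing_slice_prob=0.3, seed=config.seed
        )
        cpath = outdir / "cell_counts.csv"
        io.write_table(cpath, counts)
        record("cell_counts", cpath)
        state["sessions"] = sessions
        state["cell_counts"] = counts

    @stage("preprocess")
    def _preprocess():
        epochs = []
        for cfg, session, trials, truth, _ in state["sessions"]:
            fit = photometry.fit_isosbestic(session)
            dff = photometry.compute_dff(session, fit)
            ep = photometry.epoch_trials(dff, trials["onset_s"].to_numpy())
            epochs.append(ep)
        state["epochs"] = epochs
        epath = outdir / "epochs_mouse0.csv"
        pd.DataFrame(epochs[0].data, columns=np.round(epochs[0].t, 4)).to_csv(
            epath, index=False
        )
        record("epochs_mouse0", epath)

    @stage("detect-windows")
    def _detect():
        res = photometry.detect_response_windows(
            state["epochs"],
            bin_s=config.bin_s,
            analysis_span_s=config.analysis_span_s,
            alpha=config.alpha,
            seed=config.seed,
        )
        wpath = outdir / "windows.json"
        with open(wpath, "w") as f:
            json.dump(
                {
                    "kw_p": res.kw_p,
                    "windows": [
                        {
                            "start_s": w.start_s,
                            "end_s": w.end_s,
                            "per_bin_p": list(map(float, w.per_bin_p)),
                        }
                        for w in res.windows
                    ],
                },
                f,
                indent=1,
            )
        record("windows", wpath)
        state["windows"] = res

    @stage("score-trials")
    def _score():
        all_trials = pd.concat([t for _, _, t, _, _ in state["sessions"]])
        prob, per_mouse = behavior.awakening_probability(all_trials)
        spath = outdir / "awakening_probability.json"
        with open(spath, "w") as f:
            json.dump(
                {"pooled": prob, "per_mouse": per_mouse.to_dict()}, f, indent=1
            )
        record("awakening_probability", spath)

    @stage("stats")
    def _stats():
        res = anatomy.permutation_test(
            state["cell_counts"], n_perm=config.n_perm, seed=config.seed
        )
        apath = outdir / "anatomy_test.json"
        with open(apath, "w") as f:
            json.dump(
                {
                    "statistic": res.statistic,
                    "observed": res.observed,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                    "exact": res.exact,
                },
                f,
                indent=1,
            )
        record("anatomy_test", apath)

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
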