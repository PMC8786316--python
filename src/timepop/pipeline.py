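"""End-to-end orchestration: simulate -> SDF -> analyses -> report bundle.

A :class:`PipelineConfig` fully serializes a run (stimulus grid, observer,
stereotype mixture, SDF parameters, per-stage analysis parameters and the
master seed). Each stage receives a sub-seed derived by hashing
``(master seed, stage name)`` so adding or toggling stages never perturbs
the randomness of the others; identical config + seed gives identical
numeric outputs. A machine-readable manifest records every stage with its
sub-seed, runtime and output files (with content hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import categorize as cat_mod
from . import correlations as corr_mod
from . import decode as decode_mod
from . import popdecomp as decomp_mod
from . import scaling as scaling_mod
from . import sdf as sdf_mod
from . import speedmod as speed_mod
from . import synthetic

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "ALL_STAGES"]

ALL_STAGES = (
    "simulate",
    "behavior",
    "sdf",
    "correlate",
    "scaling",
    "decompose",
    "categorize",
    "decode",
    "speed",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    n_trials: int = 60
    n_units: int = 30
    mixture: dict | None = None
    observer_shrinkage: float = 0.7
    observer_w_m: float = 0.1
    observer_w_p: float = 0.1
    rate_noise_sd: float = 0.5
    speed_gain: float = 0.0
    n_bins: int = 40
    bin_width: float = 0.1
    ks_runs: int = 200
    decomp_bootstrap_runs: int = 100
    decomp_bootstrap_frac: float = 0.2
    decode_runs: int = 200
    decode_subset: int = 20
    decode_noise_sd: float = 0.5
    stages: tuple = ALL_STAGES

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return json.dumps(d, indent=2)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml  # optional; JSON is the primary format

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    manifest = {"seed": config.seed, "stages": []}
    ctx: dict = {}

    def record(stage: str, t_start: float, outputs: list[Path]):
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed(config.seed, stage),
                "runtime_s": round(time.time() - t_start, 3),
                "outputs": {p.name: _hash_file(p) for p in outputs},
            }
        )

    stages = config.stages

    def need(stage: str, key: str):
        if key not in ctx:
            raise RuntimeError(f"stage '{stage}' requires an upstream artifact missing "
                               f"because its producing stage was not run")

    if "simulate" in stages:
        t0 = time.time()
        sess_cfg = synthetic.SessionConfig(
            n_trials=config.n_trials,
            n_units=config.n_units,
            mixture=config.mixture,
            observer=synthetic.ObserverParams(
                shrinkage=config.observer_shrinkage,
                w_m=config.observer_w_m,
                w_p=config.observer_w_p,
            ),
            rate_noise_sd=config.rate_noise_sd,
            speed_gain=config.speed_gain,
            seed=stage_seed(config.seed, "simulate"),
        )
        trials, spikes = synthetic.generate_session(sess_cfg)
        ctx["trials"], ctx["spikes"] = trials, spikes
        session_dir = outdir / "session"
        synthetic.write_session_csv(session_dir, trials, spikes)
        synthetic.write_session_hdf5(outdir / "session.h5", trials, spikes)
        record("simulate", t0, [session_dir / "trials.csv", session_dir / "spikes.csv",
                                outdir / "session.h5"])

    if "behavior" in stages:
        need("behavior", "trials")
        t0 = time.time()
        summary = behavior_mod.summarize(ctx["trials"])
        path = outdir / "behavior_summary.csv"
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(path, index=False)
        ctx["behavior"] = summary
        record("behavior", t0, [path])

    if "sdf" in stages:
        need("sdf", "spikes")
        t0 = time.time()
        warped = sdf_mod.warp_reproduction_trials(ctx["spikes"])
        meas = sdf_mod.compute_sdf(warped, "measurement", bin_width=config.bin_width)
        repro = sdf_mod.compute_sdf(warped, "reproduction", bin_width=config.bin_width)
        meas_n = sdf_mod.normalize_and_zscore(meas, config.n_bins)
        repro_n = sdf_mod.normalize_and_zscore(repro, config.n_bins)
        ctx["sdf_measurement"], ctx["sdf_reproduction"] = meas_n, repro_n
        path = outdir / "sdf.h5"
        sdf_mod.write_sdf_hdf5(path, {"measurement": meas_n, "reproduction": repro_n})
        record("sdf", t0, [path])

    if "correlate" in stages:
        need("correlate", "sdf_measurement")
        t0 = time.time()
        fractions = {}
        outputs = []
        for mode in ("pairwise_cells", "cell_stimulus_pairs", "population_stimulus_pairs"):
            for phase, tensor in (
                ("measurement", ctx["sdf_measurement"]),
                ("reproduction", ctx["sdf_reproduction"]),
            ):
                rep = corr_mod.correlate(tensor, mode=mode)
                fractions[f"{mode}_{phase}"] = corr_mod.significant_fraction(rep)
                path = outdir / f"corr_{mode}_{phase}.csv"
                np.savetxt(path, np.atleast_2d(rep.r), delimiter=",")
                outputs.append(path)
        for mode in ("population_vector_bins", "cell_cross_phase"):
            rep = corr_mod.correlate(ctx["sdf_measurement"], ctx["sdf_reproduction"], mode=mode)
            fractions[mode] = corr_mod.significant_fraction(rep)
            path = outdir / f"corr_{mode}.csv"
            np.savetxt(path, np.atleast_2d(rep.r), delimiter=",")
            outputs.append(path)
        path = outdir / "correlation_fractions.json"
        path.write_text(json.dumps(fractions, indent=2))
        outputs.append(path)
        record("correlate", t0, outputs)

    if "scaling" in stages:
        need("scaling", "sdf_reproduction")
        t0 = time.time()
        seed = stage_seed(config.seed, "scaling")
        outputs = []
        summary = {}
        for phase in ("measurement", "reproduction"):
            tensor = ctx[f"sdf_{phase}"]
            com = scaling_mod.com_table(tensor)
            idx = scaling_mod.scaling_indices(com, tensor.stimuli)
            shuf = scaling_mod.shuffled_indices(com, tensor.stimuli, seed=seed)
            rows = []
            for u in range(com.shape[0]):
                for j, stim in enumerate(tensor.stimuli):
                    rows.append((u, stim, com[u, j] / tensor.durations[j], com[u, j], idx[u, j]))
            path = outdir / f"scaling_{phase}.csv"
            pd.DataFrame(
                rows, columns=["unit", "stimulus", "com_fraction", "com_seconds", "index"]
            ).to_csv(path, index=False)
            outputs.append(path)
            try:
                ks = scaling_mod.bootstrap_ks_scaling(
                    idx[:, tensor.stimuli != 5.25],
                    shuf[:, tensor.stimuli != 5.25],
                    frac=0.1,
                    runs=config.ks_runs,
                    seed=seed,
                )
                summary[phase] = {"fraction_significant": ks.fraction_significant}
            except ValueError as err:
                summary[phase] = {"error": str(err)}
        path = outdir / "scaling_ks.json"
        path.write_text(json.dumps(summary, indent=2))
        outputs.append(path)
        record("scaling", t0, outputs)

    if "decompose" in stages:
        need("decompose", "sdf_measurement")
        t0 = time.time()
        outputs = []
        for phase in ("measurement", "reproduction"):
            tensor = ctx[f"sdf_{phase}"]
            res = decomp_mod.demixed_pca(tensor)
            ctx[f"decomp_{phase}"] = res
            score_df = pd.DataFrame(
                np.column_stack([res.time_scores, res.stim_scores]),
                columns=[f"PC{j+1}" for j in range(res.n_time)] + ["sPC1"],
            )
            path = outdir / f"decomp_scores_{phase}.csv"
            score_df.to_csv(path, index_label="unit")
            outputs.append(path)
            conv = decomp_mod.conventional_pca(tensor)
            lengths, speeds = decomp_mod.trajectory_metrics(conv, tensor)
            path = outdir / f"trajectory_{phase}.json"
            path.write_text(
                json.dumps(
                    {
                        "ev_time": res.ev_time.tolist(),
                        "ev_stim": res.ev_stim.tolist(),
                        "lengths": lengths.tolist(),
                        "speeds": speeds.tolist(),
                    },
                    indent=2,
                )
            )
            outputs.append(path)
        record("decompose", t0, outputs)

    if "categorize" in stages:
        need("categorize", "decomp_measurement")
        t0 = time.time()
        assigns = {}
        outputs = []
        for phase in ("measurement", "reproduction"):
            assigns[phase] = cat_mod.categorize_population(
                ctx[f"sdf_{phase}"], ctx[f"decomp_{phase}"], phase
            )
            path = outdir / f"categories_{phase}.csv"
            pd.DataFrame(
                {
                    "unit": [a.unit for a in assigns[phase]],
                    "category": ["+".join(sorted(a.category)) or "unrelated" for a in assigns[phase]],
                    "ev": [a.ev for a in assigns[phase]],
                }
            ).to_csv(path, index=False)
            outputs.append(path)
        table = cat_mod.transition_table(assigns["measurement"], assigns["reproduction"])
        path = outdir / "transitions.json"
        path.write_text(
            json.dumps(
                {
                    "activity_shares": table["activity_shares"],
                    "n_units": table["n_units"],
                    "counts": {
                        f"{'+'.join(sorted(m)) or 'unrelated'}->{'+'.join(sorted(r)) or 'unrelated'}": c
                        for (m, r), c in table["counts"].items()
                    },
                },
                indent=2,
            )
        )
        outputs.append(path)
        record("categorize", t0, outputs)

    if "decode" in stages:
        need("decode", "sdf_reproduction")
        t0 = time.time()
        seed = stage_seed(config.seed, "decode")
        results = {}
        for phase in ("measurement", "reproduction"):
            tensor = ctx[f"sdf_{phase}"]
            subset = min(config.decode_subset, tensor.n_units)
            boot = decode_mod.bootstrap_decode(
                tensor,
                subset_size=subset,
                runs=config.decode_runs,
                noise_sd=config.decode_noise_sd,
                seed=seed,
            )
            results[phase] = {
                "median_slope": boot.median_slope,
                "iqr": list(boot.iqr),
                "final_decoded_mean": boot.decoded_mean[:, -1].tolist(),
                "durations": boot.durations.tolist(),
            }
        path = outdir / "decode.json"
        path.write_text(json.dumps(results, indent=2))
        record("decode", t0, [path])

    if "speed" in stages:
        need("speed", "trials")
        t0 = time.time()
        seed = stage_seed(config.seed, "speed")
        trials, spikes = ctx["trials"], ctx["spikes"]
        dt = trials[0].speed_dt
        speed_concat = []
        offsets = np.zeros(len(trials))
        total = 0.0
        for i, trial in enumerate(trials):
            offsets[i] = total
            speed_concat.append(trial.speed)
            total += len(trial.speed) * dt
        speed_trace = np.concatenate(speed_concat)
        rows = []
        rng = np.random.default_rng(seed)
        for u in range(spikes.n_units):
            times = np.concatenate(
                [spikes.trains[u][i] + offsets[i] for i in range(len(trials))]
            )
            try:
                resp = speed_mod.speed_response_function(times, speed_trace, dt, seed=rng)
                rows.append((u, speed_mod.modulation_index(resp), resp.p_value, resp.significant))
            except ValueError:
                rows.append((u, np.nan, np.nan, False))
        path = outdir / "speedmod.csv"
        pd.DataFrame(rows, columns=["unit", "index", "p", "significant"]).to_csv(path, index=False)
        record("speed", t0, [path])

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
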