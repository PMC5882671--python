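"""End-to-end orchestration: simulate -> fit -> compare -> validate -> report.

A run is fully described by a :class:`RunConfig` (YAML-serializable); every
stochastic stage derives its stream deterministically from the master seed,
so a config reproduces all outputs bit-for-bit on the same platform.  Each
stage writes its tables under the configured output directory together
with a provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import accuracy_table, conformity_delta, payoff_table
from .inference import PosteriorSample, sample_posterior
from .model_comparison import average_parameters, comparison_table, waic, waic_weights
from .model_space import MODEL_NAMES, build_model
from .synthetic_data import TRIAL_COLUMNS, generate_cohort, generate_schedule
from .validation import run_ppc, run_recovery

__all__ = [
    "RunConfig",
    "cmd_simulate",
    "cmd_fit",
    "cmd_compare",
    "cmd_recover",
    "cmd_ppc",
    "cmd_report",
    "load_trials",
]

_CONFIG_FIELDS = None  # populated after RunConfig definition


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    seed: int = 0
    experiment: str = "HO"  # BO or HO preset
    n_subjects: int = 6
    models: tuple[str, ...] = MODEL_NAMES
    n_iter: int = 500
    burn_in: int = 600
    thin: int = 2
    rhat_gate: float = 1.1
    ppc_reps: int = 100
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {
            "config": dataclasses.asdict(self),
            "config_hash": self.hash(),
            "version": __version__,
        }


def _out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_meta.json").write_text(json.dumps(config.provenance(), indent=2, default=str))
    return out


def load_trials(data_dir: str | Path) -> pd.DataFrame:
    """Read per-subject trial CSVs from a directory, validating the schema."""
    files = sorted(Path(data_dir).glob("subject_*.csv"))
    if not files:
        raise FileNotFoundError(f"no subject_*.csv files under {data_dir}")
    frames = []
    for f in files:
        df = pd.read_csv(f)
        missing = set(TRIAL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{f.name}: missing column(s) {sorted(missing)}")
        bad = ~df["norm"].isin(["NONE", "SAME", "ONLY"])
        if bad.any():
            raise ValueError(
                f"{f.name}: invalid 'norm' value in row(s) {df.index[bad].tolist()}"
            )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cmd_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate a synthetic cohort and write per-subject CSVs + truth sidecar."""
    out = _out(config)
    data, _ = generate_cohort(
        config.n_subjects,
        experiment=config.experiment,
        master_seed=config.seed,
        out_dir=out / "data",
    )
    return data


def _fit_path(out: Path, subject: int, model: str) -> Path:
    return out / "fits" / f"subject_{subject:03d}_{model}.npz"


def cmd_fit(config: RunConfig, data: pd.DataFrame | None = None) -> dict:
    """Fit every configured model to every subject; saves .npz fit files."""
    out = _out(config)
    if data is None:
        data = load_trials(out / "data")
    fits: dict[int, dict[str, PosteriorSample]] = {}
    (out / "fits").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    for subject, sdf in data.groupby("subject"):
        sdf = sdf[~sdf["no_response"]]
        fits[subject] = {}
        for model in config.models:
            fit = sample_posterior(
                sdf,
                build_model(model),
                n_iter=config.n_iter,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=int(rng.integers(0, 2**31 - 1)),
                rhat_gate=config.rhat_gate,
            )
            fit.save(_fit_path(out, subject, model))
            fits[subject][model] = fit
    return fits


def load_fits(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    fits: dict[int, dict[str, PosteriorSample]] = {}
    for f in sorted((out / "fits").glob("subject_*.npz")):
        stem = f.stem  # subject_NNN_model
        subject = int(stem.split("_")[1])
        model = "_".join(stem.split("_")[2:])
        fits.setdefault(subject, {})[model] = PosteriorSample.load(f)
    if not fits:
        raise FileNotFoundError(f"no fit files under {out / 'fits'}")
    return fits


def cmd_compare(config: RunConfig, fits: dict | None = None):
    """WAIC table and weight-averaged condition parameters per subject."""
    out = _out(config)
    if fits is None:
        fits = load_fits(config)
    comp = comparison_table(fits)
    comp.to_csv(out / "model_comparison.csv", index=False)
    rows = []
    for subject, sub_fits in fits.items():
        ws = waic_weights([waic(sub_fits[m].pointwise_loglik).waic for m in MODEL_NAMES])
        avg = average_parameters(sub_fits, dict(zip(MODEL_NAMES, ws)))
        avg.insert(0, "subject", subject)
        rows.append(avg)
    averaged = pd.concat(rows, ignore_index=True)
    averaged.to_csv(out / "averaged_parameters.csv", index=False)
    return comp, averaged


def cmd_recover(config: RunConfig, model: str = "reduced", n_subjects: int | None = None):
    """Parameter-recovery study; writes the per-parameter score table."""
    out = _out(config)
    rep = run_recovery(
        model,
        n_subjects or config.n_subjects,
        experiment=config.experiment,
        master_seed=config.seed + 2,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        rhat_gate=config.rhat_gate,
    )
    rep.table.to_csv(out / f"recovery_{model}.csv", index=False)
    rep.correlations.rename("correlation").to_csv(out / f"recovery_{model}_correlations.csv")
    return rep


def cmd_ppc(config: RunConfig, fits: dict | None = None):
    """Posterior predictive checks for each subject's best-weighted model."""
    out = _out(config)
    if fits is None:
        fits = load_fits(config)
    data = load_trials(Path(config.out_dir) / "data")
    tables = []
    rng = np.random.default_rng(config.seed + 3)
    for subject, sub_fits in fits.items():
        ws = waic_weights([waic(sub_fits[m].pointwise_loglik).waic for m in MODEL_NAMES])
        best = MODEL_NAMES[int(np.argmax(ws))]
        sdf = data[data["subject"] == subject]
        schedule = generate_schedule(seed=int(rng.integers(0, 2**31 - 1)))
        rep = run_ppc(
            sub_fits[best], build_model(best), schedule, sdf,
            n_reps=config.ppc_reps, seed=int(rng.integers(0, 2**31 - 1)),
        )
        t = rep.table.copy()
        t.insert(0, "model", best)
        t.insert(0, "subject", subject)
        tables.append(t)
    ppc = pd.concat(tables, ignore_index=True)
    ppc.to_csv(out / "ppc.csv", index=False)
    return ppc


def cmd_report(config: RunConfig) -> str:
    """Plain-text summary of behavioural and model-based results."""
    out = _out(config)
    data = load_trials(out / "data")
    lines = [
        f"DUST pipeline report (experiment {config.experiment}, "
        f"{data['subject'].nunique()} subjects, seed {config.seed})",
        "",
        "Accuracy by norm x cue validity (cohort means):",
    ]
    acc = (
        accuracy_table(data)
        .groupby(["norm", "validity"], observed=True)["accuracy"].mean().unstack()
    )
    lines.append(acc.round(3).to_string())
    lines.append("")
    lines.append("Conformity deltas vs NONE (cohort means):")
    for norm in ("SAME", "ONLY"):
        deltas = [
            conformity_delta(sdf, norm) for _, sdf in data.groupby("subject")
        ]
        lines.append(f"  {norm}: {np.mean(deltas):+.3f}")
    pay = payoff_table(data)
    lines.append("")
    lines.append(
        f"Payoff totals: self {int(pay.points_self.sum())} cents, "
        f"others {int(pay.points_others.sum())} cents"
    )
    avg_path = out / "averaged_parameters.csv"
    if avg_path.exists():
        avg = pd.read_csv(avg_path)
        lines.append("")
        lines.append("Model-averaged condition parameters (cohort means):")
        lines.append(
            avg.groupby("condition")[["sp_bias", "drift_delta"]]
            .mean().round(4).to_string()
        )
    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    return report
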