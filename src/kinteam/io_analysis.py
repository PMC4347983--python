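"""Ensemble statistics, run-length distribution fitting, and file output.

Measured single-kinesin run lengths are exponentially distributed, so the
ensemble summary carries a maximum-likelihood exponential scale (the mean
of the positive run lengths) next to the raw histogram.  Replicates that
end with a net backward displacement are counted but excluded from the
exponential fit, which describes processive forward runs.

Outputs are plain CSV (RFC 4180, header row) and JSON; every summary JSON
embeds the resolved configuration and seed so a run can be reproduced
from its output alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleSummary",
    "MixtureWeights",
    "summarize",
    "fit_exponential_run_length",
    "mixture_summary",
    "write_outputs",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "config_to_dict",
]


@dataclass
class EnsembleSummary:
    """Summary statistics of one ensemble of transport realizations."""

    n_reps: int
    mean_run_length: float        # nm
    se_run_length: float          # nm
    mean_velocity: float          # nm/s
    se_velocity: float            # nm/s
    hist_edges: np.ndarray        # nm
    hist_counts: np.ndarray
    exp_scale: float | None       # nm, MLE scale of the positive run lengths
    n_negative: int               # replicates with net backward displacement

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hist_edges"] = np.asarray(self.hist_edges).tolist()
        d["hist_counts"] = np.asarray(self.hist_counts).tolist()
        return d


@dataclass
class MixtureWeights:
    """User-supplied probabilities of the motor number n = 1..5.

    The law linking kinesin concentration to the number of engaged motors
    is external input; only the weights enter here.
    """

    weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def summarize(results, n_bins: int = 20) -> EnsembleSummary:
    """Mean/SE of run length and velocity plus the run-length histogram."""
    rl = np.array([r.run_length for r in results], dtype=float)
    v = np.array([r.mean_velocity for r in results], dtype=float)
    counts, edges = np.histogram(rl, bins=n_bins)
    pos = rl[rl > 0]
    scale = float(pos.mean()) if len(pos) else None
    return EnsembleSummary(
        n_reps=len(rl),
        mean_run_length=float(rl.mean()),
        se_run_length=_se(rl),
        mean_velocity=float(v.mean()),
        se_velocity=_se(v),
        hist_edges=edges,
        hist_counts=counts,
        exp_scale=scale,
        n_negative=int((rl <= 0).sum()),
    )


def fit_exponential_run_length(
    samples,
    n_boot: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | None = None,
):
    """MLE exponential scale of the positive run lengths, with bootstrap CI.

    Returns ``(scale, (lo, hi))``.  The MLE of the exponential scale is
    the sample mean; negative or zero samples are excluded (they are net
    backward runs, outside the exponential law).
    """
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise ValueError("exponential fit undefined: no positive run lengths")
    scale = float(x.mean())
    if rng is None:
        rng = np.random.default_rng(0)
    boots = np.array([x[rng.integers(0, len(x), len(x))].mean() for _ in range(n_boot)])
    alpha = 0.5 * (1.0 - ci)
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return scale, (float(lo), float(hi))


def mixture_summary(per_n: dict[int, EnsembleSummary], weights: MixtureWeights) -> EnsembleSummary:
    """Weighted average over team sizes (concentration-mixture view).

    Means combine linearly; histograms are superposed after rebinning onto
    a common edge grid.  Every team size with nonzero weight must be
    present in ``per_n``.
    """
    active = {n: w for n, w in weights.weights.items() if w > 0}
    missing = sorted(set(active) - set(per_n))
    if missing:
        raise KeyError(f"missing summaries for motor numbers {missing}")
    mean_rl = sum(w * per_n[n].mean_run_length for n, w in active.items())
    mean_v = sum(w * per_n[n].mean_velocity for n, w in active.items())
    se_rl = np.sqrt(sum((w * per_n[n].se_run_length) ** 2 for n, w in active.items()))
    se_v = np.sqrt(sum((w * per_n[n].se_velocity) ** 2 for n, w in active.items()))
    lo = min(per_n[n].hist_edges[0] for n in active)
    hi = max(per_n[n].hist_edges[-1] for n in active)
    n_bins = max(len(per_n[n].hist_counts) for n in active)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.zeros(n_bins)
    for n, w in active.items():
        centers = 0.5 * (per_n[n].hist_edges[:-1] + per_n[n].hist_edges[1:])
        idx = np.clip(np.searchsorted(edges, centers, side="right") - 1, 0, n_bins - 1)
        np.add.at(counts, idx, w * per_n[n].hist_counts)
    scales = [per_n[n].exp_scale for n in active if per_n[n].exp_scale is not None]
    ws = [w for n, w in active.items() if per_n[n].exp_scale is not None]
    scale = float(np.average(scales, weights=ws)) if scales else None
    return EnsembleSummary(
        n_reps=int(sum(per_n[n].n_reps for n in active)),
        mean_run_length=float(mean_rl),
        se_run_length=float(se_rl),
        mean_velocity=float(mean_v),
        se_velocity=float(se_v),
        hist_edges=edges,
        hist_counts=counts,
        exp_scale=scale,
        n_negative=int(sum(per_n[n].n_negative for n in active)),
    )


# ---------------------------------------------------------------------- #
# file output


def config_to_dict(config) -> dict:
    """Resolved configuration as a JSON-serializable dict (provenance)."""

    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return conv(config)


def trajectory_frame(result) -> pd.DataFrame:
    """Flatten a recorded trajectory into a tidy DataFrame."""
    tr = result.trajectory
    if tr is None:
        raise ValueError("run was not recorded; set record_trajectory=True")
    n_motors = len(tr["states"][0]) if tr["states"] else 0
    data = {"time_s": tr["time_s"], "x_c_nm": tr["x_c_nm"]}
    for i in range(n_motors):
        data[f"motor{i}_state"] = [s[i] for s in tr["states"]]
        data[f"motor{i}_site"] = [
            ("" if s[i] is None else s[i]) for s in tr["sites"]
        ]
        data[f"motor{i}_F_k_pN"] = [f[i] for f in tr["forces"]]
    return pd.DataFrame(data)


def write_trajectory_csv(result, path) -> Path:
    path = Path(path)
    trajectory_frame(result).to_csv(path, index=False)
    return path


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensemble_frame(results) -> pd.DataFrame:
    """One row per replicate."""
    return pd.DataFrame(
        {
            "replicate": np.arange(len(results)),
            "run_length_nm": [r.run_length for r in results],
            "duration_s": [r.duration for r in results],
            "mean_velocity_nm_s": [r.mean_velocity for r in results],
            "terminated_by": [r.terminated_by for r in results],
            "n_events": [len(r.events) for r in results],
        }
    )


def write_outputs(results, summary: EnsembleSummary, config, out_dir) -> dict[str, Path]:
    """Write the standard output set for an ensemble.

    ``ensemble.csv`` holds one row per replicate; ``summary.json`` embeds
    the summary statistics together with the resolved configuration and
    seed.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["ensemble"] = out / "ensemble.csv"
    ensemble_frame(results).to_csv(paths["ensemble"], index=False)
    paths["summary"] = out / "summary.json"
    payload = {"summary": summary.to_dict(), "config": config_to_dict(config)}
    paths["summary"].write_text(json.dumps(payload, indent=2))
    return paths
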