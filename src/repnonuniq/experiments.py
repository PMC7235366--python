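"""Experiment drivers: the four representation-equivalence analyses.

Given a similar-performing pair and a test stimulus set, these produce
figure-ready tables for:

(i)   standard EV, on all stimuli and on the correctly-categorized subset;
(ii)  EV under additive Gaussian pixel noise over a sigma grid;
(iii) EV as a function of stimulus-set size, by seeded resampling;
(iv)  EV between top-p% most selective neuron subsets (kurtosis ranking).

All drivers share one EV split seed (the experiment config seed), and the
degenerate grid points — sigma = 0, p = 100%, size = full pool — are
computed through byte-identical code paths, so those rows equal the
standard all-inputs row exactly.  Every report carries a provenance block
(configs, seeds, checksums) sufficient to reproduce it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equivalence import (
    EVReport,
    RepresentationMatrix,
    ev_between_neuron_subsets,
    explained_variance,
    selectivity_profile,
    top_fraction_indices,
)
from .nets import accuracy, forward_collect
from .synthdata import (
    LabeledImageSet,
    add_gaussian_noise,
    choose_subsample_indices,
)
from .training import PairResult, is_similar_performing

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_standard_ev",
    "run_noise_grid",
    "run_size_resampling",
    "run_selectivity_analysis",
    "run_all",
    "write_report",
    "plot_report",
]

#: Default noise standard deviations for the noise-robustness analysis.
DEFAULT_SIGMA_GRID = (0.01, 0.02, 0.03, 0.04, 0.05, 0.07, 0.1)

#: Default selectivity percentages: top 10%, 20%, ..., 100%.
DEFAULT_PERCENTAGES = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass(frozen=True)
class ExperimentConfig:
    """Grids and bookkeeping for the analysis drivers.

    ``size_grid=None`` scales the 10-point default grid to the available
    pool (e.g. [50, 100, ..., 500] for a 500-image test set), keeping the
    grid shape of the full-scale analysis rather than its absolute values.
    ``correct_mode`` decides what "correctly categorized" means for the
    restricted analyses: by "both" networks (default, so both
    representations are evaluated on a common stimulus set), by "either",
    or by one of "net1"/"net2".
    """

    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    size_grid: tuple[int, ...] | None = None
    resamples_per_size: int = 10
    selectivity_percentages: tuple[float, ...] = DEFAULT_PERCENTAGES
    correct_mode: str = "both"
    fit_fraction: float = 0.5
    ridge: float = 0.0
    min_correct_subset: int = 50
    gate_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_grid or not self.selectivity_percentages:
            raise ValueError("grids must be non-empty")
        if self.correct_mode not in ("both", "either", "net1", "net2"):
            raise ValueError(f"unknown correct_mode {self.correct_mode!r}")
        if self.resamples_per_size < 1:
            raise ValueError("resamples_per_size must be >= 1")


@dataclass
class ExperimentReport:
    """A tidy per-condition table plus the provenance needed to re-run it."""

    name: str
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _crc(arr: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(arr).tobytes())


def _provenance(name: str, pair: PairResult, data: LabeledImageSet,
                config: ExperimentConfig) -> dict:
    return {
        "experiment": name,
        "config": {
            "sigma_grid": list(config.sigma_grid),
            "size_grid": list(config.size_grid) if config.size_grid else None,
            "resamples_per_size": config.resamples_per_size,
            "selectivity_percentages": [float(p) for p in config.selectivity_percentages],
            "correct_mode": config.correct_mode,
            "fit_fraction": config.fit_fraction,
            "ridge": config.ridge,
            "min_correct_subset": config.min_correct_subset,
            "gate_threshold": config.gate_threshold,
            "seed": config.seed,
        },
        "pair": {
            "scheme": pair.scheme,
            "acc1": pair.acc1,
            "acc2": pair.acc2,
            "net1_seed": pair.net1.seed,
            "net2_seed": pair.net2.seed,
            "architecture": list(pair.net1.spec.layer_tokens),
            "net1_param_crc32": _crc(np.concatenate(
                [p.ravel() for l in pair.net1.layers for p in l.params()])),
            "net2_param_crc32": _crc(np.concatenate(
                [p.ravel() for l in pair.net2.layers for p in l.params()])),
        },
        "data": {
            "split_name": data.split_name,
            "n": data.n,
            "seed": data.seed,
            "images_crc32": _crc(data.images),
        },
    }


def _gate(pair: PairResult, config: ExperimentConfig) -> None:
    if not is_similar_performing(pair, config.gate_threshold):
        raise ValueError(
            f"pair fails the similar-performance gate: |{pair.acc1:.3f} - "
            f"{pair.acc2:.3f}| > {config.gate_threshold}"
        )


def _collect(pair: PairResult, data: LabeledImageSet):
    rep1, _, preds1 = forward_collect(pair.net1, data)
    rep2, _, preds2 = forward_collect(pair.net2, data)
    return rep1, rep2, preds1, preds2


def _correct_indices(
    preds1: np.ndarray, preds2: np.ndarray, labels: np.ndarray, mode: str
) -> np.ndarray:
    c1, c2 = preds1 == labels, preds2 == labels
    mask = {
        "both": c1 & c2,
        "either": c1 | c2,
        "net1": c1,
        "net2": c2,
    }[mode]
    return np.flatnonzero(mask)


def _sub_rep(rep: RepresentationMatrix, idx: np.ndarray) -> RepresentationMatrix:
    return RepresentationMatrix(
        values=rep.values[idx], stimulus_ids=np.arange(len(idx))
    )


def _ev(config: ExperimentConfig, a: RepresentationMatrix,
        b: RepresentationMatrix) -> EVReport:
    return explained_variance(
        a, b, fit_fraction=config.fit_fraction, ridge=config.ridge,
        seed=config.seed,
    )


def run_standard_ev(
    pair: PairResult, data: LabeledImageSet, config: ExperimentConfig
) -> ExperimentReport:
    """EV on all test stimuli and on the correctly-categorized subset."""
    _gate(pair, config)
    rep1, rep2, preds1, preds2 = _collect(pair, data)
    acc1 = accuracy(preds1, data.labels)
    acc2 = accuracy(preds2, data.labels)
    rows = []
    ev_all = _ev(config, rep1, rep2)
    rows.append({
        "condition": "all", "n_stimuli": data.n, "acc1": acc1, "acc2": acc2,
        "headline_ev": ev_all.headline_mean_ev,
        "ev_net1_to_net2": ev_all.mean_ev_src_to_tgt,
        "ev_net2_to_net1": ev_all.mean_ev_tgt_to_src,
        "flagged": False,
    })
    idx = _correct_indices(preds1, preds2, data.labels, config.correct_mode)
    flagged = len(idx) < config.min_correct_subset
    ev_cor = _ev(config, _sub_rep(rep1, idx), _sub_rep(rep2, idx))
    rows.append({
        "condition": "correct_only", "n_stimuli": len(idx),
        "acc1": acc1, "acc2": acc2,
        "headline_ev": ev_cor.headline_mean_ev,
        "ev_net1_to_net2": ev_cor.mean_ev_src_to_tgt,
        "ev_net2_to_net1": ev_cor.mean_ev_tgt_to_src,
        "flagged": flagged,
    })
    return ExperimentReport(
        name="standard_ev",
        table=pd.DataFrame(rows),
        provenance=_provenance("standard_ev", pair, data, config),
    )


def _noise_seed(config: ExperimentConfig, i: int) -> int:
    return (config.seed + 7919 * (i + 1)) % (2**31)


def run_noise_grid(
    pair: PairResult, data: LabeledImageSet, config: ExperimentConfig
) -> ExperimentReport:
    """Accuracies and EV under additive Gaussian noise, sigma = 0 baseline first.

    One noisy dataset per sigma (shared seed) serves both networks, so
    accuracy and EV are measured on identical stimuli.
    """
    _gate(pair, config)
    rows = []
    for i, sigma in enumerate((0.0, *config.sigma_grid)):
        noisy = add_gaussian_noise(data, sigma, seed=_noise_seed(config, i))
        rep1, rep2, preds1, preds2 = _collect(pair, noisy)
        ev = _ev(config, rep1, rep2)
        rows.append({
            "sigma": sigma,
            "n_stimuli": noisy.n,
            "acc1": accuracy(preds1, noisy.labels),
            "acc2": accuracy(preds2, noisy.labels),
            "headline_ev": ev.headline_mean_ev,
        })
    return ExperimentReport(
        name="noise_grid",
        table=pd.DataFrame(rows),
        provenance=_provenance("noise_grid", pair, data, config),
    )


def _default_size_grid(pool: int) -> tuple[int, ...]:
    step = max(pool // 10, 1)
    sizes = list(range(step, pool + 1, step))
    if sizes[-1] != pool:
        sizes.append(pool)
    return tuple(sizes)


def run_size_resampling(
    pair: PairResult, data: LabeledImageSet, config: ExperimentConfig
) -> ExperimentReport:
    """EV vs stimulus-set size via repeated seeded subsampling.

    Run over two pools: the whole test set and the correctly-categorized
    subset.  Rows carry the mean and sd of the headline EV over
    ``resamples_per_size`` draws; sizes exceeding a pool are skipped with
    a warning flag.
    """
    _gate(pair, config)
    rep1, rep2, preds1, preds2 = _collect(pair, data)
    pools = {
        "all": np.arange(data.n),
        "correct_only": _correct_indices(
            preds1, preds2, data.labels, config.correct_mode
        ),
    }
    rows = []
    for pool_name, pool_idx in pools.items():
        size_grid = config.size_grid or _default_size_grid(len(pool_idx))
        for si, size in enumerate(size_grid):
            if size > len(pool_idx):
                rows.append({
                    "pool": pool_name, "size": size, "mean_ev": np.nan,
                    "sd_ev": np.nan, "n_resamples": 0, "skipped": True,
                })
                continue
            evs = []
            for r in range(config.resamples_per_size):
                sub_seed = (config.seed + 104729 * si + 1299709 * r) % (2**31)
                # Row selection on the cached representation matrices is
                # identical to subsampling the stimulus set and re-running
                # the networks (forward passes are per-stimulus).
                chosen = choose_subsample_indices(pool_idx, size, sub_seed)
                ev = _ev(config, _sub_rep(rep1, chosen), _sub_rep(rep2, chosen))
                evs.append(ev.headline_mean_ev)
            if np.all(np.asarray(evs) == evs[0]):
                # All draws identical (size == pool): averaging would only
                # add round-off, so report the common value directly.
                mean_ev, sd_ev = evs[0], 0.0
            else:
                mean_ev, sd_ev = float(np.mean(evs)), float(np.std(evs))
            rows.append({
                "pool": pool_name, "size": size,
                "mean_ev": mean_ev, "sd_ev": sd_ev,
                "n_resamples": len(evs), "skipped": False,
            })
    return ExperimentReport(
        name="size_resampling",
        table=pd.DataFrame(rows),
        provenance=_provenance("size_resampling", pair, data, config),
    )


def run_selectivity_analysis(
    pair: PairResult, data: LabeledImageSet, config: ExperimentConfig
) -> ExperimentReport:
    """EV between top-p% most selective neuron subsets of each network.

    Selectivity is the Pearson kurtosis of each neuron's response
    distribution over the test stimuli, computed per network on the same
    stimuli; subsets are chosen independently per network.
    """
    _gate(pair, config)
    rep1, rep2, _, _ = _collect(pair, data)
    kurt1 = selectivity_profile(rep1)
    kurt2 = selectivity_profile(rep2)
    if np.all(np.isnan(kurt1)) or np.all(np.isnan(kurt2)):
        raise ValueError("all neurons have undefined selectivity")
    rows = []
    for p in config.selectivity_percentages:
        idx1 = top_fraction_indices(kurt1, p)
        idx2 = top_fraction_indices(kurt2, p)
        ev = ev_between_neuron_subsets(
            rep1, rep2, idx1, idx2,
            fit_fraction=config.fit_fraction, ridge=config.ridge,
            seed=config.seed,
        )
        rows.append({
            "percentage": float(p),
            "n_neurons_net1": len(idx1),
            "n_neurons_net2": len(idx2),
            "headline_ev": ev.headline_mean_ev,
        })
    return ExperimentReport(
        name="selectivity",
        table=pd.DataFrame(rows),
        provenance=_provenance("selectivity", pair, data, config),
    )


def run_all(
    pair: PairResult, data: LabeledImageSet, config: ExperimentConfig
) -> dict[str, ExperimentReport]:
    """All four analyses with shared seeds."""
    return {
        "standard_ev": run_standard_ev(pair, data, config),
        "noise_grid": run_noise_grid(pair, data, config),
        "size_resampling": run_size_resampling(pair, data, config),
        "selectivity": run_selectivity_analysis(pair, data, config),
    }


def write_report(report: ExperimentReport, out_dir: str | Path,
                 plots: bool = False) -> dict[str, Path]:
    """Write the report as CSV + provenance JSON (byte-stable on re-run).

    With ``plots=True`` a PNG mirroring the analysis layout is attempted;
    plotting failures (e.g. matplotlib absent) never fail the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{report.name}.csv"
    json_path = out / f"{report.name}_provenance.json"
    report.table.to_csv(csv_path, index=False, float_format="%.12g")
    json_path.write_text(json.dumps(report.provenance, indent=2, sort_keys=True))
    paths = {"csv": csv_path, "provenance": json_path}
    if plots:
        try:
            paths["plot"] = plot_report(report, out)
        except Exception:  # plots are best-effort by contract
            pass
    return paths


def plot_report(report: ExperimentReport, out_dir: str | Path) -> Path:
    """Bar/line plot of a report table; returns the written PNG path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir) / f"{report.name}.png"
    t = report.table
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if report.name == "standard_ev":
        ax.bar(t["condition"], t["headline_ev"], color=["C0", "C1"])
        ax.set_ylabel("mean EV")
    elif report.name == "noise_grid":
        ax.plot(t["sigma"], t["headline_ev"], "o-", label="mean EV")
        ax.plot(t["sigma"], t["acc1"], "s--", label="acc net1")
        ax.plot(t["sigma"], t["acc2"], "^--", label="acc net2")
        ax.set_xlabel("noise sd")
        ax.legend()
    elif report.name == "size_resampling":
        for pool, grp in t[~t["skipped"]].groupby("pool"):
            ax.errorbar(grp["size"], grp["mean_ev"], yerr=grp["sd_ev"],
                        label=pool, marker="o", capsize=3)
        ax.set_xlabel("stimulus-set size")
        ax.set_ylabel("mean EV")
        ax.legend()
    elif report.name == "selectivity":
        ax.plot(t["percentage"] * 100, t["headline_ev"], "o-")
        ax.set_xlabel("top % most selective neurons")
        ax.set_ylabel("mean EV")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
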