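"""One-step growth-curve analysis: latent period and burst size.

A one-step growth experiment follows a synchronized infection: the free-
phage titer (PFU/mL) stays at a baseline set by the initial infective
centers during the latent period, rises as cells lyse, and plateaus once
every infected cell has burst.  Two parameters summarize the cycle:

* the **latent period** — here, the last sampled time at which the
  replicate-mean titer is still within ``rise_factor`` (default 2x) of the
  baseline mean, reported at sampling resolution;
* the **burst size** — progeny per infected cell, estimated per replicate
  as (mean plateau titer - mean baseline titer) / mean baseline titer, the
  baseline titer standing in for the concentration of infective centers.
  The reported value is the replicate mean with its standard error (SEM,
  n-1 denominator).

Both estimators are ratios of titers, so uniform dilution factors cancel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError, NoRiseWarning, ValidationError

#: Default multiplicative rise over baseline that marks the end of latency.
DEFAULT_RISE_FACTOR = 2.0
#: Default maximum relative spread (max-min)/mean within a plateau run.
DEFAULT_PLATEAU_TOL = 0.25


@dataclass
class GrowthCurve:
    """Replicate titer time-series from a one-step growth experiment.

    ``titers`` has shape (n_replicates, n_times): every replicate covers
    every time point.  ``baseline_window`` is an inclusive index range used
    as the pre-burst baseline; when None it is found adaptively (all points
    before the titer first doubles over the initial sample).
    """

    times: np.ndarray
    titers: np.ndarray
    moi: float | None = None
    baseline_window: tuple | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.atleast_2d(np.asarray(self.titers, dtype=float))
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValidationError("need at least 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time vector must be strictly increasing")
        if self.titers.shape[1] != self.times.size:
            raise ValidationError(
                f"titer matrix has {self.titers.shape[1]} columns for "
                f"{self.times.size} time points"
            )
        if np.any(self.titers < 0) or not np.all(np.isfinite(self.titers)):
            raise ValidationError("titers must be finite and non-negative")
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
            if not (0 <= lo <= hi < self.times.size):
                raise ValidationError(f"baseline_window {self.baseline_window} out of range")

    @property
    def n_replicates(self) -> int:
        return self.titers.shape[0]

    @property
    def mean_titer(self) -> np.ndarray:
        return self.titers.mean(axis=0)


@dataclass(frozen=True)
class GrowthEstimate:
    latent_min: float
    burst_size: float
    burst_sem: float
    n_replicates: int


def _baseline_and_rise(curve: GrowthCurve, rise_factor: float):
    """Resolve (baseline index range, first rise index or None)."""
    mean = curve.mean_titer
    if curve.baseline_window is not None:
        lo, hi = curve.baseline_window
        window = mean[lo : hi + 1]
        if window.min() > 0 and window.max() / window.min() > rise_factor:
            raise ValidationError(
                "baseline window is not flat: it contains a rise beyond the "
                "rise factor and cannot precede the burst"
            )
    else:
        # Adaptive: baseline = everything before the first rise over the
        # initial sample; shrink until self-consistent.
        lo, hi = 0, curve.times.size - 1
        above = np.nonzero(mean > rise_factor * mean[0])[0]
        if above.size:
            hi = max(int(above[0]) - 1, 0)
    while True:
        base = mean[lo : hi + 1].mean()
        above = np.nonzero(mean > rise_factor * base)[0]
        rise = int(above[0]) if above.size else None
        if rise is None or rise > hi or curve.baseline_window is not None:
            break
        if rise == 0:
            raise ValidationError("baseline window does not precede the rise")
        hi = rise - 1
    if rise is not None and rise <= hi:
        raise ValidationError("baseline window does not precede the rise")
    return (lo, hi), rise


def estimate_latent(curve: GrowthCurve, rise_factor: float = DEFAULT_RISE_FACTOR) -> float:
    """Latent period: last sampled time before the mean titer exceeds
    ``rise_factor`` times the baseline mean.

    If the curve never rises the final time point is returned with a
    :class:`NoRiseWarning`.
    """
    if rise_factor <= 1:
        raise ValidationError("rise_factor must exceed 1")
    _, rise = _baseline_and_rise(curve, rise_factor)
    if rise is None:
        warnings.warn("titer never rose above the baseline threshold", NoRiseWarning)
        return float(curve.times[-1])
    return float(curve.times[rise - 1])


def _plateau_indices(mean: np.ndarray, rise: int, tol: float):
    """Longest terminal run with relative spread (max-min)/mean <= tol,
    restricted to points at or after the rise."""
    n = mean.size
    start = n - 1
    for j in range(n - 2, rise - 1, -1):
        window = mean[j:]
        if (window.max() - window.min()) / window.mean() <= tol:
            start = j
        else:
            break
    return np.arange(start, n)


def estimate_burst(
    curve: GrowthCurve,
    rise_factor: float = DEFAULT_RISE_FACTOR,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
) -> GrowthEstimate:
    """Burst size +/- SEM (and latent period) from a replicate titer series.

    Requires an estimable latent period and a terminal plateau of at least
    two points; per replicate, burst = (plateau mean - baseline mean) /
    baseline mean.
    """
    (lo, hi), rise = _baseline_and_rise(curve, rise_factor)
    if rise is None:
        raise EstimationError(
            "no titer rise detected: latent period is not estimable"
        )
    plateau = _plateau_indices(curve.mean_titer, rise, plateau_tol)
    if plateau.size < 2:
        raise EstimationError(
            f"no plateau detected: fewer than 2 terminal points within "
            f"relative spread {plateau_tol}"
        )
    base = curve.titers[:, lo : hi + 1].mean(axis=1)
    if np.any(base <= 0):
        raise EstimationError("a replicate has zero baseline titer")
    plat = curve.titers[:, plateau].mean(axis=1)
    bursts = plat / base - 1.0
    burst = float(bursts.mean())
    if burst <= 0:
        raise EstimationError(f"estimated burst size {burst:.3g} is not positive")
    n = curve.n_replicates
    sem = float(bursts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GrowthEstimate(
        latent_min=float(curve.times[rise - 1]),
        burst_size=burst,
        burst_sem=sem,
        n_replicates=n,
    )


def compute_moi(phage_titer: float, phage_volume_ml: float, cell_count: float) -> float:
    """Multiplicity of infection: (titer * volume) / cells."""
    if phage_titer <= 0 or phage_volume_ml <= 0 or cell_count <= 0:
        raise ValidationError("titer, volume and cell count must all be positive")
    return phage_titer * phage_volume_ml / cell_count


# ---------------------------------------------------------------------------
# CSV dialect: columns time_min, replicate, pfu_per_ml

GROWTH_COLUMNS = ["time_min", "replicate", "pfu_per_ml"]


def read_growth_csv(path, moi: float | None = None) -> GrowthCurve:
    """Read a replicate titer series from CSV (time_min, replicate, pfu_per_ml)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"could not read growth CSV {path}: {exc}") from exc
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"growth CSV {path} lacks required columns {missing}")
    if df.empty:
        raise InputError(f"growth CSV {path} contains no data rows")
    bad = df[GROWTH_COLUMNS].apply(pd.to_numeric, errors="coerce")
    if bad[["time_min", "pfu_per_ml"]].isna().any(axis=None):
        row = int(bad[["time_min", "pfu_per_ml"]].isna().any(axis=1).idxmax()) + 2
        raise InputError(f"growth CSV {path}: non-numeric value at line {row}")
    wide = df.pivot_table(
        index="replicate", columns="time_min", values="pfu_per_ml", aggfunc="first"
    ).sort_index()
    if wide.isna().any(axis=None):
        rep = wide.index[wide.isna().any(axis=1)][0]
        raise InputError(
            f"growth CSV {path}: replicate {rep!r} does not cover every time point"
        )
    return GrowthCurve(
        times=wide.columns.to_numpy(dtype=float),
        titers=wide.to_numpy(dtype=float),
        moi=moi,
    )


def write_growth_csv(curve: GrowthCurve, path) -> None:
    rows = [
        {"time_min": t, "replicate": r + 1, "pfu_per_ml": curve.titers[r, i]}
        for r in range(curve.n_replicates)
        for i, t in enumerate(curve.times)
    ]
    pd.DataFrame(rows, columns=GROWTH_COLUMNS).to_csv(path, index=False)


def estimate_to_dict(est: GrowthEstimate) -> dict:
    return {
        "latent_min": est.latent_min,
        "burst_size": est.burst_size,
        "burst_sem": est.burst_sem,
        "n_replicates": est.n_replicates,
    }


def write_estimate_json(est: GrowthEstimate, path) -> None:
    with open(path, "w") as fh:
        json.dump(estimate_to_dict(est), fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_growth_curve(curve: GrowthCurve, path, estimate: GrowthEstimate | None = None) -> None:
    """Semilog titer-vs-time plot with replicate points and the mean curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for r in range(curve.n_replicates):
        ax.plot(curve.times, curve.titers[r], "o", ms=3, alpha=0.5, color="#1f77b4")
    ax.plot(curve.times, curve.mean_titer, "-", color="#1f77b4", label="replicate mean")
    if estimate is not None:
        ax.axvline(estimate.latent_min, ls="--", color="grey",
                   label=f"latent {estimate.latent_min:.0f} min")
    ax.set_yscale("log")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("titer (PFU/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
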