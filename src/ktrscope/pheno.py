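"""Population phenotyping: persister calls, S-phase and transcription readouts.

A drug persister is operationally a cell whose CDK2 C/N activity exceeds
1.0 for more than 4 h (one contiguous run, strict inequality) inside the
30–48 h window after treatment. Run length is the time spanned between the
first and last frame of the run, ``(n_frames - 1) * frame_interval``;
frames falling exactly on the window edges are included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from .reporters import TraceSet


def longest_supra_threshold_run_h(times_h: np.ndarray, values: np.ndarray,
                                  threshold: float = 1.0,
                                  window: tuple[float, float] = (30.0, 48.0),
                                  frame_interval_h: float = 0.2,
                                  valid: np.ndarray | None = None,
                                  cumulative: bool = False) -> float:
    """Longest run (h) of frames above ``threshold`` inside ``window``.

    Frames at the window edges count; invalid frames break a run. With
    ``cumulative=True`` the total above-threshold time (frames x interval)
    is returned instead of the longest contiguous run.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v) if valid is None else (np.asarray(valid, bool) & np.isfinite(v))
    eps = 1e-9
    sel = (t >= window[0] - eps) & (t <= window[1] + eps)
    above = sel & ok & (v > threshold)
    if cumulative:
        return float(above.sum()) * frame_interval_h
    best = 0
    count = 0
    # a run is broken by any in-window frame that is not above threshold;
    # out-of-window frames terminate runs at the window edge
    for i in range(t.size):
        if above[i]:
            count += 1
            best = max(best, count)
        else:
            count = 0
    return max(best - 1, 0) * frame_interval_h


@dataclass
class PersisterCall:
    """Classification of one trace by the sliding-window CDK2 rule."""

    track_id: int
    is_persister: bool
    longest_run_h: float
    coverage: float
    excluded: bool = False
    reason: str = ""
    threshold: float = 1.0
    window: tuple[float, float] = (30.0, 48.0)
    min_duration_h: float = 4.0


def classify_persister(times_h: np.ndarray, cdk2: np.ndarray,
                       valid: np.ndarray | None = None, track_id: int = 0,
                       threshold: float = 1.0,
                       window: tuple[float, float] = (30.0, 48.0),
                       min_duration_h: float = 4.0,
                       frame_interval_h: float = 0.2,
                       min_coverage: float = 0.8,
                       cumulative: bool = False) -> PersisterCall:
    """Classify one CDK2 activity trace as persister / non-persister.

    The cell is a persister when its longest contiguous run of CDK2 >
    ``threshold`` inside ``window`` strictly exceeds ``min_duration_h``.
    Traces covering less than ``min_coverage`` of the window's frames are
    excluded (not counted in any denominator).
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(cdk2, dtype=float)
    ok = np.isfinite(v) if valid is None else (np.asarray(valid, bool) & np.isfinite(v))
    eps = 1e-9
    sel = (t >= window[0] - eps) & (t <= window[1] + eps)
    n_expected = int(round((window[1] - window[0]) / frame_interval_h)) + 1
    coverage = float((sel & ok).sum()) / n_expected if n_expected else 0.0
    if coverage < min_coverage:
        return PersisterCall(track_id, False, 0.0, coverage, excluded=True,
                             reason="insufficient window coverage",
                             threshold=threshold, window=window,
                             min_duration_h=min_duration_h)
    run = longest_supra_threshold_run_h(t, v, threshold, window,
                                        frame_interval_h, valid=ok,
                                        cumulative=cumulative)
    return PersisterCall(track_id, run > min_duration_h, run, coverage,
                         threshold=threshold, window=window,
                         min_duration_h=min_duration_h)


def classify_traces(traces: TraceSet, **kwargs) -> pd.DataFrame:
    """Apply :func:`classify_persister` to every trace long enough for analysis."""
    analysable = traces.for_analysis()
    rows = []
    for tid in analysable.track_ids:
        tr = analysable.track(tid).sort_values("t_h")
        call = classify_persister(tr["t_h"].to_numpy(), tr["cdk2"].to_numpy(),
                                  valid=tr["valid"].to_numpy(), track_id=int(tid),
                                  frame_interval_h=traces.frame_interval_h,
                                  **kwargs)
        rows.append(dict(track_id=call.track_id, is_persister=call.is_persister,
                         longest_run_h=call.longest_run_h,
                         coverage=call.coverage, excluded=call.excluded,
                         reason=call.reason))
    return pd.DataFrame(rows, columns=["track_id", "is_persister",
                                       "longest_run_h", "coverage",
                                       "excluded", "reason"])


def persister_fraction(calls: pd.DataFrame) -> float:
    """Fraction of persisters among cells passing coverage QC."""
    counted = calls[~calls["excluded"]]
    if counted.empty:
        return float("nan")
    return float(counted["is_persister"].mean())


@dataclass
class PopulationSummary:
    condition: str
    n_cells: int
    persister_fraction: float
    ci_low: float
    ci_high: float


def summarize_population(calls: pd.DataFrame, condition: str = "",
                         n_boot: int = 1000, rng_seed: int = 0) -> PopulationSummary:
    """Persister fraction with a seeded nonparametric bootstrap 95% CI."""
    counted = calls[~calls["excluded"]]
    n = len(counted)
    frac = persister_fraction(calls)
    if n == 0:
        return PopulationSummary(condition, 0, frac, float("nan"), float("nan"))
    rng = np.random.default_rng(rng_seed)
    flags = counted["is_persister"].to_numpy()
    boots = rng.choice(flags, size=(n_boot, n), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PopulationSummary(condition, n, frac, float(min(lo, frac)),
                             float(max(hi, frac)))


# ---------------------------------------------------------------------------
# S-phase (EdU) and transcription (EU) readouts


def edu_positive_fraction(intensities: np.ndarray, method: str = "otsu_log",
                          fixed_threshold: float | None = None
                          ) -> tuple[float, np.ndarray, float]:
    """Fraction of EdU-positive (S-phase) cells by log-intensity thresholding.

    Returns (fraction, per-cell boolean calls, threshold in intensity units).
    ``gmm2`` fits a 2-component Gaussian mixture on log intensity and falls
    back to Otsu when the components are not separated.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no intensities given")
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        calls = x > fixed_threshold
        return float(calls.mean()), calls, float(fixed_threshold)
    if x.size < 50:
        raise ValueError("automatic thresholding needs >= 50 cells")
    logx = np.log10(np.clip(x, 1e-12, None))
    if method == "gmm2":
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(logx[:, None])
        mu = gm.means_.ravel()
        sd = np.sqrt(gm.covariances_.ravel())
        # Ashman's D < 2: the two components do not form separable modes
        ashman_d = np.sqrt(2.0) * abs(mu[0] - mu[1]) / np.sqrt(np.sum(sd**2))
        if ashman_d < 2.0:
            warnings.warn("unimodal input: gmm2 falling back to otsu_log",
                          stacklevel=2)
            method = "otsu_log"
        else:
            grid = np.linspace(mu.min(), mu.max(), 512)
            post = gm.predict_proba(grid[:, None])
            hi = int(np.argmax(mu))
            cross = grid[int(np.argmin(np.abs(post[:, hi] - 0.5)))]
            thr = 10.0**cross
            calls = x > thr
            return float(calls.mean()), calls, float(thr)
    if method == "otsu_log":
        try:
            thr_log = threshold_otsu(logx)
        except ValueError:  # constant input
            calls = np.zeros_like(x, dtype=bool)
            return 0.0, calls, float("inf")
        thr = 10.0**thr_log
        calls = x > thr
        return float(calls.mean()), calls, float(thr)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EUSummary:
    sample: np.ndarray
    mean: float
    sd: float
    n: int


def eu_summarize(intensities: np.ndarray, sample_n: int = 1000,
                 rng_seed: int = 0) -> EUSummary:
    """Seeded uniform subsample (without replacement) of per-cell EU signal."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no intensities given")
    rng = np.random.default_rng(rng_seed)
    if sample_n >= x.size:
        if sample_n > x.size:
            warnings.warn(f"sample_n={sample_n} > n={x.size}; using all cells",
                          stacklevel=2)
        sample = x.copy()
    else:
        sample = rng.choice(x, size=sample_n, replace=False)
    return EUSummary(sample=sample, mean=float(sample.mean()),
                     sd=float(sample.std(ddof=1)) if sample.size > 1 else 0.0,
                     n=int(sample.size))


def dose_response_table(summaries: pd.DataFrame, readout: str = "EU",
                        dose_col: str = "dose",
                        response_col: str = "response") -> pd.DataFrame:
    """Normalise per-dose summaries to the vehicle (dose 0) mean.

    Duplicate doses are aggregated by mean with ``n`` recorded. Requires a
    vehicle row; a non-monotone response is logged, not rejected.
    """
    df = summaries[[dose_col, response_col]].rename(
        columns={dose_col: "dose", response_col: "response"})
    agg = df.groupby("dose", as_index=False).agg(
        response=("response", "mean"), n=("response", "size"))
    if not (agg["dose"] == 0).any():
        raise ValueError("dose-response table requires a vehicle (dose 0) row")
    if agg["dose"].nunique() < 4:
        warnings.warn("fewer than 4 distinct doses", stacklevel=2)
    vehicle = float(agg.loc[agg["dose"] == 0, "response"].iloc[0])
    agg["response_norm"] = agg["response"] / vehicle
    agg = agg.sort_values("dose").reset_index(drop=True)
    diffs = np.diff(agg["response_norm"])
    if (diffs > 0.05).any():
        import logging

        logging.getLogger(__name__).info(
            "non-monotone %s dose-response (max rise %.3f)", readout,
            float(diffs.max()))
    agg["readout"] = readout
    return agg
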