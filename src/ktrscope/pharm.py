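"""Dose-response fitting, Bliss-independence synergy, tumor volume.

The dose-response model is the four-parameter logistic (4PL)

    y(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

fitted by least squares on log dose with multi-start initialisation. Bliss
independence predicts combined inhibition ``ya + yb - ya*yb`` from the
single-agent margins; the synergy score is the mean excess over that
expectation (x100), with a seeded cell-wise bootstrap CI over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def hill4(dose: np.ndarray, bottom: float, top: float, ic50: float,
          hill: float) -> np.ndarray:
    """Four-parameter logistic response (y = top at dose 0)."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(top))
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (dose[pos] / ic50) ** hill)
    return out


@dataclass
class DoseResponseResults:
    """Result of a 4PL fit: estimates, uncertainties and diagnostics."""

    bottom: float
    top: float
    ic50: float
    hill: float
    bse: dict[str, float]
    rss: float
    converged: bool
    n_obs: int
    doses: np.ndarray = field(repr=False, default=None)
    responses: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> dict[str, float]:
        return dict(bottom=self.bottom, top=self.top, ic50=self.ic50,
                    hill=self.hill)

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return hill4(dose, self.bottom, self.top, self.ic50, self.hill)

    def summary(self) -> str:
        lines = ["4PL dose-response fit",
                 f"  n_obs      {self.n_obs}",
                 f"  converged  {self.converged}"]
        for name in ("bottom", "top", "ic50", "hill"):
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:<9} {getattr(self, name):10.4g}"
                         f"  (se {se:.3g})")
        lines.append(f"  RSS        {self.rss:.4g}")
        return "\n".join(lines)


class HillCurveModel:
    """4PL dose-response model in the model/results idiom.

    >>> res = HillCurveModel(doses, responses).fit()
    >>> res.ic50, res.summary()
    """

    def __init__(self, doses: np.ndarray, responses: np.ndarray) -> None:
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape:
            raise ValueError("doses and responses must have equal length")
        if (doses < 0).any():
            raise ValueError("doses must be >= 0")
        pos = doses[doses > 0]
        if np.unique(doses).size < 4:
            raise ValueError("need >= 4 distinct doses")
        if pos.size and np.log10(pos.max() / pos.min()) < 2:
            raise ValueError("positive doses must span >= 2 log10 units")
        self.doses = doses
        self.responses = responses

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "dose",
                       response_col: str = "response_norm") -> "HillCurveModel":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy())

    def fit(self) -> DoseResponseResults:
        d = self.doses
        y = self.responses
        pos = d[d > 0]
        lo, hi = y.min(), y.max()
        span = hi - lo

        def resid(p):
            bottom, top, log_ic50, hill = p
            return hill4(d, bottom, top, 10.0**log_ic50, hill) - y

        log_lo = np.log10(pos.min()) - 2
        log_hi = np.log10(pos.max()) + 2
        starts = []
        for lic in np.quantile(np.log10(pos), [0.25, 0.5, 0.75]):
            for h in (0.5, 1.0, 2.0, 4.0):
                starts.append([lo, hi, lic, h])
        best = None
        for p0 in starts:
            try:
                sol = least_squares(
                    resid, p0,
                    bounds=([-np.inf, -np.inf, log_lo, 0.05],
                            [np.inf, np.inf, log_hi, 10.0]))
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            return DoseResponseResults(np.nan, np.nan, np.nan, np.nan, {},
                                       np.nan, False, d.size, d, y)
        bottom, top, log_ic50, hill = best.x
        rss = float(2 * best.cost)
        # order so bottom <= top
        if bottom > top:
            bottom, top = top, bottom
            hill = -hill
        # a flat curve has no identifiable ic50
        fitted_span = abs(top - bottom)
        identifiable = fitted_span > 0.05 * max(abs(top), abs(bottom), 1e-12)
        bse = {}
        try:
            jac = best.jac
            dof = max(d.size - 4, 1)
            cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            ic50 = 10.0**log_ic50
            bse = dict(bottom=se[0], top=se[1],
                       ic50=se[2] * ic50 * np.log(10), hill=se[3])
        except np.linalg.LinAlgError:
            pass
        converged = bool(identifiable)
        return DoseResponseResults(
            float(bottom), float(top),
            float(10.0**log_ic50) if converged else float("nan"), float(hill),
            bse, rss, converged, d.size, d, y)


def fit_ic50(table: pd.DataFrame | None = None, doses: np.ndarray | None = None,
             responses: np.ndarray | None = None) -> DoseResponseResults:
    """Fit the 4PL model to a normalised dose-response table.

    Accepts either a table with ``dose`` and ``response_norm`` columns (as
    produced by :func:`ktrscope.pheno.dose_response_table`) or explicit
    arrays.
    """
    if table is not None:
        model = HillCurveModel.from_dataframe(table)
    else:
        model = HillCurveModel(doses, responses)
    return model.fit()


def ic50_recovery_study(ic50: float = 10.0, hill: float = 1.0,
                        noise_cv: float = 0.05, n_sim: int = 100,
                        rng_seed: int = 0,
                        doses: np.ndarray | None = None) -> np.ndarray:
    """Relative IC50 errors over repeated fits to noisy 4PL curves.

    Each simulated curve is the unit-window 4PL (top 1, bottom 0) on a
    two-fold dilution series centred on the true IC50, perturbed by
    multiplicative Gaussian noise with coefficient of variation
    ``noise_cv`` (constant-CV measurement error). Returns the array of
    ``|ic50_hat - ic50| / ic50``.
    """
    if doses is None:
        doses = np.concatenate([[0.0], ic50 * 2.0 ** np.arange(-3.5, 4.0)])
    rng = np.random.default_rng(rng_seed)
    y0 = hill4(doses, 0.0, 1.0, ic50, hill)
    errors = np.empty(n_sim)
    for i in range(n_sim):
        y = y0 * (1.0 + rng.normal(0.0, noise_cv, doses.size)) if noise_cv else y0
        res = HillCurveModel(doses, y).fit()
        errors[i] = (abs(res.ic50 - ic50) / ic50 if res.converged
                     and np.isfinite(res.ic50) else np.inf)
    return errors


# ---------------------------------------------------------------------------
# Bliss synergy


@dataclass
class DoseMatrix:
    """Checkerboard of inhibition fractions with replicates.

    ``inhibition`` has shape ``(n_replicates, len(doses_a), len(doses_b))``
    with values in [0, 1] (fraction inhibited; 0 = vehicle-level response).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.ndim == 2:
            self.inhibition = self.inhibition[np.newaxis]
        if self.inhibition.shape[1:] != (self.doses_a.size, self.doses_b.size):
            raise ValueError("inhibition shape does not match dose grids")

    @property
    def n_replicates(self) -> int:
        return self.inhibition.shape[0]

    @property
    def mean_inhibition(self) -> np.ndarray:
        return self.inhibition.mean(axis=0)

    def transpose(self) -> "DoseMatrix":
        """Relabel drugs A <-> B."""
        return DoseMatrix(self.doses_b.copy(), self.doses_a.copy(),
                          np.transpose(self.inhibition, (0, 2, 1)))

    def to_dataframe(self) -> pd.DataFrame:
        rep, ia, ib = np.meshgrid(np.arange(self.n_replicates),
                                  np.arange(self.doses_a.size),
                                  np.arange(self.doses_b.size), indexing="ij")
        return pd.DataFrame({
            "dose_a": self.doses_a[ia.ravel()],
            "dose_b": self.doses_b[ib.ravel()],
            "replicate": rep.ravel(),
            "inhibition": self.inhibition.ravel(),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "inhibition",
                       as_response: bool = False) -> "DoseMatrix":
        """Build from long format (dose_a, dose_b, replicate, value).

        With ``as_response=True`` the value column holds vehicle-normalised
        responses and is converted to inhibition ``y = 1 - response``.
        """
        da = np.sort(df["dose_a"].unique())
        db = np.sort(df["dose_b"].unique())
        reps = np.sort(df["replicate"].unique()) if "replicate" in df else [0]
        cube = np.full((len(reps), da.size, db.size), np.nan)
        ra = {v: i for i, v in enumerate(da)}
        rb = {v: i for i, v in enumerate(db)}
        rr = {v: i for i, v in enumerate(reps)}
        for row in df.itertuples():
            r = rr[getattr(row, "replicate", 0)]
            val = getattr(row, value_col)
            cube[r, ra[row.dose_a], rb[row.dose_b]] = (1.0 - val) if as_response else val
        if np.isnan(cube).any():
            raise ValueError("incomplete dose matrix")
        return cls(da, db, cube)


@dataclass
class SynergyResult:
    """Bliss-independence analysis of a dose matrix."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    excess: np.ndarray
    score: float
    ci_low: float
    ci_high: float
    n_replicates: int

    def summary(self) -> str:
        return (f"Bliss synergy score {self.score:.2f} "
                f"(95% CI {self.ci_low:.2f} to {self.ci_high:.2f}; "
                f"{self.n_replicates} replicates, "
                f"{self.doses_a.size}x{self.doses_b.size} grid)")


def _bliss_surfaces(obs: np.ndarray):
    # re-reference to the measured vehicle cell so the zero-dose margins
    # carry zero excess by construction, and clamp to effect probabilities
    corr = np.clip(obs - obs[0, 0], 0.0, 1.0)
    ya = corr[:, 0]
    yb = corr[0, :]
    expected = ya[:, None] + yb[None, :] - np.outer(ya, yb)
    return corr, expected, corr - expected


def bliss_synergy(matrix: DoseMatrix, n_boot: int = 1000,
                  rng_seed: int = 0) -> SynergyResult:
    """Score a checkerboard against the Bliss independence expectation.

    The replicate-mean matrix is re-referenced to its measured vehicle cell
    and clamped to [0, 1]; single-agent effects ``ya``, ``yb`` are its
    zero-dose margins, so margin cells carry zero excess by construction.
    Excess is observed minus ``ya + yb - ya*yb`` and the summary score is
    ``100 x mean(excess)`` over the grid. The CI is a seeded cell-wise
    nonparametric bootstrap over replicates (percentiles 2.5 / 97.5).
    """
    if 0.0 not in matrix.doses_a or 0.0 not in matrix.doses_b:
        raise ValueError("dose matrix must include zero-dose margins")
    ia = int(np.nonzero(matrix.doses_a == 0.0)[0][0])
    ib = int(np.nonzero(matrix.doses_b == 0.0)[0][0])
    # roll margins to index 0 for the formulae
    cube = np.roll(np.roll(matrix.inhibition, -ia, axis=1), -ib, axis=2)
    obs, expected, excess = _bliss_surfaces(cube.mean(axis=0))
    score = 100.0 * float(excess.mean())

    n_rep = cube.shape[0]
    if n_rep > 1 and n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        shape = cube.shape[1:]
        scores = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_rep, size=(n_rep, *shape))
            boot = np.take_along_axis(cube, idx, axis=0).mean(axis=0)
            _, _, exc = _bliss_surfaces(boot)
            scores[b] = 100.0 * exc.mean()
        ci_low, ci_high = (float(x) for x in np.percentile(scores, [2.5, 97.5]))
    else:
        ci_low = ci_high = score

    # un-roll surfaces back to the input dose ordering
    def unroll(m):
        return np.roll(np.roll(m, ia, axis=0), ib, axis=1)

    return SynergyResult(matrix.doses_a, matrix.doses_b, unroll(obs),
                         unroll(expected), unroll(excess), score,
                         ci_low, ci_high, n_rep)


# ---------------------------------------------------------------------------
# caliper tumor volume


@dataclass(frozen=True)
class TumorMeasure:
    width_mm: float
    length_mm: float

    @property
    def volume_mm3(self) -> float:
        return tumor_volume(self.width_mm, self.length_mm)


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper tumor volume ``width^2 x length / 2`` (mm^3).

    The shorter measurement is used as the width regardless of argument
    order.
    """
    w = np.asarray(width_mm, dtype=float)
    length = np.asarray(length_mm, dtype=float)
    if (w <= 0).any() or (length <= 0).any():
        raise ValueError("caliper measurements must be > 0")
    lo = np.minimum(w, length)
    hi = np.maximum(w, length)
    out = lo**2 * hi / 2.0
    return float(out) if out.ndim == 0 else out
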