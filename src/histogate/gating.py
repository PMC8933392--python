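"""Two-Gaussian mixture gating of single-cell fluorescence intensities.

Raw mean fluorescence intensities are normalized across samples — per marker,
``x -> log10(x + 1)`` followed by an additive per-sample shift aligning each
sample's median to the pooled median — then a two-component univariate
Gaussian mixture is fitted per marker by EM on the pooled normalized values.
The positive threshold is the peak of the positive (higher-mean) component,
i.e. its mean mu2, and is mapped back to the raw scale per sample by
inverting the stored transform. Cells are called positive by strict
comparison (normalized value > mu2); a value exactly at the threshold is
negative. This gate deliberately reproduces the peak-of-positive rule rather
than the inter-component valley, so roughly the lower half of the positive
component falls below it by construction.

The model-fitting surface follows the statsmodels convention: build a
:class:`TwoGaussianGateModel` from an intensity table, call :meth:`fit`, and
read estimates, gates and a ``summary()`` off the returned
:class:`GatingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import ValidationError, ZeroVarianceError

_LOG_OFFSET = 1.0  # log10(x + 1) keeps zero intensities finite


@dataclass(frozen=True)
class NormalizationTransforms:
    """Invertible per-(marker, sample) normalization bookkeeping.

    ``shifts[marker][sample_id]`` is the additive log10 shift applied after
    the log transform; ``flagged`` lists (marker, sample) pairs whose
    intensities were all zero (shift forced to 0).
    """

    shifts: dict
    flagged: tuple = ()

    def forward(self, raw, marker: str, sample_id: str) -> np.ndarray:
        return np.log10(np.asarray(raw, float) + _LOG_OFFSET) + self.shifts[marker][sample_id]

    def inverse(self, normalized, marker: str, sample_id: str) -> np.ndarray:
        return np.power(10.0, np.asarray(normalized, float) - self.shifts[marker][sample_id]) - _LOG_OFFSET


def normalize_intensities(
    table: pd.DataFrame, markers: list[str] | None = None
) -> tuple[pd.DataFrame, NormalizationTransforms]:
    """Normalize a raw intensity table across samples.

    Returns the normalized table (same layout, marker columns replaced by
    normalized values) and the stored transforms. Requires columns cell_id,
    sample_id and at least one marker column with nonnegative intensities.
    """
    if "sample_id" not in table.columns:
        raise ValidationError("table must have a sample_id column")
    markers = markers or [c for c in table.columns if c not in ("cell_id", "sample_id")]
    if not markers:
        raise ValidationError("no marker columns found")
    out = table.copy()
    shifts: dict = {}
    flagged = []
    for marker in markers:
        x = table[marker].to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValidationError(f"negative intensities in marker {marker!r}")
        logx = np.log10(x + _LOG_OFFSET)
        pooled_median = float(np.median(logx))
        shifts[marker] = {}
        normed = np.empty_like(logx)
        for sid, idx in table.groupby("sample_id").indices.items():
            if len(idx) == 0:
                raise ValidationError(f"sample {sid!r} has no cells")
            if np.all(x[idx] == 0):
                shift = 0.0
                flagged.append((marker, sid))
            else:
                shift = pooled_median - float(np.median(logx[idx]))
            shifts[marker][sid] = shift
            normed[idx] = logx[idx] + shift
        out[marker] = normed
    return out, NormalizationTransforms(shifts=shifts, flagged=tuple(flagged))


@dataclass(frozen=True)
class GmmFit:
    """A fitted 2-component univariate Gaussian mixture (mu1 < mu2)."""

    marker: str
    weights: tuple
    means: tuple
    variances: tuple
    n_iterations: int
    log_likelihood: float
    converged: bool
    loglik_trace: tuple = field(repr=False, default=())


def _em_run(x: np.ndarray, w, mu, var, max_iter: int, tol: float, var_floor: float):
    """One EM run from the given start; returns params, trace, converged."""
    n = x.size
    w = np.asarray(w, float).copy()
    mu = np.asarray(mu, float).copy()
    var = np.maximum(np.asarray(var, float), var_floor)
    trace = []
    converged = False
    for it in range(1, max_iter + 1):
        # E-step in log space for stability
        log_comp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], np.sqrt(var)[:, None])
        log_px = logsumexp(log_comp, axis=0)
        ll = float(log_px.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        resp = np.exp(log_comp - log_px[None, :])
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.array([
            float(resp[k] @ (x - mu[k]) ** 2 / nk[k]) for k in range(2)
        ])
        var = np.maximum(var, var_floor)
    return w, mu, var, trace, converged


def fit_gmm2(
    values,
    seed: int = 0,
    marker: str = "",
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 5,
    var_floor: float = 1e-6,
) -> GmmFit:
    """Fit a 2-component Gaussian mixture by EM with multiple restarts.

    Initialization splits the sorted data at a quantile (the median for the
    first restart, seeded random quantiles in [0.25, 0.75] for the others);
    the run with the best final log-likelihood wins. Components are reordered
    so mu1 < mu2. The per-iteration log-likelihood trace is retained and is
    non-decreasing by construction of EM.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 20:
        raise ValidationError("need at least 20 values to fit a 2-component mixture")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("mixture fit undefined for constant values")
    rng = np.random.default_rng(seed)
    xs = np.sort(x)
    best = None
    for r in range(max(1, n_restarts)):
        q = 0.5 if r == 0 else float(rng.uniform(0.25, 0.75))
        split = max(1, min(x.size - 1, int(round(q * x.size))))
        lo, hi = xs[:split], xs[split:]
        mu0 = np.array([lo.mean(), hi.mean()])
        var0 = np.maximum(np.array([lo.var(), hi.var()]), var_floor)
        w0 = np.array([split / x.size, 1 - split / x.size])
        w0 = np.clip(w0, 1e-3, 1 - 1e-3)
        w0 /= w0.sum()
        w, mu, var, trace, converged = _em_run(x, w0, mu0, var0, max_iter, tol, var_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, var, trace, converged)
    w, mu, var, trace, converged = best
    order = np.argsort(mu)
    return GmmFit(
        marker=marker,
        weights=tuple(float(w[k]) for k in order),
        means=tuple(float(mu[k]) for k in order),
        variances=tuple(float(var[k]) for k in order),
        n_iterations=len(trace),
        log_likelihood=float(trace[-1]),
        converged=bool(converged),
        loglik_trace=tuple(trace),
    )


@dataclass(frozen=True)
class GateResult:
    """Positivity gate for one marker: mu2 on the normalized scale, mapped
    back to a raw threshold per sample via the stored shifts."""

    marker: str
    threshold_normalized: float
    threshold_raw_per_sample: dict


def gate_marker(fit: GmmFit, transforms: NormalizationTransforms, force: bool = False) -> GateResult:
    """Set the gate at the peak (mean) of the positive component.

    Refuses a non-converged fit unless ``force`` is given.
    """
    if not fit.converged and not force:
        raise ValidationError(
            f"mixture fit for {fit.marker!r} did not converge; pass force=True to gate anyway"
        )
    mu2 = fit.means[1]
    per_sample = {
        sid: float(np.power(10.0, mu2 - shift) - _LOG_OFFSET)
        for sid, shift in transforms.shifts[fit.marker].items()
    }
    return GateResult(
        marker=fit.marker, threshold_normalized=float(mu2), threshold_raw_per_sample=per_sample
    )


def call_positive(normalized_table: pd.DataFrame, gate: GateResult) -> pd.Series:
    """Per-cell positivity: normalized value strictly above the gate."""
    missing = set(normalized_table["sample_id"]) - set(gate.threshold_raw_per_sample)
    if missing:
        raise ValidationError(f"gate does not cover samples: {sorted(missing)}")
    return normalized_table[gate.marker] > gate.threshold_normalized


class TwoGaussianGateModel:
    """Mixture-gating model over a raw cells x markers intensity table.

    Parameters
    ----------
    table : DataFrame with cell_id, sample_id and marker columns (raw MFI).
    markers : markers to gate; defaults to every non-id column.
    per_sample : fit one mixture per sample instead of pooling across samples
        after normalization (non-default sensitivity option).
    """

    def __init__(self, table: pd.DataFrame, markers: list[str] | None = None,
                 per_sample: bool = False):
        self.table = table
        self.markers = markers or [c for c in table.columns if c not in ("cell_id", "sample_id")]
        self.per_sample = per_sample
        self.normalized, self.transforms = normalize_intensities(table, self.markers)

    def fit(self, seed: int = 0, **em_kwargs) -> "GatingResults":
        fits: dict = {}
        gates: dict = {}
        for i, marker in enumerate(self.markers):
            if self.per_sample:
                fits[marker] = {}
                gates[marker] = {}
                for sid, grp in self.normalized.groupby("sample_id"):
                    f = fit_gmm2(grp[marker], seed=seed + i, marker=marker, **em_kwargs)
                    fits[marker][sid] = f
                    gates[marker][sid] = gate_marker(f, self.transforms, force=True)
            else:
                f = fit_gmm2(self.normalized[marker], seed=seed + i, marker=marker, **em_kwargs)
                fits[marker] = f
                gates[marker] = gate_marker(f, self.transforms, force=not f.converged)
        return GatingResults(self, fits, gates)


class GatingResults:
    """Fitted gates; exposes per-marker estimates, calls and a summary table."""

    def __init__(self, model: TwoGaussianGateModel, fits: dict, gates: dict):
        self.model = model
        self.fits = fits
        self.gates = gates

    def call_positive(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        """Boolean positivity calls per marker (pooled-fit mode)."""
        if self.model.per_sample:
            raise NotImplementedError("per-sample gates: call per sample explicitly")
        if table is None:
            normalized = self.model.normalized
        else:
            normalized = table.copy()
            for m in self.model.markers:
                for sid, idx in table.groupby("sample_id").indices.items():
                    normalized.loc[normalized.index[idx], m] = self.model.transforms.forward(
                        table[m].to_numpy(float)[idx], m, sid
                    )
        calls = normalized[["cell_id", "sample_id"]].copy()
        for m in self.model.markers:
            calls[m] = call_positive(normalized, self.gates[m])
        return calls

    def summary(self) -> str:
        lines = ["Two-Gaussian mixture gates (threshold = mean of positive component)"]
        lines.append(
            f"{'marker':>16} {'w1':>7} {'w2':>7} {'mu1':>8} {'mu2':>8} "
            f"{'sd1':>7} {'sd2':>7} {'iter':>5} {'conv':>5}"
        )
        for m in self.model.markers:
            f = self.fits[m]
            if isinstance(f, dict):
                for sid, fs in f.items():
                    lines.append(self._row(f"{m}[{sid}]", fs))
            else:
                lines.append(self._row(m, f))
        return "\n".join(lines)

    @staticmethod
    def _row(name: str, f: GmmFit) -> str:
        return (
            f"{name:>16} {f.weights[0]:>7.3f} {f.weights[1]:>7.3f} "
            f"{f.means[0]:>8.3f} {f.means[1]:>8.3f} "
            f"{np.sqrt(f.variances[0]):>7.3f} {np.sqrt(f.variances[1]):>7.3f} "
            f"{f.n_iterations:>5d} {str(f.converged):>5}"
        )

    def gate_report(self) -> dict:
        """JSON-serializable per-marker gate report."""
        report = {}
        for m in self.model.markers:
            f, g = self.fits[m], self.gates[m]
            if isinstance(f, dict):
                report[m] = {
                    sid: _fit_dict(f[sid], g[sid]) for sid in f
                }
            else:
                report[m] = _fit_dict(f, g)
        return report


def _fit_dict(f: GmmFit, g: GateResult) -> dict:
    return {
        "weights": list(f.weights),
        "means": list(f.means),
        "variances": list(f.variances),
        "n_iterations": f.n_iterations,
        "log_likelihood": f.log_likelihood,
        "converged": f.converged,
        "threshold_normalized": g.threshold_normalized,
        "threshold_raw_per_sample": g.threshold_raw_per_sample,
    }
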