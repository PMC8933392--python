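"""Observer concordance and Bland-Altman DAB-threshold calibration.

The DAB positivity threshold is chosen by scoring a panel of test images at
each candidate threshold and comparing the automated DAB-positive counts to
the across-observer mean manual counts with a Bland-Altman analysis; the
selected threshold is the candidate with the smallest absolute bias (ties
broken toward the larger, more conservative threshold). Pairwise Pearson
correlation quantifies inter-observer concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError, ZeroVarianceError
from .ihc import ScoringConfig, StainedImage, apply_dab_threshold, measure_image


def pearson_concordance(counts_a, counts_b) -> tuple[float, float]:
    """Pearson r with a two-sided t-distributed p-value.

    Requires n >= 3 and nonzero variance in both vectors.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("count vectors must be 1-D with equal length")
    if a.size < 3:
        raise ValidationError("need at least 3 paired counts")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("correlation undefined for constant counts")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between manual and automated counts via paired differences.

    ``bias`` is mean(manual - automated); ``loa_low/high`` are the 1.96-SD
    limits of agreement; ``ci_low/high`` is the 95% t-based confidence
    interval of the bias. Both interval types are reported and labelled since
    they answer different questions (spread of differences vs uncertainty of
    the mean difference).
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float


def bland_altman(manual_mean, automated) -> BlandAltmanResult:
    """Bland-Altman statistics of the paired differences manual - automated."""
    m = np.asarray(manual_mean, dtype=float)
    a = np.asarray(automated, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValidationError("vectors must be 1-D with equal length")
    n = m.size
    if n < 2:
        raise ValidationError("need at least 2 paired measurements")
    d = m - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    t = float(stats.t.ppf(0.975, n - 1))
    ci_half = t * sd / np.sqrt(n)
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half,
        loa_high=bias + half,
        ci_low=bias - ci_half,
        ci_high=bias + ci_half,
    )


@dataclass(frozen=True)
class CalibrationReport:
    """Outcome of the candidate-threshold sweep."""

    candidate_thresholds: tuple
    results: dict  # threshold -> BlandAltmanResult
    selected_threshold: float
    observer_pearson: pd.DataFrame | None
    manual_means: tuple
    automated_counts: dict  # threshold -> tuple of per-image counts

    def summary(self) -> str:
        lines = ["DAB threshold calibration (Bland-Altman vs mean manual counts)"]
        lines.append(f"{'threshold':>10} {'bias':>10} {'sd_diff':>10} "
                     f"{'LoA_low':>10} {'LoA_high':>10} {'CI_low':>10} {'CI_high':>10}")
        for t in self.candidate_thresholds:
            r = self.results[t]
            mark = " <- selected" if t == self.selected_threshold else ""
            lines.append(
                f"{t:>10.3g} {r.bias:>10.3f} {r.sd_diff:>10.3f} "
                f"{r.loa_low:>10.3f} {r.loa_high:>10.3f} {r.ci_low:>10.3f} {r.ci_high:>10.3f}{mark}"
            )
        if self.observer_pearson is not None:
            lines.append("pairwise observer Pearson r:")
            lines.append(self.observer_pearson.to_string())
        return "\n".join(lines)


def select_threshold(bias_by_candidate: dict) -> float:
    """Argmin of |bias| over candidates; ties go to the larger threshold."""
    return max(
        bias_by_candidate, key=lambda t: (-abs(bias_by_candidate[t]), t)
    )


def observer_pearson_matrix(observers: pd.DataFrame, count_col: str = "dab_count") -> pd.DataFrame | None:
    wide = observers.pivot(index="image_id", columns="observer_id", values=count_col)
    ids = list(wide.columns)
    if len(ids) < 2:
        return None
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            try:
                r, _ = pearson_concordance(wide[a].to_numpy(), wide[b].to_numpy())
            except ZeroVarianceError:
                r = np.nan
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def calibrate_dab_threshold(
    images: Sequence[StainedImage],
    observers: pd.DataFrame,
    candidates: Sequence[float],
    config: ScoringConfig | None = None,
    on_percentages: bool = False,
) -> CalibrationReport:
    """Sweep candidate DAB thresholds against manual observer counts.

    ``observers`` is a long table (image_id, observer_id, dab_count[,
    hema_count]); rows must cover every image in order ``img1..imgN`` matching
    ``images``. The manual reference per image is the across-observer mean
    DAB count. With ``on_percentages`` the comparison uses percent-positive
    values instead of counts (requires hema_count).
    """
    config = config or ScoringConfig()
    candidates = tuple(float(c) for c in candidates)
    if len(images) < 2:
        raise ValidationError("need at least 2 images")
    if len(candidates) < 1:
        raise ValidationError("need at least 1 candidate threshold")
    required = {"image_id", "observer_id", "dab_count"}
    if observers is None or len(observers) == 0 or not required.issubset(observers.columns):
        raise ValidationError(
            "observer table must be nonempty with columns image_id, observer_id, dab_count"
        )
    image_ids = [f"img{i + 1}" for i in range(len(images))]
    if set(image_ids) - set(observers["image_id"]):
        raise ValidationError("observer table does not cover all images")

    if on_percentages:
        if "hema_count" not in observers.columns:
            raise ValidationError("percentage mode requires hema_count column")
        obs = observers.assign(
            value=100.0 * observers["dab_count"] / observers["hema_count"]
        )
    else:
        obs = observers.assign(value=observers["dab_count"].astype(float))
    manual = obs.groupby("image_id")["value"].mean().reindex(image_ids).to_numpy()

    measured = []
    for i, img in enumerate(images):
        try:
            measured.append(measure_image(img, config))
        except Exception as exc:  # noqa: BLE001 - propagate with image id
            raise RuntimeError(f"scoring failed on image {image_ids[i]}") from exc

    results: dict = {}
    counts_by_candidate: dict = {}
    for cand in candidates:
        auto = []
        for dets in measured:
            called = apply_dab_threshold(dets, cand)
            n_pos = sum(d.dab_positive for d in called)
            if on_percentages:
                n_hema = len(called)
                auto.append(100.0 * n_pos / n_hema if n_hema else np.nan)
            else:
                auto.append(float(n_pos))
        counts_by_candidate[cand] = tuple(auto)
        results[cand] = bland_altman(manual, np.asarray(auto))

    selected = select_threshold({c: results[c].bias for c in candidates})
    return CalibrationReport(
        candidate_thresholds=candidates,
        results=results,
        selected_threshold=selected,
        observer_pearson=observer_pearson_matrix(observers),
        manual_means=tuple(manual),
        automated_counts=counts_by_candidate,
    )


def plot_bland_altman(result: BlandAltmanResult, manual, automated, path=None, ax=None):
    """Difference-vs-mean plot with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    m = np.asarray(manual, float)
    a = np.asarray(automated, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((m + a) / 2, m - a, s=20)
    ax.axhline(result.bias, color="k", label=f"bias {result.bias:.2f}")
    for y, lab in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="gray", linestyle="--", label=f"{lab} {y:.2f}")
    ax.set_xlabel("mean of manual and automated count")
    ax.set_ylabel("manual - automated")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
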