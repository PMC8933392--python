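"""Cohort-level p16 classification at the 30% positivity cutoff.

A sample is 'positive' when its percent of p16-positive cells strictly
exceeds the cutoff (default 30%), otherwise 'deficient' (exactly 30% falls
deficient, keeping one consistent strict rule). The cohort summary reports
deficient counts and proportion, per-tissue-source means +/- SD, Pearson
concordance over matched PDX/patient pairs, and an unpaired two-sided t-test
between sources. CDKN2A copy number is carried as annotation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import pearson_concordance
from .errors import ValidationError

DEFICIENT = "deficient"
POSITIVE = "positive"
DEFAULT_CUTOFF = 30.0


def classify_sample(percent_positive: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """'positive' iff percent_positive > cutoff (strict), else 'deficient'."""
    if not 0.0 <= percent_positive <= 100.0:
        raise ValidationError("percent_positive must be in [0, 100]")
    return POSITIVE if percent_positive > cutoff else DEFICIENT


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    tissue_source: str  # 'PDX' or 'patient'
    percent_positive: float
    matched_id: str | None = None
    subtype: str | None = None
    cdkn2a_cnv: int | None = None  # annotation only

    def __post_init__(self):
        if self.tissue_source not in ("PDX", "patient"):
            raise ValidationError("tissue_source must be 'PDX' or 'patient'")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValidationError("percent_positive must be in [0, 100]")

    @property
    def p16_class(self) -> str:
        return classify_sample(self.percent_positive)


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_deficient: int
    proportion_deficient: float
    per_source: dict  # source -> {'n', 'mean', 'sd'}
    matched_r: float | None
    matched_r_p: float | None
    ttest_p: float | None
    n_matched_pairs: int
    flags: tuple = ()

    def summary(self) -> str:
        lines = [
            f"cohort: n = {self.n_total}, deficient = {self.n_deficient} "
            f"({100 * self.proportion_deficient:.1f}%)"
        ]
        for src, s in self.per_source.items():
            lines.append(f"  {src}: n = {s['n']}, mean = {s['mean']:.1f}% +/- {s['sd']:.1f}%")
        if self.matched_r is not None:
            lines.append(
                f"  matched pairs (n = {self.n_matched_pairs}): "
                f"r = {self.matched_r:.2f}, p = {self.matched_r_p:.3g}"
            )
        if self.ttest_p is not None:
            lines.append(f"  unpaired t-test between sources: p = {self.ttest_p:.3g}")
        for f in self.flags:
            lines.append(f"  flag: {f}")
        return "\n".join(lines)


def _matched_pairs(records: Sequence[CohortRecord]) -> tuple[np.ndarray, np.ndarray]:
    by_source: dict = {"PDX": {}, "patient": {}}
    for r in records:
        if r.matched_id:
            by_source[r.tissue_source][r.matched_id] = r.percent_positive
    shared = sorted(set(by_source["PDX"]) & set(by_source["patient"]))
    pdx = np.array([by_source["PDX"][k] for k in shared], dtype=float)
    pat = np.array([by_source["patient"][k] for k in shared], dtype=float)
    return pdx, pat


def summarize_cohort(records: Sequence[CohortRecord], cutoff: float = DEFAULT_CUTOFF) -> CohortSummary:
    """Classify every record at the cutoff and aggregate cohort statistics."""
    if not records:
        raise ValidationError("cohort must be nonempty")
    classes = [classify_sample(r.percent_positive, cutoff) for r in records]
    n_def = sum(c == DEFICIENT for c in classes)
    per_source: dict = {}
    flags: list[str] = []
    for src in ("PDX", "patient"):
        vals = np.array([r.percent_positive for r in records if r.tissue_source == src])
        if vals.size:
            per_source[src] = {
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
    pdx, pat = _matched_pairs(records)
    matched_r = matched_p = None
    if len(pdx) >= 3:
        matched_r, matched_p = pearson_concordance(pdx, pat)
    elif len(pdx) > 0:
        flags.append("matched correlation not computable (<3 pairs)")
    ttest_p = None
    if len(per_source) == 2 and all(s["n"] >= 2 for s in per_source.values()):
        a = [r.percent_positive for r in records if r.tissue_source == "PDX"]
        b = [r.percent_positive for r in records if r.tissue_source == "patient"]
        _, ttest_p = stats.ttest_ind(a, b, equal_var=True)
        ttest_p = float(ttest_p)
    return CohortSummary(
        n_total=len(records),
        n_deficient=n_def,
        proportion_deficient=n_def / len(records),
        per_source=per_source,
        matched_r=matched_r,
        matched_r_p=matched_p,
        ttest_p=ttest_p,
        n_matched_pairs=len(pdx),
        flags=tuple(flags),
    )


def concordance_pdx_patient(
    records: Sequence[CohortRecord], paired_ttest: bool = False
) -> tuple[float, float, float]:
    """Pearson r/p over matched percent-positive pairs plus a t-test p-value.

    The t-test between sources is unpaired two-sided Student's by default; a
    paired option is exposed for sensitivity analysis.
    """
    pdx, pat = _matched_pairs(records)
    if len(pdx) < 3:
        raise ValidationError("need at least 3 matched pairs")
    r, p = pearson_concordance(pdx, pat)
    if paired_ttest:
        _, t_p = stats.ttest_rel(pdx, pat)
    else:
        _, t_p = stats.ttest_ind(pdx, pat, equal_var=True)
    return r, p, float(t_p)


def records_from_frame(df: pd.DataFrame) -> list[CohortRecord]:
    """Build cohort records from a CSV-shaped frame (see CohortRecord fields)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CohortRecord(
                sample_id=str(row.sample_id),
                tissue_source=str(row.tissue_source),
                percent_positive=float(row.percent_positive),
                matched_id=(str(row.matched_id) if getattr(row, "matched_id", None) not in (None, "", float("nan")) and not pd.isna(row.matched_id) else None) if "matched_id" in df.columns else None,
                subtype=str(row.subtype) if "subtype" in df.columns and not pd.isna(row.subtype) else None,
                cdkn2a_cnv=int(row.cdkn2a_cnv) if "cdkn2a_cnv" in df.columns and not pd.isna(row.cdkn2a_cnv) else None,
            )
        )
    return records
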