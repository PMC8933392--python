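"""Rule-based phenotyping of normalized single-cell intensities.

Tumor cells are identified by cytokeratin expression above 2.5 on the
normalized (log10-aligned) scale; tumor cells are then flagged positive for
each functional marker by a fixed strict threshold: Lamin B1 > 3.3, cleaved
caspase-3 > 1.9, pH2Ax > 2.9, p16 > 2.8, p-RB > 2.7, PCNA > 3.3. Marker
flags are only meaningful for tumor cells (NA otherwise). Per-section
positive fractions among tumor cells are aggregated per condition as
mean +/- sample SD and compared pairwise by unpaired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DEFAULT_MARKER_THRESHOLDS = {
    "LaminB1": 3.3,
    "cleaved_caspase3": 1.9,
    "pH2Ax": 2.9,
    "p16": 2.8,
    "p_RB": 2.7,
    "PCNA": 3.3,
}


@dataclass(frozen=True)
class TypingRules:
    """Thresholds for tumor identity and per-marker positivity.

    ``lamin_caspase_conjunction`` switches the Lamin B1 call to the
    sensitivity-analysis reading where Lamin B1 positivity requires both
    LaminB1 > 3.3 and cleaved_caspase3 > 1.9; by default the two are
    independent rules.
    """

    tumor_marker: str = "cytokeratin"
    tumor_threshold: float = 2.5
    marker_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_THRESHOLDS)
    )
    lamin_caspase_conjunction: bool = False

    def __post_init__(self):
        if self.tumor_threshold <= 0 or any(t <= 0 for t in self.marker_thresholds.values()):
            raise ValidationError("thresholds must be positive")


def type_cells(table: pd.DataFrame, rules: TypingRules | None = None) -> pd.DataFrame:
    """Assign tumor identity and marker flags to every cell.

    ``table`` carries normalized intensities. Returns a frame with cell_id,
    sample_id, is_tumor, and one boolean column ``<marker>_positive`` per rule
    marker present in the table (pd.NA for non-tumor cells). Typing is
    deterministic and per-cell independent. A missing tumor-marker column is
    an error; missing functional markers are skipped.
    """
    rules = rules or TypingRules()
    if rules.tumor_marker not in table.columns:
        raise ValidationError(f"missing required marker column: {rules.tumor_marker!r}")
    typed = table[[c for c in ("cell_id", "sample_id") if c in table.columns]].copy()
    is_tumor = table[rules.tumor_marker] > rules.tumor_threshold
    typed["is_tumor"] = is_tumor
    for marker, thr in rules.marker_thresholds.items():
        if marker not in table.columns:
            continue
        flag = table[marker] > thr
        if (
            rules.lamin_caspase_conjunction
            and marker == "LaminB1"
            and "cleaved_caspase3" in table.columns
        ):
            flag = flag & (
                table["cleaved_caspase3"] > rules.marker_thresholds["cleaved_caspase3"]
            )
        col = flag.astype("boolean")
        col[~is_tumor] = pd.NA
        typed[f"{marker}_positive"] = col
    return typed


def summarize_by_condition(
    typed: pd.DataFrame,
    section_map: Mapping,
    condition_map: Mapping,
    equal_var: bool = True,
) -> dict:
    """Per-condition marker fractions among tumor cells with t-tests.

    ``section_map`` maps sample_id -> section id and ``condition_map`` maps
    section id -> condition label. Fractions are computed per section over
    tumor cells, then summarized per condition as mean +/- sample SD; every
    pair of conditions is compared with a two-sided unpaired t-test
    (Student's by default, Welch via ``equal_var=False``). Conditions with
    fewer than 2 sections are flagged not-computable in comparisons.
    """
    missing = set(typed["sample_id"]) - set(section_map)
    if missing:
        raise ValidationError(f"samples without a section: {sorted(missing)}")
    df = typed.copy()
    df["section"] = df["sample_id"].map(section_map)
    missing_cond = set(df["section"]) - set(condition_map)
    if missing_cond:
        raise ValidationError(f"sections without a condition: {sorted(missing_cond)}")
    df["condition"] = df["section"].map(condition_map)
    marker_cols = [c for c in df.columns if c.endswith("_positive")]

    tumor = df[df["is_tumor"]]
    per_section = (
        tumor.groupby(["condition", "section"], sort=True)
        .agg(
            n_tumor_cells=("is_tumor", "size"),
            **{m: (m, lambda s: s.astype(float).mean()) for m in marker_cols},
        )
        .reset_index()
    )

    conditions = sorted(per_section["condition"].unique())
    summary: dict = {"per_section": per_section, "conditions": {}, "comparisons": {}}
    for cond in conditions:
        sub = per_section[per_section["condition"] == cond]
        entry = {"n_sections": int(len(sub)), "n_tumor_cells": int(sub["n_tumor_cells"].sum())}
        for m in marker_cols:
            vals = sub[m].to_numpy(dtype=float)
            entry[m] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        summary["conditions"][cond] = entry
    for a, b in combinations(conditions, 2):
        va = per_section[per_section["condition"] == a]
        vb = per_section[per_section["condition"] == b]
        comp: dict = {}
        for m in marker_cols:
            if len(va) < 2 or len(vb) < 2:
                comp[m] = {"computable": False}
                continue
            t, p = stats.ttest_ind(
                va[m].astype(float), vb[m].astype(float), equal_var=equal_var
            )
            comp[m] = {"computable": True, "t": float(t), "p": float(p)}
        summary["comparisons"][(a, b)] = comp
    return summary
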