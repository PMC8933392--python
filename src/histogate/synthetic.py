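"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_ihc_image` renders a brightfield H-DAB field of view by
  placing non-overlapping hematoxylin-stained nuclear disks, assigning a
  controlled fraction of cells DAB chromogen (nuclear or cytoplasmic-ring),
  composing optical density additively per the Beer-Lambert model, and
  converting OD back to quantized 8-bit RGB.
* :func:`simulate_intensity_table` draws per-marker single-cell fluorescence
  from a two-component Gaussian mixture on the log10 scale with additive
  per-sample scale shifts, then exponentiates to raw intensities.
* :func:`simulate_observer_counts` produces manual observer counts as the
  true count plus a per-observer bias and Gaussian miscount noise.

All generators are deterministic given their seed. By default the positive
fraction is assigned exactly (round(fraction * n) cells positive) so that
image-level ground truth is noiseless; i.i.d. Bernoulli assignment is
available via ``exact_assignment=False``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .ihc import StainedImage
from .stains import StainVectorSet, od_to_rgb


@dataclass(frozen=True)
class IhcSimParams:
    """Parameters of one synthetic H-DAB field of view."""

    n_cells: int = 200
    true_positive_fraction: float = 0.3
    nucleus_radius_px: tuple = (6.0, 1.0)  # (mean, sd)
    field_size_px: tuple = (512, 512)
    hema_od_level: float = 0.6
    dab_od_level: float = 0.6
    background_noise_sd: float = 0.01
    cytoplasm_dab_fraction: float = 0.0
    annulus_width_px: int = 3
    min_gap_px: float = 4.0
    exact_assignment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if not 0.0 <= self.true_positive_fraction <= 1.0:
            raise ValidationError("true_positive_fraction must be in [0, 1]")
        if not 0.0 <= self.cytoplasm_dab_fraction <= 1.0:
            raise ValidationError("cytoplasm_dab_fraction must be in [0, 1]")
        if min(self.hema_od_level, self.dab_od_level) < 0 or self.background_noise_sd < 0:
            raise ValidationError("OD levels and noise SD must be >= 0")
        if self.nucleus_radius_px[0] <= 0:
            raise ValidationError("mean nucleus radius must be positive")


@dataclass(frozen=True)
class MarkerMixture:
    """Two-component log10-scale mixture for one marker."""

    negative_mean: float
    positive_mean: float
    sd: float
    positive_fraction: float

    def __post_init__(self):
        if self.positive_mean <= self.negative_mean:
            raise ValidationError("positive_mean must exceed negative_mean")
        if self.sd <= 0:
            raise ValidationError("sd must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValidationError("positive_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CycifSimParams:
    """Parameters of a synthetic multi-sample single-cell intensity table."""

    n_cells_per_sample: int = 2000
    n_samples: int = 2
    markers: Mapping[str, MarkerMixture] = field(
        default_factory=lambda: {"p16": MarkerMixture(1.0, 3.0, 0.1, 0.4)}
    )
    sample_shifts: tuple | None = None  # additive log10 offsets, len n_samples
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_per_sample < 1 or self.n_samples < 1:
            raise ValidationError("need >= 1 cell per sample and >= 1 sample")
        shifts = self.sample_shifts
        if shifts is None:
            shifts = tuple(0.0 for _ in range(self.n_samples))
        shifts = tuple(float(s) for s in shifts)
        if len(shifts) != self.n_samples:
            raise ValidationError("sample_shifts must have one entry per sample")
        object.__setattr__(self, "sample_shifts", shifts)
        if not self.markers:
            raise ValidationError("at least one marker is required")


@dataclass(frozen=True)
class ObserverSimParams:
    """Noisy manual-count model: count = max(0, truth + bias + noise)."""

    n_observers: int = 3
    miscount_dispersion: float = 0.0
    bias_per_observer: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_observers < 1:
            raise ValidationError("n_observers must be >= 1")
        if self.miscount_dispersion < 0:
            raise ValidationError("miscount_dispersion must be >= 0")
        bias = self.bias_per_observer
        if bias is None:
            bias = tuple(0.0 for _ in range(self.n_observers))
        bias = tuple(float(b) for b in bias)
        if len(bias) != self.n_observers:
            raise ValidationError("bias_per_observer must have one entry per observer")
        object.__setattr__(self, "bias_per_observer", bias)


def _exact_flags(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Exactly round(fraction*n) True flags in a seeded random order."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def _place_nuclei(params: IhcSimParams, rng: np.random.Generator):
    h, w = params.field_size_px
    radii = np.clip(
        rng.normal(params.nucleus_radius_px[0], params.nucleus_radius_px[1], params.n_cells),
        2.0,
        None,
    )
    centers = np.empty((params.n_cells, 2))
    max_total_tries = max(2000, 400 * params.n_cells)
    tries = 0
    pad = params.annulus_width_px + 1
    for i in range(params.n_cells):
        placed = False
        while tries < max_total_tries:
            tries += 1
            r = radii[i]
            margin = r + pad
            if 2 * margin >= min(h, w):
                break
            row = rng.uniform(margin, h - margin)
            col = rng.uniform(margin, w - margin)
            if i == 0:
                centers[0] = (row, col)
                placed = True
                break
            d = np.hypot(centers[:i, 0] - row, centers[:i, 1] - col)
            min_d = radii[:i] + r + 2 * params.annulus_width_px + params.min_gap_px
            if np.all(d >= min_d):
                centers[i] = (row, col)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping nuclei in a "
                f"{h}x{w} field after {tries} tries"
            )
    return centers, radii


def simulate_ihc_image(
    params: IhcSimParams, vectors: StainVectorSet | None = None
) -> tuple[StainedImage, pd.DataFrame]:
    """Render one synthetic H-DAB field and return it with per-cell truth.

    Returns ``(image, ground_truth)`` where ground_truth has one row per
    placed cell: cell_id, x (column), y (row), radius_px, dab_positive and
    dab_compartment ('nucleus', 'cytoplasm' or '').
    """
    vectors = vectors or StainVectorSet()
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size_px
    hema_map = np.zeros((h, w))
    dab_map = np.zeros((h, w))

    if params.n_cells > 0:
        centers, radii = _place_nuclei(params, rng)
        if params.exact_assignment:
            positive = _exact_flags(params.n_cells, params.true_positive_fraction, rng)
        else:
            positive = rng.random(params.n_cells) < params.true_positive_fraction
        pos_idx = np.flatnonzero(positive)
        if params.exact_assignment:
            cyto_flags = _exact_flags(len(pos_idx), params.cytoplasm_dab_fraction, rng)
        else:
            cyto_flags = rng.random(len(pos_idx)) < params.cytoplasm_dab_fraction
        cytoplasmic = np.zeros(params.n_cells, dtype=bool)
        cytoplasmic[pos_idx[cyto_flags]] = True

        for i in range(params.n_cells):
            # paint within a local bounding box; placement guarantees the
            # annulus fits inside the field and clears every other cell
            r_out = radii[i] + params.annulus_width_px
            r0 = int(np.floor(centers[i, 0] - r_out))
            c0 = int(np.floor(centers[i, 1] - r_out))
            r1 = int(np.ceil(centers[i, 0] + r_out)) + 1
            c1 = int(np.ceil(centers[i, 1] + r_out)) + 1
            rr, cc = np.mgrid[r0:r1, c0:c1]
            d = np.hypot(rr - centers[i, 0], cc - centers[i, 1])
            nucleus = d <= radii[i]
            hema_map[r0:r1, c0:c1][nucleus] = params.hema_od_level
            if positive[i]:
                if cytoplasmic[i]:
                    ring = (d > radii[i]) & (d <= r_out)
                    dab_map[r0:r1, c0:c1][ring] = params.dab_od_level
                else:
                    dab_map[r0:r1, c0:c1][nucleus] = params.dab_od_level
        truth = pd.DataFrame(
            {
                "cell_id": np.arange(1, params.n_cells + 1),
                "x": centers[:, 1],
                "y": centers[:, 0],
                "radius_px": radii,
                "dab_positive": positive,
                "dab_compartment": [
                    ("cytoplasm" if cytoplasmic[i] else "nucleus") if positive[i] else ""
                    for i in range(params.n_cells)
                ],
            }
        )
    else:
        truth = pd.DataFrame(
            columns=["cell_id", "x", "y", "radius_px", "dab_positive", "dab_compartment"]
        )

    od = (
        hema_map[..., None] * vectors.hematoxylin
        + dab_map[..., None] * vectors.dab
        + rng.normal(0.0, params.background_noise_sd, (h, w, 3))
    )
    od = np.clip(od, 0.0, None)
    rgb = od_to_rgb(od, quantize=True)
    return StainedImage(pixels=rgb), truth


def simulate_intensity_table(
    params: CycifSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cells x markers raw-intensity table plus component labels.

    Per marker, log10 intensity is ``mean_k + N(0, sd) + sample_shift`` with
    component k Bernoulli(positive_fraction); raw intensity is ``10**log10``.
    Returns ``(table, labels)`` with matching cell_id/sample_id columns.
    """
    rng = np.random.default_rng(params.seed)
    n, s = params.n_cells_per_sample, params.n_samples
    sample_ids = np.repeat([f"S{j + 1}" for j in range(s)], n)
    shifts = np.repeat(np.asarray(params.sample_shifts), n)
    total = n * s
    table = pd.DataFrame(
        {"cell_id": np.arange(1, total + 1), "sample_id": sample_ids}
    )
    labels = table[["cell_id", "sample_id"]].copy()
    for marker, mix in params.markers.items():
        is_pos = rng.random(total) < mix.positive_fraction
        mean = np.where(is_pos, mix.positive_mean, mix.negative_mean)
        log10_value = mean + rng.normal(0.0, mix.sd, total) + shifts
        table[marker] = np.power(10.0, log10_value)
        labels[marker] = is_pos
    return table, labels


def simulate_observer_counts(
    true_counts: Sequence[float], params: ObserverSimParams
) -> pd.DataFrame:
    """Generate per-image, per-observer counts from true counts.

    Each observer's count is ``max(0, round(truth + bias + N(0, dispersion)))``.
    Returns a long table with columns image_id, observer_id, count.
    """
    true_counts = np.asarray(true_counts, dtype=float)
    if true_counts.size == 0:
        raise ValidationError("true_counts must be nonempty")
    rng = np.random.default_rng(params.seed)
    rows = []
    for o in range(params.n_observers):
        noise = rng.normal(0.0, params.miscount_dispersion, true_counts.size)
        counts = np.maximum(
            0, np.rint(true_counts + params.bias_per_observer[o] + noise)
        ).astype(int)
        for i, c in enumerate(counts):
            rows.append({"image_id": f"img{i + 1}", "observer_id": f"obs{o + 1}", "count": c})
    return pd.DataFrame(rows)


def simulate_observer_table(
    true_dab: Sequence[float], true_hema: Sequence[float], params: ObserverSimParams
) -> pd.DataFrame:
    """Observer counts for both DAB and hematoxylin in the calibration layout.

    Columns: image_id, observer_id, dab_count, hema_count. DAB and hematoxylin
    miscounts use decorrelated streams derived from the same seed.
    """
    if len(true_dab) != len(true_hema):
        raise ValidationError("true_dab and true_hema must have equal length")
    dab = simulate_observer_counts(true_dab, params)
    hema_params = ObserverSimParams(
        n_observers=params.n_observers,
        miscount_dispersion=params.miscount_dispersion,
        bias_per_observer=params.bias_per_observer,
        seed=params.seed + 1,
    )
    hema = simulate_observer_counts(true_hema, hema_params)
    out = dab.rename(columns={"count": "dab_count"})
    out["hema_count"] = hema["count"].to_numpy()
    return out


def write_ihc_outputs(
    image: StainedImage,
    truth: pd.DataFrame,
    params: IhcSimParams,
    out_dir,
    stem: str = "ihc_field",
    image_format: str = "tiff",
) -> dict:
    """Write image (TIFF/PNG), ground-truth CSV and a JSON params sidecar."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if image_format == "tiff":
        image_path = out_dir / f"{stem}.tiff"
        tifffile.imwrite(image_path, image.pixels)
    elif image_format == "png":
        image_path = out_dir / f"{stem}.png"
        iio.imwrite(image_path, image.pixels)
    else:
        raise ValidationError(f"unsupported image format: {image_format!r}")
    truth_path = out_dir / f"{stem}_truth.csv"
    truth[["cell_id", "x", "y", "dab_positive"]].to_csv(truth_path, index=False)
    params_path = out_dir / f"{stem}_params.json"
    params_path.write_text(json.dumps(asdict(params), indent=2, default=list))
    return {"image": str(image_path), "truth": str(truth_path), "params": str(params_path)}
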