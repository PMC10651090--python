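"""Pattern metrics, body temperatures, block summaries, and heating/cooling rates.

Per-image metrics are the melanistic proportion (melanistic area over the
whole dorsal foreground) and the mean weighted-RGB luminance of the
melanistic and non-melanistic areas, computed on the lightness-standardized
image.  Thermal records carry per-body-part infrared temperatures; the
internal body temperature is the mean of the two eye readings (falling back
to the snout, which tracks the eyes closely, when one eye is unusable).

The experiment is divided into five blocks (start plateau, cooling
transition, cold plateau, heating transition, end plateau).  The cooling rate
of an individual is its block-1 minus block-3 mean body temperature; the
heating rate block-5 minus block-3 — both positive under the intended
25 -> 15 -> 25 degC profile.  Logs (natural) of the rates feed the linear
models; non-positive rates are flagged rather than silently logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import ImageRecord, luminance, REC601_WEIGHTS
from .segmentation import SegmentationResult

__all__ = [
    "PatternMetrics",
    "IndividualPattern",
    "RateRecord",
    "DEFAULT_BLOCK_SCHEDULE",
    "pattern_metrics",
    "summarize_individual",
    "body_temperature",
    "prepare_thermal_table",
    "block_summaries",
    "thermal_rates",
]

logger = logging.getLogger(__name__)

#: Default mapping of the 15 timepoints to blocks 1-5 (3 consecutive each).
DEFAULT_BLOCK_SCHEDULE = {t: (t - 1) // 3 + 1 for t in range(1, 16)}

#: Inside-terrarium datalogger positions; "atmospheric" sits outside.
LOGGER_COLUMNS = ("logger_cold", "logger_warm", "logger_hide")

#: Plausible band for experimental temperatures (degC); a logger reading of
#: exactly 0 is a dead-battery artifact and is flagged invalid.
TEMP_BAND = (0.0, 50.0)


@dataclass(frozen=True)
class PatternMetrics:
    """Per-image melanistic proportion and segment mean luminances."""

    individual_id: str
    seq_index: int
    block: int
    melanistic_proportion: float
    mean_lum_mel: float | None
    mean_lum_nonmel: float
    low_contrast: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.melanistic_proportion <= 1.0:
            raise ValueError("melanistic_proportion must lie in [0, 1]")


@dataclass(frozen=True)
class IndividualPattern:
    """Per-individual summary over accepted images."""

    individual_id: str
    mean_proportion: float
    sd_proportion: float
    log_mean_proportion: float | None
    n_images: int


@dataclass(frozen=True)
class RateRecord:
    """Per-individual block-difference heating/cooling rates (degC)."""

    individual_id: str
    cooling_rate: float  # block1 mean - block3 mean
    heating_rate: float  # block5 mean - block3 mean
    start_end_change: float  # block5 mean - block1 mean
    log_cooling: float | None
    log_heating: float | None


def pattern_metrics(
    img: ImageRecord,
    seg: SegmentationResult,
    lum_weights=REC601_WEIGHTS,
) -> PatternMetrics:
    """Proportion and mean segment luminances for one (standardized) image.

    Images explicitly rejected at QC must not reach this function.  A
    low-contrast segmentation yields proportion 0 with the melanistic
    luminance undefined (``None``).
    """
    if seg.qc_accepted is False:
        raise ValueError("image was rejected at QC; metrics must not be computed")
    n_fg = int(seg.foreground_mask.sum())
    if n_fg == 0:
        raise ValueError("empty foreground")
    n_mel = int(seg.melanistic_mask.sum())
    proportion = n_mel / n_fg

    lum = luminance(img.pixels, lum_weights)
    nonmel = seg.foreground_mask & ~seg.melanistic_mask
    mean_lum_mel = float(lum[seg.melanistic_mask].mean()) if n_mel else None
    mean_lum_nonmel = float(lum[nonmel].mean())
    return PatternMetrics(
        individual_id=img.individual_id,
        seq_index=img.seq_index,
        block=img.block,
        melanistic_proportion=proportion,
        mean_lum_mel=mean_lum_mel,
        mean_lum_nonmel=mean_lum_nonmel,
        low_contrast=seg.low_contrast,
    )


def summarize_individual(metrics: list[PatternMetrics]) -> IndividualPattern:
    """Mean, sample SD, and log-mean of melanistic proportion over accepted images."""
    if not metrics:
        raise ValueError("no accepted images for this individual")
    ids = {m.individual_id for m in metrics}
    if len(ids) != 1:
        raise ValueError(f"metrics mix individuals: {sorted(ids)}")
    props = np.array([m.melanistic_proportion for m in metrics], dtype=float)
    mean = float(props.mean())
    sd = float(props.std(ddof=1)) if len(props) > 1 else 0.0
    if mean > 0:
        log_mean = math.log(mean)
    else:
        log_mean = None
        logger.warning("individual %s has zero mean proportion; log undefined", ids.pop())
    return IndividualPattern(
        individual_id=metrics[0].individual_id,
        mean_proportion=mean,
        sd_proportion=sd,
        log_mean_proportion=log_mean,
        n_images=len(metrics),
    )


def body_temperature(part_temps: dict[str, float]) -> float:
    """Internal body temperature: mean of both eye readings.

    Falls back to the snout reading (which tracks the eye average closely)
    with a warning if exactly one eye is unusable; raises if neither eyes nor
    snout are available.
    """
    eye_l = part_temps.get("eye_L")
    eye_r = part_temps.get("eye_R")
    eyes = [t for t in (eye_l, eye_r) if t is not None and np.isfinite(t)]
    if len(eyes) == 2:
        return float((eyes[0] + eyes[1]) / 2.0)
    snout = part_temps.get("snout")
    if snout is not None and np.isfinite(snout):
        logger.warning("eye temperature missing; falling back to snout reading")
        return float(snout)
    raise ValueError("cannot derive body temperature: eyes and snout all missing")


def prepare_thermal_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-timepoint thermal table and derive ``body_temp``.

    Expects columns ``individual_id, seq_index, block, eye_L, eye_R`` and
    optionally ``snout``, the datalogger columns and ``atmospheric``.
    Datalogger readings of exactly 0 degC are invalidated (set to NaN) and
    counted in ``df.attrs['n_logger_invalid']``; body temperatures come from
    :func:`body_temperature` row by row (NaN when underivable, counted in
    ``df.attrs['n_ir_missing']``).
    """
    required = {"individual_id", "seq_index", "block"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"thermal table missing columns: {sorted(missing)}")
    out = df.copy()

    n_invalid = 0
    for col in (*LOGGER_COLUMNS, "atmospheric"):
        if col in out.columns:
            zero = out[col] == 0.0
            n_invalid += int(zero.sum())
            out.loc[zero, col] = np.nan
    out.attrs["n_logger_invalid"] = n_invalid
    if n_invalid:
        logger.warning("flagged %d zero datalogger reading(s) as invalid", n_invalid)

    temps = []
    n_missing = 0
    for _, row in out.iterrows():
        parts = {k: row.get(k) for k in ("eye_L", "eye_R", "snout")}
        try:
            temps.append(body_temperature(parts))
        except ValueError:
            temps.append(np.nan)
            n_missing += 1
    out["body_temp"] = temps
    out.attrs["n_ir_missing"] = n_missing

    band_lo, band_hi = TEMP_BAND
    bt = out["body_temp"].dropna()
    if ((bt < band_lo) | (bt > band_hi)).any():
        raise ValueError(f"body temperatures outside plausible band {TEMP_BAND}")
    if not out["block"].isin([1, 2, 3, 4, 5]).all():
        raise ValueError("block labels must be in 1..5")
    return out


def block_summaries(
    thermal: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-individual per-block means of body temperature (and luminances).

    ``thermal`` must have passed :func:`prepare_thermal_table`.  ``metrics``
    is an optional per-image table with columns ``individual_id, block,
    mean_lum_mel, mean_lum_nonmel`` (QC-rejected rows already removed).
    Raises if any (individual, block) cell has no valid body temperature.
    """
    if "body_temp" not in thermal.columns:
        raise ValueError("run prepare_thermal_table first (body_temp missing)")
    valid = thermal.dropna(subset=["body_temp"])
    grp = valid.groupby(["individual_id", "block"], as_index=False).agg(
        mean_body_temp=("body_temp", "mean"),
        n_points=("body_temp", "size"),
    )
    expected = thermal.groupby(["individual_id", "block"]).size().reset_index()
    merged = expected.merge(grp, on=["individual_id", "block"], how="left")
    if merged["mean_body_temp"].isna().any():
        bad = merged[merged["mean_body_temp"].isna()][["individual_id", "block"]]
        raise ValueError(f"blocks with no valid body temperature: {bad.to_dict('records')}")

    if metrics is not None:
        lum = metrics.groupby(["individual_id", "block"], as_index=False).agg(
            mean_lum_mel=("mean_lum_mel", "mean"),
            mean_lum_nonmel=("mean_lum_nonmel", "mean"),
        )
        grp = grp.merge(lum, on=["individual_id", "block"], how="left")
    return grp


def thermal_rates(summaries: pd.DataFrame) -> list[RateRecord]:
    """Heating/cooling rates per individual from block-mean body temperatures.

    cooling = block1 - block3, heating = block5 - block3 (both positive under
    the intended temperature profile); start_end_change = block5 - block1 =
    heating - cooling by construction.  Natural logs are taken only for
    positive rates; non-positive rates get ``None`` with a warning.
    """
    records = []
    for ind, sub in summaries.groupby("individual_id"):
        means = sub.set_index("block")["mean_body_temp"]
        missing = {1, 3, 5} - set(means.index)
        if missing:
            raise ValueError(f"individual {ind} missing block(s) {sorted(missing)}")
        cooling = float(means[1] - means[3])
        heating = float(means[5] - means[3])
        log_c = math.log(cooling) if cooling > 0 else None
        log_h = math.log(heating) if heating > 0 else None
        if log_c is None or log_h is None:
            logger.warning("individual %s has a non-positive rate; log flagged undefined", ind)
        records.append(RateRecord(
            individual_id=str(ind),
            cooling_rate=cooling,
            heating_rate=heating,
            start_end_change=float(means[5] - means[1]),
            log_cooling=log_c,
            log_heating=log_h,
        ))
    return records
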