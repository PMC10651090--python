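"""Synthetic fixtures with known ground truth for every pipeline stage.

Two generators:

* an image generator that renders a spotted, gecko-shaped animal (an ellipse
  chain for head/trunk/tail) on a pale arena background with an in-frame
  grayscale reference patch, dark spots placed to hit a target melanistic
  coverage, on-body shadowing, per-frame illumination drift and pixel noise
  — returning the rendered frame together with the true body and spot masks;

* a thermal-cohort generator that emits per-timepoint body-part temperature
  tables and per-image pattern metrics for a cohort following the
  25 -> 15 -> 25 degC five-block profile, with hooks to inject known effects
  of melanistic proportion on heating rates and on luminance change (so the
  statistics can be validated against a known answer) plus the study-shaped
  blemishes: a couple of unusable IR frames and a dead-logger zero reading.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageRecord

__all__ = [
    "ImageGenParams",
    "ThermalGenParams",
    "SyntheticImage",
    "SyntheticCohort",
    "generate_image",
    "generate_image_series",
    "generate_thermal_cohort",
]

# Canonical body: ellipse chain (cx, cy, semi_x, semi_y) in body coordinates,
# x along the spine (head at +x), origin at the trunk center.
_BODY_ELLIPSES = (
    (70.0, 0.0, 20.0, 15.0),   # head
    (40.0, 0.0, 28.0, 20.0),   # neck/shoulders
    (0.0, 0.0, 55.0, 26.0),    # trunk
    (-60.0, 0.0, 26.0, 13.0),  # tail base
    (-85.0, 0.0, 18.0, 8.0),   # mid tail
    (-102.0, 0.0, 12.0, 4.0),  # tail tip
)


@dataclass(frozen=True)
class ImageGenParams:
    """Parameters of one rendered animal photograph.

    target_proportion is the desired melanistic coverage of the body
    (achieved to within +/-0.01 by adding spots and shrinking the last one);
    illumination_gain multiplies the whole frame, emulating lighting drift.
    """

    width: int = 260
    height: int = 200
    target_proportion: float = 0.2
    spot_radius: tuple[float, float] = (3.0, 9.0)
    base_color: tuple[float, float, float] = (0.80, 0.70, 0.30)
    melanistic_color: tuple[float, float, float] = (0.10, 0.10, 0.08)
    background_level: float = 0.97
    illumination_gain: float = 1.0
    shadow_amplitude: float = 0.05
    noise_sd: float = 0.01
    ref_patch: tuple[int, int, int, int] = (6, 6, 38, 38)
    ref_gray: float = 0.5
    roi_pad: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_proportion <= 0.5:
            raise ValueError("target_proportion must lie in [0, 0.5]")
        for c in (*self.base_color, *self.melanistic_color,
                  self.background_level, self.ref_gray):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colors must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticImage:
    """A rendered frame plus its ground truth."""

    record: ImageRecord
    truth_mask: np.ndarray       # true melanistic (spot) pixels
    true_proportion: float
    true_body_mask: np.ndarray


def _canonical_coords(width: int, height: int, pose: np.ndarray | None):
    """Map pixel centers to body coordinates via the inverse pose (3x3 affine)."""
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    x = cols - width / 2.0
    y = rows - height / 2.0
    if pose is None:
        return x, y
    inv = np.linalg.inv(pose)
    qx = inv[0, 0] * x + inv[0, 1] * y + inv[0, 2]
    qy = inv[1, 0] * x + inv[1, 1] * y + inv[1, 2]
    return qx, qy


def _body_membership(qx: np.ndarray, qy: np.ndarray) -> np.ndarray:
    mask = np.zeros(qx.shape, dtype=bool)
    for cx, cy, ax, ay in _BODY_ELLIPSES:
        mask |= ((qx - cx) / ax) ** 2 + ((qy - cy) / ay) ** 2 <= 1.0
    return mask


def _spot_membership(qx, qy, spots: list[tuple[float, float, float]]) -> np.ndarray:
    mask = np.zeros(qx.shape, dtype=bool)
    for sx, sy, r in spots:
        mask |= (qx - sx) ** 2 + (qy - sy) ** 2 <= r ** 2
    return mask


def _sample_point_in_body(rng: np.random.Generator) -> tuple[float, float]:
    while True:
        x = rng.uniform(-120, 95)
        y = rng.uniform(-30, 30)
        if _body_membership(np.array([[x]]), np.array([[y]]))[0, 0]:
            return x, y


def _plan_spots(params: ImageGenParams, rng: np.random.Generator) -> list:
    """Dart-throw spots (overlap allowed, clipped to the body) until the
    canonical-pose coverage is within +/-0.005 of target, shrinking the last
    spot by bisection on overshoot."""
    if params.target_proportion == 0:
        return []
    qx, qy = _canonical_coords(params.width, params.height, None)
    body = _body_membership(qx, qy)
    n_body = int(body.sum())
    target = params.target_proportion

    # incremental dart throwing: keep the union mask of accepted spots
    spots: list[tuple[float, float, float]] = []
    covered = np.zeros_like(body)
    stalled = 0
    while int(covered.sum()) / n_body < target:
        sx, sy = _sample_point_in_body(rng)
        r = rng.uniform(*params.spot_radius)
        disk = ((qx - sx) ** 2 + (qy - sy) ** 2 <= r ** 2) & body
        gained = int((disk & ~covered).sum())
        if gained == 0:
            stalled += 1
            if stalled > 2000:
                raise ValueError(
                    "target_proportion unattainable with given spot sizes")
            continue
        spots.append((sx, sy, r))
        covered |= disk
        if len(spots) > 3000:
            raise ValueError("target_proportion unattainable with given spot sizes")

    if int(covered.sum()) / n_body > target + 0.005 and spots:
        # shrink the last spot by bisection against the rest of the union
        sx, sy, r = spots[-1]
        rest = np.zeros_like(body)
        for px, py, pr in spots[:-1]:
            rest |= ((qx - px) ** 2 + (qy - py) ** 2 <= pr ** 2) & body

        def cov_with_last(radius: float) -> float:
            disk = ((qx - sx) ** 2 + (qy - sy) ** 2 <= radius ** 2) & body
            return int((rest | disk).sum()) / n_body

        lo, hi = 0.0, r
        for _ in range(25):
            mid = (lo + hi) / 2.0
            if cov_with_last(mid) > target:
                hi = mid
            else:
                lo = mid
        final = hi if cov_with_last(hi) >= target - 0.005 else (lo + hi) / 2.0 + 0.25
        spots[-1] = (sx, sy, final)
    return spots


def _pose_matrix(angle_deg: float, shear: float, tx: float, ty: float) -> np.ndarray:
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    m = rot @ sh
    pose = np.eye(3)
    pose[:2, :2] = m
    pose[:2, 2] = (tx, ty)
    return pose


def _render_frame(
    params: ImageGenParams,
    spots: list,
    pose: np.ndarray | None,
    gain: float,
    rng: np.random.Generator,
    individual_id: str,
    seq_index: int,
    block: int,
) -> SyntheticImage:
    h, w = params.height, params.width
    qx, qy = _canonical_coords(w, h, pose)
    body = _body_membership(qx, qy)
    spot_mask = _spot_membership(qx, qy, spots) & body

    img = np.full((h, w, 3), params.background_level, dtype=float)
    img[body] = params.base_color
    img[spot_mask] = params.melanistic_color

    if params.shadow_amplitude > 0:
        # smooth on-body shading across the animal's width — the classic
        # segmentation failure mode; background stays clean
        grad = np.clip((qy + 30.0) / 60.0, 0.0, 1.0)
        shade = 1.0 - params.shadow_amplitude * grad
        img[body] *= shade[body][:, None]

    r0, c0, r1, c1 = params.ref_patch
    img[r0:r1, c0:c1] = params.ref_gray

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img * gain, 0.0, 1.0)

    roi = ndimage.binary_dilation(body, iterations=params.roi_pad)
    roi[r0:r1, c0:c1] = False  # keep the reference patch out of the ROI

    record = ImageRecord(
        individual_id=individual_id,
        seq_index=seq_index,
        block=block,
        pixels=img,
        ref_region=params.ref_patch,
        roi=roi,
        meta={"illumination_gain": gain},
    )
    true_prop = float(spot_mask.sum()) / float(body.sum())
    return SyntheticImage(record=record, truth_mask=spot_mask,
                          true_proportion=true_prop, true_body_mask=body)


def generate_image(
    params: ImageGenParams,
    *,
    individual_id: str = "synthetic",
    seq_index: int = 1,
    block: int = 1,
) -> SyntheticImage:
    """Render one frame; deterministic for a given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    spots = _plan_spots(params, rng)
    return _render_frame(params, spots, None, params.illumination_gain, rng,
                         individual_id, seq_index, block)


def generate_image_series(
    params: ImageGenParams,
    T: int = 15,
    gains: list[float] | None = None,
    *,
    individual_id: str = "synthetic",
) -> list[SyntheticImage]:
    """Render a T-frame series of the same individual.

    The spot layout is fixed; each frame re-poses the animal by a mild affine
    jitter (rotation, translation, slight shear) and applies a per-frame
    illumination gain.  The first frame is the baseline reference shot and
    carries gain 1.0 unless gains are given explicitly; later frames draw
    gain from U[0.7, 1.3].  Blocks are assigned 3 consecutive frames each.
    """
    if T < 2:
        raise ValueError("series needs at least 2 frames")
    rng = np.random.default_rng(params.seed)
    spots = _plan_spots(params, rng)
    if gains is None:
        gains = [1.0] + list(rng.uniform(0.7, 1.3, size=T - 1))
    if len(gains) != T:
        raise ValueError("need one illumination gain per frame")

    frames = []
    for i in range(T):
        if i == 0:
            pose = None
        else:
            pose = _pose_matrix(
                angle_deg=rng.uniform(-12, 12),
                shear=rng.uniform(-0.08, 0.08),
                tx=rng.uniform(-8, 8),
                ty=rng.uniform(-8, 8),
            )
        block = min(i // max(1, T // 5), 4) + 1
        frames.append(_render_frame(
            params, spots, pose, float(gains[i]), rng,
            individual_id, i + 1, block,
        ))
    return frames


# ---------------------------------------------------------------------------
# Thermal cohort


#: Study-shaped proportions: nine animals spanning 0.01-0.11, plus 0.16,
#: 0.22 and 0.41 (the maxima reported for the cohort this emulates).
_DEFAULT_PROPORTIONS = (
    0.01, 0.02, 0.03, 0.05, 0.06, 0.07, 0.09, 0.10, 0.11, 0.16, 0.22, 0.41,
)


@dataclass(frozen=True)
class ThermalGenParams:
    """Cohort generator settings.

    The block targets trace the 25 -> 15 -> 25 degC profile (start plateau,
    cooling transition, cold plateau, heating transition, end plateau); each
    of the 15 timepoints belongs to one of 5 blocks, 3 per block.  Effect
    hooks inject known dependencies of heating rate and luminance change on
    log melanistic proportion so recovery can be checked against truth.
    """

    block_targets: tuple[float, ...] = (25.0, 20.0, 15.0, 20.0, 25.0)
    n_individuals: int = 12
    timepoints: int = 15
    true_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    body_noise_sd: float = 0.3       # per-timepoint latent body-temp noise, degC
    eye_noise_sd: float = 0.1        # per-eye reading noise, degC
    ind_offset_sd: float = 0.2       # stable per-individual temperature offset
    heating_spread_sd: float = 0.8   # individual variability of heating magnitude
    substrate_offset: float = 0.3    # IR substrate reads slightly warm
    substrate_noise_sd: float = 0.2
    logger_noise_sd: float = 0.2
    humidity_mean: float = 41.0
    humidity_sd: float = 3.0
    prop_noise_sd: float = 0.035     # per-image proportion SD (study condition)
    lum_mel_base: float = 0.22
    lum_nonmel_base: float = 0.62
    lum_change_noise_sd: float = 0.005
    lum_within_block_sd: float = 0.003
    # effect-injection hooks (all zero => null cohort)
    rate_slope: float = 0.0          # d log(heating rate) / d log(proportion)
    lum_prop_slope: float = 0.0      # d lum_change(3->5, nonmel) / d log(prop)
    lum_temp_slope: float = 0.0      # d lum_change / d temp_change
    lum_interaction: float = 0.0     # interaction coefficient
    outlier_individual: str | None = None
    outlier_magnitude: float = 0.0
    n_ir_dropouts: int = 2
    n_logger_zeros: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_targets) != 5:
            raise ValueError("block_targets must cover blocks 1..5")
        if self.timepoints % 5:
            raise ValueError("timepoints must divide evenly into 5 blocks")
        if len(self.true_proportions) != self.n_individuals:
            raise ValueError("need one true proportion per individual")


@dataclass
class SyntheticCohort:
    """Generated study tables plus the injected ground truth."""

    thermal: pd.DataFrame
    metrics: pd.DataFrame
    individuals: pd.DataFrame
    truth: dict = field(default_factory=dict)


_PART_OFFSETS = {
    "head": 0.2, "left_knee": -0.1, "left_foot": -0.3, "dorsum": 0.1,
    "snout": 0.0, "tail": -0.2,
}


def generate_thermal_cohort(params: ThermalGenParams) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a given seed.

    Eye temperatures are the latent body temperature plus independent reading
    noise; substrate and logger channels track the block schedule with their
    own offsets.  Injected effects enter exactly: the heating magnitude of
    individual i is (T5-T3) * exp(rate_slope * log p_i), and the block 3->5
    non-melanistic luminance change is
    b1*log p_i + b2*dT_i + b3*log p_i*dT_i (+ noise), with dT_i computed from
    the same eye readings the analysis will average — so with all noise terms
    at zero an OLS fit recovers the injected coefficients exactly.
    """
    rng = np.random.default_rng(params.seed)
    n, T = params.n_individuals, params.timepoints
    per_block = T // 5
    ids = [f"G{i+1:02d}" for i in range(n)]
    props = np.asarray(params.true_proportions, dtype=float)
    if (props <= 0).any():
        raise ValueError("true proportions must be positive (log is taken downstream)")
    logprop = np.log(props)

    sexes = ["M"] * 7 + ["F"] * 5
    sexes = (sexes * ((n // 12) + 1))[:n]
    individuals = pd.DataFrame({
        "individual_id": ids,
        "sex": sexes,
        "mass_g": np.round(rng.normal(55.0, 8.0, size=n), 2),
        "svl_mm": np.round(rng.normal(120.0, 10.0, size=n), 1),
    })

    ind_offset = rng.normal(0.0, params.ind_offset_sd, size=n)
    heating_jitter = rng.normal(0.0, params.heating_spread_sd, size=n)
    base_heat = params.block_targets[4] - params.block_targets[2]
    heating_target = (base_heat + heating_jitter) * np.exp(params.rate_slope * logprop)

    rows = []
    for i, ind in enumerate(ids):
        targets = list(params.block_targets)
        # block 5 realizes this individual's injected heating magnitude
        targets[4] = targets[2] + heating_target[i]
        targets[3] = (targets[2] + targets[4]) / 2.0
        for t in range(1, T + 1):
            b = (t - 1) // per_block + 1
            latent = targets[b - 1] + ind_offset[i] + rng.normal(0, params.body_noise_sd)
            sched = params.block_targets[b - 1]
            row = {
                "individual_id": ind, "seq_index": t, "block": b,
                "eye_L": latent + rng.normal(0, params.eye_noise_sd),
                "eye_R": latent + rng.normal(0, params.eye_noise_sd),
                "substrate_temp": sched + params.substrate_offset
                + rng.normal(0, params.substrate_noise_sd),
                "logger_cold": sched - 0.5 + rng.normal(0, params.logger_noise_sd),
                "logger_warm": sched + 0.8 + rng.normal(0, params.logger_noise_sd),
                "logger_hide": sched + rng.normal(0, params.logger_noise_sd),
                "atmospheric": sched - 1.2 + rng.normal(0, params.logger_noise_sd),
                "humidity": params.humidity_mean + rng.normal(0, params.humidity_sd),
            }
            for part, off in _PART_OFFSETS.items():
                row[part] = latent + off + rng.normal(0, params.eye_noise_sd)
            rows.append(row)
    thermal = pd.DataFrame(rows)

    # unusable IR frames: all body-part readings lost for a frame
    dropouts = []
    if params.n_ir_dropouts:
        drop_inds = rng.choice(n, size=params.n_ir_dropouts, replace=False)
        for i in drop_inds:
            t = int(rng.integers(1, T + 1))
            dropouts.append((ids[i], t))
            sel = (thermal["individual_id"] == ids[i]) & (thermal["seq_index"] == t)
            for col in ("eye_L", "eye_R", "snout", *(_PART_OFFSETS.keys() - {"snout"})):
                thermal.loc[sel, col] = np.nan

    # dead-battery logger artifact: an exact-zero reading
    zero_rows = []
    if params.n_logger_zeros:
        for _ in range(params.n_logger_zeros):
            ridx = int(rng.integers(len(thermal)))
            thermal.loc[ridx, "logger_hide"] = 0.0
            zero_rows.append(ridx)

    # realized block-mean body temperatures, as the analysis will compute them
    body = (thermal["eye_L"] + thermal["eye_R"]) / 2.0
    bt = thermal.assign(body_temp=body).dropna(subset=["body_temp"])
    block_means = bt.groupby(["individual_id", "block"])["body_temp"].mean().unstack()
    dT_53 = (block_means[5] - block_means[3]).reindex(ids).to_numpy()
    dT_13 = (block_means[3] - block_means[1]).reindex(ids).to_numpy()
    dT_15 = (block_means[5] - block_means[1]).reindex(ids).to_numpy()

    def block_lums(base: float, prop_slope: float, temp_slope: float,
                   interaction: float) -> np.ndarray:
        """Per-individual per-block luminance anchored at block 3."""
        L = np.empty((n, 5))
        base_i = base + rng.normal(0, 0.01, size=n)
        change_13 = rng.normal(0, params.lum_change_noise_sd, size=n)
        change_35 = (
            prop_slope * logprop + temp_slope * dT_53
            + interaction * logprop * dT_53
            + rng.normal(0, params.lum_change_noise_sd, size=n)
        )
        L[:, 2] = base_i
        L[:, 0] = L[:, 2] - change_13
        L[:, 4] = L[:, 2] + change_35
        L[:, 1] = (L[:, 0] + L[:, 2]) / 2.0
        L[:, 3] = (L[:, 2] + L[:, 4]) / 2.0
        return L

    lum_mel = block_lums(params.lum_mel_base, 0.0, 0.0, 0.0)
    lum_nonmel = block_lums(
        params.lum_nonmel_base, params.lum_prop_slope,
        params.lum_temp_slope, params.lum_interaction,
    )
    if params.outlier_individual is not None:
        oi = ids.index(params.outlier_individual)
        lum_nonmel[oi, 4] += params.outlier_magnitude
        lum_nonmel[oi, 3] += params.outlier_magnitude / 2.0

    met_rows = []
    for i, ind in enumerate(ids):
        for t in range(1, T + 1):
            b = (t - 1) // per_block + 1
            prop = float(np.clip(
                props[i] + rng.normal(0, params.prop_noise_sd), 0.0, 1.0))
            met_rows.append({
                "individual_id": ind, "seq_index": t, "block": b,
                "melanistic_proportion": prop,
                "mean_lum_mel": float(np.clip(
                    lum_mel[i, b - 1]
                    + rng.normal(0, params.lum_within_block_sd), 0, 1)),
                "mean_lum_nonmel": float(np.clip(
                    lum_nonmel[i, b - 1]
                    + rng.normal(0, params.lum_within_block_sd), 0, 1)),
            })
    metrics = pd.DataFrame(met_rows)

    truth = {
        "true_proportions": pd.Series(props, index=ids),
        "heating_target": pd.Series(heating_target, index=ids),
        "dT_53": pd.Series(dT_53, index=ids),
        "dT_13": pd.Series(dT_13, index=ids),
        "dT_15": pd.Series(dT_15, index=ids),
        "rate_slope": params.rate_slope,
        "lum_prop_slope": params.lum_prop_slope,
        "lum_temp_slope": params.lum_temp_slope,
        "lum_interaction": params.lum_interaction,
        "outlier_individual": params.outlier_individual,
        "ir_dropouts": dropouts,
        "logger_zero_rows": zero_rows,
    }
    return SyntheticCohort(thermal=thermal, metrics=metrics,
                           individuals=individuals, truth=truth)
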