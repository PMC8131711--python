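"""Synthetic datasets emulating a liminal object-recognition session.

The generator produces, per simulated subject: a randomized trial table
(15 runs x 24 trials: 20 real + 4 scrambled images, exponential-jittered
fixation), behavioral reports calibrated to the observed rates (~50% of real
and ~28% of scrambled images recognized; ~79% correct categorisation when
recognized, ~32% when not), a small ROI atlas on a 3-D grid (activated /
deactivated cortical regions and subcortical regions), and run-wise
condition beta patterns in which

    beta = class amplitude(recognition, image type) + subject offset
           + pattern strength(class, recognition) * category pattern + noise.

Category pattern vectors are unit-norm and ROI-specific; at the defaults the
pattern strength is zero for subcortical ROIs and for unrecognized trials, so
category information is an all-or-none property of recognized trials in
cortex — the statistical structure the downstream decoding and inference
stages are designed to detect.  Optional BOLD time series are generated from
the GLM forward model (TR 2 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CATEGORIES = ("face", "animal", "house", "object")
ROI_CLASSES = ("cortical_activated", "cortical_deactivated", "subcortical")

STIM_DURATION_S = 8 / 120.0  # 8 frames at 120 Hz = 66.7 ms
QUESTION_DURATION_S = 4.0  # two sequential 2-s questions


# --------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class Behavior:
    """Report-generating probabilities (defaults match the observed rates)."""

    p_recognize_real: float = 0.50
    p_recognize_scrambled: float = 0.28
    acc_recognized: float = 0.788
    acc_unrecognized: float = 0.32
    p_no_response: float = 0.0


def _default_amplitudes() -> dict[str, dict[tuple[str, str], float]]:
    # percent-signal-change response per (recognition, image_type);
    # recognition amplifies the magnitude in every class, with deactivated
    # regions responding negatively.
    return {
        "cortical_activated": {
            ("yes", "real"): 0.60,
            ("no", "real"): 0.30,
            ("yes", "scrambled"): 0.45,
            ("no", "scrambled"): 0.25,
        },
        "cortical_deactivated": {
            ("yes", "real"): -0.60,
            ("no", "real"): -0.30,
            ("yes", "scrambled"): -0.45,
            ("no", "scrambled"): -0.25,
        },
        "subcortical": {
            ("yes", "real"): 0.40,
            ("no", "real"): 0.20,
            ("yes", "scrambled"): 0.30,
            ("no", "scrambled"): 0.15,
        },
    }


def _default_pattern_strength() -> dict[tuple[str, str], float]:
    # category information only in cortical ROIs on recognized trials;
    # 2.0 calibrates default cortical decoding into the ~50-60% band at the
    # default 15-run session (voxelwise SNR stays < 0.2)
    return {
        ("cortical_activated", "yes"): 2.0,
        ("cortical_activated", "no"): 0.0,
        ("cortical_deactivated", "yes"): 2.0,
        ("cortical_deactivated", "no"): 0.0,
        ("subcortical", "yes"): 0.0,
        ("subcortical", "no"): 0.0,
    }


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters for one synthetic experiment."""

    amplitudes: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=_default_amplitudes
    )
    pattern_strength: dict[tuple[str, str], float] = field(
        default_factory=_default_pattern_strength
    )
    noise_sd: float = 1.0
    between_subject_sd: float = 0.15
    behavior: Behavior = field(default_factory=Behavior)

    def with_no_signal(self) -> "GroundTruth":
        """Copy with all category pattern strengths set to zero."""
        return replace(self, pattern_strength={k: 0.0 for k in self.pattern_strength})


# --------------------------------------------------------------------------
# trial tables and behavior


def _truncated_exp(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    u_lo = 1.0 - np.exp(-lo / mean)
    u_hi = 1.0 - np.exp(-hi / mean)
    u = rng.uniform(u_lo, u_hi)
    return float(-mean * np.log1p(-u))


def make_session(
    n_runs: int = 15,
    rng: np.random.Generator | None = None,
    *,
    subject: int = 0,
    n_per_category: int = 5,
) -> pd.DataFrame:
    """Trial table for one subject, without behavioral reports.

    Each run presents every stimulus once: ``n_per_category`` real images per
    category (20 at default) plus one scrambled image per category, in random
    order.  Pre-stimulus fixation is exponential (mean 9 s) truncated to
    [6, 20] s; post-stimulus fixation is 4 s or 6 s (2:1).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = rng or np.random.default_rng(0)
    stimuli = [
        (f"{cat}_{i}", cat, "real")
        for cat in CATEGORIES
        for i in range(n_per_category)
    ] + [(f"scr_{cat}", cat, "scrambled") for cat in CATEGORIES]
    rows = []
    for run in range(n_runs):
        order = rng.permutation(len(stimuli))
        t = 0.0
        for idx, j in enumerate(order):
            stim_id, cat, image_type = stimuli[j]
            pre = _truncated_exp(rng, 9.0, 6.0, 20.0)
            onset = t + pre
            post = 4.0 if rng.random() < 2.0 / 3.0 else 6.0
            rows.append(
                (subject, run, idx, onset, stim_id, cat, image_type, "", "", post)
            )
            t = onset + STIM_DURATION_S + post + QUESTION_DURATION_S
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "run",
            "trial_index",
            "onset_s",
            "stimulus_id",
            "category",
            "image_type",
            "recognition",
            "reported_category",
            "post_fixation_s",
        ],
    )


def simulate_behavior(
    table: pd.DataFrame, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill in recognition and category reports.

    Recognition is Bernoulli per image type; the reported category is correct
    with probability ``acc_recognized`` / ``acc_unrecognized`` and otherwise
    uniform over the three remaining categories.  With probability
    ``p_no_response`` the recognition report is missing ("none").
    """
    b = truth.behavior
    for p in (b.p_recognize_real, b.p_recognize_scrambled, b.acc_recognized, b.acc_unrecognized):
        if not 0.0 <= p <= 1.0:
            raise ValueError("behavior probabilities must lie in [0, 1]")
    out = table.copy()
    recognition = []
    reported = []
    for _, row in out.iterrows():
        if rng.random() < b.p_no_response:
            recognition.append("none")
            reported.append(rng.choice(CATEGORIES))
            continue
        p_rec = b.p_recognize_real if row["image_type"] == "real" else b.p_recognize_scrambled
        rec = rng.random() < p_rec
        recognition.append("yes" if rec else "no")
        acc = b.acc_recognized if rec else b.acc_unrecognized
        if rng.random() < acc:
            reported.append(row["category"])
        else:
            others = [c for c in CATEGORIES if c != row["category"]]
            reported.append(others[rng.integers(3)])
    out["recognition"] = recognition
    out["reported_category"] = reported
    return out


# --------------------------------------------------------------------------
# ROI geometry


@dataclass(frozen=True)
class RoiSpec:
    name: str
    roi_class: str
    n_voxels: int
    origin: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.roi_class not in ROI_CLASSES:
            raise ValueError(f"unknown ROI class {self.roi_class!r}")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be positive")


@dataclass
class RoiAtlas:
    grid_dims: tuple[int, int, int]
    masks: dict[str, np.ndarray]  # name -> boolean 3-D mask
    classes: dict[str, str]

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def labels_volume(self) -> np.ndarray:
        """Integer label volume: 0 = background, i+1 = i-th ROI."""
        vol = np.zeros(self.grid_dims, dtype=np.int32)
        for i, m in enumerate(self.masks.values()):
            vol[m] = i + 1
        return vol


def _box_dims(n: int) -> tuple[int, int, int]:
    side = max(1, round(n ** (1 / 3)))
    a = side
    b = max(1, int(np.ceil(np.sqrt(n / a))))
    c = int(np.ceil(n / (a * b)))
    return a, b, c


def make_roi_geometry(
    grid_dims: tuple[int, int, int], roi_specs: list[RoiSpec]
) -> RoiAtlas:
    """Place disjoint connected box-shaped ROIs of exact voxel counts.

    ROIs with an explicit ``origin`` are placed there; the rest are packed
    greedily with a one-voxel margin.  Overlap or insufficient capacity raises
    a configuration error.
    """
    occupied = np.zeros(grid_dims, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    for spec in roi_specs:
        if spec.name in masks:
            raise ValueError(f"duplicate ROI name {spec.name!r}")
        a, b, c = _box_dims(spec.n_voxels)
        if any(d > g for d, g in zip((a, b, c), grid_dims)):
            raise ValueError(f"ROI {spec.name!r} does not fit in grid {grid_dims}")
        placed = False
        if spec.origin is not None:
            candidates: list[tuple[int, int, int]] = [spec.origin]
        else:
            candidates = [
                (x, y, z)
                for x in range(0, grid_dims[0] - a + 1, 1)
                for y in range(0, grid_dims[1] - b + 1, 1)
                for z in range(0, grid_dims[2] - c + 1, 1)
            ]
        for (x, y, z) in candidates:
            if x + a > grid_dims[0] or y + b > grid_dims[1] or z + c > grid_dims[2]:
                raise ValueError(f"ROI {spec.name!r} exceeds grid bounds at {spec.origin}")
            # one-voxel margin around the box
            xs = slice(max(0, x - 1), min(grid_dims[0], x + a + 1))
            ys = slice(max(0, y - 1), min(grid_dims[1], y + b + 1))
            zs = slice(max(0, z - 1), min(grid_dims[2], z + c + 1))
            if spec.origin is None and occupied[xs, ys, zs].any():
                continue
            mask = np.zeros(grid_dims, dtype=bool)
            box = np.zeros((a, b, c), dtype=bool)
            box.reshape(-1)[: spec.n_voxels] = True  # truncated box stays connected
            mask[x : x + a, y : y + b, z : z + c] = box
            if (mask & occupied).any():
                raise ValueError(f"ROI {spec.name!r} overlaps an existing ROI")
            occupied |= mask
            masks[spec.name] = mask
            classes[spec.name] = spec.roi_class
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place ROI {spec.name!r} ({spec.n_voxels} voxels) in grid {grid_dims}"
            )
    return RoiAtlas(tuple(grid_dims), masks, classes)


def default_roi_specs() -> list[RoiSpec]:
    """Desk-scale atlas: 10 activated + 6 deactivated cortical, 4 subcortical."""
    activated = [
        ("visual", 150), ("ips_l", 120), ("ips_r", 110), ("acc", 100),
        ("ains_l", 95), ("ains_r", 90), ("ifj_l", 85), ("ifj_r", 80),
        ("mfg", 75), ("ofc", 70),
    ]
    deactivated = [
        ("mpfc", 130), ("pcc", 110), ("ag_l", 95), ("ag_r", 85),
        ("hc_l", 80), ("hc_r", 70),
    ]
    subcortical = [
        ("thalamus", 120), ("basal_ganglia", 90), ("brainstem", 70), ("vta", 50),
    ]
    return (
        [RoiSpec(n, "cortical_activated", v) for n, v in activated]
        + [RoiSpec(n, "cortical_deactivated", v) for n, v in deactivated]
        + [RoiSpec(n, "subcortical", v) for n, v in subcortical]
    )


def default_atlas(grid_dims: tuple[int, int, int] = (30, 30, 30)) -> RoiAtlas:
    return make_roi_geometry(grid_dims, default_roi_specs())


# --------------------------------------------------------------------------
# beta patterns


@dataclass
class SyntheticDataset:
    """Run-wise condition betas for one subject, with ROI bookkeeping.

    ``X`` has one row per (run, category, recognition, image_type) condition
    observed in the trial table and one column per voxel (ROIs concatenated
    in atlas order); betas are in percent-signal-change units.
    """

    X: np.ndarray
    samples: pd.DataFrame  # columns: run, category, recognition, image_type
    voxel_roi: np.ndarray  # ROI name per column
    atlas: RoiAtlas
    truth: GroundTruth
    subject: int = 0

    def roi_columns(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.voxel_roi == roi)

    def select(
        self, recognition: str | None = None, image_type: str | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (X, category labels, runs) for a condition subset."""
        m = np.ones(len(self.samples), dtype=bool)
        if recognition is not None:
            m &= (self.samples["recognition"] == recognition).to_numpy()
        if image_type is not None:
            m &= (self.samples["image_type"] == image_type).to_numpy()
        return (
            self.X[m],
            self.samples.loc[m, "category"].to_numpy(),
            self.samples.loc[m, "run"].to_numpy(),
        )


def make_beta_dataset(
    table: pd.DataFrame,
    atlas: RoiAtlas,
    truth: GroundTruth,
    rng: np.random.Generator,
    *,
    subject: int | None = None,
) -> SyntheticDataset:
    """Generate one beta pattern per (run, condition) present in ``table``.

    No-response trials ("none") carry no condition beta.  Subject-level
    amplitude offsets are drawn once per ROI; category pattern vectors are
    unit-norm over each ROI's voxels and specific to this dataset.
    """
    if subject is None:
        subject = int(table["subject"].iloc[0])
    conds = (
        table[table["recognition"].isin(["yes", "no"])]
        .groupby(["run", "category", "recognition", "image_type"], sort=True)
        .size()
        .reset_index()[["run", "category", "recognition", "image_type"]]
    )
    n_vox = sum(int(m.sum()) for m in atlas.masks.values())
    voxel_roi = np.concatenate(
        [np.full(int(m.sum()), name) for name, m in atlas.masks.items()]
    )
    roi_cols = {name: np.flatnonzero(voxel_roi == name) for name in atlas.names}
    offsets = {
        name: rng.normal(0.0, truth.between_subject_sd) for name in atlas.names
    }
    patterns = {
        (name, cat): _unit_vector(rng, len(roi_cols[name]))
        for name in atlas.names
        for cat in CATEGORIES
    }
    X = rng.normal(0.0, truth.noise_sd, size=(len(conds), n_vox))
    for i, row in conds.iterrows():
        key = (row["recognition"], row["image_type"])
        for name in atlas.names:
            cls = atlas.classes[name]
            amp = truth.amplitudes[cls][key] + offsets[name]
            strength = truth.pattern_strength[(cls, row["recognition"])]
            cols = roi_cols[name]
            X[i, cols] += amp
            if strength != 0.0:
                X[i, cols] += strength * patterns[(name, row["category"])]
    return SyntheticDataset(X, conds, voxel_roi, atlas, truth, subject)


def _unit_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def make_group_datasets(
    n_subjects: int,
    truth: GroundTruth,
    atlas: RoiAtlas,
    rng: np.random.Generator,
    *,
    n_runs: int = 15,
) -> list[SyntheticDataset]:
    """Independent subjects: session + behavior + betas each."""
    out = []
    for s in range(n_subjects):
        table = make_session(n_runs, rng, subject=s)
        table = simulate_behavior(table, truth, rng)
        out.append(make_beta_dataset(table, atlas, truth, rng, subject=s))
    return out


# --------------------------------------------------------------------------
# quick null-data helpers for calibration studies


def make_null_roi_data(
    n_voxels: int,
    n_runs: int,
    trials_per_category: int,
    rng: np.random.Generator,
    *,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pure-noise (X, labels, runs) with balanced categories per run."""
    labels = np.tile(np.repeat(CATEGORIES, trials_per_category), n_runs)
    runs = np.repeat(np.arange(n_runs), len(CATEGORIES) * trials_per_category)
    X = rng.normal(0.0, noise_sd, size=(len(labels), n_voxels))
    return X, labels, runs


def make_null_volume_data(
    grid_dims: tuple[int, int, int],
    n_runs: int,
    trials_per_category: int,
    rng: np.random.Generator,
    *,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pure-noise 4-D data (samples x grid) with balanced labels per run."""
    labels = np.tile(np.repeat(CATEGORIES, trials_per_category), n_runs)
    runs = np.repeat(np.arange(n_runs), len(CATEGORIES) * trials_per_category)
    X = rng.normal(0.0, noise_sd, size=(len(labels), *grid_dims))
    return X, labels, runs


# --------------------------------------------------------------------------
# BOLD forward model


@dataclass
class BoldRun:
    """Forward-modelled run: data = design @ betas + noise."""

    data: np.ndarray  # n_vols x n_voxels
    design: "object"  # glm.DesignMatrix
    true_betas: np.ndarray  # n_regressors x n_voxels
    tr: float


def make_bold_run(
    run_table: pd.DataFrame,
    true_betas: np.ndarray,
    rng: np.random.Generator,
    *,
    tr: float = 2.0,
    noise_sd: float = 0.0,
    ar_coef: float = 0.0,
    baseline: float = 100.0,
) -> BoldRun:
    """Generate a BOLD run from the GLM forward model.

    ``true_betas`` has one row per design regressor (stimulus conditions,
    control regressors, drift, intercept — in design order); the intercept
    row is overwritten with ``baseline``.  Noise is white Gaussian, or AR(1)
    when ``ar_coef`` is nonzero.
    """
    from . import glm

    last = run_table["onset_s"].max()
    n_vols = int(np.ceil((last + 20.0) / tr))
    design = glm.build_design(run_table, tr=tr, n_vols=n_vols)
    betas = np.array(true_betas, dtype=float)
    if betas.shape[0] != design.matrix.shape[1]:
        raise ValueError(
            f"true_betas rows ({betas.shape[0]}) must match design regressors "
            f"({design.matrix.shape[1]})"
        )
    betas[design.names.index("intercept")] = baseline
    signal = design.matrix @ betas
    noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
    if ar_coef != 0.0 and noise_sd > 0:
        for t in range(1, signal.shape[0]):
            noise[t] += ar_coef * noise[t - 1]
    return BoldRun(signal + noise, design, betas, tr)
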