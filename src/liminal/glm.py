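"""Voxelwise GLM: gamma HRF, stimulus design matrices, OLS fits, contrasts.

The hemodynamic response is a gamma density with mean (lag) 6 s and standard
deviation (half-width) 3 s — shape (lag/width)^2 = 4, scale width^2/lag =
1.5 s — peak-normalized to 1 so that fitted betas read as response
amplitudes.  Stimulus events (66.7 ms, far below the 2-s TR) are modelled as
impulses at onset, convolved at 16x oversampling and downsampled to the TR
grid.  Each run contributes up to 16 stimulus regressors (4 categories x
2 recognition reports x 2 image types; absent conditions are omitted), a
no-response regressor, a question-period regressor, discrete-cosine drift
columns implementing a 150-s high-pass, and an intercept.

Group inference on per-subject contrast effects uses a sign-flip permutation
test rather than a parametric mixed-effects model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_TR = 2.0
HIGHPASS_CUTOFF_S = 150.0
OVERSAMPLE = 16
HRF_SUPPORT_S = 32.0


@dataclass(frozen=True)
class HrfKernel:
    values: np.ndarray  # sampled at dt = tr / oversample
    dt: float
    lag: float
    width: float

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.values) * self.dt)


def gamma_hrf(
    tr: float = DEFAULT_TR,
    lag: float = 6.0,
    width: float = 3.0,
    oversample: int = OVERSAMPLE,
) -> HrfKernel:
    """Gamma-shaped HRF with mean ``lag`` and sd ``width``, peak = 1."""
    if lag <= 0 or width <= 0:
        raise ValueError("lag and width must be positive")
    shape = (lag / width) ** 2
    scale = width**2 / lag
    dt = tr / oversample
    t = np.arange(0.0, HRF_SUPPORT_S, dt)
    v = sps.gamma.pdf(t, a=shape, scale=scale)
    return HrfKernel(v / v.max(), dt, lag, width)


def run_table_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Convert a BIDS-style events table to the run-table layout.

    ``events`` needs columns onset, duration, trial_type, with trial_type
    encoded as "<category>_<recognition>_<imagetype>" (e.g.
    "face_yes_real") or "<category>_none_<imagetype>" for no-response
    trials.  The question period is assumed to start 4 s after stimulus
    offset unless a post_fixation_s column is present.
    """
    required = {"onset", "duration", "trial_type"}
    if not required <= set(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    parts = events["trial_type"].str.split("_", expand=True)
    if parts.shape[1] != 3:
        raise ValueError(
            "trial_type must be '<category>_<recognition>_<imagetype>'"
        )
    table = pd.DataFrame(
        {
            "onset_s": events["onset"].astype(float),
            "category": parts[0],
            "recognition": parts[1],
            "image_type": parts[2],
            "post_fixation_s": events.get(
                "post_fixation_s", pd.Series(4.0, index=events.index)
            ),
        }
    )
    return table.sort_values("onset_s").reset_index(drop=True)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # n_vols x n_regressors
    names: list[str]
    tr: float
    stimulus_names: list[str]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _dct_drift(n_vols: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass basis (periods longer than ``cutoff``)."""
    duration = n_vols * tr
    order = int(np.floor(2.0 * duration / cutoff))
    t = np.arange(n_vols)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_vols)) for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


def _convolve_events(
    onsets: np.ndarray, n_vols: int, tr: float, hrf: HrfKernel
) -> np.ndarray:
    """Impulse regressor: delta at each onset, HRF-convolved, on the TR grid."""
    n_fine = n_vols * OVERSAMPLE
    fine = np.zeros(n_fine)
    idx = np.round(onsets / hrf.dt).astype(int)
    for i in idx:
        fine[i] += 1.0
    conv = np.convolve(fine, hrf.values)[:n_fine]
    return conv[::OVERSAMPLE]


def build_design(
    run_table: pd.DataFrame,
    *,
    tr: float = DEFAULT_TR,
    n_vols: int | None = None,
    hrf: HrfKernel | None = None,
    highpass: float = HIGHPASS_CUTOFF_S,
) -> DesignMatrix:
    """Design matrix for one run of the recognition task.

    ``run_table`` needs columns onset_s, category, recognition, image_type,
    and post_fixation_s (for question-period timing).  One regressor is built
    per (category, recognition in {yes, no}, image_type) combination present;
    no-response trials share a single regressor; question periods (4 s,
    starting after the post-stimulus fixation) share another.
    """
    if hrf is None:
        hrf = gamma_hrf(tr)
    last = float(run_table["onset_s"].max())
    if n_vols is None:
        n_vols = int(np.ceil((last + 20.0) / tr))
    duration = n_vols * tr
    if (run_table["onset_s"] >= duration).any():
        raise ValueError("event onset beyond run end")

    cols: list[np.ndarray] = []
    names: list[str] = []
    responded = run_table[run_table["recognition"].isin(["yes", "no"])]
    for (cat, rec, itype), grp in responded.groupby(
        ["category", "recognition", "image_type"], sort=True
    ):
        cols.append(_convolve_events(grp["onset_s"].to_numpy(), n_vols, tr, hrf))
        names.append(f"{cat}_{rec}_{itype}")
    stimulus_names = list(names)

    no_resp = run_table[run_table["recognition"] == "none"]
    if len(no_resp):
        cols.append(_convolve_events(no_resp["onset_s"].to_numpy(), n_vols, tr, hrf))
        names.append("no_response")

    # question period: boxcar of 4 s beginning after the post-stimulus fixation
    q_on = (
        run_table["onset_s"].to_numpy()
        + 8 / 120.0
        + run_table.get("post_fixation_s", pd.Series(4.0, index=run_table.index)).to_numpy()
    )
    n_fine = n_vols * OVERSAMPLE
    fine = np.zeros(n_fine)
    for on in q_on:
        i0 = int(round(on / hrf.dt))
        i1 = min(n_fine, int(round((on + 4.0) / hrf.dt)))
        fine[i0:i1] += 1.0
    q_conv = np.convolve(fine, hrf.values)[:n_fine][::OVERSAMPLE]
    cols.append(q_conv)
    names.append("questions")

    drift = _dct_drift(n_vols, tr, highpass)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_vols))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, tr, stimulus_names)


@dataclass
class GlmFit:
    betas: np.ndarray  # n_regressors x n_voxels
    residual_var: np.ndarray  # per voxel
    design: DesignMatrix

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.design.names.index(name)]


def fit_glm(ts: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares, voxelwise.

    Raises on rank deficiency, naming the collinear columns.
    """
    Y = np.asarray(ts, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("time series rows must match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True)
        bad = sorted(design.names[j] for j in piv[rank:])
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")
    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = max(X.shape[0] - X.shape[1], 1)
    return GlmFit(betas, (resid**2).sum(axis=0) / dof, design)


def regressor_peak_height(tr: float = DEFAULT_TR, hrf: HrfKernel | None = None) -> float:
    """Peak of an isolated unit-event regressor on the TR grid.

    Used to convert betas to percent signal change; slightly below the HRF
    peak of 1 because the TR grid need not sample the exact mode.
    """
    if hrf is None:
        hrf = gamma_hrf(tr)
    return float(hrf.values[:: int(round(tr / hrf.dt))].max())


def percent_signal_change(
    fit: GlmFit, ts_mean: np.ndarray, conditions: list[str] | None = None
) -> pd.DataFrame:
    """PSC = 100 * beta * (unit-event regressor height) / voxel mean."""
    ts_mean = np.asarray(ts_mean, dtype=float)
    if np.any(ts_mean <= 0):
        raise ValueError("ts_mean must be strictly positive for PSC")
    if conditions is None:
        conditions = fit.design.stimulus_names
    height = regressor_peak_height(fit.design.tr)
    rows = {c: 100.0 * fit.beta(c) * height / ts_mean for c in conditions}
    return pd.DataFrame(rows).T


@dataclass
class ContrastResult:
    effect: np.ndarray  # group-mean effect per voxel
    p: np.ndarray  # sign-flip permutation p per voxel (one-sided)
    subject_effects: np.ndarray
    n_flips: int


def group_contrast(
    subject_effects: np.ndarray,
    *,
    n_flips: int = 1000,
    rng: np.random.Generator | None = None,
) -> ContrastResult:
    """Sign-flip permutation test of the group-mean effect against zero.

    ``subject_effects`` is (n_subjects, n_voxels) or (n_subjects,).  One-sided
    p with the +1-corrected count convention: a positive effect identical in
    every subject reaches p = 1/(n_flips + 1).
    """
    E = np.atleast_2d(np.asarray(subject_effects, dtype=float))
    if E.shape[0] < 2:
        raise ValueError("group inference needs at least 2 subjects")
    rng = rng or np.random.default_rng(0)
    obs = E.mean(axis=0)
    n_sub = E.shape[0]
    count = np.zeros_like(obs)
    for _ in range(n_flips):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        count += (signs @ E) / n_sub >= obs
    p = (1.0 + count) / (1.0 + n_flips)
    return ContrastResult(obs, p, E, n_flips)
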