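"""Region-level accuracy summaries and the accuracy ~ region mixed model.

Decoding accuracies are variance-stabilized with the angular transform
arcsin(sqrt(p)), ROI voxel counts are scaled by 1/1000 and mean-centered,
and a linear mixed model

    arcsin(sqrt(accuracy)) ~ location * scaled_count,  random by subject

is fit by REML.  Location is treatment-coded with cortical as the reference
level, so a negative location coefficient means weaker decoding in
subcortical regions.  The maximal random-effects structure (correlated
random intercept and slopes for all fixed effects) is attempted first and
pruned to random intercepts only when the fit is singular or fails to
converge; the fallback is recorded on the returned fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LOCATIONS = ("cortical", "subcortical")


def angular_transform(p):
    """arcsin(sqrt(p)) for proportions in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def prepare_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Model frame: transformed accuracy, scaled/centered counts, location factor.

    ``table`` needs columns subject, roi, location, voxel_count,
    balanced_accuracy.  Voxel counts are divided by 1000 then centered to
    zero mean; location becomes a two-level categorical with "cortical" as
    the reference.
    """
    if len(table) == 0:
        raise ValueError("empty ROI accuracy table")
    bad = set(table["location"]) - set(LOCATIONS)
    if bad:
        raise ValueError(f"unknown locations: {sorted(bad)}")
    frame = table.copy()
    scaled = frame["voxel_count"].astype(float) / 1000.0
    frame["scaled_count"] = scaled - scaled.mean()
    frame["acc_t"] = angular_transform(frame["balanced_accuracy"].to_numpy())
    frame["location"] = pd.Categorical(frame["location"], categories=LOCATIONS)
    frame["is_subcortical"] = (frame["location"] == "subcortical").astype(float)
    return frame


@dataclass
class LmmFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_re: pd.DataFrame
    converged: bool
    fallback: bool  # True when pruned to random intercepts only
    result: object  # statsmodels MixedLMResults

    def summary_text(self) -> str:
        lines = ["linear mixed model (REML)"]
        if self.fallback:
            lines.append("random effects pruned to intercept-only (singular full fit)")
        lines.append(f"{'term':<28}{'estimate':>12}{'SE':>12}{'p':>12}")
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{self.pvalues[name]:>12.4g}"
            )
        lines.append("random-effect covariance:")
        lines.append(self.cov_re.round(5).to_string())
        return "\n".join(lines)


_FORMULA = "acc_t ~ is_subcortical * scaled_count"
_RE_FULL = "~ is_subcortical * scaled_count"


def fit_lmm(frame: pd.DataFrame, *, allow_fallback: bool = True) -> LmmFit:
    """REML fit of the accuracy ~ location x voxel-count mixed model.

    Attempts the maximal per-subject random-effects structure (intercept,
    location, scaled count, interaction; correlated), falling back to random
    intercepts if that fit is singular or does not converge.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if frame["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    if frame["location"].nunique() < 2:
        raise ValueError("both locations must be represented")

    def _try(re_formula: str):
        # lbfgs first; derivative-free routines as robust backups for
        # boundary fits where the score blows up
        for method in ("lbfgs", "powell", "bfgs", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    model = smf.mixedlm(
                        _FORMULA, frame, groups=frame["subject"], re_formula=re_formula
                    )
                    res = model.fit(reml=True, method=method, maxiter=300)
                    ok = (
                        res.converged
                        and np.all(np.isfinite(res.fe_params))
                        and np.all(np.isfinite(res.bse_fe))
                    )
                if ok:
                    return res
            except (np.linalg.LinAlgError, ValueError):
                continue
        return None

    fallback = False
    res = _try(_RE_FULL)
    if res is not None:
        cov = np.asarray(res.cov_re)
        eigvals = np.linalg.eigvalsh(cov)
        singular = eigvals.min() < 1e-8 * max(eigvals.max(), 1e-12)
        if not res.converged or singular:
            res = None
    if res is None:
        if not allow_fallback:
            raise RuntimeError("maximal random-effects fit failed and fallback disabled")
        fallback = True
        res = _try("~ 1")
        if res is None or not res.converged:
            raise RuntimeError("mixed model failed to converge even with random intercepts")

    fe = res.fe_params.index
    return LmmFit(
        res.fe_params,
        res.bse_fe.loc[fe] if hasattr(res.bse_fe, "loc") else pd.Series(res.bse_fe, index=fe),
        res.pvalues.loc[fe],
        pd.DataFrame(res.cov_re),
        bool(res.converged),
        fallback,
        res,
    )


def simulate_roi_table(
    *,
    n_subjects: int,
    rois: list[tuple[str, str, int]],
    intercept: float = 0.6,
    location_effect: float = -0.1,
    count_effect: float = 0.0,
    interaction: float = 0.0,
    subject_sd: float = 0.05,
    residual_sd: float = 0.05,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthetic RoiAccuracyTable with known fixed effects (on the transformed
    scale) and per-subject random intercepts, for parameter-recovery studies.

    ``rois`` holds (name, location, voxel_count) triples.  Accuracies are
    generated on the angular scale and mapped back through sin^2, clipped to
    the transform's domain.
    """
    counts = np.array([v for _, _, v in rois], dtype=float) / 1000.0
    centered = counts - counts.mean()
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0.0, subject_sd)
        for (name, loc, v), x in zip(rois, centered):
            is_sub = 1.0 if loc == "subcortical" else 0.0
            eta = (
                intercept
                + location_effect * is_sub
                + count_effect * x
                + interaction * is_sub * x
                + u
                + rng.normal(0.0, residual_sd)
            )
            eta = float(np.clip(eta, 0.0, np.pi / 2))
            rows.append((s, name, loc, v, float(np.sin(eta) ** 2)))
    return pd.DataFrame(
        rows, columns=["subject", "roi", "location", "voxel_count", "balanced_accuracy"]
    )
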