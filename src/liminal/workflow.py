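"""End-to-end driver: generation -> decoding -> inference -> mixed model.

``run_full_analysis`` simulates a group of subjects, decodes stimulus
category per ROI separately for recognized, unrecognized and scrambled
trials, attaches label-permutation p-values with FDR correction, tests the
recognized-minus-unrecognized accuracy difference, runs a group searchlight
with TFCE/max-statistic correction over the ROI union mask, summarizes
percent-signal-change amplitudes per ROI, and fits the region-level mixed
model.  One master seed deterministically spawns per-stage generators, so
identical configurations produce byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import inference, io, roi_stats, synth

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis", "read_write_roundtrip"]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 6
    n_runs: int = 6
    grid_dims: tuple[int, int, int] = (30, 30, 30)
    n_subject_perms: int = 12
    n_group: int = 1000
    alpha: float = 0.05
    q_fdr: float = 0.05
    searchlight: bool = True
    searchlight_radius: int = 3
    searchlight_decoder: str = "nearest_centroid"
    n_searchlight_perms: int = 10  # per subject
    n_group_perms: int = 50
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_steps: int = 50
    truth: synth.GroundTruth = field(default_factory=synth.GroundTruth)

    def digest(self) -> str:
        def canonical(o: Any):
            if isinstance(o, dict):
                return {str(k): canonical(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [canonical(v) for v in o]
            return o

        payload = json.dumps(canonical(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        truth_kwargs = raw.pop("truth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "truth"})
        if truth_kwargs:
            behavior = truth_kwargs.pop("behavior", None)
            truth = synth.GroundTruth(**truth_kwargs)
            if behavior:
                truth = replace(truth, behavior=synth.Behavior(**behavior))
            cfg.truth = truth
        if "grid_dims" in raw:
            cfg.grid_dims = tuple(raw["grid_dims"])
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed (config digest {digest}): {cause}")
        self.stage = stage
        self.digest = digest


def _roi_condition_analysis(datasets, atlas, cfg, rng):
    """Per-ROI decoding + permutation nulls for the three condition subsets."""
    selectors = {
        "recognized": dict(recognition="yes", image_type="real"),
        "unrecognized": dict(recognition="no", image_type="real"),
        "scrambled": dict(image_type="scrambled"),  # recognition ignored
    }
    nulls: dict[tuple[str, str], inference.PermutationNull] = {}
    rows = []
    for roi in atlas.names:
        cols = datasets[0].roi_columns(roi)
        for cond, sel in selectors.items():
            subject_data = []
            for ds in datasets:
                X, y, runs = ds.select(**sel)
                subject_data.append((X[:, cols], y, runs))
            null = inference.build_group_null(
                subject_data,
                n_subject_perms=cfg.n_subject_perms,
                n_group=cfg.n_group,
                rng=rng,
            )
            nulls[(roi, cond)] = null
            p = inference.permutation_pvalue(null.group_observed, null.group_null)
            rows.append(
                {
                    "roi": roi,
                    "roi_class": atlas.classes[roi],
                    "condition": cond,
                    "balanced_accuracy": null.group_observed,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    table["q_significant"] = False
    for cond in selectors:
        m = table["condition"] == cond
        table.loc[m, "q_significant"] = inference.fdr_bh(
            table.loc[m, "p"].to_numpy(), cfg.q_fdr
        )
    return table, nulls


def _difference_tests(atlas, nulls, cfg, rng):
    rows = []
    for roi in atlas.names:
        diff, p = inference.accuracy_difference_test(
            nulls[(roi, "recognized")],
            nulls[(roi, "unrecognized")],
            n_group=cfg.n_group,
            rng=rng,
        )
        rows.append(
            {
                "roi": roi,
                "roi_class": atlas.classes[roi],
                "accuracy_difference": diff,
                "p": p,
                "significant": p < cfg.alpha,
            }
        )
    return pd.DataFrame(rows)


def _psc_table(datasets, atlas):
    """Mean response amplitude (PSC units) per ROI x recognition x image type."""
    rows = []
    for roi in atlas.names:
        cols = datasets[0].roi_columns(roi)
        for rec in ("yes", "no"):
            for itype in ("real", "scrambled"):
                means = []
                for ds in datasets:
                    X, _, _ = ds.select(recognition=rec, image_type=itype)
                    if len(X):
                        means.append(float(X[:, cols].mean()))
                rows.append(
                    {
                        "roi": roi,
                        "roi_class": atlas.classes[roi],
                        "recognition": rec,
                        "image_type": itype,
                        "mean_psc": float(np.mean(means)),
                        "sem_psc": float(np.std(means, ddof=1) / np.sqrt(len(means)))
                        if len(means) > 1
                        else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _searchlight_stage(datasets, atlas, cfg, rng):
    mask = np.zeros(cfg.grid_dims, dtype=bool)
    for m in atlas.masks.values():
        mask |= m
    coords = np.argwhere(mask)
    true_maps = []
    perm_maps = []
    for ds in datasets:
        X, y, runs = ds.select(recognition="yes", image_type="real")
        vol = np.zeros((len(X), *cfg.grid_dims))
        vol[:, coords[:, 0], coords[:, 1], coords[:, 2]] = X
        label_sets = [y] + [
            inference.permute_labels_within_run(y, runs, rng)
            for _ in range(cfg.n_searchlight_perms)
        ]
        if cfg.searchlight_decoder == "nearest_centroid":
            maps = inference.searchlight_map_batch(
                vol, label_sets, runs, mask, radius=cfg.searchlight_radius
            )
        else:
            maps = np.stack(
                [
                    inference.searchlight_map(
                        vol, ls, runs, mask,
                        radius=cfg.searchlight_radius, decoder=cfg.searchlight_decoder,
                    )
                    for ls in label_sets
                ]
            )
        true_maps.append(maps[0])
        perm_maps.append(maps[1:])
    result = inference.group_searchlight_tfce(
        np.stack(true_maps),
        np.stack(perm_maps),
        mask,
        n_group_perms=cfg.n_group_perms,
        alpha=cfg.alpha,
        rng=rng,
        E=cfg.tfce_E,
        H=cfg.tfce_H,
        n_steps=cfg.tfce_steps,
    )
    return result, mask


def _lmm_stage(per_subject_accuracy, atlas):
    """per_subject_accuracy: {(roi, subject): recognized-trial accuracy}."""
    voxel_counts = {name: int(m.sum()) for name, m in atlas.masks.items()}
    rows = []
    for (roi, subject), acc in per_subject_accuracy.items():
        rows.append(
            {
                "subject": subject,
                "roi": roi,
                "location": "subcortical"
                if atlas.classes[roi] == "subcortical"
                else "cortical",
                "voxel_count": voxel_counts[roi],
                "balanced_accuracy": acc,
            }
        )
    table = pd.DataFrame(rows)
    frame = roi_stats.prepare_covariates(table)
    return roi_stats.fit_lmm(frame), table


def run_full_analysis(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    *,
    atlas: synth.RoiAtlas | None = None,
) -> dict:
    """Run the whole pipeline; optionally write the report bundle to ``out_dir``.

    Returns a dict with the decoding table, difference tests, PSC table,
    searchlight result, mixed-model fit, and the generated datasets.  A
    custom ``atlas`` (matching ``cfg.grid_dims``) replaces the default ROI
    geometry.
    """
    digest = cfg.digest()
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_gen, rng_roi, rng_sl, rng_misc = (np.random.default_rng(s) for s in seeds)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as e:  # surface the failing stage + config identity
            raise PipelineError(name, digest, e) from e

    if atlas is None:
        atlas = stage("roi_geometry", synth.default_atlas, cfg.grid_dims)
    datasets = stage(
        "generate",
        lambda: synth.make_group_datasets(
            cfg.n_subjects, cfg.truth, atlas, rng_gen, n_runs=cfg.n_runs
        ),
    )
    decoding_table, nulls = stage(
        "roi_decoding", _roi_condition_analysis, datasets, atlas, cfg, rng_roi
    )
    diff_table = stage("difference_tests", _difference_tests, atlas, nulls, cfg, rng_roi)
    psc_table = stage("psc", _psc_table, datasets, atlas)

    sl_result = mask = None
    if cfg.searchlight:
        sl_result, mask = stage("searchlight", _searchlight_stage, datasets, atlas, cfg, rng_sl)

    per_subject_rec = {
        (roi, s): float(nulls[(roi, "recognized")].observed[s])
        for roi in atlas.names
        for s in range(cfg.n_subjects)
    }
    lmm_fit, lmm_table = stage("mixed_model", _lmm_stage, per_subject_rec, atlas)

    results = {
        "config": cfg,
        "digest": digest,
        "atlas": atlas,
        "datasets": datasets,
        "decoding": decoding_table,
        "difference": diff_table,
        "psc": psc_table,
        "searchlight": sl_result,
        "searchlight_mask": mask,
        "lmm": lmm_fit,
        "lmm_table": lmm_table,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_tsv(decoding_table, out / "roi_decoding.tsv", seed=cfg.seed, digest=digest)
        io.write_tsv(diff_table, out / "difference_tests.tsv", seed=cfg.seed, digest=digest)
        io.write_tsv(psc_table, out / "psc_by_roi.tsv", seed=cfg.seed, digest=digest)
        io.write_tsv(lmm_table, out / "roi_accuracies.tsv", seed=cfg.seed, digest=digest)
        with open(out / "lmm_summary.txt", "w") as fh:
            fh.write(f"# seed={cfg.seed} digest={digest}\n")
            fh.write(lmm_fit.summary_text() + "\n")
        if sl_result is not None:
            io.save_nifti(sl_result.tfce_map, out / "searchlight_tfce.nii")
            io.save_nifti(sl_result.sig_mask.astype(float), out / "searchlight_sig.nii")
        with open(out / "manifest.json", "w") as fh:
            json.dump({"seed": cfg.seed, "digest": digest}, fh, indent=1)
    return results


def read_write_roundtrip(tmp_dir: str | Path, volume: np.ndarray, table: pd.DataFrame) -> bool:
    """Save/load a volume and a table; return True when both round-trip exactly."""
    tmp_dir = Path(tmp_dir)
    tmp_dir.mkdir(parents=True, exist_ok=True)
    io.save_nifti(volume, tmp_dir / "vol.nii")
    vol2 = io.load_nifti(tmp_dir / "vol.nii")
    io.write_tsv(table, tmp_dir / "table.tsv")
    tab2 = io.read_tsv(tmp_dir / "table.tsv")
    vols_equal = np.array_equal(np.asarray(volume, dtype=np.float64), vol2)
    tables_equal = len(table) == len(tab2) and all(
        np.array_equal(table[c].to_numpy(), tab2[c].to_numpy())
        or np.allclose(
            pd.to_numeric(table[c], errors="coerce"),
            pd.to_numeric(tab2[c], errors="coerce"),
            equal_nan=True,
        )
        for c in table.columns
    )
    return bool(vols_equal and tables_equal)
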