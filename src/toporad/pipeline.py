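"""End-to-end orchestration: simulate -> preprocess -> extract -> augment ->
optimize -> evaluate, as reproducible configured runs.

A run is driven by a plain config dict (YAML on disk).  Feature families:

* ``wf``   — wavelet features of the 3D preprocessed volume;
* ``bf``   — original-polarity Betti-map features of the max-GTV slice;
* ``ibf``  — bf plus inverted-polarity map features;
* ``bwf``/``ibwf`` — concatenation of the (i)bf table at its endpoint-optimal
  (window, kernel, stride) with the wf table at its endpoint-optimal window,
  after which only alpha and the signature are re-optimized.

Every output carries the config hash and seed; two runs with equal configs
are bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantoms
from .betti import BettiMapConfig
from .cohort import stratified_split
from .features import combine_features, extract_bf, extract_ibf, extract_wf
from .evaluate import evaluate_stratification
from .images import ImageVolume, RoiMask
from .preprocess import (
    DEFAULT_ISO_MM,
    LoGConfig,
    RequantizationWindow,
    log_filter,
    requantize,
    resample_isotropic,
    resample_mask_shape_based,
    select_max_gtv_slice,
)
from .signature import optimize_signature

__all__ = ["default_config", "config_hash", "run_pipeline", "report", "preprocess_patient"]

FAMILIES = ("wf", "bf", "ibf", "bwf", "ibwf")
BASE_FAMILIES = ("wf", "bf", "ibf")


def default_config() -> dict:
    """Desk-scale defaults; full-paper scale is reached by setting
    threshold_step to 1 and the full hyperparameter grid."""
    return {
        "seed": 0,
        "out_dir": "toporad_run",
        "endpoints": ["lrr", "dm"],
        "families": list(FAMILIES),
        "cohort": {
            "n_patients": 20,
            "grid_shape": [48, 48, 48],
            "voxel_mm": 0.98,
            "tumor_radius_mm": 12.0,
            "cavity_radius_mm": 2.5,
            "noise_sd_hu": 20.0,
            "max_cavities": 4,
        },
        "split": {"n_train": None},  # None -> ceil(n/2) like the 65/60 split
        "preprocess": {"iso_mm": DEFAULT_ISO_MM, "log_sigma": 1.0, "apply_log": True},
        "windows": [[-1350, 150]],
        "kernels": [9],
        "shifts": [3],
        "threshold_step": 8,
        "texture_levels": 32,
        "augment": {"factor": 4, "k_neighbors": 5},
        "optimize": {"alphas": [0.5], "max_significant": 7, "ri_strategy": "harmonic"},
        "plots": False,
        "save_features": False,
    }


def config_hash(config: dict) -> str:
    text = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def preprocess_patient(
    volume: ImageVolume,
    mask: RoiMask,
    window: RequantizationWindow,
    *,
    iso_mm: float = DEFAULT_ISO_MM,
    log_cfg: LoGConfig = LoGConfig(),
    apply_log: bool = True,
) -> tuple[ImageVolume, RoiMask]:
    """Resample -> requantize -> (optionally) LoG-enhance one patient."""
    if not np.allclose(volume.spacing, iso_mm):
        volume = resample_isotropic(volume, iso_mm)
        mask = resample_mask_shape_based(mask, iso_mm)
        if volume.shape != mask.shape:  # distance-field grids can differ by a voxel
            shape = tuple(min(a, b) for a, b in zip(volume.shape, mask.shape))
            volume = ImageVolume(volume.values[: shape[0], : shape[1], : shape[2]], volume.spacing)
            mask = RoiMask(mask.values[: shape[0], : shape[1], : shape[2]], mask.spacing)
    quant = requantize(volume, window)
    if apply_log:
        quant = log_filter(quant, log_cfg, mask=mask)
    return quant, mask


def _thresholds(step: int) -> tuple[int, ...]:
    return tuple(range(0, 256, step))


class _FeatureCache:
    """Compute each (family, grid point) feature table exactly once."""

    def __init__(self, volumes, masks, ids, config):
        self.volumes = volumes
        self.masks = masks
        self.ids = ids
        self.config = config
        self._pre: dict[tuple, list] = {}
        self._tables: dict[tuple, pd.DataFrame] = {}
        self.extraction_counts: dict[tuple, int] = {}

    def _preprocessed(self, window_key):
        if window_key not in self._pre:
            pp = self.config["preprocess"]
            window = RequantizationWindow(*window_key)
            pairs = [
                preprocess_patient(
                    vol,
                    mask,
                    window,
                    iso_mm=pp["iso_mm"],
                    log_cfg=LoGConfig(pp["log_sigma"]),
                    apply_log=pp["apply_log"],
                )
                for vol, mask in zip(self.volumes, self.masks)
            ]
            self._pre[window_key] = pairs
        return self._pre[window_key]

    def table(self, family: str, grid_point: tuple) -> pd.DataFrame:
        key = (family, grid_point)
        if key in self._tables:
            return self._tables[key]
        self.extraction_counts[key] = self.extraction_counts.get(key, 0) + 1
        levels = self.config["texture_levels"]
        if family == "wf":
            window_key = grid_point[0]
            pairs = self._preprocessed(window_key)
            rows = [extract_wf(v.values, m.values, levels=levels) for v, m in pairs]
        elif family in ("bf", "ibf"):
            window_key, K, S = grid_point
            pairs = self._preprocessed(window_key)
            cfg = BettiMapConfig(K, S, _thresholds(self.config["threshold_step"]))
            extractor = extract_bf if family == "bf" else extract_ibf
            rows = []
            for v, m in pairs:
                sl, msl, _ = select_max_gtv_slice(v, m)
                rows.append(extractor(sl, msl, cfg, levels=levels))
        else:
            raise ValueError(f"unknown base family {family!r}")
        table = pd.DataFrame(rows, index=list(self.ids))
        self._tables[key] = table
        return table


def _grid_points(config: dict, family: str) -> list[tuple]:
    windows = [tuple(w) for w in config["windows"]]
    if family == "wf":
        return [(w,) for w in windows]
    return [(w, int(k), int(s)) for w in windows for k in config["kernels"] for s in config["shifts"]]


def run_pipeline(config: dict) -> dict:
    """Execute the configured run and return the manifest dict.

    The manifest lists every written artifact; re-running with the same
    config reproduces them byte-identically.
    """
    config = copy.deepcopy(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config["seed"])

    # --- simulate ---------------------------------------------------------
    cc = config["cohort"]
    template = phantoms.PhantomSpec(
        grid_shape=tuple(cc["grid_shape"]),
        voxel_mm=cc["voxel_mm"],
        tumor_radius_mm=cc["tumor_radius_mm"],
        cavity_radius_mm=cc["cavity_radius_mm"],
        noise_sd_hu=cc["noise_sd_hu"],
    )
    cohort_spec = phantoms.default_cohort_spec(cc["n_patients"], seed)
    volumes, masks, covariates, records = phantoms.make_synthetic_cohort(
        cohort_spec, phantom_template=template, max_cavities=cc["max_cavities"]
    )

    # --- split ------------------------------------------------------------
    n = len(records)
    n_train = config["split"]["n_train"] or (n + 1) // 2
    train_rec, test_rec, n_draws = stratified_split(records, n_train, n - n_train, seed)
    train_ids, test_ids = list(train_rec.index), list(test_rec.index)

    cache = _FeatureCache(volumes, masks, records.index, config)
    opt_cfg = config["optimize"]
    aug_cfg = config["augment"]
    families = list(config["families"])
    # combined families need their base families optimized first
    needed = list(dict.fromkeys(
        [f for fam in families for f in {"bwf": ["wf", "bf"], "ibwf": ["wf", "ibf"]}.get(fam, [fam])]
        + families
    ))
    order = [f for f in FAMILIES if f in needed]

    results: dict[tuple, dict] = {}
    reports = []
    opt_store: dict[tuple, object] = {}
    for endpoint in config["endpoints"]:
        times = records[f"time_{endpoint}"].to_numpy(float)
        events = records[f"event_{endpoint}"].to_numpy(int)
        t_tr = train_rec[f"time_{endpoint}"].to_numpy(float)
        e_tr = train_rec[f"event_{endpoint}"].to_numpy(int)
        t_te = test_rec[f"time_{endpoint}"].to_numpy(float)
        e_te = test_rec[f"event_{endpoint}"].to_numpy(int)
        for family in order:
            if family in BASE_FAMILIES:
                tables = {
                    gp: cache.table(family, gp).loc[train_ids]
                    for gp in _grid_points(config, family)
                }
                full_tables = {gp: cache.table(family, gp) for gp in _grid_points(config, family)}
            else:
                base = "bf" if family == "bwf" else "ibf"
                base_res = opt_store.get((endpoint, base))
                wf_res = opt_store.get((endpoint, "wf"))
                if base_res is None or wf_res is None:
                    raise RuntimeError(f"{family} requires {base} and wf optimized first")
                gp_base = base_res.best.grid_point
                gp_wf = wf_res.best.grid_point
                combined = combine_features(
                    cache.table(base, gp_base), cache.table("wf", gp_wf)
                )
                gp = (gp_base, gp_wf)
                tables = {gp: combined.loc[train_ids]}
                full_tables = {gp: combined}
            result = optimize_signature(
                tables,
                t_tr,
                e_tr,
                alphas=tuple(opt_cfg["alphas"]),
                factor=aug_cfg["factor"],
                k_neighbors=aug_cfg["k_neighbors"],
                max_significant=opt_cfg["max_significant"],
                ri_strategy=opt_cfg["ri_strategy"],
                seed=seed,
            )
            opt_store[(endpoint, family)] = result
            train_table = tables[result.best.grid_point]
            model = result.build_model(train_table, endpoint)
            test_table = full_tables[result.best.grid_point].loc[test_ids]
            scores_te = model.score(result.normalizer.transform(test_table))
            scores_tr = model.score(result.normalizer.transform(train_table))
            rep_tr = evaluate_stratification(
                scores_tr, t_tr, e_tr, model.training_median_score,
                endpoint=endpoint, dataset="train",
            )
            rep_te = evaluate_stratification(
                scores_te, t_te, e_te, model.training_median_score,
                endpoint=endpoint, dataset="test",
            )
            results[(endpoint, family)] = {
                "model": model.to_dict(),
                "grid_point": repr(result.best.grid_point),
                "alpha": result.best.alpha,
                "ri": result.best.ri,
                "train": asdict(rep_tr),
                "test": asdict(rep_te),
            }
            reports.append({"endpoint": endpoint, "family": family, **asdict(rep_te)})
            # persist per-family artifacts
            fam_dir = out_dir / f"{endpoint}_{family}"
            fam_dir.mkdir(exist_ok=True)
            result.ledger.to_csv(fam_dir / "optimization_ledger.csv", index=False)
            (fam_dir / "signature.json").write_text(
                json.dumps(
                    {
                        "config_hash": chash,
                        "seed": seed,
                        "model": model.to_dict(),
                        "grid_point": repr(result.best.grid_point),
                        "alpha": result.best.alpha,
                        "ri_strategy": opt_cfg["ri_strategy"],
                        "ri": result.best.ri,
                        "skips": len(result.skips),
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            if config.get("save_features"):
                for gp, tab in full_tables.items():
                    tab.to_csv(fam_dir / f"features_{hash(repr(gp)) & 0xFFFFFFFF:x}.csv")

    # --- reporting --------------------------------------------------------
    summary = pd.DataFrame(reports)
    summary_path = out_dir / "evaluation_summary.csv"
    summary.to_csv(summary_path, index=False)
    results_path = out_dir / "results.json"
    results_path.write_text(
        json.dumps(
            {
                "config_hash": chash,
                "seed": seed,
                "n_split_draws": n_draws,
                "train_ids": train_ids,
                "test_ids": test_ids,
                "results": {f"{ep}_{fam}": v for (ep, fam), v in results.items()},
            },
            indent=2,
            sort_keys=True,
        )
    )
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    manifest = {
        "config_hash": chash,
        "seed": seed,
        "config": "config.yaml",
        "summary": summary_path.name,
        "results": results_path.name,
        "clinical_counts": {
            "n": n,
            "n_train": len(train_ids),
            "n_test": len(test_ids),
        },
        "outputs": sorted(str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if config.get("plots"):
        _make_plots(out_dir, records, results, config)
    return manifest


def _make_plots(out_dir: Path, records: pd.DataFrame, results: dict, config: dict) -> None:
    """KM curves per endpoint/family and an nLPC heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    endpoints = config["endpoints"]
    families = [f for f in FAMILIES if any((ep, f) in results for ep in endpoints)]
    mat = np.full((len(endpoints), len(families)), np.nan)
    for i, ep in enumerate(endpoints):
        for j, fam in enumerate(families):
            if (ep, fam) in results:
                mat[i, j] = results[(ep, fam)]["test"]["nlpc"]
    fig, ax = plt.subplots(figsize=(1.2 * len(families) + 2, 2 + len(endpoints)))
    im = ax.imshow(mat, cmap="viridis")
    ax.set_xticks(range(len(families)), [f.upper() for f in families])
    ax.set_yticks(range(len(endpoints)), [e.upper() for e in endpoints])
    for i in range(len(endpoints)):
        for j in range(len(families)):
            if np.isfinite(mat[i, j]):
                ax.text(j, i, f"{mat[i, j]:.3f}", ha="center", va="center", color="w")
    fig.colorbar(im, label="nLPC (test)")
    fig.tight_layout()
    fig.savefig(out_dir / "nlpc_heatmap.png", dpi=120)
    plt.close(fig)


def report(run_dir: str | Path) -> pd.DataFrame:
    """Summarize a completed run: one row per family x endpoint.

    Families requested but absent from the results are marked absent
    rather than raising.
    """
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "run_manifest.json").read_text())
    results = json.loads((run_dir / manifest["results"]).read_text())["results"]
    config = yaml.safe_load((run_dir / manifest["config"]).read_text())
    rows = []
    for ep in config["endpoints"]:
        for fam in config["families"]:
            key = f"{ep}_{fam}"
            if key in results:
                r = results[key]["test"]
                rows.append(
                    {
                        "endpoint": ep,
                        "family": fam,
                        "p_logrank": r["p_logrank"],
                        "c_index": r["c_index"],
                        "nlpc": r["nlpc"],
                        "status": "ok",
                    }
                )
            else:
                rows.append(
                    {
                        "endpoint": ep,
                        "family": fam,
                        "p_logrank": np.nan,
                        "c_index": np.nan,
                        "nlpc": np.nan,
                        "status": "absent",
                    }
                )
    return pd.DataFrame(rows)
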