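"""End-to-end orchestration: simulate -> cluster -> features -> screen ->
train -> ablate -> chem -> report.

A single YAML-able config drives every stage; one global seed fans out to
per-stage seeds through a fixed :class:`numpy.random.SeedSequence`
derivation, so each stage is independently reproducible. All intermediate
artifacts are plain-text CSV; the consolidated report is JSON.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chem import cluster_fingerprints, contingency_table, group_fraction_correct
from .classify import (
    cross_validate,
    cv_predictions,
    evaluate,
    feature_ablation,
    holdout_split,
    learning_curve,
    train_classifier,
)
from .clustering import (
    DOMAIN_FRAMEWORKS,
    SITE_FRAMEWORK,
    binding_site_residues,
    gromos_cluster,
    make_framework,
    pairwise_rmsd_matrix,
    select_panel,
)
from .features import build_feature_matrix, pose_sets_from_frame, read_feature_csv
from .screen import purity_scan
from .synthetic import (
    LibrarySpec,
    LigandLibrary,
    PanelGenSpec,
    default_trajectory_spec,
    generate_docking_panel,
    generate_ligand_library,
    generate_pose_sets,
    generate_trajectory,
    write_truth_sidecar,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "cluster": True,
        "features": True,
        "screen": True,
        "train": True,
        "ablate": True,
        "learncurve": False,  # opt-in: ~10x the cost of the rest combined
        "chem": True,
    },
    "library": {},  # LibrarySpec overrides
    "trajectory": {
        "n_residues": 48,
        "n_basins": 4,
        "n_frames": 240,
        "noise_sd": 0.02,
        "basin_displacement": 0.3,
    },
    "clustering": {
        "cutoff": 0.225,  # nm
        "n_top": 3,
        "n_site": 2,
        "site_dist_cutoff": 1.0,  # nm
        "site_frac": 0.75,
    },
    "docking": {
        "base_score": -6.0,
        "class_shift": 1.0,
        "score_sd": 0.5,
        "pose_jitter_sd": 0.05,
        "n_poses": 10,
    },
    "features": {"impute_policy": "penalty", "rms_mode": "rms", "spread_mode": "to_best"},
    "screen": {"k_min": 2, "k_max": 6, "scale": True, "linkage": "ward"},
    "train": {
        "families": ["LR", "SVM", "RF"],
        "cv_folds": 10,
        "train_frac": 0.7,
        "positive_class": "activator",
    },
    "learncurve": {"n_samples": 100, "family": "SVM"},
    "chem": {"k_min": 2, "k_max": 6},
}

_STAGE_KEYS = {
    "library": 1,
    "trajectory": 2,
    "docking": 3,
    "screen": 4,
    "train": 5,
    "learncurve": 6,
    "chem": 7,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) of the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(base: dict, extra: dict) -> None:
        for key, val in extra.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                _merge(base[key], val)
            else:
                base[key] = val

    if overrides:
        _merge(cfg, overrides)
    return cfg


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def run_pipeline(config: dict | None = None, outdir: str | Path = "allofinger_out") -> dict:
    """Run the enabled stages in order and write artifacts to ``outdir``.

    Stages that are toggled off read their inputs from existing artifacts in
    ``outdir`` (so a single stage can be re-run against cached upstream
    outputs). Returns the consolidated report, also written as report.json.
    """
    cfg = merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    report: dict = {
        "versions": {"allofinger": __version__, "numpy": np.__version__},
        "config": cfg,
        "warnings": [],
    }

    library = None
    panel = None
    pose_table = None
    pose_sets = None
    fm = None

    # ------------------------------------------------------------ simulate
    if stages["simulate"]:
        library = generate_ligand_library(
            LibrarySpec(seed=stage_seed(seed, "library"), **cfg["library"])
        )
        library.write_labels(out / "labels.csv")
        library.write_fingerprints(out / "fingerprints.csv")
        report["library"] = {
            "n_ligands": len(library.labels),
            "class_counts": library.labels["class"].value_counts().to_dict(),
            "n_groups": library.labels["group"].nunique(),
        }
    elif (out / "labels.csv").exists():
        library = LigandLibrary.read(out / "labels.csv", out / "fingerprints.csv")

    # ------------------------------------------------------------- cluster
    if stages["cluster"]:
        tspec = default_trajectory_spec(
            seed=stage_seed(seed, "trajectory"), **cfg["trajectory"]
        )
        traj, basins = generate_trajectory(tspec)
        pd.DataFrame({"frame": np.arange(len(basins)), "basin": basins}).to_csv(
            out / "truth_basins.csv", index=False
        )
        ccfg = cfg["clustering"]
        site_res = binding_site_residues(
            traj, dist_cutoff=ccfg["site_dist_cutoff"], frac=ccfg["site_frac"]
        )
        pd.DataFrame({"resid": site_res}).to_csv(out / "site_residues.csv", index=False)
        domain_results = {}
        for name in DOMAIN_FRAMEWORKS:
            fw = make_framework(name, traj.atom_meta)
            rmsd = pairwise_rmsd_matrix(traj, fw)
            domain_results[name] = gromos_cluster(rmsd, ccfg["cutoff"])
            domain_results[name].to_frame().to_csv(
                out / f"clusters_{name}.csv", index=False
            )
        site_fw = make_framework(SITE_FRAMEWORK, traj.atom_meta, site_residues=site_res)
        site_result = gromos_cluster(
            pairwise_rmsd_matrix(traj, site_fw), ccfg["cutoff"]
        )
        site_result.to_frame().to_csv(out / "clusters_Site.csv", index=False)
        panel = select_panel(
            domain_results, site_result, n_top=ccfg["n_top"], n_site=ccfg["n_site"]
        )
        panel.to_csv(out / "panel.csv")
        report["panel"] = {
            "size": panel.size,
            "n_site_residues": int(len(site_res)),
            "clusters_per_framework": {
                name: int(res.n_clusters) for name, res in domain_results.items()
            }
            | {SITE_FRAMEWORK: int(site_result.n_clusters)},
        }
    elif (out / "panel.csv").exists():
        from .clustering import StructurePanel

        panel = StructurePanel(pd.read_csv(out / "panel.csv"))

    # ------------------------------------------------- simulate docking part
    if stages["simulate"]:
        if library is None:
            raise RuntimeError("docking simulation requires the ligand library")
        sids = tuple(panel.structure_ids) if panel is not None else None
        dspec = PanelGenSpec(
            n_structures=len(sids) if sids else 14,
            structure_id_override=sids,
            seed=stage_seed(seed, "docking"),
            **cfg["docking"],
        )
        pose_table, truth = generate_docking_panel(dspec, library.labels)
        pose_table.to_csv(out / "poses.csv", index=False)
        write_truth_sidecar(truth, out / "truth_preferred.csv")
        pose_sets, _ = generate_pose_sets(dspec, library.labels)
    elif (out / "poses.csv").exists():
        pose_table = pd.read_csv(out / "poses.csv")

    # ------------------------------------------------------------- features
    if stages["features"]:
        if library is None or (pose_sets is None and pose_table is None):
            raise RuntimeError("feature stage requires poses.csv and labels.csv")
        if pose_sets is None:
            pose_sets = pose_sets_from_frame(pose_table)
        sids = (
            panel.structure_ids
            if panel is not None
            else sorted(pose_table["structure_id"].unique())
        )
        fm = build_feature_matrix(
            pose_sets, sids, labels=library.labels, **cfg["features"]
        )
        fm.to_csv(out / "features.csv")
        report["features"] = {
            "shape": list(fm.X.shape),
            "n_imputed": len(fm.imputed),
            "n_excluded": len(fm.excluded),
        }
    elif (out / "features.csv").exists():
        fm = read_feature_csv(out / "features.csv")

    # --------------------------------------------------------------- screen
    if stages["screen"]:
        if fm is None:
            raise RuntimeError("screen stage requires the feature matrix")
        scfg = cfg["screen"]
        scan = purity_scan(
            fm,
            fm.labels,
            k_range=range(scfg["k_min"], scfg["k_max"] + 1),
            seed=stage_seed(seed, "screen"),
            scale=scfg["scale"],
            linkage=scfg["linkage"],
        )
        scan.to_csv(out / "purity.csv", index=False)
        report["screen"] = {
            "purity_k2": {
                row["algorithm"]: round(row["purity"], 4)
                for _, row in scan[scan["k"] == 2].iterrows()
            }
        }

    # ---------------------------------------------------------------- train
    if stages["train"]:
        if fm is None:
            raise RuntimeError("train stage requires the feature matrix")
        tcfg = cfg["train"]
        tseed = stage_seed(seed, "train")
        rows = []
        cv_rows = []
        for family in tcfg["families"]:
            tr, te = holdout_split(fm.labels, train_frac=tcfg["train_frac"], seed=tseed)
            model = train_classifier(
                fm.X.iloc[tr], fm.labels.iloc[tr], family=family, seed=tseed
            )
            rep = evaluate(
                model,
                fm.X.iloc[te],
                fm.labels.iloc[te],
                positive_class=tcfg["positive_class"],
            )
            rows.append(rep.to_dict() | {"family": family})
            cv = cross_validate(
                fm,
                family=family,
                k=tcfg["cv_folds"],
                seed=tseed,
                positive_class=tcfg["positive_class"],
            )
            cv.to_frame().assign(family=family).pipe(cv_rows.append)
        pd.DataFrame(rows).to_csv(out / "metrics_holdout.csv", index=False)
        cv_df = pd.concat(cv_rows, ignore_index=True)
        cv_df.to_csv(out / "metrics_cv.csv", index=False)
        report["train"] = {
            "cv_mean_balanced_accuracy": {
                fam: round(float(g["balanced_accuracy"].mean()), 4)
                for fam, g in cv_df.groupby("family")
            }
        }

    # --------------------------------------------------------------- ablate
    if stages["ablate"]:
        if fm is None:
            raise RuntimeError("ablate stage requires the feature matrix")
        tcfg = cfg["train"]
        results = feature_ablation(
            fm,
            family="SVM",
            k=tcfg["cv_folds"],
            seed=stage_seed(seed, "train"),
            positive_class=tcfg["positive_class"],
        )
        pd.DataFrame(
            [
                {
                    "feature_type": r.feature_type,
                    "mean_full": float(np.nanmean(r.full_scores)),
                    "mean_ablated": float(np.nanmean(r.ablated_scores)),
                    "z": r.z,
                    "note": r.note,
                }
                for r in results
            ]
        ).to_csv(out / "ablation.csv", index=False)
        report["ablation"] = {r.feature_type: round(r.z, 3) for r in results}

    # ----------------------------------------------------------- learncurve
    if stages["learncurve"]:
        if fm is None:
            raise RuntimeError("learncurve stage requires the feature matrix")
        lcfg = cfg["learncurve"]
        lc = learning_curve(
            fm,
            n_samples=lcfg["n_samples"],
            family=lcfg["family"],
            seed=stage_seed(seed, "learncurve"),
        )
        lc.to_frame().to_csv(out / "learning_curve.csv", index=False)
        report["learncurve"] = {
            "final_median_accuracy": float(lc.median_accuracy[-1])
        }

    # ----------------------------------------------------------------- chem
    if stages["chem"]:
        if library is None:
            raise RuntimeError("chem stage requires the ligand library")
        kcfg = cfg["chem"]
        results = cluster_fingerprints(
            library.fingerprints,
            library.labels["class"],
            k_range=range(kcfg["k_min"], kcfg["k_max"] + 1),
            seed=stage_seed(seed, "chem"),
        )
        contingency_table(results).to_csv(out / "chem_contingency.csv", index=False)
        assign2, purity2 = results[2]
        frames = [
            group_fraction_correct(
                assign2,
                library.labels["class"],
                library.labels["group"],
                mode="cluster",
            )
        ]
        if fm is not None:
            preds = cv_predictions(
                fm,
                family="SVM",
                k=cfg["train"]["cv_folds"],
                seed=stage_seed(seed, "train"),
            )
            frames.append(
                group_fraction_correct(
                    preds,
                    library.labels["class"],
                    library.labels["group"],
                    mode="classifier",
                    method="SVM",
                )
            )
        groups_df = pd.concat(frames, ignore_index=True)
        groups_df.to_csv(out / "group_fractions.csv", index=False)
        report["chem"] = {
            "fp_purity_k2": round(purity2.purity, 4),
            "group_fractions": {
                m: dict(zip(g["group"], g["fraction_correct"].round(3)))
                for m, g in groups_df.groupby("method")
            },
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
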