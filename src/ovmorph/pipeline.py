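"""End-to-end pipeline driver.

``run_pipeline`` chains the stages — simulate (or load) → segment → profile
→ discover/fit/predict → survival → integrate — under a single run
directory, writing every artifact plus a manifest recording the seed,
parameters and a SHA-256 per artifact, so reruns with the same configuration
are bit-identical.  Stages degrade gracefully: a missing clinical table
skips the survival stage with an explicit log line.

The configuration is a plain nested dict (YAML on disk, see ``cli``), one
section per stage; a single global ``seed`` fans out to per-stage seeds
deterministically (stage seed = global seed * 1000 + stage offset, kept
below 2**31).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import integration as integ
from . import io as ovio
from . import morphometry as morph
from . import profile as prof
from . import signature as sig
from . import survival as surv
from . import synthetic as syn

log = logging.getLogger("ovmorph")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_image_samples": 12,
        "images_per_sample": 2,
        "n_nuclei": 45,
        "area_range": [80.0, 440.0],
        "image_shape": [324, 536],
        "n_samples": 232,
        "n_genes": 1000,
        "n_informative": 40,
        "log2_fold_change": 1.0,
        "noise_sd": 0.5,
        "resistant_fraction": 67 / 232,
    },
    "segment": {"band_low": 3.0, "band_high": 40.0},
    "profile": {},
    "discover": {
        "fold_change_candidates": [1.2, 1.5, 2.0],
        "p_max": 0.05,
        "fdr_max": 0.02,
        "prescreen_quantiles": [0.1, 0.1],
    },
    "survival": {"split_feature": "Std_Ar_Bin2", "top_fraction": 0.701},
    "integrate": {"p_max_genes": 0.01, "p_max_corr": 0.005},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2**31 - 1)


def stage_simulate(cfg: dict, run_dir: Path) -> dict:
    """Write synthetic images (+truth), expression TSV and clinical TSV."""
    s = cfg["simulate"]
    seed = cfg["seed"]
    data = run_dir / "data"
    (data / "images").mkdir(parents=True, exist_ok=True)
    matrix, labels, truth = syn.generate_expression_dataset(
        n_samples=s["n_samples"],
        n_genes=s["n_genes"],
        n_informative=s["n_informative"],
        log2_fold_change=s["log2_fold_change"],
        noise_sd=s["noise_sd"],
        resistant_fraction=s["resistant_fraction"],
        seed=_stage_seed(seed, 1),
    )
    ovio.write_expression(data / "expression.tsv", matrix.round(5))
    clinical = syn.generate_clinical_table(labels, seed=_stage_seed(seed, 2))
    ovio.write_clinical(data / "clinical.tsv", clinical)
    image_samples = list(labels.index[: s["n_image_samples"]])
    for i, sid in enumerate(image_samples):
        for j in range(s["images_per_sample"]):
            img, itruth = syn.generate_nuclear_image(
                n_nuclei=s["n_nuclei"],
                area_range=tuple(s["area_range"]),
                image_shape=tuple(s["image_shape"]),
                seed=_stage_seed(seed, 100 + i * 10 + j),
            )
            stem = data / "images" / f"{sid}_img{j}"
            ovio.write_image(stem.with_suffix(".png"), img)
            ovio.write_truth(stem.with_suffix(".json"), itruth)
    log.info("simulate: %d expression samples, %d image samples x %d images",
             len(labels), len(image_samples), s["images_per_sample"])
    json.dump({"informative_genes": sorted(truth.informative_gene_ids)},
              open(run_dir / "data" / "expression_truth.json", "w"), indent=1)
    return {"n_samples": len(labels), "n_image_samples": len(image_samples)}


def stage_segment(cfg: dict, run_dir: Path) -> dict:
    """Segment every image and pool per-sample nucleus measurements to CSV."""
    s = cfg["segment"]
    images_dir = run_dir / "data" / "images"
    paths = sorted(images_dir.glob("*.png")) + sorted(images_dir.glob("*.tif*"))
    if not paths:
        raise FileNotFoundError(f"no images under {images_dir}")
    by_sample: dict[str, list] = {}
    for p in paths:
        sid = p.stem.rsplit("_img", 1)[0]
        by_sample.setdefault(sid, []).append(p)
    frames = []
    n_nuclei = 0
    for sid, sample_paths in sorted(by_sample.items()):
        images = [ovio.read_image(p) for p in sample_paths]
        nset = morph.measure_sample(
            images, sid, band_low=s["band_low"], band_high=s["band_high"]
        )
        n_nuclei += len(nset.measurements)
        frames.append(morph.measurements_to_frame(nset))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(run_dir / "nuclei.csv", index=False)
    log.info("segment: %d images, %d retained nuclei", len(paths), n_nuclei)
    return {"n_images": len(paths), "n_nuclei": n_nuclei}


def stage_profile(cfg: dict, run_dir: Path) -> dict:
    """Build per-sample 153-feature profiles and the normalized matrix."""
    nuclei = pd.read_csv(run_dir / "nuclei.csv")
    shape_path = run_dir / "data" / "images"
    sample_img = {p.stem.rsplit("_img", 1)[0]: p for p in sorted(shape_path.glob("*.png"))}
    profiles = []
    for sid, rows in nuclei.groupby("sample_id"):
        shape = ovio.read_image(sample_img[sid]).shape if sid in sample_img else (648, 1072)
        n_images = len([p for p in shape_path.glob(f"{sid}_img*.png")]) or 1
        nset = morph.SampleNucleusSet(
            sid, morph.frame_to_measurements(rows), n_images=n_images,
            image_shape=shape,
        )
        profiles.append(prof.build_profile(nset))
    raw = prof.profiles_to_matrix(profiles)
    ovio.write_feature_matrix(run_dir / "profiles_raw.csv", raw)
    norm = prof.normalize_profiles(raw)
    ovio.write_feature_matrix(run_dir / "profiles_normalized.csv", norm)
    log.info("profile: %d samples x %d features", *raw.shape)
    return {"n_profiles": len(profiles)}


def stage_discover(cfg: dict, run_dir: Path) -> dict:
    """Gene selection, weighted-voting fit, ROC cutoff, scores; morph signature."""
    d = cfg["discover"]
    matrix = ovio.read_expression(run_dir / "data" / "expression.tsv")
    labels = ovio.read_labels(run_dir / "data" / "clinical.tsv")
    q_var, q_med = d["prescreen_quantiles"]
    screened = sig.prescreen_genes(matrix, q_var, q_med)
    best_cutoff, curve = sig.tune_fold_change_cutoff(
        screened, labels, d["fold_change_candidates"], p_max=d["p_max"]
    )
    entries = sig.select_genes(screened, labels, best_cutoff, d["p_max"])
    model = sig.fit_weighted_voting(screened, labels, entries)
    scores = sig.predict_scores(model, screened)
    roc = sig.roc_and_cutoff(scores, labels)
    model.score_cutoff = roc.cutoff
    model.to_json(run_dir / "model.json")
    curve.to_csv(run_dir / "fold_change_curve.csv", index=False)
    pd.DataFrame([vars(e) for e in entries]).to_csv(
        run_dir / "gene_signature.csv", index=False
    )
    scores.round(6).to_csv(run_dir / "scores.tsv", sep="\t", header=True)
    roc.points.round(6).to_csv(run_dir / "roc_points.csv", index=False)

    morph_info = {}
    prof_path = run_dir / "profiles_normalized.csv"
    if prof_path.exists():
        feats = ovio.read_feature_matrix(prof_path)
        flabels = labels.reindex(feats.index).dropna()
        if flabels.nunique() == 2 and min(flabels.value_counts()) >= 2:
            morph_entries = sig.select_morph_features(
                feats.loc[flabels.index], flabels, fdr_max=d["fdr_max"]
            )
            pd.DataFrame([vars(e) for e in morph_entries]).to_csv(
                run_dir / "morph_signature.csv", index=False
            )
            morph_info = {"n_morph_features": len(morph_entries)}
        else:
            log.info("discover: too few labelled profile samples for a morph signature")
    log.info("discover: cutoff %.3g, %d genes, AUC %.3f, score cutoff %.4f",
             best_cutoff, len(entries), roc.auc, roc.cutoff)
    return {
        "fold_change_cutoff": best_cutoff,
        "n_genes": len(entries),
        "auc": roc.auc,
        "score_cutoff": roc.cutoff,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        **morph_info,
    }


def stage_survival(cfg: dict, run_dir: Path) -> dict:
    """KM + log-rank + Cox for score groups and for a feature median split."""
    v = cfg["survival"]
    clin_path = run_dir / "data" / "clinical.tsv"
    if not clin_path.exists():
        log.info("survival: clinical table missing, stage skipped")
        return {"skipped": True}
    clinical = ovio.read_clinical(clin_path)
    results: dict = {}
    scores = pd.read_csv(run_dir / "scores.tsv", sep="\t", index_col=0)["score"]
    score_groups = sig.split_by_quantile(scores, v["top_fraction"])
    results["score_groups"] = _compare_groups(clinical, score_groups, run_dir, "score")

    prof_path = run_dir / "profiles_normalized.csv"
    if prof_path.exists():
        feats = ovio.read_feature_matrix(prof_path)
        feat = v["split_feature"]
        if feat in feats.columns and feats[feat].notna().sum() >= 2 \
                and feats[feat].dropna().nunique() > 1:
            fgroups = surv.median_split(feats, feat)
            sub = clinical.reindex(fgroups.dropna().index).dropna(subset=["pfs_months"])
            if len(sub) >= 4:
                results["feature_groups"] = _compare_groups(
                    clinical, fgroups, run_dir, "feature"
                )
        else:
            log.info("survival: feature %s unusable for a median split", feat)
    json.dump(results, open(run_dir / "survival.json", "w"), indent=1, default=float)
    return results


def _compare_groups(
    clinical: pd.DataFrame, groups: pd.Series, run_dir: Path, tag: str
) -> dict:
    out: dict = {}
    g = groups.dropna()
    shared = clinical.index.intersection(g.index)
    g = g.loc[shared]
    levels = sorted(set(g))
    if len(levels) != 2 or min((g == lv).sum() for lv in levels) < 2:
        return {"skipped": True}
    for endpoint in ("OS", "PFS"):
        records = surv.frame_to_records(clinical.loc[shared], endpoint)
        rec_by_id = {r.sample_id: r for r in records}
        grp = [[rec_by_id[i] for i in g.index[g == lv]] for lv in levels]
        stat, p = surv.logrank_test(grp[0], grp[1])
        km = {lv: surv.km_estimate(gr) for lv, gr in zip(levels, grp)}
        curves = []
        for lv in levels:
            c = km[lv].curve.copy()
            c.insert(0, "group", lv)
            curves.append(c)
        pd.concat(curves).round(6).to_csv(
            run_dir / f"km_{tag}_{endpoint.lower()}.csv", index=False
        )
        entry = {
            "logrank_stat": stat,
            "logrank_p": p,
            "medians": {lv: km[lv].median for lv in levels},
        }
        # covariate adjustment needs enough events per parameter to be stable
        covariates = ("age", "stage", "grade") if len(g) >= 20 else ()
        try:
            cox = surv.cox_ph(records, g, covariates=covariates)
        except Exception as exc:  # noqa: BLE001 - reported in manifest and log
            log.warning("survival: Cox fit failed for %s/%s: %s", tag, endpoint, exc)
            entry["cox_error"] = str(exc)
        else:
            cox.round(6).to_csv(run_dir / f"cox_{tag}_{endpoint.lower()}.csv")
            entry["hazard_ratio"] = float(cox["hazard_ratio"].iloc[0])
        out[endpoint] = entry
    return out


def stage_integrate(cfg: dict, run_dir: Path) -> dict:
    """Feature-split supervised gene analysis and feature-gene correlation."""
    g = cfg["integrate"]
    prof_path = run_dir / "profiles_normalized.csv"
    if not prof_path.exists():
        log.info("integrate: no profiles, stage skipped")
        return {"skipped": True}
    feats = ovio.read_feature_matrix(prof_path)
    matrix = ovio.read_expression(run_dir / "data" / "expression.tsv")
    shared = feats.index.intersection(matrix.columns)
    out: dict = {}
    feat = cfg["survival"]["split_feature"]
    if len(shared) >= 5 and feat in feats.columns \
            and feats.loc[shared, feat].dropna().nunique() > 1:
        groups = surv.median_split(feats.loc[shared], feat)
        if min((groups == "low").sum(), (groups == "high").sum()) >= 2:
            genes = integ.supervised_gene_analysis(
                matrix[shared], groups, p_max=g["p_max_genes"]
            )
            genes.to_csv(run_dir / "feature_split_genes.csv", index=False)
            out["n_split_genes"] = len(genes)
        pairs = integ.feature_gene_correlation(
            feats.loc[shared], matrix[shared], p_max=g["p_max_corr"]
        )
        pairs.round(6).to_csv(run_dir / "feature_gene_pairs.csv", index=False)
        out["n_pairs"] = len(pairs)
        log.info("integrate: %s split genes, %d correlated pairs",
                 out.get("n_split_genes", "no"), len(pairs))
    else:
        log.info("integrate: fewer than 5 shared samples, stage skipped")
        out["skipped"] = True
    return out


STAGES = [
    ("simulate", stage_simulate),
    ("segment", stage_segment),
    ("profile", stage_profile),
    ("discover", stage_discover),
    ("survival", stage_survival),
    ("integrate", stage_integrate),
]


def run_pipeline(
    config: dict | None, run_dir: str | Path, stages: list[str] | None = None
) -> dict:
    """Execute the pipeline under ``run_dir`` and write ``manifest.json``.

    ``config`` overrides :data:`DEFAULT_CONFIG` per stage; ``stages`` limits
    execution (earlier artifacts must already exist).  Returns the manifest.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    info: dict = {}
    for name, fn in STAGES:
        if stages is not None and name not in stages:
            continue
        info[name] = fn(cfg, run_dir)
    artifacts = {
        str(p.relative_to(run_dir)): _sha256(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"config": cfg, "stages": info, "artifacts": artifacts}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
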