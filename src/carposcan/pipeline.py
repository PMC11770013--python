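"""Stage runners and tabular I/O tying the modules into the full pipeline.

simulate -> segment -> features -> traits -> stats, each stage consuming
and producing CSV/JSON with fixed formatting (UTF-8, comma separator,
floats at 6 significant digits) so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .color_features import extract_features, feature_names
from .config import RunConfig
from .genetic_stats import fit_blup, haplotype_effect_test
from .segmentation import (
    FruitImage,
    SegmentationError,
    radial_map,
    segment_fruit,
)
from .synthetic_data import iter_population
from .trait_derivation import (
    aggregate_genotype_year,
    correlate_components,
    filter_genotypes,
    fit_pca,
    identify_pattern_axis,
)

__all__ = [
    "read_image",
    "write_csv",
    "run_simulate",
    "run_segment",
    "run_features",
    "run_traits",
    "run_stats",
]

log = logging.getLogger("carposcan")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s stage=%(stage)s id=%(id)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _log(level: int, stage: str, ident: str, message: str) -> None:
    log.log(level, message, extra={"stage": stage, "id": ident})


FLOAT_FORMAT = "%.6g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with header, UTF-8, '.' decimal, floats at 6 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, encoding="utf-8")


def read_image(path: str | Path, image_id: str, metadata: dict) -> FruitImage:
    """Load a PNG/TIFF/JPEG as an 8-bit sRGB FruitImage."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return FruitImage(pixels=arr, image_id=image_id, metadata=metadata)


def run_simulate(cfg: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Render the configured population; write images, truth and metadata CSVs."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    truth, stream = iter_population(cfg.simulate)
    meta_rows = []
    for img in stream:
        path = img_dir / f"{img.image_id}.png"
        Image.fromarray(img.pixels).save(path)
        meta_rows.append(
            {
                "image_id": img.image_id,
                "genotype": img.metadata["genotype"],
                "year": img.metadata["year"],
                "fruit": img.metadata["fruit"],
                "file": f"images/{img.image_id}.png",
            }
        )
        _log(logging.INFO, "simulate", img.image_id, "status=ok")
    metadata = pd.DataFrame(meta_rows)
    write_csv(metadata, out / "metadata.csv")
    write_csv(truth.per_image, out / "truth_images.csv")
    write_csv(truth.per_genotype, out / "truth_genotypes.csv")
    return metadata


def _load_inputs(image_dir: str | Path, metadata_csv: str | Path) -> list[tuple[Path, dict]]:
    meta = pd.read_csv(metadata_csv, dtype=str).fillna("")
    base = Path(image_dir)
    entries = []
    for row in meta.to_dict("records"):
        rel = row.get("file") or f"{row['image_id']}.png"
        path = base / rel
        if not path.exists():
            path = base / f"{row['image_id']}.png"
        entries.append((path, row))
    if not entries:
        raise ValueError(f"no images found: empty metadata table {metadata_csv}")
    return entries


def run_segment(
    image_dir: str | Path, metadata_csv: str | Path, cfg: RunConfig, out_dir: str | Path
) -> pd.DataFrame:
    """Segment every image; write 0/255 mask PNGs and a summary CSV."""
    out = Path(out_dir)
    mask_dir = out / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path, row in _load_inputs(image_dir, metadata_csv):
        image_id = row["image_id"]
        try:
            img = read_image(path, image_id, row)
            seg = segment_fruit(img, cfg.seg)
        except (SegmentationError, OSError) as exc:
            _log(logging.ERROR, "segment", image_id, f"status=failed reason={exc}")
            continue
        Image.fromarray((seg.mask * np.uint8(255))).save(mask_dir / f"{image_id}_mask.png")
        rows.append(
            {
                "image_id": image_id,
                "centroid_row": seg.centroid[0],
                "centroid_col": seg.centroid[1],
                "equivalent_radius_px": seg.equivalent_radius,
                "area_px": int(seg.mask.sum()),
            }
        )
        _log(logging.INFO, "segment", image_id, "status=ok")
    summary = pd.DataFrame(rows)
    write_csv(summary, out / "segmentation.csv")
    return summary


def extract_features_for_image(img: FruitImage, cfg: RunConfig):
    seg = segment_fruit(img, cfg.seg)
    seg = radial_map(seg, cfg.seg)
    return extract_features(img, seg, cfg.features)


def features_to_frame(feature_vectors: list) -> pd.DataFrame:
    """Stack RingFeatureVector objects into the features table."""
    cols = feature_names()
    rows = []
    for fv in feature_vectors:
        row = {
            "image_id": fv.image_id,
            "genotype": fv.metadata.get("genotype", ""),
            "year": fv.metadata.get("year", ""),
            "fruit": fv.metadata.get("fruit", ""),
        }
        row.update(dict(zip(cols, fv.flattened)))
        row["mean_a"] = fv.mean_a
        row["sd_a"] = fv.sd_a
        for label, count in zip(("inner", "medium", "outer"), fv.ring_pixel_counts):
            row[f"npix_{label}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def run_features(
    image_dir: str | Path,
    metadata_csv: str | Path,
    cfg: RunConfig,
    out_csv: str | Path,
    strict: bool = False,
) -> pd.DataFrame:
    """Extract the 30-bin feature row for every image listed in the metadata."""
    vectors = []
    failures = []
    for path, row in _load_inputs(image_dir, metadata_csv):
        image_id = row["image_id"]
        try:
            img = read_image(path, image_id, row)
            vectors.append(extract_features_for_image(img, cfg))
            _log(logging.INFO, "features", image_id, "status=ok")
        except (SegmentationError, ValueError, OSError) as exc:
            failures.append((image_id, str(exc)))
            _log(logging.ERROR, "features", image_id, f"status=failed reason={exc}")
    if strict and failures:
        raise RuntimeError(f"{len(failures)} image(s) failed feature extraction")
    table = features_to_frame(vectors)
    write_csv(table, out_csv)
    return table


def run_traits(
    features: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
    marker_presence: pd.DataFrame | None = None,
) -> dict:
    """PCA -> axis identification -> genotype x year aggregation -> filtering.

    Writes loadings, fruit scores, correlation table, phenotype and
    filter-audit CSVs plus a run-summary JSON; returns the artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores = fit_pca(features, k=cfg.traits.k)
    corr = correlate_components(scores, features)
    pattern, intensity = identify_pattern_axis(scores)
    cells = aggregate_genotype_year(scores.fruit_scores)
    pattern_pc = scores.component_name(pattern)
    pheno = cells[["genotype", "year", pattern_pc, "mean_a", "sd_a", "n_fruits"]].rename(
        columns={pattern_pc: "score"}
    )
    retained, audit = (None, None)
    if marker_presence is not None:
        retained, audit = filter_genotypes(
            pheno, marker_presence, cfg.traits.mean_a_threshold
        )
        pheno = pheno[pheno["genotype"].isin(retained)].reset_index(drop=True)
        write_csv(audit, out / "filter_audit.csv")
    write_csv(scores.loadings.reset_index(names="feature"), out / "loadings.csv")
    write_csv(scores.fruit_scores, out / "fruit_scores.csv")
    write_csv(corr.reset_index(names="component"), out / "correlations.csv")
    write_csv(cells, out / "genotype_year_scores.csv")
    write_csv(pheno, out / "phenotype.csv")
    summary = {
        "n_fruits": int(len(features)),
        "n_components": int(scores.n_components),
        "pattern_axis": pattern_pc,
        "intensity_axis": scores.component_name(intensity),
        "corr_pattern_sd_a": float(corr.iloc[pattern]["sd_a"]),
        "corr_intensity_mean_a": float(corr.iloc[intensity]["mean_a"]),
        "explained_variance_ratio": [float(v) for v in scores.explained_variance_ratio],
        "n_genotypes_retained": None if retained is None else len(retained),
        "warnings": scores.warnings,
    }
    (out / "traits_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"scores": scores, "phenotype": pheno, "summary": summary, "audit": audit}


def run_stats(
    pheno: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
    assignment: pd.DataFrame | None = None,
    focal: str | None = None,
) -> dict:
    """Mixed-model fit, heritability and (optionally) haplotype tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vc = fit_blup(pheno, response="score")
    n_obs = pheno.groupby("genotype").size()
    blup_table = pd.DataFrame(
        {
            "genotype": vc.blups.index,
            "blup": vc.blups.to_numpy(),
            "n_obs": n_obs.reindex(vc.blups.index).to_numpy(),
        }
    )
    write_csv(blup_table, out / "blups.csv")
    vc_json = {
        "sigma_g2": vc.sigma_g2,
        "sigma_r2": vc.sigma_r2,
        "h2": vc.h2,
        "beta": {k: float(v) for k, v in vc.beta.items()},
        "convergence": vc.convergence,
        "seed": cfg.seed,
    }
    (out / "variance_components.json").write_text(json.dumps(vc_json, indent=2, sort_keys=True))
    report = None
    if assignment is not None and focal is not None:
        report = haplotype_effect_test(vc.blups, assignment, focal, alpha=cfg.stats.alpha)
        for comp, tag in ((report.diplotype, "diplotype"), (report.presence, "presence")):
            write_csv(comp.descriptives, out / f"groups_{tag}.csv")
            write_csv(comp.tukey, out / f"tukey_{tag}.csv")
            anova = pd.DataFrame(
                [
                    {
                        "grouping": comp.grouping,
                        "F": comp.f_statistic,
                        "df_between": comp.df_between,
                        "df_within": comp.df_within,
                        "p_value": comp.p_value,
                    }
                ]
            )
            write_csv(anova, out / f"anova_{tag}.csv")
    return {"variance_components": vc, "blups": blup_table, "haplotype_report": report}
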