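"""End-to-end assembly: on-disk cohort -> feature views -> matched bundle.

Glues the modality modules together the way the screening workflow runs
them: genotype QC + panel restriction + additive encoding, covariate
cleaning + digitization, image BOW extraction against a codebook built
from a seeded random half of the images, then subject matching into a
:class:`~pmfusion.types.CohortBundle` ready for the evaluation protocol.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import clean_table, encode_and_scale, read_covariates
from .evaluate import match_subjects
from .genotypes import (
    encode_additive,
    load_default_panel,
    qc_filter,
    read_genotype_tsv,
    select_panel,
)
from .images import (
    Codebook,
    DetectorConfig,
    build_codebook,
    encode_bow,
    extract_descriptors,
    load_image,
)
from .types import CohortBundle, FeatureView

__all__ = ["load_labels", "genotype_view", "demographic_view", "image_view",
           "load_cohort"]

log = logging.getLogger(__name__)


def load_labels(path) -> pd.Series:
    """labels.csv (subject_id, label in {+1, -1}) -> Series by subject id."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return df.set_index("subject_id")["label"].astype(int)


def genotype_view(
    tsv_path,
    panel=None,
    subject_missing_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> FeatureView:
    """Genotype TSV -> QC -> panel restriction -> additive [0,1] encoding."""
    g = read_genotype_tsv(tsv_path)
    g, report = qc_filter(g, subject_missing_max, maf_min, hwe_alpha)
    g = select_panel(g, panel or load_default_panel())
    view = encode_additive(g)
    view.qc_report = report
    return view


def demographic_view(csv_path, types_path, max_missing: float = 0.05) -> FeatureView:
    """Covariate CSV + type sidecar -> cleaning -> digitized feature view."""
    table = read_covariates(csv_path, types_path)
    table = clean_table(table, max_missing)
    return encode_and_scale(table)


def image_view(
    image_dir,
    codebook: Codebook | None = None,
    k: int = 100,
    codebook_seed: int = 0,
    config: DetectorConfig = DetectorConfig(),
) -> tuple[FeatureView, Codebook]:
    """Per-image BOW histograms over a k-means visual-word codebook.

    If no codebook is given, one is built from the descriptors of a seeded
    random half of the images in ``image_dir`` (ids sorted for
    reproducibility).  Returns (view, codebook).
    """
    paths = sorted(Path(image_dir).glob("*.png")) + sorted(
        Path(image_dir).glob("*.jpg")
    )
    ids = [p.stem for p in paths]
    desc_sets = []
    for p, sid in zip(paths, ids):
        desc_sets.append((sid, extract_descriptors(load_image(p, sid), config)))
    if codebook is None:
        codebook = build_codebook(desc_sets, k=k, seed=codebook_seed)
    rows = [
        encode_bow(d, codebook, config.norm).histogram for _, d in desc_sets
    ]
    view = FeatureView(
        source_id="I",
        subject_ids=ids,
        matrix=np.array(rows),
        feature_names=[f"word_{j}" for j in range(codebook.k)],
    )
    return view, codebook


def load_cohort(
    cohort_dir,
    k: int = 100,
    codebook_seed: int = 0,
    detector_config: DetectorConfig = DetectorConfig(),
    modalities: str = "DGI",
) -> CohortBundle:
    """Read a cohort directory (as written by ``simulate_cohort``) into a
    matched bundle with any subset of the D/G/I views."""
    root = Path(cohort_dir)
    labels = load_labels(root / "labels.csv")
    views = {}
    if "D" in modalities:
        views["D"] = demographic_view(
            root / "covariates.csv", root / "covariate_types.csv"
        )
    if "G" in modalities:
        views["G"] = genotype_view(root / "genotypes.tsv")
    if "I" in modalities:
        views["I"], _ = image_view(
            root / "images", k=k, codebook_seed=codebook_seed,
            config=detector_config,
        )
    return match_subjects(
        labels, views, provenance={"cohort_dir": str(root), "k": k,
                                   "codebook_seed": codebook_seed},
    )
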