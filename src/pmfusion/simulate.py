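"""Seeded synthetic-cohort generator for end-to-end pipeline testing.

No population cohort with matched fundus images, genotypes and
demographics is publicly deposited, so this module fabricates one with a
known ground truth: disease labels at a configurable prevalence, panel
genotypes in Hardy-Weinberg equilibrium among controls with per-SNP
allelic odds ratios acting multiplicatively in cases, demographic tables
with standardized case/control mean shifts on a subset of variables, and
stylized fundus images whose positive class carries a bright crescent
adjacent to the optic disc — a cartoon of the parapapillary atrophy seen
in pathological myopia.  Each modality's signal is generated
independently given the label, so the three sources are complementary by
construction.  A fixed master seed reproduces every byte of output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import SimulationError
from .genotypes import load_default_panel, panel_chromosomes

__all__ = ["SimulationConfig", "simulate_cohort", "render_fundus"]

_ALLELES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the scale of the population study the pipeline is
    designed for: 2,258 subjects at prevalence 58/2258, the shipped
    myopia SNP panel, 44 demographic variables.  ``n_subjects`` is
    routinely overridden downward for fast runs.
    """

    n_subjects: int = 2258
    prevalence: float = 58 / 2258
    image_contrast: float = 0.8  # crescent contrast in [0, 1]
    image_size: int = 512
    n_causal_snps: int = 8
    causal_odds_ratio: float = 2.0
    n_demographic_vars: int = 44
    n_categorical_vars: int = 14
    n_informative_demo: int = 5
    demo_effect_sd: float = 0.4  # standardized case mean shift
    genotype_missing_rate: float = 0.01
    demo_missing_rate: float = 0.02
    seed: int = 0

    def validate(self):
        if not 0 < self.prevalence < 1:
            raise SimulationError("prevalence must lie in (0, 1)")
        if not 0 <= self.image_contrast <= 1:
            raise SimulationError("image contrast must lie in [0, 1]")
        if self.causal_odds_ratio <= 0:
            raise SimulationError("odds ratios must be positive")
        for rate in (self.genotype_missing_rate, self.demo_missing_rate):
            if not 0 <= rate <= 1:
                raise SimulationError("missingness rates must lie in [0, 1]")
        if round(self.n_subjects * self.prevalence) < 2:
            raise SimulationError("expected case count below 2")


def _disc(shape, cy, cx, ry, rx):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_fundus(label: int, rng: np.random.Generator, contrast: float = 0.8,
                  size: int = 512) -> np.ndarray:
    """One stylized fundus raster (H x W x 3 uint8).

    Dark circular field of view, bright optic-disc ellipse at a jittered
    temporal position, a handful of vessel-like dark polylines radiating
    from the disc, and Gaussian pixel noise.  Positive subjects
    (``label == +1``) additionally get a crescent-shaped bright rim
    adjacent to the disc whose green-channel amplitude scales with
    ``contrast``.  The structure lives in the green channel.
    """
    h = w = size
    img = np.zeros((h, w, 3), dtype=float)
    img[:, :, 0] = 25.0
    img[:, :, 2] = 10.0

    fov = _disc((h, w), (h - 1) / 2, (w - 1) / 2, 0.49 * h, 0.49 * w)
    img[:, :, 0] += fov * 110.0
    img[:, :, 1] += fov * 70.0
    img[:, :, 2] += fov * 20.0

    # optic disc: bright ellipse, jittered around a temporal position
    cy = h / 2 + rng.uniform(-0.04, 0.04) * h
    cx = w * 0.64 + rng.uniform(-0.04, 0.04) * w
    ry = rng.uniform(0.055, 0.07) * h
    rx = rng.uniform(0.05, 0.065) * w
    disc = _disc((h, w), cy, cx, ry, rx)
    img[:, :, 0] += disc * 120.0
    img[:, :, 1] += disc * 130.0
    img[:, :, 2] += disc * 40.0

    # crescent adjacent to the disc on the temporal side of positives
    if label == 1 and contrast > 0:
        side = rng.choice([-1.0, 1.0])
        outer = _disc((h, w), cy, cx + side * 0.35 * rx, 1.75 * ry, 1.75 * rx)
        crescent = outer & ~_disc((h, w), cy, cx, 1.15 * ry, 1.15 * rx) & fov
        img[:, :, 1] += crescent * (110.0 * contrast)
        img[:, :, 0] += crescent * (40.0 * contrast)

    # vessel-like dark polylines radiating from the disc
    vessel_canvas = Image.new("L", (w, h), 0)
    from PIL import ImageDraw

    draw = ImageDraw.Draw(vessel_canvas)
    for _ in range(6):
        ang = rng.uniform(0, 2 * np.pi)
        y0, x0 = cy, cx
        pts = [(x0, y0)]
        for _seg in range(5):
            length = rng.uniform(0.08, 0.16) * h
            ang += rng.uniform(-0.5, 0.5)
            y0 += length * np.sin(ang)
            x0 += length * np.cos(ang)
            pts.append((x0, y0))
        draw.line(pts, fill=255, width=int(rng.uniform(3, 6)))
    vessels = (np.asarray(vessel_canvas) > 0) & fov
    img[:, :, 1] = np.where(vessels, img[:, :, 1] * 0.55, img[:, :, 1])

    img += rng.normal(0.0, 5.0, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _case_genotype_probs(freq: float, odds_ratio: float) -> np.ndarray:
    """Case genotype distribution: HWE probabilities reweighted by
    OR^(minor-allele count) and renormalized (additive risk model)."""
    p = np.array(
        [(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2]
    ) * odds_ratio ** np.arange(3)
    return p / p.sum()


def simulate_cohort(cfg: SimulationConfig, out_dir) -> dict:
    """Write a complete synthetic cohort to ``out_dir``.

    Outputs: ``images/<id>.png``, ``genotypes.tsv`` (allele-pair calls,
    headers ``rsID:chrom``), ``covariates.csv`` + ``covariate_types.csv``,
    ``labels.csv`` and ``truth.json`` holding every ground-truth
    parameter.  Returns the truth dictionary.
    """
    cfg.validate()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_subjects
    n_cases = round(n * cfg.prevalence)
    subject_ids = [f"S{i:05d}" for i in range(n)]
    labels = np.full(n, -1, dtype=int)
    labels[rng.choice(n, size=n_cases, replace=False)] = 1

    # ---- genotypes on the shipped panel -------------------------------
    panel = load_default_panel()
    chrom = panel_chromosomes()
    m = len(panel)
    freqs = rng.uniform(0.1, 0.5, size=m)
    # causal SNPs drawn among autosomal panel members
    autosomal = [
        j for j, rs in enumerate(panel.rs_ids)
        if chrom.get(rs, "NA") not in ("X", "Y")
    ]
    causal = np.sort(rng.choice(autosomal, size=cfg.n_causal_snps, replace=False))
    odds = np.ones(m)
    odds[causal] = cfg.causal_odds_ratio

    geno = np.empty((n, m), dtype=int)
    for j in range(m):
        hwe = np.array(
            [(1 - freqs[j]) ** 2, 2 * freqs[j] * (1 - freqs[j]), freqs[j] ** 2]
        )
        case_p = _case_genotype_probs(freqs[j], odds[j])
        geno[:, j] = np.where(
            labels == 1,
            rng.choice(3, size=n, p=case_p),
            rng.choice(3, size=n, p=hwe),
        )
    missing = rng.random((n, m)) < cfg.genotype_missing_rate

    # allele letters per SNP: major then minor, distinct
    allele_pairs = []
    for j in range(m):
        a, b = rng.choice(4, size=2, replace=False)
        allele_pairs.append((_ALLELES[a], _ALLELES[b]))

    geno_cols = {}
    for j, rs in enumerate(panel.rs_ids):
        major, minor = allele_pairs[j]
        strings = np.array(
            [major + major, major + minor, minor + minor]
        )[geno[:, j]]
        strings = strings.astype(object)
        strings[missing[:, j]] = "./."
        geno_cols[f"{rs}:{chrom.get(rs, 'NA')}"] = strings
    geno_df = pd.DataFrame({"subject_id": subject_ids} | geno_cols)
    geno_df.to_csv(out / "genotypes.tsv", sep="\t", index=False)

    # ---- demographics -------------------------------------------------
    n_num = cfg.n_demographic_vars - cfg.n_categorical_vars
    demo = rng.normal(size=(n, cfg.n_demographic_vars))
    informative = np.sort(
        rng.choice(cfg.n_demographic_vars, size=cfg.n_informative_demo,
                   replace=False)
    )
    demo[np.ix_(labels == 1, informative)] += cfg.demo_effect_sd
    demo_df = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    types = {}
    for v in range(cfg.n_demographic_vars):
        name = f"var_{v:02d}"
        if v < n_num:
            demo_df[name] = np.round(demo[:, v], 4)
            types[name] = "numeric"
        else:
            # categorize the latent normal into 3 lexicographic levels
            demo_df[name] = pd.cut(
                demo[:, v], [-np.inf, -0.5, 0.5, np.inf],
                labels=["lvl_a", "lvl_b", "lvl_c"],
            ).astype(str)
            types[name] = "categorical"
    demo_missing = rng.random(demo_df.shape) < cfg.demo_missing_rate
    demo_df = demo_df.mask(demo_missing)
    demo_df.to_csv(out / "covariates.csv")
    with open(out / "covariate_types.csv", "w") as fh:
        for name, kind in types.items():
            fh.write(f"{name},{kind}\n")

    # ---- labels -------------------------------------------------------
    pd.DataFrame({"subject_id": subject_ids, "label": labels}).to_csv(
        out / "labels.csv", index=False
    )

    # ---- images -------------------------------------------------------
    for i, sid in enumerate(subject_ids):
        raster = render_fundus(
            int(labels[i]), rng, cfg.image_contrast, cfg.image_size
        )
        Image.fromarray(raster).save(out / "images" / f"{sid}.png")

    truth = {
        "config": asdict(cfg),
        "n_cases": int(n_cases),
        "snp_ids": panel.rs_ids,
        "founder_freqs": freqs.tolist(),
        "odds_ratios": odds.tolist(),
        "causal_snps": [panel.rs_ids[j] for j in causal],
        "informative_demo_vars": [f"var_{v:02d}" for v in informative],
        "demo_effect_sd": cfg.demo_effect_sd,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
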