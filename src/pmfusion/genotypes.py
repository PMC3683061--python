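"""Genotype quality control, panel restriction and additive encoding.

Raw genotype calls (allele-pair strings or VCF GT fields) are polarized to
minor-allele counts, pushed through conventional GWAS-style QC — subject
call rate, monomorphic/non-autosomal/low-MAF SNP removal and the
exact conditional Hardy-Weinberg test — and
restricted to a curated panel of myopia-susceptibility rs IDs before being
encoded as a [0,1] feature view for kernel learning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import MissingDataError, PanelMatchError, QCError
from .types import FeatureView

__all__ = [
    "GenotypeMatrix",
    "SNPPanel",
    "QCReport",
    "hwe_exact_pvalue",
    "qc_filter",
    "select_panel",
    "encode_additive",
    "read_genotype_tsv",
    "read_genotype_vcf",
    "load_default_panel",
    "read_panel",
]

log = logging.getLogger(__name__)

_AUTOSOMES = {str(i) for i in range(1, 23)}
_RS_RE = re.compile(r"^rs\d+$")


@dataclass
class GenotypeMatrix:
    """Subject-by-SNP minor-allele counts; NaN marks a missing call."""

    subject_ids: list
    snp_ids: list
    calls: np.ndarray  # float matrix, entries in {0,1,2,nan}
    chrom: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match id lists")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing")
        if not self.chrom:
            self.chrom = ["NA"] * len(self.snp_ids)

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) counts for SNP column ``j``."""
        col = self.calls[:, j]
        col = col[~np.isnan(col)]
        return (
            int(np.sum(col == 0)),
            int(np.sum(col == 1)),
            int(np.sum(col == 2)),
        )


@dataclass
class SNPPanel:
    """Curated rs-ID panel with gene annotation and provenance tags."""

    rs_ids: list
    genes: list = field(default_factory=list)
    sources: list = field(default_factory=list)

    def __post_init__(self):
        if not self.rs_ids:
            raise ValueError("panel must be non-empty")
        for rs in self.rs_ids:
            if not _RS_RE.match(rs):
                raise ValueError(f"invalid rs identifier: {rs!r}")
        if not self.genes:
            self.genes = [""] * len(self.rs_ids)
        if not self.sources:
            self.sources = [""] * len(self.rs_ids)

    def __len__(self) -> int:
        return len(self.rs_ids)


@dataclass
class QCReport:
    """Itemized removals of one QC pass; reasons partition the dropped set."""

    subject_missing_max: float
    maf_min: float
    hwe_alpha: float
    removed_subjects: list = field(default_factory=list)
    removed_snps: dict = field(default_factory=dict)  # rs_id -> reason

    @property
    def n_subjects_removed(self) -> int:
        return len(self.removed_subjects)

    @property
    def n_snps_removed(self) -> dict:
        out = {"monomorphic": 0, "non_autosomal": 0, "maf": 0, "hwe": 0}
        for reason in self.removed_snps.values():
            out[reason] += 1
        return out


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  The
    support is the set of heterozygote counts with the parity of the minor
    allele total; probabilities follow the exact conditional distribution

        P(het = h) ∝ n! 2^h / (hom_r(h)! h! hom_c(h)!)

    computed in log space for stability.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n_hom_major, n_het, n_hom_minor = (int(c) for c in counts)
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * n_hom_minor + n_het
    if 2 * n - rare < rare:  # ensure 'rare' really is the minor allele total
        rare = 2 * n - rare
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    hets = hets[(rare - hets) % 2 == 0]
    hets = hets[(rare - hets) // 2 + hets <= n]
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = min(n_het, rare)  # observed het count on the minor-allele scale
    p_obs = probs[hets == obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _is_autosomal(chrom: str) -> bool:
    c = str(chrom).removeprefix("chr")
    # unknown chromosome is retained rather than discarded
    return c in _AUTOSOMES or c in ("NA", ".", "")


def qc_filter(
    g: GenotypeMatrix,
    subject_missing_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate subjects, then failing SNPs.

    Subjects whose missing fraction exceeds ``subject_missing_max`` go
    first; on the remaining subjects each SNP is tested, in order, for
    monomorphism, non-autosomal location, MAF below ``maf_min`` and
    Hardy-Weinberg exact p below ``hwe_alpha``; the first failing rule is
    recorded as the removal reason.
    """
    report = QCReport(subject_missing_max, maf_min, hwe_alpha)
    miss_frac = np.isnan(g.calls).mean(axis=1)
    keep_subj = miss_frac <= subject_missing_max
    report.removed_subjects = [
        s for s, k in zip(g.subject_ids, keep_subj) if not k
    ]
    if not keep_subj.any():
        raise QCError("all subjects removed by call-rate filter")
    calls = g.calls[keep_subj]

    keep_snp = np.ones(g.n_snps, dtype=bool)
    for j, rs in enumerate(g.snp_ids):
        col = calls[:, j]
        obs = col[~np.isnan(col)]
        n_obs = len(obs)
        minor = obs.sum()
        maf = minor / (2 * n_obs) if n_obs else 0.0
        if maf > 0.5:
            maf = 1.0 - maf
        if n_obs == 0 or maf == 0.0:
            reason = "monomorphic"
        elif not _is_autosomal(g.chrom[j]):
            reason = "non_autosomal"
        elif maf < maf_min:
            reason = "maf"
        else:
            p = hwe_exact_pvalue(
                int(np.sum(obs == 0)), int(np.sum(obs == 1)), int(np.sum(obs == 2))
            )
            if p < hwe_alpha:
                reason = "hwe"
            else:
                continue
        keep_snp[j] = False
        report.removed_snps[rs] = reason

    if not keep_snp.any():
        raise QCError("all SNPs removed by QC filters")
    out = GenotypeMatrix(
        subject_ids=[s for s, k in zip(g.subject_ids, keep_subj) if k],
        snp_ids=[s for s, k in zip(g.snp_ids, keep_snp) if k],
        calls=calls[:, keep_snp],
        chrom=[c for c, k in zip(g.chrom, keep_snp) if k],
    )
    log.info(
        "QC: removed %d subjects, %d SNPs (%s)",
        report.n_subjects_removed,
        len(report.removed_snps),
        report.n_snps_removed,
    )
    return out, report


def select_panel(g: GenotypeMatrix, panel: SNPPanel) -> GenotypeMatrix:
    """Restrict columns to the panel SNPs present in the data, panel order."""
    idx = {rs: j for j, rs in enumerate(g.snp_ids)}
    matched = [rs for rs in panel.rs_ids if rs in idx]
    unmatched = [rs for rs in panel.rs_ids if rs not in idx]
    if not matched:
        raise PanelMatchError("no panel SNP found in the genotype data")
    if unmatched:
        log.warning("%d panel SNPs not genotyped: %s ...",
                    len(unmatched), ", ".join(unmatched[:5]))
    log.info("panel match: %d of %d SNPs", len(matched), len(panel))
    cols = [idx[rs] for rs in matched]
    return GenotypeMatrix(
        subject_ids=list(g.subject_ids),
        snp_ids=matched,
        calls=g.calls[:, cols],
        chrom=[g.chrom[j] for j in cols],
    )


def encode_additive(g: GenotypeMatrix, fit_subjects=None) -> FeatureView:
    """Map minor-allele counts {0,1,2} to {0, 0.5, 1} with mode imputation.

    Missing calls are filled with the per-SNP modal genotype computed over
    ``fit_subjects`` (default: all subjects), so test subjects never inform
    the imputation.
    """
    rows = np.arange(g.n_subjects) if fit_subjects is None else np.asarray(fit_subjects)
    out = g.calls.copy()
    for j, rs in enumerate(g.snp_ids):
        fit_col = g.calls[rows, j]
        fit_obs = fit_col[~np.isnan(fit_col)]
        if len(fit_obs) == 0:
            raise MissingDataError(
                f"SNP {rs} entirely missing on the fitting subjects"
            )
        genos, counts = np.unique(fit_obs, return_counts=True)
        mode = genos[np.argmax(counts)]  # ties: lowest genotype wins
        col = out[:, j]
        col[np.isnan(col)] = mode
    return FeatureView(
        source_id="G",
        subject_ids=list(g.subject_ids),
        matrix=out / 2.0,
        feature_names=list(g.snp_ids),
    )


# ---------------------------------------------------------------------------
# I/O

_MISSING_CALLS = {"./.", "..", "--", "NN", "00", "", "NA"}


def _polarize(allele_pairs: list[str]) -> np.ndarray:
    """Allele-pair strings ('AG', './.') -> minor-allele counts with NaN."""
    counts: dict[str, int] = {}
    parsed = []
    for call in allele_pairs:
        call = call.strip()
        if call in _MISSING_CALLS:
            parsed.append(None)
            continue
        pair = call.split("/") if "/" in call else list(call)
        if len(pair) != 2:
            raise ValueError(f"cannot parse genotype call {call!r}")
        parsed.append(tuple(pair))
        for a in pair:
            counts[a] = counts.get(a, 0) + 1
    if not counts:
        return np.full(len(allele_pairs), np.nan)
    # minor allele: lowest count; ties broken alphabetically
    minor = min(sorted(counts), key=lambda a: (counts[a], a))
    if len(counts) == 1:
        minor = "\0"  # monomorphic: nothing counts as minor
    return np.array(
        [np.nan if p is None else float(sum(a == minor for a in p)) for p in parsed]
    )


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype table: subject_id column then one column per SNP.

    SNP column headers are ``rsID`` or ``rsID:chrom``; calls are allele
    pairs like ``AG`` (or ``A/G``) with ``./.`` for missing.  Calls are
    polarized to minor-allele counts on the table itself.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    subj = df.iloc[:, 0].tolist()
    snp_ids, chrom, cols = [], [], []
    for name in df.columns[1:]:
        rs, _, c = name.partition(":")
        snp_ids.append(rs)
        chrom.append(c or "NA")
        cols.append(_polarize(df[name].fillna("./.").tolist()))
    return GenotypeMatrix(
        subject_ids=subj,
        snp_ids=snp_ids,
        calls=np.column_stack(cols) if cols else np.empty((len(subj), 0)),
        chrom=chrom,
    )


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT fields) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subj = list(vcf.samples)
    snp_ids, chrom, cols = [], [], []
    for var in vcf:
        gts = var.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        col = np.array([np.nan if t == 3 else (2.0 if t == 2 else float(t)) for t in gts])
        # polarize to the minor allele within this file
        obs = col[~np.isnan(col)]
        if len(obs) and obs.sum() > len(obs):
            col = 2.0 - col
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(str(var.CHROM))
        cols.append(col)
    return GenotypeMatrix(
        subject_ids=subj,
        snp_ids=snp_ids,
        calls=np.column_stack(cols) if cols else np.empty((len(subj), 0)),
        chrom=chrom,
    )


def read_panel(path) -> SNPPanel:
    """Panel file: one rs ID per line, optional tab-separated gene/locus/source."""
    rs_ids, genes, sources = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rs_ids.append(parts[0])
            genes.append(parts[1] if len(parts) > 1 else "")
            sources.append(parts[3] if len(parts) > 3 else "")
    return SNPPanel(rs_ids=rs_ids, genes=genes, sources=sources)


def load_default_panel() -> SNPPanel:
    """The shipped myopia-susceptibility panel (linkage + GWAS loci)."""
    ref = resources.files("pmfusion.data").joinpath("myopia_snp_panel.tsv")
    with resources.as_file(ref) as path:
        return read_panel(path)


def panel_chromosomes(panel_path=None) -> dict:
    """rs_id -> chromosome label parsed from the panel locus column."""
    if panel_path is None:
        ref = resources.files("pmfusion.data").joinpath("myopia_snp_panel.tsv")
    else:
        ref = panel_path
    out = {}
    with open(ref) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            locus = parts[2] if len(parts) > 2 else "."
            m = re.match(r"^(\d+|X|Y)", locus)
            out[parts[0]] = m.group(1) if m else "NA"
    return out
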