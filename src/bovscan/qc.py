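"""Two-pass genotype quality control.

Filter cascade, applied in order on the pooled panel:

1. autosome / mapped-position restriction
2. call-rate filter (samples and markers, computed simultaneously)
3. pooled minor-allele-frequency filter
4. per-sample heterozygosity-outlier removal (upper tail, BH FDR)
5. within-breed Hardy-Weinberg exact-test filter (marker dropped if out
   of HWE in at least one breed)
6. second pass: call-rate and MAF filters re-applied to the pooled
   filtered data (a no-op on clean panels)

Every step appends to a :class:`QcReport` so the cascade is auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .genotype import MISSING, GenotypeMatrix, restrict_autosomes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Cascade thresholds; defaults follow common 50K-chip practice."""

    min_call_rate_sample: float = 0.99
    min_call_rate_marker: float = 0.99
    min_maf: float = 0.05
    het_fdr: float = 0.01
    hwe_alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "min_call_rate_sample",
            "min_call_rate_marker",
            "min_maf",
            "het_fdr",
            "hwe_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0,1]")


@dataclass
class QcStep:
    name: str
    samples_removed: int
    markers_removed: int
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_marker_ids: list[str] = field(default_factory=list)


@dataclass
class QcReport:
    steps: list[QcStep] = field(default_factory=list)
    initial_shape: tuple[int, int] | None = None
    final_shape: tuple[int, int] | None = None

    def add(self, step: QcStep) -> None:
        self.steps.append(step)
        logger.info(
            "qc step %-22s removed %d samples, %d markers",
            step.name, step.samples_removed, step.markers_removed,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "samples_removed": s.samples_removed,
                    "markers_removed": s.markers_removed,
                }
                for s in self.steps
            ]
        )

    def check_consistency(self) -> None:
        if self.initial_shape is None or self.final_shape is None:
            return
        ds = sum(s.samples_removed for s in self.steps)
        dm = sum(s.markers_removed for s in self.steps)
        assert self.initial_shape[0] - ds == self.final_shape[0]
        assert self.initial_shape[1] - dm == self.final_shape[1]


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def call_rate_filter(
    gm: GenotypeMatrix, thresholds: QcThresholds, step_name: str = "call_rate"
) -> tuple[GenotypeMatrix, QcStep]:
    """Remove samples and markers below their call-rate thresholds.

    Both rates are computed on the input panel and the removals applied
    in a single symmetric step (the sequential alternatives give
    order-dependent counts).
    """
    obs = gm.dosage != MISSING
    sample_cr = obs.mean(axis=1)
    marker_cr = obs.mean(axis=0)
    keep_s = sample_cr >= thresholds.min_call_rate_sample
    keep_m = marker_cr >= thresholds.min_call_rate_marker
    step = QcStep(
        name=step_name,
        samples_removed=int((~keep_s).sum()),
        markers_removed=int((~keep_m).sum()),
        removed_sample_ids=[gm.sample_ids[i] for i in np.flatnonzero(~keep_s)],
        removed_marker_ids=list(gm.marker_map["marker_id"].to_numpy()[~keep_m]),
    )
    if not keep_s.any() or not keep_m.any():
        raise ValueError("empty panel after call-rate filter")
    if keep_s.all() and keep_m.all():
        return gm, step
    return gm.subset(np.flatnonzero(keep_s), np.flatnonzero(keep_m)), step


def pooled_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Frequency of allele_b per marker over all non-missing genotypes."""
    obs = gm.dosage != MISSING
    d = np.where(obs, gm.dosage, 0)
    n_alleles = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_alleles > 0, d.sum(axis=0) / n_alleles, np.nan)


def maf_filter(
    gm: GenotypeMatrix, min_maf: float, step_name: str = "maf"
) -> tuple[GenotypeMatrix, QcStep]:
    """Drop markers with pooled minor-allele frequency below ``min_maf``
    (monomorphic markers always go)."""
    p = pooled_allele_freq(gm)
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    keep &= ~np.isnan(p)
    step = QcStep(
        name=step_name,
        samples_removed=0,
        markers_removed=int((~keep).sum()),
        removed_marker_ids=list(gm.marker_map["marker_id"].to_numpy()[~keep]),
    )
    if not keep.any():
        raise ValueError("empty panel after MAF filter")
    if keep.all():
        return gm, step
    return gm.subset(marker_idx=np.flatnonzero(keep)), step


def benjamini_hochberg(pvals: np.ndarray, q: float) -> np.ndarray:
    """Boolean rejection mask from the Benjamini-Hochberg step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))  # largest i with p_(i) <= iq/m
        reject[order[: k + 1]] = True
    return reject


def sample_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    obs = gm.dosage != MISSING
    het = gm.dosage == 1
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_obs > 0, het.sum(axis=1) / n_obs, np.nan)


def heterozygosity_outlier_filter(
    gm: GenotypeMatrix,
    het_fdr: float,
    step_name: str = "het_outliers",
    centre: str = "median",
) -> tuple[GenotypeMatrix, QcStep]:
    """Remove samples with abnormally *high* observed heterozygosity.

    Upper-tail p-values come from a normal model with robust
    centre/scale (median and scaled MAD by default; ``centre="mean"``
    switches to mean/sd); Benjamini-Hochberg controls the FDR.  A
    degenerate scale (all heterozygosities equal) skips the step with a
    warning.
    """
    if gm.n_samples < 10:
        raise ValueError("heterozygosity filter needs >= 10 samples")
    h = sample_heterozygosity(gm)
    if centre == "median":
        loc = float(np.median(h))
        scale = 1.4826 * float(np.median(np.abs(h - loc)))
    elif centre == "mean":
        loc = float(np.mean(h))
        scale = float(np.std(h, ddof=1))
    else:
        raise ValueError(f"unknown centre method {centre!r}")
    if scale <= 0.0:
        warnings.warn(
            "degenerate heterozygosity distribution (zero spread); "
            "skipping outlier filter",
            stacklevel=2,
        )
        return gm, QcStep(step_name, 0, 0)
    pvals = norm.sf((h - loc) / scale)  # upper tail only
    reject = benjamini_hochberg(pvals, het_fdr)
    step = QcStep(
        name=step_name,
        samples_removed=int(reject.sum()),
        markers_removed=0,
        removed_sample_ids=[gm.sample_ids[i] for i in np.flatnonzero(reject)],
    )
    if reject.all():
        raise ValueError("empty panel after heterozygosity filter")
    if not reject.any():
        return gm, step
    return gm.subset(sample_idx=np.flatnonzero(~reject)), step


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, heterozygote counts are
    distributed as ``P(h) proportional to n! / (nAA! h! naa!) * 2^h``;
    the p-value sums the probabilities of all configurations no more
    likely than the observed one.  Monomorphic input returns 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa  # count of the 'a' allele
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # feasible het counts share parity with the rare-allele count
    hs = np.arange(rare % 2, rare + 1, 2)
    # homozygote counts implied by h and the allele totals (symmetric in A/a)
    n_minor_hom = (rare - hs) // 2
    n_major_hom = n - hs - n_minor_hom
    logp = (
        hs * np.log(2.0)
        - gammaln(n_minor_hom + 1)
        - gammaln(hs + 1)
        - gammaln(n_major_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == n_Aa]
    if p_obs.size == 0:  # observed table inconsistent with parity — impossible
        raise ValueError("genotype counts inconsistent")
    p = probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square HWE test (no continuity correction); alternative
    to the exact test for very large samples."""
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def hwe_filter_within_breeds(
    gm: GenotypeMatrix,
    hwe_alpha: float,
    step_name: str = "hwe_within_breeds",
    method: str = "exact",
) -> tuple[GenotypeMatrix, QcStep]:
    """Drop a marker if it is out of HWE (p < alpha) in any single breed."""
    test = hwe_exact_test if method == "exact" else hwe_chi2_test
    idx = gm.breed_indices()
    for breed, rows in idx.items():
        if len(rows) < 2:
            raise ValueError(f"breed {breed!r} has fewer than 2 samples")
    drop = np.zeros(gm.n_markers, dtype=bool)
    for rows in idx.values():
        d = gm.dosage[rows]
        n0 = (d == 0).sum(axis=0)
        n1 = (d == 1).sum(axis=0)
        n2 = (d == 2).sum(axis=0)
        for j in np.flatnonzero(~drop):
            if n0[j] + n1[j] + n2[j] == 0:
                continue
            if test(int(n0[j]), int(n1[j]), int(n2[j])) < hwe_alpha:
                drop[j] = True
    step = QcStep(
        name=step_name,
        samples_removed=0,
        markers_removed=int(drop.sum()),
        removed_marker_ids=list(gm.marker_map["marker_id"].to_numpy()[drop]),
    )
    if drop.all():
        raise ValueError("empty panel after HWE filter")
    if not drop.any():
        return gm, step
    return gm.subset(marker_idx=np.flatnonzero(~drop)), step


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_qc_pipeline(
    gm: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    autosome_labels=None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full two-pass cascade; see module docstring for the order."""
    from .genotype import CATTLE_AUTOSOMES

    thr = thresholds or QcThresholds()
    labels = CATTLE_AUTOSOMES if autosome_labels is None else autosome_labels
    report = QcReport(initial_shape=(gm.n_samples, gm.n_markers))

    before = gm.n_markers
    gm, auto_report = restrict_autosomes(gm, labels)
    report.add(
        QcStep(
            "autosome_restriction",
            samples_removed=0,
            markers_removed=before - gm.n_markers,
        )
    )

    gm, step = call_rate_filter(gm, thr)
    report.add(step)
    gm, step = maf_filter(gm, thr.min_maf)
    report.add(step)
    gm, step = heterozygosity_outlier_filter(gm, thr.het_fdr)
    report.add(step)
    gm, step = hwe_filter_within_breeds(gm, thr.hwe_alpha)
    report.add(step)

    # second pass on the pooled filtered data: call rate + MAF once more
    gm, step = call_rate_filter(gm, thr, step_name="call_rate_pass2")
    report.add(step)
    gm, step = maf_filter(gm, thr.min_maf, step_name="maf_pass2")
    report.add(step)

    report.final_shape = (gm.n_samples, gm.n_markers)
    report.check_consistency()
    return gm, report
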