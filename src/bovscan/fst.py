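"""Per-locus multi-population fixation index and window-based genome scan.

The per-locus estimator is the sample-size-corrected Nei-Chesser form.
With ``s`` subpopulations of (non-missing) size ``n_i``, allele-b
frequency ``x_i`` in subpopulation ``i``, and harmonic mean
``n_tilde = s / sum(1/n_i)``:

    H_O = mean_i( observed het fraction in i )
    H_S = n_tilde/(n_tilde-1) * (1 - mean_i(x_i^2 + (1-x_i)^2) - H_O/(2 n_tilde))
    H_T = 1 - (xbar^2 + (1-xbar)^2) + H_S/(n_tilde*s) - H_O/(2*n_tilde*s)
    fst = (H_T - H_S) / H_T

where ``xbar`` is the unweighted mean of the ``x_i`` (each
subpopulation counts equally regardless of size).  The estimator is
slightly negative-biased-free: values just below zero are legitimate.

Scans average per-locus values over SNP windows inside each chromosome,
call outliers against genome-wide empirical quantiles, and merge
consecutive outlier windows into candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

WindowMode = Literal["non_overlapping_groups", "sliding_step1"]


@dataclass
class FstComponents:
    """All intermediate per-locus quantities, for auditability."""

    s: int
    n_i: np.ndarray
    n_tilde: float
    x_i: np.ndarray
    x_bar: float
    h_obs: float
    h_s: float
    h_t: float
    fst: float


@dataclass
class ScanResult:
    """Windowed scan with genome-wide quantile thresholds."""

    windows: pd.DataFrame  # chrom, start_bp, end_bp, n_snps, mean_fst, marker_ids
    window_width: int
    window_mode: str
    q_low: float
    q_high: float
    t_low: float
    t_high: float

    @property
    def outlier_high(self) -> pd.DataFrame:
        return self.windows[self.windows["mean_fst"] > self.t_high]

    @property
    def outlier_low(self) -> pd.DataFrame:
        return self.windows[self.windows["mean_fst"] < self.t_low]


# ---------------------------------------------------------------------------
# per-locus estimator
# ---------------------------------------------------------------------------

def _fst_from_counts(
    n0: np.ndarray, n1: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vectorised estimator from genotype-class counts.

    Parameters are ``(s, L)`` arrays of per-subpopulation counts of
    dosage 0/1/2.  Returns the ``(L,)`` fst vector (NaN where undefined)
    and the intermediate components.  Subpopulations with no data at a
    locus are dropped locus-wise; loci with fewer than 2 populated
    subpopulations, ``n_tilde <= 1`` or zero total diversity are NaN.
    """
    n0 = np.atleast_2d(np.asarray(n0, dtype=float))
    n1 = np.atleast_2d(np.asarray(n1, dtype=float))
    n2 = np.atleast_2d(np.asarray(n2, dtype=float))
    n = n0 + n1 + n2  # (s, L)
    populated = n > 0
    s_eff = populated.sum(axis=0)  # (L,)

    with np.errstate(divide="ignore", invalid="ignore"):
        inv_n = np.where(populated, 1.0 / n, 0.0)
        n_tilde = s_eff / inv_n.sum(axis=0)
        x = np.where(populated, (n1 + 2.0 * n2) / (2.0 * n), np.nan)  # allele-b freq
        het = np.where(populated, n1 / n, np.nan)
        h_obs = np.nanmean(np.where(populated, het, np.nan), axis=0)
        sum_x2 = x**2 + (1.0 - x) ** 2
        mean_sum_x2 = np.nanmean(np.where(populated, sum_x2, np.nan), axis=0)
        x_bar = np.nanmean(np.where(populated, x, np.nan), axis=0)

        h_s = (n_tilde / (n_tilde - 1.0)) * (
            1.0 - mean_sum_x2 - h_obs / (2.0 * n_tilde)
        )
        h_t = (
            1.0
            - (x_bar**2 + (1.0 - x_bar) ** 2)
            + h_s / (n_tilde * s_eff)
            - h_obs / (2.0 * n_tilde * s_eff)
        )
        fst = (h_t - h_s) / h_t

    invalid = (s_eff < 2) | (n_tilde <= 1.0) | ~(h_t > 1e-300)
    fst = np.where(invalid, np.nan, fst)
    comps = {
        "s_eff": s_eff,
        "n": n,
        "n_tilde": n_tilde,
        "x": x,
        "x_bar": x_bar,
        "h_obs": h_obs,
        "h_s": np.where(invalid, np.nan, h_s),
        "h_t": np.where(invalid, np.nan, h_t),
    }
    return fst, comps


def nei_chesser_locus(
    genotype_counts: Sequence[tuple[int, int, int]]
) -> FstComponents:
    """Single-locus estimator from per-subpopulation genotype counts.

    ``genotype_counts`` is a sequence of ``(n_AA, n_Aa, n_aa)`` triples,
    one per subpopulation, counting dosage-0 / dosage-1 / dosage-2
    genotypes.  Subpopulations with zero non-missing genotypes are
    dropped (with ``s`` decremented); a locus monomorphic overall yields
    ``fst = NaN``.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("expected a sequence of (n_AA, n_Aa, n_aa) triples")
    totals = counts.sum(axis=1)
    if (totals > 0).sum() < 2:
        raise ValueError(">=2 subpopulations with data required")
    n0 = counts[:, 0:1]
    n1 = counts[:, 1:2]
    n2 = counts[:, 2:3]
    fst, c = _fst_from_counts(n0, n1, n2)
    populated = totals > 0
    return FstComponents(
        s=int(c["s_eff"][0]),
        n_i=totals[populated],
        n_tilde=float(c["n_tilde"][0]),
        x_i=c["x"][populated, 0],
        x_bar=float(c["x_bar"][0]),
        h_obs=float(c["h_obs"][0]),
        h_s=float(c["h_s"][0]),
        h_t=float(c["h_t"][0]),
        fst=float(fst[0]),
    )


def _group_counts(
    gm: GenotypeMatrix, groups: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype-class counts per group: three (s, L) arrays."""
    n0, n1, n2 = [], [], []
    for rows in groups.values():
        d = gm.dosage[rows]
        n0.append((d == 0).sum(axis=0))
        n1.append((d == 1).sum(axis=0))
        n2.append((d == 2).sum(axis=0))
    return np.array(n0), np.array(n1), np.array(n2)


def resolve_grouping(
    gm: GenotypeMatrix, grouping: Sequence[str] | Mapping[str, Sequence[str]] | None
) -> dict[str, np.ndarray]:
    """Normalise a grouping spec to ``{subpop_name: sample row indices}``.

    ``None`` means every breed is its own subpopulation; a list of breed
    names restricts to those breeds (each still its own subpopulation); a
    mapping pools the listed breeds under each key.
    """
    idx = gm.breed_indices()
    if grouping is None:
        return idx
    if isinstance(grouping, Mapping):
        out = {}
        for name, members in grouping.items():
            missing = [b for b in members if b not in idx]
            if missing:
                raise KeyError(f"unknown breed(s) in grouping: {missing}")
            out[name] = np.concatenate([idx[b] for b in members])
        return out
    missing = [b for b in grouping if b not in idx]
    if missing:
        raise KeyError(f"unknown breed(s) in grouping: {missing}")
    return {b: idx[b] for b in grouping}


def fst_profile(
    gm: GenotypeMatrix,
    grouping: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
) -> np.ndarray:
    """Per-marker fst vector (map order); NaN at loci monomorphic overall."""
    groups = resolve_grouping(gm, grouping)
    if len(groups) < 2:
        raise ValueError(">=2 subpopulations required for an fst profile")
    n0, n1, n2 = _group_counts(gm, groups)
    fst, _ = _fst_from_counts(n0, n1, n2)
    return fst


def genomewide_fst(
    gm: GenotypeMatrix,
    grouping: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
) -> float:
    """Multi-locus fixation index: summed diversities, then one ratio.

    ``sum_l(H_T - H_S) / sum_l(H_T)`` over loci with defined diversity —
    the standard genome-wide form, free of the per-locus ratio's Jensen
    bias (the mean of per-locus ratios underestimates differentiation
    when H_T varies across loci).
    """
    groups = resolve_grouping(gm, grouping)
    if len(groups) < 2:
        raise ValueError(">=2 subpopulations required")
    n0, n1, n2 = _group_counts(gm, groups)
    _, c = _fst_from_counts(n0, n1, n2)
    h_t, h_s = c["h_t"], c["h_s"]
    ok = np.isfinite(h_t)
    denom = h_t[ok].sum()
    if denom <= 0:
        raise ValueError("no diversity: genome-wide fst undefined")
    return float((h_t[ok] - h_s[ok]).sum() / denom)


def one_vs_rest_profiles(gm: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Two-subpopulation fst per breed: focal breed vs all others pooled."""
    names = gm.breed_names
    if len(names) < 2:
        raise ValueError(">=2 breeds required")
    idx = gm.breed_indices()
    out = {}
    for breed in names:
        if len(idx[breed]) < 2:
            raise ValueError(
                f"breed {breed!r} has fewer than 2 samples; "
                "one-vs-rest fst undefined"
            )
        rest = np.concatenate([idx[b] for b in names if b != breed])
        grouping = {breed: idx[breed], "rest": rest}
        n0, n1, n2 = _group_counts(gm, grouping)
        out[breed], _ = _fst_from_counts(n0, n1, n2)
    return out


# ---------------------------------------------------------------------------
# windows, thresholds, regions
# ---------------------------------------------------------------------------

def _chrom_blocks(n: int, width: int) -> list[np.ndarray]:
    """Partition ``range(n)`` into consecutive blocks of ``width``.

    A trailing remainder of at least ``ceil(width/2)`` markers stays its
    own block, otherwise it is merged into the previous one (or kept
    alone when it is the only block).
    """
    full = n // width
    rem = n - full * width
    blocks = [np.arange(i * width, (i + 1) * width) for i in range(full)]
    if rem:
        tail = np.arange(full * width, n)
        if not blocks:
            blocks = [tail]
        elif rem >= (width + 1) // 2:
            blocks.append(tail)
        else:
            blocks[-1] = np.concatenate([blocks[-1], tail])
    return blocks


def window_average(
    fst_vector: np.ndarray,
    marker_map: pd.DataFrame,
    width: int = 8,
    mode: WindowMode = "non_overlapping_groups",
) -> pd.DataFrame:
    """Average the fst vector over SNP windows within each chromosome.

    NaN loci are excluded from each window mean; an all-NaN window is
    dropped.  Windows never span a chromosome boundary.  In sliding
    mode a chromosome shorter than ``width`` yields a single window
    covering it entirely.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    fst_vector = np.asarray(fst_vector, dtype=float)
    if len(fst_vector) != len(marker_map):
        raise ValueError("fst vector and map length mismatch")
    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    ids = marker_map["marker_id"].to_numpy()

    rows = []
    for c in pd.unique(chrom):
        loc = np.flatnonzero(chrom == c)
        n = len(loc)
        if mode == "non_overlapping_groups":
            windows = _chrom_blocks(n, width)
        elif mode == "sliding_step1":
            if n < width:
                windows = [np.arange(n)]
            else:
                windows = [np.arange(i, i + width) for i in range(n - width + 1)]
        else:
            raise ValueError(f"unknown window mode {mode!r}")
        for w in windows:
            g = loc[w]
            vals = fst_vector[g]
            finite = np.isfinite(vals)
            if not finite.any():
                continue
            rows.append(
                {
                    "chromosome": c,
                    "start_bp": int(pos[g].min()),
                    "end_bp": int(pos[g].max()),
                    "center_bp": float(pos[g].mean()),
                    "n_snps": int(len(g)),
                    "n_finite": int(finite.sum()),
                    "mean_fst": float(vals[finite].mean()),
                    "marker_ids": ",".join(ids[g]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start_bp", "end_bp", "center_bp",
            "n_snps", "n_finite", "mean_fst", "marker_ids",
        ],
    )


def quantile_thresholds(
    window_means: np.ndarray, q_low: float = 0.01, q_high: float = 0.99
) -> tuple[float, float]:
    """Genome-wide empirical quantiles (linear interpolation)."""
    if q_low > q_high:
        raise ValueError("q_low must not exceed q_high")
    vals = np.asarray(window_means, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(">=2 finite window means required")
    lo, hi = np.quantile(vals, [q_low, q_high], method="linear")
    return float(lo), float(hi)


def scan(
    gm: GenotypeMatrix,
    grouping=None,
    width: int = 8,
    mode: WindowMode = "non_overlapping_groups",
    q_low: float = 0.01,
    q_high: float = 0.99,
    fst_vector: np.ndarray | None = None,
) -> ScanResult:
    """Full windowed genome scan: profile -> windows -> thresholds."""
    if fst_vector is None:
        fst_vector = fst_profile(gm, grouping)
    windows = window_average(fst_vector, gm.marker_map, width, mode)
    t_low, t_high = quantile_thresholds(
        windows["mean_fst"].to_numpy(), q_low, q_high
    )
    return ScanResult(
        windows=windows,
        window_width=width,
        window_mode=mode,
        q_low=q_low,
        q_high=q_high,
        t_low=t_low,
        t_high=t_high,
    )


def call_outlier_regions(result: ScanResult, side: str = "high") -> pd.DataFrame:
    """Merge consecutive outlier windows on a chromosome into regions.

    ``side="high"`` (default) merges windows above the upper threshold;
    ``side="low"`` those below the lower one.  Consecutive means
    adjacent in the chromosome's window ordering.
    """
    w = result.windows.reset_index(drop=True)
    if side == "high":
        flag = (w["mean_fst"] > result.t_high).to_numpy()
    elif side == "low":
        flag = (w["mean_fst"] < result.t_low).to_numpy()
    else:
        raise ValueError("side must be 'high' or 'low'")

    rows = []
    chrom = w["chromosome"].to_numpy()
    i = 0
    n = len(w)
    while i < n:
        if not flag[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flag[j + 1] and chrom[j + 1] == chrom[i]:
            j += 1
        block = w.iloc[i : j + 1]
        rows.append(
            {
                "chromosome": chrom[i],
                "start_bp": int(block["start_bp"].min()),
                "end_bp": int(block["end_bp"].max()),
                "n_windows": int(len(block)),
                "n_snps": int(block["n_snps"].sum()),
                "max_fst": float(block["mean_fst"].max()),
                "mean_fst": float(block["mean_fst"].mean()),
            }
        )
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start_bp", "end_bp",
            "n_windows", "n_snps", "max_fst", "mean_fst",
        ],
    )


def read_bed_intervals(bed_path: str | Path) -> pd.DataFrame:
    """Read a minimal BED file (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            rows.append(
                {
                    "chromosome": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": name,
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


def annotate_regions(
    regions: pd.DataFrame, intervals: pd.DataFrame | str | Path
) -> pd.DataFrame:
    """Attach the names of overlapping BED intervals to each region.

    Region coordinates are 1-based inclusive bp and are converted to the
    BED 0-based half-open convention for the overlap test.
    """
    if not isinstance(intervals, pd.DataFrame):
        intervals = read_bed_intervals(intervals)
    out = regions.copy()
    hits = []
    for row in regions.itertuples(index=False):
        r_start0 = int(row.start_bp) - 1  # to 0-based half-open
        r_end0 = int(row.end_bp)
        sub = intervals[intervals["chromosome"].astype(str) == str(row.chromosome)]
        ov = sub[(sub["start"] < r_end0) & (r_start0 < sub["end"])]
        hits.append(",".join(ov["name"].tolist()))
    out["overlapping_intervals"] = hits
    return out


def region_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Region table in BED coordinates (chrom, start, end, name, score)."""
    bed = pd.DataFrame(
        {
            "chromosome": regions["chromosome"],
            "start": regions["start_bp"].astype(int) - 1,
            "end": regions["end_bp"].astype(int),
            "name": [
                f"region_{i + 1}" for i in range(len(regions))
            ],
            "score": regions["max_fst"],
        }
    )
    return bed


def plot_scan(result: ScanResult, out_path: str | Path, title: str = "") -> Path:
    """Manhattan-style plot of window means with quantile lines (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = result.windows
    fig, ax = plt.subplots(figsize=(12, 4))
    offset = 0.0
    ticks, labels = [], []
    for i, (c, grp) in enumerate(w.groupby("chromosome", sort=False)):
        x = grp["center_bp"].to_numpy() + offset
        ax.scatter(x, grp["mean_fst"], s=6, color="C0" if i % 2 == 0 else "C3")
        ticks.append(x.mean())
        labels.append(str(c))
        offset = x.max()
    for t in (result.t_low, result.t_high):
        ax.axhline(t, color="green", linestyle="--", linewidth=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("window mean fst")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
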