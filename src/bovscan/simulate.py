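"""Synthetic multi-breed SNP panels under the Balding-Nichols drift model.

Breed allele frequencies are drawn around a shared ancestral frequency
``p`` as ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, so the expected fixation
index of an ``s``-breed panel with drift parameter ``F`` has the closed
form ``F(1-1/s)/(1-F/s)`` — which gives every downstream estimator an
analytic target.  Optional features: breed-specific "selected" blocks
with elevated ``F``, i.i.d. missingness, forced-heterozygote HWE
violations, and admixed individuals with Dirichlet ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, _new_marker_map


@dataclass(frozen=True)
class SelectedBlock:
    """A run of consecutive markers with elevated drift in some breeds.

    ``chromosome`` is the 1-based chromosome index, ``start_index`` the
    0-based marker offset within that chromosome.  ``affected_breeds``
    of None means all breeds drift at ``f_selected`` at these loci.
    """

    chromosome: int
    start_index: int
    n_snps: int
    f_selected: float
    affected_breeds: tuple[int, ...] | None = None


@dataclass
class SimulationConfig:
    n_breeds: int = 5
    n_per_breed: tuple[int, ...] | None = None  # default: 50 each
    n_chromosomes: int = 5
    n_markers_per_chromosome: int = 200
    chrom_length_bp: int = 100_000_000
    f_background: float = 0.1
    selected_blocks: tuple[SelectedBlock, ...] = ()
    maf_floor: float = 0.05
    missing_rate: float = 0.0
    n_hwe_violating_markers: int = 0
    admixture_alpha: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_breed is None:
            self.n_per_breed = tuple([50] * self.n_breeds)
        self.n_per_breed = tuple(self.n_per_breed)
        if len(self.n_per_breed) != self.n_breeds:
            raise ValueError("n_per_breed length must equal n_breeds")
        if not 0.0 < self.f_background < 1.0:
            raise ValueError("f_background must be in (0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0,0.5)")
        for blk in self.selected_blocks:
            if not 1 <= blk.chromosome <= self.n_chromosomes:
                raise ValueError(f"block chromosome {blk.chromosome} out of range")
            if blk.start_index < 0 or (
                blk.start_index + blk.n_snps > self.n_markers_per_chromosome
            ):
                raise ValueError("selected block exceeds chromosome bounds")
            if not 0.0 < blk.f_selected < 1.0:
                raise ValueError("f_selected must be in (0,1)")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.n_markers_per_chromosome

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_breed))


@dataclass
class TruthLabels:
    """Generator-side truth emitted alongside the panel."""

    ancestral_freq: np.ndarray          # (n_markers,)
    breed_freq: np.ndarray              # (n_breeds, n_markers)
    selected: np.ndarray                # (n_markers,) bool
    hwe_violating: np.ndarray           # (n_markers,) bool
    breed_of_sample: np.ndarray         # (n_samples,) str
    admixture_q: np.ndarray | None = None  # (n_samples, n_breeds)


def _breed_names(k: int) -> list[str]:
    return [f"BREED{i + 1}" for i in range(k)]


def _marker_scaffold(cfg: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers on each chromosome (spacing = length/n)."""
    ids, chroms, pos = [], [], []
    spacing = cfg.chrom_length_bp // (cfg.n_markers_per_chromosome + 1)
    for c in range(1, cfg.n_chromosomes + 1):
        for j in range(cfg.n_markers_per_chromosome):
            ids.append(f"snp_{c}_{j + 1}")
            chroms.append(str(c))
            pos.append((j + 1) * spacing)
    n = len(ids)
    return _new_marker_map(ids, chroms, pos, ["A"] * n, ["C"] * n)


def _drift_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ancestral and per-breed frequencies; marks selected loci."""
    L = cfg.n_markers
    p = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=L)
    f = np.full((cfg.n_breeds, L), cfg.f_background)
    selected = np.zeros(L, dtype=bool)
    for blk in cfg.selected_blocks:
        lo = (blk.chromosome - 1) * cfg.n_markers_per_chromosome + blk.start_index
        sl = slice(lo, lo + blk.n_snps)
        breeds = (
            range(cfg.n_breeds) if blk.affected_breeds is None else blk.affected_breeds
        )
        for b in breeds:
            f[b, sl] = blk.f_selected
        selected[sl] = True
    a = p[None, :] * (1.0 - f) / f
    b = (1.0 - p)[None, :] * (1.0 - f) / f
    breed_freq = rng.beta(a, b)
    # guard against exact fixation from beta underflow
    eps = 1e-12
    breed_freq = np.clip(breed_freq, eps, 1.0 - eps)
    return p, breed_freq, selected


def _apply_missingness(
    dosage: np.ndarray, rate: float, rng: np.random.Generator
) -> None:
    if rate > 0:
        mask = rng.random(dosage.shape) < rate
        dosage[mask] = MISSING


def simulate_panel(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthLabels]:
    """Draw a structured multi-breed panel; reproducible from ``cfg.seed``.

    Genotypes are ``Binomial(2, p_breed)`` (HWE within breed).  HWE
    violations are planted by forcing every call heterozygous in the
    first breed at ``n_hwe_violating_markers`` non-selected loci.
    """
    rng = np.random.default_rng(cfg.seed)
    mm = _marker_scaffold(cfg)
    p, breed_freq, selected = _drift_frequencies(cfg, rng)
    names = _breed_names(cfg.n_breeds)

    rows = []
    breeds = []
    sample_ids = []
    for b, (name, n_b) in enumerate(zip(names, cfg.n_per_breed)):
        g = rng.binomial(2, breed_freq[b], size=(n_b, cfg.n_markers)).astype(np.int8)
        rows.append(g)
        breeds.extend([name] * n_b)
        sample_ids.extend(f"{name}_{i + 1}" for i in range(n_b))
    dosage = np.concatenate(rows, axis=0)

    hwe_violating = np.zeros(cfg.n_markers, dtype=bool)
    if cfg.n_hwe_violating_markers > 0:
        candidates = np.flatnonzero(~selected)
        if len(candidates) < cfg.n_hwe_violating_markers:
            raise ValueError("not enough non-selected loci for HWE violations")
        viol = rng.choice(candidates, size=cfg.n_hwe_violating_markers, replace=False)
        hwe_violating[viol] = True
        dosage[: cfg.n_per_breed[0], viol] = 1  # all-heterozygote in breed 1

    _apply_missingness(dosage, cfg.missing_rate, rng)

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        breeds=np.array(breeds, dtype=object),
        marker_map=mm,
        dosage=dosage,
    )
    truth = TruthLabels(
        ancestral_freq=p,
        breed_freq=breed_freq,
        selected=selected,
        hwe_violating=hwe_violating,
        breed_of_sample=np.array(breeds, dtype=object),
    )
    return gm, truth


def simulate_admixed(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthLabels]:
    """Panel of admixed individuals: Q ~ Dirichlet(alpha), copies drawn
    from the ancestry-weighted breed frequencies."""
    if cfg.admixture_alpha is None:
        raise ValueError("admixture_alpha must be set for simulate_admixed")
    rng = np.random.default_rng(cfg.seed)
    mm = _marker_scaffold(cfg)
    p, breed_freq, selected = _drift_frequencies(cfg, rng)

    n = cfg.n_samples
    K = cfg.n_breeds
    q = rng.dirichlet([cfg.admixture_alpha] * K, size=n)  # (n, K)
    # per-copy allele frequency given ancestry mixture
    f_mix = q @ breed_freq  # (n, L)
    dosage = (
        (rng.random(f_mix.shape) < f_mix).astype(np.int8)
        + (rng.random(f_mix.shape) < f_mix).astype(np.int8)
    )
    _apply_missingness(dosage, cfg.missing_rate, rng)

    major = np.argmax(q, axis=1)
    names = _breed_names(K)
    breeds = np.array([names[k] for k in major], dtype=object)
    sample_ids = [f"ADM_{i + 1}" for i in range(n)]
    gm = GenotypeMatrix(
        sample_ids=sample_ids, breeds=breeds, marker_map=mm, dosage=dosage
    )
    truth = TruthLabels(
        ancestral_freq=p,
        breed_freq=breed_freq,
        selected=selected,
        hwe_violating=np.zeros(cfg.n_markers, dtype=bool),
        breed_of_sample=breeds,
        admixture_q=q,
    )
    return gm, truth


def expected_gst(f: float, s: int) -> float:
    """Closed-form expected fixation index for ``s`` equal drift-``f`` breeds."""
    return f * (1.0 - 1.0 / s) / (1.0 - f / s)
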