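"""Genomic kinship, kinship-derived distances, and classical MDS.

Kinship is the allele-frequency-standardised estimator

    k_ij = (1/L_ij) * sum_l (x_il - 2 p_l)(x_jl - 2 p_l) / (4 p_l (1 - p_l))

over the markers where both genotypes are called (per-pair L_ij), with
``p_l`` the pooled allele frequency.  Self-kinship is ~0.5(1+F) and so
close to 0.5 for outbred samples, which makes ``d_ij = 0.5 - k_ij`` an
approximately zero-diagonal distance suitable for Torgerson classical
scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    k: np.ndarray
    n_markers_used: int

    def __post_init__(self) -> None:
        if not np.allclose(self.k, self.k.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.k, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    coordinates: np.ndarray     # (n, n_components)
    eigenvalues: np.ndarray     # all eigenvalues, descending
    n_negative_dropped: int

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def to_dataframe(self, breeds=None) -> pd.DataFrame:
        cols = {f"C{i + 1}": self.coordinates[:, i] for i in range(self.n_components)}
        df = pd.DataFrame({"sample_id": self.sample_ids, **cols})
        if breeds is not None:
            df.insert(1, "breed", list(breeds))
        return df


def genomic_kinship(
    gm: GenotypeMatrix, complete_cases_only: bool = False
) -> KinshipMatrix:
    """Frequency-standardised kinship from the dosage matrix.

    Monomorphic markers carry no information and are skipped.  With
    ``complete_cases_only`` markers with any missing call are dropped
    globally (exact reproducibility across pair subsets); the default
    uses pairwise-complete markers.
    """
    if gm.n_samples < 2:
        raise ValueError(">=2 samples required")
    obs = gm.dosage != MISSING
    if complete_cases_only:
        keep = obs.all(axis=0)
        obs = obs[:, keep]
        dosage = gm.dosage[:, keep]
    else:
        dosage = gm.dosage
    x = np.where(obs, dosage, 0).astype(float)
    n_alleles = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, x.sum(axis=0) / n_alleles, np.nan)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic markers for kinship")
    x = x[:, poly]
    obs = obs[:, poly]
    p = p[poly]

    z = (x - 2.0 * p) / np.sqrt(4.0 * p * (1.0 - p))
    z = np.where(obs, z, 0.0)
    num = z @ z.T
    denom = obs.astype(float) @ obs.T.astype(float)
    if (denom == 0).any():
        i, j = np.argwhere(denom == 0)[0]
        raise ValueError(
            f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share "
            "no non-missing marker"
        )
    k = num / denom
    k = 0.5 * (k + k.T)  # exact symmetry against fp noise
    return KinshipMatrix(
        sample_ids=list(gm.sample_ids), k=k, n_markers_used=int(poly.sum())
    )


def kinship_to_distance(km: KinshipMatrix) -> np.ndarray:
    """Elementwise ``d = 0.5 - k``; negative entries preserved (logged)."""
    d = 0.5 - km.k
    off = d[~np.eye(len(d), dtype=bool)]
    n_neg = int((off < 0).sum())
    if n_neg:
        logger.info("kinship_to_distance: %d negative off-diagonal distances", n_neg)
    return d


def classical_mds(
    distance_matrix: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, int]:
    """Torgerson scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns
    ``(coordinates, eigenvalues_desc, n_negative)``.  Components beyond
    the number of positive eigenvalues are truncated with a warning.
    Column signs are fixed so the first nonzero loading is positive.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        warnings.warn("distance matrix not symmetric; symmetrising", stacklevel=2)
    D = 0.5 * (D + D.T)
    if np.abs(np.diag(D)).max() > 1e-8:
        warnings.warn("nonzero diagonal in distance matrix; resetting", stacklevel=2)
    np.fill_diagonal(D, 0.0)

    D2 = D**2
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    grand = D2.mean()
    B = -0.5 * (D2 - row - col + grand)
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]

    tol = max(abs(w[0]), abs(w[-1]), 1.0) * 1e-12
    n_pos = int((w > tol).sum())
    n_neg = int((w < -tol).sum())
    k = min(n_components, n_pos)
    if k < n_components:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k} components",
            stacklevel=2,
        )
    coords = V[:, :k] * np.sqrt(np.maximum(w[:k], 0.0))
    # deterministic sign: first loading of magnitude > tol made positive
    for c in range(k):
        col_v = coords[:, c]
        nz = np.flatnonzero(np.abs(col_v) > 1e-12)
        if nz.size and col_v[nz[0]] < 0:
            coords[:, c] = -col_v
    return coords, w, n_neg


def mds_embedding(
    gm: GenotypeMatrix, n_components: int = 3, complete_cases_only: bool = False
) -> tuple[EmbeddingResult, KinshipMatrix]:
    """Convenience: kinship -> 0.5-k distance -> classical MDS."""
    km = genomic_kinship(gm, complete_cases_only=complete_cases_only)
    d = kinship_to_distance(km)
    # self-distance 0.5 - k_ii is only approximately zero; reset it
    # explicitly so classical_mds need not warn about the expected case
    np.fill_diagonal(d, 0.0)
    coords, eig, n_neg = classical_mds(d, n_components)
    emb = EmbeddingResult(
        sample_ids=list(gm.sample_ids),
        coordinates=coords,
        eigenvalues=eig,
        n_negative_dropped=n_neg,
    )
    return emb, km


def cluster_geometry(
    embedding: EmbeddingResult, breed_labels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-breed centroids and all pairwise centre distances.

    Returns ``(centres, distances)``: centres indexed by breed (plus the
    global centre of mass as ``__CENTRE__``), distances as a long table
    ``(from, to, distance)`` over all centre pairs including the global
    centre.
    """
    breeds = np.asarray(breed_labels, dtype=object)
    if len(breeds) != len(embedding.sample_ids):
        raise ValueError("breed labels length mismatch")
    coords = embedding.coordinates
    names = list(dict.fromkeys(breeds))
    centres = {b: coords[breeds == b].mean(axis=0) for b in names}
    centres["__CENTRE__"] = coords.mean(axis=0)

    centre_df = pd.DataFrame(
        {b: c for b, c in centres.items()},
        index=[f"C{i + 1}" for i in range(coords.shape[1])],
    ).T
    centre_df.index.name = "cluster"

    rows = []
    labels = list(centres)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "distance": float(np.linalg.norm(centres[a] - centres[b])),
                }
            )
    return centre_df, pd.DataFrame(rows, columns=["from", "to", "distance"])
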