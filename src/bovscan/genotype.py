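"""Genotype data model and PLINK text I/O.

The central currency of the package is :class:`GenotypeMatrix`: a
samples x markers diploid dosage matrix (values 0/1/2 counting copies of
``allele_b``, or :data:`MISSING`), a per-sample breed label, and a marker
map (chromosome, 1-based bp position, alleles).

PLINK text ``.ped``/``.map`` is the normative interchange format; the
breed label travels in the family-ID column, as is common practice for
breed panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Cattle autosome labels ("1".."29"); the default for autosome restriction.
CATTLE_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 30))

_VALID_ALLELES = frozenset("ACGT0")

_MAP_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]


class FormatError(ValueError):
    """Raised on malformed .ped/.map input; message names the offending line."""


def _new_marker_map(
    marker_id: Sequence[str],
    chromosome: Sequence[str],
    position_bp: Sequence[int],
    allele_a: Sequence[str],
    allele_b: Sequence[str],
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "marker_id": list(marker_id),
            "chromosome": [str(c) for c in chromosome],
            "position_bp": np.asarray(position_bp, dtype=np.int64),
            "allele_a": list(allele_a),
            "allele_b": list(allele_b),
        }
    )
    return df


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a multi-breed panel.

    Attributes
    ----------
    sample_ids :
        Ordered unique sample identifiers.
    breeds :
        Per-sample breed label, aligned with ``sample_ids``.
    marker_map :
        DataFrame with columns ``marker_id, chromosome, position_bp,
        allele_a, allele_b``; within a chromosome markers are sorted by
        position.
    dosage :
        ``(n_samples, n_markers)`` int8 array with values in
        ``{0, 1, 2, MISSING}`` counting copies of ``allele_b``.
    """

    sample_ids: list[str]
    breeds: np.ndarray
    marker_map: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.breeds = np.asarray(self.breeds, dtype=object)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.dtype != np.int8:
            self.dosage = self.dosage.astype(np.int8)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"dosage has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if len(self.breeds) != n:
            raise ValueError("breed label missing for some samples")
        if len(self.marker_map) != m:
            raise ValueError(
                f"dosage has {m} columns but map has {len(self.marker_map)} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids not unique")
        if self.marker_map["marker_id"].duplicated().any():
            raise ValueError("marker_ids not unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,MISSING}")
        # positions non-decreasing within each chromosome
        mm = self.marker_map
        for chrom, grp in mm.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"markers on chromosome {chrom} not sorted by bp")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def breed_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(b, None)
        return list(seen)

    def breed_indices(self) -> dict[str, np.ndarray]:
        """Map breed label -> sample row indices (order of first appearance)."""
        return {b: np.flatnonzero(self.breeds == b) for b in self.breed_names}

    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        marker_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            breeds=self.breeds[si],
            marker_map=self.marker_map.iloc[mi].reset_index(drop=True),
            dosage=self.dosage[np.ix_(si, mi)],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            breeds=self.breeds.copy(),
            marker_map=self.marker_map.copy(),
            dosage=self.dosage.copy(),
        )


# ---------------------------------------------------------------------------
# PLINK text reading
# ---------------------------------------------------------------------------

def _read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns "
                    f"(chrom, id, cM, bp), got {len(parts)}"
                )
            chrom, mid, _cm, bp = parts
            try:
                bp_i = int(bp)
            except ValueError as exc:
                raise FormatError(
                    f"{map_path}:{lineno}: non-integer bp position {bp!r}"
                ) from exc
            rows.append((mid, chrom, bp_i))
    if not rows:
        raise FormatError(f"{map_path}: empty map file")
    ids, chroms, bps = zip(*rows)
    return _new_marker_map(ids, chroms, bps, ["0"] * len(ids), ["0"] * len(ids))


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text ``.ped``/``.map`` pair into a :class:`GenotypeMatrix`.

    The family-ID column of the ``.ped`` is interpreted as the breed
    label.  ``0 0`` allele pairs become :data:`MISSING`.  Per marker, the
    lexicographically later observed allele is counted as ``allele_b``
    (so dosage is the count of that allele); both alleles are recorded
    in the returned marker map.
    """
    mm = _read_map(map_path)
    n_markers = len(mm)
    sample_ids: list[str] = []
    breeds: list[str] = []
    allele_rows: list[np.ndarray] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            expected = 6 + 2 * n_markers
            if len(parts) != expected:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {expected} fields "
                    f"(6 + 2 x {n_markers} markers), got {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            alleles = np.array(parts[6:], dtype="U1")
            bad = ~np.isin(alleles, list(_VALID_ALLELES))
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{ped_path}:{lineno}: invalid allele character "
                    f"{parts[6 + j]!r} (allowed: A,C,G,T,0)"
                )
            breeds.append(fam)
            sample_ids.append(iid)
            allele_rows.append(alleles)

    if not allele_rows:
        raise FormatError(f"{ped_path}: empty ped file")

    A = np.stack(allele_rows)  # (n_samples, 2*n_markers)
    a1 = A[:, 0::2]
    a2 = A[:, 1::2]
    half_missing = (a1 == "0") != (a2 == "0")
    if half_missing.any():
        i, j = np.argwhere(half_missing)[0]
        raise FormatError(
            f"{ped_path}: sample {sample_ids[i]!r}, marker {j + 1}: "
            "half-missing genotype (exactly one allele '0')"
        )
    missing = a1 == "0"

    dosage = np.full((len(sample_ids), n_markers), MISSING, dtype=np.int8)
    allele_a = []
    allele_b = []
    for j in range(n_markers):
        col = np.concatenate([a1[:, j], a2[:, j]])
        observed = sorted(set(col[col != "0"]))
        if len(observed) > 2:
            raise FormatError(
                f"{ped_path}: marker {mm['marker_id'].iat[j]!r} has "
                f"{len(observed)} alleles; only biallelic markers supported"
            )
        if len(observed) == 0:
            allele_a.append("0")
            allele_b.append("0")
            continue
        if len(observed) == 1:
            aa, bb = observed[0], "0"
        else:
            aa, bb = observed  # lexicographic: later allele is allele_b
        allele_a.append(aa)
        allele_b.append(bb)
        ok = ~missing[:, j]
        dosage[ok, j] = (a1[ok, j] == bb).astype(np.int8) + (
            a2[ok, j] == bb
        ).astype(np.int8)

    mm = mm.copy()
    mm["allele_a"] = allele_a
    mm["allele_b"] = allele_b
    return GenotypeMatrix(
        sample_ids=sample_ids, breeds=np.array(breeds, dtype=object),
        marker_map=mm, dosage=dosage,
    )


def write_plink_text(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> tuple[Path, Path]:
    """Write a :class:`GenotypeMatrix` as PLINK text files.

    Missing dosages become ``0 0``.  For markers whose ``allele_b`` is
    unknown (monomorphic), a placeholder allele is emitted so the file
    stays parseable.
    """
    if gm.n_samples == 0 or gm.n_markers == 0:
        raise ValueError("refusing to write empty genotype matrix")
    ped_path, map_path = Path(ped_path), Path(map_path)
    mm = gm.marker_map
    with open(map_path, "w") as fh:
        for row in mm.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")

    aa = mm["allele_a"].to_numpy(dtype="U1")
    bb = mm["allele_b"].to_numpy(dtype="U1")
    # placeholder for unknown alleles: monomorphic dosage never references them
    aa = np.where(aa == "0", "A", aa)
    bb = np.where(bb == "0", "C", bb)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            d = gm.dosage[i]
            first = np.where(d >= 1, bb, aa)
            second = np.where(d == 2, bb, aa)
            miss = d == MISSING
            first = np.where(miss, "0", first)
            second = np.where(miss, "0", second)
            pairs = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"{gm.breeds[i]} {sid} 0 0 0 -9 {pairs}\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Autosome restriction
# ---------------------------------------------------------------------------

def restrict_autosomes(
    gm: GenotypeMatrix,
    autosome_labels: Iterable[str] = CATTLE_AUTOSOMES,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop markers off the autosomes or without a mapped position.

    Returns the restricted matrix and a report
    ``{"non_autosomal": n, "no_position": n}``.  A marker failing both
    criteria is counted as non-autosomal.  Raises if nothing survives.
    """
    labels = set(str(a) for a in autosome_labels)
    chrom = gm.marker_map["chromosome"].astype(str).to_numpy()
    pos = gm.marker_map["position_bp"].to_numpy()
    non_auto = ~np.isin(chrom, list(labels))
    no_pos = (pos <= 0) & ~non_auto
    keep = ~(non_auto | no_pos)
    report = {"non_autosomal": int(non_auto.sum()), "no_position": int(no_pos.sum())}
    if not keep.any():
        raise ValueError("empty panel: all markers removed by autosome restriction")
    if keep.all():
        return gm, report
    return gm.subset(marker_idx=np.flatnonzero(keep)), report
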