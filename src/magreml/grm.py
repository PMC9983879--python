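"""Genomic relatedness matrices (GRMs).

A GRM summarizes genome-wide genetic similarity between individuals as the
average cross-product of standardized SNP dosages,

    A[j, k] = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with ``p_i`` the allele frequency of SNP ``i`` and ``m`` the number of SNPs
contributing to the pair.  In the variance-component models of this package
the GRM is the covariance model of the latent additive-genetic factors across
individuals.

This module builds GRMs from dosage matrices, prunes close relatives at a
relatedness cutoff, extracts principal components used as fixed-effect
covariates against population stratification, and reads/writes the GCTA
binary triplet (``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``).
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import scipy.linalg

SampleID = tuple[str, str]
"""A sample key: (family ID, individual ID)."""


def _as_sample_ids(ids: Sequence) -> list[SampleID]:
    out = []
    for s in ids:
        if isinstance(s, str):
            out.append(("0", s))
        else:
            fid, iid = s
            out.append((str(fid), str(iid)))
    if len(set(out)) != len(out):
        raise ValueError("sample IDs must be unique")
    return out


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with allele counts in {0, 1, 2}.

    Missing dosages are encoded as NaN.  ``allele_freqs`` are computed from
    the data (missing values ignored, which equals mean imputation for the
    frequency) unless supplied.
    """

    dosages: np.ndarray
    sample_ids: list[SampleID]
    snp_ids: list[str]
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = _as_sample_ids(self.sample_ids)
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP IDs must be unique")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage matrix is {n}x{m} but there are "
                f"{len(self.sample_ids)} sample IDs and {len(self.snp_ids)} SNP IDs"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if self.allele_freqs is None:
            with np.errstate(invalid="ignore"):
                self.allele_freqs = np.nanmean(self.dosages, axis=0) / 2.0
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (m,):
                raise ValueError("allele_freqs must have one entry per SNP")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclasses.dataclass
class GRM:
    """Symmetric n x n genomic relatedness matrix with sample IDs.

    ``n_snps_per_pair`` (optional) counts the non-missing SNPs used for each
    pair, matching the semantics of GCTA's ``.grm.N.bin``.
    """

    values: np.ndarray
    sample_ids: list[SampleID]
    n_snps_per_pair: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_sample_ids(self.sample_ids)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square and match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices: Sequence[int]) -> "GRM":
        idx = np.asarray(indices, dtype=int)
        npp = self.n_snps_per_pair
        return GRM(
            values=self.values[np.ix_(idx, idx)],
            sample_ids=[self.sample_ids[i] for i in idx],
            n_snps_per_pair=None if npp is None else npp[np.ix_(idx, idx)],
        )

    def reorder(self, ids: Sequence[SampleID]) -> "GRM":
        """Subset/reorder to the given sample IDs (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[_as_sample_ids([s])[0]] for s in ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]} not in GRM") from None
        return self.subset(idx)


def compute_grm(geno: GenotypeMatrix, per_pair_counts: bool = True) -> GRM:
    """Build the GRM from a dosage matrix.

    SNPs with allele frequency 0 or 1 are excluded (zero variance).  Missing
    dosages contribute nothing to a pair's sum; with ``per_pair_counts`` each
    pair's sum is divided by that pair's non-missing SNP count, otherwise by
    the global SNP count.
    """
    p = geno.allele_freqs
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    X = geno.dosages[:, poly]
    p = p[poly]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    miss = np.isnan(Z)
    m = Z.shape[1]
    if not miss.any():
        S = Z @ Z.T
        N = np.full((Z.shape[0], Z.shape[0]), float(m))
    else:
        Z[miss] = 0.0
        S = Z @ Z.T
        obs = (~miss).astype(float)
        N = np.rint(obs @ obs.T)
    if per_pair_counts:
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(N > 0, S / np.maximum(N, 1), 0.0)
    else:
        A = S / m
    A = 0.5 * (A + A.T)
    return GRM(values=A, sample_ids=geno.sample_ids, n_snps_per_pair=N.astype(int))


def prune_related(
    grm: GRM,
    threshold: float = 0.025,
    n_missing: Sequence[int] | None = None,
) -> tuple[GRM, list[SampleID]]:
    """Greedily remove individuals until no off-diagonal entry exceeds ``threshold``.

    At each step the individual participating in the most above-threshold
    pairs is removed (ties broken towards more missing phenotypes, then the
    larger sample index).  Near-minimal removal; idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = grm.n
    miss = np.zeros(n) if n_missing is None else np.asarray(n_missing, dtype=float)
    adj = grm.values > threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    removed: list[int] = []
    deg = adj.sum(axis=1).astype(float)
    while True:
        dmax = deg[alive].max(initial=0.0)
        if dmax <= 0:
            break
        # tie-break: degree desc, then missing phenotypes desc, then index desc
        cand = np.flatnonzero(alive & (deg == dmax))
        cand = cand[miss[cand] == miss[cand].max()]
        drop = int(cand.max())
        alive[drop] = False
        removed.append(drop)
        nbrs = np.flatnonzero(adj[drop])
        deg[nbrs] -= 1
        deg[drop] = 0
        adj[drop, :] = False
        adj[:, drop] = False
    kept = np.flatnonzero(alive)
    return grm.subset(kept), [grm.sample_ids[i] for i in removed]


def grm_pcs(grm: GRM, k: int = 20) -> np.ndarray:
    """Top-``k`` eigenvectors of the GRM, for use as fixed-effect covariates.

    Columns are unit-norm, ordered by decreasing eigenvalue, with a fixed
    sign convention (the largest-magnitude entry of each column is positive).
    """
    n = grm.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    w, V = scipy.linalg.eigh(
        grm.values, subset_by_index=(n - k, n - 1), driver="evr"
    )
    V = V[:, ::-1]  # descending eigenvalue order
    for j in range(k):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


# ---------------------------------------------------------------------------
# GCTA binary triplet I/O
# ---------------------------------------------------------------------------

def write_grm_gcta(grm: GRM, prefix: str) -> None:
    """Write ``prefix.grm.bin``, ``prefix.grm.N.bin`` and ``prefix.grm.id``.

    Binary files hold the lower triangle (including the diagonal) row-wise as
    little-endian float32.
    """
    n = grm.n
    rows, cols = np.tril_indices(n)
    grm.values[rows, cols].astype("<f4").tofile(prefix + ".grm.bin")
    if grm.n_snps_per_pair is not None:
        counts = grm.n_snps_per_pair[rows, cols].astype("<f4")
    else:
        counts = np.ones(len(rows), dtype="<f4")
    counts.tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for fid, iid in grm.sample_ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm_gcta(prefix: str) -> GRM:
    """Read a GCTA GRM triplet written by :func:`write_grm_gcta` (or GCTA)."""
    with open(prefix + ".grm.id") as fh:
        ids = [tuple(line.split()[:2]) for line in fh if line.strip()]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if len(tri) != expected:
        raise ValueError(
            f"{prefix}.grm.id lists {n} samples (triangle length {expected}) "
            f"but {prefix}.grm.bin holds {len(tri)} values"
        )
    rows, cols = np.tril_indices(n)
    A = np.zeros((n, n))
    A[rows, cols] = tri
    A[cols, rows] = tri
    npath = prefix + ".grm.N.bin"
    counts = None
    if os.path.exists(npath):
        ntri = np.fromfile(npath, dtype="<f4")
        if len(ntri) == expected:
            counts = np.zeros((n, n))
            counts[rows, cols] = ntri
            counts[cols, rows] = ntri
            counts = np.rint(counts).astype(int)
    return GRM(values=A, sample_ids=ids, n_snps_per_pair=counts)


# ---------------------------------------------------------------------------
# Plain-text genotype I/O
# ---------------------------------------------------------------------------

def write_genotypes_text(geno: GenotypeMatrix, path: str) -> None:
    """Write the canonical text format: header ``FID IID <snp ids>``, one row
    per individual, ``NA`` for missing."""
    with open(path, "w") as fh:
        fh.write("FID\tIID\t" + "\t".join(geno.snp_ids) + "\n")
        for (fid, iid), row in zip(geno.sample_ids, geno.dosages):
            vals = "\t".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{fid}\t{iid}\t{vals}\n")


def read_genotypes_text(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError(f"{path}: empty file")
        if [h.upper() for h in header[:2]] == ["FID", "IID"]:
            snp_ids = header[2:]
        else:
            snp_ids = header
        ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(snp_ids) + 2:
                raise ValueError(
                    f"{path}:{ln}: expected FID IID and {len(snp_ids)} dosages, "
                    f"got {len(parts)} fields"
                )
            ids.append((parts[0], parts[1]))
            rows.append([np.nan if v == "NA" else float(v) for v in parts[2:]])
    return GenotypeMatrix(np.array(rows, dtype=float), ids, snp_ids)
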