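"""Core in-memory containers.

Genotypes are held as an ALT-allele dosage matrix (samples x SNPs) with
``numpy.nan`` marking missing calls; all positions are 1-based as in VCF.
Sample metadata and trait observations are plain pandas DataFrames with
documented column schemas (see :mod:`dioecy.tables`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError

#: columns required of the per-SNP metadata frame
SNP_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Diploid ALT-dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_snps)
        ALT-allele counts in {0, 1, 2}; ``nan`` for missing calls.
    snps : DataFrame
        One row per SNP with columns ``chrom, pos, id, ref, alt``.
    samples : list of str
        Ordered, unique sample identifiers.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise StructuralError("dosages must be 2-D (samples x snps)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise StructuralError(
                f"{len(self.samples)} sample ids for {n} dosage rows"
            )
        if len(self.snps) != m:
            raise StructuralError(f"{len(self.snps)} SNP rows for {m} dosage columns")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise StructuralError(f"snps frame lacks columns {missing_cols}")
        if len(set(self.samples)) != n:
            raise StructuralError("sample ids are not unique")
        if (self.snps["pos"] < 1).any():
            raise StructuralError("VCF positions are 1-based; pos < 1 found")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise StructuralError("dosages must be 0, 1, 2 or nan")
        key = self.snps[["chrom", "pos", "alt"]]
        if key.duplicated().any():
            raise StructuralError("duplicate SNP (chrom, pos, alt) records")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, index) -> "GenotypeMatrix":
        """Subset to SNPs selected by a boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
        )

    def take_samples(self, ids) -> "GenotypeMatrix":
        """Subset to the given sample ids, in the given order."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [lookup[s] for s in ids]
        except KeyError as exc:
            raise StructuralError(f"unknown sample id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            dosages=self.dosages[rows, :],
            snps=self.snps.copy(),
            samples=list(ids),
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)
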