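"""Genotype panel container shared by the simulation and analysis layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: colour genotype labels indexed by T-allele dosage at the causal locus
COLOUR_GENOTYPES = np.array(["CC", "TC", "TT"])


@dataclass
class GenotypePanel:
    """Individuals × SNPs dosage matrix with a marker map.

    Dosages count copies of the alternate allele (0/1/2); missing calls are
    ``NaN``.  The marker map is a DataFrame with columns ``scaffold``,
    ``pos`` (0-based, half-open convention; written 1-based to MAP/VCF),
    ``snp_id``, ``a1`` (reference) and ``a2`` (alternate).  ``causal_index``
    marks the colour locus, where the alternate allele is the dominant
    blue allele T.
    """

    dosage: np.ndarray
    marker_map: pd.DataFrame
    ids: np.ndarray
    causal_index: int | None = None
    colour_genotype: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals × SNPs)")
        if len(self.marker_map) != self.dosage.shape[1]:
            raise ValueError("marker map length does not match dosage columns")
        if len(self.ids) != self.dosage.shape[0]:
            raise ValueError("id vector length does not match dosage rows")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for _, grp in self.marker_map.groupby("scaffold", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("map positions must be strictly increasing within a scaffold")
        if self.causal_index is not None and self.colour_genotype is None:
            d = self.dosage[:, self.causal_index]
            if np.isnan(d).any():
                raise ValueError("causal locus may not have missing calls")
            self.colour_genotype = COLOUR_GENOTYPES[d.astype(int)]
        if self.colour_genotype is not None and self.causal_index is not None:
            d = self.dosage[:, self.causal_index]
            ok = ~np.isnan(d)
            if not (COLOUR_GENOTYPES[d[ok].astype(int)] == np.asarray(self.colour_genotype)[ok]).all():
                raise ValueError("colour genotype inconsistent with causal dosage")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_markers(self, index) -> "GenotypePanel":
        """Panel restricted to the given marker indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        causal = None
        if self.causal_index is not None:
            hits = np.flatnonzero(index == self.causal_index)
            causal = int(hits[0]) if hits.size else None
        return GenotypePanel(
            dosage=self.dosage[:, index],
            marker_map=self.marker_map.iloc[index].reset_index(drop=True),
            ids=self.ids,
            causal_index=causal,
            colour_genotype=self.colour_genotype,
        )

    def subset_individuals(self, mask_or_ids) -> "GenotypePanel":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            rows = np.flatnonzero(arr)
        else:
            lookup = {v: i for i, v in enumerate(self.ids)}
            rows = np.array([lookup[v] for v in arr], dtype=int)
        colour = None if self.colour_genotype is None else np.asarray(self.colour_genotype)[rows]
        return GenotypePanel(
            dosage=self.dosage[rows],
            marker_map=self.marker_map,
            ids=np.asarray(self.ids)[rows],
            causal_index=self.causal_index,
            colour_genotype=colour,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing ignored)."""
        return np.nanmean(self.dosage, axis=0) / 2.0
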