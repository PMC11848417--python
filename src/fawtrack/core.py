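"""Shared containers for genotype data.

The central object is :class:`GenotypeMatrix`: individuals × biallelic
loci, storing alternate-allele dosages (0/1/2, NaN = missing call),
per-genotype read depths, and a sample → population map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with population labels.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    loci : list of (str, int)
        Ordered (chrom, pos) keys, 1-based VCF coordinates (columns).
    dosages : ndarray, shape (n_samples, n_loci), float
        Alternate-allele counts in {0, 1, 2}; NaN marks a missing call.
    depths : ndarray or None, same shape
        Per-genotype read depth.
    pop_labels : dict
        sample → population. Samples absent from the map are retained
        but excluded from population-level statistics.
    """

    samples: list[str]
    loci: list[tuple[str, int]]
    dosages: np.ndarray
    depths: np.ndarray | None = None
    pop_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.dosages.shape:
                raise ValueError("depths shape does not match dosages")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return ~np.isnan(self.dosages)

    def populations(self) -> list[str]:
        """Distinct population labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            if s in self.pop_labels:
                seen.setdefault(self.pop_labels[s], None)
        return list(seen)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def pop_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples labelled *population*."""
        idx = [
            i
            for i, s in enumerate(self.samples)
            if self.pop_labels.get(s) == population
        ]
        if not idx:
            raise KeyError(f"unknown population {population!r}")
        return np.asarray(idx, dtype=int)

    # -- subsetting ------------------------------------------------------

    def take_samples(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        samples = [self.samples[i] for i in indices]
        return GenotypeMatrix(
            samples=samples,
            loci=list(self.loci),
            dosages=self.dosages[indices].copy(),
            depths=None if self.depths is None else self.depths[indices].copy(),
            pop_labels={s: self.pop_labels[s] for s in samples if s in self.pop_labels},
        )

    def take_loci(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in indices],
            dosages=self.dosages[:, indices].copy(),
            depths=None if self.depths is None else self.depths[:, indices].copy(),
            pop_labels=dict(self.pop_labels),
        )
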