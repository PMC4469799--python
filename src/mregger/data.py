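"""Containers for per-variant GWAS summary statistics.

The unit of analysis is one genetic variant's pair of association estimates:
with the exposure (beta_exposure, ``gamma_hat``) and with the outcome
(beta_outcome, ``Gamma_hat``), each with a standard error.  An
:class:`MRDataset` is an ordered collection of such variants; every estimator
in :mod:`mregger.estimators` consumes an ``MRDataset``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["VariantAssociation", "MRDataset", "orient"]


@dataclass(frozen=True)
class VariantAssociation:
    """Summary statistics for a single genetic variant.

    Parameters
    ----------
    variant_id
        Opaque label (e.g. an rsID).
    beta_exposure
        Per-allele association with the exposure (gamma_hat_j).
    se_exposure
        Standard error of ``beta_exposure``; must be positive.
    beta_outcome
        Per-allele association with the outcome (Gamma_hat_j).
    se_outcome
        Standard error of ``beta_outcome`` (sigma_Yj); must be positive.
    eaf
        Effect-allele frequency, strictly in (0, 1), or ``None`` if unknown.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta_exposure) or not np.isfinite(self.beta_outcome):
            raise ValueError(f"{self.variant_id}: non-finite association estimate")
        if not (self.se_exposure > 0):
            raise ValueError(
                f"{self.variant_id}: se_exposure must be positive, got {self.se_exposure}"
            )
        if not (self.se_outcome > 0):
            raise ValueError(
                f"{self.variant_id}: se_outcome must be positive, got {self.se_outcome}"
            )
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(
                f"{self.variant_id}: eaf must lie strictly in (0, 1), got {self.eaf}"
            )


@dataclass(frozen=True)
class MRDataset:
    """Ordered collection of variant associations plus orientation state.

    ``oriented`` is True once all variants have been recoded so that every
    association with the exposure is non-negative (the canonical allele
    orientation required by MR-Egger regression).
    """

    variants: tuple[VariantAssociation, ...]
    oriented: bool = False

    def __post_init__(self) -> None:
        variants = tuple(self.variants)
        object.__setattr__(self, "variants", variants)
        if len(variants) < 1:
            raise ValueError("MRDataset requires at least one variant")
        ids = [v.variant_id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant_ids: {', '.join(dupes)}")
        if self.oriented and any(v.beta_exposure < 0 for v in variants):
            raise ValueError("oriented dataset contains negative beta_exposure")

    # -- sequence protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.variants)

    def __getitem__(self, idx: int) -> VariantAssociation:
        return self.variants[idx]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # -- array views ------------------------------------------------------
    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([v.beta_exposure for v in self.variants])

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([v.se_exposure for v in self.variants])

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([v.beta_outcome for v in self.variants])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([v.se_outcome for v in self.variants])

    @property
    def eaf(self) -> np.ndarray:
        """Effect-allele frequencies as a float array with NaN for missing."""
        return np.array(
            [np.nan if v.eaf is None else v.eaf for v in self.variants], dtype=float
        )

    @property
    def has_eaf(self) -> bool:
        return all(v.eaf is not None for v in self.variants)

    @classmethod
    def from_arrays(
        cls,
        beta_exposure: Sequence[float],
        se_exposure: Sequence[float],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        variant_ids: Sequence[str] | None = None,
        eaf: Sequence[float] | None = None,
        oriented: bool = False,
    ) -> "MRDataset":
        n = len(beta_exposure)
        if variant_ids is None:
            variant_ids = [f"snp_{j + 1}" for j in range(n)]
        variants = tuple(
            VariantAssociation(
                variant_id=str(variant_ids[j]),
                beta_exposure=float(beta_exposure[j]),
                se_exposure=float(se_exposure[j]),
                beta_outcome=float(beta_outcome[j]),
                se_outcome=float(se_outcome[j]),
                eaf=None if eaf is None else float(eaf[j]),
            )
            for j in range(n)
        )
        return cls(variants=variants, oriented=oriented)


def orient(dataset: MRDataset) -> MRDataset:
    """Recode alleles so every association with the exposure is non-negative.

    For each variant with ``beta_exposure < 0``, both ``beta_exposure`` and
    ``beta_outcome`` are sign-flipped (recoding to the exposure-increasing
    allele); standard errors are unchanged and ``eaf`` becomes ``1 - eaf``.
    Variant order is preserved and the returned dataset has ``oriented=True``.

    A variant with ``beta_exposure`` exactly zero carries no orientation
    information: it is left as-is and a warning is emitted.  The operation is
    idempotent.
    """
    out: list[VariantAssociation] = []
    for v in dataset:
        if v.beta_exposure < 0:
            out.append(
                replace(
                    v,
                    beta_exposure=-v.beta_exposure,
                    beta_outcome=-v.beta_outcome,
                    eaf=None if v.eaf is None else 1.0 - v.eaf,
                )
            )
        else:
            if v.beta_exposure == 0:
                warnings.warn(
                    f"variant {v.variant_id} has beta_exposure == 0 and cannot "
                    "be oriented; left unflipped",
                    stacklevel=2,
                )
            out.append(v)
    return MRDataset(variants=tuple(out), oriented=True)
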