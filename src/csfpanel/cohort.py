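"""Comparison-cohort selection and train/test splitting.

Two comparisons are supported:

* ``affected_vs_unaffected`` -- affected mutation carriers restricted to a
  phenotype whitelist (default bvFTD and PPA, to limit phenotypic
  heterogeneity) versus everyone without symptoms (presymptomatic
  carriers plus non-carriers).
* ``pmc_vs_nc`` -- presymptomatic carriers close to their expected
  symptom onset and with expected TDP-43 pathology (gene-specific minimum
  ages; MAPT and TBK1 carriers excluded) versus age-matched non-carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import GENES, GROUPS

__all__ = [
    "ComparisonConfig",
    "select_comparison_cohort",
    "years_to_expected_onset",
    "SplitResult",
    "stratified_split",
]


@dataclass
class ComparisonConfig:
    name: str = "affected_vs_unaffected"
    phenotype_whitelist: Tuple[str, ...] = ("bvFTD", "PPA")
    # gene -> strict minimum age for PMC inclusion (~10 years to onset)
    pmc_min_age: Dict[str, float] = field(
        default_factory=lambda: {"C9orf72": 48.0, "GRN": 51.0})
    nc_min_age: float = 48.0
    excluded_genes: Tuple[str, ...] = ("MAPT", "TBK1")

    def validate(self) -> None:
        if self.name not in ("affected_vs_unaffected", "pmc_vs_nc"):
            raise ValueError(f"unknown comparison '{self.name}'")
        for g in list(self.pmc_min_age) + list(self.excluded_genes):
            if g not in GENES:
                raise ValueError(f"unknown gene '{g}' in comparison config")
        if any(a < 0 for a in self.pmc_min_age.values()) or self.nc_min_age < 0:
            raise ValueError("minimum ages must be >= 0")


def _check_values(samples: pd.DataFrame) -> None:
    bad_group = ~samples["group"].isin(GROUPS)
    if bad_group.any():
        rows = samples.loc[bad_group, "sample_id"].tolist()
        raise ValueError(f"unknown group value(s) in rows {rows}")
    carriers = samples["group"].isin(("AMC", "PMC"))
    bad_gene = carriers & ~samples["gene"].isin(GENES)
    if bad_gene.any():
        rows = samples.loc[bad_gene, "sample_id"].tolist()
        raise ValueError(f"unknown gene value(s) in rows {rows}")


def select_comparison_cohort(samples: pd.DataFrame,
                             config: ComparisonConfig) -> pd.DataFrame:
    """Apply the comparison's inclusion filters; adds a binary ``label``.

    ``label`` is 1 for the positive class (affected, or PMC) and 0
    otherwise.  Row order of the input is preserved.
    """
    config.validate()
    _check_values(samples)
    if config.name == "affected_vs_unaffected":
        affected = (samples["group"] == "AMC") & samples["phenotype"].isin(
            config.phenotype_whitelist)
        unaffected = samples["group"].isin(("PMC", "NC"))
        out = samples[affected | unaffected].copy()
        out["label"] = affected[affected | unaffected].astype(int).to_numpy()
        return out
    # pmc_vs_nc
    pmc = samples["group"] == "PMC"
    keep_pmc = pmc & ~samples["gene"].isin(config.excluded_genes)
    age_ok = np.zeros(len(samples), bool)
    for gene, min_age in config.pmc_min_age.items():
        age_ok |= ((samples["gene"] == gene) & (samples["age"] > min_age)).to_numpy()
    keep_pmc &= age_ok
    keep_nc = (samples["group"] == "NC") & (samples["age"] > config.nc_min_age)
    out = samples[keep_pmc | keep_nc].copy()
    out["label"] = keep_pmc[keep_pmc | keep_nc].astype(int).to_numpy()
    return out


def years_to_expected_onset(age, gene, onset_means: Dict[str, float]):
    """Gene-level mean onset age minus current age (negative = past it).

    Accepts scalars or aligned sequences of ``age`` and ``gene``.
    """
    if np.isscalar(age) and isinstance(gene, str):
        if gene not in onset_means:
            raise KeyError(f"no mean onset age for gene '{gene}'")
        return onset_means[gene] - age
    age = np.asarray(age, float)
    gene = np.asarray(gene, object)
    missing = sorted({g for g in gene if g not in onset_means})
    if missing:
        raise KeyError(f"no mean onset age for gene(s) {missing}")
    means = np.array([onset_means[g] for g in gene], float)
    return means - age


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_counts: Dict[object, int]
    test_counts: Dict[object, int]


def stratified_split(labels, train_fraction: float = 2 / 3,
                     seed: int = 0) -> SplitResult:
    """Per-class (stratified) random train/test split.

    Each class contributes ``round(class_size * train_fraction)`` samples
    (round half-up) to the training set; deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    tc, sc = {}, {}
    for cls in pd.unique(labels):
        idx = np.where(labels == cls)[0]
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        k = int(np.floor(len(idx) * train_fraction + 0.5))
        train.append(idx[:k])
        test.append(idx[k:])
        tc[cls] = k
        sc[cls] = len(idx) - k
    return SplitResult(
        train_idx=np.sort(np.concatenate(train)).astype(int),
        test_idx=np.sort(np.concatenate(test)).astype(int),
        train_counts=tc, test_counts=sc)
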