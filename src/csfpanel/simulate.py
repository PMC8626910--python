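"""Synthetic genetic-FTD cohorts and bead-array-like CSF protein data.

The generator emulates the structure of a multi-centre genetic
frontotemporal-dementia cohort: three diagnostic groups (affected mutation
carriers AMC, presymptomatic mutation carriers PMC, mutation non-carriers
NC), carrier genes (C9orf72 / GRN / MAPT / TBK1), clinical phenotypes
among the affected, and a 111-protein antibody bead-array readout in
arbitrary units.  Protein signals are strictly positive: log-signal =
baseline + correlated latent + planted group shift + plate offset +
monotone readout drift + noise, then exponentiated.

Every generated dataset carries a :class:`TruthTable` recording the
planted effects and the seed, so downstream selection methods can be
scored against known ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "AssaySpec",
    "TruthTable",
    "generate_cohort",
    "generate_assay",
    "planted_truth",
    "default_panel",
    "write_matrix",
    "read_matrix",
    "write_samples",
    "read_samples",
]

GROUPS = ("AMC", "PMC", "NC")
GENES = ("C9orf72", "GRN", "MAPT", "TBK1")

# Named proteins that appear in published genetic-FTD CSF panel work; the
# remainder of the 111-plex is filled with anonymous bead identities.
_NAMED_PROTEINS = [
    "NEFM", "NPTX2", "VGF", "AQP4", "APOE4", "SEC63", "APOA1", "PTPRN2",
    "CTSS", "SERPINA3", "C4A/B", "AMPH", "SPP1", "CD14", "GRN", "TARDBP",
    "KNG1", "HBEGF", "MBP", "CLSTN1",
]


def default_panel(n_proteins: int = 111) -> List[str]:
    """Protein identifiers for the simulated assay (named + filler beads)."""
    if n_proteins < len(_NAMED_PROTEINS):
        return _NAMED_PROTEINS[:n_proteins]
    fillers = [f"PROT{i:03d}" for i in range(1, n_proteins - len(_NAMED_PROTEINS) + 1)]
    return _NAMED_PROTEINS + fillers


@dataclass
class CohortSpec:
    """Cohort composition: group sizes, gene and phenotype splits, ages, sex.

    Defaults reproduce a 221-sample genetic-FTD cohort: 47 AMC / 98 PMC /
    76 NC, with the gene and phenotype breakdown and group-wise age
    distributions (truncated normals) of that design.  ``onset_means`` are
    gene-level mean ages at symptom onset used to derive years-to-expected
    -onset for presymptomatic carriers.
    """

    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {"AMC": 47, "PMC": 98, "NC": 76})
    gene_split: Dict[str, Dict[str, int]] = field(default_factory=lambda: {
        "AMC": {"C9orf72": 27, "GRN": 12, "MAPT": 7, "TBK1": 1},
        "PMC": {"C9orf72": 41, "GRN": 38, "MAPT": 16, "TBK1": 3},
    })
    phenotype_split: Dict[str, int] = field(default_factory=lambda: {
        "bvFTD": 32, "PPA": 7, "ALS": 4, "FTD-ALS": 1, "PSP": 2, "D-NOS": 1})
    # mean, SD, low, high (years)
    age_params: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "AMC": (62.0, 9.0, 38.0, 76.0),
            "PMC": (46.0, 12.0, 20.0, 74.0),
            "NC": (47.0, 13.0, 20.0, 69.0),
        })
    sex_female_fraction: Dict[str, float] = field(default_factory=lambda: {
        "AMC": 20 / 47, "PMC": 58 / 98, "NC": 41 / 76})
    onset_means: Dict[str, float] = field(default_factory=lambda: {
        "C9orf72": 58.0, "GRN": 61.0, "MAPT": 49.0})
    seed: int = 0

    def validate(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group '{g}' in group_sizes")
            if self.group_sizes[g] < 0:
                raise ValueError(f"group_sizes[{g}] is negative")
        for grp, split in self.gene_split.items():
            bad = set(split) - set(GENES)
            if bad:
                raise ValueError(f"gene_split[{grp}] has unknown genes {sorted(bad)}")
            tot = sum(split.values())
            if tot != self.group_sizes.get(grp, 0):
                raise ValueError(
                    f"gene_split[{grp}] sums to {tot}, expected "
                    f"group_sizes[{grp}] = {self.group_sizes.get(grp, 0)}")
        ptot = sum(self.phenotype_split.values())
        if ptot != self.group_sizes.get("AMC", 0):
            raise ValueError(
                f"phenotype_split sums to {ptot}, expected group_sizes[AMC] = "
                f"{self.group_sizes.get('AMC', 0)}")
        for g, (mu, sd, lo, hi) in self.age_params.items():
            if not lo < hi:
                raise ValueError(f"age_params[{g}]: empty range [{lo}, {hi}]")
            if sd <= 0:
                raise ValueError(f"age_params[{g}]: SD must be positive")


@dataclass
class EffectSpec:
    """Planted group effects and latent correlation structure.

    ``planted_effects`` maps a contrast name to per-protein shifts in
    latent-SD units; the contrast defines which samples receive the shift
    ("affected": AMC; "grn_carrier": GRN mutation carriers).
    ``correlation_blocks`` impose a common pairwise latent correlation
    within each named protein set (single shared factor).
    """

    panel: List[str] = field(default_factory=default_panel)
    planted_effects: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "affected": {"NEFM": 2.1, "AQP4": 1.8, "NPTX2": -1.9, "VGF": -1.8},
        "grn_carrier": {"GRN": -2.0},
    })
    correlation_blocks: List[Tuple[List[str], float]] = field(default_factory=lambda: [
        (["NPTX2", "VGF", "PTPRN2"], 0.55),
        (["AQP4", "AMPH"], 0.55),
        (["SERPINA3", "APOA1", "CD14", "C4A/B"], 0.7),
    ])
    baseline_log_mean: Dict[str, float] | float | None = None
    baseline_log_sd: Dict[str, float] | float = 0.3

    def validate(self) -> None:
        pset = set(self.panel)
        for contrast, shifts in self.planted_effects.items():
            if contrast not in CONTRASTS:
                raise ValueError(f"unknown contrast '{contrast}'")
            missing = set(shifts) - pset
            if missing:
                raise ValueError(
                    f"planted proteins {sorted(missing)} absent from panel")
        for k, (block, rho) in enumerate(self.correlation_blocks):
            if abs(rho) > 1:
                raise ValueError(f"block {k} ({block[:3]}...): |rho| > 1")
            m = len(block)
            # equicorrelation matrix is PSD iff rho >= -1/(m-1)
            if m > 1 and rho < -1.0 / (m - 1):
                raise ValueError(
                    f"block {k} ({block}): common rho {rho} makes the "
                    f"correlation matrix non-positive-semi-definite")
            missing = set(block) - pset
            if missing:
                raise ValueError(f"block {k}: proteins {sorted(missing)} not in panel")

    def baseline_mean_vector(self) -> np.ndarray:
        p = len(self.panel)
        if self.baseline_log_mean is None:
            # deterministic spread of baseline abundances (log AU)
            return 5.5 + 3.0 * (np.arange(p) % 17) / 16.0
        if np.isscalar(self.baseline_log_mean):
            return np.full(p, float(self.baseline_log_mean))
        return np.array([self.baseline_log_mean[pr] for pr in self.panel], float)

    def baseline_sd_vector(self) -> np.ndarray:
        p = len(self.panel)
        if np.isscalar(self.baseline_log_sd):
            return np.full(p, float(self.baseline_log_sd))
        return np.array([self.baseline_log_sd[pr] for pr in self.panel], float)


@dataclass
class AssaySpec:
    """Technical artefact model: plates, readout drift, noise."""

    n_plates: int = 3
    plate_offset_sd: float = 0.1  # log-scale SD of per plate x protein offsets
    drift_slope: float = 0.3      # log-units across the readout-order range
    noise_sd: float = 0.1         # log-scale measurement noise
    randomization: bool = True    # constrained (stratified) plate assignment

    def validate(self) -> None:
        for name in ("plate_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")


@dataclass
class TruthTable:
    """Ground truth persisted with every generated dataset."""

    planted: List[Dict]          # records: protein, contrast, shift
    correlation_blocks: List[Tuple[List[str], float]]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        d["correlation_blocks"] = [
            (list(b), float(r)) for b, r in d["correlation_blocks"]]
        return cls(**d)


# contrast name -> boolean mask over a sample table
CONTRASTS = {
    "affected": lambda s: (s["group"] == "AMC").to_numpy(),
    "grn_carrier": lambda s: (s["gene"] == "GRN").to_numpy(),
}


def _truncnorm_location(mean: float, sd: float, lo: float, hi: float) -> float:
    """Parent-normal location whose [lo, hi]-truncated mean equals ``mean``.

    Truncation pulls the realized mean away from the parent location, so
    the location is calibrated numerically; this makes the generated group
    means match the configured (printed) cohort means.
    """

    def realized(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

    span = hi - lo
    return optimize.brentq(realized, lo - span, hi + span, xtol=1e-10)


def _sample_ages(rng: np.random.Generator, n: int, mean, sd, lo, hi) -> np.ndarray:
    mu = _truncnorm_location(mean, sd, lo, hi)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a sample-annotation table from a cohort specification.

    Returns one row per sample with columns ``sample_id, group, gene,
    phenotype, age, sex``; deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        genes = []
        if group in spec.gene_split:
            for gene, cnt in spec.gene_split[group].items():
                genes += [gene] * cnt
        else:
            genes = ["none"] * n
        genes = list(rng.permutation(genes))
        phenos = ["" for _ in range(n)]
        if group == "AMC":
            ph = []
            for name, cnt in spec.phenotype_split.items():
                ph += [name] * cnt
            phenos = list(rng.permutation(ph))
        mu, sd, lo, hi = spec.age_params[group]
        ages = _sample_ages(rng, n, mu, sd, lo, hi)
        n_f = int(np.floor(spec.sex_female_fraction.get(group, 0.5) * n + 0.5))
        sexes = list(rng.permutation(["F"] * n_f + ["M"] * (n - n_f)))
        for i in range(n):
            rows.append({
                "sample_id": f"{group}_{i + 1:03d}",
                "group": group,
                "gene": genes[i],
                "phenotype": phenos[i],
                "age": float(ages[i]),
                "sex": sexes[i],
            })
    cols = ["sample_id", "group", "gene", "phenotype", "age", "sex"]
    return pd.DataFrame(rows, columns=cols)


def _assign_plates(samples: pd.DataFrame, n_plates: int, constrained: bool,
                   rng: np.random.Generator) -> np.ndarray:
    n = len(samples)
    if not constrained:
        return rng.permutation(np.arange(n) % n_plates) + 1
    # constrained randomization: stratify by group, sex and age tertile,
    # then deal each stratum across plates in shuffled round-robin order
    age_tert = pd.qcut(samples["age"], 3, labels=False, duplicates="drop")
    strata = (samples["group"].astype(str) + "|" + samples["sex"].astype(str)
              + "|" + age_tert.astype(str))
    plates = np.zeros(n, int)
    start = 0
    for _, idx in strata.groupby(strata).groups.items():
        members = rng.permutation(np.asarray(idx))
        for j, s in enumerate(members):
            plates[samples.index.get_loc(s)] = (start + j) % n_plates + 1
        start += len(members)
    return plates


def generate_assay(samples: pd.DataFrame, effects: EffectSpec, assay: AssaySpec,
                   seed: int = 0) -> Tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate the bead-array signal matrix for a cohort.

    Returns ``(matrix, annotated_samples, truth)`` where ``matrix`` is the
    samples x proteins signal-intensity table (strictly positive, arbitrary
    units) and ``annotated_samples`` extends the input annotations with
    ``plate`` and ``readout_order`` columns.  One RNG stream, seeded by
    ``seed``, drives the whole dataset.
    """
    if len(samples) == 0:
        raise ValueError("samples is empty")
    effects.validate()
    assay.validate()
    rng = np.random.default_rng(seed)
    n = len(samples)
    panel = effects.panel
    p = len(panel)
    col = {pr: j for j, pr in enumerate(panel)}

    Z = rng.standard_normal((n, p))
    for block, rho in effects.correlation_blocks:
        if rho <= 0:
            continue
        shared = rng.standard_normal(n)
        jidx = [col[pr] for pr in block]
        Z[:, jidx] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * Z[:, jidx]

    planted_records = []
    for contrast, shifts in effects.planted_effects.items():
        mask = CONTRASTS[contrast](samples)
        for pr, shift in shifts.items():
            if shift != 0.0:
                Z[mask, col[pr]] += shift
                planted_records.append(
                    {"protein": pr, "contrast": contrast, "shift": float(shift)})

    readout_order = rng.permutation(n) + 1  # 1..n
    plates = _assign_plates(samples, assay.n_plates, assay.randomization, rng)
    plate_offsets = rng.normal(0.0, assay.plate_offset_sd,
                               size=(assay.n_plates, p)) if assay.plate_offset_sd > 0 \
        else np.zeros((assay.n_plates, p))

    base_mu = effects.baseline_mean_vector()
    base_sd = effects.baseline_sd_vector()
    quantile = (readout_order - 1) / max(n - 1, 1)
    log_signal = (base_mu[None, :] + base_sd[None, :] * Z
                  + plate_offsets[plates - 1, :]
                  + assay.drift_slope * quantile[:, None])
    if assay.noise_sd > 0:
        log_signal = log_signal + rng.normal(0.0, assay.noise_sd, size=(n, p))

    matrix = pd.DataFrame(np.exp(log_signal), index=samples["sample_id"].to_numpy(),
                          columns=panel)
    matrix.index.name = "sample_id"
    annotated = samples.copy()
    annotated["plate"] = plates
    annotated["readout_order"] = readout_order
    truth = TruthTable(planted=planted_records,
                       correlation_blocks=[(list(b), float(r))
                                           for b, r in effects.correlation_blocks],
                       seed=int(seed))
    return matrix, annotated, truth


def planted_truth(truth: TruthTable, contrast: str = "affected") -> List[str]:
    """Proteins with a nonzero planted shift for ``contrast`` (sorted)."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast '{contrast}'; "
                         f"known: {sorted(CONTRASTS)}")
    return sorted({rec["protein"] for rec in truth.planted
                   if rec["contrast"] == contrast and rec["shift"] != 0.0})


# ---------------------------------------------------------------------------
# round-tripping writers / readers (TSV for tables, JSON for truth)

def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.hasnans or m.columns.hasnans:
        raise ValueError("matrix has missing sample or protein identifiers")
    return m


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[], dtype={"phenotype": str, "gene": str})
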