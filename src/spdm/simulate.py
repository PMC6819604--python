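"""Synthetic compositional cohorts with a planted aging-like progression.

The generator emulates the structure of a cross-sectional 16S genus count
study spanning infancy to extreme old age: G ordered age groups, a dozen
samples per group, a few hundred genera, per-sample sequencing depth drawn
from a Gaussian, and a minority of "progression" genera whose group-level
log-abundance follows a smooth trajectory along the group order — either a
monotone logistic rise or a unimodal rise-then-fall bump (a late peak gives
the sharp drop in the oldest groups seen in real aging cohorts).  The
remaining background genera have order-free constant log-means.

Per-sample log-abundance adds Gaussian noise to the group log-mean; the
exponentiated vector is renormalized to a composition and counts are drawn
multinomially at the sample's depth.  Ages are drawn inside each group's
age interval so that re-binning the ages with the default age grouping
reproduces the planted groups exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import DEFAULT_AGE_GROUPING, AgeGrouping

__all__ = ["SyntheticCohortSpec", "SyntheticCohort", "generate_cohort", "worked_fixture"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror a real aging cohort: 14 age groups, ~12 samples per
    group, 240 genera of which 35 track the progression, a quarter of those
    monotone and the rest rise-then-fall, and sequencing depth 8734±2748
    reads truncated below at 1000.  ``noise_sd`` is the per-sample
    log-abundance standard deviation.
    """

    n_groups: int = 14
    samples_per_group: int | tuple[int, ...] = 12
    n_features: int = 240
    n_progression: int = 35
    monotone_fraction: float = 0.25
    depth_mean: float = 8734.0
    depth_sd: float = 2748.0
    depth_min: int = 1000
    noise_sd: float = 0.3
    seed: int = 0

    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_group, int):
            return (self.samples_per_group,) * self.n_groups
        sizes = tuple(self.samples_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("samples_per_group list must have n_groups entries")
        return sizes

    def validate(self) -> None:
        if self.n_progression > self.n_features:
            raise ValueError("n_progression cannot exceed n_features")
        if not 0 <= self.monotone_fraction <= 1:
            raise ValueError("monotone_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(s < 1 for s in self.group_sizes()):
            raise ValueError("every group needs at least one sample")


@dataclass
class SyntheticCohort:
    """Counts, metadata and the ground truth that generated them."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict

    @property
    def true_ordering(self) -> tuple[int, ...]:
        return tuple(self.truth["ordering"])


def _draw_age(group: int, grouping: AgeGrouping, rng: np.random.Generator) -> float:
    lo, hi = grouping.boundaries[group - 1]
    if math.isinf(hi):
        # centenarian bracket: the field's cohorts top out around 110
        return float(rng.uniform(100.0, 110.0))
    u = rng.uniform(0.0, 1.0)
    age = lo + (1.0 - u) * (hi - lo)  # in (lo, hi]
    return float(min(age, hi))


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a cohort from ``spec``; bit-reproducible given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G, p = spec.n_groups, spec.n_features
    sizes = spec.group_sizes()
    t = np.linspace(0.0, 1.0, G)  # latent progression positions per group

    feature_ids = [f"g{j+1:03d}" for j in range(p)]
    prog_idx = np.sort(rng.choice(p, size=spec.n_progression, replace=False))
    n_mono = int(round(spec.monotone_fraction * spec.n_progression))

    # group-level log-mean trajectories, features x groups
    log_means = np.tile(rng.normal(0.0, 2.0, size=p)[:, None], (1, G))
    traj_params: dict[str, dict] = {}
    # progression genera are minor community members: a low baseline keeps
    # their combined share small, so the compositional denominator does not
    # imprint the trajectory onto every background genus
    for rank, j in enumerate(prog_idx):
        base = rng.normal(-2.0, 1.0)
        amp = rng.uniform(2.0, 4.0)
        if rank < n_mono:
            k = rng.uniform(4.0, 10.0)
            t0 = rng.uniform(0.2, 0.8)
            log_means[j] = base + amp / (1.0 + np.exp(-k * (t - t0)))
            traj_params[feature_ids[j]] = {
                "shape": "monotone", "base": base, "amplitude": amp, "k": k, "t0": t0,
            }
        else:
            t0 = rng.uniform(0.3, 0.9)
            w = rng.uniform(0.1, 0.25)
            log_means[j] = base + amp * np.exp(-((t - t0) ** 2) / (2 * w**2))
            traj_params[feature_ids[j]] = {
                "shape": "unimodal", "base": base, "amplitude": amp, "t0": t0, "width": w,
            }

    sample_ids, ages, sexes, group_ids = [], [], [], []
    count_rows = []
    for g in range(1, G + 1):
        for s in range(sizes[g - 1]):
            sample_ids.append(f"s{g:02d}_{s+1:02d}")
            group_ids.append(g)
            ages.append(_draw_age(g, DEFAULT_AGE_GROUPING, rng))
            sexes.append("F" if rng.uniform() < 0.5 else "M")
            logab = log_means[:, g - 1] + rng.normal(0.0, spec.noise_sd, size=p)
            comp = np.exp(logab - logab.max())
            comp /= comp.sum()
            depth = max(spec.depth_min, int(round(rng.normal(spec.depth_mean, spec.depth_sd))))
            count_rows.append(rng.multinomial(depth, comp))

    counts = pd.DataFrame(np.asarray(count_rows), index=sample_ids, columns=feature_ids)
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "age": ages, "sex": sexes, "true_group": group_ids},
        index=pd.Index(sample_ids, name=None),
    )
    truth = {
        "spec": asdict(spec),
        "ordering": list(range(1, G + 1)),
        "progression_features": [feature_ids[j] for j in prog_idx],
        "trajectories": traj_params,
        "group_log_means": log_means.tolist(),
    }
    return SyntheticCohort(counts=counts, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# Hand-checkable worked fixture
# ---------------------------------------------------------------------------

# 5 groups x 6 features; every row (group) sums to 24, so with depths that
# are multiples of 24 the counts below are exact integers and every sample
# in a group shares the group's composition.  Feature roles:
#   inc  [1..5]/24  strictly increasing  -> its MST is the path 1-2-3-4-5
#   dec  [5..1]/24  strictly decreasing
#   bump / dip      unimodal / anti-unimodal
#   bg1, bg2        constant (fit no ordering better than chance)
_FIXTURE_WEIGHTS = np.array(
    [
        # inc dec bump dip bg1 bg2   (bump is deliberately asymmetric so no
        # two groups coincide in the joint inc/dec/bump/dip space)
        [1, 5, 1, 5, 4, 8],
        [2, 4, 4, 2, 4, 8],
        [3, 3, 5, 1, 4, 8],
        [4, 2, 3, 3, 4, 8],
        [5, 1, 1, 5, 4, 8],
    ],
    dtype=float,
)
_FIXTURE_FEATURES = ["inc", "dec", "bump", "dip", "bg1", "bg2"]
_FIXTURE_DEPTHS = (2400, 4800, 7200)  # multiples of the row sum 24
# ages land in the first five default age bins, so re-binning the ages
# reproduces planted groups 1..5
_FIXTURE_AGES = {1: 0.3, 2: 1.0, 3: 2.0, 4: 5.0, 5: 15.0}


def worked_fixture() -> SyntheticCohort:
    """Deterministic 5-group x 6-feature x 3-samples-per-group cohort.

    Built without randomness: each sample's counts are its depth times the
    group composition (exact integers by construction), so the group mean
    relative abundances equal the planted compositions and every per-feature
    MST can be checked by hand.
    """
    comp = _FIXTURE_WEIGHTS / _FIXTURE_WEIGHTS.sum(axis=1, keepdims=True)
    sample_ids, rows, ages, groups = [], [], [], []
    for g in range(1, 6):
        for s, depth in enumerate(_FIXTURE_DEPTHS, start=1):
            sample_ids.append(f"wf{g}_{s}")
            rows.append(np.round(depth * comp[g - 1]).astype(np.int64))
            ages.append(_FIXTURE_AGES[g])
            groups.append(g)
    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=_FIXTURE_FEATURES)
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "age": ages, "sex": ["F", "M", "F"] * 5, "true_group": groups},
        index=pd.Index(sample_ids, name=None),
    )
    truth = {
        "ordering": [1, 2, 3, 4, 5],
        "progression_features": ["inc", "dec", "bump", "dip"],
        "trajectories": {},
        "compositions": comp.tolist(),
    }
    return SyntheticCohort(counts=counts, metadata=metadata, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, header: str = "") -> None:
    """Write counts.tsv, metadata.tsv and truth.json for a cohort."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in (("counts.tsv", cohort.counts), ("metadata.tsv", cohort.metadata)):
        with open(outdir / name, "w") as fh:
            if header:
                fh.write(header)
            if name == "counts.tsv":
                df.to_csv(fh, sep="\t", index_label="sample_id")
            else:
                df.to_csv(fh, sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
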