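"""Synthetic LFQ matrices with known ground truth.

Emulates the statistical structure of a proximity-labelling LFQ experiment:
a log-normal background proteome, bait-specific interactors elevated only in
their bait samples, bystander proteins elevated in both bait and free-ligase
(eYFP) control samples, Gaussian replicate noise on the log2 scale, and
left-censored missingness whose probability decreases logistically with true
log2 intensity — the structure that downshifted-normal imputation targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lfq_io import LfqMatrix, SampleDesign, SampleInfo, write_table

__all__ = [
    "IntensityMissing",
    "SimTruth",
    "default_design",
    "simulate_lfq",
    "write_truth",
]


@dataclass(frozen=True)
class IntensityMissing:
    """Logistic left-censoring model: P(missing | x) = 1/(1+exp(steepness*(x-midpoint))).

    ``x`` is the true (pre-noise) log2 intensity; the probability decreases
    monotonically with intensity, so low-abundance proteins are censored
    preferentially, and raising ``midpoint`` raises the marginal missing rate.
    """

    steepness: float = 0.8
    midpoint: float = 22.0

    def prob(self, log2_intensity: np.ndarray) -> np.ndarray:
        z = self.steepness * (np.asarray(log2_intensity, dtype=float) - self.midpoint)
        return 1.0 / (1.0 + np.exp(z))


@dataclass
class SimTruth:
    """Ground-truth roles behind a simulated matrix.

    ``roles`` columns: ``role`` (background / interactor / bystander),
    ``baits`` (comma-joined experiments an interactor responds to),
    ``effect`` (planted log2 elevation) and ``base`` (baseline log2
    intensity).
    """

    roles: pd.DataFrame
    missing_prob: pd.DataFrame | None = None

    @property
    def interactors(self) -> set[str]:
        return set(self.roles.index[self.roles["role"] == "interactor"])

    @property
    def bystanders(self) -> set[str]:
        return set(self.roles.index[self.roles["role"] == "bystander"])

    @property
    def background(self) -> set[str]:
        return set(self.roles.index[self.roles["role"] == "background"])


def default_design(
    experiments: Sequence[str] = ("bait1",),
    n_replicates: int = 3,
    include_eyfp: bool = True,
) -> SampleDesign:
    """Triplicate bait group(s) plus parental and (optionally) eYFP controls."""
    samples: dict[str, SampleInfo] = {}
    for exp in experiments:
        for r in range(1, n_replicates + 1):
            samples[f"{exp}_{r}"] = SampleInfo(exp, "bait", r)
    for r in range(1, n_replicates + 1):
        samples[f"wt_{r}"] = SampleInfo("control", "wt_control", r)
    if include_eyfp:
        for r in range(1, n_replicates + 1):
            samples[f"eyfp_{r}"] = SampleInfo("control", "eyfp_control", r)
    return SampleDesign(samples)


def simulate_lfq(
    design: SampleDesign | None = None,
    n_proteins: int = 1500,
    n_interactors: int = 20,
    effect: float = 4.0,
    bystander_frac: float = 0.05,
    noise_sd: float = 0.4,
    missing_model: IntensityMissing | None = None,
    interactor_baits: Sequence[str] | None = None,
    base_mean: float = 26.0,
    base_sd: float = 2.0,
    seed: int | None = None,
) -> tuple[LfqMatrix, SimTruth]:
    """Simulate a raw (linear-scale) LFQ matrix with known ground truth.

    Baseline log2 intensities are Normal(``base_mean``, ``base_sd``) per
    protein (a log-normal proteome on the linear scale). ``n_interactors``
    proteins are elevated by ``effect`` log2 units in the samples of their
    bait experiment(s) only; ``round(bystander_frac * n_proteins)`` further
    proteins are elevated by ``effect`` in bait *and* eYFP-control samples,
    mimicking non-specific labelling by the free ligase. Gaussian noise of
    ``noise_sd`` log2 units is added per cell. With an
    :class:`IntensityMissing` model, each cell is censored with the logistic
    probability of its true (pre-noise) log2 value. The returned matrix is on
    the linear intensity scale (not yet log-transformed), as a protein-groups
    reader would deliver it.
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)

    bait_experiments = design.experiments("bait")
    if not design.by_group("wt_control"):
        raise ValueError("design lacks a wt_control group")
    if not bait_experiments:
        raise ValueError("design lacks bait samples")
    if n_proteins <= 0 or n_interactors < 0 or effect < 0:
        raise ValueError("counts must be positive and effect non-negative")
    targets = list(interactor_baits) if interactor_baits is not None else bait_experiments

    sample_names = design.names
    n_samples = len(sample_names)
    n_bystanders = int(round(bystander_frac * n_proteins))
    if n_interactors + n_bystanders > n_proteins:
        raise ValueError("more interactors + bystanders than proteins")

    protein_ids = [f"SIM{i:05d}" for i in range(n_proteins)]
    base = rng.normal(base_mean, base_sd, size=n_proteins)

    roles = np.array(["background"] * n_proteins, dtype=object)
    special = rng.choice(n_proteins, size=n_interactors + n_bystanders, replace=False)
    idx_int, idx_by = special[:n_interactors], special[n_interactors:]
    roles[idx_int] = "interactor"
    roles[idx_by] = "bystander"

    # expected log2 value per cell before replicate noise
    expected = np.tile(base[:, None], (1, n_samples))
    for j, name in enumerate(sample_names):
        info = design.samples[name]
        if info.group == "bait" and info.experiment in targets:
            expected[idx_int, j] += effect
        if info.group in ("bait", "eyfp_control"):
            expected[idx_by, j] += effect

    log2_values = expected + rng.normal(0.0, noise_sd, size=expected.shape)

    missing_prob = None
    if missing_model is not None:
        prob = missing_model.prob(expected)
        censored = rng.random(size=prob.shape) < prob
        log2_values[censored] = np.nan
        missing_prob = pd.DataFrame(prob, index=protein_ids, columns=sample_names)

    values = pd.DataFrame(
        np.exp2(log2_values), index=pd.Index(protein_ids, name="protein_id"),
        columns=sample_names,
    )
    matrix = LfqMatrix(values=values, log_transformed=False)

    truth_roles = pd.DataFrame(
        {
            "role": roles,
            "baits": [",".join(targets) if r == "interactor"
                      else (",".join(bait_experiments) if r == "bystander" else "")
                      for r in roles],
            "effect": [effect if r != "background" else 0.0 for r in roles],
            "base": base,
        },
        index=values.index,
    )
    return matrix, SimTruth(roles=truth_roles, missing_prob=missing_prob)


def write_truth(truth: SimTruth, path) -> None:
    write_table(truth.roles, path)
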