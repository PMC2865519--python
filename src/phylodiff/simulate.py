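"""Synthetic expression data with a planted differentiation trajectory.

The generator emulates the structure the analysis assumes in real data:
log2-scale group means with Gaussian sample noise, a root outgroup (stem
cells) at trajectory position t = 0, K tumor subtypes at interior
positions, and a fully differentiated reference at t = 1.  Three gene
classes are planted:

* monotone genes -- group mean a_g + t_k * Delta_g, with Delta_g drawn
  uniformly from +/- the effect range (log2 units); these carry the
  differentiation signal and should end up in monotone profile clusters;
* spike genes -- baseline plus an offset in one randomly chosen subtype,
  mirroring subtype-specific overexpression that profile clustering must
  reject as non-monotone;
* null genes -- constant mean, pure noise; these calibrate the false
  discovery rate of the differential-expression filter.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    DIFFERENTIATED_REFERENCE,
    ROOT_OUTGROUP,
    SUBTYPE,
    ExpressionMatrix,
    GroupAnnotation,
)

__all__ = ["GroundTruth", "SimulationSpec", "simulate_dataset"]


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic generator.

    Defaults: 2000 genes of which 60% null and 10% subtype-specific
    spikes, K = 5 subtypes with 10 samples per group, effect sizes of 2-4
    log2 units across the full trajectory, and noise sd 0.5 log2 units —
    the scale of between-replicate variation typical of RMA-normalized
    arrays.
    """

    n_genes: int = 2000
    fraction_null: float = 0.6
    fraction_spike: float = 0.1
    n_subtypes: int = 5
    samples_per_group: int = 10
    effect_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    trajectory: list[float] | None = None  # subtype positions in (0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must lie in [0, 1]")
        if not 0.0 <= self.fraction_spike <= 1.0:
            raise ValueError("fraction_spike must lie in [0, 1]")
        if self.fraction_null + self.fraction_spike > 1.0:
            raise ValueError("fraction_null + fraction_spike must be <= 1")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be > 0")
        if self.n_subtypes < 2:
            raise ValueError("need at least 2 subtypes")
        if self.samples_per_group < 1:
            raise ValueError("need at least 1 sample per group")
        if self.effect_range[0] < 0 or self.effect_range[0] > self.effect_range[1]:
            raise ValueError("effect_range must be 0 <= low <= high")
        if self.trajectory is not None:
            t = list(self.trajectory)
            if len(t) != self.n_subtypes or any(
                not 0.0 < v < 1.0 for v in t
            ) or sorted(t) != t or len(set(t)) != len(t):
                raise ValueError(
                    "trajectory must be strictly increasing subtype positions in (0, 1)"
                )

    @property
    def positions(self) -> np.ndarray:
        """Trajectory positions for root, subtypes and reference (strictly increasing)."""
        if self.trajectory is not None:
            inner = np.asarray(self.trajectory, dtype=float)
        else:
            inner = np.arange(1, self.n_subtypes + 1) / (self.n_subtypes + 1)
        return np.concatenate([[0.0], inner, [1.0]])


@dataclass
class GroundTruth:
    planted_order: list[str]  # subtypes from least to most differentiated
    genes: pd.DataFrame = field(repr=False)  # gene_id, klass, delta, spike_group

    def genes_of_class(self, klass: str) -> list[str]:
        return list(self.genes.loc[self.genes["klass"] == klass, "gene_id"])


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, GroupAnnotation, GroundTruth]:
    """Generate (expression matrix, annotation, ground truth) from the spec."""
    rng = np.random.default_rng(spec.seed)
    K = spec.n_subtypes
    groups = ["ROOT"] + [f"S{k}" for k in range(1, K + 1)] + ["REF"]
    roles = (
        {"ROOT": ROOT_OUTGROUP}
        | {f"S{k}": SUBTYPE for k in range(1, K + 1)}
        | {"REF": DIFFERENTIATED_REFERENCE}
    )
    t = spec.positions  # len K + 2

    G = spec.n_genes
    n_null = int(round(spec.fraction_null * G))
    n_spike = int(round(spec.fraction_spike * G))
    n_mono = G - n_null - n_spike
    klass = np.array(["monotone"] * n_mono + ["spike"] * n_spike + ["null"] * n_null)

    baseline = rng.uniform(*spec.baseline_range, size=G)
    group_means = np.tile(baseline[:, None], (1, K + 2))

    sign = rng.choice([-1.0, 1.0], size=n_mono)
    magnitude = rng.uniform(*spec.effect_range, size=n_mono)
    delta = np.zeros(G)
    delta[:n_mono] = sign * magnitude
    group_means[:n_mono] += delta[:n_mono, None] * t[None, :]

    spike_group = np.array([""] * G, dtype=object)
    if n_spike:
        which = rng.integers(1, K + 1, size=n_spike)  # subtype index 1..K
        spike_sign = rng.choice([-1.0, 1.0], size=n_spike)
        spike_mag = rng.uniform(*spec.effect_range, size=n_spike)
        for row, (k, s, mgt) in enumerate(zip(which, spike_sign, spike_mag)):
            group_means[n_mono + row, k] += s * mgt
            spike_group[n_mono + row] = f"S{k}"

    n_per = spec.samples_per_group
    sample_ids: list[str] = []
    sample_to_group: dict[str, str] = {}
    columns = []
    for gi, group in enumerate(groups):
        noise = rng.normal(0.0, spec.noise_sd, size=(G, n_per))
        columns.append(group_means[:, gi : gi + 1] + noise)
        for s in range(1, n_per + 1):
            sid = f"{group}_{s}"
            sample_ids.append(sid)
            sample_to_group[sid] = group

    gene_ids = [f"G{i+1:05d}" for i in range(G)]
    frame = pd.DataFrame(np.hstack(columns), index=gene_ids, columns=sample_ids)
    truth = GroundTruth(
        planted_order=[f"S{k}" for k in range(1, K + 1)],
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "klass": klass,
                "delta": delta,
                "spike_group": spike_group,
            }
        ),
    )
    return ExpressionMatrix(frame), GroupAnnotation(sample_to_group, roles), truth
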